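"""Sub-OTU unpacking and Jukes-Cantor / neighbor-joining phylogenetics.

An annotation-binned OTU can hide several distinguishable amplicons.
Unpacking splits an OTU's distinct member sequences into sub-OTUs: two
sequences belong together only when their supporting-accession sets
intersect, and the sub-OTU relation is the transitive closure of that
pairwise sharing (connected components), so sub-OTUs partition the OTU and
carry pairwise-disjoint accession sets.  Sub-OTU representatives are then
placed on a neighbor-joining tree under Jukes-Cantor distances together
with "spike" reference sequences from isolated/cultured relatives, with
bootstrap support over alignment columns, exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode

from .binning import OTU
from .errors import ArgumentError, ConsistencyError, SaturationError

GAP_CHARS = frozenset("-.")


@dataclass
class SubOTU:
    parent_otu_id: str
    subotu_id: str  # parent + " seqN", seq1 the most abundant
    member_reads: list[str]
    representative: str  # most frequent exact member sequence
    accession_set: frozenset[str]


def unpack_otu(
    otu: OTU,
    read_sequences: Mapping[str, str],
    filtered_hits: Mapping[str, frozenset[str] | set[str]] | None = None,
) -> list[SubOTU]:
    """Split an OTU into sub-OTUs by shared supporting accessions.

    Builds a graph over the OTU's distinct member sequences with an edge
    whenever two sequences' accession sets intersect; connected components
    become sub-OTUs, numbered ``seq1, seq2, ...`` by descending member
    count.  ``filtered_hits`` overrides the OTU's own accession registry
    (read_id -> accession set).
    """
    registry = filtered_hits if filtered_hits is not None else otu.accession_registry
    members = [r for reads in otu.member_reads.values() for r in reads]
    seq_reads: dict[str, list[str]] = {}
    seq_accessions: dict[str, set[str]] = {}
    for read_id in members:
        accs = registry.get(read_id)
        if not accs:
            raise ConsistencyError(
                f"member read {read_id!r} of {otu.otu_id} has no supporting accessions"
            )
        seq = read_sequences[read_id]
        seq_reads.setdefault(seq, []).append(read_id)
        seq_accessions.setdefault(seq, set()).update(accs)

    graph = nx.Graph()
    graph.add_nodes_from(seq_reads)
    seqs = sorted(seq_reads)
    for i, s1 in enumerate(seqs):
        for s2 in seqs[i + 1:]:
            if seq_accessions[s1] & seq_accessions[s2]:
                graph.add_edge(s1, s2)

    components = sorted(
        nx.connected_components(graph),
        key=lambda comp: (-sum(len(seq_reads[s]) for s in comp), min(comp)),
    )
    subotus = []
    for rank, comp in enumerate(components, start=1):
        reads = sorted(r for s in comp for r in seq_reads[s])
        representative = max(comp, key=lambda s: (len(seq_reads[s]), s))
        accessions = frozenset().union(*(seq_accessions[s] for s in comp))
        subotus.append(
            SubOTU(
                parent_otu_id=otu.otu_id,
                subotu_id=f"{otu.otu_id} seq{rank}",
                member_reads=reads,
                representative=representative,
                accession_set=accessions,
            )
        )
    return subotus


# ------------------------------------------------------------ JC distances

def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) with pairwise deletion.

    p is the mismatch proportion over columns where both sequences carry a
    base; p >= 0.75 is beyond the model's saturation bound and raises.
    """
    if len(seq_a) != len(seq_b):
        raise ArgumentError("sequences must have equal (aligned) lengths")
    compared = mismatches = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ArgumentError("no comparable (both-base) columns")
    p = mismatches / compared
    if p >= 0.75:
        raise SaturationError(f"mismatch proportion {p:.3f} >= 0.75 saturates JC")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def _alignment_matrix(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(alignment[lab]) for lab in labels}
    if len(lengths) != 1:
        raise ArgumentError("alignment is ragged: sequences differ in length")
    mat = np.stack(
        [np.frombuffer(alignment[lab].upper().encode("ascii"), dtype=np.uint8)
         for lab in labels]
    )
    return labels, mat


def jc_distance_matrix(
    alignment: Mapping[str, str], saturation_cap: bool = False
) -> DistanceMatrix:
    """All-pairs JC distances of an aligned set of sequences.

    With ``saturation_cap`` mismatch proportions at or beyond 0.75 are
    clamped just below the bound instead of raising (used inside bootstrap
    replicates, where resampled columns can transiently saturate).
    """
    labels, mat = _alignment_matrix(alignment)
    gap = np.isin(mat, np.frombuffer(b"-.", dtype=np.uint8))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ArgumentError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((mat[i, ok] != mat[j, ok]).mean())
            if p >= 0.75:
                if not saturation_cap:
                    raise SaturationError(
                        f"pair ({labels[i]!r}, {labels[j]!r}) saturates JC (p={p:.3f})"
                    )
                p = 0.75 - 1e-9
            d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(d, ids=labels)


# --------------------------------------------------------- neighbor joining

def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Q-minimization ties (within 1e-12) join the pair whose subtree leaf
    labels sort lexicographically smallest.  Negative branch lengths are
    clamped to zero.  The unrooted tree is returned in the conventional
    rooted-at-trifurcation form (root-at-edge for two leaves).
    """
    labels = list(dist.ids)
    if len(labels) < 2:
        raise ArgumentError("neighbor joining needs at least 2 leaves")
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ArgumentError("distance matrix must be symmetric")

    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # smallest leaf label within each active subtree
    d = d.copy()

    def join(i: int, j: int, li: float, lj: float) -> None:
        nodes[i].length = max(float(li), 0.0)
        nodes[j].length = max(float(lj), 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        del nodes[j]
        del keys[j]

    while len(nodes) > 3:
        n = d.shape[0]
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        du = (d[i] + d[j] - d[i, j]) / 2.0
        join(i, j, li, lj)
        du = np.delete(du, j)
        d = np.delete(np.delete(d, j, axis=0), j, axis=1)
        d[i, :] = du
        d[:, i] = du
        d[i, i] = 0.0

    if len(nodes) == 3:
        l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
        l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
        l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
        for node, length in zip(nodes, (l0, l1, l2)):
            node.length = max(float(length), 0.0)
        return TreeNode(children=list(nodes))
    # two leaves: single edge of total length d(1, 2)
    nodes[0].length = float(d[0, 1]) / 2.0
    nodes[1].length = float(d[0, 1]) / 2.0
    return TreeNode(children=list(nodes))


def _canonical_split(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    other = leaves - side
    if (len(side), tuple(sorted(side))) <= (len(other), tuple(sorted(other))):
        return side
    return other


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted tree, canonicalized as the
    smaller side (ties broken lexicographically)."""
    leaves = frozenset(t.name for t in tree.tips())
    total = len(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= total - 2:
            out.add(_canonical_split(side, leaves))
    return out


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the NJ tree's internal edges.

    Each replicate resamples alignment columns with replacement, rebuilds
    the JC/NJ tree, and scores which of the original tree's bipartitions
    reappear.  Returns bipartition -> support percent in [0, 100].
    """
    if n_reps < 1:
        raise ArgumentError("n_reps must be >= 1")
    labels, mat = _alignment_matrix(alignment)
    if len(labels) < 4:
        return {}
    original = nj_tree(jc_distance_matrix(alignment))
    targets = tree_bipartitions(original)
    if not targets:
        return {}
    hits = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        replicate = {lab: mat[k, cols].tobytes().decode("ascii")
                     for k, lab in enumerate(labels)}
        rep_tree = nj_tree(jc_distance_matrix(replicate, saturation_cap=True))
        rep_bps = tree_bipartitions(rep_tree)
        for bp in targets:
            if bp in rep_bps:
                hits[bp] += 1
    return {bp: 100.0 * count / n_reps for bp, count in hits.items()}


def annotate_supports(
    tree: TreeNode,
    supports: Mapping[frozenset[str], float],
    threshold: float = 50.0,
) -> TreeNode:
    """Write bootstrap supports as internal-node labels; values at or below
    ``threshold`` are suppressed (left blank)."""
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = _canonical_split(frozenset(t.name for t in node.tips()), leaves)
        support = supports.get(side)
        if support is not None and support > threshold:
            node.name = f"{support:.0f}"
    return tree


def spike_and_tree(
    subotus: Sequence[SubOTU],
    spikes: Mapping[str, str],
    threshold: float = 50.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, str]:
    """NJ tree over sub-OTU representatives plus spike reference sequences.

    All sequences must come pre-aligned to one length (alignment is an
    input contract, not computed here).  Returns the support-annotated tree
    and its Newick text (branch lengths in substitutions/site, supports as
    internal-node labels).
    """
    alignment: dict[str, str] = {}
    for sub in subotus:
        alignment[sub.subotu_id] = sub.representative
    for label, seq in spikes.items():
        if label in alignment:
            raise ArgumentError(f"duplicate leaf label {label!r}")
        alignment[label] = seq
    if len(alignment) < 2:
        raise ArgumentError("need at least two sequences to build a tree")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ArgumentError("unaligned (ragged) input: sequences differ in length")
    tree = nj_tree(jc_distance_matrix(alignment))
    if len(alignment) >= 4:
        supports = bootstrap_support(alignment, n_reps=n_boot, seed=seed)
        annotate_supports(tree, supports, threshold=threshold)
    return tree, write_newick(tree)


def write_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text), format="newick")
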