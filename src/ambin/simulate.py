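"""Ground-truthed synthetic communities.

Emulates the statistical structure the annotation-binning analysis assumes:
a ranked reference taxonomy whose species may share or differ in the
sequenced 16S fragment, amplicon reads with i.i.d. substitution errors,
full-length alignment hit tables consistent with read provenance, and
treatment-structured negative-binomial OTU count matrices.  Every simulated
read and count carries a truth entry so downstream stages can be scored
against known provenance.

The default experimental design mirrors a metal-contamination field trial:
five treatments (control, Pb, Zn, Cu, three_metal) in four replicate blocks,
20 samples in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ArgumentError
from .hits import Hit
from .taxonomy import RANKS, TaxonNode, TaxonomyTree

TREATMENTS = ("control", "Pb", "Zn", "Cu", "three_metal")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference 16S fragment, standing in for a public database record."""

    accession: str
    taxon_id: str  # species node in the TaxonomyTree
    sequence: str
    label: str  # display name; may carry "uncharacterized"/"uncultured" tokens

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ArgumentError(f"empty sequence for {self.accession}")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    treatment: str
    block: int


@dataclass
class SimTruth:
    """Ground truth of a simulation run, used as the scoring oracle."""

    read_provenance: dict[str, str] = field(default_factory=dict)  # read -> accession
    true_lfc: dict[tuple[str, str], float] = field(default_factory=dict)
    dispersion: dict[str, float] = field(default_factory=dict)
    baseline_mean: dict[str, float] = field(default_factory=dict)


def default_design() -> list[SampleDesign]:
    """5 treatments x 4 blocks = 20 samples."""
    return [
        SampleDesign(f"{t}_b{b}", t, b) for t in TREATMENTS for b in range(1, 5)
    ]


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute the given positions with a uniformly chosen *different* base."""
    out = arr.copy()
    if positions.size == 0:
        return out
    current = out[positions]
    # pick an offset 1..3 among the other three bases
    idx = np.searchsorted(_BASES, current)
    offsets = rng.integers(1, 4, size=positions.size)
    out[positions] = _BASES[(idx + offsets) % 4]
    return out


def generate_reference_db(
    n_species: int,
    species_per_genus: int = 2,
    fragment_length: int = 400,
    divergence: float = 0.02,
    seed: int = 0,
    n_identical_genera: int = 0,
    uncharacterized_every: int = 5,
) -> tuple[TaxonomyTree, list[ReferenceRecord]]:
    """Build a 7-rank taxonomy and one reference fragment per species.

    Within a genus, species fragments derive from a common ancestral
    fragment, each mutated independently at rate ``divergence / 2`` so
    pairwise congeneric sequences differ at about
    ``divergence * fragment_length`` positions.  The first
    ``n_identical_genera`` genera instead share the ancestral fragment
    verbatim across their species, to exercise ambiguous-call resolution.
    Every ``uncharacterized_every``-th species gets an
    "uncharacterized ..." display label to exercise label cleaning.
    """
    if n_species < 2:
        raise ArgumentError("n_species must be >= 2")
    if species_per_genus < 1:
        raise ArgumentError("species_per_genus must be positive")
    if fragment_length < 50:
        raise ArgumentError("fragment_length must be >= 50")
    if not 0 <= divergence <= 1:
        raise ArgumentError("divergence must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_genera = -(-n_species // species_per_genus)  # ceil

    # group upward by a factor of two at each rank
    def n_groups(n: int) -> int:
        return max(1, -(-n // 2))

    n_families = n_groups(n_genera)
    n_orders = n_groups(n_families)
    n_classes = n_groups(n_orders)
    n_phyla = n_groups(n_classes)

    nodes = [TaxonNode("root", "root", "root", None),
             TaxonNode("sk1", "Bacteria", "superkingdom", "root")]
    for p in range(n_phyla):
        nodes.append(TaxonNode(f"p{p + 1}", f"Phylum{p + 1:02d}", "phylum", "sk1"))
    for c in range(n_classes):
        nodes.append(TaxonNode(f"c{c + 1}", f"Class{c + 1:02d}", "class", f"p{c // 2 + 1}"))
    for o in range(n_orders):
        nodes.append(TaxonNode(f"o{o + 1}", f"Order{o + 1:02d}", "order", f"c{o // 2 + 1}"))
    for f in range(n_families):
        nodes.append(TaxonNode(f"f{f + 1}", f"Family{f + 1:02d}", "family", f"o{f // 2 + 1}"))
    for g in range(n_genera):
        nodes.append(TaxonNode(f"g{g + 1}", f"Genus{g + 1:02d}", "genus", f"f{g // 2 + 1}"))

    records: list[ReferenceRecord] = []
    species_idx = 0
    for g in range(n_genera):
        ancestor = rng.choice(_BASES, size=fragment_length)
        identical = g < n_identical_genera
        for s in range(species_per_genus):
            if species_idx >= n_species:
                break
            species_idx += 1
            taxon_id = f"s{species_idx}"
            name = f"Genus{g + 1:02d} species{s + 1}"
            nodes.append(TaxonNode(taxon_id, name, "species", f"g{g + 1}"))
            if identical or divergence == 0:
                fragment = ancestor.copy()
            else:
                n_mut = rng.binomial(fragment_length, divergence / 2.0)
                positions = rng.choice(fragment_length, size=n_mut, replace=False)
                fragment = _mutate(ancestor, positions, rng)
            if uncharacterized_every and species_idx % uncharacterized_every == 0:
                label = f"uncharacterized Genus{g + 1:02d} bacterium"
            else:
                label = name
            records.append(
                ReferenceRecord(
                    accession=f"ACC{species_idx:06d}",
                    taxon_id=taxon_id,
                    sequence=_array_to_seq(fragment),
                    label=label,
                )
            )
    return TaxonomyTree(nodes), records


def simulate_amplicons(
    refs: Sequence[ReferenceRecord],
    design: Sequence[SampleDesign],
    reads_per_sample: int,
    abundance_profile: Mapping[str, Sequence[float]] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[SeqRecord]], SimTruth]:
    """Draw reads per sample from the reference fragments with substitution errors.

    ``abundance_profile`` maps treatment -> per-species weights (aligned with
    ``refs``); ``None`` means uniform.  Each read copies its source fragment
    with i.i.d. substitutions at ``error_rate`` and its provenance is recorded.
    """
    if not refs:
        raise ArgumentError("reference set is empty")
    if reads_per_sample < 1:
        raise ArgumentError("reads_per_sample must be positive")
    if not 0 <= error_rate <= 1:
        raise ArgumentError("error_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    ref_arrays = [_seq_to_array(r.sequence) for r in refs]
    truth = SimTruth()
    reads: dict[str, list[SeqRecord]] = {}

    for sample in design:
        if abundance_profile is None:
            weights = np.ones(len(refs))
        else:
            weights = np.asarray(abundance_profile[sample.treatment], dtype=float)
            if len(weights) != len(refs):
                raise ArgumentError("abundance weights must align with refs")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ArgumentError(
                f"treatment {sample.treatment!r} needs nonnegative weights, "
                "at least one positive"
            )
        probs = weights / weights.sum()
        sources = rng.choice(len(refs), size=reads_per_sample, p=probs)
        sample_reads = []
        for k, src in enumerate(sources):
            arr = ref_arrays[src]
            if error_rate > 0:
                mask = rng.random(arr.size) < error_rate
                arr = _mutate(arr, np.flatnonzero(mask), rng)
            read_id = f"{sample.sample_id}_r{k:05d}"
            sample_reads.append(
                SeqRecord(Seq(_array_to_seq(arr)), id=read_id, description="")
            )
            truth.read_provenance[read_id] = refs[src].accession
        reads[sample.sample_id] = sample_reads
    return reads, truth


def bitscore_model(matches: np.ndarray, mismatches: np.ndarray) -> np.ndarray:
    """Documented surrogate score: 2*(matches - 3*mismatches).

    Strictly decreasing in the mismatch count at fixed length, so provenance
    hits outrank everything except identical fragments, and equal mismatch
    counts produce exact score ties.
    """
    return 2.0 * (matches - 3.0 * mismatches)


def evalue_model(bitscore: np.ndarray) -> np.ndarray:
    """Documented surrogate e-value: 10^(-bitscore/10), monotone in mismatches."""
    return np.power(10.0, -np.asarray(bitscore, dtype=float) / 10.0)


def simulate_hit_table(
    reads: Mapping[str, Iterable[SeqRecord]],
    refs: Sequence[ReferenceRecord],
    max_targets: int = 5,
    seed: int = 0,
) -> list[Hit]:
    """Emit full-length alignment hits for each read against the references.

    For every read the ``max_targets`` nearest references by Hamming distance
    are reported.  Identity is 100*matches/length, coverage is 100 (the
    full-length alignment model); reads tied in mismatch count receive
    identical bit scores.  ``seed`` is accepted for interface symmetry; the
    computation is deterministic.
    """
    del seed  # deterministic: nearest-reference search has no randomness
    if not refs:
        raise ArgumentError("reference set is empty")
    all_records = [rec for sample in sorted(reads) for rec in reads[sample]]
    if not all_records:
        raise ArgumentError("no reads provided")
    max_targets = int(max_targets)
    if max_targets < 1:
        raise ArgumentError("max_targets must be positive")

    length = len(refs[0].sequence)
    if any(len(r.sequence) != length for r in refs):
        raise ArgumentError("reference fragments must share one length")
    ref_matrix = np.stack([_seq_to_array(r.sequence) for r in refs])  # (R, L)

    hits: list[Hit] = []
    batch = 2000
    for start in range(0, len(all_records), batch):
        chunk = all_records[start:start + batch]
        read_matrix = np.stack([_seq_to_array(str(r.seq)) for r in chunk])
        if read_matrix.shape[1] != length:
            raise ArgumentError("read length differs from reference length")
        # (B, R) mismatch counts
        mm = (read_matrix[:, None, :] != ref_matrix[None, :, :]).sum(axis=2)
        order = np.argsort(mm, axis=1, kind="stable")[:, :max_targets]
        for row, rec in enumerate(chunk):
            for ref_idx in order[row]:
                mismatches = int(mm[row, ref_idx])
                matches = length - mismatches
                score = float(bitscore_model(np.array(matches), np.array(mismatches)))
                hits.append(
                    Hit(
                        query_id=rec.id,
                        accession=refs[ref_idx].accession,
                        identity=100.0 * matches / length,
                        coverage=100.0,
                        evalue=float(evalue_model(np.array(score))),
                        bitscore=score,
                        length=length,
                        mismatch=mismatches,
                    )
                )
    return hits


def simulate_count_experiment(
    n_otus: int,
    design: Sequence[SampleDesign],
    lfc_spec: Mapping[tuple[int, str], float] | None = None,
    dispersion: Sequence[float] | float = 0.1,
    baseline: Sequence[float] | float = 500.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw an OTU x sample count matrix with per-treatment log2 fold changes.

    Cell (i, j) ~ NB(mean = mu_i * 2**lfc_spec[(i, treatment_j)], dispersion
    alpha_i), independently; alpha_i = 0 degenerates to Poisson.
    ``lfc_spec`` keys are (otu index, treatment); missing keys mean 0.
    """
    if n_otus < 1:
        raise ArgumentError("n_otus must be positive")
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_otus,)).copy()
    mu = np.broadcast_to(np.asarray(baseline, dtype=float), (n_otus,)).copy()
    if np.any(alpha < 0):
        raise ArgumentError("dispersion must be nonnegative")
    if np.any(mu <= 0):
        raise ArgumentError("baseline means must be positive")
    lfc_spec = dict(lfc_spec or {})

    rng = np.random.default_rng(seed)
    otu_ids = [f"otu{i + 1:04d}" for i in range(n_otus)]
    sample_ids = [s.sample_id for s in design]
    counts = np.zeros((n_otus, len(design)), dtype=np.int64)
    truth = SimTruth()
    for i in range(n_otus):
        truth.dispersion[otu_ids[i]] = float(alpha[i])
        truth.baseline_mean[otu_ids[i]] = float(mu[i])
    for (i, treatment), lfc in lfc_spec.items():
        truth.true_lfc[(otu_ids[i], treatment)] = float(lfc)

    for j, sample in enumerate(design):
        means = mu * np.power(
            2.0, [lfc_spec.get((i, sample.treatment), 0.0) for i in range(n_otus)]
        )
        poisson = alpha == 0
        if poisson.any():
            counts[poisson, j] = rng.poisson(means[poisson])
        nb = ~poisson
        if nb.any():
            # NB with mean m and variance m + alpha m^2: shape r = 1/alpha,
            # success prob p = r / (r + m)
            r = 1.0 / alpha[nb]
            p = r / (r + means[nb])
            counts[nb, j] = rng.negative_binomial(r, p)
    matrix = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)
    return matrix, truth


# ---------------------------------------------------------------- writers

HIT_TABLE_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore qcovs"
).split()


def write_fasta(reads: Mapping[str, Iterable[SeqRecord]], out_dir) -> list[Path]:
    """One FASTA per sample, named ``<sample_id>.fasta``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample_id in sorted(reads):
        path = out_dir / f"{sample_id}.fasta"
        SeqIO.write(reads[sample_id], str(path), "fasta")
        paths.append(path)
    return paths


def write_hit_table(hits: Sequence[Hit], path) -> None:
    """12-column BLAST tabular dialect plus a qcovs column."""
    rows = []
    for h in hits:
        length = h.length if h.length is not None else 0
        rows.append(
            (
                h.query_id, h.accession, f"{h.identity:.3f}", length,
                h.mismatch if h.mismatch is not None else 0, 0, 1, length, 1,
                length, f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                f"{h.coverage:.0f}",
            )
        )
    pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_reference_taxonomy(
    refs: Sequence[ReferenceRecord], tree: TaxonomyTree, path
) -> None:
    """Accession -> ranked lineage table (accession, superkingdom..species, label)."""
    rows = []
    for r in refs:
        lineage = tree.lineage(r.taxon_id)
        rows.append(
            {"accession": r.accession, "taxon_id": r.taxon_id,
             **{rank: lineage.get(rank, "") for rank in RANKS},
             "label": r.label}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metadata(design: Sequence[SampleDesign], path) -> None:
    pd.DataFrame(
        [{"sample_id": s.sample_id, "treatment": s.treatment, "block": s.block}
         for s in design]
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleDesign]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    return [
        SampleDesign(r.sample_id, r.treatment, int(r.block))
        for r in frame.itertuples(index=False)
    ]


def write_truth(truth: SimTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if truth.read_provenance:
        pd.DataFrame(
            sorted(truth.read_provenance.items()), columns=["read_id", "accession"]
        ).to_csv(out_dir / "truth_provenance.tsv", sep="\t", index=False)
    if truth.true_lfc:
        pd.DataFrame(
            [{"otu_id": k[0], "treatment": k[1], "log2fc": v}
             for k, v in sorted(truth.true_lfc.items())]
        ).to_csv(out_dir / "truth_lfc.tsv", sep="\t", index=False)
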