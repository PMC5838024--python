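"""Ranked taxonomy with lowest-common-taxon queries.

The taxonomy is a rooted tree over a fixed seven-rank hierarchy
(superkingdom .. species).  Annotation ties between hits of equal quality
are resolved by walking to the lowest taxon shared by all candidate
species, so the central query here is :meth:`TaxonomyTree.lowest_common_taxon`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ArgumentError, LookupTaxonError

#: Fixed rank order, root-most first.  Ranks below species are not modeled.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str  # one of RANKS, or "root"
    parent: str | None  # None only for the root


class TaxonomyTree:
    """Rooted ranked tree; every species is reachable from the root.

    Parameters
    ----------
    nodes:
        Iterable of :class:`TaxonNode`.  Exactly one node must have
        ``parent is None`` (the root); ranks must strictly descend along
        the fixed rank order from parent to child.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        root = None
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise ArgumentError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
            if node.parent is None:
                if root is not None:
                    raise ArgumentError("taxonomy has more than one root")
                root = node.taxon_id
        if root is None:
            raise ArgumentError("taxonomy has no root")
        self.root = root
        self._validate()

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent is None:
                continue
            if node.parent not in self._nodes:
                raise ArgumentError(
                    f"node {node.taxon_id!r} has unknown parent {node.parent!r}"
                )
            parent = self._nodes[node.parent]
            child_depth = _RANK_DEPTH.get(node.rank)
            parent_depth = -1 if parent.rank == "root" else _RANK_DEPTH.get(parent.rank)
            if child_depth is None:
                raise ArgumentError(f"unknown rank {node.rank!r}")
            if parent_depth is not None and child_depth <= parent_depth:
                raise ArgumentError(
                    f"rank {node.rank!r} of {node.taxon_id!r} does not descend "
                    f"from parent rank {parent.rank!r}"
                )
        # reachability: path_to_root terminates for every node (acyclic by
        # construction since ranks strictly descend)
        for taxon_id in self._nodes:
            self.path_to_root(taxon_id)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise LookupTaxonError(f"unknown taxon_id {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        return self.node(taxon_id).rank

    def name(self, taxon_id: str) -> str:
        return self.node(taxon_id).name

    def species(self) -> list[str]:
        return sorted(t for t, n in self._nodes.items() if n.rank == "species")

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Taxon ids from the root down to (and including) ``taxon_id``."""
        path = []
        current: str | None = taxon_id
        while current is not None:
            if current in path:
                raise ArgumentError(f"cycle detected at taxon {current!r}")
            path.append(current)
            current = self.node(current).parent
        path.reverse()
        return path

    def lineage(self, taxon_id: str) -> dict[str, str]:
        """Rank -> taxon name along the root path (root excluded)."""
        out = {}
        for tid in self.path_to_root(taxon_id):
            node = self._nodes[tid]
            if node.rank != "root":
                out[node.rank] = node.name
        return out

    def lowest_common_taxon(self, taxa: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input taxon.

        Singleton input returns the taxon itself; congeneric species map to
        their genus; taxa sharing nothing below the root map to the root.
        """
        taxa = list(taxa)
        if not taxa:
            raise ArgumentError("lowest_common_taxon requires a nonempty set")
        paths = [self.path_to_root(t) for t in taxa]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) != 1:
                break
            lca = level[0]
        return lca

    # ------------------------------------------------------------------ IO

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_id": n.taxon_id, "name": n.name, "rank": n.rank,
             "parent": "" if n.parent is None else n.parent}
            for n in self._nodes.values()
        ]
        return pd.DataFrame(rows).sort_values("taxon_id").reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTree":
        nodes = [
            TaxonNode(r.taxon_id, r.name, r.rank, r.parent if r.parent else None)
            for r in frame.itertuples(index=False)
        ]
        return cls(nodes)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTree":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls.from_frame(frame)
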