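"""Annotation-binned OTU table construction.

OTUs here are not similarity clusters: every read resolved to the same
taxonomic call (taxon + display label) is binned together.  Construction
runs in two rounds.  Round 1 bins reads whose hits pass the strict
identity/coverage thresholds.  Round 2 rescues still-unassigned reads into
*established* OTUs at forgiving thresholds — a read joins the OTU holding
the accession of its best qualifying hit, and no new OTU may be created,
so sequencing-error variants of already-seen amplicons are captured without
minting low-confidence bins.  Sparsity and abundance filters then drop
OTUs seen in too few replicates, concentrated in one sample, or with a
trivial normalized total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError, DepthError
from .hits import Annotation, FilterConfig, Hit, BITSCORE_DECIMALS
from .simulate import SampleDesign


@dataclass
class OTU:
    """An annotation bin: reads sharing one resolved taxonomic call."""

    otu_id: str
    taxon_id: str
    label: str
    member_reads: dict[str, list[str]] = field(default_factory=dict)  # sample -> reads
    accession_registry: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(reads) for s, reads in self.member_reads.items()}

    @property
    def total(self) -> int:
        return sum(len(reads) for reads in self.member_reads.values())

    @property
    def accessions(self) -> frozenset[str]:
        out: set[str] = set()
        for accs in self.accession_registry.values():
            out |= accs
        return frozenset(out)

    def add_read(self, read_id: str, sample_id: str, accessions: Iterable[str]) -> None:
        if read_id in self.accession_registry:
            raise ConsistencyError(f"read {read_id!r} already assigned to {self.otu_id}")
        self.member_reads.setdefault(sample_id, []).append(read_id)
        self.accession_registry[read_id] = frozenset(accessions)


@dataclass(frozen=True)
class SparsityConfig:
    """Sparsity and abundance retention thresholds.

    An OTU is flagged when present in fewer than ``min_replicates`` samples,
    or when its maximum single-sample count reaches ``max_concentration`` of
    its total.  Downstream abundance retention keeps OTUs whose normalized
    total is strictly greater than ``min_total_normalized``.
    """

    min_replicates: int = 4
    max_concentration: float = 0.75
    min_total_normalized: float = 10.0

    def __post_init__(self):
        if not 0 < self.max_concentration <= 1:
            raise ArgumentError("max_concentration must lie in (0, 1]")


def make_otu_id(label: str, taxon_id: str) -> str:
    return f"{label}|{taxon_id}"


def rarefy_samples(
    reads_by_sample: Mapping[str, Sequence[str]],
    depth: int,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Subsample every sample to exactly ``depth`` reads, uniformly without
    replacement, preserving the original within-sample order."""
    if depth < 1:
        raise ArgumentError("depth must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for sample_id in sorted(reads_by_sample):
        reads = list(reads_by_sample[sample_id])
        if len(reads) < depth:
            raise DepthError(
                f"sample {sample_id!r} has {len(reads)} reads, fewer than the "
                f"rarefaction depth {depth}"
            )
        keep = np.sort(rng.choice(len(reads), size=depth, replace=False))
        out[sample_id] = [reads[i] for i in keep]
    return out


def bin_round1(
    annotations: Iterable[Annotation],
    sample_of: Mapping[str, str],
) -> list[OTU]:
    """One OTU per distinct (taxon, label) call; each annotated read joins
    exactly one OTU."""
    otus: dict[str, OTU] = {}
    seen: set[str] = set()
    for ann in annotations:
        if ann.query_id in seen:
            raise ConsistencyError(f"read {ann.query_id!r} annotated twice")
        seen.add(ann.query_id)
        otu_id = make_otu_id(ann.label, ann.taxon_id)
        otu = otus.get(otu_id)
        if otu is None:
            otu = otus[otu_id] = OTU(otu_id, ann.taxon_id, ann.label)
        otu.add_read(ann.query_id, sample_of[ann.query_id], ann.supporting_accessions)
    return [otus[k] for k in sorted(otus)]


def bin_round2(
    unassigned: Sequence[str],
    all_hits: Mapping[str, Sequence[Hit]],
    otus: Sequence[OTU],
    config: FilterConfig,
    sample_of: Mapping[str, str],
) -> tuple[list[OTU], list[str]]:
    """Rescue unassigned reads into established OTUs at round-2 thresholds.

    A read is considered against hits with evalue < evalue_max, identity and
    coverage at the forgiving thresholds, whose accession is already
    registered in some OTU.  It joins the OTU holding its highest-bitscore
    qualifying hit; score ties go to the OTU with the larger current total,
    then the lexicographically smallest otu_id.  No OTU is ever created.
    """
    acc_to_otus: dict[str, set[str]] = {}
    by_id = {o.otu_id: o for o in otus}
    if len(by_id) != len(otus):
        raise ConsistencyError("duplicate otu_id among established OTUs")
    for otu in otus:
        for acc in otu.accessions:
            acc_to_otus.setdefault(acc, set()).add(otu.otu_id)

    still_unassigned: list[str] = []
    for read_id in unassigned:
        candidates: list[tuple[float, str, str]] = []  # (bitscore, otu_id, accession)
        for hit in all_hits.get(read_id, ()):  # hits may be absent entirely
            if hit.evalue >= config.evalue_max:
                continue
            if hit.identity < config.round2_identity:
                continue
            if hit.coverage < config.round2_coverage:
                continue
            for otu_id in acc_to_otus.get(hit.accession, ()):
                candidates.append(
                    (round(hit.bitscore, BITSCORE_DECIMALS), otu_id, hit.accession)
                )
        if not candidates:
            still_unassigned.append(read_id)
            continue
        best_score = max(c[0] for c in candidates)
        tied = [c for c in candidates if c[0] == best_score]
        chosen_id = min(
            {c[1] for c in tied},
            key=lambda oid: (-by_id[oid].total, oid),
        )
        accessions = {c[2] for c in tied if c[1] == chosen_id}
        by_id[chosen_id].add_read(read_id, sample_of[read_id], accessions)
    return list(otus), still_unassigned


def build_count_matrix(
    otus: Sequence[OTU],
    samples: Sequence[SampleDesign],
) -> pd.DataFrame:
    """OTU x sample count matrix, zero-filled, rows and columns sorted."""
    sample_ids = sorted(s.sample_id for s in samples)
    otu_ids = sorted(o.otu_id for o in otus)
    if len(set(otu_ids)) != len(otu_ids):
        raise ConsistencyError("duplicate otu_id in OTU list")
    matrix = pd.DataFrame(0, index=otu_ids, columns=sample_ids, dtype=np.int64)
    for otu in otus:
        for sample_id, count in otu.counts.items():
            if sample_id not in matrix.columns:
                raise ConsistencyError(
                    f"OTU {otu.otu_id!r} has reads in unknown sample {sample_id!r}"
                )
            matrix.loc[otu.otu_id, sample_id] = count
    return matrix


def sparsity_filter(
    matrix: pd.DataFrame,
    config: SparsityConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and drop sparse or single-sample-concentrated OTUs.

    An OTU is flagged when it is present (count > 0) in fewer than
    ``min_replicates`` samples, or when max sample count / total count is at
    or above ``max_concentration`` (retention requires the ratio to be
    strictly below the threshold).  Returns the retained matrix and a flag
    report with one row per flagged OTU and a ``reason`` column
    ("absent", "replicates", "concentration"; comma-joined when several
    apply).
    """
    config = config or SparsityConfig()
    flags = []
    keep = []
    for otu_id, row in matrix.iterrows():
        values = row.to_numpy()
        total = values.sum()
        present = int((values > 0).sum())
        reasons = []
        if total == 0:
            reasons.append("absent")
        elif present < config.min_replicates:
            reasons.append("replicates")
        if total > 0 and values.max() / total >= config.max_concentration:
            reasons.append("concentration")
        if reasons:
            flags.append({"otu_id": otu_id, "reason": ",".join(reasons)})
        else:
            keep.append(otu_id)
    retained = matrix.loc[keep]
    report = pd.DataFrame(flags, columns=["otu_id", "reason"])
    return retained, report


def abundance_retention(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    config: SparsityConfig | None = None,
) -> pd.DataFrame:
    """Keep OTUs whose total normalized count is strictly above the threshold."""
    config = config or SparsityConfig()
    if matrix.empty:
        return matrix
    factors = size_factors.reindex(matrix.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ArgumentError("size factors must be positive for every sample")
    normalized_total = (matrix / factors).sum(axis=1)
    return matrix.loc[normalized_total > config.min_total_normalized]


def binned_percent(n_binned: int, n_total: int, decimals: int = 2) -> float:
    """Fraction of rarefied reads captured by binning, as a rounded percent."""
    if n_total <= 0:
        raise ArgumentError("n_total must be positive")
    return round(100.0 * n_binned / n_total, decimals)


def write_otu_annotations(otus: Sequence[OTU], tree, path) -> None:
    """OTU annotation table: id, rank, lineage, label, supporting accessions."""
    rows = []
    for otu in sorted(otus, key=lambda o: o.otu_id):
        lineage = tree.lineage(otu.taxon_id)
        rows.append(
            {
                "otu_id": otu.otu_id,
                "rank": tree.rank(otu.taxon_id),
                "lineage": ";".join(lineage.values()),
                "label": otu.label,
                "n_accessions": len(otu.accessions),
            }
        )
    pd.DataFrame(
        rows, columns=["otu_id", "rank", "lineage", "label", "n_accessions"]
    ).to_csv(path, sep="\t", index=False)
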