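"""Alignment-hit parsing, filtering, and annotation resolution.

Each amplicon read carries a set of alignment hits against a reference
database.  An annotation is resolved per read in two steps: hits are
filtered on e-value, percent identity and query coverage; then the hit
with the highest bit score names the read.  When several hits tie at the
maximal bit score the call is lifted to the lowest taxonomic level shared
by all tied hits, and display labels flagged as unknown/uncharacterized
are replaced by an informative alternative when one exists among the tie.
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ArgumentError, LookupTaxonError, ParseError
from .taxonomy import TaxonomyTree

#: Case-insensitive tokens that mark a display label as uninformative.
UNINFORMATIVE_TOKENS = ("unknown", "uncharacterized", "uncultured")

#: Bit scores are compared after rounding to this many decimals (tabular
#: output precision), so genuine ties are not split by float noise.
BITSCORE_DECIMALS = 1


@dataclass(frozen=True)
class Hit:
    """One alignment record of a query read against a reference accession."""

    query_id: str
    accession: str
    identity: float  # percent in [0, 100]
    coverage: float  # percent of the query in [0, 100]
    evalue: float
    bitscore: float
    length: int | None = None
    mismatch: int | None = None

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ArgumentError(f"identity {self.identity} outside [0, 100]")
        if not 0 <= self.coverage <= 100:
            raise ArgumentError(f"coverage {self.coverage} outside [0, 100]")
        if self.evalue < 0:
            raise ArgumentError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class FilterConfig:
    """Two-round retention thresholds.

    Round 1 builds annotations at the strict thresholds; round 2 rescues
    unannotated reads into established bins at the forgiving ones.  The
    e-value cut is strict (< evalue_max); identity/coverage cuts are
    inclusive (>=).
    """

    evalue_max: float = 1e-10
    round1_identity: float = 99.0
    round1_coverage: float = 99.0
    round2_identity: float = 98.0
    round2_coverage: float = 98.0

    def __post_init__(self):
        if self.round2_identity > self.round1_identity:
            raise ArgumentError("round-2 identity threshold exceeds round 1")
        if self.round2_coverage > self.round1_coverage:
            raise ArgumentError("round-2 coverage threshold exceeds round 1")


@dataclass(frozen=True)
class Annotation:
    query_id: str
    taxon_id: str
    label: str
    supporting_accessions: frozenset[str]
    best_bitscore: float


def parse_hit_table(
    path, query_lengths: Mapping[str, int] | None = None
) -> list[Hit]:
    """Read a 12(+1)-column BLAST tabular file into :class:`Hit` records.

    Columns are qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore [qcovs].  Query coverage comes from the
    qcovs column when present, otherwise from 100*(qend-qstart+1)/query
    length via ``query_lengths``.  Malformed rows raise :class:`ParseError`
    naming the line.
    """
    hits: list[Hit] = []
    with open(path, newline="") as handle:
        for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 12:
                raise ParseError(
                    f"{path}: line {line_no}: expected >=12 columns, got {len(row)}"
                )
            try:
                qseqid, sseqid = row[0], row[1]
                identity = float(row[2])
                qstart, qend = int(row[6]), int(row[7])
                evalue = float(row[10])
                bitscore = float(row[11])
                length = int(row[3])
                mismatch = int(row[4])
                if len(row) >= 13:
                    coverage = float(row[12])
                elif query_lengths is not None:
                    coverage = 100.0 * (qend - qstart + 1) / query_lengths[qseqid]
                else:
                    raise ParseError(
                        f"{path}: line {line_no}: no qcovs column and no "
                        "query_lengths supplied to derive coverage"
                    )
            except ParseError:
                raise
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {line_no}: {exc}") from exc
            try:
                hits.append(
                    Hit(qseqid, sseqid, identity, coverage, evalue, bitscore,
                        length=length, mismatch=mismatch)
                )
            except ArgumentError as exc:
                raise ParseError(f"{path}: line {line_no}: {exc}") from exc
    return hits


def filter_hits(
    hits: Iterable[Hit],
    min_identity: float,
    min_coverage: float,
    evalue_max: float = 1e-10,
) -> list[Hit]:
    """Retain hits with evalue < evalue_max, identity >= min_identity and
    coverage >= min_coverage, preserving input order."""
    return [
        h for h in hits
        if h.evalue < evalue_max
        and h.identity >= min_identity
        and h.coverage >= min_coverage
    ]


def lowest_common_taxon(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Deepest taxonomy node ancestral to (or equal to) every input taxon."""
    return tree.lowest_common_taxon(taxa)


_WORD = re.compile(r"\S+")


def _is_uninformative(label: str) -> bool:
    low = label.lower()
    return any(tok in low for tok in UNINFORMATIVE_TOKENS)


def _decoration_count(label: str) -> int:
    low = label.lower()
    return sum(low.count(tok) for tok in UNINFORMATIVE_TOKENS)


def clean_label(raw_labels: Sequence[str]) -> str:
    """Pick the most informative display label among candidates.

    If any candidate lacks the uninformative tokens ("unknown",
    "uncharacterized", "uncultured"; case-insensitive), the one with the
    fewest words wins (ties broken lexicographically).  Otherwise the
    least-decorated raw label is returned unchanged: fewest token
    occurrences, then fewest words, then lexicographic.
    """
    if not raw_labels:
        raise ArgumentError("clean_label requires a nonempty list")
    informative = [lab for lab in raw_labels if not _is_uninformative(lab)]
    pool = informative if informative else list(raw_labels)
    if informative:
        key = lambda lab: (len(_WORD.findall(lab)), lab)  # noqa: E731
    else:
        key = lambda lab: (_decoration_count(lab), len(_WORD.findall(lab)), lab)  # noqa: E731
    return min(pool, key=key)


def resolve_annotation(
    hits_for_query: Sequence[Hit],
    refs: Mapping[str, "ReferenceRecord"],  # noqa: F821 - structural typing
    tree: TaxonomyTree,
) -> Annotation:
    """Resolve one query's annotation from its (already filtered) hits.

    The hit with the highest bit score names the query.  Hits tying at the
    maximal score (after rounding to tabular precision) pool their
    accessions; if the tied accessions span more than one species the call
    is lifted to their lowest common taxon, otherwise it stays at species.
    """
    if not hits_for_query:
        raise ArgumentError("resolve_annotation requires at least one hit")
    best = max(round(h.bitscore, BITSCORE_DECIMALS) for h in hits_for_query)
    tied = [
        h for h in hits_for_query
        if round(h.bitscore, BITSCORE_DECIMALS) == best
    ]
    accessions = frozenset(h.accession for h in tied)
    species = set()
    labels = []
    for acc in sorted(accessions):
        if acc not in refs:
            raise LookupTaxonError(f"accession {acc!r} absent from reference set")
        rec = refs[acc]
        species.add(rec.taxon_id)
        labels.append(rec.label)
    if len(species) == 1:
        taxon = next(iter(species))
    else:
        taxon = tree.lowest_common_taxon(species)
    return Annotation(
        query_id=hits_for_query[0].query_id,
        taxon_id=taxon,
        label=clean_label(labels),
        supporting_accessions=accessions,
        best_bitscore=float(best),
    )


def group_hits_by_query(hits: Iterable[Hit]) -> dict[str, list[Hit]]:
    grouped: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    return dict(grouped)


def annotate_queries(
    hits: Iterable[Hit],
    refs: Mapping[str, "ReferenceRecord"],  # noqa: F821
    tree: TaxonomyTree,
    config: FilterConfig | None = None,
) -> dict[str, Annotation]:
    """Round-1 annotation: filter at the strict thresholds, then resolve.

    Queries whose hits all fail the strict filter receive no annotation.
    """
    config = config or FilterConfig()
    annotations: dict[str, Annotation] = {}
    for query_id, query_hits in group_hits_by_query(hits).items():
        kept = filter_hits(
            query_hits, config.round1_identity, config.round1_coverage,
            config.evalue_max,
        )
        if kept:
            annotations[query_id] = resolve_annotation(kept, refs, tree)
    return annotations
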