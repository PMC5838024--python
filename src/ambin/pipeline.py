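"""End-to-end orchestration of the synthetic-community analysis.

Stages run in a fixed order — simulate, annotate, bin, stats, da, tree —
each writing its outputs into the run directory.  A manifest records the
configuration hash, per-stage output checksums, seeds and package version,
so a rerun with the same configuration is byte-identical and verifiable.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .hits import FilterConfig, annotate_queries, group_hits_by_query
from .binning import (
    SparsityConfig, abundance_retention, bin_round1, bin_round2,
    build_count_matrix, rarefy_samples, sparsity_filter, write_otu_annotations,
)
from .da import pairwise_da_summary, results_frame, run_differential_abundance
from .phylo import spike_and_tree, unpack_otu
from .simulate import (
    default_design, generate_reference_db, simulate_amplicons,
    simulate_hit_table, write_fasta, write_hit_table, write_metadata,
    write_reference_taxonomy, write_truth,
)
from .stats import (
    bray_curtis, cap, diversity_report, group_ttest, permanova,
    size_factors_median_of_ratios,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "bin", "stats", "da", "tree")

_SEED_FIELDS = ("seed_simulate", "seed_rarefy", "seed_permanova", "seed_bootstrap")


@dataclass
class RunConfig:
    """Complete, explicit configuration of one pipeline run.

    Every stochastic stage carries its own seed; validation fails fast if
    any is missing.  The config round-trips losslessly through its INI file
    form.
    """

    out_dir: str = "run"
    # synthetic community
    n_species: int = 24
    species_per_genus: int = 2
    fragment_length: int = 400
    divergence: float = 0.05
    n_identical_genera: int = 1
    reads_per_sample: int = 600
    error_rate: float = 0.004
    # filtering / binning
    evalue_max: float = 1e-10
    round1_identity: float = 99.0
    round1_coverage: float = 99.0
    round2_identity: float = 98.0
    round2_coverage: float = 98.0
    rarefaction_depth: int = 500
    min_replicates: int = 4
    max_concentration: float = 0.75
    min_total_normalized: float = 10.0
    # statistics
    alpha: float = 0.05
    permutations: int = 999
    bootstrap: int = 200
    tree_threshold: float = 50.0
    # seeds (one per stochastic stage)
    seed_simulate: int | None = None
    seed_rarefy: int | None = None
    seed_permanova: int | None = None
    seed_bootstrap: int | None = None

    def validate(self) -> None:
        missing = [f for f in _SEED_FIELDS if getattr(self, f) is None]
        if missing:
            raise ConfigError(f"missing seed(s): {', '.join(missing)}")
        if self.rarefaction_depth < 1:
            raise ConfigError("rarefaction_depth must be positive")

    def seed_all(self, seed: int) -> "RunConfig":
        """Derive one seed per stage from a master seed (all < 2**31)."""
        for offset, name in enumerate(_SEED_FIELDS):
            setattr(self, name, (int(seed) * 1009 + offset) % (2 ** 31))
        return self

    # ---------------------------------------------------------------- file form

    def to_ini(self, path) -> None:
        parser = configparser.ConfigParser()
        parser["run"] = {
            k: "" if v is None else str(v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as handle:
            parser.write(handle)

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        parser = configparser.ConfigParser()
        if not parser.read(path):
            raise ConfigError(f"cannot read config file {path}")
        raw = dict(parser["run"])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if text == "":
                kwargs[f.name] = None
                continue
            ftype = {"int": int, "float": float, "str": str,
                     "int | None": int}.get(f.type, str)
            kwargs[f.name] = ftype(text)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seeds": {f: getattr(config, f) for f in _SEED_FIELDS},
        "stages": {},
    }
    config.to_ini(out / "run_config.ini")

    stage_outputs: dict[str, list[Path]] = {}

    def record(stage: str, paths: list[Path]) -> None:
        stage_outputs[stage] = paths
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): _checksum(p) for p in paths}
        }
        logger.info("stage %s complete (%d outputs)", stage, len(paths))

    try:
        # ---------------------------------------------------------- simulate
        design = default_design()
        tree, refs = generate_reference_db(
            n_species=config.n_species,
            species_per_genus=config.species_per_genus,
            fragment_length=config.fragment_length,
            divergence=config.divergence,
            seed=config.seed_simulate,
            n_identical_genera=config.n_identical_genera,
        )
        profile = _treatment_profile(refs, config.seed_simulate)
        reads, truth = simulate_amplicons(
            refs, design, config.reads_per_sample, profile,
            error_rate=config.error_rate, seed=config.seed_simulate + 1,
        )
        hits = simulate_hit_table(reads, refs, max_targets=5,
                                  seed=config.seed_simulate + 2)
        fasta_paths = write_fasta(reads, out / "reads")
        write_hit_table(hits, out / "hits.tsv")
        write_reference_taxonomy(refs, tree, out / "taxonomy.tsv")
        write_metadata(design, out / "samples.tsv")
        write_truth(truth, out)
        record("simulate", fasta_paths + [
            out / "hits.tsv", out / "taxonomy.tsv", out / "samples.tsv",
            out / "truth_provenance.tsv",
        ])

        # ---------------------------------------------------------- annotate
        fconfig = FilterConfig(
            evalue_max=config.evalue_max,
            round1_identity=config.round1_identity,
            round1_coverage=config.round1_coverage,
            round2_identity=config.round2_identity,
            round2_coverage=config.round2_coverage,
        )
        ref_index = {r.accession: r for r in refs}
        sample_of = {
            rec.id: sample_id for sample_id, recs in reads.items() for rec in recs
        }
        reads_by_sample = {s: [rec.id for rec in reads[s]] for s in reads}
        rarefied = rarefy_samples(reads_by_sample, config.rarefaction_depth,
                                  seed=config.seed_rarefy)
        kept_ids = {r for sample in rarefied.values() for r in sample}
        kept_hits = [h for h in hits if h.query_id in kept_ids]
        annotations = annotate_queries(kept_hits, ref_index, tree, fconfig)
        ann_frame = pd.DataFrame(
            [
                {"read_id": a.query_id, "taxon_id": a.taxon_id, "label": a.label,
                 "accessions": ",".join(sorted(a.supporting_accessions))}
                for a in annotations.values()
            ]
        ).sort_values("read_id") if annotations else pd.DataFrame(
            columns=["read_id", "taxon_id", "label", "accessions"]
        )
        ann_frame.to_csv(out / "annotations.tsv", sep="\t", index=False)
        record("annotate", [out / "annotations.tsv"])

        # --------------------------------------------------------------- bin
        otus = bin_round1(annotations.values(), sample_of)
        unassigned = sorted(kept_ids - set(annotations))
        by_query = group_hits_by_query(kept_hits)
        otus, still_unassigned = bin_round2(
            unassigned, by_query, otus, fconfig, sample_of
        )
        matrix = build_count_matrix(otus, design)
        sconfig = SparsityConfig(
            min_replicates=config.min_replicates,
            max_concentration=config.max_concentration,
            min_total_normalized=config.min_total_normalized,
        )
        retained, flags = sparsity_filter(matrix, sconfig)
        size_factors = size_factors_median_of_ratios(retained)
        retained = abundance_retention(retained, size_factors, sconfig)
        matrix.to_csv(out / "counts_raw.tsv", sep="\t")
        retained.to_csv(out / "counts.tsv", sep="\t")
        flags.to_csv(out / "otu_flags.tsv", sep="\t", index=False)
        write_otu_annotations(otus, tree, out / "otus.tsv")
        record("bin", [out / "counts_raw.tsv", out / "counts.tsv",
                       out / "otu_flags.tsv", out / "otus.tsv"])

        # ------------------------------------------------------------- stats
        groups = {s.sample_id: s.treatment for s in design}
        size_factors = size_factors_median_of_ratios(retained)
        dist = bray_curtis(retained / size_factors)
        ordination = cap(dist, groups)
        f_stat, p_value = permanova(dist, groups, n_perm=config.permutations,
                                    seed=config.seed_permanova)
        diversity = diversity_report(retained)
        ttests = pd.concat(
            [
                group_ttest(diversity[idx], groups).assign(index=idx)
                for idx in diversity.columns
            ],
            ignore_index=True,
        )
        pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        ordination.coordinates.to_csv(out / "cap_coordinates.tsv", sep="\t")
        diversity.to_csv(out / "alpha_diversity.tsv", sep="\t")
        ttests.to_csv(out / "alpha_ttests.tsv", sep="\t", index=False)
        (out / "permanova.json").write_text(json.dumps(
            {"pseudo_F": f_stat, "p": p_value,
             "constrained_fraction": ordination.constrained_fraction}, indent=2,
        ))
        record("stats", [out / "bray_curtis.tsv", out / "cap_coordinates.tsv",
                         out / "alpha_diversity.tsv", out / "alpha_ttests.tsv",
                         out / "permanova.json"])

        # ---------------------------------------------------------------- da
        da_results = run_differential_abundance(retained, groups, size_factors)
        da_paths = []
        for contrast, rows in da_results.items():
            path = out / f"da_{contrast[0]}_vs_{contrast[1]}.tsv"
            results_frame(rows).to_csv(path, sep="\t", index=False)
            da_paths.append(path)
        summary = pairwise_da_summary(da_results, alpha=config.alpha,
                                      n_retained=len(retained))
        summary_path = out / "da_summary.json"
        summary_path.write_text(json.dumps(
            {**summary,
             "per_contrast": {f"{a}_vs_{b}": v
                              for (a, b), v in summary["per_contrast"].items()}},
            indent=2,
        ))
        record("da", da_paths + [summary_path])

        # -------------------------------------------------------------- tree
        read_sequences = {
            rec.id: str(rec.seq) for recs in reads.values() for rec in recs
        }
        tree_paths = []
        target = _tree_target_otu(otus, retained.index, read_sequences)
        if target is not None:
            subotus = unpack_otu(target, read_sequences)
            spike_accs = target.accessions
            spikes = {
                f"spike {r.label} {r.accession}": r.sequence
                for r in refs if r.accession in spike_accs
            }
            _, newick = spike_and_tree(
                subotus, spikes, threshold=config.tree_threshold,
                n_boot=config.bootstrap, seed=config.seed_bootstrap,
            )
            tree_path = out / "subotu_tree.nwk"
            tree_path.write_text(newick + "\n")
            tree_paths.append(tree_path)
        subotu_table = out / "subotus.tsv"
        _write_subotu_table(otus, retained.index, read_sequences, subotu_table)
        tree_paths.append(subotu_table)
        record("tree", tree_paths)
    except Exception as exc:
        stage = STAGES[len(stage_outputs)] if len(stage_outputs) < len(STAGES) else "?"
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["n_stages"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _treatment_profile(refs, seed: int) -> dict[str, list[float]]:
    """Per-treatment species weights: a shared log-normal baseline with
    2-4 fold shifts for a subset of species under each metal treatment."""
    import numpy as np

    rng = np.random.default_rng(seed + 7)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(refs))
    profile = {"control": base.tolist()}
    for t, strength in (("Pb", 0.0), ("Zn", 1.0), ("Cu", 1.0), ("three_metal", 2.0)):
        shifted = base.copy()
        if strength > 0:
            affected = rng.choice(len(refs), size=max(1, len(refs) // 4),
                                  replace=False)
            shifted[affected] *= np.power(
                2.0, strength * rng.choice([-1.0, 1.0], size=affected.size)
            )
        profile[t] = shifted.tolist()
    return profile


def _tree_target_otu(otus, retained_ids, read_sequences):
    """Pick the retained OTU with the most distinct member sequences."""
    best, best_count = None, 1
    retained = set(retained_ids)
    for otu in otus:
        if otu.otu_id not in retained:
            continue
        distinct = len({
            read_sequences[r] for reads in otu.member_reads.values() for r in reads
        })
        if distinct > best_count:
            best, best_count = otu, distinct
    return best


def _write_subotu_table(otus, retained_ids, read_sequences, path) -> None:
    rows = []
    retained = set(retained_ids)
    for otu in sorted(otus, key=lambda o: o.otu_id):
        if otu.otu_id not in retained:
            continue
        for sub in unpack_otu(otu, read_sequences):
            rows.append(
                {"otu_id": otu.otu_id, "subotu_id": sub.subotu_id,
                 "n_reads": len(sub.member_reads),
                 "n_accessions": len(sub.accession_set)}
            )
    pd.DataFrame(
        rows, columns=["otu_id", "subotu_id", "n_reads", "n_accessions"]
    ).to_csv(path, sep="\t", index=False)
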