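"""Negative-binomial Wald tests for pairwise differential abundance.

Counts for OTU i in sample j are modeled as NB with mean s_j * q_{g(j)}
(s_j the sample's size factor, q the group abundance on the normalized
scale) and variance mu + alpha_i * mu^2.  Per-OTU dispersions alpha_i come
from a method-of-moments estimate shrunk toward a fitted mean-dispersion
trend; group means are then fit by Newton iteration on the log scale with
the dispersion held fixed, and the log2 fold change is tested against its
standard error from the expected Fisher information.  Benjamini-Hochberg
adjustment is applied within each pairwise contrast, and an OTU is called
differentially abundant only when both the raw and the adjusted p fall
below the significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .errors import ArgumentError
from .simulate import TREATMENTS

logger = logging.getLogger(__name__)

#: Lower bound on a shrunk dispersion.
DISPERSION_FLOOR = 1e-8

#: Normalized-count floor applied to a group with all-zero counts so the
#: Wald statistic of an "infinite" fold change remains finite.
ZERO_GROUP_PSEUDO_MEAN = 0.5

#: Geometric shrinkage weight of the raw dispersion toward the trend.
SHRINKAGE_WEIGHT = 0.5

STATUS_TESTED = "tested"
STATUS_ALLZERO = "untested_allzero"
STATUS_INFINITE = "infinite_fc"


@dataclass(frozen=True)
class DispersionEstimate:
    otu_id: str
    raw_dispersion: float
    fitted_dispersion: float
    final_dispersion: float


@dataclass(frozen=True)
class DAResult:
    otu_id: str
    contrast: tuple[str, str]  # (a, b); log2fc is b over a
    base_mean: float
    log2fc: float
    lfc_se: float
    wald_stat: float
    pvalue: float
    padj: float
    status: str

    @property
    def fc_display(self) -> str:
        """CSV encoding; infinite fold changes render as +INF/-INF."""
        if self.status == STATUS_INFINITE:
            return "+INF" if self.log2fc > 0 else "-INF"
        return f"{self.log2fc:.4f}"


def estimate_dispersions(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    groups: Mapping[str, str],
) -> list[DispersionEstimate]:
    """Moments + trend + shrinkage dispersion estimates per OTU.

    Raw alpha_i pools the within-group excess variance of normalized
    counts, alpha = max(0, (s^2 - mean)/mean^2), weighted by group degrees
    of freedom.  A trend alpha(mu) = a1/mu + a0 is fit to the raw values by
    robust (Huber) regression on 1/mu, and the final estimate is the
    geometric mean of raw and trend (weight 0.5), floored at 1e-8.
    All-zero OTUs receive no estimate.
    """
    factors = size_factors.reindex(matrix.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ArgumentError("positive size factors required for every sample")
    labels = np.asarray([groups[s] for s in matrix.columns])
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise ArgumentError(f"group {g!r} has fewer than 2 samples")
    norm = matrix.to_numpy(dtype=float) / factors.to_numpy()

    otu_ids, raw_list, mean_list = [], [], []
    for i, otu_id in enumerate(matrix.index):
        row = norm[i]
        if row.sum() == 0:
            continue
        num = den = 0.0
        for g in np.unique(labels):
            vals = row[labels == g]
            m = vals.mean()
            if len(vals) < 2 or m == 0:
                continue
            s2 = vals.var(ddof=1)
            df = len(vals) - 1
            num += df * (s2 - m) / (m * m)
            den += df
        alpha_raw = max(0.0, num / den) if den > 0 else 0.0
        otu_ids.append(otu_id)
        raw_list.append(alpha_raw)
        mean_list.append(row.mean())

    raw = np.asarray(raw_list)
    mu = np.asarray(mean_list)
    a0, a1 = _fit_dispersion_trend(raw, mu)
    out = []
    for otu_id, alpha_raw, m in zip(otu_ids, raw, mu):
        fitted = max(a0 + a1 / m, DISPERSION_FLOOR)
        final = float(
            np.exp(
                (1 - SHRINKAGE_WEIGHT) * np.log(max(alpha_raw, DISPERSION_FLOOR))
                + SHRINKAGE_WEIGHT * np.log(fitted)
            )
        )
        out.append(
            DispersionEstimate(otu_id, float(alpha_raw), float(fitted),
                               max(final, DISPERSION_FLOOR))
        )
    return out


def _fit_dispersion_trend(raw: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha(mu) = a0 + a1/mu over OTUs with positive raw alpha."""
    usable = raw > DISPERSION_FLOOR
    if usable.sum() < 10:
        # too few informative OTUs for a trend; fall back to a flat line at
        # the median positive raw value (or the floor)
        level = float(np.median(raw[usable])) if usable.any() else DISPERSION_FLOOR
        return max(level, DISPERSION_FLOOR), 0.0
    x = sm.add_constant(1.0 / mu[usable])
    try:
        fit = sm.RLM(raw[usable], x, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    except Exception:  # pragma: no cover - singular design fallback
        a0, a1 = float(np.median(raw[usable])), 0.0
    return max(a0, DISPERSION_FLOOR), max(a1, 0.0)


def _fit_group_mean(
    counts: np.ndarray, factors: np.ndarray, alpha: float,
    floor: float | None = None,
) -> tuple[float, float]:
    """NB log-link mean fit for one group with fixed dispersion.

    Returns (q, information) where q is the normalized-scale group mean and
    information is the expected Fisher information of ln q.  ``floor``
    bounds q from below (used for all-zero groups).
    """
    start = counts.sum() / factors.sum()
    if floor is not None:
        start = max(start, floor)
    beta = np.log(max(start, 1e-8))
    for _ in range(50):
        mu = factors * np.exp(beta)
        w = 1.0 + alpha * mu
        score = float(((counts - mu) / w).sum())
        info = float((mu / w).sum())
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5, 5)
        if floor is not None:
            beta = max(beta, np.log(floor))
        if abs(step) < 1e-12:
            break
    q = float(np.exp(beta))
    mu = factors * q
    info = float((mu / (1.0 + alpha * mu)).sum())
    return q, info


def wald_test(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: Sequence[DispersionEstimate],
    contrast: tuple[str, str],
    groups: Mapping[str, str],
) -> list[DAResult]:
    """Two-group NB Wald test of log2 fold change (group b over group a).

    OTUs with zero counts in exactly one of the two groups are reported
    with status ``infinite_fc`` (sign from the nonzero group); their
    p-value comes from the same fit with the zero group's normalized mean
    floored at 0.5.  OTUs zero in both groups are ``untested_allzero``.
    ``padj`` is filled with NaN here; apply :func:`bh_adjust` per contrast.
    """
    a, b = contrast
    labels = {s: groups[s] for s in matrix.columns}
    cols_a = [s for s in matrix.columns if labels[s] == a]
    cols_b = [s for s in matrix.columns if labels[s] == b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ArgumentError(f"contrast {contrast} needs >=2 samples per group")
    factors = size_factors.reindex(matrix.columns)
    fa = factors[cols_a].to_numpy()
    fb = factors[cols_b].to_numpy()
    disp = {d.otu_id: d.final_dispersion for d in dispersions}
    norm_all = (matrix / factors).mean(axis=1)

    results = []
    ln2 = np.log(2.0)
    for otu_id in matrix.index:
        ka = matrix.loc[otu_id, cols_a].to_numpy(dtype=float)
        kb = matrix.loc[otu_id, cols_b].to_numpy(dtype=float)
        base_mean = float(norm_all[otu_id])
        zero_a, zero_b = ka.sum() == 0, kb.sum() == 0
        if zero_a and zero_b:
            results.append(
                DAResult(otu_id, contrast, base_mean, 0.0, np.nan, np.nan,
                         np.nan, np.nan, STATUS_ALLZERO)
            )
            continue
        alpha = disp.get(otu_id, DISPERSION_FLOOR)
        floor_a = ZERO_GROUP_PSEUDO_MEAN if zero_a else None
        floor_b = ZERO_GROUP_PSEUDO_MEAN if zero_b else None
        qa, ia = _fit_group_mean(ka, fa, alpha, floor=floor_a)
        qb, ib = _fit_group_mean(kb, fb, alpha, floor=floor_b)
        log2fc = float(np.log(qb / qa) / ln2)
        se = float(np.sqrt(1.0 / ia + 1.0 / ib) / ln2)
        stat = log2fc / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(stat)))
        status = STATUS_INFINITE if (zero_a or zero_b) else STATUS_TESTED
        if status == STATUS_INFINITE and log2fc == 0.0:
            # sign carried by the nonzero group even if the floored fit ties
            log2fc = 1e-9 if zero_a else -1e-9
        results.append(
            DAResult(otu_id, contrast, base_mean, log2fc, se, stat, p,
                     np.nan, status)
        )
    return results


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries (untested OTUs) are excluded from the family size m and
    returned as NaN.
    """
    arr = np.asarray(pvalues, dtype=float)
    tested = ~np.isnan(arr)
    if np.any((arr[tested] < 0) | (arr[tested] > 1)):
        raise ArgumentError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if tested.any():
        out[tested] = multipletests(arr[tested], method="fdr_bh")[1]
    return out.tolist()


def adjust_results(results: Sequence[DAResult]) -> list[DAResult]:
    """Fill ``padj`` by BH over the tested p-values of one contrast family."""
    padj = bh_adjust([r.pvalue for r in results])
    return [
        DAResult(r.otu_id, r.contrast, r.base_mean, r.log2fc, r.lfc_se,
                 r.wald_stat, r.pvalue, q, r.status)
        for r, q in zip(results, padj)
    ]


def all_pairwise_contrasts(treatments: Sequence[str] = TREATMENTS) -> list[tuple[str, str]]:
    return list(combinations(treatments, 2))


def run_differential_abundance(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    size_factors: pd.Series | None = None,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], list[DAResult]]:
    """Dispersions once, then Wald + per-contrast BH for every treatment pair."""
    from .stats import size_factors_median_of_ratios

    if size_factors is None:
        size_factors = size_factors_median_of_ratios(matrix)
    present = sorted({groups[s] for s in matrix.columns})
    if contrasts is None:
        contrasts = [c for c in all_pairwise_contrasts() if c[0] in present and c[1] in present]
        if not contrasts:
            contrasts = list(combinations(present, 2))
    dispersions = estimate_dispersions(matrix, size_factors, groups)
    return {
        contrast: adjust_results(
            wald_test(matrix, size_factors, dispersions, contrast, groups)
        )
        for contrast in contrasts
    }


def is_da(result: DAResult, alpha: float = 0.05) -> bool:
    """Differential abundance requires raw p AND adjusted p below alpha."""
    return (
        result.status in (STATUS_TESTED, STATUS_INFINITE)
        and not np.isnan(result.pvalue)
        and result.pvalue < alpha
        and not np.isnan(result.padj)
        and result.padj < alpha
    )


def pairwise_da_summary(
    results: Mapping[tuple[str, str], Sequence[DAResult]],
    alpha: float = 0.05,
    n_retained: int | None = None,
) -> dict:
    """Bookkeeping over all pairwise contrasts.

    Returns per-contrast DA counts, the total number of DA instances, the
    number of distinct DA OTUs, and (when ``n_retained`` is given) the
    non-DA fraction of retained OTUs as a rounded percent.
    """
    per_contrast = {}
    distinct: set[str] = set()
    for contrast, rows in results.items():
        da = [r.otu_id for r in rows if is_da(r, alpha)]
        per_contrast[contrast] = len(da)
        distinct.update(da)
    summary = {
        "per_contrast": per_contrast,
        "total_instances": int(sum(per_contrast.values())),
        "distinct_da_otus": len(distinct),
        "da_otu_ids": sorted(distinct),
    }
    if n_retained is not None:
        non_da = n_retained - len(distinct)
        summary["non_da_otus"] = non_da
        summary["non_da_fraction"] = non_da / n_retained
        summary["non_da_percent"] = round(100.0 * non_da / n_retained)
    return summary


def vst_transform(matrix: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Shifted-log transform log2(count/size_factor + 1).

    A variance-flattening transform for diagnostics and plotting only;
    the Wald tests always run on raw counts.
    """
    factors = size_factors.reindex(matrix.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ArgumentError("positive size factors required for every sample")
    return np.log2(matrix / factors + 1.0)


def results_frame(results: Sequence[DAResult]) -> pd.DataFrame:
    """Tabular form of one contrast's results; infinite FCs encoded +/-INF."""
    return pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "base_mean": r.base_mean,
                "log2fc": r.fc_display,
                "lfc_se": r.lfc_se,
                "stat": r.wald_stat,
                "pvalue": r.pvalue,
                "padj": r.padj,
                "status": r.status,
            }
            for r in results
        ]
    )
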