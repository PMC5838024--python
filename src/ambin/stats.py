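"""Community-level statistics.

Covers median-of-ratios library-size normalization, six alpha-diversity
indices with pairwise Welch t-tests between treatment groups, Bray-Curtis
dissimilarities, unconstrained (PCoA) and group-constrained (CAP)
ordination, and a permutational multivariate analysis of variance
(PERMANOVA) on the distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .errors import ArgumentError

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("observed", "chao1", "shannon", "simpson", "inv_simpson", "fisher_alpha")


@dataclass
class OrdinationResult:
    """Sample coordinates on axes ordered by descending eigenvalue.

    ``eigenvalues`` includes negative values for PCoA (their axes are
    dropped from ``coordinates``).  ``constrained_fraction`` and
    ``permanova`` are populated by CAP / PERMANOVA respectively.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    constrained_fraction: float | None = None
    permanova: tuple[float, float] | None = None  # (pseudo_F, p)


# ------------------------------------------------------------ normalization

def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors.

    s_j = median over reference OTUs of count_ij / geomean_i, where the
    reference set is the OTUs with strictly positive counts in every
    sample.  When no all-positive row exists, geometric means are taken
    over positive entries only and the median over rows with a positive
    count in that sample (logged as a warning).
    """
    if matrix.empty:
        raise ArgumentError("cannot compute size factors of an empty matrix")
    counts = matrix.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref = counts[all_positive]
        log_geomean = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_geomean[:, None]
        factors = np.exp(np.median(log_ratios, axis=0))
    else:
        logger.warning(
            "no OTU with positive counts in every sample; falling back to "
            "positive-entry geometric means"
        )
        logs = np.where(counts > 0, np.log(np.where(counts > 0, counts, 1.0)),
                        np.nan)
        log_geomean = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_geomean)
        if not usable.any():
            raise ArgumentError("matrix has no positive counts")
        log_ratios = logs[usable] - log_geomean[usable, None]
        factors = np.exp(np.nanmedian(log_ratios, axis=0))
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ArgumentError("size factor computation produced nonpositive values")
    return pd.Series(factors, index=matrix.columns, name="size_factor")


# ---------------------------------------------------------- alpha diversity

def fisher_alpha(n_species: int, n_individuals: int, tol: float = 1e-12) -> float:
    """The unique alpha > 0 solving S = alpha * ln(1 + N/alpha)."""
    s, n = float(n_species), float(n_individuals)
    if s <= 0 or n <= 0:
        raise ArgumentError("fisher_alpha requires S > 0 and N > 0")
    if s >= n:
        raise ArgumentError("fisher_alpha undefined when S >= N (all singletons)")
    f = lambda a: a * np.log1p(n / a) - s  # noqa: E731
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10
        if hi > 1e15:
            raise ArgumentError("fisher_alpha failed to bracket a root")
    return float(brentq(f, lo, hi, xtol=tol))


def alpha_diversity(counts: Sequence[float]) -> dict[str, float]:
    """Six diversity indices for one sample's count vector.

    observed richness; Chao1 = S + F1(F1-1)/(2(F2+1)); Shannon H (natural
    log); Simpson 1 - sum p^2; inverse Simpson 1 / sum p^2; Fisher's alpha
    (NaN when every individual is a singleton, where the estimator
    diverges).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ArgumentError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ArgumentError("all-zero count vector")
    present = c[c > 0]
    observed = int(present.size)
    p = present / total
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p ** 2).sum())
    simpson = 1.0 - sum_p2
    inv_simpson = 1.0 / sum_p2
    f1 = int((present == 1).sum())
    f2 = int((present == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    try:
        fisher = fisher_alpha(observed, int(total))
    except ArgumentError:
        fisher = float("nan")
    return {
        "observed": observed,
        "chao1": chao1,
        "shannon": shannon,
        "simpson": simpson,
        "inv_simpson": inv_simpson,
        "fisher_alpha": fisher,
    }


def diversity_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample table of the six alpha-diversity indices (samples = columns)."""
    rows = {s: alpha_diversity(matrix[s].to_numpy()) for s in matrix.columns}
    return pd.DataFrame.from_dict(rows, orient="index")[list(ALPHA_INDICES)]


def group_ttest(
    values: pd.Series, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Welch two-sample t-test for every pair of treatment groups.

    Degenerate cases are handled explicitly: equal group means give
    (t=0, p=1) even at zero variance; unequal means with zero variance in
    both groups give the limit (t=+/-inf, p=0) and are flagged in the
    ``degenerate`` column.
    """
    by_group: dict[str, list[float]] = {}
    for sample, value in values.items():
        by_group.setdefault(groups[sample], []).append(float(value))
    out = []
    for a, b in combinations(sorted(by_group), 2):
        xa, xb = np.asarray(by_group[a]), np.asarray(by_group[b])
        if len(xa) < 2 or len(xb) < 2:
            raise ArgumentError(f"group {a if len(xa) < 2 else b!r} has <2 samples")
        degenerate = False
        if np.isclose(xa.mean(), xb.mean()):
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
                degenerate = True
            t, p = 0.0, 1.0
        elif xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            t = np.inf if xb.mean() < xa.mean() else -np.inf
            p, degenerate = 0.0, True
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        out.append(
            {"group_a": a, "group_b": b, "t": float(t), "p": float(p),
             "degenerate": degenerate}
        )
    return pd.DataFrame(out)


# ----------------------------------------------------------- beta diversity

def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns of the matrix).

    d(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b), in [0, 1].
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ArgumentError(f"sample(s) with zero total counts: {list(zero.index)}")
    data = matrix.to_numpy(dtype=float).T  # samples x OTUs
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(matrix.columns))


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * centering @ d_squared @ centering


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Negative eigenvalues are
    reported in ``eigenvalues`` but their axes are dropped (no Lingoes or
    Cailliez correction).
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ArgumentError("distance matrix must be symmetric")
    gower = _gower_center(d ** 2)
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    frame = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(coordinates=frame, eigenvalues=eigvals)


def cap(dist: DistanceMatrix, groups: Mapping[str, str]) -> OrdinationResult:
    """Constrained analysis of principal coordinates.

    PCoA sample scores are projected onto the span of the group indicator
    variables; the eigendecomposition of the fitted scores yields at most
    (number of groups - 1) constrained axes.  ``constrained_fraction`` is
    the constrained inertia over the total positive PCoA inertia.
    """
    labels = [groups[s] for s in dist.ids]
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ArgumentError("CAP requires at least two groups")
    base = pcoa(dist)
    y = base.coordinates.to_numpy()
    x = np.stack([np.asarray(labels) == g for g in unique], axis=1).astype(float)
    # projection onto the group-indicator span (equivalently, group means)
    hat = x @ np.linalg.pinv(x.T @ x) @ x.T
    fitted = hat @ y
    u, singular, _ = np.linalg.svd(fitted, full_matrices=False)
    eigvals = singular ** 2
    keep = eigvals > max(eigvals.max(), 0) * 1e-12 if eigvals.size else np.array([], bool)
    keep &= np.arange(eigvals.size) < len(unique) - 1
    coords = u[:, keep] * singular[keep]
    total_inertia = float((y ** 2).sum())
    frame = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"CAP{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=eigvals[keep],
        constrained_fraction=float((fitted ** 2).sum() / total_inertia),
    )


def _permanova_ss(
    d_squared: np.ndarray, masks: np.ndarray, group_sizes: np.ndarray
) -> np.ndarray:
    """Within-group sum of squares for each row of group masks.

    ``masks`` has shape (n_perm, n_groups, n_samples) of 0/1 indicators.
    """
    # SSW = sum_g (1 / 2 n_g) * m_g' D2 m_g
    quad = np.einsum("pgi,ij,pgj->pg", masks, d_squared, masks)
    return (quad / (2.0 * group_sizes)).sum(axis=1)


def permanova(
    dist: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    strata: Mapping[str, object] | None = None,
) -> tuple[float, float]:
    """Distance-based permutational MANOVA.

    pseudo-F = (SSB/(g-1)) / (SSW/(n-g)) from the between/within partition
    of squared distances; p = (1 + #{F* >= F}) / (1 + n_perm) over random
    label permutations.  ``strata`` restricts permutations to shuffles
    within each stratum (e.g. blocks of a split-plot design); the default
    permutes labels freely.
    """
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    ids = list(dist.ids)
    labels = np.asarray([groups[s] for s in ids])
    unique = sorted(set(labels))
    n, g = len(ids), len(unique)
    if g < 2:
        raise ArgumentError("PERMANOVA requires at least two groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    sst = d2.sum() / (2.0 * n)

    group_sizes = np.array([(labels == u).sum() for u in unique], dtype=float)

    def masks_for(label_rows: np.ndarray) -> np.ndarray:
        return np.stack(
            [label_rows == u for u in unique], axis=1
        ).astype(float)  # (P, g, n)

    obs_masks = masks_for(labels[None, :])
    ssw_obs = _permanova_ss(d2, obs_masks, group_sizes)[0]
    f_obs = ((sst - ssw_obs) / (g - 1)) / (ssw_obs / (n - g))

    rng = np.random.default_rng(seed)
    perm_labels = np.tile(labels, (n_perm, 1))
    if strata is None:
        perm_labels = rng.permuted(perm_labels, axis=1)
    else:
        strata_of = np.asarray([strata[s] for s in ids])
        for stratum in np.unique(strata_of):
            idx = np.flatnonzero(strata_of == stratum)
            shuffled = rng.permuted(perm_labels[:, idx], axis=1)
            perm_labels[:, idx] = shuffled
    ssw_perm = _permanova_ss(d2, masks_for(perm_labels), group_sizes)
    f_perm = ((sst - ssw_perm) / (g - 1)) / (ssw_perm / (n - g))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(f_obs), float(p)
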