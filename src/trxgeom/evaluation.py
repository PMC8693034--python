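"""Contact evaluation and the resampling-based method comparison.

Contacts are residue pairs with Cb-Cb distance <= 8 A.  A predicted
distance distribution is converted to a contact probability by summing the
distance bins at or below the cutoff.  Precision is assessed on the top
L/k ranked pairs within a sequence-separation class: short [6, 12),
medium [12, 24), long [24, inf); the widely used "top L, separation >= 12"
metric is the union of medium and long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from trxgeom.geometry_spec import DEFAULT_SPEC, GeometrySpec

SEPARATION_CLASSES = {
    "short": (6, 12),
    "medium": (12, 24),
    "long": (24, None),
    "medium_long": (12, None),
}


def contact_probability(p_dist: np.ndarray,
                        spec: GeometrySpec = DEFAULT_SPEC) -> np.ndarray:
    """P(contact) = sum of distance-bin probabilities with d <= 8 A."""
    if p_dist.shape[-1] != spec.n_dist_bins:
        raise ValueError(
            f"expected {spec.n_dist_bins} distance bins, got {p_dist.shape[-1]}"
        )
    return p_dist[..., spec.contact_bin_slice()].sum(axis=-1)


def class_pairs(L: int, sep: str | tuple) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of pairs i < j within a separation class."""
    lo, hi = SEPARATION_CLASSES[sep] if isinstance(sep, str) else sep
    iu, ju = np.triu_indices(L, k=lo)
    if hi is not None:
        keep = (ju - iu) < hi
        iu, ju = iu[keep], ju[keep]
    return iu, ju


def topk_precision(cp: np.ndarray, true_d: np.ndarray, k: int,
                   sep: str | tuple = "medium_long",
                   contact_cutoff: float = 8.0) -> float:
    """Precision of the k top-ranked predicted contacts in a class.

    Pairs i < j rank by descending contact probability with ties broken by
    ascending (i, j); the denominator is min(k, pairs available).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = cp.shape[0]
    iu, ju = class_pairs(L, sep)
    if len(iu) == 0:
        raise ValueError(f"no residue pairs in separation class {sep!r}")
    order = np.lexsort((ju, iu, -cp[iu, ju]))
    kk = min(k, len(iu))
    top = order[:kk]
    hits = (true_d[iu[top], ju[top]] <= contact_cutoff).sum()
    return float(hits) / kk


def contact_density(true_d: np.ndarray, sep: str | tuple = "medium_long",
                    contact_cutoff: float = 8.0) -> float:
    """Fraction of true contacts among all pairs of a separation class."""
    iu, ju = class_pairs(true_d.shape[0], sep)
    if len(iu) == 0:
        raise ValueError(f"no residue pairs in separation class {sep!r}")
    return float((true_d[iu, ju] <= contact_cutoff).mean())


@dataclass
class ComparisonResult:
    significant: bool
    pvalue: float
    test: str           # "paired-t" or "wilcoxon"
    mean_difference: float


def method_comparison(scores_a, scores_b, reps: int = 10, alpha: float = 0.05,
                      rng: np.random.Generator | None = None
                      ) -> ComparisonResult:
    """Half-resampling significance protocol for paired per-target scores.

    ``reps`` times, half of the targets are drawn at random and the mean
    score of each method over that half is recorded, giving ``reps`` paired
    means.  If the Anderson-Darling test accepts normality of their
    differences (5% level), a two-tailed paired t-test is applied;
    otherwise the Wilcoxon signed-rank test.  Differences below p < alpha
    are significant.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    n = len(a)
    if n < 4:
        raise ValueError("need at least 4 paired scores")
    rng = rng or np.random.default_rng(0)
    half = n // 2
    means_a = np.empty(reps)
    means_b = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(n, size=half, replace=False)
        means_a[r] = a[idx].mean()
        means_b[r] = b[idx].mean()
    diffs = means_a - means_b

    if np.allclose(diffs, 0.0):
        return ComparisonResult(False, 1.0, "degenerate", 0.0)
    if np.ptp(diffs) < 1e-12:
        # constant nonzero difference: infinitely strong paired evidence
        return ComparisonResult(True, 0.0, "degenerate", float(diffs.mean()))

    try:
        ad = stats.anderson(diffs, dist="norm", method="interpolate")
        looks_normal = ad.pvalue > 0.05
    except TypeError:  # older scipy without the method parameter
        ad = stats.anderson(diffs, dist="norm")
        crit_5 = ad.critical_values[list(ad.significance_level).index(5.0)]
        looks_normal = ad.statistic <= crit_5
    if looks_normal:
        test = "paired-t"
        pvalue = float(stats.ttest_rel(means_a, means_b).pvalue)
    else:
        test = "wilcoxon"
        pvalue = float(stats.wilcoxon(means_a, means_b).pvalue)
    return ComparisonResult(pvalue < alpha, pvalue, test, float(diffs.mean()))
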