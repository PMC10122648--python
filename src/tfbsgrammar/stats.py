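"""The grammar statistics battery.

Orientation, order, copy-number, position and variance effects on tile
expression, with Bonferroni correction throughout and a seeded Monte-Carlo
permutation test for the copy-number-dependent gain in orientation
asymmetry.  Effect ratios are reported on the linear activity scale
(``2**expression``) so that "x% higher activity" statements are
well-defined; mean differences are reported on the log2 scale alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .motifs import at_skew, gc_skew  # re-exported convenience

__all__ = [
    "AsymmetryResult",
    "TrendResult",
    "bonferroni_adjust",
    "orientation_asymmetry_test",
    "order_effect_test",
    "variance_difference_test",
    "copy_number_trend",
    "position_trend",
    "monte_carlo_gain_test",
    "config_anova",
    "skew_asymmetry_association",
    "gc_skew",
    "at_skew",
]


@dataclass(frozen=True)
class AsymmetryResult:
    """A two-group strand/order statistic."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    ratio: float  # mean linear activity, group2 / group1 (e.g. NT / T)
    difference: float  # mean log2 difference, group2 - group1
    relative_difference: float  # |difference|
    p_raw: float
    p_adjusted: float
    m_tests: int
    test_name: str


@dataclass(frozen=True)
class TrendResult:
    predictor: str
    rho: float
    p_raw: float
    p_adjusted: float
    m_tests: int
    n: int
    percent_change: float | None = None
    undefined: bool = False


def bonferroni_adjust(p_values, m: int):
    """min(1, p * m); ``m`` may exceed the number of supplied p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    out = np.minimum(1.0, p * m)
    return float(out) if np.isscalar(p_values) or p.ndim == 0 else out


def _two_groups(a, b, labels, min_n):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for arr, lab in ((a, labels[0]), (b, labels[1])):
        if arr.size < min_n:
            raise ValueError(f"group {lab!r} has n={arr.size} < {min_n}")
    return a, b


def _asym_result(a, b, labels, p_raw, m_tests, test_name):
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    lin_a, lin_b = float(np.mean(2.0**a)), float(np.mean(2.0**b))
    diff = mean_b - mean_a
    return AsymmetryResult(
        group_labels=tuple(labels),
        n=(a.size, b.size),
        means=(mean_a, mean_b),
        ratio=lin_b / lin_a if lin_a != 0 else float("inf"),
        difference=diff,
        relative_difference=abs(diff),
        p_raw=float(p_raw),
        p_adjusted=float(bonferroni_adjust(p_raw, m_tests)),
        m_tests=m_tests,
        test_name=test_name,
    )


def orientation_asymmetry_test(
    expr_t, expr_nt, m_tests: int = 1, equal_var: bool = True
) -> AsymmetryResult:
    """Two-sided two-sample t-test between template and non-template tiles.

    Student's t by default; ``equal_var=False`` switches to Welch.  Ratio is
    mean(NT)/mean(T) on the linear activity scale, difference NT - T on the
    log2 scale.
    """
    a, b = _two_groups(expr_t, expr_nt, ("template", "non-template"), 2)
    stat = sps.ttest_ind(b, a, equal_var=equal_var)
    p = 1.0 if np.isnan(stat.pvalue) else stat.pvalue
    name = "t-test" if equal_var else "welch-t"
    return _asym_result(a, b, ("T", "NT"), p, m_tests, name)


def order_effect_test(expr_order_ab, expr_order_ba, m_tests: int = 1,
                      labels: tuple[str, str] = ("AB", "BA"),
                      equal_var: bool = True) -> AsymmetryResult:
    """Orientation-test machinery keyed by pair order instead of strand."""
    a, b = _two_groups(expr_order_ab, expr_order_ba, labels, 2)
    stat = sps.ttest_ind(b, a, equal_var=equal_var)
    p = 1.0 if np.isnan(stat.pvalue) else stat.pvalue
    return _asym_result(a, b, labels, p, m_tests, "t-test(order)")


def variance_difference_test(expr_t, expr_nt, m_tests: int = 1,
                             center: str = "median") -> AsymmetryResult:
    """Levene test (median-centered by default) between orientation groups."""
    a, b = _two_groups(expr_t, expr_nt, ("template", "non-template"), 3)
    if np.array_equal(a, b) and np.all(a == a[0]):
        p = 1.0
    else:
        stat = sps.levene(a, b, center=center)
        p = 1.0 if np.isnan(stat.pvalue) else stat.pvalue
    return _asym_result(a, b, ("T", "NT"), p, m_tests, f"levene({center})")


def copy_number_trend(copies, expression, m_tests: int = 1) -> TrendResult:
    """Spearman correlation between homotypic copy number and expression."""
    c = np.asarray(copies, dtype=float)
    e = np.asarray(expression, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct copy-number levels")
    if np.all(e == e[0]):
        return TrendResult("copies", float("nan"), 1.0, 1.0, m_tests, e.size,
                           undefined=True)
    rho, p = sps.spearmanr(c, e)
    return TrendResult("copies", float(rho), float(p),
                       float(bonferroni_adjust(p, m_tests)), m_tests, e.size)


def position_trend(position_bins, expression, m_tests: int = 1,
                   near_bin: int = -40, far_bin: int = -200) -> TrendResult:
    """Spearman trend of TSS-relative bin position vs expression.

    Also reports the percent change of the mean linear activity in the
    promoter-proximal bin (default [-40, 0)) relative to the distal bin
    (default [-200, -160)); ``None`` (undefined flag) if either bin is empty.
    """
    b = np.asarray(position_bins, dtype=float)
    e = np.asarray(expression, dtype=float)
    if np.unique(b).size < 3:
        raise ValueError("need at least 3 populated position bins")
    if np.all(e == e[0]):
        rho, p = 0.0, 1.0
    else:
        rho, p = sps.spearmanr(b, e)
    near = 2.0 ** e[b == near_bin]
    far = 2.0 ** e[b == far_bin]
    if near.size and far.size:
        pct: float | None = 100.0 * (near.mean() - far.mean()) / far.mean()
        undefined = False
    else:
        pct, undefined = None, True
    return TrendResult("position_bin", float(rho), float(p),
                       float(bonferroni_adjust(p, m_tests)), m_tests, e.size,
                       percent_change=pct, undefined=undefined)


def monte_carlo_gain_test(
    expr_t_1copy, expr_nt_1copy, expr_t_4copy, expr_nt_4copy,
    n_perm: int = 10000, seed: int = 0,
) -> float:
    """One-sided permutation p-value for a copy-number gain in asymmetry.

    Observed statistic: |mean NT - mean T| at 4 copies minus the same at 1
    copy.  The null permutes orientation labels independently within each
    copy-number stratum; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    g = [np.asarray(x, dtype=float) for x in
         (expr_t_1copy, expr_nt_1copy, expr_t_4copy, expr_nt_4copy)]
    for i, arr in enumerate(g):
        if arr.size < 2:
            raise ValueError(f"group {i} has n={arr.size} < 2")
    rng = np.random.default_rng(seed)

    def gap(t, nt):
        return abs(nt.mean() - t.mean())

    observed = gap(g[2], g[3]) - gap(g[0], g[1])

    def null_gaps(t, nt):
        pooled = np.concatenate([t, nt])
        n_t = t.size
        # one permutation per row, via argsort of uniforms
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        return np.abs(perm[:, n_t:].mean(axis=1) - perm[:, :n_t].mean(axis=1))

    null = null_gaps(g[2], g[3]) - null_gaps(g[0], g[1])
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))


def config_anova(groups: dict, m_tests: int = 1) -> tuple[float, float, float, dict]:
    """One-way ANOVA across configuration groups (orientations, slots...).

    Groups with n < 2 are dropped with a note; if fewer than two remain the
    call is rejected.  Returns ``(F, p_raw, p_adjusted, dropped)``.
    """
    kept, dropped = {}, {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        (kept if arr.size >= 2 else dropped)[label] = arr
    if len(kept) < 2:
        raise ValueError("fewer than two groups with n >= 2")
    arrays = list(kept.values())
    if all(np.all(a == arrays[0][0]) for a in arrays):
        f, p = 0.0, 1.0  # identical constant groups: no variance anywhere
    else:
        f, p = sps.f_oneway(*arrays)
        if np.isnan(p):
            f, p = 0.0, 1.0
    return float(f), float(p), float(bonferroni_adjust(p, m_tests)), dropped


def skew_asymmetry_association(skews, asymmetries) -> tuple[float, float]:
    """Kendall tau between per-motif kmer skew and orientation effect size."""
    s = np.asarray(skews, dtype=float)
    a = np.asarray(asymmetries, dtype=float)
    if s.size != a.size:
        raise ValueError("skews and asymmetries must align")
    if s.size < 5:
        raise ValueError("need at least 5 motifs for the association test")
    tau, p = sps.kendalltau(s, a)
    return float(tau), float(p)
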