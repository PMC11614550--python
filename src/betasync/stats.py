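"""Group-level statistics applied to pipeline outputs.

Normality is screened with a Kolmogorov-Smirnov test against a normal with
the sample's mean and SD; non-normal data are routed to rank-based
alternatives (Kruskal-Wallis with Dunn-Bonferroni, or Wilcoxon signed-rank
for paired designs).  Normal data get one- or two-way ANOVA with Bonferroni
all-pairs post-hoc comparisons, a two-tailed paired t for within-subject
contrasts, and a Pearson chi-square (df = 1, no continuity correction) for
locked-unit proportions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple
    p: float
    posthoc: list[dict] = field(default_factory=list)
    n_per_group: list[int] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        for row in self.posthoc:
            if row["p_adjusted"] < row["p_raw"] - 1e-12:
                raise ValueError("adjusted p below raw p")


def ks_normality(sample: np.ndarray) -> StatResult:
    """One-sample KS against N(mean, sd) of the sample; ``extra['normal']``
    is True when p >= .05.  Note the estimated-parameter version is
    conservative (true type-I rate below alpha)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("KS normality screen needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("degenerate sample (zero SD)")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult(
        test="ks_normality",
        statistic=float(stat),
        df=(x.size,),
        p=float(p),
        n_per_group=[x.size],
        extra={"normal": bool(p >= ALPHA)},
    )


def _bonferroni_pairs(groups: dict[str, np.ndarray]) -> list[dict]:
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b])
        out.append(
            {
                "pair": (a, b),
                "statistic": float(t),
                "p_raw": float(p),
                "p_adjusted": float(min(p * m, 1.0)),
            }
        )
    return out


def anova_bonferroni(groups: dict[str, np.ndarray]) -> StatResult:
    """One-way ANOVA with all-pairs Bonferroni-adjusted t comparisons."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    values = list(arrays.values())
    if all(np.allclose(a, values[0].mean()) for a in values) and all(
        a.std() == 0 for a in values
    ):
        # identical constant groups: no variance anywhere
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*values)
        if np.isnan(f):
            f, p = 0.0, 1.0
    n = sum(a.size for a in values)
    k = len(values)
    return StatResult(
        test="one_way_anova_bonferroni",
        statistic=float(f),
        df=(k - 1, n - k),
        p=float(p),
        posthoc=_bonferroni_pairs(arrays),
        n_per_group=[a.size for a in values],
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> StatResult:
    """Two-way ANOVA (type-II sums of squares) with interaction; the
    reported statistic/p are for ``factor_a``'s main effect, with the full
    table in ``extra``.  Requires a complete factorial layout."""
    counts = data.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("incomplete factorial design: empty cells")
    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({factor_a})"]
    posthoc = _bonferroni_pairs(
        {str(g): d[value].to_numpy() for g, d in data.groupby(factor_a, observed=True)}
    )
    return StatResult(
        test="two_way_anova_bonferroni",
        statistic=float(row["F"]),
        df=(int(row["df"]), int(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]),
        posthoc=posthoc,
        n_per_group=list(data.groupby(factor_a, observed=True).size()),
        extra={"anova_table": table.to_dict()},
    )


def paired_t(before: np.ndarray, after: np.ndarray) -> StatResult:
    """Two-tailed paired-sample t test (df = n - 1)."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs equal-length samples with n >= 2")
    d = b - a
    if np.allclose(d, d[0]) and d.std(ddof=1) == 0:
        if d[0] == 0:
            return StatResult(test="paired_t", statistic=0.0, df=(a.size - 1,), p=1.0, n_per_group=[a.size])
        raise DegenerateDataError("zero variance of nonzero differences")
    t, p = sps.ttest_rel(b, a)
    return StatResult(
        test="paired_t",
        statistic=float(t),
        df=(a.size - 1,),
        p=float(p),
        n_per_group=[a.size],
    )


def chi_square_2x2(
    locked_a: int, tested_a: int, locked_b: int, tested_b: int, correction: bool = False
) -> StatResult:
    """Pearson chi-square on the 2x2 locked/unlocked table (df = 1)."""
    if min(locked_a, locked_b, tested_a, tested_b) < 0 or locked_a > tested_a or locked_b > tested_b:
        raise ValueError("need 0 <= locked <= tested in both groups")
    table = np.array(
        [[locked_a, tested_a - locked_a], [locked_b, tested_b - locked_b]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=correction)
    return StatResult(
        test="chi_square_2x2",
        statistic=float(chi2),
        df=(int(dof),),
        p=float(p),
        n_per_group=[tested_a, tested_b],
    )


def kruskal_dunn(groups: dict[str, np.ndarray]) -> StatResult:
    """Kruskal-Wallis with Dunn-style pairwise Mann-Whitney comparisons,
    Bonferroni adjusted: the rank-based fallback for non-normal data."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    h, p = sps.kruskal(*arrays.values())
    pairs = list(itertools.combinations(arrays, 2))
    posthoc = []
    for a, b in pairs:
        u, pr = sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        posthoc.append(
            {"pair": (a, b), "statistic": float(u), "p_raw": float(pr), "p_adjusted": float(min(pr * len(pairs), 1.0))}
        )
    return StatResult(
        test="kruskal_wallis_dunn_bonferroni",
        statistic=float(h),
        df=(len(arrays) - 1,),
        p=float(p),
        posthoc=posthoc,
        n_per_group=[a.size for a in arrays.values()],
    )


def compare_groups(groups: dict[str, np.ndarray]) -> StatResult:
    """Normality-screened comparison: ANOVA when every group passes the KS
    screen (or is too small to screen), Kruskal-Wallis otherwise."""
    normal = True
    for v in groups.values():
        v = np.asarray(v, dtype=float)
        if v.size >= 5 and v.std(ddof=1) > 0:
            normal = normal and ks_normality(v).extra["normal"]
    result = anova_bonferroni(groups) if normal else kruskal_dunn(groups)
    result.extra["normality_route"] = "parametric" if normal else "non_parametric"
    return result
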