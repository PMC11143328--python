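"""The statistical battery: ANOVA variants, post-hoc tests, rank tests, and
compartment-correlation analysis.

Omnibus group comparisons use standard sums-of-squares ANOVA (one-way,
two-way with Type II SS for unbalanced factorial data, and a balanced
two-way repeated-measures variant), with Tukey HSD post-hocs.
Non-parametric comparisons use Kruskal–Wallis with midrank tie correction
followed by Dunn's pairwise z tests under a Šidák adjustment.  Compartment
coupling (dendrite vs soma, dendrite vs axon initial segment) is quantified
by the Pearson correlation of per-cell max-in-window amplitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_sidak",
    "compartment_correlation",
]


@dataclass
class AnovaResult:
    """F (or H) statistics per factor with degrees of freedom and p-values."""

    factors: list[str]
    F: dict[str, float]
    df: dict[str, tuple[float, float]]
    p: dict[str, float]
    n: int
    method: str = "anova"

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f,
                "F": self.F[f],
                "df_num": self.df[f][0],
                "df_den": self.df[f][1],
                "p": self.p[f],
                "method": self.method,
            }
            for f in self.factors
        ]
        return pd.DataFrame(rows)


@dataclass
class PosthocResult:
    """One pairwise comparison with its multiplicity-adjusted p-value."""

    pair: tuple[str, str]
    statistic: float
    p_adj: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError("adjusted p must lie in [0, 1]")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    pair: tuple[str, str] = field(default=("x", "y"))


def _check_groups(groups: list[np.ndarray], min_size: int = 1) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} observations")
    return groups


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the standard SS decomposition.

    With two groups the F statistic equals the square of the pooled-variance
    two-sample t statistic.  Data with zero variance everywhere has no error
    term and is rejected.
    """
    groups = _check_groups(groups, min_size=2)
    all_vals = np.concatenate(groups)
    if np.allclose(all_vals, all_vals[0]):
        raise ValueError("degenerate data: zero variance within and between groups")
    k = len(groups)
    n = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ValueError("degenerate data: zero within-group variance everywhere")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        factors=["group"],
        F={"group": float(f)},
        df={"group": (df_b, df_w)},
        p={"group": p},
        n=n,
        method="one_way_anova",
    )


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "a",
    factor_b: str = "b",
    repeated: bool = False,
    subject: str = "subject",
    ss_type: int = 2,
) -> AnovaResult:
    """Two-way factorial ANOVA, optionally with repeated measures.

    The between-subjects variant fits ``value ~ A * B`` by OLS and uses the
    requested sums-of-squares type (Type II default, suited to unbalanced
    designs).  The repeated-measures variant requires a fully balanced
    within-subject design (every subject observed once per cell of A × B)
    and partitions error terms within subjects; unbalanced data is rejected
    rather than silently approximated.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if repeated:
        from statsmodels.stats.anova import AnovaRM

        if subject not in table.columns:
            raise ValueError("repeated-measures ANOVA requires a subject column")
        counts = table.groupby([subject, factor_a, factor_b], observed=True).size()
        if counts.nunique() != 1:
            raise ValueError("repeated-measures ANOVA requires a balanced design")
        res = AnovaRM(
            data=table, depvar=value, subject=subject, within=[factor_a, factor_b]
        ).fit()
        tab = res.anova_table
        factors, F, df, p = [], {}, {}, {}
        for name, row in tab.iterrows():
            factors.append(str(name))
            F[str(name)] = float(row["F Value"])
            df[str(name)] = (float(row["Num DF"]), float(row["Den DF"]))
            p[str(name)] = float(row["Pr > F"])
        return AnovaResult(
            factors=factors, F=F, df=df, p=p, n=len(table), method="two_way_rm_anova"
        )

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = table.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    label_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
    }
    df_resid = float(tab.loc["Residual", "df"])
    factors, F, df, p = [], {}, {}, {}
    for raw, name in label_map.items():
        factors.append(name)
        F[name] = float(tab.loc[raw, "F"])
        df[name] = (float(tab.loc[raw, "df"]), df_resid)
        p[name] = float(tab.loc[raw, "PR(>F)"])
    return AnovaResult(
        factors=factors, F=F, df=df, p=p, n=len(table), method="two_way_anova"
    )


def tukey_hsd(
    groups: dict[str, np.ndarray] | list[np.ndarray], alpha: float = 0.05
) -> list[PosthocResult]:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unbalanced groups)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(groups, dict):
        named = groups
    else:
        named = {f"g{i}": g for i, g in enumerate(groups)}
    _check_groups(list(named.values()), min_size=2)
    values = np.concatenate([np.asarray(v, dtype=float) for v in named.values()])
    labels = np.concatenate([[k] * len(v) for k, v in named.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj = str(row[0]), str(row[1]), float(row[2]), float(row[3])
        out.append(
            PosthocResult(pair=(g1, g2), statistic=meandiff, p_adj=min(max(p_adj, 0.0), 1.0), method="tukey_hsd")
        )
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with midrank tie correction.

    Identical groups give H = 0; with exactly two groups H is the square of
    the standardized Wilcoxon rank-sum statistic.
    """
    groups = _check_groups(groups)
    flat = np.concatenate(groups)
    # identical samples leave scipy's H as 0/0; the statistic is 0 by definition
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _dunn_z(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's pairwise z statistics on pooled midranks with tie correction."""
    flat = np.concatenate(groups)
    n_tot = flat.size
    ranks = sps.rankdata(flat)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[edges[i]: edges[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(flat, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_term
    z = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z[(i, j)] = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
    return z


def dunn_sidak(
    groups: dict[str, np.ndarray] | list[np.ndarray]
) -> list[PosthocResult]:
    """Dunn's rank-based pairwise comparisons with Šidák adjustment.

    For each pair, z compares mean pooled midranks under the Kruskal–Wallis
    null; raw two-sided normal p-values are adjusted as
    ``p_adj = 1 − (1 − p)^m`` over the m pairwise comparisons.  The adjusted
    p is never smaller than the raw p.
    """
    if isinstance(groups, dict):
        names = list(groups)
        glist = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"g{i}" for i in range(len(groups))]
        glist = [np.asarray(g, dtype=float) for g in groups]
    glist = _check_groups(glist)
    z = _dunn_z(glist)
    m = len(z)
    out = []
    for (i, j), zij in z.items():
        raw = 2.0 * sps.norm.sf(abs(zij))
        p_adj = 1.0 - (1.0 - min(raw, 1.0)) ** m
        out.append(
            PosthocResult(
                pair=(names[i], names[j]),
                statistic=float(zij),
                p_adj=float(min(p_adj, 1.0)),
                method="dunn_sidak",
            )
        )
    return out


def compartment_correlation(
    data: dict[str, np.ndarray] | pd.DataFrame,
    reference: str = "dendrite",
    others: tuple[str, ...] = ("soma", "ais"),
) -> dict[tuple[str, str], CorrelationResult]:
    """Pearson correlation of per-cell amplitudes between compartments.

    ``data`` holds one max-in-window amplitude per cell for each compartment
    (trial-averaged traces, no event detection).  Returns the correlation of
    the reference compartment (dendrite) against each other compartment.
    Requires at least three cells.
    """
    if isinstance(data, pd.DataFrame):
        data = {c: data[c].to_numpy() for c in data.columns}
    ref = np.asarray(data[reference], dtype=float)
    if ref.size < 3:
        raise ValueError("compartment correlation requires at least 3 cells")
    out = {}
    for name in others:
        y = np.asarray(data[name], dtype=float)
        if y.size != ref.size:
            raise ValueError(f"compartment {name!r} length mismatch")
        r, p = sps.pearsonr(ref, y)
        out[(reference, name)] = CorrelationResult(
            r=float(r), p=float(p), n=ref.size, pair=(reference, name)
        )
    return out
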