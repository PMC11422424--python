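"""Statistical characterization of trajectory clusters.

Welch two-sample t-tests (fractional Satterthwaite df, 95 % CI of the mean
difference), one-way ANOVA, Pearson chi-square without continuity
correction, and Benjamini-Hochberg FDR applied separately within variable
families (demographics, cluster characterization, clinical instruments).
Summary-statistic entry points (n/mean/sd) allow checking published tables
without raw data.  Trajectories are summarised by their mean rating and the
corrected rating variance — the within-person temporal variance divided by
the mean rating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FAMILIES = ("demographics", "cluster_characterization", "clinical")


@dataclass
class TrajectorySummary:
    participant_id: str
    mean_rating: float
    corrected_variance: float


def summarize_trajectory(traj, participant_id: str = "") -> TrajectorySummary:
    """Mean rating and corrected variance (s^2 / mean) of one trajectory."""
    x = np.asarray(traj, dtype=float).ravel()
    if np.isnan(x).any():
        raise ValueError("trajectory must be complete")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    return TrajectorySummary(
        participant_id=participant_id,
        mean_rating=mean,
        corrected_variance=var / mean,
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float


def welch_t_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> WelchResult:
    """Welch t-test from group summary statistics."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        raise ValueError("both groups have zero variance")
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(0.975, df)
    diff = mean1 - mean2
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        ci_low=float(diff - crit * se), ci_high=float(diff + crit * se),
    )


def welch_t(group_a, group_b) -> WelchResult:
    """Welch two-sample t-test with 95 % CI of the mean difference."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs n >= 2")
    return welch_t_from_stats(
        a.size, float(a.mean()), float(a.std(ddof=1)),
        b.size, float(b.mean()), float(b.std(ddof=1)),
    )


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def oneway_anova_from_stats(ns, means, sds) -> AnovaResult:
    """One-way ANOVA from per-group n/mean/sd."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    g = ns.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    N = ns.sum()
    if N <= g:
        raise ValueError("total n must exceed the number of groups")
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = g - 1, int(N - g)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(sps.f.sf(F, df1, df2)))


def oneway_anova(values, labels) -> AnovaResult:
    """Classical one-way between/within decomposition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    ns, means, sds = [], [], []
    for gr in groups:
        x = values[labels == gr]
        if x.size < 1:
            raise ValueError("empty group")
        ns.append(x.size)
        means.append(float(x.mean()))
        sds.append(float(x.std(ddof=1)) if x.size > 1 else 0.0)
    return oneway_anova_from_stats(ns, means, sds)


@dataclass
class Chi2Result:
    X2: float
    df: int
    p: float


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(O < 0):
        raise ValueError("counts must be nonnegative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("table has a zero row or column margin")
    E = np.outer(row, col) / O.sum()
    X2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return Chi2Result(X2=X2, df=df, p=float(sps.chi2.sf(X2, df)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] / (np.arange(1, m + 1) / m)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class VariableSpec:
    """One variable to compare across clusters.

    kind: "continuous" or "categorical".  ``subset`` optionally restricts
    the comparison to rows where ``subset[0] == subset[1]`` (e.g. clinician
    instruments administered only to the patient group).
    """

    name: str
    family: str
    kind: str = "continuous"
    subset: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r}")


def characterize_clusters(
    labels: pd.Series,
    data: pd.DataFrame,
    variables: list[VariableSpec],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Compare every variable across clusters, with family-wise BH-FDR.

    ``labels`` maps participant id -> cluster label and must cover every
    row of ``data`` (indexed by participant id).  Continuous variables use
    Welch t (2 clusters) or one-way ANOVA (>2); categorical variables use
    Pearson chi-square on the crosstab.  Post-hoc pairwise Welch t-tests
    (with their own FDR) are run when an ANOVA main effect survives.
    """
    if not labels.index.is_unique:
        raise ValueError("duplicate participant ids in labels")
    missing = set(data.index) - set(labels.index)
    if missing:
        raise ValueError(f"participants without cluster label: {sorted(missing)[:5]}")
    rows = []
    for spec in variables:
        sub = data
        if spec.subset is not None:
            col, val = spec.subset
            sub = data[data[col] == val]
        values = sub[spec.name]
        labs = labels.loc[sub.index]
        keep = values.notna()
        values, labs = values[keep], labs[keep]
        if pd.unique(values).size < 2 or pd.unique(labs).size < 2:
            warnings.warn(
                f"variable {spec.name!r} skipped (single level)", stacklevel=2
            )
            continue
        if spec.kind == "continuous":
            if pd.unique(labs).size == 2:
                g1, g2 = sorted(pd.unique(labs))
                res = welch_t(values[labs == g1], values[labs == g2])
                rows.append(
                    dict(variable=spec.name, family=spec.family, test="welch_t",
                         statistic=res.t, df=res.df, p=res.p,
                         ci_low=res.ci_low, ci_high=res.ci_high)
                )
            else:
                res = oneway_anova(values.to_numpy(), labs.to_numpy())
                rows.append(
                    dict(variable=spec.name, family=spec.family, test="anova",
                         statistic=res.F, df=(res.df1, res.df2), p=res.p,
                         ci_low=np.nan, ci_high=np.nan)
                )
        else:
            tab = pd.crosstab(values, labs)
            tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                warnings.warn(
                    f"variable {spec.name!r} skipped (degenerate table)",
                    stacklevel=2,
                )
                continue
            res = pearson_chi2(tab.to_numpy())
            rows.append(
                dict(variable=spec.name, family=spec.family, test="chi2",
                     statistic=res.X2, df=res.df, p=res.p,
                     ci_low=np.nan, ci_high=np.nan)
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["p_fdr"] = np.nan
    for family in result["family"].unique():
        mask = result["family"] == family
        result.loc[mask, "p_fdr"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    # post-hoc pairwise Welch t for surviving ANOVA main effects
    posthoc_rows = []
    for _, row in result[(result["test"] == "anova")
                         & (result["p_fdr"] <= fdr_level)].iterrows():
        spec = next(v for v in variables if v.name == row["variable"])
        sub = data
        if spec.subset is not None:
            col, val = spec.subset
            sub = data[data[col] == val]
        values = sub[row["variable"]]
        labs = labels.loc[sub.index]
        keep = values.notna()
        values, labs = values[keep], labs[keep]
        pairs = sorted(pd.unique(labs))
        ps, descs = [], []
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                res = welch_t(values[labs == pairs[a]], values[labs == pairs[b]])
                ps.append(res.p)
                descs.append((pairs[a], pairs[b], res))
        adj = bh_fdr(ps)
        for (ga, gb, res), q in zip(descs, adj):
            posthoc_rows.append(
                dict(variable=f"{row['variable']} ({ga} vs {gb})",
                     family=row["family"], test="posthoc_welch_t",
                     statistic=res.t, df=res.df, p=res.p,
                     ci_low=res.ci_low, ci_high=res.ci_high, p_fdr=q)
            )
    if posthoc_rows:
        result = pd.concat([result, pd.DataFrame(posthoc_rows)], ignore_index=True)
    return result
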