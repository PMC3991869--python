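"""Group statistics mirroring an SPSS-style gait-comparison workflow.

Per-subject parameter values (one walk = one subject) are compared across
groups with the routing the study used: normality is checked per group with
a Lilliefors-corrected Kolmogorov–Smirnov test; normally distributed
parameters go through one-way ANOVA (otherwise Kruskal–Wallis); post-hoc
pairwise tests are Fisher's LSD under equal variances and Dunnett's T3
under unequal variances (Brown–Forsythe decides); stance time and the
stance-to-stride ratio are compared with Mann–Whitney U tests under a
Bonferroni correction.  The parameter-to-test routing is frozen rather than
re-decided per dataset, with an override available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import InputError
from .events import PARAMETERS, WalkSummary

#: Frozen routing: chord/amplitude/time parameters through the
#: ANOVA-or-Kruskal-Wallis family, stance measures through MWU+Bonferroni.
DEFAULT_ROUTING = {
    "max_nav": "omnibus", "min_nav": "omnibus",
    "up_slope": "omnibus", "down_slope": "omnibus",
    "stride_time": "omnibus", "swing_time": "omnibus",
    "stance_time": "mwu", "stance_ratio": "mwu",
}


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   ) -> tuple[float, float]:
    """Mann–Whitney U test (mid-rank ties).

    The p-value is exact (full enumeration of the U distribution) when the
    combined sample has at most 20 observations and no ties; otherwise the
    normal approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_normality(x) -> float:
    """Lilliefors-corrected one-sample KS test against a fitted normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InputError("normality check needs at least 4 observations")
    if np.std(x) == 0:
        raise InputError("constant sample: normality undefined")
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def variance_equal(groups, alpha: float = 0.05) -> tuple[bool, float]:
    """Brown–Forsythe (median-centered Levene) equality-of-variance test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InputError("need at least 2 groups of at least 2 observations")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return True, 1.0
    _, p = sps.levene(*groups, center="median")
    if math.isnan(p):
        return True, 1.0
    return bool(p > alpha), float(p)


def omnibus_compare(groups, alpha: float = 0.05,
                    ) -> tuple[str, float, float]:
    """Omnibus group comparison: ANOVA if every group looks normal, else KW.

    A group that fails or cannot support the normality check (constant
    values) routes the comparison to Kruskal–Wallis.  Returns
    ``(test_name, statistic, p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 3 for g in groups):
        raise InputError("need at least 2 groups of at least 3 observations")
    try:
        normal = all(ks_normality(g) > alpha for g in groups)
    except InputError:
        normal = False
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        # Identical constant groups: no evidence of any difference.
        return ("kruskal_wallis" if not normal else "anova", 0.0, 1.0)
    if normal:
        stat, p = sps.f_oneway(*groups)
        return "anova", float(stat), float(p)
    stat, p = sps.kruskal(*groups)
    return "kruskal_wallis", float(stat), float(p)


def posthoc(groups, equal_variance: bool, labels=None,
            ) -> list[tuple[str, str, float]]:
    """Pairwise post-hoc p-values: Fisher LSD or Dunnett T3.

    LSD (equal variances): pairwise t statistics on the pooled within-group
    mean square with N − k degrees of freedom, unadjusted.  T3 (unequal
    variances): Welch-type pairwise t referred to the studentized maximum
    modulus; the tail is evaluated with the independence approximation
    ``p = 1 − (1 − p_welch)^m`` over the m pairwise comparisons, which is
    conservative relative to the unadjusted Welch test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("post-hoc comparison needs at least 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pairs = list(itertools.combinations(range(len(groups)), 2))
    out = []
    if equal_variance:
        ns = [g.size for g in groups]
        dof = sum(ns) - len(groups)
        if dof <= 0:
            raise InputError("not enough observations for pooled variance")
        mse = sum((n - 1) * np.var(g, ddof=1)
                  for n, g in zip(ns, groups)) / dof
        for i, j in pairs:
            se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                p = 1.0
            else:
                tval = (groups[i].mean() - groups[j].mean()) / se
                p = float(2.0 * sps.t.sf(abs(tval), dof))
            out.append((labels[i], labels[j], min(p, 1.0)))
        return out
    m = len(pairs)
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        vi, vj = np.var(gi, ddof=1) / gi.size, np.var(gj, ddof=1) / gj.size
        se = math.sqrt(vi + vj)
        if se == 0:
            out.append((labels[i], labels[j], 1.0))
            continue
        tval = (gi.mean() - gj.mean()) / se
        dof = (vi + vj) ** 2 / (vi ** 2 / (gi.size - 1)
                                + vj ** 2 / (gj.size - 1))
        p_welch = 2.0 * sps.t.sf(abs(tval), dof)
        p = 1.0 - (1.0 - min(p_welch, 1.0)) ** m
        out.append((labels[i], labels[j], float(min(p, 1.0))))
    return out


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p · m)``."""
    pvals = np.asarray(pvals, dtype=float)
    if m is None:
        m = pvals.size
    if m < pvals.size:
        raise InputError("m must be at least the number of p-values")
    return np.minimum(1.0, pvals * m)


@dataclass
class GroupComparison:
    """One parameter's group comparison as a structured record."""

    parameter: str
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    omnibus_name: str | None
    omnibus_stat: float | None
    omnibus_p: float | None
    equal_variance: bool | None
    posthoc_method: str
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_adjusted: dict[tuple[str, str], float] = field(
        default_factory=dict)


def _compare_parameter(parameter: str, samples: dict[str, np.ndarray],
                       route: str, alpha: float = 0.05) -> GroupComparison:
    labels = list(samples)
    groups = [samples[k] for k in labels]
    base = dict(
        parameter=parameter, groups=labels,
        means={k: float(np.mean(v)) for k, v in samples.items()},
        sds={k: float(np.std(v, ddof=1)) for k, v in samples.items()},
        ns={k: int(v.size) for k, v in samples.items()})
    if route == "mwu":
        pairs = list(itertools.combinations(labels, 2))
        raw = {}
        for a, b in pairs:
            _, p = mann_whitney_u(samples[a], samples[b])
            raw[(a, b)] = p
        adj = bonferroni(list(raw.values()), m=len(pairs))
        return GroupComparison(
            **base, omnibus_name=None, omnibus_stat=None, omnibus_p=None,
            equal_variance=None, posthoc_method="MWU+Bonferroni",
            pairwise_raw=raw,
            pairwise_adjusted=dict(zip(raw, adj)))
    name, stat, p = omnibus_compare(groups, alpha=alpha)
    eq, _ = variance_equal(groups, alpha=alpha)
    pairwise = posthoc(groups, equal_variance=eq, labels=labels)
    raw = {(a, b): pv for a, b, pv in pairwise}
    return GroupComparison(
        **base, omnibus_name=name, omnibus_stat=stat, omnibus_p=p,
        equal_variance=eq,
        posthoc_method="LSD" if eq else "DunnettT3",
        pairwise_raw=raw, pairwise_adjusted=dict(raw))


def build_report(summaries: list[tuple[str, WalkSummary]],
                 routing: dict[str, str] | None = None,
                 alpha: float = 0.05) -> list[GroupComparison]:
    """Group-comparison table over per-subject walk summaries.

    ``summaries`` pairs each walk summary with its group label; each walk's
    per-parameter mean is one subject-level observation.  Routing follows
    :data:`DEFAULT_ROUTING` unless overridden.
    """
    routing = dict(DEFAULT_ROUTING, **(routing or {}))
    labels = sorted({g for g, _ in summaries},
                    key=[g for g, _ in summaries].index)
    if len(labels) < 2:
        raise InputError("need summaries from at least 2 groups")
    out = []
    for parameter in PARAMETERS:
        samples = {
            g: np.array([s.means[parameter]
                         for lab, s in summaries if lab == g])
            for g in labels}
        out.append(_compare_parameter(parameter, samples,
                                      routing[parameter], alpha=alpha))
    return out


def report_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten a comparison list into a table (one row per parameter)."""
    rows = []
    for c in comparisons:
        row = {"parameter": c.parameter,
               "omnibus": c.omnibus_name or "",
               "omnibus_p": c.omnibus_p,
               "posthoc": c.posthoc_method,
               "equal_variance": c.equal_variance}
        for g in c.groups:
            row[f"{g}_mean"] = c.means[g]
            row[f"{g}_sd"] = c.sds[g]
            row[f"{g}_n"] = c.ns[g]
        for (a, b), p in c.pairwise_adjusted.items():
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def report_json(comparisons: list[GroupComparison]) -> list[dict]:
    """JSON-serializable form of a comparison list."""
    out = []
    for c in comparisons:
        out.append({
            "parameter": c.parameter,
            "groups": c.groups,
            "means": c.means, "sds": c.sds, "ns": c.ns,
            "omnibus": {"name": c.omnibus_name, "stat": c.omnibus_stat,
                        "p": c.omnibus_p},
            "equal_variance": c.equal_variance,
            "posthoc_method": c.posthoc_method,
            "pairwise_raw": {f"{a}|{b}": p
                             for (a, b), p in c.pairwise_raw.items()},
            "pairwise_adjusted": {f"{a}|{b}": p
                                  for (a, b), p
                                  in c.pairwise_adjusted.items()},
        })
    return out
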