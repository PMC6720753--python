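"""Nonparametric statistical battery for thermography cohorts.

Normality is screened per variable with Shapiro–Wilk; group differences use
the Mann–Whitney U test (exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise); clinical↔thermal associations
use Spearman rank correlation; method reproducibility is the coefficient of
variation %CV = 100·σ/μ with the population σ.

Pairwise group comparisons are reported uncorrected by default (an optional
Holm adjustment is available).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "shapiro_wilk",
    "mann_whitney_u",
    "spearman_rho",
    "percent_cv",
    "run_study",
    "StudyReport",
    "THERMAL_OUTCOMES",
    "CORRELATION_COVARIATES",
]

THERMAL_OUTCOMES = ("t_init", "t_c", "t_r", "dt_c", "dt_r", "s_c", "s_r", "contrast")
CORRELATION_COVARIATES = ("das28", "tender_joints", "rf", "anti_ccp")


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) for 3 ≤ n ≤ 5000 non-constant data."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (statistic for sample_a).

    Exact null enumeration when n_a·n_b ≤ 400 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 400 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware mid-ranks) with two-sided p.

    p comes from the t-distribution approximation; ``exact=True`` switches to
    full permutation enumeration (n ≤ 10 only).  Zero rank variance in either
    variable leaves the correlation undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, perm)[0, 1])
            count += r >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def percent_cv(replicates) -> float:
    """Coefficient of variation 100·σ/μ with the population σ (ddof=0)."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mu = x.mean()
    if mu == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * x.std(ddof=0) / mu)


# ---------------------------------------------------------------------------
# study report


@dataclass
class StudyReport:
    """Tables emitted by :func:`run_study`."""

    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    alpha: float

    def summary_text(self) -> str:
        sig = self.comparisons[self.comparisons["significant"]]
        lines = [
            f"alpha = {self.alpha}",
            f"{len(sig)}/{len(self.comparisons)} pairwise comparisons significant",
        ]
        for _, row in self.correlations.iterrows():
            if row["significant"]:
                lines.append(
                    f"  {row['group']}: rho({row['outcome']}, {row['covariate']})"
                    f" = {row['rho']:+.2f} (p = {row['p']:.3g})")
        return "\n".join(lines)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_study(cohort_metrics: pd.DataFrame, clinical_table: pd.DataFrame,
              alpha: float = 0.05, holm: bool = False) -> StudyReport:
    """Full statistical battery on a processed cohort.

    ``cohort_metrics`` is the tidy table from :func:`handtherm.run_cohort`
    (hand_mean rows are used); ``clinical_table`` carries one covariate row
    per subject.  Emits group summaries (mean/SD plus normality flag),
    pairwise Mann–Whitney comparisons of every thermal outcome, and Spearman
    correlations of ΔT_R/T_R/T_C against DAS28, tender joints, RF and
    anti-CCP within each patient group.
    """
    hand = cohort_metrics[cohort_metrics["finger"] == "hand_mean"]
    missing = set(hand["subject_id"]) - set(clinical_table["subject_id"])
    if missing:
        raise ValueError(f"subjects missing from clinical table: {sorted(missing)}")
    merged = hand.merge(clinical_table.drop(columns=["group"]), on="subject_id")

    groups = list(dict.fromkeys(merged["group"]))
    summary_rows = []
    for g in groups:
        sub = merged[merged["group"] == g]
        for var in THERMAL_OUTCOMES:
            vals = sub[var].to_numpy(dtype=float)
            try:
                _, p_norm = shapiro_wilk(vals)
                normal = p_norm > alpha
            except ValueError:
                p_norm, normal = float("nan"), False
            summary_rows.append(dict(group=g, variable=var, n=len(vals),
                                     mean=vals.mean(), sd=vals.std(ddof=1),
                                     shapiro_p=p_norm, normal=normal))
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        xa = merged[merged["group"] == ga]
        xb = merged[merged["group"] == gb]
        for var in THERMAL_OUTCOMES:
            u, p = mann_whitney_u(xa[var], xb[var])
            comp_rows.append(dict(variable=var, group_a=ga, group_b=gb,
                                  u=u, p=p))
    comparisons = pd.DataFrame(comp_rows)
    if holm and len(comparisons):
        comparisons["p_adjusted"] = _holm(comparisons["p"].to_numpy())
        comparisons["significant"] = comparisons["p_adjusted"] < alpha
    else:
        comparisons["significant"] = comparisons["p"] < alpha

    corr_rows = []
    for g in groups:
        if g == "healthy":
            continue  # covariate-outcome coupling is a patient-group question
        sub = merged[merged["group"] == g]
        for outcome in ("dt_r", "t_r", "t_c"):
            for covariate in CORRELATION_COVARIATES:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = spearman_rho(sub[outcome], sub[covariate])
                corr_rows.append(dict(group=g, outcome=outcome,
                                      covariate=covariate, rho=rho, p=p,
                                      n=len(sub),
                                      significant=bool(p < alpha)
                                      if not math.isnan(p) else False))
    correlations = pd.DataFrame(corr_rows)
    return StudyReport(group_summary=summary, comparisons=comparisons,
                       correlations=correlations, alpha=alpha)
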