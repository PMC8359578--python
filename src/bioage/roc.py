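"""AUC estimation and DeLong inference for mortality discrimination.

The AUC is estimated by the Mann-Whitney statistic with ties counted one
half, computed through midrank placement values.  Variances and covariances
of (paired) AUCs follow DeLong, DeLong & Clarke-Pearson: for m events with
placements V10 and n non-events with placements V01,

    var(AUC) = var(V10)/m + var(V01)/n,

and the covariance between two scores on the same patients uses the
empirical covariances of their placement vectors.  Unpaired comparisons
(disjoint strata) add the two independent variances.  All tests are
two-sided normal; per-predictor p-values test AUC = 0.5.  95% CIs are
normal-approximation on the AUC scale, truncated to [0, 1].

Outcomes are binary vital status at the end of (truncated) follow-up; for
the cardiovascular outcome, non-cardiovascular deaths stay in the control
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = ("ca", "ba", "ba_e", "ba_ec")
AGE_EDGES = (40.0, 60.0, 75.0)
STRATA = ("total", "20-39", "40-59", "60-74", ">=75")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


@dataclass
class AUCComponents:
    """Mann-Whitney AUC with DeLong placement values."""

    auc: float
    v10: np.ndarray  # per-event placements
    v01: np.ndarray  # per-non-event placements

    @property
    def variance(self) -> float:
        m, n = len(self.v10), len(self.v01)
        v10_var = self.v10.var(ddof=1) if m > 1 else 0.0
        v01_var = self.v01.var(ddof=1) if n > 1 else 0.0
        return v10_var / m + v01_var / n

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(self.variance)
        return (max(0.0, self.auc - z * se), min(1.0, self.auc + z * se))

    def p_vs_chance(self) -> float:
        """Two-sided test of AUC = 0.5 using the DeLong variance."""
        se = np.sqrt(self.variance)
        if se == 0:
            return 1.0 if self.auc == 0.5 else 0.0
        z = (self.auc - 0.5) / se
        return float(2 * stats.norm.sf(abs(z)))


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> AUCComponents:
    """AUC with ties counted 1/2, plus DeLong placement values.

    ``labels`` is binary: 1 = event, 0 = non-event.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one event and one non-event")
    x = scores[labels]
    y = scores[~labels]
    rank_all = _midrank(np.concatenate([x, y]))
    rank_x = _midrank(x)
    rank_y = _midrank(y)
    # Placement of event i: fraction of non-events it outscores (ties = 1/2).
    v10 = (rank_all[:m] - rank_x) / n
    v01 = 1.0 - (rank_all[m:] - rank_y) / m
    auc = float(v10.mean())
    return AUCComponents(auc=auc, v10=v10, v01=v01)


def delong_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong test for two scores on the same patients.

    Returns (delta_auc, z, two-sided p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must cover identical patients")
    ca_ = auc_mann_whitney(scores_a, labels)
    cb = auc_mann_whitney(scores_b, labels)
    m, n = len(ca_.v10), len(ca_.v01)
    delta = ca_.auc - cb.auc
    if m > 1:
        s10 = np.cov(np.vstack([ca_.v10, cb.v10]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([ca_.v01, cb.v01]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if delta == 0:
            return 0.0, 0.0, 1.0
        raise ValueError("degenerate zero variance with a non-zero AUC difference")
    z = delta / np.sqrt(var)
    return float(delta), float(z), float(2 * stats.norm.sf(abs(z)))


def delong_unpaired(
    scores_1: np.ndarray,
    labels_1: np.ndarray,
    scores_2: np.ndarray,
    labels_2: np.ndarray,
) -> tuple[float, float, float]:
    """Unpaired DeLong test for one predictor in two disjoint cohorts.

    Returns (delta_auc = AUC1 - AUC2, z, two-sided p).
    """
    c1 = auc_mann_whitney(scores_1, labels_1)
    c2 = auc_mann_whitney(scores_2, labels_2)
    delta = c1.auc - c2.auc
    var = c1.variance + c2.variance
    if var <= 0:
        if delta == 0:
            return 0.0, 0.0, 1.0
        raise ValueError("degenerate zero variance with a non-zero AUC difference")
    z = delta / np.sqrt(var)
    return float(delta), float(z), float(2 * stats.norm.sf(abs(z)))


def incidence_rate(events: int, n_patients: int, mean_followup_days: float) -> float:
    """Crude incidence per 100 patient-years."""
    patient_years = n_patients * mean_followup_days / 365.25
    if patient_years <= 0:
        raise ValueError("zero patient-years of follow-up")
    return events / patient_years * 100.0


# ---------------------------------------------------------------------------
# Stratified evaluation


@dataclass
class StratumResult:
    outcome: str
    stratum: str
    n_events: int
    n_nonevents: int
    evaluable: bool
    auc: dict[str, dict] = field(default_factory=dict)  # predictor -> auc/ci/p
    paired_p: dict[str, float] = field(default_factory=dict)  # "a_vs_b" -> p


@dataclass
class ROCComparison:
    """Full evaluation: AUCs per outcome x stratum, paired tests within
    strata, unpaired tests across strata."""

    strata: list[StratumResult]
    cross_stratum_p: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strata": [
                {
                    "outcome": s.outcome,
                    "stratum": s.stratum,
                    "n_events": s.n_events,
                    "n_nonevents": s.n_nonevents,
                    "evaluable": s.evaluable,
                    "auc": s.auc,
                    "paired_p": s.paired_p,
                }
                for s in self.strata
            ],
            "cross_stratum_p": self.cross_stratum_p,
        }

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            for pred, d in s.auc.items():
                rows.append(
                    {
                        "outcome": s.outcome,
                        "stratum": s.stratum,
                        "predictor": pred,
                        "auc": d["auc"],
                        "ci_low": d["ci"][0],
                        "ci_high": d["ci"][1],
                        "p_vs_chance": d["p"],
                        "n_events": s.n_events,
                        "n_nonevents": s.n_nonevents,
                    }
                )
        return pd.DataFrame(rows)


def _stratum_mask(ca: np.ndarray, stratum: str, edges=AGE_EDGES) -> np.ndarray:
    e1, e2, e3 = edges
    if stratum == "total":
        return np.ones(len(ca), dtype=bool)
    if stratum == "20-39":
        return ca < e1
    if stratum == "40-59":
        return (ca >= e1) & (ca < e2)
    if stratum == "60-74":
        return (ca >= e2) & (ca < e3)
    if stratum == ">=75":
        return ca >= e3
    raise ValueError(f"unknown stratum {stratum!r}")


def stratified_evaluation(
    ages: pd.DataFrame,
    outcomes: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTORS,
    edges: tuple[float, float, float] = AGE_EDGES,
) -> ROCComparison:
    """Evaluate discrimination per outcome and age stratum.

    ``ages`` carries one column per predictor (ca, ba, ba_e, ba_ec);
    ``outcomes`` carries binary ``all_cause_death`` and
    ``cardiovascular_death`` columns aligned with ``ages``.
    """
    for pred in predictors:
        if pred not in ages.columns:
            raise KeyError(f"predictions missing predictor column {pred!r}")
    ca = ages["ca"].to_numpy(dtype=float)
    results: list[StratumResult] = []
    evaluable_by_outcome: dict[str, dict[str, StratumResult]] = {}

    for outcome in ("all_cause_death", "cardiovascular_death"):
        labels_all = outcomes[outcome].to_numpy().astype(bool)
        evaluable_by_outcome[outcome] = {}
        for stratum in STRATA:
            mask = _stratum_mask(ca, stratum, edges)
            labels = labels_all[mask]
            n_events = int(labels.sum())
            n_non = int((~labels).sum())
            res = StratumResult(
                outcome=outcome,
                stratum=stratum,
                n_events=n_events,
                n_nonevents=n_non,
                evaluable=n_events > 0 and n_non > 0,
            )
            if not res.evaluable:
                warnings.warn(f"stratum {stratum!r} not evaluable for {outcome} (no events or no controls)")
                results.append(res)
                continue
            for pred in predictors:
                comp = auc_mann_whitney(ages.loc[mask, pred].to_numpy(), labels)
                res.auc[pred] = {"auc": comp.auc, "ci": list(comp.ci()), "p": comp.p_vs_chance()}
            for i, a in enumerate(predictors):
                for b in predictors[i + 1 :]:
                    _, _, p = delong_paired(
                        ages.loc[mask, a].to_numpy(), ages.loc[mask, b].to_numpy(), labels
                    )
                    res.paired_p[f"{a}_vs_{b}"] = p
            evaluable_by_outcome[outcome][stratum] = res
            results.append(res)

    cross: dict[str, dict[str, float]] = {}
    age_strata = [s for s in STRATA if s != "total"]
    for outcome, by_stratum in evaluable_by_outcome.items():
        for i, s1 in enumerate(age_strata):
            for s2 in age_strata[i + 1 :]:
                if s1 not in by_stratum or s2 not in by_stratum:
                    continue
                key = f"{outcome}:{s1}_vs_{s2}"
                cross[key] = {}
                m1 = _stratum_mask(ca, s1, edges)
                m2 = _stratum_mask(ca, s2, edges)
                labels_all = outcomes[outcome].to_numpy().astype(bool)
                for pred in predictors:
                    _, _, p = delong_unpaired(
                        ages.loc[m1, pred].to_numpy(),
                        labels_all[m1],
                        ages.loc[m2, pred].to_numpy(),
                        labels_all[m2],
                    )
                    cross[key][pred] = p
    return ROCComparison(strata=results, cross_stratum_p=cross)
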