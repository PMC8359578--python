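"""Two-step, sex-stratified parameter selection with collinearity pruning.

Step 1 keeps, within each sex, every ECG parameter whose Pearson correlation
with chronological age satisfies |r| >= theta1 (default 0.2).  Step 2 scans
all unordered pairs among the step-1 survivors; a pair with |r| >= theta2
(default 0.9) is a *strong correlation*.  A parameter is retained iff it
belongs to no strong pair, or its step-1 |r with CA| strictly exceeds that
of every strong-pair partner.  Thresholds apply to |r| so that parameters
that decline with age are not discarded.

Ties between equally age-correlated strong partners are broken by keeping
the lexicographically first column name (deterministic, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, ParameterMatrix, StandardizationModel

logger = logging.getLogger(__name__)

AGE_CORR_THRESHOLD = 0.2
COLLINEARITY_THRESHOLD = 0.9


@dataclass
class SexSelection:
    """Selection state for one sex."""

    step1_correlations: pd.Series  # parameter -> r with CA (signed)
    step1_selected: list[str]
    strong_pairs: list[tuple[str, str]] = field(default_factory=list)
    step2_selected: list[str] = field(default_factory=list)
    drop_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def n_ordered_pairs(self) -> int:
        """X*(X-1): ordered pair count over the step-1 survivors, the
        convention used when reporting the size of the pairwise scan."""
        return ordered_pair_count(len(self.step1_selected))


@dataclass
class SelectionReport:
    """Per-sex two-step selection results."""

    by_sex: dict[str, SexSelection]
    age_threshold: float = AGE_CORR_THRESHOLD
    collinearity_threshold: float = COLLINEARITY_THRESHOLD

    def selected(self, mode: str = "intersection") -> list[str]:
        """Final column list: 'intersection' (default), 'union', 'male' or
        'female'."""
        if mode in self.by_sex:
            return list(self.by_sex[mode].step2_selected)
        sets = [set(s.step2_selected) for s in self.by_sex.values()]
        if not sets:
            return []
        if mode == "intersection":
            out = set.intersection(*sets)
        elif mode == "union":
            out = set.union(*sets)
        else:
            raise ValueError(f"unknown selection mode {mode!r}")
        return sorted(out)

    def to_dict(self) -> dict:
        return {
            "age_threshold": self.age_threshold,
            "collinearity_threshold": self.collinearity_threshold,
            "by_sex": {
                sex: {
                    "step1_correlations": s.step1_correlations.to_dict(),
                    "step1_selected": s.step1_selected,
                    "n_ordered_pairs": s.n_ordered_pairs,
                    "strong_pairs": [list(p) for p in s.strong_pairs],
                    "step2_selected": s.step2_selected,
                    "drop_reasons": s.drop_reasons,
                }
                for sex, s in self.by_sex.items()
            },
        }


def ordered_pair_count(x: int) -> int:
    """Number of ordered pairs among x items, excluding self-pairs."""
    return x * (x - 1)


def standardize(params: ParameterMatrix) -> tuple[ParameterMatrix, StandardizationModel]:
    """Centre and scale each column to sample mean 0, sd 1 (ddof=1)."""
    mean = params.frame.mean()
    sd = params.frame.std(ddof=1)
    constant = sd.index[~(sd > 0)].tolist()
    if constant:
        raise ValueError(f"constant columns cannot be standardized: {constant}")
    model = StandardizationModel(mean=mean, sd=sd)
    return ParameterMatrix(model.transform(params.frame), params.column_meta), model


def _pearson_with_ca(frame: pd.DataFrame, ca: pd.Series) -> pd.Series:
    x = frame.to_numpy(dtype=float)
    y = ca.to_numpy(dtype=float)
    xs = x.std(axis=0)
    if (xs == 0).any() or y.std() == 0:
        bad = frame.columns[xs == 0].tolist() or ["ca_years"]
        raise ValueError(f"correlation undefined (zero variance): {bad}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    r = xc.T @ yc / (np.sqrt((xc**2).sum(axis=0)) * np.sqrt((yc**2).sum()))
    return pd.Series(r, index=frame.columns)


def select_by_age_correlation(
    params: ParameterMatrix,
    cohort: CohortTable,
    threshold: float = AGE_CORR_THRESHOLD,
) -> SelectionReport:
    """Step 1: per-sex Pearson correlation of each column with CA; keep
    columns with |r| >= threshold."""
    by_sex: dict[str, SexSelection] = {}
    for sex in ("male", "female"):
        mask = cohort.sex == sex
        if mask.sum() < 3:
            raise ValueError(f"need at least 3 patients of sex {sex!r}, got {int(mask.sum())}")
        sub = params.frame.loc[mask.index[mask]]
        ca = cohort.ca_years.loc[mask.index[mask]]
        r = _pearson_with_ca(sub, ca)
        selected = sorted(r.index[np.abs(r) >= threshold])
        drops = {c: "below_age_threshold" for c in r.index if c not in selected}
        by_sex[sex] = SexSelection(step1_correlations=r, step1_selected=selected, drop_reasons=drops)
    return SelectionReport(by_sex=by_sex, age_threshold=threshold)


def prune_collinear(
    params: ParameterMatrix,
    cohort: CohortTable,
    report: SelectionReport,
    threshold: float = COLLINEARITY_THRESHOLD,
) -> SelectionReport:
    """Step 2: within each sex, drop any step-1 column that is outranked by a
    strong-pair partner (higher step-1 |r with CA|)."""
    for sex, sel in report.by_sex.items():
        cols = sel.step1_selected
        if not cols:
            sel.strong_pairs = []
            sel.step2_selected = []
            continue
        mask = cohort.sex == sex
        sub = params.frame.loc[mask.index[mask], cols]
        corr = sub.corr().to_numpy()
        abs_age_r = sel.step1_correlations[cols].abs()

        partners: dict[str, list[str]] = {c: [] for c in cols}
        pairs: list[tuple[str, str]] = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(corr[i, j]) >= threshold:
                    a, b = cols[i], cols[j]
                    pairs.append((a, b))
                    partners[a].append(b)
                    partners[b].append(a)

        kept = []
        for c in cols:
            if not partners[c]:
                kept.append(c)
                continue
            wins = True
            for p in partners[c]:
                if abs_age_r[c] > abs_age_r[p]:
                    continue
                if abs_age_r[c] == abs_age_r[p] and c < p:
                    logger.info("tie between %s and %s (|r|=%.6f); keeping %s", c, p, abs_age_r[c], c)
                    continue
                wins = False
                break
            if wins:
                kept.append(c)
            else:
                sel.drop_reasons[c] = "outranked_by_partner"
        sel.strong_pairs = pairs
        sel.step2_selected = sorted(kept)
    report.collinearity_threshold = threshold
    return report


def select_parameters(
    params: ParameterMatrix,
    cohort: CohortTable,
    age_threshold: float = AGE_CORR_THRESHOLD,
    collinearity_threshold: float = COLLINEARITY_THRESHOLD,
) -> SelectionReport:
    """Run both selection steps."""
    report = select_by_age_correlation(params, cohort, age_threshold)
    return prune_collinear(params, cohort, report, collinearity_threshold)
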