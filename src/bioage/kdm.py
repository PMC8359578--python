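"""Klemera-Doubal biological age (BA_E and its age-adjusted variant BA_EC).

Each biomarker x_j is regressed on chronological age (CA) by ordinary least
squares, yielding slope k_j, intercept q_j, residual RMSE s_j (population
convention, dividing by n) and age-correlation r_j.  The unadjusted
estimator is the precision-weighted inversion of those regressions,

    BA_E = [sum_j (x_j - q_j) k_j / s_j^2] / [sum_j (k_j / s_j)^2],

i.e. the weighted-least-squares minimiser over candidate age t of
sum_j [(x_j - q_j - k_j t)/s_j]^2.  The adjusted estimator treats CA as one
more noisy reading of biological age with variance s2_BA:

    BA_EC = [sum_j (x_j - q_j) k_j / s_j^2 + CA/s2_BA]
            / [sum_j (k_j / s_j)^2 + 1/s2_BA],

so BA_EC always lies between BA_E and CA.  The panel's aggregate
age-correlation is summarised by the characteristic correlation

    r_char = [sum_j r_j^2 / sqrt(1 - r_j^2)] / [sum_j r_j / sqrt(1 - r_j^2)]

(|r_j| is used so negatively age-correlated biomarkers contribute
positively; the sign information stays in k_j), and the variance term is

    s2_BA = Var_n(BA_E - CA) - [(1 - r_char^2)/r_char^2] * (CA_max - CA_min)^2 / (12 m),

the empirical variance of the BA_E - CA gap minus the part attributable to
estimation noise for a panel of m biomarkers over a uniform age range.
Var_n divides by n.  When the correction exceeds the variance (possible at
small n), s2_BA is floored at a small positive epsilon with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, ParameterMatrix

S2_BA_FLOOR = 1e-8


def compute_r_char(r: np.ndarray | list[float]) -> float:
    """Characteristic correlation of a biomarker panel; uses |r_j|."""
    r = np.abs(np.asarray(r, dtype=float))
    if np.any(r >= 1):
        raise ValueError("all |r_j| must be < 1 (a perfectly age-determined biomarker is degenerate)")
    if np.any(r <= 0):
        raise ValueError("all |r_j| must be > 0")
    w = 1.0 / np.sqrt(1.0 - r**2)
    return float((r**2 * w).sum() / (r * w).sum())


def compute_s2_ba(
    ba_e: np.ndarray,
    ca: np.ndarray,
    r_char: float,
    ca_range: tuple[float, float],
    m: int,
) -> float:
    """Variance of true biological age around CA, noise-corrected; floored
    at a small epsilon when the correction term exceeds the variance."""
    if not 0 < r_char:
        raise ValueError("r_char must be positive")
    ba_e = np.asarray(ba_e, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ba_e.size < 2:
        raise ValueError("need at least 2 patients")
    diff = ba_e - ca
    var_n = float(np.var(diff))  # population variance, divide by n
    ca_min, ca_max = ca_range
    correction = (1.0 - r_char**2) / r_char**2 * (ca_max - ca_min) ** 2 / (12.0 * m)
    s2 = var_n - correction
    if s2 <= 0:
        warnings.warn(
            f"s2_BA non-positive ({s2:.4g}): noise correction exceeds the empirical "
            f"variance; flooring at {S2_BA_FLOOR}"
        )
        s2 = S2_BA_FLOOR
    return float(s2)


class KlemeraDoubal:
    """Klemera-Doubal biological-age model.

    Parameters
    ----------
    params : ParameterMatrix
        Raw ECG parameters (native units) for the training cohort.
    cohort : CohortTable
        Provides chronological age aligned with ``params``.
    columns : list of str, optional
        Biomarker subset; defaults to every column.
    """

    def __init__(
        self,
        params: ParameterMatrix,
        cohort: CohortTable,
        columns: list[str] | None = None,
    ):
        self.columns = list(columns) if columns is not None else list(params.frame.columns)
        if not self.columns:
            raise ValueError("no columns to model")
        missing = set(self.columns) - set(params.frame.columns)
        if missing:
            raise KeyError(f"columns absent from parameter matrix: {sorted(missing)}")
        if len(cohort.frame) < 3:
            raise ValueError("need at least 3 patients")
        self.params = ParameterMatrix(params.frame[self.columns], None)
        self.cohort = cohort

    def fit(self) -> "KlemeraDoubalResults":
        X = self.params.values
        ca = self.cohort.ca_years.to_numpy(dtype=float)
        n = len(ca)
        if np.std(ca) == 0:
            raise ValueError("chronological age is constant; regressions undefined")

        ca_c = ca - ca.mean()
        ss_ca = float((ca_c**2).sum())
        rows = []
        for j, col in enumerate(self.columns):
            x = X[:, j]
            k = float((ca_c * (x - x.mean())).sum() / ss_ca)
            q = float(x.mean() - k * ca.mean())
            resid = x - (q + k * ca)
            s = float(np.sqrt((resid**2).mean()))  # RMSE, divide by n
            if s == 0:
                raise ValueError(
                    f"column {col!r} is a deterministic function of age (s_j = 0); remove it"
                )
            r = float(np.corrcoef(x, ca)[0, 1])
            if abs(r) >= 1:
                raise ValueError(f"column {col!r} has |r| = 1 with age; remove it")
            rows.append({"column": col, "k": k, "q": q, "s": s, "r": r})
        coeffs = pd.DataFrame(rows).set_index("column")

        r_char = compute_r_char(coeffs["r"].to_numpy())
        ca_min, ca_max = float(ca.min()), float(ca.max())
        partial = KlemeraDoubalResults(
            coeffs=coeffs, r_char=r_char, s2_ba=np.inf, ca_min=ca_min, ca_max=ca_max, nobs=n
        )
        ba_e = partial.predict_ba_e(self.params).to_numpy()
        s2_ba = compute_s2_ba(ba_e, ca, r_char, (ca_min, ca_max), len(self.columns))
        partial.s2_ba = s2_ba
        return partial


@dataclass
class KlemeraDoubalResults:
    """Fitted Klemera-Doubal model."""

    coeffs: pd.DataFrame  # index: column; k, q, s, r
    r_char: float
    s2_ba: float
    ca_min: float
    ca_max: float
    nobs: int

    @property
    def columns(self) -> list[str]:
        return list(self.coeffs.index)

    @property
    def m(self) -> int:
        return len(self.coeffs)

    def _weighted_sums(self, params: ParameterMatrix) -> tuple[np.ndarray, float]:
        missing = set(self.columns) - set(params.frame.columns)
        if missing:
            raise KeyError(f"missing columns: {sorted(missing)}")
        X = params.frame[self.columns].to_numpy(dtype=float)
        k = self.coeffs["k"].to_numpy()
        q = self.coeffs["q"].to_numpy()
        s = self.coeffs["s"].to_numpy()
        num = (X - q) @ (k / s**2)
        den = float(((k / s) ** 2).sum())
        return num, den

    def predict_ba_e(self, params: ParameterMatrix) -> pd.Series:
        """Unadjusted biological age, years."""
        num, den = self._weighted_sums(params)
        return pd.Series(num / den, index=params.frame.index, name="ba_e")

    def predict_ba_ec(self, params: ParameterMatrix, ca: pd.Series | np.ndarray) -> pd.Series:
        """Age-adjusted biological age, years; lies between BA_E and CA."""
        if not self.s2_ba > 0:
            raise ValueError("s2_ba must be positive")
        num, den = self._weighted_sums(params)
        ca_arr = np.asarray(ca, dtype=float)
        if np.isinf(self.s2_ba):
            vals = num / den
        else:
            vals = (num + ca_arr / self.s2_ba) / (den + 1.0 / self.s2_ba)
        return pd.Series(vals, index=params.frame.index, name="ba_ec")

    def summary(self) -> str:
        lines = [
            "Klemera-Doubal biological age",
            "=" * 50,
            f"patients:        {self.nobs}",
            f"biomarkers (m):  {self.m}",
            f"r_char:          {self.r_char:.4f}",
            f"s2_BA:           {self.s2_ba:.4f}",
            f"CA range:        [{self.ca_min:.2f}, {self.ca_max:.2f}]",
            "",
            "per-biomarker regressions on CA (k: slope, q: intercept, s: RMSE, r: Pearson):",
            self.coeffs.round(4).to_string(),
        ]
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "kind": "kdm_bioage",
            "note": "regressions are biomarker-on-CA; s2_BA uses the canonical "
            "variance-minus-correction form with population variance",
            "columns": self.columns,
            "k": self.coeffs["k"].tolist(),
            "q": self.coeffs["q"].tolist(),
            "s": self.coeffs["s"].tolist(),
            "r": self.coeffs["r"].tolist(),
            "r_char": self.r_char,
            "s2_ba": self.s2_ba,
            "ca_min": self.ca_min,
            "ca_max": self.ca_max,
            "nobs": self.nobs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KlemeraDoubalResults":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("kind") != "kdm_bioage":
            raise ValueError(f"not a Klemera-Doubal model file: {path}")
        coeffs = pd.DataFrame(
            {"k": d["k"], "q": d["q"], "s": d["s"], "r": d["r"]},
            index=pd.Index(d["columns"], name="column"),
        )
        return cls(
            coeffs=coeffs,
            r_char=d["r_char"],
            s2_ba=d["s2_ba"],
            ca_min=d["ca_min"],
            ca_max=d["ca_max"],
            nobs=d["nobs"],
        )
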