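"""Principal-component biological age.

The model standardises the selected ECG parameters, eigendecomposes their
correlation matrix, and retains the unrotated components with eigenvalue
>= 1.0 (Kaiser rule).  Each retained component i receives a weight

    p_i = R2_i / sum_k R2_k,

where R2_i is from the univariate regression of chronological age (CA) on
the component-i scores, so components that track age dominate.  The raw
composite

    pre-BA = sum_i p_i * sum_j beta_ij * z_j

(z_j the stored standardisation of parameter j) is unitless and centred on
the training cohort; it is mapped to years by

    BA = pre-BA * sd(CA) + mean(CA) + (CA - mean(CA)) * (1 - B),

with B the standardised coefficient (equivalently the Pearson correlation)
of the regression of pre-BA on CA.  The final term pulls the estimate
toward CA exactly in proportion to how weakly the composite tracks age.

Eigenvector signs are arbitrary; each loading vector is oriented so that
its score's regression slope against CA is non-negative, which makes pre-BA
well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, ParameterMatrix, StandardizationModel
from .selection import standardize

EIGENVALUE_CUTOFF = 1.0


class PCABioAge:
    """Principal-component biological-age model.

    Parameters
    ----------
    params : ParameterMatrix
        Raw (unstandardised) ECG parameters for the training cohort.
    cohort : CohortTable
        Provides chronological age aligned with ``params``.
    columns : list of str, optional
        Parameter subset to model; defaults to every column.
    eigenvalue_cutoff : float
        Minimum eigenvalue for a component to be retained (inclusive).
    """

    def __init__(
        self,
        params: ParameterMatrix,
        cohort: CohortTable,
        columns: list[str] | None = None,
        eigenvalue_cutoff: float = EIGENVALUE_CUTOFF,
    ):
        self.columns = list(columns) if columns is not None else list(params.frame.columns)
        if not self.columns:
            raise ValueError("no columns to model")
        missing = set(self.columns) - set(params.frame.columns)
        if missing:
            raise KeyError(f"columns absent from parameter matrix: {sorted(missing)}")
        if len(cohort.frame) <= len(self.columns):
            raise ValueError("need more patients than parameters")
        self.params = ParameterMatrix(params.frame[self.columns], None)
        self.cohort = cohort
        self.eigenvalue_cutoff = float(eigenvalue_cutoff)

    def fit(self) -> "PCABioAgeResults":
        z, scaler = standardize(self.params)
        Z = z.values
        n = Z.shape[0]
        ca = self.cohort.ca_years.to_numpy(dtype=float)

        corr = np.corrcoef(Z, rowvar=False)
        corr = np.atleast_2d(corr)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

        retained = eigvals >= self.eigenvalue_cutoff
        m = int(retained.sum())
        if m == 0:
            raise ValueError(
                f"no eigenvalue >= {self.eigenvalue_cutoff}; spectrum: {np.round(eigvals, 4).tolist()}"
            )
        loadings = eigvecs[:, :m]  # columns are components

        scores = Z @ loadings
        r2 = np.empty(m)
        for i in range(m):
            s = scores[:, i]
            # Orient each component so its slope against CA is non-negative.
            r = float(np.corrcoef(s, ca)[0, 1]) if s.std() > 0 and ca.std() > 0 else 0.0
            if r < 0:
                loadings[:, i] = -loadings[:, i]
                scores[:, i] = -s
                r = -r
            r2[i] = r**2
        total = r2.sum()
        if total <= 0:
            raise ValueError("no retained component correlates with chronological age")
        weights = r2 / total

        pre_ba = scores @ weights
        sd_ca = float(np.std(ca, ddof=1))
        mean_ca = float(np.mean(ca))
        b = float(np.corrcoef(pre_ba, ca)[0, 1])

        return PCABioAgeResults(
            model=self,
            scaler=scaler,
            loadings=pd.DataFrame(loadings, index=self.columns, columns=[f"PC{i+1}" for i in range(m)]),
            eigenvalues=eigvals,
            n_components=m,
            weights=weights,
            r2=r2,
            b=b,
            sd_ca=sd_ca,
            mean_ca=mean_ca,
            nobs=n,
        )


@dataclass
class PCABioAgeResults:
    """Fitted PCA biological-age model."""

    model: PCABioAge | None
    scaler: StandardizationModel
    loadings: pd.DataFrame  # parameters x retained components
    eigenvalues: np.ndarray  # full spectrum, descending
    n_components: int
    weights: np.ndarray  # p_i, sum to 1
    r2: np.ndarray  # per-component age R2
    b: float  # standardised slope of pre-BA on CA
    sd_ca: float
    mean_ca: float
    nobs: int

    @property
    def columns(self) -> list[str]:
        return list(self.loadings.index)

    def predict_pre_ba(self, params: ParameterMatrix) -> pd.Series:
        """Unitless composite: weighted sum of component scores of the
        stored standardisation of the inputs."""
        z = self.scaler.transform(params.frame)
        scores = z.to_numpy(dtype=float) @ self.loadings.to_numpy()
        return pd.Series(scores @ self.weights, index=params.frame.index, name="pre_ba")

    def predict_ba(self, pre_ba: pd.Series | np.ndarray, ca: pd.Series | np.ndarray) -> pd.Series:
        """Map pre-BA to years: pre-BA*sd(CA) + mean(CA) + (CA-mean(CA))*(1-B)."""
        pre = np.asarray(pre_ba, dtype=float)
        ca_arr = np.asarray(ca, dtype=float)
        ba = pre * self.sd_ca + self.mean_ca + (ca_arr - self.mean_ca) * (1.0 - self.b)
        index = pre_ba.index if isinstance(pre_ba, pd.Series) else None
        return pd.Series(ba, index=index, name="ba")

    def predict(self, params: ParameterMatrix, ca: pd.Series | np.ndarray) -> pd.Series:
        return self.predict_ba(self.predict_pre_ba(params), ca)

    def summary(self) -> str:
        lines = [
            "Principal-component biological age",
            "=" * 50,
            f"patients:             {self.nobs}",
            f"parameters:           {len(self.columns)}",
            f"retained components:  {self.n_components} (eigenvalue >= 1.0)",
            f"eigenvalues retained: {np.round(self.eigenvalues[: self.n_components], 4).tolist()}",
            f"component weights:    {np.round(self.weights, 4).tolist()}",
            f"B (pre-BA ~ CA):      {self.b:.4f}",
            f"mean(CA), sd(CA):     {self.mean_ca:.2f}, {self.sd_ca:.2f}",
        ]
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "kind": "pca_bioage",
            "columns": self.columns,
            "scaler_mean": self.scaler.mean[self.columns].tolist(),
            "scaler_sd": self.scaler.sd[self.columns].tolist(),
            "loadings": self.loadings.to_numpy().tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "r2": self.r2.tolist(),
            "b": self.b,
            "sd_ca": self.sd_ca,
            "mean_ca": self.mean_ca,
            "nobs": self.nobs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCABioAgeResults":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("kind") != "pca_bioage":
            raise ValueError(f"not a PCA biological-age model file: {path}")
        cols = d["columns"]
        scaler = StandardizationModel(
            mean=pd.Series(d["scaler_mean"], index=cols), sd=pd.Series(d["scaler_sd"], index=cols)
        )
        return cls(
            model=None,
            scaler=scaler,
            loadings=pd.DataFrame(
                d["loadings"], index=cols, columns=[f"PC{i+1}" for i in range(d["n_components"])]
            ),
            eigenvalues=np.asarray(d["eigenvalues"]),
            n_components=d["n_components"],
            weights=np.asarray(d["weights"]),
            r2=np.asarray(d["r2"]),
            b=d["b"],
            sd_ca=d["sd_ca"],
            mean_ca=d["mean_ca"],
            nobs=d["nobs"],
        )
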