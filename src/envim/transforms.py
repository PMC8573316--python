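"""Normalising transforms used before and after the elastic-net fits.

Gene-family predictors are mapped to normality with a rank-based inverse
normal transform (applied per feature, across samples, independently for the
training and testing matrices).  Metabolite responses are mapped with a
Box-Cox power transform whose exponent is profiled on the training data; the
baseline mode uses the arcsine-square-root transform instead.  Shapiro-Wilk
diagnostics compare the two families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EnvimError, ParameterError
from .tables import AbundanceTable

BOX_COX_BOUNDS = (-2.0, 2.0)


@dataclass
class TransformParams:
    """Per-metabolite response-transform parameters fitted on training data.

    ``omega`` is the Box-Cox exponent, ``delta`` the offset added before the
    transform to clear zeros (half the minimum positive training value when
    the training vector contained zeros, else 0).
    """

    metabolite_ids: list[str]
    omega: np.ndarray
    delta: np.ndarray
    method: str = "BOX_COX"  # or "ARCSINE_SQRT"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        n = len(self.metabolite_ids)
        if self.omega.shape != (n,) or self.delta.shape != (n,):
            raise ParameterError("omega/delta must have one entry per metabolite")
        if (self.delta < 0).any():
            raise ParameterError("zero offsets must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"omega": self.omega, "delta": self.delta, "method": self.method},
            index=pd.Index(self.metabolite_ids, name="metabolite_id"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransformParams":
        method = str(df["method"].iloc[0]) if len(df) else "BOX_COX"
        return cls(
            metabolite_ids=[str(m) for m in df.index],
            omega=df["omega"].to_numpy(dtype=float),
            delta=df["delta"].to_numpy(dtype=float),
            method=method,
        )


# ---------------------------------------------------------------------------
# rank-based inverse normal
# ---------------------------------------------------------------------------

def rank_inverse_normal(m: np.ndarray) -> np.ndarray:
    """Map each column (feature across samples) to normal scores.

    Ties receive average ranks; rank r of n maps to Phi^{-1}((r - 0.5)/n).
    Constant columns map to all zeros.  The transform is applied to training
    and testing matrices independently by the callers.
    """
    m = np.asarray(m, dtype=float)
    if np.isnan(m).any():
        raise ParameterError("rank_inverse_normal requires a fully observed matrix")
    squeeze = m.ndim == 1
    if squeeze:
        m = m[:, None]
    n = m.shape[0]
    ranks = stats.rankdata(m, axis=0, method="average")
    out = stats.norm.ppf((ranks - 0.5) / n)
    constant = np.ptp(m, axis=0) == 0
    out[:, constant] = 0.0
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def box_cox(y: np.ndarray, omega: float) -> np.ndarray:
    """Power transform (y^omega - 1)/omega, natural log at omega = 0."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise EnvimError("box_cox requires strictly positive values")
    if omega == 0.0:
        return np.log(y)
    return (np.power(y, omega) - 1.0) / omega


def inverse_box_cox(yp: np.ndarray, omega: float) -> np.ndarray:
    """Right inverse of :func:`box_cox`; out-of-range values clamp to 0."""
    yp = np.asarray(yp, dtype=float)
    if omega == 0.0:
        return np.exp(yp)
    base = omega * yp + 1.0
    out = np.zeros_like(yp)
    ok = base > 0
    out[ok] = np.power(base[ok], 1.0 / omega)
    return out


def fit_box_cox(y: np.ndarray, bounds: tuple[float, float] = BOX_COX_BOUNDS) -> float:
    """Profile-likelihood Box-Cox exponent, maximised over a bounded interval."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise EnvimError("fit_box_cox requires strictly positive values")
    if len(y) < 5:
        raise ParameterError("fit_box_cox needs at least 5 observations")
    if np.ptp(y) == 0:
        return 1.0
    res = optimize.minimize_scalar(
        lambda w: -stats.boxcox_llf(w, y),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.clip(res.x, *bounds))


# ---------------------------------------------------------------------------
# arcsine square root (baseline transform)
# ---------------------------------------------------------------------------

def arcsine_sqrt(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise EnvimError("arcsine_sqrt requires values in [0, 1]")
    return np.arcsin(np.sqrt(y))


def inverse_arcsine_sqrt(yp: np.ndarray) -> np.ndarray:
    yp = np.asarray(yp, dtype=float)
    return np.square(np.sin(np.clip(yp, 0.0, np.pi / 2)))


# ---------------------------------------------------------------------------
# fitting / applying response transforms
# ---------------------------------------------------------------------------

def fit_response_transform(
    Y: pd.DataFrame, method: str = "BOX_COX"
) -> TransformParams:
    """Fit per-metabolite transform parameters on a training metabolite table.

    For BOX_COX, metabolites containing zeros get an offset delta of half the
    minimum positive training value; the exponent omega is then profiled on
    y + delta.  For ARCSINE_SQRT no parameters are needed (omega/delta kept
    at 1/0 for bookkeeping).
    """
    ids = [str(c) for c in Y.columns]
    n = len(ids)
    omega = np.ones(n)
    delta = np.zeros(n)
    if method == "BOX_COX":
        for j, col in enumerate(Y.columns):
            y = Y[col].to_numpy(dtype=float)
            pos = y[y > 0]
            if len(pos) == 0:
                raise EnvimError(f"metabolite {col} has no positive training values")
            if (y == 0).any():
                delta[j] = 0.5 * pos.min()
            omega[j] = fit_box_cox(y + delta[j])
    elif method != "ARCSINE_SQRT":
        raise ParameterError(f"unknown transform method {method!r}")
    return TransformParams(metabolite_ids=ids, omega=omega, delta=delta, method=method)


def apply_response_transform(Y: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    cols = {}
    for j, col in enumerate(params.metabolite_ids):
        y = Y[col].to_numpy(dtype=float)
        if params.method == "BOX_COX":
            cols[col] = box_cox(y + params.delta[j], params.omega[j])
        else:
            cols[col] = arcsine_sqrt(y)
    return pd.DataFrame(cols, index=Y.index)


def invert_response_transform(Yp: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Back-transform predictions to the compositional scale; clamps at 0."""
    cols = {}
    for j, col in enumerate(params.metabolite_ids):
        yp = Yp[col].to_numpy(dtype=float)
        if params.method == "BOX_COX":
            cols[col] = np.maximum(
                inverse_box_cox(yp, params.omega[j]) - params.delta[j], 0.0
            )
        else:
            cols[col] = inverse_arcsine_sqrt(yp)
    return pd.DataFrame(cols, index=Yp.index)


# ---------------------------------------------------------------------------
# normality diagnostics
# ---------------------------------------------------------------------------

def normality_comparison(metab: AbundanceTable) -> pd.DataFrame:
    """Shapiro-Wilk -log10 p for Box-Cox vs arcsine-sqrt, per metabolite.

    Box-Cox uses the per-metabolite fitted exponent.  Constant metabolites
    are excluded (the test is undefined for them).
    """
    Y = metab.data
    if Y.shape[0] < 3 or Y.shape[0] > 5000:
        raise ParameterError("Shapiro-Wilk requires 3 <= n <= 5000 samples")
    rows = []
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        y = y[~np.isnan(y)]
        if len(y) < 3 or np.ptp(y) == 0:
            continue
        pos = y[y > 0]
        d = 0.5 * pos.min() if (y == 0).any() else 0.0
        omega = fit_box_cox(y + d)
        p_bc = stats.shapiro(box_cox(y + d, omega)).pvalue
        p_as = stats.shapiro(arcsine_sqrt(np.clip(y, 0.0, 1.0))).pvalue
        rows.append(
            {
                "metabolite_id": str(col),
                "neglog10p_boxcox": -np.log10(max(p_bc, 1e-300)),
                "neglog10p_arcsine": -np.log10(max(p_as, 1e-300)),
            }
        )
    return pd.DataFrame(rows).set_index("metabolite_id")
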