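"""Per-metabolite scoring of predictions and summary statistics.

A metabolite counts as well-predicted (WP) when the Spearman correlation
between its predicted and observed abundances reaches 0.3 (a conventional
medium effect size).  MSE is computed on the compositional scale, after the
back-transform, so methods with different response transforms are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .tables import AbundanceTable

WP_THRESHOLD = 0.3


def evaluate_predictions(
    pred: AbundanceTable, obs: AbundanceTable, stage: str = "TEST"
) -> pd.DataFrame:
    """Spearman r, MSE and the well-predicted flag for each metabolite.

    Constant predictions or observations leave the correlation undefined
    (reported as NaN, counted as not well-predicted).
    """
    if pred.sample_ids != obs.sample_ids:
        raise ParameterError("prediction and observation sample ids differ")
    if pred.feature_ids != obs.feature_ids:
        raise ParameterError("prediction and observation metabolite ids differ")
    rows = []
    for col in pred.data.columns:
        p = pred.data[col].to_numpy(dtype=float)
        o = obs.data[col].to_numpy(dtype=float)
        ok = ~(np.isnan(p) | np.isnan(o))
        p, o = p[ok], o[ok]
        mse = float(np.mean((p - o) ** 2)) if len(p) else np.nan
        if len(p) < 2 or np.ptp(p) == 0 or np.ptp(o) == 0:
            r = np.nan
        else:
            r = float(stats.spearmanr(p, o).statistic)
        rows.append(
            dict(
                metabolite_id=str(col),
                spearman_r=r,
                mse=mse,
                well_predicted=bool(r >= WP_THRESHOLD) if not np.isnan(r) else False,
                n_samples=int(len(p)),
                stage=stage,
            )
        )
    return pd.DataFrame(rows).set_index("metabolite_id")


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """WP counts and percentages per stage (percent = round(100 * WP / NM))."""
    if report.empty:
        raise ParameterError("empty prediction report")
    rows = []
    for stage, grp in report.groupby("stage", sort=False):
        nm = len(grp)
        wp = int(grp["well_predicted"].sum())
        rows.append(dict(stage=stage, NM=nm, WP=wp, percent=int(round(100 * wp / nm))))
    return pd.DataFrame(rows)


def training_r2(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between fitted and observed values.

    Used as an overfitting diagnostic on the training stage; NaN when either
    vector is constant.
    """
    fitted = np.asarray(fitted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(fitted) != len(observed) or len(fitted) < 3:
        raise ParameterError("training_r2 needs two equal-length vectors, n >= 3")
    if np.ptp(fitted) == 0 or np.ptp(observed) == 0:
        return float("nan")
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)
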