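"""Elastic-net metabolite prediction with variable-importance thresholding.

The model predicts each (transformed) metabolite from (rank-normalised)
gene-family abundances with a penalised linear model

    L(k) = 1/(2N) sum_i (y_i - x_i' M_k b)^2
           + lambda * sum_j s_kj { (1-alpha)/2 b_j^2 + alpha |b_j| }

where s_k is the indicator of gene families whose random-forest variable
importance (scaled to 0-100) reaches the threshold k, and M_k the matching
selection matrix.  For every candidate threshold k the elastic net is fitted
over a 10-fold cross-validated (alpha, lambda) grid with fold assignments
shared across all fits for one metabolite; the global minimiser of the CV
mean squared error over (k, alpha, lambda) is kept.  With K = {0} and the
same folds the procedure reduces exactly to the plain cross-validated
elastic net, which is also the baseline comparison mode (interior alpha
grid, arcsine-square-root response transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from scipy import stats

from .errors import DegenerateTargetError, ParameterError
from .tables import AbundanceTable, WeightMatrix
from .transforms import (
    TransformParams,
    apply_response_transform,
    fit_response_transform,
    invert_response_transform,
    rank_inverse_normal,
)

DEFAULT_K_GRID = tuple(range(0, 100, 10))  # {0, 10, ..., 90}


def default_alpha_grid(size: int = 10) -> np.ndarray:
    """Evenly spaced elastic-net mixing values including the 0 and 1 endpoints."""
    return np.linspace(0.0, 1.0, size)


def baseline_alpha_grid(size: int = 10) -> np.ndarray:
    """Interior mixing grid used by the baseline mode (no ridge/lasso endpoints)."""
    return np.linspace(0.05, 0.95, size)


@dataclass
class ENMHyperparams:
    """Cross-validation settings shared by every elastic-net fit."""

    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    n_folds: int = 10
    lambda_path_length: int = 100
    min_lambda_ratio: float = 1e-3
    lambdas: np.ndarray | None = None  # explicit path overriding the automatic one
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 2000

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if ((self.alpha_grid < 0) | (self.alpha_grid > 1)).any():
            raise ParameterError("alpha grid values must lie in [0, 1]")


@dataclass
class ENMResult:
    alpha: float
    lam: float
    intercept: float
    coefficients: np.ndarray  # input scale
    cv_mse: float


@dataclass
class ThresholdSelection:
    k: float
    selected: np.ndarray  # boolean indicator over features


@dataclass
class EnvimFit:
    """Chosen model for one metabolite: threshold, penalty, coefficients."""

    metabolite_id: str
    best_k: float
    best_alpha: float
    best_lambda: float
    cv_mse: float
    coefficients: np.ndarray  # full gene-length vector, zeros outside selection
    intercept: float
    importance: np.ndarray | None = None
    n_selected: int = 0


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

def make_fold_ids(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Balanced random fold labels in [0, n_folds), reproducible by seed."""
    if n_folds > n:
        raise ParameterError(f"n_folds={n_folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    ids = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    return rng.permutation(ids)


# ---------------------------------------------------------------------------
# elastic net with shared folds
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _lambda_path(Z: np.ndarray, yc: np.ndarray, alpha: float, hp: ENMHyperparams) -> np.ndarray:
    if hp.lambdas is not None:
        return np.sort(np.asarray(hp.lambdas, dtype=float))[::-1]
    n = len(yc)
    # the lasso entry point; for the ridge end of the grid the conventional
    # 0.001 floor keeps lambda_max finite
    a = max(alpha, 1e-3)
    lam_max = np.abs(Z.T @ yc).max() / (n * a)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * hp.min_lambda_ratio, hp.lambda_path_length)


def _ridge_path_coefs(Z: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions for all lambdas at once via one SVD; shape (p, L)."""
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uy = U.T @ yc
    shrink = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
    return Vt.T @ (shrink * uy[:, None])


def _enet_path_coefs(
    Z: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray, hp: ENMHyperparams
) -> np.ndarray:
    if alpha == 0.0:
        return _ridge_path_coefs(Z, yc, lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            np.asfortranarray(Z, dtype=np.float64),
            np.ascontiguousarray(yc, dtype=np.float64),
            l1_ratio=alpha,
            alphas=lambdas,
            tol=hp.tol,
            max_iter=hp.max_iter,
            check_input=False,
        )
    return coefs


def fit_enm_cv(
    X: np.ndarray,
    y: np.ndarray,
    hp: ENMHyperparams,
    fold_ids: np.ndarray | None = None,
) -> ENMResult:
    """Cross-validated elastic net over the (alpha, lambda) grid.

    Features are standardised internally (per training fold during CV, on
    the full data for the final refit); coefficients are reported on the
    input scale.  The (alpha, lambda) pair minimising the pooled CV MSE is
    refitted on all rows.  Ties prefer the larger lambda (sparser model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if fold_ids is None:
        fold_ids = make_fold_ids(n, hp.n_folds, hp.seed)
    fold_ids = np.asarray(fold_ids)
    if len(fold_ids) != n:
        raise ParameterError("fold_ids length must match the number of rows")
    if np.unique(fold_ids).size > n:
        raise ParameterError("more folds than samples")

    Zfull, mean_full, sd_full = _standardize(X)
    yc_full = y - y.mean()

    paths = [_lambda_path(Zfull, yc_full, a, hp) for a in hp.alpha_grid]
    sq_err = [np.zeros(len(lams)) for lams in paths]
    for f in np.unique(fold_ids):
        tr, va = fold_ids != f, fold_ids == f
        Ztr, m_tr, s_tr = _standardize(X[tr])
        ytr_mean = y[tr].mean()
        ytr_c = y[tr] - ytr_mean
        Zva = (X[va] - m_tr) / s_tr
        for a_idx, alpha in enumerate(hp.alpha_grid):
            coefs = _enet_path_coefs(Ztr, ytr_c, alpha, paths[a_idx], hp)
            pred = ytr_mean + Zva @ coefs  # (n_va, L)
            sq_err[a_idx] += ((y[va][:, None] - pred) ** 2).sum(axis=0)
    best = None
    for a_idx, alpha in enumerate(hp.alpha_grid):
        cv_mse = sq_err[a_idx] / n
        # within one alpha prefer the larger lambda on ties (paths descend)
        j = int(np.argmin(cv_mse))
        cand = (float(cv_mse[j]), float(paths[a_idx][j]), float(alpha))
        if best is None or cand[0] < best[0]:
            best = cand
    cv_mse_best, lam_best, alpha_best = best

    coefs_std = _enet_path_coefs(
        Zfull, yc_full, alpha_best, np.asarray([lam_best]), hp
    )[:, 0]
    coef = coefs_std / sd_full
    intercept = float(y.mean() - coef @ mean_full)
    return ENMResult(
        alpha=alpha_best,
        lam=lam_best,
        intercept=intercept,
        coefficients=coef,
        cv_mse=cv_mse_best,
    )


# ---------------------------------------------------------------------------
# random-forest variable importance
# ---------------------------------------------------------------------------

def default_mtry_grid(p: int) -> list[int]:
    cands = {max(1, p // 3), max(1, int(np.sqrt(p))), max(1, int(0.8 * p))}
    return sorted(cands)


def rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    mtry_grid: list[int] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Random-forest variable importance, linearly rescaled to [0, 100].

    The features-per-split parameter is tuned on a small grid by CV MSE; the
    forest is then refitted on all rows and the impurity importances are
    rescaled so max = 100 and min = 0 (all zeros if the raw importances are
    all equal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise DegenerateTargetError("response is constant; importance undefined")
    if n < 2 * n_folds:
        raise ParameterError(f"need at least {2 * n_folds} rows for {n_folds}-fold tuning")
    grid = mtry_grid if mtry_grid is not None else default_mtry_grid(p)
    grid = sorted({min(max(1, int(g)), p) for g in grid})

    best_mtry = grid[0]
    if len(grid) > 1:
        fold_ids = make_fold_ids(n, n_folds, seed)
        best_err = np.inf
        for mtry in grid:
            err = 0.0
            for f in range(n_folds):
                tr, va = fold_ids != f, fold_ids == f
                rf = RandomForestRegressor(
                    n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
                )
                rf.fit(X[tr], y[tr])
                err += ((y[va] - rf.predict(X[va])) ** 2).sum()
            if err < best_err:
                best_err, best_mtry = err, mtry

    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=best_mtry, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    raw = rf.feature_importances_
    if np.ptp(raw) == 0:
        return np.zeros(p)
    return (raw - raw.min()) / np.ptp(raw) * 100.0


# ---------------------------------------------------------------------------
# threshold subsets
# ---------------------------------------------------------------------------

def threshold_subsets(
    vi: np.ndarray, K: tuple[float, ...] = DEFAULT_K_GRID
) -> list[ThresholdSelection]:
    """Cumulative importance-threshold selections, one per useful k.

    Selections are nested (larger k selects a subset); empty selections are
    dropped and identical consecutive selections are collapsed to the
    largest k producing that set.
    """
    vi = np.asarray(vi, dtype=float)
    out: list[ThresholdSelection] = []
    for k in sorted(K, reverse=True):
        sel = vi >= k
        if not sel.any():
            continue
        if out and (out[-1].selected == sel).all():
            continue  # same set already represented by a larger k
        out.append(ThresholdSelection(k=float(k), selected=sel))
    return out


# ---------------------------------------------------------------------------
# the full per-metabolite procedure
# ---------------------------------------------------------------------------

@dataclass
class RFParams:
    n_trees: int = 500
    mtry_grid: list[int] | None = None
    n_folds: int = 5


def fit_envim(
    X: np.ndarray,
    y: np.ndarray,
    K: tuple[float, ...] = DEFAULT_K_GRID,
    hp: ENMHyperparams | None = None,
    rf: RFParams | None = None,
    metabolite_id: str = "",
) -> EnvimFit:
    """Importance-thresholded elastic net for one (transformed) metabolite.

    ``X`` must already be rank-inverse-normal transformed and ``y`` response
    transformed.  All candidate thresholds share one fold assignment, so the
    chosen model is the exact minimiser of the CV MSE over (k, alpha,
    lambda); ties prefer the larger threshold.
    """
    hp = hp or ENMHyperparams()
    rf = rf or RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise DegenerateTargetError(f"metabolite {metabolite_id or '?'} is constant")
    fold_ids = make_fold_ids(n, hp.n_folds, hp.seed)

    if max(K) > 0:
        vi = rf_importance(
            X, y, n_trees=rf.n_trees, mtry_grid=rf.mtry_grid,
            n_folds=rf.n_folds, seed=hp.seed,
        )
    else:
        # K = {0} selects everything regardless of importance
        vi = np.zeros(p)

    best_fit: ENMResult | None = None
    best_k = 0.0
    best_sel: np.ndarray | None = None
    for sel in threshold_subsets(vi, K):  # descending k: ties keep larger k
        # keep the original array when everything is selected so the K={0}
        # reduction to the plain elastic net is bit-exact
        X_sub = X if sel.selected.all() else X[:, sel.selected]
        res = fit_enm_cv(X_sub, y, hp, fold_ids=fold_ids)
        if best_fit is None or res.cv_mse < best_fit.cv_mse:
            best_fit, best_k, best_sel = res, sel.k, sel.selected

    coef = np.zeros(p)
    coef[best_sel] = best_fit.coefficients
    return EnvimFit(
        metabolite_id=metabolite_id,
        best_k=best_k,
        best_alpha=best_fit.alpha,
        best_lambda=best_fit.lam,
        cv_mse=best_fit.cv_mse,
        coefficients=coef,
        intercept=best_fit.intercept,
        importance=vi if max(K) > 0 else None,
        n_selected=int(best_sel.sum()),
    )


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

@dataclass
class EnvimConfig:
    """Settings for a full training run over all metabolites."""

    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    alpha_grid_size: int = 10
    n_folds: int = 10
    n_trees: int = 500
    mtry_grid: list[int] | None = None
    rf_tune_folds: int = 5
    lambda_path_length: int = 100
    min_lambda_ratio: float = 1e-3
    seed: int = 0
    n_jobs: int = 1
    mode: str = "envim"  # or "baseline"

    def hyperparams(self, seed: int) -> ENMHyperparams:
        grid = (
            default_alpha_grid(self.alpha_grid_size)
            if self.mode == "envim"
            else baseline_alpha_grid(self.alpha_grid_size)
        )
        return ENMHyperparams(
            alpha_grid=grid,
            n_folds=self.n_folds,
            lambda_path_length=self.lambda_path_length,
            min_lambda_ratio=self.min_lambda_ratio,
            seed=seed,
        )

    def rf_params(self) -> RFParams:
        return RFParams(
            n_trees=self.n_trees, mtry_grid=self.mtry_grid, n_folds=self.rf_tune_folds
        )


def _fit_one(
    Z: np.ndarray, y: np.ndarray, cfg: EnvimConfig, seed: int, mid: str
) -> EnvimFit | Exception:
    try:
        K = cfg.k_grid if cfg.mode == "envim" else (0.0,)
        return fit_envim(
            Z, y, K=K, hp=cfg.hyperparams(seed), rf=cfg.rf_params(), metabolite_id=mid
        )
    except Exception as exc:  # error isolation: one bad metabolite is not fatal
        return exc


def fit_all_metabolites(
    genes: AbundanceTable,
    metab: AbundanceTable,
    cfg: EnvimConfig | None = None,
) -> tuple[WeightMatrix, pd.DataFrame, TransformParams]:
    """Train one model per metabolite and assemble the weight matrix.

    Per-metabolite seeds derive deterministically from the master seed
    (seed + column index) so serial and parallel execution agree.  Failures
    on individual metabolites are recorded in the report, not raised.
    """
    cfg = cfg or EnvimConfig()
    if genes.sample_ids != metab.sample_ids:
        raise ParameterError("gene and metabolite tables must share sample order")
    method = "BOX_COX" if cfg.mode == "envim" else "ARCSINE_SQRT"
    params = fit_response_transform(metab.data, method=method)
    Yt = apply_response_transform(metab.data, params)
    Z = rank_inverse_normal(genes.values)

    tasks = [
        (Yt[col].to_numpy(dtype=float), cfg.seed + j, str(col))
        for j, col in enumerate(Yt.columns)
    ]
    results = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_fit_one)(Z, y, cfg, seed, mid) for y, seed, mid in tasks
    )

    gene_ids = genes.feature_ids
    met_ids = metab.feature_ids
    coefs = np.zeros((len(gene_ids), len(met_ids)))
    intercepts = np.zeros(len(met_ids))
    rows = []
    for j, res in enumerate(results):
        if isinstance(res, Exception):
            rows.append(
                dict(metabolite_id=met_ids[j], status="failed", error=str(res),
                     k=np.nan, alpha=np.nan, lam=np.nan, cv_mse=np.nan, n_selected=0)
            )
            continue
        coefs[:, j] = res.coefficients
        intercepts[j] = res.intercept
        rows.append(
            dict(metabolite_id=met_ids[j], status="ok", error="",
                 k=res.best_k, alpha=res.best_alpha, lam=res.best_lambda,
                 cv_mse=res.cv_mse, n_selected=res.n_selected)
        )
    report = pd.DataFrame(rows).set_index("metabolite_id")
    w = WeightMatrix(
        gene_ids=gene_ids,
        metabolite_ids=met_ids,
        intercepts=intercepts,
        coefficients=coefs,
        transform_params_ref=method,
    )
    return w, report, params


def predict_metabolites(
    w: WeightMatrix,
    X_test: AbundanceTable,
    transform: TransformParams,
    already_transformed: bool = False,
) -> AbundanceTable:
    """Predict metabolite abundances for new samples from the weight matrix.

    Only gene families present in both the weight matrix and the test table
    contribute; the test matrix is rank-inverse-normal transformed
    independently of training, and predictions are back-transformed to the
    compositional scale with the training transform parameters.
    """
    test_genes = X_test.feature_ids
    Z = X_test.values if already_transformed else rank_inverse_normal(X_test.values)
    pos_in_test = {g: i for i, g in enumerate(test_genes)}
    shared_train_idx = [i for i, g in enumerate(w.gene_ids) if g in pos_in_test]
    shared_test_idx = [pos_in_test[w.gene_ids[i]] for i in shared_train_idx]
    if shared_train_idx:
        B = w.coefficients[shared_train_idx, :]
        pred_t = w.intercepts[None, :] + Z[:, shared_test_idx] @ B
    else:
        warnings.warn("no gene families shared with training; intercept-only predictions")
        pred_t = np.tile(w.intercepts, (len(X_test.sample_ids), 1))
    df = pd.DataFrame(pred_t, index=X_test.data.index, columns=w.metabolite_ids)
    out = invert_response_transform(df, transform)
    return AbundanceTable(data=out, unit="RAW", modality="METABOLITE")


def fit_baseline_enm(
    genes: AbundanceTable,
    metab: AbundanceTable,
    cfg: EnvimConfig | None = None,
) -> tuple[WeightMatrix, pd.DataFrame, TransformParams]:
    """Plain cross-validated elastic net on all features (comparison mode).

    Responses are arcsine-square-root transformed, the mixing grid is
    interior, and each metabolite gets a "predictable" flag: the BH-adjusted
    q-value of the training-set Spearman correlation test between fitted and
    observed values below 0.05.
    """
    from statsmodels.stats.multitest import multipletests

    cfg = cfg or EnvimConfig()
    cfg = EnvimConfig(**{**cfg.__dict__, "mode": "baseline"})
    w, report, params = fit_all_metabolites(genes, metab, cfg)
    fitted = predict_metabolites(w, genes, params)
    pvals = []
    for col in w.metabolite_ids:
        obs = metab.data[col].to_numpy(dtype=float)
        fit = fitted.data[col].to_numpy(dtype=float)
        if np.ptp(fit) == 0 or np.ptp(obs) == 0:
            pvals.append(1.0)
            continue
        pvals.append(float(stats.spearmanr(obs, fit).pvalue))
    rej, qvals, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
    report = report.copy()
    report["train_spearman_q"] = qvals
    report["predictable"] = rej
    return w, report, params
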