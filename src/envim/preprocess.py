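"""Preprocessing of paired gene-family and metabolite abundance tables.

The flow mirrors standard practice for paired microbiome/metabolome studies:
total-sum scaling to compositional units, abundance and prevalence filters,
removal of features and samples dominated by missing values, left-censored
(QRILC) imputation of the remaining metabolite missingness, an optional
restriction of the target metabolites to those occurring in pathways observed
in the community's functional profile, sample matching across assays, and a
reproducible train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateSampleError,
    EmptyResultError,
    ImputationError,
    MatchingError,
    ParameterError,
)
from .tables import AbundanceTable, FeatureMap, MapKind, Modality, Unit

# defaults from the published analysis: gene families are kept at mean
# relative abundance >= 5e-5 and <= 90% zeros; metabolites at >= 1e-4.
GENE_FILTER = dict(min_mean_rel_abund=5e-5, max_zero_fraction=0.9)
METABOLITE_FILTER = dict(min_mean_rel_abund=1e-4, max_zero_fraction=0.9)


@dataclass(frozen=True)
class FilterSpec:
    """Abundance/prevalence filter thresholds for RELATIVE-unit tables."""

    min_mean_rel_abund: float
    max_zero_fraction: float

    def __post_init__(self) -> None:
        if self.min_mean_rel_abund < 0:
            raise ParameterError("min_mean_rel_abund must be >= 0")
        if not 0 <= self.max_zero_fraction <= 1:
            raise ParameterError("max_zero_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SplitAssignment:
    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]
    test_fraction: float
    seed: int


def to_relative_abundance(t: AbundanceTable) -> AbundanceTable:
    """Total-sum scale each sample so features sum to 1 (compositional)."""
    if t.unit is not Unit.RAW:
        raise ParameterError("table is already in RELATIVE units")
    vals = t.values
    if np.isnan(vals).any():
        raise ParameterError("cannot normalise a table with missing values")
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = [t.sample_ids[i] for i in np.flatnonzero(zero)[:5]]
        raise DegenerateSampleError(f"sample(s) with zero total abundance: {bad}")
    df = pd.DataFrame(vals / sums[:, None], index=t.data.index, columns=t.data.columns)
    return AbundanceTable(data=df, unit=Unit.RELATIVE, modality=t.modality)


def filter_features(t: AbundanceTable, spec: FilterSpec) -> AbundanceTable:
    """Keep features with mean >= min_mean_rel_abund and zero-fraction <= max.

    Missing entries are excluded from the mean but count as zeros for
    prevalence (metabolite tables are filtered before imputation).
    """
    if t.unit is not Unit.RELATIVE:
        raise ParameterError("filter_features expects RELATIVE units")
    vals = t.values
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=0)
    zero_frac = (np.isnan(vals) | (vals == 0)).mean(axis=0)
    keep = (means >= spec.min_mean_rel_abund) & (zero_frac <= spec.max_zero_fraction)
    if not keep.any():
        raise EmptyResultError("feature filter removed every feature")
    df = t.data.loc[:, t.data.columns[keep]]
    return AbundanceTable(data=df, unit=t.unit, modality=t.modality)


def drop_high_missing(
    t: AbundanceTable, max_na_fraction: float, axis: str = "features"
) -> AbundanceTable:
    """Drop metabolite features (or samples) whose NA fraction exceeds the cap."""
    if t.modality is not Modality.METABOLITE:
        raise ParameterError("drop_high_missing applies to metabolite tables")
    na = np.isnan(t.values)
    if axis == "features":
        keep = na.mean(axis=0) <= max_na_fraction
        df = t.data.loc[:, t.data.columns[keep]]
    elif axis == "samples":
        keep = na.mean(axis=1) <= max_na_fraction
        df = t.data.loc[t.data.index[keep], :]
    else:
        raise ParameterError(f"axis must be 'features' or 'samples', got {axis!r}")
    return AbundanceTable(data=df, unit=t.unit, modality=t.modality)


def censored_normal_fit(y: np.ndarray) -> tuple[float, float, float]:
    """Estimate (mu, sigma, censor_point) of a left-censored normal sample.

    ``y`` is a log-scale vector with NaN marking the censored entries.  The
    underlying normal's (mu, sigma) are estimated by least-squares regression
    of the observed empirical quantiles, taken at probabilities in (m, 1)
    where m is the missing fraction, on standard-normal quantiles.  The
    censoring point is mu + sigma * Phi^{-1}(m), never above the smallest
    observed value.
    """
    missing = np.isnan(y)
    m = float(missing.mean())
    obs = np.sort(y[~missing])
    # probabilities spanning the uncensored part of the distribution
    probs = np.linspace(m + 0.001, 0.999, 100)
    # empirical quantile of the full distribution at p > m is the observed
    # quantile at (p - m) / (1 - m)
    emp_q = np.quantile(obs, (probs - m) / (1.0 - m))
    theo_q = stats.norm.ppf(probs)
    slope, intercept = np.polyfit(theo_q, emp_q, 1)
    sigma, mu = abs(float(slope)), float(intercept)
    censor_point = mu + sigma * stats.norm.ppf(m) if m > 0 else obs[0]
    # left-censoring semantics: nothing imputed may exceed the observed floor
    censor_point = min(censor_point, float(obs[0]))
    return mu, sigma, censor_point


def _qrilc_feature(
    y: np.ndarray, tune_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Impute one log-scale feature vector with left-censored draws.

    Missing entries are drawn from Normal(mu, tune_sigma * sigma) truncated
    above at the censoring point via the inverse CDF.
    """
    mu, sigma, censor_point = censored_normal_fit(y)
    missing = np.isnan(y)
    out = y.copy()
    n_miss = int(missing.sum())
    if tune_sigma * sigma == 0:
        out[missing] = censor_point
        return out
    upper = stats.norm.cdf(censor_point, loc=mu, scale=tune_sigma * sigma)
    u = rng.uniform(0.0, upper, size=n_miss)
    out[missing] = stats.norm.ppf(u, loc=mu, scale=tune_sigma * sigma)
    return out


def impute_qrilc(
    t: AbundanceTable, tune_sigma: float = 1.0, seed: int = 0
) -> AbundanceTable:
    """Quantile-regression imputation of left-censored metabolite values.

    Works feature-wise on the natural-log scale and exponentiates the imputed
    draws back; observed values are never altered.  Deterministic given the
    seed.
    """
    if t.modality is not Modality.METABOLITE:
        raise ParameterError("impute_qrilc applies to metabolite tables")
    vals = t.values
    if not np.isnan(vals).any():
        return t
    if (vals[~np.isnan(vals)] <= 0).any():
        raise ParameterError("impute_qrilc requires positive observed values")
    rng = np.random.default_rng(seed)
    out = np.empty_like(vals)
    for j, col in enumerate(t.data.columns):
        y = vals[:, j]
        n_obs = int((~np.isnan(y)).sum())
        if np.isnan(y).any() and n_obs < 3:
            raise ImputationError(
                f"metabolite {col} has only {n_obs} observed values (need >= 3)"
            )
        if not np.isnan(y).any():
            out[:, j] = y
            continue
        out[:, j] = np.exp(_qrilc_feature(np.log(y), tune_sigma, rng))
    df = pd.DataFrame(out, index=t.data.index, columns=t.data.columns)
    return AbundanceTable(data=df, unit=t.unit, modality=t.modality)


def filter_metabolites_by_pathway(
    t: AbundanceTable, fmap: FeatureMap, observed_pathways: set[str]
) -> AbundanceTable:
    """Keep metabolites mapped to at least one observed pathway."""
    if fmap.kind is not MapKind.METABOLITE_TO_PATHWAY:
        raise ParameterError("pathway filter needs a METABOLITE_TO_PATHWAY map")
    if not observed_pathways:
        raise EmptyResultError("the observed pathway set is empty")
    in_pathways = {f for f, g in fmap.entries if g in observed_pathways}
    keep = [c for c in t.data.columns if str(c) in in_pathways]
    if not keep:
        raise EmptyResultError("no metabolite maps to an observed pathway")
    df = t.data.loc[:, keep]
    return AbundanceTable(data=df, unit=t.unit, modality=t.modality)


def match_and_combine(
    gene_tables: list[AbundanceTable], metab: AbundanceTable
) -> tuple[AbundanceTable, AbundanceTable]:
    """Restrict all assays to their shared samples, concatenating gene tables.

    With more than one gene table, features are suffixed ``|DNA`` / ``|RNA``
    so the same gene name from both assays remains two distinct predictors
    and the combined modality becomes BOTH.
    """
    if not gene_tables:
        raise ParameterError("at least one gene table is required")
    shared = set(metab.sample_ids)
    for g in gene_tables:
        shared &= set(g.sample_ids)
    if not shared:
        raise MatchingError("no samples shared across all tables")
    order = [s for s in gene_tables[0].sample_ids if s in shared]
    if len(gene_tables) == 1:
        g = gene_tables[0]
        gene_df = g.data.loc[order]
        gene_out = AbundanceTable(data=gene_df, unit=g.unit, modality=g.modality)
    else:
        parts = []
        for g in gene_tables:
            sub = g.data.loc[order].copy()
            sub.columns = [f"{c}|{g.modality.value}" for c in sub.columns]
            parts.append(sub)
        gene_df = pd.concat(parts, axis=1)
        # each assay stays on its own compositional scale; the concatenated
        # table is no longer a single composition, so it is labelled RAW
        gene_out = AbundanceTable(data=gene_df, unit=Unit.RAW, modality=Modality.BOTH)
    metab_out = AbundanceTable(
        data=metab.data.loc[order], unit=metab.unit, modality=metab.modality
    )
    return gene_out, metab_out


def split_train_test(
    sample_ids, test_fraction: float = 0.25, seed: int = 0
) -> SplitAssignment:
    """Uniform random train/test partition of samples, reproducible by seed."""
    ids = [str(s) for s in sample_ids]
    if len(ids) < 4:
        raise ParameterError("need at least 4 samples to split")
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test_idx = set(perm[:n_test].tolist())
    test = tuple(ids[i] for i in sorted(test_idx))
    train = tuple(ids[i] for i in range(len(ids)) if i not in test_idx)
    return SplitAssignment(
        train_sample_ids=train,
        test_sample_ids=test,
        test_fraction=test_fraction,
        seed=seed,
    )
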