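"""Synthetic paired gene-family / metabolite datasets with known ground truth.

The generator emulates the statistical structure the predictor assumes in
real paired multi-omics data: zero-inflated, strongly skewed compositional
gene-family abundances; metabolites that are sparse linear functions of the
rank-normalised gene features plus Gaussian noise on the transformed scale,
pushed through an inverse Box-Cox map into positive abundances; species
structure over genes; and optional left-censored (MNAR) metabolite
missingness.  Every planted quantity is returned as ground truth so support
recovery, prediction accuracy and enrichment can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tables import AbundanceTable, FeatureMap, MapKind, Modality, Unit
from .transforms import inverse_box_cox, rank_inverse_normal

# signal metabolites are mapped into this share of the per-sample composition
_SIGNAL_LO, _SIGNAL_HI = 1e-4, 2e-2
# latent values are rescaled into this window before the inverse Box-Cox
_LATENT_LO, _LATENT_HI = 0.1, 10.0


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults give a realistic desk-scale cohort.

    ``snr`` is sd(signal part) / noise sd on the transformed scale; set
    ``noise_sd`` to override the noise level directly.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_metabolites: int = 20
    n_species: int = 10
    n_signal_metabolites: int = 3
    support_size: int = 5
    effect_size_range: tuple[float, float] = (0.5, 1.5)
    snr: float = 3.0
    noise_sd: float | None = None
    zero_inflation: float = 0.3
    censor_fraction: float = 0.0
    boxcox_omega: float = 0.0
    within_species_support: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size > self.n_genes:
            raise ParameterError("support_size cannot exceed n_genes")
        if self.n_signal_metabolites > self.n_metabolites:
            raise ParameterError("n_signal_metabolites cannot exceed n_metabolites")
        if not 0 <= self.zero_inflation < 1:
            raise ParameterError("zero_inflation must be in [0, 1)")
        if not 0 <= self.censor_fraction < 1:
            raise ParameterError("censor_fraction must be in [0, 1)")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset."""

    supports: dict[str, list[str]]  # signal metabolite -> support gene ids
    coefficients: dict[str, np.ndarray]  # signal metabolite -> b_j over support
    omega: float
    gene_species: FeatureMap
    donor_species: str | None = None  # species hosting every planted support
    censored: pd.DataFrame | None = None  # metabolite x sample boolean mask


def _species_assignment(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Gene -> species labels; every species gets at least support_size + 2 genes."""
    floor = cfg.support_size + 2
    if cfg.n_species * floor > cfg.n_genes:
        raise ParameterError(
            f"{cfg.n_species} species x floor {floor} genes exceeds n_genes={cfg.n_genes}"
        )
    sizes = np.full(cfg.n_species, floor)
    extra = cfg.n_genes - sizes.sum()
    sizes += rng.multinomial(extra, np.full(cfg.n_species, 1 / cfg.n_species))
    labels = np.repeat(np.arange(cfg.n_species), sizes)
    return labels[rng.permutation(cfg.n_genes)]


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Strictly increasing affine map of x onto [lo, hi] (constant -> midpoint)."""
    span = np.ptp(x)
    if span == 0:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (x - x.min()) / span * (hi - lo)


def generate_paired_dataset(
    cfg: SyntheticConfig,
) -> tuple[AbundanceTable, AbundanceTable, GroundTruth]:
    """Generate matched gene and metabolite tables plus full ground truth.

    Gene raw abundances are feature-specific log-normals, independently
    zeroed with probability ``zero_inflation`` and total-sum scaled.  Each
    signal metabolite is built from a sparse linear predictor on the
    rank-normalised gene features, mapped through an inverse Box-Cox into a
    small share of the composition; noise metabolites split the remaining
    mass via per-sample Dirichlet weights so every row sums to exactly 1.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:05d}" for j in range(p)]
    met_ids = [f"M{j:04d}" for j in range(cfg.n_metabolites)]

    # -- genes: skewed, zero-inflated, compositional -----------------------
    mu = rng.uniform(0.0, 4.0, size=p)
    sd = rng.uniform(0.5, 1.5, size=p)
    raw = np.exp(rng.normal(mu[None, :], sd[None, :], size=(n, p)))
    if cfg.zero_inflation > 0:
        raw[rng.random((n, p)) < cfg.zero_inflation] = 0.0
    totals = raw.sum(axis=1)
    if (totals == 0).any():
        raise ParameterError("zero_inflation produced an empty sample; lower it")
    rel = raw / totals[:, None]
    genes = AbundanceTable(
        data=pd.DataFrame(rel, index=sample_ids, columns=gene_ids),
        unit=Unit.RELATIVE,
        modality=Modality.DNA,
    )

    species_labels = _species_assignment(cfg, rng)
    species_ids = [f"SP{s:03d}" for s in species_labels]
    fmap = FeatureMap(
        entries=list(zip(gene_ids, species_ids)), kind=MapKind.GENE_TO_SPECIES
    )

    # -- metabolites -------------------------------------------------------
    Z = rank_inverse_normal(rel)
    supports: dict[str, list[str]] = {}
    coeffs: dict[str, np.ndarray] = {}
    donor_name: str | None = None
    signal_vals = np.zeros((n, cfg.n_signal_metabolites))
    lo, hi = cfg.effect_size_range
    if cfg.within_species_support and cfg.n_signal_metabolites > 0:
        # one donor species hosts every planted support, so its genes should
        # dominate the contributing-gene ranks in downstream enrichment
        donor = int(rng.integers(cfg.n_species))
        donor_pool = np.flatnonzero(species_labels == donor)
        if len(donor_pool) < cfg.support_size:
            raise ParameterError(
                f"donor species has {len(donor_pool)} genes < support_size"
            )
        donor_name = f"SP{donor:03d}"
    for s in range(cfg.n_signal_metabolites):
        mid = met_ids[s]
        pool = donor_pool if cfg.within_species_support else np.arange(p)
        support = rng.choice(pool, size=cfg.support_size, replace=False)
        b = rng.uniform(lo, hi, size=cfg.support_size) * rng.choice(
            [-1.0, 1.0], size=cfg.support_size
        )
        signal = Z[:, support] @ b
        sigma = cfg.noise_sd if cfg.noise_sd is not None else float(np.std(signal)) / cfg.snr
        latent = signal + rng.normal(0.0, sigma, size=n)
        ab = inverse_box_cox(_rescale(latent, _LATENT_LO, _LATENT_HI), cfg.boxcox_omega)
        signal_vals[:, s] = _rescale(ab, _SIGNAL_LO, _SIGNAL_HI)
        supports[mid] = [gene_ids[j] for j in support]
        coeffs[mid] = b

    n_noise = cfg.n_metabolites - cfg.n_signal_metabolites
    remainder = 1.0 - signal_vals.sum(axis=1)
    if n_noise > 0:
        weights = rng.dirichlet(np.ones(n_noise), size=n)
        noise_vals = remainder[:, None] * weights
        vals = np.hstack([signal_vals, noise_vals])
    else:
        vals = signal_vals / signal_vals.sum(axis=1, keepdims=True)
    metab = AbundanceTable(
        data=pd.DataFrame(vals, index=sample_ids, columns=met_ids),
        unit=Unit.RELATIVE,
        modality=Modality.METABOLITE,
    )

    censored = pd.DataFrame(False, index=sample_ids, columns=met_ids)
    if cfg.censor_fraction > 0:
        metab = apply_left_censoring(metab, cfg.censor_fraction, seed=cfg.seed + 1)
        censored = metab.data.isna()
    truth = GroundTruth(
        supports=supports,
        coefficients=coeffs,
        omega=cfg.boxcox_omega,
        gene_species=fmap,
        donor_species=donor_name,
        censored=censored,
    )
    return genes, metab, truth


def apply_left_censoring(
    metab: AbundanceTable, censor_fraction: float, seed: int = 0
) -> AbundanceTable:
    """Mask the lowest floor(censor_fraction * n) values of each metabolite.

    This is missing-not-at-random left-censoring: exactly the smallest
    values are hidden, so the minimum observed value is never below the
    largest censored one.  Ties are broken by a seeded random permutation.
    """
    if not 0 <= censor_fraction < 1:
        raise ParameterError("censor_fraction must be in [0, 1)")
    if np.isnan(metab.values).any():
        raise ParameterError("censoring expects a fully observed table")
    if censor_fraction == 0:
        return metab
    rng = np.random.default_rng(seed)
    vals = metab.values.copy()
    n = vals.shape[0]
    n_censor = int(np.floor(censor_fraction * n))
    for j in range(vals.shape[1]):
        tiebreak = rng.permutation(n)
        order = np.lexsort((tiebreak, vals[:, j]))
        vals[order[:n_censor], j] = np.nan
    df = pd.DataFrame(vals, index=metab.data.index, columns=metab.data.columns)
    return AbundanceTable(data=df, unit=metab.unit, modality=metab.modality)
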