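"""Species-level enrichment of prediction-contributing gene families.

Gene families with non-zero weights for at least one well-predicted
metabolite are ranked by their absolute coefficient (aggregated across those
metabolites).  For each species with enough mapped genes, a two-sample
Kolmogorov-Smirnov test compares the species' gene-rank distribution with the
background of all other scored genes; Benjamini-Hochberg control across
species yields q-values, with enrichment called at q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, ParameterError
from .tables import FeatureMap, MapKind, WeightMatrix

Q_THRESHOLD = 0.05


def contributing_gene_scores(
    w: WeightMatrix, wp_flags: dict[str, bool] | pd.Series, aggregate: str = "max"
) -> pd.DataFrame:
    """Score and rank genes contributing to well-predicted metabolites.

    Per gene the score aggregates |coefficient| over the well-predicted
    metabolite columns (``max`` by default; ``sum`` and ``count`` are the
    alternatives); genes with score 0 are dropped and the rest ranked
    descending with average ranks for ties (rank 1 = strongest).
    """
    flags = pd.Series(wp_flags)
    wp_cols = [j for j, m in enumerate(w.metabolite_ids) if bool(flags.get(m, False))]
    if not wp_cols:
        raise EmptyResultError("no well-predicted metabolites; nothing to enrich")
    sub = np.abs(w.coefficients[:, wp_cols])
    if aggregate == "max":
        score = sub.max(axis=1)
    elif aggregate == "sum":
        score = sub.sum(axis=1)
    elif aggregate == "count":
        score = (sub > 0).sum(axis=1).astype(float)
    else:
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    keep = score > 0
    if not keep.any():
        raise EmptyResultError("no gene has a non-zero weight for a WP metabolite")
    genes = np.asarray(w.gene_ids)[keep]
    score = score[keep]
    ranks = stats.rankdata(-score, method="average")
    out = pd.DataFrame(
        {"score": score, "rank": ranks}, index=pd.Index(genes, name="gene_id")
    )
    return out.sort_values("rank")


def ks_species_enrichment(
    scores: pd.DataFrame, fmap: FeatureMap, min_set_size: int = 5
) -> pd.DataFrame:
    """Two-sample KS enrichment of each species' gene ranks vs the background.

    Species with fewer than ``min_set_size`` scored genes are skipped;
    BH-adjusted q-values are computed across the tested species.  Scored
    genes missing from the map are ignored (their count is reported in the
    ``n_unmapped`` DataFrame attribute).
    """
    if fmap.kind is not MapKind.GENE_TO_SPECIES:
        raise ParameterError("enrichment needs a GENE_TO_SPECIES map")
    gene_species = dict(fmap.entries)
    ranks = scores["rank"]
    unmapped = [g for g in ranks.index if g not in gene_species]
    rows = []
    by_species: dict[str, list[float]] = {}
    for g, r in ranks.items():
        sp = gene_species.get(g)
        if sp is not None:
            by_species.setdefault(sp, []).append(float(r))
    all_ranks = ranks.to_numpy(dtype=float)
    for sp, in_set in sorted(by_species.items()):
        if len(in_set) < min_set_size:
            continue
        in_set = np.asarray(in_set)
        out_set = np.asarray(
            [float(r) for g, r in ranks.items() if gene_species.get(g) != sp]
        )
        if len(out_set) == 0:
            continue
        ks = stats.ks_2samp(in_set, out_set, alternative="two-sided")
        rows.append(
            dict(
                species_id=sp,
                set_size=len(in_set),
                ks_statistic=float(ks.statistic),
                p_value=float(ks.pvalue),
            )
        )
    if not rows:
        raise EmptyResultError(
            f"no species has >= {min_set_size} scored genes ({len(all_ranks)} genes scored)"
        )
    df = pd.DataFrame(rows).set_index("species_id")
    _, qvals, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = qvals
    df["enriched"] = df["q_value"] < Q_THRESHOLD
    df.attrs["n_unmapped"] = len(unmapped)
    return df.sort_values("p_value")
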