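"""Trend and regulatory-architecture analyses.

Cis/trans decomposition from hybrid allele-resolved expression: within a
hybrid cell both alleles share one trans-acting environment, so the hybrid
allelic log2 ratio isolates linked (cis) regulatory divergence; the
parental ratio carries cis + trans, and their difference is the trans
effect. Pearson correlations relate expression to species traits
(evolutionary divergence, brain weight, gyrification index) at the level of
individual replicate measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def cis_trans_decompose(allelic: pd.DataFrame) -> pd.DataFrame:
    """Per-gene cis and trans effects (log2 units).

    cis = log2(hybrid_human_allele / hybrid_chimp_allele);
    trans = log2(parental_human / parental_chimp) - cis.
    Genes with a zero value anywhere get NaN effects and are logged; the
    additivity identity cis + trans = parental log2 ratio holds exactly for
    all defined rows.
    """
    required = [
        "parental_human",
        "parental_chimp",
        "hybrid_human_allele",
        "hybrid_chimp_allele",
    ]
    missing = [c for c in required if c not in allelic.columns]
    if missing:
        raise ValueError(f"allelic table missing columns {missing}")
    vals = allelic[required].to_numpy(float)
    defined = (vals > 0).all(axis=1)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning("cis/trans undefined for %d gene(s) with zero expression", n_undef)
    with np.errstate(divide="ignore", invalid="ignore"):
        parental = np.log2(vals[:, 0] / vals[:, 1])
        cis = np.log2(vals[:, 2] / vals[:, 3])
    trans = parental - cis
    out = pd.DataFrame(
        {
            "gene_id": allelic["gene_id"] if "gene_id" in allelic.columns else np.arange(len(allelic)),
            "cis_effect": np.where(defined, cis, np.nan),
            "trans_effect": np.where(defined, trans, np.nan),
            "parental_log2_ratio": np.where(defined, parental, np.nan),
            "defined": defined,
        }
    )
    return out


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def expression_trait_trend(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    trait_name: str,
    species_mean: bool = False,
) -> CorrelationResult:
    """Correlate replicate-level expression with a per-species trait.

    Each replicate measurement is paired with its species' trait value
    (replicates are not averaged unless ``species_mean=True``); brain weight
    is log10-transformed, matching the convention for allometric traits.
    """
    if not {"species", "expression"} <= set(expression.columns):
        raise ValueError("expression table needs columns 'species' and 'expression'")
    unknown = set(expression["species"]) - set(traits.index)
    if unknown:
        raise ValueError(f"species {sorted(unknown)[0]!r} absent from trait table")
    if trait_name not in traits.columns:
        raise ValueError(f"unknown trait {trait_name!r}")
    expr = expression
    if species_mean:
        expr = expression.groupby("species", as_index=False)["expression"].mean()
    trait_vals = traits.loc[expr["species"], trait_name].to_numpy(float)
    if trait_name == "brain_weight_g":
        trait_vals = np.log10(trait_vals)
    return pearson_correlation(trait_vals, expr["expression"].to_numpy(float))
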