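"""Synthetic multi-species laminar RNA-seq data with planted ground truth.

The generator emulates the statistical structure the cross-species screen
assumes: four species (human, macaque, tree shrew, mouse) with their
anatomical layer repertoires, at least three biological replicates per
layer, negative-binomial counts over species-shared expression baselines, a
conserved SVZ-enriched gene program present in every species, and one (or
more) human-specific gene engineered to pass the screen's FPKM gates
(highly expressed in human SVZ, near-silent everywhere else).

Expression is planted on the FPKM scale: baselines are drawn as log2 FPKM
and renormalized so that sum(fpkm_g * length_g) = 1e9, which makes the FPKM
recomputed downstream from realized counts agree with the planted values up
to sampling noise. Expected counts are mu = fpkm * library_size * length/1e9
and counts are drawn NB(mu, alpha) with variance mu + alpha*mu^2.

One global seed drives a spawned per-purpose seed sequence, so changing one
planted program does not perturb unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_SPECIES_LAYERS,
    CountMatrix,
    svz_type_layers_present,
)

#: Illustrative species trait table (divergence time from the human lineage
#: in MYA, adult brain weight in grams, gyrification index). Values are
#: round literature-scale numbers used as simulation inputs, not measurements.
DEFAULT_SPECIES_TRAITS = pd.DataFrame(
    {
        "species": [
            "human",
            "chimpanzee",
            "gibbon",
            "macaque",
            "marmoset",
            "tree_shrew",
            "mouse",
        ],
        "divergence_mya": [0.0, 6.0, 20.0, 25.0, 43.0, 74.0, 90.0],
        "brain_weight_g": [1350.0, 385.0, 90.0, 95.0, 8.0, 3.0, 0.4],
        "gyrification_index": [2.57, 2.19, 1.9, 1.73, 1.18, 1.06, 1.0],
    }
).set_index("species", drop=False)


@dataclass
class SimulationSpec:
    """Parameters of the laminar count simulation.

    Defaults mirror the screened study design: 4 species with split-SVZ
    repertoires in human/macaque/tree shrew and a single SVZ in mouse, 5
    replicates per layer (the design requires at least 3; the default of 5
    is set by a power analysis so that a planted log2 FC = 2 effect at
    dispersion 0.1 is detectable at BH 0.05 under per-gene dispersion
    estimation), a 30-gene conserved SVZ program at log2 FC 2, and
    one human-specific gene planted at 80 FPKM in human SVZ layers and 0.5
    FPKM in every layer of every other species (the screen gates at >50 and
    <1.5).
    """

    species_layers: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_LAYERS)
    )
    n_replicates: int = 5
    n_genes: int = 2000
    baseline_log2_fpkm_range: tuple[float, float] = (0.0, 6.0)
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8e6, 12e6)
    gene_length_range: tuple[int, int] = (500, 5000)
    n_conserved_svz_genes: int = 30
    conserved_svz_lfc: float = 2.0
    n_human_specific_genes: int = 1
    human_specific_target_fpkm: float = 80.0
    human_specific_cp_fpkm: float = 5.0
    other_species_max_fpkm: float = 0.5
    ortholog_dropout_fraction: float = 0.1
    reference_species: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.ortholog_dropout_fraction <= 1:
            raise ValueError("ortholog_dropout_fraction must lie in [0, 1]")
        if self.n_conserved_svz_genes + self.n_human_specific_genes > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.reference_species not in self.species_layers:
            raise ValueError(
                f"reference_species {self.reference_species!r} not in species_layers"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    conserved_svz_gene_ids: list[str]
    human_specific_gene_ids: list[str]
    per_gene: pd.DataFrame  # gene_id, role, true log2 FC per contrast class
    extras: dict = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    counts_by_species: dict[str, CountMatrix]
    gene_lengths: pd.Series
    orthologs: pd.DataFrame
    truth: SyntheticTruth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def species_gene_id(reference_gene_id: str, species: str, reference_species: str) -> str:
    if species == reference_species:
        return reference_gene_id
    return f"{species[:3].upper()}_{reference_gene_id}"


def simulate_laminar_counts(spec: SimulationSpec) -> SimulatedDataset:
    """Generate per-species laminar count matrices plus companion tables.

    Returns count matrices keyed by species, a gene-length table covering
    every species' gene ids (orthologs share lengths), a long-format
    ortholog table with one-to-one flags, and the planted truth.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_structure, rng_assign, *rng_species = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(spec.species_layers))
    ]

    ref = spec.reference_species
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]

    lengths = rng_structure.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=spec.n_genes
    ).astype(np.int64)
    lo, hi = spec.baseline_log2_fpkm_range
    base_fpkm = 2.0 ** rng_structure.uniform(lo, hi, size=spec.n_genes)
    # renormalize so sum(fpkm * length) = 1e9: realized column totals then
    # match the nominal library sizes and recomputed FPKM matches planted FPKM
    base_fpkm *= 1e9 / float(np.sum(base_fpkm * lengths))

    perm = rng_assign.permutation(spec.n_genes)
    hs_idx = perm[: spec.n_human_specific_genes]
    cons_idx = perm[
        spec.n_human_specific_genes : spec.n_human_specific_genes + spec.n_conserved_svz_genes
    ]
    hs_ids = [gene_ids[i] for i in sorted(hs_idx)]
    cons_ids = [gene_ids[i] for i in sorted(cons_idx)]
    role = np.full(spec.n_genes, "background", dtype=object)
    role[hs_idx] = "human_specific"
    role[cons_idx] = "conserved_svz"

    counts_by_species: dict[str, CountMatrix] = {}
    length_rows: dict[str, int] = {}
    for species, rng in zip(spec.species_layers, rng_species):
        layers = list(spec.species_layers[species])
        svz_layers = set(svz_type_layers_present(layers))
        sample_ids, meta_rows = [], []
        cols = {}
        for layer in layers:
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{species}_{layer}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append((sid, species, layer, rep))
                lib = rng.uniform(*spec.library_size_range)
                fpkm = base_fpkm.copy()
                if layer in svz_layers:
                    fpkm[cons_idx] *= 2.0**spec.conserved_svz_lfc
                if species == ref:
                    fpkm[hs_idx] = (
                        spec.human_specific_target_fpkm
                        if layer in svz_layers
                        else spec.human_specific_cp_fpkm
                    )
                else:
                    fpkm[hs_idx] = spec.other_species_max_fpkm
                mu = fpkm * lib * lengths / 1e9
                cols[sid] = _nb_draw(rng, mu, spec.dispersion)
        sp_gene_ids = [species_gene_id(g, species, ref) for g in gene_ids]
        counts = pd.DataFrame(cols, index=pd.Index(sp_gene_ids, name="gene_id"))
        samples = pd.DataFrame(
            meta_rows, columns=["sample_id", "species", "layer", "replicate"]
        )
        counts_by_species[species] = CountMatrix(counts=counts, samples=samples)
        for g, l in zip(sp_gene_ids, lengths):
            length_rows[g] = int(l)

    orthologs = _make_orthologs(spec, gene_ids, hs_ids, cons_ids, rng_assign)

    per_gene = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": role,
            "lfc_svz_vs_cp_all_species": np.where(
                role == "conserved_svz", spec.conserved_svz_lfc, 0.0
            ),
            "lfc_svz_vs_cp_human": np.where(
                role == "human_specific",
                np.log2(spec.human_specific_target_fpkm / spec.human_specific_cp_fpkm),
                np.where(role == "conserved_svz", spec.conserved_svz_lfc, 0.0),
            ),
        }
    )
    truth = SyntheticTruth(
        conserved_svz_gene_ids=cons_ids,
        human_specific_gene_ids=hs_ids,
        per_gene=per_gene,
        extras={"spec": spec},
    )
    gene_lengths = pd.Series(length_rows, name="length_bp").rename_axis("gene_id")
    return SimulatedDataset(counts_by_species, gene_lengths, orthologs, truth)


def _make_orthologs(spec, gene_ids, hs_ids, cons_ids, rng) -> pd.DataFrame:
    columns = ["reference_gene_id", "species", "target_gene_id", "one_to_one"]
    other_species = [s for s in spec.species_layers if s != spec.reference_species]
    if not other_species:
        return pd.DataFrame(columns=columns)
    truth_set = set(hs_ids) | set(cons_ids)
    non_truth = [g for g in gene_ids if g not in truth_set]
    n_drop = int(round(spec.ortholog_dropout_fraction * len(non_truth)))
    drop = set(rng.choice(non_truth, size=n_drop, replace=False)) if n_drop else set()
    drop_species = {
        g: other_species[int(rng.integers(len(other_species)))] for g in drop
    }
    rows = []
    for g in gene_ids:
        for sp in other_species:
            one_to_one = drop_species.get(g) != sp
            rows.append(
                (g, sp, species_gene_id(g, sp, spec.reference_species), one_to_one)
            )
    return pd.DataFrame(rows, columns=columns)


def simulate_allelic_expression(
    n_genes: int,
    cis_effect: float,
    trans_effect: float,
    noise_sd: float,
    seed: int,
    base_expression: float = 100.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Allele-resolved expression for a parental/hybrid design.

    The parental log2(human/chimp) ratio is cis + trans + noise; the hybrid
    allelic log2 ratio (both alleles share one cellular environment, so only
    linked regulatory effects persist) is cis + noise; noise terms are
    independent N(0, noise_sd) per measurement.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise_parental = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd else np.zeros(n_genes)
    noise_hybrid = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd else np.zeros(n_genes)
    parental_ratio = cis_effect + trans_effect + noise_parental
    hybrid_ratio = cis_effect + noise_hybrid
    df = pd.DataFrame(
        {
            "gene_id": [f"A{i:05d}" for i in range(n_genes)],
            "parental_human": base_expression * 2.0**parental_ratio,
            "parental_chimp": np.full(n_genes, base_expression),
            "hybrid_human_allele": base_expression * 2.0**hybrid_ratio,
            "hybrid_chimp_allele": np.full(n_genes, base_expression),
        }
    )
    truth = SyntheticTruth(
        conserved_svz_gene_ids=[],
        human_specific_gene_ids=[],
        per_gene=pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "true_cis": np.full(n_genes, cis_effect),
                "true_trans": np.full(n_genes, trans_effect),
                "realized_cis": hybrid_ratio,
                "realized_parental_ratio": parental_ratio,
            }
        ),
        extras={"cis_effect": cis_effect, "trans_effect": trans_effect, "noise_sd": noise_sd},
    )
    return df, truth


def simulate_trait_trend(
    species_traits: pd.DataFrame,
    target_r: float,
    noise_sd: float,
    seed: int,
    trait_name: str = "gyrification_index",
    n_replicates: int = 3,
    intercept: float = 1.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-species replicate expression linear in a trait plus Gaussian noise.

    The slope is calibrated so the population (replicate-level) correlation
    with the trait equals ``target_r``: slope = sign(r) * noise_sd * |r| /
    (sd_trait * sqrt(1 - r^2)). With noise_sd = 0 the points are an exact
    line (sample r = +-1).
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    if len(species_traits) < 3:
        raise ValueError("need at least 3 species for a trait trend")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    traits = species_traits[trait_name].to_numpy(float)
    species = list(species_traits.index)
    sd_trait = traits.std()
    if sd_trait == 0:
        raise ValueError(f"trait {trait_name!r} has zero variance across species")
    if noise_sd == 0 or abs(target_r) == 1:
        slope = 1.0 if target_r >= 0 else -1.0
        sigma = 0.0
    else:
        slope = (
            np.sign(target_r) * noise_sd * abs(target_r)
            / (sd_trait * np.sqrt(1.0 - target_r**2))
        )
        sigma = noise_sd
    rows = []
    for sp, t in zip(species, traits):
        for rep in range(1, n_replicates + 1):
            eps = rng.normal(0.0, sigma) if sigma else 0.0
            rows.append((sp, rep, intercept + slope * t + eps))
    df = pd.DataFrame(rows, columns=["species", "replicate", "expression"])
    truth = SyntheticTruth(
        conserved_svz_gene_ids=[],
        human_specific_gene_ids=[],
        per_gene=pd.DataFrame(),
        extras={
            "target_r": target_r,
            "slope": slope,
            "noise_sd": sigma,
            "trait_name": trait_name,
        },
    )
    return df, truth
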