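"""The five-step cross-species cascade for human-specific SVZ genes.

Step 1 finds, in every species, genes significantly upregulated in each
SVZ-type germinal layer relative to the cortical plate (a conjunction over
ISVZ and OSVZ where the SVZ is split), and records the cross-species
consensus. Step 2 keeps human SVZ-enriched genes whose orthologs are not
SVZ-enriched in any other species. Step 3 keeps genes with clear one-to-one
orthologs in every screened species. Steps 4-5 apply absolute expression
gates: replicate-mean FPKM strictly above ``human_fpkm_min`` in the human
SVZ layers and strictly below ``other_fpkm_max`` in every layer of every
other species.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .data import CountMatrix, svz_type_layers_present
from .de import run_de
from .quantify import compute_fpkm, layer_mean_fpkm


@dataclass
class ScreenConfig:
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    human_fpkm_min: float = 50.0
    other_fpkm_max: float = 1.5
    gate_scope: str = "svz_only"  # or "all_layers_max" for the human gate
    svz_layers_by_species: Mapping[str, Sequence[str]] | None = None
    reference_species: str = "human"

    def __post_init__(self) -> None:
        for name in ("padj_threshold", "lfc_threshold", "human_fpkm_min", "other_fpkm_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gate_scope not in ("svz_only", "all_layers_max"):
            raise ValueError(f"unknown gate_scope {self.gate_scope!r}")


@dataclass
class ScreenReport:
    per_species_svz_sets: dict[str, set[str]]
    consensus_set: set[str]
    human_specific_set: set[str]
    ortholog_set: set[str]
    candidate_set: set[str]
    cardinalities: dict[str, int]
    config: ScreenConfig
    provenance: dict = field(default_factory=dict)
    de_tables: dict = field(default_factory=dict)


def _svz_layers(cm: CountMatrix, species: str, cfg: ScreenConfig) -> list[str]:
    if cfg.svz_layers_by_species and species in cfg.svz_layers_by_species:
        return list(cfg.svz_layers_by_species[species])
    return svz_type_layers_present(cm.layers(species))


def svz_enriched_genes(
    cm: CountMatrix, cfg: ScreenConfig, de_tables: dict | None = None
) -> set[str]:
    """Genes upregulated (padj < thr, log2 FC >= thr) in every SVZ-type
    layer of one species relative to CP."""
    species = cm.samples["species"].unique()
    if len(species) != 1:
        raise ValueError("svz_enriched_genes expects a single-species count matrix")
    species = species[0]
    if "CP" not in cm.layers(species):
        raise ValueError(f"species {species!r} has no CP samples")
    layers = _svz_layers(cm, species, cfg)
    if not layers:
        raise ValueError(f"species {species!r} has no SVZ-type layer")
    enriched: set[str] | None = None
    for layer in layers:
        de = run_de(cm, group_a=(species, "CP"), group_b=(species, layer))
        if de_tables is not None:
            de_tables[(species, layer)] = de
        hits = set(
            de.loc[
                de["tested"]
                & (de["padj"] < cfg.padj_threshold)
                & (de["log2_fc"] >= cfg.lfc_threshold),
                "gene_id",
            ]
        )
        enriched = hits if enriched is None else (enriched & hits)
    return enriched or set()


def _target_to_reference(orthologs: pd.DataFrame, species: str) -> dict[str, str]:
    sub = orthologs[orthologs["species"] == species]
    return dict(zip(sub["target_gene_id"], sub["reference_gene_id"]))


def map_to_reference(
    genes: set[str], orthologs: pd.DataFrame, species: str, reference_species: str
) -> set[str]:
    """Express a species' gene set in reference-species ids; genes with no
    ortholog row are dropped (they cannot participate in cross-species set
    algebra)."""
    if species == reference_species:
        return set(genes)
    if species not in set(orthologs["species"]):
        raise ValueError(f"species {species!r} absent from the ortholog table")
    mapping = _target_to_reference(orthologs, species)
    return {mapping[g] for g in genes if g in mapping}


def consensus_svz(
    per_species_sets: Mapping[str, set[str]],
    orthologs: pd.DataFrame,
    reference_species: str = "human",
) -> set[str]:
    """Intersection of SVZ-enriched sets across species, in reference ids."""
    if len(per_species_sets) < 2:
        raise ValueError("consensus requires at least 2 species")
    mapped = [
        map_to_reference(genes, orthologs, sp, reference_species)
        for sp, genes in per_species_sets.items()
    ]
    out = mapped[0]
    for m in mapped[1:]:
        out = out & m
    return out


def human_specific_genes(
    human_set: set[str],
    other_species_sets: Mapping[str, set[str]],
    orthologs: pd.DataFrame,
    reference_species: str = "human",
) -> set[str]:
    """Human SVZ-enriched genes not SVZ-enriched in any other species.

    Set difference against the union of the other species' sets mapped to
    reference ids; human genes without orthologs survive this step and are
    removed by the orthology filter.
    """
    union: set[str] = set()
    for sp, genes in other_species_sets.items():
        union |= map_to_reference(genes, orthologs, sp, reference_species)
    return set(human_set) - union


def orthology_filter(
    genes: set[str], orthologs: pd.DataFrame, species_list: Sequence[str],
    reference_species: str = "human",
) -> set[str]:
    """Keep genes with a one-to-one ortholog in every screened species."""
    keep = set(genes)
    for sp in species_list:
        if sp == reference_species:
            continue
        sub = orthologs[(orthologs["species"] == sp) & orthologs["one_to_one"]]
        keep &= set(sub["reference_gene_id"])
    return keep


def fpkm_gate(
    genes: set[str],
    fpkm_by_species: Mapping[str, pd.DataFrame],
    samples_by_species: Mapping[str, pd.DataFrame],
    orthologs: pd.DataFrame,
    cfg: ScreenConfig,
) -> set[str]:
    """Absolute expression gates (strict inequalities).

    Human condition: replicate-mean FPKM over the human SVZ-type layers
    (gate_scope="svz_only", default) or the max over all layers
    ("all_layers_max") strictly greater than ``human_fpkm_min``. Other
    species: replicate-mean FPKM strictly below ``other_fpkm_max`` in every
    layer.
    """
    ref = cfg.reference_species
    if ref not in fpkm_by_species:
        raise ValueError(f"no FPKM table for reference species {ref!r}")
    layer_means = {
        sp: layer_mean_fpkm(fpkm_by_species[sp], samples_by_species[sp])
        for sp in fpkm_by_species
    }
    ref_means = layer_means[ref]
    svz_layers = (
        list(cfg.svz_layers_by_species[ref])
        if cfg.svz_layers_by_species and ref in cfg.svz_layers_by_species
        else svz_type_layers_present(list(ref_means.columns))
    )
    mappings = {
        sp: _target_to_reference(orthologs, sp)
        for sp in fpkm_by_species
        if sp != ref
    }
    reverse = {
        sp: {r: t for t, r in mapping.items()} for sp, mapping in mappings.items()
    }
    kept = set()
    for g in genes:
        if g not in ref_means.index:
            raise ValueError(f"gene {g!r} missing from reference FPKM table")
        ref_samples = samples_by_species[ref]
        svz_sample_ids = ref_samples.index[ref_samples["layer"].isin(svz_layers)]
        if cfg.gate_scope == "svz_only":
            human_value = float(fpkm_by_species[ref].loc[g, list(svz_sample_ids)].mean())
        else:
            human_value = float(ref_means.loc[g].max())
        if not human_value > cfg.human_fpkm_min:
            continue
        ok = True
        for sp in fpkm_by_species:
            if sp == ref:
                continue
            target = reverse[sp].get(g)
            if target is None or target not in layer_means[sp].index:
                raise ValueError(
                    f"gene {g!r} has no FPKM entry in species {sp!r} after orthology mapping"
                )
            if not (layer_means[sp].loc[target] < cfg.other_fpkm_max).all():
                ok = False
                break
        if ok:
            kept.add(g)
    return kept


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def run_screen(
    counts_by_species: Mapping[str, CountMatrix],
    gene_lengths: pd.Series,
    orthologs: pd.DataFrame,
    cfg: ScreenConfig | None = None,
    keep_de_tables: bool = False,
) -> ScreenReport:
    """Execute the full cascade and record every intermediate set."""
    cfg = cfg or ScreenConfig()
    ref = cfg.reference_species
    if ref not in counts_by_species:
        raise ValueError(f"reference species {ref!r} missing from inputs")
    de_tables: dict = {}
    per_species: dict[str, set[str]] = {}
    for sp, cm in counts_by_species.items():
        try:
            per_species[sp] = svz_enriched_genes(
                cm, cfg, de_tables if keep_de_tables else None
            )
        except Exception as exc:
            raise RuntimeError(f"screen step 1 failed for species {sp!r}: {exc}") from exc
    consensus = consensus_svz(per_species, orthologs, ref)
    others = {sp: s for sp, s in per_species.items() if sp != ref}
    step2 = human_specific_genes(per_species[ref], others, orthologs, ref)
    step3 = orthology_filter(step2, orthologs, list(counts_by_species), ref)
    fpkm_by_species = {
        sp: compute_fpkm(cm.counts, gene_lengths) for sp, cm in counts_by_species.items()
    }
    samples_by_species = {sp: cm.samples for sp, cm in counts_by_species.items()}
    step45 = fpkm_gate(step3, fpkm_by_species, samples_by_species, orthologs, cfg)
    cardinalities = {
        **{f"step1_svz_enriched_{sp}": len(s) for sp, s in per_species.items()},
        "step1_consensus": len(consensus),
        "step2_human_specific": len(step2),
        "step3_orthologs": len(step3),
        "step45_candidates": len(step45),
    }
    provenance = {
        "input_hashes": {sp: _hash_frame(cm.counts) for sp, cm in counts_by_species.items()},
        "ortholog_hash": _hash_frame(orthologs),
        "gate_scope": cfg.gate_scope,
    }
    return ScreenReport(
        per_species_svz_sets=per_species,
        consensus_set=consensus,
        human_specific_set=step2,
        ortholog_set=step3,
        candidate_set=step45,
        cardinalities=cardinalities,
        config=cfg,
        provenance=provenance,
        de_tables=de_tables,
    )
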