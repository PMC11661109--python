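"""Core containers and run configuration for the laminar screen.

The screen operates on laser-capture-microdissected cortical layers from
several species. The closed layer vocabulary covers the cortical plate (CP),
the germinal ventricular zone (VZ) and the subventricular zone, which in
gyrencephalic-lineage species splits into inner (ISVZ) and outer (OSVZ)
compartments while lissencephalic rodents have a single SVZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of cortical layers handled by the pipeline.
LAYER_VOCAB: tuple[str, ...] = ("CP", "OSVZ", "ISVZ", "VZ", "SVZ")

#: Layers counted as "SVZ-type" (basal-progenitor-enriched germinal layers).
SVZ_TYPE_LAYERS: tuple[str, ...] = ("OSVZ", "ISVZ", "SVZ")

#: Default per-species layer repertoires: primates and tree shrew have a
#: split SVZ; the mouse has a single undivided SVZ.
DEFAULT_SPECIES_LAYERS: dict[str, tuple[str, ...]] = {
    "human": ("CP", "OSVZ", "ISVZ", "VZ"),
    "macaque": ("CP", "OSVZ", "ISVZ", "VZ"),
    "tree_shrew": ("CP", "OSVZ", "ISVZ", "VZ"),
    "mouse": ("CP", "SVZ", "VZ"),
}

METADATA_COLUMNS = ("sample_id", "species", "layer", "replicate")


def validate_metadata(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id."""
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    samples = samples.copy()
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    bad = samples.loc[~samples["layer"].isin(LAYER_VOCAB), "layer"]
    if len(bad):
        raise ValueError(
            f"layer {bad.iloc[0]!r} not in the closed vocabulary {LAYER_VOCAB}"
        )
    reps = pd.to_numeric(samples["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
        raise ValueError("replicate must be a positive integer for every sample")
    samples["replicate"] = reps.astype(int)
    return samples.set_index("sample_id", drop=False)


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with aligned sample metadata.

    ``counts`` is indexed by gene_id with one column per sample, in the same
    order as the rows of ``samples`` (indexed by sample_id with columns
    sample_id, species, layer, replicate).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_metadata(self.samples.reset_index(drop=True))
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id in count matrix: {dup!r}")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.samples.index) - set(self.counts.columns)
            if missing:
                raise ValueError(
                    f"samples in metadata absent from counts: {sorted(missing)}"
                )
            extra = set(self.counts.columns) - set(self.samples.index)
            if extra:
                raise ValueError(
                    f"count columns absent from metadata: {sorted(extra)}"
                )
            self.counts = self.counts[list(self.samples.index)]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValueError("counts contain missing values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(arr != np.round(arr))[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def species(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def samples_for(self, species: str | None = None, layer: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if layer is not None:
            mask &= self.samples["layer"] == layer
        return list(self.samples.index[mask])

    def layers(self, species: str | None = None) -> list[str]:
        sub = self.samples if species is None else self.samples[self.samples["species"] == species]
        present = sub["layer"].unique()
        return [l for l in LAYER_VOCAB if l in present]


def svz_type_layers_present(layers: Sequence[str]) -> list[str]:
    """SVZ-type layers among ``layers``: ISVZ/OSVZ where the SVZ is split,
    otherwise the single SVZ."""
    split = [l for l in ("OSVZ", "ISVZ") if l in layers]
    if split:
        return split
    return [l for l in layers if l == "SVZ"]


@dataclass
class RunConfig:
    """Resolved thresholds and species conventions for a screen run.

    Defaults: the FPKM gates (human > 50, every other species < 1.5) come
    from the screen definition; the differential-expression cutoffs
    (padj < 0.05, log2 fold change >= 1) are package conventions, since the
    screen itself prints no DE thresholds.
    """

    de_padj_threshold: float = 0.05
    de_lfc_threshold: float = 1.0
    human_fpkm_min: float = 50.0
    other_fpkm_max: float = 1.5
    gate_scope: str = "svz_only"
    svz_layers_by_species: Mapping[str, Sequence[str]] | None = None
    reference_species: str = "human"
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_padj_threshold", "de_lfc_threshold", "human_fpkm_min", "other_fpkm_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gate_scope not in ("svz_only", "all_layers_max"):
            raise ValueError(f"unknown gate_scope {self.gate_scope!r}")
        if self.svz_layers_by_species is not None and self.reference_species not in self.svz_layers_by_species:
            raise ValueError(
                f"reference_species {self.reference_species!r} missing from svz_layers_by_species"
            )
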