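"""Readers and writers for the pipeline's tabular artifacts.

All tables are tab-separated UTF-8 text with a header row ("." decimal
mark); contours are two-column CSV. Round-trips are lossless for
identifiers and integers and stable to 1e-9 for floats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data import CountMatrix, RunConfig, validate_metadata

FLOAT_FORMAT = "%.12g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})


def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Load a gene-by-sample count TSV plus its sample metadata TSV.

    The count table has a ``gene_id`` column followed by one column per
    sample; samples are reordered to match the metadata row order.
    """
    raw = _read_tsv(path)
    if "gene_id" not in raw.columns:
        raise ValueError(f"{path}: count table must have a 'gene_id' column")
    meta = validate_metadata(_read_tsv(metadata_path))
    counts = raw.set_index("gene_id")
    missing = [s for s in meta.index if s not in counts.columns]
    if missing:
        raise ValueError(f"{path}: sample {missing[0]!r} from metadata not in count table")
    return CountMatrix(counts=counts[list(meta.index)], samples=meta)


def write_count_matrix(cm: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    cm.samples.to_csv(metadata_path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Gene length table (gene_id, length_bp) as a Series of ints >= 1."""
    df = _read_tsv(path)
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    lengths = df.set_index("gene_id")["length_bp"].astype(np.int64)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"{path}: non-positive length for gene {bad!r}")
    return lengths


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


ORTHOLOG_COLUMNS = ("reference_gene_id", "species", "target_gene_id", "one_to_one")


def read_orthologs(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.copy()
    df["one_to_one"] = df["one_to_one"].astype(bool)
    key = df.loc[df["one_to_one"], ["reference_gene_id", "species"]]
    if key.duplicated().any():
        raise ValueError(f"{path}: duplicate one-to-one (reference_gene_id, species) pair")
    return df[list(ORTHOLOG_COLUMNS)]


def write_orthologs(orthologs: pd.DataFrame, path: str | Path) -> None:
    orthologs[list(ORTHOLOG_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species trait table: divergence time (MYA), brain weight (g), GI."""
    df = _read_tsv(path)
    required = ("species", "divergence_mya", "brain_weight_g", "gyrification_index")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["gyrification_index"] < 1).any():
        raise ValueError(f"{path}: gyrification_index must be >= 1")
    if (df["divergence_mya"] < 0).any():
        raise ValueError(f"{path}: divergence_mya must be >= 0")
    return df.set_index("species", drop=False)


def read_allelic(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = (
        "gene_id",
        "parental_human",
        "parental_chimp",
        "hybrid_human_allele",
        "hybrid_chimp_allele",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    vals = df[list(required[1:])].to_numpy(float)
    if (vals < 0).any():
        raise ValueError(f"{path}: allelic expression values must be >= 0")
    return df


def read_contour(path: str | Path) -> np.ndarray:
    """Ordered (x, y) contour points from a two-column CSV with header."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: contour CSV must have columns x,y")
    return df[["x", "y"]].to_numpy(float)


def write_contour(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["x", "y"]).to_csv(path, index=False)


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    The YAML schema mirrors the RunConfig fields; unknown keys are rejected
    naming the field.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config field: {sorted(unknown)[0]!r}")
    return RunConfig(**values)


# ---------------------------------------------------------------------------
# Screen report serialization: one gene-list TSV per cascade step plus a
# summary of cardinalities, so the full provenance of the candidate set can
# be re-read exactly.

STEP_FILES = {
    "step1_consensus": "step1_consensus_genes.tsv",
    "step2_human_specific": "step2_human_specific_genes.tsv",
    "step3_orthologs": "step3_ortholog_genes.tsv",
    "step45_candidates": "step45_candidate_genes.tsv",
}


def write_screen_report(report, out_dir: str | Path) -> None:
    """Write a ScreenReport as a directory of TSVs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for species, genes in sorted(report.per_species_svz_sets.items()):
        _write_gene_list(genes, out / f"step1_svz_enriched_{species}.tsv")
    _write_gene_list(report.consensus_set, out / STEP_FILES["step1_consensus"])
    _write_gene_list(report.human_specific_set, out / STEP_FILES["step2_human_specific"])
    _write_gene_list(report.ortholog_set, out / STEP_FILES["step3_orthologs"])
    _write_gene_list(report.candidate_set, out / STEP_FILES["step45_candidates"])
    summary = pd.DataFrame(
        sorted(report.cardinalities.items()), columns=["step", "n_genes"]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    meta = {
        "config": dataclasses.asdict(report.config),
        "provenance": report.provenance,
    }
    (out / "screen_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")


def _write_gene_list(genes, path: Path) -> None:
    pd.DataFrame({"gene_id": sorted(genes)}).to_csv(path, sep="\t", index=False)


def _read_gene_list(path: Path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return set()
    return set(df["gene_id"].astype(str))


def read_screen_report_sets(out_dir: str | Path) -> dict[str, set[str]]:
    """Re-read the gene sets written by :func:`write_screen_report`."""
    out = Path(out_dir)
    sets = {name: _read_gene_list(out / fname) for name, fname in STEP_FILES.items()}
    for f in sorted(out.glob("step1_svz_enriched_*.tsv")):
        species = f.stem.replace("step1_svz_enriched_", "")
        sets[f"step1_{species}"] = _read_gene_list(f)
    return sets


def write_de_results(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
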