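import numpy as np
import pandas as pd
import pytest

from svzscreen import CountMatrix, SimulationSpec, simulate_laminar_counts


def make_count_matrix(counts: dict, species: str, layers: list[str], n_rep: int) -> CountMatrix:
    """Build a CountMatrix from a {gene: per-sample counts} dict.

    Samples are ordered layer-major: layers[0] replicates first.
    """
    sample_ids, rows = [], []
    for layer in layers:
        for rep in range(1, n_rep + 1):
            sid = f"{species}_{layer}_r{rep}"
            sample_ids.append(sid)
            rows.append((sid, species, layer, rep))
    df = pd.DataFrame(counts, index=sample_ids).T
    df.index.name = "gene_id"
    meta = pd.DataFrame(rows, columns=["sample_id", "species", "layer", "replicate"])
    return CountMatrix(counts=df, samples=meta)


def circle_points(n: int = 720, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def folded_circle_points(n: int = 4000, amp: float = 0.1, lobes: int = 8) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = 1.0 + amp * np.sin(lobes * theta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_laminar_counts(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A fast, smaller dataset for structural tests."""
    return simulate_laminar_counts(
        SimulationSpec(seed=7, n_genes=300, n_conserved_svz_genes=10)
    )
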