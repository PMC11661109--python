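import numpy as np
import pandas as pd
import pytest

from svzscreen import (
    ScreenConfig,
    SimulationSpec,
    consensus_svz,
    fpkm_gate,
    human_specific_genes,
    orthology_filter,
    run_screen,
    simulate_laminar_counts,
    svz_enriched_genes,
)

from conftest import make_count_matrix


def identity_orthologs(genes, species_list, reference="human"):
    rows = [
        (g, sp, g, True)
        for g in genes
        for sp in species_list
        if sp != reference
    ]
    return pd.DataFrame(
        rows, columns=["reference_gene_id", "species", "target_gene_id", "one_to_one"]
    )


class TestConsensus:
    def test_simple_intersection(self):
        sets = {"human": {"A", "B", "C"}, "mouse": {"B", "C"}, "macaque": {"C"}}
        orth = identity_orthologs({"A", "B", "C"}, sets)
        assert consensus_svz(sets, orth) == {"C"}

    def test_empty_set_gives_empty_consensus(self):
        sets = {"human": {"A"}, "mouse": set()}
        orth = identity_orthologs({"A"}, sets)
        assert consensus_svz(sets, orth) == set()

    def test_matches_bruteforce_membership_scan(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(200)]
        sets = {
            sp: set(rng.choice(genes, size=rng.integers(10, 150), replace=False))
            for sp in ("human", "macaque", "mouse")
        }
        orth = identity_orthologs(genes, sets)
        expected = {g for g in genes if all(g in s for s in sets.values())}
        assert consensus_svz(sets, orth) == expected

    def test_species_missing_from_orthologs_rejected(self):
        sets = {"human": {"A"}, "platypus": {"A"}}
        orth = identity_orthologs({"A"}, {"human": set(), "mouse": set()})
        with pytest.raises(ValueError, match="platypus"):
            consensus_svz(sets, orth)


class TestHumanSpecific:
    def test_difference_semantics(self):
        orth = identity_orthologs({"A", "B", "C"}, ["human", "mouse"])
        out = human_specific_genes({"A", "B", "C"}, {"mouse": {"B"}}, orth)
        assert out == {"A", "C"}

    def test_gene_without_ortholog_survives_step2_then_dropped(self):
        # "NEW" has no ortholog rows at all
        orth = identity_orthologs({"A"}, ["human", "mouse"])
        step2 = human_specific_genes({"A", "NEW"}, {"mouse": {"A"}}, orth)
        assert step2 == {"NEW"}
        step3 = orthology_filter(step2, orth, ["human", "mouse"])
        assert step3 == set()

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(150)]
        human = set(rng.choice(genes, 80, replace=False))
        others = {
            "mouse": set(rng.choice(genes, 40, replace=False)),
            "macaque": set(rng.choice(genes, 40, replace=False)),
        }
        orth = identity_orthologs(genes, ["human", "mouse", "macaque"])
        expected = {g for g in human if g not in others["mouse"] and g not in others["macaque"]}
        assert human_specific_genes(human, others, orth) == expected


class TestOrthologyFilter:
    def test_one_to_one_everywhere_kept_else_dropped(self):
        orth = pd.DataFrame(
            [
                ("A", "mouse", "mA", True),
                ("A", "macaque", "qA", True),
                ("B", "mouse", "mB", False),
                ("B", "macaque", "qB", True),
            ],
            columns=["reference_gene_id", "species", "target_gene_id", "one_to_one"],
        )
        out = orthology_filter({"A", "B"}, orth, ["human", "mouse", "macaque"])
        assert out == {"A"}

    def test_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(100)]
        species = ["mouse", "macaque", "tree_shrew"]
        rows = [
            (g, sp, f"{sp}_{g}", bool(rng.random() > 0.2))
            for g in genes
            for sp in species
        ]
        orth = pd.DataFrame(
            rows, columns=["reference_gene_id", "species", "target_gene_id", "one_to_one"]
        )
        expected = {
            g
            for g in genes
            if all(
                any(r[0] == g and r[1] == sp and r[3] for r in rows) for sp in species
            )
        }
        assert orthology_filter(set(genes), orth, ["human"] + species) == expected


def _gate_fixture(human_svz_fpkm, other_fpkm):
    """One gene, two species, direct FPKM tables for the gate."""
    fpkm_h = pd.DataFrame(
        {"h_CP_r1": [1.0], "h_SVZ_r1": [human_svz_fpkm], "h_SVZ_r2": [human_svz_fpkm]},
        index=["A"],
    )
    fpkm_m = pd.DataFrame(
        {"m_CP_r1": [other_fpkm], "m_SVZ_r1": [other_fpkm]}, index=["mA"]
    )
    samples_h = pd.DataFrame(
        {
            "sample_id": ["h_CP_r1", "h_SVZ_r1", "h_SVZ_r2"],
            "species": ["human"] * 3,
            "layer": ["CP", "SVZ", "SVZ"],
            "replicate": [1, 1, 2],
        }
    ).set_index("sample_id", drop=False)
    samples_m = pd.DataFrame(
        {
            "sample_id": ["m_CP_r1", "m_SVZ_r1"],
            "species": ["mouse"] * 2,
            "layer": ["CP", "SVZ"],
            "replicate": [1, 1],
        }
    ).set_index("sample_id", drop=False)
    orth = pd.DataFrame(
        [("A", "mouse", "mA", True)],
        columns=["reference_gene_id", "species", "target_gene_id", "one_to_one"],
    )
    return (
        {"human": fpkm_h, "mouse": fpkm_m},
        {"human": samples_h, "mouse": samples_m},
        orth,
    )


class TestFpkmGate:
    def test_clear_pass(self):
        fpkm, samples, orth = _gate_fixture(60.0, 1.0)
        assert fpkm_gate({"A"}, fpkm, samples, orth, ScreenConfig()) == {"A"}

    def test_human_boundary_is_strict(self):
        fpkm, samples, orth = _gate_fixture(50.0, 1.0)
        assert fpkm_gate({"A"}, fpkm, samples, orth, ScreenConfig()) == set()

    def test_other_species_boundary_is_strict(self):
        fpkm, samples, orth = _gate_fixture(60.0, 1.5)
        assert fpkm_gate({"A"}, fpkm, samples, orth, ScreenConfig()) == set()

    def test_missing_target_after_mapping_is_error(self):
        fpkm, samples, orth = _gate_fixture(60.0, 1.0)
        orth_bad = orth.assign(target_gene_id=["missing"])
        with pytest.raises(ValueError, match="A"):
            fpkm_gate({"A"}, fpkm, samples, orth_bad, ScreenConfig())


class TestSvzEnriched:
    def _species_cm(self, program, seed=0, n_rep=5, mu0=400.0):
        """Counts for one species with CP/OSVZ/ISVZ; program maps gene ->
        per-layer fold change."""
        rng = np.random.default_rng(seed)
        layers = ["CP", "OSVZ", "ISVZ"]
        genes = {}
        for g, fold in program.items():
            vals = []
            for layer in layers:
                mu = mu0 * fold.get(layer, 1.0)
                size = 1 / 0.02
                vals.extend(rng.negative_binomial(size, size / (size + mu), n_rep))
            genes[g] = vals
        return make_count_matrix(genes, "human", layers, n_rep)

    def test_conjunction_over_split_svz_layers(self):
        program = {f"bg{i}": {} for i in range(60)}
        program["both"] = {"OSVZ": 8.0, "ISVZ": 8.0}
        program["isvz_only"] = {"ISVZ": 8.0}
        cm = self._species_cm(program)
        hits = svz_enriched_genes(cm, ScreenConfig())
        assert "both" in hits
        assert "isvz_only" not in hits

    def test_flat_gene_excluded_and_missing_cp_rejected(self):
        program = {f"bg{i}": {} for i in range(20)}
        cm = self._species_cm(program)
        assert svz_enriched_genes(cm, ScreenConfig()) == set()
        no_cp = cm.subset_samples(
            [s for s in cm.samples.index if cm.samples.loc[s, "layer"] != "CP"]
        )
        with pytest.raises(ValueError, match="CP"):
            svz_enriched_genes(no_cp, ScreenConfig())


class TestRunScreen:
    def test_planted_recovery_single_run(self, default_sim):
        report = run_screen(
            default_sim.counts_by_species,
            default_sim.gene_lengths,
            default_sim.orthologs,
        )
        hs = set(default_sim.truth.human_specific_gene_ids)
        assert hs <= report.candidate_set
        assert len(report.candidate_set - hs) == 0

    def test_planted_conserved_gene_in_consensus_at_low_dispersion(self):
        data = simulate_laminar_counts(
            SimulationSpec(seed=5, n_genes=400, dispersion=0.02, n_conserved_svz_genes=10)
        )
        report = run_screen(data.counts_by_species, data.gene_lengths, data.orthologs)
        cons = set(data.truth.conserved_svz_gene_ids)
        assert len(report.consensus_set & cons) >= 8
        assert not (set(data.truth.human_specific_gene_ids) & report.consensus_set)

    def test_no_planted_gene_gives_empty_candidates(self):
        data = simulate_laminar_counts(
            SimulationSpec(seed=6, n_genes=300, n_human_specific_genes=0, n_conserved_svz_genes=5)
        )
        report = run_screen(data.counts_by_species, data.gene_lengths, data.orthologs)
        assert report.candidate_set == set()

    def test_nesting_and_determinism(self, small_sim):
        r1 = run_screen(small_sim.counts_by_species, small_sim.gene_lengths, small_sim.orthologs)
        r2 = run_screen(small_sim.counts_by_species, small_sim.gene_lengths, small_sim.orthologs)
        assert r1.candidate_set <= r1.ortholog_set <= r1.human_specific_set
        assert r1.candidate_set == r2.candidate_set
        assert r1.cardinalities == r2.cardinalities

    def test_gate_monotonicity(self, default_sim):
        base = ScreenConfig()
        relaxed = ScreenConfig(human_fpkm_min=25.0, other_fpkm_max=3.0)
        r_base = run_screen(
            default_sim.counts_by_species, default_sim.gene_lengths,
            default_sim.orthologs, base,
        )
        r_relaxed = run_screen(
            default_sim.counts_by_species, default_sim.gene_lengths,
            default_sim.orthologs, relaxed,
        )
        assert r_base.candidate_set <= r_relaxed.candidate_set
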