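"""Ground-truth behaviour of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from extremesoil.design import build_design, records_to_frame
from extremesoil.simulate import (
    MEASUREMENT_FAMILIES,
    PROPERTY_GROUPS,
    CommunitySimParams,
    FunctionalShift,
    GenomeModel,
    StrategySpec,
    generate_dataset,
    make_hierarchy,
    make_loading_matrix,
    property_names,
    simulate_asv_counts,
    simulate_covariates,
    simulate_functional_profiles,
    simulate_marker_reads,
    simulate_soil_functions,
    simulate_tree_and_effects,
)


class TestTreeAndEffects:
    def test_fixed_seed_reproduces_newick_and_effects(self):
        t1, e1 = simulate_tree_and_effects(12, 0.8, seed=5)
        t2, e2 = simulate_tree_and_effects(12, 0.8, seed=5)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert (e1.to_numpy() == e2.to_numpy()).all()

    def test_lambda_bounds_validated(self):
        with pytest.raises(ValueError):
            simulate_tree_and_effects(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            simulate_tree_and_effects(2, 0.5, seed=0)

    def test_zero_lambda_effects_uncorrelated_with_tree(self):
        """At lambda=0 the tip covariance is diagonal, so effect correlation
        between closely and distantly related tips is the same (near zero)."""
        from extremesoil.phylo import tree_vcv

        reps = []
        for s in range(40):
            tree, eff = simulate_tree_and_effects(30, 0.0, seed=200 + s)
            tips, c = tree_vcv(tree)
            c = c / np.max(np.diagonal(c))
            iu = np.triu_indices(30, 1)
            shared = c[iu]
            v = eff["effect_1"].loc[tips].to_numpy()
            prod = (v[:, None] * v[None, :])[iu]
            reps.append(np.corrcoef(shared, prod)[0, 1])
        assert abs(np.mean(reps)) < 0.05


class TestAsvCounts:
    def _meta(self, nc=3):
        return records_to_frame(build_design(nc).records("amplicon"))

    def test_row_sums_equal_drawn_library_sizes(self):
        meta = self._meta()
        params = CommunitySimParams(n_taxa=30, rng_seed=4)
        table, truth = simulate_asv_counts(meta, [], params)
        libs = pd.Series(truth["library_sizes"])
        assert (table.sum(axis=1) == libs.loc[table.index]).all()
        assert (table.to_numpy() >= 0).all()
        assert np.issubdtype(table.to_numpy().dtype, np.integer)

    def test_planted_impact_displacement_recovered_in_expectation(self):
        """Monte-Carlo mean S1 displacement of relative abundance matches the
        planted impact (compensated planting keeps it undiluted)."""
        meta = self._meta(2)
        m = meta.set_index("sample_id")
        heat = m[(m["treatment"] == "heat") & (m["sampling"] == "S1")].index
        ctrl = m[(m["treatment"] == "control") & (m["sampling"] == "S1")].index
        strategies = [StrategySpec("t0003", "heat", 0.05, 0.0)]
        disp = []
        for s in range(200):
            params = CommunitySimParams(n_taxa=20, rng_seed=1000 + s)
            table, _ = simulate_asv_counts(meta, strategies, params)
            ra = table.div(table.sum(axis=1), axis=0)
            disp.append(ra.loc[heat, "t0003"].mean() - ra.loc[ctrl, "t0003"].mean())
        assert np.mean(disp) == pytest.approx(0.05, abs=0.004)

    def test_slope_moves_displacement_with_day(self):
        meta = self._meta(2)
        m = meta.set_index("sample_id")
        strategies = [StrategySpec("t0001", "flood", 0.06, -0.06 / 26)]
        params = CommunitySimParams(n_taxa=20, overdispersion=0.0, rng_seed=9)
        table, _ = simulate_asv_counts(meta, strategies, params)
        ra = table.div(table.sum(axis=1), axis=0)

        def disp(sampling):
            f = m[(m["treatment"] == "flood") & (m["sampling"] == sampling)].index
            c = m[(m["treatment"] == "control") & (m["sampling"] == sampling)].index
            return ra.loc[f, "t0001"].mean() - ra.loc[c, "t0001"].mean()

        assert disp("S1") > disp("S4")
        assert disp("S4") == pytest.approx(0.0, abs=0.02)

    def test_invalid_inputs_rejected(self):
        meta = self._meta(2)
        with pytest.raises(ValueError):
            CommunitySimParams(n_taxa=10, library_size_median=0)
        with pytest.raises(ValueError):
            CommunitySimParams(n_taxa=10, phylo_signal_lambda=2.0)
        with pytest.raises(ValueError, match="unknown taxon"):
            simulate_asv_counts(
                meta, [StrategySpec("nope", "heat", 0.1)], CommunitySimParams(n_taxa=5)
            )

    def test_truth_ledger_covers_every_planted_quantity(self):
        meta = self._meta(2)
        strategies = [
            StrategySpec("t0001", "heat", 0.02, -0.001),
            StrategySpec("t0002", "drought", -0.01, 0.0),
        ]
        _, truth = simulate_asv_counts(meta, strategies, CommunitySimParams(n_taxa=10))
        planted = {(s["taxon_id"], s["treatment"]) for s in truth["strategies"]}
        assert planted == {("t0001", "heat"), ("t0002", "drought")}


class TestFunctionalProfiles:
    def _meta(self):
        meta = records_to_frame(build_design(2).records("metagenome"))
        return meta[meta["sampling"].isin(["S1", "S4"]) | meta["sampling"].isna()]

    def test_hierarchy_structure(self):
        h = make_hierarchy()
        assert set(h.columns) == {"protein", "level1", "level2", "level3"}
        assert h["protein"].is_unique
        # every protein has exactly one ancestor path
        assert (h.groupby("protein")[["level1", "level2", "level3"]].nunique() == 1).all().all()

    def test_planted_shift_moves_category_proportion(self):
        meta = self._meta()
        h = make_hierarchy()
        shifts = [FunctionalShift("L1_01", "level1", "heat", +0.06)]
        table, _ = simulate_functional_profiles(meta, h, shifts, seed=2)
        prots = h[h["level1"] == "L1_01"]["protein"]
        prop = table[prots].sum(axis=1) / table.sum(axis=1)
        m = meta.set_index("sample_id")
        heat = m[(m["treatment"] == "heat") & (m["sampling"] == "S1")].index
        ctrl = m[(m["treatment"] == "control") & (m["sampling"] == "S1")].index
        assert prop.loc[heat].mean() - prop.loc[ctrl].mean() == pytest.approx(0.06, abs=0.02)

    def test_resilient_shift_decays_by_s4(self):
        meta = self._meta()
        h = make_hierarchy()
        shifts = [FunctionalShift("L1_02", "level1", "flood", +0.08, resilient=True)]
        table, _ = simulate_functional_profiles(meta, h, shifts, seed=3, overdispersion=0.0)
        prots = h[h["level1"] == "L1_02"]["protein"]
        prop = table[prots].sum(axis=1) / table.sum(axis=1)
        m = meta.set_index("sample_id")

        def disp(sampling):
            f = m[(m["treatment"] == "flood") & (m["sampling"] == sampling)].index
            c = m[(m["treatment"] == "control") & (m["sampling"] == sampling)].index
            return prop.loc[f].mean() - prop.loc[c].mean()

        assert disp("S1") > 0.05
        assert abs(disp("S4")) < 0.02

    def test_negative_overshoot_clipped_with_warning(self):
        meta = self._meta()
        h = make_hierarchy()
        shifts = [FunctionalShift("L1_01", "level1", "heat", -0.99)]
        with pytest.warns(UserWarning, match="clips"):
            table, _ = simulate_functional_profiles(meta, h, shifts, seed=4)
        assert (table.to_numpy() >= 0).all()


class TestCovariatesAndSoilFunctions:
    def test_twenty_properties_in_stated_groups(self):
        names = property_names()
        assert len(names) == 20
        assert PROPERTY_GROUPS == {
            "temperature": 4, "precipitation": 4, "carbon_nitrogen": 8,
            "water_holding": 3, "ph": 1,
        }

    def test_noiseless_surface_is_deterministic_function_of_covariates(self):
        meta = records_to_frame(build_design(3).records("amplicon")).dropna(
            subset=["treatment"]
        )
        cov, truth = simulate_covariates(meta, noise_sd=0.0, seed=8)
        assert cov.shape == (9, 20)
        assert np.allclose(truth["response"], truth["true_response"])

    def test_soil_function_family_sizes(self):
        assert MEASUREMENT_FAMILIES == {
            "enzyme": 4, "substrate_use": 8, "carbon_nitrogen": 4, "gas_flux": 3,
        }
        table = pd.DataFrame(
            np.random.default_rng(0).integers(1, 50, (6, 5)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"p{j}" for j in range(5)],
        )
        loading = make_loading_matrix(list(table.columns), seed=1)
        meas = simulate_soil_functions(table, loading, noise_sd=0.0, seed=2)
        assert meas.shape == (6, 19)

    def test_loading_dimension_mismatch_errors(self):
        table = pd.DataFrame([[1, 2]], columns=["a", "b"], index=["s"])
        bad = make_loading_matrix(["a", "c"], seed=0)
        with pytest.raises(ValueError):
            simulate_soil_functions(table, bad)


class TestMarkerReads:
    def test_flat_coverage_at_rho_zero(self):
        g = GenomeModel(rho=0.0, seed=1)
        w = g.coverage_weights()
        assert np.allclose(w, 1.0)

    def test_coverage_law_origin_twice_terminus_at_rho_one(self):
        g = GenomeModel(rho=1.0, seed=1)
        w = g.coverage_weights()
        assert w[g.origin_position] == pytest.approx(2.0)
        assert w[g.terminus_position] == pytest.approx(1.0)
        reads = simulate_marker_reads(g, n_reads=30_000, read_length=50, seed=3)
        # empirical origin:terminus start-density ratio from planted regions
        origin_region = set(range(19_800, 20_000)) | set(range(0, 200))
        term_region = set(range(9_800, 10_200))
        # recover start positions by exact prefix matching against the genome
        doubled = g.sequence + g.sequence
        starts = {}
        for rid, seq in reads[:4000]:
            pos = doubled.find(seq)
            if pos >= 0:
                starts[rid] = pos % g.length
        n_or = sum(1 for p in starts.values() if p in origin_region)
        n_te = sum(1 for p in starts.values() if p in term_region)
        assert n_or / max(n_te, 1) == pytest.approx(2.0, rel=0.35)

    def test_fixed_seed_reproduces_reads(self):
        g = GenomeModel(rho=0.5, seed=2)
        r1 = simulate_marker_reads(g, n_reads=50, seed=9)
        r2 = simulate_marker_reads(g, n_reads=50, seed=9)
        assert r1 == r2

    def test_wraparound_reads_have_full_length(self):
        g = GenomeModel(length=2000, rho=0.0, seed=3)
        reads = simulate_marker_reads(g, n_reads=500, read_length=150, seed=1)
        assert all(len(seq) == 150 for _, seq in reads)

    def test_invalid_parameters_rejected(self):
        g = GenomeModel(rho=0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_marker_reads(g, n_reads=0)
        with pytest.raises(ValueError):
            simulate_marker_reads(g, n_reads=10, read_length=30_000)
        with pytest.raises(ValueError):
            GenomeModel(rho=-0.5)


def test_generate_dataset_is_seed_deterministic(tmp_path):
    kwargs = dict(
        seed=3, n_countries=2, n_taxa=12, reads_per_sample=200, read_sample_limit=1
    )
    a = generate_dataset(**kwargs)
    b = generate_dataset(**kwargs)
    assert a.tree_newick == b.tree_newick
    assert (a.asv_table.to_numpy() == b.asv_table.to_numpy()).all()
    assert (a.functional_table.to_numpy() == b.functional_table.to_numpy()).all()
    assert a.reads.keys() == b.reads.keys()
    for k in a.reads:
        assert a.reads[k] == b.reads[k]
    a.write(tmp_path / "ds")
    assert (tmp_path / "ds" / "truth.json").exists()
    assert (tmp_path / "ds" / "tree.nwk").exists()
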