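"""Generators: determinism, planted truth, integrator accuracy, noise models."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from uripeg import sasa, siteselect, structio
from uripeg.synth import (
    ToyOligomerSpec,
    make_pbmc_counts,
    make_pk_profile,
    make_progress_curves,
    make_toy_oligomer,
)


class TestToyOligomer:
    def test_identical_seed_gives_byte_identical_pdb(self):
        spec = ToyOligomerSpec(rng_seed=123)
        s1, _ = make_toy_oligomer(spec)
        s2, _ = make_toy_oligomer(spec)
        assert structio.write_pdb(s1) == structio.write_pdb(s2)

    def test_different_seed_changes_geometry(self):
        s1, _ = make_toy_oligomer(ToyOligomerSpec(rng_seed=1))
        s2, _ = make_toy_oligomer(ToyOligomerSpec(rng_seed=2))
        assert structio.write_pdb(s1) != structio.write_pdb(s2)

    def test_planted_surface_and_buried_positions_resolve_correctly(self, toy_default):
        report = siteselect.run_site_selection(
            toy_default["structure"], toy_default["by_residue"], toy_default["ligand_points"]
        )
        assert report.passing_positions == toy_default["truth"]["must_pass"]

    def test_single_subunit_degenerates_to_per_chain_rule(self):
        spec = ToyOligomerSpec(n_subunits=1, rng_seed=5)
        structure, truth = make_toy_oligomer(spec)
        assert list(structure.protein_chains) == ["A"]
        result = sasa.compute_structure_sasa(structure)
        by_res = sasa.residue_sasa(result, structure)
        points = structio.select_ligand_atoms(structure, "LIG", "C5")
        cands, _ = siteselect.candidate_metrics(structure, by_res, points)
        passing = siteselect.filter_candidates(cands)
        assert passing == truth["must_pass"]

    def test_geometric_infeasibility_raises(self):
        spec = ToyOligomerSpec(
            n_positions=40,
            planted_surface_positions=tuple(range(1, 39)),
            planted_buried_positions=(39, 40),
            radius=15.0,
            rng_seed=0,
        )
        with pytest.raises(ValueError, match="infeasib"):
            make_toy_oligomer(spec)

    def test_planted_sets_must_partition_positions(self):
        with pytest.raises(ValueError, match="partition|disjoint"):
            ToyOligomerSpec(n_positions=4, planted_surface_positions=(1, 2),
                            planted_buried_positions=(2, 3))


class TestProgressCurveGenerator:
    def test_first_order_limit_is_log_linear(self):
        # s0 << km: dS/dt ≈ -(kcat e0 / km) S, so ln S declines linearly
        kcat, km, e0 = 2.0, 500.0, 0.1
        (curve,) = make_progress_curves(kcat, km, e0, [1.0])
        s = curve.a292 * 1e6 / 12300.0
        slope = np.polyfit(curve.times, np.log(s), 1)[0]
        assert slope == pytest.approx(-kcat * e0 / km, rel=0.01)

    def test_rk4_matches_adaptive_reference_integrator(self):
        kcat, km, e0, s0 = 6.08, 109.7, 0.05, 400.0
        (curve,) = make_progress_curves(kcat, km, e0, [s0])
        ref = solve_ivp(
            lambda t, s: -kcat * e0 * s / (km + s),
            (0, 600),
            [s0],
            t_eval=curve.times,
            rtol=1e-10,
            atol=1e-12,
        )
        s = curve.a292 * 1e6 / 12300.0
        assert np.allclose(s, ref.y[0], rtol=1e-6)

    def test_noise_is_seeded_and_reproducible(self):
        a = make_progress_curves(6.0, 100.0, 0.01, [400.0], noise_sd=0.01, seed=4)[0]
        b = make_progress_curves(6.0, 100.0, 0.01, [400.0], noise_sd=0.01, seed=4)[0]
        c = make_progress_curves(6.0, 100.0, 0.01, [400.0], noise_sd=0.01, seed=5)[0]
        assert np.array_equal(a.a292, b.a292)
        assert not np.array_equal(a.a292, c.a292)

    def test_sampling_grid_matches_assay_protocol(self):
        (curve,) = make_progress_curves(6.0, 100.0, 0.01, [400.0])
        assert curve.times[0] == 0.0 and curve.times[-1] == 600.0
        assert np.all(np.diff(curve.times) == 20.0)
        assert curve.times.size == 31


class TestPKGenerator:
    def test_iv_profile_exact_halving(self):
        profile = make_pk_profile(10.0, "IV", np.array([0.0, 10.0, 20.0]), dose=5.0, c0=80.0)
        assert profile.conc == pytest.approx([80.0, 40.0, 20.0])

    def test_concentration_vanishes_at_long_times(self):
        profile = make_pk_profile(5.0, "IV", np.array([1.0, 500.0]), dose=5.0, c0=80.0)
        assert profile.conc[-1] < 1e-20

    def test_sc_peak_matches_requested_cmax(self):
        ke = np.log(2) / 40.0
        ka = 1.0
        tmax = np.log(ka / ke) / (ka - ke)
        profile = make_pk_profile(40.0, "SC", np.array([0.5, tmax, 50.0]), dose=3.0, cmax=25.0, ka=ka)
        assert profile.conc[1] == pytest.approx(25.0, rel=1e-9)

    def test_lognormal_noise_reproducible(self):
        t = np.arange(1.0, 100.0, 10.0)
        a = make_pk_profile(20.0, "IV", t, dose=5.0, c0=100.0, noise_cv=0.1, seed=7)
        b = make_pk_profile(20.0, "IV", t, dose=5.0, c0=100.0, noise_cv=0.1, seed=7)
        assert np.array_equal(a.conc, b.conc)


class TestPBMCGenerator:
    def test_negative_binomial_dispersion(self):
        pairs = make_pbmc_counts(100.0, 1.0, n_replicates=8, dispersion=0.1, n_donors=500, seed=1)
        counts = np.concatenate([r.counts for _, r in pairs])
        m, v = counts.mean(), counts.var()
        # Var = m + dispersion m^2 = 100 + 1000 = 1100
        assert m == pytest.approx(100.0, rel=0.05)
        assert v == pytest.approx(1100.0, rel=0.15)

    def test_dispersion_zero_limit_is_poisson(self):
        pairs = make_pbmc_counts(100.0, 1.0, dispersion=0.0, n_donors=500, seed=2)
        counts = np.concatenate([r.counts for _, r in pairs])
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.1)

    def test_seeded_and_reproducible(self):
        a = make_pbmc_counts(50.0, 2.0, n_donors=3, seed=9)
        b = make_pbmc_counts(50.0, 2.0, n_donors=3, seed=9)
        for (t1, r1), (t2, r2) in zip(a, b):
            assert np.array_equal(t1.counts, t2.counts)
            assert np.array_equal(r1.counts, r2.counts)

    def test_treated_mean_scales_with_true_si(self):
        pairs = make_pbmc_counts(100.0, 4.2, n_donors=300, seed=11)
        treated = np.concatenate([t.counts for t, _ in pairs])
        assert treated.mean() == pytest.approx(420.0, rel=0.05)
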