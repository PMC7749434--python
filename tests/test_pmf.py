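"""WHAM reconstruction: closed-form checks, invariances, parameter recovery."""

import numpy as np
import pytest
from dataclasses import replace

from kvgate.errors import ReconstructionError
from kvgate.pmf import (
    PmfProfile,
    UmbrellaWindow,
    WhamConfig,
    anchor_pmf,
    barrier_height,
    convergence_blocks,
    convergence_metric,
    harmonic_bias,
    thermal_energy,
    unbiased_probability,
    wham_solve,
)
from kvgate.synthetic import (
    ReferencePmf,
    reference_pmf_flat,
    sample_umbrella_windows,
)


class TestClosedForms:
    @pytest.mark.parametrize("z,c,k,expected", [
        (2.0, 2.0, 10.0, 0.0),
        (3.0, 2.0, 10.0, 5.0),
        (2.5, 2.0, 10.0, 1.25),
    ])
    def test_harmonic_bias(self, z, c, k, expected):
        assert harmonic_bias(z, c, k) == pytest.approx(expected)

    def test_thermal_energy_at_300K(self):
        assert thermal_energy(300.0) == pytest.approx(0.59616, abs=1e-5)

    def test_thermal_energy_guards_zero_kelvin(self):
        with pytest.raises(ValueError):
            thermal_energy(0.0)

    def test_3_kcal_barrier_is_about_5_kT(self):
        assert round(3.0 / thermal_energy(300.0)) == 5


def _quadratic_ref(a=0.5, z_range=(-3.5, 3.5)):
    grid = np.arange(z_range[0], z_range[1] + 0.005, 0.01)
    return ReferencePmf(grid=grid, U=a * grid ** 2, description="quadratic")


class TestWhamSolve:
    def test_quadratic_free_energy_recovered(self):
        a = 0.5
        ref = _quadratic_ref(a)
        wins = sample_umbrella_windows(ref, np.arange(-3.0, 3.1, 0.5),
                                       n_per_window=4000, seed=21)
        cfg = WhamConfig.for_windows(wins, bin_width=0.1)
        prof = wham_solve(wins, cfg)
        assert prof.converged
        mask = prof.defined & (prof.counts >= 200)
        truth = a * prof.bin_centers[mask] ** 2
        resid = prof.G[mask] - truth
        resid -= resid.mean()
        assert np.sqrt(np.mean(resid ** 2)) < 0.1

    def test_gauge_invariance_under_constant_bias_shift(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.5, -3.0], n_per_window=2000, seed=4)
        cfg = WhamConfig.for_windows(wins)
        base = wham_solve(wins, cfg)
        shifted = [replace(w, bias_offset=7.3) for w in wins]
        other = wham_solve(shifted, cfg)
        np.testing.assert_allclose(other.G[other.defined], base.G[base.defined],
                                   atol=1e-8)

    def test_invariant_under_window_reordering(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.5, -3.0], n_per_window=2000, seed=5)
        cfg = WhamConfig.for_windows(wins)
        fwd = wham_solve(wins, cfg)
        rev = wham_solve(wins[::-1], cfg)
        np.testing.assert_allclose(rev.G[rev.defined], fwd.G[fwd.defined], atol=1e-8)

    def test_invariant_under_joint_translation(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.5, -3.0], n_per_window=2000, seed=6)
        cfg = WhamConfig.for_windows(wins)
        base = wham_solve(wins, cfg)
        dz = 11.0
        moved = [replace(w, center=w.center + dz, samples=w.samples + dz) for w in wins]
        cfg2 = WhamConfig(bin_edges=cfg.bin_edges + dz, temperature=cfg.temperature,
                          tolerance=cfg.tolerance, max_iterations=cfg.max_iterations)
        other = wham_solve(moved, cfg2)
        np.testing.assert_allclose(other.G[other.defined], base.G[base.defined],
                                   atol=1e-8)

    def test_probability_normalized_over_defined_bins(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.0], n_per_window=2000, seed=7)
        prof = wham_solve(wins, WhamConfig.for_windows(wins))
        p = unbiased_probability(prof)
        assert np.nansum(p) == pytest.approx(1.0, abs=1e-10)

    def test_disjoint_windows_raise_reconstruction_error(self):
        w1 = UmbrellaWindow(center=-10.0, force_constant=10.0,
                            samples=-10.0 + 0.05 * np.random.default_rng(0).standard_normal(200))
        w2 = UmbrellaWindow(center=0.0, force_constant=10.0,
                            samples=0.0 + 0.05 * np.random.default_rng(1).standard_normal(200))
        cfg = WhamConfig(bin_edges=np.arange(-11.0, 1.05, 0.1))
        with pytest.raises(ReconstructionError):
            with pytest.warns(UserWarning):
                wham_solve([w1, w2], cfg)

    def test_nonconvergence_reported_not_raised(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.5, -3.0], n_per_window=500, seed=8)
        cfg = WhamConfig.for_windows(wins, max_iterations=2)
        prof = wham_solve(wins, cfg)
        assert not prof.converged
        assert prof.iterations_used == 2


def _profile(z, G, kT=0.59616):
    G = np.asarray(G, dtype=float)
    return PmfProfile(bin_centers=np.asarray(z, float), G=G, kT=kT, anchor="min",
                      iterations_used=1, converged=True,
                      counts=np.where(np.isfinite(G), 100.0, 0.0))


class TestAnchorAndBarrier:
    def test_anchoring_is_idempotent(self):
        z = np.arange(-12.0, 0.0, 0.5)
        prof = _profile(z, np.linspace(0.0, 3.0, z.size))
        once = anchor_pmf(prof, (-12.0, -9.0))
        twice = anchor_pmf(once, (-12.0, -9.0))
        np.testing.assert_allclose(twice.G, once.G, atol=1e-14)
        ref_mask = (z >= -12.0) & (z <= -9.0)
        assert np.mean(once.G[ref_mask]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_anchors_to_zero(self):
        z = np.arange(-12.0, 0.0, 0.5)
        prof = anchor_pmf(_profile(z, np.full(z.size, 2.5)), (-12.0, -9.0))
        np.testing.assert_allclose(prof.G, 0.0, atol=1e-14)

    def test_empty_reference_interval_rejected(self):
        prof = _profile(np.arange(-5.0, 0.0, 0.5), np.zeros(10))
        with pytest.raises(ReconstructionError):
            anchor_pmf(prof, (-20.0, -15.0))

    def test_constructed_gaussian_bump_measured_exactly(self):
        z = np.arange(-14.0, 0.0, 0.1)
        G = 3.0 * np.exp(-((z + 8.0) ** 2) / (2 * 1.5 ** 2))
        G[np.abs(z + 8.0) > 4.0] = 0.0  # flat baseline outside the bump
        dg, z_at = barrier_height(_profile(z, G), (-11.0, -5.0), (-14.0, -12.5))
        assert dg == pytest.approx(3.0, abs=0.01)
        assert z_at == pytest.approx(-8.0, abs=0.051)

    def test_flat_profile_zero_barrier_first_bin_tiebreak(self):
        z = np.arange(-10.0, 0.0, 0.5)
        dg, z_at = barrier_height(_profile(z, np.zeros(z.size)), (-8.0, -2.0),
                                  (-10.0, -9.0))
        assert dg == 0.0
        assert z_at == -8.0  # first bin in the barrier region

    def test_barrier_in_thermal_units(self):
        z = np.arange(-14.0, 0.0, 0.1)
        G = 3.0 * np.exp(-((z + 8.0) ** 2) / (2 * 1.5 ** 2))
        dg, _ = barrier_height(_profile(z, G), (-11.0, -5.0), (-14.0, -12.5))
        assert dg / thermal_energy(300.0) == pytest.approx(5.03, abs=0.05)


class TestConvergenceBlocks:
    def test_full_fraction_identical_to_direct_solve(self):
        ref = reference_pmf_flat((-5.0, -1.0))
        wins = sample_umbrella_windows(ref, [-4.0, -3.5, -3.0], n_per_window=1500, seed=9)
        cfg = WhamConfig.for_windows(wins)
        blocks = convergence_blocks(wins, cfg, [0.5, 1.0])
        full = wham_solve(wins, cfg)
        np.testing.assert_allclose(blocks[-1].G[blocks[-1].defined],
                                   full.G[full.defined], atol=1e-12)
        assert convergence_metric(full, blocks[0]) < 0.3  # stationary data

    def test_tiny_fraction_rejected(self):
        w = UmbrellaWindow(center=0.0, force_constant=10.0, samples=np.zeros(50) + 0.1)
        cfg = WhamConfig(bin_edges=np.arange(-1.0, 1.05, 0.1))
        with pytest.raises(ValueError):
            convergence_blocks([w], cfg, [0.01])

    def test_fractions_must_increase_within_unit_interval(self):
        w = UmbrellaWindow(center=0.0, force_constant=10.0,
                           samples=np.random.default_rng(0).normal(0, 0.2, 100))
        cfg = WhamConfig(bin_edges=np.arange(-1.0, 1.05, 0.1))
        with pytest.raises(ValueError):
            convergence_blocks([w], cfg, [0.5, 0.5])
        with pytest.raises(ValueError):
            convergence_blocks([w], cfg, [0.0, 1.0])


class TestStochasticConvergence:
    def test_more_samples_reduce_rmse_on_average(self):
        a = 0.5
        ref = _quadratic_ref(a, (-2.5, 2.5))
        centers = np.arange(-2.0, 2.1, 0.5)

        def rmse(n, seed):
            wins = sample_umbrella_windows(ref, centers, n_per_window=n, seed=seed)
            cfg = WhamConfig.for_windows(wins, bin_width=0.1)
            prof = wham_solve(wins, cfg)
            mask = prof.defined & (prof.counts >= 10)
            assert mask.sum() > 5
            resid = prof.G[mask] - a * prof.bin_centers[mask] ** 2
            resid -= resid.mean()
            return np.sqrt(np.mean(resid ** 2))

        seeds = range(10)
        small = np.mean([rmse(150, 1000 + s) for s in seeds])
        large = np.mean([rmse(1500, 2000 + s) for s in seeds])
        assert large < small
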