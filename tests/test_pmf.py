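"""Umbrella windows and WHAM: grids, equilibration cuts, recovery, block errors."""

import numpy as np
import pytest

from mdain.pmf import (KB_KCAL, PMFProfile, UmbrellaWindow, WhamConfig,
                       block_errors, check_overlap, discard_equilibration,
                       make_windows, read_metadata, wham_solve, write_metadata,
                       write_window)
from mdain.synthetic import (double_well_potential, harmonic_potential,
                             make_umbrella_samples)


class TestWindows:
    def test_reference_grid_has_107_windows(self):
        ws = make_windows(-1.5, 25.0, 0.25, 10.0)
        assert len(ws) == 107
        assert ws[0].center == pytest.approx(-1.5)
        assert ws[-1].center == pytest.approx(25.0)

    def test_small_grid(self):
        ws = make_windows(0, 1, 0.5, 5.0)
        assert [w.center for w in ws] == [0.0, 0.5, 1.0]

    def test_incommensurate_spacing_rejected(self):
        with pytest.raises(ValueError, match="commensurate"):
            make_windows(0, 1, 0.3, 5.0)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, force_constant=-1.0, samples=np.zeros(3))


class TestDiscardEquilibration:
    def test_default_cut_leaves_1500_of_2000(self):
        w = UmbrellaWindow(0.0, 10.0, samples=np.arange(2000.0))
        out = discard_equilibration(w, cut=500.0, sample_interval=1.0)
        assert len(out.samples) == 1500
        assert out.samples[0] == 500.0

    def test_zero_cut_identity(self):
        w = UmbrellaWindow(0.0, 10.0, samples=np.arange(100.0))
        out = discard_equilibration(w, cut=0.0)
        np.testing.assert_array_equal(out.samples, w.samples)

    def test_cut_beyond_duration_rejected(self):
        w = UmbrellaWindow(0.0, 10.0, samples=np.arange(2000.0))
        with pytest.raises(ValueError):
            discard_equilibration(w, cut=2500.0, sample_interval=1.0)


class TestWhamRecovery:
    def test_flat_potential_single_unbiased_window(self):
        rng = np.random.default_rng(0)
        w = UmbrellaWindow(0.5, 0.0, samples=rng.uniform(0, 1, 10_000))
        prof = wham_solve([w], WhamConfig(bin_width=0.05))
        inner = (prof.grid > 0.05) & (prof.grid < 0.95)
        assert np.sqrt(np.mean(prof.free_energy[inner] ** 2)) < 0.1

    def test_unbiased_window_equals_log_histogram(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0, 0.5, 20_000)
        w = UmbrellaWindow(0.0, 0.0, samples=samples)
        config = WhamConfig(bin_width=0.1)
        prof = wham_solve([w], config)
        counts, edges = np.histogram(samples, bins=np.concatenate([
            [prof.grid[0] - 0.05], prof.grid + 0.05]))
        direct = -config.kt * np.log(np.where(counts > 0, counts, np.nan))
        fin = np.isfinite(direct) & np.isfinite(prof.free_energy)
        diff = prof.free_energy[fin] - direct[fin]
        assert np.std(diff) < 1e-10  # equal up to an additive constant

    def test_harmonic_recovery(self):
        ws = make_windows(-2, 2, 0.2, 10.0)
        sampled = make_umbrella_samples(harmonic_potential(2.0), ws, 310.0, 5000, seed=1)
        prof = wham_solve(sampled)
        sel = (prof.grid >= -1.5) & (prof.grid <= 1.5) & np.isfinite(prof.free_energy)
        resid = prof.free_energy[sel] - 2.0 * prof.grid[sel] ** 2
        resid -= resid.mean()
        assert np.sqrt(np.mean(resid ** 2)) < 0.15

    def test_double_well_barrier(self):
        dw = double_well_potential(3.0)
        sampled = make_umbrella_samples(dw, make_windows(-1.6, 1.6, 0.1, 10.0),
                                        310.0, 4000, seed=2)
        prof = wham_solve(sampled)
        fin = np.isfinite(prof.free_energy)
        g, f = prof.grid[fin], prof.free_energy[fin]
        barrier = f[np.abs(g) < 0.2].max() - f.min()
        assert barrier == pytest.approx(3.0, rel=0.10)

    def test_sampling_error_decreases_with_n(self):
        errs = []
        for n in (500, 5000, 50000):
            s = make_umbrella_samples(harmonic_potential(2.0),
                                      make_windows(-2, 2, 0.2, 10.0), 310.0, n, seed=3)
            prof = wham_solve(s)
            sel = (prof.grid >= -1.5) & (prof.grid <= 1.5) & np.isfinite(prof.free_energy)
            resid = prof.free_energy[sel] - 2.0 * prof.grid[sel] ** 2
            errs.append(float(np.sqrt(np.mean((resid - resid.mean()) ** 2))))
        assert errs[0] > errs[1] > errs[2]

    def test_window_order_invariance(self):
        ws = make_windows(-1, 1, 0.2, 10.0)
        sampled = make_umbrella_samples(harmonic_potential(1.0), ws, 310.0, 2000, seed=4)
        p1 = wham_solve(sampled)
        p2 = wham_solve(list(reversed(sampled)))
        np.testing.assert_allclose(p1.free_energy, p2.free_energy, atol=1e-6)

    def test_grid_shift_covariance(self):
        sampled = make_umbrella_samples(harmonic_potential(1.0),
                                        make_windows(-1, 1, 0.2, 10.0), 310.0, 2000, seed=5)
        shift = 10.0  # a multiple of the bin width, so binning is identical
        shifted = [UmbrellaWindow(w.center + shift, w.force_constant, w.samples + shift)
                   for w in sampled]
        p1, p2 = wham_solve(sampled), wham_solve(shifted)
        np.testing.assert_allclose(p2.grid, p1.grid + shift, atol=1e-9)
        np.testing.assert_allclose(p2.free_energy, p1.free_energy, atol=1e-8)

    def test_disconnected_windows_diagnosed(self):
        rng = np.random.default_rng(6)
        w1 = UmbrellaWindow(0.0, 10.0, rng.normal(0, 0.1, 500))
        w2 = UmbrellaWindow(10.0, 10.0, rng.normal(10, 0.1, 500))
        assert check_overlap([w1, w2]) == [0, 1]
        near = UmbrellaWindow(0.3, 10.0, rng.normal(0.3, 0.1, 500))
        assert check_overlap([w1, near]) == []


class TestBlockErrors:
    def test_identical_blocks_zero_error(self):
        rng = np.random.default_rng(7)
        block = rng.normal(0, 0.3, 500)
        w = UmbrellaWindow(0.0, 0.0, samples=np.tile(block, 3))
        prof = block_errors([w], WhamConfig(bin_width=0.1), n_blocks=3)
        assert np.nanmax(prof.errors) < 1e-10

    def test_error_scaling_with_sample_size(self):
        sizes = (500, 5000, 50000)
        mean_errs = []
        for n in sizes:
            vals = []
            for seed in range(5):
                s = make_umbrella_samples(harmonic_potential(2.0),
                                          make_windows(-2, 2, 0.2, 10.0), 310.0, n,
                                          seed=seed)
                prof = block_errors(s, WhamConfig(), n_blocks=3)
                sel = np.isfinite(prof.free_energy) & (np.abs(prof.grid) <= 1.5)
                vals.append(float(np.median(prof.errors[sel])))
            mean_errs.append(np.mean(vals))
        slope = np.polyfit(np.log(sizes), np.log(mean_errs), 1)[0]
        assert -0.6 <= slope <= -0.4

    def test_seven_blocks_supported(self):
        s = make_umbrella_samples(harmonic_potential(2.0),
                                  make_windows(-1, 1, 0.2, 10.0), 310.0, 700, seed=8)
        prof = block_errors(s, WhamConfig(), n_blocks=7)
        # errors are defined wherever every block sampled; check the interior
        interior = np.isfinite(prof.free_energy) & (np.abs(prof.grid) <= 0.8)
        assert np.all(np.isfinite(prof.errors[interior]))
        assert np.all(prof.errors[interior] >= 0)

    def test_bootstrap_variant(self):
        s = make_umbrella_samples(harmonic_potential(2.0),
                                  make_windows(-1, 1, 0.2, 10.0), 310.0, 900, seed=9)
        prof = block_errors(s, WhamConfig(), n_blocks=3, bootstrap=50, seed=0)
        assert np.nanmedian(prof.errors) > 0

    def test_too_few_samples_rejected(self):
        w = UmbrellaWindow(0.0, 10.0, samples=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            block_errors([w], WhamConfig(), n_blocks=3)


class TestSamplingOracle:
    def test_unbiased_window_sd_matches_gaussian(self):
        # with U = 0 the biased density is a Gaussian of variance kT/k
        ws = make_windows(-1, 1, 0.5, 10.0)
        sampled = make_umbrella_samples(harmonic_potential(0.0), ws, 310.0, 50_000, seed=10)
        expect = np.sqrt(KB_KCAL * 310.0 / 10.0)
        for w in sampled:
            assert np.std(w.samples) == pytest.approx(expect, rel=0.02)
            assert np.mean(w.samples) == pytest.approx(w.center, abs=4 * expect / np.sqrt(50_000))

    def test_quadratic_potential_moments(self):
        # complete the square: variance kT/(2(a + k/2)), mean k c / (2(a + k/2))
        a, k, c = 2.0, 10.0, 0.8
        w = make_windows(c, c + 1, 1.0, k)[:1]
        sampled = make_umbrella_samples(harmonic_potential(a), w, 310.0, 100_000, seed=11)
        kt = KB_KCAL * 310.0
        coeff = a + 0.5 * k
        assert np.mean(sampled[0].samples) == pytest.approx(0.5 * k * c / coeff, abs=0.01)
        assert np.var(sampled[0].samples) == pytest.approx(kt / (2 * coeff), rel=0.03)

    def test_determinism(self):
        ws = make_windows(-1, 1, 0.5, 10.0)
        s1 = make_umbrella_samples(harmonic_potential(2.0), ws, 310.0, 100, seed=12)
        s2 = make_umbrella_samples(harmonic_potential(2.0), ws, 310.0, 100, seed=12)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.samples, b.samples)


def test_metadata_round_trip(tmp_path):
    ws = make_umbrella_samples(harmonic_potential(1.0),
                               make_windows(-0.5, 0.5, 0.5, 10.0), 310.0, 50, seed=13)
    paths = []
    for i, w in enumerate(ws):
        p = tmp_path / f"w{i}.dat"
        write_window(w, p)
        paths.append(p.name)
    meta = tmp_path / "windows.meta"
    write_metadata(ws, paths, meta, temperature=300.0)
    back, temp = read_metadata(meta)
    assert temp == 300.0
    assert len(back) == len(ws)
    for a, b in zip(back, ws):
        assert a.center == b.center and a.force_constant == b.force_constant
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-6)
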