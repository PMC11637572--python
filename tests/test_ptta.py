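import numpy as np
import pytest

from abrgp import StimulusSpec
from abrgp.preprocess import EpochEnsemble, accumulate
from abrgp.ptta import (
    AMPLITUDE_GRID_UV,
    SIGMA2_FLOOR,
    coherent_average,
    debias_ptta,
    estimate_ptta,
    find_peak_trough,
    _HAVE_NUMBA,
    _biased_matrix,
)
from abrgp.simulate import FS_HZ, N_SAMPLES, wave_v_template

from conftest import make_noise_ensemble


def brute_force_ptta(avg, fs, search_ms, max_sep_ms):
    """Exhaustive O(n^2) scan over all constrained (peak, trough) pairs."""
    n = len(avg)
    best, arg = -np.inf, None
    for i in range(n):
        for j in range(i + 1, n):
            t_i, t_j = i / fs * 1000.0, j / fs * 1000.0
            if t_i < search_ms[0] - 1e-12 or t_j > search_ms[1] + 1e-12:
                continue
            if t_j - t_i > max_sep_ms + 1e-12:
                continue
            d = avg[i] - avg[j]
            if d > best:
                best, arg = d, (t_i, t_j)
    return max(best, 0.0), arg


class TestCoherentAverage:
    def test_identical_epochs_reproduce_epoch(self):
        epoch = np.linspace(0, 1, N_SAMPLES)
        ens = EpochEnsemble(StimulusSpec(70.0, 1000.0))
        accumulate(ens, np.tile(epoch, (6, 1)))
        avg = coherent_average(ens)
        np.testing.assert_allclose(avg.mean, epoch)
        np.testing.assert_allclose(avg.replicate_odd, epoch)
        np.testing.assert_allclose(avg.replicate_even, epoch)

    @pytest.mark.parametrize("n, n_odd, n_even", [(10, 5, 5), (9, 5, 4)])
    def test_parity_split(self, n, n_odd, n_even):
        ens = EpochEnsemble(StimulusSpec(70.0, 1000.0))
        # epoch k has constant value k (1-based), so replicate means are exact
        accumulate(ens, np.arange(1, n + 1)[:, None] * np.ones((1, N_SAMPLES)))
        avg = coherent_average(ens)
        odd_vals = np.arange(1, n + 1, 2)
        even_vals = np.arange(2, n + 1, 2)
        assert len(odd_vals) == n_odd and len(even_vals) == n_even
        assert avg.replicate_odd[0] == pytest.approx(odd_vals.mean())
        assert avg.replicate_even[0] == pytest.approx(even_vals.mean())
        # consistency: mean recombines from the replicates
        recombined = (avg.replicate_odd * n_odd + avg.replicate_even * n_even) / n
        np.testing.assert_allclose(avg.mean, recombined, atol=1e-12)

    def test_requires_two_epochs(self):
        ens = EpochEnsemble(StimulusSpec(70.0, 1000.0))
        accumulate(ens, np.zeros((1, N_SAMPLES)))
        with pytest.raises(ValueError, match="at least 2"):
            coherent_average(ens)

    def test_mean_approaches_template(self):
        # template + zero-mean noise, N=1600, rms 5: ||mean-template||_rms < 3*(5/sqrt(N))
        devs = []
        tmpl = wave_v_template(0.4, 8.0, 2.0)
        for seed in range(5):
            ens = make_noise_ensemble(1600, 5.0, seed, amplitude=0.4)
            devs.append(np.sqrt(np.mean((coherent_average(ens).mean - tmpl) ** 2)))
        assert np.mean(devs) < 3 * 5.0 / np.sqrt(1600)


class TestFindPeakTrough:
    def test_constructed_bump_and_dip(self):
        avg = np.zeros(N_SAMPLES)
        avg[40] = 0.3   # 8 ms
        avg[50] = -0.2  # 10 ms
        ptta, peak, trough = find_peak_trough(avg)
        assert ptta == pytest.approx(0.5)
        assert (peak, trough) == (8.0, 10.0)

    def test_all_zero_waveform(self):
        assert find_peak_trough(np.zeros(N_SAMPLES))[0] == 0.0

    def test_distant_pair_excluded_by_separation(self):
        # lone peak at 5 ms and trough at 14 ms are 9 ms apart: the constrained
        # search must not use that pair, and must match the exhaustive oracle
        avg = np.zeros(N_SAMPLES)
        avg[25] = 0.4   # 5 ms
        avg[70] = -0.3  # 14 ms
        ptta, peak, trough = find_peak_trough(avg)
        oracle, _ = brute_force_ptta(avg, FS_HZ, (4.0, 16.0), 8.0)
        assert ptta == pytest.approx(oracle)
        assert trough - peak <= 8.0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            avg = rng.standard_normal(50)
            got, _ = brute_force_ptta(avg, FS_HZ, (0.0, 9.8), 8.0)[0], None
            ptta, peak, trough = find_peak_trough(avg, FS_HZ, (0.0, 9.8), 8.0)
            assert ptta == pytest.approx(got, abs=1e-12)

    def test_empty_search_window_rejected(self):
        with pytest.raises(ValueError, match="search window"):
            find_peak_trough(np.zeros(N_SAMPLES), FS_HZ, (16.0, 4.0), 8.0)


@pytest.mark.skipif(not _HAVE_NUMBA, reason="numba not installed")
def test_envelope_kernel_paths_agree():
    """The numba kernel and the numpy fallback compute identical surrogates."""
    rng = np.random.default_rng(0)
    navg = rng.standard_normal((40, N_SAMPLES)) * 0.2
    unit = wave_v_template(1.0, 8.0, 2.0)
    grid = AMPLITUDE_GRID_UV
    a = _biased_matrix(navg, unit, grid, FS_HZ, (4.0, 16.0), 8.0, use_numba=True)
    b = _biased_matrix(navg, unit, grid, FS_HZ, (4.0, 16.0), 8.0, use_numba=False)
    np.testing.assert_allclose(a, b, atol=1e-12)


class TestDebias:
    def test_noise_free_ensemble_returns_exact_amplitude(self):
        tmpl = wave_v_template(0.4, 8.0, 2.0)
        ens = EpochEnsemble(StimulusSpec(70.0, 1000.0))
        accumulate(ens, np.tile(tmpl, (10, 1)))
        est = estimate_ptta(ens, np.random.default_rng(0))
        assert est.o == pytest.approx(0.4, abs=0.005)
        assert est.sigma2 <= SIGMA2_FLOOR
        assert est.degenerate

    def test_mostly_zero_under_pure_noise(self):
        os_ = [estimate_ptta(make_noise_ensemble(1000, 5.0, s), np.random.default_rng(s)).o
               for s in range(20)]
        assert np.mean(np.array(os_) > 0) <= 0.25

    def test_bias_monotonicity_in_n(self):
        # on pure noise the raw biased PTTa shrinks as the ensemble grows
        means = []
        for n in (500, 2000, 8000):
            vals = [find_peak_trough(coherent_average(make_noise_ensemble(n, 5.0, s)).mean)[0]
                    for s in range(6)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_sigma2_decreases_with_n(self):
        s2 = {n: np.mean([estimate_ptta(make_noise_ensemble(n, 5.0, 50 + s),
                                        np.random.default_rng(s)).sigma2
                          for s in range(6)])
              for n in (500, 4000)}
        assert s2[4000] < s2[500]

    def test_estimate_in_grid_range_and_reproducible(self):
        ens = make_noise_ensemble(800, 5.0, 9, amplitude=0.3)
        e1 = estimate_ptta(ens, np.random.default_rng(11))
        e2 = estimate_ptta(ens, np.random.default_rng(11))
        assert e1.o == e2.o and e1.sigma2 == e2.sigma2
        assert AMPLITUDE_GRID_UV[0] <= e1.o <= AMPLITUDE_GRID_UV[-1]
        assert e1.sigma2 >= SIGMA2_FLOOR
        assert 0 < e1.trough_latency - e1.peak_latency <= 8.0

    def test_empty_ensemble_rejected(self):
        ens = EpochEnsemble(StimulusSpec(70.0, 1000.0))
        with pytest.raises(ValueError):
            debias_ptta(ens, (0.1, 8.0, 10.0), np.random.default_rng(0))
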