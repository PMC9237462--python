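"""Phase spectra, the squared-resultant coherence statistic, the averaging
hierarchy, surrogate nulls and harmonic extraction."""

import numpy as np
import pytest
from scipy import stats

from sylentrain.eeg_preprocess import EpochedEEG
from sylentrain.itpc import (
    average_hierarchy,
    harmonic_extract,
    itpc_cell,
    itpc_table,
    peak_significance,
    phase_spectrum,
    random_phase_itpc,
    surrogate_null,
)

FS = 1000.0
DUR = 4.5  # trimmed epoch duration; bin spacing 2/9 Hz, 4 Hz at bin 18


def epochs_from(traces, condition="c", stream="s", participant="p"):
    data = np.asarray(traces)[:, None, :]  # one channel
    n = data.shape[0]
    return EpochedEEG(data, FS, ["Cz"], np.array([condition] * n, object),
                      np.array([stream] * n, object), np.arange(n),
                      np.array([participant] * n, object))


class TestPhaseSpectrum:
    t = np.arange(int(DUR * FS)) / FS

    def test_cosine_4hz_bin18_phase_zero(self):
        ps = phase_spectrum(epochs_from([np.cos(2 * np.pi * 4 * self.t)]))
        assert ps.freqs[18] == pytest.approx(4.0)
        assert ps.phases[0, 0, 18] == pytest.approx(0.0, abs=1e-6)

    def test_sine_4hz_quadrature(self):
        ps = phase_spectrum(epochs_from([np.sin(2 * np.pi * 4 * self.t)]))
        assert ps.phases[0, 0, 18] == pytest.approx(-np.pi / 2, abs=1e-6)

    def test_fourier_shift_theorem(self):
        shift_s = 0.025
        k = int(shift_s * FS)
        base = np.cos(2 * np.pi * 4 * self.t)
        shifted = np.cos(2 * np.pi * 4 * (self.t - shift_s))
        ps = phase_spectrum(epochs_from([base, shifted]))
        dphi = ps.phases[1, 0, 18] - ps.phases[0, 0, 18]
        expected = -2 * np.pi * 4 * shift_s
        assert np.angle(np.exp(1j * (dphi - expected))) == pytest.approx(0, abs=1e-3)

    def test_ceiling_and_bin_spacing(self):
        ps = phase_spectrum(epochs_from([self.t * 0 + 1.0]), ceiling=26.0)
        assert ps.freqs[-1] <= 26.0 + 1e-9
        assert np.diff(ps.freqs)[0] == pytest.approx(2.0 / 9.0)


class TestItpcCell:
    def test_identical_phases_perfect_coherence(self):
        assert itpc_cell(np.full(10, 0.7)) == pytest.approx(1.0, abs=1e-12)

    def test_evenly_spaced_phases_cancel(self):
        th = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        assert itpc_cell(th) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_mean_one_over_k(self, rng):
        vals = random_phase_itpc(100_000, K=10, rng=rng)
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.1) < 3 * se

    def test_too_few_phases(self):
        with pytest.raises(ValueError):
            itpc_cell(np.array([0.3]))

    def test_brute_force_phasor_oracle(self, rng):
        for _ in range(100):
            th = rng.uniform(-np.pi, np.pi, 10)
            oracle = np.abs(np.mean(np.exp(1j * th))) ** 2
            assert itpc_cell(th) == pytest.approx(oracle, abs=1e-12)

    def test_global_rotation_invariance(self, rng):
        th = rng.uniform(-np.pi, np.pi, 10)
        assert itpc_cell(th + 1.234) == pytest.approx(itpc_cell(th), abs=1e-12)

    def test_unsquared_variant(self, rng):
        th = rng.uniform(-np.pi, np.pi, 10)
        assert itpc_cell(th, squared=False) == pytest.approx(
            np.sqrt(itpc_cell(th)), abs=1e-12)

    def test_von_mises_concentration_monotonicity(self, rng):
        means = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            if kappa == 0:
                th = rng.uniform(-np.pi, np.pi, (10_000, 10))
            else:
                th = stats.vonmises.rvs(kappa, size=(10_000, 10),
                                        random_state=rng)
            c = np.cos(th).mean(axis=1)
            s = np.sin(th).mean(axis=1)
            means.append(np.mean(c * c + s * s))
        assert np.all(np.diff(means) > 0)


class TestHierarchy:
    def test_all_cells_equal(self):
        from sylentrain.itpc import ITPCTable
        R = np.full((3, 2, 4, 2), 0.25)
        tab = ITPCTable(R, np.arange(3.0), ["s0", "s1", "s2", "s3"],
                        {"s0": "a", "s1": "a", "s2": "b", "s3": "b"},
                        ["p0", "p1"], 10)
        R_fa, R_f, (conds, R_cond) = average_hierarchy(tab)
        assert np.allclose(R_fa, 0.25) and np.allclose(R_f, 0.25)
        assert conds == ["a", "b"] and np.allclose(R_cond, 0.25)

    def test_degenerate_single_cell_identity(self, rng):
        from sylentrain.itpc import ITPCTable
        R = rng.uniform(0, 1, (4, 1, 1, 1))
        tab = ITPCTable(R, np.arange(4.0), ["s"], {"s": "c"}, ["p"], 10)
        R_fa, R_f, _ = average_hierarchy(tab)
        assert np.allclose(R_f, R[:, 0, 0, 0])

    def test_brute_force_2x2x2(self, rng):
        from sylentrain.itpc import ITPCTable
        R = rng.uniform(0, 1, (2, 2, 2, 2))
        tab = ITPCTable(R, np.arange(2.0), ["s0", "s1"],
                        {"s0": "a", "s1": "b"}, ["p0", "p1"], 10)
        R_fa, R_f, (conds, R_cond) = average_hierarchy(tab)
        assert np.allclose(R_fa, R.mean(axis=(1, 2)))
        assert np.allclose(R_f, R.mean(axis=(1, 2, 3)))
        assert np.allclose(R_cond[:, 0, :], R[:, :, 0, :].mean(axis=1))

    def test_missing_cells_reported(self):
        from sylentrain.itpc import ITPCTable
        R = np.full((2, 2, 2, 2), np.nan)
        tab = ITPCTable(R, np.arange(2.0), ["s0", "s1"],
                        {"s0": "a", "s1": "b"}, ["p0", "p1"], 10)
        with pytest.raises(ValueError, match="missing"):
            average_hierarchy(tab)

    def test_itpc_table_groups_trials(self, rng):
        t = np.arange(int(DUR * FS)) / FS
        traces = [np.cos(2 * np.pi * 4 * t)] * 5
        ep = epochs_from(traces)
        tab = itpc_table(phase_spectrum(ep))
        assert tab.K == 5
        assert tab.R[18, 0, 0, 0] == pytest.approx(1.0, abs=1e-9)


class TestSurrogateNull:
    def test_degenerate_structure_matches_raw_cells(self):
        null = surrogate_null(1, 1, K=10, n_fictive=3000, seed=1)
        raw = random_phase_itpc(3000, K=10, rng=np.random.default_rng(2))
        ks = stats.ks_2samp(null.values, raw)
        assert ks.pvalue > 0.01

    def test_seeded_reproducibility(self):
        a = surrogate_null(4, 4, n_fictive=50, seed=9)
        b = surrogate_null(4, 4, n_fictive=50, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_null_mean_near_one_over_k(self):
        null = surrogate_null(10, 8, K=10, n_fictive=2000, seed=3)
        assert null.values.mean() == pytest.approx(0.1, abs=0.002)


class TestPeakSignificance:
    def test_separated_samples_tiny_p(self):
        null = surrogate_null(4, 4, n_fictive=1000, seed=4)
        real = np.full(10, null.values.max() + 0.1)
        _, p = peak_significance(real, null)
        assert p < 0.001

    def test_all_tied_returns_one(self):
        from sylentrain.itpc import SurrogateNull
        null = SurrogateNull(np.full(100, 0.1), 1, 1, 10, None)
        _, p = peak_significance(np.full(5, 0.1), null)
        assert p == 1.0

    def test_single_real_value_rejected(self):
        null = surrogate_null(2, 2, n_fictive=100, seed=5)
        with pytest.raises(ValueError):
            peak_significance(np.array([0.5]), null)

    def test_p_uniform_under_null(self):
        """Real participants drawn from the fictive distribution give
        uniformly distributed one-sided p-values."""
        rng = np.random.default_rng(6)
        null = surrogate_null(4, 4, K=5, n_fictive=400, seed=7)
        pvals = []
        for _ in range(200):
            real = random_phase_itpc(10 * 16, K=5, rng=rng).reshape(10, 16).mean(1)
            pvals.append(peak_significance(real, null)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestHarmonicExtract:
    def test_exact_bins_at_4p5s(self):
        freqs = np.arange(0, 118) * (2.0 / 9.0)
        R = np.zeros(118)
        R[[18, 36, 54, 72]] = [0.4, 0.3, 0.2, 0.1]
        out = harmonic_extract(R, freqs)
        assert np.allclose(out, [0.4, 0.3, 0.2, 0.1])

    def test_pure_4hz_epochs(self, rng):
        t = np.arange(int(DUR * FS)) / FS
        traces = [np.cos(2 * np.pi * 4 * t + 0.3)
                  + 0.001 * rng.standard_normal(t.size) for _ in range(40)]
        tab = itpc_table(phase_spectrum(epochs_from(traces)))
        _, R_f, _ = average_hierarchy(tab)
        vals = harmonic_extract(R_f, tab.freqs)
        assert vals[0] > 0.99
        assert vals[1] < 0.4  # 8 Hz bin carries only noise-level coherence

    def test_incommensurate_base_warns(self):
        freqs = np.arange(0, 118) * (2.0 / 9.0)
        with pytest.warns(UserWarning, match="bin"):
            harmonic_extract(np.zeros(118), freqs, harmonics=(5.0,))

    def test_above_ceiling_errors(self):
        freqs = np.arange(0, 118) * (2.0 / 9.0)
        with pytest.raises(ValueError, match="ceiling"):
            harmonic_extract(np.zeros(118), freqs, harmonics=(40.0,))
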