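"""Stochastic allocation: conservation, marginal law, determinism, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from randpam import (
    AllocationInfeasibleError,
    SamplingGeometry,
    allocate_compound_binomial,
    allocate_multinomial,
    constant_stimulus,
    empirical_multi_photon_fraction,
    hit_series,
    multi_photon_fraction,
    read_events,
    reconstruct_stimulus,
    simulate,
    white_noise_stimulus,
    write_events,
)
from randpam.stimuli import LightStimulus


class TestMultinomialAllocator:
    def test_zero_photons_empty(self, drosophila, rng):
        ids, hits = allocate_multinomial(0, drosophila, rng)
        assert ids.size == 0 and hits.size == 0

    def test_single_microvillus_takes_all(self, rng):
        ids, hits = allocate_multinomial(5, SamplingGeometry(1), rng)
        assert ids.tolist() == [0] and hits.tolist() == [5]

    def test_conservation(self, drosophila, rng):
        for n_ph in (1, 37, 1000):
            _, hits = allocate_multinomial(n_ph, drosophila, rng)
            assert hits.sum() == n_ph

    def test_marginal_law_chi_square(self):
        """Hits to one fixed microvillus over replicate bins are
        Binomial(N_ph, 1/N_u) at alpha=0.001."""
        geometry = SamplingGeometry(300)
        n_ph, n_bins = 100, 10_000
        stim = LightStimulus(counts=np.full(n_bins, n_ph))
        allocation = simulate(stim, geometry, seed=77)
        observed = hit_series(allocation, 0).counts
        exp_counts = stats.binom.pmf(np.arange(10), n_ph, 1 / 300) * n_bins
        cut = int(np.nonzero(exp_counts >= 5)[0][-1] + 1)  # merge sparse tail
        obs_freq = np.bincount(observed, minlength=cut + 1)
        obs_merged = np.append(obs_freq[:cut], obs_freq[cut:].sum())
        exp_merged = np.append(exp_counts[:cut], n_bins - exp_counts[:cut].sum())
        _, p_value = stats.chisquare(obs_merged, exp_merged)
        assert p_value > 0.001

    def test_multi_photon_fraction_converges(self, drosophila):
        """Empirical multi-hit fraction matches the Poisson P_M within 3 SE."""
        frac, se, n_hit = empirical_multi_photon_fraction(1000, drosophila, 10_000, seed=5)
        expected = multi_photon_fraction(1000 / 30_000)
        assert n_hit > 1e6
        assert abs(frac - expected) < 3 * se


class TestCompoundBinomialAllocator:
    def test_zero_photons(self, drosophila, rng):
        ids, hits, x_n = allocate_compound_binomial(0, drosophila, rng)
        assert ids.size == 0 and x_n == 0

    def test_truncation_order_at_fly_midday(self, drosophila, rng):
        """At lambda=1/30 the 2-hit class still exceeds one microvillus
        (N_u P(2) ~ 16.1) but the 3-hit class does not (N_u P(3) ~ 0.18)."""
        _, _, x_n = allocate_compound_binomial(1000, drosophila, rng)
        assert x_n == 2

    def test_exact_conservation_after_correction(self, drosophila, rng):
        for n_ph in (1, 999, 1000, 1001, 5000):
            ids, hits, _ = allocate_compound_binomial(n_ph, drosophila, rng)
            assert hits.sum() == n_ph
            assert np.unique(ids).size == ids.size  # one x-class per microvillus

    def test_conservation_under_negative_residual(self, rng):
        """High lambda makes rounded class sizes overshoot; the correction
        must remove the surplus in single-photon steps."""
        geometry = SamplingGeometry(500)
        for n_ph in (400, 900, 1700):
            _, hits, _ = allocate_compound_binomial(n_ph, geometry, rng)
            assert hits.sum() == n_ph

    def test_infeasible_tiny_population(self, rng):
        with pytest.raises(AllocationInfeasibleError):
            allocate_compound_binomial(100, SamplingGeometry(2), rng)


class TestSimulate:
    def test_dark_stimulus_no_events(self, drosophila):
        stim = constant_stimulus(0, 0.05)
        allocation = simulate(stim, drosophila, seed=1)
        assert allocation.n_events == 0
        assert np.all(reconstruct_stimulus(allocation).counts == 0)

    def test_seed_determinism(self, drosophila):
        stim = white_noise_stimulus(1e4, 0.3, 20.0, 0.2, seed=2)
        a = simulate(stim, drosophila, seed=42)
        b = simulate(stim, drosophila, seed=42)
        assert np.array_equal(a.bins, b.bins)
        assert np.array_equal(a.microvilli, b.microvilli)
        assert np.array_equal(a.hits, b.hits)

    def test_different_seeds_agree_on_totals(self, drosophila):
        stim = white_noise_stimulus(1e4, 0.3, 20.0, 0.2, seed=2)
        a = simulate(stim, drosophila, seed=1)
        b = simulate(stim, drosophila, seed=2)
        assert not np.array_equal(a.microvilli, b.microvilli)
        assert np.array_equal(
            reconstruct_stimulus(a).counts, reconstruct_stimulus(b).counts
        )

    @pytest.mark.parametrize("method", ["multinomial", "compound_binomial"])
    def test_round_trip_identity(self, drosophila, method):
        """Summing all allocated photons reproduces the input light pattern."""
        stim = white_noise_stimulus(1e5, 0.3, 20.0, 0.5, seed=3)
        allocation = simulate(stim, drosophila, seed=7, method=method)
        assert np.array_equal(reconstruct_stimulus(allocation).counts, stim.counts)

    def test_unknown_method_rejected(self, drosophila):
        with pytest.raises(ValueError):
            simulate(constant_stimulus(1000, 0.01), drosophila, seed=0, method="poisson")

    def test_lambda_recovery_is_exact(self, drosophila):
        """Conservation makes the rate estimate exact: total hits equal
        total photons, so lambda_hat = lambda to machine precision."""
        stim = constant_stimulus(1e6, 1.0)  # 1e6 photons total
        allocation = simulate(stim, drosophila, seed=11)
        lam = 1000 / 30_000
        assert allocation.lambda_estimate() == pytest.approx(lam, rel=1e-12)


class TestHitSeries:
    def test_all_zero_under_dark(self, drosophila):
        allocation = simulate(constant_stimulus(0, 0.05), drosophila, seed=0)
        assert np.all(hit_series(allocation, 123).counts == 0)

    def test_out_of_range_id(self, drosophila):
        allocation = simulate(constant_stimulus(1000, 0.01), drosophila, seed=0)
        with pytest.raises(ValueError):
            hit_series(allocation, 30_000)

    def test_dim_light_discrete_hits(self):
        """lambda=0.01 over 1e4 bins: ~100 isolated single hits."""
        geometry = SamplingGeometry(100)
        stim = LightStimulus(counts=np.ones(10_000, dtype=np.int64))
        allocation = simulate(stim, geometry, seed=13)
        series = hit_series(allocation, 0).counts
        total = series.sum()
        assert abs(total - 100) <= 3 * np.sqrt(100)
        assert series.max() <= 2  # discrete, essentially never coincident

    def test_bright_light_fluctuates_around_mean(self):
        """lambda=100: hit counts fluctuate around the mean rate."""
        geometry = SamplingGeometry(10)
        stim = LightStimulus(counts=np.full(1000, 1000, dtype=np.int64))
        allocation = simulate(stim, geometry, seed=17)
        series = hit_series(allocation, 3).counts
        se = np.sqrt(100 / 1000)  # Poisson SE of the mean over 1e3 bins
        assert abs(series.mean() - 100) < 3 * se


class TestEventIO:
    @pytest.mark.parametrize("suffix", ["h5", "csv"])
    def test_round_trip(self, drosophila, tmp_path, suffix):
        stim = white_noise_stimulus(1e4, 0.3, 20.0, 0.1, seed=21)
        allocation = simulate(stim, drosophila, seed=22)
        path = tmp_path / f"events.{suffix}"
        write_events(allocation, path)
        back = read_events(path)
        assert np.array_equal(back.bins, allocation.bins)
        assert np.array_equal(back.microvilli, allocation.microvilli)
        assert np.array_equal(back.hits, allocation.hits)
        assert back.seed == 22 and back.method == "multinomial"
        assert back.geometry.n_microvilli == 30_000


class TestPhotonAllocationType:
    def test_dense_export(self):
        geometry = SamplingGeometry(5)
        stim = LightStimulus(counts=np.array([3, 0, 2], dtype=np.int64))
        allocation = simulate(stim, geometry, seed=1)
        dense = allocation.to_dense()
        assert dense.shape == (3, 5)
        assert dense.sum(axis=1).tolist() == [3, 0, 2]

    def test_zero_hit_events_rejected(self, drosophila):
        from randpam import PhotonAllocation

        with pytest.raises(ValueError):
            PhotonAllocation(
                n_bins=1,
                geometry=drosophila,
                bins=np.array([0]),
                microvilli=np.array([4]),
                hits=np.array([0]),
            )

    @given(counts=st.lists(st.integers(min_value=0, max_value=200), min_size=1, max_size=30),
           seed=st.integers(min_value=0, max_value=2**31 - 1),
           method=st.sampled_from(["multinomial", "compound_binomial"]))
    @settings(max_examples=25, deadline=None)
    def test_conservation_property(self, counts, seed, method):
        """Every bin's hits sum to its stimulus count, for any input."""
        geometry = SamplingGeometry(200)
        stim = LightStimulus(counts=np.asarray(counts, dtype=np.int64))
        allocation = simulate(stim, geometry, seed=seed, method=method)
        assert np.array_equal(reconstruct_stimulus(allocation).counts, stim.counts)
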