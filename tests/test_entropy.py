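"""Shannon entropy identities and SampEn against a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from singlechan import (DwellTimeSeries, default_dwell_edges, dwell_histogram,
                        sample_entropy, shannon_entropy,
                        windowed_sample_entropy)


# ---------------------------------------------------------------------------
# independent oracle: direct double-loop counting of Eqs as printed
# ---------------------------------------------------------------------------

def sampen_oracle(x, m, r, variant="printed"):
    """Direct per-template counting, independent of the blocked fast path."""
    x = np.asarray(x, dtype=float)
    N = x.size

    def counts(mm, n_templates=None):
        nt = N - mm + 1 if n_templates is None else n_templates
        c = np.zeros(nt)
        for i in range(nt):
            d = np.zeros(nt)
            for k in range(mm):
                d = np.maximum(d, np.abs(x[i + k] - x[k:k + nt]))
            c[i] = np.count_nonzero(d <= r) - 1
        return c

    if variant == "printed":
        Cm = (counts(m) / (N - m)).mean()
        Cm1 = (counts(m + 1) / (N - m - 1)).mean()
    else:
        Cm = counts(m, n_templates=N - m).sum() / 2
        Cm1 = counts(m + 1).sum() / 2
    if Cm == 0 or Cm1 == 0:
        return math.nan
    return -math.log(Cm1 / Cm)


class TestShannonEntropy:
    def test_uniform_is_log2_k(self):
        for k in (2, 4, 16):
            assert shannon_entropy(np.full(k, 1 / k)) == pytest.approx(
                math.log2(k))

    def test_degenerate_is_zero(self):
        assert shannon_entropy([1.0]) == 0.0
        assert shannon_entropy([0.0, 1.0, 0.0]) == 0.0

    def test_analytic_three_state(self):
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.6])
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=32))
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_log2_k(self, weights):
        p = np.array(weights) / sum(weights)
        h = shannon_entropy(p)
        assert 0.0 <= h <= math.log2(p.size) + 1e-9


class TestDwellHistogram:
    def test_single_bin_degenerate(self):
        edges = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        h = dwell_histogram(np.full(7, 5e-3), edges)
        np.testing.assert_allclose(h.probabilities, [0, 1, 0])
        assert h.entropy_bits() == 0.0

    def test_two_bins_split(self):
        edges = np.array([1e-4, 1e-3, 1e-2])
        h = dwell_histogram(np.array([2e-4, 3e-4, 2e-3, 3e-3]), edges)
        np.testing.assert_allclose(h.probabilities, [0.5, 0.5])
        assert h.entropy_bits() == pytest.approx(1.0)

    def test_out_of_range_counted_in_end_bins(self):
        edges = np.array([1e-3, 1e-2, 1e-1])
        h = dwell_histogram(np.array([1e-5, 5e-3, 5.0]), edges)
        assert h.probabilities.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(h.probabilities, [2 / 3, 1 / 3])

    @given(st.lists(st.floats(1e-4, 50.0), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_normalization(self, durations):
        h = dwell_histogram(np.array(durations), default_dwell_edges())
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestSampleEntropy:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            x = rng.random(400)
            r = 0.2 * x.std()
            fast = sample_entropy(x, m=2, r=r)
            assert fast.value == pytest.approx(
                sampen_oracle(x, 2, r), abs=1e-12)

    def test_richman_moorman_matches_oracle(self, rng):
        x = rng.random(300)
        r = 0.2 * x.std()
        fast = sample_entropy(x, m=2, r=r, variant="richman-moorman")
        assert fast.value == pytest.approx(
            sampen_oracle(x, 2, r, variant="richman-moorman"), abs=1e-12)

    def test_periodic_series_is_zero(self):
        # every m-match extends to m+1, so SampEn vanishes up to boundary
        # terms.  The pair-counting variant is exactly 0; the per-template
        # form retains a small boundary residue whose exact value the
        # double-loop oracle confirms (25 even- vs 24 odd-parity templates
        # at N=50 give -ln[(48*23/48/47)/((25*24+24*23)/49/48)]).
        x = np.tile([1.0, 2.0], 25)
        rm = sample_entropy(x, m=2, r=0.3, variant="richman-moorman")
        assert rm.value == pytest.approx(0.0, abs=1e-12)
        res = sample_entropy(x, m=2, r=0.3)
        assert res.value == pytest.approx(sampen_oracle(x, 2, 0.3), abs=1e-12)
        assert res.value == pytest.approx(0.0, abs=1e-3)  # boundary residue only

    def test_no_matches_flagged_undefined(self):
        # strictly accelerating growth: no two m-templates within r
        x = np.array([2.0**k for k in range(12)])
        res = sample_entropy(x, m=2, r=0.1)
        assert not res.defined
        assert math.isnan(res.value)
        assert res.reason is not None

    def test_scale_invariance(self, rng):
        x = rng.random(500)
        r = 0.2 * x.std()
        a = sample_entropy(x, m=2, r=r).value
        b = sample_entropy(1000.0 * x, m=2, r=1000.0 * r).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), m=2)

    def test_zero_variance_with_relative_r_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sample_entropy(np.full(100, 3.0), m=2)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_oracle_equivalence_randomized(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(20, 200))
        x = g.normal(size=n)
        r = 0.25 * x.std()
        fast = sample_entropy(x, m=2, r=r)
        want = sampen_oracle(x, 2, r)
        if math.isnan(want):
            assert not fast.defined
        else:
            assert fast.value == pytest.approx(want, abs=1e-12)

    def test_predictability_ordering(self, rng):
        # alternating near-periodic dwells vs their i.i.d. shuffle
        base = np.tile([1.0, 3.0], 2000) + rng.normal(0, 0.05, 4000)
        shuffled = rng.permutation(base)
        h_per = sample_entropy(base, m=2, r=0.2 * base.std()).value
        h_shuf = sample_entropy(shuffled, m=2, r=0.2 * shuffled.std()).value
        assert h_per < h_shuf


class TestWindowedSampEn:
    def test_window_arithmetic(self, rng):
        x = rng.random(8000)
        res = windowed_sample_entropy(x, window=4000)
        assert res.window_values.size == 2
        v = res.window_values
        assert res.value == pytest.approx(v.mean())
        assert res.se == pytest.approx(np.std(v, ddof=1) / math.sqrt(2))

    def test_duplicated_window_zero_se(self, rng):
        half = rng.random(4000)
        res = windowed_sample_entropy(np.concatenate([half, half]),
                                      window=4000)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_short_series_single_window_fallback(self, rng):
        x = rng.random(500)
        res = windowed_sample_entropy(x, window=4000)
        assert res.window_length == 500
        assert res.window_values.size == 1

    def test_stationary_windows_agree_with_whole_series(self, rng):
        # i.i.d. dwells: windowed mean ~ whole-series SampEn
        x = rng.exponential(2e-3, 8000)
        res = windowed_sample_entropy(x, window=4000)
        whole = sample_entropy(x, m=2, r=0.2 * x.std()).value
        spread = max(3 * (res.se if res.se == res.se else 0.0), 0.2)
        assert abs(res.value - whole) < spread

    def test_accepts_dwell_time_series(self):
        n = 4002
        states = np.arange(n) % 2 == 0
        durations = np.abs(np.sin(np.arange(n))) * 1e-3 + 1e-4
        dw = DwellTimeSeries(states=states, durations=durations)
        res = windowed_sample_entropy(dw, window=2000)
        assert res.defined
        assert res.window_values.size == 2
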