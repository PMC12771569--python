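"""Symbolic transform, wSMI (vs brute-force oracle), PLV, ROI aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mindstate as ms
from mindstate import connectivity as cn
from mindstate import markers as mk
from mindstate.errors import DataError, ParameterError

from conftest import make_epochs

ALPHA = mk.BandDefinition("alpha", 8.0, 12.0)


def wsmi_bruteforce(x, y, tau=1):
    """Independent wSMI oracle: dict-based contingency counts and plain
    Python-float MI accumulation, with its own pattern coding."""
    def patterns(v):
        out = []
        for t in range(len(v) - 2 * tau):
            trip = (v[t], v[t + tau], v[t + 2 * tau])
            order = sorted(range(3), key=lambda i: (trip[i], i))
            ranks = tuple(order.index(i) for i in range(3))
            out.append(ranks)
        return out

    px_, py_, pxy = {}, {}, {}
    sx, sy = patterns(list(x)), patterns(list(y))
    n = len(sx)
    for a, b in zip(sx, sy):
        px_[a] = px_.get(a, 0) + 1
        py_[b] = py_.get(b, 0) + 1
        pxy[(a, b)] = pxy.get((a, b), 0) + 1
    if len(px_) < 2 or len(py_) < 2:
        return 0.0
    total = 0.0
    for (a, b), c in pxy.items():
        if a == b or a == tuple(2 - r for r in b):
            continue
        p_ab = c / n
        total += p_ab * math.log(p_ab / ((px_[a] / n) * (py_[b] / n)))
    return total / math.log(6)


class TestSymbolicTransform:
    def test_hand_enumerated_patterns(self):
        out = cn.symbolic_transform([3, 1, 2, 5, 4, 0], tau=1)
        # rank triples: (2,0,1), (0,1,2), (0,2,1), (2,1,0)
        expected = [cn.PATTERNS.index(p) for p in [(2, 0, 1), (0, 1, 2), (0, 2, 1), (2, 1, 0)]]
        assert list(out.symbols) == expected

    def test_strictly_increasing_all_ascending(self):
        out = cn.symbolic_transform(np.arange(50.0), tau=3)
        assert (out.symbols == cn.PATTERNS.index((0, 1, 2))).all()
        assert out.symbols.size == 50 - 2 * 3

    def test_ties_break_earlier_index_smaller(self):
        out = cn.symbolic_transform([1.0, 1.0, 1.0], tau=1)
        assert list(out.symbols) == [cn.PATTERNS.index((0, 1, 2))]

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            cn.symbolic_transform([1.0, 2.0], tau=1)


class TestSymbolicProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    # integer-valued inputs: the affine map below is then exact, so rank
    # patterns must be preserved bit-for-bit
    @given(st.lists(st.integers(-1000, 1000), min_size=12, max_size=80),
           st.integers(min_value=1, max_value=4))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_length_range_and_monotone_invariance(self, xs, tau):
        x = np.asarray(xs, dtype=float)
        if x.size <= 2 * tau:
            return
        out = cn.symbolic_transform(x, tau=tau)
        assert out.symbols.size == x.size - 2 * tau
        assert out.symbols.min() >= 0 and out.symbols.max() <= 5
        # strictly monotone transforms preserve every rank pattern
        warped = cn.symbolic_transform(3.0 * x + 7.0, tau=tau)
        assert np.array_equal(out.symbols, warped.symbols)


class TestWsmi:
    def test_self_and_negation_are_exactly_zero(self, rng):
        x = rng.standard_normal(300)
        assert cn.wsmi(x, x, tau=2) == 0.0
        assert cn.wsmi(x, -x, tau=2) == 0.0

    def test_matches_bruteforce_on_coupled_pairs(self):
        # 100 random coupled pairs, lengths up to 2000
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(50, 2000))
            tau = int(r.integers(1, 4))
            s = r.standard_normal(n)
            x = s + 0.5 * r.standard_normal(n)
            y = np.roll(s, tau) + 0.5 * r.standard_normal(n)
            assert cn.wsmi(x, y, tau=tau) == pytest.approx(
                wsmi_bruteforce(x, y, tau=tau), abs=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.standard_normal(400)
        y = np.roll(x, 1) + 0.3 * rng.standard_normal(400)
        base = cn.wsmi(x, y, tau=2)
        assert cn.wsmi(np.exp(x), y ** 3 + 5 * y, tau=2) == pytest.approx(base, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            cn.wsmi(rng.standard_normal(100), rng.standard_normal(99))

    def test_degenerate_constant_input_returns_zero(self, rng):
        assert cn.wsmi(np.arange(100.0), rng.standard_normal(100)) == 0.0


class TestPlv:
    def test_self_is_one(self, rng):
        x = rng.standard_normal(2000)
        assert cn.plv(x, x, ALPHA, 250.0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_lag_narrowband_above_099(self, rng):
        fs = 250.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 10 * (t - 0.02)) + 0.01 * rng.standard_normal(t.size)
        assert cn.plv(x, y, ALPHA, fs) > 0.99

    def test_independent_noise_below_005(self, rng):
        x = rng.standard_normal(10000)
        y = rng.standard_normal(10000)
        assert cn.plv(x, y, ALPHA, 250.0) < 0.05

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert cn.plv(3.7 * x, y, ALPHA, 250.0) == pytest.approx(
            cn.plv(x, 0.2 * y, ALPHA, 250.0), abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        assert np.isnan(cn.plv(np.zeros(1000), rng.standard_normal(1000), ALPHA, 250.0))

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ParameterError):
            cn.plv(rng.standard_normal(500), rng.standard_normal(500),
                   mk.BandDefinition("hf", 100.0, 140.0), 250.0)


class TestBandConnectivity:
    def test_independent_noise_mean_wsmi_near_zero(self, rng):
        # long (60 s) epochs: the narrowband filter leaves few effective
        # samples per second, so short epochs carry visible estimator bias
        epochs = make_epochs(rng.standard_normal((6, 4, 15000)), window=(-60.0, 0.0))
        res = cn.band_wsmi(epochs, ALPHA)
        off = res.matrix[:, ~np.eye(4, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_planted_nonlinear_coupling_beats_null_by_5sd(self, rng):
        from mindstate.synthgen import _band_noise, _monotone_distortion
        fs, n = 250.0, 1250
        null_vals, coupled_vals = [], []
        for i in range(40):
            s = _band_noise(rng, (n,), fs, 8.0, 12.0)
            x = s + 0.4 * _band_noise(rng, (n,), fs, 8.0, 12.0)
            y_c = _monotone_distortion(np.roll(s, 7)) + 0.4 * _band_noise(rng, (n,), fs, 8.0, 12.0)
            y_n = _band_noise(rng, (n,), fs, 8.0, 12.0)
            coupled_vals.append(cn.wsmi(x, y_c, tau=7))
            null_vals.append(cn.wsmi(x, y_n, tau=7))
        gap = np.mean(coupled_vals) - np.mean(null_vals)
        assert gap > 5 * np.std(null_vals)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        epochs = make_epochs(rng.standard_normal((3, 4, 1250)), window=(-5.0, 0.0))
        res = cn.band_wsmi(epochs, ALPHA)
        assert np.allclose(res.matrix, np.transpose(res.matrix, (0, 2, 1)))
        assert np.abs(res.matrix[:, np.eye(4, dtype=bool)]).max() == 0.0

    def test_band_above_nyquist_rejected(self, rng):
        epochs = make_epochs(rng.standard_normal((2, 2, 1250)), fs=60.0,
                             window=(0.0, 1250 / 60.0))
        with pytest.raises(ParameterError):
            cn.band_wsmi(epochs, mk.BandDefinition("g", 30.0, 45.0))


class TestRoiAggregation:
    def test_default_scheme_45_pairs(self):
        scheme = cn.RoiScheme.desikan_killiany_lobes(68)
        assert scheme.n_rois == 10
        assert cn.n_roi_pairs(scheme) == 45
        assert scheme.assignment.size == 68

    def test_one_source_per_roi_is_identity(self, rng):
        scheme = cn.RoiScheme(roi_names=[f"r{i}" for i in range(4)],
                              assignment=np.arange(4))
        mat = rng.standard_normal((4, 4))
        mat = (mat + mat.T) / 2
        src = cn.ConnectivityResult(band=ALPHA, metric="wsmi", matrix=mat,
                                    node_names=list("abcd"), node_kind="source")
        out = cn.roi_aggregate(src, scheme)
        iu = np.triu_indices(4, 1)
        assert np.allclose(out.matrix[iu], mat[iu])

    def test_block_constant_matrix_aggregates_to_constants(self):
        scheme = cn.RoiScheme(roi_names=["a", "b"], assignment=np.array([0, 0, 1, 1]))
        mat = np.zeros((4, 4))
        mat[:2, 2:] = 0.7
        mat[2:, :2] = 0.7
        src = cn.ConnectivityResult(band=ALPHA, metric="plv", matrix=mat,
                                    node_names=list("wxyz"), node_kind="source")
        out = cn.roi_aggregate(src, scheme)
        assert out.matrix[0, 1] == pytest.approx(0.7)

    def test_source_count_mismatch_rejected(self, rng):
        scheme = cn.RoiScheme.desikan_killiany_lobes(68)
        src = cn.ConnectivityResult(band=ALPHA, metric="wsmi",
                                    matrix=rng.standard_normal((10, 10)),
                                    node_names=list(range(10)), node_kind="source")
        with pytest.raises(DataError):
            cn.roi_aggregate(src, scheme)


class TestDissociationCheck:
    def _epochs(self, rng, n=6):
        return make_epochs(rng.standard_normal((n, 4, 1250)), window=(-5.0, 0.0))

    def test_contrast_antisymmetry_and_null_centering(self, rng):
        by_state = {"ON": self._epochs(rng), "MB": self._epochs(rng)}
        tab = cn.plv_wsmi_dissociation_check(by_state, ALPHA)
        ab = tab[(tab.state_a == "MB") & (tab.state_b == "ON")].set_index(
            ["metric", "node_i", "node_j"])["delta"]
        ba = tab[(tab.state_a == "ON") & (tab.state_b == "MB")].set_index(
            ["metric", "node_i", "node_j"])["delta"]
        assert np.allclose(ab.to_numpy(), -ba.to_numpy())
        # identical generating distributions: contrasts center near zero
        assert abs(tab[tab.metric == "wsmi"]["delta"]).mean() < 0.05

    def test_planted_profile_recovered(self, small_recording):
        import mindstate.epoching as epc
        cfg_pairs = [(2, 18), (5, 21)]
        epochs = epc.epoch_truth_segments(small_recording, 5.0, max_per_state=5)
        states = epochs.metadata["state_label"].to_numpy()
        by_state = {s: epochs.select(states == s) for s in ("ON", "MB")}
        tab = cn.plv_wsmi_dissociation_check(by_state, ALPHA, pairs=cfg_pairs)
        mb_on = tab[(tab.state_a == "MB") & (tab.state_b == "ON")]
        plv_delta = mb_on[mb_on.metric == "plv"]["delta"].mean()
        wsmi_delta = mb_on[mb_on.metric == "wsmi"]["delta"].mean()
        assert plv_delta > 0 and wsmi_delta < 0

    def test_single_state_rejected(self, rng):
        with pytest.raises(DataError):
            cn.plv_wsmi_dissociation_check({"ON": self._epochs(rng)}, ALPHA)
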