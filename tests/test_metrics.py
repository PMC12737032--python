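"""Activity metrics, thresholds, and the method roster."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actipipe as ap
from actipipe.core import ConfigurationError
from actipipe.metrics import ThresholdSpec, valid_combinations
from tests.conftest import make_constant_recording


def make_signal(values, scheme="ENMO", rate=10.0):
    ts = np.round(np.arange(len(values)) * 1000.0 / rate).astype(np.int64)
    return ap.PreprocessedSignal(scheme, values, ts, rate)


class TestThreshold:
    def test_sd_rule(self):
        rng = np.random.default_rng(0)
        sig = make_signal(np.abs(rng.normal(0, 0.05, 20000)), "ENMO")
        thr = ap.compute_threshold(sig)
        assert thr.level == pytest.approx(float(sig.values.std()))

    def test_ufm_adds_one_g(self):
        rng = np.random.default_rng(1)
        sig = make_signal(1.0 + rng.normal(0, 0.02, 20000), "UFM")
        thr = ap.compute_threshold(sig)
        assert thr.level == pytest.approx(1.0 + float(sig.values.std()),
                                          rel=1e-6)

    def test_pooled_equals_concatenation_oracle(self):
        rng = np.random.default_rng(2)
        a = make_signal(np.abs(rng.normal(0, 0.03, 500)), "ENMO")
        b = make_signal(np.abs(rng.normal(0.1, 0.08, 800)), "ENMO")
        pooled = ap.compute_threshold([a, b]).level
        brute = float(np.concatenate([a.values, b.values]).std())
        assert pooled == pytest.approx(brute)
        # with equal means, the pooled level lies between per-signal levels
        c = make_signal(rng.normal(0, 0.03, 500) + 1, "UFNM")
        d = make_signal(rng.normal(0, 0.08, 500) + 1, "UFNM")
        c.values -= c.values.mean() - 1
        d.values -= d.values.mean() - 1
        lo, hi = sorted([ap.compute_threshold(c).level,
                         ap.compute_threshold(d).level])
        assert lo <= ap.compute_threshold([c, d]).level <= hi

    def test_mixed_schemes_and_empty_rejected(self):
        a = make_signal([0.1], "ENMO")
        b = make_signal([0.1], "FMpre")
        with pytest.raises(ConfigurationError):
            ap.compute_threshold([a, b])
        with pytest.raises(ConfigurationError):
            ap.compute_threshold([])


class TestActivityValues:
    def test_constant_signal(self):
        """Constant 0.1 g at 10 Hz, 60 s epochs: PIM integrates, MAD is
        zero, TAT saturates, ZCM never crosses."""
        sig = make_signal(np.full(1200, 0.1))
        thr = ThresholdSpec(0.05, "per_recording", "ENMO")
        assert ap.compute_activity(sig, "PIM").values == pytest.approx(6.0)
        assert ap.compute_activity(sig, "MAD").values == pytest.approx(0.0)
        assert ap.compute_activity(sig, "TAT", threshold=thr).values \
            == pytest.approx(60.0)
        assert ap.compute_activity(sig, "ZCM", threshold=thr).values \
            == pytest.approx(0.0)

    def test_square_wave_counting(self):
        """1 Hz square wave alternating 0 / 0.2 g: one upward crossing of
        a 0.1 g level per cycle, above it half the time."""
        second = np.concatenate([np.zeros(5), np.full(5, 0.2)])
        sig = make_signal(np.tile(second, 120))
        thr = ThresholdSpec(0.1, "per_recording", "ENMO")
        zcm = ap.compute_activity(sig, "ZCM", threshold=thr)
        tat = ap.compute_activity(sig, "TAT", threshold=thr)
        assert zcm.values.tolist() == [60.0, 60.0]
        assert tat.values.tolist() == [30.0, 30.0]

    def test_mad_alternating(self):
        sig = make_signal(np.tile([0.0, 0.2], 600))
        assert ap.compute_activity(sig, "MAD").values == pytest.approx(0.1)

    def test_ai_constant_bundle_is_zero(self):
        rec = make_constant_recording((0.1, -0.5, 0.85))
        bundle = ap.axis_bundle(rec, filtered=False)
        vals = ap.compute_activity(bundle, "AI").values
        assert vals == pytest.approx(0.0)

    def test_hfen_requires_hfmpre(self):
        sig = make_signal(np.full(1200, 0.1), "FMpre")
        with pytest.raises(ConfigurationError):
            ap.compute_activity(sig, "HFEN")

    def test_threshold_required_for_zcm_tat(self):
        sig = make_signal(np.full(1200, 0.1))
        for metric in ("ZCM", "TAT"):
            with pytest.raises(ConfigurationError):
                ap.compute_activity(sig, metric)

    def test_ai_requires_bundle(self):
        sig = make_signal(np.full(1200, 0.1))
        with pytest.raises(ConfigurationError):
            ap.compute_activity(sig, "AI")

    def test_partial_epochs_dropped_and_aligned(self):
        # signal starts mid-minute: first epoch starts on the next minute
        ts = 30_000 + np.arange(1500, dtype=np.int64) * 100
        sig = ap.PreprocessedSignal("ENMO", np.ones(1500), ts, 10.0)
        act = ap.compute_activity(sig, "PIM")
        assert act.epoch_starts[0] == 60_000
        assert len(act) == 2  # 150 s, 30 s lead-in -> 2 whole minutes


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_zcm_matches_brute_force_oracle(seed):
    """ZCM equals a sample loop counting sign changes of (value - level)
    from - to +."""
    rng = np.random.default_rng(seed)
    vals = np.abs(rng.normal(0, 0.1, 600))
    level = float(rng.uniform(0.01, 0.2))
    sig = make_signal(vals)
    zcm = ap.compute_activity(
        sig, "ZCM", threshold=ThresholdSpec(level, "per_recording", "ENMO"))
    count = 0
    for i in range(1, 600):
        if vals[i - 1] - level <= 0 < vals[i] - level:
            count += 1
    assert zcm.values.tolist() == [float(count)]


def test_scale_covariance():
    """Scaling a gravity-free signal by c scales PIM/MAD/AI/HFEN epochs
    by c and leaves ZCM/TAT unchanged when the threshold is recomputed."""
    rng = np.random.default_rng(3)
    vals = np.abs(rng.normal(0, 0.1, 2400))
    c = 3.7
    for scheme, metrics in (("ENMO", ("PIM", "MAD")), ("HFMpre", ("HFEN",))):
        a = make_signal(vals, scheme)
        b = make_signal(c * vals, scheme)
        for m in metrics:
            va = ap.compute_activity(a, m).values
            vb = ap.compute_activity(b, m).values
            assert np.allclose(vb, c * va), m
    a = make_signal(vals)
    b = make_signal(c * vals)
    for m in ("ZCM", "TAT"):
        va = ap.compute_activity(a, m, threshold=ap.compute_threshold(a)).values
        vb = ap.compute_activity(b, m, threshold=ap.compute_threshold(b)).values
        assert np.array_equal(va, vb), m


def test_threshold_suppression_of_night_epochs(cohort_products):
    """Threshold metrics zero out more night epochs than integration on
    the same FMpre signal - the mechanism behind depressed L5 values."""
    for prod in cohort_products:
        night = np.zeros(len(prod["series"]["PIM(FMpre)"]), dtype=bool)
        starts = prod["series"]["PIM(FMpre)"].epoch_starts
        for a, b in prod["truth"].sleep_windows:
            night |= (starts >= a) & (starts + 60000 <= b)
        frac = {m: float((prod["series"][m].values[night] == 0).mean())
                for m in ("PIM(FMpre)", "ZCM(FMpre)", "TAT(FMpre)")}
        assert frac["ZCM(FMpre)"] > frac["PIM(FMpre)"]
        assert frac["TAT(FMpre)"] > frac["PIM(FMpre)"]


class TestRoster:
    def test_thirty_five_methods(self):
        combos = valid_combinations()
        assert len(combos) == 35
        labels = [c.label for c in combos]
        assert len(set(labels)) == 35

    def test_membership(self):
        labels = {c.label for c in valid_combinations()}
        assert "PIM(UFNM)" in labels
        assert "HFEN(HFMpre)" in labels
        assert "AI(UFXYZ)" in labels and "AI(FXYZ)" in labels
        assert "HFEN(FMpre)" not in labels
        assert "AI(ENMO)" not in labels

    def test_families_cover_five_groups(self):
        families = {c.family for c in valid_combinations()}
        assert families == {"unfiltered-magnitude", "filtered-axis",
                            "filtered-axis-magnitude", "filtered-magnitude",
                            "raw-axis"}
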