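import numpy as np
import pytest

from instasub import SessionBundle, UnitRecord, condition_split
from instasub.core_io import OBJECTS, EpochStats
from instasub.preprocess import (
    bin_and_smooth,
    build_time_map,
    preprocess_bundle,
    sqrt_transform,
    align_concatenate,
    load_tensor,
    save_tensor,
    subset_units,
)
from tests.test_core_io import _bundle, _trial


@pytest.fixture()
def flat_bundle(rng):
    """Two units firing at constant Poisson rates through 8 trials."""
    objs = ["sphere", "button", "coax", "perp"] * 2
    trials = [_trial(f"t{i}", o, 1000 + i * 6000) for i, o in enumerate(objs)]
    end = trials[-1].event_times["end"]
    units = []
    for i, rate in enumerate((20.0, 5.0)):
        n = rng.poisson(rate * end / 1000)
        units.append(UnitRecord(f"u{i}", "PMv", np.sort(rng.uniform(0, end, n))))
    return SessionBundle("flat", "execution", units, trials)


def test_time_map_layout():
    events, offsets = build_time_map(1000, 300)
    # I block [-500, 500), G [-1000, 150), M [-150, 200), H [-200, 200)
    assert events.size == 1000 + 1150 + 350 + 400 == 2900
    assert (events[0], offsets[0]) == ("I", -500)
    assert offsets[events == "G"].min() == -1000
    assert offsets[events == "G"].max() == 149
    assert offsets[events == "M"][0] == -150
    assert (events[-1], offsets[-1]) == ("H", 199)


def test_single_spike_smooths_to_unit_mass():
    trials = [_trial("t0", "sphere", 1000)]
    t0 = trials[0].event_times["go"]
    units = [UnitRecord("u0", "PMv", np.array([float(t0)]))]
    for o in ("button", "coax", "perp"):
        trials.append(_trial(f"t_{o}", o, trials[-1].event_times["end"] + 2000))
    bundle = SessionBundle("one", "execution", units, trials)
    sm = bin_and_smooth(bundle, sigma=50)
    r = sm.rates["t0"][0]
    # integral of rate (spikes/s) over time (ms) ~ 1 spike
    assert r.sum() / 1000.0 == pytest.approx(1.0, abs=1e-6)
    peak = np.argmax(r)
    assert abs((sm.t0["t0"] + peak) - t0) <= 1


def test_constant_rate_unit_smooths_flat(flat_bundle):
    sm = bin_and_smooth(flat_bundle)
    mid = flat_bundle.trials[0]
    r = sm.rates[mid.trial_id][0]
    interior = r[1000:-1000]
    assert interior.mean() == pytest.approx(20.0, rel=0.25)


def test_smoothing_is_linear_in_spikes():
    """Two spikes 1 ms apart carry the same smoothed mass as both in one bin."""
    trials = [_trial(f"t{i}", o, 1000 + i * 6000)
              for i, o in enumerate(OBJECTS)]
    t0 = trials[0].event_times["go"]
    a = SessionBundle("a", "execution",
                      [UnitRecord("u", "PMv", np.array([t0 + 0.2, t0 + 1.2]))],
                      trials)
    b = SessionBundle("b", "execution",
                      [UnitRecord("u", "PMv", np.array([t0 + 0.2, t0 + 0.3]))],
                      trials)
    ra = bin_and_smooth(a).rates["t0"].sum()
    rb = bin_and_smooth(b).rates["t0"].sum()
    assert ra == pytest.approx(rb, rel=1e-6)


def test_sigma_must_be_positive(flat_bundle):
    with pytest.raises(ValueError):
        bin_and_smooth(flat_bundle, sigma=0)


def test_sqrt_transform_values_and_errors(flat_bundle):
    sm = bin_and_smooth(flat_bundle)
    tid = flat_bundle.trials[0].trial_id
    sq = sqrt_transform(sm)
    assert np.allclose(sq.rates[tid], np.sqrt(sm.rates[tid]))
    sm.rates[tid][0, 0] = -1.0
    with pytest.raises(ValueError, match="negative"):
        sqrt_transform(sm)
    with pytest.raises(ValueError, match="already"):
        sqrt_transform(sq)


def test_variance_stabilization(rng):
    """Sqrt of Poisson counts has comparable variance at 5 vs 50 spikes/s."""
    low = np.sqrt(rng.poisson(5, 4000))
    high = np.sqrt(rng.poisson(50, 4000))
    ratio = high.var() / low.var()
    assert 0.5 < ratio < 2.0


class TestAlignConcatenate:
    def test_tensor_shape_and_time_map(self, flat_bundle):
        stats = EpochStats(1000.0, 300.0, 400.0)
        sm = bin_and_smooth(flat_bundle)
        tensor = align_concatenate(sm, flat_bundle, stats)
        assert tensor.T == 2900
        assert tensor.events[0] == "I" and tensor.offsets[0] == -500
        for o in OBJECTS:
            assert tensor.tensors[o].shape == (2, 2, 2900)

    def test_deterministic(self, small_session, small_tensors):
        exec_bundle, _, _ = small_session
        te, _ = small_tensors
        again = preprocess_bundle(exec_bundle, te.stats)
        for o in OBJECTS:
            assert np.array_equal(again.tensors[o], te.tensors[o])

    def test_roundtrip_h5(self, tmp_path, small_tensors):
        te, _ = small_tensors
        save_tensor(te, tmp_path / "t.h5")
        back = load_tensor(tmp_path / "t.h5")
        assert back.same_time_base(te)
        for o in OBJECTS:
            assert np.array_equal(back.tensors[o], te.tensors[o])
        assert back.unit_ids == te.unit_ids

    def test_subset_units(self, small_tensors):
        te, _ = small_tensors
        sub = subset_units(te, [0, 3])
        assert sub.n_units == 2
        assert np.array_equal(sub.tensors["coax"], te.tensors["coax"][[0, 3]])


class TestConditionSplit:
    def test_cd_zero_sum_identity(self, small_tensors):
        te, _ = small_tensors
        split = condition_split(te)
        total = sum(split.cd_courses[o] for o in OBJECTS)
        assert np.max(np.abs(total)) < 1e-9

    def test_identical_objects_give_zero_cd(self, small_tensors):
        te, _ = small_tensors
        clone = subset_units(te, range(te.n_units))
        ref = te.tensors["sphere"]
        clone.tensors = {o: ref.copy() for o in OBJECTS}
        split = condition_split(clone)
        for o in OBJECTS:
            assert np.max(np.abs(split.cd_courses[o])) < 1e-12

    def test_ci_is_mean_of_object_averages(self, small_tensors):
        te, _ = small_tensors
        split = condition_split(te)
        manual = np.mean([te.tensors[o].mean(axis=1) for o in OBJECTS], axis=0)
        assert np.allclose(split.ci_course, manual)
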