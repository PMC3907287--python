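import dataclasses

import numpy as np
import pytest

import decayamp as da

# Small, fast ensemble configs used throughout this module.
CHAIN = da.ChainConfig(n_cells=40, n_stim=30, g=0.997, c=0.006, sigma=0.02, dt=0.05)
SCHED = da.TaskSchedule(T=20.0, t_exec=10.0, f1=22.0)


@pytest.fixture(scope="module")
def noisy_ensemble():
    crit = da.EncodingCriterion(reps=6)
    return da.build_encoding_ensemble(CHAIN, SCHED, crit, base_seed=2, record_every=20), crit


@pytest.fixture(scope="module")
def quiet_ensemble():
    # perfect line attractor, no gating within the delay, no noise
    cfg = da.ChainConfig(n_cells=40, n_stim=30, g=1.0, c=0.0, sigma=0.0, dt=0.05)
    sched = da.TaskSchedule(T=10.0, t_exec=10.0, f1=22.0)
    crit = da.EncodingCriterion(reps=2)
    return da.build_encoding_ensemble(cfg, sched, crit, base_seed=0, record_every=20), crit


class TestEncoding:
    def test_noiseless_line_attractor_all_stimulated_encode(self, quiet_ensemble):
        ens, crit = quiet_ensemble
        enc = da.encoding_matrix(ens, crit)
        # deep stimulated cells encode at every sampled time
        assert enc[15:30].all()

    def test_late_cell_before_gate_not_encoding(self, noisy_ensemble):
        ens, crit = noisy_ensemble
        assert not da.is_encoding(ens, 35, 5.0, crit)

    def test_reps_invariance_when_noiseless(self):
        cfg = dataclasses.replace(CHAIN, sigma=0.0)
        mats = []
        for reps in (1, 3):
            crit = da.EncodingCriterion(reps=reps)
            ens = da.build_encoding_ensemble(cfg, SCHED, crit, base_seed=0, record_every=40)
            mats.append(da.encoding_matrix(ens, crit))
        assert np.array_equal(mats[0], mats[1])

    def test_permuted_labels_fraction_near_false_positive_rate(self, noisy_ensemble):
        """Shuffling which stimulus produced which trials destroys encoding:
        the surviving fraction is the criterion's false-positive rate."""
        ens, crit = noisy_ensemble
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(40):
            act = ens.activity.copy()
            for r in range(crit.reps):
                act[:, r] = act[rng.permutation(act.shape[0]), r]
            shuffled = dataclasses.replace(ens, activity=act)
            fracs.append(da.encoding_matrix(shuffled, crit).mean())
        assert np.mean(fracs) < 0.02

    def test_pure_noise_count_near_false_positive_level(self):
        crit = da.EncodingCriterion(reps=4)
        ens = da.build_encoding_ensemble(
            CHAIN, SCHED, crit, base_seed=9, record_every=40, plan=None, stim_map=None
        )
        zero = dataclasses.replace(ens, activity=np.zeros_like(ens.activity))
        # x0 = 0 everywhere: nothing encodes
        noise = np.random.default_rng(1).normal(0, 0.05, ens.activity.shape)
        pure = dataclasses.replace(ens, activity=noise)
        _, counts = da.encoding_count_curve(pure, crit)
        assert counts.mean() < 0.02 * ens.n_cells
        _, zcounts = da.encoding_count_curve(zero, crit)
        assert zcounts.sum() == 0

    def test_mismatched_shapes_rejected(self, noisy_ensemble):
        ens, _ = noisy_ensemble
        other = da.EncodingCriterion(reps=99)
        with pytest.raises(da.InputError):
            da.encoding_matrix(ens, other)


class TestClassification:
    def test_constant_count_for_perfect_line_attractor(self, quiet_ensemble):
        ens, crit = quiet_ensemble
        _, counts = da.encoding_count_curve(ens, crit)
        assert counts.min() == counts.max() == 30

    def test_no_late_cells_without_gating(self, quiet_ensemble):
        ens, crit = quiet_ensemble
        cls = da.classify_cells(ens, crit)
        assert cls.cells("late").size == 0

    def test_degenerate_window_rejected(self, quiet_ensemble):
        ens, crit = quiet_ensemble
        with pytest.raises(da.ConfigurationError):
            da.classify_cells(ens, crit, early_window=(0.5, 0.5))

    def test_labels_exhaustive_exclusive(self, noisy_ensemble):
        ens, crit = noisy_ensemble
        cls = da.classify_cells(ens, crit)
        assert cls.labels.size == ens.n_cells
        assert set(cls.labels) <= {"early", "persistent", "late", "unresponsive"}


@pytest.fixture(scope="module")
def pulse():
    cfg = da.ChainConfig(n_cells=80, n_stim=40, g=1.0, c=0.0, sigma=0.0, dt=0.05)
    sched = da.TaskSchedule(T=30.0, t_exec=0.0, f1=22.0)  # no gating
    return da.simulate_chain(cfg, sched, x0=1.0, record_every=4)


class TestFronts:
    def test_leading_and_trailing_speeds_equal(self, pulse):
        lead = da.track_front(pulse, mode="leading", fit_cells=np.arange(45, 65))
        trail = da.track_front(pulse, mode="trailing", fit_cells=np.arange(5, 25))
        assert lead.speed == pytest.approx(trail.speed, rel=0.1)
        assert lead.speed == pytest.approx(1.0, rel=0.2)

    def test_never_crossing_cell_is_nan(self, pulse):
        lead = da.track_front(pulse, mode="leading")
        assert np.isnan(lead.crossing_times[-1])  # front never reaches the end

    def test_no_late_crossings_before_gate(self):
        res = da.simulate_chain(CHAIN, SCHED, x0=1.0, record_every=4)
        lead = da.track_front(res, mode="leading")
        late = lead.crossing_times[30:]
        assert np.all(np.isnan(late) | (late >= SCHED.t_exec))

    def test_frozen_trailing_front_with_feedback(self):
        cfg = da.ChainConfig(n_cells=130, n_stim=100, g=0.997, c=0.02, sigma=0.02, dt=0.05)
        sched = da.TaskSchedule(T=50.0, t_exec=15.0, f1=34.0)
        res = da.simulate_chain(cfg, sched, seed=7, x0=1.2, record_every=4)
        pos = da.front_position(res, which="trailing", cells=slice(0, 100))
        i1 = np.argmin(np.abs(res.times - 20.0))
        speed = (pos[-1] - pos[i1]) / (res.times[-1] - res.times[i1])
        assert abs(speed) < 0.25  # vs 1.0 for the free pulse

    def test_bad_level_rejected(self, pulse):
        with pytest.raises(da.DomainError):
            da.track_front(pulse, level=1.5)


class TestReadout:
    def _run(self, f1, f2, g=0.997, c=0.006):
        sm = da.StimulusMap()
        cfg = da.ChainConfig(n_cells=150, n_stim=100, g=g, c=c, sigma=0.0, dt=0.05)
        sched = da.TaskSchedule(T=50.0, t_exec=25.0, t_cmp_len=3.0, f1=f1, f2=f2)
        plan = da.GainPlan(comparison=da.comparison_spec(sm.load_level(f2), g))
        return (
            da.simulate_chain(cfg, sched, plan, stim_map=sm, record_every=5),
            sched,
        )

    def test_f1_above_separatrix_reports_higher(self):
        res, sched = self._run(f1=28.0, f2=16.0)
        assert da.readout_decision(res, sched) == "f1_higher"

    def test_f1_below_separatrix_reports_lower(self):
        res, sched = self._run(f1=16.0, f2=28.0)
        assert da.readout_decision(res, sched) == "f1_lower"

    def test_exactly_at_separatrix_undecided(self):
        # perfect line attractor holds x0 exactly (short delay keeps the
        # trailing front's Poisson tail below double precision); the
        # separatrix placed at x0 leaves the readout balanced.
        sm = da.StimulusMap()
        cfg = da.ChainConfig(n_cells=150, n_stim=100, g=1.0, c=0.0, sigma=0.0, dt=0.05)
        sched = da.TaskSchedule(T=20.0, t_exec=10.0, t_cmp_len=3.0, f1=22.0, f2=22.0)
        plan = da.GainPlan(comparison=da.comparison_spec(sm.load_level(22.0), 1.0))
        res = da.simulate_chain(cfg, sched, plan, stim_map=sm, record_every=5)
        assert da.readout_decision(res, sched) == "undecided"

    def test_missing_comparison_window_rejected(self):
        res = da.simulate_chain(CHAIN, SCHED, x0=1.0, record_every=10)
        with pytest.raises(da.InputError):
            da.readout_decision(res, SCHED)

    def test_success_band_and_trial_success(self):
        band = da.success_band(0.8, 0.1)
        assert band == pytest.approx((0.72, 0.88))
        res, sched = self._run(f1=22.0, f2=16.0)
        assert da.trial_success(res, band)

    def test_unbounded_band_always_succeeds(self):
        res, _ = self._run(f1=10.0, f2=34.0)
        assert da.trial_success(res, (-np.inf, np.inf))

    def test_ts_outside_interval_fails_band(self):
        sm = da.StimulusMap()
        x0 = sm.load_level(22.0)
        cfg = da.ChainConfig(n_cells=150, n_stim=100, g=0.994, c=0.012, sigma=0.0, dt=0.05)
        iv = da.timing_interval(
            da.RateParams(g=cfg.g, c=cfg.c, eps=0.1, T=50.0, x0=x0)
        )
        good = da.simulate_chain(
            cfg, da.TaskSchedule(T=50.0, t_exec=iv.center, f1=22.0), x0=x0,
            record_every=10,
        )
        bad = da.simulate_chain(
            cfg, da.TaskSchedule(T=50.0, t_exec=min(iv.hi + 3.0, 50.0), f1=22.0),
            x0=x0, record_every=10,
        )
        band = da.success_band(x0, 0.1)
        assert da.trial_success(good, band)
        assert not da.trial_success(bad, band)
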