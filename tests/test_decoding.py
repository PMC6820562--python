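import numpy as np
import pytest

from delaycode.decoding import (
    build_pseudopopulation,
    decode_sweep,
    diag_lda_loocv,
    select_decoding_units,
    sweep_windows,
)
from delaycode.synthetic import NeuronSpec, SimConfig, generate_session

import oracles


def selective_specs(n, gain=2.5, baseline=2.0):
    """Units with strong sample selectivity, alternating preferred side."""
    return [
        NeuronSpec(unit_id=f"d{i:03d}", code_type="persistent", baseline_rate=baseline,
                   peak_gain=1.0, preferred_sample="L" if i % 2 == 0 else "R",
                   selectivity_gain=gain)
        for i in range(n)
    ]


def nonselective_specs(n, lo=0.8, hi=8.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        NeuronSpec(unit_id=f"n{i:03d}", code_type="untuned",
                   baseline_rate=float(rng.uniform(lo, hi)))
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def selective_session():
    cfg = SimConfig(n_trials_per_condition=83, p_correct=0.85, seed=41)
    units, trials, specs = generate_session(cfg, specs=selective_specs(24))
    return units, trials, specs


class TestDiagLdaLoocv:
    def test_fully_separable_is_100pct(self, rng):
        X = np.vstack([np.r_[np.full(15, 1.0), np.full(15, 9.0)]])
        X = X + rng.normal(0, 0.01, X.shape)
        labels = ["L"] * 15 + ["R"] * 15
        assert diag_lda_loocv(X, labels) == 100.0

    def test_permutation_null_is_chance(self):
        """Label-shuffled features decode at ~50%."""
        rng = np.random.default_rng(7)
        accs = []
        for _ in range(60):
            X = rng.normal(3.0, 1.0, (8, 30))
            labels = np.array(["L"] * 15 + ["R"] * 15)
            rng.shuffle(labels)
            accs.append(diag_lda_loocv(X, labels))
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < 3 * sem

    def test_matches_gaussian_posterior_oracle(self):
        """Fold-by-fold agreement with an explicit posterior computation on
        small random instances."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_units = rng.integers(1, 4)
            n_per = rng.integers(3, 6)
            X = rng.normal(2.0, 1.0, (n_units, 2 * n_per))
            X[:, n_per:] += rng.normal(0.5, 0.5)
            labels = ["L"] * n_per + ["R"] * n_per
            assert diag_lda_loocv(X, labels) == oracles.gaussian_posterior_loocv(X, labels)

    def test_zero_variance_unit_floored_not_fatal(self):
        X = np.vstack(
            [np.r_[np.full(15, 2.0), np.full(15, 2.0)],   # constant unit
             np.r_[np.full(15, 1.0), np.full(15, 5.0)]]
        )
        assert diag_lda_loocv(X, ["L"] * 15 + ["R"] * 15) == 100.0

    def test_accuracy_bounded(self, rng):
        X = rng.normal(0, 1, (5, 30))
        acc = diag_lda_loocv(X, ["L"] * 15 + ["R"] * 15)
        assert 0.0 <= acc <= 100.0


class TestSelection:
    def test_too_few_class_trials_excludes_all(self):
        cfg = SimConfig(n_trials_per_condition=20, p_correct=1.0, seed=2)
        units, trials, specs = generate_session(cfg, specs=selective_specs(3))
        # random condition: ~10 delay>=4 trials, under 15 per class
        out = select_decoding_units(units, trials, "random", "full_4s_ensemble_curve")
        assert out == []

    def test_rate_criterion_excludes_silent_units(self):
        specs = selective_specs(2) + [
            NeuronSpec(unit_id="quiet", code_type="untuned", baseline_rate=0.05)
        ]
        cfg = SimConfig(n_trials_per_condition=83, p_correct=1.0, seed=5)
        units, trials, _ = generate_session(cfg, specs=specs)
        out = select_decoding_units(units, trials, "fixed", "full_4s_ensemble_curve")
        assert {e.unit_id for e in out} == {"d000", "d001"}

    def test_sliding_zero_spike_rule(self):
        # a unit silent outside the late delay has >= 15 zero-spike trials
        # in the earliest sliding windows -> ineligible for sliding analyses
        specs = [
            NeuronSpec(unit_id="late", code_type="sequential", baseline_rate=0.0001,
                       peak_gain=60000.0, tuning_center=3.5, tuning_width=0.15),
            NeuronSpec(unit_id="tonic", code_type="untuned", baseline_rate=4.0),
        ]
        cfg = SimConfig(n_trials_per_condition=83, p_correct=1.0, seed=6)
        units, trials, _ = generate_session(cfg, specs=specs)
        sliding = select_decoding_units(units, trials, "fixed", "sliding_2s_step0.1_onset")
        full = select_decoding_units(units, trials, "fixed", "full_4s_ensemble_curve")
        assert "late" not in {e.unit_id for e in sliding}
        assert "late" in {e.unit_id for e in full}
        assert "tonic" in {e.unit_id for e in sliding}


class TestMultiSession:
    def test_eligibility_uses_each_units_own_session(self):
        """Pooling sessions: a unit from a session with too few correct
        trials per class is ineligible even when other sessions have
        plenty."""
        from delaycode.synthetic import merge_sessions

        big = SimConfig(n_trials_per_condition=83, p_correct=1.0, seed=3,
                        session_id="big")
        small = SimConfig(n_trials_per_condition=20, p_correct=1.0, seed=4,
                          session_id="small")
        units_a, trials_a, _ = generate_session(
            big, specs=[NeuronSpec(unit_id="a0", code_type="untuned", baseline_rate=3.0)]
        )
        units_b, trials_b, _ = generate_session(
            small, specs=[NeuronSpec(unit_id="b0", code_type="untuned", baseline_rate=3.0)]
        )
        units, trials = merge_sessions([(units_a, trials_a), (units_b, trials_b)])
        out = select_decoding_units(units, trials, "fixed", "full_4s_ensemble_curve")
        assert {e.unit_id for e in out} == {"a0"}
        # pools reference reindexed trials of the unit's own session
        own = set(trials[trials["session_id"] == "big"]["trial_id"])
        assert set(out[0].trials_L) <= own and set(out[0].trials_R) <= own

    def test_merge_rejects_duplicate_ids(self):
        from delaycode.synthetic import merge_sessions

        cfg = SimConfig(n_trials_per_condition=5, seed=1, session_id="s")
        units, trials, _ = generate_session(
            cfg, specs=[NeuronSpec(unit_id="u", code_type="untuned", baseline_rate=1.0)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            merge_sessions([(units, trials), (units, trials)])


class TestPseudoPopulation:
    def test_shape_and_determinism(self, selective_session):
        units, trials, specs = selective_session
        windows = sweep_windows("nonoverlap_2s")
        eligible = select_decoding_units(units, trials, "fixed", "nonoverlap_2s")[:3]
        a = build_pseudopopulation(units, trials, eligible, windows, seed=5)
        b = build_pseudopopulation(units, trials, eligible, windows, seed=5)
        assert a.features.shape == (3, 30, 2)
        np.testing.assert_array_equal(a.features, b.features)
        assert (a.labels[:15] == "L").all() and (a.labels[15:] == "R").all()

    def test_insufficient_trials_names_unit(self, selective_session):
        units, trials, _ = selective_session
        windows = sweep_windows("full_4s_ensemble_curve")
        eligible = select_decoding_units(units, trials, "fixed", "full_4s_ensemble_curve")[:1]
        eligible[0].trials_L = eligible[0].trials_L[:4]
        with pytest.raises(ValueError, match=eligible[0].unit_id):
            build_pseudopopulation(units, trials, eligible, windows, seed=0)


class TestDecodeSweep:
    def test_determinism_under_fixed_seed(self, selective_session):
        units, trials, _ = selective_session
        kw = dict(n_repeats=2, ensemble_size=6, seed=33)
        r1 = decode_sweep(units, trials, "fixed", "nonoverlap_2s", **kw)
        r2 = decode_sweep(units, trials, "fixed", "nonoverlap_2s", **kw)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_ensemble_size_exceeds_pool_errors(self, selective_session):
        units, trials, _ = selective_session
        with pytest.raises(ValueError, match="exceeds"):
            decode_sweep(units, trials, "fixed", "full_4s_ensemble_curve",
                         n_repeats=1, ensemble_size=500, seed=0)

    def test_onset_offset_agree_on_fixed_delay(self, selective_session):
        """With a constant 4-s delay, offset-aligned windows are the same
        time intervals as onset-aligned ones; identical seeds must give
        identical accuracies for corresponding windows."""
        units, trials, _ = selective_session
        kw = dict(n_repeats=2, ensemble_size=6, seed=9)
        onset = decode_sweep(units, trials, "fixed", "sliding_2s_step0.1_onset", **kw)
        offset = decode_sweep(units, trials, "fixed", "sliding_2s_step0.1_offset", **kw)
        on_by_start = {round(r.window.start, 3): r for r in onset}
        for r in offset:
            # offset window [s, s+2) from delay end == onset [s+4, s+6)
            mate = on_by_start.get(round(r.window.start + 4.0, 3))
            if mate is not None:
                np.testing.assert_allclose(r.accuracies, mate.accuracies)

    def test_accuracy_monotone_in_ensemble_size_and_saturates(self):
        """Fig-7b-shaped recovery: more selective neurons, better decoding;
        full separability saturates at 100%."""
        cfg = SimConfig(n_trials_per_condition=83, p_correct=0.85, seed=43)
        units, trials, _ = generate_session(
            cfg, specs=selective_specs(95, gain=1.12, baseline=1.2)
        )
        sizes = (10, 30, 60, 90)
        results = decode_sweep(
            units, trials, "fixed", "full_4s_ensemble_curve",
            n_repeats=20, seed=3, ensemble_sizes=sizes,
        )
        accs = [r.mean_accuracy for r in results]
        assert all(b >= a - 1e-9 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]
        # huge-gain population: ceiling behavior
        units2, trials2, _ = generate_session(
            cfg, specs=selective_specs(20, gain=8.0, baseline=2.0)
        )
        sat = decode_sweep(units2, trials2, "fixed", "full_4s_ensemble_curve",
                           n_repeats=5, ensemble_size=15, seed=1)
        assert sat[0].mean_accuracy == 100.0

    def test_prestim_nonselective_at_chance(self):
        """Pre-stimulus control: no sample information before the cue."""
        cfg = SimConfig(n_trials_per_condition=83, p_correct=0.85, seed=47)
        units, trials, _ = generate_session(cfg, specs=nonselective_specs(40, seed=8))
        results = decode_sweep(units, trials, "fixed", "prestim_1s",
                               n_repeats=30, ensemble_size=30, seed=12)
        r = results[0]
        assert abs(r.mean_accuracy - 50.0) < 3 * max(r.sem, 1e-9)

    def test_random_condition_advantage_direction(self):
        """Populations given sharper tuning and stronger selectivity in the
        random condition decode better there than in the fixed condition."""
        rng = np.random.default_rng(55)
        specs = [
            NeuronSpec(unit_id=f"m{i:03d}", code_type="persistent", baseline_rate=1.5,
                       peak_gain=1.0, preferred_sample="L" if i % 2 else "R",
                       selectivity_gain=1.08,
                       condition_gain=2.5)  # stronger modulation when random
            for i in range(40)
        ]
        cfg = SimConfig(n_trials_per_condition=160, p_correct=0.9, seed=51)
        units, trials, _ = generate_session(cfg, specs=specs)
        kw = dict(n_repeats=15, ensemble_size=20, seed=2)
        fixed = decode_sweep(units, trials, "fixed", "full_4s_ensemble_curve", **kw)
        random_ = decode_sweep(units, trials, "random", "full_4s_ensemble_curve", **kw)
        assert random_[0].mean_accuracy > fixed[0].mean_accuracy
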