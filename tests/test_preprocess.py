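"""Exclusion rules: angular error wrap, outcome drops, MADM oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cuewheel as cw
from cuewheel.preprocess import (
    MADMOutlierFilter,
    cells_for,
    drop_invalid,
    madm_filter,
    to_clean,
)
from cuewheel._angles import angular_error


class TestAngularError:
    @pytest.mark.parametrize(
        "target,resp,expected",
        [(350.0, 10.0, 20.0), (123.4, 123.4, 0.0), (0.0, 180.0, 180.0), (10.0, 350.0, -20.0)],
    )
    def test_examples(self, target, resp, expected):
        assert angular_error(target, resp) == pytest.approx(expected)

    @given(
        t=st.floats(0, 359.999), r=st.floats(0, 359.999), shift=st.floats(-720, 720)
    )
    @settings(max_examples=200, deadline=None)
    def test_rotation_invariance_and_range(self, t, r, shift):
        e = angular_error(t, r)
        assert -180.0 < e <= 180.0
        e2 = angular_error((t + shift) % 360, (r + shift) % 360)
        # identical up to circular equivalence
        assert abs(angular_error(0.0, e2 - e)) < 1e-6


class TestDropInvalid:
    def test_toy_counts(self, toy_trials):
        kept, rep = drop_invalid(toy_trials)
        assert len(kept) == 5
        assert rep.n_practice_dropped == 2
        assert rep.n_miss == 1
        assert rep.n_false_alarm == 1
        assert rep.n_pre_target == 1

    def test_all_hit_identity(self, toy_trials):
        hits = toy_trials[(toy_trials.outcome == "hit") & (toy_trials.block > 0)].copy()
        kept, rep = drop_invalid(hits)
        assert len(kept) == len(hits)
        assert rep.n_miss == rep.n_false_alarm == rep.n_pre_target == 0

    def test_missing_outcome_rejected(self, toy_trials):
        bad = toy_trials.copy()
        bad.loc[5, "outcome"] = pd.NA
        with pytest.raises(ValueError, match="outcome"):
            drop_invalid(bad)

    def test_simulated_fractions_near_rates(self):
        ds = cw.simulate_experiment(30, "E1", seed=3, n_blocks=2)
        _, rep = drop_invalid(ds.trials)
        for frac, rate, n in [
            (rep.miss_fraction, 0.0032, rep.n_target_trials),
            (rep.false_alarm_fraction, 0.0302, rep.n_catch_trials),
            (rep.pre_target_fraction, 0.0122, rep.n_target_trials),
        ]:
            sd = np.sqrt(rate * (1 - rate) / n)
            assert abs(frac - rate) < 4 * sd


def brute_force_madm_drops(log_rts: np.ndarray, multiplier: float) -> set:
    """Independent double-loop oracle for one cell."""
    m = float(np.median(log_rts))
    devs = sorted(abs(x - m) for x in log_rts)
    k = len(devs)
    madm = (devs[k // 2] if k % 2 == 1 else 0.5 * (devs[k // 2 - 1] + devs[k // 2]))
    return {i for i, x in enumerate(log_rts) if abs(x - m) > multiplier * madm}


def _frame_from_logrt(log_rts, subject="S0", cue="valid"):
    return pd.DataFrame(
        {"subject_id": subject, "cue_type": cue, "rt_ms": np.exp(log_rts)}
    )


class TestMADMFilter:
    def test_listed_six_value_cell(self):
        vals = np.array([5.8, 5.9, 6.0, 6.1, 6.2, 9.0])
        df = _frame_from_logrt(vals)
        kept, rep = madm_filter(df, ["subject_id", "cue_type"], 5.0)
        assert rep.n_madm_outliers == 1
        assert 9.0 not in np.log(kept.rt_ms.to_numpy())
        assert brute_force_madm_drops(vals, 5.0) == {5}

    def test_degenerate_identical_rts_drop_nothing(self):
        df = _frame_from_logrt(np.full(8, 5.9))
        kept, rep = madm_filter(df, ["subject_id", "cue_type"], 5.0)
        assert rep.n_madm_outliers == 0
        assert len(kept) == 8

    def test_infinite_multiplier_is_identity(self):
        df = _frame_from_logrt(np.array([5.0, 5.5, 9.0, 2.0]))
        kept, _ = madm_filter(df, ["subject_id", "cue_type"], np.inf)
        assert len(kept) == 4

    def test_oracle_equivalence_200_random_cells(self, rng):
        """Set of dropped rows equals the brute-force oracle per cell."""
        for trial in range(200):
            n = int(rng.integers(1, 25))
            vals = rng.normal(6.0, 0.5, n) + rng.choice([0, 3]) * rng.random(n)
            df = _frame_from_logrt(vals)
            kept, rep = madm_filter(df, ["subject_id", "cue_type"], 5.0)
            expected = brute_force_madm_drops(vals, 5.0)
            assert set(df.index) - set(kept.index) == expected

    def test_order_invariance(self, rng):
        vals = rng.normal(6, 0.4, 40)
        vals[::9] += 5
        df = pd.concat(
            [_frame_from_logrt(vals[:20], cue="valid"), _frame_from_logrt(vals[20:], cue="invalid")],
            ignore_index=True,
        )
        kept1, _ = madm_filter(df, ["subject_id", "cue_type"], 5.0)
        shuffled = df.sample(frac=1.0, random_state=1)
        kept2, _ = madm_filter(shuffled, ["subject_id", "cue_type"], 5.0)
        assert set(kept1.rt_ms.round(9)) == set(kept2.rt_ms.round(9))

    def test_transformer_interface(self):
        df = _frame_from_logrt(np.array([5.8, 5.9, 6.0, 6.1, 6.2, 9.0]))
        filt = MADMOutlierFilter(cell_keys=("subject_id", "cue_type"), multiplier=5.0)
        kept = filt.fit_transform(df)
        assert len(kept) == 5
        assert filt.report_.n_madm_outliers == 1
        assert filt.get_params()["multiplier"] == 5.0

    def test_invalid_multiplier(self):
        with pytest.raises(ValueError):
            madm_filter(_frame_from_logrt(np.array([5.0, 6.0])), ["subject_id"], 0.0)


class TestToClean:
    def test_direct_mapping(self):
        row = pd.DataFrame(
            [
                dict(
                    subject_id="S0", experiment="E1", block=1, cue_type="valid",
                    soa_ms=800, target_colour_deg=10.0, response_colour_deg=355.0,
                    rt_ms=350.0,
                )
            ]
        )
        out = to_clean(row, "E1")
        assert out.loc[0, "cell"] == "valid"
        assert out.loc[0, "log_rt"] == pytest.approx(np.log(350.0))
        assert out.loc[0, "error_deg"] == pytest.approx(-15.0)

    def test_e2_composite_cells(self):
        ds = cw.simulate_experiment(2, "E2", seed=9, n_blocks=1)
        clean, _ = cw.clean_pipeline(ds.trials)
        assert set(clean.cell) <= {
            f"{c}@{s}" for c in ("valid", "invalid", "neutral") for s in (100, 800)
        }

    def test_empty_input(self):
        out = to_clean(pd.DataFrame(columns=cw.design.TRIAL_COLUMNS))
        assert len(out) == 0

    def test_cells_for(self):
        assert cells_for("E1") == ["subject_id", "cue_type"]
        assert cells_for("E2") == ["subject_id", "soa_ms", "cue_type"]
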