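"""25-parameter profiles: formulas, gating, exclusions, group summaries."""

import numpy as np
import pandas as pd
import pytest

from zlap import behavior_profile as bp
from zlap.errors import InputError, SchemaError
from zlap.pose_io import default_schedule
from zlap.synthetic_data import PHENOTYPES, PhenotypeParams, simulate_screen
from zlap import pipeline


def make_rows(n_frames=1800, **overrides):
    """Feature rows with constant per-frame flags, overridable per column.

    Overrides may be scalars or (period -> value) dicts.
    """
    frames = np.arange(n_frames)
    period = frames // 100 + 1
    df = pd.DataFrame({"frame": frames, "period": period})
    defaults = {"valid": 1.0, "moved": 0.0, "scoot": 0.0, "burst": 0.0, "up": 0.0,
                "edge": 0.0, "clockwise": 0.0, "upward": 0.0, "turn": 0.0,
                "turn_abs": 0.0}
    for col, default in defaults.items():
        spec = overrides.get(col, default)
        if isinstance(spec, dict):
            values = np.full(n_frames, float(spec.get(None, default)))
            for p, v in spec.items():
                if p is not None:
                    values[period == p] = v
            df[col] = values
        else:
            df[col] = spec
    return df


def per_frame_bernoulli(period_rates, n_frames=1800, seed=0):
    """moved column with an exact fraction of 1s per period (deterministic)."""
    frames = np.arange(n_frames)
    period = frames // 100 + 1
    moved = np.zeros(n_frames)
    for p, rate in period_rates.items():
        idx = np.flatnonzero(period == p)
        moved[idx[: int(round(rate * len(idx)))]] = 1.0
    return moved


class TestPercentMeasure:
    def test_arithmetic(self):
        rows = make_rows()
        rows["moved"] = per_frame_bernoulli({p: 0.10 for p in range(1, 7)})
        assert bp.percent_measure(rows, "moved", range(1, 7)) == pytest.approx(10.0)

    def test_no_valid_frames_is_null(self):
        rows = make_rows(valid=0.0)
        rows.loc[:, "moved"] = np.nan
        assert np.isnan(bp.percent_measure(rows, "moved", range(1, 7)))

    def test_unknown_flag_rejected(self):
        with pytest.raises(SchemaError):
            bp.percent_measure(make_rows(), "wiggle", range(1, 7))

    def test_reordering_within_periods_invariant(self, rng):
        rows = make_rows(moved=per_frame_bernoulli({p: 0.2 for p in range(1, 19)}))
        shuffled = rows.sample(frac=1, random_state=7).sort_values(
            "period", kind="stable")
        a = bp.percent_measure(rows, "moved", range(1, 7))
        b = bp.percent_measure(shuffled, "moved", range(1, 7))
        assert a == pytest.approx(b)


class TestOmrMeasures:
    def test_pair_difference(self):
        rows = make_rows(moved=per_frame_bernoulli({p: 0.5 for p in range(1, 19)}))
        up = np.zeros(len(rows))
        period = rows["period"].to_numpy()
        for p, frac in {7: 0.40, 8: 0.60, 9: 0.5, 10: 0.5, 11: 0.5, 12: 0.5,
                        13: 0.5, 14: 0.5}.items():
            idx = np.flatnonzero(period == p)
            up[idx[: int(frac * len(idx))]] = 1.0
        rows["up"] = up
        out = bp.omr_measures(rows)
        assert out["R"] == pytest.approx(20.0)
        assert out["G"] == pytest.approx(0.0)

    def test_low_movement_gates_pair_to_null(self):
        moved = per_frame_bernoulli({p: 0.5 for p in range(1, 19)})
        moved[600:700] = per_frame_bernoulli({7: 0.04})[600:700]  # P7 at 4 %
        rows = make_rows(moved=moved, up=0.5)
        out = bp.omr_measures(rows)
        assert np.isnan(out["R"])
        assert not np.isnan(out["G"])

    def test_combined_is_mean_of_pairs(self):
        period_up = {7: 0.2, 8: 0.4, 9: 0.3, 10: 0.4, 11: 0.5, 12: 0.6, 13: 0.5, 14: 0.5}
        up = np.zeros(1800)
        period = np.arange(1800) // 100 + 1
        for p, frac in period_up.items():
            idx = np.flatnonzero(period == p)
            up[idx[: int(round(frac * len(idx)))]] = 1.0
        rows = make_rows(moved=per_frame_bernoulli({p: 0.5 for p in range(1, 19)}), up=up)
        out = bp.omr_measures(rows)
        # pair diffs: 20, 10, 10, 0 -> mean 10
        assert out["RGB"] == pytest.approx(np.mean([20.0, 10.0, 10.0, 0.0]))

    def test_all_pairs_null_gives_null_combined(self):
        rows = make_rows(moved=0.0, up=0.5)  # never moves: every pair gated
        out = bp.orientation_measures(rows)
        assert np.isnan(out["Or-RGB"])


class TestStimulusResponse:
    def test_startle_excitability_habituation_formulas(self):
        moved = per_frame_bernoulli({15: 0.30, 16: 0.50, 17: 0.70})
        # P17: first 50 frames at 60 %, last 50 at 40 %
        idx17 = np.flatnonzero(np.arange(1800) // 100 + 1 == 17)
        moved[idx17] = 0.0
        moved[idx17[:30]] = 1.0            # 60 % of first half
        moved[idx17[50:50 + 20]] = 1.0     # 40 % of second half
        rows = make_rows(moved=moved)
        out = bp.stimulus_response_measures(rows)
        assert out["St"] == pytest.approx(50.0 - 30.0)
        assert out["Ex"] == pytest.approx(50.0 - 50.0)  # P17 overall 50 %
        assert out["Hab"] == pytest.approx(60.0 - 40.0)  # decrease = positive


class TestLarvaProfile:
    def test_low_movement_larva_excluded(self):
        rows = make_rows(moved=per_frame_bernoulli({p: 0.005 for p in range(1, 19)}))
        profile = bp.larva_profile(rows)
        assert profile["excluded"]
        assert np.isnan(profile["1h"])

    def test_control_larva_full_profile(self, control_features):
        profile = bp.larva_profile(control_features)
        assert not profile["excluded"]
        assert profile[bp.PARAMETERS].notna().all()
        assert 0 <= profile["1h"] <= 100
        assert -100 <= profile["R"] <= 100

    def test_scoot_plus_burst_equals_activity(self, control_features):
        """Scoot and burst partition moved frames: Sc-1h + Bu-1h == 1h exactly."""
        profile = bp.larva_profile(control_features)
        assert profile["Sc-1h"] + profile["Bu-1h"] == pytest.approx(profile["1h"])
        assert profile["Sc-V"] + profile["Bu-V"] == pytest.approx(
            bp.percent_measure(control_features, "moved", range(7, 15)))

    def test_symmetric_turning_centers_on_zero(self, schedule, well):
        from zlap.kinematics import build_feature_table
        from zlap.synthetic_data import simulate_trajectory

        params = PhenotypeParams(turn_bias=0.0)
        turns = []
        for seed in range(6):
            sw = simulate_trajectory(params, schedule, 1800, seed=seed, well=well)
            table = build_feature_table({well.well_id: sw.pose}, [well], schedule)
            p = bp.larva_profile(table)
            turns.append(p["Turn-1h"])
            assert p["Tabs-1h"] > 0
        assert abs(np.mean(turns)) < 3 * np.std(turns, ddof=1) / np.sqrt(len(turns)) + 2.0

    def test_short_stream_rejected(self):
        with pytest.raises(InputError):
            bp.larva_profile(make_rows(n_frames=500))


class TestGroupSummary:
    @staticmethod
    def profiles_frame(values, excluded=None):
        n = len(values)
        df = pd.DataFrame({p: values for p in bp.PARAMETERS})
        df.insert(0, "excluded", excluded if excluded is not None else [False] * n)
        df.insert(0, "well_id", [f"A{i+1}" for i in range(n)])
        df.insert(0, "plate_id", "P1")
        return df

    @staticmethod
    def tmap(n, treatment="drug"):
        return pd.DataFrame({"plate_id": "P1", "well_id": [f"A{i+1}" for i in range(n)],
                             "treatment": treatment, "concentration_uM": 10.0})

    def test_mean_and_n(self):
        summary = bp.group_summary(self.profiles_frame([10.0, 20.0]), self.tmap(2))
        row = summary[(summary.treatment == "drug") & (summary.parameter == "1h")].iloc[0]
        assert row["mean"] == 15.0 and row["n"] == 2

    def test_fully_excluded_group(self):
        summary = bp.group_summary(
            self.profiles_frame([np.nan, np.nan], excluded=[True, True]), self.tmap(2))
        row = summary[(summary.treatment == "drug") & (summary.parameter == "1h")].iloc[0]
        assert row["n"] == 0 and np.isnan(row["mean"])

    def test_unmapped_well_rejected(self):
        with pytest.raises(InputError):
            bp.group_summary(self.profiles_frame([1.0, 2.0]), self.tmap(1))

    def test_simulated_group_mean_near_generator_expectation(self, schedule):
        """Mean baseline activity of a 48-larva group within 3 SEM of 100*p_move."""
        params = PhenotypeParams(p_move=0.2, startle_gain=0.0, excitability_gain=0.0,
                                 likelihood_noise=0.0)
        from zlap.kinematics import compute_feature_arrays
        from zlap.synthetic_data import _emit_pose, _simulate_batch, _default_well

        rng = np.random.default_rng(5)
        wells = [_default_well(i) for i in range(48)]
        truth = _simulate_batch([params] * 48, schedule, 1800, rng)
        pose = _emit_pose(truth, [params] * 48, wells, rng)
        feats = compute_feature_arrays(pose, wells)
        profiles = bp.profiles_from_arrays(feats, schedule)
        vals = profiles["1h"].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 20.0) <= 3 * sem


class TestPhenotypeRecovery:
    def test_csa_contrasts_sign_consistent_across_seeds(self):
        """CsA-like larvae vs controls: higher 1h and Ex, lower Or-RGB and Hab.

        Direction must hold for the group means in (nearly) every seed; a
        sign test across 20 seeds is significant well below p = 0.01 when at
        least 16 agree.
        """
        wins = np.zeros(4, dtype=int)
        n_seeds = 20
        for seed in range(n_seeds):
            screen = simulate_screen(n_compounds=0, n_larvae_per_group=48,
                                     n_control_larvae=48, seed=seed,
                                     include_rescues=False)
            profiles = pipeline.screen_profiles(screen)
            merged = profiles.merge(screen.treatment_map, on=["plate_id", "well_id"])
            means = merged.groupby("treatment")[["1h", "Ex", "Or-RGB", "Hab"]].mean()
            csa, ctrl = means.loc["CsA"], means.loc["DMSO"]
            wins += [csa["1h"] > ctrl["1h"], csa["Ex"] > ctrl["Ex"],
                     csa["Or-RGB"] < ctrl["Or-RGB"], csa["Hab"] < ctrl["Hab"]]
        from scipy.stats import binomtest

        for w in wins:
            assert binomtest(int(w), n_seeds, 0.5, alternative="greater").pvalue < 0.01
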