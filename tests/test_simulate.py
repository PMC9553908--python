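"""Synthetic-data generator: design arithmetic, determinism, generative
moments, missingness injection, and serialization."""

import numpy as np
import pandas as pd
import pytest

import behavar as bv
from behavar.simulate import ConfigError


def tiny_config(seed=0, **kw):
    base = dict(
        traits=("exploration",),
        groups={
            "A": bv.GroupConfig(
                n_individuals=10, n_populations=1,
                mean={"exploration": 10.0},
                v_among={"exploration": 0.4},
                v_within={"exploration": 0.6},
            ),
            "B": bv.GroupConfig(
                n_individuals=10, n_populations=1,
                mean={"exploration": 12.0},
                v_among={"exploration": 0.4},
                v_within={"exploration": 0.6},
            ),
        },
        n_trials=2,
        rng_seed=seed,
    )
    base.update(kw)
    return bv.SimConfig(**base)


class TestSimulateDataset:
    def test_record_count_forced_by_design(self):
        ds = bv.simulate_dataset(tiny_config())
        # 2 groups x 1 population x 10 individuals x 1 trait x 2 trials
        assert len(ds.frame) == 40

    def test_default_regional_design(self):
        cfg = bv.default_regional_config()
        ds = bv.simulate_dataset(cfg)
        summary = ds.design_summary()
        assert summary["n_individuals"] == 520
        assert summary["n_populations"] == 14
        sizes = ds.frame.groupby("region")["individual"].nunique()
        assert sizes.to_dict() == {"AUS": 167, "HAW": 118, "LHI": 92, "NZ": 143}
        assert cfg.n_trials == 2
        assert ds.frame.groupby(["individual", "trait"]).size().eq(2).all()

    def test_default_within_region_design(self):
        cfg = bv.default_within_region_config()
        assert {lab: g.n_individuals for lab, g in cfg.groups.items()} == {
            "Tenterfield": 30, "Auckland": 31, "Hamilton": 43,
            "Whangarei": 33, "Edgecumbe": 36,
        }
        assert all(g.n_populations == 1 for g in cfg.groups.values())
        assert cfg.v_pop_for("activity") == 0.0
        ds = bv.simulate_dataset(cfg)
        assert ds.design_summary()["n_individuals"] == 173

    def test_same_seed_identical_dataset(self, tmp_path):
        a = bv.simulate_study(tiny_config(seed=5))
        b = bv.simulate_study(tiny_config(seed=5))
        pd.testing.assert_frame_equal(a.frame, b.frame)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = bv.simulate_dataset(tiny_config(seed=5))
        b = bv.simulate_dataset(tiny_config(seed=6))
        assert not a.frame["value"].equals(b.frame["value"])

    def test_nesting_and_raw_scale_invariants(self):
        ds = bv.simulate_dataset(bv.default_regional_config(rng_seed=3))
        ds.validate()  # nesting, uniqueness, integer activity, boldness cap
        act = ds.frame[ds.frame["trait"] == "activity"]["value"]
        assert np.allclose(act, np.round(act))
        bold = ds.frame[ds.frame["trait"] == "boldness"]["value"]
        assert (bold > 0).all() and (bold <= 3600).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            bv.simulate_dataset(tiny_config(n_trials=0))
        bad = tiny_config()
        bad.groups["A"].n_individuals = 0
        with pytest.raises(ConfigError):
            bv.simulate_dataset(bad)
        bad = tiny_config()
        bad.groups["A"].v_among["exploration"] = -0.1
        with pytest.raises(ConfigError):
            bv.simulate_dataset(bad)

    def test_non_psd_correlation_rejected(self):
        cfg = bv.SimConfig(
            traits=("activity", "exploration"),
            groups={
                "A": bv.GroupConfig(
                    n_individuals=5, n_populations=1,
                    mean={"activity": 6, "exploration": 10},
                    v_among={"activity": 0.5, "exploration": 0.5},
                    v_within={"activity": 0.5, "exploration": 0.5},
                    corr_among=np.array([[1.0, 1.5], [1.5, 1.0]]),
                )
            },
            rng_seed=0,
        )
        with pytest.raises(ConfigError, match="positive semi-definite"):
            bv.simulate_dataset(cfg)


class TestGenerativeMoments:
    def test_individual_effect_variance_matches_truth(self):
        # 5000 individuals, 1 trial: Var(y) = V_A + V_W; isolate V_A via
        # per-individual means with many trials instead
        cfg = bv.SimConfig(
            traits=("exploration",),
            groups={"A": bv.GroupConfig(
                n_individuals=5000, n_populations=1,
                mean={"exploration": 10.0},
                v_among={"exploration": 0.6},
                v_within={"exploration": 0.2},
            )},
            n_trials=2,
            rng_seed=11,
        )
        ds = bv.simulate_dataset(cfg)
        y = bv.transform_trait(ds.frame["value"].to_numpy(), "exploration")
        df = ds.frame.assign(y=y)
        means = df.groupby("individual")["y"].mean()
        # Var(ind mean) = V_A + V_W / 2
        v_between = means.var(ddof=1) - 0.2 / 2
        assert v_between == pytest.approx(0.6, rel=0.05)

    def test_within_variance_only_design(self):
        # V_A = V_Pop = 0: variance of per-individual means -> V_W / n_trials
        cfg = bv.SimConfig(
            traits=("exploration",),
            groups={"A": bv.GroupConfig(
                n_individuals=2000, n_populations=1,
                mean={"exploration": 10.0},
                v_among={"exploration": 0.0},
                v_within={"exploration": 0.8},
            )},
            n_trials=2,
            rng_seed=13,
        )
        ds = bv.simulate_dataset(cfg)
        y = bv.transform_trait(ds.frame["value"].to_numpy(), "exploration")
        means = ds.frame.assign(y=y).groupby("individual")["y"].mean()
        assert means.var(ddof=1) == pytest.approx(0.8 / 2, rel=0.10)

    def test_among_individual_correlation_matches_truth(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        cfg = bv.SimConfig(
            traits=("activity", "exploration"),
            groups={"A": bv.GroupConfig(
                n_individuals=5000, n_populations=1,
                mean={"activity": 8.0, "exploration": 10.0},
                v_among={"activity": 0.5, "exploration": 0.5},
                v_within={"activity": 1e-12, "exploration": 1e-12},
                corr_among=corr,
            )},
            n_trials=1,
            rng_seed=17,
        )
        ds = bv.simulate_dataset(cfg)
        piv = ds.frame.pivot_table(index="individual", columns="trait", values="value")
        r = np.corrcoef(np.sqrt(piv["activity"]), np.sqrt(piv["exploration"]))[0, 1]
        assert abs(r - 0.5) < 0.05


class TestInjectInvalidTrials:
    def _cfg(self, **kw):
        return tiny_config(**kw)

    def test_zero_rates_leave_dataset_unchanged(self):
        cfg = self._cfg(invalid_rate_exploration=0.0, recording_failure_rate=0.0)
        ds = bv.simulate_dataset(cfg)
        out = bv.inject_invalid_trials(ds, cfg)
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_rate_one_flags_all_targeted_trials(self):
        cfg = self._cfg(invalid_rate_exploration=1.0)
        out = bv.inject_invalid_trials(bv.simulate_dataset(cfg), cfg)
        assert (~out.frame["moved"]).all()

    def test_rates_scope_and_magnitude(self):
        # large activity-only design at the study's no-movement rate
        cfg = bv.SimConfig(
            traits=("activity", "boldness"),
            groups={"A": bv.GroupConfig(
                n_individuals=5000, n_populations=1,
                mean={"activity": 6.0, "boldness": 2.5},
                v_among={"activity": 0.5, "boldness": 0.1},
                v_within={"activity": 0.5, "boldness": 0.1},
            )},
            n_trials=1,
            invalid_rate_activity=0.028,
            rng_seed=19,
        )
        out = bv.inject_invalid_trials(bv.simulate_dataset(cfg), cfg)
        summ = out.invalidation_summary().set_index("trait")
        # boldness is never flagged as not-moved; activity near binomial mean
        assert summ.loc["boldness", "n_not_moved"] == 0
        n_act = summ.loc["activity", "n_trials"]
        flagged = summ.loc["activity", "n_not_moved"]
        sd = np.sqrt(n_act * 0.028 * 0.972)
        assert abs(flagged - 0.028 * n_act) < 4 * sd
        # values untouched
        base = bv.simulate_dataset(cfg)
        assert out.frame["value"].equals(base.frame["value"])


class TestSerialization:
    def test_dataset_csv_round_trip(self, tmp_path):
        ds = bv.simulate_study(tiny_config(seed=2))
        path = tmp_path / "trials.csv"
        ds.to_csv(path)
        back = bv.Dataset.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, ds.frame)

    def test_missing_column_named_in_error(self, tmp_path):
        ds = bv.simulate_dataset(tiny_config())
        path = tmp_path / "bad.csv"
        ds.frame.drop(columns=["individual"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="individual"):
            bv.Dataset.from_csv(path)

    def test_sim_config_flat_file_round_trip(self, tmp_path):
        cfg = bv.default_regional_config(rng_seed=9)
        path = tmp_path / "sim.cfg"
        cfg.to_file(path)
        back = bv.SimConfig.from_file(path)
        pd.testing.assert_frame_equal(
            bv.simulate_dataset(back).frame, bv.simulate_dataset(cfg).frame
        )
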