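import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from focalenergy import simulate as sim
from focalenergy.ethogram import (
    BEHAVIORS,
    FORAGING,
    Bout,
    FocalSample,
    behavior_frequency,
    foraging_time,
    load_samples,
    summarize,
    summary_frame,
    time_allocation,
    write_samples,
)

from conftest import make_sample


class TestTypes:
    def test_closed_vocabulary(self):
        with pytest.raises(ValueError, match="sleeping"):
            Bout(behavior="sleeping", duration=10.0, index=0)

    def test_positive_duration(self):
        with pytest.raises(ValueError, match="duration"):
            Bout(behavior="resting", duration=0.0, index=0)

    def test_foraging_set(self):
        assert FORAGING == {"diving", "head_dipping", "eye_submerging"}
        assert len(BEHAVIORS) == 10

    def test_total_time_is_bout_sum(self):
        s = make_sample([("resting", 100.0), ("swimming", 50.0)])
        assert s.total_time == pytest.approx(150.0, abs=1e-6)

    def test_noncontiguous_indices_rejected(self):
        bouts = (
            Bout("resting", 10.0, 0),
            Bout("swimming", 10.0, 2),
        )
        with pytest.raises(ValueError, match="contiguous"):
            FocalSample(
                sample_id="x", site="y", bouts=bouts,
                outcome=make_sample([("resting", 1.0)]).outcome,
                environment=make_sample([("resting", 1.0)]).environment,
            )

    def test_excess_success_warns_only(self):
        with pytest.warns(UserWarning, match="success_count"):
            make_sample([("resting", 300.0)], success=3)


class TestIO:
    def test_single_bout_identity(self, tmp_path):
        s = make_sample([("resting", 300.0)], sample_id="a1")
        write_samples([s], tmp_path / "s.csv", tmp_path / "m.csv")
        loaded = load_samples(tmp_path / "s.csv", tmp_path / "m.csv")
        assert len(loaded) == 1
        assert loaded[0].total_time == 300.0
        assert loaded[0].bouts[0].behavior == "resting"

    def test_unknown_label_is_hard_error(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "sample_id,site,bout_index,behavior,duration_s\n"
            "a,riv,0,sleeping,300\n"
        )
        (tmp_path / "m.csv").write_text(
            "sample_id,site,success_count,failure_count,avg_fish_weight_g,"
            "fish_biomass_g_m2,temperature_C,river_width_m,water_depth_m,"
            "water_velocity_m_s,disturbance_number,disturbance_duration_s,"
            "disturbance_distance_m\n"
            "a,riv,0,0,1,1,5,50,0.5,0.1,0,0,\n"
        )
        with pytest.raises(ValueError, match="sleeping"):
            load_samples(tmp_path / "s.csv", tmp_path / "m.csv")

    def test_negative_duration_is_hard_error(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "sample_id,site,bout_index,behavior,duration_s\n"
            "a,riv,0,resting,-3\n"
        )
        (tmp_path / "m.csv").write_text("sample_id,site\na,riv\n")
        with pytest.raises(ValueError, match="duration"):
            load_samples(tmp_path / "s.csv", tmp_path / "m.csv")

    def test_missing_covariate_loads_as_nan(self, tmp_path):
        s = make_sample([("resting", 10.0)], avg_fish_weight_g=2.0)
        write_samples([s], tmp_path / "s.csv", tmp_path / "m.csv")
        loaded = load_samples(tmp_path / "s.csv", tmp_path / "m.csv")
        assert math.isnan(loaded[0].environment.temperature_C)
        assert loaded[0].environment.avg_fish_weight_g == 2.0

    def test_round_trip_on_simulated_samples(self, tmp_path):
        cfg = sim.default_config(seed=7)
        samples, _ = sim.simulate_dataset(cfg)
        samples = samples[:20]
        write_samples(samples, tmp_path / "s.csv", tmp_path / "m.csv")
        loaded = load_samples(tmp_path / "s.csv", tmp_path / "m.csv")
        assert len(loaded) == len(samples)
        for a, b in zip(samples, loaded):
            assert a.sample_id == b.sample_id and a.site == b.site
            assert len(a.bouts) == len(b.bouts)
            for ba, bb in zip(a.bouts, b.bouts):
                assert ba.behavior == bb.behavior
                assert ba.duration == bb.duration  # bit-comparable round trip
            assert a.outcome == b.outcome
            for k, v in a.environment.as_dict().items():
                w = getattr(b.environment, k)
                assert (math.isnan(v) and math.isnan(w)) or v == w


class TestTimeAllocation:
    def test_all_resting(self):
        s = make_sample([("resting", 300.0)])
        alloc = time_allocation(s)
        assert alloc["resting"] == (300.0, 100.0)
        for lab in BEHAVIORS:
            if lab != "resting":
                assert alloc[lab] == (0.0, 0.0)

    def test_three_way_symmetry(self):
        s = make_sample([("diving", 100.0), ("swimming", 100.0), ("vigilance", 100.0)])
        alloc = time_allocation(s)
        for lab in ("diving", "swimming", "vigilance"):
            assert alloc[lab][1] == pytest.approx(100.0 / 3.0)

    def test_toy_hand_arithmetic(self, toy_sample):
        alloc = time_allocation(toy_sample)
        assert alloc["diving"] == pytest.approx((120.0, 40.0))
        assert alloc["eye_submerging"] == pytest.approx((30.0, 10.0))
        assert alloc["swimming"] == pytest.approx((90.0, 30.0))
        assert alloc["vigilance"] == pytest.approx((45.0, 15.0))
        assert alloc["feeding"] == pytest.approx((15.0, 5.0))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(BEHAVIORS),
                st.floats(min_value=0.01, max_value=500.0,
                          allow_nan=False, allow_infinity=False),
            ),
            min_size=1, max_size=40,
        )
    )
    def test_partition_property(self, bout_spec):
        """Seconds always sum to total_time; percents to 100."""
        s = make_sample(bout_spec)
        alloc = time_allocation(s)
        assert sum(v[0] for v in alloc.values()) == pytest.approx(
            s.total_time, rel=1e-12
        )
        assert sum(v[1] for v in alloc.values()) == pytest.approx(100.0, abs=1e-9)


class TestFrequencyAndForaging:
    def test_single_bout(self):
        freq = behavior_frequency(make_sample([("resting", 300.0)]))
        assert freq["resting"] == 1 and sum(freq.values()) == 1

    def test_alternating(self):
        spec = [("diving", 5.0), ("swimming", 5.0)] * 5
        freq = behavior_frequency(make_sample(spec))
        assert freq["diving"] == 5 and freq["swimming"] == 5

    def test_simulator_bookkeeping(self, default_dataset):
        """Bout counts equal the simulator's emitted bout tally."""
        samples, truth = default_dataset
        for s, rec in zip(samples[:25], truth.records[:25]):
            freq = behavior_frequency(s)
            assert freq["diving"] == rec["n_dive_bouts"]
            assert sum(freq.values()) == len(s.bouts)

    def test_foraging_time(self, toy_sample):
        assert foraging_time(toy_sample) == 150.0
        assert foraging_time(make_sample([("resting", 10.0)])) == 0.0
        s = make_sample(
            [("diving", 100.0), ("eye_submerging", 50.0), ("head_dipping", 10.0)]
        )
        assert foraging_time(s) == 160.0


class TestSummarize:
    def test_closed_form_sd(self):
        samples = [
            make_sample([("resting", d)], sample_id=f"s{i}")
            for i, d in enumerate((1.0, 2.0, 3.0))
        ]
        rows = summarize(samples, variables=["total_time"], group_by="all")
        assert len(rows) == 1
        assert rows[0].mean == pytest.approx(2.0)
        assert rows[0].sd == pytest.approx(1.0)
        assert rows[0].n == 3

    def test_single_sample_degenerate(self):
        with pytest.warns(UserWarning, match="single observation"):
            rows = summarize(
                [make_sample([("resting", 5.0)])],
                variables=["total_time"], group_by="all",
            )
        assert rows[0].sd == 0.0

    def test_monte_carlo_mean_recovery(self):
        """Grouped covariate means land within 3 SE of the generative mean."""
        from conftest import single_site_config

        cfg = single_site_config(200, seed=99)
        samples, _ = sim.simulate_dataset(cfg)
        rows = summarize(samples, variables=["temperature_C"], group_by="all")
        mu, sd = cfg.sites["Shuaishui"].covariates["temperature_C"]
        se = sd / math.sqrt(200)
        assert abs(rows[0].mean - mu) < 3 * se

    def test_summary_frame_layout(self, default_dataset):
        samples, _ = default_dataset
        frame = summary_frame(summarize(samples, variables=["pct_diving"]))
        assert list(frame.columns) == ["group", "variable", "n", "mean", "sd"]
        assert set(frame["group"]) == {"Changjiang", "Shuaishui", "Jianjiang", "Total"}
        total = frame[frame["group"] == "Total"].iloc[0]
        assert total["n"] == len(samples)
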