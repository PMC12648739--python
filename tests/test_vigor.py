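import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from germtrack.simulate import RootParams, _logistic_lengths
from germtrack.vigor import (SPEED_POINTS, UniformityScore, build_profiles,
                             cluster_event_times, cluster_speed_groups,
                             uniformity_score, vigor_from_events,
                             vigor_matrix)


class TestUniformityScore:
    def test_single_bin_perfect_uniformity(self):
        s = uniformity_score([30.0] * 20)
        assert s.value == 1.0
        assert s.n_censored == 0

    def test_uniform_over_forty_hours(self):
        # peak 1/40; central 75% span = 29.25 one-hour bins
        s = uniformity_score([float(h) for h in range(40)])
        assert s.value == pytest.approx((1 / 40) / 29.25, rel=1e-6)

    def test_censored_seeds_excluded_but_counted(self):
        s = uniformity_score([30.0] * 10 + [None] * 10)
        assert s.value == 1.0
        assert s.n_censored == 10 and s.n_total == 20

    def test_all_censored_undefined(self):
        s = uniformity_score([None, None])
        assert s.value is None and s.n_censored == 2

    @given(st.lists(st.floats(0, 95), min_size=1, max_size=60))
    def test_always_in_unit_interval(self, hours):
        v = uniformity_score(hours).value
        assert 0.0 < v <= 1.0

    def test_value_one_iff_single_bin(self):
        assert uniformity_score([10.0, 10.4, 10.9]).value == 1.0
        assert uniformity_score([10.0, 17.0]).value < 1.0

    def test_monotone_in_span_at_fixed_peak(self):
        # same modal mass, increasingly wide tails
        tight = uniformity_score([30.0] * 5 + [28.0, 32.0])
        wide = uniformity_score([30.0] * 5 + [20.0, 40.0])
        assert wide.value <= tight.value


def _lengths_df(curves_by_seed, interval=1.0):
    rows = []
    for sid, curve in curves_by_seed.items():
        for f, v in enumerate(curve):
            rows.append({"seed_id": sid, "root_index": 1, "frame": f,
                         "hour": f * interval, "length_mm": float(v)})
    return pd.DataFrame(rows)


class TestProfiles:
    def _logistic(self, t_e):
        p = RootParams(0, 0, 12.0, 0.12, 18.0)
        return _logistic_lengths(np.arange(80, dtype=float), t_e, p)

    def test_identical_seeds_mean_equals_common_curve(self):
        curve = self._logistic(30)
        df = _lengths_df({0: curve, 1: curve, 2: curve})
        profs = build_profiles(df, {0: "A", 1: "A", 2: "A"})
        assert np.allclose(profs["A"].mean_length_mm, curve)
        assert (profs["A"].band_lo <= profs["A"].mean_length_mm + 1e-9).all()
        assert (profs["A"].band_hi >= profs["A"].mean_length_mm - 1e-9).all()

    def test_censored_seed_excluded_from_mean(self):
        curve = self._logistic(30)
        df = _lengths_df({0: curve, 1: curve, 2: curve,
                          3: np.zeros_like(curve)})
        profs = build_profiles(df, {i: "A" for i in range(4)})
        assert profs["A"].n_censored == 1
        assert np.allclose(profs["A"].mean_length_mm, curve)

    def test_low_support_flagged(self):
        curve = self._logistic(30)
        with pytest.warns(UserWarning, match="low-support"):
            profs = build_profiles(_lengths_df({0: curve, 1: curve}),
                                   {0: "A", 1: "A"})
        assert profs["A"].low_support


class TestSpeedClustering:
    def _profiles(self, emergences, label=None):
        import warnings as _w
        curves = {}
        genos = {}
        for i, t_e in enumerate(emergences):
            curves[i] = _logistic_lengths(np.arange(90, dtype=float), t_e,
                                          RootParams(0, 0, 12.0, 0.12, 18.0))
            genos[i] = f"G{i}"
        df = _lengths_df(curves)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # one seed per genotype: low support
            return build_profiles(df, genos)

    def test_three_separated_families_recovered(self):
        profs = self._profiles([29, 30, 31, 44, 45, 46, 59, 60, 61])
        groups = cluster_speed_groups(profs)
        assert [groups[f"G{i}"] for i in range(9)] == \
            ["quick"] * 3 + ["medium"] * 3 + ["slow"] * 3

    def test_k1_single_medium_group(self):
        profs = self._profiles([30, 40, 50])
        groups = cluster_speed_groups(profs, k=1)
        assert set(groups.values()) == {"medium"}

    def test_identical_profiles_degenerate(self):
        profs = self._profiles([40, 40, 40])
        with pytest.warns(UserWarning, match="identical"):
            groups = cluster_speed_groups(profs)
        assert set(groups.values()) == {"medium"}

    def test_k_larger_than_n_rejected(self):
        profs = self._profiles([30, 50])
        with pytest.raises(ValueError):
            cluster_speed_groups(profs, k=3)

    def test_label_order_invariant_to_input_order(self):
        profs = self._profiles([29, 30, 31, 44, 45, 46, 59, 60, 61])
        shuffled = dict(reversed(list(profs.items())))
        assert cluster_speed_groups(profs) == cluster_speed_groups(shuffled)


class TestEventClustering:
    def test_three_separated_families(self, rng):
        hours = {}
        for i, mu in enumerate([30, 30, 45, 45, 62, 62]):
            hours[f"G{i}"] = list(np.round(rng.normal(mu, 1.0, 20)))
        groups = cluster_event_times(hours)
        assert groups["G0"] == groups["G1"] == "quick"
        assert groups["G2"] == groups["G3"] == "medium"
        assert groups["G4"] == groups["G5"] == "slow"

    def test_identical_distributions_single_medium(self):
        hours = {g: [30.0] * 10 for g in "ABCD"}
        assert set(cluster_event_times(hours).values()) == {"medium"}


class TestVigorMatrix:
    def _inputs(self, groups, unis):
        sg = {g: {p: groups[g] for p in ("PRO", "RE", "SE")} for g in groups}
        un = {g: {p: unis[g] for p in ("PRO", "RE", "SE")} for g in unis}
        return sg, un

    def test_phase_score_is_points_times_uniformity(self):
        sg, un = self._inputs({"A": "quick"}, {"A": 0.5})
        df = vigor_matrix(sg, un)
        assert (df["phase_score"] == 3 * 0.5).all()
        assert df["overall_score"].iloc[0] == pytest.approx(4.5)

    def test_dominance_is_monotone(self, rng):
        for _ in range(50):
            ua, ub = sorted(rng.uniform(0, 1, 2))
            ga, gb = sorted(rng.choice(["quick", "medium", "slow"], 2),
                            key=lambda g: SPEED_POINTS[g])
            sg, un = self._inputs({"A": gb, "B": ga}, {"A": ub, "B": ua})
            df = vigor_matrix(sg, un).drop_duplicates("genotype")
            sa = df.loc[df.genotype == "A", "overall_score"].iloc[0]
            sb = df.loc[df.genotype == "B", "overall_score"].iloc[0]
            assert sa >= sb

    def test_missing_phase_contributes_zero_and_flagged(self):
        sg = {"A": {"PRO": "quick", "RE": "quick"}}  # SE missing
        un = {"A": {"PRO": 1.0, "RE": 1.0}}
        df = vigor_matrix(sg, un)
        se = df[df.phase == "SE"].iloc[0]
        assert se["phase_score"] == 0.0 and se["flagged"]
        assert df["overall_score"].iloc[0] == pytest.approx(6.0)


class TestVigorFromEvents:
    def test_toy_two_genotype_hand_computation(self):
        rows = []
        # A: perfectly uniform and early; B: later and spread out
        for i in range(10):
            rows.append({"seed_id": i, "genotype": "A", "protrusion_h": 30.0,
                         "t2mm_h": 38.0, "coleoptile_h": 60.0,
                         "chloroplast_h": 70.0})
        for i in range(10):
            rows.append({"seed_id": 10 + i, "genotype": "B",
                         "protrusion_h": 50.0 + 3 * i,
                         "t2mm_h": 58.0 + 3 * i,
                         "coleoptile_h": 80.0 + 3 * i,
                         "chloroplast_h": None})
        df = vigor_from_events(pd.DataFrame(rows))
        a = df[df.genotype == "A"]
        # two groups only: A is quick (3 points), B slow (1 point);
        # A's events all share one bin -> uniformity 1 in every phase
        assert (a["points"] == 3).all()
        assert (a["uniformity"] == 1.0).all()
        assert a["overall_score"].iloc[0] == pytest.approx(9.0)
        b = df[df.genotype == "B"]
        assert (b["points"] == 1).all()
        # B: peak 1/10, span (87.5th - 12.5th pct) of 27-h range
        expect = (1 / 10) / (0.75 * 27)
        assert b[b.phase == "PRO"]["uniformity"].iloc[0] == \
            pytest.approx(expect, rel=1e-6)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vigor_from_events(pd.DataFrame())

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="t2mm_h"):
            vigor_from_events(pd.DataFrame([{"genotype": "A",
                                             "protrusion_h": 1.0}]))
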