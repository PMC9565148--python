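"""Logsum, buffer, and gravity surfaces: identities and monotonicity."""

import numpy as np
import pandas as pd
import pytest

import accesslogit as al
from accesslogit.accessibility import compare_surfaces, nearest_time

SPEC = al.ModelSpec("park", "t_auto", (("acres", "log"),))
COEF = {"t_auto": -0.25, "log_acres": 1.0}


class TestLogsum:
    def test_single_resource_equals_its_utility(self, toy_zones, toy_skims):
        res = al.Resources(pd.DataFrame({
            "resource_id": ["p1"], "x": [0.5], "y": [0.0], "acres": [np.e],
            "playground": [0], "volleyball": [0], "basketball": [0], "tennis": [0],
        }), "park")
        from conftest import make_skims
        sk = make_skims([("A", "p1", 4.0, 10.0, 0.5),
                         ("B", "p1", 8.0, 20.0, 1.0),
                         ("C", "p1", 2.0, 6.0, 0.3)])
        surf = al.logsum_access(COEF, toy_zones, res, sk, spec=SPEC)
        # A: V = -0.25*4 + 1 = 0
        assert surf.values["A"] == pytest.approx(0.0)
        assert surf.values["B"] == pytest.approx(-0.25 * 8 + 1)

    def test_duplicating_a_resource_adds_ln2(self, toy_zones, toy_parks, toy_skims):
        surf1 = al.logsum_access(COEF, toy_zones, toy_parks, toy_skims, spec=SPEC)
        dup_df = pd.concat([
            toy_parks.df,
            toy_parks.df.assign(resource_id=["p1b", "p2b"]),
        ], ignore_index=True)
        dup = al.Resources(dup_df, "park")
        dup_sk = al.SkimSet(pd.concat([
            toy_skims.df,
            toy_skims.df.assign(resource_id=toy_skims.df["resource_id"] + "b"),
        ], ignore_index=True))
        surf2 = al.logsum_access(COEF, toy_zones, dup, dup_sk, spec=SPEC)
        np.testing.assert_allclose(surf2.values - surf1.values, np.log(2), rtol=1e-12)

    def test_constant_utility_shift_shifts_surface_by_constant(
        self, toy_zones, toy_parks, toy_skims
    ):
        surf = al.logsum_access(COEF, toy_zones, toy_parks, toy_skims, spec=SPEC)
        # doubling every park's acres adds log(2)*gamma to every utility
        bigger = al.Resources(toy_parks.df.assign(acres=toy_parks.df["acres"] * 2), "park")
        surf2 = al.logsum_access(COEF, toy_zones, bigger, toy_skims, spec=SPEC)
        np.testing.assert_allclose(surf2.values - surf.values, np.log(2), rtol=1e-12)

    def test_improving_attributes_raises_every_zone(self, toy_zones, toy_parks, toy_skims):
        surf = al.logsum_access(COEF, toy_zones, toy_parks, toy_skims, spec=SPEC)
        better = al.Resources(toy_parks.df.assign(acres=toy_parks.df["acres"] * 1.5), "park")
        surf2 = al.logsum_access(COEF, toy_zones, better, toy_skims, spec=SPEC)
        assert (surf2.values > surf.values).all()

    def test_zone_without_reachable_resource_is_nan(self, toy_zones, toy_parks):
        from conftest import make_skims
        sk = make_skims([
            ("A", "p1", 3.0, 8.0, 0.4), ("A", "p2", 6.0, 20.0, 1.0),
            ("B", "p1", 4.0, 10.0, 0.5), ("B", "p2", 3.0, 7.0, 0.35),
            ("C", "p1", np.nan, np.nan, np.nan), ("C", "p2", np.nan, np.nan, np.nan),
        ])
        surf = al.logsum_access(COEF, toy_zones, toy_parks, sk, spec=SPEC)
        assert np.isnan(surf.values["C"])
        assert np.isfinite(surf.mean())  # NaN zones excluded from means

    def test_gravity_crosscheck_with_gamma_zero(self, toy_zones, toy_parks, toy_skims):
        # with gamma=0, exp(logsum) with beta*t utility equals the gravity
        # sum with exponential decay at the same rate
        spec = al.ModelSpec("park", "t_auto", ())
        ls = al.logsum_access({"t_auto": -0.25}, toy_zones, toy_parks, toy_skims, spec=spec)
        grav = al.gravity_access(toy_zones, toy_parks, toy_skims, beta=0.25, mode="auto")
        np.testing.assert_allclose(np.exp(ls.values), grav.values, rtol=1e-12)


class TestBuffer:
    def test_closed_threshold(self, toy_zones, toy_parks):
        from conftest import make_skims
        sk = make_skims([
            ("A", "p1", 5.0, 10.0, 0.5), ("A", "p2", 9.0, 25.0, 1.2),
            ("B", "p1", 5.1, 11.0, 0.55), ("B", "p2", 8.0, 22.0, 1.1),
            ("C", "p1", 12.0, 30.0, 1.6), ("C", "p2", 14.0, 40.0, 2.0),
        ])
        surf = al.buffer_access(toy_zones, toy_parks, sk, "auto", t_star=5.0)
        assert surf.values["A"] == 1  # exactly at the threshold counts
        assert surf.values["B"] == 0
        assert surf.values["C"] == 0

    def test_cumulative_counts_within_threshold(self, toy_zones):
        parks = al.Resources(pd.DataFrame({
            "resource_id": ["q1", "q2", "q3"], "x": [0.0] * 3, "y": [0.0] * 3,
            "acres": [1.0] * 3,
            "playground": [0] * 3, "volleyball": [0] * 3,
            "basketball": [0] * 3, "tennis": [0] * 3,
        }), "park")
        from conftest import make_skims
        sk = make_skims([
            ("A", "q1", 1.0, 2.0, 0.1), ("A", "q2", 2.0, 4.0, 0.2),
            ("A", "q3", 5.0, 9.0, 0.45),
            ("B", "q1", 1.0, 2.0, 0.1), ("B", "q2", 2.0, 4.0, 0.2),
            ("B", "q3", 5.0, 9.0, 0.45),
            ("C", "q1", 1.0, 2.0, 0.1), ("C", "q2", 2.0, 4.0, 0.2),
            ("C", "q3", 5.0, 9.0, 0.45),
        ])
        surf = al.buffer_access(toy_zones, parks, sk, "walk", t_star=5.0, cumulative=True)
        assert surf.values["A"] == 2  # walk times 2, 4 within; 9 outside

    def test_invalid_threshold_and_mode(self, toy_zones, toy_parks, toy_skims):
        with pytest.raises(ValueError):
            al.buffer_access(toy_zones, toy_parks, toy_skims, "auto", t_star=0)
        with pytest.raises(ValueError):
            al.buffer_access(toy_zones, toy_parks, toy_skims, "transit", t_star=5)


class TestGravity:
    def test_single_unit_resource_at_zero_time(self, toy_zones, toy_parks):
        from conftest import make_skims
        sk = make_skims([
            ("A", "p1", 0.0, 0.0, 0.0), ("A", "p2", np.nan, np.nan, np.nan),
            ("B", "p1", np.nan, np.nan, np.nan), ("B", "p2", np.nan, np.nan, np.nan),
            ("C", "p1", np.nan, np.nan, np.nan), ("C", "p2", np.nan, np.nan, np.nan),
        ])
        surf = al.gravity_access(toy_zones, toy_parks, sk, beta=0.1)
        assert surf.values["A"] == pytest.approx(1.0)
        assert surf.values["B"] == pytest.approx(0.0)  # unreachable contributes nothing

    def test_linearity_in_size(self, toy_zones, toy_parks, toy_skims):
        s1 = al.gravity_access(toy_zones, toy_parks, toy_skims, beta=0.2, size_attr="acres")
        doubled = al.Resources(toy_parks.df.assign(acres=toy_parks.df["acres"] * 2), "park")
        s2 = al.gravity_access(toy_zones, doubled, toy_skims, beta=0.2, size_attr="acres")
        np.testing.assert_allclose(s2.values, 2 * s1.values, rtol=1e-12)

    def test_large_beta_keeps_only_nearest_floored_resource(self, toy_zones, toy_parks, toy_skims):
        surf = al.gravity_access(toy_zones, toy_parks, toy_skims, beta=50.0, decay="power")
        # all times > 1 min here, so the nearest (floored) resource dominates
        t = toy_skims.matrix(toy_zones.ids, toy_parks.ids, "t_auto")
        expected = np.max(np.maximum(t, 1.0) ** -50.0, axis=1)
        np.testing.assert_allclose(surf.values, expected, rtol=1e-6)

    def test_nonpositive_beta_rejected(self, toy_zones, toy_parks, toy_skims):
        with pytest.raises(ValueError):
            al.gravity_access(toy_zones, toy_parks, toy_skims, beta=0.0)


class TestMonotonicity:
    def test_reducing_time_never_lowers_any_measure(self, toy_zones, toy_parks, toy_skims):
        faster = al.SkimSet(toy_skims.df.assign(
            t_auto=toy_skims.df["t_auto"] * 0.5,
            t_walk=toy_skims.df["t_walk"] * 0.5,
            d_walk=toy_skims.df["d_walk"] * 0.5,
        ))
        for fn in (
            lambda sk: al.logsum_access(COEF, toy_zones, toy_parks, sk, spec=SPEC).values,
            lambda sk: al.buffer_access(toy_zones, toy_parks, sk, "auto", 5.0).values,
            lambda sk: al.gravity_access(toy_zones, toy_parks, sk, beta=0.2).values,
        ):
            assert (fn(faster) >= fn(toy_skims) - 1e-12).all()


class TestComparison:
    def test_equal_time_zones_differ_only_in_logsum(self, toy_zones):
        # two zones at identical nearest time; the parks near B are better
        parks = al.Resources(pd.DataFrame({
            "resource_id": ["p1", "p2"], "x": [0.0, 2.0], "y": [0.0, 0.0],
            "acres": [1.0, 100.0],
            "playground": [0, 0], "volleyball": [0, 0],
            "basketball": [0, 0], "tennis": [0, 0],
        }), "park")
        from conftest import make_skims
        sk = make_skims([
            ("A", "p1", 4.0, 10.0, 0.5), ("A", "p2", 30.0, 80.0, 4.0),
            ("B", "p1", 30.0, 80.0, 4.0), ("B", "p2", 4.0, 10.0, 0.5),
            ("C", "p1", 20.0, 50.0, 2.5), ("C", "p2", 20.0, 50.0, 2.5),
        ])
        buf = al.buffer_access(toy_zones, parks, sk, "auto", 5.0)
        ls = al.logsum_access(COEF, toy_zones, parks, sk, spec=SPEC)
        cmp = compare_surfaces(buf, ls, sk, toy_zones, parks)
        a, b = cmp.per_zone.loc["A"], cmp.per_zone.loc["B"]
        assert a["nearest_time"] == b["nearest_time"]
        assert a["buffer"] == b["buffer"]
        assert b["logsum"] > a["logsum"]

    def test_identical_colocated_resources_make_logsum_decreasing_in_time(self):
        # zones strung out along a line from a cluster of identical parks:
        # logsum = log(n) + V(t_nearest), strictly decreasing in nearest time
        zones = al.Zones(pd.DataFrame({
            "zone_id": [f"z{i}" for i in range(6)],
            "x": np.arange(6, dtype=float), "y": np.zeros(6),
            "households": [10] * 6, "frac_low_income": [0.1] * 6,
        }))
        parks = al.Resources(pd.DataFrame({
            "resource_id": ["p1", "p2", "p3"], "x": [0.0] * 3, "y": [0.0] * 3,
            "acres": [4.0] * 3,
            "playground": [1] * 3, "volleyball": [0] * 3,
            "basketball": [0] * 3, "tennis": [0] * 3,
        }), "park")
        from conftest import make_skims
        rows = [
            (f"z{i}", p, 2.0 + 3.0 * i, 5.0 + 8.0 * i, 0.2 + 0.4 * i)
            for i in range(6) for p in ("p1", "p2", "p3")
        ]
        sk = make_skims(rows)
        ls = al.logsum_access(COEF, zones, parks, sk, spec=SPEC)
        nt = nearest_time(zones, parks, sk, "auto")
        order = nt.values.sort_values().index
        assert (np.diff(ls.values[order]) < 0).all()

    def test_empty_resource_set_errors(self, toy_zones, toy_parks, toy_skims):
        buf = al.buffer_access(toy_zones, toy_parks, toy_skims, "auto", 5.0)
        ls = al.logsum_access(COEF, toy_zones, toy_parks, toy_skims, spec=SPEC)
        empty = al.Resources(toy_parks.df.iloc[:0], "park")
        with pytest.raises(ValueError):
            compare_surfaces(buf, ls, toy_skims, toy_zones, empty)
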