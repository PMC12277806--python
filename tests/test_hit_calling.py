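from __future__ import annotations

import numpy as np
import pytest

from mtscreen.errors import ConfigError, DomainError
from mtscreen.hit_calling import (
    HitTable,
    Thresholds,
    call_hits,
    derive_thresholds,
    intersect_hits,
    percent_decrease,
    rank_hits,
    vehicle_means,
    viability_filter,
)
from mtscreen.screen_data import ScreenDataset
from mtscreen.synthetic_screen import (
    EffectSpec,
    ScreenSimConfig,
    compound_ids,
    draw_effects,
    generate_screen,
)

from conftest import make_well, toy_dataset


class TestPercentDecrease:
    def test_arithmetic(self):
        assert percent_decrease(35.0, 100.0) == pytest.approx(65.0)

    def test_identity(self):
        assert percent_decrease(100.0, 100.0) == 0.0

    def test_elevation_goes_negative(self):
        assert percent_decrease(120.0, 100.0) == pytest.approx(-20.0)

    def test_bounded_above_by_100(self):
        assert percent_decrease(0.0, 100.0) == 100.0

    def test_nonpositive_vehicle_mean_rejected(self):
        with pytest.raises(DomainError):
            percent_decrease(10.0, 0.0)


class TestViabilityFilter:
    def _ds(self, diameters):
        return toy_dataset(
            {cid: 50.0 for cid in diameters},
            diameters=diameters,
        )

    def test_shrunk_compound_excluded(self):
        result = viability_filter(self._ds({"C1": 70.0}), tolerance=0.2)
        assert result.excluded_on("spinal_microtissue") == {"C1"}

    def test_compound_within_tolerance_retained(self):
        result = viability_filter(self._ds({"C1": 85.0}), tolerance=0.2)
        assert result.excluded_on("spinal_microtissue") == frozenset()

    def test_missing_diameter_unknown_with_warning(self):
        result = viability_filter(self._ds({"C1": None}), tolerance=0.2)
        assert result.excluded_on("spinal_microtissue") == frozenset()
        assert result.unknown_on("spinal_microtissue") == {"C1"}
        assert any("no diameter" in w for w in result.warnings)

    def test_boundary_is_inclusive_retention(self):
        # diameter exactly at (1 - tol) * reference stays in
        result = viability_filter(self._ds({"C1": 80.0}), tolerance=0.2)
        assert result.excluded_on("spinal_microtissue") == frozenset()

    def test_no_reference_diameters_is_config_error(self):
        ds = self._ds({"C1": 70.0})
        wells = [
            w if w.role != "vehicle" else _strip_diameter(w) for w in ds.wells
        ]
        ds2 = ScreenDataset(wells=wells, analyte_panel=ds.analyte_panel)
        with pytest.raises(ConfigError, match="reference"):
            viability_filter(ds2, reference="vehicle")

    def test_untreated_reference(self):
        ds = self._ds({"C1": 70.0})
        ds.wells.append(
            make_well("untreated", position="H12", analytes={"IL-6": 100.0}, diameter=100.0)
        )
        result = viability_filter(ds, tolerance=0.2, reference="untreated")
        assert result.excluded_on("spinal_microtissue") == {"C1"}


def _strip_diameter(w):
    from dataclasses import replace

    return replace(w, diameter_um=None)


class TestDeriveThresholds:
    def test_negative_control_branch(self):
        ds = toy_dataset({}, negative_values=(80.0, 80.0, 80.0))
        thr = derive_thresholds(ds, floor=0.0)
        key = ("spinal_microtissue", "IL-6")
        assert thr.values[key] == pytest.approx(20.0)
        assert thr.provenance[key] == "negative_control"

    def test_floor_branch_for_inert_negative(self):
        ds = toy_dataset({}, negative_values=(99.0, 99.0, 99.0))
        thr = derive_thresholds(ds, floor=15.0)
        key = ("spinal_microtissue", "IL-6")
        assert thr.values[key] == 15.0
        assert thr.provenance[key] == "floor"

    def test_floor_branch_for_elevating_negative(self):
        ds = toy_dataset({}, negative_values=(120.0, 120.0, 120.0))
        thr = derive_thresholds(ds, floor=10.0)
        key = ("spinal_microtissue", "IL-6")
        assert thr.values[key] == 10.0
        assert thr.provenance[key] == "floor"

    def test_missing_negative_instructs_manual(self):
        ds = toy_dataset({})
        ds = ScreenDataset(
            wells=[w for w in ds.wells if w.role != "negative"],
            analyte_panel=ds.analyte_panel,
        )
        with pytest.raises(ConfigError, match="manual"):
            derive_thresholds(ds)


class TestCallHits:
    def test_toy_plate_brute_forced(self):
        # vehicle mean 100; compounds at 75 (25%), 85 (15%), 120 (-20%); thr 20
        ds = toy_dataset({"A": 75.0, "B": 85.0, "C": 120.0})
        thr = Thresholds.manual({("spinal_microtissue", "IL-6"): 20.0})
        table = call_hits(ds, thr)
        assert table.hit_compounds() == {"A"}
        got = dict(zip(table.data["compound_id"], table.data["percent_decrease"]))
        assert got == pytest.approx({"A": 25.0, "B": 15.0, "C": -20.0})

    def test_exclusion_takes_precedence(self):
        ds = toy_dataset({"A": 50.0}, diameters={"A": 50.0})
        thr = Thresholds.manual({("spinal_microtissue", "IL-6"): 20.0})
        viability = viability_filter(ds, tolerance=0.2)
        table = call_hits(ds, thr, viability)
        assert table.hit_compounds() == frozenset()
        assert (table.data["viability"] == "excluded").all()

    def test_threshold_tie_is_not_a_hit(self):
        ds = toy_dataset({"A": 80.0})  # exactly 20% decrease
        thr = Thresholds.manual({("spinal_microtissue", "IL-6"): 20.0})
        assert call_hits(ds, thr).hit_compounds() == frozenset()

    def test_unknown_viability_remains_eligible(self):
        ds = toy_dataset({"A": 50.0}, diameters={"A": None})
        thr = Thresholds.manual({("spinal_microtissue", "IL-6"): 20.0})
        table = call_hits(ds, thr, viability_filter(ds))
        assert table.hit_compounds() == {"A"}
        assert (table.data["viability"] == "unknown").all()

    def test_missing_threshold_is_config_error(self):
        ds = toy_dataset({"A": 50.0})
        with pytest.raises(ConfigError, match="threshold"):
            call_hits(ds, Thresholds.manual({}))

    def test_zero_noise_recovers_true_effect_exactly(self):
        ids = compound_ids(6)
        effects = EffectSpec(
            effects={cid: {"IL-6": f, "IL-8": f / 2}
                     for cid, f in zip(ids, (0.0, 0.1, 0.25, 0.4, 0.6, 0.9))}
        )
        cfg = ScreenSimConfig(n_compounds=6, noise_sigma_log=0.0, seed=0)
        ds, _ = generate_screen(cfg, effects=effects)
        thr = derive_thresholds(ds, floor=15.0)
        table = call_hits(ds, thr)
        for _, row in table.data.iterrows():
            truth = 100.0 * effects.effect(row["compound_id"], row["analyte"])
            assert row["percent_decrease"] == pytest.approx(truth, abs=1e-9)


class TestRankHits:
    def _table(self, values: dict[str, float]) -> HitTable:
        ds = toy_dataset(values)
        thr = Thresholds.manual({("spinal_microtissue", "IL-6"): 20.0})
        return call_hits(ds, thr)

    def test_truncates_to_k(self):
        values = {f"C{i:02d}": 100.0 - (30 + i) for i in range(20)}  # 31%..50%
        shortlist = rank_hits(self._table(values), k=15)[("spinal_microtissue", "IL-6")]
        assert len(shortlist) == 15
        assert shortlist.iloc[0]["percent_decrease"] == max(
            100.0 - v for v in values.values()
        )
        assert list(shortlist["rank"]) == list(range(1, 16))

    def test_fewer_hits_than_k(self):
        shortlist = rank_hits(self._table({"A": 60.0, "B": 70.0, "C": 50.0, "D": 45.0}), k=15)
        got = shortlist[("spinal_microtissue", "IL-6")]
        assert len(got) == 4
        assert list(got["compound_id"]) == ["D", "C", "A", "B"]

    def test_ties_break_by_compound_id(self):
        got = rank_hits(self._table({"zzz": 70.0, "aaa": 70.0}), k=15)[
            ("spinal_microtissue", "IL-6")
        ]
        assert list(got["compound_id"]) == ["aaa", "zzz"]

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_hits(self._table({"A": 50.0}), k=0)


class TestIntersectHits:
    def _table(self, values, platform):
        ds = toy_dataset(values, platform=platform)
        thr = Thresholds.manual({(platform, "IL-6"): 20.0})
        return call_hits(ds, thr)

    def test_shared_and_exclusive(self):
        a = self._table({"tel": 30.0, "val": 40.0, "azi": 50.0, "flu": 60.0, "non": 90.0},
                        "spinal_microtissue")
        b = self._table({"tel": 35.0, "val": 45.0, "azi": 55.0, "del": 65.0, "non": 90.0},
                        "microglia_spheroid")
        result = intersect_hits(a, b)
        assert result.shared == {"tel", "val", "azi"}
        assert result.only_a == {"flu"}
        assert result.only_b == {"del"}

    def test_disjoint_sets(self):
        a = self._table({"x": 30.0}, "spinal_microtissue")
        b = self._table({"y": 30.0}, "microglia_spheroid")
        result = intersect_hits(a, b)
        assert result.shared == frozenset()

    def test_identity(self):
        a = self._table({"x": 30.0, "y": 40.0}, "spinal_microtissue")
        result = intersect_hits(a, a)
        assert result.shared == {"x", "y"}
        assert result.only_a == result.only_b == frozenset()

    def test_partition_property(self):
        a = self._table({"p": 30.0, "q": 50.0, "r": 90.0}, "spinal_microtissue")
        b = self._table({"q": 30.0, "r": 50.0, "s": 90.0}, "microglia_spheroid")
        result = intersect_hits(a, b)
        union = a.hit_compounds() | b.hit_compounds()
        assert result.union == union
        assert not (result.shared & result.only_a)
        assert not (result.shared & result.only_b)
        assert not (result.only_a & result.only_b)

    def test_per_analyte_mode(self):
        a = self._table({"x": 30.0}, "spinal_microtissue")
        b = self._table({"x": 30.0}, "microglia_spheroid")
        per = intersect_hits(a, b, mode="per_analyte")
        assert per["IL-6"].shared == {"x"}


def brute_force_hit_flags(ds, floor, tolerance):
    """Definition-level re-derivation of the three screen rules.

    Deliberately uses plain loops and no mtscreen analytics so it stays an
    independent oracle for call_hits and friends.
    """
    flags = {}
    platforms = sorted({w.platform for w in ds.wells})
    for platform in platforms:
        wells = [w for w in ds.wells if w.platform == platform]
        ref = [w.diameter_um for w in wells
               if w.role == "vehicle" and w.diameter_um is not None]
        ref_mean = sum(ref) / len(ref)
        for analyte in ds.analyte_panel:
            veh = [w.analyte_values[analyte] for w in wells if w.role == "vehicle"]
            veh_mean = sum(veh) / len(veh)
            neg = [w.analyte_values[analyte] for w in wells if w.role == "negative"]
            neg_mean = sum(neg) / len(neg)
            thr = 100.0 * (1.0 - neg_mean / veh_mean)
            if thr < floor:
                thr = floor
            for w in wells:
                if w.role != "compound":
                    continue
                pct = 100.0 * (1.0 - w.analyte_values[analyte] / veh_mean)
                excluded = (
                    w.diameter_um is not None
                    and w.diameter_um < (1.0 - tolerance) * ref_mean
                )
                flags[(w.compound_id, platform, analyte)] = (pct > thr) and not excluded
    return flags


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        cfg = ScreenSimConfig(
            n_compounds=n,
            noise_sigma_log=float(rng.uniform(0.0, 0.3)),
            seed=seed + 1000,
        )
        effects = draw_effects(
            compound_ids(n), cfg.analyte_panel, rng,
            active_rate=0.5, toxic_rate=0.3,
        )
        ds, _ = generate_screen(cfg, effects=effects)
        floor = float(rng.uniform(0.0, 30.0))
        tol = float(rng.uniform(0.05, 0.4))
        table = call_hits(
            ds,
            derive_thresholds(ds, floor=floor),
            viability_filter(ds, tolerance=tol),
        )
        got = {
            (r["compound_id"], r["platform"], r["analyte"]): bool(r["hit"])
            for _, r in table.data.iterrows()
        }
        assert got == brute_force_hit_flags(ds, floor, tol)

    def test_rank_invariants(self):
        ds, _ = generate_screen(ScreenSimConfig(n_compounds=30, seed=4))
        table = call_hits(ds, derive_thresholds(ds, floor=5.0), viability_filter(ds))
        for (_, _), sub in table.data.groupby(["platform", "analyte"]):
            hits = sub[sub["hit"]].sort_values("rank")
            assert list(hits["rank"]) == list(
                float(i) for i in range(1, len(hits) + 1)
            )
            assert (hits["percent_decrease"].diff().dropna() <= 1e-12).all()
            assert (sub["percent_decrease"] <= 100.0).all()
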