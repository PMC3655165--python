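import math

import numpy as np
import pandas as pd
import pytest

import dietghg as dg


class TestIntensities:
    def test_ratio_definition(self):
        ec, ea = dg.intensities(1560.0, 1950.0, 0.0, 300.0)
        assert ec == pytest.approx(0.80)
        assert ea == 0.0

    def test_zero_denominator_is_missing_not_infinite(self):
        ec, ea = dg.intensities(100.0, 0.0, 100.0, None)
        assert math.isnan(ec) and math.isnan(ea)

    def test_generator_intensities_recovered(self, small_world):
        """Per-country-year ec clusters around the archetype's configured
        intensity within the generator's lognormal noise."""
        ci = dg.country_intensities(small_world.food, small_world.impacts)
        truth = dg.planted_truth(small_world)
        params = small_world.config.impact_params
        ok = 0
        for row in ci.dropna(subset=["ec"]).itertuples(index=False):
            true_ec = params[truth[(row.country, row.year)]].ec
            # two lognormal(sd=0.05) factors: 4 sd ~ 22%
            if abs(math.log(row.ec / true_ec)) < 4 * 0.05 * math.sqrt(2):
                ok += 1
        assert ok / len(ci.dropna(subset=["ec"])) > 0.99


class TestFeedEnergy:
    def test_single_item(self):
        assert dg.feed_energy({"maize": 7.3e9}, {"maize": 1.0}, 10_000) == pytest.approx(2000.0)

    def test_zero_feed(self):
        assert dg.feed_energy({}, {}, 1000) == 0.0

    def test_additivity_over_items(self):
        masses = {"maize": 2.0e9, "barley": 1.1e9}
        factors = {"maize": 3.5, "barley": 3.2}
        total = dg.feed_energy(masses, factors, 5000)
        parts = sum(
            dg.feed_energy({k: masses[k]}, factors, 5000) for k in masses
        )
        assert total == pytest.approx(parts)

    def test_missing_factor_names_item(self):
        with pytest.raises(dg.EmissionError, match="soy"):
            dg.feed_energy({"soy": 1.0}, {}, 1000)


class TestPatternAverage:
    def test_plain_mean(self):
        values = {("A", 1): 2.0, ("B", 1): 4.0, ("C", 1): 6.0}
        assert dg.pattern_average(values, list(values)) == (4.0, 3)

    def test_missing_members_excluded(self):
        values = {("A", 1): 2.0, ("B", 1): math.nan, ("C", 1): 6.0}
        assert dg.pattern_average(values, list(values)) == (4.0, 2)

    def test_all_missing_gives_na(self):
        mean, n = dg.pattern_average({("A", 1): math.nan}, [("A", 1)])
        assert math.isnan(mean) and n == 0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            keys = [("C%d" % i, 2000) for i in range(rng.integers(1, 30))]
            vals = {
                k: (math.nan if rng.random() < 0.3 else float(rng.normal()))
                for k in keys
            }
            mean, n = dg.pattern_average(vals, keys)
            avail = [v for v in vals.values() if not math.isnan(v)]
            if avail:
                assert mean == pytest.approx(sum(avail) / len(avail))
                assert n == len(avail)
            else:
                assert math.isnan(mean)


class TestAccountingChain:
    def test_crop_emissions(self):
        assert dg.crop_emissions(1727, 0.82) == pytest.approx(1.41614)
        assert dg.crop_emissions(2078, 0.57) == pytest.approx(1.18446)
        assert dg.crop_emissions(1000, 0.0) == 0.0

    def test_animal_emissions(self):
        assert dg.animal_emissions(146, 12.48, 268, 0.82) == pytest.approx(2.04184)
        assert dg.animal_emissions(1090, 1.84, 3662, 0.51) == pytest.approx(3.87322)
        assert dg.animal_emissions(500, 2.0, 0, 0.5) == pytest.approx(1.0)

    def test_fossil_energy(self):
        assert dg.fossil_energy(1904, 278, 26.6) == pytest.approx(82.03, abs=0.005)
        assert dg.fossil_energy(1727, 268, 14.1) == pytest.approx(141.49, abs=0.005)
        assert dg.fossil_energy(1000, 0, 1.0) == 1000.0
        with pytest.raises(dg.EmissionError):
            dg.fossil_energy(1000, 0, 0.0)

    def test_total_emissions(self):
        fossil, _ = dg.total_emissions(0.0, 0.0, 3490.9)
        assert round(fossil, 2) == 1.26
        fossil, total = dg.total_emissions(0.0, 0.0, 0.0)
        assert fossil == 0.0 and total == 0.0

    def test_conservation_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            ec_e, ea_e, fe = rng.uniform(0, 5, 3)
            fossil, total = dg.total_emissions(ec_e, ea_e, fe * 1000)
            assert total == pytest.approx(ec_e + ea_e + fossil, abs=1e-9)

    def test_monotonicity(self):
        """Total emissions rise with each input and fall with the O/I ratio."""
        base = dict(pc=2000.0, pa=300.0, feed=600.0, ec=0.5, ea=3.0, r=5.0, e_d=0.36)

        def et(pc, pa, feed, ec, ea, r, e_d):
            fossil, total = dg.total_emissions(
                dg.crop_emissions(pc, ec),
                dg.animal_emissions(pa, ea, feed, ec),
                dg.fossil_energy(pc, feed, r),
                e_d,
            )
            return total

        ref = et(**base)
        for var in ("pc", "pa", "feed", "ec", "ea", "e_d"):
            bumped = dict(base, **{var: base[var] * 1.1})
            assert et(**bumped) >= ref
        assert et(**dict(base, r=base["r"] * 1.1)) <= ref


class TestReferenceTable:
    def test_intensity_ranges(self):
        """Livestock per-kcal intensity spans 1.44–13.06, crop 0.31–1.81."""
        ref = dg.reference_pattern_table()
        assert ref["ea_g_per_kcal"].min() == pytest.approx(1.44)
        assert ref["ea_g_per_kcal"].max() == pytest.approx(13.06)
        assert ref["ec_g_per_kcal"].min() == pytest.approx(0.31)
        assert ref["ec_g_per_kcal"].max() == pytest.approx(1.81)

    def test_animal_burden_exceeds_crop_burden(self):
        """Per kcal consumed, animal products (incl. feed) always carry a
        larger emission burden than crop products."""
        ref = dg.reference_pattern_table().dropna(subset=["ec_g_per_kcal"])
        out = dg.pattern_table_from_inputs(ref)
        merged = ref.merge(out, on="pattern")
        crop_per_kcal = merged["ec_emis"] * 1000 / merged["pc_kcal"]
        animal_per_kcal = merged["ea_emis"] * 1000 / merged["pa_kcal"]
        assert (animal_per_kcal > crop_per_kcal).all()

    def test_pattern_nine_propagates_na(self):
        ref = dg.reference_pattern_table()
        out = dg.pattern_table_from_inputs(ref)
        row9 = out[out["pattern"] == 9].iloc[0]
        assert math.isnan(row9["total_emis"]) and math.isnan(row9["fe"])


class TestBuildPatternTable:
    def test_noiseless_world_variants_agree(self, noiseless_world):
        """With identical members, averaging before or after the equations
        gives the same table."""
        w = noiseless_world
        labels = w.labels.rename(columns={"archetype": "pattern"})
        table = dg.build_pattern_table(labels, w.food, w.impacts, n_patterns=16)
        have = table.dropna(subset=["ec"])
        for a, b in [
            ("fe", "fe_cl"), ("ec_emis", "ec_emis_cl"), ("ea_emis", "ea_emis_cl"),
            ("fossil_emis", "fossil_emis_cl"), ("total_emis", "total_emis_cl"),
        ]:
            assert np.allclose(have[a], have[b], rtol=1e-9)

    def test_archetype_nine_row_is_na(self, small_world):
        labels = small_world.labels.rename(columns={"archetype": "pattern"})
        table = dg.build_pattern_table(labels, small_world.food, small_world.impacts,
                                       n_patterns=16)
        row9 = table[table["pattern"] == 9].iloc[0]
        if row9["n_members"] > 0:
            assert row9["n_oi_ratio"] == 0 and math.isnan(row9["total_emis"])
            # members exist and their consumption is still averaged
            assert row9["pc"] > 0

    def test_dropping_a_member_only_changes_its_pattern(self, small_world):
        labels = small_world.labels.rename(columns={"archetype": "pattern"})
        full = dg.build_pattern_table(labels, small_world.food, small_world.impacts,
                                      n_patterns=16)
        victim = labels.iloc[0]
        reduced = dg.build_pattern_table(
            labels.iloc[1:], small_world.food, small_world.impacts, n_patterns=16
        )
        changed = []
        for z in range(1, 17):
            a = full[full.pattern == z].drop(columns="pattern").iloc[0]
            b = reduced[reduced.pattern == z].drop(columns="pattern").iloc[0]
            same = all(
                (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y, abs=1e-12)
                for x, y in zip(a, b)
            )
            if not same:
                changed.append(z)
        assert changed == [int(victim["pattern"])]

    def test_unlabeled_record_errors(self, small_world):
        labels = small_world.labels.rename(columns={"archetype": "pattern"}).copy()
        labels.loc[0, "country"] = "NOWHERE"
        with pytest.raises(dg.EmissionError, match="NOWHERE"):
            dg.build_pattern_table(labels, small_world.food, small_world.impacts)

    def test_averaging_follows_membership_oracle(self, small_world):
        """Eq.-1 style averaging equals a brute-force mean over the members."""
        labels = small_world.labels.rename(columns={"archetype": "pattern"})
        table = dg.build_pattern_table(labels, small_world.food, small_world.impacts,
                                       n_patterns=16)
        ci = dg.country_intensities(small_world.food, small_world.impacts)
        values = {(r.country, r.year): r.oi_ratio for r in ci.itertuples(index=False)}
        for z in range(1, 17):
            members = [
                (r.country, r.year)
                for r in labels.itertuples(index=False)
                if r.pattern == z
            ]
            mean, n = dg.pattern_average(values, members)
            row = table[table.pattern == z].iloc[0]
            assert n == row["n_oi_ratio"]
            if n:
                assert mean == pytest.approx(row["oi_ratio"])
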