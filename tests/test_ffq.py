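"""FFQ engine: frequency mapping, gram conversion, nutrient derivation."""

import numpy as np
import pandas as pd
import pytest

import dietchange as dc
from dietchange import ffq
from dietchange import instrument as ins
from conftest import blank_record


class TestFrequencyMapping:
    def test_endpoints(self):
        assert dc.frequency_to_rate(0) == 0.0           # "never"
        assert dc.frequency_to_rate(8) == 4.0           # ">=4 times per day"

    def test_strictly_monotone(self):
        rates = [dc.frequency_to_rate(c) for c in range(9)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    @pytest.mark.parametrize("bad", [-1, 9, 3.5])
    def test_out_of_range_code_rejected(self, bad):
        with pytest.raises(ffq.FfqValidationError):
            dc.frequency_to_rate(bad)

    def test_non_monotone_rate_table_rejected(self):
        reversed_table = tuple(sorted(ins.DEFAULT_RATES_PER_DAY, reverse=True))
        with pytest.raises(ffq.FfqValidationError):
            dc.frequency_to_rate(3, rates=reversed_table)

    def test_never_anchor_required(self):
        shifted = tuple(r + 0.1 for r in ins.DEFAULT_RATES_PER_DAY)
        with pytest.raises(ffq.FfqValidationError):
            dc.frequency_to_rate(0, rates=shifted)


class TestGramIntake:
    def test_once_daily_times_portion(self, flat_portions):
        rec = blank_record()
        rec["ffq_egg"] = 6.0  # once per day
        flat_portions.base_portion_g["egg"] = 150.0
        grams = dc.gram_intake(rec, flat_portions)
        assert grams.loc[0, "egg"] == pytest.approx(150.0)

    def test_fractional_rate_hand_arithmetic(self, flat_portions):
        # 2-3 times per week (2.5/7 per day) of a 140 g portion -> 50 g/day
        rec = blank_record()
        rec["ffq_egg"] = 4.0
        flat_portions.base_portion_g["egg"] = 140.0
        grams = dc.gram_intake(rec, flat_portions)
        assert grams.loc[0, "egg"] == pytest.approx(2.5 * 140 / 7)

    def test_all_never_gives_zero_vector(self, record):
        grams = dc.gram_intake(record)
        assert (grams.to_numpy() == 0).all()

    def test_photo_item_uses_selected_plate(self):
        rec = blank_record(photo_level=3)
        rec["ffq_rice"] = 6.0
        grams = dc.gram_intake(rec)
        assert grams.loc[0, "rice"] == pytest.approx(
            ins.DEFAULT_PHOTO_GRAMS["staple"][2])

    def test_missing_photo_contributes_zero(self):
        rec = blank_record()
        rec["ffq_rice"] = 6.0
        rec["photo_staple"] = np.nan
        grams = dc.gram_intake(rec)
        assert grams.loc[0, "rice"] == 0.0

    def test_decreasing_photo_grams_rejected(self):
        with pytest.raises(ffq.FfqValidationError):
            dc.PortionModel(photo_grams={
                "staple": (250, 200, 150, 100),
                "meat": ins.DEFAULT_PHOTO_GRAMS["meat"],
                "vegetables": ins.DEFAULT_PHOTO_GRAMS["vegetables"]})


class TestNutrientIntake:
    def test_three_item_hand_sum_oracle(self, fct):
        rec = blank_record()
        rec["ffq_egg"] = 6.0
        rec["ffq_milk"] = 7.0
        rec["ffq_apple_pear"] = 5.0
        grams = dc.gram_intake(rec)
        nut = dc.nutrient_intake(grams, fct)
        for col in ("energy_kcal",) + ffq.NUTRIENTS:
            expected = sum(
                grams.loc[0, item] * fct.densities.loc[item, col] / 100.0
                for item in ("egg", "milk", "apple_pear"))
            assert nut.loc[0, col] == pytest.approx(expected, abs=1e-12)

    def test_energy_percent_convention(self, processed):
        # E% of protein/carb/fat must sum to exactly 100 in a no-alcohol model
        total = (processed["protein_epct"] + processed["carb_epct"]
                 + processed["fat_epct"])
        assert np.allclose(total, 100.0)
        # cholesterol treated as lipid: E% = 100 * 9 * g / kcal
        expect = 100 * 9 * processed["chol_g"] / processed["energy_kcal"]
        assert np.allclose(processed["chol_epct"], expect)

    def test_wholegrain_per_2000_kcal(self, fct):
        grams = pd.DataFrame(0.0, index=[0], columns=list(ins.ITEM_NAMES))
        nut = dc.nutrient_intake(grams, fct)
        assert nut.loc[0, "energy_zero"]
        assert np.isnan(nut.loc[0, "wholegrain_per2000"])
        # 60 g whole grain at 1500 kcal scales to 80 g / 2000 kcal
        assert 60 * 2000 / 1500 == pytest.approx(80.0)

    def test_linearity_doubling_rates(self, fct, flat_portions):
        rec = blank_record()
        rng = np.random.default_rng(5)
        for c in ins.FFQ_COLUMNS:
            rec[c] = float(rng.integers(0, 5))
        doubled = tuple(2 * r for r in ins.DEFAULT_RATES_PER_DAY)
        g1 = dc.gram_intake(rec, flat_portions)
        g2 = dc.gram_intake(rec, flat_portions, rates=doubled)
        assert np.allclose(2 * g1.to_numpy(), g2.to_numpy())
        n1 = dc.nutrient_intake(g1, fct)
        n2 = dc.nutrient_intake(g2, fct)
        assert np.allclose(2 * n1["energy_kcal"], n2["energy_kcal"])
        for col in ffq.EPCT_COLUMNS.values():
            assert np.allclose(n1[col], n2[col], equal_nan=True)


class TestHdsGroups:
    def test_fish_weekly_rates_sum(self, record):
        rec = record.copy()
        rec["ffq_fatty_fish"] = 3.0   # 1/week
        rec["ffq_lean_fish"] = 4.0    # 2-3/week
        freqs = dc.hds_group_frequencies(rec)
        assert freqs.loc[0, "fish"] == pytest.approx(1 / 7 + 2.5 / 7)
        assert freqs.loc[0, "fish"] == pytest.approx(0.5)

    def test_all_never_zero_groups(self, record):
        freqs = dc.hds_group_frequencies(record)
        assert (freqs.to_numpy() == 0).all()

    def test_eight_groups_present(self, record):
        freqs = dc.hds_group_frequencies(record)
        assert set(freqs.columns) == set(ins.HDS_GROUPS)
        assert len(freqs.columns) == 8

    def test_juice_in_fruit_group_rejected(self, record):
        bad = dict(ins.HDS_ITEM_MAP)
        bad["fruit_juice"] = "fruits"
        with pytest.raises(ValueError, match="juice"):
            dc.hds_group_frequencies(record, mapping=bad)

    def test_empty_group_rejected(self, record):
        bad = {k: v for k, v in ins.HDS_ITEM_MAP.items() if v != "fish"}
        with pytest.raises(ValueError, match="fish"):
            dc.hds_group_frequencies(record, mapping=bad)


class TestMissingFraction:
    @pytest.mark.parametrize("n_blank,expected,excl", [
        (0, 0.0, False), (6, 6 / 64, False), (7, 7 / 64, True)])
    def test_blank_counting(self, record, n_blank, expected, excl):
        rec = record.copy()
        for c in ins.FFQ_COLUMNS[:n_blank]:
            rec[c] = np.nan
        frac = dc.missing_fraction(rec)
        assert frac.iloc[0] == pytest.approx(expected)
        assert bool(frac.iloc[0] > 0.10) == excl
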