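"""FFQ conversion engine: frequency codes -> gram intakes -> daily nutrients.

Daily gram intake of an item is the reported intake frequency (times/day,
from the 9-level code) multiplied by a portion size in grams.  Staple foods,
meat dishes and vegetables take their portion from the selected portion
photograph; every other item uses a sex- and age-specific standard portion.
Nutrient intakes follow from a food composition table of densities per 100 g.

Energy percent (E%) uses the Atwater factors 4 kcal/g for protein and
carbohydrate (and sucrose), 9 kcal/g for fat, its subclasses and dietary
cholesterol.  Whole grain is additionally expressed per 2000 kcal, which is
the energy-standardised form used as a longitudinal exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import instrument as ins

NUTRIENTS = (
    "protein_g", "carb_g", "sucrose_g", "fat_g", "sfa_g", "pufa_g",
    "tfa_g", "chol_g", "wholegrain_g",
)
#: kcal per gram used for energy-percent views
ENERGY_FACTORS = {
    "protein_g": 4.0, "carb_g": 4.0, "sucrose_g": 4.0,
    "fat_g": 9.0, "sfa_g": 9.0, "pufa_g": 9.0, "tfa_g": 9.0, "chol_g": 9.0,
}
EPCT_COLUMNS = {
    "protein_g": "protein_epct", "carb_g": "carb_epct",
    "sucrose_g": "sucrose_epct", "fat_g": "fat_epct", "sfa_g": "sfa_epct",
    "pufa_g": "pufa_epct", "tfa_g": "tfa_epct", "chol_g": "chol_epct",
}


class FfqValidationError(ValueError):
    """Raised when FFQ codes, mappings or configuration tables are invalid."""


def frequency_to_rate(code, rates: tuple[float, ...] = ins.DEFAULT_RATES_PER_DAY):
    """Map a 9-level frequency code (0=never .. 8=">=4/day") to times/day.

    Accepts a scalar, array or Series; NaN (item left blank) propagates.
    """
    rates = validate_rate_table(rates)
    arr = np.asarray(code, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if vals.size and (np.any(vals < 0) or np.any(vals > 8) or np.any(vals != np.round(vals))):
        raise FfqValidationError("frequency codes must be integers in 0..8")
    out[ok] = np.asarray(rates)[vals.astype(int)]
    if np.isscalar(code):
        return float(out)
    if isinstance(code, pd.Series):
        return pd.Series(out, index=code.index)
    return out


def validate_rate_table(rates) -> tuple[float, ...]:
    rates = tuple(float(r) for r in rates)
    if len(rates) != ins.N_FREQ_LEVELS:
        raise FfqValidationError("rate table must have 9 levels")
    if rates[0] != 0.0:
        raise FfqValidationError("code 0 ('never') must map to 0/day")
    if any(b <= a for a, b in zip(rates, rates[1:])):
        raise FfqValidationError("rate table must be strictly increasing")
    if rates[8] < 4.0:
        raise FfqValidationError("code 8 must map to >= 4 times/day")
    return rates


@dataclass
class PortionModel:
    """Portion sizes: photograph grams per class plus per-item defaults."""

    photo_grams: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(ins.DEFAULT_PHOTO_GRAMS))
    base_portion_g: dict[str, float] = field(
        default_factory=lambda: {it.name: it.portion_g for it in ins.ITEMS
                                 if it.photo_class is None})
    sex_factor: dict[str, float] = field(
        default_factory=lambda: dict(ins.PORTION_SEX_FACTOR))
    age_factor: dict[int, float] = field(
        default_factory=lambda: dict(ins.PORTION_AGE_FACTOR))

    def __post_init__(self):
        for cls, grams in self.photo_grams.items():
            if len(grams) != 4 or any(g <= 0 for g in grams):
                raise FfqValidationError(f"photo grams for {cls} must be 4 positive values")
            if any(b <= a for a, b in zip(grams, grams[1:])):
                raise FfqValidationError(
                    f"photo grams for {cls} must be strictly increasing")
        if any(g <= 0 for g in self.base_portion_g.values()):
            raise FfqValidationError("default portions must be positive")

    def default_grams(self, item: str, sex: str, age_group: int) -> float:
        return (self.base_portion_g[item]
                * self.sex_factor[sex] * self.age_factor[int(age_group)])


class FoodCompositionTable:
    """Nutrient densities per 100 g for each FFQ item.

    Wraps a DataFrame indexed by item name with one column per nutrient in
    :data:`NUTRIENTS` plus ``energy_kcal``.  Construction validates
    non-negativity, the sucrose/carbohydrate and fat-subclass hierarchies and
    that item energy equals the Atwater combination of its macronutrients.
    """

    def __init__(self, densities: pd.DataFrame):
        missing = [c for c in ("energy_kcal",) + NUTRIENTS if c not in densities.columns]
        if missing:
            raise FfqValidationError(f"composition table missing columns: {missing}")
        if list(densities.index) != list(ins.ITEM_NAMES):
            raise FfqValidationError("composition table must cover the 64 items in order")
        if (densities[list(NUTRIENTS)] < 0).any().any():
            raise FfqValidationError("nutrient densities must be >= 0")
        if (densities["sucrose_g"] > densities["carb_g"] + 1e-9).any():
            raise FfqValidationError("sucrose density cannot exceed carbohydrate")
        fat_sub = densities[["sfa_g", "pufa_g", "tfa_g"]].sum(axis=1)
        if (fat_sub > densities["fat_g"] + 1e-9).any():
            raise FfqValidationError("fat subclasses cannot exceed total fat")
        atwater = (4 * densities["protein_g"] + 4 * densities["carb_g"]
                   + 9 * densities["fat_g"])
        if not np.allclose(densities["energy_kcal"], atwater, atol=1e-6):
            raise FfqValidationError("item energy must equal Atwater combination")
        self.densities = densities

    def to_tsv(self, path) -> None:
        self.densities.rename_axis("item").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FoodCompositionTable":
        return cls(pd.read_csv(path, sep="\t", index_col="item"))


def _rates_matrix(codes: pd.DataFrame, rates=ins.DEFAULT_RATES_PER_DAY) -> pd.DataFrame:
    """Frequency codes (n x 64, NaN=blank) -> times/day; blanks become 0."""
    vals = codes.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 8:
        raise FfqValidationError("frequency codes must be in 0..8")
    table = np.asarray(validate_rate_table(rates))
    out = np.zeros_like(vals)
    ok = ~np.isnan(vals)
    out[ok] = table[vals[ok].astype(int)]
    return pd.DataFrame(out, index=codes.index, columns=list(ins.ITEM_NAMES))


def gram_intake(records: pd.DataFrame, portions: PortionModel | None = None,
                rates=ins.DEFAULT_RATES_PER_DAY) -> pd.DataFrame:
    """Daily gram intake per item for each record (row).

    ``records`` must carry the 64 ``ffq_<item>`` code columns, the three
    ``photo_<class>`` selections (1-4) and ``sex`` / ``age_group`` columns.
    Blank items contribute zero grams (heavy missingness is handled by the
    exclusion cascade, not by imputation); a missing portion photograph makes
    the items of that class contribute zero and is likewise an exclusion
    matter.
    """
    portions = portions or PortionModel()
    codes = records[list(ins.FFQ_COLUMNS)].copy()
    codes.columns = list(ins.ITEM_NAMES)
    rate = _rates_matrix(codes, rates)

    n = len(records)
    portion = np.zeros((n, ins.N_ITEMS))
    sexes = records["sex"].to_numpy()
    ages = records["age_group"].to_numpy()
    for j, it in enumerate(ins.ITEMS):
        if it.photo_class is not None:
            levels = records[f"photo_{it.photo_class}"].to_numpy(dtype=float)
            grams = np.asarray(portions.photo_grams[it.photo_class])
            col = np.full(n, np.nan)
            ok = ~np.isnan(levels)
            if np.any((levels[ok] < 1) | (levels[ok] > 4)):
                raise FfqValidationError("photo selections must be in 1..4")
            col[ok] = grams[levels[ok].astype(int) - 1]
            portion[:, j] = np.where(np.isnan(col), 0.0, col)
        else:
            factors = np.array([
                portions.default_grams(it.name, s, a) for s, a in zip(sexes, ages)
            ])
            portion[:, j] = factors
    return pd.DataFrame(rate.to_numpy() * portion, index=records.index,
                        columns=list(ins.ITEM_NAMES))


def nutrient_intake(grams: pd.DataFrame, fct: FoodCompositionTable) -> pd.DataFrame:
    """Daily nutrient intakes plus energy-percent views.

    Each nutrient is sum over items of grams/100 x density; energy likewise.
    Records with zero total energy get NaN E% and are flagged via the
    returned ``energy_zero`` column.
    """
    dens = fct.densities
    g = grams[list(ins.ITEM_NAMES)].to_numpy()
    out = pd.DataFrame(index=grams.index)
    out["energy_kcal"] = g @ (dens["energy_kcal"].to_numpy() / 100.0)
    for nut in NUTRIENTS:
        out[nut] = g @ (dens[nut].to_numpy() / 100.0)
    energy = out["energy_kcal"].to_numpy()
    zero = energy <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for nut, col in EPCT_COLUMNS.items():
            e_from = ENERGY_FACTORS[nut] * out[nut].to_numpy()
            out[col] = np.where(zero, np.nan, 100.0 * e_from / energy)
        out["wholegrain_per2000"] = np.where(
            zero, np.nan, out["wholegrain_g"].to_numpy() * 2000.0 / energy)
    out["energy_zero"] = zero
    return out


def hds_group_frequencies(records: pd.DataFrame,
                          mapping: dict[str, str] | None = None,
                          rates=ins.DEFAULT_RATES_PER_DAY) -> pd.DataFrame:
    """Intake frequency per day for the eight HDS food/beverage groups."""
    mapping = mapping if mapping is not None else ins.HDS_ITEM_MAP
    ins.validate_hds_map(mapping)
    codes = records[list(ins.FFQ_COLUMNS)].copy()
    codes.columns = list(ins.ITEM_NAMES)
    rate = _rates_matrix(codes, rates)
    out = pd.DataFrame(index=records.index)
    for group in ins.HDS_GROUPS:
        members = [item for item, grp in mapping.items() if grp == group]
        out[group] = rate[members].sum(axis=1)
    return out


def missing_fraction(records: pd.DataFrame) -> pd.Series:
    """Fraction of the 64 FFQ items left blank per record."""
    codes = records[list(ins.FFQ_COLUMNS)]
    return codes.isna().sum(axis=1) / ins.N_ITEMS


def dii_parameter_intakes(grams: pd.DataFrame) -> pd.DataFrame:
    """Daily intake of the 30 DII food parameters.

    28 parameters are single-item gram intakes; caffeine merges the caffeine
    contributed by coffee and tea (mg/day); tea is also kept as its own
    (gram) parameter.
    """
    out = pd.DataFrame(index=grams.index)
    for name in ins.DII_ITEM_PARAMS:
        out[name] = grams[name]
    out["caffeine"] = sum(
        grams[bev] * mg for bev, mg in ins.CAFFEINE_MG_PER_G.items())
    out["tea"] = grams["tea"]
    return out


def process_records(records: pd.DataFrame, fct: FoodCompositionTable,
                    portions: PortionModel | None = None,
                    rates=ins.DEFAULT_RATES_PER_DAY) -> pd.DataFrame:
    """Full FFQ derivation for a cohort table: nutrients, E%, group
    frequencies, missing fraction.  Returns the input with derived columns
    appended (original columns untouched)."""
    grams = gram_intake(records, portions, rates)
    nut = nutrient_intake(grams, fct)
    groups = hds_group_frequencies(records, rates=rates)
    groups.columns = [f"grp_{c}" for c in groups.columns]
    dii_in = dii_parameter_intakes(grams)
    dii_in.columns = [f"dii_{c}" for c in dii_in.columns]
    extra = pd.concat([nut, groups, dii_in], axis=1)
    extra["ffq_missing_frac"] = missing_fraction(records)
    return pd.concat([records, extra], axis=1)
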