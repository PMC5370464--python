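"""Layout of the 64-item semi-quantitative food frequency questionnaire.

The instrument records, for each food item, how often it was consumed on a
9-level scale from "never" to ">=4 times per day".  Portion sizes for staple
foods, meat dishes and vegetables are picked from photographs of four plates
of increasing size; every other item uses a sex- and age-specific standard
portion.  Eight food/beverage groups feed the Healthy Diet Score and 30 food
parameters feed the modified Dietary Inflammatory Index (coffee and tea
caffeine are merged into a single caffeine parameter while tea is also kept
as a parameter of its own).
"""

from __future__ import annotations

from dataclasses import dataclass

# --- 9-level frequency scale -------------------------------------------------
# The instrument anchors only the endpoints ("never", ">=4 times per day");
# the intermediate rates below are the package's documented default mapping
# and can be replaced by loading an alternative (strictly increasing) table.
DEFAULT_RATES_PER_DAY: tuple[float, ...] = (
    0.0,          # 0: never
    6 / 365.25,   # 1: ~6 times per year
    2 / 30.4375,  # 2: ~2 times per month
    1 / 7,        # 3: 1 time per week
    2.5 / 7,      # 4: 2-3 times per week
    5 / 7,        # 5: 5-6 times per week
    1.0,          # 6: 1 time per day
    2.5,          # 7: 2-3 times per day
    4.0,          # 8: >=4 times per day
)

N_FREQ_LEVELS = 9
N_ITEMS = 64

# HDS food/beverage groups: four favorable, four unfavorable.
FAVORABLE_GROUPS = ("fish", "fruits", "vegetables", "whole_grains")
UNFAVORABLE_GROUPS = (
    "red_processed_meat",
    "desserts_sweets",
    "sugar_sweetened_beverages",
    "fried_potatoes",
)
HDS_GROUPS = FAVORABLE_GROUPS + UNFAVORABLE_GROUPS

# Portion-photograph classes (four plates each).
PHOTO_CLASSES = ("staple", "meat", "vegetables")

# Grams corresponding to the four portion photographs, per class.
DEFAULT_PHOTO_GRAMS: dict[str, tuple[float, float, float, float]] = {
    "staple": (100.0, 150.0, 200.0, 250.0),
    "meat": (60.0, 90.0, 120.0, 150.0),
    "vegetables": (40.0, 70.0, 100.0, 130.0),
}

# Sex / age-group multipliers applied to an item's standard portion when no
# photograph class applies.
PORTION_SEX_FACTOR = {"F": 0.87, "M": 1.15}
PORTION_AGE_FACTOR = {30: 1.05, 40: 1.00, 50: 0.95, 60: 0.90}


@dataclass(frozen=True)
class ItemDef:
    """Static definition of one FFQ item."""

    name: str
    category: str               # drives synthetic nutrient densities
    hds_group: str | None       # one of HDS_GROUPS, or None
    photo_class: str | None     # one of PHOTO_CLASSES, or None
    dii_param: bool             # item's gram intake is a DII food parameter
    portion_g: float            # standard portion before sex/age scaling
    freq_mu: float              # typical frequency level (0-8), synthetic use


# name, category, hds_group, photo_class, dii, portion_g, freq_mu
_RAW_ITEMS: list[tuple] = [
    # fish & shellfish (favorable: fish)
    ("fatty_fish",        "fish",         "fish", None, True,  125, 3.2),
    ("lean_fish",         "fish",         "fish", None, True,  125, 3.4),
    ("shellfish",         "fish",         "fish", None, True,   80, 2.2),
    ("fish_dish",         "fish",         "fish", None, False, 150, 3.0),
    # fruits (favorable; juice deliberately outside the group)
    ("apple_pear",        "fruit",        "fruits", None, True, 110, 5.2),
    ("banana",            "fruit",        "fruits", None, True, 100, 4.8),
    ("citrus_fruit",      "fruit",        "fruits", None, True, 120, 4.4),
    ("berries",           "fruit",        "fruits", None, True,  80, 3.6),
    ("other_fruit",       "fruit",        "fruits", None, False, 100, 4.0),
    ("fruit_juice",       "juice",        None, None, False, 180, 4.2),
    # vegetables (favorable; potatoes outside the group)
    ("carrots",           "vegetable",    "vegetables", "vegetables", True, 0, 4.8),
    ("cabbage",           "vegetable",    "vegetables", "vegetables", True, 0, 3.6),
    ("tomato",            "vegetable",    "vegetables", "vegetables", True, 0, 4.8),
    ("lettuce_leafy",     "vegetable",    "vegetables", "vegetables", False, 0, 4.6),
    ("peas_beans",        "vegetable",    "vegetables", "vegetables", True, 0, 3.4),
    ("onion_leek",        "vegetable",    "vegetables", "vegetables", True, 0, 4.2),
    ("other_vegetables",  "vegetable",    "vegetables", "vegetables", False, 0, 4.2),
    ("boiled_potatoes",   "potato",       None, "staple", False, 0, 5.2),
    # whole grains (favorable)
    ("oatmeal_porridge",  "grain_whole",  "whole_grains", None, True, 220, 4.0),
    ("wholegrain_bread",  "grain_whole",  "whole_grains", None, True,  40, 6.2),
    ("crispbread",        "grain_whole",  "whole_grains", None, False,  15, 5.6),
    ("muesli_bran",       "grain_whole",  "whole_grains", None, True,   45, 3.2),
    # refined grains / staples
    ("white_bread",       "grain_refined", None, None, False, 40, 5.0),
    ("pasta",             "grain_refined", None, "staple", False, 0, 3.8),
    ("rice",              "grain_refined", None, "staple", False, 0, 3.4),
    ("pancakes",          "grain_refined", None, None, False, 120, 2.6),
    # red / processed meat (unfavorable)
    ("beef_pork_dish",    "meat_red",     "red_processed_meat", "meat", True, 0, 4.4),
    ("minced_meat_dish",  "meat_red",     "red_processed_meat", "meat", False, 0, 4.2),
    ("sausage",           "meat_processed", "red_processed_meat", "meat", True, 0, 3.8),
    ("cold_cuts",         "meat_processed", "red_processed_meat", None, True, 25, 4.6),
    ("blood_pudding",     "meat_processed", "red_processed_meat", None, False, 100, 1.8),
    # other animal foods
    ("chicken",           "poultry",      None, "meat", False, 0, 3.6),
    ("egg",               "egg",          None, None, True, 55, 4.2),
    # desserts & sweets (unfavorable)
    ("sweet_buns",        "dessert",      "desserts_sweets", None, False, 50, 3.8),
    ("cookies_cakes",     "dessert",      "desserts_sweets", None, False, 40, 3.6),
    ("chocolate",         "dessert",      "desserts_sweets", None, True, 30, 3.4),
    ("candy_sweets",      "dessert",      "desserts_sweets", None, True, 30, 3.2),
    ("ice_cream",         "dessert",      "desserts_sweets", None, False, 70, 2.8),
    ("dessert_pudding",   "dessert",      "desserts_sweets", None, False, 100, 2.2),
    # sugar-sweetened beverages (unfavorable)
    ("soft_drink_sugar",  "ssb",          "sugar_sweetened_beverages", None, True, 200, 2.8),
    ("fruit_syrup_drink", "ssb",          "sugar_sweetened_beverages", None, False, 200, 2.6),
    # fried potatoes (unfavorable)
    ("french_fries",      "fried_potato", "fried_potatoes", "staple", True, 0, 2.2),
    ("fried_potatoes",    "fried_potato", "fried_potatoes", "staple", False, 0, 2.4),
    # snacks & nuts
    ("potato_crisps",     "snack",        None, None, False, 30, 2.4),
    ("nuts_almonds",      "nut",          None, None, False, 25, 2.6),
    # dairy
    ("milk",              "dairy_milk",   None, None, True, 200, 5.8),
    ("sour_milk_yoghurt", "dairy_milk",   None, None, False, 180, 4.6),
    ("cheese",            "dairy_cheese", None, None, True, 20, 5.6),
    ("cream",             "dairy_cream",  None, None, False, 25, 2.8),
    # fats & oils
    ("butter_on_bread",   "fat_butter",   None, None, True, 8, 5.2),
    ("margarine_on_bread","fat_margarine", None, None, True, 8, 5.2),
    ("cooking_fat",       "fat_margarine", None, None, False, 10, 4.8),
    ("oil_dressing",      "fat_oil",      None, None, True, 10, 3.8),
    ("mayonnaise_sauce",  "fat_oil",      None, None, False, 15, 2.8),
    # beverages
    ("coffee",            "beverage",     None, None, False, 150, 6.8),
    ("tea",               "beverage",     None, None, True, 180, 4.0),
    ("light_beer",        "beverage_energy", None, None, False, 250, 2.6),
    ("diet_soft_drink",   "beverage",     None, None, False, 200, 2.4),
    # sugar & spreads
    ("sugar_in_coffee_tea", "sugar",      None, None, False, 5, 3.6),
    ("jam_marmalade",     "sugar",        None, None, False, 20, 3.8),
    ("honey_syrup",       "sugar",        None, None, False, 12, 2.0),
    # mixed dishes
    ("pizza",             "mixed",        None, None, False, 200, 2.6),
    ("meat_soup_stew",    "mixed",        None, "meat", False, 0, 3.0),
    ("vegetarian_dish",   "mixed",        None, "vegetables", False, 0, 2.4),
]

ITEMS: tuple[ItemDef, ...] = tuple(
    ItemDef(name, cat, grp, photo, dii, portion, mu)
    for name, cat, grp, photo, dii, portion, mu in _RAW_ITEMS
)

ITEM_NAMES: tuple[str, ...] = tuple(it.name for it in ITEMS)
FFQ_COLUMNS: tuple[str, ...] = tuple(f"ffq_{name}" for name in ITEM_NAMES)
PHOTO_COLUMNS: tuple[str, ...] = tuple(f"photo_{c}" for c in PHOTO_CLASSES)

# item -> HDS group (only mapped items)
HDS_ITEM_MAP: dict[str, str] = {
    it.name: it.hds_group for it in ITEMS if it.hds_group is not None
}

# DII food parameters: 28 single-item parameters + merged caffeine + tea.
# Tea appears both through its caffeine contribution and as its own parameter.
DII_ITEM_PARAMS: tuple[str, ...] = tuple(
    it.name for it in ITEMS if it.dii_param and it.name != "tea"
)
DII_PARAMS: tuple[str, ...] = DII_ITEM_PARAMS + ("caffeine", "tea")

# caffeine content (mg per gram of beverage) used to merge coffee and tea
# caffeine into the single caffeine parameter
CAFFEINE_MG_PER_G = {"coffee": 0.40, "tea": 0.20}

# sign of the literature-derived inflammatory effect per synthetic parameter:
# -1 anti-inflammatory, +1 pro-inflammatory
_ANTI_CATEGORIES = {"fish", "fruit", "vegetable", "grain_whole", "fat_oil", "nut"}
_PRO_CATEGORIES = {
    "meat_red", "meat_processed", "dessert", "ssb", "fried_potato",
    "fat_butter", "fat_margarine", "dairy_cheese", "egg", "snack", "sugar",
}
_ITEM_BY_NAME = {it.name: it for it in ITEMS}


def dii_effect_sign(param: str) -> int:
    """Sign convention of a DII parameter's inflammatory effect weight."""
    if param == "caffeine" or param == "tea":
        return -1
    cat = _ITEM_BY_NAME[param].category
    if cat in _ANTI_CATEGORIES:
        return -1
    if cat in _PRO_CATEGORIES:
        return +1
    return +1  # dairy milk etc.: mildly pro by default


def validate_hds_map(mapping: dict[str, str]) -> None:
    """Reject HDS group maps that violate the score's definition.

    Every group must have at least one member, only the eight defined groups
    may appear, and items excluded from a group by definition (juices from
    fruits, non-fried potatoes from vegetables) may not be mapped into it.
    """
    bad = set(mapping.values()) - set(HDS_GROUPS)
    if bad:
        raise ValueError(f"unknown HDS groups: {sorted(bad)}")
    for group in HDS_GROUPS:
        if group not in mapping.values():
            raise ValueError(f"HDS group '{group}' has no member items")
    for item, group in mapping.items():
        cat = _ITEM_BY_NAME[item].category if item in _ITEM_BY_NAME else None
        if group == "fruits" and cat == "juice":
            raise ValueError("juices may not be mapped to the fruit group")
        if group == "vegetables" and cat == "potato":
            raise ValueError("potatoes may not be mapped to the vegetable group")
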