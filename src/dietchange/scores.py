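"""Diet quality scores: Healthy Diet Score and modified Dietary Inflammatory Index.

The Healthy Diet Score (HDS) ranks intake frequency of eight food/beverage
groups within each sex into quartile ranks 0-3 — ascending for the four
favorable groups (fish; fruits excluding juices; vegetables excluding
potatoes; whole grains) and descending for the four unfavorable groups (red
or processed meat; desserts and sweets; sugar-sweetened beverages; fried
potatoes) — and sums them, giving an integer from 0 to 24 where higher means
healthier choices.

The modified Dietary Inflammatory Index (DII) expresses each of 30 food
parameters as a z-score against a global reference mean/SD, multiplies by a
literature-derived signed inflammatory effect weight, and sums; lower values
are more anti-inflammatory.  Coffee and tea caffeine enter as one merged
caffeine parameter while tea is also kept as its own parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import instrument as ins


class ScoreError(ValueError):
    pass


@dataclass
class HdsConfig:
    favorable: tuple[str, ...] = ins.FAVORABLE_GROUPS
    unfavorable: tuple[str, ...] = ins.UNFAVORABLE_GROUPS

    def __post_init__(self):
        if set(self.favorable) & set(self.unfavorable):
            raise ScoreError("favorable and unfavorable groups must be disjoint")
        if len(self.favorable) + len(self.unfavorable) != 8:
            raise ScoreError("HDS uses exactly eight groups")


class DiiConfig:
    """Global reference mean, SD and signed effect weight per DII parameter."""

    def __init__(self, table: pd.DataFrame):
        need = {"global_mean", "global_sd", "effect_weight"}
        if not need <= set(table.columns):
            raise ScoreError(f"DII table needs columns {sorted(need)}")
        if (table["global_sd"] <= 0).any():
            raise ScoreError("DII global SDs must be positive")
        self.table = table

    @property
    def parameters(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("parameter").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DiiConfig":
        return cls(pd.read_csv(path, sep="\t", index_col="parameter"))


def quartile_rank(values: pd.Series, sex: pd.Series,
                  direction: str = "ascending") -> pd.Series:
    """Quartile rank 0-3 of each value within its sex stratum.

    Cuts at the within-sex P25/P50/P75 (linear interpolation).  Ascending:
    higher intake -> higher rank; descending reverses.  Values tied exactly
    with a cut point take the lower quartile's rank (deterministic tie
    policy).  Strata need at least four subjects.
    """
    if direction not in ("ascending", "descending"):
        raise ScoreError(f"unknown direction {direction!r}")
    out = pd.Series(0, index=values.index, dtype=int)
    for s, idx in values.groupby(sex).groups.items():
        vals = values.loc[idx].to_numpy(dtype=float)
        if len(vals) < 4:
            raise ScoreError(f"sex stratum {s!r} too small for quartile ranks")
        cuts = np.percentile(vals, [25, 50, 75])
        rank = (vals[:, None] > cuts[None, :]).sum(axis=1)
        if direction == "descending":
            rank = 3 - rank
        out.loc[idx] = rank
    return out


def healthy_diet_score(group_freqs: pd.DataFrame, sex: pd.Series,
                       config: HdsConfig | None = None) -> pd.Series:
    """HDS per subject: sum of eight within-sex quartile ranks, 0-24."""
    config = config or HdsConfig()
    missing = [g for g in config.favorable + config.unfavorable
               if g not in group_freqs.columns]
    if missing:
        raise ScoreError(f"missing HDS group frequencies: {missing}")
    total = pd.Series(0, index=group_freqs.index, dtype=int)
    for g in config.favorable:
        total += quartile_rank(group_freqs[g], sex, "ascending")
    for g in config.unfavorable:
        total += quartile_rank(group_freqs[g], sex, "descending")
    return total


def dii_score(param_intakes: pd.DataFrame, config: DiiConfig,
              transform: str = "identity") -> pd.Series:
    """Modified DII per subject.

    Per parameter, z = (intake - global_mean) / global_sd; the contribution
    is transform(z) * effect_weight and contributions are summed.  The
    default transform is the identity; ``transform="percentile"`` applies the
    centered-percentile form 2*Phi(z) - 1 used by the original index.
    """
    missing = [p for p in config.parameters if p not in param_intakes.columns]
    if missing:
        raise ScoreError(f"missing DII parameter intakes: {missing}")
    if transform not in ("identity", "percentile"):
        raise ScoreError(f"unknown transform {transform!r}")
    tbl = config.table
    x = param_intakes[config.parameters].to_numpy(dtype=float)
    z = (x - tbl["global_mean"].to_numpy()) / tbl["global_sd"].to_numpy()
    if transform == "percentile":
        z = 2.0 * stats.norm.cdf(z) - 1.0
    contrib = z * tbl["effect_weight"].to_numpy()
    return pd.Series(contrib.sum(axis=1), index=param_intakes.index)


def score_cohort(processed: pd.DataFrame, dii_config: DiiConfig,
                 hds_config: HdsConfig | None = None,
                 dii_transform: str = "identity") -> pd.DataFrame:
    """Append ``hds`` and ``dii`` columns to a processed cohort table.

    Quartile ranks are computed within sex, separately per visit, so the
    score is a within-cohort relative measure at each time point.
    """
    out = processed.copy()
    out["hds"] = np.nan
    out["dii"] = np.nan
    group_cols = {g: f"grp_{g}" for g in ins.HDS_GROUPS}
    dii_cols = {p: f"dii_{p}" for p in dii_config.parameters}
    for visit in sorted(out["visit"].unique()):
        sel = out["visit"] == visit
        freqs = out.loc[sel, list(group_cols.values())].copy()
        freqs.columns = list(group_cols)
        out.loc[sel, "hds"] = healthy_diet_score(
            freqs, out.loc[sel, "sex"], hds_config).astype(float)
        intakes = out.loc[sel, list(dii_cols.values())].copy()
        intakes.columns = list(dii_cols)
        out.loc[sel, "dii"] = dii_score(intakes, dii_config, dii_transform)
    return out
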