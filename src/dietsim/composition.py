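"""Food-group composition tables and the subtotal arithmetic behind them.

The central container is :class:`GroupIntakeTable`: per food group (NOVA
groups plus the named scenario groups — fruits, vegetables, nuts,
high-omega-3 fish, oils), the daily nutrient subtotal that group contributes
to the population-average diet.  Aggregating over groups gives the all-food
nutrient intake; dividing a subtotal by its gram weight gives a per-100 g
composition profile.

I/O is plain CSV: one row per canonical nutrient, one column per group,
``#`` comment lines allowed.  Packaged fixtures encode the survey's baseline
group intakes and a published modelled-intake reference table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .nutrients import (
    NUTRIENTS,
    NutrientValidationError,
    NutrientVector,
    derived_gi,
)

__all__ = [
    "FoodGroupProfile",
    "GroupIntakeTable",
    "SchemaError",
    "read_group_intake_table",
    "aggregate_total",
    "profile_from_subtotal",
    "load_baseline_intakes",
    "load_modelled_reference",
    "load_printed_totals",
    "derive_added_food_profiles",
    "baseline_profiles",
    "load_oil_profiles",
    "default_profiles",
]

#: Well-known group ids.  User-defined ids are also accepted everywhere.
KNOWN_GROUPS = (
    "PF", "MP", "PCI",
    "fruits", "vegetables", "nuts", "omega3_fish",
    "sfa_oils", "healthy_oils",
)

#: Grams of each food added in the packaged modelled-reference scenario;
#: used to derive the added-food per-100 g profiles by differencing.
REFERENCE_ADDED_GRAMS = {
    "fruits": 150.0,
    "vegetables": 225.0,
    "nuts": 30.0,
    "omega3_fish": 40.0,
}


class SchemaError(ValueError):
    """An input table does not match the documented CSV schema."""


@dataclass(frozen=True)
class FoodGroupProfile:
    """Per-100 g composition of a food or food group."""

    group_id: str
    per_100g: NutrientVector

    def __post_init__(self) -> None:
        if abs(self.per_100g.gram_weight - 100.0) > 1e-6:
            raise NutrientValidationError(
                f"profile {self.group_id!r}: per-100 g gram weight is "
                f"{self.per_100g.gram_weight}, expected exactly 100"
            )

    def amount(self, grams: float) -> NutrientVector:
        """Nutrient contribution of ``grams`` of this food."""
        if grams < 0:
            raise ValueError("grams must be non-negative")
        return self.per_100g.scale(grams / 100.0)


class GroupIntakeTable:
    """Per-group daily nutrient subtotals (nutrients x groups).

    Provenance distinguishes the survey baseline from scenario output.
    Instances are treated as immutable; edits return new tables.
    """

    def __init__(
        self,
        data: Union[pd.DataFrame, Mapping[str, NutrientVector]],
        *,
        provenance: str = "baseline",
        validate: bool = True,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            df = data.astype(float).copy()
        else:
            df = pd.DataFrame({g: v.series for g, v in data.items()})
        if df.columns.duplicated().any():
            raise SchemaError("duplicate group ids")
        df = df.reindex(list(NUTRIENTS))
        self._df = df
        self.provenance = provenance
        if validate:
            for g in df.columns:
                try:
                    NutrientVector(df[g])
                except NutrientValidationError as exc:
                    raise NutrientValidationError(f"group {g!r}: {exc}") from exc

    # -- container protocol ------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return list(self._df.columns)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._df.columns

    def vector(self, group_id: str) -> NutrientVector:
        if group_id not in self._df.columns:
            raise KeyError(f"unknown group {group_id!r}; have {self.groups}")
        return NutrientVector(self._df[group_id], validate=False)

    def with_group(self, group_id: str, vector: NutrientVector,
                   *, provenance: str | None = None) -> "GroupIntakeTable":
        df = self._df.copy()
        df[group_id] = vector.series
        return GroupIntakeTable(
            df, provenance=provenance or self.provenance, validate=False
        )

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def relabel(self, provenance: str) -> "GroupIntakeTable":
        return GroupIntakeTable(self._df, provenance=provenance, validate=False)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        *,
        allow_missing_as_zero: bool = False,
        provenance: str = "baseline",
    ) -> "GroupIntakeTable":
        try:
            raw = pd.read_csv(path, comment="#", index_col=0, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: empty or headerless file") from exc
        if raw.empty or len(raw.columns) == 0:
            raise SchemaError(f"{path}: no group columns found")
        try:
            df = raw.apply(lambda col: pd.to_numeric(col, errors="raise"))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: unparseable cell ({exc})") from exc
        missing = [n for n in NUTRIENTS if n not in df.index]
        if missing:
            if not allow_missing_as_zero:
                raise SchemaError(
                    f"{path}: missing required nutrient rows {missing} "
                    "(pass allow_missing_as_zero=True to treat them as 0)"
                )
            for n in missing:
                df.loc[n] = (
                    np.nan if n == "glycaemic_index" else 0.0
                )
        unknown = [n for n in df.index if n not in NUTRIENTS]
        if unknown:
            raise SchemaError(f"{path}: unknown nutrient rows {unknown}")
        if df.isna().any().any() and not allow_missing_as_zero:
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise SchemaError(f"{path}: blank cells in rows {bad}")
        table = df.reindex(list(NUTRIENTS))
        if table.loc["glycaemic_index"].isna().any():
            gi = [
                derived_gi(table.loc["glycaemic_load", g], table.loc["carbohydrate", g])
                if np.isnan(table.loc["glycaemic_index", g])
                else table.loc["glycaemic_index", g]
                for g in table.columns
            ]
            table.loc["glycaemic_index"] = gi
        table = table.fillna(0.0)
        return cls(table, provenance=provenance)

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self._df.copy()
        out.index.name = "nutrient"
        out.to_csv(path)

    # -- arithmetic --------------------------------------------------------
    def aggregate_total(self) -> NutrientVector:
        """All-food nutrient totals: additive fields summed over groups,
        glycaemic index re-derived as ``100 * sum(GL) / sum(CHO)``."""
        if not self.groups:
            raise SchemaError("cannot aggregate an empty table")
        s = self._df.sum(axis=1)
        s["glycaemic_index"] = derived_gi(s["glycaemic_load"], s["carbohydrate"])
        return NutrientVector(s, validate=False)

    def __repr__(self) -> str:
        return (
            f"GroupIntakeTable(groups={self.groups}, "
            f"provenance={self.provenance!r})"
        )


# -- module-level operation wrappers ---------------------------------------

def read_group_intake_table(
    path: Union[str, Path], *, allow_missing_as_zero: bool = False,
    provenance: str = "baseline",
) -> GroupIntakeTable:
    """Read a validated group-intake table from CSV.

    The schema is one row per canonical nutrient id, one column per group,
    UTF-8, decimal point.  Unparseable cells raise :class:`SchemaError`;
    values are never silently zeroed unless ``allow_missing_as_zero``.
    """
    return GroupIntakeTable.from_csv(
        path, allow_missing_as_zero=allow_missing_as_zero, provenance=provenance
    )


def aggregate_total(table: GroupIntakeTable) -> NutrientVector:
    return table.aggregate_total()


def profile_from_subtotal(subtotal: NutrientVector, group_id: str = "custom") -> FoodGroupProfile:
    """Per-100 g profile implied by a daily subtotal (its average density)."""
    return FoodGroupProfile(group_id=group_id, per_100g=subtotal.per_100g())


# -- packaged fixtures ------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("dietsim.data").joinpath(name)


def load_baseline_intakes() -> GroupIntakeTable:
    """Baseline per-group population intakes (survey women aged 19-50)."""
    with importlib.resources.as_file(_data_path("group_intakes_baseline.csv")) as p:
        return GroupIntakeTable.from_csv(p, provenance="baseline")


def load_modelled_reference() -> GroupIntakeTable:
    """Published modelled per-group intakes for the reference combination
    scenario (halve PF; +150 g fruits, +225 g vegetables, +30 g nuts,
    +40 g high-omega-3 fish per day)."""
    with importlib.resources.as_file(
        _data_path("group_intakes_modelled_reference.csv")
    ) as p:
        return GroupIntakeTable.from_csv(p, provenance="modelled")


def load_printed_totals() -> pd.DataFrame:
    """Printed all-food totals (baseline and modelled reference columns).

    These are rounded presentation values used only for cross-checks; the
    printed baseline GI (54.8) is not exactly 100*GL/CHO of its own row, so
    the frame is returned as-is rather than as validated vectors.
    """
    with importlib.resources.as_file(_data_path("printed_totals.csv")) as p:
        return pd.read_csv(p, comment="#", index_col=0)


def derive_added_food_profiles() -> dict[str, FoodGroupProfile]:
    """Per-100 g profiles of the foods *added* in the scenarios.

    The added fruits/vegetables/nuts/fish are specific healthy foods, not
    the baseline group average (e.g. added fruit is far more energy-dense
    than the baseline fruit-group mean, which is diluted by juices).  Their
    composition is recovered by differencing the modelled-reference table
    against baseline and dividing by the grams added.
    """
    base = load_baseline_intakes().to_frame()
    mod = load_modelled_reference().to_frame()
    profiles = {}
    for g, grams in REFERENCE_ADDED_GRAMS.items():
        diff = (mod[g] - base[g]) * 100.0 / grams
        diff["glycaemic_index"] = derived_gi(
            diff["glycaemic_load"], diff["carbohydrate"]
        )
        profiles[g] = FoodGroupProfile(g, NutrientVector(diff))
    return profiles


def baseline_profiles(groups: Iterable[str] | None = None) -> dict[str, FoodGroupProfile]:
    """Alternative profile set: each baseline group's own average density."""
    table = load_baseline_intakes()
    out = {}
    for g in groups or table.groups:
        out[g] = profile_from_subtotal(table.vector(g), g)
    return out


def load_oil_profiles() -> dict[str, FoodGroupProfile]:
    """Synthetic per-100 g profiles for the oil-substitution scenario."""
    with importlib.resources.as_file(_data_path("oil_profiles_synthetic.csv")) as p:
        df = pd.read_csv(p, comment="#", index_col=0)
    return {g: FoodGroupProfile(g, NutrientVector(df[g])) for g in df.columns}


def default_profiles() -> dict[str, FoodGroupProfile]:
    """The profile set the built-in scenario library uses."""
    profiles = derive_added_food_profiles()
    profiles.update(load_oil_profiles())
    return profiles
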