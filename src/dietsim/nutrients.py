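"""Canonical nutrient vocabulary and the per-person-day nutrient vector.

A :class:`NutrientVector` holds one person-day (or one food group's daily
contribution) of the 25 quantities tracked by the model: total gram weight,
energy, macronutrients, selected micronutrients, fatty-acid fractions, and
the glycaemic index / glycaemic load pair.  Every field except glycaemic
index is additive across foods and groups; glycaemic index is a quality
measure derived from the additive pair as ``GI = 100 * GL / CHO``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENTS",
    "ADDITIVE",
    "UNITS",
    "NutrientVector",
    "NutrientValidationError",
    "derived_gi",
    "round_half_away",
]

#: Canonical nutrient identifiers, in table row order.
NUTRIENTS: tuple[str, ...] = (
    "gram_weight",
    "energy_incl_fibre",
    "protein",
    "fat",
    "carbohydrate",
    "sugars",
    "added_sugars",
    "free_sugars",
    "fibre",
    "alcohol",
    "retinol_equivalents",
    "total_folate_equivalents",
    "vitamin_b12",
    "calcium",
    "iodine",
    "iron",
    "sodium",
    "zinc",
    "saturated_fat",
    "monounsaturated_fat",
    "linoleic_acid",
    "alpha_linolenic_acid",
    "lc_omega3",
    "glycaemic_index",
    "glycaemic_load",
)

UNITS: dict[str, str] = {
    "gram_weight": "g/day",
    "energy_incl_fibre": "kJ/day",
    "protein": "g/day",
    "fat": "g/day",
    "carbohydrate": "g/day",
    "sugars": "g/day",
    "added_sugars": "g/day",
    "free_sugars": "g/day",
    "fibre": "g/day",
    "alcohol": "g/day",
    "retinol_equivalents": "ug/day",
    "total_folate_equivalents": "ug/day",
    "vitamin_b12": "ug/day",
    "calcium": "mg/day",
    "iodine": "ug/day",
    "iron": "mg/day",
    "sodium": "mg/day",
    "zinc": "mg/day",
    "saturated_fat": "g/day",
    "monounsaturated_fat": "g/day",
    "linoleic_acid": "g/day",
    "alpha_linolenic_acid": "g/day",
    "lc_omega3": "mg/day",
    "glycaemic_index": "unitless",
    "glycaemic_load": "unitless/day",
}

#: Fields that sum across foods/groups.  Glycaemic index is the only
#: non-additive field; it is recomputed from GL and carbohydrate.
ADDITIVE: frozenset[str] = frozenset(n for n in NUTRIENTS if n != "glycaemic_index")

#: Tolerance for an independently supplied GI against the derived value.
GI_CONSISTENCY_TOL = 0.3

_NEG_EPS = 1e-9  # negatives smaller than this are float noise, clipped


class NutrientValidationError(ValueError):
    """A nutrient vector violates a physical or consistency invariant."""


def derived_gi(glycaemic_load: float, carbohydrate: float) -> float:
    """Glycaemic index implied by a GL/carbohydrate pair (0 when CHO = 0)."""
    if carbohydrate <= 0:
        return 0.0
    return 100.0 * glycaemic_load / carbohydrate


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention used for report cells."""
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class NutrientVector:
    """An immutable vector of daily nutrient totals.

    Parameters
    ----------
    data
        Mapping or :class:`pandas.Series` keyed by canonical nutrient ids.
        ``glycaemic_index`` may be omitted, in which case it is derived from
        glycaemic load and carbohydrate.
    validate
        Check invariants (non-negative additive fields, GI in [0, 100],
        GL <= carbohydrate, supplied GI within ``gi_tol`` of the derived GI).
    gi_tol
        Tolerance for the supplied-vs-derived GI consistency rule.
    """

    __slots__ = ("_s",)

    def __init__(
        self,
        data: Union[Mapping[str, float], pd.Series],
        *,
        validate: bool = True,
        gi_tol: float = GI_CONSISTENCY_TOL,
    ) -> None:
        s = pd.Series(data, dtype=float)
        unknown = set(s.index) - set(NUTRIENTS)
        if unknown:
            raise NutrientValidationError(f"unknown nutrient ids: {sorted(unknown)}")
        missing = [n for n in NUTRIENTS if n not in s.index and n != "glycaemic_index"]
        if missing:
            raise NutrientValidationError(f"missing nutrient ids: {missing}")
        if "glycaemic_index" not in s.index:
            s["glycaemic_index"] = derived_gi(s["glycaemic_load"], s["carbohydrate"])
        s = s.reindex(NUTRIENTS)
        # clip float-noise negatives before validation
        tiny = (s < 0) & (s > -_NEG_EPS)
        s[tiny] = 0.0
        object.__setattr__(self, "_s", s)
        if validate:
            self._validate(gi_tol)

    def _validate(self, gi_tol: float) -> None:
        s = self._s
        if s.isna().any():
            raise NutrientValidationError(
                f"non-numeric values for {list(s.index[s.isna()])}"
            )
        neg = [n for n in ADDITIVE if s[n] < 0]
        if neg:
            raise NutrientValidationError(f"negative intake for {neg}")
        gi = s["glycaemic_index"]
        if not 0.0 <= gi <= 100.0:
            raise NutrientValidationError(f"glycaemic index {gi} outside [0, 100]")
        cho, gl = s["carbohydrate"], s["glycaemic_load"]
        if gl > cho + _NEG_EPS + gi_tol / 100.0 * max(cho, 1.0):
            raise NutrientValidationError(
                f"glycaemic load {gl} exceeds carbohydrate {cho}"
            )
        if cho > 0:
            want = derived_gi(gl, cho)
            if abs(gi - want) > gi_tol:
                raise NutrientValidationError(
                    f"glycaemic index {gi} inconsistent with 100*GL/CHO = {want:.2f}"
                )

    # -- accessors ---------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        if name in NUTRIENTS:
            return float(self._s[name])
        raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        return float(self._s[name])

    @property
    def series(self) -> pd.Series:
        """The underlying values as a fresh :class:`pandas.Series`."""
        return self._s.copy()

    def to_dict(self) -> dict[str, float]:
        return self._s.to_dict()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        s = self._s + other._s
        s["glycaemic_index"] = derived_gi(s["glycaemic_load"], s["carbohydrate"])
        return NutrientVector(s, validate=False)

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        """Unfloored difference; may be invalid — callers floor explicitly."""
        if not isinstance(other, NutrientVector):
            return NotImplemented
        s = self._s - other._s
        s["glycaemic_index"] = derived_gi(s["glycaemic_load"], s["carbohydrate"])
        return NutrientVector(s, validate=False)

    def scale(self, factor: float) -> "NutrientVector":
        """Multiply every additive field by ``factor``; GI is unchanged
        (both GL and carbohydrate scale, so their ratio is preserved)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        s = self._s * factor
        s["glycaemic_index"] = self._s["glycaemic_index"]
        return NutrientVector(s, validate=False)

    def floor_negative(self) -> tuple["NutrientVector", list[str]]:
        """Clip negative additive fields to zero, returning the floored
        vector and the list of fields that were clipped."""
        s = self._s.copy()
        clipped = [n for n in ADDITIVE if s[n] < -_NEG_EPS]
        for n in ADDITIVE:
            if s[n] < 0:
                s[n] = 0.0
        s["glycaemic_index"] = derived_gi(s["glycaemic_load"], s["carbohydrate"])
        return NutrientVector(s, validate=False), clipped

    def per_100g(self) -> "NutrientVector":
        """Rescale the vector to a 100 g gram-weight basis (GI unchanged)."""
        gw = self.gram_weight
        if gw <= 0:
            raise NutrientValidationError(
                "cannot derive a per-100 g profile from zero gram weight"
            )
        return self.scale(100.0 / gw)

    # -- misc --------------------------------------------------------------
    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls(pd.Series(0.0, index=list(NUTRIENTS)), validate=False)

    def isclose(self, other: "NutrientVector", *, rtol=1e-9, atol=1e-9) -> bool:
        return bool(np.allclose(self._s.values, other._s.values, rtol=rtol, atol=atol))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NutrientVector) and self._s.equals(other._s)

    def __repr__(self) -> str:
        head = ", ".join(
            f"{n}={self._s[n]:g}" for n in ("gram_weight", "energy_incl_fibre")
        )
        return f"NutrientVector({head}, ...)"


def sum_vectors(vectors: Iterable[NutrientVector]) -> NutrientVector:
    """Sum vectors field-wise; glycaemic index is re-derived from the totals."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot sum an empty collection of nutrient vectors")
    total = vectors[0]
    for v in vectors[1:]:
        total = total + v
    return total
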