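"""Deterministic dietary scenario edits over a group-intake table.

A scenario is an ordered list of edits of three kinds:

``scale_group``
    Multiply every additive nutrient subtotal of one or more groups by a
    factor (e.g. halve the processed + ultra-processed groups).
``add_food``
    Add ``grams`` per day of a food with a given per-100 g profile to a
    group's subtotal.
``substitute``
    Remove ``grams`` of one profile and add the same grams of another,
    optionally across two groups — total gram weight is conserved.

The built-in library mirrors the published scenario set: S1 halves
processed foods (PF); S2 additionally scales up minimally processed foods;
S3a/S3b add high-omega-3 fish or nuts on top of S1; S4 adds fruits and/or
vegetables; S5 explores the combination grid (nuts x vegetables x fruits,
optionally plus fish); S6 swaps saturated-fat oils for unsaturated oils
and does not include the S1 base edit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence, Union

import yaml

from .composition import FoodGroupProfile, GroupIntakeTable, default_profiles
from .nutrients import NutrientVector

__all__ = [
    "ScenarioEdit",
    "ScenarioSpec",
    "ScenarioConfigError",
    "apply_edit",
    "run_scenario",
    "scenario_library",
]

logger = logging.getLogger(__name__)

EditKind = Literal["scale_group", "add_food", "substitute"]


class ScenarioConfigError(ValueError):
    """A scenario configuration file is malformed."""


@dataclass(frozen=True)
class ScenarioEdit:
    """One deterministic edit to a group-intake table."""

    kind: EditKind
    groups: tuple[str, ...] = ()          # scale_group targets
    factor: float | None = None           # scale_group
    group: str | None = None              # add_food target
    grams: float | None = None            # add_food / substitute
    profile: FoodGroupProfile | None = None          # add_food
    remove_profile: FoodGroupProfile | None = None   # substitute
    add_profile: FoodGroupProfile | None = None      # substitute
    remove_group: str | None = None       # substitute source group
    add_group: str | None = None          # substitute destination group

    def __post_init__(self) -> None:
        if self.kind == "scale_group":
            if not self.groups or self.factor is None or self.factor < 0:
                raise ScenarioConfigError(
                    "scale_group needs target groups and a factor >= 0"
                )
        elif self.kind == "add_food":
            if self.group is None or self.grams is None or self.profile is None:
                raise ScenarioConfigError(
                    "add_food needs a group, grams and a profile"
                )
            if self.grams < 0:
                raise ScenarioConfigError("grams must be >= 0")
        elif self.kind == "substitute":
            if (
                self.grams is None or self.grams < 0
                or self.remove_profile is None or self.add_profile is None
            ):
                raise ScenarioConfigError(
                    "substitute needs grams >= 0 and remove/add profiles"
                )
        else:
            raise ScenarioConfigError(f"unknown edit kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def scale(cls, groups: Union[str, Sequence[str]], factor: float) -> "ScenarioEdit":
        if isinstance(groups, str):
            groups = (groups,)
        return cls(kind="scale_group", groups=tuple(groups), factor=factor)

    @classmethod
    def add(cls, group: str, grams: float, profile: FoodGroupProfile) -> "ScenarioEdit":
        return cls(kind="add_food", group=group, grams=grams, profile=profile)

    @classmethod
    def substitution(
        cls,
        grams: float,
        remove_profile: FoodGroupProfile,
        add_profile: FoodGroupProfile,
        *,
        remove_group: str | None = None,
        add_group: str | None = None,
    ) -> "ScenarioEdit":
        return cls(
            kind="substitute",
            grams=grams,
            remove_profile=remove_profile,
            add_profile=add_profile,
            remove_group=remove_group or remove_profile.group_id,
            add_group=add_group or add_profile.group_id,
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """An identified, ordered list of edits.  Empty edits = identity."""

    id: str
    description: str = ""
    edits: tuple[ScenarioEdit, ...] = ()
    tags: tuple[str, ...] = field(default=())


def apply_edit(table: GroupIntakeTable, edit: ScenarioEdit) -> GroupIntakeTable:
    """Apply one edit, returning a new table (the input is never mutated)."""
    if edit.kind == "scale_group":
        out = table
        for g in edit.groups:
            if g not in table:
                raise KeyError(f"scale_group: unknown group {g!r}")
            out = out.with_group(g, out.vector(g).scale(edit.factor))
        return out

    if edit.kind == "add_food":
        current = (
            table.vector(edit.group)
            if edit.group in table
            else NutrientVector.zeros()
        )
        return table.with_group(edit.group, current + edit.profile.amount(edit.grams))

    # substitute
    removal = edit.remove_profile.amount(edit.grams)
    addition = edit.add_profile.amount(edit.grams)
    src = edit.remove_group
    dst = edit.add_group
    if src not in table:
        raise KeyError(f"substitute: unknown group {src!r}")
    src_vec, clipped = (table.vector(src) - removal).floor_negative()
    if clipped:
        logger.warning(
            "substitute of %.3g g floored %s at zero in group %r",
            edit.grams, clipped, src,
        )
    out = table.with_group(src, src_vec)
    dst_vec = out.vector(dst) if dst in out else NutrientVector.zeros()
    return out.with_group(dst, dst_vec + addition)


def run_scenario(baseline: GroupIntakeTable, spec: ScenarioSpec) -> GroupIntakeTable:
    """Fold the scenario's edits over the baseline; result is labelled
    ``modelled``.  An empty edit list returns the baseline verbatim
    (relabelled)."""
    table = baseline
    for edit in spec.edits:
        table = apply_edit(table, edit)
    return table.relabel("modelled")


# -- the built-in scenario library -----------------------------------------

_DEFAULT_GRIDS: dict = {
    "s2_factors": [1.25, 1.50, 1.75],
    "s3a": {"start": 40, "stop": 200, "step": 40},
    "s3b": {"start": 10, "stop": 40, "step": 10},
    "s4": {"start": 75, "stop": 300, "step": 75},
    "s5_nuts": [10, 20, 30, 40],
    "s5_vegetables": [75, 150, 225],
    "s5_fruits": [75, 150, 225],
    "s5_fish": [40, 80, 120],
    "s6_grams": [5, 10, 15, 20],
}

#: Combinations called out in the published results, tagged for convenience.
_NAMED_S5 = {
    (40, 225, 150, 0): ("largest_no_fish",),
    (30, 225, 150, 40): ("reference_table", "feasible"),
    (30, 225, 150, 80): ("feasible_fish80",),
}


def _grid(spec: Mapping[str, float]) -> list[float]:
    start, stop, step = spec["start"], spec["stop"], spec["step"]
    if step <= 0 or stop < start:
        raise ScenarioConfigError(f"bad grid {spec!r}")
    out, g = [], start
    while g <= stop + 1e-9:
        out.append(round(g, 9))
        g += step
    return out


def scenario_library(
    config: Union[str, Path, Mapping, None] = None,
    profiles: Mapping[str, FoodGroupProfile] | None = None,
) -> list[ScenarioSpec]:
    """Build the full scenario library.

    ``config`` may override the model grids (YAML/JSON file or mapping with
    a ``grids`` section) and append custom scenarios under ``scenarios``.
    ``profiles`` supplies the per-100 g profiles for added foods; defaults
    to the packaged reference-derived set plus the synthetic oil profiles.
    """
    grids = dict(_DEFAULT_GRIDS)
    custom: list = []
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config, "r", encoding="utf-8") as fh:
                config = yaml.safe_load(fh) or {}
        if not isinstance(config, Mapping):
            raise ScenarioConfigError("scenario config must be a mapping")
        grids.update(config.get("grids", {}))
        custom = list(config.get("scenarios", []))
    if profiles is None:
        profiles = default_profiles()

    def prof(pid: str) -> FoodGroupProfile:
        try:
            return profiles[pid]
        except KeyError:
            raise ScenarioConfigError(f"unknown profile id {pid!r}") from None

    s1 = ScenarioEdit.scale("PF", 0.5)
    lib: list[ScenarioSpec] = [
        ScenarioSpec("S1", "Halve processed + ultra-processed foods", (s1,))
    ]
    for i, f in enumerate(grids["s2_factors"], start=1):
        lib.append(ScenarioSpec(
            f"S2.m{i}",
            f"S1 plus scale minimally processed foods by {f:g}",
            (s1, ScenarioEdit.scale("MP", f)),
        ))
    for i, g in enumerate(_grid(grids["s3a"]), start=1):
        lib.append(ScenarioSpec(
            f"S3a.m{i}", f"S1 plus {g:g} g/d high-omega-3 fish",
            (s1, ScenarioEdit.add("omega3_fish", g, prof("omega3_fish"))),
        ))
    for i, g in enumerate(_grid(grids["s3b"]), start=1):
        lib.append(ScenarioSpec(
            f"S3b.m{i}", f"S1 plus {g:g} g/d nuts",
            (s1, ScenarioEdit.add("nuts", g, prof("nuts"))),
        ))
    for g in _grid(grids["s4"]):
        lib.append(ScenarioSpec(
            f"S4.veg{g:g}", f"S1 plus {g:g} g/d vegetables",
            (s1, ScenarioEdit.add("vegetables", g, prof("vegetables"))),
        ))
    for g in _grid(grids["s4"]):
        lib.append(ScenarioSpec(
            f"S4.fruit{g:g}", f"S1 plus {g:g} g/d fruits",
            (s1, ScenarioEdit.add("fruits", g, prof("fruits"))),
        ))
    for g in _grid(grids["s4"]):
        lib.append(ScenarioSpec(
            f"S4.combo{g:g}", f"S1 plus {g:g} g/d each of fruits and vegetables",
            (
                s1,
                ScenarioEdit.add("fruits", g, prof("fruits")),
                ScenarioEdit.add("vegetables", g, prof("vegetables")),
            ),
        ))
    for n, v, f in itertools.product(
        grids["s5_nuts"], grids["s5_vegetables"], grids["s5_fruits"]
    ):
        for fish in [0, *grids["s5_fish"]]:
            edits = [
                s1,
                ScenarioEdit.add("nuts", n, prof("nuts")),
                ScenarioEdit.add("vegetables", v, prof("vegetables")),
                ScenarioEdit.add("fruits", f, prof("fruits")),
            ]
            sid = f"S5.n{n:g}v{v:g}f{f:g}"
            if fish:
                edits.append(ScenarioEdit.add("omega3_fish", fish, prof("omega3_fish")))
                sid += f".fish{fish:g}"
            lib.append(ScenarioSpec(
                sid,
                f"S1 plus {n:g} g nuts, {v:g} g vegetables, {f:g} g fruits"
                + (f", {fish:g} g fish" if fish else ""),
                tuple(edits),
                tags=_NAMED_S5.get((n, v, f, fish), ()),
            ))
    for i, g in enumerate(grids["s6_grams"], start=1):
        lib.append(ScenarioSpec(
            f"S6.m{i}",
            f"Substitute {g:g} g/d saturated-fat oils with unsaturated oils "
            "(no S1 base)",
            (ScenarioEdit.substitution(
                g, prof("sfa_oils"), prof("healthy_oils"),
                remove_group="PF", add_group="PCI",
            ),),
        ))

    for entry in custom:
        lib.append(_parse_custom(entry, prof))
    return lib


def _parse_custom(entry: Mapping, prof) -> ScenarioSpec:
    try:
        sid = entry["id"]
        edits = []
        for e in entry.get("edits", []):
            kind = e["kind"]
            if kind == "scale_group":
                edits.append(ScenarioEdit.scale(e["groups"], float(e["factor"])))
            elif kind == "add_food":
                edits.append(ScenarioEdit.add(
                    e["group"], float(e["grams"]), prof(e["profile"])
                ))
            elif kind == "substitute":
                edits.append(ScenarioEdit.substitution(
                    float(e["grams"]),
                    prof(e["remove_profile"]), prof(e["add_profile"]),
                    remove_group=e.get("remove_group"),
                    add_group=e.get("add_group"),
                ))
            else:
                raise ScenarioConfigError(f"unknown edit kind {kind!r}")
        return ScenarioSpec(sid, entry.get("description", ""), tuple(edits))
    except (KeyError, TypeError, ValueError) as exc:
        sid = entry.get("id", "<missing id>") if isinstance(entry, Mapping) else entry
        raise ScenarioConfigError(f"malformed scenario {sid!r}: {exc}") from exc
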