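"""Result surfaces: per-nutrient difference profiles and scenario tables.

Rounding happens only here, at presentation time (half away from zero, to
the precision of the corresponding published table cell); computation
upstream is always at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .nutrients import NutrientVector, round_half_away
from .regression import ScenarioResult

__all__ = [
    "nutrient_diff",
    "scenario_table",
    "read_scenario_table",
    "plot_percent_changes",
]


def nutrient_diff(baseline: NutrientVector, modelled: NutrientVector) -> pd.DataFrame:
    """Per-nutrient baseline/modelled comparison.

    Columns: ``baseline``, ``modelled``, ``absolute_diff`` and
    ``percent_diff`` (NaN where the baseline is zero — written as ``n/a``
    by the CSV writer, never infinity).  Glycaemic index is compared as a
    level like every other row; it is simply not additive upstream.
    """
    b, m = baseline.series, modelled.series
    df = pd.DataFrame({
        "baseline": b,
        "modelled": m,
        "absolute_diff": m - b,
    })
    df["percent_diff"] = 100.0 * df["absolute_diff"] / b.where(b != 0)
    df.index.name = "nutrient"
    return df


def write_nutrient_diff(df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = df.copy()
    out["percent_diff"] = out["percent_diff"].map(
        lambda v: "n/a" if pd.isna(v) else f"{v:.6g}"
    )
    out.to_csv(path)


_ROUNDING = {  # presentation precision per column
    "baseline_tg": 3, "baseline_ci_lower": 3, "baseline_ci_upper": 3,
    "modelled_tg": 3, "modelled_ci_lower": 3, "modelled_ci_upper": 3,
    "absolute_change": 3, "percent_change": 1,
}


def scenario_table(
    results: Sequence[ScenarioResult],
    path: Union[str, Path, None] = None,
    *,
    fmt: str = "csv",
    rounded: bool | None = None,
) -> pd.DataFrame:
    """Tabulate scenario results (input order preserved).

    The CSV dialect is rounded for reading; the JSON dialect keeps full
    precision so that write-then-read is lossless.
    """
    if not results:
        raise ValueError("no scenario results to tabulate")
    rows = [r.to_row() for r in results]
    df = pd.DataFrame(rows)
    if rounded is None:
        rounded = fmt == "csv"
    if rounded:
        for col, nd in _ROUNDING.items():
            df[col] = df[col].map(lambda v, nd=nd: round_half_away(v, nd))
    if path is not None:
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "json":
            Path(path).write_text(
                json.dumps(rows, indent=2, allow_nan=False) + "\n", encoding="utf-8"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return df


def read_scenario_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a scenario table written by :func:`scenario_table` (JSON keeps
    full precision; CSV is the rounded presentation dialect)."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    return pd.read_csv(path)


def plot_percent_changes(
    results: Iterable[ScenarioResult], path: Union[str, Path]
) -> None:
    """Horizontal bar chart of percent TG changes per scenario (optional
    output; the CSV/JSON tables are the canonical result surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    ids = [r.scenario_id for r in results]
    pct = [r.percent_change for r in results]
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.3 * len(ids))))
    ax.barh(ids, pct, color=["#c0504d" if p > 0 else "#4f81bd" for p in pct])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Modelled change in triglycerides vs baseline (%)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
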