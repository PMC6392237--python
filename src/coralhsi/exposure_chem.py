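"""Summaries of measured toxicant concentrations in stocks and exposure beakers.

Long-format chemistry tables carry one measured concentration per row with
columns ``group`` (C0..), ``replicate`` (R1.. or "stock"), ``time_h``,
``phase`` ("beaker", "A_after_replacement", "B_before_replacement") and
``duplicate`` ("I"/"II").  Summaries report avg / std dev / min / max, with
group-level beaker averages computed as the arithmetic mean of the four
per-beaker means.  Values below the limit of quantification (0.1 mg/L) are
flagged, not dropped; the limit of detection is 0.033 mg/L.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "LOQ_MG_L",
    "LOD_MG_L",
    "validate_table",
    "summarize",
    "beaker_means",
    "percent_of_nominal",
    "flag_low_replicates",
]

LOQ_MG_L = 0.1  # limit of quantification
LOD_MG_L = 0.033  # limit of detection


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"group", "replicate", "time_h", "concentration"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"chemistry table missing columns: {sorted(missing)}")
    if (table["concentration"] < 0).any():
        raise ValueError("concentrations must be non-negative")
    out = table.copy()
    out["below_loq"] = out["concentration"] < LOQ_MG_L
    return out


def _stats(values: np.ndarray) -> dict:
    return {
        "avg": float(np.mean(values)),
        "std_dev": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n": int(values.size),
    }


def beaker_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-beaker study mean over all time points and duplicates.

    Adds a ``beaker`` key column (``group-replicate``) for joining with the
    sample registry.
    """
    t = validate_table(table)
    t = t[t["replicate"] != "stock"]
    if t.empty:
        raise ValueError("no beaker measurements present")
    g = (
        t.groupby(["group", "replicate"], sort=True)["concentration"]
        .mean()
        .reset_index()
    )
    g["beaker"] = g["group"] + "-" + g["replicate"]
    return g[["beaker", "group", "replicate", "concentration"]]


def summarize(
    table: pd.DataFrame, level: str = "beaker", group_std: str = "pooled"
) -> pd.DataFrame:
    """Avg / std dev / min / max rows at the requested aggregation level.

    level="beaker"  one row per (group, replicate);
    level="group"   one row per group; ``avg`` is the arithmetic mean of the
                    per-beaker means.  ``group_std`` chooses whether std/min/max
                    pool every measurement ("pooled", default) or use the
                    per-beaker means ("of_means");
    level="stock"   one row per group over stock-bottle measurements.
    """
    t = validate_table(table)
    if level == "stock":
        t = t[t["replicate"] == "stock"]
        if t.empty:
            raise ValueError("no stock measurements present")
        rows = [
            {"group": grp, **_stats(sub["concentration"].to_numpy())}
            for grp, sub in t.groupby("group", sort=True)
        ]
        return pd.DataFrame(rows)

    t = t[t["replicate"] != "stock"]
    if t.empty:
        raise ValueError("no beaker measurements present")
    if level == "beaker":
        rows = [
            {"group": grp, "replicate": rep, **_stats(sub["concentration"].to_numpy())}
            for (grp, rep), sub in t.groupby(["group", "replicate"], sort=True)
        ]
        return pd.DataFrame(rows)
    if level == "group":
        rows = []
        for grp, sub in t.groupby("group", sort=True):
            per_beaker = sub.groupby("replicate")["concentration"].mean().to_numpy()
            pooled = sub["concentration"].to_numpy()
            spread = pooled if group_std == "pooled" else per_beaker
            rows.append(
                {
                    "group": grp,
                    "avg": float(np.mean(per_beaker)),
                    "std_dev": float(np.std(spread, ddof=1)) if spread.size > 1 else 0.0,
                    "min": float(np.min(spread)),
                    "max": float(np.max(spread)),
                    "n": int(pooled.size),
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown summary level: {level!r}")


def percent_of_nominal(
    group_summary: pd.DataFrame, nominal: dict[str, float]
) -> pd.DataFrame:
    """100 * group mean / nominal; zero-nominal groups excluded with a note."""
    rows = []
    for _, row in group_summary.iterrows():
        grp = row["group"]
        if grp not in nominal:
            raise KeyError(f"no nominal concentration for group {grp!r}")
        nom = nominal[grp]
        if nom <= 0:
            rows.append(
                {"group": grp, "percent_of_nominal": np.nan, "note": "zero nominal; excluded"}
            )
            continue
        rows.append(
            {
                "group": grp,
                "percent_of_nominal": 100.0 * row["avg"] / nom,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def flag_low_replicates(
    table: pd.DataFrame, nominal: dict[str, float], floor_fraction: float = 0.10
) -> pd.DataFrame:
    """Flag beakers achieving under ``floor_fraction`` of nominal (outliers,
    e.g. a faulty pump channel)."""
    bm = beaker_means(table)
    out = []
    for _, row in bm.iterrows():
        nom = nominal.get(row["group"], 0.0)
        if nom <= 0:
            continue
        frac = row["concentration"] / nom
        if frac < floor_fraction:
            out.append(
                {
                    "beaker": row["beaker"],
                    "fraction_of_nominal": float(frac),
                    "floor": floor_fraction,
                }
            )
    return pd.DataFrame(out, columns=["beaker", "fraction_of_nominal", "floor"])


def report_round(value: float, decimals: int = 1) -> float:
    """Half-up rounding for report output (one decimal for concentrations)."""
    from coralhsi.classify import round_half_up

    return round_half_up(value, decimals)
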