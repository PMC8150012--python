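"""Render confirmatory and quality-control reports as markdown or CSV
tables shaped like the trial's published summary tables (demographics,
palatability cells with deltas and CIs, weight contrasts, game-experience
components)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _fmt(x, nd=2):
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def demographics_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean +/- SD of age and BMI plus the gender ratio."""
    rows = []
    for g, sub in participants.groupby("group"):
        n_f = int((sub["gender"] == "F").sum())
        n_m = int((sub["gender"] == "M").sum())
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "age": f"{sub['age'].mean():.1f} ± {sub['age'].std(ddof=1):.1f}",
                "bmi": f"{sub['bmi'].mean():.1f} ± {sub['bmi'].std(ddof=1):.1f}",
                "gender_ratio": f"{(n_f / n_m):.1f} ({n_f}F/{n_m}M)" if n_m else f"{n_f}F",
            }
        )
    return pd.DataFrame(rows)


def palatability_table(report: dict) -> pd.DataFrame:
    """Table of cell means, per-group deltas with CIs, and interaction
    statistics from a confirmatory report."""
    rows = []
    for label, cat in (("h1a", "unhealthy"), ("h1b", "healthy")):
        entry = report[label]
        inter = entry["interaction"]
        for g, dd in entry["deltas"].items():
            rows.append(
                {
                    "category": cat,
                    "group": g,
                    "delta": _fmt(dd["mean"]),
                    "ci_low": _fmt(dd["ci"][0]),
                    "ci_high": _fmt(dd["ci"][1]),
                    "F": _fmt(inter["F"]),
                    "p": _fmt(inter["p"], 4),
                    "eta_G2": _fmt(inter["eta_G2"], 3),
                    "bf01": _fmt(entry.get("bf01")),
                }
            )
    return pd.DataFrame(rows)


def weight_table(report: dict) -> pd.DataFrame:
    rows = []
    for name, entry in report["h2"]["contrasts"].items():
        inter = entry["interaction"]
        rows.append(
            {
                "contrast": name,
                "n": entry["n"],
                "F": _fmt(inter["F"]),
                "p": _fmt(inter["p"], 4),
                "eta_G2": _fmt(inter["eta_G2"], 3),
                "bf01": _fmt(entry.get("bf01")),
                "loss_experimental_kg": _fmt(entry["loss_by_group"].get("experimental")),
                "loss_control_kg": _fmt(entry["loss_by_group"].get("control")),
            }
        )
    return pd.DataFrame(rows)


def geq_table(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mean +/- SD of the global index and the six components per arm."""
    cols = [c for c in scores.columns if c != "participant_id"]
    rows = []
    for g in sorted(groups.unique()):
        sub = scores[groups.loc[scores.index] == g] if groups.index.equals(scores.index) \
            else scores[scores["participant_id"].isin(groups[groups == g].index)]
        row = {"group": g, "n": len(sub)}
        for c in cols:
            row[c] = f"{sub[c].mean():.1f} ± {sub[c].std(ddof=1):.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def render(report: dict, fmt: str = "md") -> str:
    """Serialize a confirmatory report; markdown concatenates the shaped
    tables, csv emits the palatability and weight tables back to back."""
    pal = palatability_table(report)
    wt = weight_table(report)
    if fmt == "md":
        parts = ["## Palatability ratings", pal.to_markdown(index=False),
                 "\n## Weight", wt.to_markdown(index=False)]
        if report.get("expectation_share_pct") is not None:
            parts.append(
                f"\nExpectation share of the control unhealthy devaluation: "
                f"{report['expectation_share_pct']}%"
            )
        return "\n".join(parts)
    if fmt == "csv":
        return pal.to_csv(index=False) + "\n" + wt.to_csv(index=False)
    if fmt == "json":
        return json.dumps(report, indent=2, default=str)
    raise ValueError("fmt must be md, csv or json")


def write_report(report: dict, path: str | Path, fmt: str = "json") -> None:
    Path(path).write_text(render(report, fmt))
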