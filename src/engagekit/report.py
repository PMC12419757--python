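"""Report rendering: tidy CSV artifacts and a Markdown summary table.

Comparison tables print "median (IQR)" per category, where the IQR can be
rendered either as bounds ``(q1-q3)`` or as a single width ``(q3 - q1)`` —
published tables use both conventions, so the style is a flag. Every file
starts with comment lines recording the seed and config hash so a run can be
reproduced; no timestamps are written, keeping repeated runs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import CohortComparisonResult, CorrelationResult, DistributionDiagnostics

_STYLES = ("bounds", "width")


def _fmt_iqr(q1: float, q3: float, style: str) -> str:
    if style == "bounds":
        return f"({q1:.1f}-{q3:.1f})"
    return f"({q3 - q1:.1f})"


def comparison_frame(results: list[CohortComparisonResult]) -> pd.DataFrame:
    """Tidy long-format table: one row per (characteristic, metric, category)."""
    rows = []
    for r in results:
        for g in r.groups:
            rows.append(
                {
                    "characteristic": r.characteristic,
                    "metric": r.metric,
                    "category": g.label,
                    "n": g.n,
                    "median": round(g.median, 1),
                    "q1": round(g.q1, 1),
                    "q3": round(g.q3, 1),
                    "iqr_width": round(g.iqr_width, 1),
                    "statistic_label": r.statistic_label,
                    "u": None if r.u is None else round(r.u, 1),
                    "statistic": round(r.statistic, 2),
                    "p_value": round(r.p_value, 4),
                }
            )
    return pd.DataFrame(rows)


def comparison_markdown(results: list[CohortComparisonResult], style: str = "width") -> str:
    """Markdown table in the published layout: one block per characteristic,
    one row per category, with the rank-test statistic and p on the header row."""
    if style not in _STYLES:
        raise ValueError(f"style must be one of {_STYLES}")
    metrics = list(dict.fromkeys(r.metric for r in results))
    by_char: dict[str, dict[str, CohortComparisonResult]] = {}
    for r in results:
        by_char.setdefault(r.characteristic, {})[r.metric] = r

    head = "| Variable | n (%) |" + "".join(
        f" {m} median (IQR) | statistic | p |" for m in metrics
    )
    sep = "|---" * (2 + 3 * len(metrics)) + "|"
    lines = [head, sep]
    for char, per_metric in by_char.items():
        any_r = next(iter(per_metric.values()))
        n_total = any_r.n_total
        cells = [f"**{char}**", ""]
        for m in metrics:
            r = per_metric.get(m)
            if r is None:
                cells += ["", "", ""]
                continue
            if r.statistic_label == "U/z":
                stat = f"{r.u:.1f}/{r.statistic:.2f}"
            else:
                stat = f"{r.statistic:.2f}"
            cells += ["", stat, f"{r.p_value:.3f}"]
        lines.append("| " + " | ".join(cells) + " |")
        for gi, g in enumerate(any_r.groups):
            cells = [g.label, f"{g.n} ({100.0 * g.n / n_total:.1f})"]
            for m in metrics:
                r = per_metric.get(m)
                g_m = r.groups[gi] if r is not None else None
                if g_m is None:
                    cells += ["", "", ""]
                else:
                    cells += [f"{g_m.median:.1f} {_fmt_iqr(g_m.q1, g_m.q3, style)}", "", ""]
            lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def dau_frame(counts: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"day": np.arange(len(counts)), "active_users": counts})


def header_lines(seed: int, config_hash: str) -> list[str]:
    return [f"# engagekit report", f"# seed={seed}", f"# config_sha256={config_hash}"]


def write_csv_with_header(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str) -> None:
    """CSV with reproducibility header comments (read back with ``comment='#'``)."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_json(obj, path: str | Path, seed: int, config_hash: str) -> None:
    payload = {"seed": seed, "config_sha256": config_hash}
    if isinstance(obj, (DistributionDiagnostics, CorrelationResult)):
        payload.update(asdict(obj))
    elif isinstance(obj, dict):
        payload.update(obj)
    else:
        payload["value"] = obj
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
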