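"""Human-readable and machine-readable rendering of workflow results."""

from __future__ import annotations

import json
from typing import Any, Mapping

from .capacity import ClinicReport
from .engine import StratumSummary, WorkflowResult

_COLUMNS = (
    ("read_exams", "Read examinations"),
    ("workload", "Workload"),
    ("recalls", "Recalls"),
    ("fp_recalls", "False-positive recalls"),
    ("detected", "Detected"),
    ("non_detected", "Non-detected"),
)


def _fmt(value: float) -> str:
    if isinstance(value, float) and not value.is_integer():
        return f"{value:,.1f}"
    return f"{int(value):,}"


def result_as_json_dict(
    result: WorkflowResult,
    summary: Mapping[str, Any] | None = None,
    capacity: ClinicReport | None = None,
) -> dict:
    doc = result.as_dict()
    if summary is not None:
        doc["summary"] = dict(summary)
    if capacity is not None:
        doc["capacity"] = capacity.as_dict()
    return doc


def render_text(
    result: WorkflowResult,
    summary: Mapping[str, Any] | None = None,
    capacity: ClinicReport | None = None,
    title: str = "Workflow evaluation",
) -> str:
    """Plain-text table with the six per-stratum columns (SM / DBT / Total rows)."""
    rows = [
        ("SM", result.sm_stratum),
        ("DBT", result.dbt_stratum),
        ("Total", result.total),
    ]
    header = ["Stratum"] + [label for _, label in _COLUMNS]
    table = [[name] + [_fmt(getattr(s, key)) for key, _ in _COLUMNS] for name, s in rows]
    widths = [max(len(r[i]) for r in [header] + table) for i in range(len(header))]
    lines = [title, ""]
    lines.append("  ".join(h.rjust(w) for h, w in zip(header, widths)))
    lines.append("  ".join("-" * w for w in widths))
    for row in table:
        lines.append("  ".join(c.rjust(w) for c, w in zip(row, widths)))
    if summary is not None:
        lines.append("")
        for key, value in summary.items():
            lines.append(f"{key}: {value}")
    if capacity is not None:
        lines.append("")
        for key, value in capacity.as_dict().items():
            lines.append(f"{key}: {value:.3f}" if isinstance(value, float) else f"{key}: {value}")
    return "\n".join(lines) + "\n"


def render_report(
    result: WorkflowResult,
    summary: Mapping[str, Any] | None = None,
    capacity: ClinicReport | None = None,
    destination: str | None = None,
) -> tuple[str, dict]:
    """Render a result as (text, json-dict); optionally write both to disk.

    When ``destination`` is given, writes ``<destination>.txt`` and
    ``<destination>.json``.
    """
    text = render_text(result, summary, capacity)
    doc = result_as_json_dict(result, summary, capacity)
    if destination is not None:
        with open(f"{destination}.txt", "w", encoding="utf-8") as fh:
            fh.write(text)
        with open(f"{destination}.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    return text, doc
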