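"""Aggregate per-stage summaries into an HTML + JSON run report.

The consolidated JSON is the single source of truth: the HTML is rendered
by walking the JSON, so it cannot contain a number absent from the JSON.
Five sections are shown — running information, linker filtering,
alignment, noise reduction, interaction matrix — with stages that did not
run marked as skipped.  Images (heatmaps, distributions) are embedded
inline as base64 so the report is a single static file.
"""

from __future__ import annotations

import base64
import html
import json
from pathlib import Path

__all__ = ["ReportError", "build_report", "SECTIONS"]

SECTIONS = [
    ("running_information", "Running information"),
    ("linker_filtering", "Linker filtering"),
    ("alignment", "Alignment"),
    ("noise_reduction", "Noise reduction"),
    ("interaction_matrix", "Interaction matrix"),
]

_STAGE_TO_SECTION = {
    "config": "running_information",
    "preprocess": "linker_filtering",
    "mapping": "alignment",
    "pairs": "noise_reduction",
    "matrix": "interaction_matrix",
}


class ReportError(ValueError):
    pass


def _pct(numerator: float, denominator: float) -> float:
    return round(100.0 * numerator / denominator, 2) if denominator else 0.0


def _with_percentages(section: str, data: dict) -> dict:
    """Augment count dictionaries with percentages (numerators and
    denominators stay present, so every percentage can be recomputed)."""
    out = dict(data)
    if section == "linker_filtering" and "counts" in data:
        counts = data["counts"]
        total = counts.get("total", 0)
        out["percent"] = {k: _pct(v, total) for k, v in counts.items() if k != "total"}
    if section == "alignment" and "categories" in data:
        total = sum(data["categories"].values())
        out["total_tags"] = total
        out["percent"] = {k: _pct(v, total) for k, v in data["categories"].items()}
    if section == "noise_reduction" and "classes" in data:
        total = data.get("pairs", sum(data["classes"].values()))
        out["percent"] = {k: _pct(v, total) for k, v in data["classes"].items()}
        if "duplicates" in data:
            out["percent"]["duplicates"] = _pct(data["duplicates"], total)
    return out


def _render_value(value) -> str:
    if isinstance(value, dict):
        rows = "".join(
            f"<tr><td>{html.escape(str(k))}</td><td>{_render_value(v)}</td></tr>"
            for k, v in value.items()
        )
        return f"<table>{rows}</table>"
    if isinstance(value, (list, tuple)):
        return ", ".join(_render_value(v) for v in value)
    return html.escape(f"{value}")


def _embed_image(path: Path) -> str:
    data = base64.b64encode(path.read_bytes()).decode()
    return f'<img src="data:image/png;base64,{data}" alt="{html.escape(path.name)}"/>'


def build_report(stage_summaries: dict[str, dict], out_dir: str | Path,
                 generated_at: str | None = None) -> tuple[Path, Path]:
    """Render report.html and report.json from per-stage summary dicts.

    ``stage_summaries`` maps stage names (config, preprocess, mapping,
    pairs, matrix) to their summary dictionaries; at least the preprocess
    summary must be present.  Returns (html_path, json_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "preprocess" not in stage_summaries:
        raise ReportError("preprocess summary is required to build a report")
    consolidated: dict = {"sections": {}}
    if generated_at is not None:
        consolidated["generated_at"] = generated_at
    images: dict[str, list[str]] = {}
    for stage, section in _STAGE_TO_SECTION.items():
        summary = stage_summaries.get(stage)
        if summary is None:
            consolidated["sections"][section] = {"status": "skipped"}
            continue
        if not isinstance(summary, dict):
            raise ReportError(f"malformed summary for stage {stage!r}")
        data = {k: v for k, v in summary.items() if k != "images"}
        images[section] = list(summary.get("images", []))
        consolidated["sections"][section] = {
            "status": "populated",
            "data": _with_percentages(section, data),
        }

    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(consolidated, indent=2, sort_keys=True))

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>DLO Hi-C run report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse;margin:0.5em 0}td{border:1px solid #999;padding:2px 8px}"
        "h2{border-bottom:2px solid #333}</style></head><body>",
        "<h1>DLO Hi-C run report</h1>",
    ]
    if generated_at is not None:
        parts.append(f"<p>generated: {html.escape(generated_at)}</p>")
    for key, title in SECTIONS:
        sec = consolidated["sections"][key]
        parts.append(f"<h2>{html.escape(title)}</h2>")
        if sec["status"] == "skipped":
            parts.append("<p><em>stage skipped</em></p>")
            continue
        parts.append(_render_value(sec["data"]))
        for img in images.get(key, []):
            p = Path(img)
            if p.exists():
                parts.append(_embed_image(p))
    parts.append("</body></html>")
    html_path = out_dir / "report.html"
    html_path.write_text("".join(parts))
    return html_path, json_path
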