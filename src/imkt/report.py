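"""Run report assembly and rendering (JSON canonical, minimal HTML view).

The report is a view over module outputs: every number it contains is taken
verbatim from the result objects, never recomputed. Sections mirror the
analysis flow: input parameters, descriptive statistics of the spectra,
the standard MKT table, then whichever additional tests were requested.
"""

from __future__ import annotations

import html as _html
import json
from typing import Any, Mapping

from . import __version__
from .types import DafTable, DivergenceSummary

SECTIONS = ("parameters", "descriptive_statistics", "standard_mkt", "tests")


def descriptive_statistics(
    daf: DafTable, div: DivergenceSummary
) -> dict[str, Any]:
    """Totals and per-bin spectra for the descriptive-statistics section."""
    return {
        "n_sample": daf.n_sample,
        "pn_total": daf.pn_total,
        "ps_total": daf.ps_total,
        "dn": div.dn,
        "ds": div.ds,
        "m_n": div.m_n,
        "m_s": div.m_s,
        "spectrum": [[b.daf, b.pn, b.ps] for b in daf.bins],
    }


def build_report(
    parameters: Mapping[str, Any],
    daf: DafTable,
    div: DivergenceSummary,
    results: Mapping[str, Any],
    warnings: list[str] | None = None,
) -> dict[str, Any]:
    """Assemble the canonical report document.

    ``results`` maps test names to already-serialized result dicts; the
    standard MKT entry (if present) is surfaced as its own section.
    """
    results = dict(results)
    standard = results.pop("standard", None)
    return {
        "tool_version": __version__,
        "parameters": dict(parameters),
        "descriptive_statistics": descriptive_statistics(daf, div),
        "standard_mkt": standard,
        "tests": results,
        "warnings": list(warnings or []),
    }


def render_report(report: Mapping[str, Any]) -> str:
    """Deterministic JSON serialization (sorted keys)."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def _html_table(rows: list[list[Any]], header: list[str]) -> str:
    head = "".join(f"<th>{_html.escape(str(h))}</th>" for h in header)
    body = "".join(
        "<tr>" + "".join(f"<td>{_html.escape(str(v))}</td>" for v in r) + "</tr>"
        for r in rows
    )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


def render_html(report: Mapping[str, Any]) -> str:
    """Minimal static HTML mirroring the JSON sections, in order.

    Trajectory and spectrum data are embedded as JSON for external plotting;
    no figures are baked in.
    """
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>MKT report</title></head><body>",
        f"<h1>Integrative MKT report (v{_html.escape(str(report.get('tool_version', '')))})</h1>",
    ]

    parts.append("<h2>Parameters</h2>")
    params = report.get("parameters", {})
    parts.append(_html_table([[k, v] for k, v in sorted(params.items())], ["parameter", "value"]))

    parts.append("<h2>Descriptive statistics</h2>")
    stats = dict(report.get("descriptive_statistics", {}))
    spectrum = stats.pop("spectrum", [])
    parts.append(_html_table([[k, v] for k, v in sorted(stats.items())], ["quantity", "value"]))
    parts.append(
        "<script type='application/json' id='spectrum'>"
        + json.dumps(spectrum, sort_keys=True)
        + "</script>"
    )

    parts.append("<h2>Standard MKT</h2>")
    std = report.get("standard_mkt")
    if std:
        t = std.get("table", {})
        parts.append(
            _html_table(
                [
                    ["polymorphism", t.get("pn"), t.get("ps")],
                    ["divergence", t.get("dn"), t.get("ds")],
                ],
                ["", "selected (N)", "neutral (S)"],
            )
        )
        parts.append(
            f"<p>alpha = {_html.escape(str(std.get('alpha')))}, "
            f"p = {_html.escape(str(std.get('p_value')))}</p>"
        )
    else:
        parts.append("<p>not computed</p>")

    parts.append("<h2>Selected tests</h2>")
    tests = report.get("tests", {})
    for name in sorted(tests):
        parts.append(f"<h3>{_html.escape(name)}</h3>")
        parts.append(
            "<script type='application/json' class='test-result' "
            f"id='test-{_html.escape(name)}'>"
            + json.dumps(tests[name], sort_keys=True)
            + "</script>"
        )
        flat = tests[name]
        if isinstance(flat, Mapping):
            rows = [
                [k, json.dumps(v, sort_keys=True) if isinstance(v, (dict, list)) else v]
                for k, v in sorted(flat.items())
            ]
            parts.append(_html_table(rows, ["field", "value"]))

    warnings = report.get("warnings", [])
    if warnings:
        parts.append("<h2>Warnings</h2><ul>")
        parts.extend(f"<li>{_html.escape(w)}</li>" for w in warnings)
        parts.append("</ul>")
    parts.append("</body></html>")
    return "".join(parts)
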