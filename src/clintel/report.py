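"""Static report rendering.

HTML is the canonical, bit-stable surface; PDF is produced with the
matplotlib PDF backend (tables typeset page per page).  Suppressed cells
are rendered as "<threshold" markers — the raw count never reaches the
document — and every report carries a fixed disclaimer that outputs are
statistical associations, not causal findings.
"""

from __future__ import annotations

import html
from pathlib import Path

from .pipeline import ReportBundle

DISCLAIMER = (
    "Outputs in this report are descriptive statistical associations derived "
    "from routine, de-identified health data. They are not evidence of "
    "causation and do not by themselves support clinical decisions."
)

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em auto; max-width: 60em; color: #222; }}
h1 {{ border-bottom: 2px solid #336; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #aaa; padding: 0.3em 0.7em; text-align: left; }}
th {{ background: #eef; }}
.footnote {{ font-size: 0.85em; color: #555; }}
.provenance {{ font-size: 0.8em; color: #777; border-top: 1px solid #ccc;
               margin-top: 2em; padding-top: 0.5em; }}
.disclaimer {{ font-style: italic; background: #ffe; padding: 0.6em;
               border: 1px solid #cc9; }}
@media print {{ body {{ max-width: none; }} }}
</style>
</head>
<body>
<h1>{title}</h1>
<p class="disclaimer">{disclaimer}</p>
{body}
<div class="provenance">{provenance}</div>
</body>
</html>
"""


def _table_html(name: str, table) -> str:
    rendered = table.rendered()
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in rendered.columns)
    rows = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in rendered.itertuples(index=False)
    )
    notes = "".join(
        f'<p class="footnote">{html.escape(n)}</p>' for n in table.footnotes
    )
    return (
        f"<h2>{html.escape(table.title or name)}</h2>"
        f"<table><thead><tr>{head}</tr></thead><tbody>{rows}</tbody></table>{notes}"
    )


def render_report(bundle: ReportBundle, format: str = "html",
                  out_path: str | Path = "report.html") -> Path:
    """Render a bundle to a self-contained HTML or PDF document."""
    if format not in ("html", "pdf"):
        raise ValueError(f"unsupported report format {format!r}; valid: html, pdf")
    out_path = Path(out_path)
    if format == "html":
        parts = []
        if bundle.failed:
            parts.append(f"<p><strong>Pipeline failed:</strong> {html.escape(bundle.error or '')}</p>")
        for key, definition in bundle.definitions.items():
            members = bundle.cohorts.get(key)
            n = len(members) if members is not None else "?"
            parts.append(
                f'<p class="footnote">Cohort <b>{html.escape(definition.name)}</b> '
                f"({html.escape(key)}): {len(definition.criteria)} criteria, n = {n}.</p>"
            )
        for name, table in bundle.tables.items():
            parts.append(_table_html(name, table))
        prov = " | ".join(f"{k}: {v}" for k, v in bundle.provenance.items())
        out_path.write_text(_PAGE.format(
            title=html.escape(bundle.title),
            disclaimer=html.escape(DISCLAIMER),
            body="\n".join(parts) or "<p>No analytics outputs.</p>",
            provenance=html.escape(prov),
        ))
        return out_path
    return _render_pdf(bundle, out_path)


def _render_pdf(bundle: ReportBundle, out_path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    with PdfPages(out_path) as pdf:
        fig, ax = plt.subplots(figsize=(8.3, 11.7))
        ax.axis("off")
        ax.text(0.5, 0.9, bundle.title, ha="center", fontsize=16, weight="bold")
        ax.text(0.5, 0.82, DISCLAIMER, ha="center", fontsize=8, wrap=True, style="italic")
        prov = "\n".join(f"{k}: {v}" for k, v in bundle.provenance.items())
        ax.text(0.05, 0.05, prov, fontsize=7, va="bottom")
        if bundle.failed:
            ax.text(0.5, 0.5, f"Pipeline failed: {bundle.error}", ha="center",
                    fontsize=10, color="red", wrap=True)
        pdf.savefig(fig)
        plt.close(fig)
        for name, table in bundle.tables.items():
            rendered = table.rendered()
            fig, ax = plt.subplots(figsize=(8.3, 11.7))
            ax.axis("off")
            ax.set_title(table.title or name, fontsize=12)
            if len(rendered):
                tab = ax.table(
                    cellText=rendered.values.tolist(),
                    colLabels=list(rendered.columns),
                    loc="upper center", cellLoc="left",
                )
                tab.auto_set_font_size(False)
                tab.set_fontsize(7)
            for j, note in enumerate(table.footnotes):
                ax.text(0.0, -0.02 - 0.03 * j, note, fontsize=6,
                        transform=ax.transAxes)
            pdf.savefig(fig)
            plt.close(fig)
    return out_path


__all__ = ["render_report", "DISCLAIMER"]
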