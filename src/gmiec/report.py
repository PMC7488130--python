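"""Static, self-contained HTML report over the results table.

Replaces interactive exploration with a single file: cohort-level heatmaps
(patients x modules) of the S-score, the gene alteration score and the drug
score, plus one section per patient listing each module's genes and drugs
with external NCBI and DGIdb links.
"""

from __future__ import annotations

import base64
import html
import io

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import ResultTable
from .selection import SelectionRow

NCBI_URL = "https://www.ncbi.nlm.nih.gov/gene/?term={gene}"
DGIDB_URL = "https://dgidb.org/results?searchType=drug&searchTerms={drug}"


def _heatmap_png(matrix: np.ndarray, samples, title: str, cmap: str, vmin, vmax) -> str:
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * matrix.shape[1] + 2), max(2.5, 0.25 * len(samples) + 1.5))
    )
    im = ax.imshow(matrix, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_title(title)
    ax.set_xlabel("module")
    ax.set_xticks(range(matrix.shape[1]), [str(j + 1) for j in range(matrix.shape[1])])
    ax.set_yticks(range(len(samples)), samples, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _score_matrix(result: ResultTable, attr: str) -> np.ndarray:
    kmax = result.max_modules()
    mat = np.full((len(result.samples), kmax), np.nan)
    for i, sample in enumerate(result.samples):
        for rec in result.modules[sample]:
            mat[i, rec.index - 1] = getattr(rec, attr)
    return mat


def _gene_links(genes: list[str]) -> str:
    return ", ".join(
        f'<a href="{NCBI_URL.format(gene=html.escape(g))}">{html.escape(g)}</a>'
        for g in genes
    )


def _drug_links(drugs: list[str]) -> str:
    if not drugs:
        return "NA"
    return ", ".join(
        f'<a href="{DGIDB_URL.format(drug=html.escape(d))}">{html.escape(d)}</a>'
        for d in drugs
    )


def render_report(
    result: ResultTable, selections: list[SelectionRow] | None = None
) -> str:
    """Render the results (and optional selection) to an HTML string."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Gene-module analysis report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px;font-size:90%}"
        "h2{border-bottom:1px solid #ccc}</style></head><body>",
        "<h1>Gene-module analysis report</h1>",
        f"<p>{len(result.samples)} patients, up to {result.max_modules()} modules.</p>",
        "<h2>Summary heatmaps</h2>",
    ]
    specs = [
        ("s_score", "S-score (activation balance)", "RdBu_r", -1, 1),
        ("score_genes", "Gene alteration score", "viridis", 0, 1),
        ("score_drugs", "Drug score (druggable fraction)", "viridis", 0, 1),
    ]
    for attr, title, cmap, vmin, vmax in specs:
        png = _heatmap_png(_score_matrix(result, attr), result.samples, title, cmap, vmin, vmax)
        parts.append(f'<img class="heatmap" alt="{title}" src="data:image/png;base64,{png}">')

    if selections:
        parts.append("<h2>Selected modules</h2><table><tr>"
                     "<th>patient</th><th>score</th><th>genes</th><th>drugs</th><th>category</th></tr>")
        for s in selections:
            parts.append(
                f"<tr><td>{html.escape(s.patient)}</td><td>{s.score:.3f}</td>"
                f"<td>{_gene_links(s.genes)}</td><td>{_drug_links(s.drugs)}</td>"
                f"<td>{s.category}</td></tr>"
            )
        parts.append("</table>")

    parts.append("<h2>Per-patient modules</h2>")
    for sample in result.samples:
        parts.append(f'<section class="patient"><h3>Patient {html.escape(sample)}</h3>')
        parts.append(
            "<table><tr><th>module</th><th>n genes</th><th>genes</th><th>drugs</th>"
            "<th>score_genes</th><th>score_drugs</th><th>s_score</th></tr>"
        )
        for rec in result.modules[sample]:
            parts.append(
                f"<tr><td>{rec.index}</td><td>{len(rec.genes)}</td>"
                f"<td>{_gene_links(rec.genes)}</td><td>{_drug_links(rec.drugs)}</td>"
                f"<td>{rec.score_genes:.3f}</td><td>{rec.score_drugs:.3f}</td>"
                f"<td>{rec.s_score:.3f}</td></tr>"
            )
        parts.append("</table></section>")
    parts.append("</body></html>")
    return "".join(parts)


def write_report(
    result: ResultTable, path, selections: list[SelectionRow] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(render_report(result, selections))
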