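"""Static, self-contained HTML report generation.

The report mirrors the analysis workflow: a metadata header, a table of
contents, the QC decisions, per-trial model selection and genotype rankings,
the multi-environment results, and (when markers are supplied) the genomic
breeding values.  Everything is embedded: static figures as base64 PNG data
URIs and tables as plain HTML with a dozen lines of inline JavaScript for
click-to-sort, so the file opens in any browser without network access.

Regenerating the report from the same inputs, configuration and seed is
byte-identical except for the single generated-at timestamp line.
"""

from __future__ import annotations

import base64
import html
import io as _io
from datetime import datetime, timezone

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["render_report"]

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1 { border-bottom: 2px solid #36c; }
h2 { border-bottom: 1px solid #ccc; margin-top: 2em; }
table.tk { border-collapse: collapse; margin: 1em 0; font-size: 0.9em; }
table.tk th, table.tk td { border: 1px solid #bbb; padding: 0.25em 0.6em; text-align: right; }
table.tk th { background: #eef; cursor: pointer; }
table.tk td:first-child, table.tk th:first-child { text-align: left; }
.fail { color: #a00; font-weight: bold; }
.meta { background: #f6f6f6; padding: 0.5em 1em; border: 1px solid #ddd; }
nav li { margin: 0.2em 0; }
img { max-width: 100%; }
"""

_SORT_JS = """
function tkSort(th) {
  const table = th.closest('table'); const idx = th.cellIndex;
  const tbody = table.tBodies[0];
  const dir = th.dataset.dir === 'asc' ? -1 : 1; th.dataset.dir = dir === 1 ? 'asc' : 'desc';
  const rows = Array.from(tbody.rows);
  rows.sort((a, b) => {
    const x = a.cells[idx].innerText, y = b.cells[idx].innerText;
    const nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(r => tbody.appendChild(r));
}
"""


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return ""
        return f"{v:.4g}"
    return html.escape(str(v))


def df_to_html(df: pd.DataFrame, max_rows: int = 200) -> str:
    """Sortable, self-contained HTML table (truncated past ``max_rows``)."""
    shown = df.head(max_rows)
    head = "".join(f"<th onclick='tkSort(this)'>{html.escape(str(c))}</th>" for c in shown.columns)
    body = "".join(
        "<tr>" + "".join(f"<td>{_fmt(v)}</td>" for v in row) + "</tr>"
        for row in shown.itertuples(index=False)
    )
    note = (
        f"<p><em>showing {max_rows} of {len(df)} rows</em></p>" if len(df) > max_rows else ""
    )
    return f"<table class='tk'><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>{note}"


def fig_to_data_uri(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight",
                metadata={"Software": "trialkit"})
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode("ascii")


def heatmap_figure(grid: np.ndarray, title: str):
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, origin="lower", aspect="auto", cmap="viridis",
                   extent=[0.5, grid.shape[1] + 0.5, 0.5, grid.shape[0] + 0.5])
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(title)
    return fig


def distribution_figure(values: np.ndarray, title: str):
    v = values[~np.isnan(values)]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    axes[0].hist(v, bins="auto", color="#36c")
    axes[0].set_title("histogram")
    axes[1].boxplot(v)
    axes[1].set_title("boxplot")
    srt = np.sort(v)
    pp = (np.arange(1, len(v) + 1) - 0.5) / len(v)
    from scipy import stats

    theo = stats.norm.ppf(pp, loc=v.mean(), scale=v.std(ddof=1))
    axes[2].plot(theo, srt, ".", ms=3)
    lim = [min(theo.min(), srt.min()), max(theo.max(), srt.max())]
    axes[2].plot(lim, lim, "k--", lw=0.8)
    axes[2].set_title("QQ")
    fig.suptitle(title)
    return fig


def variogram_figure(vg: pd.DataFrame, title: str):
    grid = vg.pivot(index="d_row", columns="d_col", values="gamma")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.to_numpy(), origin="lower", aspect="auto", cmap="magma")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("column displacement")
    ax.set_ylabel("row displacement")
    ax.set_title(title)
    return fig


def latent_regression_figure(slopes: pd.DataFrame, loadings: np.ndarray, gxe: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(6, 4))
    lam = np.asarray(loadings)[:, 0]
    order = np.argsort(lam)
    for _, r in slopes.iterrows():
        g = r["genotype"]
        if g in gxe.index:
            ax.plot(lam[order], gxe.loc[g].to_numpy()[order], "o", ms=3, alpha=0.5)
        xs = np.linspace(lam.min(), lam.max(), 10)
        ax.plot(xs, r["intercept"] + r["slope"] * xs, "-", color="#36c", alpha=0.6, lw=1)
    ax.set_xlabel("factor-1 environment loading")
    ax.set_ylabel("predicted genetic value")
    ax.set_title("latent regression (top genotypes)")
    return fig


def biplot_figure(biplot: dict):
    env = biplot["env_vectors"]
    sc = biplot["genotype_scores"]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    sel = sc["selected"].to_numpy(dtype=bool)
    ax.plot(sc.loc[~sel, "axis1"], sc.loc[~sel, "axis2"], "^", color="#e6a817",
            ms=4, alpha=0.7, label="unselected")
    ax.plot(sc.loc[sel, "axis1"], sc.loc[sel, "axis2"], "o", color="#36c",
            ms=5, label="selected")
    scale = np.nanmax(np.abs(sc[["axis1", "axis2"]].to_numpy())) or 1.0
    escale = np.nanmax(np.abs(env.to_numpy())) or 1.0
    for name, r in env.iterrows():
        x, y = r["axis1"] / escale * scale, r["axis2"] / escale * scale
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="#36c"))
        ax.annotate(str(name), xy=(x, y), color="#36c")
    ax.axhline(0, color="#999", lw=0.5)
    ax.axvline(0, color="#999", lw=0.5)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.legend(loc="best", fontsize=8)
    ax.set_title("FA biplot")
    return fig


def render_report(sections: list, title: str, metadata: dict) -> str:
    """Assemble the final HTML document.

    ``sections`` is a list of ``(section_id, heading, html_body)`` triples in
    display order.
    """
    toc = "".join(
        f"<li><a href='#{sid}'>{html.escape(head)}</a></li>" for sid, head, _ in sections
    )
    meta_rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in metadata.items()
    )
    body = "".join(
        f"<section id='{sid}'><h2>{html.escape(head)}</h2>{content}</section>"
        for sid, head, content in sections
    )
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%d %H:%M:%S UTC")
    return f"""<!DOCTYPE html>
<html><head><meta charset='utf-8'><title>{html.escape(title)}</title>
<style>{_CSS}</style><script>{_SORT_JS}</script></head>
<body>
<h1>{html.escape(title)}</h1>
<p id='generated-at'>generated: {stamp}</p>
<div class='meta'><table class='tk'>{meta_rows}</table></div>
<nav><ul>{toc}</ul></nav>
{body}
</body></html>
"""
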