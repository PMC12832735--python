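"""Minimal plotting: a grouped bar chart of pathway representation."""

from __future__ import annotations

from .pathways import RepresentationTable


def plot_representation(table: RepresentationTable, path=None):
    """Grouped bars of percent-in-top-K per pathway for the two sources.

    Returns the matplotlib Figure; writes it to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    t = table.table
    x = np.arange(len(t))
    width = 0.38
    fig, ax = plt.subplots(figsize=(max(6, len(t) * 1.2), 4))
    ax.bar(x - width / 2, t["percent_a"], width, label=table.source_a or "A")
    ax.bar(x + width / 2, t["percent_b"], width, label=table.source_b or "B")
    ax.set_xticks(x)
    ax.set_xticklabels(t["pathway_id"], rotation=45, ha="right")
    ax.set_ylabel(f"% of pathway genes in top {table.k}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
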