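"""Optional figures: PCA overview scatter and dose-response panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_pca(coords: pd.DataFrame, samples: pd.DataFrame, path) -> None:
    """Scatter of the first two PCs, colored by tissue, marker by condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"intima": "tab:red", "media": "tab:blue"}
    markers = {"ligated": "^", "sham": "o"}
    for sample_id, row in coords.iterrows():
        tissue = samples.at[sample_id, "tissue"]
        condition = samples.at[sample_id, "condition"]
        ax.scatter(
            row["pc1"], row["pc2"], c=colors[tissue], marker=markers[condition],
            edgecolor="k", linewidth=0.3, s=40,
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("sample overview (red=intima, blue=media; ^=ligated, o=sham)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_panels(series_by_gene: dict, fits: pd.DataFrame, path, ncols: int = 4) -> None:
    """Small-multiple expression-vs-WSS panels, annotated with the shape class."""
    genes = list(series_by_gene)
    if not genes:
        return
    nrows = -(-len(genes) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False)
    classes = fits.set_index("gene")["shape_class"] if len(fits) else pd.Series(dtype=object)
    for ax, gene in zip(axes.flat, genes):
        pts = series_by_gene[gene]
        ax.plot(pts["wss_pa"], pts["rpkm"], "o", ms=4)
        ax.set_title(f"{gene} ({classes.get(gene, '?')})", fontsize=8)
        ax.set_xlabel("WSS (Pa)", fontsize=7)
        ax.set_ylabel("RPKM", fontsize=7)
    for ax in axes.flat[len(genes):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
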