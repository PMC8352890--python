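"""Tissue-purity and sample-structure checks for microdissected samples.

Laser microdissection of the thin intimal layer inevitably captures some
underlying smooth muscle, so compartment purity is judged from marker genes:
endothelial markers (PECAM1, VWF, CDH5) should be strongly enriched in
intima over media, while smooth-muscle markers (DES, ACTA2, MYH11) appear in
intima at a modest fraction of their medial level (tissue leakage).  A PCA
overview checks that samples organize by compartment and flow condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


def _matched_pairs(samples: pd.DataFrame):
    """Yield (animal, location, condition, intima_sample, media_sample)."""
    intima = samples[samples["tissue"] == "intima"]
    media = samples[samples["tissue"] == "media"]
    media_by_key = {(r.animal_id, r.location): r.Index for r in media.itertuples()}
    for r in intima.itertuples():
        partner = media_by_key.get((r.animal_id, r.location))
        if partner is None:
            raise ValueError(
                f"no media partner for intima sample {r.Index!r} "
                f"(animal={r.animal_id!r}, location={r.location!r})"
            )
        yield r.animal_id, r.location, r.condition, r.Index, partner


def marker_purity(
    rpkm: pd.DataFrame,
    samples: pd.DataFrame,
    intima_markers,
    media_markers,
):
    """Per-pair intima/media RPKM ratios for marker genes.

    Returns ``(pairs, summary)``.  ``pairs`` has one row per marker per
    matched (animal, location) pair with the intima/media RPKM ratio; a ratio
    is flagged infinite iff media RPKM is 0 while intima RPKM is > 0 and such
    pairs are excluded from the mean.  For media markers the summary also
    reports the intima level as a percentage of the media level (leakage).
    """
    markers = [(m, "intima") for m in intima_markers] + [(m, "media") for m in media_markers]
    for marker, _ in markers:
        if marker not in rpkm.index:
            raise ValueError(f"marker gene {marker!r} absent from expression matrix")

    rows = []
    for marker, marker_class in markers:
        for animal, location, condition, i_s, m_s in _matched_pairs(samples):
            iv = float(rpkm.at[marker, i_s])
            mv = float(rpkm.at[marker, m_s])
            infinite = mv == 0 and iv > 0
            ratio = np.inf if infinite else (np.nan if mv == 0 else iv / mv)
            rows.append(
                {
                    "marker": marker,
                    "marker_class": marker_class,
                    "animal_id": animal,
                    "location": location,
                    "condition": condition,
                    "intima_rpkm": iv,
                    "media_rpkm": mv,
                    "ratio": ratio,
                    "is_infinite": infinite,
                }
            )
    pairs = pd.DataFrame(rows)

    summaries = []
    for (marker, marker_class), grp in pairs.groupby(["marker", "marker_class"], sort=False):
        finite = grp.loc[np.isfinite(grp["ratio"]), "ratio"]
        summaries.append(
            {
                "marker": marker,
                "marker_class": marker_class,
                "mean_ratio": finite.mean() if len(finite) else np.nan,
                "n_pairs": len(grp),
                "n_infinite": int(grp["is_infinite"].sum()),
                "mean_pct_of_media": 100.0 * finite.mean() if len(finite) else np.nan,
            }
        )
    summary = pd.DataFrame(summaries)
    return pairs, summary


def pca_overview(matrix: ExpressionMatrix, samples: pd.DataFrame):
    """First two principal components of log2(count+1) expression per sample.

    Genes with zero count sum across all samples are removed; the remaining
    values are log2(x+1)-transformed and centered per gene (covariance PCA).
    Returns ``(coords, explained)`` where ``coords`` has columns pc1/pc2 per
    sample and ``explained`` is the explained-variance fraction of each
    component.  A matrix with no variance at all yields all-zero coordinates.
    """
    if matrix.counts.shape[1] < 3:
        raise ValueError("PCA overview needs at least 3 samples")
    counts = matrix.counts.loc[:, samples.index]
    keep = counts.sum(axis=1) > 0
    if int(keep.sum()) < 2:
        raise ValueError("fewer than 2 genes with nonzero counts")
    x = np.log2(counts.loc[keep].to_numpy(dtype=float) + 1.0).T  # samples x genes
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        coords = pd.DataFrame(0.0, index=samples.index, columns=["pc1", "pc2"])
        return coords, np.zeros(2)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(centered)
    coords = pd.DataFrame(scores, index=samples.index, columns=["pc1", "pc2"])
    return coords, pca.explained_variance_ratio_.copy()
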