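"""All-pairs intima-media expression correlation screen.

Every intimal DEG is correlated with every medial DEG across the eight
matched measurement slots (2 locations x 2 conditions x 2 animals; each slot
holds exactly one intima and one media sample from the same animal and
location).  A pair is kept when |Pearson r| > 0.9 AND the two-sided p-value
is < 1e-4; at n = 8 the p-threshold is the binding condition (it implies
|r| >~ 0.96) and both are applied literally.  Per-intimal-gene correlate
tallies feed the candidate rule: extracellular product AND > 200 medial
correlates.

Correlations default to log2(RPKM+1); ``scale="rpkm"`` switches to raw RPKM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCALES = ("log2_rpkm", "rpkm")


def matched_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Map measurement slots to their intima/media sample pair.

    Slots are ordered canonically by (location, condition, animal_id), so any
    permutation of the input rows yields the same design.  Raises if a slot
    is missing a tissue or holds duplicates.
    """
    slots = {}
    for row in samples.itertuples():
        key = (row.location, row.condition, row.animal_id)
        slot = slots.setdefault(key, {"wss_pa": row.wss_pa})
        if row.tissue in slot and row.tissue != "wss_pa":
            raise ValueError(f"duplicate {row.tissue} sample in slot {key}")
        slot[row.tissue] = row.Index
    rows = []
    for key in sorted(slots):
        slot = slots[key]
        for tissue in ("intima", "media"):
            if tissue not in slot:
                raise ValueError(f"slot {key} is missing its {tissue} sample")
        rows.append(
            {
                "slot": "{}:{}:{}".format(*key),
                "location": key[0],
                "condition": key[1],
                "animal_id": key[2],
                "wss_pa": slot["wss_pa"],
                "intima": slot["intima"],
                "media": slot["media"],
            }
        )
    return pd.DataFrame(rows).set_index("slot")


def assemble_matched_vectors(
    rpkm: pd.DataFrame, samples: pd.DataFrame, gene: str, tissue: str
) -> pd.Series:
    """Expression of one gene over the ordered measurement slots of a tissue."""
    if gene not in rpkm.index:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    if tissue not in ("intima", "media"):
        raise ValueError(f"tissue must be 'intima' or 'media', got {tissue!r}")
    design = matched_design(samples)
    values = rpkm.loc[gene, design[tissue]].to_numpy(dtype=float)
    return pd.Series(values, index=design.index, name=gene)


def pearson_with_p(x, y):
    """Pearson r with a two-sided p from t = r sqrt(n-2)/sqrt(1-r^2).

    Requires n >= 3 and nonzero variance in both vectors; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:  # exactly collinear up to rounding
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2_rpkm":
        return np.log2(values + 1.0)
    if scale == "rpkm":
        return values
    raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def screen_pairs(
    rpkm: pd.DataFrame,
    samples: pd.DataFrame,
    intimal_genes,
    medial_genes,
    r_threshold: float = 0.9,
    p_threshold: float = 1e-4,
    scale: str = "log2_rpkm",
) -> pd.DataFrame:
    """Correlate every intimal gene against every medial gene over the slots.

    Returns the pairs with |r| > r_threshold and p < p_threshold, ordered by
    (intimal gene, medial gene).  Genes with zero variance across slots are
    skipped (logged), not fatal.
    """
    intimal_genes = sorted(set(intimal_genes))
    medial_genes = sorted(set(medial_genes))
    empty = pd.DataFrame(
        columns=["intimal_gene", "medial_gene", "r", "p_value", "sign", "n_points"]
    )
    if not intimal_genes or not medial_genes:
        logger.warning("empty DEG set supplied to the correlation screen; no pairs")
        return empty
    design = matched_design(samples)
    n = len(design)
    xi = _transform(rpkm.loc[intimal_genes, design["intima"]].to_numpy(dtype=float), scale)
    xm = _transform(rpkm.loc[medial_genes, design["media"]].to_numpy(dtype=float), scale)

    def standardize(block, labels):
        centered = block - block.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        keep = sd > 0
        dropped = [g for g, k in zip(labels, keep) if not k]
        if dropped:
            logger.info("skipping %d zero-variance gene(s) in screen", len(dropped))
        z = centered[keep] / sd[keep][:, None]
        return z, [g for g, k in zip(labels, keep) if k]

    zi, kept_i = standardize(xi, intimal_genes)
    zm, kept_m = standardize(xm, medial_genes)
    if not kept_i or not kept_m:
        return empty
    r = zi @ zm.T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(t, n - 2))
    hit_i, hit_m = np.nonzero((np.abs(r) > r_threshold) & (p < p_threshold))
    pairs = pd.DataFrame(
        {
            "intimal_gene": [kept_i[i] for i in hit_i],
            "medial_gene": [kept_m[j] for j in hit_m],
            "r": r[hit_i, hit_m],
            "p_value": p[hit_i, hit_m],
            "sign": np.where(r[hit_i, hit_m] > 0, 1, -1),
            "n_points": n,
        }
    )
    return pairs.sort_values(["intimal_gene", "medial_gene"]).reset_index(drop=True)


def count_correlates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per intimal gene: total, positive and negative medial correlates.

    Intimal genes with no passing pairs are omitted (no zero rows); the
    identity n_total = n_pos + n_neg holds by construction.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["intimal_gene", "n_total", "n_pos", "n_neg"]).set_index(
            "intimal_gene"
        )
    grouped = pairs.groupby("intimal_gene")["sign"]
    out = pd.DataFrame(
        {
            "n_pos": grouped.apply(lambda s: int((s == 1).sum())),
            "n_neg": grouped.apply(lambda s: int((s == -1).sum())),
        }
    )
    out["n_total"] = out["n_pos"] + out["n_neg"]
    out.index.name = "intimal_gene"
    return out[["n_total", "n_pos", "n_neg"]].sort_index()


def check_count_identity(table: pd.DataFrame) -> list:
    """Genes violating n_total = n_pos + n_neg (for imported correlate tables)."""
    bad = table.index[table["n_total"] != table["n_pos"] + table["n_neg"]]
    return sorted(bad)


def select_candidates(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    directions: pd.Series,
    min_correlates: int = 200,
) -> pd.DataFrame:
    """Intimal DEGs with an extracellular product and > min_correlates correlates.

    ``annotation`` is the extracellular-product table (index gene); genes
    missing from it are treated as non-extracellular (logged).  ``directions``
    maps intimal gene -> direction under flow ('up'/'down').  The boundary is
    strict: exactly ``min_correlates`` correlates is excluded.
    """
    rows = []
    missing = [g for g in counts.index if g not in annotation.index]
    if missing:
        logger.info(
            "%d screened gene(s) missing from extracellular annotation; treated as "
            "non-extracellular", len(missing)
        )
    for gene, row in counts.iterrows():
        if gene not in annotation.index or not bool(annotation.at[gene, "is_extracellular"]):
            continue
        if row["n_total"] <= min_correlates:
            continue
        rows.append(
            {
                "intimal_gene": gene,
                "direction_under_flow": directions.get(gene, "up"),
                "n_total": int(row["n_total"]),
                "n_pos": int(row["n_pos"]),
                "n_neg": int(row["n_neg"]),
                "product_class": annotation.at[gene, "product_class"],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "intimal_gene",
            "direction_under_flow",
            "n_total",
            "n_pos",
            "n_neg",
            "product_class",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["direction_under_flow", "n_total", "intimal_gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return out
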