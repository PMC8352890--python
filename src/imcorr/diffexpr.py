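"""Negative-binomial differential expression between ligated and sham groups.

Four two-group comparisons are run: intima/media x straight artery (BA) /
terminus (BT), ligated vs sham.  Genes enter a comparison if their maximum
group-mean expression exceeds 1 RPKM (the detectability rule).  Counts are
library-size normalized with total-count size factors (ratio to the
geometric-mean library), per-gene NB dispersions are estimated by method of
moments and shrunk halfway toward the median dispersion, and significance
comes from an exact-style conditional NB test on group count sums given the
total.  Benjamini-Hochberg correction is applied per comparison and a gene
is a DEG when detectable with q < 0.05.

The stage is pluggable: a TSV of (gene, log2_fc, p_value, q_value) from any
external DE tool can be fed to downstream stages instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, compute_rpkm

_FULL_SUPPORT_MAX = 20_000  # above this total, the conditional pmf is windowed
_WINDOW_SD = 50.0

DEFAULT_SHRINK_WEIGHT = 0.3  # raw vs common (mean) dispersion
DEFAULT_PRIOR_COUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample total counts divided by their geometric mean."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    gmean = np.exp(np.log(totals).mean())
    return totals / gmean


def filter_detectable(rpkm: pd.DataFrame, groups, min_rpkm: float = 1.0) -> pd.Index:
    """Genes whose maximum group-mean RPKM exceeds ``min_rpkm``.

    ``groups`` maps group label -> list of sample ids.
    """
    if not groups:
        raise ValueError("need at least one group")
    means = []
    for label, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {label!r} is empty")
        means.append(rpkm[list(members)].mean(axis=1))
    max_mean = pd.concat(means, axis=1).max(axis=1)
    return rpkm.index[max_mean > min_rpkm]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_dispersion(
    counts: pd.DataFrame,
    groups,
    sf: pd.Series | None = None,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
) -> pd.Series:
    """Per-gene NB dispersion via group-centered method of moments.

    For normalized counts y = c / sf with mean mu, Var(y) ~= mu * mean(1/sf)
    + phi * mu^2 within a group, so phi is estimated from the excess of the
    sample variance over the Poisson part.  The mu^2 denominator uses the
    bias-corrected m^2 - v/n (E[m^2] exceeds mu^2 by Var(m)).  Raw per-gene
    estimates (floored at 0) are shrunk toward the across-gene mean of the
    raw values: phi = w * raw + (1 - w) * common.  With few replicates the
    raw estimates are extremely noisy and right-skewed, so the common value
    uses the mean (a median would systematically undershoot the true
    dispersion and inflate the test's type-I error).
    """
    group_lists = [list(v) for v in groups.values()]
    for label, members in zip(groups, group_lists):
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples; cannot estimate dispersion")
    if sf is None:
        sf = size_factors(counts)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for members in group_lists:
        y = counts[members].to_numpy(dtype=float) / sf[members].to_numpy()
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        inv_sf = float(np.mean(1.0 / sf[members].to_numpy()))
        num += v - m * inv_sf
        den += np.maximum(m**2 - v / len(members), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    raw = np.maximum(raw, 0.0)
    common = float(np.mean(raw[den > 0])) if np.any(den > 0) else 0.0
    phi = shrink_weight * raw + (1.0 - shrink_weight) * common
    return pd.Series(phi, index=counts.index)


def log2_fold_change(
    counts: pd.DataFrame,
    group_a,
    group_b,
    sf: pd.Series | None = None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.Series:
    """log2((mean normalized A + prior) / (mean normalized B + prior)).

    The prior keeps fold changes finite when one group is all zeros.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if sf is None:
        sf = size_factors(counts)
    a = (counts[list(group_a)] / sf[list(group_a)]).mean(axis=1)
    b = (counts[list(group_b)] / sf[list(group_b)]).mean(axis=1)
    return np.log2((a + prior_count) / (b + prior_count))


def _conditional_two_sided_p(s_obs: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional test of group-A sum given the total.

    Under a shared mean, sum_A ~ NB(n_a * mu, phi / n_a) (Poisson when phi=0)
    and the test conditions on sum_A + sum_B = t, with the common mean
    estimated as t / (n_a + n_b).  The p-value sums all outcome probabilities
    not exceeding the observed one (minimum-likelihood rule).
    """
    if t == 0:
        return 1.0
    frac = n_a / (n_a + n_b)
    if t <= _FULL_SUPPORT_MAX:
        a = np.arange(t + 1)
    else:
        mu = t / (n_a + n_b)
        sd = np.sqrt(max(t * frac * (1 - frac) * (1.0 + phi * mu), 1.0))
        w = int(np.ceil(_WINDOW_SD * sd))
        centers = [int(round(t * frac)), int(s_obs)]
        pieces = [np.arange(max(0, c - w), min(t, c + w) + 1) for c in centers]
        a = np.unique(np.concatenate(pieces))
    if phi <= 1e-12:
        logf = stats.binom.logpmf(a, t, frac)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mu = t / (n_a + n_b)
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logf = stats.nbinom.logpmf(a, r_a, p_a) + stats.nbinom.logpmf(t - a, r_b, p_b)
    total = logsumexp(logf)
    log_obs = logf[np.searchsorted(a, s_obs)]
    keep = logf <= log_obs + 1e-8
    return float(min(1.0, np.exp(logsumexp(logf[keep]) - total)))


def nb_exact_test(
    counts: pd.DataFrame,
    group_a,
    group_b,
    dispersion: pd.Series,
    sf: pd.Series | None = None,
) -> pd.Series:
    """Two-sided conditional NB p-value per gene for group A vs group B.

    Counts are first equalized across libraries by dividing by size factors
    and rounding (pseudo-counts), so the group sums are comparable.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if sf is None:
        sf = size_factors(counts)
    if (sf[group_a + group_b] <= 0).any():
        raise ValueError("size factors must be positive")
    pseudo = np.rint(
        counts[group_a + group_b].to_numpy(dtype=float)
        / sf[group_a + group_b].to_numpy()
    ).astype(np.int64)
    n_a, n_b = len(group_a), len(group_b)
    s_a = pseudo[:, :n_a].sum(axis=1)
    s_tot = pseudo.sum(axis=1)
    phi = dispersion.reindex(counts.index).fillna(0.0).to_numpy()
    p = np.ones(len(counts))
    for i in range(len(counts)):
        p[i] = _conditional_two_sided_p(int(s_a[i]), int(s_tot[i]), n_a, n_b, float(phi[i]))
    return pd.Series(p, index=counts.index, name="p_value")


# ---------------------------------------------------------------------------
# Comparison orchestration


def de_comparison(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    tissue: str,
    location: str,
    min_rpkm: float = 1.0,
    q_threshold: float = 0.05,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """Ligated-vs-sham differential expression for one (tissue, location).

    Returns a per-gene table (all genes of the matrix) with log2_fc, p_value,
    q_value, group mean RPKM, detectable and is_deg flags.  p/q are NaN for
    non-detectable genes, which are excluded from testing and correction.
    """
    sel = samples[(samples["tissue"] == tissue) & (samples["location"] == location)]
    ligated = list(sel.index[sel["condition"] == "ligated"])
    sham = list(sel.index[sel["condition"] == "sham"])
    if not ligated or not sham:
        raise ValueError(f"comparison ({tissue}, {location}) lacks a ligated or sham group")
    cols = ligated + sham
    sub = ExpressionMatrix(
        counts=matrix.counts[cols].copy(), gene_length_bp=matrix.gene_length_bp.copy()
    )
    rpkm = compute_rpkm(sub)
    sf = size_factors(sub.counts)
    groups = {"ligated": ligated, "sham": sham}
    detectable = filter_detectable(rpkm, groups, min_rpkm=min_rpkm)

    result = pd.DataFrame(index=matrix.gene_ids)
    result["comparison"] = f"{tissue}_{location}"
    result["log2_fc"] = log2_fold_change(sub.counts, ligated, sham, sf, prior_count)
    result["mean_rpkm_ligated"] = rpkm[ligated].mean(axis=1)
    result["mean_rpkm_sham"] = rpkm[sham].mean(axis=1)
    result["detectable"] = result.index.isin(detectable)
    result["p_value"] = np.nan
    result["q_value"] = np.nan
    if len(detectable):
        det_counts = sub.counts.loc[detectable]
        phi = estimate_dispersion(det_counts, groups, sf, shrink_weight)
        p = nb_exact_test(det_counts, ligated, sham, phi, sf)
        result.loc[detectable, "p_value"] = p
        result.loc[detectable, "q_value"] = bh_adjust(p.to_numpy())
    result["is_deg"] = result["detectable"] & (result["q_value"] < q_threshold)
    result["direction"] = np.where(result["log2_fc"] > 0, "up", "down")
    return result


def run_differential_expression(matrix, samples, **kwargs) -> dict:
    """All four (tissue x location) ligated-vs-sham comparisons."""
    return {
        (tissue, location): de_comparison(matrix, samples, tissue, location, **kwargs)
        for tissue in ("intima", "media")
        for location in ("BA", "BT")
    }


@dataclass
class DegSummary:
    """DEG sets per comparison plus cross-location overlap bookkeeping."""

    per_comparison: dict = field(default_factory=dict)  # (tissue, loc) -> DataFrame of DEGs
    counts: dict = field(default_factory=dict)  # (tissue, loc) -> {up, down, total}
    overlap: dict = field(default_factory=dict)  # tissue -> |BA DEGs & BT DEGs|
    union: dict = field(default_factory=dict)  # tissue -> sorted union gene list
    volcano: dict = field(default_factory=dict)  # (tissue, loc) -> volcano table


def call_degs(results: dict, q_threshold: float = 0.05) -> DegSummary:
    """Summarize DEG calls from the four comparison tables.

    A gene is a DEG in a comparison when detectable and q < ``q_threshold``.
    For each tissue the BA/BT overlap counts genes significant at both
    locations; a gene significant at both appears once in each list and once
    in the overlap.
    """
    expected = {(t, l) for t in ("intima", "media") for l in ("BA", "BT")}
    missing = expected - set(results)
    if missing:
        raise ValueError(f"missing comparison(s): {sorted(missing)}")
    summary = DegSummary()
    for key, table in results.items():
        deg = table[table["detectable"] & (table["q_value"] < q_threshold)].copy()
        summary.per_comparison[key] = deg
        summary.counts[key] = {
            "up": int((deg["direction"] == "up").sum()),
            "down": int((deg["direction"] == "down").sum()),
            "total": len(deg),
        }
        volcano = table.loc[table["detectable"], ["log2_fc", "p_value"]].copy()
        with np.errstate(divide="ignore"):
            volcano["neg_log10_p"] = -np.log10(volcano["p_value"])
        volcano["is_deg"] = table.loc[table["detectable"], "q_value"] < q_threshold
        summary.volcano[key] = volcano
    for tissue in ("intima", "media"):
        ba = set(summary.per_comparison[(tissue, "BA")].index)
        bt = set(summary.per_comparison[(tissue, "BT")].index)
        summary.overlap[tissue] = len(ba & bt)
        summary.union[tissue] = sorted(ba | bt)
    return summary


def deg_directions(results: dict, tissue: str, genes) -> pd.Series:
    """Direction under flow for genes of one tissue: sign of the mean
    log2 fold change across the tissue's BA and BT comparisons."""
    fc = (
        results[(tissue, "BA")].loc[genes, "log2_fc"]
        + results[(tissue, "BT")].loc[genes, "log2_fc"]
    ) / 2.0
    return pd.Series(np.where(fc > 0, "up", "down"), index=pd.Index(genes), name="direction")


def read_de_table(path) -> pd.DataFrame:
    """Import an external DE result TSV (gene, log2_fc, p_value, q_value, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2_fc", "p_value", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "detectable" not in df.columns:
        df["detectable"] = True
    if "is_deg" not in df.columns:
        df["is_deg"] = df["detectable"] & (df["q_value"] < 0.05)
    if "direction" not in df.columns:
        df["direction"] = np.where(df["log2_fc"] > 0, "up", "down")
    return df
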