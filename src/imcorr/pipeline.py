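"""End-to-end orchestration: QC -> differential expression -> correlation
screen -> enrichment -> dose-response, from a single config.

Every stage threshold is a named config key defaulting to the study's value
(detectability 1 RPKM, DEG q < 0.05, screen |r| > 0.9 and p < 1e-4, > 200
correlates, enrichment q < 0.05, > 50% occurrence, similarity cutoff 0.90,
dose-response r >= 0.8), so sensitivity analyses are one-line edits.  All
randomness flows from one root seed via derived substreams, and identical
config + seed produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrscreen import count_correlates, screen_pairs, select_candidates
from .diffexpr import call_degs, deg_directions, run_differential_expression
from .doseresponse import classify_genes
from .enrich import run_candidate_ontology_analysis
from .io import (
    compute_rpkm,
    read_counts,
    read_extracellular,
    read_gmt,
    read_obo,
    read_samples,
)
from .qc import marker_purity, pca_overview
from .simulate import SimulationConfig, generate_dataset, make_extracellular_annotation, make_gene_sets

logger = logging.getLogger(__name__)

DEFAULT_INTIMA_MARKERS = ("PECAM1", "VWF", "CDH5")
DEFAULT_MEDIA_MARKERS = ("DES", "ACTA2", "MYH11")


def report_totals(n_pos: int, n_neg: int) -> int:
    """Total correlated pairs: n_total = n_pos + n_neg."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("pair counts must be non-negative")
    return int(n_pos) + int(n_neg)


@dataclass
class RunConfig:
    """Paths (or a simulation config) plus every stage threshold."""

    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    extracellular_path: str | None = None
    gene_sets_path: str | None = None
    ontology_path: str | None = None
    intima_markers: tuple = DEFAULT_INTIMA_MARKERS
    media_markers: tuple = DEFAULT_MEDIA_MARKERS
    rpkm_min: float = 1.0
    q_deg: float = 0.05
    r_threshold: float = 0.9
    p_threshold: float = 1e-4
    min_correlates: int = 200
    q_enrich: float = 0.05
    occurrence_min: float = 0.5
    similarity_cutoff: float = 0.90
    r_linear: float = 0.8
    expression_scale: str = "log2_rpkm"
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("q_deg", 0, 1), ("p_threshold", 0, 1), ("q_enrich", 0, 1),
            ("r_threshold", 0, 1), ("occurrence_min", 0, 1),
            ("similarity_cutoff", 0, 1), ("r_linear", -1, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.simulation is None and not (self.counts_path and self.samples_path):
            raise ValueError("need either a simulation config or counts/samples paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "wss_map" in sim:
                sim["wss_map"] = {
                    (loc, cond): float(v)
                    for key, v in sim["wss_map"].items()
                    for loc, cond in [tuple(key.split("/"))]
                }
            if "gene_length_range" in sim:
                sim["gene_length_range"] = tuple(sim["gene_length_range"])
            sim = SimulationConfig(**sim)
        for key in ("intima_markers", "media_markers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["wss_map"] = {f"{loc}/{cond}": v for (loc, cond), v in sim["wss_map"].items()}
            sim["gene_length_range"] = list(sim["gene_length_range"])
            out["simulation"] = sim
        out["intima_markers"] = list(self.intima_markers)
        out["media_markers"] = list(self.media_markers)
        return out


def _load_inputs(config: RunConfig):
    """Return (matrix, samples, annotation, gene_sets, ontology, truth)."""
    if config.simulation is not None:
        # substreams derived from the run seed keep one root seed in charge
        root = np.random.SeedSequence(config.seed)
        sim_seed, sets_seed = (int(s) % (2**31) for s in root.generate_state(2))
        sim = dataclasses.replace(config.simulation, seed=sim_seed)
        matrix, samples, truth = generate_dataset(sim)
        annotation = make_extracellular_annotation(truth)
        gene_sets, ontology, planted = make_gene_sets(truth, seed=sets_seed)
        return matrix, samples, annotation, gene_sets, ontology, truth, planted
    matrix = read_counts(config.counts_path)
    samples = read_samples(config.samples_path)
    annotation = (
        read_extracellular(config.extracellular_path)
        if config.extracellular_path
        else pd.DataFrame(columns=["is_extracellular", "product_class"])
    )
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    ontology = read_obo(config.ontology_path) if config.ontology_path else None
    return matrix, samples, annotation, gene_sets, ontology, None, None


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write stage outputs plus report.json.

    Returns the consolidated report dict.  Every number in the report is
    derived from the stage tables that are also written to disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, samples, annotation, gene_sets, ontology, truth, planted = _load_inputs(config)
    rpkm = compute_rpkm(matrix)

    # --- QC ------------------------------------------------------------
    intima_markers = [m for m in config.intima_markers if m in rpkm.index]
    media_markers = [m for m in config.media_markers if m in rpkm.index]
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    marker_summary = None
    if intima_markers and media_markers:
        marker_pairs, marker_summary = marker_purity(
            rpkm, samples, intima_markers, media_markers
        )
        marker_pairs.to_csv(qc_dir / "marker_purity_pairs.tsv", sep="\t", index=False)
        marker_summary.to_csv(qc_dir / "marker_purity_summary.tsv", sep="\t", index=False)
    coords, explained = pca_overview(matrix, samples)
    coords.to_csv(qc_dir / "pca_coordinates.tsv", sep="\t")

    # --- differential expression ---------------------------------------
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    results = run_differential_expression(
        matrix, samples, min_rpkm=config.rpkm_min, q_threshold=config.q_deg
    )
    for (tissue, location), table in results.items():
        table.to_csv(de_dir / f"{tissue}_{location}.tsv", sep="\t")
    degs = call_degs(results, q_threshold=config.q_deg)

    # --- correlation screen ---------------------------------------------
    screen_dir = out / "screen"
    screen_dir.mkdir(exist_ok=True)
    intimal_degs = degs.union["intima"]
    medial_degs = degs.union["media"]
    pairs = screen_pairs(
        rpkm,
        samples,
        intimal_degs,
        medial_degs,
        r_threshold=config.r_threshold,
        p_threshold=config.p_threshold,
        scale=config.expression_scale,
    )
    pairs.to_csv(screen_dir / "pairs.tsv", sep="\t", index=False)
    correlate_counts = count_correlates(pairs)
    correlate_counts.to_csv(screen_dir / "correlate_counts.tsv", sep="\t")
    directions = deg_directions(results, "intima", list(correlate_counts.index))
    candidates = select_candidates(
        correlate_counts, annotation, directions, min_correlates=config.min_correlates
    )
    candidates.to_csv(screen_dir / "candidates.tsv", sep="\t", index=False)

    # --- enrichment ------------------------------------------------------
    enrich_dir = out / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    background = sorted(
        set().union(
            *(set(t.index[t["detectable"]]) for t in results.values())
        )
    )
    enrichment_report = {}
    if gene_sets is not None and ontology is not None and len(candidates):
        strata = run_candidate_ontology_analysis(
            candidates,
            pairs,
            gene_sets,
            ontology,
            background,
            q_enrich=config.q_enrich,
            occurrence_min=config.occurrence_min,
            similarity_cutoff=config.similarity_cutoff,
        )
        for (direction, sign_label), data in strata.items():
            stem = f"{direction}_{sign_label}"
            data["pooled"].to_csv(enrich_dir / f"{stem}_pooled.tsv", sep="\t", index=False)
            data["reduced"].to_csv(enrich_dir / f"{stem}_reduced.tsv", sep="\t", index=False)
            flagged = data["pooled"]
            flagged = flagged[flagged["flagged"]] if len(flagged) else flagged
            enrichment_report[stem] = {
                "n_queries": len(data["queries"]),
                "flagged_terms": sorted(flagged["term_id"]) if len(flagged) else [],
                "representatives": sorted(set(data["reduced"]["representative"]))
                if len(data["reduced"])
                else [],
            }
    else:
        logger.info("enrichment skipped: no gene sets/ontology or no candidates")

    # --- dose-response ---------------------------------------------------
    dose_dir = out / "dose"
    dose_dir.mkdir(exist_ok=True)
    dose = classify_genes(
        list(candidates["intimal_gene"]), rpkm, samples, r_linear=config.r_linear
    )
    dose.to_csv(dose_dir / "dose_fits.tsv", sep="\t", index=False)

    # --- consolidated report --------------------------------------------
    n_pos = int((pairs["sign"] == 1).sum()) if len(pairs) else 0
    n_neg = int((pairs["sign"] == -1).sum()) if len(pairs) else 0
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "deg_counts": {
            f"{t}_{l}": degs.counts[(t, l)] for t in ("intima", "media") for l in ("BA", "BT")
        },
        "deg_overlap": {t: degs.overlap[t] for t in ("intima", "media")},
        "deg_union": {t: len(degs.union[t]) for t in ("intima", "media")},
        "pca_explained_variance": [float(v) for v in explained],
        "marker_purity": (
            {
                row["marker"]: {
                    "marker_class": row["marker_class"],
                    "mean_ratio": None
                    if pd.isna(row["mean_ratio"])
                    else float(row["mean_ratio"]),
                    "n_infinite": int(row["n_infinite"]),
                }
                for _, row in marker_summary.iterrows()
            }
            if marker_summary is not None
            else {}
        ),
        "pairs": {"total": report_totals(n_pos, n_neg), "positive": n_pos, "negative": n_neg},
        "candidates": candidates.to_dict(orient="records"),
        "enrichment": enrichment_report,
        "dose_response": {row["gene"]: row["shape_class"] for _, row in dose.iterrows()},
    }
    if planted is not None:
        report["planted_terms"] = planted
    report_json = json.dumps(report, sort_keys=True, indent=2, default=_jsonify)
    (out / "report.json").write_text(report_json, encoding="utf-8")
    return report


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON-serializable: {type(value)}")
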