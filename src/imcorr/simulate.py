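"""Synthetic paired intima/media RNA-seq count data with planted ground truth.

The generator emulates the carotid-ligation study design: 2 tissues
(intima, media) x 2 locations (basilar artery BA, basilar terminus BT) x
2 conditions (ligated, sham) x 2 animals per condition = 16 samples, each
with a local mean wall shear stress (WSS, Pa) taken from a per-cell map.

Planted structure:

* tissue markers -- highly expressed in their own compartment, near-baseline
  in the other (endothelial PECAM1/VWF/CDH5 vs smooth-muscle DES/ACTA2/MYH11);
* intimal signal genes -- true intimal expression follows a WSS dose-response
  shape (linear increase, plateau above a knee, or a peaked decline with its
  maximum near 20 Pa and near-baseline expression above 50 Pa);
* medial responders -- each tied to one signal gene, with true log-expression
  = sign * coupling_strength * (signal log-expression), centered on a common
  baseline; this is the signal-response structure the correlation screen is
  meant to recover;
* null genes -- constant expression, differing only by noise.

Noise model: a shared log-normal multiplier per (gene, animal) so that tissue
pairs from one animal stay coupled (the screen correlates matched locations,
not independent draws), then negative-binomial count sampling with mean
true_RPKM * gene_length_kb * library_size / 1e6.  Tissue cross-contamination
is applied to true expression before count sampling: observed intimal
expression = (1 - f) * intima + f * media, modeling physical admixture at
microdissection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    OntologyGraph,
    PRODUCT_CLASSES,
    ontology_from_edges,
    validate_sample_table,
    write_counts,
    write_extracellular,
    write_gmt,
    write_obo,
    write_samples,
)

SHAPES = ("linear", "plateau", "peaked_decline")

#: Default WSS (Pa) per (location, condition) cell: ~10 Pa in the straight
#: basilar artery pre-ligation rising to ~40 Pa after ligation, and ~20 Pa at
#: the terminus rising to ~130 Pa.
DEFAULT_WSS_MAP = {
    ("BA", "sham"): 10.0,
    ("BT", "sham"): 20.0,
    ("BA", "ligated"): 40.0,
    ("BT", "ligated"): 130.0,
}

#: Default dose-response shape parameters (RPKM units).  The peaked-decline
#: maximum sits at 20 Pa so the highest expression falls in the 10-30 Pa
#: range, and the curve is within 10% of its baseline above 50 Pa.
DEFAULT_SHAPE_PARAMS = {
    "linear": {"base": 5.0, "slope": 1.0},
    "plateau": {"base": 1.0, "slope": 3.0, "knee_pa": 40.0},
    "peaked_decline": {
        "baseline": 3.0,
        "amplitude": 45.0,
        "peak_pa": 20.0,
        "log_width": 0.35,
    },
}

_MARKER_LEVEL = 200.0  # RPKM in the marker's own compartment
_OTHER_TISSUE_LEVEL = 1.0  # baseline in the opposite compartment
_RESPONDER_BASE = 20.0  # geometric center of responder expression
_NULL_LOG_MEAN = np.log(40.0)
_NULL_LOG_SD = 1.2
_PARAM_JITTER_SD = 0.1  # per-gene log-normal jitter on shape amplitudes

_INTIMA_MARKERS = ("PECAM1", "VWF", "CDH5")
_MEDIA_MARKERS = ("DES", "ACTA2", "MYH11")


def response_curve(shape: str, wss, params: dict | None = None):
    """Evaluate a dose-response shape at WSS values (Pa).

    ``linear``: base + slope * wss (affine increasing).
    ``plateau``: base + slope * min(wss, knee_pa) (increasing, then flat).
    ``peaked_decline``: baseline + amplitude * exp(-(ln(wss / peak_pa))^2 /
    (2 * log_width^2)); its maximum lies at ``peak_pa`` (< 40 Pa by default)
    and the bump decays to <10% of the maximum above 50 Pa.
    """
    wss = np.asarray(wss, dtype=float)
    if np.any(wss < 0):
        raise ValueError("wss must be non-negative")
    if shape not in SHAPES:
        raise ValueError(f"unknown response shape {shape!r}; expected one of {SHAPES}")
    p = dict(DEFAULT_SHAPE_PARAMS[shape])
    if params:
        p.update(params)
    if shape == "linear":
        out = p["base"] + p["slope"] * wss
    elif shape == "plateau":
        out = p["base"] + p["slope"] * np.minimum(wss, p["knee_pa"])
    else:
        with np.errstate(divide="ignore"):
            logratio = np.where(wss > 0, np.log(np.maximum(wss, 1e-300) / p["peak_pa"]), -np.inf)
        bump = np.exp(-(logratio**2) / (2.0 * p["log_width"] ** 2))
        out = p["baseline"] + p["amplitude"] * bump
    return out if out.shape else float(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    ``n_background_genes`` is the total gene budget; marker, signal and
    responder classes are carved out of it and the remainder becomes null
    genes.  ``contamination_fraction`` is the fraction of medial true
    expression admixed into intimal samples (f in observed_intima =
    (1-f)*intima + f*media).
    """

    n_animals_per_condition: int = 2
    n_background_genes: int = 2000
    n_marker_genes_per_tissue: int = 3
    n_signal_up: int = 6
    n_signal_down: int = 12
    responders_per_signal: int = 48
    coupling_strength: float = 1.0
    wss_map: dict = field(default_factory=lambda: dict(DEFAULT_WSS_MAP))
    biological_cv: float = 0.02
    nb_dispersion: float = 0.002
    library_size_mean: int = 10_000_000
    gene_length_range: tuple = (500, 4000)
    contamination_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_animals_per_condition",
            "n_background_genes",
            "n_marker_genes_per_tissue",
            "n_signal_up",
            "n_signal_down",
            "responders_per_signal",
            "library_size_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.biological_cv < 0 or self.nb_dispersion < 0:
            raise ValueError("noise parameters must be non-negative")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be a positive (low, high) pair")
        missing = {(loc, cond) for loc in ("BA", "BT") for cond in ("ligated", "sham")} - set(
            map(tuple, self.wss_map)
        )
        if missing:
            raise ValueError(f"wss_map missing cells: {sorted(missing)}")
        n_special = (
            2 * self.n_marker_genes_per_tissue
            + self.n_signal_up
            + self.n_signal_down
            + (self.n_signal_up + self.n_signal_down) * self.responders_per_signal
        )
        if n_special >= self.n_background_genes:
            raise ValueError(
                f"planted gene classes ({n_special}) exceed the n_background_genes "
                f"budget ({self.n_background_genes})"
            )


@dataclass
class PlantedTruth:
    """Serializable ground truth for recovery tests.

    ``responder_map`` maps each intimal signal gene to a list of
    (medial responder gene, sign) pairs; ``response_params`` stores the
    realized per-gene dose-response parameters.
    """

    tissue_markers: dict = field(default_factory=dict)
    signal_genes: dict = field(default_factory=dict)
    responder_map: dict = field(default_factory=dict)
    null_genes: list = field(default_factory=list)
    response_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        classes = [
            set(self.tissue_markers),
            set(self.signal_genes),
            {g for pairs in self.responder_map.values() for g, _ in pairs},
            set(self.null_genes),
        ]
        seen: set = set()
        for cls in classes:
            if cls & seen:
                raise ValueError(f"planted gene classes overlap: {sorted(cls & seen)[:5]}")
            seen |= cls
        for signal in self.responder_map:
            if signal not in self.signal_genes:
                raise ValueError(f"responder mapped to unknown signal gene {signal!r}")

    def planted_pairs(self):
        """All (signal gene, responder gene, sign) triples."""
        return [
            (signal, responder, sign)
            for signal, pairs in sorted(self.responder_map.items())
            for responder, sign in pairs
        ]

    def responders(self, direction: str | None = None, sign: int | None = None) -> list:
        """Responder genes, optionally filtered by signal direction and coupling sign."""
        out = []
        for signal, pairs in sorted(self.responder_map.items()):
            if direction is not None and self.signal_genes[signal]["direction"] != direction:
                continue
            for responder, s in pairs:
                if sign is None or s == sign:
                    out.append(responder)
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data["responder_map"] = {
            k: [(g, int(s)) for g, s in v] for k, v in data["responder_map"].items()
        }
        return cls(**data)


def _gene_catalog(config: SimulationConfig) -> PlantedTruth:
    nm = config.n_marker_genes_per_tissue
    intima_markers = list(_INTIMA_MARKERS[:nm]) + [f"ENDO{i:02d}" for i in range(3, nm)]
    media_markers = list(_MEDIA_MARKERS[:nm]) + [f"SMC{i:02d}" for i in range(3, nm)]
    up = [f"SIGUP{i + 1:02d}" for i in range(config.n_signal_up)]
    down = [f"SIGDN{i + 1:02d}" for i in range(config.n_signal_down)]

    signal_genes = {}
    for i, g in enumerate(up):
        # one plateau gene among the up-signals (mirrors the one candidate
        # whose response flattened above ~40 Pa); the rest rise linearly
        shape = "plateau" if (config.n_signal_up > 1 and i == config.n_signal_up - 1) else "linear"
        signal_genes[g] = {"direction": "up", "response_shape": shape}
    for g in down:
        signal_genes[g] = {"direction": "down", "response_shape": "peaked_decline"}

    responder_map = {}
    for signal in up + down:
        pairs = []
        for k in range(config.responders_per_signal):
            sign = 1 if k < (config.responders_per_signal + 1) // 2 else -1
            tag = "P" if sign == 1 else "N"
            pairs.append((f"R_{signal}_{tag}{k + 1:02d}", sign))
        responder_map[signal] = pairs

    n_special = (
        len(intima_markers)
        + len(media_markers)
        + len(signal_genes)
        + sum(len(v) for v in responder_map.values())
    )
    n_null = config.n_background_genes - n_special
    null_genes = [f"NULL{i + 1:04d}" for i in range(n_null)]

    markers = {g: "intima" for g in intima_markers}
    markers.update({g: "media" for g in media_markers})
    return PlantedTruth(
        tissue_markers=markers,
        signal_genes=signal_genes,
        responder_map=responder_map,
        null_genes=null_genes,
    )


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for condition, prefix in (("ligated", "L"), ("sham", "S")):
        for a in range(config.n_animals_per_condition):
            animal = f"{prefix}{a + 1}"
            for tissue in ("intima", "media"):
                for location in ("BA", "BT"):
                    rows.append(
                        {
                            "sample_id": f"{animal}_{tissue}_{location}",
                            "animal_id": animal,
                            "tissue": tissue,
                            "location": location,
                            "condition": condition,
                            "wss_pa": float(config.wss_map[(location, condition)]),
                        }
                    )
    samples = pd.DataFrame(rows).set_index("sample_id")
    return validate_sample_table(samples)


def generate_dataset(config: SimulationConfig):
    """Generate (ExpressionMatrix, sample table, PlantedTruth).

    Deterministic for a fixed config (bit-identical counts for the same
    seed).  Counts are negative-binomial (gamma-Poisson; pure Poisson when
    ``nb_dispersion`` is 0) around mean = true_RPKM * length_kb * library/1e6.
    """
    truth = _gene_catalog(config)
    samples = _sample_frame(config)
    rng = np.random.default_rng(config.seed)

    genes = (
        sorted(truth.tissue_markers)
        + sorted(truth.signal_genes)
        + sorted(g for pairs in truth.responder_map.values() for g, _ in pairs)
        + list(truth.null_genes)
    )
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = len(genes), len(samples)

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)

    # per-gene realized shape parameters (amplitude-level jitter keeps the
    # planted genes from being exact copies of one another)
    response_params = {}
    for gene in sorted(truth.signal_genes):
        shape = truth.signal_genes[gene]["response_shape"]
        params = dict(DEFAULT_SHAPE_PARAMS[shape])
        jitter = float(np.exp(rng.normal(0.0, _PARAM_JITTER_SD)))
        if shape == "linear":
            params["base"] *= jitter
            params["slope"] *= jitter
        elif shape == "plateau":
            params["slope"] *= jitter
        else:
            params["amplitude"] *= jitter
        response_params[gene] = params
    truth.response_params = response_params

    responder_scale = {
        responder: _RESPONDER_BASE * float(np.exp(rng.normal(0.0, _PARAM_JITTER_SD)))
        for signal in sorted(truth.responder_map)
        for responder, _ in truth.responder_map[signal]
    }
    null_baseline = rng.lognormal(_NULL_LOG_MEAN, _NULL_LOG_SD, size=len(truth.null_genes))

    wss = samples["wss_pa"].to_numpy()
    intima_true = np.zeros((n_genes, n_samples))
    media_true = np.zeros((n_genes, n_samples))

    for gene, tissue in truth.tissue_markers.items():
        i = gene_idx[gene]
        own = _MARKER_LEVEL
        if tissue == "intima":
            intima_true[i, :] = own
            media_true[i, :] = _OTHER_TISSUE_LEVEL
        else:
            media_true[i, :] = own
            intima_true[i, :] = _OTHER_TISSUE_LEVEL

    signal_profile = {}
    for gene, info in truth.signal_genes.items():
        i = gene_idx[gene]
        profile = response_curve(info["response_shape"], wss, response_params[gene])
        signal_profile[gene] = profile
        intima_true[i, :] = profile
        media_true[i, :] = _OTHER_TISSUE_LEVEL

    for signal, pairs in truth.responder_map.items():
        log_signal = np.log(signal_profile[signal])
        centered = log_signal - log_signal.mean()
        for responder, sign in pairs:
            i = gene_idx[responder]
            media_true[i, :] = responder_scale[responder] * np.exp(
                sign * config.coupling_strength * centered
            )
            intima_true[i, :] = _OTHER_TISSUE_LEVEL

    for j, gene in enumerate(truth.null_genes):
        i = gene_idx[gene]
        intima_true[i, :] = null_baseline[j]
        media_true[i, :] = null_baseline[j]

    # shared animal-level multiplier per (gene, animal): replicate animals
    # differ, but intima/media pairs from one animal stay coupled
    animals = sorted(samples["animal_id"].unique())
    animal_noise = np.exp(rng.normal(0.0, config.biological_cv, size=(n_genes, len(animals))))
    animal_col = samples["animal_id"].map({a: k for k, a in enumerate(animals)}).to_numpy()
    noise = animal_noise[:, animal_col]
    intima_true = intima_true * noise
    media_true = media_true * noise

    f = config.contamination_fraction
    observed = np.where(
        (samples["tissue"] == "intima").to_numpy()[None, :],
        (1.0 - f) * intima_true + f * media_true,
        media_true,
    )

    library = np.rint(config.library_size_mean * rng.uniform(0.85, 1.15, size=n_samples))
    mean_counts = observed * (lengths[:, None] / 1000.0) * (library[None, :] / 1.0e6)
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean_counts / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean_counts)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples.index),
        gene_length_bp=pd.Series(lengths, index=pd.Index(genes, name="gene_id")),
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Companion annotation and gene-set resources for the planted genes


def make_extracellular_annotation(truth: PlantedTruth, n_decoys: int = 5) -> pd.DataFrame:
    """Annotation table: signal genes are extracellular (product classes cycle
    through the catalog); a few null genes are extracellular decoys; markers
    and responders are intracellular."""
    rows = {}
    for i, gene in enumerate(sorted(truth.signal_genes)):
        rows[gene] = (True, PRODUCT_CLASSES[i % len(PRODUCT_CLASSES)])
    for gene in truth.null_genes[:n_decoys]:
        rows[gene] = (True, "other")
    for gene in sorted(truth.tissue_markers):
        rows[gene] = (False, "other")
    for _, responder, _sign in truth.planted_pairs():
        rows[responder] = (False, "other")
    df = pd.DataFrame(
        {
            "is_extracellular": [v[0] for v in rows.values()],
            "product_class": [v[1] for v in rows.values()],
        },
        index=pd.Index(rows.keys(), name="gene"),
    )
    return df


def make_gene_sets(
    truth: PlantedTruth,
    seed: int = 0,
    n_planted_terms: int = 4,
    n_random_terms: int = 40,
    term_size: int = 15,
):
    """Synthetic GO-like resource: (GeneSetCollection, OntologyGraph, planted).

    Planted terms draw members from the positive responders of up-signals and
    the negative responders of down-signals -- the gene pools that surface in
    the up/positive and down/negative enrichment strata -- so that each
    planted term recurs across the per-candidate queries of its stratum.
    Random terms draw from null genes.  ``planted`` maps stratum name ->
    list of term ids.
    """
    rng = np.random.default_rng(seed)
    ns = "biological_process"
    terms = {
        "GO:0000001": ("biological_process", ns),
        "GO:0000002": ("flow-induced response program", ns),
        "GO:0000003": ("flow-suppressed maintenance program", ns),
        "GO:0000004": ("background process", ns),
    }
    edges = [("GO:0000002", "GO:0000001"), ("GO:0000003", "GO:0000001"),
             ("GO:0000004", "GO:0000001")]
    sets, names, planted = {}, {}, {"up_positive": [], "down_negative": []}

    pools = {
        "up_positive": (truth.responders(direction="up", sign=1), "GO:0000002", 10),
        "down_negative": (truth.responders(direction="down", sign=-1), "GO:0000003", 30),
    }
    for stratum, (pool, parent, base_id) in pools.items():
        pool = sorted(pool)
        for i in range(n_planted_terms):
            term = f"GO:{base_id + i:07d}"
            size = min(term_size, len(pool))
            members = sorted(rng.choice(pool, size=size, replace=False))
            sets[term] = frozenset(members)
            names[term] = f"planted {stratum.replace('_', ' ')} module {i + 1}"
            terms[term] = (names[term], ns)
            edges.append((term, parent))
            planted[stratum].append(term)

    null_pool = sorted(truth.null_genes)
    for i in range(n_random_terms):
        term = f"GO:{100 + i:07d}"
        size = min(term_size, len(null_pool))
        members = sorted(rng.choice(null_pool, size=size, replace=False))
        sets[term] = frozenset(members)
        names[term] = f"background module {i + 1}"
        terms[term] = (names[term], ns)
        edges.append((term, "GO:0000004"))

    collection = GeneSetCollection(sets=sets, names=names)
    ontology = ontology_from_edges(terms, edges)
    return collection, ontology, planted


def write_dataset(config: SimulationConfig, out_dir) -> dict:
    """Generate a dataset and write all artifacts as plain text files.

    Writes counts.tsv, samples.tsv, truth.json, extracellular.tsv,
    gene_sets.gmt and ontology.obo under ``out_dir``; returns the paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, samples, truth = generate_dataset(config)
    annotation = make_extracellular_annotation(truth)
    gene_sets, ontology, planted = make_gene_sets(truth, seed=config.seed)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "extracellular": out / "extracellular.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "ontology": out / "ontology.obo",
    }
    write_counts(matrix, paths["counts"])
    write_samples(samples, paths["samples"])
    truth.to_json(paths["truth"])
    write_extracellular(annotation, paths["extracellular"])
    write_gmt(gene_sets, paths["gene_sets"])
    write_obo(ontology, paths["ontology"])
    with open(out / "planted_terms.json", "w", encoding="utf-8") as fh:
        json.dump(planted, fh, indent=1, sort_keys=True)
    paths["planted_terms"] = out / "planted_terms.json"
    return {k: str(v) for k, v in paths.items()}
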