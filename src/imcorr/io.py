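"""Containers and readers/writers for expression data, annotations and ontologies.

All on-disk formats are plain text: tab-delimited tables for counts, sample
metadata and extracellular-product annotations; GMT for gene-set membership;
OBO for the ontology structure.  Containers validate their invariants on
construction, and readers fail loudly instead of silently coercing bad input.

Expression is normalized as RPKM (reads per kilobase of transcript per
million mapped reads), using the loaded matrix's per-sample total counts as
the "million mapped reads" denominator so that the unit is self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "OntologyGraph",
    "compute_rpkm",
    "read_counts",
    "read_extracellular",
    "read_gmt",
    "read_obo",
    "read_samples",
    "validate_sample_table",
]

logger = logging.getLogger(__name__)

TISSUES = ("intima", "media")
LOCATIONS = ("BA", "BT")
CONDITIONS = ("ligated", "sham")
PRODUCT_CLASSES = (
    "enzyme",
    "peptidase",
    "growth factor",
    "cytokine",
    "transporter",
    "kinase",
    "other",
)
SAMPLE_COLUMNS = ("animal_id", "tissue", "location", "condition", "wss_pa")


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Integer read counts (genes x samples) plus per-gene transcript lengths.

    Invariants: unique gene and sample identifiers, strictly positive
    lengths, integral non-negative counts.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not self.gene_length_bp.index.equals(self.counts.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any():
            gene = self.gene_length_bp.index[self.gene_length_bp.isna()][0]
            raise ValueError(f"missing gene length for {gene!r}")
        lengths = self.gene_length_bp.to_numpy()
        if not np.all(lengths > 0) or not np.allclose(lengths, np.round(lengths)):
            bad = self.gene_length_bp.index[~(lengths > 0)][:1]
            raise ValueError(f"gene lengths must be positive integers (e.g. {list(bad)})")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0) or not np.allclose(values, np.round(values)):
            gi, si = np.argwhere((values < 0) | (values != np.round(values)))[0]
            raise ValueError(
                f"invalid count for gene {self.counts.index[gi]!r} in sample "
                f"{self.counts.columns[si]!r}: {values[gi, si]!r} (must be a non-negative integer)"
            )
        self.counts = self.counts.astype(np.int64)
        self.gene_length_bp = self.gene_length_bp.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.counts.equals(other.counts) and self.gene_length_bp.equals(
            other.gene_length_bp
        )


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """RPKM[g, s] = counts[g, s] / (length_kb[g] * total_counts[s] / 1e6)."""
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        sample = totals.index[totals == 0][0]
        raise ValueError(f"sample {sample!r} has zero total counts; cannot normalize")
    length_kb = matrix.gene_length_bp.to_numpy(dtype=float) / 1000.0
    per_million = totals.to_numpy(dtype=float) / 1.0e6
    values = matrix.counts.to_numpy(dtype=float) / (length_kb[:, None] * per_million[None, :])
    return pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids)


def read_counts(path) -> ExpressionMatrix:
    """Read a counts TSV: gene_id, length_bp, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3 or df.columns[1] != "length_bp":
        raise ValueError(
            "counts table must have columns: gene_id, length_bp, <sample...>"
        )
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    lengths = df["length_bp"]
    counts = df.drop(columns=["length_bp"])
    return ExpressionMatrix(counts=counts, gene_length_bp=lengths)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length_bp", matrix.gene_length_bp)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check design invariants of a sample table (index = sample_id).

    Required columns: animal_id, tissue, location, condition, wss_pa.
    (animal_id, tissue, location) must identify samples uniquely and every
    intima sample needs a media partner at the same (animal, location).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    for col, levels in (("tissue", TISSUES), ("location", LOCATIONS), ("condition", CONDITIONS)):
        bad = set(samples[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)} (expected {levels})")
    wss = pd.to_numeric(samples["wss_pa"], errors="raise")
    if (wss < 0).any():
        raise ValueError("wss_pa must be non-negative")
    keys = samples[["animal_id", "tissue", "location"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample for (animal, tissue, location) = {tuple(dup)}")
    by_key = {
        (row.animal_id, row.location): row.tissue
        for row in samples.itertuples()
        if row.tissue == "media"
    }
    for row in samples.itertuples():
        if row.tissue == "intima" and (row.animal_id, row.location) not in by_key:
            raise ValueError(
                f"intima sample {row.Index!r} has no media partner at "
                f"(animal={row.animal_id!r}, location={row.location!r})"
            )
    return samples


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_sample_table(samples)


def write_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Extracellular-product annotation


def read_extracellular(path) -> pd.DataFrame:
    """Annotation table: gene, is_extracellular (0/1 or true/false), product_class."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, index_col="gene")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"gene {dup!r} annotated more than once")
    if "is_extracellular" not in df.columns or "product_class" not in df.columns:
        raise ValueError("annotation table needs columns: gene, is_extracellular, product_class")
    df["is_extracellular"] = df["is_extracellular"].map(
        {True: True, False: False, 1: True, 0: False, "true": True, "false": False,
         "True": True, "False": False}
    )
    if df["is_extracellular"].isna().any():
        raise ValueError("is_extracellular must be boolean")
    bad = set(df["product_class"]) - set(PRODUCT_CLASSES)
    if bad:
        raise ValueError(f"unknown product class(es): {sorted(bad)}")
    return df


def write_extracellular(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "gene"
    out["is_extracellular"] = out["is_extracellular"].astype(bool)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """term_id -> member gene set, with optional human-readable names."""

    sets: dict = field(default_factory=dict)
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            self.sets[term] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term) -> bool:
        return term in self.sets

    def restrict(self, background) -> "GeneSetCollection":
        """Intersect every set with a background; drop sets that become empty."""
        bg = frozenset(background)
        sets = {t: s & bg for t, s in self.sets.items()}
        sets = {t: s for t, s in sets.items() if s}
        return GeneSetCollection(sets=sets, names={t: self.names.get(t, t) for t in sets})


def read_gmt(path) -> GeneSetCollection:
    sets, names = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need term, description, >=1 gene")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise ValueError(f"duplicate term {term!r} in GMT")
            sets[term] = frozenset(genes)
            names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{genes}\n")


# ---------------------------------------------------------------------------
# Ontology (OBO)


@dataclass
class OntologyGraph:
    """Directed acyclic graph of ontology terms; edges run child -> parent (is_a).

    Node attributes: ``name`` and ``namespace``.  Roots are terms without
    parents; in a DAG every non-root reaches a root by following is_a edges.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"is_a relation contains a cycle: {cycle}")

    def __contains__(self, term) -> bool:
        return term in self.graph

    def terms(self):
        return list(self.graph.nodes)

    def name(self, term) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term):
        return set(self.graph.successors(term))

    def ancestors(self, term) -> set:
        """All terms reachable via is_a, including the term itself."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        return nx.descendants(self.graph, term) | {term}

    def descendants(self, term) -> set:
        """All terms that reach this term via is_a, including itself."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        return nx.ancestors(self.graph, term) | {term}

    def roots(self) -> set:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}


def ontology_from_edges(terms: dict, edges) -> OntologyGraph:
    """Build an ontology from {term: (name, namespace)} plus (child, parent) pairs."""
    g = nx.DiGraph()
    for term, (name, namespace) in terms.items():
        g.add_node(term, name=name, namespace=namespace)
    for child, parent in edges:
        if child not in g or parent not in g:
            raise ValueError(f"edge ({child}, {parent}) references unknown term")
        g.add_edge(child, parent)
    return OntologyGraph(graph=g)


def read_obo(path) -> OntologyGraph:
    """Read an OBO file, keeping only is_a edges and non-obsolete terms."""
    multi = obonet.read_obo(path)  # skips obsolete stanzas by default
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyGraph(graph=g)


def write_obo(ontology: OntologyGraph, path, header_ontology: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {header_ontology}\n")
        for term in sorted(ontology.graph.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.name(term)}\n")
            if ontology.namespace(term):
                fh.write(f"namespace: {ontology.namespace(term)}\n")
            for parent in sorted(ontology.parents(term)):
                fh.write(f"is_a: {parent} ! {ontology.name(parent)}\n")
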