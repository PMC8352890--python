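"""Over-representation analysis of medial correlate sets, with pooling and
REVIGO-style semantic reduction.

For each candidate intimal gene, its positively and negatively correlating
medial genes form separate query sets.  Each query is tested for term
over-representation with a one-sided hypergeometric test against a
background of detectable genes, BH-corrected per query.  Significant terms
(q < 0.05) are pooled across the queries of a stratum and ranked by
occurrence; terms present in more than half of the queries are summarized by
greedy clustering on semantic similarity (SimRel by default, Lin optional)
with a cutoff of 0.90, the higher-occurrence member becoming the
representative.

Term information content is computed from the supplied gene-set corpus with
ancestor propagation: IC(t) = -ln(annotated fraction), so roots have IC 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSetCollection, OntologyGraph

logger = logging.getLogger(__name__)

MEASURES = ("simrel", "lin")


def hypergeom_enrich(
    query,
    gene_sets: GeneSetCollection,
    background,
    q_threshold: float | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of every term in a query.

    p = P(overlap >= k) with term size K, query size n, background size N
    (sets are intersected with the background first).  BH correction across
    all tested terms.  If ``q_threshold`` is given, only significant terms
    are returned.
    """
    background = frozenset(background)
    query = frozenset(query)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    restricted = gene_sets.restrict(background)
    n, N = len(query), len(background)
    rows = []
    for term in sorted(restricted.sets):
        members = restricted.sets[term]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term, "name": restricted.names.get(term, term),
             "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)}
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        return result
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    result = result.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    if q_threshold is not None:
        result = result[result["q_value"] < q_threshold].reset_index(drop=True)
    return result


def pool_and_rank(per_query_terms, occurrence_min: float = 0.5) -> pd.DataFrame:
    """Pool significant term lists across queries and rank by occurrence.

    ``per_query_terms`` maps query label -> iterable of significant term ids.
    A term is flagged for summarization when its occurrence frequency is
    strictly greater than ``occurrence_min``.  Output is ordered by
    (frequency desc, term id asc).
    """
    if not per_query_terms:
        raise ValueError("need at least one query term list")
    n_queries = len(per_query_terms)
    occurrence: dict = {}
    for terms in per_query_terms.values():
        for term in set(terms):
            occurrence[term] = occurrence.get(term, 0) + 1
    rows = [
        {
            "term_id": term,
            "occurrence_count": count,
            "occurrence_frequency": count / n_queries,
            "flagged": count / n_queries > occurrence_min,
        }
        for term, count in occurrence.items()
    ]
    out = pd.DataFrame(rows, columns=["term_id", "occurrence_count", "occurrence_frequency", "flagged"])
    if len(out):
        out = out.sort_values(
            ["occurrence_frequency", "term_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def compute_information_content(
    gene_sets: GeneSetCollection, ontology: OntologyGraph
) -> pd.Series:
    """IC(t) = -ln(fraction of corpus genes annotated to t or its descendants).

    The corpus is the union of all genes in the gene-set collection; direct
    annotations are propagated to ancestors, so every root's IC is 0 and IC
    is nonincreasing from child to parent.  Terms with no (propagated)
    annotation are omitted.
    """
    corpus = frozenset().union(*gene_sets.sets.values()) if gene_sets.sets else frozenset()
    if not corpus:
        raise ValueError("empty gene-set corpus")
    annotated: dict = {}
    for term, members in gene_sets.sets.items():
        if term not in ontology:
            logger.info("gene-set term %s absent from ontology; skipped for IC", term)
            continue
        for anc in ontology.ancestors(term):
            annotated.setdefault(anc, set()).update(members)
    ic = {
        term: -np.log(len(genes) / len(corpus))
        for term, genes in annotated.items()
    }
    return pd.Series(ic, name="information_content").sort_index()


def semantic_similarity(
    term_a: str,
    term_b: str,
    ontology: OntologyGraph,
    ic: pd.Series,
    measure: str = "simrel",
) -> float:
    """Lin or SimRel similarity in [0, 1] via the most-informative common ancestor.

    Lin = 2 IC(MICA) / (IC(a) + IC(b)); SimRel = Lin * (1 - exp(-IC(MICA))),
    i.e. Lin damped by the MICA's annotation probability.  Terms must share a
    namespace.  When both terms carry zero information the similarity is 1
    for identical terms and 0 otherwise.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    for term in (term_a, term_b):
        if term not in ontology:
            raise KeyError(f"term {term!r} not in ontology")
        if term not in ic.index:
            raise KeyError(f"term {term!r} has no information content (unannotated)")
    if ontology.namespace(term_a) != ontology.namespace(term_b):
        raise ValueError(
            f"terms {term_a} and {term_b} are in different namespaces"
        )
    common = ontology.ancestors(term_a) & ontology.ancestors(term_b)
    common = [t for t in common if t in ic.index]
    if not common:
        return 0.0
    mica_ic = max(float(ic[t]) for t in common)
    denom = float(ic[term_a]) + float(ic[term_b])
    if denom <= 0:
        return 1.0 if term_a == term_b else 0.0
    lin = min(1.0, 2.0 * mica_ic / denom)
    if measure == "lin":
        return lin
    return lin * (1.0 - np.exp(-mica_ic))


def reduce_terms(
    term_stats: pd.DataFrame,
    ontology: OntologyGraph,
    ic: pd.Series,
    cutoff: float = 0.90,
    measure: str = "simrel",
) -> pd.DataFrame:
    """Greedy clustering of terms by semantic similarity.

    ``term_stats`` needs columns term_id and occurrence_frequency (optional
    best_q for tie-breaking).  Terms are processed by (frequency desc,
    best_q asc, term id asc); each joins the first existing representative
    with similarity > cutoff, else becomes a new representative.  Every input
    term appears exactly once in the output with its representative.
    """
    df = term_stats.drop_duplicates(subset="term_id").copy()
    if "best_q" not in df.columns:
        df["best_q"] = 1.0
    df = df.sort_values(
        ["occurrence_frequency", "best_q", "term_id"], ascending=[False, True, True]
    )
    representatives: list = []
    assignment = {}
    for row in df.itertuples():
        chosen = None
        for rep in representatives:
            if semantic_similarity(row.term_id, rep, ontology, ic, measure) > cutoff:
                chosen = rep
                break
        if chosen is None:
            representatives.append(row.term_id)
            chosen = row.term_id
        assignment[row.term_id] = chosen
    out = df[["term_id", "occurrence_frequency"]].copy()
    out["representative"] = out["term_id"].map(assignment)
    return out.reset_index(drop=True)


def run_candidate_ontology_analysis(
    candidates: pd.DataFrame,
    pairs: pd.DataFrame,
    gene_sets: GeneSetCollection,
    ontology: OntologyGraph,
    background,
    q_enrich: float = 0.05,
    occurrence_min: float = 0.5,
    similarity_cutoff: float = 0.90,
    measure: str = "simrel",
) -> dict:
    """Pooled, reduced enrichment for the four (direction x sign) strata.

    For every candidate intimal gene and correlation sign, the correlating
    medial genes form one query.  Queries are grouped into strata by the
    candidate's direction under flow and the correlate sign; per stratum the
    significant terms are pooled, occurrence-ranked and reduced.  Strata
    where no query returns a significant term are reported empty.
    """
    ic = compute_information_content(gene_sets, ontology)
    background = frozenset(background)
    strata = {}
    for direction in ("up", "down"):
        genes = candidates.loc[
            candidates["direction_under_flow"] == direction, "intimal_gene"
        ]
        for sign, sign_label in ((1, "positive"), (-1, "negative")):
            queries = {}
            for gene in genes:
                correlates = pairs.loc[
                    (pairs["intimal_gene"] == gene) & (pairs["sign"] == sign),
                    "medial_gene",
                ]
                query = frozenset(correlates) & background
                if query:
                    queries[gene] = query
            enrichment = {}
            significant = {}
            for gene, query in queries.items():
                table = hypergeom_enrich(query, gene_sets, background)
                enrichment[gene] = table
                significant[gene] = set(table.loc[table["q_value"] < q_enrich, "term_id"])
            if significant and any(significant.values()):
                pooled = pool_and_rank(significant, occurrence_min)
                best_q = {}
                for gene, table in enrichment.items():
                    for row in table.itertuples():
                        best_q[row.term_id] = min(best_q.get(row.term_id, 1.0), row.q_value)
                flagged = pooled[pooled["flagged"]].copy()
                if len(flagged):
                    flagged["best_q"] = flagged["term_id"].map(best_q)
                    reduced = reduce_terms(
                        flagged, ontology, ic, cutoff=similarity_cutoff, measure=measure
                    )
                else:
                    reduced = pd.DataFrame(
                        columns=["term_id", "occurrence_frequency", "representative"]
                    )
            else:
                pooled = pd.DataFrame(
                    columns=["term_id", "occurrence_count", "occurrence_frequency", "flagged"]
                )
                reduced = pd.DataFrame(
                    columns=["term_id", "occurrence_frequency", "representative"]
                )
            strata[(direction, sign_label)] = {
                "queries": {g: sorted(q) for g, q in queries.items()},
                "enrichment": enrichment,
                "pooled": pooled,
                "reduced": reduced,
            }
    return strata
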