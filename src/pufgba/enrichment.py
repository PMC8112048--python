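"""GO term enrichment over a DAG and flat KEGG over-representation.

Classic enrichment tests every term with a one-sided hypergeometric test
against the detected-protein background.  Because annotations propagate
up the ontology, ancestor terms inherit their children's signal; the
*elim* algorithm decorrelates the DAG by walking terms from the deepest
level upward and, whenever a term tests below ``elim_cutoff``, removing
that term's annotated study genes from all of its ancestors before they
are tested.  A score-based Kolmogorov-Smirnov variant tests whether a
term's members have systematically lower scores (e.g. DE p-values) than
non-members.

GO p-values are reported uncorrected — the DAG-aware tests violate the
independence assumptions of FDR procedures — while flat KEGG pathway
tests carry a BH q-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "EnrichConfig",
    "propagate",
    "ancestors",
    "fisher_term",
    "run_go_enrichment",
    "ks_enrichment",
    "kegg_overrep",
]


@dataclass
class EnrichConfig:
    algorithm: str = "elim"      # "classic" or "elim"
    elim_cutoff: float = 0.01
    test: str = "fisher"         # "fisher" or "ks"
    min_term_size: int = 3
    background_override: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.elim_cutoff < 1):
            raise ValueError("elim_cutoff must be in [0, 1)")
        if self.algorithm not in ("classic", "elim"):
            raise ValueError("algorithm must be 'classic' or 'elim'")
        if self.test not in ("fisher", "ks"):
            raise ValueError("test must be 'fisher' or 'ks'")


def ancestors(dag: nx.MultiDiGraph, term: str) -> set[str]:
    """All terms reachable upward from ``term`` (excluding itself).

    Edges point child -> parent, so ancestors are graph descendants.
    """
    return nx.descendants(dag, term)


def propagate(dag: nx.MultiDiGraph, annotation: dict[str, set[str]]) -> dict[str, set[str]]:
    """Annotation closure: every gene inherits all ancestor terms.

    Idempotent; raises on terms absent from the DAG.
    """
    closure_cache: dict[str, set[str]] = {}

    def up(term: str) -> set[str]:
        if term not in dag:
            raise ValueError(f"annotation references unknown term {term}")
        if term not in closure_cache:
            closure_cache[term] = {term} | ancestors(dag, term)
        return closure_cache[term]

    return {gene: set().union(*(up(t) for t in terms)) if terms else set()
            for gene, terms in annotation.items()}


def _term_genes(annotation: dict[str, set[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def fisher_term(study_set: set[str], background: set[str], term: str,
                annotation: dict[str, set[str]]):
    """One-sided (over-representation) hypergeometric p for one term.

    Returns ``(p, study_annotated, pop_annotated)``; ``None`` when no
    background gene carries the term (test undefined).
    """
    if not study_set <= background:
        raise ValueError("study set must be a subset of the background")
    annotated = {g for g in background if term in annotation.get(g, ())}
    if not annotated:
        return None
    k = len(study_set & annotated)
    p = float(stats.hypergeom.sf(k - 1, len(background), len(annotated),
                                 len(study_set)))
    return min(p, 1.0), k, len(annotated)


def _depth_order(dag: nx.MultiDiGraph, terms) -> list[str]:
    """Terms from deepest to shallowest (longest path to a root)."""
    depth = {}
    for t in nx.topological_sort(dag.reverse(copy=True)):
        preds = list(dag.successors(t))  # parents
        depth[t] = 0 if not preds else 1 + max(depth[p] for p in preds)
    return sorted(terms, key=lambda t: (-depth[t], t))


def run_go_enrichment(study_set: set[str], background: set[str],
                      dag: nx.MultiDiGraph, annotation: dict[str, set[str]],
                      config: EnrichConfig | None = None,
                      scores: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-term enrichment (classic or elim; Fisher or KS).

    ``annotation`` must be propagated.  With ``test="ks"``, ``scores``
    maps every background gene to a statistic where lower means more
    significant.  p-values are reported uncorrected.
    """
    config = config or EnrichConfig()
    if not study_set:
        raise ValueError("empty study set")
    if not study_set <= background:
        raise ValueError("study set must be a subset of the background")
    term_genes = _term_genes({g: annotation.get(g, set()) for g in background})
    order = _depth_order(dag, sorted(term_genes))
    removed: dict[str, set[str]] = {t: set() for t in order}
    rows = []
    for term in order:
        genes = term_genes[term] - removed[term]
        if len(genes) < config.min_term_size:
            continue
        if config.test == "fisher":
            k = len(study_set & genes)
            p = float(stats.hypergeom.sf(k - 1, len(background), len(genes),
                                         len(study_set)))
            p = min(p, 1.0)
            study_annot = k
        else:
            if scores is None:
                raise ValueError("KS enrichment requires gene scores")
            members = sorted(genes)
            others = sorted(background - genes)
            if not others:
                continue  # term covers the whole background; no complement
            p = float(stats.ks_2samp(
                [scores[g] for g in members], [scores[g] for g in others],
                alternative="greater").pvalue)
            study_annot = len(study_set & genes)
        rows.append({
            "term": term, "study_annotated": study_annot,
            "study_size": len(study_set), "pop_annotated": len(genes),
            "pop_size": len(background), "p": p,
            "algorithm": config.algorithm, "test": config.test,
        })
        if config.algorithm == "elim" and p < config.elim_cutoff:
            eliminate = study_set & genes
            for anc in ancestors(dag, term):
                if anc in removed:
                    removed[anc] |= eliminate
    out = pd.DataFrame(rows, columns=["term", "study_annotated", "study_size",
                                      "pop_annotated", "pop_size", "p",
                                      "algorithm", "test"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def ks_enrichment(scores: dict[str, float], dag: nx.MultiDiGraph,
                  annotation: dict[str, set[str]],
                  config: EnrichConfig | None = None) -> pd.DataFrame:
    """Score-based enrichment: are member scores lower than non-members?

    Convenience wrapper around :func:`run_go_enrichment` with the KS
    test; the background is the score domain and the "study set" is the
    genes below the median score (only used for bookkeeping columns —
    the KS test itself uses all scores).
    """
    config = config or EnrichConfig()
    from dataclasses import replace
    config = replace(config, test="ks")
    background = set(scores)
    med = float(np.median(list(scores.values())))
    study = {g for g, s in scores.items() if s <= med} or set(scores)
    return run_go_enrichment(study, background, dag, annotation, config,
                             scores=scores)


def kegg_overrep(study_set: set[str], background: set[str],
                 pathway_map: dict[str, set[str]]) -> pd.DataFrame:
    """Flat pathway over-representation with BH-adjusted q-values."""
    if not study_set <= background:
        raise ValueError("study set must be a subset of the background")
    pathways = _term_genes({g: pathway_map.get(g, set()) for g in background})
    rows = []
    for pw in sorted(pathways):
        genes = pathways[pw]
        if not genes:
            continue
        k = len(study_set & genes)
        p = min(float(stats.hypergeom.sf(k - 1, len(background), len(genes),
                                         len(study_set))), 1.0)
        rows.append({"term": pw, "study_annotated": k,
                     "study_size": len(study_set),
                     "pop_annotated": len(genes), "pop_size": len(background),
                     "p": p})
    out = pd.DataFrame(rows, columns=["term", "study_annotated", "study_size",
                                      "pop_annotated", "pop_size", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.sort_values("p", kind="stable").reset_index(drop=True)
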