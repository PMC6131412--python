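"""Parent–Child–Union GO-term enrichment with BH correction.

The ontology is a single-rooted DAG of ``is_a`` edges (child -> parents).
After true-path propagation of the annotations, each term's study count is
tested against the hypergeometric distribution conditioned on the genes
annotated to the union of its parent terms, and p-values are adjusted by the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

__all__ = [
    "topological_order",
    "find_roots",
    "propagate",
    "parent_child_union_test",
    "bh_adjust",
    "enriched_terms",
]


def topological_order(parents: dict) -> list:
    """Terms ordered parents-before-children; raises on cycles.

    ``parents`` maps each term to an iterable of its parent terms.  A cycle
    raises ``ValueError`` naming one offending edge.
    """
    children: dict[str, list] = {t: [] for t in parents}
    indegree = {t: 0 for t in parents}
    for term, ps in parents.items():
        for p in ps:
            if p not in parents:
                raise ValueError(f"term {term!r} has unknown parent {p!r}")
            children[p].append(term)
            indegree[term] += 1
    queue = sorted(t for t, d in indegree.items() if d == 0)
    order = []
    while queue:
        term = queue.pop()
        order.append(term)
        for child in children[term]:
            indegree[child] -= 1
            if indegree[child] == 0:
                queue.append(child)
    if len(order) != len(parents):
        stuck = next(t for t, d in indegree.items() if d > 0)
        raise ValueError(
            f"ontology contains a cycle through edge {stuck!r} -> {tuple(parents[stuck])!r}"
        )
    return order


def find_roots(parents: dict) -> list:
    return sorted(t for t, ps in parents.items() if not ps)


def propagate(parents: dict, annotations: dict) -> dict:
    """True-path closure: a gene on a term is on all of the term's ancestors.

    Returns gene -> frozenset of terms.  Idempotent; raises on cyclic DAGs.
    """
    order = topological_order(parents)
    ancestors: dict[str, frozenset] = {}
    for term in order:  # parents come first
        anc = set()
        for p in parents[term]:
            anc.add(p)
            anc |= ancestors[p]
        ancestors[term] = frozenset(anc)
    full = {}
    for gene, terms in annotations.items():
        closed = set()
        for term in terms:
            if term not in parents:
                raise ValueError(f"gene {gene!r} annotated to unknown term {term!r}")
            closed.add(term)
            closed |= ancestors[term]
        full[gene] = frozenset(closed)
    return full


def _term_gene_index(annotations: dict) -> dict:
    index: dict[str, set] = {}
    for gene, terms in annotations.items():
        for term in terms:
            index.setdefault(term, set()).add(gene)
    return index


def parent_child_union_test(
    study: set,
    population: set,
    parents: dict,
    annotations: dict,
) -> pd.DataFrame:
    """Parent–Child–Union enrichment test for every annotated term.

    ``annotations`` must already be propagated.  For a term t with parents
    P(t), let U be the genes annotated to the union of P(t); the p-value is
    the upper tail of the hypergeometric law for drawing >= k genes of t when
    sampling m = |study ∩ U| genes from M = |population ∩ U| of which
    K = |population ∩ genes(t)| carry t.  Root terms get p = 1.  Terms with
    m = 0 or K = 0 are reported as untestable (``testable = False``, p NaN)
    and excluded from BH adjustment.
    """
    study, population = set(study), set(population)
    extra = study - population
    if extra:
        raise ValueError(f"study genes absent from population: {sorted(extra)[:5]}")
    ann_pop = {g: t for g, t in annotations.items() if g in population}
    term_genes = _term_gene_index(ann_pop)

    rows = []
    for term in topological_order(parents):
        genes_t = term_genes.get(term, set())
        k_total = len(genes_t)
        if k_total == 0:
            continue
        ps = tuple(parents[term])
        if not ps:
            union = set(ann_pop)  # root: every annotated gene
        else:
            union = set()
            for p in ps:
                union |= term_genes.get(p, set())
        m_big = len(union)
        k_big = len(genes_t & union) if ps else k_total
        study_union = study & union
        m = len(study_union)
        k = len(study_union & genes_t)
        testable = bool(ps) and m > 0 and k_big > 0
        if not ps:
            p = 1.0
        elif not testable:
            p = np.nan
        else:
            p = float(hypergeom.sf(k - 1, m_big, k_big, m))
        rows.append(
            {
                "term": term,
                "k_study": k,
                "m_study_parents": m,
                "K_population": k_big,
                "M_population_parents": m_big,
                "testable": testable or not ps,
                "pvalue": 1.0 if not ps else p,
            }
        )
    result = pd.DataFrame(rows)
    result["qvalue"] = np.nan
    mask = result["testable"]
    if mask.any():
        result.loc[mask, "qvalue"] = bh_adjust(result.loc[mask, "pvalue"].to_numpy())
    return result


def enriched_terms(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Terms whose BH-adjusted p-value is <= ``alpha``.

    Typical choices in this workflow are 0.01 for host-genome gene sets and
    0.05 for donor-arm gene sets.
    """
    if results.empty:
        return results
    keep = results["qvalue"].notna() & (results["qvalue"] <= alpha)
    return results[keep].sort_values("qvalue").reset_index(drop=True)
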