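"""Term enrichment for predicted target gene sets.

Upper-tail hypergeometric test per term with Bonferroni correction
(Benjamini-Hochberg available as an alternative).  The gene universe
defaults to every gene covered by the term map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["EnrichmentResult", "hypergeom_enrich", "bonferroni"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  #: query genes annotated to the term
    K: int  #: universe genes annotated to the term
    n: int  #: query size
    N: int  #: universe size
    pvalue: float
    p_corrected: float = float("nan")


def bonferroni(pvalues: Sequence[float]) -> list[float]:
    """Multiply each p by the number of tests, capped at 1."""
    m = len(pvalues)
    for p in pvalues:
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in pvalues]


def hypergeom_enrich(
    query: Iterable[str],
    term_map: Mapping[str, set[str]] | Sequence[tuple[str, str, str]],
    universe: Iterable[str] | None = None,
    term_names: Mapping[str, str] | None = None,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of *query* genes.

    *term_map* maps gene -> set of term ids, or is a sequence of
    ``(gene, term_id, term_name)`` rows.  The universe defaults to all
    genes in the map; a query gene outside the universe is an error naming
    the offenders.  Terms with no query gene are reported with p = 1.
    Results are sorted by (p, term_id).
    """
    names: dict[str, str] = dict(term_names or {})
    gene_terms: dict[str, set[str]] = {}
    if isinstance(term_map, Mapping):
        gene_terms = {g: set(ts) for g, ts in term_map.items()}
    else:
        for gene, term_id, term_name in term_map:
            gene_terms.setdefault(gene, set()).add(term_id)
            names.setdefault(term_id, term_name)

    universe_set = set(universe) if universe is not None else set(gene_terms)
    query_set = set(query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")

    term_genes: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in gene_terms.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N = len(universe_set)
    n = len(query_set)
    results: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & query_set)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p = min(1.0, max(p, 5e-324))
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=names.get(term, ""),
                k=k,
                K=K,
                n=n,
                N=N,
                pvalue=p,
            )
        )
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    ps = [r.pvalue for r in results]
    if correction == "bonferroni":
        corrected = bonferroni(ps)
    elif correction == "bh":
        corrected = bh_adjust(ps)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    for r, pc in zip(results, corrected):
        r.p_corrected = pc
    return results
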