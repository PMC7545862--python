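"""Gene-list over-representation testing.

Hypergeometric upper-tail test per term, as ToppFun-style enrichment
does it: with ``N`` background genes, ``K`` of them in a term, and a
query of ``n`` genes overlapping the term in ``k``,

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n).

Bonferroni-corrected p-values (times the number of tested terms, capped
at 1) and Benjamini-Hochberg q-values are both reported; the
significance gate uses FDR (q) < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermMap",
    "EnrichmentResult",
    "enrich",
    "significant_terms",
    "read_gmt",
]


@dataclass
class TermMap:
    """term_id -> (term_name, member genes), plus the background universe.

    If no background is supplied it defaults to the union of all term
    gene sets.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.terms:
            raise ValueError("term map is empty")
        if not self.background:
            self.background = frozenset().union(
                *(genes for _, genes in self.terms.values())
            )
        for term_id, (_, genes) in self.terms.items():
            if not genes <= self.background:
                raise ValueError(
                    f"term {term_id!r} has genes outside the background"
                )
        if not self.background:
            raise ValueError("background is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size
    N: int  # background size
    p: float
    p_bonferroni: float
    q_fdr: float
    significant: bool


def enrich(query: set[str], terms: TermMap, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query gene list.

    Query genes outside the background are dropped with a warning.
    Results are sorted by p ascending, ties broken by term_id.
    """
    if not query:
        raise ValueError("query gene list is empty")
    inside = set(query) & terms.background
    dropped = len(query) - len(inside)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the background dropped")
    if not inside:
        raise ValueError("no query genes in the background")
    N = len(terms.background)
    n = len(inside)
    m = len(terms.terms)
    rows = []
    for term_id in sorted(terms.terms):
        name, genes = terms.terms[term_id]
        K = len(genes)
        k = len(inside & genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, k, K, min(1.0, p * m), p))
    pvals = [r[5] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=name,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            p_bonferroni=p_bonf,
            q_fdr=float(q),
            significant=bool(q < alpha),
        )
        for (term_id, name, k, K, p_bonf, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def significant_terms(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Results with FDR q below ``alpha``, preserving sort order.

    ``alpha = 1`` disables the gate and returns every result (q-values
    are capped at 1, so a strict comparison would drop p = 1 terms).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha >= 1.0:
        return list(results)
    return [r for r in results if r.q_fdr < alpha]


def read_gmt(path, background: set[str] | None = None) -> TermMap:
    """Read a GMT file: term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            terms[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return TermMap(terms=terms, background=frozenset(background or ()))
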