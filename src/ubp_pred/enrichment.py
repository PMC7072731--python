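"""Hypergeometric over-representation test for GO terms and KEGG pathways.

Given a query gene set (for example, predicted ubiquinone-binding proteins
in one organism) and a term-to-gene annotation table over a background
universe of N genes, each term with M annotated genes is scored by the
hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N-M, n-i) / C(N, n)
      = Prob(overlap >= m)

where n is the query size within the background and m the observed overlap
with the term.  Terms with P below the cutoff (0.05 by default) are flagged
significant on the raw P-value; Benjamini-Hochberg correction is available
as an option for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from ubp_pred.io_formats import AnnotationSet

DEFAULT_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics.

    N: background universe size; M: genes annotated to the term;
    n: query genes within the background; m: overlap of query and term.
    """

    term: str
    N: int
    M: int
    n: int
    m: int
    p_value: float
    significant: bool
    description: str = ""
    q_value: float | None = None


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail probability Prob(overlap >= m) of Hypergeometric(N, M, n).

    Computed in log space internally (scipy's survival function), so large
    universes are numerically safe.  ``m = 0`` gives 1 by the empty-sum
    convention.
    """
    for name, value in (("N", N), ("M", M), ("n", n), ("m", m)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    if M > N or n > N:
        raise ValueError(f"M={M} and n={n} must not exceed N={N}")
    if m > min(M, n):
        raise ValueError(f"m={m} cannot exceed min(M={M}, n={n})")
    if m == 0:
        return 1.0
    # sf(m-1) = P(X >= m) for X ~ Hypergeometric(N, M, n)
    return float(hypergeom.sf(m - 1, N, M, n))


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up adjusted q-values, preserving input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, p_values[idx] * m / rank)
        q[idx] = prev
    return q


def enrich(
    query: set[str],
    annotations: AnnotationSet,
    cutoff: float = DEFAULT_CUTOFF,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in ``query``.

    Query genes outside the background are dropped (their count is
    reported via the returned results' shared ``n``); an empty effective
    query is an error.  Results cover every term with overlap m >= 1,
    sorted ascending by P-value.  Significance is called on the raw
    P-value at ``cutoff``; with ``bh=True`` it is called on the
    Benjamini-Hochberg q-value instead.
    """
    effective = set(query) & annotations.background
    if not effective:
        raise ValueError("no query genes found in the annotation background")
    N = annotations.universe_size
    n = len(effective)

    tested: list[tuple[str, int, int, float]] = []
    for term, genes in annotations.term_to_genes.items():
        m = len(effective & genes)
        if m < 1:
            continue
        p = hypergeom_tail(N, len(genes), n, m)
        tested.append((term, len(genes), m, p))

    q_values = benjamini_hochberg([p for _, _, _, p in tested]) if bh else None

    results = []
    for i, (term, M, m, p) in enumerate(tested):
        q = q_values[i] if q_values is not None else None
        flag_value = q if bh else p
        results.append(
            EnrichmentResult(
                term=term,
                N=N,
                M=M,
                n=n,
                m=m,
                p_value=p,
                significant=flag_value < cutoff,
                description=annotations.descriptions.get(term, ""),
                q_value=q,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
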