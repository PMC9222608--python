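"""Gene-set enrichment against GMT libraries, plus term-set overlap.

Enrichment of a query list against each term of a library uses the
one-sided hypergeometric upper tail: with a universe of N genes, a term
of K genes and a query of n genes sharing k, p = P(X >= k) for
X ~ Hypergeom(N, K, n). P-values are Benjamini-Hochberg adjusted across
the library's terms and results are ranked by ascending p.

A second-order comparison treats the *terms* enriched in two analyses as
the lists and the library's term count as the background, reusing the
2x2 Fisher machinery from :mod:`epioverlap.overlap`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .genelists import GeneList
from .overlap import OverlapResult, build_table, fisher_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "enrich",
    "enriched_terms",
    "term_overlap",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class GeneSetLibrary:
    """A GMT library: term_id -> (term_name, gene set)."""

    name: str
    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise InputError(f"term {term_id!r} has an empty gene set")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int        # query ∩ term
    K: int        # term size
    n: int        # query size
    N: int        # universe size
    p: float
    p_adj: float


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file: per line, term_id TAB description TAB gene TAB gene..."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, description = f[0].strip(), f[1].strip()
            genes = frozenset(g.strip() for g in f[2:] if g.strip())
            if not term_id or not genes:
                raise InputError(f"{path}:{lineno}: empty term id or gene set")
            if term_id in terms:
                raise InputError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (description, genes)
    logger.info("read %d terms from %s", len(terms), path)
    return GeneSetLibrary(name or path.stem, terms)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in GMT format (genes sorted for stable output)."""
    with open(Path(path), "w") as fh:
        for term_id, (description, genes) in library.terms.items():
            fh.write("\t".join([term_id, description, *sorted(genes)]) + "\n")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Sort ascending, multiply p(i) by m/i, take the cumulative minimum
    from the largest rank down, cap at 1, restore input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query: GeneList, library: GeneSetLibrary,
           universe_size: int) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a query list against every library term.

    Results are BH-adjusted across the library and ranked by ascending p
    (ties broken by term_id for determinism).
    """
    if len(query) == 0:
        raise InputError("enrich requires a non-empty query list")
    if universe_size < len(query):
        raise InputError(
            f"universe_size {universe_size} < query size {len(query)}"
        )
    qset = query.as_set()
    n = len(qset)
    rows = []
    for term_id, (term_name, genes) in library.terms.items():
        k = len(qset & genes)
        big_k = len(genes)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, universe_size, big_k, n))
        rows.append((term_id, term_name, k, big_k, min(p, 1.0)))
    p_adj = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(term_id=r[0], term_name=r[1], k=r[2], K=r[3],
                         n=n, N=universe_size, p=r[4], p_adj=float(q))
        for r, q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    logger.info("enrich(%s vs %s): %d/%d terms with p < 0.05",
                query.name, library.name,
                sum(r.p < 0.05 for r in results), library.n_terms)
    return results


def enriched_terms(results: Iterable[EnrichmentResult],
                   threshold: float = 0.05,
                   adjusted: bool = False) -> set[str]:
    """Term ids passing the significance cutoff (unadjusted p by default)."""
    if not 0 < threshold <= 1:
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    key = (lambda r: r.p_adj) if adjusted else (lambda r: r.p)
    return {r.term_id for r in results if key(r) < threshold}


def term_overlap(enriched_a: Iterable[str], enriched_b: Iterable[str],
                 library_n_terms: int,
                 name_a: str = "terms_a", name_b: str = "terms_b") -> OverlapResult:
    """Fisher overlap of two enriched-term sets against the library's
    term-count background (no permutation stage)."""
    list_a = GeneList(name_a, sorted(set(enriched_a)))
    list_b = GeneList(name_b, sorted(set(enriched_b)))
    table = build_table(list_a, list_b, library_n_terms)
    fisher = fisher_overlap(table)
    members = sorted(list_a.as_set() & list_b.as_set())
    return OverlapResult(
        list_a_name=name_a,
        list_b_name=name_b,
        overlap_genes=GeneList(f"{name_a}_and_{name_b}", members,
                               provenance="shared enriched terms"),
        table=table,
        odds_ratio_sample=fisher.odds_ratio_sample,
        odds_ratio_cmle=fisher.odds_ratio_cmle,
        fisher_p_greater=fisher.p_greater,
        fisher_p_two_sided=fisher.p_two_sided,
    )


def write_enrichment_tsv(results: Sequence[EnrichmentResult],
                         path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp\tp_adj\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.p_adj:.6g}\n")
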