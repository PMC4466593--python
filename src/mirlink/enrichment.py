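"""Fisher's-exact overrepresentation with BH correction and fold enrichment.

One machinery serves three questions: are a pathway's genes, a miRNA's
predicted binding sites, or a miRNA-target union overrepresented in a query
gene list relative to a background universe? Counts follow the usual 2x2
convention: N = universe size, K = set size in universe, n = query size in
universe, k = overlap. The one-sided p is the upper hypergeometric tail
P[X >= k]; fold enrichment is (k/n)/(K/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .targets import InteractionTable, targets_of

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_tail_p",
    "fisher_overrep",
    "pathway_enrichment",
    "mirna_bindingsite_enrichment",
    "mirna_pathway_enrichment",
    "results_to_frame",
]

RESULT_COLUMNS = [
    "name", "k", "n", "K", "N", "p_raw", "fold_enrichment", "p_adj",
    "significant",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are judged against.

    Set members need not all lie in the universe; out-of-universe members are
    trimmed at test time (and the trimming logged), never at load time.
    """

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EnrichmentResult:
    """Overrepresentation of one gene set (or one miRNA's targets)."""

    name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    fold_enrichment: float  # NaN when undefined (n == 0 or K == 0)
    p_adj: float = float("nan")
    significant: bool = False
    family_size: int = 1


def hypergeom_tail_p(k, N, K, n):
    """Upper hypergeometric tail P[X >= k] for X ~ Hypergeom(N, K, n).

    The one-sided (greater) Fisher's exact p-value. Vectorized; k <= 0
    returns exactly 1. This is the single p-value routine behind every
    overrepresentation test in the package.
    """
    k, N, K, n = np.broadcast_arrays(
        np.asarray(k), np.asarray(N), np.asarray(K), np.asarray(n)
    )
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(k - 1, N, K, n)
    p = np.where(k <= 0, 1.0, p)
    return float(p) if p.ndim == 0 else p


def fisher_overrep(query, geneset, universe, name: str = "") -> EnrichmentResult:
    """One-sided Fisher's exact (hypergeometric upper tail) overrepresentation.

    The query and the set are both trimmed to the universe before counting.
    An empty trimmed query yields k = n = 0, p = 1 and NaN fold enrichment
    rather than an error.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    q = frozenset(query) & universe
    s = frozenset(geneset) & universe
    N, K, n = len(universe), len(s), len(q)
    k = len(q & s)
    if n == 0:
        logger.info("empty query after trimming to universe (%s)", name or "set")
    p_raw = float(hypergeom_tail_p(k, N, K, n))
    if n == 0 or K == 0:
        fold = float("nan")
    else:
        fold = (k / n) / (K / N)
    return EnrichmentResult(name=name, k=k, n=n, K=K, N=N, p_raw=p_raw,
                            fold_enrichment=fold)


def _finalize_family(results: list[EnrichmentResult], alpha: float) -> list[EnrichmentResult]:
    """BH across one tested family; sort by (p_adj, p_raw, name)."""
    if not results:
        return results
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.family_size = len(results)
        r.significant = bool(a < alpha and r.k > 0)
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.name))


def pathway_enrichment(
    query, sets: GeneSetCollection, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Test a gene list against every set in the collection.

    BH is applied across the whole collection (the tested family); results
    are sorted by adjusted then raw p, then name. Rows with k = 0 are kept
    for completeness but can never be flagged significant.
    """
    results = [
        fisher_overrep(query, gs.members, sets.universe, name=name)
        for name, gs in sets.sets.items()
    ]
    return _finalize_family(results, alpha)


def mirna_bindingsite_enrichment(
    de_genes,
    t: InteractionTable,
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-miRNA binding-site overrepresentation within a DE gene list.

    For every miRNA with at least one in-universe predicted target, the
    overlap of its target set with ``de_genes`` is tested against the
    universe; BH runs across all tested miRNAs. miRNAs with zero in-universe
    targets are skipped (logged), not tested. Run separately for the up and
    down gene lists, which form separate BH families.
    """
    universe = frozenset(universe)
    results = []
    skipped = 0
    for mirna, grp in t.frame.groupby("mirna", sort=True):
        target_set = frozenset(grp["gene"]) & universe
        if not target_set:
            skipped += 1
            continue
        results.append(
            fisher_overrep(de_genes, target_set, universe, name=str(mirna))
        )
    if skipped:
        logger.info("skipped %d miRNA(s) with no in-universe targets", skipped)
    return _finalize_family(results, alpha)


def mirna_pathway_enrichment(
    de_mirnas,
    t: InteractionTable,
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], int]:
    """Pathway overrepresentation of the pooled targets of a miRNA list.

    The query is the union of consensus targets of ``de_mirnas``; returns the
    enrichment list plus the in-universe query size used.
    """
    query = targets_of(t, set(de_mirnas))
    n_query = len(query & set(sets.universe))
    return pathway_enrichment(query, sets, alpha), n_query


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of an enrichment family, ready for the TSV writer."""
    return pd.DataFrame(
        [
            {
                "name": r.name, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_raw": r.p_raw, "fold_enrichment": r.fold_enrichment,
                "p_adj": r.p_adj, "significant": int(r.significant),
            }
            for r in results
        ],
        columns=RESULT_COLUMNS[:-1] + ["significant"],
    )
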