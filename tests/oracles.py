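"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately slow and literal: exact integer arithmetic,
explicit loops, direct definitions. None of it shares code with the package.
"""

from __future__ import annotations

import math


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exact big-integer summation of the hypergeometric pmf."""
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    num = 0
    for j in range(k, min(K, n) + 1):
        num += math.comb(K, j) * math.comb(N - K, n - j)
    return num / denom


def hypergeom_tail_table(N: int, K: int, n: int) -> list[float]:
    """Exact tail P[X >= k] for every k in 0..min(K, n), via suffix sums."""
    kmax = min(K, n)
    terms = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(kmax + 1)]
    denom = math.comb(N, n)
    tails = [0] * (kmax + 1)
    acc = 0
    for j in range(kmax, -1, -1):
        acc += terms[j]
        tails[j] = acc / denom
    tails[0] = 1.0
    return tails


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg by direct enumeration of the step-up minimisation.

    adjusted_i = min over j with p_(j) >= p_i of min(1, m * p_(j) / rank_j).
    """
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = indexed[pos]
        rank = pos + 1
        running = min(running, min(1.0, m * pvalues[i] / rank))
        adjusted[i] = running
    return adjusted


def quantile_normalize_column(col, reference) -> list[float]:
    """Normalize one column against a sorted reference, tie blocks averaged."""
    order = sorted(range(len(col)), key=lambda i: col[i])
    out = [None] * len(col)
    pos = 0
    while pos < len(col):
        end = pos
        while end + 1 < len(col) and col[order[end + 1]] == col[order[pos]]:
            end += 1
        block = reference[pos:end + 1]
        mean = sum(block) / len(block)
        for r in range(pos, end + 1):
            out[order[r]] = mean
        pos = end + 1
    return out


def summary_counts_bruteforce(
    up_genes, down_genes, up_mirnas, down_mirnas, pairs,
    gene_pw_up, gene_pw_down, mirna_pw_up, mirna_pw_down,
    enriched_up, enriched_down,
):
    """Every Table-style summary count by exhaustive double loops over pairs."""
    inv_ud_pairs, inv_du_pairs = set(), set()
    for m, g in pairs:
        for mm in down_mirnas:
            for gg in up_genes:
                if m == mm and g == gg:
                    inv_ud_pairs.add((m, g))
        for mm in up_mirnas:
            for gg in down_genes:
                if m == mm and g == gg:
                    inv_du_pairs.add((m, g))
    common_pw_up = [p for p in gene_pw_up if p in list(mirna_pw_down)]
    common_pw_down = [p for p in gene_pw_down if p in list(mirna_pw_up)]
    eo_up = [m for m in down_mirnas if m in list(enriched_up)]
    eo_down = [m for m in up_mirnas if m in list(enriched_down)]
    return {
        "genes_up": len(set(up_genes)),
        "genes_down": len(set(down_genes)),
        "mirnas_up": len(set(up_mirnas)),
        "mirnas_down": len(set(down_mirnas)),
        "common_genes_up_genes_down_mirnas": len({g for _, g in inv_ud_pairs}),
        "common_genes_down_genes_up_mirnas": len({g for _, g in inv_du_pairs}),
        "common_pairs_up_genes_down_mirnas": len(inv_ud_pairs),
        "common_pairs_down_genes_up_mirnas": len(inv_du_pairs),
        "common_pathways_up_genes_down_mirnas": len(set(common_pw_up)),
        "common_pathways_down_genes_up_mirnas": len(set(common_pw_down)),
        "common_enriched_mirnas_up_genes": len(set(eo_up)),
        "common_enriched_mirnas_down_genes": len(set(eo_down)),
    }
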