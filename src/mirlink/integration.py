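"""Integration of the mRNA and miRNA layers under negative regulation.

Because miRNAs predominantly repress their targets, a regulated miRNA and a
genuinely regulated target should move in opposite directions between the
groups. The integration stage therefore intersects up-regulated genes with
the consensus targets of down-regulated miRNAs (and vice versa), intersects
the significant pathway lists of the two layers per direction pairing, and
intersects DE miRNAs with the binding-site-enriched miRNAs of the
opposite-direction gene list. The three blocks are rendered as one summary
table (mRNA results, miRNA results, common results).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .targets import InteractionTable

__all__ = [
    "InversePairs",
    "IntegrationSummary",
    "inverse_intersection",
    "overlap_pathways",
    "enriched_mirna_overlap",
    "build_summary",
    "render_summary_frame",
    "render_summary_text",
]


class ConsistencyError(RuntimeError):
    """Stage outputs built under different configurations were mixed."""


@dataclass
class InversePairs:
    """Inverse-expression intersections and their supporting pairs."""

    up_gene_down_mirna_genes: set[str]
    down_gene_up_mirna_genes: set[str]
    up_gene_down_mirna_pairs: set[tuple[str, str]]  # (miRNA, gene)
    down_gene_up_mirna_pairs: set[tuple[str, str]]

    def all_pairs(self) -> set[tuple[str, str]]:
        return self.up_gene_down_mirna_pairs | self.down_gene_up_mirna_pairs

    def supporting_mirnas(self, gene: str) -> set[str]:
        return {m for m, g in self.all_pairs() if g == gene}


def inverse_intersection(
    up_genes,
    down_genes,
    up_mirnas,
    down_mirnas,
    t: InteractionTable,
) -> InversePairs:
    """Genes whose direction opposes a targeting DE miRNA's direction.

    ``up_gene_down_mirna_genes`` = up_genes that are consensus targets of at
    least one down-miRNA; symmetric for the other pairing. Pair lists carry
    the supporting (miRNA, gene) edges.
    """
    up_genes, down_genes = set(up_genes), set(down_genes)
    up_mirnas, down_mirnas = set(up_mirnas), set(down_mirnas)
    f = t.frame
    dn_m = f["mirna"].isin(down_mirnas) & f["gene"].isin(up_genes)
    up_m = f["mirna"].isin(up_mirnas) & f["gene"].isin(down_genes)
    pairs_ud = set(zip(f.loc[dn_m, "mirna"], f.loc[dn_m, "gene"]))
    pairs_du = set(zip(f.loc[up_m, "mirna"], f.loc[up_m, "gene"]))
    return InversePairs(
        up_gene_down_mirna_genes={g for _, g in pairs_ud},
        down_gene_up_mirna_genes={g for _, g in pairs_du},
        up_gene_down_mirna_pairs=pairs_ud,
        down_gene_up_mirna_pairs=pairs_du,
    )


def overlap_pathways(
    gene_pathways_up,
    gene_pathways_down,
    mirna_pathways_up,
    mirna_pathways_down,
) -> tuple[list[str], list[str]]:
    """Pathways significant in both layers, per inverse direction pairing.

    Returns (up-genes with down-miRNAs, down-genes with up-miRNAs), sorted.
    """
    up = sorted(set(gene_pathways_up) & set(mirna_pathways_down))
    down = sorted(set(gene_pathways_down) & set(mirna_pathways_up))
    return up, down


def enriched_mirna_overlap(
    up_mirnas,
    down_mirnas,
    enriched_in_up_genes,
    enriched_in_down_genes,
) -> tuple[set[str], set[str]]:
    """DE miRNAs binding-site-enriched in the opposite-direction gene list.

    Returns (down-miRNAs enriched in up-genes, up-miRNAs enriched in
    down-genes).
    """
    return (
        set(down_mirnas) & set(enriched_in_up_genes),
        set(up_mirnas) & set(enriched_in_down_genes),
    )


@dataclass
class IntegrationSummary:
    """The three-block summary; every count has its constructible set."""

    up_genes: set[str]
    down_genes: set[str]
    up_mirnas: set[str]
    down_mirnas: set[str]
    gene_pathways_up: list[str]
    gene_pathways_down: list[str]
    mirna_pathways_up: list[str]
    mirna_pathways_down: list[str]
    enriched_in_up_genes: set[str]
    enriched_in_down_genes: set[str]
    inverse: InversePairs
    overlap_pathways_up: list[str]
    overlap_pathways_down: list[str]
    enriched_overlap_up: set[str]     # down-miRNAs enriched in up-genes
    enriched_overlap_down: set[str]   # up-miRNAs enriched in down-genes
    config_fingerprint: str = ""

    @property
    def counts(self) -> dict[str, int]:
        inv = self.inverse
        return {
            "genes_up": len(self.up_genes),
            "genes_down": len(self.down_genes),
            "gene_pathways_up": len(self.gene_pathways_up),
            "gene_pathways_down": len(self.gene_pathways_down),
            "bindingsite_enriched_in_up_genes": len(self.enriched_in_up_genes),
            "bindingsite_enriched_in_down_genes": len(self.enriched_in_down_genes),
            "mirnas_up": len(self.up_mirnas),
            "mirnas_down": len(self.down_mirnas),
            "mirna_pathways_up": len(self.mirna_pathways_up),
            "mirna_pathways_down": len(self.mirna_pathways_down),
            "common_genes_up_genes_down_mirnas": len(inv.up_gene_down_mirna_genes),
            "common_genes_down_genes_up_mirnas": len(inv.down_gene_up_mirna_genes),
            "common_pairs_up_genes_down_mirnas": len(inv.up_gene_down_mirna_pairs),
            "common_pairs_down_genes_up_mirnas": len(inv.down_gene_up_mirna_pairs),
            "common_pathways_up_genes_down_mirnas": len(self.overlap_pathways_up),
            "common_pathways_down_genes_up_mirnas": len(self.overlap_pathways_down),
            "common_enriched_mirnas_up_genes": len(self.enriched_overlap_up),
            "common_enriched_mirnas_down_genes": len(self.enriched_overlap_down),
        }


def build_summary(
    *,
    gene_de,
    mirna_de,
    gene_pathways_up,
    gene_pathways_down,
    mirna_pathways_up,
    mirna_pathways_down,
    enriched_in_up_genes,
    enriched_in_down_genes,
    interactions: InteractionTable,
    config_fingerprint: str = "",
    stage_fingerprints: dict[str, str] | None = None,
) -> IntegrationSummary:
    """Assemble the full cross-layer summary from the stage outputs.

    ``gene_de`` / ``mirna_de`` are classified :class:`~mirlink.diffexpr.DEResult`
    objects; pathway arguments are significant-name lists from enrichment;
    ``enriched_in_*`` are binding-site-enriched miRNA id sets. When
    ``stage_fingerprints`` is given, any entry disagreeing with
    ``config_fingerprint`` raises :class:`ConsistencyError`.
    """
    if stage_fingerprints:
        bad = {k: v for k, v in stage_fingerprints.items()
               if v != config_fingerprint}
        if bad:
            raise ConsistencyError(
                f"stage outputs from mismatched configs: {sorted(bad)}"
            )
    inverse = inverse_intersection(
        gene_de.up_features,
        gene_de.down_features,
        mirna_de.up_features,
        mirna_de.down_features,
        interactions,
    )
    ov_up, ov_down = overlap_pathways(
        gene_pathways_up, gene_pathways_down,
        mirna_pathways_up, mirna_pathways_down,
    )
    eo_up, eo_down = enriched_mirna_overlap(
        mirna_de.up_features, mirna_de.down_features,
        enriched_in_up_genes, enriched_in_down_genes,
    )
    return IntegrationSummary(
        up_genes=set(gene_de.up_features),
        down_genes=set(gene_de.down_features),
        up_mirnas=set(mirna_de.up_features),
        down_mirnas=set(mirna_de.down_features),
        gene_pathways_up=list(gene_pathways_up),
        gene_pathways_down=list(gene_pathways_down),
        mirna_pathways_up=list(mirna_pathways_up),
        mirna_pathways_down=list(mirna_pathways_down),
        enriched_in_up_genes=set(enriched_in_up_genes),
        enriched_in_down_genes=set(enriched_in_down_genes),
        inverse=inverse,
        overlap_pathways_up=ov_up,
        overlap_pathways_down=ov_down,
        enriched_overlap_up=eo_up,
        enriched_overlap_down=eo_down,
        config_fingerprint=config_fingerprint,
    )


_BLOCKS = [
    ("mRNA profiling results", [
        ("Genes", "genes_up", "genes_down"),
        ("Pathways", "gene_pathways_up", "gene_pathways_down"),
        ("Enriched putative miRNAs",
         "bindingsite_enriched_in_up_genes", "bindingsite_enriched_in_down_genes"),
    ]),
    ("miRNA profiling results", [
        ("miRNAs", "mirnas_up", "mirnas_down"),
        ("Pathways", "mirna_pathways_up", "mirna_pathways_down"),
    ]),
    ("Common results", [
        ("Genes", "common_genes_up_genes_down_mirnas",
         "common_genes_down_genes_up_mirnas"),
        ("Pairs", "common_pairs_up_genes_down_mirnas",
         "common_pairs_down_genes_up_mirnas"),
        ("Pathways", "common_pathways_up_genes_down_mirnas",
         "common_pathways_down_genes_up_mirnas"),
        ("Enriched miRNAs", "common_enriched_mirnas_up_genes",
         "common_enriched_mirnas_down_genes"),
    ]),
]


def render_summary_frame(summary: IntegrationSummary) -> pd.DataFrame:
    """Machine-readable three-block table (block, row, up, down)."""
    counts = summary.counts
    rows = []
    for block, entries in _BLOCKS:
        for label, up_key, down_key in entries:
            rows.append(
                {"block": block, "row": label,
                 "up": counts[up_key], "down": counts[down_key]}
            )
    return pd.DataFrame(rows, columns=["block", "row", "up", "down"])


def render_summary_text(summary: IntegrationSummary) -> str:
    """Human-readable rendering of the three-block summary."""
    counts = summary.counts
    lines = []
    width = 28
    for block, entries in _BLOCKS:
        lines.append(block)
        lines.append("-" * len(block))
        for label, up_key, down_key in entries:
            lines.append(
                f"{label:<{width}} up: {counts[up_key]:>6}   "
                f"down: {counts[down_key]:>6}"
            )
        lines.append("")
    if summary.config_fingerprint:
        lines.append(f"config: {summary.config_fingerprint}")
    return "\n".join(lines).rstrip() + "\n"
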