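"""Multi-source miRNA-target predictions: consensus filtering and hubs.

A prediction table holds one row per (miRNA, gene) pair with a 0/1 flag per
prediction source and a ``support`` column equal to the number of flagging
sources. Accepting only pairs flagged by at least two independent algorithms
(the consensus filter) is the standard way to suppress the high per-source
false-positive rate of sequence-based target predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "HubReport",
    "SchemaError",
    "consensus_filter",
    "targets_of",
    "mirnas_targeting",
    "find_hubs",
]

KEY_COLUMNS = ("mirna", "gene")


class SchemaError(ValueError):
    """Raised when an interaction table violates its schema contract."""


@dataclass
class InteractionTable:
    """miRNA-gene prediction records with per-source flags.

    ``frame`` columns: mirna, gene, one 0/1 column per source name, support.
    ``min_support`` records the consensus threshold already applied (1 for an
    unfiltered table).
    """

    frame: pd.DataFrame
    source_names: tuple[str, ...]
    min_support: int = 1

    def __post_init__(self) -> None:
        self.source_names = tuple(self.source_names)
        f = self.frame
        expected = list(KEY_COLUMNS) + list(self.source_names) + ["support"]
        missing = [c for c in expected if c not in f.columns]
        if missing:
            raise SchemaError(f"interaction table missing columns: {missing}")
        if len(f) and f.duplicated(subset=list(KEY_COLUMNS)).any():
            raise SchemaError("duplicate (mirna, gene) pairs; merge rows first")
        if len(f):
            flags = f[list(self.source_names)].to_numpy()
            if ((flags != 0) & (flags != 1)).any():
                raise SchemaError("source flags must be 0/1")
            bad = f.index[flags.sum(axis=1) != f["support"].to_numpy()]
            if len(bad):
                raise SchemaError(
                    f"support inconsistent with source flags at row {bad[0]}"
                )
            if (f["support"].to_numpy() < 1).any():
                raise SchemaError("stored records must have support >= 1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def consensus_applied(self) -> bool:
        return self.min_support >= 2

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["mirna"], self.frame["gene"]))


def merge_duplicate_rows(
    frame: pd.DataFrame, source_names: list[str]
) -> pd.DataFrame:
    """OR together flags of duplicated (mirna, gene) rows; recompute support."""
    merged = (
        frame.groupby(list(KEY_COLUMNS), as_index=False, sort=True)[source_names]
        .max()
    )
    merged["support"] = merged[source_names].sum(axis=1)
    return merged


def consensus_filter(t: InteractionTable, min_algorithms: int = 2) -> InteractionTable:
    """Keep only pairs predicted by at least ``min_algorithms`` sources.

    Idempotent; filtering at a higher threshold always yields a subset.
    """
    if min_algorithms < 1:
        raise ValueError("min_algorithms must be >= 1")
    kept = t.frame[t.frame["support"] >= min_algorithms].reset_index(drop=True)
    return InteractionTable(
        frame=kept,
        source_names=t.source_names,
        min_support=max(min_algorithms, t.min_support),
    )


def _require_consensus(t: InteractionTable, caller: str) -> None:
    if not t.consensus_applied:
        raise ValueError(
            f"{caller} expects a consensus-filtered table; "
            "run consensus_filter(t, min_algorithms>=2) first "
            "(or consensus_filter(t, 1) explicitly for the raw union)"
        )


def targets_of(
    t: InteractionTable, mirnas, *, enforce_consensus: bool = True
) -> set[str]:
    """Union of predicted target genes of the given miRNAs.

    Unknown miRNA ids contribute nothing and are logged (expression arrays
    routinely probe miRNAs absent from prediction tables).
    """
    if enforce_consensus:
        _require_consensus(t, "targets_of")
    mirnas = set(mirnas)
    known = set(t.frame["mirna"])
    unknown = mirnas - known
    if unknown:
        logger.warning(
            "%d miRNA id(s) absent from the interaction table (e.g. %s)",
            len(unknown),
            sorted(unknown)[:3],
        )
    hit = t.frame["mirna"].isin(mirnas)
    return set(t.frame.loc[hit, "gene"])


def mirnas_targeting(
    t: InteractionTable, genes, *, enforce_consensus: bool = True
) -> set[str]:
    """Union of miRNAs predicted to target any of the given genes."""
    if enforce_consensus:
        _require_consensus(t, "mirnas_targeting")
    hit = t.frame["gene"].isin(set(genes))
    return set(t.frame.loc[hit, "mirna"])


@dataclass
class HubReport:
    """Highly connected entities of the (filtered) prediction network.

    A target-hub is a gene with >= ``min_hub`` distinct predicted miRNA
    partners; a miRNA-hub targets >= ``min_hub`` distinct genes. Degrees are
    distinct-partner counts in the table the report was built from.
    """

    target_hubs: pd.DataFrame  # columns: entity, degree
    mirna_hubs: pd.DataFrame
    min_hub: int
    min_support: int = 1

    @property
    def target_hub_ids(self) -> set[str]:
        return set(self.target_hubs["entity"])

    @property
    def mirna_hub_ids(self) -> set[str]:
        return set(self.mirna_hubs["entity"])


def _degree_report(degrees: pd.Series, min_hub: int) -> pd.DataFrame:
    hubs = degrees[degrees >= min_hub]
    out = (
        hubs.rename("degree")
        .rename_axis("entity")
        .reset_index()
        .sort_values(["degree", "entity"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def find_hubs(
    t: InteractionTable, min_hub: int = 15, *, enforce_consensus: bool = True
) -> HubReport:
    """Classify target-hubs and miRNA-hubs at the given degree threshold."""
    if enforce_consensus:
        _require_consensus(t, "find_hubs")
    if min_hub < 1:
        raise ValueError("min_hub must be >= 1")
    gene_deg = t.frame.groupby("gene")["mirna"].nunique()
    mirna_deg = t.frame.groupby("mirna")["gene"].nunique()
    return HubReport(
        target_hubs=_degree_report(gene_deg, min_hub),
        mirna_hubs=_degree_report(mirna_deg, min_hub),
        min_hub=min_hub,
        min_support=t.min_support,
    )
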