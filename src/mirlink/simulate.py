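"""Two-group coupled mRNA/miRNA simulator with known ground truth.

Emulates the study design the pipeline targets: two age groups (young,
adult) with four arrays each, log2-scale intensities with Gaussian residual
noise, a subset of miRNAs given a planted adult-vs-young shift, each planted
miRNA repressing a regulon of genes (gene shift = -coupling_beta x miRNA
shift, the inverse-expression signature of negative regulation), a further
set of independently DE genes, a ten-source prediction table in which true
pairs are flagged with probability ``source_tpr`` per source and non-pairs
with ``source_fpr``, and pathway-style gene sets oversampling the expected-DE
genes.

All randomness flows through one generator consumed in a fixed, documented
order: miRNA effects -> gene effects -> noise -> sources -> pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ADULT, YOUNG, ExpressionMatrix
from .enrichment import GeneSet, GeneSetCollection
from .targets import InteractionTable

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SimulatedBundle",
    "generate_design",
    "simulate_dataset",
    "write_fixture",
]


class ConfigurationError(ValueError):
    """Raised for infeasible or invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults are the desk-scale conditions.

    Effects and noise are in log2 units. ``coupling_beta`` is dimensionless:
    each regulon gene receives a group shift of ``-coupling_beta`` times its
    regulator's shift (summed over regulators when regulons overlap).
    """

    n_genes: int = 2000
    n_mirnas: int = 200
    n_young: int = 4
    n_adult: int = 4
    frac_de_mirnas: float = 0.15
    mirna_effect: float = 1.5
    regulon_size: int = 20
    coupling_beta: float = 1.0
    indep_gene_effect: float = 1.0
    frac_de_genes_indep: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_sources: int = 10
    source_tpr: float = 0.8
    source_fpr: float = 0.01
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 50)
    pathway_de_bias: float = 4.0
    overlap_regulons: bool = False
    seed: int = 0

    def n_de_mirnas(self) -> int:
        return int(round(self.frac_de_mirnas * self.n_mirnas))

    def validate(self) -> None:
        for name in ("frac_de_mirnas", "frac_de_genes_indep",
                     "source_tpr", "source_fpr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_sources < 2:
            raise ConfigurationError("n_sources must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_young < 2 or self.n_adult < 2:
            raise ConfigurationError("each group needs >= 2 samples")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigurationError("invalid pathway_size_range")
        if self.pathway_de_bias < 1:
            raise ConfigurationError("pathway_de_bias must be >= 1")
        if (not self.overlap_regulons
                and self.regulon_size * self.n_de_mirnas() > self.n_genes):
            raise ConfigurationError(
                "disjoint regulons infeasible: regulon_size x n_de_mirnas "
                f"= {self.regulon_size * self.n_de_mirnas()} > {self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery scoring.

    ``de_genes_expected`` maps gene -> expected direction, the sign of the
    summed planted shift; genes whose shifts cancel exactly are excluded
    (no direction is scoreable).
    """

    de_mirnas: dict[str, str]              # miRNA id -> "up" | "down"
    regulons: dict[str, frozenset[str]]    # miRNA id -> target genes
    true_interactions: frozenset[tuple[str, str]]
    de_genes_expected: dict[str, str]      # gene id -> "up" | "down"

    def inverse_pairs(self) -> frozenset[tuple[str, str]]:
        """Planted (miRNA, gene) pairs whose expected directions oppose."""
        pairs = []
        for m, genes in self.regulons.items():
            md = self.de_mirnas[m]
            want = "down" if md == "up" else "up"
            pairs.extend(
                (m, g) for g in genes if self.de_genes_expected.get(g) == want
            )
        return frozenset(pairs)


@dataclass
class SimulatedBundle:
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    interactions: InteractionTable
    pathways: GeneSetCollection
    truth: GroundTruth
    params: SimulationParams


def generate_design(n_young: int, n_adult: int) -> pd.Series:
    """Ordered sample ids labelled young/adult (young first)."""
    if n_young < 2 or n_adult < 2:
        raise ConfigurationError(
            "invalid design: need >= 2 samples per group "
            "(within-group variance undefined otherwise)"
        )
    ids = [f"young_{i + 1}" for i in range(n_young)]
    ids += [f"adult_{i + 1}" for i in range(n_adult)]
    groups = [YOUNG] * n_young + [ADULT] * n_adult
    return pd.Series(groups, index=ids, name="group")


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_dataset(params: SimulationParams) -> SimulatedBundle:
    """Draw one full synthetic study; identical seed => identical bundle."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    gene_ids = np.array(_feature_ids("gene", params.n_genes))
    mirna_ids = np.array(_feature_ids("mir", params.n_mirnas))
    design = generate_design(params.n_young, params.n_adult)

    # 1) miRNA effects
    n_de = params.n_de_mirnas()
    de_idx = np.sort(rng.choice(params.n_mirnas, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mirna_shift = np.zeros(params.n_mirnas)
    mirna_shift[de_idx] = signs * params.mirna_effect

    # 2) gene effects: regulon coupling, then independent DE genes
    gene_shift = np.zeros(params.n_genes)
    regulons: dict[str, frozenset[str]] = {}
    true_pairs: set[tuple[str, str]] = set()
    if n_de and params.regulon_size:
        if params.overlap_regulons:
            target_idx = np.stack(
                [rng.choice(params.n_genes, params.regulon_size, replace=False)
                 for _ in range(n_de)]
            )
        else:
            perm = rng.permutation(params.n_genes)
            target_idx = perm[: n_de * params.regulon_size].reshape(
                n_de, params.regulon_size
            )
        for row, mi in enumerate(de_idx):
            tgt = target_idx[row]
            gene_shift[tgt] += -params.coupling_beta * mirna_shift[mi]
            regulons[mirna_ids[mi]] = frozenset(gene_ids[tgt])
            true_pairs.update((mirna_ids[mi], g) for g in gene_ids[tgt])
    n_indep = int(round(params.frac_de_genes_indep * params.n_genes))
    indep_idx = rng.choice(params.n_genes, size=n_indep, replace=False)
    indep_signs = rng.choice([-1.0, 1.0], size=n_indep)
    gene_shift[indep_idx] += indep_signs * params.indep_gene_effect

    # 3) noise: baselines then residuals, genes before miRNAs
    n_samples = params.n_young + params.n_adult
    adult_mask = (design == ADULT).to_numpy().astype(float)

    def _expression(n_feat: int, shift: np.ndarray) -> np.ndarray:
        base = rng.normal(params.baseline_mean, params.baseline_sd, n_feat)
        noise = rng.normal(0.0, params.noise_sd, (n_feat, n_samples))
        return base[:, None] + shift[:, None] * adult_mask[None, :] + noise

    gene_x = _expression(params.n_genes, gene_shift)
    mirna_x = _expression(params.n_mirnas, mirna_shift)

    # 4) sources: one uniform draw per (pair, source); true pairs use tpr,
    #    everything else fpr. miRNA-major pair order.
    is_true = np.zeros((params.n_mirnas, params.n_genes), dtype=bool)
    for m, genes in regulons.items():
        mi = np.where(mirna_ids == m)[0][0]
        gi = np.isin(gene_ids, list(genes))
        is_true[mi, gi] = True
    u = rng.random((params.n_mirnas * params.n_genes, params.n_sources))
    thresh = np.where(is_true.ravel(), params.source_tpr, params.source_fpr)
    flags = u < thresh[:, None]
    del u
    support = flags.sum(axis=1)
    keep = support >= 1
    mi_grid, gi_grid = np.divmod(np.nonzero(keep)[0], params.n_genes)
    source_names = tuple(f"source_{i + 1:02d}" for i in range(params.n_sources))
    itab = pd.DataFrame(
        {"mirna": mirna_ids[mi_grid], "gene": gene_ids[gi_grid]}
    )
    for j, s in enumerate(source_names):
        itab[s] = flags[keep, j].astype(int)
    itab["support"] = support[keep]
    interactions = InteractionTable(frame=itab, source_names=source_names)

    # expected gene directions from the summed shift
    de_genes_expected = {
        gene_ids[i]: ("up" if gene_shift[i] > 0 else "down")
        for i in np.nonzero(gene_shift)[0]
    }
    truth = GroundTruth(
        de_mirnas={
            mirna_ids[i]: ("up" if mirna_shift[i] > 0 else "down")
            for i in de_idx
        },
        regulons=regulons,
        true_interactions=frozenset(true_pairs),
        de_genes_expected=de_genes_expected,
    )

    # 5) pathways: size uniform in range, members weighted toward expected-DE
    weights = np.ones(params.n_genes)
    de_gene_mask = gene_shift != 0
    weights[de_gene_mask] = params.pathway_de_bias
    weights /= weights.sum()
    sets = {}
    for p in range(params.n_pathways):
        lo, hi = params.pathway_size_range
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(params.n_genes, size=size, replace=False, p=weights)
        name = f"PW{p + 1:04d}"
        sets[name] = GeneSet(
            name=name,
            description=f"synthetic pathway {p + 1}",
            members=frozenset(gene_ids[members]),
        )
    pathways = GeneSetCollection(sets=sets, universe=frozenset(gene_ids))

    def _matrix(x: np.ndarray, ids: np.ndarray) -> ExpressionMatrix:
        return ExpressionMatrix(
            values=pd.DataFrame(x, index=ids, columns=design.index),
            design=design,
            log2=True,
        )

    return SimulatedBundle(
        genes=_matrix(gene_x, gene_ids),
        mirnas=_matrix(mirna_x, mirna_ids),
        interactions=interactions,
        pathways=pathways,
        truth=truth,
        params=params,
    )


def expected_mean_difference(params: SimulationParams, truth: GroundTruth):
    """Noiseless adult-young mean difference per feature, from the truth.

    Returns (gene_diff, mirna_diff) dicts; features absent from a dict have
    expected difference zero. Used by coupling-sign checks.
    """
    eff = params.mirna_effect
    mirna_diff = {
        m: (eff if d == "up" else -eff) for m, d in truth.de_mirnas.items()
    }
    gene_diff: dict[str, float] = {}
    for m, genes in truth.regulons.items():
        for g in genes:
            gene_diff[g] = gene_diff.get(g, 0.0) - params.coupling_beta * mirna_diff[m]
    return gene_diff, mirna_diff


def write_fixture(bundle: SimulatedBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as the pipeline's plain-text input files.

    Produces genes.tsv, mirnas.tsv, design.tsv, interactions.tsv,
    pathways.gmt, universe.txt and ground_truth.tsv under ``out_dir`` and
    returns {name: path}. Files round-trip losslessly through the readers in
    :mod:`mirlink.io`.
    """
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": bundle.params.seed}
    paths = {
        "genes": out / "genes.tsv",
        "mirnas": out / "mirnas.tsv",
        "design": out / "design.tsv",
        "interactions": out / "interactions.tsv",
        "pathways": out / "pathways.gmt",
        "universe": out / "universe.txt",
        "ground_truth": out / "ground_truth.tsv",
    }
    mio.write_expression(paths["genes"], bundle.genes, meta=meta)
    mio.write_expression(paths["mirnas"], bundle.mirnas, meta=meta)
    mio.write_design(paths["design"], bundle.genes.design, meta=meta)
    mio.write_interactions(paths["interactions"], bundle.interactions, meta=meta)
    mio.write_gmt(paths["pathways"], bundle.pathways)
    mio.write_id_list(paths["universe"], sorted(bundle.pathways.universe), meta=meta)
    mio.write_ground_truth(paths["ground_truth"], bundle.truth, meta=meta)
    return paths
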