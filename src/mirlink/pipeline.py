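"""End-to-end driver: simulate -> DE -> targets -> enrich -> integrate.

Orchestrates the full workflow on one configuration and writes every stage
output plus a checksummed manifest under one directory. Deterministic for a
fixed (config, seed): outputs carry no timestamps, so re-running a config
reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as mio
from .config import AnalysisConfig
from .diffexpr import (
    DEResult,
    ExpressionMatrix,
    anova_per_feature,
    classify_de,
    log2_if_linear,
    quantile_normalize,
)
from .enrichment import (
    mirna_bindingsite_enrichment,
    mirna_pathway_enrichment,
    pathway_enrichment,
    results_to_frame,
)
from .integration import build_summary, render_summary_frame, render_summary_text
from .simulate import SimulationParams, simulate_dataset, write_fixture
from .targets import consensus_filter, find_hubs

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_de", "run_all"]

INPUT_FILES = ("genes", "mirnas", "design", "interactions", "pathways",
               "universe", "ground_truth")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


def run_de(m: ExpressionMatrix, spec, linear: bool = False,
           offset: float = 0.0, normalize: bool = True) -> DEResult:
    """Normalize, test and classify one expression matrix.

    ``normalize=False`` skips quantile normalization; appropriate for small
    matrices where most features carry real group effects (quantile
    normalization assumes the bulk of the distribution is unchanged between
    samples and would smear such effects).
    """
    if linear:
        m = ExpressionMatrix(values=m.values, design=m.design, log2=False)
    m = log2_if_linear(m, offset=offset)
    if normalize:
        m = quantile_normalize(m)
    stats = anova_per_feature(m)
    return classify_de(stats, spec)


def _significant_names(results) -> list[str]:
    return [r.name for r in results if r.significant]


def run_all(
    config: AnalysisConfig,
    out_dir,
    params: SimulationParams | None = None,
    input_dir=None,
) -> dict:
    """Execute the whole pipeline; returns the manifest dictionary.

    Either ``params`` (simulate fresh inputs into ``out_dir/inputs``) or
    ``input_dir`` (a directory laid out like a written fixture) must be
    given. Any stage failure aborts with :class:`StageError` after writing a
    manifest marked incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    manifest: dict = {
        "config": config.to_dict(),
        "config_fingerprint": config.fingerprint(),
        "complete": False,
        "files": {},
    }
    paths: dict[str, Path] = {}

    def _record(name: str, path: Path) -> None:
        paths[name] = Path(path)

    stage = "simulate"
    try:
        if params is not None:
            if params.seed is None:
                raise StageError(stage, "a seed is mandatory for simulation")
            bundle = simulate_dataset(params)
            fixture = write_fixture(bundle, out / "inputs")
            for name, p in fixture.items():
                _record(f"inputs/{name}", p)
            genes, mirnas = bundle.genes, bundle.mirnas
            interactions = bundle.interactions
            pathways = bundle.pathways
            universe = set(pathways.universe)
        elif input_dir is not None:
            stage = "load"
            ind = Path(input_dir)
            design = mio.read_design(ind / "design.tsv")
            genes = mio.read_expression(ind / "genes.tsv", design)
            mirnas = mio.read_expression(ind / "mirnas.tsv", design)
            interactions = mio.load_interactions(ind / "interactions.tsv")
            gmt_path = ind / "pathways.gmt"
            if not gmt_path.exists():
                raise StageError("enrich", f"missing GMT file: {gmt_path}")
            universe_path = ind / "universe.txt"
            universe = (set(mio.read_id_list(universe_path))
                        if universe_path.exists() else None)
            pathways = mio.read_gmt(gmt_path, universe=universe)
            universe = set(pathways.universe)
        else:
            raise StageError("configure", "need simulation params or an input directory")

        if config.universe_mode == "measured":
            universe = set(genes.feature_ids)

        stage = "de"
        gene_de = run_de(genes, config.gene_filter())
        mirna_de = run_de(mirnas, config.mirna_filter())
        mio.write_de_table(out / "de_genes.tsv", gene_de, meta=meta)
        mio.write_de_table(out / "de_mirnas.tsv", mirna_de, meta=meta)
        for name, ids in (
            ("genes_up", gene_de.up_features),
            ("genes_down", gene_de.down_features),
            ("mirnas_up", mirna_de.up_features),
            ("mirnas_down", mirna_de.down_features),
        ):
            p = out / f"{name}.txt"
            mio.write_id_list(p, sorted(ids), meta=meta)
            _record(name, p)
        _record("de_genes", out / "de_genes.tsv")
        _record("de_mirnas", out / "de_mirnas.tsv")
        logger.info("de: %d up / %d down genes, %d up / %d down miRNAs",
                    len(gene_de.up_features), len(gene_de.down_features),
                    len(mirna_de.up_features), len(mirna_de.down_features))

        stage = "targets"
        consensus = consensus_filter(interactions, config.min_algorithms)
        hubs = find_hubs(consensus, config.min_hub)
        mio.write_interactions(out / "consensus_interactions.tsv", consensus,
                               meta=meta)
        hub_frame = hubs.target_hubs.assign(kind="target_hub")
        hub_frame = hub_frame[["entity", "kind", "degree"]]
        mirna_frame = hubs.mirna_hubs.assign(kind="mirna_hub")[
            ["entity", "kind", "degree"]]
        mio.write_enrichment(out / "hubs.tsv",
                             pd.concat([hub_frame, mirna_frame],
                                       ignore_index=True), meta=meta)
        _record("consensus_interactions", out / "consensus_interactions.tsv")
        _record("hubs", out / "hubs.tsv")
        logger.info("targets: %d consensus pairs, %d target-hubs, %d miRNA-hubs",
                    len(consensus), len(hubs.target_hubs), len(hubs.mirna_hubs))

        stage = "enrich"
        alpha = config.alpha_enrichment
        gp_up = pathway_enrichment(gene_de.up_features, pathways, alpha)
        gp_down = pathway_enrichment(gene_de.down_features, pathways, alpha)
        bs_up = mirna_bindingsite_enrichment(gene_de.up_features, consensus,
                                             universe, alpha)
        bs_down = mirna_bindingsite_enrichment(gene_de.down_features, consensus,
                                               universe, alpha)
        mp_up, mp_up_n = mirna_pathway_enrichment(mirna_de.up_features,
                                                  consensus, pathways, alpha)
        mp_down, mp_down_n = mirna_pathway_enrichment(mirna_de.down_features,
                                                      consensus, pathways, alpha)
        for name, res, extra in (
            ("pathways_genes_up", gp_up, {}),
            ("pathways_genes_down", gp_down, {}),
            ("bindingsite_up", bs_up, {}),
            ("bindingsite_down", bs_down, {}),
            ("pathways_mirna_targets_up", mp_up, {"query_size": mp_up_n}),
            ("pathways_mirna_targets_down", mp_down, {"query_size": mp_down_n}),
        ):
            p = out / f"{name}.tsv"
            mio.write_enrichment(p, results_to_frame(res), meta={**meta, **extra})
            _record(name, p)

        stage = "integrate"
        summary = build_summary(
            gene_de=gene_de,
            mirna_de=mirna_de,
            gene_pathways_up=_significant_names(gp_up),
            gene_pathways_down=_significant_names(gp_down),
            mirna_pathways_up=_significant_names(mp_up),
            mirna_pathways_down=_significant_names(mp_down),
            enriched_in_up_genes=_significant_names(bs_up),
            enriched_in_down_genes=_significant_names(bs_down),
            interactions=consensus,
            config_fingerprint=config.fingerprint(),
        )
        mio.write_enrichment(out / "summary.tsv", render_summary_frame(summary),
                             meta=meta)
        (out / "summary.txt").write_text(render_summary_text(summary),
                                         encoding="utf-8")
        pair_rows = pd.DataFrame(
            sorted(summary.inverse.all_pairs()), columns=["mirna", "gene"]
        )
        mio.write_enrichment(out / "inverse_pairs.tsv", pair_rows, meta=meta)
        for name in ("summary", "inverse_pairs"):
            _record(name, out / f"{name}.tsv")
        _record("summary_text", out / "summary.txt")

        manifest["complete"] = True
    except StageError:
        raise
    except Exception as exc:
        _write_manifest(out, manifest, paths, incomplete_stage=stage)
        raise StageError(stage, str(exc)) from exc

    _write_manifest(out, manifest, paths)
    manifest["summary_counts"] = summary.counts
    return manifest


def _write_manifest(out: Path, manifest: dict, paths: dict[str, Path],
                    incomplete_stage: str | None = None) -> None:
    manifest["files"] = {
        name: {"path": str(p.relative_to(out)), "sha256": mio.file_sha256(p)}
        for name, p in sorted(paths.items()) if p.exists()
    }
    if incomplete_stage is not None:
        manifest["incomplete_stage"] = incomplete_stage
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
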