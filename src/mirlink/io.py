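"""Plain-text readers and writers shared by every pipeline stage.

All tables are UTF-8, tab-separated; writers prepend '#'-prefixed metadata
header lines (tool version, config fingerprint, seed) which every reader
ignores. Gene sets use the standard GMT dialect (set name, description, then
tab-separated member genes; at least three fields per line). Schema
violations raise :class:`SchemaError` with the offending line or id named.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import DEResult, ExpressionMatrix
from .enrichment import GeneSet, GeneSetCollection
from .targets import InteractionTable, SchemaError, merge_duplicate_rows

FLOAT_FORMAT = "%.10g"

__all__ = [
    "SchemaError",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "load_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_id_list",
    "write_id_list",
    "write_enrichment",
    "read_enrichment",
    "write_de_table",
    "write_ground_truth",
    "read_ground_truth",
    "file_sha256",
]


def _meta_lines(meta: dict | None) -> list[str]:
    fields = {"tool": f"mirlink {__version__}"}
    if meta:
        fields.update(meta)
    return [f"# {k}={v}" for k, v in fields.items()]


def _write_frame(path, frame: pd.DataFrame, meta: dict | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT,
                     lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    # explicit ragged-row check: pandas silently truncates or pads
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise SchemaError(
                    f"{path}:{lineno}: ragged row ({n} fields, header has {width})"
                )
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False, index_col=False)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc


def read_expression(path, design: pd.Series, log2: bool = True) -> ExpressionMatrix:
    """Read a feature x sample intensity TSV against a known design."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: expected feature column plus samples")
    feature_col = raw.columns[0]
    undeclared = [s for s in raw.columns[1:] if s not in design.index]
    if undeclared:
        raise SchemaError(
            f"{path}: sample(s) absent from design: {undeclared}"
        )
    try:
        values = raw.set_index(feature_col).astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric or missing intensity ({exc})") from exc
    values.index.name = None
    return ExpressionMatrix(values=values, design=design, log2=log2)


def write_expression(path, m: ExpressionMatrix, meta: dict | None = None) -> None:
    frame = m.values.copy()
    frame.insert(0, "feature", frame.index)
    _write_frame(path, frame, meta, index=False)


def read_design(path) -> pd.Series:
    raw = _read_table(path)
    if list(raw.columns[:2]) != ["sample", "group"]:
        raise SchemaError(f"{path}: design needs columns sample, group")
    if raw["sample"].duplicated().any():
        dup = raw.loc[raw["sample"].duplicated(), "sample"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(raw["group"].to_numpy(), index=raw["sample"], name="group")


def write_design(path, design: pd.Series, meta: dict | None = None) -> None:
    frame = pd.DataFrame({"sample": design.index, "group": design.to_numpy()})
    _write_frame(path, frame, meta, index=False)


def load_interactions(path, source_names=None) -> InteractionTable:
    """Read and validate an interaction TSV.

    Source columns are all columns between the key columns and ``support``
    unless ``source_names`` is given. Duplicate (mirna, gene) rows are merged
    by OR-ing their flags; a stored support value inconsistent with the row's
    flags is a schema error naming the row.
    """
    raw = _read_table(path)
    for col in ("mirna", "gene", "support"):
        if col not in raw.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    file_sources = [c for c in raw.columns if c not in ("mirna", "gene", "support")]
    if source_names is not None:
        extra = sorted(set(file_sources) - set(source_names))
        if extra:
            raise SchemaError(f"{path}: undeclared source column(s): {extra}")
        sources = [c for c in source_names if c in file_sources]
    else:
        sources = file_sources
    frame = raw.copy()
    try:
        frame[sources] = frame[sources].astype(int)
        frame["support"] = frame["support"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer flag or support ({exc})") from exc
    declared = frame["support"].to_numpy()
    actual = frame[sources].to_numpy().sum(axis=1) if sources else np.zeros(len(frame))
    bad = np.nonzero(declared != actual)[0]
    if len(bad):
        i = int(bad[0])
        raise SchemaError(
            f"{path}: support={declared[i]} but {int(actual[i])} flag(s) set "
            f"for pair ({frame['mirna'].iloc[i]}, {frame['gene'].iloc[i]})"
        )
    merged = merge_duplicate_rows(frame, sources)
    merged = merged[merged["support"] >= 1].reset_index(drop=True)
    return InteractionTable(frame=merged, source_names=tuple(sources))


def write_interactions(path, t: InteractionTable, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("min_support", t.min_support)
    _write_frame(path, t.frame, meta, index=False)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT gene-set file; the universe defaults to the union of sets."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and >= 1 member"
                )
            name, description, *members = fields
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, description=description,
                                 members=frozenset(members))
    if universe is None:
        universe = frozenset().union(*(s.members for s in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(path, collection: GeneSetCollection) -> None:
    # GMT has no comment dialect; no metadata header here
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, gs in collection.sets.items():
            members = "\t".join(sorted(gs.members))
            fh.write(f"{name}\t{gs.description}\t{members}\n")


def read_id_list(path) -> list[str]:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def write_id_list(path, ids, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        for i in ids:
            fh.write(f"{i}\n")


def write_enrichment(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    _write_frame(path, frame, meta, index=False)


def read_enrichment(path) -> pd.DataFrame:
    frame = _read_table(path)
    for col in ("k", "n", "K", "N", "significant"):
        frame[col] = frame[col].astype(int)
    for col in ("p_raw", "fold_enrichment", "p_adj"):
        frame[col] = frame[col].replace("", "nan").astype(float)
    return frame


def write_de_table(path, result: DEResult, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    if result.filter_spec is not None:
        s = result.filter_spec
        meta.setdefault("filter_kind", s.kind)
        meta.setdefault("p_threshold", s.p_threshold)
        meta.setdefault("use_adjusted", s.use_adjusted)
        meta.setdefault("fc_threshold", s.fc_threshold)
    frame = result.table.copy()
    frame.insert(0, "feature", frame.index)
    _write_frame(path, frame, meta, index=False)


def write_ground_truth(path, truth, meta: dict | None = None) -> None:
    """Planted features as (feature, layer, role, direction, regulator)."""
    rows = []
    for m, d in sorted(truth.de_mirnas.items()):
        rows.append({"feature": m, "layer": "mirna", "role": "de_mirna",
                     "direction": d, "regulator": ""})
    for m, genes in sorted(truth.regulons.items()):
        for g in sorted(genes):
            rows.append({"feature": g, "layer": "gene", "role": "regulon_target",
                         "direction": truth.de_genes_expected.get(g, "none"),
                         "regulator": m})
    regulon_genes = {g for gs in truth.regulons.values() for g in gs}
    for g, d in sorted(truth.de_genes_expected.items()):
        if g not in regulon_genes:
            rows.append({"feature": g, "layer": "gene", "role": "independent_de",
                         "direction": d, "regulator": ""})
    frame = pd.DataFrame(
        rows, columns=["feature", "layer", "role", "direction", "regulator"]
    )
    _write_frame(path, frame, meta, index=False)


def read_ground_truth(path):
    """Rebuild a :class:`~mirlink.simulate.GroundTruth` from its TSV."""
    from .simulate import GroundTruth

    frame = _read_table(path)
    de_mirnas = {}
    regulons: dict[str, set[str]] = {}
    de_genes: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        if row.role == "de_mirna":
            de_mirnas[row.feature] = row.direction
        elif row.role == "regulon_target":
            regulons.setdefault(row.regulator, set()).add(row.feature)
            if row.direction in ("up", "down"):
                de_genes[row.feature] = row.direction
        elif row.role == "independent_de":
            de_genes[row.feature] = row.direction
    true_pairs = frozenset(
        (m, g) for m, genes in regulons.items() for g in genes
    )
    return GroundTruth(
        de_mirnas=de_mirnas,
        regulons={m: frozenset(g) for m, g in regulons.items()},
        true_interactions=true_pairs,
        de_genes_expected=de_genes,
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
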