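"""On-disk formats: TSV expression matrices, GMT gene sets, ortholog maps,
and Java TreeView CDT/GTR/ATR cluster files.

Expression matrices are plain TSV: one header row of sample ids, first
column feature ids, empty cells (or ``NA``) meaning missing. Sample
annotations travel in a sidecar TSV (``<stem>.annotations.tsv``) and channel
intensities in ``<stem>.cy5.tsv`` / ``<stem>.cy3.tsv`` when present.
Readers reject malformed input (duplicate ids, ragged rows) rather than
coercing it.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import BundleError, ExpressionBundle, FeatureMap, GeneSet, GeneSetCollection

log = logging.getLogger("gemmclass")

_NA_STRINGS = ("", "NA", "NaN", "nan")


class FormatError(ValueError):
    """Malformed on-disk input."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    sample_ids = header[1:]
    _reject_duplicates(sample_ids, "sample", path)
    feature_ids, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise FormatError(f"{path}:{lineno}: ragged row "
                              f"({len(row)} fields, expected {ncol})")
        feature_ids.append(row[0])
        data.append([np.nan if cell in _NA_STRINGS else float(cell)
                     for cell in row[1:]])
    _reject_duplicates(feature_ids, "feature", path)
    return pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)


def _reject_duplicates(ids, what, path):
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"{path}: duplicate {what} id(s): {', '.join(dups[:5])}")


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", *df.columns])
        for fid, row in zip(df.index, df.to_numpy()):
            w.writerow([fid, *("" if np.isnan(v) else format(v, ".8g") for v in row)])


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_name(path.name.removesuffix(".tsv") + f".{kind}.tsv")


def read_expression(path) -> ExpressionBundle:
    """Read a bundle from ``path`` plus any sidecar annotation/channel files."""
    path = Path(path)
    values = _read_matrix(path)
    ann = None
    ann_path = _sidecar(path, "annotations")
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t", index_col=0)
        if "is_bridge" in ann.columns:
            ann["is_bridge"] = ann["is_bridge"].astype(bool)
    cy5 = cy3 = None
    if _sidecar(path, "cy5").exists():
        cy5 = _read_matrix(_sidecar(path, "cy5"))
        cy3 = _read_matrix(_sidecar(path, "cy3"))
    return ExpressionBundle(values, ann, cy5, cy3)


def write_expression(bundle: ExpressionBundle, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_matrix(bundle.values, path)
    bundle.sample_annotations.to_csv(_sidecar(path, "annotations"), sep="\t",
                                     index_label="sample")
    if bundle.cy5 is not None:
        _write_matrix(bundle.cy5, _sidecar(path, "cy5"))
        _write_matrix(bundle.cy3, _sidecar(path, "cy3"))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line ``id<TAB>description<TAB>gene...``."""
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has "
                                  f"{len(fields)} fields, expected >= 3")
            genes = []
            for g in fields[2:]:
                if g == "":
                    log.warning("%s:%d: empty member field skipped", path, lineno)
                    continue
                genes.append(g)
            sets.append(GeneSet(fields[0], fields[1], genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in collection:
            if not s.genes:
                log.warning("gene set %s is empty; not written", s.set_id)
                continue
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# feature / ortholog maps
# ---------------------------------------------------------------------------

def read_feature_map(probe_path=None, ortholog_path=None) -> FeatureMap:
    """Read probe→gene and mouse↔human ortholog TSVs (two columns each).

    Duplicate mouse or human symbols in the ortholog file are resolved by
    keeping the first occurrence; the number dropped is logged.
    """
    probe_to_gene: dict[str, str] = {}
    if probe_path is not None:
        for lineno, row in _two_columns(probe_path):
            probe_to_gene[row[0]] = row[1]
    orthologs: dict[str, str] = {}
    if ortholog_path is not None:
        used_human: set[str] = set()
        dropped = 0
        for lineno, row in _two_columns(ortholog_path):
            mouse, human = row
            if mouse in orthologs or human in used_human:
                dropped += 1
                continue
            orthologs[mouse] = human
            used_human.add(human)
        if dropped:
            log.info("ortholog map: dropped %d non-1:1 pair(s)", dropped)
    return FeatureMap(probe_to_gene, orthologs)


def write_feature_map(fmap: FeatureMap, probe_path=None, ortholog_path=None) -> None:
    if probe_path is not None:
        with open(probe_path, "w") as fh:
            for probe, gene in fmap.probe_to_gene.items():
                fh.write(f"{probe}\t{gene}\n")
    if ortholog_path is not None:
        with open(ortholog_path, "w") as fh:
            for mouse, human in fmap.orthologs.items():
                fh.write(f"{mouse}\t{human}\n")


def _two_columns(path):
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            yield lineno, fields[:2]


# ---------------------------------------------------------------------------
# Java TreeView CDT/GTR/ATR
# ---------------------------------------------------------------------------

def write_treeview(bundle: ExpressionBundle, tree_rows, tree_cols, path_prefix) -> list[Path]:
    """Write a clustered dataset in the CDT/GTR/ATR dialect.

    Row/column order in the CDT equals the trees' leaf orders; each GTR/ATR
    node line carries the merge correlation (1 − merge distance). Either
    tree may be None, in which case input order is kept and the
    corresponding tree file is omitted.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    features = bundle.feature_ids
    samples = bundle.sample_ids
    if tree_rows is not None and tree_rows.n_leaves != len(features):
        raise FormatError("row tree leaves do not match bundle features")
    if tree_cols is not None and tree_cols.n_leaves != len(samples):
        raise FormatError("column tree leaves do not match bundle samples")

    row_order = tree_rows.leaf_order if tree_rows is not None else range(len(features))
    col_order = tree_cols.leaf_order if tree_cols is not None else range(len(samples))
    gids = [f"GENE{i}X" for i in range(len(features))]
    aids = [f"ARRY{j}X" for j in range(len(samples))]

    if tree_rows is not None:
        gtr = prefix.with_suffix(".gtr")
        _write_tree_file(tree_rows, gtr, "GENE")
        written.append(gtr)
    if tree_cols is not None:
        atr = prefix.with_suffix(".atr")
        _write_tree_file(tree_cols, atr, "ARRY")
        written.append(atr)

    cdt = prefix.with_suffix(".cdt")
    vals = bundle.values.to_numpy()
    with open(cdt, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + [samples[j] for j in col_order]
        w.writerow(header)
        if tree_cols is not None:
            w.writerow(["AID", "", "", ""] + [aids[j] for j in col_order])
        w.writerow(["EWEIGHT", "", "", ""] + ["1"] * len(samples))
        for i in row_order:
            row = ["" if np.isnan(v) else format(v, ".6g") for v in vals[i, list(col_order)]]
            w.writerow([gids[i], features[i], features[i], "1"] + row)
    written.append(cdt)
    return written


def _write_tree_file(tree, path: Path, kind: str) -> None:
    n = tree.n_leaves

    def node_name(idx: int) -> str:
        return f"{kind}{idx}X" if idx < n else f"NODE{idx - n + 1}X"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for k, (left, right, r) in enumerate(tree.merges):
            w.writerow([f"NODE{k + 1}X", node_name(left), node_name(right),
                        format(float(r), ".6f")])
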