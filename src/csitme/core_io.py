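"""Readers and writers for the on-disk artifacts consumed and produced by the
pipeline.

All tabular artifacts are TSV (tab-delimited, UTF-8, header row).  Expression
matrices may alternatively be MatrixMarket triplets with plain-text sidecar
files listing gene and sample identifiers, one per line, matching the matrix
row/column order.  Every table is keyed by sample identifier; the working
cohort for any cross-table operation is the intersection of sample ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("csitme")

GRADE_CODES = {"II": 2, "III": 3, "IV": 4, "2": 2, "3": 3, "4": 4, 2: 2, 3: 3, 4: 4}

CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")
CLINICAL_OPTIONAL = ("age", "sex", "grade", "subtype", "patient_id", "timepoint", "response")


def _check_unique(ids: Sequence, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups.index[:10]))}")


@dataclass
class ExpressionMatrix:
    """One cell type's deconvolved genes x samples expression values.

    ``values`` holds TPM-like non-negative values unless ``is_log`` is set,
    in which case they are already on a log scale and the log step of
    preprocessing is skipped downstream.
    """

    cell_type: str
    values: pd.DataFrame  # genes (index) x samples (columns)
    is_log: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene identifiers")
        _check_unique(self.values.columns, "sample identifiers")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class LRDatabase:
    """A set of ligand-receptor gene pairs with counts recomputed from content."""

    pairs: frozenset  # of (ligand, receptor) tuples

    @property
    def ligands(self) -> frozenset:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptors(self) -> frozenset:
        return frozenset(r for _, r in self.pairs)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def load_expression(
    path: str | Path,
    format: str = "tsv",
    cell_type: str | None = None,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    confidence_path: str | Path | None = None,
    min_confidence: float = 0.95,
    is_log: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    ``format`` is ``tsv`` (gene rows, sample columns, header row) or ``mtx``
    (MatrixMarket triplets plus ``genes_path``/``samples_path`` sidecars).
    If ``confidence_path`` is given it must be a two-column TSV
    (gene, confidence); genes whose deconvolution confidence is not strictly
    greater than ``min_confidence`` are removed.
    """
    path = Path(path)
    if cell_type is None:
        cell_type = path.stem
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
    elif format == "mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("mtx format requires genes_path and samples_path sidecars")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # locate the offending triplet for the message
            raise ValueError(f"malformed MatrixMarket file {path}: {_describe_mtx_error(path)}") from exc
        genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
        samples = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format: {format!r}")

    if confidence_path is not None:
        conf = pd.read_csv(confidence_path, sep="\t", index_col=0).iloc[:, 0]
        keep = conf[conf > min_confidence].index
        dropped = df.index.difference(keep)
        if len(dropped):
            logger.info(
                "dropping %d/%d genes below confidence %.2f in %s",
                len(dropped), len(df), min_confidence, cell_type,
            )
        df = df.loc[df.index.intersection(keep)]
    return ExpressionMatrix(cell_type=cell_type, values=df, is_log=is_log)


def _describe_mtx_error(path: Path) -> str:
    """Best-effort location of the first malformed triplet line."""
    try:
        lines = Path(path).read_text().splitlines()
    except OSError:
        return "unreadable"
    body = [(i + 1, l) for i, l in enumerate(lines) if l.strip() and not l.startswith("%")]
    if not body:
        return "empty file"
    try:
        nrow, ncol, _ = (int(x) for x in body[0][1].split()[:3])
    except (ValueError, IndexError):
        return f"bad size header at line {body[0][0]}"
    for lineno, line in body[1:]:
        parts = line.split()
        try:
            i, j = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            return f"unparseable triplet at line {lineno}"
        if not (1 <= i <= nrow) or not (1 <= j <= ncol):
            return f"out-of-range index at line {lineno}: ({i}, {j}) for shape ({nrow}, {ncol})"
    return "unknown parse error"


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Load and validate a clinical table.

    Required columns: sample_id, os_time (days, > 0), os_event (0/1).
    Optional: age, sex, grade (II/III/IV mapped to ordinal 2/3/4), subtype,
    patient_id, timepoint, response.  Unknown grade categories become NA.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    _check_unique(df["sample_id"], "sample_id")
    df = df.set_index("sample_id", drop=False)
    df["os_time"] = pd.to_numeric(df["os_time"])
    if (df["os_time"] <= 0).any():
        bad = df.index[df["os_time"] <= 0].tolist()
        raise ValueError(f"non-positive os_time for samples: {bad[:10]}")
    ev = pd.to_numeric(df["os_event"])
    if not ev.isin([0, 1]).all():
        raise ValueError("os_event must be binary 0/1")
    df["os_event"] = ev.astype(int)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "grade" in df.columns:
        df["grade"] = df["grade"].map(GRADE_CODES)
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_lr_database(path: str | Path) -> LRDatabase:
    """Load a two-column (ligand, receptor) TSV into an :class:`LRDatabase`.

    Duplicate rows collapse; ligand/receptor/pair counts are recomputed from
    the loaded content, never trusted from any header.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or len(df) == 0:
        raise ValueError(f"ligand-receptor table {path} is empty or lacks two columns")
    pairs = frozenset(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return LRDatabase(pairs=pairs)


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    pd.DataFrame(sorted(db.pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


def load_mutations(path: str | Path) -> pd.DataFrame:
    """Load a gene x sample mutation-count matrix and binarize it.

    Entries count nonsynonymous somatic mutations; any count >= 1 becomes 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    _check_unique(df.index, "gene identifiers")
    _check_unique(df.columns, "sample identifiers")
    if (df.to_numpy() < 0).any():
        raise ValueError("mutation counts must be non-negative")
    return (df > 0).astype(int)


def write_mutations(mut: pd.DataFrame, path: str | Path) -> None:
    mut.to_csv(path, sep="\t", index_label="gene")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def working_cohort(sample_lists: Iterable[Sequence]) -> list:
    """Intersection of sample ids across tables, preserving first-list order."""
    lists = [list(s) for s in sample_lists]
    if not lists:
        return []
    common = set(lists[0])
    for s in lists[1:]:
        common &= set(s)
    return [s for s in lists[0] if s in common]
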