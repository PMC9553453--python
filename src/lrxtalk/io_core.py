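"""Core data containers and readers/writers for the pipeline's file formats.

Gene identity throughout the package is the upper-cased symbol; no alias or
identifier mapping is performed. All readers validate and raise
:class:`~lrxtalk.errors.FormatError` on malformed input rather than coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import FormatError

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("tumor", "normal")

#: Substage labels collapse to their main stage (IA/IB -> I, IIIA -> III, ...).
_STAGE_ORDER = ("IV", "III", "II", "I")


@dataclass
class CountMatrix:
    """Raw counts, cells x genes, with unique cell ids and gene symbols."""

    values: np.ndarray  # (n_cells, n_genes) non-negative integers
    cell_ids: list[str]
    gene_symbols: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_symbols = [str(g).strip().upper() for g in self.gene_symbols]
        if self.values.ndim != 2:
            raise FormatError("count matrix must be two-dimensional")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} cells but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_symbols):
            raise FormatError(
                f"matrix has {n_genes} genes but {len(self.gene_symbols)} gene symbols"
            )
        if any(not g for g in self.gene_symbols):
            raise FormatError("empty gene symbol")
        dupes = _duplicates(self.gene_symbols)
        if dupes:
            raise FormatError(f"duplicate gene symbols: {sorted(dupes)}")
        dupes = _duplicates(self.cell_ids)
        if dupes:
            raise FormatError(f"duplicate cell ids: {sorted(dupes)}")
        if np.any(self.values < 0):
            raise FormatError("negative count entries")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise FormatError("non-integer count entries")
            self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol.strip().upper())
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None


@dataclass
class ExprMatrix:
    """Log-normalized expression, cells x genes (log2(1 + scaled counts))."""

    values: np.ndarray
    cell_ids: list[str]
    gene_symbols: list[str]
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = [str(g).strip().upper() for g in self.gene_symbols]
        if self.values.shape != (len(self.cell_ids), len(self.gene_symbols)):
            raise FormatError("expression matrix dimensions do not match id lists")
        if np.any(self.values < 0):
            raise FormatError("negative expression entries")
        if self.scale_factor <= 0:
            raise FormatError("scale factor must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol.strip().upper())
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def cell_indices(self, cells) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.asarray([pos[c] for c in cells], dtype=int)
        except KeyError as exc:
            raise KeyError(f"cell {exc.args[0]!r} not in matrix") from None


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Counts


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from a 10x-style MTX triplet directory or dense TSV.

    The MTX file on disk is genes x cells (10x convention) and is transposed
    to cells x genes in memory. A dense TSV has gene symbols as columns and
    cell ids as the first column.
    """
    path = Path(path)
    if path.is_dir():
        return _read_counts_mtx(path)
    return _read_counts_tsv(path)


def _read_counts_mtx(directory: Path) -> CountMatrix:
    mtx = directory / "matrix.mtx"
    barcodes = directory / "barcodes.tsv"
    features = directory / "features.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise FormatError(f"missing file: {f}")
    try:
        mat = spio.mmread(str(mtx))
    except Exception as exc:  # noqa: BLE001 - re-raise as typed error
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    cell_ids = [line.split("\t")[0] for line in _read_lines(barcodes)]
    feat_rows = [line.split("\t") for line in _read_lines(features)]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    n_genes, n_cells = mat.shape
    if n_cells != len(cell_ids):
        raise FormatError(
            f"matrix has {n_cells} columns but barcodes file lists {len(cell_ids)} cells"
        )
    if n_genes != len(gene_symbols):
        raise FormatError(
            f"matrix has {n_genes} rows but features file lists {len(gene_symbols)} genes"
        )
    dense = np.asarray(mat.T.todense())
    if np.any(dense != np.round(dense)) or np.any(dense < 0):
        raise FormatError("matrix.mtx contains negative or non-integer entries")
    return CountMatrix(dense.astype(np.int64), cell_ids, gene_symbols)


def _read_counts_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))


def _read_lines(path: Path) -> list[str]:
    return [ln for ln in path.read_text().splitlines() if ln.strip()]


def write_counts(counts: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as an MTX triplet (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(directory / "matrix.mtx"), sparse.coo_matrix(counts.values.T), field="integer"
    )
    (directory / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    (directory / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}" for g in counts.gene_symbols) + "\n"
    )


# ---------------------------------------------------------------------------
# Cell annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation table (cell, sample_id, sample_type, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell": str})
    required = {"cell", "sample_id", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise FormatError(f"invalid sample_type values: {sorted(bad)}")
    if df["cell"].duplicated().any():
        raise FormatError("duplicate cell ids in annotation")
    return df.set_index("cell", drop=False)


def validate_annotation(annotation: pd.DataFrame, counts: CountMatrix) -> None:
    """Check that every matrix cell has exactly one annotation row."""
    ann_cells = set(annotation["cell"])
    mat_cells = set(counts.cell_ids)
    if ann_cells != mat_cells:
        missing = sorted(mat_cells - ann_cells)[:5]
        extra = sorted(ann_cells - mat_cells)[:5]
        raise FormatError(
            f"annotation/matrix cell mismatch (missing {missing}, extra {extra})"
        )


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ligand-receptor pairs


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Read a two-column (ligand, receptor) reference table.

    Symbols are upper-cased and trimmed; duplicate rows are collapsed and
    self-pairs dropped, each with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise FormatError(f"ligand-receptor table missing columns: {sorted(missing)}")
    return validate_lr_pairs(df)


def validate_lr_pairs(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ligand"] = df["ligand"].astype(str).str.strip().str.upper()
    df["receptor"] = df["receptor"].astype(str).str.strip().str.upper()
    n0 = len(df)
    df = df.drop_duplicates(subset=["ligand", "receptor"])
    n_dup = n0 - len(df)
    if n_dup:
        logger.info("dropped %d duplicate ligand-receptor rows", n_dup)
    self_pairs = df["ligand"] == df["receptor"]
    if self_pairs.any():
        logger.info("dropped %d self-pair rows", int(self_pairs.sum()))
        df = df[~self_pairs]
    return df.reset_index(drop=True)[["ligand", "receptor"]]


def write_lr_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df[["ligand", "receptor"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk cohort


def read_bulk(path: str | Path) -> pd.DataFrame:
    """Read a samples x genes log2-scale expression TSV (sample ids in col 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c).strip().upper() for c in df.columns]
    if df.index.duplicated().any():
        raise FormatError("duplicate sample ids in bulk matrix")
    dupes = _duplicates(list(df.columns))
    if dupes:
        raise FormatError(f"duplicate gene symbols in bulk matrix: {sorted(dupes)}")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise FormatError("non-finite values in bulk matrix")
    return df


def write_bulk(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Survival


def map_stage(stage) -> str | None:
    """Collapse substage labels (IA, IIIB, ...) to I/II/III/IV; None if missing."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return None
    s = str(stage).strip().upper()
    if not s or s in {"NA", "NAN", "UNKNOWN", ""}:
        return None
    for main in _STAGE_ORDER:
        if s.startswith(main):
            return main
    raise FormatError(f"unrecognized stage label: {stage!r}")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a per-sample survival table with columns sample, time, event[, stage]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise FormatError(f"survival table missing columns: {sorted(missing)}")
    return validate_survival(df)


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["time"] = pd.to_numeric(df["time"])
    bad = df.loc[df["time"] <= 0, "sample"].tolist()
    if bad:
        raise FormatError(f"non-positive survival time for samples: {bad}")
    df["event"] = pd.to_numeric(df["event"])
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "sample"].tolist()
        raise FormatError(f"event not in {{0,1}} for samples: {bad}")
    df["event"] = df["event"].astype(int)
    if "stage" in df.columns:
        df["stage"] = df["stage"].map(map_stage)
    else:
        df["stage"] = None
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in survival table")
    return df.set_index("sample", drop=False)


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
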