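"""Expression-matrix containers and I/O.

Datasets are cells × genes matrices with per-cell barcodes, gene
identifiers, an optional categorical label per cell, and a domain tag
(``source`` or ``target``).  Three on-disk formats are supported: AnnData
``.h5ad`` (labels in ``obs``), dense CSV/TSV with a header gene row, and
MatrixMarket ``.mtx`` with ``barcodes.tsv`` / ``features.tsv`` sidecars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "LabelCodec",
    "FormatError",
    "read_dataset",
    "write_dataset",
    "harmonize_genes",
    "normalize",
]

#: fixed per-cell total used by the log-normalization contract
TARGET_TOTAL = 10_000.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the requested format."""


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix with identifiers and optional labels.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_genes)`` float array.  Sparse input is
        densified on construction.
    gene_ids, cell_ids
        Ordered gene identifiers (columns) and cell barcodes (rows).
    labels
        Optional per-cell cell-type labels; must be non-empty strings.
    domain_tag
        ``"source"`` (labelled reference) or ``"target"`` (query).
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    domain_tag: str = "source"

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense())
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {self.matrix.shape}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, m = self.matrix.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{n} matrix rows but {len(self.cell_ids)} cell_ids")
        if m != len(self.gene_ids):
            raise ValueError(f"{m} matrix columns but {len(self.gene_ids)} gene_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError(
                    f"{len(self.labels)} labels but {n} cells"
                )
            if any(l == "" for l in self.labels):
                raise ValueError("labels must be non-empty strings")
        if self.domain_tag not in ("source", "target"):
            raise ValueError(f"domain_tag must be source/target, got {self.domain_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            domain_tag=self.domain_tag,
        )


@dataclass(frozen=True)
class LabelCodec:
    """Bijection between class names and integer indices in ``[0, p)``."""

    classes: tuple[str, ...]
    _index: dict = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.classes)})

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "LabelCodec":
        return cls(tuple(sorted(set(map(str, labels)))))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(l)] for l in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"label {e} not in codec classes {self.classes}") from None

    def decode(self, idx: Sequence[int]) -> list[str]:
        return [self.classes[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# readers / writers


def _read_h5ad(path: Path, labels_key: str | None) -> ExpressionDataset:
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as e:
        raise FormatError(f"cannot parse {path} as h5ad: {e}") from e
    labels = None
    if labels_key is not None:
        if labels_key not in adata.obs.columns:
            raise KeyError(
                f"labels_key {labels_key!r} not found in obs columns "
                f"{list(adata.obs.columns)}"
            )
        labels = [str(l) for l in adata.obs[labels_key]]
    X = adata.X
    return ExpressionDataset(
        matrix=X,
        gene_ids=list(map(str, adata.var_names)),
        cell_ids=list(map(str, adata.obs_names)),
        labels=labels,
    )


def _read_csv(path: Path, labels_key: str | None) -> ExpressionDataset:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as e:
        raise FormatError(f"cannot parse {path} as delimited text: {e}") from e
    labels = None
    if labels_key is not None:
        if labels_key not in df.columns:
            raise KeyError(f"labels_key {labels_key!r} not a column of {path}")
        labels = [str(l) for l in df[labels_key]]
        df = df.drop(columns=[labels_key])
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise FormatError(f"non-numeric expression values in {path}: {e}") from e
    return ExpressionDataset(
        matrix=mat,
        gene_ids=list(map(str, df.columns)),
        cell_ids=list(map(str, df.index)),
        labels=labels,
    )


def _read_mtx(path: Path, labels_key: str | None) -> ExpressionDataset:
    folder = path if path.is_dir() else path.parent
    mtx_path = path if path.suffix == ".mtx" else folder / "matrix.mtx"
    barcodes = folder / "barcodes.tsv"
    features = folder / "features.tsv"
    for p in (mtx_path, barcodes, features):
        if not p.exists():
            raise FormatError(f"missing mtx sidecar or matrix file: {p}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as e:
        raise FormatError(f"cannot parse {mtx_path} as MatrixMarket: {e}") from e
    cell_ids = [l.split("\t")[0] for l in barcodes.read_text().splitlines() if l]
    gene_ids = [l.split("\t")[0] for l in features.read_text().splitlines() if l]
    labels = None
    if labels_key is not None:
        lab_path = folder / labels_key
        if not lab_path.exists():
            raise KeyError(
                f"labels_key for mtx must name a sidecar TSV; {lab_path} missing"
            )
        labels = [l for l in lab_path.read_text().splitlines() if l]
    return ExpressionDataset(
        matrix=mat, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels
    )


def read_dataset(
    path: str | Path,
    format: str | None = None,
    labels_key: str | None = None,
    domain_tag: str = "source",
) -> ExpressionDataset:
    """Read an expression dataset from ``h5ad``, ``csv``/``tsv`` or ``mtx``.

    ``format`` is inferred from the file suffix when omitted.  For ``mtx``
    the ``barcodes.tsv`` and ``features.tsv`` sidecars must sit next to the
    matrix file; ``labels_key`` then names an optional labels sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".h5ad": "h5ad", ".csv": "csv", ".tsv": "csv", ".mtx": "mtx"}.get(
            suffix, "mtx" if path.is_dir() else None
        )
        if format is None:
            raise FormatError(f"cannot infer format from {path}")
    readers = {"h5ad": _read_h5ad, "csv": _read_csv, "mtx": _read_mtx}
    if format not in readers:
        raise ValueError(f"format must be one of {sorted(readers)}, got {format!r}")
    ds = readers[format](path, labels_key)
    return replace(ds, domain_tag=domain_tag)


def write_dataset(ds: ExpressionDataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset in the named format; the inverse of :func:`read_dataset`."""
    path = Path(path)
    if format is None:
        format = {".h5ad": "h5ad", ".csv": "csv", ".tsv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from {path}")
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
        if ds.labels is not None:
            obs["cell_type"] = ds.labels
        adata = ad.AnnData(
            X=ds.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids)
        if ds.labels is not None:
            df.insert(0, "cell_type", ds.labels)
        df.to_csv(path, sep=sep)
    elif format == "mtx":
        folder = path if path.suffix != ".mtx" else path.parent
        folder.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(folder / "matrix.mtx"), sp.coo_matrix(ds.matrix))
        (folder / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
        (folder / "features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
        if ds.labels is not None:
            (folder / "labels.tsv").write_text("\n".join(ds.labels) + "\n")
        return folder
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# gene-space harmonization and normalization


def _dedupe(gene_ids: list[str]) -> tuple[list[str], np.ndarray]:
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, g in enumerate(gene_ids):
        if g not in seen:
            seen[g] = i
            keep.append(i)
    if len(keep) != len(gene_ids):
        warnings.warn(
            f"collapsed {len(gene_ids) - len(keep)} duplicated gene ids to first occurrence"
        )
    return [gene_ids[i] for i in keep], np.array(keep, dtype=int)


def harmonize_genes(
    source: ExpressionDataset, target: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared genes, in source order.

    Duplicated gene ids are collapsed to the first occurrence.  Raises if
    the two vocabularies are disjoint.
    """
    if not source.gene_ids or not target.gene_ids:
        raise ValueError("both datasets need non-empty gene_ids")
    s_genes, s_keep = _dedupe(source.gene_ids)
    t_genes, t_keep = _dedupe(target.gene_ids)
    t_pos = {g: j for j, g in enumerate(t_genes)}
    shared = [g for g in s_genes if g in t_pos]
    if not shared:
        raise ValueError("no shared genes between source and target")
    s_pos = {g: j for j, g in enumerate(s_genes)}
    s_cols = s_keep[[s_pos[g] for g in shared]]
    t_cols = t_keep[[t_pos[g] for g in shared]]
    out_s = ExpressionDataset(
        matrix=source.matrix[:, s_cols],
        gene_ids=shared,
        cell_ids=list(source.cell_ids),
        labels=None if source.labels is None else list(source.labels),
        domain_tag=source.domain_tag,
    )
    out_t = ExpressionDataset(
        matrix=target.matrix[:, t_cols],
        gene_ids=shared,
        cell_ids=list(target.cell_ids),
        labels=None if target.labels is None else list(target.labels),
        domain_tag=target.domain_tag,
    )
    return out_s, out_t


def normalize(ds: ExpressionDataset, mode: str = "lognorm") -> ExpressionDataset:
    """Apply the normalization contract.

    ``lognorm`` scales every cell to a fixed total of 10,000 and applies
    ``log1p`` (the dominant scanpy convention); ``none`` returns the input
    unchanged.  Cells with zero total are left all-zero with a warning.
    """
    if mode == "none":
        return ds
    if mode != "lognorm":
        raise ValueError(f"mode must be 'none' or 'lognorm', got {mode!r}")
    if np.any(ds.matrix < 0):
        raise ValueError("lognorm expects nonnegative (count-like) values")
    totals = ds.matrix.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total count left all-zero")
    scale = np.where(zero, 0.0, TARGET_TOTAL / np.where(zero, 1.0, totals))
    out = np.log1p(ds.matrix * scale[:, None])
    return replace(ds, matrix=out)
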