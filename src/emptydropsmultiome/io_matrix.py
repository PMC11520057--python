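"""Reading and writing CellRanger-arc-style raw feature-barcode matrices.

A 10x multiome run produces one unfiltered matrix over *all* droplet barcodes
with gene-expression features and ATAC peak regions interleaved on the row
axis; the third column of ``features.tsv`` tags the modality of each row.
This module splits that layout into the paired per-modality container
:class:`MultiomeCounts` (genes x barcodes and regions x barcodes, sharing one
barcode axis) and writes it back out bit-identically.

Only the plain-text Matrix Market / TSV layout is supported (optionally
gzipped); HDF5 and fragment files are out of scope.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import ValidationError

#: Default feature-type tags written by CellRanger-arc.
GEX_TAG = "Gene Expression"
ATAC_TAG = "Peaks"

_MATRIX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz")


@dataclass
class MultiomeCounts:
    """Paired sparse count matrices over a shared, ordered barcode axis.

    Parameters
    ----------
    rna_counts : scipy.sparse matrix, genes x barcodes
    atac_counts : scipy.sparse matrix, regions x barcodes
    barcodes : array of unique barcode strings (column axis of both matrices)
    gene_ids, region_ids : unique feature identifiers per modality
    gene_names, region_names : optional display names (default: the ids)
    """

    rna_counts: sp.csc_matrix
    atac_counts: sp.csc_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    region_ids: np.ndarray
    gene_names: np.ndarray | None = None
    region_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rna_counts = sp.csc_matrix(self.rna_counts)
        self.atac_counts = sp.csc_matrix(self.atac_counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.region_ids = np.asarray(self.region_ids, dtype=object)
        if self.gene_names is None:
            self.gene_names = self.gene_ids.copy()
        if self.region_names is None:
            self.region_names = self.region_ids.copy()
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.region_names = np.asarray(self.region_names, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_bc = len(self.barcodes)
        if self.rna_counts.shape != (len(self.gene_ids), n_bc):
            raise ValidationError(
                f"rna_counts shape {self.rna_counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {n_bc} barcodes"
            )
        if self.atac_counts.shape != (len(self.region_ids), n_bc):
            raise ValidationError(
                f"atac_counts shape {self.atac_counts.shape} does not match "
                f"{len(self.region_ids)} regions x {n_bc} barcodes"
            )
        if len(set(self.barcodes)) != n_bc:
            raise ValidationError("duplicate barcode strings are not allowed")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region_ids must be unique")
        for name, mat in (("rna_counts", self.rna_counts), ("atac_counts", self.atac_counts)):
            _check_count_matrix(mat, name)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def subset_barcodes(self, index: np.ndarray) -> "MultiomeCounts":
        """Column subset (or reorder) by integer index, preserving features."""
        index = np.asarray(index)
        return MultiomeCounts(
            rna_counts=self.rna_counts[:, index],
            atac_counts=self.atac_counts[:, index],
            barcodes=self.barcodes[index],
            gene_ids=self.gene_ids,
            region_ids=self.region_ids,
            gene_names=self.gene_names,
            region_names=self.region_names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiomeCounts):
            return NotImplemented
        return (
            np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.region_ids, other.region_ids)
            and (self.rna_counts != other.rna_counts).nnz == 0
            and (self.atac_counts != other.atac_counts).nnz == 0
        )


def _check_count_matrix(mat: sp.spmatrix, name: str) -> None:
    data = mat.data
    if data.size == 0:
        return
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValidationError(f"{name} contains non-integer entries")
    if data.min() < 0:
        raise ValidationError(f"{name} contains negative entries")


def _find_file(path: str, candidates: tuple[str, ...]) -> str:
    for name in candidates:
        full = os.path.join(path, name)
        if os.path.exists(full):
            return full
    raise FileNotFoundError(
        f"none of {candidates} found in directory {path!r}"
    )


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_mtx_integer(path: str) -> sp.csc_matrix:
    """Read a coordinate MTX file, insisting on an integer field."""
    with _open_text(path) as fh:
        header = fh.readline()
    tokens = header.strip().lower().split()
    if len(tokens) < 4 or tokens[0] != "%%matrixmarket":
        raise ValidationError(f"{path!r} is not a Matrix Market file")
    if "integer" not in tokens:
        # scipy labels an empty matrix "real" regardless of dtype; accept
        # that sole case, otherwise insist on an integer count matrix.
        with _open_text(path) as fh:
            nnz = None
            for line in fh:
                if line.startswith("%"):
                    continue
                dims = line.split()
                if len(dims) >= 3:
                    nnz = int(dims[2])
                break
        if nnz != 0:
            raise ValidationError(
                f"{path!r} has MTX field {tokens[3]!r}; count matrices must be integer"
            )
    with _open_text(path) as fh:
        mat = mmread(fh)
    mat = sp.csc_matrix(mat)
    mat.data = mat.data.astype(np.int64, copy=False)
    return mat


def read_multiome_dir(
    path: str, gex_tag: str = GEX_TAG, atac_tag: str = ATAC_TAG
) -> MultiomeCounts:
    """Read a CellRanger-arc-style raw matrix directory.

    The directory must contain ``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]`` and
    ``features.tsv[.gz]``; the features file needs at least three columns
    (id, name, feature type).  Rows are partitioned by feature type into the
    two modalities, preserving the on-disk order within each modality; the
    barcode order is preserved as-is.  MTX indices are 1-based on disk and
    converted to 0-based in memory (handled by the Matrix Market reader).
    """
    mtx_path = _find_file(path, _MATRIX_NAMES)
    bc_path = _find_file(path, _BARCODE_NAMES)
    feat_path = _find_file(path, _FEATURE_NAMES)

    matrix = _read_mtx_integer(mtx_path)

    with _open_text(bc_path) as fh:
        barcodes = np.array([line.rstrip("\n") for line in fh if line.strip()], dtype=object)

    ids, names, types = [], [], []
    with _open_text(feat_path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValidationError(
                    f"features file line {i + 1} has {len(cols)} column(s); "
                    "expected at least 3 (id, name, type)"
                )
            ids.append(cols[0])
            names.append(cols[1])
            types.append(cols[2])
    types_arr = np.array(types, dtype=object)

    unknown = sorted(set(types_arr) - {gex_tag, atac_tag})
    if unknown:
        raise ValidationError(
            f"unknown feature-type value(s) {unknown}; expected "
            f"{gex_tag!r} or {atac_tag!r}"
        )
    if matrix.shape != (len(ids), len(barcodes)):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match {len(ids)} features "
            f"x {len(barcodes)} barcodes"
        )

    gex_rows = np.flatnonzero(types_arr == gex_tag)
    atac_rows = np.flatnonzero(types_arr == atac_tag)
    ids_arr = np.array(ids, dtype=object)
    names_arr = np.array(names, dtype=object)
    return MultiomeCounts(
        rna_counts=matrix[gex_rows, :],
        atac_counts=matrix[atac_rows, :],
        barcodes=barcodes,
        gene_ids=ids_arr[gex_rows],
        region_ids=ids_arr[atac_rows],
        gene_names=names_arr[gex_rows],
        region_names=names_arr[atac_rows],
    )


def write_multiome_dir(
    mc: MultiomeCounts,
    path: str,
    gex_tag: str = GEX_TAG,
    atac_tag: str = ATAC_TAG,
    compress: bool = True,
) -> None:
    """Write the three-file raw-matrix layout readable by :func:`read_multiome_dir`.

    RNA features are written first, then ATAC features; barcodes keep their
    order. Files are gzipped when ``compress`` is true. All-zero barcodes are
    written like any other column (no silent dropping).
    """
    mc.validate()
    os.makedirs(path, exist_ok=True)
    suffix = ".gz" if compress else ""

    stacked = sp.vstack(
        [sp.coo_matrix(mc.rna_counts), sp.coo_matrix(mc.atac_counts)]
    ).tocoo()
    stacked.data = stacked.data.astype(np.int64, copy=False)

    mtx_path = os.path.join(path, "matrix.mtx" + suffix)
    opener = gzip.open if compress else open
    with opener(mtx_path, "wb") as fh:
        mmwrite(fh, stacked, field="integer", symmetry="general")

    with opener(os.path.join(path, "barcodes.tsv" + suffix), "wt") as fh:
        for bc in mc.barcodes:
            fh.write(f"{bc}\n")

    with opener(os.path.join(path, "features.tsv" + suffix), "wt") as fh:
        for fid, fname in zip(mc.gene_ids, mc.gene_names):
            fh.write(f"{fid}\t{fname}\t{gex_tag}\n")
        for fid, fname in zip(mc.region_ids, mc.region_names):
            fh.write(f"{fid}\t{fname}\t{atac_tag}\n")


def library_sizes(mc: MultiomeCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-barcode total counts ``(t_A, t_R)`` (ATAC first, then RNA)."""
    t_a = np.asarray(mc.atac_counts.sum(axis=0)).ravel().astype(np.int64)
    t_r = np.asarray(mc.rna_counts.sum(axis=0)).ravel().astype(np.int64)
    return t_a, t_r
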