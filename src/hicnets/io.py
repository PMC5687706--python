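"""Readers, writers and balancing for binned Hi-C contact matrices and interval lists.

Coordinate convention: 0-based, half-open (BED) throughout the package.
Domain lists are BED3; subcompartment annotations are BED4 with the label
(A1, A2, B1, B2, B3 or B4) in column 4.  Contact matrices are either sparse
triples ``bin_i<TAB>bin_j<TAB>value`` or dense whitespace-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

SUBCOMPARTMENTS = ("A1", "A2", "B1", "B2", "B3", "B4")

#: default chromosome universe: autosomes plus X (Y and MT excluded)
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


class ParseError(ValueError):
    """A malformed line in a text input; carries the offending line number."""


class BalanceError(RuntimeError):
    """Matrix balancing failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Containment (not necessarily strict) of *other* in *self*."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlapped base pairs with *other* (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ContactMatrix:
    """Binned contact intensities for one chromosome (cis) or one pair (trans).

    ``values`` is a CSR sparse matrix of nonnegative intensities; row bins
    belong to ``chrom_row`` and column bins to ``chrom_col``.  Cis matrices
    (``chrom_row == chrom_col``) are symmetric.
    """

    chrom_row: str
    chrom_col: str
    bin_size: int
    values: sp.csr_matrix
    normalized: bool = False
    excluded_bins: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("contact matrix holds negative intensities")
        if self.is_cis:
            if self.values.shape[0] != self.values.shape[1]:
                raise ValueError("cis contact matrix must be square")
            asym = abs(self.values - self.values.T)
            if asym.nnz and asym.max() > 1e-6 * max(1.0, abs(self.values).max()):
                raise ValueError("cis contact matrix is not symmetric")

    @property
    def is_cis(self) -> bool:
        return self.chrom_row == self.chrom_col

    @property
    def shape(self):
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


# ---------------------------------------------------------------------------
# interval I/O


def read_domains(path) -> list[GenomicInterval]:
    """Read a BED3(+) domain list; returns intervals sorted by (chrom, start, end)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not intervals:
        logger.warning("%s: empty domain list", path)
    return sorted(intervals)


def write_domains(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_subcompartments(path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED4 subcompartment annotation: (interval, label) pairs, sorted.

    Lines whose label is '.' or 'NA' are skipped (unannotated gaps).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns (BED4)")
            label = fields[3]
            if label in (".", "NA", "N.A."):
                continue
            if label not in SUBCOMPARTMENTS:
                raise ParseError(
                    f"{path}: line {lineno}: unknown subcompartment label {label!r}"
                )
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            out.append((iv, label))
    return sorted(out, key=lambda t: t[0])


def write_subcompartments(annotation, path) -> None:
    with open(path, "w") as fh:
        for iv, label in annotation:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# matrix I/O


def read_contact_matrix(
    path,
    bin_size: int,
    chrom_row: str,
    chrom_col: str | None = None,
    fmt: str = "sparse",
    n_bins: int | None = None,
    normalized: bool = False,
) -> ContactMatrix:
    """Read a contact matrix from text.

    ``fmt='sparse'``: triples ``bin_i<TAB>bin_j<TAB>value``; for cis input an
    upper-triangle-only file is mirrored to a full symmetric matrix.
    ``fmt='dense'``: a whitespace-separated rectangular matrix.
    """
    chrom_col = chrom_col or chrom_row
    cis = chrom_row == chrom_col
    if fmt == "dense":
        values = np.loadtxt(path, ndmin=2)
        if values.size and values.min() < 0:
            raise ParseError(f"{path}: negative intensity in dense matrix")
        if cis:
            if values.shape[0] != values.shape[1]:
                raise ParseError(f"{path}: dense cis matrix is not square")
            if values.size and np.abs(values - values.T).max() > 1e-6:
                raise ParseError(f"{path}: dense cis matrix asymmetric beyond 1e-6")
            values = 0.5 * (values + values.T)
        mat = sp.csr_matrix(values)
    elif fmt == "sparse":
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 3:
                    raise ParseError(f"{path}: line {lineno}: expected 3 columns")
                try:
                    i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: unparseable triple") from exc
                if i < 0 or j < 0:
                    raise ParseError(f"{path}: line {lineno}: negative bin index")
                if v < 0:
                    raise ParseError(f"{path}: line {lineno}: negative intensity {v}")
                rows.append(i)
                cols.append(j)
                vals.append(v)
        nr = nc = n_bins
        if nr is None:
            nr = max(rows, default=-1) + 1
            nc = max(cols, default=-1) + 1
            if cis:
                nr = nc = max(nr, nc)
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(nr, nc))
        if cis:
            upper = sp.triu(mat)
            if (abs(mat - mat.T)).nnz == 0:
                pass  # already symmetric
            elif (mat - upper).nnz == 0:
                mat = upper + sp.triu(upper, k=1).T  # mirror upper triangle
            else:
                diff = abs(mat - mat.T)
                if diff.max() > 1e-6:
                    raise ParseError(f"{path}: inconsistent (i,j)/(j,i) cis triples")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return ContactMatrix(chrom_row, chrom_col, bin_size, mat, normalized=normalized)


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Write sparse triples; for cis matrices only the upper triangle is stored."""
    coo = (sp.triu(matrix.values) if matrix.is_cis else matrix.values).tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# balancing


def kr_balance(
    matrix: ContactMatrix, tol: float = 1e-10, max_iter: int = 3000
) -> ContactMatrix:
    """Balance a raw cis matrix to equal row sums (Knight–Ruiz fixed point).

    Finds a positive diagonal scaling ``D`` such that every non-excluded row of
    ``D M D`` sums to 1, using the symmetric Sinkhorn-type iteration
    ``d <- d / sqrt(rowsum(D M D))``.  All-zero rows are excluded from the
    balancing and zeroed in the output; their indices are recorded in
    ``excluded_bins``.
    """
    if not matrix.is_cis:
        raise ValueError("balancing requires a square cis matrix")
    M = matrix.values.toarray()
    n = M.shape[0]
    rowsum = M.sum(axis=1)
    keep = rowsum > 0
    excluded = tuple(int(i) for i in np.flatnonzero(~keep))
    A = M[np.ix_(keep, keep)]
    if A.size == 0:
        raise BalanceError("all rows empty; nothing to balance", residual=np.inf)
    d = 1.0 / np.sqrt(A.sum(axis=1))
    residual = np.inf
    for _ in range(max_iter):
        rs = (d[:, None] * A * d[None, :]).sum(axis=1)
        residual = float(np.max(np.abs(rs - 1.0)))
        if residual <= tol:
            break
        d /= np.sqrt(rs)
    else:
        raise BalanceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} > tol {tol:.3g})",
            residual=residual,
        )
    B = np.zeros_like(M)
    B[np.ix_(keep, keep)] = d[:, None] * A * d[None, :]
    return replace(
        matrix, values=sp.csr_matrix(B), normalized=True, excluded_bins=excluded
    )
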