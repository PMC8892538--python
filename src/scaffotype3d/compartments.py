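"""A/B compartment eigenvectors from Hi-C contact matrices.

Pipeline per chromosome-scale scaffold, at a fixed bin size (default
500 kb):

1. load raw contacts (sparse triplet TSV or a cooler-dialect HDF5
   container) into a symmetric per-scaffold matrix;
2. mask low-coverage bins (marginal below the 5th percentile of nonzero
   marginals);
3. balance the matrix to equal row sums (the Knight-Ruiz fixed point,
   reached here by Sinkhorn iteration);
4. divide by the expected contact frequency at each genomic distance
   (observed/expected);
5. Pearson-correlate the O/E rows;
6. take principal component 1 of the correlation matrix as the compartment
   profile; the sign convention (A = positive) is fixed afterwards by
   anchoring against a reference profile, or by making the first valid bin
   non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg

__all__ = [
    "BinTable",
    "ContactMatrix",
    "EigenProfile",
    "CompartmentError",
    "load_contacts",
    "write_contacts",
    "kr_balance",
    "observed_expected",
    "pearson_correlation",
    "leading_eigenvector",
    "orient_sign",
    "compartment_profile",
    "write_bedgraph",
]

DEFAULT_BIN_SIZE = 500_000
COVERAGE_PERCENTILE = 5.0


class CompartmentError(ValueError):
    """Raised for invalid contact data or degenerate matrices."""


@dataclass
class BinTable:
    """Ordered fixed-size bins tiling one scaffold; last bin may be short."""

    scaffold: str
    scaffold_length: int
    bin_size: int = DEFAULT_BIN_SIZE
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scaffold_length <= 0:
            raise CompartmentError("scaffold length must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.n_bins, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.valid_mask) != self.n_bins:
            raise CompartmentError("valid_mask length must equal bin count")

    @property
    def n_bins(self) -> int:
        return -(-self.scaffold_length // self.bin_size)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        return i * self.bin_size, min((i + 1) * self.bin_size, self.scaffold_length)


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact counts over the bins of one scaffold."""

    bin_table: BinTable
    counts: np.ndarray
    balanced: bool = False
    scaling: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.bin_table.n_bins
        if self.counts.shape != (n, n):
            raise CompartmentError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if not np.allclose(self.counts, self.counts.T):
            raise CompartmentError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise CompartmentError("contact matrix must be non-negative")


@dataclass
class EigenProfile:
    """Signed per-bin compartment eigenvector for one scaffold.

    ``values`` has one entry per bin; masked bins carry NaN.  The vector has
    unit Euclidean norm over valid bins, and ``explained_fraction`` is the
    leading eigenvalue's share of the total absolute spectrum.
    """

    bin_table: BinTable
    values: np.ndarray
    sign_anchor: Literal["reference-correlation", "first-bin-positive", "none"] = "none"
    explained_fraction: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.bin_table.n_bins:
            raise CompartmentError("profile length must equal bin count")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


# ---------------------------------------------------------------------------
# Loading


def load_contacts(
    path: str | Path,
    format: Literal["triplet_tsv", "hdf5_container"] = "triplet_tsv",
    bin_size: int = DEFAULT_BIN_SIZE,
    scaffold: str | None = None,
    scaffold_length: int | None = None,
    coverage_percentile: float = COVERAGE_PERCENTILE,
) -> ContactMatrix:
    """Load a per-scaffold contact matrix.

    ``triplet_tsv`` holds one upper-triangle entry per line as
    ``bin_i<TAB>bin_j<TAB>count``; the matrix is mirrored on load.
    ``hdf5_container`` follows the cooler dialect (``bins/`` and ``pixels/``
    groups); ``scaffold`` selects the intra-scaffold submatrix.
    """
    if format == "triplet_tsv":
        if scaffold is None or scaffold_length is None:
            raise CompartmentError("triplet_tsv loading requires scaffold and scaffold_length")
        table = BinTable(scaffold, scaffold_length, bin_size)
        mat = _load_triplets(Path(path), table.n_bins)
    elif format == "hdf5_container":
        table, mat = _load_hdf5(Path(path), scaffold, bin_size)
    else:
        raise CompartmentError(f"unknown contact format {format!r}")
    _apply_coverage_mask(table, mat, coverage_percentile)
    return ContactMatrix(bin_table=table, counts=mat)


def _load_triplets(path: Path, n_bins: int) -> np.ndarray:
    mat = np.zeros((n_bins, n_bins))
    seen_mirror = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise CompartmentError(f"{path}:{lineno}: expected 'bin_i bin_j count'")
        i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise CompartmentError(
                f"{path}:{lineno}: bin index ({i},{j}) out of range for {n_bins} bins"
            )
        if i > j:
            i, j = j, i
            seen_mirror = True
        mat[i, j] += c
    if seen_mirror:
        warnings.warn("lower-triangle triplets present; summed into upper triangle")
    upper = np.triu(mat, 1)
    return mat - upper + upper.T + upper  # mirror upper triangle, keep diagonal


def _load_hdf5(path: Path, scaffold: str | None, bin_size: int) -> tuple[BinTable, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as f:
        chroms = [c.decode() if isinstance(c, bytes) else str(c) for c in f["bins/chrom"][:]]
        starts = f["bins/start"][:]
        ends = f["bins/end"][:]
        if scaffold is None:
            uniq = sorted(set(chroms))
            if len(uniq) != 1:
                raise CompartmentError(
                    f"container holds {len(uniq)} scaffolds; pass scaffold="
                )
            scaffold = uniq[0]
        idx = np.array([i for i, c in enumerate(chroms) if c == scaffold])
        if idx.size == 0:
            raise CompartmentError(f"scaffold {scaffold!r} not in container")
        length = int(ends[idx].max())
        table = BinTable(scaffold, length, bin_size)
        if len(idx) != table.n_bins or int(starts[idx[0]]) != 0:
            raise CompartmentError("container bin table inconsistent with bin size")
        offset = idx[0]
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        counts = f["pixels/count"][:]
        mat = np.zeros((table.n_bins, table.n_bins))
        sel = np.isin(b1, idx) & np.isin(b2, idx)
        for i, j, c in zip(b1[sel] - offset, b2[sel] - offset, counts[sel]):
            i, j = (j, i) if i > j else (i, j)
            mat[i, j] += c
        upper = np.triu(mat, 1)
        return table, mat - upper + upper.T + upper


def write_contacts(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle as triplet TSV (nonzero entries only)."""
    lines = ["#bin_i\tbin_j\tcount"]
    n = matrix.bin_table.n_bins
    for i in range(n):
        for j in range(i, n):
            c = matrix.counts[i, j]
            if c != 0:
                lines.append(f"{i}\t{j}\t{c:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _apply_coverage_mask(table: BinTable, mat: np.ndarray, percentile: float) -> None:
    marginals = mat.sum(axis=0)
    nonzero = marginals[marginals > 0]
    if nonzero.size == 0:
        table.valid_mask = np.zeros_like(table.valid_mask)
        return
    threshold = np.percentile(nonzero, percentile)
    table.valid_mask = table.valid_mask & (marginals >= threshold) & (marginals > 0)


# ---------------------------------------------------------------------------
# Balancing and normalisation


def kr_balance(
    matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000
) -> ContactMatrix:
    """Balance to the Knight-Ruiz fixed point by Sinkhorn iteration.

    Returns M' = D M D over valid bins such that every valid row of M' sums
    to the same constant (the mean row sum), to relative tolerance ``tol``.
    Bins whose rows cannot be balanced (all-zero) are masked out.
    """
    table = matrix.bin_table
    mask = table.valid_mask.copy()
    mask &= matrix.counts.sum(axis=0) > 0
    sub = matrix.counts[np.ix_(mask, mask)]
    n = sub.shape[0]
    d = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = (d[:, None] * sub * d[None, :]).sum(axis=1)
        if (s == 0).any():
            break
        target = s.mean()
        if np.abs(s / target - 1.0).max() < tol:
            converged = True
            break
        d *= np.sqrt(target / s)
    if not converged:
        warnings.warn("KR balancing did not converge; unbalanced bins masked")
        s = (d[:, None] * sub * d[None, :]).sum(axis=1)
        bad = np.abs(s / s.mean() - 1.0) >= 10 * tol
        keep_idx = np.flatnonzero(mask)
        mask[keep_idx[bad]] = False
        sub = matrix.counts[np.ix_(mask, mask)]
        d = np.delete(d, np.flatnonzero(bad))

    balanced = np.full_like(matrix.counts, np.nan)
    scaling = np.full(table.n_bins, np.nan)
    balanced[np.ix_(mask, mask)] = d[:, None] * sub * d[None, :]
    scaling[mask] = d
    new_table = BinTable(table.scaffold, table.scaffold_length, table.bin_size, mask)
    out = ContactMatrix.__new__(ContactMatrix)
    out.bin_table = new_table
    out.counts = balanced
    out.balanced = True
    out.scaling = scaling
    return out


def observed_expected(matrix: ContactMatrix) -> np.ndarray:
    """Divide each entry by the mean valid entry at its genomic distance."""
    mask = matrix.bin_table.valid_mask
    n = matrix.bin_table.n_bins
    oe = np.full((n, n), np.nan)
    idx = np.flatnonzero(mask)
    sub = matrix.counts[np.ix_(idx, idx)]
    m = len(idx)
    dist = np.abs(idx[:, None] - idx[None, :])
    oe_sub = np.full((m, m), np.nan)
    for s in np.unique(dist):
        sel = dist == s
        vals = sub[sel]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        mean = vals[finite].mean()
        if mean > 0:
            oe_sub[sel] = sub[sel] / mean
    oe[np.ix_(idx, idx)] = oe_sub
    return oe


def pearson_correlation(oe: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between valid O/E rows.

    Rows with zero variance are masked (NaN).  Requires at least 3 valid
    bins.
    """
    n = oe.shape[0]
    if mask is None:
        mask = np.isfinite(oe).any(axis=0)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise CompartmentError("scaffold too short for compartment analysis")
    sub = oe[np.ix_(idx, idx)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr_sub = np.corrcoef(sub)
    corr = np.full((n, n), np.nan)
    corr[np.ix_(idx, idx)] = corr_sub
    return corr


def leading_eigenvector(
    corr: np.ndarray, bin_table: BinTable | None = None
) -> EigenProfile:
    """PC1 of the correlation matrix as a unit-norm compartment profile.

    The correlation matrix is double-centered (row and column means removed,
    grand mean restored), which keeps it symmetric; the eigenvector of the
    algebraically largest eigenvalue is the compartment profile, and
    ``explained_fraction`` is that eigenvalue over the sum of absolute
    eigenvalues.  Deterministic up to overall sign.
    """
    n = corr.shape[0]
    mask = np.isfinite(corr).any(axis=0) & np.isfinite(np.diagonal(corr))
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise CompartmentError("scaffold too short for compartment analysis")
    sub = corr[np.ix_(idx, idx)]
    if not np.isfinite(sub).all():
        raise CompartmentError("correlation matrix has NaN entries among valid bins")
    row_means = sub.mean(axis=1, keepdims=True)
    centered = sub - row_means - row_means.T + sub.mean()
    if np.abs(centered).max() < 1e-12:
        raise CompartmentError("degenerate (constant) correlation matrix")
    eigvals, eigvecs = scipy.linalg.eigh(centered)
    lead = eigvecs[:, -1]
    lead = lead / np.linalg.norm(lead)
    explained = float(eigvals[-1] / np.abs(eigvals).sum())
    values = np.full(n, np.nan)
    values[idx] = lead
    if bin_table is None:
        bin_table = BinTable("unknown", n, 1, mask)
    else:
        bin_table = BinTable(
            bin_table.scaffold, bin_table.scaffold_length, bin_table.bin_size, mask
        )
    return EigenProfile(bin_table=bin_table, values=values, explained_fraction=explained)


def orient_sign(
    profile: EigenProfile, anchor_profile: EigenProfile | None = None
) -> EigenProfile:
    """Fix the arbitrary eigenvector sign.

    With an anchor (a reference-species profile over the same coordinates),
    the sign making the Pearson correlation with the anchor non-negative is
    chosen; with no anchor (or zero overlap / exactly-zero correlation), the
    first valid bin is made non-negative.
    """
    values = profile.values.copy()
    anchor_used: Literal["reference-correlation", "first-bin-positive"] = "first-bin-positive"
    flip = False
    if anchor_profile is not None:
        both = profile.valid & anchor_profile.valid
        if both.sum() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = np.corrcoef(values[both], anchor_profile.values[both])[0, 1]
            if np.isfinite(r) and r != 0:
                flip = r < 0
                anchor_used = "reference-correlation"
        if anchor_used != "reference-correlation":
            warnings.warn("no usable overlap with anchor; using first-bin rule")
    if anchor_used == "first-bin-positive":
        valid = np.flatnonzero(profile.valid)
        if valid.size:
            flip = values[valid[0]] < 0
    if flip:
        values = -values
    return EigenProfile(
        bin_table=profile.bin_table,
        values=values,
        sign_anchor=anchor_used,
        explained_fraction=profile.explained_fraction,
    )


def compartment_profile(
    matrix: ContactMatrix,
    anchor_profile: EigenProfile | None = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
) -> EigenProfile:
    """Full pipeline: balance, O/E, correlate, PC1, orient sign."""
    balanced = kr_balance(matrix, tol=tol, max_iter=max_iter)
    oe = observed_expected(balanced)
    corr = pearson_correlation(oe, balanced.bin_table.valid_mask)
    profile = leading_eigenvector(corr, balanced.bin_table)
    return orient_sign(profile, anchor_profile)


def read_bedgraph(
    path: str | Path,
    bin_size: int = DEFAULT_BIN_SIZE,
    scaffold_length: int | None = None,
) -> EigenProfile:
    """Read a single-scaffold bedGraph back into a profile (NaN where absent)."""
    rows: list[tuple[str, int, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise CompartmentError(f"{path}:{lineno}: expected 4 bedGraph columns")
        rows.append((parts[0], int(parts[1]), float(parts[3])))
    if not rows:
        raise CompartmentError(f"{path}: empty bedGraph")
    scaffolds = {r[0] for r in rows}
    if len(scaffolds) != 1:
        raise CompartmentError(f"{path}: expected one scaffold, found {sorted(scaffolds)}")
    scaffold = rows[0][0]
    if scaffold_length is None:
        scaffold_length = max(r[1] for r in rows) + bin_size
    table = BinTable(scaffold, scaffold_length, bin_size)
    values = np.full(table.n_bins, np.nan)
    for _, start, value in rows:
        values[start // bin_size] = value
    table.valid_mask = np.isfinite(values)
    return EigenProfile(bin_table=table, values=values)


def write_bedgraph(profile: EigenProfile, path: str | Path) -> None:
    """Write the profile as bedGraph; masked bins are omitted."""
    lines = []
    for i in np.flatnonzero(profile.valid):
        start, end = profile.bin_table.bin_bounds(int(i))
        lines.append(
            f"{profile.bin_table.scaffold}\t{start}\t{end}\t{profile.values[i]:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
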