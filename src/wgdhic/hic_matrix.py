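"""Binned Hi-C contact matrices: genome binning, sparse I/O, ICE balancing and
distance (observed/expected) normalization.

The on-disk contract is deliberately plain: a 3-column tab-separated COO file
(``bin_i  bin_j  value``, upper triangle only) with a sidecar BED bin table
(``chrom  start  end  bin_id``).  In memory a :class:`ContactMatrix` holds the
full symmetric matrix as ``scipy.sparse.csr_matrix`` together with its bin
table, a normalization state (``raw -> ice -> oe``) and a boolean mask of
excluded low-coverage bins.

ICE (iterative correction) removes multiplicative per-bin coverage biases by
rescaling the matrix until every unmasked row has the same marginal sum; the
balanced matrix equals ``raw(i, j) / (b_i * b_j)`` up to a global scale, and
the per-bin bias vector ``b`` is returned alongside the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, DataError, DegenerateMatrixError

log = logging.getLogger(__name__)

BIN_COLUMNS = ["chrom", "start", "end", "bin_id"]

STATE_RAW = "raw"
STATE_ICE = "ice"
STATE_OE = "oe"
_STATES = (STATE_RAW, STATE_ICE, STATE_OE)


@dataclass(frozen=True)
class BinTable:
    """Genome-wide bin table at a fixed resolution.

    Coordinates are 0-based half-open.  Bins within a chromosome are
    contiguous, sorted and non-overlapping; ``bin_id`` is a consecutive
    genome-wide index.  The last bin of each chromosome may be shorter than
    the resolution.
    """

    table: pd.DataFrame
    resolution: int

    def __post_init__(self):
        df = self.table
        missing = [c for c in BIN_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"bin table missing columns {missing}")
        if len(df) == 0:
            raise DataError("bin table is empty")
        ids = df["bin_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise DataError("bin_id must be consecutive integers from 0")
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        if np.any(ends <= starts):
            raise DataError("bin end must exceed bin start")
        chrom = df["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (starts[1:] != ends[:-1])):
            raise DataError("bins within a chromosome must be contiguous")

    @cached_property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @cached_property
    def _chrom_ranges(self) -> dict[str, tuple[int, int]]:
        out = {}
        chrom = self.table["chrom"].to_numpy()
        for c in self.chroms:
            idx = np.flatnonzero(chrom == c)
            out[c] = (int(idx[0]), int(idx[-1]) + 1)
        return out

    @cached_property
    def chrom_code(self) -> np.ndarray:
        """Integer chromosome code per bin (order of :attr:`chroms`)."""
        lut = {c: i for i, c in enumerate(self.chroms)}
        return np.array([lut[c] for c in self.table["chrom"]], dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._chrom_ranges[chrom]
        return slice(lo, hi)

    def chrom_size(self, chrom: str) -> int:
        sl = self.chrom_slice(chrom)
        return int(self.table["end"].iloc[sl.stop - 1])

    def n_bins_chrom(self, chrom: str) -> int:
        lo, hi = self._chrom_ranges[chrom]
        return hi - lo

    def bin_at(self, chrom: str, pos: int) -> int:
        """Genome-wide bin id containing ``pos`` on ``chrom``."""
        if chrom not in self._chrom_ranges:
            raise DataError(f"unknown chromosome {chrom!r}")
        lo, hi = self._chrom_ranges[chrom]
        if pos < 0 or pos >= self.chrom_size(chrom):
            raise DataError(f"position {chrom}:{pos} outside chromosome")
        return min(lo + pos // self.resolution, hi - 1)

    def lengths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()


def bin_genome(chrom_sizes: dict[str, int], resolution: int) -> BinTable:
    """Tile every chromosome end-to-end with fixed-size bins.

    The last bin of a chromosome is shortened to the chromosome end when the
    size is not an exact multiple of the resolution.
    """
    if not chrom_sizes:
        raise ConfigurationError("chrom_sizes is empty")
    if resolution <= 0:
        raise ConfigurationError(f"resolution must be positive, got {resolution}")
    rows = []
    bid = 0
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ConfigurationError(f"chromosome {chrom!r} has non-positive size {size}")
        for start in range(0, size, resolution):
            rows.append((chrom, start, min(start + resolution, size), bid))
            bid += 1
    df = pd.DataFrame(rows, columns=BIN_COLUMNS)
    return BinTable(df, resolution)


@dataclass
class ContactMatrix:
    """Symmetric binned contact map with a normalization state."""

    bins: BinTable
    matrix: sp.csr_matrix
    state: str = STATE_RAW
    mask: np.ndarray = field(default=None)  # True = excluded bin

    def __post_init__(self):
        n = self.bins.n_bins
        if self.matrix.shape != (n, n):
            raise DataError(
                f"matrix shape {self.matrix.shape} does not match {n} bins"
            )
        if self.state not in _STATES:
            raise ConfigurationError(f"unknown matrix state {self.state!r}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise DataError("contact values must be non-negative")

    def check_symmetric(self, rtol: float = 1e-8) -> None:
        diff = abs(self.matrix - self.matrix.T)
        if diff.nnz:
            scale = max(abs(self.matrix).max(), 1.0)
            if diff.max() > rtol * scale:
                raise DataError("contact matrix is not symmetric")

    def cis_dense(self, chrom: str) -> np.ndarray:
        sl = self.bins.chrom_slice(chrom)
        return self.matrix[sl, sl].toarray()

    def trans_dense(self, chrom_i: str, chrom_j: str) -> np.ndarray:
        si = self.bins.chrom_slice(chrom_i)
        sj = self.bins.chrom_slice(chrom_j)
        return self.matrix[si, sj].toarray()


@dataclass
class DecayProfile:
    """Mean contact value per bin separation, one curve per chromosome."""

    expected: dict[str, np.ndarray]  # chrom -> value indexed by separation d
    include_zeros: bool = True


# ---------------------------------------------------------------------------
# I/O: COO TSV + BED bin table
# ---------------------------------------------------------------------------

def write_bins_bed(bins: BinTable, path) -> None:
    bins.table[BIN_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path, resolution: int | None = None) -> BinTable:
    df = pd.read_csv(path, sep="\t", header=None, names=BIN_COLUMNS, comment="#")
    if resolution is None:
        resolution = int((df["end"] - df["start"]).max())
    return BinTable(df, resolution)


def write_contacts(M: ContactMatrix, path) -> None:
    """Write the upper triangle (including the diagonal) as a 3-column TSV."""
    coo = sp.triu(M.matrix).tocoo()
    data = coo.data
    integral = np.allclose(data, np.round(data))
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, data):
            if integral:
                fh.write(f"{i}\t{j}\t{int(round(v))}\n")
            else:
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_contacts(path, bins: BinTable, state: str = STATE_RAW,
                  mask: np.ndarray | None = None) -> ContactMatrix:
    """Read a COO TSV (upper triangle) and symmetrize."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["bin_i", "bin_j", "value"], comment="#")
    n = bins.n_bins
    i = df["bin_i"].to_numpy(dtype=np.int64)
    j = df["bin_j"].to_numpy(dtype=np.int64)
    v = df["value"].to_numpy(dtype=float)
    if len(i) and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
        raise DataError("contact record references a bin outside the bin table")
    off = i != j
    rows = np.concatenate([i, j[off]])
    cols = np.concatenate([j, i[off]])
    vals = np.concatenate([v, v[off]])
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(bins, mat, state=state, mask=mask)


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_normalize(
    M: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_coverage_frac: float = 0.02,
) -> tuple[ContactMatrix, np.ndarray]:
    """Iteratively correct a raw matrix so unmasked marginals are equal.

    Bins with zero raw marginal, plus the lowest ``low_coverage_frac``
    quantile of the remaining raw marginals, are masked and removed from the
    output entries.  Convergence is declared when the relative variance of
    the unmasked marginals drops below ``tol``.  The corrected matrix is
    rescaled so its total mass equals the unmasked raw total; the returned
    bias vector satisfies ``corrected = raw / (b_i * b_j)`` (``NaN`` at
    masked bins).
    """
    if M.state != STATE_RAW:
        raise DataError(f"ICE requires a raw matrix, got state {M.state!r}")
    if max_iter <= 0 or tol <= 0:
        raise ConfigurationError("max_iter and tol must be positive")
    M.check_symmetric()
    n = M.bins.n_bins
    A = M.matrix.tocsr().astype(float)
    marg = np.asarray(A.sum(axis=1)).ravel()

    mask = M.mask | (marg == 0)
    alive = np.flatnonzero(~mask)
    n_low = int(np.floor(low_coverage_frac * alive.size))
    if n_low > 0:
        order = alive[np.argsort(marg[alive], kind="stable")]
        mask[order[:n_low]] = True
    if mask.all():
        raise DegenerateMatrixError("no unmasked bins left to balance")

    keep = ~mask
    dk = sp.diags(keep.astype(float))
    W = (dk @ A @ dk).tocoo()
    rows, cols, data0 = W.row, W.col, W.data.copy()
    data = data0.copy()
    bias = np.ones(n)

    for _ in range(max_iter):
        s = np.bincount(rows, weights=data, minlength=n)
        su = s[keep]
        mean = su.mean()
        if mean == 0:
            raise DegenerateMatrixError("matrix mass vanished during balancing")
        if su.var() / mean**2 < tol:
            break
        snorm = s / mean
        snorm[snorm == 0] = 1.0
        # damped multiplicative update; stable on bipartite-like support
        snorm = np.sqrt(snorm)
        bias *= snorm
        data = data0 / (bias[rows] * bias[cols])

    total = data.sum()
    if total > 0:
        g = data0.sum() / total
        data = data * g
        bias = bias / np.sqrt(g)
    out = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return ContactMatrix(M.bins, out, state=STATE_ICE, mask=mask), bias_out


# ---------------------------------------------------------------------------
# Distance decay and O/E
# ---------------------------------------------------------------------------

def expected_by_distance(M: ContactMatrix, include_zeros: bool = True) -> DecayProfile:
    """Per-chromosome mean contact value at each bin separation.

    With ``include_zeros`` (the dense convention, the default) the mean at
    separation ``d`` runs over every unmasked bin pair at that separation,
    counting unstored positions as zero.  With ``include_zeros=False`` only
    stored entries enter the mean.
    """
    if M.state != STATE_ICE:
        raise DataError(f"expected_by_distance requires an ICE matrix, got {M.state!r}")
    keep = ~M.mask
    profiles: dict[str, np.ndarray] = {}
    stored = 0
    for chrom in M.bins.chroms:
        sl = M.bins.chrom_slice(chrom)
        n_c = sl.stop - sl.start
        block = M.matrix[sl, sl].tocoo()
        up = block.row <= block.col
        r, c, v = block.row[up], block.col[up], block.data[up]
        ku = keep[sl]
        ok = ku[r] & ku[c]
        r, c, v = r[ok], c[ok], v[ok]
        stored += v.size
        d = c - r
        num = np.bincount(d, weights=v, minlength=n_c)
        if include_zeros:
            kf = ku.astype(float)
            den = np.correlate(kf, kf, mode="full")[n_c - 1:]
        else:
            den = np.bincount(d, minlength=n_c).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        profiles[chrom] = exp
    if stored == 0:
        raise DataError("matrix has no cis entries")
    return DecayProfile(profiles, include_zeros=include_zeros)


def oe_normalize(M: ContactMatrix, decay: DecayProfile, trans: str = "drop") -> ContactMatrix:
    """Divide cis entries by the expected value at their separation.

    Entries whose expected value is zero (or undefined) are removed; a
    warning is logged when an observed contact is discarded this way.
    ``trans`` controls interchromosomal entries: ``"drop"`` (default)
    removes them, ``"keep"`` leaves them untouched, ``"mean"`` divides each
    chromosome-pair block by its mean trans value.
    """
    if M.state != STATE_ICE:
        raise DataError(f"oe_normalize requires an ICE matrix, got {M.state!r}")
    if trans not in ("drop", "keep", "mean"):
        raise ConfigurationError(f"unknown trans mode {trans!r}")
    coo = M.matrix.tocoo()
    code = M.bins.chrom_code
    rows, cols, vals = coo.row, coo.col, coo.data.astype(float)
    is_cis = code[rows] == code[cols]
    keep_entry = np.ones(len(vals), dtype=bool)

    for ci, chrom in enumerate(M.bins.chroms):
        sel = is_cis & (code[rows] == ci)
        if not sel.any():
            continue
        d = np.abs(rows[sel] - cols[sel])
        prof = decay.expected.get(chrom)
        if prof is None or d.max() >= len(prof):
            raise DataError(f"decay profile missing distances for {chrom}")
        exp = prof[d]
        if np.isnan(exp).any():
            raise DataError(f"decay profile undefined at some distances on {chrom}")
        zero = exp == 0
        if zero.any():
            n_obs = int((vals[sel][zero] > 0).sum())
            if n_obs:
                log.warning(
                    "%s: masking %d observed entries with zero expected value",
                    chrom, n_obs,
                )
            idx = np.flatnonzero(sel)[zero]
            keep_entry[idx] = False
            exp = np.where(zero, 1.0, exp)
        vals[sel] = vals[sel] / exp

    if trans == "drop":
        keep_entry &= is_cis
    elif trans == "mean":
        keep_mask = ~M.mask
        for ci, chrom_i in enumerate(M.bins.chroms):
            for cj in range(ci + 1, len(M.bins.chroms)):
                sel = (
                    ((code[rows] == ci) & (code[cols] == cj))
                    | ((code[rows] == cj) & (code[cols] == ci))
                )
                if not sel.any():
                    continue
                si = M.bins.chrom_slice(chrom_i)
                sj = M.bins.chrom_slice(M.bins.chroms[cj])
                n_pairs = keep_mask[si].sum() * keep_mask[sj].sum()
                block_sum = vals[sel].sum() / 2.0  # both triangles stored
                mean = block_sum / n_pairs if n_pairs else 0.0
                if mean == 0:
                    keep_entry[np.flatnonzero(sel)] = False
                else:
                    vals[sel] = vals[sel] / mean

    out = sp.coo_matrix(
        (vals[keep_entry], (rows[keep_entry], cols[keep_entry])),
        shape=M.matrix.shape,
    ).tocsr()
    return ContactMatrix(M.bins, out, state=STATE_OE, mask=M.mask.copy())
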