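"""A/B compartment calling and compartment-stratified comparisons.

Compartments are called per chromosome from the observed/expected (O/E) cis
matrix: the Pearson correlation matrix of the O/E rows is computed, its first
principal component extracted, and bins are labeled A or B by the sign of
their PC1 loading.  The eigenvector sign is arbitrary, so the track is
oriented by gene density: the sign whose bins carry the higher mean gene
density becomes A (euchromatic, gene-rich); a tie falls back to transposable
element density (lower in A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TestResult, mann_whitney
from .errors import DataError
from .hic_matrix import STATE_ICE, STATE_OE, BinTable, ContactMatrix

log = logging.getLogger(__name__)

LABEL_A = "A"
LABEL_B = "B"
LABEL_NA = "NA"


@dataclass
class FeatureTrack:
    """Per-bin scalar feature (gene count, TE fraction, TPM sum, ...)."""

    bins: BinTable
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.bins.n_bins:
            raise DataError("feature track length does not match bin table")


def feature_track_from_positions(bins: BinTable, positions: pd.DataFrame,
                                 weight: str | None = None) -> FeatureTrack:
    """Count point features (e.g. gene midpoints) per bin, optionally weighted."""
    values = np.zeros(bins.n_bins)
    for chrom, grp in positions.groupby("chrom"):
        if chrom not in bins.chroms:
            continue
        sl = bins.chrom_slice(chrom)
        size = bins.chrom_size(chrom)
        pos = grp["pos"].to_numpy()
        ok = (pos >= 0) & (pos < size)
        idx = sl.start + pos[ok] // bins.resolution
        w = grp[weight].to_numpy()[ok] if weight else np.ones(ok.sum())
        np.add.at(values, idx.astype(int), w)
    return FeatureTrack(bins, values)


@dataclass
class CompartmentTrack:
    """Per-bin PC1 loading and A/B/NA label."""

    bins: BinTable
    pc1: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.pc1) != self.bins.n_bins or len(self.labels) != self.bins.n_bins:
            raise DataError("compartment track length does not match bin table")

    def label_at(self, chrom: str, pos: int) -> str:
        return self.labels[self.bins.bin_at(chrom, pos)]


def call_compartments(
    M_oe: ContactMatrix,
    gene_density: FeatureTrack,
    te_density: FeatureTrack | None = None,
    min_bins: int = 10,
    use_correlation: bool = True,
) -> CompartmentTrack:
    """Call A/B compartments per chromosome from the O/E cis matrix.

    ``use_correlation`` switches between PCA of the Pearson correlation
    matrix of the O/E rows (default, the convention of eigenvector-based
    compartment callers) and PCA of the O/E matrix itself.
    """
    if M_oe.state != STATE_OE:
        raise DataError(f"compartment calling requires an O/E matrix, got {M_oe.state!r}")
    bins = M_oe.bins
    n = bins.n_bins
    pc1 = np.full(n, np.nan)
    labels = np.full(n, LABEL_NA, dtype=object)

    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        dense = M_oe.matrix[sl, sl].toarray()
        keep = ~M_oe.mask[sl]
        idx_local = np.flatnonzero(keep)
        sub = dense[np.ix_(idx_local, idx_local)]
        rowvar = sub.var(axis=1)
        good = rowvar > 0
        idx_local = idx_local[good]
        sub = sub[np.ix_(good, good)]
        if idx_local.size < min_bins:
            log.warning("%s: only %d usable bins, skipping compartment call",
                        chrom, idx_local.size)
            continue
        mat = np.corrcoef(sub) if use_correlation else sub
        if not np.isfinite(mat).all():
            mat = np.nan_to_num(mat)
        if np.allclose(mat, mat.flat[0]):
            continue  # zero-variance matrix: NA chromosome
        centered = mat - mat.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        pc = u[:, 0] * s[0]

        gidx = sl.start + idx_local
        pc = _orient_by_density(pc, gene_density.values[gidx],
                                None if te_density is None else te_density.values[gidx],
                                chrom)
        pc1[gidx] = pc
        labels[gidx[pc > 0]] = LABEL_A
        labels[gidx[pc < 0]] = LABEL_B
    return CompartmentTrack(bins, pc1, labels)


def _orient_by_density(pc, gene_density, te_density, chrom):
    pos, neg = pc > 0, pc < 0
    if not pos.any() or not neg.any():
        # single-sign chromosome: compare against the chromosome mean density
        side = pos if pos.any() else neg
        lbl_a = gene_density[side].mean() >= gene_density.mean()
        want_positive = pos.any()
        if lbl_a != want_positive:
            return -pc
        return pc
    mp, mn = gene_density[pos].mean(), gene_density[neg].mean()
    if mp > mn:
        return pc
    if mp < mn:
        return -pc
    if te_density is not None:
        tp, tn = te_density[pos].mean(), te_density[neg].mean()
        if tp < tn:
            return pc
        if tp > tn:
            return -pc
    raise DataError(
        f"{chrom}: cannot orient PC1, gene (and TE) densities tie exactly"
    )


def compartment_fractions(track: CompartmentTrack) -> dict:
    """Fractions of labeled genomic length (and bin counts) in A and B."""
    lengths = track.bins.lengths()
    is_a = track.labels == LABEL_A
    is_b = track.labels == LABEL_B
    a_bp = int(lengths[is_a].sum())
    b_bp = int(lengths[is_b].sum())
    if a_bp + b_bp == 0:
        raise DataError("compartment track has no labeled bins")
    total = a_bp + b_bp
    return {
        "A_frac": a_bp / total,
        "B_frac": b_bp / total,
        "A_bp": a_bp,
        "B_bp": b_bp,
        "A_bins": int(is_a.sum()),
        "B_bins": int(is_b.sum()),
    }


def compare_ab_counts(track_x: CompartmentTrack, track_y: CompartmentTrack) -> dict:
    """Two-sided Fisher exact test on the 2x2 A/B bin-count table of two tracks."""
    fx = compartment_fractions(track_x)
    fy = compartment_fractions(track_y)
    table = [[fx["A_bins"], fx["B_bins"]], [fy["A_bins"], fy["B_bins"]]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "pvalue": float(p)}


def compare_feature_by_compartment(track: CompartmentTrack,
                                   feature: FeatureTrack) -> TestResult:
    """Mann-Whitney U of a per-bin feature between A and B bins."""
    if feature.bins.n_bins != track.bins.n_bins:
        raise DataError("feature and compartment tracks use different binnings")
    a = feature.values[track.labels == LABEL_A]
    b = feature.values[track.labels == LABEL_B]
    return mann_whitney(a, b, group1="A", group2="B")


def trans_compartment_preference(
    M: ContactMatrix,
    track_x: CompartmentTrack,
    track_y: CompartmentTrack | None = None,
) -> dict:
    """Mean ICE trans contact for each label combination (AA/AB/BA/BB).

    Zero (unstored) bin pairs are included in the means; masked bins are
    excluded.  With a single track the table is symmetric (AB == BA).
    """
    if M.state != STATE_ICE:
        raise DataError(f"trans preference requires an ICE matrix, got {M.state!r}")
    track_y = track_y if track_y is not None else track_x
    bins = M.bins
    keep = ~M.mask
    sums = {k: 0.0 for k in ("AA", "AB", "BA", "BB")}
    counts = {k: 0 for k in sums}
    nnz_trans = 0
    chroms = bins.chroms
    for ci, chrom_i in enumerate(chroms):
        for cj, chrom_j in enumerate(chroms):
            if ci == cj:
                continue
            si = bins.chrom_slice(chrom_i)
            sj = bins.chrom_slice(chrom_j)
            block = M.matrix[si, sj]
            nnz_trans += block.nnz
            dense = block.toarray()
            for a in (LABEL_A, LABEL_B):
                ii = (track_x.labels[si] == a) & keep[si]
                if not ii.any():
                    continue
                for b in (LABEL_A, LABEL_B):
                    jj = (track_y.labels[sj] == b) & keep[sj]
                    if not jj.any():
                        continue
                    key = a + b
                    sums[key] += dense[np.ix_(ii, jj)].sum()
                    counts[key] += int(ii.sum()) * int(jj.sum())
    if nnz_trans == 0:
        raise DataError("matrix has no trans entries")
    return {k: (sums[k] / counts[k] if counts[k] else np.nan) for k in sums}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_track_bedgraph(track: CompartmentTrack, path) -> None:
    df = track.bins.table[["chrom", "start", "end"]].copy()
    df["pc1"] = track.pc1
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_track_bed(track: CompartmentTrack, path) -> None:
    """A/B intervals as BED with the label in the name field."""
    df = track.bins.table[["chrom", "start", "end"]].copy()
    df["name"] = track.labels
    df[df["name"] != LABEL_NA].to_csv(path, sep="\t", header=False, index=False)


def read_track_bedgraph(path, bins: BinTable, labels_path=None) -> CompartmentTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "pc1"], comment="#")
    if len(df) != bins.n_bins:
        raise DataError("bedGraph does not match the bin table")
    pc1 = df["pc1"].to_numpy(dtype=float)
    labels = np.full(bins.n_bins, LABEL_NA, dtype=object)
    labels[pc1 > 0] = LABEL_A
    labels[pc1 < 0] = LABEL_B
    labels[~np.isfinite(pc1)] = LABEL_NA
    return CompartmentTrack(bins, pc1, labels)
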