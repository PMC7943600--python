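"""Spatial statistics of WGD-derived paralog pairs.

Paralog pairs are selected by synonymous substitution rate (Ks) in a fixed
window, classified by expression bias (twofold rule on TPM with a minimum
expression filter), and annotated with spatial statistics: the ICE trans
contact between the two gene bins (interaction frequency), the mean O/E cis
contact of each gene's bin with the rest of its chromosome (interaction
score), and a coverage-weighted binomial colocalization test with
Benjamini-Hochberg FDR control.  A randomization null re-runs the
colocalization test on random interchromosomal gene pairs to show the
observed colocalization count is not a coverage artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TestResult, benjamini_hochberg, mann_whitney
from .errors import ConfigurationError, DataError
from .hic_matrix import STATE_ICE, STATE_OE, STATE_RAW, ContactMatrix

log = logging.getLogger(__name__)

KS_WINDOW = (0.05, 0.6)
MIN_TPM = 0.5
FOLD_CUTOFF = 2.0
MIN_SEPARATION = 2  # bins excluded around the diagonal in interaction scores

BIAS_BIASED = "biased"
BIAS_SIMILAR = "similar"
BIAS_EXCLUDED = "excluded"

METH_CONTEXTS = ("cg", "chg", "chh")


def filter_wgd_paralogs(pairs: pd.DataFrame,
                        ks_window: tuple[float, float] = KS_WINDOW) -> pd.DataFrame:
    """Retain pairs with Ks inside the WGD window (inclusive both ends)."""
    if "ks" not in pairs.columns:
        raise DataError("paralog table missing 'ks' column")
    ks = pairs["ks"].to_numpy(dtype=float)
    if not np.isfinite(ks).all():
        raise DataError("paralog table contains non-finite Ks values")
    if (ks < 0).any():
        raise DataError("paralog table contains negative Ks values")
    lo, hi = ks_window
    return pairs[(ks >= lo) & (ks <= hi)].reset_index(drop=True)


def classify_expression_bias(tpm1: float, tpm2: float,
                             min_tpm: float = MIN_TPM,
                             fold: float = FOLD_CUTOFF) -> str:
    """biased / similar / excluded by the twofold rule (symmetric in its args)."""
    if tpm1 < 0 or tpm2 < 0:
        raise DataError("TPM values must be non-negative")
    lo, hi = min(tpm1, tpm2), max(tpm1, tpm2)
    if lo < min_tpm:
        return BIAS_EXCLUDED
    return BIAS_BIASED if hi / lo > fold else BIAS_SIMILAR


def pair_interaction_frequency(M_ice: ContactMatrix, bin1: int, bin2: int) -> float:
    """ICE trans contact between two gene bins (0 if unstored, NaN if masked)."""
    if M_ice.state != STATE_ICE:
        raise DataError(f"interaction frequency requires an ICE matrix, got {M_ice.state!r}")
    code = M_ice.bins.chrom_code
    if code[bin1] == code[bin2]:
        raise DataError(
            f"bins {bin1} and {bin2} are on the same chromosome; "
            "interaction frequency is a trans statistic"
        )
    if M_ice.mask[bin1] or M_ice.mask[bin2]:
        return float("nan")
    return float(M_ice.matrix[bin1, bin2])


def interaction_score(M_oe: ContactMatrix, bin_id: int,
                      min_sep: int = MIN_SEPARATION) -> float:
    """Mean O/E contact of a bin with the unmasked rest of its chromosome.

    Separations below ``min_sep`` bins are excluded to avoid diagonal
    dominance.  Returns NaN for a masked bin.
    """
    if M_oe.state != STATE_OE:
        raise DataError(f"interaction score requires an O/E matrix, got {M_oe.state!r}")
    if M_oe.mask[bin_id]:
        return float("nan")
    bins = M_oe.bins
    chrom = bins.chroms[bins.chrom_code[bin_id]]
    sl = bins.chrom_slice(chrom)
    row = np.asarray(M_oe.matrix[bin_id, sl].todense()).ravel()
    offsets = np.arange(sl.start, sl.stop)
    eligible = (~M_oe.mask[sl]) & (np.abs(offsets - bin_id) >= min_sep)
    if not eligible.any():
        return float("nan")
    return float(row[eligible].mean())


# ---------------------------------------------------------------------------
# Colocalization: coverage-weighted binomial test per chromosome pair
# ---------------------------------------------------------------------------

class TransColocModel:
    """Precomputed trans counts and marginals per chromosome pair.

    For a pair of bins (i on c1, j on c2): with ``n`` the total raw trans
    count between c1 and c2 and ``m`` the per-bin trans marginals restricted
    to that chromosome pair, the null probability of a single contact
    falling on (i, j) is ``p0 = m_i * m_j / n**2``; the p-value is the
    upper-tail binomial probability of the observed count.
    """

    def __init__(self, M_raw: ContactMatrix):
        if M_raw.state != STATE_RAW:
            raise DataError("colocalization requires the raw count matrix")
        if M_raw.matrix.nnz and not np.allclose(
                M_raw.matrix.data, np.round(M_raw.matrix.data)):
            raise DataError("colocalization requires integer raw counts")
        self.bins = M_raw.bins
        self.code = M_raw.bins.chrom_code
        self._blocks: dict[tuple[int, int], dict] = {}
        chroms = M_raw.bins.chroms
        for ci in range(len(chroms)):
            for cj in range(ci + 1, len(chroms)):
                si = M_raw.bins.chrom_slice(chroms[ci])
                sj = M_raw.bins.chrom_slice(chroms[cj])
                block = M_raw.matrix[si, sj].toarray()
                self._blocks[(ci, cj)] = {
                    "x": block,
                    "n": float(block.sum()),
                    "m_row": block.sum(axis=1),
                    "m_col": block.sum(axis=0),
                    "off_i": si.start,
                    "off_j": sj.start,
                }

    def pvalues(self, bin1: np.ndarray, bin2: np.ndarray,
                null: str = "coverage") -> np.ndarray:
        if null not in ("coverage", "uniform"):
            raise ConfigurationError(f"unknown null model {null!r}")
        bin1 = np.asarray(bin1, dtype=int)
        bin2 = np.asarray(bin2, dtype=int)
        c1, c2 = self.code[bin1], self.code[bin2]
        if (c1 == c2).any():
            raise DataError("colocalization pairs must be interchromosomal")
        lo = np.minimum.reduce([c1, c2])
        hi = np.maximum.reduce([c1, c2])
        b_lo = np.where(c1 < c2, bin1, bin2)
        b_hi = np.where(c1 < c2, bin2, bin1)
        p = np.ones(len(bin1))
        for (ci, cj), blk in self._blocks.items():
            sel = (lo == ci) & (hi == cj)
            if not sel.any():
                continue
            i = b_lo[sel] - blk["off_i"]
            j = b_hi[sel] - blk["off_j"]
            n = blk["n"]
            if n == 0:
                continue
            x = blk["x"][i, j]
            if null == "coverage":
                p0 = blk["m_row"][i] * blk["m_col"][j] / n**2
            else:
                p0 = np.full(len(i), 1.0 / blk["x"].size)
            p0 = np.clip(p0, 0.0, 1.0)
            p[sel] = stats.binom.sf(x - 1, int(n), p0)
        return p


def colocalization_test(
    M_raw: ContactMatrix,
    pairs: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    null: str = "coverage",
    model: TransColocModel | None = None,
) -> pd.DataFrame:
    """Binomial colocalization p-values with BH FDR across all tested pairs.

    ``pairs`` needs integer columns ``bin1`` and ``bin2`` (genome-wide bin
    ids on different chromosomes).  Returns a copy with ``coloc_p``,
    ``coloc_fdr`` and the boolean ``colocalized`` (FDR strictly below the
    cutoff).
    """
    model = model or TransColocModel(M_raw)
    out = pairs.copy()
    p = model.pvalues(out["bin1"].to_numpy(), out["bin2"].to_numpy(), null=null)
    out["coloc_p"] = p
    out["coloc_fdr"] = benjamini_hochberg(p, alpha=fdr_cutoff)
    out["colocalized"] = out["coloc_fdr"] < fdr_cutoff
    return out


@dataclass
class RandomizationResult:
    counts: np.ndarray       # colocalized count per randomization
    observed: int | None
    p_empirical: float | None
    reps: int


def randomization_null(
    n_pairs: int,
    genes: pd.DataFrame,
    M_raw: ContactMatrix,
    reps: int = 1000,
    seed: int = 0,
    observed_count: int | None = None,
    fdr_cutoff: float = 0.05,
    null: str = "coverage",
    model: TransColocModel | None = None,
) -> RandomizationResult:
    """Colocalization counts for random interchromosomal gene-pair draws.

    Each of ``reps`` draws samples ``n_pairs`` distinct unordered
    interchromosomal pairs uniformly from the gene universe and applies the
    colocalization test (including BH within the draw).  The empirical
    p-value uses the add-one rule ``(1 + #{null >= observed}) / (reps + 1)``.
    """
    if reps <= 0:
        raise ConfigurationError(f"reps must be positive, got {reps}")
    if n_pairs <= 0:
        raise ConfigurationError(f"n_pairs must be positive, got {n_pairs}")
    rng = np.random.default_rng(seed)
    model = model or TransColocModel(M_raw)
    gbins = genes["bin"].to_numpy(dtype=int)
    gchrom = model.code[gbins]
    n_genes = len(genes)
    if len(np.unique(gchrom)) < 2:
        raise DataError("gene universe spans a single chromosome")

    counts = np.zeros(reps, dtype=int)
    for r in range(reps):
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_pairs:
            need = n_pairs - len(chosen)
            i = rng.integers(0, n_genes, size=2 * need + 8)
            j = rng.integers(0, n_genes, size=2 * need + 8)
            ok = gchrom[i] != gchrom[j]
            for a, b in zip(i[ok], j[ok]):
                chosen.add((min(a, b), max(a, b)))
                if len(chosen) >= n_pairs:
                    break
        idx = np.array(sorted(chosen))
        p = model.pvalues(gbins[idx[:, 0]], gbins[idx[:, 1]], null=null)
        fdr = benjamini_hochberg(p, alpha=fdr_cutoff)
        counts[r] = int((fdr < fdr_cutoff).sum())

    p_emp = None
    if observed_count is not None:
        p_emp = (1 + int((counts >= observed_count).sum())) / (reps + 1)
    return RandomizationResult(counts=counts, observed=observed_count,
                               p_empirical=p_emp, reps=reps)


# ---------------------------------------------------------------------------
# Expression bias vs interaction statistics
# ---------------------------------------------------------------------------

def frequency_bias_test(table: pd.DataFrame) -> TestResult:
    """Interaction frequency of biased vs similar expression pairs."""
    biased = table.loc[table["bias_class"] == BIAS_BIASED, "inter_freq"]
    similar = table.loc[table["bias_class"] == BIAS_SIMILAR, "inter_freq"]
    return mann_whitney(biased, similar, group1=BIAS_BIASED, group2=BIAS_SIMILAR)


def copy_score_asymmetry_test(table: pd.DataFrame) -> TestResult:
    """Within biased pairs: interaction score of the high- vs low-TPM copy."""
    sub = table[table["bias_class"] == BIAS_BIASED]
    high, low = [], []
    for row in sub.itertuples(index=False):
        if row.tpm1 >= row.tpm2:
            high.append(row.score1)
            low.append(row.score2)
        else:
            high.append(row.score2)
            low.append(row.score1)
    return mann_whitney(high, low, group1="high_tpm_copy", group2="low_tpm_copy")


def compare_bias_vs_interaction(table: pd.DataFrame) -> dict:
    """Run both bias-vs-interaction tests; a failing test records its error."""
    out = {}
    for name, fn in (
        ("freq_biased_vs_similar", frequency_bias_test),
        ("score_high_vs_low_copy", copy_score_asymmetry_test),
    ):
        try:
            out[name] = fn(table)
        except DataError as exc:
            out[name] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# Methylation similarity and cross-species conservation
# ---------------------------------------------------------------------------

def methylation_similarity(
    table: pd.DataFrame,
    meth: pd.DataFrame,
    contexts: tuple[str, ...] = METH_CONTEXTS,
) -> dict[str, TestResult]:
    """|level(gene1) - level(gene2)| per context, colocalized vs not.

    ``meth`` is indexed by gene id with one column per context; levels must
    lie in [0, 1].
    """
    if "colocalized" not in table.columns:
        raise DataError("pair table has no 'colocalized' flags")
    results = {}
    for ctx in contexts:
        if ctx not in meth.columns:
            raise DataError(f"methylation table missing context {ctx!r}")
        levels = meth[ctx]
        if ((levels < 0) | (levels > 1)).any():
            raise DataError(f"methylation levels outside [0, 1] in context {ctx!r}")
        diffs, flags = [], []
        for row in table.itertuples(index=False):
            if row.gene1 not in levels.index or row.gene2 not in levels.index:
                continue
            diffs.append(abs(levels[row.gene1] - levels[row.gene2]))
            flags.append(bool(row.colocalized))
        diffs = np.array(diffs)
        flags = np.array(flags, dtype=bool)
        results[ctx] = mann_whitney(diffs[flags], diffs[~flags],
                                    group1="colocalized", group2="noncolocalized")
    return results


def colocalization_conservation(
    coloc_a,
    coloc_b,
    orthologs,
    n_universe: int | None = None,
) -> dict:
    """Cross-species overlap of colocalized pair sets through orthology.

    A pair in species A overlaps when both genes have orthologs and the
    orthologous pair is colocalized in species B.  The Fisher test compares
    the overlap against random pair sets of the same sizes drawn from a
    shared universe of ``n_universe`` candidate pairs.
    """
    a2b = orthologs.a_to_b
    set_a = {frozenset(p) for p in coloc_a}
    set_b = {frozenset(p) for p in coloc_b}
    overlap = 0
    for pair in set_a:
        g1, g2 = tuple(pair)
        if g1 in a2b and g2 in a2b and frozenset((a2b[g1], a2b[g2])) in set_b:
            overlap += 1
    n_a, n_b = len(set_a), len(set_b)
    result = {
        "overlap_n": overlap,
        "frac_a": overlap / n_a if n_a else 0.0,
        "frac_b": overlap / n_b if n_b else 0.0,
        "fisher_p": np.nan,
        "odds_ratio": np.nan,
    }
    if n_a == 0 or n_b == 0:
        log.warning("empty colocalized set: Fisher test skipped")
        return result
    if n_universe is None:
        log.warning("no pair universe size given: Fisher test skipped")
        return result
    neither = n_universe - n_a - n_b + overlap
    if neither < 0:
        raise DataError("pair universe smaller than the union of colocalized sets")
    table = [[overlap, n_a - overlap], [n_b - overlap, neither]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    result["fisher_p"] = float(p)
    result["odds_ratio"] = float(odds)
    return result


# ---------------------------------------------------------------------------
# Pair-table assembly
# ---------------------------------------------------------------------------

def build_pair_table(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    M_ice: ContactMatrix,
    M_oe: ContactMatrix,
    M_raw: ContactMatrix,
    ks_window: tuple[float, float] = KS_WINDOW,
    min_tpm: float = MIN_TPM,
    fold: float = FOLD_CUTOFF,
    fdr_cutoff: float = 0.05,
    null: str = "coverage",
    model: TransColocModel | None = None,
) -> pd.DataFrame:
    """Annotate Ks-filtered paralog pairs with all spatial statistics.

    ``pairs`` has columns gene1, gene2, ks; ``genes`` has gene, chrom,
    start, end, tpm.  Same-chromosome pairs are dropped (the statistics here
    are trans statistics).  Returns the annotated ParalogPairTable.
    """
    wgd = filter_wgd_paralogs(pairs, ks_window)
    ginfo = genes.set_index("gene")
    bins = M_ice.bins
    code = bins.chrom_code

    rows = []
    for row in wgd.itertuples(index=False):
        g1, g2 = ginfo.loc[row.gene1], ginfo.loc[row.gene2]
        b1 = bins.bin_at(g1["chrom"], int((g1["start"] + g1["end"]) // 2))
        b2 = bins.bin_at(g2["chrom"], int((g2["start"] + g2["end"]) // 2))
        if code[b1] == code[b2]:
            continue
        rows.append({
            "gene1": row.gene1, "gene2": row.gene2, "ks": row.ks,
            "tpm1": float(g1["tpm"]), "tpm2": float(g2["tpm"]),
            "bin1": b1, "bin2": b2,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataError("no interchromosomal WGD paralog pairs to annotate")
    table["bias_class"] = [
        classify_expression_bias(t1, t2, min_tpm, fold)
        for t1, t2 in zip(table["tpm1"], table["tpm2"])
    ]
    table["inter_freq"] = [
        pair_interaction_frequency(M_ice, b1, b2)
        for b1, b2 in zip(table["bin1"], table["bin2"])
    ]
    table["score1"] = [interaction_score(M_oe, b) for b in table["bin1"]]
    table["score2"] = [interaction_score(M_oe, b) for b in table["bin2"]]
    return colocalization_test(M_raw, table, fdr_cutoff=fdr_cutoff,
                               null=null, model=model)
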