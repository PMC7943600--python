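"""Two-species synthetic datasets with planted ground truth.

The generator emulates every input the pipeline consumes: binned Hi-C count
matrices at the analysis (10 kb) and compartment (50 kb) resolutions, gene
annotations with expression, per-gene methylation levels, syntenic blocks
with structural variants, and ortholog/paralog tables.  Structure is planted
explicitly so every pipeline stage can be scored against the truth:

* checkerboard A/B compartments (fixed-length blocks per chromosome) with
  enriched same-compartment contact, double gene density and elevated
  expression in A, and elevated methylation in B;
* TADs nested inside compartment blocks with enriched within-domain contact;
* power-law distance decay and multiplicative per-bin coverage biases;
* an A-A preference in trans contact;
* a second species whose compartment labels switch on a planted fraction of
  the syntenic length, with planted inversions, translocations and
  species-specific regions;
* WGD-like paralog pairs with Ks in a fixed window (plus out-of-window
  decoys), planted colocalized pairs (multiplied trans counts, correlated
  methylation) and biased-expression pairs (twofold-plus expression fold
  change, damped trans counts).

Counts are Poisson unless an overdispersion parameter switches them to
negative binomial.  All randomness derives from the single seed in the
configuration; the same seed reproduces a byte-identical dataset directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .comparative import BLOCK_COLUMNS, OrthologTable, SyntenyMap
from .errors import ConfigurationError, DataError
from .hic_matrix import (BinTable, ContactMatrix, bin_genome, write_bins_bed,
                         write_contacts)

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions of the planted two-species genome."""

    seed: int = 0
    species: tuple[str, str] = ("speciesA", "speciesB")
    n_chroms: int = 3
    chrom_length: int = 5_000_000
    resolution: int = 10_000
    compartment_resolution: int = 50_000
    compartment_block_len: int = 250_000
    tad_len_range: tuple[int, int] = (80_000, 200_000)
    decay_exponent: float = 1.0
    cis_depth: float = 2e6          # expected cis counts per chromosome
    trans_depth: float = 1e6        # expected counts per chromosome pair
    bias_sd: float = 0.25           # lognormal sigma of per-bin coverage biases
    tad_enrichment: float = 2.0
    compartment_same_factor: float = 1.4
    compartment_cross_factor: float = 0.6
    aa_trans_multiplier: float = 2.0
    gene_rate_a: float = 6.0        # shared genes per compartment bin in A
    gene_rate_b: float = 3.0
    extra_gene_rate: float = 1.0    # species-private genes per A bin
    expression_a_boost: float = 4.0
    n_paralog_pairs: int = 400
    ks_window: tuple[float, float] = (0.05, 0.6)
    ks_decoy_frac: float = 0.3
    frac_colocalized: float = 0.18  # of in-window pairs (~50 at defaults)
    coloc_overlap_frac: float = 0.5
    coloc_multiplier: float = 5.0
    frac_biased_expression: float = 0.5
    frac_low_expressed: float = 0.05
    bias_trans_coupling: float = 0.5
    switch_frac: float = 0.3        # syntenic compartment blocks label-switched
    sv_counts: dict = field(default_factory=lambda: {
        "inversion": 18, "translocation": 12,
        "species_specific_A": 3, "species_specific_B": 3,
    })
    meth_a: dict = field(default_factory=lambda: {"cg": 0.35, "chg": 0.15, "chh": 0.05})
    meth_b: dict = field(default_factory=lambda: {"cg": 0.65, "chg": 0.40, "chh": 0.15})
    meth_gene_sd: float = 0.08
    meth_coloc_sd: float = 0.03
    overdispersion: float | None = None  # NB dispersion; None -> Poisson

    def validate(self) -> None:
        pos = ["n_chroms", "chrom_length", "resolution", "compartment_resolution",
               "compartment_block_len", "cis_depth", "trans_depth",
               "tad_enrichment", "n_paralog_pairs"]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"config field {name} must be positive")
        for name in ["frac_colocalized", "coloc_overlap_frac",
                     "frac_biased_expression", "frac_low_expressed",
                     "switch_frac", "ks_decoy_frac"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"config field {name} must be in [0, 1]")
        if self.coloc_multiplier <= 1.0:
            raise ConfigurationError("config field coloc_multiplier must exceed 1")
        if self.compartment_resolution % self.resolution != 0:
            raise ConfigurationError(
                "config field compartment_resolution must be a multiple of resolution")
        if self.compartment_block_len % self.compartment_resolution != 0:
            raise ConfigurationError(
                "config field compartment_block_len must be a multiple of "
                "compartment_resolution")
        if self.chrom_length % self.compartment_block_len != 0:
            raise ConfigurationError(
                "config field chrom_length must be a multiple of compartment_block_len")
        lo, hi = self.tad_len_range
        if not (0 < lo <= hi) or lo % self.resolution or hi % self.resolution:
            raise ConfigurationError(
                "config field tad_len_range must be positive multiples of resolution")
        if len(self.species) != 2 or len(set(self.species)) != 2:
            raise ConfigurationError("config field species must name two distinct species")


@dataclass
class SpeciesData:
    name: str
    bins_hi: BinTable        # analysis resolution (10 kb)
    bins_lo: BinTable        # compartment resolution (50 kb)
    matrix_hi: ContactMatrix  # raw counts, genome-wide
    matrix_lo: ContactMatrix
    genes: pd.DataFrame      # gene, chrom, start, end, tpm
    methylation: pd.DataFrame  # gene, cg, chg, chh
    paralogs: pd.DataFrame   # gene1, gene2, ks


@dataclass
class GroundTruth:
    labels_hi: dict          # species -> per-bin label array (10 kb)
    labels_lo: dict          # species -> per-bin label array (50 kb)
    tad_splits_bp: dict      # species -> {chrom: split positions in bp}
    biases_hi: dict
    biases_lo: dict
    colocalized: dict        # species -> list of (gene1, gene2)
    biased: dict
    switch_blocks: list      # (chrom, block_start_bp) flipped in species B
    switched_syntenic_frac: float


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    species: dict            # name -> SpeciesData
    synteny: SyntenyMap
    orthologs: OrthologTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _sample_counts(rng, mean, overdispersion):
    if overdispersion:
        r = 1.0 / overdispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))
    return rng.poisson(mean)


def _sample_symmetric(rng, mean, overdispersion):
    n = mean.shape[0]
    iu = np.triu_indices(n)
    out = np.zeros_like(mean)
    out[iu] = _sample_counts(rng, mean[iu], overdispersion)
    return out + out.T - np.diag(np.diag(out))


def _tad_splits_for_block(rng, block_len, lo, hi, res):
    """Split offsets (bp, within the block) of the nested TAD partition."""
    splits, pos = [], 0
    while True:
        remaining = block_len - pos
        if remaining < 2 * lo:
            break
        d = int(rng.integers(lo // res, min(hi, remaining - lo) // res + 1)) * res
        pos += d
        splits.append(pos)
    return splits


def _plant_compartments(rng, cfg, chroms):
    """Per-chromosome block labels for species A (alternating checkerboard)."""
    nb = cfg.chrom_length // cfg.compartment_block_len
    labels = {}
    for chrom in chroms:
        start = int(rng.integers(0, 2))
        labels[chrom] = np.where((np.arange(nb) + start) % 2 == 0, "A", "B")
    return labels


def _expand_block_labels(block_labels, cfg, resolution, chroms):
    per_block = cfg.compartment_block_len // resolution
    return np.concatenate([np.repeat(block_labels[c], per_block) for c in chroms])


def _plant_synteny(rng, cfg, chroms):
    """Block-aligned synteny segmentation with species-specific carve-outs."""
    nb = cfg.chrom_length // cfg.compartment_block_len
    ss_len = 3  # compartment blocks per species-specific region
    n_ss_a = cfg.sv_counts.get("species_specific_A", 0)
    n_ss_b = cfg.sv_counts.get("species_specific_B", 0)
    ss_assign = (["A"] * n_ss_a + ["B"] * n_ss_b)
    per_chrom_ss: dict[str, list] = {c: [] for c in chroms}
    for k, owner in enumerate(ss_assign):
        per_chrom_ss[chroms[k % len(chroms)]].append(owner)

    blocks, ss_records = [], []
    syntenic_blocks = []  # (chrom, block_index) available for label switching
    bl = cfg.compartment_block_len
    for chrom in chroms:
        owners = per_chrom_ss[chrom]
        taken: set[int] = set()
        for owner in owners:
            feasible = [s for s in range(nb - ss_len + 1)
                        if not (set(range(s, s + ss_len)) & taken)]
            if not feasible:
                raise ConfigurationError(
                    "sv_counts: species-specific regions do not fit on "
                    f"{chrom} ({nb} compartment blocks)")
            s = int(feasible[int(rng.integers(0, len(feasible)))])
            taken |= set(range(s, s + ss_len))
            ss_records.append({
                "type": f"species_specific_{owner}",
                "chrom": chrom, "start": s * bl, "end": (s + ss_len) * bl,
            })
        free = sorted(set(range(nb)) - taken)
        # maximal runs of free blocks become identity synteny blocks
        run_start = None
        prev = None
        for b in free + [None]:
            if run_start is None:
                run_start = b
            elif b is None or b != prev + 1:
                blocks.append((chrom, run_start * bl, (prev + 1) * bl,
                               chrom, run_start * bl, (prev + 1) * bl, "+"))
                syntenic_blocks.extend((chrom, k) for k in range(run_start, prev + 1))
                run_start = b
            prev = b
    block_df = pd.DataFrame(blocks, columns=BLOCK_COLUMNS)
    return block_df, ss_records, syntenic_blocks


def _plant_svs(rng, cfg, chroms, block_df, ss_records):
    rows = []
    bl = cfg.compartment_block_len
    res = cfg.compartment_resolution
    n_inv = cfg.sv_counts.get("inversion", 0)
    n_tra = cfg.sv_counts.get("translocation", 0)
    blocks = list(block_df.itertuples(index=False))
    lengths = np.array([b.endA - b.startA for b in blocks], dtype=float)
    weights = lengths / lengths.sum()  # uniform over genomic position

    def pick_block():
        return blocks[int(rng.choice(len(blocks), p=weights))]

    for _ in range(n_inv):
        b = pick_block()
        span = b.endA - b.startA
        length = int(rng.integers(2, 5)) * res  # 100-200 kb
        length = min(length, span)
        start = b.startA + int(rng.integers(0, (span - length) // res + 1)) * res
        rows.append({"type": "inversion", "chromA": b.chromA, "startA": start,
                     "endA": start + length, "chromB": b.chromB, "startB": start,
                     "endB": start + length, "orientation": "-"})
    for _ in range(n_tra):
        b = pick_block()
        span = b.endA - b.startA
        length = min(3 * res, span)
        start = b.startA + int(rng.integers(0, (span - length) // res + 1)) * res
        target_chrom = chroms[int(rng.integers(0, len(chroms)))]
        t_start = int(rng.integers(0, (cfg.chrom_length - length) // res + 1)) * res
        rows.append({"type": "translocation", "chromA": b.chromA, "startA": start,
                     "endA": start + length, "chromB": target_chrom,
                     "startB": t_start, "endB": t_start + length, "orientation": "+"})
    for rec in ss_records:
        side = rec["type"][-1]
        row = {"type": rec["type"], "chromA": np.nan, "startA": np.nan,
               "endA": np.nan, "chromB": np.nan, "startB": np.nan,
               "endB": np.nan, "orientation": "+"}
        row[f"chrom{side}"] = rec["chrom"]
        row[f"start{side}"] = rec["start"]
        row[f"end{side}"] = rec["end"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["type"] + BLOCK_COLUMNS)


def _cis_mean(cfg, bias_c, label_codes, tad_ids):
    n = len(bias_c)
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    base = (d + 1.0) ** (-cfg.decay_exponent)
    same_comp = np.equal.outer(label_codes, label_codes)
    comp = np.where(same_comp, cfg.compartment_same_factor, cfg.compartment_cross_factor)
    same_tad = np.equal.outer(tad_ids, tad_ids)
    tadf = np.where(same_tad, cfg.tad_enrichment, 1.0)
    mean = np.outer(bias_c, bias_c) * base * comp * tadf
    iu = np.triu_indices(n)
    mean *= cfg.cis_depth / mean[iu].sum()
    return mean


def _trans_mean(cfg, bias_i, bias_j, labels_i, labels_j):
    base = np.outer(bias_i, bias_j)
    aa = np.logical_and.outer(labels_i == "A", labels_j == "A")
    mean = base * np.where(aa, cfg.aa_trans_multiplier, 1.0)
    mean *= cfg.trans_depth / mean.sum()
    return mean


def _simulate_matrix(rng, cfg, bins, labels, tad_ids, bias,
                     pair_boost=None):
    """Genome-wide raw count matrix (dense assembly, returned sparse).

    ``pair_boost`` maps (bin_i, bin_j) with i < j in genome order to a
    multiplier applied to the trans mean before sampling.
    """
    n = bins.n_bins
    dense = np.zeros((n, n))
    chroms = bins.chroms
    for chrom in chroms:
        sl = bins.chrom_slice(chrom)
        mean = _cis_mean(cfg, bias[sl], labels[sl] == "A", tad_ids[sl])
        dense[sl, sl] = _sample_symmetric(rng, mean, cfg.overdispersion)
    for ci in range(len(chroms)):
        for cj in range(ci + 1, len(chroms)):
            si = bins.chrom_slice(chroms[ci])
            sj = bins.chrom_slice(chroms[cj])
            mean = _trans_mean(cfg, bias[si], bias[sj], labels[si], labels[sj])
            if pair_boost:
                for (b1, b2), mult in pair_boost.items():
                    if si.start <= b1 < si.stop and sj.start <= b2 < sj.stop:
                        mean[b1 - si.start, b2 - sj.start] *= mult
            block = _sample_counts(rng, mean, cfg.overdispersion)
            dense[si, sj] = block
            dense[sj, si] = block.T
    return ContactMatrix(bins, sp.csr_matrix(dense), state="raw")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig | None = None,
                     out_dir=None) -> SyntheticDataset:
    """Generate the full two-species dataset (optionally writing it to disk)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sp_a, sp_b = cfg.species
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sizes = {c: cfg.chrom_length for c in chroms}
    bins_hi = bin_genome(sizes, cfg.resolution)
    bins_lo = bin_genome(sizes, cfg.compartment_resolution)

    # --- compartments, synteny, label switching -------------------------
    blocks_a = _plant_compartments(rng, cfg, chroms)
    block_df, ss_records, syntenic_blocks = _plant_synteny(rng, cfg, chroms)
    n_switch = int(round(cfg.switch_frac * len(syntenic_blocks)))
    switch_idx = rng.choice(len(syntenic_blocks), size=n_switch, replace=False)
    switch_set = {syntenic_blocks[i] for i in switch_idx}
    blocks_b = {c: blocks_a[c].copy() for c in chroms}
    for chrom, k in switch_set:
        blocks_b[chrom][k] = "A" if blocks_b[chrom][k] == "B" else "B"
    switched_frac = n_switch / len(syntenic_blocks) if syntenic_blocks else 0.0

    species_blocks = {sp_a: blocks_a, sp_b: blocks_b}
    labels_lo = {s: _expand_block_labels(bl, cfg, cfg.compartment_resolution, chroms)
                 for s, bl in species_blocks.items()}
    labels_hi = {s: _expand_block_labels(bl, cfg, cfg.resolution, chroms)
                 for s, bl in species_blocks.items()}

    svs = _plant_svs(rng, cfg, chroms, block_df, ss_records)
    synteny = SyntenyMap(block_df, svs)

    # --- TADs nested in compartment blocks ------------------------------
    lo_len, hi_len = cfg.tad_len_range
    tad_splits_bp: dict[str, dict[str, np.ndarray]] = {}
    tad_ids: dict[str, np.ndarray] = {}
    for s in cfg.species:
        per_chrom = {}
        ids = np.zeros(bins_hi.n_bins, dtype=int)
        next_id = 0
        for chrom in chroms:
            splits = []
            for b0 in range(0, cfg.chrom_length, cfg.compartment_block_len):
                if b0 > 0:
                    splits.append(b0)
                splits.extend(b0 + off for off in _tad_splits_for_block(
                    rng, cfg.compartment_block_len, lo_len, hi_len, cfg.resolution))
            splits = np.array(sorted(splits), dtype=int)
            per_chrom[chrom] = splits
            sl = bins_hi.chrom_slice(chrom)
            edges = np.concatenate([[0], splits // cfg.resolution,
                                    [bins_hi.n_bins_chrom(chrom)]])
            for k in range(len(edges) - 1):
                ids[sl.start + edges[k]: sl.start + edges[k + 1]] = next_id
                next_id += 1
        tad_splits_bp[s] = per_chrom
        tad_ids[s] = ids

    # --- coverage biases -------------------------------------------------
    biases_hi = {s: rng.lognormal(0.0, cfg.bias_sd, bins_hi.n_bins)
                 for s in cfg.species}
    biases_lo = {s: rng.lognormal(0.0, cfg.bias_sd, bins_lo.n_bins)
                 for s in cfg.species}

    # --- genes ------------------------------------------------------------
    shared = _place_genes(rng, cfg, bins_lo, labels_lo[sp_a], chroms, "g")
    extras = {s: _place_extra_genes(rng, cfg, bins_lo, labels_lo[s], chroms, "x")
              for s in cfg.species}
    genes_by_species = {}
    for s in cfg.species:
        g = pd.concat([shared, extras[s]], ignore_index=True)
        g = g.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        g = g.assign(gene=[f"{s}_{gid}" for gid in g["gene"]])
        genes_by_species[s] = g
    orthologs = OrthologTable(pd.DataFrame({
        "gene_a": [f"{sp_a}_{gid}" for gid in shared["gene"]],
        "gene_b": [f"{sp_b}_{gid}" for gid in shared["gene"]],
    }))

    # --- paralog pairs on the shared genes --------------------------------
    pair_idx = _sample_pairs(rng, shared, cfg.n_paralog_pairs)
    n_pairs = len(pair_idx)
    n_in = int(round((1.0 - cfg.ks_decoy_frac) * n_pairs))
    n_cc = int(round(cfg.frac_colocalized * n_in))
    n_shared_cc = int(round(cfg.coloc_overlap_frac * n_cc))
    cc_a = list(range(0, n_cc))
    cc_b = list(range(0, n_shared_cc)) + list(range(n_cc, 2 * n_cc - n_shared_cc))
    cc_union = set(cc_a) | set(cc_b)
    rest = [k for k in range(n_in) if k not in cc_union]
    n_bias = int(round(cfg.frac_biased_expression * len(rest)))
    biased_idx = rest[:n_bias]
    similar_rest = rest[n_bias:]
    n_low = int(round(cfg.frac_low_expressed * len(similar_rest)))
    low_idx = similar_rest[:n_low]

    truth_coloc = {sp_a: set(cc_a), sp_b: set(cc_b)}
    truth_biased = set(biased_idx)

    # per-species attributes: ks, tpm, methylation, planted trans boosts
    species_data = {}
    meth_base = {"A": cfg.meth_a, "B": cfg.meth_b}
    coloc_pairs_named = {}
    biased_pairs_named = {}
    for s in cfg.species:
        genes = genes_by_species[s]
        glabel = _gene_labels(genes, bins_lo, labels_lo[s])
        tpm = rng.lognormal(1.0, 1.0, len(genes))
        tpm = tpm * np.where(glabel == "A", cfg.expression_a_boost, 1.0)

        shared_names = shared["gene"].to_numpy()
        name1 = np.array([f"{s}_{shared_names[i]}" for i, _ in pair_idx])
        name2 = np.array([f"{s}_{shared_names[j]}" for _, j in pair_idx])
        gindex = pd.Index(genes["gene"])
        pos1 = gindex.get_indexer(name1)
        pos2 = gindex.get_indexer(name2)

        ks = np.empty(n_pairs)
        ks[:n_in] = rng.uniform(cfg.ks_window[0], cfg.ks_window[1], n_in)
        n_decoy = n_pairs - n_in
        half = n_decoy // 2
        ks[n_in:n_in + half] = rng.uniform(0.0, cfg.ks_window[0] * 0.9, half)
        ks[n_in + half:] = rng.uniform(cfg.ks_window[1] * 1.05, 2.0, n_decoy - half)

        for k in range(n_in):
            t = float(np.exp(rng.uniform(np.log(2.0), np.log(20.0))))
            if k in truth_biased:
                fc = 2.0 ** float(rng.uniform(1.2, 3.0))
            else:
                fc = 2.0 ** float(rng.uniform(0.0, 0.9))
            hi_first = bool(rng.integers(0, 2))
            t1, t2 = t * np.sqrt(fc), t / np.sqrt(fc)
            if not hi_first:
                t1, t2 = t2, t1
            tpm[pos1[k]], tpm[pos2[k]] = t1, t2
            if k in low_idx:
                tpm[pos2[k]] = float(rng.uniform(0.05, 0.4))
        genes = genes.assign(tpm=tpm)

        meth = np.empty((len(genes), 3))
        for col, ctx in enumerate(("cg", "chg", "chh")):
            base = np.array([meth_base[l][ctx] for l in glabel])
            meth[:, col] = np.clip(base + rng.normal(0.0, cfg.meth_gene_sd,
                                                     len(genes)), 0.0, 1.0)
        for k in sorted(truth_coloc[s]):
            meth[pos2[k]] = np.clip(
                meth[pos1[k]] + rng.normal(0.0, cfg.meth_coloc_sd, 3), 0.0, 1.0)
        methylation = pd.DataFrame(meth, columns=["cg", "chg", "chh"])
        methylation.insert(0, "gene", genes["gene"].to_numpy())

        # planted trans multipliers at the pair gene bins (10 kb)
        pair_boost: dict[tuple[int, int], float] = {}
        mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
        chrom_arr = genes["chrom"].to_numpy()
        gbin = np.array([bins_hi.bin_at(c, int(m)) for c, m in zip(chrom_arr, mid)])
        for k in range(n_in):
            b1, b2 = int(gbin[pos1[k]]), int(gbin[pos2[k]])
            if b1 == b2:
                continue
            key = (min(b1, b2), max(b1, b2))
            if k in truth_coloc[s]:
                pair_boost[key] = pair_boost.get(key, 1.0) * cfg.coloc_multiplier
            elif k in truth_biased:
                pair_boost[key] = pair_boost.get(key, 1.0) * cfg.bias_trans_coupling

        matrix_hi = _simulate_matrix(rng, cfg, bins_hi, labels_hi[s],
                                     tad_ids[s], biases_hi[s], pair_boost)
        tad_ids_lo = np.zeros(bins_lo.n_bins, dtype=int)  # no sub-bin TADs at 50 kb
        matrix_lo = _simulate_matrix(rng, cfg, bins_lo, labels_lo[s],
                                     tad_ids_lo, biases_lo[s])

        paralogs = pd.DataFrame({"gene1": name1, "gene2": name2, "ks": ks})
        species_data[s] = SpeciesData(
            name=s, bins_hi=bins_hi, bins_lo=bins_lo,
            matrix_hi=matrix_hi, matrix_lo=matrix_lo,
            genes=genes, methylation=methylation, paralogs=paralogs,
        )
        coloc_pairs_named[s] = [(name1[k], name2[k]) for k in sorted(truth_coloc[s])]
        biased_pairs_named[s] = [(name1[k], name2[k]) for k in sorted(truth_biased)]

    truth = GroundTruth(
        labels_hi=labels_hi,
        labels_lo=labels_lo,
        tad_splits_bp=tad_splits_bp,
        biases_hi=biases_hi,
        biases_lo=biases_lo,
        colocalized=coloc_pairs_named,
        biased=biased_pairs_named,
        switch_blocks=sorted((c, int(k * cfg.compartment_block_len))
                             for c, k in switch_set),
        switched_syntenic_frac=switched_frac,
    )
    dataset = SyntheticDataset(cfg, species_data, synteny, orthologs, truth)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def _place_genes(rng, cfg, bins_lo, labels, chroms, prefix):
    rows = []
    gid = 0
    table = bins_lo.table
    for bi in range(bins_lo.n_bins):
        rate = cfg.gene_rate_a if labels[bi] == "A" else cfg.gene_rate_b
        k = int(rng.poisson(rate))
        start_bp = int(table["start"].iloc[bi])
        end_bp = int(table["end"].iloc[bi])
        for _ in range(k):
            s = int(rng.integers(start_bp, max(start_bp + 1, end_bp - 2000)))
            rows.append((f"{prefix}{gid:05d}", table["chrom"].iloc[bi], s,
                         min(s + 2000, end_bp)))
            gid += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _place_extra_genes(rng, cfg, bins_lo, labels, chroms, prefix):
    rows = []
    gid = 0
    table = bins_lo.table
    for bi in range(bins_lo.n_bins):
        if labels[bi] != "A":
            continue
        k = int(rng.poisson(cfg.extra_gene_rate))
        start_bp = int(table["start"].iloc[bi])
        end_bp = int(table["end"].iloc[bi])
        for _ in range(k):
            s = int(rng.integers(start_bp, max(start_bp + 1, end_bp - 2000)))
            rows.append((f"{prefix}{gid:05d}", table["chrom"].iloc[bi], s,
                         min(s + 2000, end_bp)))
            gid += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _gene_labels(genes, bins_lo, labels_lo):
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    out = []
    for chrom, m in zip(genes["chrom"], mid):
        out.append(labels_lo[bins_lo.bin_at(chrom, int(m))])
    return np.array(out, dtype=object)


def _sample_pairs(rng, shared, n_pairs):
    """Disjoint cross-chromosome index pairs over the shared gene table."""
    chrom = shared["chrom"].to_numpy()
    perm = rng.permutation(len(shared))
    pairs = []
    for k in range(0, len(perm) - 1, 2):
        i, j = int(perm[k]), int(perm[k + 1])
        if chrom[i] != chrom[j]:
            pairs.append((i, j))
        if len(pairs) >= n_pairs:
            break
    if len(pairs) < n_pairs:
        raise ConfigurationError(
            f"config field n_paralog_pairs={n_pairs} exceeds the available "
            f"cross-chromosome gene pairs ({len(pairs)})")
    return pairs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write all pipeline input files plus the ground truth as JSON."""
    from .comparative import write_orthologs_tsv, write_synteny_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, data in dataset.species.items():
        d = out / s
        d.mkdir(exist_ok=True)
        write_bins_bed(data.bins_hi, d / "bins_10kb.bed")
        write_bins_bed(data.bins_lo, d / "bins_50kb.bed")
        write_contacts(data.matrix_hi, d / "matrix_10kb.tsv")
        write_contacts(data.matrix_lo, d / "matrix_50kb.tsv")
        data.genes.to_csv(d / "genes.tsv", sep="\t", index=False,
                          float_format="%.6g")
        data.methylation.to_csv(d / "methylation.tsv", sep="\t", index=False,
                                float_format="%.6g")
        data.paralogs.to_csv(d / "paralogs.tsv", sep="\t", index=False,
                             float_format="%.6g")
    write_synteny_tsv(dataset.synteny, out / "synteny.tsv")
    write_orthologs_tsv(dataset.orthologs, out / "orthologs.tsv")
    truth = dataset.truth
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(dataset.config).items()},
        "labels_lo": {s: list(map(str, v)) for s, v in truth.labels_lo.items()},
        "labels_hi": {s: list(map(str, v)) for s, v in truth.labels_hi.items()},
        "tad_splits_bp": {s: {c: [int(x) for x in v] for c, v in d.items()}
                          for s, d in truth.tad_splits_bp.items()},
        "biases_hi": {s: [round(float(x), 8) for x in v]
                      for s, v in truth.biases_hi.items()},
        "biases_lo": {s: [round(float(x), 8) for x in v]
                      for s, v in truth.biases_lo.items()},
        "colocalized": {s: [list(p) for p in v]
                        for s, v in truth.colocalized.items()},
        "biased": {s: [list(p) for p in v] for s, v in truth.biased.items()},
        "switch_blocks": [[c, int(p)] for c, p in truth.switch_blocks],
        "switched_syntenic_frac": truth.switched_syntenic_frac,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def boundary_f1(true_bp: dict, pred_bp: dict, tol_bp: int) -> dict:
    """Precision/recall/F1 of predicted split positions within a tolerance."""
    tp_r = n_true = 0
    tp_p = n_pred = 0
    for chrom, tb in true_bp.items():
        tb = np.asarray(sorted(tb))
        pb = np.asarray(sorted(pred_bp.get(chrom, [])))
        n_true += len(tb)
        n_pred += len(pb)
        if len(pb):
            for b in tb:
                if np.min(np.abs(pb - b)) <= tol_bp:
                    tp_r += 1
        if len(tb):
            for b in pb:
                if np.min(np.abs(tb - b)) <= tol_bp:
                    tp_p += 1
    recall = tp_r / n_true if n_true else np.nan
    precision = tp_p / n_pred if n_pred else np.nan
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1}


def truth_report(dataset: SyntheticDataset, outputs: dict) -> pd.DataFrame:
    """Score pipeline outputs against the planted truth.

    ``outputs`` maps each species to a dict with keys
    ``compartment_labels`` (per-bin labels at the compartment resolution),
    ``tad_splits_bp`` ({chrom: positions}) and ``colocalized`` (pair id
    tuples); an optional top-level key ``concordance_same_frac`` scores the
    cross-species stage.
    """
    rows = []
    truth = dataset.truth
    res = dataset.config.resolution
    for s in dataset.config.species:
        if s not in outputs:
            raise DataError(f"missing pipeline outputs for species {s!r}")
        out = outputs[s]
        for key in ("compartment_labels", "tad_splits_bp", "colocalized"):
            if key not in out:
                raise DataError(f"{s}: missing pipeline stage output {key!r}")

        called = np.asarray(out["compartment_labels"], dtype=object)
        true_l = truth.labels_lo[s]
        if len(called) != len(true_l):
            raise DataError(f"{s}: compartment label track length mismatch")
        ok = (called != "NA") & (true_l != "NA")
        acc = float((called[ok] == true_l[ok]).mean()) if ok.any() else np.nan
        rows.append((s, "compartment_label_accuracy", acc))

        f1 = boundary_f1(truth.tad_splits_bp[s], out["tad_splits_bp"], tol_bp=res)
        rows.append((s, "boundary_precision", f1["precision"]))
        rows.append((s, "boundary_recall", f1["recall"]))
        rows.append((s, "boundary_f1", f1["f1"]))

        true_cc = {frozenset(p) for p in truth.colocalized[s]}
        pred_cc = {frozenset(p) for p in out["colocalized"]}
        tp = len(true_cc & pred_cc)
        rows.append((s, "coloc_precision", tp / len(pred_cc) if pred_cc else np.nan))
        rows.append((s, "coloc_recall", tp / len(true_cc) if true_cc else np.nan))

    if "concordance_same_frac" in outputs:
        err = abs(outputs["concordance_same_frac"]
                  - (1.0 - truth.switched_syntenic_frac))
        rows.append(("both", "concordance_error", float(err)))
    return pd.DataFrame(rows, columns=["species", "metric", "value"])
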