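"""Cross-species conservation of compartments and TADs.

Conservation of A/B compartments is measured bp-weighted over syntenic
blocks: each block is walked in fixed steps, the label of the corresponding
segment in the other genome is looked up (orientation-aware), and the
fraction of labeled syntenic length with identical status is reported,
together with the compartment-switch regions.  Structural variants are
classified against the two compartment tracks.  TAD conservation follows an
orthology rule: a domain is conserved when more than a threshold fraction of
its syntenic (ortholog-bearing) genes map into a single domain of the other
species; domains with too few syntenic genes are excluded from the
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import TestResult, mann_whitney
from .compartments import LABEL_A, LABEL_B, LABEL_NA, CompartmentTrack
from .errors import DataError
from .tads import TADSet

log = logging.getLogger(__name__)

BLOCK_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "orientation"]
SV_TYPES = ("inversion", "translocation", "species_specific_A", "species_specific_B")


@dataclass
class SyntenyMap:
    """Aligned syntenic blocks plus structural-variant records."""

    blocks: pd.DataFrame  # BLOCK_COLUMNS
    svs: pd.DataFrame     # type + BLOCK_COLUMNS (coordinates NaN where absent)

    def __post_init__(self):
        for col in BLOCK_COLUMNS:
            if col not in self.blocks.columns:
                raise DataError(f"synteny blocks missing column {col!r}")
        if "type" not in self.svs.columns:
            self.svs = self.svs.assign(type=pd.Series(dtype=str))
        bad = set(self.svs["type"]) - set(SV_TYPES)
        if bad:
            raise DataError(f"unknown SV types {sorted(bad)}")


@dataclass
class OrthologTable:
    """One-to-one cross-species gene pairs."""

    pairs: pd.DataFrame  # gene_a, gene_b

    def __post_init__(self):
        if self.pairs.empty:
            raise DataError("ortholog table is empty")
        for col in ("gene_a", "gene_b"):
            if col not in self.pairs.columns:
                raise DataError(f"ortholog table missing column {col!r}")
            if self.pairs[col].duplicated().any():
                raise DataError(f"ortholog table is not one-to-one in {col}")

    @property
    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    @property
    def b_to_a(self) -> dict:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))


@dataclass
class ConcordanceResult:
    same_bp: int
    switched_bp: int
    switched_a_to_b_bp: int   # labeled A in species A, B in species B
    switched_b_to_a_bp: int
    switch_regions_a: pd.DataFrame  # chrom, start, end
    switch_regions_b: pd.DataFrame

    @property
    def same_frac(self) -> float:
        total = self.same_bp + self.switched_bp
        return self.same_bp / total if total else float("nan")


def compartment_concordance(
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
    synteny: SyntenyMap,
    step: int | None = None,
) -> ConcordanceResult:
    """bp-weighted compartment agreement over syntenic blocks.

    Each block is walked in ``step``-bp segments (default: the track
    resolution); labels are looked up at segment midpoints, honouring block
    orientation.  Only segments labeled A or B in both species count.
    """
    if synteny.blocks.empty:
        raise DataError("synteny map has no blocks")
    if track_a.bins.resolution != track_b.bins.resolution:
        raise DataError("compartment tracks use different resolutions")
    step = step or track_a.bins.resolution
    same = sw = a2b = b2a = 0
    seg_a, seg_b = [], []
    for row in synteny.blocks.itertuples(index=False):
        length = min(row.endA - row.startA, row.endB - row.startB)
        for off in range(0, length, step):
            seg = min(step, length - off)
            a_start = row.startA + off
            if row.orientation == "+":
                b_start = row.startB + off
            else:
                b_start = row.endB - off - seg
            la = track_a.label_at(row.chromA, a_start + seg // 2)
            lb = track_b.label_at(row.chromB, b_start + seg // 2)
            if la == LABEL_NA or lb == LABEL_NA:
                continue
            if la == lb:
                same += seg
            else:
                sw += seg
                if la == LABEL_A:
                    a2b += seg
                else:
                    b2a += seg
                seg_a.append((row.chromA, a_start, a_start + seg))
                seg_b.append((row.chromB, b_start, b_start + seg))
    return ConcordanceResult(
        same_bp=same,
        switched_bp=sw,
        switched_a_to_b_bp=a2b,
        switched_b_to_a_bp=b2a,
        switch_regions_a=_merge_intervals(seg_a),
        switch_regions_b=_merge_intervals(seg_b),
    )


def _merge_intervals(segments: list[tuple]) -> pd.DataFrame:
    cols = ["chrom", "start", "end"]
    if not segments:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(segments, columns=cols).sort_values(["chrom", "start"])
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for _, s, e in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=cols)


def _interval_label(track: CompartmentTrack, chrom: str, start: int, end: int,
                    record: str = "") -> str:
    """Majority compartment label over an interval; ties and all-NA give NA."""
    bins = track.bins
    if chrom not in bins.chroms:
        raise DataError(f"SV record {record or '?'}: unknown chromosome {chrom!r}")
    size = bins.chrom_size(chrom)
    if start < 0 or end > size or start >= end:
        raise DataError(
            f"SV record {record or '?'}: interval {chrom}:{start}-{end} outside bounds"
        )
    sl = bins.chrom_slice(chrom)
    starts = bins.table["start"].to_numpy()[sl]
    ends = bins.table["end"].to_numpy()[sl]
    overlap = np.minimum(ends, end) - np.maximum(starts, start)
    overlap = np.clip(overlap, 0, None)
    labels = track.labels[sl]
    a_bp = overlap[labels == LABEL_A].sum()
    b_bp = overlap[labels == LABEL_B].sum()
    if a_bp > b_bp:
        return LABEL_A
    if b_bp > a_bp:
        return LABEL_B
    return LABEL_NA


def _overlap_with_regions(chrom: str, start: int, end: int,
                          regions: pd.DataFrame) -> int:
    sub = regions[regions["chrom"] == chrom]
    if sub.empty:
        return 0
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    ov = np.clip(np.minimum(e, end) - np.maximum(s, start), 0, None)
    return int(ov.sum())


def classify_sv_compartment(
    svs: pd.DataFrame,
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
    switch_regions_a: pd.DataFrame,
    min_switch_overlap: float = 0.5,
) -> dict:
    """Per-type compartment summary of structural variants.

    Inversions: fraction whose majority label is identical in both species.
    Translocations: fraction whose source interval overlaps compartment
    switch regions by at least ``min_switch_overlap`` of its length.
    Species-specific regions: fraction labeled A in the owning genome.
    """
    out: dict[str, dict] = {}

    inv = svs[svs["type"] == "inversion"]
    n = unchanged = 0
    for k, row in enumerate(inv.itertuples(index=False)):
        la = _interval_label(track_a, row.chromA, int(row.startA), int(row.endA),
                             record=f"inversion[{k}]")
        lb = _interval_label(track_b, row.chromB, int(row.startB), int(row.endB),
                             record=f"inversion[{k}]")
        if la == LABEL_NA or lb == LABEL_NA:
            continue
        n += 1
        unchanged += la == lb
    out["inversion"] = {"n": n, "frac_unchanged": unchanged / n if n else np.nan}

    tra = svs[svs["type"] == "translocation"]
    n = in_switch = 0
    for k, row in enumerate(tra.itertuples(index=False)):
        length = int(row.endA) - int(row.startA)
        if length <= 0:
            raise DataError(f"translocation[{k}] has non-positive length")
        ov = _overlap_with_regions(row.chromA, int(row.startA), int(row.endA),
                                   switch_regions_a)
        n += 1
        in_switch += ov >= min_switch_overlap * length
    out["translocation"] = {"n": n, "frac_in_switch": in_switch / n if n else np.nan}

    for sv_type, track, side in (
        ("species_specific_A", track_a, "A"),
        ("species_specific_B", track_b, "B"),
    ):
        sub = svs[svs["type"] == sv_type]
        n = n_a = 0
        for k, row in enumerate(sub.itertuples(index=False)):
            chrom = getattr(row, f"chrom{side}")
            start = int(getattr(row, f"start{side}"))
            end = int(getattr(row, f"end{side}"))
            lbl = _interval_label(track, chrom, start, end, record=f"{sv_type}[{k}]")
            if lbl == LABEL_NA:
                continue
            n += 1
            n_a += lbl == LABEL_A
        out[sv_type] = {"n": n, "frac_A": n_a / n if n else np.nan}
    return out


# ---------------------------------------------------------------------------
# TAD conservation
# ---------------------------------------------------------------------------

def assign_genes_to_tads(genes: pd.DataFrame, tads: TADSet) -> pd.Series:
    """Domain id per gene (by gene midpoint); genes outside domains get None."""
    result = pd.Series([None] * len(genes), index=genes.index, dtype=object)
    for chrom, grp in genes.groupby("chrom"):
        doms = tads.domains[tads.domains["chrom"] == chrom].sort_values("start")
        if doms.empty:
            continue
        starts = doms["start"].to_numpy()
        ends = doms["end"].to_numpy()
        ids = doms["domain_id"].to_numpy()
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
        k = np.searchsorted(starts, mid, side="right") - 1
        ok = (k >= 0) & (mid < ends[np.clip(k, 0, len(ends) - 1)])
        vals = np.where(ok, ids[np.clip(k, 0, len(ids) - 1)], None)
        result.loc[grp.index] = vals
    return result


def tad_conservation(
    tads_a: TADSet,
    tads_b: TADSet,
    orthologs: OrthologTable,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    min_genes: int = 6,
    threshold: float = 0.7,
    reciprocal: bool = False,
) -> dict:
    """Orthology-based TAD conservation between two species.

    For each domain with at least ``min_genes`` ortholog-bearing genes, find
    the single domain of the other species capturing the most of those
    orthologs; the domain is conserved when that count exceeds ``threshold``
    of its syntenic genes.  ``reciprocal`` additionally requires the ratio
    to pass from the target domain's side.
    """
    a2b, b2a = orthologs.a_to_b, orthologs.b_to_a
    dom_a = dict(zip(genes_a["gene"], assign_genes_to_tads(genes_a, tads_a)))
    dom_b = dict(zip(genes_b["gene"], assign_genes_to_tads(genes_b, tads_b)))

    def one_side(dom_q, dom_t, omap, tmap):
        by_dom: dict[str, list] = {}
        for g, d in dom_q.items():
            if d is not None and g in omap:
                by_dom.setdefault(d, []).append(g)
        syn_count_t: dict[str, int] = {}
        for g, d in dom_t.items():
            if d is not None and g in tmap:
                syn_count_t[d] = syn_count_t.get(d, 0) + 1
        conserved, evaluated = [], 0
        for d, genes in by_dom.items():
            if len(genes) < min_genes:
                continue
            evaluated += 1
            counts: dict[str, int] = {}
            for g in genes:
                td = dom_t.get(omap[g])
                if td is not None:
                    counts[td] = counts.get(td, 0) + 1
            if not counts:
                continue
            best_dom = max(counts, key=lambda k: (counts[k], k))
            ratio = counts[best_dom] / len(genes)
            # strict threshold; a perfect mapping (ratio 1) always counts
            ok = ratio > threshold or ratio == 1.0
            if ok and reciprocal:
                denom = syn_count_t.get(best_dom, 0)
                rec = counts[best_dom] / denom if denom else 0.0
                ok = rec > threshold or rec == 1.0
            if ok:
                conserved.append(d)
        return conserved, evaluated

    cons_a, eval_a = one_side(dom_a, dom_b, a2b, b2a)
    cons_b, eval_b = one_side(dom_b, dom_a, b2a, a2b)
    return {
        "conserved_a_ids": sorted(cons_a),
        "conserved_b_ids": sorted(cons_b),
        "n_evaluated_a": eval_a,
        "n_evaluated_b": eval_b,
        "frac_a": len(cons_a) / eval_a if eval_a else np.nan,
        "frac_b": len(cons_b) / eval_b if eval_b else np.nan,
    }


def flag_pairs_in_conserved_tads(
    pairs: pd.DataFrame,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    tads_a: TADSet,
    tads_b: TADSet,
    conserved_a_ids,
    conserved_b_ids,
) -> np.ndarray:
    """True for pairs whose two genes both sit in conserved domains."""
    dom_a = dict(zip(genes_a["gene"], assign_genes_to_tads(genes_a, tads_a)))
    dom_b = dict(zip(genes_b["gene"], assign_genes_to_tads(genes_b, tads_b)))
    ca, cb = set(conserved_a_ids), set(conserved_b_ids)
    flags = []
    for row in pairs.itertuples(index=False):
        flags.append(dom_a.get(row.gene_a) in ca and dom_b.get(row.gene_b) in cb)
    return np.array(flags, dtype=bool)


def conserved_tad_expression_similarity(
    pairs: pd.DataFrame,
    conserved_flags: np.ndarray,
    tpm_a: dict,
    tpm_b: dict,
    min_tpm: float = 0.5,
) -> TestResult:
    """|log2 fold change| of gene pairs in conserved TADs vs other pairs."""
    conserved_flags = np.asarray(conserved_flags, dtype=bool)
    if len(conserved_flags) != len(pairs):
        raise DataError("conserved_flags length does not match pairs")
    lfc, flags = [], []
    for flag, row in zip(conserved_flags, pairs.itertuples(index=False)):
        ta = tpm_a.get(row.gene_a)
        tb = tpm_b.get(row.gene_b)
        if ta is None or tb is None or min(ta, tb) < min_tpm:
            continue
        lfc.append(abs(np.log2(ta / tb)))
        flags.append(flag)
    lfc = np.array(lfc)
    flags = np.array(flags, dtype=bool)
    return mann_whitney(lfc[flags], lfc[~flags],
                        group1="conserved_tad", group2="other")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_synteny_tsv(path) -> SyntenyMap:
    """Combined TSV with header (type, chromA, startA, endA, chromB, startB,
    endB, orientation); rows of type ``block`` are syntenic blocks."""
    df = pd.read_csv(path, sep="\t")
    blocks = df[df["type"] == "block"][BLOCK_COLUMNS].reset_index(drop=True)
    for col in ("startA", "endA", "startB", "endB"):
        blocks[col] = blocks[col].astype(int)
    svs = df[df["type"] != "block"].reset_index(drop=True)
    return SyntenyMap(blocks, svs)


def write_synteny_tsv(synteny: SyntenyMap, path) -> None:
    blocks = synteny.blocks.copy()
    blocks.insert(0, "type", "block")
    svs = synteny.svs.copy()
    cols = ["type"] + BLOCK_COLUMNS
    for c in cols:
        if c not in svs.columns:
            svs[c] = np.nan
    pd.concat([blocks[cols], svs[cols]], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_orthologs_tsv(path) -> OrthologTable:
    return OrthologTable(pd.read_csv(path, sep="\t"))


def write_orthologs_tsv(orthologs: OrthologTable, path) -> None:
    orthologs.pairs.to_csv(path, sep="\t", index=False)
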