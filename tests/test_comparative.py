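"""Cross-species concordance, SV classification and TAD conservation."""

import numpy as np
import pandas as pd
import pytest

from wgdhic import (DataError, OrthologTable, SyntenyMap,
                    classify_sv_compartment, compartment_concordance,
                    conserved_tad_expression_similarity, tad_conservation)
from wgdhic.compartments import CompartmentTrack
from wgdhic.comparative import BLOCK_COLUMNS, read_synteny_tsv, write_synteny_tsv
from wgdhic.hic_matrix import bin_genome
from wgdhic.tads import build_tads


def track_from_labels(labels, resolution=50_000, chrom="chr1"):
    labels = np.asarray(labels, dtype=object)
    bins = bin_genome({chrom: len(labels) * resolution}, resolution)
    pc = np.where(labels == "A", 1.0, np.where(labels == "B", -1.0, np.nan))
    return CompartmentTrack(bins, pc, labels)


def identity_synteny(length, chrom="chr1"):
    blocks = pd.DataFrame([(chrom, 0, length, chrom, 0, length, "+")],
                          columns=BLOCK_COLUMNS)
    return SyntenyMap(blocks, pd.DataFrame(columns=["type"] + BLOCK_COLUMNS))


class TestConcordance:
    def test_identical_tracks(self):
        t = track_from_labels(["A", "B", "A", "B"])
        res = compartment_concordance(t, t, identity_synteny(200_000))
        assert res.same_frac == 1.0 and res.switched_bp == 0

    def test_complementary_tracks(self):
        ta = track_from_labels(["A", "B", "A", "B"])
        tb = track_from_labels(["B", "A", "B", "A"])
        res = compartment_concordance(ta, tb, identity_synteny(200_000))
        assert res.same_frac == 0.0
        assert res.switched_a_to_b_bp == 100_000
        assert res.switched_b_to_a_bp == 100_000

    def test_bp_accounting_invariant(self):
        rng = np.random.default_rng(0)
        la = rng.choice(["A", "B", "NA"], 40)
        lb = rng.choice(["A", "B", "NA"], 40)
        ta, tb = track_from_labels(la), track_from_labels(lb)
        res = compartment_concordance(ta, tb, identity_synteny(2_000_000))
        both = ((la != "NA") & (lb != "NA")).sum() * 50_000
        assert res.same_bp + res.switched_bp == both

    def test_reverse_orientation_mapping(self):
        ta = track_from_labels(["A", "A", "B", "B"])
        tb = track_from_labels(["B", "B", "A", "A"])
        blocks = pd.DataFrame([("chr1", 0, 200_000, "chr1", 0, 200_000, "-")],
                              columns=BLOCK_COLUMNS)
        syn = SyntenyMap(blocks, pd.DataFrame(columns=["type"] + BLOCK_COLUMNS))
        res = compartment_concordance(ta, tb, syn)
        assert res.same_frac == 1.0  # reversed block aligns A run onto A run

    def test_switch_regions_merged(self):
        ta = track_from_labels(["A", "A", "A", "B"])
        tb = track_from_labels(["B", "B", "A", "B"])
        res = compartment_concordance(ta, tb, identity_synteny(200_000))
        assert res.switch_regions_a.to_numpy().tolist() == [["chr1", 0, 100_000]]

    def test_empty_synteny_errors(self):
        t = track_from_labels(["A", "B"])
        syn = SyntenyMap(pd.DataFrame(columns=BLOCK_COLUMNS),
                         pd.DataFrame(columns=["type"] + BLOCK_COLUMNS))
        with pytest.raises(DataError):
            compartment_concordance(t, t, syn)


class TestSvClassification:
    def test_toy_classifications(self):
        ta = track_from_labels(["A", "A", "B", "B"])
        tb = track_from_labels(["A", "A", "A", "B"])
        svs = pd.DataFrame([
            ("inversion", "chr1", 0, 100_000, "chr1", 0, 100_000, "-"),
            ("inversion", "chr1", 100_000, 150_000, "chr1", 100_000, 150_000, "-"),
            ("translocation", "chr1", 10_000, 40_000, "chr1", 150_000, 180_000, "+"),
            ("species_specific_A", "chr1", 0, 50_000, None, None, None, "+"),
            ("species_specific_A", "chr1", 150_000, 200_000, None, None, None, "+"),
        ], columns=["type"] + BLOCK_COLUMNS)
        switch = pd.DataFrame([("chr1", 0, 60_000)],
                              columns=["chrom", "start", "end"])
        out = classify_sv_compartment(svs, ta, tb, switch)
        assert out["inversion"]["n"] == 2
        assert out["inversion"]["frac_unchanged"] == 0.5  # B->A flip on 2nd
        assert out["translocation"]["frac_in_switch"] == 1.0
        assert out["species_specific_A"]["frac_A"] == 0.5

    def test_out_of_bounds_named(self):
        ta = track_from_labels(["A", "B"])
        svs = pd.DataFrame([("inversion", "chr1", 0, 999_000, "chr1", 0,
                             999_000, "-")], columns=["type"] + BLOCK_COLUMNS)
        with pytest.raises(DataError, match="inversion"):
            classify_sv_compartment(svs, ta, ta,
                                    pd.DataFrame(columns=["chrom", "start", "end"]))


def toy_species(n_genes_per_tad, chrom_bins=30, prefix="a"):
    """One chromosome split into equal domains with the given gene counts."""
    n_dom = len(n_genes_per_tad)
    edges = [round(i * chrom_bins / n_dom) for i in range(n_dom + 1)]
    bins = bin_genome({"chr1": chrom_bins * 10_000}, 10_000)
    tads = build_tads({"chr1": np.array(edges[1:-1])}, bins)
    rows = []
    g = 0
    for k in range(len(edges) - 1):
        lo, hi = edges[k] * 10_000, edges[k + 1] * 10_000
        for j in range(n_genes_per_tad[k]):
            pos = lo + 100 + j * max(1, (hi - lo - 200) // n_genes_per_tad[k])
            rows.append((f"{prefix}{g:03d}", "chr1", pos, pos + 50))
            g += 1
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return tads, genes


class TestTadConservation:
    def _identity_orthologs(self, genes_a, genes_b):
        return OrthologTable(pd.DataFrame({"gene_a": genes_a["gene"],
                                           "gene_b": genes_b["gene"]}))

    def test_reflexive_identity(self):
        tads, genes = toy_species([8, 8, 8])
        orth = OrthologTable(pd.DataFrame({"gene_a": genes["gene"],
                                           "gene_b": genes["gene"]}))
        for thr in (0.5, 0.7, 0.95, 1.0):
            out = tad_conservation(tads, tads, orth, genes, genes,
                                   threshold=thr)
            assert out["frac_a"] == out["frac_b"] == 1.0

    def test_eight_of_ten_is_conserved(self):
        tads_a, genes_a = toy_species([10, 6])
        tads_b, genes_b = toy_species([10, 6], prefix="b")
        # move 2 genes of the first A-TAD into the second B-TAD by remapping
        orth = pd.DataFrame({"gene_a": genes_a["gene"],
                             "gene_b": genes_b["gene"]})
        orth.loc[0, "gene_b"] = genes_b["gene"].iloc[12]
        orth.loc[12, "gene_b"] = genes_b["gene"].iloc[0]
        orth.loc[1, "gene_b"] = genes_b["gene"].iloc[13]
        orth.loc[13, "gene_b"] = genes_b["gene"].iloc[1]
        out = tad_conservation(tads_a, tads_b, OrthologTable(orth),
                               genes_a, genes_b)
        # first A-TAD: 8/10 orthologs stay in one B-TAD -> conserved (>0.7);
        # second: 4/6 = 0.67 -> not conserved
        assert "tad_00000" in out["conserved_a_ids"]
        assert out["frac_a"] == 0.5

    def test_small_tads_excluded_from_denominator(self):
        tads, genes = toy_species([5, 8])
        orth = OrthologTable(pd.DataFrame({"gene_a": genes["gene"],
                                           "gene_b": genes["gene"]}))
        out = tad_conservation(tads, tads, orth, genes, genes, min_genes=6)
        assert out["n_evaluated_a"] == 1  # 5-gene domain discarded

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        tads_a, genes_a = toy_species([8, 8, 8])
        tads_b, genes_b = toy_species([8, 8, 8], prefix="b")
        gb = genes_b["gene"].to_numpy().copy()
        rng.shuffle(gb[:12])  # scramble half the orthology
        orth = OrthologTable(pd.DataFrame({"gene_a": genes_a["gene"],
                                           "gene_b": gb}))
        prev = 1.1
        for thr in np.arange(0.5, 0.96, 0.05):
            out = tad_conservation(tads_a, tads_b, orth, genes_a, genes_b,
                                   threshold=float(thr))
            assert out["frac_a"] <= prev + 1e-12
            prev = out["frac_a"]

    def test_no_orthologs_errors(self):
        with pytest.raises(DataError):
            OrthologTable(pd.DataFrame(columns=["gene_a", "gene_b"]))

    def test_duplicate_orthologs_rejected(self):
        with pytest.raises(DataError):
            OrthologTable(pd.DataFrame({"gene_a": ["g1", "g1"],
                                        "gene_b": ["h1", "h2"]}))


class TestConservedTadExpression:
    def test_planted_similarity_detected(self):
        rng = np.random.default_rng(0)
        n = 200
        genes_a = [f"a{i}" for i in range(2 * n)]
        genes_b = [f"b{i}" for i in range(2 * n)]
        pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
        flags = np.array([True] * n + [False] * n)
        lfc = np.concatenate([np.abs(rng.normal(0, 0.3, n)),
                              np.abs(rng.normal(0, 1.2, n))])
        tpm_a = {g: 10.0 for g in genes_a}
        tpm_b = {g: 10.0 * 2 ** l for g, l in zip(genes_b, lfc)}
        res = conserved_tad_expression_similarity(pairs, flags, tpm_a, tpm_b)
        assert res.pvalue < 0.01
        assert res.direction == "conserved_tad<other"

    def test_low_expression_filtered_and_empty_group_errors(self):
        pairs = pd.DataFrame({"gene_a": ["a1", "a2", "a3", "a4"],
                              "gene_b": ["b1", "b2", "b3", "b4"]})
        tpm_a = {"a1": 1.0, "a2": 1.0, "a3": 1.0, "a4": 0.1}
        tpm_b = {"b1": 2.0, "b2": 2.0, "b3": 2.0, "b4": 2.0}
        with pytest.raises(DataError):
            conserved_tad_expression_similarity(
                pairs, np.array([False, False, False, True]), tpm_a, tpm_b)


class TestSyntenyIO:
    def test_roundtrip(self, tmp_path):
        blocks = pd.DataFrame([("chr1", 0, 100_000, "chr1", 0, 100_000, "+")],
                              columns=BLOCK_COLUMNS)
        svs = pd.DataFrame([("inversion", "chr1", 10_000, 20_000, "chr1",
                             10_000, 20_000, "-")],
                           columns=["type"] + BLOCK_COLUMNS)
        syn = SyntenyMap(blocks, svs)
        write_synteny_tsv(syn, tmp_path / "syn.tsv")
        back = read_synteny_tsv(tmp_path / "syn.tsv")
        assert len(back.blocks) == 1 and len(back.svs) == 1
        assert back.svs["type"].iloc[0] == "inversion"
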