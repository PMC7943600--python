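# wgdhic

Comparative Hi-C analysis of 3D genome organization between two plant
species that share a whole-genome duplication (WGD).

After a WGD, duplicated gene pairs (paralogs) gradually diverge in
expression during diploidization. This package implements the full
desk-scale analysis linking that divergence to chromatin architecture
across two related genomes:

* **Contact-matrix normalization** — ICE (iterative correction) balancing
  of binned Hi-C count matrices, per-chromosome distance-decay estimation
  and observed/expected (O/E) transformation.
* **A/B compartments** — per chromosome, the Pearson correlation matrix of
  the O/E cis matrix is decomposed and bins are labeled by the sign of the
  first principal component (PC1), oriented so the gene-dense sign is the
  (euchromatic) A compartment; plus compartment fractions, Fisher tests on
  A/B counts, feature comparisons by compartment (Mann–Whitney *U*), and
  A–A trans-interaction preference.
* **TADs** — TopDom-style calling on the 10-kb ICE matrix: the *binSignal*
  of bin *i* is the mean contact between the upstream window
  `[i−w+1, i]` and the downstream window `[i+1, i+w]`; local minima are
  boundaries, optionally filtered by a rank-sum test on per-diagonal
  z-scored contacts; plus gene/methylation profiles around boundaries.
* **Cross-species conservation** — bp-weighted compartment concordance
  over syntenic blocks (orientation-aware), classification of structural
  variants (inversions, translocations, species-specific regions) against
  compartment status, and orthology-based TAD conservation: a domain is
  conserved when more than 70 % of its syntenic genes (≥ 6 required) map
  into a single domain of the other species.
* **WGD-paralog spatial statistics** — pairs selected by synonymous
  substitution rate 0.05 ≤ Ks ≤ 0.6; expression-bias classes by the
  twofold TPM rule (pairs with min TPM < 0.5 excluded); ICE trans contact
  between the two gene bins; per-gene interaction scores (mean cis O/E);
  trans colocalization by an upper-tail binomial test with a
  coverage-weighted null `p0 = m_i·m_j / n²` and Benjamini–Hochberg FDR;
  a 1000-draw randomization null; methylation-difference comparisons
  (CG/CHG/CHH) between colocalized and non-colocalized pairs; and
  cross-species conservation of colocalization with a Fisher exact test.
* **Synthetic data** — a generator that plants all of the above
  (checkerboard compartments, nested TADs, distance decay, coverage
  biases, label switching between species, structural variants,
  colocalized and expression-biased paralog pairs, methylation structure)
  with serialized ground truth, so every stage is verifiable end to end.

## Worked example

```python
from wgdhic import (SimulationConfig, generate_dataset,
                    compartment_concordance, tad_conservation)
from wgdhic.pipeline import analyze_species
from wgdhic.paralog_interactions import (TransColocModel, build_pair_table,
                                         frequency_bias_test)

ds = generate_dataset(SimulationConfig(seed=1))
res = {s: analyze_species(d.matrix_hi, d.matrix_lo, d.genes)
       for s, d in ds.species.items()}
a, b = ds.config.species
conc = compartment_concordance(res[a].track, res[b].track, ds.synteny)
tc = tad_conservation(res[a].tads, res[b].tads, ds.orthologs,
                      ds.species[a].genes, ds.species[b].genes)
d = ds.species[a]
table = build_pair_table(d.paralogs, d.genes, res[a].hi.ice, res[a].hi.oe,
                         d.matrix_hi, model=TransColocModel(d.matrix_hi))
t = frequency_bias_test(table)
```

prints (assembled from the objects above):

```
A-compartment fraction: 50.3% (speciesA), 48.0% (speciesB)
TADs called: 136 (speciesA), median size 100 kb
syntenic compartment concordance: 69.6%
TAD conservation: 81.6% (speciesA), 79.6% (speciesB)
colocalized paralog pairs (speciesA): 48 of 280 tested at FDR < 0.05
biased vs similar trans contact: U=3466, p=2.42e-15 (biased<similar)
```

The generator planted a 30 % compartment-label switch on the syntenic
length, so ~70 % concordance is the expected recovery; the 48 colocalized
pairs recover the 50 planted ones (recall 0.96 at FDR < 0.05); and the
planted damping of trans contact for expression-biased pairs is recovered
with the correct direction (biased < similar).

## Command line

Each stage is exposed as a thin subcommand over the library:

```bash
wgdhic simulate --seed 3 --out data/
wgdhic normalize --matrix data/speciesA/matrix_10kb.tsv \
    --bins data/speciesA/bins_10kb.bed --out-ice ice.tsv --out-oe oe.tsv
wgdhic compartments --matrix data/speciesA/matrix_50kb.tsv \
    --bins data/speciesA/bins_50kb.bed --genes data/speciesA/genes.tsv \
    --out trackA
wgdhic tads --matrix data/speciesA/matrix_10kb.tsv \
    --bins data/speciesA/bins_10kb.bed --out tadsA
wgdhic compare --track-a trackA.bedgraph --track-b trackB.bedgraph \
    --bins-a data/speciesA/bins_50kb.bed --bins-b data/speciesB/bins_50kb.bed \
    --synteny data/synteny.tsv --out report/
wgdhic paralogs --raw data/speciesA/matrix_10kb.tsv \
    --bins data/speciesA/bins_10kb.bed --pairs data/speciesA/paralogs.tsv \
    --genes data/speciesA/genes.tsv --meth data/speciesA/methylation.tsv \
    --out pairsA.tsv
```

Contact matrices are plain 3-column TSV (upper-triangle COO
`bin_i  bin_j  value`) with a sidecar BED bin table; tracks are
bedGraph/BED; all other tables are headered TSV.

## Documentation

`docs/methods.md` describes the models, the statistical procedures, the
synthetic-data design, numerical conventions and known limitations.
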