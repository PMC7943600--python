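# Methods

This note documents the models and procedures implemented in `wgdhic`, the
design decisions taken where conventions were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Contact-matrix normalization

A binned Hi-C map is a symmetric non-negative matrix over genome-wide bins
(0-based half-open coordinates, BED dialect on disk; the last bin of a
chromosome may be short). Its normalization state moves strictly
`raw → ice → oe`; each operation checks the state of its input.

**ICE balancing.** Per-bin coverage biases in Hi-C are well approximated as
multiplicative: `raw(i,j) ≈ b_i b_j t(i,j)` with `t` the true contact
propensity. ICE finds `b` such that the corrected matrix
`raw(i,j)/(b_i b_j)` has equal marginal sums over unmasked bins. The
implementation uses the multiplicative marginal update with a square-root
damping factor: the plain simultaneous update can enter period-2
oscillations on matrices with bipartite-like support (e.g. zero diagonals),
while the damped update converges to the same fixed point. Convergence is
declared when the relative variance of the unmasked marginals drops below
`tol` (default `1e-5`; `max_iter` 200). Bins with zero raw marginal and the
lowest 2 % (`low_coverage_frac`) of the remaining raw marginals are masked
before balancing and carry no entries afterwards. The corrected matrix is
rescaled to the raw total mass, and the bias vector is returned (NaN at
masked bins). On symmetric matrices the result agrees entrywise with
alternating iterative proportional fitting run to convergence (tested to
`1e-8` and better).

**Identifiability caveat.** The planted decomposition `b_i b_j f(|i−j|)` is
recoverable by marginal balancing only when `f`'s row sums are constant.
For a generic decaying kernel on a linear chromosome they are not: exact
ICE then absorbs a genuine edge correction into the bias vector, and the
subsequent O/E matrix is not identically 1 (deviations of tens of percent
near chromosome ends are expected and correct). The exactness tests
therefore use kernels of the form `f(d) = g(min(d, n−d))` (a function of
the circular distance, hence constant row sums), for which bias recovery
and O/E self-normalization hold to machine precision. On the structured
synthetic genome the recovered biases correlate with the planted ones at
r ≈ 0.96; the remaining variance is the structural marginal variation
(compartments, TADs, A–A trans preference) that balancing legitimately
removes, not an estimation error.

**Distance decay and O/E.** The expected contact at bin separation `d` is
the arithmetic mean over all unmasked cis bin pairs at that separation,
computed per chromosome; unstored pairs count as zeros (dense convention;
a flag switches to stored-entries-only means). The profile covers every
separation occurring in the matrix, including the diagonal (`d = 0`), so
that every stored cis entry has a defined expectation. O/E divides each
cis entry by `expected(d)`; entries with zero expectation are removed with
a warning. Trans entries are dropped by default; optional modes keep them
raw or scale each chromosome-pair block by its mean.

## A/B compartments

Per chromosome, the O/E cis matrix (50-kb resolution by default) is reduced
to the Pearson correlation matrix of its rows (a flag switches to PCA of
the O/E matrix itself); zero-variance and masked rows are excluded, and a
chromosome needs ≥ 10 usable bins. The matrix is column-centered and its
first principal component extracted by SVD. Because the eigenvector sign is
arbitrary, the track is oriented by gene density: bins on the side with the
higher mean gene-midpoint count per bin become A. An exact density tie
falls back to transposable-element density (lower in A); a further tie is
an error rather than a silent guess. Bins with PC1 exactly 0, masked bins
and skipped chromosomes are `NA`.

Downstream statistics: compartment fractions are reported over labeled
genomic length; A/B bin counts of two tracks are compared by a two-sided
Fisher exact test; per-bin features (expression, TE density, methylation)
are compared between A and B bins by a two-sided Mann–Whitney *U*; and the
trans-preference table reports the mean ICE trans contact for each label
combination over all unmasked interchromosomal bin pairs, zeros included.

## TAD calling

The binSignal of bin `i` is the mean ICE contact between the upstream
window `[i−w+1, i]` and the downstream window `[i+1, i+w]`, truncated at
chromosome edges, zeros at unstored positions included; `w` defaults to 5
bins (50 kb at 10-kb resolution). Masked bins are excluded from windows and
carry NaN signal. Boundaries are local minima of the signal, with a
deterministic plateau rule (the leftmost bin of a flat minimum wins). A
minimum at bin `i` separates the two windows at the edge between bins `i`
and `i+1`, so the domain split is placed at `i+1`. Runs of ≥ `w`
consecutive masked bins split domains at the run edges and host no
boundaries. Domains are the intervals between consecutive splits and always
tile the chromosome; no minimum size is imposed at calling time (the
≥ 6-gene rule applies only to conservation analysis).

**Statistical boundary filter.** At realistic sequencing depth the raw
local-minima rule overcalls boundaries substantially: sampling noise plants
shallow minima in flat domain interiors (measured on the default synthetic
genome: precision ≈ 0.6 at perfect recall). The filter re-tests each
candidate with a one-sided rank-sum test of within-window versus
cross-window contacts at `alpha = 0.05`, computed on values z-scored per
diagonal so that distance decay does not confound the comparison (without
this normalization the test is uninformative, because within-window pairs
sit at systematically shorter distances). The filter is **on by default**
in `call_tads`; the unfiltered rule remains available as `filter="none"`,
and `detect_boundaries` itself defaults to the pure minima rule. With the
filter, boundary precision and recall on the planted genome are ≈ 1.0.

**Boundary profiles.** Features (gene midpoints grouped e.g. by TPM
quartile, or methylation measurements with a value column) are aggregated
in 1-kb windows over ± 30 kb around each boundary; densities are per window
per boundary, levels are window means.

## Cross-species conservation

**Compartment concordance** walks every syntenic block in steps of the
track resolution, maps each segment to the partner genome (reverse
orientation maps offsets from the block end) and compares the labels at the
segment midpoints. Only segments labeled A/B in both species count; the
result is bp-weighted (same, switched per direction, fraction identical),
and the switched segments are merged into compartment-switch region BEDs
per genome.

**Structural variants.** An interval's compartment status is its
majority label by overlap length (ties → NA, excluded). Inversions are
"unchanged" when the majority label agrees between the species;
translocations are "in a switch region" when ≥ 50 % of the source interval
overlaps the switch regions; species-specific regions report the fraction
labeled A in the owning genome.

**TAD conservation.** Genes are assigned to domains by midpoint. For each
domain with ≥ 6 genes having orthologs, the domain of the other species
capturing the most of those orthologs is found; the domain is conserved
when that count exceeds 70 % of its syntenic genes (a perfect mapping,
ratio exactly 1, always counts — this keeps self-comparison fully conserved
at every threshold). The denominator is always the query domain's syntenic
gene count; a strict mode additionally requires the reciprocal ratio to
pass. Gene pairs in conserved domains are compared with other pairs on
|log2 TPM fold change| (both TPM ≥ 0.5) by Mann–Whitney *U*.

## WGD-paralog spatial statistics

Pairs with 0.05 ≤ Ks ≤ 0.6 (inclusive) are retained as WGD-derived.
Expression-bias classes (twofold rule on TPM, minimum 0.5, symmetric in the
two genes): `excluded` if min(TPM) < 0.5, `biased` if max/min > 2, else
`similar`. Genes map to 10-kb bins by midpoint.

*Interaction frequency* is the ICE trans entry between the two gene bins
(0 if unstored, NaN if masked; same-chromosome pairs are a contract
error). *Interaction score* is the mean O/E contact of a gene's bin with
all unmasked bins of its chromosome at separations ≥ 2 bins (the exclusion
avoids diagonal dominance). Two tests relate these to expression: biased
vs similar pairs on interaction frequency, and within biased pairs the
score of the high- vs low-TPM copy; both two-sided Mann–Whitney *U* with
group sizes reported.

*Colocalization.* For a pair of bins (i, j) on chromosomes (c1, c2), with
`n` the total raw trans count between c1 and c2 and `m` the per-bin trans
marginals restricted to that chromosome pair, the null probability of one
contact landing on (i, j) is the coverage-weighted `p0 = m_i m_j / n²`
(a uniform-null mode `p0 = 1/#bin pairs` is available); the p-value is the
exact upper binomial tail `P(X ≥ x_ij | n, p0)`. Benjamini–Hochberg
adjustment runs across all tested pairs and `colocalized` means adjusted
p strictly below 0.05. The test requires integer raw counts. The
randomization null redraws the same number of distinct interchromosomal
gene pairs uniformly from all annotated genes (not only paralogs), applies
the identical test per draw, and reports the empirical p-value with the
add-one rule `(1 + #{null ≥ observed})/(reps + 1)`; 1000 draws by default.

*Methylation similarity* compares |level(gene1) − level(gene2)| per context
(CG, CHG, CHH; levels must lie in [0, 1]) between colocalized and
non-colocalized pairs. *Colocalization conservation* maps each colocalized
pair through the one-to-one ortholog table and counts pairs colocalized in
both species; the Fisher exact test contrasts the overlap with independent
random sets of the same sizes over a declared universe of candidate pairs.

## Synthetic data: what it emulates

The default configuration is two species, three chromosomes of 5 Mb,
matrices at 10 kb (500 bins/chromosome) and 50 kb — small enough for
exhaustive testing, large enough for stable PCA and boundary statistics.

Planted structure, with defaults and reasons:

| parameter | default | meaning / rationale |
|---|---|---|
| `compartment_block_len` | 250 kb | checkerboard A/B block; 5 compartment bins, megabase-scale pattern scaled to the toy genome |
| `decay_exponent` | 1.0 | contact ∝ (d+1)^−1, the canonical cis decay |
| `cis_depth` | 2 × 10⁶ | expected cis counts per chromosome |
| `trans_depth` | 1 × 10⁶ | expected counts per chromosome pair; yields a ~1/3 trans fraction, typical of Hi-C libraries, and makes the planted 5× colocalization signal recoverable (recall ≥ 0.9) |
| `bias_sd` | 0.25 | lognormal σ of per-bin coverage biases (≈ ±60 % range) |
| `tad_enrichment` | 2.0 | within-domain contact multiplier; domains of 80–200 kb nested inside compartment blocks, so compartment edges are also domain edges |
| `compartment_same/cross_factor` | 1.4 / 0.6 | cis checkerboard contrast driving the O/E correlation structure |
| `aa_trans_multiplier` | 2.0 | A–A trans preference |
| `gene_rate_a/b` | 6 / 3 per 50-kb bin | twofold gene-density enrichment in A at a poplar-like overall density (~5 genes/50 kb) |
| `expression_a_boost` | 4× | elevated transcription in A bins |
| `n_paralog_pairs` | 400 | 30 % Ks decoys outside [0.05, 0.6]; ~50 colocalized pairs (5× trans counts) and ~50 % biased-expression pairs (fold 2.3–8, trans damped 0.5×) among the in-window pairs |
| `switch_frac` | 0.3 | compartment blocks label-switched in species B, drawn only from blocks fully inside syntenic blocks so the planted switched fraction of syntenic length is exact |
| methylation | A: 0.35/0.15/0.05, B: 0.65/0.40/0.15 (CG/CHG/CHH) | heterochromatic B elevated; colocalized pairs get correlated levels (σ = 0.03) |

Counts are Poisson (a negative-binomial switch adds overdispersion).
Synteny is an identity mapping segmented on the compartment-block grid,
with species-specific carve-outs, inversions (equal coordinates, `-`
orientation) and translocations placed length-weighted within syntenic
runs. Orthologs are the shared genes; each species additionally gets
private genes in its own A bins. All randomness flows from the single
config seed; the same seed writes a byte-identical dataset directory.

**What passing tests do not show.** The generator emulates the statistical
skeleton of real two-species Hi-C data, not its full complexity: no
restriction-fragment or mappability structure beyond smooth multiplicative
biases, no nested/hierarchical TADs or loops, clean block compartments
rather than gradual transitions, identity synteny without real breakpoint
geometry or repeat-driven unalignable regions, and independent Poisson
counts without the spatial correlation of real ligation noise. Recovery
rates measured here are therefore upper bounds on real-data performance;
the logic, exactness and calibration results (oracle equivalence, FDR
control, determinism) transfer directly.

## Numerical conventions and degenerate inputs

* Coordinates 0-based half-open throughout; on-disk formats are BED,
  bedGraph, headered TSV and upper-triangle COO TSV.
* Plateau minima: leftmost bin; PC1 orientation ties: TE density, then
  error; interval majority-label ties: NA; best-target-domain ties in TAD
  conservation: lexicographically smallest domain id (deterministic).
* Mann–Whitney groups need n ≥ 3, otherwise a data error; empty
  colocalized sets skip the Fisher test with a warning.
* Asymmetric matrices, negative values, non-integer counts where raw
  counts are required, out-of-bounds SV records and unknown chromosomes
  raise data errors naming the offender; invalid parameters raise
  configuration errors naming the field.
* Significance conventions: BH-adjusted p strictly below the cutoff;
  Ks window inclusive at both ends; "more than twofold" strict.

## Known limitations

* Compartment calling assigns one PC per chromosome; sub-compartments and
  cases where PC1 tracks chromosome arms rather than A/B are out of scope.
* TAD calling is single-level (no nesting, no loops) and the boundary
  filter's alpha is a fixed default, not adaptively calibrated.
* The trans O/E expectation (chromosome-pair mean) is a declared
  convention; trans statistics are otherwise computed on ICE counts.
* The colocalization null conditions on per-bin trans marginals but not on
  3D distance structure; strong compartment-level trans preference is
  partially absorbed by the marginals only.
* The randomization universe is all annotated interchromosomal gene pairs;
  restricting it to paralog-like pairs would give a more conservative null.
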