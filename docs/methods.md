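# Methods notes

## Model and scope

`scmod` models plate-based single-cell sequencing of cytosine modifications
with *direct* conversion chemistry: a modified cytosine on the template
strand is read as T (on a bottom-strand template this appears as G→A
relative to the top reference strand), while unmodified C is read as C up
to a small false-positive probability. Two chemistries are shipped as
presets of the per-state conversion probabilities
(`p_read_T_given_{mC,hmC,uC}`): `sctaps-paper` (0.966 / 0.850 / 0.0019)
profiles 5mC+5hmC jointly, `sccaps-paper` (0.0025 / 0.930 / 0.0038)
profiles 5hmC alone. Conversion events are independent across sites,
molecules and cells — a deliberate simplification (see *Limitations*).

The package covers the dry-lab arc of such an assay: reference/truth
simulation → barcoded read simulation → demultiplexing → methylation
calling → spike-in and cell QC → region-level quantification → clustering
and marker detection. Alignment itself is out of scope: the simulator emits
a truth-position SAM (all-match CIGARs at the fragment's true coordinates)
so the caller is testable without an aligner; externally aligned SAM/BAM
with a `CB` cell tag works identically through `calls.load_sam`.

## Coordinates and strand conventions

All coordinates are 0-based, half-open. The strand of a CpG call is the
strand of its cytosine; the bottom-strand partner of the CpG whose C sits
at `p` is the G at `p+1`. `merge_cpg_strands` collapses the pair onto the
C's position, summing counts.

The simulated library is **directional**: R1 always reports the converted
template strand. This fixes the caller's inference rule — template is `top`
iff (R1 ∧ forward) ∨ (R2 ∧ reverse) — which is the simplest model
consistent with Tn5 tagmentation followed by PCR. `infer_template_strand`
is the single point to change for non-directional protocols.

## Simulator

* **Genome**: i.i.d. bases at a configurable GC fraction (default 0.5).
  No repeat structure. CpH sites are unmodified by default.
* **Spike-ins**: three contigs — `spike_mC` (2 kb, every CpG cytosine on
  both strands carries 5mC; a random-sequence stand-in for the fully
  methylated lambda control, since only its all-methylated property enters
  the estimators), `spike_uC` (2 kb, no modifications), `spike_hmC`
  (oligo-like, default 400 bp, 5hmC only at declared positions, defaulting
  to all CpG cytosines). Eligible sites for rate estimation are exactly
  these truth sets; for the uC control, *all* cytosines in any context.
* **Methylome**: per-CpG states drawn independently with probabilities
  `global_mC`/`global_hmC`, symmetric across strands by default. Around
  each TSS both rates are multiplied by `1 − depth·k(d)` with a triangular
  kernel `k` of half-width `tss_dip_width` (default 2 kb) and depth 0.8,
  emulating the joint 5mC/5hmC depletion at transcription start sites; the
  published figure shows the dip qualitatively, so width and depth are this
  package's own defaults. The hippocampal global 5hmC levels (neuron 22.04%,
  non-neuron 9.29%) are used as generating per-CpG probabilities; under the
  default shared-methylome scope the pooled ratio and the per-cell mean
  coincide in expectation, and `MethylomeTruth.scope` exposes per-cell
  overrides when the distinction matters.
* **Tagmentation**: fragments land on a spike-in contig with probability
  `spikein_fraction` (experimental mass fraction ~0.1%; fixtures raise it
  for statistical power), and within either pool the contig is chosen
  length-weighted — i.e. uniform per base. Insert length is uniform on
  `insert_range` (default 200–700 bp, a stand-in: the published 500–700 bp
  size selection includes adapters), clipped to the contig; template strand
  is Bernoulli(0.5).
* **Reads**: 120-bp paired-end FR reads off the converted template;
  fragments shorter than the read length yield truncated, fully overlapping
  pairs. Sequencing errors are uniform substitutions (default 0.1%,
  constant `I` quality strings); no indels, adapters or quality models.
  PCR duplicates are modelled by re-emitting a configurable fraction of
  fragments once, with fresh conversion/error draws per copy — duplicate
  marking is positional, so caller correctness does not depend on copies
  being sequence-identical.
* **Barcodes**: 8 i5 × 12 i7 tags of length 8, drawn deterministically
  with pairwise Hamming distance ≥ 3 within each index set, so
  one-mismatch demultiplexing is uniquely decodable. Barcodes ride in the
  read name (the plate protocol demultiplexes by name); an inline mode
  prepends them to the read sequence instead.

## Caller and filters

Reads with MAPQ < 10 (the "uniquely mapped" gate) or a duplicate flag are
excluded; query positions within 10 bp of either physical read end are
ignored (end repair and tagmentation artefacts concentrate there). Where
mates overlap, the overlap is counted once with R1 preferred — counting it
twice would double-weight a single template molecule. Base calls other than
the converted/unconverted pair are tallied as `n_other` and never enter
level denominators: a level is the modified fraction of C-or-T
observations. Supported CIGAR ops are M/=/X/S/I/D; reads with other ops are
skipped with a warning. Duplicate marking groups fragments per cell by
(contig, start, end, template strand) and keeps the first by name order;
it is per cell because identical coordinates in different cells are
distinct molecules.

QC counts "properly mapped reads" with the separate MAPQ > 1 post-dedup
definition, and cells pass iff that count lies in [500000, 3000000].

## Quantification

Region levels are pooled counts over sites in `[start0, end0)`; regions
with fewer than 5 total calls are reported missing rather than as noisy
levels (default `min_calls=1` for browser-style bin tracks). Chromatin-state
aggregation is the same operation over a BED of labelled intervals. The
metagene uses scale-regions semantics (real-coordinate 5-kb flanks, gene
body linearly rescaled to 5 kb, 10-bp bins → 1500 bins, minus-strand genes
reversed); each covered site contributes its level once per gene and bins
average pooled sites across genes — pooled-site means rather than per-gene
profile means, chosen because single-cell per-gene profiles are mostly
empty at realistic coverage.

## Clustering and markers

Cells × genes levels are filtered (QC-failing cells out; genes missing in
> 80% of cells out; constant genes out), mean-imputed and z-scored **for
the reduction only**; raw levels with missingness are retained for testing.
PCA (20 PCs) feeds either a shared-nearest-neighbor graph (k = 15, Jaccard
edge weights) partitioned by Leiden modularity optimization at resolution
1.0, or k-means; the published analysis used an external package's
equivalent of the graph route, and the acceptance surface here is recovery
of simulated population structure, not label-identical output. If every
gene is constant (e.g. duplicated cells) there is no structure and all
cells receive one label. t-SNE (perplexity min(30, (n−1)/3)) is attached
for visualization only. PCs, neighbors, resolution and perplexity are this
package's defaults, not published values.

Markers use a two-sided Wilcoxon rank-sum test on non-missing levels
(in-cluster vs rest), gated by `min.pct = 0.25` on the *detected*
(non-missing) fraction — the closest analogue of expression-positive
fraction for coverage-limited data — with Benjamini–Hochberg adjustment and
selection at `p_adj < 0.05`. Missing levels are excluded rather than
imputed, because imputation would fabricate evidence.

## Numerical and statistical choices

* Spike-in rates: pooled proportions with Wilson 95% intervals (Wald
  degenerates at the ~0.2–0.4% false-positive rates). Classes with zero
  calls are reported absent, not as 0. Rates are pooled over cells by
  default (one number per library), with per-cell rates available.
* Saturation: one seeded permutation of reads; each fraction takes a
  prefix, so subsamples are nested and the curve is monotone by
  construction.
* Ties/determinism: every stochastic step takes a seed
  (`numpy.random.default_rng`); composite simulations derive sub-seeds via
  `SeedSequence.spawn`; duplicate keepers and marker orderings use stable
  sorts.
* Degenerate inputs: fragments shorter than the read length truncate;
  genes shorter than a metagene bin rescale through the same linear map;
  `n_pcs` larger than the data is clamped with a warning; correlation
  requires ≥ 3 common non-missing observations.

## Problem sizes

Unit tests run on 3–20-kb genomes with hundreds to thousands of fragments;
the spike-in rate report in `scripts/acceptance.py` uses 8 cells × 8000
fragments at spike-in fraction 0.96, giving roughly 3×10⁵ calls on the
methylated control, 10⁵ on the hmC oligo and over 10⁶ on the unmodified
control per preset — enough that three binomial standard errors sit well
inside a few percent relative even for the sub-percent false-positive
rates. Clustering acceptance uses 48+48 cells × 200 genes with 30 genes
shifted by 0.15 at ~30 calls per gene-cell.

## What the simulations do and do not show

The generator reproduces the *statistical* structure the pipeline's
estimators rely on — known-state spike-ins, binomial conversion, barcode
structure, strand symmetry, coverage sparsity, TSS depletion, population
level shifts — so passing tests demonstrate correct calling arithmetic,
filter behaviour, estimator calibration and recovery of planted structure.
They do not demonstrate performance on real genomes: no repeats or mapping
ambiguity (MAPQ is uniformly 60 in truth alignments), no C→T SNVs (which
masquerade as permanently modified sites), no CpH methylation by default,
no coverage or amplification bias, no index hopping and no indel errors.
Absolute CpG-coverage figures from real libraries are likewise out of
scope, as they depend on genome size and sequencing depth.
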