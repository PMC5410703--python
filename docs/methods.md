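# Methods

## Weighted methylation

All levels are *weighted* methylation: for a region and sequence context,
`m = Σ mc / Σ cov`, summing methylated and total read counts over every
cytosine record in the region. The estimator is coverage-weighted, so a
deeply covered site contributes proportionally to its read support; at ~1×
mean depth it remains unbiased where per-site fractions are not. When the
denominator is zero the level is *undefined* (NaN), never 0 — the distinction
matters when averaging across genes.

Contexts are CG, CHG and CHH (H ∈ {A,C,T}), assigned from the trinucleotide
string of each record; symmetric CpG positions on the two strands are kept
as independent records (no strand merging), consistent with read-count
pooling.

## Metagene profiles

Each gene body (start to stop codon, 1-based inclusive) is divided into 20
windows with boundaries at `round(i·L/20)`; a cytosine belongs to exactly
one window by its position (right-exclusive boundaries). Flanks of 1000 or
4000 bp are divided into 20 equal windows. Minus-strand genes are reversed
so profiles read 5'→3'. The profile value for a window is the **unweighted
mean of per-gene weighted levels** over genes with coverage in that window;
genes shorter than 20 bp are excluded from profiling (but still summarised
per gene). Flank windows overlapping neighbouring genes are *not* masked —
a documented caveat, since dense gene spacing bleeds genic methylation into
flank averages. The resampling control (`resampled_metaplot`) averages the
profile over repeated seeded draws of k genes without replacement,
mitigating gene-number bias when comparing sets of different size.

## gbM classification

Per gene and context, the pooled methylated read count k out of n total
reads is tested against the context's background p0 with the one-sided
exact binomial upper tail P(X ≥ k), X ~ Binomial(n, p0). The background is
the weighted methylation of *all* coding sequence in the dataset, clamped
to [1e−9, 1−1e−9]; this background is estimated from the same records being
tested — a circularity inherent to the design, documented rather than
"corrected". P-values are Benjamini–Hochberg adjusted **per context across
genes** (the joint genes×contexts scope is available via `fdr_scope`).

A gene is **gbM** iff it has reads on ≥ 10 covered CG sites, q(CG) < α and
q(CHG) > α and q(CHH) > α (α = 0.05). Contexts with zero coverage have no
test; by default an undefined non-CG test counts as "not enriched" so that
sparse genes remain classifiable (`strict_noncg=True` flips this).
Remaining labels are derived from the same q-values: no significant context
→ `unmethylated`; ≥ 2 significant → `multi_context`; exactly CHG or CHH →
`mCHG_enriched` / `mCHH_enriched`; too few covered CG sites (or no CG
reads) → `unclassified`. Only the gbM label carries a substantive contract;
the others are reporting conveniences.

The binomial unit is **reads** (default): the classification threshold
counts reads mapping to CG sites, and read-level testing stays defined at
~1× coverage. A site-level mode (`unit="sites"`: sites with ≥ 1 methylated
read out of covered sites) ships for cross-checking; it is cruder because a
single non-converted read "calls" a site at high coverage.

## Coverage downsampling and calibration

`downsample_records` thins each site's methylated and unmethylated reads
independently with retention probability r = target / current mean coverage
(per-read Bernoulli thinning, Binomial(mc, r) + Binomial(cov−mc, r)). The
expectation of weighted methylation is preserved exactly; the suite
verifies unbiasedness over seeds.

The calibration regresses thinned-to-1× levels (y) on deep levels (x)
across reference datasets by OLS — slope, intercept and residual SD are
exposed on `CalibrationResults`. Estimating a deep level from a shallow
observation is an inverse-prediction (calibration) problem: the point
estimate is x̂ = (y − intercept)/slope and the 95% interval is the set of x
whose 95% *prediction band* covers y, solved in closed form (a Fieller-type
quadratic) and truncated to [0,1]. Prediction-band inversion was chosen
over re-regressing x on y because it is the statistically standard
construction and avoids the bias of the naive reverse fit (the reverse fit
remains available for comparison). Whether published error bars of this
kind are confidence or prediction intervals is usually unstated; outputs
here are labelled as prediction-band inversions. Calibration is fitted per
context. When the fitted slope is ≤ 0 the calibration is rejected rather
than inverted.

## Longest-ORF transcript filter

For transcriptome-only assemblies, each transcript is scanned in all six
frames for the longest ORF that starts with ATG and ends with TAA/TAG/TGA
(stop included in the span) with no internal stop; transcripts without such
an ORF are dropped. Codons containing N are neither start nor stop. Ties
are broken deterministically (forward strand, lower frame, leftmost start)
— the tie rule is plumbing; determinism is the requirement.

## The simulator: what it emulates, and what it does not

`simulate_methylome` writes the statistical world the analysis assumes:

* one synthetic chromosome; non-overlapping genes, alternating strand,
  separated by fixed intergenic spacers (default 1000 bp);
* three gene classes with proportions 0.70 unmethylated / 0.20 gbM /
  0.10 TE-like. True per-read methylation probabilities: gbM CG 0.8 shaped
  by a 20-window body profile (0.3 at the gene edges rising to 1.0 at
  windows 9–12, i.e. TSS/TTS depletion), gbM non-CG 0.01; TE-like 0.8 in
  all contexts; unmethylated 0 everywhere;
* cytosine placement with per-strand densities CG 0.02, CHG 0.02,
  CHH 0.10 per bp — approximately angiosperm dinucleotide frequencies;
* gene lengths uniform on 300–2700 bp (mean 1.5 kb, plant-CDS-like). The
  short tail matters: a 300-bp gene carries ~12 CG sites, so the
  ≥ 10-covered-CG-sites rule becomes coverage-sensitive near 1×, as it is
  in real shallow data;
* per-site read depth Poisson(mean coverage, default 20); per-read apparent
  methylation p_app = p_true + (1 − p_true)·ncr with non-conversion rate
  ncr = 0.005 (a conventional value — published per-species rates are
  rarely printed). Non-conversion is modelled as false methylation only;
  over-conversion (a truly methylated read appearing unmethylated) is
  second-order and omitted;
* context labels are assigned directly, not read off a simulated genome
  sequence — contexts, not k-mer composition, drive the analysis.

The simulator does **not** model read alignment, PCR duplicates, CNV,
cell-type heterogeneity, partial (allelic) methylation, or spatial
autocorrelation of methylation beyond the gbM body profile. A green test
therefore establishes that the *statistical machinery* is correct under the
stated generative model — not that biological gbM calls on real data are
accurate at any given coverage.

## Numerical choices

* Binomial tails via the regularised incomplete beta (scipy); verified in
  the suite against exact rational enumeration to 1e−12 relative.
* BH step-up computed directly (sort, `m·p/rank`, suffix minimum, cap at 1)
  so results are exactly the textbook quantity; cross-checked against
  statsmodels.
* Window index from a closed-form candidate `floor(o·20/L)` corrected by at
  most one step against the `round` boundaries — exact and vectorised.
* Backgrounds clamped to [1e−9, 1−1e−9]; q-values are NaN wherever no test
  exists and all NaN-handling is explicit.
* All randomness flows through `numpy.random.default_rng`; multi-stage runs
  derive stage seeds from a master seed via `SeedSequence`, so identical
  configs are byte-identical.

## Known limitations

* Gene interval logic assumes sorted, non-overlapping genes per chromosome
  (readers reject violations) — adequate for CDS spans, not for nested or
  overlapping loci.
* Flank windows are unmasked (above).
* The classifier's background circularity means very high genome-wide
  methylation inflates p0 and deflates sensitivity; that is the method, not
  a bug.
* CX-report/bedGraph dialects and SAM/BAM input are out of scope (future
  adapters); the allc-style TSV is the only call-table dialect.
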