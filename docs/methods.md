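# Methods

## The risk model

A DSB at genomic position `x` is modeled as destroying the base at `x`;
5'→3' resection then proceeds bidirectionally, so after time `t` the left
tract covers `[x−L, x)` and the right tract `[x, x+L)` with `L = v·t`
(`v` = 4,000 bp/h by default). All coordinates are 0-based half-open; the
model is a continuous approximation evaluated on integer positions, and
merged-interval arithmetic is exact position-set arithmetic (adjacent
half-open intervals coalesce).

**Resection-exposure geometry.** A repeat `[s, e)` of length `len = e−s`
becomes a usable ectopic donor once at least `E_min` *contiguous* bp of it
are single-stranded within a single tract (default `E_min` = 300 bp;
exposure never sums across different repeats). Solving
`overlap(tract, repeat) ≥ E_min` for integer `x` gives, when `L ≥ E_min`
and `len ≥ E_min`:

* right tract: `x ∈ [s−(L−E_min), e−E_min]`
* left tract: `x ∈ [s+E_min, e+(L−E_min)]`

stored half-open as `[s−(L−E_min), e−E_min+1)` and
`[s+E_min, e+(L−E_min)+1)`, clipped to the chromosome. The two arms
coalesce when `len ≥ 2·E_min − 1`; shorter repeats leave a central band of
positions from which neither side can expose `E_min` bp. The genome-wide
at-risk fraction is the merged union of all per-repeat sets divided by the
summed chromosome lengths. The inclusive integer endpoints differ from the
continuous-measure formula by 1 bp per arm; the discrete form is used
because the per-base oracle (below) is the reference and the equivalence is
asserted *exactly*. At the `~1%`-scale precision of the genome fractions
this choice is immaterial.

By default a single exposed side suffices (one-ended pathways: half-CO,
BIR, multi-invasion need one usable end); `both_ends=True` intersects the
left-tract and right-tract risk sets instead. A `naive_extend=True`
compatibility mode extends each repeat by `L` on both sides with no
minimal-exposure requirement — the simplest extension rule — and is always
reported alongside in the genome-scale analysis, since published interval-
extension analyses do not always state which rule was used.

**CO geometry.** A crossover between the broken locus and an ectopic repeat
requires the break inside the repeat with at least `margin` intact bp on
each side of the destroyed base: eligible zone `[s+margin, e−margin)`, i.e.
`max(0, len − 2·margin)` positions, merged across overlapping repeats
before summing. Repeats of length ≤ 2·margin contribute nothing.

**Oracle.** `per_base_oracle` scans every integer position, computes the
contiguous tract/repeat overlaps directly from the min/max overlap formula,
and marks positions with any overlap ≥ `E_min`. It shares no code with the
closed form and must agree exactly; it refuses genomes above 10 Mb (the
closed form is exact at any scale). `per_base_co_oracle` does the same for
CO eligibility.

Assumptions and limits: uniform DSB distribution (the conservative case —
real recombinogenic lesions are enriched at highly transcribed genes);
constant resection speed with no stalling; linear chromosomes only
(circular topology is rejected, and the mitochondrial genome should not be
included in chrom.sizes); strand is parsed but ignored (homology, not
orientation, defines donor capacity); no modeling of homology-search
kinetics or donor choice.

## Similarity scoring

The pairwise score is the maximal number of identical aligned pairs under
global alignment with match = 1, mismatch = 0, gap = 0 — exactly the LCS
length — computed by an O(|a|·|b|) rolling-row DP vectorized with
`numpy.maximum.accumulate` (each DP row is the running maximum of its
candidate vector because rows are non-decreasing). Comparison is
case-insensitive; `N` matches nothing.

Normalization divides by the longer sequence length (`norm="max"`), the
conservative choice: it penalizes length mismatch and makes 1.0 equivalent
to byte identity. `min` and `alignment` (|a|+|b|−LCS) conventions are
implemented so genome-scale runs can be repeated under each, because a
published "score < 0.7 removed" filter does not pin down the normalizer.
Pairs are scored within families only by default (`all_pairs=True` for the
exhaustive matrix); the retained-gene set is every gene in at least one
pair with similarity ≥ θ (default θ = 0.7).

## Assay statistics

Group summaries are arithmetic means ± SEM. Ratios are per-replicate when
sample and control were scored in parallel (pairing given), else ratio of
group means; both are carried in `RatioSummary` because mean-of-ratios and
ratio-of-means differ under multiplicative noise (the former is biased
upward by `1+cv²`). Fold inhibition is mean(inactive)/mean(active);
NCO/CO frequencies are junction signal over the circularization-efficiency
control, per replicate, in percent (the shared loading control cancels but
is validated); MIR frequency subtracts the no-break background frequency,
floored at zero, with both raw frequencies always reported. Significance
uses the two-tailed Mann–Whitney–Wilcoxon rank-sum test (exact null when
tie-free; Wilcoxon signed-rank when paired), switching to a two-tailed
Student t-test when either group has fewer than 4 replicates; identical
constant groups return p = 1 by convention. The conversion from raw qPCR
quantities to per-replicate signals is assay-protocol territory and is out
of scope: the module contract starts at signal values.

## Synthetic data generation

Each family descends from one uniform-random ancestral sequence; every copy
independently substitutes each base with probability `s` (uniform over the
three alternatives) and applies single-base indels at rate `d`
(insertion/deletion equally likely). Two copies then agree per site with
probability `(1−s)² + s²/3` (exact for `d = 0`; confirmed by Monte-Carlo
simulation of the two-branch process), which is recorded as the planted
truth. Placement is dispersed (uniform, overlap-rejecting, chromosomes
weighted by length) or tandem (fixed spacer), the latter to exercise
interval merging. Intergenic composition is irrelevant to the interval math
and is not modeled. Assay noise is multiplicative lognormal parameterized
by CV with `E[value] = truth`, so the ratio of group means is a consistent
estimator of the planted ratio. One `numpy.random.default_rng(seed)` stream
drives everything: identical spec + seed ⇒ byte-identical FASTA/BED/TSV.

The `yeast_like_spec` preset is a synthetic stand-in for a curated yeast
paralog list. It reproduces stated summary features — 270 genes on the
sixteen real sacCer3 chromosome lengths (12,071,326 bp total), family
coverage near 3% of the genome, within-family similarity above 70% — with
composition chosen once as realistic: 100 two-copy families (the whole-
genome-duplication mode), 10 three-copy and 5 four-copy families, two
ten-copy tandem arrays (subtelomeric-style), lognormal gene lengths
(median ≈ 1.2 kb, clipped to 0.3–6 kb) and substitution rates uniform on
[0.02, 0.12]. What the preset does **not** emulate: the true family-size
and length distributions of the curated list, real tandem-cluster
structure, GC content, or any correlation between divergence and position.
Risk fractions computed on it are therefore *method* outputs under stated
summary conditions, not reproductions of the real-genome numbers; passing
tests show the pipeline and its math are correct, not that the emulation
matches the curated annotation.

## Numerical and design choices

* Problem sizes: oracle-equivalence suites use 200 randomized genomes of
  ≤ ~150 kb (1–3 chromosomes, 0–8 repeats each plus tandem/overlapping and
  edge-hugging partners) — small enough for the quadratic-ish scan, large
  enough to hit every clipping/coalescence branch. Alignment correctness
  uses 500 random pairs of length ≤ 10 against exhaustive subsequence
  enumeration, plus a C global aligner as an independent cross-check on
  longer pairs.
* The time grid defaults to 0–4 h in 0.1-h steps, bracketing the 1 h and
  4 h anchor points used in genome-scale runs.
* Degenerate inputs: empty sequences score 0 matches but have undefined
  normalized similarity (error); empty annotations give fraction 0;
  `L < E_min` gives the empty risk set; zero active-group means give
  infinite fold with a warning rather than an error.
* Estimator tolerances in tests derive from the lognormal/Poisson standard
  errors at the stated n (e.g. ratio-of-means SE ≈ R·cv·√(2/n)), set at
  ~3× SE.
* Known limitation: with non-zero indel rates the planted-truth identity is
  the substitution-level expectation; the BED interval keeps the planted
  footprint while the FASTA sequence length floats with the net indel
  balance.
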