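# Methods

## Data model and conventions

The unit of input is a segmented CNV call: one aberrant interval in one
sample with an integer copy number (≠ 2) and a non-negative confidence
score, typically a log Bayes factor from an HMM-based SNP-array caller.
Coordinates are 1-based and inclusive at both ends; BED export converts to
0-based half-open. Only autosomes are analysed — the diallelic genotype
mapping assumes diploidy — and non-autosomal or copy-number-2 rows are
dropped with a warning rather than an error, since they are out of scope
rather than corrupt. Region sizes are reported as `(end − start)/1000` kb
to one decimal; this matches how such regions' sizes are conventionally
printed from their boundary coordinates.

When no probe manifest is supplied, the per-chromosome probe grid is the
sorted union of all call breakpoints. Both per-probe statistics are
piecewise constant between consecutive breakpoints, so this pseudo-probe
grid is lossless: any manifest restricted to the covered intervals yields
the same regions up to boundary probes. Supplying the real array manifest
changes only the resolution at which region boundaries are expressed.

## COVER and COMPOSITE

For probe `k`, COVER counts the state-matched calls with confidence ≥ `c`
covering the probe (`y_k`), and COMPOSITE sums the confidences of all
state-matched covering calls (`s_k`). Both are computed with a
difference-array accumulation over probe index ranges (O(calls + probes)
per chromosome); tiny negative residues from floating cancellation are
clamped to zero. A sample with two overlapping calls contributes twice to
the statistic at shared probes — the definitions sum over calls, not
samples — and a warning flags such samples.

Choices that the definitions leave open, and what this implementation does:

* **Confidence filter is `C_ij ≥ c`** (not strict `>`), so resolving `c` at
  the 0th percentile keeps every call and filtering degrades continuously
  to "none".
* **Losses and gains are tracked separately by default** (`state_handling=
  "separate"`), with a pooled "combined" mode available. Separate tracks
  avoid merging biologically distinct events, and the downstream genotype
  mapping needs the state anyway.
* **Percentile conventions.** Confidence cutoffs resolve by linear
  interpolation between order statistics of the pooled call scores.  The
  composite threshold resolves to the *lower* order statistic of the pooled
  per-probe scores (zeros included): most probes carry no call and score 0,
  and any percentile at or below that zero fraction must yield exactly
  `v = 0` — the regime in which every covered probe passes, equivalent to
  COVER with `u = 1, c = 0`. Linear interpolation would leak a small
  positive threshold on short pools and break that equivalence.
* **A probe passes when its value is ≥ threshold *and* positive.** This
  makes a resolved threshold of 0 mean "any covered probe" rather than
  "every probe on the chromosome".
* **Region boundaries are probe positions** (first/last probe of the run),
  not the extremes of supporting calls: the regions are defined as sets of
  consecutive probes.
* **Supporting calls** of a region are the qualifying calls overlapping at
  least one probe of the run; region frequency is the number of distinct
  supporting samples over the total number of samples studied, and the
  region confidence summary is the median over supporting calls.

Regions are emitted in (chromosome, first probe) order; identical inputs
give identical outputs.

## CLUSTER refinement

Within a parent region of length `L` bases, each pair of supporting calls
reduces to `(a, b, c, d)` base counts of their footprints inside the
region; the dissimilarity is `1 − a/(a+b+c)`, the complement of the Jaccard
similarity of the footprints. (The raw `a/(a+b+c)` is a similarity; the
clustering consumes its complement, so a "members at least 60% similar"
requirement is a dendrogram cut at height 0.4.) `d` is carried for
completeness but unused by the Jaccard form. Overlap counting is in bases,
not probes: the `(a, b, c, d)` decomposition is defined base-wise.

Agglomeration uses `scipy.cluster.hierarchy` with complete linkage by
default (single and average available) and a default `cluster_limit` of
0.6. Members are pre-sorted by (start, end, sample) so equal-height merges
resolve identically across runs and platforms. Each flat cluster becomes a
subregion spanning its members' min/max positions, clipped to the parent
when a member overshoots; member sets partition the parent's supporting
calls, and subregions are numbered in genomic order as `<parent>.1`,
`<parent>.2`, …

Single linkage merges at minimum pairwise distance and therefore yields the
fewest clusters at a given cut (threshold-graph components); complete
linkage the most; average linkage sits between. The suite asserts this
ordering on randomised instances.

## Hardy-Weinberg testing

A sample's copy number at a region is that of its supporting call covering
the most bases of the region, ties broken by higher confidence then lower
copy number; samples without a supporting call are diploid. Regions whose
observed copy numbers fit {0,1,2} (loss) or {2,3,4} (gain) are diallelic
and map to genotype counts; anything mixing losses and gains, or outside
those ranges, is multi-allelic and excluded from HWE testing — unphased
copy number is ambiguous there (e.g. two single-copy alleles and a 0+2
combination both total two copies). A region where every sample is diploid
is treated as monomorphic diallelic.

The default test is the conditional exact test: given the allele counts,
the heterozygote count follows a known discrete distribution, and the
two-sided p-value sums the probabilities of all configurations no more
probable than the one observed. Per-group sample sizes in the intended
studies are a few dozen, where the asymptotic test is unreliable; the 1-df
chi-square test is provided as an option. Monomorphic counts return p = 1
by convention. The implementation works in log-space with a `1e-10`
log-tolerance for ties; the test suite checks it against an exact
big-integer enumeration for every genotype table with n ≤ 50.

Group-wise tests run on the unrelated members of each group only (related
samples still contribute to discovery and association). The violation rate
is the fraction of diallelic regions with p < α (default 0.01) in at least
one group. `tune_thresholds` scans a grid of settings, reporting region
counts, violation rates, mean pooled MAF and median size per point, and
flags the point after which the violation rate's first difference is most
negative — the heuristic is to prefer thresholds past the steepest drop.
The tool reports the table and the flag; it does not auto-select, because
the choice also weighs discordance and region size.

## Concordance evaluation

A region is concordant with a reference CNV when contained in it or when
the overlap covers at least half **of the reference** (inclusive base
counts; the boundary case counts). This is deliberately not reciprocal
overlap — most interval toolkits default to reciprocal, so the distinction
is documented prominently. Type matching (loss vs gain) is optional and
skipped when either side's type is unknown. A region is attributed to a
sample for per-sample discordance if the sample is among its supporting
calls; samples supporting no region get an undefined (NaN) rate rather
than 0 or 1. Method-versus-method comparison applies the same rule with the
second region set as references and summarises each partition by count,
mean frequency and median confidence.

## Association and PCA

Association dichotomises each region to carrier (copy number ≠ 2) versus
non-carrier per sample and tests the 2×k carrier-by-group table with an
exact conditional test (exhaustive enumeration over tables with the
observed margins; identical to Fisher's test at k = 2 and cross-checked
against `scipy` there) or chi-square; a genotype-level table mode (chi-
square only) is available. Regions with no carriers get p = 1 and a flag.
FDR control is Benjamini-Hochberg via `statsmodels`.

PCA runs on the samples × regions integer copy-number matrix (raw integers,
not carrier indicators), mean-centred by default and unscaled — copy
numbers share a scale, so variance-normalising would inflate rare regions.
Components are computed by SVD; each component's sign is fixed by making
its largest-magnitude loading positive, so scores are reproducible across
runs and sample orderings.

## Synthetic data

The generator emulates PennCNV-style output for a population panel: loci
segregate independently at HWE (genotype probabilities `(1−q)²,
2q(1−q), q²`), heterozygous carriers emit copy number 1 (loss) or 3
(gain) and homozygous carriers 0 or 4, breakpoints jitter by a Normal of
SD `jitter_sd_bp` (rounded, clipped to valid intervals), and confidence
follows Normal(`a + b·ln(length)`, sd) truncated at 0 by clipping —
longer regions carry more probes and stronger evidence, so the planted
scores grow with length. Noise calls arrive per sample at a Poisson rate,
placed uniformly on the autosomes with rejection away from planted loci,
short (1–20 kb), with low confidence (Normal(5, 2) clipped at 0) and a
random aberrant copy number. Defaults model a small population study: 20
loss loci spread across chromosomes, core sizes 30–150 kb, MAFs evenly
spaced in [0.15, 0.45], 2 kb jitter, 100 samples, 0.5 noise calls per
sample.

One integer seed governs everything; each locus draws from its own
deterministic substream, so extending a specification does not perturb
existing loci, and identical seeds give byte-identical tables. What the
generator does *not* model — linkage disequilibrium between loci,
multi-allelic loci, genotyping failure, batch effects, probe-density
variation along the genome — bounds what passing tests show: recovery and
calibration results demonstrate correctness of the statistics under the
stated population-genetic model, not caller performance on real arrays.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulated studies of 100
samples and 20 loci (20 replicate seeds), 200 random instances of ≤ 20
calls × ≤ 50 probes for brute-force agreement, the full enumeration of
genotype tables to n = 50, and 2,000 HWE-calibration loci in three groups
of 46/29/37 — sizes chosen to exercise every code path at interactive
speed. Exact-test tie comparison uses a `1e-10` log tolerance; track
accumulation clamps floating-point residue at zero; percentile conventions
are as above. Degenerate inputs (empty call sets, empty region lists,
monomorphic counts, constant matrices, single supporting calls) return
defined values or clear errors as documented in each docstring.

## Known limitations

* Thresholds are descriptive, not inferential: no permutation-based
  significance for region discovery is provided.
* Multi-allelic regions are excluded from HWE rather than modelled with
  three or more alleles.
* The per-sample copy-number assignment takes the single best-overlapping
  call; a sample with genuinely split coverage of a region is summarised by
  one call.
* Exact association enumeration is exponential in the number of groups;
  it is intended for the 2–4 group panels typical of this analysis.
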