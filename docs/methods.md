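# Methods

This note documents the models and procedures implemented in `paleogt`,
their parameters and defaults, the design choices made where the design was
genuinely open, and the limits of what the synthetic-data tests demonstrate.

## Setting

Low-coverage ancient genomes are usually reduced to pseudohaploid calls:
per site, one read-sampled allele. Imputation against a phased modern
reference panel can instead produce diploid genotypes with per-call
genotype probabilities (GP), but the result must be validated — error is
concentrated in rare alleles (low panel MAF), heterozygous sites, low
coverage, and (in ancient DNA) transitions, which are confounded by
postmortem deamination. The package takes truth/imputed callsets,
panel frequencies, a genetic map and IBD segment tables, and computes the
validation metrics and the downstream ROH/IBD analyses. All interval
arithmetic is 0-based half-open internally; VCF positions are converted at
the boundary.

## Imputation validation

For each sample, a 4×4 confusion matrix of truth × imputed dosage
(0, 1, 2, missing) is accumulated per stratum (MAF tranche × substitution
class), after setting imputed calls to missing when their max GP falls
below the threshold or when the recorded genotype is not the GP argmax (a
consistency guard; imputation engines emit the argmax genotype, so a
disagreement marks a corrupted record). Sites with missing truth are
excluded entirely.

* Non-reference concordance = (n[1→1] + n[2→2]) / Σ_{d∈{1,2}, i∈{0,1,2}} n[d→i].
  The denominator is *conditional on a call being made* — GP-filtered calls
  are excluded. The unconditional variant (filtered calls count as not
  recovered) is available via `conditional=False`; which convention a given
  validation pipeline uses is rarely stated, so both are exposed.
* Het FPR = FP/(FP+TN) with FP = n[0→1] + n[2→1] and TN = n[0→0] + n[2→2].
  Cross-homozygote errors (n[0→2], n[2→0]) sit in neither FP nor TN,
  following the formula's letter rather than a rate over all truth homs.
* Het FNR = (n[1→0] + n[1→2]) / (n[1→0] + n[1→1] + n[1→2]).
* Undefined rates (empty denominators) are returned as `None`, never 0 or
  silent NaN.

MAF tranches are left-open/right-closed in percent — (0,1], (1,2], (2,5],
(5,10], (10,20], (20,50] — so a MAF of exactly 5% falls in (2,5], while
minimum-MAF *filters* ("MAF ≥ 5%") are inclusive thresholds. MAF always
means the reference-panel frequency, never a frequency recomputed from the
analysed samples. MAF-0 sites are labelled monomorphic and excluded from
tranche statistics.

## Windowed scans

Windows follow the bedtools-makewindows dialect (start at 0, advance by the
step while inside the chromosome, truncate at the end; defaults 500 kb /
100 kb). A site contributes to every window containing it. Outlier windows
are selected by the nearest-rank percentile (ceil rank) over windows with a
defined rate; empty windows are excluded from ranking rather than scored 0,
so coverage deserts are not called outliers; ties at the threshold are all
selected. Selected windows are merged (touching intervals merge). Regions
recurrent across samples are the merged union of all samples' outliers,
kept when at least `min_samples` (default 3) samples contribute. A
convenience flag annotates—but does not remove—regions overlapping the
first/last 2 Mb of a chromosome, where assembly edges inflate artefacts.
Heterozygosity profiles use consecutive non-overlapping blocks of exactly
50 non-missing calls per chromosome, dropping the trailing partial block.

## ROH calling

**Scanning-window caller** (plink `--homozyg` parameterisation): every
window of 50 consecutive SNPs is a "hit" if it contains ≤1 heterozygote and
≤5 missing calls; a SNP passes if ≥5% of the windows covering it are hits;
maximal passing runs are trimmed so both ends are homozygous non-missing
calls, split where adjacent SNPs are >100 kb apart, and kept when they have
≥200 SNPs, span ≥500 kb, and average ≤50 kb per SNP. The end-trimming rule
is this package's fixed, oracle-testable choice; the reference tool's exact
extension behaviour is undocumented. No cap is placed on heterozygotes
inside a final segment (the windows provide that control).

**HMM caller**: two hidden states, autozygous (AZ) and Hardy–Weinberg (HW),
over called genotypes collapsed to het/hom. With genotype error
e = 10^(−Phred/10) (default Phred 30) and panel ALT frequency p (default
0.4 where unknown or degenerate): P(het|AZ) = e, and
P(het|HW) = 2p(1−p)(1−e) + (1−2p(1−p))e. Transitions between adjacent
called sites at distance d bp are P(HW→AZ) = min(6.7e−8·d, 0.49) and
P(AZ→HW) = min(5e−9·d, 0.49) — the standard defaults of the reference
tool, which the analysis this package reimplements left untouched. The
start distribution is uniform. Viterbi defines AZ segments; per-site AZ
posteriors come from forward–backward, and segment quality is
−10·log10(1 − median posterior) — the reference tool's quality definition
is internal and unstated, and any monotone posterior summary serves the
">10" filter; the median is used for robustness. Segments are kept with
≥200 SNPs, quality >10 and length ≥500 kb.

**Fusion**: the scan caller under-calls long ROHs at low SNP density while
the HMM over-calls short ones, so HMM segments strictly longer than 4 Mb
are unioned into the scan profile (touching intervals merge); each fused
segment records its contributing-source count and collapsed input lengths.
Thresholds follow their wording: ">4 Mb" strict, "≥200 SNPs" and "≥500 kb"
inclusive.

**Exact Mann–Whitney U**: for comparing per-group cumulative ROH at tiny
sample sizes, U counts pairs with a < b and the one-tailed p is
P(U′ ≤ U) under the exact permutation null, computed from the Gaussian-
binomial coefficient generating function by integer dynamic programming
(no overflow, no normal approximation). Ties across groups are refused
rather than approximated — cumulative-Mb inputs are effectively continuous,
so a tie signals a data problem.

## IBD post-processing

Segment *detection* is external; the package consumes RefinedIBD-style
tables. Repeated runs are combined by dropping records with LOD <3,
clipping configurable exclusion regions (default: the first 2 Mb of chr18,
a putative assembly artifact with a huge apparent recombination rate),
taking the per-pair interval union across runs, and keeping union segments
≥3 cM on the genetic map. Within a pair, consecutive segments with a cM
gap strictly under 0.6 merge (an epsilon of 1e−9 cM keeps a gap of exactly
0.6 from merging through interpolation round-off). A further
discordant-homozygote criterion used by detection-side mergers needs
genotype access inside the gaps and cannot be evaluated from segment tables;
gap-distance merging alone is applied here.

A pair is *related* when it shares ≥3 segments each >3 cM whose summed
length is ≥21 cM (the cumulative clause binds to the qualifying segments
only). Normalized relatedness of a group (≥3 members) is the fraction of
members with at least one in-group relative — chosen because published
values are glossed as "all individuals related" (1) and "roughly half" —
with a pair-fraction variant behind a flag. Between-group cumulative IBD is
the symmetric matrix of summed cM over cross-group pairs. The main-analysis
mode consumes IBD1 segments without extra cross-gap merging; a validation
mode merging within a larger gap is a parameter choice (`max_gap_cm`).

## Outgroup f3

f3(O; A, B) = mean over sites of (o−a)(o−b), with frequencies from allele
counts over non-missing diploids; sites unobserved in any of the three
populations are skipped. Standard errors use a delete-one block jackknife
over contiguous physical blocks (default 5 Mb — the conventional scale at
which linkage is absorbed; the block scheme is a tool default, not a
published choice), weighted by block site counts (Busing's weighted
jackknife, which reduces to the classic delete-one formula for equal
blocks). No finite-sample bias correction is applied — the outgroup-mode
convention, since only the ranking of f3 values is interpreted — with the
heterozygosity correction available behind a flag.

## Synthetic-data generator

The generator produces data with the statistical structure the analyses
assume; its defaults define the package's study conditions.

* **Panel**: 2 chromosomes × 50 Mb at 1 cM/Mb with 50k sites each — a
  desk-scale stand-in for a livestock genome of ~30 autosomes — carrying
  200 haplotypes mosaic-copied from 20 founders with donor switches at
  0.1 per cM (Li–Stephens-style), and per-site founder frequencies from
  Beta(0.3, 0.3), giving LD and a realistic rare-allele excess with two
  parameters. A coalescent simulator could be swapped in, but is not needed
  for what the tests measure.
* **Truth diploids**: fresh mosaics over the panel. Planted ROHs overwrite
  the second haplotype with the first (exact homozygosity); planted IBD
  tracts give both pair members a common donor haplotype.
* **Imputation error model**: a call in MAF tranche t with truth class c is
  wrong with probability p_wrong[t][c]·exp(−k·coverage). Defaults grade
  from 25% (het, rarest tranche) down to 1.2% (hom, commonest), with
  k = 2·ln 2 so error halves per +0.5× coverage. Wrong hets become the
  major-allele homozygote and wrong homs become het with probability 0.8
  (else the opposite hom), reproducing the qualitative finding that
  heterozygote errors dominate. Max GP is 0.5 + 0.5·Beta(a,b) — the affine
  map guarantees the emitted genotype stays the argmax — with Beta(30,1)
  for correct and Beta(4,2) for wrong calls, so stricter GP thresholds
  preferentially drop wrong calls; the remaining mass splits 9:1 between
  the runner-up (the truth class, when the call is wrong) and the third
  class. The Beta laws are calibration devices: real engines' empirical GP
  distributions are not published, and only the max-GP ordering matters
  downstream. Uninformative (1/3,1/3,1/3) triples mark engine-missing calls
  (rate 2% by default).
* **Pseudohaploid calls**: per-site depth ~ Poisson(coverage); depth 0 is
  missing, otherwise one allele sampled uniformly from the diploid genotype
  and recorded as the homozygous dosage.
* **IBD tables**: each planted tract is emitted per run with ±0.2 cM
  uniform endpoint jitter, split with configurable probability into two
  pieces separated by a gap <0.6 cM (so downstream merging must
  reconstitute it), and LOD = 3 + Exponential. Decoy negatives — short
  (<3 cM) high-LOD and long low-LOD (<3) segments — are planted only on
  designated pairs, so positives and negatives never mix on one pair.

All generators are seed-deterministic (byte-identical outputs per seed).

What the generator does **not** emulate: reference-panel phasing errors and
ancestry-dependent panel representation, postmortem deamination and other
read-level artefacts, LD-aware error correlation along the chromosome
(errors are conditionally independent given the stratum), and real
recombination-rate variation (the default map is uniform). Passing tests
therefore demonstrate that the *analysis stack* is correct and calibrated
against a known generating process — not that any particular real dataset
imputes accurately.

## Validation strategy and problem sizes

Optimised code paths are checked against naive references that share no
code with them (`paleogt.reference`): the window-scan caller against a
literal loop implementation on 1,000 random ≤500-SNP instances with
randomised parameters (exact segment boundaries); Viterbi against
exhaustive enumeration of all 2^L paths for L ≤ 12 over 500 random
parameterisations; the exact U distribution against closed-form
normalisation and (n, m) symmetry for all n+m ≤ 12, against full labeling
enumeration at the published group sizes, and against scipy's exact tail;
the f3 jackknife against literal leave-one-block recomputation. Parameter
recovery and trend checks run on the default 100k-site panel with planted
6 / 2.5 / 3 Mb ROHs and three 8 cM IBD tracts; at these sizes the whole
suite and the acceptance script each run in well under a minute on one
core. The ROH density study compares 64k- and 20k-site subsets of the
synthetic genome — the same sites-per-bp as 1.6 M and 0.5 M sites on a
~2.5 Gb genome, the densities at which fragmentation effects appear in
practice.

## Known limitations

* The window-scan caller's end-trimming and the HMM's quality score are
  fixed choices where the reference tools are undocumented; both are
  exercised by oracles, but neither is guaranteed to match those tools
  call-for-call on real data.
* Normalized relatedness has several defensible definitions; the
  individual-fraction default is one of them (see above).
* Multi-allelic records are skipped, sex chromosomes are out of scope, and
  genotypes are treated as unphased diploid throughout.
* The exact Mann–Whitney implementation refuses ties; use a tie-aware
  approximate test if tied inputs are meaningful in your setting.
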