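# Methods

## The analysis problem

A biparental F2 population genotyped on a dense SNP array records, in each
individual, the outcome of two independent meioses: along every
chromosome the genotype switches class (parent-A homozygote AA,
heterozygote H, parent-B homozygote BB) wherever a crossover occurred in
one of the two transmitted gametes. `recland` reconstructs the
population-level recombination landscape from these switches and compares
two populations — typically a control cross and a cross segregating a
meiotic perturbation — along physical chromosome coordinates.

## Crossover calling

A candidate crossover is a change of call class between two markers that
are consecutive among an individual's *non-missing* calls. Scoring:

* AA ↔ H or BB ↔ H: one crossover, score 1;
* AA ↔ BB between consecutive markers: a crossover in each gamete
  (a coincident double event), score 2;
* H ↔ H and identical calls: no event.

To keep isolated array miscalls from inflating the count, a transition is
valid only if the outgoing call is maintained over the `window` preceding
non-missing markers and the incoming call over the `window` following
ones (default 3, i.e. the change must persist in the previous and next
three markers). Missing calls are condensed out of the sequence before
the window is applied (`skip_missing`); a `strict` policy that lets
missing calls break the window is retained for sensitivity analysis.

At chromosome ends the full window does not exist. By default the window
truncates to however many markers remain (at least one), because a strict
rule would discard exactly the distal crossovers that matter most in a
telomere-dominated landscape; `strict_full` is available behind a flag.
The cost of truncation is that a miscall at an outermost marker is
indistinguishable from a terminal crossover — with a three-marker window,
calls within three markers of an end get progressively weaker validation.

Two valid transitions closer than `window` markers are both reported when
each independently satisfies its (overlapping) window; no merging
heuristic is applied. A plain-loop reference transcription of the rule
(`call_crossovers_reference`) ships with the package and the suite checks
the production caller against it exhaustively (all sequences to length 8)
and on random length-12 sequences.

## Recombination fractions and the genetic map

For each consecutive marker pair, `r` = summed crossover scores assigned
to the interval divided by the number of individuals with non-missing
calls at both flanking markers. An event whose flanking informative
markers are non-adjacent (missing calls in between) is assigned to the
single consecutive-pair interval containing the physical midpoint of its
flanking pair — unbiased and integer-weighted. Intervals with no
informative individuals get undefined `r` and are excluded from totals
with a warning.

Distances use the Kosambi map function, d(cM) = 25·ln((1+2r)/(1−2r)),
which assumes moderate positive interference; r ≥ 0.5 is clipped to
0.49999 with a warning, never extrapolated. `r` is used exactly as
computed — a per-F2-individual fraction pooling both meioses — with no
halving and no maximum-likelihood F2 estimator, so the genome total
estimates *twice* the per-gamete genetic length. This mirrors standard
array-based F2 practice and is what the parameter-recovery test asserts.

Expected crossover counts are reported as genome cM / 50 both at full
precision and truncated (not rounded) to one decimal, matching the
conventional one-decimal presentation of such summaries.

## Genomic zones and physical bins

Chromosomes partition into distal (Z1), interstitial (Z2) and proximal
(Z3) zones. Boundary coordinates are configuration data (a TSV of
1-based inclusive segments that must tile each chromosome), not code; a
symmetric default layout places Z1/Z2/Z3 boundaries at 4%, 38%, 62% and
96% of each chromosome. Markers are assigned to zones by position;
intervals by the midpoint of their flanking markers (segments are
inclusive, so a midpoint 1 bp left of a boundary belongs to the left
segment).

Bin profiles split every chromosome into `n_bins` equal relative physical
spans (default 50, i.e. 2% bins) and apportion each interval's cM
pro-rata by physical overlap (midpoint assignment available as a flag).
Bin 1 starts at the short-arm telomere. Conservation — zone cM sums, bin
cM sums and the genome total all equal — is asserted to 1e-9 relative.

## Two-population statistics

* **Per-zone χ²**: for each zone, a 2×2 Pearson chi-square (population ×
  in-zone/out-of-zone crossover scores), 1 dof, no continuity correction
  by default (counts are in the hundreds at study scale; Yates available
  behind a flag). The Z1-vs-Z2 2×2 table tests the distal-vs-interstitial
  shift specifically. Zero marginals leave p undefined.
* **Wilcoxon signed-rank** on paired cM vectors: zeros dropped, exact
  two-sided p up to 25 tie-free pairs, tie-corrected normal approximation
  above. The pairing unit is the chromosome: per-chromosome map totals
  (genome test), per-chromosome zone cM (zone tests), per-chromosome bin
  cM (per-bin tests). The *terminal-bin* test pairs the first and last
  bin of every chromosome — one value per chromosome arm, 14 pairs for a
  7-chromosome genome. With only 7 chromosome pairs the exact two-sided
  p-value floor is 0.031 and the null distribution is too coarse for
  calibration statements, which is why the terminal contrast pools arms.
* No multiple-testing adjustment across the 50 bins by default
  (Benjamini–Hochberg available), matching how such bin scans are usually
  presented.

Zone shares are reported both from cM totals and from crossover-score
totals; published zone-share pairs are not always consistent with one of
the two conventions, so both are exposed.

## The simulator

Each F2 individual is the fusion of two independent gametes. Crossovers
are placed on the genetic scale by a stationary gamma renewal process
with mean inter-event distance 100 cM; shape ν = 1 (default) is the
no-interference Poisson case, ν > 1 underdisperses counts as positive
interference would. The stationary start draws the first waiting time as
U × (length-biased interarrival). Genetic positions map to physical bp
through the inverse CDF of a piecewise-constant landscape. No
obligate-crossover mechanism is enforced by default. Coincident
crossovers of the two gametes in one marker interval are simulated
faithfully; they surface as AA↔BB double events (score 2) or as invisible
H↔H transitions. Each gamete's starting haplotype is uniform (F1 phase is
arbitrary).

Defaults emulate the barley study design this package targets:

| parameter | default | rationale |
|---|---|---|
| individuals per population | 90 | study population size after QC |
| chromosomes | 7, 522–665 Mbp | MorexV2-like physical sizes |
| per-gamete genetic length | 74 cM/chromosome | F2 map total ≈ 1,035 cM |
| marker density | 2.6 /Mbp (~11,000 markers) | polymorphic-marker density of a 50k array cross |
| zone bounds (relative) | 0.04 / 0.38 / 0.62 / 0.96 | physical zone shares back-computed from published per-zone marker counts and densities (Z1 ≈ 8%, Z2 ≈ 68%, Z3 ≈ 24%) |
| genetic mass per zone | Z1 50.7%, Z2 49.2%, Z3 0.1% | published control per-zone cM totals; uniform within zone |
| allele error rate | 0.002 | placeholder; array miscall rate not published |
| missing rate | 0.02 | placeholder; exposed in `SimConfig` |

Genotyping noise is applied after truth is recorded: an erroneous call is
replaced by one of the other two codes uniformly; missingness is
independent Bernoulli. Markers are evenly spaced — the real array is
denser in gene-rich distal regions, so simulated Z1 marker *density* is
not elevated the way a real array's is. The knockdown-like alternative
(`apply_distal_shift`) moves a fraction (default 10%) of the interstitial
genetic mass to the terminal 2% of each arm, total length unchanged.

What passing tests on these simulations do **not** show: robustness to
segregation-distorted regions, heterozygosity-dependent miscalls,
position errors in the physical assembly, or array marker ascertainment —
none of which the generator emulates.

## Numerical and design choices

* Call codes are int8 (AA=0, H=1, BB=2, missing=−1); an F2 genotype is
  the sum of its two gamete haplotypes.
* Coordinates are 1-based inclusive bp; BED/BEDGRAPH exports convert to
  0-based half-open.
* QC defaults: marker missing ≤ 10%, marker HET ≤ 85%, segregation
  distortion α = 1e-6 (1:2:1 χ², 2 dof), individual missing ≤ 20%,
  individual HET ≤ 80% (F2 expectation is 50%). "Low quality" is not a
  published threshold set, so all are configurable; re-deriving the
  published surviving-marker and surviving-individual counts from the
  deposited data would require a threshold search.
* Filtering order is markers first, then individuals; filtering is
  idempotent.
* Marker spacing interacts with the confirmation window: the window's
  physical extent is `window` × spacing, and crossover pairs closer than
  that (across both gametes) are *both* discarded by the rule, thinning
  the count. At 2.6 markers/Mbp the loss is ~2–3% of crossovers; at 0.5
  markers/Mbp it reaches ~17% and the thinning measurably underdisperses
  zone counts (a conservative zone χ²). Calibration and recovery
  experiments therefore run at marker spacings where the window is small
  against the mean inter-crossover distance: study density (2.6/Mbp) for
  the calibration replicates, 0.05 cM spacing for parameter recovery.

## Experiment problem sizes

The replicated experiments (`recland.experiments`) use: exhaustive caller
validation to sequence length 8 plus 10,000 random length-12 sequences;
robustness on an error-free 90 × 1,500-marker population with ~1,900
injected singletons; parameter recovery over 10 seeds of a 200-individual,
500 cM-per-gamete genome at 0.05 cM marker spacing; calibration with 500
null replicate pairs at 60 individuals/population and 100 alternative
replicate pairs at 90/population, both at study marker density. These
sizes are the package's scaled-down re-enactment of the study design;
the alternative's effect (10% of interstitial cM moved to the terminal 2%
bins) is detected by the terminal-bin Wilcoxon or the Z1-vs-Z2 χ² only in
a minority of replicates at n = 90 — the per-replicate effect is ~0.5 SD
on 14 paired bins and ~2 SD on the χ² — so the calibration report states
component and joint detection rates rather than claiming high power.

Null calibration of the χ² p-values is judged by a KS test against the
uniform (the statistic is effectively continuous at these counts). The
exact signed-rank p-value is *discrete* — with 14 pairs it takes ~50
attainable values — and a continuous-uniform KS test rejects such
p-values purely for their discreteness as replicates accumulate.
Calibration of the terminal-bin test is therefore judged by a chi-square
goodness-of-fit against the exact finite-sample p-value distribution
(the signed-rank statistic's pmf enumerated by dynamic programming,
atoms merged to expected counts ≥ 5); the continuous-uniform KS is
reported alongside as a reference number.

## Known limitations

* The caller cannot see crossovers beyond the outermost markers or
  distinguish terminal-marker miscalls from terminal crossovers.
* `r` pools two meioses per individual and is not corrected for double
  reduction or estimator bias; map totals are presentation-faithful, not
  maximum-likelihood.
* Zone boundaries ship as configuration; analyses of real data need the
  assembly's published zone coordinates.
* The Wilcoxon pairing unit (chromosomes) is one defensible choice among
  several; per-arm and per-bin alternatives are exposed rather than
  hard-coded.
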