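# Methods

## The model

Multiplexed DNA FISH (seqFISH+-style) imaging localizes many genomic loci
per nucleus in 3D but does not show the fiber connecting them, does not
discriminate chromosome copies, drops a large fraction of true signals and
adds stray localizations. `fiberalign` reconstructs chromatin fibers from
such data by treating the chromatin between two imaged loci as a freely
jointed Gaussian chain: the spatial displacement between loci separated by
`L` bp is Gaussian per axis with variance

    S^2 = sigma_i^2 + sigma_j^2 + (2/3) * l_p * tau^2 * L

where `l_p` is the persistence length in bp (fixed at 150 bp), `tau` the
compaction scale in nm/bp that converts genomic into spatial distance
(`tau` scales both the contour length and the persistence length, removing
one free parameter), and `sigma_i`, `sigma_j` the localization
uncertainties of the two spots (default 50 nm per axis when the data carry
none). The bond probability of an observed separation `R` is the Gaussian
density; its negative log,

    w = (3/2) ln(2 pi S^2) + R^2 / (2 S^2),

is the edge weight of the alignment graph. An optional spherical-shell
variant subtracts `ln(4 pi R^2)`; it is off by default. All weights are
computed in pixel units (100 nm/px): with `tau = 0.34` nm/bp and zero
uncertainty, a 1-Mb segment evaluated at its full contour length costs
5013.34 and a 2-Mb segment 10014.38 — the two worked examples every
implementation should reproduce to two decimals.

## Spatial genome alignment

Each candidate spot of locus order `t` is a node; edges run strictly
5'→3' from order `t` to `t + c`, `1 ≤ c ≤ C`, so inversions,
translocations and duplications are outside the model by construction. A
source connects to candidates of the first `K + 1` orders and candidates
of the last `K + 1` orders connect to a sink; terminal pseudo-bonds price
late starts and early ends as an imaginary genomic segment stretched by
`alpha` (cost of the bond at `alpha` times the RMS displacement, plus the
standard gap charge per skipped locus). The minimum-cost source→sink path
— Dijkstra with a lexicographic (cost, locus order, candidate index)
tie-break for platform-stable results — is the maximum-likelihood polymer.
A path assigning fewer than `min_assigned_fraction` (default 25%) of the
reference loci is not a valid polymer.

### Gap penalties: affine, not geometric

A skipped locus must be penalized, or the aligner would prefer skipping:
under diffusive chain statistics (`E[R^2]` linear in `L`) the expected
bond exponent of an edge spanning `c` intervals is the same ~3/2
regardless of `c`, while `c` honest consecutive edges pay `c` entropic
prefactors. A multiplicative penalty `gamma^(c-1)` cannot work here: any
`gamma` large enough to forbid preferential skipping (~2 at typical
displacements) multiplies the cost of the long bridges that 50% signal
dropout requires by `gamma^(c-1)` (128x at `c = 8`), making heavily
dropped chromosomes untraceable, while any smaller `gamma` reinstates
skip-everything. The default penalty is therefore *affine*: each skipped
locus is charged the expected cost of the honest edge it avoided (the bond
cost at the RMS displacement of the median imaged interval, exponent
exactly 3/2) plus `skip_margin` expected exponents of reluctance (default
1.0). With this margin the aligner skips a detected locus only when its
local fit is roughly one expected exponent worse than typical, which
reproduces ~90% coverage at perfect information and graceful omission
under dropout. The geometric form (`gap_mode="geometric"`, default
`gamma = 2.0`, derived from the expected-cost no-preferential-skip
condition; the frequently quoted bound 10026.68/10014.38 ≈ 1.0012 holds
only for fully stretched chains) is retained for comparison.

`C = 11` is sized from run-length statistics: at 50% detection efficiency
the longest dropout run of a `T`-locus chromosome exceeds `C - 1` with
probability ≈ `T / 2^C`, so `C = 11` keeps even a 175-locus chromosome
traceable ~95% of the time; affine charges grow only linearly in `c`, so
the wide lookahead is safe. `K = 7` bounds terminal losses at
`0.5^(K+1)` ≈ 0.4% per end.

## Estimating the compaction scale

`tau` is chromosome specific and estimated from the data in two passes.
Pass one fits the power law `d = A L^beta` by log-log least squares
through nearest-candidate distances of adjacent imaged loci (pairs beyond
4x the median distance are trimmed as cross-territory artifacts), reads
the scale at the median imaged interval, and converts the geometric-mean
distance to the per-axis Gaussian scale through the chi-3 log-mean. Pass
two aligns single-copy-looking chromosomes (no locus offering two
candidates) under the rough scale and re-fits from within-trace
consecutive steps, which are same-fiber by construction. Because the
aligner preferentially skips poorly fitting loci, traced steps are
censored in their upper tail; the refit therefore matches the 25th
percentile of the observed exponent ratios `d^2 / ((4/3) l_p L)` against
the corresponding chi-square(3) quantile instead of fitting moments, and
iterates to a fixed point (3 rounds). On simulated confined chains this
recovers the generating scale to within a few percent at 0% dropout and
~6% at 50% dropout; on clean unconfined chains the plain power-law fit
recovers `tau` well within 10%.

## Polymer fiber karyotyping

Copy numbers are the count of physically plausible fibers, discovered by
iterative path subtraction: align, accept if the score passes the
physical-likelihood cut, remove the selected nodes, repeat (cap 8). The
search is greedy — the first fiber selects as many loci as it sees fit and
spots cannot be re-selected — so traces are node-disjoint and the method
may undercount but essentially never overcounts.

The likelihood cut comes from a scrambled-interval null: polymers
simulated at the fitted scale, degraded with the same dropout and stray
rates as the cohort, are *scored as laid down* against a reference whose
interval sequence has been permuted, so their observed distances no longer
abide by the genomic intervals. The null path is forced (no re-optimized
alignment, which would adaptively skip its worst loci and deflate the
null) and chain-following (each locus contributes the candidate nearest
the previous one, so strays do not inflate it). Scores are normalized per
assigned locus; a trace is accepted when its normalized score is below the
null median times `threshold_headroom` (default 1.5). The headroom
reflects a measured fact: genuine fibers in confined nuclei score within
~20% of the null scale (residual fitted-scale error plus confinement
compression), while junk paths — stray clouds, post-subtraction residues —
score severalfold above it or fail structurally (unbridgeable gaps, too
few assigned loci) before the threshold is ever consulted.

A stringent trisomy filter is available for 3N+ calls: the call must be
routed through three separate detections per locus for at least three
loci.

## The simulator

The built-in generator replaces molecular-dynamics polymer simulation with
a confined Gaussian-chain sampler whose per-interval, per-axis variance
`(2/3) tau^2 l_p L` matches the alignment model by construction; the
acceptance surface (alignment and karyotype error rates) depends on chain
statistics, not force-field detail. Study conditions, fixed once:

* 19 mouse autosomes + chrX with mm10-like lengths; loci from 3 Mb with
  i.i.d. U(0.3, 1.9) Mb spacing (~175 loci on chr1, matching 1-Mb-scale
  probe sets);
* generator compaction 0.035 nm/bp, giving an RMS 1-Mb separation of
  ~0.6 um as in published chromatin-tracing measurements;
* a 5-um-radius nucleus; each copy confined to a spherical territory of
  radius `R_nuc (L_chr / L_genome)^(1/3)`; same-chromosome territory
  centers repel to 0.8 territory diameters (best-effort in crowded
  nuclei), emulating territorial volume exclusion — without it, the
  globally optimal path forms a chimera through the pooled double-density
  spots of overlapping copies and copy-number detection collapses;
* copy numbers independent and uniform on {0..4}; 50-nm per-axis
  localization jitter; dropout i.i.d. per spot; strays uniform in the
  nuclear sphere with uniform locus identities at a rate per true locus
  slot;
* sister pairs: fiber B shadows fiber A with locus-wise isotropic Gaussian
  displacement of sd `500 nm / pairing_strength` (independent second fiber
  at strength 0).

What passing tests on this generator do *not* show: real chromatin is not
a Gaussian chain (compartment-dependent compaction, loop extrusion,
excluded volume), localization errors are not isotropic or independent,
stray spots cluster near bright sources, and detection efficiency varies
per probe. Conclusions about error *mechanisms* (placeholding, greedy
sister stealing, undercount-not-overcount) transfer; absolute rates need
not.

## Numerical choices and degeneracies

* Costs are clamped at zero after the negative-log transform (the
  spherical-term variant can otherwise go negative at large `R`).
* Equal-cost paths resolve to the lexicographically smallest
  (order, candidate) sequence; exact float ties only.
* Per-axis uncertainties are collapsed to the isotropic equivalent
  `sqrt(mean(sigma_x^2, sigma_y^2, sigma_z^2))`.
* Loci with no candidates contribute no nodes; empty chromosomes
  karyotype to zero copies.
* Degenerate power-law fits (single interval, equal distances) fall back
  with warnings; missing-locus interpolation for the misselection scan is
  linear in 3D between nearest assigned flanks with ends held constant.
* The misselection window follows the published chr1 procedure (3-locus
  window from locus 3 to `T - 2`, upstream bonds recalculated, both
  fibers must improve strictly); interpolated loci are eligible windows,
  since the procedure interpolates before scanning.
* In `assign_sisters`, SA/EA tie-breaks follow the fixed matching
  enumeration order, deterministic in the input trace order.

## Known limitations

* Strictly 5'→3' edges: structural variants are invisible by design.
* The scrambled null is weakly separated from genuine fibers in the
  diffusive regime (scramble shift ~0.4 per locus); the acceptance
  decision therefore leans on structural rejection for gross errors and
  uses the null only to cut egregious paths. Data whose distance scaling
  is locally string-like would separate far more sharply.
* Greedy subtraction steals sister spots when territories overlap
  (quantified by the misselection scan); a joint multi-fiber optimization
  is out of scope.
* `tau` estimation assumes enough single-copy-looking chromosomes in the
  cohort; pure-tetraploid cohorts fall back to the (bias-prone)
  all-traces refit.
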