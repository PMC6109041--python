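# Methods

This note documents the statistical procedures, the synthetic world the
test suite runs against, the numerical choices, and what a green test
does and does not establish. All coordinates are 0-based half-open;
intervals never include their end position.

## 1. Site calling (ChIP vs IgG control)

For each fixed-size bin *i* (default 1 kb) the ChIP count
*x<sub>i</sub>* is tested against a Poisson null with rate

    lambda_i = max( c_i * L_chip/L_ctrl,
                    mean(c_{i-w..i+w}) * L_chip/L_ctrl,
                    pseudocount )

where *c* is the control track, *L* are library sizes, *w* = 10 bins of
local background, and the pseudocount is 1.0. The one-sided p-value is
the exact Poisson survival function; Benjamini–Hochberg correction runs
across all bins, significant adjacent bins merge into peaks, and a peak
is kept only if its aggregate fold enrichment (Σx/Σλ) reaches
`min_fold` (default 2).

Choosing the *maximum* of the three rates makes the test deliberately
conservative: under a ChIP ≡ control null the realized false-positive
bin fraction is far below the nominal FDR (the suite checks the median
over 20 simulated nulls stays ≤ 0.05). An all-zero control falls back
to the global ChIP mean with a warning. The peak caller used in the
original experiments is not public; this transparent construction is
analytically checkable instead, so absolute peak counts from real data
are not comparable — only relative structure is.

- Defaults: bin 1 kb, FDR 0.05, min_fold 2.
- A "lamin B1+ gene" is a gene whose TSS ± 2 kb (configurable) is
  touched by a peak.
- Peak location categories: proximal = overlap with TSS ± 0.5 kb;
  distal = overlap with the strand-aware 2.5–0.5 kb upstream window
  (for minus-strand genes, upstream lies at larger coordinates);
  otherwise intragenic on gene-body overlap; otherwise intergenic.
  Precedence proximal > distal > intragenic.

## 2. eLAD segmentation

eLADs are clusters of neighbouring lamin B1+ sites: single-linkage
chaining with `max_gap` = 100 kb, keeping clusters with `min_sites` ≥ 3
peaks, spanning first-peak start to last-peak end. The span is
peak-bounded rather than gap-padded, giving conservative coverage
estimates. Both parameters are exposed because the original study's
exact values live in supplementary material that does not pin them
down; the defaults were chosen so domains on the default synthetic
world sit near the reported ~0.34 Mb mean size.

Increasing `max_gap` can only merge clusters (never split), so domain
count is non-increasing and coverage non-decreasing in `max_gap`; the
caller is idempotent on the peaks inside its own output. Both are
property-tested.

## 3. Hi-C: balancing, compartments, insulation, borders

**Balancing** is iterative proportional fitting to uniform row sums
(tolerance 1e-6 on the max relative deviation, ≤ 500 iterations,
error on non-convergence). Bins with a raw marginal below the 2nd
percentile of positive marginals — or zero — are masked and excluded
from every downstream statistic.

**Compartments** (100 kb): each diagonal of the balanced matrix is
divided by its mean (observed/expected), the Pearson correlation matrix
across bins is formed, and its leading eigenvector is PC1. The sign is
fixed by correlating PC1 with an orientation covariate — gene density
by default — and flipping if negative, so A (PC1 > 0) is the gene-dense
active state. Negating the eigenvector or the covariate therefore
flips nothing / everything predictably, which the suite asserts. A bin
changes compartment between conditions when PC1 flips sign (optionally
with a |PC1| floor, default 0).

**Insulation** (40 kb): score(i) is the mean balanced contact in the
`window × window` (default 5×5) square linking the bins upstream of *i*
to those downstream, log2-normalized by the chromosome-wide mean of
that quantity. Edge bins within `window` of a chromosome end and masked
bins carry NaN.

**Borders** are local minima of insulation with prominence ≥ 0.5.
Low-coverage masked bins are bridged by linear interpolation during
minimum detection, and a minimum landing on a masked bin is snapped to
its lower unmasked neighbour — masked bins never become borders. The
0.5 default separates the Poisson noise floor of the insulation profile
at ~10⁶ cis reads (spurious prominences ≲ 0.3) from planted-boundary
prominences (≳ 0.9 even at the weakest simulated TAD contrast).
Border strength is 10 × prominence / (max prominence on the
chromosome): a normalized 0–10 scale on which the strongest border per
chromosome always scores 10. Because that scale is
normalization-invariant by construction, cross-condition comparisons of
absolute border sharpening use the raw prominence, which grows
monotonically with the simulated TAD contrast (tested over three
contrast levels).

**Conservation**: borders of all conditions are pooled and clustered
greedily (seed at the smallest unassigned bin, absorb everything within
± tol = 2 bins); a cluster is conserved when every condition
contributes. **Occupancy** counts peaks intersecting the border bin ± 1
bin.

## 4. Integration statistics

*Feature × landmark contingency*: features (peaks, eLADs, cLADs, …) are
binarized per 100-kb bin by any-overlap (a minimum-fraction mode
exists); landmarks are A-compartment bins, B-compartment bins, or
border bins (40-kb border intervals lifted onto the 100-kb grid by
any-overlap — the native resolutions differ and this lifting is an
explicit assumption). The effect size is the natural-log odds ratio,
with the Haldane–Anscombe ½ correction applied *only* when a zero cell
would make it infinite, so exact values are preserved whenever defined.
The p-value is the two-sided Fisher exact test (scipy); the test suite
verifies it against an independent hypergeometric enumeration to 1e-10
relative error over an exhaustive small-table grid plus random tables
with margins ≤ 50.

*Border enrichment*: with `binomial`, the observed number of peaks
touching a border interval is tested one-sided against Binomial(n, p₀)
with p₀ = border bp / chromosome bp — an approximation that ignores
peak width (slightly conservative for wide peaks); `permutation`
re-places peaks uniformly preserving lengths (default 10⁴ rounds,
p = (1 + #{perm ≥ obs})/(1 + N)). Both agree to an order of magnitude
on the same input, which is tested.

*Dynamics*: exact set algebra over per-condition target-gene sets; all
Venn regions, the full intersection ("maintained") and its complement
within the union ("changed"). Percentages are reported rounded to
integers alongside exact fractions. DE overlap reports both directional
percentages (share of targets that are DE, and share of DE genes that
are targets).

*FRAP*: per-frame double normalization of the bleached-ROI intensity by
background and non-bleached ROIs, relative to the same ratio before the
bleach. Scale-invariant in the common intensity unit; zero denominators
raise an error naming the offending ROI.

## 5. The synthetic world

The generator plants everything downstream analysis should recover, in
one seeded `numpy.random.default_rng` stream (identical config + seed ⇒
byte-identical output). Defaults describe one 20-Mb chromosome:

| parameter | default | rationale |
|---|---|---|
| chromosome | 1 × 20 Mb | large enough for ~200 compartment bins and ~25 TADs, small enough for seconds-scale tests |
| compartment blocks | 1.0–2.2 Mb, alternating A/B, edges on a 200-kb unit grid | megabase-scale checkerboard; the 200-kb unit is the lcm of the 100-kb and 40-kb analysis grids, so block edges land on whole bins at both resolutions |
| cLADs | 20% of the genome, ~1-Mb blocks, inside B | gene-poor heterochromatic domains |
| planted eLADs | 16 per condition, gamma-distributed sizes, mean 0.34 Mb (CV 0.5) | ≈ 27% coverage, inside the 25.9–40.1% range reported for real eLAD sets |
| eLAD placement | weighted 3:1 towards the condition's A compartment, excluding cLADs | eLADs are A-enriched but not A-exclusive (new domains can arise in B) |
| eLAD separation | ≥ 220 kb between planted domains | identifiability: with `max_gap` = 100 kb, even a single 4-kb boundary site falling mid-gap cannot chain two planted domains into one |
| condition structure | 3 conditions; each later condition retains 28% of the base domains and plants replacements | exercises the dynamics accounting with a known answer |
| ChIP signal | punctate sites: 6-kb blocks / 1-kb gaps tiled through each domain at multiplier m = (E−1)/f + 1, f = 6/7 | the *mean* signal inside a domain is exactly E-fold the outside mean, while the 1-kb gaps split each domain into many peaks so the ≥ 3-site rule is meaningful; site coverage f ≈ 0.86 keeps bin-level recall ≥ 0.8 achievable |
| TSS bump / border sites | additive (E−1)·0.5 at lamin-positive TSSs; half of TAD boundaries carry a site at multiplier m | couples signal to expression status and to borders; both vanish at E = 1 so the null is exactly uniform |
| read depth | 10⁶ per track, Poisson | genome-scaled desk depth; overdispersion off by default for an analytically checkable null |
| TADs | 0.4–1.2 Mb on the 200-kb grid; compartment edges are always boundaries; in-block boundaries kept with p = 0.8 per later condition | TADs nest within compartments, so every A/B transition is also an insulation break; partial conservation gives the border-matching code something to do |
| Hi-C counts | decay (1+d)⁻¹ × 1.6 same-compartment × 2.0 same-TAD, 10⁶ cis reads, Poisson; per-bin log-normal visibility (sd 0.2) with 2% near-dropout bins | realistic O/E contrasts; the visibility term is what balancing removes and the dropouts are what the 2%-marginal mask is for — without them the mask would systematically eat true boundary bins |
| expression | log-normal, log-shift +2 for lamin-positive genes, σ = 1, 20% exact zeros | reproduces the "lamin-positive genes are expressed" contrast |

What the generator does **not** emulate: read-level artefacts
(duplicates, mappability structure beyond a flat optional track, GC
bias), fragment-length selection (only its net effect — enrichment
restricted to open chromatin — is modelled), diploidy, trans contacts,
and realistic gene-length/expression correlation. A green recovery test
therefore establishes the *algorithms* behave as specified on data with
the assumed statistical structure, not that real-data peak or domain
counts would be reproduced.

## 6. Numerical and degenerate-input choices

- Domain summaries use exact rational arithmetic (`fractions.Fraction`)
  before any float conversion; an empty domain set reports (0, 0.0, 0.0).
- GC content excludes ambiguous bases from the denominator; an all-N
  peak reports NaN.
- Expression strata: silent = FPKM < 0.5 (no threshold is published;
  configurable); remaining genes are ranked by (FPKM, gene id) — the id
  makes tie order stable — and split into three near-equal tertiles via
  `numpy.array_split`.
- Empty peak sets are legal everywhere (zero peaks ⇒ enrichment p = 1,
  fold 0; empty eLAD set; all-zero occupancy histogram). An empty gene
  set for a metaprofile is an error.
- Dense-matrix I/O symmetrizes asymmetries up to 1e-8 relative with a
  warning and rejects anything larger; loaded counts must be
  non-negative.
- The pipeline re-derives every per-stage seed from the master seed by
  fixed offsets, and the JSON report records the seed and the full
  parameter set.

## 7. Known limitations

- The per-bin Poisson test ignores overdispersion in real ChIP data;
  with the simulator's gamma-Poisson option enabled the caller is
  anti-conservative and a negative-binomial null would be needed.
- The binomial border-enrichment null ignores peak width and peak
  clustering; the permutation mode is the safer choice on real data.
- PC1-based compartment calls assume two dominant states; sub-
  compartments and chromosome-arm effects are out of scope.
- Border matching is greedy and seed-anchored; an optimal assignment
  could differ for pathological border spacings within the tolerance.
- With three conditions the dynamics accounting treats "maintained" as
  the full triple intersection, as in the figure it mirrors; pairwise
  persistence is available from the Venn regions.
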