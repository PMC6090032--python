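# Methods and model assumptions

This document records how each model in `rdnacn` is constructed: what is
taken from the published study design, what is calibrated, and what is this
package's own modelling choice. Coordinates throughout are base pairs
relative to the transcription start site (TSS) of the 47S precursor;
half-open intervals; window length = end − start.

## 1. Repeat-unit map (`repeat_model`)

**Published anatomy.** The unit is 43,000 bp with the unit frame starting
at −2,000 (upstream spacer) and a 13,300-bp coding region at 0..13300.
Probe windows are `p(ETS-18S)` = −515..5321 (5,836 bp ≈ 5.8 kb) and
`p(28S)` = 8289..10702 (2,413 bp), plus two 30-mer oligo windows inside
18S and 28S.

**Schematic site table.** The real unit contains hundreds of CCGG sites;
positions are not enumerated in the study. The default site table is
therefore *schematic*: 10 Csp6I (GTAC) sites and 24 CCGG (HpaII/MspI)
sites placed so that

- a Csp6I-only digest yields four probe-detected fragments,
- the complete CCGG digest reduces the probed region to sub-kilobase
  fragments (median ≈ 0.8 kb),
- four CCGG sites flank/straddle the promoter window (−200..100), two of
  them inside it, so that promoter-only methylation of the low-methylated
  fraction merges a promoter-proximal fragment without affecting the gene
  body.

`unit_from_fasta` can build a map from a real sequence by motif scan when
one is available; everything downstream is agnostic to where the site
table came from.

**Fractions.** A genome is a mixture of three copy classes:
fraction 1 (active, unmethylated), fraction 2 (inactive, promoter-CpG
methylated only) and fraction 3 (hypermethylated at every CCGG).
`genome_from_hyper(cn, f)` splits the non-hypermethylated share with a
default active share of 0.45. Digestion is circular (tandem-array context):
fragments tile the unit exactly, and a single cut produces one wrap-around
fragment. HpaII is blocked at methylated CCGG sites (Bernoulli per site
with the profile's methylation probability); MspI and Csp6I always cut.
Fractions with zero copies are omitted from the digest output, since they
leave no signal.

## 2. Membrane simulation (`membrane_sim`)

Dots are truncated (3σ) discrete Gaussians normalised to integrate exactly
to the requested amount, placed on a grid (pitch 48 px, σ 5 px). The noise
preset applies, in order: a constant background plus a linear gradient, a
multiplicative per-dot lognormal factor with CV `dot_cv`, additive read
noise, and uint16 saturation (flagged in the ground-truth ledger).

**Calibration of `dot_cv = 0.26`.** The study reports that CN estimates
from six replicate dots carry a relative standard error of ~11%. A grid
search over `dot_cv` with the full render→quantify pipeline showed
`dot_cv = 0.26` reproduces a mean per-sample relative SE of ≈ 10.5–11%
(0.26/√6 ≈ 0.106 analytically). Background 800, gradient 300 and read
noise 25 are plausibility choices; results are insensitive to them because
quantification subtracts local background.

The standard layout carries six genomic-DNA standards (200..700 copies) in
**triplicate rows**: with single-dot standards the noisy fitted slope
enters the estimate as 1/slope, whose Jensen bias inflated CN by ~8%;
triplicate standards reduce that bias below 2%.

`render_southern_pattern` converts a digest spectrum to a band list
(length, intensity = copies × probe overlap, relative intensity) for
electrophoresis-style comparisons; band *positions* in the published
figures are graphics-only and are not reproduced.

## 3. Densitometry (`dot_quantifier`)

Dot centres are found by mean-shift from the layout's nominal grid
positions (window 0.55 × pitch); dots displaced by more than pitch/2 are
flagged `off_grid`, dim dots `low_signal` (MAD-based threshold). The
integral is the background-subtracted sum over a circular aperture
(3σ + 2 px); background is the median of an annulus with the apertures of
neighbouring dots masked out. Saturated dots are excluded.

Calibration regresses standard-dot integrals on copies × ng (OLS through
`scipy.stats.linregress`) after subtracting the lambda-control floor
(mean lambda integral, an estimate of nonspecific binding + residual
background). Sample CN = (integral − floor − intercept)/(slope × ng),
averaged over usable replicates with an SE; a single usable replicate is
flagged `low_confidence`, none `no_usable_replicates`.

## 4. Methylation index (`methylation_index`)

**Retention model.** Membrane retention of a fragment of length L is
`w(L) = L^k / (L^k + l50^k)` with steepness k = 4 — a logistic in log L.
The dot signal of a digest is Σ copies × probe-overlap × w(L). Under the
three-fraction model M is exactly affine in the hypermethylated fraction:
`M = M0 + f·(M1 − M0)`, with M0 ≈ 1 (the small excess over 1 comes from
the promoter-methylated fraction-2 copies) and M1 equal to the per-copy
gain g of an uncut over a fully cut spectrum.

**Calibration.** The single free parameter l50 is solved (Brent root find
in log10 l50) so that f = 0.30 — the top of the published 3M band — gives
M = 2.9, the top of the published M range. This yields l50 ≈ 1,210 bp and
g ≈ 7.3. Nothing else is tuned; that the published correspondences then
emerge (f = 0 → M ≈ 1.0, f ≈ 0.05 → M ≈ 1.3, f ≈ 0.10 → M ≈ 1.6,
2M band ≈ f 0.05–0.12) is a consistency check of the model, and the group
thresholds 1.3 and 1.8 sit in the gaps between the published bands
(boundary values classify upward).

**Inversion.** `estimate_hyper_fraction` inverts the affine model exactly
(round-trip error < 1e−9), clips to [0, 1], and propagates an M
uncertainty into an f interval. `compute_M_membrane` measures M through
rendered membranes (ratio of floor-corrected mean dot integrals of the two
digests, averaged over replicate experiments) instead of the closed form.

## 5. Cohort synthesis (`cohort_synth`)

The study cohort is 651 adults: non-elderly (NE, n = 525, 17–71 y) and
elderly (E, n = 126, 72–91 y; 72 is the mean-lifetime cut).

**NE generator.** Five published facts constrain the NE CN distribution:
support 200–711, mean 419, SD 110, median 410, 10% below 272 and 15% above
541. No standard parametric family satisfies all of them, so NE values are
drawn through a monotone piecewise-linear quantile function that passes
exactly through the five printed quantile anchors, with four free knots
(at probabilities 0.05, 0.30, 0.70, 0.93) solved once by least squares so
the distribution's mean and SD match the printed moments (achieved within
0.05 copies; construction fails loudly if the constraints are infeasible).

**Elderly group.** E CN values are survivors of the NE distribution:
either hard truncation to the printed E support [272, 541] (default) or a
product of two logistic survival weights whose parameters are fitted so
survivors reproduce the printed E mean 396 / SD 63; `e_mode="none"` is the
null model. Ages are uniform within each group's range; the 545:106 sex
ratio is reproduced marginally.

**Methylation groups.** Group probabilities follow the 40 + 40 survey:
NE (1M/2M/3M) = 0.50/0.20/0.30 (20 of 40 carriers), E = 0.90/0.05/0.05
(4 of 40 carriers). True hypermethylated fractions are drawn uniformly in
group-consistent bands: 1M 0–0.02, 2M 0.05–0.12, 3M 0.13–0.30.

## 6. Cohort statistics (`cohort_stats`)

Summaries use ddof = 1 SD and CV = SD/mean. Mann–Whitney and KS two-sample
tests delegate to `scipy.stats` (exact small-sample methods where
applicable). The published dispersion contrast has no stated test
construction, so the package defines its own: a pooled label-permutation
test of a CV or range difference, two-sided, with the add-one convention
p = (1 + #{|T*| ≥ |T|})/(n_perm + 1). Binned dispersion profiles use
5-year NE bins and 2-year E bins, flagging bins with n < 5.

The hard survivor fit estimates truncation bounds from the E extremes with
a first-order spacing correction, lower = x(1) − (x(2) − x(1)) and
upper = x(n) + (x(n) − x(n−1)), which removes most of the inward bias of
the raw min/max; at the study's group sizes the bounds are recovered
within ~10 copies on average. A KS test of truncated-NE vs observed E
serves as goodness of fit.

## 7. Senescence model (`senescence`)

Each fibroblast line starts at passage 5 with CN equal to its donor's
leukocyte CN and a hypermethylated copy count obtained by inverting the
leukocyte M. Per passage, each hypermethylated copy is lost independently
with probability λ (binomial thinning; geometric decay in expectation);
all other copies are conserved exactly, and M is recomputed every passage.

Only the endpoints were observed, so λ is an assumption: the default
λ = 0.10 makes loss essentially complete by even the shortest line's final
passage ((0.9)^40 ≈ 0.015). Endpoint change calls compare passage-5 and
final values against ±1 SE measurement intervals using the per-line SEs in
the packaged table. The packaged five-line table (`data/fibroblast_lines.yaml`)
carries each line's donor age, final passage (encoded in the line name),
and leukocyte/passage-5 CN and M with SEs.

## Limitations

- The CCGG/GTAC site table is schematic; fragment lengths and band
  positions are illustrative, not sequence-accurate. Conclusions that
  depend only on probe-mass and retention contrasts are robust to this;
  per-band comparisons with real gels are not supported.
- The retention model is a single logistic; real membrane retention also
  depends on transfer chemistry and probe stripping.
- Copy methylation is modelled as three discrete classes; real copies show
  intermediate CpG patterns.
- The NE quantile function is only constrained at five probabilities plus
  two moments; distributional detail between anchors is interpolation.
- Survivor selection is modelled on CN alone; mortality obviously depends
  on much else. The model formalises a hypothesis, not a demographic
  claim.
- The per-passage loss rate in senescence is unidentifiable from endpoint
  data; any λ with near-complete terminal loss fits the observations.
- Statistical conventions (two-sided tests, permutation construction,
  add-one p-values) are this package's own where the study did not state
  them; exact published p-values are therefore not reproduced.
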