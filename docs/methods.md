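# Methods

## The screen and its latent model

`adhescreen` analyses arrayed RNAi adhesion screens: every well of a
384-well plate silences one gene (round 1: the gene's three siRNA duplexes
pooled; validation rounds: duplexes in separate wells), bacteria adhere to
the silenced monolayer, and two-channel imaging yields the per-well
bacteria-to-nuclei ratio. The simulator draws from the latent model the
analysis is meant to invert:

* **Gene effect** e ∈ [0, 1] — fractional loss of adhesion under complete
  silencing. Non-receptor genes have e = 0; planted receptors draw
  e ~ Uniform(0.7, 0.95). The upper range reflects that screens of this
  design can only recover receptors whose loss substantially reduces
  binding; weak receptors are a stated limitation (below).
* **Knockdown efficacy** k ~ Uniform(0.6, 0.9) per duplex. No public
  measurements of per-duplex efficacy exist for this assay, so the range
  brackets what transfection-optimised commercial libraries typically
  achieve; it is a free parameter of the generator.
* **Pooling rule** — a pooled well combines duplexes by independent action,
  k_eff = 1 − Π(1 − k_i) (a `max` alternative is available). With three
  duplexes the default gives k_eff ≈ 0.94–0.99, so the pooled round is more
  sensitive than single-duplex rounds, matching how pooled primary screens
  behave.
* **Off-target noise** — the well multiplier is m = (1 − e·k_eff)·L with
  L lognormal, sd 0.15 on the log scale and E[L] = 1. The noise is
  two-sided because real screens show wells with *increased* adhesion;
  those wells are binned into the remainder and never followed up.
* **Controls** — scrambled and untreated wells have m = L; antiserum-block
  wells sit at a residual adhesion of 5% of baseline (the assay floor is
  visible but small); death-control wells keep m = 1 while nuclei drop to
  1 − death_efficacy = 15% of normal, which is what the transfection-
  efficiency rule inspects.
* **Counts** — N_nuclei ~ Poisson(300·survival) per field;
  N_bacteria | N_nuclei ~ Poisson(N_nuclei · 4.0 · m). A per-plate
  lognormal scale (sd 0.15) on the bacterial channel models staining/batch
  effects and must be cancelled by per-plate normalization.

## Image rendering and quantification

Rendered wells are single-plane, two-channel 16-bit images (default
512×512 px at 0.65 µm/px): nuclei as Gaussian blobs (radius 8 ± 2 px,
σ = radius/2, amplitude 3000 counts), bacteria as puncta (σ = 1.2 px,
amplitude 1500), over a per-channel offset (100/80 counts) plus diagonal
ramp (40/30), with Poisson photon noise and Gaussian read noise (σ = 2).
Placement keeps ≥4 nucleus radii between nucleus centres and ≥8 punctum
sigmas between puncta so that, in noise-free renders, thresholded
footprints are disjoint and quantification recovers the embedded object
list exactly — the basis of the oracle-equivalence tests. Fields too
crowded to satisfy the separation fall back to unconstrained placement and
carry a `clipped` flag; the default 300-nuclei field is such a confluent
case, which is fine for count-level simulation but only the sparser
(~50-nuclei) renders are used for exact-recovery checks.

Quantification subtracts a Gaussian-blurred copy of each channel
(scale 50 px; morphological top-hat available), clips at zero, applies
Otsu's threshold per channel (fixed thresholds available), labels
8-connected components, and filters by area (nuclei 30–3000 px², bacteria
1–80 px²). An optional distance-transform watershed splits touching
nuclei; it is off by default because confluent monolayers make splitting
error-prone and a systematic undercount cancels in the ratio and in
per-plate normalization. Bacteria may additionally be gated by mean
intensity; the default gate is 0 so that counts are invariant under
detector gain with Otsu thresholding. Per-well flags: `zero_nuclei`
(ratio undefined), `low_confluence` (< 20 nuclei), `saturated` (> 1% of
pixels at the bit-depth maximum). Multiple fields of view per well are
summed object-wise before the ratio. Note that component counts are only
guaranteed monotone in the threshold for non-merging objects; at very low
thresholds touching objects merge and the area filter can remove them.

The ratio uses object *counts*; an `intensity_sum_ratio` column
(integrated green over integrated DAPI object intensity) is reported in
parallel since instrument software is ambiguous about which "total amount"
enters the ratio.

## Plate QC

Per plate, medians/means/sds of ratio and nuclei counts are computed per
control class over unflagged wells. Three rules gate a plate (thresholds
config-exposed; the defaults are the package's own choices):
death-control nuclei median must be < 0.5× the negative-control median
(`transfection`), antiserum-block ratio median < 0.3× the negative median
(`block`), and scrambled vs untreated ratio medians within 30% relative
(`reagent`). A failing plate is re-screened once with a fresh seed — as a
laboratory would repeat a failed plate — and excluded if it fails again.
With 8 wells per control class the `reagent` rule has a small
false-alarm rate from median sampling noise, which the single repeat
absorbs. A separation score (neg − block medians over summed sds) is
reported but never gates.

## Normalization and hit calling

*Percent-of-negative-control*: normalized = 100 · r / median(r_neg) per
plate, decrease = 100 − normalized. *Fold-over-antiserum-block*:
normalized = r / median(r_block) per plate; because this rescales rather
than centres, decreases for hit calling in fold mode are referenced to the
same plate's negative-control fold median (algebraically identical to the
percent-mode decrease, kept explicit for auditability). Flagged wells are
dropped before medians; a plate with no usable reference wells or a zero
median is a hard error. Median anchoring (neg median ↦ exactly 100, block
median ↦ exactly 1) and invariance to any positive per-plate scale are
tested properties.

Decrease bins are half-open, upper-inclusive — (70, 100], (50, 70],
(25, 50] — so boundary wells go to the bin whose upper edge they equal and
the three labels partition cleanly; increased-adhesion wells land in the
remainder.

The cascade: round 1 calls a pooled gene a hit iff decrease > 30%
(strict); round 2 requires ≥2 of 3 single duplexes each with decrease >
30%; round 3 requires ≥2 of 5 duplexes from an independent library under
fold-over-block normalization. The 30% per-duplex threshold in rounds 2–3
is a package choice (kept equal to round 1 for consistency); it is
config-exposed. Genes losing all wells are reported as unmeasured rather
than not-hit; sorting ties break lexicographically by gene id for
reproducible reports. Final candidates are genes that are hits in every
round; recall and null false-positive rate against the generator's truth
are part of the run report.

## Blocking assay statistics

Percent adhesion is 100 · cpm_adherent / cpm_added per replicate well
(five technical replicates by default); "sd" is the sample (n−1) standard
deviation. Each antibody condition is compared with the basic assay by a
two-sided, equal-variance two-sample Student's t-test computed from the
pooled-variance formula (a Welch variant is available); "pairwise" here
means each condition against the basic assay, not a paired test —
replicate wells are independent. Only the Student-t survival function is
delegated to scipy; the statistic is tested against scipy and against a
simulated null distribution, and its type-I error is calibrated by
simulation. No multiple-testing correction is applied across the (four)
antibody conditions. Degenerate zero-variance inputs: equal means give
t = 0, p = 1; unequal means give ±∞, p = 0. Replicate counts below two are
rejected.

## Reproducibility and problem sizes

Every generator is a pure function of its spec and a seed; a top-level
seed expands to per-well generators via `SeedSequence(seed,
spawn_key=(plate_index, well_index))`, so any well can be re-simulated in
isolation, and a whole run is reproducible from (config, seed) alone. The
multi-seed checks use 200-gene screens with 4 planted receptors (or none)
over 50 seeds in counts mode, and 25–50 rendered wells at ~50 nuclei /
~200 puncta for imaging checks — sizes chosen so the behaviour of interest
(cascade selectivity, exact object recovery) is measured at comfortable
statistical resolution while a full suite runs in well under a minute.

## What the simulator does and does not emulate

It emulates: control-block plate layouts, pooled vs deconvolved rounds,
plate-to-plate scaling, two-sided off-target variation, Poisson count
noise, death-control nuclei loss, the antiserum floor, background
gradients and sensor noise in images. It does **not** emulate: transfection
chemistry or mRNA kinetics (knockdown is a scalar), cell-cycle or
morphology variation, uneven illumination beyond a smooth ramp, bacterial
aggregation or per-nucleus spatial association of bacteria, 3D/time-lapse
imaging, or seed-sequence-driven correlated off-target effects (noise is
independent across wells, which makes multi-round false positives rarer
than in real screens — passing recovery tests bounds pipeline errors, not
biological artefacts). Genome-scale plate counts are exercised
arithmetically, not simulated well-by-well.
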