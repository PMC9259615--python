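# Methods

## The reaction model

PEN DNA reactions are driven by three enzymes acting on short templates: a
polymerase extends a primer bound to the template, a nickase cuts the
extended duplex so the product strand can leave, and an exonuclease degrades
free single strands. An *autocatalytic* node is a template whose product is
its own primer; a *linear* node produces a different strand. The mechanistic
literature describes these steps but gives no rate constants for the
conditions modelled here, so the simulator uses deliberately lumped rate
laws whose purpose is to reproduce the observed regimes, not to be fitted:

    v_prod(s; T) = k_pol · P · T · s/(K_m + s) · 1/(1 + s/K_i)
    v_deg(s)     = k_exo · E · s/(K_exo + s)

The first factor is primer occupancy on the template, the second is product
inhibition (at high concentration the primer occupies both template ends and
blocks extension); degradation saturates the exonuclease. dNTPs are treated
as unlimited — plateaus arise from product inhibition and degradation, not
pool depletion. Stochastic kinetics and intra-droplet spatial gradients are
out of scope.

Compartments couple to the outer phase by first-order exchange `k_ex(s_out −
s_j)`, volume-weighted on the outside. Polymerase partitions into the
droplets; the measured sequestration ratio of ≈ 5.7 enters as an interior
production multiplier (`seq`). The fluorescence observable mimics an
intercalating dye: `F = F0 + α · (T·s/(K_m+s) + 0.1·s)` — template occupancy
plus a small extended-strand term. The 0.1 coefficient is an arbitrary fixed
constant exposed in the configuration.

### Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| k_pol | 5·10⁻³ | min⁻¹ per nM template | buffer reaction at 1 µM template grows at ~0.1/min |
| K_m | 50 | nM | primer occupancy half-saturation; sets sigmoid midpoint scale |
| K_i | 100 | nM | product inhibition onset above the occupancy scale |
| k_exo | 0.4 | min⁻¹ per nM exonuclease | places the dispersion switch-off inside the 0.6–9.6 nM window |
| K_exo | 50 | nM | degradation saturates at tens of nM substrate |
| k_ex | 0.03 | min⁻¹ | effective membrane exchange of the reacting strand (template binding retards the free-DNA exchange seen in FRAP) |
| seq | 5.7 | — | measured polymerase enrichment in the droplet interior |
| T_in | 0.12 | µM | calibrated per-droplet template content |
| α, F0 | 10, 50 | RFU/nM, RFU | arbitrary camera scale |

With these values the model reproduces, qualitatively: sigmoidal growth with
onset delay in droplets at nanomolar *total* template; full switch-off at
9.6 nM exonuclease in the dispersion while the 1 µM buffer reaction keeps a
positive rate at every tested level; monotone rate increase with droplet
density; and, in the two-node network, a pulse in the linear population, a
delayed sigmoid in the autocatalytic one, and rates tunable by the
linear-template level. These defaults were chosen once to sit in the
documented experimental regimes and are not presented as fitted to any
measured kinetics.

### Integration and initial conditions

Fixed-step classical RK4 on the sampling grid (optionally substepped);
round-off negatives are clamped to zero, anything below −10⁻⁹ nM or
non-finite aborts with the offending time. A unit test pins RK4 against a
100×-finer forward-Euler oracle (agreement < 0.5% relative).

The externally supplied primer is placed at its outer-phase concentration
*inside* the compartments as well at t = 0: membrane passage of a 20-mer
(D ≈ 8 µm² s⁻¹ over ~12 µm) takes seconds, far below the minutes-scale frame
interval. This also makes the sealed single-compartment case (`k_ex = 0`)
reduce exactly to the bulk model, which the tests exploit as an oracle.

## Rate extraction

Growth curves are fit with the logistic `A(x) = L/(1 + e^{k(x−x₀)})` written
exactly in this form — an *increasing* sigmoid therefore fits with k < 0 and
the reported rate is |k| (or the maximum slope |k|·L/4 in RFU/min for
unnormalised droplet traces; the mode is recorded in the estimate and mixing
modes in one dr/d[T] fit is an error). The fit window [0, t_f] comes from
the data: the discrete differences of the signal peak at the inflection; a
Gaussian `a₁·exp(−((x−b₁)/c₁)²)` fit to them is inverted (natural log, as
forced by the exponential) at `f = a₁/2` to give
`t_f = b₁ + c₁·√(ln(a₁/f))` — the time where the growth increment has
decayed to half its maximum. Convergence of the Gaussian step requires
solver success *and* `a₁ > 2 × MAD-noise` of the difference series (a
scale-free criterion); on failure, or when t_f falls outside the sampled
times, a fallback window of 60% of the trace duration is used and recorded
(`window_source`). Differences are fit raw by default; a 3-point moving
average is available in the configuration.

A trace whose smoothed signal never climbs above its starting value (beyond
5× the noise floor) is flagged *no-growth* with rate 0 — this covers both
truly flat traces and switched-off compartments whose pre-loaded primer
signal only decays. Profile classification uses the same rise criterion:
*flat* when there is no rise, *pulse* when the maximum is followed by a
sustained decline of ≥ 20% of the rise, else *sigmoidal*.

Box statistics use Tukey adjacent values at 1.5×IQR (the whisker rule is not
specified in the source descriptions; Tukey is the common default).

## Image analysis

Segmentation: Gaussian blur (σ = 2 px default; the blur is only there to
avoid empty pixels at thresholding), Otsu threshold (method unspecified
upstream; Otsu keeps the result invariant to global intensity scaling),
hole filling, distance-transform watershed to split touching droplets, then
connected components filtered on circularity 4πA/P² ∈ [0.7, 1.0] (values up
to 1.1 from discretisation are clipped to 1, beyond that the object is
rejected) and equivalent-circle diameter ∈ [17, 25] µm. The diameter filter
is interpreted on the equivalent-area-circle diameter in µm, consistent with
droplet radii ≈ 12 µm (the original macro's size argument could also denote
areas; this reading is a documented choice). Segmentation runs once on a
reference frame and the masks are reused across frames — the droplets are
sedimented and immobile, so no tracking or drift correction is attempted.
Readout per droplet and frame is integrated intensity divided by mask area.

Size statistics use the sample (n−1) standard deviation; RSD = 100·sd/mean.
Note that a population quoted as 12.1 ± 1.8 µm has RSD 14.9% by this
definition even where 14% is quoted — the generator targets the quoted
(mean, RSD) pair and tests check within sampling error only.

The count↔fluorescence calibration is an OLS line; the dispersion-wide
template concentration is `0.12 µM × (droplet volume / sample volume)`,
reported in nM.

## FRAP

Normalization: `(raw − background)/(reference − background)`, rescaled by the
pre-bleach mean; whole-droplet bleaches additionally divide by the
background-corrected whole-droplet series. Recovery is fit on post-bleach
samples with `I(t) = 1 − A·exp(−(t−t₀)/τ)`, t₀ being the first post-bleach
sample (the two time symbols in the usual write-up are treated as the same
instant). When residuals reject full recovery (F-test on the nested fits at
5%), the plateau C becomes free and the immobile fraction is
`1 − (C − I(t₀⁺))/(1 − I(t₀⁺))`; the same quantity computed from the last
measured points is reported alongside, since either convention is found in
practice. The reported A is always the bleach depth `1 − I(t₀⁺)`.
`D = 0.88 r²/(4 τ ln 2)` uses the natural log (the relation converts τ to
the half-time t½ = τ ln 2 in the classic half-time formula); the bleach-spot
radius r is always user input, never inferred from images. Apparent D values
support comparisons between conditions, not absolute transport measurements;
profile-based (Soumpasis/Axelrod) fitting is deliberately out of scope.

## Synthetic data: what it does and does not emulate

The generators produce: sigmoidal autocatalytic growth with onset delay and
plateau, pulse-shaped linear-node profiles, exonuclease-dependent switch-off,
near-monodisperse (RSD ≈ 14%, normal) and polydisperse (RSD ≈ 48%,
log-normal) droplet populations, normal/log-normal per-droplet template
loading, uniform-interior disks with additive Gaussian read noise, and
exponential FRAP recovery with an immobile fraction. They do **not**
reproduce membrane-edge dye enrichment, Poisson photon statistics, focus
drift, droplet motion, or intra-droplet gradients. Passing tests therefore
demonstrate that the analysis code is correct on data obeying its stated
model, and say nothing about optical artefacts real microscopy may add.

## Problem sizes and determinism

The benchmark studies default to desk scale: 100 traces for rate and FRAP
recovery, 1000 draws for the window-inversion check, 50 frames for the
segmentation benchmark, 3–8 compartments per simulated dispersion. Every
stochastic step takes an explicit seed; the pipeline derives all randomness
from the single config seed and writes SHA-256 checksums of every output, so
identical configs give byte-identical CSVs.

## Known limitations

- The rate constants are illustrative; only the regime structure (which
  behaviours occur in which concentration windows) is meaningful.
- The two-node study's droplet volume fractions are larger than typical
  experimental densities so that communication is visible with a handful of
  compartments; the template *ratios* (0.25:1, 0.5:1, 1:1) are preserved.
- Segmented masks include ~1 px of boundary background, biasing extracted
  intensities low by ~1–2%; ground-truth masks in the tests quantify this.
- The printed logistic form makes k's sign opposite to intuition; all
  reported rates are magnitudes.
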