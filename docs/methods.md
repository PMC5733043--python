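# Methods

This note documents the models, conventions and numerical choices behind
`oisi`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and where
the design was genuinely open.

## Signal model

The optical intrinsic signal is treated as a small relative intensity change
of cortical tissue under band-limited illumination. Two processes drive it:

* **Hemodynamic response (HR):** concentration changes of oxy- and
  deoxyhemoglobin, Δ[HbO] and Δ[HbR] (µM), absorbing with band-averaged
  extinction coefficients ε (mm⁻¹ µM⁻¹). Total hemoglobin is defined as
  HbT = Δ[HbO] + Δ[HbR] and is computed as that sum at every timepoint — it
  is an identity, not a fitted quantity.
* **Light scattering (LS):** an activity-dependent tissue-transparency
  change modeled as a dimensionless pseudo-chromophore ΔS with "extinction"
  μs′, the reduced scattering coefficient (mm⁻¹). μs′ varies weakly with
  wavelength over the visible/NIR range, so band-constant values are a
  reasonable default, but it remains a per-band field and non-uniform
  values are accepted.

The modified Beer–Lambert law links these to the measured attenuation per
band λ:

    OIS_λ(t) = (Δ[HbO]·ε_HbO,λ + Δ[HbR]·ε_HbR,λ + μs′_λ·ΔS(t)) · 2·d_IV

The effective photon path is exactly `2·d_IV` — down to cortical layer 4 and
back — identical for absorption and scattering (D_a = D_s). Wavelength-
dependent differential pathlength factors and photon-transport modeling
(Monte Carlo, diffusion theory) are deliberately out of scope; the linear
small-signal model is the point of the package. Recovered concentration
changes may be negative (they are changes from baseline); no positivity
constraint is imposed.

**Units are carried, not assumed**: ε in mm⁻¹ µM⁻¹ (base-10 convention),
μs′ in mm⁻¹, lengths in mm, concentrations in µM, ΔS dimensionless.
Spectrum CSVs carry a units header; band definitions are pure data, so any
diode set can be described without code changes.

### Band-averaged coefficients

LED emission is not monochromatic, so extinction curves are averaged with
the emission spectrum as weight: ε̄ = ∫L(λ)ε(λ)dλ / ∫L(λ)dλ, trapezoidal
quadrature on the union of the two wavelength grids with linear
interpolation; a single-sample emission degenerates to point evaluation.
The shipped GREEN/RED/IR coefficients are representative literature-scale
values for hemoglobin extinction and cortical μs′; they are editable
defaults for demonstrations and tests, not measurements of any particular
rig, and any quantitative application should supply its own curves.

### Inversion

With n ≥ 3 bands the 3-unknown system is solved per timepoint: exact
`solve` for n = 3 (the default; no regularization), least squares with
per-timepoint residual reporting for n > 3. The coefficient matrix's
condition number is computed at assembly and logged; inversion refuses to
proceed above 1e8. With the default bands and d_IV = 0.35 mm the condition
number is ≈ 4.6e3 — ill-looking only because the ΔS column (≈1 mm⁻¹ scale)
and the hemoglobin columns (≈1e-3 mm⁻¹ µM⁻¹ scale) live in different
units; the round-trip error is at machine precision (≈1e-15).

Sign conventions are explicit metadata. Raw reflectance traces are relative
intensity (darkening negative); attenuation is their negation. Transmission
traces carry the attenuation sign directly (a scattering increase brightens
transmitted light while darkening reflected light, so the same response
flips sign between modes). The decomposer consumes the (mode, polarity)
pair, which is why reflectance and transmission recordings of one scene
yield identical chromophores.

## Preprocessing

* **Spatial smoothing:** per-frame 2-D Gaussian, default σ = 2 px, kernel
  truncated at 4σ, reflect boundary. No temporal filtering anywhere in the
  raw-stack path.
* **Illumination correction:** the mean intensity over a response-free
  reference region gives the shared profile I_ref(t); each pixel is
  corrected as I(t) − α·I_ref(t) with α the time-mean of I(t)/I_ref(t),
  computed per pixel. The averaging window for α is the full trial by
  default; a baseline-only window is available as an option without
  endorsement, since neither choice is canonical. A purely multiplicative
  fluctuation shared with the reference region cancels exactly. Frames
  where I_ref drops below 1% of its median are an error, never silently
  skipped. The default reference region is the 10-px image-border ring (an
  operator-drawn region has no algorithmic definition); any user mask can
  replace it.
* **Trial averaging:** per-frame arithmetic mean, accumulated in extended
  precision so the result is independent of trial order.

Because α is estimated over the whole trial, it absorbs part of the
response mean at response pixels. Extracted time courses are therefore
re-referenced to their own baseline-window mean — the same contrast the
OIS map uses. With this convention the noiseless
simulate → render → analyze closure is exact (≈1e-9 relative).

## Mapping and extraction

The map contrasts window means (full 10 s stimulation vs. full 5 s
baseline, both overridable) normalized by the raw baseline; frame-by-frame
difference movies are not produced. Active-region detection replaces the
operator: pixels with |value| ≥ 0.5·max|value| (threshold overridable), the
4-connected component containing the global extremum, row-major tie-break —
fully deterministic, invariant to sign and scale. Only single-region
extraction is supported per call.

Mask-averaging a bell-shaped response underestimates its center amplitude,
and the spatial filter widens/deflates the profile further. When the true
spatial profile is known (synthetic scenes record it in the sidecar), the
exact correction factor is the mask mean of the filtered profile, and
center amplitudes are restored to numerical precision — this keeps
parameter-recovery tests sharp. For recorded data the factor falls back to
the map's own mask-mean/peak ratio, which corrects mask shape but not
filter widening; absolute amplitudes on real data are correspondingly
approximate (relative comparisons and all timing quantities are
unaffected).

## Response metrics

* **Amplitude:** the 95th percentile of the signal over the analysis window
  (stimulus onset → trace end by default), linear interpolation between
  order statistics (the percentile definition is pinned so oracle tests are
  exact). Fractions internally, percent in reports.
* **Peak position:** first sample at/after onset reaching the amplitude;
  granularity one frame (0.2 s at 5 Hz).
* **Half-recovery T₀.₅:** first post-peak time the signal falls to half
  amplitude, linearly interpolated between the bracketing samples; a trace
  that never recovers returns an explicit unresolved sentinel (None), not a
  number.
* **Average LFP:** rectified integral over the stimulation window divided
  by its duration. "Cumulative averaged" LFP admits several readings
  (integral, mean, per-second cumulative sum); the rectified-mean
  convention is recorded in output metadata and the alternatives are not
  endorsed.
* **Optimal rates:** the 3 stimulation rates with the largest amplitudes
  (pooling the strongest responses is how low-SNR per-rate data are made
  usable), ties toward the lower rate.
* **Statistics:** one-tailed Mann–Whitney U — exact by enumeration of all
  C(m+n, n) group assignments for m+n ≤ 12 (ties as ½), tie-corrected
  normal approximation with continuity correction otherwise; one-tailed
  sign test — exact binomial tail after dropping exact ties. Directions are
  explicit arguments, never inferred from the data. No multiple-testing
  correction is applied across pairwise group grids; reports note this.

### Kinetic read-out on decomposed traces

Peak times and T₀.₅ of the decomposed chromophore traces are read out by
least-squares fitting a gamma-variate kernel (free amplitude, peak time and
shape; free onset delay for the hemodynamic components; negative-going
traces fitted on their negation). Local estimators are inadequate here:
sample argmax of a broad noisy peak jitters by seconds, and a quadratic
vertex fit is biased late on these asymmetric kernels (the bias grows with
the fit window). The matched parametric fit is the standard approach for
transient hemodynamic-type curves and recovers peak times to well under one
frame at the pipeline's operating noise level. T₀.₅ follows from the fitted
shape in closed form. If a fit fails to converge, the read-out falls back
to the smoothed (Savitzky–Golay, 3 s quadratic) argmax/vertex estimate and
the sample-level half-recovery operator.

## Synthetic data generator

The generator is the forward model the analysis must invert, emulating a
one-condition evoked-response acquisition: 5 s baseline, 10 s stimulation,
45 s recovery at 5 Hz per band; 130×174 px frames; a Gaussian "active
barrel" blob (σ = 8 px, unit peak) fully inside the frame.

* **Kinetics:** unit-peak gamma-variate kernels
  f(t) = (t/tp)^a·exp(a(1−t/tp)) — smooth, positive, standard for
  hemodynamic modeling. The shape that yields a prescribed post-peak
  half-recovery t_h has the closed form a = ln2/(r − ln(1+r)), r = t_h/tp,
  so the ΔS kernel honors its peak time and half-recovery exactly; the
  hemodynamic kernels share a peak time (HbT peak) and an explicit onset
  delay, with a separate shape parameter (default 3). All components are
  identically zero before stimulus onset.
* **Presets:** *neonatal* — ΔS peaks at the 10 s train offset with 25 s
  half-recovery; hemodynamics delayed 10 s with HbT peaking 30 s after
  onset (+2.0 µM HbO, −0.5 µM HbR ⇒ +1.5 µM HbT), ΔS amplitude 5e-3.
  *adult* — both components fast and inside the train (ΔS peak 4 s, HbT
  peak 6 s). Peak *times* follow the two-regime phenomenology the package
  targets; the *amplitudes* are illustrative round numbers at a comfortable
  SNR — group-average amplitudes of real recordings are several-fold
  smaller, and no published values exist for the neonatal early-phase
  hemoglobin changes.
* **Rendering:** frame = baseline·(1+g(t))·(1 ∓ trace·B) + noise, with B
  the unit-peak blob (+ brightens in transmission, − darkens in
  reflectance), g(t) a 0.1 Hz sinusoid of relative amplitude 1% applied
  multiplicatively and uniformly — matching the shared-illumination model
  the reference-region correction assumes — and i.i.d. Gaussian pixel noise
  of σ = 0.5% of baseline per frame. Bands are rendered as synchronized
  stacks on one time grid; the sub-second diode-interleaving offsets of a
  real rig (≤0.2 s) are ignored as far below the response time scales.
* **Determinism:** one master seed; per-(trial, band) seed-sequence
  substreams; identical parameters give bit-identical stacks, and σ = 0
  scenes are deterministic functions of the parameters.
* **LFP:** one negative alpha-shaped deflection (10 ms peak) per stimulus in
  the train, amplitudes geometrically depressed per stimulus
  (use-dependent synaptic depression), ≥1 kHz sampling, optional Gaussian
  noise.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: photon transport and wavelength-dependent
point-spread (the forward optics are exactly the linear model the inversion
assumes, so decomposition accuracy on synthetic data does not validate the
Beer–Lambert approximation itself), motion, photobleaching, heartbeat and
respiration artifacts, vessel anatomy, camera nonlinearity, and non-Gaussian
noise. Coordinates are 0-based (row, col); time 0 is trial start; stimulus
onset at t = 5 s.

## Pipeline

Stages run as simulate/load → preprocess → map → decompose → metrics.
Trials are streamed (one rendered trial in memory at a time). The active
region is detected on the band with the strongest map and shared across
bands, matching the single-region acquisition geometry. A provenance
manifest records the config hash, package version, seed and per-artifact
SHA-256 checksums; identical config + seed reproduces identical checksums.
Logs record every default actually used (percentile method, α window,
threshold, units). Config validation returns problems as data (field +
reason), and `run` aborts before any stage on a non-empty list.

## Problem sizes and runtime

Defaults were chosen so a full analysis stays desk-scale: 12 trials × 3
bands × 300 frames at 130×174 px runs in well under a minute; the test
suite and the acceptance script each complete in about a minute on one CPU.

## Known limitations

* Absolute chromophore amplitudes on recorded data inherit the approximate
  attenuation factor (above) and the literature-scale default coefficients;
  timing quantities are robust to both.
* The exact Mann–Whitney path is enumerative and is capped at pooled n = 12
  before switching to the asymptotic approximation.
* The kinetic read-out assumes a unimodal gamma-variate-like transient per
  component; genuinely biphasic components (e.g. an initial dip in HbR)
  would need a two-kernel extension.
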