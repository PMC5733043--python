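# oisi — multispectral optical intrinsic signal imaging analysis

Optical intrinsic signal (OIS) imaging records slow changes in the light
reflectance (or transmittance) of cortical tissue evoked by neural activity.
The signal mixes two physical processes: the hemodynamic response (HR —
changes in blood volume and oxygenation) and activity-dependent light
scattering (LS — transient tissue-transparency changes from cellular
swelling). In the neonatal rodent barrel cortex these two components are
temporally separated — an early scattering phase during the stimulation
train, and a hemodynamic phase that peaks tens of seconds later — while in
adults they overlap inside the train. Telling them apart is what this
package does.

`oisi` is a tested, reusable pipeline from raw trial-structured multispectral
frame stacks to chromophore time courses:

1. **preprocess** — per-frame 2-D Gaussian smoothing (σ = 2 px); illumination
   correction against a response-free reference region,
   `I_corr(t) = I(t) − α·I_ref(t)` with `α = ⟨I(t)/I_ref(t)⟩_t`; trial
   averaging;
2. **mapping** — the evoked-response map
   `OIS = (⟨I_corr⟩_stim − ⟨I_corr⟩_baseline) / ⟨I⟩_baseline`, deterministic
   active-region detection (connected component around the extremum), and
   polarity-aware ROI time-course extraction;
3. **mbll** — modified Beer–Lambert decomposition with a scattering
   pseudo-chromophore:

   `OIS_λ(t) ≈ (Δ[HbO]·ε_HbO,λ + Δ[HbR]·ε_HbR,λ + μs′_λ·ΔS(t)) · 2·d_IV`

   where ε are LED-emission-weighted extinction coefficients
   (mm⁻¹ µM⁻¹), μs′ is the reduced scattering coefficient (mm⁻¹), ΔS a
   dimensionless scattering change, and the effective photon path is twice
   the cortical layer-4 depth `d_IV` (0.35 mm neonatal, 0.75 mm adult).
   With ≥ 3 spectral bands the system is inverted per timepoint (exact 3×3
   solve; least squares when overdetermined). The inverter is a
   scikit-learn-style estimator (`MBLLDecomposer`: `fit` /`transform` /
   `inverse_transform`);
4. **metrics & statistics** — 95th-percentile peak amplitude, first-crossing
   peak position, interpolated half-recovery T₀.₅, rectified average LFP,
   optimal-stimulation-rate ranking, Pearson correlation, exact one-tailed
   Mann–Whitney U and sign tests;
5. **synthetic data** — a forward model (gamma-variate chromophore kinetics
   → Beer–Lambert optics → camera rendering with illumination drift and
   shot-like noise) that generates trial stacks the pipeline must invert, so
   every stage is verifiable without animal data.

## Worked example

```bash
ois demo-neonatal --out demo_neonatal --seed 0
```

simulates 12 noisy trials of a neonatal-type response (130×174 px, 5 Hz,
5 s baseline / 10 s stimulation / 45 s recovery; GREEN/RED/IR bands), runs
the full pipeline and prints the metrics table:

```
group,metric,value
GREEN,amplitude_percent,0.540452
GREEN,peak_position_s,22
RED,amplitude_percent,0.422551
RED,peak_position_s,8.2
IR,amplitude_percent,0.351634
IR,peak_position_s,7
chromophores,s_peak_time_s,9.91993
chromophores,s_peak_value,0.00495959
chromophores,s_half_recovery_s,25.1026
chromophores,hbt_peak_time_s,30.1695
chromophores,hbt_peak_value,1.51928
chromophores,hbo_peak_time_s,30.1133
chromophores,hbo_peak_value,1.99736
chromophores,hbr_peak_time_s,30.1267
chromophores,hbr_peak_value,-0.479093
```

Reading: the GREEN band (blood-volume sensitive) peaks 22 s after stimulus
onset — the delayed hemodynamic phase — while RED and IR (oximetric- and
scattering-sensitive) peak inside the 10 s train. The decomposition makes
this explicit: the scattering component ΔS peaks at ~10 s (the end of the
train) and takes ~25 s to fall to half amplitude, whereas total hemoglobin
HbT (+1.5 µM, from +2.0 µM HbO and −0.5 µM HbR) peaks ~30 s after onset.
`ois demo-adult` shows the contrasting fast regime with both components
inside the train. The output directory also contains per-band OIS maps
(TIFF + PNG), the active mask, time-course and chromophore CSVs, the
assembled model (JSON with condition number), and a provenance manifest.

Library use mirrors the CLI:

```python
import oisi

res = oisi.analyze_scene(oisi.SceneParams(seed=0), oisi.NEONATAL,
                         oisi.default_bands(), d_iv=0.35)
print(res.chromophore_metrics["s_peak_time_s"])   # ~10 s
print(res.chromophore_metrics["hbt_peak_time_s"]) # ~30 s
```

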