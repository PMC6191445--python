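# thrombofret

Quantitative analysis of ratiometric FRET/cGMP (and Fura-2 Ca²⁺) imaging of
platelet thrombi under flow.

## The problem

Nitric oxide limits thrombosis by raising cGMP in platelets, and this
NO→cGMP signal is strongly potentiated by fluid shear: in flow-chamber
experiments with an NO donor present, switching flow on drives a sustained
cGMP rise and switching it off lets cGMP fall back to baseline within tens
of seconds, while in vivo the shear-exposed thrombus periphery carries more
cGMP than the densely packed core.  Quantifying this requires a small but
complete image-analysis pipeline: dynamic segmentation of a growing and
dissolving thrombus, a core/periphery partition, background-corrected
emission-ratio traces, sensor calibration with saturation handling, growth
and lead-lag kinetics, and the usual group statistics.  `thrombofret`
implements that pipeline as a tested, reusable library for experimentalists
working with CFP/YFP FRET biosensors (cGi500-class) and Fura-2 in
flow-chamber or intravital microscopy.

## The model in brief

* **Shear.** Ideal parallel-plate chamber: γ̇ = 6Q/(wh²), τ = ηγ̇.  With
  η = 0.01 dyn·s/cm² (1 cP), 500 s⁻¹ ↔ 5 dyn/cm².
* **Segmentation.** Per frame, the CFP+YFP sum is Gaussian-blurred
  (σ = 2 px) and thresholded (manual counts or Otsu); the largest
  8-connected component is the thrombus.  Core = pixels ≥ 1.2 × threshold
  (intensity erosion); periphery = the remainder — an exact partition.
* **Ratiometrics.** R = F480/F535 from background-corrected region means;
  ΔR/R normalized to a pre-stimulus baseline; traces with SNR < 2.5
  (peak baseline-deviation over baseline SD) are excluded.  Calibration is
  a Hill model R(c) = R_min + (R_max−R_min)·cⁿ/(EC₅₀ⁿ+cⁿ) with an exact
  inverse; above c_sat = 3 µM the inverse reports "≥ 3 µM" plus a
  saturation flag.  Ca²⁺ is the classic Fura-2 F340/F380 ratio.
* **Kinetics.** Growth profiles yield t_max, A_max, half-dissolution time
  (linearly interpolated, censored if unreached), trapezoidal AUC, and end
  size; ΔR/R peak areas subtract a linear chord baseline; cGMP→Ca²⁺ order
  is quantified by derivative cross-correlation (negative lag = cGMP
  precedes).
* **Statistics.** Student/Welch t (Welch auto-selected by an F-test at
  α = 0.05), Mann–Whitney U with censoring-at-cap tie handling (exact for
  small no-tie samples), one-way ANOVA + Tukey HSD, and the platelet-count
  inclusion filter (800–1300 × 10⁶ mL⁻¹).

Because raw imaging data of this kind are rarely shareable, the package
ships a first-class synthetic movie generator (`thrombofret.synth`) that
renders the full forward model — flow-schedule-driven first-order cGMP
kinetics per region, a saturating sensor mapping with anticorrelated
CFP/YFP channels, lagged anticorrelated Ca²⁺, hemispherical-cap brightness,
Poisson + read noise — together with exact ground truth, so every stage of
the pipeline is testable end to end.

## Worked example

```python
import thrombofret as tf

chamber = tf.ChamberSpec(width_mm=5.0, height_mm=0.1)
rate = tf.shear_rate_from_flow(0.25, chamber)
print(f"wall shear rate : {rate:.0f} 1/s")
print(f"wall shear stress: {tf.shear_stress(rate):.1f} dyn/cm2")

bundle = tf.run_pipeline(tf.RunConfig(seed=1))   # default simulated scenario
s = bundle["summary"]
for region in ("core", "periphery"):
    r = s["regions"][region]
    print(f"{region:9s}  mean dR/R (flow on) = {r['mean_dr_over_r_response']:.2f}  "
          f"plateau cGMP = {r['plateau_c_uM']:.1f} uM"
          f"{' (saturated, lower bound)' if r['plateau_saturated'] else ''}")
print(f"return to baseline after flow-off: {s['recovery_time_s']:.0f} s")
```

prints

```
wall shear rate : 500 1/s
wall shear stress: 5.0 dyn/cm2
core       mean dR/R (flow on) = 0.37  plateau cGMP = 0.8 uM
periphery  mean dR/R (flow on) = 0.59  plateau cGMP = 3.0 uM (saturated, lower bound)
return to baseline after flow-off: 18 s
```

The default scenario is a preformed thrombus at 1 Hz with flow on during
60–120 s.  The ratio rise is larger in the periphery than in the core
(0.59 vs 0.37), the periphery plateau sits above the sensor's quantifiable
range so the calibration reports the 3 µM lower bound with its saturation
flag, and after flow cessation the whole-thrombus ΔR/R trace re-enters a
±5 % baseline band within 18 s.

The same stages are available from the shell:

```bash
thrombofret shear --flow-rate 0.25 --width 5 --height 0.1
thrombofret simulate --out scratch/movie --seed 1
thrombofret run --out scratch/report --seed 1
```

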