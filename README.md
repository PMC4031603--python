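# footroll

Foot-rollover analysis for plantar-pressure gait studies: regional
loading metrics from insole recordings, sagittal ankle inverse
dynamics, clinical foot-function scoring, and the repeated-measures
statistics of a two-arm exercise trial in diabetic polyneuropathy
(DPN) — with synthetic-data generators that provide closed-form ground
truth for every stage.

## Who it is for

Researchers analysing barefoot gait in neuropathic (or other) cohorts
who need the standard rollover description — peak pressure (PP),
time-to-peak pressure (TPP), pressure–time integral (PTI) and
centre-of-pressure (COP) velocity over six anatomical foot regions —
plus ankle kinetics and an intention-to-treat statistical pipeline, in
open, testable code rather than vendor software and ad-hoc scripts.

## What it computes

**Regions.** The footprint splits by foot length into heel (0–27 %),
midfoot (27–55 %), forefoot (55–80 %; 55/45 % medial/lateral across
width) and toe band (80–100 %; 33 % hallux medially, 67 % toes), with
the long axis estimated from the loaded-sensor cloud.

**Rollover metrics.** Per region r, with p_r(t) the per-frame maximum
pressure over the region's sensors during stance [0, T]:

    PP_r  = max_t p_r(t)                         [kPa]
    TPP_r = 100 · argmax_t p_r(t) / T            [% of stance]
    PTI_r = ∫₀ᵀ p_r(t) dt                        [kPa·s]
    v̄_COP = path length / elapsed time           [m/s]

**Ankle dynamics.** Zero-phase Butterworth filtering (net 4th order;
20 Hz force, 6 Hz kinematics), sagittal ankle angle (dorsiflexion
positive, zero at neutral standing), and the net ankle moment from a
Newton–Euler balance on the foot segment with Dempster anthropometrics,
reported as 100·M/(m·g·h) %BW·h, plantarflexor positive. Outcomes:
sagittal ROM, end-propulsion angle, and the extensor (~20 % stance) and
flexor (~80 %) moment peaks.

**Trial statistics.** MCAR mean/median-of-series imputation,
Lilliefors-KS and Levene checks, mixed group×time repeated-measures
ANOVA with Newman–Keuls post hoc, one-way rm-ANOVA / Friedman
follow-up, exact small-sample Mann–Whitney and Wilcoxon tests, Cohen's
d = |m₁−m₂|/√((s₁²+s₂²)/2) with trial-calibrated labels
(small < 0.4 ≤ medium < 0.7 ≤ large), Hodges–Lehmann median differences
with distribution-free CIs, balanced block randomization (block sizes
1–8), and noncentral-F sample-size computation for the
repeated-measures design.

See `docs/methods.md` for every convention and its rationale.

## Worked example

```python
import footroll as fr

# one synthetic barefoot stance with analytic ground truth
rec, truth = fr.generate_rollover_recording(fr.RolloverScenario(), seed=0)
phase = fr.detect_stance_phases(rec)[0]
masks = fr.build_region_masks(rec, phase)
m = fr.compute_rollover_metrics(rec, phase, masks)
for r in fr.REGIONS:
    print(f"{r:17s}  PP {m.pp[r]:6.1f} kPa   TPP {m.tpp[r]:5.1f} %   "
          f"PTI {m.pti[r]:6.1f} kPa.s")
print(f"total COP mean velocity: {m.total_cop_velocity:.3f} m/s")

# ankle outcomes from synthetic gait mechanics
mech, gt = fr.generate_gait_mechanics(fr.GaitProfile(), seed=0)
out = fr.extract_ankle_outcomes(fr.sagittal_ankle_angle(mech),
                                fr.inverse_dynamics_ankle_moment(mech),
                                gt.stance)
print(f"ankle ROM {out.rom:.1f} deg | extensor {out.extensor_peak:.2f} "
      f"| flexor {out.flexor_peak:.2f} %BW.h")

# trial statistics on a simulated two-arm table
table, _ = fr.generate_trial_dataset(fr.TrialScenario(), seed=0)
res = fr.rm_anova_interaction(fr.impute_missing(table), "pp_lateral_forefoot")
F, d1, d2, p = res.terms["interaction"]
print(f"group x time interaction: F({d1},{d2}) = {F:.2f}, p = {p:.3f}")
```

prints

```
heel               PP  315.0 kPa   TPP  18.5 %   PTI   80.0 kPa.s
midfoot            PP  125.0 kPa   TPP  52.3 %   PTI   44.8 kPa.s
medial_forefoot    PP  360.0 kPa   TPP  83.1 %   PTI   98.3 kPa.s
lateral_forefoot   PP  320.0 kPa   TPP  81.5 %   PTI   90.0 kPa.s
hallux             PP  215.0 kPa   TPP  86.2 %   PTI   46.8 kPa.s
toes               PP  195.0 kPa   TPP  83.1 %   PTI   43.1 kPa.s
total COP mean velocity: 0.461 m/s
ankle ROM 20.9 deg | extensor -0.92 | flexor 8.30 %BW.h
group x time interaction: F(1,53) = 10.93, p = 0.002
```

The regional metrics recover the generator's closed-form ground truth
(PP exactly, TPP to frame quantisation, PTI to < 1 %); their magnitudes
— heel peaking at ≈ 315 kPa early in stance, forefoot and toes near
80 % of stance — are typical of barefoot DPN gait. The significant
interaction reflects the 0.8 SD group×time effect the default trial
scenario injects into lateral-forefoot peak pressure.

A `footroll` console script wraps the same pipeline
(`footroll simulate rollover|gait|trial`, `footroll rollover`,
`footroll dynamics`, `footroll stats`, `footroll all`), writing CSV/JSON
outputs and a reproducibility manifest; `footroll all --seed N --out
dir` runs the simulate-then-analyze round trip end to end.

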