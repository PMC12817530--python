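# perturbalance

Analysis pipeline for **perturbed single-leg balance**: from raw multi-rate
trial signals — surface EMG (tibialis anterior, peroneus longus, soleus),
ground reaction force and centre of pressure, segment kinematics, and a
platform accelerometer — to muscle co-contraction indices, margin-of-stability
waveforms, frontal-plane ankle and hip torques, MoS–torque coupling, and both
scalar and one-dimensional (waveform-level) repeated-measures inference.

The package targets the study design used in chronic ankle instability (CAI)
research: two groups (CAI vs healthy controls, operationalized by a
Cumberland Ankle Instability Tool score below 24 vs a perfect 30), three
practice sessions of repeated mediolateral platform perturbations (a 1-s,
0.017-m, 1-Hz sinusoidal translation followed by 7 s of quiet stance), with
the first successful trial in block one and the first three successful trials
in blocks two and three entering analysis. Because raw human datasets of this
kind are rarely public, the package ships a first-class synthetic-data
generator — a controlled two-link frontal-plane inverted pendulum on a
translating base — whose group/session structure is prescribed and therefore
recoverable, so every stage of the pipeline is verifiable end to end.

## Core quantities

* **Margin of stability (MoS)** — the absolute mediolateral distance between
  the extrapolated centre of mass and the base of support, here the
  instantaneous centre of pressure:
  `MoS(t) = | XCoM(t) − CoP(t) |`, with `XCoM = x + v/ω₀` and
  `ω₀ = √(g/l)` for CoM height `l`.
* **Co-contraction index (CCI)** — for agonist/antagonist envelope samples
  over the 1-s perturbation window:
  `CCI = (2/n) Σᵢ min(EMG_AG(i), EMG_ANT(i)) / (EMG_AG(i) + EMG_ANT(i)) × 100%`,
  computed for the TA–PL (inversion–eversion) and TA–SOL
  (dorsi–plantarflexion) pairs on envelopes normalized to each participant's
  maximum across successful trials.
* **MoS–torque coupling** — the zero-lag normalized cross-correlation
  (Pearson r of the mean-removed windowed series) between MoS and the
  frontal-plane ankle or hip torque over 0–0.5 s and 0.5–1 s, with |r|
  categorized as strong (≥ 0.5), moderate (≥ 0.3) or weak.
* **Inference** — two-way mixed ANOVA (group × session) with
  Greenhouse–Geisser correction, partial eta squared, and Bonferroni post
  hoc on the scalar outcomes; a **permutation-based 1D repeated-measures
  ANOVA** on the 101-node waveforms, using the permutation distribution of
  the trace-wide maximum F for family-wise cluster inference.

## Worked example

```python
from perturbalance.pipeline import RunConfig, run_pipeline
from perturbalance.synthdata import SimConfig

report = run_pipeline(RunConfig(sim=SimConfig(seed=11), n_permutations=300))

pl = report.summary.query("outcome == 'cci_ta_pl'")
print(pl.pivot(index="group", columns="session", values="mean").round(1))
inter = {r.effect: r for r in report.anova["cci_ta_pl"]}["interaction"]
print(f"TA-PL interaction: F = {inter.F:.2f}, p = {inter.p:.4f}")
print("CAI MoS session clusters:",
      report.spm["mos"]["one_way_CAI"]["session"].clusters)
r = report.correlations["cci_ta_sol"]
print(f"CAIT vs TA-SOL CCI: r = {r['r']:.3f}, p = {r['p']:.4f}")
```

Output (seed 11):

```
session     1     2     3
group
CAI      61.7  64.5  65.5
HC       67.2  64.8  62.0
TA-PL interaction: F = 15.30, p = 0.0000
CAI MoS session clusters: [(0.04, 0.21), (0.29, 0.58), (0.71, 1.0)]
CAIT vs TA-SOL CCI: r = -0.722, p = 0.0002
```

The summary table is the per-group, per-session mean TA–PL co-contraction
index (percent): the control group's co-contraction falls across practice
sessions while the CAI group's does not, which the mixed ANOVA flags as a
group × session interaction. The cluster list gives the time intervals (s,
within the 1-s perturbation) where the CAI group's margin of stability
changed significantly across sessions under the one-way permutation
waveform ANOVA, and the final line is the Pearson relation between ankle
function (CAIT) and overall TA–SOL co-contraction in the CAI group —
participants with poorer self-perceived ankle function co-contract more.

A command-line layer wraps the same machinery:

```bash
perturbalance simulate --out trials/ --seed 3          # write raw trials
perturbalance run --out results/ --seed 11 --permutations 300
```

Stage-level operations (EMG envelopes, QC, onset detection, mechanics, CCI,
coupling, statistics) are ordinary library functions in
`perturbalance.signal_prep`, `.mechanics`, `.cocontraction`, `.coupling` and
`.inference`.

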