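# pdcflow

Source-space directed functional connectivity for developmental EEG
studies, with a normative-gaze Proximity Index and the nonparametric
statistics used to compare groups and relate brain measures to
behaviour.

The scientific question this pipeline serves: when toddlers watch
naturalistic social movies, which brain regions *drive* the ongoing
network — and does that driving differ between autistic and typically
developing children, and relate to how normatively they explore the
scene visually? Because the original infant EEG recordings of such
studies are rarely shared, the package pairs every analysis stage with a
synthetic-data generator that plants known network structure, so each
stage has a ground-truth recovery test.

## The model

Regional source activity is modelled as a multivariate autoregressive
(MVAR) process over n = 82 atlas regions,

    x_t = Σ_{r=1..p} A_r x_{t−r} + ε_t,  ε_t ~ N(0, Σ),

with order p = 5 at 125 Hz (a 40 ms lag span). Directed influence in the
frequency domain is Partial Directed Coherence (PDC): with
Ā(f) = I − Σ_r A_r e^{−i2πfr/fs},

    PDC(i←j, f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²),

column-normalised so each sender's squared outflows sum to 1 at every
frequency. PDC is scaled 0–1 across regions and frequencies (1–40 Hz)
and weighted by the sender's scaled spectral power (wPDC); band means
(theta 4–7, alpha 8–12, beta 13–30 Hz) are reduced to the **summed
outflow** S(j) = Σ_{i≠j} wPDC(i←j), the "driving importance" of region
j. Sources come from a distributed LORETA-type inverse
K = (LᵀL + λ BᵀB)⁻¹Lᵀ (B the block spatial Laplacian) applied to
average-referenced scalp EEG, reduced to one solution point per region
and projected onto each region's predominant dipole direction.

Visual exploration is scored by the **Proximity Index**: per film frame,
a Gaussian kernel density over the reference group's gaze points defines
the normative distribution; a subject's frame score is the density at
their gaze point divided by the frame's density maximum, and PI is the
mean over usable frames (1 = fully normative gaze).

Group comparisons use the Mann-Whitney-Wilcoxon test with rank sum Ws,
normal deviate z and effect size r = z/√N, Benjamini-Hochberg FDR within
explicit families, Spearman/Pearson correlations, the D'Agostino-Pearson
K2 normality test, and pooled t tests (including from printed summary
statistics alone).

## Worked example

The numbered scripts under `analysis/` run the full synthetic study.
`python analysis/03_run_pipeline.py` simulates 8 test vs 8 reference
subjects (the test group's theta hub drives six regions, the reference
group's two), pushes every subject through forward projection at SNR 10,
the inverse, and the wPDC outflow pipeline, then prints:

```
top theta-band driving difference: ROI00 (Ws=100, z=3.361, p=0.0002, r=0.840, FDR significant: True)
Proximity Index across test subjects: mean 0.522, range [0.372, 0.623]
correlation theta_hub_vs_pi: rs=-0.762, p=0.0368 (n=8)
```

ROI00 is the planted hub: the group comparison recovers it as the
top-ranked driving difference, and its driving correlates with the
planted gaze behaviour. `python analysis/05_published_statistics.py`
recomputes the published phenotype-table t statistics and rank-sum
triples, e.g.

```
VABS communication: t = -8.70 (printed -8.7), df = 34
Ws = 267: z = -2.088, r = -0.348, p = 0.037
```

`analysis/04_recovery_experiments.py` reports the planted-truth
recovery suite (hub detected in 25/25 seeds; MVAR coefficient RMSE
0.021 at T = 5000; source-series recovery correlations ≥ 0.91), and
`analysis/06_gaze_proximity_curve.py` traces the monotone fall of PI
with planted gaze deviation (0.57 at δ=0 down to 0.13 at δ=4).

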