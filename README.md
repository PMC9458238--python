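# msi-ith

Intratumor-heterogeneity (ITH) analysis for MALDI mass spectrometry
imaging (MSI) of tissue sections.

MALDI-MSI records a full mass spectrum at every pixel of a tissue
section. In oncology this makes the *molecular* heterogeneity of a tumor
measurable: a pathologist delineates cancer regions of interest (ROIs),
and the pixel spectra inside each ROI are segmented and compared. This
package implements the complete desk-scale pipeline for that analysis —
from raw pixel spectra to per-patient heterogeneity indices and
effect-size differential tables — together with a synthetic-data
generator that plants known ground truth, so every stage is testable.

## What it computes

1. **Preprocessing** (`msi_ith.preprocess`): mass-channel unification,
   rolling-minimum baseline subtraction, robust log-TIC outlier removal,
   cross-correlation peak alignment, TIC normalization; then the average
   spectrum is modeled as a Gaussian mixture,

   $$\bar s(m) \approx \sum_{k=1}^{G} w_k\,
     \mathcal N(m;\,\mu_k, \sigma_k^2),$$

   and each pixel's abundance of component $k$ is the inner product of
   its spectrum with the unit-area component profile (the
   component–spectrum convolution at zero lag).
2. **Segmentation** (`msi_ith.segmentation`): DivIK — divisive iterative
   k-means under the Pearson-correlation distance $1-r$, with
   region-driven two-stage feature selection (drop low-amplitude
   features, keep high-variance ones) at every node, k chosen by the
   Dunn index, yielding nested cluster levels.
3. **Heterogeneity** (`msi_ith.heterogeneity`): the pairwise spectral
   similarity index (Pearson correlation of component-abundance
   vectors, with CDF summaries per ROI) and the Gini–Simpson diversity
   $D = 1-\sum_i p_i^2$ over a ROI's cluster composition — the
   probability that two random pixels fall in different clusters.
   Group contrasts use the Wilcoxon rank-sum / Kruskal–Wallis tests.
4. **Differential analysis** (`msi_ith.differential`): Cohen's
   $d = (\bar x_a - \bar x_b)/s_\text{pooled}$ per component, Cohen's
   $h = 2\arcsin\sqrt{p_1} - 2\arcsin\sqrt{p_2}$ per cluster
   proportion, magnitude classes at 0.2/0.5/0.8, three-set overlap
   counts, exact Fisher tests (Freeman–Halton for r×c) and Student's t.
5. **Annotation** (`msi_ith.annotation`): matching component m/z
   positions to an LC-MS/MS peptide library within ±0.05% relative mass
   tolerance.
6. **Synthetic data** (`msi_ith.synthetic`): pixel spectra as sums of
   unit-area Gaussian peptide peaks with spatially coherent planted
   clusters, paired tumor/node ROIs, baseline drift, TIC variation,
   additive noise and outlier pixels — all deterministic under a seed.

## Worked example

```python
import dataclasses
from msi_ith import SimulationConfig, simulate_two_arm_study
from msi_ith.pipeline import analyze_study, study_analysis_params, two_arm_study_conditions

high, low = two_arm_study_conditions(seed=1)   # 4 balanced vs 2 skewed clusters
bundle = simulate_two_arm_study(high, low)     # 20 + 20 patients
prep, seg = study_analysis_params()
report = analyze_study(bundle, preprocess_params=prep, divik_params=seg,
                       max_pairs=2000, seed=1)

per_roi = report["per_roi"]
for arm in ("NED", "PD"):
    sub = per_roi[per_roi.group == arm]
    print(arm, round(sub.simpson_d.median(), 3),
          round(sub.median_similarity.median(), 4))
print("Simpson Wilcoxon p:", report["simpson_comparison"]["p_value"])
```

prints

```
NED 0.741 0.3369
PD 0.435 0.999
Simpson Wilcoxon p: 6.292924314800138e-08
```

The high-ITH arm (labeled NED) has a median Simpson diversity of 0.741 —
essentially the planted value for four nearly balanced clusters — and a
much lower median intra-ROI spectral similarity than the single-phenotype
arm (labeled PD), and the arm difference is highly significant. This is
the qualitative signature of prognostic ITH the pipeline is built to
detect: more favorable-outcome-like tissue shows *more* molecular
diversity and *less* internal similarity.

A shell workflow is available through the `msi-ith` command
(`simulate`, `preprocess`, `segment`, `run`, `annotate`).

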