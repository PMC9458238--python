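# Methods

This note documents the models, algorithmic choices and standing
parameters of the package, and what the synthetic-data experiments do
and do not demonstrate.

## Data model

An `MSIDataset` holds pixel spectra on one strictly increasing m/z axis
(the instrument scenario is tryptic-peptide imaging in the 700–3000 m/z
range at roughly 0.1 m/z channel spacing, i.e. ≥ 10 channels per peak),
integer pixel coordinates, a per-pixel ROI id and per-ROI clinical
metadata: patient, outcome group (NED = no evidence of disease, PD =
progressive disease), tissue (T = primary tumor, N = lymph-node
metastasis) and the ordinal lymphocytic-host-response grade
(weak/intermediate/strong).

## Preprocessing

Stages run in a fixed order, recorded in a provenance log:
unification → baseline → outliers → alignment → TIC normalization →
GMM componentization → abundance estimation.

- **Mass-channel unification.** All datasets are linearly interpolated
  onto the intersection of their ranges at the finest native spacing.
- **Baseline.** Rolling minimum over `baseline_window` channels (default
  201 ≈ 20 m/z at 0.1 m/z spacing), smoothed with a moving average of
  the same width, subtracted, negatives clipped. The window must dwarf
  the peak width (σ ≈ 0.2–0.35 m/z) while following slow drift. On a
  noisy spectrum the operation is only approximately idempotent: the
  clipped noise floor contributes a small (&lt; ~3% of total intensity)
  re-subtraction on a second pass.
- **Outliers.** A pixel is discarded when its log total ion current
  deviates from the cohort median by more than 3 MAD-based robust
  standard deviations. When the MAD is zero (degenerate spread) any
  deviation from the median flags. The rule assumes a continuous TIC
  distribution; on noise-free data with a handful of discrete TIC
  values it can flag whole clusters, which is why recovery tests of
  other stages bypass it.
- **Alignment.** Per-pixel constant integer channel shift (±5 channels
  by default) maximizing cross-correlation with the average spectrum,
  ties toward zero shift.
- **TIC normalization.** Each spectrum is scaled to the mean TIC of the
  retained pixels, preserving the intensity scale.
- **GMM componentization.** The baseline-subtracted average spectrum,
  normalized to unit mass, is treated as a density over m/z.
  Components are initialized at local maxima above the q-quantile
  intensity (default q = 50) with widths from the half-prominence peak
  width, then refined by EM on the binned data (convergence at relative
  log-likelihood change `tol`, default 1e-8; 500 iterations cap; each
  component truncated at 6σ so the cost is linear in the number of
  components). Components with weight &lt; 1e-5 or width outside
  0.5–100 channel spacings are pruned. The median-quantile threshold
  deliberately over-detects: weak noise maxima become low-amplitude
  components that the segmentation's amplitude filter removes later,
  mirroring a detect-generously/filter-downstream design. Cohort-level
  analyses in this package run EM at `tol` = 1e-6 — on our synthetic
  spectra recovery is indistinguishable from 1e-8 at a fraction of the
  iterations. An optional isotope-envelope merge (1.00235 Da spacing) is
  provided but off by default: components are interpreted as peptide
  species including their envelopes.
- **Abundance.** `abundance[p, k]` is the inner product of pixel
  spectrum p with the unit-area profile of component k times the
  channel spacing — the component–spectrum convolution at zero lag. For
  a pure peak of area a this evaluates to a/(2σ√π).

## DivIK segmentation

Correlation-distance k-means is implemented by mapping every pixel
vector to zero mean and unit norm, where squared Euclidean distance
equals 2(1−r); Lloyd iterations on these vectors minimize the
correlation k-means objective. Rows are presented to the solver in a
canonical lexicographic order, making the result equivariant under
pixel permutations; tiny nodes (≤ 32 pixels) get 50 k-means++ restarts
instead of 10.

At every node, feature selection runs on the node's own pixels
("region-driven"): a two-component 1-D Gaussian mixture on log mean
abundance drops the low-mean (noise) component, then one on log
variance of the survivors keeps the high-variance component; a
degenerate fit (component means closer than the sum of their SDs, or an
SD ratio above 10) skips its stage.

k = 2..k_max (default 10) is scored by a Dunn index on the squared
correlation-distance scale: minimum inter-centroid distance (u-space
centroid means, not re-standardized — renormalizing would inflate
vanishing centroid differences on homogeneous nodes) over maximum
intra-cluster diameter (clusters beyond 2000 pixels are subsampled).
Ties in k go to the smaller k. A split is accepted when the best Dunn
index reaches `split_dunn_threshold` and every child holds at least
`min_cluster_fraction` of the input pixels. The default threshold is
0.3: on unstructured data the best-k Dunn statistic stays below ~0.18
across sizes and k (measured over 48 independent draws), while planted
cluster structure scores above 1, so 0.3 separates the two regimes with
about a two-fold margin on either side. Levels are nested by
construction: unsplit nodes carry forward with fresh ids, so deeper
levels always refine shallower ones.

## Heterogeneity indices

The similarity index of two pixels is the Pearson correlation of their
component-abundance vectors (cosine similarity available by option);
per ROI the package reports the median and the empirical CDF on a fixed
grid over [−1, 1]. Pair enumeration is exhaustive up to `max_pairs`
(analysis default 2×10⁴ per ROI, configurable up to full enumeration)
and a seeded uniform subsample beyond that; the subsampled median is
within 0.01 of the exhaustive one on 300-pixel ROIs.

Diversity is the Gini–Simpson index D = 1 − Σ p² over the ROI's cluster
composition at a chosen tree level (the with-replacement form; the
finite-sample variant is exposed and differs by at most 1/N). Two-group
contrasts use the two-sided Wilcoxon rank-sum test — exact when both
groups have ≤ 20 untied values, otherwise the tie-corrected normal
approximation without continuity correction — and Kruskal–Wallis beyond
two groups.

## Differential analysis

Cohen's d treats pixels as observations (the spectra are the compared
groups); a patient-aggregated mode can be obtained by feeding per-ROI
means. Components with zero pooled SD are flagged undefined and
excluded. Magnitude classes follow the 0.2/0.5/0.8 conventions for both
d and h; selection is by magnitude class and direction, not p-value,
and no multiple-testing correction is applied. Fisher's exact test
enumerates all tables with the observed margins (Freeman–Halton; the
2×2 case reduces to hypergeometric tail summation) for totals up to
10⁴, with a seeded Monte Carlo estimate (Patefield sampling, 10⁶ draws
by default) beyond. The diversity-vs-LHR association reports
Kruskal–Wallis across grades, the Spearman correlation on the ordinal
coding, and Fisher's test of the LHR × outcome table.

## Annotation

A component matches a library peptide when |μ − m|/m ≤ 5×10⁻⁴ (±0.05%),
with the library's measured mass in the denominator as the reference
measurement; swapping the reference changes the match set only at
O(tol²). The library is mass-sorted and candidates are found by binary
search; matching uses the Gaussian mean, which coincides with the mode
for the symmetric peak model. Matches are not unique by design.

## Synthetic data

A pixel spectrum is TIC_scale × (Σ_k A[c,k]·N(m; μ_k, σ_k) + baseline)
+ noise, clipped at zero: unit-area Gaussian peaks (areas lognormal per
cluster), peak positions uniform with 3σ minimum spacing (so the GMM
recovery problem is well-posed), an exponentially decaying baseline,
lognormal per-pixel TIC scaling, and a minority of outlier pixels
scaled ×10 or ×0.1 (the TIC-based outlier detector's target). Cluster
maps are contiguous patches (each cluster claims its quota of pixels
nearest a random seed point), matching the spatial coherence of real
segmentations; configured proportions are planted exactly unless a
Dirichlet `proportion_concentration` is set, in which case each ROI's
composition is drawn around them — cohort-level analyses use
concentration 50, giving the realistic patient-to-patient composition
variability that a rank test between arms needs. Paired T/N ROIs
diverge on a configurable fraction of peaks (×2 or ×0.5 per diverging
peak). Not simulated: isotope envelopes (one Gaussian per species),
detector saturation, nonlinear mass drift, histology.

Because the generator satisfies the pipeline's assumptions by
construction, passing recovery tests demonstrates internal correctness
and calibration — not performance on real FFPE tissue, where peak
shapes, baselines and cluster geometry are less benign.

## Standing study conditions

The cohort-level experiments are frozen in `msi_ith.pipeline`:

- **Two-arm study**: 20 patients per arm, 16×16-pixel tumor ROIs, 60
  peptide peaks on 700–1200 m/z at 5000 channels, shared across
  patients; the high-ITH arm plants 4 balanced clusters (design Simpson
  0.75), the low-ITH arm 2 skewed clusters (8:4, design 0.44);
  preprocessing with window 151 and EM tol 1e-6; DivIK with k_max 8,
  one level. These sizes keep the full pooled run at about half a
  minute while leaving the contrast strongly detectable.
- **Null calibration**: both arms drawn from one configuration (8
  patients per arm, 10×10 ROIs, 20 peaks on 700–900 m/z at 1500
  channels), 200 replicates; the Wilcoxon rejection rate at α = 0.05 is
  expected inside the 3σ binomial band [0.01, 0.10] around 5%.

## Known limitations

- The GMM intensity threshold (median) over-detects on noisy spectra;
  several-fold more components than planted peaks are normal and are
  handled by the downstream amplitude filter, at some memory cost.
- Freeman–Halton enumeration is practical for the r×2 tables used here;
  wide tables with large margins should use the Monte Carlo mode.
- Exact pair enumeration for similarity is capped; ROIs beyond ~10⁴
  pixels are summarized from a seeded subsample.
- The Dunn-based split acceptance is calibrated for the squared
  correlation-distance scale used here; other metrics would need a
  re-calibrated threshold.
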