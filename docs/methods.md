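# Methods

`gutmap` implements a spatially resolved, targeted gut-metabolomics
analysis chain — calibration-based absolute quantification, spatial and
differential description of the metabolome along the intestine,
microbial-origin inference from colonized (SPF) versus germ-free (GF)
comparisons, post-ASV community processing, and a metabolite–microbe
association cascade — together with a synthetic study generator whose
planted ground truth makes every downstream stage testable.

## Study design

The sampling frame is 15 ordered sites along the mouse gut: stomach
(site 1), ten small-intestinal (SI) sites (2–11), caecum (12) and three
colonic sites (13–15). The ten SI sites are partitioned into duodenum /
jejunum / ileum as 3/4/3 (configurable; three named subregions over ten
sites admit no canonical split, and 3/4/3 is the most balanced). Each
site is sampled in two habitats (luminal content and mucus) in each of
`n_mice = 5` animals per colonization group, giving 15 × 2 × 5 = 150
samples per group. Community profiling covers five regions (duodenum,
jejunum, ileum, caecum, colon) in both habitats.

## Calibration and quantification

Ion response is modelled as log-linear: log10(count) = a + b·log10(c)
over an interior concentration window, saturating at a detector ceiling
and degenerating to noise-floor counts at the dilute end. Standards are
a 24-point two-fold serial dilution from 150 µM (lowest point 17.9 pM,
about seven decades).

`fit_calibration` exhaustively evaluates every removal pair (t, b) with
t ≤ 6 steps from the concentrated end and b ≤ 12 from the dilute end,
fits ordinary least squares of log10(count) on log10(concentration) on
the retained window, and keeps the window maximizing R². Ties are broken
toward fewer removals (more retained information), then fewer top
removals. Windows containing non-positive counts are skipped rather than
failing the series. The lowest and highest retained steps define the
LLOQ and ULOL. Because raw R² is maximized, the search occasionally
trims a step or two beyond the truly nonlinear points on noisy series —
an inherent property of the criterion, visible in the synthetic runs and
accounted for in the generator's concentration ranges.

Quantification inverts the fitted line, log10(c) = (log10(y) − a)/b, and
censors rather than extrapolates: values below the LLOQ are reported as
"censored below" (not detected), above the ULOL as "censored above".
In-range molar concentrations are scaled to nmol per mg of sample using
the 1:1 mobile-phase injection dilution (×2) and the extraction ratio of
20 µL water per mg sample (1 M ≡ 1000 nmol/µL). Censoring happens at
step boundaries, not interpolated limits, since the limits are defined
as accepted dilution steps.

Up to five adducts ("modifications") are measured per metabolite; one is
selected by a deterministic ranking: detected-sample coverage
(descending), then R² (descending), then linear-range width in log10
units (descending). A metabolite fails QC when its selected fit has
R² < 0.99 (default) or fewer than `min_points = 5` retained steps; QC
failures are dropped and reported. The slope of an optional
matrix-matched curve relative to the water curve can be carried as a
matrix-effect QC metric; quantification always uses the water curve.

`CalibrationCurve` exposes this as a scikit-learn estimator
(`fit(concentrations, counts)`, fitted attributes `slope_`, `lloq_`,
…, `predict_concentration`), so curves compose with sklearn tooling;
the module-level functions are the plain-function surface.

## Landscape description

Z-scoring is per metabolite with the sample (n−1) standard deviation —
recorded here because either convention is defensible; constant rows are
emitted as zeros with a warning. Site clustering uses average-linkage
agglomerative clustering on Euclidean distances of the z-scored site
means; cutting at k = 3 recovers the stomach / SI / LI compartments on
structured data. PCA (via scikit-learn) operates on samples ×
metabolites after per-metabolite mean-imputation of censored values; the
imputed fraction triggers a warning above 10%. Longitudinal profiles
report per-site mean ± s.e.m. over mice with a centred moving average
(default window 3 sites, shrinking at the boundaries). Peak-region
assignment uses the unsmoothed means; ties break toward the proximal
(oral) end — arbitrary but deterministic.

## Differential analyses and origin calling

Paired contrasts (lumen vs mucus, SI vs LI) average within mouse per
group and run a two-sided paired t-test across the five mice — the mouse
is the only pairing unit shared by both groups. P values are
Benjamini–Hochberg adjusted per contrast family (all metabolites in one
contrast); significance requires both |log2FC| above a threshold
(default 1.5) and adjusted P ≤ 0.05. Zero-variance zero-difference pairs
get P = 1. Fold changes never use pseudo-counts: a metabolite whose
values are entirely censored below the LLOQ in one group while detected
in the other is flagged *exclusive* — the categorical analogue of an
infinite fold change — and carries no numeric log2FC.

SPF/GF fold-change points at site granularity divide each SPF mouse's
value by the GF mean at that site (4 LI sites × 5 mice = 20 points per
metabolite and habitat; 10 SI sites give 50); at region granularity each
mouse is first averaged over the subset.

Origin calling is a two-stage fourfold rule. Stage 1: mean concentration
≥ 4× higher in the large than the small intestine in either habitat
(high bacterial load implicates microbial activity). Stage 2, on stage-1
metabolites: SPF mean ≥ 4× the GF mean within the LI; SPF-exclusive
metabolites pass by definition. Independently, a subregion-specific call
fires when the SPF/GF ratio reaches 4 within the duodenum, jejunum or
ileum while the whole-SI ratio stays below 4. Labels: stage 1 + stage 2
→ `supported_microbial`; stage 1 only, or a subregion-only call →
`candidate`; pooled SPF/GF ratio ≤ 1/4 (enriched in germ-free animals,
pointing at diet or host) → `host_diet`; otherwise `unclassified`. The
mapping from flags to the four labels is this package's choice; the
flags themselves are always emitted so other rules can be applied.
SPF/GF comparisons are primarily fold-change-thresholded; an unpaired
Welch test is available where a P value is wanted (different animals
cannot be paired).

The diet screen ranks annotated ion intensities, reports cumulative
shares, the minimal prefix covering 50% of total signal, and each
queried compound's fraction with a flag at 0.05% — compounds whose gut
enrichment might merely reflect the chow.

## Community processing

Samples with fewer than 1,000 reads are dropped (exactly 1,000 is
kept). Rarefaction subsamples each retained sample without replacement
(multivariate hypergeometric — the behaviour of vegan's `rrarefy`) to a
common depth, defaulting to the minimum retained sample sum; the seed is
mandatory. Taxa left all-zero after rarefaction are retained. Rank
aggregation sums ASVs sharing a label; taxa unannotated at the rank pool
as "unclassified ⟨nearest annotated ancestor⟩".

## Association cascade

Metabolites are classified against two enzyme networks: the host EC set
and the predicted microbiome network (union of per-taxon EC sets from
PICRUSt2-style functional prediction). A metabolite whose EC set
intersects one, the other, both or neither is labelled host / microbe /
both / unmatched; the labels partition the panel by construction.

For correlation, the 15-site metabolome is aggregated to the five
community regions by averaging each region's sites within mouse and
habitat; observations are matched (mouse, region, habitat) strata
present in both data sets, with both habitats contributing by default
(lumen-only available). Spearman's rank correlation uses average ranks,
the t-approximation for the two-sided P at n > 8 and an exact
permutation distribution at n ≤ 8 where the approximation is
unreliable. Pairs with fewer than 3 matched points carry undefined rho
and are excluded from filtering.

The filter funnel is sequential with survivor counts reported at each
stage: raw P < 0.01 (uncorrected, as the stage is a screen; a BH column
is available for transparency), metabolite SPF/GF fold change > 2
(pooled SPF mean over GF mean across all regions; SPF-exclusive
metabolites pass by definition), enzyme possession (the paired taxon
carries an EC acting on the metabolite), and positive correlation.
Passing pairs are summarized per bacterial order with unique metabolite
and taxon counts.

## Synthetic data generator

The generator emulates every input: dilution-series standards under the
saturating/floored response model; concentration landscapes with
region × habitat × colonization structure; ASV tables with lineages,
depth variation and planted producers; and the EC networks.

Concentrations are drawn log-normally around the stratum mean with a
mean-one multiplicative factor (σ² = ln(1+CV²)), so zero CV reproduces
the means exactly and the expectation is unbiased at any CV. The default
biological CV is 0.2 — the scale of between-mouse variation a targeted
gut metabolomics panel typically shows. Measurement noise on counts is
0.05 in log10 (~12%). GF-exclusive metabolites are generated as exact
zeros; a blank measurement reads at a third of the noise floor (clearly
below the noise shoulder of a real low-signal sample), so exclusives
censor below the LLOQ reliably. Response-model floors are placed so the
line crosses them midway between two dilution steps of the default
series, keeping the censoring boundary crisp on both sides. Base
concentration scales are log-uniform over 1.1 decades, chosen so every
stratum mean sits inside the calibration linear range with headroom for
noise-driven trim steps.

The default panel of 138 metabolites plants: 31 LI-enriched (LI/SI mean
ratio ≈ 6), of which 24 carry an 8-fold SPF/GF ratio in the LI
(3 of them SPF-exclusive); 10 subregion-specific SI effects (8-fold in
one of duodenum/jejunum/ileum only); 8 lumen- and 3 mucus-enriched
(8-fold habitat ratio); 8 GF-enriched (host/diet-like); 10 calibration
QC failures (near-flat, noisy response), leaving 128 quantifiable; and a
7/13/81/27 host/microbe/both/unmatched EC partition. All counts, effect
sizes and noise levels are arguments.

The community generator covers the 5 × 2 × 5 factorial padded with
replicate columns to 72 samples, plants 9 samples below 1,000 reads and
sets the post-filter minimum depth to exactly 6,000. Taxa carry 7-rank
lineages over 14 bacterial orders, log-normal regional weights, a
log-normal lumen:mucus preference and per-mouse carriage factors
(σ = 0.5 each — real communities differ between habitats and
individuals, and without these the community is unrealistically
reproducible across strata), plus multiplicative per-sample noise
(σ = 0.3). Planted producers have regional weights proportional to the
paired metabolite's regional means and carry an EC from its set; each
microbe/both metabolite's EC is additionally given to 3 random carrier
taxa so enzyme possession is not a give-away.

What the generator does **not** emulate: raw spectra, chromatography,
retention-time drift, matrix effects varying by sample, compositional
coupling between metabolites, phylogenetic correlation among taxa, or
sequencing error. Passing tests therefore demonstrate the correctness
and statistical calibration of the analysis chain on data matching the
stated model, not robustness to those real-data pathologies.

## Numerical and edge-case choices

- Log base 10 throughout calibration; any fixed base gives identical R²
  and selections.
- Calibration windows containing zero counts are skipped, not fatal.
- Non-positive fitted slopes are treated as failed calibrations
  (uninvertible).
- Censored values are excluded from all means; a group is "undetected"
  only when every measured value is censored below.
- Division by a zero or undetected reference yields NaN / an
  exclusivity flag, never infinity.
- `peak_region`, modification selection and clustering tie-breaks are
  deterministic (proximal site, lexicographic id, scipy's ordering).
- Rarefaction at a sample's exact depth returns the sample unchanged.

## Evaluation experiments

`gutmap.benchmarks` packages the recovery experiments the acceptance
script reruns: calibration slope bias over 200 replicate series; exact
planted fold-change recovery through the full
simulate→calibrate→quantify chain at zero noise and within confidence
bands at CV 0.2; type-I error of the paired habitat contrast on 1,000
null landscapes of 50 metabolites (no planted effect; a metabolite
"fires" at |log2FC| ≥ 2 with BH-adjusted P ≤ 0.05); and association
recovery over 100 reduced fixtures (30 metabolites × 40 taxa, 8 planted
producers at FC 8, CV 0.2), reporting funnel sensitivity and the
false-pair rate. The reduced fixture sizes keep a full run in minutes on
one core while leaving hundreds of planted and > 10⁵ null pairs.

## Known limitations

- The R²-maximizing trim search can narrow the linear range on noisy
  series; sample values near the range edges may be censored although a
  human analyst would have kept the window wider.
- Exclusivity detection depends on blanks censoring below the LLOQ; with
  a noise floor close to the lowest retained step this becomes
  borderline, as it would on a real instrument.
- Spearman P values at the default per-mouse matching are
  anti-conservative in absolute terms (observations within a region are
  not independent); the funnel treats them as a screening gate, as the
  fixed 0.01 threshold implies, not as calibrated inference.
- The origin labels are evidence summaries over fold-change rules, not
  causal statements; cross-feeding and host responses to colonization
  produce the same signatures.
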