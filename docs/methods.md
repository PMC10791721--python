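# Methods

## Gradient model

A subject's functional connectome is a symmetric P × P Pearson correlation
matrix over cortical parcels, each parcel pre-assigned to one of K = 7
functional networks. The group connectome is the element-wise Fisher-z mean
(`tanh(mean(atanh r))`) with the unit diagonal excluded from the transform
and restored afterwards — atanh(1) is infinite, and the diagonal carries no
information. Off-diagonal |r| ≥ 1 − 1e-12 (duplicate time courses in
degenerate synthetic data) is clipped to ±(1 − 1e-12) with a logged warning
rather than an error, so simulations remain robust while real duplicates
still surface.

Gradients are extracted by the standard sparsified-affinity recipe:

1. **Row sparsification.** Within each row, the smallest `floor(s·P)`
   entries by *signed* value are set to zero (s = 0.95 by default), so
   retained negatives are removed before weak positives. Ties are broken by
   zeroing the lower parcel index first (stable sort), making the output
   platform-deterministic. The matrix is not re-symmetrized; the affinity
   step consumes rows as connectivity profiles.
2. **Cosine affinity.** `a_ij = <row_i, row_j> / (‖row_i‖‖row_j‖)`. An
   all-zero row (no surviving connections) is an error naming the parcel.
3. **PCA.** Columns of the affinity are mean-centred; the scores are the
   projections of the P parcels onto the top n = 10 principal axes, and
   explained variance is each eigenvalue's fraction of the total. PCA signs
   are arbitrary, so each component is flipped to make its
   largest-magnitude score positive; after alignment the group reference
   fixes all signs.
4. **Procrustes alignment.** Individual scores are multiplied by the
   orthogonal matrix (rotation + reflection, no scaling or translation)
   minimizing the Frobenius distance to the group-average gradients —
   a single pass against a fixed template, no iterative re-referencing.

Degenerate inputs fail loudly: an affinity whose centred matrix is zero
(all rows identical) and a rank below the requested number of components
both raise with advice to request fewer gradients.

## Segregation metrics

All metrics operate on the aligned scores. Distances are reported as
absolute values (a signed variant is available behind a flag).

* **Network median distance** — |median(A) − median(B)| on gradient 1; the
  primary compression/expansion proxy.
* **Gradient range / SD** — max − min and the sample (n − 1) standard
  deviation of gradient-1 scores. The sample convention was chosen for
  between-subject comparison; nothing downstream depends on the choice.
* **Network peak distance** — distance between the networks' density modes.
  The mode is the argmax of a Gaussian KDE (Silverman bandwidth) on a
  512-point grid spanning [min − 3h, max + 3h]; ties resolve to the lower
  score. A KDE argmax is a deterministic, documented peak-finder; it needs
  at least 5 parcels per network, and pairs involving smaller networks are
  omitted from the per-subject report.
* **Eccentricity** — distance of a network's parcels from the origin of
  the space spanned by gradients 1–3, aggregated by the **mean** norm by
  default; a sum-of-squares aggregation is a config option
  (`eccentricity_agg="sum_sq"`). Both aggregations are legitimate readings
  of the construct; the mean is scale-stable across network sizes, which is
  why it is the default. A global (all-parcel) eccentricity is also
  reported.
* **Within-network dispersion** — Σ‖x_i − centroid‖² with the centroid the
  coordinate-wise median; **between-network dispersion** — distance between
  two network centroids. At one embedding dimension, between-network
  dispersion reduces *exactly* (same arithmetic) to the network median
  distance, and the test suite asserts that identity on every simulated
  subject.
* **Binned distributions** — gradient-1 histograms over 50 bins with shared
  edges across participants; averaging requires identical edges and
  conserves the parcel count.

## Association statistics

Spearman rank correlations (tie-corrected, two-sided p by the t
approximation; an exact-permutation oracle backs the tests at n ≤ 8) relate
each metric to each trait. The exploratory grid covers all K(K−1)/2 = 21
network pairs × 2 traits = 42 tests per pairwise metric family, flagged at
the Bonferroni threshold α/n_tests (0.05/42 ≈ 0.0012, displayed at four
decimals); per-network families (eccentricity, within-dispersion) use their
own test counts. Covariate-adjusted inference uses OLS with an intercept
and raw-unit AQ, GSQ, age, a 0/1 gender indicator, FD and DVARS;
a rank-deficient design raises, naming the collinear columns. Median splits
assign ties to the low group (value ≤ median → low), which reproduces
unequal group sizes under tied integer scores.

Motion summaries follow their operational definitions: FD is the mean over
the twelve realignment parameters of the median absolute frame-to-frame
derivative (a conventional sum-per-frame variant sits behind a flag), and
DVARS is the RMS over voxels of the temporal derivative, summarized as the
mean over volume pairs. Rotation parameters are consumed as given, without
conversion to millimetres. Questionnaire scoring takes the AQ keying
direction as data rather than hard-coding it; the GSQ item table encodes
the 7-modality × hyper/hypo structure (6 items per modality, 21 per
polarity).

## Synthetic cohorts

The generator targets the statistical structure the analysis assumes — not
realistic BOLD spectra or spatial autocorrelation.

**Traits.** AQ-like and GSQ-like totals are correlated truncated normals
(defaults: GSQ mean 50.1, SD 18.2 on [0, 168]; AQ mean 19.6, SD 5.3 on
[0, 50]; inter-trait correlation 0.25, on the low side of reported values
and appropriate for a non-Western sample). Item-level responses are then
generated to reproduce each total exactly: GSQ responses by a multivariate
hypergeometric split of the total across 42 items with capacity 4, AQ
responses by placing the scored count on the keyed pole. Age and gender
follow the study's demographics.

**Connectomes.** Parcels live on a latent three-axis geometry. Axis 1 is a
connected chain: each network's parcels are spread evenly over an interval
(width 0.45) around its network centre (centres −0.9 … 0.9 in gradient rank
order), with per-subject jitter (σ = 0.015). Correlations combine a
short-range band, `0.25·exp(−d/0.1)`, with a rank-2 *two-pole* term,
`0.7·(p_i p_j + q_i q_j)`, where p and q decay (scale 0.8) with axis-1
distance from fixed anchors at ±1 — graded connectivity to a sensory and a
transmodal core. Gaussian edge noise (σ = 0.015) is added and the matrix is
clipped, symmetrized, and given a unit diagonal.

The two-pole term is what makes individual differences *measurable* by the
sparsity-0.95 cosine pipeline. A pure distance-decay connectome is nearly
invisible to it: row sparsification keeps each parcel's top 5% by rank, a
global stretch of the axis leaves those ranks unchanged, and between-network
affinity saturates at zero once survivor supports are disjoint — the
embedding then degenerates into exchangeable clusters whose separations are
noise. With the pole term, every row's survivors include pole-proximal
parcels whose weights vary smoothly with position, so stretching the axis
(poles fixed) weakens mid-hierarchy pole coupling and widens the measured
gradient monotonically.

**Planted effect.** Each subject's axis-1 positions are multiplied by an
expansion factor g = base·(1 + β·w), base 0.85, β 0.18, clipped to
[0.5, 1.15] — the monotone, non-saturated regime of the
expansion-to-distance transfer. The latent w mixes the standardized
GSQ-like total with independent noise at Pearson weight 2·sin(πρ/6) (the
bivariate-normal weight whose population Spearman is ρ), divided by the
generator's fixed transfer constant 0.85 — the empirically measured rank
fidelity between the expansion factor and the pipeline's visual–default
median distance at the 200-subject / 100-parcel scale. The division places
the planted correlation on the *measured* metric rather than on the
unobserved latent. The AQ-like trait couples to the geometry only through
its correlation with GSQ. Strict pointwise monotonicity of the noiseless
transfer is not attainable — the 95% threshold makes survivor sets change
discretely with geometry — so the generator guarantees a monotone trend
(rank correlation ≥ 0.9 over the operating range), not a strictly
increasing function.

**Motion.** Realignment traces are Gaussian random walks with the step size
set so the median absolute step equals the target FD (0.03 mm, mid-range of
plausible compliant-subject motion); masked voxel series are white noise
scaled to a target DVARS of 1. Motion is independent of traits and
geometry, so motion covariates in the linear models are planted nulls.

All randomness flows from a single root seed through
`numpy.random.SeedSequence` substreams: one for traits, one per subject.

**What passing tests do and do not show.** The generator validates the
pipeline's statistical behaviour — planted-effect recovery, false-positive
control, metric identities — under its own assumptions. It does not emulate
haemodynamics, spatial autocorrelation, scanner artefacts, site effects, or
the hyper/hypo asymmetry of real GSQ responses, so green tests certify the
*method*, not any empirical claim about real cohorts.

## Problem sizes

The default cohort mirrors the study shape (370 subjects, 400 parcels,
7 networks). The test suite and the acceptance script run at desk scale:
planted-effect recovery uses 200 subjects × 100 parcels (100 replicate
cohorts in the tests, 50 in the script), false-positive level uses 500
Spearman replicates at n = 60, and the family-wise-error check uses 40
null cohorts of 30 subjects × 60 parcels. These sizes were chosen so the
whole suite completes in a few minutes while keeping the binomial noise of
the simulated rates well inside the asserted bands.

## Known limitations

* The KDE peak-finder is a stand-in for signal-processing peak detection on
  histograms; on flat distributions the peak location is inherently
  unstable, and the peak-distance metric inherits that.
* Whether the affinity should be computed with retained negative values is
  under-determined; the implementation removes the most negative entries
  first during sparsification, which at sparsity 0.95 leaves survivors that
  are overwhelmingly positive.
* The transfer constant (0.85) is calibrated at the reduced test scale; at
  other P/n the realized trait–distance correlation deviates modestly from
  the nominal planted value (downward at P = 400, where 20 survivors per
  row dilute the pole coupling).
* Spearman p-values use the t approximation throughout; at very small n an
  exact permutation test would be preferable.
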