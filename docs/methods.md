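# Methods

## Scope and model

`abmsi` implements a single-plaque analysis of amyloid-β (Aβ) truncation
variants in MALDI-TOF mass spectrometry imaging (MSI) data acquired in
reflector (isotopically resolved) mode over m/z 2500–5000 at 20 µm pixels.
The pipeline has five computational stages:

1. **Theoretical mass list.** Human Aβ numbering is 1–43 on the canonical
   APP fragment `DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIAT`. The variant
   space enumerates all (start, end) spans with starts 1–12 and ends 34–43,
   plus N-terminal pyroglutamate at the internal glutamates E3 and E11
   (Δ = −H₂O = −18.0106 Da), filtered to the acquisition m/z window at
   charge +1 ([M+H]⁺, proton 1.007276 Da). Elemental compositions are
   residue sums plus one water; monoisotopic masses use the standard
   lightest-isotope masses; isotope envelopes are aggregated-by-nominal-mass
   convolutions of natural element isotope distributions, pruned at
   probability 10⁻⁶ and renormalised, with isotopologues spaced 1.0033548 Da
   at charge +1. The enumeration bounds are configuration, not a claim: they
   cover every species reported in plaque tissue with margin, and the m/z
   window is the operative constraint.

2. **Spectral processing.** Fixed per-pixel chain — morphological top-hat
   baseline subtraction (rolling minimum then maximum, default 15 Da
   window), weak per-spectrum denoising (Savitzky–Golay, window 5, order 2,
   plus hot-sample capping, see below), and TIC normalisation to unit total.
   There is deliberately no spatial smoothing: every operation touches one
   spectrum at a time, and the batch kernels are bit-identical to the
   single-spectrum API. Noise is estimated as 1.4826 × the median absolute
   deviation on tiling 50 Da windows (a robust scale estimate that tolerates
   sparse peaks); peaks are local maxima with SNR above 3, apex-refined by
   3-point parabolic interpolation.

3. **Annotation.** A variant is *detected* in a spectrum when (i) a local
   maximum lies within the m/z tolerance (default 200 ppm) of its [M+H]⁺,
   (ii) that signal clears SNR 3, and (iii) the observed intensities sampled
   at the envelope positions have cosine similarity ≥ 0.8 with the
   theoretical envelope. Observed envelope samples are parabolic-interpolated
   at the exact isotopologue positions and corrected for the local pedestal
   (estimated at the two flank positions one isotopologue spacing outside
   the envelope — outside the envelope's own peaks, so the correction never
   eats signal). Without this correction, the rectified-noise pedestal that
   survives baseline subtraction both inflates abundances and passes the
   cosine test spuriously (an all-positive constant vector has cosine ≈ 0.85
   with a smooth envelope). Abundance of an isolated detected variant is the
   summed corrected envelope intensity.

4. **Envelope deconvolution.** Variants whose envelope spans approach within
   2 Da (transitive closure) form overlap groups. For spectra where a group
   member passes the peak and envelope-top SNR gates, the grid segment
   covering the group (1 Da margin, strictly inside the grouping window so
   foreign peaks cannot leak in) is modelled as a non-negative linear
   combination of theoretical envelope profiles rendered at the instrument
   peak width, plus constant and linear background columns whose
   coefficients are discarded. When the data passed through the weak
   denoiser, the same filter is applied to the design columns so model and
   data share one lineshape. Fitted components whose apex contribution stays
   below 3 × the local noise are zeroed — the SNR > 3 rule applied to
   deconvolved components; without it, non-negativity turns noise into a
   positive abundance floor smeared over the many theoretical variants.
   Exactly degenerate pairs (distinct truncations with identical elemental
   composition, e.g. Aβ2-41/Aβ3-42) are reduced to the lower-m/z member with
   a warning in the pipeline and raise an ambiguity error in the dedicated
   deconvolution API.

5. **Segmentation, quantification, statistics.** Per-pixel abundances form
   the feature matrix for bisecting k-means (Euclidean; repeatedly 2-means-
   split the leaf with the largest SSE until k = 8 leaves; each split is
   Lloyd's algorithm with farthest-point seeding, best of 10 seeded
   restarts; deterministic given the seed, with the full split hierarchy and
   per-node SSE retained, and a half-depth hierarchy cut available as the
   coarse segmentation map). Clusters whose mean reference abundance
   (Aβ1-42 + Aβ1-40) exceeds 3 × the grand mean and whose pixels carry
   reference signal in ≥ 25 % of cases are plaque class; the support
   condition prevents noise-only clusters in Aβ-negative control tissue from
   being flagged. Plaque objects are 4-connected components of ≥ 2 pixels.
   Each object is quantified from its *average* processed spectrum
   (averaging before annotation raises the effective SNR of small plaques by
   √n and stabilises minor species) — object mean feature vectors are also
   retained. Per-plaque abundances yield four truncation-category fractions
   (full-length = unmodified Aβ1-40/1-42; C-truncated = start 1, other end;
   N-truncated = ragged or pyroglutamate N-terminus ending at 40/42;
   bi-truncated = both) and the Aβx-40/x-42 terminal split of the
   N-truncated pool. Subjects are capped at 300 randomly sampled plaques
   (seeded, without replacement) so no subject dominates. Group summaries
   pool abundance within subject before taking fractions (per-plaque-mean
   averaging is available and agrees closely; pooling is the default because
   it is the natural abundance-weighted summary of a subject's signal).
   Co-localization is Pearson correlation of log-transformed abundances
   across plaques, zeros floored at half the per-variant minimum positive
   value; zero-variance variants give NaN entries, never 0. Group
   comparisons gate on Shapiro–Wilk (α = 0.05) into Welch's t-test or
   Mann–Whitney U (exact for n ≤ 20 without ties), and Kruskal–Wallis with
   Dunn's pairwise z-tests (tie-corrected; no multiplicity adjustment by
   default, Bonferroni/Holm available) for more than two groups.

Registration of fluorescence deposit masks onto the MSI grid is a
least-squares affine fit to ≥ 3 non-collinear landmark pairs with
nearest-neighbour resampling (preserving binarity); morphometry is
connected-component areas (pixel count × pixel area) and densities per
10⁶ µm² of tissue.

## Synthetic phantoms: what they emulate, and what they do not

No public MSI dataset carries per-plaque ground-truth compositions, so
validation rests on phantoms with known ground truth. A phantom is a
150 × 150-pixel field (20 µm pixels) carrying non-overlapping elliptical
plaques (aspect 1–2) and thin elongated tangle blobs (aspect 4–8), placed by
rejection sampling with a one-pixel separation ring. Deposit areas are
lognormal (log-scale sd 0.4) with means encoding the study conditions: sAD
plaques 1 600 µm² vs DS 8 000 µm² (ratio 5), sAD tangles 1 200 µm² vs DS
2 400 µm² (ratio 2); 150 plaques and 100 tangles per section (Poisson-
jittered between subjects). Counts are scaled to the phantom's 9 mm² field
of view — a package choice, not a biological claim; the per-subject
sampling cap of 300 then clamps with a warning.

Plaque compositions are Dirichlet draws (concentration 50, moderate
plaque-to-plaque variability) around subject compositions, which are in turn
Dirichlet draws (concentration 2000) around the group composition — subject
effects are kept small relative to plaque effects so that three subjects
still represent their group. Group compositions combine the four category
weights (sAD: full 24.1 %, N 45.9 %, C 23.5 %, bi 6.5 %; DS: full 13.7 %,
N 75.2 %, C 11.1 %, bi 0 %; the C and N values are the study conditions, the
full/bi split follows the groups' reported repertoires), terminal splits
(sAD 85:15 toward x-40, DS 35:65 toward x-42) and within-category species
weights over each group's reported repertoire (DS carrying the
pyroglutamate and x-42 N-truncated species, sAD the broader C- and
bi-terminal diversity).

Spectra are rendered as envelope Gaussians at a constant peak width (FWHM =
centre m/z / resolving power 6000 ≈ 0.625 Da), with unit apex per unit
isotopologue probability so summed apex intensity is proportional to species
weight, over an exponentially decaying chemical baseline (amplitude 30,
decay 800 Da), diffuse parenchyma signal with the subject composition
(amplitude 30, at or below the per-pixel detection limit, as in tissue
where single-pixel parenchyma Aβ is not reliably callable), 30-fold plaque
enrichment, per-pixel lognormal TIC variation (sd 0.25) and white Gaussian
noise (sd 1). Tangles are tau pathology and contribute no Aβ signal; they
exist only in the deposit masks. Fluorescence-style masks are re-rasterised
from the same deposit ellipses at 10 µm.

The phantom deliberately omits: mass-dependent TOF peak-width variation and
calibration drift, detector saturation, matrix cluster ions, partial-volume
plaque edges, intra-plaque microdomains, and any spatial correlation of
noise. Passing recovery tests therefore demonstrates that the pipeline's
inference is correct under its own forward model at realistic SNR — not
that it is robust to every instrumental artefact of real acquisitions.

## Numerical choices and degenerate inputs

- m/z axis: 0.1 Da sampling (≈ 6 samples per FWHM); observed envelope
  values are parabolic-interpolated, so sub-sample apex misalignment (< 2 %
  attenuation) is corrected.
- Hot-sample capping: at 3 × the per-spectrum 99.9th intensity percentile
  rather than the percentile itself — in plaque spectra genuine peak tops
  occupy more than 0.1 % of the axis, and capping at the raw percentile
  would clip them; an isolated detector spike still exceeds 3 × the
  percentile and is capped.
- Noise MAD uses every 4th sample per 50 Da window (≥ 125 samples): a
  several-fold cheaper scale estimate with ≈ 6 % estimator noise, immaterial
  against the SNR-3 gate.
- All-zero spectra flag empty pixels and are excluded from normalisation
  and statistics; plaques with zero total abundance are excluded from
  profiles with a warning.
- 2-means ties: restart with the lowest SSE wins, first-come on exact ties;
  empty clusters are reseeded with the farthest point. Leaves with all-
  identical rows are never split, and k beyond the number of distinct rows
  is an error.
- NNLS rank degeneracy is decided on rendered design columns at cosine
  > 1 − 10⁻⁹.
- Affine fits reject < 3 pairs or collinear landmark clouds
  (rank-deficient centred source matrix).
- Mann–Whitney switches to the normal approximation (tie-corrected) above
  n = 20 or in the presence of ties.

## Problem sizes used in validation

The recovery studies run at the full 150 × 150-pixel, 3-subjects-per-group
scale (the conditions above) for truncation fractions, and three replicate
seeds of layout-only phantoms for morphometry ratios. Unit and property
tests use 20–60-pixel grids and narrowed m/z windows around the species
under test; oracle equivalences (exhaustive 2-means, atom-by-atom envelope
convolution, residue-sum masses) run at the small sizes where exhaustive
computation is exact.

## Known limitations

- Equivalence with the vendor software's proprietary baseline, denoising
  and segmentation implementations is not claimed; the chain here is a
  documented, deterministic reading of the processing steps as described.
- Whether envelope presence is judged visually or numerically in vendor
  workflows varies; the cosine ≥ 0.8 rule is this package's numeric
  operationalisation.
- The m/z match tolerance (200 ppm) and cluster count (k = 8) are defaults
  where the source protocol states none; both are configuration.
- Species pairs with identical elemental composition are fundamentally
  indistinguishable by mass spectrometry; the pipeline reports the
  lower-m/z member and logs the ambiguity.
- Morphological deposit inclusion criteria ("characteristic morphology")
  are emulated only as minimum-size filtering; plaque/tangle discrimination
  from fluorescence texture is out of scope (phantom masks carry kind
  labels as ground truth).
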