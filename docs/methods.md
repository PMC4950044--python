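# Methods and design notes

## The survey model

The package analyses samples-by-OTU abundance tables from latitudinal ocean
transects. Two observation modes are distinguished throughout:

* **counts** — integer sequencing reads per OTU per library; supports the
  richness estimators (Chao1, ACE) and exact rarefaction;
* **relative** — normalized T-RFLP peak heights summing to 1 per sample;
  richness extrapolation is refused in this mode (a detection-thresholded
  fingerprint has no sampling-theory singletons), while Shannon, Simpson and
  all beta-diversity statistics apply.

Stations are binned into six latitudinal province bands (ARCT 55–70°N,
NADR 40–55°N, NAG 12–40°N, WTRA 6°S–12°N, SATL 40–6°S, SANT 55–40°S;
half-open, north-favouring on interior boundaries — any consistent rule
works, this one is documented and property-tested to tile the domain) and
four depth layers (epipelagic < 200 m, mesopelagic 200–1000 m, upper
bathypelagic 1000–2000 m inclusive, lower bathypelagic > 2000 m). The
epipelagic floor at 200 m is the conventional one; the transect design this
emulates sampled the euphotic zone at 50 m, so the choice is not exercised
hard and is configurable by editing `tables.LAYERS`.

## The synthetic transect generator

`synthetic.build_metacommunity` draws, per OTU: a latitudinal niche center,
a Gaussian niche breadth σ = σ0 + k·|center| (k = `rapoport_k`; the
generative version of the Rapoport pattern), a bipolar flag (probability
`bipolar_fraction`; bipolar taxa respond to |latitude|, so one niche yields
both high-latitude occurrences — this directly produces the U-shaped
similarity profile and cross-polar OTU sharing), depth-layer affinities
(Dirichlet(0.5 + 4·onehot of a uniformly drawn preferred layer)), and a
lognormal(0, 1) carrying-capacity multiplier.

Niche centers are uniform over the survey span shrunk by
min(2.5 σ0, 30 % of span) at each end; the `richness_gradient` fraction is
instead drawn from a tropical pool (normal, mean 0°, sd 15°), producing a
latitudinal diversity gradient. The margin keeps baseline-breadth ranges
from being clipped by the survey boundary, which would otherwise imprint a
spurious *negative* range-vs-latitude trend (a mid-domain artifact, not
biology). `sigma0 = inf` is the neutral limit — no latitudinal selection at
all — used as the exchangeable null for regression calibration (below).

Expected relative abundance of OTU i in sample s is

    p_is ∝ scale_i · exp(−(x_s − c_i)² / 2σ_i²) · affinity_i[layer(s)]

with x_s = |lat_s| for bipolar taxa and signed latitude otherwise. The two
observation processes then differ deliberately:

* **reads** — one multinomial draw of `read_depth` (default 2000) per
  sample: pure sampling noise, the dominant error of amplicon libraries;
* **fingerprints** — multiplicative lognormal noise with CV `noise_cv`
  (default 0.25), then removal of peaks below `trflp_threshold` (default
  0.5 % of the sample total, boundary kept) and renormalization: the
  dominant errors of electropherogram quantification.

Hydrography is a smooth caricature with realistic magnitudes (temperature
declining with |lat| and depth toward a 2 °C deep ocean; a tropical oxygen
minimum near 250 m with a nitrite maximum beside it; subtropical surface
salinity maxima; Thaumarchaeota 16S abundance declining with depth; the
ecotype ratio increasing with depth). Sampling dates advance with station
index, so time is confounded with latitude exactly as on a real cruise —
visible in the variation partitioning as a space∩time overlap with a near
zero unique time fraction.

Defaults (51 stations, 55°S–64°N, depths 50/250/500/1000/1500/2500/4000 m)
mirror the transect design the package emulates. What the generator does
*not* contain: dispersal limitation or neutral drift (species sorting only),
ocean circulation, sequencing chimeras/frameshifts, or peak bleed-through —
so passing recovery tests show the statistics detect niche-generated
structure, not that real data are this clean.

All randomness flows from one master seed through named `SeedSequence`
substreams (0 = metacommunity, 1 = reads, 2 = peak noise), so any stage can
be regenerated independently and whole runs are bit-reproducible.

## Statistical procedures and numerical choices

* **Bray–Curtis** is always computed on row-normalized abundances
  (d = Σ|x−y|/Σ(x+y), similarity 1 − d), making counts and fingerprints
  comparable and the statistic library-size invariant. No square-root or
  fourth-root pre-transformation is applied by default.
* **Distance–decay** regresses ln(similarity) on great-circle distance
  (haversine, R = 6371 km) per 1000 km. Zero similarities are dropped and
  counted, not offset. Segments split at the equator; equator samples belong
  to whichever segment is being fit (the equator is the joint endpoint).
  Fits with p ≥ 0.05 are flagged non-significant. The overall
  similarity-trend correlation is reported twice — linear in distance and
  quadratic in latitude — labelled explicitly, since the two summaries
  answer different questions about a U-shaped profile.
* **Stevens ranges**: presence is abundance > 0 after upstream thresholding
  (no extra occupancy filter); single-occurrence OTUs get range 0; the
  per-sample mean is unweighted. Abundance classes use maximum relative
  abundance: high-abundance (HA) > 5 %, low-abundance (LA) > 0.5 %, so
  HA ⊂ LA; LA is reported both inclusive and exclusive of HA.
* **ANOSIM** ranks dissimilarities with mean ranks for ties (fingerprint
  distances tie often). Monte-Carlo p = (1 + #{R* ≥ R})/(n_perm + 1) —
  never 0; the default 999 permutations makes the smallest reportable
  p = 0.001. Exact mode enumerates distinct label assignments (one-way) or
  the product space of within-stratum assignments (two-way). The two-way
  crossed statistic averages per-stratum R unweighted; strata where a factor
  is inestimable are skipped and logged. A constant distance matrix yields
  R = 0 with a warning.
* **PCoA** uses Gower double-centering without Cailliez/Lingoes correction;
  negative eigenvalues are reported but excluded from coordinates, and
  proportions explained divide by the positive-eigenvalue sum. Metric PCoA
  deliberately stands in where non-metric MDS might be used elsewhere:
  it is deterministic and exactly testable (stress optimisation is a
  non-goal, and users should expect ordinations to differ from nMDS plots).
* **CCA** follows ter Braak: SVD of the row-weighted projection of the
  chi-square residual matrix Q̄ = (p_ij − r_i c_j)/√(r_i c_j) onto the
  weighted-centered constraints. Collinear constraint columns are dropped
  greedily (warning lists them). Axis proportions are reported against both
  total and constrained inertia, labelled, because the "% of variation"
  convention differs between software. Site scores are weighted averages of
  species scores (scaling 2); scaling does not affect the tested quantities
  (eigenvalues, inertias).
* **RDA / partial RDA** centers responses, optionally residualizes both
  sides on covariates, and eigen-decomposes the fitted values. Predictor
  rank is judged against the pre-partialling scale so directions annihilated
  by covariates cannot resurface as numerical noise. Adjusted R² is
  Ezekiel's 1 − (1 − R²)(n − 1)/(n − m − 1) with m the predictor rank;
  partial RDA with an empty covariate set equals plain RDA bit-for-bit.
* **Variation partitioning** fits the seven nested RDAs, converts to
  adjusted R², and solves the (invertible) inclusion–exclusion system for
  the seven Venn fractions; negative fractions — a standard feature of
  adjusted-R² partitioning — are reported as computed and flagged. The
  spatial block is latitude, |latitude| and depth; the temporal block is
  day-of-cruise.
* **Fingerprint processing**: terminal-fragment lengths come from the first
  restriction site on the labelled strand (MboI ^GATC, RsaI GT^AC,
  HaeIII GG^CC; the 3′-labelled fragment is computed on the reverse
  complement). Peaks at exactly the 0.5 % threshold are kept. Binning is by
  floor into `bin_width` intervals per (enzyme, dye) channel; each sample is
  normalized per channel and channels averaged with equal weight (composite
  fingerprint) — bin width and the composite rule are exposed because
  fingerprint software conventions differ. The 98 %-identity clusterer is
  greedy-incremental in decreasing abundance order (ties by input order),
  with identity = matches/alignment-length under global alignment; it is
  intended for synthetic amplicons, not raw 454 reads.

## Calibration philosophy

Two different nulls calibrate the Rapoport regression, on purpose:

1. *Permutation null* — latitude labels shuffled against observed Stevens
   means: valid for any community, structured or not; the rejection rate is
   checked to sit at ≈ α.
2. *Generator null* — surveys from the neutral limit (`sigma0 = inf`,
   `rapoport_k = 0`, no bipolarity, no richness gradient): samples are
   exchangeable and the plain-OLS type-I error is well defined, checked at
   ≈ 5 % over a seed grid.

A *finite-breadth* k = 0 community is not a usable null for plain OLS: its
per-sample Stevens means are spatially autocorrelated (neighbouring samples
share OTUs) and boundary-truncated, so ordinary regression — which this
toolkit intentionally uses, matching field practice, with no Mantel/dbMEM
spatial correction (a declared non-goal) — is anti-conservative there
regardless of implementation correctness. Interpret significant Rapoport
slopes on real transects accordingly.

## Problem sizes

The packaged analyses and checks run at desk scale by choice: the default
survey is 51 stations × 7 depths × 300 OTUs; recovery and calibration grids
use 20 seeds of 60 stations × 4 depths × 300 OTUs; permutation tests use
999 (pipeline) or 199 (calibration grids) permutations. These sizes give
the acceptance properties (≥ 18/20 recovery, type-I within the binomial CI
of 5 %) comfortable margins while keeping any single script in the
seconds-to-a-minute range.

## Known limitations

* No dispersal-limited/neutral assembly simulator — parameter-recovery
  results speak to species-sorting structure only.
* Provinces are latitude bands, not true Longhurst polygons; longitude is
  ignored in assignment.
* Greedy clustering is quadratic in the number of unique sequences; fine
  for toy/synthetic marker sets, wrong tool for large read sets.
* The exact-enumeration ANOSIM is capped (5·10⁵ assignments) and meant for
  oracle-scale designs.
* nMDS, UniFrac, PERMANOVA, Mantel tests and constraint forward selection
  are out of scope.
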