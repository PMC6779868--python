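# Methods

## The seed-screen model

A mature angiosperm seed couples two DNA contents through one reproductive
event. Writing the monoploid genome as x and C-values in multiples of 1C:

* egg cell: `m/2` if meiotically reduced, `m` if unreduced, for a mother of
  ploidy `m`;
* each of `k` polar nuclei of the central cell (`k = 2` normally, `k = 3`
  for the rare tri-nucleate central cell): `m/2` or `m` likewise;
* each sperm from a pollen donor of ploidy `p`: `p/2` or `p`;
* embryo = egg (+ one sperm if the embryo is fertilized);
* endosperm = `k` polar nuclei + `s` sperms, `s ∈ {0, 1, 2}` (`s = 0` is
  autonomous endosperm).

All C-values are carried as exact rationals (`fractions.Fraction`), so
reduced gametes of odd ploidy (e.g. a 3/2-x sperm from a triploid) never
lose precision, and profile labels such as `2/5` or `3/4.5` render exactly.
Mode classes follow the structure, not the numbers: reduced egg + fertilized
embryo = sexual; unreduced egg + fertilized embryo = BIII hybrid;
parthenogenetic egg with `s = 0` = autonomous apomixis, with `s ≥ 1` =
pseudogamous apomixis.

The default enumerated candidate set per maternal cytotype contains sexual
double fertilization, autonomous endosperm, and pseudogamy with one or two
reduced or unreduced sperms — for a diploid with diploid pollen the
profiles 2/3, 2/4, 2/5, 2/6 and 2/8 (quotients 1.5, 2.0, 2.5, 3.0, 4.0).
Tri-nucleate (`k = 3`) and BIII variants are opt-in, per species or
population, because they are rare embryo-sac aberrations that would dilute
classification specificity if always present. Scenarios with identical
(embryo C, endosperm C, mode) are merged, but merged variants stay
attached to the representative so classification can report genuine
biological ties — 2/6 as "one unreduced sperm *or* two reduced sperms" is
the canonical example.

## Quotient classification

An observed endosperm:embryo quotient is assigned to the scenario with the
smallest relative deviation `|obs − exp| / exp`; all scenarios tying at the
minimum are kept. If even the nearest scenario deviates more than the
relative tolerance (default **8%**), the call is `unresolved` — aberrant
quotients are reported with their deviation, never force-fitted. The 8%
default is chosen so that the closest pair of default diploid quotients
(2.5 vs 3.0, 18% apart) cannot both match one observation, while still
absorbing realistic peak-position error at CVs of a few percent;
classification always reports the deviation so near-ties can be audited.

When tied matches span mode classes (with BIII enabled, quotient 1.5 is
both sexual 2/3 and BIII 4/6; with `k = 3`, quotient 3.0 is both
pseudogamous 2/6 and autonomous tri-nucleate), the reported mode follows a
fixed conservative priority — sexual, then pseudogamous, then autonomous,
then BIII — and all tied scenarios remain in the call. Quotients alone
cannot resolve these ties; absolute genome sizes can (below).

## Gamete back-calculation (internal-standard samples)

With an internal standard (leaf tissue of known 2C content co-chopped with
the seed), fluorescence converts to picograms linearly:
`gs = peak_mean / standard_mean × standard_2C`. For each candidate scenario
the embryo genome size pins the monoploid genome `g1 = embryo_gs /
embryo_C`; the polar contribution follows, and the implied sperm genome
size solves `endosperm_gs = k·polar_gs + s·sperm_gs`. A scenario is
plausible when the implied sperm is close to the maternal unreduced gamete
size `m·g1` (unreduced) or half of it (reduced); for every parthenogenetic
scenario `m·g1` equals the embryo genome size itself, so this is the
familiar "close to the embryo genome size or half of it" rule — phrasing it
through the maternal contribution keeps it correct for fertilized-embryo
(sexual, BIII) scenarios as well. The consistency tolerance defaults to
12%, looser than the quotient tolerance because two measured genome sizes
(embryo and endosperm) both carry error. Autonomous scenarios are tested by
whether the polar nuclei alone account for the endosperm. Solutions are
ranked by deviation and exact ties cross-referenced as alternates.

## Peak detection and role assignment

Histograms are smoothed with a short moving average (width 5 channels,
nearest-edge padding so flat histograms stay flat), local maxima above a
relative prominence floor (1.5% of the smoothed maximum) are located with
`scipy.signal.find_peaks`, and each peak's mean, CV and nuclei count come
from weighted moments of the *raw* counts within ±2.5 estimated sigma
(iterated once so the window tracks the estimate; ±2.5σ captures ≈ 98.8% of
a Gaussian while limiting debris leakage). Peaks with CV above 8% are
flagged, not dropped. A sample with fewer than 5000 recorded particles
triggers a warning, not a failure — weak samples (old or tiny seeds) can
still carry usable peaks.

Role assignment: the most nucleus-rich non-standard peak is the embryo
(embryos contribute roughly 2–3× the endosperm's nuclei in practice; count
ties break toward the lower position and are logged). Endosperm candidates
are the remaining peaks whose quotient falls in [1.2, 6.0], after excluding
*replicate* peaks — a peak within 6% of twice a lower peak's position with
fewer than 25% of its nuclei is read as G2/endoreduplication, which
otherwise would masquerade as an endosperm at quotient 2.0 whenever the
true profile is 2/5 or 2/6. The most nucleus-rich surviving candidate wins.
The 25% count threshold separates the two populations it must separate:
replicate peaks are simulated (and typically observed) at ~10% of their G1,
while a true endosperm G1 carries ~40% of the embryo's nuclei.

The second-endosperm-peak rule for strongly endopolyploid taxa — when the
endosperm G1 peak is depleted, measure the endosperm's first replicate peak
and halve its mean — is **opt-in**. Geometry alone cannot distinguish an
endopolyploid sexual seed (replicate at 3× the embryo) from a genuine 2/6
apomictic seed at the same position; the rule is applied per taxon from
prior knowledge, as in practice. When enabled, it fires only if the halved
position matches an expected endosperm quotient (default: sexual 1.5) and
nothing sits at the expected G1 position itself; every firing is logged.

Endosperm percentage is `100 × endosperm_count / (embryo_count +
endosperm_count)`, per seed; family- or species-level summaries average the
per-seed percentages rather than pooling counts.

## Synthetic data

The generator emulates what the analysis consumes, not the instrument:
Gaussian G0/G1 peaks (default CV 3%, a clean DAPI preparation), replicate
peaks at exactly 2× each G1 with 10% of its count, exponential debris
(default 5% of events, decay constant 60 channels), 1024 unit-spaced linear
channels, and exactly `total_particles` (default 5000) events per sample,
allocated multinomially across components so the recorded total is exact.
Expected embryo:endosperm nuclei default to 1500:600, the magnitude
reported in real seed screens. Mixed scenario sets are allocated to seeds
by largest-remainder rounding (exact counts, e.g. 2 apomictic seeds out of
22) and shuffled; per-seed RNG streams derive from one master seed, so
identical configurations are bit-identical. Not modelled: DAPI's AT base
preference, the S-phase continuum, aggregates/doublets, and instrument
drift — so passing recovery tests demonstrate the pipeline's logic on clean
signals, not robustness to every laboratory artifact.

The trait generator draws continuous traits as `N(shift, noise_sd²)` with a
configurable standardized between-group shift, and binary clonal-growth
indicators as Bernoulli with per-group probabilities (baseline 0.30), over
a default template of whole-plant, organ, clonal and ecological trait
groups.

## Trait comparison

All trait columns are centered and scaled to unit variance before RDA —
the inputs mix units (cm, %, pg, indicator scores), so correlation-scale
ordination is the defensible default; constant columns are dropped with a
warning. With one binary constraint the constrained ordination has a single
axis and `pseudo-F = SS_explained / (SS_residual / (n − 2))`, which equals
the classical two-group ANOVA F for a single trait (the test suite verifies
this against `scipy.stats.f_oneway` to 1e-10). Permutation inference
shuffles the group labels (default 9999 permutations) and uses the
add-one estimator `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, whose floor
is `1/(n_perm+1)`; the permutation statistics are computed in one
vectorized pass. Univariate summaries use a two-sided permutation test on
the mean difference (continuous) and Fisher's exact test (binary), starred
at 0.05/0.01/0.001, unadjusted by default with an optional Holm flag —
mirroring the usual presentation of such trait tables.

## Pipeline determinism and problem sizes

Every CSV and report carries a 12-hex config hash and the RNG seed; reruns
with an identical config are byte-identical. Per-sample failures are logged
and skipped. Simulation-based test claims run at deliberately modest sizes
chosen to estimate the relevant rates tightly: 200 seeds per scenario for
mode recovery, 1000 histograms for peak accuracy, 500 replicates × 999
permutations for type-I error control.

## Known limitations

* Fluorescence is assumed linear; no log-amplifier support.
* No doublet/aggregate discrimination or multi-channel compensation; input
  is a single fluorescence histogram per sample.
* Pooled multi-seed samples are measured as one histogram; a pooled sample
  mixing modes yields whichever peaks dominate (the screen's remedy —
  re-measuring single seeds — is the user's workflow decision).
* Haploid maternal plants are rejected by default.
* The second-peak endopolyploidy rule depends on taxon knowledge; enabling
  it globally would misread genuine 2/6 apomicts.
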