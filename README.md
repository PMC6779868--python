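# seedscreen

Flow-cytometric seed screening (FCSS) infers how a plant made its seeds —
sexually, or by gametophytic apomixis — from the relative DNA contents of the
two seed tissues. A sexual angiosperm seed from reduced gametes and normal
double fertilization has a 2C embryo (1C egg + 1C sperm) and a 3C endosperm
(2C fused polar nuclei + 1C sperm), so the endosperm:embryo fluorescence
quotient is 1.5. Apomictic seeds break this geometry: an unreduced
parthenogenetic egg with autonomous endosperm gives 2C/4C (quotient 2.0);
pseudogamy — the endosperm alone still needs fertilization — gives 2C/5C with
one reduced sperm or 2C/6C with an unreduced sperm (or two reduced ones);
tri-nucleate central cells push profiles to 2/7, 2/8 or 2/10; and
fertilization of the unreduced egg produces ploidy-raising BIII hybrids
(e.g. 4x embryo / 6x endosperm).

`seedscreen` is a tested, reusable pipeline for this analysis, aimed at plant
reproductive biologists running DAPI seed screens:

* **`seedscreen.simulate`** — synthetic DAPI seed histograms (Gaussian G0/G1
  peaks, G2/endoreduplication replicates, exponential debris, optional
  internal standard) and species × trait tables, all with recorded ground
  truth, so every downstream stage is testable without raw cytometry files.
* **`seedscreen.io` / `seedscreen.peaks`** — plain-text histogram I/O,
  automatic G0/G1 peak detection (mean fluorescence, CV, nuclei count),
  embryo/endosperm/standard role assignment including the
  second-endosperm-peak rule for strongly endopolyploid taxa, endosperm
  percentage, and internal-standard genome-size conversion (e.g. *Pisum
  sativum* 'Ctirad' 2C = 9.09 pg, *Bellis perennis* 2C = 3.38 pg).
* **`seedscreen.scenarios`** — the fertilization-scenario calculus: exact
  C-value profiles as rationals of x, scenario enumeration (sexual,
  autonomous, pseudogamous; optional tri-nucleate and BIII extensions),
  quotient classification into reproductive modes with explicit deviations
  and preserved ties, gamete genome-size back-calculation, and species-level
  aggregation (facultative apomixis, no-endosperm flagging).
* **`seedscreen.traits`** — apomict vs sexual trait-syndrome comparison:
  redundancy-analysis (RDA) pseudo-F with a binary constraint,

      pseudo-F = (SS_explained / 1) / (SS_residual / (n − 2)),

  Monte Carlo permutation p-values, and per-trait univariate summaries
  (permutation mean-difference tests, Fisher exact tests, significance
  stars).
* **`seedscreen.pipeline` / `seedscreen.cli`** — a `seedscreen` console
  command with `simulate`, `detect`, `classify`, `screen` and `compare`
  subcommands driven by a declarative YAML config; every output carries the
  config hash and RNG seed.

## Worked example

Classify the aberrant quotient 3.32 observed in a single seed against the
extended diploid scenario set:

```console
$ seedscreen classify --quotient 3.32 --trinucleate --biii
observed quotient : 3.32
mode              : apomictic_pseudogamous
deviation         : 0.0514 (tolerance 0.08)
  matched 2/7 [apomictic_pseudogamous]: parthenogenetic unreduced egg; 3 unreduced polar nuclei + 1 reduced sperm (2x pollen)
```

The quotient sits 5.1% below 3.5, the expected value of the 2/7 profile
(tri-nucleate central cell fertilized by one reduced sperm) — formally the
closest scenario, with every other candidate more than 8% away.

A facultative-apomict screen end to end, from a config that simulates 22
seeds of one species with a 20:2 sexual:apomictic mix:

```console
$ seedscreen screen --config examples/festuca_like.yaml
species,n_seeds,n_sexual,n_apomictic,n_no_endosperm,n_unresolved,species_mode
festuca_like,22,20,2,0,0,facultative_apomict
```

Both apomictic seeds carry the 2/6 profile (one unreduced or two reduced
sperms in the endosperm — an exact tie the per-seed CSV preserves in its
`alternates` column).

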