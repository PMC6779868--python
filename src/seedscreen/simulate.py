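"""Synthetic seed-screen data with known ground truth.

Emulates DAPI-stained seed flow cytometry well enough to exercise every
downstream stage: Gaussian G0/G1 peaks for embryo, endosperm and an optional
internal standard; G2/endoreduplication replicate peaks at exactly twice each
G1 position; an exponential-decay debris background; and a fixed number of
recorded particles.  A parallel trait-table generator produces species-level
apomict/sexual contrasts with configurable effect sizes.

Default magnitudes mirror a typical seed screen: ~1500 embryo and ~600
endosperm nuclei per seed, 5000 recorded particles, CVs of a few percent on
1024 linear channels.  Deliberately not modelled: fluorochrome
base-composition bias, the S-phase continuum between G1 and G2, and
instrument drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scenarios as sc
from .io import HistogramData

__all__ = [
    "PeakSim",
    "SeedScenarioSim",
    "TraitSimConfig",
    "HistogramTruth",
    "simulate_histogram",
    "simulate_seed_set",
    "simulate_trait_table",
    "largest_remainder_allocation",
    "DEFAULT_TRAITS",
]

N_CHANNELS = 1024


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g. unknown scenario label)."""


@dataclass(frozen=True)
class PeakSim:
    """Ground-truth parameters of one simulated peak."""

    position: float
    cv: float
    count: int
    role_truth: str  # embryo_G1 | embryo_G2 | endosperm_G1 | endosperm_replicate | standard

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ConfigurationError("peak position must be positive")
        if not 0 < self.cv <= 25:
            raise ConfigurationError("peak cv must be in (0, 25] percent")
        if self.count < 1:
            raise ConfigurationError("peak count must be >= 1")


@dataclass
class SeedScenarioSim:
    """Configuration for one simulated seed sample.

    ``scenario_truth`` is either a ScenarioSpec or a profile label resolvable
    against the default diploid scenario set extended with tri-nucleate and
    BIII variants.  The endosperm position follows from the scenario's
    expected quotient times ``embryo_position``.
    """

    scenario_truth: sc.ScenarioSpec | str
    embryo_position: float = 100.0
    cv: float = 3.0
    embryo_count: int = 1500
    endosperm_count: int = 600
    g2_fraction: float = 0.10  # replicate-peak count as a fraction of its G1
    endopolyploid: bool = False  # deplete endosperm G1 into its replicate peak
    debris_fraction: float = 0.05
    debris_scale: float = 60.0
    total_particles: int = 5000
    seeds_pooled: int = 1
    standard: tuple[str, float, float] | None = None  # (species, 2C pg, position)
    species: str = "sim"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.total_particles < 1:
            raise ConfigurationError("total_particles must be >= 1")
        if self.seeds_pooled < 1:
            raise ConfigurationError("seeds_pooled must be >= 1")
        if self.debris_scale <= 0:
            raise ConfigurationError("debris_scale must be positive")

    def resolve_scenario(self) -> sc.ScenarioSpec:
        if isinstance(self.scenario_truth, sc.ScenarioSpec):
            return self.scenario_truth
        label = str(self.scenario_truth)
        embryo_c, endosperm_c = sc.parse_label(label)
        for m in (2, 3, 4):
            pool = sc.enumerate_scenarios(
                m, (2, 3), include_trinucleate=True, include_biii=True
            )
            for cand in pool:
                if cand.embryo_c == embryo_c and cand.endosperm_c == endosperm_c:
                    return cand
        raise ConfigurationError(
            f"scenario label {label!r} does not match any enumerable profile "
            "for maternal ploidies 2-4"
        )


@dataclass(frozen=True)
class HistogramTruth:
    """Ground truth attached to one simulated histogram."""

    scenario: sc.ScenarioSpec
    peaks: tuple[PeakSim, ...]
    expected_quotient: float

    def peak(self, role: str) -> PeakSim | None:
        for p in self.peaks:
            if p.role_truth == role:
                return p
        return None


def _build_peaks(sim: SeedScenarioSim, scenario: sc.ScenarioSpec) -> list[PeakSim]:
    q = float(scenario.quotient)
    endo_pos = q * sim.embryo_position
    peaks = [PeakSim(sim.embryo_position, sim.cv, sim.embryo_count, "embryo_G1")]
    if sim.g2_fraction > 0:
        peaks.append(
            PeakSim(
                2 * sim.embryo_position,
                sim.cv,
                max(1, int(round(sim.g2_fraction * sim.embryo_count))),
                "embryo_G2",
            )
        )
    if sim.endosperm_count > 0:
        if sim.endopolyploid:
            # endopolyploidy empties the G1 endosperm peak into its replicate
            peaks.append(
                PeakSim(2 * endo_pos, sim.cv, sim.endosperm_count, "endosperm_replicate")
            )
        else:
            peaks.append(PeakSim(endo_pos, sim.cv, sim.endosperm_count, "endosperm_G1"))
            if sim.g2_fraction > 0:
                peaks.append(
                    PeakSim(
                        2 * endo_pos,
                        sim.cv,
                        max(1, int(round(sim.g2_fraction * sim.endosperm_count))),
                        "endosperm_replicate",
                    )
                )
    if sim.standard is not None:
        _, _, pos = sim.standard
        peaks.append(PeakSim(pos, sim.cv, max(1, sim.embryo_count // 2), "standard"))
    return peaks


def simulate_histogram(
    sim: SeedScenarioSim, rng_seed: int
) -> tuple[HistogramData, HistogramTruth]:
    """Simulate one seed sample's binned fluorescence histogram.

    Exactly ``total_particles`` events are drawn: each is assigned to a peak
    or to debris with probability proportional to the configured expected
    counts (debris weight = ``debris_fraction`` of the total), then given a
    Gaussian (peaks) or exponential (debris) fluorescence value and binned
    onto 1024 unit-spaced channels.  Out-of-range values are clipped into the
    edge bins so the recorded particle total is exact.  Identical
    (sim, rng_seed) pairs give bit-identical output.
    """
    scenario = sim.resolve_scenario()
    peaks = _build_peaks(sim, scenario)
    rng = np.random.default_rng(rng_seed)

    peak_weights = np.array([p.count for p in peaks], dtype=float)
    debris_weight = sim.debris_fraction * peak_weights.sum() / max(
        1e-12, 1.0 - sim.debris_fraction
    )
    weights = np.append(peak_weights, debris_weight)
    weights /= weights.sum()
    alloc = rng.multinomial(sim.total_particles, weights)

    values = []
    for p, n in zip(peaks, alloc[:-1]):
        if n:
            values.append(rng.normal(p.position, p.cv / 100.0 * p.position, size=n))
    if alloc[-1]:
        values.append(rng.exponential(sim.debris_scale, size=alloc[-1]))
    all_values = np.concatenate(values) if values else np.empty(0)

    edges = np.arange(0.5, N_CHANNELS + 1.5)
    clipped = np.clip(all_values, edges[0] + 1e-9, edges[-1] - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    channels = np.arange(1, N_CHANNELS + 1, dtype=float)

    std_species = std_pg = None
    if sim.standard is not None:
        std_species, std_pg, _ = sim.standard
    h = HistogramData(
        channels,
        counts,
        sample_id=sim.sample_id or f"{sim.species}_{rng_seed}",
        species=sim.species,
        seeds_pooled=sim.seeds_pooled,
        standard_species=std_species,
        standard_2c_pg=std_pg,
    )
    truth = HistogramTruth(scenario, tuple(peaks), float(scenario.quotient))
    return h, truth


def largest_remainder_allocation(proportions: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` items to proportions exactly (largest-remainder)."""
    props = np.asarray(proportions, dtype=float)
    if props.size == 0 or np.any(props < 0):
        raise ConfigurationError("proportions must be a nonempty non-negative sequence")
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ConfigurationError("scenario-mix proportions must sum to 1")
    quota = props * n
    base = np.floor(quota).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:remainder]:
        base[i] += 1
    return base.tolist()


@dataclass
class SpeciesSimConfig:
    """Scenario mix for one simulated species."""

    species: str
    scenario_mix: Mapping[str, float]  # profile label -> proportion
    n_seeds: int
    sim_kwargs: dict = field(default_factory=dict)


def simulate_seed_set(
    species_config: Sequence[SpeciesSimConfig], rng_seed: int
) -> tuple[list[tuple[HistogramData, HistogramTruth]], pd.DataFrame]:
    """Simulate a multi-species seed set with exact per-scenario seed counts.

    Scenario labels are allocated to seeds by largest-remainder rounding of
    the mix proportions (so a 2/22 apomictic fraction yields exactly two
    apomictic seeds) and then shuffled; per-seed RNG streams derive from
    ``rng_seed`` so the whole set is reproducible bit-for-bit.
    """
    if not species_config:
        raise ConfigurationError("species_config must be nonempty")
    master = np.random.default_rng(rng_seed)
    results: list[tuple[HistogramData, HistogramTruth]] = []
    rows = []
    for cfg in species_config:
        labels = list(cfg.scenario_mix)
        alloc = largest_remainder_allocation(
            [cfg.scenario_mix[lab] for lab in labels], cfg.n_seeds
        )
        seed_labels = [lab for lab, k in zip(labels, alloc) for _ in range(k)]
        master.shuffle(seed_labels)
        for i, lab in enumerate(seed_labels):
            child_seed = int(master.integers(0, 2**31 - 1))
            sim = SeedScenarioSim(
                scenario_truth=lab,
                species=cfg.species,
                sample_id=f"{cfg.species}_seed{i:03d}",
                **cfg.sim_kwargs,
            )
            h, truth = simulate_histogram(sim, child_seed)
            results.append((h, truth))
            rows.append(
                {
                    "sample_id": h.sample_id,
                    "species": cfg.species,
                    "scenario_truth": truth.scenario.label,
                    "mode_truth": truth.scenario.mode,
                    "expected_quotient": truth.expected_quotient,
                    "rng_seed": child_seed,
                }
            )
    return results, pd.DataFrame(rows)


# Trait template emulating a functional-trait screen: continuous organ and
# whole-plant measurements, binary clonal-growth indicators, and continuous
# ecological indicator values, each assigned to exactly one trait group.
DEFAULT_TRAITS: dict[str, list[tuple[str, str]]] = {
    "whole_plant": [("plant_height", "continuous"), ("seed_mass", "continuous")],
    "organ": [
        ("leaf_nitrogen", "continuous"),
        ("leaf_phosphorus", "continuous"),
        ("leaf_dry_matter", "continuous"),
        ("root_nitrogen", "continuous"),
        ("starch_content", "continuous"),
    ],
    "clonal": [
        ("clonal", "binary"),
        ("epigeogenic_rhizome", "binary"),
        ("splitter", "binary"),
        ("spreading", "binary"),
    ],
    "ecological": [
        ("landscape_abundance", "continuous"),
        ("elevation_range", "continuous"),
        ("moisture_indicator", "continuous"),
        ("nutrient_indicator", "continuous"),
    ],
}


@dataclass
class TraitSimConfig:
    """Configuration for the species x trait table generator.

    ``effects`` maps trait name -> effect size: for continuous traits a
    between-group mean shift in units of ``noise_sd``; for binary traits
    either a probability shift added to the 0.30 baseline or an explicit
    ``(p_apomict, p_sexual)`` pair.
    """

    n_species: int = 200
    apomict_fraction: float = 0.06
    effects: Mapping[str, object] = field(default_factory=dict)
    noise_sd: float = 1.0
    rng_seed: int = 0
    traits: Mapping[str, list[tuple[str, str]]] = field(
        default_factory=lambda: DEFAULT_TRAITS
    )
    binary_baseline: float = 0.30

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ConfigurationError("n_species must be >= 4")
        if not 0 < self.apomict_fraction < 1:
            raise ConfigurationError("apomict_fraction must be in (0, 1)")
        known = {name for group in self.traits.values() for name, _ in group}
        unknown = set(self.effects) - known
        if unknown:
            raise ConfigurationError(f"effects specified for unknown traits: {sorted(unknown)}")


def simulate_trait_table(cfg: TraitSimConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate a species x trait table with a known apomict/sexual contrast.

    Returns ``(table, trait_groups)`` where the table has a ``mode_label``
    column ('apomict' / 'sexual') and one column per trait, and
    ``trait_groups`` maps trait name -> group name.  Group sizes follow
    ``apomict_fraction`` deterministically (at least one species per group).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_species
    n_apo = int(round(cfg.apomict_fraction * n))
    n_apo = min(max(n_apo, 1), n - 1)
    labels = np.array(["apomict"] * n_apo + ["sexual"] * (n - n_apo))

    data: dict[str, np.ndarray] = {
        "species": np.array([f"sp{i:04d}" for i in range(n)]),
        "mode_label": labels,
    }
    groups: dict[str, str] = {}
    is_apo = labels == "apomict"
    for group, traits in cfg.traits.items():
        for name, kind in traits:
            groups[name] = group
            eff = cfg.effects.get(name, 0.0)
            if kind == "continuous":
                shift = float(eff) * cfg.noise_sd
                col = rng.normal(0.0, cfg.noise_sd, size=n)
                col[is_apo] += shift
            else:
                if isinstance(eff, (tuple, list)):
                    p_apo, p_sex = float(eff[0]), float(eff[1])
                else:
                    p_sex = cfg.binary_baseline
                    p_apo = float(np.clip(p_sex + float(eff), 0.0, 1.0))
                p = np.where(is_apo, p_apo, p_sex)
                col = (rng.random(n) < p).astype(int)
            data[name] = col
    return pd.DataFrame(data), groups
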