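"""Fertilization-scenario calculus for the flow-cytometric seed screen.

A mature angiosperm seed carries two tissues whose DNA contents are coupled
through the events of embryo-sac formation and fertilization: the embryo
(egg cell, optionally fertilized by one sperm) and the endosperm (the fused
polar nuclei of the central cell plus zero, one or two sperm cells).  In a
regular sexual diploid both gametes are meiotically reduced, so the embryo is
2C and the endosperm 3C and their fluorescence quotient is 1.5.  Gametophytic
apomixis breaks the coupling: an unreduced, parthenogenetic egg with
autonomous endosperm gives 2C/4C (quotient 2.0); pseudogamy — fertilization of
the endosperm only — with one reduced sperm gives 2C/5C (2.5), with an
unreduced sperm or two reduced sperms 2C/6C (3.0); a tri-nucleate central
cell pushes the endosperm higher still (2/7, 2/8, 2/10); and fertilization of
an unreduced egg produces a ploidy-raising BIII hybrid (e.g. 4x embryo with
6x endosperm).

This module enumerates such scenarios, computes their expected C-values
exactly (as rationals in units of the monoploid genome x), classifies an
observed endosperm:embryo quotient into a reproductive mode, and
back-calculates implied gamete genome sizes when absolute genome sizes (via
an internal standard) are available — choosing the scenario under which every
implied gamete is close to the embryo genome size (unreduced) or half of it
(reduced).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "ScenarioSpec",
    "CValueProfile",
    "ModeCall",
    "GameteSolution",
    "SpeciesSummary",
    "MODE_SEXUAL",
    "MODE_PSEUDOGAMOUS",
    "MODE_AUTONOMOUS",
    "MODE_BIII",
    "MODE_UNRESOLVED",
    "MODE_NO_ENDOSPERM",
    "expected_c_values",
    "enumerate_scenarios",
    "classify_quotient",
    "gamete_backcalc",
    "aggregate_species",
    "parse_label",
    "format_c",
]

MODE_SEXUAL = "sexual"
MODE_PSEUDOGAMOUS = "apomictic_pseudogamous"
MODE_AUTONOMOUS = "apomictic_autonomous"
MODE_BIII = "BIII_hybrid"
MODE_UNRESOLVED = "unresolved"
MODE_NO_ENDOSPERM = "no_endosperm"

# Conservative priority when tied quotients span mode classes (quotient alone
# cannot separate e.g. sexual 2/3 from BIII 4/6, both 1.5; absolute genome
# sizes are needed — see gamete_backcalc).
_MODE_PRIORITY = {
    MODE_SEXUAL: 0,
    MODE_PSEUDOGAMOUS: 1,
    MODE_AUTONOMOUS: 2,
    MODE_BIII: 3,
}


class ScenarioError(ValueError):
    """Raised for an invalid or inconsistent scenario specification."""


def format_c(c: Fraction) -> str:
    """Render a C-value in x units: integers plainly, halves as decimals."""
    if c.denominator == 1:
        return str(c.numerator)
    return str(float(c))


@dataclass(frozen=True)
class ScenarioSpec:
    """One hypothesis about embryo-sac formation and fertilization.

    C-values are expressed in multiples of the monoploid genome x.  The egg
    contributes ``m/2`` if reduced else ``m``; each of the ``k`` polar nuclei
    contributes ``m/2`` or ``m`` likewise; each sperm contributes ``p/2`` or
    ``p`` from a pollen donor of ploidy ``p``.  If the embryo is fertilized it
    receives exactly one sperm of the same C-value as the endosperm sperms.
    """

    maternal_ploidy: int = 2
    egg_reduced: bool = True
    embryo_fertilized: bool = True
    polar_nuclei: int = 2
    polar_reduced: bool = True
    endosperm_sperms: int = 1
    pollen_ploidy: int = 2
    sperm_reduced: bool = True
    # scenarios merged into this one by profile-level deduplication
    equivalents: tuple["ScenarioSpec", ...] = field(
        default=(), compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.maternal_ploidy < 1:
            raise ScenarioError("maternal ploidy must be >= 1")
        if self.polar_nuclei not in (2, 3):
            raise ScenarioError("polar_nuclei must be 2 (normal) or 3 (tri-nucleate)")
        if self.endosperm_sperms not in (0, 1, 2):
            raise ScenarioError("endosperm_sperms must be 0, 1 or 2")
        if (self.embryo_fertilized or self.endosperm_sperms > 0) and self.pollen_ploidy < 1:
            raise ScenarioError("pollen ploidy must be >= 1 when sperm are involved")
        if self.embryo_fertilized and self.egg_reduced and self.endosperm_sperms == 0:
            # a fertilized embryo with autonomous endosperm is not among the
            # modes considered (sexual seeds always carry an endosperm sperm)
            raise ScenarioError(
                "fertilized embryo with autonomous endosperm is not a supported scenario"
            )

    # --- derived C-values (exact rationals of x/2) -------------------------

    @property
    def egg_c(self) -> Fraction:
        m = Fraction(self.maternal_ploidy)
        return m / 2 if self.egg_reduced else m

    @property
    def sperm_c(self) -> Fraction:
        p = Fraction(self.pollen_ploidy)
        return p / 2 if self.sperm_reduced else p

    @property
    def polar_c(self) -> Fraction:
        m = Fraction(self.maternal_ploidy)
        return m / 2 if self.polar_reduced else m

    @property
    def embryo_c(self) -> Fraction:
        c = self.egg_c
        if self.embryo_fertilized:
            c += self.sperm_c
        return c

    @property
    def endosperm_c(self) -> Fraction:
        return self.polar_nuclei * self.polar_c + self.endosperm_sperms * self.sperm_c

    @property
    def quotient(self) -> Fraction:
        return self.endosperm_c / self.embryo_c

    @property
    def label(self) -> str:
        """Embryo-first profile label, e.g. ``"2/5"``."""
        return f"{format_c(self.embryo_c)}/{format_c(self.endosperm_c)}"

    @property
    def mode(self) -> str:
        if self.embryo_fertilized:
            return MODE_SEXUAL if self.egg_reduced else MODE_BIII
        return MODE_AUTONOMOUS if self.endosperm_sperms == 0 else MODE_PSEUDOGAMOUS

    def describe(self) -> str:
        egg = f"{'reduced' if self.egg_reduced else 'unreduced'} egg"
        fert = "fertilized" if self.embryo_fertilized else "parthenogenetic"
        pol = (
            f"{self.polar_nuclei} {'reduced' if self.polar_reduced else 'unreduced'}"
            " polar nuclei"
        )
        if self.endosperm_sperms:
            sp = (
                f"{self.endosperm_sperms} {'reduced' if self.sperm_reduced else 'unreduced'}"
                f" sperm ({self.pollen_ploidy}x pollen)"
            )
        else:
            sp = "autonomous endosperm"
        return f"{self.label} [{self.mode}]: {fert} {egg}; {pol} + {sp}"


@dataclass(frozen=True)
class CValueProfile:
    """Expected embryo and endosperm C-values (x units) and their quotient."""

    embryo_c: Fraction
    endosperm_c: Fraction

    @property
    def quotient(self) -> Fraction:
        return self.endosperm_c / self.embryo_c

    @property
    def label(self) -> str:
        return f"{format_c(self.embryo_c)}/{format_c(self.endosperm_c)}"


def expected_c_values(sc: ScenarioSpec) -> CValueProfile:
    """Compute the expected embryo/endosperm C-value profile of a scenario."""
    profile = CValueProfile(sc.embryo_c, sc.endosperm_c)
    if profile.embryo_c <= 0 or profile.endosperm_c <= 0:
        raise ScenarioError(f"non-positive C-value in scenario {sc!r}")
    return profile


def parse_label(label: str) -> tuple[Fraction, Fraction]:
    """Parse an embryo/endosperm profile label into (embryo_C, endosperm_C).

    Both orders are accepted (the literature writes "2/5" and "5/2" for the
    same seed); the pair is normalized so the embryo is the smaller value,
    which holds for every enumerable scenario with at least two polar nuclei.
    """
    parts = label.strip().split("/")
    if len(parts) != 2:
        raise ScenarioError(f"cannot parse profile label {label!r}")
    try:
        a, b = (Fraction(p.strip()) for p in parts)
    except (ValueError, ZeroDivisionError) as exc:
        raise ScenarioError(f"cannot parse profile label {label!r}") from exc
    if a <= 0 or b <= 0:
        raise ScenarioError(f"non-positive C-value in label {label!r}")
    return (a, b) if a <= b else (b, a)


def enumerate_scenarios(
    maternal_ploidy: int,
    pollen_ploidies: Sequence[int] = (2,),
    *,
    include_trinucleate: bool = False,
    include_biii: bool = False,
    allow_haploid_maternal: bool = False,
) -> list[ScenarioSpec]:
    """Enumerate the candidate scenario set for one maternal cytotype.

    The default set contains sexual double fertilization, apomixis with
    autonomous endosperm, and pseudogamy with one or two reduced or unreduced
    sperms (central cell always from two unreduced polar nuclei in the
    apomictic embryo sac).  ``include_trinucleate`` adds k=3 central-cell
    variants and ``include_biii`` adds fertilization of the unreduced egg;
    both are extensions used only for taxa whose profiles demand them.

    Scenarios whose (embryo_C, endosperm_C, mode) coincide are merged; the
    representative keeps the merged variants in ``equivalents`` so that ties
    such as 2/6 = "one unreduced sperm or two reduced sperms" stay visible.
    """
    if maternal_ploidy < 1:
        raise ScenarioError("maternal ploidy must be >= 1")
    if maternal_ploidy == 1 and not allow_haploid_maternal:
        raise ScenarioError(
            "haploid maternal plants are out of scope by default; "
            "pass allow_haploid_maternal=True to override"
        )
    if not pollen_ploidies:
        raise ScenarioError("pollen_ploidies must be nonempty")

    m = maternal_ploidy
    ks = (2, 3) if include_trinucleate else (2,)
    raw: list[ScenarioSpec] = []

    for p in pollen_ploidies:
        # sexual: reduced gametes throughout, one sperm to each target
        raw.append(
            ScenarioSpec(m, True, True, 2, True, 1, p, True)
        )
    # autonomous: unreduced parthenogenetic egg, unreduced polars, no sperm
    for k in ks:
        raw.append(ScenarioSpec(m, False, False, k, False, 0, 2, True))
    # pseudogamy: unreduced egg, unreduced polars, 1-2 (un)reduced sperms
    for p, k, s, red in itertools.product(pollen_ploidies, ks, (1, 2), (True, False)):
        raw.append(ScenarioSpec(m, False, False, k, False, s, p, red))
    if include_biii:
        # fertilization of the unreduced egg; endosperm receives one sperm of
        # the same kind (2n + n and 2n + 2n hybrids)
        for p, k, red in itertools.product(pollen_ploidies, ks, (True, False)):
            raw.append(ScenarioSpec(m, False, True, k, False, 1, p, red))

    merged: dict[tuple[Fraction, Fraction, str], list[ScenarioSpec]] = {}
    for sc in raw:
        merged.setdefault((sc.embryo_c, sc.endosperm_c, sc.mode), []).append(sc)

    out = []
    for group in merged.values():
        rep = group[0]
        if len(group) > 1:
            rep = ScenarioSpec(
                rep.maternal_ploidy,
                rep.egg_reduced,
                rep.embryo_fertilized,
                rep.polar_nuclei,
                rep.polar_reduced,
                rep.endosperm_sperms,
                rep.pollen_ploidy,
                rep.sperm_reduced,
                equivalents=tuple(group[1:]),
            )
        out.append(rep)
    out.sort(key=lambda sc: (sc.quotient, _MODE_PRIORITY[sc.mode]))
    return out


@dataclass(frozen=True)
class ModeCall:
    """Reproductive-mode assignment for one observed quotient."""

    observed_quotient: float | None
    matched: tuple[ScenarioSpec, ...]
    mode: str
    deviation: float | None
    tolerance: float

    @property
    def label(self) -> str:
        return self.matched[0].label if self.matched else ""


def classify_quotient(
    observed: float,
    scenarios: Sequence[ScenarioSpec],
    rel_tolerance: float = 0.08,
) -> ModeCall:
    """Match an observed endosperm:embryo quotient to the nearest scenario.

    The nearest scenario by relative deviation |obs - exp| / exp wins; all
    scenarios tying for the minimum (including profile-merged equivalents)
    are kept.  If even the nearest deviates by more than ``rel_tolerance``
    the call is ``unresolved`` — aberrant quotients are reported, never
    force-fitted.
    """
    if observed <= 0:
        raise ValueError("observed quotient must be positive")
    if not scenarios:
        raise ValueError("scenario set must be nonempty")

    devs = [abs(observed - float(sc.quotient)) / float(sc.quotient) for sc in scenarios]
    dmin = min(devs)
    if dmin > rel_tolerance:
        return ModeCall(observed, (), MODE_UNRESOLVED, dmin, rel_tolerance)

    matched: list[ScenarioSpec] = []
    for sc, d in zip(scenarios, devs):
        if d <= dmin + 1e-12:
            matched.append(sc)
            matched.extend(sc.equivalents)
    matched.sort(key=lambda sc: _MODE_PRIORITY[sc.mode])
    return ModeCall(observed, tuple(matched), matched[0].mode, dmin, rel_tolerance)


@dataclass(frozen=True)
class GameteSolution:
    """Implied gamete genome sizes under one scenario, with consistency.

    Consistency follows the selection rule for seeds measured with an
    internal standard: the plausible scenario is the one under which every
    implied gamete genome size is close to the embryo genome size (unreduced
    gamete) or half of it (reduced gamete).
    """

    scenario: ScenarioSpec
    implied_sperm_gs: float | None
    implied_polar_sum_gs: float
    consistency: str  # reduced_consistent | unreduced_consistent | inconsistent
    deviation: float
    alternate_labels: tuple[str, ...] = ()

    @property
    def consistent(self) -> bool:
        return self.consistency != "inconsistent"


def _expand(scenarios: Iterable[ScenarioSpec]) -> list[ScenarioSpec]:
    out: list[ScenarioSpec] = []
    for sc in scenarios:
        out.append(sc)
        out.extend(sc.equivalents)
    return out


def gamete_backcalc(
    embryo_gs_pg: float,
    endosperm_gs_pg: float,
    scenarios: Sequence[ScenarioSpec],
    rel_tolerance: float = 0.12,
) -> list[GameteSolution]:
    """Back-calculate gamete genome sizes under each scenario and rank them.

    For a scenario the embryo genome size pins the monoploid genome
    ``g1 = embryo_gs / embryo_C``; each polar nucleus then contributes
    ``polar_C * g1`` and the sperm genome size follows from
    ``endosperm_gs = k * polar_gs + s * sperm_gs``.  The implied sperm is
    classified unreduced if close to the maternal unreduced gamete size
    ``m * g1`` or reduced if close to half of it.  For every parthenogenetic
    scenario ``m * g1`` equals the embryo genome size itself, so this is the
    familiar "close to the embryo genome size or half of it" rule; phrasing
    it via the maternal contribution keeps it correct for fertilized-embryo
    (sexual and BIII) scenarios too.  For autonomous scenarios (s = 0) the
    test is whether the polar nuclei alone account for the endosperm.
    Solutions are sorted by deviation; those tying with the best are
    cross-referenced as alternates.
    """
    if embryo_gs_pg <= 0 or endosperm_gs_pg <= 0:
        raise ValueError("genome sizes must be positive")
    if not scenarios:
        raise ValueError("scenario set must be nonempty")

    sols: list[GameteSolution] = []
    for sc in _expand(scenarios):
        g1 = embryo_gs_pg / float(sc.embryo_c)
        polar_sum = sc.polar_nuclei * float(sc.polar_c) * g1
        s = sc.endosperm_sperms
        if s == 0:
            dev = abs(endosperm_gs_pg - polar_sum) / endosperm_gs_pg
            if dev <= rel_tolerance:
                consistency = (
                    "reduced_consistent" if sc.polar_reduced else "unreduced_consistent"
                )
            else:
                consistency = "inconsistent"
            sols.append(GameteSolution(sc, None, polar_sum, consistency, dev))
            continue
        sperm = (endosperm_gs_pg - polar_sum) / s
        if sperm <= 0:
            sols.append(GameteSolution(sc, sperm, polar_sum, "inconsistent", float("inf")))
            continue
        unred = sc.maternal_ploidy * g1  # = embryo_gs for parthenogenetic embryos
        dev_unred = abs(sperm - unred) / unred
        dev_red = abs(sperm - unred / 2) / (unred / 2)
        if dev_red <= dev_unred:
            dev, consistency = dev_red, "reduced_consistent"
        else:
            dev, consistency = dev_unred, "unreduced_consistent"
        if dev > rel_tolerance:
            consistency = "inconsistent"
        sols.append(GameteSolution(sc, sperm, polar_sum, consistency, dev))

    sols.sort(key=lambda s: s.deviation)
    best = sols[0].deviation
    tied = [s for s in sols if s.consistent and s.deviation <= best + 1e-9]
    if len(tied) > 1:
        labels = {id(s): tuple(t.scenario.label for t in tied if t is not s) for s in tied}
        sols = [
            GameteSolution(
                s.scenario,
                s.implied_sperm_gs,
                s.implied_polar_sum_gs,
                s.consistency,
                s.deviation,
                labels.get(id(s), ()),
            )
            for s in sols
        ]
    return sols


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species aggregation of seed-level mode calls."""

    species: str
    n_seeds: int
    counts: dict[str, int]
    mode: str

    @property
    def n_apomictic(self) -> int:
        return sum(
            self.counts.get(m, 0)
            for m in (MODE_PSEUDOGAMOUS, MODE_AUTONOMOUS, MODE_BIII)
        )

    @property
    def n_sexual(self) -> int:
        return self.counts.get(MODE_SEXUAL, 0)


def aggregate_species(species: str, calls: Sequence[ModeCall]) -> SpeciesSummary:
    """Summarize seed calls for one species.

    A species is apomictic if at least one seed is apomictic, facultatively
    apomictic if sexual and apomictic seeds co-occur (a single apomictic seed
    among twenty sexual ones is real signal, not noise), and excluded from
    mode inference when no seed shows an endosperm peak.
    """
    if not calls:
        raise ValueError("at least one seed call is required")
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.mode] = counts.get(c.mode, 0) + 1

    n_apo = sum(counts.get(m, 0) for m in (MODE_PSEUDOGAMOUS, MODE_AUTONOMOUS, MODE_BIII))
    n_sex = counts.get(MODE_SEXUAL, 0)
    if counts.get(MODE_NO_ENDOSPERM, 0) == len(calls):
        mode = MODE_NO_ENDOSPERM
    elif n_apo and n_sex:
        mode = "facultative_apomict"
    elif n_apo:
        mode = "apomictic"
    elif n_sex:
        mode = MODE_SEXUAL
    else:
        mode = MODE_UNRESOLVED
    return SpeciesSummary(species, len(calls), counts, mode)
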