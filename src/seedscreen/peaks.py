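"""G0/G1 peak detection and embryo/endosperm role assignment.

A seed-screen histogram typically shows, from low to high fluorescence: an
exponential debris slope, the embryo G0/G1 peak (the most nucleus-rich), the
endosperm G0/G1 peak at the scenario-determined quotient above it, small G2 /
endoreduplication replicate peaks at twice each G1 position, and optionally
an internal-standard peak.  For each detected local maximum we record the
mean fluorescence, coefficient of variation and nuclei count from a window
of ±2.5 estimated sigma, then assign tissue roles.

Two subtleties from real seed material are handled explicitly:

* replicate peaks — a peak sitting at ≈2x a lower peak with a small fraction
  of its count is treated as a G2/endoreduplication replicate and excluded
  from endosperm candidacy;
* strong endopolyploidy — in taxa whose endosperm G1 peak is depleted, the
  second (2C-replicate) endosperm peak is measured instead and its mean
  halved.  Because quotient geometry alone cannot distinguish this situation
  from a genuinely higher endosperm C-value, the rule is opt-in per sample
  set, as in practice where it is applied from prior knowledge of the taxon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io import HistogramData

__all__ = [
    "PeakStats",
    "SeedMeasurement",
    "PeakDetectParams",
    "RoleParams",
    "NoPeaksDetected",
    "detect_peaks",
    "assign_roles",
    "endosperm_percentage",
    "relative_genome_size",
]

log = logging.getLogger(__name__)

ROLE_UNASSIGNED = "unassigned"
ROLE_EMBRYO = "embryo_G1"
ROLE_EMBRYO_G2 = "embryo_G2"
ROLE_ENDOSPERM = "endosperm_G1"
ROLE_ENDOSPERM_SECOND = "endosperm_second"
ROLE_STANDARD = "standard"


class NoPeaksDetected(RuntimeError):
    """No local maximum rose above the prominence floor."""


@dataclass
class PeakStats:
    """Summary statistics of one G0/G1 (or replicate) peak."""

    mean_fluorescence: float
    cv_percent: float
    nuclei_count: int
    role: str = ROLE_UNASSIGNED
    cv_flagged: bool = False

    def __post_init__(self) -> None:
        if self.mean_fluorescence <= 0:
            raise ValueError("mean_fluorescence must be positive")
        if self.nuclei_count < 1:
            raise ValueError("nuclei_count must be >= 1")


@dataclass
class SeedMeasurement:
    """Embryo/endosperm readout for one seed sample.

    ``endosperm_effective_mean`` is the G1-equivalent endosperm fluorescence
    (the measured second-peak mean divided by two when the endopolyploidy
    rule fired).  When no endosperm candidate exists the endosperm fields are
    None and downstream classification yields ``no_endosperm``.
    """

    embryo: PeakStats
    endosperm_effective_mean: float | None = None
    endosperm_counts: int | None = None
    used_second_peak: bool = False
    standard: PeakStats | None = None
    embryo_relative_gs: float | None = None
    endosperm_relative_gs: float | None = None

    @property
    def has_endosperm(self) -> bool:
        return self.endosperm_effective_mean is not None

    @property
    def quotient(self) -> float | None:
        if not self.has_endosperm:
            return None
        return self.endosperm_effective_mean / self.embryo.mean_fluorescence

    @property
    def endosperm_percent(self) -> float | None:
        if not self.has_endosperm:
            return None
        return endosperm_percentage(self.embryo.nuclei_count, self.endosperm_counts)


@dataclass
class PeakDetectParams:
    """Tunables for automatic peak finding.

    ``min_particles`` is a soft gate (warn, don't fail) because weak samples
    — e.g. old herbarium seed — can still carry usable peaks.  ``max_cv``
    flags peaks too broad to trust rather than discarding them.
    """

    min_particles: int = 5000
    smooth_width: int = 5
    prominence_fraction: float = 0.015  # of the smoothed maximum
    window_sigmas: float = 2.5
    max_cv: float = 8.0
    min_peak_count: int = 20


@dataclass
class RoleParams:
    """Tunables for embryo/endosperm role assignment."""

    valid_quotient_range: tuple[float, float] = (1.2, 6.0)
    # replicate suppression: a peak at ~2x a lower one with < this count
    # fraction is a G2/endoreduplication artifact, not an endosperm G1
    replicate_position_tol: float = 0.06
    replicate_count_ratio: float = 0.25
    # endopolyploid second-endosperm-peak rule (opt-in)
    second_peak_rule: bool = False
    second_peak_expected_quotients: tuple[float, ...] = (1.5,)
    second_peak_position_tol: float = 0.08
    # internal standard, located by an approximate channel window
    standard_window: tuple[float, float] | None = None


def detect_peaks(h: HistogramData, params: PeakDetectParams | None = None) -> list[PeakStats]:
    """Detect G0/G1-type peaks and compute their statistics.

    The histogram is smoothed with a short moving average, local maxima above
    a relative prominence floor are found, and each peak's mean, CV and
    nuclei count are computed by weighted moments of the *raw* counts inside
    ±``window_sigmas`` estimated sigma (iterated once so the window tracks
    the moment estimate).  Peaks are returned sorted by position.
    """
    params = params or PeakDetectParams()
    counts = h.counts.astype(float)
    total = counts.sum()
    if total < params.min_particles:
        warnings.warn(
            f"sample {h.sample_id or '<unnamed>'}: only {int(total)} particles "
            f"recorded (< {params.min_particles}); peak statistics may be weak",
            stacklevel=2,
        )

    w = max(1, int(params.smooth_width))
    # nearest-edge padding keeps a flat histogram flat (no spurious plateau)
    smoothed = ndimage.uniform_filter1d(counts, size=w, mode="nearest")

    floor = params.prominence_fraction * smoothed.max()
    idx, props = signal.find_peaks(smoothed, prominence=floor, distance=max(2, w))
    if idx.size == 0:
        raise NoPeaksDetected(
            f"sample {h.sample_id or '<unnamed>'}: no peak above the prominence floor"
        )

    channels = h.channels
    widths, _, _, _ = signal.peak_widths(smoothed, idx, rel_height=0.5)
    # channel spacing may be non-unit
    dch = float(np.median(np.diff(channels))) if channels.size > 1 else 1.0

    peaks: list[PeakStats] = []
    for i, fwhm_bins in zip(idx, widths):
        sigma = max(fwhm_bins * dch / 2.3548, dch / 2)
        mean = channels[i]
        for _ in range(2):
            lo, hi = mean - params.window_sigmas * sigma, mean + params.window_sigmas * sigma
            mask = (channels >= lo) & (channels <= hi)
            wsum = counts[mask].sum()
            if wsum <= 0:
                break
            mean = float(np.average(channels[mask], weights=counts[mask]))
            var = float(np.average((channels[mask] - mean) ** 2, weights=counts[mask]))
            sigma = max(np.sqrt(var), dch / 2)
        if wsum < params.min_peak_count or mean <= 0:
            continue
        cv = 100.0 * sigma / mean
        peaks.append(
            PeakStats(mean, cv, int(round(wsum)), cv_flagged=cv > params.max_cv)
        )

    if not peaks:
        raise NoPeaksDetected(
            f"sample {h.sample_id or '<unnamed>'}: no peak passed the statistics filters"
        )
    peaks.sort(key=lambda p: p.mean_fluorescence)
    return peaks


def _is_replicate(p: PeakStats, others: list[PeakStats], rp: RoleParams) -> bool:
    for q in others:
        if q is p or q.mean_fluorescence >= p.mean_fluorescence:
            continue
        expected = 2.0 * q.mean_fluorescence
        if (
            abs(p.mean_fluorescence - expected) / expected <= rp.replicate_position_tol
            and p.nuclei_count < rp.replicate_count_ratio * q.nuclei_count
        ):
            return True
    return False


def assign_roles(
    peaks: list[PeakStats],
    h: HistogramData | None = None,
    params: RoleParams | None = None,
) -> SeedMeasurement:
    """Assign embryo / endosperm / standard roles to detected peaks.

    The embryo is the most nucleus-rich non-standard peak (count ties broken
    toward the lower position, logged).  Endosperm candidates are the
    remaining non-replicate peaks whose quotient over the embryo falls in
    ``valid_quotient_range``; the most nucleus-rich candidate wins.  With the
    endopolyploidy rule enabled, a candidate parked at twice an expected
    endosperm position — with nothing at the expected G1 position itself —
    is recorded as the second endosperm peak and its mean halved.
    """
    params = params or RoleParams()
    if not peaks:
        raise ValueError("no peaks to assign")
    peaks = sorted(peaks, key=lambda p: p.mean_fluorescence)

    standard: PeakStats | None = None
    working = list(peaks)
    if params.standard_window is not None:
        lo, hi = params.standard_window
        in_win = [p for p in working if lo <= p.mean_fluorescence <= hi]
        if in_win:
            standard = max(in_win, key=lambda p: p.nuclei_count)
            standard.role = ROLE_STANDARD
            working = [p for p in working if p is not standard]
    if not working:
        raise ValueError("all detected peaks fell in the standard window")

    top = max(p.nuclei_count for p in working)
    embryo_cands = [p for p in working if p.nuclei_count == top]
    if len(embryo_cands) > 1:
        log.info(
            "embryo tie between %d equal-count peaks; choosing the lower position",
            len(embryo_cands),
        )
    embryo = min(embryo_cands, key=lambda p: p.mean_fluorescence)
    embryo.role = ROLE_EMBRYO

    others = [p for p in working if p is not embryo]
    qlo, qhi = params.valid_quotient_range
    candidates = []
    for p in others:
        q = p.mean_fluorescence / embryo.mean_fluorescence
        if q < qlo or q > qhi:
            continue
        if _is_replicate(p, working, params):
            if abs(q - 2.0) < 1e-9:
                p.role = ROLE_EMBRYO_G2
            continue
        candidates.append(p)

    def _finish(endo: PeakStats | None, eff_mean, used_second: bool) -> SeedMeasurement:
        m = SeedMeasurement(
            embryo,
            endosperm_effective_mean=eff_mean,
            endosperm_counts=endo.nuclei_count if endo else None,
            used_second_peak=used_second,
            standard=standard,
        )
        if standard is not None and h is not None and h.standard_2c_pg:
            m.embryo_relative_gs = relative_genome_size(
                embryo.mean_fluorescence, standard.mean_fluorescence, h.standard_2c_pg
            )
            if eff_mean is not None:
                m.endosperm_relative_gs = relative_genome_size(
                    eff_mean, standard.mean_fluorescence, h.standard_2c_pg
                )
        return m

    if not candidates:
        if params.second_peak_rule:
            hit = _second_peak_candidate(others, embryo, working, params)
            if hit is not None:
                hit.role = ROLE_ENDOSPERM_SECOND
                log.info(
                    "endopolyploidy rule: using second endosperm peak at %.1f, mean halved",
                    hit.mean_fluorescence,
                )
                return _finish(hit, hit.mean_fluorescence / 2.0, True)
        return _finish(None, None, False)

    endosperm = max(candidates, key=lambda p: (p.nuclei_count, -p.mean_fluorescence))
    if params.second_peak_rule:
        q = endosperm.mean_fluorescence / embryo.mean_fluorescence
        if _matches_doubled_expectation(q, working, embryo, params):
            endosperm.role = ROLE_ENDOSPERM_SECOND
            log.info(
                "endopolyploidy rule: peak at %.1f read as the second endosperm peak",
                endosperm.mean_fluorescence,
            )
            return _finish(endosperm, endosperm.mean_fluorescence / 2.0, True)
    endosperm.role = ROLE_ENDOSPERM
    return _finish(endosperm, endosperm.mean_fluorescence, False)


def _matches_doubled_expectation(
    q: float, working: list[PeakStats], embryo: PeakStats, params: RoleParams
) -> bool:
    tol = params.second_peak_position_tol
    for e in params.second_peak_expected_quotients:
        if abs(q / 2.0 - e) / e > tol:
            continue
        # fire only if the expected G1 endosperm position itself is empty
        g1_present = any(
            p is not embryo
            and abs(p.mean_fluorescence / embryo.mean_fluorescence - e) / e <= tol
            for p in working
        )
        if not g1_present:
            return True
    return False


def _second_peak_candidate(
    others: list[PeakStats],
    embryo: PeakStats,
    working: list[PeakStats],
    params: RoleParams,
) -> PeakStats | None:
    hits = [
        p
        for p in others
        if _matches_doubled_expectation(
            p.mean_fluorescence / embryo.mean_fluorescence, working, embryo, params
        )
    ]
    if not hits:
        return None
    return max(hits, key=lambda p: p.nuclei_count)


def endosperm_percentage(embryo_count: int, endosperm_count: int) -> float:
    """Percent of seed nuclei attributed to the endosperm peak.

    100 x endosperm / (embryo + endosperm); scale-invariant in the counts.
    """
    if embryo_count < 0 or endosperm_count < 0:
        raise ValueError("counts must be non-negative")
    total = embryo_count + endosperm_count
    if total == 0:
        raise ValueError("embryo and endosperm counts are both zero")
    return 100.0 * endosperm_count / total


def relative_genome_size(peak_mean: float, standard_mean: float, standard_2c_pg: float) -> float:
    """Convert a peak's fluorescence to picograms via the internal standard.

    Linear fluorescence is assumed, so genome size = peak/standard x the
    standard's 2C value (e.g. Pisum sativum 'Ctirad' 9.09 pg, Bellis perennis
    3.38 pg).
    """
    if peak_mean <= 0 or standard_mean <= 0:
        raise ValueError("fluorescence means must be positive")
    if standard_2c_pg is None or standard_2c_pg <= 0:
        raise ValueError(
            "internal-standard 2C value missing or non-positive; "
            "without a standard only fluorescence ratios are available"
        )
    return peak_mean / standard_mean * standard_2c_pg
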