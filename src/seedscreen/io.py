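"""Reading and writing seed-screen fluorescence histograms.

The on-disk format is deliberately plain: a two-column delimited text file
(channel, count) per sample, with an optional ``<name>.meta`` sidecar of
``key: value`` lines carrying sample metadata (species, seeds pooled,
preparation protocol, internal standard).  Histograms exported from cytometer
software as channel/count tables load directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["HistogramData", "HistogramParseError", "read_histogram", "write_histogram"]

PROTOCOLS = ("seed_buffer", "two_step_otto")


class HistogramParseError(ValueError):
    """Malformed histogram file; carries the offending line number."""


@dataclass
class HistogramData:
    """One sample's binned fluorescence distribution plus metadata.

    ``channels`` are bin centers on a linear fluorescence axis (arbitrary
    units) and must be strictly increasing; ``counts`` are non-negative
    particle counts per bin.
    """

    channels: np.ndarray
    counts: np.ndarray
    sample_id: str = ""
    species: str = ""
    seeds_pooled: int = 1
    protocol: str = "seed_buffer"
    standard_species: str | None = None
    standard_2c_pg: float | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise ValueError("channels and counts must be 1-D arrays of equal length")
        if self.channels.size and np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("histogram must contain at least one particle")
        if self.seeds_pooled < 1:
            raise ValueError("seeds_pooled must be >= 1")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.standard_2c_pg is not None and self.standard_2c_pg <= 0:
            raise ValueError("standard_2c_pg must be positive")

    @property
    def total_particles(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "HistogramData":
        return replace(self, channels=self.channels.copy(), counts=self.counts.copy())


_META_FIELDS = {
    "sample_id": str,
    "species": str,
    "seeds_pooled": int,
    "protocol": str,
    "standard_species": str,
    "standard_2c_pg": float,
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def read_histogram(path: str | Path, **metadata) -> HistogramData:
    """Read a two-column (channel, count) text histogram.

    Metadata is taken from the ``.meta`` sidecar if present, then overridden
    by keyword arguments.  Comment lines start with ``#``; columns may be
    separated by whitespace, commas or tabs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channels: list[float] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise HistogramParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                ch = float(parts[0])
                ct = float(parts[1])
            except ValueError as exc:
                raise HistogramParseError(f"{path}:{lineno}: non-numeric value") from exc
            if ct < 0:
                raise HistogramParseError(f"{path}:{lineno}: negative count {ct}")
            channels.append(ch)
            counts.append(int(round(ct)))
    if not channels:
        raise HistogramParseError(f"{path}: no data rows")

    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        for raw in sidecar.read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#") or ":" not in raw:
                continue
            key, _, val = raw.partition(":")
            key, val = key.strip(), val.strip()
            if key in _META_FIELDS and val:
                meta[key] = _META_FIELDS[key](val)
    meta.update(metadata)
    if "sample_id" not in meta:
        meta["sample_id"] = path.stem
    return HistogramData(np.array(channels), np.array(counts), **meta)


def write_histogram(h: HistogramData, path: str | Path) -> Path:
    """Write a histogram plus its metadata sidecar; returns the data path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# channel\tcount\n")
        for ch, ct in zip(h.channels, h.counts):
            fh.write(f"{ch:g}\t{int(ct)}\n")
    lines = [f"sample_id: {h.sample_id}", f"species: {h.species}",
             f"seeds_pooled: {h.seeds_pooled}", f"protocol: {h.protocol}"]
    if h.standard_species:
        lines.append(f"standard_species: {h.standard_species}")
    if h.standard_2c_pg:
        lines.append(f"standard_2c_pg: {h.standard_2c_pg}")
    _sidecar(path).write_text("\n".join(lines) + "\n")
    return path
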