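"""Coverage tracks: bedGraph I/O, smoothing, anchored windows, enrichment.

This module is the shared signal substrate.  A :class:`CoverageTrack` holds
per-chromosome arrays of non-negative values at 1-nt resolution together
with the sample metadata (factor, genotype, temperature, replicate).  All
genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit
from .errors import TrackIOError, ValidationError

#: canonical factor labels understood by the simulator and pipeline
FACTORS = (
    "PolII_total",
    "PolII_Ser2P",
    "PolII_Ser5P",
    "Nrd1",
    "Pcf11",
    "RNADNA_hybrid",
    "other",
)


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval; strand optional."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base occupancy signal for one sample."""

    factor: str
    genotype: str
    temperature: int
    data: dict[str, np.ndarray]
    replicate: int = 1

    def __post_init__(self) -> None:
        for chrom, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"track {self.label}: non-finite values on {chrom}")
            if np.any(arr < 0):
                raise ValidationError(f"track {self.label}: negative values on {chrom}")
            self.data[chrom] = arr

    @property
    def label(self) -> str:
        return f"{self.factor}_{self.genotype}_{self.temperature}C_r{self.replicate}"

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def mean(self) -> float:
        """Genome-wide mean signal (length-weighted across chromosomes)."""
        total = sum(float(v.sum()) for v in self.data.values())
        length = sum(len(v) for v in self.data.values())
        return total / length if length else 0.0

    def scaled(self, k: float) -> "CoverageTrack":
        if k <= 0:
            raise ValidationError("scale factor must be > 0")
        return replace(self, data={c: v * k for c, v in self.data.items()})

    def normalized(self) -> "CoverageTrack":
        """Total-signal normalization: scale so the genome-wide mean is 1."""
        m = self.mean()
        if m == 0:
            return replace(self, data={c: v.copy() for c, v in self.data.items()})
        return self.scaled(1.0 / m)


# -- bedGraph ---------------------------------------------------------------


def read_bedgraph(
    path: str | Path,
    chrom_sizes: dict[str, int],
    factor: str = "other",
    genotype: str = "NA",
    temperature: int = 25,
    replicate: int = 1,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base track.

    Bases not covered by any interval are 0.  Overlapping intervals are an
    error when their values conflict.
    """
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    assigned = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    except OSError as exc:
        raise TrackIOError(f"cannot read bedGraph {path}: {exc}") from exc
    frame = frame[~frame["chrom"].str.startswith(("track", "browser"))]
    for row in frame.itertuples(index=False):
        chrom, start, end, value = row.chrom, int(row.start), int(row.end), float(row.value)
        if chrom not in data:
            raise TrackIOError(f"{path}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= chrom_sizes[chrom]):
            raise TrackIOError(f"{path}: interval {chrom}:{start}-{end} out of bounds")
        clash = assigned[chrom][start:end] & (data[chrom][start:end] != value)
        if clash.any():
            raise TrackIOError(
                f"{path}: overlapping intervals with conflicting values at "
                f"{chrom}:{start + int(np.flatnonzero(clash)[0])}"
            )
        data[chrom][start:end] = value
        assigned[chrom][start:end] = True
    return CoverageTrack(
        factor=factor, genotype=genotype, temperature=temperature,
        replicate=replicate, data=data,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted).

    Values are formatted with 17 significant digits so write->read is an
    identity on float64 arrays.
    """
    try:
        with open(path, "w") as fh:
            for chrom in track.data:
                values = track.data[chrom]
                if len(values) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(values)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(values)]))
                for s, e in zip(starts, ends):
                    v = values[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
    except OSError as exc:
        raise TrackIOError(f"cannot write bedGraph {path}: {exc}") from exc


# -- smoothing --------------------------------------------------------------


def moving_average(values: np.ndarray, window: int = 220) -> np.ndarray:
    """Centred moving average with shrink-to-fit (truncated) edges.

    Position ``i`` is averaged over ``[i - (window-1)//2, i + window//2]``
    clipped to the array; the divisor is the number of positions actually
    covered, so edges stay defined and constants are fixed points.
    """
    if window < 1:
        raise ValidationError(f"smoothing window must be >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0 or window == 1:
        return values.copy()
    cs = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.clip(idx - (window - 1) // 2, 0, n)
    hi = np.clip(idx + window // 2 + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


# -- anchored extraction ----------------------------------------------------


class AnchoredVector(NamedTuple):
    """Signal around an anchor, ordered 5'->3' in transcript orientation."""

    positions: np.ndarray  #: relative start of each bin; 0 = anchor base
    values: np.ndarray  #: mean signal per bin (NaN where fully masked)
    mask: np.ndarray  #: True where the bin contains at least one valid base


def anchored_vector(
    track: CoverageTrack,
    unit: TranscriptionUnit,
    upstream: int,
    downstream: int,
    bin: int = 1,
    anchor_kind: Optional[str] = None,
) -> AnchoredVector:
    """Extract signal over ``[-upstream, downstream)`` around a unit anchor.

    Relative position 0 is the anchor base itself; positive positions are
    3' of the anchor in transcript orientation (so the vector is reversed
    on - strand units).  Positions beyond chromosome ends are masked.
    """
    if bin < 1 or (upstream + downstream) % bin != 0:
        raise ValidationError(
            f"bin ({bin}) must be >= 1 and divide upstream+downstream "
            f"({upstream + downstream})"
        )
    if unit.chrom not in track.data:
        raise ValidationError(f"unit {unit.id!r}: chromosome {unit.chrom!r} not in track")
    anchor = unit.anchor(anchor_kind)
    rel = np.arange(-upstream, downstream)
    genomic = anchor + rel if unit.strand == "+" else anchor - rel
    chrom_values = track.data[unit.chrom]
    valid = (genomic >= 0) & (genomic < len(chrom_values))
    raw = np.full(len(rel), np.nan)
    raw[valid] = chrom_values[genomic[valid]]

    nbins = (upstream + downstream) // bin
    per_bin = raw.reshape(nbins, bin)
    valid_bins = valid.reshape(nbins, bin)
    counts = valid_bins.sum(axis=1)
    mask = counts > 0
    with np.errstate(invalid="ignore"):
        values = np.where(mask, np.nansum(per_bin, axis=1) / np.maximum(counts, 1), np.nan)
    positions = np.arange(-upstream, downstream, bin)
    return AnchoredVector(positions=positions, values=values, mask=mask)


# -- region statistics ------------------------------------------------------


def region_mean(track: CoverageTrack, region: GenomicRegion) -> float:
    """Arithmetic mean of per-base values over a region."""
    if region.chrom not in track.data:
        raise ValidationError(f"chromosome {region.chrom!r} not in track")
    values = track.data[region.chrom]
    if region.end > len(values):
        raise ValidationError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {len(values)}"
        )
    return float(values[region.start:region.end].mean())


class FoldEnrichment(NamedTuple):
    ratio: float
    pseudocount: float


DEFAULT_PSEUDOCOUNT_FRACTION = 1e-6


def fold_enrichment(
    track: CoverageTrack,
    region: GenomicRegion,
    background_region: GenomicRegion,
    pseudocount: Optional[float] = None,
) -> FoldEnrichment:
    """Ratio of a query region's mean to a background region's mean.

    The default pseudocount is 1e-6 of the genome-wide track mean, which
    makes the ratio invariant under global track scaling.
    """
    if pseudocount is None:
        pseudocount = DEFAULT_PSEUDOCOUNT_FRACTION * track.mean()
    bg = max(region_mean(track, background_region), pseudocount)
    if bg == 0:
        raise ValidationError(
            "background mean is zero and pseudocount is zero; cannot form ratio"
        )
    return FoldEnrichment(ratio=region_mean(track, region) / bg, pseudocount=pseudocount)
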