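"""Amplicon-level ChIP/DIP quantification.

Mirrors bench-style readouts: fold enrichment of query amplicons over one
background amplicon (per replicate, then averaged), normalization of
phospho-CTD signals to total Pol II, and time-course amplicon ratios.
RNA:DNA-hybrid (DIP) tracks are handled identically to ChIP tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .tracks_io import CoverageTrack, GenomicRegion, fold_enrichment, region_mean


@dataclass(frozen=True)
class Amplicon:
    id: str
    region: GenomicRegion
    role: str = "query"  # "query" | "background"

    def __post_init__(self) -> None:
        if self.role not in ("query", "background"):
            raise ValidationError(f"amplicon {self.id!r}: role must be query or background")


@dataclass
class AmpliconQuant:
    amplicon_id: str
    enrichments: list[float]  #: per-replicate fold enrichments
    mean: float
    sd: float  #: sample SD (n-1); 0 by convention when n == 1
    n: int

    @property
    def single_replicate(self) -> bool:
        return self.n == 1


def _background(panel: Sequence[Amplicon]) -> Amplicon:
    background = [a for a in panel if a.role == "background"]
    if len(background) != 1:
        raise ValidationError(
            f"panel must contain exactly one background amplicon, found {len(background)}"
        )
    return background[0]


def amplicon_quant(
    tracks: Sequence[CoverageTrack],
    panel: Sequence[Amplicon],
    pseudocount: Optional[float] = None,
) -> list[AmpliconQuant]:
    """Fold enrichment per query amplicon, ratio-per-replicate then averaged.

    Ratios are formed within each replicate before aggregation (mean of fold
    enrichments, not fold enrichment of means), so unequal backgrounds
    between replicates cannot bias the average.
    """
    if not tracks:
        raise ValidationError("amplicon_quant requires at least one replicate track")
    background = _background(panel)
    out = []
    for amp in panel:
        if amp.role != "query":
            continue
        ratios = [
            fold_enrichment(t, amp.region, background.region, pseudocount).ratio
            for t in tracks
        ]
        n = len(ratios)
        mean = sum(ratios) / n
        sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1)) if n > 1 else 0.0
        out.append(AmpliconQuant(amplicon_id=amp.id, enrichments=ratios, mean=mean, sd=sd, n=n))
    return out


class NormalizedRatio(NamedTuple):
    amplicon_id: str
    ratio: float
    sd: float  #: propagated in quadrature from the replicate SDs
    reliable: bool


def phospho_normalize(
    phospho: Sequence[AmpliconQuant],
    total: Sequence[AmpliconQuant],
    floor: float = 1e-9,
) -> list[NormalizedRatio]:
    """Normalize phospho-CTD enrichments to total Pol II, amplicon by amplicon."""
    totals = {q.amplicon_id: q for q in total}
    if set(q.amplicon_id for q in phospho) != set(totals):
        raise ValidationError("phospho and total panels cover different amplicons")
    out = []
    for p in phospho:
        t = totals[p.amplicon_id]
        reliable = t.mean > floor
        denom = max(t.mean, floor)
        ratio = p.mean / denom
        rel_var = 0.0
        if p.mean > 0:
            rel_var += (p.sd / p.mean) ** 2
        if t.mean > floor:
            rel_var += (t.sd / t.mean) ** 2
        out.append(
            NormalizedRatio(
                amplicon_id=p.amplicon_id,
                ratio=ratio,
                sd=abs(ratio) * math.sqrt(rel_var),
                reliable=reliable,
            )
        )
    return out


def kinetics_ratio(
    timecourse: Sequence[tuple[float, CoverageTrack]],
    amp_a: Amplicon,
    amp_b: Amplicon,
    pseudocount: float = 1e-9,
) -> list[tuple[float, float]]:
    """Ratio of mean signal over amplicon A to amplicon B at each time point."""
    if len(timecourse) < 2:
        raise ValidationError("kinetics_ratio requires at least two time points")
    times = [t for t, _ in timecourse]
    if len(set(times)) != len(times):
        raise ValidationError(f"duplicate time labels in time course: {sorted(times)}")
    series = []
    for time, track in sorted(timecourse, key=lambda pair: pair[0]):
        a = region_mean(track, amp_a.region)
        b = region_mean(track, amp_b.region)
        series.append((float(time), max(a, pseudocount) / max(b, pseudocount)))
    return series


def quant_to_frame(quants: Sequence[AmpliconQuant]) -> pd.DataFrame:
    """TSV-ready export with replicate columns preserved."""
    n_max = max((q.n for q in quants), default=0)
    rows = []
    for q in quants:
        row = {"amplicon_id": q.amplicon_id, "mean": q.mean, "sd": q.sd, "n": q.n}
        for i in range(n_max):
            row[f"rep{i + 1}"] = q.enrichments[i] if i < q.n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
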