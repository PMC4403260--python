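"""Readthrough-index classification of termination-defective units.

For a mutant-vs-WT contrast each unit gets a readthrough index

    RI = (D_mut / R_mut) / (D_wt / R_wt)

where D is the mean smoothed signal in a window downstream of the unit's
terminator anchor and R the mean over an upstream reference window (the
unit body by default).  The ratio-of-ratios cancels expression differences
between strains; pseudocounts guard empty windows.  Units whose WT
reference signal is too low are flagged and excluded from all fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit
from .errors import ValidationError
from .tracks_io import (
    DEFAULT_PSEUDOCOUNT_FRACTION,
    CoverageTrack,
    anchored_vector,
    moving_average,
)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windows for one unit class, relative to the terminator anchor.

    ``reference`` of None means "from the unit 5' end to the anchor".
    ``clip_to_unit_end`` truncates the downstream window at the annotated 3'
    end (used for NAPC attenuation windows inside genes).
    """

    anchor_kind: str
    downstream: tuple[int, int]
    reference: Optional[tuple[int, int]] = None
    clip_to_unit_end: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.downstream
        if lo >= hi:
            raise ValidationError(f"downstream window [{lo}, {hi}) is empty")
        if self.reference is not None:
            rlo, rhi = self.reference
            if rlo >= rhi:
                raise ValidationError(f"reference window [{rlo}, {rhi}) is empty")
            if rhi > lo:
                raise ValidationError("downstream window must lie 3' of the reference window")


#: default contrast windows per unit class
DEFAULT_WINDOWS: dict[str, WindowSpec] = {
    "snoRNA": WindowSpec(anchor_kind="mature_3p_end", downstream=(150, 650)),
    "CUT": WindowSpec(anchor_kind="annotated_3p_end", downstream=(100, 600)),
    "SUT": WindowSpec(anchor_kind="annotated_3p_end", downstream=(100, 600)),
    "XUT": WindowSpec(anchor_kind="annotated_3p_end", downstream=(100, 600)),
    "NAPC": WindowSpec(anchor_kind="nbs", downstream=(100, 600), clip_to_unit_end=True),
    "PC": WindowSpec(anchor_kind="annotated_3p_end", downstream=(100, 600)),
}

PATHWAY_CATEGORIES = ("CID-only", "cleavage-only", "both", "neither")


@dataclass
class ReadthroughCall:
    """Per-unit readthrough quantification for one contrast."""

    unit_id: str
    unit_class: str
    contrast: str
    ref_wt: float
    ref_mut: float
    down_wt: float
    down_mut: float
    readthrough_index: float  #: NaN when low_signal
    low_signal: bool = False
    is_defective: bool = False


def _window_means(
    track: CoverageTrack,
    unit: TranscriptionUnit,
    spec: WindowSpec,
    smooth: int,
) -> tuple[float, float]:
    """Mean smoothed signal over the reference and downstream windows."""
    anchor = unit.anchor(spec.anchor_kind)
    anchor_rel = unit.transcript_offset(anchor)  # nt from TSS to anchor
    if spec.reference is not None:
        ref_lo, ref_hi = spec.reference
    else:
        ref_lo, ref_hi = -anchor_rel, 0  # unit 5' end .. anchor
        if ref_lo >= ref_hi:
            ref_lo = ref_hi - 1
    down_lo, down_hi = spec.downstream
    if spec.clip_to_unit_end:
        end_rel = unit.transcript_offset(unit.anchor("annotated_3p_end")) - anchor_rel
        down_hi = min(down_hi, max(end_rel, down_lo + 1))
    margin = smooth  # extraction margin so edge truncation stays clear of windows
    lo, hi = ref_lo - margin, down_hi + margin
    vec = anchored_vector(track, unit, upstream=-lo if lo < 0 else 0,
                          downstream=max(hi, 1), bin=1, anchor_kind=spec.anchor_kind)
    smoothed = moving_average(np.where(vec.mask, vec.values, 0.0), smooth)
    pos = vec.positions

    def mean_over(a: int, b: int) -> float:
        sel = (pos >= a) & (pos < b)
        if not sel.any():
            raise ValidationError(
                f"unit {unit.id!r}: window [{a}, {b}) outside extracted range"
            )
        return float(smoothed[sel].mean())

    return mean_over(ref_lo, ref_hi), mean_over(down_lo, down_hi)


def readthrough_index(
    wt: CoverageTrack,
    mut: CoverageTrack,
    unit: TranscriptionUnit,
    windows: Mapping[str, WindowSpec] = DEFAULT_WINDOWS,
    smooth: int = 220,
    pseudocount: Optional[float] = None,
) -> ReadthroughCall:
    """Compute the readthrough index for one unit in a mutant-vs-WT contrast."""
    if wt.temperature != mut.temperature:
        raise ValidationError(
            f"contrast mixes temperatures: WT {wt.temperature}C vs mutant {mut.temperature}C"
        )
    spec = windows.get(unit.unit_class)
    if spec is None:
        raise ValidationError(f"no window spec for class {unit.unit_class!r}")
    ref_wt, down_wt = _window_means(wt, unit, spec, smooth)
    ref_mut, down_mut = _window_means(mut, unit, spec, smooth)
    if pseudocount is None:
        pseudocount = DEFAULT_PSEUDOCOUNT_FRACTION * max(wt.mean(), mut.mean())
        if pseudocount == 0:
            pseudocount = 1e-9
    contrast = f"{mut.genotype}_vs_{wt.genotype}_{mut.temperature}C"
    if ref_wt < pseudocount and ref_mut < pseudocount:
        return ReadthroughCall(
            unit_id=unit.id, unit_class=unit.unit_class, contrast=contrast,
            ref_wt=ref_wt, ref_mut=ref_mut, down_wt=down_wt, down_mut=down_mut,
            readthrough_index=float("nan"), low_signal=True,
        )
    ratio_mut = max(down_mut, pseudocount) / max(ref_mut, pseudocount)
    ratio_wt = max(down_wt, pseudocount) / max(ref_wt, pseudocount)
    return ReadthroughCall(
        unit_id=unit.id, unit_class=unit.unit_class, contrast=contrast,
        ref_wt=ref_wt, ref_mut=ref_mut, down_wt=down_wt, down_mut=down_mut,
        readthrough_index=ratio_mut / ratio_wt,
    )


def low_signal_filter(
    calls: Sequence[ReadthroughCall],
    floor: Optional[float] = None,
    quantile: float = 0.25,
    median_fraction: float = 0.5,
    per_class: bool = False,
) -> list[ReadthroughCall]:
    """Flag calls whose WT reference mean falls below the signal floor.

    With an absolute ``floor`` the rule is simply ``ref_wt < floor``.
    Otherwise the floor is data-driven: ``min(quantile(ref_wt, q),
    median_fraction * median(ref_wt))``.  The quantile caps how much of the
    cohort can ever be discarded; the median term keeps units within the
    bulk of a tight cohort from being flagged by quantile alone.  With
    ``per_class`` the data-driven floor is computed within each unit class
    (window geometries differ between classes).  Flagged calls get
    ``readthrough_index`` set to NaN and can never be defective.
    """
    if not calls:
        raise ValidationError("low_signal_filter requires a non-empty cohort")
    if floor is not None and floor < 0:
        raise ValidationError("signal floor must be >= 0")

    def data_floor(refs: np.ndarray) -> float:
        return float(min(np.quantile(refs, quantile), median_fraction * np.median(refs)))

    floors: dict[str, float] = {}
    if floor is None:
        if per_class:
            classes = {c.unit_class for c in calls}
            for cls in classes:
                refs = np.array([c.ref_wt for c in calls if c.unit_class == cls])
                floors[cls] = data_floor(refs)
        else:
            shared = data_floor(np.array([c.ref_wt for c in calls]))
            floors = {c.unit_class: shared for c in calls}
    else:
        floors = {c.unit_class: floor for c in calls}
    out = []
    for c in calls:
        low = bool(c.ref_wt < floors[c.unit_class]) or c.low_signal
        out.append(
            replace(
                c,
                low_signal=low,
                readthrough_index=float("nan") if low else c.readthrough_index,
                is_defective=False if low else c.is_defective,
            )
        )
    return out


def classify_defective(
    call: ReadthroughCall,
    ri_threshold: float = 1.5,
    min_abs_increase: float = 0.0,
) -> ReadthroughCall:
    """Set the defect flag: RI above threshold and a real downstream gain."""
    if call.low_signal:
        return replace(call, is_defective=False)
    defective = (
        np.isfinite(call.readthrough_index)
        and call.readthrough_index >= ri_threshold
        and (call.down_mut - call.down_wt) >= min_abs_increase
    )
    return replace(call, is_defective=bool(defective))


def classify_all(
    calls: Sequence[ReadthroughCall],
    ri_threshold: float = 1.5,
    min_abs_increase: float = 0.0,
    floor: Optional[float] = None,
    quantile: float = 0.25,
    per_class: bool = True,
) -> list[ReadthroughCall]:
    """Low-signal filter then threshold classification, in one pass."""
    filtered = low_signal_filter(calls, floor=floor, quantile=quantile, per_class=per_class)
    return [classify_defective(c, ri_threshold, min_abs_increase) for c in filtered]


def class_fractions(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    """Per-class defective fractions among analyzed (non-low-signal) units."""
    rows = []
    frame = pd.DataFrame(
        {
            "unit_class": [c.unit_class for c in calls],
            "low_signal": [c.low_signal for c in calls],
            "is_defective": [c.is_defective for c in calls],
        }
    )
    for cls, group in frame.groupby("unit_class", sort=True):
        analyzed = group[~group["low_signal"]]
        n_analyzed = len(analyzed)
        n_defective = int(analyzed["is_defective"].sum())
        rows.append(
            {
                "unit_class": cls,
                "n_total": len(group),
                "n_low_signal": int(group["low_signal"].sum()),
                "n_analyzed": n_analyzed,
                "n_defective": n_defective,
                "fraction_defective": n_defective / n_analyzed if n_analyzed else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PathwayAssignment:
    unit_id: str
    cid_defective: bool
    cleavage_defective: bool

    @property
    def category(self) -> str:
        if self.cid_defective and self.cleavage_defective:
            return "both"
        if self.cid_defective:
            return "CID-only"
        if self.cleavage_defective:
            return "cleavage-only"
        return "neither"


def pathway_assignment(
    calls_by_genotype: Mapping[str, Sequence[ReadthroughCall]],
    cid_genotype: str,
    cleavage_genotype: str,
) -> tuple[list[PathwayAssignment], dict[str, int]]:
    """Assign termination-pathway categories from two mutant contrasts.

    Every unit must be classified (and not low-signal) in both contrasts;
    missing or filtered units raise an error naming them.
    """
    for g in (cid_genotype, cleavage_genotype):
        if g not in calls_by_genotype:
            raise ValidationError(f"no calls supplied for genotype {g!r}")
    cid = {c.unit_id: c for c in calls_by_genotype[cid_genotype]}
    cleavage = {c.unit_id: c for c in calls_by_genotype[cleavage_genotype]}
    assignments = []
    for uid, call in sorted(cid.items()):
        other = cleavage.get(uid)
        if other is None:
            raise ValidationError(
                f"unit {uid!r} classified in {cid_genotype} but missing from {cleavage_genotype}"
            )
        if call.low_signal or other.low_signal:
            continue  # filtered out of the pathway cohort entirely
        assignments.append(
            PathwayAssignment(
                unit_id=uid,
                cid_defective=call.is_defective,
                cleavage_defective=other.is_defective,
            )
        )
    counts = {cat: 0 for cat in PATHWAY_CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return assignments, counts


def calls_to_frame(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    """Long-format export with every intermediate quantity preserved."""
    return pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "unit_class": c.unit_class,
                "contrast": c.contrast,
                "ref_wt": c.ref_wt,
                "ref_mut": c.ref_mut,
                "down_wt": c.down_wt,
                "down_mut": c.down_mut,
                "readthrough_index": c.readthrough_index,
                "low_signal": c.low_signal,
                "is_defective": c.is_defective,
            }
            for c in calls
        ]
    )
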