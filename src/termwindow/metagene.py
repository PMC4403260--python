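"""Anchored matrices, metagene profiles, heat maps, and peak-shift tests."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit
from .errors import ValidationError
from .tracks_io import CoverageTrack, anchored_vector, moving_average


@dataclass
class AnchoredMatrix:
    """Units x relative-position signal matrix around a common anchor."""

    unit_ids: list[str]
    anchor_kind: str
    upstream: int
    downstream: int
    bin: int
    values: np.ndarray  #: (n_units, n_bins); NaN where masked
    mask: np.ndarray  #: (n_units, n_bins) boolean validity
    per_unit_normalized: bool = False

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream, self.bin)

    @property
    def n_bins(self) -> int:
        return (self.upstream + self.downstream) // self.bin

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.unit_ids, columns=self.positions)
        frame.index.name = "unit_id"
        return frame

    def write_tsv(self, path: str | Path) -> None:
        out = self.to_frame()
        out.insert(0, "n_valid_bins", self.mask.sum(axis=1))
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class MetageneProfile:
    positions: np.ndarray
    mean: np.ndarray
    n_contributing: np.ndarray
    smooth_window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean_signal": self.mean, "n_units": self.n_contributing}
        )


@dataclass
class PeakShiftResult:
    """Paired sign-flip permutation test on per-unit peak positions."""

    peaks_a: np.ndarray
    peaks_b: np.ndarray
    observed_shift: float  #: mean of (B - A)
    p_value: float
    n_permutations: int
    exact: bool


def build_matrix(
    track: CoverageTrack,
    units: Sequence[TranscriptionUnit],
    upstream: int,
    downstream: int,
    bin: int = 1,
    anchor_kind: Optional[str] = None,
    per_unit_normalize: bool = True,
) -> AnchoredMatrix:
    """Stack anchored vectors for a cohort of units.

    With per-unit normalization each row is divided by its unmasked mean so
    high-occupancy units do not dominate the cohort average; rows whose mean
    is zero are masked entirely.
    """
    if not units:
        raise ValidationError("build_matrix requires a non-empty cohort")
    missing = []
    for u in units:
        try:
            u.anchor(anchor_kind)
        except ValidationError:
            missing.append(u.id)
    if missing:
        raise ValidationError(
            f"units lacking anchor {anchor_kind or 'default'}: {missing}"
        )
    rows, masks = [], []
    for u in units:
        vec = anchored_vector(track, u, upstream, downstream, bin, anchor_kind)
        rows.append(vec.values)
        masks.append(vec.mask)
    values = np.vstack(rows)
    mask = np.vstack(masks)
    if per_unit_normalize:
        with np.errstate(invalid="ignore"):
            row_means = np.nanmean(np.where(mask, values, np.nan), axis=1)
        zero = ~np.isfinite(row_means) | (row_means == 0)
        row_means[zero] = 1.0
        values = values / row_means[:, None]
        values[zero, :] = np.nan
        mask[zero, :] = False
    return AnchoredMatrix(
        unit_ids=[u.id for u in units],
        anchor_kind=anchor_kind or units[0].anchor_kind,
        upstream=upstream,
        downstream=downstream,
        bin=bin,
        values=values,
        mask=mask,
        per_unit_normalized=per_unit_normalize,
    )


def _smooth_with_gaps(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Truncated centred moving average that ignores NaN gaps."""
    finite = np.isfinite(values)
    if finite.all():
        return moving_average(values, window_bins)
    filled = np.where(finite, values, 0.0)
    sums = moving_average(filled, window_bins)
    weights = moving_average(finite.astype(float), window_bins)
    out = np.full_like(values, np.nan)
    ok = weights > 0
    out[ok] = sums[ok] / weights[ok]
    out[~finite] = np.nan  # gaps stay gaps, never interpolated
    return out


def metagene_profile(matrix: AnchoredMatrix, smooth_window: int = 220) -> MetageneProfile:
    """Column-wise mean over unmasked cells, then moving-average smoothing.

    ``smooth_window`` is in nucleotides and converted to bins; fully masked
    columns are recorded as gaps (NaN).
    """
    if matrix.values.size == 0:
        raise ValidationError("metagene_profile requires a non-empty matrix")
    masked = np.where(matrix.mask, matrix.values, np.nan)
    n_contributing = matrix.mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        column_mean = np.where(n_contributing > 0, np.nanmean(masked, axis=0), np.nan)
    window_bins = max(1, int(round(smooth_window / matrix.bin)))
    smoothed = _smooth_with_gaps(column_mean, window_bins)
    return MetageneProfile(
        positions=matrix.positions,
        mean=smoothed,
        n_contributing=n_contributing,
        smooth_window=smooth_window,
    )


def heatmap_matrix(
    track: CoverageTrack,
    snoRNA_units: Sequence[TranscriptionUnit],
    upstream: int = 500,
    downstream: int = 1000,
    bin: int = 10,
    per_unit_normalize: bool = True,
) -> tuple[AnchoredMatrix, list[str], dict[str, int]]:
    """Heat-map substrate around snoRNA mature 3' ends.

    Rows are sorted by unit length (ascending).  For each unit the relative
    position of its 5' end (bin-quantized) is returned so the plot can mark
    it; units whose 5' end lies outside the window get no marker.
    """
    bad = [u.id for u in snoRNA_units if u.unit_class != "snoRNA"]
    if bad:
        raise ValidationError(f"heatmap_matrix accepts snoRNA only; offending units: {bad}")
    order = sorted(snoRNA_units, key=lambda u: (u.length, u.id))
    matrix = build_matrix(
        track, order, upstream, downstream, bin,
        anchor_kind="mature_3p_end", per_unit_normalize=per_unit_normalize,
    )
    markers: dict[str, int] = {}
    for u in order:
        rel_5p = -(u.transcript_offset(u.anchor("mature_3p_end")))  # TSS rel to anchor
        if -upstream <= rel_5p < downstream:
            markers[u.id] = (rel_5p // bin) * bin
    return matrix, [u.id for u in order], markers


def peak_position(
    values: np.ndarray,
    positions: np.ndarray,
    search_window: tuple[float, float],
    mask: Optional[np.ndarray] = None,
    smooth_window_bins: int = 1,
) -> float:
    """Relative position of the (smoothed) signal maximum within a window.

    Ties are broken toward the most 5' (smallest) position.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    if mask is None:
        mask = np.isfinite(values)
    if smooth_window_bins > 1:
        values = _smooth_with_gaps(np.where(mask, values, np.nan), smooth_window_bins)
    lo, hi = search_window
    in_window = (positions >= lo) & (positions <= hi) & mask & np.isfinite(values)
    if not in_window.any():
        raise ValidationError(
            f"no unmasked positions in search window [{lo}, {hi}]"
        )
    idx = np.flatnonzero(in_window)
    best = idx[np.argmax(values[idx])]  # argmax returns the first maximum
    return float(positions[best])


def peak_shift_test(
    peaks_a: Sequence[float],
    peaks_b: Sequence[float],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    exact_limit: int = 20,
) -> PeakShiftResult:
    """One-sided paired sign-flip permutation test for a 3'-ward shift.

    Tests whether factor B peaks downstream of factor A: the statistic is the
    mean paired difference B - A; sign assignments with mean >= observed are
    counted.  All 2^n assignments are enumerated when n <= ``exact_limit``,
    otherwise ``n_perm`` Monte-Carlo draws are used and the identity
    assignment is included so p is never 0.
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("peak vectors must be equal-length 1-D arrays")
    n = len(a)
    if n < 2:
        raise ValidationError("peak_shift_test requires n >= 2 pairs")
    diffs = b - a
    observed = float(diffs.mean())
    if np.all(diffs == 0):
        return PeakShiftResult(a, b, 0.0, 1.0, 0, True)

    tol = 1e-9 * max(1.0, float(np.abs(diffs).max()))
    if n <= exact_limit:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        means = signs @ diffs / n
        p = float(np.count_nonzero(means >= observed - tol)) / len(means)
        return PeakShiftResult(a, b, observed, p, len(means), True)
    rng = np.random.default_rng(seed)
    hits = 0
    block = 512
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        signs = rng.choice((1.0, -1.0), size=(m, n))
        means = signs @ diffs / n
        hits += int(np.count_nonzero(means >= observed - tol))
        done += m
    p = (1 + hits) / (1 + n_perm)  # identity assignment included
    return PeakShiftResult(a, b, observed, float(p), n_perm, False)


def per_unit_peaks(
    matrix: AnchoredMatrix,
    search_window: tuple[float, float],
    smooth_window: int = 50,
) -> pd.Series:
    """Peak position per matrix row (unit), smoothed within each row."""
    window_bins = max(1, int(round(smooth_window / matrix.bin)))
    peaks = {}
    for i, uid in enumerate(matrix.unit_ids):
        peaks[uid] = peak_position(
            matrix.values[i], matrix.positions, search_window,
            mask=matrix.mask[i], smooth_window_bins=window_bins,
        )
    return pd.Series(peaks, name="peak_position")
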