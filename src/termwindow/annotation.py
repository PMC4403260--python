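"""Transcription-unit annotations and their on-disk representation.

A :class:`TranscriptionUnit` is the atom of every per-unit analysis: a
strand-aware genomic interval with an optional mature 3' end (snoRNA), a
proximal NRD-binding-site centre, and an optional distal poly(A) site.
Coordinates are 0-based half-open genomic positions throughout.

On disk a cohort is a BED6 file (name column = unit id) plus a TSV sidecar
holding the class label and the per-unit anchor coordinates that BED cannot
carry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import TrackIOError, ValidationError

UNIT_CLASSES = ("snoRNA", "CUT", "SUT", "XUT", "NAPC", "PC")

ANCHOR_KINDS = ("mature_3p_end", "tss", "nbs", "annotated_3p_end")

#: anchor used by default when none is requested explicitly
DEFAULT_ANCHORS = {
    "snoRNA": "mature_3p_end",
    "CUT": "annotated_3p_end",
    "SUT": "annotated_3p_end",
    "XUT": "annotated_3p_end",
    "NAPC": "nbs",
    "PC": "annotated_3p_end",
}


@dataclass(frozen=True)
class TranscriptionUnit:
    """One annotated transcription unit.

    ``start``/``end`` delimit the annotated unit; ``tss`` equals ``start``
    on the + strand and ``end - 1`` on the - strand.  ``mature_end``
    (snoRNA only), ``nbs_center`` and ``pas_position`` are genomic
    coordinates of single bases.
    """

    id: str
    unit_class: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_end: Optional[int] = None
    nbs_center: Optional[int] = None
    pas_position: Optional[int] = None
    anchor_kind: str = field(default="")

    def __post_init__(self) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise ValidationError(
                f"unit {self.id!r}: unknown class {self.unit_class!r}; "
                f"expected one of {UNIT_CLASSES}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unit {self.id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"unit {self.id!r}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if not self.anchor_kind:
            object.__setattr__(self, "anchor_kind", DEFAULT_ANCHORS[self.unit_class])
        if self.anchor_kind not in ANCHOR_KINDS:
            raise ValidationError(
                f"unit {self.id!r}: unknown anchor kind {self.anchor_kind!r}"
            )
        if self.unit_class == "snoRNA" and self.mature_end is None:
            raise ValidationError(f"snoRNA unit {self.id!r} requires mature_end")

    # -- coordinate helpers -------------------------------------------------

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def genomic(self, offset: int) -> int:
        """Genomic coordinate at transcript offset ``offset`` from the TSS."""
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def transcript_offset(self, genomic: int) -> int:
        """Transcript offset (nt from TSS, 5'->3') of a genomic coordinate."""
        return genomic - self.tss if self.strand == "+" else self.tss - genomic

    def anchor(self, kind: Optional[str] = None) -> int:
        """Resolve an anchor kind to its genomic coordinate.

        Raises :class:`ValidationError` naming the unit when the requested
        anchor is not defined for it (e.g. ``mature_3p_end`` on a CUT).
        """
        kind = kind or self.anchor_kind
        if kind == "tss":
            return self.tss
        if kind == "annotated_3p_end":
            return self.end - 1 if self.strand == "+" else self.start
        if kind == "mature_3p_end":
            if self.mature_end is None:
                raise ValidationError(
                    f"unit {self.id!r} ({self.unit_class}) has no mature 3' end"
                )
            return self.mature_end
        if kind == "nbs":
            if self.nbs_center is None:
                raise ValidationError(f"unit {self.id!r} has no NBS centre")
            return self.nbs_center
        raise ValidationError(f"unknown anchor kind {kind!r}")

    def with_anchor(self, kind: str) -> "TranscriptionUnit":
        return replace(self, anchor_kind=kind)


# -- chrom.sizes ------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV."""
    sizes: dict[str, int] = {}
    try:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, size = line.split("\t")[:2]
                sizes[name] = int(size)
    except (OSError, ValueError) as exc:
        raise TrackIOError(f"cannot read chrom sizes from {path}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


# -- BED6 + TSV sidecar -----------------------------------------------------

_SIDECAR_COLUMNS = ["id", "unit_class", "mature_end", "nbs_center", "pas_position", "anchor_kind"]


def write_units(units: Sequence[TranscriptionUnit], bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write a cohort as BED6 plus the TSV sidecar (empty cohorts allowed)."""
    with open(bed_path, "w") as bed:
        for u in units:
            bed.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.id}\t0\t{u.strand}\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SIDECAR_COLUMNS)
        for u in units:
            writer.writerow(
                [
                    u.id,
                    u.unit_class,
                    "" if u.mature_end is None else u.mature_end,
                    "" if u.nbs_center is None else u.nbs_center,
                    "" if u.pas_position is None else u.pas_position,
                    u.anchor_kind,
                ]
            )


def read_units(bed_path: str | Path, tsv_path: str | Path) -> list[TranscriptionUnit]:
    """Read a cohort written by :func:`write_units`."""
    side: dict[str, dict] = {}
    with open(tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            side[row["id"]] = row
    units: list[TranscriptionUnit] = []
    with open(bed_path) as bed:
        for line in bed:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TrackIOError(f"{bed_path}: BED6 line with {len(fields)} fields")
            chrom, start, end, name, _score, strand = fields[:6]
            meta = side.get(name)
            if meta is None:
                raise TrackIOError(f"{bed_path}: unit {name!r} missing from sidecar {tsv_path}")

            def _opt(key: str) -> Optional[int]:
                value = meta.get(key, "")
                return int(value) if value not in ("", None) else None

            units.append(
                TranscriptionUnit(
                    id=name,
                    unit_class=meta["unit_class"],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    mature_end=_opt("mature_end"),
                    nbs_center=_opt("nbs_center"),
                    pas_position=_opt("pas_position"),
                    anchor_kind=meta.get("anchor_kind") or "",
                )
            )
    return units


def read_units_gff3(path: str | Path, unit_class: str = "PC") -> list[TranscriptionUnit]:
    """Read gene-level records from a GFF3 file (read-only convenience).

    GFF3 is 1-based closed; coordinates are converted to 0-based half-open.
    All records are assigned ``unit_class`` because GFF3 carries no NRD
    metadata; use the TSV sidecar format for full annotations.
    """
    units = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("gene", "transcript", "mRNA"):
                continue
            chrom, _src, _type, start, end, _score, strand, _frame, attrs = fields[:9]
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            uid = attr_map.get("ID") or attr_map.get("Name") or f"{chrom}:{start}-{end}"
            units.append(
                TranscriptionUnit(
                    id=uid,
                    unit_class=unit_class,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    return units


def units_by_class(units: Iterable[TranscriptionUnit]) -> dict[str, list[TranscriptionUnit]]:
    out: dict[str, list[TranscriptionUnit]] = {}
    for u in units:
        out.setdefault(u.unit_class, []).append(u)
    return out
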