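"""Hazard-based Pol II occupancy simulator with planted ground truth.

The generative model is a survival process along the template: a polymerase
initiates at the TSS, dwells ``d(x)`` time units at each position and
terminates there with per-nt hazard ``h(x)``.  Expected steady-state
occupancy is therefore ``density(x) = init_rate * S(x) * d(x)`` with
``S(x) = prod_{i<x} (1 - h(i))``.

Terminator geometry per unit: a proximal element (NRD-binding site zone), a
distal element downstream of it, and an optional poly(A)-site element; a
far-downstream failsafe zone stops whatever reads through everything.
Genotype modifiers scale the element hazards, the post-NBS pause dwell, and
the Ser2-P amplitude; temperature scales elongation speed, and because
hazards are per unit time, a faster polymerase sees a lower per-nt hazard
and terminates further downstream.

Every stochastic output is reproducible from the configured seed, and a
:class:`SimulationTruth` table records the planted per-unit parameters so
downstream classifiers can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    UNIT_CLASSES,
    TranscriptionUnit,
    read_chrom_sizes,
    read_units,
    write_chrom_sizes,
    write_units,
)
from .errors import PlacementError, ValidationError
from .tracks_io import CoverageTrack, read_bedgraph, write_bedgraph

SIMULATED_FACTORS = (
    "PolII_total",
    "PolII_Ser2P",
    "PolII_Ser5P",
    "Nrd1",
    "Pcf11",
    "RNADNA_hybrid",
)


# -- configuration ----------------------------------------------------------


@dataclass
class ElementSpec:
    """A terminator element: hazard window relative to its reference base."""

    offset: int
    width: int
    hazard: float

    def validate(self, name: str) -> None:
        if self.width < 1:
            raise ValidationError(f"{name}: width must be >= 1")
        if not (0.0 <= self.hazard < 1.0):
            raise ValidationError(f"{name}: per-nt hazard must lie in [0, 1)")


@dataclass
class FactorKernel:
    """Gaussian recruitment kernel, centred relative to the NBS base."""

    center_offset: float
    sigma: float
    amplitude: float = 1.0

    def validate(self, name: str) -> None:
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValidationError(f"kernel {name}: sigma and amplitude must be > 0")


@dataclass
class GenotypeModifiers:
    """Multipliers a genotype applies to the wild-type parameters."""

    proximal: float = 1.0
    distal: float = 1.0
    pas: float = 1.0
    pause_dwell: float = 1.0
    ser2p: float = 1.0

    def validate(self, name: str) -> None:
        for key, value in asdict(self).items():
            if value <= 0:
                raise ValidationError(f"genotype {name}: {key} multiplier must be > 0")


@dataclass
class ClassGeometry:
    """Unit counts and geometry for one unit class.

    ``length`` is the mature-RNA length for snoRNA and the annotated unit
    length otherwise.  ``nbs_offset`` is interpreted per class: nt downstream
    of the mature 3' end (snoRNA), of the annotated 3' end (CUT/SUT/XUT), or
    of the TSS (NAPC).
    """

    n_units: int = 0
    length: tuple[int, int] = (200, 500)
    spacing: tuple[int, int] = (200, 800)
    annotated_extension: int = 250
    nbs_offset: int = 10
    pas_setback: int = 30
    has_proximal: bool = True
    has_distal: bool = True
    has_pas: bool = False
    susceptible_fraction: float = 1.0
    silent_fraction: float = 0.0
    strand_prob: float = 0.5

    def validate(self, name: str) -> None:
        if self.n_units < 0:
            raise ValidationError(f"class {name}: n_units must be >= 0")
        for attr in ("length", "spacing"):
            lo, hi = getattr(self, attr)
            if not (0 < lo <= hi):
                raise ValidationError(f"class {name}: bad {attr} range ({lo}, {hi})")
        for attr in ("susceptible_fraction", "silent_fraction", "strand_prob"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"class {name}: {attr} must lie in [0, 1]")


def _default_classes() -> dict[str, ClassGeometry]:
    return {
        "snoRNA": ClassGeometry(length=(150, 500)),
        "CUT": ClassGeometry(length=(300, 600)),
        "SUT": ClassGeometry(length=(300, 600)),
        "XUT": ClassGeometry(length=(300, 600)),
        "NAPC": ClassGeometry(length=(1000, 2000), nbs_offset=150, has_pas=True),
        "PC": ClassGeometry(
            length=(1000, 2000), has_proximal=False, has_distal=False,
            has_pas=True, susceptible_fraction=0.0,
        ),
    }


def _default_genotypes() -> dict[str, GenotypeModifiers]:
    return {"WT": GenotypeModifiers()}


def _default_kernels() -> dict[str, FactorKernel]:
    return {
        "Nrd1": FactorKernel(center_offset=0.0, sigma=60.0),
        "Pcf11": FactorKernel(center_offset=140.0, sigma=80.0),
    }


@dataclass
class SimulationConfig:
    """Full parameterization of the toy genome and occupancy model."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrI": 500_000})
    classes: dict[str, ClassGeometry] = field(default_factory=_default_classes)
    genotypes: dict[str, GenotypeModifiers] = field(default_factory=_default_genotypes)
    kernels: dict[str, FactorKernel] = field(default_factory=_default_kernels)
    init_rate: float = 1.0
    speed: float = 30.0  # nt per unit time at 25C
    temp_speed_multiplier: float = 1.5  # applied at 37C; must be >= 1
    proximal: ElementSpec = field(default_factory=lambda: ElementSpec(0, 60, 0.004))
    distal: ElementSpec = field(default_factory=lambda: ElementSpec(80, 120, 0.015))
    pas: ElementSpec = field(default_factory=lambda: ElementSpec(0, 60, 0.03))
    failsafe_offset: int = 700
    failsafe_hazard: float = 0.02
    ctd_decay: float = 400.0
    depth: float = 3000.0
    background: float = 0.5
    upstream_flank: int = 300
    downstream_flank: int = 1200
    defect_hazard_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {name}: length must be > 0")
        for name, geom in self.classes.items():
            if name not in UNIT_CLASSES:
                raise ValidationError(f"unknown unit class {name!r}")
            geom.validate(name)
        for name, mods in self.genotypes.items():
            mods.validate(name)
        for name, kernel in self.kernels.items():
            kernel.validate(name)
        if self.init_rate <= 0 or self.speed <= 0:
            raise ValidationError("init_rate and speed must be > 0")
        if self.temp_speed_multiplier < 1:
            raise ValidationError("temp_speed_multiplier must be >= 1")
        self.proximal.validate("proximal")
        self.distal.validate("distal")
        self.pas.validate("pas")
        if not (0.0 <= self.failsafe_hazard < 1.0):
            raise ValidationError("failsafe hazard must lie in [0, 1)")
        if self.depth < 0 or self.background < 0:
            raise ValidationError("depth and background must be >= 0")
        if not (0.0 < self.defect_hazard_fraction < 1.0):
            raise ValidationError("defect_hazard_fraction must lie in (0, 1)")
        if "WT" not in self.genotypes:
            raise ValidationError("genotype table must contain 'WT'")

    def speed_at(self, temperature: int) -> float:
        return self.speed * (self.temp_speed_multiplier if temperature == 37 else 1.0)

    # YAML snapshot -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "classes" in raw:
            raw["classes"] = {
                k: v if isinstance(v, ClassGeometry) else ClassGeometry(**_tupled(v, ("length", "spacing")))
                for k, v in raw["classes"].items()
            }
        if "genotypes" in raw:
            raw["genotypes"] = {
                k: v if isinstance(v, GenotypeModifiers) else GenotypeModifiers(**v)
                for k, v in raw["genotypes"].items()
            }
        if "kernels" in raw:
            raw["kernels"] = {
                k: v if isinstance(v, FactorKernel) else FactorKernel(**v)
                for k, v in raw["kernels"].items()
            }
        for key in ("proximal", "distal", "pas"):
            if key in raw and not isinstance(raw[key], ElementSpec):
                raw[key] = ElementSpec(**raw[key])
        return cls(**raw)


def _tupled(mapping: dict, keys: tuple[str, ...]) -> dict:
    out = dict(mapping)
    for key in keys:
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    return out


# -- sample specs -----------------------------------------------------------


class SampleSpec(NamedTuple):
    factor: str
    genotype: str
    temperature: int
    replicate: int = 1


def _as_spec(spec) -> SampleSpec:
    if isinstance(spec, SampleSpec):
        return spec
    return SampleSpec(*spec)


# -- annotation generator ---------------------------------------------------


def make_toy_annotation(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[list[TranscriptionUnit], dict[str, int]]:
    """Place non-overlapping units of every configured class on the toy genome.

    Deterministic given the seed.  Raises :class:`PlacementError` naming the
    class when a chromosome cannot accommodate the requested units.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed if seed is None else seed, spawn_key=(0,))
    )
    chrom_names = list(config.chrom_sizes)
    cursors = {c: 0 for c in chrom_names}
    units: list[TranscriptionUnit] = []

    for cls in UNIT_CLASSES:
        geom = config.classes.get(cls)
        if geom is None or geom.n_units == 0:
            continue
        for i in range(geom.n_units):
            length = int(rng.integers(geom.length[0], geom.length[1] + 1))
            spacing = int(rng.integers(geom.spacing[0], geom.spacing[1] + 1))
            strand = "+" if rng.random() < geom.strand_prob else "-"
            annotated_len = length + (geom.annotated_extension if cls == "snoRNA" else 0)
            footprint = config.upstream_flank + annotated_len + config.downstream_flank

            placed = False
            for chrom in chrom_names:
                slot_start = cursors[chrom] + spacing
                if slot_start + footprint <= config.chrom_sizes[chrom]:
                    cursors[chrom] = slot_start + footprint
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"no chromosome can fit {cls} unit {i + 1}/{geom.n_units} "
                    f"(footprint {footprint} nt)"
                )

            if strand == "+":
                tss = slot_start + config.upstream_flank
                start, end = tss, tss + annotated_len
            else:
                tss = slot_start + config.upstream_flank + annotated_len - 1
                start, end = tss - annotated_len + 1, tss + 1

            def genomic(offset: int) -> int:
                return tss + offset if strand == "+" else tss - offset

            mature_end = nbs_center = pas_position = None
            if cls == "snoRNA":
                mature_end = genomic(length - 1)
                nbs_center = genomic(length - 1 + geom.nbs_offset)
            elif cls in ("CUT", "SUT", "XUT"):
                nbs_center = genomic(annotated_len - 1 + geom.nbs_offset)
            elif cls == "NAPC":
                nbs_center = genomic(geom.nbs_offset)
            if geom.has_pas:
                pas_position = genomic(annotated_len - 1 - geom.pas_setback)

            units.append(
                TranscriptionUnit(
                    id=f"{cls}_{i:04d}",
                    unit_class=cls,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    mature_end=mature_end,
                    nbs_center=nbs_center,
                    pas_position=pas_position,
                )
            )
    return units, dict(config.chrom_sizes)


# -- hazard / dwell / occupancy ---------------------------------------------


class HazardProfile(NamedTuple):
    """Per-nt hazard and dwell over transcript coordinates [0, L + flank)."""

    hazard: np.ndarray
    dwell: np.ndarray
    zone: tuple[int, int]  #: [start, end) of the terminator zone (failsafe excluded)
    cumulative_hazard: float  #: sum of -log(1 - h) over the terminator zone


def hazard_profile(
    unit: TranscriptionUnit,
    config: SimulationConfig,
    genotype: str = "WT",
    temperature: int = 25,
    susceptible: bool = True,
) -> HazardProfile:
    """Planted hazard and dwell profile for one unit under one condition.

    Genotype multipliers are applied only when the unit is susceptible to the
    mutation; the temperature speed multiplier rescales per-nt hazards as
    ``h -> 1 - (1-h)^(1/m)`` (hazards are per unit time) and shortens dwell.
    """
    if genotype not in config.genotypes:
        raise ValidationError(
            f"genotype {genotype!r} not in modifier table {sorted(config.genotypes)}"
        )
    mods = config.genotypes[genotype] if susceptible else GenotypeModifiers(
        ser2p=config.genotypes[genotype].ser2p
    )
    geom = config.classes.get(unit.unit_class, ClassGeometry())
    mult = config.temp_speed_multiplier if temperature == 37 else 1.0
    n = unit.length + config.downstream_flank

    # accumulate log-survival so overlapping elements compose correctly
    log_surv = np.zeros(n)
    zone_lo, zone_hi = n, 0

    def add_element(ref_rel: int, spec: ElementSpec, multiplier: float) -> None:
        nonlocal zone_lo, zone_hi
        h = min(spec.hazard * multiplier, 1.0 - 1e-12)
        lo = max(ref_rel + spec.offset, 0)
        hi = min(lo + spec.width, n)
        if lo >= hi:
            return
        log_surv[lo:hi] += np.log1p(-h)
        zone_lo, zone_hi = min(zone_lo, lo), max(zone_hi, hi)

    nbs_rel = unit.transcript_offset(unit.nbs_center) if unit.nbs_center is not None else None
    if nbs_rel is not None:
        if geom.has_proximal:
            add_element(nbs_rel, config.proximal, mods.proximal)
        if geom.has_distal:
            add_element(nbs_rel, config.distal, mods.distal)
    if unit.pas_position is not None:
        add_element(unit.transcript_offset(unit.pas_position), config.pas, mods.pas)

    if zone_hi <= zone_lo:  # no terminator element at all
        zone_lo = zone_hi = unit.length
    fail_lo = min(zone_hi + config.failsafe_offset, n)
    log_surv[fail_lo:] += np.log1p(-min(config.failsafe_hazard, 1.0 - 1e-12))

    cumulative = float(-log_surv[zone_lo:zone_hi].sum())
    # temperature: hazards are per unit time; per-nt hazard scales as 1/m
    hazard = 1.0 - np.exp(log_surv / mult)

    dwell = np.full(n, 1.0 / (config.speed * mult))
    if nbs_rel is not None and mods.pause_dwell != 1.0:
        dwell[max(nbs_rel, 0):] *= mods.pause_dwell
    return HazardProfile(hazard=hazard, dwell=dwell, zone=(zone_lo, zone_hi),
                         cumulative_hazard=cumulative / mult)


def occupancy_from_hazard(hazard: np.ndarray, dwell: np.ndarray) -> np.ndarray:
    """Closed-form expected occupancy ``S(x) * d(x)`` per initiation event."""
    hazard = np.asarray(hazard, dtype=float)
    dwell = np.asarray(dwell, dtype=float)
    if np.any(hazard < 0) or np.any(hazard >= 1):
        raise ValidationError("hazards must lie in [0, 1)")
    if np.any(dwell <= 0):
        raise ValidationError("dwell must be > 0 (zero or negative speed)")
    log_surv = np.concatenate(([0.0], np.cumsum(np.log1p(-hazard))[:-1]))
    return np.exp(log_surv) * dwell


class OccupancyProfile(NamedTuple):
    positions: np.ndarray  #: transcript offsets from the TSS
    density: np.ndarray


def expected_occupancy(
    unit: TranscriptionUnit,
    config: SimulationConfig,
    genotype: str = "WT",
    temperature: int = 25,
    susceptible: bool = True,
) -> OccupancyProfile:
    """Expected per-position density over ``[-upstream_flank, L + downstream_flank)``.

    Density is zero upstream of the TSS and flat between the TSS and the
    first hazard element.
    """
    prof = hazard_profile(unit, config, genotype, temperature, susceptible)
    body = occupancy_from_hazard(prof.hazard, prof.dwell)
    positions = np.arange(-config.upstream_flank, len(body))
    density = np.concatenate((np.zeros(config.upstream_flank), body))
    return OccupancyProfile(positions=positions, density=density)


def monte_carlo_occupancy(
    hazard: np.ndarray,
    dwell: np.ndarray,
    n_trajectories: int,
    rng: np.random.Generator,
    chunk: int = 8192,
) -> np.ndarray:
    """Estimate occupancy by simulating individual polymerase trajectories.

    Each trajectory draws an independent Bernoulli(h(x)) at every position and
    terminates at the first success; it contributes its dwell time at every
    position up to and including the termination site.  Serves as the
    independent stochastic oracle for :func:`occupancy_from_hazard`.
    """
    hazard = np.asarray(hazard, dtype=float)
    dwell = np.asarray(dwell, dtype=float)
    n = len(hazard)
    reached = np.zeros(n + 1, dtype=np.int64)
    done = 0
    while done < n_trajectories:
        m = min(chunk, n_trajectories - done)
        hits = rng.random((m, n)) < hazard[None, :]
        any_hit = hits.any(axis=1)
        term = np.where(any_hit, hits.argmax(axis=1), n)
        reached += np.bincount(term, minlength=n + 1)
        done += m
    # trajectory with termination site t occupies positions 0..t
    survivors = np.cumsum(reached[::-1])[::-1]  # survivors[x] = #(term >= x)
    return survivors[:n] / n_trajectories * dwell


# -- track simulation -------------------------------------------------------


@dataclass
class SimulationTruth:
    """Planted per-unit parameters for recovery testing.

    ``per_unit`` has one row per unit (susceptibility, silencing, initiation
    rate); ``per_condition`` one row per (unit, genotype, temperature) with
    the realized terminator hazards, the planted-defect flag, and the
    closed-form expected readthrough fraction.
    """

    per_unit: pd.DataFrame
    per_condition: pd.DataFrame

    def planted_defective(self, genotype: str, temperature: int = 25) -> set[str]:
        sub = self.per_condition
        sel = (sub["genotype"] == genotype) & (sub["temperature"] == temperature)
        return set(sub.loc[sel & sub["planted_defect"], "unit_id"])

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.per_unit.to_csv(directory / "truth_units.tsv", sep="\t", index=False)
        self.per_condition.to_csv(directory / "truth_conditions.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "SimulationTruth":
        directory = Path(directory)
        return cls(
            per_unit=pd.read_csv(directory / "truth_units.tsv", sep="\t"),
            per_condition=pd.read_csv(directory / "truth_conditions.tsv", sep="\t"),
        )


def _exact_count_flags(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with exactly round(fraction * n) True entries."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def plant_unit_states(
    config: SimulationConfig, units: Sequence[TranscriptionUnit], seed: Optional[int] = None
) -> pd.DataFrame:
    """Assign susceptible/silent flags per unit with exact per-class counts."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed if seed is None else seed, spawn_key=(1,))
    )
    rows = []
    for cls in UNIT_CLASSES:
        members = [u for u in units if u.unit_class == cls]
        if not members:
            continue
        geom = config.classes.get(cls, ClassGeometry())
        susceptible = _exact_count_flags(len(members), geom.susceptible_fraction, rng)
        silent = _exact_count_flags(len(members), geom.silent_fraction, rng)
        for u, su, si in zip(members, susceptible, silent):
            rows.append(
                {
                    "unit_id": u.id,
                    "unit_class": cls,
                    "susceptible": bool(su),
                    "silent": bool(si),
                    "init_rate": 0.0 if si else config.init_rate,
                }
            )
    columns = ["unit_id", "unit_class", "susceptible", "silent", "init_rate"]
    return pd.DataFrame(rows, columns=columns)


def _condition_truth(
    config: SimulationConfig,
    units: Sequence[TranscriptionUnit],
    per_unit: pd.DataFrame,
    conditions: Iterable[tuple[str, int]],
) -> pd.DataFrame:
    susceptible = dict(zip(per_unit["unit_id"], per_unit["susceptible"]))
    rows = []
    for genotype, temperature in conditions:
        for u in units:
            wt = hazard_profile(u, config, "WT", temperature, susceptible=True)
            mut = hazard_profile(u, config, genotype, temperature, susceptible[u.id])
            defect = (
                genotype != "WT"
                and wt.cumulative_hazard > 0
                and mut.cumulative_hazard
                < config.defect_hazard_fraction * wt.cumulative_hazard
            )
            mods = config.genotypes[genotype]
            rows.append(
                {
                    "unit_id": u.id,
                    "genotype": genotype,
                    "temperature": temperature,
                    "cum_hazard": mut.cumulative_hazard,
                    "cum_hazard_wt": wt.cumulative_hazard,
                    "pause_dwell": mods.pause_dwell if susceptible[u.id] else 1.0,
                    "ser2p": mods.ser2p,
                    "planted_defect": bool(defect),
                    "expected_readthrough": float(np.exp(-mut.cumulative_hazard)),
                }
            )
    columns = [
        "unit_id", "genotype", "temperature", "cum_hazard", "cum_hazard_wt",
        "pause_dwell", "ser2p", "planted_defect", "expected_readthrough",
    ]
    return pd.DataFrame(rows, columns=columns)


def _expected_factor_arrays(
    config: SimulationConfig,
    units: Sequence[TranscriptionUnit],
    per_unit: pd.DataFrame,
    genotype: str,
    temperature: int,
    factors: Sequence[str],
) -> dict[str, dict[str, np.ndarray]]:
    """Noise-free expected signal per factor for one (genotype, temperature)."""
    unknown = [f for f in factors if f not in SIMULATED_FACTORS]
    if unknown:
        raise ValidationError(
            f"unknown factor(s) {unknown}; supported: {list(SIMULATED_FACTORS)}"
        )
    state = per_unit.set_index("unit_id")
    speed_eff = config.speed_at(temperature)
    mods = config.genotypes[genotype]
    expected = {
        f: {c: np.zeros(n) for c, n in config.chrom_sizes.items()} for f in factors
    }
    for u in units:
        init = float(state.loc[u.id, "init_rate"])
        if init == 0.0:
            continue
        susceptible = bool(state.loc[u.id, "susceptible"])
        prof = hazard_profile(u, config, genotype, temperature, susceptible)
        occ = init * occupancy_from_hazard(prof.hazard, prof.dwell)
        x = np.arange(len(occ), dtype=float)  # transcript offset from TSS
        genomic = u.tss + x.astype(int) if u.strand == "+" else u.tss - x.astype(int)
        inside = (genomic >= 0) & (genomic < config.chrom_sizes[u.chrom])
        gi = genomic[inside]
        nbs_rel = (
            u.transcript_offset(u.nbs_center) if u.nbs_center is not None else None
        )
        for f in factors:
            if f == "PolII_total":
                signal = occ
            elif f == "PolII_Ser5P":
                signal = occ * np.exp(-x / config.ctd_decay)
            elif f == "PolII_Ser2P":
                signal = occ * (1.0 - np.exp(-x / config.ctd_decay)) * mods.ser2p
            elif f == "RNADNA_hybrid":
                pause = np.ones_like(occ)
                if nbs_rel is not None and susceptible:
                    pause[max(nbs_rel, 0):] = mods.pause_dwell
                signal = occ * pause
            elif f in ("Nrd1", "Pcf11"):
                if nbs_rel is None:
                    continue
                kernel = config.kernels.get(f)
                if kernel is None:
                    raise ValidationError(f"no kernel configured for factor {f!r}")
                center = nbs_rel + kernel.center_offset
                amp = init / speed_eff * kernel.amplitude
                signal = amp * np.exp(-0.5 * ((x - center) / kernel.sigma) ** 2)
            else:  # pragma: no cover - guarded above
                continue
            expected[f][u.chrom][gi] += signal[inside]
    return expected


def simulate_tracks(
    config: SimulationConfig,
    units: Sequence[TranscriptionUnit],
    sample_specs: Sequence[tuple],
    seed: Optional[int] = None,
) -> tuple[list[CoverageTrack], SimulationTruth]:
    """Simulate Poisson count tracks for every requested sample.

    Per-base counts are Poisson(depth * expected + background).  Runs are
    deterministic under a fixed seed; planted parameters are returned as a
    :class:`SimulationTruth`.
    """
    specs = [_as_spec(s) for s in sample_specs]
    for s in specs:
        if s.genotype not in config.genotypes:
            raise ValidationError(
                f"genotype {s.genotype!r} not in modifier table {sorted(config.genotypes)}"
            )
    base_seed = config.seed if seed is None else seed
    rng_noise = np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(2,))
    )
    per_unit = plant_unit_states(config, units, seed=base_seed)
    conditions = sorted({(s.genotype, s.temperature) for s in specs})
    truth = SimulationTruth(
        per_unit=per_unit,
        per_condition=_condition_truth(config, units, per_unit, conditions),
    )

    expected_cache: dict[tuple[str, int], dict[str, dict[str, np.ndarray]]] = {}
    for genotype, temperature in conditions:
        factors = sorted({s.factor for s in specs if (s.genotype, s.temperature) == (genotype, temperature)})
        expected_cache[(genotype, temperature)] = _expected_factor_arrays(
            config, units, per_unit, genotype, temperature, factors
        )

    tracks = []
    for s in specs:
        expected = expected_cache[(s.genotype, s.temperature)][s.factor]
        data = {
            chrom: rng_noise.poisson(config.depth * arr + config.background).astype(float)
            for chrom, arr in expected.items()
        }
        tracks.append(
            CoverageTrack(
                factor=s.factor, genotype=s.genotype, temperature=s.temperature,
                replicate=s.replicate, data=data,
            )
        )
    return tracks, truth


# -- fixtures on disk -------------------------------------------------------


def write_fixture(
    directory: str | Path,
    units: Sequence[TranscriptionUnit],
    chrom_sizes: dict[str, int],
    tracks: Sequence[CoverageTrack],
    truth: Optional[SimulationTruth] = None,
    config: Optional[SimulationConfig] = None,
) -> None:
    """Write a complete text-only fixture: annotation, tracks, truth, config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_units(units, directory / "units.bed", directory / "units.tsv")
    write_chrom_sizes(chrom_sizes, directory / "chrom.sizes")
    manifest = []
    for track in tracks:
        fname = f"{track.label}.bedgraph"
        write_bedgraph(track, directory / fname)
        manifest.append(
            {
                "file": fname,
                "factor": track.factor,
                "genotype": track.genotype,
                "temperature": track.temperature,
                "replicate": track.replicate,
            }
        )
    pd.DataFrame(
        manifest, columns=["file", "factor", "genotype", "temperature", "replicate"]
    ).to_csv(directory / "samples.tsv", sep="\t", index=False)
    if truth is not None:
        truth.write(directory)
    if config is not None:
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_fixture(
    directory: str | Path,
) -> tuple[list[TranscriptionUnit], dict[str, int], list[CoverageTrack]]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    units = read_units(directory / "units.bed", directory / "units.tsv")
    chrom_sizes = read_chrom_sizes(directory / "chrom.sizes")
    tracks = []
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    for row in samples.itertuples(index=False):
        tracks.append(
            read_bedgraph(
                directory / row.file,
                chrom_sizes,
                factor=row.factor,
                genotype=row.genotype,
                temperature=int(row.temperature),
                replicate=int(row.replicate),
            )
        )
    return units, chrom_sizes, tracks
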