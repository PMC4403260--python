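"""End-to-end orchestration: simulate -> quantify -> classify -> test -> report.

A single structured config drives everything; the CLI only selects the
config path, output directory, seed override, and verbosity.  All outputs
are TSV/JSON (plus optional SVG plots) and carry the config hash and seed
in a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import TranscriptionUnit, units_by_class, write_units
from .chip_quant import Amplicon, amplicon_quant, quant_to_frame
from .errors import TermwindowError, ValidationError
from .metagene import (
    build_matrix,
    heatmap_matrix,
    metagene_profile,
    peak_position,
    peak_shift_test,
    per_unit_peaks,
)
from .readthrough import (
    DEFAULT_WINDOWS,
    calls_to_frame,
    class_fractions,
    classify_all,
    pathway_assignment,
    readthrough_index,
)
from .setstats import overlap_test, venn_counts
from .synthetic import (
    SampleSpec,
    SimulationConfig,
    make_toy_annotation,
    read_fixture,
    simulate_tracks,
    write_fixture,
)
from .tracks_io import CoverageTrack, GenomicRegion

logger = logging.getLogger("termwindow")

DEFAULT_PEAK_WINDOWS = {"Nrd1": (-200, 400), "Pcf11": (0, 600)}


@dataclass
class RunConfig:
    """Validated view of the run configuration tree."""

    raw: dict[str, Any]
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    input_dir: Optional[Path] = None
    samples: list[SampleSpec] = field(default_factory=list)
    contrasts: list[dict] = field(default_factory=list)
    classifier: dict = field(default_factory=dict)
    pathway: Optional[dict] = None
    metagene: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    heatmap: dict = field(default_factory=dict)
    amplicons: Optional[dict] = None
    normalize_tracks: bool = True
    plots: bool = False

    @classmethod
    def from_dict(cls, raw: dict[str, Any], seed: Optional[int] = None) -> "RunConfig":
        raw = dict(raw)
        run_seed = int(raw.get("seed", 0) if seed is None else seed)
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            sim_raw["seed"] = run_seed
            sim = SimulationConfig.from_dict(sim_raw)
        samples = [
            SampleSpec(
                s["factor"], s["genotype"], int(s.get("temperature", 25)),
                int(s.get("replicate", 1)),
            )
            for s in raw.get("samples", [])
        ]
        return cls(
            raw=raw,
            seed=run_seed,
            simulate=sim,
            input_dir=Path(raw["input_dir"]) if "input_dir" in raw else None,
            samples=samples,
            contrasts=list(raw.get("contrasts", [])),
            classifier=dict(raw.get("classifier", {})),
            pathway=raw.get("pathway"),
            metagene=dict(raw.get("metagene", {})),
            peaks=dict(raw.get("peaks", {})),
            heatmap=dict(raw.get("heatmap", {})),
            amplicons=raw.get("amplicons"),
            normalize_tracks=bool(raw.get("normalize_tracks", True)),
            plots=bool(raw.get("plots", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, seed=seed)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(
            {"config": self.raw, "seed": self.seed}, sort_keys=True
        )
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate(config: RunConfig) -> list[str]:
    """Referential and numeric checks; an empty list means runnable."""
    findings: list[str] = []
    if config.simulate is None and config.input_dir is None:
        findings.append("config must provide either a 'simulate' block or 'input_dir'")
    if config.simulate is not None and not config.samples:
        findings.append("simulate mode requires a non-empty 'samples' list")
    declared = {(s.factor, s.genotype, s.temperature) for s in config.samples}
    for contrast in config.contrasts:
        mutant = contrast.get("mutant")
        wt = contrast.get("wt", "WT")
        temp = int(contrast.get("temperature", 25))
        if mutant is None:
            findings.append(f"contrast {contrast} lacks a 'mutant' genotype")
            continue
        if config.simulate is not None:
            if config.simulate is not None and mutant not in config.simulate.genotypes:
                findings.append(f"contrast mutant {mutant!r} not in simulated genotype table")
            for genotype in (wt, mutant):
                if ("PolII_total", genotype, temp) not in declared:
                    findings.append(
                        f"no PolII_total sample declared for {genotype} at {temp}C "
                        f"(needed by contrast {mutant} vs {wt})"
                    )
        mut_t = contrast.get("temperature")
        wt_t = contrast.get("wt_temperature", mut_t)
        if mut_t is not None and wt_t is not None and int(mut_t) != int(wt_t):
            findings.append(f"contrast {mutant} vs {wt} mixes temperatures")
    thr = config.classifier.get("ri_threshold", 1.5)
    if thr <= 0:
        findings.append(f"ri_threshold must be > 0, got {thr}")
    if config.pathway is not None:
        for key in ("cid", "cleavage"):
            genotype = config.pathway.get(key)
            if genotype is None:
                findings.append(f"pathway block lacks {key!r} genotype")
            elif genotype not in {c.get("mutant") for c in config.contrasts}:
                findings.append(
                    f"pathway {key} genotype {genotype!r} has no matching contrast"
                )
    return findings


def _find_track(
    tracks: list[CoverageTrack], factor: str, genotype: str, temperature: int
) -> CoverageTrack:
    for t in tracks:
        if (t.factor, t.genotype, t.temperature) == (factor, genotype, temperature):
            return t
    raise ValidationError(
        f"no track for factor={factor} genotype={genotype} temperature={temperature}C"
    )


def _plot_profile(profile, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(profile.positions, profile.mean, lw=1.2)
    ax.axvline(0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("position relative to anchor (nt)")
    ax.set_ylabel("mean signal")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every configured stage; returns the manifest dictionary.

    Any stage failure aborts with the stage name attached; outputs written
    before the failure are marked partial in the manifest.
    """
    findings = validate(config)
    if findings:
        raise ValidationError("config invalid: " + "; ".join(findings))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }
    stage = "setup"
    t_start = time.time()
    try:
        # -- inputs ---------------------------------------------------------
        stage = "inputs"
        t0 = time.time()
        truth = None
        if config.simulate is not None:
            units, chrom_sizes = make_toy_annotation(config.simulate, seed=config.seed)
            tracks, truth = simulate_tracks(
                config.simulate, units, config.samples, seed=config.seed
            )
            write_fixture(outdir / "fixture", units, chrom_sizes, tracks, truth, config.simulate)
        else:
            units, chrom_sizes, tracks = read_fixture(config.input_dir)
        write_units(units, outdir / "units.bed", outdir / "units.tsv")
        if config.normalize_tracks:
            tracks = [t.normalized() for t in tracks]
        manifest["n_units"] = len(units)
        manifest["n_tracks"] = len(tracks)
        manifest["tracks_normalized"] = config.normalize_tracks
        manifest["stages"]["inputs"] = round(time.time() - t0, 3)
        logger.info("inputs: %d units, %d tracks", len(units), len(tracks))

        # -- readthrough contrasts -----------------------------------------
        stage = "readthrough"
        t0 = time.time()
        classifier = config.classifier
        calls_by_genotype: dict[str, list] = {}
        defective_sets: dict[str, set[str]] = {}
        analyzed_sets: dict[str, set[str]] = {}
        for contrast in config.contrasts:
            mutant = contrast["mutant"]
            wt_name = contrast.get("wt", "WT")
            temp = int(contrast.get("temperature", 25))
            wt = _find_track(tracks, "PolII_total", wt_name, temp)
            mut = _find_track(tracks, "PolII_total", mutant, temp)
            calls = [
                readthrough_index(wt, mut, u, windows=DEFAULT_WINDOWS,
                                  smooth=int(classifier.get("smooth", 220)))
                for u in units
            ]
            calls = classify_all(
                calls,
                ri_threshold=float(classifier.get("ri_threshold", 1.5)),
                min_abs_increase=float(classifier.get("min_abs_increase", 0.0)),
                floor=classifier.get("low_signal_floor"),
                quantile=float(classifier.get("low_signal_quantile", 0.25)),
            )
            label = f"{mutant}_vs_{wt_name}_{temp}C"
            calls_by_genotype[mutant] = calls
            defective_sets[label] = {c.unit_id for c in calls if c.is_defective}
            analyzed_sets[label] = {c.unit_id for c in calls if not c.low_signal}
            calls_to_frame(calls).to_csv(
                outdir / f"calls_{label}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            class_fractions(calls).to_csv(
                outdir / f"class_fractions_{label}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            logger.info(
                "contrast %s: %d/%d defective (%d low-signal filtered)",
                label, len(defective_sets[label]), len(units),
                len(units) - len(analyzed_sets[label]),
            )
        manifest["stages"]["readthrough"] = round(time.time() - t0, 3)

        # -- overlap / venn -------------------------------------------------
        stage = "overlap"
        if len(defective_sets) >= 2:
            t0 = time.time()
            labels = list(defective_sets)[:2]
            universe = analyzed_sets[labels[0]] & analyzed_sets[labels[1]]
            a = defective_sets[labels[0]] & universe
            b = defective_sets[labels[1]] & universe
            result = overlap_test(a, b, universe)
            venn = venn_counts(a, b, universe)
            with open(outdir / "overlap.json", "w") as fh:
                json.dump(
                    {
                        "set_a": labels[0],
                        "set_b": labels[1],
                        "universe_size": result.universe_size,
                        "size_a": result.size_a,
                        "size_b": result.size_b,
                        "intersection": result.intersection,
                        "overlap_fraction": result.overlap_fraction,
                        "p_enrichment": result.p_enrichment,
                        "p_depletion": result.p_depletion,
                        "venn": venn._asdict(),
                    },
                    fh,
                    indent=2,
                )
            manifest["stages"]["overlap"] = round(time.time() - t0, 3)

        # -- pathway --------------------------------------------------------
        stage = "pathway"
        if config.pathway is not None:
            t0 = time.time()
            assignments, counts = pathway_assignment(
                calls_by_genotype,
                cid_genotype=config.pathway["cid"],
                cleavage_genotype=config.pathway["cleavage"],
            )
            pd.DataFrame(
                [
                    {
                        "unit_id": a.unit_id,
                        "cid_defective": a.cid_defective,
                        "cleavage_defective": a.cleavage_defective,
                        "category": a.category,
                    }
                    for a in assignments
                ]
            ).to_csv(outdir / "pathway_assignments.tsv", sep="\t", index=False)
            pd.DataFrame([counts]).to_csv(outdir / "pathway_counts.tsv", sep="\t", index=False)
            manifest["stages"]["pathway"] = round(time.time() - t0, 3)

        # -- metagenes ------------------------------------------------------
        stage = "metagene"
        t0 = time.time()
        mg = config.metagene
        cohorts = units_by_class(units)
        for cls in mg.get("classes", ["snoRNA"]):
            cohort = cohorts.get(cls, [])
            if not cohort:
                continue
            for track in tracks:
                if track.factor != "PolII_total":
                    continue
                matrix = build_matrix(
                    track, cohort,
                    upstream=int(mg.get("upstream", 500)),
                    downstream=int(mg.get("downstream", 1000)),
                    bin=int(mg.get("bin", 10)),
                    per_unit_normalize=bool(mg.get("per_unit_normalize", True)),
                )
                profile = metagene_profile(matrix, smooth_window=int(mg.get("smooth", 220)))
                name = f"metagene_{cls}_{track.label}"
                profile.to_frame().to_csv(
                    outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                if config.plots:
                    _plot_profile(profile, outdir / f"{name}.svg", name)
        manifest["stages"]["metagene"] = round(time.time() - t0, 3)

        # -- factor peaks and shift test ------------------------------------
        stage = "peaks"
        pk = config.peaks
        factor_names = pk.get("factors", [])
        if factor_names:
            t0 = time.time()
            cohort = cohorts.get(pk.get("cohort_class", "snoRNA"), [])
            genotype = pk.get("genotype", "WT")
            temp = int(pk.get("temperature", 25))
            peak_table = {}
            metagene_peaks = {}
            for factor in factor_names:
                track = _find_track(tracks, factor, genotype, temp)
                window = tuple(pk.get("windows", {}).get(factor, DEFAULT_PEAK_WINDOWS.get(factor, (-200, 600))))
                matrix = build_matrix(
                    track, cohort,
                    upstream=int(pk.get("upstream", 400)),
                    downstream=int(pk.get("downstream", 800)),
                    bin=int(pk.get("bin", 10)),
                )
                peak_table[factor] = per_unit_peaks(matrix, window, smooth_window=int(pk.get("smooth", 50)))
                profile = metagene_profile(matrix, smooth_window=int(pk.get("smooth", 50)))
                metagene_peaks[factor] = peak_position(profile.mean, profile.positions, window)
            peaks_frame = pd.DataFrame(peak_table)
            peaks_frame.index.name = "unit_id"
            peaks_frame.to_csv(outdir / "factor_peaks.tsv", sep="\t")
            summary: dict[str, Any] = {"metagene_peaks": metagene_peaks}
            if len(factor_names) == 2:
                f_a, f_b = factor_names
                shift = peak_shift_test(
                    peaks_frame[f_a].to_numpy(), peaks_frame[f_b].to_numpy(),
                    n_perm=int(pk.get("n_perm", 9999)), seed=config.seed,
                )
                summary["shift_test"] = {
                    "factor_a": f_a,
                    "factor_b": f_b,
                    "observed_shift": shift.observed_shift,
                    "p_value": shift.p_value,
                    "n_permutations": shift.n_permutations,
                    "exact": shift.exact,
                }
            with open(outdir / "peak_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["stages"]["peaks"] = round(time.time() - t0, 3)

        # -- heat map -------------------------------------------------------
        stage = "heatmap"
        if config.heatmap.get("enabled", True) and cohorts.get("snoRNA"):
            t0 = time.time()
            genotype = config.heatmap.get("genotype", "WT")
            temp = int(config.heatmap.get("temperature", 25))
            track = _find_track(tracks, "PolII_total", genotype, temp)
            matrix, order, markers = heatmap_matrix(
                track, cohorts["snoRNA"], bin=int(config.heatmap.get("bin", 10))
            )
            matrix.write_tsv(outdir / "heatmap_snoRNA.tsv")
            with open(outdir / "heatmap_markers.json", "w") as fh:
                json.dump({"row_order": order, "five_prime_markers": markers}, fh, indent=2)
            manifest["stages"]["heatmap"] = round(time.time() - t0, 3)

        # -- amplicon quantification ---------------------------------------
        stage = "amplicons"
        if config.amplicons is not None:
            t0 = time.time()
            panel = [
                Amplicon(
                    id=str(a["id"]),
                    region=GenomicRegion(a["chrom"], int(a["start"]), int(a["end"])),
                    role=a.get("role", "query"),
                )
                for a in config.amplicons.get("panel", [])
            ]
            factor = config.amplicons.get("factor", "PolII_total")
            genotype = config.amplicons.get("genotype", "WT")
            temp = int(config.amplicons.get("temperature", 25))
            replicates = [
                t for t in tracks
                if (t.factor, t.genotype, t.temperature) == (factor, genotype, temp)
            ]
            quants = amplicon_quant(replicates, panel)
            quant_to_frame(quants).to_csv(
                outdir / f"amplicon_quant_{factor}_{genotype}_{temp}C.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
            manifest["stages"]["amplicons"] = round(time.time() - t0, 3)

        manifest["complete"] = True
    except TermwindowError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise TermwindowError(f"stage {stage!r} failed: {exc}") from exc
    manifest["runtime_s"] = round(time.time() - t_start, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def demo_config_dict(seed: int = 0) -> dict[str, Any]:
    """Packaged demo: ~200 units, two mutant genotypes, two temperatures."""
    return {
        "seed": seed,
        "simulate": {
            "chrom_sizes": {"chrI": 400_000, "chrII": 400_000},
            "classes": {
                "snoRNA": {"n_units": 50, "length": [150, 500], "susceptible_fraction": 0.7},
                "CUT": {"n_units": 40, "length": [300, 600], "susceptible_fraction": 0.7},
                "SUT": {"n_units": 30, "length": [300, 600], "susceptible_fraction": 0.7},
                "XUT": {"n_units": 30, "length": [300, 600], "susceptible_fraction": 0.7},
                "NAPC": {
                    "n_units": 25, "length": [1000, 1800], "nbs_offset": 150,
                    "has_pas": True, "susceptible_fraction": 0.6,
                },
                "PC": {
                    "n_units": 25, "length": [1000, 1800], "has_proximal": False,
                    "has_distal": False, "has_pas": True, "susceptible_fraction": 0.8,
                },
            },
            "genotypes": {
                "WT": {},
                "cid-mut": {"distal": 0.2, "ser2p": 0.5},
                "cleavage-mut": {"pas": 0.1},
            },
            "depth": 1000.0,
            "background": 0.5,
        },
        "samples": [
            {"factor": "PolII_total", "genotype": "WT", "temperature": 25},
            {"factor": "PolII_total", "genotype": "WT", "temperature": 37},
            {"factor": "PolII_total", "genotype": "cid-mut", "temperature": 25},
            {"factor": "PolII_total", "genotype": "cid-mut", "temperature": 37},
            {"factor": "PolII_total", "genotype": "cleavage-mut", "temperature": 25},
            {"factor": "Nrd1", "genotype": "WT", "temperature": 25},
            {"factor": "Pcf11", "genotype": "WT", "temperature": 25},
        ],
        "contrasts": [
            {"mutant": "cid-mut", "wt": "WT", "temperature": 25},
            {"mutant": "cleavage-mut", "wt": "WT", "temperature": 25},
            {"mutant": "cid-mut", "wt": "WT", "temperature": 37},
        ],
        "classifier": {"ri_threshold": 1.5, "low_signal_quantile": 0.1},
        "pathway": {"cid": "cid-mut", "cleavage": "cleavage-mut"},
        "metagene": {"classes": ["snoRNA", "CUT"], "bin": 10},
        "peaks": {"factors": ["Nrd1", "Pcf11"], "cohort_class": "snoRNA", "n_perm": 9999},
        "heatmap": {"enabled": True, "bin": 10},
        "normalize_tracks": True,
        "plots": False,
    }
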