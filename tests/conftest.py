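import numpy as np
import pytest

from termwindow.annotation import TranscriptionUnit
from termwindow.synthetic import ClassGeometry, SimulationConfig
from termwindow.tracks_io import CoverageTrack


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(values, factor="PolII_total", genotype="WT", temperature=25, replicate=1):
    """Build a CoverageTrack from {chrom: array-like}."""
    return CoverageTrack(
        factor=factor,
        genotype=genotype,
        temperature=temperature,
        replicate=replicate,
        data={c: np.asarray(v, dtype=float) for c, v in values.items()},
    )


def plus_unit(
    uid="u1",
    unit_class="snoRNA",
    chrom="chrI",
    start=1000,
    mature_len=200,
    ext=250,
    nbs_offset=10,
):
    """A + strand snoRNA-style unit with simple geometry."""
    end = start + mature_len + ext
    mature_end = start + mature_len - 1
    return TranscriptionUnit(
        id=uid, unit_class=unit_class, chrom=chrom, start=start, end=end,
        strand="+", mature_end=mature_end, nbs_center=mature_end + nbs_offset,
    )


def minus_unit(uid="u1m", chrom="chrI", tss=5000, mature_len=200, ext=250, nbs_offset=10):
    start = tss - (mature_len + ext) + 1
    mature_end = tss - (mature_len - 1)
    return TranscriptionUnit(
        id=uid, unit_class="snoRNA", chrom=chrom, start=start, end=tss + 1,
        strand="-", mature_end=mature_end, nbs_center=mature_end - nbs_offset,
    )


def sno_config(n=10, chrom_len=200_000, seed=0, **class_kwargs):
    """Simulation config with snoRNA only."""
    return SimulationConfig(
        chrom_sizes={"chrI": chrom_len},
        classes={"snoRNA": ClassGeometry(n_units=n, **class_kwargs)},
        seed=seed,
    )
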