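import numpy as np
import pytest

from termwindow.annotation import write_units
from termwindow.errors import PlacementError, ValidationError
from termwindow.synthetic import (
    ClassGeometry,
    SimulationConfig,
    SimulationTruth,
    expected_occupancy,
    hazard_profile,
    make_toy_annotation,
    monte_carlo_occupancy,
    occupancy_from_hazard,
    read_fixture,
    simulate_tracks,
    write_fixture,
)

from conftest import sno_config


# -- annotation generator ---------------------------------------------------


class TestMakeToyAnnotation:
    def test_single_snoRNA(self):
        config = sno_config(n=1, chrom_len=10_000)
        units, sizes = make_toy_annotation(config)
        assert len(units) == 1
        u = units[0]
        assert u.unit_class == "snoRNA"
        if u.strand == "+":
            assert u.mature_end < u.end
        else:
            assert u.mature_end > u.start
        assert sizes == {"chrI": 10_000}

    def test_empty_config(self, tmp_path):
        config = SimulationConfig(chrom_sizes={"chrI": 10_000}, classes={})
        units, _ = make_toy_annotation(config)
        assert units == []
        write_units(units, tmp_path / "u.bed", tmp_path / "u.tsv")  # valid empty files
        assert (tmp_path / "u.bed").read_text() == ""
        assert (tmp_path / "u.tsv").read_text().startswith("id\t")

    def test_determinism_byte_identical(self, tmp_path):
        config = SimulationConfig(
            chrom_sizes={"chrI": 900_000, "chrII": 900_000},
            classes={c: ClassGeometry(n_units=50) for c in ("snoRNA", "CUT")},
            seed=1,
        )
        for run in ("a", "b"):
            units, _ = make_toy_annotation(config)
            write_units(units, tmp_path / f"{run}.bed", tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_placement_error_names_class(self):
        config = sno_config(n=100, chrom_len=5_000)
        with pytest.raises(PlacementError, match="snoRNA"):
            make_toy_annotation(config)

    def test_units_non_overlapping(self):
        config = sno_config(n=40, chrom_len=400_000, seed=3)
        units, _ = make_toy_annotation(config)
        spans = sorted((u.start, u.end) for u in units)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_non_pc_units_have_nbs(self):
        config = SimulationConfig(
            chrom_sizes={"chrI": 2_000_000},
            classes={
                "snoRNA": ClassGeometry(n_units=5),
                "CUT": ClassGeometry(n_units=5),
                "NAPC": ClassGeometry(n_units=5, length=(1000, 1500), nbs_offset=150, has_pas=True),
                "PC": ClassGeometry(n_units=5, length=(1000, 1500), has_proximal=False,
                                    has_distal=False, has_pas=True),
            },
        )
        units, _ = make_toy_annotation(config)
        for u in units:
            if u.unit_class == "PC":
                assert u.nbs_center is None
            else:
                assert u.nbs_center is not None
                # NBS lies within the unit or its downstream flank
                offset = u.transcript_offset(u.nbs_center)
                assert 0 <= offset < u.length + config.downstream_flank


# -- occupancy model --------------------------------------------------------


class TestExpectedOccupancy:
    def test_zero_hazard_flat(self):
        occ = occupancy_from_hazard(np.zeros(500), np.full(500, 0.02))
        np.testing.assert_allclose(occ, 0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            occupancy_from_hazard(np.array([-0.1]), np.array([1.0]))
        with pytest.raises(ValidationError):
            occupancy_from_hazard(np.array([0.5]), np.array([0.0]))

    def test_constant_hazard_survival(self):
        """h = 0.01/nt from the anchor: density at +100 = 0.99^100 of plateau."""
        hazard = np.concatenate([np.zeros(200), np.full(400, 0.01)])
        occ = occupancy_from_hazard(hazard, np.ones(600))
        plateau = occ[:200].mean()
        assert occ[300] / plateau == pytest.approx(0.99**100, rel=1e-12)

    def test_monte_carlo_oracle_constant_hazard(self, rng):
        """MC trajectory simulation agrees with the closed form within 3 SE."""
        n = 30_000
        hazard = np.concatenate([np.zeros(200), np.full(400, 0.01)])
        dwell = np.ones(600)
        mc = monte_carlo_occupancy(hazard, dwell, n, rng)
        closed = occupancy_from_hazard(hazard, dwell)
        p = closed[300]  # survival probability, Bernoulli per trajectory
        se = np.sqrt(p * (1 - p) / n)
        assert abs(mc[300] - p) < 3 * se

    def test_non_increasing_where_dwell_constant(self, rng):
        hazard = np.clip(rng.random(300) * 0.02, 0, 0.99)
        occ = occupancy_from_hazard(hazard, np.ones(300))
        assert np.all(np.diff(occ) <= 1e-15)

    def test_pause_pileup_phenotype(self):
        """5x dwell over [+50,+300] with weak distal hazard piles Pol II downstream."""
        hazard = np.zeros(600)
        hazard[250:350] = 0.015 * 0.2  # distal element at +50..+150, hazard x0.2
        dwell = np.ones(600)
        dwell[250:500] = 5.0  # pause zone [+50, +300] past the anchor at 200
        occ = occupancy_from_hazard(hazard, dwell)
        downstream = occ[300:500].mean()  # [+100, +300]
        upstream = occ[100:200].mean()  # [-100, 0]
        assert downstream > upstream

    def test_pause_pileup_monte_carlo(self, rng):
        hazard = np.zeros(600)
        hazard[250:350] = 0.003
        dwell = np.ones(600)
        dwell[250:] = 5.0
        mc = monte_carlo_occupancy(hazard, dwell, 20_000, rng)
        assert mc[300:500].mean() > mc[100:200].mean()

    def test_expected_occupancy_unit_api(self):
        config = sno_config(n=1, chrom_len=10_000)
        units, _ = make_toy_annotation(config)
        prof = expected_occupancy(units[0], config)
        assert len(prof.positions) == len(prof.density)
        assert np.all(prof.density >= 0)
        assert np.all(prof.density[prof.positions < 0] == 0)
        # flat upstream of the first hazard element
        body = prof.density[(prof.positions >= 0) & (prof.positions < 50)]
        np.testing.assert_allclose(body, body[0])

    def test_monte_carlo_convergence_invariant(self, rng):
        """Sup-norm error shrinks as trajectory count grows (1e4 vs 1e5-scale)."""
        hazard = np.concatenate([np.zeros(100), np.full(900, 0.004)])
        dwell = np.ones(1000)
        closed = occupancy_from_hazard(hazard, dwell)
        err_small = np.abs(monte_carlo_occupancy(hazard, dwell, 2_000, rng) - closed).max()
        err_large = np.abs(monte_carlo_occupancy(hazard, dwell, 50_000, rng) - closed).max()
        assert err_large < err_small


class TestHazardProfile:
    def test_temperature_shifts_survival_midpoint_downstream(self):
        config = sno_config(n=5, chrom_len=100_000)
        units, _ = make_toy_annotation(config)
        for u in units:
            cold = hazard_profile(u, config, "WT", 25)
            hot = hazard_profile(u, config, "WT", 37)

            def midpoint(h):
                surv = np.exp(np.concatenate(([0.0], np.cumsum(np.log1p(-h.hazard)))))
                return int(np.argmax(surv < 0.5))

            assert midpoint(hot) > midpoint(cold)

    def test_planted_defect_monotone_in_distal_multiplier(self):
        """Lowering the distal multiplier never rescues a defective unit."""
        base = sno_config(n=3, chrom_len=100_000)
        units, _ = make_toy_annotation(base)
        u = units[0]
        wt = hazard_profile(u, base, "WT", 25).cumulative_hazard
        previous_defect = False
        for mult in (1.0, 0.8, 0.5, 0.3, 0.2, 0.1, 0.05):
            config = sno_config(n=3, chrom_len=100_000)
            from termwindow.synthetic import GenotypeModifiers

            config.genotypes["mut"] = GenotypeModifiers(distal=mult)
            cum = hazard_profile(u, config, "mut", 25).cumulative_hazard
            defect = cum < config.defect_hazard_fraction * wt
            assert defect or not previous_defect  # once defective, stays defective
            previous_defect = defect

    def test_unknown_genotype(self):
        config = sno_config(n=1)
        units, _ = make_toy_annotation(config)
        with pytest.raises(ValidationError, match="nope"):
            hazard_profile(units[0], config, "nope", 25)


# -- track simulation -------------------------------------------------------


class TestSimulateTracks:
    def test_degenerate_depth_all_zero(self):
        config = sno_config(n=2, chrom_len=50_000)
        config.depth = 0.0
        config.background = 0.0
        units, _ = make_toy_annotation(config)
        tracks, _ = simulate_tracks(config, units, [("PolII_total", "WT", 25)])
        assert np.all(tracks[0].data["chrI"] == 0)

    def test_determinism(self):
        config = sno_config(n=5, chrom_len=100_000, seed=7)
        units, _ = make_toy_annotation(config)
        specs = [("PolII_total", "WT", 25), ("Nrd1", "WT", 25)]
        t1, _ = simulate_tracks(config, units, specs)
        t2, _ = simulate_tracks(config, units, specs)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.data["chrI"], b.data["chrI"])

    def test_unknown_factor_lists_supported(self):
        config = sno_config(n=1)
        units, _ = make_toy_annotation(config)
        with pytest.raises(ValidationError, match="PolII_total"):
            simulate_tracks(config, units, [("H3K4me3", "WT", 25)])

    def test_all_signals_finite_nonnegative(self):
        config = sno_config(n=3, chrom_len=80_000)
        units, _ = make_toy_annotation(config)
        specs = [(f, "WT", 25) for f in ("PolII_total", "PolII_Ser2P", "PolII_Ser5P",
                                         "Nrd1", "Pcf11", "RNADNA_hybrid")]
        tracks, _ = simulate_tracks(config, units, specs)
        for t in tracks:
            assert np.all(np.isfinite(t.data["chrI"]))
            assert np.all(t.data["chrI"] >= 0)

    def test_mutant_downstream_gain_matches_closed_form(self, rng):
        """Distal hazard x0.2 on one snoRNA: downstream window gain within 3 SE."""
        from termwindow.synthetic import GenotypeModifiers, hazard_profile as hp

        config = sno_config(n=1, chrom_len=50_000, length=(300, 300))
        config.depth = 20_000.0
        config.background = 0.0
        config.genotypes["mut"] = GenotypeModifiers(distal=0.2)
        units, _ = make_toy_annotation(config)
        u = units[0]
        tracks, _ = simulate_tracks(
            config, units, [("PolII_total", "WT", 25), ("PolII_total", "mut", 25)]
        )
        wt, mut = tracks
        anchor = u.anchor("mature_3p_end")
        rel = np.arange(150, 650)
        coords = anchor + rel if u.strand == "+" else anchor - rel
        obs_wt = wt.data["chrI"][coords].mean()
        obs_mut = mut.data["chrI"][coords].mean()
        assert obs_mut > obs_wt

        def closed_form(genotype):
            prof = hp(u, config, genotype, 25)
            occ = config.depth * config.init_rate * (
                np.exp(np.concatenate(([0.0], np.cumsum(np.log1p(-prof.hazard))[:-1])))
                * prof.dwell
            )
            anchor_rel = u.transcript_offset(anchor)
            return occ[anchor_rel + 150 : anchor_rel + 650]

        exp_wt, exp_mut = closed_form("WT"), closed_form("mut")
        ratio_expected = exp_mut.mean() / exp_wt.mean()
        ratio_observed = obs_mut / obs_wt
        n = len(rel)
        # delta method: the window means are sums of independent Poisson counts
        rel_var = exp_mut.sum() / (n * exp_mut.mean()) ** 2 + exp_wt.sum() / (n * exp_wt.mean()) ** 2
        se = ratio_expected * np.sqrt(rel_var)
        assert abs(ratio_observed - ratio_expected) < 3 * se

    def test_truth_silent_units_have_zero_rate(self):
        config = sno_config(n=10, chrom_len=200_000, silent_fraction=0.2)
        units, _ = make_toy_annotation(config)
        _, truth = simulate_tracks(config, units, [("PolII_total", "WT", 25)])
        silent = truth.per_unit[truth.per_unit["silent"]]
        assert len(silent) == 2  # exact planted count
        assert (silent["init_rate"] == 0).all()


# -- fixtures ---------------------------------------------------------------


class TestFixtureIO:
    def test_empty_fixture(self, tmp_path):
        write_fixture(tmp_path, [], {"chrI": 1000}, [])
        units, sizes, tracks = read_fixture(tmp_path)
        assert units == [] and tracks == []
        assert sizes == {"chrI": 1000}

    def test_round_trip_units_and_tracks(self, tmp_path):
        config = sno_config(n=10, chrom_len=200_000, seed=5)
        units, sizes = make_toy_annotation(config)
        tracks, truth = simulate_tracks(config, units, [("PolII_total", "WT", 25)])
        write_fixture(tmp_path, units, sizes, tracks, truth, config)
        units2, sizes2, tracks2 = read_fixture(tmp_path)
        assert len(units2) == 10
        for a, b in zip(units, units2):
            assert (a.id, a.start, a.end, a.strand, a.mature_end, a.nbs_center) == (
                b.id, b.start, b.end, b.strand, b.mature_end, b.nbs_center
            )
        np.testing.assert_array_equal(tracks[0].data["chrI"], tracks2[0].data["chrI"])

    def test_bedgraph_sum_preserved(self, tmp_path):
        config = sno_config(n=3, chrom_len=80_000, seed=2)
        units, sizes = make_toy_annotation(config)
        tracks, _ = simulate_tracks(
            config, units, [("PolII_total", "WT", 25), ("Nrd1", "WT", 25)]
        )
        sums_before = [t.data["chrI"].sum() for t in tracks]  # oracle: direct summation
        write_fixture(tmp_path, units, sizes, tracks)
        _, _, tracks2 = read_fixture(tmp_path)
        for expected, t in zip(sums_before, tracks2):
            assert t.data["chrI"].sum() == expected

    def test_truth_round_trip(self, tmp_path):
        config = sno_config(n=4, chrom_len=100_000)
        units, _ = make_toy_annotation(config)
        _, truth = simulate_tracks(config, units, [("PolII_total", "WT", 25)])
        truth.write(tmp_path)
        back = SimulationTruth.read(tmp_path)
        assert back.per_unit.shape == truth.per_unit.shape
        assert list(back.per_condition["unit_id"]) == list(truth.per_condition["unit_id"])
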