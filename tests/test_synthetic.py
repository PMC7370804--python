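"""Synthetic experiment generator: dynamics, reads, fixture files."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainvade.demux import MarkerDB, match_reads, reverse_complement
from strainvade.stats import MicrocosmDesign
from strainvade.synthetic import (
    SimulationConfig,
    StrainTrait,
    make_marker_db,
    make_traits,
    per_strain_inoculum,
    simulate_microcosm,
    simulate_reads,
)


def _design(strains, herbivore="none", density=0.0):
    return MicrocosmDesign("m1", "e", len(strains), tuple(strains),
                           herbivore, density)


def _uniform_traits(strains, rate=0.6, susceptibility=0.5):
    return {s: StrainTrait(s, rate, susceptibility) for s in strains}


class TestTraits:
    def test_invalid_trait_values_rejected(self):
        with pytest.raises(ValueError):
            StrainTrait("s", -0.1, 0.5)
        with pytest.raises(ValueError):
            StrainTrait("s", 0.5, 1.5)
        with pytest.raises(ValueError):
            StrainTrait("s", 0.5, 0.5, marker_copy_bias=0.0)

    def test_planted_growth_rate_spread(self):
        traits = make_traits(10, seed=3)
        rates = [t.growth_rate for t in traits.values()]
        assert max(rates) / min(rates) == pytest.approx(2.0)


class TestSimulateMicrocosm:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=1, n_strains=3, diversity_levels=(3,),
                               replicates_per_level=(1,))
        traits = _uniform_traits(["A", "B", "C"])
        d = _design(["A", "B", "C"])
        a = simulate_microcosm(d, traits, cfg, 42)
        b = simulate_microcosm(d, traits, cfg, 42)
        assert a.resident_biomass.equals(b.resident_biomass)
        assert a.strain_biomass.equals(b.strain_biomass)

    def test_identical_traits_equal_endpoints(self):
        """With identical traits and no grazer the strains are exchangeable,
        so endpoint biomasses must agree to numerical tolerance."""
        cfg = SimulationConfig(herbivore_regime="none", seed=1, n_strains=3,
                               diversity_levels=(3,), replicates_per_level=(1,))
        traits = _uniform_traits(["A", "B", "C"])
        sim = simulate_microcosm(_design(["A", "B", "C"]), traits, cfg, 0)
        end = sim.strain_biomass.iloc[-1]
        assert end.max() - end.min() < 1e-12 * end.max()

    def test_high_generalist_grazing_prevents_invasion(self):
        """Grazing mortality above the growth rate drives the invader to
        effectively zero: consumptive resistance."""
        cfg = SimulationConfig(herbivore_regime="generalist_high", seed=1,
                               n_strains=2, diversity_levels=(2,),
                               replicates_per_level=(1,))
        traits = _uniform_traits(["A", "B"], rate=0.8, susceptibility=1.0)
        sim = simulate_microcosm(_design(["A", "B"], "generalist", 1.5),
                                 traits, cfg, 0)
        inv = sim.strain_biomass.iloc[-1].sum()
        total = inv + sim.resident_biomass.iloc[-1].sum()
        assert inv / total < 1e-6
        # monotone decline from the invasion day onward
        traj = sim.strain_biomass.sum(axis=1).loc[cfg.invasion_day:]
        assert (np.diff(traj.values) <= 0).all()

    def test_invader_can_dominate_without_grazer(self):
        cfg = SimulationConfig(herbivore_regime="none", seed=1, n_strains=2,
                               diversity_levels=(2,), replicates_per_level=(1,))
        traits = _uniform_traits(["A", "B"], rate=0.9)
        sim = simulate_microcosm(_design(["A", "B"]), traits, cfg, 0)
        inv = sim.strain_biomass.iloc[-1].sum()
        share = inv / (inv + sim.resident_biomass.iloc[-1].sum())
        assert share > 0.5

    def test_unknown_strain_rejected(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(KeyError):
            simulate_microcosm(_design(["ZZZ"]), _uniform_traits(["A"]), cfg, 0)


class TestInoculum:
    @pytest.mark.parametrize("level, expected", [
        (10, 0.01), (1, 0.1), (3, 0.1 / 3),
    ])
    def test_substitutive_split(self, level, expected):
        assert per_strain_inoculum(0.1, level) == pytest.approx(
            expected, abs=1e-12
        )

    @given(total=st.floats(min_value=1e-3, max_value=10.0),
           level=st.integers(min_value=1, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, total, level):
        assert per_strain_inoculum(total, level) * level == pytest.approx(
            total, abs=1e-12
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            per_strain_inoculum(0.0, 3)
        with pytest.raises(ValueError):
            per_strain_inoculum(0.1, 0)


class TestSimulateReads:
    def setup_method(self):
        self.db = make_marker_db(["A", "B"], seed=0, length=60)

    def test_depth_zero_empty(self):
        assert simulate_reads({"A": 1.0}, self.db, 0, seed=1) == []

    def test_single_strain_all_exact(self):
        reads = simulate_reads({"A": 1.0}, self.db, 500, seed=1)
        marker = self.db.records["A"][0]
        assert len(reads) == 500
        assert all(r in (marker, reverse_complement(marker)) for r in reads)

    def test_three_to_one_ratio_recovered(self):
        depth = 10_000
        reads = simulate_reads({"A": 3.0, "B": 1.0}, self.db, depth, seed=2)
        counts = match_reads(reads, self.db)
        sd = np.sqrt(0.75 * 0.25 / depth)
        assert abs(counts.counts["A"] / depth - 0.75) < 3 * sd

    def test_copy_bias_shifts_read_shares(self):
        traits = {"A": StrainTrait("A", 0.5, 0.5, marker_copy_bias=3.0),
                  "B": StrainTrait("B", 0.5, 0.5, marker_copy_bias=1.0)}
        reads = simulate_reads({"A": 1.0, "B": 1.0}, self.db, 10_000, seed=3,
                               traits=traits)
        counts = match_reads(reads, self.db)
        assert counts.counts["A"] / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_error_rate_breaks_exact_matching(self):
        reads = simulate_reads({"A": 1.0}, self.db, 2000, seed=4,
                               error_rate=0.01)
        counts = match_reads(reads, self.db)
        assert counts.n_unmatched > 0
        # error-free fraction ≈ (1-ε)^L = 0.99^60 ≈ 0.547
        assert counts.counts["A"] / 2000 == pytest.approx(0.547, abs=0.05)

    def test_strain_without_marker_rejected(self):
        with pytest.raises(KeyError):
            simulate_reads({"C": 1.0}, self.db, 10, seed=1)

    def test_seeded_determinism(self):
        a = simulate_reads({"A": 2.0, "B": 1.0}, self.db, 300, seed=9)
        b = simulate_reads({"A": 2.0, "B": 1.0}, self.db, 300, seed=9)
        assert a == b


class TestGenerateExperiment:
    def test_all_fixture_files_written(self, small_experiment):
        _, bundle, out = small_experiment
        for key in ("design", "census", "markers", "cnp", "truth"):
            assert bundle.paths[key].exists()
        assert len(bundle.read_paths) == 2 * sum(
            1 for d in bundle.designs if d.diversity_level >= 1
        )

    def test_every_read_sample_has_a_design(self, small_experiment):
        _, bundle, _ = small_experiment
        ids = {d.microcosm_id for d in bundle.designs}
        for sample in bundle.read_paths:
            micro = sample.rsplit("_", 1)[0]
            assert micro in ids

    def test_truth_matches_census_invader_biomass(self, small_experiment):
        _, bundle, _ = small_experiment
        census = bundle.census
        truth = bundle.strain_biomass_truth
        from strainvade.biovolume import census_to_biomass

        biomass = census_to_biomass(census)
        for (micro, day), grp in truth.groupby(["microcosm_id", "day"]):
            sid = f"{micro}_d{day}"
            inv = biomass[(biomass["sample_id"] == sid)
                          & (biomass["species_id"] == "invader")]
            assert inv["biomass_ug_ml"].iloc[0] == pytest.approx(
                grp["biomass_ug_ml"].sum(), rel=1e-6
            )

    def test_byte_identical_regeneration(self, small_experiment, tmp_path):
        config, bundle, out = small_experiment
        from strainvade.synthetic import generate_experiment

        again = generate_experiment(config, tmp_path / "again")
        for key in ("design", "census", "markers", "cnp", "truth"):
            assert bundle.paths[key].read_bytes() == \
                again.paths[key].read_bytes()
        for sample, path in bundle.read_paths.items():
            assert path.read_bytes() == again.read_paths[sample].read_bytes()


class TestMarkerGeneration:
    def test_markers_unique_and_orientation_distinct(self):
        db = make_marker_db([f"S{i}" for i in range(20)], seed=5, length=50)
        seqs = [m for ms in db.records.values() for m in ms]
        all_orient = seqs + [reverse_complement(s) for s in seqs]
        assert len(set(all_orient)) == len(all_orient)

    def test_groups_passed_through(self):
        db = make_marker_db(["A", "B", "C"], seed=1,
                            groups=[("A", "B")])
        assert db.groups == [frozenset({"A", "B"})]
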