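"""Simulator: root composition, branch evolution, truth-log replay."""

import numpy as np
import pytest

from denovoscenario import (
    BirthOp,
    SimConfig,
    SubstitutionModel,
    evolve_branch,
    replay_events,
    simulate_catalogue,
    simulate_root,
    write_simulation,
)
from denovoscenario.features import RULE_ATG, scan_orfs
from denovoscenario.sequtil import gc_fraction

from conftest import RECOVERY_TREE


class TestSimulateRoot:
    def test_empty(self, rng):
        assert simulate_root(0, 0.5, rng) == ""

    def test_pure_gc(self, rng):
        seq = simulate_root(100, 1.0, rng)
        assert set(seq) <= {"G", "C"}

    def test_empirical_gc_within_binomial_noise(self):
        rng = np.random.default_rng(1)
        seq = simulate_root(10_000, 0.40, rng)
        # 3 binomial SDs: sqrt(0.4*0.6/10000) ~ 0.0049
        assert abs(gc_fraction(seq) - 0.40) <= 0.015

    def test_negative_length_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_root(-1, 0.5, rng)


class TestEvolveBranch:
    def test_zero_branch_is_identity(self, rng):
        seq = simulate_root(200, 0.4, rng)
        child, events = evolve_branch(seq, 0.0, SubstitutionModel(), rng)
        assert child == seq and events == []

    def test_negative_branch_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_branch("ACGT", -0.1, SubstitutionModel(), rng)

    def test_substitution_count_poisson_scale(self):
        # expected ~ t*L = 500 net changes, within 3*sqrt(500)
        rng = np.random.default_rng(7)
        seq = simulate_root(10_000, 0.5, rng)
        model = SubstitutionModel.from_gc(0.5, kappa=2.0)
        child, events = evolve_branch(seq, 0.05, model, rng)
        n_subs = sum(1 for e in events if e["kind"] == "sub")
        assert abs(n_subs - 500) <= 3 * np.sqrt(500)
        assert replay_events(seq, events) == child

    def test_saturation_reaches_stationary_gc(self):
        rng = np.random.default_rng(3)
        seq = simulate_root(10_000, 0.20, rng)
        model = SubstitutionModel.from_gc(0.60)
        child, _ = evolve_branch(seq, 50.0, model, rng)
        assert abs(gc_fraction(child) - 0.60) <= 0.02

    def test_jukes_cantor_transversions_twice_transitions(self):
        # kappa=1, uniform frequencies: every substitution type equally
        # likely, so transversions (8 types) are twice transitions (4)
        rng = np.random.default_rng(11)
        model = SubstitutionModel.from_gc(0.5, kappa=1.0)
        ts = tv = 0
        for _ in range(20):
            seq = simulate_root(10_000, 0.5, rng)
            _, events = evolve_branch(seq, 0.04, model, rng)
            for e in events:
                if e["kind"] != "sub":
                    continue
                if {e["old"], e["new"]} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
        total = ts + tv
        assert total >= 5000
        assert abs(ts - tv / 2) <= 4 * np.sqrt(total)

    def test_indel_events_replay(self, rng):
        seq = simulate_root(2_000, 0.4, rng)
        model = SubstitutionModel.from_gc(0.4)
        child, events = evolve_branch(
            seq, 0.1, model, rng, indel_rate=1.0, indel_mean_len=2.0
        )
        assert any(e["kind"] in ("ins", "del") for e in events)
        assert replay_events(seq, events) == child


class TestSimulateCatalogue:
    def test_empty_config(self):
        config = SimConfig(
            n_loci_per_class={"S0+": 0, "S1": 0, "S2": 0, "intergene": 0}
        )
        result = simulate_catalogue(config)
        assert result.catalogue == [] and result.truth.loci == []

    def test_class_counts_match_config(self, small_sim):
        config, sim = small_sim
        counts = {}
        for entry in sim.catalogue:
            counts[entry.conservation_class] = (
                counts.get(entry.conservation_class, 0) + 1
            )
        assert counts == config.n_loci_per_class

    def test_catalogue_coordinates_point_at_core(self, small_sim):
        _, sim = small_sim
        chrom = sim.genomes["cerevisiae"]["chr1"]
        for entry in sim.catalogue:
            truth = sim.truth.locus(entry.id)
            assert chrom[entry.start - 1 : entry.end] == (
                truth.node_seqs["cerevisiae"]["core"]
            )

    def test_replay_reproduces_every_child(self, small_sim):
        _, sim = small_sim
        for locus in sim.truth.loci:
            for edge, seg_events in locus.events.items():
                parent, child = edge.split("->")
                for segment, events in seg_events.items():
                    assert (
                        replay_events(locus.node_seqs[parent][segment], events)
                        == locus.node_seqs[child][segment]
                    )

    def test_same_seed_byte_identical(self, tmp_path):
        config = SimConfig(
            n_loci_per_class={"S0+": 3, "S1": 0, "S2": 0, "intergene": 5},
            locus_length=90,
            flank_length=30,
            seed=4,
        )
        for d in ("a", "b"):
            write_simulation(simulate_catalogue(config), tmp_path / d)
        for name in ("cerevisiae.fa", "catalogue.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_stop_removal_extends_most_upstream_orf(self):
        """Injected stop removals lengthen the most-upstream-ATG ORF of
        the focal species relative to the true A1 ancestor."""
        config = SimConfig(
            tree_spec=RECOVERY_TREE,
            n_loci_per_class={"S0+": 0, "S1": 300, "S2": 0, "intergene": 0},
            locus_length=300,
            flank_length=50,
            seed=123,
            birth_ops={
                "S0+": [],
                "S2": [],
                "intergene": [],
                "S1": [BirthOp("stop_removal", ("A1", "cerevisiae"))],
            },
        )
        sim = simulate_catalogue(config)

        def most_upstream_orf_len(seq):
            orfs = scan_orfs(seq, RULE_ATG)
            if not orfs:
                return 0
            first = min(o.start for o in orfs)
            return max(o.length for o in orfs if o.start == first)

        extended = sum(
            most_upstream_orf_len(loc.node_seqs["cerevisiae"]["core"])
            > most_upstream_orf_len(loc.node_seqs["A1"]["core"])
            for loc in sim.truth.loci
        )
        assert extended / len(sim.truth.loci) >= 0.80

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValueError):
            simulate_catalogue(SimConfig(tree_spec="((a,b);"))

    def test_truth_log_roundtrip(self, small_sim, tmp_path):
        _, sim = small_sim
        sim.truth.to_json(tmp_path / "t.json")
        from denovoscenario import TruthLog

        back = TruthLog.from_json(tmp_path / "t.json")
        assert back.loci[0].node_seqs == sim.truth.loci[0].node_seqs
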