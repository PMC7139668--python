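"""Generator contracts: determinism, designed truth, degenerate configs."""

import numpy as np
import pandas as pd
import pytest

from cistrokit import simulate as sim
from cistrokit.expression import de_filter, de_test
from cistrokit.intervals import overlap_partition
from cistrokit.loops import loop_count_stratify, se_overlap_fraction
from cistrokit.motifs import percent_of_targets
from cistrokit.simulate import FixtureConfig


def cistrome_cfg(**overrides):
    params = {
        "n_era": 60, "n_nr2f2": 40, "n_shared": 20, "peak_width": 400,
        "slot_spacing": 3000, "genome_start": 10_000, "chrom": "chrS",
        "frag_length": 200, "frag_jitter": 500,
        "frag_mean_shared": 30.0, "frag_mean_only_a": 5.0,
        "frag_mean_only_b": 5.0, "background_fragments": 100,
    }
    params.update(overrides)
    return FixtureConfig("toy", seed=5, params=params)


class TestFixtureConfigs:
    def test_all_packaged_fixtures_load(self):
        for name in sim.FIXTURES:
            cfg = sim.load_fixture(name)
            assert cfg.fixture == name and isinstance(cfg.seed, int)

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            sim.load_fixture("nope")

    def test_parse_types_and_errors(self):
        cfg = sim.parse_fixture("fixture = x\nseed = 3\na = 2\nb = 2.5\nc = hi\n")
        assert cfg["a"] == 2 and cfg["b"] == 2.5 and cfg["c"] == "hi"
        with pytest.raises(ValueError):
            sim.parse_fixture("a = 1\n")  # no fixture/seed
        with pytest.raises(KeyError, match="missing"):
            _ = sim.parse_fixture("fixture = x\nseed = 1\n")["missing"]


class TestGenCistrome:
    def test_designed_fraction_recovered(self):
        a, b, truth = sim.gen_cistrome(cistrome_cfg())
        part = overlap_partition(a, b)
        assert part.shared_percent_b() == pytest.approx(50.0)
        assert len(a) == 60 and len(b) == 40

    def test_shared_zero_and_full(self):
        a, b, _ = sim.gen_cistrome(cistrome_cfg(n_shared=0))
        part = overlap_partition(a, b)
        assert len(part.shared_b) == 0
        a, b, _ = sim.gen_cistrome(cistrome_cfg(n_shared=40))
        part = overlap_partition(a, b)
        assert len(part.only_b) == 0

    def test_infeasible_designs_error(self):
        with pytest.raises(ValueError, match="exceed"):
            sim.gen_cistrome(cistrome_cfg(n_shared=50))
        with pytest.raises(ValueError, match="genome_length"):
            sim.gen_cistrome(cistrome_cfg(genome_length=1000))

    def test_deterministic(self):
        a1, b1, t1 = sim.gen_cistrome(cistrome_cfg())
        a2, b2, t2 = sim.gen_cistrome(cistrome_cfg())
        assert [(p.start, p.summit) for p in a1] == [(p.start, p.summit) for p in a2]
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_changes_placement_not_fraction(self):
        a1, b1, _ = sim.gen_cistrome(cistrome_cfg(), seed=1)
        a2, b2, _ = sim.gen_cistrome(cistrome_cfg(), seed=2)
        assert [p.start for p in a1] != [p.start for p in a2]
        assert overlap_partition(a1, b1).shared_percent_b() == \
            overlap_partition(a2, b2).shared_percent_b()


class TestGenFragments:
    def test_empty_when_rates_zero(self):
        cfg = cistrome_cfg(frag_mean_shared=0.0, frag_mean_only_a=0.0,
                           frag_mean_only_b=0.0, background_fragments=0)
        _, b, truth = sim.gen_cistrome(cfg)
        class_of = dict(zip(truth["peak"], truth["cls"]))
        frags = sim.gen_fragments(cfg, b, class_of, sim.cistrome_genome_length(cfg))
        assert len(frags) == 0

    def test_deterministic(self):
        cfg = cistrome_cfg()
        _, b, truth = sim.gen_cistrome(cfg)
        class_of = dict(zip(truth["peak"], truth["cls"]))
        f1 = sim.gen_fragments(cfg, b, class_of, sim.cistrome_genome_length(cfg))
        f2 = sim.gen_fragments(cfg, b, class_of, sim.cistrome_genome_length(cfg))
        assert [(f.start, f.end) for f in f1.fragments] == \
            [(f.start, f.end) for f in f2.fragments]


class TestGenSequences:
    def _cfg(self, n, embed):
        return FixtureConfig("toy", seed=11, params={
            "motif": "GATA3", "seq_length": 100, "gc": 0.5,
            "class_x_n": n, "class_x_embedded": embed,
        })

    def test_embed_zero_and_full(self, gata3):
        seqs, _ = sim.gen_sequences(self._cfg(50, 0), pwm=gata3)
        assert percent_of_targets(gata3, seqs["x"])[2] == 0.0
        seqs, _ = sim.gen_sequences(self._cfg(50, 50), pwm=gata3)
        assert percent_of_targets(gata3, seqs["x"])[2] == 100.0

    def test_sequence_length_and_alphabet(self, gata3):
        seqs, _ = sim.gen_sequences(self._cfg(20, 5), pwm=gata3)
        for s in seqs["x"].values():
            assert len(s) == 100 and set(s) <= set("ACGT")

    def test_deterministic(self, gata3):
        s1, _ = sim.gen_sequences(self._cfg(30, 10), pwm=gata3)
        s2, _ = sim.gen_sequences(self._cfg(30, 10), pwm=gata3)
        assert s1 == s2

    def test_invalid_embed_count(self, gata3):
        with pytest.raises(ValueError, match="embed"):
            sim.gen_sequences(self._cfg(10, 11), pwm=gata3)


class TestGenLoopsSe:
    def _cfg(self, **overrides):
        params = {
            "chrom": "chrS", "n_se": 20, "daughters_per_se": 2,
            "mothers_looped": 10, "daughters_looped": 8,
            "mothers_peak_only": 2, "extra_multi": 5, "extra_single": 5,
            "extra_none": 5, "mother_width": 2000, "daughter_width": 1000,
            "peak_width": 400, "anchor_pad": 100, "se_spacing": 12_000,
        }
        params.update(overrides)
        return FixtureConfig("toy", seed=21, params=params)

    def test_designed_fractions(self):
        regions, loops, peaks, _ = sim.gen_loops_and_se(self._cfg())
        strat = loop_count_stratify(peaks, loops)
        fr = se_overlap_fraction(regions, peaks, strat)
        assert fr["mother"] == 50.0
        assert fr["daughter"] == 20.0

    def test_zero_and_full_looping(self):
        regions, loops, peaks, _ = sim.gen_loops_and_se(
            self._cfg(mothers_looped=0, daughters_looped=0, mothers_peak_only=5)
        )
        strat = loop_count_stratify(peaks, loops)
        fr = se_overlap_fraction(regions, peaks, strat)
        assert fr == {"mother": 0.0, "daughter": 0.0}
        regions, loops, peaks, _ = sim.gen_loops_and_se(
            self._cfg(mothers_looped=20, daughters_looped=40,
                      mothers_peak_only=0)
        )
        strat = loop_count_stratify(peaks, loops)
        fr = se_overlap_fraction(regions, peaks, strat)
        assert fr == {"mother": 100.0, "daughter": 100.0}

    def test_designed_strata_counts(self):
        _, loops, peaks, truth = sim.gen_loops_and_se(self._cfg())
        strat = loop_count_stratify(peaks, loops)
        for _, row in truth.iterrows():
            assert strat.counts[row["peak"]] == row["designed_loops"]

    def test_infeasible_errors(self):
        with pytest.raises(ValueError, match="looped"):
            sim.gen_loops_and_se(self._cfg(mothers_looped=25))
        with pytest.raises(ValueError, match="spacing"):
            sim.gen_loops_and_se(self._cfg(se_spacing=3000))


class TestGenCounts:
    def _cfg(self, **overrides):
        params = {
            "n_genes": 300, "n_down": 30, "n_up": 40, "samples_per_group": 6,
            "base_mean": 500.0, "dispersion": 0.01, "log2fc": 2.0,
            "n_se_genes": 50, "n_se_de": 20,
        }
        params.update(overrides)
        return FixtureConfig("toy", seed=31, params=params)

    def test_designed_recovery_small(self):
        cm, truth = sim.gen_counts_matrix(self._cfg())
        res = de_test(cm)
        down, up = de_filter(res)
        assert (len(down), len(up)) == (30, 40)
        assert truth["se_flag"].sum() == 50

    def test_zero_designed_de(self):
        cm, _ = sim.gen_counts_matrix(self._cfg(n_down=0, n_up=0, n_se_de=0))
        res = de_test(cm)
        down, up = de_filter(res)
        assert (len(down), len(up)) == (0, 0)

    def test_balanced_group_library_sizes(self, de_data):
        """The designed baseline shift keeps group library sizes matched, so
        CPM normalization stays composition-unbiased."""
        cm = de_data["cm"]
        libs = cm.library_sizes()
        ctrl = libs[cm.samples_in("control")].mean()
        kd = libs[cm.samples_in("knockdown")].mean()
        assert abs(np.log2(ctrl / kd)) < 0.05

    def test_deterministic(self):
        cm1, t1 = sim.gen_counts_matrix(self._cfg())
        cm2, t2 = sim.gen_counts_matrix(self._cfg())
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="dispersion"):
            sim.gen_counts_matrix(self._cfg(dispersion=-0.1))
        with pytest.raises(ValueError, match="exceed"):
            sim.gen_counts_matrix(self._cfg(n_down=200, n_up=200))
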