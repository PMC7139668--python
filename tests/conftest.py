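"""Shared fixtures: the packaged synthetic datasets, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cistrokit import simulate as sim
from cistrokit.expression import de_filter, de_test
from cistrokit.intervals import overlap_partition
from cistrokit.loops import loop_count_stratify
from cistrokit.motifs import load_motif_library


@pytest.fixture(scope="session")
def motif_library():
    return load_motif_library()


@pytest.fixture(scope="session")
def gata3(motif_library):
    return motif_library["GATA3"]


@pytest.fixture(scope="session")
def mcf7_data():
    cfg = sim.load_fixture("mcf7_like")
    era, nr2f2, truth = sim.gen_cistrome(cfg)
    part = overlap_partition(era, nr2f2, min_overlap=1)
    return {"cfg": cfg, "era": era, "nr2f2": nr2f2, "truth": truth, "part": part}


@pytest.fixture(scope="session")
def mcf7_fragments(mcf7_data):
    cfg = mcf7_data["cfg"]
    truth = mcf7_data["truth"]
    class_of = dict(zip(truth["peak"], truth["cls"]))
    return sim.gen_fragments(
        cfg, mcf7_data["nr2f2"], class_of, sim.cistrome_genome_length(cfg),
        label="NR2F2_chip",
    )


@pytest.fixture(scope="session")
def se_data():
    cfg = sim.load_fixture("se_loops")
    regions, loops, peaks, truth = sim.gen_loops_and_se(cfg)
    strat = loop_count_stratify(peaks, loops)
    return {"cfg": cfg, "regions": regions, "loops": loops, "peaks": peaks,
            "truth": truth, "strat": strat}


@pytest.fixture(scope="session")
def motif_classes(gata3):
    cfg = sim.load_fixture("motif_freq")
    seqs, truth = sim.gen_sequences(cfg, pwm=gata3)
    return {"cfg": cfg, "seqs": seqs, "truth": truth}


@pytest.fixture(scope="session")
def de_data():
    cfg = sim.load_fixture("de_se_genes")
    cm, truth = sim.gen_counts_matrix(cfg)
    results = de_test(cm)
    down, up = de_filter(results)
    return {"cfg": cfg, "cm": cm, "truth": truth, "results": results,
            "down": down, "up": up}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
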