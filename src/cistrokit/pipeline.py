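"""End-to-end orchestration of the fixture-driven analysis stages.

``run_pipeline`` executes, in order: cistrome overlap partitioning with
summit-centered signal profiles, known-motif occurrence on the sequence
classes, loop stratification with super-enhancer occupancy, differential
expression with SE-gene intersection, and the survival comparison.  Every
stage logs its parameters and record counts, writes its tables under the
run directory, and contributes scalar quantities to a single report whose
serialization is byte-identical across re-runs with the same configuration
and seed.  Removing a stage from ``stages`` disables only that stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import loops as lp
from . import motifs as mf
from . import signal as sg
from . import simulate as sim
from . import survival as sv
from .expression import de_filter, de_test, se_gene_de_count
from .intervals import overlap_partition

log = logging.getLogger(__name__)

ALL_STAGES = ("cistrome", "motif", "loops", "de", "survival")


@dataclass
class PipelineConfig:
    """Run-level configuration; fixture-driven by default."""

    outdir: Path = Path("cistrokit_run")
    seed: int | None = None  # None -> each fixture's packaged seed
    stages: tuple[str, ...] = ALL_STAGES
    min_overlap: int = 1
    profile_flank: int = 500
    profile_bin: int = 10
    rpkm_flank: int = 50
    fc_min: float = 1.5
    fdr_max: float = 0.01
    min_loops: int = 1
    split_quantile: float = 0.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.min_overlap < 1 or self.profile_flank < 1 or self.rpkm_flank < 0:
            raise ValueError("thresholds outside documented ranges")
        if not (0 < self.split_quantile < 1):
            raise ValueError("split_quantile must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _seed_for(config: PipelineConfig, stage_index: int) -> int | None:
    if config.seed is None:
        return None
    return (int(config.seed) * 1_000_003 + stage_index) % (2**31)


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def stage_cistrome(config: PipelineConfig, outdir: Path) -> dict:
    cfg = sim.load_fixture("mcf7_like")
    seed = _seed_for(config, 1)
    era, nr2f2, truth = sim.gen_cistrome(cfg, seed=seed)
    log.info("cistrome: %d ERa peaks, %d NR2F2 peaks, min_overlap=%d",
             len(era), len(nr2f2), config.min_overlap)
    part = overlap_partition(era, nr2f2, min_overlap=config.min_overlap)
    class_of = dict(zip(truth["peak"], truth["cls"]))
    frags = sim.gen_fragments(
        cfg, nr2f2, class_of, sim.cistrome_genome_length(cfg),
        seed=None if seed is None else seed + 101, label="NR2F2_chip",
    )
    shared_names = truth.loc[
        (truth["set"] == "nr2f2") & (truth["cls"] == "shared"), "peak"
    ]
    only_names = truth.loc[
        (truth["set"] == "nr2f2") & (truth["cls"] == "only_b"), "peak"
    ]
    prof_shared = sg.tag_density_profile(
        nr2f2.subset(shared_names), frags,
        flank=config.profile_flank, bin_size=config.profile_bin,
    )
    prof_only = sg.tag_density_profile(
        nr2f2.subset(only_names), frags,
        flank=config.profile_flank, bin_size=config.profile_bin,
    )
    sg.write_profile_tsv(prof_shared, outdir / "profile_nr2f2_shared.tsv")
    sg.write_profile_tsv(prof_only, outdir / "profile_nr2f2_only.tsv")
    pd.DataFrame(
        {
            "component": ["shared_era", "only_era", "shared_nr2f2", "only_nr2f2"],
            "n_peaks": [len(part.shared_a), len(part.only_a),
                        len(part.shared_b), len(part.only_b)],
        }
    ).to_csv(outdir / "partition_counts.tsv", sep="\t", index=False)
    return {
        "cistrome.n_era": len(era),
        "cistrome.n_nr2f2": len(nr2f2),
        "cistrome.shared_percent_nr2f2": part.shared_percent_b(),
        "cistrome.shared_percent_era": part.shared_percent_a(),
        "cistrome.profile_center_shared": float(
            prof_shared.values[len(prof_shared.values) // 2]
        ),
        "cistrome.profile_center_only": float(
            prof_only.values[len(prof_only.values) // 2]
        ),
    }


def stage_motif(config: PipelineConfig, outdir: Path) -> dict:
    cfg = sim.load_fixture("motif_freq")
    pwm = mf.load_motif_library()[str(cfg["motif"])]
    seqs, _ = sim.gen_sequences(cfg, seed=_seed_for(config, 2), pwm=pwm)
    log.info("motif: %s over classes %s", pwm.name, sorted(seqs))
    report: dict = {}
    rows = []
    for cls, class_seqs in sorted(seqs.items()):
        k, n, pct = mf.percent_of_targets(pwm, class_seqs)
        report[f"motif.percent_of_target_{cls}"] = pct
        rows.append({"class": cls, "motif": pwm.name, "k": k, "n": n,
                     "percent_of_target": round(pct, 2)})
    enr = mf.motif_enrichment_test(pwm, seqs["shared"], seqs["only_era"])
    report["motif.enrichment_p_shared_vs_only"] = enr.p
    pd.DataFrame(rows).to_csv(outdir / "motif_percents.tsv", sep="\t", index=False)
    return report


def stage_loops(config: PipelineConfig, outdir: Path) -> dict:
    cfg = sim.load_fixture("se_loops")
    seed = _seed_for(config, 3)
    regions, loop_list, peaks, truth = sim.gen_loops_and_se(cfg, seed=seed)
    log.info("loops: %d SE regions, %d loops, %d peaks",
             len(regions), len(loop_list), len(peaks))
    strat = lp.loop_count_stratify(peaks, loop_list)
    strat.to_frame().to_csv(outdir / "loop_strata.tsv", sep="\t", index=False)
    class_of = {
        name: {0: "none", 1: "single"}.get(count, "multi")
        for name, count in strat.counts.items()
    }
    frags = sim.gen_fragments(
        cfg, peaks, class_of, sim.se_genome_length(cfg),
        seed=None if seed is None else seed + 101, label="NR2F2_chip",
    )
    rpkm = sg.rpkm_summit(peaks, frags, flank=config.rpkm_flank)
    comparisons = lp.compare_intensity_by_stratum(rpkm, strat)
    fractions = lp.se_overlap_fraction(regions, peaks, strat,
                                       min_loops=config.min_loops)
    sizes = strat.stratum_sizes()
    report = {
        "loops.stratum_size_0": sizes["0"],
        "loops.stratum_size_1": sizes["1"],
        "loops.stratum_size_ge2": sizes[">=2"],
        "loops.se_mother_percent": fractions["mother"],
        "loops.se_daughter_percent": fractions["daughter"],
    }
    rows = []
    for c in comparisons:
        key = f"loops.mw_p_{c.stratum_a.replace('>=', 'ge')}_vs_{c.stratum_b}"
        report[key] = c.result.p if c.result else float("nan")
        rows.append({
            "stratum_a": c.stratum_a, "stratum_b": c.stratum_b,
            "U": c.result.statistic if c.result else "NA",
            "p": _fmt(c.result.p) if c.result else "NA",
            "median_a": _fmt(c.median_a), "median_b": _fmt(c.median_b),
        })
    pd.DataFrame(rows).to_csv(outdir / "loop_intensity_tests.tsv", sep="\t",
                              index=False)
    return report


def stage_de(config: PipelineConfig, outdir: Path) -> dict:
    cfg = sim.load_fixture("de_se_genes")
    cm, truth = sim.gen_counts_matrix(cfg, seed=_seed_for(config, 4))
    log.info("de: %d genes x %d samples", len(cm.genes), len(cm.samples))
    results = de_test(cm)
    down, up = de_filter(results, fc_min=config.fc_min, fdr_max=config.fdr_max)
    n_se, n_se_de = se_gene_de_count(results, truth["se_flag"])
    results.round(6).to_csv(outdir / "de_results.tsv", sep="\t")
    return {
        "de.n_down": len(down),
        "de.n_up": len(up),
        "de.n_se_genes": n_se,
        "de.n_se_de": n_se_de,
    }


def stage_survival(config: PipelineConfig, outdir: Path) -> dict:
    cfg = sim.load_fixture("survival_cohort")
    cohort = sim.gen_survival(cfg, seed=_seed_for(config, 5))
    log.info("survival: %d patients", len(cohort))
    res = sv.cohort_logrank(cohort, quantile=config.split_quantile)
    res["km_high"].to_frame().round(6).to_csv(
        outdir / "km_high.tsv", sep="\t", index=False
    )
    res["km_low"].to_frame().round(6).to_csv(
        outdir / "km_low.tsv", sep="\t", index=False
    )
    return {
        "survival.n_high": res["n_high"],
        "survival.n_low": res["n_low"],
        "survival.logrank_chi2": res["chi2"],
        "survival.logrank_p": res["p"],
    }


_STAGE_FUNCS = {
    "cistrome": stage_cistrome,
    "motif": stage_motif,
    "loops": stage_loops,
    "de": stage_de,
    "survival": stage_survival,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write a deterministic report.

    Returns the report mapping; writes ``report.tsv`` (key/value) and
    ``summary.txt`` under ``config.outdir``.  A stage failure aborts with
    the stage name in the error; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            log.info("stage %s disabled", stage)
            continue
        try:
            report.update(_STAGE_FUNCS[stage](config, outdir))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    lines = [f"{key}\t{_fmt(report[key])}" for key in report]
    (outdir / "report.tsv").write_text("\n".join(lines) + "\n")
    summary = ["cistrokit pipeline report", "=" * 25]
    summary += [f"{key:40s} {_fmt(report[key])}" for key in report]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    manifest = {
        "stages": [s for s in ALL_STAGES if s in config.stages],
        "seed": config.seed,
        "parameters": {
            "min_overlap": config.min_overlap,
            "profile_flank": config.profile_flank,
            "profile_bin": config.profile_bin,
            "rpkm_flank": config.rpkm_flank,
            "fc_min": config.fc_min,
            "fdr_max": config.fdr_max,
            "min_loops": config.min_loops,
            "split_quantile": config.split_quantile,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
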