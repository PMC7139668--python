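"""Synthetic-data generators with constructed ground truth.

Every input class of the pipeline can be generated here with a known,
exactly representable answer: cistromes with a designed shared/specific
overlap structure, fragment piles enriched at summits with class-dependent
intensity, 100-bp sequence sets with a configured number of embedded motif
instances and certified hit-free backgrounds, super-enhancer mother /
daughter regions with loops anchored on a configured subset, negative-
binomial count matrices with designed differentially expressed genes and
SE-association flags, and two-group survival cohorts with a configured
hazard ratio.

Each generator is a pure function of its :class:`FixtureConfig` and seed:
re-running with the same arguments reproduces the data byte for byte.
Quantities that are constructed combinatorially (overlap fractions, SE
percents, motif percents, DE counts) are invariant to the seed — the seed
only moves placements, signal shapes and survival draws.  Packaged fixture
configurations (``data/fixtures/*.cfg``) encode the study conditions used
throughout the test-suite; class sizes in those files are chosen so the
designed fractions are exact two-decimal percents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .intervals import GenomicInterval, Peak, PeakSet
from .loops import Loop, SERegion, make_loop
from .motifs import BASES, PWM, load_motif_library
from .signal import FragmentSet

log = logging.getLogger(__name__)

FIXTURES = ("mcf7_like", "se_loops", "motif_freq", "de_se_genes", "survival_cohort")


@dataclass(frozen=True)
class FixtureConfig:
    """A named, flat parameter mapping with a recorded seed."""

    fixture: str
    seed: int
    params: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        try:
            return self.params[key]
        except KeyError as exc:
            raise KeyError(f"fixture {self.fixture!r} has no parameter {key!r}") from exc

    def get(self, key: str, default=None):
        return self.params.get(key, default)


def parse_fixture(text: str) -> FixtureConfig:
    """Parse a flat ``key = value`` fixture file (ints, floats, strings)."""
    params: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"malformed fixture line: {raw!r}")
        key, value = key.strip(), value.strip()
        for cast in (int, float):
            try:
                params[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            params[key] = value
    if "fixture" not in params or "seed" not in params:
        raise ValueError("fixture file must define 'fixture' and 'seed'")
    return FixtureConfig(
        fixture=str(params.pop("fixture")),
        seed=int(params.pop("seed")),
        params=params,
    )


def load_fixture(name: str) -> FixtureConfig:
    """Load a packaged fixture configuration by name."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    text = (resources.files("cistrokit") / "data" / "fixtures" /
            f"{name}.cfg").read_text()
    return parse_fixture(text)


def _rng(cfg: FixtureConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Cistromes and fragments
# ---------------------------------------------------------------------------

def cistrome_genome_length(cfg: FixtureConfig) -> int:
    n_slots = cfg["n_era"] + cfg["n_nr2f2"] - cfg["n_shared"]
    return int(cfg["genome_start"] + n_slots * cfg["slot_spacing"] + 10_000)


def gen_cistrome(
    cfg: FixtureConfig, seed: int | None = None
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two peak sets with an exact designed shared/specific structure.

    Shared pairs are placed with a guaranteed overlap of at least half the
    peak width; factor-specific peaks sit in their own slots, separated
    from every peak of the other factor by well over 1 kb, so the realized
    shared fraction equals the configured one exactly for any seed.
    """
    rng = _rng(cfg, seed)
    n_a, n_b, n_shared = cfg["n_era"], cfg["n_nr2f2"], cfg["n_shared"]
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared cannot exceed either set size")
    width = int(cfg["peak_width"])
    spacing = int(cfg["slot_spacing"])
    if spacing < 3 * width:
        raise ValueError(
            "slot spacing too small for isolation; use a larger genome/spacing"
        )
    chrom = str(cfg["chrom"])
    start0 = int(cfg["genome_start"])
    glen = cfg.get("genome_length")
    if glen is not None and cistrome_genome_length(cfg) > glen:
        raise ValueError("infeasible packing; increase genome_length")

    classes = (["shared"] * n_shared
               + ["only_a"] * (n_a - n_shared)
               + ["only_b"] * (n_b - n_shared))
    order = rng.permutation(len(classes))

    def new_peak(prefix: str, idx: int, start: int) -> Peak:
        summit = start + width // 2 + int(rng.integers(-width // 8, width // 8 + 1))
        return Peak(
            GenomicInterval(chrom, start, start + width),
            name=f"{prefix}_{idx:05d}",
            score=float(np.round(rng.uniform(50, 1000), 3)),
            summit=summit,
        )

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    rows: list[dict] = []
    ia = ib = 0
    for slot, class_idx in enumerate(order):
        cls = classes[class_idx]
        x = start0 + slot * spacing
        if cls in ("shared", "only_a"):
            shift = int(rng.integers(-width // 2, width // 2 + 1)) if cls == "shared" else 0
            ia += 1
            pa = new_peak("ERa", ia, x + max(0, shift))
            peaks_a.append(pa)
            rows.append({"peak": pa.name, "set": "era", "cls": cls})
        if cls in ("shared", "only_b"):
            ib += 1
            pb = new_peak("NR2F2", ib, x)
            peaks_b.append(pb)
            rows.append({"peak": pb.name, "set": "nr2f2", "cls": cls})
    truth = pd.DataFrame(rows)
    return (
        PeakSet(peaks_a, label="ERa"),
        PeakSet(peaks_b, label="NR2F2"),
        truth,
    )


def gen_fragments(
    cfg: FixtureConfig,
    peaks: PeakSet,
    class_of: Mapping[str, str],
    genome_length: int,
    seed: int | None = None,
    label: str = "fragments",
) -> FragmentSet:
    """Fragment piles around summits with class-dependent Poisson intensity.

    Per peak of class ``c`` the fragment count is Poisson with mean
    ``frag_mean_<c>``; each fragment of length ``frag_length`` is centered
    uniformly within ``+/- frag_jitter`` of the summit.  An additional
    ``background_fragments`` are placed uniformly on the toy genome.
    """
    rng = _rng(cfg, seed)
    length = int(cfg["frag_length"])
    jitter = int(cfg["frag_jitter"])
    n_bg = int(cfg.get("background_fragments", 0))
    frags: list[GenomicInterval] = []
    for p in peaks:
        cls = class_of[p.name]
        mean = float(cfg[f"frag_mean_{cls}"])
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        centers = rng.integers(p.summit_or_midpoint() - jitter,
                               p.summit_or_midpoint() + jitter + 1, size=n)
        for c in centers:
            start = max(0, int(c) - length // 2)
            frags.append(GenomicInterval(p.chrom, start, start + length))
    if n_bg:
        chrom = peaks[0].chrom if len(peaks) else str(cfg["chrom"])
        starts = rng.integers(0, max(1, genome_length - length), size=n_bg)
        for s in starts:
            frags.append(GenomicInterval(chrom, int(s), int(s) + length))
    return FragmentSet(frags, label=label)


# ---------------------------------------------------------------------------
# Motif-bearing sequences
# ---------------------------------------------------------------------------

def _random_sequences(rng: np.random.Generator, n: int, length: int,
                      gc: float) -> list[str]:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=(n, length), p=probs)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[codes]]


def gen_sequences(
    cfg: FixtureConfig,
    seed: int | None = None,
    pwm: PWM | None = None,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Per-class sequence sets with exact embedded-motif counts.

    For each class ``c`` configured as ``class_<c>_n`` / ``class_<c>_embedded``,
    exactly the configured number of sequences carry one embedded consensus
    instance of the configured motif at a random offset; every remaining
    sequence is rejection-sampled until it contains no hit at the motif's
    threshold on either strand.  Sequence-level motif occurrence is
    therefore exact by construction for any seed.
    """
    from .motifs import has_hit_batch

    rng = _rng(cfg, seed)
    if pwm is None:
        pwm = load_motif_library()[str(cfg["motif"])]
    length = int(cfg.get("seq_length", 100))
    gc = float(cfg.get("gc", 0.5))
    consensus = pwm.consensus
    classes = sorted(
        key[len("class_"):-len("_n")]
        for key in cfg.params
        if key.startswith("class_") and key.endswith("_n")
    )
    if not classes:
        raise ValueError("no sequence classes configured")

    out: dict[str, dict[str, str]] = {}
    rows: list[dict] = []
    max_tries = 200
    for cls in classes:
        n = int(cfg[f"class_{cls}_n"])
        n_embed = int(cfg[f"class_{cls}_embedded"])
        if not 0 <= n_embed <= n:
            raise ValueError(f"class {cls}: embed count outside [0, n]")
        # embedded sequences: background with one consensus instance
        embedded = _random_sequences(rng, n_embed, length, gc)
        offsets = rng.integers(0, length - pwm.width + 1, size=n_embed)
        embedded = [
            s[:o] + consensus + s[o + pwm.width:]
            for s, o in zip(embedded, offsets)
        ]
        # hit-free backgrounds by rejection sampling
        clean: list[str] = []
        tries = 0
        need = n - n_embed
        while len(clean) < need:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "rejection sampling exceeded the retry cap; raise the "
                    "motif threshold or lower the embed density"
                )
            batch = _random_sequences(rng, max(need - len(clean), 64), length, gc)
            hits = has_hit_batch(pwm, batch)
            clean.extend(s for s, h in zip(batch, hits) if not h)
        clean = clean[:need]
        seqs: dict[str, str] = {}
        flags = np.zeros(n, dtype=bool)
        flags[:n_embed] = True
        perm = rng.permutation(n)
        pool = embedded + clean
        for i, j in enumerate(perm):
            sid = f"{cls}_{i + 1:05d}"
            seqs[sid] = pool[j]
            rows.append({"seq": sid, "cls": cls, "embedded": bool(flags[j])})
        out[cls] = seqs
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Super-enhancers and loops
# ---------------------------------------------------------------------------

def gen_loops_and_se(
    cfg: FixtureConfig, seed: int | None = None
) -> tuple[list[SERegion], list[Loop], PeakSet, pd.DataFrame]:
    """SE mother/daughter regions with loops anchored at exact fractions.

    Exactly ``mothers_looped`` mothers and ``daughters_looped`` daughters
    receive a peak joined by a loop to a distant hub anchor; the remaining
    regions receive either no peak or (for ``mothers_peak_only`` of them) a
    loop-free peak.  Additional free-standing peaks populate the >=2 / 1 /
    0 interaction strata (``extra_multi`` with two loops, ``extra_single``
    with one, ``extra_none`` with none), all placements disjoint.
    """
    rng = _rng(cfg, seed)
    chrom = str(cfg["chrom"])
    n_se = int(cfg["n_se"])
    d_per = int(cfg.get("daughters_per_se", 2))
    m_loop = int(cfg["mothers_looped"])
    d_loop = int(cfg["daughters_looped"])
    m_peak_only = int(cfg.get("mothers_peak_only", 0))
    mw, dw = int(cfg["mother_width"]), int(cfg["daughter_width"])
    pw = int(cfg["peak_width"])
    pad = int(cfg.get("anchor_pad", 100))
    spacing = int(cfg["se_spacing"])
    unit_span = mw + d_per * (dw + 2000) + 2000
    if spacing < unit_span:
        raise ValueError("se_spacing too small for the region layout")
    if m_loop > n_se or d_loop > n_se * d_per:
        raise ValueError("infeasible placement: looped counts exceed regions")

    regions: list[SERegion] = []
    base = 10_000
    for i in range(n_se):
        u = base + i * spacing
        se_id = f"SE{i + 1:04d}"
        regions.append(SERegion(GenomicInterval(chrom, u, u + mw), se_id, "mother"))
        for d in range(d_per):
            ds = u + mw + 1000 + d * (dw + 2000)
            regions.append(
                SERegion(GenomicInterval(chrom, ds, ds + dw), se_id, "daughter")
            )
    mothers = [r for r in regions if r.role == "mother"]
    daughters = [r for r in regions if r.role == "daughter"]

    looped_m = set(rng.choice(len(mothers), size=m_loop, replace=False).tolist())
    looped_d = set(rng.choice(len(daughters), size=d_loop, replace=False).tolist())
    free_mothers = sorted(set(range(len(mothers))) - looped_m)
    if m_peak_only > len(free_mothers):
        raise ValueError(
            "infeasible placement: mothers_peak_only exceeds non-looped mothers"
        )
    peak_only_m = set(
        rng.choice(free_mothers, size=m_peak_only, replace=False).tolist()
    ) if m_peak_only else set()

    hub_base = base + n_se * spacing + 100_000
    hub_width = 500
    hub_step = 2_000
    n_hub = 0

    def next_hub() -> GenomicInterval:
        nonlocal n_hub
        iv = GenomicInterval(chrom, hub_base + n_hub * hub_step,
                             hub_base + n_hub * hub_step + hub_width)
        n_hub += 1
        return iv

    peaks: list[Peak] = []
    loops: list[Loop] = []
    rows: list[dict] = []
    n_peaks = 0

    def place_peak(region: GenomicInterval, n_loops: int, origin: str) -> None:
        nonlocal n_peaks
        n_peaks += 1
        off = int(rng.integers(0, len(region) - pw + 1))
        start = region.start + off
        peak = Peak(
            GenomicInterval(chrom, start, start + pw),
            name=f"NR2F2_{n_peaks:05d}",
            score=float(np.round(rng.uniform(50, 1000), 3)),
            summit=start + pw // 2,
        )
        peaks.append(peak)
        anchor = GenomicInterval(chrom, max(0, start - pad), start + pw + pad)
        for _ in range(n_loops):
            loops.append(make_loop(anchor, next_hub(), support=int(rng.integers(2, 20))))
        rows.append({"peak": peak.name, "origin": origin, "designed_loops": n_loops})

    for i, r in enumerate(mothers):
        if i in looped_m:
            place_peak(r.interval, 1, "mother")
        elif i in peak_only_m:
            place_peak(r.interval, 0, "mother_no_loop")
    for i, r in enumerate(daughters):
        if i in looped_d:
            place_peak(r.interval, 1, "daughter")

    extra_base = hub_base + 5_000_000
    extra_spacing = 3_000
    extra_idx = 0
    for n_loops, count, origin in (
        (2, int(cfg.get("extra_multi", 0)), "extra_multi"),
        (1, int(cfg.get("extra_single", 0)), "extra_single"),
        (0, int(cfg.get("extra_none", 0)), "extra_none"),
    ):
        for _ in range(count):
            slot = GenomicInterval(
                chrom,
                extra_base + extra_idx * extra_spacing,
                extra_base + extra_idx * extra_spacing + pw,
            )
            extra_idx += 1
            place_peak(slot, n_loops, origin)

    looped_flags: dict[tuple[str, int], bool] = {}
    for i in range(len(mothers)):
        looped_flags[("mother", i)] = i in looped_m
    for i in range(len(daughters)):
        looped_flags[("daughter", i)] = i in looped_d
    role_counter = {"mother": 0, "daughter": 0}
    flags = []
    for r in regions:
        flags.append(looped_flags[(r.role, role_counter[r.role])])
        role_counter[r.role] += 1
    truth_regions = pd.DataFrame(
        {
            "se_id": [r.se_id for r in regions],
            "role": [r.role for r in regions],
            "looped": flags,
        }
    )
    truth = pd.DataFrame(rows)
    truth.attrs["regions"] = truth_regions
    return regions, loops, PeakSet(peaks, label="NR2F2"), truth


def se_genome_length(cfg: FixtureConfig) -> int:
    extra = (int(cfg.get("extra_multi", 0)) + int(cfg.get("extra_single", 0))
             + int(cfg.get("extra_none", 0)))
    return int(10_000 + int(cfg["n_se"]) * int(cfg["se_spacing"])
               + 100_000 + 5_000_000 + extra * 3_000 + 100_000)


# ---------------------------------------------------------------------------
# Count matrices with designed differential expression
# ---------------------------------------------------------------------------

def gen_counts_matrix(
    cfg: FixtureConfig, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with designed DE genes and SE-association flags.

    ``n_down`` genes drop and ``n_up`` genes rise by ``log2fc`` in the
    knockdown group; the remaining genes are null.  Down-regulated genes
    are given a higher baseline so the expected library sizes of the two
    groups match, which keeps per-sample CPM normalization unbiased.  The
    design margin (effect 2 in log2 units against a null log-fold-change
    standard deviation near 0.09 at the default mean and dispersion)
    guarantees that any reasonable NB test recovers exactly the designed
    sets.  ``n_se_de`` of the ``n_se_genes`` SE-flagged genes are designed
    DE; the rest are null.
    """
    rng = _rng(cfg, seed)
    n_genes = int(cfg["n_genes"])
    n_down, n_up = int(cfg["n_down"]), int(cfg["n_up"])
    n_per = int(cfg["samples_per_group"])
    base = float(cfg["base_mean"])
    phi = float(cfg["dispersion"])
    lfc = float(cfg["log2fc"])
    n_se = int(cfg["n_se_genes"])
    n_se_de = int(cfg["n_se_de"])
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if n_down + n_up > n_genes:
        raise ValueError("designed DE genes exceed gene count")
    if n_se_de > min(n_se, n_down + n_up) or n_se - n_se_de > n_genes - n_down - n_up:
        raise ValueError("SE flag design infeasible")

    fold = 2.0 ** lfc
    # higher baseline for down genes balances expected group library sizes
    base_down = (n_up * base * (fold - 1)) / (n_down * (1 - 1 / fold)) if n_down else base

    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    status = np.array(["null"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    down_idx = order[:n_down]
    up_idx = order[n_down:n_down + n_up]
    status[down_idx] = "down"
    status[up_idx] = "up"

    mean_ctrl = np.full(n_genes, base)
    mean_ctrl[down_idx] = base_down
    mean_kd = mean_ctrl.copy()
    mean_kd[down_idx] = base_down / fold
    mean_kd[up_idx] = base * fold

    def draw(mean: np.ndarray, n_samples: int) -> np.ndarray:
        out = np.empty((n_genes, n_samples), dtype=np.int64)
        for j in range(n_samples):
            if phi > 0:
                r = 1.0 / phi
                out[:, j] = rng.negative_binomial(r, r / (r + mean))
            else:
                out[:, j] = rng.poisson(mean)
        return out

    ctrl = draw(mean_ctrl, n_per)
    kd = draw(mean_kd, n_per)
    samples = [f"shCTRL_{j + 1}" for j in range(n_per)] + [
        f"shKD_{j + 1}" for j in range(n_per)
    ]
    counts = pd.DataFrame(
        np.hstack([ctrl, kd]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = {s: ("control" if s.startswith("shCTRL") else "knockdown")
              for s in samples}

    de_idx = np.concatenate([down_idx, up_idx])
    null_idx = np.array([i for i in range(n_genes) if status[i] == "null"])
    se_flag = np.zeros(n_genes, dtype=bool)
    se_flag[rng.choice(de_idx, size=n_se_de, replace=False)] = True
    se_flag[rng.choice(null_idx, size=n_se - n_se_de, replace=False)] = True

    truth = pd.DataFrame(
        {"gene": genes, "designed": status, "se_flag": se_flag}
    ).set_index("gene")
    return CountMatrix(counts, groups), truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def gen_survival(cfg: FixtureConfig, seed: int | None = None) -> pd.DataFrame:
    """Two-group survival cohort with a configured hazard ratio.

    Expression z-scores are standard normal; patients above the median form
    the high-expression group with baseline exponential hazard, the rest
    get hazard multiplied by ``hazard_ratio`` (low expression = worse
    outcome).  Follow-up is censored uniformly on ``[0, censor_max]``; a
    non-positive ``censor_max`` disables censoring.
    """
    rng = _rng(cfg, seed)
    n = 2 * int(cfg["n_per_arm"])
    lam = float(cfg["baseline_hazard"])
    hr = float(cfg["hazard_ratio"])
    censor_max = float(cfg.get("censor_max", 0))
    z = rng.standard_normal(n)
    high = z > np.median(z)
    hazard = np.where(high, lam, lam * hr)
    t_event = rng.exponential(1.0 / hazard)
    if censor_max > 0:
        t_cens = rng.uniform(0, censor_max, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {
            "patient": [f"P{i + 1:04d}" for i in range(n)],
            "time": np.round(time, 4),
            "event": event,
            "expression_z": np.round(z, 4),
        }
    )
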