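"""Chromatin-loop stratification and super-enhancer occupancy statistics.

Loops are paired anchor intervals (ChIA-PET style, BEDPE interchange).  A
peak "overlaps a loop" when it intersects either anchor; a loop is counted
at most once per peak even when the peak touches both anchors.  Peaks are
stratified by their loop count into the three interaction classes
(">=2", "1", "0") used to compare binding intensities, and super-enhancer
mother/daughter regions are scored by whether they contain a peak whose
loop count reaches a configurable minimum (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .intervals import GenomicInterval, PeakSet
from .signal import RpkmVector

log = logging.getLogger(__name__)

STRATA = ("0", "1", ">=2")
ROLES = ("mother", "daughter")


class BedpeParseError(ValueError):
    """Raised on malformed BEDPE records; carries the line number."""


@dataclass(frozen=True)
class Loop:
    """A chromatin interaction between two anchors, anchor1 <= anchor2."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: int = 0

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be non-negative")
        key1 = (self.anchor1.chrom, self.anchor1.start, self.anchor1.end)
        key2 = (self.anchor2.chrom, self.anchor2.start, self.anchor2.end)
        if key1 > key2:
            raise ValueError("anchor1 must not follow anchor2 in genome order")

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor1, self.anchor2)


def make_loop(a: GenomicInterval, b: GenomicInterval, support: int = 0) -> Loop:
    """Build a loop with anchors normalized into genome order."""
    key_a = (a.chrom, a.start, a.end)
    key_b = (b.chrom, b.start, b.end)
    return Loop(a, b, support) if key_a <= key_b else Loop(b, a, support)


@dataclass(frozen=True)
class SERegion:
    """A super-enhancer constituent region with its role and SE id."""

    interval: GenomicInterval
    se_id: str
    role: str  # {"mother", "daughter"}

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class LoopStratification:
    """Per-peak loop counts with the >=2 / 1 / 0 stratum labels."""

    counts: dict[str, int]

    def stratum(self, peak_name: str) -> str:
        c = self.counts[peak_name]
        return ">=2" if c >= 2 else str(c)

    def strata(self) -> dict[str, str]:
        return {name: self.stratum(name) for name in self.counts}

    def stratum_sizes(self) -> dict[str, int]:
        sizes = {s: 0 for s in STRATA}
        for name in self.counts:
            sizes[self.stratum(name)] += 1
        return sizes

    def names_in_stratum(self, stratum: str) -> list[str]:
        return [n for n in self.counts if self.stratum(n) == stratum]

    def to_frame(self) -> pd.DataFrame:
        names = list(self.counts)
        return pd.DataFrame(
            {
                "peak": names,
                "loop_count": [self.counts[n] for n in names],
                "stratum": [self.stratum(n) for n in names],
            }
        )


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path) -> list[Loop]:
    """Read a 6-8 column BEDPE file; anchors are normalized into order.

    The optional 8th column is parsed as the PET support count.
    """
    path = Path(path)
    loops: list[Loop] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedpeParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns"
                )
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise BedpeParseError(f"{path}:{lineno}: {exc}") from exc
            support = 0
            if len(fields) >= 8 and fields[7] not in ("", "."):
                try:
                    support = int(fields[7])
                except ValueError as exc:
                    raise BedpeParseError(
                        f"{path}:{lineno}: bad support column"
                    ) from exc
            loops.append(make_loop(a, b, support))
    return loops


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, lp in enumerate(loops):
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                f"loop_{i + 1}\t{lp.support}\n"
            )


def read_se_bed(path: str | Path) -> list[SERegion]:
    """Read SE regions from BED6 with ``SEid:role`` in the name column."""
    from .intervals import read_bed

    regions: list[SERegion] = []
    for p in read_bed(path, dialect="bed3plus"):
        se_id, _, role = p.name.partition(":")
        if role not in ROLES:
            raise ValueError(
                f"SE region name {p.name!r} must be '<SEid>:mother' or "
                f"'<SEid>:daughter'"
            )
        regions.append(SERegion(p.interval, se_id, role))
    return regions


def write_se_bed(regions: Sequence[SERegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.se_id}:{r.role}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# Stratification and SE occupancy
# ---------------------------------------------------------------------------

def loop_count_stratify(peaks: PeakSet, loops: Sequence[Loop]) -> LoopStratification:
    """Count, per peak, the loops with at least one overlapped anchor.

    A peak overlapping both anchors of the same loop counts that loop once.
    With no loops every peak lands in stratum "0".
    """
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, idx)
    counts = np.zeros(len(peaks), dtype=int)
    for lp in loops:
        touched: set[int] = set()
        for anchor in lp.anchors:
            tree = trees.get(anchor.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(anchor.start, anchor.end):
                touched.add(iv.data)
        for idx in touched:
            counts[idx] += 1
    return LoopStratification(
        counts={p.name: int(counts[i]) for i, p in enumerate(peaks)}
    )


@dataclass(frozen=True)
class StratumComparison:
    stratum_a: str
    stratum_b: str
    result: stats.TestResult | None  # None when a stratum is empty
    median_a: float
    median_b: float


def compare_intensity_by_stratum(
    rpkm: RpkmVector | pd.Series,
    strat: LoopStratification,
) -> list[StratumComparison]:
    """Pairwise two-sided Mann-Whitney tests of RPKM between loop strata.

    Compares >=2 vs 1, >=2 vs 0 and 1 vs 0.  Empty strata yield a
    comparison with ``result=None`` and a warning.
    """
    series = rpkm.as_series() if isinstance(rpkm, RpkmVector) else rpkm
    missing = [n for n in series.index if n not in strat.counts]
    if missing:
        raise ValueError(f"peaks without stratum: {missing[:5]}")
    groups = {
        s: series.loc[[n for n in strat.names_in_stratum(s) if n in series.index]]
        for s in STRATA
    }
    out: list[StratumComparison] = []
    for a, b in ((">=2", "1"), (">=2", "0"), ("1", "0")):
        va, vb = groups[a].to_numpy(), groups[b].to_numpy()
        if va.size == 0 or vb.size == 0:
            log.warning("stratum %s vs %s: empty group, comparison is NA", a, b)
            out.append(StratumComparison(a, b, None, float("nan"), float("nan")))
            continue
        res = stats.mann_whitney(va, vb, alternative="two-sided")
        out.append(
            StratumComparison(a, b, res, float(np.median(va)), float(np.median(vb)))
        )
    return out


def se_overlap_fraction(
    regions: Sequence[SERegion],
    peaks: PeakSet,
    strat: LoopStratification,
    min_loops: int = 1,
) -> dict[str, float]:
    """Percent of mother/daughter regions containing a loop-linked peak.

    A region is positive iff it overlaps at least one peak whose loop count
    is >= ``min_loops``.  Percents are rounded to 2 decimals per role.
    """
    qualifying = PeakSet(
        [p for p in peaks if strat.counts.get(p.name, 0) >= min_loops],
        label=peaks.label,
    )
    trees: dict[str, IntervalTree] = {}
    for p in qualifying:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    totals = {role: 0 for role in ROLES}
    positives = {role: 0 for role in ROLES}
    for r in regions:
        totals[r.role] += 1
        tree = trees.get(r.interval.chrom)
        if tree is not None and tree.overlap(r.interval.start, r.interval.end):
            positives[r.role] += 1
    out: dict[str, float] = {}
    for role in ROLES:
        if totals[role] == 0:
            raise ValueError(f"no regions with role {role!r}")
        out[role] = round(100.0 * positives[role] / totals[role], 2)
    return out
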