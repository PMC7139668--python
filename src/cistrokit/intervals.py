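"""Genomic interval types, BED I/O and the occupancy overlap engine.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base
under that arithmetic, so ``[0, 10)`` and ``[10, 20)`` do *not* overlap.

The central operation is :func:`overlap_partition`, which classifies every
peak of two transcription-factor peak sets as *shared* (overlapping a peak
of the other factor by at least ``min_overlap`` bp) or factor-specific —
the peak-fraction semantics behind Venn-style cistrome comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised on malformed BED/narrowPeak records; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap


@dataclass(frozen=True)
class Peak:
    """A called binding site with an optional summit position.

    The summit, when present, is the absolute base of maximal signal and
    must lie inside ``[start, end)``.
    """

    interval: GenomicInterval
    name: str
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end}) for peak {self.name}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    def summit_or_midpoint(self) -> int:
        return self.summit if self.summit is not None else self.midpoint


class PeakSet:
    """An ordered collection of uniquely named peaks for one factor."""

    def __init__(self, peaks: Iterable[Peak], label: str = "") -> None:
        self.peaks: list[Peak] = list(peaks)
        self.label = label
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})[:5]
            raise ValueError(f"duplicate peak names in set {label!r}: {dup}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.peaks]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end, p.name)),
            label=self.label,
        )

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def subset(self, names: Iterable[str], label: str | None = None) -> "PeakSet":
        wanted = set(names)
        return PeakSet(
            [p for p in self.peaks if p.name in wanted],
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class OccupancyPartition:
    """Shared/specific classification of two peak sets.

    ``|shared_a| + |only_a| == |A|`` and symmetrically for B; every peak in
    a *shared* component overlaps at least one peak of the other set by at
    least the ``min_overlap`` used to build the partition.
    """

    shared_a: PeakSet
    only_a: PeakSet
    shared_b: PeakSet
    only_b: PeakSet
    min_overlap: int = 1

    def shared_fraction_a(self) -> float:
        n = len(self.shared_a) + len(self.only_a)
        return len(self.shared_a) / n if n else float("nan")

    def shared_fraction_b(self) -> float:
        n = len(self.shared_b) + len(self.only_b)
        return len(self.shared_b) / n if n else float("nan")

    def shared_percent_a(self) -> float:
        return 100.0 * self.shared_fraction_a()

    def shared_percent_b(self) -> float:
        return 100.0 * self.shared_fraction_b()


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    dialect: str = "bed3plus",
    label: str | None = None,
) -> PeakSet:
    """Read a BED3+/BED6 or 10-column narrowPeak file into a :class:`PeakSet`.

    ``narrowpeak`` sets ``summit = start + offset`` from column 10 when the
    offset is non-negative, otherwise the interval midpoint.  ``bed3plus``
    always uses the midpoint summit.  Record order is preserved.
    """
    if dialect not in ("bed3plus", "narrowpeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else (
                f"peak_{lineno}"
            )
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            summit = (start + end) // 2
            if dialect == "narrowpeak":
                if len(fields) < 10:
                    raise BedParseError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns"
                    )
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad summit offset") from exc
                if offset >= 0:
                    summit = start + offset
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), name, score, summit)
            )
    return PeakSet(peaks, label=label or path.stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a peak set as BED6 (name = peak id, score preserved)."""
    with Path(path).open("w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t"
                f"{p.interval.strand}\n"
            )


def subtract_exclusion(peaks: PeakSet, exclusion: Iterable[GenomicInterval]) -> PeakSet:
    """Drop peaks overlapping any exclusion-list (artifact/blacklist) region."""
    trees: dict[str, IntervalTree] = {}
    for iv in exclusion:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = [
        p
        for p in peaks
        if p.chrom not in trees or not trees[p.chrom].overlap(p.start, p.end)
    ]
    removed = len(peaks) - len(kept)
    if removed:
        log.info("exclusion list removed %d/%d peaks from %s", removed, len(peaks),
                 peaks.label)
    return PeakSet(kept, label=peaks.label)


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def _chrom_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _classify(query: PeakSet, trees: Mapping[str, IntervalTree],
              min_overlap: int) -> tuple[list[Peak], list[Peak]]:
    shared: list[Peak] = []
    only: list[Peak] = []
    for p in query:
        tree = trees.get(p.chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(p.start, p.end):
                if min(p.end, iv.end) - max(p.start, iv.begin) >= min_overlap:
                    hit = True
                    break
        (shared if hit else only).append(p)
    return shared, only


def overlap_partition(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> OccupancyPartition:
    """Partition two peak sets into shared and factor-specific components.

    A peak of A is *shared* iff it overlaps at least one peak of B by at
    least ``min_overlap`` bases (half-open arithmetic); classification is
    binary per peak — a peak overlapping several partners is counted once.
    Empty inputs are valid and yield all-``only`` partitions.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    shared_a, only_a = _classify(a, _chrom_trees(b), min_overlap)
    shared_b, only_b = _classify(b, _chrom_trees(a), min_overlap)
    return OccupancyPartition(
        shared_a=PeakSet(shared_a, label=a.label),
        only_a=PeakSet(only_a, label=a.label),
        shared_b=PeakSet(shared_b, label=b.label),
        only_b=PeakSet(only_b, label=b.label),
        min_overlap=min_overlap,
    )


def summit_window(peak: Peak, flank: int) -> GenomicInterval:
    """Summit-centered window ``[summit - flank, summit + flank + 1)``.

    The window includes the summit base, so an unclipped window spans
    ``2*flank + 1`` bp (101 bp for the RPKM flank of 50).  Clipped at 0 on
    the left.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    s = peak.summit_or_midpoint()
    return GenomicInterval(peak.chrom, max(0, s - flank), s + flank + 1,
                           peak.interval.strand)


def nearest_tss_annotate(
    peaks: PeakSet,
    tss: Sequence[tuple[GenomicInterval, str]],
) -> dict[str, str]:
    """Assign each peak the gene with the nearest TSS to its summit.

    The TSS position is the interval start.  Distance is ``|summit - TSS|``;
    ties break toward the smaller genomic coordinate, then the
    lexicographically smaller gene id.  Peaks on chromosomes without any
    TSS map to ``"NA"`` (logged).
    """
    if not tss:
        raise ValueError("TSS annotation is empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for iv, gene in tss:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, gene))
    arrays: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, entries in by_chrom.items():
        entries.sort()  # (coordinate, gene id) — encodes the tie rule
        arrays[chrom] = (np.array([e[0] for e in entries]), [e[1] for e in entries])

    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in arrays:
            log.warning("peak %s on chromosome %s with no TSS; assigned NA",
                        p.name, p.chrom)
            out[p.name] = "NA"
            continue
        pos, genes = arrays[p.chrom]
        s = p.summit_or_midpoint()
        i = int(np.searchsorted(pos, s))
        best: tuple[int, int] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(pos):
                cand = (abs(s - int(pos[j])), int(pos[j]))
                if best is None or cand < best:
                    best = cand
        assert best is not None
        # several TSS may share the winning coordinate; take the
        # lexicographically smallest gene id among them (sorted order)
        j0 = int(np.searchsorted(pos, best[1], side="left"))
        out[p.name] = genes[j0]
    return out
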