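"""PWM construction, log-odds scanning and known-motif enrichment.

Motifs are position weight matrices scored in bits against a background
base distribution.  Scanning reports every window on either strand whose
log-odds score reaches the motif threshold; windows containing N are
skipped.  Sequence-level counting is ZOOPS (zero-or-one occurrence per
sequence), and enrichment of a motif in a target set against a background
set uses the upper hypergeometric tail, the classic known-motif statistic.

The default hit threshold of a PWM is the smallest score whose
false-positive probability per scanned window is at most ``DEFAULT_FPR``
under the background model, obtained by exact dynamic programming over the
discretized per-position score distribution.  Very short or extremely
sharp motifs may not admit such a score; the threshold is then capped at
the maximum achievable score (the consensus still scores a hit) and a
warning is logged.

The packaged motif library (``data/motif_counts_synthetic.txt``) contains
synthetic consensus-derived count matrices for the classic estrogen-
receptor cofactor motifs (ERE, DR1, FOXA1, GATA3, AP-1, AP2-gamma, CTCF,
NR half-site); see the file header for how they were constructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import stats

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4

#: default per-window false-positive probability for the hit threshold
DEFAULT_FPR = 1.0e-4

#: default pseudocount added to each base count
DEFAULT_PSEUDOCOUNT = 0.25

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with a log-odds hit threshold in bits."""

    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray  # (4,)
    threshold: float

    def __post_init__(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if self.width < 4:
            raise ValueError(f"PWM width must be >= 4, got {self.width}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-position probabilities must sum to 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background) matrix, shape (width, 4)."""
        return np.log2(self.probs / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    strand: str  # {"+", "-"}
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    p: float

    @property
    def percent_of_target(self) -> float:
        return 100.0 * self.k_target / self.n_target


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def score_threshold_for_fpr(
    log_odds: np.ndarray,
    background: np.ndarray,
    fpr: float = DEFAULT_FPR,
    resolution: float = 1.0e-3,
) -> float:
    """Smallest score s with P(window score >= s) <= ``fpr`` under background.

    Exact dynamic programming over the per-position score distribution,
    discretized to ``resolution`` bits.  Returns the maximum achievable
    score (with a warning) when no score satisfies the bound.
    """
    # floor-discretize so every true window score is >= its grid score;
    # the returned threshold is then padded by one grid step per position,
    # making the FPR bound conservative against rounding drift
    scaled = np.floor(log_odds / resolution).astype(np.int64)
    width = scaled.shape[0]
    true_max = float(log_odds.max(axis=1).sum())
    lo_min = int(scaled.min(axis=1).sum())
    lo_max = int(scaled.max(axis=1).sum())
    dist = np.zeros(lo_max - lo_min + 1)
    dist[-lo_min] = 1.0  # score 0 before any position is added
    for i in range(scaled.shape[0]):
        new = np.zeros_like(dist)
        row = scaled[i]
        for b in range(4):
            shift = int(row[b])
            if shift >= 0:
                new[shift:] += dist[: dist.size - shift] * background[b]
            else:
                new[:shift] += dist[-shift:] * background[b]
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= fpr)[0]
    if ok.size == 0:
        log.warning(
            "no score reaches per-window FPR <= %g; capping threshold at the "
            "maximum achievable score", fpr,
        )
        return true_max
    threshold = (int(ok[0]) + lo_min + width) * resolution
    return min(threshold, true_max)


def pwm_from_counts(
    counts: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    name: str = "motif",
    fpr: float = DEFAULT_FPR,
) -> PWM:
    """Build a PWM from per-position base counts.

    ``probs = (count + pseudocount) / (total + 4 * pseudocount)``; the hit
    threshold is set by :func:`score_threshold_for_fpr`.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must have shape (width, 4)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("every position needs at least one observation")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    log_odds = np.log2(probs / bg[None, :])
    threshold = score_threshold_for_fpr(log_odds, bg, fpr=fpr)
    return PWM(name=name, probs=probs, background=bg, threshold=threshold)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as int8 codes 0..4; rejects other characters."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _extended_log_odds(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement log-odds with an N column of NaN."""
    lo = pwm.log_odds
    nan_col = np.full((lo.shape[0], 1), np.nan)
    fwd = np.hstack([lo, nan_col])
    rc = np.hstack([lo[::-1, ::-1], nan_col])
    return fwd, rc


def _window_scores(lo_ext: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of every window of one strand matrix; NaN where N occurs."""
    w = lo_ext.shape[0]
    if enc.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return lo_ext[np.arange(w), windows].sum(axis=-1)


def scan_sequence(pwm: PWM, seq: str, seq_id: str = "seq") -> list[MotifHit]:
    """All hits (score >= threshold) on both strands of ``seq``.

    A reverse-strand hit at offset i means the reverse complement of
    ``seq[i:i+width]`` matches the motif.  Sequences shorter than the motif
    yield an empty list.
    """
    enc = encode_sequence(seq)
    fwd, rc = _extended_log_odds(pwm)
    hits: list[MotifHit] = []
    thr = pwm.threshold - 1e-9
    for strand, mat in (("+", fwd), ("-", rc)):
        scores = _window_scores(mat, enc)
        for off in np.nonzero(scores >= thr)[0]:
            hits.append(MotifHit(seq_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _encode_matrix(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("batch scanning requires equal-length sequences")
    return np.vstack([encode_sequence(s) for s in seqs])


def has_hit_batch(pwm: PWM, seqs: Sequence[str]) -> np.ndarray:
    """Boolean array: does each (equal-length) sequence contain >=1 hit."""
    mat = _encode_matrix(seqs)
    n, length = mat.shape if mat.size else (len(seqs), 0)
    w = pwm.width
    if length < w:
        return np.zeros(len(seqs), dtype=bool)
    fwd, rc = _extended_log_odds(pwm)
    windows = np.lib.stride_tricks.sliding_window_view(mat, w, axis=1)
    thr = pwm.threshold - 1e-9
    out = np.zeros(n, dtype=bool)
    for lo_ext in (fwd, rc):
        scores = lo_ext[np.arange(w), windows].sum(axis=-1)
        with np.errstate(invalid="ignore"):
            out |= np.any(scores >= thr, axis=1)
    return out


def percent_of_targets(
    pwm: PWM,
    seqs: Sequence[str] | Mapping[str, str],
) -> tuple[int, int, float]:
    """ZOOPS motif occurrence: (k sequences with a hit, n, percent).

    A sequence counts once however many hits it contains.
    """
    values = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    if not values:
        raise ValueError("percent_of_targets requires at least one sequence")
    if len({len(s) for s in values}) == 1:
        k = int(has_hit_batch(pwm, values).sum())
    else:
        k = sum(bool(scan_sequence(pwm, s)) for s in values)
    n = len(values)
    return k, n, 100.0 * k / n


def motif_enrichment_test(
    pwm: PWM,
    target_seqs: Sequence[str] | Mapping[str, str],
    background_seqs: Sequence[str] | Mapping[str, str],
) -> EnrichmentResult:
    """Hypergeometric known-motif enrichment of target vs background.

    The urn pools both sets; p is the probability of drawing at least
    ``k_target`` hit-sequences in ``n_target`` draws.
    """
    k_t, n_t, _ = percent_of_targets(pwm, target_seqs)
    k_b, n_b, _ = percent_of_targets(pwm, background_seqs)
    if n_b < n_t:
        log.warning("background (%d) smaller than target (%d)", n_b, n_t)
    p = stats.hypergeom_tail(k_t, n_t + n_b, k_t + k_b, n_t)
    return EnrichmentResult(
        motif=pwm.name, n_target=n_t, k_target=k_t,
        n_background=n_b, k_background=k_b, p=p,
    )


# ---------------------------------------------------------------------------
# Motif library and FASTA I/O
# ---------------------------------------------------------------------------

def parse_motif_counts(text: str) -> dict[str, np.ndarray]:
    """Parse a simple count-matrix library.

    Format: ``>NAME`` header followed by four lines ``A: c1 c2 ...`` etc.
    """
    library: dict[str, np.ndarray] = {}
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is not None:
            if set(rows) != set(BASES):
                raise ValueError(f"motif {name}: need rows for A, C, G, T")
            library[name] = np.array([rows[b] for b in BASES], dtype=float).T
        name, rows = None, {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
        else:
            base, _, values = line.partition(":")
            base = base.strip().upper()
            if base not in BASES:
                raise ValueError(f"unexpected row label {base!r}")
            rows[base] = [float(v) for v in values.split()]
    flush()
    return library


def load_motif_library(
    path: str | Path | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    fpr: float = DEFAULT_FPR,
) -> dict[str, PWM]:
    """Load the packaged (or a user) motif count library as ready PWMs."""
    if path is None:
        text = (resources.files("cistrokit") / "data" /
                "motif_counts_synthetic.txt").read_text()
    else:
        text = Path(path).read_text()
    return {
        name: pwm_from_counts(counts, pseudocount=pseudocount,
                              background=background, name=name, fpr=fpr)
        for name, counts in parse_motif_counts(text).items()
    }


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning an id -> sequence mapping."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
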