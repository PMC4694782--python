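"""Dimeric p53 response-element model: spaced PWMs, exact p-values, scanning.

The p53 response element consists of two decameric half sites (consensus
RRRCWWGYYY each) that occur either adjacent ("unsplit") or separated by a
1-15 nt spacer. The scanner therefore works with an array of 16 PWM
variants: the unsplit 20-column model plus 15 variants whose spacer columns
are fixed to the background distribution (so the spacer contributes nothing
to the log-odds score).

Match significance is the exact per-match p-value of the log-odds score
under the i.i.d. background model, computed by dynamic programming over a
discretized score lattice (the same construction FIMO uses). Among all
positions, strands and spacer variants in a scanned window, the hit with the
lowest p-value is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Pwm",
    "SpacedPwm",
    "MotifHit",
    "MotifClass",
    "build_spaced_pwm",
    "log_odds_score",
    "score_pvalue",
    "scan_window",
    "classify_hits",
    "spacer_distribution",
    "group_compare",
    "encode_sequence",
    "reverse_complement",
    "p53_consensus_pwm",
]

_ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)
_COMP = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN (case-insensitive) as int8 codes 0..4; reject others."""
    seq = seq.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    out = lut[codes]
    if (out < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(out < 0)[0][:5]})
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix over A,C,G,T with an i.i.d. background model.

    ``probs`` rows sum to one and are strictly positive (pseudocounted when
    built from counts), so log-odds scores are finite everywhere.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if (probs <= 0).any():
            raise ValueError("PWM entries must be strictly positive (pseudocount)")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9) or (bg <= 0).any():
            raise ValueError("background must be a positive length-4 probability vector")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        smoothed = counts + pseudocount
        probs = smoothed / smoothed.sum(axis=1, keepdims=True)
        bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
        return cls(probs=probs, background=bg, pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        """width x 5 log2-odds matrix; the 5th column (N) scores 0."""
        lo = np.log2(self.probs / self.background[None, :])
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Total information content in bits (uniform-background convention)."""
        p = self.probs
        return float(np.sum(2.0 + (p * np.log2(p)).sum(axis=1)))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


class MotifClass(Enum):
    NO_MOTIF = "no_motif"
    UNSPLIT = "unsplit"
    SPACED = "spaced"


@dataclass(frozen=True)
class MotifHit:
    """Best motif match within a scanned window."""

    peak_name: str
    offset: int
    strand: str
    spacer: int
    score: float
    pvalue: float
    matched_seq: str

    @property
    def motif_class(self) -> MotifClass:
        return MotifClass.UNSPLIT if self.spacer == 0 else MotifClass.SPACED


class SpacedPwm:
    """Array of spacer variants (s = 0..max_spacer) of a dimeric PWM.

    Variant ``s`` has width ``20 + s`` with the s spacer columns equal to the
    background, so a spacer base contributes zero bits. Per-variant exact
    score distributions are cached lazily for p-value lookup.
    """

    def __init__(self, half1: Pwm, half2: Pwm, max_spacer: int = 15) -> None:
        if half1.width != 10 or half2.width != 10:
            raise ValueError("half sites must each be 10 columns wide")
        if not np.allclose(half1.background, half2.background):
            raise ValueError("half sites must share a background model")
        self.half1 = half1
        self.half2 = half2
        self.max_spacer = max_spacer
        self.background = half1.background
        self.variants: dict[int, Pwm] = {}
        for s in range(max_spacer + 1):
            spacer_block = np.tile(self.background, (s, 1))
            probs = np.vstack([half1.probs, spacer_block, half2.probs])
            self.variants[s] = Pwm(probs=probs, background=self.background)
        self._sf_cache: dict[tuple[int, float], tuple[int, float, np.ndarray]] = {}

    def variant_sf(self, spacer: int, granularity: float = 1e-3):
        key = (spacer, granularity)
        if key not in self._sf_cache:
            self._sf_cache[key] = _score_lattice_sf(self.variants[spacer], granularity)
        return self._sf_cache[key]


def build_spaced_pwm(
    full: Pwm, max_spacer: int = 15, background: np.ndarray | None = None
) -> SpacedPwm:
    """Split a 20-column dimeric PWM into half sites and build spacer variants."""
    if full.width != 20:
        raise ValueError(f"dimeric PWM must have width 20, got {full.width}")
    bg = full.background if background is None else np.asarray(background, float)
    half1 = Pwm(probs=full.probs[:10].copy(), background=bg)
    half2 = Pwm(probs=full.probs[10:].copy(), background=bg)
    return SpacedPwm(half1, half2, max_spacer=max_spacer)


def log_odds_score(pwm: Pwm, seq: str) -> float:
    """log2 likelihood ratio of ``seq`` under the PWM vs background (bits).

    N bases contribute 0 bits (background-equivalent).
    """
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != PWM width {pwm.width}")
    codes = encode_sequence(seq)
    lo = pwm.log_odds()
    return float(lo[np.arange(pwm.width), codes].sum())


def _score_lattice_sf(pwm: Pwm, granularity: float) -> tuple[int, float, np.ndarray]:
    """Exact discretized score distribution of a PWM under its background.

    Per-column log-odds scores are rounded to a lattice of bin width
    ``granularity`` bits; the distribution of the lattice sum is built by
    convolving the four-point per-column mass functions. Returns
    ``(lo_index, granularity, sf)`` where ``sf[i] = P(lattice sum >= lo + i)``.
    """
    lo_mat = np.round(np.log2(pwm.probs / pwm.background[None, :]) / granularity)
    lo_mat = lo_mat.astype(np.int64)
    bg = pwm.background
    pmf = np.array([1.0])
    lo = 0
    for c in range(pwm.width):
        shifts = lo_mat[c]
        smin, smax = int(shifts.min()), int(shifts.max())
        new = np.zeros(len(pmf) + (smax - smin))
        for b in range(4):
            k = int(shifts[b]) - smin
            new[k:k + len(pmf)] += pmf * bg[b]
        pmf = new
        lo += smin
    sf = np.cumsum(pmf[::-1])[::-1]
    return lo, granularity, sf, pwm.width


def _sf_lookup(lattice, scores: np.ndarray) -> np.ndarray:
    """Vectorized p-value lookup: P(score' >= score) on the lattice.

    Per-column rounding can displace a sequence's lattice sum by up to
    width/2 bins from the rounded total score, so the query index is
    shifted down by that slack: every sequence whose exact score reaches
    the query is counted (ties at the query score are never dropped), at
    the cost of also counting mass within width*granularity below it.
    """
    lo, g, sf, width = lattice
    slack = width / 2.0
    idx = np.ceil(np.asarray(scores, dtype=float) / g - slack - 1e-9).astype(np.int64) - lo
    idx = np.clip(idx, 0, len(sf) - 1)
    return sf[idx]


_EXACT_WIDTH_LIMIT = 10


def _exact_score_sf(pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution by column-wise convolution with atom merging.

    Feasible for narrow matrices (the atom count is bounded by 4^width);
    returns (sorted distinct scores, suffix probability sums).
    """
    lo = np.log2(pwm.probs / pwm.background[None, :])
    scores = np.zeros(1)
    probs = np.ones(1)
    for c in range(pwm.width):
        scores = (scores[:, None] + lo[c][None, :]).ravel()
        probs = (probs[:, None] * pwm.background[None, :]).ravel()
        scores, inverse = np.unique(scores, return_inverse=True)
        probs = np.bincount(inverse, weights=probs)
    suffix = np.cumsum(probs[::-1])[::-1]
    return scores, suffix


def score_pvalue(pwm: Pwm, score: float, granularity: float = 1e-3) -> float:
    """P(score' >= score) for a background-drawn sequence of the PWM's width.

    The score distribution is built by dynamic programming (column-wise
    convolution): exactly for narrow matrices, on a lattice of bin width
    ``granularity`` bits for wide ones, where the result is exact up to
    discretization. Monotonically non-increasing in ``score``; 1.0 at or
    below the minimum achievable score.
    """
    return float(score_pvalues(pwm, np.array([score]), granularity)[0])


def score_pvalues(
    pwm: Pwm, scores: np.ndarray, granularity: float = 1e-3
) -> np.ndarray:
    """Vectorized :func:`score_pvalue` (one distribution build, many lookups)."""
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    scores = np.asarray(scores, dtype=float)
    if pwm.width <= _EXACT_WIDTH_LIMIT:
        atoms, suffix = _exact_score_sf(pwm)
        idx = np.searchsorted(atoms, scores - 1e-9, side="left")
        return suffix[np.minimum(idx, len(suffix) - 1)]
    lattice = _score_lattice_sf(pwm, granularity)
    return _sf_lookup(lattice, scores)


def _best_variant_hits(
    codes: np.ndarray,
    model: SpacedPwm,
    threshold: float,
    granularity: float,
) -> list[tuple[float, int, int, float]]:
    """All (pvalue, spacer, offset, score) passing threshold on one strand."""
    out = []
    n = len(codes)
    for s, pwm in model.variants.items():
        w = pwm.width
        if n < w:
            continue
        lo = pwm.log_odds()
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
        pvals = _sf_lookup(model.variant_sf(s, granularity), scores)
        for j in np.nonzero(pvals < threshold)[0]:
            out.append((float(pvals[j]), s, int(j), float(scores[j])))
    return out


def scan_window(
    seq: str,
    model: SpacedPwm,
    threshold: float = 1e-4,
    peak_name: str = "",
    granularity: float = 1e-3,
    report_all: bool = False,
):
    """Scan a summit-flanking window with every spacer variant on both strands.

    Returns the :class:`MotifHit` with the lowest exact p-value among all
    (position, strand, spacer) candidates passing ``threshold``, or ``None``
    if nothing passes. Ties are broken by smaller spacer, then smaller offset
    (in the input window's coordinates), then + strand. With ``report_all``
    every passing hit is returned, best first.
    """
    codes = encode_sequence(seq)
    n = len(codes)
    candidates: list[tuple[tuple, MotifHit]] = []
    for strand, strand_codes in (("+", codes), ("-", _COMPLEMENT_CODE[codes[::-1]])):
        for pval, s, j, score in _best_variant_hits(strand_codes, model, threshold, granularity):
            w = model.variants[s].width
            offset = j if strand == "+" else n - j - w
            matched = seq[offset:offset + w]
            if strand == "-":
                matched = reverse_complement(matched)
            hit = MotifHit(
                peak_name=peak_name, offset=offset, strand=strand,
                spacer=s, score=score, pvalue=pval, matched_seq=matched,
            )
            candidates.append(((pval, s, offset, 0 if strand == "+" else 1), hit))
    if not candidates:
        return [] if report_all else None
    candidates.sort(key=lambda t: t[0])
    if report_all:
        return [hit for _, hit in candidates]
    return candidates[0][1]


def classify_hits(
    hits: Mapping[str, MotifHit | None],
) -> tuple[dict[str, MotifClass], dict[MotifClass, float]]:
    """Per-peak motif class plus the class frequency summary (sums to 1)."""
    classes = {
        name: (MotifClass.NO_MOTIF if hit is None else hit.motif_class)
        for name, hit in hits.items()
    }
    n = len(classes)
    summary = {cls: 0.0 for cls in MotifClass}
    if n:
        for cls in classes.values():
            summary[cls] += 1.0 / n
    return classes, summary


def spacer_distribution(hits: Iterable[MotifHit | None]) -> np.ndarray:
    """Counts of spacer lengths 1..15 over SPACED hits (index 0 = spacer 1)."""
    counts = np.zeros(15, dtype=int)
    for hit in hits:
        if hit is not None and hit.spacer >= 1:
            counts[hit.spacer - 1] += 1
    return counts


def group_compare(
    values_by_class: Mapping[object, Sequence[float]],
    welch: bool = False,
) -> dict:
    """Pairwise two-sample Student's t-tests plus per-group box summaries.

    Pooled-variance Student's t by default (``welch=True`` for unequal
    variances). Every group must contain at least two observations.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_class.items()}
    for key, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {key!r} has fewer than 2 observations")
    summaries = {
        key: {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
        for key, vals in groups.items()
    }
    tests = {}
    keys = list(groups)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            t, p = stats.ttest_ind(groups[ka], groups[kb], equal_var=not welch)
            tests[(ka, kb)] = {"t": float(t), "pvalue": float(p)}
    return {"summaries": summaries, "tests": tests}


def p53_consensus_pwm(
    strong: float = 0.97,
    background: np.ndarray | None = None,
) -> Pwm:
    """High-information dimeric p53 PWM built from the RRRCWWGYYY consensus.

    Each half site follows the canonical decamer (R = A/G, W = A/T,
    Y = C/T); degenerate positions split ``strong`` probability evenly over
    the two allowed bases, invariant C/G positions concentrate it on one.
    The dimer is the tandem repeat of the half site (zero spacer).
    """
    if not (0.5 < strong < 1.0):
        raise ValueError("strong must be in (0.5, 1)")
    weak = (1.0 - strong) / 2.0   # disallowed bases at a 2-fold degenerate position
    split = strong / 2.0          # each of the two allowed bases
    off = (1.0 - strong) / 3.0    # disallowed bases at an invariant position
    rows = {
        "R": [split, weak, split, weak],
        "C": [off, strong, off, off],
        "W": [split, weak, weak, split],
        "G": [off, off, strong, off],
        "Y": [weak, split, weak, split],
    }
    half = np.array([rows[c] for c in "RRRCWWGYYY"])
    probs = np.vstack([half, half])
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    return Pwm(probs=probs, background=bg)
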