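"""Candidate spacer (target-window) ranking.

Every 32-nt window of a target transcript is scored on the criteria a guide
designer cares about for a type III complex: balanced GC content, low
self-complementarity (a proxy for secondary-structure propensity), minimal
complementarity of the derived spacer to other transcripts, and absence of
known polymorphisms. The composite is a transparent weighted penalty sum; the
returned list is best-first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._seq import gc_fraction, normalize, revcomp
from .errors import ParameterError
from .types import SPACER_LENGTH, TranscriptomeModel


@dataclass(frozen=True)
class SpacerWeights:
    """Penalty weights for the composite score (all penalties in [0, 1] after
    normalisation, except polymorphism hits which count raw)."""

    gc: float = 1.0
    hairpin: float = 1.0
    offtarget: float = 2.0
    polymorphism: float = 5.0


@dataclass
class SpacerCandidate:
    transcript_id: str
    start: int
    end: int
    gc_fraction: float
    gc_penalty: float
    hairpin_score: int
    offtarget_matches: int
    polymorphism_hits: int
    composite_score: float  # higher is better (negated penalty)


def hairpin_stem_score(window: str, min_stem: int = 4, min_loop: int = 3) -> int:
    """Longest ungapped self-complementary stem within the window with a loop of
    at least ``min_loop`` nt; 0 when no stem of ``min_stem`` or more exists."""
    w = normalize(window)
    n = len(w)
    comp = revcomp(w)  # comp[k] pairs with w[n-1-k]
    best = 0
    # stem arms [i, i+s) and (j-s, j]; w[i+t] pairs w[j-t]
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            s = 0
            while (
                i + s < n
                and j - s >= 0
                and (j - s) - (i + s) > min_loop
                and w[i + s] == comp[n - 1 - (j - s)]
            ):
                s += 1
            if s > best:
                best = s
    return best if best >= min_stem else 0


def scan_candidates(
    transcript_id: str,
    transcriptome: TranscriptomeModel,
    variants: Iterable[int] | None = None,
    coding_region: tuple[int, int] | None = None,
    weights: SpacerWeights = SpacerWeights(),
    allow_gu: bool = False,
) -> list[SpacerCandidate]:
    """Score and rank every 32-nt window of ``transcript_id``.

    ``variants`` is an iterable of 0-based transcript positions of known
    polymorphisms; ``coding_region`` restricts windows to a half-open interval.
    Returns candidates best-first (ties by coordinate); empty (with a warning)
    when the transcript is shorter than 32 nt.
    """
    from .offtarget import max_complementarity

    seq = transcriptome.get(transcript_id).sequence
    lo, hi = 0, len(seq)
    if coding_region is not None:
        lo, hi = coding_region
        if not 0 <= lo < hi <= len(seq):
            raise ParameterError("coding_region outside transcript")
    if hi - lo < SPACER_LENGTH:
        import warnings

        warnings.warn(f"region of {transcript_id} shorter than {SPACER_LENGTH} nt; no candidates", stacklevel=2)
        return []
    variant_positions = np.array(sorted(set(int(v) for v in (variants or []))), dtype=int)
    others = [t for t in transcriptome.transcripts if t.id != transcript_id]

    candidates = []
    for start in range(lo, hi - SPACER_LENGTH + 1):
        end = start + SPACER_LENGTH
        window = seq[start:end]
        gc = gc_fraction(window)
        spacer = revcomp(window)
        off = 0
        for t in others:
            m, _ = max_complementarity(spacer, t.sequence, allow_gu=allow_gu)
            off = max(off, m)
        hits = int(((variant_positions >= start) & (variant_positions < end)).sum())
        hp = hairpin_stem_score(window)
        penalty = (
            weights.gc * abs(gc - 0.5) * 2.0
            + weights.hairpin * hp / (SPACER_LENGTH / 2)
            + weights.offtarget * off / SPACER_LENGTH
            + weights.polymorphism * hits
        )
        candidates.append(
            SpacerCandidate(
                transcript_id,
                start,
                end,
                gc,
                abs(gc - 0.5),
                hp,
                off,
                hits,
                -penalty,
            )
        )
    candidates.sort(key=lambda c: (-c.composite_score, c.start))
    return candidates
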