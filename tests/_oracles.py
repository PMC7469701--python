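"""Independent brute-force oracles used to check the package's fast paths.

These are deliberately naive implementations (pure-Python loops, direct
definitions) kept independent of the package internals they validate.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def brute_force_max_complementarity(spacer: str, transcript: str, allow_gu: bool = False) -> tuple[int, int]:
    """Enumerate every ungapped register of the spacer against the transcript
    (including partial overlaps) and count pairing positions directly.

    Position j of the aligned transcript window pairs with spacer base
    s = spacer[len-1-j]; Watson-Crick pairing means s == complement(t), G:U
    wobble additionally allows (s=G, t=T) and (s=T, t=G).
    """
    k = len(spacer)
    L = len(transcript)
    best, best_start = -1, 0
    for start in range(-(k - 1), L):
        matches = 0
        for j in range(k):
            t_pos = start + j
            if not 0 <= t_pos < L:
                continue
            s = spacer[k - 1 - j]
            t = transcript[t_pos]
            if s == COMPLEMENT[t]:
                matches += 1
            elif allow_gu and ((s == "G" and t == "T") or (s == "T" and t == "G")):
                matches += 1
        if matches > best:
            best, best_start = matches, start
    return best, best_start


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, straight from the
    definition: sort, compute p*(m/rank), enforce monotonicity from the
    largest rank down, cap at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvalues[i] * m / rank_from_top
        running = min(running, val)
        adj[i] = min(running, 1.0)
    return adj
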