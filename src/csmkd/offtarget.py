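"""crRNA off-target complementarity scanning and the grouped trend test.

The scorer counts, over every ungapped alignment register of the 32-nt spacer
against a transcript's mRNA sequence (including partial overlaps at the ends),
the number of positions where the spacer base is the Watson-Crick complement of
the transcript base (optionally also G:U wobble pairs). Transcripts are then
grouped cumulatively by minimal match count and each group's summed counts are
tested for a condition effect with the batch-aware negative-binomial
likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import A, C, G, T, encode, normalize, revcomp
from .errors import InputError, ParameterError
from .types import SPACER_LENGTH, CountMatrix, SampleDesign, TranscriptomeModel


def max_complementarity(
    spacer: str,
    transcript: str,
    allow_gu: bool = False,
    spacer_length: int = SPACER_LENGTH,
) -> tuple[int, int]:
    """Maximal number of spacer:transcript base pairs over all ungapped
    registers.

    Returns ``(max_matches, start)`` where ``start`` is the 0-based transcript
    coordinate of the aligned window's first position (negative when the
    alignment overhangs the transcript 5' end). Ties resolve to the smallest
    start.
    """
    spacer = normalize(spacer)
    if len(spacer) != spacer_length:
        raise ParameterError(f"spacer must be {spacer_length} nt, got {len(spacer)}")
    transcript = normalize(transcript)
    k = len(spacer)
    # identity frame: position j of the aligned window pairs with the spacer
    # iff it equals position j of the spacer's reverse complement
    query = encode(revcomp(spacer))
    padded = np.full(len(transcript) + 2 * (k - 1), 255, dtype=np.uint8)
    padded[k - 1 : k - 1 + len(transcript)] = encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(padded, k)
    match = windows == query
    if allow_gu:
        # spacer G : transcript U  <=>  query C vs window T
        # spacer U : transcript G  <=>  query A vs window G
        match = match | ((query == C) & (windows == T)) | ((query == A) & (windows == G))
    scores = match.sum(axis=1)
    best = int(np.argmax(scores))
    return int(scores[best]), best - (k - 1)


@dataclass
class ComplementarityIndex:
    """Per-gene maximal spacer complementarity; ``table`` has columns
    max_matches and window_start, indexed by gene id."""

    table: pd.DataFrame
    spacer: str

    def genes_at_least(self, k: int, exclude: Sequence[str] = ()) -> list[str]:
        sel = self.table.index[self.table["max_matches"] >= k]
        return [g for g in sel if g not in set(exclude)]

    def histogram(self) -> pd.Series:
        return self.table["max_matches"].value_counts().sort_index()


def complementarity_index(
    spacer: str,
    transcriptome: TranscriptomeModel,
    allow_gu: bool = False,
) -> ComplementarityIndex:
    """Score every transcript in the model against the spacer."""
    if not transcriptome.transcripts:
        raise ParameterError("empty transcriptome")
    rows = {}
    for t in transcriptome.transcripts:
        m, start = max_complementarity(spacer, t.sequence, allow_gu=allow_gu)
        rows[t.id] = (m, start)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["max_matches", "window_start"])
    table.index.name = "gene_id"
    return ComplementarityIndex(table, normalize(spacer))


def group_trend(
    cm: CountMatrix,
    design: SampleDesign,
    index: ComplementarityIndex,
    thresholds: Sequence[int],
    exclude_target: bool = True,
    target_id: str = "target",
    knockdown_applies_to: str = "injected",
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Condition-effect test per cumulative complementarity group.

    For each threshold ``k`` (descending), the genes with ``max_matches >= k``
    (minus the target, so on-target signal cannot masquerade as an off-target
    trend) are summed into one pseudo-gene count vector and tested full
    (batch+condition) vs reduced (batch) with the NB LRT. Returns a table with
    columns threshold, n_genes, lfc, se, p, genes.
    """
    from .abundance import (
        estimate_dispersions_matrix,
        group_dispersion,
        lrt_counts,
        normalized_counts,
        size_factors,
    )

    thresholds = [int(k) for k in thresholds]
    if any(not 0 <= k <= SPACER_LENGTH for k in thresholds):
        raise ParameterError("thresholds must lie in [0, 32]")
    if sorted(thresholds, reverse=True) != thresholds:
        raise InputError("thresholds must be given in descending order")
    if aggregate not in ("sum", "median"):
        raise ParameterError("aggregate must be 'sum' or 'median'")

    cm = cm.align_to(design)
    sf = size_factors(cm)
    offsets = np.log(sf.to_numpy())
    exclude = [target_id] if exclude_target else []
    counts = cm.counts

    # the pseudo-gene dispersion is derived from the gene-wise trend (a sum of
    # independent NB genes is close to NB with alpha_G = sum a_i m_i^2 / (sum m_i)^2);
    # this borrows strength across the matrix instead of re-profiling 6 points
    norm_means = normalized_counts(cm, sf).mean(axis=1)
    informative = [g for g in cm.gene_ids if norm_means[g] >= 1.0]
    trend = None
    if len(informative) >= 20:
        est = estimate_dispersions_matrix(cm, design, offsets, genes=informative, treated=knockdown_applies_to)
        trend = est.trend

    rows = []
    for k in thresholds:
        genes = [g for g in index.genes_at_least(k, exclude=exclude) if g in counts.index]
        if not genes:
            rows.append({"threshold": k, "n_genes": 0, "lfc": np.nan, "se": np.nan, "p": np.nan, "genes": ()})
            continue
        if aggregate == "sum":
            y = counts.loc[genes].sum(axis=0).to_numpy()
        else:
            y = np.median(counts.loc[genes].to_numpy(), axis=0).round().astype(np.int64)
        alpha = None
        if trend is not None and aggregate == "sum":
            members = [g for g in genes if g in trend.index]
            if members:
                alpha = group_dispersion(
                    norm_means.loc[members].to_numpy(), trend.loc[members].to_numpy()
                )
        res = lrt_counts(y, design, offsets=offsets, alpha=alpha, treated=knockdown_applies_to)
        rows.append(
            {
                "threshold": k,
                "n_genes": len(genes),
                "lfc": res.log2_fold_change,
                "se": res.lfc_se,
                "p": res.p_value,
                "genes": tuple(genes),
            }
        )
    return pd.DataFrame(rows)
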