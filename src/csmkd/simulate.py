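"""Synthetic-data generator for stranded, polyA-selected RNA-seq of a Csm
RNA-knockdown experiment.

The generator is the study-condition oracle for every downstream module: it
produces transcriptomes with a designated target, crRNA guides, per-sample
fragment sets with known cleavage parameters, batch effects and crRNA
contamination, FACS-like event tables, and count matrices with known fold
changes.

Sampling model
--------------
Each sequenced fragment originates from one observable template molecule:

* an uncleaved target (or any background) molecule -> template ``[0, L)``;
* a cleaved, not fully degraded target molecule -> 3' fragment template
  ``[c, L)`` (carries the polyA tail, always selectable), plus its 5' fragment
  ``[0, c)`` which enters only with probability ``five_prime_survival``
  (incomplete polyA selection);
* a cleaved molecule that is degraded to completion contributes nothing.

A template of length ``L_t`` is fragmented into roughly
``n = round(L_t / mean_fragment_length)`` pieces; the sampled fragment is the
template-initial piece (start exactly at the template 5' end) with probability
``1/n``, the terminal piece (end at the template 3' end) with probability
``1/n``, and an interior uniform window otherwise. Templates shorter than one
mean fragment are sequenced whole. The initial-piece anchoring is what creates
the fragment-end pileup at a cleavage site that the profile module detects.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import ALPHABET, revcomp
from .errors import GenerationError, ParameterError
from .types import (
    ANTISENSE,
    SENSE,
    SPACER_LENGTH,
    CleavageModel,
    CountMatrix,
    CrRNA,
    FacsEventSet,
    FragmentSet,
    Sample,
    SampleDesign,
    Transcript,
    TranscriptomeModel,
)

TARGET_ID = "target"
LN2 = math.log(2.0)


def _rng(seed, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salt)]))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[c] for c in codes)


def make_transcriptome(
    n_genes: int = 50,
    length_range: tuple[int, int] = (400, 2000),
    gc_target: float = 0.5,
    target_length: int = 720,
    seed: int = 0,
    abundance_logmean: float = 2.0,
    abundance_logsd: float = 1.2,
    target_weight: float | None = None,
) -> TranscriptomeModel:
    """Random transcriptome with one designated target transcript.

    Sequences are i.i.d. with P(G)=P(C)=gc_target/2; base abundances are
    log-normal (long-tailed, like real expression levels). If ``target_weight``
    is given, the target's abundance is set so that it accounts for that
    fraction of total expression (the maternally deposited target transcript in
    the emulated study is highly expressed).
    """
    lo, hi = int(length_range[0]), int(length_range[1])
    if n_genes < 2:
        raise ParameterError("n_genes must be >= 2")
    if lo < 200 or hi < lo:
        raise ParameterError("transcript lengths must be >= 200 and range ordered")
    if not 0.0 < gc_target < 1.0:
        raise ParameterError("gc_target must be in (0, 1)")
    if target_length < 200:
        raise ParameterError("target_length must be >= 200")

    rng = _rng(seed, 1)
    lengths = rng.integers(lo, hi + 1, size=n_genes - 1)
    abundances = rng.lognormal(abundance_logmean, abundance_logsd, size=n_genes)
    transcripts = [Transcript(TARGET_ID, _random_sequence(rng, target_length, gc_target), float(abundances[0]))]
    for i, L in enumerate(lengths, start=1):
        transcripts.append(Transcript(f"g{i:04d}", _random_sequence(rng, int(L), gc_target), float(abundances[i])))
    model = TranscriptomeModel(tuple(transcripts), TARGET_ID)
    if target_weight is not None:
        if not 0.0 < target_weight < 1.0:
            raise ParameterError("target_weight must be in (0, 1)")
        other = sum(t.base_abundance for t in transcripts[1:])
        tgt = replace(transcripts[0], base_abundance=target_weight / (1 - target_weight) * other)
        model = TranscriptomeModel((tgt, *transcripts[1:]), TARGET_ID)
    return model


def make_crrna(model: TranscriptomeModel, protospacer_start: int) -> CrRNA:
    """Derive the crRNA whose spacer is the reverse complement of the target's
    protospacer window."""
    target = model.target
    if protospacer_start + SPACER_LENGTH > len(target):
        raise ParameterError("protospacer window does not fit on the target transcript")
    window = target.sequence[protospacer_start : protospacer_start + SPACER_LENGTH]
    crrna = CrRNA(revcomp(window), model.target_id, protospacer_start)
    crrna.check_against(model)
    return crrna


def make_design(
    n_batches: int = 3,
    timepoints: Sequence[str] = ("128cell", "5hpf", "24hpf"),
    conditions: Sequence[str] = ("injected", "mock"),
) -> SampleDesign:
    """Factorial design mirroring the emulated study: per timepoint, each
    replicate batch contributes one sample per condition (batch labels shared
    across conditions within a replica pairing)."""
    samples = []
    for tp in timepoints:
        for b in range(1, n_batches + 1):
            for cond in conditions:
                samples.append(Sample(f"{cond}_b{b}_{tp}", cond, f"b{b}", str(tp), b))
    return SampleDesign(tuple(samples))


def apply_batch_effects(
    model: TranscriptomeModel,
    design: SampleDesign,
    batch_factors: Mapping[str, float] | None = None,
    sigma: float = 0.6,
    seed: int = 0,
) -> TranscriptomeModel:
    """Attach per-sample multiplicative batch factors for the target's abundance
    (the emulated study saw strong target batch variation from homo-/
    heterozygous mothers). Explicit ``batch_factors`` map batch label -> factor;
    otherwise factors are drawn log-normally with the given sigma."""
    batches = sorted({s.batch for s in design.samples})
    if batch_factors is None:
        rng = _rng(seed, 2)
        batch_factors = {b: float(rng.lognormal(0.0, sigma)) for b in batches}
    multipliers = {s.sample_id: float(batch_factors[s.batch]) for s in design.samples}
    return model.with_multipliers(multipliers)


# ---------------------------------------------------------------------------
# complementarity planting
# ---------------------------------------------------------------------------


def plant_complementarity_spectrum(
    model: TranscriptomeModel,
    crrna: CrRNA,
    spectrum: Mapping[int, int],
    seed: int = 0,
    max_retries: int = 50,
    allow_gu: bool = False,
) -> TranscriptomeModel:
    """Splice spacer-pairing windows into non-target transcripts so that, for
    each ``k -> m`` in ``spectrum``, exactly ``m`` transcripts score a maximal
    complementarity of exactly ``k`` (verified with the off-target scorer;
    violating transcripts are resampled)."""
    from .offtarget import max_complementarity  # local import to avoid a cycle

    if not spectrum:
        return model
    for k, m in spectrum.items():
        if not 0 <= k <= SPACER_LENGTH or m < 0:
            raise ParameterError(f"invalid spectrum entry {k}:{m}")
    n_planted = sum(spectrum.values())
    others = [t for t in model.transcripts if t.id != model.target_id]
    if n_planted > len(others):
        raise ParameterError("spectrum requests more genes than available non-target transcripts")

    rng = _rng(seed, 3)
    proto = crrna.protospacer()
    kmin = min(spectrum)

    assignments: list[tuple[Transcript, int]] = []
    order = list(rng.permutation(len(others)))
    idx = 0
    for k, m in sorted(spectrum.items(), reverse=True):
        for _ in range(m):
            assignments.append((others[order[idx]], k))
            idx += 1
    planted_ids = {t.id: k for t, k in assignments}

    def plant_window(k: int) -> str:
        keep = rng.choice(SPACER_LENGTH, size=k, replace=False)
        window = list(proto)
        for j in range(SPACER_LENGTH):
            if j in set(keep.tolist()):
                continue
            choices = [b for b in ALPHABET if b != proto[j]]
            if allow_gu:
                # avoid bases that would still wobble-pair with the spacer
                spacer_base = revcomp(proto[j])  # single-base complement
                choices = [b for b in choices if not (spacer_base == "G" and b == "T") and not (spacer_base == "T" and b == "G")]
            window[j] = choices[rng.integers(len(choices))]
        return "".join(window)

    def splice(seq: str, window: str) -> str:
        pos = int(rng.integers(0, len(seq) - SPACER_LENGTH + 1))
        return seq[:pos] + window + seq[pos + SPACER_LENGTH :]

    new_transcripts = {t.id: t for t in model.transcripts}
    for t, k in assignments:
        for attempt in range(max_retries):
            cand = replace(t, sequence=splice(t.sequence, plant_window(k)))
            score, _ = max_complementarity(crrna.spacer, cand.sequence, allow_gu=allow_gu)
            if score == k:
                new_transcripts[t.id] = cand
                break
        else:
            raise GenerationError(f"could not plant complementarity {k} into {t.id} after {max_retries} tries")

    # keep unplanted background strictly below the smallest planted score
    gc = 0.5
    for t in others:
        if t.id in planted_ids:
            continue
        cur = new_transcripts[t.id]
        for attempt in range(max_retries):
            score, _ = max_complementarity(crrna.spacer, cur.sequence, allow_gu=allow_gu)
            if score < kmin:
                break
            cur = replace(cur, sequence=_random_sequence(rng, len(cur), gc))
        else:
            raise GenerationError(f"background transcript {t.id} kept reaching score >= {kmin}")
        new_transcripts[t.id] = cur

    return TranscriptomeModel(
        tuple(new_transcripts[i] for i in model.ids), model.target_id, dict(model.sample_multipliers)
    )


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------


def _draw_from_template(
    rng: np.random.Generator,
    a: int,
    b: int,
    n: int,
    fraglen: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised fragment sampling from template [a, b) under the piece model."""
    flmin, flmax = fraglen
    L = b - a
    mean_fl = 0.5 * (flmin + flmax)
    n_pieces = max(1, int(round(L / mean_fl)))
    if n_pieces == 1 or L <= flmin:
        starts = np.full(n, a, dtype=np.int64)
        ends = np.full(n, b, dtype=np.int64)
        return starts, ends
    ell = rng.integers(flmin, flmax + 1, size=n)
    np.minimum(ell, L, out=ell)
    starts = a + np.floor(rng.random(n) * (L - ell + 1)).astype(np.int64)
    u = rng.random(n)
    first = u < 1.0 / n_pieces
    last = (~first) & (u < 2.0 / n_pieces)
    starts[first] = a
    starts[last] = b - ell[last]
    return starts, starts + ell


def simulate_fragments(
    model: TranscriptomeModel,
    crrna: CrRNA | None,
    cleave: CleavageModel | None,
    design: SampleDesign,
    depth: int = 100_000,
    fraglen: tuple[int, int] = (180, 320),
    knockdown_applies_to: str = "injected",
    seed: int = 0,
    dispersion: float = 0.05,
) -> FragmentSet:
    """Simulate stranded, polyA-selected sense fragments for every sample.

    Per sample, per-transcript fragment counts are negative-binomial around
    ``depth`` split by effective abundance (the target's abundance is scaled by
    its per-sample batch multiplier, and in treated samples by the cleavage
    model's observable-mass factor). Treated-sample target fragments draw their
    template from the uncleaved / 3'-fragment / surviving-5'-fragment mixture.
    """
    if depth <= 0:
        raise ParameterError("depth must be > 0")
    if fraglen[0] < 1 or fraglen[1] < fraglen[0]:
        raise ParameterError("fragment length range must be ordered and >= 1")
    if crrna is not None:
        crrna.check_against(model)
    if not 0.0 <= dispersion:
        raise ParameterError("dispersion must be >= 0")

    treat = cleave is not None and crrna is not None
    base = np.array([t.base_abundance for t in model.transcripts], dtype=float)
    ids = model.ids
    lengths = model.lengths
    t_idx = ids.index(model.target_id)

    rows_sample: list[np.ndarray] = []
    rows_transcript: list[np.ndarray] = []
    rows_start: list[np.ndarray] = []
    rows_end: list[np.ndarray] = []

    for si, s in enumerate(design.samples):
        rng = _rng(seed, 10, si)
        ab = base.copy()
        ab[t_idx] *= model.sample_multipliers.get(s.sample_id, 1.0)
        treated_sample = treat and s.condition == knockdown_applies_to
        if treated_sample:
            ab[t_idx] *= cleave.observable_mass()
        mu = depth * ab / ab.sum()
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)

        for ti, tid in enumerate(ids):
            n = int(counts[ti])
            if n == 0:
                continue
            L = lengths[tid]
            if treated_sample and ti == t_idx and cleave.cut_prob > 0:
                p, d, f5 = cleave.cut_prob, cleave.degradation_to_completion_prob, cleave.five_prime_survival
                w = np.array([1.0 - p, p * (1.0 - d), p * (1.0 - d) * f5])
                if w.sum() <= 0:
                    continue
                w = w / w.sum()
                kind = rng.choice(3, size=n, p=w)
                cuts = cleave.cut_positions(crrna.protospacer_start)
                for c in cuts:
                    if not 0 < c < L:
                        raise ParameterError(f"cut position {c} outside target transcript")
                cut_choice = rng.integers(0, len(cuts), size=n)
                parts: list[tuple[int, int, int]] = [(0, L, int((kind == 0).sum()))]
                for ci, c in enumerate(cuts):
                    sel = cut_choice == ci
                    parts.append((c, L, int(((kind == 1) & sel).sum())))
                    parts.append((0, c, int(((kind == 2) & sel).sum())))
                for a, b, m in parts:
                    if m == 0 or b <= a:
                        continue
                    st, en = _draw_from_template(rng, a, b, m, fraglen)
                    rows_sample.append(np.full(m, s.sample_id, dtype=object))
                    rows_transcript.append(np.full(m, tid, dtype=object))
                    rows_start.append(st)
                    rows_end.append(en)
            else:
                st, en = _draw_from_template(rng, 0, L, n, fraglen)
                rows_sample.append(np.full(n, s.sample_id, dtype=object))
                rows_transcript.append(np.full(n, tid, dtype=object))
                rows_start.append(st)
                rows_end.append(en)

    if rows_sample:
        df = pd.DataFrame(
            {
                "sample_id": np.concatenate(rows_sample),
                "transcript_id": np.concatenate(rows_transcript),
                "start": np.concatenate(rows_start),
                "end": np.concatenate(rows_end),
            }
        )
    else:
        df = pd.DataFrame(columns=["sample_id", "transcript_id", "start", "end"])
    df["strand"] = SENSE
    df["flag"] = "sim"
    return FragmentSet(df, lengths)


def expected_target_count_ratio(cleave: CleavageModel, model: TranscriptomeModel, target_weight: float | None = None) -> float:
    """Closed-form expected treated/mock ratio of total target fragment counts
    (equal batch multipliers), accounting for the per-sample depth
    renormalisation over the transcriptome."""
    base = np.array([t.base_abundance for t in model.transcripts], dtype=float)
    t_idx = model.ids.index(model.target_id)
    E = cleave.observable_mass()
    tot = base.sum()
    tot_treated = tot - base[t_idx] + base[t_idx] * E
    return E * tot / tot_treated


def spike_crrna_contamination(
    frags: FragmentSet,
    crrna: CrRNA,
    rate_per_sample: Mapping[str, float],
    seed: int = 0,
    min_length: int = 16,
) -> FragmentSet:
    """Add antisense crRNA-contamination records confined to the protospacer
    window on the target; per sample the count is ``round(rate * sample
    total)``."""
    for r in rate_per_sample.values():
        if r < 0:
            raise ParameterError("contamination rates must be >= 0")
    if all(r == 0 for r in rate_per_sample.values()):
        return frags
    totals = frags.counts_per_sample()
    ps, pe = crrna.protospacer_start, crrna.protospacer_end
    chunks = [frags.df]
    for si, (sample_id, rate) in enumerate(sorted(rate_per_sample.items())):
        n = int(round(rate * int(totals.get(sample_id, 0))))
        if n == 0:
            continue
        rng = _rng(seed, 20, si)
        ell = rng.integers(min_length, SPACER_LENGTH + 1, size=n)
        starts = ps + np.floor(rng.random(n) * (SPACER_LENGTH - ell + 1)).astype(np.int64)
        chunks.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "transcript_id": crrna.target_id,
                    "start": starts,
                    "end": starts + ell,
                    "strand": ANTISENSE,
                    "flag": "contam",
                }
            )
        )
    df = pd.concat(chunks, ignore_index=True)
    return FragmentSet(df, dict(frags.transcript_lengths))


def counts_from_fragments(frags: FragmentSet, strand: str = SENSE) -> CountMatrix:
    """Aggregate a FragmentSet into a gene-by-sample count matrix (sense
    fragments only by default, so contamination does not inflate counts)."""
    sub = frags.df[frags.df["strand"] == strand]
    table = sub.groupby(["transcript_id", "sample_id"]).size().unstack(fill_value=0)
    table = table.reindex(index=sorted(frags.transcript_lengths), fill_value=0)
    table = table.reindex(columns=sorted(sub["sample_id"].unique()), fill_value=0)
    table.index.name = "gene_id"
    return CountMatrix(table)


# ---------------------------------------------------------------------------
# count-level simulation (for the abundance-test module)
# ---------------------------------------------------------------------------


def simulate_counts(
    design: SampleDesign,
    n_genes: int = 1000,
    libsize: float = 100_000.0,
    dispersion: float = 0.05,
    condition_log2fc: Mapping[str, float] | None = None,
    target_batch_log2fc: Mapping[str, float] | None = None,
    knockdown_applies_to: str = "injected",
    seed: int = 0,
    mean_logmean: float = 2.0,
    mean_logsd: float = 1.2,
) -> CountMatrix:
    """Negative-binomial count matrix with known per-gene condition effects.

    ``condition_log2fc`` maps gene id -> log2 fold change applied in treated
    samples; ``target_batch_log2fc`` maps batch label -> log2 effect applied to
    the gene named ``target`` (batch effects on the target only, as in the
    emulated study). Gene ids are ``target, g0001, ...``.
    """
    rng = _rng(seed, 30)
    gene_ids = [TARGET_ID] + [f"g{i:04d}" for i in range(1, n_genes)]
    base = rng.lognormal(mean_logmean, mean_logsd, size=n_genes)
    rel = base / base.sum()
    condition_log2fc = dict(condition_log2fc or {})
    target_batch_log2fc = dict(target_batch_log2fc or {})

    cols = {}
    for si, s in enumerate(design.samples):
        mu = libsize * rel.copy()
        if s.condition == knockdown_applies_to:
            for g, lfc in condition_log2fc.items():
                mu[gene_ids.index(g)] *= 2.0**lfc
        if s.batch in target_batch_log2fc:
            mu[0] *= 2.0 ** target_batch_log2fc[s.batch]
        srng = _rng(seed, 31, si)
        if dispersion > 0:
            lam = srng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        else:
            lam = mu
        cols[s.sample_id] = srng.poisson(lam)
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# FACS simulation
# ---------------------------------------------------------------------------


def simulate_facs_events(
    n: int,
    log_mean: float = 2.0,
    log_sd: float = 0.8,
    high_frac: float = 0.002,
    high_multiplier: float = 2000.0,
    knockdown_factor: float = 1.0,
    seed: int = 0,
    sample_id: str = "sample",
) -> FacsEventSet:
    """Mixture of a log-normal background population and a rare
    high-fluorescence population (the strongly expressing cells); knockdown
    divides the high-population frequency by ``knockdown_factor``. High events
    carry elevated side scatter."""
    if not 0.0 <= high_frac <= 1.0:
        raise ParameterError("high_frac must be in [0, 1]")
    if knockdown_factor < 1.0:
        raise ParameterError("knockdown_factor must be >= 1")
    rng = _rng(seed, 40)
    hf = high_frac / knockdown_factor
    is_high = rng.random(n) < hf
    mu = log_mean + np.where(is_high, math.log(high_multiplier), 0.0)
    fluor = np.exp(rng.normal(mu, log_sd))
    ssc = np.exp(rng.normal(1.0 + np.where(is_high, 1.5, 0.0), 0.5))
    return FacsEventSet(pd.DataFrame({"sample_id": sample_id, "fluorescence": fluor, "side_scatter": ssc}))
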