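"""Core domain containers shared by the simulator and the analysis modules.

Coordinates are 0-based, half-open, transcript-relative, ascending 5'->3'.
Strand is defined relative to the mRNA: ``sense`` reads come from the transcript
itself, ``antisense`` reads (e.g. crRNA contamination) from its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import normalize, revcomp
from .errors import InputError, ParameterError

SENSE = "sense"
ANTISENSE = "antisense"

FRAGMENT_COLUMNS = ["sample_id", "transcript_id", "start", "end", "strand", "flag"]


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    base_abundance: float

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize(self.sequence))
        if not self.id:
            raise ParameterError("transcript id must be non-empty")
        if not self.base_abundance > 0:
            raise ParameterError(f"abundance of {self.id} must be > 0")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptomeModel:
    """Transcript sequences with expression ground truth.

    ``sample_multipliers`` holds per-sample multiplicative factors applied to the
    *target's* abundance (batch effects act on the target by default; see
    :func:`csmkd.simulate.apply_batch_effects`).
    """

    transcripts: tuple[Transcript, ...]
    target_id: str
    sample_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate transcript ids")
        if self.target_id not in ids:
            raise ParameterError(f"target_id {self.target_id!r} not among transcripts")
        for m in self.sample_multipliers.values():
            if not m > 0:
                raise ParameterError("sample multipliers must be > 0")

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    @property
    def lengths(self) -> dict[str, int]:
        return {t.id: len(t) for t in self.transcripts}

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def target(self) -> Transcript:
        return self.get(self.target_id)

    def with_multipliers(self, multipliers: dict[str, float]) -> "TranscriptomeModel":
        return replace(self, sample_multipliers=dict(multipliers))


SPACER_LENGTH = 32


@dataclass(frozen=True)
class CrRNA:
    """A crRNA guide. The 32-nt spacer is the reverse complement of the
    protospacer window ``[protospacer_start, protospacer_start + 32)`` on the
    target mRNA."""

    spacer: str
    target_id: str
    protospacer_start: int

    def __post_init__(self):
        object.__setattr__(self, "spacer", normalize(self.spacer))
        if len(self.spacer) != SPACER_LENGTH:
            raise ParameterError(f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}")
        if self.protospacer_start < 0:
            raise ParameterError("protospacer_start must be >= 0")

    @property
    def protospacer_end(self) -> int:
        return self.protospacer_start + SPACER_LENGTH

    def protospacer(self) -> str:
        """The mRNA-side sequence the spacer pairs with."""
        return revcomp(self.spacer)

    def check_against(self, model: TranscriptomeModel) -> None:
        t = model.get(self.target_id)
        if self.protospacer_end > len(t):
            raise ParameterError("protospacer window extends beyond the target transcript")
        window = t.sequence[self.protospacer_start : self.protospacer_end]
        if window != self.protospacer():
            raise ParameterError("spacer is not the reverse complement of the protospacer window")


@dataclass(frozen=True)
class CleavageModel:
    """Csm cleavage parameters.

    cut_prob
        Fraction of target molecules cleaved in treated samples.
    cut_offsets
        Cut positions relative to ``protospacer_start``; more than one entry
        models staggered cutting (type III complexes cut at regularly spaced
        sites within the protospacer).
    stagger
        Nominal spacing in nt between staggered cuts (bookkeeping only; the
        actual sites are ``cut_offsets``).
    five_prime_survival
        Probability that a 5' cleavage fragment (no polyA tail) still enters
        the library despite polyA selection.
    degradation_to_completion_prob
        Probability that a cleaved molecule is removed entirely by endogenous
        decay before sampling.
    """

    cut_prob: float = 0.9
    cut_offsets: tuple[int, ...] = (0,)
    stagger: int = 6
    five_prime_survival: float = 0.05
    degradation_to_completion_prob: float = 0.9

    def __post_init__(self):
        object.__setattr__(self, "cut_offsets", tuple(int(o) for o in self.cut_offsets))
        for p, name in [
            (self.cut_prob, "cut_prob"),
            (self.five_prime_survival, "five_prime_survival"),
            (self.degradation_to_completion_prob, "degradation_to_completion_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if len(self.cut_offsets) < 1:
            raise ParameterError("cut_offsets must have at least one entry")
        for o in self.cut_offsets:
            if not 0 <= o < SPACER_LENGTH:
                raise ParameterError(f"cut offsets must lie in [0, {SPACER_LENGTH}), got {o}")

    def cut_positions(self, protospacer_start: int) -> list[int]:
        return [protospacer_start + o for o in self.cut_offsets]

    def observable_mass(self) -> float:
        """Expected number of library-observable template molecules per original
        target molecule: uncleaved molecules count 1; a cleaved, not fully
        degraded molecule contributes its 3' fragment plus (with probability
        ``five_prime_survival``) its 5' fragment."""
        p, d, f5 = self.cut_prob, self.degradation_to_completion_prob, self.five_prime_survival
        return (1.0 - p) + p * (1.0 - d) * (1.0 + f5)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    batch: str
    timepoint: str
    replicate: int = 0


@dataclass(frozen=True)
class SampleDesign:
    samples: tuple[Sample, ...]

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        return sorted({s.condition for s in self.samples})

    def get(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, *, timepoint: str | None = None, condition: str | None = None) -> "SampleDesign":
        kept = [
            s
            for s in self.samples
            if (timepoint is None or s.timepoint == timepoint)
            and (condition is None or s.condition == condition)
        ]
        return SampleDesign(tuple(kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(
            tuple(
                Sample(
                    str(r.sample_id),
                    str(r.condition),
                    str(r.batch),
                    str(r.timepoint),
                    int(r.replicate),
                )
                for r in df.itertuples()
            )
        )


@dataclass
class FragmentSet:
    """Per-sample sequenced fragment intervals in transcript coordinates.

    ``df`` columns: sample_id, transcript_id, start, end, strand, flag.
    ``transcript_lengths`` lets the profile machinery validate coordinates and
    size its per-position vectors.
    """

    df: pd.DataFrame
    transcript_lengths: dict[str, int]

    def __post_init__(self):
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"fragment table missing columns {missing}")
        self.df = self.df[FRAGMENT_COLUMNS].reset_index(drop=True)
        if len(self.df):
            starts = self.df["start"].to_numpy()
            ends = self.df["end"].to_numpy()
            if (starts < 0).any() or (ends <= starts).any():
                raise InputError("fragments must satisfy 0 <= start < end")
            lens = self.df["transcript_id"].map(self.transcript_lengths)
            if lens.isna().any():
                unknown = sorted(self.df.loc[lens.isna(), "transcript_id"].unique())
                raise InputError(f"fragments on transcripts of unknown length: {unknown}")
            if (ends > lens.to_numpy()).any():
                raise InputError("fragment end exceeds transcript length")
            bad = set(self.df["strand"].unique()) - {SENSE, ANTISENSE}
            if bad:
                raise InputError(f"unknown strand values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def counts_per_sample(self) -> pd.Series:
        return self.df.groupby("sample_id").size()

    @staticmethod
    def empty(transcript_lengths: dict[str, int]) -> "FragmentSet":
        df = pd.DataFrame({c: pd.Series(dtype=("int64" if c in ("start", "end") else "object")) for c in FRAGMENT_COLUMNS})
        return FragmentSet(df, dict(transcript_lengths))


@dataclass
class FacsEventSet:
    """Flow-cytometry-like event table: sample_id, fluorescence, side_scatter."""

    df: pd.DataFrame

    def __post_init__(self):
        for c in ("sample_id", "fluorescence", "side_scatter"):
            if c not in self.df.columns:
                raise InputError(f"FACS event table missing column {c!r}")
        if (self.df["fluorescence"].to_numpy() < 0).any():
            raise InputError("fluorescence must be non-negative")

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.df[self.df["sample_id"] == sample_id]
        if not len(sub):
            raise InputError(f"no events for sample {sample_id!r}")
        return sub


@dataclass
class CountMatrix:
    """Gene-by-sample integer count matrix (genes as rows)."""

    counts: pd.DataFrame

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise InputError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def align_to(self, design: SampleDesign) -> "CountMatrix":
        missing = [s for s in design.sample_ids if s not in self.counts.columns]
        if missing:
            raise InputError(f"count matrix lacks samples {missing}")
        return CountMatrix(self.counts[design.sample_ids])
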