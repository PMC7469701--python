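import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from csmkd import simulate
from csmkd.types import CleavageModel, FragmentSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_model():
    """Five-gene transcriptome with a highly expressed 720-nt target."""
    return simulate.make_transcriptome(n_genes=5, target_length=720, target_weight=0.25, seed=7)


@pytest.fixture(scope="session")
def crrna(small_model):
    return simulate.make_crrna(small_model, 300)


@pytest.fixture(scope="session")
def design_1tp():
    return simulate.make_design(n_batches=3, timepoints=["t1"])


@pytest.fixture(scope="session")
def cleaved_frags(small_model, crrna, design_1tp):
    """Treated-vs-mock fragment sets with a single cut at 300 (cut_prob 0.8)."""
    cleave = CleavageModel(cut_prob=0.8)
    return simulate.simulate_fragments(small_model, crrna, cleave, design_1tp, depth=100_000, seed=11)


def make_frags(records, lengths):
    """FragmentSet from (sample, transcript, start, end[, strand, flag]) tuples."""
    rows = []
    for r in records:
        strand = r[4] if len(r) > 4 else "sense"
        flag = r[5] if len(r) > 5 else "sim"
        rows.append((r[0], r[1], r[2], r[3], strand, flag))
    df = pd.DataFrame(rows, columns=["sample_id", "transcript_id", "start", "end", "strand", "flag"])
    return FragmentSet(df, lengths)


@pytest.fixture
def frag_builder():
    return make_frags
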