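import itertools

import pytest

from seqhet import (
    ABSENT,
    RankedSequence,
    SearchParams,
    load_paper_dataset,
    run_pipeline,
)


def make_seq(**ranks):
    """Sequence over letter events A, B, C, ... (ids 1, 2, 3, ...)."""
    ids = {ch: i + 1 for i, ch in enumerate("ABCDEFGHIJKL")}
    return RankedSequence.from_ranks(
        {ids[k]: (ABSENT if v is None else v) for k, v in ranks.items()}
    )


def brute_force_parsimov_cost(seq_a, seq_b):
    """Independent oracle: smallest event subset meeting every changed pair."""
    from seqhet import changed_pairs

    pairs = [set(p) for p in changed_pairs(seq_a, seq_b)]
    if not pairs:
        return 0
    events = sorted(set().union(*pairs))
    for k in range(len(events) + 1):
        for subset in itertools.combinations(events, k):
            s = set(subset)
            if all(p & s for p in pairs):
                return k
    raise AssertionError("unreachable")


@pytest.fixture(scope="session")
def paper_ds():
    return load_paper_dataset()


@pytest.fixture(scope="session")
def paper_pipeline(paper_ds):
    """Full three-run analysis of the built-in dataset at default settings."""
    return run_pipeline(paper_ds, SearchParams(seed=1), n_runs=3)
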