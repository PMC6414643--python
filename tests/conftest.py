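import numpy as np
import pytest

from combedit import AmpliconReference, reported_profile_pair


@pytest.fixture(scope="session")
def ref() -> AmpliconReference:
    return AmpliconReference.default()


@pytest.fixture(scope="session")
def profile_pair():
    return reported_profile_pair()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def naive_pattern_from_read(seq: str, ref: AmpliconReference) -> str | None:
    """Independent per-read re-scan: inspect the raw read string directly.

    Assumes a full-length, indel-free read (length == full contig); returns
    the pattern label from direct character inspection at the site offsets,
    or None when any site base is not A/G.  Deliberately bypasses the
    package's alignment, classification and calling machinery.
    """
    assert len(seq) == len(ref.full_contig)
    edited = []
    for label, pos in ref.site_positions.items():
        base = seq[pos]
        if base == "G":
            edited.append(label)
        elif base != "A":
            return None
    if not edited:
        return "NoEdit"
    order = "123ABECDFGH"
    return "".join(sorted(edited, key=order.index))


def stepup_bh_oracle(p_values):
    """Hand-coded Benjamini-Hochberg step-up: sort ascending, multiply by
    m/rank, enforce monotonicity from the largest p down, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted
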