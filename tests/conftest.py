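import numpy as np
import pandas as pd
import pytest

from dropculture.kinetics import GompertzParams
from dropculture.synthesize import SyntheticCommunitySpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_spec(params, growing, fractions=None, carbons=("inulin", "xylan"),
              truth=None, taxonomy=None, seed=0):
    """Hand-build a small community spec for targeted tests."""
    n = len(params)
    sv_ids = [f"sv{i:03d}" for i in range(n)]
    if fractions is None:
        fractions = np.full(n, 1.0 / n)
    if taxonomy is None:
        taxonomy = pd.Series(["Firmicutes"] * n, index=sv_ids, name="phylum")
    cols = list(carbons) + ["glucose"]
    if truth is None:
        truth = pd.DataFrame(False, index=sv_ids, columns=cols)
        truth["glucose"] = growing
    return SyntheticCommunitySpec(
        growth_params=np.array([[p.A, p.mu, p.lam, p.A0] for p in params]),
        growing_flags=np.asarray(growing, dtype=bool),
        initial_fractions=np.asarray(fractions, dtype=float),
        taxonomy=taxonomy,
        utilization_truth=truth,
        seed=seed,
        sv_ids=sv_ids,
    )


@pytest.fixture
def single_grower_spec():
    """One growing SV alone, known curve (A=5, mu=1, lam=3, A0=2)."""
    return make_spec([GompertzParams(5.0, 1.0, 3.0, 2.0)], [True])
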