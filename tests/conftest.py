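from __future__ import annotations

import numpy as np
import pytest

from egt.core import Genome, Role


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def make_genome():
    def _make(seq: str, gid: str = "g", **kw) -> Genome:
        return Genome(id=gid, seq=seq, **kw)

    return _make
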