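from __future__ import annotations

import numpy as np
import pytest

from mtharvest import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def small_fixture(tmp_path):
    """A small multi-study dataset with every pathology switched on."""
    spec = fixtures.FixtureSpec(
        seed=11,
        studies=(
            fixtures.StudySpec(n_samples=10),
            fixtures.StudySpec(n_samples=8),
            fixtures.StudySpec(n_samples=6, deposition="unique"),
        ),
        n_haplotypes=4,
        n_refseq_duplicates=2,
        n_outliers=1,
        gene_length=480,
    )
    out = fixtures.generate_records(spec, tmp_path / "fx")
    return spec, out
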