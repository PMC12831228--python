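import numpy as np
import pandas as pd
import pytest

from wormepi.chipseq import CoverageTrack, GenomeAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_annotation():
    """Three genes on one 10 kb chromosome, mixed strands."""
    return GenomeAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": ["chrI", "chrI", "chrI"],
                "start": [2000, 5000, 8000],
                "end": [2600, 5600, 8600],
                "strand": ["+", "-", "+"],
            }
        )
    )


def constant_track(value: float, length: int = 10_000, chrom: str = "chrI", **meta):
    return CoverageTrack({chrom: np.full(length, float(value))}, **meta)


@pytest.fixture
def constant_track_factory():
    return constant_track
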