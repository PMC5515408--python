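import numpy as np
import pytest

from eboxscape import pbm_analysis, synthetic_data


@pytest.fixture(scope="session")
def library():
    return pbm_analysis.build_probe_library(seed=0)


@pytest.fixture(scope="session")
def affinity():
    return synthetic_data.default_affinity_table()


@pytest.fixture(scope="session")
def noiseless_scores(library, affinity):
    raw = synthetic_data.gen_pbm_intensities(library, affinity, noise_cv=0.0, seed=0)
    return pbm_analysis.normalize_array(raw)


@pytest.fixture(scope="session")
def small_genome():
    return synthetic_data.gen_genome(n_chrom=2, length=50_000, gc=0.5, seed=42)


def brute_force_motif_count(seq: str, motif: str) -> int:
    """Independent oracle: overlapping exact substring matches on both strands.

    Palindromes are counted once per position.
    """
    import re

    from eboxscape import revcomp

    total = len(re.findall(f"(?={motif})", seq))
    rc = revcomp(motif)
    if rc != motif:
        total += len(re.findall(f"(?={rc})", seq))
    return total


@pytest.fixture(scope="session")
def brute_count():
    return brute_force_motif_count
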