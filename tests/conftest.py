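import numpy as np
import pandas as pd
import pytest

from cagepeaks import CTSSTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ctss():
    """Three CTSS records on one strand."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [100, 150, 400],
            "strand": ["+", "+", "+"],
            "count": [1, 1, 2],
        }
    )
    return CTSSTable(df)


def make_sam(path, records, chroms=(("chr1", 100000),)):
    """Write a minimal SAM file; records are (name, flag, chrom, pos1, cigar)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for name, length in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for name, flag, chrom, pos1, cigar in records:
            seq = "A" * 20
            fh.write(
                f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )
    return path
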