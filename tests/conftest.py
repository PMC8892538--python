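import numpy as np
import pytest

from scaffotype3d.synteny import AlignmentBlock, SyntenyBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_block(ref_chrom="chrA", ref_start=0, ref_end=1000, tgt="s1",
               tgt_start=0, tgt_end=1000, orientation="+"):
    return AlignmentBlock(ref_chrom, ref_start, ref_end, tgt, tgt_start, tgt_end, orientation)


def make_hsb(id=1, ref_chrom="chrA", ref_start=0, ref_end=1_000_000, tgt="s1",
             tgt_start=0, tgt_end=1_000_000, orientation="+", resolution=300_000, n=1):
    return SyntenyBlock(id, ref_chrom, ref_start, ref_end, tgt, tgt_start, tgt_end,
                        orientation, resolution, n)
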