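import numpy as np
import pytest

from mitomethyl import (
    EndCountProfile,
    GeneAnnotation,
    LibraryMeta,
    MtAnnotation,
    ReferenceIndex,
    Strand,
)
from mitomethyl.occupancy import OverlapInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ref100():
    return ReferenceIndex(name="toy", length_nt=100)


@pytest.fixture
def toy_annotation():
    """One 300-nt plus-strand CDS starting at position 101."""
    gene = GeneAnnotation(gene="TOY1", category="mRNA", strand=Strand.plus,
                          cds_start=101, cds_end=400)
    return MtAnnotation(genes=(gene,))


@pytest.fixture
def overlap_annotation():
    """Two plus-strand CDSs sharing positions 251-300."""
    a = GeneAnnotation(gene="GA", category="mRNA", strand=Strand.plus,
                       cds_start=101, cds_end=300)
    b = GeneAnnotation(gene="GB", category="mRNA", strand=Strand.plus,
                       cds_start=251, cds_end=500)
    ov = OverlapInterval(gene_a="GA", gene_b="GB", start=251, end=300)
    return MtAnnotation(genes=(a, b), overlaps=(ov,))


def random_intervals(rng, n, L, lmin=25, lmax=55):
    """n random 1-based inclusive read spans on a length-L reference."""
    out = []
    for _ in range(n):
        length = int(rng.integers(lmin, lmax + 1))
        s = int(rng.integers(1, L - length + 2))
        out.append((s, s + length - 1))
    return out


def brute_force_profile(intervals, reference, strand=Strand.plus):
    """Per-position tally of interval membership and endpoints by loops."""
    L = reference.length_nt
    C = np.zeros(L, dtype=np.int64)
    S = np.zeros(L, dtype=np.int64)
    E = np.zeros(L, dtype=np.int64)
    for s, e in intervals:
        S[s - 1] += 1
        E[e - 1] += 1
        for j in range(s, e + 1):
            C[j - 1] += 1
    return EndCountProfile(
        reference=reference, strand=strand, coverage=C, starts5=S, ends3=E,
        meta=LibraryMeta(sample_id="brute"),
    )
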