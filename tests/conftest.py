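import numpy as np
import pytest

from ampcnv import Cluster, CountTable, PrimerCount, PrimerSite


def make_primer(chrom="chr1", pos=100, c_sample=1000, c_control=1000, x=None, gene=None, name=""):
    p = PrimerCount(PrimerSite(chrom, pos, "+", name or f"a{pos}", gene), c_sample, c_control)
    if x is not None:
        p.x = float(x)
        p.r = float(x)
    return p


def make_cluster(xs, weights=None, chrom="chr1", start=100, spacing=200, cid="chr1:c1"):
    """Cluster with given normalized log2 ratios; weights split evenly into counts."""
    if weights is None:
        weights = [2000.0] * len(xs)
    members = [
        make_primer(chrom, start + i * spacing, w / 2, w / 2, x=x)
        for i, (x, w) in enumerate(zip(xs, weights))
    ]
    return Cluster(cid, chrom, members)


def make_table(records, **kw):
    """records: iterable of (chrom, pos, c_sample, c_control[, gene])."""
    primers = []
    for rec in records:
        chrom, pos, c_s, c_c = rec[:4]
        gene = rec[4] if len(rec) > 4 else None
        primers.append(make_primer(chrom, pos, c_s, c_c, gene=gene))
    return CountTable(primers, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
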