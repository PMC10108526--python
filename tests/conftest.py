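import numpy as np
import pandas as pd
import pytest

from inophase.io import EventRead, PileupTable


def make_pileup(sample_id, rows):
    """Build a PileupTable from (transcript_id, pos, ref, nA, nC, nG, nT) tuples."""
    df = pd.DataFrame(
        rows, columns=["transcript_id", "pos", "ref_base", "nA", "nC", "nG", "nT"]
    )
    df["depth"] = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    df = df[["transcript_id", "pos", "ref_base", "depth", "nA", "nC", "nG", "nT"]]
    return PileupTable(sample_id=sample_id, df=df).validate()


def make_read(read_id, transcript_id, start, ref_seq, called_seq=None, norm_mean=None):
    """Small EventRead with contiguous positions and benign defaults."""
    n = len(ref_seq)
    called = called_seq if called_seq is not None else ref_seq
    return EventRead(
        read_id=read_id,
        transcript_id=transcript_id,
        pos=np.arange(start, start + n),
        ref_base=list(ref_seq),
        called_base=list(called),
        norm_mean=np.zeros(n) if norm_mean is None else np.asarray(norm_mean, float),
        norm_std=np.full(n, 0.5),
        dwell=np.full(n, 10),
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def random_reads(rng):
    """A batch of randomized valid reads on two transcripts."""
    bases = np.array(list("ACGT"))
    refs = {f"tx{k}": rng.choice(bases, size=30) for k in range(2)}
    reads = []
    for i in range(50):
        tx = f"tx{i % 2}"
        start = int(rng.integers(0, 5))
        n = int(rng.integers(6, 15))
        ref = refs[tx][start : start + n]
        called = ref.copy()
        flip = rng.random(n) < 0.1
        called[flip] = rng.choice(bases, size=int(flip.sum()))
        reads.append(
            EventRead(
                read_id=f"r{i:03d}",
                transcript_id=tx,
                pos=np.arange(start, start + n),
                ref_base=ref,
                called_base=called,
                norm_mean=rng.standard_normal(n),
                norm_std=rng.gamma(5.0, 0.1, n),
                dwell=rng.geometric(0.1, n),
            ).validate()
        )
    return reads
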