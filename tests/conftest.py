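import numpy as np
import pandas as pd
import pytest

from rtsig import AlignedRead, ReferenceSet, build_profile


@pytest.fixture
def ten_nt_refs():
    return ReferenceSet({"ref1": "ACGTAACGTA"})


@pytest.fixture
def rng():
    return np.random.default_rng(20151)


def make_reads(ref_id, specs):
    """Build AlignedReads from (start, bases) pairs."""
    return [AlignedRead(ref_id=ref_id, start=s, bases=b) for s, b in specs]


def random_instance(rng, max_refs=2, max_len=100, max_reads=50):
    """A random reference set plus reads with substitutions and deletions."""
    refs = {}
    for r in range(rng.integers(1, max_refs + 1)):
        L = int(rng.integers(10, max_len + 1))
        refs[f"r{r}"] = "".join(rng.choice(list("ACGT"), size=L))
    refset = ReferenceSet(refs)
    reads = []
    for _ in range(rng.integers(0, max_reads + 1)):
        rid = str(rng.choice(list(refs)))
        L = len(refs[rid])
        start = int(rng.integers(1, L + 1))
        span = int(rng.integers(1, L - start + 2))
        bases = list(refs[rid][start - 1:start - 1 + span])
        for i in range(span):  # sprinkle substitutions / deletions / Ns
            u = rng.random()
            if u < 0.05:
                bases[i] = "-"
            elif u < 0.15:
                bases[i] = str(rng.choice(list("ACGTN")))
        reads.append(AlignedRead(rid, start, "".join(bases)))
    return refset, reads


def brute_force_profile(refset, reads):
    """Independent per-read enumeration oracle for base/start counts."""
    counts = {rid: {p: {b: 0 for b in "ACGTN-"}
                    for p in range(1, len(seq) + 1)}
              for rid, seq in refset}
    starts = {rid: {p: 0 for p in range(1, len(seq) + 1)} for rid, seq in refset}
    for read in reads:
        starts[read.ref_id][read.start] += 1
        for offset, base in enumerate(read.bases):
            counts[read.ref_id][read.start + offset][base] += 1
    return counts, starts
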