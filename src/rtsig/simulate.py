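"""Synthetic template-sense read sets with configurable m1A sites.

The generative model follows the biochemistry of an RT-arrest/read-through
library: RNA is fragmented and size-selected (fragment 3' ends uniform over
the reference, lengths uniform in 50-150 nt, sub-minimum fragments at the 5'
boundary discarded); each molecule carries the modification at each covered
site independently with probability ``occupancy``; reverse transcription
walks the fragment from its 3' end (highest reference coordinate) toward 5';
at a modified site the enzyme terminates with probability ``p_arrest`` so
that the read's leftmost reference position is site+1, otherwise it reads
through and the emitted base at the site is drawn from the site's
misincorporation distribution; every other emitted base is the reference base
flipped uniformly to one of the other three with the background
``error_rate``.  Reads are emitted directly as forward-strand end-to-end
alignments, so no mapper is needed downstream.

Under this model the expected arrest rate at the site is ``f * p_arrest`` and
the expected mismatch rate among reads covering the site is
``f * (1 - p_arrest) * P(off-reference | misinc) / (1 - f * p_arrest)`` —
both affine in the occupancy ``f``, which is what occupancy-titration series
probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import yaml

from .profiles import AlignedRead, decode_bases, encode_bases
from .refs import ReferenceSet

#: Template-sense emission distributions (A, C, G, T order) at a read-through
#: m1A, keyed by the +1 reference base.  Chosen to reproduce the qualitative
#: clusters seen at natural sites: a 3'-U neighbor drives a T-dominated
#: mismatch signal; G and A neighbors give G/T mixes with low C; a C neighbor
#: gives a C-heavy, T-poor pattern.  The residual A share models occasional
#: correct dTTP incorporation.  All presets are configurable per site.
PLUS1_PRESETS: Dict[str, Dict[str, float]] = {
    "T": {"A": 0.10, "C": 0.04, "G": 0.10, "T": 0.76},
    "G": {"A": 0.10, "C": 0.05, "G": 0.42, "T": 0.43},
    "A": {"A": 0.10, "C": 0.06, "G": 0.54, "T": 0.30},
    "C": {"A": 0.10, "C": 0.52, "G": 0.26, "T": 0.12},
}

TRUTH_COLUMNS = ["ref_id", "pos", "occupancy", "p_arrest",
                 "misinc_A", "misinc_C", "misinc_G", "misinc_T"]


@dataclass
class SimSite:
    """Ground truth for one simulated m1A site."""

    reference_id: str
    position: int              # 1-based
    occupancy: float = 1.0     # fraction of molecules modified
    p_arrest: float = 0.8      # P(RT terminates | modified encounter)
    misinc: Optional[Dict[str, float]] = None  # emission over A,C,G,T on read-through

    def misinc_vector(self, refs: ReferenceSet) -> np.ndarray:
        if self.misinc is None:
            plus1 = refs.base(self.reference_id, self.position + 1)
            dist = PLUS1_PRESETS.get(plus1, PLUS1_PRESETS["T"])
        else:
            dist = self.misinc
        v = np.array([dist.get(b, 0.0) for b in "ACGT"], dtype=float)
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"misinc distribution for {self.reference_id}:{self.position} "
                             f"sums to {v.sum()}, not 1")
        if not 0.0 <= self.occupancy <= 1.0 or not 0.0 <= self.p_arrest <= 1.0:
            raise ValueError("occupancy and p_arrest must lie in [0,1]")
        return v


@dataclass
class SimConfig:
    """Configuration of one simulation run; ``seed`` is mandatory."""

    seed: int
    depth: int = 1000                 # accepted reads per reference
    frag_len_range: Tuple[int, int] = (50, 150)
    error_rate: float = 0.001         # background per-base substitution
    sites: List[SimSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        lo, hi = self.frag_len_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid fragment length range {self.frag_len_range}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        sites = [SimSite(reference_id=s["reference_id"], position=int(s["position"]),
                         occupancy=float(s.get("occupancy", 1.0)),
                         p_arrest=float(s.get("p_arrest", 0.8)),
                         misinc=s.get("misinc"))
                 for s in d.get("sites", [])]
        return cls(seed=int(d["seed"]), depth=int(d.get("depth", 1000)),
                   frag_len_range=tuple(d.get("frag_len_range", (50, 150))),
                   error_rate=float(d.get("error_rate", 0.001)), sites=sites)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class ReadSet:
    """Simulated reads stored as per-reference arrays.

    Iterating yields :class:`AlignedRead`; ``iter_arrays()`` exposes the raw
    (starts, lengths, flat base codes) batches that profile building consumes
    directly.
    """

    def __init__(self, refs: ReferenceSet):
        self.refs = refs
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add(self, ref_id: str, starts: np.ndarray, lengths: np.ndarray,
            flat_codes: np.ndarray) -> None:
        self._data[ref_id] = (starts, lengths, flat_codes)

    def iter_arrays(self) -> Iterator[Tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
        for rid, (starts, lengths, flat) in self._data.items():
            yield rid, starts, lengths, flat

    def __len__(self) -> int:
        return sum(len(starts) for starts, _, _ in self._data.values())

    def __iter__(self) -> Iterator[AlignedRead]:
        for rid, (starts, lengths, flat) in self._data.items():
            offsets = np.concatenate(([0], np.cumsum(lengths)))
            for i in range(len(starts)):
                bases = decode_bases(flat[offsets[i]:offsets[i + 1]])
                yield AlignedRead(ref_id=rid, start=int(starts[i]), bases=bases)

    def write_sam(self, path) -> None:
        header = pysam.AlignmentHeader.from_references(
            [rid for rid, _ in self.refs],
            [len(seq) for _, seq in self.refs])
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            i = 0
            for read in self:
                a = pysam.AlignedSegment(header)
                a.query_name = f"sim_{i}"
                a.query_sequence = read.bases
                a.flag = 0
                a.reference_id = header.get_tid(read.ref_id)
                a.reference_start = read.start - 1
                a.mapping_quality = 42
                a.cigartuples = [(0, len(read.bases))]
                out.write(a)
                i += 1


def _sample_fragments(rng: np.random.Generator, L: int, depth: int,
                      frag_range: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform 3' ends + uniform lengths, clipped at the 5' boundary; fragments
    falling below the minimum size after clipping are discarded (size
    selection), resampling until ``depth`` fragments are accepted."""
    lo, hi = frag_range
    min_len = min(lo, L)  # references shorter than the gel window are kept whole
    starts_acc: List[np.ndarray] = []
    ends_acc: List[np.ndarray] = []
    n = 0
    while n < depth:
        k = max(2 * (depth - n), 1000)
        end3 = rng.integers(1, L + 1, size=k)
        length = rng.integers(lo, hi + 1, size=k)
        start5 = np.maximum(1, end3 - length + 1)
        keep = (end3 - start5 + 1) >= min_len
        starts_acc.append(start5[keep])
        ends_acc.append(end3[keep])
        n += int(keep.sum())
    starts = np.concatenate(starts_acc)[:depth]
    ends = np.concatenate(ends_acc)[:depth]
    return starts, ends


def simulate(refs: ReferenceSet, config: SimConfig) -> Tuple[ReadSet, pd.DataFrame]:
    """Generate a read set and its ground-truth table; reproducible from seed."""
    for site in config.sites:
        if site.reference_id not in refs:
            raise ValueError(f"site references unknown sequence {site.reference_id!r}")
        if not 1 <= site.position <= refs.length(site.reference_id):
            raise ValueError(f"site {site.reference_id}:{site.position} outside reference")

    rng = np.random.default_rng(config.seed)
    reads = ReadSet(refs)
    truth_rows = []
    sites_by_ref: Dict[str, List[SimSite]] = {}
    for site in config.sites:
        sites_by_ref.setdefault(site.reference_id, []).append(site)
        v = site.misinc_vector(refs)
        truth_rows.append({"ref_id": site.reference_id, "pos": site.position,
                           "occupancy": site.occupancy, "p_arrest": site.p_arrest,
                           "misinc_A": v[0], "misinc_C": v[1],
                           "misinc_G": v[2], "misinc_T": v[3]})

    for rid, seq in refs:
        L = len(seq)
        starts, ends = _sample_fragments(rng, L, config.depth, config.frag_len_range)

        # RT walks 3'->5'; process sites from high to low coordinate so an
        # arrest at a downstream (higher) site shields lower sites.
        readthrough: List[Tuple[np.ndarray, int, np.ndarray]] = []
        for site in sorted(sites_by_ref.get(rid, []), key=lambda s: -s.position):
            p = site.position
            covered = (starts <= p) & (ends >= p)
            modified = covered & (rng.random(len(starts)) < site.occupancy)
            arrested = modified & (rng.random(len(starts)) < site.p_arrest)
            through = modified & ~arrested
            starts = np.where(arrested, p + 1, starts)
            if through.any():
                misinc = site.misinc_vector(refs)
                emit = rng.choice(4, size=int(through.sum()), p=misinc)
                readthrough.append((np.flatnonzero(through), p, emit))

        # arrest exactly at a fragment's 3' end leaves no cDNA
        keep = starts <= ends
        old_to_new = np.cumsum(keep) - 1
        starts, ends = starts[keep], ends[keep]
        lengths = ends - starts + 1
        offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        total = int(lengths.sum())

        ref_codes = encode_bases(seq)
        flat_pos = np.repeat(starts, lengths) + (np.arange(total) - np.repeat(offsets, lengths))
        flat = ref_codes[flat_pos - 1].copy()

        # background errors everywhere (N positions left untouched)
        err = (rng.random(total) < config.error_rate) & (flat < 4)
        n_err = int(err.sum())
        if n_err:
            flat[err] = (flat[err] + rng.integers(1, 4, size=n_err)) % 4

        # read-through emissions override the site base
        for idx, p, emit in readthrough:
            still = keep[idx]
            idx_new = old_to_new[idx[still]]
            emit = emit[still]
            sel = starts[idx_new] <= p  # arrest at a higher site may have passed it
            tgt = offsets[idx_new[sel]] + (p - starts[idx_new[sel]])
            flat[tgt] = emit[sel]

        reads.add(rid, starts.astype(np.int64), lengths.astype(np.int64), flat)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def titration_series(refs: ReferenceSet, base_config: SimConfig,
                     fractions: Sequence[float]
                     ) -> List[Tuple[float, ReadSet, pd.DataFrame]]:
    """One simulation per occupancy fraction (seed offset per level).

    Every site's occupancy is set to the series fraction, emulating mixes of
    modified and unmodified molecules at 0/25/50/75/100%-style levels.
    """
    out = []
    for i, f in enumerate(fractions):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0,1]")
        cfg = replace(
            base_config,
            seed=base_config.seed + i,
            sites=[replace(s, occupancy=f) for s in base_config.sites])
        reads, truth = simulate(refs, cfg)
        out.append((f, reads, truth))
    return out


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"ref_id": str})
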