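"""Per-position Profile tables from template-sense alignments.

A *Profile* is a per-reference-position summary of a mapped library: coverage,
read-start counts, base-call counts and the two statistics that carry the
RT signature of a blocking modification such as m1A:

* arrest rate  ``a(p) = e(p+1) / c(p+1)`` — the fraction of reads covering
  position p+1 whose leftmost mapped position is p+1, i.e. reads that end one
  position 3' of p and do not cover p.  Reads are template-sense and reverse
  transcription proceeds from high to low reference coordinates, so a read's
  leftmost coordinate is the RT stop.
* mismatch rate ``m(p)`` — the fraction of non-reference base calls among the
  A/C/G/T calls at p (N and deletions excluded from both numerator and
  denominator), together with the composition of the mismatched calls.

Coordinates are 1-based and closed throughout.  Zero-denominator ratios are
reported as 0 with an explicit flag token instead of NaN, so downstream
filters can exclude them deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .refs import ReferenceSet

logger = logging.getLogger(__name__)

# base encoding used throughout the package
BASES = ("A", "C", "G", "T", "N", "DEL")
A, C, G, T, N, DEL = range(6)
DEL_SYMBOL = "-"

_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN-"):
    _CODE_LUT[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

PROFILE_COLUMNS = [
    "ref_id", "pos", "ref_base", "coverage", "start_count",
    "A", "C", "G", "T", "N", "DEL",
    "arrest_rate", "mismatch_rate", "flags",
]

FLAG_ARREST_UNDEF = "arrest_undef"
FLAG_MISMATCH_UNDEF = "mismatch_undef"


def encode_bases(s: str) -> np.ndarray:
    """Encode a read-base string over {A,C,G,T,N,-} to integer codes."""
    codes = _CODE_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(s) - set("ACGTN-"))
        raise ValueError(f"invalid read base(s) {bad}")
    return codes.astype(np.int64)


def decode_bases(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


@dataclass
class AlignedRead:
    """End-to-end, forward-strand alignment of one read.

    ``bases`` holds the observed base per covered reference position, in
    reference order, '-' marking a deletion.  ``start`` is the 1-based
    leftmost reference position (the RT stop of the cDNA).
    """

    ref_id: str
    start: int
    bases: str

    @property
    def end(self) -> int:
        return self.start + len(self.bases) - 1


class _Accumulator:
    """Per-reference base-count and start-count accumulation."""

    def __init__(self, refs: ReferenceSet):
        self.refs = refs
        self.counts: Dict[str, np.ndarray] = {
            rid: np.zeros(len(seq) * 6, dtype=np.int64) for rid, seq in refs
        }
        self.starts: Dict[str, np.ndarray] = {
            rid: np.zeros(len(seq), dtype=np.int64) for rid, seq in refs
        }
        self.n_reads = 0
        self.n_skipped_reverse = 0
        self.n_skipped_unmapped = 0

    def add_batch(self, ref_id: str, starts: np.ndarray, lengths: np.ndarray,
                  flat_codes: np.ndarray) -> None:
        if ref_id not in self.refs:
            raise KeyError(f"alignment references unknown sequence {ref_id!r}")
        L = self.refs.length(ref_id)
        if len(starts) == 0:
            return
        if starts.min() < 1 or (starts + lengths - 1).max() > L:
            raise ValueError(f"alignment outside reference {ref_id!r} (length {L})")
        offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        total = int(lengths.sum())
        # flat 1-based reference position of every base call
        flat_pos = np.repeat(starts, lengths) + (np.arange(total) - np.repeat(offsets, lengths))
        lin = (flat_pos - 1) * 6 + flat_codes
        self.counts[ref_id] += np.bincount(lin, minlength=L * 6)
        self.starts[ref_id] += np.bincount(starts - 1, minlength=L)
        self.n_reads += len(starts)

    def add_read(self, read: AlignedRead) -> None:
        codes = encode_bases(read.bases)
        self.add_batch(read.ref_id,
                       np.array([read.start], dtype=np.int64),
                       np.array([len(codes)], dtype=np.int64),
                       codes)


def _iter_sam(path, accumulator: _Accumulator) -> None:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        pending: Dict[str, Tuple[List[int], List[np.ndarray]]] = {}

        def flush(rid: str) -> None:
            st, seqs = pending.pop(rid)
            starts = np.array(st, dtype=np.int64)
            lengths = np.array([len(s) for s in seqs], dtype=np.int64)
            accumulator.add_batch(rid, starts, lengths, np.concatenate(seqs))

        for aln in sam:
            if aln.is_unmapped:
                accumulator.n_skipped_unmapped += 1
                continue
            if aln.is_reverse:
                accumulator.n_skipped_reverse += 1
                continue
            rid = aln.reference_name
            if rid not in accumulator.refs:
                raise KeyError(f"alignment references unknown sequence {rid!r}")
            cig = aln.cigartuples or []
            if any(op in (4, 5) for op, _ in cig):
                raise ValueError(
                    f"soft/hard-clipped alignment for read {aln.query_name!r}: "
                    "only end-to-end alignments are admitted")
            qseq = aln.query_sequence or ""
            if len(cig) == 1 and cig[0][0] == 0:  # pure match/mismatch
                codes = encode_bases(qseq)
            else:
                parts: List[np.ndarray] = []
                qpos = 0
                for op, n in cig:
                    if op in (0, 7, 8):       # M/=/X: consumes both
                        parts.append(encode_bases(qseq[qpos:qpos + n]))
                        qpos += n
                    elif op == 2:             # D: deletion w.r.t. reference
                        parts.append(np.full(n, DEL, dtype=np.int64))
                    elif op == 1:             # I: no reference position
                        qpos += n
                    else:
                        raise ValueError(f"unsupported CIGAR op {op} in read {aln.query_name!r}")
                codes = np.concatenate(parts)
            pending.setdefault(rid, ([], []))
            pending[rid][0].append(aln.reference_start + 1)
            pending[rid][1].append(codes)
            if len(pending[rid][0]) >= 20000:
                flush(rid)
        for rid in list(pending):
            flush(rid)


def build_profile(refs: ReferenceSet,
                  alignments: Union[str, Path, Iterable[AlignedRead], "object"],
                  ) -> pd.DataFrame:
    """Build a Profile table from alignments over ``refs``.

    ``alignments`` may be a SAM path, an iterable of :class:`AlignedRead`, or
    any object with an ``iter_arrays()`` method yielding
    ``(ref_id, starts, lengths, flat_codes)`` batches (the simulator's read
    sets use this fast path).  Reverse-strand and unmapped records are skipped
    with a logged count; an unknown reference id is a hard error.
    """
    acc = _Accumulator(refs)
    if isinstance(alignments, (str, Path)):
        _iter_sam(alignments, acc)
    elif hasattr(alignments, "iter_arrays"):
        for ref_id, starts, lengths, flat in alignments.iter_arrays():
            acc.add_batch(ref_id, starts, lengths, flat)
    else:
        for read in alignments:
            acc.add_read(read)
    if acc.n_skipped_reverse or acc.n_skipped_unmapped:
        logger.warning("skipped %d reverse-strand and %d unmapped records",
                       acc.n_skipped_reverse, acc.n_skipped_unmapped)

    frames = []
    for rid, seq in refs:
        L = len(seq)
        counts = acc.counts[rid].reshape(L, 6)
        starts = acc.starts[rid]
        coverage = counts.sum(axis=1)
        ref_codes = encode_bases(seq)

        # arrest rate at p uses starts/coverage at p+1
        a = np.zeros(L, dtype=float)
        arrest_undef = np.zeros(L, dtype=bool)
        cov_next = np.concatenate((coverage[1:], [0]))
        start_next = np.concatenate((starts[1:], [0]))
        ok = cov_next > 0
        a[ok] = start_next[ok] / cov_next[ok]
        arrest_undef[~ok] = True
        arrest_undef[L - 1] = True  # no p+1 inside the reference

        acgt = counts[:, :4]
        acgt_total = acgt.sum(axis=1)
        ref_calls = np.zeros(L, dtype=np.int64)
        valid_ref = ref_codes < 4
        ref_calls[valid_ref] = acgt[np.arange(L)[valid_ref], ref_codes[valid_ref]]
        m = np.zeros(L, dtype=float)
        m_ok = (acgt_total > 0) & valid_ref
        m[m_ok] = (acgt_total[m_ok] - ref_calls[m_ok]) / acgt_total[m_ok]
        mism_undef = ~m_ok

        flags = [
            ",".join(
                tok for tok, on in ((FLAG_ARREST_UNDEF, arrest_undef[i]),
                                    (FLAG_MISMATCH_UNDEF, mism_undef[i])) if on)
            for i in range(L)
        ]
        frames.append(pd.DataFrame({
            "ref_id": rid,
            "pos": np.arange(1, L + 1),
            "ref_base": list(seq),
            "coverage": coverage,
            "start_count": starts,
            "A": counts[:, A], "C": counts[:, C], "G": counts[:, G],
            "T": counts[:, T], "N": counts[:, N], "DEL": counts[:, DEL],
            "arrest_rate": a,
            "mismatch_rate": m,
            "flags": flags,
        }))
    profile = pd.concat(frames, ignore_index=True)
    profile.attrs["n_reads"] = acc.n_reads
    profile.attrs["n_skipped_reverse"] = acc.n_skipped_reverse
    return profile


def _row(profile: pd.DataFrame, ref_id: str, p: int) -> pd.Series:
    sel = profile[(profile["ref_id"] == ref_id) & (profile["pos"] == p)]
    if sel.empty:
        raise KeyError(f"no profile row for {ref_id!r} position {p}")
    return sel.iloc[0]


def arrest_rate(profile: pd.DataFrame, ref_id: str, p: int) -> float:
    """Arrest rate a(p) = e(p+1)/c(p+1); 0 (flagged in the table) when c(p+1)=0."""
    return float(_row(profile, ref_id, p)["arrest_rate"])


def mismatch_stats(profile: pd.DataFrame, ref_id: str, p: int
                   ) -> Tuple[float, Dict[str, float]]:
    """Mismatch rate and composition at p.

    Returns ``(m, composition)`` where composition maps each of the three
    non-reference bases to its share of the mismatched A/C/G/T calls (sums to
    1 when mismatches exist, all zeros otherwise).
    """
    row = _row(profile, ref_id, p)
    ref_base = row["ref_base"]
    if ref_base not in "ACGT":
        raise ValueError(f"mismatch statistics need an A/C/G/T reference base, got {ref_base!r}")
    others = [b for b in "ACGT" if b != ref_base]
    mism = {b: int(row[b]) for b in others}
    total_mism = sum(mism.values())
    m = float(row["mismatch_rate"])
    if total_mism == 0:
        return m, {b: 0.0 for b in others}
    return m, {b: cnt / total_mism for b, cnt in mism.items()}


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write a Profile table as TSV (documented header, no '.' placeholders)."""
    out = profile[PROFILE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_profile(path) -> pd.DataFrame:
    """Read and validate a Profile TSV; malformed rows error with line number."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"ref_id": str, "ref_base": str, "flags": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile file {path} lacks columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header line
        counts = [row[b] for b in BASES]
        if any(c < 0 for c in counts) or row["coverage"] < 0 or row["start_count"] < 0:
            raise ValueError(f"{path}:{line}: negative count")
        if sum(counts) != row["coverage"]:
            raise ValueError(f"{path}:{line}: base counts do not sum to coverage")
        for col in ("arrest_rate", "mismatch_rate"):
            if not 0.0 <= row[col] <= 1.0:
                raise ValueError(f"{path}:{line}: {col} outside [0,1]")
    return df
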