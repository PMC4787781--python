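"""Per-adenosine RT-signature records.

A signature summarizes, for one reference adenosine, the features that an
m1A residue imprints on a sequencing profile: the arrest rate ``a`` one
position 3' of the site, the read-through mismatch rate ``m`` with its
composition over the three non-A bases, the ``m/a`` ratio, and the
context-sensitive arrest rate (CSA) — the fold change of ``a`` over the mean
arrest rate in the site's +/-5 nt neighborhood.  The -1/+1/+2 context bases
are carried along for sequence-context analyses but are deliberately not part
of the classifier feature set.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .profiles import FLAG_ARREST_UNDEF
from .refs import ReferenceSet

logger = logging.getLogger(__name__)

#: numeric classifier features, in canonical order
FEATURE_COLUMNS = ["a", "m", "m_over_a", "comp_G", "comp_T", "comp_C", "csa"]

SIGNATURE_COLUMNS = [
    "ref_id", "pos", "a", "m", "comp_G", "comp_T", "comp_C", "m_over_a", "csa",
    "minus1", "plus1", "plus2", "coverage", "coverage_3p", "label", "flags",
]

EPS_RATIO = 1e-3  # guard for zero denominators in m/a and CSA

FLAG_CSA_EPS = "csa_eps"
FLAG_CSA_UNDEF = "csa_undef"
FLAG_MA_EPS = "m_over_a_eps"


def csa(profile: pd.DataFrame, ref_id: str, p: int, window: int = 5,
        exclude_center: bool = True, eps: float = EPS_RATIO) -> float:
    """Context-sensitive arrest rate: a(p) over the mean a in [p-w, p+w].

    The window is truncated at reference boundaries; positions whose arrest
    rate is undefined (flagged) are excluded from the mean.  A zero
    neighborhood mean falls back to ``a(p)/eps``; an entirely undefined
    neighborhood yields 0.
    """
    value, _ = _csa_with_flag(profile, ref_id, p, window, exclude_center, eps)
    return value


def _csa_with_flag(profile: pd.DataFrame, ref_id: str, p: int, window: int,
                   exclude_center: bool, eps: float) -> Tuple[float, str]:
    sub = profile[profile["ref_id"] == ref_id]
    return _csa_from_arrays(
        sub["arrest_rate"].to_numpy(),
        sub["flags"].str.contains(FLAG_ARREST_UNDEF, regex=False).to_numpy(),
        p, window, exclude_center, eps)


def _csa_from_arrays(a: np.ndarray, undef: np.ndarray, p: int, window: int,
                     exclude_center: bool, eps: float) -> Tuple[float, str]:
    L = len(a)
    if not 1 <= p <= L:
        raise IndexError(f"position {p} outside reference of length {L}")
    lo, hi = max(1, p - window), min(L, p + window)
    idx = [q - 1 for q in range(lo, hi + 1)
           if not (exclude_center and q == p) and not undef[q - 1]]
    a_p = float(a[p - 1])
    if not idx:
        return 0.0, FLAG_CSA_UNDEF
    mean = float(np.mean(a[idx]))
    if mean == 0.0:
        return a_p / eps, FLAG_CSA_EPS
    return a_p / mean, ""


def extract_signatures(profile: pd.DataFrame, refs: ReferenceSet,
                       min_cov: int = 10, min_cov_3prime: int = 15,
                       annotations: Optional[pd.DataFrame] = None,
                       window: int = 5) -> pd.DataFrame:
    """One SignatureRecord per reference adenosine passing the coverage filters.

    Filters follow the site-candidate rule: coverage at the site >= ``min_cov``
    and coverage one position 3' (where the arrest signal lives) >=
    ``min_cov_3prime``.  ``annotations`` may carry per-site metadata
    (``label`` in {m1A, non_m1A}, and optional grouping keys such as
    ``replicate``, ``isotype``, ``rna_class``) joined on (ref_id, pos);
    unannotated sites are labeled "unknown".
    """
    records: List[dict] = []
    for rid, seq in refs:
        sub = profile[profile["ref_id"] == rid].sort_values("pos")
        if sub.empty:
            continue
        cov = sub["coverage"].to_numpy()
        a_arr = sub["arrest_rate"].to_numpy()
        undef = sub["flags"].str.contains(FLAG_ARREST_UNDEF, regex=False).to_numpy()
        counts = sub[["A", "C", "G", "T"]].to_numpy()
        m_arr = sub["mismatch_rate"].to_numpy()
        L = len(seq)
        for p in range(1, L + 1):
            if seq[p - 1] != "A":
                continue
            c_p = int(cov[p - 1])
            c_3p = int(cov[p]) if p < L else 0
            if c_p < min_cov or c_3p < min_cov_3prime:
                continue
            flags: List[str] = []
            a = float(a_arr[p - 1])
            m = float(m_arr[p - 1])
            row_counts = counts[p - 1]
            n_mism = int(row_counts[[1, 2, 3]].sum())  # C, G, T calls at a ref-A
            if n_mism > 0:
                comp_G = row_counts[2] / n_mism
                comp_T = row_counts[3] / n_mism
                comp_C = row_counts[1] / n_mism
            else:
                comp_G = comp_T = comp_C = 0.0
            if a > 0:
                m_over_a = m / a
            else:
                m_over_a = m / EPS_RATIO
                flags.append(FLAG_MA_EPS)
            csa_val, csa_flag = _csa_from_arrays(a_arr, undef, p, window, True, EPS_RATIO)
            if csa_flag:
                flags.append(csa_flag)
            records.append({
                "ref_id": rid, "pos": p, "a": a, "m": m,
                "comp_G": float(comp_G), "comp_T": float(comp_T), "comp_C": float(comp_C),
                "m_over_a": float(m_over_a), "csa": float(csa_val),
                "minus1": refs.base(rid, p - 1), "plus1": refs.base(rid, p + 1),
                "plus2": refs.base(rid, p + 2),
                "coverage": c_p, "coverage_3p": c_3p,
                "label": "unknown", "flags": ",".join(flags),
            })
    sig = pd.DataFrame(records, columns=SIGNATURE_COLUMNS)
    if annotations is not None and not sig.empty:
        ann = annotations.copy()
        ann["pos"] = ann["pos"].astype(int)
        sig = sig.drop(columns=["label"]).merge(ann, on=["ref_id", "pos"], how="left")
        sig["label"] = sig["label"].fillna("unknown")
        sig = sig[[c for c in SIGNATURE_COLUMNS if c in sig.columns]
                  + [c for c in sig.columns if c not in SIGNATURE_COLUMNS]]
    return sig


def is_confusable_negative(rec: Union[Mapping, pd.Series],
                           a_min: float = 0.2, m_min: float = 0.2,
                           m_weak: float = 0.1, share_min: float = 0.1,
                           n_types: int = 2) -> bool:
    """Minimum m1A-signature resemblance rule for stringent negatives.

    True iff a >= 0.2, or m >= 0.2, or (m >= 0.1 and at least two of the
    three mismatch-composition shares are >= 0.1).  Thresholds configurable.
    """
    if rec["a"] >= a_min or rec["m"] >= m_min:
        return True
    shares = [rec["comp_G"], rec["comp_T"], rec["comp_C"]]
    return rec["m"] >= m_weak and sum(s >= share_min for s in shares) >= n_types


def average_signatures(records: pd.DataFrame,
                       by: Optional[Union[str, Sequence[str]]] = None,
                       features: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Arithmetic mean of signature features within groups.

    ``by`` is a grouping column (or list; None averages all rows into one).
    Returns one row per group with mean features, per-feature SDs
    (``<f>_sd``, ddof=0) and the group size ``n``.  Hierarchical averaging
    (replicates, then isotypes, then the final mean) is obtained by chaining
    calls — see :func:`hierarchical_average`.
    """
    if features is None:
        candidates = FEATURE_COLUMNS + ["coverage", "coverage_3p"]
        features = [f for f in candidates if f in records.columns]
    if records.empty:
        logger.warning("average_signatures: empty input, nothing to average")
        return pd.DataFrame(columns=list(features))
    if by is None:
        grouped = [((), records)]
        keys: List[str] = []
    else:
        keys = [by] if isinstance(by, str) else list(by)
        dropped = records[records[keys].isna().any(axis=1)]
        if len(dropped):
            logger.warning("average_signatures: %d records lack %s keys, skipped",
                           len(dropped), keys)
        grouped = list(records.dropna(subset=keys).groupby(keys, sort=True))
    rows = []
    for key, grp in grouped:
        if isinstance(key, tuple) and len(keys) == 1:
            key = key[0] if key else key
        row = {} if not keys else dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(grp)
        for f in features:
            row[f] = float(grp[f].mean())
            row[f + "_sd"] = float(grp[f].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def hierarchical_average(records: pd.DataFrame, levels: Sequence[Sequence[str]],
                         features: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Successive group means, e.g. replicates -> isotypes -> final mean.

    ``levels`` lists the grouping keys of each stage, outermost first; after
    the last stage a grand mean over the remaining rows is taken, so the final
    value is a mean of group means, not a pooled mean.
    """
    if features is None:
        features = [f for f in FEATURE_COLUMNS if f in records.columns]
    out = records
    for keys in levels:
        out = average_signatures(out, by=list(keys), features=features)
    return average_signatures(out, by=None, features=features)


def write_signatures(sig: pd.DataFrame, path) -> None:
    sig.to_csv(path, sep="\t", index=False)


def read_signatures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"ref_id": str, "flags": str, "label": str,
                            "minus1": str, "plus1": str, "plus2": str})
    missing = [c for c in ("ref_id", "pos", "a", "m") if c not in df.columns]
    if missing:
        raise ValueError(f"signature file {path} lacks columns {missing}")
    return df
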