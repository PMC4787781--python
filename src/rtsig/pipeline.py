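"""End-to-end helpers: synthetic benchmarks and site-level measurements.

These functions chain the simulator, profile builder and signature extractor
into labeled datasets — the self-contained test bed that stands in for the
curated natural m1A collections (which depend on unreleased sequencing data).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiles import build_profile
from .refs import ReferenceSet
from .signatures import extract_signatures
from .simulate import PLUS1_PRESETS, ReadSet, SimConfig, SimSite, simulate

_PLUS1_CYCLE = "TGAC"


def random_references(n: int, length: int = 120, site_pos: int = 60,
                      seed: int = 0, prefix: str = "ref") -> Tuple[ReferenceSet, pd.DataFrame]:
    """Random reference set with one designated adenosine site per sequence.

    The site base is fixed to A and the +1 base cycles through T/G/A/C so all
    four misincorporation presets are represented.  Returns the references and
    a table (ref_id, pos, plus1).
    """
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    rows = []
    for i in range(n):
        arr = rng.choice(list("ACGT"), size=length)
        plus1 = _PLUS1_CYCLE[i % 4]
        arr[site_pos - 1] = "A"
        arr[site_pos] = plus1
        rid = f"{prefix}{i:03d}"
        seqs[rid] = "".join(arr)
        rows.append({"ref_id": rid, "pos": site_pos, "plus1": plus1})
    return ReferenceSet(seqs), pd.DataFrame(rows)


def benchmark_signatures(n_sites: int = 45, depth: int = 5000,
                         p_arrest_range: Tuple[float, float] = (0.7, 0.9),
                         occupancy: float = 1.0, error_rate: float = 0.001,
                         seed: int = 0, ref_length: int = 120, site_pos: int = 60,
                         misinc_override: Optional[Sequence[Optional[dict]]] = None,
                         rna_class_split: Optional[float] = None,
                         min_cov: int = 10, min_cov_3prime: int = 15,
                         ) -> pd.DataFrame:
    """Simulate ``n_sites`` modified references and return labeled signatures.

    Each reference carries one m1A site (occupancy and +1-preset
    misincorporation as configured, arrest probability drawn uniformly from
    ``p_arrest_range``); every other adenosine passing the coverage filters
    becomes a non_m1A instance.  ``rna_class_split`` optionally tags the first
    fraction of references as tRNA and the rest as rRNA.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    refs, site_table = random_references(n_sites, ref_length, site_pos,
                                         seed=int(rng.integers(2**31)))
    sites = []
    for i, row in site_table.iterrows():
        mis = misinc_override[i] if misinc_override is not None else None
        sites.append(SimSite(reference_id=row["ref_id"], position=int(row["pos"]),
                             occupancy=occupancy,
                             p_arrest=float(rng.uniform(*p_arrest_range)),
                             misinc=mis))
    config = SimConfig(seed=int(rng.integers(2**31)), depth=depth,
                       error_rate=error_rate, sites=sites)
    reads, truth = simulate(refs, config)
    profile = build_profile(refs, reads)
    sig = extract_signatures(profile, refs, min_cov=min_cov,
                             min_cov_3prime=min_cov_3prime)
    return label_from_truth(sig, truth, rna_class_split=rna_class_split)


def label_from_truth(signatures: pd.DataFrame, truth: pd.DataFrame,
                     rna_class_split: Optional[float] = None) -> pd.DataFrame:
    """Label signature rows from a simulation truth table.

    Sites present in the truth table become m1A; every other simulated
    adenosine is genuinely unmodified, hence non_m1A.
    """
    sig = signatures.copy()
    truth_keys = set(zip(truth["ref_id"], truth["pos"].astype(int)))
    is_site = [
        (r, int(p)) in truth_keys for r, p in zip(sig["ref_id"], sig["pos"])
    ]
    sig["label"] = np.where(is_site, "m1A", "non_m1A")
    if rna_class_split is not None:
        ref_ids = sorted(sig["ref_id"].unique())
        n_trna = int(round(rna_class_split * len(ref_ids)))
        trna = set(ref_ids[:n_trna])
        sig["rna_class"] = [
            "tRNA" if r in trna else "rRNA" for r in sig["ref_id"]
        ]
    return sig


def mixed_difficulty_signatures(n_sites: int = 40, depth: int = 400,
                                occupancy: float = 0.35, error_rate: float = 0.002,
                                seed: int = 0) -> pd.DataFrame:
    """A harder benchmark where neither RT channel suffices alone.

    Half the sites are arrest-dominant (high arrest probability, read-through
    emitting mostly the correct base, so the mismatch channel is nearly
    silent); the other half are mismatch-dominant (rare arrest, strongly
    off-reference read-through).  Combined with partial occupancy and modest
    depth this separates the full feature set from arrest-only and
    mismatch-only subsets.
    """
    rng = np.random.default_rng(seed)
    refs, site_table = random_references(n_sites, seed=int(rng.integers(2**31)))
    arrest_like = {"A": 0.85, "C": 0.02, "G": 0.05, "T": 0.08}
    sites = []
    for i, row in site_table.iterrows():
        if i % 2 == 0:
            sites.append(SimSite(row["ref_id"], int(row["pos"]), occupancy=occupancy,
                                 p_arrest=float(rng.uniform(0.75, 0.95)),
                                 misinc=arrest_like))
        else:
            sites.append(SimSite(row["ref_id"], int(row["pos"]), occupancy=occupancy,
                                 p_arrest=float(rng.uniform(0.0, 0.08)),
                                 misinc=None))  # +1-preset, strongly off-reference
    config = SimConfig(seed=int(rng.integers(2**31)), depth=depth,
                       error_rate=error_rate, sites=sites)
    reads, truth = simulate(refs, config)
    profile = build_profile(refs, reads)
    sig = extract_signatures(profile, refs)
    return label_from_truth(sig, truth)


def site_measurements(profile: pd.DataFrame, truth: pd.DataFrame,
                      error_rate: float = 0.0) -> pd.DataFrame:
    """Measured vs expected arrest and mismatch statistics per true site.

    Expected values under the generative model: a = f * p_arrest and
    m = [f (1-p_arrest) (1-misinc_A) + (1-f) e] / (1 - f p_arrest), with
    binomial standard errors from the local coverages.

    Because arrested molecules drop out of the site's coverage, the
    read-conditional mismatch rate m(p) is *not* affine in the occupancy f
    when arrest is strong.  The affine misincorporation measure — what an
    occupancy titration probes — is the per-molecule rate
    ``m_molecule = mismatched calls at p / coverage at p+1`` (pre-arrest
    molecule count), with expectation ~ f (1-p_arrest) (1-misinc_A).
    """
    rows = []
    for _, site in truth.iterrows():
        rid, p = site["ref_id"], int(site["pos"])
        prow = profile[(profile["ref_id"] == rid) & (profile["pos"] == p)].iloc[0]
        nrow = profile[(profile["ref_id"] == rid) & (profile["pos"] == p + 1)]
        c_next = int(nrow.iloc[0]["coverage"]) if len(nrow) else 0
        acgt = int(prow[["A", "C", "G", "T"]].sum())
        mism_calls = acgt - int(prow[prow["ref_base"]]) if prow["ref_base"] in "ACGT" else 0
        f, pa = site["occupancy"], site["p_arrest"]
        a_exp = f * pa
        denom = 1.0 - f * pa
        m_exp = ((f * (1 - pa) * (1 - site["misinc_A"]) + (1 - f) * error_rate) / denom
                 if denom > 0 else np.nan)
        mm_exp = f * (1 - pa) * (1 - site["misinc_A"]) + (1 - f) * error_rate
        rows.append({
            "ref_id": rid, "pos": p,
            "a_measured": float(prow["arrest_rate"]), "a_expected": a_exp,
            "a_se": np.sqrt(a_exp * (1 - a_exp) / c_next) if c_next else np.nan,
            "m_measured": float(prow["mismatch_rate"]), "m_expected": m_exp,
            "m_se": (np.sqrt(m_exp * (1 - m_exp) / acgt)
                     if acgt and np.isfinite(m_exp) else np.nan),
            "m_molecule": mism_calls / c_next if c_next else np.nan,
            "m_molecule_expected": mm_exp,
            "coverage_site": acgt, "coverage_3p": c_next,
        })
    return pd.DataFrame(rows)
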