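"""Sequence-context analysis of m1A misincorporation patterns.

The read-through mismatch composition (shares of G, T and C among mismatched
calls at a template adenosine) is treated as a point on the 2-simplex and
mapped to ternary plot coordinates.  Redundant measurements are reduced in
three stages (replicates, >95%-identity reference groups, identical
-1/+1/+2 context triples), the reduced instances are hierarchically
clustered, the apparent grouping by the +1 base is tested with a label
permutation test, and a Levenshtein distance matrix quantifies mismapping
risk between similar references (isoacceptor-style confusability).
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .refs import ReferenceSet
from .signatures import average_signatures

logger = logging.getLogger(__name__)

SQRT3_2 = np.sqrt(3.0) / 2.0

COMP_COLUMNS = ["comp_G", "comp_T", "comp_C"]


def ternary_coords(composition: Sequence[float]) -> Tuple[float, float]:
    """Map a (G, T, C) composition to ternary plot coordinates.

    Corners: G = (0, 0), T = (1, 0), C = (0.5, sqrt(3)/2); the mapping is the
    affine barycentric embedding x = T + C/2, y = C * sqrt(3)/2.
    """
    g, t, c = composition
    if not np.isclose(g + t + c, 1.0, atol=1e-9):
        raise ValueError(f"composition sums to {g + t + c}, not 1")
    if min(g, t, c) < -1e-12:
        raise ValueError("negative composition share")
    return float(t + c / 2.0), float(c * SQRT3_2)


def ternary_inverse(x: float, y: float) -> Tuple[float, float, float]:
    """Recover the (G, T, C) composition from ternary coordinates."""
    c = y / SQRT3_2
    t = x - c / 2.0
    return float(1.0 - t - c), float(t), float(c)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identities / alignment columns.

    End gaps are penalized (plain global mode), so diverging ends count
    against identity — a conservative choice for the >95% merge rule.
    """
    aligner = Align.PairwiseAligner(mode="global", match_score=2,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    counts = aligner.align(seq_a, seq_b)[0].counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns if columns else 1.0


def _identity_groups(seqs: Dict[str, str], threshold: float) -> Dict[str, int]:
    """Single-linkage components of the >threshold identity graph."""
    ids = list(seqs)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(ids, 2):
        if pairwise_identity(seqs[a], seqs[b]) > threshold:
            parent[find(a)] = find(b)
    roots = {i: find(i) for i in ids}
    index = {r: k for k, r in enumerate(dict.fromkeys(roots.values()))}
    return {i: index[r] for i, r in roots.items()}


def reduce_instances(records: pd.DataFrame,
                     refs: Optional[ReferenceSet] = None,
                     identity_threshold: float = 0.95) -> pd.DataFrame:
    """Collapse redundant signature records into context instances.

    Three sequential reductions: (1) mean over experimental replicates of the
    same site; (2) mean over sites shared by references of more than
    ``identity_threshold`` global-alignment identity (single-linkage groups —
    e.g. tRNA sequence variants differing by a SNP); (3) mean over identical
    (-1, +1, +2) context triples.  Provenance (merged source records) is
    retained; records whose reference sequence is unavailable pass through
    stage 2 unmerged with a warning.
    """
    needed = ["ref_id", "pos"] + COMP_COLUMNS + ["minus1", "plus1", "plus2"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"records lack columns {missing}")
    df = records.copy()
    features = [c for c in COMP_COLUMNS + ["a", "m"] if c in df.columns]

    # (1) replicate averaging per site
    stage1 = average_signatures(df, by=["ref_id", "pos"], features=features)
    ctx = df.groupby(["ref_id", "pos"], sort=True)[["minus1", "plus1", "plus2"]].first()
    stage1 = stage1.merge(ctx.reset_index(), on=["ref_id", "pos"])
    stage1["sources"] = stage1["ref_id"] + ":" + stage1["pos"].astype(str)

    # (2) >95% identity grouping of references
    if refs is not None:
        known = {rid: refs[rid] for rid in stage1["ref_id"].unique() if rid in refs}
        unknown = sorted(set(stage1["ref_id"].unique()) - set(known))
        if unknown:
            logger.warning("no reference sequence for %s; passed through unmerged", unknown)
        groups = _identity_groups(known, identity_threshold) if known else {}
        next_id = max(groups.values(), default=-1) + 1
        for rid in unknown:
            groups[rid] = next_id
            next_id += 1
    else:
        groups = {rid: i for i, rid in enumerate(stage1["ref_id"].unique())}
    stage1["ref_group"] = stage1["ref_id"].map(groups)
    agg = {f: "mean" for f in features}
    agg.update({"minus1": "first", "plus1": "first", "plus2": "first",
                "sources": lambda s: ";".join(s), "n": "sum"})
    stage2 = stage1.groupby(["ref_group", "pos"], sort=True, as_index=False).agg(agg)

    # (3) identical context triples
    stage3 = stage2.groupby(["minus1", "plus1", "plus2"], sort=True, as_index=False).agg(
        {**{f: "mean" for f in features}, "sources": lambda s: ";".join(s), "n": "sum"})
    stage3["ref_id"] = ("ctx:" + stage3["minus1"] + stage3["plus1"] + stage3["plus2"])
    stage3["pos"] = 0
    xy = stage3.apply(
        lambda r: ternary_coords((r["comp_G"], r["comp_T"], r["comp_C"]))
        if r["comp_G"] + r["comp_T"] + r["comp_C"] > 0 else (np.nan, np.nan),
        axis=1, result_type="expand")
    stage3["ternary_x"], stage3["ternary_y"] = xy[0], xy[1]
    cols = (["ref_id", "pos", "minus1", "plus1", "plus2"] + features
            + ["ternary_x", "ternary_y", "n", "sources"])
    return stage3[cols]


def cluster_by_context(instances: pd.DataFrame, method: str = "average",
                       n_clusters: int = 4) -> Tuple[np.ndarray, pd.DataFrame]:
    """Agglomerative clustering of mismatch compositions.

    Returns the scipy linkage matrix and the instances annotated with flat
    cluster labels (``maxclust`` cut at ``n_clusters``).
    """
    if len(instances) < 2:
        raise ValueError("need at least two instances to cluster")
    X = instances[COMP_COLUMNS].to_numpy(dtype=float)
    Z = linkage(X, method=method, metric="euclidean")
    out = instances.copy()
    out["cluster"] = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, out


def separation_test(instances: pd.DataFrame, grouping: str = "plus1",
                    n_perm: int = 999, seed: int = 0) -> Dict[str, float]:
    """Permutation test for grouping structure in composition space.

    Statistic S = (mean between-group pairwise Euclidean distance) - (mean
    within-group pairwise distance) over the composition vectors; the p-value
    is the add-one-smoothed fraction of label permutations with
    S_perm >= S_obs.  Groups with fewer than two members contribute no
    within-group pairs and are noted.  This test is this package's own
    verification procedure for the visually apparent +1-base clustering.
    """
    labels = instances[grouping].to_numpy()
    X = instances[COMP_COLUMNS].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need at least three instances")
    D = squareform(pdist(X, metric="euclidean"))
    sizes = pd.Series(labels).value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        logger.info("groups with <2 members excluded from the within term: %s",
                    list(singletons.index))

    ii, jj = np.triu_indices(len(labels), k=1)
    dvec = D[ii, jj]

    def stat(lab: np.ndarray) -> float:
        same = lab[ii] == lab[jj]
        n_within = int(same.sum())
        if n_within == 0 or n_within == len(same):
            return np.nan
        return float(dvec[~same].mean() - dvec[same].mean())

    s_obs = stat(labels)
    if np.isnan(s_obs):
        raise ValueError("statistic undefined: need both within- and between-group pairs")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        s_p = stat(rng.permutation(labels))
        if s_p >= s_obs:
            exceed += 1
    return {"statistic": s_obs, "p_value": (exceed + 1) / (n_perm + 1),
            "n_perm": n_perm}


def levenshtein(seq_a: str, seq_b: str) -> int:
    """Unit-cost edit distance between two sequences (empty strings allowed)."""
    if not seq_a or not seq_b:
        return max(len(seq_a), len(seq_b))
    return int(edlib.align(seq_a, seq_b, task="distance", mode="NW")["editDistance"])


def levenshtein_matrix(refs: ReferenceSet) -> pd.DataFrame:
    """Pairwise unit-cost edit distances between all references.

    The Levenshtein distance (minimum number of substitutions, insertions and
    deletions interconverting two sequences) inversely tracks mismapping risk:
    near-identical species — typically isoacceptors — are the ones reads
    cross-map between.
    """
    ids = [rid for rid, _ in refs]
    if len(ids) < 2:
        raise ValueError("need at least two references")
    n = len(ids)
    M = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        M[i, j] = M[j, i] = levenshtein(refs[ids[i]], refs[ids[j]])
    return pd.DataFrame(M, index=ids, columns=ids)


def plot_ternary(instances: pd.DataFrame, path, color_by: str = "plus1") -> None:
    """Scatter the instances in the ternary triangle (G left, T right, C top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    tri_x = [0, 1, 0.5, 0]
    tri_y = [0, 0, SQRT3_2, 0]
    ax.plot(tri_x, tri_y, color="black", lw=1)
    palette = {"A": "tab:green", "C": "tab:blue", "G": "tab:olive", "T": "tab:red"}
    for key, grp in instances.groupby(color_by):
        ax.scatter(grp["ternary_x"], grp["ternary_y"], s=25,
                   color=palette.get(key, "gray"), label=f"{color_by}={key}")
    for label, (x, y) in (("G", (-0.03, -0.04)), ("T", (1.01, -0.04)),
                          ("C", (0.5, SQRT3_2 + 0.02))):
        ax.text(x, y, label)
    ax.legend(fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
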