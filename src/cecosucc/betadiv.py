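"""Beta diversity: dissimilarities, ordination, permutation tests, maturity.

Distances are Bray-Curtis on counts and unweighted UniFrac on
presence/absence over a rooted tree. Group structure is tested with
PERMANOVA (pseudo-F on the distance matrix, free label permutation) and
PERMDISP (homogeneity of dispersion around group spatial medians in
principal-coordinate space). Community maturity is the mean dissimilarity
of a sample to the reference-age (default 49 d) samples of its own diet
group; higher values mean further from the mature community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.distance import permdisp as _skbio_permdisp
from skbio.stats.ordination import pcoa
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

from .tableio import CountTable


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame   # samples x k
    stress: float               # Kruskal stress-1
    n_restarts: int


@dataclass(frozen=True)
class PermutationTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    grouping: str = ""


@dataclass(frozen=True)
class MaturityResult:
    per_sample: pd.DataFrame    # sample_id, age_days, diet_group, maturity
    summary: pd.DataFrame       # (age_days, diet_group) -> mean, sd, n


# ---------------------------------------------------------------------------
# Distances


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = sum|x_i - x_j| / sum(x_i + x_j)."""
    x = table.counts.to_numpy(dtype=float).T   # samples x OTUs
    if (x.sum(axis=1) == 0).any():
        empty = [s for s, t in zip(table.sample_ids, x.sum(axis=1)) if t == 0]
        raise ValueError(f"all-zero samples: {empty}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          ids=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / total observed branch length.

    Presence/absence only; each branch counts toward the union if any tip
    below it is present in either sample, and toward the unique fraction
    if those tips are present in exactly one of the two.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    tree = _binarize_root(tree)
    counts = table.counts.to_numpy().T
    return beta_diversity("unweighted_unifrac", counts,
                          ids=table.sample_ids, taxa=table.otu_ids,
                          tree=tree, validate=True)


def _binarize_root(tree: TreeNode) -> TreeNode:
    """Nest a multifurcating root under zero-length internal nodes.

    Inserting zero-length branches leaves every UniFrac value unchanged
    while satisfying the rooted-tree (binary root) requirement.
    """
    if len(tree.children) <= 2:
        return tree
    tree = tree.copy()
    while len(tree.children) > 2:
        a, b = tree.children[0], tree.children[1]
        tree.remove(a)
        tree.remove(b)
        joint = TreeNode(children=[a, b])
        joint.length = 0.0
        tree.append(joint)
    return tree


# ---------------------------------------------------------------------------
# Ordination


def nmds(dist: DistanceMatrix, k: int = 2, seed: int = 0,
         n_restarts: int = 20) -> OrdinationResult:
    """Non-metric MDS by SMACOF with monotone regression.

    One run is initialised from classical (metric) scaling of the distance
    matrix; the remaining ``n_restarts - 1`` runs are random. The lowest
    Kruskal stress-1 configuration wins. Deterministic given ``seed``.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    if not d.any():
        raise ValueError("all-zero distance matrix cannot be ordinated")
    init = pcoa(dist, number_of_dimensions=min(k, n - 1),
                method="eigh").samples.to_numpy()[:, :k]
    if init.shape[1] < k:   # degenerate: pad with zeros
        init = np.hstack([init, np.zeros((n, k - init.shape[1]))])
    best_coords, best_stress = smacof(
        d, metric=False, n_components=k, init=init, n_init=1,
        max_iter=500, eps=1e-9, normalized_stress=True,
        random_state=np.random.RandomState(seed))
    if n_restarts > 1:
        coords, stress = smacof(
            d, metric=False, n_components=k, n_init=n_restarts - 1,
            max_iter=500, eps=1e-9, normalized_stress=True,
            random_state=np.random.RandomState(seed + 1))
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best_coords, index=list(dist.ids), columns=cols),
        stress=float(best_stress), n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# Permutation tests


def _as_grouping(dist: DistanceMatrix, groups) -> pd.Series:
    if isinstance(groups, pd.Series):
        g = groups.loc[list(dist.ids)]
    else:
        g = pd.Series(list(groups), index=list(dist.ids))
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    return g


def permanova(dist: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int = 0) -> PermutationTestResult:
    """One-factor PERMANOVA (pseudo-F, free label permutation).

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    """
    g = _as_grouping(dist, groups)
    res = _skbio_permanova(dist, g.to_numpy(), permutations=n_permutations,
                           seed=seed)
    return PermutationTestResult(
        method="PERMANOVA", statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]), n_permutations=n_permutations,
        grouping=getattr(groups, "name", "") or "")


def pairwise_permanova(dist: DistanceMatrix, groups,
                       n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """PERMANOVA over all group pairs with Benjamini-Hochberg adjustment."""
    g = _as_grouping(dist, groups)
    levels = sorted(g.unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            ids = g.index[g.isin([a, b])].tolist()
            sub = dist.filter(ids)
            res = permanova(sub, g.loc[ids], n_permutations, seed)
            rows.append({"group_a": a, "group_b": b,
                         "pseudo_F": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def permdisp(dist: DistanceMatrix, groups, n_permutations: int = 999,
             seed: int = 0) -> PermutationTestResult:
    """Homogeneity of multivariate dispersion (distance to group spatial
    median in principal-coordinate space; ANOVA F; permutation p)."""
    g = _as_grouping(dist, groups)
    res = _skbio_permdisp(dist, g.to_numpy(), test="median",
                          permutations=n_permutations, seed=seed)
    return PermutationTestResult(
        method="PERMDISP", statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]), n_permutations=n_permutations,
        grouping=getattr(groups, "name", "") or "")


# ---------------------------------------------------------------------------
# Community maturity


def maturity_distance(dist: DistanceMatrix, meta: pd.DataFrame,
                      reference_age: int = 49) -> MaturityResult:
    """Mean dissimilarity of each sample to the reference-age samples of its
    own diet group.

    A sample at the reference age is compared leave-self-out, so the
    reference group keeps a nonzero within-group baseline.
    """
    ids = list(dist.ids)
    meta = meta.loc[ids]
    rows = []
    for diet, sub in meta.groupby("diet_group", sort=True):
        ref_ids = sub.index[sub["age_days"] == reference_age].tolist()
        if not ref_ids:
            raise ValueError(
                f"diet group {diet!r} has no samples at reference age "
                f"{reference_age}")
        for sid in sub.index:
            others = [r for r in ref_ids if r != sid]
            if not others:
                raise ValueError(
                    f"sample {sid!r} is the only reference-age sample in "
                    f"group {diet!r}")
            val = float(np.mean([dist[sid, r] for r in others]))
            rows.append({"sample_id": sid,
                         "age_days": int(sub.loc[sid, "age_days"]),
                         "diet_group": diet, "maturity": val})
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    summary = (per_sample.groupby(["age_days", "diet_group"])["maturity"]
               .agg(["mean", "std", "count"])
               .rename(columns={"std": "sd", "count": "n"}))
    return MaturityResult(per_sample=per_sample, summary=summary)
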