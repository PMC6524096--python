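"""Synthetic study generator with known ground truth.

Emulates a cross-sectional cecal-microbiota succession design: five ages
(18, 28, 35, 43, 49 days), three diet groups (RL, LL, HH), ten animals per
age x diet cell, library sizes around 48,670 +/- 11,497 reads. Communities
shift from Bacteroidetes-dominant (56% at 18 d) to Firmicutes-dominant
(91% at 49 d). The generator plants:

* prevalence-structured core classes (persistent, milk-only, acquired with
  solid feed, milk-and-late shared) realised as OTUs whose base abundance
  is exactly zero outside their active ages;
* co-occurrence blocks whose members share a latent log-normal factor in a
  configurable age window, so downstream Spearman networks have known true
  edges that densify with age.

Counts are Dirichlet-multinomial within each phylum around age-specific
base compositions, with per-age phylum masses interpolated linearly between
the 18 d and 49 d endpoint profiles, so the expected phylum trajectory is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .tableio import CountTable, TAXONOMY_RANKS

DEFAULT_AGES = (18, 28, 35, 43, 49)
DEFAULT_DIETS = ("RL", "LL", "HH")

# Endpoint phylum profiles (relative abundance at 18 d and 49 d).
PHYLA = ("Bacteroidetes", "Firmicutes", "Proteobacteria", "Other")
PHYLUM_START = {"Bacteroidetes": 0.56, "Firmicutes": 0.37,
                "Proteobacteria": 0.05, "Other": 0.02}
PHYLUM_END = {"Bacteroidetes": 0.06, "Firmicutes": 0.91,
              "Proteobacteria": 0.017, "Other": 0.013}


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-occurrence block.

    ``weight`` is each member's share of its phylum's mass; ``rho`` the
    latent pairwise correlation (negative values alternate member signs);
    ``window`` the inclusive age range in which the block factor is active.
    """
    name: str
    phylum: str
    size: int
    weight: float
    rho: float
    window: tuple[int, int]


# Defaults chosen so early networks are sparse and Bacteroides-centred and
# late networks dense and Firmicutes-centred, mirroring the succession.
DEFAULT_BLOCKS = (
    BlockSpec("early", "Bacteroidetes", 3, 0.040, 0.99, (18, 28)),
    BlockSpec("mid", "Firmicutes", 3, 0.020, 0.99, (35, 49)),
    BlockSpec("late1", "Firmicutes", 4, 0.015, 0.99, (43, 49)),
    BlockSpec("late2", "Firmicutes", 4, 0.015, 0.99, (43, 49)),
    BlockSpec("neg", "Firmicutes", 2, 0.015, -0.97, (43, 49)),
)

# Planted core classes: (class name, phylum, n OTUs, per-OTU phylum share,
# active ages as a predicate over the design's ages).
CORE_CLASSES = (
    ("persistent", "Firmicutes", 12, 0.012, lambda ages: set(ages)),
    ("milk_only", "Bacteroidetes", 8, 0.012, lambda ages: {ages[0]}),
    ("acquired", "Firmicutes", 10, 0.012, lambda ages: set(ages[1:])),
    ("milk_late_shared", "Bacteroidetes", 6, 0.025,
     lambda ages: {ages[0], ages[-2], ages[-1]}),
)


@dataclass
class StudyDesign:
    """Parameters of the simulated cross-sectional study."""

    ages: tuple[int, ...] = DEFAULT_AGES
    diet_groups: tuple[str, ...] = DEFAULT_DIETS
    n_per_cell: int = 10
    n_otus: int = 300
    depth_mean: float = 48670.0
    depth_sd: float = 11497.0
    depth_floor: int = 1000
    concentration: float = 1200.0  # within-phylum Dirichlet concentration
    block_sd: float = 1.0          # latent log-normal scale of block factors
    idio_sd: float = 0.6           # idiosyncratic overdispersion, non-block OTUs
    blocks: tuple[BlockSpec, ...] = DEFAULT_BLOCKS
    seed: int = 0

    def __post_init__(self) -> None:
        ages = tuple(self.ages)
        if list(ages) != sorted(set(ages)):
            raise ValueError("ages must be strictly increasing")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.n_otus < 10:
            raise ValueError("n_otus must be >= 10")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        n_planted = sum(c[2] for c in CORE_CLASSES) + sum(
            b.size for b in self.blocks)
        if self.n_otus < n_planted + 10:
            raise ValueError(
                f"n_otus must cover the {n_planted} planted OTUs "
                "plus background (>= 10 more)")
        for b in self.blocks:
            if abs(b.rho) > 1:
                raise ValueError(f"block {b.name}: |rho| must be <= 1")
            if b.size < 2:
                raise ValueError(f"block {b.name}: size must be >= 2")

    @property
    def n_samples(self) -> int:
        return len(self.ages) * len(self.diet_groups) * self.n_per_cell


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    core_sets: dict[str, list[str]]
    planted_edges: list[tuple[str, str, float, tuple[int, int]]]
    phylum_trajectory: pd.DataFrame            # age x phylum expected fractions
    base_composition: pd.DataFrame             # OTU x age expected rel. abundance
    otu_phylum: dict[str, str]

    def edges_at_age(self, age: int) -> list[tuple[str, str, float]]:
        return [(a, b, r) for a, b, r, (lo, hi) in self.planted_edges
                if lo <= age <= hi]


def phylum_trajectory(ages) -> pd.DataFrame:
    """Expected per-age phylum fractions, linear between the endpoints."""
    ages = list(ages)
    lo, hi = ages[0], ages[-1]
    rows = {}
    for age in ages:
        t = 0.0 if hi == lo else (age - lo) / (hi - lo)
        rows[age] = {p: PHYLUM_START[p] + t * (PHYLUM_END[p] - PHYLUM_START[p])
                     for p in PHYLA}
    return pd.DataFrame.from_dict(rows, orient="index")[list(PHYLA)]


# ---------------------------------------------------------------------------
# OTU roster: ids, phyla, taxonomy, planted weights


_B_FAMILIES = [("Bacteroidaceae", "Bacteroides"),
               ("Rikenellaceae", "dgA-11 gut group"),
               ("Rikenellaceae", "Alistipes"),
               ("Barnesiellaceae", "")]
_F_FAMILIES = [("Ruminococcaceae", "Ruminococcaceae NK4A214 group"),
               ("Ruminococcaceae", ""),
               ("Lachnospiraceae", "Lachnospiraceae NK4A136 group"),
               ("Lachnospiraceae", "Blautia"),
               ("Christensenellaceae", ""),
               ("Eubacteriaceae", "Eubacterium")]
_P_FAMILIES = [("Rhodospirillaceae", "")]
_O_FAMILIES = [("Mycoplasmataceae", ""), ("Bifidobacteriaceae", "")]


def _family_for(phylum: str, k: int) -> tuple[str, str]:
    fams = {"Bacteroidetes": _B_FAMILIES, "Firmicutes": _F_FAMILIES,
            "Proteobacteria": _P_FAMILIES, "Other": _O_FAMILIES}[phylum]
    return fams[k % len(fams)]


def _build_roster(design: StudyDesign):
    """Assign ids, phyla, planted roles and within-phylum weights."""
    ids, phyla, roles = [], [], []
    core_sets: dict[str, list[str]] = {}
    weights: dict[str, float] = {}
    active: dict[str, set[int]] = {}
    k = 0

    def add(phylum, role, weight, active_ages):
        nonlocal k
        oid = f"otu{k + 1:04d}"
        k += 1
        ids.append(oid)
        phyla.append(phylum)
        roles.append(role)
        weights[oid] = weight
        active[oid] = set(active_ages)
        return oid

    ages = list(design.ages)
    for name, phylum, n, w, window_fn in CORE_CLASSES:
        core_sets[name] = [add(phylum, f"core:{name}", w, window_fn(ages))
                           for _ in range(n)]
    block_members: dict[str, list[str]] = {}
    for b in design.blocks:
        block_members[b.name] = [add(b.phylum, f"block:{b.name}", b.weight, ages)
                                 for _ in range(b.size)]
    n_background = design.n_otus - k
    # background phylum mix: enough ids in every phylum to carry its mass
    bg_share = {"Bacteroidetes": 0.31, "Firmicutes": 0.62,
                "Proteobacteria": 0.05, "Other": 0.02}
    counts = {p: max(2, int(round(bg_share[p] * n_background))) for p in PHYLA}
    while sum(counts.values()) > n_background:
        counts["Firmicutes"] -= 1
    counts["Firmicutes"] += n_background - sum(counts.values())
    for p in PHYLA:
        for _ in range(counts[p]):
            add(p, "background", np.nan, ages)  # weight drawn later
    return ids, phyla, roles, core_sets, block_members, weights, active


def _taxonomy_frame(ids, phyla) -> pd.DataFrame:
    rows = []
    per_phylum_counter: dict[str, int] = {}
    for oid, p in zip(ids, phyla):
        k = per_phylum_counter.get(p, 0)
        per_phylum_counter[p] = k + 1
        fam, genus = _family_for(p, k)
        kingdom = "Bacteria"
        phylum_label = {"Other": "Tenericutes"}.get(p, p)
        rows.append({"kingdom": kingdom, "phylum": phylum_label,
                     "class": "", "order": "", "family": fam, "genus": genus})
    tax = pd.DataFrame(rows, index=pd.Index(ids, name="otu_id"))
    return tax[list(TAXONOMY_RANKS)]


# ---------------------------------------------------------------------------
# Trees


def generate_tree(otu_ids, seed: int) -> TreeNode:
    """Random bifurcating rooted tree over ``otu_ids`` with positive lengths."""
    otu_ids = list(otu_ids)
    if len(otu_ids) != len(set(otu_ids)):
        raise ValueError("duplicate OTU ids")
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTU ids")
    rng = np.random.default_rng(seed)
    nodes = []
    for oid in otu_ids:
        tip = TreeNode(name=str(oid))
        tip.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Correlated count blocks (standalone primitive)


def simulate_correlated_counts(block_spec, n_samples: int, depth: int,
                               seed: int, latent_sd: float = 1.0,
                               sampling: str = "poisson") -> np.ndarray:
    """Draw a count matrix (OTU x sample) with planted within-block correlation.

    ``block_spec`` is a list of ``(size, latent_rho)``. Each block shares a
    standard-normal factor; member ``i``'s log intensity is
    ``latent_sd * (s_i * sqrt(|rho|) * z_block + sqrt(1 - |rho|) * e_i)``
    with ``s_i`` alternating between +1 and -1 when ``rho < 0``. Counts are
    Poisson around ``depth/n_otus`` times the intensity (``sampling="none"``
    returns the rounded intensities, removing sampling noise).
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    for size, rho in block_spec:
        if size < 2:
            raise ValueError("block size must be >= 2")
        if abs(rho) > 1:
            raise ValueError("|latent_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    n_otus = sum(size for size, _ in block_spec)
    lam = np.empty((n_otus, n_samples))
    row = 0
    for size, rho in block_spec:
        z_block = rng.standard_normal(n_samples)
        for m in range(size):
            sign = -1.0 if (rho < 0 and m % 2 == 1) else 1.0
            e = rng.standard_normal(n_samples)
            g = sign * np.sqrt(abs(rho)) * z_block + np.sqrt(1 - abs(rho)) * e
            lam[row] = (depth / n_otus) * np.exp(latent_sd * g)
            row += 1
    if sampling == "poisson":
        return rng.poisson(lam).astype(np.int64)
    if sampling == "none":
        return np.round(lam).astype(np.int64)
    raise ValueError(f"unknown sampling mode {sampling!r}")


# ---------------------------------------------------------------------------
# Full study


def generate_study(design: StudyDesign):
    """Generate (CountTable, PhyloTree, GroundTruth) for a study design.

    Deterministic given ``design.seed``; the seed is expanded into
    independent substreams for the tree, the library depths and the counts.
    """
    ss = np.random.SeedSequence(design.seed)
    s_tree, s_depth, s_counts, s_weights = ss.spawn(4)
    (ids, phyla, roles, core_sets, block_members,
     weights, active) = _build_roster(design)
    ages = list(design.ages)
    traj = phylum_trajectory(ages)

    # background within-phylum weights: lognormal, filling the share of the
    # phylum not taken by planted OTUs (per age, over active planted OTUs)
    wrng = np.random.default_rng(s_weights)
    bg_raw = {oid: float(wrng.lognormal(0.0, 1.0))
              for oid, role in zip(ids, roles) if role == "background"}

    idx = pd.Index(ids, name="otu_id")
    base = pd.DataFrame(0.0, index=idx, columns=ages)
    for age in ages:
        for p in PHYLA:
            members = [o for o, ph in zip(ids, phyla) if ph == p]
            planted = [o for o in members if not np.isnan(weights.get(o, np.nan))]
            bg = [o for o in members if o in bg_raw]
            planted_w = {o: (weights[o] if age in active[o] else 0.0)
                         for o in planted}
            taken = sum(planted_w.values())
            if taken >= 1.0:
                raise ValueError(
                    f"planted weights exceed phylum share for {p} at {age}")
            bg_total = sum(bg_raw[o] for o in bg)
            mass = traj.loc[age, p]
            for o in planted:
                base.loc[o, age] = planted_w[o] * mass
            for o in bg:
                base.loc[o, age] = (1.0 - taken) * bg_raw[o] / bg_total * mass

    # sample roster
    sample_ids, meta_rows = [], []
    for age in ages:
        for diet in design.diet_groups:
            for rep in range(design.n_per_cell):
                sid = f"{diet}_{age}d_{rep + 1:02d}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "age_days": age,
                                  "diet_group": diet,
                                  "doe_id": f"doe_{diet}_{rep + 1:02d}"})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # depths: truncated normal, floor depth_floor
    drng = np.random.default_rng(s_depth)
    a = (design.depth_floor - design.depth_mean) / design.depth_sd
    depths = stats.truncnorm.rvs(
        a, np.inf, loc=design.depth_mean, scale=design.depth_sd,
        size=len(sample_ids), random_state=drng).round().astype(int)

    # counts: within-phylum Dirichlet + windowed block factors, multinomial
    crng = np.random.default_rng(s_counts)
    phylum_of = dict(zip(ids, phyla))
    pos = {oid: i for i, oid in enumerate(ids)}
    counts = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
    block_by_name = {b.name: b for b in design.blocks}
    for j, sid in enumerate(sample_ids):
        age = meta.loc[sid, "age_days"]
        p_vec = np.zeros(len(ids))
        base_age = base[age].to_numpy()
        in_block = np.zeros(len(ids), dtype=bool)
        for members in block_members.values():
            for oid in members:
                in_block[pos[oid]] = True
        jitter = np.ones(len(ids))
        if design.idio_sd > 0:
            z_idio = crng.standard_normal((~in_block).sum())
            jitter[~in_block] = np.exp(
                design.idio_sd * z_idio - design.idio_sd ** 2 / 2)
        for bname, members in block_members.items():
            b = block_by_name[bname]
            if not (b.window[0] <= age <= b.window[1]):
                continue
            z = crng.standard_normal()
            rho = b.rho
            for m, oid in enumerate(members):
                sign = -1.0 if (rho < 0 and m % 2 == 1) else 1.0
                e = crng.standard_normal()
                g = sign * np.sqrt(abs(rho)) * z + np.sqrt(1 - abs(rho)) * e
                jitter[pos[oid]] = np.exp(design.block_sd * g)
        for p in PHYLA:
            sel = np.array([phylum_of[o] == p for o in ids])
            w = base_age[sel]
            act = w > 0
            alpha = design.concentration * w[act] / w[act].sum()
            x = np.zeros(w.shape)
            draw = crng.dirichlet(alpha)
            jit = jitter[sel][act]
            draw = draw * jit
            x[act] = draw / draw.sum() * w.sum()
            p_vec[sel] = x
        counts[:, j] = crng.multinomial(depths[j], p_vec / p_vec.sum())

    counts_df = pd.DataFrame(counts, index=idx, columns=sample_ids)
    tax = _taxonomy_frame(ids, phyla)
    table = CountTable(counts_df, meta, tax)
    tree = generate_tree(ids, int(s_tree.generate_state(1)[0] % (2 ** 31)))

    planted_edges = []
    for bname, members in block_members.items():
        b = block_by_name[bname]
        for i in range(len(members)):
            for j2 in range(i + 1, len(members)):
                rho = b.rho
                if rho < 0:
                    rho = abs(rho) if (i % 2) == (j2 % 2) else -abs(rho)
                planted_edges.append((members[i], members[j2], rho, b.window))
    truth = GroundTruth(
        core_sets=core_sets,
        planted_edges=planted_edges,
        phylum_trajectory=traj,
        base_composition=base,
        otu_phylum=phylum_of,
    )
    return table, tree, truth


# ---------------------------------------------------------------------------
# Writers


def write_study(table: CountTable, tree: TreeNode, truth: GroundTruth,
                outdir) -> dict[str, str]:
    """Write counts/metadata/taxonomy TSVs, Newick tree and ground-truth JSON."""
    import json
    from pathlib import Path
    from . import tableio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "taxonomy": str(outdir / "taxonomy.tsv"),
        "tree": str(outdir / "tree.nwk"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    tableio.write_count_table(table, paths["counts"])
    tableio.write_sample_metadata(table.sample_meta, paths["metadata"])
    tableio.write_taxonomy(table.taxonomy, paths["taxonomy"])
    tableio.write_newick(tree, paths["tree"])
    gt = {
        "core_sets": truth.core_sets,
        "planted_edges": [
            {"otu_a": a, "otu_b": b, "latent_rho": r,
             "age_window": list(w)} for a, b, r, w in truth.planted_edges],
        "phylum_trajectory": {
            str(age): row.to_dict()
            for age, row in truth.phylum_trajectory.iterrows()},
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt, fh, indent=1)
    return paths
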