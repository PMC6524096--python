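"""End-to-end pipeline: simulate/load -> rarefy -> diversity -> beta diversity
and maturity -> core partition -> per-age networks -> intersections -> report.

Driven by a :class:`PipelineConfig` (usually parsed from YAML). Every run
writes its artifacts plus ``summary.json``, the resolved configuration and a
``MANIFEST.tsv`` with a content hash per artifact; a failed stage leaves the
manifest marked incomplete. Deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import betadiv, coreotus, diversity, network, synthdata, tableio

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    prevalence: float = 0.75
    abundance: float = 0.01
    rho: float = 0.7
    p: float = 2.32e-5
    pathway: float = 1 / 3

    def validate(self) -> None:
        for name, lo, hi in (("prevalence", 0, 1), ("abundance", 0, 1),
                             ("rho", 0, 1), ("p", 0, 1), ("pathway", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"threshold {name}={v} outside [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    simulate: dict | None = None          # StudyDesign overrides, or None
    inputs: dict | None = None            # counts/metadata/taxonomy/tree paths
    rarefaction_depth: int | str = "auto"
    thresholds: Thresholds = field(default_factory=Thresholds)
    permutations: int = 999
    reference_age: int = 49
    maturity_metric: str = "bray"         # or "unifrac"

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.thresholds.validate()
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a simulate block or inputs")
        if self.maturity_metric not in ("bray", "unifrac"):
            raise ValueError("maturity_metric must be 'bray' or 'unifrac'")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict = {"seed": config.seed}

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    def manifest(complete: bool) -> None:
        rows = [f"{p.name}\t{_sha256(p)}" for p in artifacts if p.exists()]
        status = "complete" if complete else "INCOMPLETE"
        (out / "MANIFEST.tsv").write_text(
            f"# status: {status}\n" + "\n".join(rows) + "\n")

    resolved = {
        "out_dir": str(config.out_dir), "seed": config.seed,
        "simulate": config.simulate, "inputs": config.inputs,
        "rarefaction_depth": config.rarefaction_depth,
        "thresholds": asdict(config.thresholds),
        "permutations": config.permutations,
        "reference_age": config.reference_age,
        "maturity_metric": config.maturity_metric,
    }
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved))
    artifacts.append(out / "config.resolved.yaml")

    stage = "input"
    try:
        if config.simulate is not None:
            design = synthdata.StudyDesign(
                **{**config.simulate, "seed": config.seed})
            table, tree, truth = synthdata.generate_study(design)
            paths = synthdata.write_study(table, tree, truth, out / "input")
            for p in paths.values():
                artifacts.append(Path(p))
        else:
            table, tree = tableio.load_study(
                config.inputs["counts"], config.inputs["metadata"],
                config.inputs.get("taxonomy"), config.inputs.get("tree"),
                counts_format=config.inputs.get("format", "tsv"))

        stage = "rarefy"
        depth = (diversity.auto_depth(table)
                 if config.rarefaction_depth == "auto"
                 else int(config.rarefaction_depth))
        rt = diversity.rarefy(table, depth, seed=config.seed)
        summary["rarefaction_depth"] = depth
        summary["n_samples"] = len(rt.sample_ids)

        stage = "diversity"
        alpha = diversity.alpha_frame(diversity.alpha_diversity(rt))
        alpha.to_csv(emit(out / "alpha.tsv"), sep="\t")
        summary["alpha_mean_shannon"] = float(alpha["shannon"].mean())

        stage = "betadiv"
        dm_bray = betadiv.bray_curtis(rt)
        pd.DataFrame(dm_bray.data, index=list(dm_bray.ids),
                     columns=list(dm_bray.ids)).to_csv(
            emit(out / "bray_curtis.tsv"), sep="\t")
        dm_uni = None
        if tree is not None:
            dm_uni = betadiv.unweighted_unifrac(rt, tree)
            pd.DataFrame(dm_uni.data, index=list(dm_uni.ids),
                         columns=list(dm_uni.ids)).to_csv(
                emit(out / "unifrac.tsv"), sep="\t")
        ord_res = betadiv.nmds(dm_bray, seed=config.seed)
        ord_res.coordinates.to_csv(emit(out / "nmds.tsv"), sep="\t")
        summary["nmds_stress"] = ord_res.stress

        meta = rt.sample_meta
        adonis = betadiv.pairwise_permanova(
            dm_bray, meta["diet_group"], config.permutations, config.seed)
        adonis.to_csv(emit(out / "permanova_diet_pairwise.tsv"),
                      sep="\t", index=False)
        disp = betadiv.permdisp(dm_bray, meta["age_days"].astype(str),
                                config.permutations, config.seed)
        summary["permdisp_age"] = {"F": disp.statistic, "p": disp.p_value}

        stage = "maturity"
        dm_mat = dm_bray if config.maturity_metric == "bray" else dm_uni
        if dm_mat is None:
            raise ValueError("unifrac maturity requested but no tree given")
        mat = betadiv.maturity_distance(dm_mat, meta, config.reference_age)
        mat.per_sample.to_csv(emit(out / "maturity.tsv"), sep="\t")
        summary["maturity_by_age"] = {
            str(a): float(v) for a, v in
            mat.per_sample.groupby("age_days")["maturity"].mean().items()}

        stage = "core"
        presence = coreotus.presence_by_age(rt, config.thresholds.prevalence)
        part = coreotus.venn_partition(presence)
        core_doc = {
            "union_size": part.union_size,
            "regions": {k: sorted(v) for k, v in part.named.items()},
            "sizes": part.region_sizes(),
            "percentages": {k: part.percentage(k) for k in part.named},
        }
        emit(out / "core_partition.json").write_text(
            json.dumps(core_doc, indent=1))
        summary["core_sizes"] = part.region_sizes()

        stage = "network"
        ages = rt.ages()
        nets = {}
        net_metrics = {}
        for age in ages:
            net = network.network_from_table(
                rt, age, config.thresholds.abundance,
                config.thresholds.rho, config.thresholds.p)
            nets[age] = net
            network.write_graphml(net, emit(out / f"net_{age}d.graphml"))
            net.edge_frame().to_csv(emit(out / f"net_{age}d_edges.tsv"),
                                    sep="\t", index=False)
            try:
                m = network.network_metrics(net)
                net_metrics[str(age)] = asdict(m)
            except ValueError:
                net_metrics[str(age)] = None   # all isolates at this age
        emit(out / "network_metrics.json").write_text(
            json.dumps(net_metrics, indent=1))
        summary["network_metrics"] = net_metrics

        stage = "intersect"
        inter_reports = {}
        for a, b in zip(ages, ages[1:]):
            inter, report = network.intersect_networks(nets[a], nets[b])
            network.write_graphml(
                inter, emit(out / f"net_{a}d_{b}d_intersection.graphml"))
            inter_reports[f"{a}-{b}"] = report
        emit(out / "intersections.json").write_text(
            json.dumps(inter_reports, indent=1))
        summary["intersections"] = inter_reports

        stage = "summary"
        emit(out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
    except Exception as exc:
        manifest(complete=False)
        raise StageError(stage, exc) from exc
    manifest(complete=True)
    return summary
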