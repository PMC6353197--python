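"""End-to-end orchestration: simulate or ingest, recode, stratify, learn,
bootstrap, average, score — with per-stratum reports and deterministic seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .bnlearn_core import StructureConfig
from .bootstrap_averaging import (
    AveragedNetwork,
    EdgeStrengthTable,
    annotate_clusters,
    average_network,
    bootstrap_networks,
)
from .dataset import CategoricalDataset
from .netstats import NetworkStatsReport, compute_stats, format_distance
from .operationalize import apply_recodes, complete_case_filter
from .schema import CLUSTERS, PA_VARIABLE, SB_VARIABLE, VariableSchema
from .synthetic_data import GroundTruthModel, sample_categorical

logger = logging.getLogger(__name__)

__all__ = [
    "StratumSpec",
    "RunConfig",
    "StratumResult",
    "RunResult",
    "stratify",
    "exclude_pa",
    "run_full_analysis",
    "export_reports",
]

AGE_BAND_LABELS = ("15_25", "26_44", "45_64", "65plus")
SEX_LABELS = ("female", "male")


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum; 'all' selects every respondent."""

    sex: str = "all"
    age_band: str = "all"

    def __post_init__(self) -> None:
        if self.sex not in (*SEX_LABELS, "all"):
            raise ValueError(f"sex must be female/male/all, got {self.sex!r}")
        if self.age_band not in (*AGE_BAND_LABELS, "all"):
            raise ValueError(f"unknown age band {self.age_band!r}")

    @property
    def name(self) -> str:
        if self.sex == "all" and self.age_band == "all":
            return "all"
        return f"{self.age_band}_{self.sex}"

    @property
    def is_overall(self) -> bool:
        return self.sex == "all" and self.age_band == "all"


def default_strata() -> list[StratumSpec]:
    """The overall sample plus the eight sex-by-age strata."""
    out = [StratumSpec()]
    for band in AGE_BAND_LABELS:
        for sex in SEX_LABELS:
            out.append(StratumSpec(sex=sex, age_band=band))
    return out


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``max_sepset`` defaults to 1 here (vs 2 in :class:`StructureConfig`) to
    keep full-scale bootstrap runs within desk-scale runtime; raise it for
    smaller problems.
    """

    include_pa: bool = False
    replicates: int = 1000
    threshold: float = 0.40
    alpha: float = 0.05
    max_sepset: int = 1
    score: str = "bic"
    seed: int = 0
    n: int = 24000
    exclude: tuple[str, ...] = ()
    weight_mode: str = "inverse"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def structure_config(self) -> StructureConfig:
        return StructureConfig(
            alpha=self.alpha, max_sepset=self.max_sepset, score=self.score
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def exclude_pa(
    columns: Sequence[str], config: RunConfig
) -> list[str]:
    """Analysis variable list: PA dropped unless sensitivity mode is on."""
    cols = list(columns)
    for name in config.exclude:
        if name not in cols:
            raise ValueError(f"cannot exclude unknown variable {name!r}")
        cols.remove(name)
    if not config.include_pa and PA_VARIABLE in cols:
        cols.remove(PA_VARIABLE)
    return cols


def stratify(
    data: CategoricalDataset, specs: Sequence[StratumSpec] | None = None
) -> dict[str, CategoricalDataset]:
    """Split into named strata; stratification variables are removed from
    within-stratum datasets but kept in the overall one."""
    specs = list(specs) if specs is not None else default_strata()
    for field in ("sex", "age_group"):
        if field not in data:
            raise ValueError(f"stratification variable {field!r} missing from data")
    sex_levels = data.variable("sex").levels
    age_levels = data.variable("age_group").levels
    out: dict[str, CategoricalDataset] = {}
    for spec in specs:
        mask = np.ones(data.n_rows, dtype=bool)
        if spec.sex != "all":
            mask &= data.column("sex") == sex_levels.index(spec.sex)
        if spec.age_band != "all":
            mask &= data.column("age_group") == age_levels.index(spec.age_band)
        sub = data.mask_rows(mask)
        if not spec.is_overall:
            keep = [c for c in sub.columns if c not in ("sex", "age_group")]
            sub = sub.select(keep)
        if sub.n_rows == 0:
            logger.warning("stratum %s is empty; skipped", spec.name)
            continue
        out[spec.name] = sub
    return out


@dataclasses.dataclass
class StratumResult:
    name: str
    n_rows: int
    strengths: EdgeStrengthTable
    network: AveragedNetwork
    stats: NetworkStatsReport


@dataclasses.dataclass
class RunResult:
    strata: dict[str, StratumResult]
    manifest: dict
    schema: list[VariableSchema]


def _prepare_dataset(
    config: RunConfig, source
) -> CategoricalDataset:
    if isinstance(source, GroundTruthModel):
        return sample_categorical(source, config.n, seed=config.seed)
    if isinstance(source, pd.DataFrame):
        recoded = apply_recodes(source)
        return complete_case_filter(recoded)
    if isinstance(source, CategoricalDataset):
        return source
    raise TypeError(f"unsupported input type {type(source).__name__}")


def run_full_analysis(config: RunConfig, source) -> RunResult:
    """Complete analysis for the overall sample and every stratum.

    Input may be a ground-truth model (sampled at ``config.n``), a raw survey
    table (recoded and complete-case filtered) or a ready categorical dataset.
    A failing stratum is logged and skipped; the others proceed.
    """
    data = _prepare_dataset(config, source)
    if data.n_rows == 0:
        raise ValueError("empty stratum: no complete-case rows to analyse")
    columns = exclude_pa(data.columns, config)
    data = data.select(columns)
    strata = stratify(data)
    structure = config.structure_config()

    results: dict[str, StratumResult] = {}
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_total": data.n_rows,
        "variables": columns,
        "strata": {},
    }
    for idx, (name, sub) in enumerate(sorted(strata.items(), key=lambda kv: kv[0])):
        stratum_seed = config.seed * 100003 + idx
        t0 = time.perf_counter()
        try:
            strengths = bootstrap_networks(
                sub, config.replicates, config=structure, seed=stratum_seed
            )
            net = average_network(strengths, threshold=config.threshold)
            annotate_clusters(net, data.schema)
            if SB_VARIABLE in net.graph:
                stats = compute_stats(
                    net, data.schema, weight_mode=config.weight_mode
                )
            else:
                raise ValueError(f"target {SB_VARIABLE!r} absent from stratum network")
        except Exception:
            logger.exception("stratum %s failed; continuing with the others", name)
            continue
        elapsed = time.perf_counter() - t0
        logger.info("stratum %s: n=%d, %.1fs", name, sub.n_rows, elapsed)
        results[name] = StratumResult(name, sub.n_rows, strengths, net, stats)
        manifest["strata"][name] = {
            "n": sub.n_rows,
            "seed": stratum_seed,
            "replicates": config.replicates,
            "nodes": len(net.nodes),
            "edges": net.graph.number_of_edges(),
        }
    return RunResult(results, manifest, data.schema)


# --------------------------------------------------------------------------- #
# exports
# --------------------------------------------------------------------------- #

CLUSTER_COLORS = {
    "psychology_behaviour": "#e41a1c",
    "institutional_home": "#377eb8",
    "physical_health": "#4daf4a",
    "built_natural": "#984ea3",
    "social_cultural": "#ff7f00",
    "politics_economics": "#a65628",
    "demographic": "#999999",
}


def write_dot(network: AveragedNetwork, path: Path) -> None:
    """DOT export with cluster-coloured nodes and width-by-stability edges."""
    lines = ["graph averaged {", "  node [style=filled];"]
    for node in network.nodes:
        cluster = network.graph.nodes[node].get("cluster", "demographic")
        color = CLUSTER_COLORS.get(cluster, "#cccccc")
        lines.append(f'  "{node}" [fillcolor="{color}", tooltip="{cluster}"];')
    for u, v, strength, cls in network.edges:
        width = 3.0 if cls == "strong" else 1.0
        lines.append(
            f'  "{u}" -- "{v}" [penwidth={width}, label="{strength:.2f}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def table1_frame(result: RunResult) -> pd.DataFrame:
    """Summary table: one column per stratum, rows mirroring the report shape."""
    order = [s.name for s in default_strata() if s.name in result.strata]
    order += [n for n in sorted(result.strata) if n not in order]
    rows: dict[str, dict[str, str]] = {}
    for name in order:
        res = result.strata[name]
        top = res.stats.top_nodes
        cell: dict[str, str] = {
            "sample_size": str(res.n_rows),
            "highest_betweenness": top[0][0] if top else "",
            "second_highest_betweenness": " & ".join(
                n for n, _ in top[1:]
            ) if len(top) > 1 else "",
            "denseness_pct": f"{res.stats.denseness:.1f}",
        }
        for cluster in CLUSTERS:
            if cluster == "demographic":
                continue
            cell[f"distance_{cluster}"] = format_distance(
                res.stats.cluster_distances.get(cluster)
            )
        rows[name] = cell
    return pd.DataFrame(rows)[order]


def export_reports(result: RunResult, outdir) -> list[Path]:
    """Write GraphML + DOT + strength CSV per stratum, the summary table and
    the run manifest.  Outputs are byte-deterministic for a fixed seed."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    if not result.strata:
        raise ValueError("no stratum results to export")
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    for name in sorted(result.strata):
        res = result.strata[name]
        nx.write_graphml(res.network.graph, emit(outdir / f"network_{name}.graphml"))
        write_dot(res.network, emit(outdir / f"network_{name}.dot"))
        res.strengths.to_csv(emit(outdir / f"strengths_{name}.csv"))
        payload = res.stats.to_dict()
        payload["stratum"] = name
        payload["n"] = res.n_rows
        (emit(outdir / f"stats_{name}.json")).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    table1_frame(result).to_csv(emit(outdir / "table1.csv"))
    (emit(outdir / "manifest.json")).write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    return written
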