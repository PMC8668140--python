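"""Config-driven orchestration: simulate -> score -> networks -> report.

A :class:`PipelineConfig` (loadable from YAML) names either existing input
CSVs or a simulation block, plus the analysis choices (alpha, n rule, sex
pooling). :func:`run_pipeline` runs every stage, writes all artifacts
under the output directory, and records a manifest (package version,
seed, config hash, artifact list) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as fio
from .behavior import score_drinking, score_usv_table, summarize_nausea_table, tally_emitters
from .network import (
    CoactivationNetwork,
    DifferentialCoactivationNetwork,
    network_summary,
)
from .simulate import SyntheticBehaviorConfig, SyntheticFosConfig, simulate_behavior, simulate_fos

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULT_TASK_CONDITIONS = ("COT", "BOT", "BLT")
DEFAULT_CONTRASTS = (("BOT", "COT"), ("BLT", "COT"))


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``fos_csv`` (plus optional behavioral CSVs) or ``simulate=True``
    must be given. Defaults mirror the study design: alpha 0.05, sexes
    pooled, networks for the three task conditions and the two
    task-minus-control contrasts.
    """

    out_dir: str = "fosnet_out"
    seed: int = 0
    simulate: bool = False
    fos_csv: str | None = None
    drinking_csv: str | None = None
    usv_csv: str | None = None
    nausea_csv: str | None = None
    conditions: tuple[str, ...] = DEFAULT_TASK_CONDITIONS
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    alpha: float = 0.05
    n_rule: str = "task_n"
    pool_sexes: bool = True
    subtract_thresholded: bool = False
    bh_correct: bool = False
    sim_n_per_condition: int = 12
    sim_planted_edges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.simulate and self.fos_csv is None:
            raise ValueError("either simulate=true or fos_csv must be provided")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "contrasts" in raw:
        raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
    if "conditions" in raw:
        raw["conditions"] = tuple(raw["conditions"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def emit(path: Path) -> Path:
        artifacts.append(str(path.relative_to(out)))
        return path

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        planted = {
            cond: [tuple(e) for e in edges]
            for cond, edges in config.sim_planted_edges.items()
        }
        fos_cfg = SyntheticFosConfig(
            planted_edges=planted,
            n_per_condition=config.sim_n_per_condition,
            seed=config.seed,
        )
        fos, truth = simulate_fos(fos_cfg)
        beh_cfg = SyntheticBehaviorConfig(seed=config.seed + 1)
        drinking, usv, nausea = simulate_behavior(beh_cfg)
        fio.write_fos_table(fos, emit(out / "fos.csv"))
        drinking.to_csv(emit(out / "drinking.csv"), index=False)
        usv.to_csv(emit(out / "usv.csv"), index=False)
        nausea.to_csv(emit(out / "nausea.csv"), index=False)
        fio.write_validation_report(truth, emit(out / "truth.json"))
    else:
        fos = fio.load_fos_table(config.fos_csv)
        drinking = fio.load_behavior_table(config.drinking_csv) if config.drinking_csv else None
        usv = fio.load_usv_table(config.usv_csv) if config.usv_csv else None
        nausea = fio.load_nausea_table(config.nausea_csv) if config.nausea_csv else None

    fio.write_validation_report(fos.report, emit(out / "fos_validation.json"))

    # --- behavioral scoring ----------------------------------------------
    if drinking is not None:
        scores, excluded = score_drinking(drinking)
        scores.to_csv(emit(out / "cta_scores.csv"), index=False)
        fio.write_validation_report({"excluded_subjects": excluded}, emit(out / "cta_exclusions.json"))
    if usv is not None:
        scored = score_usv_table(usv)
        scored.to_csv(emit(out / "usv_scores.csv"), index=False)
        tally, none_counts = tally_emitters(scored)
        flat = tally.copy()
        flat.columns = [f"{c}_{s}" if s else c for c, s in tally.columns]
        flat["none"] = none_counts
        flat.to_csv(emit(out / "usv_emitter_tally.csv"), index_label="condition")
    if nausea is not None:
        summarize_nausea_table(nausea).to_csv(emit(out / "nausea_summaries.csv"), index=False)

    # --- networks ---------------------------------------------------------
    report: dict = {"networks": {}, "contrasts": {}}
    results = {}
    for cond in config.conditions:
        res = CoactivationNetwork(fos, cond, pool_sexes=config.pool_sexes).fit(alpha=config.alpha)
        results[cond] = res
        for fmt, suffix in (("edge_list", "edges.tsv"), ("adjacency", "adjacency.csv"), ("graphml", "graph.graphml")):
            res.save(emit(out / f"net_{cond}_{suffix.replace('/', '_')}"), format=fmt)
        report["networks"][cond] = _summary_dict(res.network)
        (out / f"net_{cond}_summary.txt").write_text(res.summary() + "\n")
        emit(out / f"net_{cond}_summary.txt")

    for task, control in config.contrasts:
        res = DifferentialCoactivationNetwork(
            fos, task, control, pool_sexes=config.pool_sexes
        ).fit(
            alpha=config.alpha,
            n_rule=config.n_rule,
            subtract_thresholded=config.subtract_thresholded,
            bh_correct=config.bh_correct,
        )
        tag = f"{task}-{control}"
        res.table.to_csv(emit(out / f"diff_{tag}_pairs.csv"), index=False)
        for fmt, suffix in (("edge_list", "edges.tsv"), ("adjacency", "adjacency.csv"), ("graphml", "graph.graphml")):
            res.save(emit(out / f"diff_{tag}_{suffix}"), format=fmt)
        report["contrasts"][tag] = _summary_dict(res.network.retained)
        (out / f"diff_{tag}_summary.txt").write_text(res.summary() + "\n")
        emit(out / f"diff_{tag}_summary.txt")

    fio.write_validation_report(report, emit(out / "report.json"))
    (out / "report.md").write_text(_render_markdown(report))
    emit(out / "report.md")

    manifest = {
        "fosnet_version": __version__,
        "seed": int(config.seed),
        "config": asdict(config),
        "config_sha256": _config_hash(config),
        "artifacts": sorted(artifacts),
    }
    fio.write_validation_report(manifest, out / "manifest.json")
    return manifest


def _summary_dict(net) -> dict:
    s = network_summary(net)
    return {
        "n_edges": s.n_edges,
        "n_components": s.n_components,
        "isolates": list(s.isolates),
        "degrees": s.degrees,
        "degree_ranking": list(s.ranked),
        "all_regions_involved": s.all_regions_involved,
        "hub": s.hub,
    }


def _render_markdown(report: dict) -> str:
    lines = ["# Coactivation network report", ""]
    for section, title in (("networks", "Per-condition networks"), ("contrasts", "Differential networks")):
        lines += [f"## {title}", ""]
        for name, s in report[section].items():
            lines += [
                f"### {name}",
                "",
                f"- edges: {s['n_edges']}",
                f"- components: {s['n_components']}",
                f"- isolates: {', '.join(s['isolates']) or '(none)'}",
                f"- hub (top degree): {s['hub']}",
                f"- degree ranking: {', '.join(s['degree_ranking'])}",
                "",
            ]
    return "\n".join(lines)
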