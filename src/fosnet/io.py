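"""Readers, writers and validated tables for the pipeline's file formats.

All tabular inputs are UTF-8 comma-separated files with a header row.
Per-subject Fos counts travel in long ("tidy") form, one row per
subject x region; behavioral inputs use one row per subject (drinking,
USV minute counts) or one row per observation block (nausea scoring).

Networks are written as edge-list TSV, symmetric adjacency CSV (absent
edges as 0, matching the thresholding convention), or GraphML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .registries import ConditionRegistry, RegionRegistry, SEXES, UnknownCodeError

__all__ = [
    "SchemaError",
    "IntegrityError",
    "FosCountTable",
    "load_fos_table",
    "write_fos_table",
    "load_behavior_table",
    "load_usv_table",
    "load_nausea_table",
    "write_network",
    "read_network_graphml",
    "write_validation_report",
]

FOS_COLUMNS = ("subject_id", "sex", "condition", "region", "fos_count")
BEHAVIOR_COLUMNS = (
    "subject_id",
    "sex",
    "condition",
    "body_weight",
    "intake_d1",
    "intake_d2",
    "licl_dose",
    "estrous_state",
)
NAUSEA_COLUMNS = ("subject_id", "behavior", "epoch_index", "block_index", "score")
NAUSEA_BEHAVIORS = ("pica", "LOB", "ptosis")
ESTROUS_STATES = ("high_E2", "low_E2", "NA")
DEFAULT_LICL_DOSES = (0.0, 19.0, 38.0, 80.0)


class SchemaError(ValueError):
    """The file is structurally wrong (missing/mistyped columns or blocks)."""


class IntegrityError(ValueError):
    """The file violates a dataset invariant (duplicates, unknown codes...)."""


@dataclass
class FosCountTable:
    """Validated per-subject, per-region Fos counts.

    ``data`` holds one row per (subject, region) with columns
    ``subject_id, sex, condition, region, fos_count``; ``fos_count`` is the
    per-animal mean number of Fos-positive cells per image (a real number,
    since counts are averaged over slices). ``report`` is a small
    machine-readable validation summary.
    """

    data: pd.DataFrame
    regions: RegionRegistry = field(default_factory=RegionRegistry)
    conditions: ConditionRegistry = field(default_factory=ConditionRegistry)
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data, self.report = _validate_fos_frame(self.data, self.regions, self.conditions)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.data["subject_id"].unique())

    def subjects_in(self, condition: str) -> tuple[str, ...]:
        cond = self.conditions.canonical(condition)
        sub = self.data.loc[self.data["condition"] == cond, "subject_id"]
        return tuple(sub.unique())

    def condition_matrix(self, condition: str, sex: str | None = None) -> pd.DataFrame:
        """Subjects x regions count matrix for one condition (NaN = missing).

        Columns follow registry order; rows follow subject order of first
        appearance. ``sex`` restricts to one sex instead of pooling.
        """
        cond = self.conditions.canonical(condition)
        sel = self.data[self.data["condition"] == cond]
        if sex is not None:
            if sex not in SEXES:
                raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
            sel = sel[sel["sex"] == sex]
        if sel.empty:
            raise ValueError(f"no subjects for condition {condition!r}" + (f" sex {sex!r}" if sex else ""))
        wide = sel.pivot(index="subject_id", columns="region", values="fos_count")
        wide = wide.reindex(columns=list(self.regions.regions))
        # preserve first-appearance subject order
        order = sel["subject_id"].drop_duplicates().tolist()
        return wide.loc[order]

    def to_csv(self, path: str | Path) -> Path:
        return write_fos_table(self, path)


def _validate_fos_frame(
    df: pd.DataFrame, regions: RegionRegistry, conditions: ConditionRegistry
) -> tuple[pd.DataFrame, dict]:
    missing = [c for c in FOS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"Fos table is missing column(s): {missing}")
    df = df.loc[:, list(FOS_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)

    for i, row in enumerate(df.itertuples(index=False)):
        if row.region not in regions:
            raise IntegrityError(
                f"row {i}: unknown region code {row.region!r} (subject {row.subject_id})"
            )
        if row.condition not in conditions:
            raise IntegrityError(
                f"row {i}: unknown condition code {row.condition!r} (subject {row.subject_id})"
            )
        if row.sex not in SEXES:
            raise IntegrityError(f"row {i}: sex must be F or M, got {row.sex!r}")
    df["region"] = [regions.canonical(r) for r in df["region"]]

    df["fos_count"] = pd.to_numeric(df["fos_count"], errors="raise")
    if (df["fos_count"] < 0).any():
        bad = df.loc[df["fos_count"] < 0].iloc[0]
        raise ValueError(
            f"negative fos_count for subject {bad['subject_id']} region {bad['region']}"
        )

    dup = df.duplicated(subset=["subject_id", "region"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate (subject, region) pair: ({bad['subject_id']}, {bad['region']})"
        )

    per_subj = df.groupby("subject_id")[["sex", "condition"]].nunique()
    multi = per_subj[(per_subj["sex"] > 1) | (per_subj["condition"] > 1)]
    if not multi.empty:
        raise IntegrityError(
            f"subject(s) with more than one sex/condition label: {list(multi.index)}"
        )

    subj_cond = df.drop_duplicates("subject_id").groupby("condition")["subject_id"].count()
    report = {
        "n_rows": int(len(df)),
        "n_subjects": int(df["subject_id"].nunique()),
        "subjects_per_condition": {
            c: int(subj_cond.get(c, 0)) for c in conditions.conditions
        },
        "regions_per_subject": {
            s: int(k) for s, k in df.groupby("subject_id")["region"].count().items()
        },
    }
    return df.reset_index(drop=True), report


def load_fos_table(
    path: str | Path,
    regions: RegionRegistry | None = None,
    conditions: ConditionRegistry | None = None,
) -> FosCountTable:
    """Load and validate a long-format per-subject Fos count CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return FosCountTable(
        df,
        regions=regions or RegionRegistry(),
        conditions=conditions or ConditionRegistry(),
    )


def write_fos_table(table: FosCountTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.data.copy()
    # deterministic row order: condition, subject, then registry region order
    out["_r"] = [table.regions.index(r) for r in out["region"]]
    out["_c"] = [table.conditions.index(c) for c in out["condition"]]
    out = out.sort_values(["_c", "subject_id", "_r"], kind="stable").drop(columns=["_r", "_c"])
    out.to_csv(path, index=False)
    return path


def load_behavior_table(
    path: str | Path,
    conditions: ConditionRegistry | None = None,
    allowed_doses: Iterable[float] = DEFAULT_LICL_DOSES,
) -> pd.DataFrame:
    """Load per-subject drinking/CTA records.

    Columns: subject_id, sex, condition, body_weight (g), intake_d1 (mL),
    intake_d2 (mL), licl_dose (mg/kg), estrous_state.
    """
    conditions = conditions or ConditionRegistry()
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"behavior table is missing column(s): {missing}")
    df = df.loc[:, list(BEHAVIOR_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise IntegrityError("duplicate subject_id in behavior table")
    for code in df["condition"]:
        conditions.canonical(code)
    if (df["body_weight"] <= 0).any():
        raise ValueError("body_weight must be > 0")
    if (df[["intake_d1", "intake_d2"]] < 0).to_numpy().any():
        raise ValueError("intakes must be >= 0")
    allowed = set(float(d) for d in allowed_doses)
    bad = set(df["licl_dose"].astype(float)) - allowed
    if bad:
        raise ValueError(f"licl_dose value(s) {sorted(bad)} not in allowed doses {sorted(allowed)}")
    bad_es = set(df["estrous_state"].fillna("NA")) - set(ESTROUS_STATES)
    if bad_es:
        raise ValueError(f"unknown estrous_state value(s): {sorted(bad_es)}")
    return df.reset_index(drop=True)


def load_usv_table(path: str | Path, conditions: ConditionRegistry | None = None) -> pd.DataFrame:
    """Load per-subject USV minute counts (wide format).

    Columns: subject_id, sex, condition, khz55_min_1..khz55_min_10,
    khz22_min_1..khz22_min_10 — call counts in each of the ten 1-minute
    blocks of the task-day recording window, per channel.
    """
    conditions = conditions or ConditionRegistry()
    df = pd.read_csv(path)
    cols55 = [f"khz55_min_{i}" for i in range(1, 11)]
    cols22 = [f"khz22_min_{i}" for i in range(1, 11)]
    missing = [c for c in ("subject_id", "sex", "condition", *cols55, *cols22) if c not in df.columns]
    if missing:
        raise SchemaError(f"USV table is missing column(s): {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise IntegrityError("duplicate subject_id in USV table")
    for code in df["condition"]:
        conditions.canonical(code)
    counts = df[cols55 + cols22]
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("USV counts must be non-negative")
    if not (arr == arr.astype(int)).all():
        raise ValueError("USV counts must be integers")
    return df.reset_index(drop=True)


def load_nausea_table(path: str | Path) -> pd.DataFrame:
    """Load long-format nausea observations.

    One row per scored 15-second block: subject_id, behavior
    (pica/LOB/ptosis), epoch_index 0..11 (one epoch every 5 minutes over
    1 hour), block_index 0..1 (two consecutive blocks per epoch), score 0..3.
    """
    df = pd.read_csv(path)
    missing = [c for c in NAUSEA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"nausea table is missing column(s): {missing}")
    df = df.loc[:, list(NAUSEA_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    bad_b = set(df["behavior"]) - set(NAUSEA_BEHAVIORS)
    if bad_b:
        raise ValueError(f"unknown nausea behavior(s): {sorted(bad_b)}")
    if not df["epoch_index"].between(0, 11).all():
        raise ValueError("epoch_index must be in 0..11")
    if not df["block_index"].isin((0, 1)).all():
        raise ValueError("block_index must be 0 or 1")
    if not df["score"].isin((0, 1, 2, 3)).all():
        raise ValueError("scores must be integers in 0..3")
    if df.duplicated(subset=["subject_id", "behavior", "epoch_index", "block_index"]).any():
        raise IntegrityError("duplicate (subject, behavior, epoch, block) observation")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# network serialization

NETWORK_FORMATS = ("edge_list", "adjacency", "graphml")


def _net_graph(net) -> nx.Graph:
    """Build an nx.Graph (all registry regions as nodes) from a network object."""
    g = nx.Graph()
    weight_attr = getattr(net, "weight_attr", "r")
    for i, region in enumerate(net.regions):
        g.add_node(region, order=i)
    for e in net.edges:
        g.add_edge(
            e.region_a,
            e.region_b,
            **{weight_attr: float(getattr(e, "r", getattr(e, "r_diff", 0.0)))},
            p=float(e.p),
            n=int(e.n),
            sign=e.sign,
        )
    for region in net.regions:
        g.nodes[region]["degree"] = int(g.degree(region))
        g.nodes[region]["isolate"] = g.degree(region) == 0
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            g.nodes[node]["component"] = cid
    return g


def write_network(net, path: str | Path, format: str = "edge_list") -> Path:
    """Serialize a thresholded or differential network.

    ``edge_list``: TSV with node_a, node_b, r (or r_diff), p, n, sign;
    ``adjacency``: symmetric CSV with non-significant pairs as 0;
    ``graphml``: full graph with node/edge attributes.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    weight_attr = getattr(net, "weight_attr", "r")
    if format == "edge_list":
        rows = []
        for e in sorted(net.edges, key=lambda e: (net.regions.index(e.region_a), net.regions.index(e.region_b))):
            rows.append(
                {
                    "node_a": e.region_a,
                    "node_b": e.region_b,
                    weight_attr: getattr(e, "r", getattr(e, "r_diff", None)),
                    "p": e.p,
                    "n": e.n,
                    "sign": e.sign,
                }
            )
        pd.DataFrame(rows, columns=["node_a", "node_b", weight_attr, "p", "n", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "adjacency":
        net.adjacency().to_csv(path)
    else:
        nx.write_graphml(_net_graph(net), path)
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def write_validation_report(report: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
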