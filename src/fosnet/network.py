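"""Significance-thresholded and differential c-Fos coactivation networks.

The coactivation analysis treats each brain region's per-subject Fos count
as a variable and asks which region pairs covary across animals within a
condition. For every pair the sample Pearson correlation r is tested with

    t = r * sqrt(n - 2) / sqrt(1 - r**2),  df = n - 2,

two-tailed. Pairs with p < alpha (default 0.05) keep their r as a signed
edge; all other correlations are set to 0. "Independent substructures" are
the connected components of the retained undirected graph, and regions
with no retained edges are isolates.

The differential (subtraction) network contrasts a task condition with a
control: every raw pairwise correlation is Fisher-transformed,

    z = 1/2 * ln((1 + r) / (1 - r)),

the control z is subtracted from the task z, the difference is
back-transformed to a correlation r_diff = tanh(z_task - z_control), and
r_diff is re-tested with the same t formula. Edges with p < alpha form the
differential graph. Note the re-test treats r_diff as if it were a single
correlation estimated from n subjects; the true sampling SD of a
difference of two independent z estimates is sqrt(2) larger, so the
procedure is anti-conservative under the null (documented in the methods
note).

Two entry points:

* functional: :func:`condition_correlation_matrix`,
  :func:`threshold_network`, :func:`differential_network`,
  :func:`network_summary`;
* model objects: :class:`CoactivationNetwork` and
  :class:`DifferentialCoactivationNetwork`, whose ``fit`` returns results
  with estimates, graphs, ``summary()`` tables and plotting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .registries import RegionRegistry

__all__ = [
    "fisher_z",
    "inverse_fisher",
    "r_to_t",
    "pearson_r_p",
    "correlation_matrix_from_array",
    "condition_correlation_matrix",
    "threshold_network",
    "differential_network",
    "network_summary",
    "CorrelationResult",
    "Edge",
    "ThresholdedNetwork",
    "DifferentialNetwork",
    "NetworkSummary",
    "CoactivationNetwork",
    "DifferentialCoactivationNetwork",
    "CoactivationResults",
    "DifferentialResults",
    "R_CLAMP",
]

R_CLAMP = 1.0 - 1e-12  # |r| clamped here before the Fisher transform
MIN_PAIR_N = 3

NRule = Literal["task_n", "control_n", "min_n"]


class ConstantRegionWarning(UserWarning):
    """A region had zero variance in a condition; its pairs are missing."""


# ---------------------------------------------------------------------------
# scalar building blocks


def fisher_z(r, clamp: bool = True):
    """Fisher variance-stabilizing transform z = arctanh(r) = 1/2 ln((1+r)/(1-r)).

    With ``clamp`` (default) |r| is limited to ``R_CLAMP`` so degenerate
    |r| = 1 pairs map to a large finite z instead of infinity.
    """
    r = np.asarray(r, dtype=float)
    if clamp:
        r = np.clip(r, -R_CLAMP, R_CLAMP)
    elif np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1 is outside the domain of the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Back-transform a Fisher z to a correlation: r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def r_to_t(r: float, n: int) -> tuple[float, int]:
    """t statistic and df for a correlation r estimated from n subjects.

    t = r * sqrt(n-2) / sqrt(1-r^2), df = n - 2. |r| = 1 yields an
    infinite t (p = 0 downstream).
    """
    if n < MIN_PAIR_N:
        raise ValueError(f"need n >= {MIN_PAIR_N} subjects, got {n}")
    df = int(n) - 2
    if abs(r) > 1:
        raise ValueError("|r| > 1 is not a correlation")
    if abs(r) == 1:
        return math.copysign(math.inf, r), df
    return r * math.sqrt(df) / math.sqrt(1.0 - r * r), df


def _t_two_tailed_p(t: float, df: int) -> float:
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r, two-tailed p and complete-case n for one region pair.

    Missing values are removed pairwise. Returns (nan, nan, n) — with a
    warning — when fewer than 3 complete pairs remain or either vector is
    constant, mirroring how such pairs are flagged missing in the matrix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < MIN_PAIR_N:
        warnings.warn(f"only {n} complete pairs (< {MIN_PAIR_N}); correlation undefined")
        return math.nan, math.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; correlation undefined", ConstantRegionWarning)
        return math.nan, math.nan, n
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    t, df = r_to_t(r, n)
    return r, _t_two_tailed_p(t, df), n


# ---------------------------------------------------------------------------
# correlation matrices


@dataclass
class CorrelationResult:
    """All-pairs correlation estimates for one condition.

    ``r``, ``p`` and ``n`` are symmetric region x region DataFrames in
    registry order; the diagonal is NaN (r of a region with itself is not
    a quantity of interest here). ``missing`` marks pairs with undefined
    correlations (constant region or n < 3).
    """

    condition: str
    regions: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    missing: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("r", "p", "n", "missing"):
            m = getattr(self, name)
            if list(m.index) != list(self.regions) or list(m.columns) != list(self.regions):
                raise ValueError(f"{name} matrix must be indexed by the region list, in order")
        offdiag = ~np.eye(len(self.regions), dtype=bool)
        rv = self.r.to_numpy()[offdiag]
        if np.nanmax(np.abs(rv), initial=0.0) > 1.0:
            raise ValueError("correlations must lie in [-1, 1]")

    def pairs(self):
        """Yield (region_a, region_b, r, p, n, missing) over the upper triangle."""
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                yield (
                    a,
                    b,
                    float(self.r.at[a, b]),
                    float(self.p.at[a, b]),
                    int(self.n.at[a, b]),
                    bool(self.missing.at[a, b]),
                )


def correlation_matrix_from_array(
    data: np.ndarray, regions: Sequence[str], condition: str = ""
) -> CorrelationResult:
    """All-pairs Pearson r/p/n from a subjects x regions array (NaN = missing)."""
    data = np.asarray(data, dtype=float)
    k = len(regions)
    if data.ndim != 2 or data.shape[1] != k:
        raise ValueError("data must be a subjects x regions 2-D array")
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    miss = np.zeros((k, k), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(k):
            for j in range(i + 1, k):
                rij, pij, nij = pearson_r_p(data[:, i], data[:, j])
                r[i, j] = r[j, i] = rij
                p[i, j] = p[j, i] = pij
                n[i, j] = n[j, i] = nij
                miss[i, j] = miss[j, i] = math.isnan(rij)
    if miss.any():
        bad = sorted(
            regions[i]
            for i in range(k)
            if all(miss[i, j] for j in range(k) if j != i)
        )
        if bad:
            warnings.warn(
                f"region(s) with undefined correlations in {condition or 'input'}: {bad}",
                ConstantRegionWarning,
            )
    idx = list(regions)
    return CorrelationResult(
        condition=condition,
        regions=tuple(regions),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        missing=pd.DataFrame(miss, index=idx, columns=idx),
    )


def condition_correlation_matrix(
    table,
    condition: str,
    pool_sexes: bool = True,
    sex: str | None = None,
) -> CorrelationResult:
    """All-pairs correlations among regions for one condition of a Fos table.

    Sexes are pooled by default (the design's choice for statistical
    power); pass ``pool_sexes=False`` with ``sex`` to fit one sex.
    """
    if not pool_sexes and sex is None:
        raise ValueError("pool_sexes=False requires sex='F' or 'M'")
    wide = table.condition_matrix(condition, sex=None if pool_sexes else sex)
    if len(wide) < MIN_PAIR_N:
        raise ValueError(
            f"condition {condition!r} has {len(wide)} subjects; need >= {MIN_PAIR_N}"
        )
    label = condition if pool_sexes else f"{condition}/{sex}"
    return correlation_matrix_from_array(wide.to_numpy(), tuple(wide.columns), condition=label)


# ---------------------------------------------------------------------------
# thresholded graphs


@dataclass(frozen=True)
class Edge:
    region_a: str
    region_b: str
    r: float
    p: float
    n: int
    sign: str  # "+" or "-"


@dataclass
class ThresholdedNetwork:
    """Signed graph of significant pairwise correlations for one condition."""

    condition: str
    regions: tuple[str, ...]
    alpha: float
    edges: tuple[Edge, ...]
    weight_attr: str = "r"

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.regions)
        for e in self.edges:
            g.add_edge(e.region_a, e.region_b, **{self.weight_attr: e.r}, p=e.p, n=e.n, sign=e.sign)
        return g

    @property
    def isolates(self) -> tuple[str, ...]:
        g = self.graph
        return tuple(r for r in self.regions if g.degree(r) == 0)

    @property
    def components(self) -> tuple[frozenset, ...]:
        """Maximal connected sets of non-isolated regions ("substructures")."""
        g = self.graph
        comps = [frozenset(c) for c in nx.connected_components(g) if len(c) > 1]
        return tuple(sorted(comps, key=lambda c: (-len(c), min(self.regions.index(x) for x in c))))

    def adjacency(self) -> pd.DataFrame:
        """Symmetric matrix with retained r values; all other pairs set to 0."""
        adj = pd.DataFrame(0.0, index=list(self.regions), columns=list(self.regions))
        for e in self.edges:
            adj.at[e.region_a, e.region_b] = e.r
            adj.at[e.region_b, e.region_a] = e.r
        return adj

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": e.region_a, "node_b": e.region_b, self.weight_attr: e.r, "p": e.p, "n": e.n, "sign": e.sign}
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", self.weight_attr, "p", "n", "sign"])


def threshold_network(cr: CorrelationResult, alpha: float = 0.05) -> ThresholdedNetwork:
    """Retain exactly the pairs with p < alpha as signed edges.

    Missing pairs (constant region, insufficient n) are never edges.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    edges = []
    for a, b, r, p, n, missing in cr.pairs():
        if missing or not p < alpha:
            continue
        edges.append(Edge(a, b, r, p, n, "+" if r >= 0 else "-"))
    return ThresholdedNetwork(
        condition=cr.condition, regions=cr.regions, alpha=alpha, edges=tuple(edges)
    )


# ---------------------------------------------------------------------------
# differential (subtraction) networks


@dataclass
class DifferentialNetwork:
    """Task-minus-control subtraction network.

    ``table`` holds one row per region pair with z_task, z_control,
    z_diff, r_diff, t, df, p and n_used; ``retained`` is the p < alpha
    graph over r_diff edges. Pairs missing in either input are excluded
    and listed in ``excluded_pairs``.
    """

    task_condition: str
    control_condition: str
    regions: tuple[str, ...]
    alpha: float
    n_rule: str
    table: pd.DataFrame
    excluded_pairs: tuple[tuple[str, str], ...]
    retained: ThresholdedNetwork

    # delegate graph conveniences to the retained network
    @property
    def edges(self):
        return self.retained.edges

    @property
    def weight_attr(self) -> str:
        return "r_diff"

    @property
    def graph(self) -> nx.Graph:
        return self.retained.graph

    @property
    def isolates(self):
        return self.retained.isolates

    @property
    def components(self):
        return self.retained.components

    def adjacency(self) -> pd.DataFrame:
        return self.retained.adjacency()

    def edge_frame(self) -> pd.DataFrame:
        return self.retained.edge_frame()


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_network(
    task: CorrelationResult,
    control: CorrelationResult,
    alpha: float = 0.05,
    n_rule: NRule = "task_n",
    subtract_thresholded: bool = False,
    bh_correct: bool = False,
) -> DifferentialNetwork:
    """Fisher z-subtraction network: task correlations minus control.

    By default the *raw* correlation matrices are subtracted; with
    ``subtract_thresholded`` non-significant (p >= alpha) input
    correlations are zeroed first, reproducing the alternative reading in
    which only the already-significant matrices are differenced.
    ``n_rule`` chooses the n given to the re-test: the task pair's
    complete-case n (default), the control's, or the smaller of the two.
    ``bh_correct`` applies Benjamini-Hochberg across pairs before
    thresholding (stricter than the per-pair rule).
    """
    if task.regions != control.regions:
        raise ValueError("task and control must cover the same regions in the same order")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_rule not in ("task_n", "control_n", "min_n"):
        raise ValueError(f"unknown n_rule {n_rule!r}")

    rows, excluded = [], []
    for (a, b, r_t, p_t, n_t, miss_t), (_, _, r_c, p_c, n_c, miss_c) in zip(
        task.pairs(), control.pairs()
    ):
        if miss_t or miss_c:
            excluded.append((a, b))
            continue
        if subtract_thresholded:
            r_t = r_t if p_t < alpha else 0.0
            r_c = r_c if p_c < alpha else 0.0
        n_used = {"task_n": n_t, "control_n": n_c, "min_n": min(n_t, n_c)}[n_rule]
        if n_used < MIN_PAIR_N:
            excluded.append((a, b))
            continue
        z_t = fisher_z(r_t)
        z_c = fisher_z(r_c)
        z_d = z_t - z_c
        r_d = inverse_fisher(z_d)
        t, df = r_to_t(r_d, n_used)
        p = _t_two_tailed_p(t, df)
        rows.append(
            {
                "region_a": a,
                "region_b": b,
                "r_task": r_t,
                "r_control": r_c,
                "z_task": z_t,
                "z_control": z_c,
                "z_diff": z_d,
                "r_diff": r_d,
                "t": t,
                "df": df,
                "p": p,
                "n_used": n_used,
            }
        )
    cols = [
        "region_a", "region_b", "r_task", "r_control", "z_task", "z_control",
        "z_diff", "r_diff", "t", "df", "p", "n_used",
    ]
    tab = pd.DataFrame(rows, columns=cols)
    p_for_threshold = tab["p"].to_numpy()
    if bh_correct and len(tab):
        p_for_threshold = _bh_adjust(p_for_threshold)
        tab["p_bh"] = p_for_threshold
    edges = tuple(
        Edge(row.region_a, row.region_b, row.r_diff, row.p, int(row.n_used),
             "+" if row.r_diff >= 0 else "-")
        for row, p_thr in zip(tab.itertuples(index=False), p_for_threshold)
        if p_thr < alpha
    )
    label = f"{task.condition}-{control.condition}"
    retained = ThresholdedNetwork(
        condition=label, regions=task.regions, alpha=alpha, edges=edges, weight_attr="r_diff"
    )
    return DifferentialNetwork(
        task_condition=task.condition,
        control_condition=control.condition,
        regions=task.regions,
        alpha=alpha,
        n_rule=n_rule,
        table=tab,
        excluded_pairs=tuple(excluded),
        retained=retained,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class NetworkSummary:
    """Degree-based description of one retained graph."""

    condition: str
    degrees: dict[str, int]
    ranked: tuple[str, ...]  # by degree desc, ties broken by registry order
    n_edges: int
    n_components: int
    isolates: tuple[str, ...]
    betweenness: dict[str, float] | None = None

    @property
    def all_regions_involved(self) -> bool:
        return len(self.isolates) == 0

    @property
    def hub(self) -> str | None:
        """Top-ranked region, or None for an empty network."""
        if self.n_edges == 0:
            return None
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r,
                "degree": self.degrees[r],
                "rank": self.ranked.index(r) + 1,
                "isolate": r in self.isolates,
            }
            for r in self.degrees
        ]
        df = pd.DataFrame(rows)
        if self.betweenness is not None:
            df["betweenness"] = [self.betweenness[r] for r in df["region"]]
        return df


def network_summary(
    net: ThresholdedNetwork | DifferentialNetwork, betweenness: bool = False
) -> NetworkSummary:
    """Per-node degree, degree ranking, components and isolates."""
    g = net.graph
    regions = net.regions
    degrees = {r: int(g.degree(r)) for r in regions}
    ranked = tuple(sorted(regions, key=lambda r: (-degrees[r], regions.index(r))))
    bt = None
    if betweenness:
        bt = {r: float(v) for r, v in nx.betweenness_centrality(g).items()}
    return NetworkSummary(
        condition=getattr(net, "condition", getattr(net, "task_condition", "")),
        degrees=degrees,
        ranked=ranked,
        n_edges=len(net.edges),
        n_components=len(net.components),
        isolates=net.isolates,
        betweenness=bt,
    )


# ---------------------------------------------------------------------------
# model / results objects


class CoactivationNetwork:
    """Coactivation-network model for one condition of a Fos count table.

    Parameters
    ----------
    table : FosCountTable
        Validated per-subject counts (see :mod:`fosnet.io`).
    condition : str
        Condition code whose subjects define the correlation sample.
    pool_sexes : bool
        Pool F and M subjects (the default, for power); with
        ``pool_sexes=False`` supply ``sex``.

    ``fit(alpha)`` estimates all pairwise correlations and thresholds
    them, returning :class:`CoactivationResults`.
    """

    def __init__(self, table, condition: str, pool_sexes: bool = True, sex: str | None = None):
        self.table = table
        self.condition = table.conditions.canonical(condition)
        self.pool_sexes = pool_sexes
        self.sex = sex

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, condition: str, **kwargs) -> "CoactivationNetwork":
        from .io import FosCountTable

        return cls(FosCountTable(data), condition, **kwargs)

    def fit(self, alpha: float = 0.05) -> "CoactivationResults":
        cr = condition_correlation_matrix(
            self.table, self.condition, pool_sexes=self.pool_sexes, sex=self.sex
        )
        return CoactivationResults(self, cr, threshold_network(cr, alpha=alpha))


@dataclass
class CoactivationResults:
    """Fitted coactivation network: estimates, retained graph, summaries."""

    model: CoactivationNetwork
    correlations: CorrelationResult
    network: ThresholdedNetwork

    @property
    def alpha(self) -> float:
        return self.network.alpha

    def degree_summary(self, betweenness: bool = False) -> NetworkSummary:
        return network_summary(self.network, betweenness=betweenness)

    def summary(self) -> str:
        return _render_summary(
            title=f"Coactivation network [{self.correlations.condition}]",
            net=self.network,
            extra={"alpha": self.network.alpha},
        )

    def plot(self, ax=None):
        return _plot_network(self.network, ax=ax)

    def save(self, path, format: str = "edge_list"):
        from .io import write_network

        return write_network(self.network, path, format=format)


class DifferentialCoactivationNetwork:
    """Task-minus-control subtraction model over a Fos count table."""

    def __init__(
        self,
        table,
        task: str,
        control: str,
        pool_sexes: bool = True,
        sex: str | None = None,
    ):
        self.table = table
        self.task = table.conditions.canonical(task)
        self.control = table.conditions.canonical(control)
        self.pool_sexes = pool_sexes
        self.sex = sex

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, task: str, control: str, **kwargs):
        from .io import FosCountTable

        return cls(FosCountTable(data), task, control, **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        n_rule: NRule = "task_n",
        subtract_thresholded: bool = False,
        bh_correct: bool = False,
    ) -> "DifferentialResults":
        kw = dict(pool_sexes=self.pool_sexes, sex=self.sex)
        cr_task = condition_correlation_matrix(self.table, self.task, **kw)
        cr_control = condition_correlation_matrix(self.table, self.control, **kw)
        diff = differential_network(
            cr_task,
            cr_control,
            alpha=alpha,
            n_rule=n_rule,
            subtract_thresholded=subtract_thresholded,
            bh_correct=bh_correct,
        )
        return DifferentialResults(self, cr_task, cr_control, diff)


@dataclass
class DifferentialResults:
    """Fitted subtraction network with the full per-pair test table."""

    model: DifferentialCoactivationNetwork
    task_correlations: CorrelationResult
    control_correlations: CorrelationResult
    network: DifferentialNetwork

    @property
    def table(self) -> pd.DataFrame:
        return self.network.table

    def degree_summary(self, betweenness: bool = False) -> NetworkSummary:
        return network_summary(self.network, betweenness=betweenness)

    def summary(self) -> str:
        return _render_summary(
            title=(
                f"Differential coactivation network "
                f"[{self.network.task_condition} - {self.network.control_condition}]"
            ),
            net=self.network.retained,
            extra={
                "alpha": self.network.alpha,
                "n rule": self.network.n_rule,
                "excluded pairs": len(self.network.excluded_pairs),
            },
        )

    def plot(self, ax=None):
        return _plot_network(self.network.retained, ax=ax)

    def save(self, path, format: str = "edge_list"):
        from .io import write_network

        return write_network(self.network, path, format=format)


def _render_summary(title: str, net: ThresholdedNetwork, extra: dict) -> str:
    s = network_summary(net)
    width = 64
    lines = [title.center(width), "=" * width]
    for k, v in extra.items():
        lines.append(f"{k:<24}{v}")
    lines.append(f"{'edges':<24}{s.n_edges}")
    lines.append(f"{'components':<24}{s.n_components}")
    lines.append(f"{'isolates':<24}{', '.join(s.isolates) or '(none)'}")
    lines.append("-" * width)
    lines.append(f"{'pair':<18}{net.weight_attr:>10}{'p':>12}{'n':>6}  sign")
    for e in net.edges:
        lines.append(
            f"{e.region_a + '-' + e.region_b:<18}{e.r:>10.3f}{e.p:>12.4g}{e.n:>6d}  {e.sign}"
        )
    if not net.edges:
        lines.append("(no retained edges)")
    lines.append("-" * width)
    lines.append("degree ranking: " + ", ".join(f"{r}({s.degrees[r]})" for r in s.ranked))
    return "\n".join(lines)


def _plot_network(net: ThresholdedNetwork, ax=None):
    """Draw the retained graph: circular layout, positive edges black,
    negative magenta, isolates grey."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = net.graph
    pos = nx.circular_layout(g)
    colors = ["0.6" if g.degree(r) == 0 else "tab:red" for r in g.nodes]
    edge_colors = ["black" if d["sign"] == "+" else "magenta" for _, _, d in g.edges(data=True)]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=600)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    nx.draw_networkx_edges(g, pos, ax=ax, edge_color=edge_colors)
    ax.set_title(net.condition)
    ax.set_axis_off()
    return ax
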