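"""Analysis of trajectories and final states.

Bond-count kinetics, cluster decomposition and morphology, tail-window
box-whisker statistics, equilibrium and changepoint detection, and
affinity/copy-number grid sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sps
from scipy.sparse.csgraph import connected_components as _cc

from .engine import TS_COLUMNS, SystemState, count_bond_types, run
from .model import RULE_NAMES, SimulationConfig, Species

__all__ = [
    "BondCounts",
    "ClusterReport",
    "GridSpec",
    "count_bonds",
    "connected_components",
    "classify_morphology",
    "classify_clusters",
    "tail_statistics",
    "detect_equilibrium",
    "detect_changepoint",
    "sweep_grid",
    "equilibrium_tail_means",
    "heatmap_table",
    "render_heatmap",
]

#: map rule name -> time-series column
RULE_COLUMNS = {
    "trans_ctla4_b7": "n_trans_ctla4_b7",
    "trans_pd1_pdl1": "n_trans_pd1_pdl1",
    "dimer_b7": "n_dimer_b7",
    "cis_b7_pdl1": "n_cis_b7_pdl1",
}


class BondCounts(NamedTuple):
    """Live-bond tally at one instant."""

    time_ns: float
    n_trans_ctla4_b7: int
    n_trans_pd1_pdl1: int
    n_dimer_b7: int
    n_cis_b7_pdl1: int


@dataclass
class ClusterReport:
    """One connected component of the bond graph."""

    members: np.ndarray
    size: int
    bond_counts: dict
    morphology: str | None = None
    gyration_eigenvalues: tuple[float, float] | None = None


def count_bonds(state: SystemState) -> BondCounts:
    """Exact tally of live bonds by rule type."""
    c = count_bond_types(state)
    return BondCounts(state.t, int(c[0]), int(c[1]), int(c[2]), int(c[3]))


def _bond_edges(state: SystemState):
    rows, cols, rules = [], [], []
    for i in range(state.n_mol):
        for s in range(int(state.library.s_cnt[state.sp[i]])):
            j = int(state.bp_mol[i, s])
            if j > i:
                rows.append(i)
                cols.append(j)
                rules.append(int(state.b_rule[i, s]))
    return rows, cols, rules


def connected_components(state: SystemState) -> list[ClusterReport]:
    """Partition molecules by live-bond connectivity, largest first.

    Uses scipy's sparse graph machinery (independent of the engine's
    incremental BFS bookkeeping).
    """
    n = state.n_mol
    rows, cols, rules = _bond_edges(state)
    graph = sps.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    ncomp, labels = _cc(graph, directed=False)
    reports = []
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        counts = {name: 0 for name in RULE_NAMES}
        reports.append(ClusterReport(members, len(members), counts))
    by_label = {c: r for c, r in enumerate(reports)}
    for i, j, r in zip(rows, cols, rules):
        by_label[labels[i]].bond_counts[RULE_NAMES[r]] += 1
    reports.sort(key=lambda r: -r.size)
    return reports


def _unwrap_members(state: SystemState, members: np.ndarray) -> np.ndarray:
    """Member anchor coordinates unwrapped by minimum image along bonds."""
    cfg = state.config
    members = np.asarray(members)
    idx = {int(m): k for k, m in enumerate(members)}
    pos = np.zeros((len(members), 2))
    seen = np.zeros(len(members), dtype=bool)
    for start in range(len(members)):
        if seen[start]:
            continue
        pos[start] = (state.x[members[start]], state.y[members[start]])
        seen[start] = True
        queue = [int(members[start])]
        while queue:
            u = queue.pop()
            ku = idx[u]
            for s in range(int(state.library.s_cnt[state.sp[u]])):
                v = int(state.bp_mol[u, s])
                if v < 0 or v not in idx or seen[idx[v]]:
                    continue
                kv = idx[v]
                dx = state.x[v] - state.x[u]
                dy = state.y[v] - state.y[u]
                dx -= cfg.box_x * np.round(dx / cfg.box_x)
                dy -= cfg.box_y * np.round(dy / cfg.box_y)
                pos[kv] = pos[ku] + (dx, dy)
                seen[kv] = True
                queue.append(v)
    return pos


def _gyration_eigenvalues(pos: np.ndarray) -> tuple[float, float]:
    centered = pos - pos.mean(axis=0)
    gyr = centered.T @ centered / len(pos)
    ev = np.linalg.eigvalsh(gyr)
    return float(ev[1]), float(ev[0])  # (lambda1 >= lambda2)


def _is_simple_path(state: SystemState, members: np.ndarray) -> bool:
    mset = set(int(m) for m in members)
    deg = {m: 0 for m in mset}
    edges = 0
    for u in mset:
        for s in range(int(state.library.s_cnt[state.sp[u]])):
            v = int(state.bp_mol[u, s])
            if v >= 0 and v in mset:
                deg[u] += 1
                if v > u:
                    edges += 1
    if edges != len(mset) - 1:  # acyclic and connected
        return False
    ends = sum(1 for d in deg.values() if d == 1)
    return ends == 2 and all(d <= 2 for d in deg.values())


def classify_morphology(
    cluster: ClusterReport | Sequence[int],
    state: SystemState,
    linear_ratio: float = 0.2,
    planar_min_size: int = 6,
) -> str:
    """Label a cluster MONOMER / DIMER / LINEAR / PLANAR / OTHER.

    LINEAR requires the molecule-level bond graph to be a simple path
    and the 2-D gyration-tensor anisotropy lambda2/lambda1 < ``linear_ratio``;
    PLANAR requires size >= ``planar_min_size`` and ratio >= ``linear_ratio``.
    The label is invariant under global translation, rotation and
    periodic re-wrapping (coordinates are unwrapped along bonds first).
    """
    members = cluster.members if isinstance(cluster, ClusterReport) else np.asarray(cluster)
    size = len(members)
    if size == 1:
        label, ev = "MONOMER", (0.0, 0.0)
    elif size == 2:
        label, ev = "DIMER", (0.0, 0.0)
    else:
        pos = _unwrap_members(state, members)
        lam1, lam2 = _gyration_eigenvalues(pos)
        ratio = lam2 / lam1 if lam1 > 0 else 1.0
        ev = (lam1, lam2)
        if _is_simple_path(state, members) and ratio < linear_ratio:
            label = "LINEAR"
        elif size >= planar_min_size and ratio >= linear_ratio:
            label = "PLANAR"
        else:
            label = "OTHER"
    if isinstance(cluster, ClusterReport):
        cluster.morphology = label
        cluster.gyration_eigenvalues = ev
    return label


def classify_clusters(state: SystemState, **kw) -> list[ClusterReport]:
    """Connected components with morphology labels attached."""
    reports = connected_components(state)
    for r in reports:
        classify_morphology(r, state, **kw)
    return reports


def tail_statistics(ts: pd.DataFrame, window_ns: float) -> pd.DataFrame:
    """Box-whisker summary of each bond count over the trailing window.

    Returns one row per bond type with mean, median, quartiles, IQR and
    the 1.5*IQR whiskers (most extreme samples within the fences).
    Raises ``ValueError`` when the window exceeds the series duration.
    """
    t = ts["time_ns"].to_numpy()
    duration = t[-1] - t[0]
    if window_ns > duration:
        raise ValueError(
            f"tail window {window_ns} ns longer than series duration {duration} ns"
        )
    tail = ts[t >= t[-1] - window_ns]
    rows = []
    for col in TS_COLUMNS[1:]:
        v = tail[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        rows.append(
            {
                "bond_type": col,
                "mean": v.mean(),
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "whisker_low": inside.min() if len(inside) else np.nan,
                "whisker_high": inside.max() if len(inside) else np.nan,
                "n_samples": len(v),
            }
        )
    return pd.DataFrame(rows).set_index("bond_type")


def detect_equilibrium(
    ts: pd.DataFrame, tolerance: float = 0.05, window: int = 10
) -> float | None:
    """Earliest time after which every bond count has stopped drifting.

    The series is cut into consecutive blocks of ``window`` samples; the
    earliest block from which every later block-to-block relative change
    of every bond count stays below ``tolerance`` marks equilibrium.
    Returns the block's start time in ns, or None.
    """
    if len(ts) < 2 * window:
        raise ValueError("need at least two windows of samples")
    t = ts["time_ns"].to_numpy()
    counts = ts[list(TS_COLUMNS[1:])].to_numpy(dtype=float)
    nblocks = len(ts) // window
    means = np.array(
        [counts[b * window : (b + 1) * window].mean(axis=0) for b in range(nblocks)]
    )
    denom = np.maximum(np.abs(means[:-1]), 1.0)
    rel = np.abs(np.diff(means, axis=0)) / denom  # (nblocks-1, 4)
    ok = (rel < tolerance).all(axis=1)
    for b in range(len(ok)):
        if ok[b:].all():
            return float(t[b * window])
    return None


def _segment_sse(t, y, i0, i1):
    # SSE of the least-squares line through samples [i0, i1)
    tt = t[i0:i1]
    yy = y[i0:i1]
    if len(tt) < 2:
        return 0.0
    tm = tt.mean()
    ym = yy.mean()
    stt = np.sum((tt - tm) ** 2)
    sty = np.sum((tt - tm) * (yy - ym))
    sse = np.sum((yy - ym) ** 2)
    if stt > 0:
        sse -= sty * sty / stt
    return max(sse, 0.0)


def detect_changepoint(
    ts: pd.DataFrame, bond_type: str, min_improvement: float = 0.5
) -> float | None:
    """Breakpoint of the best two-segment piecewise-linear fit.

    Scans all interior breakpoints, keeps the one maximizing the SSE
    reduction over a single-line fit, and returns its time when the
    relative improvement ``1 - sse2/sse1`` exceeds ``min_improvement``
    (None otherwise, e.g. for a series that is already linear).
    """
    col = RULE_COLUMNS.get(bond_type, bond_type)
    if len(ts) < 20:
        raise ValueError("need at least 20 samples")
    t = ts["time_ns"].to_numpy(dtype=float)
    y = ts[col].to_numpy(dtype=float)
    sse1 = _segment_sse(t, y, 0, len(t))
    if sse1 <= 1e-12 * max(1.0, float(np.sum(y * y))):
        return None
    best_k, best_sse = None, np.inf
    for k in range(2, len(t) - 2):
        sse2 = _segment_sse(t, y, 0, k) + _segment_sse(t, y, k, len(t))
        if sse2 < best_sse:
            best_sse = sse2
            best_k = k
    if best_k is None:
        return None
    improvement = 1.0 - best_sse / sse1
    if improvement < min_improvement:
        return None
    return float(t[best_k])


def equilibrium_tail_means(ts: pd.DataFrame, tail_fraction: float = 0.2) -> dict:
    """Mean of each bond count over the trailing fraction of the run."""
    t = ts["time_ns"].to_numpy()
    t_cut = t[-1] - tail_fraction * (t[-1] - t[0])
    tail = ts[t >= t_cut]
    return {col: float(tail[col].mean()) for col in TS_COLUMNS[1:]}


@dataclass(frozen=True)
class GridSpec:
    """Axes of a parameter sweep.

    Each axis is ``(name, values)`` where name is either
    ``"affinity:<rule>"`` (kT) or ``"copies:<SPECIES>"``.
    """

    axes: tuple[tuple[str, tuple], ...]

    def apply(self, config: SimulationConfig, values: Sequence) -> SimulationConfig:
        affinities = dict(config.affinities)
        copies = dict(config.copy_numbers)
        for (name, _vals), v in zip(self.axes, values):
            kind, _, key = name.partition(":")
            if kind == "affinity":
                if key not in RULE_NAMES:
                    raise KeyError(f"unknown rule {key!r}")
                affinities[key] = float(v)
            elif kind == "copies":
                Species[key]  # validates
                copies[key] = int(v)
            else:
                raise KeyError(f"unknown axis kind {kind!r}")
        return config.replace(affinities=affinities, copy_numbers=copies)


def sweep_grid(
    base_config: SimulationConfig,
    grid_spec: GridSpec,
    seeds: Iterable[int] = (0, 1, 2),
    tail_fraction: float = 0.2,
) -> pd.DataFrame:
    """One simulation per (grid cell, seed); tidy long-format result.

    Per cell and seed the equilibrium-tail mean of each bond count is
    recorded (one row per cell x seed x bond type).  A failing cell is
    annotated in the ``error`` column and the sweep continues.
    """
    seeds = list(seeds)
    mesh = [()]
    for _name, values in grid_spec.axes:
        mesh = [m + (v,) for m in mesh for v in values]
    records = []
    for values in mesh:
        for seed in seeds:
            base = {
                name: v for (name, _), v in zip(grid_spec.axes, values)
            }
            try:
                cfg = grid_spec.apply(base_config, values)
                result = run(cfg, seed=seed)
                means = equilibrium_tail_means(result.time_series, tail_fraction)
                for rule, col in RULE_COLUMNS.items():
                    records.append(
                        {**base, "seed": seed, "bond_type": rule,
                         "mean_count": means[col], "error": ""}
                    )
            except Exception as exc:  # annotate and continue
                for rule in RULE_NAMES:
                    records.append(
                        {**base, "seed": seed, "bond_type": rule,
                         "mean_count": np.nan, "error": str(exc)}
                    )
    return pd.DataFrame(records)


def render_heatmap(sweep: pd.DataFrame, bond_type: str, path) -> None:
    """Render a sweep's cell means for one bond type as a heat-map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = heatmap_table(sweep, bond_type)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(table.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(table.shape[1]), [f"{v:g}" for v in table.columns])
    ax.set_yticks(range(table.shape[0]), [f"{v:g}" for v in table.index])
    ax.set_xlabel(table.columns.name)
    ax.set_ylabel(table.index.name)
    ax.set_title(bond_type)
    fig.colorbar(im, ax=ax, label="mean bond count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap_table(sweep: pd.DataFrame, bond_type: str) -> pd.DataFrame:
    """Pivot a sweep result into a 2-D cell-mean table for one bond type."""
    axes = [c for c in sweep.columns if c not in
            ("seed", "bond_type", "mean_count", "error")]
    if len(axes) != 2:
        raise ValueError("heatmap_table needs a two-axis sweep")
    sub = sweep[sweep["bond_type"] == bond_type]
    return sub.pivot_table(
        index=axes[1], columns=axes[0], values="mean_count", aggfunc="mean"
    )
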