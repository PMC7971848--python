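"""Diffusion-reaction engine: system state, per-step operations, full runs.

Each time step executes two scenarios in a fixed, documented order:

1. *diffusion* — every mobile unit (an isolated molecule, or a whole
   component whose bonds are all trans) is visited in random order and
   receives a Gaussian translation (per-axis variance ``2*D_t*dt``) and a
   Gaussian rotation about its centroid (standard deviation ``D_r*dt``);
   moves that violate excluded volume are rejected and the unit stays put
   for the step.  Components holding at least one same-surface bond
   (B7-B7 homodimer or B7/PD-L1 cis) do not diffuse at all.
2. *reaction* — every live bond dissociates independently with its
   rule's ``p_off``; then all eligible site pairs within the association
   cutoff are collected, shuffled, and fire with probability ``p_on``
   first-come-first-served.  Sites freed in this very step become
   eligible again the next step, which is when geminate recombination of
   a still-close pair occurs.

Runs are bit-reproducible from ``(config, seed)``.  The fused
:func:`run` path and the single-step operation wrappers (used by tests)
consume the random streams differently — each public operation reseeds
the kernel RNG from a deterministic per-state draw counter — but both
are individually deterministic.
"""

from __future__ import annotations

import copy as _copy
import time as _time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels as _k
from .model import (
    IMMOBILIZING_RULES,
    RULE_NAMES,
    ConfigError,
    PackingError,
    SimulationConfig,
    Species,
    SpeciesLibrary,
    Surface,
    build_interaction_table,
    build_species_library,
    config_hash,
    validate_config,
)

__all__ = [
    "SystemState",
    "RunResult",
    "TS_COLUMNS",
    "initialize_system",
    "make_state",
    "diffuse",
    "find_candidate_pairs",
    "attempt_associations",
    "attempt_dissociations",
    "update_mobility",
    "step",
    "run",
    "bond_list",
    "count_bond_types",
    "group_coordinates",
]

#: canonical time-series column order
TS_COLUMNS = (
    "time_ns",
    "n_trans_ctla4_b7",
    "n_trans_pd1_pdl1",
    "n_dimer_b7",
    "n_cis_b7_pdl1",
)

MOBILITY_NAMES = {0: "MONOMER", 1: "TRANS_COMPLEX", 2: "IMMOBILE"}

# one-directional probing table: each rule is searched from exactly one
# of its site classes so every candidate pair is generated once
_PROBE_RULE = np.full((5, 5), -1, dtype=np.int64)
_PROBE_RULE[0, 1] = 0  # CTLA4_TRANS -> B7_TRANS
_PROBE_RULE[3, 4] = 1  # PD1_TRANS -> PDL1_SIDE
_PROBE_RULE[2, 2] = 2  # B7_SIDE <-> B7_SIDE (deduped on molecule order)
_PROBE_RULE[2, 4] = 3  # B7_SIDE -> PDL1_SIDE
_PROBE_ANY = np.ascontiguousarray((_PROBE_RULE >= 0).any(axis=1))

_RULE_IMMOB = np.zeros(4, dtype=np.bool_)
_RULE_IMMOB[list(IMMOBILIZING_RULES)] = True

_EMPTY_TS = np.empty((0, 5), dtype=np.float64)

_PLACEMENT_ATTEMPTS = 2000
_NORM_CHUNK_STEPS = 512
_VLIST_SKIN = 6.0  # nm; Verlet lists valid while total drift < skin


@dataclass
class SystemState:
    """All molecule poses, the bond graph, and bookkeeping for one run."""

    config: SimulationConfig
    library: SpeciesLibrary
    seed: int
    n_mol: int
    sp: np.ndarray
    surf: np.ndarray
    x: np.ndarray
    y: np.ndarray
    th: np.ndarray  # radians
    bp_mol: np.ndarray
    bp_site: np.ndarray
    b_rule: np.ndarray
    b_time: np.ndarray
    b_break: np.ndarray
    comp: np.ndarray
    mob: np.ndarray
    grp_x: np.ndarray
    grp_y: np.ndarray
    grp_z: np.ndarray
    cell_of: np.ndarray
    cell_next: np.ndarray
    cell_head: np.ndarray
    ncx: int
    ncy: int
    t: float = 0.0
    ncomp: int = 0
    _scratch: dict = field(default_factory=dict, repr=False)
    _draw_counter: int = 0
    _gstep: int = 0
    _norm_buf: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _norm_idx: int = 0
    _norm_rng: np.random.Generator | None = field(default=None, repr=False)

    # -- convenience views ------------------------------------------------
    def molecules(self) -> pd.DataFrame:
        """Per-molecule table (species, surface, pose, component, mobility)."""
        return pd.DataFrame(
            {
                "molecule": np.arange(self.n_mol),
                "species": [Species(s).name for s in self.sp],
                "surface": [Surface(s).name for s in self.surf],
                "x": self.x.copy(),
                "y": self.y.copy(),
                "theta_deg": np.degrees(self.th),
                "component": self.comp.copy(),
                "mobility": [MOBILITY_NAMES[m] for m in self.mob],
            }
        )

    def species_counts(self) -> dict[str, int]:
        return {s.name: int(np.sum(self.sp == s)) for s in Species}

    def clone(self) -> "SystemState":
        new = _copy.copy(self)
        for name in (
            "x", "y", "th", "bp_mol", "bp_site", "b_rule", "b_time", "b_break",
            "comp", "mob", "grp_x", "grp_y", "grp_z",
            "cell_of", "cell_next", "cell_head",
        ):
            setattr(new, name, getattr(self, name).copy())
        new._scratch = _alloc_scratch(self.n_mol, self.ncx * self.ncy)
        new._norm_buf = self._norm_buf.copy()
        new._norm_rng = _copy.deepcopy(self._norm_rng)
        return new

    def next_kernel_seed(self) -> int:
        """Deterministic per-operation seed derived from (seed, counter)."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(self._draw_counter,))
        self._draw_counter += 1
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunResult:
    """Completed trajectory: final state, time series, provenance."""

    config: SimulationConfig
    seed: int
    config_hash: str
    time_series: pd.DataFrame
    final_state: SystemState
    snapshots: list = field(default_factory=list)
    runtime_s: float = 0.0


def _alloc_scratch(n: int, ncells: int) -> dict:
    n = max(n, 1)
    return {
        "comp_start": np.zeros(n + 1, dtype=np.int64),
        "comp_items": np.zeros(n, dtype=np.int64),
        "comp_mob": np.zeros(n, dtype=np.int64),
        "mobile_list": np.zeros(n, dtype=np.int64),
        "queue": np.zeros(n, dtype=np.int64),
        "cand": np.zeros((8 * n + 8, 5), dtype=np.int64),
        "frozen": np.zeros((n, 2), dtype=np.bool_),
        "frozen_list": np.zeros(2 * n + 2, dtype=np.int64),
        "mgx": np.zeros(64, dtype=np.float64),
        "mgy": np.zeros(64, dtype=np.float64),
        "relx": np.zeros(n, dtype=np.float64),
        "rely": np.zeros(n, dtype=np.float64),
        "nxa": np.zeros(n, dtype=np.float64),
        "nya": np.zeros(n, dtype=np.float64),
        "ntha": np.zeros(n, dtype=np.float64),
        "active": np.zeros(ncells, dtype=np.uint8),
        "active_list": np.zeros(ncells, dtype=np.int64),
        "wake_list": np.zeros(2 * n + 4, dtype=np.int64),
        "counters": np.zeros(4, dtype=np.int64),
        "vstart": np.zeros(n + 1, dtype=np.int64),
        "vitems": np.zeros(256 * n + 64, dtype=np.int64),
        "vref_x": np.zeros(n, dtype=np.float64),
        "vref_y": np.zeros(n, dtype=np.float64),
        "vref_th": np.zeros(n, dtype=np.float64),
        "vmax": np.zeros(1, dtype=np.float64),
    }


def _grid_shape(cfg: SimulationConfig, lib: SpeciesLibrary) -> tuple[int, int]:
    # the cell edge must cover both the interaction reach (3x3 scans are
    # exhaustive) and the Verlet build radius; a coarse grid also keeps
    # the head array cache-friendly
    reach = lib.interaction_reach + cfg.cutoff
    cell = max(2.0 * reach, reach + _VLIST_SKIN)
    ncx = max(1, int(cfg.box_x // cell))
    ncy = max(1, int(cfg.box_y // cell))
    return ncx, ncy


def _ev_thresholds(lib: SpeciesLibrary, gap: float) -> np.ndarray:
    """Species-pair anchor-distance^2 prefilter for hard-core overlap.

    ``thr2[a, b] < 0`` means species a and b can never clash (e.g. they
    live on opposite surfaces and their bodies do not reach the other's
    z range); otherwise two molecules closer (anchor-anchor, lateral)
    than sqrt(thr2) may overlap and need the full group-pair check.
    """
    thr2 = np.full((4, 4), -1.0)
    geo = {}
    for s in Species:
        spec = lib[s]
        off = spec.group_array()
        rad = spec.radii()
        zg = off[:, 2] if spec.surface == Surface.APC else gap - off[:, 2]
        lat = np.hypot(off[:, 0], off[:, 1])
        geo[s] = (lat, rad, zg)
    for a in Species:
        lat_a, rad_a, z_a = geo[a]
        for b in Species:
            lat_b, rad_b, z_b = geo[b]
            best = -1.0
            for gi in range(len(rad_a)):
                if rad_a[gi] <= 0:
                    continue
                for gj in range(len(rad_b)):
                    if rad_b[gj] <= 0:
                        continue
                    rr = rad_a[gi] + rad_b[gj]
                    dz = abs(z_a[gi] - z_b[gj])
                    if dz >= rr:
                        continue
                    reach = lat_a[gi] + lat_b[gj] + float(np.sqrt(rr * rr - dz * dz))
                    best = max(best, reach * reach)
            thr2[a, b] = best
    return thr2


def _species_vector(cfg: SimulationConfig, lib: SpeciesLibrary):
    sp = []
    surf = []
    for s in Species:
        n = cfg.copies(s)
        sp.extend([int(s)] * n)
        surf.extend([int(lib[s].surface)] * n)
    return (
        np.array(sp, dtype=np.int64),
        np.array(surf, dtype=np.int64),
    )


def _empty_state(cfg: SimulationConfig, lib: SpeciesLibrary, seed: int) -> SystemState:
    sp, surf = _species_vector(cfg, lib)
    n = len(sp)
    ncx, ncy = _grid_shape(cfg, lib)
    from .model import MAX_GROUPS

    grp_z = np.zeros((n, MAX_GROUPS))
    for i in range(n):
        for g in range(int(lib.g_cnt[sp[i]])):
            oz = lib.g_off[sp[i], g, 2]
            grp_z[i, g] = oz if surf[i] == 1 else cfg.gap - oz
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(0xD1FF,)))
    )
    return SystemState(
        config=cfg,
        library=lib,
        seed=seed,
        n_mol=n,
        sp=sp,
        surf=surf,
        x=np.zeros(n),
        y=np.zeros(n),
        th=np.zeros(n),
        bp_mol=np.full((n, 2), -1, dtype=np.int64),
        bp_site=np.full((n, 2), -1, dtype=np.int64),
        b_rule=np.full((n, 2), -1, dtype=np.int64),
        b_time=np.zeros((n, 2)),
        b_break=np.full((n, 2), _k.UNSET, dtype=np.int64),
        comp=np.zeros(n, dtype=np.int64),
        mob=np.zeros(n, dtype=np.int64),
        grp_x=np.zeros((n, MAX_GROUPS)),
        grp_y=np.zeros((n, MAX_GROUPS)),
        grp_z=grp_z,
        cell_of=np.zeros(n, dtype=np.int64),
        cell_next=np.full(n, -1, dtype=np.int64),
        cell_head=np.full(ncx * ncy, -1, dtype=np.int64),
        ncx=ncx,
        ncy=ncy,
        _scratch=_alloc_scratch(n, ncx * ncy),
        _norm_rng=rng,
    )


def initialize_system(config: SimulationConfig, seed: int | None = None) -> SystemState:
    """Place all molecules uniformly at random on their surfaces.

    Orientation is uniform on [0, 2pi); with excluded volume enabled,
    placement is rejection-sampled so no two hard-core groups overlap.
    Deterministic given (config, seed).
    """
    cfg = validate_config(config)
    lib = build_species_library()
    if seed is None:
        seed = cfg.seed
    state = _empty_state(cfg, lib, int(seed))
    sc = state._scratch
    place_seed = state.next_kernel_seed()
    fail = _k._place(
        state.n_mol, state.sp, state.surf, state.x, state.y, state.th,
        state.comp, state.cell_of, state.cell_next, state.cell_head,
        state.ncx, state.ncy,
        lib.g_off, lib.g_rad, lib.g_cnt,
        state.grp_x, state.grp_y, state.grp_z, _ev_thresholds(lib, cfg.gap),
        cfg.box_x, cfg.box_y, cfg.excluded_volume,
        _PLACEMENT_ATTEMPTS, place_seed, sc["mgx"], sc["mgy"],
    )
    if fail >= 0:
        raise PackingError(
            f"could not place molecule {fail} after {_PLACEMENT_ATTEMPTS} attempts; "
            "system too dense"
        )
    update_mobility(state)
    return state


def make_state(
    config: SimulationConfig,
    placements: Sequence[tuple],
    bonds: Iterable[tuple] = (),
    seed: int = 0,
) -> SystemState:
    """Build a state with explicit poses (and optionally bonds).

    ``placements`` is a sequence of ``(species, x, y, theta_deg)``;
    ``bonds`` of ``((i, site_i), (j, site_j))`` indexing the placement
    list.  The copy numbers in ``config`` are ignored and replaced by
    the placement list.  Intended for fixtures, oracle scenarios, and
    snapshot re-ingestion.
    """
    lib = build_species_library()
    counts = {s.name: 0 for s in Species}
    rows = []
    for spec in placements:
        s, px, py, deg = spec
        s = Species[s] if isinstance(s, str) else Species(s)
        counts[s.name] += 1
        rows.append((s, float(px), float(py), float(deg)))
    cfg = validate_config(config.replace(copy_numbers=counts))
    state = _empty_state(cfg, lib, seed)
    # molecules are ordered species-major, preserving input order per species
    order = sorted(range(len(rows)), key=lambda k: int(rows[k][0]))
    remap = {old: new for new, old in enumerate(order)}
    for new, old in enumerate(order):
        s, px, py, deg = rows[old]
        state.x[new] = px % cfg.box_x
        state.y[new] = py % cfg.box_y
        state.th[new] = np.radians(deg) % (2 * np.pi)
        c, si = np.cos(state.th[new]), np.sin(state.th[new])
        for g in range(int(lib.g_cnt[state.sp[new]])):
            ox, oy = lib.g_off[state.sp[new], g, 0], lib.g_off[state.sp[new], g, 1]
            state.grp_x[new, g] = state.x[new] + ox * c - oy * si
            state.grp_y[new, g] = state.y[new] + ox * si + oy * c
        cell = _cell_index(state, state.x[new], state.y[new])
        state.cell_of[new] = cell
        state.cell_next[new] = state.cell_head[cell]
        state.cell_head[cell] = new
    table = build_interaction_table(cfg.affinities, cfg.p_on)
    lut = table.lookup()
    for (i, si_), (j, sj) in bonds:
        i, j = remap[i], remap[j]
        ca = lib.s_cls[state.sp[i], si_]
        cb = lib.s_cls[state.sp[j], sj]
        rule = int(lut[ca, cb])
        if rule < 0:
            raise ConfigError(f"no interaction rule pairs site classes {ca} and {cb}")
        if state.bp_mol[i, si_] >= 0 or state.bp_mol[j, sj] >= 0:
            raise ConfigError("site already bonded")
        state.bp_mol[i, si_] = j
        state.bp_site[i, si_] = sj
        state.b_rule[i, si_] = rule
        state.bp_mol[j, sj] = i
        state.bp_site[j, sj] = si_
        state.b_rule[j, sj] = rule
    update_mobility(state)
    return state


def _cell_index(state: SystemState, px: float, py: float) -> int:
    cfg = state.config
    cx = min(int(px / cfg.box_x * state.ncx), state.ncx - 1)
    cy = min(int(py / cfg.box_y * state.ncy), state.ncy - 1)
    return cy * state.ncx + cx


def _rule_enabled(cfg: SimulationConfig) -> np.ndarray:
    return np.array(
        [name not in cfg.disabled_rules for name in RULE_NAMES], dtype=np.bool_
    )


def _advance_state(
    state: SystemState,
    n_steps: int,
    do_diffuse: bool,
    do_dissoc: bool,
    do_assoc: bool,
    stride: int = 0,
    ts_out: np.ndarray | None = None,
    seed: int | None = None,
    force_full: bool = False,
) -> int:
    cfg = state.config
    lib = state.library
    table = build_interaction_table(cfg.affinities, cfg.p_on)
    enabled = _rule_enabled(cfg)
    ev_thr2 = _ev_thresholds(lib, cfg.gap)
    sc = state._scratch
    ts = ts_out if ts_out is not None else _EMPTY_TS
    kseed = state.next_kernel_seed() if seed is None else seed
    sig_t_mono = float(np.sqrt(2.0 * cfg.D_mono_t * cfg.dt))
    sig_t_cplx = float(np.sqrt(2.0 * cfg.D_cplx_t * cfg.dt))
    sig_r_mono = float(np.radians(cfg.D_mono_r * cfg.dt))
    sig_r_cplx = float(np.radians(cfg.D_cplx_r * cfg.dt))
    need_per_step = 3 * max(state.n_mol, 1)
    done = 0
    nrec = 0
    first = True
    while True:
        if do_diffuse and (
            state._norm_buf.shape[0] - state._norm_idx < need_per_step
        ):
            chunk = min(n_steps - done, _NORM_CHUNK_STEPS)
            state._norm_buf = state._norm_rng.standard_normal(
                need_per_step * max(chunk, 1)
            )
            state._norm_idx = 0
        sd, nrec, ncomp, nidx = _k._advance(
            state.n_mol, state.sp, state.surf, state.x, state.y, state.th,
            state.bp_mol, state.bp_site, state.b_rule, state.b_time, state.b_break,
            state.comp, state.mob,
            state.cell_of, state.cell_next, state.cell_head, state.ncx, state.ncy,
            lib.g_off, lib.g_rad, lib.g_cnt, lib.s_grp, lib.s_cls, lib.s_cnt,
            state.grp_x, state.grp_y, state.grp_z, ev_thr2,
            _PROBE_RULE, _PROBE_ANY, table.p_off_vector(), enabled, _RULE_IMMOB,
            cfg.p_on,
            cfg.box_x, cfg.box_y, cfg.cutoff**2, cfg.excluded_volume,
            sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
            sc["comp_start"], sc["comp_items"], sc["comp_mob"],
            sc["mobile_list"], sc["queue"],
            sc["cand"], sc["frozen"], sc["frozen_list"],
            sc["mgx"], sc["mgy"],
            sc["relx"], sc["rely"], sc["nxa"], sc["nya"], sc["ntha"],
            sc["active"], sc["active_list"], sc["wake_list"], sc["counters"],
            sc["vstart"], sc["vitems"], sc["vref_x"], sc["vref_y"], sc["vref_th"],
            sc["vmax"], (lib.interaction_reach + cfg.cutoff + _VLIST_SKIN) ** 2,
            _VLIST_SKIN, 0.0,
            state._norm_buf, state._norm_idx,
            state.t, cfg.dt, n_steps - done, state._gstep, done,
            kseed if first else -1, force_full,
            do_diffuse, do_dissoc, do_assoc,
            stride, ts, nrec,
        )
        first = False
        state._norm_idx = int(nidx)
        state.t += sd * cfg.dt
        state._gstep += int(sd)
        state.ncomp = int(ncomp)
        done += int(sd)
        if done >= n_steps:
            break
    return nrec


# -- single-scenario operations (unit-testable pieces of one step) --------

def diffuse(state: SystemState, n_steps: int = 1) -> SystemState:
    """Run only the diffusion scenario for ``n_steps`` steps (in place)."""
    _advance_state(state, n_steps, True, False, False)
    return state


def attempt_dissociations(state: SystemState, n_steps: int = 1) -> SystemState:
    """Run only the dissociation half of the reaction scenario."""
    _advance_state(state, n_steps, False, True, False)
    return state


def attempt_associations(state: SystemState, n_steps: int = 1) -> SystemState:
    """Run only the association half of the reaction scenario."""
    _advance_state(state, n_steps, False, False, True)
    return state


def update_mobility(state: SystemState) -> SystemState:
    """Recompute bond-graph components and per-component mobility classes.

    Isolated molecules are MONOMER, components whose bonds are all trans
    are TRANS_COMPLEX, and components containing at least one cis or
    homodimer bond are IMMOBILE.
    """
    sc = state._scratch
    state.ncomp = int(
        _k._rebuild_components(
            state.n_mol, state.sp, state.library.s_cnt,
            state.bp_mol, state.b_rule, _RULE_IMMOB,
            state.comp, state.mob, sc["queue"],
            sc["comp_start"], sc["comp_items"], sc["comp_mob"],
        )
    )
    return state


def find_candidate_pairs(state: SystemState) -> list[tuple]:
    """Eligible (site, site, rule) triples within the association cutoff.

    Returns ``[(i, site_i, j, site_j, rule_name), ...]``, each unordered
    pair exactly once.  Uses the cell-list neighbor search; equivalent to
    the brute-force all-pairs scan.
    """
    cfg = state.config
    lib = state.library
    sc = state._scratch
    frozen = np.zeros((max(state.n_mol, 1), 2), dtype=np.bool_)
    cand = sc["cand"]
    ncand, _overflow = _k._find_candidates(
        state.n_mol, state.sp, lib.s_grp, lib.s_cls, lib.s_cnt,
        state.bp_mol, state.grp_x, state.grp_y, state.grp_z,
        _PROBE_RULE, _PROBE_ANY, _rule_enabled(cfg),
        cfg.box_x, cfg.box_y, cfg.cutoff**2,
        state.ncx, state.ncy, state.cell_of, state.cell_head, state.cell_next,
        False, sc["vstart"], sc["vitems"],
        frozen, False, sc["active"], cand,
    )
    return [
        (
            int(cand[q, 0]), int(cand[q, 1]),
            int(cand[q, 2]), int(cand[q, 3]),
            RULE_NAMES[cand[q, 4]],
        )
        for q in range(ncand)
    ]


def step(
    state: SystemState, n_steps: int = 1, stride: int = 0, force_full: bool = False
) -> np.ndarray | None:
    """Execute full steps: diffuse -> dissociate -> associate -> mobility.

    With ``stride`` > 0, returns the recorded (time, 4 counts) rows.
    ``force_full`` disables the active-cell association shortcut for the
    first step (used in equivalence tests).
    """
    ts = None
    if stride > 0:
        ts = np.zeros((n_steps // stride, 5))
    _advance_state(
        state, n_steps, True, True, True, stride=stride, ts_out=ts,
        force_full=force_full,
    )
    return ts


def bond_list(state: SystemState) -> list[tuple]:
    """Live bonds as ``(i, site_i, j, site_j, rule_name, t_form)``, i < j."""
    out = []
    for i in range(state.n_mol):
        for s in range(int(state.library.s_cnt[state.sp[i]])):
            j = int(state.bp_mol[i, s])
            if j > i:
                out.append(
                    (
                        i, s, j, int(state.bp_site[i, s]),
                        RULE_NAMES[state.b_rule[i, s]],
                        float(state.b_time[i, s]),
                    )
                )
    return out


def count_bond_types(state: SystemState) -> np.ndarray:
    """Exact tally of live bonds in canonical rule order (length 4)."""
    out = np.zeros(4, dtype=np.int64)
    _k._count_bonds(
        state.n_mol, state.sp, state.library.s_cnt, state.bp_mol, state.b_rule, out
    )
    return out


def group_coordinates(state: SystemState):
    """Global (x, y, z) of every coarse-grained group, with labels.

    Returns ``(labels, coords)`` where labels are strings like ``"B7:2"``
    (species:group) and coords is an (n_groups_total, 3) array.
    """
    lib = state.library
    labels = []
    coords = []
    for i in range(state.n_mol):
        spi = int(state.sp[i])
        for g in range(int(lib.g_cnt[spi])):
            labels.append(f"{Species(spi).name}:{g}")
            coords.append(
                (state.grp_x[i, g], state.grp_y[i, g], state.grp_z[i, g])
            )
    return labels, np.array(coords) if coords else np.zeros((0, 3))


def run(
    config: SimulationConfig,
    seed: int | None = None,
    snapshot_stride: int | None = None,
) -> RunResult:
    """Initialize and run a full trajectory.

    Samples the four bond-type counts every ``config.record_stride``
    steps (the t = 0 row is included).  With ``snapshot_stride`` (a
    multiple of ``record_stride``), group-coordinate snapshots are
    collected along the way.  Fully reproducible from (config, seed).
    """
    t_start = _time.perf_counter()
    cfg = validate_config(config)
    if seed is None:
        seed = cfg.seed
    state = initialize_system(cfg, seed)
    n = cfg.n_steps
    stride = cfg.record_stride
    nrec_max = n // stride
    ts = np.zeros((nrec_max, 5))
    snapshots = []
    if snapshot_stride is None:
        nrec = _advance_state(state, n, True, True, True, stride=stride, ts_out=ts)
    else:
        if snapshot_stride % stride:
            raise ConfigError("snapshot_stride must be a multiple of record_stride")
        nrec = 0
        done = 0
        while done < n:
            chunk = min(snapshot_stride, n - done)
            seg = ts[nrec : nrec + chunk // stride]
            _advance_state(state, chunk, True, True, True, stride=stride, ts_out=seg)
            nrec += chunk // stride
            done += chunk
            snapshots.append((state.t, group_coordinates(state), bond_list(state)))
    rows = np.vstack([np.zeros((1, 5)), ts[:nrec]])
    df = pd.DataFrame(rows, columns=list(TS_COLUMNS))
    for c in TS_COLUMNS[1:]:
        df[c] = df[c].astype(int)
    return RunResult(
        config=cfg,
        seed=int(seed),
        config_hash=config_hash(cfg),
        time_series=df,
        final_state=state,
        snapshots=snapshots,
        runtime_s=_time.perf_counter() - t_start,
    )
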