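"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cgsynapse.model import RULE_NAMES, SimulationConfig, Species
from cgsynapse import engine

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def tiny_config(**kw) -> SimulationConfig:
    """Small, fast configuration for constructed-state tests."""
    base = dict(
        box_x=60.0,
        box_y=60.0,
        copy_numbers={"CTLA4_DIMER": 0, "B7": 0, "PD1": 0, "PDL1": 0},
        affinities={n: -7.0 for n in RULE_NAMES},
        n_steps=10,
        record_stride=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


def pinned_config(dG: float, **kw) -> SimulationConfig:
    """Diffusion disabled; all four rules at affinity ``dG``."""
    return tiny_config(
        D_mono_t=0.0, D_mono_r=0.0, D_cplx_t=0.0, D_cplx_r=0.0,
        affinities={n: dG for n in RULE_NAMES},
        **kw,
    )


# -- constructed molecular arrangements (canonical site geometry) ---------
# CTLA-4 dimer at theta=0 has trans sites at x -2 and +2; B7 at theta=0
# has its trans site at +1 and side site at -1; PD-1/PD-L1 have their
# single site at +1.  All sites sit at global z = 10 (gap mid-plane).

def trans_pair(cfg, gap_nm=0.1):
    """CTLA-4 (mol 0) and B7 (mol 1) with trans sites ``gap_nm`` apart.

    Bondable sites: CTLA-4 site 1 (at +2) vs B7 site 0 (trans).
    """
    x0 = 20.0
    return engine.make_state(
        cfg,
        [("CTLA4_DIMER", x0, 20.0, 0.0), ("B7", x0 + 3.0 + gap_nm, 20.0, 180.0)],
    )


def dimer_pair(cfg, gap_nm=0.1):
    """Two B7 with side sites ``gap_nm`` apart (homodimer geometry)."""
    return engine.make_state(
        cfg,
        [("B7", 20.0, 20.0, 0.0), ("B7", 20.0 - 2.0 - gap_nm, 20.0, 180.0)],
    )


def cis_pair(cfg, gap_nm=0.1):
    """B7 and PD-L1 with side sites ``gap_nm`` apart (cis geometry)."""
    return engine.make_state(
        cfg,
        [("B7", 20.0, 20.0, 0.0), ("PDL1", 20.0 - 2.0 - gap_nm, 20.0, 0.0)],
    )


def zipper_chain(cfg, y=30.0, bonded=True):
    """CTLA4 - B7 = B7 - CTLA4 linear oligomer (placements + bonds).

    Returns (placements, bonds) with molecule indices in placement order:
    0,1 the two B7 (dimerized), 2,3 the flanking CTLA-4 receptors.
    """
    placements = [
        ("B7", 30.0, y, 0.0),        # trans site (31,y), side (29,y)
        ("B7", 28.0, y, 180.0),      # trans site (27,y), side (29,y)
        ("CTLA4_DIMER", 33.0, y, 0.0),   # sites (31,y) and (35,y)
        ("CTLA4_DIMER", 25.0, y, 0.0),   # sites (23,y) and (27,y)
    ]
    bonds = [((0, 1), (1, 1)), ((0, 0), (2, 0)), ((1, 0), (3, 1))] if bonded else []
    return placements, bonds


def brute_force_candidates(state) -> set:
    """All-pairs oracle for the engine's cell-list candidate search."""
    from cgsynapse.model import build_interaction_table

    cfg = state.config
    lib = state.library
    table = build_interaction_table(cfg.affinities, cfg.p_on)
    lut = table.lookup()
    found = set()
    n = state.n_mol
    for i in range(n):
        for s in range(int(lib.s_cnt[state.sp[i]])):
            if state.bp_mol[i, s] >= 0:
                continue
            for j in range(i + 1, n):
                for t in range(int(lib.s_cnt[state.sp[j]])):
                    if state.bp_mol[j, t] >= 0:
                        continue
                    ca = int(lib.s_cls[state.sp[i], s])
                    cb = int(lib.s_cls[state.sp[j], t])
                    rule = int(lut[ca, cb])
                    if rule < 0 or RULE_NAMES[rule] in cfg.disabled_rules:
                        continue
                    dx = state.grp_x[i, lib.s_grp[state.sp[i], s]] - \
                        state.grp_x[j, lib.s_grp[state.sp[j], t]]
                    dy = state.grp_y[i, lib.s_grp[state.sp[i], s]] - \
                        state.grp_y[j, lib.s_grp[state.sp[j], t]]
                    dz = state.grp_z[i, lib.s_grp[state.sp[i], s]] - \
                        state.grp_z[j, lib.s_grp[state.sp[j], t]]
                    dx -= cfg.box_x * np.round(dx / cfg.box_x)
                    dy -= cfg.box_y * np.round(dy / cfg.box_y)
                    if dx * dx + dy * dy + dz * dz <= cfg.cutoff**2:
                        found.add(frozenset(((i, s), (j, t))))
    return found


def random_soup_state(rng: np.random.Generator, box=40.0):
    """A random small state with all four species at random poses."""
    placements = []
    for name in ("CTLA4_DIMER", "B7", "PD1", "PDL1"):
        for _ in range(int(rng.integers(0, 7))):
            placements.append(
                (name, rng.uniform(0, box), rng.uniform(0, box), rng.uniform(0, 360))
            )
    if not placements:
        placements.append(("B7", 1.0, 1.0, 0.0))
    cfg = tiny_config(box_x=box, box_y=box, excluded_volume=False)
    return engine.make_state(cfg, placements)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
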