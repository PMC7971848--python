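"""Engine operations against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest

from cgsynapse import engine
from cgsynapse.model import RULE_NAMES, PackingError, SimulationConfig, Species

from conftest import (
    brute_force_candidates,
    cis_pair,
    dimer_pair,
    pinned_config,
    random_soup_state,
    tiny_config,
    trans_pair,
    zipper_chain,
)


def fig2_like(n=200, box=500.0, **kw):
    return SimulationConfig(
        box_x=box, box_y=box,
        copy_numbers={"CTLA4_DIMER": n, "B7": n, "PD1": 0, "PDL1": 0},
        affinities={r: -7.0 for r in RULE_NAMES},
        n_steps=100, record_stride=10, **kw,
    )


class TestInitialize:
    def test_counts_and_no_bonds(self):
        state = engine.initialize_system(fig2_like(), seed=3)
        assert state.n_mol == 400
        assert state.species_counts()["CTLA4_DIMER"] == 200
        assert state.species_counts()["B7"] == 200
        assert (state.bp_mol == -1).all()
        assert state.t == 0.0

    def test_same_seed_bit_identical(self):
        a = engine.initialize_system(fig2_like(), seed=5)
        b = engine.initialize_system(fig2_like(), seed=5)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.th, b.th)

    def test_different_seed_differs(self):
        a = engine.initialize_system(fig2_like(), seed=5)
        b = engine.initialize_system(fig2_like(), seed=6)
        assert not np.array_equal(a.x, b.x)

    def test_excluded_volume_holds_at_t0(self):
        state = engine.initialize_system(
            fig2_like(n=120, box=220.0, excluded_volume=True), seed=7
        )
        assert not _any_hardcore_overlap(state)

    def test_infeasible_packing_raises(self):
        # near the jamming density of random sequential placement:
        # passes the coarse area check but cannot actually be packed
        cfg = SimulationConfig(
            box_x=40.0, box_y=40.0,
            copy_numbers={"CTLA4_DIMER": 150, "B7": 0, "PD1": 0, "PDL1": 0},
            affinities={r: -7.0 for r in RULE_NAMES},
            n_steps=10, record_stride=1, excluded_volume=True,
        )
        with pytest.raises(PackingError):
            engine.initialize_system(cfg, seed=0)


def _any_hardcore_overlap(state) -> bool:
    lib = state.library
    cfg = state.config
    n = state.n_mol
    for i in range(n):
        for j in range(i + 1, n):
            for gi in range(int(lib.g_cnt[state.sp[i]])):
                ri = lib.g_rad[state.sp[i], gi]
                if ri <= 0:
                    continue
                for gj in range(int(lib.g_cnt[state.sp[j]])):
                    rj = lib.g_rad[state.sp[j], gj]
                    if rj <= 0:
                        continue
                    dx = state.grp_x[i, gi] - state.grp_x[j, gj]
                    dy = state.grp_y[i, gi] - state.grp_y[j, gj]
                    dz = state.grp_z[i, gi] - state.grp_z[j, gj]
                    dx -= cfg.box_x * round(dx / cfg.box_x)
                    dy -= cfg.box_y * round(dy / cfg.box_y)
                    if dx * dx + dy * dy + dz * dz < (ri + rj) ** 2 - 1e-6:
                        return True
    return False


class TestDiffusion:
    def test_zero_diffusion_leaves_state_unchanged(self):
        cfg = tiny_config(D_mono_t=0.0, D_mono_r=0.0, D_cplx_t=0.0, D_cplx_r=0.0)
        state = engine.make_state(
            cfg, [("B7", 10, 10, 0.0), ("PD1", 30, 30, 45.0)]
        )
        x0, th0 = state.x.copy(), state.th.copy()
        engine.diffuse(state, 50)
        assert np.array_equal(state.x, x0)
        assert np.array_equal(state.th, th0)

    def test_dimerized_component_is_immobile(self):
        state = dimer_pair(tiny_config())
        engine.attempt_associations(state)
        assert engine.count_bond_types(state)[2] == 1
        x0, y0, th0 = state.x.copy(), state.y.copy(), state.th.copy()
        engine.diffuse(state, 100)
        assert np.array_equal(state.x, x0)
        assert np.array_equal(state.y, y0)
        assert np.array_equal(state.th, th0)

    def test_trans_complex_moves_rigidly(self):
        state = trans_pair(tiny_config())
        engine.attempt_associations(state)
        assert engine.count_bond_types(state)[0] == 1
        dx0 = state.x[1] - state.x[0]
        dy0 = state.y[1] - state.y[0]
        x0 = state.x.copy()
        engine.diffuse(state, 200)
        assert not np.array_equal(state.x, x0)  # it does move
        d_new = math.hypot(state.x[1] - state.x[0], state.y[1] - state.y[0])
        assert d_new == pytest.approx(math.hypot(dx0, dy0), abs=1e-9)

    def test_steric_rejection_prevents_overlap(self):
        # two B7 almost touching on the same surface: with excluded
        # volume on, diffusion never drives their hard cores into overlap
        cfg = tiny_config(excluded_volume=True)
        state = engine.make_state(
            cfg, [("B7", 20.0, 20.0, 0.0), ("B7", 22.05, 20.0, 0.0)]
        )
        for _ in range(20):
            engine.diffuse(state, 100)
            d = np.hypot(state.x[0] - state.x[1], state.y[0] - state.y[1])
            assert d >= 2.0 - 1e-6

    def test_msd_slope_matches_4D_dt(self):
        # free monomers: ensemble MSD grows as 4*D*dt per step
        n, nsteps, every = 1500, 1200, 60
        cfg = SimulationConfig(
            box_x=2500.0, box_y=2500.0, excluded_volume=False,
            copy_numbers={"CTLA4_DIMER": 0, "B7": 0, "PD1": n, "PDL1": 0},
            n_steps=10, record_stride=10,
        )
        state = engine.initialize_system(cfg, seed=42)
        x0, y0, th0 = state.x.copy(), state.y.copy(), state.th.copy()
        lags, msd, thvar = [], [], []
        for k in range(nsteps // every):
            engine.diffuse(state, every)
            dx = state.x - x0
            dy = state.y - y0
            dx -= cfg.box_x * np.round(dx / cfg.box_x)
            dy -= cfg.box_y * np.round(dy / cfg.box_y)
            lags.append((k + 1) * every)
            msd.append(np.mean(dx * dx + dy * dy))
            dth = np.angle(np.exp(1j * (state.th - th0)))
            thvar.append(np.var(dth))
        slope = np.polyfit(lags, msd, 1)[0]
        expected = 4.0 * cfg.D_mono_t * cfg.dt
        assert slope == pytest.approx(expected, rel=0.05)
        # orientation variance grows as (D_r*dt)^2 * t
        rot_slope = np.polyfit(lags, thvar, 1)[0]
        assert rot_slope == pytest.approx(math.radians(1.0) ** 2, rel=0.10)


class TestCandidates:
    def test_pair_inside_cutoff_listed(self):
        state = trans_pair(tiny_config(), gap_nm=0.4)
        cands = engine.find_candidate_pairs(state)
        assert len(cands) == 1
        assert cands[0][4] == "trans_ctla4_b7"

    def test_pair_outside_cutoff_not_listed(self):
        state = trans_pair(tiny_config(), gap_nm=0.6)
        assert engine.find_candidate_pairs(state) == []

    def test_occupied_site_excluded(self):
        # B7 side site consumed by a homodimer; a PD-L1 site within
        # cutoff of it must not be listed (one bond per site)
        cfg = tiny_config()
        state = engine.make_state(
            cfg,
            [
                ("B7", 20.0, 20.0, 0.0),       # side site (19, 20)
                ("B7", 17.9, 20.0, 180.0),     # side site (18.9, 20) - bonded
                ("PDL1", 18.0, 20.3, 0.0),     # site (19, 20.3), 0.3 from B7 side
            ],
            bonds=[((0, 1), (1, 1))],
        )
        cands = engine.find_candidate_pairs(state)
        assert all(rule != "cis_b7_pdl1" for *_ids, rule in cands)

    def test_cell_list_equals_brute_force_on_random_states(self, rng):
        for _ in range(100):
            state = random_soup_state(rng)
            found = {
                frozenset(((i, si), (j, sj)))
                for i, si, j, sj, _r in engine.find_candidate_pairs(state)
            }
            assert found == brute_force_candidates(state)

    def test_disabled_rule_filtered(self):
        cfg = tiny_config(disabled_rules=("cis_b7_pdl1",))
        state = cis_pair(cfg)
        assert engine.find_candidate_pairs(state) == []


class TestAssociation:
    def test_isolated_pair_binds_in_one_step(self):
        state = trans_pair(tiny_config())
        engine.attempt_associations(state)
        assert engine.count_bond_types(state)[0] == 1

    def test_p_on_zero_never_binds(self):
        state = trans_pair(tiny_config(p_on=0.0))
        engine.step(state, 200)
        assert engine.count_bond_types(state).sum() == 0

    def test_partner_choice_is_unbiased(self):
        # one free B7 trans site, two CTLA-4 sites in range: exactly one
        # bond forms; each partner is chosen about half the time
        cfg = tiny_config()
        wins = {0: 0, 1: 0}
        n_trials = 1000
        for seed in range(n_trials):
            state = engine.make_state(
                cfg,
                [
                    ("B7", 20.0, 20.0, 180.0),       # trans site (19, 20)
                    ("CTLA4_DIMER", 17.0, 20.0, 0.0),  # site 1 at (19, 20)
                    ("CTLA4_DIMER", 21.0, 20.2, 0.0),  # site 0 at (19, 20.2)
                ],
                seed=seed,
            )
            engine.attempt_associations(state)
            counts = engine.count_bond_types(state)
            assert counts[0] == 1  # exactly one bond
            b7 = int(np.flatnonzero(state.sp == Species.B7)[0])
            partner = int(state.bp_mol[b7, 0])
            ctla4s = sorted(np.flatnonzero(state.sp == Species.CTLA4_DIMER))
            wins[ctla4s.index(partner)] += 1
        freq = wins[0] / n_trials
        assert abs(freq - 0.5) < 3.5 * math.sqrt(0.25 / n_trials)


class TestDissociationAndDetailedBalance:
    def test_p_off_zero_never_breaks(self):
        cfg = pinned_config(-1e9)  # p_off = exp(-1e9) underflows to 0
        state = trans_pair(cfg)
        engine.attempt_associations(state)
        engine.step(state, 500)
        assert engine.count_bond_types(state)[0] == 1

    def test_zero_affinity_alternates_deterministically(self):
        # dG=0, p_on=1: the bond breaks every step and reforms (geminate
        # recombination) the next -> occupancy exactly 1/2
        state = trans_pair(pinned_config(0.0))
        ts = engine.step(state, 400, stride=1)
        occ = ts[:, 1]
        assert abs(occ.mean() - 0.5) < 0.01
        assert (occ[:-1] != occ[1:]).all()  # strict alternation

    @pytest.mark.parametrize("dG", [-2.0, -5.0])
    def test_two_state_occupancy_matches_stationary_law(self, dG):
        # pinned eligible pair with diffusion off is an exact two-state
        # chain; occupancy -> p_on/(p_on + p_off) with p_off = exp(dG)
        nsteps = 60_000
        state = trans_pair(pinned_config(dG))
        ts = engine.step(state, nsteps, stride=1)
        occ = ts[:, 1]
        expected = 1.0 / (1.0 + math.exp(dG))
        blocks = occ[: (len(occ) // 30) * 30].reshape(30, -1).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(len(blocks))
        assert abs(occ.mean() - expected) < max(3 * se, 1e-3)


class TestMobilityClasses:
    def test_trans_complex_label(self):
        state = trans_pair(tiny_config())
        engine.attempt_associations(state)
        assert set(state.mob) == {1}

    def test_immobile_label_via_dimer(self):
        state = dimer_pair(tiny_config())
        engine.attempt_associations(state)
        assert set(state.mob) == {2}

    def test_monomer_label(self):
        state = engine.make_state(tiny_config(), [("PD1", 5, 5, 0.0)])
        assert set(state.mob) == {0}

    def test_mixed_component_with_cis_is_immobile(self):
        placements, bonds = zipper_chain(tiny_config())
        state = engine.make_state(tiny_config(), placements, bonds)
        assert set(state.mob) == {2}  # contains a homodimer bond


class TestStep:
    def test_empty_system_only_advances_clock(self):
        cfg = tiny_config()
        state = engine.make_state(cfg, [("PD1", 5, 5, 0.0)])
        t0 = state.t
        engine.step(state, 10)
        assert state.t == pytest.approx(t0 + 10 * cfg.dt)

    def test_counts_conserved_and_invariants_hold(self):
        cfg = fig2_like(n=30, box=150.0)
        state = engine.initialize_system(cfg, seed=2)
        before = state.species_counts()
        engine.step(state, 500)
        assert state.species_counts() == before
        _assert_bond_invariants(state)

    def test_active_cell_shortcut_equals_full_scan(self):
        # with p_on = 1 the incremental candidate search must reproduce
        # the exhaustive scan trajectory bit for bit
        cfg = fig2_like(n=25, box=120.0)
        a = engine.initialize_system(cfg, seed=9)
        b = a.clone()
        ts_a = engine.step(a, 3000, stride=50, force_full=False)
        ts_b = engine.step(b, 3000, stride=50, force_full=True)
        assert np.array_equal(ts_a, ts_b)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.bp_mol, b.bp_mol)

    def test_run_is_reproducible(self):
        cfg = fig2_like(n=20, box=120.0)
        cfg = cfg.replace(n_steps=2000, record_stride=200)
        r1 = engine.run(cfg, seed=4)
        r2 = engine.run(cfg, seed=4)
        assert r1.time_series.equals(r2.time_series)
        assert np.array_equal(r1.final_state.x, r2.final_state.x)

    def test_all_zero_with_association_disabled(self):
        cfg = fig2_like(n=10, box=100.0).replace(
            p_on=0.0, n_steps=500, record_stride=100
        )
        res = engine.run(cfg, seed=1)
        assert (res.time_series[list(engine.TS_COLUMNS[1:])].to_numpy() == 0).all()


def _assert_bond_invariants(state):
    lib = state.library
    seen = set()
    for i in range(state.n_mol):
        for s in range(int(lib.s_cnt[state.sp[i]])):
            j = int(state.bp_mol[i, s])
            if j < 0:
                continue
            t = int(state.bp_site[i, s])
            # symmetry and exclusivity
            assert int(state.bp_mol[j, t]) == i
            assert int(state.bp_site[j, t]) == s
            key = (i, s)
            assert key not in seen
            seen.add(key)
            # topology: trans across surfaces, cis/homodimer on the APC
            rule = int(state.b_rule[i, s])
            if rule in (0, 1):
                assert state.surf[i] != state.surf[j]
            else:
                assert state.surf[i] == 1 and state.surf[j] == 1
    # component index equals a from-scratch recomputation
    import networkx as g

    G = g.Graph()
    G.add_nodes_from(range(state.n_mol))
    for i, si, j, sj, rule, t in engine.bond_list(state):
        G.add_edge(i, j)
    comps = list(g.connected_components(G))
    labels = {}
    for k, comp in enumerate(comps):
        for m in comp:
            labels[m] = k
    for i in range(state.n_mol):
        for j in range(i + 1, state.n_mol):
            assert (labels[i] == labels[j]) == (state.comp[i] == state.comp[j])
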