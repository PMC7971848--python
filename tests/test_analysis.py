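"""Cluster analysis, tail statistics, equilibrium and changepoint detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cgsynapse import analysis, engine
from cgsynapse.analysis import GridSpec
from cgsynapse.model import RULE_NAMES, SimulationConfig

from conftest import random_soup_state, tiny_config, zipper_chain


def _ts_from_counts(times, **cols):
    data = {"time_ns": times}
    for c in engine.TS_COLUMNS[1:]:
        data[c] = cols.get(c, np.zeros(len(times)))
    return pd.DataFrame(data)


class TestCountBonds:
    def test_empty_state_all_zero(self):
        state = engine.make_state(tiny_config(), [("B7", 5, 5, 0.0)])
        counts = analysis.count_bonds(state)
        assert counts[1:] == (0, 0, 0, 0)

    def test_constructed_state_tally(self):
        # 3 trans bonds + 1 homodimer
        placements = []
        bonds = []
        for k in range(3):
            y = 10.0 + 12 * k
            placements += [
                ("CTLA4_DIMER", 10.0, y, 0.0),
                ("B7", 13.1, y, 180.0),
            ]
            bonds.append(((2 * k, 1), (2 * k + 1, 0)))
        placements += [("B7", 40.0, 40.0, 0.0), ("B7", 37.9, 40.0, 180.0)]
        bonds.append(((6, 1), (7, 1)))
        state = engine.make_state(tiny_config(), placements, bonds)
        counts = analysis.count_bonds(state)
        assert (counts.n_trans_ctla4_b7, counts.n_trans_pd1_pdl1,
                counts.n_dimer_b7, counts.n_cis_b7_pdl1) == (3, 0, 1, 0)

    def test_counts_match_independent_graph_recount(self, rng):
        for _ in range(20):
            state = random_soup_state(rng)
            engine.step(state, 30)
            counts = analysis.count_bonds(state)
            tally = {r: 0 for r in RULE_NAMES}
            for *_ids, rule, _t in engine.bond_list(state):
                tally[rule] += 1
            assert counts.n_trans_ctla4_b7 == tally["trans_ctla4_b7"]
            assert counts.n_trans_pd1_pdl1 == tally["trans_pd1_pdl1"]
            assert counts.n_dimer_b7 == tally["dimer_b7"]
            assert counts.n_cis_b7_pdl1 == tally["cis_b7_pdl1"]


class TestConnectedComponents:
    def test_no_bonds_gives_singletons(self):
        state = engine.make_state(
            tiny_config(), [("PD1", 5 + 3 * k, 5, 0.0) for k in range(6)]
        )
        reports = analysis.connected_components(state)
        assert [r.size for r in reports] == [1] * 6

    def test_chain_is_single_component(self):
        placements, bonds = zipper_chain(tiny_config())
        state = engine.make_state(tiny_config(), placements, bonds)
        reports = analysis.connected_components(state)
        assert reports[0].size == 4
        assert reports[0].bond_counts["dimer_b7"] == 1
        assert reports[0].bond_counts["trans_ctla4_b7"] == 2

    def test_matches_networkx_on_random_states(self, rng):
        import networkx as nx

        for _ in range(100):
            state = random_soup_state(rng)
            engine.step(state, 20)
            reports = analysis.connected_components(state)
            G = nx.Graph()
            G.add_nodes_from(range(state.n_mol))
            for i, _si, j, _sj, _r, _t in engine.bond_list(state):
                G.add_edge(i, j)
            nx_sizes = sorted((len(c) for c in nx.connected_components(G)),
                              reverse=True)
            assert [r.size for r in reports] == nx_sizes
            # engine's incremental component index agrees as a partition
            for r in reports:
                assert len(set(state.comp[r.members])) == 1


class TestMorphology:
    def test_monomer_and_dimer_labels(self):
        state = engine.make_state(
            tiny_config(),
            [("B7", 10, 10, 0.0), ("B7", 7.9, 10, 180.0), ("PD1", 40, 40, 0.0)],
            bonds=[((0, 1), (1, 1))],
        )
        reports = analysis.classify_clusters(state)
        assert sorted(r.morphology for r in reports) == ["DIMER", "MONOMER"]

    def test_zipper_chain_is_linear(self):
        placements, bonds = zipper_chain(tiny_config())
        state = engine.make_state(tiny_config(), placements, bonds)
        reports = analysis.classify_clusters(state)
        assert reports[0].morphology == "LINEAR"

    def test_parallel_chain_array_is_planar(self):
        cfg = tiny_config()
        placements, bonds = [], []
        for row in range(3):
            p, b = zipper_chain(cfg, y=20.0 + 3.0 * row)
            offset = len(placements)
            placements += p
            bonds += [
                ((i + offset, si), (j + offset, sj)) for (i, si), (j, sj) in b
            ]
        state = engine.make_state(cfg, placements, bonds)
        members = np.arange(state.n_mol)
        assert analysis.classify_morphology(members, state) == "PLANAR"

    def test_labels_invariant_under_rigid_motion_and_rewrap(self):
        cfg = tiny_config()
        base, bonds = zipper_chain(cfg)
        ref_state = engine.make_state(cfg, base, bonds)
        ref = analysis.classify_clusters(ref_state)[0].morphology
        for angle, shift in [(30.0, 25.0), (90.0, 55.0), (135.0, 58.0)]:
            # rotate the whole arrangement and push it across the
            # periodic boundary
            th = math.radians(angle)
            moved = []
            for name, px, py, deg in base:
                qx = (px - 30) * math.cos(th) - (py - 30) * math.sin(th) + shift
                qy = (px - 30) * math.sin(th) + (py - 30) * math.cos(th) + shift
                moved.append((name, qx % cfg.box_x, qy % cfg.box_y, deg + angle))
            state = engine.make_state(cfg, moved, bonds)
            assert analysis.classify_clusters(state)[0].morphology == ref


class TestTailStatistics:
    def test_constant_series(self):
        ts = _ts_from_counts(
            np.arange(0, 1000, 10.0), n_dimer_b7=np.full(100, 7.0)
        )
        stats = analysis.tail_statistics(ts, 500.0)
        assert stats.loc["n_dimer_b7", "mean"] == 7.0
        assert stats.loc["n_dimer_b7", "iqr"] == 0.0

    def test_window_longer_than_series_rejected(self):
        ts = _ts_from_counts(np.arange(0, 100, 10.0))
        with pytest.raises(ValueError):
            analysis.tail_statistics(ts, 1e6)

    @given(st.integers(0, 2**31 - 1))
    def test_quartiles_match_order_statistics(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 50, size=40).astype(float)
        ts = _ts_from_counts(np.arange(len(v)) * 10.0, n_cis_b7_pdl1=v)
        stats = analysis.tail_statistics(ts, (len(v) - 1) * 10.0)
        row = stats.loc["n_cis_b7_pdl1"]
        assert row["median"] == np.median(v)
        assert row["q1"] == np.percentile(v, 25)
        assert row["q3"] == np.percentile(v, 75)
        iqr = row["q3"] - row["q1"]
        inside = v[(v >= row["q1"] - 1.5 * iqr) & (v <= row["q3"] + 1.5 * iqr)]
        assert row["whisker_low"] == inside.min()
        assert row["whisker_high"] == inside.max()


class TestEquilibriumDetection:
    def test_monotone_ramp_never_settles(self):
        t = np.arange(0, 3000, 10.0)
        ts = _ts_from_counts(t, n_trans_ctla4_b7=0.1 * t)
        assert analysis.detect_equilibrium(ts, tolerance=0.005) is None

    def test_saturating_curve_detected_between_3_and_6_tau(self):
        tau = 100.0  # in samples
        k = np.arange(1000)
        y = 120.0 * (1.0 - np.exp(-k / tau))
        ts = _ts_from_counts(k * 10.0, n_trans_ctla4_b7=y)
        t_eq = analysis.detect_equilibrium(ts, tolerance=0.005, window=10)
        assert t_eq is not None
        assert 3 * tau * 10.0 <= t_eq <= 6 * tau * 10.0

    def test_flat_series_settles_immediately(self):
        ts = _ts_from_counts(np.arange(0, 2000, 10.0))
        assert analysis.detect_equilibrium(ts) == 0.0


class TestChangepoint:
    def test_pure_linear_series_has_none(self):
        t = np.arange(0, 4000, 10.0)
        ts = _ts_from_counts(t, n_trans_ctla4_b7=0.05 * t)
        assert analysis.detect_changepoint(ts, "trans_ctla4_b7") is None

    def test_piecewise_break_recovered_within_one_stride(self):
        t = np.arange(0, 4000, 10.0)
        t0 = 2000.0
        y = np.where(t < t0, 0.02 * t, 0.02 * t0 + 0.15 * (t - t0))
        rng = np.random.default_rng(7)
        ts = _ts_from_counts(t, n_trans_ctla4_b7=y + rng.normal(0, 0.5, len(t)))
        found = analysis.detect_changepoint(ts, "trans_ctla4_b7")
        assert found is not None
        assert abs(found - t0) <= 10.0

    def test_too_short_series_rejected(self):
        ts = _ts_from_counts(np.arange(0, 100, 10.0))
        with pytest.raises(ValueError):
            analysis.detect_changepoint(ts, "trans_ctla4_b7")


class TestSweeps:
    def _tiny_base(self):
        return SimulationConfig(
            box_x=80.0, box_y=80.0,
            copy_numbers={"CTLA4_DIMER": 6, "B7": 6, "PD1": 0, "PDL1": 4},
            affinities={r: -5.0 for r in RULE_NAMES},
            n_steps=300, record_stride=30,
        )

    def test_single_cell_grid(self):
        spec = GridSpec((("affinity:dimer_b7", (-5.0,)),))
        table = analysis.sweep_grid(self._tiny_base(), spec, seeds=[0])
        assert len(table) == 4  # one cell x one seed x four bond types
        assert (table["error"] == "").all()

    def test_grid_shape_and_reproducibility(self):
        spec = GridSpec(
            (("affinity:cis_b7_pdl1", (-3.0, -9.0)), ("copies:PDL1", (2, 6)))
        )
        t1 = analysis.sweep_grid(self._tiny_base(), spec, seeds=[0, 1])
        t2 = analysis.sweep_grid(self._tiny_base(), spec, seeds=[0, 1])
        assert len(t1) == 2 * 2 * 2 * 4
        pd.testing.assert_frame_equal(t1, t2)

    def test_failing_cell_annotated_not_fatal(self):
        base = self._tiny_base().replace(
            box_x=12.0, box_y=12.0, excluded_volume=True
        )
        spec = GridSpec((("copies:B7", (2, 500)),))  # 500 cannot pack
        table = analysis.sweep_grid(base, spec, seeds=[0])
        errs = table.groupby("copies:B7")["error"].first()
        assert errs[2] == ""
        assert errs[500] != ""

    def test_heatmap_pivot(self):
        spec = GridSpec(
            (("affinity:cis_b7_pdl1", (-3.0, -9.0)), ("copies:PDL1", (2, 6)))
        )
        table = analysis.sweep_grid(self._tiny_base(), spec, seeds=[0])
        hm = analysis.heatmap_table(table, "cis_b7_pdl1")
        assert hm.shape == (2, 2)
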