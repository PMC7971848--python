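"""Numba kernels for the diffusion-reaction engine.

Everything here operates on flat numpy arrays owned by
:class:`cgsynapse.engine.SystemState`; the Python layer is a thin wrapper.
Discrete randomness (shuffles, acceptance draws, placement) comes from
numba's internal RNG, seeded explicitly at kernel entry; Gaussian
displacement noise is consumed from a pre-filled buffer generated by a
seeded numpy PCG64 stream.  Runs are bit-reproducible.

Conventions:

* coordinates are continuous nm in a half-open [0, box) with periodic
  wrap in x and y; minimum-image convention for all distances;
* orientation is a single angle (radians) about the membrane normal;
* ``surf`` codes 0 = T cell (anchored at z = gap, groups hang downward),
  1 = APC (anchored at z = 0, groups point upward);
* global group coordinates are cached in ``grp_x/grp_y/grp_z`` (z is
  fixed per molecule) and refreshed whenever a pose changes;
* neighbor search uses a linked-cell grid whose cell edge is at least
  the largest anchor-anchor interaction distance, so scanning the 3x3
  neighborhood of a cell is exhaustive; 3x3 indices are computed by
  conditional +/-1 wrap (no divisions), with duplicate guards for
  degenerate grids narrower than three cells;
* per-site bond bookkeeping: ``bp_mol[i, s]`` is the partner molecule of
  site ``s`` of molecule ``i`` (-1 when free), with ``bp_site``,
  ``b_rule`` and ``b_time`` alongside; every live bond appears at both
  endpoints.  Bond lifetimes are geometrically distributed with the
  rule's per-step ``p_off``; the break step is sampled lazily (the
  geometric law is memoryless) and stored in ``b_break``;
* mobility codes: 0 monomer, 1 trans-only complex, 2 immobile (any
  same-surface bond in the component);
* association bookkeeping uses an *active-cell* mask: a cell is marked
  whenever a molecule in it moves (old and new cell), and a dissociated
  site wakes its cell the following step; probing sites scan the mask
  over their 3x3 neighborhood.  Sites whose neighborhood is entirely
  unmarked cannot have gained an eligible partner when ``p_on == 1``
  (every within-cutoff free pair is resolved the step it appears), so
  they are skipped.  With ``p_on < 1`` or after a candidate overflow the
  kernel falls back to exhaustive scans.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWOPI = 2.0 * np.pi

MONOMER = 0
TRANS_COMPLEX = 1
IMMOBILE = 2

NEVER = np.int64(2) ** 62  # break-step sentinel for p_off = 0
UNSET = np.int64(-1)  # break step not yet sampled

# counters array layout (persisted across kernel invocations)
C_NACTIVE = 0
C_FULLNEXT = 1
C_NWAKE = 2


@njit(inline="always")
def _wrap(v, L):
    v = v % L
    if v < 0.0:
        v += L
    if v >= L:
        v -= L
    return v


@njit(inline="always")
def _mi(d, L):
    return d - L * np.round(d / L)


@njit(inline="always")
def _cell_xy(px, py, box_x, box_y, ncx, ncy):
    cx = int(px / box_x * ncx)
    if cx >= ncx:
        cx = ncx - 1
    if cx < 0:
        cx = 0
    cy = int(py / box_y * ncy)
    if cy >= ncy:
        cy = ncy - 1
    if cy < 0:
        cy = 0
    return cx, cy


@njit(inline="always")
def _pm(c, nc):
    """(c-1, c+1) with periodic wrap, by comparison (no division)."""
    cm = c - 1
    if cm < 0:
        cm = nc - 1
    cp = c + 1
    if cp >= nc:
        cp = 0
    return cm, cp


@njit(inline="always")
def _skip_dup(q, cm, c0, cp):
    """Skip duplicate +/-1 neighbors on grids narrower than 3 cells."""
    if q == 0:
        return cm == c0
    if q == 2:
        return cp == c0 or cp == cm
    return False


@njit(inline="always")
def _sel3(q, cm, c0, cp):
    if q == 0:
        return cm
    if q == 1:
        return c0
    return cp


@njit(inline="always")
def _fill_groups(spi, px, py, pth, g_off, g_cnt, mgx, mgy, off):
    """Proposed global group coordinates into mgx/mgy at slot ``off``."""
    c = np.cos(pth)
    s = np.sin(pth)
    for g in range(g_cnt[spi]):
        ox = g_off[spi, g, 0]
        oy = g_off[spi, g, 1]
        mgx[off + g] = px + ox * c - oy * s
        mgy[off + g] = py + ox * s + oy * c


@njit(inline="always")
def _overlap_groups(
    i, j, spi, px, py,
    sp, x, y, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, mgx, mgy, off,
):
    """Hard-core test of molecule ``i`` (proposed groups in mgx/mgy at
    ``off``) against molecule ``j`` (cached groups), with the
    species-pair anchor prefilter."""
    spj = sp[j]
    t2 = ev_thr2[spi, spj]
    if t2 < 0.0:
        return False
    adx = _mi(px - x[j], box_x)
    ady = _mi(py - y[j], box_y)
    if adx * adx + ady * ady > t2:
        return False
    for gi in range(g_cnt[spi]):
        ri = g_rad[spi, gi]
        if ri <= 0.0:
            continue
        for gj in range(g_cnt[spj]):
            rj = g_rad[spj, gj]
            if rj <= 0.0:
                continue
            ddx = _mi(mgx[off + gi] - grp_x[j, gj], box_x)
            ddy = _mi(mgy[off + gi] - grp_y[j, gj], box_y)
            ddz = grp_z[i, gi] - grp_z[j, gj]
            rr = ri + rj
            if ddx * ddx + ddy * ddy + ddz * ddz < rr * rr - 1e-9:
                return True
    return False


@njit(inline="always")
def _mol_overlap(
    i, px, py, skip_comp,
    sp, comp, x, y,
    g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, ncx, ncy, cell_head, cell_next, mgx, mgy, off,
):
    """Cell-scan hard-core overlap test (proposed groups pre-filled)."""
    spi = sp[i]
    cx, cy = _cell_xy(px, py, box_x, box_y, ncx, ncy)
    cxm, cxp = _pm(cx, ncx)
    cym, cyp = _pm(cy, ncy)
    for qx in range(3):
        if _skip_dup(qx, cxm, cx, cxp):
            continue
        ax = _sel3(qx, cxm, cx, cxp)
        for qy in range(3):
            if _skip_dup(qy, cym, cy, cyp):
                continue
            ay = _sel3(qy, cym, cy, cyp)
            j = cell_head[ay * ncx + ax]
            while j >= 0:
                if comp[j] != skip_comp and _overlap_groups(
                    i, j, spi, px, py,
                    sp, x, y, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                    box_x, box_y, mgx, mgy, off,
                ):
                    return True
                j = cell_next[j]
    return False


@njit(inline="always")
def _update_cell(i, px, py, box_x, box_y, ncx, ncy, cell_of, cell_next, cell_head):
    cx, cy = _cell_xy(px, py, box_x, box_y, ncx, ncy)
    nc = cy * ncx + cx
    oc = cell_of[i]
    if nc == oc:
        return
    j = cell_head[oc]
    if j == i:
        cell_head[oc] = cell_next[i]
    else:
        while cell_next[j] != i:
            j = cell_next[j]
        cell_next[j] = cell_next[i]
    cell_next[i] = cell_head[nc]
    cell_head[nc] = i
    cell_of[i] = nc


@njit(inline="always")
def _mark_active(cell, active, active_list, counters):
    """Mark ``cell`` as changed; probes scan their 3x3 neighborhood."""
    if active[cell] == 0:
        active[cell] = 1
        active_list[counters[C_NACTIVE]] = cell
        counters[C_NACTIVE] += 1


@njit(cache=True)
def _rebuild_components(
    n_mol, sp, s_cnt, bp_mol, b_rule, rule_immob,
    comp, mob, queue, comp_start, comp_items, comp_mob,
):
    """Connected components of the live bond graph (BFS) and the mobility
    class of each component; returns the number of components."""
    for i in range(n_mol):
        comp[i] = -1
    ncomp = 0
    pos = 0
    for i in range(n_mol):
        if comp[i] >= 0:
            continue
        head = 0
        tail = 0
        queue[tail] = i
        tail += 1
        comp[i] = ncomp
        comp_start[ncomp] = pos
        immob = False
        has_bond = False
        while head < tail:
            u = queue[head]
            head += 1
            comp_items[pos] = u
            pos += 1
            for s_ in range(s_cnt[sp[u]]):
                v = bp_mol[u, s_]
                if v >= 0:
                    has_bond = True
                    if rule_immob[b_rule[u, s_]]:
                        immob = True
                    if comp[v] < 0:
                        comp[v] = ncomp
                        queue[tail] = v
                        tail += 1
        if immob:
            comp_mob[ncomp] = IMMOBILE
        elif has_bond:
            comp_mob[ncomp] = TRANS_COMPLEX
        else:
            comp_mob[ncomp] = MONOMER
        ncomp += 1
    comp_start[ncomp] = pos
    for c in range(ncomp):
        for k in range(comp_start[c], comp_start[c + 1]):
            mob[comp_items[k]] = comp_mob[c]
    return ncomp


@njit(cache=True)
def _count_bonds(n_mol, sp, s_cnt, bp_mol, b_rule, out4):
    for r in range(4):
        out4[r] = 0
    for i in range(n_mol):
        for s_ in range(s_cnt[sp[i]]):
            j = bp_mol[i, s_]
            if j > i:
                out4[b_rule[i, s_]] += 1



@njit(cache=True)
def _rebuild_vlist(
    n_mol, x, y, th,
    box_x, box_y, ncx, ncy, cell_head, cell_next,
    R2, vstart, vitems, vref_x, vref_y, vref_th, vmax,
):
    """Rebuild the Verlet neighbor lists (anchor distance <= sqrt(R2)).

    Stores both directions.  Also resets the reference poses and the
    displacement budget.  Returns False when the item buffer is too
    small (caller falls back to cell scans)."""
    cap = vitems.shape[0]
    pos = 0
    ok = True
    for i in range(n_mol):
        vstart[i] = pos
        xi = x[i]
        yi = y[i]
        cx, cy = _cell_xy(xi, yi, box_x, box_y, ncx, ncy)
        cxm, cxp = _pm(cx, ncx)
        cym, cyp = _pm(cy, ncy)
        for qx in range(3):
            if _skip_dup(qx, cxm, cx, cxp):
                continue
            ax = _sel3(qx, cxm, cx, cxp)
            for qy in range(3):
                if _skip_dup(qy, cym, cy, cyp):
                    continue
                ay = _sel3(qy, cym, cy, cyp)
                j = cell_head[ay * ncx + ax]
                while j >= 0:
                    if j != i:
                        dx = _mi(xi - x[j], box_x)
                        dy = _mi(yi - y[j], box_y)
                        if dx * dx + dy * dy <= R2:
                            if pos < cap:
                                vitems[pos] = j
                                pos += 1
                            else:
                                ok = False
                    j = cell_next[j]
    vstart[n_mol] = pos
    if ok:
        for i in range(n_mol):
            vref_x[i] = x[i]
            vref_y[i] = y[i]
            vref_th[i] = th[i]
        vmax[0] = 0.0
    return ok


@njit(inline="always")
def _vbudget_update(i, x, y, th, vref_x, vref_y, vref_th, vmax, box_x, box_y, maxext):
    dx = _mi(x[i] - vref_x[i], box_x)
    dy = _mi(y[i] - vref_y[i], box_y)
    da = th[i] - vref_th[i]
    da -= TWOPI * np.round(da / TWOPI)
    bd = np.sqrt(dx * dx + dy * dy) + maxext * abs(da)
    if bd > vmax[0]:
        vmax[0] = bd


@njit(inline="always")
def _mol_overlap_v(
    i, px, py, skip_comp,
    sp, comp, x, y,
    g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, vstart, vitems, mgx, mgy, off,
):
    """Verlet-list hard-core overlap test (proposed groups pre-filled)."""
    spi = sp[i]
    for k in range(vstart[i], vstart[i + 1]):
        j = vitems[k]
        if comp[j] != skip_comp and _overlap_groups(
            i, j, spi, px, py,
            sp, x, y, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
            box_x, box_y, mgx, mgy, off,
        ):
            return True
    return False


@njit(cache=True)
def _find_candidates(
    n_mol, sp, s_grp, s_cls, s_cnt,
    bp_mol, grp_x, grp_y, grp_z,
    probe_rule, probe_any, rule_enabled,
    box_x, box_y, cutoff2,
    ncx, ncy, cell_of, cell_head, cell_next,
    use_vlist, vstart, vitems,
    frozen, use_active, active, cand,
):
    """Unordered pairs of free, non-refractory sites whose classes match
    an enabled rule and whose 3-D site-site distance is within the
    cutoff.  Each pair is listed once (probing is one-directional per
    rule; the symmetric homodimer rule dedupes on molecule order).

    Neighbors come from the Verlet lists when valid, else from a 3x3
    cell scan.  With ``use_active`` only sites with a marked (changed)
    cell in their 3x3 neighborhood are probed.
    Returns (count, overflowed)."""
    ncand = 0
    overflow = False
    cap = cand.shape[0]
    for i in range(n_mol):
        spi = sp[i]
        nsi = s_cnt[spi]
        if nsi == 0:
            continue
        ci_cell = cell_of[i]
        cx = ci_cell % ncx
        cy = ci_cell // ncx
        cxm, cxp = _pm(cx, ncx)
        cym, cyp = _pm(cy, ncy)
        if use_active:
            touched = False
            for qx in range(3):
                if _skip_dup(qx, cxm, cx, cxp):
                    continue
                ax = _sel3(qx, cxm, cx, cxp)
                for qy in range(3):
                    if _skip_dup(qy, cym, cy, cyp):
                        continue
                    if active[_sel3(qy, cym, cy, cyp) * ncx + ax] != 0:
                        touched = True
                        break
                if touched:
                    break
            if not touched:
                continue
        for s_ in range(nsi):
            if bp_mol[i, s_] >= 0 or frozen[i, s_]:
                continue
            ci_cls = s_cls[spi, s_]
            if not probe_any[ci_cls]:
                continue
            g = s_grp[spi, s_]
            sx = grp_x[i, g]
            sy = grp_y[i, g]
            sz = grp_z[i, g]
            if use_vlist:
                for k in range(vstart[i], vstart[i + 1]):
                    j = vitems[k]
                    nc2, ovf = _probe_site_vs_mol(
                        i, s_, ci_cls, sx, sy, sz, j,
                        sp, s_grp, s_cls, s_cnt,
                        bp_mol, grp_x, grp_y, grp_z,
                        probe_rule, rule_enabled,
                        box_x, box_y, cutoff2, frozen, cand, ncand, cap,
                    )
                    ncand = nc2
                    overflow = overflow or ovf
            else:
                for qx in range(3):
                    if _skip_dup(qx, cxm, cx, cxp):
                        continue
                    ax = _sel3(qx, cxm, cx, cxp)
                    for qy in range(3):
                        if _skip_dup(qy, cym, cy, cyp):
                            continue
                        ay = _sel3(qy, cym, cy, cyp)
                        j = cell_head[ay * ncx + ax]
                        while j >= 0:
                            if j != i:
                                nc2, ovf = _probe_site_vs_mol(
                                    i, s_, ci_cls, sx, sy, sz, j,
                                    sp, s_grp, s_cls, s_cnt,
                                    bp_mol, grp_x, grp_y, grp_z,
                                    probe_rule, rule_enabled,
                                    box_x, box_y, cutoff2, frozen, cand,
                                    ncand, cap,
                                )
                                ncand = nc2
                                overflow = overflow or ovf
                            j = cell_next[j]
    return ncand, overflow


@njit(inline="always")
def _probe_site_vs_mol(
    i, s_, ci_cls, sx, sy, sz, j,
    sp, s_grp, s_cls, s_cnt,
    bp_mol, grp_x, grp_y, grp_z,
    probe_rule, rule_enabled,
    box_x, box_y, cutoff2, frozen, cand, ncand, cap,
):
    overflow = False
    spj = sp[j]
    for t_ in range(s_cnt[spj]):
        if bp_mol[j, t_] >= 0 or frozen[j, t_]:
            continue
        cj_cls = s_cls[spj, t_]
        r_ = probe_rule[ci_cls, cj_cls]
        if r_ < 0 or not rule_enabled[r_]:
            continue
        if ci_cls == cj_cls and j < i:
            continue
        g2 = s_grp[spj, t_]
        ddx = _mi(sx - grp_x[j, g2], box_x)
        ddy = _mi(sy - grp_y[j, g2], box_y)
        ddz = sz - grp_z[j, g2]
        if ddx * ddx + ddy * ddy + ddz * ddz <= cutoff2:
            if ncand < cap:
                cand[ncand, 0] = i
                cand[ncand, 1] = s_
                cand[ncand, 2] = j
                cand[ncand, 3] = t_
                cand[ncand, 4] = r_
                ncand += 1
            else:
                overflow = True
    return ncand, overflow


@njit(cache=True)
def _place(
    n_mol, sp, surf, x, y, th,
    comp, cell_of, cell_next, cell_head, ncx, ncy,
    g_off, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, excluded_volume, max_attempts, seed, mgx, mgy,
):
    """Uniform random placement with excluded-volume rejection sampling.

    Returns -1 on success, else the index of the first molecule that
    could not be placed within ``max_attempts`` tries."""
    np.random.seed(seed)
    for i in range(n_mol):
        comp[i] = i  # placement-time unique component ids
        placed = False
        for _att in range(max_attempts):
            px = np.random.random() * box_x
            py = np.random.random() * box_y
            pth = np.random.random() * TWOPI
            _fill_groups(sp[i], px, py, pth, g_off, g_cnt, mgx, mgy, 0)
            if excluded_volume and _mol_overlap(
                i, px, py, i,
                sp, comp, x, y,
                g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                box_x, box_y, ncx, ncy, cell_head, cell_next, mgx, mgy, 0,
            ):
                continue
            x[i] = px
            y[i] = py
            th[i] = pth
            for g in range(g_cnt[sp[i]]):
                grp_x[i, g] = mgx[g]
                grp_y[i, g] = mgy[g]
            cx, cy = _cell_xy(px, py, box_x, box_y, ncx, ncy)
            cell = cy * ncx + cx
            cell_of[i] = cell
            cell_next[i] = cell_head[cell]
            cell_head[cell] = i
            placed = True
            break
        if not placed:
            return i
    return -1


@njit(cache=True)
def _diffusion_pass(
    ncomp, comp_mob, comp_start, comp_items, mobile_list,
    sp, comp, x, y, th,
    g_off, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, ncx, ncy,
    cell_of, cell_next, cell_head,
    use_vlist, vstart, vitems, vref_x, vref_y, vref_th, vmax, maxext,
    active, active_list, counters,
    excluded_volume,
    sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
    mgx, mgy, relx, rely, nxa, nya, ntha,
    norm_buf, nidx,
):
    """One diffusion scenario: visit mobile units in random order, apply
    Gaussian rigid moves with excluded-volume rejection.  Returns the
    new Gaussian-buffer index and False when the buffer is too low."""
    nmobile = 0
    for c in range(ncomp):
        if comp_mob[c] != IMMOBILE:
            mobile_list[nmobile] = c
            nmobile += 1
    if nidx + 3 * nmobile > norm_buf.shape[0]:
        return nidx, False
    for q in range(nmobile - 1, 0, -1):
        r_ = np.random.randint(0, q + 1)
        tmp = mobile_list[q]
        mobile_list[q] = mobile_list[r_]
        mobile_list[r_] = tmp
    for q in range(nmobile):
        c = mobile_list[q]
        mc = comp_mob[c]
        st = sig_t_mono if mc == MONOMER else sig_t_cplx
        sr = sig_r_mono if mc == MONOMER else sig_r_cplx
        dxm = norm_buf[nidx] * st
        dym = norm_buf[nidx + 1] * st
        dth = norm_buf[nidx + 2] * sr
        nidx += 3
        a = comp_start[c]
        b = comp_start[c + 1]
        nm = b - a
        if nm == 1:
            i = comp_items[a]
            spi = sp[i]
            px = _wrap(x[i] + dxm, box_x)
            py = _wrap(y[i] + dym, box_y)
            pth = (th[i] + dth) % TWOPI
            _fill_groups(spi, px, py, pth, g_off, g_cnt, mgx, mgy, 0)
            if excluded_volume:
                if use_vlist:
                    hit = _mol_overlap_v(
                        i, px, py, comp[i], sp, comp, x, y,
                        g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                        box_x, box_y, vstart, vitems, mgx, mgy, 0,
                    )
                else:
                    hit = _mol_overlap(
                        i, px, py, comp[i], sp, comp, x, y,
                        g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                        box_x, box_y, ncx, ncy, cell_head, cell_next,
                        mgx, mgy, 0,
                    )
                if hit:
                    continue
            x[i] = px
            y[i] = py
            th[i] = pth
            for g in range(g_cnt[spi]):
                grp_x[i, g] = mgx[g]
                grp_y[i, g] = mgy[g]
            _mark_active(cell_of[i], active, active_list, counters)
            _update_cell(
                i, px, py, box_x, box_y, ncx, ncy,
                cell_of, cell_next, cell_head,
            )
            _mark_active(cell_of[i], active, active_list, counters)
            if use_vlist:
                _vbudget_update(
                    i, x, y, th, vref_x, vref_y, vref_th, vmax,
                    box_x, box_y, maxext,
                )
        else:
            # rigid move of a trans-only complex about its centroid
            i0 = comp_items[a]
            cxm2 = 0.0
            cym2 = 0.0
            for w in range(nm):
                jm = comp_items[a + w]
                rx = _mi(x[jm] - x[i0], box_x)
                ry = _mi(y[jm] - y[i0], box_y)
                relx[w] = rx
                rely[w] = ry
                cxm2 += rx
                cym2 += ry
            cxm2 /= nm
            cym2 /= nm
            cr = np.cos(dth)
            srn = np.sin(dth)
            for w in range(nm):
                vx = relx[w] - cxm2
                vy = rely[w] - cym2
                rx2 = vx * cr - vy * srn
                ry2 = vx * srn + vy * cr
                nxa[w] = _wrap(x[i0] + cxm2 + rx2 + dxm, box_x)
                nya[w] = _wrap(y[i0] + cym2 + ry2 + dym, box_y)
                jm = comp_items[a + w]
                ntha[w] = (th[jm] + dth) % TWOPI
                _fill_groups(
                    sp[jm], nxa[w], nya[w], ntha[w], g_off, g_cnt,
                    mgx, mgy, 4 * w,
                )
            ok = True
            if excluded_volume:
                cidv = comp[i0]
                for w in range(nm):
                    jm = comp_items[a + w]
                    if use_vlist:
                        hit = _mol_overlap_v(
                            jm, nxa[w], nya[w], cidv, sp, comp, x, y,
                            g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                            box_x, box_y, vstart, vitems, mgx, mgy, 4 * w,
                        )
                    else:
                        hit = _mol_overlap(
                            jm, nxa[w], nya[w], cidv, sp, comp, x, y,
                            g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                            box_x, box_y, ncx, ncy, cell_head, cell_next,
                            mgx, mgy, 4 * w,
                        )
                    if hit:
                        ok = False
                        break
            if ok:
                for w in range(nm):
                    jm = comp_items[a + w]
                    x[jm] = nxa[w]
                    y[jm] = nya[w]
                    th[jm] = ntha[w]
                    for g in range(g_cnt[sp[jm]]):
                        grp_x[jm, g] = mgx[4 * w + g]
                        grp_y[jm, g] = mgy[4 * w + g]
                    _mark_active(cell_of[jm], active, active_list, counters)
                    _update_cell(
                        jm, nxa[w], nya[w], box_x, box_y, ncx, ncy,
                        cell_of, cell_next, cell_head,
                    )
                    _mark_active(cell_of[jm], active, active_list, counters)
                    if use_vlist:
                        _vbudget_update(
                            jm, x, y, th, vref_x, vref_y, vref_th, vmax,
                            box_x, box_y, maxext,
                        )
    return nidx, True


@njit(cache=True)
def _diffusion_pass_fast(
    ncomp, comp_mob, comp_start, comp_items, mobile_list,
    sp, comp, x, y, th,
    g_off, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
    box_x, box_y, ncx, ncy,
    cell_of, cell_next, cell_head,
    vstart, vitems, vref_x, vref_y, vref_th, vmax,
    active, active_list, counters,
    excluded_volume,
    sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
    mgx, mgy, relx, rely, nxa, nya, ntha,
    norm_buf, nidx,
):
    """Verlet-list diffusion scenario with a hand-flattened inner loop.

    Semantically identical to :func:`_diffusion_pass` with valid Verlet
    lists; kept separate because the flattened form compiles to much
    tighter code for the dominant single-molecule case."""
    nmobile = 0
    for c in range(ncomp):
        if comp_mob[c] != IMMOBILE:
            mobile_list[nmobile] = c
            nmobile += 1
    if nidx + 3 * nmobile > norm_buf.shape[0]:
        return nidx, False
    for q in range(nmobile - 1, 0, -1):
        r_ = np.random.randint(0, q + 1)
        tmp = mobile_list[q]
        mobile_list[q] = mobile_list[r_]
        mobile_list[r_] = tmp
    for q in range(nmobile):
        c = mobile_list[q]
        mc = comp_mob[c]
        st = sig_t_mono if mc == MONOMER else sig_t_cplx
        sr = sig_r_mono if mc == MONOMER else sig_r_cplx
        dxm = norm_buf[nidx] * st
        dym = norm_buf[nidx + 1] * st
        dth = norm_buf[nidx + 2] * sr
        nidx += 3
        a = comp_start[c]
        nm = comp_start[c + 1] - a
        if nm == 1:
            i = comp_items[a]
            spi = sp[i]
            px = x[i] + dxm
            if px >= box_x:
                px -= box_x
                if px >= box_x:
                    px = px % box_x
            elif px < 0.0:
                px += box_x
                if px < 0.0:
                    px = px % box_x
            py = y[i] + dym
            if py >= box_y:
                py -= box_y
                if py >= box_y:
                    py = py % box_y
            elif py < 0.0:
                py += box_y
                if py < 0.0:
                    py = py % box_y
            pth = th[i] + dth
            if pth >= TWOPI:
                pth -= TWOPI
                if pth >= TWOPI:
                    pth = pth % TWOPI
            elif pth < 0.0:
                pth += TWOPI
                if pth < 0.0:
                    pth = pth % TWOPI
            cth = np.cos(pth)
            sth = np.sin(pth)
            ng = g_cnt[spi]
            for g in range(ng):
                ox = g_off[spi, g, 0]
                oy = g_off[spi, g, 1]
                mgx[g] = px + ox * cth - oy * sth
                mgy[g] = py + ox * sth + oy * cth
            hit = False
            if excluded_volume:
                ci_comp = comp[i]
                for kk in range(vstart[i], vstart[i + 1]):
                    j = vitems[kk]
                    if comp[j] == ci_comp:
                        continue
                    spj = sp[j]
                    t2 = ev_thr2[spi, spj]
                    if t2 < 0.0:
                        continue
                    adx = px - x[j]
                    adx -= box_x * np.round(adx / box_x)
                    ady = py - y[j]
                    ady -= box_y * np.round(ady / box_y)
                    if adx * adx + ady * ady > t2:
                        continue
                    for gi in range(ng):
                        ri = g_rad[spi, gi]
                        if ri <= 0.0:
                            continue
                        for gj in range(g_cnt[spj]):
                            rj = g_rad[spj, gj]
                            if rj <= 0.0:
                                continue
                            ddx = mgx[gi] - grp_x[j, gj]
                            ddx -= box_x * np.round(ddx / box_x)
                            ddy = mgy[gi] - grp_y[j, gj]
                            ddy -= box_y * np.round(ddy / box_y)
                            ddz = grp_z[i, gi] - grp_z[j, gj]
                            rr = ri + rj
                            if ddx * ddx + ddy * ddy + ddz * ddz < rr * rr - 1e-9:
                                hit = True
                                break
                        if hit:
                            break
                    if hit:
                        break
            if hit:
                continue
            x[i] = px
            y[i] = py
            th[i] = pth
            for g in range(ng):
                grp_x[i, g] = mgx[g]
                grp_y[i, g] = mgy[g]
            oc = cell_of[i]
            if active[oc] == 0:
                active[oc] = 1
                active_list[counters[C_NACTIVE]] = oc
                counters[C_NACTIVE] += 1
            cx = int(px / box_x * ncx)
            if cx >= ncx:
                cx = ncx - 1
            cy = int(py / box_y * ncy)
            if cy >= ncy:
                cy = ncy - 1
            nc = cy * ncx + cx
            if nc != oc:
                j = cell_head[oc]
                if j == i:
                    cell_head[oc] = cell_next[i]
                else:
                    while cell_next[j] != i:
                        j = cell_next[j]
                    cell_next[j] = cell_next[i]
                cell_next[i] = cell_head[nc]
                cell_head[nc] = i
                cell_of[i] = nc
                if active[nc] == 0:
                    active[nc] = 1
                    active_list[counters[C_NACTIVE]] = nc
                    counters[C_NACTIVE] += 1
            bdx = px - vref_x[i]
            bdx -= box_x * np.round(bdx / box_x)
            bdy = py - vref_y[i]
            bdy -= box_y * np.round(bdy / box_y)
            bd2 = bdx * bdx + bdy * bdy
            if bd2 > vmax[0] * vmax[0]:
                vmax[0] = np.sqrt(bd2)
        else:
            # rigid move of a trans-only complex about its centroid
            i0 = comp_items[a]
            cxm2 = 0.0
            cym2 = 0.0
            for w in range(nm):
                jm = comp_items[a + w]
                rx = x[jm] - x[i0]
                rx -= box_x * np.round(rx / box_x)
                ry = y[jm] - y[i0]
                ry -= box_y * np.round(ry / box_y)
                relx[w] = rx
                rely[w] = ry
                cxm2 += rx
                cym2 += ry
            cxm2 /= nm
            cym2 /= nm
            cr = np.cos(dth)
            srn = np.sin(dth)
            for w in range(nm):
                vx = relx[w] - cxm2
                vy = rely[w] - cym2
                jm = comp_items[a + w]
                nxa[w] = (x[i0] + cxm2 + vx * cr - vy * srn + dxm) % box_x
                nya[w] = (y[i0] + cym2 + vx * srn + vy * cr + dym) % box_y
                ntha[w] = (th[jm] + dth) % TWOPI
                cth = np.cos(ntha[w])
                sth = np.sin(ntha[w])
                spj0 = sp[jm]
                for g in range(g_cnt[spj0]):
                    ox = g_off[spj0, g, 0]
                    oy = g_off[spj0, g, 1]
                    mgx[4 * w + g] = nxa[w] + ox * cth - oy * sth
                    mgy[4 * w + g] = nya[w] + ox * sth + oy * cth
            ok = True
            if excluded_volume:
                cidv = comp[i0]
                for w in range(nm):
                    i = comp_items[a + w]
                    spi = sp[i]
                    px = nxa[w]
                    py = nya[w]
                    for kk in range(vstart[i], vstart[i + 1]):
                        j = vitems[kk]
                        if comp[j] == cidv:
                            continue
                        spj = sp[j]
                        t2 = ev_thr2[spi, spj]
                        if t2 < 0.0:
                            continue
                        adx = px - x[j]
                        adx -= box_x * np.round(adx / box_x)
                        ady = py - y[j]
                        ady -= box_y * np.round(ady / box_y)
                        if adx * adx + ady * ady > t2:
                            continue
                        for gi in range(g_cnt[spi]):
                            ri = g_rad[spi, gi]
                            if ri <= 0.0:
                                continue
                            for gj in range(g_cnt[spj]):
                                rj = g_rad[spj, gj]
                                if rj <= 0.0:
                                    continue
                                ddx = mgx[4 * w + gi] - grp_x[j, gj]
                                ddx -= box_x * np.round(ddx / box_x)
                                ddy = mgy[4 * w + gi] - grp_y[j, gj]
                                ddy -= box_y * np.round(ddy / box_y)
                                ddz = grp_z[i, gi] - grp_z[j, gj]
                                rr = ri + rj
                                if (
                                    ddx * ddx + ddy * ddy + ddz * ddz
                                    < rr * rr - 1e-9
                                ):
                                    ok = False
                                    break
                            if not ok:
                                break
                        if not ok:
                            break
                    if not ok:
                        break
            if ok:
                for w in range(nm):
                    jm = comp_items[a + w]
                    x[jm] = nxa[w]
                    y[jm] = nya[w]
                    th[jm] = ntha[w]
                    spj0 = sp[jm]
                    for g in range(g_cnt[spj0]):
                        grp_x[jm, g] = mgx[4 * w + g]
                        grp_y[jm, g] = mgy[4 * w + g]
                    oc = cell_of[jm]
                    if active[oc] == 0:
                        active[oc] = 1
                        active_list[counters[C_NACTIVE]] = oc
                        counters[C_NACTIVE] += 1
                    cx = int(nxa[w] / box_x * ncx)
                    if cx >= ncx:
                        cx = ncx - 1
                    cy = int(nya[w] / box_y * ncy)
                    if cy >= ncy:
                        cy = ncy - 1
                    nc = cy * ncx + cx
                    if nc != oc:
                        j = cell_head[oc]
                        if j == jm:
                            cell_head[oc] = cell_next[jm]
                        else:
                            while cell_next[j] != jm:
                                j = cell_next[j]
                            cell_next[j] = cell_next[jm]
                        cell_next[jm] = cell_head[nc]
                        cell_head[nc] = jm
                        cell_of[jm] = nc
                        if active[nc] == 0:
                            active[nc] = 1
                            active_list[counters[C_NACTIVE]] = nc
                            counters[C_NACTIVE] += 1
                    bdx = nxa[w] - vref_x[jm]
                    bdx -= box_x * np.round(bdx / box_x)
                    bdy = nya[w] - vref_y[jm]
                    bdy -= box_y * np.round(bdy / box_y)
                    bd = np.sqrt(bdx * bdx + bdy * bdy)
                    if bd > vmax[0]:
                        vmax[0] = bd
    return nidx, True


@njit(cache=True)
def _advance(
    n_mol, sp, surf, x, y, th,
    bp_mol, bp_site, b_rule, b_time, b_break,
    comp, mob,
    cell_of, cell_next, cell_head, ncx, ncy,
    g_off, g_rad, g_cnt, s_grp, s_cls, s_cnt,
    grp_x, grp_y, grp_z, ev_thr2,
    probe_rule, probe_any, rule_p_off, rule_enabled, rule_immob, p_on,
    box_x, box_y, cutoff2, excluded_volume,
    sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
    comp_start, comp_items, comp_mob, mobile_list, queue,
    cand, frozen, frozen_list, mgx, mgy,
    relx, rely, nxa, nya, ntha,
    active, active_list, wake_list, counters,
    vstart, vitems, vref_x, vref_y, vref_th, vmax, vlist_R2, vlist_skin, maxext,
    norm_buf, norm_idx,
    t0, dt, n_steps, k0_global, k0_record, seed, force_full,
    do_diffuse, do_dissoc, do_assoc,
    stride, ts_out, nrec0,
):
    """Advance up to ``n_steps`` steps (early return when the Gaussian
    buffer runs low; the wrapper refills and re-enters).

    Per-step order: diffusion scenario (mobile units in random order,
    Gaussian moves, excluded-volume rejection), then the reaction
    scenario as dissociation followed by association.  Sites freed by a
    dissociation are refractory until the next step, so a just-broken
    pair re-associates (geminate recombination) no earlier than the
    following association pass; this makes a pinned pair an exact
    two-state chain with stationary occupancy p_on/(p_on+p_off).

    Records the four bond counts every ``stride`` steps (relative to
    ``k0_record``) into ``ts_out`` starting at row ``nrec0``.
    Returns (steps_done, nrec, ncomp, norm_idx).
    """
    if seed >= 0:
        np.random.seed(seed)
        # stale incremental bookkeeping from a previous operation is void
        for q in range(counters[C_NACTIVE]):
            active[active_list[q]] = 0
        counters[C_NACTIVE] = 0
        counters[C_NWAKE] = 0
        counters[C_FULLNEXT] = 1
    if force_full:
        counters[C_FULLNEXT] = 1  # and use_active is suppressed every step
    ncomp = _rebuild_components(
        n_mol, sp, s_cnt, bp_mol, b_rule, rule_immob,
        comp, mob, queue, comp_start, comp_items, comp_mob,
    )
    nrec = nrec0
    nidx = norm_idx
    steps_done = 0
    use_vlist = _rebuild_vlist(
        n_mol, x, y, th, box_x, box_y, ncx, ncy, cell_head, cell_next,
        vlist_R2, vstart, vitems, vref_x, vref_y, vref_th, vmax,
    )
    for k in range(n_steps):
        gstep = k0_global + k + 1
        tnow = t0 + (k + 1) * dt

        # refresh the neighbor lists before the displacement budget can
        # let an unlisted pair drift into interaction range
        if use_vlist and 2.0 * vmax[0] > vlist_skin - 1.0:
            use_vlist = _rebuild_vlist(
                n_mol, x, y, th, box_x, box_y, ncx, ncy, cell_head, cell_next,
                vlist_R2, vstart, vitems, vref_x, vref_y, vref_th, vmax,
            )

        # ---- scenario 1: stochastic diffusion of mobile units ----
        if do_diffuse:
            if use_vlist:
                nidx, enough = _diffusion_pass_fast(
                    ncomp, comp_mob, comp_start, comp_items, mobile_list,
                    sp, comp, x, y, th,
                    g_off, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                    box_x, box_y, ncx, ncy,
                    cell_of, cell_next, cell_head,
                    vstart, vitems, vref_x, vref_y, vref_th, vmax,
                    active, active_list, counters,
                    excluded_volume,
                    sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
                    mgx, mgy, relx, rely, nxa, nya, ntha,
                    norm_buf, nidx,
                )
            else:
                nidx, enough = _diffusion_pass(
                    ncomp, comp_mob, comp_start, comp_items, mobile_list,
                    sp, comp, x, y, th,
                    g_off, g_rad, g_cnt, grp_x, grp_y, grp_z, ev_thr2,
                    box_x, box_y, ncx, ncy,
                    cell_of, cell_next, cell_head,
                    use_vlist, vstart, vitems, vref_x, vref_y, vref_th, vmax,
                    maxext,
                    active, active_list, counters,
                    excluded_volume,
                    sig_t_mono, sig_t_cplx, sig_r_mono, sig_r_cplx,
                    mgx, mgy, relx, rely, nxa, nya, ntha,
                    norm_buf, nidx,
                )
            if not enough:
                break  # wrapper refills the Gaussian buffer

        # ---- scenario 2a: dissociation ----
        nfroz = 0
        bonds_changed = False
        if do_dissoc:
            for i in range(n_mol):
                for s_ in range(s_cnt[sp[i]]):
                    j = bp_mol[i, s_]
                    if j <= i:  # free, or counted from the other endpoint
                        continue
                    if b_break[i, s_] == UNSET:
                        p = rule_p_off[b_rule[i, s_]]
                        if p <= 0.0:
                            b_break[i, s_] = NEVER
                        elif p >= 1.0:
                            b_break[i, s_] = gstep
                        else:
                            u = np.random.random()
                            b_break[i, s_] = gstep + np.int64(
                                np.log(1.0 - u) / np.log(1.0 - p)
                            )
                    if b_break[i, s_] <= gstep:
                        t_ = bp_site[i, s_]
                        bp_mol[i, s_] = -1
                        b_rule[i, s_] = -1
                        b_break[i, s_] = UNSET
                        bp_mol[j, t_] = -1
                        b_rule[j, t_] = -1
                        b_break[j, t_] = UNSET
                        frozen[i, s_] = True
                        frozen[j, t_] = True
                        frozen_list[nfroz] = i * 2 + s_
                        nfroz += 1
                        frozen_list[nfroz] = j * 2 + t_
                        nfroz += 1
                        wake_list[counters[C_NWAKE]] = cell_of[i]
                        counters[C_NWAKE] += 1
                        wake_list[counters[C_NWAKE]] = cell_of[j]
                        counters[C_NWAKE] += 1
                        bonds_changed = True

        # ---- scenario 2b: association ----
        if do_assoc:
            use_active = (
                (not force_full) and counters[C_FULLNEXT] == 0 and p_on >= 1.0
            )
            counters[C_FULLNEXT] = 1 if p_on < 1.0 else 0
            ncand, overflow = _find_candidates(
                n_mol, sp, s_grp, s_cls, s_cnt,
                bp_mol, grp_x, grp_y, grp_z,
                probe_rule, probe_any, rule_enabled,
                box_x, box_y, cutoff2,
                ncx, ncy, cell_of, cell_head, cell_next,
                use_vlist, vstart, vitems,
                frozen, use_active, active, cand,
            )
            if overflow:
                counters[C_FULLNEXT] = 1
            for q in range(ncand - 1, 0, -1):
                r_ = np.random.randint(0, q + 1)
                for col in range(5):
                    tmp = cand[q, col]
                    cand[q, col] = cand[r_, col]
                    cand[r_, col] = tmp
            for q in range(ncand):
                i = cand[q, 0]
                s_ = cand[q, 1]
                j = cand[q, 2]
                t_ = cand[q, 3]
                r_ = cand[q, 4]
                if bp_mol[i, s_] >= 0 or bp_mol[j, t_] >= 0:
                    continue  # a site was consumed earlier this pass
                if np.random.random() < p_on:
                    bp_mol[i, s_] = j
                    bp_site[i, s_] = t_
                    b_rule[i, s_] = r_
                    b_time[i, s_] = tnow
                    b_break[i, s_] = UNSET
                    bp_mol[j, t_] = i
                    bp_site[j, t_] = s_
                    b_rule[j, t_] = r_
                    b_time[j, t_] = tnow
                    b_break[j, t_] = UNSET
                    bonds_changed = True

        # ---- end-of-step bookkeeping ----
        for q in range(nfroz):
            code = frozen_list[q]
            frozen[code // 2, code % 2] = False
        # retire this step's active marks, then wake dissociation sites
        # so their neighborhoods are re-probed next step
        for q in range(counters[C_NACTIVE]):
            active[active_list[q]] = 0
        counters[C_NACTIVE] = 0
        nw = counters[C_NWAKE]
        counters[C_NWAKE] = 0
        for q in range(nw):
            _mark_active(wake_list[q], active, active_list, counters)

        if bonds_changed:
            ncomp = _rebuild_components(
                n_mol, sp, s_cnt, bp_mol, b_rule, rule_immob,
                comp, mob, queue, comp_start, comp_items, comp_mob,
            )

        steps_done = k + 1
        if stride > 0 and (k0_record + k + 1) % stride == 0:
            c0 = 0
            c1 = 0
            c2 = 0
            c3 = 0
            for i2 in range(n_mol):
                for s2 in range(s_cnt[sp[i2]]):
                    j2 = bp_mol[i2, s2]
                    if j2 > i2:
                        rr = b_rule[i2, s2]
                        if rr == 0:
                            c0 += 1
                        elif rr == 1:
                            c1 += 1
                        elif rr == 2:
                            c2 += 1
                        else:
                            c3 += 1
            ts_out[nrec, 0] = tnow
            ts_out[nrec, 1] = c0
            ts_out[nrec, 2] = c1
            ts_out[nrec, 3] = c2
            ts_out[nrec, 4] = c3
            nrec += 1

    return steps_done, nrec, ncomp, nidx
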