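"""Compiled Monte Carlo engine.

The kernel advances the whole population in place on flat arrays.  Living
individuals occupy slots ``0..n-1``; a death moves the last slot into the
vacated one (swap-with-last), so uniform actor selection stays O(1).  The
cell list stores, per cell, a fixed-capacity array of member slots plus the
reverse maps ``cell_of``/``slot_of`` so insert/delete/move are O(1).

Random draw order per elementary step (shared with the pure-Python
reference layer in :mod:`mayleonard.dynamics`):

1. ``rng.integers(0, n)`` - actor slot;
2. ``rng.random()`` - action (u < m: move; u < m+p: predate; else reproduce);
3. move: one ``rng.random()`` for the direction;
   reproduce, only if the capacity check passes: two ``rng.random()`` for
   offspring radius then angle;
   predate: no further draws.

Status codes returned: 0 ok, 1 cell-capacity overflow, 2 population-array
overflow (the caller re-runs from the seed with larger buffers).
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CELL_OVERFLOW = 1
STATUS_POP_OVERFLOW = 2

TWO_PI = 2.0 * math.pi


@njit(cache=True, inline="always")
def _cell_index(xi, yi, inv_cell, n_side):
    ix = int(xi * inv_cell)
    if ix >= n_side:
        ix = n_side - 1
    iy = int(yi * inv_cell)
    if iy >= n_side:
        iy = n_side - 1
    return iy * n_side + ix


@njit(cache=True, inline="always")
def _min_image_sq(dx, dy, L):
    if dx > 0.5 * L:
        dx -= L
    elif dx < -0.5 * L:
        dx += L
    if dy > 0.5 * L:
        dy -= L
    elif dy < -0.5 * L:
        dy += L
    return dx * dx + dy * dy


@njit(cache=True)
def simulate(x, y, sp, n, counts, L, lp, lr, lo, lm, M, pm, pp,
             n_side, cell_cap, cell_count, cell_items, cell_of, slot_of,
             relax_steps, measure_steps, counts_out, ext_out, rng, use_grid):
    """Run relax_steps + measure_steps full MC steps; record counts per measured step.

    Mutates all array arguments in place and returns a status code.  On a
    nonzero status the trajectory is invalid and must be re-run with larger
    buffers.  ``ext_out[s]`` receives the 1-based global MC step at whose
    end species ``s`` first had zero individuals (-1 if never).
    """
    max_n = x.shape[0]
    inv_cell = n_side / L
    lp2 = lp * lp
    lr2 = lr * lr

    if use_grid:
        for c in range(n_side * n_side):
            cell_count[c] = 0
        for i in range(n):
            c = _cell_index(x[i], y[i], inv_cell, n_side)
            s = cell_count[c]
            if s >= cell_cap:
                return STATUS_CELL_OVERFLOW
            cell_items[c, s] = i
            cell_of[i] = c
            slot_of[i] = s
            cell_count[c] = s + 1

    total_steps = relax_steps + measure_steps
    for t in range(total_steps):
        n_start = n
        for _ in range(n_start):
            if n == 0:
                break
            i = rng.integers(0, n)
            u = rng.random()
            if u < pm:
                # -- movement: always succeeds ---------------------------
                theta = TWO_PI * rng.random()
                nx = (x[i] + lm * math.cos(theta)) % L
                ny = (y[i] + lm * math.sin(theta)) % L
                x[i] = nx
                y[i] = ny
                if use_grid:
                    c_new = _cell_index(nx, ny, inv_cell, n_side)
                    c_old = cell_of[i]
                    if c_new != c_old:
                        # remove from old cell (swap within cell)
                        s = slot_of[i]
                        last = cell_count[c_old] - 1
                        moved = cell_items[c_old, last]
                        cell_items[c_old, s] = moved
                        slot_of[moved] = s
                        cell_count[c_old] = last
                        # insert into new cell
                        s2 = cell_count[c_new]
                        if s2 >= cell_cap:
                            return STATUS_CELL_OVERFLOW
                        cell_items[c_new, s2] = i
                        cell_of[i] = c_new
                        slot_of[i] = s2
                        cell_count[c_new] = s2 + 1
            elif u < pm + pp:
                # -- predation: closest prey within lp dies ---------------
                prey = (sp[i] + 1) % 3
                cx = x[i]
                cy = y[i]
                best = -1
                best_d2 = lp2
                found = False
                if use_grid:
                    c0 = cell_of[i]
                    iy0 = c0 // n_side
                    ix0 = c0 - iy0 * n_side
                    for dyc in range(-1, 2):
                        iy = iy0 + dyc
                        if iy < 0:
                            iy += n_side
                        elif iy >= n_side:
                            iy -= n_side
                        for dxc in range(-1, 2):
                            ix = ix0 + dxc
                            if ix < 0:
                                ix += n_side
                            elif ix >= n_side:
                                ix -= n_side
                            c = iy * n_side + ix
                            for s in range(cell_count[c]):
                                j = cell_items[c, s]
                                if sp[j] != prey:
                                    continue
                                d2 = _min_image_sq(x[j] - cx, y[j] - cy, L)
                                if d2 <= best_d2 and (not found or d2 < best_d2):
                                    best = j
                                    best_d2 = d2
                                    found = True
                else:
                    for j in range(n):
                        if sp[j] != prey:
                            continue
                        d2 = _min_image_sq(x[j] - cx, y[j] - cy, L)
                        if d2 <= best_d2 and (not found or d2 < best_d2):
                            best = j
                            best_d2 = d2
                            found = True
                if found:
                    j = best
                    counts[prey] -= 1
                    if use_grid:
                        c = cell_of[j]
                        s = slot_of[j]
                        last = cell_count[c] - 1
                        moved = cell_items[c, last]
                        cell_items[c, s] = moved
                        slot_of[moved] = s
                        cell_count[c] = last
                    last_id = n - 1
                    if j != last_id:
                        x[j] = x[last_id]
                        y[j] = y[last_id]
                        sp[j] = sp[last_id]
                        if use_grid:
                            cell_of[j] = cell_of[last_id]
                            slot_of[j] = slot_of[last_id]
                            cell_items[cell_of[j], slot_of[j]] = j
                    n = last_id
            else:
                # -- reproduction: capacity-gated birth -------------------
                cx = x[i]
                cy = y[i]
                cnt = 0
                if use_grid:
                    c0 = cell_of[i]
                    iy0 = c0 // n_side
                    ix0 = c0 - iy0 * n_side
                    done = False
                    for dyc in range(-1, 2):
                        if done:
                            break
                        iy = iy0 + dyc
                        if iy < 0:
                            iy += n_side
                        elif iy >= n_side:
                            iy -= n_side
                        for dxc in range(-1, 2):
                            if done:
                                break
                            ix = ix0 + dxc
                            if ix < 0:
                                ix += n_side
                            elif ix >= n_side:
                                ix -= n_side
                            c = iy * n_side + ix
                            for s in range(cell_count[c]):
                                j = cell_items[c, s]
                                d2 = _min_image_sq(x[j] - cx, y[j] - cy, L)
                                if d2 <= lr2:
                                    cnt += 1
                                    if cnt >= M:
                                        done = True
                                        break
                else:
                    for j in range(n):
                        d2 = _min_image_sq(x[j] - cx, y[j] - cy, L)
                        if d2 <= lr2:
                            cnt += 1
                            if cnt >= M:
                                break
                if cnt < M:
                    u1 = rng.random()
                    u2 = rng.random()
                    rad = lo * math.sqrt(u1)
                    th = TWO_PI * u2
                    nx = (cx + rad * math.cos(th)) % L
                    ny = (cy + rad * math.sin(th)) % L
                    k = n
                    if k >= max_n:
                        return STATUS_POP_OVERFLOW
                    x[k] = nx
                    y[k] = ny
                    sp[k] = sp[i]
                    counts[sp[i]] += 1
                    if use_grid:
                        c = _cell_index(nx, ny, inv_cell, n_side)
                        s = cell_count[c]
                        if s >= cell_cap:
                            return STATUS_CELL_OVERFLOW
                        cell_items[c, s] = k
                        cell_of[k] = c
                        slot_of[k] = s
                        cell_count[c] = s + 1
                    n = k + 1
        for s in range(3):
            if counts[s] == 0 and ext_out[s] < 0:
                ext_out[s] = t + 1
        if t >= relax_steps:
            m_idx = t - relax_steps
            counts_out[m_idx, 0] = counts[0]
            counts_out[m_idx, 1] = counts[1]
            counts_out[m_idx, 2] = counts[2]
    return STATUS_OK
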