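"""Compiled event loop for the birth-death simulation.

The kernel advances the tissue event by event inside one @njit function,
returning to Python only for rare bookkeeping (mutation-log drain, crypt
extinction/fission registration, array growth, RNG-buffer refill) and at
endpoints.  All randomness is consumed from a pre-drawn uniform buffer
filled by the run's seeded numpy Generator, so runs are bit-reproducible.

Scheduling: per event, each kind (symmetric division, cell loss,
asymmetric division) draws one exponential waiting time at its aggregate
rate, floored at its minimum time; the earliest kind fires and the cell
is chosen rate-proportionally within the kind.  For clocks sharing a
common floor F, ``min_i max(T_i, F) == max(min_i T_i, F)`` and the argmin
of competing exponentials is rate-proportional whatever the minimum's
value, so this per-kind aggregation reproduces per-cell floored clocks
exactly.

In thinned mode (the default for full runs), asymmetric divisions that
would produce no mutation are integrated out: the asymmetric kind fires
at rate ``a_i * P(any mutation)`` and silent divisions are counted by a
Poisson draw per inter-event interval.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- status codes returned to the Python driver -----------------------
EVENT = 0          # an event fired that needs Python-side logging
REFILL = 1         # uniform buffer nearly exhausted
GROW = 2           # cell arrays nearly full
MUTLOG_FULL = 3    # mutation log buffer nearly full
CENSORED = 4
INITIATION = 5
TISSUE_DEAD = 6
UNCONTROLLED = 7

# --- event kinds / flags ----------------------------------------------
KIND_SYM = 0
KIND_LOSS = 1
KIND_ASYM = 2

FLAG_MUTATION = 1
FLAG_EXTINCTION = 2
FLAG_BIFURCATION = 4

# --- PF (float params) layout -----------------------------------------
PF_R_DIV = 0
PF_RATIO = 1
PF_R_LOSS = 2
PF_K_SIZE = 3
PF_INV_DEV = 4
PF_DIV_BASE = 5
PF_LOSS_BASE = 6
PF_DEAD_MULT = 7
PF_DIV_MIN = 8
PF_LOSS_MIN = 9
PF_MAX_DAYS = 10
PF_G_BASE = 11
PF_G_MUT = 12
PF_TAU_BASE = 13
PF_TAU_MUT = 14
PF_DEL_FRAC = 15
PF_DEL_SPLIT0 = 16
PF_BEN0 = 17
PF_BEN01 = 18
PF_BIF_THRESHOLD = 19
PF_UNCONTROLLED_CELLS = 20
PF_K_FIT = 21
PF_INV_K = 22
PF_N = 23

# --- PI (int params) layout -------------------------------------------
PI_N_SLOTS = 0
PI_TSG_THRESHOLD = 1
PI_THIN = 2
PI_RECORD_ALL = 3
PI_UNCONTROLLED_ON = 4
PI_N = 5

# --- S (int state) layout ---------------------------------------------
S_N_CELLS = 0
S_LIVING = 1
S_NEXT_ID = 2
S_BUF_POS = 3
S_MUT_COUNT = 4
S_N = 5

# --- T (float accumulators) layout ------------------------------------
T_TIME = 0
T_INT_CELLS = 1        # integral of total cells dt
T_INT_PER_CRYPT = 2    # integral of (cells / living crypts) dt
T_N_SYM = 3
T_N_ASYM = 4           # includes silent (thinned) asymmetric divisions
T_N_LOSS = 5
T_N_GENERAL_MUT = 6
T_N_TSG_MUT = 7
T_N = 8

# --- info_i layout -----------------------------------------------------
II_KIND = 0
II_CELL_ID = 1
II_SLOT = 2
II_N_AFTER = 3
II_TSG_AFTER = 4
II_FLAGS = 5
II_EXTINCT_SLOT = 6
II_BIF_TARGET = 7
II_BIF_PARENT = 8
II_BIF_MOVED = 9
II_INIT_MUTATOR = 10
II_N = 11

# Mutation-log integer columns: category, cell_id, slot, tsg_after
ML_COLS = 4

_HEADROOM = 4096


@njit(cache=False)
def _u(U, S):
    v = U[S[S_BUF_POS]]
    S[S_BUF_POS] += 1
    return v


@njit(cache=False)
def _exp_floored(rate, floor, U, S):
    if rate <= 0.0:
        return np.inf
    t = -np.log(1.0 - _u(U, S)) / rate
    if t < floor:
        t = floor
    return t


@njit(cache=False)
def _poisson(lam, U, S):
    if lam <= 0.0:
        return 0
    if lam > 64.0:
        # normal approximation via Box-Muller; reporting counts only
        u1 = _u(U, S)
        if u1 < 1e-300:
            u1 = 1e-300
        u2 = _u(U, S)
        z = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
        v = lam + np.sqrt(lam) * z
        if v < 0.0:
            return 0
        return int(v + 0.5)
    limit = np.exp(-lam)
    k = 0
    prod = 1.0
    while True:
        prod *= _u(U, S)
        if prod <= limit:
            return k
        k += 1
        if k > 2000:  # unreachable guard
            return k


@njit(cache=False)
def compute_feedback(crypt_counts, dead, dead_nbrs, PF, DF, LF):
    """Per-slot division and loss feedback multipliers (in place)."""
    for s in range(crypt_counts.shape[0]):
        if dead[s] == 1:
            DF[s] = 0.0
            LF[s] = 0.0
            continue
        df = 1.0
        deficit = PF[PF_K_SIZE] - crypt_counts[s]
        if deficit > 0.0 and PF[PF_INV_DEV] > 0.0:
            df = PF[PF_DIV_BASE] ** (deficit * PF[PF_INV_DEV])
        lf = 1.0
        if dead_nbrs[s] > 0:
            df *= PF[PF_DEAD_MULT] ** dead_nbrs[s]
        else:
            excess = crypt_counts[s] - PF[PF_K_SIZE]
            if excess > 0.0 and PF[PF_INV_DEV] > 0.0:
                lf = PF[PF_LOSS_BASE] ** (excess * PF[PF_INV_DEV])
        DF[s] = df
        LF[s] = lf


@njit(cache=False)
def compute_cell_rates(n, crypt_of, div_fit, loss_fit, mut, PF, thin,
                       DF, LF, SC, LC, MC):
    """Per-cell clock rates; returns (Rs, Rl, Rm) aggregate sums."""
    Rs = 0.0
    Rl = 0.0
    Rm = 0.0
    for i in range(n):
        c = crypt_of[i]
        s_i = PF[PF_R_DIV] * div_fit[i] * DF[c]
        l_i = PF[PF_R_LOSS] * loss_fit[i] * LF[c]
        a_i = PF[PF_RATIO] * s_i
        if thin == 1:
            if mut[i] == 1:
                g = PF[PF_G_MUT]
                tau = PF[PF_TAU_MUT]
            else:
                g = PF[PF_G_BASE]
                tau = PF[PF_TAU_BASE]
            m_i = a_i * (g + tau - g * tau)
        else:
            m_i = a_i
        SC[i] = s_i
        LC[i] = l_i
        MC[i] = m_i
        Rs += s_i
        Rl += l_i
        Rm += m_i
    return Rs, Rl, Rm


@njit(cache=False)
def _select_cell(rates, n, total, U, S):
    target = _u(U, S) * total
    acc = 0.0
    last = 0
    for i in range(n):
        if rates[i] > 0.0:
            last = i
            acc += rates[i]
            if acc >= target:
                return i
    return last


@njit(cache=False)
def _refresh_dead_neighbors(dead, dead_nbrs, nbr_flat, nbr_start):
    for s in range(dead_nbrs.shape[0]):
        cnt = 0
        for j in range(nbr_start[s], nbr_start[s + 1]):
            if dead[nbr_flat[j]] == 1:
                cnt += 1
        dead_nbrs[s] = cnt


@njit(cache=False)
def _refresh_fitness(i, nbd, nbs, ndd, nds, div_fit, loss_fit, PF):
    k = PF[PF_K_FIT]
    inv_k = PF[PF_INV_K]
    div_fit[i] = k ** np.int64(nbd[i]) * inv_k ** np.int64(ndd[i])
    loss_fit[i] = k ** np.int64(nds[i]) * inv_k ** np.int64(nbs[i])


@njit(cache=False)
def _log_mutation(cat, i, t, S, cell_id, crypt_of, tsg, mut_t, mut_i):
    m = S[S_MUT_COUNT]
    mut_t[m] = t
    mut_i[m, 0] = cat
    mut_i[m, 1] = cell_id[i]
    mut_i[m, 2] = crypt_of[i]
    mut_i[m, 3] = tsg[i]
    S[S_MUT_COUNT] = m + 1


@njit(cache=False)
def _apply_general(i, u_cat, PF, nbd, nbs, ndd, nds, mut, div_fit, loss_fit):
    """Apply a general mutation drawn from ``u_cat``; returns category."""
    d = PF[PF_DEL_FRAC]
    if u_cat < d:
        if u_cat < d * PF[PF_DEL_SPLIT0]:
            ndd[i] += 1
            cat = 0  # deleterious_div
        else:
            nds[i] += 1
            cat = 1  # deleterious_surv
    else:
        if d < 1.0:
            b = (u_cat - d) / (1.0 - d)
        else:
            b = 0.0
        if b < PF[PF_BEN0]:
            nbd[i] += 1
            cat = 2  # beneficial_div
        elif b < PF[PF_BEN01]:
            nbs[i] += 1
            cat = 3  # beneficial_surv
        else:
            mut[i] = 1  # no further effect on an existing mutator
            cat = 4  # mutator
    _refresh_fitness(i, nbd, nbs, ndd, nds, div_fit, loss_fit, PF)
    return cat


@njit(cache=False)
def run_kernel(nbd, nbs, ndd, nds, mut, tsg, crypt_of, cell_id, birth_t,
               div_fit, loss_fit,
               crypt_counts, dead, dead_nbrs, nbr_flat, nbr_start,
               PF, PI, S, T, U,
               DF, LF, SC, LC, MC, MEMB,
               mut_t, mut_i, info_f, info_i):
    """Advance the tissue until an exit condition; returns a status code."""
    n_slots = PI[PI_N_SLOTS]
    thin = PI[PI_THIN]
    record_all = PI[PI_RECORD_ALL]
    cap = nbd.shape[0]
    tsg_threshold = PI[PI_TSG_THRESHOLD]

    while True:
        if U.shape[0] - S[S_BUF_POS] < _HEADROOM:
            return REFILL
        if S[S_N_CELLS] >= cap - 2:
            return GROW
        if S[S_MUT_COUNT] >= mut_t.shape[0] - 8:
            return MUTLOG_FULL

        n = S[S_N_CELLS]
        compute_feedback(crypt_counts, dead, dead_nbrs, PF, DF, LF)
        Rs, Rl, Rm = compute_cell_rates(n, crypt_of, div_fit, loss_fit, mut,
                                        PF, thin, DF, LF, SC, LC, MC)

        ts = _exp_floored(Rs, PF[PF_DIV_MIN], U, S)
        tl = _exp_floored(Rl, PF[PF_LOSS_MIN], U, S)
        tm = _exp_floored(Rm, PF[PF_DIV_MIN], U, S)

        dt = ts
        kind = KIND_SYM
        if tl < dt:
            dt = tl
            kind = KIND_LOSS
        if tm < dt:
            dt = tm
            kind = KIND_ASYM
        # Floored ties between the two division kinds: rate-proportional.
        if kind == KIND_SYM and tm == ts and np.isfinite(ts):
            if _u(U, S) * (Rs + Rm) >= Rs:
                kind = KIND_ASYM

        if T[T_TIME] + dt >= PF[PF_MAX_DAYS] or not np.isfinite(dt):
            gap = PF[PF_MAX_DAYS] - T[T_TIME]
            T[T_INT_CELLS] += n * gap
            if S[S_LIVING] > 0:
                T[T_INT_PER_CRYPT] += (n / S[S_LIVING]) * gap
            if thin == 1:
                T[T_N_ASYM] += _poisson((PF[PF_RATIO] * Rs - Rm) * gap, U, S)
            T[T_TIME] = PF[PF_MAX_DAYS]
            return CENSORED

        T[T_INT_CELLS] += n * dt
        T[T_INT_PER_CRYPT] += (n / S[S_LIVING]) * dt
        if thin == 1:
            T[T_N_ASYM] += _poisson((PF[PF_RATIO] * Rs - Rm) * dt, U, S)
        T[T_TIME] += dt
        t_now = T[T_TIME]

        flags = 0
        info_i[II_FLAGS] = 0
        info_i[II_EXTINCT_SLOT] = -1
        info_i[II_BIF_TARGET] = -1
        info_f[0] = t_now

        if kind == KIND_SYM:
            i = _select_cell(SC, n, Rs, U, S)
            c = crypt_of[i]
            T[T_N_SYM] += 1.0
            # birth: append a daughter inheriting the parent's full state
            j = S[S_N_CELLS]
            nbd[j] = nbd[i]
            nbs[j] = nbs[i]
            ndd[j] = ndd[i]
            nds[j] = nds[i]
            mut[j] = mut[i]
            tsg[j] = tsg[i]
            crypt_of[j] = c
            div_fit[j] = div_fit[i]
            loss_fit[j] = loss_fit[i]
            cell_id[j] = S[S_NEXT_ID]
            birth_t[j] = t_now
            S[S_NEXT_ID] += 1
            S[S_N_CELLS] += 1
            crypt_counts[c] += 1

            info_i[II_KIND] = KIND_SYM
            info_i[II_CELL_ID] = cell_id[i]
            info_i[II_SLOT] = c
            info_i[II_TSG_AFTER] = tsg[i]

            # each daughter gets one mutation opportunity
            for d_idx in range(2):
                cell = i if d_idx == 0 else j
                if mut[cell] == 1:
                    g = PF[PF_G_MUT]
                    tau = PF[PF_TAU_MUT]
                else:
                    g = PF[PF_G_BASE]
                    tau = PF[PF_TAU_BASE]
                if _u(U, S) < g:
                    cat = _apply_general(cell, _u(U, S), PF, nbd, nbs, ndd,
                                         nds, mut, div_fit, loss_fit)
                    T[T_N_GENERAL_MUT] += 1.0
                    _log_mutation(cat, cell, t_now, S, cell_id, crypt_of,
                                  tsg, mut_t, mut_i)
                    flags |= FLAG_MUTATION
                if _u(U, S) < tau:
                    if tsg[cell] < tsg_threshold:
                        tsg[cell] += 1
                    T[T_N_TSG_MUT] += 1.0
                    _log_mutation(5, cell, t_now, S, cell_id, crypt_of,
                                  tsg, mut_t, mut_i)
                    flags |= FLAG_MUTATION
                    info_i[II_TSG_AFTER] = tsg[cell]
                    if tsg[cell] >= tsg_threshold:
                        info_i[II_FLAGS] = flags
                        info_i[II_N_AFTER] = crypt_counts[c]
                        info_i[II_INIT_MUTATOR] = mut[cell]
                        return INITIATION

            info_i[II_N_AFTER] = crypt_counts[c]
            if PI[PI_UNCONTROLLED_ON] == 1 and \
                    crypt_counts[c] >= PF[PF_UNCONTROLLED_CELLS]:
                info_i[II_FLAGS] = flags
                return UNCONTROLLED

            # fission check: at threshold and bordering a dead slot
            if crypt_counts[c] >= PF[PF_BIF_THRESHOLD]:
                n_dead = 0
                for jj in range(nbr_start[c], nbr_start[c + 1]):
                    if dead[nbr_flat[jj]] == 1:
                        n_dead += 1
                if n_dead > 0:
                    pick = int(_u(U, S) * n_dead)
                    if pick >= n_dead:
                        pick = n_dead - 1
                    target = -1
                    seen = 0
                    for jj in range(nbr_start[c], nbr_start[c + 1]):
                        if dead[nbr_flat[jj]] == 1:
                            if seen == pick:
                                target = nbr_flat[jj]
                                break
                            seen += 1
                    # uniform half of the members move (without replacement)
                    m = 0
                    for idx in range(S[S_N_CELLS]):
                        if crypt_of[idx] == c:
                            MEMB[m] = idx
                            m += 1
                    n_move = m // 2
                    for x in range(n_move):
                        pickx = x + int(_u(U, S) * (m - x))
                        if pickx >= m:
                            pickx = m - 1
                        tmp = MEMB[x]
                        MEMB[x] = MEMB[pickx]
                        MEMB[pickx] = tmp
                        crypt_of[MEMB[x]] = target
                    crypt_counts[c] -= n_move
                    crypt_counts[target] += n_move
                    dead[target] = 0
                    S[S_LIVING] += 1
                    _refresh_dead_neighbors(dead, dead_nbrs, nbr_flat, nbr_start)
                    flags |= FLAG_BIFURCATION
                    info_i[II_BIF_TARGET] = target
                    info_i[II_BIF_PARENT] = c
                    info_i[II_BIF_MOVED] = n_move
                    info_i[II_N_AFTER] = crypt_counts[c]

        elif kind == KIND_LOSS:
            i = _select_cell(LC, n, Rl, U, S)
            c = crypt_of[i]
            T[T_N_LOSS] += 1.0
            info_i[II_KIND] = KIND_LOSS
            info_i[II_CELL_ID] = cell_id[i]
            info_i[II_SLOT] = c
            info_i[II_TSG_AFTER] = tsg[i]
            last = S[S_N_CELLS] - 1
            if i != last:
                nbd[i] = nbd[last]
                nbs[i] = nbs[last]
                ndd[i] = ndd[last]
                nds[i] = nds[last]
                mut[i] = mut[last]
                tsg[i] = tsg[last]
                crypt_of[i] = crypt_of[last]
                cell_id[i] = cell_id[last]
                birth_t[i] = birth_t[last]
                div_fit[i] = div_fit[last]
                loss_fit[i] = loss_fit[last]
            S[S_N_CELLS] = last
            crypt_counts[c] -= 1
            info_i[II_N_AFTER] = crypt_counts[c]
            if crypt_counts[c] == 0:
                dead[c] = 1
                S[S_LIVING] -= 1
                _refresh_dead_neighbors(dead, dead_nbrs, nbr_flat, nbr_start)
                flags |= FLAG_EXTINCTION
                info_i[II_EXTINCT_SLOT] = c
                if S[S_LIVING] == 0:
                    info_i[II_FLAGS] = flags
                    return TISSUE_DEAD

        else:  # KIND_ASYM: population unchanged, one mutation opportunity
            i = _select_cell(MC, n, Rm, U, S)
            c = crypt_of[i]
            T[T_N_ASYM] += 1.0
            info_i[II_KIND] = KIND_ASYM
            info_i[II_CELL_ID] = cell_id[i]
            info_i[II_SLOT] = c
            info_i[II_N_AFTER] = crypt_counts[c]
            info_i[II_TSG_AFTER] = tsg[i]
            if mut[i] == 1:
                g = PF[PF_G_MUT]
                tau = PF[PF_TAU_MUT]
            else:
                g = PF[PF_G_BASE]
                tau = PF[PF_TAU_BASE]
            do_general = False
            do_tsg = False
            if thin == 1:
                # conditioned on >= 1 mutation at this opportunity
                p_any = g + tau - g * tau
                u = _u(U, S) * p_any
                if u < g * (1.0 - tau):
                    do_general = True
                elif u < g:
                    do_general = True
                    do_tsg = True
                else:
                    do_tsg = True
            else:
                do_general = _u(U, S) < g
                do_tsg = _u(U, S) < tau
            if do_general:
                cat = _apply_general(i, _u(U, S), PF, nbd, nbs, ndd,
                                     nds, mut, div_fit, loss_fit)
                T[T_N_GENERAL_MUT] += 1.0
                _log_mutation(cat, i, t_now, S, cell_id, crypt_of,
                              tsg, mut_t, mut_i)
                flags |= FLAG_MUTATION
            if do_tsg:
                if tsg[i] < tsg_threshold:
                    tsg[i] += 1
                T[T_N_TSG_MUT] += 1.0
                _log_mutation(5, i, t_now, S, cell_id, crypt_of,
                              tsg, mut_t, mut_i)
                flags |= FLAG_MUTATION
                info_i[II_TSG_AFTER] = tsg[i]
                if tsg[i] >= tsg_threshold:
                    info_i[II_FLAGS] = flags
                    info_i[II_INIT_MUTATOR] = mut[i]
                    return INITIATION

        info_i[II_FLAGS] = flags
        if record_all == 1 or flags != 0:
            return EVENT
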