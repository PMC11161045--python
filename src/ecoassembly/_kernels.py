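"""Compiled inner loops: the Moran assembly event loop and the coalescent.

Everything here is numba-njit compiled and operates on flat arrays; the
user-facing containers live in :mod:`ecoassembly.assembly` and
:mod:`ecoassembly.popgen`.  The event loop maintains species-level
aggregates (kernel sums, member lists) so each death-birth event costs
O(S) in the number of extant species rather than O(J) or O(J^2); a full
O(S^2) refresh of the pairwise kernel sums runs once per generation to
bound floating-point drift from the incremental updates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# model codes shared with ecoassembly.assembly
NEUTRAL = 0
FILTERING = 1
MEAN = 2
PAIRWISE = 3
BETA = 4

# exponent clamp: exp(x) for x < -700 underflows; treat as exact zero
_EXP_CLAMP = -700.0
_TINY = 1e-300


@njit(cache=True)
def _kexp(x: float) -> float:
    if x < _EXP_CLAMP:
        return 0.0
    v = np.exp(x)
    if v < _TINY:
        return 0.0
    return v


@njit(cache=True)
def run_assembly(
    model,
    J,
    m,
    nu,
    s_E,
    z_E,
    beta_intra,
    beta_inter,
    meta_cum,
    meta_trait,
    sigma_sp,
    lambda_target,
    max_gens,
    seed,
):
    """Run the zero-sum death-birth loop for up to ``max_gens`` generations.

    One generation = J single-death events.  Stops early once the fraction
    of post-start colonist descendants (Lambda) reaches ``lambda_target``
    (pass a negative target to disable).  Returns per-generation history
    rows (generation 0 = initial state) plus the final per-slot species
    table and per-individual state.
    """
    np.random.seed(seed)
    n_meta = meta_cum.shape[0]
    S_cap = J + 2

    sp_of = np.empty(J, np.int64)
    colonist = np.zeros(J, np.uint8)
    pos_in_sp = np.empty(J, np.int64)
    members = np.zeros((S_cap, J), np.int32)
    n_of = np.zeros(S_cap, np.int64)

    slot_trait = np.zeros(S_cap)
    slot_rfilt = np.zeros(S_cap)  # static filtering death rate per species
    slot_meta = np.full(S_cap, -1, np.int64)
    slot_uid = np.full(S_cap, -1, np.int64)
    slot_colgen = np.zeros(S_cap)
    meta_to_slot = np.full(n_meta, -1, np.int64)

    active = np.empty(S_cap, np.int64)
    act_pos = np.full(S_cap, -1, np.int64)
    n_active = 0
    free_stack = np.empty(S_cap, np.int64)
    for i in range(S_cap):
        free_stack[i] = S_cap - 1 - i
    n_free = S_cap

    use_pair = model == PAIRWISE or model == BETA
    if use_pair:
        K = np.zeros((S_cap, S_cap))
    else:
        K = np.zeros((1, 1))
    C = np.zeros(S_cap)  # C[a] = sum_b n_b * K[a, b] over active slots

    hist_ab = np.zeros((max_gens + 1, S_cap), np.int32)
    hist_lam = np.zeros(max_gens + 1)
    hist_S = np.zeros(max_gens + 1, np.int64)
    hist_zbar = np.zeros(max_gens + 1)

    w = np.zeros(S_cap)  # scratch: per-active-slot death weight

    # --- initialise: one founder species, abundance-weighted draw ---
    u0 = np.random.random()
    msp = np.searchsorted(meta_cum, u0)
    if msp >= n_meta:
        msp = n_meta - 1
    founder = free_stack[n_free - 1]
    n_free -= 1
    slot_trait[founder] = meta_trait[msp]
    d0 = meta_trait[msp] - z_E
    slot_rfilt[founder] = 1.0 - _kexp(-s_E * d0 * d0)
    slot_meta[founder] = msp
    slot_uid[founder] = 0
    slot_colgen[founder] = 0.0
    meta_to_slot[msp] = founder
    active[0] = founder
    act_pos[founder] = 0
    n_active = 1
    next_uid = 1
    for i in range(J):
        sp_of[i] = founder
        members[founder, i] = i
        pos_in_sp[i] = i
    n_of[founder] = J
    if use_pair:
        K[founder, founder] = 1.0
        C[founder] = float(J)
    zsum = float(J) * meta_trait[msp]
    ncol = 0

    hist_ab[0, founder] = J
    hist_lam[0] = 0.0
    hist_S[0] = 1
    hist_zbar[0] = zsum / J

    gens_done = 0
    truncated = False
    reached = lambda_target <= 0.0

    for g in range(1, max_gens + 1):
        for e in range(J):
            # ---------------- choose the victim ----------------
            if model == NEUTRAL:
                v = int(np.random.random() * J)
                if v >= J:
                    v = J - 1
                a = sp_of[v]
            else:
                W = 0.0
                if model == FILTERING:
                    for ia in range(n_active):
                        s = active[ia]
                        w[ia] = n_of[s] * slot_rfilt[s]
                        W += w[ia]
                elif model == MEAN:
                    zbar = zsum / J
                    for ia in range(n_active):
                        s = active[ia]
                        d = slot_trait[s] - zbar
                        w[ia] = n_of[s] * _kexp(-s_E * d * d)
                        W += w[ia]
                else:  # PAIRWISE or BETA
                    for ia in range(n_active):
                        s = active[ia]
                        na = n_of[s]
                        q = beta_inter * (C[s] - na) + beta_intra * (na - 1.0)
                        if q < 0.0:
                            q = 0.0  # guard against incremental round-off
                        w[ia] = na * q
                        W += w[ia]
                if W <= 0.0:
                    # degenerate rate vector: fall back to the neutral draw
                    v = int(np.random.random() * J)
                    if v >= J:
                        v = J - 1
                    a = sp_of[v]
                else:
                    u = np.random.random() * W
                    acc = 0.0
                    ia_hit = n_active - 1
                    for ia in range(n_active):
                        acc += w[ia]
                        if u < acc:
                            ia_hit = ia
                            break
                    a = active[ia_hit]
                    kidx = int(np.random.random() * n_of[a])
                    if kidx >= n_of[a]:
                        kidx = n_of[a] - 1
                    v = members[a, kidx]

            # ---------------- remove the victim ----------------
            kpos = pos_in_sp[v]
            last = members[a, n_of[a] - 1]
            members[a, kpos] = last
            pos_in_sp[last] = kpos
            n_of[a] -= 1
            zsum -= slot_trait[a]
            if colonist[v] == 1:
                ncol -= 1
            if use_pair:
                for ia in range(n_active):
                    s = active[ia]
                    C[s] -= K[s, a]
            if n_of[a] == 0:
                # species extinct: free the slot
                pa = act_pos[a]
                moved = active[n_active - 1]
                active[pa] = moved
                act_pos[moved] = pa
                n_active -= 1
                act_pos[a] = -1
                free_stack[n_free] = a
                n_free += 1
                if slot_meta[a] >= 0:
                    meta_to_slot[slot_meta[a]] = -1

            # ---------------- choose the replacement ----------------
            gen_time = (g - 1) + e / J
            b = -1
            flag = np.uint8(1)
            if np.random.random() < m:
                # immigrant from the regional pool
                um = np.random.random()
                imsp = np.searchsorted(meta_cum, um)
                if imsp >= n_meta:
                    imsp = n_meta - 1
                b = meta_to_slot[imsp]
                if b < 0:
                    # new local colonisation of a metacommunity species
                    b = free_stack[n_free - 1]
                    n_free -= 1
                    slot_trait[b] = meta_trait[imsp]
                    db = meta_trait[imsp] - z_E
                    slot_rfilt[b] = 1.0 - _kexp(-s_E * db * db)
                    slot_meta[b] = imsp
                    slot_uid[b] = next_uid
                    next_uid += 1
                    slot_colgen[b] = gen_time
                    meta_to_slot[imsp] = b
                    active[n_active] = b
                    act_pos[b] = n_active
                    n_active += 1
                    n_of[b] = 0
                    if use_pair:
                        Cb = 0.0
                        zb = slot_trait[b]
                        for ia in range(n_active):
                            s = active[ia]
                            dz = zb - slot_trait[s]
                            kv = _kexp(-s_E * dz * dz)
                            K[b, s] = kv
                            K[s, b] = kv
                            Cb += n_of[s] * kv
                        K[b, b] = 1.0
                        C[b] = Cb
            else:
                # local birth: uniform parent among the J-1 survivors
                p = int(np.random.random() * J)
                if p >= J:
                    p = J - 1
                while p == v:
                    p = int(np.random.random() * J)
                    if p >= J:
                        p = J - 1
                if nu > 0.0 and np.random.random() < nu:
                    # point-mutation speciation
                    b = free_stack[n_free - 1]
                    n_free -= 1
                    zb = slot_trait[sp_of[p]] + np.random.normal(0.0, sigma_sp)
                    slot_trait[b] = zb
                    db = zb - z_E
                    slot_rfilt[b] = 1.0 - _kexp(-s_E * db * db)
                    slot_meta[b] = -1
                    slot_uid[b] = next_uid
                    next_uid += 1
                    slot_colgen[b] = gen_time
                    active[n_active] = b
                    act_pos[b] = n_active
                    n_active += 1
                    n_of[b] = 0
                    if use_pair:
                        Cb = 0.0
                        for ia in range(n_active):
                            s = active[ia]
                            dz = zb - slot_trait[s]
                            kv = _kexp(-s_E * dz * dz)
                            K[b, s] = kv
                            K[s, b] = kv
                            Cb += n_of[s] * kv
                        K[b, b] = 1.0
                        C[b] = Cb
                else:
                    b = sp_of[p]
                    flag = colonist[p]

            # ---------------- place the newborn at index v ----------------
            sp_of[v] = b
            members[b, n_of[b]] = v
            pos_in_sp[v] = n_of[b]
            n_of[b] += 1
            zsum += slot_trait[b]
            colonist[v] = flag
            if flag == 1:
                ncol += 1
            if use_pair:
                for ia in range(n_active):
                    s = active[ia]
                    C[s] += K[s, b]

        # ----- end of generation: refresh aggregates, record history -----
        zs = 0.0
        for ia in range(n_active):
            s = active[ia]
            zs += n_of[s] * slot_trait[s]
        zsum = zs
        if use_pair:
            for ia in range(n_active):
                s = active[ia]
                Cs = 0.0
                for ib in range(n_active):
                    t = active[ib]
                    Cs += n_of[t] * K[s, t]
                C[s] = Cs

        for ia in range(n_active):
            s = active[ia]
            hist_ab[g, s] = np.int32(n_of[s])
        lam = ncol / J
        hist_lam[g] = lam
        hist_S[g] = n_active
        hist_zbar[g] = zsum / J
        gens_done = g
        if lambda_target > 0.0 and lam >= lambda_target:
            reached = True
            break

    if not reached:
        truncated = True

    return (
        gens_done,
        truncated,
        hist_ab,
        hist_lam,
        hist_S,
        hist_zbar,
        slot_trait,
        slot_colgen,
        slot_meta,
        slot_uid,
        sp_of,
        colonist.astype(np.bool_),
        n_of,
    )


@njit(cache=True)
def coalesce_pi(sizes, durations, n, mu_total, seed):
    """Hudson coalescent with piecewise-constant haploid Ne, infinite sites.

    ``sizes``/``durations`` describe epochs backward in time from the
    sampling point; the last duration may be ``inf`` (the source pool).
    ``mu_total`` is the per-generation mutation rate over the whole locus.
    Returns (pi_locus, segregating_sites, tmrca) where ``pi_locus`` is the
    mean pairwise difference count per haplotype pair (not yet per site).
    """
    np.random.seed(seed)
    nn = 2 * n - 1
    t_node = np.zeros(nn)
    nleaf = np.zeros(nn, np.int64)
    parent = np.full(nn, -1, np.int64)
    act = np.empty(n, np.int64)
    for i in range(n):
        act[i] = i
        nleaf[i] = 1
    k = n
    next_node = n
    t = 0.0
    ep = 0
    n_ep = sizes.shape[0]
    ep_end = durations[0]
    while k > 1:
        N = sizes[ep]
        rate = k * (k - 1) / 2.0 / N
        wtime = np.random.exponential(1.0 / rate)
        if t + wtime > ep_end and ep < n_ep - 1:
            t = ep_end
            ep += 1
            ep_end += durations[ep]
            continue
        t += wtime
        i = int(np.random.random() * k)
        if i >= k:
            i = k - 1
        j = int(np.random.random() * (k - 1))
        if j >= k - 1:
            j = k - 2
        if j >= i:
            j += 1
        a = act[i]
        b = act[j]
        node = next_node
        next_node += 1
        t_node[node] = t
        parent[a] = node
        parent[b] = node
        nleaf[node] = nleaf[a] + nleaf[b]
        lo = i if i < j else j
        hi = j if i < j else i
        act[lo] = node
        act[hi] = act[k - 1]
        k -= 1

    seg = 0
    psum = 0.0
    for nd in range(nn - 1):
        bl = t_node[parent[nd]] - t_node[nd]
        muts = np.random.poisson(mu_total * bl)
        if muts > 0:
            seg += muts
            d = nleaf[nd]
            psum += muts * d * (n - d)
    pairs = n * (n - 1) / 2.0
    return psum / pairs, seg, t_node[nn - 1]
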