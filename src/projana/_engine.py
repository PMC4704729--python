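"""Compiled core of the serial-sampling coalescent simulator.

One genealogy per independent locus: lineages enter at their sampling times,
coalesce within demes at rate C(k,2)/(2N) under piecewise-constant N, and
move between demes at pulse and split events.  The kernel tracks, for every
branch, the number of panel leaves it subtends and whether it subtends the
test leaf — that is all the projection needs — so no explicit tree is built.

Mutations follow the infinite-sites model: a genealogy contributes
polymorphic sites in proportion to its total branch length, and each site's
mutation falls on a branch chosen proportionally to that branch's length.
The sampled path realises this by drawing a Poisson number of sites per tree
(rate calibrated so one site is expected per tree); the expectation path
accumulates every branch's raw length into a (panel count, test flag) table,
integrating the mutation placement out analytically.

Everything here operates on flat arrays prepared by
:func:`projana.coalescent._flatten_model`; the public API lives in
:mod:`projana.coalescent`.
"""

import numpy as np
from numba import njit

# event kind codes (pulses sort before splits at equal times)
PULSE = 0
SPLIT = 1

# kernel modes
MODE_EXPECTED = 0
MODE_SAMPLED = 1


@njit(cache=True, inline="always")
def _deme_size(t, d, ep_start, ep_N, ep_off):
    """Diploid size of deme d at time t (last epoch with start <= t)."""
    n = ep_N[ep_off[d]]
    for j in range(ep_off[d], ep_off[d + 1]):
        if ep_start[j] <= t:
            n = ep_N[j]
        else:
            break
    return n


@njit(cache=True)
def _one_tree(
    n_demes, ep_start, ep_N, ep_off,
    ev_time, ev_kind, ev_a, ev_b, ev_frac,
    smp_time, smp_deme, smp_count, smp_istest,
    bp_times,
    birth, pcount, istest, member, kcount,
    br_len, br_p, br_t,
):
    """Simulate one genealogy; fill the branch table and return its size
    (negative on stranded lineages)."""
    total_samples = 0
    for g in range(smp_count.shape[0]):
        total_samples += smp_count[g]
    n_ev = ev_time.shape[0]
    n_smp = smp_time.shape[0]
    n_bp = bp_times.shape[0]

    next_id = 0
    for d in range(n_demes):
        kcount[d] = 0
    n_branch = 0
    smp_i = 0
    ev_i = 0
    bp_i = 0
    entered = 0
    n_active = 0
    t = 0.0

    while True:
        # sample groups entering at (or before) the current time
        while smp_i < n_smp and smp_time[smp_i] <= t:
            d = smp_deme[smp_i]
            for _ in range(smp_count[smp_i]):
                lid = next_id
                next_id += 1
                birth[lid] = smp_time[smp_i]
                if smp_istest[smp_i] == 1:
                    pcount[lid] = 0
                    istest[lid] = 1
                else:
                    pcount[lid] = 1
                    istest[lid] = 0
                member[d, kcount[d]] = lid
                kcount[d] += 1
                n_active += 1
            entered += smp_count[smp_i]
            smp_i += 1

        # demographic events due now (pulses sorted before splits)
        while ev_i < n_ev and ev_time[ev_i] <= t:
            a = ev_a[ev_i]
            b = ev_b[ev_i]
            if ev_kind[ev_i] == PULSE:
                f = ev_frac[ev_i]
                j = 0
                while j < kcount[a]:
                    if np.random.random() < f:
                        lid = member[a, j]
                        member[a, j] = member[a, kcount[a] - 1]
                        kcount[a] -= 1
                        member[b, kcount[b]] = lid
                        kcount[b] += 1
                    else:
                        j += 1
            else:  # SPLIT: move everything from a into b
                for j in range(kcount[a]):
                    member[b, kcount[b]] = member[a, j]
                    kcount[b] += 1
                kcount[a] = 0
            ev_i += 1

        if n_active <= 1 and entered == total_samples:
            break

        # next breakpoint strictly after t (epoch/event/sampling times)
        while bp_i < n_bp and bp_times[bp_i] <= t:
            bp_i += 1
        nb = bp_times[bp_i] if bp_i < n_bp else np.inf

        # candidate coalescence: min of per-deme exponential waits
        best_t = np.inf
        best_d = -1
        for d in range(n_demes):
            k = kcount[d]
            if k >= 2:
                big_n = _deme_size(t, d, ep_start, ep_N, ep_off)
                rate = k * (k - 1) / (4.0 * big_n)
                w = np.random.exponential(1.0 / rate)
                if t + w < best_t:
                    best_t = t + w
                    best_d = d
        if best_t < nb:
            d = best_d
            k = kcount[d]
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            l1 = member[d, i1]
            l2 = member[d, i2]
            br_len[n_branch] = best_t - birth[l1]
            br_p[n_branch] = pcount[l1]
            br_t[n_branch] = istest[l1]
            n_branch += 1
            br_len[n_branch] = best_t - birth[l2]
            br_p[n_branch] = pcount[l2]
            br_t[n_branch] = istest[l2]
            n_branch += 1
            hi = i1 if i1 > i2 else i2
            lo = i2 if i1 > i2 else i1
            member[d, hi] = member[d, kcount[d] - 1]
            kcount[d] -= 1
            member[d, lo] = member[d, kcount[d] - 1]
            kcount[d] -= 1
            lid = next_id
            next_id += 1
            birth[lid] = best_t
            pcount[lid] = pcount[l1] + pcount[l2]
            istest[lid] = istest[l1] | istest[l2]
            member[d, kcount[d]] = lid
            kcount[d] += 1
            n_active -= 1
            t = best_t
        else:
            if nb == np.inf:
                return -1  # stranded lineages
            t = nb

    return n_branch


@njit(cache=True)
def _simulate_kernel(
    n_demes, ep_start, ep_N, ep_off,
    ev_time, ev_kind, ev_a, ev_b, ev_frac,
    smp_time, smp_deme, smp_count, smp_istest,
    bp_times,
    num, seed, mode, site_rate,
    out_derived, out_test, acc,
):
    """Run the simulator.

    mode == MODE_EXPECTED: simulate ``num`` genealogies, accumulating each
    branch's raw length into ``acc[panel_count, test_flag]``.
    mode == MODE_SAMPLED: emit exactly ``num`` sites into
    ``out_derived``/``out_test``, drawing Poisson(site_rate * tree_length)
    sites per genealogy.

    Returns the number of genealogies simulated, or -1 on stranded lineages.
    """
    np.random.seed(seed)
    total_samples = 0
    for g in range(smp_count.shape[0]):
        total_samples += smp_count[g]
    cap = 2 * total_samples

    birth = np.empty(cap, dtype=np.float64)
    pcount = np.empty(cap, dtype=np.int64)
    istest = np.empty(cap, dtype=np.uint8)
    member = np.empty((n_demes, total_samples), dtype=np.int64)
    kcount = np.empty(n_demes, dtype=np.int64)
    br_len = np.empty(cap, dtype=np.float64)
    br_p = np.empty(cap, dtype=np.int64)
    br_t = np.empty(cap, dtype=np.uint8)

    trees = 0
    filled = 0
    while True:
        if mode == MODE_EXPECTED:
            if trees >= num:
                break
        elif filled >= num:
            break
        n_branch = _one_tree(
            n_demes, ep_start, ep_N, ep_off,
            ev_time, ev_kind, ev_a, ev_b, ev_frac,
            smp_time, smp_deme, smp_count, smp_istest,
            bp_times,
            birth, pcount, istest, member, kcount,
            br_len, br_p, br_t,
        )
        if n_branch < 0:
            return -1
        trees += 1

        total_len = 0.0
        for j in range(n_branch):
            total_len += br_len[j]

        if mode == MODE_EXPECTED:
            for j in range(n_branch):
                acc[br_p[j], br_t[j]] += br_len[j]
        else:
            m = np.random.poisson(site_rate * total_len)
            for _ in range(m):
                if filled >= num:
                    break
                u = np.random.random() * total_len
                c = 0.0
                pick = n_branch - 1
                for j in range(n_branch):
                    c += br_len[j]
                    if u <= c:
                        pick = j
                        break
                out_derived[filled] = br_p[pick]
                out_test[filled] = br_t[pick]
                filled += 1

    return trees
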