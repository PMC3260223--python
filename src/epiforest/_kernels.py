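"""Compiled inner loops (numba) with a pure-Python fallback.

Everything here operates on flat numpy arrays; the public modules wrap these
kernels in documented dataclasses and estimator methods.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def best_split_kernel(G, y, idx, cand_a, cand_b, min_gain):
    """Best Gini-decrease split over candidate variables at one node.

    For each candidate (single SNP ``b < 0`` or SNP pair), genotype cells are
    ordered by their in-node case fraction; for two-class Gini the optimal
    bipartition is contiguous in that order, so only nne-1 splits are scanned.
    Candidates must be pre-sorted (singles ascending, then pairs lexicographic)
    so that the strict ``>`` update implements the documented tie-break.

    Returns ``(best_c, best_mask, best_decrease)``; ``best_c == -1`` means no
    candidate admits a split with decrease above ``min_gain`` (both children
    nonempty).  The mask is canonical: empty cells are folded onto the side
    containing cell 0, and bit 0 of the mask is always set.
    """
    k = idx.size
    n0p = 0
    n1p = 0
    for t in range(k):
        if y[idx[t]] == 1:
            n1p += 1
        else:
            n0p += 1
    ntot = n0p + n1p
    f0 = n0p / ntot
    f1 = n1p / ntot
    gp = 1.0 - f0 * f0 - f1 * f1

    best_dec = min_gain
    best_c = np.int64(-1)
    best_mask = np.int64(0)

    c0 = np.zeros(9, np.int64)
    c1 = np.zeros(9, np.int64)
    order = np.empty(9, np.int64)

    for c in range(cand_a.size):
        a = cand_a[c]
        b = cand_b[c]
        if b < 0:
            ncell = 3
            for j in range(3):
                c0[j] = 0
                c1[j] = 0
            for t in range(k):
                i = idx[t]
                cell = G[i, a]
                if y[i] == 1:
                    c1[cell] += 1
                else:
                    c0[cell] += 1
        else:
            ncell = 9
            for j in range(9):
                c0[j] = 0
                c1[j] = 0
            for t in range(k):
                i = idx[t]
                cell = G[i, a] * 3 + G[i, b]
                if y[i] == 1:
                    c1[cell] += 1
                else:
                    c0[cell] += 1

        nne = 0
        for j in range(ncell):
            if c0[j] + c1[j] > 0:
                order[nne] = j
                nne += 1
        if nne < 2:
            continue

        # stable insertion sort of nonempty cells by case fraction
        for u in range(1, nne):
            oj = order[u]
            pj = c1[oj] / (c0[oj] + c1[oj])
            v = u - 1
            while v >= 0:
                ov = order[v]
                if c1[ov] / (c0[ov] + c1[ov]) > pj:
                    order[v + 1] = ov
                    v -= 1
                else:
                    break
            order[v + 1] = oj

        l0 = 0
        l1 = 0
        maskacc = np.int64(0)
        cbest = -1.0
        cmask = np.int64(0)
        for s in range(nne - 1):
            oj = order[s]
            l0 += c0[oj]
            l1 += c1[oj]
            maskacc |= np.int64(1) << oj
            r0 = n0p - l0
            r1 = n1p - l1
            nl = l0 + l1
            nr = r0 + r1
            gl = 1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2
            gr = 1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2
            dec = gp - (nl / ntot) * gl - (nr / ntot) * gr
            if dec > cbest:
                cbest = dec
                cmask = maskacc
        if cbest > best_dec:
            # canonicalize: empty cells join the side of cell 0
            full = (np.int64(1) << ncell) - 1
            if cmask & 1 == 0:
                cmask = full & ~cmask
            else:
                # attach empty cells to the left (cell-0) side
                for j in range(ncell):
                    if c0[j] + c1[j] == 0:
                        cmask |= np.int64(1) << j
            # recompute the decrease in canonical orientation so the stored
            # value equals a left/right recomputation bit for bit
            l0 = 0
            l1 = 0
            for j in range(ncell):
                if (cmask >> j) & 1:
                    l0 += c0[j]
                    l1 += c1[j]
            r0 = n0p - l0
            r1 = n1p - l1
            nl = l0 + l1
            nr = r0 + r1
            gl = 1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2
            gr = 1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2
            best_dec = gp - (nl / ntot) * gl - (nr / ntot) * gr
            best_c = c
            best_mask = cmask
    return best_c, best_mask, best_dec


@njit(cache=True, inline="always")
def _splitmix64(state):
    """One step of the splitmix64 generator; returns (new_state, value)."""
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return state, z ^ (z >> np.uint64(31))


@njit(cache=True)
def sample_and_best_split(G, y, idx, m, mtry, max_order, seed, min_gain):
    """Sample ``mtry`` distinct candidates uniformly (seeded splitmix64 stream,
    first-distinct == without replacement) and return the best split among
    them: ``(a, b, mask, decrease)`` with ``a == -1`` when no candidate admits
    a split above ``min_gain``.  Ties at exactly equal decrease prefer fewer
    SNPs, then smaller SNP indices.
    """
    universe = m if max_order == 1 else m + m * (m - 1) // 2
    k = idx.size
    n0p = 0
    n1p = 0
    for t in range(k):
        if y[idx[t]] == 1:
            n1p += 1
        else:
            n0p += 1
    ntot = n0p + n1p
    gp = 1.0 - (n0p / ntot) ** 2 - (n1p / ntot) ** 2

    # open-addressing hash set for dedup of sampled universe indices
    cap = 1
    while cap < 2 * mtry:
        cap <<= 1
    table = np.full(cap, -1, np.int64)
    capm = np.uint64(cap - 1)

    state = np.uint64(seed)
    # rejection bound for unbiased draws in [0, universe)
    uni = np.uint64(universe)
    lim = (np.uint64(0xFFFFFFFFFFFFFFFF) // uni) * uni

    best_dec = min_gain
    best_a = np.int64(-1)
    best_b = np.int64(-1)
    best_mask = np.int64(0)

    c0 = np.zeros(9, np.int64)
    c1 = np.zeros(9, np.int64)
    order = np.empty(9, np.int64)

    exhaustive = mtry >= universe
    n_drawn = 0
    u64 = np.uint64(0)
    u_next = np.int64(0)
    while n_drawn < mtry if not exhaustive else u_next < universe:
        if exhaustive:
            u = u_next
            u_next += 1
        else:
            state, u64 = _splitmix64(state)
            if u64 >= lim:
                continue
            u = np.int64(u64 % uni)
            # dedupe
            h = np.uint64(u) & capm
            dup = False
            while table[h] != -1:
                if table[h] == u:
                    dup = True
                    break
                h = (h + np.uint64(1)) & capm
            if dup:
                continue
            table[h] = u
        n_drawn += 1

        if u < m:
            a = u
            b = np.int64(-1)
            ncell = 3
        else:
            v = u - m
            # invert the lexicographic pair index: offs(a) = a(2m-a-1)/2
            af = (2 * m - 1 - np.sqrt(float((2 * m - 1) ** 2 - 8 * v))) / 2.0
            a = np.int64(af)
            if a > m - 2:
                a = np.int64(m - 2)
            while a > 0 and a * (2 * m - a - 1) // 2 > v:
                a -= 1
            while (a + 1) * (2 * m - a - 2) // 2 <= v:
                a += 1
            b = a + 1 + (v - a * (2 * m - a - 1) // 2)
            ncell = 9

        for j in range(ncell):
            c0[j] = 0
            c1[j] = 0
        if b < 0:
            for t in range(k):
                i = idx[t]
                cell = G[i, a]
                if y[i] == 1:
                    c1[cell] += 1
                else:
                    c0[cell] += 1
        else:
            for t in range(k):
                i = idx[t]
                cell = G[i, a] * 3 + G[i, b]
                if y[i] == 1:
                    c1[cell] += 1
                else:
                    c0[cell] += 1

        nne = 0
        for j in range(ncell):
            if c0[j] + c1[j] > 0:
                order[nne] = j
                nne += 1
        if nne < 2:
            continue
        for u2 in range(1, nne):
            oj = order[u2]
            pj = c1[oj] / (c0[oj] + c1[oj])
            v2 = u2 - 1
            while v2 >= 0:
                ov = order[v2]
                if c1[ov] / (c0[ov] + c1[ov]) > pj:
                    order[v2 + 1] = ov
                    v2 -= 1
                else:
                    break
            order[v2 + 1] = oj

        l0 = 0
        l1 = 0
        maskacc = np.int64(0)
        cbest = -1.0
        cmask = np.int64(0)
        for s in range(nne - 1):
            oj = order[s]
            l0 += c0[oj]
            l1 += c1[oj]
            maskacc |= np.int64(1) << oj
            r0 = n0p - l0
            r1 = n1p - l1
            nl = l0 + l1
            nr = r0 + r1
            gl = 1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2
            gr = 1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2
            dec = gp - (nl / ntot) * gl - (nr / ntot) * gr
            if dec > cbest:
                cbest = dec
                cmask = maskacc
        if cbest <= best_dec:
            continue_flag = True
            if cbest == best_dec and best_a >= 0:
                # tie-break: fewer SNPs, then smaller indices
                cur_order = 1 if b < 0 else 2
                old_order = 1 if best_b < 0 else 2
                if (cur_order, a, b if b >= 0 else 0) < (old_order, best_a,
                                                         best_b if best_b >= 0 else 0):
                    continue_flag = False
            if continue_flag:
                continue
        full = (np.int64(1) << ncell) - 1
        if cmask & 1 == 0:
            cmask = full & ~cmask
        else:
            for j in range(ncell):
                if c0[j] + c1[j] == 0:
                    cmask |= np.int64(1) << j
        # store the decrease recomputed in canonical orientation (bit-exact
        # against a left/right recomputation from child counts)
        l0 = 0
        l1 = 0
        for j in range(ncell):
            if (cmask >> j) & 1:
                l0 += c0[j]
                l1 += c1[j]
        r0 = n0p - l0
        r1 = n1p - l1
        nl = l0 + l1
        nr = r0 + r1
        gl = 1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2
        gr = 1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2
        best_dec = gp - (nl / ntot) * gl - (nr / ntot) * gr
        best_a = a
        best_b = b
        best_mask = cmask
    return best_a, best_b, best_mask, best_dec


@njit(cache=True)
def node_cells(G, idx, a, b):
    """Genotype cell index of each in-node individual for variable (a[, b])."""
    k = idx.size
    out = np.empty(k, np.int64)
    if b < 0:
        for t in range(k):
            out[t] = G[idx[t], a]
    else:
        for t in range(k):
            out[t] = G[idx[t], a] * 3 + G[idx[t], b]
    return out


@njit(cache=True)
def predict_kernel(fa, fb, mask, cl, cr, leafc, G, rows):
    n = rows.size
    out = np.empty(n, np.int8)
    for t in range(n):
        i = rows[t]
        node = 0
        while leafc[node] < 0:
            a = fa[node]
            b = fb[node]
            if b < 0:
                cell = G[i, a]
            else:
                cell = G[i, a] * 3 + G[i, b]
            if (mask[node] >> cell) & 1:
                node = cl[node]
            else:
                node = cr[node]
        out[t] = leafc[node]
    return out


@njit(cache=True)
def tree_importance_kernel(fa, fb, mask, cl, cr, leafc, G, y, oob, used, permvals):
    """OOB accuracy drop per used SNP after permuting that SNP among OOB rows.

    ``permvals[u, t]`` is the permuted genotype of SNP ``used[u]`` for the t-th
    OOB individual.  Returns (n_correct_baseline, n_correct_permuted[u]).
    """
    no = oob.size
    base = 0
    for t in range(no):
        i = oob[t]
        node = 0
        while leafc[node] < 0:
            a = fa[node]
            b = fb[node]
            if b < 0:
                cell = G[i, a]
            else:
                cell = G[i, a] * 3 + G[i, b]
            if (mask[node] >> cell) & 1:
                node = cl[node]
            else:
                node = cr[node]
        if leafc[node] == y[i]:
            base += 1
    corr = np.zeros(used.size, np.int64)
    for u in range(used.size):
        s = used[u]
        for t in range(no):
            i = oob[t]
            node = 0
            while leafc[node] < 0:
                a = fa[node]
                b = fb[node]
                ga = permvals[u, t] if a == s else G[i, a]
                if b < 0:
                    cell = ga
                else:
                    gb = permvals[u, t] if b == s else G[i, b]
                    cell = ga * 3 + gb
                if (mask[node] >> cell) & 1:
                    node = cl[node]
                else:
                    node = cr[node]
            if leafc[node] == y[i]:
                corr[u] += 1
    return base, corr


@njit(cache=True)
def tree_depth_leaves(cl, cr, leafc):
    """(max internal-node path length, number of leaves) of one tree."""
    n = cl.size
    stack_node = np.empty(n + 1, np.int64)
    stack_depth = np.empty(n + 1, np.int64)
    sp = 0
    stack_node[0] = 0
    stack_depth[0] = 0
    maxd = 0
    nleaf = 0
    while sp >= 0:
        node = stack_node[sp]
        d = stack_depth[sp]
        sp -= 1
        if leafc[node] >= 0:
            nleaf += 1
            if d > maxd:
                maxd = d
        else:
            sp += 1
            stack_node[sp] = cl[node]
            stack_depth[sp] = d + 1
            sp += 1
            stack_node[sp] = cr[node]
            stack_depth[sp] = d + 1
    return maxd, nleaf


@njit(cache=True)
def branch_sets_kernel(cl, cr, leafc, la, lb, flat, ptr):
    """Distinct-SNP sets of every root-to-leaf branch, under labels (la, lb).

    Writes concatenated sets into ``flat`` with leaf boundaries in ``ptr``
    (``ptr[0] = 0``; branch i occupies ``flat[ptr[i]:ptr[i+1]]``).  Labels are
    passed separately from topology so relabelled forests reuse the arrays.
    Returns the number of branches written.
    """
    n = cl.size
    stack_node = np.empty(2 * n + 2, np.int64)
    stack_phase = np.empty(2 * n + 2, np.int64)
    added = np.empty(2 * n + 2, np.int64)
    path = np.empty(2 * n + 2, np.int64)
    plen = 0
    sp = 0
    stack_node[0] = 0
    stack_phase[0] = 0
    nb = 0
    pos = 0
    while sp >= 0:
        node = stack_node[sp]
        phase = stack_phase[sp]
        if phase == 0:
            if leafc[node] >= 0:
                # emit branch set
                for t in range(plen):
                    flat[pos] = path[t]
                    pos += 1
                nb += 1
                ptr[nb] = pos
                sp -= 1
            else:
                nadd = 0
                a = la[node]
                found = False
                for t in range(plen):
                    if path[t] == a:
                        found = True
                        break
                if not found:
                    path[plen] = a
                    plen += 1
                    nadd += 1
                b = lb[node]
                if b >= 0:
                    found = False
                    for t in range(plen):
                        if path[t] == b:
                            found = True
                            break
                    if not found:
                        path[plen] = b
                        plen += 1
                        nadd += 1
                added[sp] = nadd
                stack_phase[sp] = 1
                sp += 1
                stack_node[sp] = cl[node]
                stack_phase[sp] = 0
        elif phase == 1:
            stack_phase[sp] = 2
            sp += 1
            stack_node[sp] = cr[node]
            stack_phase[sp] = 0
        else:
            plen -= added[sp]
            sp -= 1
    return nb


@njit(cache=True)
def count_combos(ptr, nb, combo_size):
    total = 0
    for i in range(nb):
        s = ptr[i + 1] - ptr[i]
        if combo_size == 2:
            total += s * (s - 1) // 2
        else:
            total += s * (s - 1) * (s - 2) // 6
    return total


@njit(cache=True)
def emit_combos_kernel(flat, ptr, nb, combo_size, m, out):
    """Encode every size-2 or size-3 subset of each branch set into ``out``.

    Pairs encode as a*m+b with a<b; triples as (a*m+b)*m+c with a<b<c.
    Returns the number of combos written.
    """
    pos = 0
    smax = 4
    for i in range(nb):
        s = ptr[i + 1] - ptr[i]
        if s > smax:
            smax = s
    buf = np.empty(smax, np.int64)
    for i in range(nb):
        lo = ptr[i]
        s = ptr[i + 1] - lo
        if s < combo_size:
            continue
        for t in range(s):
            buf[t] = flat[lo + t]
        # insertion sort (sets are small)
        for u in range(1, s):
            v = buf[u]
            w = u - 1
            while w >= 0 and buf[w] > v:
                buf[w + 1] = buf[w]
                w -= 1
            buf[w + 1] = v
        if combo_size == 2:
            for u in range(s):
                for v in range(u + 1, s):
                    out[pos] = buf[u] * m + buf[v]
                    pos += 1
        else:
            for u in range(s):
                for v in range(u + 1, s):
                    e = (buf[u] * m + buf[v]) * m
                    for w in range(v + 1, s):
                        out[pos] = e + buf[w]
                        pos += 1
    return pos
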