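"""Independent reference implementations used by several test modules.

Each oracle re-derives a quantity by a different route than the package:
the combo score by a literal transliteration of the published rule list,
the widest path by a bottleneck Dijkstra instead of threshold bisection.
"""

import heapq

import numpy as np


def oracle_score(combo, domains, gaps, resolution, params):
    """Empirical docking score, coded directly from the rule list.

    Plain loops, no shared helpers with the implementation.  Bonus (2)
    ("essentially a rigid-body docking") requires every domain docked with
    mutually similar transforms.
    """
    placed_ids = sorted(d for d, p in combo.items() if p is not None)
    ccs = [combo[d].cc for d in placed_ids]
    cas = {}
    for d in placed_ids:
        ca = domains[d].ca_coords()
        cas[d] = ca[np.all(np.isfinite(ca), axis=1)]
    placed_ca = {d: combo[d].transform.apply(cas[d]) for d in placed_ids}

    def similar(t1, t2):
        worst = 0.0
        for d in placed_ids:
            a = cas[d] @ t1.rotation.T + t1.translation
            b = cas[d] @ t2.rotation.T + t2.translation
            worst = max(worst, np.sqrt(((a - b) ** 2).sum(1).mean()))
        return worst <= resolution

    n_ca = sum(len(placed_ca[d]) for d in placed_ids)
    n_over = 0
    for d in placed_ids:
        others = [placed_ca[e] for e in placed_ids if e != d]
        if not others:
            continue
        big = np.vstack(others)
        for pt in placed_ca[d]:
            if ((big - pt) ** 2).sum(1).min() \
                    <= params.overlap_ca_ca_distance ** 2:
                n_over += 1
    overlap = n_over / n_ca if n_ca else 0.0

    dev_sum = allowed_sum = 0.0
    unspannable = beyond = False
    for (d1, d2), gap in gaps.items():
        if d1 not in placed_ids or d2 not in placed_ids:
            continue
        dist = np.linalg.norm(placed_ca[d2][0] - placed_ca[d1][-1])
        allowed = 3.8 * (gap + 1)
        allowed_sum += allowed
        dev_sum += max(0.0, dist - allowed)
        if dist > allowed:
            unspannable = True
        if dist > allowed + 2 * resolution \
                + params.maximum_connectivity_deviation:
            beyond = True

    score = 0.0
    all_docked = placed_ids and len(placed_ids) == len(combo)
    if placed_ids and min(ccs) >= params.minimum_docking_cc:
        if min(ccs) > params.acceptable_docking_cc:
            score += 200.0
            first = combo[placed_ids[0]].transform
            if all_docked and all(similar(first, combo[d].transform)
                                  for d in placed_ids[1:]):
                score += 200.0
        if all_docked:
            score += 200.0
        if overlap < params.allowed_fraction_overlapping:
            score += 200.0
        if not unspannable:
            score += 200.0
    if beyond:
        score -= 200.0
    if placed_ids:
        score += min(ccs) + float(np.mean(ccs))
        first = combo[placed_ids[0]].transform
        n_diff = sum(0 if similar(first, combo[d].transform) else 1
                     for d in placed_ids)
        score -= n_diff / len(placed_ids)
    score -= overlap
    if allowed_sum > 0:
        score -= dev_sum / allowed_sum
    return score


def oracle_widest_path(dmap, a_xyz, b_xyz):
    """Exact max-min path value by a bottleneck Dijkstra (26-connected)."""
    grid = dmap.grid.astype(float)
    shape = grid.shape

    def to_idx(p):
        return tuple(int(round(x)) for x in
                     (np.asarray(p) - dmap.origin) / dmap.voxel_size)

    a, b = to_idx(a_xyz), to_idx(b_xyz)
    best = {a: grid[a]}
    heap = [(-grid[a], a)]
    while heap:
        neg, node = heapq.heappop(heap)
        if node == b:
            return -neg
        if -neg < best.get(node, -np.inf):
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    nb = (node[0] + di, node[1] + dj, node[2] + dk)
                    if not all(0 <= nb[ax] < shape[ax] for ax in range(3)):
                        continue
                    cand = min(-neg, grid[nb])
                    if cand > best.get(nb, -np.inf):
                        best[nb] = cand
                        heapq.heappush(heap, (-cand, nb))
    return -np.inf
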