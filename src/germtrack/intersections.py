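"""Detection and resolution of root-crossing regions on skeletons.

Where two roots cross, thinning produces a local 3- or 4-valent tangle (a
branch point or a pair of nearby branch points).  Around each such centre we
trace the skeleton *arms* leaving the region and estimate each arm's outward
direction over a short window.  Arms are then paired so that paired arms are
as close to opposite (180 deg) as possible — a growing root passes through a
crossing roughly straight, so its entry and exit arms form the straightest
available pair.  Tangles with five or more arms are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .skeleton import SkeletonGraph, neighbor_counts

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Arm:
    arm_id: int
    direction: np.ndarray            # unit (drow, dcol) pointing outward
    endpoint: tuple[int, int]        # where the traced arm stopped
    path: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CrossingRegion:
    center: tuple[float, float]
    arms: list[Arm]
    clique_order: int
    center_pixels: set[tuple[int, int]] = field(default_factory=set)
    pairs: list[tuple[int, int]] | None = None   # filled by resolve_crossing

    def continuation(self) -> dict[int, int]:
        """arm_id -> paired arm_id map (after resolution)."""
        out = {}
        for a, b in self.pairs or []:
            out[a] = b
            out[b] = a
        return out


def _neighbors(p):
    return [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS]


def _on(mask, p):
    return (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
            and mask[p])


def _walk_arm(mask, seed, forbidden, max_steps):
    """Follow a skeleton chain outward from the centre region."""
    path = [seed]
    visited = set(forbidden)
    visited.add(seed)
    cur = seed
    for _ in range(max_steps - 1):
        nxt = [n for n in _neighbors(cur) if _on(mask, n) and n not in visited]
        if len(nxt) != 1:
            break  # endpoint reached or another junction: stop the window
        cur = nxt[0]
        path.append(cur)
        visited.add(cur)
    return path


def _trace_arms(skel: SkeletonGraph, center_pixels, center, arm_len_px):
    """One arm per skeleton chain leaving the centre pixel set."""
    mask = skel.mask
    boundary = set()
    for p in center_pixels:
        for n in _neighbors(p):
            if _on(mask, n) and n not in center_pixels:
                boundary.add(n)
    # group mutually adjacent boundary seeds: they start the same chain
    seeds = sorted(boundary)
    groups: list[list[tuple[int, int]]] = []
    for s in seeds:
        placed = False
        for g in groups:
            if any(max(abs(s[0] - q[0]), abs(s[1] - q[1])) <= 1 for q in g):
                g.append(s)
                placed = True
                break
        if not placed:
            groups.append([s])
    # merge transitively
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(groups)), 2):
            if any(max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1
                   for a in groups[i] for b in groups[j]):
                groups[i].extend(groups[j])
                del groups[j]
                merged = True
                break

    arms = []
    cr = np.array(center, float)
    for gi, g in enumerate(sorted(groups)):
        # start from the seed farthest along (any member works; pick nearest
        # to centre so the walk covers the whole chain)
        seed = min(g, key=lambda q: np.hypot(q[0] - cr[0], q[1] - cr[1]))
        forbidden = center_pixels | (set(g) - {seed})
        path = _walk_arm(skel.mask, seed, forbidden, arm_len_px)
        ref = np.array(path[-1], float)
        vec = ref - cr
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        arms.append(Arm(arm_id=gi, direction=vec / norm,
                        endpoint=path[-1], path=path))
    for i, a in enumerate(arms):
        a.arm_id = i
    return arms


def detect_crossing_regions(skel: SkeletonGraph, arm_len_px: int = 15
                            ) -> list[CrossingRegion]:
    """One region per (equivalent) branch point; only 3- and 4-arm regions
    are returned, larger tangles are silently excluded (paired resolution is
    not defined for them)."""
    if skel.n_pixels == 0:
        return []
    regions = []
    paired_members = {m for _, members in skel.equivalent_branch_points
                      for m in members}
    clustered = {m for cluster in skel.branch_clusters for m in cluster}

    centers = []
    for mid, members in skel.equivalent_branch_points:
        cset = _center_pixels_between(skel.mask, members)
        centers.append((mid, cset))
    for bp in skel.branch_points:
        if bp not in paired_members and bp not in clustered:
            centers.append(((float(bp[0]), float(bp[1])), {bp}))
    # thinning an X-crossing of thick roots often leaves a small web of
    # branch points rather than a single 4-valent pixel: treat the whole
    # proximity cluster as one region centred on its centroid
    for cluster in skel.branch_clusters:
        pts = np.array(cluster, float)
        centroid = pts.mean(axis=0)
        radius = float(np.hypot(*(pts - centroid).T).max()) + 1.5
        coords = np.argwhere(skel.mask)
        d = np.hypot(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
        cset = {tuple(p) for p in coords[d <= radius]}
        centers.append((tuple(centroid), cset))

    for center, cset in centers:
        arms = _trace_arms(skel, cset, center, arm_len_px)
        if len(arms) in (3, 4):
            regions.append(CrossingRegion(center=center, arms=arms,
                                          clique_order=len(arms),
                                          center_pixels=cset))
    return regions


def _center_pixels_between(mask, members):
    """Skeleton pixels connecting two paired branch points (BFS shortest)."""
    a, b = members
    if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1:
        return {a, b}
    from collections import deque
    prev = {a: None}
    q = deque([a])
    while q:
        cur = q.popleft()
        if cur == b:
            break
        for n in _neighbors(cur):
            if _on(mask, n) and n not in prev:
                prev[n] = cur
                q.append(n)
    if b not in prev:
        return {a, b}
    path = {b}
    cur = b
    while cur is not None:
        path.add(cur)
        cur = prev[cur]
    return path


def pair_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two outward arm directions."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _pairing_score(arms, pairing):
    return sum(abs(180.0 - pair_angle(arms[i].direction, arms[j].direction))
               for i, j in pairing)


def resolve_crossing(region: CrossingRegion,
                     last_directions: list[np.ndarray] | None = None,
                     tie_deg: float = 5.0) -> list[tuple[int, int]]:
    """Pair arms preferring angles closest to 180 deg.

    Four arms admit three disjoint pairings; the one minimising the summed
    deviation from 180 deg wins.  Three arms yield one best pair, the third
    arm stays unpaired (a root terminus or origin inside the region).  When
    the best and runner-up scores differ by less than ``tie_deg`` and recent
    growth directions are supplied, the pairing most consistent with those
    directions is chosen instead.
    """
    arms = region.arms
    if region.clique_order == 4:
        pairings = [[(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]]
    elif region.clique_order == 3:
        pairings = [[(0, 1)], [(0, 2)], [(1, 2)]]
    else:
        raise ValueError(f"cannot resolve clique of order {region.clique_order}")

    # round so exact ties (common when all arms share a half-plane) are not
    # broken by floating-point noise; ties then fall to pairing order
    scored = sorted(((round(_pairing_score(arms, p), 6), p)
                     for p in pairings), key=lambda sp: (sp[0], sp[1]))
    best_score, best = scored[0]
    if (last_directions and len(scored) > 1
            and scored[1][0] - best_score < tie_deg):
        best = max((p for _, p in scored),
                   key=lambda p: _direction_consistency(arms, p,
                                                        last_directions))
    region.pairs = list(best)
    return region.pairs


def _direction_consistency(arms, pairing, directions):
    """How well a pairing matches known growth directions of nearby tracks."""
    total = 0.0
    for d in directions:
        d = np.asarray(d, float)
        n = np.linalg.norm(d)
        if n == 0:
            continue
        d = d / n
        # the track enters along the arm pointing back against its motion
        entry = max(range(len(arms)),
                    key=lambda i: float(np.dot(-d, arms[i].direction)))
        cont = None
        for a, b in pairing:
            if a == entry:
                cont = b
            elif b == entry:
                cont = a
        if cont is not None:
            total += float(np.dot(d, arms[cont].direction))
    return total


def route_respects_crossings(route, regions: list[CrossingRegion]) -> bool:
    """Check a pixel route only passes through crossings along paired arms.

    For every resolved region the route traverses, the arms used to enter
    and leave the centre must be paired continuations of each other.
    Traversal is judged by proximity to the region centre (thinning webs
    can contain parallel paths that miss the exact centre pixels).
    """
    route_list = list(map(tuple, route))
    if not route_list:
        return True
    pts = np.array(route_list, float)
    for region in regions:
        if region.pairs is None:
            continue
        cr = np.array(region.center, float)
        if region.center_pixels:
            cp = np.array(sorted(region.center_pixels), float)
            radius = float(np.hypot(*(cp - cr).T).max()) + 1.5
        else:
            radius = 1.5
        d = np.hypot(pts[:, 0] - cr[0], pts[:, 1] - cr[1])
        inside = np.flatnonzero(d <= radius)
        if inside.size == 0:
            continue
        arm_of = {}
        for arm in region.arms:
            for p in arm.path:
                arm_of[p] = arm.arm_id
        entry = exit_ = None
        for i in range(inside[0] - 1, -1, -1):
            if route_list[i] in arm_of:
                entry = arm_of[route_list[i]]
                break
        for i in range(inside[-1] + 1, len(route_list)):
            if route_list[i] in arm_of:
                exit_ = arm_of[route_list[i]]
                break
        if entry is None or exit_ is None:
            continue  # route starts or ends inside the region
        if entry == exit_:
            continue  # brushes one arm without traversing the centre
        cont = region.continuation()
        if cont.get(entry) != exit_:
            return False
    return True
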