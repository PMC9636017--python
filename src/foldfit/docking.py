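"""Rigid-body docking of trimmed domains into a density map.

Two placement searches are available, tried in order:

* **SSM docking** — secondary-structure elements (SSEs) detected in the map
  are paired, two at a time, with matching elements of the domain; every
  sliding alignment of the shorter element on the longer (both directions)
  defines a candidate least-squares superposition.  Candidates whose paired
  CAs agree within ``match_distance_high`` (5 Å) are scored by masked
  map-model correlation, kept above ``ok_brute_force_cc`` (0.25) and
  refined by rigid-body refinement.  If the best SSM placement reaches
  ``ssm_search_min_cc`` (0.3) the correlation search is skipped.

* **Correlation docking** — an exhaustive search over a quasi-uniform
  rotation grid with an FFT translation scan per rotation, followed by
  local rigid-body refinement of the top peaks.

Per-domain placement lists are expanded with the transforms found for
other domains and with user-supplied symmetry operators, and the final
combination (one optional placement per domain) is chosen by maximising an
additive empirical score: five 200-unit bonuses (good worst correlation;
additionally rigid-body-consistent transforms; all domains docked; little
overlap; spannable inter-domain gaps), a 200-unit penalty for a gap that
exceeds what the intervening residues plus ``2*resolution + 15`` Å can
span, and small continuous adjustments (worst and mean correlation added;
fraction of divergent transforms, overlap fraction, and normalised span
deviation subtracted).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .density import interpolate_density, map_model_cc, synthesize_map
from .io_core import DensityMap, Model, Transform

__all__ = [
    "SSE",
    "Placement",
    "PlacementCombo",
    "DockingParams",
    "detect_sse_from_model",
    "detect_sse_from_map",
    "ssm_dock",
    "correlation_dock",
    "rigid_body_refine",
    "expand_placements",
    "score_placement_combo",
    "select_placements",
    "dock_domains",
]

logger = logging.getLogger(__name__)

CA_CA_BOND = 3.8  # Å virtual bond used to convert residue counts to spans


@dataclass
class SSE:
    kind: str                    # "helix" | "strand"
    ca_coords: np.ndarray        # ordered CA positions, Å
    positions: list[int] | None = None  # model positions; None if map-derived

    def __len__(self) -> int:
        return len(self.ca_coords)


@dataclass
class Placement:
    domain_id: int
    transform: Transform
    cc: float
    source: str  # ssm | correlation | reused | symmetry


@dataclass
class PlacementCombo:
    placements: dict[int, Placement | None]
    score: float
    breakdown: dict[str, float] = field(default_factory=dict)


@dataclass
class DockingParams:
    """Docking parameters (field-standard names) plus performance knobs."""

    match_distance_high: float = 5.0
    ok_brute_force_cc: float = 0.25
    ssm_search_min_cc: float = 0.3
    minimum_docking_cc: float = 0.15
    acceptable_docking_cc: float = 0.5
    allowed_fraction_overlapping: float = 0.1
    overlap_ca_ca_distance: float = 3.0
    maximum_connectivity_deviation: float = 15.0
    rotation_spacing_deg: float = 24.0
    top_k: int = 5
    mask_radius: float = 2.5
    use_both_dock_modes: bool = False
    max_cc_evaluations: int = 40
    seed: int = 0


# ---------------------------------------------------------------------------
# SSE detection


def detect_sse_from_model(model: Model, min_helix: int = 5,
                          min_strand: int = 4) -> list[SSE]:
    """Assign helices/strands from CA geometry.

    Helix signature: CA(i)-CA(i+3) distance ~5.1 Å with bonded consecutive
    CAs.  Strand signature: CA(i)-CA(i+2) ~6.6 Å with a genuine zigzag
    (chord/arc ratio below 0.95, which rejects gently curved loops).
    Windows never span breaks in residue numbering.
    """
    ca = model.ca_coords()
    nums = model.residue_numbers
    n = len(ca)
    finite = np.all(np.isfinite(ca), axis=1)

    def contiguous(i, j):
        return (nums[j] - nums[i] == j - i) and finite[i:j + 1].all()

    d1 = np.full(n, np.nan)
    for i in range(n - 1):
        if contiguous(i, i + 1):
            d1[i] = np.linalg.norm(ca[i + 1] - ca[i])

    helix_flag = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        if not contiguous(i, i + 3):
            continue
        if not np.all((d1[i:i + 3] >= 2.8) & (d1[i:i + 3] <= 4.5)):
            continue
        d13 = np.linalg.norm(ca[i + 3] - ca[i])
        if 4.3 <= d13 <= 5.7:
            helix_flag[i:i + 4] = True

    strand_flag = np.zeros(n, dtype=bool)
    for i in range(n - 2):
        if not contiguous(i, i + 2):
            continue
        arc = d1[i] + d1[i + 1]
        if not (5.6 <= arc <= 8.8):
            continue
        d02 = np.linalg.norm(ca[i + 2] - ca[i])
        if 5.9 <= d02 <= 7.1 and d02 / arc <= 0.95:
            strand_flag[i:i + 3] = True
    strand_flag &= ~helix_flag

    sses: list[SSE] = []
    for flag, kind, min_len in ((helix_flag, "helix", min_helix),
                                (strand_flag, "strand", min_strand)):
        i = 0
        while i < n:
            if not flag[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and flag[j + 1] and contiguous(j, j + 1):
                j += 1
            if j - i + 1 >= min_len:
                pos = list(range(i, j + 1))
                sses.append(SSE(kind, ca[i:j + 1].copy(), pos))
            i = j + 1
    sses.sort(key=lambda s: -len(s))
    return sses


def _ideal_helix_on_axis(n: int, base: np.ndarray, axis: np.ndarray,
                         u: np.ndarray, v: np.ndarray,
                         phase: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    ang = np.deg2rad(100.0) * i + phase
    return (base + 1.5 * i[:, None] * axis
            + 2.3 * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v))


def _rod_from_voxels(xyz: np.ndarray, w: np.ndarray):
    """Weighted-PCA rod fit: (center, axis, length, thickness)."""
    center = np.average(xyz, axis=0, weights=w)
    cov = np.cov((xyz - center).T, aweights=w)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    proj = (xyz - center) @ axis
    length = float(np.ptp(proj))
    thickness = float(np.sqrt(max(evals[1], 0.0)))
    center = center + axis * float(proj.min() + proj.max()) / 2.0
    return center, axis, length, thickness


def detect_sse_from_map(dmap: DensityMap, resolution: float,
                        min_length: float = 6.0,
                        min_voxels: int = 20) -> list[SSE]:
    """Find rod-like density regions and fit CA traces to them.

    Segmentation runs on a 2 Å-blurred copy of the map, where secondary
    structure (many atoms per Å of chain) stands out against loops: a
    descending threshold sweep collects connected components that are
    elongated, each at the highest level where it appears as a separate
    rod.  Each rod's axis and extent are then refined against the original
    map, and a CA trace is fitted: an ideal helix along the axis (helical
    phase chosen to maximise the map density at the CAs) for thick rods, a
    straight axial trace at the strand rise for thin ones.  A functional
    detector in the find-helices-strands role; it makes no claim to
    reproduce any particular program's output.
    """
    sigma_vox = 2.0 / dmap.voxel_size
    blurred = ndimage.gaussian_filter(dmap.grid.astype(np.float64), sigma_vox)
    fine = ndimage.gaussian_filter(dmap.grid.astype(np.float64), 0.5)
    peak = float(blurred.max())
    if peak <= 0:
        return []
    struct = np.ones((3, 3, 3), dtype=int)
    rods: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    for frac in np.arange(0.85, 0.34, -0.05):
        labels, n_comp = ndimage.label(blurred > frac * peak, struct)
        for comp in range(1, n_comp + 1):
            idx = np.array(np.nonzero(labels == comp)).T
            if len(idx) < min_voxels:
                continue
            xyz = dmap.origin + idx * dmap.voxel_size
            w = blurred[tuple(idx.T)]
            center, axis, length, thickness = _rod_from_voxels(xyz, w)
            if length < min_length or length < 2.5 * thickness:
                continue
            # skip if an already-accepted rod covers this region: nearby
            # radially and overlapping along the shared axis direction
            dup = False
            for c2, a2, l2, _ in rods:
                if abs(float(np.dot(axis, a2))) < 0.8:
                    continue
                sep = center - c2
                along = float(np.dot(sep, a2))
                radial = float(np.linalg.norm(sep - along * a2))
                if radial < 4.0 and abs(along) < 0.5 * (length + l2):
                    dup = True
                    break
            if not dup:
                rods.append((center, axis, length, thickness))

    sses: list[SSE] = []
    fine_peak = float(fine.max())
    # support reference: a typical high in-structure value, robust to
    # local density pile-ups that inflate the global maximum
    in_structure = fine[fine > 0.25 * fine_peak]
    support_ref = float(np.percentile(in_structure, 75)) \
        if in_structure.size else fine_peak
    for center, axis, length, _ in rods:
        # refine on the original map: voxels near the (extended) axis line
        idx = np.array(np.nonzero(fine > 0.25 * fine_peak)).T
        if len(idx) == 0:
            continue
        xyz = dmap.origin + idx * dmap.voxel_size
        rel = xyz - center
        along = rel @ axis
        radial = np.linalg.norm(rel - along[:, None] * axis[None, :], axis=1)
        near = (np.abs(along) <= 0.5 * length + 1.5) & (radial <= 3.0)
        if near.sum() < min_voxels:
            continue
        center_r, axis_r, length_r, thickness_r = _rod_from_voxels(
            xyz[near], fine[tuple(idx[near].T)])
        # robust extent: a uniform rod has std = L / sqrt(12); the peak-to-
        # peak extent is inflated by stray loop density at the rod ends
        w_r = fine[tuple(idx[near].T)]
        proj = (xyz[near] - center_r) @ axis_r
        std_along = np.sqrt(np.average((proj - np.average(proj, weights=w_r))
                                       ** 2, weights=w_r))
        length_r = min(length_r, float(np.sqrt(12.0) * std_along))
        if np.dot(axis_r, axis) < 0:
            axis_r = -axis_r
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(axis_r, ref)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(axis_r, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis_r, u)
        if thickness_r >= 1.2:  # helical tube
            n_res = max(int(round(length_r / 1.5)) - 1, 4)
            base0 = center_r - 0.5 * 1.5 * (n_res - 1) * axis_r
            # fit both the circular phase and the longitudinal offset of
            # the spiral so the trace locks onto the CA positions
            best, best_val = None, -np.inf
            for shift in np.linspace(-0.75, 0.75, 7):
                base = base0 + shift * axis_r
                for phase in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                    trace = _ideal_helix_on_axis(n_res, base, axis_r, u, v,
                                                 phase)
                    vals, _ = interpolate_density(dmap, trace)
                    m = float(vals.mean())
                    if m > best_val:
                        best_val, best = m, trace
            candidate = SSE("helix", best)
        else:  # thin straight rod: strand trace on the axis
            n_res = max(int(round(length_r / 3.3)), 3)
            i = np.arange(n_res, dtype=float)
            base = center_r - 0.5 * length_r * axis_r
            trace = base + (i * length_r / max(n_res - 1, 1))[:, None] \
                * axis_r
            candidate = SSE("strand", trace)
        # density support: a genuine element's CA trace runs through
        # contiguous density well above the overall map fluctuation level;
        # random blobs in a noise map sit only a little above it
        vals, _ = interpolate_density(dmap, candidate.ca_coords)
        if (float(vals.mean()) < 4.0 * float(fine.std())
                or float(vals.mean()) < 0.7 * support_ref
                or float(np.mean(vals > 0.45 * support_ref)) < 0.75):
            logger.debug("rod at %s rejected: support %.2f / frac %.2f",
                         np.round(center, 1), vals.mean() / support_ref,
                         float(np.mean(vals > 0.45 * support_ref)))
            continue
        sses.append(candidate)
    sses.sort(key=lambda s: -len(s))
    return sses[:12]


# ---------------------------------------------------------------------------
# rigid transforms from SSE pairings


def _kabsch_transform(mobile: np.ndarray, target: np.ndarray,
                      ) -> tuple[Transform, float]:
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = Transform(rot, tc - rot @ mc)
    dev = t.apply(mobile) - target
    return t, float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def _sliding_pairings(model_sse: SSE, target_sse: SSE):
    """Yield (model CA block, target CA block) for every alignment of the
    shorter element on the longer, in both target directions."""
    a, b = model_sse.ca_coords, target_sse.ca_coords
    for tgt in (b, b[::-1]):
        if len(a) <= len(tgt):
            for off in range(len(tgt) - len(a) + 1):
                yield a, tgt[off:off + len(a)]
        else:
            for off in range(len(a) - len(tgt) + 1):
                yield a[off:off + len(tgt)], tgt


def _transform_rms(t1: Transform, t2: Transform, points: np.ndarray) -> float:
    d = t1.apply(points) - t2.apply(points)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _dedup_transforms(candidates: list[Transform], points: np.ndarray,
                      tol: float) -> list[Transform]:
    if not candidates:
        return []
    # vectorised greedy dedup on each transform's action on the point set
    actions = np.stack([t.apply(points) for t in candidates])
    kept_idx: list[int] = []
    kept_actions = np.empty((0,) + actions.shape[1:])
    for i, act in enumerate(actions):
        if len(kept_idx):
            d = kept_actions - act[None]
            rms = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
            if float(rms.min()) <= tol:
                continue
        kept_idx.append(i)
        kept_actions = np.concatenate([kept_actions, act[None]])
    return [candidates[i] for i in kept_idx]


def ssm_dock(domain: Model, target_sses: list[SSE], dmap: DensityMap,
             resolution: float, domain_id: int = 0,
             params: DockingParams | None = None) -> list[Placement] | None:
    """Secondary-structure-matching placement search.

    Returns None (not applicable) when the domain has fewer than two SSEs;
    an empty list when no placement survives the correlation threshold.
    """
    params = params or DockingParams()
    model_sses = detect_sse_from_model(domain)
    if len(model_sses) < 2:
        return None
    if not target_sses:
        return []
    dom_ca = domain.ca_coords()
    dom_ca = dom_ca[np.all(np.isfinite(dom_ca), axis=1)]

    def sse_axis_mid(sse: SSE):
        axis = sse.ca_coords[-1] - sse.ca_coords[0]
        n = np.linalg.norm(axis)
        return (axis / n if n > 1e-9 else np.array([0.0, 0.0, 1.0]),
                sse.ca_coords.mean(axis=0))

    geom = {id(s): sse_axis_mid(s) for s in model_sses + list(target_sses)}

    # pair-of-pairs enumeration, prefiltered on inter-element geometry:
    # the angle between the two elements' axes and the distance between
    # their midpoints must roughly agree between domain and map (the
    # element-indexing trick that makes SSM searches tractable)
    raw: list[Transform] = []
    for m1, m2 in itertools.permutations(model_sses, 2):
        am1, mm1 = geom[id(m1)]
        am2, mm2 = geom[id(m2)]
        ang_m = abs(float(np.dot(am1, am2)))
        dist_m = float(np.linalg.norm(mm1 - mm2))
        for t1, t2 in itertools.permutations(target_sses, 2):
            if m1.kind != t1.kind or m2.kind != t2.kind:
                continue
            at1, mt1 = geom[id(t1)]
            at2, mt2 = geom[id(t2)]
            ang_t = abs(float(np.dot(at1, at2)))
            dist_t = float(np.linalg.norm(mt1 - mt2))
            if abs(dist_m - dist_t) > 2.0 * params.match_distance_high:
                continue
            if abs(np.arccos(np.clip(ang_m, 0, 1))
                   - np.arccos(np.clip(ang_t, 0, 1))) > np.deg2rad(30):
                continue
            for a1, b1 in _sliding_pairings(m1, t1):
                for a2, b2 in _sliding_pairings(m2, t2):
                    mob = np.vstack([a1, a2])
                    tar = np.vstack([b1, b2])
                    t, rms = _kabsch_transform(mob, tar)
                    if rms <= params.match_distance_high:
                        raw.append(t)
    # the input pose is always a hypothesis: in later cycles the domain
    # arrives already positioned in the map frame
    raw.append(Transform.identity())
    candidates = _dedup_transforms(raw, dom_ca, resolution / 2.0)

    # cheap density prescore, then full masked CC on the best few
    prescores = []
    for t in candidates:
        vals, _ = interpolate_density(dmap, t.apply(dom_ca))
        prescores.append(float(vals.mean()))
    order = np.argsort(prescores)[::-1][:params.max_cc_evaluations]

    scored: list[tuple[float, Transform]] = []
    for i in order:
        t = candidates[i]
        try:
            cc = map_model_cc(dmap, domain.transformed(t), resolution,
                              params.mask_radius).cc
        except ValueError:  # placed entirely outside the map
            continue
        if cc >= params.ok_brute_force_cc:
            scored.append((cc, t))
    scored.sort(key=lambda s: -s[0])
    placements: list[Placement] = []
    for cc, t in scored[:2 * params.top_k]:
        t_ref, cc_ref, _ = rigid_body_refine(domain, dmap, resolution, t)
        placements.append(Placement(domain_id, t_ref, cc_ref, "ssm"))
    return _dedup_placements(placements, dom_ca, resolution)


def _dedup_placements(placements: list[Placement], points: np.ndarray,
                      tol: float) -> list[Placement]:
    placements = sorted(placements, key=lambda p: -p.cc)
    kept: list[Placement] = []
    for p in placements:
        if all(_transform_rms(p.transform, k.transform, points) > tol
               for k in kept):
            kept.append(p)
    return kept


def _super_fibonacci(n: int) -> np.ndarray:
    """Quasi-uniform unit quaternions (super-Fibonacci spiral)."""
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041  # positive root of x^4 = x + 4
    i = np.arange(n, dtype=float) + 0.5
    s = i / n
    r = np.sqrt(s)
    rc = np.sqrt(1.0 - s)
    alpha = 2.0 * np.pi * i / phi
    beta = 2.0 * np.pi * i / psi
    return np.stack([r * np.sin(alpha), r * np.cos(alpha),
                     rc * np.sin(beta), rc * np.cos(beta)], axis=1)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def rotation_grid(spacing_deg: float, cap: int = 4000) -> list[np.ndarray]:
    """Quasi-uniform rotation matrices at roughly the given angular spacing.

    The identity is always included (the input pose is a natural
    hypothesis: translation-only displacements are common).
    """
    delta = np.deg2rad(spacing_deg)
    n = min(max(int(48.0 * np.pi / delta ** 3), 8), cap)
    return [np.eye(3)] + [_quat_to_matrix(q) for q in _super_fibonacci(n)]


def correlation_dock(domain: Model, dmap: DensityMap, resolution: float,
                     domain_id: int = 0,
                     params: DockingParams | None = None) -> list[Placement]:
    """Exhaustive rotation grid + FFT translation scan.

    For every rotation the rotated domain's model density is cross-correlated
    with the map on the grid; the strongest peaks are refined locally and
    kept when the masked correlation reaches ``minimum_docking_cc``.
    """
    params = params or DockingParams()
    coords = domain.atom_coords()
    if len(coords) < 10:
        raise ValueError("domain too small for correlation docking")
    extent = np.ptp(coords, axis=0)
    map_extent = (np.array(dmap.shape) - 1) * dmap.voxel_size
    if np.any(extent > map_extent):
        raise ValueError("grid too small to contain the domain")

    centroid = domain.ca_coords()
    centroid = centroid[np.all(np.isfinite(centroid), axis=1)].mean(axis=0)
    map_center = dmap.origin + 0.5 * (np.array(dmap.shape) - 1) \
        * dmap.voxel_size
    dom_ca = domain.ca_coords()
    dom_ca = dom_ca[np.all(np.isfinite(dom_ca), axis=1)]

    f_map = np.fft.rfftn(dmap.grid.astype(np.float64)
                         - float(dmap.grid.mean()))
    shape = dmap.shape
    hits: list[tuple[float, Transform]] = []
    for rot in rotation_grid(params.rotation_spacing_deg):
        # rotate about the domain centroid, recenter on the map
        t0 = Transform(rot, map_center - rot @ centroid)
        dens = synthesize_map(domain.transformed(t0), resolution, dmap)
        f_dom = np.fft.rfftn(dens.grid.astype(np.float64))
        corr = np.fft.irfftn(f_map * np.conj(f_dom), s=shape)
        peak_idx = np.unravel_index(np.argmax(corr), shape)
        shift = np.array(peak_idx, dtype=float)
        # wrap negative shifts
        shift = np.where(shift > np.array(shape) / 2,
                         shift - np.array(shape), shift)
        t = Transform(rot, t0.translation + shift * dmap.voxel_size)
        hits.append((float(corr[peak_idx]), t))

    hits.sort(key=lambda h: -h[0])
    placements: list[Placement] = []
    seen: list[Transform] = []
    for _, t in hits[:params.max_cc_evaluations]:
        if any(_transform_rms(t, s, dom_ca) <= resolution for s in seen):
            continue
        seen.append(t)
        cc = map_model_cc(dmap, domain.transformed(t), resolution,
                          params.mask_radius).cc
        if cc <= 0:
            continue
        t_ref, cc_ref, _ = rigid_body_refine(domain, dmap, resolution, t)
        if cc_ref >= params.minimum_docking_cc:
            placements.append(Placement(domain_id, t_ref, cc_ref,
                                        "correlation"))
        if len(placements) >= 2 * params.top_k:
            break
    return _dedup_placements(placements, dom_ca, resolution)


def rigid_body_refine(domain: Model, dmap: DensityMap, resolution: float,
                      initial: Transform) -> tuple[Transform, float, bool]:
    """Local six-parameter optimisation of a placement.

    The search objective is the mean interpolated density at the atoms (a
    smooth proxy); acceptance is by masked correlation — if the refined
    pose does not improve the correlation the initial one is returned with
    a failure flag.
    """
    coords = domain.atom_coords()
    centroid = coords.mean(axis=0)
    centered = coords - centroid

    def pose(p):
        rv = p[:3]
        angle = np.linalg.norm(rv)
        if angle < 1e-12:
            rot = np.eye(3)
        else:
            axis = rv / angle
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = (np.eye(3) + np.sin(angle) * k
                   + (1 - np.cos(angle)) * (k @ k))
        full_rot = rot @ initial.rotation
        trans = (rot @ (initial.rotation @ centroid + initial.translation
                        - centroid) + centroid - full_rot @ centroid
                 + p[3:])
        return Transform(full_rot, trans)

    def objective(p):
        vals, _ = interpolate_density(dmap, pose(p).apply(coords))
        return -float(vals.mean())

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxiter": 100, "xtol": 5e-3, "ftol": 1e-5})
    refined = pose(res.x)

    def safe_cc(t: Transform) -> float:
        try:
            return map_model_cc(dmap, domain.transformed(t), resolution).cc
        except ValueError:  # entirely outside the map
            return -1.0

    cc0 = safe_cc(initial)
    cc1 = safe_cc(refined)
    if cc1 >= cc0 - 1e-9 and cc1 > -1.0:
        return refined, cc1, True
    return initial, cc0, False


# ---------------------------------------------------------------------------
# placement expansion and combo scoring


def expand_placements(per_domain: dict[int, list[Placement]],
                      domains: dict[int, Model], dmap: DensityMap,
                      resolution: float,
                      symmetry_ops: list[Transform] | None = None,
                      params: DockingParams | None = None,
                      ) -> dict[int, list[Placement]]:
    """Augment each domain's placements with other domains' transforms and
    with symmetry images; correlations are recomputed, duplicates merged."""
    params = params or DockingParams()
    out: dict[int, list[Placement]] = {}
    all_transforms = [(d, p.transform) for d, ps in per_domain.items()
                      for p in ps]
    for dom_id, placements in per_domain.items():
        domain = domains[dom_id]
        dom_ca = domain.ca_coords()
        dom_ca = dom_ca[np.all(np.isfinite(dom_ca), axis=1)]
        expanded = list(placements)
        def cc_of(t: Transform) -> float | None:
            try:
                return map_model_cc(dmap, domain.transformed(t), resolution,
                                    params.mask_radius).cc
            except ValueError:  # placed outside the map
                return None

        for src_id, t in all_transforms:
            if src_id == dom_id:
                continue
            cc = cc_of(t)
            if cc is not None:
                expanded.append(Placement(dom_id, t, cc, "reused"))
        if symmetry_ops:
            for p in list(expanded):
                for op in symmetry_ops:
                    t = op.compose(p.transform)
                    cc = cc_of(t)
                    if cc is not None:
                        expanded.append(Placement(dom_id, t, cc, "symmetry"))
        out[dom_id] = _dedup_placements(expanded, dom_ca, resolution / 2.0)
    return out


def _similar(t1: Transform, t2: Transform, ca_sets: list[np.ndarray],
             resolution: float) -> bool:
    """Transforms are similar when applying both to every domain's CA set
    differs by at most the map resolution (maximum r.m.s. over domains)."""
    return max(_transform_rms(t1, t2, ca) for ca in ca_sets) <= resolution


def score_placement_combo(combo: dict[int, Placement | None],
                          domains: dict[int, Model],
                          inter_domain_gaps: dict[tuple[int, int], int],
                          resolution: float,
                          params: DockingParams | None = None,
                          ) -> PlacementCombo:
    """Additive empirical score of one placement combination.

    The score starts at zero.  If every placed domain has correlation of at
    least ``minimum_docking_cc``, five 200-unit bonuses apply (see module
    docstring); a 200-unit connectivity penalty and five small continuous
    adjustments apply in any case.  ``inter_domain_gaps`` maps sequence-
    adjacent domain-id pairs to the number of intervening residues.
    """
    params = params or DockingParams()
    breakdown: dict[str, float] = {}
    placed = {d: p for d, p in combo.items() if p is not None}
    ids = sorted(placed)
    ccs = np.array([placed[d].cc for d in ids]) if ids else np.array([])

    ca_sets = []
    placed_ca = {}
    for d in ids:
        ca = domains[d].ca_coords()
        ca = ca[np.all(np.isfinite(ca), axis=1)]
        ca_sets.append(ca)
        placed_ca[d] = placed[d].transform.apply(ca)

    # overlap: placed CA atoms within overlap_ca_ca_distance of another
    # placed domain's CAs, as a fraction of all placed CAs
    n_total = sum(len(c) for c in placed_ca.values())
    n_overlap = 0
    for d in ids:
        others = [placed_ca[e] for e in ids if e != d]
        if not others:
            continue
        other = np.vstack(others)
        for pt in placed_ca[d]:
            if np.min(np.sum((other - pt) ** 2, axis=1)) \
                    <= params.overlap_ca_ca_distance ** 2:
                n_overlap += 1
    overlap_fraction = n_overlap / n_total if n_total else 0.0

    # inter-domain spans between sequence-adjacent placed pairs, measured
    # between the chain-end CAs that the linker must connect
    span_dev_sum = 0.0
    span_allowed_sum = 0.0
    any_unspannable = False
    any_beyond_max = False
    for (d1, d2), gap in inter_domain_gaps.items():
        if d1 not in placed or d2 not in placed:
            continue
        end1 = placed_ca[d1][-1]
        start2 = placed_ca[d2][0]
        dist = float(np.linalg.norm(start2 - end1))
        allowed = CA_CA_BOND * (gap + 1)
        span_allowed_sum += allowed
        span_dev_sum += max(0.0, dist - allowed)
        if dist > allowed:
            any_unspannable = True
        if dist > allowed + 2.0 * resolution \
                + params.maximum_connectivity_deviation:
            any_beyond_max = True

    gate = bool(ids) and bool(np.all(ccs >= params.minimum_docking_cc))
    all_docked = len(placed) == len(combo) and bool(ids)
    if gate:
        bonus1 = float(ccs.min()) > params.acceptable_docking_cc
        breakdown["bonus_min_cc"] = 200.0 if bonus1 else 0.0
        # "essentially a rigid-body docking" is a statement about the whole
        # model: every domain docked, all with mutually similar transforms
        # (a mutually consistent subset does not qualify)
        first_t = placed[ids[0]].transform
        similar_all = all(_similar(first_t, placed[d].transform, ca_sets,
                                   resolution) for d in ids[1:])
        breakdown["bonus_rigid"] = (
            200.0 if (bonus1 and all_docked and similar_all) else 0.0)
        breakdown["bonus_all_docked"] = 200.0 if all_docked else 0.0
        breakdown["bonus_overlap"] = (
            200.0 if overlap_fraction < params.allowed_fraction_overlapping
            else 0.0)
        breakdown["bonus_span"] = 0.0 if any_unspannable else 200.0
    breakdown["penalty_connectivity"] = -200.0 if any_beyond_max else 0.0

    if len(ids):
        breakdown["adj_min_cc"] = float(ccs.min())
        breakdown["adj_mean_cc"] = float(ccs.mean())
        first_t = placed[ids[0]].transform
        n_diff = sum(0 if _similar(first_t, placed[d].transform, ca_sets,
                                   resolution) else 1 for d in ids)
        breakdown["adj_diff_transforms"] = -n_diff / len(ids)
    breakdown["adj_overlap"] = -overlap_fraction
    breakdown["adj_span_dev"] = (-span_dev_sum / span_allowed_sum
                                 if span_allowed_sum > 0 else 0.0)
    return PlacementCombo(dict(combo), float(sum(breakdown.values())),
                          breakdown)


def select_placements(per_domain: dict[int, list[Placement]],
                      domains: dict[int, Model],
                      inter_domain_gaps: dict[tuple[int, int], int],
                      resolution: float,
                      params: DockingParams | None = None,
                      max_exhaustive: int = 10000,
                      beam_width: int = 50) -> PlacementCombo:
    """Best combination of (top-K placements + "not placed") per domain.

    Exhaustive when the product of options is small; otherwise a greedy
    beam search over domains in sequence order.
    """
    params = params or DockingParams()
    ids = sorted(per_domain)
    options: dict[int, list[Placement | None]] = {
        d: (sorted(per_domain[d], key=lambda p: -p.cc)[:params.top_k]
            + [None])
        for d in ids}
    n_combos = int(np.prod([len(options[d]) for d in ids]))

    def score(combo):
        return score_placement_combo(combo, domains, inter_domain_gaps,
                                     resolution, params)

    if n_combos <= max_exhaustive:
        best = None
        for choice in itertools.product(*(options[d] for d in ids)):
            combo = dict(zip(ids, choice))
            sc = score(combo)
            if best is None or sc.score > best.score:
                best = sc
    else:
        beams: list[dict[int, Placement | None]] = [{}]
        for d in ids:
            grown = []
            for partial in beams:
                for opt in options[d]:
                    c = dict(partial)
                    c[d] = opt
                    grown.append(c)
            grown.sort(key=lambda c: -score(c).score)
            beams = grown[:beam_width]
        best = max((score(c) for c in beams), key=lambda s: s.score)

    if all(p is None for p in best.placements.values()):
        warnings.warn("no domain could be placed")
    return best


def dock_domains(domains: dict[int, Model], dmap: DensityMap,
                 resolution: float,
                 inter_domain_gaps: dict[tuple[int, int], int],
                 symmetry_ops: list[Transform] | None = None,
                 params: DockingParams | None = None,
                 ) -> tuple[PlacementCombo, dict[int, list[Placement]]]:
    """Full docking stage: SSM first, correlation fallback, expansion,
    empirical-score selection."""
    params = params or DockingParams()
    map_sses = detect_sse_from_map(dmap, resolution)
    per_domain: dict[int, list[Placement]] = {}
    for dom_id, domain in sorted(domains.items()):
        placements = ssm_dock(domain, map_sses, dmap, resolution,
                              dom_id, params)
        best_cc = max((p.cc for p in placements), default=-1.0) \
            if placements else -1.0
        need_correlation = (placements is None
                            or best_cc < params.ssm_search_min_cc
                            or params.use_both_dock_modes)
        if need_correlation:
            extra = correlation_dock(domain, dmap, resolution, dom_id, params)
            placements = (placements or []) + extra
            dom_ca = domain.ca_coords()
            dom_ca = dom_ca[np.all(np.isfinite(dom_ca), axis=1)]
            placements = _dedup_placements(placements, dom_ca, resolution)
        per_domain[dom_id] = placements or []
    per_domain = expand_placements(per_domain, domains, dmap, resolution,
                                   symmetry_ops, params)
    combo = select_placements(per_domain, domains, inter_domain_gaps,
                              resolution, params)
    return combo, per_domain
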