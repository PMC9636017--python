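"""Segment rebuilding: find poorly fitting parts, rebuild, assemble.

After docking and morphing, parts of the model that either carry low
predicted confidence (smoothed plDDT below 70) or sit in poor density
(smoothed CA density more than ``cc_sd_ratio`` standard deviations below
the mean of the well-fitting half) are marked for rebuilding.  Up to six
independent strategies each produce a full-length candidate model:

1. iterative resolution refinement (restrained real-space refinement
   against progressively less blurred maps, starting at 6 Å);
2. loop fitting (seeded conformational sampling closed onto the flanks,
   scored by CA density);
3. loop retracing (widest path through the density between the flanks:
   the path whose minimum grid value is maximal);
4. a combination of retracing the clear part with grafting the refined
   model over the unclear part;
5. iterative window morphing;
6. splicing a matching fragment from an externally built model.

Every candidate is refined, scored per segment by masked map correlation,
and the best version of each segment is assembled into the final model
(3-residue splice morphs at the junctions, then one more refinement).
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .density import (DensityMap, MaskedCC, density_outlier_threshold,
                      interpolate_density, map_model_cc,
                      sigma_for_resolution)
from .confidence_domains import smooth_profile
from .io_core import Model, backbone_from_ca
from .morphing import graft_segment, window_morph

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentPlan",
    "Segment",
    "CandidateModel",
    "STRATEGY_ORDER",
    "identify_poor_segments",
    "simple_real_space_refine",
    "iterative_resolution_refine",
    "retrace_loop",
    "fit_loop",
    "combination_rebuild",
    "splice_external_fragment",
    "generate_candidates",
    "assemble_best_segments",
]

STRATEGY_ORDER = ("iterative_refine", "fit_loops", "retrace", "combination",
                  "window_morph", "external")


@dataclass
class Segment:
    start: int                  # half-open positions in the model
    stop: int
    label: str                  # "keep" | "rebuild"
    reason: str | None = None   # "low_confidence" | "low_density"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.stop)


@dataclass
class SegmentPlan:
    segments: list[Segment]
    warnings: list[str] = field(default_factory=list)

    @property
    def rebuild_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "rebuild"]

    def tiles(self, n: int) -> bool:
        pos = 0
        for s in self.segments:
            if s.start != pos or s.stop <= s.start:
                return False
            pos = s.stop
        return pos == n


@dataclass
class CandidateModel:
    model: Model
    strategy: str
    per_segment_cc: list[MaskedCC] = field(default_factory=list)


# ---------------------------------------------------------------------------
# poor-segment identification


def identify_poor_segments(model: Model, dmap: DensityMap,
                           confidence: np.ndarray, window: int = 10,
                           plddt_threshold: float = 70.0,
                           sd_ratio: float = 3.0,
                           sd_floor_frac: float = 0.1,
                           pad: int = 2) -> SegmentPlan:
    """Partition the chain into keep/rebuild segments.

    A residue needs rebuilding when its smoothed confidence falls below
    ``plddt_threshold`` or its smoothed CA density falls below the
    outlier threshold derived from the upper half of all CA densities.
    When every well-fitting residue sits in near-identical density (sharp
    noiseless maps), the good-half standard deviation collapses to grid-
    sampling jitter; ``sd_floor_frac`` keeps the effective deviation at a
    fraction of the good-half mean so that only genuine dropouts are
    flagged.  Rebuild runs are padded by ``pad`` residues into the keep
    regions so that splices land on sound flanks.
    """
    n = len(model)
    conf = smooth_profile(np.asarray(confidence, dtype=float), window)
    ca = model.ca_coords()
    dens, _ = interpolate_density(dmap, ca)
    dens_s = smooth_profile(dens, window)
    if n >= 4:
        thr = density_outlier_threshold(dens_s, sd_ratio)
        upper = dens_s[dens_s >= np.median(dens_s)]
        thr = min(thr, float(upper.mean()
                             - sd_ratio * sd_floor_frac * abs(upper.mean())))
    else:
        thr = -np.inf

    low_conf = conf < plddt_threshold
    low_dens = dens_s < thr
    flag = low_conf | low_dens

    # pad rebuild runs into the keep regions
    padded = flag.copy()
    for i in np.nonzero(flag)[0]:
        padded[max(0, i - pad):min(n, i + pad + 1)] = True

    notes: list[str] = []
    if padded.all():
        notes.append("every residue flagged: whole-model rebuild")
        warnings.warn(notes[-1])

    segments: list[Segment] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and padded[j + 1] == padded[i]:
            j += 1
        if padded[i]:
            reason = ("low_confidence"
                      if low_conf[i:j + 1].sum() >= low_dens[i:j + 1].sum()
                      else "low_density")
            segments.append(Segment(i, j + 1, "rebuild", reason))
        else:
            segments.append(Segment(i, j + 1, "keep"))
        i = j + 1
    return SegmentPlan(segments, notes)


# ---------------------------------------------------------------------------
# restrained real-space refinement


def _blur_to_resolution(dmap: DensityMap, target: float,
                        native: float) -> DensityMap:
    """Low-pass the map from its native resolution to ``target`` (Å)."""
    if target <= native:
        return dmap
    s_extra = np.sqrt(sigma_for_resolution(target) ** 2
                      - sigma_for_resolution(native) ** 2)
    return dmap.like(ndimage.gaussian_filter(
        dmap.grid.astype(np.float64), s_extra / dmap.voxel_size))


def simple_real_space_refine(model: Model, dmap: DensityMap,
                             resolution: float,
                             reference: Model | None = None,
                             k_bond: float = 5.0, k_local: float = 2.0,
                             k_reference: float = 0.0,
                             maxiter: int = 150,
                             cc_guard: float = 0.05,
                             ) -> tuple[Model, bool]:
    """Gradient-based restrained refinement of all atoms against the map.

    Minimises ``-sum(density at atoms) / max(density)`` plus harmonic
    terms: consecutive CA-CA bonds at 3.8 Å, each atom's offset from its
    own CA held near its starting value (keeps residue geometry together),
    and optional harmonic restraints to a reference model.  Returns
    ``(model, ok)``: if the masked correlation drops the input model is
    returned, with ``ok`` False on a drop larger than ``cc_guard`` or a
    contrast-free map.
    """
    grid = dmap.grid.astype(np.float64)
    peak = float(grid.max())
    flat = peak <= float(grid.min()) + 1e-12
    scale = 1.0 / peak if peak > 0 else 1.0
    gradients = np.gradient(grid, *dmap.voxel_size)

    flat_atoms = model.all_atoms()
    x0 = model.atom_coords()
    n_atoms = len(x0)
    res_pos = np.array([p for p, _ in flat_atoms])
    is_ca = np.array([a.name == "CA" for _, a in flat_atoms])
    ca_index_of_res = {}
    for k, (p, a) in enumerate(flat_atoms):
        if a.name == "CA":
            ca_index_of_res[p] = k
    ca_of_atom = np.array([ca_index_of_res.get(p, -1) for p in res_pos])
    local_mask = (~is_ca) & (ca_of_atom >= 0)
    local_off0 = np.zeros((n_atoms, 3))
    local_off0[local_mask] = (x0[local_mask]
                              - x0[ca_of_atom[local_mask]])

    nums = model.residue_numbers
    ca_positions = sorted(ca_index_of_res)
    bonds = []
    for a, b in zip(ca_positions, ca_positions[1:]):
        if nums[b] - nums[a] == 1:
            bonds.append((ca_index_of_res[a], ca_index_of_res[b]))
    bonds = np.array(bonds, dtype=int) if bonds else np.empty((0, 2), int)
    # bond targets: the input spacing when plausible, the canonical 3.8 Å
    # CA-CA virtual bond when the input geometry is broken
    if len(bonds):
        d0 = np.linalg.norm(x0[bonds[:, 1]] - x0[bonds[:, 0]], axis=1)
        bond_targets = np.where((d0 >= 2.9) & (d0 <= 4.1), d0, 3.8)
    else:
        bond_targets = np.empty(0)

    ref_coords = reference.atom_coords() if reference is not None else None

    def energy_grad(xf):
        x = xf.reshape(n_atoms, 3)
        frac = (x - dmap.origin) / dmap.voxel_size
        clip = np.clip(frac, 0, np.array(dmap.shape) - 1)
        vals = ndimage.map_coordinates(grid, clip.T, order=1, mode="nearest")
        g = np.stack([ndimage.map_coordinates(gi, clip.T, order=1,
                                              mode="nearest")
                      for gi in gradients], axis=1)
        e = -scale * float(vals.sum())
        de = -scale * g
        if len(bonds):
            vec = x[bonds[:, 1]] - x[bonds[:, 0]]
            d = np.linalg.norm(vec, axis=1)
            dev = d - bond_targets
            e += k_bond * float(np.sum(dev ** 2))
            f = (2.0 * k_bond * dev / np.maximum(d, 1e-9))[:, None] * vec
            np.add.at(de, bonds[:, 1], f)
            np.add.at(de, bonds[:, 0], -f)
        if local_mask.any():
            off = (x[local_mask] - x[ca_of_atom[local_mask]]) \
                - local_off0[local_mask]
            e += k_local * float(np.sum(off ** 2))
            de[local_mask] += 2.0 * k_local * off
            np.add.at(de, ca_of_atom[local_mask], -2.0 * k_local * off)
        if ref_coords is not None and k_reference > 0:
            dev = x - ref_coords
            e += k_reference * float(np.sum(dev ** 2))
            de += 2.0 * k_reference * dev
        return e, de.ravel()

    result = minimize(energy_grad, x0.ravel(), jac=True, method="L-BFGS-B",
                      options={"maxiter": maxiter})
    refined = model.copy()
    refined.set_atom_coords(result.x.reshape(n_atoms, 3))
    if flat:
        return refined, False
    cc0 = map_model_cc(dmap, model, resolution).cc
    cc1 = map_model_cc(dmap, refined, resolution).cc
    if cc1 >= cc0:
        return refined, True
    if cc0 - cc1 > cc_guard:
        logger.info("refinement diverged (cc %.3f -> %.3f); keeping input",
                    cc0, cc1)
        return model.copy(), False
    return model.copy(), True


def iterative_resolution_refine(model: Model, dmap: DensityMap,
                                resolution: float, start: float = 6.0,
                                step: float = 1.0, **refine_kwargs) -> Model:
    """Refine against maps low-passed to start, start-step, ..., resolution.

    Starting at low resolution widens the convergence radius: atoms a few Å
    out of density feel a gradient from the blurred blobs, then the
    sharper passes lock the details in.
    """
    if resolution > start:
        levels = [resolution]
    else:
        levels = list(np.arange(start, resolution, -step)) + [resolution]
    current = model
    for level in levels:
        blurred = _blur_to_resolution(dmap, level, resolution)
        current, _ = simple_real_space_refine(current, blurred, level,
                                              **refine_kwargs)
    return current


# ---------------------------------------------------------------------------
# loop retracing (widest path)


def _connected(mask: np.ndarray, a: tuple, b: tuple) -> bool:
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    return labels[a] != 0 and labels[a] == labels[b]


def _shortest_path_on_mask(mask: np.ndarray, a: tuple, b: tuple,
                           ) -> list[tuple]:
    """BFS shortest path between voxels of a boolean mask (26-connected)."""
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    shape = mask.shape
    prev = {a: None}
    frontier = [a]
    while frontier and b not in prev:
        nxt = []
        for node in frontier:
            for off in offsets:
                nb = (node[0] + off[0], node[1] + off[1], node[2] + off[2])
                if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                        and 0 <= nb[2] < shape[2]
                        and nb not in prev and mask[nb]):
                    prev[nb] = node
                    nxt.append(nb)
        frontier = nxt
    if b not in prev:
        return []
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    return path[::-1]


def retrace_bottleneck(dmap: DensityMap, start_anchor: np.ndarray,
                       end_anchor: np.ndarray,
                       margin: float = 8.0) -> float | None:
    """Optimal widest-path value between two anchors (diagnostic).

    The highest density threshold at which the anchor voxels remain
    26-connected — the minimum grid value along the best retraced path.
    None when the anchors share no positive density.
    """
    found = _widest_path_mask(dmap, np.asarray(start_anchor, float),
                              np.asarray(end_anchor, float), margin)
    return None if found is None else found[0]


def _widest_path_mask(dmap: DensityMap, start_anchor: np.ndarray,
                      end_anchor: np.ndarray, margin: float):
    """Shared search: (threshold, mask, a, b, sub_origin) or None."""
    lo_corner = np.minimum(start_anchor, end_anchor) - margin
    hi_corner = np.maximum(start_anchor, end_anchor) + margin
    lo_idx = np.maximum(np.floor((lo_corner - dmap.origin)
                                 / dmap.voxel_size).astype(int), 0)
    hi_idx = np.minimum(np.ceil((hi_corner - dmap.origin)
                                / dmap.voxel_size).astype(int) + 1,
                        np.array(dmap.shape))
    sub = dmap.grid[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1],
                    lo_idx[2]:hi_idx[2]].astype(np.float64)
    sub_origin = dmap.origin + lo_idx * dmap.voxel_size

    def to_idx(p):
        idx = np.round((p - sub_origin) / dmap.voxel_size).astype(int)
        return tuple(np.clip(idx, 0, np.array(sub.shape) - 1))

    a, b = to_idx(start_anchor), to_idx(end_anchor)
    values = np.unique(sub[sub > 0])
    if len(values) == 0 or not _connected(sub > 0, a, b):
        return None
    if not _connected(sub >= values[0], a, b):
        return None
    lo, hi = 0, len(values) - 1  # values[lo] always keeps them connected
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _connected(sub >= values[mid], a, b):
            lo = mid
        else:
            hi = mid - 1
    return float(values[lo]), sub >= values[lo], a, b, sub_origin


def retrace_loop(dmap: DensityMap, start_anchor: np.ndarray,
                 end_anchor: np.ndarray, n_residues: int,
                 margin: float = 8.0) -> np.ndarray | None:
    """Widest-path CA trace between two anchors.

    Finds the path between the anchor voxels that maximises the minimum
    grid value along the path (binary search over density thresholds with
    26-connected component checks — exact on grid values — with a
    shortest-path tie-break at the optimal threshold), then resamples it
    to ``n_residues`` CA positions.  Returns None when the anchors are not
    connected by positive density.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    start_anchor = np.asarray(start_anchor, dtype=float)
    end_anchor = np.asarray(end_anchor, dtype=float)
    found = _widest_path_mask(dmap, start_anchor, end_anchor, margin)
    if found is None:
        return None
    _, mask, a, b, sub_origin = found
    path = _shortest_path_on_mask(mask, a, b)
    if not path:
        return None
    pts = sub_origin + np.array(path, dtype=float) * dmap.voxel_size
    pts[0], pts[-1] = start_anchor, end_anchor
    # arc-length resample to n_residues interior CA positions
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_residues + 2)[1:-1]
    trace = np.stack([np.interp(targets, s, pts[:, ax]) for ax in range(3)],
                     axis=1)
    return trace


# ---------------------------------------------------------------------------
# loop fitting


def _smooth_perturbation(n: int, scale: float,
                         rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(size=(n + 8, 3))
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    kernel /= kernel.sum()
    out = np.stack([np.convolve(raw[:, ax], kernel, mode="same")
                    for ax in range(3)], axis=1)[4:4 + n]
    # zero at both ends so the flanks stay pinned
    taper = np.sin(np.pi * np.arange(1, n + 1) / (n + 1))[:, None]
    return scale * out * taper


def _roughness(trace: np.ndarray) -> float:
    if len(trace) < 3:
        return 0.0
    sec = np.diff(trace, n=2, axis=0)
    return float(np.sum(sec * sec))


def fit_loop(model: Model, dmap: DensityMap, segment: tuple[int, int],
             resolution: float, seed: int = 0, n_candidates: int = 200,
             extra_candidates: list[np.ndarray] | None = None,
             ) -> np.ndarray | None:
    """Sampled loop rebuilding: seeded conformations closed on the flanks,
    scored by mean CA density (smoothest candidate on ties or flat maps).

    Returns the winning CA trace for the segment, or None when no chain of
    the segment's length can span the flank gap.
    """
    start, stop = segment
    n = stop - start
    ca = model.ca_coords()
    left = ca[start - 1] if start > 0 else None
    right = ca[stop] if stop < len(model) else None
    rng = np.random.default_rng(seed)

    if left is None and right is None:
        return None
    if left is None or right is None:  # terminal segment: keep direction
        base = ca[start:stop].copy()
        candidates = [base]
        for _ in range(n_candidates):
            candidates.append(base + _smooth_perturbation(n, 1.5, rng))
    else:
        gap = float(np.linalg.norm(right - left))
        if gap > 3.8 * (n + 1):
            return None
        if n == 1:
            # place a single residue at the best density point between flanks
            mid = 0.5 * (left + right)
            best, best_val = mid, -np.inf
            for _ in range(100):
                p = mid + rng.normal(0.0, 1.5, 3)
                if (np.linalg.norm(p - left) <= 4.1
                        and np.linalg.norm(p - right) <= 4.1):
                    v = float(interpolate_density(dmap, p[None])[0][0])
                    if v > best_val:
                        best, best_val = p, v
            return best[None, :]
        t = (np.arange(1, n + 1) / (n + 1))[:, None]
        base = left + t * (right - left)
        candidates = [base, ca[start:stop].copy()]
        for _ in range(n_candidates):
            candidates.append(base + _smooth_perturbation(n, 2.5, rng))

    def spacing_ok(trace):
        full = [x for x in (left,) if x is not None] + list(trace) \
            + [x for x in (right,) if x is not None]
        d = np.linalg.norm(np.diff(np.array(full), axis=0), axis=1)
        return np.all((d >= 2.7) & (d <= 4.3))

    scored = []
    for k, cand in enumerate(candidates):
        if not spacing_ok(cand):
            continue
        vals, _ = interpolate_density(dmap, cand)
        scored.append((float(vals.mean()), -_roughness(cand), k, cand))
    for k, cand in enumerate(extra_candidates or []):
        vals, _ = interpolate_density(dmap, cand)
        scored.append((float(vals.mean()), -_roughness(cand),
                       len(candidates) + k, cand))
    if not scored:
        return None
    scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
    return scored[0][3]


# ---------------------------------------------------------------------------
# combination and external strategies


def combination_rebuild(model: Model, dmap: DensityMap,
                        segment: tuple[int, int], resolution: float,
                        sd_ratio: float = 3.0) -> np.ndarray | None:
    """Retrace the clear part of a segment, graft the refined model over
    the unclear part.

    "Clear" residues are those whose current CA density clears the outlier
    threshold computed over the whole model.  Fully clear segments reduce
    to retracing; fully unclear ones to grafting (i.e. the refined input).
    """
    start, stop = segment
    ca = model.ca_coords()
    all_dens, _ = interpolate_density(dmap, ca)
    thr = density_outlier_threshold(all_dens, sd_ratio)
    seg_dens = all_dens[start:stop]
    clear = seg_dens >= thr

    new_ca = ca.copy()
    n = stop - start
    # process maximal clear runs by retracing between their anchors
    i = 0
    while i < n:
        if not clear[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and clear[j + 1]:
            j += 1
        a = new_ca[start + i - 1] if start + i > 0 else new_ca[start + i]
        b = new_ca[start + j + 1] if start + j + 1 < len(ca) \
            else new_ca[start + j]
        trace = retrace_loop(dmap, a, b, j - i + 1)
        if trace is not None:
            new_ca[start + i:start + j + 1] = trace
        i = j + 1
    # unclear runs: graft the refined model piece onto its (possibly
    # retraced) flanks so ends connect smoothly
    sub = model.subset(range(start, stop))
    left = new_ca[max(start - 3, 0):start] if start > 0 else None
    right = new_ca[stop:stop + 3] if stop < len(ca) else None
    if not clear.all():
        grafted = graft_segment(sub, left, right)
        graft_ca = grafted.ca_coords()
        for k in range(n):
            if not clear[k]:
                new_ca[start + k] = graft_ca[k]
    return new_ca[start:stop]


def splice_external_fragment(model: Model, segment: tuple[int, int],
                             external_model: Model, dmap: DensityMap,
                             ca_distance: float = 3.8) -> np.ndarray | None:
    """Find an external-model fragment of the segment's exact length whose
    terminal CAs connect to the flanks within ``ca_distance``; the best
    (by mean CA density) qualifying fragment's CA trace is returned."""
    start, stop = segment
    n = stop - start
    ca = model.ca_coords()
    left = ca[start - 1] if start > 0 else None
    right = ca[stop] if stop < len(model) else None
    ext_ca = external_model.ca_coords()
    ext_nums = external_model.residue_numbers
    best, best_val = None, -np.inf
    for i in range(0, len(ext_ca) - n + 1):
        if ext_nums[i + n - 1] - ext_nums[i] != n - 1:
            continue  # not a contiguous fragment
        frag = ext_ca[i:i + n]
        if not np.all(np.isfinite(frag)):
            continue
        for cand in (frag, frag[::-1]):
            if left is not None \
                    and np.linalg.norm(cand[0] - left) > ca_distance:
                continue
            if right is not None \
                    and np.linalg.norm(cand[-1] - right) > ca_distance:
                continue
            vals, _ = interpolate_density(dmap, cand)
            v = float(vals.mean())
            if v > best_val:
                best, best_val = cand.copy(), v
    return best


# ---------------------------------------------------------------------------
# candidate generation and assembly


def _replace_segment_ca(model: Model, segment: tuple[int, int],
                        trace: np.ndarray) -> Model:
    """Rebuild a segment's residues along a new CA trace (backbone atoms
    re-derived from the local chain frame)."""
    start, stop = segment
    out = model.copy()
    old_ca = out.ca_coords()
    ca = old_ca.copy()
    ca[start:stop] = trace
    new_atoms = backbone_from_ca(ca[max(0, start - 1):min(len(ca), stop + 1)])
    offset = max(0, start - 1)
    for p in range(start, stop):
        res = out.residues[p]
        rebuilt = {a.name: a for a in new_atoms[p - offset]}
        for atom in res.atoms:
            if atom.name in rebuilt:
                atom.xyz = rebuilt[atom.name].xyz
            else:  # side-chain atom: carry the CA displacement
                atom.xyz = atom.xyz + (trace[p - start] - old_ca[p])
    return out


def _segment_cc(model: Model, dmap: DensityMap, segment: Segment,
                resolution: float) -> MaskedCC:
    sub = model.subset(range(segment.start, segment.stop))
    return map_model_cc(dmap, sub, resolution)


def generate_candidates(model: Model, dmap: DensityMap, plan: SegmentPlan,
                        resolution: float,
                        external_model: Model | None = None,
                        seed: int = 0,
                        refine: bool = True) -> list[CandidateModel]:
    """One full-length candidate per rebuilding strategy that succeeded.

    Strategies producing no segment are omitted; every candidate is
    refined and scored per plan segment.
    """
    rebuilds = plan.rebuild_segments
    candidates: list[CandidateModel] = []

    if not rebuilds:
        refined, _ = simple_real_space_refine(model, dmap, resolution)
        cand = CandidateModel(refined, "iterative_refine")
        cand.per_segment_cc = [_segment_cc(refined, dmap, s, resolution)
                               for s in plan.segments]
        return [cand]

    ca = model.ca_coords()
    for strategy in STRATEGY_ORDER:
        if strategy == "external" and external_model is None:
            continue
        try:
            if strategy == "iterative_refine":
                built = iterative_resolution_refine(model, dmap, resolution)
                n_done = len(rebuilds)
            elif strategy == "window_morph":
                built = model
                n_done = 0
                for seg in rebuilds:
                    built = window_morph(built, dmap, seg.interval,
                                         seed=seed)
                    n_done += 1
            else:
                built = model.copy()
                n_done = 0
                for seg in rebuilds:
                    trace = None
                    if strategy == "fit_loops":
                        trace = fit_loop(built, dmap, seg.interval,
                                         resolution, seed=seed)
                    elif strategy == "retrace":
                        if seg.start > 0 and seg.stop < len(ca):
                            trace = retrace_loop(
                                dmap, ca[seg.start - 1], ca[seg.stop],
                                seg.stop - seg.start)
                    elif strategy == "combination":
                        trace = combination_rebuild(built, dmap,
                                                    seg.interval, resolution)
                    elif strategy == "external":
                        trace = splice_external_fragment(
                            built, seg.interval, external_model, dmap)
                    if trace is not None \
                            and len(trace) == seg.stop - seg.start:
                        built = _replace_segment_ca(built, seg.interval,
                                                    trace)
                        n_done += 1
        except Exception as exc:  # strategy failure is not fatal
            logger.info("strategy %s failed: %s", strategy, exc)
            continue
        if n_done == 0:
            logger.info("strategy %s produced no segments", strategy)
            continue
        if refine:
            built, _ = simple_real_space_refine(built, dmap, resolution)
        cand = CandidateModel(built, strategy)
        cand.per_segment_cc = [_segment_cc(built, dmap, s, resolution)
                               for s in plan.segments]
        candidates.append(cand)
    return candidates


def assemble_best_segments(candidates: list[CandidateModel],
                           plan: SegmentPlan, dmap: DensityMap,
                           resolution: float, splice_n: int = 3,
                           final_refine: bool = True,
                           ) -> tuple[Model, dict]:
    """Chimera of the best-scoring candidate segment for every plan segment.

    Selection ties break toward the earlier strategy in the fixed order.
    Junctions of rebuild segments are smoothed with 3-residue splice
    morphs, then the assembly is refined once more.  The returned info
    dict records the chosen strategy and the pre-refinement segment
    correlation for every segment.
    """
    if not candidates:
        raise ValueError("no candidate models to assemble")
    base = candidates[0].model.copy()
    n = len(base)
    ca = base.ca_coords()
    choice: list[tuple[Segment, CandidateModel, float]] = []
    for si, seg in enumerate(plan.segments):
        best = max(candidates, key=lambda c: c.per_segment_cc[si].cc)
        choice.append((seg, best, best.per_segment_cc[si].cc))
    assembled = base
    for seg, cand, _ in choice:
        for p in range(seg.start, seg.stop):
            src = cand.model.residues[p]
            for atom in assembled.residues[p].atoms:
                src_atom = src.atom(atom.name)
                if src_atom is not None:
                    atom.xyz = src_atom.xyz.copy()
    info = {
        "segments": [
            {"interval": seg.interval, "label": seg.label,
             "strategy": cand.strategy, "cc": cc}
            for seg, cand, cc in choice],
    }
    # splice morphs at junctions: when the chimera breaks the chain at a
    # rebuild-segment boundary, morph that segment so its terminal CA sits
    # a bond length from the neighbour, tapering the pull over splice_n
    # residues; intact junctions are left untouched
    def junction_shift(anchor, end_ca):
        v = end_ca - anchor
        d = float(np.linalg.norm(v))
        if 2.5 <= d <= 4.5:
            return None
        return anchor + 3.8 * v / max(d, 1e-9) - end_ca

    final_ca = assembled.ca_coords()
    for seg, cand, _ in choice:
        if seg.label != "rebuild":
            continue
        seg_ca = final_ca[seg.start:seg.stop]
        k = min(splice_n, len(seg_ca))
        taper = np.linspace(1.0, 1.0 / k, k)[:, None]
        left = right = None
        if seg.start > 0:
            shift = junction_shift(final_ca[seg.start - 1], seg_ca[0])
            if shift is not None:
                left = seg_ca[:k] + taper * shift
        if seg.stop < n:
            shift = junction_shift(final_ca[seg.stop], seg_ca[-1])
            if shift is not None:
                right = seg_ca[-k:] + taper[::-1] * shift
        if left is None and right is None:
            continue
        sub = assembled.subset(range(seg.start, seg.stop))
        grafted = graft_segment(sub, left, right, splice_n)
        for p, res in zip(range(seg.start, seg.stop), grafted.residues):
            for atom in assembled.residues[p].atoms:
                src_atom = res.atom(atom.name)
                if src_atom is not None:
                    atom.xyz = src_atom.xyz.copy()
        final_ca = assembled.ca_coords()
    if final_refine:
        assembled, _ = simple_real_space_refine(assembled, dmap, resolution)
    return assembled, info
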