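"""Shift-field morphing: smooth distortion of a model onto docked domains.

A shift field is defined by anchor pairs (coordinate c_i, vector v_i) and a
distance scale D (``shift_field_distance``, default 10 Å).  Its value at a
point x is the Gaussian-weighted average of the anchor vectors,

    f(x) = sum_i w_i v_i / sum_i w_i,   w_i = exp(-|x - c_i|^2 / D^2).

When the field is built from docked domains there is one anchor per docked
CA: the coordinate is that CA's position in the full predicted model, the
vector is (docked position - predicted position).  Morphing displaces every
atom by the field value at its own coordinate, so rigid offsets are
reproduced exactly and local distortions occur on the ~D scale.

Two windowed variants serve model rebuilding: ``window_morph`` adjusts a
poorly fitting segment a few residues at a time from both ends inward, and
``graft_segment`` splices a segment onto fixed flank coordinates by
morphing with anchors on ``splice_n`` residues at each end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityMap, interpolate_density
from .io_core import Model

__all__ = [
    "ShiftField",
    "evaluate_shift_field",
    "build_field_from_docked",
    "morph_model",
    "window_morph",
    "graft_segment",
]


@dataclass
class ShiftField:
    anchors_xyz: np.ndarray      # (n, 3) anchor coordinates, Å
    vectors: np.ndarray          # (n, 3) shift vectors, Å
    shift_field_distance: float = 10.0

    def __post_init__(self):
        self.anchors_xyz = np.atleast_2d(np.asarray(self.anchors_xyz,
                                                    dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if (len(self.anchors_xyz) == 0
                or self.anchors_xyz.shape != self.vectors.shape):
            raise ValueError("need >= 1 anchor with matching vectors")
        if self.shift_field_distance <= 0:
            raise ValueError("shift_field_distance must be positive")


def evaluate_shift_field(field: ShiftField, points: np.ndarray) -> np.ndarray:
    """Field value at each point: Gaussian-weighted mean of anchor vectors."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts[:, None, :] - field.anchors_xyz[None, :, :]) ** 2).sum(axis=2)
    d2 = d2 - d2.min(axis=1, keepdims=True)  # stabilise the exponentials
    w = np.exp(-d2 / field.shift_field_distance ** 2)
    out = (w[:, :, None] * field.vectors[None, :, :]).sum(axis=1) \
        / w.sum(axis=1)[:, None]
    return out if np.asarray(points).ndim == 2 else out[0]


def build_field_from_docked(full_model: Model, docked_domains: list[Model],
                            shift_field_distance: float = 10.0,
                            n_iter: int = 5) -> ShiftField:
    """One anchor per docked CA: predicted position -> docked position.

    The Gaussian-weighted average smooths over neighbouring anchors, which
    would leave a systematic residual at the anchors themselves (a rigidly
    rotated domain would not quite reach its docked pose).  ``n_iter``
    rounds of residual correction adjust the stored vectors so the field
    interpolates the anchor displacements essentially exactly while
    staying smooth in between; ``n_iter=0`` gives the plain single-pass
    field.
    """
    anchors, vectors = [], []
    full_nums = {int(n): i for i, n in enumerate(full_model.residue_numbers)}
    full_ca = full_model.ca_coords()
    for dom in docked_domains:
        for res in dom.residues:
            if res.ca is None:
                continue
            if res.number not in full_nums:
                raise ValueError(
                    f"docked residue {res.number} not in the full model")
            i = full_nums[res.number]
            if not np.all(np.isfinite(full_ca[i])):
                continue
            anchors.append(full_ca[i])
            vectors.append(res.ca.xyz - full_ca[i])
    if not anchors:
        raise ValueError("no docked CA anchors found")
    anchors_arr = np.array(anchors)
    displacements = np.array(vectors)
    if n_iter > 0:
        # solve for stored vectors such that the weighted average at every
        # anchor reproduces its displacement exactly (RBF interpolation)
        d2 = ((anchors_arr[:, None, :] - anchors_arr[None, :, :]) ** 2
              ).sum(axis=2)
        w = np.exp(-d2 / shift_field_distance ** 2)
        w /= w.sum(axis=1, keepdims=True)
        try:
            solved = np.linalg.solve(w, displacements)
        except np.linalg.LinAlgError:
            solved = np.linalg.lstsq(w, displacements, rcond=None)[0]
        return ShiftField(anchors_arr, solved, shift_field_distance)
    return ShiftField(anchors_arr, displacements, shift_field_distance)


def morph_model(full_model: Model, field: ShiftField) -> Model:
    """Displace every atom by the field at its own coordinate.

    Topology, numbering and confidence are untouched.
    """
    morphed = full_model.copy()
    coords = morphed.atom_coords()
    morphed.set_atom_coords(coords + evaluate_shift_field(field, coords))
    return morphed


def _local_window_search(ca: np.ndarray, window_idx: np.ndarray,
                         dmap: DensityMap, rng: np.random.Generator,
                         max_shift: float = 1.5, n_restarts: int = 8,
                         n_steps: int = 20) -> np.ndarray:
    """Best common translation of a window's CAs that raises mean density
    while keeping consecutive CA distances in [2.9, 4.3] Å.

    A small quadratic displacement penalty keeps a window that already
    sits on its density from wandering on interpolation artifacts of
    sharply peaked grids.
    """
    penalty = 0.05 * float(dmap.grid.max())

    def mean_density(shift):
        vals, _ = interpolate_density(dmap, ca[window_idx] + shift)
        return float(vals.mean()) - penalty * float(np.dot(shift, shift))

    def geometry_ok(shift):
        trial = ca.copy()
        trial[window_idx] += shift
        lo = max(window_idx.min() - 1, 0)
        hi = min(window_idx.max() + 2, len(ca))
        d = np.linalg.norm(np.diff(trial[lo:hi], axis=0), axis=1)
        return bool(np.all((d >= 2.9) & (d <= 4.3)))

    baseline = mean_density(np.zeros(3))
    best_shift = np.zeros(3)
    best_val = baseline
    for restart in range(n_restarts):
        shift = (np.zeros(3) if restart == 0
                 else rng.uniform(-max_shift, max_shift, size=3))
        if not geometry_ok(shift):
            continue
        val = mean_density(shift)
        step = 0.6
        for _ in range(n_steps):
            improved = False
            for ax in range(3):
                for sgn in (1.0, -1.0):
                    trial = shift.copy()
                    trial[ax] += sgn * step
                    if np.linalg.norm(trial) > max_shift:
                        continue
                    if not geometry_ok(trial):
                        continue
                    v = mean_density(trial)
                    if v > val + 1e-12:
                        shift, val = trial, v
                        improved = True
            if not improved:
                step *= 0.5
                if step < 0.05:
                    break
        if val > best_val:
            best_val, best_shift = val, shift
    # a well-placed window gains only marginally by sliding along its own
    # density (tapering tube ends, interpolation texture); demand a clear
    # improvement before moving at all
    if best_val <= baseline + 0.20 * abs(baseline):
        return np.zeros(3)
    return best_shift


def window_morph(model: Model, dmap: DensityMap, segment: tuple[int, int],
                 n_window: int = 6, resolution: float | None = None,
                 shift_field_distance: float = 10.0, seed: int = 0) -> Model:
    """Morph a segment into density a window at a time, ends inward.

    ``n_window`` residues at each end are adjusted to raise the density at
    their CAs (subject to chain geometry), the rest of the segment is
    carried along by a shift field anchored on the adjusted windows, then
    the windows step one residue inward and the process repeats until the
    whole segment has been visited.
    """
    start, stop = segment
    if start < 0 or stop > len(model) or start >= stop:
        raise ValueError(f"segment {segment} outside model of {len(model)}")
    rng = np.random.default_rng(seed)
    out = model.copy()
    left, right = start, stop
    while left < right:
        windows = []
        w = min(n_window, right - left)
        windows.append(np.arange(left, left + w))
        if right - w > left + w:
            windows.append(np.arange(right - w, right))
        ca = out.ca_coords()
        anchors, vectors = [], []
        for idx in windows:
            shift = _local_window_search(ca, idx, dmap, rng)
            anchors.append(ca[idx])
            vectors.append(np.tile(shift, (len(idx), 1)))
        field = ShiftField(np.vstack(anchors), np.vstack(vectors),
                           shift_field_distance)
        # morph only the segment; the rest of the model stays put
        seg_positions = list(range(start, stop))
        coords = np.array([a.xyz for p in seg_positions
                           for a in out.residues[p].atoms])
        moved = coords + evaluate_shift_field(field, coords)
        k = 0
        for p in seg_positions:
            for a in out.residues[p].atoms:
                a.xyz = moved[k]
                k += 1
        left += 1
        right -= 1
    return out


def graft_segment(segment_model: Model, left_targets: np.ndarray | None,
                  right_targets: np.ndarray | None, splice_n: int = 3,
                  shift_field_distance: float = 10.0,
                  n_iter: int = 8) -> Model:
    """Morph a segment so its splice residues land on flank targets.

    ``left_targets`` / ``right_targets`` are target CA coordinates for the
    first / last ``splice_n`` residues of ``segment_model`` (either may be
    None for a free end).  Anchor vectors are refined iteratively so the
    splice CAs coincide with their targets to well under 0.5 Å, while the
    interior deforms smoothly on the shift-field scale.
    """
    out = segment_model.copy()
    n = len(out)
    idx: list[int] = []
    targets: list[np.ndarray] = []
    if left_targets is not None:
        lt = np.atleast_2d(left_targets)
        k = min(splice_n, len(lt), n)
        idx += list(range(k))
        targets += [lt[i] for i in range(k)]
    if right_targets is not None:
        rt = np.atleast_2d(right_targets)
        k = min(splice_n, len(rt), n)
        idx += list(range(n - k, n))
        targets += [rt[-k + i] for i in range(k)]
    if not idx:
        raise ValueError("graft requires at least one flank")
    targets_arr = np.array(targets, dtype=float)

    anchors = out.ca_coords()[idx]
    vectors = targets_arr - anchors
    for _ in range(n_iter):
        field = ShiftField(anchors, vectors, shift_field_distance)
        achieved = anchors + evaluate_shift_field(field, anchors)
        residual = targets_arr - achieved
        if float(np.abs(residual).max()) < 1e-3:
            break
        vectors = vectors + residual
    field = ShiftField(anchors, vectors, shift_field_distance)
    coords = out.atom_coords()
    out.set_atom_coords(coords + evaluate_shift_field(field, coords))
    return out
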