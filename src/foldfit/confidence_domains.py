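"""Confidence processing: normalisation, smoothing, trimming, domain split.

Predicted models carry per-residue confidence (plDDT) in the B-value
column, on either a 0-1 or a 0-100 scale.  Before docking, residues below
the "good prediction" cutoff (70 on the 0-100 scale) are removed and the
remainder is grouped into up to ``maximum_domains`` compact units, each of
at least ``minimum_domain_length`` residues.  Grouping is by spatial
proximity (single-linkage clustering of contiguous chain segments on
minimum CA-CA distance) or, when a predicted aligned-error matrix is
available, by connectivity of the low-PAE residue graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import EmptyModelError, Model

__all__ = [
    "ConfidenceProfile",
    "Domain",
    "DomainSet",
    "normalize_confidence",
    "smooth_profile",
    "trim_low_confidence",
    "split_into_domains",
    "load_pae_json",
]


@dataclass
class ConfidenceProfile:
    values: np.ndarray          # per-residue, 0-100
    source_scale: str           # "0-1" or "0-100"


@dataclass
class Domain:
    """One compact unit: half-open intervals of 0-based chain positions."""

    intervals: list[tuple[int, int]]

    @property
    def positions(self) -> list[int]:
        return [p for a, b in self.intervals for p in range(a, b)]

    def __len__(self) -> int:
        return sum(b - a for a, b in self.intervals)


@dataclass
class DomainSet:
    domains: list[Domain]
    method: str = "proximity"
    warnings: list[str] = field(default_factory=list)


def normalize_confidence(raw: np.ndarray) -> ConfidenceProfile:
    """Detect the confidence scale and normalise to 0-100.

    Values with max <= 1 are treated as the 0-1 convention and multiplied
    by 100; anything outside [0, 100.5] after normalisation is rejected as
    not being a confidence column.
    """
    vals = np.asarray(raw, dtype=float)
    if vals.size == 0:
        raise ValueError("empty confidence column")
    if np.nanmax(vals) <= 1.0:
        vals = vals * 100.0
        scale = "0-1"
    else:
        scale = "0-100"
    if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 100.5:
        raise ValueError(
            f"values in [{np.nanmin(vals):.1f}, {np.nanmax(vals):.1f}] after "
            "normalisation: not a plDDT-style confidence column")
    return ConfidenceProfile(np.clip(vals, 0.0, 100.0), scale)


def smooth_profile(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered running mean; the window truncates at the chain ends.

    The window covers ``window`` residues where the full window fits
    (``(window-1)//2`` to the left, ``window//2`` to the right).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    out = np.empty(n)
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    for i in range(n):
        a = max(0, i - left)
        b = min(n, i + right + 1)
        out[i] = (csum[b] - csum[a]) / (b - a)
    return out


def trim_low_confidence(model: Model, profile: ConfidenceProfile,
                        threshold: float = 70.0, window: int = 10,
                        ) -> Model:
    """Remove residues whose smoothed confidence is below ``threshold``.

    Residue numbering is preserved.  ``window=1`` disables smoothing.
    """
    if len(profile.values) != len(model):
        raise ValueError("profile length != residue count")
    smoothed = smooth_profile(profile.values, window)
    keep = np.nonzero(smoothed >= threshold)[0]
    if len(keep) == 0:
        raise EmptyModelError(
            f"all residues trimmed: max smoothed confidence "
            f"{smoothed.max():.1f} < threshold {threshold}")
    return model.subset(keep)


def load_pae_json(path: str | Path) -> np.ndarray:
    """Read a predicted-aligned-error matrix (AlphaFold pae.json dialect)."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        data = data[0]
    mat = np.asarray(data["predicted_aligned_error"], dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or np.any(mat < 0):
        raise ValueError("not a square non-negative PAE matrix")
    return mat


def _contiguous_segments(model: Model) -> list[tuple[int, int]]:
    """Half-open position intervals of runs with consecutive numbering."""
    nums = model.residue_numbers
    breaks = np.nonzero(np.diff(nums) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [len(nums)]])
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_to_count(segments: list[tuple[int, int]], labels: np.ndarray,
                    seg_dist: np.ndarray, n_target: int,
                    join_distance: float = 8.0) -> np.ndarray:
    """Single-linkage merging of segment clusters.

    Merges until at most ``n_target`` clusters remain, and keeps merging
    while the two nearest clusters are within ``join_distance`` (clusters
    that close are one compact unit, so a compact fold yields a single
    domain rather than being split to the maximum count).
    """
    labels = labels.copy()
    while len(np.unique(labels)) > 1:
        uniq = np.unique(labels)
        best = (np.inf, None)
        for i, la in enumerate(uniq):
            for lb in uniq[i + 1:]:
                d = seg_dist[np.ix_(labels == la, labels == lb)].min()
                if d < best[0]:
                    best = (d, (la, lb))
        if len(uniq) <= n_target and best[0] >= join_distance:
            break
        la, lb = best[1]
        labels[labels == lb] = la
    return labels


def split_into_domains(model: Model, maximum_domains: int = 3,
                       minimum_domain_length: int = 10,
                       method: str = "proximity",
                       pae: np.ndarray | None = None,
                       pae_cutoff: float = 6.0) -> DomainSet:
    """Group a trimmed model into up to ``maximum_domains`` compact units.

    ``proximity``: contiguous chain segments are clustered by single
    linkage on minimum inter-segment CA-CA distance until at most
    ``maximum_domains`` clusters remain.  ``pae``: segments are connected
    when any residue pair across them has predicted aligned error below
    ``pae_cutoff`` (Å), then the same count/size constraints are applied.
    Clusters shorter than ``minimum_domain_length`` are merged into their
    spatially nearest cluster.
    """
    if len(model) == 0:
        raise EmptyModelError("cannot split an empty model")
    notes: list[str] = []
    if len(model) < minimum_domain_length:
        notes.append(f"model shorter than minimum_domain_length "
                     f"({len(model)} < {minimum_domain_length}); "
                     "single domain returned")
        warnings.warn(notes[-1])
        return DomainSet([Domain([(0, len(model))])], method, notes)

    segments = _contiguous_segments(model)
    ca = model.ca_coords()
    nseg = len(segments)
    seg_dist = np.zeros((nseg, nseg))
    for i, (a1, b1) in enumerate(segments):
        for j, (a2, b2) in enumerate(segments):
            if j <= i:
                continue
            d = cdist(ca[a1:b1], ca[a2:b2]).min()
            seg_dist[i, j] = seg_dist[j, i] = d

    if method == "proximity":
        labels = np.arange(nseg)
        labels = _merge_to_count(segments, labels, seg_dist, maximum_domains)
    elif method == "pae":
        if pae is None:
            raise ValueError("pae method requires a PAE matrix")
        # map trimmed positions back to the PAE's residue indexing via
        # residue numbers (PAE rows follow the untrimmed chain, 0-based)
        nums = model.residue_numbers - model.residue_numbers.min()
        labels = np.arange(nseg)
        # union segments whose cross-PAE dips below the cutoff
        for i, (a1, b1) in enumerate(segments):
            for j in range(i + 1, nseg):
                a2, b2 = segments[j]
                block = pae[np.ix_(nums[a1:b1], nums[a2:b2])]
                if block.min() < pae_cutoff:
                    labels[labels == labels[j]] = labels[i]
        labels = _merge_to_count(segments, labels, seg_dist, maximum_domains)
    else:
        raise ValueError(f"unknown method {method!r}")

    # absorb undersized clusters into the spatially nearest cluster
    def cluster_len(lab):
        return sum(b - a for (a, b), l in zip(segments, labels) if l == lab)

    changed = True
    while changed:
        changed = False
        uniq = list(np.unique(labels))
        if len(uniq) <= 1:
            break
        for lab in uniq:
            if cluster_len(lab) < minimum_domain_length:
                others = [l for l in uniq if l != lab]
                dmin, best = np.inf, others[0]
                for other in others:
                    d = seg_dist[np.ix_(labels == lab,
                                        labels == other)].min()
                    if d < dmin:
                        dmin, best = d, other
                labels[labels == lab] = best
                changed = True
                break

    domains = []
    for lab in sorted(np.unique(labels),
                      key=lambda l: min(segments[i][0]
                                        for i in np.nonzero(labels == l)[0])):
        ivs = sorted(segments[i] for i in np.nonzero(labels == lab)[0])
        # merge touching intervals
        merged: list[tuple[int, int]] = []
        for a, b in ivs:
            if merged and merged[-1][1] == a:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        domains.append(Domain([tuple(iv) for iv in merged]))
    return DomainSet(domains, method, notes)
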