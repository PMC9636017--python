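"""Per-cycle dock-and-rebuild orchestration and the multi-cycle loop.

One cycle takes a predicted model (confidence in the B-value column) and a
density map and runs five stages in order: trim and split into domains,
dock the domains, morph the full model onto the docked domains, create
rebuilt candidate models, and assemble the best parts.  The multi-cycle
driver feeds each cycle's rebuilt model back to a pluggable predictor as a
template — a deterministic stub stands in for a real structure-prediction
network, which is outside this package's scope.

Two outputs are distinguished after iteration: the last predictor output
(a predicted model informed by the map through its template) and the last
rebuilt model (the procedure's final map-fitted model).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np

from .confidence_domains import (normalize_confidence, split_into_domains,
                                 trim_low_confidence)
from .density import DensityMap, map_model_cc
from .docking import DockingParams, PlacementCombo, dock_domains
from .io_core import EmptyModelError, Model, Transform
from .metrics import chain_comparison
from .morphing import build_field_from_docked, morph_model
from .rebuilding import (assemble_best_segments, generate_candidates,
                         identify_poor_segments, simple_real_space_refine)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CycleResult",
    "StubPredictor",
    "run_cycle",
    "run_iterative",
    "load_symmetry_operators",
]


@dataclass
class PipelineConfig:
    """Every tunable of the procedure, under its field-standard name."""

    # trimming / splitting
    maximum_domains: int = 3
    minimum_domain_length: int = 10
    plddt_threshold: float = 70.0
    domain_method: str = "proximity"
    # docking
    match_distance_high: float = 5.0
    ok_brute_force_cc: float = 0.25
    ssm_search_min_cc: float = 0.3
    minimum_docking_cc: float = 0.15
    acceptable_docking_cc: float = 0.5
    allowed_fraction_overlapping: float = 0.1
    overlap_ca_ca_distance: float = 3.0
    maximum_connectivity_deviation: float = 15.0
    rotation_spacing_deg: float = 24.0
    use_both_dock_modes: bool = False
    # morphing / rebuilding
    shift_field_distance: float = 10.0
    iterative_refine_start_resolution: float = 6.0
    n_window: int = 6
    ca_distance: float = 3.8
    cc_sd_ratio: float = 3.0
    # iteration
    n_cycles: int = 4
    early_stop_rmsd: float = 0.3
    seed: int = 0

    def docking_params(self) -> DockingParams:
        return DockingParams(
            match_distance_high=self.match_distance_high,
            ok_brute_force_cc=self.ok_brute_force_cc,
            ssm_search_min_cc=self.ssm_search_min_cc,
            minimum_docking_cc=self.minimum_docking_cc,
            acceptable_docking_cc=self.acceptable_docking_cc,
            allowed_fraction_overlapping=self.allowed_fraction_overlapping,
            overlap_ca_ca_distance=self.overlap_ca_ca_distance,
            maximum_connectivity_deviation=self.maximum_connectivity_deviation,
            rotation_spacing_deg=self.rotation_spacing_deg,
            use_both_dock_modes=self.use_both_dock_modes,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` file; unknown keys are rejected."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{line_no}: expected key = value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{line_no}: unknown parameter "
                                     f"{key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class CycleResult:
    cycle_index: int
    docked_morphed_model: Model | None
    rebuilt_model: Model | None
    placement_combo: PlacementCombo | None
    metrics: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)
    config_used: dict = field(default_factory=dict)
    error: str | None = None


class Predictor(Protocol):
    """Contract: (sequence, optional template model, seed) -> Model with
    per-residue confidence covering the sequence."""

    def __call__(self, sequence: str, template: Model | None,
                 seed: int) -> Model: ...


class StubPredictor:
    """Deterministic predictor stand-in for testing the iteration loop.

    Without a template it returns a configured initial prediction; with a
    template it returns the template with seeded coordinate jitter
    (sigma 0.3 Å) and confidence pulled halfway toward 90 — emulating a
    network that trusts a map-consistent template.
    """

    def __init__(self, initial_model: Model, jitter_sigma: float = 0.3):
        self.initial_model = initial_model
        self.jitter_sigma = jitter_sigma

    def __call__(self, sequence: str, template: Model | None = None,
                 seed: int = 0) -> Model:
        if template is None:
            return self.initial_model.copy()
        if template.sequence != sequence:
            raise ValueError("template sequence does not match the request")
        rng = np.random.default_rng(seed)
        out = template.copy()
        coords = out.atom_coords()
        out.set_atom_coords(coords + rng.normal(0.0, self.jitter_sigma,
                                                size=coords.shape))
        out.confidence = np.clip(0.5 * (out.confidence + 90.0), 0.0, 98.0)
        return out


def load_symmetry_operators(path: str | Path) -> list[Transform]:
    """Plain-text operators: one row-major 3x4 matrix (12 numbers) per line."""
    ops = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            vals = [float(x) for x in line.replace(",", " ").split()]
            if len(vals) != 12:
                raise ValueError(f"{path}:{line_no}: expected 12 numbers")
            m = np.array(vals).reshape(3, 4)
            ops.append(Transform(m[:, :3], m[:, 3]))
    return ops


def _domain_models_and_gaps(trimmed: Model, domain_set,
                            ) -> tuple[dict[int, Model],
                                       dict[tuple[int, int], int]]:
    domains = {i: trimmed.subset(d.positions)
               for i, d in enumerate(domain_set.domains)}
    order = sorted(domains,
                   key=lambda i: int(domains[i].residue_numbers[0]))
    gaps: dict[tuple[int, int], int] = {}
    for a, b in zip(order, order[1:]):
        gap = int(domains[b].residue_numbers[0]
                  - domains[a].residue_numbers[-1]) - 1
        gaps[(a, b)] = max(gap, 0)
    return domains, gaps


def run_cycle(predicted_model: Model, dmap: DensityMap, resolution: float,
              config: PipelineConfig | None = None,
              external_model: Model | None = None,
              symmetry_ops: list[Transform] | None = None,
              pae: np.ndarray | None = None,
              reference: Model | None = None,
              cycle_index: int = 1) -> CycleResult:
    """One dock-and-rebuild cycle.

    Stages: trim/split, dock, morph + refine, rebuild candidates, assemble.
    On total docking failure the cycle aborts and returns the inputs with a
    diagnostic.  ``reference`` (a known answer, for benchmarking only) adds
    connectivity-free match fractions to the metrics.
    """
    config = config or PipelineConfig()
    result = CycleResult(cycle_index, None, None, None,
                         config_used=config.to_dict())
    log = result.stage_log

    # stage 1: trim and split into domains
    try:
        profile = normalize_confidence(predicted_model.confidence)
        trimmed = trim_low_confidence(predicted_model, profile,
                                      config.plddt_threshold,
                                      config.minimum_domain_length)
    except EmptyModelError as exc:
        result.error = f"trimming failed: {exc}"
        logger.warning(result.error)
        return result
    domain_set = split_into_domains(trimmed, config.maximum_domains,
                                    config.minimum_domain_length,
                                    config.domain_method, pae)
    domains, gaps = _domain_models_and_gaps(trimmed, domain_set)
    log.append(("trim_and_split", {
        "n_residues": len(predicted_model), "n_kept": len(trimmed),
        "n_domains": len(domains),
        "domain_sizes": [len(m) for m in domains.values()]}))

    # stage 2: dock domains
    combo, per_domain = dock_domains(domains, dmap, resolution, gaps,
                                     symmetry_ops, config.docking_params())
    placed = {d: p for d, p in combo.placements.items() if p is not None}
    log.append(("dock", {
        "n_placed": len(placed), "score": combo.score,
        "breakdown": dict(combo.breakdown),
        "ccs": {d: p.cc for d, p in placed.items()}}))
    result.placement_combo = combo
    if not placed:
        result.error = "docking failed: no domain could be placed"
        logger.warning(result.error)
        return result

    # stage 3: morph the full model onto the docked domains, then refine
    docked_models = [domains[d].transformed(p.transform)
                     for d, p in placed.items()]
    sf = build_field_from_docked(predicted_model, docked_models,
                                 config.shift_field_distance)
    morphed = morph_model(predicted_model, sf)
    refined, _ = simple_real_space_refine(morphed, dmap, resolution)
    result.docked_morphed_model = refined
    cc_docked = map_model_cc(dmap, refined, resolution).cc
    log.append(("morph_refine", {"cc": cc_docked}))

    # stage 4: identify poor segments, build candidates
    conf_norm = normalize_confidence(predicted_model.confidence).values
    plan = identify_poor_segments(refined, dmap, conf_norm,
                                  window=config.minimum_domain_length,
                                  plddt_threshold=config.plddt_threshold,
                                  sd_ratio=config.cc_sd_ratio)
    candidates = generate_candidates(refined, dmap, plan, resolution,
                                     external_model, seed=config.seed)
    log.append(("rebuild", {
        "n_rebuild_segments": len(plan.rebuild_segments),
        "strategies": [c.strategy for c in candidates]}))

    # stage 5: assemble the best parts
    rebuilt, assembly = assemble_best_segments(candidates, plan, dmap,
                                               resolution)
    cc_rebuilt = map_model_cc(dmap, rebuilt, resolution).cc
    if cc_rebuilt < cc_docked - 0.05:
        logger.warning("rebuilt model lost correlation (%.3f -> %.3f); "
                       "keeping docked/morphed model", cc_docked, cc_rebuilt)
        rebuilt, cc_rebuilt = refined, cc_docked
    result.rebuilt_model = rebuilt
    log.append(("assemble", {"cc": cc_rebuilt, "assembly": assembly}))

    result.metrics = {"cc_docked_morphed": cc_docked,
                      "cc_rebuilt": cc_rebuilt}
    if reference is not None:
        result.metrics["fraction_matched_input"] = chain_comparison(
            reference, predicted_model).fraction_matched
        result.metrics["fraction_matched_rebuilt"] = chain_comparison(
            reference, rebuilt).fraction_matched
    return result


def run_iterative(predictor: Predictor, sequence: str, dmap: DensityMap,
                  resolution: float, config: PipelineConfig | None = None,
                  n_cycles: int | None = None,
                  external_model: Model | None = None,
                  symmetry_ops: list[Transform] | None = None,
                  reference: Model | None = None) -> list[CycleResult]:
    """Multi-cycle loop: predict, dock and rebuild, re-template.

    Cycle 1 calls the predictor with the sequence alone; later cycles pass
    the previous rebuilt model as template.  Iteration stops early when
    consecutive rebuilt models agree within ``config.early_stop_rmsd``
    (CA r.m.s.d.).
    """
    config = config or PipelineConfig()
    n_cycles = n_cycles or config.n_cycles
    results: list[CycleResult] = []
    template: Model | None = None
    previous: Model | None = None
    for cycle in range(1, n_cycles + 1):
        try:
            predicted = predictor(sequence, template,
                                  seed=config.seed + cycle)
        except Exception as exc:
            raise RuntimeError(f"predictor failed at cycle {cycle}: {exc}"
                               ) from exc
        res = run_cycle(predicted, dmap, resolution, config,
                        external_model, symmetry_ops,
                        reference=reference, cycle_index=cycle)
        res.metrics["predicted_model"] = predicted
        results.append(res)
        if res.rebuilt_model is None:
            break
        template = res.rebuilt_model
        if previous is not None and len(previous) == len(template):
            d = template.ca_coords() - previous.ca_coords()
            rmsd = float(np.sqrt(np.nanmean(np.sum(d * d, axis=1))))
            res.metrics["rmsd_to_previous"] = rmsd
            if rmsd < config.early_stop_rmsd:
                logger.info("converged at cycle %d (r.m.s.d. %.2f Å)",
                            cycle, rmsd)
                break
        previous = template
    return results
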