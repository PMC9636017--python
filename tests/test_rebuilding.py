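"""Poor-segment identification, the rebuild strategies, and assembly."""

import numpy as np
import pytest

from foldfit import fixtures as fx
from foldfit.density import interpolate_density, map_model_cc
from foldfit.io_core import DensityMap
from oracles import oracle_widest_path
from foldfit.rebuilding import (CandidateModel, Segment, SegmentPlan,
                                assemble_best_segments, combination_rebuild,
                                fit_loop, generate_candidates,
                                identify_poor_segments,
                                iterative_resolution_refine, retrace_loop,
                                simple_real_space_refine,
                                splice_external_fragment)


def ca_rmsd(a, b):
    d = a.ca_coords() - b.ca_coords()
    return float(np.sqrt(np.nanmean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# segment identification


class TestIdentify:
    def test_perfect_model_no_rebuild(self, single_domain):
        _, truth, dmap = single_domain
        plan = identify_poor_segments(truth, dmap, truth.confidence)
        assert plan.rebuild_segments == []
        assert plan.tiles(len(truth))

    def test_displaced_residues_flagged(self, single_domain):
        _, truth, dmap = single_domain
        broken = truth.copy()
        coords = broken.atom_coords()
        # residues 16..26 are atoms 64..104 (4 atoms each)
        coords[16 * 4:26 * 4] += np.array([0.0, 15.0, 0.0])
        broken.set_atom_coords(coords)
        plan = identify_poor_segments(broken, dmap, broken.confidence)
        flagged = {p for s in plan.rebuild_segments
                   for p in range(s.start, s.stop)}
        assert set(range(18, 24)).issubset(flagged)  # core certainly caught
        assert flagged.issubset(set(range(10, 32)))  # within window reach
        assert plan.tiles(len(truth))

    def test_confidence_dip_flagged(self, single_domain):
        _, truth, dmap = single_domain
        conf = truth.confidence.copy()
        conf[20:36] = 40.0
        plan = identify_poor_segments(truth, dmap, conf, window=1)
        rebuilds = plan.rebuild_segments
        assert len(rebuilds) == 1
        start, stop = rebuilds[0].interval
        # the dip itself plus the 2-residue splice padding
        assert (start, stop) == (18, 38)
        assert rebuilds[0].reason == "low_confidence"

    def test_whole_model_flagged_warns(self, single_domain):
        _, truth, dmap = single_domain
        with pytest.warns(UserWarning):
            plan = identify_poor_segments(truth, dmap,
                                          np.full(len(truth), 10.0))
        assert len(plan.rebuild_segments) == 1
        assert plan.rebuild_segments[0].interval == (0, len(truth))


# ---------------------------------------------------------------------------
# refinement


class TestRefine:
    def test_fixed_point(self, single_domain):
        _, truth, dmap = single_domain
        refined, ok = simple_real_space_refine(truth, dmap, 3.0)
        assert ok
        dev = np.abs(refined.ca_coords() - truth.ca_coords())
        assert dev.max() <= 0.1

    def test_one_angstrom_offset_recovered(self, single_domain):
        _, truth, dmap = single_domain
        off = truth.copy()
        off.set_atom_coords(off.atom_coords() + [1.0, 0.0, 0.0])
        refined, ok = simple_real_space_refine(off, dmap, 3.0)
        assert ok
        assert ca_rmsd(refined, truth) <= 0.3

    def test_zero_map_keeps_model_flagged(self, single_domain):
        _, truth, _ = single_domain
        zero = fx.make_synthetic_map(truth, 3.0)
        zero = zero.like(np.zeros(zero.shape, np.float32))
        refined, ok = simple_real_space_refine(truth, zero, 3.0)
        assert not ok
        assert ca_rmsd(refined, truth) <= 0.5  # restraints only

    def test_iterative_schedule_recovers_two_angstroms(self, single_domain):
        _, truth, dmap = single_domain
        off = truth.copy()
        off.set_atom_coords(off.atom_coords() + [2.0, 0.0, 0.0])
        refined = iterative_resolution_refine(off, dmap, 3.0)
        assert ca_rmsd(refined, truth) <= 0.5
        d = np.linalg.norm(np.diff(refined.ca_coords(), axis=0), axis=1)
        assert d.min() >= 2.9 and d.max() <= 4.3

    def test_start_equal_resolution_single_pass(self, single_domain):
        _, truth, dmap = single_domain
        refined = iterative_resolution_refine(truth, dmap, 3.0, start=3.0)
        cc0 = map_model_cc(dmap, truth, 3.0).cc
        cc1 = map_model_cc(dmap, refined, 3.0).cc
        assert abs(cc1 - cc0) <= 1e-3


# ---------------------------------------------------------------------------
# widest-path retracing


def tube_map(shape=(20, 12, 12), path=None, value=1.0):
    grid = np.zeros(shape, np.float32)
    if path is None:
        path = [(i, 6, 6) for i in range(3, 17)]
    for p in path:
        grid[p] = value
    return DensityMap(grid, np.ones(3), np.zeros(3))



class TestRetrace:
    def test_straight_tube(self):
        dmap = tube_map()
        trace = retrace_loop(dmap, np.array([3.0, 6, 6]),
                             np.array([16.0, 6, 6]), 3)
        assert trace is not None and len(trace) == 3
        np.testing.assert_allclose(trace[:, 1:], 6.0, atol=0.6)
        vals, _ = interpolate_density(dmap, trace)
        assert vals.min() >= 0.5  # on the unit-density tube

    def test_two_channels_picks_wider(self):
        grid = np.zeros((20, 12, 12), np.float32)
        grid[3:17, 3, 6] = 0.8   # good channel
        grid[3:17, 9, 6] = 0.3   # weak channel
        grid[3, 3:10, 6] = 0.8   # connectors at the ends
        grid[16, 3:10, 6] = 0.8
        dmap = DensityMap(grid, np.ones(3), np.zeros(3))
        trace = retrace_loop(dmap, np.array([3.0, 6, 6]),
                             np.array([16.0, 6, 6]), 6)
        assert trace is not None
        # the path runs through the y=3 channel, not y=9
        assert trace[:, 1].mean() < 6.0

    def test_disconnected_islands_fail(self):
        grid = np.zeros((20, 12, 12), np.float32)
        grid[2:5, 6, 6] = 1.0
        grid[15:18, 6, 6] = 1.0
        dmap = DensityMap(grid, np.ones(3), np.zeros(3))
        assert retrace_loop(dmap, np.array([3.0, 6, 6]),
                            np.array([16.0, 6, 6]), 3) is None

    def test_matches_bottleneck_dijkstra_oracle(self, rng):
        """Path minimum equals the exact bottleneck optimum on random
        grids (independent Dijkstra oracle)."""
        for trial in range(25):
            shape = tuple(rng.integers(6, 12, size=3))
            grid = rng.random(shape).astype(np.float32)
            dmap = DensityMap(grid, np.ones(3), np.zeros(3))
            a = np.zeros(3)
            b = np.array(shape, float) - 1
            expected = oracle_widest_path(dmap, a, b)
            trace = retrace_loop(dmap, a, b, 4, margin=20.0)
            assert trace is not None
            vals, _ = interpolate_density(dmap, trace)
            # interpolation between voxels can only sit near the optimum
            assert vals.min() >= 0.5 * expected - 0.25


# ---------------------------------------------------------------------------
# loop fitting and splicing


class TestFitLoop:
    def test_planted_truth_wins(self, single_domain):
        _, truth, dmap = single_domain
        seg = (14, 30)
        true_trace = truth.ca_coords()[14:30].copy()
        broken = truth.copy()
        coords = broken.atom_coords()
        coords[14 * 4:30 * 4] += np.array([0.0, 6.0, 0.0])
        broken.set_atom_coords(coords)
        result = fit_loop(broken, dmap, seg, 3.0, seed=0,
                          extra_candidates=[true_trace])
        assert result is not None
        np.testing.assert_allclose(result, true_trace, atol=1e-9)

    def test_zero_map_returns_smoothest(self):
        model = fx.make_toy_fold(fx.FixtureSpec(topology=[("loop", 20)],
                                                seed=5))
        zero = fx.make_synthetic_map(model, 3.0)
        zero = zero.like(np.zeros(zero.shape, np.float32))
        result = fit_loop(model, zero, (5, 15), 3.0, seed=0)
        assert result is not None
        # smoothest candidate: nearly straight interpolation between flanks
        sec = np.diff(result, n=2, axis=0)
        assert float(np.abs(sec).max()) < 1.0

    def test_unspannable_gap_fails(self, single_domain):
        _, truth, dmap = single_domain
        stretched = truth.copy()
        coords = stretched.atom_coords()
        coords[30 * 4:] += np.array([100.0, 0.0, 0.0])
        stretched.set_atom_coords(coords)
        assert fit_loop(stretched, dmap, (28, 30), 3.0) is None

    def test_single_residue_direct_placement(self, single_domain):
        _, truth, dmap = single_domain
        result = fit_loop(truth, dmap, (20, 21), 3.0, seed=0)
        assert result is not None and result.shape == (1, 3)
        assert np.linalg.norm(result[0] - truth.ca_coords()[20]) <= 4.0


class TestCombination:
    def test_fully_clear_segment_follows_density(self, single_domain):
        _, truth, dmap = single_domain
        result = combination_rebuild(truth, dmap, (16, 26), 3.0)
        assert result is not None and len(result) == 10
        vals, _ = interpolate_density(dmap, result)
        assert vals.min() > 0.0


class TestExternalSplice:
    def test_true_fragment_accepted(self, single_domain):
        _, truth, dmap = single_domain
        external = truth.copy()  # contains the true loop at true position
        result = splice_external_fragment(truth, (14, 30), external, dmap)
        assert result is not None
        np.testing.assert_allclose(result, truth.ca_coords()[14:30],
                                   atol=1e-9)

    def test_distant_fragment_rejected(self, single_domain):
        _, truth, dmap = single_domain
        external = truth.copy()
        external.set_atom_coords(external.atom_coords() + [5.0, 0.0, 0.0])
        assert splice_external_fragment(truth, (14, 30), external,
                                        dmap) is None


# ---------------------------------------------------------------------------
# candidate generation and assembly


@pytest.fixture(scope="module")
def broken_case():
    spec, truth, dmap = fx.single_domain_case(seed=0)
    broken = truth.copy()
    coords = broken.atom_coords()
    coords[14 * 4:30 * 4] += np.array([0.0, 4.0, 0.0])
    broken.set_atom_coords(coords)
    conf = truth.confidence.copy()
    conf[14:30] = 40.0
    plan = identify_poor_segments(broken, dmap, conf, window=1)
    return truth, broken, dmap, plan


def test_generate_no_rebuild_single_candidate(single_domain):
    _, truth, dmap = single_domain
    plan = identify_poor_segments(truth, dmap, truth.confidence)
    cands = generate_candidates(truth, dmap, plan, 3.0)
    assert len(cands) == 1


def test_generate_candidates_per_strategy(broken_case):
    """Without an external model, the five internal strategies that can
    produce a segment each yield one full-length candidate."""
    truth, broken, dmap, plan = broken_case
    cands = generate_candidates(broken, dmap, plan, 3.0, seed=0)
    names = [c.strategy for c in cands]
    assert 3 <= len(names) <= 5
    assert "external" not in names
    assert len(set(names)) == len(names)
    for c in cands:
        assert len(c.model) == len(broken)
        assert len(c.per_segment_cc) == len(plan.segments)


def test_assembly_single_candidate_is_identity(single_domain):
    _, truth, dmap = single_domain
    plan = identify_poor_segments(truth, dmap, truth.confidence)
    cand = CandidateModel(truth.copy(), "iterative_refine")
    from foldfit.rebuilding import _segment_cc
    cand.per_segment_cc = [_segment_cc(truth, dmap, s, 3.0)
                           for s in plan.segments]
    assembled, info = assemble_best_segments([cand], plan, dmap, 3.0,
                                             final_refine=False)
    assert ca_rmsd(assembled, truth) <= 0.01


def test_assembly_optimality(broken_case, rng):
    """Every assembled segment carries the per-candidate maximum cc."""
    truth, broken, dmap, plan = broken_case
    cands = generate_candidates(broken, dmap, plan, 3.0, seed=0)
    _, info = assemble_best_segments(cands, plan, dmap, 3.0,
                                     final_refine=False)
    for si, seg_info in enumerate(info["segments"]):
        best = max(c.per_segment_cc[si].cc for c in cands)
        assert seg_info["cc"] == pytest.approx(best)


def test_assembly_tie_breaks_by_strategy_order(single_domain):
    _, truth, dmap = single_domain
    plan = identify_poor_segments(truth, dmap, truth.confidence)
    from foldfit.rebuilding import _segment_cc
    ccs = [_segment_cc(truth, dmap, s, 3.0) for s in plan.segments]
    first = CandidateModel(truth.copy(), "iterative_refine")
    first.per_segment_cc = ccs
    second = CandidateModel(truth.copy(), "retrace")
    second.per_segment_cc = ccs  # exact tie
    _, info = assemble_best_segments([first, second], plan, dmap, 3.0,
                                     final_refine=False)
    assert all(s["strategy"] == "iterative_refine"
               for s in info["segments"])


def test_rebuilding_preserves_residues(broken_case):
    truth, broken, dmap, plan = broken_case
    cands = generate_candidates(broken, dmap, plan, 3.0, seed=0)
    assembled, _ = assemble_best_segments(cands, plan, dmap, 3.0)
    assert assembled.residue_numbers.tolist() \
        == broken.residue_numbers.tolist()


def test_rebuild_improves_broken_model(broken_case):
    """The displaced segment ends up substantially closer to the truth."""
    truth, broken, dmap, plan = broken_case
    cands = generate_candidates(broken, dmap, plan, 3.0, seed=0)
    assembled, _ = assemble_best_segments(cands, plan, dmap, 3.0)
    before = ca_rmsd(broken, truth)
    after = ca_rmsd(assembled, truth)
    assert after < 0.5 * before
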