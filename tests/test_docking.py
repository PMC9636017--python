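"""SSE detection, SSM and correlation docking, empirical combo scoring."""

import numpy as np
import pytest

from foldfit import fixtures as fx
from foldfit.docking import (DockingParams, Placement, correlation_dock,
                             detect_sse_from_map, detect_sse_from_model,
                             expand_placements, rigid_body_refine,
                             score_placement_combo, select_placements,
                             ssm_dock)
from foldfit.io_core import DensityMap, Transform
from oracles import oracle_score


def random_rigid(rng, max_angle=180.0, max_shift=5.0):
    rot = fx.rotation_about_axis(rng.normal(size=3),
                                 rng.uniform(0, max_angle))
    return Transform(rot, rng.uniform(-max_shift, max_shift, size=3))


def recovery_rmsd(domain, placement, truth):
    back = domain.transformed(placement.transform)
    d = back.ca_coords() - truth.ca_coords()
    return float(np.sqrt(np.nanmean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# SSE detection


class TestModelSSE:
    def test_ideal_helix_detected_full_length(self, helix12):
        sses = detect_sse_from_model(helix12)
        assert len(sses) == 1
        assert sses[0].kind == "helix"
        assert len(sses[0]) == 12

    def test_ideal_strand_detected(self):
        strand = fx.make_toy_fold(fx.FixtureSpec(topology=[("strand", 6)],
                                                 seed=0))
        sses = detect_sse_from_model(strand)
        assert len(sses) == 1
        assert sses[0].kind == "strand"
        assert len(sses[0]) >= 4

    def test_random_coil_rejected(self):
        coil = fx.make_toy_fold(fx.FixtureSpec(topology=[("loop", 25)],
                                               seed=3))
        assert detect_sse_from_model(coil) == []

    def test_no_windows_across_numbering_breaks(self, single_domain):
        _, truth, _ = single_domain
        # keep only helix residues: three separate helices, not one
        trimmed = truth.subset([p for p in range(44)
                                if not (12 <= p < 16 or 28 <= p < 32)])
        sses = detect_sse_from_model(trimmed)
        assert len(sses) == 3
        assert all(s.kind == "helix" for s in sses)


class TestMapSSE:
    def test_helix_axis_recovered(self, helix12):
        dmap = fx.make_synthetic_map(helix12, 3.0)
        sses = detect_sse_from_map(dmap, 3.0)
        assert len(sses) >= 1 and sses[0].kind == "helix"
        trace = sses[0].ca_coords
        axis = trace[-1] - trace[0]
        axis /= np.linalg.norm(axis)
        true_axis = np.array([0.0, 0.0, 1.0])  # fixture helices run along z
        angle = np.degrees(np.arccos(abs(float(np.dot(axis, true_axis)))))
        assert angle <= 10.0
        # trace center within 2 Å of the true helix axis
        center = trace.mean(axis=0)
        true_center = helix12.ca_coords().mean(axis=0)
        assert np.linalg.norm(center[:2] - true_center[:2]) <= 2.0

    def test_pure_noise_gives_nothing(self, rng):
        noise = DensityMap(rng.normal(0, 1, (40, 40, 40)).astype(np.float32),
                           np.ones(3), np.zeros(3))
        assert detect_sse_from_map(noise, 3.0) == []

    def test_two_parallel_helices_resolved(self):
        two = fx.make_toy_fold(fx.FixtureSpec(
            topology=[("helix", 12), ("loop", 4), ("helix", 12)], seed=0))
        dmap = fx.make_synthetic_map(two, 3.0)
        sses = detect_sse_from_map(dmap, 3.0)
        assert sum(s.kind == "helix" for s in sses) == 2


# ---------------------------------------------------------------------------
# docking searches


class TestSSMDock:
    def test_identity_case(self, single_domain):
        _, truth, dmap = single_domain
        sses = detect_sse_from_map(dmap, 3.0)
        placements = ssm_dock(truth, sses, dmap, 3.0)
        assert placements
        assert recovery_rmsd(truth, placements[0], truth) <= 0.5

    def test_transform_recovery(self, single_domain, rng):
        _, truth, dmap = single_domain
        sses = detect_sse_from_map(dmap, 3.0)
        for _ in range(3):
            t = random_rigid(rng)
            moved = truth.transformed(t)
            placements = ssm_dock(moved, sses, dmap, 3.0)
            assert placements
            assert recovery_rmsd(moved, placements[0], truth) <= 1.5

    def test_single_sse_domain_not_applicable(self, helix12, single_domain):
        _, _, dmap = single_domain
        sses = detect_sse_from_map(dmap, 3.0)
        assert ssm_dock(helix12, sses, dmap, 3.0) is None

    def test_kind_mismatch_gives_empty(self, single_domain):
        """A helix-only domain cannot pair with strand-only map elements."""
        _, truth, dmap = single_domain
        # two strands in separate spatial groups so the map detector can
        # resolve them individually
        strand = fx.make_toy_fold(fx.FixtureSpec(
            topology=[("strand", 8), ("loop", 12), ("strand", 8)],
            domain_boundaries=[(0, 8), (20, 28)], seed=1))
        strand_map = fx.make_synthetic_map(strand, 3.0)
        strand_sses = [s for s in detect_sse_from_map(strand_map, 3.0)
                       if s.kind == "strand"]
        assert len(strand_sses) >= 2  # precondition
        # displace the domain so its current pose is not itself a hit
        moved = truth.copy()
        moved.set_atom_coords(moved.atom_coords() + 30.0)
        assert ssm_dock(moved, strand_sses, dmap, 3.0) == []


class TestCorrelationDock:
    def test_translation_only_recovery(self, single_domain):
        _, truth, dmap = single_domain
        moved = truth.copy()
        moved.set_atom_coords(moved.atom_coords() + [6.0, 4.0, 0.0])
        placements = correlation_dock(moved, dmap, 3.0,
                                      params=DockingParams(
                                          rotation_spacing_deg=40.0))
        assert placements
        assert recovery_rmsd(moved, placements[0], truth) <= 1.0

    def test_zero_map_gives_empty(self, single_domain):
        _, truth, _ = single_domain
        zero = fx.make_synthetic_map(truth, 3.0)
        zero = zero.like(np.zeros(zero.shape, np.float32))
        assert correlation_dock(truth, zero, 3.0,
                                params=DockingParams(
                                    rotation_spacing_deg=60.0)) == []

    def test_domain_too_large_rejected(self, single_domain):
        _, truth, _ = single_domain
        tiny = DensityMap(np.zeros((5, 5, 5), np.float32), np.ones(3),
                          np.zeros(3))
        with pytest.raises(ValueError):
            correlation_dock(truth, tiny, 3.0)


class TestRigidBodyRefine:
    def test_small_perturbation_recovered(self, single_domain):
        _, truth, dmap = single_domain
        centroid = truth.ca_coords().mean(axis=0)
        rot = fx.rotation_about_axis([0, 0, 1.0], 3.0)
        t = Transform(rot, centroid - rot @ centroid + [1.0, 0.0, 0.0])
        refined, cc, ok = rigid_body_refine(truth, dmap, 3.0, t)
        assert ok
        back = truth.transformed(refined)
        d = back.ca_coords() - truth.ca_coords()
        assert float(np.sqrt(np.mean(np.sum(d * d, axis=1)))) <= 0.3

    def test_exact_truth_is_fixed_point(self, single_domain):
        _, truth, dmap = single_domain
        from foldfit.density import map_model_cc
        cc0 = map_model_cc(dmap, truth, 3.0).cc
        refined, cc, ok = rigid_body_refine(truth, dmap, 3.0,
                                            Transform.identity())
        assert cc >= cc0 - 1e-6
        back = truth.transformed(refined)
        d = back.ca_coords() - truth.ca_coords()
        assert float(np.abs(d).max()) <= 0.2

    def test_far_from_density_flagged(self, single_domain):
        _, truth, dmap = single_domain
        t = Transform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        refined, cc, ok = rigid_body_refine(truth, dmap, 3.0, t)
        assert not ok or cc <= 0.05


# ---------------------------------------------------------------------------
# expansion


def fake_placement(dom_id, transform, cc, source="ssm"):
    return Placement(dom_id, transform, cc, source)


class TestExpand:
    def test_other_domains_transform_reused(self, two_domain):
        spec, truth, _, dmap = two_domain
        (a0, b0), (a1, b1) = spec.domain_boundaries
        domains = {0: truth.subset(range(a0, b0)),
                   1: truth.subset(range(a1, b1))}
        per = {0: [fake_placement(0, Transform.identity(), 0.9)], 1: []}
        out = expand_placements(per, domains, dmap, 3.0)
        assert any(p.source == "reused" for p in out[1])

    def test_identity_symmetry_is_noop(self, two_domain):
        spec, truth, _, dmap = two_domain
        a0, b0 = spec.domain_boundaries[0]
        domains = {0: truth.subset(range(a0, b0))}
        per = {0: [fake_placement(0, Transform.identity(), 0.9)]}
        out = expand_placements(per, domains, dmap, 3.0,
                                symmetry_ops=[Transform.identity()])
        assert len(out[0]) == 1

    def test_c2_operator_generates_image(self, two_domain, rng):
        spec, truth, _, dmap = two_domain
        a0, b0 = spec.domain_boundaries[0]
        domain = truth.subset(range(a0, b0))
        c2 = Transform(fx.rotation_about_axis([0, 0, 1.0], 180.0),
                       np.array([30.0, 10.0, 0.0]))
        per = {0: [fake_placement(0, Transform.identity(), 0.9)]}
        out = expand_placements({0: per[0]}, {0: domain}, dmap, 3.0,
                                symmetry_ops=[c2])
        sym = [p for p in out[0] if p.source == "symmetry"]
        assert sym
        # transform algebra: the image is exactly C2 composed with identity
        ca = domain.ca_coords()
        np.testing.assert_allclose(sym[0].transform.apply(ca), c2.apply(ca),
                                   atol=1e-9)


# ---------------------------------------------------------------------------
# the empirical scoring function, with an independently coded oracle



@pytest.fixture(scope="module")
def scoring_setup():
    spec, truth, _, _ = fx.two_domain_3a(0)
    (a0, b0), (a1, b1) = spec.domain_boundaries
    domains = {0: truth.subset(range(a0, b0)),
               1: truth.subset(range(a1, b1))}
    gaps = {(0, 1): 19}
    return domains, gaps


def test_score_hand_example(scoring_setup):
    """Two docked domains, cc 0.6/0.7, identical transforms, no overlap,
    spannable gap: five 200-unit bonuses plus 0.6 + 0.65 = 1001.25."""
    domains, gaps = scoring_setup
    combo = {0: fake_placement(0, Transform.identity(), 0.6),
             1: fake_placement(1, Transform.identity(), 0.7)}
    result = score_placement_combo(combo, domains, gaps, 3.0,
                                   DockingParams())
    assert result.score == pytest.approx(1001.25, abs=1e-9)
    assert sum(result.breakdown.values()) == pytest.approx(result.score,
                                                           abs=1e-9)


def test_score_below_gate_no_bonuses(scoring_setup):
    domains, gaps = scoring_setup
    combo = {0: fake_placement(0, Transform.identity(), 0.10), 1: None}
    result = score_placement_combo(combo, domains, gaps, 3.0,
                                   DockingParams())
    # adjustments only: min + mean cc, nothing else fires
    assert result.score == pytest.approx(0.10 + 0.10, abs=1e-9)


def test_score_connectivity_penalty(scoring_setup):
    domains, gaps = scoring_setup
    far = Transform(np.eye(3), np.array([500.0, 0.0, 0.0]))
    combo = {0: fake_placement(0, Transform.identity(), 0.6),
             1: fake_placement(1, far, 0.7)}
    result = score_placement_combo(combo, domains, gaps, 3.0,
                                   DockingParams())
    assert result.breakdown["penalty_connectivity"] == -200.0


def test_score_matches_oracle_on_randomised_combos(scoring_setup, rng):
    """500 random combos agree with the independent rule-list oracle
    to 1e-9."""
    domains, gaps = scoring_setup
    params = DockingParams()
    for _ in range(500):
        combo = {}
        for d in (0, 1):
            if rng.random() < 0.2:
                combo[d] = None
            else:
                combo[d] = fake_placement(
                    d, random_rigid(rng, max_shift=rng.uniform(0, 60)),
                    float(rng.uniform(-0.2, 1.0)))
        ours = score_placement_combo(combo, domains, gaps, 3.0, params)
        expected = oracle_score(combo, domains, gaps, 3.0, params)
        assert ours.score == pytest.approx(expected, abs=1e-9)
        assert sum(ours.breakdown.values()) == pytest.approx(ours.score,
                                                             abs=1e-9)


# ---------------------------------------------------------------------------
# selection


def test_select_single_option(scoring_setup):
    domains, gaps = scoring_setup
    p = fake_placement(0, Transform.identity(), 0.8)
    best = select_placements({0: [p]}, {0: domains[0]}, {}, 3.0)
    assert best.placements[0] is p


def test_select_truth_beats_decoys(scoring_setup, rng):
    domains, gaps = scoring_setup
    per = {}
    for d in (0, 1):
        truth_p = fake_placement(d, Transform.identity(), 0.85)
        decoys = [fake_placement(d, random_rigid(rng, max_shift=80.0),
                                 float(rng.uniform(0.2, 0.5)))
                  for _ in range(3)]
        per[d] = [truth_p] + decoys
    best = select_placements(per, domains, gaps, 3.0)
    assert best.placements[0].cc == 0.85
    assert best.placements[1].cc == 0.85


def test_select_exhaustive_matches_oracle(scoring_setup, rng):
    """Exhaustive enumeration is optimal: every combo scores no higher
    than the selected one (checked by brute force)."""
    import itertools
    domains, gaps = scoring_setup
    per = {d: [fake_placement(d, random_rigid(rng), float(rng.uniform(0, 1)))
               for _ in range(3)] for d in (0, 1)}
    best = select_placements(per, domains, gaps, 3.0)
    params = DockingParams()
    for choice in itertools.product(*[per[d] + [None] for d in (0, 1)]):
        combo = dict(zip((0, 1), choice))
        assert score_placement_combo(combo, domains, gaps, 3.0,
                                     params).score <= best.score + 1e-9


def test_select_overlap_tradeoff(scoring_setup):
    """Two overlapping high-cc placements lose to lower-cc non-overlapping
    ones once the 200-unit overlap bonus dominates."""
    domains, gaps = scoring_setup
    # same pose for both domains: total overlap
    onto_0 = Transform.identity()
    ca0 = domains[0].ca_coords()
    ca1 = domains[1].ca_coords()
    shift_onto_0 = Transform(np.eye(3), ca0.mean(axis=0) - ca1.mean(axis=0))
    per = {0: [fake_placement(0, onto_0, 0.9)],
           1: [fake_placement(1, shift_onto_0, 0.9),
               fake_placement(1, Transform.identity(), 0.6)]}
    best = select_placements(per, domains, gaps, 3.0)
    assert best.placements[1].cc == 0.6
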