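# Methods

`foldfit` implements an automated procedure for fitting a predicted
protein model into an experimental density map and rebuilding the parts
that fit poorly. One cycle runs five stages in order: trim and split the
model into compact domains by predicted confidence, dock each domain
rigidly into the map, morph the full model onto the docked domains with a
shift field, rebuild poorly fitting segments by several independent
strategies, and assemble the best version of every segment into the final
model. A multi-cycle driver feeds each cycle's rebuilt model back to a
pluggable structure predictor as a template; a deterministic stub stands
in for a real prediction network, which is out of scope here.

## Model of the data

A predicted model is one protein chain with a per-residue confidence
(plDDT semantics, 0–100 or 0–1, carried in the B-value column of PDB/mmCIF
files). A density map is a 3-D scalar grid on an orthogonal cell with a
stated nominal resolution d (Å). Model-based density places an isotropic
Gaussian on every atom with

    sigma = 0.425 * sqrt(2) / pi * d  (~0.191 d),

normalised on the grid so each atom deposits exactly its electron count
(the discrete normalisation keeps total mass exact even when sigma is
below the voxel size). The constant is a convention: the procedure only
ever compares densities synthesised with the same kernel, so any smooth
resolution-dependent width serves; this one puts the kernel's Fourier
falloff near 1/e at spatial frequency 1/d. Map-model agreement is the
Pearson correlation over the union of 2.5 Å spheres around the model's
atoms (the CC_mask convention). Per-atom displacement parameters are not
used in synthesis — the B column holds confidence for predicted models.

## Stage parameters (defaults, units)

| parameter | default | role |
|---|---|---|
| `plddt_threshold` | 70 | residues below this (0–100 scale) are trimmed |
| `maximum_domains` | 3 | upper bound on compact units after splitting |
| `minimum_domain_length` | 10 residues | minimum unit size; also the smoothing window |
| `ssm_search_min_cc` | 0.3 | SSM result good enough to skip correlation docking |
| `ok_brute_force_cc` | 0.25 | minimum correlation to keep an SSM candidate |
| `match_distance_high` | 5 Å | paired-CA agreement required of an SSM superposition |
| `minimum_docking_cc` | 0.15 | gate for the scoring function's bonus block |
| `acceptable_docking_cc` | 0.5 | "well docked" correlation level |
| `overlap_ca_ca_distance` | 3 Å | CA–CA distance counted as inter-domain overlap |
| `allowed_fraction_overlapping` | 0.1 | overlap fraction allowed before losing a bonus |
| `maximum_connectivity_deviation` | 15 Å | slack (plus 2d) before the connectivity penalty |
| `shift_field_distance` | 10 Å | Gaussian scale D of the morphing field |
| `iterative_refine_start_resolution` | 6 Å | first level of the low-pass refinement ladder |
| `n_window` | 6 residues | window size of iterative window morphing |
| `ca_distance` | 3.8 Å | maximum end deviation for an external fragment splice |
| `cc_sd_ratio` | 3 | SD multiple below the good-half mean marking poor density |

## Docking

Domains are trimmed (smoothed confidence below 70 removed) and grouped by
single-linkage clustering of contiguous chain segments on minimum CA–CA
distance. Merging continues past the `maximum_domains` bound while the two
nearest clusters are within 8 Å, so a compact fold yields one domain
rather than always the maximum count; clusters shorter than
`minimum_domain_length` are absorbed into their nearest neighbour. When a
predicted aligned-error matrix is supplied, segments are instead connected
where any cross pair has error below 6 Å (no published value exists for
this cutoff; 6 Å is of the order of the domain-contact errors that
matter), with the same count/size constraints.

Secondary-structure matching (SSM) docking pairs two elements detected in
the map with two matching elements of the domain, tries every sliding
alignment of the shorter element on the longer in both directions, keeps
least-squares superpositions whose paired CAs agree within
`match_distance_high`, scores survivors by masked correlation, and refines
the best by rigid-body refinement. Pair-of-pairs enumeration is prefiltered
on inter-element geometry (axis angle within 30°, midpoint distance within
2×`match_distance_high`) — the element-indexing device that keeps the
search tractable. The map-side detector segments a 2 Å-blurred copy of the
map by a descending threshold sweep (secondary structure, with several
atoms per Å of chain, stands out against loops there), fits rods by
density-weighted PCA, refines axis and extent on the unblurred map, and
lays an ideal helical CA trace (phase and axial offset fitted to the map)
or a straight strand trace along each rod. Rods whose trace is not
supported by density well above the map's fluctuation level (mean below
4 SD of the map, or below 70% of the typical in-structure level) are
rejected, which empirically separates genuine elements (≥9 SD on the
synthetic fixtures) from pure-noise blobs (≤2 SD). This detector fills the
find-helices-strands role functionally; it does not claim to reproduce any
particular program's output.

Correlation docking scans a quasi-uniform rotation grid (24° spacing by
default, super-Fibonacci sampling, identity always included) with an FFT
cross-correlation translation scan per rotation, then refines the top
peaks. It runs only when SSM produces nothing better than
`ssm_search_min_cc` (or always, via `use_both_dock_modes`).

Placements found for one domain are offered to every other domain
(correlations recomputed), and user-supplied symmetry operators (plain
text, one 3×4 row-major matrix per line) generate additional images.

The final combination — one optional placement per domain — maximises an
additive empirical score: starting from zero, five 200-unit bonuses when
every placed domain clears `minimum_docking_cc` (worst correlation above
`acceptable_docking_cc`; additionally the whole docking being essentially
rigid-body; all domains docked; overlap fraction below 0.1; every
inter-domain gap spannable by its intervening residues at 3.8 Å per
residue), a 200-unit penalty when a gap exceeds the spannable distance
plus 2d + 15 Å, and small continuous adjustments (worst and mean
correlation added; the fraction of transforms differing from the first,
the overlap fraction, and the normalised span deviation subtracted).
Two reading choices deserve note. First, the rigid-body bonus is granted
only when *all* domains are docked with mutually similar transforms:
granted vacuously to single placements or mutually-consistent subsets, it
would make dropping a genuinely moved domain outscore docking everything —
the very case the procedure exists for (verified numerically on the
two-domain fixture). Second, transform similarity applies both transforms
to every placed domain's CA set and takes the worst r.m.s. difference,
with the map resolution as the threshold. Inter-domain distance is
measured between the chain-end CAs that the linker must actually connect.
Overlap counts placed CAs within `overlap_ca_ca_distance` of another
placed domain's CAs, as a fraction of all placed CAs. Selection is
exhaustive over (top-5 placements + unplaced) per domain up to 10,000
combinations, beam search (width 50) beyond.

## Morphing

The shift field is defined by anchor pairs (coordinate c_i, vector v_i)
and evaluates at x to the Gaussian-weighted average
sum_i w_i v_i / sum_i w_i with w_i = exp(−|x−c_i|²/D²), D =
`shift_field_distance`. Built from docked domains there is one anchor per
docked CA: coordinate = that CA in the full predicted model, displacement
= docked minus predicted position. Because the weighted average smooths
over neighbouring anchors, the raw field would leave a systematic residual
at the anchors themselves; the stored vectors are therefore solved from
the anchor-weight matrix so the field interpolates the displacements
exactly (plain radial-basis interpolation; `n_iter=0` recovers the
single-pass field). Morphing displaces every atom — not only CAs — by the
field at its own coordinate, so side chains follow their backbone and a
uniform displacement is reproduced as an exact rigid translation.

Window morphing adjusts a segment `n_window` residues from each end at a
time: each window takes the common translation (local search with seeded
random restarts, shifts up to 1.5 Å) that maximises the mean interpolated
density at its CAs subject to consecutive CA distances in [2.9, 4.3] Å,
the rest of the segment is carried along by a field anchored on the
windows, and the windows step one residue inward until the segment is
covered. A window moves only if it gains more than 20% density — a
well-placed window can always milk a few percent by sliding along its own
tube (tapering ends, interpolation texture on sharply-peaked grids), and
the gate keeps a correctly placed segment exactly where it is. Grafting
splices a segment onto fixed flank coordinates by morphing with anchors on
three residues per end (iteratively corrected so splice residues land on
their targets).

## Rebuilding and assembly

Residues are marked for rebuilding when their smoothed (10-residue window)
confidence falls below 70 or their smoothed CA density falls below the
outlier threshold: the lower half of all CA densities (strictly below the
median) is discarded and the threshold is mean − `cc_sd_ratio`·SD of the
remaining good half. On sharp noiseless synthetic maps all well-fitting CA
densities are nearly identical, the good-half SD collapses to
grid-sampling jitter, and the literal threshold would flag noise; the
effective SD is therefore floored at 10% of the good-half mean. Rebuild
runs are padded two residues into the keep regions so splices land on
sound flanks.

Up to six strategies each produce one full-length candidate:

1. **iterative resolution refinement** — restrained real-space refinement
   against the map low-passed to 6 Å, then 1 Å steps down to the native
   resolution; the early blurred passes widen the convergence radius.
   The refinement itself is a gradient (L-BFGS) minimisation of
   −(density at atoms)/max plus harmonic terms: consecutive CA–CA bonds
   (target = the input spacing clipped to [2.9, 4.1] Å, falling back to
   the canonical 3.8 Å virtual bond when the input is broken — a hard 3.8
   target would bias geometries built at other spacings), each atom's
   offset from its own CA held near its start (keeps residues intact),
   and optional reference-coordinate restraints. If the masked
   correlation drops, the input is returned (flagged if the drop exceeds
   0.05).
2. **loop fitting** — seeded smooth perturbations of the flank-to-flank
   interpolation (200 candidates, spacing-checked), scored by mean CA
   density; smoothest candidate on ties or featureless maps; single
   residues are placed directly at the best density point between flanks.
3. **loop retracing** — the widest path through the density between the
   flank CAs: binary search over grid-value thresholds with 26-connected
   component checks finds the highest threshold at which the anchors stay
   connected (exact on grid values), a BFS shortest path at that threshold
   breaks ties, and the path is resampled to the segment's residue count.
4. **combination** — clear sub-runs (CA density above the outlier
   threshold) are retraced; unclear runs keep the refined model, grafted
   onto the retraced flanks.
5. **window morphing** as above.
6. **external fragment** — a contiguous fragment of exactly the expected
   length from a user-supplied model, accepted when its terminal CAs lie
   within `ca_distance` of the flanks; best mean CA density wins.

Candidates are refined, scored per plan segment by masked correlation, and
the best version of each segment (ties to the earlier strategy in the
fixed order above) is copied atom-for-atom into the assembly. Only genuinely
broken junctions (bond outside [2.5, 4.5] Å) are repaired by a tapered
three-residue splice morph, then the assembly is refined once more.
Candidates are refined before their per-segment correlations are measured,
and the assembly refined once after — so the per-segment optimality
guarantee refers to the pre-final-refinement chimera. If the final model
loses more than 0.05 correlation against the docked/morphed model, the
cycle falls back to the latter.

## Synthetic study conditions

The generator builds ground-truth folds from canonical geometry (helix: CA
radius 2.30 Å, rise 1.50 Å, twist 100°/residue, right-handed in either
chain direction; strand: rise 3.30 Å with a 0.94 Å zigzag; loops: smooth
arcs at ~3.55 Å spacing with 0.12 Å seeded jitter, elements laid out as
per-domain bundles 27 Å apart). Backbone N, CA, C, O atoms are derived
from the CA trace by local-frame offsets; there are no side chains.
A "predicted" model perturbs designated domains rigidly about their
centroids (the displacement blended smoothly into inter-domain residues so
the chain stays connected, as real predictions are) and adds
sequence-correlated noise (correlation length ~2 residues) to loops.
Confidence is 100·exp(−err/4 Å) clipped to [20, 98], where err is the
magnitude of the *non-rigid* displacement: a rigidly misplaced domain
keeps high confidence (plDDT is superposition-free and local), noised
loops fall below the 70 cutoff. Maps are Gaussian-atom renderings on a
1 Å grid with a 10 Å margin, plus optional seeded white noise scaled to
the map maximum.

The standard conditions are: two three-helix bundles (44 residues each)
joined by a 20-residue linker, the second bundle rotated 15° and
translated 4 Å, loops noised to 3 Å r.m.s., rendered noiseless at 3 Å.
What these fixtures do **not** emulate: CTF and B-factor falloff,
anisotropy, local resolution variation, side-chain density, solvent,
neighbouring chains, or miscalibrated confidence. Passing tests therefore
demonstrate the correctness and self-consistency of the machinery — exact
scoring, exact widest paths, pose recovery, segment-level optimality —
not performance on real cryo-EM data.

## Numerical choices and determinism

All randomised components (loop sampling, window search restarts, fixture
generation, the stub predictor) take explicit seeds; identical inputs,
configuration and seeds give bit-identical outputs. Placements are
deduplicated when their actions on the domain CAs differ by less than half
the resolution (r.m.s.); refined placements at the full resolution.
Trilinear interpolation is used for all density lookups; points outside
the grid read the map minimum and are flagged. Map I/O uses the ORIGIN
header when nonzero, NSTART×voxel otherwise, and writes mode-2 (float32)
maps with the ORIGIN convention. Degenerate inputs are handled explicitly:
empty masks and all-trimmed models raise informative errors, zero-variance
correlation regions return 0 with a warning, featureless maps leave models
unchanged with a failure flag.

Problem sizes used in the shipped tests and the acceptance script — 44 to
108 residue folds, maps of ~10^5 voxels, 20 docking trials, four
iteration cycles — were chosen as the smallest conditions that exercise
every code path meaningfully (multi-domain docking, linker morphing, every
rebuild strategy).

## Known limitations

* The map SSE detector is a functional stand-in tuned for maps at ~2.5–5 Å
  with discrete secondary structure; tightly packed beta sheets are often
  segmented as a single rod and recovered only through correlation docking.
* Refinement is CA-bond plus local-offset restrained gradient descent, not
  a full stereochemical refinement; Ramachandran statistics and rotamers
  are out of scope.
* Register (sequence) shifts along a correctly traced backbone are not
  detected: the connectivity-free CA match used throughout deliberately
  ignores them.
* Symmetry must be supplied as operators; the package does not detect it
  from the map.
* The stub predictor only jitters its template; the synergy achievable
  with a real prediction network is outside what these tests can show.
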