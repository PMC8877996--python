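# Methods

## Data model and conventions

All grids are 3D arrays in `(slice, row, col)` order, axis 0 being the
axial slice direction, with per-axis voxel spacing in mm. Intensities are
scaled to [0, 1] by min–max normalization before any segmentation or
editing; normalization is monotone and idempotent, and a constant volume
degenerates to all zeros with a warning rather than an exception so that
blank phantom slices do not abort a pipeline. By default the min and max
are taken over the whole volume; a ROI-restricted variant (with clipping
of out-of-ROI values) is available because scanner inhomogeneity outside
the liver can otherwise compress the in-liver dynamic range. Mask volume
in mL is `count · voxel-volume(mm³) / 1000`.

## Level-set segmentation

The automated stage minimises, independently on each axial slice and only
over ROI voxels, the two-phase piecewise-constant (Chan–Vese) energy with
a discrete boundary-length term counted over 4-neighbour ROI pairs. The
numerical scheme is chosen for exact reproducibility and a provable
energy decrease rather than for PDE fidelity:

1. **Initialization.** A `(2·init_patch+1)²` square centred on the
   slice's minimum-intensity ROI voxel (ties broken lexicographically by
   (row, col)) seeds the *dark* phase — the lowest-intensity region is
   reliably non-cyst, so the two phase means start on opposite sides of
   the lesion/background split.
2. **Stage 1 — fidelity only.** Alternating exact mean updates and
   pointwise assignments of the fidelity part of the energy (equivalent
   to seeded two-means on the ROI intensities). Pointwise moves cannot be
   blocked by the boundary penalty, so the phases reach the global
   intensity split. (Starting iterated conditional modes directly from a
   3×3 patch freezes: flipping any isolated pixel costs up to `4·mu` in
   boundary length, which dwarfs per-pixel fidelity differences.)
3. **Stage 2 — full energy.** Red–black iterated-conditional-modes
   sweeps: the checkerboard colours are mutually non-adjacent under the
   4-neighbourhood, so updating one colour at a time given the other is
   an exact block coordinate-descent step. Together with the exact mean
   updates this makes the recorded per-iteration energy non-increasing,
   which the test suite asserts to 1e−6 relative tolerance. Iteration
   stops when a sweep changes nothing, when the relative energy decrease
   falls below `tolerance`, or at `max_iterations`.

The phase with the higher mean is reported as foreground and the output
is always a subset of the ROI. Two conservative degenerate-case rules
apply: a slice with (numerically) constant ROI intensity returns empty,
and a slice whose converged phase means differ by less than
`min_contrast` returns empty. The second rule exists because a smooth
bias field can otherwise be split into two low-contrast halves on
cyst-free slices, reporting half the liver as lesion; a genuine cyst or
vessel at typical contrast-to-noise separates the means by several times
the default 0.1.

Defaults: `mu = 0.1`, `λ1 = λ2 = 1`, `max_iterations = 200`,
`tolerance = 1e−3`, `init_patch = 1`, `min_contrast = 0.1` (normalized
units). `mu` trades speckle suppression against small-lesion loss; at 0.1
a single bright voxel flips only if its fidelity gain exceeds `4·mu`,
which suppresses isolated noise voxels at the default noise level while
keeping 2-voxel-radius lesions. These are implementation choices,
documented as tunable; they segment the noiseless two-constant phantom
exactly. `skimage.segmentation.chan_vese` (a PDE-style implementation of
the same energy, without ROI support) is used as an independent
cross-check on full-frame disk images in the tests.

One level set evolves per slice, in 2D: clinical thick-slice breath-hold
acquisitions (8 mm slices vs 1.5 mm in-plane) make a 3D curvature term
physically dubious, and per-slice evolution matches how such data are
reviewed. A 3D mode is deliberately out of scope.

## Interactive editing

Affinity region growth accepts a frontier voxel `g` adjacent to an
accepted voxel `s` iff `ρ = 1 − |I_g − I_s|/a ≥ threshold`, i.e.
`|I_g − I_s| ≤ a(1 − threshold)`; the boundary case is accepted, growth
stops strictly when ρ drops under the threshold. Two comparison modes are
provided because the natural-language description of such tools is
ambiguous: `chain` (default) compares against the accepted neighbour,
which handles slow intensity drift across a lesion; `seed` compares
against the originally clicked voxel, which bounds the total excursion.
In chain mode the accepted set is exactly the connected component of the
seed in the graph whose edges join adjacent voxels within the tolerance —
hence independent of frontier ordering (breadth- vs depth-first is
property-tested); in seed mode it is the connected component of the
thresholded difference image containing the seed, which the tests verify
against an independent `scipy.ndimage.label` oracle.

Defaults: `a = 0.2`, `threshold = 0.5`, 4-connectivity in-plane, scope
restricted to the clicked slice (`3d` adds the two axial neighbours),
`closing_radius = 1`. Smart-add closes the grown region in-plane
(dilation then erosion with a disk, computed on a padded frame so the
operation equals unbounded-domain closing: extensive and idempotent)
before uniting it with the mask; smart-remove applies no closing, since
hole-filling is a lesion-growth feature and would refill erased holes.
Smart-add never shrinks the mask; smart-remove never grows it; the
paintbrush touches only the clicked in-plane disk.

Sessions are JSON scripts (an array of events, or an object with
`defaults` plus `events`), validated before any mutation and replayed
strictly in order; the first invalid event aborts with its index. Replay
logs per-event voxel-count deltas and is bit-deterministic.

## Phantom generator

The generator emulates the thick-slice T2-weighted appearance that makes
liver-cyst segmentation hard, with exact ground truth:

- 64×96×96 grid at (8.0, 1.5, 1.5) mm — thick axial slices;
- an ellipsoidal liver (semi-axes 26, 40, 40 voxels) at intensity 0.35 on
  a 0.12 background;
- 25 spherical cysts, radius 2–8 voxels, intensity 0.7–1.0, centres
  inside the liver, pairwise centre separation at least the sum of radii
  plus 2 voxels (so narrow inter-cyst gaps exist), placed by rejection
  sampling with an explicit failure if the packing is infeasible;
- 3 tubes of radius 2 voxels at intensity 0.9 whose centerlines drift
  2–3.5 in-plane voxels per slice with a gentle sinusoidal curve, clamped
  to the liver interior (hepatic vessels are intra-hepatic). The oblique
  drift is the point: each slice sees a blob-shaped cross-section that a
  2D region-based method cannot distinguish from a cyst by intensity or
  shape. Vessels avoid a 2-voxel dilation of the cyst mask so the vessel
  and cyst ground truths are disjoint and separated by liver-intensity
  voxels;
- a low-order random polynomial bias field scaled to ±0.05, then clipping
  to [0, 1], then additive Gaussian noise (σ = 0.03).

A given (spec, seed) pair is bit-reproducible. What the phantom does
*not* model: Rician noise statistics (Gaussian is adequate for testing
segmentation logic but misrepresents low-SNR magnitude images), partial
volume at cyst rims, respiratory slice misregistration, bile ducts, and
the anatomic variety of real livers. Passing end-to-end tests on the
phantom therefore demonstrates the correctness and the qualitative
failure-mode behaviour of the algorithms, not clinical accuracy on
patient data.

The scripted cleanup session automates what a reviewer does: one
smart-remove per connected vessel component present in the current mask
(seeded at the in-mask component centroid snapped to the nearest true
voxel, scope `3d`), plus one smart-add per ground-truth cyst component
the mask missed entirely. Given the normalized volume it simulates each
round by replay and appends further rounds until clean (noise can break
the affinity chain mid-vessel, so a single click occasionally leaves a
fragment — as it does for a human, who simply clicks again); without the
volume a single round is scripted. The session is a pure function of its
inputs.

## Metrics

- Dice `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 with a warning
  (agreement on absence), keeping phantom edge cases total.
- Normalized volume error `|V_ref − V_cand|/V_ref`.
- ICC form ICC(2,1): two-way random effects, single measure, absolute
  agreement, computed from the classical ANOVA mean squares. Absolute
  agreement is the standard choice for method comparison on a common
  scale; the form is recorded in the report metadata. The consistency
  form would ignore a fixed offset between methods; the absolute form
  strictly penalises it (property-tested). Cross-checked in tests
  against `pingouin.intraclass_corr` and an independently coded ANOVA
  oracle.
- RMSE of paired volumes, in mL.
- Bland–Altman on per-case percent differences
  `100·(cand − ref)/mean(cand, ref)` (the symmetric percent-difference
  construction); bias ± 1.96·STD limits of agreement.
- SNR = cyst-ROI mean/STD, CNR = (cyst mean − adjacent liver mean)/cyst
  STD; both scale-invariant.
- Sample standard deviation (n−1) everywhere, including cohort summaries
  and Bland–Altman; singleton lists report STD 0.
- Method comparison uses a paired two-sided Student's t-test on per-case
  metrics, reported as such (no further inference).

## Benchmark and problem sizes

`iris benchmark` generates `n` phantom cases (case seeds derived as
`base·1000 + i`), runs the level set, builds and replays the scripted
cleanup, and reports per-case and cohort statistics for both the
automatic and the edited masks against ground truth. The default cohort
of 10 default-sized phantoms runs in a few seconds on one CPU; the full
test suite takes well under a minute. `scripts/acceptance.py` wraps the
10-case benchmark and emits the headline numbers as JSON.

On this phantom the automatic level set typically includes >99% of
in-ROI vessel voxels and overshoots the cyst volume by ~25–30%, while the
edited masks remove essentially all vessel voxels; the edited ICC is
near 1 whereas the automatic ICC is low and volatile, because the phantom
cohort's cyst volumes span a much narrower range than a patient cohort
and a near-constant vessel surplus dominates the between-case variance in
the absolute-agreement form.

## Known limitations

- The level-set weights and the affinity defaults are phantom-validated
  choices, not clinically tuned values; real data will need per-protocol
  adjustment (all are exposed as CLI flags and session overrides).
- No 3D level set, no multiphase or vector-valued energies, no
  edge-based (geodesic) models.
- No resampling: volume, ROI and masks must share one grid.
- The liver ROI is an input; automatic liver segmentation is a separate
  problem and out of scope.
- Session replay is the only undo mechanism (re-run without the offending
  event).
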