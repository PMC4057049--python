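# Methods

## Model

The knee during stance is treated as a body with first-order freedom: at
each instant it may only twist about one screw, the instantaneous axis of
the knee (IAK). The constraints enforcing that freedom are pure force
lines — the two cruciate ligaments (ACL, PCL), the two collaterals (MCL,
LCL), and the medial and lateral articular contact normals (P1, P2). A
line constrains a freedom exactly when the two screws are *not*
reciprocal, so the admissible constraint lines of a given IAK form the
fifth-order screw system reciprocal to it; conversely the one screw
reciprocal to five independent constraint lines is the axis they jointly
permit. Static equilibrium about the IAK then has two faces used here:

1. **Replacement.** Any applied wrench φ (the ground reaction) can be
   traded for a wrench on another screw η (a muscle line) of intensity
   `η″ = −φ″·vc(φ,IAK)/vc(η,IAK)`, the unique intensity making the pair
   do zero net virtual work on any twist about the IAK. The trade is
   impossible when η is reciprocal to the IAK (no leverage).
2. **Decomposition.** A wrench lying in the span of the constraint lines
   is neutralized by constraint reactions: solve `Σ xᵢ Sᵢ + w = 0` in
   Plücker coordinates. The P1 and P2 components are the medial and
   lateral contact forces. A wrench with a component outside that span
   (e.g. a couple about the flexion axis) would move the joint and is
   reported as an inconsistency, not solved.

All computations use ray-order Plücker coordinates `(d; m)`, SI units
(metres, radians, seconds, newtons), and a right-handed lab frame.

### Conventions that matter

* **Virtual coefficient without the ½.** `vc(p,q) = d_p·m_q + d_q·m_p`,
  equal to `(h+h′)cosθ − a sinθ` with `a` signed along `d_p×d_q`. Ball's
  classical virtual coefficient is half this; reciprocity (`vc = 0`) is
  unaffected by the factor. The coordinate form is authoritative (it stays
  finite for infinite-pitch screws); the geometric form is the cross-check.
* **Normalization.** Screws are stored normalized (`|d| = 1`, or `d = 0`,
  `|m| = 1` for pure translations/couples); magnitudes live in twist
  amplitudes and wrench intensities. Raw 6-vectors are normalized on
  construction.
* **Principal screws from first principles.** The pitch of
  `λ₁p₁ + λ₂p₂` is the generalized Rayleigh quotient `λᵀAλ/λᵀBλ`
  (`A_ij = (d_i·m_j + d_j·m_i)/2`, `B_ij = d_i·d_j`), so the principal
  screws and extremal pitches h_α ≤ h_β are the eigenpairs of
  `Av = hBv`. For two zero-pitch generators with half-angle σ and
  half-distance b this yields h_α = −b·tanσ and h_β = +b·cotσ. The
  canonical frame is built from the principal screws (origin at their
  intersection, x along p_α, y along p_β, z along the nodal line); for
  equal-pitch generators this coincides with the textbook placement
  "origin midway on the generators' common perpendicular, x bisecting
  them". In that frame every screw of the system lies on the cubic ruled
  surface `z(x²+y²) = (h_β−h_α)xy`.
* **Constraint-line orientation.** Positive intensity is the force the
  femur exerts on the tibia: contact normals point distally (compression
  positive), ligament lines point from tibial insertion to femoral origin
  (tension positive). Negative contact intensities are reported and
  flagged physiologically inconsistent, never clamped.

## Axis estimation from markers

Per-frame segment poses come from the least-squares orthogonal (Kabsch)
fit of each marker cluster to a reference layout. When a body-frame
calibration of the cluster is available the poses map the anatomical
(tibia/femur) frame to the lab, which is what lets tibia-frame constraint
geometry be carried into the lab; without one, poses are relative to the
first frame's layout (a technical frame) and the geometry must be supplied
in that frame.

The instantaneous screw axis of a segment is the screw of the finite
displacement across the window `[t−1, t+1]` (one-sided at the ends),
extracted in closed form: rotation axis/angle from the matrix log, pitch
`u·p/φ`, axis point `½(p⊥ + cot(φ/2)·u×p⊥)`. For motion about a fixed
axis this is exact for any rate profile, which is what makes the synthetic
ground truth exact. The IAK is the difference of the two segments'
amplitude-weighted twist 6-vectors — a linear combination of the two ISAs,
hence a screw of their cylindroid.

Two reliability gates protect downstream stages:

* frames whose window rotation is below **0.1°** are translation-dominated;
  the twist is returned as an infinite-pitch translation and flagged;
* with the optional adaptive window (`min_window_rotation_deg`), the
  differentiation window grows until it spans the requested rotation;
  where the series is exhausted first (e.g. at a flexion reversal, where
  net rotation cancels) the estimate is kept but flagged. Axis-direction
  noise scales inversely with the rotation increment, so this is the
  standard finite-helical-axis remedy. A centred moving-average marker
  smoother (odd width, off by default) is the only filtering offered.

Defaults for clean/synthetic data are exact: no smoothing, plain central
windows. For 1 mm marker noise the recommended configuration is
`smooth_window=5`, `min_window_rotation_deg=8`, and a reciprocity gate
`recip_tol` of a few centimetres — the gate exists to catch gross
axis/geometry mismatches, not measurement noise.

## Decomposition and identifiability

The six anatomical lines of one IAK all lie in its five-dimensional
reciprocal system, so their 6×6 coordinate matrix has rank 5 and one
coefficient combination produces the zero wrench. The decomposition is
therefore determined only up to that combination; the solver returns the
minimum-norm least-squares representative (`numpy.linalg.lstsq` with a
relative singular-value cutoff of 1e-10) and reports the rank, so a user
supplying five independent lines gets the unique solution. The synthetic
generator stores the same representative as its ground truth — the
intensities it reports are exactly recoverable, while the raw nonnegative
generating intensities are also stored for reference. Consequence worth
stating plainly: with six lines, medial/lateral forces are only defined
relative to this canonical resolution; supplying five lines (or external
muscle information via the replacement operation) removes the ambiguity.

## Synthetic trials

The generator builds the study conditions forwards from the answer:

* **Geometry.** Tibia frame with origin at the joint centre, x
  medial→lateral, y anterior, z proximal; the flexion axis is the x-axis
  (the transepicondylar line). Femoral attachments are idealized onto
  that axis, so every constraint line intersects it and is exactly
  reciprocal to the IAK by construction; tibial insertions and contact
  points use anatomically plausible defaults (contact offsets ±22 mm,
  epicondyles ±45 mm, collateral insertions 65 mm distal, 5° contact-
  normal tilt), optionally jittered. Draws are re-sampled if rank ≠ 5.
* **Kinematics.** The shank is held at a fixed pose (foot planted; an
  optional slow sway exercises the moving-frame path) and the thigh
  flexes about the knee axis with a smooth `sin²` stance wave of 15°
  amplitude at 100 Hz over 0.6 s, padded with zero-GRF swing frames.
  Marker clouds are jittered tetrahedra (4 markers/segment by default)
  carried rigidly, with optional isotropic Gaussian noise.
* **Loads.** The vertical GRF follows the classic double-hump stance
  profile scaled to 1.1 body weight (70 kg); the wrench of each frame is
  assembled as a known nonnegative combination of the lab-frame
  constraint lines (contacts split 58/42 medial/lateral, ligaments a few
  tens of newtons), then reduced to force-plate records (COP on the
  ground plane, vertical free moment) that reproduce it exactly.

What passing tests on these trials show: the algebra, the estimator and
the solver are mutually consistent and exact at machine precision on
rigid, span-consistent inputs, and degrade gracefully (and monotonically)
with marker noise. What they do not show: robustness to soft-tissue
artifact, to constraint lines that are only approximately reciprocal to
the true axis (real ligament geometry), to force-plate calibration error,
or to the rank-deficiency pattern of a real radiograph-derived geometry —
real knees do not have their femoral attachments exactly on the flexion
axis.

## Numerical choices

* Rank and nullspace cutoffs: singular values below 1e-10 × largest are
  zero. Reciprocity tolerance defaults to 1e-9 m for exact algebra.
* Degenerate cylindroids (coaxial or parallel generators) raise rather
  than return an infinite-pitch principal screw.
* Value iteration starts from the zero value function (monotone for
  nonnegative costs), stops on a 1e-12 sup-norm change, and breaks ties
  to the lowest action index; undiscounted processes require terminal
  states. The stage cost defaults to |vc|, making the optimal stance
  policy reciprocity-seeking.
* Stance detection: vertical force ≥ 20 N, boundary inclusive,
  configurable.
* TRC frame numbers are 1-based on disk, 0-based in memory; mm units are
  converted on load. Readers reject malformed input naming the offending
  line/column.

## Problem sizes

Ensemble checks use 1000 random screw pairs (algebra), 200 surface
samples over the 0.3–2.5 transmission-ratio arc, 100 seeded helical
trials for the noise study, and three-seed stance batches; one stance
trial is 71 frames at 100 Hz. These sizes hold all reported error
statistics stable to well under their asserted bounds.

## Known limitations

* The six-line decomposition ambiguity above; reported contact forces are
  the minimum-norm representative.
* Muscle action enters only through the replacement operation; there is
  no muscle-force optimization or EMG processing.
* No soft-tissue-artifact compensation; no C3D binary support (TRC and
  CSV only); ligaments are rigid lines, not springs.
* The frontal-plane geometry file format (origin/insertion JSON) is this
  package's own convention.
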