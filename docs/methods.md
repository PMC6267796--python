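# Methods

`sitstand` is a forward simulation of the sit-to-stand (STS) transfer built
to ask one question: how does the hip flexion angle at seat-off — the
instant the buttocks leave the chair — shape the hip joint contact force
(HJCF) while standing up?  Because that question needs *many* systematically
varied movements rather than the handful an experiment can capture, the
package generates the movements itself and carries each one through inverse
dynamics, muscle-force estimation and a joint-contact-force balance.

## The model

**Body.**  A planar (sagittal) four-segment linkage: head–arms–trunk (HAT),
thighs, shanks, feet, bilaterally symmetric, scaled to a 1.74 m / 73.8 kg
adult.  Segment lengths, masses, centre-of-mass positions and gyration radii
come from Winter's classic anthropometric fractions
(`_fixtures/anthropometry.csv`); the HAT row is the standard greater
trochanter → glenohumeral definition with the arms folded in (mass fraction
0.678).  The fixture loader re-normalises the HAT mass so that
`hat + 2*(thigh+shank+foot)` equals body mass exactly.  The ankle joint
centre sits at the standard malleolus height 0.039·H; the foot is a flat
plate from heel (0.06 m behind the ankle) to toe (0.152·H long) that defines
the support base.  Two candidate readings of the leg geometry existed
(ankle on the floor vs at malleolus height); the malleolus reading was
pinned because it reproduces the study's own reported mean seat-off angles
(120°/109°/35°) and adoption counts, whereas the ankle-on-floor reading does
not (see *Design choices*).

**Movements.**  Seat-off postures form a grid: hip height fixed at 0.513 m,
hip X swept 0 to 0.40 m posterior to the ankle in 1 cm steps (41 values),
trunk inclined 0–70° forward of vertical in 1° steps (71 values) — 2911
postures.  The knee follows from two-link inverse kinematics (anterior
intersection; the knee flexes forward).  Each posture becomes a movement by
multiplying its seat-off joint angles with a half-period cosine
`w(t) = (1 + cos(pi t/T))/2` over T = 1.55 s, ending at the zero-angle
standing reference.  A movement is **adopted** when its seat-off angles lie
in hip 85–145°, knee 95–120°, ankle 15–45° dorsiflexion (closed intervals)
*and* the whole-body COM stays horizontally inside the support base at every
frame; adopted movements with seat-off hip flexion in 93 ± 8° are **normal**
movements.  Defaults: 101 frames per movement; the adoption counts are
discretisation-robust (identical at 51/101/201 frames).

**Inverse dynamics.**  Velocities and accelerations are analytic
derivatives of the cosine trajectories (no finite differences).  A top-down
Newton–Euler pass per leg (half the HAT mass and inertia per leg, g = 9.8
m/s²) yields hip/knee/ankle moments — extension/plantarflexion positive,
per leg, normalised by body mass (Nm/kg) — and the hip intersegmental force
v_HJF (force on the femoral head from the pelvis side, N/kg).  The *static
component* of a moment re-runs the pass with all velocities and
accelerations zeroed.  Tests cross-check every frame against an
independently formulated momentum-balance pass (subsystem angular momentum
about each joint) to 1e-6.

**Muscles.**  Eight per leg: iliopsoas, gluteus maximus, vastus, rectus
femoris, hamstrings, tibialis anterior, soleus, gastrocnemius.  Each has a
published PCSA (mean, SD) and constant sagittal moment arms evaluated at the
mean seat-off posture; specific tension σ = 60 N/cm².  Only the contractile
element is modelled — no series/parallel elastic elements, no pennation.
Per frame,

    F_MAX = k · f_ce(Lr) · f_v(Ldot) · PCSA · σ

with `f_ce` a Gaussian force–length curve `exp(-((Lr-1)/0.45)^2)` truncated
to zero outside (0.5, 1.5), and `f_v` a normalised Hill force–velocity
curve: concentric branch `(1+v)/(1-v/0.25)` (zero at the maximum shortening
velocity, 1 isometric), eccentric branch rising C¹-continuously to a 1.5
plateau.  `k = 1` nominally; the sensitivity sweep draws it in [0.5, 1.5].

**Fiber lengths.**  The fiber-length ratio Lr is a quadratic in the spanned
joint angles.  The source models behind the published curves are not
available, so the fixture (`_fixtures/muscles.csv`) is a documented
synthetic stand-in constructed from two constraints: (i) the linear
coefficient of each joint equals the signed moment arm divided by a
normalising fiber length, so extensors lengthen under flexion at exactly the
tendon-excursion rate implied by their arms, and (ii) the normalising
lengths are chosen so Lr stays within [0.6, 1.4] — f_ce ≥ 0.45 — over every
simulated posture (verified by test).  A small negative curvature
(−0.06 × linear term per rad²) adds gentle saturation.  Fiber velocity is
the analytic chain rule through the quadratic and the cosine trajectory,
normalised by v_max = 10 fiber lengths/s.

**Static optimization.**  Each frame poses a convex QP in the eight
contractile forces: minimise the summed squared activations
`J1 = Σ (F/F_MAX)²` (or squared stresses `J2 = Σ (F/PCSA)²`) subject to the
three joint-moment equalities `R F = M` and bounds `0 ≤ F ≤ F_MAX`.  Frames
are independent (no activation dynamics); one solve covers both legs.  A
frame with no feasible force vector marks the movement-run *non-optimal* —
the bookkeeping used when reporting how many runs admitted optimal
solutions.

**Contact force.**  The hip joint contact force is

    HJCF = || v_HJF − Σₙ F_n ê_n ||,   n ∈ {iliopsoas, GMax, RF, hamstrings}

with ê_n the unit vector of muscle pull on the femur toward the pelvic
attachment, from a 2-D attachment fixture (`_fixtures/attachments.csv`,
synthetic; pelvis- and femur-fixed frames sharing the hip centre).  The
coordinates were calibrated once so the hip moment arms implied by the lines
at the mean seat-off posture match the constant arms used by the
optimization (iliopsoas 0.022 m flexion, GMax 0.028 m extension, RF 0.016 m
flexion, correct signs); the hamstrings line is kept anatomical (ischial
tuberosity → distal posterior thigh) and implies a larger hip arm than the
unusually short published 0.011 m — an internal inconsistency of the source
data we document rather than hide.  Forces and v_HJF being per leg and
mass-normalised, HJCF is in N/kg per hip.

**Sensitivity analysis.**  Four parameters are perturbed: objective
function (J1 vs J2), PCSA (uniform within ±1 SD per muscle), every nonzero
moment arm (uniform within ±1 cm), and force–length ability k (uniform in
[0.5, 1.5], one global value per run by default; a config switch draws it
per muscle).  Ten draws per objective, the same ten applied to every adopted
movement (20 re-estimations per movement).  Uniform distributions are the
minimal reading of "random values within" a bounded range.  Draws violating
positivity are redrawn element-wise and logged.  Per-draw association
statistics (hip angle vs peak HJCF) are computed over optimal movement-runs
only, mirroring the source study's "optimal solutions found" accounting.

## Numerical choices

- **QP solver**: primal active-set iteration exploiting the diagonal
  Hessian (each step solves a ≤3×3 KKT system on the free variables),
  ~0.3 ms per frame.  On the rare near-capacity frames where that stalls, a
  phase-1 HiGHS LP certifies feasibility, SLSQP from the LP point proposes
  an active pattern that is then re-solved and KKT-verified exactly, and an
  exhaustive 3^8 active-set enumeration is the deterministic last resort.
  Feasible solutions satisfy the moment equalities to 1e-6 Nm.
- **Infeasibility** is certified by linear programming, never inferred from
  solver failure codes.
- Closed intervals for every angle filter (boundary postures are adopted);
  ties in the two-link IK resolve to the anterior knee.
- Geometrically unreachable grid postures are flagged invalid and retained,
  so the grid cardinality is always 41 × 71.
- Degenerate summaries (single movement, constant columns) return NaN
  correlations instead of raising.

## Design choices made where the design was open

- **Anthropometric table**: Winter's fractions rather than a de Leva-style
  reconstruction, because Winter tabulates the combined HAT segment this
  model needs; the fixture CSV is swappable.
- **Ankle height** is absent from the movement-generation description; of
  the two natural readings, ankle at malleolus height (0.039·H) was pinned
  because it reproduces the reported mean seat-off angles and counts as a
  by-product of standard anthropometry (ankle-on-floor yields 924 adopted
  movements with a 101.7° mean knee angle — clearly a different model).
- **"Sum of the peak hip and knee moments"** is computed from the static
  moment components, following the footnote that marks that comparison as a
  static one (the comparator study's movements were 4–11 s, quasi-static).
- **COM filter** applies at every frame, not only seat-off ("moved outside
  the support base" reads as a whole-movement condition).
- **Per-leg reporting** throughout (moments, forces, HJCF), matching the
  per-joint character of instrumented-prosthesis comparator data.

## What the generator emulates, and what it does not

The movement generator emulates the *kinematic envelope* of standing up —
every admissible combination of seat-off posture and balance — under
idealised assumptions: perfectly symmetric execution, cosine joint
trajectories, fixed 1.55 s duration, foot flat throughout, no chair-contact
phase before seat-off, no arm push-off.  Real STS data contain asymmetry,
trunk-velocity strategies, variable timing and anticipatory COM shifts; none
of that variance exists here.  Passing tests therefore demonstrate internal
correctness of the mechanics and optimization on the idealised envelope,
not fidelity to any individual's movement.

## Known limitations

- The mean peak HJCF over normal movements computes to ≈ 19.6 N/kg against
  26.3 N/kg in the source study (in-vivo references: 19–21 N/kg).  Two
  drivers, both rooted in fixtures the source did not publish: the
  optimizer assigns the hamstrings a smaller share (≈ 3.7 vs 7.0 N/kg mean
  peak) under this fiber-length fixture, and with near-horizontal extensor
  lines of action at seat-off the muscle pull adds to the mostly vertical
  intersegmental force in quadrature rather than linearly.
- Knee moments run ≈ 15–25 % above the source values (minimum peak static
  knee moment 0.58 vs 0.47 Nm/kg), consistent with a heavier/longer
  above-knee lever in Winter's table than in the unpublished Japanese
  inertial table the source cites.  Consequently force bounds saturate
  earlier in low-k sensitivity draws: some draws keep far fewer optimal
  runs than the source's 6617/7180 and 5850/7180.
- The headline *findings* are nevertheless reproduced robustly: peak HJCF
  rises approximately linearly with seat-off hip angle (Pearson r ≈ 0.98
  across 732 adopted movements), and the minimum-HJCF movement falls inside
  the normal band (seat-off hip 85.5°).  The association's sign survives
  all 20 sensitivity draws.
- Gluteus medius (frontal plane) is not modelled; the package provides only
  the published rough correction (+4.1 N/kg at 11 % activation).

## Problem sizes used by the test suite

The suite evaluates the full 2911-posture grid and all 732 adopted
movements for the dynamics-level checks; the optimization/contact stage
runs on all adopted movements once (session fixture) and the sensitivity
robustness check samples every 12th adopted movement across all 20 draws —
the sampled movements span the full hip-angle range, which is what the
association statistic needs.  The full unsampled sweep (14,640 runs) is
available through `run_full_study` / `sitstand run-all` and completes in
roughly 10 minutes on one core.
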