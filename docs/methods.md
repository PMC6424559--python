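# Methods

## Model

The runner is a point mass on massless telescoping legs in 3D (x sideways,
y fore-aft, z vertical). Everything internal is nondimensional with
m = g = ℓ_max = 1: lengths in maximum leg length, time in √(ℓ/g), speeds in
√(gℓ), forces in body weights. Dimensional IO goes through
`runcontrol.states.Scales` (defaults: 66.8 kg, 9.81 m/s², 1.05 m — a typical
adult runner).

Flight is parabolic free flight (air drag neglected; at treadmill speeds its
effect on COM velocity is orders of magnitude below step-to-step
variability). During stance the leg transmits a scalar force along the
foot-to-body line; the ground reaction force equals that force times the
unit leg vector. Touchdown happens when the distance from the body to the
target foot position equals the commanded landing leg length (if at apex the
body is already inside that sphere, stance begins immediately); takeoff
happens when the leg regains its maximum length. The commanded foot target
is expressed as a *relative* placement — foot minus COM at touchdown — and
converted to an absolute target with the closed-form ballistic trajectory,
which makes the programmed placement gains exactly the quantity the
regressions of the inference pipeline estimate.

Two variants produce the leg force from the two-term sine series
u(t) = A1·sin(πt/T_stance) + A2·sin(2πt/T_stance) (clamped outside the
stance window, rectified to be non-negative):

* **direct-force**: F_leg(t) = u(t);
* **muscle**: u(t) is the activation of a lumped Hill-type muscle-tendon
  unit (MTU).

### Muscle-tendon unit

The MTU has an active contractile element (CE) with force
F_CE = a·F_iso·ψ_ℓ(l_m)·ψ_v, a linear series elastic element (tendon) and a
linear parallel element. The force-length factor is Gaussian,
ψ_ℓ = exp(−((l_m−l_opt)/(w·l_opt))²); the force-velocity factor is linear in
the CE shortening rate, ψ_v = clip(1 − s/v_max, 0, f_ecc), with an eccentric
cap f_ecc = 1.5 to keep lengthening force bounded.

A kneed leg is abstracted into an affine leg-length-to-MTU-length map,
l_mtu = β − α·ℓ_leg (α = 1, β = 1.6): when the leg compresses the extensor
MTU *lengthens*, so the force-velocity relation boosts force during rapid
compression and sheds it during rapid extension — a damper along the leg
axis. This is the intrinsic stabilizing muscle property responsible for the
muscle variant's superior noise tolerance.

The force balance of the massless MTU is solved *quasistatically* at each
instant: the CE length satisfies
F_SE(l_mtu − l_m) = a·F_iso·ψ_ℓ(l_m)·ψ_v(s) + F_PE(l_m) with the CE rate
tied to the MTU rate (the tendon stretch rate is treated as zero at the
equilibrium point). This avoids an extra ODE state while preserving the
force-length and force-velocity behavior; the solver is a warm-started
Newton iteration with a bisection fallback, and the slack-tendon boundary
(zero force) is handled explicitly. All muscle parameters
(F_iso = 6 bw, l_opt = 0.55, w = 0.5, v_max = 2, k_SE = 80, k_PE = 5) are
package defaults chosen so the nominal gait's peak activation is ≈ 0.4,
leaving headroom for feedback; they are not measured values.

### Numerical integration and events

Stance is integrated with DOP853 at rtol 1e-10 / atol 1e-12; impulse
components and leg work ∫F dℓ ride along as quadrature states so they share
the integrator's accuracy. Terminal events (takeoff at ℓ = 1, fall) are
localized by the integrator's root polishing; flight events (apex,
touchdown) are closed-form (the touchdown condition is a quartic in time,
solved exactly). Event timing feeds the stability estimates, hence the tight
tolerances.

Falls — never defined by the source experiments — are declared when the body
drops below 0.2 ℓ, the leg collapses below 0.1 ℓ, a stance exceeds 3× the
nominal duration, or no touchdown exists before the body passes the foot
height. All thresholds are configurable (`SimConfig`).

## Nominal gait

The periodic, left-right mirror-symmetric gait is solved for ten unknowns
(stance-start position and velocity relative to the foot, stance and flight
durations, A1, A2) against ten constraints: landing leg length 0.95 ℓ,
takeoff at full leg length, mirror periodicity of the post-flight state
(height plus all velocities), and four targets — forward speed 0.9037,
step period 1.2232, step width 0.08, peak leg force 2.5 bw (nondimensional
equivalents of 2.9 m/s treadmill running with a 1.05 m leg, a 0.40 s step,
and typical running GRFs; configuration, not claims). `scipy.optimize.
least_squares` drives the residual to ~1e-12 (required < 1e-6). The solved
stance is naturally asymmetric about mid-stance (landing at 0.95 ℓ, takeoff
at 1.0 ℓ, A2 ≠ 0).

## Controller

Feedback acts once per step at flight apex on (Δẋₐ, Δẏₐ, Δzₐ). When the
body leaves the ground already descending there is no apex and the
end-of-stance state substitutes. All gains live in a side-canonical (left)
frame; right stances mirror the sideways axis, which enforces exact mirror
symmetry of the control (cross-coupled sideways gains flip sign between
sides).

Foot placement (0.95 sideways; 0.42 and −0.76 fore-aft) and landing leg
length (0.3) use the human-derived regression gains directly. The
force/activation gains G (2×3: ΔA1, ΔA2 per deviation component) are fitted
so the model's one-step apex-return map matches the human map K_R→L: the map
is measured by central finite differences (default step 1e-4, balancing
truncation against the 1e-10 integration tolerance) and is linear in G
through the sensitivity B of the next apex to (A1, A2), so an iterated
linear least-squares solve minimizes the Frobenius mismatch. Only the
significant entries of the target map can and need be matched: the starred
(insignificant) entries — notably the sideways response to apex height —
are not reproducible with a scalar force magnitude and sagittal-plane foot
placement, and the achieved map matches every significant entry to within
0.05. The fitted closed loop has stride spectral radius ≈ 0.12 (muscle and
direct variants alike); without feedback the gait is strongly unstable
(spectral radius ≈ 5–18).

## Motor noise and calibration

Noise enters exactly two ways: one multiplicative Gaussian draw per stance
scales the whole force/activation profile (rectification re-applied), and
independent Gaussian offsets perturb the commanded foot placement (drawn in
the canonical frame, mirrored onto the side). Defaults
(sd_eps = 0.010, sd_fp_x = 0.006, sd_fp_y = 0.007) were calibrated once on
the muscle variant so that the emergent apex-state variability matches the
experimental order — apex height s.d. ≈ 0.0075 nondimensional (≈ 8 mm on a
1.05 m leg, within a factor of two of the observed ≈ 5 mm) and
foot-placement regressions with R² ≈ 0.7 — and then frozen. The variability
is emergent: nothing prescribes the apex scatter directly.

At this calibrated noise the muscle variant runs 2000+ steps without
falling. The direct-force variant is 2–3× noisier in apex height — the
muscle's force-velocity damping visibly filters motor noise — but does not
fall within 1000 steps; outright falls of the direct-force model appear at
3–5× the calibrated noise (sd_eps ≈ 0.03–0.05), where the muscle variant
still completes 1000+ steps. The qualitative muscle-vs-direct contrast is
therefore reproduced at the larger noise scale, not at the calibrated one;
both conditions are exercised in the test suite.

## Synthetic datasets

`runcontrol.synthetic` samples the closed-loop simulation like a laboratory
trial: per-belt 3D GRFs on a 1 ms-equivalent clock, COM-proxy and one
marker per foot on a 10 ms clock, Gaussian measurement noise (0.002 bw on
forces, 1e-4 ℓ on positions), optional slow force drift (linear ramp or
sinusoid). Swing-foot channels follow a minimum-jerk path toward a nominal
advance target, with the actual (feedback + noise) target blended in only
during the final flight — reproducing the observation that the COM state
predicts the upcoming placement long before the swing foot does. The
on-disk format is two TSV tables plus a JSON metadata sidecar, SI units; a
documented stub (`load_external`) describes how to map third-party
recordings onto the schema. Each dataset ships with a ground-truth bundle
for recovery tests.

What the generator does *not* emulate: multi-segment bodies and soft-tissue
artifacts, force-plate crosstalk, marker occlusions, belt-speed
fluctuations, or inter-subject physiological differences (multi-subject
datasets are emulated by multiple seeds). Passing recovery tests therefore
demonstrate pipeline correctness under the model's own assumptions, not
robustness to every artifact of real recordings.

## Inference pipeline

* **COM velocities** integrate the mass-normalized net force once, with
  integration constants fixed by zero trial means. Two drift estimators are
  applied: force-channel offsets measured from the *flight phases* (while
  airborne the true GRF is zero, so any reading is bias; a piecewise-linear
  interpolant through per-flight means tracks load-cell drift without
  touching the stance signal), then a piecewise-linear detrend of the
  integrated velocity over 20-step windows. A zero-phase Butterworth
  high-pass (cutoff = step frequency / divisor) is available as an
  alternative, but at the conventional cutoff of one eighth of step
  frequency it removes ~30% of the variance of the near-white apex-deviation
  sequence and inflates regression slopes by ~40% — the impulse deviations
  are first differences of the velocity sequence, so their covariance with
  the removed low-frequency band is negligible while the regressor variance
  shrinks. The detrend default keeps recovered gains within a few percent of
  truth; this choice is a documented deviation from the high-pass
  convention, justified by parameter recovery.
* **Events**: stances are contiguous samples with a foot's vertical GRF
  above 0.05 bw (≈ 30 N for a 67 kg runner), sub-sample refined; sides must
  alternate without double support. The apex preceding each stance is the
  descending zero of the reconstructed vertical velocity in the flight, with
  end-of-stance substitution flagged when absent.
* **Features**: stance impulses by trapezoid integration of the emitted
  channels; vertical half-impulses split at the detected stance midpoint
  (the half-step split of the idealized vertical model coincides with the
  stance midpoint in its infinitesimal-flight limit); foot placement = foot
  marker minus COM at touchdown; landing leg length = COM-to-foot distance
  at touchdown; GRFs bin-averaged into 20 equal phase bins. Deviations
  subtract subject × side means; pooling across trials/subjects re-subtracts
  within groups.
* **Regressions**: OLS (statsmodels) per side, raw p-values, with three
  predictor sets — apex (Δẋₐ, Δẏₐ, Δzₐ), apex+position (the station-keeping
  check), continuous (the COM state at the start of the current stance) —
  plus the reduced forms with only the empirically significant predictors. Apex-to-apex maps are per-side
  3×3 OLS fits; stride eigenvalues come from the product of the two side
  maps. Rank-deficient designs fail loudly, naming the collinear
  predictors. Phase-resolved sensitivities fit each of 20 bins per GRF
  component. Bootstrap gain-versus-sample-size resamples steps with
  replacement and reports the log-log slope of the estimate s.d. (≈ −0.5).

### Measurement conventions matter

Two findings from the recovery experiments are worth flagging.

1. The *half-impulse* and *landing-leg-length* sensitivities depend on the
   stance-window convention. For the muscle variant the force dwells below
   the detection threshold near takeoff, so the detected stance end tracks
   the activation profile rather than the leg-extension event; the measured
   half-impulse sensitivity to apex height is then ≈ 2.5 rather than the
   ≈ 1.2 of the event-based window. Oracles in the test suite therefore use
   the same threshold-based convention as the pipeline. Similarly the
   measured landing-length gain (≈ 0.32) carries a small mechanical
   component on top of the programmed 0.3.
2. In this model a *higher* apex increases the first-half vertical impulse
   (landing momentum dominates), whereas human runners show the opposite
   sign — their within-stance timing shift is stronger. The inference
   pipeline recovers the model's true behavior exactly; the sign difference
   is a structural property of the fitted minimal model, not a pipeline
   artifact.

## Problem sizes

The packaged recovery run is 2000 steps of the muscle variant at calibrated
noise (seed 1); unit tests use 40–600-step direct-force datasets. At 2000
steps the recovered left-stance sideways impulse slope is −1.07 ± 0.03 (the
human value is −1.03), the sideways placement gain 0.98 ± 0.02 (programmed
0.95), and the measured stride spectral radius ≈ 0.14. The acceptance
script reruns this end-to-end in about six minutes on one core.

## Known limitations

Point mass, massless legs, no trunk or swing dynamics, no activation lag
(excitation equals activation), quasistatic tendon, flat terrain by default
(terrain enters as touchdown-height or apex-height offsets), linear
force-velocity relation, single lumped muscle. The controller corrects no
absolute-position errors (no station keeping), matching its inputs. The
half-impulse sign difference from human data and the direct-force variant's
noise tolerance at calibrated noise (see above) are the two places where
this minimal model's behavior measurably departs from the human
observations it was built around.
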