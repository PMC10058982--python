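# Methods

`vesseluq` implements a three-stage pipeline: (1) estimation of a vessel
wall's elastic modulus from flow–area curves measured at a single imaging
plane, (2) a deterministic lumped-parameter (0D) model of a compliant
aorta whose wall stiffness is the uncertain input, and (3) non-intrusive
generalized Polynomial Chaos (gPC) that turns four deterministic runs into
time-resolved stochastic summaries of flow and lumen area at five
cross-sections. This note records the models, the assumptions behind
them, the defaults and why they were chosen, and the known limitations.
All internal units are strict SI (m, s, kg, Pa); megapascals appear only
in reports.

## 1. Elastic modulus from QA curves

A cine phase-contrast acquisition yields, per cardiac frame, the lumen
cross-sectional area `A(t)` and the through-plane volumetric flow `Q(t)`.
During the early-systolic upstroke — before reflected waves return from
the periphery — the flow–area trajectory is approximately linear and its
slope is the local pulse wave velocity (the QA-loop method):

    PWV = dQ/dA |_(early systole).

The wall modulus then follows from the corrected image-based stiffness
formula

    E = 3 χ ρ PWV² (1 + A0 / WCSA),        χ = γ / RAC,

with `A0` the diastolic lumen area, `WCSA` the wall cross-sectional area
(annulus between inner and outer wall contours at diastole), `ρ` the
blood density (default 1060 kg/m³), `RAC = (Amax − Amin)/Amax` the
relative area change over the cycle, and `γ` a dimensionless factor that
in the originating formulation depends on diastolic area, flow and
internal pressure.

Design choices where the problem is genuinely open:

* **γ is pluggable, default χ = 1.** No closed form for γ is fixed by
  this package; `γ` may be a scalar or a callable of the curve set. The
  default sets `γ = RAC`, i.e. `χ = 1`, which reduces the formula to its
  uncorrected form. All recovery tests use the same convention on both
  the generator and estimator side so that they probe numerics, not the γ
  ambiguity.
* **RAC normalization.** `(Amax − Amin)/Amax` by default (keeps RAC in
  (0,1)); `min` and `mean` denominators are selectable.
* **Early-systole window.** No universal frame rule exists, so the window
  is the contiguous run of samples on the rising limb of flow (walking
  back from the global flow peak) whose flow lies between 0.15 and 0.85
  of the peak (both fractions configurable); ties between candidate runs
  resolve to the run ending nearest the peak. At least 3 samples are
  required, and an explicit index window can always be supplied instead.
* **Fit.** Ordinary least squares of Q on A over the window; `r²` is
  reported from the same fit. A non-positive slope raises instead of
  propagating a meaningless modulus.

Degenerate inputs raise typed errors: constant flow (no rising limb),
fewer than 3 qualifying samples, zero area variance in the window, zero
area excursion over the cycle.

**Known statistical limitation.** OLS of Q on noisy A is an
errors-in-variables problem: frame-wise area noise of standard deviation
σ attenuates the expected slope by roughly `var(A_win)/(var(A_win)+σ²)`,
where `var(A_win)` is the true area variance inside the fit window. For a
stiff aorta the within-window area variation is below 1% of `A0`, so
area noise of a few percent of `A0` biases the recovered modulus low by
tens of percent, and no estimator of a single 30-frame curve can remove
this (moment-corrected and Deming-type fits are unstable at 3–7 window
points). The replicate machinery in `synthetic_data.noisy_replicates`
exists precisely to quantify this; see §5.

## 2. Generalized Polynomial Chaos (one uniform parameter)

The uncertain modulus is modelled as uniform on
`[Ê(1−h), Ê(1+h)]` with relative halfwidth `h = 0.23` by default — the
least-informative distribution for a bounded estimation error of about
±20% with margin. On the standard coordinate `ζ ∈ [−1,1]` with
probability weight `η(ζ) = 1/2`, the matching orthogonal basis is the
Legendre family, with `⟨P_r, P_r⟩ = 1/(2r+1)`.

* **Quadrature.** `gauss_legendre_rule(n)` wraps
  `numpy.polynomial.legendre.leggauss` and rescales the weights to sum to
  one. The affine map onto the parameter support returns values in
  *descending* order, so the first run `x1` uses the largest modulus
  (matching the conventional labelling of the quadrature points).
* **Projection.** With model outputs `X(ζ_q)` at the nodes,
  `a_r = (2r+1) Σ_q w_q X(ζ_q) P_r(ζ_q)`, applied independently per time
  sample, cross-section and quantity. The truncation order is 3, so 4
  deterministic runs suffice. Note that the discrete projection with the
  minimal (order+1)-point rule aliases the model's content beyond the
  rule's exactness degree; for analytic test functions such as `exp(ζ)`
  this aliasing is of order 1e-3 on the top coefficient and vanishes
  rapidly with finer rules.
* **Moments.** `mean = a0`, `var = Σ_{r≥1} a_r²/(2r+1)` — exact under the
  truncated expansion, no sampling involved.
* **Densities.** `estimate_pdf` draws `ζ ~ U[−1,1]` with an explicit seed
  (default 10⁵ samples), evaluates the truncated series, and histograms
  per time instant on 64 bins spanning a *shared* value axis (so the
  result is a plottable density surface); every column is normalized to
  unit integral. Monte-Carlo sampling is preferred over the analytic
  change of variables because a cubic surrogate may be non-monotone on
  the support, making the analytic density multi-branch; fold points then
  appear as a double-lobed histogram. A (numerically) constant surrogate
  returns a single-bin point mass with a flag instead of a zero-width
  histogram.
* **Convergence diagnostic.** `|a_r/a0|` per sample, with a warning when
  the highest-order summary ratio exceeds 0.1 (the truncation is then
  suspect). Samples whose `|a0|` is below 5% of the stream's largest
  `|a0|` are excluded from the summary: flow crosses zero within the
  cycle, and normalizing by a vanishing mean measures nothing about
  truncation.

Non-goals: multi-dimensional parameter spaces, sparse grids, non-uniform
input densities, intrusive Galerkin formulations.

## 3. The lumped-parameter aortic surrogate

The forward model is a chain of five compliant segments (CS1–CS5:
ascending aorta, arch before and after the supra-aortic trunks, and two
descending stations) with three-element Windkessel (RCR) outlets: the
brachiocephalic, left common carotid and left subclavian arteries shunt
the junction node between CS2 and CS3, and the descending aorta
terminates the chain. It is a desk-scale stand-in for a 3D
fluid–structure-interaction model: it reproduces the *contract* — flow
and area time curves per cross-section responding to wall stiffness under
physiological loads — not patient-specific hemodynamics, and no claim of
equivalence with a 3D model is made.

Each segment of length `L`, diastolic lumen `A0` and modulus `E`
contributes:

* wave speed `c` from the inverse of the stiffness formula of §1;
* compliance `C = A0 L / (ρ c²)` at its proximal node (Bramwell–Hill:
  `dA/dp = A0/(ρc²)` per unit length);
* Poiseuille resistance `R = 8π μ L / A0²` and plug-flow inertance
  `L_in = ρ L / A0` on the link to the next node (μ = 0.05 kg/m/s).

The lumen area reported at a cross-section follows the linearized tube
law `A(t) = A0 (1 + (p(t) − p_dias)/(ρc²))`, with the diastolic reference
pressure taken per node as the minimum of the converged cycle (a constant
reference is configurable). The flow reported at a cross-section is the
flow leaving its node distally.

**Integration.** Classical explicit RK4 at the reporting step
Δt = 0.005 s (which must divide the 1.12 s period), with 4 internal
substeps per reported sample; the substeps keep the stiffest
node–outlet coupling (`1/(C_node·Rp_parallel)` ≈ 10³ s⁻¹ at the arch
junction) well inside the stability region with margin across the whole
quadrature range of moduli. The reported final cycle is phase-aligned to
the cycle boundary. Divergence (non-finite state or nodal pressure
beyond 10⁸ Pa) raises an instability error advising a smaller step.
Step-halving consistency and mass conservation over the converged cycle
are asserted by the test suite.

**Run-in and warm start.** Runs last 10 cycles and report the last; the
periodicity error is the relative L2 difference between the last two
cycles' node-pressure traces (warning above 5e-3, no failure). Because
the outlet time constants `Rd·C ≈ 1.9 s` are comparable to the total
simulated time, the default fixtures pre-charge each peripheral reservoir
at its closed-form cycle-mean pressure (mean inflow split by outlet
conductances) and the nodes at the mean arterial pressure; segment flows
still start at zero. Starting from a fully zero state is possible but
leaves a visible run-in drift after ten cycles.

**Fixture values.** The default geometry tapers from `A0 = 8·10⁻⁴ m²`
(ascending) to `3·10⁻⁴ m²` (distal descending) over a total length of
0.35 m with `WCSA = 0.25·A0` — synthetic fixture choices in the
physiological range, not patient measurements. The RCR values are
published constants for the four outlets. The inflow is a half-sine
systole over 35% of the cycle scaled to a stroke volume of 80 ml
(`Q_peak = π·SV/(2·f·T)`), giving a cardiac output of ≈4.3 l/min and
simulated pressures of roughly 74–107 mmHg with a ~69/31 split between
descending aorta and supra-aortic branches.

**Limitation: no wave propagation.** The pulse transit time through the
chain (~30 ms) is far below the systolic upstroke (~200 ms), so the
network loads every node quasi-statically; the QA-loop slope measured on
curves extracted from the *chain* therefore reflects the downstream load
impedance, not the local wave speed (it overestimates PWV by ~60% at CS1
and more distally). This is a property of any coarse 0D network, and it
is why closed-loop PWV recovery is exact only for the matched
single-segment topology of §4. The stochastic-analysis outputs are
unaffected: they only require the deterministic map from modulus to
curves to be smooth, which it is.

## 4. Synthetic PCMRI-like data

The generator emulates a retrospectively gated 30-frame acquisition over
a 1.12 s cycle at a single plane. It builds a one-segment model from the
requested ground-truth modulus and terminates it with its characteristic
impedance `Z_c = ρc/A0` in front of a large (10⁻⁶ m³/Pa), pre-charged
peripheral reservoir closing through a distal resistance chosen to
balance the mean inflow at ~80 mmHg. A matched resistive termination is
the lumped equivalent of a reflection-free distal bed: with the reservoir
pressure quasi-static, outlet flow and node pressure (hence area) are
exactly proportional, so the QA slope *equals* the imposed wave speed by
physics rather than by construction of the curves — the estimation chain
still has to find the window, fit the slope and apply the stiffness
formula. The ~0.5% residual recovery error comes from the small
within-cycle reservoir ripple and the 30-frame discretization.

Frames are obtained by linear interpolation of the converged cycle onto a
uniform 30-point grid; frame-wise independent Gaussian noise (separate
standard deviations for flow and area, explicit seed) may be added, and
areas are floored at a tiny positive value. `noisy_replicates` redraws
only the noise, reusing the single deterministic simulation.

What the generator does **not** emulate: MRI physics (partial volume,
velocity-encoding errors, eddy currents), correlated segmentation errors,
beat-to-beat variability, and wave reflections in the measured vessel.
Passing recovery tests therefore demonstrate the numerical correctness
and internal consistency of the chain under the stated model, not its
accuracy on clinical data.

## 5. The uncertainty study and its problem sizes

`run_uq` resolves `Ê` (literal value, QA file, or synthetic dataset),
maps the 4-point rule onto `[0.77Ê, 1.23Ê]`, runs the surrogate once per
quadrature point (identical topology and inflow), fits a separate
expansion per cross-section and per quantity — never a joint expansion —
and emits per-pair mean/std CSVs, density-grid CSVs, per-run curve files
and a JSON manifest (config echo, seed, quadrature values, convergence
report; no timestamps, so identical configurations reproduce identical
artifacts bit for bit). Deterministic-run failure aborts the batch;
statistical-quality findings (slow coefficient decay, degenerate
densities) warn and annotate but never abort.

Problem sizes used by the test suite and kept deliberately desk-scale:
10 cycles × 224 samples per deterministic run (4 runs per study); 10⁵
Monte-Carlo samples × 64 bins per density surface (reduced to 2·10³–2·10⁴
in fast tests); 200 replicates in noise studies; a 5-point modulus grid
(1.0–3.0 MPa) for zero-noise recovery. A full study completes in well
under a minute on one core.

## 6. Numerical conventions and edge cases

* Quadrature weights sum to 1 within 1e-12; nodes are symmetric about 0.
* Worked-example comparisons round to two decimals only at report time;
  full precision is kept internally.
* QA CSV round-trips are lossless (`%.17e` on write, correctly rounded
  parsing on read).
* `windkessel_step` is the explicit single-outlet primitive (forward
  Euler for `dp_c/dt = (Q − p_c/Rd)/C`); the network integrator advances
  the same dynamics inside the global RK4 state.
* Derived seeds for per-stream density sampling are
  `seed·1000 + 10·section + quantity`, kept below 2³¹.
* Histogram value axes come from a dense deterministic sweep of the
  surrogate (513 points per time sample) rather than from the random
  samples, so the binning itself is seed-independent.
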