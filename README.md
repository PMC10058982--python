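# vesseluq

Image-based arterial stiffness estimation and uncertainty propagation for
cardiovascular modelling.

Patient-specific hemodynamic simulations need the elastic modulus *E* of
the vessel wall, but *E* is rarely measurable in vivo without invasive
pressure data. One practical route estimates it from routine
phase-contrast MRI alone: the flow–area (QA) loop of a single imaging
plane is approximately linear during the reflection-free early-systolic
upstroke, its slope is the local pulse wave velocity,

```
PWV = dQ/dA |_(early systole),
E   = 3 χ ρ PWV² (1 + A0/WCSA),      χ = γ / RAC,
```

and the residual uncertainty of that estimate (±23% here) can then be
propagated through a deterministic hemodynamic model with generalized
Polynomial Chaos (gPC): the uncertain modulus is uniform on
`[0.77·Ê, 1.23·Ê]`, Legendre polynomials form the matching basis, a
4-point Gauss–Legendre rule fixes the four wall stiffnesses to simulate,
and spectral projection of the four runs yields time-resolved means,
standard deviations and probability densities of flow and lumen area at
each cross-section — at the cost of four deterministic simulations
instead of thousands.

The package is aimed at cardiovascular-modelling researchers who want a
tested, reproducible, desk-scale implementation of this workflow. The
deterministic forward model is a lumped-parameter (0D) aortic network —
five compliant segments with three-element Windkessel outlets — standing
in for a full 3D fluid–structure-interaction solver; see
[docs/methods.md](docs/methods.md) for the model, its assumptions and its
limits.

Modules:

| module | contents |
| --- | --- |
| `vesseluq.qa_elasticity` | QA-loop window detection, PWV fit, χ correction, modulus formula and its inverse |
| `vesseluq.gpc_engine` | Gauss–Legendre rules, Legendre projection, surrogate evaluation, moments, sampled densities, convergence diagnostics |
| `vesseluq.aorta_surrogate` | segment/Windkessel network, RK4 integration to periodic state, per-section curve extraction |
| `vesseluq.synthetic_data` | PCMRI-like QA datasets with known ground truth; fixture network configs |
| `vesseluq.uq_pipeline` | end-to-end study, CSV/JSON artifacts, manifest |
| `vesseluq.cli` | `vesseluq estimate-e / simulate / uq / synth` |

## Worked example

Generate a synthetic 30-frame QA dataset from a known ground truth of
2.0 MPa, then estimate the modulus back from the curves alone:

```sh
$ vesseluq synth --e-true 2.0e6 --seed 7 --out qa_demo.csv
{"elastic_modulus_true_pa": 2000000.0, "pwv_true_m_per_s": 11.215443081840885, "seed": 7, "n_frames": 30}

$ vesseluq estimate-e qa_demo.csv --a0 8e-4 --wcsa 2e-4
QA-loop elastic-modulus estimate
  E              = 1.98944e+06 Pa (1.99 MPa)
  PWV            = 11.19 m/s (r^2 = 1.0000)
  RAC            = 0.03421
  chi            = 1 (gamma = 0.03421)
  blood density  = 1060 kg/m^3
  fit window     = samples 1..3 (fractions(0.15,0.85))
```

The chain recovers the 2.0 MPa ground truth to 0.5% from 30 frames: the
fit finds the early-systolic window (frames 1–3 of the upstroke), its
slope is the pulse wave velocity (11.19 m/s vs 11.22 m/s imposed), and
the stiffness formula converts it to a modulus.

Run the full uncertainty study around an image-based estimate
Ê = 2.02 MPa:

```sh
$ vesseluq uq --ehat 2.02e6 --seed 1 --out study/
E_hat = 2.02 MPa (literal)
quadrature points: 2.42, 2.18, 1.86, 1.62 MPa
artifacts in study/
```

The four quadrature points are the wall stiffnesses of the four
deterministic simulations (x1 = 2.42 MPa the stiffest, x4 = 1.62 MPa the
softest — the factors 1.2·Ê, 1.08·Ê, 0.92·Ê, 0.8·Ê of the 4-point
Gauss–Legendre rule on a ±23% uniform interval). `study/` then contains,
per cross-section CS1–CS5 and per quantity (flow, area):
`summary_*.csv` (time, mean, std), `pdf_*.csv` (time, value-bin,
density), the per-run curve files, and `manifest.json` recording seed,
quadrature values and the gPC coefficient-decay report. On the bundled
aortic fixture the study reproduces the expected physics: area
uncertainty concentrates in the ascending aorta (largest lumen) around
the area peak, vanishes toward late diastole, and flow is far less
sensitive to the wall modulus than area.

Everything is importable as a library as well:

```python
from vesseluq.uq_pipeline import StudyConfig, run_uq
result = run_uq(StudyConfig(elastic_modulus=2.02e6, seed=1))
result.summaries[("CS1", "area")].std   # sigma(t) of lumen area at CS1
```

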