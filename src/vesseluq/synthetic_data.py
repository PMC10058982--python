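"""Synthetic PCMRI-like QA datasets and fixture configurations.

Every pipeline stage can be exercised without external data: this module
generates periodic flow--area curve sets from a *known* ground-truth
elastic modulus, plus ready-made network configurations.

The QA generator runs the one-segment lumped surrogate whose wall modulus
is the requested ground truth and terminates it with its characteristic
impedance (``rho * c / A0``) in front of a large, pre-charged peripheral
reservoir.  A matched resistive termination is the lumped equivalent of a
reflection-free distal bed, which is exactly the regime in which the
QA-loop slope equals the wave speed -- so the generated curves obey the
estimation model by physics, not by shortcut, and the full estimation
chain must still detect the window, fit the slope and apply the stiffness
formula to recover the modulus.

The 30-frame default emulates a retrospectively gated cine PCMRI
acquisition over a 1.12 s cardiac cycle; optional frame-wise Gaussian
noise stands in for segmentation scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aorta_surrogate import (
    BLOOD_DENSITY,
    BLOOD_VISCOSITY,
    InflowWaveform,
    SimulationResult,
    assemble_network,
    run_cycles,
)
from .qa_elasticity import QACurveSet, VesselGeometry, pwv_from_modulus

__all__ = [
    "SyntheticSpec",
    "SyntheticQAResult",
    "make_inflow_waveform",
    "synthesize_qa_curves",
    "noisy_replicates",
    "make_fixture_config",
    "FIXTURE_PRESETS",
]

#: reservoir (diastolic bed) pressure the generator pre-charges to, Pa (~80 mmHg)
RESERVOIR_PRESSURE = 1.07e4
#: reservoir capacitance, m^3/Pa -- large, so the bed pressure is quasi-static
RESERVOIR_CAPACITANCE = 1.0e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and acquisition parameters for one synthetic dataset."""

    ground_truth_modulus: float                   # Pa
    geometry: VesselGeometry = field(
        default_factory=lambda: VesselGeometry(8.0e-4, 2.0e-4)
    )
    period: float = 1.12                          # s
    n_frames: int = 30
    noise_sd_flow: float = 0.0                    # m^3/s, per frame
    noise_sd_area: float = 0.0                    # m^2, per frame
    seed: int = 0
    chi: float = 1.0
    stroke_volume: float = 8.0e-5                 # m^3
    systolic_fraction: float = 0.35
    segment_length: float = 0.1                   # m

    def __post_init__(self) -> None:
        if self.ground_truth_modulus <= 0:
            raise ValueError("ground_truth_modulus must be > 0")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.noise_sd_flow < 0 or self.noise_sd_area < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class SyntheticQAResult:
    """Generated curves together with their ground truth."""

    curves: QACurveSet
    elastic_modulus_true: float
    pwv_true: float
    spec: SyntheticSpec
    simulation: SimulationResult


def make_inflow_waveform(
    period: float,
    stroke_volume: float = 8.0e-5,
    systolic_fraction: float = 0.35,
    n_samples: int | None = None,
) -> InflowWaveform:
    """Half-sine systolic inflow with zero diastolic flow.

    ``Q(t) = Q_pk sin(pi t / (f T))`` for ``t < f T`` and 0 otherwise, with
    the peak ``Q_pk = pi SV / (2 f T)`` chosen so the integral over one
    period equals the stroke volume exactly.  This is a stand-in for a
    measured patient waveform, which is not part of the fixture data.
    """
    if not (0 < systolic_fraction < 1):
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if stroke_volume <= 0:
        raise ValueError("stroke_volume must be > 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    t_sys = systolic_fraction * period
    q_peak = np.pi * stroke_volume / (2.0 * t_sys)

    def flow_func(t):
        t = np.asarray(t, dtype=float)
        out = np.where(t < t_sys, q_peak * np.sin(np.pi * np.minimum(t, t_sys) / t_sys), 0.0)
        return out if out.ndim else float(out)

    return InflowWaveform(
        period=period,
        flow_func=flow_func,
        description={
            "shape": "half-sine",
            "stroke_volume": stroke_volume,
            "systolic_fraction": systolic_fraction,
            "peak_flow": q_peak,
            "n_samples": n_samples,
        },
    )


def _single_segment_config(spec: SyntheticSpec) -> dict:
    """One-segment network with a matched (reflection-free) termination."""
    a0 = spec.geometry.lumen_area_diastole
    pwv = pwv_from_modulus(spec.ground_truth_modulus, spec.geometry,
                           BLOOD_DENSITY, spec.chi)
    seg = {
        "label": "CS1",
        "length": spec.segment_length,
        "lumen_area_diastole": a0,
        "wall_cross_sectional_area": spec.geometry.wall_cross_sectional_area,
        "elastic_modulus": spec.ground_truth_modulus,
        "chi": spec.chi,
    }
    # characteristic impedance of the segment: a matched, purely resistive
    # termination is the lumped equivalent of a reflection-free distal bed
    r_char = BLOOD_DENSITY * pwv / a0
    q_mean = spec.stroke_volume / spec.period
    return {
        "blood": {"density": BLOOD_DENSITY, "viscosity": BLOOD_VISCOSITY},
        "segments": [seg],
        "outlets": {
            "distal_bed": {
                "proximal_resistance": r_char,
                "capacitance": RESERVOIR_CAPACITANCE,
                "distal_resistance": RESERVOIR_PRESSURE / q_mean,
                "initial_pressure": RESERVOIR_PRESSURE,
                "attach": "node",
                "node": 0,
            }
        },
        "inflow": {
            "period": spec.period,
            "stroke_volume": spec.stroke_volume,
            "systolic_fraction": spec.systolic_fraction,
        },
    }


def synthesize_qa_curves(
    spec: SyntheticSpec,
    inflow: InflowWaveform | None = None,
    *,
    n_cycles: int = 5,
    samples_per_cycle: int = 224,
) -> SyntheticQAResult:
    """Generate a noisy n-frame QA dataset from a known elastic modulus.

    Runs the one-segment surrogate to periodicity, resamples flow and area
    onto a uniform ``n_frames`` grid (linear interpolation, emulating
    retrospective gating), and adds seeded frame-wise Gaussian noise.
    """
    config = _single_segment_config(spec)
    if inflow is None:
        inflow = make_inflow_waveform(
            spec.period, spec.stroke_volume, spec.systolic_fraction
        )
    network = assemble_network(config)
    dt = spec.period / samples_per_cycle
    result = run_cycles(network, inflow, n_cycles=n_cycles, dt=dt)

    t_frames = np.arange(spec.n_frames) * (spec.period / spec.n_frames)
    # append the wrap-around point so frames beyond the last dt-sample interpolate
    t_grid = np.concatenate([result.time, [spec.period]])
    lab = network.labels[0]
    q_grid = np.concatenate([result.flow[lab], [result.flow[lab][0]]])
    a_grid = np.concatenate([result.area[lab], [result.area[lab][0]]])
    q = np.interp(t_frames, t_grid, q_grid)
    a = np.interp(t_frames, t_grid, a_grid)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_flow > 0:
        q = q + rng.normal(0.0, spec.noise_sd_flow, spec.n_frames)
    if spec.noise_sd_area > 0:
        a = a + rng.normal(0.0, spec.noise_sd_area, spec.n_frames)
        a = np.clip(a, 1e-9, None)  # areas stay positive even under heavy noise

    pwv_true = pwv_from_modulus(spec.ground_truth_modulus, spec.geometry,
                                BLOOD_DENSITY, spec.chi)
    curves = QACurveSet(time=t_frames, flow=q, area=a, period=spec.period)
    return SyntheticQAResult(
        curves=curves,
        elastic_modulus_true=spec.ground_truth_modulus,
        pwv_true=pwv_true,
        spec=spec,
        simulation=result,
    )


def noisy_replicates(
    base: SyntheticQAResult,
    n_replicates: int,
    noise_sd_flow: float = 0.0,
    noise_sd_area: float = 0.0,
    seed: int = 0,
) -> list[QACurveSet]:
    """Seeded noisy replicates of one noise-free synthetic dataset.

    The deterministic simulation behind ``base`` is identical across
    replicates, so it is run once and only the frame-wise Gaussian noise is
    redrawn -- the same noise model ``synthesize_qa_curves`` applies.
    Useful for replicate studies (bias/dispersion of the estimation chain).
    """
    if noise_sd_flow < 0 or noise_sd_area < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    t, q0, a0 = base.curves.time, base.curves.flow, base.curves.area
    out = []
    for _ in range(n_replicates):
        q = q0 + rng.normal(0.0, noise_sd_flow, len(q0)) if noise_sd_flow > 0 else q0
        a = a0 + rng.normal(0.0, noise_sd_area, len(a0)) if noise_sd_area > 0 else a0
        out.append(
            QACurveSet(time=t.copy(), flow=np.asarray(q, float).copy(),
                       area=np.clip(a, 1e-9, None), period=base.curves.period)
        )
    return out


def _aorta_default_config() -> dict:
    """Five tapering thoracic-aorta segments with RCR outlets.

    Geometry values are synthetic fixture choices (ascending-to-descending
    taper, wall area 25% of lumen area, total length 0.35 m), not patient
    measurements.  Outlet RCR parameters are standard published values for
    the three supra-aortic branches and the descending aorta.
    """
    seg = lambda label, length, a0: {
        "label": label,
        "length": length,
        "lumen_area_diastole": a0,
        "wall_cross_sectional_area": 0.25 * a0,
        "elastic_modulus": 2.0e6,
        "chi": 1.0,
    }
    # warm-start each peripheral reservoir at its closed-form cycle-mean
    # pressure (mean inflow split by outlet conductances); the Windkessel
    # time constants (~1.9 s) would otherwise still be relaxing after ten
    # 1.12 s cycles
    rcr = {
        "brachiocephalic_artery": (1.3e7, 1.5e-9, 1.3e9),
        "left_common_carotid_artery": (5.1e7, 3.8e-10, 5.0e9),
        "left_subclavian_artery": (1.1e7, 1.7e-9, 1.1e9),
        "descending_aorta": (2.5e6, 7.7e-9, 2.4e8),
    }
    q_mean = 8.0e-5 / 1.12
    g = {k: 1.0 / (rp + rd) for k, (rp, c, rd) in rcr.items()}
    g_tot = sum(g.values())
    p_init = {k: rcr[k][2] * q_mean * g[k] / g_tot for k in rcr}
    outlets = {}
    for k, (rp, c, rd) in rcr.items():
        outlets[k] = {
            "proximal_resistance": rp, "capacitance": c,
            "distal_resistance": rd, "initial_pressure": p_init[k],
        }
        if k == "descending_aorta":
            outlets[k]["attach"] = "terminal"
        else:
            outlets[k].update(attach="node", node=2)
    return {
        "blood": {"density": BLOOD_DENSITY, "viscosity": BLOOD_VISCOSITY},
        "segments": [
            seg("CS1", 0.06, 8.0e-4),
            seg("CS2", 0.07, 7.0e-4),
            seg("CS3", 0.07, 5.0e-4),
            seg("CS4", 0.07, 4.0e-4),
            seg("CS5", 0.08, 3.0e-4),
        ],
        "outlets": outlets,
        "initial_node_pressure": sum(p_init.values()) / len(p_init),
        "inflow": {"period": 1.12, "stroke_volume": 8.0e-5,
                   "systolic_fraction": 0.35},
    }


def make_fixture_config(preset: str, **overrides) -> dict:
    """Complete, valid network configuration for a named preset.

    Presets: ``aorta_default`` (five segments, four RCR outlets),
    ``stiff_aorta`` (same, wall modulus doubled), ``single_segment``
    (the topology the QA generator uses; accepts ``elastic_modulus``).
    """
    if preset == "aorta_default":
        config = _aorta_default_config()
    elif preset == "stiff_aorta":
        config = _aorta_default_config()
        for s in config["segments"]:
            s["elastic_modulus"] *= 2.0
    elif preset == "single_segment":
        e = overrides.pop("elastic_modulus", 2.0e6)
        spec = SyntheticSpec(ground_truth_modulus=e)
        config = _single_segment_config(spec)
    else:
        raise KeyError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    if overrides:
        elastic = overrides.pop("elastic_modulus", None)
        if elastic is not None:
            for s in config["segments"]:
                s["elastic_modulus"] = elastic
        config.update(overrides)
    return config


FIXTURE_PRESETS = ("aorta_default", "stiff_aorta", "single_segment")
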