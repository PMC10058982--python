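"""Deterministic 0D (lumped-parameter) surrogate of a compliant aorta.

The model is a chain of compliant vessel segments with three-element
Windkessel (RCR) outlets.  Each segment contributes

* a compliance ``C = A0 * L / (rho * PWV^2)`` lumped at its proximal node
  (Bramwell--Hill: the wall stiffness enters through the wave speed that
  the elastic modulus implies for the segment geometry),
* a Poiseuille resistance ``R = 8 pi mu L / A0^2`` and a blood inertance
  ``L_in = rho * L / A0`` on the link to the next node.

Outlets either shunt a node (supra-aortic branches at the arch junction)
or terminate the chain in series with the last segment's resistance and
inertance (descending aorta).  The inlet is a prescribed periodic flow
waveform.  Integration is explicit classical Runge--Kutta (RK4) at a fixed
reporting step, with internal substeps for stability of the stiff
node--outlet couplings.

Cross-section ``CS_i`` of segment ``i`` reports the segment's node
pressure, the flow leaving that node distally, and the lumen area from the
linearized tube law

    A_i(t) = A0_i * (1 + (p_i(t) - p_dias_i) / (rho * PWV_i^2)),

with the diastolic reference pressure taken per node as the minimum of the
converged cycle (configurable constant alternative).

This is a desk-scale stand-in for a 3D fluid--structure-interaction
simulation: it reproduces the *contract* (per-section flow and area time
curves responding to wall stiffness) and physiological orders of
magnitude, not patient-specific hemodynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    ConvergenceWarning,
    InstabilityError,
    UnknownLabelError,
)
from .qa_elasticity import QACurveSet, VesselGeometry, pwv_from_modulus

__all__ = [
    "VesselSegmentSpec",
    "DerivedSegmentParams",
    "WindkesselOutlet",
    "InflowWaveform",
    "NetworkModel",
    "SimulationResult",
    "derive_segment_params",
    "windkessel_step",
    "assemble_network",
    "run_cycles",
    "extract_curves",
]

BLOOD_DENSITY = 1060.0    # kg/m^3
BLOOD_VISCOSITY = 0.05    # kg/(m s), whole blood at aortic shear rates

# hard ceiling on nodal pressure used to detect a diverging explicit step
_PRESSURE_CEILING = 1.0e8  # Pa


@dataclass(frozen=True)
class VesselSegmentSpec:
    """Geometry and wall stiffness of one aortic segment (strict SI)."""

    label: str
    length: float
    lumen_area_diastole: float
    wall_cross_sectional_area: float
    elastic_modulus: float
    chi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("length", "lumen_area_diastole", "wall_cross_sectional_area",
                     "elastic_modulus", "chi"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"segment {self.label!r}: {name} must be > 0")

    @property
    def geometry(self) -> VesselGeometry:
        return VesselGeometry(self.lumen_area_diastole, self.wall_cross_sectional_area)


@dataclass(frozen=True)
class DerivedSegmentParams:
    """Lumped-element re-expression of a segment's wall and fluid mechanics."""

    pwv: float          # m/s
    compliance: float   # m^3/Pa
    resistance: float   # Pa s/m^3
    inertance: float    # Pa s^2/m^3


def derive_segment_params(
    spec: VesselSegmentSpec,
    blood_density: float = BLOOD_DENSITY,
    blood_viscosity: float = BLOOD_VISCOSITY,
) -> DerivedSegmentParams:
    """Wave speed and lumped R, L, C for one segment.

    The wave speed comes from the stiffness formula inverse; compliance
    follows from Bramwell--Hill (``dA/dp = A0 / (rho c^2)`` per unit
    length); resistance and inertance are Poiseuille and plug-flow values
    for a straight tube of the segment's diastolic calibre.
    """
    pwv = pwv_from_modulus(spec.elastic_modulus, spec.geometry, blood_density, spec.chi)
    a0, ell = spec.lumen_area_diastole, spec.length
    params = DerivedSegmentParams(
        pwv=pwv,
        compliance=a0 * ell / (blood_density * pwv**2),
        resistance=8.0 * np.pi * blood_viscosity * ell / a0**2,
        inertance=blood_density * ell / a0,
    )
    for name in ("pwv", "compliance", "resistance", "inertance"):
        if not getattr(params, name) > 0:
            raise ConfigurationError(f"derived {name} non-positive for {spec.label!r}")
    return params


@dataclass(frozen=True)
class WindkesselOutlet:
    """Three-element (RCR) Windkessel: Rp in series, then C parallel Rd.

    ``state_pressure`` is the pressure on the capacitor (the peripheral
    reservoir); the interface pressure seen by the network is
    ``state_pressure + Q * Rp``.
    """

    proximal_resistance: float  # kg s^-1 m^-4  (= Pa s / m^3)
    capacitance: float          # m^3 / Pa
    distal_resistance: float    # kg s^-1 m^-4
    state_pressure: float = 0.0

    def __post_init__(self) -> None:
        if min(self.proximal_resistance, self.capacitance, self.distal_resistance) <= 0:
            raise ConfigurationError("Rp, C and Rd must all be > 0")


def windkessel_step(
    outlet: WindkesselOutlet, inflow: float, dt: float
) -> tuple[float, WindkesselOutlet]:
    """Advance one outlet by one explicit Euler step under inflow ``Q``.

    Integrates ``dp_c/dt = (Q - p_c/Rd) / C`` and returns the interface
    pressure ``p_c + Q * Rp`` together with the updated outlet.  This is
    the single-outlet primitive; the network integrator advances the same
    dynamics inside its global RK4 state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pc = outlet.state_pressure + dt * (
        inflow - outlet.state_pressure / outlet.distal_resistance
    ) / outlet.capacitance
    if not np.isfinite(pc) or abs(pc) > _PRESSURE_CEILING:
        raise InstabilityError("Windkessel state overflow; reduce dt")
    new = replace(outlet, state_pressure=pc)
    return pc + inflow * outlet.proximal_resistance, new


@dataclass
class InflowWaveform:
    """Periodic inlet flow, given as a callable of time (seconds -> m^3/s)."""

    period: float
    flow_func: Callable[[np.ndarray], np.ndarray]
    description: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be > 0")

    def __call__(self, t):
        return self.flow_func(np.mod(t, self.period))

    def sample(self, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
        """Left-endpoint sampling of one period at ``n_samples`` points."""
        t = np.arange(n_samples) * (self.period / n_samples)
        return t, np.asarray(self(t), dtype=float)


@dataclass
class NetworkModel:
    """Segment chain plus Windkessel outlets (built by :func:`assemble_network`).

    ``attachments`` maps each outlet name to ``("node", i)`` for a shunt at
    node ``i`` or ``("terminal",)`` for the series termination behind the
    last segment.
    """

    segments: list[VesselSegmentSpec]
    derived: list[DerivedSegmentParams]
    outlets: dict[str, WindkesselOutlet]
    attachments: dict[str, tuple]
    blood_density: float = BLOOD_DENSITY
    blood_viscosity: float = BLOOD_VISCOSITY
    diastolic_reference: object = "minimum"  # or a float (Pa)
    initial_node_pressure: float = 0.0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def with_elastic_modulus(self, elastic_modulus: float) -> "NetworkModel":
        """Copy of the network with every segment's modulus replaced."""
        segs = [replace(s, elastic_modulus=elastic_modulus) for s in self.segments]
        der = [derive_segment_params(s, self.blood_density, self.blood_viscosity)
               for s in segs]
        return NetworkModel(
            segments=segs, derived=der, outlets=dict(self.outlets),
            attachments=dict(self.attachments),
            blood_density=self.blood_density,
            blood_viscosity=self.blood_viscosity,
            diastolic_reference=self.diastolic_reference,
            initial_node_pressure=self.initial_node_pressure,
        )


def _require(config: dict, key: str, context: str):
    if key not in config:
        raise ConfigurationError(f"missing key {key!r} in {context}")
    return config[key]


def assemble_network(config: dict) -> NetworkModel:
    """Build and validate a :class:`NetworkModel` from a plain config dict.

    The schema mirrors the YAML fixtures: ``blood`` (density, viscosity),
    ``segments`` (list of segment dicts, proximal to distal) and
    ``outlets`` (name -> RCR parameters plus an ``attach`` clause).  All
    units are SI.  Errors name the offending key.
    """
    blood = config.get("blood", {})
    rho = float(blood.get("density", BLOOD_DENSITY))
    mu = float(blood.get("viscosity", BLOOD_VISCOSITY))
    if rho <= 0 or mu <= 0:
        raise ConfigurationError("blood density and viscosity must be > 0")

    seg_cfgs = _require(config, "segments", "network config")
    if not seg_cfgs:
        raise ConfigurationError("segments list is empty")
    segments = []
    for i, sc in enumerate(seg_cfgs):
        kwargs = {}
        for key in ("label", "length", "lumen_area_diastole",
                    "wall_cross_sectional_area", "elastic_modulus"):
            kwargs[key] = _require(sc, key, f"segment #{i}")
        kwargs["chi"] = sc.get("chi", 1.0)
        segments.append(VesselSegmentSpec(**kwargs))
    derived = [derive_segment_params(s, rho, mu) for s in segments]

    out_cfgs = _require(config, "outlets", "network config")
    if not out_cfgs:
        raise ConfigurationError("outlets mapping is empty")
    outlets: dict[str, WindkesselOutlet] = {}
    attachments: dict[str, tuple] = {}
    n_terminal = 0
    for name, oc in out_cfgs.items():
        ctx = f"outlet {name!r}"
        outlets[name] = WindkesselOutlet(
            proximal_resistance=float(_require(oc, "proximal_resistance", ctx)),
            capacitance=float(_require(oc, "capacitance", ctx)),
            distal_resistance=float(_require(oc, "distal_resistance", ctx)),
            state_pressure=float(oc.get("initial_pressure", 0.0)),
        )
        attach = oc.get("attach", "terminal")
        if attach == "terminal":
            attachments[name] = ("terminal",)
            n_terminal += 1
        elif attach == "node":
            node = int(_require(oc, "node", ctx))
            if not (0 <= node < len(segments)):
                raise ConfigurationError(f"{ctx}: node {node} out of range")
            attachments[name] = ("node", node)
        else:
            raise ConfigurationError(f"{ctx}: unknown attach mode {attach!r}")
    if n_terminal > 1:
        raise ConfigurationError("at most one terminal outlet is allowed")
    if n_terminal == 0 and not any(
        kind == "node" and node == len(segments) - 1
        for (kind, *rest) in attachments.values()
        for node in rest
    ):
        raise ConfigurationError(
            "network is not terminated: no terminal outlet and no shunt outlet "
            "at the last node (offending key: 'outlets')"
        )

    return NetworkModel(
        segments=segments, derived=derived, outlets=outlets,
        attachments=attachments, blood_density=rho, blood_viscosity=mu,
        diastolic_reference=config.get("diastolic_reference", "minimum"),
        initial_node_pressure=float(config.get("initial_node_pressure", 0.0)),
    )


@dataclass
class SimulationResult:
    """Final-cycle traces per cross-section, on a shared uniform time grid."""

    time: np.ndarray                     # seconds within the final cycle
    flow: dict[str, np.ndarray]          # m^3/s per cross-section label
    area: dict[str, np.ndarray]          # m^2
    pressure: dict[str, np.ndarray]      # Pa
    periodicity_error: float
    dt: float
    period: float
    converged: bool = True
    diastolic_pressure: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.flow.keys())


class _ChainDynamics:
    """Precompiled right-hand side of the network ODEs.

    State layout: ``[p_node(0..N-1), q_link(0..N-2), q_term?, p_wk(..)]``.
    """

    def __init__(self, network: NetworkModel, inflow: InflowWaveform):
        n = network.n_segments
        self.n = n
        self.inflow = inflow
        self.p_node_init = network.initial_node_pressure
        der = network.derived
        self.c_node = np.array([d.compliance for d in der])
        self.r_link = np.array([d.resistance for d in der])
        self.l_link = np.array([d.inertance for d in der])

        self.shunt_nodes: list[int] = []
        self.shunt_params: list[tuple[float, float, float]] = []  # Rp, C, Rd
        self.term_params: tuple[float, float, float] | None = None
        self.wk_order: list[str] = []
        self.wk_init: list[float] = []
        term_name = None
        for name, outlet in network.outlets.items():
            kind = network.attachments[name][0]
            if kind == "terminal":
                term_name = name
                continue
            self.wk_order.append(name)
            self.wk_init.append(outlet.state_pressure)
            self.shunt_nodes.append(network.attachments[name][1])
            self.shunt_params.append(
                (outlet.proximal_resistance, outlet.capacitance,
                 outlet.distal_resistance)
            )
        if term_name is not None:
            o = network.outlets[term_name]
            self.term_params = (o.proximal_resistance, o.capacitance,
                                o.distal_resistance)
            self.wk_order.append(term_name)
            self.wk_init.append(o.state_pressure)
        self.has_term = self.term_params is not None
        self.n_shunt = len(self.shunt_nodes)
        self.n_links = n - 1
        self.n_state = n + self.n_links + (1 if self.has_term else 0) + len(self.wk_order)
        self.shunt_nodes_arr = np.array(self.shunt_nodes, dtype=int)
        self.shunt_rp = np.array([p[0] for p in self.shunt_params])
        self.shunt_c = np.array([p[1] for p in self.shunt_params])
        self.shunt_rd = np.array([p[2] for p in self.shunt_params])

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_state)
        y[: self.n] = self.p_node_init
        if self.wk_order:
            y[-len(self.wk_order):] = self.wk_init
        return y

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        n, nl = self.n, self.n_links
        p = y[:n]
        q = y[n:n + nl]
        pos = n + nl
        q_term = y[pos] if self.has_term else 0.0
        if self.has_term:
            pos += 1
        pwk = y[pos:]

        dy = np.empty_like(y)
        # node volume balance
        net = np.zeros(n)
        net[0] += self.inflow(t)
        if nl:
            net[1:] += q          # link i feeds node i+1
            net[:-1] -= q         # and drains node i
        if self.n_shunt:
            q_sh = (p[self.shunt_nodes_arr] - pwk[: self.n_shunt]) / self.shunt_rp
            np.subtract.at(net, self.shunt_nodes_arr, q_sh)
        if self.has_term:
            net[n - 1] -= q_term
        dy[:n] = net / self.c_node
        # link momentum balance
        if nl:
            dy[n:n + nl] = (p[:-1] - p[1:] - self.r_link[:-1] * q) / self.l_link[:-1]
        pos = n + nl
        if self.has_term:
            rp, c, rd = self.term_params
            pc = pwk[-1]
            dy[pos] = (p[n - 1] - pc - (self.r_link[-1] + rp) * q_term) / self.l_link[-1]
            pos += 1
        # peripheral reservoirs
        if self.n_shunt:
            dy[pos:pos + self.n_shunt] = (q_sh - pwk[: self.n_shunt] / self.shunt_rd) \
                / self.shunt_c
        if self.has_term:
            rp, c, rd = self.term_params
            dy[-1] = (q_term - pwk[-1] / rd) / c
        return dy

    def section_flows(self, p_hist, q_hist, qterm_hist, pwk_hist):
        """Flow leaving each node distally, per cross-section (columns)."""
        n = self.n
        flows = np.empty((p_hist.shape[0], n))
        if self.n_links:
            flows[:, :-1] = q_hist
        if self.has_term:
            flows[:, n - 1] = qterm_hist
        else:
            # terminate via shunt(s) at the last node
            last = n - 1
            total = np.zeros(p_hist.shape[0])
            for k, node in enumerate(self.shunt_nodes):
                if node == last:
                    total += (p_hist[:, last] - pwk_hist[:, k]) / self.shunt_rp[k]
            flows[:, n - 1] = total
        return flows


def run_cycles(
    network: NetworkModel,
    inflow: InflowWaveform,
    n_cycles: int = 10,
    dt: float = 0.005,
    *,
    substeps: int = 4,
    periodicity_tol: float = 5.0e-3,
    warn_on_nonconvergence: bool = True,
) -> SimulationResult:
    """Integrate the network for ``n_cycles`` cardiac cycles, return the last.

    Classical explicit RK4 at reporting step ``dt`` (which must divide the
    period), with ``substeps`` internal stages per reported sample for
    stability of the node--outlet couplings.  The periodicity error is the
    relative L2 difference between the last two cycles' node-pressure
    traces; exceeding ``periodicity_tol`` attaches a non-convergence
    warning to the result instead of failing.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    period = inflow.period
    steps_per_cycle = period / dt
    if abs(steps_per_cycle - round(steps_per_cycle)) > 1e-6 * steps_per_cycle:
        raise ValueError("dt must divide the period (to within 1e-6)")
    spc = int(round(steps_per_cycle))
    if substeps < 1:
        raise ValueError("substeps must be >= 1")

    dyn = _ChainDynamics(network, inflow)
    y = dyn.initial_state()
    n_steps = n_cycles * spc
    hist = np.empty((n_steps + 1, dyn.n_state))
    hist[0] = y
    h = dt / substeps
    rhs = dyn
    t = 0.0
    for k in range(n_steps):
        for _ in range(substeps):
            k1 = rhs(t, y)
            k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
            k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        if not np.all(np.isfinite(y)) or np.max(np.abs(y[: dyn.n])) > _PRESSURE_CEILING:
            raise InstabilityError(
                f"state diverged at t = {t:.3f} s; use a smaller dt or more substeps"
            )
        hist[k + 1] = y

    n = dyn.n
    nl = dyn.n_links
    # final cycle: samples at t = (n_cycles-1)*T ... n_cycles*T - dt, so the
    # reported grid arange(spc)*dt aligns with the cycle phase exactly
    last = hist[-spc - 1:-1]
    prev = hist[-2 * spc - 1:-spc - 1]
    p_last = last[:, :n]
    p_prev = prev[:, :n]
    norm = np.linalg.norm(p_last)
    per_err = 0.0 if norm == 0 else float(np.linalg.norm(p_last - p_prev) / norm)
    converged = per_err <= periodicity_tol
    if not converged and warn_on_nonconvergence:
        warnings.warn(
            f"periodic steady state not reached: periodicity error {per_err:.2e} "
            f"> {periodicity_tol:.1e} after {n_cycles} cycles",
            ConvergenceWarning,
            stacklevel=2,
        )

    q_hist = last[:, n:n + nl]
    pos = n + nl
    qterm_hist = last[:, pos] if dyn.has_term else None
    pwk_hist = last[:, -len(dyn.wk_order):] if dyn.wk_order else last[:, :0]
    flows = dyn.section_flows(p_last, q_hist, qterm_hist, pwk_hist)

    labels = network.labels
    rho = network.blood_density
    time = np.arange(spc) * dt
    flow_d, area_d, pres_d, pdias_d = {}, {}, {}, {}
    for i, lab in enumerate(labels):
        p_i = p_last[:, i]
        if network.diastolic_reference == "minimum":
            p_dias = float(np.min(p_i))
        else:
            p_dias = float(network.diastolic_reference)
        a0 = network.segments[i].lumen_area_diastole
        c2 = rho * network.derived[i].pwv ** 2
        area = a0 * (1.0 + (p_i - p_dias) / c2)
        if np.any(area <= 0):
            raise InstabilityError(f"non-physical (non-positive) area at {lab}")
        flow_d[lab] = flows[:, i].copy()
        area_d[lab] = area
        pres_d[lab] = p_i.copy()
        pdias_d[lab] = p_dias

    return SimulationResult(
        time=time, flow=flow_d, area=area_d, pressure=pres_d,
        periodicity_error=per_err, dt=dt, period=period, converged=converged,
        diastolic_pressure=pdias_d,
    )


def extract_curves(
    result: SimulationResult, labels: Sequence[str] | None = None
) -> dict[str, QACurveSet]:
    """Per-label :class:`QACurveSet` over the final cycle.

    The returned curve sets feed directly into the QA-loop estimator and
    the gPC machinery.
    """
    if labels is None:
        labels = result.labels
    out = {}
    for lab in labels:
        if lab not in result.flow:
            raise UnknownLabelError(
                f"cross-section {lab!r} not in result (have {result.labels})"
            )
        out[lab] = QACurveSet(
            time=result.time.copy(),
            flow=result.flow[lab].copy(),
            area=result.area[lab].copy(),
            period=result.period,
        )
    return out
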