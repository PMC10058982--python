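"""End-to-end uncertainty-quantification study.

Workflow: estimate the wall elastic modulus ``E_hat`` from a QA curve set
(or accept a literal value), place a uniform uncertainty interval
``[E_hat (1-h), E_hat (1+h)]`` around it, run one deterministic surrogate
simulation per Gauss--Legendre quadrature point, fit a separate Legendre
chaos expansion per cross-section and per quantity (flow, area), and emit
time-resolved means, standard deviations, sampled probability densities
and a coefficient-decay convergence report.

File interfaces: QA curves travel as CSV with columns ``time_s,
flow_m3_per_s, area_m2``; summaries as schema-stable CSVs plus a JSON
manifest that records everything needed to reproduce the run bit for bit
(config echo, seed, quadrature values, package version).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aorta_surrogate import (
    InflowWaveform,
    SimulationResult,
    assemble_network,
    extract_curves,
    run_cycles,
)
from .errors import ParseError, UnitSanityWarning
from .gpc_engine import (
    DEFAULT_DECAY_THRESHOLD,
    GPCExpansion,
    StochasticSummary,
    UniformParameter,
    convergence_ratios,
    estimate_pdf,
    gauss_legendre_rule,
    parameter_values_from_rule,
    project,
)
from .qa_elasticity import (
    ElasticityEstimate,
    PWVEstimate,
    QACurveSet,
    VesselGeometry,
    estimate_from_curves,
)
from .synthetic_data import (
    SyntheticSpec,
    make_fixture_config,
    make_inflow_waveform,
    synthesize_qa_curves,
)

__all__ = [
    "StudyConfig",
    "StochasticResult",
    "read_qa_csv",
    "write_qa_csv",
    "run_deterministic_batch",
    "run_uq",
    "write_summaries",
    "elasticity_report",
]

logger = logging.getLogger(__name__)

QA_COLUMNS = ("time_s", "flow_m3_per_s", "area_m2")
QUANTITIES = ("flow", "area")


@dataclass
class StudyConfig:
    """Everything a UQ study needs; exactly one modulus provenance.

    ``elastic_modulus`` (a literal E_hat in Pa), ``qa_csv`` (estimate E_hat
    from a measured curve file) and ``synthetic`` (estimate from generated
    curves) are mutually exclusive; the provenance is recorded in the
    manifest.
    """

    elastic_modulus: float | None = None
    qa_csv: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    geometry: VesselGeometry | None = None          # needed when estimating
    gamma: object = None                            # None -> chi = 1
    halfwidth_fraction: float = 0.23
    order: int = 3
    network: dict | str | Path = "aorta_default"    # config dict, preset, or YAML path
    n_cycles: int = 10
    dt: float = 0.005
    pdf_samples: int = 100_000
    pdf_bins: int = 64
    seed: int = 0
    decay_threshold: float = DEFAULT_DECAY_THRESHOLD
    out_dir: str | Path | None = None

    def resolve_network_config(self) -> dict:
        if isinstance(self.network, dict):
            return self.network
        name = str(self.network)
        if name in ("aorta_default", "stiff_aorta", "single_segment"):
            return make_fixture_config(name)
        path = Path(name)
        if not path.exists():
            raise ParseError(f"network config {name!r}: not a preset and not a file")
        with open(path) as fh:
            return yaml.safe_load(fh)


@dataclass
class StochasticResult:
    """Outputs of one UQ study."""

    e_hat: float
    e_provenance: str
    parameter: UniformParameter
    quadrature_values: np.ndarray                   # descending, Pa
    expansions: dict[tuple[str, str], GPCExpansion]
    summaries: dict[tuple[str, str], StochasticSummary]
    convergence: dict[str, list[float]]             # "label/quantity" -> max|a_r/a0|
    deterministic: list[SimulationResult]
    elasticity: ElasticityEstimate | None = None
    pwv: PWVEstimate | None = None
    manifest: dict = field(default_factory=dict)


def read_qa_csv(path) -> QACurveSet:
    """Read a QA curve file (CSV, '#' comments, SI columns).

    Raises :class:`ParseError` naming any missing column; warns when area
    values fall outside the plausible vascular range [1e-6, 1e-2] m^2.
    """
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalize to schema error
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in QA_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    q = df["flow_m3_per_s"].to_numpy(float)
    a = df["area_m2"].to_numpy(float)
    if np.any((a < 1e-6) | (a > 1e-2)):
        warnings.warn(
            f"{path}: area values outside [1e-6, 1e-2] m^2; check units",
            UnitSanityWarning,
            stacklevel=2,
        )
    # period: the sampling convention is left-endpoint over one cycle
    period = float(t[-1] + (t[-1] - t[0]) / max(len(t) - 1, 1))
    return QACurveSet(time=t, flow=q, area=a, period=period)


def write_qa_csv(curves: QACurveSet, path) -> None:
    """Write a QA curve set in the canonical CSV schema (lossless floats)."""
    df = pd.DataFrame(
        {"time_s": curves.time, "flow_m3_per_s": curves.flow, "area_m2": curves.area}
    )
    with open(path, "w") as fh:
        fh.write(f"# QA curve set, period_s={curves.period!r}\n")
        df.to_csv(fh, index=False, float_format="%.17e")


def _inflow_from_config(net_cfg: dict) -> InflowWaveform:
    inf = net_cfg.get("inflow", {})
    return make_inflow_waveform(
        period=float(inf.get("period", 1.12)),
        stroke_volume=float(inf.get("stroke_volume", 8.0e-5)),
        systolic_fraction=float(inf.get("systolic_fraction", 0.35)),
    )


def run_deterministic_batch(
    config: StudyConfig, parameter_values
) -> list[SimulationResult]:
    """One surrogate run per modulus value, identical inflow and topology.

    Results are returned in the order of ``parameter_values`` (descending
    quadrature values x1 > x2 > ... by convention).  A non-converged run
    aborts the batch, naming its index.
    """
    values = np.asarray(parameter_values, dtype=float)
    if values.ndim != 1 or len(values) < config.order + 1:
        raise ValueError("need at least order+1 parameter values")
    net_cfg = config.resolve_network_config()
    base = assemble_network(net_cfg)
    inflow = _inflow_from_config(net_cfg)
    results = []
    for i, e in enumerate(values):
        net = base.with_elastic_modulus(float(e))
        res = run_cycles(net, inflow, n_cycles=config.n_cycles, dt=config.dt,
                         warn_on_nonconvergence=False)
        if not res.converged:
            raise RuntimeError(
                f"deterministic run #{i} (E = {e:.4g} Pa) did not reach a "
                f"periodic state: periodicity error {res.periodicity_error:.2e}"
            )
        results.append(res)
    return results


def _resolve_e_hat(config: StudyConfig):
    """E_hat with provenance; estimation chain runs when no literal is given."""
    provenance_sources = [
        config.elastic_modulus is not None,
        config.qa_csv is not None,
        config.synthetic is not None,
    ]
    if sum(provenance_sources) != 1:
        raise ValueError(
            "exactly one of elastic_modulus, qa_csv, synthetic must be set"
        )
    if config.elastic_modulus is not None:
        return float(config.elastic_modulus), "literal", None, None
    if config.qa_csv is not None:
        if config.geometry is None:
            raise ValueError("geometry is required to estimate E from curves")
        curves = read_qa_csv(config.qa_csv)
        est, pwv = estimate_from_curves(curves, config.geometry, gamma=config.gamma)
        return est.elastic_modulus, f"estimated from {config.qa_csv}", est, pwv
    synth = synthesize_qa_curves(config.synthetic)
    geometry = config.geometry or config.synthetic.geometry
    est, pwv = estimate_from_curves(synth.curves, geometry, gamma=config.gamma)
    return est.elastic_modulus, "estimated from synthetic curves", est, pwv


def run_uq(config: StudyConfig) -> StochasticResult:
    """Execute the full study; optionally persist artifacts to out_dir.

    Steps: resolve E_hat, build the quadrature, run the deterministic
    batch, project per (cross-section, quantity), then summarize.  A
    coefficient-decay breach annotates the report (warning), it does not
    fail the study.
    """
    e_hat, provenance, est, pwv = _resolve_e_hat(config)
    logger.info("E_hat = %.4g Pa (%s)", e_hat, provenance)
    parameter = UniformParameter(e_hat, config.halfwidth_fraction)
    rule = gauss_legendre_rule(config.order + 1)
    values_desc = parameter_values_from_rule(rule, parameter)
    logger.info("quadrature points (Pa): %s", [f"{v:.4g}" for v in values_desc])
    results = run_deterministic_batch(config, values_desc)
    logger.info("deterministic batch done; periodicity errors: %s",
                [f"{r.periodicity_error:.1e}" for r in results])

    # model outputs per quadrature node, ascending zeta for projection
    results_asc = results[::-1]
    time = results[0].time
    expansions: dict[tuple[str, str], GPCExpansion] = {}
    summaries: dict[tuple[str, str], StochasticSummary] = {}
    convergence: dict[str, list[float]] = {}
    labels = results[0].labels
    for label in labels:
        for iq, quantity in enumerate(QUANTITIES):
            stack = np.stack(
                [getattr(r, quantity)[label] for r in results_asc], axis=0
            )
            exp = project(stack, rule, config.order)
            expansions[(label, quantity)] = exp
            # independent sub-seed per output stream, derived from the study seed
            sub_seed = (config.seed * 1000 + labels.index(label) * 10 + iq) % (2**31)
            summ = estimate_pdf(
                exp, n_samples=config.pdf_samples, seed=sub_seed,
                n_bins=config.pdf_bins, time=time,
            )
            summaries[(label, quantity)] = summ
            _, max_ratios = convergence_ratios(
                exp, threshold=config.decay_threshold, warn=True
            )
            convergence[f"{label}/{quantity}"] = [float(x) for x in max_ratios]

    manifest = {
        "package": "vesseluq",
        "version": __version__,
        "seed": config.seed,
        "e_hat_pa": e_hat,
        "e_hat_mpa": e_hat / 1e6,
        "e_provenance": provenance,
        "halfwidth_fraction": config.halfwidth_fraction,
        "order": config.order,
        "n_deterministic_runs": len(results),
        "quadrature_points_pa": [float(v) for v in values_desc],
        "quadrature_points_mpa": [round(float(v) / 1e6, 2) for v in values_desc],
        "n_cycles": config.n_cycles,
        "dt_s": config.dt,
        "pdf_samples": config.pdf_samples,
        "pdf_bins": config.pdf_bins,
        "periodicity_errors": [r.periodicity_error for r in results],
        "convergence_max_ratio_per_order": convergence,
        "decay_threshold": config.decay_threshold,
        "network": config.network if isinstance(config.network, str) else "inline dict",
    }
    out = StochasticResult(
        e_hat=e_hat,
        e_provenance=provenance,
        parameter=parameter,
        quadrature_values=values_desc,
        expansions=expansions,
        summaries=summaries,
        convergence=convergence,
        deterministic=results,
        elasticity=est,
        pwv=pwv,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_summaries(out, config.out_dir)
    return out


def write_summaries(result: StochasticResult, directory) -> list[Path]:
    """Persist summaries, PDF grids, per-run curves and the manifest.

    Layout: ``summary_{label}_{quantity}.csv`` (time_s, mean, std),
    ``pdf_{label}_{quantity}.csv`` (time_s, bin_center, density),
    ``curves_x{i}_{label}.csv`` (QA schema, one per quadrature run), and
    ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (label, quantity), summ in result.summaries.items():
        p = directory / f"summary_{label}_{quantity}.csv"
        pd.DataFrame(
            {"time_s": summ.time, "mean": summ.mean, "std": summ.std}
        ).to_csv(p, index=False, float_format="%.17e")
        written.append(p)
        grid = pd.DataFrame(
            {
                "time_s": np.repeat(summ.time, len(summ.bin_centers)),
                "bin_center": np.tile(summ.bin_centers, len(summ.time)),
                "density": summ.pdf.T.reshape(-1),
            }
        )
        p = directory / f"pdf_{label}_{quantity}.csv"
        grid.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    for i, res in enumerate(result.deterministic, start=1):
        for label, curves in extract_curves(res).items():
            p = directory / f"curves_x{i}_{label}.csv"
            write_qa_csv(curves, p)
            written.append(p)
    p = directory / "manifest.json"
    with open(p, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written


def elasticity_report(est: ElasticityEstimate, pwv: PWVEstimate) -> str:
    """Human-readable report of one modulus estimation."""
    w = pwv.window
    return "\n".join(
        [
            "QA-loop elastic-modulus estimate",
            f"  E              = {est.elastic_modulus:.6g} Pa "
            f"({est.elastic_modulus / 1e6:.2f} MPa)",
            f"  PWV            = {est.pwv:.4g} m/s (r^2 = {pwv.r_squared:.4f})",
            f"  RAC            = {est.rac:.4g}",
            f"  chi            = {est.chi:.4g} (gamma = {est.gamma:.4g})",
            f"  blood density  = {est.blood_density:.4g} kg/m^3",
            f"  fit window     = samples {w.start_index}..{w.end_index} "
            f"({w.method})",
        ]
    )
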