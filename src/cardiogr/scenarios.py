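"""Scenario execution: hypertension steps, reversal, stability classification.

A scenario starts from a prestressed, settled baseline at the systolic
baseline pressure, applies Heaviside pressure steps (each realized as a
single static re-solve between two G&R steps), and integrates the coupled
G&R/equilibrium problem until the stability classifier fires or the horizon
is reached.

Classification follows the stress-deviation criteria: a run is *stable* once
``max_i max_gp |sigma^i - sigma_h^i| / sigma_h^i <= eps`` and *unstable* when
the deviation grows for all remodeling constituents over a sustained window
of consecutive steps; anything else at the horizon is *undecided*.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import PointFields
from .gnr import GnRStepConfig, step_gnr
from .lv_model import LVModel
from .mesh import LVGeometry
from .params import MMHG, MixtureParams, human_lv_mixture
from .prestress import PrestressConfig, run_prestress

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "classify_stability",
    "measure_metrics",
    "prepare_baseline",
    "run_scenario",
    "sweep_stability_map",
    "load_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Scenario definition (pressures in mmHg, lengths in mm, times in days)."""

    model: str = "fem"  # "fem" | "reduced"
    gain_times_T: float = 0.1  # growth constant k^i T^i of all constituents
    baseline_pressure: float = 120.0
    steps: list[tuple[float, float]] = dc_field(default_factory=list)  # (day, mmHg)
    horizon: float = 2000.0
    dt: float | None = None  # day; default min(T^i)/20
    scheme: str = "forward-euler"
    eps_sigma: float = 1e-3
    instability_window: int = 10
    # FEM settings
    target_elements: int = 1500
    order: int = 1
    eps_pre_mm: float = 0.01
    prestress_ramp: int = 10
    prestress_max_iters: int = 500
    settle_steps: int = 100
    volume_weighted: bool = False
    # reduced settings
    radius_mm: float = 24.5
    thickness_mm: float = 11.0
    # material switches
    elastin_half_coefficient: bool = False
    active_reference: str = "total"
    # output
    output_dir: str | None = None
    vtu_stride: int = 0  # write VTU snapshots every n steps (0 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("fem", "reduced"):
            raise ValueError("model must be 'fem' or 'reduced'")
        times = [t for t, _ in self.steps]
        if times != sorted(times):
            raise ValueError("schedule times must be increasing")
        if self.eps_sigma <= 0:
            raise ValueError("stability threshold must be positive")

    def mixture(self) -> MixtureParams:
        return human_lv_mixture(
            gain_times_T=self.gain_times_T,
            elastin_half_coefficient=self.elastin_half_coefficient,
            active_reference=self.active_reference,
        )

    def pressure_of(self, s: float) -> float:
        """Pressure (Pa) at G&R time ``s`` (days)."""
        p = self.baseline_pressure
        for t, val in self.steps:
            if s >= t:
                p = val
        return p * MMHG

    def gnr_dt(self, mix: MixtureParams) -> float:
        return self.dt if self.dt else min(f.T_survival for f in mix.fibers) / 20.0


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "steps" in raw:
        raw["steps"] = [tuple(s) for s in raw["steps"]]
    return ScenarioConfig(**raw)


# ---------------------------------------------------------------------------
# stability classification
# ---------------------------------------------------------------------------

def classify_stability(
    deviations: np.ndarray, eps: float, *, window: int = 10
) -> tuple[str, int]:
    """Classify a deviation history, shape (n_steps, n_constituents).

    Returns ``(verdict, index)`` with the step index at which the verdict was
    reached (last index for "undecided").  The first sample is the
    post-perturbation state and may already satisfy the stable criterion.
    """
    dev = np.asarray(deviations, dtype=float)
    if dev.ndim != 2 or dev.shape[0] < 2:
        raise ValueError("need at least two samples of all constituents")
    run = 0
    for k in range(dev.shape[0]):
        if np.max(dev[k]) <= eps:
            return "stable", k
        if k > 0:
            run = run + 1 if np.all(dev[k] > dev[k - 1]) else 0
            if run >= window:
                return "unstable", k
    return "undecided", dev.shape[0] - 1


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def measure_metrics(model: LVModel, u: np.ndarray) -> dict[str, float]:
    """Mid-cavity wall thickness, endocardial diameter and cavity volume.

    Thickness is the mean distance between paired endo/epi nodes of the
    equatorial rings; the diameter is the largest in-plane endocardial chord;
    the cavity volume closes the endocardial surface with a fan over the
    basal ring.
    """
    x = model.deformed_nodes(u)
    F = model.disc.deformation_gradients(u)
    if np.any(np.linalg.det(F) <= 0):
        return {"thickness": np.nan, "diameter": np.nan, "cavity_volume": np.nan}
    rings = model.mesh.rings
    en = x[rings["equator_endo"]]
    ep = x[rings["equator_epi"]]
    thickness = float(np.linalg.norm(ep - en, axis=1).mean())
    d2 = np.sum((en[:, None, :] - en[None, :, :]) ** 2, axis=-1)
    diameter = float(np.sqrt(d2.max()))
    vol = model.surfaces["endo"].enclosed_volume(x, rings["base_endo"])
    return {"thickness": thickness, "diameter": diameter, "cavity_volume": vol}


def local_mass_change(model: LVModel) -> np.ndarray:
    """Per-Gauss-point relative referential mass change rho0(s)/rho0(0) - 1."""
    return model.fields.mass_ratio(model.mix) - 1.0


# ---------------------------------------------------------------------------
# baseline preparation (prestress + settling)
# ---------------------------------------------------------------------------

@dataclass
class Baseline:
    model: LVModel
    u: np.ndarray
    fields: PointFields
    ref_metrics: dict[str, float]
    prestress_report: object


def prepare_baseline(cfg: ScenarioConfig, *, model: LVModel | None = None) -> Baseline:
    """Prestress the LV at the baseline pressure and settle G&R for
    ``settle_steps`` steps so the constituents sit close to homeostasis."""
    mix = cfg.mixture()
    if model is None:
        model = LVModel.from_geometry(
            LVGeometry(), mix, target_elements=cfg.target_elements, order=cfg.order
        )
    p0 = cfg.baseline_pressure * MMHG
    pre = run_prestress(
        model,
        p0,
        PrestressConfig(
            eps_pre=cfg.eps_pre_mm * 1e-3,
            ramp_steps=cfg.prestress_ramp,
            max_iters=cfg.prestress_max_iters,
        ),
    )
    u = model.prestress_displacement.copy()
    gcfg = GnRStepConfig(dt=cfg.gnr_dt(mix), scheme=cfg.scheme)
    for _ in range(cfg.settle_steps):
        F = model.disc.deformation_gradients(u)
        model.fields = step_gnr(model.fields, F, model.sigma_h, mix, gcfg)
        u, rep = model.solve(p0, u0=u)
    ref_metrics = measure_metrics(model, np.zeros_like(u))  # reference mesh
    return Baseline(model, u, model.fields.copy(), ref_metrics, pre)


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    series: pd.DataFrame
    verdict: str
    stop_day: float
    ref_metrics: dict[str, float]
    config: ScenarioConfig

    def summary(self) -> dict:
        def clean(d: dict) -> dict:
            return {
                k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in d.items()
            }

        return {
            "verdict": self.verdict,
            "stop_day": self.stop_day,
            "reference": clean(self.ref_metrics),
            "final": clean(self.series.iloc[-1].to_dict()),
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(directory / "timeseries.csv", index=False)
        with open(directory / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)


def _stats(values: np.ndarray, weights: np.ndarray | None) -> tuple[float, float]:
    if weights is None:
        return float(values.mean()), float(values.std())
    w = weights / weights.sum()
    m = float((w * values).sum())
    return m, float(np.sqrt((w * (values - m) ** 2).sum()))


def run_scenario(cfg: ScenarioConfig, baseline: Baseline | None = None) -> ScenarioResult:
    """Run one pressure-step scenario and classify its stability."""
    if cfg.model == "reduced":
        return _run_reduced(cfg)
    if baseline is None:
        baseline = prepare_baseline(cfg)
    model = baseline.model
    mix = model.mix
    model.fields = baseline.fields.copy()
    u = baseline.u.copy()
    gcfg = GnRStepConfig(dt=cfg.gnr_dt(mix), scheme=cfg.scheme)
    weights = model.disc.w.ravel() if cfg.volume_weighted else None
    names = [p.name for p in mix.fibers]

    n_steps = int(round(cfg.horizon / gcfg.dt))
    rows: list[dict] = []
    devs: list[np.ndarray] = []
    p_prev = cfg.baseline_pressure * MMHG  # pre-perturbation state
    # classification starts once the last scheduled pressure change is active
    last_t = max((t for t, _ in cfg.steps), default=0.0)
    k0 = int(np.ceil(last_t / gcfg.dt))
    verdict, stop_k = "undecided", n_steps
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None

    for k in range(n_steps + 1):
        s = k * gcfg.dt
        p = cfg.pressure_of(s)
        if p != p_prev:  # Heaviside step: single static re-solve
            u, rep = model.solve(p, u0=u)
            p_prev = p
        sig, _, _ = model.constituent_stresses(u)
        dev = np.abs(sig - model.sigma_h) / model.sigma_h
        dev_max = dev.max(axis=0)
        devs.append(dev_max)
        met = measure_metrics(model, u)
        mass = model.fields.mass_ratio(mix)
        coll_frac = model.fields.rho0[:, 1:].sum(axis=1) / (
            model.fields.rho0.sum(axis=1) + model.fields.rho0_elastin
        )
        sig_m, sig_s = _stats(sig[:, 0], weights)
        cf_m, cf_s = _stats(coll_frac, weights)
        row = {
            "time": s,
            "pressure": p / MMHG,
            "sigma_myocyte_mean": sig_m,
            "sigma_myocyte_sd": sig_s,
            "collagen_fraction_mean": cf_m,
            "collagen_fraction_sd": cf_s,
            "mass_ratio_mean": float(mass.mean()),
            **met,
        }
        for c, name in enumerate(names):
            row[f"dev_{name}"] = dev_max[c]
        rows.append(row)
        if out_dir and cfg.vtu_stride and k % cfg.vtu_stride == 0:
            from .io import write_state_vtu

            write_state_vtu(model, u, out_dir / f"state_{k:05d}.vtu")
        if len(devs) >= k0 + 2:
            verdict, idx = classify_stability(
                np.array(devs[k0:]), cfg.eps_sigma, window=cfg.instability_window
            )
            if verdict != "undecided":
                stop_k = k
                break
        if k < n_steps:
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                F = model.disc.deformation_gradients(u)
                model.fields = step_gnr(model.fields, F, model.sigma_h, mix, gcfg)
                u, rep = model.solve(p, u0=u)
            if not rep.converged:
                row["solver_failure"] = True
                verdict = "undecided"
                break

    model.fields = baseline.fields  # leave the shared baseline state intact
    result = ScenarioResult(
        pd.DataFrame(rows), verdict, rows[-1]["time"], baseline.ref_metrics, cfg
    )
    if out_dir:
        result.save(out_dir)
    return result


def _run_reduced(cfg: ScenarioConfig) -> ScenarioResult:
    from .reduced import ThinWallLV, prestress_thin_wall, run_reduced_gnr

    mix = cfg.mixture()
    lv = ThinWallLV(
        mix=mix, radius=cfg.radius_mm * 1e-3, thickness=cfg.thickness_mm * 1e-3
    )
    prestress_thin_wall(lv, cfg.baseline_pressure * MMHG)
    ref = {
        "thickness": lv.thickness,
        "diameter": 2.0 * lv.radius,
        "cavity_volume": np.nan,
    }
    df = run_reduced_gnr(
        lv, cfg.pressure_of, cfg.horizon, dt=cfg.dt, scheme=cfg.scheme
    )
    dev_cols = [f"dev_{p.name}" for p in mix.fibers]
    dt = cfg.gnr_dt(mix)
    last_t = max((t for t, _ in cfg.steps), default=0.0)
    k0 = int(np.ceil(last_t / dt))
    if "elastic_failure" in df.columns or df["mass_ratio"].iloc[-1] > 4.0:
        verdict, idx = "unstable", len(df) - 1
    elif len(df) >= k0 + 2:
        verdict, idx = classify_stability(
            df[dev_cols].to_numpy()[k0:], cfg.eps_sigma, window=cfg.instability_window
        )
        idx += k0
    else:
        verdict, idx = "undecided", len(df) - 1
    df = df.iloc[: idx + 1]
    result = ScenarioResult(df, verdict, float(df["time"].iloc[-1]), ref, cfg)
    if cfg.output_dir:
        result.save(cfg.output_dir)
    return result


# ---------------------------------------------------------------------------
# stability map sweep
# ---------------------------------------------------------------------------

def sweep_stability_map(
    cfg: ScenarioConfig,
    gains: np.ndarray,
    pressures: np.ndarray,
    *,
    refine: int = 0,
    step_time: float = 0.0,
) -> pd.DataFrame:
    """Verdict per (k T, p+) grid cell, with optional bisection refinement of
    the stability boundary along the pressure axis."""
    records = []
    for g in np.asarray(gains, dtype=float):
        verdicts = {}

        def run_at(p_plus: float) -> str:
            c = copy.deepcopy(cfg)
            c.gain_times_T = float(g)
            c.steps = [(step_time, float(p_plus))]
            c.output_dir = None
            r = run_scenario(c)
            return r.verdict

        for p_plus in np.asarray(pressures, dtype=float):
            verdicts[float(p_plus)] = run_at(float(p_plus))
        # refine the boundary between the last stable and first unstable cell
        ps = sorted(verdicts)
        for _ in range(refine):
            bound = None
            for a, b in zip(ps[:-1], ps[1:]):
                if verdicts[a] == "stable" and verdicts[b] == "unstable":
                    bound = (a, b)
            if bound is None:
                break
            mid = 0.5 * (bound[0] + bound[1])
            verdicts[mid] = run_at(mid)
            ps = sorted(verdicts)
        for p_plus, v in sorted(verdicts.items()):
            records.append({"gain_times_T": float(g), "p_plus": p_plus, "verdict": v})
    return pd.DataFrame(records)
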