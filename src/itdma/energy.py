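"""Longitudinal vehicle-dynamics energy model for driving-mode comparison.

An electric car drives a fixed route at constant cruise speed, braking and
restarting at intersections.  The traction force is the classic longitudinal
balance

    F = m g f  +  delta m dv/dt  +  (rho C_D A / 2) v^2

(rolling resistance, inertia with rotating-mass factor delta, aerodynamic
drag).  Mechanical energy is accumulated as E = sum max(F, 0) v dt / eta —
motoring only, no regeneration, so braking draws no energy and the
cumulative curve jumps in slope at each restart.

Driving modes are parameterized by a damping coefficient lambda in [0, 1]
that rescales the driver's acceleration command on top of an ideal
recommended acceleration:

    a = a_ideal + (1 - lambda) * a_user.

lambda = 1 yields the economical mode (acceleration pinned to the
recommendation); smaller lambda yields a more aggressive mode with a higher
startup acceleration and energy draw.  A misclassification coupling samples
the executed mode from a detector's confusion matrix to quantify the energy
cost of imperfect brain-computer-interface mode selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VehicleParams",
    "DriveScenario",
    "EnergyTrace",
    "effective_acceleration",
    "traction_force",
    "simulate_drive",
    "energy_with_misselection",
    "load_vehicle_config",
]


@dataclass
class VehicleParams:
    """Vehicle and environment constants (SI units).

    Defaults: 1500 kg mid-size car, rolling friction 0.015, rotating-mass
    factor 1.2, air density 1.2258 kg/m^3, drag coefficient 0.3 over a 2 m^2
    frontal area, g = 9.81 m/s^2, ideal drivetrain (eta = 1).
    """

    m: float = 1500.0
    f: float = 0.015
    delta: float = 1.2
    rho: float = 1.2258
    cd: float = 0.3
    area: float = 2.0
    g: float = 9.81
    eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m", "f", "delta", "rho", "cd", "area", "g", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eta > 1:
            raise ValueError("drivetrain efficiency eta must be <= 1")


@dataclass
class DriveScenario:
    """Route kinematics: 5 km at 15 m/s with stops at 1000 m and 3000 m.

    ``lambda_`` selects the driving mode; ``a_ideal``/``a_user`` are the
    recommended and driver accelerations feeding the mode law;
    ``brake_decel_mps2`` is the (positive) deceleration magnitude at stops.
    """

    total_distance_m: float = 5000.0
    cruise_speed_mps: float = 15.0
    stop_positions_m: tuple[float, ...] = (1000.0, 3000.0)
    lambda_: float = 1.0
    a_ideal_mps2: float = 2.0
    a_user_mps2: float = 0.5
    dt_s: float = 0.01
    brake_decel_mps2: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_ <= 1:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lambda_}")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.brake_decel_mps2 <= 0:
            raise ValueError("brake_decel_mps2 must be positive")
        if self.cruise_speed_mps <= 0 or self.total_distance_m <= 0:
            raise ValueError("cruise speed and total distance must be positive")
        stops = tuple(sorted(self.stop_positions_m))
        if any(not 0 < s < self.total_distance_m for s in stops):
            raise ValueError(
                f"stops must lie strictly inside (0, {self.total_distance_m}), got {stops}"
            )
        self.stop_positions_m = stops


@dataclass
class EnergyTrace:
    """Aligned per-step sequences from a simulated drive."""

    time_s: np.ndarray
    position_m: np.ndarray
    velocity_mps: np.ndarray
    force_N: np.ndarray
    cumulative_energy_J: np.ndarray

    @property
    def total_energy_J(self) -> float:
        return float(self.cumulative_energy_J[-1])

    def save_tsv(self, path: str | Path) -> None:
        cols = np.column_stack(
            [self.time_s, self.position_m, self.velocity_mps, self.force_N,
             self.cumulative_energy_J]
        )
        np.savetxt(
            path, cols, fmt="%.6f", delimiter="\t",
            header="time_s\tposition_m\tvelocity_mps\tforce_N\tcumulative_energy_J",
        )


def effective_acceleration(lambda_: float, a_ideal: float, a_user: float) -> float:
    """Mode-dependent startup acceleration: a_ideal + (1 - lambda) * a_user."""
    if not 0 <= lambda_ <= 1:
        raise ValueError(f"lambda must lie in [0, 1], got {lambda_}")
    return a_ideal + (1.0 - lambda_) * a_user


def traction_force(v: float, dv_dt: float, params: VehicleParams) -> float:
    """Longitudinal traction force in newtons at speed v and acceleration dv_dt."""
    if v < 0:
        raise ValueError(f"velocity must be nonnegative, got {v}")
    rolling = params.m * params.g * params.f
    inertial = params.delta * params.m * dv_dt
    drag = 0.5 * params.rho * params.cd * params.area * v * v
    return rolling + inertial + drag


def simulate_drive(scenario: DriveScenario, params: VehicleParams | None = None) -> EnergyTrace:
    """Integrate the stop-and-go drive and accumulate motoring energy.

    Each segment between stops: accelerate at the mode's effective
    acceleration to cruise speed, cruise, then brake at constant
    deceleration to stop exactly at the next stop position.  The final
    segment ends at the total distance at cruise speed (no terminal
    braking).  Per-step energy is max(F, 0) * v * dt / eta.
    """
    if params is None:
        params = VehicleParams()
    a_go = effective_acceleration(
        scenario.lambda_, scenario.a_ideal_mps2, scenario.a_user_mps2
    )
    vc = scenario.cruise_speed_mps
    b = scenario.brake_decel_mps2
    dt = scenario.dt_s
    boundaries = list(scenario.stop_positions_m) + [scenario.total_distance_m]
    # reachability: accel + brake distance must fit in every segment
    prev = 0.0
    for k, end in enumerate(boundaries):
        need = vc * vc / (2 * a_go) + (vc * vc / (2 * b) if k < len(boundaries) - 1 else 0.0)
        if need > end - prev:
            raise ValueError(
                f"cruise speed {vc} m/s unreachable in segment [{prev}, {end}] m: "
                f"needs {need:.1f} m to accelerate and brake; shorten dt or "
                "inspect the scenario"
            )
        prev = end

    t_list, x_list, v_list, f_list, e_list = [0.0], [0.0], [0.0], [], []
    t, x, v, e = 0.0, 0.0, 0.0, 0.0
    f_list.append(traction_force(0.0, a_go, params))
    e_list.append(0.0)

    for k, end in enumerate(boundaries):
        final = k == len(boundaries) - 1
        brake_dist = 0.0 if final else vc * vc / (2 * b)
        while True:
            if not final and x + max(v, 0.0) ** 2 / (2 * b) >= end - 1e-9:
                a = -min(b, v / dt) if v > 0 else 0.0
            elif v < vc:
                a = min(a_go, (vc - v) / dt)
            else:
                a = 0.0
            F = traction_force(v, a, params)
            e += max(F, 0.0) * v * dt / params.eta
            x += v * dt
            if not final:
                # the car stops at the intersection; cap braking overshoot
                x = min(x, end)
            v = max(v + a * dt, 0.0)
            t += dt
            stopped = (not final) and v <= 1e-12 and x >= end - brake_dist - 1e-9
            if stopped:
                x = end
                v = 0.0
            t_list.append(t)
            x_list.append(x)
            v_list.append(v)
            f_list.append(F)
            e_list.append(e)
            if stopped:
                break
            if final and x >= end:
                break
    return EnergyTrace(
        time_s=np.asarray(t_list),
        position_m=np.asarray(x_list),
        velocity_mps=np.asarray(v_list),
        force_N=np.asarray(f_list),
        cumulative_energy_J=np.asarray(e_list),
    )


def _confusion_from(confusion, n_modes: int) -> np.ndarray:
    if np.isscalar(confusion):
        acc = float(confusion)
        if not 0 <= acc <= 1:
            raise ValueError(f"fixed accuracy must be in [0, 1], got {acc}")
        off = (1.0 - acc) / (n_modes - 1)
        mat = np.full((n_modes, n_modes), off)
        np.fill_diagonal(mat, acc)
        return mat
    mat = np.asarray(confusion, float)
    if mat.shape != (n_modes, n_modes):
        raise ValueError(f"confusion must be {n_modes}x{n_modes}, got {mat.shape}")
    if np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0):
        raise ValueError("confusion rows must be probability vectors")
    return mat


def energy_with_misselection(
    intended_mode: int,
    mode_lambdas: tuple[float, ...],
    confusion,
    scenario: DriveScenario | None = None,
    params: VehicleParams | None = None,
    n_rep: int = 300,
    seed: int | None = None,
) -> dict:
    """Energy distribution when the executed mode may differ from the intended one.

    ``intended_mode`` is 1-based into ``mode_lambdas`` (one damping
    coefficient per driving mode).  Each repetition samples the executed
    mode from the intended mode's confusion row (``confusion`` may also be a
    scalar fixed accuracy) and runs the deterministic drive under that
    mode's lambda.  Returns per-rep totals, their mean, and the executed
    mode draws; reproducible by seed.
    """
    if scenario is None:
        scenario = DriveScenario()
    n_modes = len(mode_lambdas)
    if not 1 <= intended_mode <= n_modes:
        raise ValueError(f"intended_mode {intended_mode} outside 1..{n_modes}")
    mat = _confusion_from(confusion, n_modes)
    rng = np.random.default_rng(seed)
    per_mode = np.array(
        [
            simulate_drive(replace(scenario, lambda_=lam), params).total_energy_J
            for lam in mode_lambdas
        ]
    )
    draws = rng.choice(n_modes, size=n_rep, p=mat[intended_mode - 1])
    energies = per_mode[draws]
    return {
        "energies_J": energies,
        "mean_J": float(energies.mean()),
        "executed_modes": draws + 1,
        "per_mode_J": per_mode,
    }


_CONFIG_KEYS = {
    # Table-style parameter names -> (object, attribute)
    "aideal": ("scenario", "a_ideal_mps2"),
    "auser": ("scenario", "a_user_mps2"),
    "m": ("vehicle", "m"),
    "f": ("vehicle", "f"),
    "delta": ("vehicle", "delta"),
    "cd": ("vehicle", "cd"),
    "a": ("vehicle", "area"),
    "v": ("scenario", "cruise_speed_mps"),
    "rho": ("vehicle", "rho"),
    "g": ("vehicle", "g"),
    "eta": ("vehicle", "eta"),
    "lambda": ("scenario", "lambda_"),
    "total_distance": ("scenario", "total_distance_m"),
    "dt": ("scenario", "dt_s"),
    "brake_decel": ("scenario", "brake_decel_mps2"),
}


def load_vehicle_config(path: str | Path) -> tuple[DriveScenario, VehicleParams]:
    """Parse a flat ``key = value`` config into a scenario and vehicle params.

    Keys mirror the customary symbol names (aideal, auser, m, f, delta, CD,
    A, v) plus rho, g, eta, lambda, total_distance, dt, brake_decel and
    ``stops`` (comma-separated positions in meters).  Unset keys keep their
    defaults.
    """
    sc: dict = {}
    vp: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if key == "stops":
            sc["stop_positions_m"] = tuple(
                float(s) for s in val.split(",") if s.strip()
            )
            continue
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        where, attr = _CONFIG_KEYS[key]
        (sc if where == "scenario" else vp)[attr] = float(val)
    return DriveScenario(**sc), VehicleParams(**vp)
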