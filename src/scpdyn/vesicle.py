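"""Compartmental model of vesicle-mediated membrane delivery during neurite outgrowth.

The neurite grows by adding membrane at the growth cone.  Anterograde
vesicles bud at the trans-Golgi network (TGN), each fully equipped with a
fixed complement of v-SNAREs and kinesin receptors, travel along the
microtubule scaffold (only a fraction of shaft vesicles is
microtubule-bound and moving; the rest form a reservoir), and fuse at the
growth cone.  Excess growth-cone membrane converts into shaft length.
Retrograde vesicles form by endocytosis, recover cargo from the growth
cone membrane up to per-vesicle caps, and return membrane and cargo to the
TGN by dynein transport.

Two entry points:

* :func:`simulate_outgrowth` integrates the ordinary differential
  equations numerically (deterministic, stiff-capable integrator).
* :func:`analytic_parameter_solution` solves the quasi-steady flux balance
  in closed form: given a target outgrowth velocity and a membrane
  back-transport rate it returns the total v-SNARE and kinesin-receptor
  copy numbers required at the start of a simulation, plus a feasibility
  flag.  The balance is

      anterograde membrane flux = 2*pi*radius*velocity + back transport,

  and every cargo copy consumed by budding must be returned by retrograde
  vesicles, each of which can carry at most its cap.  Below a critical
  back-transport rate the recycling loop cannot close and outgrowth at the
  requested velocity is infeasible; approaching it, required totals rise
  hyperbolically.  :func:`scan_backtransport_thresholds` maps both
  thresholds over a (velocity, back rate) grid.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

TWO_PI = 2.0 * math.pi


class IntegrationError(RuntimeError):
    """Numerical trajectory left the physical (non-negative) domain."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, geometry and literature-curated constraints.

    Units: lengths in μm, areas in μm², times in h, cargo in copies.  The
    geometric placeholders (radius, vesicle area from a ~100 nm vesicle,
    motor speeds of order 1 μm/s) set realistic magnitudes; the cargo
    caps, per-vesicle complements and maximum totals are the configurable
    curated constraints.
    """

    target_velocity: float = 10.0            # μm/h
    back_transport_rate: float = 30.0        # μm²/h membrane returned to the TGN
    membrane_synthesis_rate: float | None = None  # μm²/h; default 2*pi*r*v
    vesicle_area: float = math.pi * 0.1 ** 2  # μm² (100 nm diameter)
    snare_cap: int = 12                      # max v-SNAREs per vesicle
    kinesin_receptor_cap: int = 8            # max kinesin receptors per vesicle
    snares_per_anterograde_vesicle: int = 3
    receptors_per_anterograde_vesicle: int = 2
    kinesin_speed: float = 3600.0            # μm/h (1 μm/s)
    dynein_speed: float = 2880.0             # μm/h (0.8 μm/s)
    bound_fraction: float = 0.10             # microtubule-bound share of shaft vesicles
    neurite_radius: float = 0.5              # μm
    snare_synthesis_rate: float = 0.0        # copies/h delivered to the TGN pool
    receptor_synthesis_rate: float = 0.0
    max_snare_total: float = 25_000.0        # feasibility caps on initial totals
    max_receptor_total: float = 17_500.0
    budding_rate: float = 200.0              # 1/h, first-order on the limiting TGN resource
    fusion_rate: float = 200.0               # 1/h
    shaft_conversion_rate: float = 100.0     # 1/h, growth-cone excess membrane -> shaft
    growth_cone_rest_area: float = 50.0      # μm²
    endocytosis_km: float = 0.1              # μm², saturation scale of endocytosis
    binding_exchange_rate: float = 1.0e4     # 1/h, microtubule on/off kinetics
    initial_length: float = 1.0              # μm neurite stub after axotomy

    def __post_init__(self) -> None:
        positive = (
            "target_velocity back_transport_rate vesicle_area kinesin_speed "
            "dynein_speed neurite_radius budding_rate fusion_rate "
            "shaft_conversion_rate growth_cone_rest_area endocytosis_km "
            "binding_exchange_rate initial_length max_snare_total max_receptor_total"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.bound_fraction <= 1):
            raise ValueError("bound_fraction must be in (0, 1]")
        if self.snares_per_anterograde_vesicle > self.snare_cap:
            raise ValueError("snares per anterograde vesicle exceed the vesicle cap")
        if self.receptors_per_anterograde_vesicle > self.kinesin_receptor_cap:
            raise ValueError("receptors per anterograde vesicle exceed the vesicle cap")
        if self.snare_synthesis_rate < 0 or self.receptor_synthesis_rate < 0:
            raise ValueError("protein synthesis rates must be >= 0")

    @property
    def shaft_area_per_length(self) -> float:
        return TWO_PI * self.neurite_radius

    @property
    def effective_membrane_synthesis(self) -> float:
        if self.membrane_synthesis_rate is not None:
            return self.membrane_synthesis_rate
        return required_membrane_synthesis(
            self.target_velocity, self.back_transport_rate, self
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls(**yaml.safe_load(Path(path).read_text()))


_STATE_FIELDS = (
    "tgn_membrane",
    "anterograde_bound",
    "anterograde_reservoir",
    "anterograde_at_growth_cone",
    "retrograde_in_transit",
    "growth_cone_membrane",
    "neurite_length",
    "snare_tgn",
    "receptor_tgn",
    "snare_growth_cone",
    "receptor_growth_cone",
    "snare_retrograde",
    "receptor_retrograde",
)


@dataclass(frozen=True)
class ModelState:
    """Compartment contents at one instant (areas in μm², cargo in copies)."""

    tgn_membrane: float
    anterograde_bound: float
    anterograde_reservoir: float
    anterograde_at_growth_cone: float
    retrograde_in_transit: float
    growth_cone_membrane: float
    neurite_length: float
    snare_tgn: float
    receptor_tgn: float
    snare_growth_cone: float
    receptor_growth_cone: float
    snare_retrograde: float
    receptor_retrograde: float

    def __post_init__(self) -> None:
        for name in _STATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "ModelState":
        return cls(**{f: max(float(v), 0.0) for f, v in zip(_STATE_FIELDS, y)})

    def snare_total(self, params: ModelParameters) -> float:
        n = params.snares_per_anterograde_vesicle
        in_transit = self.anterograde_bound + self.anterograde_reservoir + self.anterograde_at_growth_cone
        return self.snare_tgn + n * in_transit + self.snare_growth_cone + self.snare_retrograde

    def receptor_total(self, params: ModelParameters) -> float:
        n = params.receptors_per_anterograde_vesicle
        in_transit = self.anterograde_bound + self.anterograde_reservoir + self.anterograde_at_growth_cone
        return self.receptor_tgn + n * in_transit + self.receptor_growth_cone + self.receptor_retrograde

    def membrane_total(self, params: ModelParameters) -> float:
        vesicles = (
            self.anterograde_bound
            + self.anterograde_reservoir
            + self.anterograde_at_growth_cone
            + self.retrograde_in_transit
        )
        return (
            self.tgn_membrane
            + params.vesicle_area * vesicles
            + self.growth_cone_membrane
            + params.shaft_area_per_length * self.neurite_length
        )


@dataclass(frozen=True)
class FeasibilitySolution:
    """Closed-form cargo requirement for one (velocity, back rate) pair."""

    target_velocity: float
    back_transport_rate: float
    required_snare_total: float
    required_receptor_total: float
    feasible: bool
    violation: str | None = None           # "negative_parameter" | "exceeds_max"
    detail: str | None = None
    required_snare_synthesis: float = 0.0  # copies/h covering the neurite sink
    required_receptor_synthesis: float = 0.0
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feasible and self.violation is None:
            raise ValueError("infeasible solutions must carry a violation reason")


def required_membrane_synthesis(
    target_velocity: float, back_transport_rate: float, params: ModelParameters
) -> float:
    """Membrane synthesis rate sustaining growth at the target velocity.

    Beyond the shaft demand 2*pi*r*v, synthesis must cover the vesicle
    membrane resident in transit: the lengthening shaft holds ever more
    anterograde (bound + reservoir) and retrograde vesicles, a sink
    proportional to the growth velocity.
    """
    p = params
    demand = p.shaft_area_per_length * target_velocity
    flux_a = (demand + back_transport_rate) / p.vesicle_area
    flux_r = back_transport_rate / p.vesicle_area
    sink = p.vesicle_area * target_velocity * (
        flux_a / (p.kinesin_speed * p.bound_fraction) + flux_r / p.dynein_speed
    )
    return demand + sink


def analytic_parameter_solution(
    target_velocity: float,
    back_transport_rate: float,
    params: ModelParameters,
) -> FeasibilitySolution:
    """Quasi-steady flux balance: required cargo totals at simulation start.

    Anterograde vesicle flux J_A = (2*pi*r*v + Q_back) / a_v must carry
    n copies of each cargo species per vesicle; retrograde flux
    J_R = Q_back / a_v must return them, at most ``cap`` per vesicle, so
    closing the recycling loop requires per-retro-vesicle capture
    n * J_A / J_R <= cap.  Protein synthesis covers only the neurite sink
    (pools residing in the lengthening shaft).  Totals are evaluated at
    the initial length; infeasibility is a return value, never an error.
    """
    p = params
    v = target_velocity
    qb = back_transport_rate
    if v <= 0:
        return FeasibilitySolution(v, qb, 0.0, 0.0, False, "negative_parameter",
                                   "target velocity must be > 0")
    if qb < 0:
        return FeasibilitySolution(v, qb, 0.0, 0.0, False, "negative_parameter",
                                   "back transport rate must be >= 0")

    demand = p.shaft_area_per_length * v          # μm²/h into the shaft
    flux_a = (demand + qb) / p.vesicle_area       # anterograde vesicles/h
    flux_r = qb / p.vesicle_area                  # retrograde vesicles/h
    gc_area = p.growth_cone_rest_area + demand / p.shaft_conversion_rate
    length = p.initial_length

    species = {
        "snare": (p.snares_per_anterograde_vesicle, p.snare_cap, p.max_snare_total),
        "receptor": (p.receptors_per_anterograde_vesicle, p.kinesin_receptor_cap,
                     p.max_receptor_total),
    }
    totals: dict[str, float] = {}
    synthesis: dict[str, float] = {}
    breakdown: dict[str, float] = {
        "anterograde_flux": flux_a,
        "retrograde_flux": flux_r,
        "growth_cone_area": gc_area,
        "shaft_demand": demand,
    }
    violation = detail = None
    for name, (per_vesicle, cap, max_total) in species.items():
        if flux_r <= 0:
            capture = math.inf
        else:
            capture = per_vesicle * flux_a / flux_r  # copies per retrograde vesicle
        breakdown[f"{name}_per_retro_vesicle"] = capture
        if capture > cap and violation is None:
            violation = "exceeds_max"
            detail = (
                f"recycling needs {capture:.2f} {name}s per retrograde vesicle, "
                f"above the per-vesicle cap of {cap}"
            )
        n_antero = flux_a * length / (p.kinesin_speed * p.bound_fraction)  # shaft, incl. reservoir
        n_queue = flux_a / p.fusion_rate
        n_retro = flux_r * length / p.dynein_speed
        pool_tgn = per_vesicle * flux_a / p.budding_rate
        pool_gc = min(capture, cap) * gc_area / p.vesicle_area
        pool_retro = min(capture, cap) * n_retro
        total = pool_tgn + per_vesicle * (n_antero + n_queue) + pool_gc + pool_retro
        totals[name] = total
        synthesis[name] = v * per_vesicle * flux_a * (
            1.0 / (p.kinesin_speed * p.bound_fraction) + 1.0 / p.dynein_speed
        )
        breakdown[f"{name}_tgn_pool"] = pool_tgn
        breakdown[f"{name}_growth_cone_pool"] = pool_gc
        if total < 0 and violation is None:
            violation = "negative_parameter"
            detail = f"required {name} total is negative"
        if total > max_total and violation is None:
            violation = "exceeds_max"
            detail = f"required {name} total {total:.0f} exceeds the maximum of {max_total:.0f}"

    return FeasibilitySolution(
        target_velocity=v,
        back_transport_rate=qb,
        required_snare_total=totals["snare"],
        required_receptor_total=totals["receptor"],
        feasible=violation is None,
        violation=violation,
        detail=detail,
        required_snare_synthesis=synthesis["snare"],
        required_receptor_synthesis=synthesis["receptor"],
        breakdown=breakdown,
    )


def initial_state_from_solution(
    solution: FeasibilitySolution, params: ModelParameters
) -> ModelState:
    """Quasi-steady initial compartment contents implied by the analytic solution."""
    p = params
    b = solution.breakdown
    flux_a, flux_r = b["anterograde_flux"], b["retrograde_flux"]
    length = p.initial_length
    n_bound = flux_a * length / p.kinesin_speed
    n_res = n_bound * (1 - p.bound_fraction) / p.bound_fraction
    n_retro = flux_r * length / p.dynein_speed
    cap_s = min(b["snare_per_retro_vesicle"], p.snare_cap)
    cap_r = min(b["receptor_per_retro_vesicle"], p.kinesin_receptor_cap)
    return ModelState(
        tgn_membrane=flux_a * p.vesicle_area / p.budding_rate,
        anterograde_bound=n_bound,
        anterograde_reservoir=n_res,
        anterograde_at_growth_cone=flux_a / p.fusion_rate,
        retrograde_in_transit=n_retro,
        growth_cone_membrane=b["growth_cone_area"],
        neurite_length=length,
        snare_tgn=b["snare_tgn_pool"],
        receptor_tgn=b["receptor_tgn_pool"],
        snare_growth_cone=b["snare_growth_cone_pool"],
        receptor_growth_cone=b["receptor_growth_cone_pool"],
        snare_retrograde=cap_s * n_retro,
        receptor_retrograde=cap_r * n_retro,
    )


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course with per-time derived quantities."""

    times: np.ndarray
    states: list[ModelState]
    frame: pd.DataFrame

    @property
    def final(self) -> ModelState:
        return self.states[-1]


def _rhs(t: float, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    (m_tgn, a_b, a_r, a_gc, r_tr, m_gc, length,
     s_tgn, k_tgn, s_gc, k_gc, s_ret, k_ret) = np.maximum(y, 0.0)
    n_s = p.snares_per_anterograde_vesicle
    n_r = p.receptors_per_anterograde_vesicle
    a_v = p.vesicle_area
    length = max(length, 1e-6)

    # budding: first-order on the scarcest TGN resource; every vesicle fully equipped
    bud = p.budding_rate * min(m_tgn / a_v, s_tgn / n_s, k_tgn / n_r)
    k_on = p.bound_fraction * p.binding_exchange_rate
    k_off = (1.0 - p.bound_fraction) * p.binding_exchange_rate
    bind = k_on * a_r
    unbind = k_off * a_b
    arrive_a = p.kinesin_speed / length * a_b
    fuse = p.fusion_rate * a_gc
    endo = (p.back_transport_rate / a_v) * m_gc / (m_gc + p.endocytosis_km)
    # retrograde vesicles capture membrane-density-proportional cargo up to the cap
    s_capture = min(p.snare_cap, a_v * s_gc / max(m_gc, 1e-9))
    k_capture = min(p.kinesin_receptor_cap, a_v * k_gc / max(m_gc, 1e-9))
    arrive_r = p.dynein_speed / length * r_tr
    s_return = p.dynein_speed / length * s_ret
    k_return = p.dynein_speed / length * k_ret
    # one-way conversion: excess growth-cone membrane extends the shaft, but
    # the shaft never resorbs back into the growth cone
    dlength = (
        p.shaft_conversion_rate
        * max(m_gc - p.growth_cone_rest_area, 0.0)
        / p.shaft_area_per_length
    )

    return np.array([
        p.effective_membrane_synthesis + a_v * arrive_r - a_v * bud,   # TGN membrane
        bind - unbind - arrive_a,                                      # bound anterograde
        bud - bind + unbind,                                           # reservoir
        arrive_a - fuse,                                               # at growth cone
        endo - arrive_r,                                               # retrograde in transit
        a_v * fuse - a_v * endo - p.shaft_area_per_length * dlength,   # growth cone membrane
        dlength,                                                       # neurite length
        p.snare_synthesis_rate + s_return - n_s * bud,                 # SNAREs at TGN
        p.receptor_synthesis_rate + k_return - n_r * bud,              # receptors at TGN
        n_s * fuse - endo * s_capture,                                 # SNAREs at growth cone
        n_r * fuse - endo * k_capture,                                 # receptors at growth cone
        endo * s_capture - s_return,                                   # SNAREs on retro vesicles
        endo * k_capture - k_return,                                   # receptors on retro vesicles
    ])


def simulate_outgrowth(
    params: ModelParameters,
    initial: ModelState | None = None,
    duration: float = 48.0,
    n_output: int = 97,
    rtol: float = 1e-8,
    negative_tolerance: float = 1e-6,
) -> Trajectory:
    """Integrate the outgrowth ODEs for ``duration`` hours.

    Without an explicit initial state, the quasi-steady state of the
    analytic solution at the parameters' target velocity and back rate is
    used.  Raises :class:`IntegrationError` if any compartment goes
    negative beyond ``negative_tolerance`` (relative to its scale).
    """
    if initial is None:
        sol = analytic_parameter_solution(
            params.target_velocity, params.back_transport_rate, params
        )
        initial = initial_state_from_solution(sol, params)
    times = np.linspace(0.0, duration, n_output)
    result = solve_ivp(
        _rhs,
        (0.0, duration),
        initial.to_vector(),
        t_eval=times,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=1e-10,
    )
    if not result.success:
        raise IntegrationError(f"integration failed: {result.message}")
    scale = np.maximum(np.abs(result.y).max(axis=1), 1.0)
    worst = (result.y / scale[:, None]).min(axis=1)
    if np.any(worst < -negative_tolerance):
        name = _STATE_FIELDS[int(np.argmin(worst))]
        raise IntegrationError(f"compartment {name!r} went negative during integration")

    states = [ModelState.from_vector(result.y[:, i]) for i in range(result.y.shape[1])]
    rows = []
    for t, st in zip(times, states):
        shaft_total = st.anterograde_bound + st.anterograde_reservoir
        rows.append({
            "time": t,
            **{f: getattr(st, f) for f in _STATE_FIELDS},
            "velocity": params.shaft_conversion_rate
            * max(st.growth_cone_membrane - params.growth_cone_rest_area, 0.0)
            / params.shaft_area_per_length,
            "bound_fraction": st.anterograde_bound / shaft_total if shaft_total > 0 else math.nan,
            "membrane_total": st.membrane_total(params),
            "snare_total": st.snare_total(params),
            "receptor_total": st.receptor_total(params),
        })
    return Trajectory(times=times, states=states, frame=pd.DataFrame(rows))


@dataclass(frozen=True)
class ThresholdScan:
    """Requirement surfaces plus per-velocity threshold curves."""

    surface: pd.DataFrame
    thresholds: pd.DataFrame
    metadata: dict[str, object]


def scan_backtransport_thresholds(
    velocities: Sequence[float],
    back_rates: Sequence[float],
    params: ModelParameters,
    rapid_factor: float = 2.0,
) -> ThresholdScan:
    """Evaluate the analytic solution over a (velocity, back rate) grid.

    Per velocity, ``threshold_stall`` is the smallest scanned back rate
    with a feasible solution, and ``threshold_rapid_increase`` the
    smallest back rate at which the required total stays within
    ``rapid_factor`` times its value at the largest scanned back rate
    (the large-back-rate asymptote).  Infeasible grid cells appear in the
    surface with NaN totals — the feasibility edge of the requirement wall.
    """
    velocities = sorted(set(float(v) for v in velocities))
    back_rates = sorted(set(float(q) for q in back_rates))
    if not velocities or not back_rates:
        raise ValueError("velocity and back-rate grids must be non-empty")
    rows = []
    thresholds = []
    for v in velocities:
        solutions = [analytic_parameter_solution(v, qb, params) for qb in back_rates]
        for qb, sol in zip(back_rates, solutions):
            rows.append({
                "velocity": v,
                "back_rate": qb,
                "feasible": sol.feasible,
                "snare_total": sol.required_snare_total if sol.feasible else math.nan,
                "receptor_total": sol.required_receptor_total if sol.feasible else math.nan,
                "violation": sol.violation or "",
            })
        feasible = [(qb, s) for qb, s in zip(back_rates, solutions) if s.feasible]
        entry: dict[str, float] = {"velocity": v}
        if feasible:
            entry["threshold_stall"] = feasible[0][0]
            asym_s = feasible[-1][1].required_snare_total
            asym_r = feasible[-1][1].required_receptor_total
            rapid_s = [qb for qb, s in feasible if s.required_snare_total <= rapid_factor * asym_s]
            rapid_r = [qb for qb, s in feasible if s.required_receptor_total <= rapid_factor * asym_r]
            entry["threshold_rapid_increase"] = min(rapid_s) if rapid_s else math.nan
            entry["threshold_rapid_increase_receptor"] = min(rapid_r) if rapid_r else math.nan
        else:
            entry["threshold_stall"] = math.nan
            entry["threshold_rapid_increase"] = math.nan
            entry["threshold_rapid_increase_receptor"] = math.nan
        thresholds.append(entry)
    metadata = {
        "rapid_increase_definition": (
            f"smallest back rate where the required total is <= {rapid_factor}x "
            "its value at the largest scanned back rate"
        ),
        "rapid_factor": rapid_factor,
        "grid_velocities": velocities,
        "grid_back_rates": back_rates,
    }
    return ThresholdScan(
        surface=pd.DataFrame(rows),
        thresholds=pd.DataFrame(thresholds),
        metadata=metadata,
    )
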