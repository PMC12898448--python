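"""Temperature extrapolation, literature comparison, and run summaries.

Elevated-temperature permeabilities are extrapolated to physiological
temperature by ordinary least squares on the Arrhenius axes (ln P vs 1/T); the
literature comparison picks, per molecule, the published value closest to the
effective permeability and reports |P_eff - P_lit| / P_lit.  ``summarize``
assembles the per-molecule report row mirroring the published summary tables.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .free_energy import BarrierFit
from .kinetics import ReplicaPermeability, SteadyState


@dataclass
class ExtrapolationResult:
    """Arrhenius fit of ln P against 1/T and its evaluation at a target T."""

    target_temperature: float
    p_cm_s: float
    slope: float  # d(ln P)/d(1/T), in K
    intercept: float
    p_se_cm_s: Optional[float] = None
    temperatures: Tuple[float, ...] = ()
    residuals: Tuple[float, ...] = ()


def arrhenius_extrapolate(temperatures: Sequence[float], p_values: Sequence[float],
                          target_temperature: float = 310.0) -> ExtrapolationResult:
    """Least-squares linear fit of ln P vs 1/T, evaluated at the target T.

    Requires >= 2 distinct temperatures and strictly positive permeabilities;
    with exactly two points the fit interpolates them exactly.  The first-order
    (delta-method) standard error from the fit covariance is attached when
    there are more than two points.
    """
    t = np.asarray(temperatures, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if t.size != p.size or t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need permeabilities at >= 2 distinct temperatures")
    if np.any(p <= 0):
        raise ValueError("all permeabilities must be positive for the log fit")
    x = 1.0 / t
    y = np.log(p)
    if t.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        cov = None
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    x0 = 1.0 / target_temperature
    ln_p = intercept + slope * x0
    p0 = float(np.exp(ln_p))
    se = None
    if cov is not None:
        v = np.array([x0, 1.0])
        se = float(p0 * np.sqrt(v @ cov @ v))
    resid = tuple(float(r) for r in (y - (intercept + slope * x)))
    return ExtrapolationResult(float(target_temperature), p0, float(slope),
                               float(intercept), se, tuple(t), resid)


@dataclass
class LiteratureComparison:
    """Relative error of P_eff against the nearest published value."""

    p_eff: float
    p_lit: Optional[float]
    provenance: Optional[str]
    relative_error: Optional[float]
    candidates: Tuple[Tuple[float, str], ...] = ()

    @property
    def has_literature(self) -> bool:
        return self.p_lit is not None


def relative_error(p_eff: float,
                   candidates: Sequence[Tuple[float, str]]) -> LiteratureComparison:
    """Pick the literature candidate nearest to p_eff; report |P_eff - P_lit|/P_lit.

    An empty candidate list yields a comparison marked "no literature value"
    rather than an error.  Scale-invariant: rescaling p_eff and all candidates
    by the same positive factor leaves the result unchanged.
    """
    cands = [(float(v), str(src)) for v, src in candidates]
    if not cands:
        return LiteratureComparison(float(p_eff), None, "no literature value", None)
    if any(v <= 0 for v, _ in cands):
        raise ValueError("literature candidates must be positive")
    best_v, best_src = min(cands, key=lambda c: abs(p_eff - c[0]))
    return LiteratureComparison(float(p_eff), best_v, best_src,
                                abs(p_eff - best_v) / best_v, tuple(cands))


def summarize(molecule: str,
              permeability: Optional[ReplicaPermeability] = None,
              steady_state: Optional[SteadyState] = None,
              extrapolation: Optional[ExtrapolationResult] = None,
              comparison: Optional[LiteratureComparison] = None,
              barrier: Optional[BarrierFit] = None,
              n_events: Optional[int] = None,
              config: Optional[dict] = None) -> dict:
    """One report row per molecule; missing stages are reported as nulls.

    A run with no detected steady state carries a null effective permeability
    and the flag ``no_passive_steady_state`` - the elevated-temperature
    approach then implies the molecule does not cross by passive diffusion.
    """
    # only flag a missing steady state when kinetics were actually run
    no_steady = steady_state is None and (permeability is not None or
                                          n_events is not None)
    row = {
        "molecule": molecule,
        "p_sim_cm_s": None if permeability is None else permeability.mean_cm_s,
        "p_sim_sd_cm_s": None if permeability is None else permeability.sd_cm_s,
        "temperature_K": None if permeability is None else permeability.temperature,
        "t_steady_state_ns": None if no_steady else steady_state.t_ss,
        "k_ss_per_ns": None if no_steady else steady_state.k_ss,
        "no_passive_steady_state": bool(no_steady),
        "n_events": n_events,
        "p_eff_cm_s": (None if (no_steady or extrapolation is None)
                       else extrapolation.p_cm_s),
        "p_lit_cm_s": None if comparison is None else comparison.p_lit,
        "relative_error": None if comparison is None else comparison.relative_error,
        "dg_barrier_kcal_mol": None if barrier is None else barrier.barrier_height,
        "sigma_nm": None if barrier is None else barrier.width,
        "sigma_ci": None if barrier is None else barrier.ci,
        "config": config or {},
    }
    return row


def write_report(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(list(rows), fh, indent=2, default=float)
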