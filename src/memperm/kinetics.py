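"""Translocation-event detection, rate constants, and permeability.

A completed crossing requires full dissociation from the bilayer: a molecule
must pass from the bulk on one side of the membrane (beyond the phosphate plane
plus a dissociation margin) to the bulk on the other side.  Excursions that
linger at or below the phosphates and return to the same side add no event.

The implementation works on the *unwrapped* membrane-normal coordinate: bulk
regions between periodic membrane images are labelled with an integer zone
index, and an event is a change of that index.  Walking through the periodic
box boundary keeps the index constant, so boundary passages can never be
mistaken for membrane crossings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .constants import AVOGADRO, NM_PER_NS_TO_CM_PER_S
from .geometry import MembraneFrameSeries, ZSeries


@dataclass(frozen=True)
class CrossingEvent:
    """One completed bilayer translocation."""

    molecule_id: object
    t_entry: float
    t_exit: float
    direction: str  # "down" | "up"

    def __post_init__(self):
        if self.t_exit <= self.t_entry:
            raise ValueError("t_exit must follow t_entry")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")


def _planes(membrane, n_frames) -> Tuple[np.ndarray, np.ndarray]:
    """Midplane-referenced (lower, upper) plane arrays from a frame series or pair."""
    if isinstance(membrane, MembraneFrameSeries):
        mid = membrane.midplane
        return membrane.lower - mid, membrane.upper - mid
    lo, up = membrane
    return np.full(n_frames, float(lo)), np.full(n_frames, float(up))


def detect_crossings(z: ZSeries,
                     membrane: Union[MembraneFrameSeries, Tuple[float, float]],
                     dissociation_margin: float = 0.5) -> List[CrossingEvent]:
    """Detect completed translocations under the dissociation rule.

    Per molecule, each sample is classified as dissociated above a membrane
    image, dissociated below it, or membrane-associated; dissociation means
    strictly beyond plane + margin.  An event is recorded only on a transition
    between the bulk zones flanking a membrane image; its entry time is the
    last dissociated sample before the transit.
    """
    if dissociation_margin < 0:
        raise ValueError("margin must be non-negative")
    n_frames = z.time.shape[0]
    lower, upper = _planes(membrane, n_frames)
    if lower.shape[0] != n_frames:
        raise ValueError("z and membrane series must share the time grid")

    L = z.box_z
    eta = z.eta  # unwrapped, midplane-referenced
    image = np.round(eta / L)
    local = eta - image * L
    # bulk-zone index: zone m lies between membrane image m and image m+1
    bulk = np.where(local > upper[:, None] + dissociation_margin, image,
                    np.where(local < lower[:, None] - dissociation_margin,
                             image - 1, np.nan))

    events: List[CrossingEvent] = []
    for j, mol in enumerate(z.ids):
        idx = np.flatnonzero(~np.isnan(bulk[:, j]))
        if idx.size < 2:
            continue
        zones = bulk[idx, j]
        change = np.flatnonzero(np.diff(zones) != 0)
        for k in change:
            step = zones[k + 1] - zones[k]
            direction = "up" if step > 0 else "down"
            events.append(CrossingEvent(mol, float(z.time[idx[k]]),
                                        float(z.time[idx[k + 1]]), direction))
    events.sort(key=lambda e: (e.t_exit, e.t_entry))
    return events


def events_to_dataframe(events: Sequence[CrossingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"molecule_id": e.molecule_id, "t_entry_ns": e.t_entry,
          "t_exit_ns": e.t_exit, "direction": e.direction} for e in events],
        columns=["molecule_id", "t_entry_ns", "t_exit_ns", "direction"])


# ---------------------------------------------------------------------------
# rate series and steady state
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Cumulative crossing count N(t) and rate constant k(t) = N(t)/t on a grid."""

    time: np.ndarray
    counts: np.ndarray
    total_time: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.time <= 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be positive and strictly increasing")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("N(t) must be non-decreasing")

    @property
    def k(self) -> np.ndarray:
        """Rate constant k(t) = N(t)/t in ns^-1."""
        return self.counts / self.time

    @property
    def r(self) -> np.ndarray:
        """Molar rate constant r(t) = k(t)/N_A in mol/ns."""
        return self.k / AVOGADRO


def rate_constant_series(events: Sequence[CrossingEvent], total_time: float,
                         time_grid: Optional[np.ndarray] = None,
                         n_points: int = 200) -> RateSeries:
    """Build k(t) = N(t)/t; an event counts once its exit time has passed."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if time_grid is None:
        time_grid = np.linspace(total_time / n_points, total_time, n_points)
    time_grid = np.asarray(time_grid, dtype=float)
    exits = np.sort([e.t_exit for e in events])
    counts = np.searchsorted(exits, time_grid, side="right")
    return RateSeries(time_grid, counts, float(total_time))


@dataclass(frozen=True)
class SteadyState:
    t_ss: float
    k_ss: float
    r_ss: float
    window: Tuple[float, float]


def detect_steady_state(series: RateSeries, tolerance: float = 0.05,
                        min_window: Optional[float] = None) -> Optional[SteadyState]:
    """Earliest t_ss with k(t) within +-tolerance of the window mean thereafter.

    The window mean is taken over [t_ss, t_end]; windows shorter than
    ``min_window`` (default 20% of the trajectory) are not considered.  Returns
    None when no steady state exists - a valid, reportable outcome indicating
    the molecule does not passively diffuse at a measurable rate.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if min_window is None:
        min_window = 0.2 * series.total_time
    t, k = series.time, series.k
    t_end = t[-1]
    for i in range(t.size):
        if t_end - t[i] < min_window:
            break
        window = k[i:]
        mean = window.mean()
        if mean == 0:
            ok = np.all(window == 0)
        else:
            ok = np.all(np.abs(window / mean - 1.0) <= tolerance)
        if ok:
            return SteadyState(float(t[i]), float(mean), float(mean / AVOGADRO),
                               (float(t[i]), float(t_end)))
    return None


# ---------------------------------------------------------------------------
# permeability
# ---------------------------------------------------------------------------

@dataclass
class PermeabilityEstimate:
    """Crossing-count permeability P = k_ss / (2 A C) at the simulation temperature.

    The factor 2 accounts for the bidirectional nature of the equilibrium flux
    (both up- and down-crossings are counted).  A is the membrane patch area
    (nm^2), C the solute number concentration (molecules/nm^3); in these units
    P comes out in nm/ns and is stored in cm/s.
    """

    p_cm_s: float
    k_ss: float
    area: float
    concentration: float
    temperature: float
    n_events: Optional[int] = None
    total_time: Optional[float] = None

    def __post_init__(self):
        if self.p_cm_s < 0:
            raise ValueError("permeability must be non-negative")


def number_concentration(n_molecules: int, box_volume: float) -> float:
    """Solute number concentration over the total box volume (molecules/nm^3)."""
    if box_volume <= 0:
        raise ValueError("box volume must be positive")
    return n_molecules / box_volume


def compute_permeability(k_ss: float, area: float, concentration: float,
                         temperature: float = 440.0,
                         n_events: Optional[int] = None,
                         total_time: Optional[float] = None) -> PermeabilityEstimate:
    """Convert a steady-state crossing rate constant (ns^-1) to cm/s."""
    if area <= 0 or concentration <= 0:
        raise ValueError("area and concentration must be positive")
    if k_ss < 0:
        raise ValueError("k_ss must be non-negative")
    p_nm_ns = k_ss / (2.0 * area * concentration)
    return PermeabilityEstimate(p_nm_ns * NM_PER_NS_TO_CM_PER_S, k_ss, area,
                                concentration, temperature, n_events, total_time)


@dataclass
class ReplicaPermeability:
    """Mean +- sample SD over replicas, plus the pooled-count estimate."""

    mean_cm_s: float
    sd_cm_s: float
    pooled_cm_s: Optional[float]
    temperature: float
    replicas: List[PermeabilityEstimate] = field(default_factory=list)

    @property
    def sem_cm_s(self) -> float:
        return self.sd_cm_s / np.sqrt(len(self.replicas))


def aggregate_replicas(estimates: Sequence[PermeabilityEstimate]) -> ReplicaPermeability:
    """Average independent replica estimates (>=2 for a spread, equal T).

    When every replica records its event count and duration, a pooled estimate
    from total events over total time is reported as well; for equal-length
    replicas it coincides with the replica mean.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two replicas for a spread")
    temps = {e.temperature for e in estimates}
    if len(temps) > 1:
        raise ValueError(f"mixed replica temperatures: {sorted(temps)}")
    values = np.array([e.p_cm_s for e in estimates])
    pooled = None
    if all(e.n_events is not None and e.total_time for e in estimates):
        k_pool = sum(e.n_events for e in estimates) / sum(e.total_time for e in estimates)
        a, c = estimates[0].area, estimates[0].concentration
        pooled = compute_permeability(k_pool, a, c, estimates[0].temperature).p_cm_s
    return ReplicaPermeability(float(values.mean()), float(values.std(ddof=1)),
                               pooled, temps.pop(), list(estimates))
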