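"""Trajectory readers and membrane-frame geometry.

Reads topology+trajectory pairs through MDAnalysis, establishes the membrane
frame (per-leaflet phosphate planes and their midplane), extracts per-solute
membrane-normal tracks eta(t) referenced to the midplane, and computes the
standard bilayer descriptors (area per lipid, phosphate-phosphate thickness).

The membrane normal is taken as the box z axis (planar patch).  Coordinates are
converted to nm and times to ns at the reader boundary regardless of the source
format's native units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM_PER_NM, PS_PER_NS


# ---------------------------------------------------------------------------
# periodic helpers
# ---------------------------------------------------------------------------

def wrap_coordinate(x, box_z):
    """Wrap coordinate(s) into [-box_z/2, box_z/2)."""
    x = np.asarray(x, dtype=float)
    return x - box_z * np.round(x / box_z)


def unwrap_series(eta_wrapped, box_z):
    """Remove periodic jumps from a wrapped time series (first axis = time).

    The reconstruction is exact provided per-step displacements are below half
    the box, so membrane crossings remain distinguishable from box-boundary
    crossings.  ``wrap_coordinate(unwrap_series(x), box_z) == x``.
    """
    eta = np.asarray(eta_wrapped, dtype=float)
    d = np.diff(eta, axis=0)
    d -= box_z * np.round(d / box_z)
    out = np.empty_like(eta)
    out[0] = eta[0]
    out[1:] = eta[0] + np.cumsum(d, axis=0)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MembraneFrameSeries:
    """Per-frame membrane frame: leaflet phosphate planes and midplane (nm, ns)."""

    time: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    box_x: np.ndarray
    box_y: np.ndarray

    def __post_init__(self):
        for name in ("time", "upper", "lower", "box_x", "box_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.time) <= 0) and self.time.size > 1:
            raise ValueError("time must be strictly increasing")
        if np.any(self.upper <= self.lower):
            raise ValueError("upper phosphate plane must lie above the lower plane")

    @property
    def midplane(self) -> np.ndarray:
        return 0.5 * (self.upper + self.lower)

    @property
    def thickness(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def constant(cls, time, upper, lower, box_x=5.0, box_y=5.0) -> "MembraneFrameSeries":
        """Static membrane frame, e.g. for synthetic Langevin trajectories."""
        t = np.asarray(time, dtype=float)
        ones = np.ones_like(t)
        return cls(t, upper * ones, lower * ones, box_x * ones, box_y * ones)


@dataclass
class ZSeries:
    """Per-molecule membrane-normal track eta(t), midplane-referenced and unwrapped.

    ``eta`` has shape (n_frames, n_molecules) and is continuous across the
    periodic boundary; :meth:`wrapped` folds it back into the box.
    """

    time: np.ndarray
    eta: np.ndarray
    ids: List
    box_z: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.eta = np.atleast_2d(np.asarray(self.eta, dtype=float))
        if self.eta.shape[0] != self.time.shape[0]:
            self.eta = self.eta.T
        if self.eta.shape[0] != self.time.shape[0]:
            raise ValueError("eta first axis must match time")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(self.ids) != self.eta.shape[1]:
            raise ValueError("one id per molecule required")
        if self.box_z <= 0:
            raise ValueError("box_z must be positive")

    @property
    def n_molecules(self) -> int:
        return self.eta.shape[1]

    def wrapped(self) -> np.ndarray:
        return wrap_coordinate(self.eta, self.box_z)


# ---------------------------------------------------------------------------
# system reader
# ---------------------------------------------------------------------------

class SelectionError(ValueError):
    pass


@dataclass
class SystemReader:
    """An MDAnalysis universe plus validated solute/lipid selections."""

    universe: "object"
    solute_selection: str
    lipid_selection: str
    solute_atoms: "object" = field(init=False)
    lipid_atoms: "object" = field(init=False)

    def __post_init__(self):
        self.solute_atoms = self.universe.select_atoms(self.solute_selection)
        self.lipid_atoms = self.universe.select_atoms(self.lipid_selection)
        if len(self.solute_atoms) == 0:
            raise SelectionError(f"solute selection {self.solute_selection!r} matches no atoms")
        if len(self.lipid_atoms) == 0:
            raise SelectionError(f"lipid selection {self.lipid_selection!r} matches no atoms")

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    def times_ns(self) -> np.ndarray:
        t = np.array([ts.time for ts in self.universe.trajectory]) / PS_PER_NS
        if t.size > 1 and np.all(np.diff(t) == 0):
            # formats without time stamps: fall back to a unit-frame grid (ns)
            t = np.arange(t.size, dtype=float)
        return t

    def iter_frames(self):
        """Yield (time_ns, box_nm (3,), timestep) per frame."""
        for ts in self.universe.trajectory:
            box = np.asarray(ts.dimensions[:3], dtype=float) / ANGSTROM_PER_NM
            yield ts.time / PS_PER_NS, box, ts


def load_system(topology, trajectory=None, solute_selection="resname SOLU",
                lipid_selection="not resname SOLU") -> SystemReader:
    """Open a topology (GRO/PDB) with an optional trajectory (XTC/DCD/TRR).

    Selections use the MDAnalysis selection grammar.  Raises on empty
    selections or topology/trajectory atom-count mismatches.
    """
    import MDAnalysis as mda

    if trajectory is None:
        u = mda.Universe(str(topology))
    else:
        u = mda.Universe(str(topology), str(trajectory))
    return SystemReader(u, solute_selection, lipid_selection)


# ---------------------------------------------------------------------------
# leaflets and membrane frame
# ---------------------------------------------------------------------------

def assign_leaflets(z_positions, reference, previous=None, hysteresis=0.5):
    """Sticky leaflet labels (+1 upper / -1 lower) for per-lipid z positions.

    A lipid flips leaflet only once it sits beyond ``hysteresis`` nm on the
    other side of the reference plane, preventing flip-flop during thermal
    fluctuation of lipids near the midplane.
    """
    z = np.asarray(z_positions, dtype=float)
    fresh = np.where(z >= reference, 1, -1)
    if previous is None:
        return fresh
    previous = np.asarray(previous)
    out = previous.copy()
    flip_up = (previous == -1) & (z > reference + hysteresis)
    flip_dn = (previous == 1) & (z < reference - hysteresis)
    out[flip_up] = 1
    out[flip_dn] = -1
    return out


def membrane_frames(system: SystemReader, phosphate_selection="name P",
                    hysteresis=0.5) -> MembraneFrameSeries:
    """Per-frame leaflet phosphate planes and midplane.

    Leaflets are assigned from the sign of each phosphate's z relative to the
    median z of all lipid atoms in the first frame, then kept sticky with a
    hysteresis band.  Fails if either leaflet is empty in any frame.
    """
    phos = system.universe.select_atoms(phosphate_selection)
    if len(phos) == 0:
        raise SelectionError(f"phosphate selection {phosphate_selection!r} matches no atoms")

    times, uppers, lowers, bxs, bys = [], [], [], [], []
    labels = None
    for t_ns, box, _ in system.iter_frames():
        z_phos = phos.positions[:, 2].astype(np.float64) / ANGSTROM_PER_NM
        ref = float(np.median(system.lipid_atoms.positions[:, 2])) / ANGSTROM_PER_NM
        labels = assign_leaflets(z_phos, ref, previous=labels, hysteresis=hysteresis)
        up = z_phos[labels == 1]
        lo = z_phos[labels == -1]
        if up.size == 0 or lo.size == 0:
            raise ValueError(f"empty leaflet at t={t_ns} ns")
        times.append(t_ns)
        uppers.append(up.mean())
        lowers.append(lo.mean())
        bxs.append(box[0])
        bys.append(box[1])
    times = np.asarray(times)
    if times.size > 1 and np.all(np.diff(times) == 0):
        times = np.arange(times.size, dtype=float)
    return MembraneFrameSeries(times, np.asarray(uppers), np.asarray(lowers),
                               np.asarray(bxs), np.asarray(bys))


def solute_z_series(system: SystemReader, membrane: MembraneFrameSeries,
                    tracking="com") -> ZSeries:
    """Midplane-referenced, unwrapped eta(t) per solute molecule.

    ``tracking`` is either ``"com"`` (center of mass, the default) or the name
    of a single tracking atom per molecule.  The raw per-frame coordinate is
    wrapped into the box around the midplane and then unwrapped in time so that
    passage through the periodic boundary never mimics a membrane crossing.
    """
    groups = [res.atoms for res in system.solute_atoms.residues]
    if not groups:
        raise SelectionError("solute selection contains no residues")
    ids = [res.resid for res in system.solute_atoms.residues]

    rows = []
    box_zs = []
    for i, (t_ns, box, _) in enumerate(system.iter_frames()):
        mid = membrane.midplane[i]
        row = []
        for g in groups:
            if tracking == "com":
                masses = g.masses
                if masses.sum() > 0:
                    z = float(np.average(g.positions[:, 2], weights=masses))
                else:
                    z = float(g.positions[:, 2].mean())
            else:
                sel = g[np.asarray(g.names) == tracking]
                if len(sel) != 1:
                    raise SelectionError(
                        f"tracking atom {tracking!r} not unique in molecule {g.resids[0]}")
                z = float(sel.positions[0, 2])
            row.append(z / ANGSTROM_PER_NM - mid)
        rows.append(row)
        box_zs.append(box[2])
    box_z = float(np.median(box_zs))
    eta_w = wrap_coordinate(np.asarray(rows), box_z)
    eta = unwrap_series(eta_w, box_z)
    return ZSeries(membrane.time, eta, ids, box_z)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def area_per_lipid(system: SystemReader, membrane: MembraneFrameSeries,
                   hysteresis=0.5) -> pd.DataFrame:
    """Per-leaflet area per lipid, box_x*box_y / n_lipids(leaflet), in nm^2.

    Lipids (residues of the lipid selection) are assigned to leaflets by the z
    of their geometric center relative to the midplane, sticky across frames.
    Returns a tidy frame {time_ns, value, leaflet} including the leaflet mean.
    """
    residues = system.lipid_atoms.residues
    if len(residues) == 0:
        raise ValueError("no lipid residues")
    records = []
    labels = None
    for i, (t_ns, box, _) in enumerate(system.iter_frames()):
        centers = np.array([r.atoms.positions[:, 2].astype(np.float64).mean()
                            for r in residues]) / ANGSTROM_PER_NM
        labels = assign_leaflets(centers, membrane.midplane[i], previous=labels,
                                 hysteresis=hysteresis)
        area = box[0] * box[1]
        n_up = int(np.sum(labels == 1))
        n_lo = int(np.sum(labels == -1))
        if n_up == 0 or n_lo == 0:
            raise ValueError(f"leaflet with zero lipids at t={t_ns} ns")
        t = membrane.time[i]
        records.append({"time_ns": t, "value": area / n_up, "leaflet": "upper"})
        records.append({"time_ns": t, "value": area / n_lo, "leaflet": "lower"})
        records.append({"time_ns": t, "value": 0.5 * (area / n_up + area / n_lo),
                        "leaflet": "mean"})
    return pd.DataFrame.from_records(records)


def membrane_thickness(membrane: MembraneFrameSeries) -> pd.DataFrame:
    """Phosphate-phosphate thickness per frame as a tidy series (nm)."""
    return pd.DataFrame({"time_ns": membrane.time, "value": membrane.thickness,
                         "leaflet": "both"})
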