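"""Desk-scale surrogate inputs for validating the permeability estimators.

Three generators stand in for expensive all-atom MD:

* :func:`simulate_langevin` - overdamped Brownian dynamics of non-interacting
  solute particles on a 1-D free-energy landscape inside a periodic box,
  emulating membrane-normal permeation trajectories;
* :func:`sample_boltzmann` - i.i.d. equilibrium position draws for testing the
  density -> free-energy route;
* :func:`make_toy_membrane` - a pseudo-atom bilayer in the published BBB lipid
  composition plus solute copies, written in standard formats (GRO/XTC/PDB) so
  the readers and contact analysis can be exercised end to end.

:func:`analytic_permeability` is the independent closed-form oracle
(inhomogeneous solubility-diffusion integral) the crossing-count estimator is
validated against.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy import integrate

from .constants import NM_PER_NS_TO_CM_PER_S, thermal_energy
from .geometry import ZSeries, wrap_coordinate
from .models import PMFSpec


class UnstableTimestepError(RuntimeError):
    pass


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the overdamped Langevin generator.

    diffusivity is spatially constant (nm^2/ns), which avoids the spurious-drift
    term required for position-dependent D; dt in ns; box_z is the periodic
    extent in nm.  Stability requires the per-step drift displacement
    (D/kBT)*max|G'|*dt to stay below the analysis bin scale (see
    ``max_drift_step``), and in practice dt << min(sigma)^2 / D.
    """

    diffusivity: float
    temperature: float
    dt: float
    n_steps: int
    n_particles: int
    box_z: float
    seed: int
    sample_every: int = 1
    max_drift_step: float = 0.1

    def __post_init__(self):
        if self.dt <= 0 or self.diffusivity <= 0 or self.box_z <= 0:
            raise ValueError("dt, diffusivity and box_z must be positive")
        if self.n_steps < 1 or self.n_particles < 1 or self.sample_every < 1:
            raise ValueError("n_steps, n_particles and sample_every must be >= 1")


def simulate_langevin(pmf: PMFSpec, params: LangevinParams,
                      initial_positions: Optional[np.ndarray] = None) -> ZSeries:
    """Euler-Maruyama integration of eta' = -(D/kBT) G'(eta) dt + sqrt(2 D dt) xi.

    The landscape is evaluated periodically (positions are wrapped into the box
    for force evaluation) while the returned :class:`~memperm.geometry.ZSeries`
    keeps the unwrapped, continuous coordinate.  Bit-reproducible for a given
    seed.
    """
    if not pmf.differentiable:
        raise ValueError(f"PMF form {pmf.form!r} is not differentiable; "
                         "use a smooth form for Langevin dynamics")
    half = params.box_z / 2.0
    lo, hi = pmf.domain
    if lo < -half - 1e-9 or hi > half + 1e-9:
        raise ValueError("pmf domain must lie inside [-box_z/2, box_z/2]")

    kt = thermal_energy(params.temperature)
    mobility = params.diffusivity / kt
    drift_step = mobility * pmf.max_abs_grad() * params.dt
    if drift_step > params.max_drift_step:
        raise UnstableTimestepError(
            f"max drift displacement per step {drift_step:.4f} nm exceeds "
            f"{params.max_drift_step} nm; reduce dt (dt << min(sigma)^2/D)")

    rng = np.random.default_rng(params.seed)
    if initial_positions is None:
        eta = rng.uniform(-half, half, size=params.n_particles)
    else:
        eta = np.array(initial_positions, dtype=float)
        if eta.shape != (params.n_particles,):
            raise ValueError("initial_positions must have shape (n_particles,)")

    noise_scale = np.sqrt(2.0 * params.diffusivity * params.dt)
    n_stored = params.n_steps // params.sample_every + 1
    stored = np.empty((n_stored, params.n_particles))
    stored[0] = eta
    flat = pmf.form == "flat"
    j = 1
    for step in range(1, params.n_steps + 1):
        if not flat:
            x = wrap_coordinate(eta, params.box_z)
            eta = eta - mobility * pmf.grad(x) * params.dt
        eta = eta + noise_scale * rng.standard_normal(params.n_particles)
        if step % params.sample_every == 0:
            stored[j] = eta
            j += 1
    times = params.dt * params.sample_every * np.arange(n_stored)
    # time grid must be strictly increasing and start after 0 for rate series
    return ZSeries(times, stored, list(range(params.n_particles)), params.box_z)


def sample_boltzmann(pmf: PMFSpec, temperature: float, n: int, seed: int,
                     grid_points: int = 8193) -> np.ndarray:
    """I.i.d. draws with density proportional to exp(-G(eta)/kBT) on the domain.

    Inverse-transform sampling on a dense quadrature grid of the (normalized)
    Boltzmann weight.  Raises if the density is unnormalizable.
    """
    kt = thermal_energy(temperature)
    lo, hi = pmf.domain
    grid = np.linspace(lo, hi, grid_points)
    g = pmf.energy(grid)
    if not np.all(np.isfinite(g)):
        raise ValueError("PMF must be bounded below / finite on its domain")
    w = np.exp(-(g - g.min()) / kt)
    cdf = integrate.cumulative_trapezoid(w, grid, initial=0.0)
    if not np.isfinite(cdf[-1]) or cdf[-1] <= 0:
        raise ValueError("Boltzmann density is unnormalizable")
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def boltzmann_density(pmf: PMFSpec, temperature: float, grid_points: int = 8193):
    """Quadrature-normalized equilibrium density on the PMF domain."""
    kt = thermal_energy(temperature)
    lo, hi = pmf.domain
    grid = np.linspace(lo, hi, grid_points)
    w = np.exp(-pmf.energy(grid) / kt)
    z = integrate.trapezoid(w, grid)
    return grid, w / z


def analytic_permeability(pmf: PMFSpec, diffusivity: float, temperature: float,
                          bounds: Optional[Sequence[float]] = None) -> float:
    """Solubility-diffusion permeability P = [int exp(G/kBT)/D deta]^-1 in cm/s.

    G must be referenced to 0 in bulk; ``bounds`` (nm) span the membrane slab
    and default to the PMF domain.  For constant D the closed form reduces to
    D/L on a flat landscape.
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    kt = thermal_energy(temperature)
    lo, hi = bounds if bounds is not None else pmf.domain
    if hi <= lo:
        raise ValueError("bounds must be increasing")

    if pmf.form == "square_barrier":
        # piecewise-constant integrand: do the integral exactly
        c, hw, h = (pmf.params[k] for k in ("center", "half_width", "height"))
        in_lo, in_hi = max(lo, c - hw), min(hi, c + hw)
        inside = max(0.0, in_hi - in_lo)
        resistance = (inside * np.exp(h / kt) + (hi - lo - inside)) / diffusivity
    else:
        val, _ = integrate.quad(
            lambda x: np.exp(pmf.energy(x) / kt) / diffusivity, lo, hi, limit=400)
        resistance = val
    if not np.isfinite(resistance) or resistance <= 0:
        raise ValueError("divergent solubility-diffusion integrand")
    return (1.0 / resistance) * NM_PER_NS_TO_CM_PER_S


# ---------------------------------------------------------------------------
# lipid composition and toy membrane
# ---------------------------------------------------------------------------

def largest_remainder_counts(percentages: Mapping[str, float], total: int) -> Dict[str, int]:
    """Deterministic, sum-preserving integer apportionment of shares.

    Quotas are the normalized shares times ``total``; each species gets the
    floor of its quota, and the leftover units go to the largest fractional
    remainders (ties broken by input order).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    species = list(percentages)
    shares = np.array([percentages[s] for s in species], dtype=float)
    if np.any(shares < 0) or shares.sum() <= 0:
        raise ValueError("percentages must be non-negative with positive sum")
    quotas = shares / shares.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = sorted(range(len(species)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(species, (int(c) for c in counts)))


def bbb_composition(n_per_leaflet: int) -> Dict[str, int]:
    """Integer per-leaflet lipid counts for the published BBB model ratios."""
    from .datasets import load_lipid_composition

    table = load_lipid_composition()
    percentages = dict(zip(table["species"], table["percentage"]))
    return largest_remainder_counts(percentages, n_per_leaflet)


# pseudo-atom templates: (name, mass, z-offset from the phosphate plane toward
# the midplane).  Phosphate-bearing species carry exactly one P reference atom.
_PHOSPHOLIPID_ATOMS = (("P", 30.97, 0.0), ("GL", 12.01, -0.45),
                       ("T1", 12.01, -1.0), ("T2", 12.01, -1.6))
_CHOL_ATOMS = (("O3", 16.0, -0.2), ("R1", 12.01, -0.8), ("T1", 12.01, -1.4))
_SOLUTE_ATOMS = (("S1", 12.01, 0.0), ("S2", 12.01, 0.1))

SOLUTE_RESNAME = "SOLU"


@dataclass
class ToyMembraneSystem:
    """A pseudo-lipid bilayer plus solute copies as an MDAnalysis universe."""

    universe: "object"
    composition: Dict[str, int]
    box: tuple
    n_solute: int
    leaflet_labels: np.ndarray
    seed: int

    def write(self, out_dir, stem="toy", trajectory_format="xtc") -> Dict[str, str]:
        """Write a GRO topology (plus PDB twin) and the trajectory; returns paths."""
        import os

        import MDAnalysis as mda

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        self.universe.trajectory[0]
        gro = os.path.join(out_dir, f"{stem}.gro")
        self.universe.atoms.write(gro)
        paths["gro"] = gro
        pdb = os.path.join(out_dir, f"{stem}.pdb")
        self.universe.atoms.write(pdb)
        paths["pdb"] = pdb
        traj = os.path.join(out_dir, f"{stem}.{trajectory_format}")
        with mda.Writer(traj, self.universe.atoms.n_atoms) as w:
            for _ in self.universe.trajectory:
                w.write(self.universe.atoms)
        paths["trajectory"] = traj
        return paths


def make_toy_membrane(composition: Optional[Mapping[str, int]] = None,
                      n_solute: int = 8,
                      box=(5.0, 5.0, 12.0),
                      seed: int = 0,
                      n_frames: int = 5,
                      half_thickness: float = 2.0,
                      jitter: float = 0.02,
                      solute_depths: Optional[Sequence[float]] = None,
                      density_cap: float = 100.0) -> ToyMembraneSystem:
    """Build a two-leaflet pseudo-lipid membrane with solute copies.

    Phosphate reference atoms sit near +-``half_thickness`` and tail
    pseudo-atoms point toward the midplane; solute molecules are placed at
    ``solute_depths`` (nm, midplane-referenced; random if omitted).  Fails if
    the resulting atom density exceeds ``density_cap`` atoms/nm^3.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if composition is None:
        composition = bbb_composition(18)
    if any(c < 0 for c in composition.values()):
        raise ValueError("lipid counts must be non-negative")
    if min(box) <= 0:
        raise ValueError("box must be positive")

    rng = np.random.default_rng(seed)
    bx, by, bz = box
    names, masses, resnames, resindex, positions, leaflets = [], [], [], [], [], []
    res_i = -1

    n_per_leaflet = sum(composition.values())
    grid_n = max(1, int(np.ceil(np.sqrt(max(n_per_leaflet, 1)))))
    xs = (np.arange(grid_n) + 0.5) * bx / grid_n
    ys = (np.arange(grid_n) + 0.5) * by / grid_n

    for leaflet in (1, -1):
        slot = 0
        for species, count in composition.items():
            template = _CHOL_ATOMS if species == "CHOL" else _PHOSPHOLIPID_ATOMS
            for _ in range(count):
                res_i += 1
                gx, gy = xs[slot % grid_n], ys[slot // grid_n % grid_n]
                slot += 1
                leaflets.append(leaflet)
                for name, mass, dz in template:
                    names.append(name)
                    masses.append(mass)
                    resindex.append(res_i)
                    z = leaflet * (half_thickness + dz)
                    positions.append((gx + rng.normal(0, jitter),
                                      gy + rng.normal(0, jitter), z))
                resnames.append(species)

    if solute_depths is None:
        solute_depths = rng.uniform(-bz / 2 + 0.3, bz / 2 - 0.3, size=n_solute)
    elif len(solute_depths) != n_solute:
        raise ValueError("need one depth per solute molecule")
    for depth in solute_depths:
        res_i += 1
        sx, sy = rng.uniform(0, bx), rng.uniform(0, by)
        for name, mass, dz in _SOLUTE_ATOMS:
            names.append(name)
            masses.append(mass)
            resindex.append(res_i)
            positions.append((sx, sy, depth + dz))
        resnames.append(SOLUTE_RESNAME)

    n_atoms = len(names)
    if n_atoms == 0:
        raise ValueError("empty system: no lipids and no solute")
    if n_atoms / (bx * by * bz) > density_cap:
        raise ValueError(
            f"overfilled box: {n_atoms / (bx * by * bz):.1f} atoms/nm^3 "
            f"exceeds cap {density_cap}")

    u = mda.Universe.empty(n_atoms, n_residues=res_i + 1,
                           atom_resindex=np.asarray(resindex),
                           residue_segindex=np.zeros(res_i + 1, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("masses", masses)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, res_i + 2))

    base = np.asarray(positions) * 10.0  # nm -> Angstrom
    # fold into [0, box) as a simulation engine would; z stored about midplane
    base[:, 2] += bz / 2 * 10.0
    frames = np.empty((n_frames, n_atoms, 3))
    frames[0] = base
    for f in range(1, n_frames):
        frames[f] = base + rng.normal(0, jitter * 10.0, size=base.shape)
    dims = np.tile([bx * 10, by * 10, bz * 10, 90.0, 90.0, 90.0], (n_frames, 1))
    u.load_new(frames, format=MemoryReader, dimensions=dims, dt=100.0)

    return ToyMembraneSystem(u, dict(composition), tuple(box), int(n_solute),
                             np.asarray(leaflets), seed)
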