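"""Atom-resolved solute-lipid contact matrices.

A contact is a (solute atom, lipid atom) pair within the hydrogen-bond
interaction distance (default 0.33 nm, minimum-image convention), counted once
per frame per pair; counts are accumulated over frames and pooled over solute
copies.  The matrix is indexed by solute atom x (lipid species, lipid atom
name), can be collapsed into per-species head/tail totals, and mapped to
linearly spaced colour bins for visualization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import ANGSTROM_PER_NM
from .geometry import SystemReader


class MinimumImageError(ValueError):
    pass


def contact_pairs_frame(solute_pos: np.ndarray, lipid_pos: np.ndarray,
                        box: Sequence[float], cutoff: float) -> np.ndarray:
    """(i, j) index pairs with minimum-image distance <= cutoff (strict at > cutoff).

    Positions in nm, orthorhombic box (3,).  Uses MDAnalysis' grid-based
    neighbour search; the O(N^2) reference lives in the test suite.
    """
    from MDAnalysis.lib.distances import capped_distance

    box = np.asarray(box, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > box.min() / 2.0:
        raise MinimumImageError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({box.min() / 2.0:.3f} nm); minimum image is ill-defined")
    mda_box = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    pairs, dists = capped_distance(
        np.asarray(solute_pos, dtype=np.float32),
        np.asarray(lipid_pos, dtype=np.float32),
        max_cutoff=cutoff * 1.0001, box=mda_box, return_distances=True)
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    return pairs[dists <= cutoff]


@dataclass
class ContactMatrix:
    """Contact counts: rows = solute atoms, columns = (lipid species, atom name)."""

    counts: np.ndarray
    solute_atoms: List[str]
    lipid_columns: List[Tuple[str, str]]
    n_frames: int
    cutoff: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.solute_atoms), len(self.lipid_columns)):
            raise ValueError("counts shape must match index labels")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self, n_bins: int = 200) -> pd.DataFrame:
        """Long-format export {solute_atom, lipid_species, lipid_atom, count, bin_index}."""
        bins = colormap_bins(self.counts, n_bins)
        rows = []
        for i, sat in enumerate(self.solute_atoms):
            for j, (species, lat) in enumerate(self.lipid_columns):
                rows.append({"solute_atom": sat, "lipid_species": species,
                             "lipid_atom": lat, "count": int(self.counts[i, j]),
                             "bin_index": int(bins[i, j])})
        return pd.DataFrame(rows)


def count_contacts(system: SystemReader, cutoff: float = 0.33, stride: int = 1,
                   pool_copies: bool = True) -> ContactMatrix:
    """Accumulate the solute x lipid contact matrix over trajectory frames.

    With ``pool_copies`` (the default) the counts of all solute copies are
    summed onto the atoms of a single molecule; otherwise every copy keeps its
    own rows.  ``stride`` analyses every stride-th frame.
    """
    solute = system.solute_atoms
    lipids = system.lipid_atoms
    species = np.asarray(lipids.resnames)
    lnames = np.asarray(lipids.names)
    col_labels = sorted({(s, n) for s, n in zip(species, lnames)})
    col_of_label = {lab: j for j, lab in enumerate(col_labels)}
    lipid_col = np.array([col_of_label[(s, n)] for s, n in zip(species, lnames)])

    res_sizes = [len(r.atoms) for r in solute.residues]
    if pool_copies:
        if len(set(res_sizes)) != 1:
            raise ValueError("pool_copies requires identical solute copies")
        per_mol = res_sizes[0]
        row_of_atom = np.concatenate([np.arange(per_mol) for _ in res_sizes])
        row_labels = list(solute.residues[0].atoms.names)
    else:
        row_of_atom = np.arange(len(solute))
        row_labels = [f"{rid}:{n}" for rid, n in zip(solute.resids, solute.names)]

    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    n_used = 0
    for f, (t_ns, box, _) in enumerate(system.iter_frames()):
        if f % stride:
            continue
        pairs = contact_pairs_frame(solute.positions / ANGSTROM_PER_NM,
                                    lipids.positions / ANGSTROM_PER_NM,
                                    box, cutoff)
        for i, j in pairs:
            counts[row_of_atom[i], lipid_col[j]] += 1
        n_used += 1
    return ContactMatrix(counts, row_labels, col_labels, n_used, cutoff)


def aggregate_by_moiety(matrix: ContactMatrix,
                        scheme: Optional[Mapping[str, Mapping[str, set]]] = None
                        ) -> pd.DataFrame:
    """Collapse the matrix into per-species head/tail totals and fractions.

    The scheme maps species -> {head: set of atom names, tail: set}.  Every
    lipid atom name present must be assigned; unassigned names raise, listing
    them, so users can extend the editable default table.
    """
    if scheme is None:
        from .datasets import load_head_tail_scheme

        scheme = load_head_tail_scheme()
    unassigned = []
    for species, name in matrix.lipid_columns:
        part = scheme.get(species)
        if part is None or (name not in part["head"] and name not in part["tail"]):
            unassigned.append(f"{species}:{name}")
    if unassigned:
        raise ValueError(f"atom names missing from head/tail scheme: {unassigned}")

    records = []
    col_totals = matrix.counts.sum(axis=0)
    for species in sorted({s for s, _ in matrix.lipid_columns}):
        head = tail = 0
        for j, (s, name) in enumerate(matrix.lipid_columns):
            if s != species:
                continue
            if name in scheme[species]["head"]:
                head += int(col_totals[j])
            else:
                tail += int(col_totals[j])
        tot = head + tail
        records.append({"species": species, "head": head, "tail": tail,
                        "head_fraction": head / tot if tot else np.nan,
                        "tail_fraction": tail / tot if tot else np.nan})
    return pd.DataFrame(records)


def colormap_bins(counts: np.ndarray, n_bins: int = 200) -> np.ndarray:
    """Map counts to linearly spaced bins between 0 and the maximum value.

    A count c maps to floor(c / c_max * (n_bins - 1)): zero to bin 0, the
    maximum to bin n_bins - 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    counts = np.asarray(counts)
    c_max = counts.max() if counts.size else 0
    if c_max <= 0:
        if counts.size:
            warnings.warn("all-zero contact matrix; every cell maps to bin 0")
        return np.zeros_like(counts, dtype=int)
    return np.floor(counts / c_max * (n_bins - 1)).astype(int)
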