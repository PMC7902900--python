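"""Shrake–Rupley solvent-accessible surface area with a deterministic
generalized-spiral quadrature.

Each atom is expanded by the probe radius; test points are placed on the
expanded sphere using the golden-angle spiral (no RNG, so results are
bit-reproducible), and a point is accessible when it lies outside every
neighbour's expanded sphere.  The per-atom area is the accessible fraction of
the expanded-sphere area 4π(r_i + r_probe)².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .topology import AtomSelection, Topology


@dataclass
class SasaResult:
    per_atom: np.ndarray      # Å², aligned with the selection order
    atom_indices: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(np.sum(self.per_atom))


def spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    frame: np.ndarray,
    topology: Topology,
    selection: AtomSelection | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom SASA of one frame (Å²).

    All atoms of the topology act as occluders; ``selection`` restricts which
    atoms are reported (default: all).  Atoms need a positive PB/SASA radius.
    """
    topology.require_parameters("radii")
    coords = np.asarray(frame, dtype=float)
    radii = np.asarray(topology.radii, dtype=float)
    if selection is None:
        sel_idx = np.arange(topology.n_atoms)
    else:
        selection.validate(topology)
        sel_idx = selection.indices
    if np.any(~np.isfinite(radii)):
        bad = int(np.argmax(~np.isfinite(radii)))
        raise ParameterError(f"atom id {topology.ids[bad]} has no radius")

    expanded = radii + probe_radius
    unit = spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    per_atom = np.zeros(len(sel_idx))
    for out_i, i in enumerate(sel_idx):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = np.count_nonzero(accessible) / n_points
        per_atom[out_i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom, sel_idx, probe_radius, n_points)
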