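"""Synthetic trajectories, collective-variable series, contact schedules and
toy molecular systems with known ground truth.

Real microsecond MD is far beyond desk scale, so every analysis stage is
validated against generated data whose statistical structure is known
exactly:

* Gaussian coordinate fluctuations with a prescribed inter-atom correlation
  matrix (DCCM recovery oracle),
* two-/multi-basin collective-variable series with prescribed occupancies
  (free-energy-landscape oracle),
* residue-pair contact schedules with *exact* per-pair contact fractions —
  integer frame counts, no sampling error — for boundary tests of the
  4.5 Å / 75% network edge rule,
* small toy complexes with charges and Lennard-Jones/PB parameters for the
  energetics stack.

All generators draw from ``numpy.random.default_rng(seed)`` and are
bit-reproducible under a fixed seed.  Contact frame counts use half-up
rounding so boundary cases are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InfeasibleScheduleError, InvalidSpecError
from .landscape import CVSeries
from .topology import Topology
from .trajectory import Trajectory

#: protein-like default parameter magnitudes (well-conditioned for LJ/PB tests)
DEFAULT_SIGMA = 3.4     # Å
DEFAULT_EPSILON = 0.1   # kcal/mol
DEFAULT_RADIUS = 1.9    # Å


@dataclass
class SyntheticSpec:
    """Blueprint for a toy molecular system.

    ``chain_layout`` lists (chain id, residue count) pairs; per-atom
    parameter arrays, when given, must match the total atom count
    (residues × atoms_per_residue).
    """

    n_residues: int = 10
    atoms_per_residue: int = 1
    chain_layout: list[tuple[str, int]] | None = None
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    pb_radius: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain_layout is None:
            self.chain_layout = [("A", self.n_residues)]
        total_res = sum(n for _, n in self.chain_layout)
        if total_res != self.n_residues:
            self.n_residues = total_res
        if self.n_residues < 1 or self.atoms_per_residue < 1:
            raise InvalidSpecError("counts must be >= 1")
        n = self.n_atoms
        for name in ("charges", "lj_sigma", "lj_epsilon", "pb_radius"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise InvalidSpecError(
                        f"{name} must have length {n}, got {arr.shape}"
                    )
                if name != "charges" and np.any(arr < 0):
                    raise InvalidSpecError(f"{name} must be non-negative")
                setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue


@dataclass
class GroundTruth:
    """Exact generating parameters recorded alongside synthetic data."""

    true_correlation: np.ndarray | None = None
    true_rmsf: np.ndarray | None = None
    true_occupancies: np.ndarray | None = None
    true_contact_fractions: dict | None = None
    basin_membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.true_correlation is not None:
            c = np.asarray(self.true_correlation, float)
            if not np.allclose(c, c.T) or np.any(np.abs(c) > 1 + 1e-12):
                raise InvalidSpecError("true_correlation must be symmetric in [-1,1]")
            if not np.allclose(np.diag(c), 1.0):
                raise InvalidSpecError("true_correlation must have unit diagonal")
        if self.true_occupancies is not None:
            p = np.asarray(self.true_occupancies, float)
            if abs(p.sum() - 1.0) > 1e-12 or np.any(p < 0):
                raise InvalidSpecError("occupancies must be >= 0 and sum to 1")
        if self.true_contact_fractions is not None:
            for pair, f in self.true_contact_fractions.items():
                if not 0.0 <= f <= 1.0:
                    raise InvalidSpecError(f"contact fraction {f} for {pair}")

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            return v

        Path(path).write_text(
            json.dumps({k: conv(v) for k, v in self.__dict__.items()}, indent=1)
        )


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding (0.5 -> 1), used for contact counts."""
    return int(math.floor(x + 0.5))


def build_toy_system(spec: SyntheticSpec) -> Topology:
    """Topology with one node-defining "CA" atom per residue plus optional
    extra atoms, and a full parameter table (defaults are protein-like)."""
    n = spec.n_atoms
    names, elements, resids, resnames, chains = [], [], [], [], []
    next_resid: dict[str, int] = {}
    for chain_id, n_res in spec.chain_layout:
        start = next_resid.get(chain_id, 1)
        for r in range(start, start + n_res):
            for a in range(spec.atoms_per_residue):
                names.append("CA" if a == 0 else f"X{a}")
                elements.append("C")
                resids.append(r)
                resnames.append("TOY")
                chains.append(chain_id)
        next_resid[chain_id] = start + n_res
    rng = np.random.default_rng(spec.seed)
    charges = (
        spec.charges if spec.charges is not None
        else rng.choice([-1.0, 0.0, 1.0], size=n)
    )
    return Topology(
        ids=np.arange(1, n + 1),
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(chains),
        charges=np.asarray(charges, float),
        lj_sigma=(spec.lj_sigma if spec.lj_sigma is not None
                  else np.full(n, DEFAULT_SIGMA)),
        lj_epsilon=(spec.lj_epsilon if spec.lj_epsilon is not None
                    else np.full(n, DEFAULT_EPSILON)),
        radii=(spec.pb_radius if spec.pb_radius is not None
               else np.full(n, DEFAULT_RADIUS)),
    )


def default_reference_coords(topology: Topology, spacing: float = 3.8) -> np.ndarray:
    """Simple extended-chain reference: atoms on a line, chains offset in y."""
    coords = np.zeros((topology.n_atoms, 3))
    chain_ids = list(dict.fromkeys(topology.chains))
    for i in range(topology.n_atoms):
        coords[i, 0] = spacing * i
        coords[i, 1] = 20.0 * chain_ids.index(topology.chains[i])
    return coords


def sample_correlated_trajectory(
    topology: Topology,
    covariance: np.ndarray,
    n_frames: int,
    seed: int = 0,
    reference: np.ndarray | None = None,
    atom_indices: np.ndarray | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Gaussian displacements with a prescribed inter-atom covariance.

    The covariance is an (M, M) matrix over the selected atoms, applied
    independently and identically to x, y and z, so the vector-dot-product
    DCCM of the sample converges to the normalised covariance.  Atoms not in
    ``atom_indices`` stay fixed at the reference.  Displacements are drawn
    through a symmetric (eigen) factorisation; a covariance with eigenvalues
    below -1e-8 raises an error naming the offending eigenvalue.
    """
    if n_frames < 2:
        raise InvalidSpecError("n_frames must be >= 2")
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise InvalidSpecError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise InvalidSpecError("covariance must be symmetric")
    if atom_indices is None:
        atom_indices = np.arange(topology.n_atoms)
    atom_indices = np.asarray(atom_indices, dtype=int)
    if cov.shape[0] != len(atom_indices):
        raise InvalidSpecError("covariance size must match the atom selection")

    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8:
        raise InvalidSpecError(
            f"covariance is not positive semidefinite "
            f"(smallest eigenvalue {evals.min():.3e})"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    ref = (
        default_reference_coords(topology)
        if reference is None else np.asarray(reference, float)
    )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, 3, cov.shape[0]))
    disp = z @ root.T                       # (F, 3, M)
    coords = np.repeat(ref[None, :, :], n_frames, axis=0)
    coords[:, atom_indices, :] += np.transpose(disp, (0, 2, 1))

    var = np.diag(cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(np.outer(var, var))
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    truth = GroundTruth(
        true_correlation=np.clip(corr, -1.0, 1.0),
        true_rmsf=np.sqrt(3.0 * var),
    )
    return Trajectory(topology, coords), truth


def sample_two_state_cv(
    basin_centers: list[tuple[float, float]],
    basin_widths: list[float] | float,
    occupancies: list[float],
    n_frames: int,
    seed: int = 0,
) -> tuple[CVSeries, CVSeries, GroundTruth]:
    """Two collective-variable series from a Gaussian mixture over basins.

    Each frame picks a basin with the given occupancy probabilities and
    draws (d1, d2) from an isotropic Gaussian at that basin's center.
    Per-frame basin membership is recorded in the ground truth.
    """
    centers = np.asarray(basin_centers, dtype=float)
    k = len(centers)
    widths = np.broadcast_to(np.asarray(basin_widths, dtype=float), (k,))
    occ = np.asarray(occupancies, dtype=float)
    if len(occ) != k:
        raise InvalidSpecError("one occupancy per basin required")
    if abs(occ.sum() - 1.0) > 1e-9 or np.any(occ < 0):
        raise InvalidSpecError(
            f"occupancies must be non-negative and sum to 1 (got sum {occ.sum()})"
        )
    if np.any(widths <= 0):
        raise InvalidSpecError("basin widths must be positive")
    occ = occ / occ.sum()

    rng = np.random.default_rng(seed)
    membership = rng.choice(k, size=n_frames, p=occ)
    noise = rng.standard_normal(size=(n_frames, 2)) * widths[membership][:, None]
    vals = centers[membership] + noise
    truth = GroundTruth(true_occupancies=occ, basin_membership=membership)
    return (
        CVSeries("d1", vals[:, 0]),
        CVSeries("d2", vals[:, 1]),
        truth,
    )


def sample_contact_schedule(
    topology: Topology,
    pair_fractions: dict[tuple, float],
    contact_distance: float = 4.0,
    apart_distance: float = 10.0,
    n_frames: int = 1000,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Trajectory in which each residue pair is in contact in *exactly*
    round(fraction * n_frames) frames (half-up rounding).

    Pairs are keyed by (chain, resid) tuples.  Each scheduled pair is laid
    out on its own lane along x and the second residue toggles between the
    contact and apart separation; which frames are in contact is a seeded
    random subset.  A residue taking part in two pairs would need
    co-satisfied frame sets, which this generator does not attempt: it
    raises the infeasible-schedule error instead.
    """
    if not contact_distance < apart_distance:
        raise InvalidSpecError("contact_distance must be < apart_distance")
    for pair, f in pair_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise InvalidSpecError(f"fraction {f} for pair {pair} outside [0,1]")
    seen: set = set()
    for a, b in pair_fractions:
        for key in (tuple(a), tuple(b)):
            if key in seen:
                raise InfeasibleScheduleError(
                    f"residue {key} appears in more than one scheduled pair"
                )
            seen.add(key)

    res_idx = topology.residue_atom_indices()
    coords = np.zeros((n_frames, topology.n_atoms, 3))
    # unscheduled residues parked far apart on a diagonal, one slot each
    for slot, (key, atoms) in enumerate(res_idx.items()):
        coords[:, atoms, :] = 100.0 * (slot + 1)

    rng = np.random.default_rng(seed)
    fractions_exact: dict = {}
    for lane, ((a, b), fraction) in enumerate(sorted(pair_fractions.items())):
        key_a, key_b = tuple(a), tuple(b)
        atoms_a, atoms_b = res_idx[key_a], res_idx[key_b]
        n_contact = round_half_up(fraction * n_frames)
        in_contact = np.zeros(n_frames, dtype=bool)
        in_contact[rng.permutation(n_frames)[:n_contact]] = True
        base = np.array([0.0, 1000.0 * (lane + 1), 0.0])
        coords[:, atoms_a, :] = base
        sep = np.where(in_contact, contact_distance, apart_distance)
        coords[:, atoms_b, :] = base
        coords[:, atoms_b, 0] += sep[:, None]
        fractions_exact[(key_a, key_b)] = n_contact / n_frames
    truth = GroundTruth(true_contact_fractions=fractions_exact)
    return Trajectory(topology, coords), truth
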