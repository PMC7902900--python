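"""Trajectory container and per-frame geometric/statistical primitives.

The trajectory model is deliberately plain: an ``(F, N, 3)`` float array of
Cartesian coordinates in Å bound to a :class:`~mdpost.topology.Topology`,
with optional per-frame time stamps in ns.  On top of it this module provides
the workhorse operations of any MD post-analysis:

* Kabsch least-squares superposition and per-frame RMSD,
* per-atom RMSF about the time-mean structure (with an optional two-pass
  iterative alignment to the mean),
* per-frame distances/angles with probability-density histograms,
* residue-pair contact / salt-bridge persistence fractions,
* Welch's unequal-variance two-sample t-test.

Distance and persistence thresholds are inclusive (``<=``) throughout, so
boundary cases such as a contact fraction of exactly 75% are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateGeometryError,
    SelectionError,
    StructuralError,
    UndefinedStatisticError,
)
from .topology import AtomSelection, Topology

#: Heavy-atom side-chain atoms carrying the formal charge, per residue type.
#: Used by salt-bridge persistence; phosphotyrosine (PTR/TPO-style "PTR")
#: contributes its phosphate oxygens.
CHARGED_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "PTR": ("O1P", "O2P", "O3P"),
}

ACIDIC_RESNAMES = {"ASP", "GLU", "PTR"}
BASIC_RESNAMES = {"LYS", "ARG", "HIS"}


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) bound to a topology."""

    topology: Topology
    coords: np.ndarray                 # (F, N, 3), Å
    times: np.ndarray | None = None    # (F,), ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError("coordinates must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if self.coords.shape[0] < 1:
            raise StructuralError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def select(self, expression: str) -> AtomSelection:
        return self.topology.select(expression)


# ---------------------------------------------------------------------------
# superposition

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) mapping centered ``mobile`` onto
    centered ``reference`` in the least-squares sense."""
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _check_selection_geometry(ref_sel: np.ndarray) -> None:
    if ref_sel.shape[0] < 3:
        raise DegenerateGeometryError(
            "superposition needs at least 3 selected atoms"
        )
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateGeometryError(
            "selected atoms are collinear; rotation is not unique"
        )


def superpose(
    mobile: Trajectory,
    reference: np.ndarray | None = None,
    selection: AtomSelection | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Superpose every frame onto a reference and return (aligned, rmsd).

    ``reference`` defaults to the first frame (analysis convention: align to
    the initial structure); ``selection`` defaults to all atoms.  The rotation
    is the Kabsch solution, constrained to a proper rotation, fitted on the
    selection; the whole frame is transformed.  Returned RMSD is the
    post-superposition value over the selection, per frame.
    """
    if selection is None:
        selection = AtomSelection(np.arange(mobile.n_atoms), "all")
    selection.validate(mobile.topology)
    idx = selection.indices
    ref = mobile.coords[0] if reference is None else np.asarray(reference, float)
    if ref.shape != (mobile.n_atoms, 3):
        raise StructuralError("reference frame has wrong shape")
    ref_sel = ref[idx]
    _check_selection_geometry(ref_sel)
    ref_center = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_center

    aligned = np.empty_like(mobile.coords)
    rmsd = np.empty(mobile.n_frames)
    for f in range(mobile.n_frames):
        mob = mobile.coords[f]
        mob_center = mob[idx].mean(axis=0)
        rot = kabsch_rotation(mob[idx] - mob_center, ref_centered)
        aligned[f] = (mob - mob_center) @ rot.T + ref_center
        diff = aligned[f][idx] - ref_sel
        rmsd[f] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return Trajectory(mobile.topology, aligned, mobile.times), rmsd


def align_to_mean(
    traj: Trajectory, selection: AtomSelection | None = None, passes: int = 2
) -> Trajectory:
    """Iteratively superpose onto the running mean structure (default 2 passes)."""
    out = traj
    for _ in range(passes):
        mean = out.coords.mean(axis=0)
        out, _ = superpose(out, reference=mean, selection=selection)
    return out


def rmsf(traj: Trajectory, selection: AtomSelection | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    The trajectory is assumed to be superposed already; a single-frame
    trajectory has no defined fluctuation.
    """
    if traj.n_frames < 2:
        raise UndefinedStatisticError("RMSF undefined for a single frame")
    if selection is None:
        idx = np.arange(traj.n_atoms)
    else:
        selection.validate(traj.topology)
        idx = selection.indices
    x = traj.coords[:, idx, :]
    dx = x - x.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dx * dx, axis=2), axis=0))


# ---------------------------------------------------------------------------
# geometry series

@dataclass
class GeometrySeries:
    """Per-frame values for one distance/angle definition plus a histogram."""

    kind: str                 # "distance" | "angle"
    atoms: tuple[int, ...]
    values: np.ndarray        # Å or degrees; NaN where undefined
    flagged_frames: np.ndarray  # frames where the value was undefined
    bin_edges: np.ndarray
    density: np.ndarray       # probability density over bins


def _histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    ok = values[np.isfinite(values)]
    if len(ok) == 0:
        return np.array([0.0, bin_width]), np.array([0.0])
    lo = np.floor(ok.min() / bin_width) * bin_width
    hi = np.ceil(ok.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(ok, bins=edges, density=True)
    return edges, density


def geometry_series(
    traj: Trajectory,
    spec: list[tuple[int, ...]],
    bin_width: float = 0.1,
) -> list[GeometrySeries]:
    """Per-frame distances (i, j) and planar angles (i, j, k) with histograms.

    Angles are measured at the middle atom ``j`` and returned in degrees.
    Frames where an angle is undefined (coincident points) are recorded as NaN
    and listed in ``flagged_frames`` rather than dropped.
    """
    out: list[GeometrySeries] = []
    n = traj.n_atoms
    for definition in spec:
        if any(i < 0 or i >= n for i in definition):
            raise SelectionError(f"atom indices {definition} out of range")
        if len(definition) == 2:
            i, j = definition
            d = np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=1)
            edges, dens = _histogram(d, bin_width)
            out.append(
                GeometrySeries("distance", tuple(definition), d,
                               np.array([], dtype=int), edges, dens)
            )
        elif len(definition) == 3:
            i, j, k = definition
            v1 = traj.coords[:, i] - traj.coords[:, j]
            v2 = traj.coords[:, k] - traj.coords[:, j]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            bad = (n1 < 1e-12) | (n2 < 1e-12)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ang[bad] = np.nan
            edges, dens = _histogram(ang, bin_width)
            out.append(
                GeometrySeries("angle", tuple(definition), ang,
                               np.nonzero(bad)[0], edges, dens)
            )
        else:
            raise SelectionError(
                f"geometry definition must have 2 or 3 atoms, got {definition}"
            )
    return out


# ---------------------------------------------------------------------------
# contact / salt-bridge persistence

def _charged_group_indices(
    topology: Topology, key: tuple[str, int]
) -> np.ndarray:
    """Heavy-atom indices of the charged side-chain group of one residue."""
    res_atoms = topology.residue_atom_indices()[key]
    resname = str(topology.resnames[res_atoms[0]])
    names = CHARGED_GROUP_ATOMS.get(resname)
    if names is None:
        raise SelectionError(
            f"residue {resname} {key} is not an ionizable type"
        )
    idx = res_atoms[np.isin(topology.names[res_atoms], names)]
    if len(idx) == 0:
        raise SelectionError(
            f"residue {resname} {key} lacks charged-group atoms {names}"
        )
    return idx


def _min_group_distance(
    coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Per-frame minimum distance between two atom groups; coords (F, N, 3)."""
    diff = coords[:, idx_a, None, :] - coords[:, None, idx_b, :]
    d = np.sqrt(np.sum(diff * diff, axis=3))
    return d.reshape(coords.shape[0], -1).min(axis=1)


def persistence_table(
    traj: Trajectory,
    pair_definitions: list[tuple],
    cutoff: float = 4.0,
    mode: str = "atom-pair",
) -> tuple[dict, dict]:
    """Contact fraction per pair and the underlying per-frame distance series.

    ``mode="atom-pair"``: each pair is (i, j) atom indices; the distance is the
    plain atom-atom distance.  ``mode="salt-bridge"``: each pair is two
    (chain, resid) keys, one acidic (Asp/Glu/pTyr) and one basic
    (Lys/Arg/His); the distance is the minimum over the charged-group heavy
    atoms.  A frame with distance exactly equal to ``cutoff`` counts as a
    contact (inclusive threshold).
    """
    fractions: dict = {}
    series: dict = {}
    for pair in pair_definitions:
        a, b = pair
        if mode == "atom-pair":
            d = np.linalg.norm(
                traj.coords[:, int(a)] - traj.coords[:, int(b)], axis=1
            )
        elif mode == "salt-bridge":
            key_a, key_b = (str(a[0]), int(a[1])), (str(b[0]), int(b[1]))
            res_idx = traj.topology.residue_atom_indices()
            rn_a = str(traj.topology.resnames[res_idx[key_a][0]])
            rn_b = str(traj.topology.resnames[res_idx[key_b][0]])
            acidic = {rn_a, rn_b} & ACIDIC_RESNAMES
            basic = {rn_a, rn_b} & BASIC_RESNAMES
            if not acidic or not basic:
                raise SelectionError(
                    f"salt-bridge pair {pair} must name one acidic and one "
                    f"basic residue (got {rn_a}, {rn_b})"
                )
            ia = _charged_group_indices(traj.topology, key_a)
            ib = _charged_group_indices(traj.topology, key_b)
            d = _min_group_distance(traj.coords, ia, ib)
        else:
            raise SelectionError(f"unknown persistence mode {mode!r}")
        key = (a, b) if mode == "atom-pair" else (tuple(a), tuple(b))
        series[key] = d
        fractions[key] = float(np.count_nonzero(d <= cutoff)) / traj.n_frames
    return fractions, series


def residue_contact_fractions(
    traj: Trajectory, cutoff: float = 4.5, heavy_only: bool = True
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Contact-persistence matrix over all residue pairs.

    Entry (p, q) is the fraction of frames in which the minimum heavy-atom
    distance between residues p and q is <= cutoff.  Returns the symmetric
    matrix and the ordered residue keys.
    """
    top = traj.topology
    res_idx = top.residue_atom_indices()
    keys = list(res_idx)
    if heavy_only:
        heavy = top.elements != "H"
        groups = []
        for k in keys:
            g = res_idx[k][heavy[res_idx[k]]]
            groups.append(g if len(g) else res_idx[k])
    else:
        groups = [res_idx[k] for k in keys]
    nr = len(keys)
    frac = np.zeros((nr, nr))
    for p in range(nr):
        frac[p, p] = 1.0
        for q in range(p + 1, nr):
            d = _min_group_distance(traj.coords, groups[p], groups[q])
            f = float(np.count_nonzero(d <= cutoff)) / traj.n_frames
            frac[p, q] = frac[q, p] = f
    return frac, keys


# ---------------------------------------------------------------------------
# statistics

def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch–Satterthwaite degrees of freedom, two-sided p).  Frames
    are treated as independent observations; serially correlated trajectory
    data will overstate significance (see the methods note).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatisticError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise UndefinedStatisticError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
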