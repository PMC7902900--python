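"""MM/PBSA binding free-energy machinery.

The binding free energy is assembled end-point style from complex, receptor
and ligand terms taken from the *same* trajectory (single-trajectory
protocol), so the internal molecular-mechanics difference dE_int is
identically zero and the gas-phase part reduces to the receptor–ligand
cross interaction:

    dG_binding = dE_MM + dG_solv            (the -T dS term is omitted)
    dE_MM      = dE_vdW + dE_ele + dE_int,   dE_int = 0
    dG_solv    = dE_PB + dE_nonpolar
    dE_nonpolar = gamma * SASA + b,  gamma = 0.00542 kcal/(mol Å^2),
                                     b = 0.92 kcal/mol

Electrostatics uses k_c = 332.0636 kcal Å/(mol e^2) with no distance cutoff;
van der Waals is 12-6 Lennard-Jones with Lorentz–Berthelot combining.  The
polar term comes from the finite-difference PB solver; the nonpolar term is
linear in the Shrake–Rupley SASA.

Per-residue decomposition attributes each receptor–ligand MM pair term half
to the residue owning each atom, the polar term as (1/2) q_i * change in
reaction-field potential at atom i between the complex and the isolated
subsystem, and the nonpolar term through per-atom SASA differences (the
constant b, which belongs to no atom, is spread uniformly over residues so
residue sums reproduce the totals exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError, SingularityError
from .pbsolver import COULOMB_K, PBGridSpec, reaction_field_potentials, solve_pb
from .sasa import shrake_rupley_sasa
from .topology import AtomSelection, Topology, subset_topology
from .trajectory import Trajectory

GAMMA_NONPOLAR = 0.00542  # kcal mol^-1 Å^-2
B_NONPOLAR = 0.92         # kcal mol^-1


def mm_pair_energy(
    frame: np.ndarray,
    topology: Topology,
    group_a: AtomSelection,
    group_b: AtomSelection,
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """Cross-group (E_vdW, E_ele) in kcal/mol; exact sums, no cutoff."""
    topology.require_parameters("charges", "lj_sigma", "lj_epsilon")
    group_a.validate(topology)
    group_b.validate(topology)
    ia, ib = group_a.indices, group_b.indices
    if np.intersect1d(ia, ib).size:
        raise SelectionError("groups overlap")
    xa, xb = np.asarray(frame, float)[ia], np.asarray(frame, float)[ib]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r < 1e-6):
        p, q = np.unravel_index(int(np.argmin(r)), r.shape)
        raise SingularityError(
            f"atoms id {topology.ids[ia[p]]} and id {topology.ids[ib[q]]} overlap"
        )
    qa = np.asarray(topology.charges, float)[ia]
    qb = np.asarray(topology.charges, float)[ib]
    e_ele = COULOMB_K * np.sum(np.outer(qa, qb) / r) / dielectric

    sig = 0.5 * (
        np.asarray(topology.lj_sigma, float)[ia][:, None]
        + np.asarray(topology.lj_sigma, float)[ib][None, :]
    )
    eps = np.sqrt(
        np.outer(
            np.asarray(topology.lj_epsilon, float)[ia],
            np.asarray(topology.lj_epsilon, float)[ib],
        )
    )
    sr6 = (sig / r) ** 6
    e_vdw = np.sum(4.0 * eps * (sr6 * sr6 - sr6))
    return float(e_vdw), float(e_ele)


def mm_pair_energy_matrix(
    frame: np.ndarray,
    topology: Topology,
    group_a: AtomSelection,
    group_b: AtomSelection,
    dielectric: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (vdW, ele) matrices over (len(a), len(b)); decomposition helper."""
    ia, ib = group_a.indices, group_b.indices
    xa, xb = np.asarray(frame, float)[ia], np.asarray(frame, float)[ib]
    r = np.sqrt(np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=2))
    if np.any(r < 1e-6):
        raise SingularityError("overlapping atoms in pair-energy matrix")
    qa = np.asarray(topology.charges, float)[ia]
    qb = np.asarray(topology.charges, float)[ib]
    ele = COULOMB_K * np.outer(qa, qb) / r / dielectric
    sig = 0.5 * (
        np.asarray(topology.lj_sigma, float)[ia][:, None]
        + np.asarray(topology.lj_sigma, float)[ib][None, :]
    )
    eps = np.sqrt(
        np.outer(
            np.asarray(topology.lj_epsilon, float)[ia],
            np.asarray(topology.lj_epsilon, float)[ib],
        )
    )
    sr6 = (sig / r) ** 6
    vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    return vdw, ele


def nonpolar_energy(
    total_sasa: float,
    gamma: float = GAMMA_NONPOLAR,
    b: float = B_NONPOLAR,
) -> float:
    """Surface-area-linear nonpolar solvation term gamma*SASA + b (kcal/mol)."""
    if total_sasa < 0:
        raise ParameterError("SASA must be non-negative")
    return gamma * total_sasa + b


@dataclass
class EnergyBreakdown:
    """Per-frame binding components (kcal/mol); dE_int == 0 under the
    single-trajectory protocol."""

    e_vdw: np.ndarray
    e_ele: np.ndarray
    e_pb: np.ndarray
    e_nonpolar: np.ndarray
    e_int: np.ndarray

    @property
    def e_mm(self) -> np.ndarray:
        return self.e_vdw + self.e_ele + self.e_int

    @property
    def g_solv(self) -> np.ndarray:
        return self.e_pb + self.e_nonpolar

    @property
    def g_binding(self) -> np.ndarray:
        return self.e_mm + self.g_solv


@dataclass
class BindingReport:
    """Means ± std of the binding components, Table-style."""

    breakdown: EnergyBreakdown
    n_frames: int
    frame_indices: np.ndarray
    receptor_expression: str
    ligand_expression: str
    entropy_term: str = "omitted (-T dS set to 0)"

    def summary(self) -> pd.DataFrame:
        b = self.breakdown
        rows = {
            "dE_vdw": b.e_vdw,
            "dE_ele": b.e_ele,
            "dE_PB": b.e_pb,
            "dE_nonpolar": b.e_nonpolar,
            "dE_MM": b.e_mm,
            "dG_solv": b.g_solv,
            "dG_binding": b.g_binding,
        }
        return pd.DataFrame(
            {
                "component": list(rows),
                "mean": [float(np.mean(v)) for v in rows.values()],
                "std": [float(np.std(v)) for v in rows.values()],
            }
        )

    def mean(self, component: str) -> float:
        df = self.summary().set_index("component")
        return float(df.loc[component, "mean"])


def _frame_indices(n_frames: int, stride: int) -> np.ndarray:
    if stride < 1:
        raise ParameterError("frame stride must be >= 1")
    return np.arange(0, n_frames, stride)


def mmpbsa_binding(
    traj: Trajectory,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    grid: PBGridSpec | None = None,
    frame_stride: int = 10,
    sasa_points: int = 960,
) -> BindingReport:
    """Single-trajectory MM/PBSA over every ``frame_stride``-th frame.

    The selections must be disjoint and jointly cover the complex; receptor
    and ligand conformations are cut from the complex frames, so dE_int = 0
    by construction and dE_vdW/dE_ele reduce to the cross interaction.
    """
    grid = grid or PBGridSpec()
    top = traj.topology
    receptor_sel.validate(top)
    ligand_sel.validate(top)
    union = np.union1d(receptor_sel.indices, ligand_sel.indices)
    if np.intersect1d(receptor_sel.indices, ligand_sel.indices).size:
        raise SelectionError("receptor and ligand selections overlap")
    if len(union) != top.n_atoms:
        raise SelectionError(
            "receptor and ligand selections must jointly cover the complex"
        )
    top.require_parameters("charges", "lj_sigma", "lj_epsilon", "radii")

    frames = _frame_indices(traj.n_frames, frame_stride)
    rec_top = subset_topology(top, receptor_sel.indices)
    lig_top = subset_topology(top, ligand_sel.indices)

    e_vdw = np.empty(len(frames))
    e_ele = np.empty(len(frames))
    e_pb = np.empty(len(frames))
    e_np = np.empty(len(frames))
    for n, f in enumerate(frames):
        frame = traj.coords[f]
        try:
            e_vdw[n], e_ele[n] = mm_pair_energy(
                frame, top, receptor_sel, ligand_sel
            )
            pb_c = solve_pb(frame, top, grid)
            pb_r = solve_pb(frame[receptor_sel.indices], rec_top, grid)
            pb_l = solve_pb(frame[ligand_sel.indices], lig_top, grid)
            e_pb[n] = pb_c - pb_r - pb_l
            s_c = shrake_rupley_sasa(frame, top, n_points=sasa_points).total
            s_r = shrake_rupley_sasa(
                frame[receptor_sel.indices], rec_top, n_points=sasa_points
            ).total
            s_l = shrake_rupley_sasa(
                frame[ligand_sel.indices], lig_top, n_points=sasa_points
            ).total
            e_np[n] = (
                nonpolar_energy(s_c) - nonpolar_energy(s_r) - nonpolar_energy(s_l)
            )
        except Exception as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
    breakdown = EnergyBreakdown(
        e_vdw, e_ele, e_pb, e_np, np.zeros(len(frames))
    )
    return BindingReport(
        breakdown, len(frames), frames,
        receptor_sel.expression, ligand_sel.expression,
    )


def per_residue_decomposition(
    traj: Trajectory,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    grid: PBGridSpec | None = None,
    frame_stride: int = 10,
    sasa_points: int = 960,
) -> pd.DataFrame:
    """Per-residue dE_vdW / dE_ele / dE_polar / dE_nonpolar contributions.

    Averaged over the strided frames; residue sums reproduce the
    corresponding totals of :func:`mmpbsa_binding` (same stride) exactly up
    to round-off.
    """
    grid = grid or PBGridSpec()
    top = traj.topology
    receptor_sel.validate(top)
    ligand_sel.validate(top)
    top.require_parameters("charges", "lj_sigma", "lj_epsilon", "radii")
    frames = _frame_indices(traj.n_frames, frame_stride)

    res_keys = top.residue_keys()
    key_of_atom = [
        (str(top.chains[i]), int(top.resids[i])) for i in range(top.n_atoms)
    ]
    res_pos = {k: p for p, k in enumerate(res_keys)}
    nr = len(res_keys)
    acc = {
        "dE_vdw": np.zeros(nr),
        "dE_ele": np.zeros(nr),
        "dE_polar": np.zeros(nr),
        "dE_nonpolar": np.zeros(nr),
    }
    rec_idx, lig_idx = receptor_sel.indices, ligand_sel.indices
    rec_top = subset_topology(top, rec_idx)
    lig_top = subset_topology(top, lig_idx)

    for f in frames:
        frame = traj.coords[f]
        vdw, ele = mm_pair_energy_matrix(frame, top, receptor_sel, ligand_sel)
        for p, i in enumerate(rec_idx):
            acc["dE_vdw"][res_pos[key_of_atom[i]]] += 0.5 * vdw[p].sum()
            acc["dE_ele"][res_pos[key_of_atom[i]]] += 0.5 * ele[p].sum()
        for q, j in enumerate(lig_idx):
            acc["dE_vdw"][res_pos[key_of_atom[j]]] += 0.5 * vdw[:, q].sum()
            acc["dE_ele"][res_pos[key_of_atom[j]]] += 0.5 * ele[:, q].sum()

        phi_c = reaction_field_potentials(frame, top, grid)
        phi_r = reaction_field_potentials(frame[rec_idx], rec_top, grid)
        phi_l = reaction_field_potentials(frame[lig_idx], lig_top, grid)
        charges = np.asarray(top.charges, float)
        for p, i in enumerate(rec_idx):
            contrib = 0.5 * charges[i] * (phi_c[i] - phi_r[p])
            acc["dE_polar"][res_pos[key_of_atom[i]]] += contrib
        for q, j in enumerate(lig_idx):
            contrib = 0.5 * charges[j] * (phi_c[j] - phi_l[q])
            acc["dE_polar"][res_pos[key_of_atom[j]]] += contrib

        s_c = shrake_rupley_sasa(frame, top, n_points=sasa_points).per_atom
        s_r = shrake_rupley_sasa(
            frame[rec_idx], rec_top, n_points=sasa_points
        ).per_atom
        s_l = shrake_rupley_sasa(
            frame[lig_idx], lig_top, n_points=sasa_points
        ).per_atom
        for p, i in enumerate(rec_idx):
            acc["dE_nonpolar"][res_pos[key_of_atom[i]]] += GAMMA_NONPOLAR * (
                s_c[i] - s_r[p]
            )
        for q, j in enumerate(lig_idx):
            acc["dE_nonpolar"][res_pos[key_of_atom[j]]] += GAMMA_NONPOLAR * (
                s_c[j] - s_l[q]
            )
        # the b offset enters once per subsystem: +b (complex) -b -b = -b in
        # the total; no atom owns it, so spread it uniformly over residues
        acc["dE_nonpolar"] += -B_NONPOLAR / nr

    for k in acc:
        acc[k] /= len(frames)
    df = pd.DataFrame(
        {
            "chain": [k[0] for k in res_keys],
            "resid": [k[1] for k in res_keys],
            "resname": [
                str(top.resnames[top.residue_atom_indices()[k][0]])
                for k in res_keys
            ],
            **acc,
        }
    )
    df["total"] = (
        df["dE_vdw"] + df["dE_ele"] + df["dE_polar"] + df["dE_nonpolar"]
    )
    return df
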