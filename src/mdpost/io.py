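"""Trajectory and parameter-table I/O.

PDB files (ATOM/HETATM records, multi-MODEL for trajectories) are handled
through biotite; DCD coordinate files (CHARMM/X-PLOR dialect, little-endian)
through MDAnalysis' libdcd reader/writer.  A lightweight pre-scan of PDB text
lets parse errors cite the offending line number, which the delegating
libraries do not report.

The per-atom parameter table is whitespace- or comma-delimited text with a
header line ``atom_id charge sigma epsilon radius`` (charge in e, sigma and
radius in Å, epsilon in kcal/mol).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from MDAnalysis.lib.formats.libdcd import DCDFile

from .errors import ParseError, StructuralError
from .topology import Topology
from .trajectory import Trajectory

_PDB_MIN_ATOM_LINE = 54  # through the z-coordinate field


def _prescan_pdb(path: Path) -> None:
    """Reject truncated ATOM/HETATM records, citing the 1-based line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < _PDB_MIN_ATOM_LINE:
                raise ParseError(
                    f"{path}: truncated {rec} record at line {lineno}"
                )


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a Trajectory.

    Parameter columns of the topology are left unset; attach them from a
    parameter table with :func:`read_parameter_table` + :func:`attach_parameters`.
    """
    path = Path(path)
    _prescan_pdb(path)
    try:
        pdbf = PDBFile.read(str(path))
        stack = pdbf.get_structure(model=None)
    except Exception as exc:  # biotite raises various subclasses
        raise ParseError(f"{path}: PDB parse failure: {exc}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no atoms found")
    topo = Topology(
        ids=np.arange(1, stack.array_length() + 1),
        names=np.asarray(stack.atom_name),
        elements=np.asarray(stack.element),
        resids=np.asarray(stack.res_id, dtype=int),
        resnames=np.asarray(stack.res_name),
        chains=np.asarray(stack.chain_id),
    )
    return Trajectory(topo, np.asarray(stack.coord, dtype=float))


def write_pdb(path: str | Path, traj: Trajectory) -> None:
    """Write all frames as MODEL records of one PDB file."""
    top = traj.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    stack.atom_name = top.names.astype("U6")
    stack.element = top.elements.astype("U2")
    stack.res_id = top.resids.astype(int)
    stack.res_name = top.resnames.astype("U5")
    stack.chain_id = top.chains.astype("U4")
    stack.hetero = np.zeros(n, dtype=bool)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def read_dcd(path: str | Path, topology: Topology) -> Trajectory:
    """Read a DCD coordinate file against a known topology."""
    path = Path(path)
    frames = []
    try:
        with DCDFile(str(path)) as f:
            if f.header["natoms"] != topology.n_atoms:
                raise StructuralError(
                    f"{path}: DCD holds {f.header['natoms']} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            # libdcd floors a trailing partial frame away; reject it instead
            body = path.stat().st_size - f._header_size
            if body < f._firstframesize or (
                (body - f._firstframesize) % f._framesize != 0
            ):
                raise StructuralError(
                    f"{path}: DCD frame block of wrong size "
                    f"(file truncated after frame {f.n_frames})"
                )
            for frame in f:
                frames.append(np.array(frame.xyz, dtype=float))
    except StructuralError:
        raise
    except Exception as exc:
        raise StructuralError(
            f"{path}: corrupt or misaligned DCD frame block: {exc}"
        ) from exc
    if not frames:
        raise StructuralError(f"{path}: DCD contains no frames")
    return Trajectory(topology, np.stack(frames))


def write_dcd(path: str | Path, traj: Trajectory) -> None:
    """Write coordinates as little-endian CHARMM-dialect DCD (float32)."""
    with DCDFile(str(path), "w") as f:
        f.write_header(
            remarks="written by mdpost",
            natoms=traj.n_atoms,
            istart=0,
            nsavc=1,
            delta=1.0,
            is_periodic=0,
        )
        for frame in traj.coords:
            f.write(xyz=np.ascontiguousarray(frame, dtype=np.float32))


def trajectory_io(
    path: str | Path,
    mode: str,
    format: str,
    traj: Trajectory | None = None,
    topology: Topology | None = None,
) -> Trajectory | None:
    """Uniform entry point: read or write a trajectory in PDB or DCD format."""
    fmt = format.upper()
    if mode == "r":
        if fmt == "PDB":
            return read_pdb(path)
        if fmt == "DCD":
            if topology is None:
                raise StructuralError("reading DCD requires a topology")
            return read_dcd(path, topology)
    elif mode == "w":
        if traj is None:
            raise StructuralError("writing requires a trajectory")
        if fmt == "PDB":
            write_pdb(path, traj)
            return None
        if fmt == "DCD":
            write_dcd(path, traj)
            return None
    raise ParseError(f"unsupported mode/format: {mode!r}/{format!r}")


# ---------------------------------------------------------------------------
# parameter tables

PARAM_COLUMNS = ["atom_id", "charge", "sigma", "epsilon", "radius"]


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/comma-delimited per-atom parameter table."""
    try:
        df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse parameter table: {exc}") from exc
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: parameter table missing columns {missing}")
    return df[PARAM_COLUMNS]


def write_parameter_table(path: str | Path, table: pd.DataFrame) -> None:
    table[PARAM_COLUMNS].to_csv(path, sep=" ", index=False)


def attach_parameters(topology: Topology, table: pd.DataFrame) -> Topology:
    """Return a topology with charge/LJ/radius columns filled from a table,
    matched on atom id."""
    indexed = table.set_index("atom_id")
    try:
        rows = indexed.loc[topology.ids]
    except KeyError as exc:
        raise StructuralError(f"parameter table missing atom ids: {exc}") from exc
    return Topology(
        ids=topology.ids,
        names=topology.names,
        elements=topology.elements,
        resids=topology.resids,
        resnames=topology.resnames,
        chains=topology.chains,
        charges=rows["charge"].to_numpy(float),
        lj_sigma=rows["sigma"].to_numpy(float),
        lj_epsilon=rows["epsilon"].to_numpy(float),
        radii=rows["radius"].to_numpy(float),
    )
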