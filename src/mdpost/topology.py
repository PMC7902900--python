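"""Topology and atom-selection data model.

A :class:`Topology` holds per-atom identity (name, element, residue, chain)
plus the per-atom force-field-style parameters used by the energetics stage:
partial charge (e), Lennard-Jones sigma (Å) and epsilon (kcal/mol), and the
PB/SASA radius (Å).  Coordinates live in :class:`mdpost.trajectory.Trajectory`.

Selections use a small expression language with ``name``, ``resid``,
``resname``, ``chain`` and ``element`` predicates combined with ``and``::

    name CA
    chain A and resid 1:20
    resname ASP GLU
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError, StructuralError


@dataclass
class Topology:
    """Per-atom identity and parameters for one molecular system.

    All arrays have length ``n_atoms``.  Residue indices are 1-based, as in
    PDB files; atom identifiers are unique integers.
    """

    ids: np.ndarray          # int, unique
    names: np.ndarray        # str, e.g. "CA"
    elements: np.ndarray     # str, e.g. "C"
    resids: np.ndarray       # int, 1-based, non-decreasing within a chain
    resnames: np.ndarray     # str
    chains: np.ndarray       # str, single-character chain ids
    charges: np.ndarray | None = None   # e
    lj_sigma: np.ndarray | None = None  # Å
    lj_epsilon: np.ndarray | None = None  # kcal/mol
    radii: np.ndarray | None = None     # Å (PB / SASA)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("names", "elements", "resids", "resnames", "chains"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"topology field {name!r} has wrong length")
        if len(np.unique(self.ids)) != n:
            raise StructuralError("atom identifiers are not unique")
        for ch in np.unique(self.chains):
            r = self.resids[self.chains == ch]
            if np.any(np.diff(r) < 0):
                raise StructuralError(
                    f"residue indices decrease within chain {ch!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resid) keys."""
        seen: dict[tuple[str, int], None] = {}
        for ch, ri in zip(self.chains, self.resids):
            seen.setdefault((str(ch), int(ri)), None)
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain, resid) -> array of atom indices belonging to it."""
        keys = self.residue_keys()
        out: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
        for i, (ch, ri) in enumerate(zip(self.chains, self.resids)):
            out[(str(ch), int(ri))].append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def total_charge(self) -> float:
        if self.charges is None:
            raise ParameterError("missing per-atom parameter: charges")
        return float(np.sum(self.charges))

    def require_parameters(self, *fields_: str) -> None:
        """Raise if any named parameter array is missing or (for radii) non-positive."""
        for f in fields_:
            arr = getattr(self, f)
            if arr is None:
                raise ParameterError(f"missing per-atom parameter: {f}")
            if f == "radii" and np.any(np.asarray(arr) <= 0):
                bad = int(np.argmax(np.asarray(arr) <= 0))
                raise ParameterError(
                    f"missing/invalid radius for atom id {self.ids[bad]}"
                )

    def select(self, expression: str) -> "AtomSelection":
        return select(self, expression)


@dataclass
class AtomSelection:
    """Ordered, duplicate-free atom indices plus the expression that made them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise SelectionError(f"duplicate indices in selection {self.expression!r}")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology) -> None:
        if len(self.indices) == 0:
            raise SelectionError(f"empty selection {self.expression!r}")
        if self.indices.min() < 0 or self.indices.max() >= topology.n_atoms:
            raise SelectionError(
                f"selection {self.expression!r} has out-of-range indices"
            )


def _parse_int_values(tokens: list[str]) -> np.ndarray:
    vals: list[int] = []
    for t in tokens:
        if ":" in t:
            lo, hi = t.split(":")
            vals.extend(range(int(lo), int(hi) + 1))
        else:
            vals.append(int(t))
    return np.asarray(vals)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Supports ``all`` and ``and``-joined clauses of the form
    ``<field> v1 v2 ...`` where field is one of name/resid/resname/chain/element
    and resid values may be ``lo:hi`` ranges (inclusive).
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    for clause in expr.split(" and "):
        tokens = clause.split()
        key, values = tokens[0].lower(), tokens[1:]
        if key == "all":
            continue
        if not values:
            raise SelectionError(f"clause {clause!r} has no values")
        if key == "name":
            mask &= np.isin(topology.names, values)
        elif key == "resname":
            mask &= np.isin(topology.resnames, values)
        elif key == "chain":
            mask &= np.isin(topology.chains, values)
        elif key == "element":
            mask &= np.isin(topology.elements, values)
        elif key == "resid":
            mask &= np.isin(topology.resids, _parse_int_values(values))
        else:
            raise SelectionError(f"unknown selection keyword {key!r}")
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return AtomSelection(indices=idx, expression=expression)


def subset_topology(topology: Topology, indices: np.ndarray) -> Topology:
    """Topology restricted to the given atom indices (order preserved)."""
    idx = np.asarray(indices, dtype=int)

    def take(arr):
        return None if arr is None else np.asarray(arr)[idx]

    return Topology(
        ids=topology.ids[idx],
        names=topology.names[idx],
        elements=topology.elements[idx],
        resids=topology.resids[idx],
        resnames=topology.resnames[idx],
        chains=topology.chains[idx],
        charges=take(topology.charges),
        lj_sigma=take(topology.lj_sigma),
        lj_epsilon=take(topology.lj_epsilon),
        radii=take(topology.radii),
    )


def parameter_table(topology: Topology) -> pd.DataFrame:
    """Per-atom parameter table (atom id, charge, sigma, epsilon, radius)."""
    return pd.DataFrame(
        {
            "atom_id": topology.ids,
            "charge": topology.charges,
            "sigma": topology.lj_sigma,
            "epsilon": topology.lj_epsilon,
            "radius": topology.radii,
        }
    )
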