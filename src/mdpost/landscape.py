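"""Conformational landscapes over two collective variables and
average-linkage conformational clustering.

The free-energy surface is the Boltzmann inversion of a 2D occupancy
histogram,

    G(b) = -k_B T ln( n_b / n_max ),

referenced to the most populated bin, so min G = 0 and empty bins are
undefined (NaN, masked) rather than zero.  Basins are 4-connected components
of bins with G at or below a depth cutoff, labelled in order of ascending
minimum G.  Conformational clustering is agglomerative average linkage on the
pairwise RMSD matrix of globally superposed frames, with per-cluster medoids
(the frame minimising summed RMSD to its cluster mates; ties go to the lowest
frame index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError, UndefinedStatisticError
from .topology import AtomSelection
from .trajectory import Trajectory

KBOLTZ = 0.0019872  # kcal mol^-1 K^-1


@dataclass
class CVSeries:
    """A named per-frame scalar collective variable (Å)."""

    name: str
    values: np.ndarray
    atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise UndefinedStatisticError(f"CV {self.name!r} has non-finite values")


@dataclass
class PMFGrid:
    """2D binned free-energy surface over two collective variables."""

    edges1: np.ndarray
    edges2: np.ndarray
    counts: np.ndarray          # (n1, n2) frame counts
    free_energy: np.ndarray     # kcal/mol; NaN on empty bins
    temperature: float          # K
    basin_labels: np.ndarray | None = None  # -1 = no basin

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def pmf_2d(
    cv1: CVSeries,
    cv2: CVSeries,
    bins: int | tuple = 50,
    temperature: float = 300.0,
    range_padding: float = 0.05,
) -> PMFGrid:
    """Potential of mean force over (cv1, cv2).

    The grid spans the observed CV ranges padded by ``range_padding`` (5%
    default).  Free energies are relative to the most occupied bin with
    k_B = 0.0019872 kcal/(mol K); empty bins are NaN.
    """
    if len(cv1.values) == 0 or len(cv2.values) == 0:
        raise UndefinedStatisticError("empty collective-variable series")
    if len(cv1.values) != len(cv2.values):
        raise UndefinedStatisticError("CV series lengths differ")

    def padded_range(v):
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo if hi > lo else 1.0
        return lo - range_padding * span, hi + range_padding * span

    counts, e1, e2 = np.histogram2d(
        cv1.values, cv2.values, bins=bins,
        range=[padded_range(cv1.values), padded_range(cv2.values)],
    )
    n_max = counts.max()
    g = np.full_like(counts, np.nan, dtype=float)
    occ = counts > 0
    g[occ] = -KBOLTZ * temperature * np.log(counts[occ] / n_max)
    return PMFGrid(e1, e2, counts, g, temperature)


def segment_basins(
    grid: PMFGrid,
    depth_cutoff: float = 1.0,
    cv1: CVSeries | None = None,
    cv2: CVSeries | None = None,
) -> tuple[PMFGrid, np.ndarray | None]:
    """Label free-energy basins and optionally assign frames to them.

    Basins are 4-connected components of occupied bins with
    G <= depth_cutoff (kcal/mol above the global minimum), labelled 0, 1, ...
    by ascending minimum G.  If the CV series are given, the second return
    value assigns each frame to its bin's basin (-1 = unassigned).
    """
    if depth_cutoff <= 0:
        raise ParameterError("depth_cutoff must be positive")
    low = np.zeros_like(grid.counts, dtype=bool)
    occ = grid.occupied
    low[occ] = grid.free_energy[occ] <= depth_cutoff
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    raw_labels, n_comp = ndimage.label(low, structure=structure)

    # order components by their minimum free energy
    comp_min = [
        (grid.free_energy[raw_labels == c].min(), c) for c in range(1, n_comp + 1)
    ]
    comp_min.sort()
    remap = {c: rank for rank, (_, c) in enumerate(comp_min)}
    basin = np.full(grid.counts.shape, -1, dtype=int)
    for c, rank in remap.items():
        basin[raw_labels == c] = rank
    labelled = PMFGrid(
        grid.edges1, grid.edges2, grid.counts, grid.free_energy,
        grid.temperature, basin_labels=basin,
    )

    frame_basins = None
    if cv1 is not None and cv2 is not None:
        i1 = np.clip(np.digitize(cv1.values, grid.edges1) - 1, 0, basin.shape[0] - 1)
        i2 = np.clip(np.digitize(cv2.values, grid.edges2) - 1, 0, basin.shape[1] - 1)
        frame_basins = basin[i1, i2]
    return labelled, frame_basins


# ---------------------------------------------------------------------------
# average-linkage clustering

@dataclass
class ClusterAssignment:
    labels: np.ndarray          # per-frame cluster label, 0-based
    medoids: np.ndarray         # per-cluster medoid frame index
    merge_history: np.ndarray   # scipy linkage matrix
    rmsd_matrix: np.ndarray


def pairwise_rmsd_matrix(traj: Trajectory, selection: AtomSelection | None = None) -> np.ndarray:
    """All-pairs coordinate RMSD over a selection, with no per-pair refit
    (frames are expected to be superposed onto a common reference already)."""
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    x = traj.coords[:, idx, :]
    f = x.shape[0]
    # ||a-b||^2 summed over atoms via the Gram trick, then / n_atoms
    flat = x.reshape(f, -1)
    sq = np.sum(flat * flat, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    d2 = np.maximum(d2, 0.0) / x.shape[1]
    m = np.sqrt(d2)
    np.fill_diagonal(m, 0.0)
    return 0.5 * (m + m.T)


def _medoid(rmsd: np.ndarray, members: np.ndarray) -> int:
    sub = rmsd[np.ix_(members, members)]
    totals = sub.sum(axis=1)
    # ties resolved toward the lowest frame index (argmin is first minimum)
    return int(members[int(np.argmin(totals))])


def cluster_average_linkage(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    n_clusters: int = 2,
) -> ClusterAssignment:
    """Agglomerative average-linkage clustering of frames on pairwise RMSD."""
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if n_clusters > traj.n_frames:
        raise ParameterError("n_clusters exceeds the frame count")
    rmsd = pairwise_rmsd_matrix(traj, selection)
    if traj.n_frames == 1:
        return ClusterAssignment(
            np.zeros(1, dtype=int), np.zeros(1, dtype=int),
            np.empty((0, 4)), rmsd,
        )
    z = linkage(squareform(rmsd, checks=False), method="average")
    labels_1based = fcluster(z, t=n_clusters, criterion="maxclust")
    # relabel clusters by first appearance for determinism
    order: dict[int, int] = {}
    labels = np.empty_like(labels_1based)
    for i, lab in enumerate(labels_1based):
        order.setdefault(lab, len(order))
        labels[i] = order[lab]
    medoids = np.array(
        [_medoid(rmsd, np.nonzero(labels == c)[0]) for c in range(labels.max() + 1)]
    )
    return ClusterAssignment(labels, medoids, z, rmsd)
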