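"""Configuration-driven orchestration of the full analysis battery.

A single YAML config describes one or more systems (file inputs or synthetic
blocks) and which stages to run — geometry, landscape, clustering,
energetics, network — with all stage parameters defaulted as in the
individual modules.  Outputs land under ``outdir/<system>/<stage>/`` as
delimited text, and a machine-readable ``summary.json`` enumerates every
artifact with its stage.  One global seed fans out to per-stage seeds by
fixed offsets so toggling a stage never changes another stage's randomness.
Every defaulted parameter is logged, making gap-filling decisions auditable
per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mdio
from .errors import ConfigError, StageError
from .landscape import CVSeries, cluster_average_linkage, pmf_2d, segment_basins
from .energetics import mmpbsa_binding, per_residue_decomposition
from .network import build_network, dccm, detect_communities, mask_dccm, paths
from .pbsolver import PBGridSpec
from .synthetic import (
    SyntheticSpec,
    build_toy_system,
    sample_correlated_trajectory,
    sample_two_state_cv,
)
from .trajectory import (
    Trajectory,
    align_to_mean,
    geometry_series,
    persistence_table,
    rmsf,
    superpose,
)

log = logging.getLogger("mdpost.pipeline")

STAGE_SEED_OFFSETS = {
    "synthetic": 11,
    "geometry": 23,
    "landscape": 37,
    "clustering": 41,
    "energetics": 53,
    "network": 67,
}

STAGE_ORDER = ["geometry", "landscape", "clustering", "energetics", "network"]


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration."""

    systems: dict                 # name -> input block
    stages: dict                  # stage name -> stage params (dict) or None
    selections: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "mdpost_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        systems = raw.get("systems")
        if systems is None:
            # single-system shorthand: inputs/synthetic at top level
            block = {}
            for key in ("inputs", "synthetic"):
                if key in raw:
                    block[key] = raw[key]
            if not block:
                raise ConfigError("config needs 'systems', 'inputs' or 'synthetic'")
            systems = {"system": block}
        stages = raw.get("stages")
        if not stages:
            raise ConfigError("config enables no stages")
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return cls(
            systems=systems,
            stages={k: (v or {}) for k, v in stages.items()},
            selections=raw.get("selections", {}),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "mdpost_out")),
        )

    def to_dict(self) -> dict:
        return {
            "systems": self.systems,
            "stages": self.stages,
            "selections": self.selections,
            "seed": self.seed,
            "outdir": self.outdir,
        }


def _load_system(name: str, block: dict, seed: int) -> Trajectory:
    if "inputs" in block:
        inputs = block["inputs"]
        topo_path = inputs.get("topology")
        if topo_path is None or not Path(topo_path).exists():
            raise ConfigError(f"system {name!r}: topology file not found")
        traj = mdio.read_pdb(topo_path)
        if "parameters" in inputs:
            table = mdio.read_parameter_table(inputs["parameters"])
            traj = Trajectory(
                mdio.attach_parameters(traj.topology, table), traj.coords
            )
        if "trajectory" in inputs:
            dcd_path = inputs["trajectory"]
            if not Path(dcd_path).exists():
                raise ConfigError(f"system {name!r}: trajectory file not found")
            traj = mdio.read_dcd(dcd_path, traj.topology)
        return traj
    if "synthetic" in block:
        syn = dict(block["synthetic"])
        n_frames = int(syn.pop("n_frames", 200))
        sigma = float(syn.pop("fluctuation_sigma", 0.5))
        coupling = float(syn.pop("coupling", 0.3))
        layout = syn.pop("chains", None)  # e.g. [["A", 6], ["B", 2]]
        spec = SyntheticSpec(
            n_residues=int(syn.pop("n_residues", 10)),
            atoms_per_residue=int(syn.pop("atoms_per_residue", 1)),
            chain_layout=(
                None if layout is None
                else [(str(c), int(n)) for c, n in layout]
            ),
            seed=seed,
        )
        top = build_toy_system(spec)
        n = top.n_atoms
        cov = sigma**2 * (
            (1 - coupling) * np.eye(n) + coupling * np.ones((n, n))
        )
        traj, _ = sample_correlated_trajectory(top, cov, n_frames, seed=seed)
        return traj
    raise ConfigError(f"system {name!r} has neither 'inputs' nor 'synthetic'")


def _resolve_selection(traj: Trajectory, selections: dict, name_or_expr: str):
    expr = selections.get(name_or_expr, name_or_expr)
    return traj.topology.select(expr)


def _write_table(path: Path, df) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, only_stage: str | None = None) -> dict:
    """Run all enabled stages for every system; return the summary dict.

    The summary (also written to ``outdir/summary.json``) lists every
    produced artifact with its system and stage.  A stage failure aborts the
    run with a :class:`StageError` naming the stage; artifacts written by
    earlier stages are left intact.
    """
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "systems": {}, "applied_defaults": []}

    stages = dict(config.stages)
    if only_stage is not None:
        if only_stage not in stages:
            raise ConfigError(f"stage {only_stage!r} not enabled in config")
        stages = {only_stage: stages[only_stage]}

    for sys_name in sorted(config.systems):
        block = config.systems[sys_name]
        traj = _load_system(
            sys_name, block, config.seed + STAGE_SEED_OFFSETS["synthetic"]
        )
        sys_out = outdir / sys_name
        artifacts: list[dict] = []

        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            params = stages[stage]
            try:
                produced = _run_stage(
                    stage, params, traj, config, sys_out / stage, summary
                )
            except Exception as exc:
                raise StageError(
                    f"stage {stage!r} failed on system {sys_name!r}: {exc}"
                ) from exc
            for p in produced:
                artifacts.append(
                    {"stage": stage, "path": str(Path(p).relative_to(outdir))}
                )
        summary["systems"][sys_name] = {
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
            "artifacts": artifacts,
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary


def _run_stage(
    stage: str,
    params: dict,
    traj: Trajectory,
    config: PipelineConfig,
    stage_dir: Path,
    summary: dict,
) -> list[Path]:
    import pandas as pd

    stage_dir.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def note_default(key, value):
        msg = f"{stage}: defaulted {key} = {value}"
        log.info(msg)
        summary["applied_defaults"].append(msg)

    if stage == "geometry":
        sel_expr = params.get("selection", "all")
        aligned, rmsd_series = superpose(
            traj, selection=_resolve_selection(traj, config.selections, sel_expr)
        )
        df = pd.DataFrame({"frame": np.arange(len(rmsd_series)), "rmsd": rmsd_series})
        _write_table(stage_dir / "rmsd.tsv", df)
        produced.append(stage_dir / "rmsd.tsv")
        if traj.n_frames >= 2:
            mean_aligned = align_to_mean(aligned)
            fl = rmsf(mean_aligned)
            df = pd.DataFrame({"atom_id": traj.topology.ids, "rmsf": fl})
            _write_table(stage_dir / "rmsf.tsv", df)
            produced.append(stage_dir / "rmsf.tsv")
        pairs = [tuple(p) for p in params.get("pairs", [])]
        if pairs:
            bw = params.get("bin_width")
            if bw is None:
                bw = 0.1
                note_default("bin_width", bw)
            for gs in geometry_series(traj, pairs, bin_width=bw):
                tag = "-".join(str(a) for a in gs.atoms)
                df = pd.DataFrame({"frame": np.arange(len(gs.values)),
                                   gs.kind: gs.values})
                _write_table(stage_dir / f"{gs.kind}_{tag}.tsv", df)
                produced.append(stage_dir / f"{gs.kind}_{tag}.tsv")
        contacts = [tuple(map(int, p)) for p in params.get("contact_pairs", [])]
        if contacts:
            cutoff = params.get("contact_cutoff", 4.0)
            fractions, _series = persistence_table(traj, contacts, cutoff=cutoff)
            df = pd.DataFrame(
                {
                    "pair": [f"{a}-{b}" for a, b in fractions],
                    "fraction": list(fractions.values()),
                }
            )
            _write_table(stage_dir / "persistence.tsv", df)
            produced.append(stage_dir / "persistence.tsv")

    elif stage == "landscape":
        seed = config.seed + STAGE_SEED_OFFSETS["landscape"]
        if "cv_atoms" in params:
            (i1, j1), (i2, j2) = params["cv_atoms"]
            gs = geometry_series(traj, [(i1, j1), (i2, j2)])
            cv1 = CVSeries("d1", gs[0].values)
            cv2 = CVSeries("d2", gs[1].values)
        else:
            centers = params.get("basin_centers", [(6.0, 6.0), (10.0, 9.0)])
            occ = params.get("occupancies", [0.8, 0.2])
            widths = params.get("basin_widths", 0.4)
            note_default("synthetic CV basins", (centers, occ, widths))
            cv1, cv2, _ = sample_two_state_cv(
                centers, widths, occ, n_frames=traj.n_frames, seed=seed
            )
        bins = params.get("bins", 50)
        temperature = params.get("temperature", 300.0)
        grid = pmf_2d(cv1, cv2, bins=bins, temperature=temperature)
        grid, frame_basins = segment_basins(
            grid, params.get("depth_cutoff", 1.0), cv1, cv2
        )
        rows = []
        for i in range(grid.counts.shape[0]):
            for j in range(grid.counts.shape[1]):
                rows.append(
                    (grid.edges1[i], grid.edges2[j], int(grid.counts[i, j]),
                     grid.free_energy[i, j], int(grid.basin_labels[i, j]))
                )
        df = pd.DataFrame(rows, columns=["cv1_edge", "cv2_edge", "count",
                                         "free_energy", "basin"])
        _write_table(stage_dir / "pmf.tsv", df)
        produced.append(stage_dir / "pmf.tsv")
        df = pd.DataFrame({"frame": np.arange(len(frame_basins)),
                           "basin": frame_basins})
        _write_table(stage_dir / "frame_basins.tsv", df)
        produced.append(stage_dir / "frame_basins.tsv")

    elif stage == "clustering":
        sel_expr = params.get("selection", "name CA")
        sel = _resolve_selection(traj, config.selections, sel_expr)
        aligned, _ = superpose(traj, selection=sel)
        n_clusters = params.get("n_clusters", 2)
        assignment = cluster_average_linkage(aligned, sel, n_clusters)
        df = pd.DataFrame({"frame": np.arange(len(assignment.labels)),
                           "cluster": assignment.labels})
        _write_table(stage_dir / "clusters.tsv", df)
        df = pd.DataFrame({"cluster": np.arange(len(assignment.medoids)),
                           "medoid_frame": assignment.medoids})
        _write_table(stage_dir / "medoids.tsv", df)
        produced += [stage_dir / "clusters.tsv", stage_dir / "medoids.tsv"]

    elif stage == "energetics":
        rec = _resolve_selection(traj, config.selections,
                                 params.get("receptor", "chain A"))
        lig = _resolve_selection(traj, config.selections,
                                 params.get("ligand", "chain B"))
        pb = PBGridSpec(**params.get("pb", {}))
        stride = params.get("stride", 10)
        report = mmpbsa_binding(traj, rec, lig, pb, frame_stride=stride)
        _write_table(stage_dir / "binding.tsv", report.summary())
        produced.append(stage_dir / "binding.tsv")
        if params.get("decompose", False):
            df = per_residue_decomposition(traj, rec, lig, pb, frame_stride=stride)
            _write_table(stage_dir / "per_residue.tsv", df)
            produced.append(stage_dir / "per_residue.tsv")

    elif stage == "network":
        sel_expr = params.get("selection", "name CA")
        sel = _resolve_selection(traj, config.selections, sel_expr)
        aligned, _ = superpose(traj, selection=sel)
        c = dccm(aligned, sel)
        np.savetxt(stage_dir / "dccm.tsv", c.values, delimiter="\t", fmt="%.6f")
        produced.append(stage_dir / "dccm.tsv")
        masked = mask_dccm(c, params.get("mask_threshold", 0.3))
        np.savetxt(stage_dir / "dccm_masked.tsv", masked.filled(np.nan),
                   delimiter="\t", fmt="%.6f")
        produced.append(stage_dir / "dccm_masked.tsv")
        net = build_network(
            aligned if params.get("contacts_from_selection", False) else traj,
            c,
            contact_cutoff=params.get("contact_cutoff", 4.5),
            persistence=params.get("persistence", 0.75),
        )
        rows = [
            (u, v, d["persistence"], d["correlation"], d["weight"])
            for u, v, d in net.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["node_i", "node_j", "persistence",
                                         "correlation", "weight"])
        _write_table(stage_dir / "edges.tsv", df)
        produced.append(stage_dir / "edges.tsv")
        if net.graph.number_of_edges() > 0:
            part = detect_communities(net)
            df = pd.DataFrame(
                {"node": sorted(part.node_labels),
                 "community": [part.node_labels[n] for n in sorted(part.node_labels)]}
            )
            _write_table(stage_dir / "communities.tsv", df)
            produced.append(stage_dir / "communities.tsv")
            if "path_source" in params and "path_sink" in params:
                ps = paths(net, params["path_source"], params["path_sink"],
                           tolerance=params.get("path_tolerance", 20.0))
                df = pd.DataFrame(
                    {"length": [l for l, _ in ps.paths],
                     "nodes": ["-".join(map(str, p)) for _, p in ps.paths]}
                )
                _write_table(stage_dir / "paths.tsv", df)
                produced.append(stage_dir / "paths.tsv")
    else:
        raise ConfigError(f"unknown stage {stage!r}")

    return produced
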