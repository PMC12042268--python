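"""Run orchestration: configuration, block-parallel analysis, reports.

A :class:`RunConfig` names the inputs and the metrics to compute;
:func:`run` executes it and writes a report bundle (CSV series, matrix
CSVs, optional heatmaps/meshes, and a machine-readable ``summary.json``
with a Table-style row: memIT, nISA, ccMat total, doMat total, each with
a block-averaged error).  :func:`parallel_blocks` splits the frame range
into contiguous blocks whose accumulators merge additively, so the
merged result is identical to a single pass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from . import contacts, density, dynamics, trajectory, voronoi
from .contacts import CarbonMatrix, carbon_position_table, _position_labels

ALL_METRICS = ("nisa", "ccmat", "domat", "memit")


@dataclass
class RunConfig:
    """Validated, serializable description of one analysis run."""

    psf: str = ""
    trajectory: str = ""
    outdir: str = "interdigit_out"
    metrics: tuple = ALL_METRICS
    start: int | None = None
    stop: int | None = None
    stride: int | None = None
    cutoff: float = contacts.DEFAULT_CUTOFF        # Angstrom
    bin_width: float = density.DEFAULT_BIN_WIDTH   # Angstrom
    memit_variant: str = "membplugin"
    anchor_name: str = "P"
    lipid_resnames: tuple = ()
    water_resnames: tuple = ()
    write_heatmaps: bool = False
    write_mesh: bool = False
    map_resolution: float = 1.0                    # Angstrom
    n_blocks: int = 1
    seed: int = 0

    def __post_init__(self):
        self.metrics = tuple(self.metrics)
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.cutoff <= 0 or self.bin_width <= 0 or self.map_resolution <= 0:
            raise ValueError("cutoff, bin width and map resolution must be > 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BlockResult:
    """Additively mergeable per-block accumulators."""

    n_frames: int = 0
    rows: list = field(default_factory=list)       # per-frame records
    ccmat_sum: np.ndarray | None = None
    carbon_top: density.ProfileAccumulator | None = None
    carbon_bottom: density.ProfileAccumulator | None = None
    leaflet_mass: density.ProfileAccumulator | None = None

    def merge(self, other: "BlockResult"):
        self.n_frames += other.n_frames
        self.rows.extend(other.rows)
        if other.ccmat_sum is not None:
            self.ccmat_sum = (other.ccmat_sum if self.ccmat_sum is None
                              else self.ccmat_sum + other.ccmat_sum)
        for name in ("carbon_top", "carbon_bottom", "leaflet_mass"):
            mine, theirs = getattr(self, name), getattr(other, name)
            if theirs is not None:
                if mine is None:
                    setattr(self, name, theirs)
                else:
                    mine.merge(theirs)
        return self


def _make_accumulators(topology, chains, leaflets, z_edges, metrics):
    labels, n1, n2 = _position_labels(topology, chains)
    carbon_top = carbon_bottom = leaflet_mass = None
    if "domat" in metrics:
        accs = {}
        for side, name in ((+1, "top"), (-1, "bottom")):
            atoms, positions = carbon_position_table(topology, chains,
                                                     leaflets, side)
            sels = [atoms[positions == p] for p in range(n1 + n2)]
            accs[name] = density.ProfileAccumulator(
                z_edges, sels, labels=[f"{name}:{l}" for l in labels])
        carbon_top, carbon_bottom = accs["top"], accs["bottom"]
    if "memit" in metrics:
        atom_labels = leaflets.atom_labels(topology)
        sels, weights, labs = [], [], []
        for side, name in ((+1, "top"), (-1, "bottom")):
            sel = np.flatnonzero(atom_labels == side)
            sels.append(sel)
            weights.append(topology.masses[sel])
            labs.append(f"{name} leaflet mass density")
        leaflet_mass = density.ProfileAccumulator(z_edges, sels, weights, labs)
    return carbon_top, carbon_bottom, leaflet_mass


def _analyze_block(topology, chains, leaflets, frames, frame_offset,
                   config: RunConfig, z_edges) -> BlockResult:
    result = BlockResult()
    result.carbon_top, result.carbon_bottom, result.leaflet_mass = \
        _make_accumulators(topology, chains, leaflets, z_edges, config.metrics)
    for k, f in enumerate(frames):
        row = {"frame": frame_offset + k, "time": f.time, "axy": f.axy}
        if "nisa" in config.metrics:
            diagram = voronoi.tessellate(f, topology)
            mesh = voronoi.interface_mesh(diagram, leaflets, topology)
            row["isa"] = mesh.total_area
            row["nisa"] = voronoi.nisa(mesh)
        if "ccmat" in config.metrics:
            m = contacts.count_contacts(f, topology, chains, leaflets,
                                        config.cutoff)
            row["contacts"] = m.total
            result.ccmat_sum = (m.values if result.ccmat_sum is None
                                else result.ccmat_sum + m.values)
        for acc in (result.carbon_top, result.carbon_bottom,
                    result.leaflet_mass):
            if acc is not None:
                acc.add_frame(f)
        result.rows.append(row)
        result.n_frames += 1
    return result


def _series_error(series: np.ndarray):
    """Block-averaged SE where possible, naive SE otherwise (flagged)."""
    if len(series) >= 32 and np.ptp(series) > 0:
        r = dynamics.block_average_error(series)
        return r.se, "block-averaged"
    if len(series) < 2 or np.ptp(series) == 0:
        return 0.0, "degenerate"
    return float(np.std(series, ddof=1) / np.sqrt(len(series))), "naive"


def _finalize(result: BlockResult, topology, chains, config: RunConfig):
    labels, n1, n2 = _position_labels(topology, chains)
    summary = {"n_frames": result.n_frames, "metrics": {},
               "config_hash": config.digest(), "version": __version__}
    outputs = {"rows": result.rows}
    if "nisa" in config.metrics:
        series = np.array([r["nisa"] for r in result.rows])
        se, kind = _series_error(series)
        summary["metrics"]["nisa"] = {"value": float(series.mean()),
                                      "error": se, "error_kind": kind}
    if "ccmat" in config.metrics:
        series = np.array([r["contacts"] for r in result.rows])
        se, kind = _series_error(series)
        ccmat = CarbonMatrix(values=result.ccmat_sum / result.n_frames,
                             row_labels=labels, col_labels=labels,
                             n_sn1=n1, n_sn2=n2)
        outputs["ccmat"] = ccmat
        summary["metrics"]["ccmat_total"] = {
            "value": ccmat.total, "error": se, "error_kind": kind,
            "quadrants": ccmat.quadrant_sums()}
    if "domat" in config.metrics:
        k = n1 + n2
        top = [result.carbon_top.profile(i) for i in range(k)]
        bot = [result.carbon_bottom.profile(i) for i in range(k)]
        values = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                values[i, j] = density.overlap_integral(top[i], bot[j])
        dom = CarbonMatrix(values=values, row_labels=labels, col_labels=labels,
                           n_sn1=n1, n_sn2=n2, units="A^-2")
        outputs["domat"] = dom
        outputs["carbon_profiles"] = (top, bot)
        summary["metrics"]["domat_total"] = {
            "value": dom.total, "quadrants": dom.quadrant_sums()}
    if "memit" in config.metrics:
        rt = result.leaflet_mass.profile(0)
        rb = result.leaflet_mass.profile(1)
        t, b = rt.values, rb.values
        dz = rt.bin_width
        total = (t + b).sum() * dz
        report = {"min-ratio": float(2 * np.minimum(t, b).sum() * dz / total)}
        s = t + b
        with np.errstate(invalid="ignore", divide="ignore"):
            ov = np.where(s > 0, 4 * t * b / s**2, 0.0)
        report["membplugin"] = float((ov * s / total).sum() * dz)
        outputs["leaflet_profiles"] = (rt, rb)
        summary["metrics"]["memit"] = {
            "value": report[config.memit_variant],
            "variant": config.memit_variant, "variants": report}
    return summary, outputs


def _load_system(config: RunConfig):
    kwargs = {}
    if config.lipid_resnames:
        kwargs["lipid_resnames"] = tuple(config.lipid_resnames)
    if config.water_resnames:
        kwargs["water_resnames"] = tuple(config.water_resnames)
    topology, frames = trajectory.load_trajectory(
        config.psf, config.trajectory, config.start, config.stop,
        config.stride, **kwargs)
    chains = trajectory.index_chains(topology)
    frames = trajectory.prepare_frames(topology, frames, chains)
    leaflets = trajectory.assign_leaflets(topology, frames,
                                          anchor_name=config.anchor_name)
    return topology, chains, leaflets, frames


def analyze(topology, chains, leaflets, frames, config: RunConfig,
            n_blocks: int | None = None):
    """Compute the configured metrics over prepared frames.

    Frames are split into ``n_blocks`` contiguous blocks (each analyzed
    independently, accumulators merged additively); the result does not
    depend on the block count.  Returns ``(summary, outputs)``.
    """
    n_blocks = config.n_blocks if n_blocks is None else n_blocks
    frames = list(frames)
    if n_blocks > len(frames):
        raise ValueError("more blocks than frames")
    z_edges = density._global_z_edges(frames, config.bin_width)
    bounds = np.linspace(0, len(frames), n_blocks + 1).astype(int)
    merged = None
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        block = _analyze_block(topology, chains, leaflets, frames[lo:hi],
                               lo, config, z_edges)
        merged = block if merged is None else merged.merge(block)
    return _finalize(merged, topology, chains, config)


def _write_outputs(summary, outputs, topology, chains, leaflets, frames,
                   config: RunConfig, outdir):
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    pd.DataFrame(outputs["rows"]).to_csv(outdir / "series.csv", index=False)
    for name in ("ccmat", "domat"):
        if name in outputs:
            outputs[name].to_dataframe().to_csv(outdir / f"{name}.csv")
            if config.write_heatmaps:
                _heatmap(outputs[name], outdir / f"{name}.png")
    if "leaflet_profiles" in outputs:
        rt, rb = outputs["leaflet_profiles"]
        pd.DataFrame({"z": rt.z_centers, "rho_top": rt.values,
                      "rho_bottom": rb.values}).to_csv(
            outdir / "leaflet_mass_profiles.csv", index=False)
    if config.write_mesh and "nisa" in config.metrics and frames:
        diagram = voronoi.tessellate(frames[0], topology)
        mesh = voronoi.interface_mesh(diagram, leaflets, topology)
        voronoi.export_mesh(mesh, outdir / "interface_frame0.obj")
        values, (xe, ye) = voronoi.intensity_map(mesh, config.map_resolution)
        np.savetxt(outdir / "intensity_map_frame0.csv", values, delimiter=",")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _heatmap(matrix: CarbonMatrix, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(matrix.values, origin="lower", cmap="hot",
                   interpolation="nearest")
    k = matrix.n_sn1
    ax.axhline(k - 0.5, color="w", lw=0.8)
    ax.axvline(k - 0.5, color="w", lw=0.8)
    ax.set_xlabel("bottom-leaflet carbon")
    ax.set_ylabel("top-leaflet carbon")
    fig.colorbar(im, ax=ax, label=matrix.units)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run(config: RunConfig):
    """Execute a full configured analysis and write the report bundle."""
    topology, chains, leaflets, frames = _load_system(config)
    summary, outputs = analyze(topology, chains, leaflets, frames, config)
    _write_outputs(summary, outputs, topology, chains, leaflets, frames,
                   config, config.outdir)
    return summary


def parallel_blocks(config: RunConfig, n_blocks: int):
    """Run with the frame range split into ``n_blocks`` contiguous blocks.

    Block results merge additively, so all per-frame series and averaged
    matrices are identical to the single-pass output.
    """
    topology, chains, leaflets, frames = _load_system(config)
    summary, outputs = analyze(topology, chains, leaflets, frames, config,
                               n_blocks=n_blocks)
    _write_outputs(summary, outputs, topology, chains, leaflets, frames,
                   config, config.outdir)
    return summary
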