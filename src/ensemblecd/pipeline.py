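"""Config-driven orchestration of the full protocol.

The pipeline mirrors the protocol's flow: superpose the free-MD
trajectory, run essential dynamics, build the free-energy landscape,
weight and extract representative conformations; then, per conformation,
analyse a constrained trajectory into solvation-shell basins with
hierarchical weights; finally convolve per-conformer stick spectra and
combine them with the weights into ensemble eps/Deps curves.

Every stage writes CSV reports (plus structures/plots) into the output
directory, stamped with a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import essential_dynamics as ed
from . import landscape as ls
from . import solvation_shell as sh
from . import spectra as sp
from . import trajectory_io as tio
from .errors import ConfigError, DataError
from .superposition import iterative_fit

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable).

    Temperatures are entered in Celsius, as spectroscopic conditions are
    usually quoted, and converted to Kelvin once at load time.
    """

    # inputs
    trajectory: str | None = None
    topology: str | None = None
    constrained_trajectories: dict[str, str] = field(default_factory=dict)
    sticks: dict[str, str] = field(default_factory=dict)
    weights_csv: str | None = None

    # analysis parameters
    selection: str = "backbone"
    fit_selection: str | None = None       # defaults to `selection`
    temperature_celsius: float = 30.0
    bins: tuple[int, int] = (100, 100)
    cutoff_kJmol: float = 3.0
    representatives_per_basin: int = 1
    n_solvent: int = 30
    solvent_site: str = "oxygen"
    ellipsoid_padding_nm: float = 0.0

    # spectra parameters
    hwhm_eV: float = 0.4
    lambda_min_nm: float = 170.0
    lambda_max_nm: float = 260.0
    grid_points: int = 2000
    rotatory_units: str = "1e-40cgs"
    plot: bool = False

    # bookkeeping
    output_dir: str = "ensemblecd_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fit_selection is None:
            self.fit_selection = self.selection
        if isinstance(self.bins, (list, tuple)):
            self.bins = tuple(int(b) for b in self.bins)
        else:
            self.bins = (int(self.bins), int(self.bins))
        if self.cutoff_kJmol <= 0:
            raise ConfigError("cutoff_kJmol must be positive")
        if self.representatives_per_basin < 1:
            raise ConfigError("representatives_per_basin must be >= 1")
        if self.n_solvent < 1:
            raise ConfigError("n_solvent must be >= 1")
        if self.solvent_site not in ("oxygen", "cog"):
            raise ConfigError(f"unknown solvent_site {self.solvent_site!r}")
        if self.rotatory_units not in ("1e-40cgs", "raw_cgs"):
            raise ConfigError(f"unknown rotatory_units {self.rotatory_units!r}")
        if self.hwhm_eV <= 0:
            raise ConfigError("hwhm_eV must be positive")
        self.thermo = ls.Thermo.from_celsius(self.temperature_celsius)
        logger.info("temperature %.2f C = %.2f K", self.temperature_celsius,
                    self.thermo.temperature)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {unknown}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Hash of the scientific parameters (the output location excluded)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def outdir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ensemblecd stage={stage} config={config.digest()}\n")
        df.to_csv(fh, index=False)
    logger.info("wrote %s", path)


def _read_report_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stage 1: free-MD -> conformational basins and representatives
# ---------------------------------------------------------------------------

@dataclass
class SoluteStageResult:
    trajectory: tio.Trajectory
    model: ed.EDModel
    projection: ed.Projection | None = None
    grid: ls.LandscapeGrid | None = None
    basins: list[ls.Basin] | None = None


def run_solute_stage(config: RunConfig, through: str = "extract") -> SoluteStageResult:
    """Superposition -> ED -> landscape -> representative extraction.

    ``through`` limits the stage for the partial CLI verbs: ``"ed"`` stops
    after the eigen-analysis, ``"landscape"`` after basin detection,
    ``"extract"`` (default) also pulls representative structures.
    """
    if config.trajectory is None:
        raise ConfigError("no trajectory configured")
    if through not in ("ed", "landscape", "extract"):
        raise ConfigError(f"unknown stage bound {through!r}")
    out = config.outdir()

    traj = tio.read_trajectory(config.trajectory, config.topology)
    selection = tio.select(traj, config.selection)
    fit_sel = tio.select(traj, config.fit_selection)
    logger.info("stage solute: %d frames, %d atoms, %d selected",
                traj.n_frames, traj.n_atoms, len(selection))

    fitted = iterative_fit(traj, fit_sel)
    model = ed.build_covariance(fitted, selection)
    _write_csv(model.spectrum_frame(), out / "eigenvalues.csv", config, "ed")
    frac2 = ed.fluctuation_fraction(model, min(2, model.n_dof))
    logger.info("first two eigenvectors capture %.1f%% of the fluctuation",
                100 * frac2)
    result = SoluteStageResult(trajectory=fitted, model=model)
    if through == "ed":
        return result

    proj = ed.project(fitted, model, n_vectors=2)
    _write_csv(proj.to_frame(), out / "projections.csv", config, "ed")
    grid = ls.build_grid(proj, bins=config.bins, thermo=config.thermo)
    basins = ls.detect_basins(grid, cutoff=config.cutoff_kJmol)
    result.projection, result.grid, result.basins = proj, grid, basins
    grid.to_frame().to_csv(out / "landscape.csv", index=False, header=False)
    if through == "landscape":
        _write_csv(ls.basin_report(basins), out / "basins.csv", config, "landscape")
        return result

    for basin in basins:
        basin.representatives = ls.select_representatives(
            basin, proj, k=config.representatives_per_basin, seed=config.seed
        )
        reps = tio.subset_trajectory(traj, basin.representatives)
        tio.write_trajectory(reps, out / f"representatives_{basin.id}.pdb")
    _write_csv(ls.basin_report(basins), out / "basins.csv", config, "extract")
    weights = pd.DataFrame(
        {"label": [b.id for b in basins], "weight": [b.population for b in basins]}
    )
    _write_csv(weights, out / "weights_solute.csv", config, "extract")
    return result


# ---------------------------------------------------------------------------
# stage 2: constrained-MD -> solvation-shell basins and p(j,i)
# ---------------------------------------------------------------------------

def run_cluster_stage(config: RunConfig, conformation_id: str, P_i: float,
                      trajectory_path: str | None = None,
                      tree: sh.WeightTree | None = None) -> sh.WeightTree:
    """Ellipsoid -> nearest-N extraction -> cluster ED -> p(j,i) report."""
    out = config.outdir()
    path = trajectory_path or config.constrained_trajectories.get(conformation_id)
    if path is None:
        raise ConfigError(
            f"no constrained trajectory configured for conformation {conformation_id!r}"
        )
    traj = tio.read_trajectory(path, config.topology)
    solute = tio.select(traj, "not water")
    clusters = sh.extract_clusters(
        traj, solute, config.n_solvent, solvent_site=config.solvent_site,
        padding=config.ellipsoid_padding_nm,
    )
    _, basins, tree = sh.cluster_ed_and_weights(
        clusters, config.thermo, P_i, conformation_id=conformation_id,
        bins=config.bins, cutoff=config.cutoff_kJmol, tree=tree,
    )
    # one representative cluster per solvent basin, written for external QM
    for basin in basins:
        rep = int(basin.frame_indices[0])
        rep_traj = sh.clusters_to_trajectory([clusters[rep]], traj, solute)
        tio.write_trajectory(
            rep_traj, out / f"cluster_{conformation_id}_{basin.id}.pdb"
        )
    df = tree.to_frame(config.thermo)
    _write_csv(df, out / "weights_clusters.csv", config, "solvshell")
    weights = pd.DataFrame(
        {
            "label": [f"{r.conformation_id}/{r.basin_id}"
                      for r in df.itertuples(index=False)],
            "weight": df["p_ji"],
        }
    )
    _write_csv(weights, out / "weights_spectra.csv", config, "solvshell")
    return tree


# ---------------------------------------------------------------------------
# stage 3: stick spectra + weights -> ensemble eps / Deps
# ---------------------------------------------------------------------------

def run_spectra_stage(config: RunConfig,
                      sticks: dict[str, str] | None = None,
                      weights: dict[str, float] | None = None) -> sp.ConvolvedSpectrum:
    """Convolve every weighted stick table and combine into the ensemble
    spectrum; labels in the weight table and stick set must reconcile."""
    out = config.outdir()
    sticks = sticks if sticks is not None else dict(config.sticks)
    if weights is None:
        if config.weights_csv is None:
            raise ConfigError("no weights configured (weights_csv)")
        wdf = _read_report_csv(config.weights_csv)
        if not {"label", "weight"} <= set(wdf.columns):
            raise ConfigError(f"{config.weights_csv} needs columns label,weight")
        weights = dict(zip(wdf["label"].astype(str), wdf["weight"].astype(float)))
    if not sticks:
        raise ConfigError("no stick tables configured")

    missing_sticks = sorted(set(weights) - set(sticks))
    missing_weights = sorted(set(sticks) - set(weights))
    if missing_sticks or missing_weights:
        raise DataError(
            "stick/weight reconciliation failed: "
            f"weights without sticks {missing_sticks}, "
            f"sticks without weights {missing_weights}"
        )

    grid = sp.default_grid(config.lambda_min_nm, config.lambda_max_nm,
                           config.grid_points)
    shape = sp.Lineshape(hwhm=config.hwhm_eV)
    labels = sorted(sticks)
    convolved = []
    for label in labels:
        spectrum = sp.read_sticks(sticks[label], label=label)
        curve = sp.convolve(spectrum, shape, grid,
                            rotatory_units=config.rotatory_units)
        _write_csv(curve.to_frame(), out / f"spectrum_{label.replace('/', '_')}.csv",
                   config, "spectrum")
        convolved.append(curve)
    w = np.array([weights[label] for label in labels])
    total = sp.combine_weighted(convolved, w, renormalize=True)
    logger.info("combined %d spectra; raw weight sum %.4f (renormalized)",
                len(labels), w.sum())
    _write_csv(total.to_frame(), out / "spectrum_total.csv", config, "spectrum")
    if config.plot:
        _plot_spectrum(total, out / "spectrum_total.png")
    return total


def _plot_spectrum(spectrum: sp.ConvolvedSpectrum, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    lam = spectrum.wavelengths
    ax1.plot(lam, spectrum.epsilon)
    ax1.set_ylabel(r"$\varepsilon$ (M$^{-1}$ cm$^{-1}$)")
    ax2.plot(lam, spectrum.delta_epsilon)
    ax2.axhline(0.0, lw=0.5, color="k")
    ax2.set_ylabel(r"$\Delta\varepsilon$ (M$^{-1}$ cm$^{-1}$)")
    ax2.set_xlabel("wavelength (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    logger.info("wrote %s", path)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> sp.ConvolvedSpectrum | SoluteStageResult:
    """Free-MD analysis, optional constrained-MD analyses, optional spectra.

    What runs depends on what the configuration provides: constrained
    trajectories enable the solvation-shell stage; stick tables enable the
    spectra stage (weighted by cluster basins when present, else by solute
    basins).
    """
    result = run_solute_stage(config, through="extract")
    assert result.basins is not None

    weights: dict[str, float]
    if config.constrained_trajectories:
        tree: sh.WeightTree | None = None
        by_id = {b.id: b for b in result.basins}
        for conf_id in sorted(config.constrained_trajectories):
            if conf_id not in by_id:
                raise ConfigError(
                    f"constrained trajectory {conf_id!r} does not match any "
                    f"detected basin ({sorted(by_id)})"
                )
            tree = run_cluster_stage(config, conf_id, by_id[conf_id].population,
                                     tree=tree)
        assert tree is not None
        weights = dict(zip(tree.labels(), tree.weights()))
    else:
        weights = {b.id: b.population for b in result.basins}

    if config.sticks:
        return run_spectra_stage(config, weights=weights)
    return result
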