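"""Orchestration: simulate -> (optional imaging) -> MSD -> confinement, with
domain assignment, flat-key configuration and tidy CSV reports.

Two study designs are provided. The homogeneous benchmark mirrors a tracking
calibration on a one-phase membrane: an ensemble of free Brownian tracks whose
fitted anomalous exponents should pile up at 1 and whose two-point diffusion
rates should recover the configured truth. The raft experiment simulates a
micron-scale Lo domain (with its nano-trap field) in an Ld background,
assigns each frame to a domain, and runs the per-domain MSD, transient-D and
confinement analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import confinement as conf
from . import msd as msdmod
from .simulate import MembraneModel, SimConfig, calibrate_trap_area_fraction, simulate_brownian, simulate_membrane
from .trajectory import Trajectory

logger = logging.getLogger("raftspt")

# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

_DEFAULTS: dict[str, object] = {
    "seed": 0,
    "outdir": ".",
    "sim.frame_interval_s": 2.0e-5,
    "sim.loc_noise_nm": 3.0,
    "sim.blur_substeps": 10,
    "benchmark.n_traj": 62,
    "benchmark.n_steps": 6000,
    "benchmark.d_mean": 1.48,
    "benchmark.d_sd": 0.39,
    "raft.n_ld_traj": 166,
    "raft.n_lo_traj": 88,
    "raft.n_steps": 2000,
    "raft.d_ld": 1.48,
    "raft.d_lo_free": 0.28,
    "raft.trap_area_fraction": -1.0,  # < 0: calibrate against target_micro_d
    "raft.target_micro_d": 0.24,
    "raft.burn_in_steps": 250,
    "raft.extent_um": 8.0,
    "raft.lo_radius_um": 1.5,
    "msd.fit_min_s": 2.0e-5,
    "msd.fit_max_s": 2.0e-2,
    "msd.lo_fit_max_s": 1.0e-3,
    "confinement.window_steps": 25,
    "confinement.smooth_steps": 10,
    "confinement.l_critical": 1.0,
    "confinement.d_ref_um2_s": -1.0,  # < 0: per-trajectory microscopic D
    "imaging.pixel_size_nm": 48.0,
    "imaging.fwhm_nm": 300.0,
    "imaging.snr": 20.0,
    "imaging.contrast": 0.04,
    "pipeline.min_subtraj_steps": 1000,
}


@dataclass
class RunConfig:
    """Flat namespaced configuration (``sim.*``, ``msd.*``, ...).

    Unknown keys are rejected; the config round-trips through YAML unchanged.
    """

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def replace(self, **overrides) -> "RunConfig":
        vals = {k.replace("__", "."): v for k, v in overrides.items()}
        merged = dict(self.values)
        merged.update(vals)
        unknown = set(merged) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(merged)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        return cls(values)

    def sim_config(self, n_steps: int, d_free: float, seed: int) -> SimConfig:
        return SimConfig(
            n_steps=n_steps,
            d_free=d_free,
            frame_interval_s=float(self["sim.frame_interval_s"]),
            loc_noise_nm=float(self["sim.loc_noise_nm"]),
            blur_substeps=int(self["sim.blur_substeps"]),
            seed=seed,
        )


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-trajectory child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ----------------------------------------------------------------------
# domain assignment
# ----------------------------------------------------------------------


@dataclass
class DomainMask:
    """Binary Lo/Ld map in the trajectory coordinate frame."""

    mask: np.ndarray  # True = Lo
    pixel_size_nm: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size == 0:
            raise ValueError("mask must be nonempty")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @classmethod
    def from_membrane(cls, model: MembraneModel) -> "DomainMask":
        return cls(
            mask=model.lo_mask,
            pixel_size_nm=model.pixel_size_um * 1e3,
            origin_um=model.origin_um,
        )

    def labels(self, traj: Trajectory) -> np.ndarray:
        """Per-frame labels: 1 = LO, 0 = LD, -1 = outside the mask."""
        px = self.pixel_size_nm * 1e-3
        j = np.floor((traj.x - self.origin_um[0]) / px).astype(int)
        i = np.floor((traj.y - self.origin_um[1]) / px).astype(int)
        ny, nx = self.mask.shape
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        out = np.full(traj.n_steps, -1, dtype=int)
        out[ok] = self.mask[i[ok], j[ok]].astype(int)
        return out


@dataclass
class DomainAssignment:
    labels: np.ndarray  # 1 LO / 0 LD / -1 UNKNOWN per frame
    crossings: np.ndarray  # frame positions where the label changes (known->known)
    subtrajectories: list[Trajectory]  # per-domain pieces >= min length


def assign_domains(
    traj: Trajectory, mask: DomainMask, min_subtraj_steps: int = 1000
) -> DomainAssignment:
    """Label every frame by nearest-pixel mask lookup, list crossing events,
    and emit per-domain sub-trajectories of at least ``min_subtraj_steps``.

    The crossing frame itself belongs to the destination domain. Frames
    outside the mask are labelled UNKNOWN and break sub-trajectories.
    """
    labels = mask.labels(traj)
    known = labels >= 0
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    crossings = np.array([c for c in change if known[c] and known[c - 1]], dtype=int)
    subs: list[Trajectory] = []
    start = 0
    for i in range(1, traj.n_steps + 1):
        if i == traj.n_steps or labels[i] != labels[start]:
            if known[start] and i - start >= min_subtraj_steps:
                sub = traj.slice(start, i)
                sub.meta["domain"] = "LO" if labels[start] == 1 else "LD"
                subs.append(sub)
            start = i
    return DomainAssignment(labels=labels, crossings=crossings, subtrajectories=subs)


# ----------------------------------------------------------------------
# homogeneous-membrane benchmark
# ----------------------------------------------------------------------


def histogram_peak(values: np.ndarray, bw: float | None = None) -> float:
    """Mode of a sample via a Gaussian kernel density (stable for the small
    ensembles used here, where a raw histogram mode jumps bin to bin)."""
    values = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(values, bw_method=bw)
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, 2001)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class HomogeneousReport:
    alphas: np.ndarray
    alpha_peak: float
    d_micros: np.ndarray
    d_true: np.ndarray
    step_gaussian_p: float
    ensemble: msdmod.MSDCurve
    fits: list = field(repr=False, default_factory=list)

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"alpha": self.alphas, "d_micro_um2_s": self.d_micros, "d_true": self.d_true}
        ).to_csv(outdir / "benchmark_per_trajectory.csv", index=False, float_format="%.9g")
        self.ensemble.to_csv(outdir / "benchmark_ensemble_msd.csv")


def run_benchmark_homogeneous(config: RunConfig) -> HomogeneousReport:
    """Free-Brownian benchmark: an ensemble of long tracks, each with its own
    particle diffusion rate drawn from a (truncated) normal to mirror
    particle-to-particle variability, analyzed with the time-averaged MSD and
    the free-offset anomalous fit."""
    n_traj = int(config["benchmark.n_traj"])
    n_steps = int(config["benchmark.n_steps"])
    if n_traj < 62 or n_steps < 6000:
        warnings.warn("benchmark scale below the standard 62 x 6000 steps")
    rng = np.random.default_rng(int(config["seed"]))
    d_true = rng.normal(float(config["benchmark.d_mean"]), float(config["benchmark.d_sd"]), n_traj)
    d_true = np.clip(d_true, 0.1, None)
    seeds = child_seeds(int(config["seed"]) + 1, n_traj)
    fit_range = (float(config["msd.fit_min_s"]), float(config["msd.fit_max_s"]))
    alphas = np.empty(n_traj)
    d_micros = np.empty(n_traj)
    curves = []
    fits = []
    steps_pool = []
    for i in range(n_traj):
        cfg = config.sim_config(n_steps, float(d_true[i]), seeds[i])
        traj = simulate_brownian(cfg)
        curve = msdmod.time_averaged_msd(traj, max_lag_s=fit_range[1])
        res = msdmod.fit_anomalous(curve, fit_range_s=fit_range)
        alphas[i] = res.alpha
        d_micros[i] = msdmod.microscopic_d(curve)
        curves.append(curve)
        fits.append(res)
        if len(steps_pool) < 2:
            steps_pool.append(np.diff(traj.x))
    steps = np.concatenate(steps_pool)
    gauss_p = float(stats.normaltest(steps).pvalue)
    report = HomogeneousReport(
        alphas=alphas,
        alpha_peak=histogram_peak(alphas),
        d_micros=d_micros,
        d_true=d_true,
        step_gaussian_p=gauss_p,
        ensemble=msdmod.ensemble_msd(curves),
        fits=fits,
    )
    logger.info(
        "benchmark: alpha peak %.3f, mean D %.3f um^2/s", report.alpha_peak, d_micros.mean()
    )
    return report


# ----------------------------------------------------------------------
# Lo trap-model ensemble (shared by the raft experiment and calibration users)
# ----------------------------------------------------------------------


@dataclass
class LoEnsembleResult:
    trajectories: list[Trajectory]
    curves: list[msdmod.MSDCurve]
    ensemble: msdmod.MSDCurve
    fit: msdmod.AnomalousFitResults
    trap_area_fraction: float
    model: MembraneModel


def run_lo_trap_ensemble(
    config: RunConfig,
    n_traj: int | None = None,
    n_steps: int | None = None,
    trap_area_fraction: float | None = None,
    fit_max_s: float | None = None,
) -> LoEnsembleResult:
    """Simulate an ensemble deep inside an Lo domain with the calibrated trap
    field and fit the length-weighted ensemble MSD over short lags.

    When the configured trap area fraction is negative it is first calibrated
    by bisection so the measured microscopic D matches the configured target.
    """
    seed = int(config["seed"])
    n_traj = n_traj if n_traj is not None else int(config["raft.n_lo_traj"])
    n_steps = n_steps if n_steps is not None else int(config["raft.n_steps"])
    d_lo_free = float(config["raft.d_lo_free"])
    frac = trap_area_fraction
    if frac is None:
        frac = float(config["raft.trap_area_fraction"])
    if frac < 0:
        frac = calibrate_trap_area_fraction(
            target_d_um2_s=float(config["raft.target_micro_d"]),
            d_lo_free=d_lo_free,
            seed=seed + 100,
            frame_interval_s=float(config["sim.frame_interval_s"]),
            loc_noise_nm=float(config["sim.loc_noise_nm"]),
            blur_substeps=int(config["sim.blur_substeps"]),
            burn_in_steps=int(config["raft.burn_in_steps"]),
        )
        logger.info("calibrated trap area fraction: %.3f", frac)
    seeds = child_seeds(seed + 200, n_traj + 1)
    model = MembraneModel.uniform_lo(
        extent_um=(2.0, 2.0), trap_area_fraction=frac, seed=seeds[0]
    )
    burn_in = int(config["raft.burn_in_steps"])
    fit_max = fit_max_s if fit_max_s is not None else float(config["msd.lo_fit_max_s"])
    trajs = []
    curves = []
    for s in seeds[1:]:
        cfg = config.sim_config(n_steps, d_lo_free, s)
        tr = simulate_membrane(cfg, model, d_lo_free=d_lo_free, burn_in_steps=burn_in)
        trajs.append(tr)
        curves.append(msdmod.time_averaged_msd(tr, max_lag_s=float(config["msd.fit_max_s"])))
    ens = msdmod.ensemble_msd(curves)
    fit = msdmod.fit_anomalous(ens, fit_range_s=(float(config["msd.fit_min_s"]), fit_max))
    return LoEnsembleResult(
        trajectories=trajs,
        curves=curves,
        ensemble=ens,
        fit=fit,
        trap_area_fraction=frac,
        model=model,
    )


def loglog_slope(curve: msdmod.MSDCurve, lag_range_s: tuple[float, float]) -> float:
    """Local log-log slope of an MSD curve inside a lag window."""
    m = (curve.lag_s >= lag_range_s[0] * (1 - 1e-9)) & (
        curve.lag_s <= lag_range_s[1] * (1 + 1e-9)
    )
    if m.sum() < 2:
        raise ValueError("need at least two lags in the window")
    return float(np.polyfit(np.log(curve.lag_s[m]), np.log(curve.msd_um2[m]), 1)[0])


# ----------------------------------------------------------------------
# raft experiment
# ----------------------------------------------------------------------


@dataclass
class RaftReport:
    ld_ensemble: msdmod.MSDCurve
    lo_ensemble: msdmod.MSDCurve
    ld_fit: msdmod.AnomalousFitResults
    lo_fit: msdmod.AnomalousFitResults
    ld_alphas: np.ndarray
    lo_alphas: np.ndarray
    ld_d: np.ndarray
    lo_d: np.ndarray
    transient_d: pd.DataFrame
    events: pd.DataFrame
    null_summary: dict
    trap_area_fraction: float
    crossings_measured: int
    crossings_truth: int
    n_ld_steps: int
    n_lo_steps: int

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ld_ensemble.to_csv(outdir / "raft_ld_ensemble_msd.csv")
        self.lo_ensemble.to_csv(outdir / "raft_lo_ensemble_msd.csv")
        pd.DataFrame({"alpha": self.ld_alphas, "d_um2_s": self.ld_d}).to_csv(
            outdir / "raft_ld_per_subtraj.csv", index=False, float_format="%.9g"
        )
        pd.DataFrame({"alpha": self.lo_alphas, "d_um2_s": self.lo_d}).to_csv(
            outdir / "raft_lo_per_subtraj.csv", index=False, float_format="%.9g"
        )
        self.transient_d.to_csv(outdir / "raft_transient_d.csv", index=False, float_format="%.9g")
        self.events.to_csv(outdir / "raft_confinement_events.csv", index=False, float_format="%.9g")


def run_raft_experiment(config: RunConfig) -> RaftReport:
    """Simulate a raft membrane (circular Lo domain with its trap field inside
    an Ld background), assign domains, and run the per-domain MSD, transient-D
    and confinement analyses with a matched Brownian null."""
    seed = int(config["seed"])
    extent = float(config["raft.extent_um"])
    lo_r = float(config["raft.lo_radius_um"])
    d_ld = float(config["raft.d_ld"])
    d_lo_free = float(config["raft.d_lo_free"])
    frac = float(config["raft.trap_area_fraction"])
    if frac < 0:
        frac = calibrate_trap_area_fraction(
            target_d_um2_s=float(config["raft.target_micro_d"]),
            d_lo_free=d_lo_free,
            seed=seed + 100,
            frame_interval_s=float(config["sim.frame_interval_s"]),
            loc_noise_nm=float(config["sim.loc_noise_nm"]),
            blur_substeps=int(config["sim.blur_substeps"]),
            burn_in_steps=int(config["raft.burn_in_steps"]),
        )
    n_lo = int(config["raft.n_lo_traj"])
    n_ld = int(config["raft.n_ld_traj"])
    n_steps = int(config["raft.n_steps"])
    seeds = child_seeds(seed + 300, n_lo + n_ld + 1)
    center = (extent / 2, extent / 2)
    model = MembraneModel.disk_lo(
        extent_um=(extent, extent),
        lo_center_um=center,
        lo_radius_um=lo_r,
        trap_area_fraction=frac,
        seed=seeds[0],
    )
    mask = DomainMask.from_membrane(model)
    min_steps = int(config["pipeline.min_subtraj_steps"])
    burn_in = int(config["raft.burn_in_steps"])
    fit_range = (float(config["msd.fit_min_s"]), float(config["msd.fit_max_s"]))
    lo_fit_range = (float(config["msd.fit_min_s"]), float(config["msd.lo_fit_max_s"]))

    subs: list[Trajectory] = []
    crossings_measured = 0
    crossings_truth = 0
    transient_frames = []
    # Lo-resident tracks start at the domain center, Ld tracks in the corner
    # quadrant, mirroring how tracks are harvested per domain experimentally.
    for k, s in enumerate(seeds[1:]):
        in_lo = k < n_lo
        start = center if in_lo else (extent / 8, extent / 8)
        cfg = config.sim_config(n_steps, d_ld, s)
        tr = simulate_membrane(
            cfg, model, d_lo_free=d_lo_free, start_um=start, burn_in_steps=burn_in if in_lo else 0
        )
        asn = assign_domains(tr, mask, min_subtraj_steps=min_steps)
        crossings_measured += asn.crossings.size
        truth_states = np.where(np.asarray(tr.state) > 0, 1, 0)
        crossings_truth += int(np.sum(truth_states[1:] != truth_states[:-1]))
        subs.extend(asn.subtrajectories)
        if asn.crossings.size and len(transient_frames) < 5:
            df = msdmod.transient_d(tr)
            df["traj_id"] = k
            transient_frames.append(df)

    ld_subs = [s for s in subs if s.meta.get("domain") == "LD"]
    lo_subs = [s for s in subs if s.meta.get("domain") == "LO"]
    if not ld_subs or not lo_subs:
        raise RuntimeError("raft run produced no usable sub-trajectories in one domain")

    def analyze(sub_list, fit_rng):
        # curves span the full lag range (to expose the Lo crossover); the
        # anomalous fit is restricted to fit_rng
        curves, alphas, ds = [], [], []
        for t in sub_list:
            c = msdmod.time_averaged_msd(t, max_lag_s=fit_range[1])
            curves.append(c)
            alphas.append(msdmod.fit_anomalous(c, fit_range_s=fit_rng).alpha)
            ds.append(msdmod.microscopic_d(c))
        ens = msdmod.ensemble_msd(curves)
        return ens, msdmod.fit_anomalous(ens, fit_range_s=fit_rng), np.array(alphas), np.array(ds)

    ld_ens, ld_fit, ld_alphas, ld_d = analyze(ld_subs, fit_range)
    lo_ens, lo_fit, lo_alphas, lo_d = analyze(lo_subs, lo_fit_range)

    d_ref_cfg = float(config["confinement.d_ref_um2_s"])
    params = conf.ConfinementParams(
        window_steps=int(config["confinement.window_steps"]),
        smooth_steps=int(config["confinement.smooth_steps"]),
        l_critical=float(config["confinement.l_critical"]),
        d_ref_um2_s=None if d_ref_cfg < 0 else d_ref_cfg,
        loc_noise_nm=float(config["sim.loc_noise_nm"]),
    )
    ev_frames = []
    for i, t in enumerate(lo_subs):
        events = conf.detect_confinements(t, params)
        if events:
            ev_frames.append(conf.events_to_frame(events, traj_id=i))
    events_df = (
        pd.concat(ev_frames, ignore_index=True)
        if ev_frames
        else pd.DataFrame(
            columns=["traj_id", "start_frame", "end_frame", "residence_ms", "diameter_nm", "peak_L"]
        )
    )
    null_summary = conf.calibrate_null(
        lo_subs,
        params,
        n_sim=max(100, len(lo_subs)),
        loc_noise_nm=float(config["sim.loc_noise_nm"]),
        seed=seed + 400,
    )
    return RaftReport(
        ld_ensemble=ld_ens,
        lo_ensemble=lo_ens,
        ld_fit=ld_fit,
        lo_fit=lo_fit,
        ld_alphas=ld_alphas,
        lo_alphas=lo_alphas,
        ld_d=ld_d,
        lo_d=lo_d,
        transient_d=(
            pd.concat(transient_frames, ignore_index=True)
            if transient_frames
            else pd.DataFrame(columns=["t_center_s", "d_um2_s", "traj_id"])
        ),
        events=events_df,
        null_summary=null_summary,
        trap_area_fraction=frac,
        crossings_measured=crossings_measured,
        crossings_truth=crossings_truth,
        n_ld_steps=int(sum(s.n_steps for s in ld_subs)),
        n_lo_steps=int(sum(s.n_steps for s in lo_subs)),
    )
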