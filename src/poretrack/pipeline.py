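"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the five analysis stages — mobility
classification, jump-distance diffusion mixture, photobleaching step
counting, PICCS spatial correlation and binding kinetics — on data from
the synthetic generators, and collects the results into one
machine-readable report.  Configuration is a nested dataclass that
round-trips through YAML; unknown keys are rejected so that typos fail
loudly.  Every stage default equals the acquisition value it models
(107 nm pixel, 19 ms frames, 2% false-positive limit, 70 photon state
separation, 50 frame dwell, 6 frame lag, MSD lags 1-5 / 10-50).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffusion, kinetics, piccs, simkit, stepcount, trackstats
from .io import write_json

__all__ = ["PipelineConfig", "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("poretrack")


@dataclass
class DiffusionParams:
    populations: list = field(default_factory=lambda: [[2.5, 0.5], [1.0, 0.5]])
    immobile_fraction: float = 0.2
    n_trajectories: int = 2000
    lag_range_2d: list = field(default_factory=lambda: [10, 50])
    lag_range_1d: list = field(default_factory=lambda: [1, 5])
    d_threshold: float = 0.05


@dataclass
class StepcountParams:
    fp_limit: float = 0.02
    min_separation: float = 70.0
    min_dwell: int = 50
    max_lag: int = 6
    n_traces: int = 100
    oligomer_weights: list = field(default_factory=lambda: [0.6, 0.25, 0.1, 0.05])
    noise_sigma: float = 50.0


@dataclass
class PiccsParams:
    density_per_um2: float = 2.0
    alpha_true: float = 0.092
    displacement_sigma_nm: float = 22.5
    area_um2: float = 2500.0
    r_max_um: float = 0.5
    n_mc: int = 0              # Monte Carlo nulls; 0 disables


@dataclass
class KineticsParams:
    ka: float = 1.5e5
    kd: float = 4.1e-4
    conc_molar: float = 1.0e-7
    noise_sigma: float = 0.0
    molar_mass_g_mol: float = 96000.0
    mass_signal_ng_mm2: float = 0.8


@dataclass
class PipelineConfig:
    acquisition: simkit.AcquisitionConfig = field(
        default_factory=simkit.AcquisitionConfig
    )
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    stepcount: StepcountParams = field(default_factory=StepcountParams)
    piccs: PiccsParams = field(default_factory=PiccsParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    seed: int = 0
    out_dir: str | None = None


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        ftype = fields[k].type
        sub = {
            "simkit.AcquisitionConfig": simkit.AcquisitionConfig,
            "AcquisitionConfig": simkit.AcquisitionConfig,
            "DiffusionParams": DiffusionParams,
            "StepcountParams": StepcountParams,
            "PiccsParams": PiccsParams,
            "KineticsParams": KineticsParams,
        }.get(ftype if isinstance(ftype, str) else getattr(ftype, "__name__", ""))
        if sub is not None and isinstance(v, dict):
            kwargs[k] = _from_dict(sub, v)
        elif k == "loc_precision_um" and isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(PipelineConfig, data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(clean(cfg), sort_keys=False))


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run all stages on synthetic data and return the JSON-ready report.

    The report carries one block per stage: mobile/immobile fractions,
    fitted diffusion mixture components, bleach-step histogram, PICCS
    alpha and correlation length, and the recovered kinetic constants,
    plus the seed and parameter values for provenance.  When
    ``cfg.out_dir`` is set, intermediate tables and the report are written
    there.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    acq = cfg.acquisition.with_seed(cfg.seed)
    dt = acq.frame_interval_s
    eps = acq.loc_precision_um[0]
    report: dict = {"seed": cfg.seed}

    # --- mobility + diffusion mixture -------------------------------------
    dp = cfg.diffusion
    pops = [tuple(p) for p in dp.populations]
    locs, truth = simkit.simulate_planar_trajectories(
        pops, dp.immobile_fraction, dp.n_trajectories, acq
    )
    log.info("diffusion stage: %d trajectories", dp.n_trajectories)
    classes = trackstats.classify_trajectories(
        locs.rename(columns={"particle": "traj_id"}),
        d_threshold=dp.d_threshold, dt_s=dt,
    )
    frac_mobile = float((classes["mobility"] == "mobile").mean())
    mobile_ids = classes.loc[classes["mobility"] == "mobile", "traj_id"]
    mobile = locs[locs["particle"].isin(mobile_ids)]
    jumps = diffusion.extract_jumps(mobile, lag=1, d=2)
    fit = diffusion.fit_jump_distribution(
        jumps, d=2, n_components=len(pops), dt_s=dt, epsilon_um=eps,
        seed=int(rng.integers(2**31)),
    )
    report["mobility"] = {
        "fraction_mobile": frac_mobile,
        "fraction_immobile": 1.0 - frac_mobile,
        "true_immobile_fraction": dp.immobile_fraction,
    }
    report["diffusion"] = {
        "components": [{"D_um2_s": D, "weight": w} for D, w in fit.components],
        "epsilon_nm": eps * 1e3,
        "log_likelihood": fit.log_likelihood,
    }

    # --- step counting -----------------------------------------------------
    sp = cfg.stepcount
    weights = np.asarray(sp.oligomer_weights, dtype=float)
    weights = weights / weights.sum()
    hist: dict[int, int] = {}
    true_hist: dict[int, int] = {}
    for i in range(sp.n_traces):
        n_fl = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
        trace, _ = simkit.simulate_bleach_trace(
            n_fl, acq.with_seed(int(rng.integers(2**31))), noise_sigma=sp.noise_sigma
        )
        sf = stepcount.segment(trace, sp.fp_limit, sp.min_separation)
        k = stepcount.count_bleach_steps(sf, sp.min_dwell, sp.max_lag)
        hist[k] = hist.get(k, 0) + 1
        true_hist[n_fl] = true_hist.get(n_fl, 0) + 1
    report["stepcount"] = {
        "histogram": {str(k): v for k, v in sorted(hist.items())},
        "true_histogram": {str(k): v for k, v in sorted(true_hist.items())},
        "n_traces": sp.n_traces,
    }

    # --- PICCS -------------------------------------------------------------
    pp = cfg.piccs
    a, b, _ = simkit.simulate_point_pattern_pair(
        pp.density_per_um2, pp.alpha_true, pp.displacement_sigma_nm,
        pp.area_um2, acq.with_seed(int(rng.integers(2**31))),
    )
    side = float(np.sqrt(pp.area_um2))
    res = piccs.run_piccs(a, b, r_max_um=pp.r_max_um, bounds_um=(0.0, side))
    block = {
        "alpha_percent": res.alpha * 100.0,
        "sigma_c_nm": res.sigma_c_um * 1e3,
        "density_per_um2": res.rho_per_um2,
        "true_alpha_percent": pp.alpha_true * 100.0,
    }
    if pp.n_mc >= 100:
        lo, hi = piccs.background_null(
            a, b, n_mc=pp.n_mc, r_max_um=pp.r_max_um,
            bounds_um=(0.0, side), seed=int(rng.integers(2**31)),
        )
        block["null_ci_95_percent"] = [lo * 100.0, hi * 100.0]
    report["piccs"] = block

    # --- kinetics ----------------------------------------------------------
    kp = cfg.kinetics
    curve, _ = simkit.simulate_binding_curve(
        kp.ka, kp.kd, kp.conc_molar, noise_sigma=kp.noise_sigma,
        cfg=acq.with_seed(int(rng.integers(2**31))),
    )
    kfit = kinetics.fit_phases(curve)
    density, side_nm = kinetics.surface_density(
        kp.mass_signal_ng_mm2, kp.molar_mass_g_mol
    )
    report["kinetics"] = {
        "ka_per_M_s": kfit.ka,
        "kd_per_s": kfit.kd,
        "KD_nM": kfit.kD_molar * 1e9,
        "k_obs_per_s": kfit.k_obs,
        "surface_density_per_um2": density,
        "area_side_nm": side_nm,
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        locs.to_csv(out / "planar_locs.csv", index=False)
        write_json(report, out / "report.json")
        save_config(cfg, out / "config.yaml")
    return report
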