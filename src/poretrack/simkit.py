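"""Synthetic single-molecule data with recorded ground truth.

Every generator in this module emulates one of the raw inputs of the
nanopore single-molecule pipeline — planar and nanotube-confined Brownian
trajectories, camera movies, stepwise photobleaching traces, partially
correlated point patterns and pseudo-first-order binding curves — and
returns the generating parameters alongside, so that downstream estimators
can be validated by parameter recovery.

Conventions: physical coordinates in µm with the origin at the field
corner, frames 0-based, pixel (i, j) spanning the half-open square
[i*px, (i+1)*px) x [j*px, (j+1)*px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "GroundTruth",
    "simulate_planar_trajectories",
    "simulate_nanotube_trajectories",
    "render_movie",
    "simulate_bleach_trace",
    "simulate_point_pattern_pair",
    "simulate_binding_curve",
]

#: column order of every localization table produced or consumed here
LOC_COLUMNS = ["frame", "x_um", "y_um", "photons", "background", "channel"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging parameters shared by all generators.

    Defaults reproduce the TIRF acquisition used throughout: 107 nm pixels,
    19 ms frame interval and localization precisions of 19 nm (AF647
    channel 0) / 25 nm (SRhoB/Cy3 channel 1).
    """

    pixel_size_um: float = 0.107
    frame_interval_s: float = 0.019
    frame_count: int = 30
    field_size_px: int = 64
    psf_sigma_um: float = 0.128          # ~1.2 px, x150/1.45 NA at 670 nm
    loc_precision_um: tuple[float, float] = (0.019, 0.025)
    photons_per_fluorophore: float = 500.0
    background_photons: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("lengths must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.frame_count < 1 or self.field_size_px < 1:
            raise ValueError("frame_count and field_size_px must be >= 1")
        if any(p < 0 for p in self.loc_precision_um):
            raise ValueError("localization precision must be >= 0")

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.pixel_size_um

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def with_seed(self, seed: int) -> "AcquisitionConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic dataset.

    Only the fields relevant to the generator that produced the dataset
    are populated; the rest stay None.
    """

    particles: pd.DataFrame | None = None     # per-particle D, label, class
    true_positions: pd.DataFrame | None = None
    n_fluorophores: int | None = None
    change_points: list[int] = field(default_factory=list)
    level_photons: float | None = None
    alpha_true: float | None = None
    displacement_sigma_um: float | None = None
    ka: float | None = None
    kd: float | None = None
    conc_molar: float | None = None


def _finalize_locs(frames, x, y, photons, background, channel) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "frame": np.asarray(frames, dtype=int),
            "x_um": np.asarray(x, dtype=float),
            "y_um": np.asarray(y, dtype=float),
            "photons": np.asarray(photons, dtype=float),
            "background": np.asarray(background, dtype=float),
            "channel": channel,
        }
    )
    return df.sort_values(["frame", "x_um"], kind="stable").reset_index(drop=True)


def simulate_planar_trajectories(
    populations: list[tuple[float, float]],
    immobile_fraction: float = 0.0,
    n: int = 2000,
    cfg: AcquisitionConfig | None = None,
    *,
    channel: int = 0,
    brightness_factors: list[float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-dimensional Brownian mixture in a planar membrane.

    Each mobile population ``(D, fraction)`` contributes
    ``fraction * (1 - immobile_fraction)`` of the ``n`` particles; steps per
    coordinate are N(0, 2*D*dt) and independent localization noise of std
    ``loc_precision`` is added per coordinate and frame.  ``brightness_factors``
    (one per population, immobile last if present) scale the emitted photons,
    enabling oligomer-intensity scenarios.

    Returns the localization table (long format, one row per particle and
    frame) and the ground truth with per-particle D, population label and
    mobility class.
    """
    cfg = cfg or AcquisitionConfig()
    if not populations:
        raise ValueError("populations must not be empty")
    if any(D < 0 for D, _ in populations):
        raise ValueError("diffusion coefficients must be >= 0")
    fracs = np.array([f for _, f in populations], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must be >= 0 and sum to 1")
    if not 0.0 <= immobile_fraction <= 1.0:
        raise ValueError("immobile_fraction must be in [0, 1]")

    rng = cfg.rng()
    n_immobile = int(round(n * immobile_fraction))
    n_mobile = n - n_immobile
    # deterministic largest-remainder split of the mobile part
    counts = np.floor(fracs * n_mobile).astype(int)
    remainder = n_mobile - counts.sum()
    order = np.argsort(-(fracs * n_mobile - counts))
    counts[order[:remainder]] += 1

    d_values = np.concatenate(
        [np.full(c, D) for (D, _), c in zip(populations, counts)]
        + [np.zeros(n_immobile)]
    )
    labels = np.concatenate(
        [np.full(c, i) for i, c in enumerate(counts)]
        + [np.full(n_immobile, len(populations))]
    ).astype(int)
    if brightness_factors is not None:
        bf = np.asarray(brightness_factors, dtype=float)
        brightness = bf[labels]
    else:
        brightness = np.ones(n)

    nf = cfg.frame_count
    dt = cfg.frame_interval_s
    sigma_loc = cfg.loc_precision_um[channel]
    L = cfg.field_size_um

    x0 = rng.uniform(0, L, size=(n, 1))
    y0 = rng.uniform(0, L, size=(n, 1))
    step_std = np.sqrt(2.0 * d_values * dt)[:, None]
    dx = rng.standard_normal((n, nf - 1)) * step_std
    dy = rng.standard_normal((n, nf - 1)) * step_std
    x_true = np.concatenate([x0, x0 + np.cumsum(dx, axis=1)], axis=1)
    y_true = np.concatenate([y0, y0 + np.cumsum(dy, axis=1)], axis=1)
    x_obs = x_true + rng.standard_normal((n, nf)) * sigma_loc
    y_obs = y_true + rng.standard_normal((n, nf)) * sigma_loc

    particle = np.repeat(np.arange(n), nf)
    frames = np.tile(np.arange(nf), n)
    photons = np.repeat(brightness, nf) * cfg.photons_per_fluorophore
    locs = pd.DataFrame(
        {
            "frame": frames,
            "x_um": x_obs.ravel(),
            "y_um": y_obs.ravel(),
            "photons": photons,
            "background": cfg.background_photons,
            "channel": channel,
            "particle": particle,
        }
    )
    truth_particles = pd.DataFrame(
        {
            "particle": np.arange(n),
            "D_true": d_values,
            "population": labels,
            "mobility": np.where(d_values > 0, "mobile", "immobile"),
            "brightness": brightness,
        }
    )
    true_pos = pd.DataFrame(
        {
            "particle": particle,
            "frame": frames,
            "x_um": x_true.ravel(),
            "y_um": y_true.ravel(),
        }
    )
    return locs, GroundTruth(particles=truth_particles, true_positions=true_pos)


def simulate_nanotube_trajectories(
    D: float = 1.0,
    tube_length_um: float = 10.0,
    tube_diameter_nm: float = 16.0,
    n: int = 50,
    cfg: AcquisitionConfig | None = None,
    *,
    channel: int = 0,
    axis_origin_um: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One-dimensional diffusion confined to a lipid nanotube.

    The axial coordinate performs 1D Brownian motion with reflecting tube
    ends; the transverse coordinate is the projection of a uniformly
    distributed angle on a circle of ``tube_diameter_nm`` (arcsine law,
    variance (d/2)^2 / 2), i.e. the emitter sits on the tube wall.  The
    tube axis lies along x, at y = axis_origin_um[1].
    """
    cfg = cfg or AcquisitionConfig()
    if tube_length_um <= 0:
        raise ValueError("tube_length_um must be positive")
    if D < 0:
        raise ValueError("D must be >= 0")
    if tube_diameter_nm * 1e-3 >= cfg.pixel_size_um:
        raise ValueError("tube diameter must be below one pixel")

    rng = cfg.rng()
    nf = cfg.frame_count
    dt = cfg.frame_interval_s
    sigma_loc = cfg.loc_precision_um[channel]
    radius_um = tube_diameter_nm * 1e-3 / 2.0
    if axis_origin_um is None:
        axis_origin_um = (
            (cfg.field_size_um - tube_length_um) / 2.0,
            cfg.field_size_um / 2.0,
        )

    s0 = rng.uniform(0, tube_length_um, size=(n, 1))
    steps = rng.standard_normal((n, nf - 1)) * np.sqrt(2.0 * D * dt)
    s = np.concatenate([s0, s0 + np.cumsum(steps, axis=1)], axis=1)
    # reflect into [0, L]
    s = np.abs(np.mod(s, 2 * tube_length_um))
    s = np.where(s > tube_length_um, 2 * tube_length_um - s, s)

    theta = rng.uniform(0, 2 * np.pi, size=(n, nf))
    transverse = radius_um * np.cos(theta)

    x_true = axis_origin_um[0] + s
    y_true = axis_origin_um[1] + transverse
    x_obs = x_true + rng.standard_normal((n, nf)) * sigma_loc
    y_obs = y_true + rng.standard_normal((n, nf)) * sigma_loc

    particle = np.repeat(np.arange(n), nf)
    frames = np.tile(np.arange(nf), n)
    locs = pd.DataFrame(
        {
            "frame": frames,
            "x_um": x_obs.ravel(),
            "y_um": y_obs.ravel(),
            "photons": cfg.photons_per_fluorophore,
            "background": cfg.background_photons,
            "channel": channel,
            "particle": particle,
        }
    )
    truth_particles = pd.DataFrame(
        {
            "particle": np.arange(n),
            "D_true": D,
            "population": 0,
            "mobility": "mobile" if D > 0 else "immobile",
            "brightness": 1.0,
        }
    )
    true_pos = pd.DataFrame(
        {
            "particle": particle,
            "frame": frames,
            "x_um": x_true.ravel(),
            "y_um": y_true.ravel(),
        }
    )
    return locs, GroundTruth(particles=truth_particles, true_positions=true_pos)


def render_movie(
    locs: pd.DataFrame,
    cfg: AcquisitionConfig,
    *,
    shot_noise: bool = True,
) -> np.ndarray:
    """Rasterize a localization table into a camera movie.

    Each emitter is drawn as a pixel-integrated 2D Gaussian of width
    ``psf_sigma`` whose total integral is its ``photons`` value, on a
    uniform background; Poisson shot noise is applied to signal plus
    background.  Returns a (frames, ny, nx) float array of photon counts
    (uint16-compatible range for the default settings).
    """
    from scipy.special import erf

    rng = cfg.rng()
    npx = cfg.field_size_px
    px = cfg.pixel_size_um
    nf = int(locs["frame"].max()) + 1 if len(locs) else cfg.frame_count
    nf = max(nf, cfg.frame_count)
    stack = np.full((nf, npx, npx), float(cfg.background_photons))

    L = cfg.field_size_um
    x = locs["x_um"].to_numpy(dtype=float)
    y = locs["y_um"].to_numpy(dtype=float)
    if np.any((x < 0) | (x > L) | (y < 0) | (y > L)):
        warnings.warn("positions outside field were clipped", stacklevel=2)
        x = np.clip(x, 0, L - 1e-9)
        y = np.clip(y, 0, L - 1e-9)

    s = cfg.psf_sigma_um
    half = max(3, int(np.ceil(4 * s / px)))
    edges = np.arange(npx + 1) * px
    for fr, xi, yi, ph in zip(
        locs["frame"].to_numpy(int), x, y, locs["photons"].to_numpy(float)
    ):
        ci, cj = int(xi // px), int(yi // px)
        i0, i1 = max(0, ci - half), min(npx, ci + half + 1)
        j0, j1 = max(0, cj - half), min(npx, cj + half + 1)
        fx = 0.5 * (erf((edges[i0 : i1 + 1] - xi) / (np.sqrt(2) * s)))
        fy = 0.5 * (erf((edges[j0 : j1 + 1] - yi) / (np.sqrt(2) * s)))
        gx = np.diff(fx)
        gy = np.diff(fy)
        # row index = y (axis 0), column index = x (axis 1)
        stack[fr, j0:j1, i0:i1] += ph * np.outer(gy, gx)
    if shot_noise:
        stack = rng.poisson(stack).astype(float)
    return stack


def simulate_bleach_trace(
    n_fluorophores: int,
    cfg: AcquisitionConfig | None = None,
    noise_sigma: float = 50.0,
    *,
    mean_lifetime_frames: float = 150.0,
    trace_length: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Stepwise photobleaching intensity trace of one immobile spot.

    Each fluorophore bleaches irreversibly after an exponentially
    distributed lifetime (mean 150 frames by default); the photon level is
    the number of surviving fluorophores times ``photons_per_fluorophore``
    plus white Gaussian noise.  The bleach frames are the recorded change
    points.
    """
    cfg = cfg or AcquisitionConfig()
    if n_fluorophores < 1:
        raise ValueError("n_fluorophores must be >= 1")
    rng = cfg.rng()
    length = trace_length or max(cfg.frame_count, int(6 * mean_lifetime_frames))
    lifetimes = rng.exponential(mean_lifetime_frames, size=n_fluorophores)
    bleach_frames = np.sort(np.ceil(lifetimes).astype(int))
    bleach_frames = np.clip(bleach_frames, 1, None)
    frames = np.arange(length)
    alive = (frames[None, :] < bleach_frames[:, None]).sum(axis=0)
    signal = alive * cfg.photons_per_fluorophore
    photons = signal + rng.standard_normal(length) * noise_sigma
    trace = pd.DataFrame({"frame": frames, "photons": photons})
    cps = sorted(set(int(b) for b in bleach_frames if b < length))
    return trace, GroundTruth(
        n_fluorophores=n_fluorophores,
        change_points=cps,
        level_photons=cfg.photons_per_fluorophore,
    )


def simulate_point_pattern_pair(
    density_per_um2: float,
    alpha_true: float,
    displacement_sigma_nm: float,
    area_um2: float,
    cfg: AcquisitionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Pair of point patterns with a known correlated fraction.

    Pattern A is complete spatial randomness on a square field of the given
    area.  Pattern B retains a Bernoulli(``alpha_true``) subset of A's
    points, each displaced by isotropic Gaussian noise of per-coordinate
    std ``displacement_sigma_nm``; the remaining points are redrawn
    uniformly so both patterns have the same expected density.  Emulates
    immobile-cluster maps localized before and after photobleaching.
    """
    cfg = cfg or AcquisitionConfig()
    if not 0.0 <= alpha_true <= 1.0:
        raise ValueError("alpha_true must be in [0, 1]")
    if density_per_um2 * area_um2 < 10:
        warnings.warn(
            "fewer than ~10 points expected; PICCS will be unstable", stacklevel=2
        )
    rng = cfg.rng()
    side = np.sqrt(area_um2)
    n = rng.poisson(density_per_um2 * area_um2)
    a = rng.uniform(0, side, size=(n, 2))
    keep = rng.random(n) < alpha_true
    jitter = rng.standard_normal((int(keep.sum()), 2)) * displacement_sigma_nm * 1e-3
    b_corr = a[keep] + jitter
    n_new = n - int(keep.sum())
    b_new = rng.uniform(0, side, size=(n_new, 2))
    b = np.concatenate([b_corr, b_new], axis=0)
    truth = GroundTruth(
        alpha_true=alpha_true,
        displacement_sigma_um=displacement_sigma_nm * 1e-3,
    )
    return a, b, truth


def simulate_binding_curve(
    ka: float,
    kd: float,
    conc_molar: float,
    t_assoc_s: float = 220.0,
    t_diss_s: float = 600.0,
    noise_sigma: float = 0.0,
    cfg: AcquisitionConfig | None = None,
    *,
    r_max: float = 1.0,
    dt_s: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Pseudo-first-order association/dissociation curve.

    Association follows R(t) = Req*(1 - exp(-(ka*C + kd)*t)) with
    Req = r_max * ka*C/(ka*C + kd); dissociation decays exponentially with
    rate kd from the level reached at the end of association.  Additive
    Gaussian noise of std ``noise_sigma`` (same units as the signal).
    """
    cfg = cfg or AcquisitionConfig()
    if ka < 0 or kd < 0 or conc_molar < 0:
        raise ValueError("rates and concentration must be >= 0")
    rng = cfg.rng()
    k_obs = ka * conc_molar + kd
    req = r_max * (ka * conc_molar / k_obs if k_obs > 0 else 0.0)
    t_a = np.arange(0.0, t_assoc_s, dt_s)
    t_d = np.arange(0.0, t_diss_s, dt_s)
    r_a = req * (1.0 - np.exp(-k_obs * t_a))
    r_end = req * (1.0 - np.exp(-k_obs * t_assoc_s))
    r_d = r_end * np.exp(-kd * t_d)
    t = np.concatenate([t_a, t_assoc_s + t_d])
    r = np.concatenate([r_a, r_d])
    if noise_sigma > 0:
        r = r + rng.standard_normal(len(r)) * noise_sigma
    phase = np.array(["association"] * len(t_a) + ["dissociation"] * len(t_d))
    curve = pd.DataFrame({"t_s": t, "signal": r, "phase": phase})
    curve.attrs["conc_molar"] = conc_molar
    curve.attrs["t_assoc_s"] = t_assoc_s
    return curve, GroundTruth(ka=ka, kd=kd, conc_molar=conc_molar)
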