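"""Diffusion analysis of single-particle trajectories.

Two complementary estimators of the lateral diffusion coefficient are
provided:

* the mean square displacement (MSD) of pooled jump magnitudes, fitted
  with the free-Brownian model ``MSD(t) = d * (2*D*t + 2*eps^2)`` where
  ``d`` is the dimensionality and ``eps`` the localization precision;
* maximum-likelihood fitting of the jump-magnitude probability density at
  a fixed lag — half-normal in 1D, Rayleigh in 2D — including mixtures of
  up to three diffusive sub-populations with BIC model selection.

Throughout, "MSD" inside the jump pdfs denotes the per-dimension quantity
``2*(D*t + eps^2)``: the 2D density ``P(x) = x/MSD * exp(-x^2 / (2 MSD))``
is a Rayleigh density exactly under this reading, which simulation oracles
confirm (using the full 2D MSD ``4*D*t`` would double the variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MsdCurve",
    "MsdFit",
    "JumpDistFit",
    "OligomerProfile",
    "extract_jumps",
    "compute_msd",
    "fit_msd",
    "fit_jump_distribution",
    "jump_pdf",
    "oligomer_analysis",
    "project_onto_axis",
    "per_trajectory_d",
]

_ID_CANDIDATES = ("traj_id", "particle")


def _id_column(trajs: pd.DataFrame) -> str:
    for c in _ID_CANDIDATES:
        if c in trajs.columns:
            return c
    raise ValueError("trajectory table needs a 'traj_id' or 'particle' column")


@dataclass
class MsdCurve:
    lag_s: np.ndarray          # lag times, seconds, increasing
    msd_um2: np.ndarray        # pooled mean squared jump magnitude
    counts: np.ndarray         # jumps pooled per lag
    d: int                     # dimensionality, 1 or 2

    def __post_init__(self) -> None:
        if self.d not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")


@dataclass
class MsdFit:
    D: float                   # µm²/s
    epsilon_um: float          # localization precision, µm
    flagged: bool = False      # True when the raw slope was negative


@dataclass
class JumpDistFit:
    """Mixture fit of the jump-magnitude pdf at one lag.

    ``components`` is sorted descending by D; ``msd_components`` holds the
    per-dimension scale 2*(D_i*dt + eps^2) actually fitted.
    """

    components: list[tuple[float, float]]   # (D_i µm²/s, weight_i)
    epsilon_um: float
    dt_s: float
    d: int
    log_likelihood: float
    bic: float
    msd_components: list[float]
    n_jumps: int
    converged: bool = True
    ll_by_k: dict[int, float] | None = None


@dataclass
class OligomerProfile:
    table: pd.DataFrame            # traj_id, D, norm_intensity, d_bin
    reference_intensity: float
    d_bin_edges: np.ndarray

    def intensity_values(self, d_bin: int | None = None) -> np.ndarray:
        t = self.table if d_bin is None else self.table[self.table["d_bin"] == d_bin]
        return t["norm_intensity"].to_numpy()


def extract_jumps(
    trajs: pd.DataFrame, lag: int = 1, d: int = 2
) -> np.ndarray:
    """Pool jump magnitudes at a fixed frame lag over all trajectories.

    Only frame pairs separated by exactly ``lag`` frames contribute, so
    gap-closed trajectories do not inject spurious long jumps.  For d=1
    the x coordinate is used (project onto the tube axis first).
    """
    j = _jump_components(trajs, lag, d)
    if j is None:
        return np.empty(0)
    dx, dy = j
    return np.hypot(dx, dy) if d == 2 else np.abs(dx)


def _jump_components(trajs: pd.DataFrame, lag: int, d: int,
                     with_id: bool = False):
    """Vectorized per-lag displacement components via a frame self-join."""
    idc = _id_column(trajs)
    cols = [idc, "frame", "x_um"] + (["y_um"] if d == 2 else [])
    df = trajs[cols]
    late = df.copy()
    late["frame"] = late["frame"] - lag
    merged = df.merge(late, on=[idc, "frame"], suffixes=("", "_b"))
    if len(merged) == 0:
        return None
    dx = (merged["x_um_b"] - merged["x_um"]).to_numpy()
    dy = (merged["y_um_b"] - merged["y_um"]).to_numpy() if d == 2 else np.zeros_like(dx)
    if with_id:
        return dx, dy, merged[idc].to_numpy()
    return dx, dy


def compute_msd(
    trajs: pd.DataFrame,
    d: int = 2,
    max_lag: int = 50,
    dt_s: float = 0.019,
) -> MsdCurve:
    """MSD(lag) as the mean of squared jump magnitudes pooled over trajectories."""
    if d not in (1, 2):
        raise ValueError("dimensionality must be 1 or 2")
    lags, msds, counts = [], [], []
    for m in range(1, max_lag + 1):
        jumps = extract_jumps(trajs, lag=m, d=d)
        if jumps.size == 0:
            continue
        lags.append(m * dt_s)
        msds.append(float(np.mean(jumps**2)))
        counts.append(jumps.size)
    return MsdCurve(
        lag_s=np.asarray(lags),
        msd_um2=np.asarray(msds),
        counts=np.asarray(counts),
        d=d,
    )


def fit_msd(
    curve: MsdCurve,
    lag_range: tuple[int, int] | None = None,
) -> MsdFit:
    """Weighted least-squares line through the MSD curve.

    Model: MSD = d*(2*D*t + 2*eps^2).  The default lag window follows the
    dimensionality: lags 1-5 for nanotube (1D) data, 10-50 for planar (2D)
    membranes; weights are the jump counts per lag.  A negative fitted
    slope is clamped to D = 0 and flagged.
    """
    if lag_range is None:
        lag_range = (1, 5) if curve.d == 1 else (10, 50)
    dt = np.min(np.diff(curve.lag_s)) if len(curve.lag_s) > 1 else curve.lag_s[0]
    lag_idx = np.rint(curve.lag_s / dt).astype(int)
    sel = (lag_idx >= lag_range[0]) & (lag_idx <= lag_range[1])
    if sel.sum() < 2:
        sel = np.ones_like(sel, dtype=bool)  # fall back to the whole curve
    t = curve.lag_s[sel]
    y = curve.msd_um2[sel]
    w = curve.counts[sel].astype(float)
    wm = lambda v: np.sum(w * v) / np.sum(w)  # noqa: E731
    tbar, ybar = wm(t), wm(y)
    slope = wm((t - tbar) * (y - ybar)) / wm((t - tbar) ** 2)
    intercept = ybar - slope * tbar
    flagged = slope < 0
    D = max(slope, 0.0) / (2 * curve.d)
    eps = np.sqrt(max(intercept, 0.0) / (2 * curve.d))
    return MsdFit(D=float(D), epsilon_um=float(eps), flagged=bool(flagged))


def jump_pdf(x: np.ndarray, msd: float, d: int) -> np.ndarray:
    """Jump-magnitude density with per-dimension scale ``msd`` = 2*(D*t+eps^2)."""
    x = np.asarray(x, dtype=float)
    if d == 2:
        return x / msd * np.exp(-(x**2) / (2 * msd))
    return np.sqrt(2.0 / (np.pi * msd)) * np.exp(-(x**2) / (2 * msd))


def fit_jump_distribution(
    jumps: np.ndarray,
    d: int = 2,
    n_components: int | str = 1,
    dt_s: float = 0.019,
    epsilon_um: float = 0.0,
    *,
    n_starts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> JumpDistFit:
    """Maximum-likelihood (EM) fit of a jump-magnitude mixture at one lag.

    Each component contributes a Rayleigh (d=2) or half-normal (d=1)
    density with scale MSD_i = 2*(D_i*dt + eps^2); eps is shared across
    components and supplied by the caller (one optical precision per
    dataset).  ``n_components`` may be 1-3 or ``"bic"`` to select the
    component count by the Bayesian information criterion.
    """
    jumps = np.asarray(jumps, dtype=float)
    jumps = jumps[jumps > 0]
    if jumps.size < 10:
        raise ValueError("need at least 10 positive jump magnitudes")
    if n_components == "bic":
        k_max, select = 3, True
    else:
        k_max = int(n_components)
        select = False
        if k_max not in (1, 2, 3):
            raise ValueError("n_components must be 1, 2, 3 or 'bic'")

    x2 = jumps**2
    n = jumps.size
    # sample-dependent part of the log density that does not involve msd
    log_base = np.log(jumps) if d == 2 else np.full(n, 0.5 * np.log(2.0 / np.pi))
    denom = 2.0 if d == 2 else 1.0
    rng = np.random.default_rng(seed)

    def em(msd0: np.ndarray, w0: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        msd, w = msd0.copy(), w0.copy()
        ll_prev = -np.inf
        ll = -np.inf
        for _ in range(max_iter):
            logp = (
                log_base[:, None]
                - (0.5 if d == 1 else 1.0) * np.log(msd)[None, :]
                - x2[:, None] / (2 * msd[None, :])
                + np.log(w)[None, :]
            )
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            tot = p.sum(axis=1)
            ll = float(np.sum(np.log(tot) + m[:, 0]))
            gamma = p / tot[:, None]
            nk = gamma.sum(axis=0)
            w = np.maximum(nk / n, 1e-12)
            w = w / w.sum()
            msd = np.maximum((gamma * x2[:, None]).sum(axis=0) / (denom * nk), 1e-12)
            if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
                break
            ll_prev = ll
        return ll, msd, w

    # fits for k = 1..k_max; each k seeds one start from the (k-1) optimum with
    # its heaviest component duplicated, which makes the maximized likelihood
    # non-decreasing in the component count by construction
    best_by_k: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    for k in range(1, k_max + 1):
        inits: list[tuple[np.ndarray, np.ndarray]] = []
        qs = np.quantile(x2, (np.arange(k) + 0.5) / k)
        inits.append((np.maximum(qs / denom, 1e-12), np.full(k, 1.0 / k)))
        if k > 1:
            ll_p, msd_p, w_p = best_by_k[k - 1]
            j = int(np.argmax(w_p))
            msd_s = np.append(msd_p, msd_p[j])
            w_s = np.append(w_p, w_p[j] / 2)
            w_s[j] /= 2
            inits.append((msd_s, w_s))
            for _ in range(n_starts - 2):
                inits.append(
                    (
                        np.maximum(np.mean(x2) * rng.uniform(0.2, 3.0, size=k), 1e-12),
                        np.full(k, 1.0 / k),
                    )
                )
        best_by_k[k] = max((em(m0, w0) for m0, w0 in inits), key=lambda r: r[0])

    if select:
        def bic_of(k):
            ll_k = best_by_k[k][0]
            return (2 * k - 1) * np.log(n) - 2 * ll_k

        k_best = min(range(1, k_max + 1), key=bic_of)
    else:
        k_best = k_max
    ll, msd, w = best_by_k[k_best]
    k = k_best
    n_params = 2 * k - 1
    bic = n_params * np.log(n) - 2 * ll
    D = (msd / 2.0 - epsilon_um**2) / dt_s
    D = np.maximum(D, 0.0)
    order = np.argsort(-D)
    components = [(float(D[i]), float(w[i])) for i in order]
    return JumpDistFit(
        components=components,
        epsilon_um=epsilon_um,
        dt_s=dt_s,
        d=d,
        log_likelihood=ll,
        bic=float(bic),
        msd_components=[float(msd[i]) for i in order],
        n_jumps=n,
        ll_by_k={k_: v[0] for k_, v in best_by_k.items()},
    )


def per_trajectory_d(
    trajs: pd.DataFrame,
    d: int = 2,
    dt_s: float = 0.019,
    max_lag: int = 4,
    min_steps: int = 5,
) -> pd.DataFrame:
    """Per-trajectory diffusion coefficient from a short-lag MSD fit.

    Trajectories with fewer than ``min_steps`` jumps are dropped.  Returns
    columns traj_id, D, n_steps, median_photons.  The fit is the same
    weighted least squares as :func:`fit_msd`, vectorized over
    trajectories; a negative per-trajectory slope is clamped to D = 0.
    """
    idc = _id_column(trajs)
    pieces = []
    for lag in range(1, max_lag + 1):
        j = _jump_components(trajs, lag, d, with_id=True)
        if j is None:
            continue
        dx, dy, ids = j
        sq = dx**2 + dy**2
        pieces.append(pd.DataFrame({"id": ids, "t": lag * dt_s, "sq": sq}))
    if not pieces:
        return pd.DataFrame(columns=["traj_id", "D", "n_steps", "median_photons"])
    tbl = pd.concat(pieces, ignore_index=True)
    per_lag = tbl.groupby(["id", "t"])["sq"].agg(["mean", "count"]).reset_index()
    per_lag.columns = ["id", "t", "y", "w"]
    g = per_lag.assign(
        wt=lambda r: r.w * r.t,
        wy=lambda r: r.w * r.y,
        wtt=lambda r: r.w * r.t**2,
        wty=lambda r: r.w * r.t * r.y,
    ).groupby("id")[["w", "wt", "wy", "wtt", "wty"]].sum()
    denom = g.w * g.wtt - g.wt**2
    slope = (g.w * g.wty - g.wt * g.wy) / denom.replace(0, np.nan)
    d_fit = (slope / (2 * d)).clip(lower=0.0)

    sizes = trajs.groupby(idc).size() - 1
    med = (
        trajs.groupby(idc)["photons"].median()
        if "photons" in trajs.columns
        else pd.Series(np.nan, index=sizes.index)
    )
    out = pd.DataFrame(
        {
            "traj_id": sizes.index,
            "D": d_fit.reindex(sizes.index).to_numpy(),
            "n_steps": sizes.to_numpy(),
            "median_photons": med.reindex(sizes.index).to_numpy(dtype=float),
        }
    )
    out = out[(out["n_steps"] >= min_steps) & out["D"].notna()]
    return out.reset_index(drop=True)


def oligomer_analysis(
    trajs: pd.DataFrame,
    reference_intensity: float,
    d_bin_edges: np.ndarray | list[float],
    dt_s: float = 0.019,
    min_steps: int = 10,
) -> OligomerProfile:
    """Intensity-based oligomer profiling of mobile trajectories.

    Each trajectory's median photon count is normalized to the single
    fluorophore reference; trajectories (>= ``min_steps`` jumps) are then
    partitioned by their MSD-fitted D into the given bins so that the
    normalized-intensity distribution can be compared across diffusion
    regimes (slower regimes showing higher intensities indicate oligomers).
    """
    if reference_intensity <= 0:
        raise ValueError("reference_intensity must be positive")
    edges = np.asarray(d_bin_edges, dtype=float)
    table = per_trajectory_d(trajs, d=2, dt_s=dt_s, min_steps=min_steps)
    if len(table) == 0:
        raise ValueError("no trajectory passed the minimum-length filter")
    table = table.copy()
    table["norm_intensity"] = table["median_photons"] / reference_intensity
    table["d_bin"] = np.digitize(table["D"], edges) - 1
    return OligomerProfile(
        table=table,
        reference_intensity=float(reference_intensity),
        d_bin_edges=edges,
    )


def project_onto_axis(trajs: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Project localizations onto the principal axis of the point cloud.

    Used for nanotube data: returns a copy where ``x_um`` is the axial
    coordinate (along the first principal component) and ``y_um`` the
    transverse residual, plus the unit axis vector.
    """
    xy = trajs[["x_um", "y_um"]].to_numpy(dtype=float)
    center = xy.mean(axis=0)
    u, s, vt = np.linalg.svd(xy - center, full_matrices=False)
    axis = vt[0]
    axial = (xy - center) @ axis
    transverse = (xy - center) @ vt[1]
    out = trajs.copy()
    out["x_um"] = axial
    out["y_um"] = transverse
    return out, axis
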