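"""Trajectory building and spatiotemporal statistics.

Covers the glue between raw localizations and diffusion analysis:
DBSCAN-based separation of immobile clusters from mobile emitters,
frame-to-frame trajectory linking by optimal bipartite assignment with gap
closing, per-trajectory mobility classification, rigid dual-color channel
registration, mutual-nearest-neighbor co-localization (107 nm = 1 pixel by
default) and kymograph extraction along a polyline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .diffusion import compute_msd, fit_msd

__all__ = [
    "RigidTransform2D",
    "filter_immobile",
    "link",
    "classify_mobility",
    "estimate_transform",
    "colocalize",
    "kymograph",
]


@dataclass
class RigidTransform2D:
    """Rotation + translation mapping channel B coordinates onto channel A."""

    angle_rad: float
    translation_um: np.ndarray
    rms_residual_um: float
    flagged: bool = False

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        return np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.rotation.T + self.translation_um


def filter_immobile(
    locs: pd.DataFrame,
    eps_nm: float = 57.0,
    min_samples: int = 10,
    window_frames: int = 100,
    min_lifetime: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split localizations into immobile clusters and mobile remainder.

    DBSCAN runs on the spatial coordinates pooled over each window of
    ``window_frames`` frames (default eps = 3x the 19 nm localization
    precision): an immobile emitter deposits a precision-limited cloud of
    localizations at one spot, which clusters, whereas a mobile emitter at
    membrane-diffusion speeds moves several pixels between frames.
    Clusters spanning at least ``min_lifetime`` frames are immobile; all
    other localizations are returned as mobile.
    """
    if len(locs) == 0:
        return locs.copy(), locs.copy()
    eps_um = eps_nm * 1e-3
    immobile_mask = np.zeros(len(locs), dtype=bool)
    frames = locs["frame"].to_numpy()
    for w0 in range(0, int(frames.max()) + 1, window_frames):
        sel = (frames >= w0) & (frames < w0 + window_frames)
        idx = np.flatnonzero(sel)
        if idx.size < min_samples:
            continue
        xy = locs.iloc[idx][["x_um", "y_um"]].to_numpy(dtype=float)
        labels = DBSCAN(eps=eps_um, min_samples=min_samples).fit_predict(xy)
        for lab in np.unique(labels):
            if lab < 0:
                continue
            member = idx[labels == lab]
            f = frames[member]
            if f.max() - f.min() + 1 >= min_lifetime:
                immobile_mask[member] = True
    return (
        locs[immobile_mask].reset_index(drop=True),
        locs[~immobile_mask].reset_index(drop=True),
    )


def link(
    locs: pd.DataFrame,
    max_disp_um: float = 0.8,
    max_gap: int = 1,
) -> pd.DataFrame:
    """Link localizations into trajectories.

    Frame-by-frame optimal bipartite assignment (Hungarian algorithm on
    squared displacements) between open trajectory ends and the detections
    of the current frame; a trajectory end stays assignable for ``max_gap``
    missed frames (gap closing), with the allowed displacement scaling as
    max_disp * (gap + 1).  Unassigned detections start new trajectories, so
    linking conserves detections exactly.  Returns the localization table
    with an added ``traj_id`` column.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    n = len(locs)
    traj_id = np.full(n, -1, dtype=int)
    frames = locs["frame"].to_numpy()
    xy = locs[["x_um", "y_um"]].to_numpy(dtype=float)
    next_id = 0
    # open ends: list of [traj_id, last_frame, x, y]
    open_ends: list[list[float]] = []
    for f in np.unique(frames):
        det_idx = np.flatnonzero(frames == f)
        open_ends = [e for e in open_ends if f - e[1] <= max_gap + 1]
        cand = [e for e in open_ends if f > e[1]]
        if cand and det_idx.size:
            ends_xy = np.array([[e[2], e[3]] for e in cand])
            gaps = np.array([f - e[1] for e in cand])
            d2 = (
                (ends_xy[:, None, 0] - xy[det_idx][None, :, 0]) ** 2
                + (ends_xy[:, None, 1] - xy[det_idx][None, :, 1]) ** 2
            )
            limit = (max_disp_um * gaps[:, None]) ** 2
            big = 1e12
            cost = np.where(d2 <= limit, d2, big)
            row, col = linear_sum_assignment(cost)
            for r, c in zip(row, col):
                if cost[r, c] >= big:
                    continue
                e = cand[r]
                i = det_idx[c]
                traj_id[i] = int(e[0])
                e[1], e[2], e[3] = f, xy[i, 0], xy[i, 1]
        for i in det_idx:
            if traj_id[i] < 0:
                traj_id[i] = next_id
                open_ends.append([next_id, f, xy[i, 0], xy[i, 1]])
                next_id += 1
    out = locs.copy()
    out["traj_id"] = traj_id
    return out


def classify_mobility(
    traj: pd.DataFrame,
    d_threshold: float = 0.05,
    dt_s: float = 0.019,
    min_frames: int = 5,
) -> str:
    """Mobility class of one trajectory from its MSD-fitted D.

    The default threshold of 0.05 µm²/s sits an order of magnitude below
    the slow membrane-spanning population (1 µm²/s) and above the apparent
    D of an immobile, precision-limited emitter (~0.02 µm²/s worth of
    noise never survives the intercept term).  Trajectories shorter than
    ``min_frames`` frames are left unclassified.
    """
    if len(traj) < min_frames:
        return "unclassified"
    curve = compute_msd(
        traj.assign(traj_id=0), d=2, max_lag=min(4, len(traj) - 1), dt_s=dt_s
    )
    if len(curve.lag_s) < 2:
        return "unclassified"
    fit = fit_msd(curve, lag_range=(1, 4))
    return "immobile" if fit.D < d_threshold else "mobile"


def classify_trajectories(
    trajs: pd.DataFrame,
    d_threshold: float = 0.05,
    dt_s: float = 0.019,
    min_frames: int = 5,
) -> pd.DataFrame:
    """Vector version of :func:`classify_mobility` over a linked table."""
    from .diffusion import per_trajectory_d

    table = per_trajectory_d(
        trajs, d=2, dt_s=dt_s, max_lag=4, min_steps=min_frames - 1
    )
    sizes = trajs.groupby("traj_id").size()
    out = pd.DataFrame({"traj_id": sizes.index, "n_frames": sizes.to_numpy()})
    d_map = table.set_index("traj_id")["D"]
    d_vals = d_map.reindex(out["traj_id"]).to_numpy()
    out["mobility"] = np.where(
        np.isnan(d_vals),
        "unclassified",
        np.where(d_vals < d_threshold, "immobile", "mobile"),
    )
    return out


def estimate_transform(
    beads_a: np.ndarray, beads_b: np.ndarray
) -> RigidTransform2D:
    """Least-squares rigid registration from matched bead positions.

    Kabsch-style solution mapping B onto A; at least two non-coincident
    pairs are required, collinear or degenerate geometries are flagged.
    """
    a = np.asarray(beads_a, dtype=float)
    b = np.asarray(beads_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need >= 2 matched bead pairs of equal shape")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    angle = float(np.arctan2(rot[1, 0], rot[0, 0]))
    trans = ca - rot @ cb
    mapped = b @ rot.T + trans
    rms = float(np.sqrt(np.mean(np.sum((mapped - a) ** 2, axis=1))))
    spread = np.linalg.svd(b - cb, compute_uv=False)
    flagged = bool(spread[-1] < 1e-9)  # collinear beads: rotation ill-posed
    return RigidTransform2D(
        angle_rad=angle, translation_um=trans, rms_residual_um=rms, flagged=flagged
    )


def colocalize(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    radius_nm: float = 107.0,
) -> pd.DataFrame:
    """Per-frame mutual nearest neighbors within the co-localization radius.

    The default radius of 107 nm equals one camera pixel.  Mutuality (A's
    nearest B must also have A as its nearest neighbor) prevents double
    counting at higher densities.  Returns rows (frame, index_a, index_b,
    distance_nm) referring to positional indices in the input tables.
    """
    rows = []
    r_um = radius_nm * 1e-3
    frames = np.intersect1d(locs_a["frame"].unique(), locs_b["frame"].unique())
    for f in frames:
        ia = np.flatnonzero(locs_a["frame"].to_numpy() == f)
        ib = np.flatnonzero(locs_b["frame"].to_numpy() == f)
        pa = locs_a.iloc[ia][["x_um", "y_um"]].to_numpy(dtype=float)
        pb = locs_b.iloc[ib][["x_um", "y_um"]].to_numpy(dtype=float)
        ta, tb = cKDTree(pa), cKDTree(pb)
        d_ab, j_ab = tb.query(pa, k=1)
        d_ba, j_ba = ta.query(pb, k=1)
        for i in range(len(pa)):
            j = j_ab[i]
            if d_ab[i] <= r_um and j_ba[j] == i:
                rows.append(
                    {
                        "frame": f,
                        "index_a": int(ia[i]),
                        "index_b": int(ib[j]),
                        "distance_nm": float(d_ab[i] * 1e3),
                    }
                )
    return pd.DataFrame(rows, columns=["frame", "index_a", "index_b", "distance_nm"])


def kymograph(
    data: np.ndarray | pd.DataFrame,
    polyline_um: np.ndarray,
    cfg,
    width_px: int = 3,
    sample_um: float | None = None,
) -> np.ndarray:
    """Intensity (or localization density) along a polyline vs time.

    For an image stack, intensity is sampled along the polyline per frame
    (linear interpolation) and averaged over ``width_px`` transverse
    offsets.  For a localization table, localizations are projected onto
    the polyline and histogrammed per frame, counting only points within
    ``width_px``/2 pixels of the line.  Returns (position, time) array.
    """
    poly = np.asarray(polyline_um, dtype=float)
    if poly.ndim != 2 or len(poly) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("polyline has zero length")
    px = cfg.pixel_size_um
    ds = sample_um or px / 2
    n_samples = max(int(np.ceil(total / ds)), 2)
    s_grid = np.linspace(0, total, n_samples)
    # arc-length parameterization of the polyline
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = np.empty((n_samples, 2))
    normals = np.empty((n_samples, 2))
    for i, s in enumerate(s_grid):
        k = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = (s - cum[k]) / seg_len[k] if seg_len[k] > 0 else 0.0
        pts[i] = poly[k] + frac * seg[k]
        t = seg[k] / seg_len[k]
        normals[i] = (-t[1], t[0])

    if isinstance(data, pd.DataFrame):
        nf = int(data["frame"].max()) + 1
        out = np.zeros((n_samples, nf))
        xy = data[["x_um", "y_um"]].to_numpy(dtype=float)
        frames = data["frame"].to_numpy(int)
        tree = cKDTree(pts)
        d, j = tree.query(xy, k=1)
        ok = d <= width_px * px / 2
        for f, jj in zip(frames[ok], j[ok]):
            out[jj, f] += 1
        return out

    stack = np.asarray(data, dtype=float)
    nf = stack.shape[0]
    offsets = (np.arange(width_px) - (width_px - 1) / 2) * px
    out = np.zeros((n_samples, nf))
    for off in offsets:
        sample_pts = pts + off * normals
        cols = sample_pts[:, 0] / px - 0.5  # x -> column
        rows_ = sample_pts[:, 1] / px - 0.5  # y -> row
        for f in range(nf):
            out[:, f] += ndimage.map_coordinates(
                stack[f], [rows_, cols], order=1, mode="nearest"
            )
    return out / width_px
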