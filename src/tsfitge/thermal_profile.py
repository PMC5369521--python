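"""Inter-gel analysis: spot tracking, internal-standard normalization,
melting-curve fitting, and thermal-shift scoring.

The Cy2 channel carries the same unheated proteome in every gel, so for a
tracked spot the ratio R_c(T) = I_c(T) / I_cy2(T) cancels per-gel gain
exactly; self-normalizing to the baseline, rel_c(T) = R_c(T) / R_c(T0),
yields the fractional melting curve that starts at 1.  Two comparison
criteria are computed per track:

* the *transverse* shift ΔTm = Tm(drug) − Tm(vehicle) from two independent
  logistic fits (the thermal-proteome-profiling readout), and
* the *longitudinal* y-deviation — the maximum and the trapezoidal area of
  |rel_drug − rel_vehicle| over the measured temperatures — computed on the
  data points, not the fits, so steep-slope / marginal-ΔTm shifts are still
  detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .gel_image import Spot
from .melting import logistic_melt

log = logging.getLogger(__name__)


@dataclass
class SpotTrack:
    track_id: str
    reference_spot: Spot
    members: dict[float, Spot] = field(default_factory=dict)
    rel_vehicle: dict[float, float] = field(default_factory=dict)
    rel_drug: dict[float, float] = field(default_factory=dict)
    complete: bool = False
    partial: bool = False  # >50% heated points missing -> y-deviation only


@dataclass
class MeltingFit:
    tm: float = float("nan")
    slope_k: float = float("nan")
    plateau_p: float = float("nan")
    r_squared: float = float("nan")
    converged: bool = False


@dataclass
class ShiftResult:
    track_id: str
    delta_tm: float = float("nan")  # drug - vehicle, NaN when either fit failed
    y_dev_max: float = 0.0
    y_dev_area: float = 0.0
    z_score: float = float("nan")
    direction: str = "none"  # sign of rel_drug - rel_vehicle at max deviation
    fit_vehicle: MeltingFit = field(default_factory=MeltingFit)
    fit_drug: MeltingFit = field(default_factory=MeltingFit)


# ---------------------------------------------------------------------------
# Matching


def _positions(spots: list[Spot]) -> np.ndarray:
    return np.array([[s.x, s.y] for s in spots]) if spots else np.empty((0, 2))


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray, max_distance: float):
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, k=1)
    d_ba, j_ba = ta.query(b, k=1)
    pairs = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if d <= max_distance and j_ba[j] == i:
            pairs.append((i, int(j)))
    return pairs


def estimate_affine(src: np.ndarray, dst: np.ndarray):
    """Least-squares 2x3 affine mapping src -> dst, with one round of
    3xMAD residual rejection.  Returns ((a,b,c),(d,e,f))."""
    def solve(s, d):
        A = np.column_stack([s[:, 0], s[:, 1], np.ones(len(s))])
        coef_x, *_ = np.linalg.lstsq(A, d[:, 0], rcond=None)
        coef_y, *_ = np.linalg.lstsq(A, d[:, 1], rcond=None)
        return coef_x, coef_y

    cx, cy = solve(src, dst)
    pred = np.column_stack(
        [src @ np.array([cx[0], cx[1]]) + cx[2], src @ np.array([cy[0], cy[1]]) + cy[2]]
    )
    resid = np.hypot(*(dst - pred).T)
    med = np.median(resid)
    mad = 1.4826 * np.median(np.abs(resid - med)) + 1e-12
    keep = resid <= med + 3.0 * mad
    if keep.sum() >= 3 and keep.sum() < len(src):
        cx, cy = solve(src[keep], dst[keep])
    return (tuple(float(v) for v in cx), tuple(float(v) for v in cy))


def _apply_affine(points: np.ndarray, affine):
    (a, b, c), (d, e, f) = affine
    x = a * points[:, 0] + b * points[:, 1] + c
    y = d * points[:, 0] + e * points[:, 1] + f
    return np.column_stack([x, y])


def match_spots(
    gels: dict[float, list[Spot]],
    max_distance: float = 3.0,
    registration_max_distance: float = 6.0,
) -> list[SpotTrack]:
    """Match spots across the temperature series into tracks.

    The lowest temperature is the baseline.  Each heated gel is registered
    to the baseline by a least-squares affine estimated from mutual-nearest-
    neighbor pairs (falling back to identity, with a warning, below 3
    pairs); spots are then assigned to baseline spots by nearest neighbor
    within ``max_distance``.  Heated spots without a baseline partner start
    no track (a protein absent at baseline has no internal standard).
    """
    temps = sorted(gels)
    t0 = temps[0]
    baseline = gels[t0]
    base_xy = _positions(baseline)
    tracks = [
        SpotTrack(track_id=f"t{i:04d}", reference_spot=s, members={t0: s})
        for i, s in enumerate(baseline)
    ]
    for t in temps[1:]:
        spots = gels[t]
        xy = _positions(spots)
        pairs = _mutual_nn_pairs(xy, base_xy, registration_max_distance)
        if len(pairs) < 3:
            log.warning("gel at %.1f C: <3 mutual pairs, identity registration", t)
            affine = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
        else:
            src = xy[[i for i, _ in pairs]]
            dst = base_xy[[j for _, j in pairs]]
            affine = estimate_affine(src, dst)
        if len(xy) == 0:
            continue
        mapped = _apply_affine(xy, affine)
        # greedy one-to-one assignment by distance within max_distance
        if len(base_xy) == 0:
            continue
        tree = cKDTree(base_xy)
        dists, idxs = tree.query(mapped, k=1)
        order = np.argsort(dists)
        used = set()
        for i in order:
            if dists[i] > max_distance:
                break
            j = int(idxs[i])
            if j in used:
                continue
            used.add(j)
            tracks[j].members[t] = spots[int(i)]
    n_temps = len(temps)
    for tr in tracks:
        tr.complete = len(tr.members) == n_temps
        n_heated = n_temps - 1
        missing_heated = n_heated - (len(tr.members) - 1)
        tr.partial = n_heated > 0 and missing_heated > 0.5 * n_heated
    return tracks


# ---------------------------------------------------------------------------
# Normalization


def normalize_track(track: SpotTrack, cy2_floor: float = 1e-9) -> SpotTrack:
    """Fill rel_vehicle / rel_drug by internal-standard normalization.

    R_c(T) = I_c(T)/I_cy2(T), rel_c(T) = R_c(T)/R_c(T_baseline); per-gel
    gain cancels exactly.  Points whose Cy2 is at/below the floor are left
    missing (and logged), never zero-filled.
    """
    temps = sorted(track.members)
    t0 = temps[0]
    s0 = track.members[t0]
    if s0.intensity_cy2 <= cy2_floor:
        log.warning("track %s: baseline Cy2 below floor, no normalization", track.track_id)
        track.rel_vehicle, track.rel_drug = {}, {}
        return track
    r3_0 = s0.intensity_cy3 / s0.intensity_cy2
    r5_0 = s0.intensity_cy5 / s0.intensity_cy2
    rel_v, rel_d = {}, {}
    for t in temps:
        s = track.members[t]
        if s.intensity_cy2 <= cy2_floor:
            log.info("track %s: Cy2 below floor at %.1f C, point missing", track.track_id, t)
            continue
        if r3_0 > 0:
            rel_v[t] = (s.intensity_cy3 / s.intensity_cy2) / r3_0
        if r5_0 > 0:
            rel_d[t] = (s.intensity_cy5 / s.intensity_cy2) / r5_0
    track.rel_vehicle, track.rel_drug = rel_v, rel_d
    return track


# ---------------------------------------------------------------------------
# Melting-curve fitting


def fit_melting(temperatures, fractions) -> MeltingFit:
    """Nonlinear least-squares fit of the 3-parameter logistic melt.

    Requires >= 4 non-missing points spanning both sides of the apparent
    midpoint; otherwise (or for flat input) returns converged=False with
    NaN parameters.  Initialization: coarse grid over Tm (observed range)
    and k in {0.2, 0.5, 1, 2}; bounds 0 <= p <= 0.5, k > 0.
    """
    t = np.asarray(temperatures, float)
    f = np.asarray(fractions, float)
    ok = np.isfinite(t) & np.isfinite(f)
    t, f = t[ok], f[ok]
    if len(t) < 4:
        return MeltingFit()
    span = float(f.max() - f.min())
    if span < 0.2:  # flat curve: no resolvable transition
        return MeltingFit()
    mid = (f.max() + f.min()) / 2.0
    if not (np.any(f > mid) and np.any(f < mid)):
        return MeltingFit()

    tm_grid = np.linspace(t.min(), t.max(), 16)
    k_grid = np.array((0.2, 0.5, 1.0, 2.0))
    p_grid = np.array((0.0, 0.2))
    tm_g, k_g, p_g = np.meshgrid(tm_grid, k_grid, p_grid, indexing="ij")
    tm_g, k_g, p_g = tm_g.ravel(), k_g.ravel(), p_g.ravel()
    z = np.clip(k_g[:, None] * (t[None, :] - tm_g[:, None]), -500, 500)
    model = p_g[:, None] + (1.0 - p_g[:, None]) / (1.0 + np.exp(z))
    sse = ((model - f[None, :]) ** 2).sum(axis=1)
    ibest = int(np.argmin(sse))
    best = (float(tm_g[ibest]), float(k_g[ibest]), float(p_g[ibest]))

    def resid(p):
        return logistic_melt(t, p[0], p[1], p[2]) - f

    def jac(p):
        tm, k, pl = p
        zz = np.clip(k * (t - tm), -500, 500)
        s = 1.0 / (1.0 + np.exp(zz))
        ss = s * (1.0 - s)
        return np.column_stack(
            [(1.0 - pl) * k * ss, -(1.0 - pl) * ss * (t - tm), 1.0 - s]
        )

    lb = [t.min() - 15.0, 1e-3, 0.0]
    ub = [t.max() + 15.0, 10.0, 0.5]
    x0 = np.clip(best, lb, ub)
    try:
        res = optimize.least_squares(resid, x0, jac=jac, bounds=(lb, ub), max_nfev=500)
    except Exception:  # pragma: no cover
        return MeltingFit()
    tm, k, p = (float(v) for v in res.x)
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if k <= 0:
        return MeltingFit()
    return MeltingFit(tm=tm, slope_k=k, plateau_p=p, r_squared=r2, converged=True)


# ---------------------------------------------------------------------------
# Shift scoring


def score_shift(track: SpotTrack, fit_vehicle: MeltingFit, fit_drug: MeltingFit) -> ShiftResult:
    """Longitudinal (y-deviation) and transverse (ΔTm) shift statistics.

    y_dev_max / y_dev_area are computed from the normalized *data points*
    over temperatures where both conditions were measured; ΔTm only when
    both logistic fits converged.  ``z_score`` is filled later across the
    whole run (see :func:`score_run`).
    """
    common = sorted(set(track.rel_vehicle) & set(track.rel_drug))
    res = ShiftResult(track_id=track.track_id, fit_vehicle=fit_vehicle, fit_drug=fit_drug)
    if common:
        diffs = np.array([track.rel_drug[t] - track.rel_vehicle[t] for t in common])
        adiffs = np.abs(diffs)
        imax = int(np.argmax(adiffs))
        res.y_dev_max = float(adiffs[imax])
        if len(common) >= 2:
            res.y_dev_area = float(np.trapezoid(adiffs, np.asarray(common, float)))
        if adiffs[imax] > 0:
            res.direction = "up" if diffs[imax] > 0 else "down"
    if fit_vehicle.converged and fit_drug.converged:
        res.delta_tm = fit_drug.tm - fit_vehicle.tm
    return res


def score_run(tracks: list[SpotTrack], fit_curves: bool = True) -> list[ShiftResult]:
    """Normalize, fit (unless the track is flagged partial) and score every
    track; z-scores standardize y_dev_max against all tracks in the run."""
    results = []
    for tr in tracks:
        if not tr.rel_vehicle and not tr.rel_drug:
            normalize_track(tr)
        fv = fd = MeltingFit()
        if fit_curves and not tr.partial:
            temps_v = sorted(tr.rel_vehicle)
            temps_d = sorted(tr.rel_drug)
            fv = fit_melting(temps_v, [tr.rel_vehicle[t] for t in temps_v])
            fd = fit_melting(temps_d, [tr.rel_drug[t] for t in temps_d])
        results.append(score_shift(tr, fv, fd))
    ydev = np.array([r.y_dev_max for r in results])
    if len(ydev) >= 2 and ydev.std() > 0:
        z = (ydev - ydev.mean()) / ydev.std()
        for r, zi in zip(results, z):
            r.z_score = float(zi)
    return results
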