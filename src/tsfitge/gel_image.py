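"""Gel-image ingestion, background correction, spot detection and quantification.

A gel carries three co-registered fluorescence rasters: Cy2 (unheated
internal-standard proteome), Cy3 (vehicle-treated) and Cy5 (drug-treated).
Detection runs on the per-pixel maximum of the background-corrected
channels so that spots present in only one channel (PTM satellites, fully
destabilized proteins) are still found.  Each detected spot is refined by an
elliptical 2D-Gaussian least-squares fit, and all three channels are
quantified over the *same* 3-sigma elliptical footprint so that per-spot
ratios compare like with like.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.morphology import disk

log = logging.getLogger(__name__)

SATURATION_FRACTION = 0.995  # of dtype max; such pixels excluded from fits


@dataclass
class GelImage:
    """One temperature point: three co-registered intensity rasters."""

    cy2: np.ndarray
    cy3: np.ndarray
    cy5: np.ndarray
    temperature: float
    gel_id: str = ""
    pixel_scale: tuple[float, float] | None = None  # (pI/px, log10 kDa/px)

    def __post_init__(self):
        if not (self.cy2.shape == self.cy3.shape == self.cy5.shape):
            raise ValueError("the three channel rasters must share one shape")
        if not np.isfinite(self.temperature):
            raise ValueError("gel temperature must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cy2.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {"cy2": self.cy2, "cy3": self.cy3, "cy5": self.cy5}


@dataclass
class Spot:
    """A detected gel feature with per-channel integrated intensities.

    ``x`` is the column coordinate (increasing pI), ``y`` the row coordinate
    (increasing row = decreasing molecular weight); both sub-pixel, 0-based.
    Integrated intensities are background-corrected and clipped at zero
    (clipping is flagged).
    """

    spot_id: str
    x: float
    y: float
    sigma_x: float
    sigma_y: float
    theta: float
    intensity_cy2: float
    intensity_cy3: float
    intensity_cy5: float
    fit_quality: float = 0.0
    flags: tuple[str, ...] = ()

    @property
    def total_intensity(self) -> float:
        return self.intensity_cy2 + self.intensity_cy3 + self.intensity_cy5


# ---------------------------------------------------------------------------
# I/O


def read_gel(path, manifest_row: dict) -> GelImage:
    """Read a multi-page TIFF (pages ordered Cy2, Cy3, Cy5) into a GelImage.

    ``manifest_row`` must carry ``temperature_C`` and may carry ``gel_id``.
    Raises ``ValueError`` naming the file on page-count or shape mismatch.
    """
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim != 3 or pages.shape[0] < 3:
        raise ValueError(
            f"{path}: expected a >=3-page TIFF (Cy2, Cy3, Cy5), "
            f"got shape {pages.shape}"
        )
    cy2, cy3, cy5 = (pages[i].astype(float) for i in range(3))
    return GelImage(
        cy2=cy2,
        cy3=cy3,
        cy5=cy5,
        temperature=float(manifest_row["temperature_C"]),
        gel_id=str(manifest_row.get("gel_id", "")),
    )


# ---------------------------------------------------------------------------
# Background


def subtract_background(raster: np.ndarray, ball_radius: float) -> np.ndarray:
    """Morphological (rolling-ball style) background subtraction.

    Estimates the background as a grey opening with a disk footprint of the
    given radius, lightly smoothed, and subtracts it.  Flat regions map to
    ~0; the result is clipped to be non-negative.  ``ball_radius`` should be
    at least 3x the spot sigma (a warning is logged otherwise, but 3x is not
    checkable here without a spot model, so only non-positive radii error).
    """
    if ball_radius <= 0:
        raise ValueError("ball_radius must be positive")
    r = int(math.ceil(ball_radius))
    footprint = disk(r)
    background = ndimage.grey_opening(raster, footprint=footprint)
    background = ndimage.gaussian_filter(background, sigma=max(1.0, r / 4.0))
    # opening never exceeds the signal, so the subtraction is >= 0 up to the
    # smoothing; clip the remainder
    return np.clip(raster - background, 0.0, None)


def background_mad(raster: np.ndarray) -> float:
    """Robust per-pixel noise scale.

    Uses the larger of 1.4826*MAD and the upper-side percentile spread
    (P84.1 - median, = 1 sd for a Gaussian); the latter stays calibrated
    when the lower half of the distribution has been clipped at zero by
    background subtraction, which would otherwise halve the MAD.
    """
    med = float(np.median(raster))
    mad = 1.4826 * float(np.median(np.abs(raster - med)))
    upper = float(np.percentile(raster, 84.13)) - med
    return max(mad, upper)


# ---------------------------------------------------------------------------
# Elliptical Gaussian model


def _gauss2d(coords, amp, x0, y0, sx, sy, theta):
    x, y = coords
    ct, st = math.cos(theta), math.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def _fit_gaussians(window, origin, peaks, sigma_guess, mask=None):
    """Least-squares fit of a sum of elliptical Gaussians to a window.

    ``peaks``: list of (row, col) in full-image coordinates.  Returns a list
    of parameter tuples (amp, x0, y0, sx, sy, theta) in image coordinates and
    the fit R^2.
    """
    oy, ox = origin
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    if mask is None:
        mask = np.ones_like(window, dtype=bool)
    xs, ys, data = xx[mask].ravel(), yy[mask].ravel(), window[mask].ravel()
    n = len(peaks)
    sx0, sy0 = sigma_guess

    p0, lb, ub = [], [], []
    for (pr, pc) in peaks:
        amp0 = max(window[int(pr - oy), int(pc - ox)], 1e-6)
        p0 += [amp0, pc - ox, pr - oy, sx0, sy0, 0.0]
        lb += [0.0, pc - ox - 3.0, pr - oy - 3.0, 0.3, 0.3, -math.pi / 2]
        ub += [np.inf, pc - ox + 3.0, pr - oy + 3.0, 6.0 * sx0, 6.0 * sy0, math.pi / 2]

    def resid(p):
        model = np.zeros_like(data)
        for i in range(n):
            a, x0, y0, sx, sy, th = p[6 * i : 6 * i + 6]
            model += _gauss2d((xs, ys), a, x0, y0, sx, sy, th)
        return model - data

    try:
        res = optimize.least_squares(resid, p0, bounds=(lb, ub), max_nfev=400)
        p = res.x
        ss_res = float(np.sum(res.fun**2))
    except Exception:  # pragma: no cover - fit pathologies
        p = np.asarray(p0)
        ss_res = float(np.sum(resid(p) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    out = []
    for i in range(n):
        a, x0, y0, sx, sy, th = p[6 * i : 6 * i + 6]
        out.append((a, x0 + ox, y0 + oy, sx, sy, th))
    return out, max(0.0, min(1.0, r2))


def _ellipse_mask(shape, x0, y0, sx, sy, theta, n_sigma=3.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = math.cos(theta), math.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return (xr / (n_sigma * sx)) ** 2 + (yr / (n_sigma * sy)) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Detection


def detect_spots(
    gel: GelImage,
    min_snr: float = 5.0,
    min_separation: int = 1,
    sigma_guess: tuple[float, float] = (1.3, 0.9),
    smooth_sigma: float = 0.7,
    saturation_level: float | None = None,
) -> list[Spot]:
    """Detect and quantify spots on a background-corrected gel.

    Detection raster = per-pixel max over channels; candidates are local
    maxima above ``median + min_snr * MAD`` of the smoothed raster, with
    greedy suppression inside ``min_separation``.  Candidates whose fit
    windows overlap by more than 30% are refined jointly as a sum of
    Gaussians.  Each channel is quantified by integrating its raw
    (background-corrected) pixels inside the fitted 3-sigma ellipse — the
    identical pixel set for Cy2, Cy3 and Cy5.

    Returns spots sorted by total intensity, descending.
    """
    detection = np.maximum(np.maximum(gel.cy2, gel.cy3), gel.cy5)
    if float(detection.max() - detection.min()) == 0.0:
        log.warning("gel %s: zero-variance raster, no spots", gel.gel_id)
        return []
    smoothed = ndimage.gaussian_filter(detection, sigma=smooth_sigma)
    noise = background_mad(smoothed)
    if noise == 0.0:
        # noiseless synthetic rasters: fall back to a tiny absolute scale
        noise = 1e-9 * float(smoothed.max())
    threshold = float(np.median(smoothed)) + min_snr * noise
    coords = peak_local_max(
        smoothed,
        min_distance=int(min_separation),
        threshold_abs=threshold,
        exclude_border=False,
    )
    if len(coords) == 0:
        return []
    # deterministic tie-break: row-major order among equal maxima
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]

    sx0, sy0 = sigma_guess
    half = max(5, int(math.ceil(4.0 * max(sx0, sy0))))
    h, w = detection.shape

    sat_mask = None
    if saturation_level is None:
        saturation_level = SATURATION_FRACTION * 65535.0
    raw_max = np.maximum(np.maximum(gel.cy2, gel.cy3), gel.cy5)
    if float(raw_max.max()) >= saturation_level:
        sat_mask = raw_max >= saturation_level

    # group peaks whose square windows overlap > 30% (joint refinement)
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    win = 2 * half + 1
    for i in range(n):
        for j in range(i + 1, n):
            dy = abs(int(coords[i][0]) - int(coords[j][0]))
            dx = abs(int(coords[i][1]) - int(coords[j][1]))
            if dy >= win or dx >= win:
                continue
            overlap = (win - dy) * (win - dx) / float(win * win)
            if overlap > 0.30:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    # fit the total-intensity raster (sum of channels) for spot shape
    shape_raster = gel.cy2 + gel.cy3 + gel.cy5

    spots: list[Spot] = []
    for members in groups.values():
        pts = [(float(coords[i][0]), float(coords[i][1])) for i in members]
        r0 = max(0, int(min(p[0] for p in pts)) - half)
        r1 = min(h, int(max(p[0] for p in pts)) + half + 1)
        c0 = max(0, int(min(p[1] for p in pts)) - half)
        c1 = min(w, int(max(p[1] for p in pts)) + half + 1)
        window = shape_raster[r0:r1, c0:c1]
        wmask = None
        if sat_mask is not None:
            wmask = ~sat_mask[r0:r1, c0:c1]
            if not wmask.any():
                continue
        params, r2 = _fit_gaussians(window, (r0, c0), pts, sigma_guess, mask=wmask)
        for (amp, x0c, y0c, sx, sy, th) in params:
            if not (0 <= x0c < w and 0 <= y0c < h):
                continue
            flags: list[str] = []
            if sat_mask is not None and sat_mask[r0:r1, c0:c1].any():
                flags.append("saturated")
            # quantify the three channels over the identical 3-sigma ellipse
            er0 = max(0, int(y0c - 3 * sy - 2))
            er1 = min(h, int(y0c + 3 * sy + 3))
            ec0 = max(0, int(x0c - 3 * sx - 2))
            ec1 = min(w, int(x0c + 3 * sx + 3))
            emask = _ellipse_mask(
                (er1 - er0, ec1 - ec0), x0c - ec0, y0c - er0, sx, sy, th
            )
            intensities = {}
            for name, chan in gel.channels().items():
                val = float(chan[er0:er1, ec0:ec1][emask].sum())
                if val < 0:
                    flags.append(f"clipped_{name}")
                    val = 0.0
                intensities[name] = val
            spots.append(
                Spot(
                    spot_id="",
                    x=float(x0c),
                    y=float(y0c),
                    sigma_x=float(sx),
                    sigma_y=float(sy),
                    theta=float(th),
                    intensity_cy2=intensities["cy2"],
                    intensity_cy3=intensities["cy3"],
                    intensity_cy5=intensities["cy5"],
                    fit_quality=r2,
                    flags=tuple(flags),
                )
            )

    spots.sort(key=lambda s: (-s.total_intensity, s.y, s.x))
    return [replace(s, spot_id=f"s{i:04d}") for i, s in enumerate(spots)]


# ---------------------------------------------------------------------------
# Spot table I/O

SPOT_COLUMNS = [
    "gel_id",
    "spot_id",
    "x",
    "y",
    "sigma_x",
    "sigma_y",
    "theta",
    "I_cy2",
    "I_cy3",
    "I_cy5",
    "fit_quality",
    "flags",
]


def spots_to_frame(spots: list[Spot], gel_id: str = ""):
    """Spot list -> tidy DataFrame with the canonical column order."""
    import pandas as pd

    rows = [
        {
            "gel_id": gel_id,
            "spot_id": s.spot_id,
            "x": s.x,
            "y": s.y,
            "sigma_x": s.sigma_x,
            "sigma_y": s.sigma_y,
            "theta": s.theta,
            "I_cy2": s.intensity_cy2,
            "I_cy3": s.intensity_cy3,
            "I_cy5": s.intensity_cy5,
            "fit_quality": s.fit_quality,
            "flags": ";".join(s.flags),
        }
        for s in spots
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def frame_to_spots(frame) -> list[Spot]:
    return [
        Spot(
            spot_id=str(r.spot_id),
            x=float(r.x),
            y=float(r.y),
            sigma_x=float(r.sigma_x),
            sigma_y=float(r.sigma_y),
            theta=float(r.theta),
            intensity_cy2=float(r.I_cy2),
            intensity_cy3=float(r.I_cy3),
            intensity_cy5=float(r.I_cy5),
            fit_quality=float(r.fit_quality),
            flags=tuple(str(r.flags).split(";")) if str(r.flags) not in ("", "nan") else (),
        )
        for r in frame.itertuples(index=False)
    ]
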