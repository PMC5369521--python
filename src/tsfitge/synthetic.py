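"""Forward model of a thermal-shift difference-gel (TS-FITGE) experiment.

Generates a virtual proteome and renders, for each temperature in the
series, a three-channel gel image with full ground-truth annotation:

* Cy2 — unheated internal-standard proteome, heat-independent by design,
  added in equal amount to every gel so that per-gel imaging gain cancels
  in downstream normalization;
* Cy3 — vehicle-treated soluble fraction after heating;
* Cy5 — drug-treated soluble fraction after heating.

Thermal denaturation follows the 3-parameter logistic of
:mod:`tsfitge.melting`; drug binding shifts a target's midpoint by
``delta_tm``.  Drug-induced post-translational modification (PTM) of a
substrate moves a fraction ``phi`` of the drug-channel material to a
satellite position shifted in pI (horizontally), with
``phi = ptm_fraction_max * (1 - exp(-treatment_minutes / ptm_tau_min))`` —
at the unheated baseline this produces the characteristic horizontal
red/green spot pair.  Optional per-gel affine warp, inter-channel vertical
misregistration of the Cy5 raster, per-gel gain, and additive plus
signal-proportional Gaussian noise emulate the main imaging nuisances.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gel_image import GelImage, Spot
from .melting import logistic_melt, four_pl

# pI / molecular-weight extent of the virtual gel
PI_RANGE = (3.0, 11.0)
LOG10_MASS_RANGE = (1.0, 2.5)  # 10 .. ~316 kDa
MARGIN_PX = 16


@dataclass
class ProteinSpecies:
    """Ground-truth virtual protein."""

    species_id: str
    pI: float
    mass_kda: float
    abundance: float
    tm_vehicle: float
    slope_k: float
    plateau_p: float
    delta_tm: float = 0.0
    ptm_fraction_max: float = 0.0
    ptm_tau_min: float = 10.0
    ptm_delta_pi: float = 0.0

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.slope_k <= 0:
            raise ValueError("slope_k must be > 0")
        if not (0.0 <= self.plateau_p < 1.0):
            raise ValueError("plateau_p must be in [0, 1)")

    @property
    def is_target(self) -> bool:
        return self.delta_tm != 0.0

    @property
    def is_ptm_substrate(self) -> bool:
        return self.ptm_fraction_max != 0.0


@dataclass
class NoiseModel:
    background: float = 100.0
    additive_sd: float = 5.0
    proportional_cv: float = 0.03

    def off(self) -> "NoiseModel":
        return NoiseModel(background=0.0, additive_sd=0.0, proportional_cv=0.0)


@dataclass
class ExperimentDesign:
    """Per-run experimental and imaging parameters.

    ``temperatures`` must be strictly increasing with the first entry the
    unheated baseline.  ``gel_gain``, ``warp`` and ``misregistration_dy``
    each carry one entry per temperature.
    """

    temperatures: tuple[float, ...] = (37.0, 41.0, 45.0, 49.0, 53.0, 57.0, 61.0, 64.0)
    treatment_minutes: float = 20.0
    gel_gain: tuple[float, ...] | None = None
    warp: tuple | None = None  # per gel: 2x3 affine, pixel units
    misregistration_dy: tuple[float, ...] | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    image_shape: tuple[int, int] = (384, 384)
    psf_sigma: tuple[float, float] = (1.3, 0.9)  # (sigma_x, sigma_y) px
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.temperatures, float)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.treatment_minutes < 0:
            raise ValueError("treatment_minutes must be >= 0")
        n = len(self.temperatures)
        if self.gel_gain is None:
            self.gel_gain = tuple([1.0] * n)
        if len(self.gel_gain) != n or any(g <= 0 for g in self.gel_gain):
            raise ValueError("gel_gain: one positive value per temperature")
        if self.warp is None:
            self.warp = tuple(((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)) for _ in range(n))
        if self.misregistration_dy is None:
            self.misregistration_dy = tuple([0.0] * n)
        if len(self.misregistration_dy) != n or len(self.warp) != n:
            raise ValueError("warp / misregistration_dy: one entry per temperature")
        if min(self.image_shape) <= 2 * MARGIN_PX:
            raise ValueError("image_shape too small")

    @property
    def baseline_temperature(self) -> float:
        return float(self.temperatures[0])


def make_design(
    seed: int = 0,
    gain_sd: float = 0.10,
    warp_shift_px: float = 2.0,
    misregistration_dy: float = 0.0,
    **kwargs,
) -> ExperimentDesign:
    """Randomized-nuisance design: log-normal per-gel gain and small random
    affine shifts for heated gels; the baseline gel is the identity frame."""
    rng = np.random.default_rng(seed)
    base = ExperimentDesign(seed=seed, **kwargs)
    n = len(base.temperatures)
    gains = np.exp(rng.normal(0.0, gain_sd, size=n))
    warps = [((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))]
    for _ in range(n - 1):
        dx, dy = rng.uniform(-warp_shift_px, warp_shift_px, size=2)
        warps.append(((1.0, 0.0, float(dx)), (0.0, 1.0, float(dy))))
    return ExperimentDesign(
        temperatures=base.temperatures,
        treatment_minutes=base.treatment_minutes,
        gel_gain=tuple(float(g) for g in gains),
        warp=tuple(warps),
        misregistration_dy=tuple([float(misregistration_dy)] * n),
        noise=base.noise,
        image_shape=base.image_shape,
        psf_sigma=base.psf_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Coordinate convention: row 0 = top = high molecular weight;
# column 0 = left = low pI; 0-based pixel centers at integers.


def pi_mass_to_pixel(pI, mass_kda, image_shape) -> tuple[np.ndarray, np.ndarray]:
    """Map (pI, mass) to (x=column, y=row), with a margin inside the raster."""
    rows, cols = image_shape
    lo, hi = PI_RANGE
    x = MARGIN_PX + (np.asarray(pI, float) - lo) / (hi - lo) * (cols - 1 - 2 * MARGIN_PX)
    mlo, mhi = LOG10_MASS_RANGE
    frac = (mhi - np.log10(np.asarray(mass_kda, float))) / (mhi - mlo)
    y = MARGIN_PX + frac * (rows - 1 - 2 * MARGIN_PX)
    return x, y


def apply_warp(x, y, warp) -> tuple[np.ndarray, np.ndarray]:
    (a, b, c), (d, e, f) = warp
    return a * x + b * y + c, d * x + e * y + f


# ---------------------------------------------------------------------------
# Proteome generation

DEFAULT_RANGES: dict = {
    "pI": (3.5, 10.5),
    "log10_mass": (1.1, 2.4),
    "log_abundance_mean": math.log(4.0e4),
    "log_abundance_sd": 0.4,
    "tm_mean": 50.0,
    "tm_sd": 5.0,
    "tm_clip": (40.0, 65.0),
    "log_slope_sd": 0.25,  # slope_k ~ lognormal around 1 /degC
    "plateau": (0.0, 0.15),
    "delta_tm": (8.0, 8.0),  # targets; sign as given
    "ptm_fraction_max": (0.4, 0.7),
    "ptm_tau_min": (5.0, 15.0),
    "ptm_delta_pi_abs": (0.10, 0.20),  # sign randomized
}


def generate_proteome(
    n_species: int,
    n_targets: int = 0,
    n_ptm_substrates: int = 0,
    seed: int = 0,
    param_ranges: dict | None = None,
    min_separation_px: float | None = None,
    image_shape: tuple[int, int] = (384, 384),
) -> list[ProteinSpecies]:
    """Draw a virtual proteome; deterministic given ``seed``.

    Exactly ``n_targets`` species carry a nonzero ``delta_tm`` and exactly
    ``n_ptm_substrates`` (disjoint from the targets) carry a nonzero
    ``ptm_fraction_max``.  If ``min_separation_px`` is given, positions are
    re-drawn (dart throwing) until every pair of species is at least that
    far apart when mapped onto ``image_shape``.
    """
    if n_targets < 0 or n_ptm_substrates < 0 or n_species < 0:
        raise ValueError("counts must be non-negative")
    if n_targets + n_ptm_substrates > n_species:
        raise ValueError(
            "invalid design: n_targets + n_ptm_substrates exceeds n_species"
        )
    pr = dict(DEFAULT_RANGES)
    if param_ranges:
        pr.update(param_ranges)
    rng = np.random.default_rng(seed)

    pis = np.empty(n_species)
    masses = np.empty(n_species)
    accepted_xy: list[tuple[float, float]] = []
    for i in range(n_species):
        for _attempt in range(200):
            pi = rng.uniform(*pr["pI"])
            mass = 10.0 ** rng.uniform(*pr["log10_mass"])
            if min_separation_px is None:
                break
            x, y = pi_mass_to_pixel(pi, mass, image_shape)
            if all(
                (x - ax) ** 2 + (y - ay) ** 2 >= min_separation_px**2
                for ax, ay in accepted_xy
            ):
                break
        else:
            raise RuntimeError("could not place species with requested separation")
        pis[i], masses[i] = pi, mass
        if min_separation_px is not None:
            x, y = pi_mass_to_pixel(pi, mass, image_shape)
            accepted_xy.append((float(x), float(y)))

    abundance = np.exp(rng.normal(pr["log_abundance_mean"], pr["log_abundance_sd"], n_species))
    tm = np.clip(rng.normal(pr["tm_mean"], pr["tm_sd"], n_species), *pr["tm_clip"])
    slope = np.exp(rng.normal(0.0, pr["log_slope_sd"], n_species))
    plateau = rng.uniform(*pr["plateau"], n_species)

    order = rng.permutation(n_species)
    target_idx = set(order[:n_targets].tolist())
    ptm_idx = set(order[n_targets : n_targets + n_ptm_substrates].tolist())

    species = []
    for i in range(n_species):
        dtm = float(rng.uniform(*pr["delta_tm"])) if i in target_idx else 0.0
        if i in ptm_idx:
            fmax = float(rng.uniform(*pr["ptm_fraction_max"]))
            tau = float(rng.uniform(*pr["ptm_tau_min"]))
            dpi = float(rng.uniform(*pr["ptm_delta_pi_abs"])) * (
                1.0 if rng.random() < 0.5 else -1.0
            )
        else:
            fmax, tau, dpi = 0.0, 10.0, 0.0
        species.append(
            ProteinSpecies(
                species_id=f"p{i:04d}",
                pI=float(pis[i]),
                mass_kda=float(masses[i]),
                abundance=float(abundance[i]),
                tm_vehicle=float(tm[i]),
                slope_k=float(slope[i]),
                plateau_p=float(plateau[i]),
                delta_tm=dtm,
                ptm_fraction_max=fmax,
                ptm_tau_min=tau,
                ptm_delta_pi=dpi,
            )
        )
    return species


# ---------------------------------------------------------------------------
# Melting / amounts


def soluble_fraction(species: ProteinSpecies, temperature: float, condition: str) -> float:
    """Soluble fraction after heating to ``temperature``.

    ``condition`` is ``"vehicle"`` or ``"drug"``; under drug the midpoint is
    shifted by ``delta_tm``.  Monotone non-increasing in temperature, in
    [plateau_p, 1].
    """
    if condition not in ("vehicle", "drug"):
        raise ValueError("condition must be 'vehicle' or 'drug'")
    tm_eff = species.tm_vehicle + (species.delta_tm if condition == "drug" else 0.0)
    return logistic_melt(temperature, tm_eff, species.slope_k, species.plateau_p)


def ptm_fraction(species: ProteinSpecies, treatment_minutes: float) -> float:
    """Fraction of drug-channel material converted to the PTM form."""
    if species.ptm_fraction_max == 0.0:
        return 0.0
    return species.ptm_fraction_max * (
        1.0 - math.exp(-treatment_minutes / species.ptm_tau_min)
    )


def channel_amounts(species: ProteinSpecies, design: ExperimentDesign, temperature: float):
    """Ground-truth integrated amounts (before gain) for one species/gel.

    Returns dict with cy2, cy3, cy5_parent, cy5_satellite.  The internal
    standard (Cy2) is heat-independent; PTM splits the Cy5 amount between
    the parent position (1 - phi) and the pI-shifted satellite (phi).
    """
    phi = ptm_fraction(species, design.treatment_minutes)
    cy5_total = species.abundance * soluble_fraction(species, temperature, "drug")
    return {
        "cy2": species.abundance,
        "cy3": species.abundance * soluble_fraction(species, temperature, "vehicle"),
        "cy5_parent": cy5_total * (1.0 - phi),
        "cy5_satellite": cy5_total * phi,
    }


# ---------------------------------------------------------------------------
# Rendering


def _deposit(raster, x0, y0, total, sx, sy, trunc=4.0):
    """Add an elliptical Gaussian of integrated intensity ``total``."""
    h, w = raster.shape
    r0 = max(0, int(math.floor(y0 - trunc * sy)))
    r1 = min(h, int(math.ceil(y0 + trunc * sy)) + 1)
    c0 = max(0, int(math.floor(x0 - trunc * sx)))
    c1 = min(w, int(math.ceil(x0 + trunc * sx)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    amp = total / (2.0 * math.pi * sx * sy)
    raster[r0:r1, c0:c1] += amp * np.exp(
        -0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2)
    )


def ground_truth_positions(proteome, design: ExperimentDesign, temperature_index: int):
    """Per-species warped pixel positions and channel amounts for one gel."""
    t = float(design.temperatures[temperature_index])
    warp = design.warp[temperature_index]
    rows = []
    for sp in proteome:
        x, y = pi_mass_to_pixel(sp.pI, sp.mass_kda, design.image_shape)
        xw, yw = apply_warp(float(x), float(y), warp)
        amounts = channel_amounts(sp, design, t)
        sat_x = None
        if amounts["cy5_satellite"] > 0:
            xs, _ = pi_mass_to_pixel(sp.pI + sp.ptm_delta_pi, sp.mass_kda, design.image_shape)
            sat_x, _ = apply_warp(float(xs), float(y), warp)
        rows.append(
            {
                "species_id": sp.species_id,
                "x": float(xw),
                "y": float(yw),
                "satellite_x": None if sat_x is None else float(sat_x),
                **amounts,
            }
        )
    return rows


def render_gel(proteome, design: ExperimentDesign, temperature_index: int) -> GelImage:
    """Render the three-channel raster for one temperature point."""
    if not 0 <= temperature_index < len(design.temperatures):
        raise IndexError("temperature_index out of range")
    t = float(design.temperatures[temperature_index])
    gain = float(design.gel_gain[temperature_index])
    dy5 = float(design.misregistration_dy[temperature_index])
    sx, sy = design.psf_sigma
    shape = design.image_shape
    cy2 = np.zeros(shape)
    cy3 = np.zeros(shape)
    cy5 = np.zeros(shape)

    h, w = shape
    for row in ground_truth_positions(proteome, design, temperature_index):
        x, y = row["x"], row["y"]
        if not (0 <= x < w and 0 <= y < h):
            import logging

            logging.getLogger(__name__).warning(
                "species %s maps outside raster at (%.1f, %.1f); clipped",
                row["species_id"], x, y,
            )
            x = min(max(x, 0.0), w - 1.0)
            y = min(max(y, 0.0), h - 1.0)
        _deposit(cy2, x, y, gain * row["cy2"], sx, sy)
        _deposit(cy3, x, y, gain * row["cy3"], sx, sy)
        _deposit(cy5, x, y + dy5, gain * row["cy5_parent"], sx, sy)
        if row["cy5_satellite"] > 0:
            _deposit(cy5, row["satellite_x"], y + dy5, gain * row["cy5_satellite"], sx, sy)

    nz = design.noise
    rng = np.random.default_rng([int(design.seed) % (2**31), 1000 + temperature_index])
    for raster in (cy2, cy3, cy5):
        if nz.proportional_cv > 0:
            raster += rng.normal(0.0, 1.0, shape) * (nz.proportional_cv * raster)
        raster += nz.background
        if nz.additive_sd > 0:
            raster += rng.normal(0.0, nz.additive_sd, shape)
        np.clip(raster, 0.0, None, out=raster)

    return GelImage(
        cy2=cy2, cy3=cy3, cy5=cy5, temperature=t,
        gel_id=f"gel_{temperature_index:02d}_{t:g}C",
    )


# ---------------------------------------------------------------------------
# Run serialization (images + manifest + ground truth)


def write_run(proteome, design: ExperimentDesign, outdir) -> pd.DataFrame:
    """Render every gel, write 16-bit 3-page TIFFs (Cy2, Cy3, Cy5), a run
    manifest TSV and a ground-truth JSON.  Returns the manifest frame."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_gels = {}
    for i, t in enumerate(design.temperatures):
        gel = render_gel(proteome, design, i)
        fname = f"{gel.gel_id}.tif"
        stack = np.stack(
            [np.clip(np.round(c), 0, 65535).astype(np.uint16)
             for c in (gel.cy2, gel.cy3, gel.cy5)]
        )
        tifffile.imwrite(outdir / fname, stack, photometric="minisblack")
        rows.append(
            {"filename": fname, "temperature_C": float(t), "gel_id": gel.gel_id,
             "page_order": "cy2,cy3,cy5"}
        )
        truth_gels[gel.gel_id] = ground_truth_positions(proteome, design, i)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth = {
        "design": _design_dict(design),
        "species": [asdict(sp) for sp in proteome],
        "gels": truth_gels,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest


def _design_dict(design: ExperimentDesign) -> dict:
    d = asdict(design)
    d["noise"] = asdict(design.noise)
    return d


# ---------------------------------------------------------------------------
# Pre-quantified spot-table route (skips image rendering)


def simulate_spot_tables(
    proteome,
    design: ExperimentDesign,
    position_jitter_px: float = 0.3,
) -> dict[float, list[Spot]]:
    """Forward-model *quantified* spot tables directly, one per temperature.

    Emulates the output of perfect detection with measurement noise:
    integrated intensities get the design's signal-proportional CV plus
    additive noise on the integrated scale (additive_sd scaled by the
    ~3-sigma footprint area), positions get the per-gel warp, the Cy5
    misregistration has no effect on integrated amounts and is omitted.
    PTM satellites appear as separate spots.  Deterministic given the
    design seed.
    """
    sx, sy = design.psf_sigma
    foot_px = math.pi * (3 * sx) * (3 * sy)
    add_sd = design.noise.additive_sd * math.sqrt(foot_px)
    cv = design.noise.proportional_cv
    out: dict[float, list[Spot]] = {}
    for i, t in enumerate(design.temperatures):
        rng = np.random.default_rng([int(design.seed) % (2**31), 2000 + i])
        gain = float(design.gel_gain[i])
        spots: list[Spot] = []
        k = 0
        for row in ground_truth_positions(proteome, design, i):
            entries = [(row["x"], row["y"], row["cy2"], row["cy3"], row["cy5_parent"])]
            if row["cy5_satellite"] > 0:
                entries.append((row["satellite_x"], row["y"], 0.0, 0.0, row["cy5_satellite"]))
            for (x, y, a2, a3, a5) in entries:
                jx, jy = rng.normal(0.0, position_jitter_px, size=2)
                ints = []
                for amount in (a2, a3, a5):
                    v = gain * amount
                    v = v * (1.0 + rng.normal(0.0, cv)) + rng.normal(0.0, add_sd)
                    ints.append(max(v, 0.0))
                spots.append(
                    Spot(
                        spot_id=f"s{k:04d}",
                        x=float(x + jx),
                        y=float(y + jy),
                        sigma_x=sx,
                        sigma_y=sy,
                        theta=0.0,
                        intensity_cy2=ints[0],
                        intensity_cy3=ints[1],
                        intensity_cy5=ints[2],
                        fit_quality=1.0,
                    )
                )
                k += 1
        out[float(t)] = spots
    return out


# ---------------------------------------------------------------------------
# Dose-response forward model


def simulate_dose_response(
    ec50: float,
    hill: float,
    top: float,
    bottom: float,
    doses,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter-logistic dose-response table with Gaussian noise."""
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    doses = np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ValueError("invalid input: doses must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in doses:
        mu = four_pl(float(c), ec50, hill, top, bottom)
        for r in range(replicates):
            rows.append(
                {"dose_uM": float(c), "replicate": r,
                 "response": mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)}
            )
    return pd.DataFrame(rows)
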