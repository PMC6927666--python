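"""Ground-truthed synthetic data: PLA scenes, force curves and QI grids.

The generators emulate the statistical structure the analysis pipelines key
on — not photorealism:

* **PLA scenes**: blurred axis-aligned elliptical nuclei on a dark nuclear
  channel; diffraction-limited Gaussian puncta placed at known positions
  strictly inside (nuclear) or outside (cytosolic) the nuclei on a signal
  channel with a smooth planar background gradient; optional additive
  Gaussian (or Poisson) noise.
* **Force curves**: a linear non-contact baseline followed by the Hertz
  sphere or Sneddon cone contact law, solved self-consistently with
  cantilever bending (``z - z_contact = delta + F/k``), truncated at the
  maximum load, with seeded additive force noise.
* **QI grids**: one curve per pixel with pixel-specific modulus and contact
  height, seeded independently per pixel by splitmix-style seed mixing.

Every generator is a pure function of its spec (including the seed), so the
same spec reproduces bit-identical data, and the returned ground truth is
sufficient to score every downstream pipeline exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .afm import ForceCurve, ProbeSpec, hertz_sphere_force, sneddon_cone_force
from .errors import GeneratorError, InvalidParameterError
from .image_ops import Image2D

__all__ = [
    "PlaSceneSpec",
    "PlaSceneTruth",
    "make_pla_scene",
    "make_spread_scene",
    "ForceSceneSpec",
    "make_force_curve",
    "make_qi_grid",
    "mix_seed",
]

_MAX_ATTEMPTS = 10_000


def mix_seed(seed: int, *salt: int) -> int:
    """Splitmix64-style mixing of a base seed with salts; result < 2**31."""
    x = (seed & 0xFFFFFFFFFFFFFFFF) ^ 0x9E3779B97F4A7C15
    for s in salt:
        x = (x + 0x9E3779B97F4A7C15 + (s & 0xFFFFFFFFFFFFFFFF)) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 30
        x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 27
        x = (x * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 31
    return int(x % (2**31))


# ---------------------------------------------------------------------------
# PLA scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlaSceneSpec:
    """Specification of a two-channel synthetic PLA scene.

    Default values describe a typical high-content frame: a dozen nuclei of
    10-16 px radius in a 256x256 field, 15 nuclear and 25 cytosolic puncta of
    sigma 1.5 px whose peak stands 5x above the background plane.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 12
    nucleus_radii: tuple[float, float] = (10.0, 16.0)
    nucleus_intensity: float = 120.0
    nucleus_blur_sigma: float = 3.0
    n_nuclear_spots: int = 15
    n_cytosolic_spots: int = 25
    spot_sigma: float = 1.5
    spot_peak: float = 100.0
    background: tuple[float, float, float] = (20.0, 0.02, 0.03)  # base, row & col slope
    noise_sd: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.n_nuclear_spots < 0 or self.n_cytosolic_spots < 0:
            raise InvalidParameterError("counts must be >= 0")
        if self.n_nuclear_spots > 0 and self.n_nuclei == 0:
            raise InvalidParameterError("nuclear spots require at least one nucleus")
        if self.spot_sigma <= 0 or self.nucleus_blur_sigma <= 0:
            raise InvalidParameterError("sigmas must be > 0")
        if min(self.nucleus_radii) <= 0 or self.nucleus_radii[0] > self.nucleus_radii[1]:
            raise InvalidParameterError("nucleus_radii must be an increasing positive pair")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class PlaSceneTruth:
    """Ground truth of a generated scene: every nucleus and every punctum."""

    nuclei: list[dict]  # {"center": (r, c), "axes": (a, b)}
    spots: list[dict]  # {"center": (r, c), "compartment": "nuclear"|"cytosolic"}

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_nuclear(self) -> int:
        return sum(s["compartment"] == "nuclear" for s in self.spots)

    @property
    def n_cytosolic(self) -> int:
        return sum(s["compartment"] == "cytosolic" for s in self.spots)


def _inside_ellipse(p, center, axes, margin: float = 0.0) -> bool:
    """Point inside the ellipse grown by an absolute margin on each axis."""
    dr = (p[0] - center[0]) / (axes[0] + margin)
    dc = (p[1] - center[1]) / (axes[1] + margin)
    return dr * dr + dc * dc <= 1.0


def make_pla_scene(spec: PlaSceneSpec) -> tuple[Image2D, Image2D, PlaSceneTruth]:
    """Generate a (dapi, pla, truth) triple for one synthetic scene.

    Nuclei are rejection-sampled so they neither touch each other nor the
    image border; nuclear puncta sit well inside a nucleus ellipse (75% of
    the axes) and cytosolic puncta well outside every nucleus (125%), with a
    minimum punctum separation so each punctum is countable.  Placement
    failure after 10,000 attempts raises a generator error.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape

    # --- nuclei -----------------------------------------------------------
    nuclei: list[dict] = []
    r_lo, r_hi = spec.nucleus_radii
    for _ in range(spec.n_nuclei):
        placed = False
        for _attempt in range(_MAX_ATTEMPTS):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            margin_r = a + 3 * spec.nucleus_blur_sigma
            margin_c = b + 3 * spec.nucleus_blur_sigma
            if 2 * margin_r >= rows or 2 * margin_c >= cols:
                continue
            cr = rng.uniform(margin_r, rows - margin_r)
            cc = rng.uniform(margin_c, cols - margin_c)
            # keep nuclei individual and well separated: their blurred skirts
            # must not merge into one thresholded object
            gap = 4.0 * spec.nucleus_blur_sigma + 2.0
            ok = all(
                math.hypot(cr - nuc["center"][0], cc - nuc["center"][1])
                > max(a, b) + max(nuc["axes"]) + gap
                for nuc in nuclei
            )
            if ok:
                nuclei.append({"center": (cr, cc), "axes": (a, b)})
                placed = True
                break
        if not placed:
            raise GeneratorError("could not place nuclei without overlap")

    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    dapi = np.zeros((rows, cols))
    for nuc in nuclei:
        (r0, c0), (a, b) = nuc["center"], nuc["axes"]
        inside = ((rr - r0) / a) ** 2 + ((cc_grid - c0) / b) ** 2 <= 1.0
        dapi[inside] = spec.nucleus_intensity
    dapi = ndi.gaussian_filter(dapi, spec.nucleus_blur_sigma, mode="nearest")

    # --- puncta -----------------------------------------------------------
    base, slope_r, slope_c = spec.background
    pla = base + slope_r * rr + slope_c * cc_grid

    min_sep = max(6.0, 4.0 * spec.spot_sigma)
    border = 5.0 + 3.0 * spec.spot_sigma
    spots: list[dict] = []

    def too_close(p) -> bool:
        return any(
            math.hypot(p[0] - s["center"][0], p[1] - s["center"][1]) < min_sep
            for s in spots
        )

    for _ in range(spec.n_nuclear_spots):
        placed = False
        for _attempt in range(_MAX_ATTEMPTS):
            nuc = nuclei[rng.integers(len(nuclei))]
            (r0, c0), (a, b) = nuc["center"], nuc["axes"]
            t = rng.uniform(0, 2 * math.pi)
            rho = math.sqrt(rng.uniform(0, 1.0))
            p = (r0 + 0.75 * a * rho * math.sin(t), c0 + 0.75 * b * rho * math.cos(t))
            if not too_close(p):
                spots.append({"center": p, "compartment": "nuclear"})
                placed = True
                break
        if not placed:
            raise GeneratorError("could not place nuclear puncta")

    for _ in range(spec.n_cytosolic_spots):
        placed = False
        for _attempt in range(_MAX_ATTEMPTS):
            p = (rng.uniform(border, rows - border), rng.uniform(border, cols - border))
            # clearance beyond the blurred, thresholded nucleus boundary so the
            # punctum is unambiguously cytosolic
            clearance = 3.0 * spec.nucleus_blur_sigma + 2.0
            outside_all = all(
                not _inside_ellipse(p, nuc["center"], nuc["axes"], margin=clearance)
                for nuc in nuclei
            )
            if outside_all and not too_close(p):
                spots.append({"center": p, "compartment": "cytosolic"})
                placed = True
                break
        if not placed:
            raise GeneratorError("could not place cytosolic puncta")

    for s in spots:
        r0, c0 = s["center"]
        win = int(math.ceil(4 * spec.spot_sigma))
        ri, rj = int(r0) - win, int(r0) + win + 1
        ci, cj = int(c0) - win, int(c0) + win + 1
        ri, ci = max(ri, 0), max(ci, 0)
        rj, cj = min(rj, rows), min(cj, cols)
        sub_r = rr[ri:rj, ci:cj]
        sub_c = cc_grid[ri:rj, ci:cj]
        pla[ri:rj, ci:cj] += spec.spot_peak * np.exp(
            -((sub_r - r0) ** 2 + (sub_c - c0) ** 2) / (2 * spec.spot_sigma**2)
        )

    # --- noise ------------------------------------------------------------
    if spec.poisson_noise:
        dapi = rng.poisson(np.clip(dapi, 0, None)).astype(float)
        pla = rng.poisson(np.clip(pla, 0, None)).astype(float)
    elif spec.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sd, dapi.shape)
        pla = pla + rng.normal(0.0, spec.noise_sd, pla.shape)
    dapi = np.clip(dapi, 0.0, None)
    pla = np.clip(pla, 0.0, None)

    truth = PlaSceneTruth(nuclei=nuclei, spots=spots)
    return (
        Image2D(dapi, channel="dapi"),
        Image2D(pla, channel="pla"),
        truth,
    )


def make_spread_scene(
    radii: np.ndarray,
    image_shape: tuple[int, int] = (512, 512),
    cells_per_image: int = 10,
    intensity: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[list[Image2D], np.ndarray]:
    """Membrane-labelled images of filled discs with known radii.

    Discs are packed without overlap and away from borders (border-touching
    cells are excluded by the measurement); returns the image list and the
    true per-cell areas ``pi * r^2`` in placement order.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0 or radii.min() <= 0:
        raise InvalidParameterError("radii must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = image_shape
    images: list[Image2D] = []
    rr, cc = np.mgrid[0:rows, 0:cols]
    for start in range(0, radii.size, cells_per_image):
        chunk = radii[start : start + cells_per_image]
        img = np.zeros((rows, cols))
        centers: list[tuple[float, float, float]] = []
        for r in chunk:
            placed = False
            for _attempt in range(_MAX_ATTEMPTS):
                margin = r + 10
                p = (rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin))
                if all(
                    math.hypot(p[0] - q[0], p[1] - q[1]) > r + q[2] + 8
                    for q in centers
                ):
                    centers.append((p[0], p[1], r))
                    placed = True
                    break
            if not placed:
                raise GeneratorError("could not pack discs into the image")
            img[(rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= r * r] = intensity
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
        images.append(Image2D(img, channel="membrane"))
    return images, math.pi * radii**2


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForceSceneSpec:
    """Specification of one synthetic force-distance curve.

    Defaults emulate a colloidal-probe acquisition: sphere of radius
    11,500 nm, cantilever k = 0.03 N/m, sensitivity 50 nm/V, contact at
    z = 2,000 nm, 1 nN maximum load, 2 nm z sampling.  ``noise_sd_frac``
    scales additive Gaussian force noise by the maximum force.
    """

    E_true: float = 1000.0  # Pa
    probe: ProbeSpec = field(
        default_factory=lambda: ProbeSpec(geometry="sphere", R=11_500.0, nu=0.5)
    )
    contact_z: float = 2000.0  # nm
    z_span: float = 3000.0  # nm, total sampled piezo travel starting at 0
    dz: float = 2.0  # nm sample spacing
    k: float = 0.03  # N/m
    sensitivity: float = 50.0  # nm/V
    baseline: tuple[float, float] = (0.0, 0.0)  # V per nm slope, V intercept
    noise_sd_frac: float = 0.0
    noise_model: str = "additive"  # SD = frac * max force; "multiplicative": frac * F
    max_load: float = 1.0  # nN
    segment: str = "approach"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise InvalidParameterError("E_true must be > 0")
        if self.contact_z <= 0 or self.contact_z >= self.z_span:
            raise InvalidParameterError("contact_z must lie inside the z range")
        if self.dz <= 0 or self.k <= 0 or self.sensitivity <= 0:
            raise InvalidParameterError("dz, k and sensitivity must be > 0")
        if self.noise_sd_frac < 0:
            raise InvalidParameterError("noise_sd_frac must be >= 0")
        if self.noise_model not in ("additive", "multiplicative"):
            raise InvalidParameterError("noise_model must be additive or multiplicative")
        if self.max_load <= 0:
            raise InvalidParameterError("max_load must be > 0")


def _contact_force(delta_nm: float, spec: ForceSceneSpec) -> float:
    p = spec.probe
    if p.geometry == "sphere":
        return float(hertz_sphere_force(delta_nm, spec.E_true, p.R, p.nu))
    return float(sneddon_cone_force(delta_nm, spec.E_true, p.half_angle, p.nu))


def make_force_curve(spec: ForceSceneSpec) -> ForceCurve:
    """Generate one force curve from the contact law and cantilever mechanics.

    Past contact, the indentation at piezo position z solves
    ``z - z_contact = delta + F(delta)/k`` (travel is shared between sample
    indentation and cantilever bending); the scalar root is found to 1e-9 nm.
    The curve is truncated at the first sample reaching ``max_load`` (the
    spec must allow the load to be reached, else a generator error).  Seeded
    Gaussian force noise (SD = ``noise_sd_frac`` x max force) is added to
    the whole trace, and deflection is emitted in volts via sensitivity.
    """
    rng = np.random.default_rng(spec.seed)
    z = np.arange(0.0, spec.z_span + 0.5 * spec.dz, spec.dz)
    defl_nm = np.zeros_like(z)
    force_at_max_travel = None
    for i, zi in enumerate(z):
        travel = zi - spec.contact_z
        if travel <= 0:
            continue

        def residual(delta: float) -> float:
            return delta + _contact_force(delta, spec) / spec.k - travel

        delta = brentq(residual, 0.0, travel, xtol=1e-9)
        F = _contact_force(delta, spec)
        defl_nm[i] = F / spec.k
        force_at_max_travel = F
        if F >= spec.max_load:
            z = z[: i + 1]
            defl_nm = defl_nm[: i + 1]
            break
    else:
        if force_at_max_travel is None or force_at_max_travel < spec.max_load:
            raise GeneratorError("max_load not reached within the z range")

    if spec.noise_sd_frac > 0:
        if spec.noise_model == "multiplicative":
            # SD proportional to the local force: pre-contact stays clean
            noise_nN = rng.normal(0.0, 1.0, z.size) * spec.noise_sd_frac * defl_nm * spec.k
        else:
            f_max = defl_nm.max() * spec.k
            noise_nN = rng.normal(0.0, spec.noise_sd_frac * f_max, z.size)
        defl_nm = defl_nm + noise_nN / spec.k
    defl_V = defl_nm / spec.sensitivity
    slope, intercept = spec.baseline
    defl_V = defl_V + slope * z + intercept

    if spec.segment == "retract":
        z = z[::-1].copy()
        defl_V = defl_V[::-1].copy()
    return ForceCurve(
        z=z,
        deflection=defl_V,
        k=spec.k,
        segment=spec.segment,
        sensitivity=spec.sensitivity,
        probe=spec.probe,
    )


def make_qi_grid(
    E_map: np.ndarray,
    template: ForceSceneSpec,
    contact_z_map: np.ndarray | None = None,
) -> list[list[ForceCurve]]:
    """One force curve per pixel of a modulus map (optionally with topography).

    Pixel (i, j) uses ``E_map[i, j]`` and, when given, ``contact_z_map[i, j]``
    as the contact height; its seed is a splitmix mix of the template seed
    with (i, j), keeping pixels independent but fully reproducible.
    """
    E_map = np.asarray(E_map, dtype=float)
    if E_map.ndim != 2:
        raise InvalidParameterError("E_map must be 2D")
    if contact_z_map is not None:
        contact_z_map = np.asarray(contact_z_map, dtype=float)
        if contact_z_map.shape != E_map.shape:
            raise InvalidParameterError("contact_z_map must match E_map geometry")
    grid: list[list[ForceCurve]] = []
    for i in range(E_map.shape[0]):
        row = []
        for j in range(E_map.shape[1]):
            spec = replace(
                template,
                E_true=float(E_map[i, j]),
                contact_z=float(contact_z_map[i, j])
                if contact_z_map is not None
                else template.contact_z,
                seed=mix_seed(template.seed, i, j),
            )
            row.append(make_force_curve(spec))
        grid.append(row)
    return grid
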