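"""AFM force-spectroscopy analysis: CFS curve fitting and QI map reconstruction.

Two acquisition modes are supported:

* **CFS** (colloidal force spectroscopy): a micrometre-scale sphere indents a
  live cell; force-distance curves are converted to force-indentation curves
  and fitted with the linearized Hertz sphere model
  ``F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)`` over the first
  ``fit_depth`` nanometres of indentation (default 50 nm, keeping the fit
  inside the small-deformation validity range of ~10% of the probe radius).
* **QI** (quantitative imaging): a sharp conical tip collects a grid of
  curves; each pixel is fitted with the Sneddon cone model
  ``F = (2/pi) * tan(alpha) * E / (1 - nu^2) * delta^2`` and the results are
  assembled into stiffness and contact-height maps.

Unit conventions: piezo position ``z`` in nm (increasing toward the sample),
deflection in the recorded unit (V, or nm with sensitivity 1), spring
constant ``k`` in N/m, sensitivity in nm/V, force in nN, Young's modulus in
Pa.  With these units ``F[nN] = k[N/m] * deflection[nm]`` and a modulus in
nN/nm^2 equals 1e9 Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    FitError,
    InsufficientDataError,
    InvalidParameterError,
    NoContactError,
)

__all__ = [
    "ProbeSpec",
    "ForceCurve",
    "IndentationCurve",
    "ContactPoint",
    "ElasticFit",
    "QIMap",
    "calibrate_sensitivity",
    "baseline_correct",
    "find_contact_point",
    "to_force_indentation",
    "fit_hertz_sphere",
    "fit_sneddon_cone",
    "analyze_curve",
    "reconstruct_qi_map",
    "height_profile_difference",
    "summarize_cfs",
    "hertz_sphere_force",
    "sneddon_cone_force",
]

_GPA_TO_PA = 1e9  # 1 nN/nm^2 = 1 GPa


@dataclass(frozen=True)
class ProbeSpec:
    """Indenter geometry and sample Poisson ratio.

    ``R`` (nm) for spherical probes, ``half_angle`` (degrees, half-opening)
    for cones.  ``nu`` is the Poisson ratio of the sample surface; 0.5 treats
    the cell as incompressible.
    """

    geometry: str  # "sphere" | "cone"
    R: float | None = None
    half_angle: float | None = None
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.geometry not in ("sphere", "cone"):
            raise InvalidParameterError("geometry must be 'sphere' or 'cone'")
        if self.geometry == "sphere" and (self.R is None or self.R <= 0):
            raise InvalidParameterError("spherical probe requires R > 0")
        if self.geometry == "cone" and (
            self.half_angle is None or not 0 < self.half_angle < 90
        ):
            raise InvalidParameterError("conical probe requires 0 < half_angle < 90")
        if not 0 <= self.nu <= 0.5:
            raise InvalidParameterError("nu must lie in [0, 0.5]")


def hertz_sphere_force(delta_nm, E_pa: float, R_nm: float, nu: float):
    """Hertz sphere contact law, force in nN for indentation in nm."""
    E = E_pa / _GPA_TO_PA  # nN/nm^2
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R_nm) * np.asarray(delta_nm) ** 1.5


def sneddon_cone_force(delta_nm, E_pa: float, half_angle_deg: float, nu: float):
    """Sneddon cone contact law, force in nN for indentation in nm."""
    E = E_pa / _GPA_TO_PA
    tan_a = math.tan(math.radians(half_angle_deg))
    return (2.0 / math.pi) * tan_a * E / (1.0 - nu**2) * np.asarray(delta_nm) ** 2


@dataclass
class ForceCurve:
    """A raw piezo-displacement vs cantilever-deflection record.

    ``z`` increases toward the sample.  For retract segments the samples are
    stored in acquisition order (z decreasing); analysis routines reorder
    internally.
    """

    z: np.ndarray  # nm
    deflection: np.ndarray  # V (or nm when sensitivity == 1)
    k: float  # N/m
    segment: str = "approach"
    sensitivity: float | None = None  # nm/V
    probe: ProbeSpec | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.deflection.shape:
            raise InvalidParameterError("z and deflection must be equal-length 1D")
        if self.z.size < 10:
            raise InvalidParameterError("force curve needs >= 10 samples")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise InvalidParameterError("z must be strictly monotone within a segment")
        if self.k <= 0:
            raise InvalidParameterError("spring constant must be > 0")
        if self.segment not in ("approach", "retract"):
            raise InvalidParameterError("segment must be 'approach' or 'retract'")
        if self.sensitivity is not None and self.sensitivity <= 0:
            raise InvalidParameterError("sensitivity must be > 0")

    def toward_sample(self) -> "ForceCurve":
        """Samples ordered by increasing z (away-from-sample end first)."""
        if self.z[0] <= self.z[-1]:
            return self
        return replace(self, z=self.z[::-1].copy(), deflection=self.deflection[::-1].copy())


@dataclass
class ContactPoint:
    """Contact location: sample index plus sub-sample refined piezo position."""

    index: int
    z_contact: float  # nm, back-extrapolated


@dataclass
class IndentationCurve:
    """Force vs indentation depth after contact."""

    delta: np.ndarray  # nm, >= 0
    F: np.ndarray  # nN
    contact_index: int
    z_contact: float
    baseline_params: tuple[float, float] = (0.0, 0.0)  # (slope, intercept) removed

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.delta.shape != self.F.shape:
            raise InvalidParameterError("delta and F must have equal length")


@dataclass
class ElasticFit:
    """Young's modulus with fit diagnostics."""

    E: float  # Pa
    model: str  # "hertz_sphere" | "sneddon_cone"
    contact_z: float  # nm
    fit_depth: float  # nm
    r_squared: float
    n_points: int


@dataclass
class QIMap:
    """Grid of per-pixel elasticity fits and contact heights.

    ``E_map`` in Pa and ``height_map`` in nm share the grid geometry; failed
    pixels are NaN in both, never zero.
    """

    E_map: np.ndarray
    height_map: np.ndarray
    scan_size_um: tuple[float, float] | None = None
    applied_load_nN: float | None = None
    fits: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.E_map = np.asarray(self.E_map, dtype=float)
        self.height_map = np.asarray(self.height_map, dtype=float)
        if self.E_map.shape != self.height_map.shape:
            raise InvalidParameterError("stiffness and height maps must be congruent")

    @property
    def shape(self) -> tuple[int, int]:
        return self.E_map.shape

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.E_map).sum())


# ---------------------------------------------------------------------------
# calibration and preprocessing
# ---------------------------------------------------------------------------


def calibrate_sensitivity(hard_curve: ForceCurve) -> float:
    """Deflection sensitivity (nm/V) from a curve on a rigid substrate.

    On mica/glass the probe cannot indent, so past contact every nanometre of
    piezo travel becomes one nanometre of cantilever bending; the inverse
    slope of deflection vs z in the contact region (auto-selected as the
    samples in the upper 50% of the deflection range) is the sensitivity.
    """
    curve = hard_curve.toward_sample()
    defl = curve.deflection
    span = defl.max() - defl.min()
    if span <= 0 or not np.isfinite(span):
        raise CalibrationError("flat deflection trace: no contact region")
    sel = defl >= defl.min() + 0.5 * span
    if sel.sum() < 3:
        raise CalibrationError("contact region too short for a slope fit")
    slope = np.polyfit(curve.z[sel], defl[sel], 1)[0]
    if slope <= 0:
        raise CalibrationError("non-positive contact slope: no hard contact")
    residual = defl[sel] - np.polyval(np.polyfit(curve.z[sel], defl[sel], 1), curve.z[sel])
    if np.std(residual) > 0.25 * (defl[sel].max() - defl[sel].min()):
        raise CalibrationError("contact region is not linear: not a rigid substrate")
    return 1.0 / slope


def baseline_correct(
    curve: ForceCurve, noncontact_fraction: float = 0.3
) -> ForceCurve:
    """Remove the linear free-of-contact baseline from the deflection trace.

    A line is fitted to the declared fraction of samples farthest from the
    sample (lowest z) and subtracted from the whole trace, so the non-contact
    deflection averages ~0.  Raises if the window is visibly curved, which
    indicates the curve has no free-of-contact region.
    """
    if not 0 < noncontact_fraction <= 0.9:
        raise InvalidParameterError("noncontact_fraction must lie in (0, 0.9]")
    ordered = curve.toward_sample()
    n = ordered.z.size
    m = max(int(round(noncontact_fraction * n)), 5)
    zw, dw = ordered.z[:m], ordered.deflection[:m]
    quad = np.polyfit(zw, dw, 2)
    resid_sd = float(np.std(dw - np.polyval(quad, zw)))
    span = zw[-1] - zw[0]
    curvature = abs(quad[0]) * span**2 / 4.0
    defl_range = float(ordered.deflection.max() - ordered.deflection.min())
    if curvature > max(10.0 * resid_sd / math.sqrt(m), 0.02 * defl_range):
        raise NoContactError(
            "non-contact window is curved: curve appears to be all-contact"
        )
    slope, intercept = np.polyfit(zw, dw, 1)
    corrected = ordered.deflection - (slope * ordered.z + intercept)
    out = replace(ordered, deflection=corrected)
    out._baseline_params = (float(slope), float(intercept))  # type: ignore[attr-defined]
    return out


def _deflection_nm(curve: ForceCurve) -> np.ndarray:
    sens = 1.0 if curve.sensitivity is None else curve.sensitivity
    return curve.deflection * sens


def find_contact_point(
    curve: ForceCurve,
    threshold_sds: float = 3.0,
    persistence: int = 10,
    noncontact_fraction: float = 0.3,
    force_exponent: float = 1.5,
) -> ContactPoint:
    """Locate the probe-sample contact point on a baseline-corrected curve.

    The baseline noise SD is estimated from the non-contact window; contact
    is the last sample before the deflection first exceeds
    ``threshold_sds * SD`` and stays above it for ``persistence`` samples.
    The position is then refined by back-extrapolating a linear fit of
    ``F^(1/force_exponent)`` against tip-sample separation over the whole
    contact region to zero force: for a contact law ``F ~ delta^q`` this
    transform is exactly linear in separation when ``force_exponent = q``
    (3/2 for spheres, 2 for cones), so the zero crossing recovers the
    contact position without model bias.
    """
    ordered = curve.toward_sample()
    defl = _deflection_nm(ordered)
    n = defl.size
    m = max(int(round(noncontact_fraction * n)), 5)
    noise_sd = float(np.std(defl[:m]))
    scale = float(np.abs(defl).max())
    if scale == 0:
        raise NoContactError("zero deflection everywhere")
    thr = max(threshold_sds * noise_sd, 1e-9 * scale)

    above = defl > thr
    # persist[i]: deflection stays above threshold from i for `persistence`
    # samples (or to the end of the curve)
    false_pos = np.flatnonzero(~above)
    if false_pos.size:
        k = np.searchsorted(false_pos, np.arange(n))
        next_false = np.where(
            k < false_pos.size, false_pos[np.minimum(k, false_pos.size - 1)], n
        )
    else:
        next_false = np.full(n, n)
    window_end = np.minimum(np.arange(n) + persistence, n)
    persist = next_false >= window_end
    candidates = np.flatnonzero(persist & above)
    if candidates.size == 0:
        raise NoContactError("deflection never exceeds the contact threshold")
    crossing = int(candidates[0])

    # refine over the whole contact region: with soft samples the threshold
    # crossing can sit tens of nm past true contact, and the linearized
    # transform stays valid over the full indentation range, so using every
    # post-crossing sample minimises extrapolation variance.
    if force_exponent <= 0:
        raise InvalidParameterError("force_exponent must be > 0")
    j0, j1 = crossing, n
    sep = ordered.z[j0:j1] - defl[j0:j1]
    f23 = np.clip(defl[j0:j1], 0.0, None) ** (1.0 / force_exponent)
    z_contact = float(ordered.z[max(crossing - 1, 0)])
    if j1 - j0 >= 2 and np.ptp(sep) > 0:
        a, b = np.polyfit(sep, f23, 1)
        if a > 0:
            z0 = -b / a
            lo = float(ordered.z[0])
            hi = float(ordered.z[crossing])
            z_contact = min(max(z0, lo), hi)
    index = int(np.searchsorted(ordered.z, z_contact, side="right") - 1)
    index = min(max(index, 0), n - 1)
    return ContactPoint(index=index, z_contact=z_contact)


def to_force_indentation(
    curve: ForceCurve, contact: ContactPoint | int
) -> IndentationCurve:
    """Convert a calibrated, baseline-corrected curve to force vs indentation.

    ``F = k * sensitivity * deflection`` and ``delta = (z - z_contact) -
    deflection_nm``: piezo travel past contact minus cantilever bending.
    Samples before contact are dropped.
    """
    if curve.sensitivity is None:
        raise InvalidParameterError(
            "sensitivity must be calibrated before force conversion"
        )
    ordered = curve.toward_sample()
    if isinstance(contact, ContactPoint):
        z_contact = contact.z_contact
        index = contact.index
    else:
        index = int(contact)
        z_contact = float(ordered.z[index])
    defl_nm = _deflection_nm(ordered)
    force = curve.k * defl_nm  # nN
    delta = (ordered.z - z_contact) - defl_nm
    post = delta > 0
    baseline = getattr(curve, "_baseline_params", (0.0, 0.0))
    return IndentationCurve(
        delta=delta[post],
        F=force[post],
        contact_index=index,
        z_contact=z_contact,
        baseline_params=baseline,
    )


# ---------------------------------------------------------------------------
# elasticity fits
# ---------------------------------------------------------------------------


def _fit_through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y ~ m*x through the origin, with R^2 of y on m*x."""
    denom = float(np.dot(x, x))
    if denom == 0:
        raise FitError("degenerate abscissa in linearized fit")
    m = float(np.dot(x, y)) / denom
    ss_res = float(np.sum((y - m * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return m, r2


_MIN_INDENTATION_NM = 0.5  # below AFM depth resolution: sample effectively rigid


def _fit_range(ind: IndentationCurve, fit_depth: float) -> tuple[np.ndarray, np.ndarray]:
    if fit_depth <= 0:
        raise InvalidParameterError("fit_depth must be > 0")
    sel = (ind.delta > 0) & (ind.delta <= fit_depth)
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"only {int(sel.sum())} samples with 0 < delta <= {fit_depth} nm (need >= 5)"
        )
    if float(ind.delta[sel].max()) < _MIN_INDENTATION_NM:
        raise FitError(
            "maximum indentation below depth resolution: sample is not indentable"
        )
    return ind.delta[sel], ind.F[sel]


def fit_hertz_sphere(
    ind: IndentationCurve, probe: ProbeSpec, fit_depth: float = 50.0
) -> ElasticFit:
    """Linearized Hertz fit for a spherical indenter.

    ``F^(2/3)`` is regressed against ``delta`` through the origin over
    ``0 < delta <= fit_depth``; the slope m gives
    ``E = (3/4) * m^(3/2) * (1 - nu^2) / sqrt(R)``.  The 50 nm default depth
    keeps the fit within the small-deformation validity of the Hertz model
    (~10% of the probe radius).
    """
    if probe.geometry != "sphere":
        raise InvalidParameterError("fit_hertz_sphere requires a spherical probe")
    delta, force = _fit_range(ind, fit_depth)
    if np.max(force) <= 0:
        raise FitError("no positive force in the fitting range")
    y = np.clip(force, 0.0, None) ** (2.0 / 3.0)
    m, r2 = _fit_through_origin(delta, y)
    if m <= 0:
        raise FitError("non-positive linearized slope")
    E = 0.75 * m**1.5 * (1.0 - probe.nu**2) / math.sqrt(probe.R) * _GPA_TO_PA
    return ElasticFit(
        E=E,
        model="hertz_sphere",
        contact_z=ind.z_contact,
        fit_depth=fit_depth,
        r_squared=r2,
        n_points=int(delta.size),
    )


def fit_sneddon_cone(
    ind: IndentationCurve, probe: ProbeSpec, fit_depth: float | None = None
) -> ElasticFit:
    """Sneddon fit for a conical indenter.

    ``F`` is regressed against ``delta^2`` through the origin; the slope m
    gives ``E = m * pi * (1 - nu^2) / (2 * tan(half_angle))``.  With no
    ``fit_depth`` the full indentation range is used (QI batch convention).
    """
    if probe.geometry != "cone":
        raise InvalidParameterError("fit_sneddon_cone requires a conical probe")
    depth = fit_depth if fit_depth is not None else float(np.inf)
    delta, force = _fit_range(ind, depth)
    if np.max(force) <= 0:
        raise FitError("no positive force in the fitting range")
    m, r2 = _fit_through_origin(delta**2, force)
    if m <= 0:
        raise FitError("non-positive linearized slope")
    tan_a = math.tan(math.radians(probe.half_angle))
    E = m * math.pi * (1.0 - probe.nu**2) / (2.0 * tan_a) * _GPA_TO_PA
    return ElasticFit(
        E=E,
        model="sneddon_cone",
        contact_z=ind.z_contact,
        fit_depth=depth,
        r_squared=r2,
        n_points=int(delta.size),
    )


def analyze_curve(
    curve: ForceCurve,
    probe: ProbeSpec | None = None,
    fit_depth: float | None = None,
    noncontact_fraction: float = 0.3,
    threshold_sds: float = 3.0,
) -> ElasticFit:
    """Full single-curve pipeline: baseline -> contact -> conversion -> fit."""
    probe = probe or curve.probe
    if probe is None:
        raise InvalidParameterError("no probe specification available")
    corrected = baseline_correct(curve, noncontact_fraction)
    contact = find_contact_point(
        corrected,
        threshold_sds=threshold_sds,
        noncontact_fraction=noncontact_fraction,
        force_exponent=1.5 if probe.geometry == "sphere" else 2.0,
    )
    ind = to_force_indentation(corrected, contact)
    if probe.geometry == "sphere":
        return fit_hertz_sphere(ind, probe, 50.0 if fit_depth is None else fit_depth)
    return fit_sneddon_cone(ind, probe, fit_depth)


# ---------------------------------------------------------------------------
# QI maps
# ---------------------------------------------------------------------------


def reconstruct_qi_map(
    curves,
    probe: ProbeSpec,
    fit_depth: float | None = None,
    scan_size_um: tuple[float, float] | None = None,
    applied_load_nN: float | None = None,
) -> QIMap:
    """Reconstruct stiffness and height maps from a rectangular grid of curves.

    Each pixel runs the full curve pipeline (retract segments are the QI
    convention; the analysis only requires monotone z).  Pixels whose
    analysis fails for any reason are encoded as NaN — never zero — so map
    statistics are not biased toward soft values.
    """
    rows = len(curves)
    if rows == 0:
        raise InvalidParameterError("empty curve grid")
    cols = len(curves[0])
    if any(len(r) != cols for r in curves):
        raise InvalidParameterError("ragged curve grid")
    E_map = np.full((rows, cols), np.nan)
    height = np.full((rows, cols), np.nan)
    fits: list[list[ElasticFit | None]] = []
    for i in range(rows):
        fit_row: list[ElasticFit | None] = []
        for j in range(cols):
            try:
                fit = analyze_curve(curves[i][j], probe=probe, fit_depth=fit_depth)
            except Exception:
                fit_row.append(None)
                continue
            E_map[i, j] = fit.E
            height[i, j] = fit.contact_z
            fit_row.append(fit)
        fits.append(fit_row)
    return QIMap(
        E_map=E_map,
        height_map=height,
        scan_size_um=scan_size_um,
        applied_load_nN=applied_load_nN,
        fits=fits,
    )


def height_profile_difference(qi_map: QIMap, path_a, path_b) -> float:
    """Difference of mean contact heights (um) along two pixel paths.

    Intended for nucleus-to-junction height comparisons: declare one path
    over the nuclear dome and one over the junction, and get the mean height
    difference in micrometres.
    """
    rows, cols = qi_map.shape

    def mean_height(path) -> float:
        vals = []
        for r, c in path:
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvalidParameterError(f"path pixel {(r, c)} outside grid")
            vals.append(qi_map.height_map[r, c])
        return float(np.nanmean(vals))

    return (mean_height(path_a) - mean_height(path_b)) / 1000.0


def summarize_cfs(fits, group_labels) -> pd.DataFrame:
    """Per-group summary of Young's moduli and fold ratios vs the first group.

    Returns one row per group (mean, SD, median, n of E in Pa) plus
    ``mean_ratio``/``median_ratio`` columns relative to the first group that
    appears in ``group_labels`` — the natural readout when comparing a mutant
    against wild type.
    """
    E = np.array([f.E for f in fits], dtype=float)
    labels = list(group_labels)
    if len(labels) != E.size:
        raise InvalidParameterError("one group label per fit required")
    table = pd.DataFrame({"group": labels, "E": E})
    if (table.groupby("group").size() < 1).any():
        raise InvalidParameterError("empty group")
    summary = (
        table.groupby("group", sort=False)["E"]
        .agg(mean="mean", sd="std", median="median", n="count")
        .reset_index()
    )
    ref = summary.iloc[0]
    if len(summary) > 1:
        summary["mean_ratio"] = summary["mean"] / ref["mean"]
        summary["median_ratio"] = summary["median"] / ref["median"]
    return summary
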