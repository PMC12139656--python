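"""Forward acoustic scattering models and sound-speed computation.

These models predict the target strength TS(f) = 10*log10(sigma_bs) of
candidate mesopelagic organisms at the survey frequencies, from which the
volume backscattering Sv for one organism per cubic metre (numerically equal
to TS) and its dB-difference triplet relative to 38 kHz follow.  Classifying
the triplet against a fitted echo-class model suggests which organisms each
echo-class could represent.

Families
--------
- ``dwba_bent_cylinder``: distorted-wave Born approximation line integral
  along a uniformly bent fluid cylinder (weak scatterers: copepods,
  euphausiids), Gaussian orientation averaging.
- ``fluid_bent_cylinder_random``: high-pass interpolation between the
  Rayleigh cylinder limit and the geometric ray plateau, uniformly averaged
  over orientation (shrimp, salps).
- ``highpass_fluid_sphere``: Stanton-style high-pass dense fluid sphere
  (gastropods).
- ``gas_bubble_spherical`` / ``gas_bubble_ellipsoid``: damped Minnaert
  resonator (free gas inclusions; the ellipsoid variant corrects the
  resonance with the equal-volume prolate-spheroid capacitance).
- ``hybrid_gas_body``: incoherent cross-section sum of a gas inclusion and a
  fluid body (pneumatophore-bearing siphonophores, small swimbladdered fish).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import j1

__all__ = [
    "Medium",
    "ScatterModelSpec",
    "FrequencyResponse",
    "mackenzie_sound_speed",
    "minnaert_frequency",
    "ts_dwba_bent_cylinder",
    "ts_fluid_bent_cylinder_random",
    "ts_highpass_fluid_sphere",
    "ts_gas_bubble",
    "ts_hybrid",
    "target_strength",
    "frequency_response",
    "classify_model",
    "read_model_csv",
    "write_response_csv",
]

SURVEY_KHZ = (18.0, 38.0, 70.0, 120.0)
GRAVITY = 9.81          # m s^-2
ATM_PA = 101325.0       # Pa
WATER_VISCOSITY = 1.05e-3  # Pa s, seawater near 20-26 degC

FAMILIES = (
    "dwba_bent_cylinder",
    "fluid_bent_cylinder_random",
    "highpass_fluid_sphere",
    "gas_bubble_spherical",
    "gas_bubble_ellipsoid",
    "hybrid_gas_body",
)


def mackenzie_sound_speed(T: float, S: float, D: float) -> float:
    """Sound speed in seawater (m/s), Mackenzie's 9-term equation.

    ``T`` in degC, ``S`` in PSU, ``D`` depth in metres.  Validity envelope
    T in [-2, 35], S in [25, 40], D in [0, 8000]; outside it a warning is
    emitted but the polynomial is still evaluated.
    """
    import warnings

    if not (np.isfinite(T) and np.isfinite(S) and np.isfinite(D)):
        raise ValueError("non-finite input to the sound-speed equation")
    if not (-2 <= T <= 35 and 25 <= S <= 40 and 0 <= D <= 8000):
        warnings.warn("inputs outside the sound-speed validity envelope")
    return (
        1448.96
        + 4.591 * T
        - 5.304e-2 * T**2
        + 2.374e-4 * T**3
        + 1.340 * (S - 35.0)
        + 1.630e-2 * D
        + 1.675e-7 * D**2
        - 1.025e-2 * T * (S - 35.0)
        - 7.139e-13 * T * D**3
    )


@dataclass
class Medium:
    """Ambient water properties at the modelling depth.

    Sound speed is derived from temperature/salinity/depth via the Mackenzie
    equation; ambient pressure is atmospheric plus hydrostatic.
    """

    temperature_c: float = 26.0
    salinity_psu: float = 35.5
    depth_m: float = 25.0
    density_kg_m3: float = 1026.5

    @property
    def sound_speed(self) -> float:
        return mackenzie_sound_speed(self.temperature_c, self.salinity_psu, self.depth_m)

    @property
    def pressure_pa(self) -> float:
        return ATM_PA + self.density_kg_m3 * GRAVITY * self.depth_m

    def wavenumber(self, f_hz: float) -> float:
        return 2.0 * np.pi * f_hz / self.sound_speed


@dataclass
class ScatterModelSpec:
    """Parameters of one theoretical scatterer.

    Either ``esr_mm`` (equivalent spherical radius) or ``length_mm`` sizes
    the organism; cylinder geometry is derived volume-preservingly with the
    length-to-width ratio.  ``g`` and ``h`` are the density and sound-speed
    contrasts; orientation is a Gaussian in tilt from broadside (degrees).
    Gas families take the polytropic exponent ``gamma`` and, for the
    ellipsoid variant, the prolate ``aspect`` ratio; the hybrid family sizes
    its gas inclusion with ``gas_esr_mm`` (default 5% of body length, a
    swimbladder-fraction convention).
    """

    name: str
    family: str
    esr_mm: float | None = None
    length_mm: float | None = None
    g: float = 1.04
    h: float = 1.04
    lw_ratio: float = 4.0
    orient_mean_deg: float = 0.0
    orient_sd_deg: float = 20.0
    aspect: float = 1.0
    gamma: float = 1.4
    gas_esr_mm: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.esr_mm is None and self.length_mm is None:
            raise ValueError("either esr_mm or length_mm must be given")
        for nm in ("esr_mm", "length_mm", "gas_esr_mm"):
            v = getattr(self, nm)
            if v is not None and v <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.g <= 0 or self.h <= 0:
            raise ValueError("contrasts g and h must be positive")
        if self.lw_ratio < 1:
            raise ValueError("length-to-width ratio must be >= 1")
        if self.aspect < 1:
            raise ValueError("aspect ratio must be >= 1")

    def cylinder_geometry(self) -> tuple[float, float]:
        """(radius a, length L) in metres, volume-preserving from ESR.

        With L = lw_ratio * 2a, equating (4/3) pi r^3 = pi a^2 L gives
        a = r * (2 / (3 lw_ratio))^(1/3).
        """
        if self.length_mm is not None:
            L = self.length_mm * 1e-3
            return L / (2.0 * self.lw_ratio), L
        r = self.esr_mm * 1e-3
        a = r * (2.0 / (3.0 * self.lw_ratio)) ** (1.0 / 3.0)
        return a, 2.0 * self.lw_ratio * a

    def sphere_radius(self) -> float:
        """Equivalent spherical radius in metres."""
        if self.esr_mm is not None:
            return self.esr_mm * 1e-3
        a, L = self.cylinder_geometry()
        return (0.75 * a * a * L) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# material terms
# ---------------------------------------------------------------------------

def _gamma_kappa(g: float, h: float) -> float:
    return (1.0 - g * h * h) / (g * h * h)


def _gamma_rho(g: float) -> float:
    return (g - 1.0) / g


def _reflection_coefficient(g: float, h: float) -> float:
    return (g * h - 1.0) / (g * h + 1.0)


# ---------------------------------------------------------------------------
# DWBA uniformly bent cylinder
# ---------------------------------------------------------------------------

def _dwba_sigma_bs_at_tilt(
    theta: np.ndarray, k1: float, a: float, L: float, g: float, h: float,
    rho_c: float, n_arc: int = 128,
) -> np.ndarray:
    """|f_bs|^2 of a uniformly bent fluid cylinder at tilt angles ``theta``.

    Line-integral DWBA: the axis is an arc of radius ``rho_c`` spanning
    half-angle L/(2 rho_c); with phi the arc parameter and theta the tilt
    from broadside, the local angle between the incident direction and the
    cross-sectional plane is (theta - phi), giving

        f_bs = (k1/4) (gk - gr) * Integral a e^{2 i k2 rho_c cos(theta-phi)}
               * J1(2 k2 a cos(theta-phi)) / cos(theta-phi) * rho_c dphi
    """
    k2 = k1 / h
    gk, gr = _gamma_kappa(g, h), _gamma_rho(g)
    phi0 = L / (2.0 * rho_c)
    phi = np.linspace(-phi0, phi0, n_arc)
    ang = theta[:, None] - phi[None, :]
    cosang = np.cos(ang)
    # J1(x)/x is finite at 0; guard the explicit division
    x = 2.0 * k2 * a * cosang
    with np.errstate(invalid="ignore", divide="ignore"):
        bessel_term = np.where(np.abs(cosang) < 1e-12, k2 * a, j1(x) / cosang)
    integrand = a * np.exp(2j * k2 * rho_c * cosang) * bessel_term * rho_c
    f_bs = (k1 / 4.0) * (gk - gr) * np.trapezoid(integrand, phi, axis=1)
    return np.abs(f_bs) ** 2


def ts_dwba_bent_cylinder(
    spec: ScatterModelSpec, medium: Medium, f_khz: float, n_orient: int = 64
) -> float:
    """TS (dB re 1 m^2) of a weakly scattering uniformly bent fluid cylinder.

    The DWBA integral is evaluated along an arc with radius of curvature
    3 x body length and averaged (in cross-section) over the Gaussian tilt
    distribution with Gauss-Hermite quadrature.  Null contrast (g = h = 1)
    returns NaN (zero cross-section; TS undefined).
    """
    a, L = spec.cylinder_geometry()
    if spec.g == 1.0 and spec.h == 1.0:
        return float("nan")
    k1 = medium.wavenumber(f_khz * 1e3)
    rho_c = 3.0 * L
    nodes, weights = hermegauss(n_orient)
    theta = np.deg2rad(spec.orient_mean_deg) + np.deg2rad(spec.orient_sd_deg) * nodes
    sig = _dwba_sigma_bs_at_tilt(theta, k1, a, L, spec.g, spec.h, rho_c)
    sigma_bs = float(np.sum(weights * sig) / np.sum(weights))
    if not np.isfinite(sigma_bs) or sigma_bs <= 0:
        raise ArithmeticError(
            f"DWBA quadrature did not converge for {spec.name!r} at {f_khz} kHz"
        )
    return 10.0 * np.log10(sigma_bs)


# ---------------------------------------------------------------------------
# randomly oriented fluid bent cylinder (reduced-TS high-pass form)
# ---------------------------------------------------------------------------

def ts_fluid_bent_cylinder_random(
    spec: ScatterModelSpec, medium: Medium, f_khz: float, n_orient: int = 64
) -> float:
    """TS of a fluid bent cylinder averaged over uniformly random orientation.

    High-pass ray form: at tilt theta from broadside the Rayleigh-regime
    cross-section sigma_R = (k1 k2 a^2 L (gk-gr) / 4)^2 sinc^2(k2 L sin theta)
    is blended with the geometric ray plateau sigma_G = R^2 a rho_c / 4
    (rho_c = 3 L) as sigma = sigma_R / (1 + sigma_R / sigma_G), then averaged
    over the spherical-uniform tilt density cos(theta).
    """
    a, L = spec.cylinder_geometry()
    if spec.g == 1.0 and spec.h == 1.0:
        return float("nan")
    k1 = medium.wavenumber(f_khz * 1e3)
    k2 = k1 / spec.h
    amp = k1 * k2 * a * a * L * (_gamma_kappa(spec.g, spec.h) - _gamma_rho(spec.g)) / 4.0
    refl = _reflection_coefficient(spec.g, spec.h)
    sigma_g = refl * refl * a * (3.0 * L) / 4.0

    # Gauss-Legendre over tilt in [0, pi/2] with the cos(theta) density
    x, w = np.polynomial.legendre.leggauss(n_orient)
    theta = (x + 1.0) * (np.pi / 4.0)
    dens = np.cos(theta)
    arg = k2 * L * np.sin(theta)
    sinc = np.where(np.abs(arg) < 1e-12, 1.0, np.sin(arg) / np.where(arg == 0, 1, arg))
    sigma_r = amp * amp * sinc * sinc
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(sigma_g > 0, sigma_r / (1.0 + sigma_r / sigma_g), 0.0)
    mean_sigma = float(np.sum(w * dens * sigma) / np.sum(w * dens))
    if mean_sigma <= 0:
        return float("nan")
    return 10.0 * np.log10(mean_sigma)


# ---------------------------------------------------------------------------
# high-pass dense fluid sphere
# ---------------------------------------------------------------------------

def ts_highpass_fluid_sphere(
    spec: ScatterModelSpec, medium: Medium, f_khz: float
) -> float:
    """TS of a dense fluid sphere in the high-pass approximation.

    sigma_bs = a^2 (ka)^4 alpha / (1 + (ka)^4 alpha / R^2) with the Rayleigh
    coefficient alpha = ((1 - g h^2)/(3 g h^2) + (1 - g)/(1 + 2g))^2 and
    plateau R^2 from the plane-wave reflection coefficient, so TS rises at
    40 dB/decade for ka << 1 and plateaus at a^2 R^2 for ka >> 1.
    """
    a = spec.sphere_radius()
    ka = medium.wavenumber(f_khz * 1e3) * a
    alpha = (
        (1.0 - spec.g * spec.h**2) / (3.0 * spec.g * spec.h**2)
        + (1.0 - spec.g) / (1.0 + 2.0 * spec.g)
    ) ** 2
    r2 = _reflection_coefficient(spec.g, spec.h) ** 2
    if alpha == 0.0 or r2 == 0.0:
        return float("nan")
    sigma_bs = a * a * ka**4 * alpha / (1.0 + ka**4 * alpha / r2)
    return 10.0 * np.log10(sigma_bs)


# ---------------------------------------------------------------------------
# gas bubble
# ---------------------------------------------------------------------------

def minnaert_frequency(a_m: float, medium: Medium, gamma: float = 1.4) -> float:
    """Minnaert resonance frequency (Hz) of a spherical gas bubble of radius
    ``a_m`` at the medium's ambient pressure (surface tension ignored)."""
    if a_m <= 0:
        raise ValueError("bubble radius must be positive")
    return (1.0 / (2.0 * np.pi * a_m)) * np.sqrt(
        3.0 * gamma * medium.pressure_pa / medium.density_kg_m3
    )


def _prolate_capacitance_ratio(aspect: float) -> float:
    """C_prolate / a_eq for a prolate spheroid of equal volume.

    Semi-axes A = a_eq q^(2/3), b = a_eq q^(-1/3) (q = aspect); capacitance
    C = 2 A eps / ln((1+eps)/(1-eps)) with eps the eccentricity.
    """
    if aspect <= 1.0:
        return 1.0
    eps = np.sqrt(1.0 - aspect**-2)
    A = aspect ** (2.0 / 3.0)
    return 2.0 * A * eps / np.log((1.0 + eps) / (1.0 - eps))


def ts_gas_bubble(spec: ScatterModelSpec, medium: Medium, f_khz: float) -> float:
    """TS of a resonant damped gas bubble.

    sigma_bs = a^2 / ( ((f0/f)^2 - 1)^2 + delta^2 ) with f0 the Minnaert
    frequency (internal pressure = ambient hydrostatic, no surface tension)
    and total damping delta = radiation (ka) + viscous (4 mu / (rho omega
    a^2)).  The ellipsoid variant raises f0 by the equal-volume prolate
    capacitance factor sqrt(C/a_eq) (a resonance of the same gas volume in a
    stiffer, elongated geometry).
    """
    a = spec.sphere_radius()
    f = f_khz * 1e3
    f0 = minnaert_frequency(a, medium, spec.gamma)
    if spec.family == "gas_bubble_ellipsoid":
        f0 *= np.sqrt(_prolate_capacitance_ratio(spec.aspect))
    omega = 2.0 * np.pi * f
    k = medium.wavenumber(f)
    delta = k * a + 4.0 * WATER_VISCOSITY / (medium.density_kg_m3 * omega * a * a)
    sigma_bs = a * a / (((f0 / f) ** 2 - 1.0) ** 2 + delta * delta)
    return 10.0 * np.log10(sigma_bs)


# ---------------------------------------------------------------------------
# hybrid gas + fluid body
# ---------------------------------------------------------------------------

def ts_hybrid(spec: ScatterModelSpec, medium: Medium, f_khz: float) -> float:
    """TS of a gas inclusion plus fluid body, summed incoherently.

    sigma_bs = sigma_bs(gas bubble at gas_esr) + sigma_bs(DWBA bent-cylinder
    body).  With no gas inclusion the body-only TS is returned; with null
    body contrast the bubble-only TS is returned.
    """
    gas_esr = spec.gas_esr_mm
    if gas_esr is None and spec.length_mm is not None:
        gas_esr = 0.05 * spec.length_mm  # swimbladder-fraction convention
    sigma = 0.0
    if gas_esr is not None and gas_esr > 0:
        bubble = ScatterModelSpec(
            name=spec.name + ":gas",
            family="gas_bubble_spherical",
            esr_mm=gas_esr,
            gamma=spec.gamma,
        )
        sigma += 10.0 ** (ts_gas_bubble(bubble, medium, f_khz) / 10.0)
    body_ts = ts_dwba_bent_cylinder(spec, medium, f_khz) if not (
        spec.g == 1.0 and spec.h == 1.0
    ) else float("nan")
    if np.isfinite(body_ts):
        sigma += 10.0 ** (body_ts / 10.0)
    if sigma <= 0:
        return float("nan")
    return 10.0 * np.log10(sigma)


_DISPATCH = {
    "dwba_bent_cylinder": ts_dwba_bent_cylinder,
    "fluid_bent_cylinder_random": ts_fluid_bent_cylinder_random,
    "highpass_fluid_sphere": ts_highpass_fluid_sphere,
    "gas_bubble_spherical": ts_gas_bubble,
    "gas_bubble_ellipsoid": ts_gas_bubble,
    "hybrid_gas_body": ts_hybrid,
}


def target_strength(spec: ScatterModelSpec, medium: Medium, f_khz: float) -> float:
    """TS (dB re 1 m^2) of ``spec`` at one frequency; NaN for a null return."""
    return _DISPATCH[spec.family](spec, medium, f_khz)


@dataclass
class FrequencyResponse:
    """TS(f) at the survey frequencies and the derived ΔSv triplet.

    ``sv_db`` is the volume backscattering for one organism per m^3, which is
    numerically equal to TS; the triplet is Sv(f) - Sv(38) on the
    (18, 70, 120) axes.
    """

    name: str
    frequencies_khz: tuple[float, ...]
    ts_db: np.ndarray
    sv_db: np.ndarray = field(init=False)
    delta_triplet: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ts_db = np.asarray(self.ts_db, dtype=float)
        self.sv_db = self.ts_db.copy()
        freqs = list(self.frequencies_khz)
        ref = self.sv_db[freqs.index(38.0)]
        self.delta_triplet = np.array(
            [self.sv_db[freqs.index(f)] - ref for f in (18.0, 70.0, 120.0)]
        )


def frequency_response(
    spec: ScatterModelSpec,
    medium: Medium,
    frequencies_khz: Sequence[float] = SURVEY_KHZ,
) -> FrequencyResponse:
    """Evaluate TS at the survey frequencies and derive the ΔSv triplet."""
    ts = np.array([target_strength(spec, medium, f) for f in frequencies_khz])
    return FrequencyResponse(
        name=spec.name, frequencies_khz=tuple(frequencies_khz), ts_db=ts
    )


def classify_model(
    spec: ScatterModelSpec, medium: Medium, model
) -> tuple[int, float]:
    """Classify a theoretical scatterer against a fitted echo-class model.

    Returns ``(label, escore)``: the winning class (or UNCLASSIFIED when the
    minimum Escore is at or above the ellipsoid threshold, or when any TS is
    undefined) and the winning Escore.  Identical to classifying a one-cell
    grid holding the model's triplet.
    """
    from .scoring import UNCLASSIFIED, classify_triplets

    resp = frequency_response(spec, medium)
    if np.isnan(resp.ts_db).any():
        return UNCLASSIFIED, float("nan")
    labels, mins = classify_triplets(resp.delta_triplet[None, :], model)
    return int(labels[0]), float(mins[0])


# ---------------------------------------------------------------------------
# parameter / response tables
# ---------------------------------------------------------------------------

def read_model_csv(path) -> list[ScatterModelSpec]:
    """Read scattering-model parameters: CSV columns
    ``name,family,esr_mm_or_length_mm,g,h,lw_ratio,orient_mean_deg,
    orient_sd_deg,aspect,gamma``.  The size column is interpreted as body
    length for cylinder-based families and as ESR otherwise.
    """
    df = pd.read_csv(path)
    specs = []
    for _, row in df.iterrows():
        size = float(row["esr_mm_or_length_mm"])
        fam = str(row["family"])
        is_cyl = fam in ("dwba_bent_cylinder", "fluid_bent_cylinder_random",
                         "hybrid_gas_body")
        specs.append(
            ScatterModelSpec(
                name=str(row["name"]),
                family=fam,
                esr_mm=None if is_cyl else size,
                length_mm=size if is_cyl else None,
                g=float(row.get("g", 1.04)),
                h=float(row.get("h", 1.04)),
                lw_ratio=float(row.get("lw_ratio", 4.0)),
                orient_mean_deg=float(row.get("orient_mean_deg", 0.0)),
                orient_sd_deg=float(row.get("orient_sd_deg", 20.0)),
                aspect=float(row.get("aspect", 1.0)),
                gamma=float(row.get("gamma", 1.4)),
            )
        )
    return specs


def write_response_csv(
    specs: Sequence[ScatterModelSpec], medium: Medium, model, path
) -> pd.DataFrame:
    """Tabulate TS/Sv responses and echo-class assignments of many specs.

    Output columns: ``name,f_khz,ts_db,sv_db,d18_38,d70_38,d120_38,class,
    escore`` (one row per spec x frequency; triplet and classification
    repeated across the spec's rows).
    """
    rows = []
    for spec in specs:
        resp = frequency_response(spec, medium)
        label, score = classify_model(spec, medium, model)
        d = resp.delta_triplet
        for f, ts in zip(resp.frequencies_khz, resp.ts_db):
            rows.append(
                {
                    "name": spec.name,
                    "f_khz": f,
                    "ts_db": ts,
                    "sv_db": ts,
                    "d18_38": d[0],
                    "d70_38": d[1],
                    "d120_38": d[2],
                    "class": label,
                    "escore": score,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.4f")
    return df
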