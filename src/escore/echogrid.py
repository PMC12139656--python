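"""Echogram data model, Sv CSV I/O, echo-integration, alignment and NASC.

The central container is :class:`Echogram`: a calibrated, gridded matrix of
volume backscattering strength Sv (dB re 1 m^-1) on a ping x depth lattice for
one acoustic frequency.  Missing data are carried as NaN and propagate through
every operation; they are never imputed.

Echo-integration reduces a fine raw grid to elementary sampling distance units
(ESDUs; by default 3 pings x 1.5 m) by averaging in the *linear* domain
(sv = 10^(Sv/10)), with samples below a threshold (default -100 dB)
contributing zero linear energy.  NASC (nautical area scattering coefficient,
sA, m^2 nmi^-2) is the depth-integrated linear backscatter scaled by
4*pi*1852^2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Echogram",
    "EchogramSet",
    "IntegrationConfig",
    "SolarPeriod",
    "read_sv_csv",
    "write_sv_csv",
    "echo_integrate",
    "align_frequencies",
    "sv_to_nasc",
    "classify_solar",
    "solar_elevation",
]

#: Reserved missing-data marker for Sv grids.
MISSING = np.nan

# 4*pi*(1852 m / nmi)^2 -- conversion from area backscattering coefficient
# (m^2 m^-2) to NASC (m^2 nmi^-2).
NASC_FACTOR = 4.0 * np.pi * 1852.0**2


def _as_utc_datetime64(times) -> np.ndarray:
    """Coerce a time sequence to tz-naive datetime64[ns] interpreted as UTC."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(times), utc=True))
    return np.asarray(idx.tz_convert("UTC").tz_localize(None).values)


@dataclass
class Echogram:
    """Single-frequency Sv grid on a ping x depth lattice.

    Parameters
    ----------
    frequency_khz
        Acoustic frequency of this grid in kHz.
    ping_times
        Per-ping UTC timestamps, non-decreasing (datetime64[ns]).
    positions
        ``(n_pings, 2)`` array of (latitude, longitude) in degrees.
    depth_edges
        Strictly increasing bin boundaries in metres, positive down;
        ``len(depth_edges) == n_bins + 1``.  Bin intervals are half-open
        ``[top, bottom)``.
    sv
        ``(n_pings, n_bins)`` Sv in dB re 1 m^-1; NaN marks MISSING cells.
    """

    frequency_khz: float
    ping_times: np.ndarray
    positions: np.ndarray
    depth_edges: np.ndarray
    sv: np.ndarray

    def __post_init__(self):
        self.ping_times = _as_utc_datetime64(self.ping_times)
        self.positions = np.asarray(self.positions, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        self.sv = np.asarray(self.sv, dtype=float)
        if self.sv.ndim != 2:
            raise ValueError("sv must be a 2-D (n_pings, n_bins) array")
        n_pings, n_bins = self.sv.shape
        if len(self.ping_times) != n_pings:
            raise ValueError("ping_times length does not match sv rows")
        if self.positions.shape != (n_pings, 2):
            raise ValueError("positions must have shape (n_pings, 2)")
        if len(self.depth_edges) != n_bins + 1:
            raise ValueError("len(depth_edges) must equal n_bins + 1")
        if not np.all(np.diff(self.depth_edges) > 0):
            raise ValueError("depth_edges must be strictly increasing")
        if np.any(np.diff(self.ping_times.astype("int64")) < 0):
            raise ValueError("ping_times must be non-decreasing")
        finite_or_nan = np.isfinite(self.sv) | np.isnan(self.sv)
        if not finite_or_nan.all():
            raise ValueError("every non-missing Sv value must be finite")

    @property
    def n_pings(self) -> int:
        return self.sv.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv.shape[1]

    @property
    def bin_thickness(self) -> np.ndarray:
        return np.diff(self.depth_edges)

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])


@dataclass
class EchogramSet:
    """Multifrequency bundle of Sv grids on one shared lattice.

    ``sv`` maps frequency (kHz) to an ``(n_pings, n_bins)`` array; cells
    outside a frequency's usable depth range are MISSING for that frequency.
    """

    ping_times: np.ndarray
    positions: np.ndarray
    depth_edges: np.ndarray
    sv: dict[float, np.ndarray]

    def __post_init__(self):
        self.ping_times = _as_utc_datetime64(self.ping_times)
        self.positions = np.asarray(self.positions, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        shape = (len(self.ping_times), len(self.depth_edges) - 1)
        for f, grid in self.sv.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != shape:
                raise ValueError(f"grid for {f} kHz does not share the lattice")
            self.sv[f] = grid

    @property
    def frequencies(self) -> list[float]:
        return sorted(self.sv)

    def echogram(self, frequency_khz: float) -> Echogram:
        """View one frequency as a standalone :class:`Echogram`."""
        return Echogram(
            frequency_khz=frequency_khz,
            ping_times=self.ping_times,
            positions=self.positions,
            depth_edges=self.depth_edges,
            sv=self.sv[frequency_khz],
        )


DEFAULT_MAX_DEPTH_M: dict[float, float] = {
    18.0: 1000.0,
    38.0: 800.0,
    70.0: 500.0,
    120.0: 250.0,
    200.0: 120.0,
}


@dataclass
class IntegrationConfig:
    """Echo-integration parameters.

    Defaults follow the standard mesopelagic survey configuration: 3-ping x
    1.5 m ESDUs, a -100 dB re 1 m^-1 integration threshold, exclusion of the
    top 15 m (surface turbulence), and per-frequency maximum usable depths.
    """

    esdu_pings: int = 3
    vertical_bin_m: float = 1.5
    sv_threshold_db: float = -100.0
    surface_exclusion_m: float = 15.0
    max_depth_m: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_DEPTH_M)
    )

    def __post_init__(self):
        if self.esdu_pings < 1:
            raise ValueError("esdu_pings must be >= 1")
        if self.vertical_bin_m <= 0:
            raise ValueError("vertical_bin_m must be > 0")
        if self.surface_exclusion_m < 0:
            raise ValueError("surface_exclusion_m must be >= 0")


class SolarPeriod(str, Enum):
    NIGHT = "night"
    SUNRISE = "sunrise"
    DAY = "day"
    SUNSET = "sunset"


# ---------------------------------------------------------------------------
# Sv CSV dialect
# ---------------------------------------------------------------------------

_DEPTH_COL_RE = re.compile(r"^d_(\d+(?:\.\d+)?)_(\d+(?:\.\d+)?)$")


def _depth_col(top: float, bottom: float) -> str:
    return f"d_{top:.1f}_{bottom:.1f}"


def read_sv_csv(path, frequency_khz: float) -> Echogram:
    """Read one frequency's Sv grid from the CSV dialect.

    Layout: header ``ping_time,lat,lon,d_<top>_<bottom>,...`` with depth
    column names in metres at 0.1 m precision; one row per ping; empty or
    unparseable fields become MISSING; timestamps are ISO-8601 UTC.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:3] != ["ping_time", "lat", "lon"]:
        raise ValueError(
            f"malformed header in {path}: expected ping_time,lat,lon,... got {cols[:3]}"
        )
    tops, bottoms = [], []
    for c in cols[3:]:
        m = _DEPTH_COL_RE.match(c)
        if m is None:
            raise ValueError(f"malformed depth column name {c!r} in {path}")
        tops.append(float(m.group(1)))
        bottoms.append(float(m.group(2)))
    if not tops:
        raise ValueError(f"no depth columns in {path}")
    edges = np.array(tops + [bottoms[-1]])
    if not np.all(np.diff(edges) > 0) or not np.allclose(
        bottoms[:-1], tops[1:], atol=1e-6
    ):
        raise ValueError(f"non-monotone or non-contiguous depth columns in {path}")

    times = pd.to_datetime(df["ping_time"], utc=True, format="ISO8601")
    lat = pd.to_numeric(df["lat"], errors="raise").to_numpy()
    lon = pd.to_numeric(df["lon"], errors="raise").to_numpy()
    sv = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy() for c in cols[3:]]
    )
    return Echogram(
        frequency_khz=frequency_khz,
        ping_times=times,
        positions=np.column_stack([lat, lon]),
        depth_edges=edges,
        sv=sv,
    )


def write_sv_csv(echogram: Echogram, path, precision: int = 4) -> None:
    """Write an :class:`Echogram` in the Sv CSV dialect (lossless round-trip
    at the written precision; MISSING cells become empty fields)."""
    edges = echogram.depth_edges
    cols = [_depth_col(edges[i], edges[i + 1]) for i in range(echogram.n_bins)]
    times = pd.DatetimeIndex(echogram.ping_times).strftime("%Y-%m-%dT%H:%M:%SZ")
    fmt = f"%.{precision}f"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ping_time,lat,lon," + ",".join(cols) + "\n")
        for i in range(echogram.n_pings):
            row = [times[i], f"{echogram.positions[i, 0]:.6f}",
                   f"{echogram.positions[i, 1]:.6f}"]
            for v in echogram.sv[i]:
                row.append("" if np.isnan(v) else fmt % v)
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# Echo-integration
# ---------------------------------------------------------------------------

def _overlap_weights(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """(n_src, n_dst) matrix of overlap thickness between half-open bins.

    Proportional-overlap resampling: a source bin contributes to each target
    bin in proportion to the thickness of their intersection, so source grids
    that are not an exact multiple of the target bin are handled without
    silent truncation.
    """
    tops = np.maximum.outer(src_edges[:-1], dst_edges[:-1])
    bots = np.minimum.outer(src_edges[1:], dst_edges[1:])
    return np.clip(bots - tops, 0.0, None)


def echo_integrate(raw: Echogram, config: IntegrationConfig | None = None) -> Echogram:
    """Echo-integrate a fine raw grid to the ESDU lattice.

    Each ESDU cell is ``10*log10(mean linear sv)`` over its constituent
    samples, where samples below ``sv_threshold_db`` contribute zero linear
    energy.  Cells whose samples are all MISSING, or whose linear sum is zero
    (all samples thresholded), are MISSING.  Bins with top edge above the
    surface-exclusion depth, and bins extending below the frequency's maximum
    echo-integrated depth, are removed.
    """
    config = config or IntegrationConfig()
    lin = np.where(
        np.isnan(raw.sv) | (raw.sv < config.sv_threshold_db),
        0.0,
        10.0 ** (raw.sv / 10.0),
    )
    valid = (~np.isnan(raw.sv)).astype(float)

    # vertical: proportional overlap onto a grid aligned at 0 m
    max_depth = raw.depth_edges[-1]
    n_dst = int(np.ceil(max_depth / config.vertical_bin_m - 1e-9))
    dst_edges = np.arange(n_dst + 1) * config.vertical_bin_m
    w = _overlap_weights(raw.depth_edges, dst_edges)
    num_v = lin @ w          # (n_pings, n_dst) linear energy * thickness
    den_v = valid @ w        # (n_pings, n_dst) non-missing thickness

    # horizontal: consecutive groups of esdu_pings (trailing partial kept)
    n_pings = raw.n_pings
    n_groups = int(np.ceil(n_pings / config.esdu_pings))
    group = np.arange(n_pings) // config.esdu_pings
    num = np.zeros((n_groups, n_dst))
    den = np.zeros((n_groups, n_dst))
    np.add.at(num, group, num_v)
    np.add.at(den, group, den_v)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_lin = num / den
    sv = np.where((den > 0) & (mean_lin > 0), 10.0 * np.log10(
        np.where(mean_lin > 0, mean_lin, 1.0)), MISSING)

    first = np.arange(n_groups) * config.esdu_pings
    times = raw.ping_times[first]
    # ESDU position = mean of constituent ping positions
    pos = np.zeros((n_groups, 2))
    counts = np.bincount(group, minlength=n_groups).astype(float)
    np.add.at(pos, group, raw.positions)
    pos /= counts[:, None]

    keep = dst_edges[:-1] >= config.surface_exclusion_m
    fmax = dict(config.max_depth_m).get(float(raw.frequency_khz), np.inf)
    keep &= dst_edges[1:] <= fmax + 1e-9
    return Echogram(
        frequency_khz=raw.frequency_khz,
        ping_times=times,
        positions=pos,
        depth_edges=np.append(dst_edges[:-1][keep], dst_edges[1:][keep][-1])
        if keep.any()
        else dst_edges[:1],
        sv=sv[:, keep],
    )


def align_frequencies(echograms: Sequence[Echogram]) -> EchogramSet:
    """Stack per-frequency ESDU grids onto one shared lattice.

    All inputs must share identical ping times and an identical vertical bin
    structure over their common range; the output lattice is the union of
    depth ranges, with cells outside a frequency's own range MISSING for that
    frequency.
    """
    if not echograms:
        raise ValueError("no echograms to align")
    ref = echograms[0]
    for e in echograms[1:]:
        if e.n_pings != ref.n_pings or np.any(e.ping_times != ref.ping_times):
            raise ValueError("ping-time mismatch between frequencies")
    # union vertical lattice: echogram with deepest coverage defines it
    deepest = max(echograms, key=lambda e: e.depth_edges[-1])
    edges = deepest.depth_edges
    sv = {}
    for e in echograms:
        # each grid's edges must be a contiguous slice of the union lattice
        i0 = int(np.argmin(np.abs(edges - e.depth_edges[0])))
        seg = edges[i0 : i0 + len(e.depth_edges)]
        if len(seg) != len(e.depth_edges) or not np.allclose(
            seg, e.depth_edges, atol=1e-6
        ):
            raise ValueError(
                f"{e.frequency_khz} kHz grid is not on the shared vertical lattice"
            )
        full = np.full((ref.n_pings, len(edges) - 1), MISSING)
        full[:, i0 : i0 + e.n_bins] = e.sv
        if float(e.frequency_khz) in (float(k) for k in sv):
            raise ValueError(f"duplicate frequency {e.frequency_khz} kHz")
        sv[float(e.frequency_khz)] = full
    return EchogramSet(
        ping_times=ref.ping_times,
        positions=ref.positions,
        depth_edges=edges,
        sv=sv,
    )


def sv_to_nasc(
    echogram: Echogram, depth_from: float, depth_to: float
) -> np.ndarray:
    """Per-ping NASC, sA (m^2 nmi^-2), over the depth window [from, to).

    A bin belongs to the window when its *top* edge lies in ``[from, to)``,
    so disjoint windows partition the water column and their sA values sum
    exactly to the whole-column sA.  MISSING bins contribute zero.
    """
    if not depth_from < depth_to:
        raise ValueError("depth_from must be < depth_to")
    tops = echogram.depth_edges[:-1]
    sel = (tops >= depth_from) & (tops < depth_to)
    if not sel.any():
        raise ValueError("empty depth selection")
    lin = np.where(np.isnan(echogram.sv[:, sel]), 0.0,
                   10.0 ** (echogram.sv[:, sel] / 10.0))
    return NASC_FACTOR * (lin @ echogram.bin_thickness[sel])


# ---------------------------------------------------------------------------
# Solar geometry (NOAA low-precision solar position)
# ---------------------------------------------------------------------------

def solar_elevation(times, lat, lon) -> np.ndarray:
    """Solar elevation angle (degrees) for UTC times at (lat, lon).

    NOAA's low-precision solar position algorithm (Julian-century polynomial
    ephemeris + equation of time); accurate to ~0.1 degree, ample for twilight
    banding.  Atmospheric refraction is not applied.
    """
    t64 = _as_utc_datetime64(np.atleast_1d(times))
    lat = np.broadcast_to(np.asarray(lat, dtype=float), t64.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), t64.shape)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
        raise ValueError("invalid coordinates")

    # Julian day from Unix epoch seconds
    jd = t64.astype("datetime64[s]").astype("int64") / 86400.0 + 2440587.5
    T = (jd - 2451545.0) / 36525.0

    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.deg2rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(app_long))

    y = np.tan(eps / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eq_time = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )  # minutes

    minutes_utc = (
        t64.astype("datetime64[s]").astype("int64") % 86400
    ) / 60.0
    true_solar_min = np.mod(minutes_utc + eq_time + 4.0 * lon, 1440.0)
    ha = true_solar_min / 4.0 - 180.0  # degrees, 0 at local solar noon
    ha_r = np.deg2rad(ha)
    lat_r = np.deg2rad(lat)
    elev = np.arcsin(
        np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha_r)
    )
    out = np.rad2deg(elev)
    return out if np.ndim(times) else float(out[0])


def classify_solar(times, lat, lon, twilight_band_deg: float = 6.0):
    """Classify times into night / sunrise / day / sunset from solar elevation.

    Day when elevation > +band, night when < -band; within the +-band the
    period is sunrise on the ascending side of the solar arc and sunset on the
    descending side (determined from the elevation one minute later).
    """
    scalar = np.ndim(times) == 0
    t = np.atleast_1d(_as_utc_datetime64(np.atleast_1d(times)))
    elev = np.atleast_1d(solar_elevation(t, lat, lon))
    elev_next = np.atleast_1d(solar_elevation(t + np.timedelta64(60, "s"), lat, lon))
    rising = elev_next > elev
    out = np.empty(len(elev), dtype=object)
    out[elev > twilight_band_deg] = SolarPeriod.DAY
    out[elev < -twilight_band_deg] = SolarPeriod.NIGHT
    band = (elev >= -twilight_band_deg) & (elev <= twilight_band_deg)
    out[band & rising] = SolarPeriod.SUNRISE
    out[band & ~rising] = SolarPeriod.SUNSET
    return out[0] if scalar else out
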