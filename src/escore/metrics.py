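"""Acoustic summary metrics: total sA, DVM strength, depth-category NASC, EKE.

Metrics are computed per oceanographic zone (anticyclone / cyclone /
transition zone) and solar period; sunrise and sunset pings are excluded so
only day and night cells contribute.  DVM (diel vertical migration) strength
is 1 - sA_meso_night / sA_meso_day with the mesopelagic realm defined as
200 m down to the maximum echo-integrated depth, and is reported for the
18, 38 and 70 kHz channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .echogrid import Echogram, SolarPeriod, sv_to_nasc

__all__ = [
    "ZoneLabeling",
    "total_sa",
    "dvm_strength",
    "depth_category_nasc",
    "eke",
    "DEPTH_CATEGORIES",
    "MESO_TOP_M",
    "DVM_FREQUENCIES_KHZ",
]

MESO_TOP_M = 200.0
DVM_FREQUENCIES_KHZ = (18.0, 38.0, 70.0)

#: Depth categories (m): surface / intermediate / deep.  120 kHz resolves
#: only surface + intermediate, 200 kHz only surface (range limits).
DEPTH_CATEGORIES = {
    "surface": (15.0, 200.0),
    "intermediate": (200.0, 400.0),
    "deep": (400.0, np.inf),
}
CATEGORY_RULE = {
    120.0: ("surface", "intermediate"),
    200.0: ("surface",),
}


@dataclass
class ZoneLabeling:
    """Non-overlapping time intervals labelled with an oceanographic zone.

    Zones outside the AC/C/TZ set (e.g. "mix") are carried but excluded from
    metric summaries by the callers below.
    """

    starts: np.ndarray  # datetime64[ns]
    ends: np.ndarray
    zones: list[str]

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype="datetime64[ns]")
        self.ends = np.asarray(self.ends, dtype="datetime64[ns]")
        order = np.argsort(self.starts)
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.zones = [self.zones[i] for i in order]
        if np.any(self.ends <= self.starts):
            raise ValueError("zone intervals must be non-empty")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("zone intervals must not overlap")

    @classmethod
    def from_csv(cls, path) -> "ZoneLabeling":
        """Read ``start_iso,end_iso,zone`` rows."""
        df = pd.read_csv(path)
        return cls(
            starts=pd.to_datetime(df["start_iso"], utc=True)
            .dt.tz_localize(None)
            .to_numpy(),
            ends=pd.to_datetime(df["end_iso"], utc=True)
            .dt.tz_localize(None)
            .to_numpy(),
            zones=[str(z) for z in df["zone"]],
        )

    def zone_of(self, times) -> np.ndarray:
        """Per-time zone label; None where no interval covers the time."""
        t = np.asarray(times, dtype="datetime64[ns]")
        out = np.array([None] * len(t), dtype=object)
        for s, e, z in zip(self.starts, self.ends, self.zones):
            out[(t >= s) & (t < e)] = z
        return out


def _period_strings(periods) -> np.ndarray:
    return np.array(
        [p.value if isinstance(p, SolarPeriod) else str(p) for p in periods]
    )


def total_sa(
    echogram: Echogram,
    periods,
    zones,
) -> pd.DataFrame:
    """Mean +- SD per-ping total sA by (zone, day/night).

    Per ping, sA is integrated from the top to the maximum echo-integrated
    depth of the grid; pings are grouped by zone and solar period (sunrise /
    sunset and unzoned pings dropped) and summarized as mean and SD across
    pings.
    """
    per_ping = sv_to_nasc(
        echogram, echogram.depth_edges[0], echogram.depth_edges[-1]
    )
    return _summarize(per_ping, periods, zones, echogram.frequency_khz)


def _summarize(per_ping, periods, zones, frequency_khz) -> pd.DataFrame:
    p = _period_strings(periods)
    z = np.asarray(zones, dtype=object)
    rows = []
    for zone in sorted({str(v) for v in z if v is not None}):
        for period in ("day", "night"):
            m = (z == zone) & (p == period)
            if not m.any():
                continue
            rows.append(
                {
                    "frequency_khz": frequency_khz,
                    "zone": zone,
                    "period": period,
                    "mean_sa": float(per_ping[m].mean()),
                    "sd_sa": float(per_ping[m].std(ddof=1))
                    if m.sum() > 1
                    else float("nan"),
                    "n_pings": int(m.sum()),
                }
            )
    if not rows:
        raise ValueError("no qualifying pings (day/night within a zone)")
    return pd.DataFrame(rows)


def dvm_strength(sa_meso_day: float, sa_meso_night: float) -> float:
    """DVM strength = 1 - sA_meso_night / sA_meso_day.

    Scale-invariant fraction of the daytime mesopelagic backscatter that
    leaves the mesopelagic realm at night; undefined (NaN) when the daytime
    backscatter is zero.
    """
    if sa_meso_day == 0:
        return float("nan")
    return 1.0 - sa_meso_night / sa_meso_day


def depth_category_nasc(
    echogram: Echogram,
    periods,
    zones,
) -> pd.DataFrame:
    """Mean per-ping NASC within the surface / intermediate / deep categories
    by (zone, day/night); 120 kHz reports only surface + intermediate and
    200 kHz only surface.  Category sums conserve the total NASC over
    [15 m, max depth) exactly in the linear domain."""
    f = float(echogram.frequency_khz)
    cats = CATEGORY_RULE.get(f, tuple(DEPTH_CATEGORIES))
    max_depth = echogram.depth_edges[-1]
    frames = []
    for cat in cats:
        lo, hi = DEPTH_CATEGORIES[cat]
        hi = min(hi, max_depth)
        if lo >= hi:
            continue
        per_ping = sv_to_nasc(echogram, lo, hi)
        df = _summarize(per_ping, periods, zones, f)
        df.insert(3, "depth_category", cat)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def eke(u, v):
    """Eddy kinetic energy 0.5 (u^2 + v^2) in m^2 s^-2, element-wise."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("velocities must be finite")
    out = 0.5 * (u * u + v * v)
    return float(out) if out.ndim == 0 else out
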