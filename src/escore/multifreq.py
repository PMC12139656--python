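"""Frequency differencing relative to 38 kHz and RGB composite echograms.

dB-differencing is the classification feature space: per ESDU cell the
triplet (Sv18-Sv38, Sv70-Sv38, Sv120-Sv38).  A triplet is MISSING when any of
the four contributing frequency cells is MISSING.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .echogrid import MISSING, Echogram, EchogramSet, _as_utc_datetime64

__all__ = [
    "DeltaSvGrid",
    "RgbComposite",
    "compute_delta_sv",
    "rgb_composite",
    "read_delta_csv",
    "write_delta_csv",
]

REFERENCE_KHZ = 38.0
DIFF_KHZ = (18.0, 70.0, 120.0)
AXIS_NAMES = ("d18_38", "d70_38", "d120_38")


@dataclass
class DeltaSvGrid:
    """Per-cell ΔSv triplets (dB) relative to 38 kHz on a shared lattice.

    ``delta`` has shape ``(n_pings, n_bins, 3)`` ordered (18-38, 70-38,
    120-38); a cell is MISSING (all-NaN triplet) iff any contributing
    frequency was MISSING there.
    """

    ping_times: np.ndarray
    positions: np.ndarray
    depth_edges: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        self.ping_times = _as_utc_datetime64(self.ping_times)
        self.positions = np.asarray(self.positions, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 3 or self.delta.shape[2] != 3:
            raise ValueError("delta must have shape (n_pings, n_bins, 3)")
        if self.delta.shape[:2] != (len(self.ping_times), len(self.depth_edges) - 1):
            raise ValueError("delta does not match the lattice")

    @property
    def n_pings(self) -> int:
        return self.delta.shape[0]

    @property
    def n_bins(self) -> int:
        return self.delta.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """(n_pings, n_bins) True where the triplet is MISSING."""
        return np.isnan(self.delta).any(axis=2)

    def triplets(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (coords, triplets) over non-MISSING cells.

        ``coords`` is an (m, 2) integer array of (ping index, bin index).
        """
        ok = ~self.missing_mask
        coords = np.argwhere(ok)
        return coords, self.delta[ok]


@dataclass
class RgbComposite:
    """RGB rendering of three frequencies' Sv, channel values in [0, 1]."""

    image: np.ndarray  # (n_pings, n_bins, 3)
    channel_khz: tuple[float, float, float]  # (red, green, blue)
    display_range_db: tuple[float, float]

    def to_png(self, path) -> None:
        """Export as PNG with pings on the x-axis and depth downward."""
        from PIL import Image

        arr = (np.clip(self.image, 0, 1) * 255).astype(np.uint8)
        # transpose so depth runs down the image
        Image.fromarray(arr.transpose(1, 0, 2), mode="RGB").save(path)


def compute_delta_sv(eset: EchogramSet) -> DeltaSvGrid:
    """Per-cell ΔSv triplet (Sv18-Sv38, Sv70-Sv38, Sv120-Sv38).

    Requires the 18, 38, 70 and 120 kHz grids on the shared lattice; the
    38 kHz reference is mandatory.  Any MISSING contributor makes the whole
    triplet MISSING (the three axes are kept jointly valid).
    """
    if REFERENCE_KHZ not in eset.sv:
        raise ValueError("38 kHz reference frequency is required")
    for f in DIFF_KHZ:
        if f not in eset.sv:
            raise ValueError(f"{f:g} kHz grid is required for dB-differencing")
    ref = eset.sv[REFERENCE_KHZ]
    delta = np.stack([eset.sv[f] - ref for f in DIFF_KHZ], axis=2)
    delta[np.isnan(delta).any(axis=2)] = MISSING
    return DeltaSvGrid(
        ping_times=eset.ping_times,
        positions=eset.positions,
        depth_edges=eset.depth_edges,
        delta=delta,
    )


def rgb_composite(
    eset: EchogramSet,
    frequency_triple: tuple[float, float, float],
    display_range_db: tuple[float, float] = (-90.0, -50.0),
) -> RgbComposite:
    """Render three frequencies as an RGB composite.

    Each channel is the linear rescale of that frequency's Sv from
    ``display_range_db`` to [0, 1], clipped; MISSING cells render as 0.
    The conventional triples are (18, 38, 70) and (38, 70, 120) kHz with the
    lowest frequency coded red.
    """
    low, high = display_range_db
    if low >= high:
        raise ValueError("degenerate display range (low >= high)")
    chans = []
    for f in frequency_triple:
        if float(f) not in eset.sv:
            raise ValueError(f"{f:g} kHz not present in the echogram set")
        sv = eset.sv[float(f)]
        chan = np.clip((sv - low) / (high - low), 0.0, 1.0)
        chans.append(np.where(np.isnan(sv), 0.0, chan))
    return RgbComposite(
        image=np.stack(chans, axis=2),
        channel_khz=tuple(float(f) for f in frequency_triple),
        display_range_db=(low, high),
    )


def write_delta_csv(grid: DeltaSvGrid, path, precision: int = 4) -> None:
    """Serialize a ΔSv grid in the Sv CSV dialect with three value columns per
    depth bin (suffixes _d18_38, _d70_38, _d120_38)."""
    edges = grid.depth_edges
    cols = []
    for i in range(grid.n_bins):
        base = f"d_{edges[i]:.1f}_{edges[i + 1]:.1f}"
        cols.extend(f"{base}_{ax}" for ax in AXIS_NAMES)
    times = pd.DatetimeIndex(grid.ping_times).strftime("%Y-%m-%dT%H:%M:%SZ")
    fmt = f"%.{precision}f"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ping_time,lat,lon," + ",".join(cols) + "\n")
        for i in range(grid.n_pings):
            row = [times[i], f"{grid.positions[i, 0]:.6f}",
                   f"{grid.positions[i, 1]:.6f}"]
            for j in range(grid.n_bins):
                for a in range(3):
                    v = grid.delta[i, j, a]
                    row.append("" if np.isnan(v) else fmt % v)
            fh.write(",".join(row) + "\n")


def read_delta_csv(path) -> DeltaSvGrid:
    """Read a ΔSv grid written by :func:`write_delta_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:3] != ["ping_time", "lat", "lon"]:
        raise ValueError(f"malformed header in {path}")
    if (len(cols) - 3) % 3:
        raise ValueError(f"depth columns not in triplets in {path}")
    tops, bottoms = [], []
    for c in cols[3::3]:
        if not c.endswith("_" + AXIS_NAMES[0]):
            raise ValueError(f"unexpected column {c!r}")
        base = c[: -len("_" + AXIS_NAMES[0])]
        _, top, bottom = base.split("_")
        tops.append(float(top))
        bottoms.append(float(bottom))
    edges = np.array(tops + [bottoms[-1]])
    times = pd.to_datetime(df["ping_time"], utc=True, format="ISO8601")
    lat = pd.to_numeric(df["lat"]).to_numpy()
    lon = pd.to_numeric(df["lon"]).to_numpy()
    vals = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy() for c in cols[3:]]
    )
    delta = vals.reshape(len(df), len(tops), 3)
    return DeltaSvGrid(
        ping_times=times,
        positions=np.column_stack([lat, lon]),
        depth_edges=edges,
        delta=delta,
    )
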