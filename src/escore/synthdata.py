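"""Synthetic multifrequency echogram scenes with known truth.

The generator plants horizontal scattering layers with distinct per-frequency
mean Sv (hence distinct ΔSv signatures), Gaussian dB noise, optional
along-track segment-wise mean drift (emulating the natural echo-type-to-
echo-type variability a training library exhibits), partial occupancy, and an
optional diel step change of layer depth.  Scenes are emitted directly on the
ESDU lattice (1.5 m x ESDU-ping) together with truth class labels and one ROI
per layer segment, so every pipeline stage is testable without cruise data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .echogrid import EchogramSet, SolarPeriod, classify_solar
from .training import Roi

__all__ = ["LayerSpec", "SceneSpec", "generate_scene", "reference_scene"]

SCENE_FREQUENCIES = (18.0, 38.0, 70.0, 120.0)


@dataclass
class LayerSpec:
    """One planted scattering layer.

    ``depth_day`` / ``depth_night`` are [top, bottom) bands in metres (equal
    bands = no migration); ``mean_sv`` maps frequency (kHz) to the layer's
    mean Sv in dB; ``noise_sd`` is the per-cell Gaussian dB noise SD;
    ``mean_jitter_sd`` is the SD of the per-segment, per-frequency mean
    offset (along-track drift); ``occupancy`` is the per-cell presence
    probability; ``class_id`` is the truth echo-class.
    """

    depth_day: tuple[float, float]
    depth_night: tuple[float, float]
    mean_sv: dict[float, float]
    noise_sd: float = 0.5
    mean_jitter_sd: float = 0.0
    occupancy: float = 1.0
    class_id: int = 1

    def __post_init__(self):
        for band in (self.depth_day, self.depth_night):
            if band[1] <= band[0] or band[0] < 0:
                raise ValueError("layer depth bands must be non-empty, >= 0 m")
        if self.noise_sd < 0 or self.mean_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")

    @property
    def delta_triplet(self) -> np.ndarray:
        """Planted ΔSv triplet (18-38, 70-38, 120-38) of the layer."""
        ref = self.mean_sv[38.0]
        return np.array([self.mean_sv[f] - ref for f in (18.0, 70.0, 120.0)])


@dataclass
class SceneSpec:
    """Scene geometry, timing and layer content (seeded, bit-reproducible)."""

    layers: list[LayerSpec]
    n_pings: int = 600
    ping_interval_s: float = 9.0  # one ESDU = 3 raw pings at 3 s
    start_time: str = "2022-04-26T09:00:00Z"
    lat: float = -25.0
    lon: float = 40.0
    vertical_bin_m: float = 1.5
    max_depth_m: float = 250.0
    background_sv: dict[float, float] = field(
        default_factory=lambda: {f: -95.0 for f in SCENE_FREQUENCIES}
    )
    segment_pings: int = 12  # along-track extent of one ROI / drift segment
    seed: int = 0


def _band_for_period(layer: LayerSpec, period) -> tuple[float, float]:
    # step change at period boundaries: sunrise joins day, sunset joins night
    if period in (SolarPeriod.DAY, SolarPeriod.SUNRISE):
        return layer.depth_day
    return layer.depth_night


def generate_scene(
    spec: SceneSpec,
) -> tuple[EchogramSet, np.ndarray, list[Roi]]:
    """Generate a multifrequency scene with truth labels and training ROIs.

    Returns ``(echogram_set, truth_labels, rois)``: the EchogramSet on the
    ESDU lattice, an (n_pings, n_bins) integer grid of truth class ids (0 =
    background), and one ROI per (layer, along-track segment) covering the
    layer's band during that segment.  Where layers overlap, the first layer
    in declaration order wins and the truth records that layer.
    """
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.max_depth_m / spec.vertical_bin_m))
    edges = np.arange(n_bins + 1) * spec.vertical_bin_m
    tops = edges[:-1]
    t0 = np.datetime64(spec.start_time.replace("Z", ""), "ns")
    times = t0 + (np.arange(spec.n_pings) * spec.ping_interval_s * 1e9).astype(
        "timedelta64[ns]"
    )
    positions = np.column_stack(
        [np.full(spec.n_pings, spec.lat), np.full(spec.n_pings, spec.lon)]
    )
    periods = classify_solar(times, spec.lat, spec.lon)

    sv = {
        f: np.full((spec.n_pings, n_bins), spec.background_sv[f])
        + rng.normal(0.0, 0.1, size=(spec.n_pings, n_bins))
        for f in SCENE_FREQUENCIES
    }
    truth = np.zeros((spec.n_pings, n_bins), dtype=int)
    claimed = np.zeros((spec.n_pings, n_bins), dtype=bool)
    rois: list[Roi] = []

    n_segments = int(np.ceil(spec.n_pings / spec.segment_pings))
    for li, layer in enumerate(spec.layers):
        # per-segment per-frequency mean drift, fixed for the whole segment
        drift = rng.normal(
            0.0, layer.mean_jitter_sd, size=(n_segments, len(SCENE_FREQUENCIES))
        )
        occupied = rng.random((spec.n_pings, n_bins)) < layer.occupancy
        for seg in range(n_segments):
            p0 = seg * spec.segment_pings
            p1 = min(spec.n_pings, (seg + 1) * spec.segment_pings)
            band = [_band_for_period(layer, periods[p]) for p in range(p0, p1)]
            cells = []
            for j, p in enumerate(range(p0, p1)):
                in_band = (tops >= band[j][0]) & (tops < band[j][1])
                c = in_band & occupied[p] & ~claimed[p]
                truth[p, c] = layer.class_id
                claimed[p, c] = True
                cells.append(c)
            for fi, f in enumerate(SCENE_FREQUENCIES):
                mean = layer.mean_sv[f] + drift[seg, fi]
                for j, p in enumerate(range(p0, p1)):
                    n_cells = int(cells[j].sum())
                    if n_cells:
                        sv[f][p, cells[j]] = mean + rng.normal(
                            0.0, layer.noise_sd, size=n_cells
                        )
            # one training ROI per segment over the segment's (constant) band,
            # provided it sits above 250 m
            top, bot = band[0]
            if bot <= 250.0 and all(b == band[0] for b in band):
                rois.append(
                    Roi(
                        id=f"layer{li + 1}_seg{seg}",
                        ping_start=p0,
                        ping_end=p1,
                        depth_top=float(top),
                        depth_bottom=float(bot),
                    )
                )

    eset = EchogramSet(
        ping_times=times, positions=positions, depth_edges=edges, sv=sv
    )
    return eset, truth, rois


def reference_scene(seed: int = 0) -> SceneSpec:
    """Canonical 4-layer scene mirroring the qualitative echo-class shapes.

    Layer truth classes reproduce the field-observed frequency-response
    ordering: class 3 is 18 kHz dominant with a monotonically falling
    response; classes 1, 2 and 4 all peak at 38 kHz but differ in their
    high-frequency slopes (class 1 a weak-scatterer rise from 18 to 38, class
    2 a sharp 38 kHz resonance, class 4 nearly flat above 38 kHz).  Planted
    ΔSv signatures are at least ~6.4 dB apart, per-cell noise is 0.5 dB per
    frequency and segment-wise mean drift 0.5 dB, so classes are separated by
    well over six combined noise SDs.  Different seeds change only the noise
    and drift draws, never the layer means.
    """
    mk = lambda s18, s38, s70, s120: {18.0: s18, 38.0: s38, 70.0: s70, 120.0: s120}
    layers = [
        # class 1: zooplankton-like, response rising from 18 to 38 kHz
        LayerSpec(
            depth_day=(30.0, 60.0),
            depth_night=(30.0, 60.0),
            mean_sv=mk(-87.0, -78.0, -79.0, -80.0),
            noise_sd=0.5,
            mean_jitter_sd=0.5,
            class_id=1,
        ),
        # class 2: sharp 38 kHz resonance (small gas bubbles)
        LayerSpec(
            depth_day=(75.0, 105.0),
            depth_night=(75.0, 105.0),
            mean_sv=mk(-86.0, -72.0, -81.0, -85.0),
            noise_sd=0.5,
            mean_jitter_sd=0.5,
            class_id=2,
        ),
        # class 3: 18 kHz dominant, decreasing at higher frequencies
        LayerSpec(
            depth_day=(120.0, 150.0),
            depth_night=(120.0, 150.0),
            mean_sv=mk(-70.0, -76.0, -83.0, -89.0),
            noise_sd=0.5,
            mean_jitter_sd=0.5,
            class_id=3,
        ),
        # class 4: 38 kHz peak with a strong high-frequency response
        LayerSpec(
            depth_day=(165.0, 195.0),
            depth_night=(165.0, 195.0),
            mean_sv=mk(-79.0, -76.0, -78.5, -76.5),
            noise_sd=0.5,
            mean_jitter_sd=0.5,
            class_id=4,
        ),
    ]
    return SceneSpec(
        layers=layers,
        n_pings=624,  # 52 twelve-ping ROI segments per layer
        segment_pings=12,
        seed=seed,
    )
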