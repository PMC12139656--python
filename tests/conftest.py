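import numpy as np
import pytest

from escore import pipeline, synthdata
from escore.echogrid import Echogram, EchogramSet


def make_echogram(
    frequency_khz=38.0,
    n_pings=6,
    n_bins=20,
    bin_m=1.5,
    depth_top=0.0,
    sv=None,
    seed=0,
    start="2022-04-26T10:00:00",
):
    rng = np.random.default_rng(seed)
    if sv is None:
        sv = rng.uniform(-95.0, -60.0, size=(n_pings, n_bins))
    sv = np.asarray(sv, dtype=float)
    n_pings, n_bins = sv.shape
    times = np.datetime64(start) + np.arange(n_pings) * np.timedelta64(9, "s")
    pos = np.tile([-25.0, 40.0], (n_pings, 1))
    edges = depth_top + np.arange(n_bins + 1) * bin_m
    return Echogram(frequency_khz, times, pos, edges, sv)


def make_set(sv_by_freq, bin_m=1.5, depth_top=0.0, start="2022-04-26T10:00:00"):
    """EchogramSet from {khz: (n_pings, n_bins) array} on one lattice."""
    first = next(iter(sv_by_freq.values()))
    n_pings, n_bins = np.asarray(first).shape
    times = np.datetime64(start) + np.arange(n_pings) * np.timedelta64(9, "s")
    pos = np.tile([-25.0, 40.0], (n_pings, 1))
    edges = depth_top + np.arange(n_bins + 1) * bin_m
    return EchogramSet(
        ping_times=times,
        positions=pos,
        depth_edges=edges,
        sv={float(f): np.asarray(v, dtype=float) for f, v in sv_by_freq.items()},
    )


@pytest.fixture(scope="session")
def reference_run():
    """Canonical 4-layer scene (seed 0) with the full training run.

    Session-scoped: the scene and its trained model are shared by the
    end-to-end and acceptance tests.
    """
    spec = synthdata.reference_scene(seed=0)
    eset, truth, rois = synthdata.generate_scene(spec)
    result = pipeline.run_train(eset, rois)
    return {
        "spec": spec,
        "eset": eset,
        "truth": truth,
        "rois": rois,
        "result": result,
    }


def map_model_to_truth(model, spec):
    """Map fitted class ids to planted truth class ids by nearest planted
    ΔSv triplet (class numbering is deterministic but arbitrary)."""
    planted = {layer.class_id: layer.delta_triplet for layer in spec.layers}
    mapping = {}
    for i, cid in enumerate(model.class_ids):
        dists = {t: np.linalg.norm(model.mu[i] - v) for t, v in planted.items()}
        mapping[int(cid)] = min(dists, key=dists.get)
    return mapping
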