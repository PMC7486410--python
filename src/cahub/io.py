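"""Plain-text readers and writers for rasters, epochs, protocols and graphs.

Formats:

* raster — tab-delimited integer matrix (rows = cells, columns =
  frames) plus a JSON sidecar ``<name>.json`` holding
  ``{"frame_rate_hz": ..., "cell_ids": [...], "tag": [...]}``;
* epochs — CSV with columns ``label,start_frame,end_frame`` (half-open);
* stimulation protocol and ground truth — JSON;
* functional graph — GraphML plus a CSV edge list
  ``source,target,mean_lag_ms,n_samples``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cahub.connectivity import FunctionalGraph
from cahub.raster import ActivityRaster, EpochSet, StimulationProtocol


def write_raster(path: str | Path, r: ActivityRaster) -> None:
    path = Path(path)
    np.savetxt(path, r.onsets, fmt="%d", delimiter="\t")
    sidecar = {
        "frame_rate_hz": r.frame_rate_hz,
        "cell_ids": list(r.cell_ids),
        "tag": list(r.tag) if r.tag is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_raster(path: str | Path) -> ActivityRaster:
    path = Path(path)
    onsets = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ActivityRaster(
        onsets, meta["frame_rate_hz"], meta["cell_ids"], meta.get("tag")
    )


def write_epochs(path: str | Path, *epoch_sets: EpochSet) -> None:
    rows = [
        {"label": es.label, "start_frame": int(s), "end_frame": int(e)}
        for es in epoch_sets
        for s, e in es.intervals
    ]
    pd.DataFrame(rows, columns=["label", "start_frame", "end_frame"]).to_csv(
        path, index=False
    )


def read_epochs(path: str | Path) -> dict[str, EpochSet]:
    df = pd.read_csv(path)
    out = {}
    for label, grp in df.groupby("label"):
        out[str(label)] = EpochSet(
            str(label), grp[["start_frame", "end_frame"]].to_numpy()
        )
    return out


def write_protocol(path: str | Path, proto: StimulationProtocol) -> None:
    Path(path).write_text(json.dumps({
        "stim_frames": proto.stim_frames.tolist(),
        "trial_len_frames": int(proto.trial_len_frames),
        "pre": list(proto.pre),
        "stim": list(proto.stim),
        "post": list(proto.post),
        "stim_rate_hz": proto.stim_rate_hz,
    }, indent=1))


def read_protocol(path: str | Path) -> StimulationProtocol:
    d = json.loads(Path(path).read_text())
    return StimulationProtocol(
        np.asarray(d["stim_frames"], dtype=np.int64),
        d["trial_len_frames"],
        tuple(d["pre"]), tuple(d["stim"]), tuple(d["post"]),
        d.get("stim_rate_hz", 0.1),
    )


def write_ground_truth(path: str | Path, gt: dict) -> None:
    Path(path).write_text(json.dumps(gt, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_graph(path_prefix: str | Path, fg: FunctionalGraph) -> None:
    """Write ``<prefix>.graphml`` and ``<prefix>_edges.csv``."""
    prefix = Path(path_prefix)
    nx.write_graphml(fg.graph, prefix.with_suffix(".graphml"))
    rows = [
        {"source": u, "target": v,
         "mean_lag_ms": d.get("mean_lag_ms", np.nan),
         "n_samples": d.get("n_samples", 0)}
        for u, v, d in fg.graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "mean_lag_ms", "n_samples"]
    ).to_csv(prefix.parent / f"{prefix.stem}_edges.csv", index=False)


def read_graph(path: str | Path, fov_id: str = "fov0") -> FunctionalGraph:
    g = nx.read_graphml(path, node_type=int)
    return FunctionalGraph(nx.DiGraph(g), fov_id=fov_id)
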