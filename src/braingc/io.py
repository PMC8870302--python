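"""Plain-text I/O: recordings, GC matrices, networks, and sidecar metadata.

Recordings travel as a delimited numeric matrix (channels x samples, TSV)
with a JSON sidecar holding sample rate, labels, state tag and provenance;
EDF files are read through :mod:`mne`. All numeric text output is written at
full repr precision so reruns are byte-comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .granger import GCMatrix
from .network import DirectedNetwork
from .recording import BandDefinition, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_segments",
    "write_gc_matrix",
    "read_gc_matrix",
    "write_network",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path: str | Path, extra: dict | None = None) -> Path:
    """Write a recording as TSV plus a JSON sidecar; returns the data path."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.17g")
    meta = {
        "sample_rate": rec.sample_rate,
        "channel_labels": list(rec.channel_labels),
        "state_tag": rec.state_tag,
        "units": "uV",
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording from EDF (via mne) or delimited matrix + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads volts; recordings are in uV
        return Recording(
            data=data,
            sample_rate=float(raw.info["sfreq"]),
            channel_labels=tuple(raw.ch_names),
        )
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Recording(
        data=data,
        sample_rate=float(meta["sample_rate"]),
        channel_labels=tuple(meta["channel_labels"]),
        state_tag=meta.get("state_tag", ""),
    )


def write_segments(segs, outdir: str | Path) -> Path:
    """Write a SegmentSet as one delimited matrix per segment plus a JSON
    manifest (band, window starts, seed, state). Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, seg in enumerate(segs.segments):
        path = outdir / f"segment_{k:02d}.tsv"
        np.savetxt(path, seg.data, delimiter="\t", fmt="%.17g")
        files.append(path.name)
    manifest = {
        "files": files,
        "band": None
        if segs.band is None
        else {"name": segs.band.name, "low_hz": segs.band.low_hz, "high_hz": segs.band.high_hz},
        "source_state": segs.source_state,
        "seed": segs.seed,
        "window_starts": list(segs.window_starts),
        "sample_rate": segs.segments[0].sample_rate,
        "channel_labels": list(segs.channel_labels),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def write_gc_matrix(gc: GCMatrix, path: str | Path, extra: dict | None = None) -> Path:
    """Write a labelled square GCI matrix as CSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(gc.values, index=gc.channel_labels, columns=gc.channel_labels)
    df.to_csv(path, float_format="%.17g")
    meta = {
        "orientation": "row -> column (values[i][j] is channel i -> channel j)",
        "order_used": gc.order_used,
        "n_segments_averaged": gc.n_segments_averaged,
        "band": None
        if gc.band is None
        else {"name": gc.band.name, "low_hz": gc.band.low_hz, "high_hz": gc.band.high_hz},
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_gc_matrix(path: str | Path) -> GCMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar_path(path).read_text())
    band = meta.get("band")
    return GCMatrix(
        values=df.to_numpy(dtype=float),
        channel_labels=tuple(df.index),
        order_used=int(meta["order_used"]),
        band=None if band is None else BandDefinition(band["name"], band["low_hz"], band["high_hz"]),
        n_segments_averaged=int(meta.get("n_segments_averaged", 1)),
    )


def write_network(net: DirectedNetwork, stem: str | Path) -> tuple[Path, Path]:
    """Write adjacency (labelled CSV of 0/1) and a source->target edge list."""
    stem = Path(stem)
    adj_path = stem.with_suffix(".adjacency.csv")
    edges_path = stem.with_suffix(".edges.tsv")
    df = pd.DataFrame(
        net.adjacency.astype(int), index=net.node_labels, columns=net.node_labels
    )
    df.to_csv(adj_path)
    lines = [f"{s}\t{t}" for s, t in net.edge_list()]
    edges_path.write_text("\n".join(["source\ttarget"] + lines) + "\n")
    return adj_path, edges_path
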