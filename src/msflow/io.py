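"""Reading and writing multi-set cytometry data.

Samples enter the package either as per-sample CSV matrices (header row
of marker names, one row per cell) or as FCS 2.0/3.0/3.1 files, tied
together by a *manifest* — a CSV or YAML table with columns ``file``,
``sample_id`` and ``group``.  Group labels may be integers (0 = control)
or strings; string labels are mapped to integers through an explicit
dictionary that is recorded in ``MultiSet.meta["group_labels"]``.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (ChannelError, MarkerPanel, MultiSet,
                        PanelMismatchError, SampleSet)
from . import fcs as _fcs

__all__ = [
    "read_manifest",
    "map_group_labels",
    "read_csv_sample",
    "read_fcs",
    "read_multiset",
    "read_csv_multiset",
    "write_multiset_csv",
]

_CONTROL_ALIASES = {"control", "ctrl", "reference", "ref", "healthy", "lean", "0"}


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load a manifest (CSV or YAML) with columns file, sample_id, group."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        if isinstance(entries, Mapping) and "samples" in entries:
            entries = entries["samples"]
        table = pd.DataFrame(entries)
    else:
        table = pd.read_csv(path)
    missing = {"file", "sample_id", "group"} - set(table.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return table


def map_group_labels(labels: Sequence, group_map: Mapping | None = None
                     ) -> tuple[list[int], dict]:
    """Map manifest group labels to integer group ids (0 = control).

    Integer-like labels pass through.  String labels are assigned through
    ``group_map`` when given; otherwise control-like names (control,
    ctrl, reference, healthy, lean) map to 0 and the remaining distinct
    labels to 1, 2, ... in sorted order.  The mapping used is returned so
    callers can record it.
    """
    if group_map is not None:
        mapping = dict(group_map)
        try:
            ids = [int(mapping[lab]) for lab in labels]
        except KeyError as exc:
            raise ValueError(f"group label {exc} missing from group_map") from exc
        return ids, mapping
    mapping = {}
    strings = []
    for lab in dict.fromkeys(labels):  # unique, order-preserving
        try:
            mapping[lab] = int(lab)
        except (TypeError, ValueError):
            strings.append(str(lab))
    next_id = 1
    for lab in sorted(strings):
        if lab.lower() in _CONTROL_ALIASES:
            mapping[lab] = 0
        else:
            mapping[lab] = next_id
            next_id += 1
    ids = [mapping[lab] if lab in mapping else mapping[str(lab)] for lab in labels]
    return ids, mapping


def read_csv_sample(path: str | os.PathLike, sample_id: str, group_id: int,
                    panel: MarkerPanel | None = None) -> SampleSet:
    """Read one cell x marker CSV (header row = marker names).

    When a panel is supplied, columns are re-aligned to panel order;
    missing or extra columns are a panel mismatch.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if panel is not None:
        have = list(frame.columns)
        if set(have) != set(panel.names):
            raise PanelMismatchError(
                f"{path}: header {have} does not match panel {list(panel.names)}"
            )
        frame = frame[list(panel.names)]
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any() and not frame[col].isna().any():
                row = int(coerced.isna().idxmax())
                raise ValueError(
                    f"{path}: non-numeric value {frame[col][row]!r} at row "
                    f"{row}, column {col!r}"
                )
        values = frame.astype(float).to_numpy()
    return SampleSet(sample_id, group_id, values)


def read_fcs(path: str | os.PathLike, channels: Sequence[str] | None = None,
             sample_id: str | None = None, group_id: int = 0) -> SampleSet:
    """Read one FCS file into a :class:`SampleSet`.

    Marker names come from ``$PnS`` with fallback to ``$PnN``.  When
    ``channels`` is given, only those channels are kept, in request
    order; an unknown channel raises :class:`ChannelError` listing the
    names available in the file.
    """
    path = Path(path)
    keywords, events = _fcs.parse_fcs(path)
    names = _fcs.channel_names(keywords)
    if channels is not None:
        idx = []
        for ch in channels:
            if ch not in names:
                raise ChannelError(
                    f"channel {ch!r} not in {path.name}; available: {names}"
                )
            idx.append(names.index(ch))
        events = events[:, idx]
        names = list(channels)
    if sample_id is None:
        sample_id = path.stem
    s = SampleSet(sample_id, group_id, events)
    s.marker_names = names  # caller may build the panel from the first file
    return s


def read_multiset(manifest_path: str | os.PathLike,
                  group_map: Mapping | None = None,
                  channels: Sequence[str] | None = None) -> MultiSet:
    """Assemble a MultiSet from a manifest of CSV and/or FCS files.

    File paths in the manifest are resolved relative to the manifest's
    directory.  All files must share one marker panel (CSV headers are
    re-aligned to the first file's column order).
    """
    manifest_path = Path(manifest_path)
    table = read_manifest(manifest_path)
    ids, mapping = map_group_labels(list(table["group"]), group_map)
    base = manifest_path.parent
    panel: MarkerPanel | None = None
    samples: list[SampleSet] = []
    for (_, row), gid in zip(table.iterrows(), ids):
        fpath = base / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(f"manifest entry not found: {fpath}")
        if fpath.suffix.lower() == ".fcs":
            s = read_fcs(fpath, channels=channels,
                         sample_id=str(row["sample_id"]), group_id=gid)
            if panel is None:
                panel = MarkerPanel(tuple(s.marker_names))
            elif tuple(s.marker_names) != panel.names:
                raise PanelMismatchError(
                    f"{fpath}: channels {s.marker_names} do not match panel "
                    f"{list(panel.names)}"
                )
        else:
            s = read_csv_sample(fpath, str(row["sample_id"]), gid, panel=panel)
            if panel is None:
                panel = MarkerPanel(tuple(pd.read_csv(fpath, nrows=0).columns))
        samples.append(s)
    assert panel is not None
    return MultiSet(panel, samples, meta={"group_labels": mapping})


# manifest-of-CSVs is the common path; keep the explicit name as an alias
read_csv_multiset = read_multiset


def write_multiset_csv(ms: MultiSet, outdir: str | os.PathLike,
                       model=None, float_format: str = "%.10g") -> Path:
    """Write one CSV per sample plus a manifest and optional model sidecar.

    Returns the manifest path.  ``model`` may be a fitted
    :class:`~msflow.preprocess.PreprocessModel`; its parameters are then
    written next to the data as ``preprocess_model.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ms.samples:
        fname = f"{s.sample_id}_g{s.group_id}.csv"
        frame = pd.DataFrame(s.data, columns=list(ms.panel.names))
        frame.to_csv(outdir / fname, index=False, float_format=float_format)
        rows.append({"file": fname, "sample_id": s.sample_id,
                     "group": s.group_id})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if model is not None:
        with open(outdir / "preprocess_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
    return manifest
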