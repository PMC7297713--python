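"""Multi-set container for multicolor flow cytometry (MFC) data.

An MFC experiment yields one cell x marker matrix per biological sample
(rows are measured cells, "events"; columns are fluorescence markers).
When the same marker panel is measured across all samples, the matrices
can be linked column-wise into a *multi-set* structure: an ordered
collection of per-sample blocks, each tagged with a sample id and a group
label (``0`` is reserved for the control/reference group, ``>= 1`` for
responder groups).  All preprocessing, decomposition and evaluation code
in this package operates on :class:`MultiSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPanel",
    "SampleSet",
    "MultiSet",
    "PanelMismatchError",
    "ChannelError",
    "concatenate",
    "split",
    "replicate_sample",
    "summarize",
]


class PanelMismatchError(ValueError):
    """Raised when per-sample matrices do not share one marker panel."""


class ChannelError(KeyError):
    """Raised when a requested marker/channel does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, unique marker names shared by every sample of a multi-set."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 1:
            raise ValueError("a marker panel needs at least one marker")
        if len(set(names)) != len(names):
            raise ValueError(f"marker names must be unique, got {names}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ChannelError(
                f"marker {name!r} not in panel; available: {list(self.names)}"
            ) from None

    def indices(self, names: Sequence[str]) -> list[int]:
        return [self.index(n) for n in names]


@dataclass
class SampleSet:
    """One sample: an ``N_i x J`` matrix of cell-level marker intensities.

    Parameters
    ----------
    sample_id : str
        Identifier of the biological sample.  In paired designs the same
        id may recur under different group ids.
    group_id : int
        Nonnegative group label; ``0`` denotes the control group.
    data : ndarray
        ``(n_cells, n_markers)`` float matrix.  Non-finite entries are a
        hard error: location/scale statistics would be silently corrupted
        by NaN/inf propagation, so nothing is imputed.
    """

    sample_id: str
    group_id: int
    data: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id)
        self.group_id = int(self.group_id)
        if self.group_id < 0:
            raise ValueError(f"group_id must be >= 0, got {self.group_id}")
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(
                f"sample {self.sample_id!r}: data must be 2-D (cells x markers), "
                f"got shape {data.shape}"
            )
        if data.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id!r}: needs at least one cell")
        if self.validate and not np.isfinite(data).all():
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"sample {self.sample_id!r}: non-finite value at cell {bad[0]}, "
                f"marker column {bad[1]}"
            )
        self.data = data

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def key(self) -> tuple[str, int]:
        return (self.sample_id, self.group_id)


class MultiSet:
    """Ordered collection of :class:`SampleSet` sharing one marker panel."""

    def __init__(self, panel: MarkerPanel, samples: Sequence[SampleSet],
                 meta: dict | None = None):
        samples = list(samples)
        if not samples:
            raise ValueError("a MultiSet needs at least one sample")
        j = len(panel)
        for s in samples:
            if s.data.shape[1] != j:
                raise PanelMismatchError(
                    f"sample {s.sample_id!r} has {s.data.shape[1]} columns, "
                    f"panel has {j} markers"
                )
        keys = [s.key for s in samples]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValueError(f"duplicate (sample_id, group_id) pair {dup}")
        self.panel = panel
        self.samples = samples
        self.meta = dict(meta or {})

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleSet]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> SampleSet:
        return self.samples[i]

    # -- derived views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([s.n_cells for s in self.samples], dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def group_ids(self) -> np.ndarray:
        return np.array([s.group_id for s in self.samples], dtype=np.int64)

    @property
    def paired(self) -> bool:
        """True when a sample_id recurs across different groups (paired design)."""
        ids = self.sample_ids
        return len(set(ids)) != len(ids)

    @property
    def controls(self) -> list[SampleSet]:
        return [s for s in self.samples if s.group_id == 0]

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    # -- constructive helpers -------------------------------------------
    def with_blocks(self, blocks: Sequence[np.ndarray], validate: bool = False
                    ) -> "MultiSet":
        """New MultiSet with the same labels but replaced data blocks."""
        if len(blocks) != len(self.samples):
            raise ValueError("need one block per sample")
        samples = [
            SampleSet(s.sample_id, s.group_id, b, validate=validate)
            for s, b in zip(self.samples, blocks)
        ]
        return MultiSet(self.panel, samples, meta=self.meta)

    def subset(self, indices: Sequence[int]) -> "MultiSet":
        """New MultiSet containing the selected samples (order preserved)."""
        return MultiSet(self.panel, [self.samples[i] for i in indices],
                        meta=self.meta)

    def relabel(self, group_ids: Sequence[int]) -> "MultiSet":
        """New MultiSet with replaced group labels (data shared, not copied)."""
        if len(group_ids) != len(self.samples):
            raise ValueError("need one group id per sample")
        samples = [
            SampleSet(s.sample_id, g, s.data, validate=False)
            for s, g in zip(self.samples, group_ids)
        ]
        return MultiSet(self.panel, samples, meta=self.meta)


def concatenate(ms: MultiSet) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack all sample blocks row-wise into one ``(sum N_i) x J`` matrix.

    Returns the matrix together with a per-row index mapping each row to
    its ``(sample_id, group_id)``; block order follows sample order.
    """
    x = np.vstack([s.data for s in ms.samples])
    index = pd.DataFrame(
        {
            "sample_id": np.repeat(ms.sample_ids, ms.n_cells),
            "group_id": np.repeat(ms.group_ids, ms.n_cells),
        }
    )
    return x, index


def split(x: np.ndarray, index: pd.DataFrame, panel: MarkerPanel) -> MultiSet:
    """Inverse of :func:`concatenate`: rebuild a MultiSet from matrix + index."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != len(index):
        raise ValueError("matrix rows and index length differ")
    samples = []
    keys = list(zip(index["sample_id"], index["group_id"]))
    start = 0
    while start < len(keys):
        key = keys[start]
        stop = start
        while stop < len(keys) and keys[stop] == key:
            stop += 1
        samples.append(SampleSet(key[0], int(key[1]), x[start:stop]))
        start = stop
    return MultiSet(panel, samples)


def replicate_sample(ms: MultiSet, index: int, factor: int) -> MultiSet:
    """Duplicate every cell of one sample ``factor`` times.

    Used to probe how preprocessing reacts when one sample carries many
    more cells than the others while its cell-level distribution is
    unchanged (sample-weighted statistics must be invariant; pooled ones
    are not).
    """
    if factor < 1:
        raise ValueError(f"replication factor must be >= 1, got {factor}")
    blocks = [s.data for s in ms.samples]
    blocks[index] = np.tile(blocks[index], (int(factor), 1))
    return ms.with_blocks(blocks)


def summarize(ms: MultiSet, markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample table of cell count, group and raw per-marker mean/sd."""
    if markers is None:
        markers = list(ms.panel)
    else:
        markers = list(markers)
        if not markers:
            raise ValueError("marker subset must not be empty")
    cols = ms.panel.indices(markers)
    rows = []
    for s in ms.samples:
        row: dict = {"sample_id": s.sample_id, "group_id": s.group_id,
                     "n_cells": s.n_cells}
        sub = s.data[:, cols]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=0)
        for m, mu, sd in zip(markers, means, sds):
            row[f"mean_{m}"] = mu
            row[f"sd_{m}"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
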