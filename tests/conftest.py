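"""Shared fixtures: small hand-built multi-sets and a synthetic FCS writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from msflow.datamodel import MarkerPanel, MultiSet, SampleSet


def make_multiset(blocks, groups=None, ids=None, names=None) -> MultiSet:
    """Build a MultiSet from a list of 2-D arrays."""
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    j = blocks[0].shape[1]
    if groups is None:
        groups = [0] * len(blocks)
    if ids is None:
        ids = [f"s{i + 1}" for i in range(len(blocks))]
    if names is None:
        names = [f"M{k + 1}" for k in range(j)]
    panel = MarkerPanel(tuple(names))
    return MultiSet(panel, [SampleSet(i, g, b)
                            for i, g, b in zip(ids, groups, blocks)])


def random_multiset(rng, n_samples=3, n_markers=4, max_cells=10,
                    n_controls=1) -> MultiSet:
    """Random small MultiSet for oracle/property tests."""
    blocks, groups = [], []
    for i in range(n_samples):
        n = int(rng.integers(2, max_cells + 1))
        blocks.append(rng.normal(rng.normal(0, 2, n_markers),
                                 rng.uniform(0.5, 3, n_markers),
                                 size=(n, n_markers)))
        groups.append(0 if i < n_controls else 1)
    return make_multiset(blocks, groups)


def write_synthetic_fcs(path, data, short_names, long_names=None,
                        version="FCS3.0", datatype="F", big_endian=False):
    """Write a minimal synthetic list-mode FCS file (test fixture only).

    This writer exists solely to produce parseable fixtures at test
    time; FCS writing is not part of the package.
    """
    data = np.asarray(data)
    n_tot, n_par = data.shape
    endian = ">" if big_endian else "<"
    byteord = "4,3,2,1" if big_endian else "1,2,3,4"
    if datatype == "F":
        payload = data.astype(endian + "f4").tobytes()
        bits = 32
    elif datatype == "D":
        payload = data.astype(endian + "f8").tobytes()
        bits = 64
    elif datatype == "I":
        payload = data.astype(endian + "u2").tobytes()
        bits = 16
    else:
        raise ValueError(datatype)

    d = "/"
    kw = {
        "$MODE": "L",
        "$DATATYPE": datatype,
        "$BYTEORD": byteord,
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
        "$BEGINDATA": "%08d" % 0,   # fixed width, filled below
        "$ENDDATA": "%08d" % 0,
    }
    for i in range(n_par):
        kw[f"$P{i + 1}N"] = short_names[i]
        kw[f"$P{i + 1}B"] = str(bits)
        kw[f"$P{i + 1}E"] = "0,0"
        kw[f"$P{i + 1}R"] = "262144"
        if long_names is not None and long_names[i] is not None:
            kw[f"$P{i + 1}S"] = long_names[i]

    def render(begin, end):
        kw["$BEGINDATA"] = "%08d" % begin
        kw["$ENDDATA"] = "%08d" % end
        return (d + d.join(f"{k}{d}{v}" for k, v in kw.items()) + d).encode()

    text_begin = 58
    text = render(0, 0)
    data_begin = text_begin + len(text)
    data_end = data_begin + len(payload) - 1
    text = render(data_begin, data_end)
    assert text_begin + len(text) == data_begin

    header = version.ljust(10).encode()
    header += b"%8d%8d" % (text_begin, text_begin + len(text) - 1)
    header += b"%8d%8d" % (data_begin, data_end)
    header += b"%8d%8d" % (0, 0)  # no ANALYSIS segment
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header + text + payload)
    return path


@pytest.fixture
def two_sample_ms() -> MultiSet:
    """Two 2-marker samples with very unequal cell counts.

    Sample means are (1, 1) with 10 cells and (3, 3) with 1000 cells, so
    the pooled grand mean is (10*1 + 1000*3)/1010 = 2.980198... while the
    sample-weighted mean is exactly (2, 2).
    """
    rng = np.random.default_rng(42)
    a = rng.normal(0, 0.5, size=(10, 2))
    a = a - a.mean(axis=0) + 1.0          # exact mean (1, 1)
    b = rng.normal(0, 0.5, size=(1000, 2))
    b = b - b.mean(axis=0) + 3.0          # exact mean (3, 3)
    return make_multiset([a, b], groups=[0, 1])


@pytest.fixture
def small_cohort() -> MultiSet:
    """4 controls + 4 responders, 40 cells each, 3 markers, fixed seed."""
    rng = np.random.default_rng(7)
    blocks = []
    for i in range(8):
        mean = np.array([0.0, -1.0, 1.0]) if i < 4 else np.array([0.0, 1.0, -1.0])
        blocks.append(rng.normal(mean, [1.0, 2.0, 0.5], size=(40, 3)))
    return make_multiset(blocks, groups=[0] * 4 + [1] * 4)
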