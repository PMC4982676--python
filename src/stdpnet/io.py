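"""Plain-text serialization for all package artifacts.

Formats are whitespace-delimited text with a small ``#``-prefixed header so
every artifact survives a read/write round trip bitwise (floats are printed
with 17 significant digits).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .motifs import MotifCoefficientTable
from .network import ConnectivityState
from .score import ScoreResult
from .simulation import SpikeRecord

__all__ = [
    "write_connectivity", "read_connectivity",
    "write_spike_record", "read_spike_record",
    "write_coefficient_table", "read_coefficient_table",
    "write_score_report",
    "write_function_table", "read_function_table",
    "write_correlogram_long",
]

FMT = "%.17g"


class ParseError(ValueError):
    def __init__(self, path, line_no, msg):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


def _header_fields(path, expected_keys):
    """Parse '# key=value ...' from the first line."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ParseError(path, 1, "missing header line")
    out = {}
    for tok in first[1:].split():
        if "=" not in tok:
            raise ParseError(path, 1, f"malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    for k in expected_keys:
        if k not in out:
            raise ParseError(path, 1, f"header missing key {k!r}")
    return out


def write_connectivity(path: str, state: ConnectivityState) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N={state.n} w_max={FMT % state.w_max}\n")
        np.savetxt(fh, state.W_ex, fmt=FMT)


def read_connectivity(path: str) -> ConnectivityState:
    hdr = _header_fields(path, ("N", "w_max"))
    W = np.loadtxt(path, comments="#", ndmin=2)
    n = int(hdr["N"])
    if W.shape != (n, n):
        raise ParseError(path, 2, f"expected {n}x{n} matrix, got {W.shape}")
    return ConnectivityState(W, float(hdr["w_max"]))


def write_spike_record(path: str, record: SpikeRecord) -> None:
    times, ids = record.merged()
    with open(path, "w") as fh:
        fh.write(f"# N={record.n} duration={FMT % record.duration} "
                 f"dt={FMT % record.dt} seed={record.seed}\n")
        for t, k in zip(times, ids):
            fh.write(f"{k:d} {FMT % t}\n")


def read_spike_record(path: str) -> SpikeRecord:
    hdr = _header_fields(path, ("N", "duration", "dt", "seed"))
    n = int(hdr["N"])
    ids, times = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(path, line_no, "expected 'neuron_index time_s'")
            ids.append(int(parts[0]))
            times.append(float(parts[1]))
    ids = np.asarray(ids, dtype=np.int64)
    times = np.asarray(times, dtype=float)
    spikes = [np.sort(times[ids == k]) for k in range(n)]
    return SpikeRecord(spikes=spikes, duration=float(hdr["duration"]),
                       dt=float(hdr["dt"]), seed=int(hdr["seed"]))


def write_coefficient_table(path: str, table: MotifCoefficientTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# f0={FMT % table.f0} provenance={table.provenance}\n")
        fh.write("# alpha beta f_value\n")
        for (a, b), f in sorted(table.coeffs.items()):
            fh.write(f"{a:d} {b:d} {FMT % f}\n")


def read_coefficient_table(path: str) -> MotifCoefficientTable:
    hdr = _header_fields(path, ("f0", "provenance"))
    coeffs: Dict[Tuple[int, int], float] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(path, line_no, "expected 'alpha beta f_value'")
            coeffs[(int(parts[0]), int(parts[1]))] = float(parts[2])
    return MotifCoefficientTable(f0=float(hdr["f0"]), coeffs=coeffs,
                                 provenance=hdr["provenance"])


def write_score_report(path: str, result: ScoreResult) -> None:
    with open(path, "w") as fh:
        fh.write(f"score: {FMT % result.score}\n")
        fh.write(f"best_k: {result.best_k}\n")
        fh.write(f"mode: {result.mode}\n")
        fh.write(f"degenerate: {result.degenerate}\n")
        fh.write("labels: " + " ".join(str(int(x)) for x in result.labels) + "\n")
        fh.write("ordering: " + " ".join(str(int(x)) for x in result.ordering) + "\n")


def write_function_table(path: str, t: np.ndarray, values: np.ndarray) -> None:
    """Two-column export (time_s, value) of a tabulated kernel/window."""
    with open(path, "w") as fh:
        fh.write("# time_s value\n")
        np.savetxt(fh, np.column_stack([t, values]), fmt=FMT)


def read_function_table(path: str):
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise ParseError(path, 2, "expected two columns (time_s, value)")
    return data[:, 0], data[:, 1]


def write_correlogram_long(path: str, tau: np.ndarray, values: np.ndarray) -> None:
    """Long-format export: one line (i, j, tau_s, value) per grid point."""
    n = values.shape[0]
    with open(path, "w") as fh:
        fh.write("# i j tau_s value\n")
        for i in range(n):
            for j in range(n):
                for m, t in enumerate(tau):
                    fh.write(f"{i:d} {j:d} {FMT % t} {FMT % values[i, j, m]}\n")
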