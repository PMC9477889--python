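"""On-disk formats and the run configuration.

Supported inputs: benchmark-style MAT-files (a continuous trace in ``data``
plus optional ``spike_times``/``spike_class`` ground truth; both the v5 and
the v7.3/HDF5 dialects), delimited text waveform matrices (CSV/TSV
autodetected, one spike per row), and JSON for configurations and sort
results. Spike times in files are 1-based sample indices; everything in
memory is 0-based. Some benchmark releases store spike times in ms rather
than samples, so the reader takes a units flag (default: samples).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import h5py
import numpy as np
import scipy.io

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import SortResult

from .detection import SpikeWaveformMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingBundle",
    "RunConfig",
    "read_waveclus_dataset",
    "write_waveclus_dataset",
    "read_waveform_matrix",
    "write_waveform_matrix",
    "write_sort_result",
    "read_sort_result",
]


@dataclass
class RecordingBundle:
    """A continuous voltage trace with optional ground truth.

    ``gt_times`` are 0-based sample indices, strictly increasing;
    ``gt_labels`` are integer unit ids (0 conventionally marks
    overlap/noise events and is excluded from accuracy scoring).
    """

    trace: np.ndarray
    fs: float
    gt_times: np.ndarray | None = None
    gt_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.gt_times is not None:
            self.gt_times = np.asarray(self.gt_times).ravel()
            if self.gt_times.size > 1 and not np.all(np.diff(self.gt_times) > 0):
                raise ValueError("ground-truth times must be strictly increasing")
        if self.gt_labels is not None:
            self.gt_labels = np.asarray(self.gt_labels, dtype=int).ravel()
            if self.gt_times is None or len(self.gt_times) != len(self.gt_labels):
                nt = None if self.gt_times is None else len(self.gt_times)
                raise ValueError(
                    f"ground-truth lengths differ: {nt} times vs {len(self.gt_labels)} labels"
                )


@dataclass
class RunConfig:
    """All tunable parameters of the sorter, with study defaults.

    K_init : initial (over-split) cluster count; 4 suits sparse electrodes.
    d : feature subspace dimension.
    t : cutoff-distance index for density peaks (rule of thumb 0.01–0.02).
    alpha : merge-threshold coefficient (> 1.4 by rule of thumb).
    min_ite/max_ite : iteration bounds of the LDA↔DP loop.
    convergence : matched label agreement at which the loop stops.
    band : detection band-pass in Hz; thresh_mult : threshold multiplier.
    wave_len : samples per waveform; peak_index : 1-based alignment sample
    (stored 1-based to match the conventional description; use
    ``peak_index0`` internally).
    match_tol_ms : ground-truth matching tolerance.
    """

    K_init: int = 4
    d: int = 3
    t: float = 0.015
    alpha: float = 1.6
    min_ite: int = 5
    max_ite: int = 50
    convergence: float = 0.99
    band: tuple[float, float] = (300.0, 3000.0)
    thresh_mult: float = 4.0
    wave_len: int = 64
    peak_index: int = 20
    refractory_ms: float = 1.0
    match_tol_ms: float = 0.3

    def __post_init__(self) -> None:
        if not (0.01 <= self.t <= 0.02):
            warnings.warn(
                f"cutoff index t={self.t} outside the usual 0.01–0.02 range", stacklevel=2
            )
        if self.alpha <= 1:
            raise ValueError(f"alpha must exceed 1, got {self.alpha}")
        if self.min_ite > self.max_ite:
            raise ValueError("min_ite must not exceed max_ite")
        if not (1 <= self.peak_index <= self.wave_len):
            raise ValueError("peak_index must lie in [1, wave_len]")
        self.band = tuple(self.band)

    @property
    def peak_index0(self) -> int:
        """0-based alignment column."""
        return self.peak_index - 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _first_numeric(obj) -> np.ndarray:
    """Unwrap MATLAB cell/object nesting down to a numeric array."""
    arr = np.asarray(obj)
    while arr.dtype == object:
        arr = np.asarray(arr.ravel()[0])
    return arr


def read_waveclus_dataset(
    path: str | Path,
    fs: float | None = None,
    time_units: str = "samples",
) -> RecordingBundle:
    """Read a benchmark MAT-file with fields ``data`` (continuous trace),
    optional ``spike_times`` and ``spike_class``.

    ``fs`` overrides/supplies the sampling rate (falls back to an ``sr``
    field, then to 24 kHz with a log message). ``time_units`` is "samples"
    (default) or "ms", covering both release conventions; file times are
    1-based and converted to 0-based sample indices.
    """
    path = Path(path)
    try:
        mat = scipy.io.loadmat(path, squeeze_me=True)
    except (NotImplementedError, ValueError):  # v7.3 / plain-HDF5 dialects
        mat = {}
        with h5py.File(path, "r") as f:
            for key in f.keys():
                mat[key] = np.asarray(f[key])
    if "data" not in mat:
        raise ValueError(f"{path}: missing required field 'data'")
    trace = _first_numeric(mat["data"]).ravel().astype(float)

    if fs is None:
        if "sr" in mat:
            fs = float(_first_numeric(mat["sr"]).ravel()[0])
        else:
            fs = 24000.0
            logger.info("no sampling rate in %s; assuming %g Hz", path.name, fs)

    gt_times = gt_labels = None
    if "spike_times" in mat:
        raw = _first_numeric(mat["spike_times"]).ravel().astype(float)
        if time_units == "ms":
            gt_times = np.round(raw * 1e-3 * fs).astype(int)
        elif time_units == "samples":
            gt_times = raw.astype(int) - 1  # file convention is 1-based
        else:
            raise ValueError(f"unknown time_units {time_units!r}")
        logger.info("interpreting spike_times as %s", time_units)
    if "spike_class" in mat:
        gt_labels = _first_numeric(mat["spike_class"]).ravel().astype(int)
    return RecordingBundle(trace=trace, fs=fs, gt_times=gt_times, gt_labels=gt_labels)


def write_waveclus_dataset(bundle: RecordingBundle, path: str | Path) -> None:
    """Write a RecordingBundle as a v5 MAT-file (inverse of the reader,
    with 1-based sample times)."""
    out = {"data": bundle.trace, "sr": bundle.fs}
    if bundle.gt_times is not None:
        out["spike_times"] = np.asarray(bundle.gt_times) + 1
    if bundle.gt_labels is not None:
        out["spike_class"] = bundle.gt_labels
    scipy.io.savemat(str(path), out)


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def read_waveform_matrix(path: str | Path, fs: float = 24000.0, peak_index: int = 19) -> SpikeWaveformMatrix:
    """Read a delimited text file of one spike waveform per row."""
    path = Path(path)
    rows: list[list[float]] = []
    delim: str | None = None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = line.split(delim) if delim else line.split()
            try:
                row = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value at row {lineno}") from exc
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {lineno} has {len(row)} columns, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no spikes")
    return SpikeWaveformMatrix(waves=np.array(rows), fs=fs, peak_index=peak_index)


def write_waveform_matrix(waves: np.ndarray | SpikeWaveformMatrix, path: str | Path) -> None:
    """Write a waveform matrix as CSV (one spike per row)."""
    arr = waves.waves if isinstance(waves, SpikeWaveformMatrix) else np.atleast_2d(waves)
    np.savetxt(path, arr, delimiter=",", fmt="%.9g")


def write_sort_result(result: "SortResult", path: str | Path) -> None:
    """Serialize a sort result to JSON: per-spike labels in input order,
    cluster count, iteration/convergence info, merge history, and the
    configuration echo."""
    report = result.merge_report
    doc = {
        "n_clusters": int(result.n_clusters),
        "labels": [int(v) for v in result.labels],
        "pre_merge_labels": [int(v) for v in result.pre_merge_labels],
        "iterations": int(result.iterations),
        "converged": bool(result.converged),
        "agreement_trace": [float(a) for a in result.agreement_trace],
        "merge_report": {
            "final_K": int(report.final_K),
            "merges": [[int(a), int(b), int(r)] for a, b, r in report.merges],
            "Rth_history": [float(v) for v in report.Rth_history],
            "R_history": [
                [[None if not np.isfinite(v) else float(v) for v in row] for row in R]
                for R in report.R_history
            ],
        },
        "config": asdict(result.config),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_sort_result(path: str | Path) -> dict:
    """Read back a sort-result JSON file as a dict with arrays restored."""
    doc = json.loads(Path(path).read_text())
    doc["labels"] = np.asarray(doc["labels"], dtype=int)
    doc["pre_merge_labels"] = np.asarray(doc["pre_merge_labels"], dtype=int)
    return doc
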