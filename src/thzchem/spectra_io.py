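"""Spectral data model and plain-text dataset I/O.

Conventions
-----------
Frequencies are in THz throughout.  The default acquisition grid covers the
half-open interval (0.3, 3.0] THz at 5 GHz (0.005 THz) resolution, which gives
exactly 540 points: 0.305, 0.310, ..., 3.000.  The half-open convention is what
lets a "0.3-3.0 THz" band and a 540-feature vector coexist.

Absorbance is defined base-10 from the magnitude ratio of the reference and
sample field spectra, A(f) = log10 |R(f)| - log10 |S(f)|, the usual chemometric
convention: reference compensation is a subtraction in the log domain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "TimeTrace",
    "Spectrum",
    "Composition",
    "SampleRecord",
    "SpectraDataset",
    "default_grid",
    "timetrace_to_absorbance",
    "read_dataset",
    "write_dataset",
]

#: number of points of the default acquisition grid
DEFAULT_N_POINTS = 540
#: default spectral resolution, THz (5 GHz)
DEFAULT_RESOLUTION = 0.005
#: default band, THz, half-open (low, high]
DEFAULT_BAND = (0.3, 3.0)

COMPOSITION_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform, strictly increasing frequency axis in THz."""

    frequencies: np.ndarray
    resolution: float

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("grid needs at least two frequencies")
        steps = np.diff(freqs)
        if np.any(steps <= 0):
            raise ValueError("grid frequencies must be strictly increasing")
        if not np.allclose(steps, self.resolution, rtol=0, atol=1e-12):
            raise ValueError("grid spacing must be uniform and equal to resolution")

    def __len__(self) -> int:
        return self.frequencies.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyGrid)
            and self.resolution == other.resolution
            and self.frequencies.shape == other.frequencies.shape
            and bool(np.array_equal(self.frequencies, other.frequencies))
        )


def default_grid(
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    resolution: float = DEFAULT_RESOLUTION,
) -> FrequencyGrid:
    """Build the half-open grid (low, high] at the given resolution.

    With the defaults this is the 540-point acquisition grid, first point
    0.305 THz, last point 3.000 THz.
    """
    n = int(round((high - low) / resolution))
    freqs = low + resolution * np.arange(1, n + 1)
    return FrequencyGrid(frequencies=freqs, resolution=resolution)


@dataclass(frozen=True)
class TimeTrace:
    """Field amplitude versus optical delay; ``sampling_step`` in picoseconds."""

    samples: np.ndarray
    sampling_step: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1:
            raise ValueError("time trace must be one-dimensional")
        if not np.all(np.isfinite(s)):
            raise ValueError("time trace contains non-finite samples")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")


@dataclass(frozen=True)
class Spectrum:
    """Absorbance values (arbitrary units), one per grid point."""

    grid: FrequencyGrid
    absorbance: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.shape != (len(self.grid),):
            raise ValueError(
                f"absorbance length {a.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")


@dataclass(frozen=True)
class Composition:
    """Mass ratios of the three analytes; nonnegative, summing to one.

    Ratios are dimensionless analyte-mass fractions of the total analyte mass
    (the HDPE binder is excluded from the ratio).
    """

    caffeine: float
    quinic_acid: float
    nicotinic_acid: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < -COMPOSITION_TOL) or np.any(vals > 1 + COMPOSITION_TOL):
            raise ValueError(f"mass ratios must lie in [0, 1]: {vals}")
        if abs(vals.sum() - 1.0) > COMPOSITION_TOL:
            raise ValueError(f"mass ratios must sum to 1, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.caffeine, self.quinic_acid, self.nicotinic_acid])

    @property
    def mixture_order(self) -> int:
        """Number of components present: 1 unitary, 2 binary, 3 ternary."""
        return int(np.count_nonzero(self.as_array() > 0))


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    composition: Composition
    replicate_index: int
    spectrum: Spectrum

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValueError("replicate_index starts at 1")

    @property
    def mixture_order(self) -> int:
        return self.composition.mixture_order


@dataclass
class SpectraDataset:
    """A list of replicate spectra sharing one frequency grid."""

    records: list[SampleRecord]
    grid: FrequencyGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.grid is None:
            if not self.records:
                raise ValueError("empty dataset needs an explicit grid")
            self.grid = self.records[0].spectrum.grid
        for rec in self.records:
            if rec.spectrum.grid != self.grid:
                raise ValueError(f"record {rec.sample_id} is on a different grid")
        seen = set()
        for rec in self.records:
            key = (rec.sample_id, rec.replicate_index)
            if key in seen:
                raise ValueError(f"duplicate (sample_id, replicate) {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.sample_id not in seen:
                seen.add(rec.sample_id)
                out.append(rec.sample_id)
        return out

    def absorbance_matrix(self) -> np.ndarray:
        """(n_records, n_features) matrix of absorbances in record order."""
        return np.vstack([rec.spectrum.absorbance for rec in self.records])

    def composition_matrix(self) -> np.ndarray:
        return np.vstack([rec.composition.as_array() for rec in self.records])

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraDataset":
        """Copy of the dataset with absorbances replaced row by row."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.records), len(self.grid)):
            raise ValueError("replacement matrix shape mismatch")
        recs = [
            SampleRecord(
                sample_id=r.sample_id,
                composition=r.composition,
                replicate_index=r.replicate_index,
                spectrum=Spectrum(grid=self.grid, absorbance=row),
            )
            for r, row in zip(self.records, matrix)
        ]
        return SpectraDataset(records=recs, grid=self.grid)

    def subset(self, indices) -> "SpectraDataset":
        recs = [self.records[i] for i in indices]
        return SpectraDataset(records=recs, grid=self.grid)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # centered window, truncated at the edges (each point averages the
    # samples of the window that actually fall inside the trace)
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _field_magnitude(trace: TimeTrace, freqs_thz: np.ndarray) -> np.ndarray:
    # discrete-time Fourier transform of the trace, evaluated at the
    # requested frequencies; sampling_step is ps so f*dt is dimensionless
    k = np.arange(trace.samples.size)
    phase = -2j * np.pi * np.outer(freqs_thz * trace.sampling_step, k)
    return np.abs(np.exp(phase) @ trace.samples)


def timetrace_to_absorbance(
    sample: TimeTrace,
    reference: TimeTrace,
    grid: FrequencyGrid,
    smoothing_window: int = 2000,
) -> Spectrum:
    """Turn a (sample, reference) pair of time traces into an absorbance spectrum.

    Both traces are smoothed with a centered, edge-truncated moving average of
    ``smoothing_window`` samples, Fourier-transformed, and combined as
    ``A = log10 |R| - log10 |S|`` on the grid frequencies.

    Raises
    ------
    ValueError
        If trace lengths or sampling steps differ, the window is out of range,
        or the reference magnitude vanishes at some grid frequency (the error
        names the first such frequency).
    """
    if sample.samples.size != reference.samples.size:
        raise ValueError(
            f"trace lengths differ: {sample.samples.size} != {reference.samples.size}"
        )
    if sample.sampling_step != reference.sampling_step:
        raise ValueError("sampling steps differ between sample and reference")
    if not (1 <= smoothing_window <= sample.samples.size):
        raise ValueError("smoothing_window must be in [1, trace length]")

    s_sm = TimeTrace(_moving_average(sample.samples, smoothing_window), sample.sampling_step)
    r_sm = TimeTrace(_moving_average(reference.samples, smoothing_window), reference.sampling_step)
    mag_s = _field_magnitude(s_sm, grid.frequencies)
    mag_r = _field_magnitude(r_sm, grid.frequencies)
    zero = np.flatnonzero(mag_r == 0)
    if zero.size:
        raise ValueError(
            f"reference magnitude is zero at {grid.frequencies[zero[0]]:.3f} THz"
        )
    absorb = np.log10(mag_r) - np.log10(mag_s)
    return Spectrum(grid=grid, absorbance=absorb)


# ---------------------------------------------------------------------------
# plain-text dataset layout: one header row of frequencies, then one row per
# record: sample_id, replicate_index, three mass ratios, absorbances.
# Floats are serialized with repr (17 significant digits) so a write->read
# round-trip is bit exact.
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "replicate_index", "caffeine", "quinic_acid", "nicotinic_acid"]


def write_dataset(dataset: SpectraDataset, path) -> None:
    """Write a dataset as CSV (header: meta columns then grid frequencies)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_COLS + [repr(float(f)) for f in dataset.grid.frequencies])
        for rec in dataset.records:
            y = rec.composition
            row = [
                rec.sample_id,
                str(rec.replicate_index),
                repr(float(y.caffeine)),
                repr(float(y.quinic_acid)),
                repr(float(y.nicotinic_acid)),
            ]
            row += [repr(float(v)) for v in rec.spectrum.absorbance]
            writer.writerow(row)


def read_dataset(path) -> SpectraDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises ``ValueError`` on row-length mismatches, non-normalized
    compositions (naming the offending row) or duplicate
    (sample_id, replicate_index) pairs.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header[: len(_META_COLS)] != _META_COLS:
            raise ValueError(f"{path}: unexpected header {header[:5]}")
        freqs = np.array([float(v) for v in header[len(_META_COLS):]])
        if freqs.size < 2:
            raise ValueError(f"{path}: header has no frequency columns")
        # snap the inferred spacing so float noise in the diffs cannot make
        # the reconstructed grid compare unequal to the one written
        resolution = float(np.round(np.median(np.diff(freqs)), 12))
        grid = FrequencyGrid(frequencies=freqs, resolution=resolution)

        records: list[SampleRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_META_COLS) + freqs.size:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_META_COLS) + freqs.size} "
                    f"columns, got {len(row)}"
                )
            ratios = [float(v) for v in row[2:5]]
            if abs(sum(ratios) - 1.0) > COMPOSITION_TOL:
                raise ValueError(
                    f"{path}:{lineno}: mass ratios sum to {sum(ratios)!r}, not 1"
                )
            comp = Composition(*ratios)
            absorb = np.array([float(v) for v in row[5:]])
            records.append(
                SampleRecord(
                    sample_id=row[0],
                    composition=comp,
                    replicate_index=int(row[1]),
                    spectrum=Spectrum(grid=grid, absorbance=absorb),
                )
            )
    return SpectraDataset(records=records, grid=grid)
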