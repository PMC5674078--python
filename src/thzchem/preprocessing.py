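"""Spectral preprocessing: absorbance extraction, band cropping, normalization.

Time-domain THz traces are Fourier-transformed and referenced against the
blank diluting medium to obtain decadic absorbance; the informative band
(20-80 cm^-1 in the canonical configuration) is then cropped and each
spectrum is row-normalized -- standard normal variate (SNV) by default --
before any multivariate modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSpectrumError,
    EmptyBandError,
    GridMismatchError,
    InvalidArgumentError,
    NumericDomainError,
)

#: speed of light expressed so that wavenumber [cm^-1] = frequency [GHz] / C_GHZ_CM
C_GHZ_CM = 29.9792458

NormalizationMethod = Literal["snv", "minmax", "unit_vector", "none"]


@dataclass
class TimeDomainTrace:
    """A sampled THz electric-field pulse.

    Parameters
    ----------
    time:
        Strictly increasing, uniformly sampled time axis in picoseconds.
    amplitude:
        Detector amplitude in arbitrary units, same length as ``time``.
    sample_id:
        Label identifying the measured pellet.
    """

    time: np.ndarray
    amplitude: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.ndim != 1 or self.time.size < 16:
            raise InvalidArgumentError("time axis must be 1-D with >= 16 points")
        if self.time.shape != self.amplitude.shape:
            raise GridMismatchError("time and amplitude lengths differ")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise InvalidArgumentError("time axis must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise InvalidArgumentError("time axis must be uniformly sampled")

    @property
    def dt(self) -> float:
        """Sampling interval in picoseconds."""
        return float(self.time[1] - self.time[0])


@dataclass
class AbsorbanceSpectrum:
    """One sample's absorbance on a wavenumber grid (cm^-1, dimensionless A)."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape:
            raise GridMismatchError("wavenumber and absorbance lengths differ")
        if self.wavenumber.size >= 2 and np.any(np.diff(self.wavenumber) <= 0):
            raise InvalidArgumentError("wavenumber grid must be strictly increasing")


@dataclass
class SpectraMatrix:
    """A stack of absorbance spectra on a shared wavenumber grid.

    Rows align with ``sample_ids``; columns with ``grid``.
    """

    sample_ids: list[str]
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.sample_ids):
            raise GridMismatchError("row count does not match sample_ids")
        if self.values.shape[1] != self.grid.size:
            raise GridMismatchError("column count does not match grid length")

    @classmethod
    def from_spectra(cls, spectra: Iterable[AbsorbanceSpectrum]) -> "SpectraMatrix":
        spectra = list(spectra)
        if not spectra:
            raise InvalidArgumentError("no spectra given")
        grid = spectra[0].wavenumber
        for s in spectra[1:]:
            if s.wavenumber.shape != grid.shape or not np.allclose(s.wavenumber, grid):
                raise GridMismatchError(f"sample {s.sample_id!r} is on a different grid")
        return cls(
            sample_ids=[s.sample_id for s in spectra],
            grid=grid.copy(),
            values=np.vstack([s.absorbance for s in spectra]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.grid)

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with the wavenumber grid as the header row."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraMatrix":
        df = pd.read_csv(path, index_col=0)
        grid = df.columns.to_numpy(dtype=float)
        return cls(sample_ids=[str(i) for i in df.index], grid=grid, values=df.to_numpy(float))


def compute_absorbance(
    sample: TimeDomainTrace,
    reference: TimeDomainTrace,
    *,
    window: Literal["none", "hann"] = "none",
    zero_pad_factor: int = 1,
    convention: Literal["power", "amplitude"] = "power",
) -> AbsorbanceSpectrum:
    """Decadic absorbance from a sample/reference pair of time traces.

    The traces are (optionally Hann-windowed and zero-padded) discrete-Fourier
    transformed; the absorbance is ``A = -2 log10 |S/R|`` under the default
    power convention (``-log10`` under the amplitude convention), on a
    wavenumber axis derived from the sampling interval.

    Raises
    ------
    GridMismatchError
        If the two traces are not on the same time axis.
    NumericDomainError
        If the reference amplitude spectrum vanishes at a retained point.
    """
    if sample.time.shape != reference.time.shape or not np.allclose(
        sample.time, reference.time
    ):
        raise GridMismatchError("sample and reference traces must share the time axis")
    if zero_pad_factor < 1:
        raise InvalidArgumentError("zero_pad_factor must be >= 1")

    n = sample.time.size
    w = np.hanning(n) if window == "hann" else np.ones(n)
    n_fft = n * int(zero_pad_factor)
    s = np.abs(np.fft.rfft(sample.amplitude * w, n=n_fft))
    r = np.abs(np.fft.rfft(reference.amplitude * w, n=n_fft))

    dt_s = sample.dt * 1e-12  # ps -> s
    freq_ghz = np.fft.rfftfreq(n_fft, d=dt_s) * 1e-9
    wavenumber = freq_ghz / C_GHZ_CM

    if np.any(r == 0.0):
        raise NumericDomainError("reference amplitude spectrum is zero at a grid point")
    factor = 2.0 if convention == "power" else 1.0
    absorbance = -factor * np.log10(s / r)
    return AbsorbanceSpectrum(wavenumber, absorbance, sample.sample_id)


def crop_band(spec: AbsorbanceSpectrum, lo: float, hi: float) -> AbsorbanceSpectrum:
    """Retain exactly the grid points with ``lo <= nu <= hi`` (closed interval)."""
    if not lo < hi:
        raise InvalidArgumentError("crop bounds require lo < hi")
    mask = (spec.wavenumber >= lo) & (spec.wavenumber <= hi)
    if not mask.any():
        raise EmptyBandError(f"no grid points in [{lo}, {hi}] cm^-1")
    return AbsorbanceSpectrum(spec.wavenumber[mask], spec.absorbance[mask], spec.sample_id)


def crop_matrix(m: SpectraMatrix, lo: float, hi: float) -> SpectraMatrix:
    """Band-crop every row of a spectra matrix (closed interval on the grid)."""
    if not lo < hi:
        raise InvalidArgumentError("crop bounds require lo < hi")
    mask = (m.grid >= lo) & (m.grid <= hi)
    if not mask.any():
        raise EmptyBandError(f"no grid points in [{lo}, {hi}] cm^-1")
    return SpectraMatrix(m.sample_ids, m.grid[mask], m.values[:, mask])


def snv(row: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0, scale to sample sd 1 (n-1)."""
    x = np.asarray(row, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidArgumentError("SNV requires a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSpectrumError("zero-variance spectrum cannot be SNV-normalized")
    return (x - x.mean()) / sd


def normalize_matrix(m: SpectraMatrix, method: NormalizationMethod = "snv") -> SpectraMatrix:
    """Row-wise normalization of a spectra matrix.

    ``snv`` centers and scales each row to unit sample sd; ``minmax`` maps each
    row onto [0, 1]; ``unit_vector`` scales each row to Euclidean norm 1;
    ``none`` returns the input unchanged.
    """
    if method == "none":
        return m
    out = np.empty_like(m.values)
    for i, row in enumerate(m.values):
        if method == "snv":
            out[i] = snv(row)
        elif method == "minmax":
            lo, hi = row.min(), row.max()
            if hi == lo:
                raise DegenerateSpectrumError("constant row cannot be min-max scaled")
            out[i] = (row - lo) / (hi - lo)
        elif method == "unit_vector":
            norm = np.linalg.norm(row)
            if norm == 0.0:
                raise DegenerateSpectrumError("zero row cannot be scaled to unit norm")
            out[i] = row / norm
        else:
            raise InvalidArgumentError(f"unknown normalization method {method!r}")
    return SpectraMatrix(m.sample_ids, m.grid.copy(), out)


def read_trace_csv(path: str | Path, sample_id: str | None = None) -> TimeDomainTrace:
    """Read a two-column (time_ps, amplitude) CSV into a trace."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidArgumentError("trace CSV must have two columns (time, amplitude)")
    sid = sample_id if sample_id is not None else Path(path).stem
    return TimeDomainTrace(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), sid)
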