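"""Synthetic descriptor tables and THz absorbance spectra.

The measured benzothiazine dataset is not publicly deposited, so this module
generates datasets carrying the same statistical structure the downstream
analysis relies on:

* a descriptor table (MP, PSA, logP, HBD, HBA, Mr, ROTB, AROMS) whose
  covariance is dominated by melting point and molecular mass, with a
  moderate positive PSA-MP correlation;
* absorbance spectra that are sums of a few Gaussian lattice-vibration bands
  on a shared wavenumber grid, with the dominant band center tied to the
  melting point through a configurable latent link;
* frequency-dependent multiplicative noise whose relative standard deviation
  is small at low wavenumbers and grows toward the band edge, suppressed by
  the square root of the number of coherently averaged acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .preprocessing import AbsorbanceSpectrum, SpectraMatrix

DESCRIPTOR_COLUMNS = ["MP", "PSA", "logP", "HBD", "HBA", "Mr", "ROTB", "AROMS"]

# Descriptor marginals. Only the ordering of spreads matters for the pipeline:
# MP and Mr must dominate the covariance by >= 10x in standard deviation.
_MP_MEAN, _MP_STD = 150.0, 40.0      # degC
_MR_MEAN, _MR_STD = 420.0, 60.0      # g/mol
_PSA_MEAN, _PSA_STD = 108.0, 4.0     # A^2
_PSA_MP_RHO = 0.46
_LOGP_MEAN, _LOGP_STD = 3.1, 0.45

# Affine melting-point -> dominant-peak-center link (cm^-1 per degC); maps
# MP within +-2 sd onto roughly the central 75% of the 20-80 cm^-1 band.
_CENTER_INTERCEPT = 10.5
_CENTER_SLOPE = 0.28
_CENTER_JITTER_STD = 20.0  # cm^-1, fully applied at mp_link_strength = 0


@dataclass
class SimConfig:
    """Generator configuration.

    Attributes
    ----------
    n_samples:
        Number of compounds to simulate.
    grid_min, grid_max, n_points:
        Shared wavenumber grid in cm^-1 (defaults 20-80 cm^-1, 1137 points).
    peaks_per_sample:
        Inclusive (min, max) range for the number of Gaussian bands.
    peak_width_range:
        Inclusive (min, max) Gaussian sigma range in cm^-1.
    noise_rel_std_low:
        Relative noise std below ``noise_breakpoint`` at a single acquisition.
    noise_rel_std_high:
        Relative noise std at ``grid_max`` at a single acquisition.
    noise_breakpoint:
        Wavenumber up to which the low noise level applies; the level rises
        linearly from there to ``grid_max``.
    n_averages:
        Number of coherently averaged acquisitions; the applied relative std
        is the configured level divided by sqrt(n_averages).
    seed:
        Base seed for all random draws.
    mp_link_strength:
        In [0, 1]; 1 makes the dominant peak center a deterministic affine
        function of MP, 0 decouples spectra from the melting point.
    """

    n_samples: int = 27
    grid_min: float = 20.0
    grid_max: float = 80.0
    n_points: int = 1137
    peaks_per_sample: tuple[int, int] = (1, 4)
    peak_width_range: tuple[float, float] = (2.0, 6.0)
    noise_rel_std_low: float = 0.05
    noise_rel_std_high: float = 0.30
    noise_breakpoint: float = 50.0
    n_averages: int = 1
    seed: int = 0
    mp_link_strength: float = 0.9

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise InvalidArgumentError("n_samples must be >= 3")
        if self.grid_min >= self.grid_max:
            raise InvalidArgumentError("grid_min must be < grid_max")
        if self.n_points < 2:
            raise InvalidArgumentError("n_points must be >= 2")
        for frac in (self.noise_rel_std_low, self.noise_rel_std_high):
            if not 0.0 <= frac < 1.0:
                raise InvalidArgumentError("relative noise stds must lie in [0, 1)")
        if self.n_averages < 1:
            raise InvalidArgumentError("n_averages must be >= 1")
        if not 0.0 <= self.mp_link_strength <= 1.0:
            raise InvalidArgumentError("mp_link_strength must lie in [0, 1]")
        lo, hi = self.peaks_per_sample
        if lo < 1 or hi < lo:
            raise InvalidArgumentError("peaks_per_sample range invalid")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_points)


@dataclass
class SyntheticDataset:
    """A generated descriptor table plus matched spectra and ground truth."""

    descriptors: pd.DataFrame
    spectra: list[AbsorbanceSpectrum]
    truth: dict[str, dict[str, Any]]
    config: SimConfig

    def spectra_matrix(self) -> SpectraMatrix:
        return SpectraMatrix.from_spectra(self.spectra)


def simulate_descriptors(n_samples: int, seed: int) -> pd.DataFrame:
    """Draw a descriptor table with MP/Mr-dominated covariance.

    MP and Mr are independent wide normals; PSA shares a latent factor with MP
    giving a Pearson correlation of about 0.46; the remaining descriptors are
    small-spread integers or floats in drug-like ranges. Unscaled PCA on the
    result concentrates essentially all variance in two components.
    """
    if n_samples < 3:
        raise InvalidArgumentError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    z_mp = rng.standard_normal(n_samples)
    z_mr = rng.standard_normal(n_samples)
    z_psa = rng.standard_normal(n_samples)

    mp = _MP_MEAN + _MP_STD * z_mp
    mr = _MR_MEAN + _MR_STD * z_mr
    psa = _PSA_MEAN + _PSA_STD * (
        _PSA_MP_RHO * z_mp + np.sqrt(1.0 - _PSA_MP_RHO**2) * z_psa
    )
    logp = _LOGP_MEAN + _LOGP_STD * rng.standard_normal(n_samples)
    hbd = np.clip(np.rint(1.5 + 0.6 * rng.standard_normal(n_samples)), 0, 5)
    hba = np.clip(np.rint(6.5 + 0.9 * rng.standard_normal(n_samples)), 2, 10)
    rotb = np.clip(np.rint(5.0 + 1.0 * rng.standard_normal(n_samples)), 0, 10)
    aroms = np.clip(np.rint(3.0 + 0.7 * rng.standard_normal(n_samples)), 1, 5)

    ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    return pd.DataFrame(
        {
            "MP": mp,
            "PSA": psa,
            "logP": logp,
            "HBD": hbd,
            "HBA": hba,
            "Mr": mr,
            "ROTB": rotb,
            "AROMS": aroms,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def dominant_peak_center(mp: float, cfg: SimConfig, rng: np.random.Generator) -> float:
    """Dominant band center: affine in MP, jittered by (1 - link strength)."""
    center = _CENTER_INTERCEPT + _CENTER_SLOPE * float(mp)
    center += (1.0 - cfg.mp_link_strength) * _CENTER_JITTER_STD * rng.standard_normal()
    margin = cfg.peak_width_range[1]
    return float(np.clip(center, cfg.grid_min + margin, cfg.grid_max - margin))


def simulate_spectrum(
    descriptor_row: pd.Series, cfg: SimConfig, seed: int
) -> tuple[AbsorbanceSpectrum, dict[str, Any]]:
    """One noiseless absorbance spectrum for a descriptor record.

    The spectrum is a non-negative sum of 1-4 Gaussian bands on the config
    grid. The dominant (highest-amplitude) band center follows the melting
    point through the affine link; secondary bands are placed uniformly.

    Returns the spectrum and a truth record (peak centers, widths,
    amplitudes, and the MP used).
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    lo_n, hi_n = cfg.peaks_per_sample
    n_peaks = int(rng.integers(lo_n, hi_n + 1))
    w_lo, w_hi = cfg.peak_width_range

    mp = float(descriptor_row["MP"])
    centers = np.empty(n_peaks)
    widths = rng.uniform(w_lo, w_hi, size=n_peaks)
    amplitudes = np.empty(n_peaks)
    centers[0] = dominant_peak_center(mp, cfg, rng)
    amplitudes[0] = rng.uniform(0.7, 1.0)
    if n_peaks > 1:
        margin = w_hi
        centers[1:] = rng.uniform(cfg.grid_min + margin, cfg.grid_max - margin, n_peaks - 1)
        amplitudes[1:] = rng.uniform(0.15, 0.5, n_peaks - 1)

    absorbance = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, amplitudes):
        absorbance += a * np.exp(-0.5 * ((grid - c) / w) ** 2)

    sid = str(descriptor_row.name) if descriptor_row.name is not None else ""
    truth = {
        "MP": mp,
        "centers": centers.tolist(),
        "widths": widths.tolist(),
        "amplitudes": amplitudes.tolist(),
        "dominant_center": float(centers[0]),
    }
    return AbsorbanceSpectrum(grid, absorbance, sid), truth


def noise_rel_std(wavenumber: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Single-acquisition relative noise std sigma(nu), piecewise linear.

    Constant at ``noise_rel_std_low`` up to the breakpoint, rising linearly to
    ``noise_rel_std_high`` at the grid maximum.
    """
    nu = np.asarray(wavenumber, dtype=float)
    sigma = np.full_like(nu, cfg.noise_rel_std_low)
    span = cfg.grid_max - cfg.noise_breakpoint
    if span > 0:
        above = nu > cfg.noise_breakpoint
        frac = (nu[above] - cfg.noise_breakpoint) / span
        sigma[above] = cfg.noise_rel_std_low + frac * (
            cfg.noise_rel_std_high - cfg.noise_rel_std_low
        )
    return sigma


def add_noise(spectrum: AbsorbanceSpectrum, cfg: SimConfig, seed: int) -> AbsorbanceSpectrum:
    """Apply multiplicative Gaussian noise with std sigma(nu)/sqrt(n_averages)."""
    sigma = noise_rel_std(spectrum.wavenumber, cfg) / np.sqrt(cfg.n_averages)
    rng = np.random.default_rng(seed)
    noisy = spectrum.absorbance * (1.0 + sigma * rng.standard_normal(spectrum.absorbance.size))
    return AbsorbanceSpectrum(spectrum.wavenumber.copy(), noisy, spectrum.sample_id)


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate a full matched dataset: descriptors, noisy spectra, truth.

    Seeds for each sample are derived deterministically from ``cfg.seed`` via
    a SeedSequence spawn, so the whole dataset is bit-reproducible.
    """
    descriptors = simulate_descriptors(cfg.n_samples, cfg.seed)
    # independent child seeds: one per sample for the lineshape, one for noise
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_samples)
    spectra: list[AbsorbanceSpectrum] = []
    truth: dict[str, dict[str, Any]] = {}
    for i, (sid, row) in enumerate(descriptors.iterrows()):
        shape_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        noise_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        clean, rec = simulate_spectrum(row, cfg, shape_seed)
        spectra.append(add_noise(clean, cfg, noise_seed))
        truth[str(sid)] = rec
    return SyntheticDataset(descriptors, spectra, truth, cfg)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write descriptors.csv, spectra.csv and truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "descriptors": out / "descriptors.csv",
        "spectra": out / "spectra.csv",
        "truth": out / "truth.json",
    }
    ds.descriptors.to_csv(paths["descriptors"], float_format="%.10g")
    ds.spectra_matrix().to_csv(paths["spectra"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return paths
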