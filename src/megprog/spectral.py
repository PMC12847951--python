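"""Welch spectra and parameterization into aperiodic + periodic components.

A region power spectrum is modeled in log10 power as an aperiodic power law

    log10 P(f) = offset - exponent * log10(f)

plus up to ``max_n_peaks`` Gaussian oscillatory peaks, each described by a
center frequency (CF, Hz), power above the aperiodic component (PW, log10
units) and bandwidth (BW = 2 standard deviations, Hz).  The aperiodic fit is
robust (two-pass, peak-dominated bins excluded via a residual percentile
threshold); peaks are detected iteratively on the flattened spectrum, then
jointly refit by bounded least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "PowerSpectrum",
    "RegionTimeSeries",
    "FitSettings",
    "SpectralPeak",
    "SpectralFit",
    "BandFeature",
    "BANDS",
    "n_welch_segments",
    "welch_psd",
    "fit_aperiodic",
    "SpectralModel",
    "fit_spectral_model",
    "extract_band_peak",
    "parameterize_cohort",
]

#: analysis band definitions in Hz (upper beta bound 30 Hz; the 35 Hz
#: extension is a visualization choice only)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "extended_alpha": (4.0, 12.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class RegionTimeSeries:
    subject_id: str
    timepoint: str
    region_label: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 2 * 47.0:
            raise ValueError("sampling rate must exceed twice the 47 Hz analysis band")


@dataclass(frozen=True)
class PowerSpectrum:
    """Linear power spectral density on a strictly increasing frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or freqs.shape != power.shape:
            raise ValueError("freqs and power must be matching 1-d arrays")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(power <= 0) or not np.all(np.isfinite(power)):
            raise ValueError("power values must be positive and finite")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class FitSettings:
    """Parameterization settings (defaults as used for the cohort analysis)."""

    max_n_peaks: int = 6
    peak_threshold: float = 2.0  # in SD of the flattened spectrum
    min_peak_height: float = 0.15  # log10 power
    peak_width_limits: tuple[float, float] = (1.0, 10.0)  # BW bounds, Hz
    fit_range: tuple[float, float] = (1.0, 47.0)
    aperiodic_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.peak_width_limits[0] >= self.peak_width_limits[1]:
            raise ValueError("peak_width_limits must be (low, high) with low < high")
        if self.max_n_peaks < 0:
            raise ValueError("max_n_peaks must be >= 0")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the fixed (no-knee) aperiodic mode is supported")


@dataclass(frozen=True)
class SpectralPeak:
    cf: float  # center frequency, Hz
    pw: float  # power above aperiodic, log10 units
    bw: float  # bandwidth = 2 SD, Hz


@dataclass(frozen=True)
class SpectralFit:
    offset: float
    exponent: float
    peaks: tuple[SpectralPeak, ...]
    r_squared: float
    freqs: np.ndarray
    flattened: np.ndarray  # log10 residual spectrum after aperiodic removal

    def model_log_psd(self, freqs: np.ndarray | None = None) -> np.ndarray:
        freqs = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        out = self.offset - self.exponent * np.log10(freqs)
        for p in self.peaks:
            out = out + p.pw * np.exp(-0.5 * ((freqs - p.cf) / (p.bw / 2.0)) ** 2)
        return out


@dataclass(frozen=True)
class BandFeature:
    band: str
    peak_freq: float | None
    peak_power: float | None


def n_welch_segments(duration_s: float, segment_s: float = 5.0,
                     overlap_frac: float = 0.5) -> int:
    """Number of averaged segments for the given duration and overlap."""
    step = segment_s * (1.0 - overlap_frac)
    return int(np.floor((duration_s - segment_s) / step)) + 1


def welch_psd(
    ts: RegionTimeSeries | np.ndarray,
    fs: float | None = None,
    segment_s: float = 5.0,
    overlap_frac: float = 0.5,
    fit_range: tuple[float, float] = (1.0, 47.0),
) -> PowerSpectrum:
    """Welch PSD with Hann window and mean-detrended segments.

    The grid resolution is ``1/segment_s`` Hz; output is truncated to
    ``fit_range``.
    """
    if isinstance(ts, RegionTimeSeries):
        samples, fs = ts.samples, ts.fs
    else:
        samples = np.asarray(ts, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw sample array")
    nperseg = int(round(segment_s * fs))
    if samples.size < nperseg:
        raise ValueError(
            f"input too short: need at least {segment_s:g} s "
            f"({nperseg} samples at fs={fs:g}), got {samples.size} samples"
        )
    freqs, power = signal.welch(
        samples, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)), detrend="constant",
    )
    lo, hi = fit_range
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return PowerSpectrum(freqs=freqs[mask], power=np.maximum(power[mask], 1e-300))


def _aperiodic_ols(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(log_f, log_p, 1)
    return float(intercept), float(-slope)


def fit_aperiodic(psd: PowerSpectrum, robust: bool = True,
                  percentile: float = 2.5) -> tuple[float, float]:
    """Fit ``log10 P = offset - exponent * log10 f``; two-pass by default.

    The second pass excludes bins whose positive residual from the first-pass
    line exceeds the given percentile of positive residuals — these are the
    peak-dominated bins that would otherwise flatten the estimated slope.
    """
    if psd.freqs.size < 10:
        raise ValueError("need at least 10 frequency bins for an aperiodic fit")
    log_f = np.log10(psd.freqs)
    log_p = np.log10(psd.power)
    offset, exponent = _aperiodic_ols(log_f, log_p)
    if not robust:
        return offset, exponent
    resid = log_p - (offset - exponent * log_f)
    resid_pos = np.clip(resid, 0.0, None)
    thresh = np.percentile(resid_pos, percentile)
    mask = resid_pos <= thresh
    if mask.sum() >= 2:
        offset, exponent = _aperiodic_ols(log_f[mask], log_p[mask])
    return offset, exponent


def _gaussians(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        cf, height, sd = params[i : i + 3]
        out = out + height * np.exp(-0.5 * ((freqs - cf) / sd) ** 2)
    return out


class SpectralModel(BaseEstimator):
    """Parameterize one power spectrum into aperiodic and periodic parts.

    Parameters follow :class:`FitSettings`.  After :meth:`fit`, the fitted
    attributes are ``offset_``, ``exponent_``, ``peaks_`` (tuple of
    :class:`SpectralPeak`), ``r_squared_`` and ``flattened_``.
    """

    def __init__(
        self,
        max_n_peaks: int = 6,
        peak_threshold: float = 2.0,
        min_peak_height: float = 0.15,
        peak_width_limits: tuple[float, float] = (1.0, 10.0),
        fit_range: tuple[float, float] = (1.0, 47.0),
        aperiodic_mode: str = "fixed",
    ):
        self.max_n_peaks = max_n_peaks
        self.peak_threshold = peak_threshold
        self.min_peak_height = min_peak_height
        self.peak_width_limits = peak_width_limits
        self.fit_range = fit_range
        self.aperiodic_mode = aperiodic_mode

    # -- internal helpers -------------------------------------------------
    def _settings(self) -> FitSettings:
        return FitSettings(
            max_n_peaks=self.max_n_peaks,
            peak_threshold=self.peak_threshold,
            min_peak_height=self.min_peak_height,
            peak_width_limits=tuple(self.peak_width_limits),
            fit_range=tuple(self.fit_range),
            aperiodic_mode=self.aperiodic_mode,
        )

    def _guess_peaks(self, freqs: np.ndarray, flat: np.ndarray,
                     settings: FitSettings) -> list[tuple[float, float, float]]:
        sd_lo = settings.peak_width_limits[0] / 2.0
        sd_hi = settings.peak_width_limits[1] / 2.0
        work = flat.copy()
        guesses: list[tuple[float, float, float]] = []
        for _ in range(settings.max_n_peaks):
            idx = int(np.argmax(work))  # ties resolve toward lower frequency
            height = work[idx]
            thresh = max(settings.min_peak_height,
                         settings.peak_threshold * np.std(work))
            if height < thresh:
                break
            cf = freqs[idx]
            # width guess from half-height crossing distance
            half = height / 2.0
            right = idx
            while right + 1 < work.size and work[right + 1] > half:
                right += 1
            left = idx
            while left - 1 >= 0 and work[left - 1] > half:
                left -= 1
            fwhm = max(freqs[min(right + 1, work.size - 1)] - freqs[max(left - 1, 0)],
                       freqs[1] - freqs[0])
            sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
            guesses.append((float(cf), float(height), sd))
            work = work - height * np.exp(-0.5 * ((freqs - cf) / sd) ** 2)
        return guesses

    def _joint_refit(self, freqs: np.ndarray, flat: np.ndarray,
                     guesses: list[tuple[float, float, float]],
                     settings: FitSettings) -> list[tuple[float, float, float]]:
        if not guesses:
            return []
        sd_lo = settings.peak_width_limits[0] / 2.0
        sd_hi = settings.peak_width_limits[1] / 2.0
        p0, lower, upper = [], [], []
        for cf, height, sd in guesses:
            bw = 2.0 * sd
            p0.extend([cf, height, sd])
            lower.extend([max(cf - 2.0 * bw, freqs[0]), 0.0, sd_lo])
            upper.extend([min(cf + 2.0 * bw, freqs[-1]), np.inf, sd_hi])
        try:
            popt, _ = curve_fit(
                _gaussians, freqs, flat, p0=p0, bounds=(lower, upper),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            popt = np.asarray(p0)
        return [tuple(popt[i : i + 3]) for i in range(0, len(popt), 3)]

    def _polish(self, freqs: np.ndarray, log_p: np.ndarray, offset: float,
                exponent: float, peaks: list[tuple[float, float, float]],
                settings: FitSettings):
        """Simultaneous bounded least squares over aperiodic + all peaks."""
        if not peaks:
            return offset, exponent, peaks
        sd_lo = settings.peak_width_limits[0] / 2.0
        sd_hi = settings.peak_width_limits[1] / 2.0
        p0 = [offset, max(exponent, 0.0)]
        lower = [-np.inf, 0.0]
        upper = [np.inf, np.inf]
        for cf, height, sd in peaks:
            bw = 2.0 * np.clip(sd, sd_lo, sd_hi)
            p0.extend([np.clip(cf, freqs[0], freqs[-1]),
                       max(height, 0.0), np.clip(sd, sd_lo, sd_hi)])
            lower.extend([max(cf - 2.0 * bw, freqs[0]), 0.0, sd_lo])
            upper.extend([min(cf + 2.0 * bw, freqs[-1]), np.inf, sd_hi])

        def model(f, off, exp, *pk):
            return off - exp * np.log10(f) + _gaussians(f, *pk)

        try:
            popt, _ = curve_fit(model, freqs, log_p, p0=p0,
                                bounds=(lower, upper), maxfev=10000,
                                xtol=1e-12, ftol=1e-12)
        except (RuntimeError, ValueError):
            popt = np.asarray(p0)
        new_peaks = [tuple(popt[i: i + 3]) for i in range(2, len(popt), 3)]
        return float(popt[0]), float(popt[1]), new_peaks

    # -- sklearn-style API -------------------------------------------------
    def fit(self, psd: PowerSpectrum, y: None = None) -> "SpectralModel":
        settings = self._settings()
        lo, hi = settings.fit_range
        if psd.freqs[0] > lo + 1e-9 or psd.freqs[-1] < hi - 1e-9:
            raise ValueError(
                f"spectrum support [{psd.freqs[0]:g}, {psd.freqs[-1]:g}] Hz does "
                f"not cover fit range [{lo:g}, {hi:g}] Hz"
            )
        mask = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
        freqs = psd.freqs[mask]
        log_p = np.log10(psd.power[mask])
        sub = PowerSpectrum(freqs=freqs, power=psd.power[mask])

        offset, exponent = fit_aperiodic(sub)
        flat = log_p - (offset - exponent * np.log10(freqs))

        guesses = self._guess_peaks(freqs, flat, settings)
        peaks = self._joint_refit(freqs, flat, guesses, settings)

        # polish aperiodic and peaks simultaneously: the reported parameters
        # are a least-squares optimum of the full model, so refitting a model
        # reconstruction reproduces them
        log_f = np.log10(freqs)
        peak_model = _gaussians(freqs, *np.ravel(peaks)) if peaks else 0.0
        offset, exponent = _aperiodic_ols(log_f, log_p - peak_model)
        offset, exponent, peaks = self._polish(
            freqs, log_p, offset, exponent, peaks, settings
        )
        peaks = [p for p in peaks if p[1] >= settings.min_peak_height]
        if peaks:
            # re-polish without the sub-threshold peaks
            offset, exponent, peaks = self._polish(
                freqs, log_p, offset, exponent, peaks, settings
            )
        else:
            offset, exponent = fit_aperiodic(sub)
        peak_model = _gaussians(freqs, *np.ravel(peaks)) if peaks else 0.0
        exponent = max(exponent, 0.0)

        aperiodic = offset - exponent * np.log10(freqs)
        model = aperiodic + (peak_model if peaks else 0.0)
        ss_res = float(np.sum((log_p - model) ** 2))
        ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
        self.offset_ = float(offset)
        self.exponent_ = float(exponent)
        self.peaks_ = tuple(
            SpectralPeak(cf=float(cf), pw=float(h), bw=float(2.0 * sd))
            for cf, h, sd in sorted(peaks, key=lambda p: p[0])
        )
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.freqs_ = freqs
        self.flattened_ = log_p - aperiodic
        return self

    def result_(self) -> SpectralFit:
        return SpectralFit(
            offset=self.offset_, exponent=self.exponent_, peaks=self.peaks_,
            r_squared=self.r_squared_, freqs=self.freqs_, flattened=self.flattened_,
        )


def fit_spectral_model(psd: PowerSpectrum,
                       settings: FitSettings | None = None) -> SpectralFit:
    """Functional wrapper over :class:`SpectralModel`."""
    settings = settings or FitSettings()
    model = SpectralModel(
        max_n_peaks=settings.max_n_peaks,
        peak_threshold=settings.peak_threshold,
        min_peak_height=settings.min_peak_height,
        peak_width_limits=settings.peak_width_limits,
        fit_range=settings.fit_range,
        aperiodic_mode=settings.aperiodic_mode,
    )
    return model.fit(psd).result_()


def extract_band_peak(fit: SpectralFit, band: str) -> BandFeature:
    """Highest-power fitted peak with center frequency inside *band*."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    candidates = [p for p in fit.peaks if lo <= p.cf <= hi]
    if not candidates:
        return BandFeature(band=band, peak_freq=None, peak_power=None)
    best = max(candidates, key=lambda p: p.pw)
    return BandFeature(band=band, peak_freq=best.cf, peak_power=best.pw)


def parameterize_cohort(
    spectra: pd.DataFrame,
    settings: FitSettings | None = None,
    bands: Sequence[str] = ("extended_alpha", "beta"),
) -> pd.DataFrame:
    """Parameterize a wide spectra table into a per-region feature table.

    *spectra* must have ``subject_id``, ``timepoint``, ``region_label``
    columns followed by ``f_<freq>`` power columns.  Returns one row per
    spectrum with offset, exponent, r_squared and per-band
    ``peak_<band>_freq`` / ``peak_<band>_power`` (NaN when no peak).
    """
    settings = settings or FitSettings()
    freq_cols = [c for c in spectra.columns if c.startswith("f_")]
    if not freq_cols:
        raise ValueError("spectra table has no f_<freq> power columns")
    freqs = np.array([float(c[2:]) for c in freq_cols])
    order = np.argsort(freqs)
    freqs = freqs[order]
    freq_cols = [freq_cols[i] for i in order]

    band_alias = {"extended_alpha": "alpha"}  # feature-name shorthand
    power_matrix = spectra[freq_cols].to_numpy(dtype=float)
    meta = spectra[["subject_id", "timepoint", "region_label"]].to_numpy()
    rows = []
    for (subject_id, timepoint, region_label), power in zip(meta, power_matrix):
        fit = fit_spectral_model(PowerSpectrum(freqs=freqs, power=power), settings)
        row = {
            "subject_id": subject_id,
            "timepoint": timepoint,
            "region_label": region_label,
            "offset": fit.offset,
            "exponent": fit.exponent,
            "r_squared": fit.r_squared,
        }
        for band in bands:
            feat = extract_band_peak(fit, band)
            name = band_alias.get(band, band)
            row[f"peak_{name}_freq"] = np.nan if feat.peak_freq is None else feat.peak_freq
            row[f"peak_{name}_power"] = np.nan if feat.peak_power is None else feat.peak_power
        rows.append(row)
    return pd.DataFrame(rows)
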