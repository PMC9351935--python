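"""Realistic fMRI simulation: task signal, structured noise, and matching.

The simulator builds a 4-D volume as a linear combination of noise sources
inspired by MRI physics and physiology:

* a per-voxel baseline intensity,
* low-frequency scanner drift (a cosine set below 1/128 Hz),
* temporally autocorrelated (AR(1)) physiological/neural fluctuations with
  a spatially coherent component,
* sinusoidal respiratory/cardiac components (aliased onto the TR grid),
* spatially smoothed system noise,
* white machine noise, which also fills the out-of-mask background.

Because the mapping from component amplitudes to *measured* summary
statistics (SFNR, lag-1 autocorrelation) is indirect, generation runs a
small fixed-point loop: generate, measure with :func:`measure_noise`,
rescale the component amplitudes multiplicatively, repeat until measured
SFNR and AR(1) are within 5% relative error of the requested profile (or
the iteration budget is exhausted, with a warning). Each component draws
from its own named random stream derived from the user seed, so the loop's
adjustments reuse identical innovations and the output is reproducible
bit-for-bit for a given seed.

Task signal is specified as a BIDS-style events table (onset, duration,
trial_type, amplitude), expanded to an upsampled boxcar, convolved with a
double-gamma haemodynamic response function, and inserted into an ROI as a
percent-signal-change modulation of the local baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .core import DegenerateDataWarning, SubjectTimeSeries, ValidationError, VolumeGeometry

__all__ = [
    "NoiseProfile",
    "StimTimecourse",
    "DesignTable",
    "generate_stimfunction",
    "convolve_hrf",
    "double_gamma_hrf",
    "generate_noise",
    "measure_noise",
    "apply_signal",
    "volume_to_timeseries",
]

DRIFT_CUTOFF_HZ = 1.0 / 128.0


@dataclass
class NoiseProfile:
    """Summary statistics that define (or describe) a noise simulation.

    sfnr
        Temporal signal-to-fluctuation-noise ratio: voxel mean divided by
        the temporal sd of the detrended series, averaged in-mask.
    snr
        Spatial signal-to-noise: in-mask mean intensity over the spatial sd
        of the out-of-mask background at the middle timepoint.
    ar_rho
        Lag-1 autocorrelation of the detrended in-mask average time series.
    drift_sd_pct
        Amplitude of the low-frequency drift as a percentage of the mean.
    physio_freqs_hz
        Sinusoidal physiological components (defaults: respiratory ~0.2 Hz,
        cardiac ~1.17 Hz); frequencies above Nyquist alias implicitly.
    spatial_fwhm_mm
        FWHM of the spatially smoothed system-noise component.
    baseline
        Mean in-mask intensity.
    """

    sfnr: float = 70.0
    snr: float = 100.0
    ar_rho: float = 0.45
    drift_sd_pct: float = 1.0
    physio_freqs_hz: list[float] = field(default_factory=lambda: [0.2, 1.17])
    spatial_fwhm_mm: float = 4.0
    baseline: float = 1000.0

    def __post_init__(self) -> None:
        if self.sfnr <= 0 or self.snr <= 0 or self.baseline <= 0:
            raise ValidationError("sfnr, snr and baseline must be positive")
        if not -1 < self.ar_rho < 1:
            raise ValidationError("ar_rho must lie in (-1, 1)")
        if self.drift_sd_pct < 0 or self.spatial_fwhm_mm < 0:
            raise ValidationError("drift_sd_pct and spatial_fwhm_mm must be >= 0")


@dataclass
class StimTimecourse:
    values: np.ndarray
    upsample_factor: int
    tr_seconds: float


@dataclass
class DesignTable:
    """Event design: rows of (onset_seconds, duration_seconds, condition,
    amplitude); serializes to/from a BIDS-style events TSV."""

    events: pd.DataFrame

    COLUMNS = ("onset", "duration", "trial_type", "amplitude")

    def __post_init__(self) -> None:
        df = self.events
        missing = [c for c in ("onset", "duration", "trial_type") if c not in df]
        if missing:
            raise ValidationError(f"design table missing columns {missing}")
        if "amplitude" not in df:
            df = df.assign(amplitude=1.0)
        if (df["onset"] < 0).any():
            raise ValidationError("onsets must be non-negative")
        if (df["duration"] <= 0).any():
            raise ValidationError("durations must be positive")
        self.events = df[list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str) -> "DesignTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.events["trial_type"].unique())


def generate_stimfunction(
    design: DesignTable,
    total_time_s: float,
    tr_seconds: float,
    upsample_factor: int = 10,
) -> dict[str, StimTimecourse]:
    """Expand the event table into one upsampled boxcar per condition.

    Sample i covers time [i*dt, (i+1)*dt) with dt = tr/upsample; an event
    contributes its amplitude on [onset, onset+duration). Overlapping events
    of the same condition sum, with a warning.
    """
    if upsample_factor < 1:
        raise ValidationError("upsample_factor must be >= 1")
    n_tr = int(np.ceil(total_time_s / tr_seconds))
    n = n_tr * upsample_factor
    dt = tr_seconds / upsample_factor
    if (design.events["onset"] >= total_time_s).any():
        raise ValidationError("event onset beyond scan end")
    out: dict[str, StimTimecourse] = {}
    for cond in design.conditions:
        rows = design.events[design.events["trial_type"] == cond]
        tc = np.zeros(n)
        for _, r in rows.iterrows():
            lo = int(np.ceil(r["onset"] / dt - 1e-9))
            hi = min(int(np.ceil((r["onset"] + r["duration"]) / dt - 1e-9)), n)
            tc[lo:hi] += r["amplitude"]
        if (tc > rows["amplitude"].max() + 1e-12).any():
            warnings.warn(
                f"overlapping events in condition {cond!r}: amplitudes summed",
                DegenerateDataWarning,
                stacklevel=2,
            )
        out[cond] = StimTimecourse(tc, upsample_factor, tr_seconds)
    return out


def double_gamma_hrf(
    dt: float,
    response_shape: float = 6.0,
    response_dispersion: float = 0.9,
    undershoot_shape: float = 12.0,
    undershoot_dispersion: float = 0.9,
    undershoot_ratio: float = 0.35,
    duration_s: float = 30.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt`` seconds,
    normalized to peak 1. The positive lobe peaks at
    (response_shape - 1) * response_dispersion seconds (4.5 s by default).
    """
    t = np.arange(0, duration_s, dt)

    def gamma_density(a: float, b: float) -> np.ndarray:
        return t ** (a - 1) * np.exp(-t / b) / (b**a * special.gamma(a))

    h = gamma_density(response_shape, response_dispersion) - (
        undershoot_ratio * gamma_density(undershoot_shape, undershoot_dispersion)
    )
    return h / h.max()


def convolve_hrf(stim: StimTimecourse, **hrf_params) -> np.ndarray:
    """Convolve an upsampled stimulus boxcar with the double-gamma HRF and
    downsample to the TR grid by taking the sample at each TR onset."""
    dt = stim.tr_seconds / stim.upsample_factor
    hrf = double_gamma_hrf(dt, **hrf_params)
    full = np.convolve(stim.values, hrf)[: len(stim.values)] * dt
    return full[:: stim.upsample_factor]


# ---------------------------------------------------------------------------
# Noise generation and measurement


def _component_rng(seed: int, component: str) -> np.random.Generator:
    """One named stream per noise component: adding a component never
    perturbs another's draws."""
    ids = {"drift": 1, "ar": 2, "ar_shared": 3, "physio": 4, "spatial": 5, "machine": 6}
    return np.random.default_rng([ids[component], seed])


def _drift_basis(t: int, tr_seconds: float) -> np.ndarray:
    """Cosine set at frequencies k/(2 T tr) below the 1/128 Hz cutoff,
    unit-variance columns; empty (t, 0) if the scan is too short."""
    ks = []
    k = 1
    while k / (2 * t * tr_seconds) < DRIFT_CUTOFF_HZ:
        ks.append(k)
        k += 1
    grid = np.arange(t)
    cols = [np.cos(np.pi * kk * (grid + 0.5) / t) for kk in ks]
    if not cols:
        return np.zeros((t, 0))
    basis = np.stack(cols, axis=1)
    sd = basis.std(axis=0)
    return basis / sd


def _ar1(innov: np.ndarray, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series along axis 0 from unit-variance
    innovations."""
    t = innov.shape[0]
    out = np.empty_like(innov)
    out[0] = innov[0]
    for i in range(1, t):
        out[i] = rho * out[i - 1] + np.sqrt(1 - rho**2) * innov[i]
    return out


def generate_noise(
    geometry: VolumeGeometry,
    t: int,
    tr_seconds: float,
    profile: NoiseProfile | None = None,
    fit_iterations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Generate a 4-D noise volume matching the requested profile.

    See the module docstring for the component inventory and the iterative
    amplitude-fitting scheme. Identical seeds give bit-identical volumes.
    """
    if profile is None:
        profile = NoiseProfile()
    if t < 10:
        raise ValidationError("need T >= 10")
    dims = geometry.dims
    mask = geometry.mask
    v = geometry.n_voxels

    # fixed innovations per component (regenerated identically each pass)
    drift_rng = _component_rng(seed, "drift")
    ar_rng = _component_rng(seed, "ar")
    shared_rng = _component_rng(seed, "ar_shared")
    physio_rng = _component_rng(seed, "physio")
    spatial_rng = _component_rng(seed, "spatial")
    machine_rng = _component_rng(seed, "machine")

    basis = _drift_basis(t, tr_seconds)
    # drift is spatially coherent: one low-frequency course, per-voxel gain
    # jittered around 1 so it neither cancels in the global average nor is
    # perfectly uniform
    drift_course = drift_rng.standard_normal(basis.shape[1])
    drift_gain = 1.0 + 0.2 * drift_rng.standard_normal(v)
    ar_innov = ar_rng.standard_normal((t, v))
    shared_innov = shared_rng.standard_normal(t)
    physio_phases = physio_rng.uniform(0, 2 * np.pi, size=(len(profile.physio_freqs_hz), v))
    spatial_white = spatial_rng.standard_normal(dims + (t,))
    machine = machine_rng.standard_normal(dims + (t,))

    times = np.arange(t) * tr_seconds
    sigma_machine = profile.baseline / profile.snr
    sigma_total = profile.baseline / profile.sfnr
    sigma_resid2 = sigma_total**2 - sigma_machine**2
    if sigma_resid2 <= 0:
        warnings.warn(
            "requested SFNR implies less temporal noise than the machine "
            "noise floor; structured components set to minimal amplitude",
            DegenerateDataWarning,
            stacklevel=2,
        )
        sigma_resid2 = (0.1 * sigma_total) ** 2
    # variance split of the structured fluctuation: AR 0.8, physio 0.1,
    # smoothed system noise 0.1
    amp_ar = np.sqrt(0.8 * sigma_resid2)
    amp_physio = np.sqrt(0.1 * sigma_resid2 / max(len(profile.physio_freqs_hz), 1))
    amp_spatial = np.sqrt(0.1 * sigma_resid2)
    rho_gen = profile.ar_rho
    drift_amp = profile.drift_sd_pct / 100.0 * profile.baseline

    if profile.spatial_fwhm_mm > 0:
        sig_vox = np.array(
            [profile.spatial_fwhm_mm / 2.3548 / z for z in geometry.voxel_size_mm]
        )
        smoothed = ndimage.gaussian_filter(
            spatial_white, sigma=tuple(sig_vox) + (0.0,), mode="nearest"
        )
        smoothed /= smoothed[mask].std() or 1.0
    else:
        smoothed = spatial_white

    if basis.shape[1]:
        course = basis @ drift_course
        course /= course.std() or 1.0
        drift_series = course[:, None] * drift_gain[None, :]
    else:
        drift_series = np.zeros((t, v))
    physio_mat = np.stack(
        [np.sin(2 * np.pi * f * times) for f in profile.physio_freqs_hz]
    ) if profile.physio_freqs_hz else np.zeros((0, t))

    achieved = None
    vol = None
    for _ in range(max(fit_iterations, 1)):
        ar_part = np.sqrt(0.7) * _ar1(ar_innov, rho_gen) + np.sqrt(0.3) * _ar1(
            shared_innov, rho_gen
        )[:, None]
        physio_part = np.zeros((t, v))
        for j in range(physio_mat.shape[0]):
            physio_part += np.sin(
                2 * np.pi * profile.physio_freqs_hz[j] * times[:, None]
                + physio_phases[j][None, :]
            )
        in_mask = (
            profile.baseline
            + drift_amp * drift_series
            + amp_ar * ar_part
            + amp_physio * physio_part
        )
        vol = sigma_machine * machine.copy()
        vol += amp_spatial * smoothed
        flat = vol.reshape(-1, t, order="F")
        mflat = mask.ravel(order="F")
        flat[mflat] += in_mask.T
        flat[~mflat] += 0.0
        vol = flat.reshape(dims + (t,), order="F")

        achieved = measure_noise(vol, geometry, tr_seconds)
        sfnr_ok = abs(achieved.sfnr - profile.sfnr) <= 0.05 * profile.sfnr
        ar_ok = abs(achieved.ar_rho - profile.ar_rho) <= max(
            0.05 * abs(profile.ar_rho), 0.01
        )
        if sfnr_ok and ar_ok:
            break
        # multiplicative refinement: too-high measured SFNR means too little
        # noise, so amplitudes scale by sfnr_meas / sfnr_target
        scale = np.clip(achieved.sfnr / profile.sfnr, 0.25, 4.0)
        amp_ar *= scale
        amp_physio *= scale
        amp_spatial *= scale
        if profile.ar_rho != 0 and achieved.ar_rho > 1e-6:
            rho_gen = float(
                np.clip(rho_gen * profile.ar_rho / achieved.ar_rho, -0.98, 0.98)
            )
        else:
            rho_gen = float(np.clip(rho_gen + (profile.ar_rho - achieved.ar_rho), -0.98, 0.98))
    else:
        warnings.warn(
            "noise fitting budget exhausted: achieved "
            f"SFNR={achieved.sfnr:.1f} (target {profile.sfnr}), "
            f"AR(1)={achieved.ar_rho:.2f} (target {profile.ar_rho})",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return vol


def _quad_detrend(x: np.ndarray) -> np.ndarray:
    """Remove a per-column quadratic trend from (T, V) or (T,) data."""
    t = x.shape[0]
    grid = np.arange(t)
    design = np.column_stack([np.ones(t), grid, grid**2])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def measure_noise(
    volume: np.ndarray,
    geometry: VolumeGeometry,
    tr_seconds: float,
) -> NoiseProfile:
    """Estimate the noise profile of a 4-D volume.

    SFNR averages voxel mean / temporal sd of the quadratically detrended
    series over the mask; SNR compares the in-mask mean with the spatial sd
    of the out-of-mask background at the middle timepoint (falling back to a
    high-frequency temporal proxy, with a warning, when the mask covers
    everything); AR(1) is the lag-1 autocorrelation of the detrended in-mask
    average; drift is the sd of the low-frequency cosine projection of the
    in-mask average, as % of its mean.
    """
    volume = np.asarray(volume, float)
    if volume.ndim != 4:
        raise ValidationError("volume must be 4-D")
    if volume.shape[:3] != geometry.dims:
        raise ValidationError("volume grid does not match geometry")
    mask = geometry.mask
    t = volume.shape[3]
    if t < 10:
        raise ValidationError("need T >= 10")
    data = volume.reshape(-1, t, order="F")[mask.ravel(order="F")].T  # (T, V)
    baseline = float(data.mean())

    detr = _quad_detrend(data)
    sds = detr.std(axis=0)
    # relative floor: numerically-exact polynomial fits leave ~1e-13 residue
    sds[sds < 1e-10 * (np.abs(data).mean() + 1e-30)] = 0.0
    if (sds == 0).any():
        warnings.warn(
            "time-constant voxel(s): SFNR reported as +inf",
            DegenerateDataWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        sfnr = float(np.mean(np.where(sds > 0, data.mean(axis=0) / np.where(sds == 0, 1, sds), np.inf)))

    mid = t // 2
    out_mask = ~mask
    if out_mask.any():
        bg = volume[..., mid][out_mask]
        snr = float(data[mid].mean() / bg.std()) if bg.std() > 0 else np.inf
    else:
        warnings.warn(
            "mask covers the whole volume: SNR uses a high-frequency "
            "temporal proxy",
            DegenerateDataWarning,
            stacklevel=2,
        )
        hf = np.diff(data, axis=0) / np.sqrt(2)
        snr = float(baseline / hf.std()) if hf.std() > 0 else np.inf

    basis = _drift_basis(t, tr_seconds)
    gavg = data.mean(axis=1)
    # AR(1) of the global average after removing both the quadratic trend
    # and the low-frequency drift set (drift is itself highly autocorrelated
    # and would masquerade as AR noise)
    g = _quad_detrend(gavg)
    if basis.shape[1]:
        coef, *_ = np.linalg.lstsq(basis, g, rcond=None)
        g = g - basis @ coef
    denom = float((g**2).sum())
    ar_rho = float((g[1:] * g[:-1]).sum() / denom) if denom > 0 else 0.0
    if basis.shape[1]:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(t), basis]), gavg, rcond=None
        )
        drift_fit = basis @ coef[1:]
        drift_sd_pct = float(drift_fit.std() / gavg.mean() * 100.0)
    else:
        drift_sd_pct = 0.0

    return NoiseProfile(
        sfnr=sfnr if np.isfinite(sfnr) else np.inf,
        snr=snr if np.isfinite(snr) else np.inf,
        ar_rho=float(np.clip(ar_rho, -0.999, 0.999)),
        drift_sd_pct=max(drift_sd_pct, 0.0),
        physio_freqs_hz=[],
        spatial_fwhm_mm=0.0,
        baseline=baseline,
    )


def apply_signal(
    noise_volume: np.ndarray,
    geometry: VolumeGeometry,
    roi: np.ndarray,
    condition_patterns: dict[str, np.ndarray],
    convolved_timecourses: dict[str, np.ndarray],
    scale_pct_signal_change: float,
) -> np.ndarray:
    """Insert task signal into an ROI of a noise volume.

    For each ROI voxel v and TR t the output adds
    ``scale/100 * baseline_v * sum_c pattern_c[v] * timecourse_c[t]``,
    where baseline_v is the voxel's temporal mean; voxels outside the ROI
    are untouched.
    """
    roi = np.asarray(roi, bool)
    if roi.shape != geometry.dims:
        raise ValidationError("roi grid does not match geometry")
    if (roi & ~geometry.mask).any():
        raise ValidationError("roi extends outside the mask")
    if set(condition_patterns) != set(convolved_timecourses):
        raise ValidationError("patterns and timecourses must cover the same conditions")
    vol = np.array(noise_volume, float, copy=True)
    t = vol.shape[3]
    roi_flat = roi.ravel(order="F")
    flat = vol.reshape(-1, t, order="F")
    series = flat[roi_flat]  # (n_roi, T)
    baseline_v = series.mean(axis=1)
    n_roi = int(roi.sum())
    add = np.zeros((n_roi, t))
    for cond, pattern in condition_patterns.items():
        pattern = np.asarray(pattern, float).ravel()
        tc = np.asarray(convolved_timecourses[cond], float).ravel()
        if pattern.size != n_roi:
            raise ValidationError(f"pattern for {cond!r} must have {n_roi} entries")
        if tc.size != t:
            raise ValidationError(f"timecourse for {cond!r} must have {t} entries")
        add += np.outer(pattern, tc)
    flat[roi_flat] = series + scale_pct_signal_change / 100.0 * baseline_v[:, None] * add
    return flat.reshape(geometry.dims + (t,), order="F")


def volume_to_timeseries(
    volume: np.ndarray, geometry: VolumeGeometry, tr_seconds: float,
    subject_id: str = "sim",
) -> SubjectTimeSeries:
    """Extract the in-mask (T, V) matrix using the package's fixed
    x-fastest voxel ordering."""
    t = volume.shape[3]
    data = volume.reshape(-1, t, order="F")[geometry.mask.ravel(order="F")].T
    return SubjectTimeSeries(data, tr_seconds, subject_id)
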