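"""Auditory spectrogram and the eleven acoustic salience features.

The spectrogram is a constant-Q magnitude envelope representation: an STFT
whose bins are pooled into 128 log-spaced channels (24 per octave, base
90 Hz) at a 125 Hz frame rate.  From it (plus a bark-band stream for
loudness and a 500 Hz short-window envelope stream for fast modulations) the
module computes:

    LD  loudness              mean of 28 bark-band envelopes, 250 Hz - 12 kHz
    P   pitch                 optimum-processor harmonic template match
    H   harmonicity           quality of the best template match
    BR  brightness            power-weighted spectral centroid
    BW  bandwidth             magnitude-weighted mean |f - BR|
    IR  irregularity          sum (dy)^2 / sum y^2 across channels
    FL  flatness              geometric / arithmetic mean of the spectrum
    LR  low-rate energy       temporal modulations, 1-20 Hz
    HR  high-rate energy      temporal modulations, 20-100 Hz
    RC  rate centroid         energy-weighted centroid over 1-32 Hz
    SC  scale centroid        spectral modulations, 0.25-8 cyc/oct

All series are resampled to a 64 ms hop by window-mean pooling and z-scored
per scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

FEATURE_NAMES = ("LD", "P", "H", "BR", "BW", "IR", "FL", "LR", "HR", "RC", "SC")

TARGET_FS = 22_000
FRAME_RATE = 125
HI_FRAME_RATE = 500
HOP_S = 0.064

RATE_CENTERS = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0])
SCALE_CENTERS = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
_GABOR_SIGMA_OCT = 0.55  # log-Gabor spread for modulation filters

_EPS = 1e-12


@dataclass
class AuditorySpectrogram:
    """Nonnegative magnitude envelope y(t, f) on log-spaced channels."""

    y: np.ndarray  # (n_frames, n_channels)
    freqs: np.ndarray  # channel center frequencies, Hz
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.y.shape[0]


@dataclass
class FeatureMatrix:
    """The eleven feature series of one scene at a 64 ms hop."""

    scene_id: str
    data: pd.DataFrame  # columns FEATURE_NAMES
    hop: float = HOP_S
    norm_stats: pd.DataFrame | None = None  # rows mean/sd per feature

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.data)) * self.hop

    @property
    def duration(self) -> float:
        return len(self.data) * self.hop


# ---------------------------------------------------------------------------
# spectrogram front end
# ---------------------------------------------------------------------------


def _stft_magnitude(x: np.ndarray, fs: int, frame_rate: int, win: int):
    """Centered magnitude STFT with one frame per hop, hop = fs / frame_rate."""
    if fs % frame_rate:
        raise ValueError("sample rate must be divisible by the frame rate")
    hop = fs // frame_rate
    n_frames = int(np.ceil(x.size / hop))
    pad = win // 2
    xp = np.pad(x.astype(float), (pad, pad + win))
    frames = np.lib.stride_tricks.sliding_window_view(xp, win)[: n_frames * hop : hop]
    mag = np.abs(np.fft.rfft(frames * np.hanning(win)[None, :], axis=1))
    bin_freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    return mag, bin_freqs


def _log_channel_weights(bin_freqs: np.ndarray, centers: np.ndarray, per_octave: int):
    """Triangular log-frequency pooling weights, one row per channel.

    Rows are normalized to unit sum; a channel too narrow to catch any bin
    falls back to its nearest bin so low channels are never silent.
    """
    with np.errstate(divide="ignore"):
        log_bins = np.log2(np.maximum(bin_freqs, _EPS))
    w = np.maximum(0.0, 1.0 - np.abs(log_bins[None, :] - np.log2(centers)[:, None]) * per_octave)
    w[:, bin_freqs <= 0] = 0.0
    empty = w.sum(axis=1) == 0
    if empty.any():
        nearest = np.argmin(np.abs(bin_freqs[None, :] - centers[empty, None]), axis=1)
        w[np.flatnonzero(empty), nearest] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def _resample_to_target(x: np.ndarray, fs: int) -> np.ndarray:
    if fs == TARGET_FS:
        return np.asarray(x, dtype=float)
    from fractions import Fraction

    frac = Fraction(TARGET_FS, int(fs)).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def auditory_spectrogram(
    x: np.ndarray,
    fs: int = TARGET_FS,
    frame_rate: int = FRAME_RATE,
    n_channels: int = 128,
    per_octave: int = 24,
    f_base: float = 90.0,
    win: int = 2048,
) -> AuditorySpectrogram:
    """Constant-Q log-channel magnitude envelope of a mono waveform.

    Input below 22 kHz sampling is resampled internally; stereo input is
    rejected (average to mono upstream).  The number of frames is
    ``ceil(duration * frame_rate)``.
    """
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D); average channels upstream")
    if x.size == 0:
        raise ValueError("empty waveform")
    if fs < 16_000:
        raise ValueError("sample rate must be at least 16 kHz")
    x = _resample_to_target(x, fs)
    mag, bin_freqs = _stft_magnitude(x, TARGET_FS, frame_rate, win)
    centers = f_base * 2.0 ** (np.arange(n_channels) / per_octave)
    weights = _log_channel_weights(bin_freqs, centers, per_octave)
    return AuditorySpectrogram(y=mag @ weights.T, freqs=centers, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def _bark(f: np.ndarray) -> np.ndarray:
    return 26.81 * f / (1960.0 + f) - 0.53


def loudness(
    x: np.ndarray,
    fs: int = TARGET_FS,
    frame_rate: int = FRAME_RATE,
    n_bands: int = 28,
    f_lo: float = 250.0,
    f_hi: float = 12_000.0,
    log_compress: bool = False,
    win: int = 2048,
    _stft: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean of 28 bark-band envelopes per frame.

    Band centers are equally spaced on the bark axis between ``f_lo`` and
    ``f_hi`` (clipped below Nyquist); envelopes come from the same STFT front
    end as the spectrogram.  Linear averaging by default, with an optional
    log compression of the band envelopes before averaging.
    """
    if _stft is None:
        x = _resample_to_target(np.asarray(x, dtype=float), fs)
        mag, bin_freqs = _stft_magnitude(x, TARGET_FS, frame_rate, win)
    else:
        mag, bin_freqs = _stft
    f_hi = min(f_hi, 0.495 * TARGET_FS)
    z_centers = np.linspace(_bark(np.array([f_lo]))[0], _bark(np.array([f_hi]))[0], n_bands)
    z_bins = _bark(bin_freqs)
    width = z_centers[1] - z_centers[0]
    w = np.maximum(0.0, 1.0 - np.abs(z_bins[None, :] - z_centers[:, None]) / width)
    w[:, bin_freqs <= 0] = 0.0
    w /= np.maximum(w.sum(axis=1, keepdims=True), _EPS)
    env = mag @ w.T  # (n_frames, n_bands)
    if log_compress:
        env = np.log1p(env)
    return env.mean(axis=1)


def _pitch_templates(
    freqs: np.ndarray,
    f0_min: float = 50.0,
    f0_max: float = 800.0,
    steps_per_octave: int = 48,
    n_harmonics: int = 8,
    sigma_oct: float = 1.0 / 24.0,
):
    """Unit-norm harmonic templates on the log-channel axis.

    Harmonic amplitudes decay as 1/h (the usual optimum-processor weighting);
    each partial is a Gaussian on the log-frequency axis matched to the
    channel bandwidth.
    """
    n_steps = int(round(steps_per_octave * np.log2(f0_max / f0_min))) + 1
    f0s = f0_min * 2.0 ** (np.arange(n_steps) / steps_per_octave)
    log_c = np.log2(freqs)
    templates = np.zeros((n_steps, freqs.size))
    for h in range(1, n_harmonics + 1):
        d = log_c[None, :] - np.log2(h * f0s)[:, None]
        templates += (1.0 / h) * np.exp(-(d**2) / (2 * sigma_oct**2))
    templates /= np.maximum(np.linalg.norm(templates, axis=1, keepdims=True), _EPS)
    return f0s, templates


def pitch_harmonicity(
    spec: AuditorySpectrogram,
    f0_min: float = 50.0,
    f0_max: float = 800.0,
    steps_per_octave: int = 48,
    n_harmonics: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame pitch (Hz) and harmonicity by harmonic template matching.

    Each unit-normalized spectral slice is correlated with every template;
    the pitch is the best template's f0 and the harmonicity the maximized
    normalized correlation in [0, 1].  Silent frames keep the previous pitch
    and get harmonicity 0.
    """
    f0s, templates = _pitch_templates(
        spec.freqs, f0_min, f0_max, steps_per_octave, n_harmonics
    )
    norms = np.linalg.norm(spec.y, axis=1)
    valid = norms > _EPS
    slices = spec.y / np.maximum(norms, _EPS)[:, None]
    corr = slices @ templates.T
    best = np.argmax(corr, axis=1)
    pitch = f0s[best]
    harmonicity = corr[np.arange(corr.shape[0]), best]
    harmonicity[~valid] = 0.0
    if not valid.all():
        pitch = pitch.copy()
        last = f0_min
        for i in range(pitch.size):
            if valid[i]:
                last = pitch[i]
            else:
                pitch[i] = last
    return pitch, harmonicity


def spectral_shape(spec: AuditorySpectrogram):
    """Brightness, bandwidth, irregularity and flatness per frame.

    Brightness weights frequencies by power (y^2), bandwidth by magnitude.
    All-zero frames propagate the previous brightness/bandwidth and take
    IR = 0, FL = 1 by convention; a validity mask is returned alongside.
    """
    y = spec.y
    f = spec.freqs
    power = np.square(y)
    mag_sum = y.sum(axis=1)
    pow_sum = power.sum(axis=1)
    valid = mag_sum > _EPS

    br = np.full(y.shape[0], np.nan)
    bw = np.full(y.shape[0], np.nan)
    br[valid] = (power[valid] * f[None, :]).sum(axis=1) / pow_sum[valid]
    bw[valid] = (y[valid] * np.abs(f[None, :] - br[valid][:, None])).sum(axis=1) / mag_sum[valid]

    ir = np.zeros(y.shape[0])
    ir[valid] = np.square(np.diff(y[valid], axis=1)).sum(axis=1) / pow_sum[valid]

    fl = np.ones(y.shape[0])
    ymin = y.min(axis=1)
    amean = y.mean(axis=1)
    safe = valid & (ymin > 0)
    fl[valid & (ymin <= 0)] = 0.0
    fl[safe] = np.exp(np.mean(np.log(y[safe]), axis=1)) / amean[safe]

    # propagate brightness/bandwidth through silent frames
    for arr in (br, bw):
        isnan = np.isnan(arr)
        if isnan.any() and not isnan.all():
            idx = np.where(~isnan, np.arange(arr.size), -1)
            np.maximum.accumulate(idx, out=idx)
            first = np.argmax(~isnan)
            idx[idx < 0] = first
            arr[:] = arr[idx]
        elif isnan.all():
            arr[:] = 0.0
    return br, bw, ir, fl, valid


def _log_gabor(freqs: np.ndarray, center: float, sigma_oct: float = _GABOR_SIGMA_OCT):
    """Magnitude response of a log-Gabor filter; identically zero at DC."""
    h = np.zeros_like(freqs)
    pos = freqs > 0
    h[pos] = np.exp(-(np.log2(freqs[pos] / center) ** 2) / (2 * sigma_oct**2))
    return h


def _analytic_band_energy(x: np.ndarray, rate: float, centers: np.ndarray, sigma_oct: float):
    """|analytic bandpass|^2 of a real series for each filter center."""
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    out = np.empty((centers.size, n))
    for i, c in enumerate(centers):
        full = np.zeros(n, dtype=complex)
        band = spec * _log_gabor(freqs, c)
        full[: band.size] = band
        full[1 : (n + 1) // 2] *= 2.0  # analytic signal: double positive freqs
        z = np.fft.ifft(full)
        out[i] = np.abs(z) ** 2
    return out


@dataclass
class ModulationFeatures:
    lr: np.ndarray
    hr: np.ndarray
    rc: np.ndarray
    sc: np.ndarray
    rate_temporal: float
    rate_spectral: float


def modulation_features(
    spec_hi: AuditorySpectrogram,
    spec_lo: AuditorySpectrogram | None = None,
    rate_centers: np.ndarray = RATE_CENTERS,
    scale_centers: np.ndarray = SCALE_CENTERS,
) -> ModulationFeatures:
    """Temporal (rate) and spectral (scale) modulation features.

    Temporal modulations are measured on the channel-averaged envelope of the
    high-rate stream (coherent averaging across channels before energy, which
    suppresses channel-incoherent stochastic envelope fluctuations while
    preserving scene-wide modulations) through octave-spaced log-Gabor
    filters.  LR/HR are mean band energies over 1-20 / 20-100 Hz; RC is the
    energy-weighted centroid over 1-32 Hz.  Scale filters act on the
    log-frequency axis of each frame of the 125 Hz spectrogram; SC is the
    energy-weighted centroid over 0.25-8 cyc/oct.
    """
    if spec_hi.n_frames / spec_hi.frame_rate < 2.0:
        raise ValueError("scene shorter than 2 s: modulation filters unsupported")
    if spec_hi.frame_rate < 2 * rate_centers.max():
        raise ValueError("high-rate stream frame rate too low for the rate bank")
    env = spec_hi.y.mean(axis=1)
    z = _analytic_band_energy(env, spec_hi.frame_rate, rate_centers, _GABOR_SIGMA_OCT)

    lr_mask = (rate_centers >= 1.0) & (rate_centers <= 20.0)
    hr_mask = (rate_centers >= 20.0) & (rate_centers <= 100.0)
    rc_mask = (rate_centers >= 1.0) & (rate_centers <= 32.0)
    lr = z[lr_mask].mean(axis=0)
    hr = z[hr_mask].mean(axis=0)
    rc_e = z[rc_mask]
    denom = rc_e.sum(axis=0)
    rc = np.where(
        denom > _EPS,
        (rate_centers[rc_mask][:, None] * rc_e).sum(axis=0) / np.maximum(denom, _EPS),
        rate_centers[rc_mask][0],
    )

    sl = spec_lo if spec_lo is not None else spec_hi
    n_ch = sl.y.shape[1]
    ch_per_oct = 1.0 / np.log2(sl.freqs[1] / sl.freqs[0])
    w_spec = np.fft.rfft(sl.y - sl.y.mean(axis=1, keepdims=True), axis=1)
    s_axis = np.fft.rfftfreq(n_ch, d=1.0 / ch_per_oct)
    e_scales = np.stack(
        [
            (np.abs(w_spec) ** 2 * _log_gabor(s_axis, c)[None, :] ** 2).sum(axis=1)
            for c in scale_centers
        ]
    )
    denom_s = e_scales.sum(axis=0)
    sc = np.where(
        denom_s > _EPS,
        (scale_centers[:, None] * e_scales).sum(axis=0) / np.maximum(denom_s, _EPS),
        scale_centers[0],
    )
    return ModulationFeatures(
        lr=lr, hr=hr, rc=rc, sc=sc,
        rate_temporal=spec_hi.frame_rate, rate_spectral=sl.frame_rate,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _pool_to_hop(series: np.ndarray, rate: float, n_out: int, hop: float = HOP_S) -> np.ndarray:
    """Window-mean pooling of a series onto the 64 ms grid."""
    series = np.asarray(series, dtype=float)
    out = np.empty(n_out)
    for i in range(n_out):
        lo = int(np.floor(i * hop * rate + 1e-9))
        hi = int(np.floor((i + 1) * hop * rate + 1e-9))
        hi = min(max(hi, lo + 1), series.size)
        lo = min(lo, series.size - 1)
        out[i] = series[lo:hi].mean()
    return out


def assemble_features(
    x: np.ndarray,
    fs: int = TARGET_FS,
    scene_id: str = "",
    normalize: bool = True,
    hop: float = HOP_S,
) -> FeatureMatrix:
    """All eleven features of a scene on the 64 ms grid, z-scored per scene.

    The number of output frames is ``floor(duration / hop)``.  Normalization
    statistics (mean and sd per feature before z-scoring) are recorded on the
    returned matrix; ``normalize=False`` emits the raw series.
    """
    x = _resample_to_target(np.asarray(x, dtype=float), fs)
    duration = x.size / TARGET_FS
    n_out = int(np.floor(duration / hop + 1e-9))

    # one STFT feeds both the log-channel spectrogram and the bark loudness
    mag, bin_freqs = _stft_magnitude(x, TARGET_FS, FRAME_RATE, 2048)
    centers = 90.0 * 2.0 ** (np.arange(128) / 24)
    weights = _log_channel_weights(bin_freqs, centers, 24)
    spec = AuditorySpectrogram(y=mag @ weights.T, freqs=centers, frame_rate=FRAME_RATE)
    spec_hi = auditory_spectrogram(x, frame_rate=HI_FRAME_RATE, win=128)

    ld = loudness(x, _stft=(mag, bin_freqs))
    pitch, harm = pitch_harmonicity(spec)
    br, bw, ir, fl, _ = spectral_shape(spec)
    mod = modulation_features(spec_hi, spec)

    raw = {
        "LD": (ld, FRAME_RATE),
        "P": (pitch, FRAME_RATE),
        "H": (harm, FRAME_RATE),
        "BR": (br, FRAME_RATE),
        "BW": (bw, FRAME_RATE),
        "IR": (ir, FRAME_RATE),
        "FL": (fl, FRAME_RATE),
        "LR": (mod.lr, mod.rate_temporal),
        "HR": (mod.hr, mod.rate_temporal),
        "RC": (mod.rc, mod.rate_temporal),
        "SC": (mod.sc, mod.rate_spectral),
    }
    data = {}
    stats = {}
    for name in FEATURE_NAMES:
        series, rate = raw[name]
        pooled = _pool_to_hop(series, rate, n_out, hop)
        mu = float(pooled.mean())
        sd = float(pooled.std())
        stats[name] = {"mean": mu, "sd": sd}
        if normalize:
            pooled = (pooled - mu) / sd if sd > 0 else pooled - mu
        data[name] = pooled
    return FeatureMatrix(
        scene_id=scene_id,
        data=pd.DataFrame(data, columns=list(FEATURE_NAMES)),
        hop=hop,
        norm_stats=pd.DataFrame(stats),
    )


def feature_change(matrix: FeatureMatrix, onset: float) -> pd.Series | None:
    """Per-feature change around an event onset, in the matrix's units.

    Difference between the mean over [onset + 0.5, onset + 1.0) and the mean
    over [onset - 1.0, onset - 0.5).  Onsets closer than 1 s to either scene
    edge are flagged missing (None).
    """
    if onset < 1.0 or onset + 1.0 > matrix.duration:
        return None
    t = matrix.times
    pre = (t >= onset - 1.0) & (t < onset - 0.5)
    post = (t >= onset + 0.5) & (t < onset + 1.0)
    if not pre.any() or not post.any():
        return None
    return matrix.data[post].mean() - matrix.data[pre].mean()


def feature_correlations(matrices: list[FeatureMatrix]) -> pd.DataFrame:
    """Pearson correlation between each pair of features, pooled over scenes.

    Constant features get NaN rows/columns (flagged undefined) rather than a
    spurious value.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two scenes for feature correlations")
    pooled = pd.concat([m.data for m in matrices], ignore_index=True)
    corr = pooled.corr()
    constant = pooled.std() == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
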