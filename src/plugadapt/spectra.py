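"""Stimulus spectra on a uniform log-frequency grid.

Stimuli for the localization task are described entirely by their
log-amplitude spectra (dB re. a flat reference) sampled on a grid that is
uniform in log2 frequency.  Three stimulus kinds exist: flat-spectrum
broadband noise (the all-zero profile), random-spectrum noise (a flat
profile perturbed by a band-limited Gaussian randomization vector), and
pure tones (no profile; described by their frequency alone).  No audio
waveform is ever synthesized -- duration, ramp and sampling rate are
carried as metadata only.

The randomization vector is the experimental workhorse: Gaussian noise in
the log-spectral domain, low-pass filtered along the log-frequency axis so
that all modulation energy above 3 cycles/octave is removed (listeners are
insensitive to finer spectral detail; every surviving peak or notch is
wider than 1/6 octave), then scaled to an RMS of exactly 10 dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencyGrid",
    "SpectralProfile",
    "StimulusSpec",
    "BandStats",
    "make_frequency_grid",
    "generate_random_vector",
    "generate_flat_profile",
    "band_statistics",
    "feature_width_check",
    "write_profile",
    "read_profile",
    "MAX_SPACING_OCT",
    "DEFAULT_CUTOFF_CPO",
    "DEFAULT_RMS_DB",
    "TONE_FREQS_HZ",
    "LEVELS_DB_SPL",
]

#: Coarsest grid able to represent spectral modulation up to 3 cycles/octave.
MAX_SPACING_OCT = 1.0 / 6.0

#: Modulation low-pass cutoff for randomization vectors, cycles/octave.
DEFAULT_CUTOFF_CPO = 3.0

#: Target RMS of randomization vectors, dB.
DEFAULT_RMS_DB = 10.0

#: Pure-tone frequencies used in the task (octave steps).
TONE_FREQS_HZ = (1000.0, 2000.0, 4000.0, 8000.0)

#: Presentation levels, dB SPL (7 dB roving steps).
LEVELS_DB_SPL = (49.0, 56.0, 63.0, 70.0, 77.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform grid in log2 frequency.

    Parameters
    ----------
    frequencies : ndarray
        Ordered positive frequencies in Hz, arithmetic in log2.
    spacing_oct : float
        Grid step in octaves; must not exceed 1/6 octave.
    """

    frequencies: np.ndarray
    spacing_oct: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("grid needs at least two frequencies")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be positive")
        if self.spacing_oct <= 0:
            raise ValueError(f"spacing_oct must be positive, got {self.spacing_oct}")
        log2f = np.log2(freqs)
        steps = np.diff(log2f)
        if not np.allclose(steps, self.spacing_oct, rtol=1e-9, atol=1e-12):
            raise ValueError("frequencies are not uniform in log2 at spacing_oct")

    @property
    def n(self) -> int:
        return self.frequencies.size

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])

    @property
    def span_oct(self) -> float:
        """Total span in octaves."""
        return float(np.log2(self.f_max / self.f_min))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return (
            self.frequencies.shape == other.frequencies.shape
            and np.allclose(self.frequencies, other.frequencies, rtol=1e-12)
        )


@dataclass(frozen=True)
class SpectralProfile:
    """Log-amplitude spectrum: one dB value per grid frequency (0 dB = flat)."""

    grid: FrequencyGrid
    amp_db: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amp_db, dtype=float)
        object.__setattr__(self, "amp_db", amp)
        if amp.shape != (self.grid.n,):
            raise ValueError(
                f"amp_db has shape {amp.shape}, expected ({self.grid.n},)"
            )
        if not np.all(np.isfinite(amp)):
            raise ValueError("amp_db must be finite")

    @property
    def rms_db(self) -> float:
        return float(np.sqrt(np.mean(self.amp_db**2)))


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: kind, level, and (for noise) its spectral profile.

    ``duration_ms``, ``ramp_ms`` and ``nominal_rate_hz`` are metadata only;
    no waveform is synthesized anywhere in the package.
    """

    kind: str  # 'flat' | 'random' | 'tone'
    level_db_spl: float
    tone_freq_hz: float | None = None
    profile: SpectralProfile | None = None
    duration_ms: float = 100.0
    ramp_ms: float = 10.0
    nominal_rate_hz: float = 97600.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "random", "tone"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if float(self.level_db_spl) not in LEVELS_DB_SPL:
            raise ValueError(
                f"level_db_spl must be one of {LEVELS_DB_SPL}, got {self.level_db_spl}"
            )
        if self.kind == "tone":
            if self.profile is not None:
                raise ValueError("tone stimuli carry no spectral profile")
            if self.tone_freq_hz is None or float(self.tone_freq_hz) not in TONE_FREQS_HZ:
                raise ValueError(f"tone_freq_hz must be one of {TONE_FREQS_HZ}")
        else:
            if self.profile is None:
                raise ValueError(f"{self.kind} stimuli require a spectral profile")
            if self.tone_freq_hz is not None:
                raise ValueError("noise stimuli carry no tone frequency")


@dataclass(frozen=True)
class BandStats:
    """Per-band mean and SD of a profile over contiguous octave-wide bands."""

    band_centers: np.ndarray
    band_mean_db: np.ndarray
    band_sd_db: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.band_sd_db) < 0):
            raise ValueError("band SDs must be nonnegative")


def make_frequency_grid(
    f_min: float, f_max: float, spacing_oct: float = 1.0 / 24.0
) -> FrequencyGrid:
    """Build a grid spanning [f_min, f_max], uniform in log2 frequency.

    The grid starts exactly at ``f_min`` and extends in steps of
    ``spacing_oct`` octaves up to the largest point not exceeding ``f_max``.
    Grids meant to carry randomization vectors need spacing of at most
    1/6 octave (the Nyquist step for 3 cycles/octave modulation); the
    generator enforces that requirement.
    """
    if not (0 < f_min < f_max):
        raise ValueError(f"need 0 < f_min < f_max, got {f_min}, {f_max}")
    if spacing_oct <= 0:
        raise ValueError(f"spacing_oct must be positive, got {spacing_oct}")
    span = np.log2(f_max / f_min)
    n = int(np.floor(span / spacing_oct + 1e-9)) + 1
    freqs = f_min * 2.0 ** (np.arange(n) * spacing_oct)
    return FrequencyGrid(frequencies=freqs, spacing_oct=float(spacing_oct))


def default_grid() -> FrequencyGrid:
    """The stimulus-band grid: 0.5-20 kHz at 1/24 octave (128 points)."""
    return make_frequency_grid(500.0, 20000.0, 1.0 / 24.0)


def _modulation_lowpass(values: np.ndarray, spacing_oct: float,
                        cutoff_cyc_per_oct: float) -> np.ndarray:
    """Brickwall low-pass along the log2-frequency axis (last axis).

    Real-input DFT; bins at modulation frequencies strictly above the cutoff
    are zeroed, then the inverse transform is taken.
    """
    n = values.shape[-1]
    spec = np.fft.rfft(values, axis=-1)
    mod_freqs = np.fft.rfftfreq(n, d=spacing_oct)  # cycles/octave
    spec[..., mod_freqs > cutoff_cyc_per_oct + 1e-12] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _modulation_lowpass_sym(values: np.ndarray, spacing_oct: float,
                            cutoff_cyc_per_oct: float) -> np.ndarray:
    """Brickwall low-pass under symmetric (mirror) extension.

    DCT-based: avoids the wrap-around discontinuity of the circular DFT,
    which matters when filtering profiles that are not statistically
    stationary across the grid (e.g. masked directional templates).
    """
    from scipy import fft as sfft

    n = values.shape[-1]
    coeffs = sfft.dct(values, axis=-1, norm="ortho")
    mod_freqs = np.arange(n) / (2.0 * n * spacing_oct)  # cycles/octave
    coeffs[..., mod_freqs > cutoff_cyc_per_oct + 1e-12] = 0.0
    return sfft.idct(coeffs, axis=-1, norm="ortho")


def modulation_spectrum_sym(values: np.ndarray, spacing_oct: float):
    """Magnitude of the symmetric-extension modulation transform and its
    frequency axis (cycles/octave)."""
    from scipy import fft as sfft

    n = values.shape[-1]
    coeffs = sfft.dct(values, axis=-1, norm="ortho")
    mod_freqs = np.arange(n) / (2.0 * n * spacing_oct)
    return np.abs(coeffs), mod_freqs


def generate_random_vector(
    grid: FrequencyGrid,
    cutoff_cyc_per_oct: float = DEFAULT_CUTOFF_CPO,
    rms_db: float = DEFAULT_RMS_DB,
    seed: int | np.random.Generator = 0,
) -> SpectralProfile:
    """Draw one spectral randomization vector.

    White Gaussian noise per grid bin is low-pass filtered along the
    log-frequency axis (hard cutoff at ``cutoff_cyc_per_oct``) and rescaled
    so its RMS is exactly ``rms_db``.  Identical ``(grid, seed)`` yield
    bit-identical output.  Grids coarser than the modulation Nyquist step
    (1 / (2 * cutoff)) cannot represent the band limit and are rejected.
    """
    if grid.spacing_oct > 1.0 / (2.0 * cutoff_cyc_per_oct) + 1e-12:
        raise ValueError(
            f"grid spacing {grid.spacing_oct} octaves cannot represent "
            f"{cutoff_cyc_per_oct} cycles/octave modulation"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = rng.standard_normal(grid.n)
    y = _modulation_lowpass(x, grid.spacing_oct, cutoff_cyc_per_oct)
    rms = np.sqrt(np.mean(y**2))
    if rms == 0:  # pragma: no cover - probability zero
        raise RuntimeError("degenerate all-zero filtered vector")
    return SpectralProfile(grid=grid, amp_db=y * (rms_db / rms))


def generate_flat_profile(grid: FrequencyGrid) -> SpectralProfile:
    """The flat-spectrum reference: 0 dB everywhere."""
    return SpectralProfile(grid=grid, amp_db=np.zeros(grid.n))


def band_statistics(
    profile: SpectralProfile, band_width_oct: float = 1.0
) -> BandStats:
    """Mean and SD of the profile over contiguous bands of fixed octave width.

    Bands tile the grid starting at ``f_min``; the top grid point is folded
    into the last band.  The band width must be a positive multiple of the
    grid spacing and no wider than the grid span.
    """
    grid = profile.grid
    ratio = band_width_oct / grid.spacing_oct
    if band_width_oct <= 0 or abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            "band_width_oct must be a positive multiple of the grid spacing"
        )
    if band_width_oct > grid.span_oct + 1e-9:
        raise ValueError("band wider than grid span")
    offsets_oct = np.log2(grid.frequencies / grid.f_min)
    n_bands = int(np.ceil(grid.span_oct / band_width_oct - 1e-9))
    idx = np.minimum(
        (offsets_oct / band_width_oct + 1e-9).astype(int), n_bands - 1
    )
    centers, means, sds = [], [], []
    for b in range(n_bands):
        sel = profile.amp_db[idx == b]
        centers.append(grid.f_min * 2.0 ** ((b + 0.5) * band_width_oct))
        means.append(float(np.mean(sel)))
        sds.append(float(np.std(sel)))
    return BandStats(
        band_centers=np.asarray(centers),
        band_mean_db=np.asarray(means),
        band_sd_db=np.asarray(sds),
    )


def feature_width_check(profile: SpectralProfile) -> float:
    """Minimum width of spectral peaks/notches, in octaves.

    Measured as the minimum spacing between consecutive zero crossings of
    the profile along the log-frequency axis (linear interpolation between
    bins).  Diagnostic only: for a vector band-limited at 3 cycles/octave
    the typical value is >= 1/6 octave (half the cutoff period), though
    sums of band-limited components can in principle cross faster.  A
    profile with fewer than two crossings returns the full grid span.
    """
    u = np.log2(profile.grid.frequencies / profile.grid.f_min)
    a = profile.amp_db
    crossings = []
    for i in range(len(a) - 1):
        if a[i] == 0.0:
            crossings.append(u[i])
        elif a[i] * a[i + 1] < 0:
            # linear interpolation for the crossing position
            t = a[i] / (a[i] - a[i + 1])
            crossings.append(u[i] + t * (u[i + 1] - u[i]))
    if a[-1] == 0.0:
        crossings.append(u[-1])
    if len(crossings) < 2:
        return profile.grid.span_oct
    widths = np.diff(sorted(crossings))
    widths = widths[widths > 1e-12]
    if widths.size == 0:
        return profile.grid.span_oct
    return float(widths.min())


def write_profile(profile: SpectralProfile, path) -> None:
    """Serialize a profile as delimited text (columns freq_hz, amp_db)."""
    import pandas as pd

    pd.DataFrame(
        {"freq_hz": profile.grid.frequencies, "amp_db": profile.amp_db}
    ).to_csv(path, index=False)


def read_profile(path) -> SpectralProfile:
    """Read a profile written by :func:`write_profile`."""
    import pandas as pd

    df = pd.read_csv(path)
    freqs = df["freq_hz"].to_numpy(dtype=float)
    spacing = float(np.median(np.diff(np.log2(freqs))))
    grid = FrequencyGrid(frequencies=freqs, spacing_oct=spacing)
    return SpectralProfile(grid=grid, amp_db=df["amp_db"].to_numpy(dtype=float))


def _rng_from(seed) -> np.random.Generator:
    """Accept an int seed or pass through an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
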