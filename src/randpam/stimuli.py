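"""Light-input generators and CSV serialization.

The simulator consumes a ``LightStimulus``: an integer photon count per
time-bin at a stated sampling rate (1 kHz by default, i.e. 1 ms bins).
Three generators cover the standard test regimes: a constant rate, a
band-limited Gaussian white noise, and a 1/f "naturalistic" sequence whose
power spectrum mimics natural scene statistics.  Counts are what a
photoreceptor actually absorbs, so they are non-negative integers; the
generators clip at zero and round half-to-even, and record the residual
mean shift rather than re-normalising.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LightStimulus",
    "constant_stimulus",
    "white_noise_stimulus",
    "naturalistic_stimulus",
    "read_stimulus",
    "write_stimulus",
]

#: Below this input sampling rate the fastest fly-photoreceptor dynamics
#: (contrast responses up to ~100 Hz) are under-resolved.
MIN_RECOMMENDED_RATE_HZ = 200.0

#: Standard deviation of the log-intensity used in 1/f synthesis; keeps the
#: exponentiated trace positively skewed with occasional bright events while
#: preserving the 1/f spectral shape through the exponential.
NATURALISTIC_LOG_SIGMA = 0.5


@dataclass
class LightStimulus:
    """Per-bin absorbed-photon counts at a sampling rate.

    ``counts`` are non-negative integers; ``mean_rate`` (photons/s) and
    ``metadata`` carry provenance only and never enter computations.
    """

    counts: np.ndarray
    sampling_rate: float = 1000.0
    mean_rate: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("photon counts must be integral")
            counts = counts.astype(np.int64)
        self.counts = counts.astype(np.int64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sampling_rate < MIN_RECOMMENDED_RATE_HZ:
            warnings.warn(
                f"sampling_rate {self.sampling_rate} Hz is below {MIN_RECOMMENDED_RATE_HZ:g} Hz; "
                "fly photoreceptor dynamics may be under-sampled",
                stacklevel=2,
            )

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_s(self) -> float:
        return self.n_bins / self.sampling_rate

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


def constant_stimulus(
    rate_photons_per_s: float, duration_s: float, sampling_rate: float = 1000.0
) -> LightStimulus:
    """Constant light: every bin carries round(rate / sampling_rate) photons.

    The rounding residual (achieved minus requested photons per bin) is
    recorded in metadata.
    """
    if rate_photons_per_s < 0:
        raise ValueError("rate must be non-negative")
    per_bin_exact = rate_photons_per_s / sampling_rate
    per_bin = int(np.round(per_bin_exact))  # round-half-even
    n_bins = int(round(duration_s * sampling_rate))
    counts = np.full(n_bins, per_bin, dtype=np.int64)
    return LightStimulus(
        counts=counts,
        sampling_rate=sampling_rate,
        mean_rate=rate_photons_per_s,
        metadata={"kind": "constant", "rounding_residual_per_bin": per_bin - per_bin_exact},
    )


def _integerize(intensity: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip at zero, round half-even; return counts and the mean shift."""
    clipped = np.clip(intensity, 0.0, None)
    counts = np.rint(clipped).astype(np.int64)
    return counts, float(counts.mean() - intensity.mean())


def white_noise_stimulus(
    mean_rate: float,
    contrast: float,
    cutoff_hz: float,
    duration_s: float,
    sampling_rate: float = 1000.0,
    seed: int | None = None,
) -> LightStimulus:
    """Band-limited Gaussian white-noise light.

    Spectral synthesis: Fourier amplitudes are iid complex Gaussian (flat
    spectrum) up to ``cutoff_hz`` and zero above, so all power is confined
    to the pass band.  The trace is scaled to mean ``mean_rate/sampling_rate``
    photons per bin with standard deviation ``contrast`` times the mean,
    then clipped at zero and rounded to integer counts.
    """
    if mean_rate < 0:
        raise ValueError("mean_rate must be non-negative")
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    if cutoff_hz >= sampling_rate / 2:
        raise ValueError(
            f"cutoff_hz must be below the Nyquist frequency {sampling_rate / 2:g} Hz"
        )
    n_bins = int(round(duration_s * sampling_rate))
    mean_per_bin = mean_rate / sampling_rate
    if contrast == 0 or n_bins == 1:
        return constant_stimulus(mean_rate, duration_s, sampling_rate)

    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_bins, d=1.0 / sampling_rate)
    spectrum = np.zeros(freqs.size, dtype=complex)
    band = (freqs > 0) & (freqs <= cutoff_hz)
    spectrum[band] = rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum())
    noise = np.fft.irfft(spectrum, n=n_bins)
    std = noise.std()
    if std > 0:
        noise = noise / std
    intensity = mean_per_bin * (1.0 + contrast * noise)
    counts, shift = _integerize(intensity)
    return LightStimulus(
        counts=counts,
        sampling_rate=sampling_rate,
        mean_rate=mean_rate,
        metadata={
            "kind": "white_noise",
            "contrast": contrast,
            "cutoff_hz": cutoff_hz,
            "seed": seed,
            "integerization_mean_shift": shift,
        },
    )


def naturalistic_stimulus(
    mean_rate: float,
    duration_s: float,
    sampling_rate: float = 1000.0,
    seed: int | None = None,
    log_sigma: float = NATURALISTIC_LOG_SIGMA,
) -> LightStimulus:
    """1/f naturalistic light intensity time series.

    A log-intensity trace with amplitude spectrum proportional to
    1/sqrt(f) (power spectrum 1/f) and random phases is exponentiated —
    giving the positive, positively skewed intensities typical of natural
    scenes — then scaled to the target mean and rounded to integer counts.
    For moderate ``log_sigma`` the exponential preserves the 1/f power-law
    shape of the spectrum.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    n_bins = int(round(duration_s * sampling_rate))
    if n_bins < 2:
        return constant_stimulus(mean_rate, duration_s, sampling_rate)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_bins, d=1.0 / sampling_rate)
    amplitude = np.zeros(freqs.size)
    amplitude[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = amplitude * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    spectrum[0] = 0.0
    log_intensity = np.fft.irfft(spectrum, n=n_bins)
    sd = log_intensity.std()
    if sd > 0:
        log_intensity = log_intensity / sd * log_sigma
    intensity = np.exp(log_intensity)
    intensity *= (mean_rate / sampling_rate) / intensity.mean()
    counts, shift = _integerize(intensity)
    return LightStimulus(
        counts=counts,
        sampling_rate=sampling_rate,
        mean_rate=mean_rate,
        metadata={
            "kind": "naturalistic",
            "seed": seed,
            "log_sigma": log_sigma,
            "integerization_mean_shift": shift,
        },
    )


def write_stimulus(stimulus: LightStimulus, path) -> None:
    """Serialize to single-column CSV with ``#``-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={stimulus.sampling_rate:g}\n")
        if stimulus.mean_rate is not None:
            fh.write(f"# mean_rate_photons_per_s={stimulus.mean_rate:g}\n")
        for key, value in stimulus.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write("photons_per_bin\n")
        np.savetxt(fh, stimulus.counts, fmt="%d")


def read_stimulus(path) -> LightStimulus:
    """Read a stimulus CSV written by :func:`write_stimulus` (or bare counts).

    Raises a ValueError naming the offending line for negative or
    non-integer entries.
    """
    sampling_rate = 1000.0
    mean_rate = None
    metadata: dict = {}
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "sampling_rate_hz":
                        sampling_rate = float(val)
                    elif key == "mean_rate_photons_per_s":
                        mean_rate = float(val)
                    else:
                        metadata[key] = val
                continue
            if text == "photons_per_bin":
                continue
            for tok in text.replace(",", " ").split():
                try:
                    value = float(tok)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: not a number: {tok!r}") from exc
                if value != int(value):
                    raise ValueError(
                        f"{path}: line {lineno}: photon count must be an integer, got {tok!r}"
                    )
                if value < 0:
                    raise ValueError(
                        f"{path}: line {lineno}: photon count must be non-negative, got {tok!r}"
                    )
                values.append(int(value))
    if not values:
        raise ValueError(f"{path}: no photon counts found")
    return LightStimulus(
        counts=np.asarray(values, dtype=np.int64),
        sampling_rate=sampling_rate,
        mean_rate=mean_rate,
        metadata=metadata,
    )
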