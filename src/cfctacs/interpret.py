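"""Spectral interpretation of the learned decoder.

Two read-outs of what the first convolutional layer has learned:

* the **kernel spectrum** — the magnitude-squared FFT of each learned
  temporal kernel, averaged over kernels and normalised to its maximum per
  participant, then grand-averaged with an SEM band;
* the **feature-map PSD** — the PSD of EEG trials after convolution with the
  learned kernels, normalised to the per-trial maximum and averaged across
  trials; contrasting post-minus-pre difference profiles between the two
  stimulation conditions localises the discriminative band (lower beta,
  13-20 Hz, for the planted parietal effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .evaluation import StatTestResult, paired_ttest_fdr

__all__ = [
    "SpectralProfile",
    "kernel_spectrum",
    "feature_map_psd",
    "grand_average",
    "band_mean",
    "contrast_lower_beta",
    "KERNEL_NFFT",
]

#: FFT length for kernel spectra: 64-tap kernels are zero-padded to 256 for
#: a 0.5-Hz grid at the 128-Hz model rate.
KERNEL_NFFT = 256


@dataclass
class SpectralProfile:
    """A normalised power-density curve with provenance."""

    freqs: np.ndarray
    power: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("frequency grid and power must align")


def _normalise(p: np.ndarray) -> np.ndarray:
    return p / np.maximum(p.max(), 1e-30)


def kernel_spectrum(
    kernels: np.ndarray,
    model_rate: float = 128.0,
    nfft: int = KERNEL_NFFT,
    provenance: dict | None = None,
    remove_dc: bool = True,
) -> SpectralProfile:
    """Normalised power spectrum of a participant's first-layer kernels.

    Each kernel's magnitude-squared FFT (zero-padded to ``nfft``) is
    normalised to its own maximum, the kernels are averaged, and the average
    is renormalised so its maximum equals one.

    ``remove_dc`` subtracts each kernel's mean first: a temporal kernel is
    followed by batch normalisation, so its mean is a gauge freedom with no
    effect on the network function — optimisers let it drift, and the
    spurious DC term would otherwise dominate the spectrum.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    if remove_dc:
        kernels = kernels - kernels.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(kernels, n=nfft, axis=-1)) ** 2
    per_kernel = spec / np.maximum(
        spec.max(axis=-1, keepdims=True), 1e-30
    )
    power = _normalise(per_kernel.mean(axis=0))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / model_rate)
    return SpectralProfile(freqs, power, provenance or {})


def feature_map_psd(
    kernels: np.ndarray,
    trials: np.ndarray,
    model_rate: float = 128.0,
    estimator: str = "periodogram",
    nfft: int = KERNEL_NFFT,
    provenance: dict | None = None,
) -> SpectralProfile:
    """Average normalised PSD of trials passed through the learned kernels.

    Each trial's channels are convolved with every kernel ('same' length),
    the PSD of each filtered series is computed (periodogram by default,
    ``estimator='welch'`` optional), averaged over channels and kernels, and
    the per-trial curve is normalised to its maximum before averaging across
    trials — so every per-trial profile peaks at exactly 1.

    Parameters
    ----------
    trials : ndarray (n_trials, n_channels, T) at the model rate.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] == 0:
        raise ValueError("need a non-empty (n, C, T) trial array")
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    n, C, T = trials.shape
    # convolve every (trial, channel) with every kernel: (n, F, C, T)
    filtered = signal.fftconvolve(
        trials[:, None, :, :], kernels[None, :, None, :], mode="same", axes=-1
    )
    if estimator == "periodogram":
        freqs, psd = signal.periodogram(
            filtered, fs=model_rate, nfft=max(nfft, T), axis=-1
        )
    elif estimator == "welch":
        freqs, psd = signal.welch(
            filtered, fs=model_rate, nperseg=min(T, 64), axis=-1
        )
    else:
        raise ValueError("estimator must be 'periodogram' or 'welch'")
    per_trial = psd.mean(axis=(1, 2))  # (n, n_freq)
    per_trial = per_trial / np.maximum(
        per_trial.max(axis=-1, keepdims=True), 1e-30
    )
    prov = {"estimator": estimator, "n_trials": n}
    prov.update(provenance or {})
    return SpectralProfile(freqs, per_trial.mean(axis=0), prov)


def grand_average(
    profiles: list[SpectralProfile],
) -> tuple[SpectralProfile, np.ndarray]:
    """Mean profile across participants plus the SEM band."""
    if not profiles:
        raise ValueError("no profiles to average")
    P = np.stack([p.power for p in profiles])
    mean = P.mean(axis=0)
    sem = (
        P.std(axis=0, ddof=1) / np.sqrt(len(profiles))
        if len(profiles) > 1
        else np.zeros_like(mean)
    )
    return (
        SpectralProfile(
            profiles[0].freqs, mean, {"n_participants": len(profiles)}
        ),
        sem,
    )


def band_mean(
    profile: SpectralProfile, low: float, high: float
) -> float:
    """Mean profile value over the inclusive [low, high] Hz bins."""
    sel = (profile.freqs >= low) & (profile.freqs <= high)
    if not sel.any():
        raise ValueError(f"no bins in [{low}, {high}] Hz")
    return float(profile.power[sel].mean())


def contrast_lower_beta(
    profiles_by_condition: dict[int, list[tuple[SpectralProfile, SpectralProfile]]],
    band: tuple[float, float] = (13.0, 20.0),
    alpha: float = 0.05,
) -> StatTestResult:
    """Paired t-test of the lower-beta post-minus-pre profile change
    between the two stimulation conditions.

    ``profiles_by_condition[cond]`` holds one (pre_profile, post_profile)
    pair per participant, in the same participant order for both conditions.
    """
    conds = sorted(profiles_by_condition)
    if len(conds) != 2:
        raise ValueError("need exactly two conditions")
    deltas = {}
    for cond in conds:
        pairs = profiles_by_condition[cond]
        deltas[str(cond)] = np.array(
            [
                band_mean(post, *band) - band_mean(pre, *band)
                for pre, post in pairs
            ]
        )
    res = paired_ttest_fdr(
        deltas, [(str(conds[0]), str(conds[1]))], alpha=alpha
    )[0]
    return StatTestResult(
        label=f"lower-beta change {conds[0]} vs {conds[1]}",
        t=res.t, df=res.df, p=res.p, p_adj=res.p_adj,
        significant=res.significant, alpha=alpha,
    )
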