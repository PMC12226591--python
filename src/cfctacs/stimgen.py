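"""Cross-frequency-coupled tACS waveform synthesis.

The stimulation waveform couples a slow "phase frequency" ``f_P`` to a fast
"amplitude frequency" ``f_A`` in a phase-amplitude manner:

    s(t) = (A_fA / 2) * (sin(2*pi*f_P*t + phi) + 1) * sin(2*pi*f_A*t)
         + A_fP * sin(2*pi*f_P*t + phi)

so that the envelope of the fast component rides on the slow oscillation.
Two functional networks are targeted simultaneously — the central executive
network (CEN: bilateral DLPFC and PPC) and the default mode network (DMN:
mPFC and PCC) — and the experimental conditions differ only in the phase
offset ``phi`` applied to the DMN waveform's slow component relative to the
CEN waveform (45 deg, partially in-phase, or 180 deg, out-of-phase).

Each stimulation electrode is surrounded by return electrodes that each
carry -1/N of the stimulus current, so the net injected current is zero at
every sample.  The summed instantaneous source current across the montage is
capped at a configurable safety limit (1.5 mA by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "StimulationConfigError",
    "StimConfig",
    "TargetSpec",
    "MontageSpec",
    "StimulusWaveformSet",
    "synthesize_stimulus",
    "derive_return_currents",
    "build_condition_waveforms",
    "estimate_phase_lag",
    "export_waveform_set",
    "default_montage",
    "CONDITIONS",
]

#: Valid phase-lag conditions (degrees of DMN lag relative to CEN at f_P).
CONDITIONS = (45, 180)


class StimulationConfigError(ValueError):
    """Raised when a stimulation configuration violates its constraints."""


@dataclass(frozen=True)
class StimConfig:
    """Parameters of one cross-frequency-coupled stimulus.

    Parameters
    ----------
    f_p : float
        Phase (slow, envelope-carrying) frequency in Hz.  Default 6 Hz
        (theta), configurable per participant.
    f_a : float
        Amplitude (fast, modulated) frequency in Hz.  Default 40 Hz (gamma).
    a_fa : float
        Intensity constant of the amplitude-modulated fast component, mA.
    a_fp : float
        Intensity constant of the slow component, mA.  The defaults keep the
        field-standard 2:8 intensity ratio between the two components.
    fs : float
        Sampling rate of the generated series, Hz.  Must exceed ``2 * f_a``.
    duration : float
        Length of the generated series, s.
    """

    f_p: float = 6.0
    f_a: float = 40.0
    a_fa: float = 0.2
    a_fp: float = 0.8
    fs: float = 500.0
    duration: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.f_p < self.f_a:
            raise StimulationConfigError(
                f"require 0 < f_p < f_a, got f_p={self.f_p}, f_a={self.f_a}"
            )
        if self.fs <= 2 * self.f_a:
            raise StimulationConfigError(
                f"sampling rate {self.fs} Hz aliases the {self.f_a} Hz "
                f"component; need fs > {2 * self.f_a} Hz"
            )
        if self.a_fa < 0 or self.a_fp < 0:
            raise StimulationConfigError("intensity constants must be >= 0")
        if self.duration <= 0:
            raise StimulationConfigError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class TargetSpec:
    """One cortical stimulation target and its electrode layout."""

    region: str
    network: str  # "CEN" or "DMN"
    stim_electrode: str
    return_electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.network not in ("CEN", "DMN"):
            raise StimulationConfigError(f"unknown network {self.network!r}")
        if len(self.return_electrodes) < 1:
            raise StimulationConfigError(
                f"target {self.region}: at least one return electrode required"
            )


def default_montage(total_current_cap: float = 1.5) -> "MontageSpec":
    """Six-target CEN/DMN montage with four returns per target.

    Bilateral DLPFC and PPC carry the CEN stimulus, mPFC and PCC the DMN
    stimulus; electrode IDs follow the 10-10 neighbourhood of each target.
    """
    targets = (
        TargetSpec("l-DLPFC", "CEN", "F3", ("F1", "F5", "FC3", "AF3")),
        TargetSpec("r-DLPFC", "CEN", "F4", ("F2", "F6", "FC4", "AF4")),
        TargetSpec("l-PPC", "CEN", "P3", ("P1", "P5", "CP3", "PO3")),
        TargetSpec("r-PPC", "CEN", "P4", ("P2", "P6", "CP4", "PO4")),
        TargetSpec("mPFC", "DMN", "Fpz", ("Fp1", "Fp2", "AFz", "Fz")),
        TargetSpec("PCC", "DMN", "Pz", ("CPz", "POz", "Cz", "Oz")),
    )
    return MontageSpec(targets=targets, total_current_cap=total_current_cap)


@dataclass(frozen=True)
class MontageSpec:
    """Multi-target electrode montage with a global current safety cap.

    ``weights`` splits the stimulus intensity across targets; the default is
    an equal split.
    """

    targets: tuple[TargetSpec, ...]
    total_current_cap: float = 1.5
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise StimulationConfigError("montage needs at least one target")
        if self.total_current_cap <= 0:
            raise StimulationConfigError("current cap must be positive")
        if self.weights is not None and len(self.weights) != len(self.targets):
            raise StimulationConfigError("one weight per target required")

    def target_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.targets), 1.0 / len(self.targets))
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise StimulationConfigError("weights must be non-negative")
        return w


@dataclass
class StimulusWaveformSet:
    """Per-electrode injected currents for one phase-lag condition.

    ``currents`` has one row per electrode (mA, sampled at ``fs``); rows sum
    to zero at every sample because every stimulus is balanced by its return
    electrodes.  ``is_stim`` marks stimulation (vs. return) electrodes.
    """

    condition: int
    fs: float
    electrodes: list[str]
    currents: np.ndarray
    is_stim: np.ndarray
    scale: float = 1.0

    def source_current(self) -> np.ndarray:
        """Total instantaneous source (positive) current, mA per sample."""
        return np.clip(self.currents, 0.0, None).sum(axis=0)

    def net_current(self) -> np.ndarray:
        return self.currents.sum(axis=0)

    def electrode(self, name: str) -> np.ndarray:
        return self.currents[self.electrodes.index(name)]


def synthesize_stimulus(
    config: StimConfig, phase_offset_deg: float = 0.0
) -> np.ndarray:
    """Generate one cross-frequency-coupled stimulus current series.

    The phase offset is applied to the slow-frequency phase argument, which
    is shared by the envelope of the fast component and the additive slow
    component.

    Returns
    -------
    ndarray
        Current in mA, ``round(duration * fs)`` samples.
    """
    t = config.times()
    phi = np.deg2rad(phase_offset_deg)
    slow_arg = 2 * np.pi * config.f_p * t + phi
    envelope = (config.a_fa / 2.0) * (np.sin(slow_arg) + 1.0)
    return envelope * np.sin(2 * np.pi * config.f_a * t) + config.a_fp * np.sin(
        slow_arg
    )


def derive_return_currents(stimulus: np.ndarray, n_returns: int) -> np.ndarray:
    """Split the balancing current over ``n_returns`` return electrodes.

    Each return carries ``-stimulus / n_returns`` so the target's net
    injected current is exactly zero.
    """
    if n_returns < 1:
        raise StimulationConfigError("need at least one return electrode")
    one = -np.asarray(stimulus, dtype=float) / n_returns
    return np.tile(one, (n_returns, 1))


def build_condition_waveforms(
    montage: MontageSpec, config: StimConfig, condition: int
) -> StimulusWaveformSet:
    """Assemble the full-montage waveform set for one phase-lag condition.

    CEN targets receive zero phase offset; DMN targets receive the
    condition's offset at the phase frequency.  All waveforms are rescaled
    by a common factor so the peak summed source current never exceeds the
    montage cap; when the cap does not bind, the waveforms are unchanged.
    """
    if condition not in CONDITIONS:
        raise StimulationConfigError(
            f"condition must be one of {CONDITIONS}, got {condition}"
        )
    weights = montage.target_weights()
    electrodes: list[str] = []
    rows: list[np.ndarray] = []
    stim_flags: list[bool] = []
    for target, w in zip(montage.targets, weights):
        offset = 0.0 if target.network == "CEN" else float(condition)
        stim = w * synthesize_stimulus(config, offset)
        returns = derive_return_currents(stim, len(target.return_electrodes))
        electrodes.append(target.stim_electrode)
        rows.append(stim)
        stim_flags.append(True)
        for name, series in zip(target.return_electrodes, returns):
            electrodes.append(name)
            rows.append(series)
            stim_flags.append(False)
    currents = np.vstack(rows)
    source_peak = float(np.clip(currents, 0.0, None).sum(axis=0).max())
    scale = 1.0
    if source_peak > montage.total_current_cap:
        scale = montage.total_current_cap / source_peak
        currents = currents * scale
    return StimulusWaveformSet(
        condition=condition,
        fs=config.fs,
        electrodes=electrodes,
        currents=currents,
        is_stim=np.asarray(stim_flags),
        scale=scale,
    )


def estimate_phase_lag(
    series_a: np.ndarray,
    series_b: np.ndarray,
    f_p: float,
    fs: float,
) -> float:
    """Phase of ``series_a`` relative to ``series_b`` at ``f_p``, degrees.

    Both series are band-pass filtered around ``f_p`` (2nd-order Butterworth,
    [f_p / 1.5, 1.5 * f_p], zero phase), the instantaneous phase difference
    of their analytic signals is taken, and its circular mean over the
    central half of the series (avoiding filter edge effects) is returned in
    [0, 360).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and identically sampled")
    n = a.size
    if n < 3 * fs / f_p:
        raise ValueError(
            f"series too short: need at least 3 cycles of f_p={f_p} Hz"
        )
    sos = signal.butter(
        2, [f_p / 1.5, f_p * 1.5], btype="bandpass", fs=fs, output="sos"
    )
    fa = signal.sosfiltfilt(sos, a)
    fb = signal.sosfiltfilt(sos, b)
    sl = slice(n // 4, 3 * n // 4)
    dphi = np.angle(signal.hilbert(fa))[sl] - np.angle(signal.hilbert(fb))[sl]
    mean_angle = np.angle(np.exp(1j * dphi).mean())
    return float(np.rad2deg(mean_angle) % 360.0)


def export_waveform_set(ws: StimulusWaveformSet, path: str | Path) -> Path:
    """Write a waveform set as a TSV (one column per electrode) plus a JSON
    sidecar carrying the sample period, condition and rescale factor."""
    path = Path(path)
    header = "\t".join(ws.electrodes)
    np.savetxt(path, ws.currents.T, delimiter="\t", header=header, comments="")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "sample_period_s": 1.0 / ws.fs,
        "fs_hz": ws.fs,
        "condition_deg": ws.condition,
        "units": "mA",
        "rescale_factor": ws.scale,
        "stim_electrodes": [
            e for e, s in zip(ws.electrodes, ws.is_stim) if s
        ],
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
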