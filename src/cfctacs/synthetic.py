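"""Synthetic peri-stimulation EEG cohorts.

The generator emulates the data structure of a phase-lag tACS decoding
study: per participant, trials of a working-memory task during which
cross-frequency-coupled tACS was applied mid-retention in one of two
phase-lag conditions (45 or 180 deg), with two 500-ms EEG segments per trial
— immediately before (0-0.5 s of retention) and after (8.5-9 s) the
stimulation window — on the nine analysis electrodes (frontal Fz/F1/F2,
parietal Pz/P1/P2, occipital Oz/O1/O2).

Each channel is 1/f-shaped Gaussian background noise plus band-limited
oscillations whose per-trial amplitudes are log-normally distributed.  The
planted condition effect is a multiplicative pre-to-post gain on the
lower-beta (13-20 Hz) component of the parietal channels: the gain depends
on the condition, the baseline amplitude does not, so a single segment in
isolation carries (almost) no condition information while the pre-to-post
change does — the structure the decoding analysis assumes.

Per-trial amplitude variability is deliberately large (log-SD 0.7) so that
the marginal distribution of the post-segment band amplitude overlaps
heavily between conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "OscBand",
    "EffectSpec",
    "CohortConfig",
    "TrialRecord",
    "Cohort",
    "pink_noise",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("Fz", "F1", "F2", "Pz", "P1", "P2", "Oz", "O1", "O2")
PARIETAL = ("Pz", "P1", "P2")


@dataclass(frozen=True)
class OscBand:
    """One band-limited oscillatory component of the synthetic EEG."""

    label: str
    low: float
    high: float
    mean_amp: float  # cohort-median amplitude, uV
    amp_sigma: float = 0.7  # log-SD of the per-trial amplitude
    #: per-trial log-amplitudes are truncated at this many SDs so clean
    #: trials stay well below the +-100 uV artifact-rejection threshold
    amp_clip_sigmas: float = 2.5


@dataclass(frozen=True)
class EffectSpec:
    """Planted condition-dependent pre-to-post gain.

    The component of ``band`` in ``channels`` is scaled, in the post
    segment, by ``g45`` in the 45-deg condition and by ``g180`` in the
    180-deg condition.  Gains act multiplicatively on the band-limited
    component only, leaving the 1/f background untouched.
    """

    band: tuple[float, float] = (13.0, 20.0)
    channels: tuple[str, ...] = PARIETAL
    g45: float = 1.30
    g180: float = 0.75


def default_bands() -> tuple[OscBand, ...]:
    return (
        OscBand("theta", 4.0, 8.0, 2.5),
        OscBand("alpha", 8.0, 13.0, 4.0),
        OscBand("lower_beta", 13.0, 20.0, 5.0),
        OscBand("upper_beta", 20.0, 30.0, 2.0),
        OscBand("gamma", 30.0, 45.0, 1.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Shape and statistics of a synthetic cohort.

    Defaults mirror the emulated study: 21 participants, 2 sessions of 30
    trials per phase-lag condition, 500 Hz sampling, 500-ms segments, nine
    analysis channels.
    """

    n_participants: int = 21
    trials_per_condition: int = 60
    sessions_per_condition: int = 2
    fs: float = 500.0
    segment_ms: float = 500.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_exponent: float = 1.0
    noise_rms: float = 4.0  # uV, broadband background
    osc_bands: tuple[OscBand, ...] = field(default_factory=default_bands)
    effect: EffectSpec = field(default_factory=EffectSpec)
    participant_sigma: float = 0.4  # log-SD of per-participant amplitude scale
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        missing = [c for c in self.effect.channels if c not in self.channels]
        if missing:
            raise ValueError(f"effect channels {missing} not in channel list")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_ms / 1000.0))


@dataclass
class TrialRecord:
    """One task trial: a pre- and a post-stimulation EEG segment."""

    participant: int
    session: int
    condition: int  # 45 or 180
    pre: np.ndarray  # (channels, samples), uV
    post: np.ndarray
    artifact: bool = False  # generator ground truth


@dataclass
class Cohort:
    """A generated dataset of trials plus the configuration that made it."""

    config: CohortConfig
    trials: list[TrialRecord]

    @property
    def participants(self) -> list[int]:
        return sorted({t.participant for t in self.trials})

    def participant_arrays(
        self, participant: int
    ) -> dict[str, np.ndarray]:
        """Stack one participant's trials into arrays.

        Returns a dict with ``pre``/``post`` of shape (n, C, S), integer
        ``condition``, ``session`` and boolean ``artifact`` vectors.
        """
        trs = [t for t in self.trials if t.participant == participant]
        return {
            "pre": np.stack([t.pre for t in trs]),
            "post": np.stack([t.post for t in trs]),
            "condition": np.array([t.condition for t in trs]),
            "session": np.array([t.session for t in trs]),
            "artifact": np.array([t.artifact for t in trs]),
        }


def pink_noise(
    n_samples: int,
    exponent: float,
    rng: np.random.Generator,
    n_channels: int = 1,
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Shaped in the frequency domain (amplitude ~ f^(-exponent/2), DC removed)
    and returned with unit RMS per channel, shape (n_channels, n_samples).
    """
    n_freq = n_samples // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    shaping = np.zeros(n_freq)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, n_freq))
        + 1j * rng.standard_normal((n_channels, n_freq))
    ) * shaping
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _band_component(
    band: OscBand,
    amps: np.ndarray,
    freqs: np.ndarray,
    phases: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Sum-of-sinusoids realisation of one band: (C, S)."""
    return amps[:, None] * np.sin(
        2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
    )


@dataclass
class ParticipantParams:
    """Per-participant random parameters drawn once per cohort.

    Each participant has a stable peak frequency per band (individual
    peak frequencies are a robust feature of real EEG); trials jitter
    around it by a fraction of a hertz.
    """

    amp_scale: dict[str, float]  # band label -> amplitude scale, uV
    band_freq: dict[str, float]  # band label -> peak frequency, Hz
    noise_rms: float


def _draw_participant(
    config: CohortConfig, rng: np.random.Generator
) -> ParticipantParams:
    scales = {
        b.label: b.mean_amp
        * float(np.exp(rng.normal(0.0, config.participant_sigma)))
        for b in config.osc_bands
    }
    margin = 0.5  # keep the jittered frequency inside the band
    freqs = {
        b.label: float(rng.uniform(b.low + margin, b.high - margin))
        for b in config.osc_bands
    }
    noise = config.noise_rms * float(np.exp(rng.normal(0.0, 0.2)))
    return ParticipantParams(amp_scale=scales, band_freq=freqs, noise_rms=noise)


def generate_trial(
    params: ParticipantParams,
    condition: int,
    rng: np.random.Generator,
    config: CohortConfig,
    participant: int = 0,
    session: int = 0,
) -> TrialRecord:
    """Generate one trial (pre and post segment) for one participant.

    The effect-band component of the effect channels is drawn once per trial
    and reused in the post segment scaled by the condition gain; every other
    component is drawn independently per segment.
    """
    if condition not in (45, 180):
        raise ValueError(f"condition must be 45 or 180, got {condition}")
    n = config.n_samples
    n_ch = len(config.channels)
    t = np.arange(n) / config.fs
    gain = config.effect.g45 if condition == 45 else config.effect.g180
    eff_lo, eff_hi = config.effect.band
    eff_idx = np.array(
        [config.channels.index(c) for c in config.effect.channels]
    )

    segments = []
    effect_component = None  # (len(eff_idx), S), drawn with the pre segment
    for seg_i in (0, 1):  # pre, post
        x = params.noise_rms * pink_noise(
            n, config.noise_exponent, rng, n_channels=n_ch
        )
        for band in config.osc_bands:
            log_amp = np.clip(
                rng.normal(0.0, band.amp_sigma, size=n_ch),
                -band.amp_clip_sigmas * band.amp_sigma,
                band.amp_clip_sigmas * band.amp_sigma,
            )
            amps = params.amp_scale[band.label] * np.exp(log_amp)
            freqs = params.band_freq[band.label] + rng.uniform(
                -0.5, 0.5, size=n_ch
            )
            phases = rng.uniform(0.0, 2 * np.pi, size=n_ch)
            is_effect_band = (
                abs(band.low - eff_lo) < 1e-9 and abs(band.high - eff_hi) < 1e-9
            )
            if is_effect_band and seg_i == 0:
                comp = _band_component(band, amps, freqs, phases, t)
                effect_component = comp[eff_idx]
                x += comp
            elif is_effect_band and seg_i == 1:
                comp = _band_component(band, amps, freqs, phases, t)
                # effect channels: reuse the pre-segment component, scaled
                comp[eff_idx] = gain * effect_component
                x += comp
            else:
                x += _band_component(band, amps, freqs, phases, t)
        segments.append(x)

    artifact = bool(rng.random() < config.artifact_rate)
    if artifact:
        seg = segments[int(rng.integers(2))]
        ch = int(rng.integers(n_ch))
        start = int(rng.integers(0, n - 20))
        seg[ch, start : start + 20] += 200.0 * (1 if rng.random() < 0.5 else -1)

    return TrialRecord(
        participant=participant,
        session=session,
        condition=condition,
        pre=segments[0],
        post=segments[1],
        artifact=artifact,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort, deterministically from ``config.seed``.

    Sessions alternate condition blocks; trial order within the returned
    list is participant-major.  The same seed and config always produce a
    bit-identical cohort.
    """
    root = np.random.SeedSequence(config.seed)
    trials: list[TrialRecord] = []
    per_session = max(
        1, config.trials_per_condition // config.sessions_per_condition
    )
    for p_i, p_seq in enumerate(root.spawn(config.n_participants)):
        p_rng = np.random.default_rng(p_seq)
        params = _draw_participant(config, p_rng)
        trial_seqs = iter(p_seq.spawn(2 * config.trials_per_condition))
        for condition in (45, 180):
            for k in range(config.trials_per_condition):
                session = min(
                    k // per_session, config.sessions_per_condition - 1
                )
                rng = np.random.default_rng(next(trial_seqs))
                trials.append(
                    generate_trial(
                        params,
                        condition,
                        rng,
                        config,
                        participant=p_i,
                        session=session,
                    )
                )
    return Cohort(config=config, trials=trials)


# ---------------------------------------------------------------------------
# Container I/O (HDF5)

def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to one hierarchical HDF5 file.

    Layout: one group per participant holding stacked trial arrays, with the
    generator configuration JSON-encoded in a root attribute.
    """
    import h5py

    path = Path(path)
    cfg = asdict(cohort.config)
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(cfg)
        f.attrs["channels"] = list(cohort.config.channels)
        for pid in cohort.participants:
            arrs = cohort.participant_arrays(pid)
            g = f.create_group(f"participants/p{pid:03d}")
            for key, val in arrs.items():
                g.create_dataset(key, data=val)
    return path


def _config_from_dict(cfg: dict) -> CohortConfig:
    cfg = dict(cfg)
    cfg["channels"] = tuple(cfg["channels"])
    cfg["osc_bands"] = tuple(OscBand(**b) for b in cfg["osc_bands"])
    eff = dict(cfg["effect"])
    eff["band"] = tuple(eff["band"])
    eff["channels"] = tuple(eff["channels"])
    cfg["effect"] = EffectSpec(**eff)
    return CohortConfig(**cfg)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises
    ------
    IOError
        If the file is missing, truncated or not a cohort container.
    """
    import h5py

    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "config_json" not in f.attrs:
                raise IOError(f"{path} is not a cohort container")
            config = _config_from_dict(json.loads(f.attrs["config_json"]))
            trials: list[TrialRecord] = []
            for name in sorted(f.get("participants", {})):
                g = f[f"participants/{name}"]
                pid = int(name[1:])
                pre = g["pre"][...]
                post = g["post"][...]
                cond = g["condition"][...]
                sess = g["session"][...]
                art = g["artifact"][...]
                for i in range(pre.shape[0]):
                    trials.append(
                        TrialRecord(
                            participant=pid,
                            session=int(sess[i]),
                            condition=int(cond[i]),
                            pre=pre[i],
                            post=post[i],
                            artifact=bool(art[i]),
                        )
                    )
    except OSError as exc:  # h5py raises OSError on corrupt/truncated files
        raise IOError(f"cannot read cohort container {path}: {exc}") from exc
    return Cohort(config=config, trials=trials)
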