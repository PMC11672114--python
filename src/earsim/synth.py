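"""Synthetic recordings and scorer panels with the statistical structure the
pipeline assumes.

The generator is deliberately simple: each 30-second epoch of each electrode
is a mixture of band-limited noise whose relative band powers follow the
epoch's true stage, over a 1/f background.  The in-ear channel is an
attenuated, noisier average of the scalp electrodes resampled to its own
clock, so "similar but degraded" is true by construction and parameter
recovery can be tested.  No physiological microstructure (spindles,
K-complexes, eye movements) is modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import Hypnogram, Recording, ScorerPanel, STAGES3
from .montage import ELECTRODES, ELECTRODE_ROLES

#: EEG band edges in Hz (delta..gamma); gamma closes at the 35 Hz filter edge
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 35.0),
}

#: stage-dependent relative band powers: alpha-rich wake, delta/sigma-rich
#: NREM, theta-mixed REM
DEFAULT_BAND_WEIGHTS = {
    "W": {"delta": 0.15, "theta": 0.15, "alpha": 0.35, "sigma": 0.10, "beta": 0.20, "gamma": 0.05},
    "NREM": {"delta": 0.55, "theta": 0.20, "alpha": 0.08, "sigma": 0.12, "beta": 0.04, "gamma": 0.01},
    "REM": {"delta": 0.25, "theta": 0.35, "alpha": 0.15, "sigma": 0.08, "beta": 0.14, "gamma": 0.03},
}

#: slow-mixing sleep-like stage dynamics over {W, NREM, REM}
DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.10, 0.00],
        [0.02, 0.93, 0.05],
        [0.05, 0.15, 0.80],
    ]
)


@dataclass
class SimConfig:
    """Parameters of one synthetic overnight session."""

    n_epochs: int = 40
    epoch_len_s: float = 30.0
    fs_psg: float = 256.0
    fs_inear: float = 250.0
    electrodes: tuple[str, ...] = ELECTRODES
    stage_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy()
    )
    band_weights: dict = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_BAND_WEIGHTS.items()}
    )
    pink_exponent: float = 1.0
    pink_level: float = 0.2  # relative power of the 1/f background
    inear_attenuation: float = 0.6
    inear_noise_sd: float = 0.3  # white noise, relative to mixture std
    seed: int = 0
    stage_sequence: tuple[str, ...] | None = None  # fixed truth override

    def __post_init__(self) -> None:
        self.stage_transition = np.asarray(self.stage_transition, dtype=float)
        if self.stage_transition.shape != (3, 3) or np.any(self.stage_transition < 0):
            raise ValueError("stage_transition must be a nonnegative 3x3 matrix")
        if not np.allclose(self.stage_transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("stage_transition rows must sum to 1")
        for stage, w in self.band_weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative band weight for stage {stage}")
        for fs in (self.fs_psg, self.fs_inear):
            if fs <= 2 * 35.0:
                raise ValueError("sampling rate must exceed 70 Hz (2 x 35 Hz band)")
            if abs(self.epoch_len_s * fs - round(self.epoch_len_s * fs)) > 1e-9:
                raise ValueError("epoch_len_s x fs must be an integer sample count")
        if self.stage_sequence is not None:
            bad = set(self.stage_sequence) - set(STAGES3)
            if bad:
                raise ValueError(f"unknown stages in stage_sequence: {bad}")
            if len(self.stage_sequence) != self.n_epochs:
                raise ValueError("stage_sequence length must equal n_epochs")


@dataclass
class ConfusionSpec:
    """Per-scorer stage confusion P(assigned | true) over (W, NREM, REM)."""

    matrix: np.ndarray
    p_artifact: float = 0.0  # probability of MOVEMENT/UNKNOWN insertion

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3) or np.any(self.matrix < 0):
            raise ValueError("confusion matrix must be a nonnegative 3x3 matrix")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("confusion matrix rows must sum to 1")
        if not 0.0 <= self.p_artifact <= 1.0:
            raise ValueError("p_artifact must lie in [0, 1]")


def _sample_stages(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.stage_sequence is not None:
        return np.asarray(cfg.stage_sequence, dtype=object)
    idx = np.empty(cfg.n_epochs, dtype=int)
    state = 0  # sessions start awake
    for t in range(cfg.n_epochs):
        idx[t] = state
        state = rng.choice(3, p=cfg.stage_transition[state])
    return np.asarray([STAGES3[i] for i in idx], dtype=object)


def _band_sos(fs: float) -> dict[str, np.ndarray]:
    return {
        name: signal.butter(4, (lo, hi), "bandpass", fs=fs, output="sos")
        for name, (lo, hi) in DEFAULT_BANDS.items()
    }


def _pink(shape: tuple[int, int], exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _stage_epoch(
    stage: str,
    n_rows: int,
    n_samp: int,
    sos: dict[str, np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_rows, n_samp) band-noise mixture drawn from the stage's weights."""
    weights = cfg.band_weights[stage]
    total = sum(weights.values())
    out = np.zeros((n_rows, n_samp))
    for name, w in weights.items():
        if w <= 0:
            continue
        band = signal.sosfilt(sos[name], rng.standard_normal((n_rows, n_samp)), axis=-1)
        sd = band.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += np.sqrt(w / total) * band / sd
    out += np.sqrt(cfg.pink_level) * _pink((n_rows, n_samp), cfg.pink_exponent, rng)
    return out


def generate_recording_pair(
    cfg: SimConfig,
) -> tuple[Recording, Recording, Hypnogram]:
    """Generate one PSG recording, its in-ear companion, and the true stages.

    The PSG recording carries the configured electrode potentials at
    ``fs_psg``; the in-ear channel is the mean of the scalp electrodes,
    polyphase-resampled to ``fs_inear``, attenuated and contaminated with
    white noise.  Both start at wall-clock zero.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _sample_stages(cfg, rng)
    n_samp = int(round(cfg.epoch_len_s * cfg.fs_psg))
    sos = _band_sos(cfg.fs_psg)
    n_el = len(cfg.electrodes)

    data = np.empty((n_el, cfg.n_epochs * n_samp))
    for t, stage in enumerate(truth):
        data[:, t * n_samp : (t + 1) * n_samp] = _stage_epoch(
            stage, n_el, n_samp, sos, cfg, rng
        )

    channels = {name: data[i] for i, name in enumerate(cfg.electrodes)}
    roles = {name: ELECTRODE_ROLES[name] for name in cfg.electrodes}
    psg = Recording(channels, {n: cfg.fs_psg for n in cfg.electrodes}, roles)

    scalp = [n for n in cfg.electrodes if ELECTRODE_ROLES[n] == "scalp-EEG"]
    if not scalp:
        raise ValueError("in-ear synthesis needs at least one scalp electrode")
    mix = np.mean([channels[n] for n in scalp], axis=0)
    ratio = Fraction(int(round(cfg.fs_inear)), int(round(cfg.fs_psg)))
    inear = signal.resample_poly(mix, ratio.numerator, ratio.denominator)
    inear = inear[: int(round(cfg.n_epochs * cfg.epoch_len_s * cfg.fs_inear))]
    inear = cfg.inear_attenuation * inear + rng.normal(
        0.0, cfg.inear_noise_sd * mix.std(), size=inear.shape
    )
    inear_rec = Recording({"CH1": inear}, {"CH1": cfg.fs_inear}, {"CH1": "in-ear"})

    return psg, inear_rec, Hypnogram(truth, cfg.epoch_len_s, source="PSG")


def generate_scorer_panel(
    truth: Hypnogram, specs: list[ConfusionSpec], seed: int, source: str | None = None
) -> ScorerPanel:
    """Draw J noisy hypnograms from per-scorer confusion matrices.

    Epoch t of scorer j is drawn from row ``truth[t]`` of spec j; with
    probability ``p_artifact`` the label is replaced by MOVEMENT or UNKNOWN
    (equiprobable).
    """
    if len(specs) == 0:
        raise ValueError("need at least one ConfusionSpec")
    rng = np.random.default_rng(seed)
    src = source if source is not None else truth.source
    stage_idx = {s: i for i, s in enumerate(STAGES3)}
    true_idx = np.array([stage_idx[l] for l in truth.labels])
    hyps = []
    for j, spec in enumerate(specs):
        labels = np.empty(len(truth), dtype=object)
        for t, ti in enumerate(true_idx):
            labels[t] = STAGES3[rng.choice(3, p=spec.matrix[ti])]
        if spec.p_artifact > 0:
            hit = rng.random(len(truth)) < spec.p_artifact
            kinds = rng.choice(["MOVEMENT", "UNKNOWN"], size=len(truth))
            labels[hit] = kinds[hit]
        hyps.append(Hypnogram(labels, truth.epoch_len, source=src, scorer=j))
    return ScorerPanel(hyps)


def inject_flat_epochs(
    rec: Recording, channel: str, fraction: float, seed: int, epoch_len_s: float = 30.0
) -> Recording:
    """Replace a uniformly sampled fraction of one channel's epochs by a
    constant (the epoch mean), emulating contact-loss segments."""
    if channel not in rec.channels:
        raise KeyError(f"unknown channel {channel!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = rec.copy()
    x = out.channels[channel]
    n_samp = int(round(epoch_len_s * rec.fs[channel]))
    n_ep = len(x) // n_samp
    n_flat = int(round(fraction * n_ep))
    rng = np.random.default_rng(seed)
    for t in rng.choice(n_ep, size=n_flat, replace=False):
        seg = x[t * n_samp : (t + 1) * n_samp]
        seg[:] = seg.mean()
    return out
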