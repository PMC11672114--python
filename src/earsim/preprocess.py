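"""Preprocessing: zero-phase band-pass filtering, bipolar derivations,
in-ear amplitude scaling, alignment/trimming, epoching and noisy-epoch
flagging.

PSG channels are filtered 0.2–35 Hz and the in-ear channel 0.5–35 Hz
(4th-order Butterworth, forward–backward so the phase is zero).  The in-ear
signal is then rescaled by the standard-deviation ratio of a PSG reference
(by default the mean std across scalp-EEG derivations) to the in-ear data,
matching amplitude ranges across devices.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .core import EpochedSignal, Recording, ROLE_SCALP
from .montage import MONTAGE_21, derivation_parts, infer_role

#: band edges per device role
FILTER_BANDS = {"PSG": (0.2, 35.0), "in-ear": (0.5, 35.0)}

DEFAULT_FLAT_TOL = 1e-9
DEFAULT_CHANNEL_EXCLUDE_FRAC = 0.5


def bandpass(
    rec: Recording, role: str, order: int = 4, band: tuple[float, float] | None = None
) -> Recording:
    """Zero-phase Butterworth band-pass of every channel of a recording.

    ``role`` selects the device band ("PSG": 0.2-35 Hz, "in-ear":
    0.5-35 Hz) unless ``band`` overrides it.
    """
    if band is None:
        if role not in FILTER_BANDS:
            raise ValueError(f"role must be one of {sorted(FILTER_BANDS)}, got {role!r}")
        band = FILTER_BANDS[role]
    out = rec.copy()
    for name, x in out.channels.items():
        nyq = rec.fs[name] / 2.0
        if band[1] >= nyq:
            raise ValueError(
                f"upper band edge {band[1]} Hz >= Nyquist {nyq} Hz for {name!r}"
            )
        sos = signal.butter(order, band, "bandpass", fs=rec.fs[name], output="sos")
        out.channels[name] = signal.sosfiltfilt(sos, x)
    return out


def materialize_montage(
    rec: Recording, channels: list[str] | None = None
) -> Recording:
    """Build requested derivations (e.g. C3-M2 = C3 - M2) from electrode
    potentials; unipolar names pass through."""
    if channels is None:
        channels = list(MONTAGE_21)
    out_channels: dict[str, np.ndarray] = {}
    out_fs: dict[str, float] = {}
    out_roles: dict[str, str] = {}
    for name in channels:
        parts = derivation_parts(name)
        missing = [p for p in parts if p not in rec.channels]
        if missing:
            raise KeyError(f"derivation {name!r} needs missing electrodes {missing}")
        if len(parts) == 1:
            x = rec.channels[parts[0]].copy()
            fs = rec.fs[parts[0]]
        else:
            a, b = parts
            if rec.fs[a] != rec.fs[b]:
                raise ValueError(f"cannot derive {name!r} across sampling rates")
            x = rec.channels[a] - rec.channels[b]
            fs = rec.fs[a]
        out_channels[name] = x
        out_fs[name] = fs
        out_roles[name] = infer_role(name)
    return Recording(out_channels, out_fs, out_roles, rec.start_offset)


def scale_inear(
    inear: Recording, psg: Recording, reference: str = "mean-scalp"
) -> Recording:
    """Rescale the in-ear channel by the PSG/in-ear standard-deviation ratio.

    ``reference`` is either ``"mean-scalp"`` (mean std across scalp-EEG
    channels of ``psg``, robust to one bad channel) or a PSG channel name.
    """
    if reference == "mean-scalp":
        stds = [psg.channels[n].std() for n in psg.names if psg.roles[n] == ROLE_SCALP]
        if not stds:
            raise ValueError("PSG recording has no scalp-EEG channels to reference")
        ref_std = float(np.mean(stds))
    else:
        if reference not in psg.channels:
            raise KeyError(f"reference channel {reference!r} not in PSG recording")
        ref_std = float(psg.channels[reference].std())
    out = inear.copy()
    for name, x in out.channels.items():
        sd = x.std()
        if sd == 0:
            raise ValueError(f"in-ear channel {name!r} is constant; cannot scale")
        out.channels[name] = x * (ref_std / sd)
    return out


def align_and_trim(
    psg: Recording, inear: Recording, offset_s: float = 0.0
) -> tuple[Recording, Recording]:
    """Crop both recordings to their overlapping wall-clock interval.

    ``offset_s`` is the start of the in-ear stream relative to the PSG
    stream (positive: in-ear started later); it replaces the manual
    artifact-based synchronization performed in the lab.
    """
    start_psg = psg.start_offset
    start_inear = inear.start_offset + offset_s
    t0 = max(start_psg, start_inear)
    t1 = min(start_psg + psg.duration(), start_inear + inear.duration())
    if t1 - t0 <= 0:
        raise ValueError("recordings do not overlap in time")

    def crop(rec: Recording, start: float) -> Recording:
        out = rec.copy()
        for name, x in out.channels.items():
            fs = rec.fs[name]
            i0 = int(round((t0 - start) * fs))
            i1 = int(round((t1 - start) * fs))
            out.channels[name] = x[i0:i1]
        out.start_offset = 0.0
        return out

    return crop(psg, start_psg), crop(inear, start_inear)


def epoch_and_flag(
    rec: Recording,
    epoch_len_s: float = 30.0,
    flat_tol: float = DEFAULT_FLAT_TOL,
    channel_exclude_frac: float = DEFAULT_CHANNEL_EXCLUDE_FRAC,
) -> EpochedSignal:
    """Cut non-overlapping epochs at native rates and flag flat ones.

    An epoch is noisy when its peak-to-peak amplitude is <= ``flat_tol``
    (no reliable brain activity); a channel whose noisy fraction exceeds
    ``channel_exclude_frac`` is excluded from analysis.  The trailing
    partial epoch is dropped.
    """
    epochs: dict[str, np.ndarray] = {}
    noisy: dict[str, np.ndarray] = {}
    excluded: set[str] = set()
    for name, x in rec.channels.items():
        n_samp = int(round(epoch_len_s * rec.fs[name]))
        n_ep = len(x) // n_samp
        if n_ep < 1:
            raise ValueError(f"channel {name!r} shorter than one epoch")
        mat = x[: n_ep * n_samp].reshape(n_ep, n_samp)
        epochs[name] = mat
        mask = np.ptp(mat, axis=1) <= flat_tol
        noisy[name] = mask
        if mask.mean() > channel_exclude_frac:
            excluded.add(name)
    return EpochedSignal(
        epochs, dict(rec.fs), dict(rec.roles), epoch_len_s, noisy, excluded
    )
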