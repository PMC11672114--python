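"""The 21-channel PSG montage investigated in the study design.

Ten electrode potentials (two mastoids, six scalp-EEG, two EOG) give rise to
21 analysis channels: the two mastoid references, six bipolar and six
unipolar scalp-EEG derivations, four bipolar and two unipolar EOG
derivations, and the mastoid-to-mastoid derivation.  The single in-ear
channel is named ``CH1``.
"""
from __future__ import annotations

from .core import ROLE_EOG, ROLE_INEAR, ROLE_MASTOID, ROLE_SCALP

#: electrode potentials recorded by the PSG device
ELECTRODES = ("M1", "M2", "C3", "C4", "F3", "F4", "O1", "O2", "E1", "E2")

ELECTRODE_ROLES = {
    "M1": ROLE_MASTOID,
    "M2": ROLE_MASTOID,
    "C3": ROLE_SCALP,
    "C4": ROLE_SCALP,
    "F3": ROLE_SCALP,
    "F4": ROLE_SCALP,
    "O1": ROLE_SCALP,
    "O2": ROLE_SCALP,
    "E1": ROLE_EOG,
    "E2": ROLE_EOG,
}

#: the 21 PSG channels (set Q): name -> role
MONTAGE_21 = {
    "M1": ROLE_MASTOID,
    "M2": ROLE_MASTOID,
    "C3-M2": ROLE_SCALP,
    "F3-M2": ROLE_SCALP,
    "O1-M2": ROLE_SCALP,
    "C4-M1": ROLE_SCALP,
    "F4-M1": ROLE_SCALP,
    "O2-M1": ROLE_SCALP,
    "C3": ROLE_SCALP,
    "C4": ROLE_SCALP,
    "F3": ROLE_SCALP,
    "F4": ROLE_SCALP,
    "E1-M1": ROLE_EOG,
    "E1-M2": ROLE_EOG,
    "E2-M1": ROLE_EOG,
    "E2-M2": ROLE_EOG,
    "E1": ROLE_EOG,
    "E2": ROLE_EOG,
    "O1": ROLE_SCALP,
    "O2": ROLE_SCALP,
    "M2-M1": ROLE_SCALP,  # mastoid-to-mastoid analysed among the scalp set
}

INEAR_CHANNEL = "CH1"


def infer_role(name: str) -> str:
    """Role of a channel name, deriving bipolar roles from the minuend."""
    if name == INEAR_CHANNEL:
        return ROLE_INEAR
    if name in MONTAGE_21:
        return MONTAGE_21[name]
    head = name.split("-")[0]
    if head in ELECTRODE_ROLES:
        return ELECTRODE_ROLES[head]
    raise KeyError(f"cannot infer role of channel {name!r}")


def derivation_parts(name: str) -> tuple[str, ...]:
    """Electrodes needed to build a channel (1 for unipolar, 2 for bipolar)."""
    parts = tuple(name.split("-"))
    if not all(p in ELECTRODE_ROLES for p in parts):
        raise KeyError(f"unknown electrodes in derivation {name!r}")
    return parts
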