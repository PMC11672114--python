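"""File interchange: EDF signals, hypnogram CSVs and YAML configs.

Hypnogram dialect: CSV with header ``epoch_index,label``, one row per
30-second epoch, labels uppercase from
{W, N1, N2, N3, REM, MOVEMENT, UNKNOWN} (or the merged {W, NREM, REM}).
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from . import edf as _edf
from .core import Hypnogram, Recording, STAGES3, STAGES_FULL
from .montage import infer_role
from .synth import ConfusionSpec, SimConfig

_VALID_LABELS = set(STAGES_FULL) | set(STAGES3)


def read_edf(path: str | Path, roles: dict[str, str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Channel roles are inferred from the montage naming convention unless
    given explicitly.
    """
    channels, fs = _edf.read_edf(path)
    if roles is None:
        roles = {name: infer_role(name) for name in channels}
    return Recording(channels, fs, roles)


def write_edf(path: str | Path, rec: Recording) -> None:
    _edf.write_edf(path, rec.channels, rec.fs)


def read_hypnogram(
    path: str | Path,
    map_to_3: bool = True,
    source: str = "PSG",
    scorer: str | int | None = None,
    epoch_len: float = 30.0,
) -> Hypnogram:
    """Read a hypnogram CSV, validating every label.

    Unknown tokens raise with the offending line number; with ``map_to_3``
    the N1/N2/N3 labels are merged into NREM.  MOVEMENT/UNKNOWN rows are
    retained — downstream steps carry and honour the exclusion flag.
    """
    labels = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty hypnogram file")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            token = row[-1].strip().upper()
            if token not in _VALID_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown stage label {token!r}")
            labels.append(token)
    hyp = Hypnogram(np.array(labels, dtype=object), epoch_len, source, scorer)
    return hyp.map3() if map_to_3 else hyp


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "label"])
        for t, label in enumerate(hyp.labels):
            writer.writerow([t, label])


def sim_config_to_yaml(cfg: SimConfig, path: str | Path) -> None:
    data = {
        "n_epochs": cfg.n_epochs,
        "epoch_len_s": cfg.epoch_len_s,
        "fs_psg": cfg.fs_psg,
        "fs_inear": cfg.fs_inear,
        "electrodes": list(cfg.electrodes),
        "stage_transition": cfg.stage_transition.tolist(),
        "band_weights": cfg.band_weights,
        "pink_exponent": cfg.pink_exponent,
        "pink_level": cfg.pink_level,
        "inear_attenuation": cfg.inear_attenuation,
        "inear_noise_sd": cfg.inear_noise_sd,
        "seed": cfg.seed,
        "stage_sequence": list(cfg.stage_sequence) if cfg.stage_sequence else None,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def sim_config_from_yaml(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    if data.get("electrodes") is not None:
        data["electrodes"] = tuple(data["electrodes"])
    if data.get("stage_sequence") is not None:
        data["stage_sequence"] = tuple(data["stage_sequence"])
    return SimConfig(**{k: v for k, v in data.items() if v is not None or k == "stage_sequence"})


def load_config(path: str | Path) -> dict:
    """Load a pipeline config (YAML mapping); see docs/methods.md for keys."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: pipeline config must be a YAML mapping")
    return data


def confusion_specs_from_config(entries: list) -> list[ConfusionSpec]:
    return [
        ConfusionSpec(np.asarray(e["matrix"], dtype=float), float(e.get("p_artifact", 0.0)))
        for e in entries
    ]
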