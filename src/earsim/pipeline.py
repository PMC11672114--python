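"""End-to-end orchestration: simulate (or ingest) -> preprocess -> consensus
-> agreement -> features -> selection+similarity -> reports.

Everything is driven by one YAML config (see ``default_config``) and a seed;
equal configs and seeds give byte-identical artifacts.  Artifacts are plain
CSV/JSON (plus EDF for the signals) in the output directory.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .agreement import agreement_tables, cohen_kappa, fleiss_kappa, stage_prf
from .consensus import ConsensusResult, consensus_labels, intersection_labels
from .core import Hypnogram, Recording, ScorerPanel, STAGES3
from .features import FeatureParams, build_feature_dataset
from .montage import MONTAGE_21, INEAR_CHANNEL
from .preprocess import (
    align_and_trim,
    bandpass,
    epoch_and_flag,
    materialize_montage,
    scale_inear,
)
from .report import plot_score_distributions, stage_count_table, summarize
from .similarity import similarity_report
from .stats import compare_stage_scores, stat_report_to_dict
from .synth import ConfusionSpec, SimConfig, generate_recording_pair, generate_scorer_panel

log = logging.getLogger("earsim")

#: reliable PSG scorers vs noisier in-ear scorers (study-like panel of 3)
DEFAULT_PSG_CONFUSION = [
    [0.92, 0.06, 0.02],
    [0.03, 0.92, 0.05],
    [0.03, 0.10, 0.87],
]
DEFAULT_INEAR_CONFUSION = [
    [0.80, 0.15, 0.05],
    [0.07, 0.83, 0.10],
    [0.08, 0.27, 0.65],
]


def default_config() -> dict:
    return {
        "subject": "S01",
        "simulation": {
            "n_epochs": 40,
            "seed": 0,
            "n_scorers": 3,
        },
        "preprocess": {
            "offset_s": 0.0,
            "montage": list(MONTAGE_21),
            "reference": "mean-scalp",
            "flat_tol": 1e-9,
            "channel_exclude_frac": 0.5,
            "filter_order": 4,
        },
        "similarity": {
            "k_grid": None,
            "m_min": 5,
            "estimator": "kde",
            "include_psg_pairs": True,
        },
        "report": {"plots": False},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _sim_config(sim: dict) -> SimConfig:
    keys = (
        "n_epochs", "epoch_len_s", "fs_psg", "fs_inear", "electrodes",
        "stage_transition", "band_weights", "pink_exponent", "pink_level",
        "inear_attenuation", "inear_noise_sd", "seed", "stage_sequence",
    )
    kwargs = {k: sim[k] for k in keys if k in sim}
    if "electrodes" in kwargs:
        kwargs["electrodes"] = tuple(kwargs["electrodes"])
    if kwargs.get("stage_sequence") is not None:
        kwargs["stage_sequence"] = tuple(kwargs["stage_sequence"])
    return SimConfig(**kwargs)


def _panels(sim: dict, truth: Hypnogram) -> tuple[ScorerPanel, ScorerPanel]:
    n = int(sim.get("n_scorers", 3))
    seed = int(sim.get("seed", 0))
    psg_specs = [
        ConfusionSpec(np.asarray(m, dtype=float))
        for m in sim.get("psg_confusion", [DEFAULT_PSG_CONFUSION] * n)
    ]
    inear_specs = [
        ConfusionSpec(np.asarray(m, dtype=float))
        for m in sim.get("inear_confusion", [DEFAULT_INEAR_CONFUSION] * n)
    ]
    panel_psg = generate_scorer_panel(truth, psg_specs, seed + 1, source="PSG")
    panel_inear = generate_scorer_panel(truth, inear_specs, seed + 2, source="in-ear")
    return panel_psg, panel_inear


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline; returns the artifact paths.

    ``config`` is a mapping (or a YAML path) overriding
    :func:`default_config`.  A ``simulation`` section generates the inputs;
    an ``inputs`` section (paths to EDFs and per-scorer hypnogram CSVs)
    ingests real files instead.
    """
    if not isinstance(config, dict):
        config = eio.load_config(config)
    cfg = _merge(default_config(), config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    subject = cfg["subject"]
    timing: dict[str, float] = {}

    def tic(stage: str):
        timing[stage] = time.perf_counter()

    def toc(stage: str):
        timing[stage] = round(time.perf_counter() - timing[stage], 3)
        log.info("stage %s: %.3fs", stage, timing[stage])

    # ------------------------------------------------------------------ input
    tic("input")
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("psg_edf", "inear_edf", "hypnograms_psg", "hypnograms_inear"):
            if key not in inp:
                raise ValueError(f"inputs section is missing {key!r}")
        for p in [inp["psg_edf"], inp["inear_edf"], *inp["hypnograms_psg"], *inp["hypnograms_inear"]]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        psg_raw = eio.read_edf(inp["psg_edf"])
        inear_raw = eio.read_edf(inp["inear_edf"])
        panel_psg = ScorerPanel([
            eio.read_hypnogram(p, source="PSG", scorer=j)
            for j, p in enumerate(inp["hypnograms_psg"])
        ])
        panel_inear = ScorerPanel([
            eio.read_hypnogram(p, source="in-ear", scorer=j)
            for j, p in enumerate(inp["hypnograms_inear"])
        ])
    else:
        sim_cfg = _sim_config(cfg["simulation"])
        psg_raw, inear_raw, truth = generate_recording_pair(sim_cfg)
        panel_psg, panel_inear = _panels(cfg["simulation"], truth)
        eio.write_edf(out / "psg.edf", psg_raw)
        eio.write_edf(out / "inear.edf", inear_raw)
        eio.write_hypnogram(out / "truth.csv", truth)
        artifacts["truth"] = out / "truth.csv"
    for j, hyp in enumerate(panel_psg.hypnograms):
        eio.write_hypnogram(out / f"hypnogram_psg_scorer{j}.csv", hyp)
    for j, hyp in enumerate(panel_inear.hypnograms):
        eio.write_hypnogram(out / f"hypnogram_inear_scorer{j}.csv", hyp)
    toc("input")

    # ------------------------------------------------------------- preprocess
    tic("preprocess")
    pp = cfg["preprocess"]
    order = int(pp["filter_order"])
    psg_f = bandpass(psg_raw, "PSG", order=order)
    inear_f = bandpass(inear_raw, "in-ear", order=order)
    psg_m = materialize_montage(psg_f, pp["montage"])
    inear_s = scale_inear(inear_f, psg_m, pp["reference"])
    psg_t, inear_t = align_and_trim(psg_m, inear_s, float(pp["offset_s"]))
    ep_psg = epoch_and_flag(psg_t, 30.0, pp["flat_tol"], pp["channel_exclude_frac"])
    ep_inear = epoch_and_flag(inear_t, 30.0, pp["flat_tol"], pp["channel_exclude_frac"])
    n_epochs = min(ep_psg.n_epochs, ep_inear.n_epochs)
    toc("preprocess")

    # -------------------------------------------------------------- consensus
    tic("consensus")
    cons_psg = consensus_labels(panel_psg)
    cons_inear = consensus_labels(panel_inear)
    inter = intersection_labels(cons_psg, cons_inear)
    eio.write_hypnogram(out / "consensus_psg.csv", Hypnogram(cons_psg.labels, source="PSG"))
    eio.write_hypnogram(out / "consensus_inear.csv", Hypnogram(cons_inear.labels, source="in-ear"))
    _write_json(out / "consensus.json", {
        "psg": {
            "soft_agreement": cons_psg.soft_agreement.tolist(),
            "ranking": cons_psg.ranking.tolist(),
            "n_ties": int(cons_psg.tie_mask.sum()),
        },
        "inear": {
            "soft_agreement": cons_inear.soft_agreement.tolist(),
            "ranking": cons_inear.ranking.tolist(),
            "n_ties": int(cons_inear.tie_mask.sum()),
        },
        "intersection": {
            "counts": inter.counts,
            "n_retained": inter.n_retained,
            "n_epochs": len(inter.mask),
        },
    })
    pd.DataFrame({
        "epoch_index": np.flatnonzero(inter.mask),
        "label": inter.labels,
    }).to_csv(out / "intersection.csv", index=False)
    artifacts["consensus"] = out / "consensus.json"
    artifacts["intersection"] = out / "intersection.csv"
    toc("consensus")

    # -------------------------------------------------------------- agreement
    tic("agreement")
    cohen_rows = [
        {
            "subject": subject,
            "scorer": j,
            "kappa": cohen_kappa(panel_psg.hypnograms[j], panel_inear.hypnograms[j]),
        }
        for j in range(min(panel_psg.n_scorers, panel_inear.n_scorers))
    ]
    fleiss_rows = [
        {"subject": subject, "source": "PSG", "kappa": fleiss_kappa(panel_psg)},
        {"subject": subject, "source": "in-ear", "kappa": fleiss_kappa(panel_inear)},
    ]
    gold, pred = cons_psg.labels, cons_inear.labels
    usable = ~np.isin(gold.astype(str), ("MOVEMENT", "UNKNOWN")) & ~np.isin(
        pred.astype(str), ("MOVEMENT", "UNKNOWN")
    )
    prf_rows = []
    for stage in STAGES3:
        res = stage_prf(gold[usable], pred[usable], stage)
        prf_rows.append({
            "subject": subject, "stage": stage,
            "precision": res.precision, "recall": res.recall, "f1": res.f1,
            "undefined_precision": res.undefined_precision, "missing": res.missing,
        })
    tables = agreement_tables(cohen_rows, fleiss_rows, prf_rows)
    for name, df in tables.items():
        df.to_csv(out / f"agreement_{name}.csv", index=False)
        artifacts[f"agreement_{name}"] = out / f"agreement_{name}.csv"
    toc("agreement")

    # ---------------------------------------------------------------- features
    tic("features")
    inter_crop = intersection_labels(
        cons_psg.labels[:n_epochs], cons_inear.labels[:n_epochs]
    )
    params = FeatureParams()
    datasets: dict[str, dict] = {}
    roles: dict[str, str] = {}
    for epoched in (ep_psg, ep_inear):
        for name in epoched.good_channels():
            datasets[name] = build_feature_dataset(
                epoched, inter_crop, name, subject, params
            )
            roles[name] = epoched.roles[name]
    tidy_rows = []
    for chan, per_stage in datasets.items():
        for stage, fd in per_stage.items():
            if fd is None:
                continue
            melted = fd.data.reset_index(names="epoch_index").melt(
                id_vars="epoch_index", var_name="feature", value_name="value"
            )
            melted.insert(0, "stage", stage)
            melted.insert(0, "channel", chan)
            melted.insert(0, "subject", subject)
            tidy_rows.append(melted)
    features_df = pd.concat(tidy_rows, ignore_index=True) if tidy_rows else pd.DataFrame()
    features_df.to_csv(out / "features.csv", index=False)
    artifacts["features"] = out / "features.csv"
    toc("features")

    # --------------------------------------------------- selection + similarity
    tic("similarity")
    sim = cfg["similarity"]
    scores, feat_jsd = similarity_report(
        datasets,
        roles,
        subject=subject,
        inear_channel=INEAR_CHANNEL,
        include_psg_pairs=bool(sim["include_psg_pairs"]),
        k_grid=sim["k_grid"],
        m_min=int(sim["m_min"]),
        estimator=sim["estimator"],
    )
    scores.to_csv(out / "similarity.csv", index=False)
    feat_jsd.to_csv(out / "similarity_per_feature.csv", index=False)
    artifacts["similarity"] = out / "similarity.csv"
    toc("similarity")

    # ------------------------------------------------------------------ report
    tic("report")
    if not scores.empty:
        summarize(scores).to_csv(out / "table_jsdfsi.csv")
        artifacts["table_jsdfsi"] = out / "table_jsdfsi.csv"
        stage_groups = {
            s: scores.loc[
                (scores["stage"] == s) & (scores["pair_class"] == "PSG-to-in-ear"),
                "score",
            ].to_numpy()
            for s in STAGES3
        }
        stats_out = {}
        try:
            stats_out["jsdfsi_by_stage"] = stat_report_to_dict(
                compare_stage_scores(stage_groups)
            )
        except ValueError as exc:
            stats_out["jsdfsi_by_stage"] = {"skipped": str(exc)}
        _write_json(out / "stats.json", stats_out)
        artifacts["stats"] = out / "stats.json"
    counts_psg = {s: int((cons_psg.labels == s).sum()) for s in STAGES3}
    counts_inear = {s: int((cons_inear.labels == s).sum()) for s in STAGES3}
    stage_count_table({
        "PSG": counts_psg,
        "In-ear-EEG": counts_inear,
        "PSG ∩ In-ear-EEG": inter.counts,
    }).to_csv(out / "table_stage_counts.csv")
    artifacts["table_stage_counts"] = out / "table_stage_counts.csv"
    if cfg["report"]["plots"] and not scores.empty:
        plot_score_distributions(scores, out / "figures")
    _write_json(out / "timing.json", timing)
    toc("report")

    return artifacts
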