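"""End-to-end orchestration: simulate/load -> preprocess -> cluster ->
back-fit -> features -> statistics.

The pipeline reproduces the analysis chain of a within-subject emotion
study: per-trial microstate templates are estimated from GFP-peak maps by
AAHC, averaged into emotion-condition templates and a global template,
label-aligned down the hierarchy, and back-fitted to each trial's epoch.
Per-trial features (durations, occurrences, coverages, transition
probabilities) are averaged per subject x emotion; frequency bands whose
mean GEV falls below the gate threshold (default 70%) are excluded from
statistics; the remaining features are compared across emotions with
normality-gated repeated-measures tests and Bonferroni post hocs, and
transition probabilities with paired tests against the neutral reference.

Everything is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .containers import EEGEpoch, MicrostateFeatures, TemplateSet
from .core import aahc, extract_peak_maps
from .errors import ConfigurationError, MstateError
from .features import (EMOTIONS, average_by_condition, categorize_valence,
                       compute_features, features_to_frame)
from .hierarchy import average_template_sets, backfit, sort_templates
from .preprocess import (BROADBAND, STANDARD_BANDS, bandpass, preprocess_epochs,
                         split_bands)
from .simulate import SimConfig, generate_study
from .stats import bonferroni_posthoc, gate_bands, omnibus_repeated_measures, paired_test

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "BandResult", "run_pipeline",
           "analyze_band"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``manifest`` points at recorded data (EDF or delimited matrices
    plus a trials manifest CSV) or ``sim`` describes a synthetic study.
    """

    sim: SimConfig | None = None
    manifest: str | Path | None = None
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    n_states: int = 4
    epoch_window_s: float = 2.0
    backfit_mode: str = "samplewise"      # or "peaks"
    gev_gate: float = 0.70
    reject_threshold_uv: float = 100.0
    broadband: tuple[float, float] = (BROADBAND.low_hz, BROADBAND.high_hz)
    notch_hz: float | None = None
    smoothing_samples: int = 0
    transition_adjust: str = "none"       # or "holm" across the 12 transitions
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ConfigurationError("n_states must be >= 2")
        if not 0.0 <= self.gev_gate <= 1.0:
            raise ConfigurationError("gev_gate must lie in [0, 1]")
        if self.backfit_mode not in ("samplewise", "peaks"):
            raise ConfigurationError("backfit_mode must be samplewise|peaks")
        if self.transition_adjust not in ("none", "holm"):
            raise ConfigurationError("transition_adjust must be none|holm")
        if self.sim is None and self.manifest is None:
            self.sim = SimConfig(seed=self.seed)


@dataclass
class PipelineResult:
    trial_features: pd.DataFrame
    subject_features: pd.DataFrame
    excluded_subjects: list[str]
    gev_by_band: dict[str, float]
    included_bands: list[str]
    stats: pd.DataFrame
    global_templates: dict[str, TemplateSet]
    condition_templates: dict[str, dict[str, TemplateSet]]
    provenance: dict = field(default_factory=dict)


def _condition_of(epoch: EEGEpoch) -> str:
    if epoch.valence is not None:
        return categorize_valence(epoch.valence)
    return epoch.condition


@dataclass
class BandResult:
    """Per-band outcome of the cluster -> hierarchy -> back-fit chain."""

    features: list[MicrostateFeatures]
    mean_gev: float                        # mean per-trial clustering GEV
    global_templates: TemplateSet
    condition_templates: dict[str, TemplateSet]
    trial_templates: list[TemplateSet]     # sorted (label-aligned) per trial
    label_sequences: list                  # LabelSequence per trial


def analyze_band(
    epochs: list[EEGEpoch], k: int, backfit_mode: str = "samplewise",
    emotions: tuple[str, ...] = EMOTIONS, smoothing_samples: int = 0,
) -> BandResult:
    """Cluster, build the template hierarchy, back-fit and extract features
    for one band's epochs."""
    trial_sets: list[TemplateSet] = []
    for ep in epochs:
        maps, weights, _ = extract_peak_maps(ep)
        if maps.shape[0] < k:
            raise MstateError(
                f"epoch {ep.subject_id}/{ep.trial_id} has {maps.shape[0]} GFP "
                f"peaks, fewer than k={k}"
            )
        tset = aahc(maps, k, weights)
        tset.band = ep.band
        tset.meta["epoch_index"] = len(trial_sets)
        trial_sets.append(tset)

    conditions = [_condition_of(ep) for ep in epochs]
    by_cond: dict[str, list[TemplateSet]] = {}
    for cond, tset in zip(conditions, trial_sets):
        by_cond.setdefault(cond, []).append(tset)

    cond_sets = {cond: average_template_sets(sets)
                 for cond, sets in by_cond.items()}
    order = [c for c in emotions if c in cond_sets] + [
        c for c in cond_sets if c not in emotions]
    global_set = average_template_sets([cond_sets[c] for c in order])
    global_set.level = "global"
    cond_sets = {c: sort_templates(s, global_set) for c, s in cond_sets.items()}

    feats: list[MicrostateFeatures] = []
    sorted_trials: list[TemplateSet] = []
    sequences = []
    for ep, cond, tset in zip(epochs, conditions, trial_sets):
        aligned = sort_templates(tset, cond_sets[cond])
        sorted_trials.append(aligned)
        seq = backfit(ep, aligned, peaks_only=(backfit_mode == "peaks"),
                      smoothing_samples=smoothing_samples)
        seq.condition = cond
        sequences.append(seq)
        feats.append(compute_features(seq))

    mean_gev = float(np.mean([t.gev for t in trial_sets]))
    return BandResult(
        features=feats, mean_gev=mean_gev, global_templates=global_set,
        condition_templates=cond_sets, trial_templates=sorted_trials,
        label_sequences=sequences,
    )


def _stats_stage(
    subject_features: pd.DataFrame, bands: list[str],
    emotions: tuple[str, ...] = EMOTIONS, n_states: int = 4,
    transition_adjust: str = "none",
) -> pd.DataFrame:
    """Omnibus + post hoc tests per feature and band on complete cases."""
    rows = []
    feature_cols = MicrostateFeatures.feature_names(n_states)
    scalar_cols = [c for c in feature_cols if not c.startswith("p_")]
    trans_cols = [c for c in feature_cols if c.startswith("p_")]

    for band in bands:
        sub = subject_features[subject_features["band"] == band]
        wide_all = {}
        for col in feature_cols:
            w = sub.pivot(index="subject", columns="condition", values=col)
            w = w.reindex(columns=list(emotions)).dropna()
            wide_all[col] = w

        for col in scalar_cols:
            w = wide_all[col]
            if len(w) < 3:
                continue
            res = omnibus_repeated_measures(w.to_numpy(), tuple(w.columns))
            rows.append({
                "band": band, "feature": col, "test": res.test_name,
                "statistic": res.statistic, "df": str(res.df),
                "p": res.p_value, "p_adjusted": np.nan,
                "effect_size": res.effect_size,
                "effect_size_name": res.effect_size_name,
                "correction": res.correction, "groups": "omnibus",
            })
            if res.p_value < 0.05:
                for ph in bonferroni_posthoc(w.to_numpy(), tuple(w.columns)):
                    rows.append({
                        "band": band, "feature": col, "test": ph.test_name,
                        "statistic": ph.statistic, "df": str(ph.df),
                        "p": ph.extra.get("p_raw", ph.p_value),
                        "p_adjusted": ph.p_value,
                        "effect_size": ph.effect_size,
                        "effect_size_name": ph.effect_size_name,
                        "correction": ph.correction,
                        "groups": " vs ".join(ph.groups),
                    })

        # transitions: neutral is the reference condition; per-test p
        # values by default, optional Holm adjustment across the 12
        # features within each comparison
        others = [e for e in emotions if e != "neutral"]
        trans_rows: list[dict] = []
        for col in trans_cols:
            w = wide_all[col]
            if len(w) < 3 or "neutral" not in w.columns:
                continue
            for other in others:
                res = paired_test(w[other].to_numpy(), w["neutral"].to_numpy())
                trans_rows.append({
                    "band": band, "feature": col, "test": res.test_name,
                    "statistic": res.statistic, "df": str(res.df),
                    "p": res.p_value, "p_adjusted": np.nan,
                    "effect_size": res.effect_size,
                    "effect_size_name": res.effect_size_name,
                    "correction": res.correction,
                    "groups": f"{other} vs neutral",
                })
        if transition_adjust == "holm" and trans_rows:
            import pingouin as pg

            for other in others:
                idx = [i for i, r in enumerate(trans_rows)
                       if r["groups"].startswith(other)]
                _, p_adj = pg.multicomp(
                    [trans_rows[i]["p"] for i in idx], method="holm")
                for i, p in zip(idx, p_adj):
                    trans_rows[i]["p_adjusted"] = float(p)
                    trans_rows[i]["correction"] = "Holm"
        rows.extend(trans_rows)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write all outputs to
    ``config.out_dir``.

    A stage failure is logged with its stage name and re-raised; when an
    output directory is set, partial outputs are kept alongside a FAILED
    marker file recording the stage and the error.
    """
    progress = {"stage": "acquire"}
    try:
        return _run_pipeline_stages(config, progress)
    except Exception as err:
        logger.error("pipeline failed in stage %r: %s", progress["stage"], err)
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text(
                f"stage: {progress['stage']}\nerror: {err!r}\n")
        raise


def _run_pipeline_stages(config: PipelineConfig, progress: dict) -> PipelineResult:
    t0 = time.time()
    prov: dict = {"seed": config.seed, "stages": {}}

    # ------------------------------------------------ acquire
    if config.manifest is not None:
        raw_epochs = msio.read_study(config.manifest)
        prov["input"] = str(config.manifest)
    else:
        study = generate_study(config.sim)
        raw_epochs = study.epochs
        prov["input"] = "simulated"
        prov["sim_seed"] = config.sim.seed
    prov["stages"]["acquire"] = {"n_epochs": len(raw_epochs),
                                 "elapsed_s": round(time.time() - t0, 3)}

    # ------------------------------------------------ preprocess
    progress["stage"] = "preprocess"
    t1 = time.time()
    windowed = []
    n_win = None
    for ep in raw_epochs:
        n_win = int(round(config.epoch_window_s * ep.sfreq))
        if ep.n_samples < n_win:
            raise ConfigurationError(
                f"epoch shorter ({ep.n_samples}) than analysis window ({n_win})"
            )
        ep = ep.copy_with(data=ep.data[:, :n_win])  # initial window of each trial
        ep = bandpass(ep, *config.broadband)
        windowed.append(ep)
    clean, rejections = preprocess_epochs(
        windowed, threshold_uv=config.reject_threshold_uv,
        notch_hz=config.notch_hz,
    )
    if not clean:
        raise MstateError("all epochs rejected; nothing to analyze")
    band_specs = [b for b in STANDARD_BANDS if b.name in config.bands]
    band_epochs: dict[str, list[EEGEpoch]] = {b.name: [] for b in band_specs}
    for ep in clean:
        for b in band_specs:
            band_epochs[b.name].append(bandpass(ep, b.low_hz, b.high_hz, band=b.name))
    prov["stages"]["preprocess"] = {
        "n_rejected": len(rejections),
        "rejections": rejections,
        "window_samples": n_win,
        "elapsed_s": round(time.time() - t1, 3),
    }

    # ------------------------------------------------ cluster + features
    progress["stage"] = "cluster"
    t2 = time.time()
    all_feats: list[MicrostateFeatures] = []
    gev_by_band: dict[str, float] = {}
    global_templates: dict[str, TemplateSet] = {}
    condition_templates: dict[str, dict[str, TemplateSet]] = {}
    for band, eps_list in band_epochs.items():
        band_res = analyze_band(eps_list, config.n_states, config.backfit_mode,
                                smoothing_samples=config.smoothing_samples)
        all_feats.extend(band_res.features)
        gev_by_band[band] = band_res.mean_gev
        global_templates[band] = band_res.global_templates
        condition_templates[band] = band_res.condition_templates
    prov["stages"]["cluster"] = {
        "gev_by_band": gev_by_band,
        "elapsed_s": round(time.time() - t2, 3),
    }

    # ------------------------------------------------ aggregate + gate
    progress["stage"] = "aggregate"
    trial_table = features_to_frame(all_feats)
    subject_table, flagged = average_by_condition(all_feats)
    included, gate_report = gate_bands(gev_by_band, config.gev_gate)
    complete = subject_table[~subject_table["subject"].isin(flagged)]
    prov["stages"]["aggregate"] = {
        "excluded_subjects": flagged,
        "gate": gate_report,
    }

    # ------------------------------------------------ statistics
    progress["stage"] = "statistics"
    t3 = time.time()
    stats_table = _stats_stage(complete, included, n_states=config.n_states,
                               transition_adjust=config.transition_adjust)
    prov["stages"]["stats"] = {"n_tests": len(stats_table),
                               "elapsed_s": round(time.time() - t3, 3)}
    prov["total_elapsed_s"] = round(time.time() - t0, 3)

    result = PipelineResult(
        trial_features=trial_table, subject_features=subject_table,
        excluded_subjects=flagged, gev_by_band=gev_by_band,
        included_bands=included, stats=stats_table,
        global_templates=global_templates,
        condition_templates=condition_templates, provenance=prov,
    )

    if config.out_dir is not None:
        progress["stage"] = "write"
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trial_table.to_csv(out / "features_trial.csv", index=False)
        subject_table.to_csv(out / "features_subject.csv", index=False)
        stats_table.to_csv(out / "statistics.csv", index=False)
        pd.DataFrame(rejections, columns=[
            "epoch_index", "subject", "trial", "channel", "sample", "value_uv",
        ]).to_csv(out / "rejections.csv", index=False)
        for band, gset in global_templates.items():
            msio.write_template_set(gset, out / f"templates_global_{band}.csv")
            for cond, cset in condition_templates[band].items():
                msio.write_template_set(
                    cset, out / f"templates_{cond}_{band}.csv")
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        logger.info("pipeline outputs written to %s", out)
    return result
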