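"""Reading and writing the package's file formats.

Recordings come in as EDF files (via MNE's reader) or as delimited text
matrices — channels x samples, with a header row of channel labels.
Outputs (template sets, label sequences, feature tables, rejection and
statistics reports, ground truth) are plain CSV; simulation configs are
YAML.  EDF export is not provided; simulated studies are written as
delimited matrices, one file per epoch, plus a trials manifest CSV
(subject, trial, condition, valence, file).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import UNASSIGNED, EEGEpoch, LabelSequence, TemplateSet
from .errors import InvalidInputError

__all__ = [
    "read_edf",
    "read_matrix",
    "write_matrix",
    "write_template_set",
    "read_template_set",
    "write_labels",
    "read_labels",
    "write_study",
    "read_study",
    "save_config",
    "load_config",
]


def read_edf(path: str | Path, **meta) -> EEGEpoch:
    """Load an EDF recording as one broadband epoch (microvolts)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return EEGEpoch(data=data, sfreq=float(raw.info["sfreq"]),
                    ch_names=tuple(raw.ch_names), **meta)


def read_matrix(path: str | Path, sfreq: float, **meta) -> EEGEpoch:
    """Load a delimited channels x samples matrix with a channel-label
    header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    labels = tuple(str(c) for c in df.columns)
    data = df.to_numpy(dtype=float).T  # file rows = samples
    return EEGEpoch(data=data, sfreq=sfreq, ch_names=labels, **meta)


def write_matrix(epoch: EEGEpoch, path: str | Path) -> None:
    """Write an epoch as a CSV with channels as columns, samples as rows."""
    pd.DataFrame(epoch.data.T, columns=list(epoch.ch_names)).to_csv(
        path, index=False, float_format="%.6g"
    )


def write_template_set(tset: TemplateSet, path: str | Path) -> None:
    """Serialize a template set as channels x K CSV with a label header."""
    df = pd.DataFrame(tset.maps.T, columns=list(tset.labels))
    df.to_csv(path, index=False)
    side = Path(path).with_suffix(".meta.yaml")
    side.write_text(yaml.safe_dump(
        {"gev": float(tset.gev), "band": tset.band, "level": tset.level}
    ))


def read_template_set(path: str | Path) -> TemplateSet:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return TemplateSet(
        maps=df.to_numpy(dtype=float).T, labels=tuple(df.columns),
        gev=float(meta.get("gev", float("nan"))),
        band=meta.get("band", "broadband"), level=meta.get("level", "trial"),
    )


def write_labels(seq: LabelSequence, path: str | Path) -> None:
    pd.DataFrame({"sample": np.arange(seq.n_samples),
                  "label": seq.labels}).to_csv(path, index=False)


def read_labels(path: str | Path, sfreq: float, n_states: int,
                **meta) -> LabelSequence:
    df = pd.read_csv(path)
    return LabelSequence(labels=df["label"].to_numpy(dtype=int),
                         sfreq=sfreq, n_states=n_states, **meta)


def write_gfp(gfp_series: np.ndarray, path: str | Path) -> None:
    """Write a GFP series as CSV (sample index, gfp)."""
    pd.DataFrame({"sample": np.arange(len(gfp_series)),
                  "gfp": np.asarray(gfp_series, float)}).to_csv(
        path, index=False)


def write_study(study, out_dir: str | Path) -> Path:
    """Write a simulated study: one matrix CSV per epoch, per-sample
    ground-truth labels, the generating config as YAML, and a trials
    manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    save_config({
        "n_channels": cfg.n_channels, "sfreq": cfg.sfreq,
        "n_states": cfg.n_states, "dwell_ms": cfg.dwell_ms,
        "carrier_hz": cfg.carrier_hz, "snr": cfg.snr,
        "amplitude_uv": cfg.amplitude_uv, "epoch_s": cfg.epoch_s,
        "n_subjects": cfg.n_subjects,
        "n_trials_per_condition": cfg.n_trials_per_condition,
        "subject_rotation_deg": cfg.subject_rotation_deg,
        "noise_smoothing": cfg.noise_smoothing, "seed": cfg.seed,
        "condition_params": {
            k: {kk: (vv.tolist() if hasattr(vv, "tolist") else vv)
                for kk, vv in dict(v).items()}
            for k, v in cfg.condition_params.items()
        },
    }, out / "sim_config.yaml")
    rows = []
    for i, (ep, truth) in enumerate(zip(study.epochs, study.truths)):
        fname = f"epoch_{i:04d}_{ep.subject_id}_{ep.trial_id}.csv"
        write_matrix(ep, out / fname)
        rows.append({
            "subject": ep.subject_id, "trial": ep.trial_id,
            "condition": ep.condition, "valence": ep.valence,
            "file": fname, "sfreq": ep.sfreq,
            "dwell_ms": truth.dwell_ms,
        })
        pd.DataFrame({"sample": np.arange(truth.state_sequence.size),
                      "state": truth.state_sequence}).to_csv(
            out / f"truth_{i:04d}.csv", index=False)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_study(manifest_path: str | Path) -> list[EEGEpoch]:
    """Load epochs listed in a trials manifest CSV (columns: subject,
    trial, condition, valence, file, sfreq)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject", "trial", "condition", "file", "sfreq"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"manifest missing columns {sorted(required - set(df.columns))}"
        )
    epochs = []
    for _, row in df.iterrows():
        path = manifest_path.parent / str(row["file"])
        loader = read_edf if path.suffix.lower() == ".edf" else read_matrix
        kwargs = {} if path.suffix.lower() == ".edf" else {"sfreq": float(row["sfreq"])}
        ep = loader(path, **kwargs)
        ep.subject_id = str(row["subject"])
        ep.trial_id = str(row["trial"])
        ep.condition = str(row["condition"])
        if "valence" in row and not pd.isna(row["valence"]):
            ep.valence = int(row["valence"])
        epochs.append(ep)
    return epochs


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
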