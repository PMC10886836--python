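"""Synthetic multichannel EEG with planted microstate structure.

The generator produces the forward model the analysis assumes: a small set
of orthogonal, average-referenced template topographies; a hidden Markov
state sequence with geometric (memoryless) dwell times; a rectified-
sinusoid carrier that amplitude-modulates the active template (so GFP local
maxima are dense, two per carrier cycle, and well defined); and spatially
smoothed additive noise scaled to a requested signal-to-noise ratio.

Every quantity the downstream pipeline estimates — templates, per-sample
state labels, dwell times, transition probabilities — is returned as ground
truth, which makes full-pipeline parameter recovery testable.

A simulated study is a subjects x conditions x trials grid of epochs.
Conditions (negative / neutral / positive emotion, by default) differ in
their planted dwell times and/or transition matrices; subjects differ by a
small random rotation of the template maps (topographic heterogeneity);
each trial carries a valence rating (1-9) consistent with its condition.
All randomness derives from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .containers import EEGEpoch, normalize_map
from .errors import ConfigurationError, DimensionError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_templates",
    "uniform_transition_matrix",
    "sample_state_sequence",
    "synthesize_epoch",
    "generate_study",
    "StudyData",
]

#: valence bins per condition: negative 1-3, neutral 4-5, positive 6-9
_VALENCE_BINS: dict[str, tuple[int, ...]] = {
    "negative": (1, 2, 3),
    "neutral": (4, 5),
    "positive": (6, 7, 8, 9),
}


def uniform_transition_matrix(n_states: int) -> np.ndarray:
    """Row-stochastic matrix with zero diagonal and uniform off-diagonal."""
    if n_states < 2:
        raise ConfigurationError("need at least 2 states for transitions")
    m = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(m, 0.0)
    return m


def _check_transition_matrix(m: np.ndarray, n_states: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n_states, n_states):
        raise ConfigurationError(f"transition matrix must be {n_states}x{n_states}")
    if np.any(np.diag(m) != 0.0):
        raise ConfigurationError("transition matrix diagonal must be exactly 0")
    if np.any(m < 0):
        raise ConfigurationError("transition probabilities must be nonnegative")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
        raise ConfigurationError("transition matrix rows must sum to 1 (1e-12)")
    return m


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reflect the emulated recording setup — 59 scalp channels, four
    microstate classes with ~100-150 ms dwell — at a reduced 250 Hz sampling
    rate (set ``sfreq=1000`` to mirror the original hardware).  Per-
    condition overrides plant group differences: by default the negative
    condition dwells longer (140 ms) than neutral (125 ms) and positive
    (110 ms), a duration ordering the pipeline should recover.
    """

    n_channels: int = 59
    sfreq: float = 250.0
    n_states: int = 4
    dwell_ms: float = 125.0
    transition_matrix: np.ndarray | None = None
    carrier_hz: float = 10.0
    snr: float = 4.0
    amplitude_uv: float = 10.0
    epoch_s: float = 2.0
    n_subjects: int = 10
    n_trials_per_condition: int = 5
    condition_params: Mapping[str, Mapping] = field(default_factory=lambda: {
        "negative": {"dwell_ms": 140.0},
        "neutral": {"dwell_ms": 125.0},
        "positive": {"dwell_ms": 110.0},
    })
    subject_rotation_deg: float = 5.0
    noise_smoothing: int = 5          # channel-ring moving-average width; 1 = iid
    rectified_carrier: bool = False   # True: |sin| envelope (energy at DC/2f)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.n_states < 1:
            raise ConfigurationError("counts must be >= 1 (channels >= 2)")
        if self.dwell_ms <= 0 or self.snr <= 0 or self.sfreq <= 0:
            raise ConfigurationError("dwell_ms, snr and sfreq must be positive")
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ConfigurationError("subject/trial counts must be >= 1")
        if self.transition_matrix is None:
            self.transition_matrix = uniform_transition_matrix(self.n_states)
        self.transition_matrix = _check_transition_matrix(
            self.transition_matrix, self.n_states
        )

    def for_condition(self, condition: str) -> tuple[float, np.ndarray]:
        """(dwell_ms, transition_matrix) with condition overrides applied."""
        over = dict(self.condition_params.get(condition, {}))
        dwell = float(over.get("dwell_ms", self.dwell_ms))
        tm = over.get("transition_matrix", self.transition_matrix)
        return dwell, _check_transition_matrix(np.asarray(tm, float), self.n_states)


@dataclass
class GroundTruth:
    """Planted truth for one epoch (or, in a study, shared fields)."""

    templates: np.ndarray                 # (K, n_channels) subject-level maps
    state_sequence: np.ndarray            # per-sample state index
    dwell_ms: float
    transition_matrix: np.ndarray


@dataclass
class StudyData:
    """A full simulated study: epochs plus everything planted in them."""

    epochs: list[EEGEpoch]
    truths: list[GroundTruth]             # parallel to epochs
    base_templates: np.ndarray            # (K, n_channels) before subject rotation
    subject_templates: dict[str, np.ndarray]
    config: SimConfig
    conditions: tuple[str, ...]


def make_templates(n_channels: int, n_states: int, seed: int) -> np.ndarray:
    """Random orthonormal zero-mean template topographies.

    The average-reference constraint removes one spatial degree of freedom,
    so at most ``n_channels - 1`` mutually orthogonal zero-mean maps exist;
    asking for more is a configuration error.  Deterministic given ``seed``.
    """
    if n_states > n_channels - 1:
        raise ConfigurationError(
            f"cannot build {n_states} orthogonal zero-mean maps over "
            f"{n_channels} channels (subspace rank {n_channels - 1})"
        )
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, n_states))
    x -= x.mean(axis=0, keepdims=True)          # project onto zero-mean subspace
    q, r = np.linalg.qr(x)
    q *= np.sign(np.diag(r))                    # fix QR sign ambiguity
    return q.T.copy()                           # (K, n_channels), unit columns of Q


def sample_state_sequence(
    cfg: SimConfig,
    duration_s: float,
    condition: str = "",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hidden Markov state sequence with geometric dwell times.

    Run lengths are geometric with mean ``dwell_ms`` (converted to samples);
    the successor of each run is drawn from the transition-matrix row of the
    current state, so adjacent runs never share a state (zero diagonal).
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dwell_ms, tm = cfg.for_condition(condition) if condition else (
        cfg.dwell_ms, cfg.transition_matrix)
    n_samples = int(round(duration_s * cfg.sfreq))
    mean_samples = dwell_ms * cfg.sfreq / 1000.0
    if mean_samples < 1.0:
        raise ConfigurationError("dwell shorter than one sample")
    p_leave = 1.0 / mean_samples

    seq = np.empty(n_samples, dtype=int)
    state = int(rng.integers(cfg.n_states))
    pos = 0
    while pos < n_samples:
        run = int(rng.geometric(p_leave))
        end = min(pos + run, n_samples)
        seq[pos:end] = state
        pos = end
        if cfg.n_states > 1:
            state = int(rng.choice(cfg.n_states, p=tm[state]))
    return seq


def _smooth_ring(noise: np.ndarray, width: int) -> np.ndarray:
    """Moving average over a circular channel ring (crude volume-conduction
    surrogate); width 1 returns iid noise unchanged."""
    if width <= 1:
        return noise
    n_ch = noise.shape[0]
    out = np.zeros_like(noise)
    half = width // 2
    for off in range(-half, width - half):
        out += np.roll(noise, off, axis=0)
    return out / width


def synthesize_epoch(
    templates: np.ndarray,
    state_sequence: np.ndarray,
    cfg: SimConfig,
    condition: str = "",
    seed: int | None = None,
) -> tuple[EEGEpoch, GroundTruth]:
    """Render one epoch from templates and a state sequence.

    ``signal(t) = A * sin(2 pi f t) * template[state(t)] + noise`` with
    noise scaled so RMS(signal)/RMS(noise) equals ``cfg.snr``; the output
    is average-referenced.  With ``snr = inf`` the noise term is omitted.

    The carrier is a *signed* sinusoid: its amplitude envelope is the
    rectified ``|sin|`` (so GFP maxima are dense, two per cycle, aligned
    with the carrier extrema), while its spectral energy sits at the
    carrier frequency, so band-pass filtering around ``carrier_hz``
    preserves the planted structure.  Under the polarity equivalence of
    topographies the sign of the carrier is invisible to every downstream
    stage.  Set ``cfg.rectified_carrier=True`` for a strictly nonnegative
    envelope (spectral energy at DC and even harmonics instead).
    """
    templates = np.atleast_2d(np.asarray(templates, float))
    if templates.shape[1] != cfg.n_channels:
        raise DimensionError(
            f"templates have {templates.shape[1]} channels, config says "
            f"{cfg.n_channels}"
        )
    seq = np.asarray(state_sequence, int)
    if seq.min() < 0 or seq.max() >= templates.shape[0]:
        raise ConfigurationError("state sequence indexes unknown templates")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    t = np.arange(seq.size) / cfg.sfreq
    carrier = np.sin(2.0 * np.pi * cfg.carrier_hz * t)
    if cfg.rectified_carrier:
        carrier = np.abs(carrier)
    signal = cfg.amplitude_uv * carrier[None, :] * templates[seq].T

    if np.isfinite(cfg.snr):
        noise = _smooth_ring(
            rng.standard_normal(signal.shape), cfg.noise_smoothing
        )
        noise -= noise.mean(axis=0, keepdims=True)   # keep average reference
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        data = signal + noise * (sig_rms / (cfg.snr * noise_rms))
    else:
        data = signal
    data = data - data.mean(axis=0, keepdims=True)

    dwell_ms, tm = cfg.for_condition(condition) if condition else (
        cfg.dwell_ms, cfg.transition_matrix)
    epoch = EEGEpoch(data=data, sfreq=cfg.sfreq, condition=condition)
    truth = GroundTruth(
        templates=templates, state_sequence=seq,
        dwell_ms=dwell_ms, transition_matrix=tm,
    )
    return epoch, truth


def _rotate_templates(
    templates: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb each template by ``angle_deg`` toward a random zero-mean
    direction orthogonal to it, then re-orthonormalize the set.

    For small angles every output map correlates with its source at about
    cos(angle); the set stays orthonormal and average-referenced.
    """
    if angle_deg == 0:
        return templates.copy()
    k, n_ch = templates.shape
    theta = np.deg2rad(angle_deg)
    out = np.empty_like(templates)
    for i in range(k):
        d = rng.standard_normal(n_ch)
        d -= d.mean()
        d -= (d @ templates[i]) * templates[i]
        d /= np.linalg.norm(d)
        out[i] = np.cos(theta) * templates[i] + np.sin(theta) * d
    # re-orthonormalize (Gram-Schmidt keeps each map close to its source)
    for i in range(k):
        for j in range(i):
            out[i] -= (out[i] @ out[j]) * out[j]
        out[i] = normalize_map(out[i])
    return out


def _valence_for(condition: str, rng: np.random.Generator) -> int:
    bins = _VALENCE_BINS.get(condition)
    if bins is None:                        # custom condition names: mid-scale
        return 5
    return int(rng.choice(bins))


def generate_study(
    cfg: SimConfig, conditions: tuple[str, ...] = ("negative", "neutral", "positive")
) -> StudyData:
    """Simulate a full subjects x conditions x trials study.

    Each subject receives slightly rotated copies of the base templates
    (inter-subject topographic variability); each condition uses its
    planted dwell/transition parameters; each trial gets a valence rating
    from the bin matching its condition.  Fully reproducible from
    ``cfg.seed``: child generators are derived by fixed offsets.
    """
    base = make_templates(cfg.n_channels, cfg.n_states, cfg.seed)
    epochs: list[EEGEpoch] = []
    truths: list[GroundTruth] = []
    subject_templates: dict[str, np.ndarray] = {}

    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:02d}"
        rot_rng = np.random.default_rng(cfg.seed + 1000 + s)
        templ = _rotate_templates(base, cfg.subject_rotation_deg, rot_rng)
        subject_templates[sid] = templ
        for c, cond in enumerate(conditions):
            for tr in range(cfg.n_trials_per_condition):
                child = cfg.seed + 100_000 * (s + 1) + 1000 * (c + 1) + tr
                rng = np.random.default_rng(child)
                seq = sample_state_sequence(cfg, cfg.epoch_s, cond, rng)
                epoch, truth = synthesize_epoch(templ, seq, cfg, cond, seed=child + 7)
                epoch.subject_id = sid
                epoch.trial_id = f"{cond[:3]}{tr + 1:02d}"
                epoch.valence = _valence_for(cond, rng)
                epochs.append(epoch)
                truths.append(truth)
    return StudyData(
        epochs=epochs, truths=truths, base_templates=base,
        subject_templates=subject_templates, config=cfg,
        conditions=tuple(conditions),
    )
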