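"""Core data containers.

The package works on four in-memory objects:

``EEGEpoch``
    A channels x samples potential matrix in microvolts with its sampling
    rate, channel labels, frequency-band tag and trial metadata.
``TemplateSet``
    K normalized microstate topographies (zero channel-mean, unit L2 norm)
    with ordered class labels, the global explained variance they achieve,
    and the hierarchy level they were estimated at.
``LabelSequence``
    Per-sample microstate class indices for one epoch; ``UNASSIGNED`` (-1)
    marks samples where no label is defined (zero global field power).
``MicrostateFeatures``
    The 24-feature summary of one label sequence for K = 4: per-class mean
    duration (ms), occurrence rate (1/s), time coverage (%) and the K*(K-1)
    conditional transition probabilities.

Topographies are polarity-invariant throughout: a map and its negation
denote the same microstate, so every spatial comparison uses the absolute
Pearson correlation across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DimensionError, InvalidInputError

#: Sentinel label for samples with no defined microstate assignment.
UNASSIGNED: int = -1

#: Canonical microstate class names in estimation order.
CLASS_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")

BANDS = ("broadband", "theta", "alpha", "beta", "gamma")


@dataclass
class EEGEpoch:
    """One epoch of multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    sfreq
        Sampling frequency in Hz.
    ch_names
        Channel labels (10-20 names for real data); length must match rows.
    band
        One of ``broadband, theta, alpha, beta, gamma``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: Sequence[str] = ()
    band: str = "broadband"
    subject_id: str = ""
    trial_id: str = ""
    condition: str = ""
    valence: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("epoch contains non-finite values")
        if self.sfreq <= 0:
            raise InvalidInputError("sfreq must be positive")
        if not self.ch_names:
            self.ch_names = tuple(f"ch{i:03d}" for i in range(self.n_channels))
        if len(self.ch_names) != self.n_channels:
            raise DimensionError(
                f"{len(self.ch_names)} channel labels for {self.n_channels} channels"
            )
        if self.band not in BANDS:
            raise InvalidInputError(f"unknown band {self.band!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, **changes) -> "EEGEpoch":
        """Return a copy with ``data`` (and any metadata) replaced."""
        return replace(self, **changes)


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Project a topography onto the average-reference subspace and scale to
    unit L2 norm.  Raises for an all-constant map (zero spatial variance)."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidInputError("cannot normalize a spatially constant map")
    return v / n


@dataclass
class TemplateSet:
    """K microstate template maps plus the variance they explain.

    ``maps`` is ``(K, n_channels)`` with each row zero-mean and unit-norm.
    ``level`` records where in the averaging hierarchy the set was produced:
    ``trial``, ``condition`` or ``global``.
    """

    maps: np.ndarray
    labels: tuple[str, ...] = ()
    gev: float = float("nan")
    band: str = "broadband"
    level: str = "trial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not self.labels:
            self.labels = tuple(CLASS_LABELS[: self.k])
        if len(self.labels) != self.k:
            raise DimensionError("number of labels must equal number of maps")
        if len(set(self.labels)) != self.k:
            raise InvalidInputError("template labels must be unique")
        if not np.isnan(self.gev) and not 0.0 <= self.gev <= 1.0 + 1e-12:
            raise InvalidInputError(f"gev must lie in [0, 1], got {self.gev}")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels for one epoch."""

    labels: np.ndarray
    sfreq: float
    n_states: int
    subject_id: str = ""
    trial_id: str = ""
    condition: str = ""
    band: str = "broadband"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DimensionError("labels must be 1-D")
        bad = (self.labels != UNASSIGNED) & (
            (self.labels < 0) | (self.labels >= self.n_states)
        )
        if np.any(bad):
            raise InvalidInputError("labels outside [0, n_states) and not UNASSIGNED")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class MicrostateFeatures:
    """The per-trial (or per-subject-condition) microstate feature vector.

    For K classes: ``duration_ms[k]`` mean run length of class k in ms,
    ``occurrence_hz[k]`` runs of k per second of labeled time,
    ``coverage_pct[k]`` percent of labeled samples in class k, and
    ``transition_prob[i, j]`` the conditional probability that a run of i is
    immediately followed by a run of j (rows sum to 1 where class i has at
    least one outgoing transition; the diagonal is structurally zero).
    For K = 4 this is the standard 24-feature summary:
    4 durations + 4 occurrences + 4 coverages + 12 transition probabilities.
    """

    duration_ms: np.ndarray
    occurrence_hz: np.ndarray
    coverage_pct: np.ndarray
    transition_prob: np.ndarray
    n_states: int
    subject_id: str = ""
    trial_id: str = ""
    condition: str = ""
    band: str = "broadband"

    def __post_init__(self) -> None:
        k = self.n_states
        for name in ("duration_ms", "occurrence_hz", "coverage_pct"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise DimensionError(f"{name} must have shape ({k},)")
            setattr(self, name, arr)
        self.transition_prob = np.asarray(self.transition_prob, dtype=float)
        if self.transition_prob.shape != (k, k):
            raise DimensionError(f"transition_prob must have shape ({k}, {k})")

    @property
    def n_features(self) -> int:
        """3*K scalar features plus K*(K-1) off-diagonal transitions."""
        return 3 * self.n_states + self.n_states * (self.n_states - 1)

    def to_dict(self) -> dict[str, float]:
        """Flatten to the fixed CSV column schema
        (``A_dur .. D_cov, p_AB .. p_DC``)."""
        labels = CLASS_LABELS[: self.n_states]
        out: dict[str, float] = {}
        for k, lab in enumerate(labels):
            out[f"{lab}_dur"] = float(self.duration_ms[k])
        for k, lab in enumerate(labels):
            out[f"{lab}_occ"] = float(self.occurrence_hz[k])
        for k, lab in enumerate(labels):
            out[f"{lab}_cov"] = float(self.coverage_pct[k])
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i != j:
                    out[f"p_{li}{lj}"] = float(self.transition_prob[i, j])
        return out

    @staticmethod
    def feature_names(n_states: int = 4) -> list[str]:
        labels = CLASS_LABELS[:n_states]
        names = [f"{lab}_dur" for lab in labels]
        names += [f"{lab}_occ" for lab in labels]
        names += [f"{lab}_cov" for lab in labels]
        names += [
            f"p_{li}{lj}" for i, li in enumerate(labels)
            for j, lj in enumerate(labels) if i != j
        ]
        return names
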