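"""Preprocessing: broadband filter, band split, epoching, amplitude
rejection, average reference and baseline removal.

The contract mirrors a conventional scalp-EEG cleaning chain: a zero-phase
FIR band-pass at 3-80 Hz, an optional power-line notch, segmentation into
fixed non-overlapping windows, rejection of any segment whose absolute
amplitude exceeds 100 uV, average referencing, per-channel baseline (epoch
mean) removal, and a split into the four canonical frequency bands

    theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz, gamma 30-49 Hz.

Filtering is delegated to MNE's FIR designer (Hamming window, forward-
backward application), with the filter order scaled to the transition width
rather than fixed, so the attenuation contract holds at any sampling rate.
Artifact removal by ICA/PCA is out of scope for synthetic data; the
``artifact_hook`` argument of :func:`preprocess_epochs` lets real-data users
insert an external cleaning step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from mne.filter import filter_data, notch_filter

from .containers import EEGEpoch
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "STANDARD_BANDS",
    "bandpass",
    "split_bands",
    "segment",
    "reject_amplitude",
    "average_reference",
    "remove_baseline",
    "preprocess_epochs",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError(
                f"band {self.name}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


STANDARD_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 49.0),
)

BROADBAND = BandSpec("broadband", 3.0, 80.0)


def _filter(data: np.ndarray, sfreq: float, low: float, high: float) -> np.ndarray:
    with warnings.catch_warnings():
        # short synthetic epochs trigger MNE's filter-length advisories
        warnings.simplefilter("ignore")
        return filter_data(
            data, sfreq, l_freq=low, h_freq=high,
            method="fir", phase="zero", fir_window="hamming",
            fir_design="firwin", verbose="error",
        )


def bandpass(epoch: EEGEpoch, low_hz: float, high_hz: float,
             band: str | None = None) -> EEGEpoch:
    """Zero-phase FIR band-pass of one epoch.

    Out-of-band sinusoids are attenuated by at least 20 dB and in-band ones
    passed within 1 dB, outside the transition bands.  ``band`` optionally
    retags the output epoch.
    """
    nyq = epoch.sfreq / 2.0
    if not 0 < low_hz < high_hz:
        raise ConfigurationError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ConfigurationError(
            f"high edge {high_hz} Hz at or above Nyquist {nyq} Hz"
        )
    out = _filter(epoch.data, epoch.sfreq, low_hz, high_hz)
    return epoch.copy_with(data=out, band=band or epoch.band)


def apply_notch(epoch: EEGEpoch, freq_hz: float = 50.0) -> EEGEpoch:
    """Optional power-line notch filter (off by default in the pipeline;
    synthetic data carry no line noise)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = notch_filter(epoch.data, epoch.sfreq, freqs=freq_hz,
                           verbose="error")
    return epoch.copy_with(data=out)


def split_bands(epoch: EEGEpoch,
                bands: tuple[BandSpec, ...] = STANDARD_BANDS) -> list[EEGEpoch]:
    """Split a broadband epoch into band-limited copies (theta, alpha,
    beta, gamma by default)."""
    if epoch.band != "broadband":
        raise InvalidInputError(
            f"split_bands expects a broadband epoch, got {epoch.band!r}"
        )
    return [bandpass(epoch, b.low_hz, b.high_hz, band=b.name) for b in bands]


def segment(recording: EEGEpoch, window_s: float) -> list[EEGEpoch]:
    """Cut a continuous recording into non-overlapping ``window_s`` epochs.

    Windows are half-open ``[start, start + W)``; a trailing remainder
    shorter than one window is dropped.  A recording shorter than one
    window yields an empty list (with a warning in the log).
    """
    if window_s <= 0:
        raise ConfigurationError("window_s must be positive")
    w = int(round(window_s * recording.sfreq))
    n = recording.n_samples // w
    if n == 0:
        logger.warning(
            "recording of %d samples shorter than window of %d samples; "
            "no epochs produced", recording.n_samples, w,
        )
        return []
    out = []
    for i in range(n):
        out.append(recording.copy_with(
            data=recording.data[:, i * w:(i + 1) * w],
            trial_id=recording.trial_id or f"seg{i:03d}",
        ))
    return out


def reject_amplitude(
    epochs: list[EEGEpoch], threshold_uv: float = 100.0
) -> tuple[list[EEGEpoch], list[dict]]:
    """Drop epochs containing any sample with ``|value| > threshold_uv``.

    The threshold is strict (a value of exactly 100 uV is kept).  Returns
    the kept epochs unchanged plus a report of the first violation in each
    rejected epoch (epoch index, trial id, channel, sample, value).
    """
    kept: list[EEGEpoch] = []
    report: list[dict] = []
    for i, ep in enumerate(epochs):
        over = np.abs(ep.data) > threshold_uv
        if over.any():
            ch, smp = np.unravel_index(int(np.argmax(over)), over.shape)
            report.append({
                "epoch_index": i,
                "subject": ep.subject_id,
                "trial": ep.trial_id,
                "channel": ep.ch_names[ch],
                "sample": int(smp),
                "value_uv": float(ep.data[ch, smp]),
            })
        else:
            kept.append(ep)
    return kept, report


def average_reference(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract the instantaneous mean over channels from every sample."""
    if epoch.n_channels < 2:
        raise ConfigurationError("average reference requires >= 2 channels")
    return epoch.copy_with(data=epoch.data - epoch.data.mean(axis=0))


def remove_baseline(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract each channel's own epoch mean (DC offset removal).

    There is no pre-stimulus interval in continuous viewing data, so the
    baseline is taken as the whole-epoch mean per channel.
    """
    if epoch.n_channels < 2:
        raise ConfigurationError("baseline removal requires >= 2 channels")
    return epoch.copy_with(data=epoch.data - epoch.data.mean(axis=1, keepdims=True))


def preprocess_epochs(
    epochs: list[EEGEpoch],
    threshold_uv: float = 100.0,
    notch_hz: float | None = None,
    artifact_hook=None,
) -> tuple[list[EEGEpoch], list[dict]]:
    """Reject, (optionally) clean, reference and de-baseline a list of
    epochs.

    ``artifact_hook`` is an optional callable ``EEGEpoch -> EEGEpoch``
    applied after rejection — the insertion point for ICA/PCA-cleaned real
    data.
    """
    kept, report = reject_amplitude(epochs, threshold_uv)
    out = []
    for ep in kept:
        if notch_hz is not None:
            ep = apply_notch(ep, notch_hz)
        if artifact_hook is not None:
            ep = artifact_hook(ep)
        ep = remove_baseline(average_reference(ep))
        out.append(ep)
    return out, report
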