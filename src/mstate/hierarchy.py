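"""Template averaging hierarchy, label sorting, and back-fitting.

Microstate templates are estimated per trial, averaged into condition-
specific sets (negative / neutral / positive), and those into one global
set.  Because clustering labels are arbitrary per trial and polarity is
ambiguous, sets are aligned before averaging: an optimal one-to-one map
matching (maximizing total absolute spatial correlation, solved as a
linear assignment problem) gives the permutation, and each matched map is
flipped to correlate positively with its reference before the mean is
taken.  Sorting then propagates labels back down: condition sets are
sorted against the global set, trial sets against their condition set, so
class "A" means the same topography everywhere.

Back-fitting labels each epoch sample with the template of highest
absolute spatial correlation.  Two modes: ``samplewise`` labels every
sample independently; ``peaks`` labels only GFP peaks and propagates each
peak's label to the surrounding samples up to the midpoint between
adjacent peaks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import UNASSIGNED, EEGEpoch, LabelSequence, TemplateSet, normalize_map
from .core import gfp, gfp_peaks
from .errors import ConfigurationError, DimensionError

__all__ = ["sort_templates", "average_template_sets", "backfit",
           "smooth_labels"]

_LEVEL_UP = {"trial": "condition", "condition": "global", "global": "global"}


def _abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    an = a - a.mean(axis=1, keepdims=True)
    bn = b - b.mean(axis=1, keepdims=True)
    an /= np.linalg.norm(an, axis=1, keepdims=True)
    bn /= np.linalg.norm(bn, axis=1, keepdims=True)
    return np.abs(an @ bn.T)


def sort_templates(tset: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Permute a template set to best match a reference set.

    Solves the optimal one-to-one assignment maximizing the total absolute
    spatial correlation between matched maps (exact for any K via the
    Hungarian algorithm — greedy matching can fail on correlated maps).
    The returned set carries the reference's labels in reference order,
    with each map sign-aligned to its reference map.
    """
    if tset.k != reference.k:
        raise ConfigurationError("template sets must share K to be sorted")
    if tset.n_channels != reference.n_channels:
        raise DimensionError("template sets must share the channel count")
    c = _abs_corr_matrix(reference.maps, tset.maps)   # (K_ref, K_set)
    ref_idx, set_idx = linear_sum_assignment(-c)
    order = set_idx[np.argsort(ref_idx)]
    maps = tset.maps[order].copy()
    for i in range(reference.k):
        if maps[i] @ reference.maps[i] < 0:
            maps[i] = -maps[i]
    return TemplateSet(
        maps=maps, labels=reference.labels, gev=tset.gev,
        band=tset.band, level=tset.level,
        meta={**tset.meta, "sort_permutation": order},
    )


def average_template_sets(
    sets: list[TemplateSet], reference: TemplateSet | None = None
) -> TemplateSet:
    """Average aligned template sets into one set a level up the hierarchy.

    Each set is first sorted against ``reference`` (the first set when no
    reference is given); corresponding maps are then sign-aligned, averaged
    and renormalized.  The mean GEV of the inputs is carried along as a
    descriptive summary.
    """
    if not sets:
        raise ConfigurationError("cannot average an empty list of template sets")
    k = sets[0].k
    n_ch = sets[0].n_channels
    for s in sets:
        if s.k != k:
            raise ConfigurationError("all template sets must share K")
        if s.n_channels != n_ch:
            raise DimensionError("all template sets must share the channel count")
    ref = reference if reference is not None else sets[0]
    aligned = [sort_templates(s, ref) for s in sets]
    maps = np.empty((k, n_ch))
    for i in range(k):
        stack = np.array([s.maps[i] for s in aligned])  # already sign-aligned to ref
        maps[i] = normalize_map(stack.mean(axis=0))
    gevs = [s.gev for s in sets if not np.isnan(s.gev)]
    return TemplateSet(
        maps=maps, labels=ref.labels,
        gev=float(np.mean(gevs)) if gevs else float("nan"),
        band=sets[0].band, level=_LEVEL_UP.get(sets[0].level, "global"),
    )


def smooth_labels(labels: np.ndarray, window_samples: int) -> np.ndarray:
    """Majority-vote smoothing of a label sequence (off by default
    everywhere).

    Each sample takes the most frequent label in the centred window of
    ``2 * window_samples + 1``; ties keep the current label; UNASSIGNED
    samples are left untouched and do not vote.
    """
    if window_samples <= 0:
        return labels
    labels = np.asarray(labels, int)
    out = labels.copy()
    n = labels.size
    for t in range(n):
        if labels[t] == UNASSIGNED:
            continue
        lo, hi = max(0, t - window_samples), min(n, t + window_samples + 1)
        win = labels[lo:hi]
        win = win[win != UNASSIGNED]
        counts = np.bincount(win)
        best = int(np.argmax(counts))
        if counts[best] > counts[labels[t]]:
            out[t] = best
    return out


def backfit(
    epoch: EEGEpoch, templates: TemplateSet, peaks_only: bool = False,
    smoothing_samples: int = 0,
) -> LabelSequence:
    """Label every sample of an epoch with its best-matching template.

    A sample's label is the argmax over templates of the absolute spatial
    correlation with the sample's topography; zero-GFP samples get
    ``UNASSIGNED``.  With ``peaks_only`` the labels computed at GFP local
    maxima are propagated outward to the midpoint between adjacent peaks
    (and to the epoch edges beyond the first/last peak); an epoch with no
    GFP peak falls back to sample-wise labeling.  ``smoothing_samples``
    applies an optional majority-vote filter (see :func:`smooth_labels`);
    default off.  Invariant to global sign flips and positive rescaling of
    the data.
    """
    if epoch.n_channels != templates.n_channels:
        raise DimensionError(
            f"epoch has {epoch.n_channels} channels, templates "
            f"{templates.n_channels}"
        )
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    g = gfp(epoch)
    t = templates.maps - templates.maps.mean(axis=1, keepdims=True)
    t = t / np.linalg.norm(t, axis=1, keepdims=True)

    norms = np.sqrt(np.sum(data**2, axis=0))
    labels = np.full(epoch.n_samples, UNASSIGNED, dtype=int)
    ok = norms > 0
    if np.any(ok):
        corr = np.abs(t @ data[:, ok]) / norms[ok]
        labels[ok] = np.argmax(corr, axis=0)

    if peaks_only:
        peaks = gfp_peaks(g)
        if peaks.size > 0:
            prop = np.full(epoch.n_samples, UNASSIGNED, dtype=int)
            bounds = (peaks[:-1] + peaks[1:] + 1) // 2  # midpoints between peaks
            starts = np.concatenate(([0], bounds))
            ends = np.concatenate((bounds, [epoch.n_samples]))
            for p, s, e in zip(peaks, starts, ends):
                prop[s:e] = labels[p]
            labels = prop

    labels = smooth_labels(labels, smoothing_samples)

    return LabelSequence(
        labels=labels, sfreq=epoch.sfreq, n_states=templates.k,
        subject_id=epoch.subject_id, trial_id=epoch.trial_id,
        condition=epoch.condition, band=epoch.band,
    )
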