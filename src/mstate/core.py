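"""Global field power, GFP-peak extraction, GEV, and AAHC clustering.

Global field power (GFP) at sample t is the spatial standard deviation of
the average-referenced potential over the N electrodes,

    GFP(t) = sqrt( (1/N) * sum_n (U_n(t) - mean_n U_n(t))^2 ),

i.e. the uncorrected population SD across channels.  Its local maxima mark
the moments of highest topographic signal-to-noise ratio, and only the maps
at those maxima enter clustering.

Clustering is the atomize-and-agglomerate hierarchical algorithm (AAHC):
every input map starts as its own cluster; at each step the cluster that
contributes least to the global explained variance (GEV) is dissolved and
its members are reassigned, one by one, to the surviving cluster whose
centroid they correlate with most strongly in absolute value.  Polarity is
ignored throughout — a topography and its sign-flipped copy are the same
microstate — so all correlations are absolute Pearson correlations across
channels and centroids are sign-aligned means.

GEV of an assignment is the GFP^2-weighted mean squared spatial correlation
between each map and its assigned template:

    GEV = sum_t (GFP_t * C(u_t, T_a(t)))^2 / sum_t GFP_t^2
"""

from __future__ import annotations

import numpy as np

from .containers import EEGEpoch, TemplateSet, normalize_map
from .errors import ConfigurationError, UndefinedResultError

__all__ = [
    "gfp",
    "gfp_peaks",
    "spatial_correlation",
    "gev",
    "extract_peak_maps",
    "aahc",
]


def gfp(epoch: EEGEpoch | np.ndarray) -> np.ndarray:
    """Per-sample global field power of an epoch.

    Accepts an :class:`EEGEpoch` or a raw ``(n_channels, n_samples)`` array.
    Invariant to adding a common offset to all channels at a sample.
    """
    data = epoch.data if isinstance(epoch, EEGEpoch) else np.asarray(epoch, float)
    if data.shape[0] < 2:
        raise ConfigurationError("GFP requires at least 2 channels")
    return np.std(data, axis=0)  # population SD across channels


def gfp_peaks(series: np.ndarray, min_separation_samples: int = 1) -> np.ndarray:
    """Indices of strict local maxima of a GFP series.

    A sample is a peak when it is greater than both neighbours; a plateau
    that is a local maximum is resolved to its first sample.  Endpoints are
    never peaks.  When ``min_separation_samples > 1``, peaks closer than the
    separation are thinned greedily by descending height (ties by index).
    Series shorter than 3 samples have no interior sample and yield an
    empty result.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("GFP series must be 1-D")
    if x.size < 3:
        return np.array([], dtype=int)

    # Compress plateaus: for runs of equal values, compare run-level
    # neighbours and report the run's first sample.
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))            # first index of each run
    vals = x[starts]
    peaks = []
    for r in range(1, len(starts) - 1):
        if vals[r] > vals[r - 1] and vals[r] > vals[r + 1]:
            peaks.append(starts[r])
    peaks_arr = np.asarray(peaks, dtype=int)

    if min_separation_samples > 1 and peaks_arr.size > 1:
        order = np.lexsort((peaks_arr, -x[peaks_arr]))  # height desc, index asc
        kept: list[int] = []
        for idx in peaks_arr[order]:
            if all(abs(idx - k) >= min_separation_samples for k in kept):
                kept.append(int(idx))
        peaks_arr = np.sort(np.asarray(kept, dtype=int))
    return peaks_arr


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across channels of two topographies.

    Maps are re-centred to zero channel-mean before correlating, so the
    result is invariant to common offsets.  The sign is returned; polarity-
    invariant comparisons take the absolute value at the call site.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedResultError("correlation undefined for a constant map")
    return float(a @ b / (na * nb))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Absolute spatial correlations, ``(n_maps, n_templates)``.

    Both inputs are assumed zero-mean per row; rows need not be unit norm.
    """
    mn = np.linalg.norm(maps, axis=1, keepdims=True)
    tn = np.linalg.norm(templates, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (maps / mn) @ (templates / tn).T
    return np.abs(c)


def gev(
    maps: np.ndarray,
    gfp_weights: np.ndarray,
    templates: np.ndarray,
    assignment: np.ndarray,
) -> float:
    """Global explained variance of ``assignment`` of maps to templates.

    Parameters
    ----------
    maps
        ``(n_maps, n_channels)`` topographies (any scale; re-centred and
        normalized internally).
    gfp_weights
        Per-map GFP values (the GFP of the sample the map was taken from).
    templates
        ``(K, n_channels)`` template maps.
    assignment
        Per-map template index in ``[0, K)``.
    """
    maps = np.atleast_2d(np.asarray(maps, float))
    templates = np.atleast_2d(np.asarray(templates, float))
    w = np.asarray(gfp_weights, float)
    a = np.asarray(assignment, int)
    denom = float(np.sum(w**2))
    if denom == 0:
        raise UndefinedResultError("GEV undefined: total GFP is zero")
    maps = maps - maps.mean(axis=1, keepdims=True)
    templates = templates - templates.mean(axis=1, keepdims=True)
    c = _corr_matrix(maps, templates)[np.arange(len(a)), a]
    return float(np.sum((w * c) ** 2) / denom)


def extract_peak_maps(
    epoch: EEGEpoch, min_separation_samples: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GFP-peak topographies of an epoch.

    Returns ``(maps, weights, peak_indices)`` where ``maps`` holds the
    normalized (zero-mean, unit-norm) topographies at the GFP local maxima
    and ``weights`` the GFP values there.
    """
    g = gfp(epoch)
    idx = gfp_peaks(g, min_separation_samples)
    maps = np.empty((idx.size, epoch.n_channels))
    for i, t in enumerate(idx):
        maps[i] = normalize_map(epoch.data[:, t])
    return maps, g[idx], idx


def _centroid(members: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Sign-aligned, renormalized mean of member maps.

    Members are flipped to correlate positively with ``ref`` before
    averaging, which makes the centroid well defined under the polarity
    equivalence; the mean is then recentred and scaled to unit norm.
    """
    signs = np.sign(members @ ref)
    signs[signs == 0] = 1.0
    return normalize_map((signs[:, None] * members).mean(axis=0))


def aahc(
    maps: np.ndarray,
    k_target: int,
    gfp_weights: np.ndarray | None = None,
    criterion: str = "merge",
) -> TemplateSet:
    """Agglomerative (AAHC) clustering of topographies.

    Every input map starts as its own cluster; clusters are combined one
    step at a time until ``k_target`` remain.  Deterministic for a given
    input order (ties broken toward lower cluster indices).  Three
    schedules are available:

    * ``"merge"`` (default): at each step, merge the *pair* of clusters
      whose union loses the least global explained variance, evaluating
      the union's actual (sign-aligned, renormalized mean) centroid.
      Exact pairwise accounting avoids the classic greedy failure where a
      genuine small cluster is dissolved while a dominant state stays
      split in two.
    * ``"gev_loss"``: atomization with one-step lookahead — dissolve the
      cluster whose members retain the most variance from their next-best
      surviving clusters (measured against the *current* centroids), and
      reassign each member to its best cluster by absolute correlation.
    * ``"contribution"``: classical atomization — dissolve the cluster
      with the smallest absolute GEV contribution and reassign its
      members.

    Parameters
    ----------
    maps
        ``(n_maps, n_channels)`` topographies; normalized internally.
    k_target
        Number of microstate classes to retain.
    gfp_weights
        GFP value of the sample each map came from; defaults to 1 for all
        maps (unweighted).

    Returns
    -------
    TemplateSet with the final centroids, the achieved GEV, and the
    per-input-map assignment in ``meta["assignment"]``.
    """
    maps = np.atleast_2d(np.asarray(maps, float))
    n_maps = maps.shape[0]
    if not 1 <= k_target <= n_maps:
        raise ConfigurationError(
            f"k_target must be in [1, {n_maps}], got {k_target}"
        )
    if gfp_weights is None:
        gfp_weights = np.ones(n_maps)
    w = np.asarray(gfp_weights, float)
    if w.shape != (n_maps,):
        raise ConfigurationError("gfp_weights must have one entry per map")
    if criterion not in ("merge", "gev_loss", "contribution"):
        raise ConfigurationError(f"unknown criterion {criterion!r}")

    norm_maps = np.array([normalize_map(m) for m in maps])

    # cluster state: list of member-index arrays + centroid matrix
    members: list[list[int]] = [[i] for i in range(n_maps)]
    centroids = norm_maps.copy()

    def contribution(ci: int) -> float:
        idx = members[ci]
        c = np.abs(norm_maps[idx] @ centroids[ci])
        return float(np.sum((w[idx] * c) ** 2))

    if criterion == "merge":
        assignment, centroids = _aahc_merge(norm_maps, w, k_target)
        total_gev = gev(norm_maps, w, centroids, assignment)
        return TemplateSet(
            maps=centroids,
            gev=total_gev,
            meta={"assignment": assignment, "gfp_weights": w},
        )

    while len(members) > k_target:
        contribs = np.array([contribution(ci) for ci in range(len(members))])
        if criterion == "gev_loss":
            # what each cluster's members would still explain from their
            # next-best surviving cluster
            all_corr = np.abs(norm_maps @ centroids.T)   # (n_maps, n_clusters)
            losses = np.empty(len(members))
            for ci in range(len(members)):
                idx = members[ci]
                others = np.delete(all_corr[idx], ci, axis=1)
                best_other = others.max(axis=1) if others.size else np.zeros(len(idx))
                losses[ci] = contribs[ci] - float(np.sum((w[idx] * best_other) ** 2))
            worst = int(np.argmin(losses))
        else:
            worst = int(np.argmin(contribs))  # first minimum: low-index tie rule
        orphan_idx = members.pop(worst)
        centroids = np.delete(centroids, worst, axis=0)
        for i in orphan_idx:
            c = np.abs(centroids @ norm_maps[i])
            best = int(np.argmax(c))
            members[best].append(i)
        # recompute centroids of clusters that gained members
        for ci in range(len(members)):
            centroids[ci] = _centroid(norm_maps[members[ci]], centroids[ci])

    assignment = np.empty(n_maps, dtype=int)
    for ci, idx in enumerate(members):
        assignment[idx] = ci
    total_gev = gev(norm_maps, w, centroids, assignment)
    return TemplateSet(
        maps=centroids,
        gev=total_gev,
        meta={"assignment": assignment, "gfp_weights": w},
    )


def _aahc_merge(
    norm_maps: np.ndarray, w: np.ndarray, k_target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise agglomeration by exact GEV merge cost.

    Merge costs are cached and only the rows touching a freshly merged
    cluster are recomputed, so the schedule costs O(n^2) centroid
    evaluations overall.
    """
    n_maps = norm_maps.shape[0]
    members: list[list[int] | None] = [[i] for i in range(n_maps)]
    centroids: list[np.ndarray | None] = [m.copy() for m in norm_maps]
    contribs: list[float] = [float(w[i] ** 2) for i in range(n_maps)]

    def union_stats(ci: int, cj: int) -> tuple[float, np.ndarray]:
        idx = members[ci] + members[cj]
        cen = _centroid(norm_maps[idx], centroids[ci])
        c = np.abs(norm_maps[idx] @ cen)
        return float(np.sum((w[idx] * c) ** 2)), cen

    alive = list(range(n_maps))
    costs: dict[tuple[int, int], float] = {}
    for a in range(len(alive)):
        for b in range(a + 1, len(alive)):
            i, j = alive[a], alive[b]
            u, _ = union_stats(i, j)
            costs[(i, j)] = contribs[i] + contribs[j] - u

    while len(alive) > k_target:
        (ci, cj) = min(costs, key=lambda p: (costs[p], p))
        u, cen = union_stats(ci, cj)
        members[ci] = members[ci] + members[cj]
        centroids[ci] = cen
        contribs[ci] = u
        members[cj] = None
        centroids[cj] = None
        alive.remove(cj)
        costs = {p: c for p, c in costs.items() if cj not in p and ci not in p}
        for other in alive:
            if other == ci:
                continue
            pair = (min(ci, other), max(ci, other))
            u2, _ = union_stats(*pair)
            costs[pair] = contribs[pair[0]] + contribs[pair[1]] - u2

    assignment = np.empty(n_maps, dtype=int)
    final_centroids = np.empty((k_target, norm_maps.shape[1]))
    for out_i, ci in enumerate(alive):
        assignment[members[ci]] = out_i
        final_centroids[out_i] = centroids[ci]
    return assignment, final_centroids
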