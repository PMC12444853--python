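"""Waveform sorting: cluster SN spikes into putative single units.

Each waveform is decomposed with a 4-level discrete Haar wavelet; the
coefficients whose distributions across spikes deviate most from normality
(largest Kolmogorov-Smirnov distance to a fitted normal) are kept as
features, on the rationale that multimodal coefficients are the ones that
separate units. The features are clustered with a Gaussian-mixture model
whose component count is selected by BIC; spikes with a maximum posterior
below 0.5 are left unassigned (-1), as are members of clusters smaller than
``min_cluster_size``. Because population-level feature selection favours
the coefficients that separate the dominant groups, each cluster is then
recursively re-clustered on features re-selected within it (recursive
bisection); shifted-duplicate subclusters are recombined afterwards. Clusters whose waveforms do not cohere around their
template (mean waveform correlation below ``noise_corr_floor``) are treated
as noise or spike-collision artifacts and also unassigned: genuine units at
workable SNR cohere at 0.85+, while threshold-crossing noise and collision
mixtures stay well below 0.7.

Unit labels are assigned on the SN channel only; DR spikes inherit identity
through latency matching downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import InsufficientDataError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_N_KEEP = 10
DEFAULT_MIN_CLUSTER_SIZE = 20
DEFAULT_MAX_UNITS = 8
POSTERIOR_FLOOR = 0.5
NOISE_CORR_FLOOR = 0.75


@dataclass
class SortedUnits:
    """Per-spike unit labels with per-unit templates and quality metrics."""

    labels: np.ndarray                 # -1 = unassigned / noise
    templates: np.ndarray              # (n_units, window_samples); may be empty
    features: np.ndarray               # per-spike kept wavelet coefficients
    quality: "list[dict]" = field(default_factory=list)
    shifts: np.ndarray | None = None   # samples each snippet was realigned by
    noise_mask: np.ndarray | None = None  # True = member of a rejected noise cluster

    @property
    def unit_ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u >= 0]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def haar_decomposition(waveforms: np.ndarray, level: int = 4) -> np.ndarray:
    """Full multilevel Haar coefficient matrix, one row per waveform."""
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    coeffs = pywt.wavedec(waveforms, "haar", level=level, axis=1)
    return np.hstack(coeffs)


def wavelet_features(waveforms: np.ndarray, n_keep: int = DEFAULT_N_KEEP,
                     level: int = 4) -> np.ndarray:
    """Select the ``n_keep`` most non-normal Haar coefficients as features.

    Normality is scored per coefficient by the KS distance between the
    empirical distribution and a normal fitted by sample mean and standard
    deviation; constant coefficients score zero. Selection is deterministic
    (stable sort, ties broken by coefficient index).
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if waveforms.shape[0] < 2:
        raise InsufficientDataError("need at least 2 waveforms")
    if waveforms.shape[1] < 16:
        raise ParameterError("waveform window must span at least 16 samples")
    full = haar_decomposition(waveforms, level=level)
    n_coeff = full.shape[1]
    if n_keep > n_coeff:
        raise ParameterError(
            f"n_keep={n_keep} exceeds available coefficients ({n_coeff})"
        )
    ks = np.zeros(n_coeff)
    for j in range(n_coeff):
        col = full[:, j]
        mu, sd = col.mean(), col.std()
        if sd <= 1e-12 * max(1.0, abs(mu)):
            continue  # constant coefficient carries no cluster information
        ks[j] = stats.kstest(col, "norm", args=(mu, sd)).statistic
    order = np.argsort(-ks, kind="stable")[:n_keep]
    return full[:, order]


def _canonical_order(features: np.ndarray) -> np.ndarray:
    """Row order independent of input permutation (lexicographic)."""
    return np.lexsort(features.T[::-1])


def cluster_units(features: np.ndarray,
                  min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                  max_units: int = DEFAULT_MAX_UNITS,
                  seed: int = 0,
                  waveforms: np.ndarray | None = None,
                  posterior_floor: float = POSTERIOR_FLOOR,
                  noise_corr_floor: float | None = NOISE_CORR_FLOOR) -> SortedUnits:
    """Gaussian-mixture clustering of spike features with BIC model selection.

    Deterministic given ``seed``; invariant to the order of the input rows
    (rows are canonically sorted before fitting). Unit ids are 0..K-1 in
    order of decreasing cluster size.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if waveforms is not None:
        waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
        if waveforms.shape[0] != n:
            raise ParameterError("waveforms row count differs from features")
    if n < min_cluster_size:
        log.warning("only %d spikes (< min_cluster_size=%d): all unassigned",
                    n, min_cluster_size)
        return SortedUnits(labels=np.full(n, -1, dtype=int),
                           templates=np.empty((0, 0 if waveforms is None
                                               else waveforms.shape[1])),
                           features=features,
                           noise_mask=np.zeros(n, dtype=bool))

    labels = _fit_gmm_labels(features, min_cluster_size, max_units, seed,
                             posterior_floor)

    if waveforms is not None:
        labels = _refine_splits(labels, waveforms, min_cluster_size,
                                max_units, seed, posterior_floor)
        labels = _merge_shifted_duplicates(labels, waveforms)
    templates, quality = _templates_and_quality(labels, waveforms)
    noise_mask = np.zeros(n, dtype=bool)
    if waveforms is not None and noise_corr_floor is not None:
        labels, templates, quality, noise_mask = _reject_noise_clusters(
            labels, waveforms, templates, quality, noise_corr_floor
        )
    return SortedUnits(labels=labels, templates=templates,
                       features=features, quality=quality,
                       noise_mask=noise_mask)


def _fit_gmm_labels(features: np.ndarray, min_cluster_size: int,
                    max_units: int, seed: int,
                    posterior_floor: float) -> np.ndarray:
    """BIC-selected Gaussian-mixture labels, -1 for low-posterior/small.

    Deterministic in ``seed`` and invariant to row permutation (rows are
    canonically ordered before fitting). Surviving clusters are numbered
    0..K-1 by decreasing size.
    """
    n = features.shape[0]
    order = _canonical_order(features)
    x = features[order]
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd

    best, best_bic = None, np.inf
    k_max = min(max_units, max(1, n // max(1, min_cluster_size)))
    rises = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, k_max + 1):
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 reg_covar=1e-6, n_init=3, max_iter=300,
                                 random_state=seed & 0x7FFFFFFF)
            gm.fit(z)
            bic = gm.bic(z)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
                rises = 0
            else:
                # BIC is near-convex in k here; stop after two consecutive
                # non-improvements instead of fitting every k
                rises += 1
                if rises >= 2:
                    break

    post = best.predict_proba(z)
    raw = post.argmax(axis=1)
    raw[post.max(axis=1) < posterior_floor] = -1

    labels_sorted = np.full(n, -1, dtype=int)
    comp_ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    keep = comp_ids[counts >= min_cluster_size]
    keep_counts = counts[counts >= min_cluster_size]
    rank = keep[np.argsort(-keep_counts, kind="stable")]
    for new_id, comp in enumerate(rank):
        labels_sorted[raw == comp] = new_id

    labels = np.full(n, -1, dtype=int)
    labels[order] = labels_sorted
    return labels


def _refine_splits(labels: np.ndarray, waveforms: np.ndarray,
                   min_cluster_size: int, max_units: int, seed: int,
                   posterior_floor: float, n_keep: int = DEFAULT_N_KEEP,
                   depth: int = 2) -> np.ndarray:
    """Recursively re-cluster each cluster on features selected within it.

    KS feature selection over the whole population favours coefficients that
    separate the dominant groups, so structure between minority units can be
    invisible at the top level (the mixture then spends components splitting
    the dominant unit instead). Re-running selection and the mixture inside
    each cluster exposes that finer structure — the standard recursive
    bisection idea. A split is kept only when at least two subclusters
    survive the posterior and size floors; subclusters that are merely
    shifted copies of one another are recombined by the downstream
    duplicate-merge step, and incoherent ones by the noise rejection.
    """
    if depth <= 0:
        return labels
    out = labels.copy()
    next_id = int(out.max()) + 1
    for u in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == u)
        if len(idx) < 2 * min_cluster_size:
            continue
        try:
            feats = wavelet_features(waveforms[idx], n_keep=n_keep)
        except (InsufficientDataError, ParameterError):
            continue
        sub_seed = (seed * 31 + int(u) + 1) & 0x7FFFFFFF
        sub = _fit_gmm_labels(feats, min_cluster_size, max_units, sub_seed,
                              posterior_floor)
        if len(np.unique(sub[sub >= 0])) < 2:
            continue
        sub = _refine_splits(sub, waveforms[idx], min_cluster_size,
                             max_units, sub_seed, posterior_floor,
                             n_keep=n_keep, depth=depth - 1)
        out[idx] = -1
        for s in np.unique(sub[sub >= 0]):
            out[idx[sub == s]] = next_id
            next_id += 1
    return out


def _merge_shifted_duplicates(labels: np.ndarray, waveforms: np.ndarray,
                              corr_thresh: float = 0.9,
                              max_lag: int | None = None,
                              amp_ratio: float = 1.5) -> np.ndarray:
    """Merge clusters whose templates coincide up to a small time shift.

    Noise perturbs the alignment extremum by a sample or two, which can make
    one unit appear as several shifted copies to the mixture model. Two
    clusters are merged when their templates' peak normalised
    cross-correlation over lags within ``max_lag`` samples exceeds
    ``corr_thresh`` AND their RMS amplitudes agree within ``amp_ratio``
    (correlation alone is amplitude-blind and would conflate same-shape
    units of different size).
    """
    ids = np.unique(labels[labels >= 0])
    if len(ids) < 2:
        # nothing to merge; still ensure a dense 0..K-1 public numbering
        remap = {int(u): k for k, u in enumerate(ids)}
        return np.array([remap.get(int(l), -1) for l in labels], dtype=int)
    if max_lag is None:
        # noise can re-align a snippet onto the opposite waveform lobe, so
        # allow shifts up to a third of the window
        max_lag = max(5, waveforms.shape[1] // 3)
    templates = {u: waveforms[labels == u].mean(axis=0) for u in ids}
    parent = {int(u): int(u) for u in ids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def xcorr_max(a, b):
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        best = 0.0
        for lag in range(-max_lag, max_lag + 1):
            if lag >= 0:
                c = float(a[lag:] @ b[:len(b) - lag])
            else:
                c = float(a[:lag] @ b[-lag:])
            best = max(best, c / (na * nb))
        return best

    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            ta, tb = templates[u], templates[v]
            ra = np.sqrt(np.mean(ta ** 2))
            rb = np.sqrt(np.mean(tb ** 2))
            if max(ra, rb) > amp_ratio * min(ra, rb):
                continue
            if xcorr_max(ta, tb) >= corr_thresh:
                pa, pb = find(int(u)), find(int(v))
                if pa != pb:
                    parent[max(pa, pb)] = min(pa, pb)
                    log.info("merged shifted duplicate clusters %d and %d", u, v)

    merged = labels.copy()
    for u in ids:
        merged[labels == u] = find(int(u))
    # relabel densely by decreasing size for a stable public numbering
    roots, counts = np.unique(merged[merged >= 0], return_counts=True)
    rank = roots[np.argsort(-counts, kind="stable")]
    remap = {int(r): k for k, r in enumerate(rank)}
    return np.array([remap.get(int(l), -1) for l in merged], dtype=int)


def _best_lags(w: np.ndarray, t: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-row lag maximising correlation with ``t`` (rows mean-removed)."""
    scores = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            scores.append(w[:, lag:] @ t[:len(t) - lag])
        else:
            scores.append(w[:, :lag] @ t[-lag:])
    return np.argmax(np.vstack(scores), axis=0) - max_lag


def _shift_rows(wf: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wf)
    n = wf.shape[1]
    for i, s in enumerate(shifts):
        if s >= 0:
            out[i, :n - s] = wf[i, s:]
        else:
            out[i, -s:] = wf[i, :s]
    return out


def _aligned_template(wf: np.ndarray, max_lag: int | None = None):
    """Iteratively realigned cluster template and mean member correlation.

    Members whose detection extremum snapped to a different waveform lobe sit
    at shifted positions; two rounds of best-lag realignment to the running
    mean recover a crisp template, and quality is the mean zero-lag
    correlation of the realigned members with it.
    """
    if max_lag is None:
        max_lag = max(2, wf.shape[1] // 3)
    total = np.zeros(len(wf), dtype=int)
    aligned = wf
    tmpl = aligned.mean(axis=0)
    for _ in range(2):
        lags = _best_lags(aligned - aligned.mean(axis=1, keepdims=True),
                          tmpl - tmpl.mean(), max_lag)
        total = np.clip(total + lags, -max_lag, max_lag)
        aligned = _shift_rows(wf, total)
        tmpl = aligned.mean(axis=0)
    return tmpl, _mean_template_corr(aligned, tmpl, max_lag=0)


def _templates_and_quality(labels: np.ndarray, waveforms: np.ndarray | None):
    ids = np.unique(labels[labels >= 0])
    if waveforms is None:
        return np.empty((len(ids), 0)), [
            {"unit_id": int(u), "n_spikes": int((labels == u).sum()),
             "mean_corr": np.nan} for u in ids
        ]
    templates, quality = [], []
    for u in ids:
        wf = waveforms[labels == u]
        tmpl, corr = _aligned_template(wf)
        templates.append(tmpl)
        quality.append({"unit_id": int(u), "n_spikes": int(len(wf)),
                        "mean_corr": corr})
    shape = (len(ids), waveforms.shape[1])
    return (np.asarray(templates).reshape(shape), quality)


def _mean_template_corr(wf: np.ndarray, tmpl: np.ndarray,
                        max_lag: int | None = None) -> float:
    """Mean best-lag correlation of each waveform with the template.

    Shift-invariant (small lags) so that members of a cluster whose
    alignment extremum jittered by a few samples still score as coherent.
    """
    if max_lag is None:
        max_lag = max(2, len(tmpl) // 8)
    t = tmpl - tmpl.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        return 0.0
    w = wf - wf.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(w, axis=1)
    wn[wn == 0] = np.inf
    best = np.full(len(w), -np.inf)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            c = w[:, lag:] @ t[:len(t) - lag]
        else:
            c = w[:, :lag] @ t[-lag:]
        best = np.maximum(best, c / (wn * tn))
    return float(np.mean(best))


def _reject_noise_clusters(labels, waveforms, templates, quality, floor):
    """Unassign clusters that do not cohere around their template.

    Threshold crossings caused by noise alone share no common waveform, so
    their mean correlation to the cluster template stays low; genuine units
    at usable SNR sit well above 0.5. Also returns a boolean mask marking
    members of rejected clusters, which distinguishes positively identified
    noise from spikes that are merely ambiguous between real units — a
    distinction event-screening callers need.
    """
    labels = labels.copy()
    noise_mask = np.zeros(len(labels), dtype=bool)
    keep = [q["mean_corr"] >= floor for q in quality]
    for q, ok in zip(quality, keep):
        if not ok:
            log.info("cluster %d rejected as noise (mean_corr=%.2f, n=%d)",
                     q["unit_id"], q["mean_corr"], q["n_spikes"])
            noise_mask[labels == q["unit_id"]] = True
            labels[labels == q["unit_id"]] = -1
    # relabel surviving clusters to a dense 0..K-1 range, preserving order
    survivors = [q["unit_id"] for q, ok in zip(quality, keep) if ok]
    remap = {old: new for new, old in enumerate(survivors)}
    labels = np.array([remap.get(l, -1) for l in labels], dtype=int)
    templates = templates[[q["unit_id"] in remap for q in quality]]
    new_quality = []
    for q in quality:
        if q["unit_id"] in remap:
            q = dict(q, unit_id=remap[q["unit_id"]])
            new_quality.append(q)
    return labels, templates, new_quality, noise_mask


def canonical_min_alignment(waveforms: np.ndarray, align_index: int):
    """Realign snippets so the most negative sample sits at ``align_index``.

    Threshold detection aligns each snippet to the signed extremum of its
    excursion; for biphasic spikes with comparable lobes, noise decides the
    lobe and one unit shows up at two alignments. The negative lobe is a
    stable landmark across those outcomes, so realigning every snippet to
    its global minimum removes the ambiguity. Returns the realigned matrix
    and the per-snippet shift in samples (time correction = shift / fs).
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    shifts = np.argmin(waveforms, axis=1) - align_index
    return _shift_rows(waveforms, shifts), shifts


def sort_spikes(waveforms: np.ndarray, n_keep: int = DEFAULT_N_KEEP,
                seed: int = 0, align_index: int | None = None,
                **kwargs) -> SortedUnits:
    """Convenience wrapper: realign, wavelet features, then GMM clustering.

    When ``align_index`` is given, snippets are first realigned to their
    negative peak (see :func:`canonical_min_alignment`) and the applied
    shifts are reported on the result so spike times can be corrected.
    """
    shifts = None
    if align_index is not None:
        waveforms, shifts = canonical_min_alignment(waveforms, align_index)
    feats = wavelet_features(waveforms, n_keep=n_keep)
    units = cluster_units(feats, seed=seed, waveforms=waveforms, **kwargs)
    units.shifts = shifts
    return units
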