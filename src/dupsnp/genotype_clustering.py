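"""Axiom-style intensity-based genotype calling.

Pipeline per probeset:

1. quantile-normalize the two channels separately across samples;
2. median-polish the replicate-probe x sample log2 matrix into one A and
   one B signal per sample;
3. transform to contrast/size space, ``contrast = log2 A - log2 B`` and
   ``size = (log2 A + log2 B) / 2``;
4. scan all placements of two vertical boundaries on the contrast axis to
   find the maximum-posterior three-cluster labeling under a Gaussian
   prior on cluster locations;
5. update the prior mixture to a posterior by conjugate-style blending and
   call each sample to the cluster with maximal responsibility;
6. optionally augment the mixture with an off-target-variant (OTV)
   component at zero contrast / low size and rerun EM to relabel samples
   whose probe simply failed to hybridise.

The posterior model is serialisable and reusable as a prior for a new
batch of samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_LOG2PI = np.log(2 * np.pi)


def _gauss2_logpdf(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log-density of a 2-D Gaussian, explicit 2x2 algebra (fast path)."""
    a, b, c, d = cov[0, 0], cov[0, 1], cov[1, 0], cov[1, 1]
    det = a * d - b * c
    dx = points[:, 0] - mean[0]
    dy = points[:, 1] - mean[1]
    # inverse of [[a, b], [c, d]] applied to (dx, dy)
    quad = (d * dx * dx - (b + c) * dx * dy + a * dy * dy) / det
    return -0.5 * (quad + np.log(det)) - _LOG2PI

__all__ = [
    "ClusterModel",
    "GenotypeCalls",
    "quantile_normalize_channels",
    "median_polish",
    "summarize_replicate_probes",
    "to_contrast_size",
    "scan_boundaries",
    "posterior_update_clusters",
    "call_genotypes",
    "detect_otv",
    "call_probeset",
    "call_intensity_table",
]

CLUSTER_LABELS = ("AA", "AB", "BB")


@dataclass
class ClusterModel:
    """Gaussian mixture over genotype clusters in (contrast, size) space.

    ``nu`` are the prior pseudo-counts controlling how strongly the prior
    location resists the data during the Bayesian update; the same object
    serves as prior and posterior.
    """

    labels: tuple[str, ...] = CLUSTER_LABELS
    means: np.ndarray = field(
        default_factory=lambda: np.array([[1.5, 10.0], [0.0, 10.0], [-1.5, 10.0]])
    )
    covariances: np.ndarray = field(
        default_factory=lambda: np.array([np.diag([0.05, 0.05])] * 3)
    )
    weights: np.ndarray = field(default_factory=lambda: np.full(3, 1 / 3))
    nu: np.ndarray = field(default_factory=lambda: np.ones(3))
    confidence_threshold: float = 0.95

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        for cov in self.covariances:
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError("covariances must be positive definite")

    @property
    def n_clusters(self) -> int:
        return len(self.labels)

    def responsibilities(self, points: np.ndarray) -> np.ndarray:
        """Posterior cluster probabilities, one row per point."""
        points = np.atleast_2d(points)
        logp = np.empty((len(points), self.n_clusters))
        for g in range(self.n_clusters):
            logp[:, g] = _gauss2_logpdf(
                points, self.means[g], self.covariances[g]
            ) + np.log(self.weights[g])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.labels),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "weights": self.weights.tolist(),
                "nu": self.nu.tolist(),
                "confidence_threshold": self.confidence_threshold,
                "posterior_update": "conjugate pseudo-count blend",
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(
            labels=tuple(d["labels"]),
            means=np.asarray(d["means"]),
            covariances=np.asarray(d["covariances"]),
            weights=np.asarray(d["weights"]),
            nu=np.asarray(d["nu"]),
            confidence_threshold=d.get("confidence_threshold", 0.95),
        )


@dataclass
class GenotypeCalls:
    """Per-sample calls for one probeset."""

    sample_ids: list[str]
    calls: list[str]  # AA | AB | BB | NoCall | OTV
    confidences: np.ndarray
    model: ClusterModel

    def to_frame(self, probeset_id: str | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "call": self.calls,
                "confidence": self.confidences,
            }
        )
        if probeset_id is not None:
            out.insert(0, "probeset_id", probeset_id)
        return out


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


def quantile_normalize_channels(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) to their common mean distribution.

    After normalization every sample's sorted vector equals the reference
    (the mean of sorted vectors across samples); ties within a sample map
    to the average of the reference values they would span.
    """
    if values.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity", stacklevel=2)
        return values.copy()
    ranks = values.rank(method="average")
    reference = np.sort(values.to_numpy(), axis=0).mean(axis=1)

    def interp(col: pd.Series) -> pd.Series:
        # rank r (1-based, possibly fractional for ties) -> reference value
        return pd.Series(
            np.interp(col.to_numpy(), np.arange(1, len(reference) + 1), reference),
            index=col.index,
        )

    return ranks.apply(interp)


def median_polish(
    matrix: np.ndarray, tol: float = 1e-6, max_sweeps: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish: matrix ~ overall + row + col + residual.

    Alternates sweeping row and column medians into the effects until the
    medians of the residuals fall below ``tol`` or ``max_sweeps`` is hit.
    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = np.asarray(matrix, dtype=float).copy()
    n_rows, n_cols = resid.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    for _ in range(max_sweeps):
        row_med = np.median(resid, axis=1)
        resid -= row_med[:, None]
        row_eff += row_med
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        col_med = np.median(resid, axis=0)
        resid -= col_med[None, :]
        col_eff += col_med
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        if np.abs(row_med).max(initial=0) < tol and np.abs(col_med).max(initial=0) < tol:
            break
    return overall, row_eff, col_eff, resid


def summarize_replicate_probes(replicate_matrix: pd.DataFrame) -> pd.Series:
    """Collapse a replicate-probe x sample intensity matrix to one signal
    per sample via median polish on the log2 scale.

    The per-sample summary is overall effect + column effect,
    back-transformed to the linear scale.
    """
    if replicate_matrix.shape[0] < 1:
        raise ValueError("need at least one replicate row")
    logm = np.log2(replicate_matrix.to_numpy(dtype=float))
    overall, _, col_eff, _ = median_polish(logm)
    return pd.Series(2.0 ** (overall + col_eff), index=replicate_matrix.columns)


def to_contrast_size(
    signal_a: np.ndarray | float,
    signal_b: np.ndarray | float,
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Contrast/size transform (log2): the space in which clusters are fitted.

    Non-positive signals are floor-clipped to ``epsilon`` (and flagged via a
    warning) rather than rejected, since a failed probe still needs a row.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        warnings.warn("non-positive signal floor-clipped", stacklevel=2)
        a = np.maximum(a, epsilon)
        b = np.maximum(b, epsilon)
    la, lb = np.log2(a), np.log2(b)
    return la - lb, (la + lb) / 2


# ---------------------------------------------------------------------------
# boundary scan initialization
# ---------------------------------------------------------------------------


def scan_boundaries(contrasts: np.ndarray, prior: ClusterModel) -> np.ndarray:
    """Initial labeling by exhaustive scan of two vertical boundaries.

    All ordered boundary pairs between sorted distinct contrast values are
    scored (including degenerate placements yielding one or two clusters)
    by the sum of per-segment Gaussian log-likelihoods (segment mean,
    prior contrast SD) plus the log prior density of each implied segment
    mean under the prior for its genotype cluster.  Sorted segments map
    left-to-right onto BB, AB, AA (A-positive convention).

    Returns integer labels per point: 0=AA, 1=AB, 2=BB.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    n = len(contrasts)
    if n < 1:
        raise ValueError("need at least one point")
    order = np.argsort(contrasts, kind="stable")
    x = contrasts[order]

    prior_c_mean = prior.means[:, 0]  # AA, AB, BB
    prior_c_sd = np.sqrt(prior.covariances[:, 0, 0])

    # prefix sums for O(1) segment statistics
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def segment_score(i: int, j: int, cluster: int) -> float:
        """Score of x[i:j] assigned to cluster (0=AA,1=AB,2=BB)."""
        m = j - i
        if m == 0:
            return 0.0
        s, s2 = csum[j] - csum[i], csum2[j] - csum2[i]
        mean = s / m
        sd = prior_c_sd[cluster]
        var = sd * sd
        # Gaussian log-likelihood around the segment mean with the prior SD
        ll = -0.5 * m * np.log(2 * np.pi * var) - 0.5 * (
            s2 - 2 * mean * s + m * mean**2
        ) / var
        dev = mean - prior_c_mean[cluster]
        lp = -0.5 * (np.log(2 * np.pi * var) + dev * dev / var)
        return float(ll + lp)

    best_score = -np.inf
    best = (0, 0)
    # boundaries at indices (i, j): BB = x[:i], AB = x[i:j], AA = x[j:]
    for i in range(n + 1):
        sc_bb = segment_score(0, i, 2)
        for j in range(i, n + 1):
            score = sc_bb + segment_score(i, j, 1) + segment_score(j, n, 0)
            if score > best_score + 1e-12:
                best_score = score
                best = (i, j)
    i, j = best
    labels_sorted = np.empty(n, dtype=int)
    labels_sorted[:i] = 2
    labels_sorted[i:j] = 1
    labels_sorted[j:] = 0
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


# ---------------------------------------------------------------------------
# Bayesian update and calling
# ---------------------------------------------------------------------------


def posterior_update_clusters(
    points: np.ndarray, labels: np.ndarray, prior: ClusterModel
) -> ClusterModel:
    """Conjugate-style blend of prior and per-cluster sample statistics.

    posterior mean = (nu * prior_mean + n * sample_mean) / (nu + n);
    covariance blended with the same weights; weights proportional to
    (nu + n).  Empty clusters keep their prior.  The result can be reused
    as a prior for a later batch.
    """
    points = np.atleast_2d(points)
    k = prior.n_clusters
    means = prior.means.copy()
    covs = prior.covariances.copy()
    counts = np.zeros(k)
    for g in range(k):
        sel = points[labels == g]
        n_g = len(sel)
        counts[g] = n_g
        if n_g == 0:
            continue
        sample_mean = sel.mean(axis=0)
        w = prior.nu[g] / (prior.nu[g] + n_g)
        means[g] = w * prior.means[g] + (1 - w) * sample_mean
        if n_g >= 2:
            sample_cov = np.cov(sel.T, bias=False)
        else:
            sample_cov = prior.covariances[g]
        blended = w * prior.covariances[g] + (1 - w) * sample_cov
        # variance floor keeps the model usable on degenerate clusters
        blended += np.eye(2) * 1e-6
        covs[g] = blended
    total = prior.nu + counts
    return replace(
        prior,
        means=means,
        covariances=covs,
        weights=total / total.sum(),
        nu=prior.nu.copy(),
    )


def call_genotypes(
    points: np.ndarray,
    posterior: ClusterModel,
    sample_ids: list[str] | None = None,
    confidence_threshold: float | None = None,
) -> GenotypeCalls:
    """Assign each sample to the cluster with maximal responsibility.

    Confidence is the winning responsibility; calls below the threshold
    become NoCall.
    """
    points = np.atleast_2d(points)
    threshold = (
        posterior.confidence_threshold
        if confidence_threshold is None
        else confidence_threshold
    )
    resp = posterior.responsibilities(points)
    winners = resp.argmax(axis=1)
    conf = resp.max(axis=1)
    calls = [
        posterior.labels[w] if c >= threshold else "NoCall"
        for w, c in zip(winners, conf)
    ]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(points))]
    return GenotypeCalls(
        sample_ids=list(sample_ids), calls=calls, confidences=conf, model=posterior
    )


# ---------------------------------------------------------------------------
# OTV detection by EM
# ---------------------------------------------------------------------------


def _em_gaussian_mixture(
    points: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    var_floor: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Plain EM for a Gaussian mixture; returns the loglik trace too."""
    k = len(means)
    means, covs, weights = means.copy(), covs.copy(), weights.copy()
    loglik_trace: list[float] = []
    resp = np.empty((len(points), k))
    for _ in range(max_iter):
        logp = np.empty((len(points), k))
        for g in range(k):
            logp[:, g] = _gauss2_logpdf(points, means[g], covs[g]) + np.log(
                max(weights[g], 1e-300)
            )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        if loglik_trace and loglik - loglik_trace[-1] < tol:
            loglik_trace.append(loglik)
            break
        loglik_trace.append(loglik)
        # M step
        nk = resp.sum(axis=0)
        for g in range(k):
            if nk[g] < 1e-12:
                continue
            means[g] = resp[:, g] @ points / nk[g]
            diff = points - means[g]
            cov = (resp[:, g][:, None] * diff).T @ diff / nk[g]
            ev = np.linalg.eigvalsh(cov)
            if ev.min() < var_floor:
                cov += np.eye(2) * (var_floor - min(ev.min(), 0))
            covs[g] = cov
        weights = nk / nk.sum()
    return means, covs, weights, resp, loglik_trace


def detect_otv(
    points: np.ndarray,
    posterior: ClusterModel,
    calls: GenotypeCalls,
    size_offset: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[GenotypeCalls, list[float]]:
    """Relabel samples belonging to a low-size, zero-contrast OTV cluster.

    The fitted three-cluster posterior is augmented with a fourth component
    initialised at contrast 0 and size = (lowest cluster size mean -
    ``size_offset``), then EM is run to convergence.  Samples whose maximal
    responsibility is for the OTV component are relabelled "OTV"; if the
    component ends up empty the calls are returned unchanged.

    Returns (updated calls, EM log-likelihood trace).
    """
    points = np.atleast_2d(points)
    # seed the OTV component from the points that actually sit below the
    # genotype clusters; fall back to the configured offset when none do
    size_ref = float(np.median(posterior.means[:, 1]))
    low = points[:, 1] < size_ref - size_offset / 2
    if low.any():
        otv_mean = np.array([0.0, float(points[low, 1].mean())])
        w0 = max(low.mean(), 1.0 / (len(points) + 1))
    else:
        otv_mean = np.array([0.0, posterior.means[:, 1].min() - size_offset])
        w0 = 1.0 / (len(points) + 1)
    means = np.vstack([posterior.means, otv_mean])
    covs = np.concatenate(
        [posterior.covariances, posterior.covariances.mean(axis=0)[None]], axis=0
    )
    weights = np.concatenate([posterior.weights * (1 - w0), [w0]])
    means, covs, weights, resp, trace = _em_gaussian_mixture(
        points, means, covs, weights, tol=tol, max_iter=max_iter
    )
    winners = resp.argmax(axis=1)
    otv_idx = posterior.n_clusters
    if not np.any(winners == otv_idx):
        return calls, trace
    new_calls = list(calls.calls)
    conf = calls.confidences.copy()
    for i in np.flatnonzero(winners == otv_idx):
        new_calls[i] = "OTV"
        conf[i] = resp[i, otv_idx]
    return (
        GenotypeCalls(
            sample_ids=calls.sample_ids,
            calls=new_calls,
            confidences=conf,
            model=calls.model,
        ),
        trace,
    )


# ---------------------------------------------------------------------------
# end-to-end per-probeset and per-table drivers
# ---------------------------------------------------------------------------


def call_probeset(
    contrast: np.ndarray,
    size: np.ndarray,
    prior: ClusterModel | None = None,
    sample_ids: list[str] | None = None,
    otv: bool = True,
    confidence_threshold: float | None = None,
) -> GenotypeCalls:
    """Boundary scan -> posterior update -> calling -> optional OTV EM."""
    prior = prior or ClusterModel()
    points = np.column_stack([contrast, size])
    labels = scan_boundaries(points[:, 0], prior)
    posterior = posterior_update_clusters(points, labels, prior)
    calls = call_genotypes(points, posterior, sample_ids, confidence_threshold)
    if otv:
        calls, _ = detect_otv(points, posterior, calls)
    return calls


def call_intensity_table(
    intensities: pd.DataFrame,
    prior: ClusterModel | None = None,
    otv: bool = True,
    confidence_threshold: float | None = None,
    quantile_normalize: bool = True,
) -> pd.DataFrame:
    """Full calling pipeline over a long intensity table.

    Expects columns probeset_id, probe_replicate, sample_id, signal_A,
    signal_B.  Channels are quantile-normalized across samples (per
    channel, over all probeset x replicate rows), replicates are
    median-polish summarized per probeset, and each probeset is called
    independently.  Returns a long calls frame.
    """
    prior = prior or ClusterModel()
    wide_a = intensities.pivot_table(
        index=["probeset_id", "probe_replicate"], columns="sample_id", values="signal_A"
    )
    wide_b = intensities.pivot_table(
        index=["probeset_id", "probe_replicate"], columns="sample_id", values="signal_B"
    )
    if quantile_normalize and wide_a.shape[1] >= 2:
        wide_a = quantile_normalize_channels(wide_a)
        wide_b = quantile_normalize_channels(wide_b)

    out = []
    for ps in wide_a.index.get_level_values(0).unique():
        sig_a = summarize_replicate_probes(wide_a.loc[ps])
        sig_b = summarize_replicate_probes(wide_b.loc[ps])
        contrast, size = to_contrast_size(sig_a.to_numpy(), sig_b.to_numpy())
        calls = call_probeset(
            contrast,
            size,
            prior=prior,
            sample_ids=list(sig_a.index),
            otv=otv,
            confidence_threshold=confidence_threshold,
        )
        frame = calls.to_frame(probeset_id=ps)
        frame["contrast"] = contrast
        frame["size"] = size
        out.append(frame)
    return pd.concat(out, ignore_index=True)
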