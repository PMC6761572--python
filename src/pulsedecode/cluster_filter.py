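"""K-means clustering of activation traces and frequency-filter classes.

Traces are partitioned into k = 4 clusters by k-means under the
*correlation distance* (1 - Pearson correlation), repeated from 5 random
initializations with the lowest-inertia run kept — the standard treatment
for grouping time-series by shape rather than scale.  Because correlation
distance equals half the squared Euclidean distance between per-trace
standardized vectors, the implementation standardizes each trace (zero
mean, unit norm) and re-standardizes centroids after every mean update.

Promoter frequency responses are summarized by a metric value at the low,
natural and high p53 pulse frequencies, and classified as all-pass,
band-pass or low-pass by a relative-margin rule (default margin 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import TraceSet

DEFAULT_K = 4
DEFAULT_RESTARTS = 5
DEFAULT_MARGIN = 0.2

FILTER_CLASSES = ("all_pass", "band_pass", "low_pass", "unclassified")


@dataclass
class ClusterAssignment:
    """Result of trace k-means: cell_id -> 1-based cluster index."""

    assignments: dict[str, int]
    k: int
    distance: str
    inertia: float
    seed: int

    def sizes(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.assignments.values():
            out[c] += 1
        return out


def correlation_distance(trace_a, trace_b) -> float:
    """1 - Pearson correlation of two equal-length series; in [0, 2].

    Undefined (raises) for constant traces.  Zero for any positive affine
    transform of the same shape.
    """
    a = np.asarray(getattr(trace_a, "values", trace_a), dtype=float)
    b = np.asarray(getattr(trace_b, "values", trace_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation distance is undefined for constant traces")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows; correlation distance becomes
    ||u - v||^2 / 2 on these vectors."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant trace: correlation distance undefined")
    return Xc / norms


def _corr_dist_matrix(U: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise correlation distances between standardized rows U and
    standardized centroids C."""
    return 1.0 - U @ C.T


def kmeans_traces(
    traceset: TraceSet,
    k: int = DEFAULT_K,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Best-of-restarts k-means under correlation distance.

    Deterministic given ``seed``.  Ties in the assignment step go to the
    lowest-index centroid; a cluster emptied during iteration is repaired
    by splitting the largest cluster (its farthest member seeds the empty
    one).  Inertia is the total correlation distance of members to their
    centroid and is non-increasing across iterations within a restart.
    """
    n = len(traceset)
    if n < k:
        raise ValueError(f"need at least k={k} traces, got {n}")
    X = traceset.values_matrix()
    U = _standardize_rows(X)
    rng = np.random.default_rng(seed)

    best_labels = None
    best_inertia = np.inf
    for _ in range(restarts):
        idx = rng.choice(n, size=k, replace=False)
        C = U[idx].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            D = _corr_dist_matrix(U, C)
            new_labels = np.argmin(D, axis=1)  # argmin takes lowest index on ties
            # empty-cluster repair: seed from the farthest member of the
            # largest cluster
            for c in range(k):
                if not np.any(new_labels == c):
                    sizes = np.bincount(new_labels, minlength=k)
                    big = int(np.argmax(sizes))
                    members = np.where(new_labels == big)[0]
                    far = members[int(np.argmax(D[members, big]))]
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = U[labels == c]
                mean = members.mean(axis=0)
                mean -= mean.mean()
                norm = np.linalg.norm(mean)
                if norm > 0:
                    C[c] = mean / norm
        D = _corr_dist_matrix(U, C)
        inertia = float(D[np.arange(n), labels].sum())
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best_labels = labels.copy()

    assignments = {
        tr.cell_id: int(c) + 1 for tr, c in zip(traceset, best_labels)
    }
    return ClusterAssignment(
        assignments=assignments,
        k=k,
        distance="correlation",
        inertia=best_inertia,
        seed=seed,
    )


# ----------------------------------------------------------- filter classes

@dataclass
class FilterProfile:
    """One promoter metric evaluated at low, natural and high p53 pulse
    frequency (frequencies ordered low < natural < high)."""

    low: float
    natural: float
    high: float
    metric: str = "rate"
    margin: float = DEFAULT_MARGIN

    def values(self) -> tuple[float, float, float]:
        return (self.low, self.natural, self.high)


def frequency_response_profile(
    params,
    metric: str = "magnitude",
    normalize_by_exposure: bool = False,
    generator_config=None,
    margin: float = DEFAULT_MARGIN,
    seed: int = 0,
) -> FilterProfile:
    """Profile a promoter's response across the three pulse frequencies.

    Drives the delayed Hill model with synthetic p53 under the low-,
    natural- and high-frequency regimens and summarizes the reporter with
    one metric per regimen.  By default the input is the deterministic
    pulse train (no amplitude variability or noise), isolating the
    promoter's amplitude-thresholding behavior; pass a ``generator_config``
    for population-style inputs (required for metric
    ``percent_responding``).

    ``normalize_by_exposure`` divides the metric by the cumulative p53
    delivered over the movie, comparing regimens at equal p53 exposure in
    the spirit of the matched-cumulative-rate analysis; this is the readout
    in which high-threshold promoters express low-pass filtering (see the
    methods note).
    """
    from .hillmodel import HillParams, simulate_reporter
    from .metrics import compute_metrics, percent_responding
    from .regimens import make_regimen
    from .synthetic_data import GeneratorConfig, generate_p53_traces, generate_reporter_traces
    from .trace_processing import cumulative_signal

    if metric not in ("magnitude", "rate", "timing", "percent_responding"):
        raise ValueError(f"unknown profile metric {metric!r}")
    deterministic = generator_config is None
    if metric == "percent_responding" and deterministic:
        raise ValueError("percent_responding requires a population generator_config")
    values = []
    for name in ("low_frequency", "natural", "high_frequency"):
        regimen = make_regimen(name)
        if deterministic:
            cfg = GeneratorConfig(n_cells=1, amp_cv=0.0, noise_sd=0.0, seed=seed)
        else:
            cfg = generator_config
        p53 = generate_p53_traces(regimen, cfg)
        rep = generate_reporter_traces(p53, params, noise_sd=cfg.noise_sd, seed=seed + 1)
        if metric == "percent_responding":
            v = percent_responding(rep)
        else:
            m = compute_metrics(rep.mean_trace())
            v = {"magnitude": m.magnitude, "rate": m.rate, "timing": m.timing}[metric]
        if normalize_by_exposure:
            v = v / cumulative_signal(p53.mean_trace())
        values.append(float(v))
    label = metric + ("_per_exposure" if normalize_by_exposure else "")
    return FilterProfile(*values, metric=label, margin=margin)


def classify_filter(profile: FilterProfile) -> str:
    """Classify a frequency-response profile.

    With margin d (default 0.2):

    * band-pass  — the natural-frequency response exceeds both neighbors
      by more than the margin;
    * low-pass   — low and natural responses are comparable (within d of
      the larger) and both exceed the high-frequency response;
    * all-pass   — all three responses within d of their maximum;
    * otherwise  — unclassified.

    Scale-invariant: multiplying the profile by c > 0 preserves the class.
    """
    m_low, m_nat, m_high = profile.values()
    if not all(np.isfinite(profile.values())):
        raise ValueError("filter profile values must be finite")
    if m_low < 0 or m_nat < 0 or m_high < 0:
        raise ValueError("filter profile values must be non-negative")
    d = profile.margin
    top = max(m_low, m_nat, m_high)
    if m_nat > (1 + d) * m_low and m_nat > (1 + d) * m_high:
        return "band_pass"
    if (
        min(m_low, m_nat) > (1 + d) * m_high
        and abs(m_low - m_nat) <= d * max(m_low, m_nat)
    ):
        return "low_pass"
    if top > 0 and all(v >= (1 - d) * top for v in profile.values()):
        return "all_pass"
    return "unclassified"
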