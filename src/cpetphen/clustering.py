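"""DTW k-medoids phenogrouping with silhouette x Dunn model selection.

Recordings are clustered on the channel set {HR, VO2, RER, PETO2,
PETCO2} after pooled z-scaling (without it VO2, ~10^3 mL/min, would
dominate RER, ~1).  Distances are multivariate DTW on the scaled series,
clustering is PAM-style k-medoids over the precomputed distance matrix,
and the number of clusters is chosen by the cluster validity index
``cvi = silhouette x dunn``.  Men and women are fitted separately;
fitted phenogroups are numbered 1..k in order of declining fitness (peak
VO2 per kg of the medoid), and external cohorts are assigned by
nearest-medoid distance using the stored training scaler.

The clustering surface follows the scikit-learn estimator protocol
(:class:`CohortChannelScaler`, :class:`DtwKMedoids`); the module-level
functions are thin wrappers composing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.metrics import silhouette_score

from .dtw import DtwConfig, _as_2d, distance_matrix, dtw_distance
from .records import CLUSTER_CHANNELS, CleanRecording, Participant
from .summary_metrics import compute_summary

# ---------------------------------------------------------------------------
# channel scaling
# ---------------------------------------------------------------------------


class CohortChannelScaler(TransformerMixin, BaseEstimator):
    """Pooled per-channel z-scaler over variable-length series.

    ``fit`` pools every sample of every training series and stores the
    per-channel mean and SD; ``transform`` maps any list of series into
    those units.  The training moments are reused verbatim for external
    cohorts (no refit), so external recordings land in the same space
    the medoids live in.
    """

    def __init__(self, channels: tuple[str, ...] | None = None):
        self.channels = channels

    def fit(self, X: list[np.ndarray], y=None) -> "CohortChannelScaler":
        if len(X) < 2:
            raise ValueError("need at least 2 series to fit the scaler")
        pooled = np.vstack([_as_2d(x) for x in X])
        self.mean_ = pooled.mean(axis=0)
        self.scale_ = pooled.std(axis=0)
        if np.any(self.scale_ <= 0):
            bad = np.flatnonzero(self.scale_ <= 0)
            names = (
                [self.channels[i] for i in bad]
                if self.channels
                else bad.tolist()
            )
            raise ValueError(f"zero-variance channel(s): {names}")
        return self

    def transform(self, X: list[np.ndarray]) -> list[np.ndarray]:
        return [
            (np.asarray(x, float) - self.mean_) / self.scale_ for x in X
        ]


# ---------------------------------------------------------------------------
# k-medoids (PAM on a precomputed distance matrix)
# ---------------------------------------------------------------------------


def _labels_for(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # ties broken toward the first (lowest-position) medoid by argmin
    return np.argmin(D[:, medoids], axis=1)


def _cost(D: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    return float(D[np.arange(len(D)), medoids[labels]].sum())


def _kmedoids_pp_init(
    D: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-medoids++ seeding: points chosen with probability ~ D_min^2."""
    n = len(D)
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        dmin = D[:, medoids].min(axis=1)
        w = dmin**2
        total = w.sum()
        if total <= 0:  # all remaining points coincide with a medoid
            choices = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(choices)))
            continue
        medoids.append(int(rng.choice(n, p=w / total)))
    return np.array(sorted(set(medoids)))


def _pam_once(
    D: np.ndarray, k: int, medoids: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternate nearest-medoid assignment and in-cluster medoid update."""
    medoids = medoids.copy()
    if len(medoids) < k:  # degenerate init (duplicate points): pad
        pool = [i for i in range(len(D)) if i not in medoids]
        medoids = np.array(sorted(list(medoids) + pool[: k - len(medoids)]))
    prev_cost = np.inf
    while True:
        labels = _labels_for(D, medoids)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        new_medoids = np.array(sorted(new_medoids))
        labels = _labels_for(D, new_medoids)
        cost = _cost(D, new_medoids, labels)
        if cost >= prev_cost - 1e-12:  # no improvement: converged
            return new_medoids, labels, cost
        medoids, prev_cost = new_medoids, cost


def _kmedoids_exhaustive(
    D: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, float]:
    best = None
    for combo in combinations(range(len(D)), k):
        medoids = np.array(combo)
        labels = _labels_for(D, medoids)
        cost = _cost(D, medoids, labels)
        if best is None or cost < best[2] - 1e-15:
            best = (medoids, labels, cost)
    return best


def kmedoids_fit(
    D: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    exhaustive_threshold: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cluster a precomputed distance matrix into ``k`` medoid groups.

    Runs PAM-style alternation (nearest-medoid assignment, in-cluster
    medoid update) from ``n_restarts`` k-medoids++ seedings and keeps
    the lowest-cost solution; instances with at most
    ``exhaustive_threshold`` candidate medoid sets are solved exactly by
    enumeration instead.  Returns (medoid indices sorted ascending,
    labels, total cost).
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    if comb(n, k) <= exhaustive_threshold:
        return _kmedoids_exhaustive(D, k)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        init = _kmedoids_pp_init(D, k, rng)
        medoids, labels, cost = _pam_once(D, k, init)
        if best is None or cost < best[2] - 1e-12:
            best = (medoids, labels, cost)
    return best


class DtwKMedoids(ClusterMixin, BaseEstimator):
    """k-medoids clustering of multichannel series under DTW distance.

    Parameters
    ----------
    n_clusters : number of phenogroups.
    metric : "dtw" (``X`` is a list of (n_i, d) arrays) or "precomputed"
        (``X`` is a square distance matrix).
    band : optional Sakoe–Chiba radius passed to the DTW recurrence.
    n_restarts, random_state : PAM initialization control.

    Attributes (after ``fit``)
    --------------------------
    medoid_indices_, labels_, inertia_, distance_matrix_, and — for
    metric="dtw" — ``medoids_`` (the stored medoid series, enabling
    ``predict`` on unseen series).
    """

    def __init__(
        self,
        n_clusters: int = 5,
        metric: str = "dtw",
        band: int | None = None,
        n_restarts: int = 10,
        random_state: int = 0,
        exhaustive_threshold: int = 200,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.band = band
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.exhaustive_threshold = exhaustive_threshold

    def _dtw_config(self) -> DtwConfig:
        return DtwConfig(band=self.band)

    def fit(self, X, y=None) -> "DtwKMedoids":
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)
        elif self.metric == "dtw":
            self.medoids_ = None
            D = distance_matrix(list(X), self._dtw_config())
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        medoids, labels, cost = kmedoids_fit(
            D,
            self.n_clusters,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            exhaustive_threshold=self.exhaustive_threshold,
        )
        self.distance_matrix_ = D
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = cost
        if self.metric == "dtw":
            self.medoids_ = [np.asarray(X[i], float) for i in medoids]
        return self

    def predict(self, X) -> np.ndarray:
        if self.metric != "dtw":
            raise ValueError("predict requires metric='dtw'")
        cfg = self._dtw_config()
        out = np.empty(len(X), dtype=int)
        for i, series in enumerate(X):
            dists = [dtw_distance(series, m, cfg) for m in self.medoids_]
            out[i] = int(np.argmin(dists))
        return out


# ---------------------------------------------------------------------------
# cluster validity index
# ---------------------------------------------------------------------------


@dataclass
class CviResult:
    k: int
    silhouette: float
    dunn: float
    cvi: float
    degenerate: bool = False  # zero within-cluster spread (dunn -> inf)


def dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max within-cluster distance."""
    labels = np.asarray(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    max_within = 0.0
    for idx in groups:
        if idx.size > 1:
            max_within = max(max_within, float(D[np.ix_(idx, idx)].max()))
    min_between = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            min_between = min(
                min_between, float(D[np.ix_(groups[a], groups[b])].min())
            )
    if max_within == 0.0:
        return float("inf")
    return min_between / max_within


def cvi(D: np.ndarray, labels: np.ndarray) -> CviResult:
    """Cluster validity index ``silhouette x dunn`` on precomputed distances.

    The silhouette is used on the DTW distances directly even though DTW
    is not a metric; this mirrors common practice and is documented.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("cvi needs at least 2 clusters")
    if np.all(counts == 1):
        raise ValueError("cvi undefined for singleton-only clusterings")
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    dunn = dunn_index(D, labels)
    degenerate = not np.isfinite(dunn)
    return CviResult(
        k=len(uniq), silhouette=sil, dunn=dunn, cvi=sil * dunn,
        degenerate=degenerate,
    )


def select_k(
    D: np.ndarray,
    k_range=range(2, 9),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, list[CviResult]]:
    """Fit every k in ``k_range`` and return the argmax-cvi k.

    Ties are broken toward the smaller k.
    """
    results: list[CviResult] = []
    best_k, best_cvi = None, -np.inf
    for k in sorted(k_range):
        _, labels, _ = kmedoids_fit(D, k, seed=seed, n_restarts=n_restarts)
        res = cvi(D, labels)
        res.k = k
        results.append(res)
        if res.cvi > best_cvi:  # strict: ties keep the smaller k
            best_k, best_cvi = k, res.cvi
    return best_k, results


# ---------------------------------------------------------------------------
# sex-stratified model fitting and assignment
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Persisted per-sex phenogrouping model."""

    sex: str
    k: int
    channels: tuple[str, ...]
    medoids: list[np.ndarray]  # scaled medoid series, raw cluster order
    medoid_ids: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    label_order: np.ndarray  # raw medoid index -> phenogroup 1..k
    medoid_fitness: np.ndarray  # peak VO2/kg per raw medoid
    band: int | None = None

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "k": self.k,
            "channels": list(self.channels),
            "medoids": [m.tolist() for m in self.medoids],
            "medoid_ids": self.medoid_ids,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "label_order": self.label_order.tolist(),
            "medoid_fitness": self.medoid_fitness.tolist(),
            "band": self.band,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            sex=d["sex"],
            k=int(d["k"]),
            channels=tuple(d["channels"]),
            medoids=[np.asarray(m, float) for m in d["medoids"]],
            medoid_ids=list(d["medoid_ids"]),
            scaler_mean=np.asarray(d["scaler_mean"], float),
            scaler_scale=np.asarray(d["scaler_scale"], float),
            label_order=np.asarray(d["label_order"], int),
            medoid_fitness=np.asarray(d["medoid_fitness"], float),
            band=d.get("band"),
        )


@dataclass
class Assignment:
    id: str
    phenogroup: int  # 1..k
    distance_to_medoid: float


@dataclass
class SexFitResult:
    model: ClusterModel
    assignments: dict[str, int]  # id -> phenogroup 1..k
    cvi_table: list[CviResult] = field(default_factory=list)
    selected_k: int | None = None


def relabel_by_fitness(fitness) -> np.ndarray:
    """Map raw medoid indices to phenogroups 1..k by declining fitness.

    Phenogroup 1 is the medoid with the highest fitness value (peak VO2
    per kg); ties keep the original medoid order.
    """
    fitness = np.asarray(fitness, dtype=float)
    order = np.argsort(-fitness, kind="stable")  # raw indices best-first
    label_order = np.empty(len(fitness), dtype=int)
    label_order[order] = np.arange(1, len(fitness) + 1)
    return label_order


def _recording_fitness(
    rec: CleanRecording, participant: Participant | None
) -> float:
    s = compute_summary(rec, participant)
    return s.peak_VO2_per_kg if s.peak_VO2_per_kg is not None else s.peak_VO2


def fit_sex_models(
    recordings: list[CleanRecording],
    participants: list[Participant] | None = None,
    channels: tuple[str, ...] = CLUSTER_CHANNELS,
    k: int | None = 5,
    k_range=range(2, 9),
    seed: int = 0,
    n_restarts: int = 10,
    band: int | None = None,
) -> dict[str, SexFitResult]:
    """Fit one phenogrouping model per sex.

    Per sex: z-scale the channel set on the stratum, build the DTW
    distance matrix, choose k by the cvi (unless forced via ``k``), run
    k-medoids, and number the clusters by declining medoid fitness.
    """
    part_by_id = {p.id: p for p in (participants or [])}
    out: dict[str, SexFitResult] = {}
    for sex in ("male", "female"):
        stratum = [r for r in recordings if r.sex == sex]
        k_max = k if k is not None else max(k_range)
        if len(stratum) < k_max + 1:
            raise ValueError(
                f"{sex} stratum too small: {len(stratum)} recordings "
                f"for k={k_max}"
            )
        raw = [r.matrix(channels) for r in stratum]
        scaler = CohortChannelScaler(channels=channels).fit(raw)
        scaled = scaler.transform(raw)
        D = distance_matrix(scaled, DtwConfig(band=band))

        cvi_table: list[CviResult] = []
        use_k = k
        if use_k is None:
            use_k, cvi_table = select_k(
                D, k_range, seed=seed, n_restarts=n_restarts
            )
        medoids, labels, _ = kmedoids_fit(
            D, use_k, seed=seed, n_restarts=n_restarts
        )
        # fitness per raw cluster: mean peak VO2/kg over members (robust to
        # the medoid subject's own anthropometrics)
        member_fitness = np.array(
            [
                _recording_fitness(stratum[i], part_by_id.get(stratum[i].id))
                for i in range(len(stratum))
            ]
        )
        fitness = np.array(
            [member_fitness[labels == j].mean() for j in range(use_k)]
        )
        label_order = relabel_by_fitness(fitness)
        model = ClusterModel(
            sex=sex,
            k=use_k,
            channels=tuple(channels),
            medoids=[scaled[i] for i in medoids],
            medoid_ids=[stratum[i].id for i in medoids],
            scaler_mean=scaler.mean_,
            scaler_scale=scaler.scale_,
            label_order=label_order,
            medoid_fitness=fitness,
            band=band,
        )
        assignments = {
            stratum[i].id: int(label_order[labels[i]])
            for i in range(len(stratum))
        }
        out[sex] = SexFitResult(
            model=model,
            assignments=assignments,
            cvi_table=cvi_table,
            selected_k=use_k,
        )
    return out


def scale_with_model(model: ClusterModel, rec: CleanRecording) -> np.ndarray:
    x = rec.matrix(model.channels)
    return (x - model.scaler_mean) / model.scaler_scale


def assign(model: ClusterModel, rec: CleanRecording) -> Assignment:
    """Assign one recording to the nearest medoid's phenogroup."""
    scaled = scale_with_model(model, rec)
    cfg = DtwConfig(band=model.band)
    dists = np.array([dtw_distance(scaled, m, cfg) for m in model.medoids])
    raw = int(np.argmin(dists))
    return Assignment(
        id=rec.id,
        phenogroup=int(model.label_order[raw]),
        distance_to_medoid=float(dists[raw]),
    )


def assign_cohort(
    models: dict[str, ClusterModel] | dict[str, SexFitResult],
    recordings: list[CleanRecording],
) -> list[Assignment]:
    """Assign every recording using its sex's model."""
    out = []
    for rec in recordings:
        entry = models[rec.sex]
        model = entry.model if isinstance(entry, SexFitResult) else entry
        out.append(assign(model, rec))
    return out
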