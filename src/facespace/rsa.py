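"""Face-space geometry comparison between neural data and network layers.

The neural face space is the set of pairwise Euclidean distances between
exemplar response patterns (N exemplars give N(N−1)/2 distances; 45 at
N = 10). Each network layer contributes the same pair-distance vector over
its unit activations. The layer profile is the Spearman correlation of the
neural vector with every layer's vector; inference shuffles exemplar labels
of the *neural* representation (equivalently, applies the induced pair
permutation to the neural distance vector) with the layer vectors held
fixed, and Benjamini–Hochberg FDR is applied across layers.

Cross-set pooling Fisher-z transforms the per-set correlations and averages
them weighted by each set's face-contact count n^i:

    R̂_z = Σ_i R_z^i n^i / Σ_i n^i
    SE_z = Σ_i (R_z^i − R̂_z)² n^i / (√N Σ_i n^i)

both back-transformed with tanh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from ._rng import rng_for
from .contacts import ResponseMatrix
from .images import ImageParams, image_params, params_table  # noqa: F401  (re-export)

RHO_CLIP = 1 - 1e-7


# ---------------------------------------------------------------------------
# distance vectors
# ---------------------------------------------------------------------------

@dataclass
class DistanceVector:
    """Condensed pairwise-distance vector in fixed (i < j) order."""

    values: np.ndarray
    n_exemplars: int
    exemplar_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.n_exemplars
        if len(self.values) != n * (n - 1) // 2:
            raise ValueError("length must be N(N-1)/2")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("distances must be finite and non-negative")

    @property
    def pair_index(self) -> list:
        n = self.n_exemplars
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    @classmethod
    def from_representation(cls, X: np.ndarray, exemplar_ids=None) -> "DistanceVector":
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("representation contains non-finite values")
        return cls(pdist(X, metric="euclidean"), X.shape[0], exemplar_ids)

    def permuted(self, perm) -> "DistanceVector":
        """Distance vector after relabelling exemplars by ``perm``.

        Shuffling exemplar labels and recomputing distances is exactly a
        permutation of the condensed vector: d'(i,j) = d(perm[i], perm[j]).
        """
        M = squareform(self.values)
        return DistanceVector(
            squareform(M[np.ix_(perm, perm)], checks=False), self.n_exemplars, self.exemplar_ids
        )


def pairwise_distances(representation) -> DistanceVector:
    """Euclidean distances over all unordered exemplar pairs.

    ``representation`` is an exemplar -> vector mapping or an
    (exemplars x features) matrix.
    """
    if isinstance(representation, dict):
        lens = {len(np.atleast_1d(v)) for v in representation.values()}
        if len(lens) > 1:
            raise ValueError("representation vectors differ in length")
        ids = list(representation)
        X = np.stack([np.atleast_1d(representation[e]) for e in ids])
        return DistanceVector.from_representation(X, ids)
    return DistanceVector.from_representation(np.asarray(representation))


def layer_distance_vectors(layers) -> list:
    """Normalize a layer source to [(name, DistanceVector), ...].

    Accepts a SyntheticLayerStack, a dict name -> activations/DistanceVector,
    or a list of (name, activations/DistanceVector) pairs.
    """
    if hasattr(layers, "layers"):
        layers = layers.layers()
    if isinstance(layers, dict):
        layers = list(layers.items())
    out = []
    for name, val in layers:
        dv = val if isinstance(val, DistanceVector) else pairwise_distances(np.asarray(val))
        out.append((name, dv))
    return out


# ---------------------------------------------------------------------------
# layer correlation profiles
# ---------------------------------------------------------------------------

@dataclass
class LayerCorrelationProfile:
    """Per-layer Spearman rho with permutation p-values and FDR flags."""

    table: pd.DataFrame  # index: layer name; rho, p_perm, p_fdr, significant
    n_perm: int
    seed: int | None = None

    @property
    def n_layers(self) -> int:
        return len(self.table)

    @property
    def layer_names(self) -> list:
        return list(self.table.index)

    @property
    def rho(self) -> pd.Series:
        return self.table["rho"]

    @property
    def best_layer(self) -> str:
        return self.table["rho"].idxmax()

    @property
    def significant_layers(self) -> list:
        return list(self.table.index[self.table["significant"]])


def _ranks_matrix(vectors: np.ndarray) -> np.ndarray:
    """Rank-transform then z-score rows; Pearson of these rows = Spearman."""
    r = np.apply_along_axis(stats.rankdata, 1, vectors)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = np.nan
    return r / norm


def _check_not_constant(name, values):
    if np.allclose(values, values[0]):
        raise ValueError(f"distance vector {name!r} is constant; Spearman rho undefined")


def _exemplar_perm_pair_indices(n: int, rng, n_perm: int) -> np.ndarray:
    """Pair-space index maps induced by ``n_perm`` exemplar permutations."""
    pos = np.zeros((n, n), dtype=int)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            pos[i, j] = pos[j, i] = k
            k += 1
    maps = np.empty((n_perm, k), dtype=int)
    for p in range(n_perm):
        perm = rng.permutation(n)
        m = 0
        for i in range(n):
            for j in range(i + 1, n):
                maps[p, m] = pos[perm[i], perm[j]]
                m += 1
    return maps


def correlate_profile(
    neural: DistanceVector,
    layers,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> LayerCorrelationProfile:
    """Spearman correlation of the neural distance vector with every layer.

    The permutation null relabels exemplars in the neural representation
    (distances recomputed per shuffle; layer vectors fixed); p per layer is
    the proportion of null correlations exceeding the observed one, followed
    by Benjamini–Hochberg FDR across layers.
    """
    layer_dvs = layer_distance_vectors(layers)
    _check_not_constant("neural", neural.values)
    for name, dv in layer_dvs:
        _check_not_constant(name, dv.values)
        if dv.n_exemplars != neural.n_exemplars:
            raise ValueError(f"layer {name!r} has a different exemplar count")

    L = _ranks_matrix(np.stack([dv.values for _, dv in layer_dvs]))  # layers x pairs
    neural_rank = _ranks_matrix(neural.values[None, :])[0]
    obs = L @ neural_rank

    rng = rng_for(seed, "profile_perm")
    maps = _exemplar_perm_pair_indices(neural.n_exemplars, rng, n_perm)
    null_ranks = neural_rank[maps]  # ranks permute with the values
    null = null_ranks @ L.T  # n_perm x layers
    p_perm = (null > obs[None, :]).mean(axis=0)
    p_fdr = multipletests(p_perm, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "rho": obs,
            "p_perm": p_perm,
            "p_fdr": p_fdr,
            "significant": p_fdr < fdr_alpha,
        },
        index=[name for name, _ in layer_dvs],
    )
    table.index.name = "layer"
    return LayerCorrelationProfile(table, n_perm, seed)


# ---------------------------------------------------------------------------
# weighted cross-set pooling (Fisher z)
# ---------------------------------------------------------------------------

@dataclass
class WeightedProfile:
    table: pd.DataFrame  # rho (back-transformed weighted mean), sem
    set_weights: list

    @property
    def rho(self) -> pd.Series:
        return self.table["rho"]


def _fisher_z(rho: np.ndarray) -> np.ndarray:
    clipped = np.clip(rho, -RHO_CLIP, RHO_CLIP)
    if (np.abs(rho) > RHO_CLIP).any():
        warnings.warn("rho at ±1 clipped before Fisher z", RuntimeWarning, stacklevel=2)
    return np.arctanh(clipped)


def weighted_profile(profiles: list, weights) -> WeightedProfile:
    """Pool per-set layer profiles, weighting by face-contact counts."""
    weights = np.asarray(weights, dtype=float)
    if len(profiles) != len(weights):
        raise ValueError("one weight per profile required")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    names = profiles[0].layer_names
    for p in profiles[1:]:
        if p.layer_names != names:
            raise ValueError("profiles have different layer lists")
    Rz = np.stack([_fisher_z(p.rho.values) for p in profiles])  # sets x layers
    n_sets = len(profiles)
    rhat = (Rz * weights[:, None]).sum(axis=0) / weights.sum()
    se = ((Rz - rhat[None, :]) ** 2 * weights[:, None]).sum(axis=0) / (
        np.sqrt(n_sets) * weights.sum()
    )
    table = pd.DataFrame({"rho": np.tanh(rhat), "sem": np.tanh(se)}, index=names)
    table.index.name = "layer"
    return WeightedProfile(table, list(weights))


def bootstrap_sem_pairs(
    neural: DistanceVector, layer: DistanceVector, n_boot: int = 1000, seed: int = 0
) -> float:
    """Image-pairs bootstrap s.e.m. of one layer's Spearman correlation."""
    nv, lv = neural.values, layer.values
    if len(nv) < 3:
        raise ValueError("need at least 3 pairs to bootstrap")
    rng = rng_for(seed, "boot_pairs")
    rhos = []
    for _ in range(n_boot):
        idx = rng.integers(len(nv), size=len(nv))
        a, b = nv[idx], lv[idx]
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            continue  # degenerate resample
        rhos.append(stats.spearmanr(a, b).statistic)
    return float(np.std(rhos, ddof=1))


# ---------------------------------------------------------------------------
# neural representations from the grand matrix
# ---------------------------------------------------------------------------

def neural_distance_vector(
    response_matrix: ResponseMatrix, time_average: bool = False, window_ms=None
) -> DistanceVector:
    X = response_matrix.representation(time_average=time_average, window_ms=window_ms)
    return DistanceVector.from_representation(X, list(response_matrix.exemplar_ids))


def time_averaged_profile(
    response_matrix: ResponseMatrix, layers, n_perm: int = 1000, seed: int = 0
) -> LayerCorrelationProfile:
    """Profile after collapsing each cell to its temporal mean amplitude."""
    return correlate_profile(
        neural_distance_vector(response_matrix, time_average=True), layers, n_perm, seed
    )


def sliding_window_profile(
    response_matrix: ResponseMatrix,
    layers,
    window_ms: float = 200.0,
    stride_ms: float = 50.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Layer profiles over sliding response windows.

    Returns a tidy table (window_start_ms, layer, rho, p_perm, p_fdr,
    significant, argmax flag); with a 200 ms window and 50 ms stride over
    [50, 500) there are six windows.
    """
    t0, t1 = response_matrix.times_ms[0], response_matrix.times_ms[-1] + (
        response_matrix.times_ms[1] - response_matrix.times_ms[0]
    )
    if window_ms > t1 - t0:
        raise ValueError("window longer than the epoch")
    starts = np.arange(t0, t1 - window_ms + 1e-9, stride_ms)
    rows = []
    for s in starts:
        prof = correlate_profile(
            neural_distance_vector(response_matrix, window_ms=(s, s + window_ms)),
            layers, n_perm, seed,
        )
        t = prof.table.reset_index()
        t.insert(0, "window_start_ms", s)
        t["argmax_layer"] = t["layer"] == prof.best_layer
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# partial correlation given low-level image parameters
# ---------------------------------------------------------------------------

def covariate_distance_vectors(params: pd.DataFrame, exemplar_ids) -> np.ndarray:
    """|param_i − param_j| per pair, one column per image parameter."""
    cols = [c for c in params.columns if params[c].notna().all()]
    vals = params.loc[list(exemplar_ids), cols].values
    n = len(exemplar_ids)
    out = np.empty((n * (n - 1) // 2, len(cols)))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = np.abs(vals[i] - vals[j])
            k += 1
    return out


def _residual_projector(covariate_ranks: np.ndarray) -> np.ndarray:
    n = covariate_ranks.shape[0]
    X = np.column_stack([np.ones(n), covariate_ranks])
    # drop collinear columns (greedy, keeping the intercept)
    keep = [0]
    for c in range(1, X.shape[1]):
        cand = X[:, keep + [c]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(c)
        else:
            warnings.warn(f"collinear covariate column {c - 1} dropped", RuntimeWarning,
                          stacklevel=2)
    X = X[:, keep]
    return np.eye(n) - X @ np.linalg.pinv(X)


def partial_profile(
    neural: DistanceVector,
    layers,
    params: pd.DataFrame | None,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> LayerCorrelationProfile:
    """Rank-based partial correlation of neural vs layer distances, given
    the pairwise covariate distances of the low-level image parameters.

    With no covariates this reduces exactly to the plain Spearman profile.
    """
    layer_dvs = layer_distance_vectors(layers)
    _check_not_constant("neural", neural.values)
    n_pairs = len(neural.values)
    if params is None or params.shape[1] == 0:
        cov = np.empty((n_pairs, 0))
    else:
        ids = neural.exemplar_ids or list(params.index)
        cov = covariate_distance_vectors(params, ids)
    cov_ranks = np.apply_along_axis(stats.rankdata, 0, cov) if cov.shape[1] else cov
    P = _residual_projector(cov_ranks)

    def partial_rho(nr: np.ndarray, lr: np.ndarray) -> np.ndarray:
        rn = P @ nr
        rl = P @ lr.T  # pairs x layers
        rn = rn / np.linalg.norm(rn)
        rl = rl / np.linalg.norm(rl, axis=0, keepdims=True)
        return rn @ rl

    L_ranks = np.stack([stats.rankdata(dv.values) for _, dv in layer_dvs])
    n_rank = stats.rankdata(neural.values)
    obs = partial_rho(n_rank, L_ranks)

    rng = rng_for(seed, "partial_perm")
    maps = _exemplar_perm_pair_indices(neural.n_exemplars, rng, n_perm)
    null = np.stack([partial_rho(n_rank[m], L_ranks) for m in maps])
    p_perm = (null > obs[None, :]).mean(axis=0)
    p_fdr = multipletests(p_perm, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"rho": obs, "p_perm": p_perm, "p_fdr": p_fdr, "significant": p_fdr < fdr_alpha},
        index=[name for name, _ in layer_dvs],
    )
    table.index.name = "layer"
    return LayerCorrelationProfile(table, n_perm, seed)


# ---------------------------------------------------------------------------
# per-patient and ROI analyses
# ---------------------------------------------------------------------------

def per_patient_profiles(
    response_matrix: ResponseMatrix,
    layers,
    min_contacts: int = 5,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Average the layer profiles of patients with enough face contacts.

    Returns (average table with mean rho per layer, per-patient profiles).
    """
    if response_matrix.patients is None:
        raise ValueError("response matrix lacks per-contact patient ids")
    patients = np.asarray(response_matrix.patients)
    per_patient = {}
    for p in np.unique(patients):
        ids = [c for c, q in zip(response_matrix.contact_ids, patients) if q == p]
        if len(ids) < min_contacts:
            continue
        sub = response_matrix.subset_contacts(ids)
        per_patient[p] = correlate_profile(
            neural_distance_vector(sub), layers, n_perm, seed
        )
    if not per_patient:
        raise ValueError(f"no patient has at least {min_contacts} face contacts")
    rho = pd.DataFrame({p: prof.rho for p, prof in per_patient.items()})
    avg = pd.DataFrame({"rho": rho.mean(axis=1), "n_patients": len(per_patient)})
    avg.index.name = "layer"
    return avg, per_patient


def roi_profile(
    response_matrix: ResponseMatrix,
    roi_labels: dict,
    layers,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[LayerCorrelationProfile, LayerCorrelationProfile, pd.DataFrame]:
    """Layer profiles for two anatomical clusters plus difference p-values.

    ``roi_labels`` maps contact id -> cluster label (exactly two labels,
    each with at least 2 contacts). Per-layer differences are tested by
    shuffling the contacts' cluster labels (cluster sizes preserved);
    two-sided p = proportion of |null differences| exceeding the observed.
    """
    labels = sorted(set(roi_labels.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 ROI labels, got {labels}")
    members = {lab: [c for c in response_matrix.contact_ids if roi_labels.get(c) == lab]
               for lab in labels}
    for lab, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"cluster {lab!r} has fewer than 2 contacts")
    layer_dvs = layer_distance_vectors(layers)

    def cluster_rho(ids) -> np.ndarray:
        dv = neural_distance_vector(response_matrix.subset_contacts(ids))
        L = _ranks_matrix(np.stack([d.values for _, d in layer_dvs]))
        return L @ _ranks_matrix(dv.values[None, :])[0]

    prof_a = correlate_profile(
        neural_distance_vector(response_matrix.subset_contacts(members[labels[0]])),
        layer_dvs, n_perm, seed)
    prof_b = correlate_profile(
        neural_distance_vector(response_matrix.subset_contacts(members[labels[1]])),
        layer_dvs, n_perm, seed)
    obs_diff = prof_a.rho.values - prof_b.rho.values

    pool = members[labels[0]] + members[labels[1]]
    n_a = len(members[labels[0]])
    rng = rng_for(seed, "roi_perm")
    null = np.empty((n_perm, len(layer_dvs)))
    for k in range(n_perm):
        perm = rng.permutation(len(pool))
        ids_a = [pool[i] for i in perm[:n_a]]
        ids_b = [pool[i] for i in perm[n_a:]]
        null[k] = cluster_rho(ids_a) - cluster_rho(ids_b)
    p_diff = (np.abs(null) > np.abs(obs_diff)[None, :]).mean(axis=0)
    diff = pd.DataFrame(
        {"rho_diff": obs_diff, "p_perm": p_diff,
         "p_fdr": multipletests(p_diff, method="fdr_bh")[1]},
        index=[name for name, _ in layer_dvs],
    )
    diff.index.name = "layer"
    return prof_a, prof_b, diff
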