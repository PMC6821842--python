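"""Greedy template-matching decoding of face exemplars from ensemble HFA.

Each decoding iteration draws one random trial per (exemplar, contact) cell
into a test matrix T; the remaining repetitions are averaged into a
reference matrix R. Rows are the concatenated per-contact [50, 500) ms time
series for one exemplar. Labels are assigned greedily: at every step the
globally minimal Euclidean distance between an unassigned test row and an
unassigned reference row is taken and both rows are retired, so each
reference label is used exactly once. Accuracy is the fraction of test rows
that received their own label, averaged over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._rng import rng_for
from .contacts import ResponseMatrix


@dataclass
class DecodingResult:
    accuracy: float
    per_iteration_accuracies: np.ndarray
    n_iterations: int
    seed: int
    permutation_p: float | None = None

    def __post_init__(self):
        self.per_iteration_accuracies = np.asarray(self.per_iteration_accuracies, dtype=float)
        assert len(self.per_iteration_accuracies) == self.n_iterations

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "permutation_p": self.permutation_p,
        }


def split_test_reference(
    response_matrix: ResponseMatrix, seed: int = 0, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """One decoding split: (T, R), each exemplars x (contacts · timepoints).

    T rows concatenate one randomly chosen trial per contact; R rows
    concatenate the means of the remaining trials. No trial contributes to
    both.
    """
    if rng is None:
        rng = rng_for(seed, "split")
    G = response_matrix.G
    n_ex, n_con, n_tr, n_t = G.shape
    valid = np.isfinite(G).all(axis=3)  # exemplars x contacts x trials
    if (valid.sum(axis=2) < 2).any():
        raise ValueError("every (exemplar, contact) cell needs at least 2 trials")

    if valid.all():  # equal trial counts: vectorized draw
        choice = rng.integers(n_tr, size=(n_ex, n_con))
        chosen = np.take_along_axis(G, choice[:, :, None, None], axis=2)[:, :, 0]
        rest = (G.sum(axis=2) - chosen) / (n_tr - 1)
    else:
        chosen = np.empty((n_ex, n_con, n_t))
        rest = np.empty((n_ex, n_con, n_t))
        for e in range(n_ex):
            for c in range(n_con):
                idx = np.where(valid[e, c])[0]
                pick = idx[rng.integers(len(idx))]
                chosen[e, c] = G[e, c, pick]
                rest[e, c] = G[e, c, idx[idx != pick]].mean(axis=0)
    return chosen.reshape(n_ex, -1), rest.reshape(n_ex, -1)


def greedy_assign(distance_matrix: np.ndarray) -> np.ndarray:
    """Sequential-minimum assignment of test rows to reference rows.

    Repeatedly takes the global minimum among unassigned rows/columns; ties
    break on the lexicographically smallest (test, reference) index. Returns
    ``perm`` with ``perm[test_row] = reference_row`` — always a bijection.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")
    D = D.copy()
    n = D.shape[0]
    perm = np.full(n, -1, dtype=int)
    for _ in range(n):
        flat = np.argmin(D)  # first occurrence = lexicographically smallest
        t, r = divmod(flat, n)
        perm[t] = r
        D[t, :] = np.inf
        D[:, r] = np.inf
    return perm


def decode_exemplars(
    response_matrix: ResponseMatrix, n_iter: int = 1000, seed: int = 0
) -> DecodingResult:
    """Template-matching decoding accuracy over ``n_iter`` random splits."""
    rng = rng_for(seed, "decode")
    n_ex = response_matrix.shape[0]
    accs = np.empty(n_iter)
    for it in range(n_iter):
        T, R = split_test_reference(response_matrix, rng=rng)
        perm = greedy_assign(cdist(T, R))
        accs[it] = np.mean(perm == np.arange(n_ex))
    return DecodingResult(float(accs.mean()), accs, n_iter, seed)


def _shuffle_exemplar_labels(response_matrix: ResponseMatrix, rng) -> ResponseMatrix:
    """Shuffle single trials' exemplar labels within each contact.

    Valid trials are permuted among the valid (exemplar, repetition) slots,
    preserving each contact's repetition counts per exemplar while breaking
    the correspondence between repetitions of the same exemplar.
    """
    G = response_matrix.G
    out = G.copy()
    n_ex, n_con = G.shape[:2]
    valid = np.isfinite(G).all(axis=3)
    for c in range(n_con):
        ee, kk = np.where(valid[:, c])
        perm = rng.permutation(len(ee))
        out[ee, c, kk] = G[ee[perm], c, kk[perm]]
    return ResponseMatrix(
        out, list(response_matrix.exemplar_ids), list(response_matrix.contact_ids),
        response_matrix.times_ms, response_matrix.set_id, response_matrix.smoothing_ms,
        response_matrix.patients,
    )


def decoding_permutation_test(
    response_matrix: ResponseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    n_iter: int = 100,
    observed: DecodingResult | None = None,
) -> tuple[float, DecodingResult]:
    """Exemplar-label (image) permutation test of decoding accuracy.

    The null shuffles exemplar labels within each contact and re-runs the
    decoder; p is the proportion of shuffled accuracies exceeding the
    observed one (0.0 means below 1/n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if observed is None:
        observed = decode_exemplars(response_matrix, n_iter=n_iter, seed=seed)
    rng = rng_for(seed, "decode_perm")
    exceed = 0
    for k in range(n_perm):
        shuffled = _shuffle_exemplar_labels(response_matrix, rng)
        acc = decode_exemplars(shuffled, n_iter=n_iter, seed=int(rng.integers(2**31 - 1))).accuracy
        if acc > observed.accuracy:
            exceed += 1
    p = exceed / n_perm
    observed.permutation_p = p
    return p, observed
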