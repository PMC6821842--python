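"""Leave-one-out search for single network units predicting single contacts.

Unlike the representational (second-order) comparison, this assumes a
first-order similarity between one contact's exemplar tuning curve and one
unit's. Per contact and layer: in each of N leave-one-out folds, the Pearson
correlation between every unit's activations and the contact's mean HFA
responses over the N−1 training exemplars is computed; the best unit is
recorded. Only if a single unit wins *every* fold, its per-fold
least-squares line predicts the held-out response; the unit is a model
unit when the N held-out predictions correlate significantly with the
observations (one-sided label permutation, p < α).

Cluster correction guards the per-layer count: the search is re-run under
exemplar-label shuffles and the observed count must strictly exceed the
95th percentile of the null count distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_for


@dataclass
class ModelUnitMatch:
    layer: str
    unit: int
    contact_id: str
    fold_best_units: np.ndarray  # best unit per leave-one-out fold
    predictions: np.ndarray  # held-out predictions, one per fold
    observations: np.ndarray
    prediction_r: float
    prediction_p: float
    cluster_significant: bool | None = None


def _fold_best_units(responses: np.ndarray, activations: np.ndarray) -> np.ndarray:
    """argmax-correlation unit per leave-one-out fold (ties -> lowest index)."""
    n = len(responses)
    best = np.empty(n, dtype=int)
    for f in range(n):
        keep = np.arange(n) != f
        A = activations[keep]
        r = responses[keep]
        Ac = A - A.mean(axis=0)
        rc = r - r.mean()
        denom = np.sqrt((Ac**2).sum(axis=0) * (rc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (Ac * rc[:, None]).sum(axis=0) / denom, -np.inf)
        best[f] = int(np.argmax(corr))
    return best


def loo_unit_search(
    contact_responses: np.ndarray,
    layer_activations: np.ndarray,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 1000,
    layer: str = "",
    contact_id: str = "",
) -> ModelUnitMatch | None:
    """Search one layer for a unit predicting one contact's tuning curve.

    ``contact_responses``: mean [50, 500) ms HFA per exemplar (length N ≥ 4);
    ``layer_activations``: exemplars x units. Constant units are skipped.
    Returns a :class:`ModelUnitMatch` or None.
    """
    r = np.asarray(contact_responses, dtype=float)
    A = np.asarray(layer_activations, dtype=float)
    n = len(r)
    if n < 4:
        raise ValueError("need at least 4 exemplars")
    if A.shape[0] != n:
        raise ValueError("activations and responses disagree on exemplar count")
    keep_units = A.std(axis=0) > 0
    if not keep_units.any():
        return None
    unit_index = np.where(keep_units)[0]
    A = A[:, keep_units]

    best = _fold_best_units(r, A)
    if len(np.unique(best)) != 1:
        return None
    u = best[0]
    x = A[:, u]
    preds = np.empty(n)
    for f in range(n):
        keep = np.arange(n) != f
        slope, intercept = np.polyfit(x[keep], r[keep], 1)
        preds[f] = slope * x[f] + intercept

    pc = preds - preds.mean()
    rc = r - r.mean()
    denom = np.sqrt((pc @ pc) * (rc @ rc))
    if denom == 0:
        return None
    obs_r = float((pc @ rc) / denom)
    rng = rng_for(seed, "fit_perm")
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null = (pc[perms] @ rc) / denom
    p = float((null > obs_r).mean())
    if p >= alpha:
        return None
    return ModelUnitMatch(
        layer, int(unit_index[u]), contact_id, best, preds, r, obs_r, p
    )


def layer_unit_search(
    responses_by_contact: dict,
    layer_activations: np.ndarray,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 1000,
    layer: str = "",
) -> list:
    """Run the leave-one-out search for every contact against one layer."""
    matches = []
    for contact_id, resp in responses_by_contact.items():
        m = loo_unit_search(
            resp, layer_activations, alpha=alpha, seed=seed, n_perm=n_perm,
            layer=layer, contact_id=str(contact_id),
        )
        if m is not None:
            matches.append(m)
    return matches


def cluster_correction(
    observed_count: int, search, n_perm: int = 1000, seed: int = 0
) -> tuple[float, bool, np.ndarray]:
    """Cluster-level correction of a per-layer model-unit count.

    ``search`` is a closure re-running the search under one exemplar-label
    shuffle: it receives a numpy Generator and returns the null count. The
    layer is significant iff the observed count strictly exceeds the 95th
    percentile of the null counts.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20 for a 95th percentile")
    rng = rng_for(seed, "cluster")
    null = np.array([search(rng) for _ in range(n_perm)])
    threshold = float(np.percentile(null, 95))
    return threshold, bool(observed_count > threshold), null


def cluster_corrected_layer_search(
    responses_by_contact: dict,
    layer_activations: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    n_perm_fit: int = 200,
    layer: str = "",
) -> dict:
    """Full per-layer pipeline: search, then label-shuffle cluster correction."""
    matches = layer_unit_search(
        responses_by_contact, layer_activations, alpha, seed, n_perm_fit, layer
    )
    contacts = list(responses_by_contact)
    n = len(next(iter(responses_by_contact.values())))

    def null_search(rng) -> int:
        count = 0
        for k, c in enumerate(contacts):
            shuffled = np.asarray(responses_by_contact[c])[rng.permutation(n)]
            m = loo_unit_search(
                shuffled, layer_activations, alpha=alpha,
                seed=int(rng.integers(2**31 - 1)), n_perm=n_perm_fit, layer=layer,
            )
            count += m is not None
        return count

    threshold, significant, null = cluster_correction(len(matches), null_search, n_perm, seed)
    for m in matches:
        m.cluster_significant = significant
    return {
        "matches": matches,
        "observed_count": len(matches),
        "threshold": threshold,
        "cluster_significant": significant,
        "null_counts": null,
    }
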