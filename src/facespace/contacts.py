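"""Contact screening, exemplar selectivity and the grand response matrix.

Screening is two-staged. A contact is *visually responsive* when its mean
per-exemplar response at [50, 500) ms beats its [−200, 0) ms baseline in a
paired t-test at pFDR < 0.05 (Benjamini–Hochberg across all contacts pooled)
with a Glass' Δ effect size above 1 (Δ uses the SD of the exemplar-mean
baseline values as denominator). A visually responsive contact is a *face
contact* when two one-sided Wilcoxon rank-sum tests show larger responses
to faces than to each of two contrast categories (p < 0.05 uncorrected) and
the anatomical constraints hold: not in V1/V2/frontal labels and no deeper
than 10 mm from the cortical surface.

The grand response matrix G (exemplars x contacts x trials, each cell a
[50, 500) ms time series) feeds both the decoder (with 50 ms running-mean
smoothing) and the representational-distance analyses (unsmoothed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.multitest import multipletests

from ._rng import rng_for
from .signal import EpochedResponse

EXCLUDED_REGIONS = ("V1", "V2", "frontal")
MAX_DEPTH_MM = 10.0

CONTACT_COLUMNS = [
    "contact_id", "patient", "anatomical_label", "depth_from_surface_mm",
    "visual_flag", "face_flag", "selectivity_index", "selectivity_p",
]


def make_contact_table(
    channel_names, patients=None, anatomical_labels=None, depths_mm=None
) -> pd.DataFrame:
    """Blank contact table; anatomy arrives as metadata strings."""
    n = len(channel_names)
    return pd.DataFrame(
        {
            "contact_id": list(channel_names),
            "patient": patients if patients is not None else ["p01"] * n,
            "anatomical_label": anatomical_labels if anatomical_labels is not None else [""] * n,
            "depth_from_surface_mm": depths_mm if depths_mm is not None else np.zeros(n),
            "visual_flag": False,
            "face_flag": False,
            "selectivity_index": np.nan,
            "selectivity_p": np.nan,
        }
    )


def _exemplar_means(epochs: EpochedResponse, window_ms) -> np.ndarray:
    """exemplars x channels matrix of mean responses in a window."""
    per_trial = epochs.mean_response(window_ms)  # trials x channels
    ids = sorted(epochs.trials["stimulus_id"].unique())
    return np.stack(
        [per_trial[(epochs.trials["stimulus_id"] == s).values].mean(axis=0) for s in ids]
    )


def detect_visual_contacts(
    epochs,
    alpha: float = 0.05,
    delta_min: float = 1.0,
    contact_table: pd.DataFrame | None = None,
    response_window_ms=(50, 500),
    baseline_window_ms=(-200, 0),
) -> pd.DataFrame:
    """Screen channels for visual responsiveness.

    ``epochs`` may be a single :class:`EpochedResponse` or a list (one per
    task version the patient performed; exemplar means are pooled across
    versions before the paired test). Contacts with degenerate difference
    variance are untestable and excluded (flag False, p NaN).
    """
    if isinstance(epochs, EpochedResponse):
        epochs = [epochs]
    names = epochs[0].channel_names
    resp = np.concatenate([_exemplar_means(e, response_window_ms) for e in epochs])
    base = np.concatenate([_exemplar_means(e, baseline_window_ms) for e in epochs])
    if resp.shape[0] < 2:
        raise ValueError("need at least 2 exemplars for the paired test")

    table = contact_table.copy() if contact_table is not None else make_contact_table(names)
    pvals = np.full(len(names), np.nan)
    deltas = np.full(len(names), np.nan)
    for ci in range(len(names)):
        diff = resp[:, ci] - base[:, ci]
        if np.allclose(diff.std(ddof=1), 0):
            continue  # untestable
        t, p = stats.ttest_rel(resp[:, ci], base[:, ci])
        pvals[ci] = p
        sd_base = base[:, ci].std(ddof=1)
        deltas[ci] = (resp[:, ci].mean() - base[:, ci].mean()) / sd_base if sd_base > 0 else np.inf
    testable = np.isfinite(pvals)
    p_fdr = np.full(len(names), np.nan)
    if testable.any():
        p_fdr[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    table["t_p"] = pvals
    table["p_fdr"] = p_fdr
    table["glass_delta"] = deltas
    table["visual_flag"] = testable & (p_fdr < alpha) & (deltas > delta_min)
    return table


def detect_face_contacts(
    contact_table: pd.DataFrame,
    epochs: EpochedResponse,
    contrast_categories=("places", "patterns"),
    alpha: float = 0.05,
    response_window_ms=(50, 500),
) -> pd.DataFrame:
    """Flag face-selective contacts among the visually responsive ones.

    Two one-sided rank-sum tests on single-trial mean responses (faces
    greater than each contrast category), p < ``alpha`` uncorrected, plus
    anatomical constraints (V1/V2/frontal labels and depth > 10 mm excluded).
    """
    present = set(epochs.trials["category"].unique())
    for cat in ("faces",) + tuple(contrast_categories):
        if cat not in present:
            raise ValueError(f"category {cat!r} missing from the epoched trials")
    per_trial = epochs.mean_response(response_window_ms)
    cats = epochs.trials["category"].values
    face_resp = per_trial[cats == "faces"]

    table = contact_table.copy()
    sel_p = np.ones((len(table), len(contrast_categories)))
    for k, cat in enumerate(contrast_categories):
        other = per_trial[cats == cat]
        for ci in range(len(table)):
            sel_p[ci, k] = stats.ranksums(face_resp[:, ci], other[:, ci], alternative="greater").pvalue
    selective = (sel_p < alpha).all(axis=1)
    anatomical_ok = (
        ~table["anatomical_label"].isin(EXCLUDED_REGIONS).values
        & (table["depth_from_surface_mm"].values <= MAX_DEPTH_MM)
    )
    table["face_p_" + contrast_categories[0]] = sel_p[:, 0]
    table["face_p_" + contrast_categories[1]] = sel_p[:, 1]
    table["face_flag"] = table["visual_flag"].values & selective & anatomical_ok
    return table


# ---------------------------------------------------------------------------
# grand response matrix
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """G: exemplars x contacts x trials x time over [50, 500) ms.

    Missing repetitions are NaN-marked, never silently zero-filled.
    """

    G: np.ndarray
    exemplar_ids: list
    contact_ids: list
    times_ms: np.ndarray
    set_id: int = 0
    smoothing_ms: float | None = None
    patients: list | None = None  # per contact

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 4:
            raise ValueError("G must be exemplars x contacts x trials x time")

    @property
    def shape(self) -> tuple:
        return self.G.shape

    def trial_counts(self) -> np.ndarray:
        """Valid repetitions per (exemplar, contact)."""
        return np.isfinite(self.G).all(axis=3).sum(axis=2)

    def mean_over_trials(self) -> np.ndarray:
        """exemplars x contacts x time, NaN-aware."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.G, axis=2)

    def representation(self, time_average: bool = False, window_ms=None) -> np.ndarray:
        """Neural face representation: exemplars x features.

        Features are the concatenated per-contact time series (or the
        per-contact temporal means when ``time_average``); optionally
        restricted to a sub-window of [50, 500) ms first.
        """
        m = self.mean_over_trials()
        if window_ms is not None:
            mask = (self.times_ms >= window_ms[0]) & (self.times_ms < window_ms[1])
            m = m[:, :, mask]
        if time_average:
            return m.mean(axis=2)
        return m.reshape(m.shape[0], -1)

    def subset_contacts(self, contact_ids) -> "ResponseMatrix":
        idx = [self.contact_ids.index(c) for c in contact_ids]
        patients = [self.patients[i] for i in idx] if self.patients else None
        return ResponseMatrix(
            self.G[:, idx], list(self.exemplar_ids), list(contact_ids),
            self.times_ms, self.set_id, self.smoothing_ms, patients,
        )

    def save(self, path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.G)
        meta = {
            "exemplar_ids": list(self.exemplar_ids),
            "contact_ids": list(self.contact_ids),
            "times_ms": self.times_ms.tolist(),
            "set_id": self.set_id,
            "smoothing_ms": self.smoothing_ms,
            "patients": self.patients,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ResponseMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            np.load(path.with_suffix(".npy")), meta["exemplar_ids"], meta["contact_ids"],
            np.asarray(meta["times_ms"]), meta["set_id"], meta["smoothing_ms"], meta["patients"],
        )


def smooth_running_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Running-average smoothing along the last axis (edge-replicated)."""
    return uniform_filter1d(x, size=window_samples, axis=-1, mode="nearest")


def build_response_matrix(
    epochs: EpochedResponse,
    contact_table: pd.DataFrame,
    smoothing_ms: float | None = 50.0,
    window_ms=(50, 500),
    set_id: int = 0,
) -> ResponseMatrix:
    """Assemble G from face contacts' face-trial responses.

    ``smoothing_ms`` is the running-average window (50 ms for decoding
    input; pass None for the representational analyses).
    """
    face_mask = contact_table["face_flag"].values
    if not face_mask.any():
        raise ValueError("no face contacts in the table")
    contact_ids = list(contact_table.loc[face_mask, "contact_id"])
    chan_idx = [epochs.channel_names.index(c) for c in contact_ids]
    patients = list(contact_table.loc[face_mask, "patient"])

    tmask = epochs.time_mask(window_ms)
    times = epochs.times_ms[tmask]
    face_trials = epochs.trials["category"].values == "faces"
    stim = epochs.trials["stimulus_id"].values
    exemplar_ids = sorted(np.unique(stim[face_trials]))

    counts = [int((stim[face_trials] == e).sum()) for e in exemplar_ids]
    if min(counts) == 0:
        raise ValueError("face exemplar with zero trials")
    max_rep = max(counts)
    G = np.full((len(exemplar_ids), len(contact_ids), max_rep, tmask.sum()), np.nan)
    for ei, e in enumerate(exemplar_ids):
        rows = np.where(face_trials & (stim == e))[0]
        for k, r in enumerate(rows):
            G[ei, :, k, :] = epochs.data[r][np.ix_(chan_idx, np.where(tmask)[0])]
    if smoothing_ms:
        fs = 1000.0 / float(np.median(np.diff(times)))
        win = max(1, int(round(smoothing_ms / 1000.0 * fs)))
        valid = np.isfinite(G)
        G = np.where(valid, smooth_running_mean(np.where(valid, G, 0.0), win), np.nan)
    return ResponseMatrix(G, exemplar_ids, contact_ids, times, set_id, smoothing_ms, patients)


# ---------------------------------------------------------------------------
# exemplar selectivity (d' between best and worst face)
# ---------------------------------------------------------------------------

def _selectivity_from_groups(per_trial: list) -> float:
    means = np.array([g.mean() for g in per_trial])
    best, worst = means.argmax(), means.argmin()
    v_best = per_trial[best].var(ddof=1)
    v_worst = per_trial[worst].var(ddof=1)
    denom = np.sqrt(0.5 * (v_best + v_worst))
    if denom == 0:
        raise ZeroDivisionError("both extreme exemplars have zero variance; index undefined")
    return float((means[best] - means[worst]) / denom)


def exemplar_selectivity_index(
    response_matrix: ResponseMatrix, contact, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """d' between the most- and least-preferred face exemplars of one contact.

    Responses are each trial's [50, 500) ms temporal mean; μ and σ² are taken
    across repetitions of the best/worst exemplar. Significance is a label
    permutation: the proportion of ``n_perm`` single-trial-label shuffles
    whose index exceeds the observed one.
    """
    ci = (
        response_matrix.contact_ids.index(contact)
        if isinstance(contact, str)
        else int(contact)
    )
    cell = response_matrix.G[:, ci]  # exemplars x trials x time
    per_exemplar = []
    for ei in range(cell.shape[0]):
        vals = cell[ei].mean(axis=1)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError("need at least 2 repetitions per exemplar")
        per_exemplar.append(vals)
    observed = _selectivity_from_groups(per_exemplar)

    rng = rng_for(seed, "selectivity", ci)
    pool = np.concatenate(per_exemplar)
    sizes = [len(v) for v in per_exemplar]
    edges = np.cumsum([0] + sizes)
    exceed = 0
    for _ in range(n_perm):
        shuffled = pool[rng.permutation(len(pool))]
        groups = [shuffled[edges[i]: edges[i + 1]] for i in range(len(sizes))]
        try:
            if _selectivity_from_groups(groups) > observed:
                exceed += 1
        except ZeroDivisionError:
            continue
    return observed, exceed / n_perm
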