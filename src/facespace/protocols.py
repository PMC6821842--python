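"""1-back task protocols.

Three task versions are modelled, differing in stimulus roster, pacing and
design:

* set 1 — 60 stimuli (10 each: faces, animals, tools, words, patterns,
  places), 6 presentations each, 360 trials of which 24 are immediate
  (1-back) repeats, 250 ms stimulus, 750–1050 ms jittered ISI;
* set 2 — 56 stimuli (10 faces plus tools, patterns, houses, body parts),
  205 trials at a fixed 1 Hz pace, 25 repeats, each stimulus shown 3–4
  times (37 stimuli x 4 and 19 x 3 — the unique split reaching 205);
* set 3 — 50 stimuli in 5 categories, block design: 26 single-category
  blocks of 10 trials (260 trials), 18 repeats, 500 ms stimulus, 750–1500 ms
  ISI, 4 or 8 s between blocks.

A 1-back repeat is a trial whose stimulus equals the previous trial's.
Repeat trials are flagged `excluded` (they are response trials — hits — and
are dropped from all response analyses downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for

SET_CATEGORIES = {
    1: ("faces", "animals", "tools", "words", "patterns", "places"),
    2: ("faces", "tools", "patterns", "houses", "body_parts"),
    3: ("faces", "tools", "patterns", "houses", "body_parts"),
}

_SET2_COUNTS = {"faces": 10, "tools": 12, "patterns": 12, "houses": 11, "body_parts": 11}


@dataclass
class TaskProtocol:
    """Ordered trial table for one task version."""

    set_id: int
    trials: pd.DataFrame  # onset_ms, stimulus_id, category, is_repeat, block_id, excluded
    stimulus_duration_ms: int
    n_stimuli_per_category: dict
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_repeats(self) -> int:
        return int(self.trials["is_repeat"].sum())

    def included_trials(self) -> pd.DataFrame:
        """Trials retained for response analyses (hits/misses/FAs dropped)."""
        return self.trials[~self.trials["excluded"]]

    def to_events_tsv(self, path) -> None:
        """Write a BIDS-style events table."""
        ev = self.trials.rename(columns={"onset_ms": "onset", "category": "trial_type"})
        ev = ev.assign(duration=self.stimulus_duration_ms)
        cols = ["onset", "duration", "trial_type", "stimulus_id", "is_repeat", "block_id"]
        ev[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events_tsv(cls, path, set_id: int) -> "TaskProtocol":
        ev = pd.read_csv(path, sep="\t")
        tr = ev.rename(columns={"onset": "onset_ms", "trial_type": "category"})
        tr["is_repeat"] = tr["is_repeat"].astype(bool)
        tr["excluded"] = tr["is_repeat"]
        dur = int(ev["duration"].iloc[0])
        counts = tr.groupby("category")["stimulus_id"].nunique().to_dict()
        cols = ["onset_ms", "stimulus_id", "category", "is_repeat", "block_id", "excluded"]
        return cls(set_id, tr[cols].reset_index(drop=True), dur, counts)


def _stimulus_roster(set_id: int) -> pd.DataFrame:
    cats = SET_CATEGORIES[set_id]
    rows = []
    for cat in cats:
        n = _SET2_COUNTS[cat] if set_id == 2 else 10
        for i in range(n):
            rows.append((f"{cat[:-1] if cat.endswith('s') else cat}_{i + 1:02d}", cat))
    return pd.DataFrame(rows, columns=["stimulus_id", "category"])


def _draw_doubles(counts: dict, n_repeats: int, rng) -> dict:
    """Pick which stimuli contribute an adjacent pair; capacity floor(count/2)."""
    capacity = {s: c // 2 for s, c in counts.items()}
    doubles: dict = {}
    ids = list(counts)
    for _ in range(n_repeats):
        eligible = [s for s in ids if doubles.get(s, 0) < capacity[s]]
        s = eligible[rng.integers(len(eligible))]
        doubles[s] = doubles.get(s, 0) + 1
    return doubles


def _arrange_no_adjacent(tokens: list, rng, max_rounds: int = 200) -> list:
    """Shuffle tokens (stimulus ids) so no two adjacent tokens share an id."""
    tokens = list(tokens)
    for _ in range(max_rounds):
        rng.shuffle(tokens)
        ok = True
        for i in range(1, len(tokens)):
            if tokens[i][0] != tokens[i - 1][0]:
                continue
            placed = False
            for j in rng.permutation(len(tokens)):
                if abs(j - i) <= 1:
                    continue
                a, b = tokens[i], tokens[j]
                left_j = tokens[j - 1][0] if j > 0 else None
                right_j = tokens[j + 1][0] if j < len(tokens) - 1 else None
                right_i = tokens[i + 1][0] if i < len(tokens) - 1 else None
                if a[0] in (left_j, right_j):
                    continue
                if b[0] in (tokens[i - 1][0], right_i):
                    continue
                tokens[i], tokens[j] = b, a
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok and all(tokens[i][0] != tokens[i - 1][0] for i in range(1, len(tokens))):
            return tokens
    raise RuntimeError("could not arrange tokens without accidental repeats")


def _expand(tokens: list) -> list:
    out = []
    for stim, double in tokens:
        out.append(stim)
        if double:
            out.append(stim)
    return out


def _sequence_flat(set_id: int, rng) -> tuple[list, pd.DataFrame]:
    roster = _stimulus_roster(set_id)
    if set_id == 1:
        counts = {s: 6 for s in roster["stimulus_id"]}
        n_rep = 24
    else:  # set 2: 37 x 4 + 19 x 3 = 205
        ids = list(roster["stimulus_id"])
        four = rng.choice(len(ids), size=37, replace=False)
        counts = {s: 3 for s in ids}
        for i in four:
            counts[ids[i]] = 4
        n_rep = 25
    doubles = _draw_doubles(counts, n_rep, rng)
    tokens = []
    for s, c in counts.items():
        d = doubles.get(s, 0)
        tokens += [(s, True)] * d + [(s, False)] * (c - 2 * d)
    tokens = _arrange_no_adjacent(tokens, rng)
    return _expand(tokens), roster


def _sequence_blocks(rng) -> tuple[list, list, pd.DataFrame]:
    """Set 3: 26 single-category blocks of 10 trials, 18 repeats."""
    roster = _stimulus_roster(3)
    cats = list(SET_CATEGORIES[3])
    block_cats = [("faces", None)] * 6 + [(c, None) for c in cats if c != "faces" for _ in range(5)]
    block_cats = [t for t, _ in _arrange_no_adjacent(block_cats, rng)]
    repeat_blocks = set(rng.choice(26, size=18, replace=False).tolist())
    seq, block_ids = [], []
    for b, cat in enumerate(block_cats):
        members = list(roster.loc[roster["category"] == cat, "stimulus_id"])
        if b in repeat_blocks:
            r = members[rng.integers(10)]
            others = [m for m in members if m != r]
            omit = others[rng.integers(9)]
            toks = [(r, True)] + [(m, False) for m in others if m != omit]
        else:
            toks = [(m, False) for m in members]
        toks = [toks[i] for i in rng.permutation(len(toks))]
        # keep the block's first stimulus distinct from the previous block's last
        if seq and toks[0][0] == seq[-1]:
            toks[0], toks[-1] = toks[-1], toks[0]
        trials = _expand(toks)
        seq += trials
        block_ids += [b] * len(trials)
    return seq, block_ids, roster


def generate_protocol(set_id: int, seed: int) -> TaskProtocol:
    """Generate a pseudo-random 1-back protocol for one task version.

    Parameters
    ----------
    set_id : {1, 2, 3}
        Task version.
    seed : int
        Master seed; the trial order, repeat placement and ISI jitter are all
        reproducible from it.
    """
    if set_id not in (1, 2, 3):
        raise ValueError(f"unknown set_id {set_id!r}; expected 1, 2 or 3")
    rng = rng_for(seed, "protocol", set_id)
    if set_id == 3:
        seq, block_ids, roster = _sequence_blocks(rng)
    else:
        seq, roster = _sequence_flat(set_id, rng)
        block_ids = [None] * len(seq)
    cat_of = dict(zip(roster["stimulus_id"], roster["category"]))

    dur = {1: 250, 2: 250, 3: 500}[set_id]
    onsets = np.empty(len(seq), dtype=int)
    t = 1000
    for i in range(len(seq)):
        onsets[i] = t
        if set_id == 1:
            t += dur + int(rng.integers(750, 1051))
        elif set_id == 2:
            t += 1000
        else:
            if i + 1 < len(seq) and block_ids[i + 1] != block_ids[i]:
                t += dur + int(rng.choice([4000, 8000]))
            else:
                t += dur + int(rng.integers(750, 1501))

    is_rep = np.zeros(len(seq), dtype=bool)
    is_rep[1:] = np.array(seq[1:]) == np.array(seq[:-1])
    trials = pd.DataFrame(
        {
            "onset_ms": onsets,
            "stimulus_id": seq,
            "category": [cat_of[s] for s in seq],
            "is_repeat": is_rep,
            "block_id": block_ids,
            "excluded": is_rep,  # hits: response trials dropped from analyses
        }
    )
    counts = roster.groupby("category")["stimulus_id"].nunique().to_dict()
    return TaskProtocol(set_id, trials, dur, counts, seed=seed)


EXPECTED_TOTALS = {1: (360, 24), 2: (205, 25), 3: (260, 18)}


def validate_protocol(protocol: TaskProtocol) -> None:
    """Raise AssertionError if a protocol violates its set's invariants."""
    n_tr, n_rep = EXPECTED_TOTALS[protocol.set_id]
    tr = protocol.trials
    assert len(tr) == n_tr, f"{len(tr)} trials, expected {n_tr}"
    assert protocol.n_repeats == n_rep, f"{protocol.n_repeats} repeats, expected {n_rep}"
    assert (np.diff(tr["onset_ms"]) > 0).all(), "onsets not strictly increasing"
    same = tr["stimulus_id"].values[1:] == tr["stimulus_id"].values[:-1]
    assert (tr["is_repeat"].values[1:] == same).all() and not tr["is_repeat"].iloc[0]
    if protocol.set_id == 1:
        assert tr["stimulus_id"].value_counts().eq(6).all()
    elif protocol.set_id == 2:
        vc = tr["stimulus_id"].value_counts()
        assert vc.isin([3, 4]).all() and len(vc) == 56
    else:
        groups = tr.groupby("block_id")
        assert groups.ngroups == 26
        assert (groups.size() == 10).all()
        assert (groups["category"].nunique() == 1).all()
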