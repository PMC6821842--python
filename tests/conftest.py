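import numpy as np
import pandas as pd
import pytest

from facespace import contacts as cm
from facespace import signal as sig
from facespace import synthdata

FACE_IDS = [f"face_{i:02d}" for i in range(1, 11)]


@pytest.fixture(scope="session")
def latent10():
    return synthdata.LatentFaceSpace.random(FACE_IDS, k=4, seed=11)


@pytest.fixture(scope="session")
def planted_stack(latent10):
    profile = synthdata.planted_match_profile(12, 0.95, 0.2)
    return synthdata.simulate_layer_stack(latent10, profile, seed=11)


@pytest.fixture(scope="session")
def planted_rm(latent10):
    """Direct grand response matrix with tuning planted from the latent space."""
    rm, W = synthdata.simulate_response_matrix(latent10, n_contacts=40, n_trials=5, seed=11)
    return rm


@pytest.fixture(scope="session")
def full_chain():
    """One forward-modelled set-2 session run through the signal pipeline.

    Session-scoped: simulate_recording + HFA estimation dominate the cost and
    several test modules only need the resulting epochs / contact table /
    response matrices.
    """
    seed = 21
    protocol = synthdata.generate_protocol(2, seed)
    face_ids = sorted(
        protocol.trials.loc[protocol.trials["category"] == "faces", "stimulus_id"].unique()
    )
    latent = synthdata.LatentFaceSpace.random(face_ids, k=4, seed=seed)
    config = synthdata.default_contacts_config(10, latent, n_face=5, seed=seed)
    recording, truth = synthdata.simulate_recording(protocol, config, latent, seed=seed)
    referenced = sig.common_average_reference(recording)
    hfa = sig.estimate_hfa(referenced)
    epochs = sig.epoch_and_normalize(hfa, protocol)
    table = cm.detect_visual_contacts(epochs)
    table = cm.detect_face_contacts(table, epochs, contrast_categories=("houses", "patterns"))
    return {
        "protocol": protocol,
        "latent": latent,
        "config": config,
        "recording": recording,
        "truth": truth,
        "referenced": referenced,
        "hfa": hfa,
        "epochs": epochs,
        "contact_table": table,
    }


def make_epochs(data, trials, fs=500.0, units="% signal change"):
    """EpochedResponse straight from arrays (trials x channels x time)."""
    n_t = data.shape[2]
    times = -200 + np.arange(n_t) * 1000.0 / fs
    names = [f"ch{i + 1:03d}" for i in range(data.shape[1])]
    return sig.EpochedResponse(data, times, names, trials.reset_index(drop=True), units)


def make_trials(n_per_exemplar, exemplar_ids, category="faces"):
    rows = []
    for e in exemplar_ids:
        for _ in range(n_per_exemplar):
            rows.append({"stimulus_id": e, "category": category, "is_repeat": False,
                         "block_id": None, "excluded": False, "onset_ms": 0})
    return pd.DataFrame(rows)
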