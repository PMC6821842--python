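"""End-to-end orchestration of the synthetic face-space analysis.

One integer seed drives everything: the task protocol, the latent face
space, the forward-modelled recording, the synthetic layer stack and every
permutation test. Stage toggles select what runs; each stage writes its
results (TSV/JSON) into the output directory and the run ends with a
machine-readable summary carrying all derived seeds and package versions.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import derive_seed
from . import contacts as contacts_mod
from . import decoding as decoding_mod
from . import model_units as units_mod
from . import rf_viz as rfviz_mod
from . import rsa as rsa_mod
from . import signal as signal_mod
from . import synthdata

logger = logging.getLogger("facespace")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "facespace_results",
    "set_id": 1,
    "n_contacts": 16,
    "n_face_contacts": 8,
    "latent_dim": 4,
    "n_layers": 22,
    "planted_layer_index": 12,
    "alpha_planted": 0.95,
    "alpha_other": 0.2,
    "n_perm": 200,
    "n_boot": 200,
    "decode_iterations": 200,
    "decode_permutations": 20,
    "unit_cluster_permutations": 50,
    "rf_iterations": 50,
    "rf_learning_rate": 20.0,
    "fdr_alpha": 0.05,
    "glass_delta_min": 1.0,
    "stages": {
        "simulate": True,
        "signal": True,
        "contacts": True,
        "decode": True,
        "rsa": True,
        "units": True,
        "rfviz": True,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if k == "stages":
                cfg["stages"].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


class StageFailure(RuntimeError):
    pass


def run_pipeline(config: dict) -> Path:
    """Run the toggled stages; returns the results directory."""
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["stages"] = {**DEFAULT_CONFIG["stages"], **config.get("stages", {})}
    seed = int(cfg["seed"])
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    fhandler = logging.FileHandler(out / "run.log", mode="w")
    logging.basicConfig(level=logging.INFO, handlers=[handler, fhandler], force=True)
    summary: dict = {"seed": seed, "version": __version__, "config": cfg, "stages": {}}
    stages = cfg["stages"]
    state: dict = {}

    def stage(name):
        def deco(fn):
            if stages.get(name):
                logger.info("stage %s (seed %d)", name, derive_seed(seed, name))
                try:
                    summary["stages"][name] = fn() or {}
                except Exception as exc:  # halt with stage context
                    raise StageFailure(f"stage {name!r} failed: {exc}") from exc
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        protocol = synthdata.generate_protocol(cfg["set_id"], seed)
        synthdata.validate_protocol(protocol)
        protocol.to_events_tsv(out / "events.tsv")
        face_ids = sorted(
            protocol.trials.loc[protocol.trials["category"] == "faces", "stimulus_id"].unique()
        )
        latent = synthdata.LatentFaceSpace.random(face_ids, cfg["latent_dim"], seed)
        ccfg = synthdata.default_contacts_config(
            cfg["n_contacts"], latent, n_face=cfg["n_face_contacts"],
            seed=derive_seed(seed, "contacts_cfg"),
        )
        recording, truth = synthdata.simulate_recording(
            protocol, ccfg, latent, seed=derive_seed(seed, "recording")
        )
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        state.update(protocol=protocol, latent=latent, recording=recording, truth=truth)
        return {"n_trials": protocol.n_trials, "n_channels": recording.n_channels}

    @stage("signal")
    def _signal():
        rec = signal_mod.common_average_reference(state["recording"])
        hfa = signal_mod.estimate_hfa(rec)
        epochs = signal_mod.epoch_and_normalize(hfa, state["protocol"])
        state.update(referenced=rec, epochs=epochs)
        return {"n_epochs": epochs.data.shape[0], "units": epochs.units}

    @stage("contacts")
    def _contacts():
        epochs = state["epochs"]
        table = contacts_mod.detect_visual_contacts(
            epochs, alpha=cfg["fdr_alpha"], delta_min=cfg["glass_delta_min"]
        )
        contrast = ("places", "patterns") if cfg["set_id"] == 1 else ("houses", "patterns")
        table = contacts_mod.detect_face_contacts(table, epochs, contrast)
        rm_smooth = contacts_mod.build_response_matrix(epochs, table, smoothing_ms=50.0,
                                                       set_id=cfg["set_id"])
        rm_raw = contacts_mod.build_response_matrix(epochs, table, smoothing_ms=None,
                                                    set_id=cfg["set_id"])
        for ci, cid in enumerate(rm_raw.contact_ids):
            idx, p = contacts_mod.exemplar_selectivity_index(
                rm_raw, cid, n_perm=cfg["n_perm"], seed=derive_seed(seed, "selectivity", cid)
            )
            table.loc[table["contact_id"] == cid, ["selectivity_index", "selectivity_p"]] = idx, p
        table.to_csv(out / "contacts.tsv", sep="\t", index=False)
        state.update(contact_table=table, rm_smooth=rm_smooth, rm_raw=rm_raw)
        return {
            "n_visual": int(table["visual_flag"].sum()),
            "n_face": int(table["face_flag"].sum()),
        }

    @stage("decode")
    def _decode():
        result = decoding_mod.decode_exemplars(
            state["rm_smooth"], n_iter=cfg["decode_iterations"], seed=derive_seed(seed, "decode")
        )
        p, result = decoding_mod.decoding_permutation_test(
            state["rm_smooth"], n_perm=cfg["decode_permutations"],
            seed=derive_seed(seed, "decode_perm"),
            n_iter=max(20, cfg["decode_iterations"] // 10), observed=result,
        )
        _dump(result.as_dict(), out / "decoding.json")
        return result.as_dict()

    @stage("rsa")
    def _rsa():
        latent = state["latent"]
        profile_cfg = synthdata.planted_match_profile(
            cfg["planted_layer_index"], cfg["alpha_planted"], cfg["alpha_other"], cfg["n_layers"]
        )
        stack = synthdata.simulate_layer_stack(latent, profile_cfg,
                                               seed=derive_seed(seed, "stack"))
        neural = rsa_mod.neural_distance_vector(state["rm_raw"])
        prof = rsa_mod.correlate_profile(neural, stack, n_perm=cfg["n_perm"],
                                         seed=derive_seed(seed, "rsa"))
        prof.table.to_csv(out / "layer_profile.tsv", sep="\t")
        prof_avg = rsa_mod.time_averaged_profile(state["rm_raw"], stack,
                                                 n_perm=cfg["n_perm"],
                                                 seed=derive_seed(seed, "rsa_avg"))
        prof_avg.table.to_csv(out / "layer_profile_time_averaged.tsv", sep="\t")
        state.update(stack=stack, profile=prof)
        return {
            "best_layer": prof.best_layer,
            "planted_layer": stack.layer_names[cfg["planted_layer_index"]],
            "significant_layers": prof.significant_layers,
        }

    @stage("units")
    def _units():
        stack, prof = state["stack"], state["profile"]
        rm = state["rm_raw"]
        responses = {
            cid: rm.representation(time_average=True)[:, ci]
            for ci, cid in enumerate(rm.contact_ids)
        }
        search_layers = prof.significant_layers or [prof.best_layer]
        results = {}
        for name in search_layers:
            res = units_mod.cluster_corrected_layer_search(
                responses, stack.activations[name], alpha=cfg["fdr_alpha"],
                n_perm=cfg["unit_cluster_permutations"],
                seed=derive_seed(seed, "units", name), n_perm_fit=cfg["n_perm"], layer=name,
            )
            results[name] = {
                "observed_count": res["observed_count"],
                "threshold": res["threshold"],
                "cluster_significant": res["cluster_significant"],
                "matches": [
                    {"unit": m.unit, "contact": m.contact_id, "p": m.prediction_p}
                    for m in res["matches"]
                ],
            }
        _dump(results, out / "model_units.json")
        rows = [
            {"layer": lay, "unit": m["unit"], "contact": m["contact"], "p": m["p"],
             "cluster_flag": res["cluster_significant"]}
            for lay, res in results.items() for m in res["matches"]
        ]
        pd.DataFrame(rows, columns=["layer", "unit", "contact", "p", "cluster_flag"]).to_csv(
            out / "model_units.tsv", sep="\t", index=False
        )
        return {k: {"count": v["observed_count"], "significant": v["cluster_significant"]}
                for k, v in results.items()}

    @stage("rfviz")
    def _rfviz():
        spec = synthdata.build_toy_convnet(seed=derive_seed(seed, "toy_net"))
        rng = np.random.default_rng(derive_seed(seed, "rf_image"))
        image = rng.uniform(0, 255, (spec.input_channels, spec.input_size, spec.input_size))
        fp = rfviz_mod.forward(spec, image)
        unit = int(np.argmax(fp.outputs[spec.layer_index("conv3")].max(axis=(1, 2))))
        pos = np.unravel_index(
            np.argmax(fp.outputs[spec.layer_index("conv3")][unit]), fp.outputs[2][unit].shape
        )
        target = (unit, *pos)
        rf = rfviz_mod.deconvolve_unit(spec, image, "conv3", target)
        rf.save_png(out / "rf_deconvolution.png")
        rf_max, trace = rfviz_mod.activation_maximization(
            spec, image, "conv3", target,
            n_iter=cfg["rf_iterations"], lr=cfg["rf_learning_rate"],
        )
        rf_max.save_png(out / "rf_delta.png", which="delta")
        _dump({"unit": [int(u) for u in target], "activation_trace": trace.tolist()},
              out / "rf_trace.json")
        return {"initial_activation": trace[0], "final_activation": trace[-1]}

    _dump(summary, out / "summary.json")
    logger.info("pipeline complete: %s", out)
    return out
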