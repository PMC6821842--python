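"""Declarative specification of the evaluation network family.

The evaluation family is a VGG-Face-like feedforward architecture: five
convolutional blocks (2–3 convolutions each, 13 in total, each followed by
ReLU and the block by max-pooling) and three fully connected layers, 224 x
224 input, 2622-way class-score output. Weights are out of scope — the spec
is structural metadata consumed by the synthetic-layer generator and the
adapter for externally supplied real activations.

The evaluation layer list has 22 entries by default: the 13 convolution
outputs, the 5 pooling outputs, the 3 fully connected outputs and the final
class-score output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class NetworkArchitectureSpec:
    """Block structure of the VGG-like evaluation network."""

    blocks: list  # (n_convs, channels) per block
    fc_sizes: list
    input_side: int = 224
    n_classes: int = 2622
    include_output_layer: bool = True  # the 22nd evaluation entry

    @property
    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.blocks)

    @property
    def n_fc_layers(self) -> int:
        return len(self.fc_sizes)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {
                "blocks": [list(b) for b in self.blocks],
                "fc_sizes": list(self.fc_sizes),
                "input_side": self.input_side,
                "n_classes": self.n_classes,
                "include_output_layer": self.include_output_layer,
            },
            indent=1,
        ))

    @classmethod
    def from_json(cls, path) -> "NetworkArchitectureSpec":
        d = json.loads(Path(path).read_text())
        return cls([tuple(b) for b in d["blocks"]], d["fc_sizes"], d["input_side"],
                   d["n_classes"], d["include_output_layer"])


def default_architecture() -> NetworkArchitectureSpec:
    """VGG-Face-like: 13 conv layers in 5 blocks, 3 fc layers, 2622 classes."""
    return NetworkArchitectureSpec(
        blocks=[(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)],
        fc_sizes=[4096, 4096, 2622],
    )


def enumerate_layers(spec: NetworkArchitectureSpec) -> list:
    """Canonical ordered evaluation-layer names.

    conv1_1 … conv5_3, pool1 … pool5, fc6 … fc8, and (by default) the final
    class-score ``output`` — 22 names for the default architecture.
    """
    if not spec.blocks or not spec.fc_sizes:
        raise ValueError("malformed architecture spec: empty blocks or fc list")
    names = []
    for b, (n_convs, _) in enumerate(spec.blocks, start=1):
        if n_convs < 1:
            raise ValueError(f"malformed architecture spec: block {b} has no convolutions")
        names += [f"conv{b}_{c}" for c in range(1, n_convs + 1)]
    names += [f"pool{b}" for b in range(1, len(spec.blocks) + 1)]
    first_fc = len(spec.blocks) + 1
    names += [f"fc{first_fc + i}" for i in range(len(spec.fc_sizes))]
    if spec.include_output_layer:
        names.append("output")
    return names


def save_external_activations(path, layers: dict, exemplar_ids) -> None:
    """Write per-layer 2-D activation matrices keyed by canonical layer name."""
    np.savez(
        path,
        exemplar_ids=np.asarray(list(exemplar_ids), dtype=object),
        **{name: np.asarray(mat) for name, mat in layers.items()},
    )


def load_external_activations(path, exemplar_ids, spec: NetworkArchitectureSpec | None = None):
    """Load externally supplied layer activations, ordered canonically.

    Rows are reordered to match ``exemplar_ids``; a stimulus id missing from
    the container is an error; layers absent from the container are
    tolerated with a warning and skipped.
    """
    with np.load(path, allow_pickle=True) as archive:
        stored_ids = [str(s) for s in archive["exemplar_ids"]]
        missing = set(map(str, exemplar_ids)) - set(stored_ids)
        if missing:
            raise ValueError(f"stimulus ids missing from activation container: {sorted(missing)}")
        order = [stored_ids.index(str(e)) for e in exemplar_ids]
        canonical = enumerate_layers(spec or default_architecture())
        present = [n for n in canonical if n in archive.files]
        skipped = [n for n in canonical if n not in archive.files]
        if skipped:
            warnings.warn(
                f"{len(skipped)} evaluation layers absent from container: {skipped}; "
                "proceeding on the present layers",
                RuntimeWarning, stacklevel=2,
            )
        return [(name, np.asarray(archive[name], dtype=float)[order]) for name in present]
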