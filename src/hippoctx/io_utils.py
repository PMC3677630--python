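"""Serialization: pattern tables, run manifests, weight snapshots.

Pattern sets go to a plain TSV (one row per pattern: id, role, binary digit
string); the object->context map to a CSV; run manifests to JSON.  Weight
snapshots use a compressed array container with a JSON sidecar recording the
spec name, seed and epoch.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import AssociationSet, BinaryPattern, Role

__all__ = [
    "RunManifest",
    "save_association_set",
    "load_association_set",
    "save_weights",
    "load_weights",
]


def _pkg_version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunManifest:
    """Reproducibility record written next to every result file set."""

    command: str
    config: dict
    seeds: Sequence[int]
    outputs: list[str] = field(default_factory=list)
    status: str = "running"
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def finish(self, status: str = "ok") -> None:
        self.status = status
        self.finished = time.time()

    def write(self, path: Path | str) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seeds": [int(s) for s in self.seeds],
            "outputs": self.outputs,
            "status": self.status,
            "started": self.started,
            "finished": self.finished,
            "package_version": _pkg_version(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_association_set(assoc: AssociationSet, directory: Path | str) -> list[Path]:
    """Write patterns.tsv and associations.csv; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {"id": p.id, "role": p.role.value, "values": "".join(map(str, p.values))}
        for p in list(assoc.objects) + list(assoc.contexts)
    ]
    patterns_path = directory / "patterns.tsv"
    pd.DataFrame(rows).to_csv(patterns_path, sep="\t", index=False)
    assoc_path = directory / "associations.csv"
    pd.DataFrame(
        sorted(assoc.context_of.items()), columns=["object_id", "context_id"]
    ).to_csv(assoc_path, index=False)
    return [patterns_path, assoc_path]


def load_association_set(directory: Path | str) -> AssociationSet:
    directory = Path(directory)
    table = pd.read_csv(directory / "patterns.tsv", sep="\t", dtype={"values": str})
    links = pd.read_csv(directory / "associations.csv")
    context_of = dict(zip(links["object_id"], links["context_id"]))

    def mk(row) -> BinaryPattern:
        values = np.frombuffer(row["values"].encode(), dtype=np.uint8) - ord("0")
        return BinaryPattern(values=values, role=Role(row["role"]), id=int(row["id"]))

    objects = tuple(mk(r) for _, r in table[table.role == "object"].iterrows())
    contexts = tuple(mk(r) for _, r in table[table.role == "context"].iterrows())
    n_ctx = len(contexts)
    per_ctx = len(objects) // n_ctx if n_ctx else 0
    return AssociationSet(
        objects=objects,
        contexts=contexts,
        objects_per_context=per_ctx,
        context_of=context_of,
    )


def save_weights(state, path: Path | str, *, seed: int | None = None, epoch: int | None = None) -> None:
    """Weight snapshot: .npz container plus a JSON sidecar."""
    path = Path(path)
    arrays = {f"{src}->{tgt}": w for (src, tgt), w in state.weights.items()}
    np.savez_compressed(path, **arrays)
    sidecar = {
        "spec": state.spec.name,
        "layers": {l.name: l.size for l in state.spec.layers},
        "seed": seed,
        "epoch": epoch,
        "package_version": _pkg_version(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_weights(state, path: Path | str) -> None:
    """Load a snapshot into an existing state (shapes must match)."""
    with np.load(Path(path)) as data:
        for key in data.files:
            src, tgt = key.split("->")
            if (src, tgt) not in state.weights:
                raise ValueError(f"snapshot projection {key} missing from spec")
            if state.weights[(src, tgt)].shape != data[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            state.weights[(src, tgt)][...] = data[key]
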