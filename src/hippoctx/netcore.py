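"""Rate-coded network engine: kWTA inhibition, two-phase settling, CHL learning.

Each layer is a vector of rate-coded units in [0, 1].  Inhibition within a
layer is a k-winner-take-all competition: the k most driven units fire (with a
logistic rate above 0.5), all others are silenced.  Learning is contrastive
Hebbian (the GeneRec family): a *minus* phase settles with only the inputs
clamped, a *plus* phase additionally clamps the target outputs, and weights
move toward the plus-phase unit coproducts and away from the minus-phase
coproducts, with a small normalizing Hebbian component and soft weight
bounding that keeps every weight in [0, 1].

Net input to a layer sums over incoming projections, each scaled by a relative
weight multiplier and normalized by the expected number of active sender
units, so that multipliers are comparable across source layers of different
sizes and sparseness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .patterns import BinaryPattern, Trial

__all__ = [
    "LayerSpec",
    "ProjectionSpec",
    "NetworkSpec",
    "NetworkState",
    "SettleConfig",
    "LearningConfig",
    "PhasePair",
    "init_network",
    "net_input",
    "kwta_threshold",
    "kwta_winners",
    "settle",
    "run_trial",
    "chl_update",
    "binarize",
    "output_error",
]

# deterministic, vanishingly small index-order perturbation used to break ties
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class LayerSpec:
    name: str
    size: int
    activity_fraction: float
    clampable: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"layer {self.name!r}: size must be positive")
        if not 0.0 < self.activity_fraction <= 1.0:
            raise ValueError(f"layer {self.name!r}: activity_fraction must be in (0, 1]")
        if self.k_active > self.size:
            raise ValueError(f"layer {self.name!r}: k_active exceeds size")

    @property
    def k_active(self) -> int:
        # round-half-to-even is fine here: no published fraction sits on a tie
        return max(1, int(np.rint(self.activity_fraction * self.size)))


@dataclass(frozen=True)
class ProjectionSpec:
    """Dense projection; ``connectivity`` < 1 keeps a random subset of synapses.

    Sparse connectivity is optional — anatomically sparse-but-strong pathways
    (mossy fibers) are represented by their relative weight multiplier by
    default.
    """

    source: str
    target: str
    rel_weight: float = 1.0
    learnable: bool = True
    bidirectional: bool = False
    connectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.rel_weight < 0:
            raise ValueError("rel_weight must be nonnegative")
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError("connectivity must be in (0, 1]")


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    projections: tuple[ProjectionSpec, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        known = set(names)
        for p in self.projections:
            if p.source not in known or p.target not in known:
                raise ValueError(f"projection {p.source}->{p.target} references a missing layer")

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"unknown layer {name!r}")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.layers)

    def weight_edges(self) -> list[tuple[str, str, float, bool, float]]:
        """Directed (source, target, rel_weight, learnable, connectivity) edges.

        Bidirectional projections contribute one edge per direction, each with
        an independent weight table.
        """
        edges = []
        for p in self.projections:
            edges.append((p.source, p.target, p.rel_weight, p.learnable, p.connectivity))
            if p.bidirectional:
                edges.append((p.target, p.source, p.rel_weight, p.learnable, p.connectivity))
        return edges

    def incoming(self, target: str) -> list[tuple[str, str, float, bool, float]]:
        return [e for e in self.weight_edges() if e[1] == target]


@dataclass
class SettleConfig:
    """Settling dynamics: synchronous damped updates under kWTA inhibition.

    ``step_size`` is the per-cycle integration step: each free unit moves that
    fraction of the way toward its instantaneous kWTA-gated logistic rate.
    Values below 1 damp the winner-set oscillations that bidirectional
    projections otherwise sustain.
    """

    max_cycles: int = 8
    tolerance: float = 1e-3
    gain: float = 6.0
    step_size: float = 0.5
    clamp_value: float = 1.0

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.step_size <= 1.0:
            raise ValueError("step_size must be in (0, 1]")


@dataclass
class LearningConfig:
    learning_rate: float = 0.05
    hebbian_mix: float = 0.01
    soft_bounding: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.hebbian_mix <= 1.0:
            raise ValueError("hebbian_mix must be in [0, 1]")


class NetworkState:
    """Mutable weights and activations for one network instance."""

    def __init__(
        self,
        spec: NetworkSpec,
        weights: dict[tuple[str, str], np.ndarray],
        rng: np.random.Generator,
    ) -> None:
        self.spec = spec
        self.weights = weights
        self.rng = rng
        self.activations: dict[str, np.ndarray] = {
            l.name: np.zeros(l.size) for l in spec.layers
        }
        self._incoming_cache = {name: spec.incoming(name) for name in spec.layer_names}
        # precomputed (source, weight-key, rel_weight / k_active(source)) per target
        self._drive_terms: dict[str, list[tuple[str, tuple[str, str], float]]] = {
            name: [
                (src, (src, tgt), rel / spec.layer(src).k_active)
                for src, tgt, rel, _learn, _conn in self._incoming_cache[name]
                if rel != 0.0
            ]
            for name in spec.layer_names
        }
        # boolean masks for projections with partial connectivity
        self.masks: dict[tuple[str, str], np.ndarray] = {}

    def incoming(self, target: str) -> list[tuple[str, str, float, bool]]:
        return self._incoming_cache[target]

    def weight_hash(self) -> int:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.weights):
            h.update(repr(key).encode())
            h.update(self.weights[key].tobytes())
        return int.from_bytes(h.digest()[:8], "big")


@dataclass(frozen=True)
class PhasePair:
    """Minus- and plus-phase activation snapshots of one trial."""

    minus: Mapping[str, np.ndarray]
    plus: Mapping[str, np.ndarray]


def init_network(spec: NetworkSpec, rng: np.random.Generator) -> NetworkState:
    """Fresh state: weights uniform in [0.25, 0.75], activations zero.

    Projections with ``connectivity`` < 1 get a fixed random synapse mask;
    masked synapses stay at zero through learning.
    """
    weights: dict[tuple[str, str], np.ndarray] = {}
    masks: dict[tuple[str, str], np.ndarray] = {}
    for src, tgt, _rel, _learn, conn in spec.weight_edges():
        n_src = spec.layer(src).size
        n_tgt = spec.layer(tgt).size
        w = rng.uniform(0.25, 0.75, size=(n_src, n_tgt))
        if conn < 1.0:
            mask = rng.random((n_src, n_tgt)) < conn
            w *= mask
            masks[(src, tgt)] = mask
        weights[(src, tgt)] = w
    state = NetworkState(spec, weights, rng)
    state.masks = masks
    return state


def net_input(
    state: NetworkState,
    target_layer: str,
    activations: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Total drive to a layer.

    Each projection contributes rel_weight * (senders @ W) / k_active(source):
    normalizing by the expected active sender count makes relative multipliers
    comparable across source layers of different sizes.
    """
    acts = state.activations if activations is None else activations
    spec = state.spec
    tgt_size = spec.layer(target_layer).size
    a_any = next(iter(acts.values()))
    batched = a_any.ndim == 2
    drive = np.zeros((a_any.shape[0], tgt_size)) if batched else np.zeros(tgt_size)
    for src, key, scale in state._drive_terms[target_layer]:
        drive += scale * (acts[src] @ state.weights[key])
    return drive


def _perturbed(drives: np.ndarray) -> np.ndarray:
    idx = np.arange(drives.shape[-1])
    return drives - _TIE_EPS * idx


def kwta_threshold(drives: np.ndarray, k: int) -> float:
    """Midpoint between the k-th and (k+1)-th largest (tie-perturbed) drives.

    Exactly k units strictly exceed the returned threshold; ties are broken in
    favor of lower indices by a deterministic index-order perturbation.
    """
    drives = np.asarray(drives, dtype=float)
    n = drives.shape[-1]
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range [0, {n}]")
    d = _perturbed(drives)
    if k == 0:
        return float(np.max(d, axis=-1) + 1.0)
    if k == n:
        return float(np.min(d, axis=-1) - 1.0)
    part = np.partition(d, (n - k - 1, n - k), axis=-1)
    kth = part[..., n - k]      # k-th largest
    k1th = part[..., n - k - 1] # (k+1)-th largest
    return float((kth + k1th) / 2.0)


def _kwta_threshold_batch(d: np.ndarray, k: int) -> np.ndarray:
    """Threshold for already tie-perturbed drives (batched over leading axes)."""
    n = d.shape[-1]
    if k == 0:
        return np.max(d, axis=-1) + 1.0
    if k == n:
        return np.min(d, axis=-1) - 1.0
    part = np.partition(d, (n - k - 1, n - k), axis=-1)
    return (part[..., n - k] + part[..., n - k - 1]) / 2.0


def kwta_winners(drives: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k winning units (lowest index wins ties)."""
    d = _perturbed(np.asarray(drives, dtype=float))
    n = d.shape[-1]
    if k == 0:
        return np.zeros_like(d, dtype=bool)
    if k == n:
        return np.ones_like(d, dtype=bool)
    part = np.partition(d, (n - k - 1, n - k), axis=-1)
    thr = (part[..., n - k] + part[..., n - k - 1]) / 2.0
    return d > np.expand_dims(thr, -1) if d.ndim == 2 else d > thr


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -500, 500, out=out)
    np.negative(out, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def _clamp_array(
    pattern: BinaryPattern | np.ndarray, size: int, clamp_value: float
) -> np.ndarray:
    vals = pattern.values if isinstance(pattern, BinaryPattern) else np.asarray(pattern)
    vals = vals.astype(float)
    if vals.shape[-1] != size:
        raise ValueError(f"clamp length {vals.shape[-1]} != layer size {size}")
    return vals * clamp_value


@dataclass
class SettleResult:
    activations: dict[str, np.ndarray]
    cycles: int
    converged: bool


def settle(
    state: NetworkState,
    clamps: Mapping[str, BinaryPattern | np.ndarray],
    cfg: SettleConfig | None = None,
    *,
    init: Mapping[str, np.ndarray] | None = None,
    batch: int | None = None,
) -> SettleResult:
    """Synchronously settle the free layers under the given clamps.

    Clamped layers stay fixed; each cycle every free layer recomputes its
    drive, the kWTA threshold picks its k winners, winners fire at
    logistic(gain * (drive - threshold)) and losers are silenced.  Settling
    stops when the largest activation change drops below the tolerance or
    after ``max_cycles`` cycles (flagged as non-converged).

    ``batch`` evaluates many independent input rows against the same frozen
    weights (clamp values must then be 2-D arrays).
    """
    if cfg is None:
        cfg = SettleConfig()
    spec = state.spec
    B = batch
    shape = (lambda n: (B, n)) if B is not None else (lambda n: (n,))

    acts: dict[str, np.ndarray] = {}
    for l in spec.layers:
        if init is not None and l.name in init:
            a = np.array(init[l.name], dtype=float)
            if B is not None and a.ndim == 1:
                a = np.broadcast_to(a, shape(l.size)).copy()
            acts[l.name] = a
        else:
            acts[l.name] = np.zeros(shape(l.size))
    for name, pattern in clamps.items():
        lspec = spec.layer(name)
        if not lspec.clampable:
            raise ValueError(f"layer {name!r} is not clampable")
        arr = _clamp_array(pattern, lspec.size, cfg.clamp_value)
        if B is not None and arr.ndim == 1:
            arr = np.broadcast_to(arr, shape(lspec.size)).copy()
        acts[name] = arr

    free = [(l.name, l.k_active) for l in spec.layers if l.name not in clamps]
    terms = {name: state._drive_terms[name] for name, _k in free}
    weights = state.weights
    converged = False
    cycles = 0
    dt = cfg.step_size
    gain = cfg.gain
    for cycle in range(cfg.max_cycles):
        cycles = cycle + 1
        new_acts = dict(acts)
        max_delta = 0.0
        for name, k in free:
            drive = None
            for src, key, scale in terms[name]:
                contrib = acts[src] @ weights[key]
                contrib *= scale
                if drive is None:
                    drive = contrib
                else:
                    drive += contrib
            if drive is None:
                drive = np.zeros_like(acts[name])
            d = _perturbed(drive)
            thr = _kwta_threshold_batch(d, k)
            thr_e = np.expand_dims(thr, -1) if d.ndim == 2 else thr
            target = _logistic(gain * (drive - thr_e))
            target[d <= thr_e] = 0.0
            old = acts[name]
            a = old + dt * (target - old)
            delta = float(np.max(np.abs(a - old))) if a.size else 0.0
            if delta > max_delta:
                max_delta = delta
            new_acts[name] = a
        acts = new_acts
        if max_delta < cfg.tolerance:
            converged = True
            break
    return SettleResult(activations=acts, cycles=cycles, converged=converged)


def _trial_input_clamps(state: NetworkState, trial: Trial) -> dict[str, np.ndarray]:
    spec = state.spec
    clamps = {}
    lec = trial.lec_input.values if trial.lec_input is not None else np.zeros(
        spec.layer("LEC").size, dtype=np.uint8
    )
    mec = trial.mec_input.values if trial.mec_input is not None else np.zeros(
        spec.layer("MEC").size, dtype=np.uint8
    )
    clamps["LEC"] = lec
    clamps["MEC"] = mec
    return clamps


def run_trial(
    state: NetworkState,
    trial: Trial,
    cfg: SettleConfig | None = None,
) -> PhasePair:
    """Minus phase (inputs clamped) then plus phase (inputs + targets clamped).

    The plus phase starts from the minus-phase activations.
    """
    input_clamps = _trial_input_clamps(state, trial)
    minus = settle(state, input_clamps, cfg)
    plus_clamps = dict(input_clamps)
    for name, target in trial.targets.as_dict().items():
        plus_clamps[name] = target
    plus = settle(state, plus_clamps, cfg, init=minus.activations)
    return PhasePair(minus=minus.activations, plus=plus.activations)


def chl_update(
    state: NetworkState,
    phases: PhasePair,
    cfg: LearningConfig | None = None,
) -> NetworkState:
    """Contrastive-Hebbian weight update (in place) for learnable projections.

    dw_ij = eps * [(1-lam) * (x+_i y+_j - x-_i y-_j) + lam * y+_j (x+_i - w_ij)]

    With soft bounding, positive raw changes are scaled by (1 - w) and
    negative ones by w, which confines weights to [0, 1].
    """
    if cfg is None:
        cfg = LearningConfig()
    eps, lam = cfg.learning_rate, cfg.hebbian_mix
    for src, tgt, _rel, learnable, _conn in state.spec.weight_edges():
        if not learnable:
            continue
        w = state.weights[(src, tgt)]
        mask = state.masks.get((src, tgt))
        xp, yp = phases.plus[src], phases.plus[tgt]
        xm, ym = phases.minus[src], phases.minus[tgt]
        # sender activities are sparse (kWTA); only rows with an active sender
        # in either phase can change, so restrict the update to those rows
        rows = np.flatnonzero((xp != 0) | (xm != 0))
        if rows.size == 0:
            continue
        xpr, xmr = xp[rows, None], xm[rows, None]
        wr = w[rows]
        raw = (1.0 - lam) * (xpr * yp[None, :] - xmr * ym[None, :])
        if lam:
            raw += lam * yp[None, :] * (xpr - wr)
        if cfg.soft_bounding:
            raw *= np.where(raw > 0, 1.0 - wr, wr)
        wr += eps * raw
        np.clip(wr, 0.0, 1.0, out=wr)
        if mask is not None:
            wr *= mask[rows]
        w[rows] = wr
    return state


def binarize(activations: np.ndarray, m: int) -> np.ndarray:
    """Top-m units by activation set to 1 (ties to the lowest index)."""
    activations = np.asarray(activations, dtype=float)
    n = activations.shape[-1]
    if not 0 <= m <= n:
        raise ValueError(f"m={m} out of range [0, {n}]")
    out = np.zeros_like(activations, dtype=np.uint8)
    if m == 0:
        return out
    d = _perturbed(activations)
    if activations.ndim == 1:
        top = np.argpartition(-d, m - 1)[:m]
        out[top] = 1
    else:
        top = np.argpartition(-d, m - 1, axis=-1)[..., :m]
        np.put_along_axis(out, top, 1, axis=-1)
    return out


def output_error(
    activations: np.ndarray,
    target: np.ndarray | BinaryPattern,
    metric: str = "miss_rate",
) -> float:
    """Recall error of an output layer against a binary target.

    ``miss_rate`` (default): fraction of target-active units missed by a
    top-m readout (m = the target's active count).  ``sse``: mean squared
    deviation of the raw activations from the binary target.
    """
    tgt = target.values if isinstance(target, BinaryPattern) else np.asarray(target)
    activations = np.asarray(activations, dtype=float)
    if activations.shape[-1] != tgt.shape[-1]:
        raise ValueError("activation/target length mismatch")
    m = int(tgt.sum())
    if m == 0:
        raise ValueError("target has no active units")
    if metric == "sse":
        return float(np.mean((activations - tgt) ** 2))
    if metric != "miss_rate":
        raise ValueError(f"unknown metric {metric!r}")
    pred = binarize(activations, m)
    misses = int(np.sum((tgt == 1) & (pred == 0)))
    return misses / m
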