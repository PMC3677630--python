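"""Training, evaluation and the comparative experiment batteries.

A *study* fixes the world (number of contexts, objects per context, pattern
geometry), the architecture scale, the training schedule and the engine
parameters.  ``full_study()`` is the published configuration (120 objects,
40 contexts, full layer sizes, 20 epochs); ``reduced_study()`` is a smaller
world at reduced layer sizes that preserves the 3:1 object:context ratio and
the layer-size ratios, used for fast replication runs.

Training presents all matched object-context pairs in a random order each
epoch, runs the minus/plus phase pair and applies one contrastive-Hebbian
update per presentation.  Training error is measured at each epoch end by
pure minus-phase recall on the full training set, the same read-out used at
test time.  After training the weights are frozen; evaluation never modifies
them.

The error of an output layer on a trial is the fraction of target-active
units missed by a top-m readout of the layer's minus-phase activation (m =
the target's active count); the CBOG error averages this over its
object-pattern slots.  The combined score of a network on a test is
mean(O error, min(C error, OBCG error)) -- the object output plus the best
context output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import patterns as pt
from .architectures import ArchitectureConfig, VARIANTS, build_network, default_config
from .netcore import (
    LearningConfig,
    NetworkSpec,
    NetworkState,
    SettleConfig,
    binarize,
    chl_update,
    init_network,
    run_trial,
    settle,
)

__all__ = [
    "StudyConfig",
    "full_study",
    "reduced_study",
    "TrainingLog",
    "ErrorReport",
    "SweepResult",
    "matched_trials",
    "train",
    "evaluate",
    "combined_score",
    "summarize_reports",
    "run_sample_tasks",
    "sweep_crossconnections",
    "run_battery",
    "sweep_ca3_size",
    "training_error_comparison",
    "NOISE_LEVELS",
    "COMPLETENESS_LEVELS",
]

OUTPUTS = ("O", "OBCG", "CBOG", "C")

# level grids for the corruption batteries
NOISE_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
COMPLETENESS_LEVELS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)


@dataclass(frozen=True)
class StudyConfig:
    """World size, architecture scale and engine parameters for one study."""

    n_contexts: int = 40
    objects_per_context: int = 3
    n_units: int = 64
    n_active: int = 16
    epochs: int = 20
    dg_size: int = 800
    ca3_size: int = 256
    ca1_size: int = 400
    settle: SettleConfig = field(default_factory=SettleConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)

    @property
    def n_objects(self) -> int:
        return self.n_contexts * self.objects_per_context

    def architecture(self, variant: str, **overrides) -> ArchitectureConfig:
        cfg = default_config(variant)
        fields = dict(
            ec_size=self.n_units,
            output_size=self.n_units,
            objects_per_context=self.objects_per_context,
            dg_size=self.dg_size,
            ca3_size=self.ca3_size,
            ca1_size=self.ca1_size,
        )
        fields.update(overrides)
        return replace(cfg, **fields)

    def world(self, rng: np.random.Generator) -> pt.AssociationSet:
        return pt.build_association_set(
            n_contexts=self.n_contexts,
            objects_per_context=self.objects_per_context,
            n_units=self.n_units,
            n_active=self.n_active,
            rng=rng,
        )


def full_study() -> StudyConfig:
    """The published study conditions (120 objects / 40 contexts, full sizes)."""
    return StudyConfig()


def reduced_study() -> StudyConfig:
    """Desk-scale study: 36 objects / 12 contexts, layers at roughly half size.

    Preserves the 3:1 object:context ratio, the pattern geometry (16-of-64)
    and the layer-size ratios of the full study, so the comparative effects
    survive while a full training run takes seconds rather than minutes.
    """
    return StudyConfig(n_contexts=12, dg_size=400, ca3_size=128, ca1_size=200)


@dataclass
class TrainingLog:
    """Per-epoch, per-output mean training error for one seed."""

    errors: pd.DataFrame  # index: epoch (1-based), columns: OUTPUTS
    seed: int
    variant: str

    @property
    def final(self) -> pd.Series:
        return self.errors.iloc[-1]


@dataclass
class ErrorReport:
    """Per-trial errors of one trained network on one trial set."""

    per_trial: pd.DataFrame  # one row per trial; output columns + tag columns
    outputs: tuple[str, ...]
    seed: int | None = None

    @property
    def means(self) -> pd.Series:
        return self.per_trial[list(self.outputs)].mean()

    @property
    def combined(self) -> float:
        return combined_score(self.means)


def combined_score(means: Mapping[str, float]) -> float:
    """mean(O error, best context output error)."""
    best_context = min(means["C"], means["OBCG"])
    return (means["O"] + best_context) / 2.0


def summarize_reports(reports: Sequence[ErrorReport]) -> pd.DataFrame:
    """Mean and SEM across replicate seeds for each output plus the combined score."""
    rows = []
    for rep in reports:
        row = rep.means.to_dict()
        if {"O", "C", "OBCG"} <= set(rep.outputs):
            row["combined"] = rep.combined
        rows.append(row)
    df = pd.DataFrame(rows)
    out = pd.DataFrame({"mean": df.mean()})
    out["sem"] = df.sem() if len(df) >= 2 else np.nan
    return out


def matched_trials(assoc: pt.AssociationSet) -> list[pt.Trial]:
    """The clean training trials: every object with its trained context."""
    return [
        pt.Trial(
            lec_input=obj,
            mec_input=assoc.context_by_id(assoc.context_of[obj.id]),
            targets=pt.make_targets(obj.id, assoc.context_of[obj.id], assoc),
            tags={"battery": "training"},
        )
        for obj in assoc.objects
    ]


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _trial_matrices(spec: NetworkSpec, trials: Sequence[pt.Trial]) -> dict[str, np.ndarray]:
    n = spec.layer("LEC").size
    lec = np.stack(
        [t.lec_input.values if t.lec_input is not None else np.zeros(n, dtype=np.uint8) for t in trials]
    )
    mec = np.stack(
        [t.mec_input.values if t.mec_input is not None else np.zeros(n, dtype=np.uint8) for t in trials]
    )
    return {"LEC": lec, "MEC": mec}


def _slot_errors(
    acts: np.ndarray, targets: np.ndarray, slot: int, permutation_invariant: bool = False
) -> np.ndarray:
    """Per-trial miss fraction, averaged over ``slot``-sized target slots.

    By default slots are scored on the canonical (ascending object-id)
    ordering; ``permutation_invariant`` scores the best assignment of
    predicted slots to target slots instead.
    """
    import itertools

    B, n = targets.shape
    n_slots = n // slot

    def miss(a: np.ndarray, t: np.ndarray) -> np.ndarray:
        m = int(t[0].sum())
        pred = binarize(a, m)
        return ((t == 1) & (pred == 0)).sum(axis=1) / m

    if not permutation_invariant or n_slots == 1:
        errs = np.zeros(B)
        for s in range(n_slots):
            errs += miss(
                acts[:, s * slot : (s + 1) * slot], targets[:, s * slot : (s + 1) * slot]
            )
        return errs / n_slots

    pairwise = np.zeros((n_slots, n_slots, B))
    for i in range(n_slots):
        for j in range(n_slots):
            pairwise[i, j] = miss(
                acts[:, i * slot : (i + 1) * slot], targets[:, j * slot : (j + 1) * slot]
            )
    best = np.full(B, np.inf)
    for perm in itertools.permutations(range(n_slots)):
        total = sum(pairwise[i, j] for i, j in enumerate(perm)) / n_slots
        best = np.minimum(best, total)
    return best


def evaluate(
    state: NetworkState,
    trials: Sequence[pt.Trial],
    outputs: Sequence[str] = OUTPUTS,
    settle_cfg: SettleConfig | None = None,
    seed: int | None = None,
    cbog_permutation_invariant: bool = False,
) -> ErrorReport:
    """Frozen-weight minus-phase recall over a trial set (batched)."""
    spec = state.spec
    clamps = _trial_matrices(spec, trials)
    B = len(trials)
    result = settle(state, clamps, settle_cfg, batch=B)
    acts = result.activations

    data: dict[str, np.ndarray] = {}
    slot = spec.layer("O").size
    for out in outputs:
        targets = np.stack([t.targets.as_dict()[out] for t in trials])
        slot_size = slot if out == "CBOG" else targets.shape[1]
        data[out] = _slot_errors(
            acts[out],
            targets,
            slot_size,
            permutation_invariant=(out == "CBOG" and cbog_permutation_invariant),
        )
    df = pd.DataFrame(data)
    for key in sorted({k for t in trials for k in t.tags}):
        df[key] = [t.tags.get(key) for t in trials]
    return ErrorReport(per_trial=df, outputs=tuple(outputs), seed=seed)


def train(
    spec: NetworkSpec,
    assoc: pt.AssociationSet,
    epochs: int = 20,
    seeds: Sequence[int] = (0,),
    settle_cfg: SettleConfig | None = None,
    learn_cfg: LearningConfig | None = None,
    log_every_epoch: bool = True,
) -> list[tuple[NetworkState, TrainingLog]]:
    """Train one network replicate per seed on the matched pairs.

    Each epoch presents all object-context pairs in a fresh random order and
    applies one weight update per presentation; the end-of-epoch training
    error is minus-phase recall on the full (clean) training set.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    trials = matched_trials(assoc)
    results = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        state = init_network(spec, rng)
        rows = []
        for epoch in range(1, epochs + 1):
            order = rng.permutation(len(trials))
            for idx in order:
                phases = run_trial(state, trials[idx], settle_cfg)
                chl_update(state, phases, learn_cfg)
            if log_every_epoch or epoch == epochs:
                report = evaluate(state, trials, settle_cfg=settle_cfg)
                rows.append(report.means.rename(epoch))
        log = TrainingLog(errors=pd.DataFrame(rows), seed=int(seed), variant=spec.name)
        results.append((state, log))
    return results


def _spawn_seeds(base_seed: int, n: int, stream: str) -> list[int]:
    import zlib

    ss = np.random.SeedSequence([base_seed, zlib.crc32(stream.encode()) % (2**31)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# the calibration (sample-task) sweep
# ---------------------------------------------------------------------------

# which output is scored on which sample battery
SAMPLE_BATTERY_OF = {
    "O": "sample_O_C",
    "C": "sample_O_C",
    "OBCG": "sample_OBCG",
    "CBOG": "sample_CBOG",
}


def _uniform_cross_config(study: StudyConfig, variant: str, multiplier: float) -> ArchitectureConfig:
    cfg = study.architecture(variant)
    cross = {region: multiplier for region in cfg.posterior_cross}
    return replace(cfg, posterior_cross=cross, anterior_cross=multiplier)


def run_sample_tasks(
    variant: str,
    multiplier: float,
    n_seeds: int = 10,
    study: StudyConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Train at one crossconnection multiplier and score the sample tasks.

    The multiplier is applied uniformly: to every posterior MEC
    crossconnection and to the shared anterior LEC crossconnection.  Returns
    one row per seed with the four per-output mean errors (each output scored
    on its own battery: mixed noise / partial for O and C, mismatch plus
    degraded context for OBCG, mismatch plus degraded object for CBOG).
    """
    if multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    study = study or reduced_study()
    world_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "world")[0])
    assoc = study.world(world_rng)
    cfg = _uniform_cross_config(study, variant, multiplier)
    spec = build_network(cfg)
    seeds = _spawn_seeds(base_seed, n_seeds, f"train-{variant}-{multiplier}")
    trained = train(
        spec, assoc, study.epochs, seeds, study.settle, study.learning, log_every_epoch=False
    )
    battery_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "batteries")[0])
    batteries = {
        name: pt.build_test_battery(assoc, name, rng=battery_rng)
        for name in ("sample_O_C", "sample_OBCG", "sample_CBOG")
    }
    rows = []
    for (state, _log), seed in zip(trained, seeds):
        row = {"seed": seed}
        for out, bat in SAMPLE_BATTERY_OF.items():
            rep = evaluate(state, batteries[bat], outputs=(out,), settle_cfg=study.settle)
            row[out] = float(rep.means[out])
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")[list(OUTPUTS)]


@dataclass
class SweepResult:
    """Per-grid-point error summaries for one swept parameter."""

    parameter: str
    grid: tuple[float, ...]
    summaries: pd.DataFrame  # index: grid value; columns: <output>_mean/_sem

    def curve(self, output: str) -> pd.Series:
        return self.summaries[f"{output}_mean"]


def _summary_row(df: pd.DataFrame, cols: Sequence[str]) -> dict[str, float]:
    row: dict[str, float] = {}
    for c in cols:
        row[f"{c}_mean"] = float(df[c].mean())
        row[f"{c}_sem"] = float(df[c].sem()) if len(df) >= 2 else np.nan
    return row


def sweep_crossconnections(
    variant: str = "Baseline",
    grid: Sequence[float] = (0.0, 1.5, 3.0),
    n_seeds: int = 10,
    study: StudyConfig | None = None,
    base_seed: int = 0,
) -> SweepResult:
    """Sample-task error per output as a function of crossconnection strength.

    The per-output curves identify the optimal posterior/anterior multipliers;
    the ``average`` column is the mean of the four per-output curves.
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    rows = []
    for mult in grid:
        per_seed = run_sample_tasks(variant, mult, n_seeds, study, base_seed)
        per_seed = per_seed.copy()
        per_seed["average"] = per_seed[list(OUTPUTS)].mean(axis=1)
        row = _summary_row(per_seed, list(OUTPUTS) + ["average"])
        row["multiplier"] = mult
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("multiplier")
    return SweepResult(parameter="crossconnection_multiplier", grid=tuple(grid), summaries=summaries)


# ---------------------------------------------------------------------------
# the comparative batteries
# ---------------------------------------------------------------------------


def train_variant(
    variant: str,
    study: StudyConfig,
    assoc: pt.AssociationSet,
    seeds: Sequence[int],
    log_every_epoch: bool = False,
    **arch_overrides,
) -> list[tuple[NetworkState, TrainingLog]]:
    """Train replicates of one variant at its default multipliers."""
    spec = build_network(study.architecture(variant, **arch_overrides))
    return train(
        spec, assoc, study.epochs, seeds, study.settle, study.learning, log_every_epoch
    )


def run_battery(
    variants: Sequence[str],
    battery_name: str,
    levels: Sequence[float] | None = None,
    n_seeds: int = 10,
    study: StudyConfig | None = None,
    base_seed: int = 0,
    trained: Mapping[str, Sequence[tuple[NetworkState, TrainingLog]]] | None = None,
) -> dict[str, SweepResult]:
    """Per-variant error curves over corruption levels for one battery.

    ``trained`` may supply pre-trained replicates per variant (they are reused
    read-only); otherwise each variant is trained at its default multipliers.
    Returns, per variant, a SweepResult over levels with per-output and
    combined-score means and SEMs.
    """
    study = study or reduced_study()
    if levels is None:
        levels = (
            COMPLETENESS_LEVELS if battery_name.startswith("partial") else NOISE_LEVELS
        )
    world_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "world")[0])
    assoc = study.world(world_rng)
    battery_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "batteries")[0])
    no_levels = battery_name in ("cbog_context_only", "mismatch")
    trials = pt.build_test_battery(
        assoc, battery_name, levels=None if no_levels else levels, rng=battery_rng
    )

    results: dict[str, SweepResult] = {}
    for variant in variants:
        if trained is not None and variant in trained:
            replicates = trained[variant]
        else:
            seeds = _spawn_seeds(base_seed, n_seeds, f"train-{variant}")
            replicates = train_variant(variant, study, assoc, seeds)
        rows = []
        level_values = [None] if no_levels else list(levels)
        for level in level_values:
            if level is None:
                level_trials = trials
            else:
                level_trials = [t for t in trials if t.tags.get("level") == level]
            reports = [
                evaluate(state, level_trials, settle_cfg=study.settle, seed=log.seed)
                for state, log in replicates
            ]
            per_seed = pd.DataFrame(
                [{**rep.means.to_dict(), "combined": rep.combined} for rep in reports]
            )
            # the object/context average used by the degraded-input panels
            per_seed["oc"] = (per_seed["O"] + per_seed["C"]) / 2.0
            row = _summary_row(per_seed, list(OUTPUTS) + ["combined", "oc"])
            row["level"] = np.nan if level is None else level
            rows.append(row)
        summaries = pd.DataFrame(rows).set_index("level")
        results[variant] = SweepResult(
            parameter=f"{battery_name}_level", grid=tuple(l for l in level_values if l is not None), summaries=summaries
        )
    return results


def sweep_ca3_size(
    sizes: Sequence[int] = (32, 128, 256, 512),
    n_seeds: int = 10,
    study: StudyConfig | None = None,
    base_seed: int = 0,
    partial_level: float = 0.4,
    trained: Mapping[int, Sequence[tuple[NetworkState, TrainingLog]]] | None = None,
) -> SweepResult:
    """Baseline O error on the partial-object task versus posterior CA3 size.

    ``trained`` may supply pre-trained Baseline replicates for specific sizes
    (e.g. the default-size pool shared with other experiments).
    """
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    study = study or reduced_study()
    world_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "world")[0])
    assoc = study.world(world_rng)
    battery_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "batteries")[0])
    trials = pt.build_test_battery(assoc, "partial_object", levels=[partial_level], rng=battery_rng)

    rows = []
    for size in sizes:
        if trained is not None and size in trained:
            replicates = trained[size]
        else:
            seeds = _spawn_seeds(base_seed, n_seeds, f"train-ca3-{size}")
            replicates = train_variant(
                "Baseline", study, assoc, seeds, posterior_ca3_size=int(size)
            )
        reports = [
            evaluate(state, trials, outputs=("O",), settle_cfg=study.settle, seed=log.seed)
            for state, log in replicates
        ]
        per_seed = pd.DataFrame([{"O": rep.means["O"]} for rep in reports])
        row = _summary_row(per_seed, ["O"])
        row["ca3_size"] = size
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("ca3_size")
    return SweepResult(parameter="posterior_ca3_size", grid=tuple(sizes), summaries=summaries)


EQUAL_UNITS_GROUP = ("Baseline", "SplitDG", "AllSplit")
EQUAL_ERROR_GROUP = ("Baseline", "SplitDGplus", "AllSplitplus")


def training_error_comparison(
    variants: Sequence[str] = VARIANTS,
    n_seeds: int = 10,
    study: StudyConfig | None = None,
    base_seed: int = 0,
    trained: Mapping[str, Sequence[tuple[NetworkState, TrainingLog]]] | None = None,
) -> pd.DataFrame:
    """Final training error per variant and output, with SEM and group flags."""
    study = study or reduced_study()
    world_rng = np.random.default_rng(_spawn_seeds(base_seed, 1, "world")[0])
    assoc = study.world(world_rng)
    rows = []
    for variant in variants:
        if trained is not None and variant in trained:
            replicates = trained[variant]
        else:
            seeds = _spawn_seeds(base_seed, n_seeds, f"train-{variant}")
            replicates = train_variant(variant, study, assoc, seeds)
        finals = pd.DataFrame([log.final.to_dict() for _state, log in replicates])
        row: dict[str, object] = {"variant": variant}
        row.update(_summary_row(finals, list(OUTPUTS)))
        row["equal_units_group"] = variant in EQUAL_UNITS_GROUP
        row["equal_error_group"] = variant in EQUAL_ERROR_GROUP
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
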