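"""Modified cascaded-ANFIS multiclass classifier.

The classifier consumes feature *groups* (default: seven groups of nine
ICA-reduced descriptor components per image) and wires small 2-input
Takagi–Sugeno ANFIS units into a cascade:

* **Level 1** holds one module per feature group.  A group module digests its
  nine features through an internal chain of eight 2-input units
  (``f1,f2 -> u1``; ``u1,f3 -> u2``; ... ``u7,f9 -> out``), so every unit
  keeps the canonical 2-input rule form and each unit consumes the previous
  unit's output.
* **Levels 2..G** each hold a single 2-input combiner that fuses the previous
  level's scalar with the next level-1 module's output, giving exactly ``G``
  levels for ``G`` groups.

Every unit is trained against the encoded class target (hybrid LSE +
premise-gradient, see :mod:`cascadefis.anfis`).  A *passthrough guard* keeps
the level-wise training RMSE non-increasing: a chain unit or combiner whose
training RMSE exceeds that of its first input is replaced by an identity
passthrough of that input.

Class labels map to the scalar regression target through a
:class:`LabelCodec`; the default ``index-regression`` strategy encodes sorted
classes as ``0..l-1`` and decodes by nearest-integer rounding with clamping.
A ``one-vs-rest`` strategy (one cascade per class, argmax of scores) is
available for problems where a single scalar ordering of classes is too
restrictive.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .anfis import (
    AnfisModel,
    TrainConfig,
    ZeroFiringError,
    build_grid_model,
    fit_consequents_lse,
    forward_batch,
    train,
)

__all__ = [
    "LabelCodec",
    "CascadeConfig",
    "CascadeArchitecture",
    "build_modified_architecture",
    "select_pairs",
    "train_cascade",
    "predict_cascade",
    "CascadedAnfis",
    "CascadeResults",
    "load_cascade",
]

_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# label codec
# ---------------------------------------------------------------------------

@dataclass
class LabelCodec:
    """Maps class labels onto the scalar ANFIS output and back.

    Classes are kept sorted; ``index-regression`` encodes them as the reals
    ``0.0 .. l-1`` and decodes by nearest-integer rounding clamped into the
    valid range.
    """

    classes: list
    strategy: str = "index-regression"

    def __post_init__(self) -> None:
        if len(self.classes) == 0:
            raise ValueError("at least one class required")
        if len(set(map(str, self.classes))) != len(self.classes):
            raise ValueError("duplicate classes")
        if self.strategy not in ("index-regression", "one-vs-rest"):
            raise ValueError(f"unknown codec strategy {self.strategy!r}")

    @classmethod
    def from_labels(cls, labels, strategy: str = "index-regression"):
        return cls(classes=sorted(set(labels)), strategy=strategy)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([index[l] for l in labels], dtype=float)
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None

    def decode(self, scalars) -> list:
        s = np.asarray(scalars, dtype=float)
        if np.any(~np.isfinite(s)):
            raise ValueError("cannot decode non-finite scalar output")
        idx = np.clip(np.rint(s).astype(int), 0, self.n_classes - 1)
        return [self.classes[i] for i in idx]


# ---------------------------------------------------------------------------
# configuration and architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeConfig:
    """Training configuration shared by every unit in the cascade."""

    mfs_per_input: int = 2
    epochs: int = 1
    premise_lr: float = 0.01
    lse_ridge: float = 1e-8
    seed: int = 0
    strategy: str = "one-vs-rest"
    kary_groups: bool = False  # True: one m^9-rule unit per group (no chain)
    pair_selection: bool = False  # True: pick the chain's seed pair by score

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            premise_lr=self.premise_lr,
            lse_ridge=self.lse_ridge,
            seed=self.seed,
        )


@dataclass
class CascadeArchitecture:
    """Wiring of the modified cascade.

    ``levels[0]`` lists one ``("group", g)`` wire per level-1 module;
    ``levels[j]`` (j >= 1) lists the single combiner's two wires, each either
    ``("group-module", g)`` (a level-1 output) or ``("module", level, index)``
    (a previous combiner's output).
    """

    n_groups: int
    group_dim: int
    levels: list

    def validate(self) -> None:
        if len(self.levels) != max(self.n_groups, 1):
            raise ValueError("total levels must equal the number of groups")
        if len(self.levels[0]) != self.n_groups:
            raise ValueError("level 1 must hold one module per group")
        if self.n_groups > 1 and len(self.levels[-1]) != 1:
            raise ValueError("final level must hold exactly one module")


def build_modified_architecture(
    n_groups: int, group_dim: int = 9
) -> CascadeArchitecture:
    """Sequential-chain wiring: G level-1 group modules + G-1 combiners.

    For ``n_groups == 7`` this yields seven level-1 modules and seven levels
    in total; each combiner level ``j`` fuses the previous level's output
    with the level-1 output of group ``j``.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if group_dim < 1:
        raise ValueError("group_dim must be >= 1")
    levels: list = [[("group", g) for g in range(n_groups)]]
    for j in range(1, n_groups):
        prev = ("group-module", 0) if j == 1 else ("module", j - 1, 0)
        levels.append([(prev, ("group-module", j))])
    arch = CascadeArchitecture(n_groups=n_groups, group_dim=group_dim,
                               levels=levels)
    arch.validate()
    return arch


# ---------------------------------------------------------------------------
# pair selection
# ---------------------------------------------------------------------------

def select_pairs(candidate_inputs, X, y, config: CascadeConfig = CascadeConfig()):
    """Rank input pairs by the training RMSE of a one-epoch 2-input fit.

    Each candidate pair gets a fresh grid-partition unit whose consequents
    are solved by a single LSE pass; pairs are returned best-first with ties
    broken by lexicographic pair index.
    """
    candidates = list(candidate_inputs)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate inputs")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scored = []
    for i, j in itertools.combinations(sorted(candidates), 2):
        Xp = X[:, [i, j]]
        ranges = np.column_stack([Xp.min(axis=0), Xp.max(axis=0)])
        unit = build_grid_model(ranges, config.mfs_per_input)
        unit = fit_consequents_lse(Xp, y, unit, ridge=config.lse_ridge)
        pred = forward_batch(Xp, unit, on_zero_firing="clamp")
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        scored.append((rmse, (i, j)))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [pair for _, pair in scored]


# ---------------------------------------------------------------------------
# unit fitting helpers
# ---------------------------------------------------------------------------

def _fit_unit(X2: np.ndarray, y: np.ndarray, config: CascadeConfig):
    """Train one 2-input unit; returns (model, rmse, predictions)."""
    ranges = np.column_stack([X2.min(axis=0), X2.max(axis=0)])
    unit = build_grid_model(ranges, config.mfs_per_input)
    unit, trace = train(X2, y, unit, config.train_config())
    pred = forward_batch(X2, unit, on_zero_firing="clamp")
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return unit, rmse, pred, trace


def _fit_kary_unit(X: np.ndarray, y: np.ndarray, config: CascadeConfig):
    """Train one k-ary unit over a whole group (m**k rules)."""
    ranges = np.column_stack([X.min(axis=0), X.max(axis=0)])
    unit = build_grid_model(ranges, config.mfs_per_input)
    unit, trace = train(X, y, unit, config.train_config())
    pred = forward_batch(X, unit, on_zero_firing="clamp")
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return unit, rmse, pred, trace


def _fit_chain(X: np.ndarray, y: np.ndarray, config: CascadeConfig):
    """Internal chain of 2-input units over a group's feature columns.

    Returns (steps, rmse, outputs, traces).  Each step is either
    ``{"kind": "anfis", "feature": j, "model": AnfisModel}`` consuming
    (previous output, feature j), or ``{"kind": "pass"}`` when the
    passthrough guard rejected the unit.  The first step consumes two raw
    features (duplicated when the group has a single column).
    """
    n, d = X.shape
    steps: list[dict] = []
    traces: list[np.ndarray] = []
    if d == 1:
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        unit, rmse, pred, trace = _fit_unit(X2, y, config)
        steps.append({"kind": "anfis", "feature": 0, "first": [0, 0],
                      "model": unit})
        return steps, rmse, pred, [trace]
    if config.pair_selection:
        first_pair = select_pairs(range(d), X, y, config)[0]
    else:
        first_pair = (0, 1)
    rest = [j for j in range(d) if j not in first_pair]
    unit, rmse, prev, trace = _fit_unit(X[:, list(first_pair)], y, config)
    steps.append({"kind": "anfis", "feature": first_pair[1],
                  "first": list(first_pair), "model": unit})
    traces.append(trace)
    for j in rest:
        X2 = np.column_stack([prev, X[:, j]])
        unit, new_rmse, pred, trace = _fit_unit(X2, y, config)
        if new_rmse > rmse:  # guard: keep the better upstream signal
            steps.append({"kind": "pass", "feature": j})
        else:
            steps.append({"kind": "anfis", "feature": j, "model": unit})
            rmse, prev = new_rmse, pred
            traces.append(trace)
    return steps, rmse, prev, traces


def _chain_forward(steps: list[dict], X: np.ndarray) -> np.ndarray:
    prev = None
    for step in steps:
        if step["kind"] == "pass":
            continue
        if "first" in step:
            i, j = step["first"]
            X2 = np.column_stack([X[:, i], X[:, j]])
        else:
            X2 = np.column_stack([prev, X[:, step["feature"]]])
        prev = forward_batch(X2, step["model"], on_zero_firing="clamp")
    return prev


# ---------------------------------------------------------------------------
# cascade training / prediction (functional surface)
# ---------------------------------------------------------------------------

def _check_groups(X_grouped) -> list[np.ndarray]:
    tables = []
    for g, T in enumerate(X_grouped):
        T = np.asarray(T, dtype=float)
        if T.ndim != 2:
            raise ValueError(f"group {g} table must be 2-D")
        if not np.all(np.isfinite(T)):
            raise ValueError(f"non-finite features in group {g}")
        tables.append(T)
    if len({T.shape[0] for T in tables}) > 1:
        raise ValueError("groups disagree on the number of samples")
    return tables


def _train_core(tables, target, config: CascadeConfig):
    """Train one scalar-output cascade; returns (core dict, rmse_per_level,
    traces)."""
    n_groups = len(tables)
    group_slots = []
    group_out = []
    group_rmse = []
    all_traces: list[np.ndarray] = []
    for g, T in enumerate(tables):
        if config.kary_groups:
            unit, rmse, pred, trace = _fit_kary_unit(T, target, config)
            group_slots.append({"kind": "kary", "model": unit})
            all_traces.append(trace)
        else:
            steps, rmse, pred, traces = _fit_chain(T, target, config)
            group_slots.append({"kind": "chain", "steps": steps})
            all_traces.extend(traces)
        group_out.append(pred)
        group_rmse.append(rmse)
    rmse_per_level = [group_rmse[0]]
    prev_out, prev_rmse = group_out[0], group_rmse[0]
    combiners = []
    for j in range(1, n_groups):
        X2 = np.column_stack([prev_out, group_out[j]])
        unit, rmse, pred, trace = _fit_unit(X2, target, config)
        if rmse > prev_rmse:  # passthrough guard -> monotone level RMSE
            combiners.append({"kind": "pass"})
            rmse_per_level.append(prev_rmse)
        else:
            combiners.append({"kind": "anfis", "model": unit})
            prev_out, prev_rmse = pred, rmse
            rmse_per_level.append(rmse)
            all_traces.append(trace)
    core = {"groups": group_slots, "combiners": combiners}
    return core, np.asarray(rmse_per_level), all_traces


def _core_forward(core: dict, tables: list[np.ndarray]) -> np.ndarray:
    outs = []
    for slot, T in zip(core["groups"], tables):
        if slot["kind"] == "kary":
            outs.append(forward_batch(T, slot["model"], on_zero_firing="clamp"))
        else:
            outs.append(_chain_forward(slot["steps"], T))
    prev = outs[0]
    for j, comb in enumerate(core["combiners"], start=1):
        if comb["kind"] == "pass":
            continue
        X2 = np.column_stack([prev, outs[j]])
        prev = forward_batch(X2, comb["model"], on_zero_firing="clamp")
    return prev


def train_cascade(X_grouped, y, config: CascadeConfig = CascadeConfig()):
    """Train the modified cascade on grouped features.

    Returns ``(results, rmse_per_level, rmse_trace)`` where ``results`` is a
    fitted :class:`CascadeResults`, ``rmse_per_level`` the (non-increasing)
    training RMSE after each cascade level, and ``rmse_trace`` the
    concatenated per-unit epoch traces in training order.
    """
    tables = _check_groups(X_grouped)
    y = list(y)
    if tables and tables[0].shape[0] != len(y):
        raise ValueError("label count does not match sample count")
    codec = LabelCodec.from_labels(y, strategy=config.strategy)
    if codec.n_classes < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    arch = build_modified_architecture(
        len(tables), tables[0].shape[1] if tables else 0
    )
    if config.strategy == "one-vs-rest":
        target_idx = codec.encode(y)
        cores, levels, traces = [], [], []
        for k in range(codec.n_classes):
            t = (target_idx == k).astype(float)
            core, rpl, tr = _train_core(tables, t, config)
            cores.append(core)
            levels.append(rpl)
            traces.extend(tr)
        rmse_per_level = np.mean(levels, axis=0)
        fitted = {"strategy": "one-vs-rest", "cores": cores}
    else:
        target = codec.encode(y)
        core, rmse_per_level, traces = _train_core(tables, target, config)
        fitted = {"strategy": "index-regression", "cores": [core]}
    results = CascadeResults(
        architecture=arch, fitted=fitted, codec=codec, config=config,
        rmse_per_level=rmse_per_level, rmse_trace=traces,
    )
    return results, rmse_per_level, traces


def predict_cascade(results: "CascadeResults", X_grouped) -> list:
    """Forward pass through the fitted cascade; returns decoded labels."""
    return results.predict(X_grouped)


# ---------------------------------------------------------------------------
# results object (statsmodels-style)
# ---------------------------------------------------------------------------

class CascadeResults:
    """Fitted modified cascaded-ANFIS classifier.

    Carries the architecture, every fitted unit, the label codec, the
    level-wise training RMSE diagnostics, and prediction / serialization.
    """

    def __init__(self, architecture, fitted, codec, config,
                 rmse_per_level, rmse_trace, model=None):
        self.architecture = architecture
        self.fitted = fitted
        self.codec = codec
        self.config = config
        self.rmse_per_level = np.asarray(rmse_per_level, dtype=float)
        self.rmse_trace = rmse_trace
        self.model = model

    # -- inference -------------------------------------------------------
    def decision_scores(self, X_grouped) -> np.ndarray:
        """Raw scalar outputs: (n,) for index regression, (n, l) for OVR."""
        tables = _check_groups(X_grouped)
        if len(tables) != self.architecture.n_groups:
            raise ValueError(
                f"expected {self.architecture.n_groups} feature groups, "
                f"got {len(tables)}"
            )
        n = tables[0].shape[0]
        if n == 0:
            return (np.empty((0, self.codec.n_classes))
                    if self.fitted["strategy"] == "one-vs-rest"
                    else np.empty(0))
        if self.fitted["strategy"] == "one-vs-rest":
            return np.column_stack(
                [_core_forward(c, tables) for c in self.fitted["cores"]]
            )
        return _core_forward(self.fitted["cores"][0], tables)

    def predict(self, X_grouped) -> list:
        scores = self.decision_scores(X_grouped)
        if scores.shape[0] == 0:
            return []
        if self.fitted["strategy"] == "one-vs-rest":
            return [self.codec.classes[i] for i in np.argmax(scores, axis=1)]
        return self.codec.decode(scores)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        a = self.architecture
        lines = [
            "Modified cascaded-ANFIS classification results",
            "=" * 48,
            f"Classes:               {self.codec.n_classes}",
            f"Codec strategy:        {self.codec.strategy}",
            f"Feature groups:        {a.n_groups} x {a.group_dim}",
            f"Cascade levels:        {len(a.levels)}",
            f"MFs per input:         {self.config.mfs_per_input}",
            f"Epochs per unit:       {self.config.epochs}",
            "-" * 48,
            "level  training RMSE",
        ]
        for j, r in enumerate(self.rmse_per_level, start=1):
            lines.append(f"{j:>5}  {r:.6f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def slot_to_dict(slot):
            if slot["kind"] == "pass":
                return {"kind": "pass", "feature": slot.get("feature")}
            if slot["kind"] == "kary":
                return {"kind": "kary", "model": slot["model"].to_dict()}
            if slot["kind"] == "chain":
                return {"kind": "chain",
                        "steps": [slot_to_dict(s) for s in slot["steps"]]}
            d = {"kind": "anfis", "model": slot["model"].to_dict()}
            if "feature" in slot:
                d["feature"] = slot["feature"]
            if "first" in slot:
                d["first"] = slot["first"]
            return d

        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "cascadefis-cascade",
            "architecture": {
                "n_groups": self.architecture.n_groups,
                "group_dim": self.architecture.group_dim,
                # canonical JSON form (tuples -> lists) so round-trips compare
                "levels": json.loads(json.dumps(self.architecture.levels)),
            },
            "codec": {"classes": list(self.codec.classes),
                      "strategy": self.codec.strategy},
            "config": {
                "mfs_per_input": self.config.mfs_per_input,
                "epochs": self.config.epochs,
                "premise_lr": self.config.premise_lr,
                "lse_ridge": self.config.lse_ridge,
                "seed": self.config.seed,
                "strategy": self.config.strategy,
                "kary_groups": self.config.kary_groups,
                "pair_selection": self.config.pair_selection,
            },
            "rmse_per_level": self.rmse_per_level.tolist(),
            "fitted": {
                "strategy": self.fitted["strategy"],
                "cores": [
                    {"groups": [slot_to_dict(s) for s in c["groups"]],
                     "combiners": [slot_to_dict(s) for s in c["combiners"]]}
                    for c in self.fitted["cores"]
                ],
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeResults":
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported cascade schema version {d.get('schema_version')!r}"
            )

        def slot_from_dict(s):
            if s["kind"] == "pass":
                return {"kind": "pass", "feature": s.get("feature")}
            if s["kind"] == "kary":
                return {"kind": "kary", "model": AnfisModel.from_dict(s["model"])}
            if s["kind"] == "chain":
                return {"kind": "chain",
                        "steps": [slot_from_dict(x) for x in s["steps"]]}
            out = {"kind": "anfis", "model": AnfisModel.from_dict(s["model"])}
            if "feature" in s:
                out["feature"] = s["feature"]
            if "first" in s:
                out["first"] = s["first"]
            return out

        arch = CascadeArchitecture(
            n_groups=d["architecture"]["n_groups"],
            group_dim=d["architecture"]["group_dim"],
            levels=json.loads(json.dumps(d["architecture"]["levels"])),
        )
        codec = LabelCodec(classes=d["codec"]["classes"],
                           strategy=d["codec"]["strategy"])
        config = CascadeConfig(**d["config"])
        fitted = {
            "strategy": d["fitted"]["strategy"],
            "cores": [
                {"groups": [slot_from_dict(s) for s in c["groups"]],
                 "combiners": [slot_from_dict(s) for s in c["combiners"]]}
                for c in d["fitted"]["cores"]
            ],
        }
        return cls(architecture=arch, fitted=fitted, codec=codec,
                   config=config,
                   rmse_per_level=np.asarray(d["rmse_per_level"]),
                   rmse_trace=[])

    @classmethod
    def load(cls, path) -> "CascadeResults":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as e:
                raise ValueError(f"corrupt cascade file {path}: {e}") from None
        return cls.from_dict(d)


def load_cascade(path) -> CascadeResults:
    """Load a cascade saved with :meth:`CascadeResults.save`."""
    return CascadeResults.load(path)


class CascadedAnfis:
    """Modified cascaded-ANFIS classification model (statsmodels-style).

    Parameters
    ----------
    endog : sequence of labels, length n
    exog_groups : sequence of arrays, each (n, d_g)
        One feature table per group (canonically 7 groups x 9 components).

    ``fit`` trains every unit of the cascade and returns a
    :class:`CascadeResults`.
    """

    def __init__(self, endog, exog_groups):
        self.endog = list(endog)
        self.exog_groups = _check_groups(exog_groups)
        if self.exog_groups and self.exog_groups[0].shape[0] != len(self.endog):
            raise ValueError("endog length does not match exog rows")

    @classmethod
    def from_frame(cls, df, label_col: str = "label"):
        """Build from a grouped feature DataFrame with ``g<G>_...`` columns."""
        group_ids = sorted(
            {int(c.split("_")[0][1:]) for c in df.columns if c != label_col}
        )
        groups = []
        for g in group_ids:
            cols = [c for c in df.columns
                    if c != label_col and c.startswith(f"g{g}_")]
            groups.append(df[cols].to_numpy(dtype=float))
        return cls(df[label_col].tolist(), groups)

    def fit(self, config: CascadeConfig | None = None, **kwargs) -> CascadeResults:
        if config is None:
            config = CascadeConfig(**kwargs)
        results, _, _ = train_cascade(self.exog_groups, self.endog, config)
        results.model = self
        return results
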