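"""Single Takagi–Sugeno ANFIS unit with hybrid least-squares/gradient training.

A first-order Takagi–Sugeno fuzzy system over ``k`` inputs assigns ``m``
triangular membership functions to each input and forms one rule per
membership combination (grid partition, ``n = m**k`` rules).  For an input
vector ``x`` the rule firing strengths are the products of the premise
membership degrees; the crisp output is the firing-strength-weighted mean of
the per-rule linear consequents::

    mu(x; a, b, c) = max(min((x - a)/(b - a), (c - x)/(c - b)), 0)
    w_j   = prod_i mu_{j,i}(x_i)
    wbar_j = w_j / sum_i w_i
    y     = sum_j wbar_j (p_j . x + r_j)

Training is the conventional hybrid scheme: the consequent coefficients are a
linear least-squares problem given fixed premises (solved exactly, with an
optional ridge), and the premise parameters take a small gradient step per
epoch, realised here by central finite differences on the training RMSE.

The module exposes both a functional surface (``mf_eval``, ``forward``,
``train`` ... operating on an :class:`AnfisModel` parameter container) and a
statsmodels-style ``Anfis(endog, exog).fit() -> AnfisResults`` pair built on
top of it.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TriangularMF",
    "Rule",
    "AnfisModel",
    "TrainConfig",
    "mf_eval",
    "firing_strengths",
    "normalize_firing",
    "forward",
    "forward_batch",
    "fit_consequents_lse",
    "train",
    "build_grid_model",
    "Anfis",
    "AnfisResults",
]


class ZeroFiringError(ValueError):
    """No rule fires for the given input (zero total firing strength)."""


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``a``, ``c`` and peak ``b``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"triangular MF requires a <= b <= c, got {self}")
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c)):
            raise ValueError(f"non-finite MF parameters: {self}")


@dataclass
class Rule:
    """One fuzzy rule: a premise MF per input and a linear consequent.

    ``consequent`` has one slope per input plus a trailing bias, so for the
    canonical 2-input unit it is ``(p, q, r)``.
    """

    premise: tuple[TriangularMF, ...]
    consequent: np.ndarray

    def __post_init__(self) -> None:
        self.consequent = np.asarray(self.consequent, dtype=float)
        if self.consequent.shape != (len(self.premise) + 1,):
            raise ValueError(
                "consequent length must be arity + 1, got "
                f"{self.consequent.shape} for arity {len(self.premise)}"
            )


@dataclass
class AnfisModel:
    """Grid-partition Takagi–Sugeno model: ``mfs_per_input**arity`` rules."""

    arity: int
    mfs_per_input: int
    rules: list[Rule]
    input_ranges: np.ndarray  # (arity, 2) [min, max] per input

    def __post_init__(self) -> None:
        self.input_ranges = np.asarray(self.input_ranges, dtype=float)
        n_expected = self.mfs_per_input ** self.arity
        if len(self.rules) != n_expected:
            raise ValueError(
                f"grid partition requires {n_expected} rules, got {len(self.rules)}"
            )
        if self.input_ranges.shape != (self.arity, 2):
            raise ValueError("input_ranges must be (arity, 2)")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "arity": self.arity,
            "mfs_per_input": self.mfs_per_input,
            "input_ranges": self.input_ranges.tolist(),
            "rules": [
                {
                    "premise": [[mf.a, mf.b, mf.c] for mf in r.premise],
                    "consequent": r.consequent.tolist(),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnfisModel":
        rules = [
            Rule(
                premise=tuple(TriangularMF(*mf) for mf in r["premise"]),
                consequent=np.asarray(r["consequent"], dtype=float),
            )
            for r in d["rules"]
        ]
        return cls(
            arity=d["arity"],
            mfs_per_input=d["mfs_per_input"],
            rules=rules,
            input_ranges=np.asarray(d["input_ranges"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "AnfisModel":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TrainConfig:
    """Hybrid-training configuration.

    epochs
        Number of LSE + premise-step alternations.
    premise_lr
        Step size for the finite-difference gradient step on (a, b, c),
        in units of the input range span.
    lse_ridge
        Tikhonov regularisation for the consequent least-squares solve.
    seed
        Recorded for provenance; training itself is deterministic.
    init
        Premise initialisation scheme; only ``uniform-grid`` is defined.
    """

    epochs: int = 10
    premise_lr: float = 0.01
    lse_ridge: float = 1e-8
    seed: int = 0
    init: str = "uniform-grid"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.premise_lr <= 0:
            raise ValueError("premise_lr must be > 0")
        if self.lse_ridge < 0:
            raise ValueError("lse_ridge must be >= 0")
        if self.init != "uniform-grid":
            raise ValueError(f"unknown init scheme {self.init!r}")


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def mf_eval(x: float, mf: TriangularMF) -> float:
    """Degree of membership of ``x`` in a triangular fuzzy set.

    Implements ``max(min((x-a)/(b-a), (c-x)/(c-b)), 0)``; a collapsed ramp
    (``a == b`` or ``b == c``) evaluates as 1 at the shared point, the limit
    of the ramp as its width shrinks to zero.
    """
    if not math.isfinite(x):
        raise ValueError(f"membership input must be finite, got {x}")
    a, b, c = mf.a, mf.b, mf.c
    if x < a or x > c:
        return 0.0
    left = 1.0 if b == a else (x - a) / (b - a)
    right = 1.0 if c == b else (c - x) / (c - b)
    return max(min(left, right), 0.0)


def _mf_eval_vec(x: np.ndarray, mf: TriangularMF) -> np.ndarray:
    """Vectorised :func:`mf_eval` over a 1-d sample array."""
    a, b, c = mf.a, mf.b, mf.c
    left = np.ones_like(x) if b == a else (x - a) / (b - a)
    right = np.ones_like(x) if c == b else (c - x) / (c - b)
    out = np.maximum(np.minimum(left, right), 0.0)
    out[(x < a) | (x > c)] = 0.0
    return out


def firing_strengths(inputs, model: AnfisModel) -> np.ndarray:
    """Layer-3 rule firing strengths: product of premise memberships."""
    x = np.asarray(inputs, dtype=float)
    if x.shape != (model.arity,):
        raise ValueError(f"expected {model.arity} inputs, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    w = np.empty(model.n_rules)
    for j, rule in enumerate(model.rules):
        w[j] = math.prod(mf_eval(x[i], mf) for i, mf in enumerate(rule.premise))
    return w


def normalize_firing(w) -> np.ndarray:
    """Layer-4 normalisation: ``wbar_j = w_j / sum_i w_i``."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("firing strengths must be non-negative")
    total = w.sum()
    if total == 0:
        raise ZeroFiringError("zero total firing: no rule fires for this input")
    return w / total


def forward(inputs, model: AnfisModel) -> float:
    """Layer-5 defuzzified output: ``sum_j wbar_j f_j(x)``."""
    x = np.asarray(inputs, dtype=float)
    wbar = normalize_firing(firing_strengths(x, model))
    out = 0.0
    for j, rule in enumerate(model.rules):
        f_j = float(rule.consequent[:-1] @ x + rule.consequent[-1])
        out += wbar[j] * f_j
    return out


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------

def _membership_matrix(X: np.ndarray, model: AnfisModel) -> np.ndarray:
    """Firing strengths for every sample: (n_samples, n_rules).

    Evaluates each rule's own premise MFs (no shared-grid assumption, so
    models with per-rule perturbed premises evaluate exactly like the
    scalar path); memoises repeated MF objects per input.
    """
    n = X.shape[0]
    cache: dict[tuple[int, TriangularMF], np.ndarray] = {}
    W = np.ones((n, model.n_rules))
    for j, rule in enumerate(model.rules):
        for i, mf in enumerate(rule.premise):
            key = (i, mf)
            if key not in cache:
                cache[key] = _mf_eval_vec(X[:, i], mf)
            W[:, j] *= cache[key]
    return W


def _grid_mfs(model: AnfisModel) -> list[list[TriangularMF]]:
    """Recover the per-input MF lists from the rule grid."""
    m = model.mfs_per_input
    out: list[list[TriangularMF]] = []
    for i in range(model.arity):
        seen: list[TriangularMF] = []
        for rule in model.rules:
            mf = rule.premise[i]
            if mf not in seen:
                seen.append(mf)
        if len(seen) != m:
            # duplicate MFs across the grid (can arise after degenerate
            # premise updates); fall back to positional extraction
            combos = list(_rule_combos(model))
            by_index: dict[int, TriangularMF] = {}
            for j, combo in enumerate(combos):
                by_index.setdefault(combo[i], model.rules[j].premise[i])
            seen = [by_index[k] for k in range(m)]
        out.append(seen)
    return out


def _rule_combos(model: AnfisModel):
    return itertools.product(range(model.mfs_per_input), repeat=model.arity)


def forward_batch(
    X, model: AnfisModel, on_zero_firing: str = "error"
) -> np.ndarray:
    """Vectorised forward pass over a sample matrix.

    ``on_zero_firing`` selects the handling of inputs outside every rule's
    support: ``"error"`` raises :class:`ZeroFiringError`; ``"clamp"`` clamps
    the offending inputs into the fitted per-input range (the nearest firing
    region in input space) and re-evaluates.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.arity:
        raise ValueError(f"X must be (n, {model.arity})")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    W = _membership_matrix(X, model)
    total = W.sum(axis=1)
    dead = total == 0
    if np.any(dead):
        if on_zero_firing == "error":
            raise ZeroFiringError(
                f"zero total firing for {int(dead.sum())} sample(s)"
            )
        if on_zero_firing != "clamp":
            raise ValueError(f"unknown on_zero_firing {on_zero_firing!r}")
        lo, hi = model.input_ranges[:, 0], model.input_ranges[:, 1]
        Xc = np.clip(X[dead], lo, hi)
        W[dead] = _membership_matrix(Xc, model)
        X = X.copy()
        X[dead] = Xc
        total = W.sum(axis=1)
        if np.any(total == 0):
            raise ZeroFiringError("zero total firing even after range clamp")
    Wbar = W / total[:, None]
    # per-rule linear consequents evaluated at the (possibly clamped) inputs
    C = np.stack([r.consequent for r in model.rules])  # (n_rules, arity+1)
    F = X @ C[:, :-1].T + C[:, -1]
    return np.sum(Wbar * F, axis=1)


# ---------------------------------------------------------------------------
# initialisation and training
# ---------------------------------------------------------------------------

def build_grid_model(
    input_ranges, mfs_per_input: int = 2, arity: int | None = None
) -> AnfisModel:
    """Uniform grid-partition model over the given per-input ranges.

    ``m`` triangles per input with peaks at the grid nodes and feet at the
    neighbouring nodes (half-overlap); the outermost feet extend one grid
    step beyond the range so boundary values keep full membership coverage.
    Consequents start at zero.
    """
    ranges = np.asarray(input_ranges, dtype=float)
    if arity is None:
        arity = ranges.shape[0]
    if ranges.shape != (arity, 2):
        raise ValueError("input_ranges must be (arity, 2)")
    m = mfs_per_input
    if m < 2:
        raise ValueError("mfs_per_input must be >= 2")
    per_input: list[list[TriangularMF]] = []
    for lo, hi in ranges:
        if hi <= lo:  # zero-variance input: widen to a unit interval
            lo, hi = lo - 0.5, lo + 0.5
        step = (hi - lo) / (m - 1)
        peaks = np.linspace(lo, hi, m)
        per_input.append(
            [TriangularMF(p - step, p, p + step) for p in peaks]
        )
    rules = [
        Rule(
            premise=tuple(per_input[i][k] for i, k in enumerate(combo)),
            consequent=np.zeros(arity + 1),
        )
        for combo in itertools.product(range(m), repeat=arity)
    ]
    return AnfisModel(
        arity=arity, mfs_per_input=m, rules=rules, input_ranges=ranges
    )


def _design_matrix(X: np.ndarray, model: AnfisModel) -> np.ndarray:
    """LSE design: columns ``wbar_j * [x_1..x_k, 1]`` for each rule."""
    W = _membership_matrix(X, model)
    total = W.sum(axis=1)
    if np.any(total == 0):
        raise ZeroFiringError(
            "zero total firing during fitting; inputs fall outside the grid"
        )
    Wbar = W / total[:, None]
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])  # (n, arity+1)
    # (n, n_rules*(arity+1)) with rule-major column blocks
    return (Wbar[:, :, None] * Xa[:, None, :]).reshape(X.shape[0], -1)


def fit_consequents_lse(
    X, y, model: AnfisModel, ridge: float = 1e-8
) -> AnfisModel:
    """Exact (ridge-regularised) least-squares update of all consequents.

    With the premises held fixed the network output is linear in the stacked
    consequent coefficients, so the global minimiser is available in closed
    form.  Deterministic; raises if the design is rank-deficient at
    ``ridge == 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.arity:
        raise ValueError(f"X must be (n, {model.arity})")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    Phi = _design_matrix(X, model)
    p = Phi.shape[1]
    if ridge > 0:
        beta = np.linalg.solve(Phi.T @ Phi + ridge * np.eye(p), Phi.T @ y)
    else:
        beta, _, rank, _ = np.linalg.lstsq(Phi, y, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"rank-deficient LSE design (rank {rank} < {p}); "
                "use ridge > 0"
            )
    beta = beta.reshape(model.n_rules, model.arity + 1)
    new_rules = [
        Rule(premise=r.premise, consequent=beta[j])
        for j, r in enumerate(model.rules)
    ]
    return replace(model, rules=new_rules)


def _rmse(X: np.ndarray, y: np.ndarray, model: AnfisModel) -> float:
    pred = forward_batch(X, model, on_zero_firing="clamp")
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _premise_step(
    X: np.ndarray, y: np.ndarray, model: AnfisModel, lr: float
) -> AnfisModel:
    """One finite-difference gradient step on every premise (a, b, c).

    Parameters are perturbed by a fraction of the input span; after the step
    each triple is re-sorted to restore ``a <= b <= c``.
    """
    mfs = _grid_mfs(model)
    spans = np.maximum(
        model.input_ranges[:, 1] - model.input_ranges[:, 0], 1e-12
    )
    new_mfs: list[list[TriangularMF]] = []
    for i in range(model.arity):
        h = 1e-4 * spans[i]
        row: list[TriangularMF] = []
        for mf in mfs[i]:
            params = [mf.a, mf.b, mf.c]
            grads = []
            for p_idx in range(3):
                plus = params.copy()
                plus[p_idx] += h
                minus = params.copy()
                minus[p_idx] -= h
                m_plus = _swap_mf(model, i, mf, TriangularMF(*sorted(plus)))
                m_minus = _swap_mf(model, i, mf, TriangularMF(*sorted(minus)))
                grads.append((_rmse(X, y, m_plus) - _rmse(X, y, m_minus)) / (2 * h))
            stepped = [
                p - lr * spans[i] * g for p, g in zip(params, grads)
            ]
            row.append(TriangularMF(*sorted(stepped)))
        new_mfs.append(row)
    return _rebuild_with_mfs(model, new_mfs)


def _swap_mf(
    model: AnfisModel, input_idx: int, old: TriangularMF, new: TriangularMF
) -> AnfisModel:
    rules = [
        Rule(
            premise=tuple(
                new if (i == input_idx and mf == old) else mf
                for i, mf in enumerate(r.premise)
            ),
            consequent=r.consequent,
        )
        for r in model.rules
    ]
    return replace(model, rules=rules)


def _rebuild_with_mfs(
    model: AnfisModel, mfs: list[list[TriangularMF]]
) -> AnfisModel:
    rules = [
        Rule(
            premise=tuple(mfs[i][k] for i, k in enumerate(combo)),
            consequent=model.rules[j].consequent,
        )
        for j, combo in enumerate(_rule_combos(model))
    ]
    return replace(model, rules=rules)


def train(
    X, y, model: AnfisModel, config: TrainConfig = TrainConfig()
) -> tuple[AnfisModel, np.ndarray]:
    """Hybrid training loop; returns the fitted model and per-epoch RMSE.

    Each epoch solves the consequent LSE exactly, records the training RMSE,
    then (except after the final epoch) takes one gradient step on the
    premise parameters.  Fully deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        model = fit_consequents_lse(X, y, model, ridge=config.lse_ridge)
        trace[epoch] = _rmse(X, y, model)
        if not math.isfinite(trace[epoch]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}"
            )
        if epoch < config.epochs - 1:
            model = _premise_step(X, y, model, config.premise_lr)
    return model, trace


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class Anfis:
    """Takagi–Sugeno ANFIS regression model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Target values.
    exog : array-like, shape (n, k)
        Input features; ``k`` is the module arity (canonically 2).
    mfs_per_input : int
        Number of triangular fuzzy sets per input (grid partition).
    input_ranges : array-like (k, 2), optional
        Ranges used to place the initial MF grid; defaults to the observed
        per-column min/max of ``exog``.

    Examples
    --------
    >>> model = Anfis(y, X, mfs_per_input=2)
    >>> res = model.fit(epochs=10)
    >>> res.predict(X_new)
    """

    def __init__(self, endog, exog, mfs_per_input: int = 2, input_ranges=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.mfs_per_input = mfs_per_input
        if input_ranges is None:
            input_ranges = np.column_stack(
                [self.exog.min(axis=0), self.exog.max(axis=0)]
            )
        self.input_ranges = np.asarray(input_ranges, dtype=float)

    def fit(self, epochs: int = 10, premise_lr: float = 0.01,
            lse_ridge: float = 1e-8, seed: int = 0) -> "AnfisResults":
        config = TrainConfig(
            epochs=epochs, premise_lr=premise_lr, lse_ridge=lse_ridge,
            seed=seed,
        )
        model = build_grid_model(self.input_ranges, self.mfs_per_input)
        fitted, trace = train(self.exog, self.endog, model, config)
        return AnfisResults(self, fitted, trace, config)


class AnfisResults:
    """Fitted ANFIS: parameters, training trace and prediction."""

    def __init__(self, model: Anfis, fitted: AnfisModel,
                 rmse_trace: np.ndarray, config: TrainConfig):
        self.model = model
        self.fitted_model = fitted
        self.rmse_trace = rmse_trace
        self.config = config

    @property
    def rmse(self) -> float:
        return float(self.rmse_trace[-1])

    def predict(self, exog=None, on_zero_firing: str = "clamp") -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return forward_batch(X, self.fitted_model, on_zero_firing)

    def summary(self) -> str:
        m = self.fitted_model
        lines = [
            "ANFIS (Takagi-Sugeno) regression results",
            "=" * 44,
            f"Inputs (arity):        {m.arity}",
            f"MFs per input:         {m.mfs_per_input}",
            f"Rules (grid):          {m.n_rules}",
            f"Observations:          {self.model.exog.shape[0]}",
            f"Epochs:                {self.config.epochs}",
            f"Training RMSE:         {self.rmse:.6g}",
            "-" * 44,
            "rule  premise peaks           consequent",
        ]
        for j, rule in enumerate(m.rules):
            peaks = ", ".join(f"{mf.b:.4g}" for mf in rule.premise)
            coef = ", ".join(f"{v:.4g}" for v in rule.consequent)
            lines.append(f"{j:>4}  ({peaks:<20})  ({coef})")
        return "\n".join(lines)
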