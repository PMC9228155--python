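"""Per-group dimensionality reduction to a fixed component count.

Each descriptor group is reduced *independently* to ``n_components``
(default 9) so that G groups yield a ``G x 9`` feature block — 63 components
for the canonical seven groups.  The default method is fixed-point ICA
(FastICA: whitening + tanh/log-cosh contrast); PCA is available as a
deterministic alternative, and classical metric MDS participates only in the
method-comparison harness because it has no out-of-sample transform.

ICA and PCA reductions are affine maps (centering vector + linear map), so
they serialise to JSON and transform new samples exactly.
"""

from __future__ import annotations

import json
import time
import warnings

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import MDS

__all__ = ["GroupReducer", "fit_group_reducers", "transform",
           "compare_methods"]

_METHODS = ("ICA", "PCA", "MDS")


class GroupReducer:
    """Independent per-group affine reduction (ICA or PCA).

    Attributes after :meth:`fit`: ``means_`` (per-group centering vectors)
    and ``components_`` (per-group ``(d_g, n_components)`` maps applied as
    ``(X - mean) @ components``).
    """

    def __init__(self, method: str = "ICA", n_components: int = 9,
                 seed: int = 0):
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if method == "MDS":
            raise ValueError(
                "MDS has no out-of-sample transform; it is supported only "
                "in compare_methods"
            )
        self.method = method
        self.n_components = n_components
        self.seed = seed
        self.means_: list[np.ndarray] | None = None
        self.components_: list[np.ndarray] | None = None

    @property
    def n_groups(self) -> int:
        self._check_fitted()
        return len(self.means_)

    def _check_fitted(self) -> None:
        if self.means_ is None:
            raise ValueError("reducer is not fitted")

    def fit(self, tables) -> "GroupReducer":
        """Fit one transform per group table (each (n, d_g),
        d_g >= n_components, n >= n_components + 1)."""
        self.means_, self.components_ = [], []
        for g, T in enumerate(tables):
            T = np.asarray(T, dtype=float)
            if T.ndim != 2:
                raise ValueError(f"group {g}: table must be 2-D")
            if T.shape[1] < self.n_components:
                raise ValueError(
                    f"group {g}: raw dimension {T.shape[1]} < "
                    f"n_components {self.n_components}"
                )
            if T.shape[0] < self.n_components + 1:
                raise ValueError(
                    f"group {g}: need at least {self.n_components + 1} samples"
                )
            mean = T.mean(axis=0)
            # ICA whitening divides by singular values; a group whose
            # empirical rank falls below the component count would produce
            # NaN components, so such groups fall back to PCA (which
            # represents degenerate directions as zero-variance components)
            method = self.method
            if method == "ICA":
                sv = np.linalg.svd(T - mean, compute_uv=False)
                rank = int(np.sum(sv > (sv[0] if sv.size else 0.0) * 1e-9))
                if rank < self.n_components:
                    warnings.warn(
                        f"group {g}: empirical rank {rank} < "
                        f"{self.n_components} components; using PCA for "
                        "this group", RuntimeWarning, stacklevel=2,
                    )
                    method = "PCA"
            est = None
            if method == "ICA":
                est = FastICA(n_components=self.n_components,
                              fun="logcosh", max_iter=500, tol=1e-4,
                              whiten="unit-variance", random_state=self.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    try:
                        est.fit(T)
                        if not np.all(np.isfinite(est.components_)):
                            raise ValueError("non-finite unmixing matrix")
                    except (ValueError, np.linalg.LinAlgError):
                        # fixed-point iteration diverged on this group
                        warnings.warn(
                            f"group {g}: ICA did not produce a finite "
                            "unmixing matrix; using PCA for this group",
                            RuntimeWarning, stacklevel=2,
                        )
                        est = None
            if est is None:
                est = PCA(n_components=self.n_components,
                          random_state=self.seed)
                est.fit(T)
            # components_ applies to centred data: S = (X - mean) W^T;
            # keep a C-contiguous copy so transforms are bit-reproducible
            # after a JSON round-trip (BLAS paths differ by memory layout)
            comp = np.ascontiguousarray(est.components_.T)
            self.means_.append(mean)
            self.components_.append(comp)
        return self

    def transform(self, tables) -> np.ndarray:
        """Apply the per-group maps; returns (n, n_groups * n_components)
        with group-major column blocks."""
        self._check_fitted()
        tables = list(tables)
        if len(tables) != len(self.means_):
            raise ValueError(
                f"expected {len(self.means_)} groups, got {len(tables)}"
            )
        blocks = []
        for g, T in enumerate(tables):
            T = np.asarray(T, dtype=float)
            if T.ndim != 2 or T.shape[1] != self.means_[g].shape[0]:
                raise ValueError(
                    f"group {g}: dimension mismatch with the fitted reducer"
                )
            blocks.append((T - self.means_[g]) @ self.components_[g])
        return np.hstack(blocks)

    def fit_transform(self, tables) -> np.ndarray:
        return self.fit(tables).transform(tables)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "method": self.method,
            "n_components": self.n_components,
            "seed": self.seed,
            "means": [m.tolist() for m in self.means_],
            "components": [c.tolist() for c in self.components_],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GroupReducer":
        r = cls(method=d["method"], n_components=d["n_components"],
                seed=d["seed"])
        r.means_ = [np.asarray(m, dtype=float) for m in d["means"]]
        r.components_ = [np.asarray(c, dtype=float) for c in d["components"]]
        return r

    @classmethod
    def load(cls, path) -> "GroupReducer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_group_reducers(tables, method: str = "ICA", n_components: int = 9,
                       seed: int = 0) -> GroupReducer:
    """Functional wrapper: fit a :class:`GroupReducer` on per-group tables."""
    return GroupReducer(method=method, n_components=n_components,
                        seed=seed).fit(tables)


def transform(reducer: GroupReducer, tables) -> np.ndarray:
    """Functional wrapper around :meth:`GroupReducer.transform`."""
    return reducer.transform(tables)


def _mds_embed(tables, n_components: int, seed: int) -> np.ndarray:
    blocks = []
    for T in tables:
        T = np.asarray(T, dtype=float)
        k = min(n_components, T.shape[1])
        est = MDS(n_components=k, random_state=seed, normalized_stress=False)
        blocks.append(est.fit_transform(T))
    return np.hstack(blocks)


def compare_methods(tables, labels, methods, downstream_evaluator,
                    n_components_list=(9,), seed: int = 0):
    """Method-comparison harness: accuracy and wall time per (method, k).

    For each reduction method and component count the grouped tables are
    reduced and handed, with the labels, to ``downstream_evaluator(X, y) ->
    accuracy``.  Wall times are reported for orientation only — they are
    hardware-bound and never asserted.  A failing evaluator marks its row
    ``failed`` and the sweep continues.  Returns a pandas DataFrame with
    columns ``method, n_components, accuracy, seconds, status``.
    """
    import pandas as pd

    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    rows = []
    for method in methods:
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}")
        for k in n_components_list:
            t0 = time.perf_counter()
            try:
                if method == "MDS":
                    X = _mds_embed(tables, k, seed)
                else:
                    X = GroupReducer(method=method, n_components=k,
                                     seed=seed).fit_transform(tables)
                acc = float(downstream_evaluator(X, labels))
                status = "ok"
            except Exception:
                acc, status = np.nan, "failed"
            rows.append({"method": method, "n_components": k,
                         "accuracy": acc,
                         "seconds": time.perf_counter() - t0,
                         "status": status})
    return pd.DataFrame(rows)
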