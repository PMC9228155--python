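"""Dataset folders, feature-table CSV round-trips, and model file I/O.

The on-disk contracts:

* image datasets live in the standard two-split folder layout
  (``Training/<ClassName>/*.png|jpg``, ``Test/<ClassName>/*.png|jpg``);
  class labels are the sorted folder names;
* grouped feature tables are CSV with a ``label`` column and ``g<G>_f<K>``
  (raw) or ``g<G>_c<K>`` (reduced) columns, written at full float
  precision so a read-back reproduces values exactly, with a JSON sidecar
  recording the provenance (descriptor config, group map, reducer);
* models (cascade, reducer) are JSON documents with a ``kind`` tag and a
  schema version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeResults
from .dimreduce import GroupReducer

__all__ = [
    "DatasetFolder",
    "load_image_folder",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

logger = logging.getLogger("cascadefis")

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class DatasetFolder:
    """Discovered image-folder dataset: sorted classes, paths per split."""

    root: Path
    classes: list[str]
    train_paths: dict = field(default_factory=dict)  # class -> [Path]
    test_paths: dict = field(default_factory=dict)

    def load_split(self, which: str):
        """Load a split as ``(images (n,H,W,3) uint8, labels (n,) int)``.

        Labels index into the sorted ``classes`` list.
        """
        from PIL import Image

        paths = self.train_paths if which == "train" else self.test_paths
        images, labels = [], []
        for c, name in enumerate(self.classes):
            for p in paths.get(name, []):
                try:
                    with Image.open(p) as im:
                        images.append(np.asarray(im.convert("RGB")))
                except Exception as e:
                    raise ValueError(f"unreadable image {p}: {e}") from None
                labels.append(c)
        if not images:
            return (np.empty((0, 0, 0, 3), dtype=np.uint8),
                    np.empty(0, dtype=int))
        return np.stack(images), np.asarray(labels)


def _scan_split(split_dir: Path) -> dict:
    out = {}
    for d in sorted(p for p in split_dir.iterdir() if p.is_dir()):
        files = sorted(
            p for p in d.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"empty class folder: {d}")
        out[d.name] = files
    return out


def load_image_folder(root) -> DatasetFolder:
    """Discover a ``Training``/``Test`` image-folder tree.

    A flat tree of class folders (no split subfolders) is treated as a
    training-only dataset.  The class lists of both splits must agree when
    both exist.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    train_dir, test_dir = root / "Training", root / "Test"
    if train_dir.is_dir():
        train = _scan_split(train_dir)
        test = _scan_split(test_dir) if test_dir.is_dir() else {}
        if not test:
            logger.warning("no Test subtree under %s; test split empty", root)
        if test and sorted(train) != sorted(test):
            raise ValueError(
                "Training and Test subtrees disagree on the class list"
            )
        classes = sorted(train)
    else:
        train = _scan_split(root)
        test = {}
        classes = sorted(train)
        if not classes:
            raise ValueError(f"no class folders under {root}")
    return DatasetFolder(root=root, classes=classes, train_paths=train,
                         test_paths=test)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(path, tables, labels, sidecar: dict | None = None,
                        kind: str = "raw") -> None:
    """Write grouped features as CSV ``label, g<G>_f<K>...`` (or ``_c`` for
    reduced tables) plus an optional JSON sidecar.

    Values survive the round-trip exactly (written at shortest exact float
    representation).
    """
    path = Path(path)
    tag = "f" if kind == "raw" else "c"
    cols, data = ["label"], {}
    data["label"] = list(labels)
    for g, T in enumerate(tables):
        T = np.asarray(T, dtype=float)
        if T.shape[0] != len(data["label"]):
            raise ValueError(f"group {g}: row count mismatch with labels")
        for k in range(T.shape[1]):
            name = f"g{g + 1}_{tag}{k + 1}"
            cols.append(name)
            data[name] = T[:, k]
    df = pd.DataFrame(data, columns=cols)
    df.to_csv(path, index=False, float_format=None)
    if sidecar is not None:
        meta = dict(sidecar)
        meta["group_dims"] = [int(np.asarray(T).shape[1]) for T in tables]
        meta["kind"] = kind
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def read_feature_table(path):
    """Read a grouped feature CSV back as ``(tables, labels, sidecar)``.

    Groups are inferred from the ``g<G>_*`` column prefixes; when a sidecar
    exists its recorded group dimensions are checked against the header.
    """
    path = Path(path)
    # round_trip parsing: the default fast parser can be 1 ulp off
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    group_ids = sorted({
        int(c.split("_")[0][1:]) for c in df.columns if c != "label"
    })
    tables = []
    for g in group_ids:
        cols = [c for c in df.columns if c.startswith(f"g{g}_")]
        cols.sort(key=lambda c: int(c.split("_")[1][1:]))
        tables.append(df[cols].to_numpy(dtype=float))
    labels = df["label"].tolist()
    sidecar = None
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)
        dims = sidecar.get("group_dims")
        if dims is not None and dims != [T.shape[1] for T in tables]:
            raise ValueError(
                f"{path}: column layout disagrees with the sidecar "
                f"({[T.shape[1] for T in tables]} vs {dims})"
            )
    return tables, labels, sidecar


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

def save_model(obj, path) -> None:
    """Save a cascade (:class:`CascadeResults`) or reducer
    (:class:`GroupReducer`) to a JSON file."""
    if isinstance(obj, CascadeResults):
        obj.save(path)
    elif isinstance(obj, GroupReducer):
        d = obj.to_dict()
        d["kind"] = "cascadefis-reducer"
        d["schema_version"] = 1
        with open(path, "w") as fh:
            json.dump(d, fh)
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")


def load_model(path):
    """Load a model JSON, dispatching on its ``kind`` tag."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt model file {path}: {e}") from None
    kind = d.get("kind")
    if kind == "cascadefis-cascade":
        return CascadeResults.from_dict(d)
    if kind == "cascadefis-reducer":
        if d.get("schema_version") != 1:
            raise ValueError(
                f"unsupported reducer schema version {d.get('schema_version')!r}"
            )
        return GroupReducer.from_dict(d)
    raise ValueError(f"unrecognised model kind {kind!r} in {path}")
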