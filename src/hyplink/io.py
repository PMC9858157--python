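"""File I/O for attribute hypernetworks.

Formats:

* hyperedge list — plain UTF-8 text, one hyperedge per line, whitespace-
  separated node labels, ``#`` comments allowed;
* attributes — header-free numeric TSV (dense) or MatrixMarket ``.mtx``
  coordinate format (sparse), row ``i`` aligned to node id ``i``;
* split — TSV of ``edge_id  partition`` with partitions train/val/test;
* checkpoint — NumPy ``.npz`` archive of parameter tensors plus a JSON
  config header (format-versioned).
"""

from __future__ import annotations

import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .core import AttributeHypernetwork, ValidationError

CHECKPOINT_FORMAT = 1

__all__ = [
    "read_hyperedges", "write_hyperedges",
    "read_attributes", "write_attributes",
    "read_hypernetwork", "write_hypernetwork",
    "read_split", "write_split",
    "save_checkpoint", "load_checkpoint",
]


def read_hyperedges(path) -> tuple[list[frozenset[int]], list[str]]:
    """Parse a hyperedge list file.

    All-integer labels are taken as the (dense, 0-based) node ids directly,
    so row ``i`` of the attribute file matches node ``i``.  Non-integer
    labels are mapped to ids in first-seen order and the label table is
    returned alongside.  Duplicate labels within one line are dropped with
    a warning.
    """
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(set(tokens)) < len(tokens):
                warnings.warn(f"{path}:{lineno}: duplicate node id in hyperedge; "
                              "deduplicated", stacklevel=2)
            if len(set(tokens)) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: hyperedge has fewer than 2 distinct nodes")
            rows.append(tokens)

    numeric = all(tok.lstrip("-").isdigit() for row in rows for tok in row)
    labels: list[str] = []
    if numeric:
        edges = [frozenset(int(tok) for tok in row) for row in rows]
        if any(i < 0 for e in edges for i in e):
            raise ValidationError(f"{path}: negative node id")
    else:
        label_to_id: dict[str, int] = {}
        edges = []
        for row in rows:
            ids = []
            for tok in row:
                if tok not in label_to_id:
                    label_to_id[tok] = len(labels)
                    labels.append(tok)
                ids.append(label_to_id[tok])
            edges.append(frozenset(ids))
    return edges, labels


def write_hyperedges(path, hyperedges, node_labels: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for edge in hyperedges:
            ids = sorted(edge)
            toks = [node_labels[i] if node_labels else str(i) for i in ids]
            fh.write(" ".join(toks) + "\n")


def read_attributes(path) -> np.ndarray:
    """Load a node-by-attribute matrix from TSV (dense) or MTX (sparse)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        return np.asarray(mmread(path).todense(), dtype=np.float64)
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=np.float64))
    except ValueError as exc:
        raise ValidationError(f"malformed attribute TSV {path}: {exc}") from exc


def write_attributes(path, X: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mmwrite(str(path), coo_matrix(X))
    else:
        np.savetxt(path, np.asarray(X), delimiter="\t", fmt="%.10g")


def read_hypernetwork(edge_path, attr_path) -> AttributeHypernetwork:
    """Load and validate an attribute hypernetwork from its two files."""
    edges, labels = read_hyperedges(edge_path)
    X = read_attributes(attr_path)
    m = max((max(e) for e in edges), default=-1) + 1
    if X.shape[0] < m:
        raise ValidationError(
            f"attribute matrix has {X.shape[0]} rows but hyperedges reference "
            f"{m} nodes")
    # extra attribute rows are legal: nodes in no hyperedge are isolated
    return AttributeHypernetwork.from_data(edges, X, node_labels=labels or None)


def write_hypernetwork(net: AttributeHypernetwork, edge_path, attr_path) -> None:
    write_hyperedges(edge_path, net.hyperedges, None)
    write_attributes(attr_path, net.X)


def read_split(path) -> dict[str, np.ndarray]:
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                eid, part = line.split("\t")
                parts[part].append(int(eid))
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}:{lineno}: bad split row") from exc
    return {k: np.asarray(v, dtype=np.intp) for k, v in parts.items()}


def write_split(path, split) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for part in ("train", "val", "test"):
            for eid in getattr(split, f"{part}_edges"):
                fh.write(f"{eid}\t{part}\n")


def save_checkpoint(path, params: dict, config: dict) -> None:
    """Archive parameter tensors with a JSON header (versioned)."""
    header = json.dumps({"format": CHECKPOINT_FORMAT, "config": config})
    arrays = {name: np.asarray(p.data if hasattr(p, "data") else p)
              for name, p in params.items()}
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    try:
        with np.load(path) as archive:
            header = json.loads(bytes(archive["__header__"]).decode())
            if header.get("format") != CHECKPOINT_FORMAT:
                raise ValidationError(
                    f"unsupported checkpoint format {header.get('format')!r}")
            params = {k: archive[k] for k in archive.files if k != "__header__"}
    except (KeyError, OSError, ValueError, zipfile.BadZipFile,
            json.JSONDecodeError) as exc:
        raise ValidationError(f"corrupted checkpoint {path}: {exc}") from exc
    return params, header["config"]
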