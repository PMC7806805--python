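"""CSV / text I/O for node tables, edge lists, fingerprints and embeddings.

Dialects
--------
nodes CSV         ``node_id,name,node_type,category`` (category may be empty)
edges CSV         ``src,dst,edge_type,weight`` with edge_type in {ii,if,id};
                  weight required for ii rows, empty otherwise
fingerprints CSV  ``node_id,bits`` with bits an 881-char 0/1 string
embeddings        word2vec text format: ``<vocab> <dim>`` header then one
                  ``token v1 ... vd`` line per token
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np

from .graph import Fingerprint, HeteroGraph, NodeRecord, NodeType

PathLike = Union[str, Path]


class MalformedRowError(ValueError):
    """A CSV row that violates the expected dialect; carries the line number."""

    def __init__(self, path: PathLike, line_no: int, message: str) -> None:
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


NODES_HEADER = ["node_id", "name", "node_type", "category"]
EDGES_HEADER = ["src", "dst", "edge_type", "weight"]
FINGERPRINTS_HEADER = ["node_id", "bits"]


def _check_header(path: PathLike, row: List[str], expected: List[str]) -> None:
    if row != expected:
        raise MalformedRowError(path, 1, f"expected header {expected}, got {row}")


def read_nodes_csv(path: PathLike) -> List[NodeRecord]:
    records: List[NodeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        _check_header(path, next(reader), NODES_HEADER)
        for line_no, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise MalformedRowError(path, line_no, f"expected 4 fields, got {len(row)}")
            node_id, name, node_type, category = row
            try:
                records.append(
                    NodeRecord(
                        node_id=node_id,
                        name=name,
                        node_type=NodeType(node_type),
                        category=category or None,
                    )
                )
            except ValueError as exc:
                raise MalformedRowError(path, line_no, str(exc)) from exc
    return records


def write_nodes_csv(records: List[NodeRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NODES_HEADER)
        for rec in records:
            writer.writerow(
                [rec.node_id, rec.name, rec.node_type.value, rec.category or ""]
            )


def read_edges_csv(
    path: PathLike,
) -> Tuple[List[Tuple[str, str, float]], List[Tuple[str, str]]]:
    """Parse an edge list into (weighted ii triples, ic pairs)."""
    ii: List[Tuple[str, str, float]] = []
    ic: List[Tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        _check_header(path, next(reader), EDGES_HEADER)
        for line_no, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise MalformedRowError(path, line_no, f"expected 4 fields, got {len(row)}")
            src, dst, edge_type, weight = row
            if edge_type == "ii":
                if not weight:
                    raise MalformedRowError(path, line_no, "ii edge requires a weight")
                try:
                    ii.append((src, dst, float(weight)))
                except ValueError as exc:
                    raise MalformedRowError(path, line_no, f"bad weight {weight!r}") from exc
            elif edge_type in ("if", "id"):
                if weight:
                    raise MalformedRowError(
                        path, line_no, f"{edge_type} edge must have empty weight"
                    )
                ic.append((src, dst))
            else:
                raise MalformedRowError(path, line_no, f"unknown edge_type {edge_type!r}")
    return ii, ic


def write_edges_csv(graph: HeteroGraph, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EDGES_HEADER)
        for (u, v), w in sorted(graph.edges_ii.items()):
            writer.writerow([u, v, "ii", repr(w)])
        for u, v in sorted(graph.edges_if):
            writer.writerow([u, v, "if", ""])
        for u, v in sorted(graph.edges_id):
            writer.writerow([u, v, "id", ""])


def read_fingerprints_csv(path: PathLike) -> Dict[str, Fingerprint]:
    fps: Dict[str, Fingerprint] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        _check_header(path, next(reader), FINGERPRINTS_HEADER)
        for line_no, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise MalformedRowError(path, line_no, f"expected 2 fields, got {len(row)}")
            node_id, bits = row
            if node_id in fps:
                raise MalformedRowError(path, line_no, f"duplicate node id {node_id!r}")
            try:
                fps[node_id] = Fingerprint.from_string(bits)
            except ValueError as exc:
                raise MalformedRowError(path, line_no, str(exc)) from exc
    return fps


def write_fingerprints_csv(fps: Dict[str, Fingerprint], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FINGERPRINTS_HEADER)
        for node_id in sorted(fps):
            writer.writerow([node_id, fps[node_id].to_string()])


def write_embeddings_text(
    tokens: List[str], vectors: np.ndarray, path: PathLike
) -> None:
    """Write vectors in word2vec text format (one ``token v1 ... vd`` per line)."""
    vectors = np.asarray(vectors)
    if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
        raise ValueError("vectors must be a (len(tokens), dim) matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(tokens)} {vectors.shape[1]}\n")
        for tok, vec in zip(tokens, vectors):
            fh.write(tok + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def read_embeddings_text(path: PathLike) -> Tuple[List[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise MalformedRowError(path, 1, "expected '<vocab> <dim>' header")
        n, dim = int(header[0]), int(header[1])
        tokens: List[str] = []
        rows: List[List[float]] = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != dim + 1:
                raise MalformedRowError(
                    path, line_no, f"expected 1 token + {dim} values, got {len(parts)} fields"
                )
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != n:
        raise MalformedRowError(path, 1, f"header declares {n} rows, found {len(tokens)}")
    return tokens, np.asarray(rows, dtype=np.float64)
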