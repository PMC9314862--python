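"""Readers and writers for the standard inputs and outputs.

Everything downstream indexes entities through :class:`EntityIndex`, which
fixes the canonical integer id of every miRNA and disease: the position of
the (normalized) name in first-appearance order.  The association matrix is
oriented disease x miRNA — rows are diseases, columns are miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "EmptyInputError",
    "CycleError",
    "EntityIndex",
    "AssociationMatrix",
    "SequenceSet",
    "DiseaseDagForest",
    "ScoredPair",
    "normalize_name",
    "read_association_table",
    "read_fasta",
    "read_dag_forest",
    "write_scores",
    "read_scores",
]


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class EmptyInputError(ValueError):
    """Input file contains no usable records."""


class CycleError(ValueError):
    """A disease graph that must be acyclic contains a cycle."""


def normalize_name(name: str) -> str:
    """Canonical entity name: case-folded, stripped, internal whitespace collapsed."""
    return " ".join(str(name).strip().split()).casefold()


class EntityIndex:
    """Ordered set of unique entity names; position is the entity's integer id."""

    def __init__(self, names: Iterable[str], kind: str):
        if kind not in ("mirna", "disease"):
            raise ValueError(f"kind must be 'mirna' or 'disease', got {kind!r}")
        self.kind = kind
        self._names: list[str] = []
        self._pos: dict[str, int] = {}
        for raw in names:
            key = normalize_name(raw)
            if not key:
                continue
            if key not in self._pos:
                self._pos[key] = len(self._names)
                self._names.append(key)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._names)

    def position(self, name: str) -> int:
        key = normalize_name(name)
        if key not in self._pos:
            raise KeyError(f"unknown {self.kind} name: {name!r}")
        return self._pos[key]

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._pos

    def __iter__(self):
        return iter(self._names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EntityIndex)
            and self.kind == other.kind
            and self._names == other._names
        )

    def __repr__(self) -> str:
        return f"EntityIndex(kind={self.kind!r}, n={len(self)})"


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA association matrix ``bm``.

    ``bm[j, i] == 1`` iff disease ``j`` is known to be associated with
    miRNA ``i``.  Shape is ``(nd, nm)``.
    """

    bm: np.ndarray
    disease_index: EntityIndex
    mirna_index: EntityIndex

    def __post_init__(self):
        self.bm = np.asarray(self.bm, dtype=np.int8)
        nd, nm = self.bm.shape
        if nd != len(self.disease_index) or nm != len(self.mirna_index):
            raise ValueError(
                f"matrix shape {self.bm.shape} inconsistent with indices "
                f"({len(self.disease_index)}, {len(self.mirna_index)})"
            )
        if not np.isin(self.bm, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def nd(self) -> int:
        return self.bm.shape[0]

    @property
    def nm(self) -> int:
        return self.bm.shape[1]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known associations as (disease_id, mirna_id) pairs, row-major order."""
        rows, cols = np.nonzero(self.bm)
        return list(zip(rows.tolist(), cols.tolist()))

    def masked(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (disease_id, mirna_id) entries zeroed."""
        bm = self.bm.copy()
        for j, i in pairs:
            bm[j, i] = 0
        return AssociationMatrix(bm, self.disease_index, self.mirna_index)


class SequenceSet(dict):
    """Mapping miRNA name -> RNA sequence (upper-case, T already mapped to U)."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        super().__init__()
        if mapping:
            for name, seq in mapping.items():
                self[normalize_name(name)] = str(seq).upper().replace("T", "U")

    def get_for(self, name: str) -> str | None:
        return self.get(normalize_name(name))


@dataclass
class DiseaseDagForest:
    """Rooted disease DAGs plus the disease -> DAG membership map."""

    dags: dict[str, nx.DiGraph]
    membership: dict[str, set[str]] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.roots:
            self.roots = {gid: _find_root(g, gid) for gid, g in self.dags.items()}
        if not self.membership:
            self.membership = {}
            for gid, g in self.dags.items():
                for node in g.nodes:
                    self.membership.setdefault(node, set()).add(gid)

    @property
    def diseases(self) -> set[str]:
        return set(self.membership)

    def __contains__(self, disease: str) -> bool:
        return normalize_name(disease) in self.membership

    def ancestors_with_self(self, disease: str) -> dict[str, set[str]]:
        """Per DAG id: the disease plus every ancestor reachable upward."""
        key = normalize_name(disease)
        if key not in self.membership:
            raise KeyError(f"disease not in any DAG: {disease!r}")
        out = {}
        for gid in self.membership[key]:
            g = self.dags[gid]
            out[gid] = nx.ancestors(g, key) | {key}
        return out


def _find_root(g: nx.DiGraph, gid: str) -> str:
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) != 1:
        raise FormatError(f"DAG {gid!r} must have exactly one root, found {len(roots)}")
    root = roots[0]
    reachable = nx.descendants(g, root) | {root}
    if reachable != set(g.nodes):
        raise FormatError(f"DAG {gid!r} has nodes unreachable from root {root!r}")
    return root


@dataclass
class ScoredPair:
    mirna: str
    disease: str
    score: float
    label: int | None = None


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header only, no rows")
    return df


def read_association_table(path) -> AssociationMatrix:
    """Read a miRNA/disease pair table (TSV, columns ``mirna`` and ``disease``).

    Duplicate pairs are collapsed to a single 1 entry; rows with an empty
    name in either column are dropped.  Indices are built in first-appearance
    order of the surviving rows.
    """
    df = _read_table(path, ["mirna", "disease"])
    mirnas = df["mirna"].map(normalize_name)
    diseases = df["disease"].map(normalize_name)
    keep = (mirnas != "") & (diseases != "") & mirnas.notna() & diseases.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with empty fields", path, n_dropped)
    mirnas, diseases = mirnas[keep], diseases[keep]
    if len(mirnas) == 0:
        raise EmptyInputError(f"{path}: no usable association rows")

    pairs = list(zip(mirnas, diseases))
    seen: set[tuple[str, str]] = set()
    unique_pairs = []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            unique_pairs.append(p)
    n_dup = len(pairs) - len(unique_pairs)
    if n_dup:
        logger.info("%s: %d duplicate association row(s) collapsed", path, n_dup)

    mirna_index = EntityIndex((m for m, _ in unique_pairs), "mirna")
    disease_index = EntityIndex((d for _, d in unique_pairs), "disease")
    bm = np.zeros((len(disease_index), len(mirna_index)), dtype=np.int8)
    for m, d in unique_pairs:
        bm[disease_index.position(d), mirna_index.position(m)] = 1
    return AssociationMatrix(bm, disease_index, mirna_index)


def read_fasta(path) -> SequenceSet:
    """Read miRNA sequences from FASTA; keys are the first header token.

    Sequences are upper-cased and DNA T is normalized to RNA U.  Duplicate
    headers keep the first record.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if not stripped.startswith(">"):
                raise FormatError(f"{path}: sequence data before first FASTA header")
            break
    out = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        key = normalize_name(record.id)
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            logger.warning("%s: empty sequence for %s skipped", path, record.id)
            continue
        if key in out:
            logger.warning("%s: duplicate header %s, keeping first", path, record.id)
            continue
        dict.__setitem__(out, key, seq)
    return out


def read_dag_forest(edges_path, membership_path=None) -> DiseaseDagForest:
    """Read a disease DAG forest from a (dag_id, parent, child) edge list.

    An optional membership table (columns ``disease``, ``dag_id``) may add
    memberships; it is validated against the DAG node sets.  Each DAG must be
    acyclic with a single root from which all nodes are reachable.
    """
    edges = _read_table(edges_path, ["dag_id", "parent", "child"])
    dags: dict[str, nx.DiGraph] = {}
    for _, row in edges.iterrows():
        gid = str(row["dag_id"]).strip()
        g = dags.setdefault(gid, nx.DiGraph())
        g.add_edge(normalize_name(row["parent"]), normalize_name(row["child"]))
    for gid, g in dags.items():
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(f"cycle detected in DAG {gid!r}")
    forest = DiseaseDagForest(dags)
    if membership_path is not None:
        mem = _read_table(membership_path, ["disease", "dag_id"])
        for _, row in mem.iterrows():
            disease = normalize_name(row["disease"])
            gid = str(row["dag_id"]).strip()
            if gid not in dags or disease not in dags[gid]:
                logger.warning(
                    "membership row (%s, %s) not backed by an edge-list node; skipped",
                    disease, gid,
                )
                continue
            forest.membership.setdefault(disease, set()).add(gid)
    return forest


def write_scores(scores: Sequence[ScoredPair], path) -> None:
    """Write scored pairs as TSV, descending score, ties by (disease, mirna)."""
    if not scores:
        raise EmptyInputError("refusing to write an empty score list")
    ordered = sorted(scores, key=lambda r: (-r.score, r.disease, r.mirna))
    has_labels = any(r.label is not None for r in ordered)
    with open(path, "w") as fh:
        cols = ["mirna", "disease", "score"] + (["label"] if has_labels else [])
        fh.write("\t".join(cols) + "\n")
        for r in ordered:
            row = [r.mirna, r.disease, f"{r.score:.6f}"]
            if has_labels:
                row.append("" if r.label is None else str(int(r.label)))
            fh.write("\t".join(row) + "\n")


def read_scores(path) -> list[ScoredPair]:
    df = _read_table(path, ["mirna", "disease", "score"])
    out = []
    for _, row in df.iterrows():
        label = row.get("label")
        label = None if label is None or pd.isna(label) or label == "" else int(label)
        out.append(
            ScoredPair(
                normalize_name(row["mirna"]),
                normalize_name(row["disease"]),
                float(row["score"]),
                label,
            )
        )
    return out
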