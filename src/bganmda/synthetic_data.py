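"""Download-free synthetic datasets with planted low-rank structure.

The generator emulates the three real inputs — an association table, miRNA
sequences and a disease DAG forest — under a planted block model: miRNAs and
diseases are partitioned into ``latent_rank`` latent blocks, and positive
associations concentrate on block-matched (miRNA, disease) pairs.  Sequences
of miRNAs in the same block are mutated copies of a shared ancestor, and
diseases of the same block sit in the same DAG subtree, so the
guilt-by-association premise (functionally similar miRNAs associate with
semantically similar diseases) holds by construction and a predictor has a
recoverable signal.

Block-matched pairs that the density threshold left *unobserved* are
recorded as ``held_out_pairs`` in the truth object: these are the planted
positives a good ranker should surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import networkx as nx
import numpy as np

from .io_formats import AssociationMatrix, DiseaseDagForest, EntityIndex, SequenceSet

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "gen_sequences",
    "gen_dag_forest",
    "gen_associations",
    "gen_dataset",
    "write_dataset",
]

_NUCS = np.array(list("ACGU"))


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block synthetic dataset.

    nm, nd            entity counts.
    latent_rank       number of planted blocks on each side.
    density           fraction of the nm*nd pairs set positive (before noise).
    seq_length_range  inclusive bounds of sequence lengths (miRNA-like, ~22 nt).
    mutation_rate     per-base substitution rate within a block family.
    n_dags            number of rooted disease DAGs.
    dag_depth         maximum depth of any DAG.
    noise_rate        independent label-flip probability applied to the matrix.
    seed              generator seed; all outputs are pure functions of the spec.
    """

    nm: int = 60
    nd: int = 40
    latent_rank: int = 4
    density: float = 0.08
    seq_length_range: tuple[int, int] = (20, 24)
    mutation_rate: float = 0.05
    n_dags: int = 4
    dag_depth: int = 4
    noise_rate: float = 0.0
    seed: int = 7

    def __post_init__(self):
        if not 0.0 < self.density < 1.0:
            raise ValueError(f"density must be in (0, 1), got {self.density}")
        if self.latent_rank > min(self.nm, self.nd):
            raise ValueError("latent_rank cannot exceed min(nm, nd)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError(f"noise_rate must be in [0, 0.5), got {self.noise_rate}")
        if self.n_dags < 1 or self.dag_depth < 1:
            raise ValueError("n_dags and dag_depth must be positive")
        self.seq_length_range = tuple(self.seq_length_range)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    mirna_blocks: dict[str, int]
    disease_blocks: dict[str, int]
    held_out_pairs: list[tuple[str, str]] = field(default_factory=list)


def _mirna_names(spec: SyntheticSpec) -> list[str]:
    return [f"mir-{i:04d}" for i in range(spec.nm)]


def _disease_names(spec: SyntheticSpec) -> list[str]:
    return [f"disease-{j:04d}" for j in range(spec.nd)]


def _blocks(n: int, rank: int) -> np.ndarray:
    """Round-robin block assignment, every block non-empty."""
    return np.arange(n) % rank


def gen_sequences(spec: SyntheticSpec) -> SequenceSet:
    """Block-family sequences: mutated copies of a per-block ancestor."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    blocks = _blocks(spec.nm, spec.latent_rank)
    lo, hi = spec.seq_length_range
    ancestors = {}
    for b in range(spec.latent_rank):
        length = int(rng.integers(lo, hi + 1))
        ancestors[b] = rng.choice(_NUCS, size=length)
    out = {}
    for name, b in zip(_mirna_names(spec), blocks):
        seq = ancestors[b].copy()
        if spec.mutation_rate > 0:
            hit = rng.random(len(seq)) < spec.mutation_rate
            seq[hit] = rng.choice(_NUCS, size=int(hit.sum()))
        out[name] = "".join(seq)
    return SequenceSet(out)


def gen_dag_forest(spec: SyntheticSpec) -> DiseaseDagForest:
    """Random rooted trees in which same-block diseases share a subtree.

    Blocks are distributed round-robin over ``n_dags`` DAGs; within a DAG
    each disease attaches to a parent of its own block when one is already
    placed (falling back to any placed node), respecting ``dag_depth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    names = _disease_names(spec)
    blocks = _blocks(spec.nd, spec.latent_rank)
    dag_of_block = {b: b % spec.n_dags for b in range(spec.latent_rank)}
    dags: dict[str, nx.DiGraph] = {}
    depth: dict[str, int] = {}
    placed_by_dag: dict[str, list[str]] = {}
    placed_by_block: dict[int, list[str]] = {}
    for name, b in zip(names, blocks):
        gid = f"dag{dag_of_block[int(b)]}"
        g = dags.setdefault(gid, nx.DiGraph())
        placed = placed_by_dag.setdefault(gid, [])
        if not placed:
            g.add_node(name)
            depth[name] = 0
        else:
            same_block = [p for p in placed_by_block.get(int(b), [])
                          if depth[p] < spec.dag_depth]
            candidates = same_block or [p for p in placed if depth[p] < spec.dag_depth]
            if not candidates:  # depth budget exhausted: reattach at root level
                candidates = [placed[0]]
            parent = candidates[int(rng.integers(len(candidates)))]
            g.add_edge(parent, name)
            depth[name] = min(depth[parent] + 1, spec.dag_depth)
        placed.append(name)
        placed_by_block.setdefault(int(b), []).append(name)
    return DiseaseDagForest(dags)


def gen_associations(spec: SyntheticSpec) -> tuple[AssociationMatrix, SyntheticTruth]:
    """Planted block-model association matrix thresholded to the target density.

    Pair affinity = block-match indicator plus small Gaussian jitter; the
    ``ceil(density * nm * nd)`` highest-affinity pairs become positives,
    then every entry is flipped independently with ``noise_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    m_names, d_names = _mirna_names(spec), _disease_names(spec)
    m_blocks = _blocks(spec.nm, spec.latent_rank)
    d_blocks = _blocks(spec.nd, spec.latent_rank)
    match = (d_blocks[:, None] == m_blocks[None, :]).astype(float)  # (nd, nm)
    affinity = match + rng.normal(0.0, 0.1, size=match.shape)
    k = int(np.ceil(spec.density * spec.nm * spec.nd))
    flat = affinity.ravel()
    top = np.argpartition(flat, -k)[-k:]
    bm = np.zeros(spec.nd * spec.nm, dtype=np.int8)
    bm[top] = 1
    bm = bm.reshape(spec.nd, spec.nm)
    if spec.noise_rate > 0:
        flips = rng.random(bm.shape) < spec.noise_rate
        bm = np.where(flips, 1 - bm, bm).astype(np.int8)

    truth = SyntheticTruth(
        mirna_blocks={n: int(b) for n, b in zip(m_names, m_blocks)},
        disease_blocks={n: int(b) for n, b in zip(d_names, d_blocks)},
        held_out_pairs=[
            (m_names[i], d_names[j])
            for j, i in zip(*np.nonzero((match > 0) & (bm == 0)))
        ],
    )
    matrix = AssociationMatrix(
        bm, EntityIndex(d_names, "disease"), EntityIndex(m_names, "mirna")
    )
    return matrix, truth


def gen_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[AssociationMatrix, SequenceSet, DiseaseDagForest, SyntheticTruth]:
    """Compose the three generators under one spec/seed."""
    spec = spec or SyntheticSpec()
    bm, truth = gen_associations(spec)
    seqs = gen_sequences(spec)
    forest = gen_dag_forest(spec)
    return bm, seqs, forest, truth


def write_dataset(spec: SyntheticSpec, out_dir) -> None:
    """Write the dataset as the standard on-disk formats plus truth.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bm, seqs, forest, truth = gen_dataset(spec)
    with open(out / "associations.tsv", "w") as fh:
        fh.write("mirna\tdisease\n")
        for j, i in bm.positive_pairs():
            fh.write(f"{bm.mirna_index.names[i]}\t{bm.disease_index.names[j]}\n")
    with open(out / "sequences.fasta", "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    with open(out / "dag_edges.tsv", "w") as fh:
        fh.write("dag_id\tparent\tchild\n")
        for gid, g in forest.dags.items():
            for parent, child in g.edges:
                fh.write(f"{gid}\t{parent}\t{child}\n")
    with open(out / "dag_membership.tsv", "w") as fh:
        fh.write("disease\tdag_id\n")
        for disease in sorted(forest.membership):
            for gid in sorted(forest.membership[disease]):
                fh.write(f"{disease}\t{gid}\n")
    (out / "truth.json").write_text(json.dumps(asdict(truth), indent=1))
    (out / "spec.json").write_text(spec.to_json())
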