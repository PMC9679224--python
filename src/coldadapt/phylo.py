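"""Pairwise alignment, Jukes-Cantor distances, neighbor-joining and
bootstrap supports -- the multigene phylogeny workflow.

Distances follow the k-state Jukes-Cantor correction

    d = -((k-1)/k) * ln(1 - (k/(k-1)) * p)

with ``k = 4`` for nucleotides and ``k = 20`` for amino acids, where ``p``
is the proportion of differing sites over gap-free columns (pairwise
deletion).  Trees are canonical Saitou-Nei neighbor-joining with the
Studier-Keppler Q-criterion and are carried as :mod:`dendropy` trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

MSA = Sequence[tuple[str, str]]  # (label, aligned sequence) rows


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two aligned rows plus score, identity and query coverage.

    Identity is computed over gap-free columns; coverage is the aligned
    span of the first (query) sequence over its full length.
    """

    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    mode: str
    score: float
    identity_percent: float
    coverage_percent: float


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix; inf marks saturated entries."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T]
        ):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(label + "  " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _make_aligner(
    mode: str,
    substitution: str | None,
    gap_open: float,
    gap_extend: float,
    match: float,
    mismatch: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if substitution is not None:
        aligner.substitution_matrix = substitution_matrices.load(substitution)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(row_a: str, row_b: str) -> tuple[float, int]:
    matches = cols = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        cols += 1
        matches += x == y
    identity = 100.0 * matches / cols if cols else 0.0
    return identity, cols


def _align(
    a: str,
    b: str,
    mode: str,
    substitution: str | None,
    gap_open: float,
    gap_extend: float,
    match: float,
    mismatch: float,
    a_id: str,
    b_id: str,
) -> PairwiseAlignment:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(mode, substitution, gap_open, gap_extend, match, mismatch)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identity, _ = _alignment_stats(row_a, row_b)
    blocks = aln.aligned[0]  # aligned blocks on the first (query) sequence
    if len(blocks):
        span = int(blocks[-1][1] - blocks[0][0])
    else:
        span = 0
    coverage = 100.0 * span / len(a)
    return PairwiseAlignment(
        seq_a_id=a_id,
        seq_b_id=b_id,
        aligned_a=row_a,
        aligned_b=row_b,
        mode=mode,
        score=float(aln.score),
        identity_percent=identity,
        coverage_percent=coverage,
    )


def global_align(
    a: str,
    b: str,
    substitution: str | None = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
    a_id: str = "a",
    b_id: str = "b",
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    Pass ``substitution=None`` for nucleotide match/mismatch scoring.
    """
    return _align(a, b, "global", substitution, gap_open, gap_extend,
                  match, mismatch, a_id, b_id)


def local_align(
    a: str,
    b: str,
    substitution: str | None = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
    a_id: str = "a",
    b_id: str = "b",
) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment; coverage is over the query ``a``."""
    return _align(a, b, "local", substitution, gap_open, gap_extend,
                  match, mismatch, a_id, b_id)


def p_distance(alignment: PairwiseAlignment | tuple[str, str]) -> float:
    """Observed proportion of differing sites over gap-free columns.

    Gap columns are deleted pairwise; NaN (flagged by a warning) if no
    gap-free column remains.
    """
    if isinstance(alignment, PairwiseAlignment):
        row_a, row_b = alignment.aligned_a, alignment.aligned_b
    else:
        row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    identity, cols = _alignment_stats(row_a, row_b)
    if cols == 0:
        logger.warning("no gap-free columns; p-distance undefined")
        return float("nan")
    return 1.0 - identity / 100.0


def jukes_cantor(p: float, alphabet_size: int = 4) -> float:
    """k-state Jukes-Cantor correction of an observed difference proportion.

    Saturated inputs (``p >= (k-1)/k``) return ``inf``.
    """
    k = alphabet_size
    if k < 2:
        raise ValueError("alphabet_size must be at least 2")
    if math.isnan(p):
        return float("nan")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a proportion")
    limit = (k - 1) / k
    if p >= limit:
        logger.warning("p=%.4f saturated for k=%d; distance infinite", p, k)
        return float("inf")
    return -limit * math.log(1.0 - p / limit)


def _seq_matrix(msa: MSA) -> np.ndarray:
    lengths = {len(seq) for _, seq in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    return np.array([list(seq) for _, seq in msa], dtype="U1")


def msa_distance_matrix(
    msa: MSA, alphabet_size: int = 20, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Jukes-Cantor distance matrix from an alignment.

    ``deletion`` is ``pairwise`` (default; gap columns removed per pair) or
    ``complete`` (columns with any gap removed once for all pairs).
    """
    labels = [label for label, _ in msa]
    mat = _seq_matrix(msa)
    gaps = mat == "-"
    if deletion == "complete":
        keep = ~gaps.any(axis=0)
        mat, gaps = mat[:, keep], gaps[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            total = int(ok.sum())
            if total == 0:
                p = float("nan")
            else:
                p = float((mat[i, ok] != mat[j, ok]).sum()) / total
            d[i, j] = d[j, i] = jukes_cantor(p, alphabet_size)
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Uses the Studier-Keppler Q-criterion; Q-ties break toward the smallest
    (i, j) index pair; negative branch lengths are clamped to zero with the
    deficit moved onto the sister edge.  The returned tree is unrooted with
    a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains non-finite entries")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)

        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj

        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # trifurcating root over the last three nodes (three-point formulas)
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        tree.seed_node.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of leaves."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    labels = sorted(lf.taxon.label for lf in leaves)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = dist
    return DistanceMatrix(labels=labels, values=values)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a tree, each named by one canonical side."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    parts: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        if len(canon) >= 2:  # non-trivial splits only
            parts.add(canon)
    return parts


def bootstrap_tree(
    msa: MSA,
    n_reps: int = 1000,
    seed: int = 0,
    alphabet_size: int = 20,
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """Neighbor-joining tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate, each replicate
    runs the full p-distance -> Jukes-Cantor -> NJ pipeline, and supports
    are the percentage of retained replicates containing each bipartition
    of the full-data tree.  Replicates with a saturated or undefined
    distance are dropped and counted (warning above 10%); the result is
    bit-reproducible for a fixed seed.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    ncols = len(msa[0][1])
    if ncols < 10:
        raise ValueError("alignment too short to resample")
    full_dm = msa_distance_matrix(msa, alphabet_size, deletion)
    if not np.all(np.isfinite(full_dm.values)):
        raise ValueError("full-data distance matrix is saturated or undefined")
    tree = neighbor_joining(full_dm)
    target = tree_bipartitions(tree)
    counts = {part: 0 for part in target}

    labels = [label for label, _ in msa]
    mat = _seq_matrix(msa)
    rng = np.random.default_rng(seed)
    dropped = 0
    kept = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, ncols)
        rep_msa = [
            (label, "".join(row)) for label, row in zip(labels, mat[:, cols])
        ]
        rep_dm = msa_distance_matrix(rep_msa, alphabet_size, deletion)
        if not np.all(np.isfinite(rep_dm.values)):
            dropped += 1
            continue
        kept += 1
        rep_parts = tree_bipartitions(neighbor_joining(rep_dm))
        for part in target & rep_parts:
            counts[part] += 1
    if dropped > 0.1 * n_reps:
        logger.warning("%d of %d bootstrap replicates dropped", dropped, n_reps)

    all_labels = frozenset(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        canon = min(side, all_labels - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in counts and kept:
            node.label = str(round(100.0 * counts[canon] / kept))
    return tree


@dataclass(frozen=True)
class OrthologGroup:
    """A shared annotation label with one representative peptide per species."""

    label: str
    members: Mapping[str, tuple[str, str]]  # species -> (cds_id, peptide)


def select_common_proteins(
    tables: Mapping[str, Sequence[tuple[str, str, str]]],
    min_species: int = 8,
    required_species: Sequence[str] = (),
) -> list[OrthologGroup]:
    """Annotation labels shared by enough species, one peptide per species.

    ``tables`` maps species to ``(cds_id, annotation_label, peptide)`` rows.
    A label qualifies when present in at least ``min_species`` species and
    in every species of ``required_species``; the representative per
    species is the longest peptide (ties to the smallest cds_id).
    """
    presence: dict[str, dict[str, tuple[str, str]]] = {}
    for species, rows in tables.items():
        for cds_id, label, peptide in rows:
            if not label:
                continue
            current = presence.setdefault(label, {}).get(species)
            cand = (cds_id, peptide)
            if current is None or (len(peptide), ) > (len(current[1]), ) or (
                len(peptide) == len(current[1]) and cds_id < current[0]
            ):
                presence[label][species] = cand
    groups = []
    required = set(required_species)
    for label in sorted(presence):
        members = presence[label]
        if len(members) >= min_species and required <= set(members):
            groups.append(OrthologGroup(label=label, members=dict(sorted(members.items()))))
    return groups


def star_align(seqs: MSA, **align_kwargs) -> list[tuple[str, str]]:
    """Multiple alignment by progressive pairwise alignment to the longest member.

    Every sequence is globally aligned to the longest one (ties to the
    first listed); reference gap patterns are merged column-wise
    ("once a gap, always a gap" on the reference).
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return [tuple(seqs[0])]
    ref_idx = max(range(len(seqs)), key=lambda i: len(seqs[i][1]))
    ref_id, ref = seqs[ref_idx]
    rlen = len(ref)

    # per-sequence: gaps inserted into the reference before each ref position
    ins: list[np.ndarray] = []
    rows: list[tuple[str, str]] = []
    for label, seq in seqs:
        if label == ref_id and seq == ref:
            ins.append(np.zeros(rlen + 1, dtype=int))
            rows.append((label, ref))
            continue
        aln = global_align(ref, seq, **align_kwargs)
        gaps = np.zeros(rlen + 1, dtype=int)
        rpos = 0
        for ch in aln.aligned_a:
            if ch == "-":
                gaps[rpos] += 1
            else:
                rpos += 1
        ins.append(gaps)
        rows.append((label, aln.aligned_b))
    merged = np.max(np.stack(ins), axis=0)

    out = []
    for (label, row), gaps in zip(rows, ins):
        pieces = []
        # row is aligned to the reference with `gaps` insertions; re-pad to `merged`
        idx = 0
        for rpos in range(rlen + 1):
            take = int(gaps[rpos])
            pad = int(merged[rpos]) - take
            pieces.append(row[idx : idx + take])
            pieces.append("-" * pad)
            idx += take
            if rpos < rlen:
                pieces.append(row[idx])
                idx += 1
        out.append((label, "".join(pieces)))
    widths = {len(s) for _, s in out}
    assert len(widths) == 1, "star alignment produced ragged rows"
    return out


def concatenate_alignments(
    groups: Mapping[str, MSA | Mapping[str, str]]
) -> list[tuple[str, str]]:
    """Row-wise concatenation of per-group alignments over one species set.

    Groups are concatenated in sorted label order; a group whose species
    set differs from the first raises an error naming the offender.
    """
    if not groups:
        raise ValueError("no groups to concatenate")
    norm: dict[str, dict[str, str]] = {}
    for name, msa in groups.items():
        norm[name] = dict(msa)
        widths = {len(s) for s in norm[name].values()}
        if len(widths) > 1:
            raise ValueError(f"group {name!r} is not rectangular")
    order = sorted(norm)
    species = sorted(norm[order[0]])
    for name in order:
        if sorted(norm[name]) != species:
            raise ValueError(f"group {name!r} has a different species set")
    return [(sp, "".join(norm[name][sp] for name in order)) for sp in species]
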