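"""Ortholog clustering and the presence/absence pangenome.

Protein-coding genes are grouped into families by greedy, length-sorted
centroid clustering at a fixed identity cutoff (default 50%), the style of
incremental clustering used by CD-HIT/USEARCH.  The resulting family ×
genome matrix is partitioned into the core genome (present in every
genome), the accessory genome (in ≥2 but not all) and unique genes (exactly
one genome); a gene-cluster-frequency dendrogram over genomes and a
nearest-neighbour mislabel check are derived from the same matrix.

Identity between two sequences is computed from a global alignment with
free end gaps: identity = matches / aligned columns excluding end
overhangs, coverage = fraction of the shorter sequence inside the aligned
span.  Both definitions are fixed here because the clustering literature
leaves them tool-specific.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .genome_io import SPECIES_ONLY, GenomeSet

_NT_LETTERS = set("ACGTUNRYSWKMBDHV")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_internal_gap_score = -2.0
    aligner.extend_internal_gap_score = -0.5
    aligner.end_gap_score = 0.0  # free end gaps
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class ClusterParams:
    """Greedy clustering thresholds.

    ``identity_cutoff`` is the minimum pairwise identity for a sequence to
    join an existing cluster; ``min_coverage`` the minimum fraction of the
    shorter sequence spanned by the alignment; ``kmer_prefilter_k`` the word
    size of the shared-k-mer prefilter (0 disables it).
    """

    identity_cutoff: float = 0.50
    min_coverage: float = 0.80
    kmer_prefilter_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise ValidationError("identity_cutoff must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValidationError("min_coverage must be in (0, 1]")
        if self.kmer_prefilter_k < 0:
            raise ValidationError("kmer_prefilter_k must be >= 0")


@dataclass
class GeneCluster:
    cluster_id: str
    centroid: tuple[str, str]  # (genome_id, gene_id)
    members: list[tuple[str, str]]
    representative_seq: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.cluster_id}: empty cluster")
        if self.centroid not in self.members:
            raise ValidationError(f"{self.cluster_id}: centroid not among members")


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and coverage from a free-end-gap global alignment.

    Identity counts matches over aligned columns between the first and last
    residue pair (end overhangs excluded); coverage is the fraction of the
    shorter sequence lying inside that span.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValidationError("empty sequence")
    a_nt = set(seq_a) <= _NT_LETTERS
    b_nt = set(seq_b) <= _NT_LETTERS
    if a_nt != b_nt:
        raise ValidationError("mixed alphabets (nucleotide vs amino acid)")
    # canonical argument order makes the result exactly symmetric
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        seq_a, seq_b = seq_b, seq_a
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    first = last = -1
    for i, (x, y) in enumerate(zip(row_a, row_b)):
        if x != "-" and y != "-":
            if first < 0:
                first = i
            last = i
    if first < 0:
        return 0.0, 0.0
    matches = 0
    short_in_span = 0
    for i in range(first, last + 1):
        x, y = row_a[i], row_b[i]
        if x != "-" and x == y:
            matches += 1
        if x != "-":  # row_a holds the shorter sequence
            short_in_span += 1
    columns = last - first + 1
    return matches / columns, short_in_span / len(seq_a)


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def greedy_cluster(genome_set: GenomeSet, params: ClusterParams | None = None,
                   ) -> list[GeneCluster]:
    """Length-sorted greedy centroid clustering of all protein sequences.

    Sequences are visited in order of decreasing length (ties broken by
    ``(genome_id, gene_id)``); each joins the first cluster — in founding
    order — whose centroid it matches at ``identity_cutoff`` and
    ``min_coverage``, else it founds a new cluster.  Deterministic given the
    input and parameters.
    """
    params = params or ClusterParams()
    if len(genome_set) == 0:
        raise ValidationError("empty genome set")
    entries = []
    for genome in genome_set:
        for gene_id, aa in genome.proteins().items():
            entries.append((genome.genome_id, gene_id, aa))
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))

    k = params.kmer_prefilter_k
    clusters: list[GeneCluster] = []
    centroid_seqs: list[str] = []
    centroid_kmers: list[frozenset[str]] = []
    for genome_id, gene_id, seq in entries:
        hit = None
        if seq:
            query_kmers = _kmers(seq, k) if k and len(seq) >= k else None
            for idx in range(len(clusters)):
                if (
                    query_kmers is not None
                    and centroid_kmers[idx] is not None
                    and not (query_kmers & centroid_kmers[idx])
                ):
                    continue
                ident, cov = pairwise_identity(seq, centroid_seqs[idx])
                if ident >= params.identity_cutoff and cov >= params.min_coverage:
                    hit = idx
                    break
        if hit is None:
            clusters.append(GeneCluster(
                cluster_id=f"GC{len(clusters) + 1:05d}",
                centroid=(genome_id, gene_id),
                members=[(genome_id, gene_id)],
                representative_seq=seq,
            ))
            centroid_seqs.append(seq)
            centroid_kmers.append(
                _kmers(seq, k) if k and len(seq) >= k else None
            )
        else:
            clusters[hit].members.append((genome_id, gene_id))
    return clusters


@dataclass
class PresenceAbsenceMatrix:
    """Gene family × genome membership profile (copy numbers and 0/1 presence)."""

    cluster_ids: list[str]
    genome_ids: list[str]
    copy_number: np.ndarray  # shape (clusters, genomes), int

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=int)
        if self.copy_number.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise ValidationError("copy_number shape does not match id lists")
        if (self.copy_number.sum(axis=1) == 0).any():
            raise ValidationError("cluster row with no presence")
        self._row = {c: i for i, c in enumerate(self.cluster_ids)}
        self._col = {g: j for j, g in enumerate(self.genome_ids)}

    @property
    def presence(self) -> np.ndarray:
        return (self.copy_number >= 1).astype(int)

    def genomes_with(self, cluster_id: str) -> list[str]:
        row = self.copy_number[self._row[cluster_id]]
        return [g for g, v in zip(self.genome_ids, row) if v >= 1]

    def columns_for(self, genome_ids: list[str]) -> np.ndarray:
        return self.copy_number[:, [self._col[g] for g in genome_ids]]

    def to_frame(self, kind: str = "presence"):
        import pandas as pd

        data = self.presence if kind == "presence" else self.copy_number
        return pd.DataFrame(data, index=self.cluster_ids, columns=self.genome_ids)


def build_presence_matrix(clusters: list[GeneCluster],
                          genome_set: GenomeSet) -> PresenceAbsenceMatrix:
    """Count cluster members per genome into a family × genome matrix."""
    genome_ids = genome_set.genome_ids
    col = {g: j for j, g in enumerate(genome_ids)}
    counts = np.zeros((len(clusters), len(genome_ids)), dtype=int)
    for i, cluster in enumerate(clusters):
        for genome_id, _gene_id in cluster.members:
            if genome_id not in col:
                raise ValidationError(
                    f"{cluster.cluster_id}: member references unknown genome "
                    f"{genome_id!r}"
                )
            counts[i, col[genome_id]] += 1
    return PresenceAbsenceMatrix(
        cluster_ids=[c.cluster_id for c in clusters],
        genome_ids=genome_ids,
        copy_number=counts,
    )


@dataclass
class PangenomePartition:
    core: set[str]
    accessory: set[str]
    unique: set[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.core), len(self.accessory), len(self.unique)

    @property
    def pangenome_size(self) -> int:
        return sum(self.sizes)


def partition_pangenome(matrix: PresenceAbsenceMatrix) -> PangenomePartition:
    """Split clusters into core / accessory / unique by genome occupancy."""
    n = len(matrix.genome_ids)
    if n < 2:
        raise ValidationError("partition undefined for a single-genome matrix")
    occupancy = matrix.presence.sum(axis=1)
    core, accessory, unique = set(), set(), set()
    for cid, occ in zip(matrix.cluster_ids, occupancy):
        if occ == n:
            core.add(cid)
        elif occ == 1:
            unique.add(cid)
        else:
            accessory.add(cid)
    return PangenomePartition(core=core, accessory=accessory, unique=unique)


def subspecies_core(matrix: PresenceAbsenceMatrix, genome_set: GenomeSet,
                    label: str, labels: dict[str, str] | None = None) -> set[str]:
    """Clusters present in every genome carrying ``label``.

    ``labels`` overrides the declared labels (e.g. after mislabel
    correction).
    """
    labels = labels or genome_set.declared_labels()
    members = [g for g in matrix.genome_ids if labels.get(g) == label]
    if not members:
        raise ValidationError(f"no genome carries label {label!r}")
    sub = matrix.columns_for(members) >= 1
    keep = sub.all(axis=1)
    return {cid for cid, k in zip(matrix.cluster_ids, keep) if k}


def _genome_profiles(matrix: PresenceAbsenceMatrix, metric: str):
    order = sorted(range(len(matrix.genome_ids)),
                   key=lambda j: matrix.genome_ids[j])
    ids = [matrix.genome_ids[j] for j in order]
    if metric == "euclidean":
        data = matrix.copy_number[:, order].T.astype(float)
        dists = pdist(data, metric="euclidean")
    elif metric == "jaccard":
        data = (matrix.copy_number[:, order] >= 1).T
        dists = pdist(data, metric="jaccard")
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return ids, dists


def cluster_frequency_tree(matrix: PresenceAbsenceMatrix,
                           metric: str = "euclidean",
                           linkage: str = "ward") -> str:
    """Agglomerative genome dendrogram over cluster copy-number profiles.

    Default Euclidean distance with Ward linkage; ``jaccard`` (on presence)
    and ``upgma`` are the configurable alternatives.  Genomes are processed
    in lexicographic order so the newick output is deterministic.
    """
    if len(matrix.genome_ids) < 3:
        raise ValidationError("tree requires at least 3 genomes")
    method = {"ward": "ward", "upgma": "average"}.get(linkage)
    if method is None:
        raise ValidationError(f"unknown linkage {linkage!r}")
    ids, dists = _genome_profiles(matrix, metric)
    z = hierarchy.linkage(dists, method=method)
    root = hierarchy.to_tree(z)

    def render(node) -> tuple[str, float]:
        if node.is_leaf():
            return ids[node.id], 0.0
        height = node.dist / 2.0
        left, lh = render(node.left)
        right, rh = render(node.right)
        return f"({left}:{height - lh:.6g},{right}:{height - rh:.6g})", height

    newick, _ = render(root)
    return newick + ";"


def infer_labels(matrix: PresenceAbsenceMatrix, genome_set: GenomeSet,
                 k_neighbors: int = 3,
                 metric: str = "euclidean") -> dict[str, str]:
    """k-nearest-neighbour label inference for every genome.

    Neighbours are drawn from genomes with a real subspecies label (self
    excluded), nearest first with ties broken by genome_id; the inferred
    label is the majority declared label among the k neighbours, ties broken
    toward the genome's own declared label, then lexicographically.
    """
    if k_neighbors <= 0:
        raise ValidationError("k_neighbors must be positive")
    declared = genome_set.declared_labels()
    labeled = [g for g in matrix.genome_ids if declared[g] != SPECIES_ONLY]
    if len({declared[g] for g in labeled}) < 2:
        raise ValidationError("label inference requires >= 2 labels")
    if k_neighbors >= len(labeled):
        raise ValidationError("k_neighbors must be < number of labeled genomes")
    ids, dists = _genome_profiles(matrix, metric)
    dmat = squareform(dists)
    idx = {g: i for i, g in enumerate(ids)}

    inferred: dict[str, str] = {}
    for g in matrix.genome_ids:
        pool = sorted(
            (dmat[idx[g], idx[h]], h) for h in labeled if h != g
        )
        votes: dict[str, int] = {}
        for _, h in pool[:k_neighbors]:
            votes[declared[h]] = votes.get(declared[h], 0) + 1
        top = max(votes.values())
        tied = sorted(lbl for lbl, v in votes.items() if v == top)
        own = declared[g]
        inferred[g] = own if own in tied else tied[0]
    return inferred


def detect_mislabels(matrix: PresenceAbsenceMatrix, genome_set: GenomeSet,
                     k_neighbors: int = 3, metric: str = "euclidean",
                     ) -> list[tuple[str, str, str]]:
    """Genomes whose declared subspecies disagrees with their gene-content
    neighbourhood.

    Returns ``(genome_id, declared_label, inferred_label)`` for each flagged
    genome; genomes labeled only at species level receive an inference but
    are never flagged.
    """
    inferred = infer_labels(matrix, genome_set, k_neighbors=k_neighbors,
                            metric=metric)
    declared = genome_set.declared_labels()
    flagged = []
    for g in matrix.genome_ids:
        if declared[g] == SPECIES_ONLY:
            continue
        if inferred[g] != declared[g]:
            flagged.append((g, declared[g], inferred[g]))
    return flagged
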