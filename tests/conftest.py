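"""Shared fixtures: one synthetic study dataset plus its discovery products.

The study conditions — 3 subspecies × 4 genomes, 2 planted markers per
subspecies, 2% within-family divergence, 2 deliberately mislabeled
genomes — are fixed here and reused session-wide so the expensive
clustering runs once.
"""

from __future__ import annotations

import pytest

from pangmark import (
    SyntheticConfig,
    build_presence_matrix,
    candidate_markers,
    detect_mislabels,
    generate_pangenome_set,
    greedy_cluster,
    specificity_screen,
)
from pangmark.pangenome import ClusterParams, pairwise_identity

STUDY_CONDITIONS = dict(
    n_subspecies=3,
    genomes_per_subspecies=4,
    planted_markers_per_label=2,
    within_family_divergence=0.02,
    mislabeled_genomes=2,
)


def study_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **STUDY_CONDITIONS)


@pytest.fixture(scope="session")
def base_config():
    return study_config(seed=7)


@pytest.fixture(scope="session")
def base_dataset(base_config):
    """(genome_set, truth) for the session's reference dataset."""
    return generate_pangenome_set(base_config)


@pytest.fixture(scope="session")
def base_clusters(base_dataset):
    genome_set, _ = base_dataset
    return greedy_cluster(genome_set)


@pytest.fixture(scope="session")
def base_matrix(base_dataset, base_clusters):
    genome_set, _ = base_dataset
    return build_presence_matrix(base_clusters, genome_set)


@pytest.fixture(scope="session")
def corrected_labels(base_dataset, base_matrix):
    genome_set, _ = base_dataset
    labels = genome_set.declared_labels()
    for genome_id, _declared, inferred in detect_mislabels(base_matrix, genome_set):
        labels[genome_id] = inferred
    return labels


@pytest.fixture(scope="session")
def screened_by_label(base_config, base_dataset, base_clusters, base_matrix,
                      corrected_labels):
    """label -> list of screened MarkerCandidate for the reference dataset."""
    genome_set, _ = base_dataset
    out = {}
    for label in base_config.labels:
        cands = candidate_markers(base_matrix, genome_set, label,
                                  clusters=base_clusters,
                                  labels=corrected_labels)
        out[label] = [
            specificity_screen(c, genome_set, labels=corrected_labels)
            for c in cands
        ]
    return out


@pytest.fixture(scope="session")
def centroid_of(base_clusters):
    return {c.cluster_id: c.centroid for c in base_clusters}


def brute_force_greedy(genome_set, params: ClusterParams | None = None):
    """Reference clustering: same greedy rule, no k-mer prefilter.

    Computes every query-vs-centroid identity by full alignment and returns
    the member partition as a list of member lists, in founding order.
    """
    params = params or ClusterParams()
    entries = []
    for genome in genome_set:
        for gene_id, aa in genome.proteins().items():
            entries.append((genome.genome_id, gene_id, aa))
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))
    centroids: list[str] = []
    members: list[list[tuple[str, str]]] = []
    for genome_id, gene_id, seq in entries:
        placed = False
        for idx, cseq in enumerate(centroids):
            ident, cov = pairwise_identity(seq, cseq)
            if ident >= params.identity_cutoff and cov >= params.min_coverage:
                members[idx].append((genome_id, gene_id))
                placed = True
                break
        if not placed:
            centroids.append(seq)
            members.append([(genome_id, gene_id)])
    return members


@pytest.fixture(scope="session")
def greedy_oracle():
    return brute_force_greedy
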