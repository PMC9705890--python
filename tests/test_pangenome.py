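import numpy as np
import pytest

from pangmark import (
    GenomeRecord,
    GenomeSet,
    SyntheticConfig,
    ValidationError,
    build_presence_matrix,
    cluster_frequency_tree,
    detect_mislabels,
    generate_pangenome_set,
    greedy_cluster,
    pairwise_identity,
    partition_pangenome,
    subspecies_core,
)
from pangmark.pangenome import ClusterParams, PresenceAbsenceMatrix


def _set_from_seqs(per_genome: dict[str, list[str]], label="bulgaricus"):
    genomes = [
        GenomeRecord(gid, label, {f"g{i}": s for i, s in enumerate(seqs)})
        for gid, seqs in per_genome.items()
    ]
    return GenomeSet(genomes)


class TestPairwiseIdentity:
    def test_self_identity(self):
        assert pairwise_identity("ACGT" * 8, "ACGT" * 8) == (1.0, 1.0)

    def test_single_mismatch(self):
        ident, cov = pairwise_identity("AAAAACAAAA", "AAAAAGAAAA")
        assert ident == pytest.approx(0.9)
        assert cov == pytest.approx(1.0)

    def test_no_matches(self):
        ident, _ = pairwise_identity("AAAA", "TTTT")
        assert ident == 0.0

    def test_symmetric(self):
        a, b = "ATGGCGTTAGCATGCAAT", "ATGGCGTAGGCATGGAATCCT"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_matches_hamming_oracle_on_substitution_pairs(self):
        # with scattered substitutions and equal lengths the gapless
        # alignment is optimal, so identity must equal the Hamming identity
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            n = int(rng.integers(50, 200))
            seq = rng.choice(bases, size=n)
            other = seq.copy()
            k = int(rng.integers(1, max(2, n // 10)))
            sites = rng.choice(n, size=k, replace=False)
            for pos in sites:
                choices = [b for b in "ACGT" if b != other[pos]]
                other[pos] = choices[int(rng.integers(0, 3))]
            ident, cov = pairwise_identity("".join(seq), "".join(other))
            assert ident == pytest.approx(1.0 - k / n)
            assert cov == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "ACGT")

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValidationError, match="alphabet"):
            pairwise_identity("ACGT", "MKLF")


class TestGreedyCluster:
    def test_identical_copies_form_one_cluster(self):
        seq = "ATGGCTGCTAAAGCTGGTGCTTAA" * 3
        gs = _set_from_seqs({f"G{i}": [seq] for i in range(5)})
        clusters = greedy_cluster(gs)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_unrelated_sequences_stay_singletons(self):
        rng = np.random.default_rng(0)
        gs = _set_from_seqs({
            f"G{i}": ["".join(rng.choice(list("ACGT"), size=120))]
            for i in range(4)
        })
        clusters = greedy_cluster(gs)
        assert len(clusters) == 4

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValidationError):
            greedy_cluster(GenomeSet([], {"bulgaricus"}))

    def test_clustering_is_a_partition(self, base_dataset, base_clusters):
        genome_set, _ = base_dataset
        seen = set()
        for cluster in base_clusters:
            for member in cluster.members:
                assert member not in seen
                seen.add(member)
        expected = {
            (g.genome_id, gene_id) for g in genome_set for gene_id in g.cds_nt
        }
        assert seen == expected

    def test_recovers_planted_families(self, base_dataset, base_clusters):
        _, truth = base_dataset
        recovered = {
            frozenset(c.members) for c in base_clusters
        }
        planted: dict[str, set] = {}
        for gene, fam in truth.family_of_gene.items():
            planted.setdefault(fam, set()).add(gene)
        assert recovered == {frozenset(m) for m in planted.values()}

    def test_lower_cutoff_never_increases_cluster_count(self):
        for seed in range(3):
            config = SyntheticConfig(
                n_subspecies=2, genomes_per_subspecies=2,
                universal_core_families=4, subspecies_core_families=2,
                planted_markers_per_label=1, accessory_families=2,
                unique_families_per_genome=1, seed=seed,
            )
            gs, _ = generate_pangenome_set(config)
            counts = [
                len(greedy_cluster(gs, ClusterParams(identity_cutoff=c)))
                for c in (0.9, 0.5, 0.3)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_agrees_with_brute_force_oracle(self, greedy_oracle):
        for seed in range(3):
            config = SyntheticConfig(
                n_subspecies=2, genomes_per_subspecies=2,
                universal_core_families=3, subspecies_core_families=2,
                planted_markers_per_label=1, accessory_families=2,
                unique_families_per_genome=1, seed=100 + seed,
            )
            gs, _ = generate_pangenome_set(config)
            ours = {frozenset(c.members) for c in greedy_cluster(gs)}
            oracle = {frozenset(m) for m in greedy_oracle(gs)}
            assert ours == oracle


class TestPresenceMatrix:
    def test_trivial_rows(self):
        seq = "ATGGCTAAAGCTGGTTCTTGGTAA" * 3
        rng = np.random.default_rng(1)
        private = "".join(rng.choice(list("ACGT"), size=90))
        gs = _set_from_seqs({
            "G1": [seq, private], "G2": [seq], "G3": [seq],
        })
        matrix = build_presence_matrix(greedy_cluster(gs), gs)
        rows = {tuple(r) for r in matrix.presence}
        assert (1, 1, 1) in rows
        assert (1, 0, 0) in rows

    def test_column_sums_equal_gene_counts(self, base_dataset, base_matrix):
        genome_set, _ = base_dataset
        for j, genome_id in enumerate(base_matrix.genome_ids):
            assert base_matrix.copy_number[:, j].sum() == \
                genome_set.get(genome_id).cds_count

    def test_presence_iff_copy_number(self, base_matrix):
        assert ((base_matrix.presence == 1) ==
                (base_matrix.copy_number >= 1)).all()

    def test_unknown_genome_member_rejected(self, base_dataset, base_clusters):
        genome_set, _ = base_dataset
        import copy

        clusters = copy.deepcopy(base_clusters[:1])
        clusters[0].members.append(("ghost", "g1"))
        with pytest.raises(ValidationError, match="unknown genome"):
            build_presence_matrix(clusters, genome_set)


class TestPartition:
    def test_core_and_unique_rows(self):
        matrix = PresenceAbsenceMatrix(
            ["c1", "c2"], ["G1", "G2", "G3"],
            np.array([[1, 1, 1], [1, 0, 0]]),
        )
        part = partition_pangenome(matrix)
        assert part.sizes == (1, 0, 1)

    def test_conservation(self, base_matrix):
        part = partition_pangenome(base_matrix)
        assert part.pangenome_size == len(base_matrix.cluster_ids)
        assert not (part.core & part.accessory)
        assert not (part.core & part.unique)
        assert not (part.accessory & part.unique)

    def test_matches_planted_design(self, base_dataset, base_matrix):
        _, truth = base_dataset
        part = partition_pangenome(base_matrix)
        design = truth.design_matrix
        occupancy = design.sum(axis=1)
        n = design.shape[1]
        assert len(part.core) == int((occupancy == n).sum())
        assert len(part.unique) == int((occupancy == 1).sum())
        assert len(part.accessory) == int(
            ((occupancy > 1) & (occupancy < n)).sum())

    def test_single_genome_rejected(self):
        matrix = PresenceAbsenceMatrix(["c1"], ["G1"], np.array([[1]]))
        with pytest.raises(ValidationError):
            partition_pangenome(matrix)


class TestSubspeciesCore:
    def test_single_genome_label_degenerate(self):
        matrix = PresenceAbsenceMatrix(
            ["c1", "c2", "c3"], ["G1", "G2"],
            np.array([[1, 1], [1, 0], [0, 1]]),
        )
        gs = GenomeSet([
            GenomeRecord("G1", "lactis", {"g1": "ATGTAA"}),
            GenomeRecord("G2", "sunkii", {"g1": "ATGTAA"}),
        ])
        assert subspecies_core(matrix, gs, "lactis") == {"c1", "c2"}

    def test_absent_from_one_member_excluded(self):
        matrix = PresenceAbsenceMatrix(
            ["c1", "c2"], ["G1", "G2", "G3"],
            np.array([[1, 1, 1], [1, 0, 1]]),
        )
        gs = GenomeSet([
            GenomeRecord("G1", "lactis", {"g1": "ATGTAA"}),
            GenomeRecord("G2", "lactis", {"g1": "ATGTAA"}),
            GenomeRecord("G3", "sunkii", {"g1": "ATGTAA"}),
        ])
        assert subspecies_core(matrix, gs, "lactis") == {"c1"}

    def test_unknown_label_rejected(self, base_dataset, base_matrix):
        genome_set, _ = base_dataset
        with pytest.raises(ValidationError):
            subspecies_core(base_matrix, genome_set, "martian")

    def test_contains_universal_core(self, base_config, base_dataset,
                                     base_matrix, corrected_labels):
        genome_set, _ = base_dataset
        universal = partition_pangenome(base_matrix).core
        for label in base_config.labels:
            core = subspecies_core(base_matrix, genome_set, label,
                                   labels=corrected_labels)
            assert universal <= core


class TestClusterFrequencyTree:
    def _matrix(self):
        return PresenceAbsenceMatrix(
            ["c1", "c2", "c3", "c4"], ["A", "B", "C"],
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 1, 1]]),
        )

    def test_identical_pair_groups_together(self):
        newick = cluster_frequency_tree(self._matrix())
        assert "(A:0,B:0)" in newick or "(B:0,A:0)" in newick

    def test_genome_order_invariance(self):
        m1 = self._matrix()
        m2 = PresenceAbsenceMatrix(
            m1.cluster_ids, ["C", "A", "B"],
            m1.copy_number[:, [2, 0, 1]],
        )
        assert cluster_frequency_tree(m1) == cluster_frequency_tree(m2)

    def test_subspecies_form_clades(self, base_dataset, base_matrix):
        import dendropy

        genome_set, truth = base_dataset
        newick = cluster_frequency_tree(base_matrix)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True  # Ward dendrograms are rooted
        tree.encode_bipartitions()
        groups = {}
        for gid, label in truth.true_label.items():
            groups.setdefault(label, set()).add(gid)
        taxa = {t.label: t for t in tree.taxon_namespace}
        for label, members in groups.items():
            mrca = tree.mrca(taxa=[taxa[m] for m in members])
            leaves = {l.taxon.label for l in mrca.leaf_iter()}
            assert leaves == members, f"{label} not monophyletic"

    def test_too_few_genomes_rejected(self):
        matrix = PresenceAbsenceMatrix(
            ["c1"], ["A", "B"], np.array([[1, 1]]))
        with pytest.raises(ValidationError):
            cluster_frequency_tree(matrix)


class TestDetectMislabels:
    def test_consistent_neighborhood_not_flagged(self):
        copy = np.array([
            [1, 1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 1],
            [1, 1, 1, 1, 1, 1],
        ])
        gs = GenomeSet([
            GenomeRecord(g, l, {"g1": "ATGTAA"})
            for g, l in zip("ABCDEF",
                            ["lactis"] * 3 + ["sunkii"] * 3)
        ])
        matrix = PresenceAbsenceMatrix(
            ["c1", "c2", "c3", "c4"], list("ABCDEF"), copy)
        assert detect_mislabels(matrix, gs, k_neighbors=2) == []

    def test_flags_exactly_planted_swaps(self, base_dataset, base_matrix):
        genome_set, truth = base_dataset
        flagged = detect_mislabels(base_matrix, genome_set)
        planted = {
            g for g in truth.true_label
            if truth.true_label[g] != truth.declared_label[g]
        }
        assert {f[0] for f in flagged} == planted
        for genome_id, _declared, inferred in flagged:
            assert inferred == truth.true_label[genome_id]

    def test_invalid_k_rejected(self, base_dataset, base_matrix):
        genome_set, _ = base_dataset
        with pytest.raises(ValidationError):
            detect_mislabels(base_matrix, genome_set, k_neighbors=0)
        with pytest.raises(ValidationError):
            detect_mislabels(base_matrix, genome_set, k_neighbors=len(genome_set))
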