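"""Synthetic pangenomes with planted ground truth.

The generator emulates the input structure of a multi-subspecies genome
collection: every genome carries a universal core; each subspecies carries
its own core genes, among them single-copy planted *markers* present in all
genomes of that subspecies and nowhere else; accessory families occur at
intermediate frequency; each genome has private unique genes.  A
configurable number of genomes is deliberately mislabeled (declared label
swapped to a different subspecies while the gene content follows the true
one), emulating mislabeled public deposits.

Non-marker subspecies-core families are shared between *pairs* of
subspecies, so per-subspecies cores exceed the universal core while the
planted markers remain the only families whose presence pattern exactly
matches one subspecies.  Accessory presence patterns are resampled if they
would collide with a subspecies pattern (or fall outside intermediate
frequency), which keeps the planted markers identifiable as ground truth.

``within_family_divergence`` is the expected *pairwise* divergence between
two members of a family: each copy is mutated at half that rate from the
family ancestor.  Sequences are ORF-like (start codon, sense codons, one
stop); mutation is substitution-only so identity arithmetic stays analytic.

Everything is reproducible from ``seed``; each genome draws from its own
RNG stream derived from (seed, genome index) so generation order cannot
leak between genomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import SPECIES_ONLY, GenomeRecord, GenomeSet

SUBSPECIES_EPITHETS = (
    "bulgaricus", "lactis", "delbrueckii", "indicus", "jakobsenii", "sunkii",
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass
class SyntheticConfig:
    n_subspecies: int = 3
    genomes_per_subspecies: int = 4
    universal_core_families: int = 30
    subspecies_core_families: int = 10  # per label, planted markers included
    planted_markers_per_label: int = 2
    accessory_families: int = 15
    accessory_presence_probability: float = 0.5
    unique_families_per_genome: int = 3
    gene_length_range: tuple[int, int] = (300, 900)
    within_family_divergence: float = 0.02  # expected pairwise member divergence
    mislabeled_genomes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subspecies, self.genomes_per_subspecies,
            self.universal_core_families, self.subspecies_core_families,
            self.planted_markers_per_label, self.accessory_families,
            self.unique_families_per_genome, self.mislabeled_genomes,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.n_subspecies < 1:
            raise ValidationError("need at least one subspecies")
        if self.planted_markers_per_label > self.subspecies_core_families:
            raise ValidationError(
                "planted markers exceed subspecies core size")
        if not 0 <= self.accessory_presence_probability <= 1:
            raise ValidationError("presence probability must be in [0, 1]")
        if not 0 <= self.within_family_divergence < 0.5:
            raise ValidationError("within_family_divergence must be in [0, 0.5)")
        lo, hi = self.gene_length_range
        if lo < 9 or hi < lo:
            raise ValidationError("invalid gene_length_range")
        if self.mislabeled_genomes > self.n_subspecies * self.genomes_per_subspecies:
            raise ValidationError("more mislabels than genomes")
        if self.mislabeled_genomes > 0 and self.n_subspecies < 2:
            raise ValidationError("mislabels require >= 2 subspecies")
        if self.mislabeled_genomes > self.n_subspecies:
            raise ValidationError(
                "at most one mislabeled genome per subspecies is supported"
            )

    @property
    def labels(self) -> list[str]:
        out = list(SUBSPECIES_EPITHETS[:self.n_subspecies])
        out += [f"subsp{i}" for i in range(len(out), self.n_subspecies)]
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth used as the oracle for every pipeline stage."""

    family_of_gene: dict[tuple[str, str], str]
    marker_families: dict[str, frozenset[str]]
    true_label: dict[str, str]
    declared_label: dict[str, str]
    design_matrix: pd.DataFrame  # families x genomes, 0/1
    ancestors: dict[str, str]
    family_category: dict[str, str]

    def label_core_families(self, label: str) -> list[str]:
        cols = [g for g, l in self.true_label.items() if l == label]
        sub = self.design_matrix[cols]
        return list(sub.index[(sub == 1).all(axis=1)])


def _random_cds(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    length -= length % 3
    n_codons = max(length // 3, 3)
    middle = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + "TAA"


def mutate_sequence(seq: str, rate: float, seed=0) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to a *different* base, uniformly
    among the other three.  ``seed`` may be an integer or an existing
    numpy Generator (the generator is advanced in place).
    """
    if not 0 <= rate < 1:
        raise ValidationError("rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if rate == 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    picks = rng.integers(0, 3, size=hits.size)
    out = list(seq)
    for pos, pick in zip(hits, picks):
        alternatives = [b for b in _BASES if b != out[pos]]
        out[pos] = alternatives[pick]
    return "".join(out)


def _shared_family_pairs(n_labels: int, per_label: int) -> list[tuple[int, int]]:
    """Label-pair coverage for non-marker subspecies-core families."""
    if per_label == 0:
        return []
    if n_labels == 1:
        return [(0, 0)] * per_label
    cycle = [(i, (i + 1) % n_labels) for i in range(n_labels)]
    n_families = -(-per_label * n_labels // 2)  # ceil
    return list(itertools.islice(itertools.cycle(cycle), n_families))


def generate_pangenome_set(config: SyntheticConfig,
                           ) -> tuple[GenomeSet, SyntheticTruth]:
    """Generate a labeled genome set and its planted truth."""
    labels = config.labels
    master = np.random.default_rng([config.seed, 1])
    genome_ids = [
        f"{label}{j + 1:02d}"
        for label in labels
        for j in range(config.genomes_per_subspecies)
    ]
    true_label = {
        gid: labels[i // config.genomes_per_subspecies]
        for i, gid in enumerate(genome_ids)
    }

    # --- family layout -------------------------------------------------
    coverage: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    family_order: list[str] = []

    def add(fam: str, genomes: set[str], cat: str) -> None:
        family_order.append(fam)
        coverage[fam] = genomes
        category[fam] = cat

    all_genomes = set(genome_ids)
    for i in range(config.universal_core_families):
        add(f"U{i:03d}", all_genomes, "universal")

    per_label_shared = (
        config.subspecies_core_families - config.planted_markers_per_label
    )
    label_members = {
        label: {g for g, l in true_label.items() if l == label}
        for label in labels
    }
    for i, (a, b) in enumerate(
            _shared_family_pairs(len(labels), per_label_shared)):
        add(f"S{i:03d}", label_members[labels[a]] | label_members[labels[b]],
            "shared_core")

    marker_families: dict[str, set[str]] = {label: set() for label in labels}
    for label in labels:
        for i in range(config.planted_markers_per_label):
            fam = f"M_{label}_{i}"
            add(fam, set(label_members[label]), "marker")
            marker_families[label].add(fam)

    n = len(genome_ids)
    label_patterns = {
        frozenset(m) for m in label_members.values()
    }
    for i in range(config.accessory_families):
        carriers = None
        for _attempt in range(1000):
            draw = master.random(n) < config.accessory_presence_probability
            cand = {g for g, hit in zip(genome_ids, draw) if hit}
            if not 2 <= len(cand) <= n - 1:
                continue
            if frozenset(cand) in label_patterns:
                continue
            carriers = cand
            break
        if carriers is None:
            raise ValidationError(
                "could not draw an intermediate-frequency accessory pattern; "
                "adjust accessory_presence_probability"
            )
        add(f"A{i:03d}", carriers, "accessory")

    for gid in genome_ids:
        for i in range(config.unique_families_per_genome):
            add(f"Q_{gid}_{i}", {gid}, "unique")

    ancestors = {
        fam: _random_cds(master, config.gene_length_range)
        for fam in family_order
    }

    # --- mislabels -----------------------------------------------------
    # At most one swap per true subspecies: a neighbourhood vote cannot
    # identify the culprits once half a group is consistently mislabeled,
    # and the deposits being emulated were lone strays in their groups.
    declared = dict(true_label)
    if config.mislabeled_genomes:
        order = master.permutation(genome_ids)
        hit_groups: set[str] = set()
        swapped = []
        for gid in order:
            if true_label[gid] in hit_groups:
                continue
            swapped.append(gid)
            hit_groups.add(true_label[gid])
            if len(swapped) == config.mislabeled_genomes:
                break
        for gid in swapped:
            others = [l for l in labels if l != true_label[gid]]
            declared[gid] = others[int(master.integers(0, len(others)))]

    # --- per-genome sequences ------------------------------------------
    copy_rate = config.within_family_divergence / 2.0
    genomes = []
    family_of_gene: dict[tuple[str, str], str] = {}
    for gi, gid in enumerate(genome_ids):
        rng = np.random.default_rng([config.seed, 2, gi])
        cds: dict[str, str] = {}
        idx = 0
        for fam in family_order:
            if gid not in coverage[fam]:
                continue
            idx += 1
            gene_id = f"g{idx:04d}"
            cds[gene_id] = mutate_sequence(ancestors[fam], copy_rate, rng)
            family_of_gene[(gid, gene_id)] = fam
        genomes.append(GenomeRecord(
            genome_id=gid, declared_label=declared[gid], cds_nt=cds,
            source_accession=f"SYN_{gid}",
        ))

    design = pd.DataFrame(
        [[1 if g in coverage[fam] else 0 for g in genome_ids]
         for fam in family_order],
        index=family_order, columns=genome_ids, dtype=int,
    )
    truth = SyntheticTruth(
        family_of_gene=family_of_gene,
        marker_families={l: frozenset(s) for l, s in marker_families.items()},
        true_label=true_label,
        declared_label=declared,
        design_matrix=design,
        ancestors=ancestors,
        family_category=category,
    )
    return GenomeSet(genomes, label_vocabulary=set(labels)), truth


def generate_query_genomes(config: SyntheticConfig, truth: SyntheticTruth,
                           query_labels: list[str], seed: int = 0,
                           ) -> tuple[GenomeSet, dict[str, str]]:
    """Unlabeled genomes drawn from known subspecies, for assignment tests.

    Each query genome carries the full core of its true subspecies (derived
    from the truth design matrix, markers included) plus fresh private
    genes, declared only at species level.  Returns the set and the hidden
    true labels.
    """
    genomes = []
    hidden: dict[str, str] = {}
    copy_rate = config.within_family_divergence / 2.0
    for i, label in enumerate(query_labels):
        if label not in truth.marker_families:
            raise ValidationError(f"unknown subspecies label {label!r}")
        rng = np.random.default_rng([seed, 3, i])
        gid = f"query{i + 1:02d}"
        cds: dict[str, str] = {}
        idx = 0
        for fam in truth.label_core_families(label):
            idx += 1
            cds[f"g{idx:04d}"] = mutate_sequence(
                truth.ancestors[fam], copy_rate, rng)
        for _ in range(config.unique_families_per_genome):
            idx += 1
            cds[f"g{idx:04d}"] = _random_cds(rng, config.gene_length_range)
        genomes.append(GenomeRecord(
            genome_id=gid, declared_label=SPECIES_ONLY, cds_nt=cds,
            source_accession=f"SYN_{gid}",
        ))
        hidden[gid] = label
    return GenomeSet(genomes, label_vocabulary=set(config.labels)), hidden


def simulate_qpcr(efficiency_percent: float, log10_inputs, ct_at_1ng: float = 25.0,
                  noise_sd: float = 0.0, seed: int = 0) -> list[float]:
    """Ct values of a dilution series at a given amplification efficiency.

    Ct = ct_at_1ng − log10(amount) / log10(1 + E/100) + N(0, noise_sd).
    """
    if not 0 < efficiency_percent <= 100:
        raise ValidationError("efficiency must be in (0, 100]")
    x = np.asarray(log10_inputs, dtype=float)
    slope = -1.0 / np.log10(1.0 + efficiency_percent / 100.0)
    ct = ct_at_1ng + slope * x
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 4])
        ct = ct + rng.normal(0.0, noise_sd, size=x.size)
    return [float(v) for v in ct]


def truth_to_json_dict(truth: SyntheticTruth) -> dict:
    """JSON-serializable form of the planted truth (for the CLI)."""
    return {
        "family_of_gene": {
            f"{g}\t{gene}": fam for (g, gene), fam in truth.family_of_gene.items()
        },
        "marker_families": {l: sorted(s) for l, s in truth.marker_families.items()},
        "true_label": truth.true_label,
        "declared_label": truth.declared_label,
        "design_matrix": {
            fam: {g: int(v) for g, v in row.items()}
            for fam, row in truth.design_matrix.iterrows()
        },
        "family_category": truth.family_category,
    }
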