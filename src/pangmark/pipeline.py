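"""End-to-end orchestration and product label-compliance reporting.

``run_pipeline`` chains the stages: load genomes → cluster genes → build
the presence/absence pangenome → partition → gene-cluster-frequency tree →
mislabel detection (labels corrected by default before marker selection) →
per-subspecies candidate markers → specificity screen → marker FASTA +
identity heatmap → assignment of species-only genomes → optional primer
evaluation.  All tabular outputs are TSV, the tree is newick, and two runs
with identical inputs and configuration produce byte-identical files.

``normalize_label`` and ``monitoring_report`` implement the product-label
compliance check: a claim is compliant only when it uses the full trinomial
nomenclature (genus, species, subspecies); abbreviated binomials such as
"L. bulgaricus" are normalized to the trinomial but flagged, and generic
claims ("lactic acid bacteria") are unspecified.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .genome_io import (
    SPECIES_ONLY,
    GenomeSet,
    load_genome_set,
    summary_table,
    total_gene_count,
)
from .marker_selection import (
    MarkerCandidate,
    ScreenParams,
    assign_subspecies,
    candidate_markers,
    rank_markers,
    specificity_screen,
)
from .pangenome import (
    ClusterParams,
    build_presence_matrix,
    cluster_frequency_tree,
    detect_mislabels,
    greedy_cluster,
    partition_pangenome,
    subspecies_core,
)
from .primer_insilico import in_silico_pcr, primer_pairs_from_frame
from .synthetic_data import SUBSPECIES_EPITHETS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest_path: str
    out_dir: str
    sequence_dir: str | None = None
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    target_labels: list[str] | None = None  # default: all labels in manifest
    correct_mislabels: bool = True
    k_neighbors: int = 3
    tree_metric: str = "euclidean"
    tree_linkage: str = "ward"
    primer_table: str | None = None
    seed: int = 0
    log_level: str = "INFO"


def _write_tsv(frame: pd.DataFrame, path: Path, float_format="%.4f") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all reports; returns the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pangmark")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    def done(name):
        log.info("stage %s finished in %.2fs", name,
                 time.perf_counter() - timings[name])

    try:
        stage("load")
        genome_set = load_genome_set(config.manifest_path, config.sequence_dir)
        targets = config.target_labels or genome_set.labels_present()
        if not targets:
            raise ValidationError("no target labels (only species_only genomes)")
        _write_tsv(summary_table(genome_set), out / "genome_summary.tsv")
        done("load")

        stage("cluster")
        clusters = greedy_cluster(genome_set, config.cluster_params)
        rows = []
        for c in clusters:
            for genome_id, gene_id in c.members:
                rows.append({
                    "cluster_id": c.cluster_id, "genome_id": genome_id,
                    "gene_id": gene_id,
                    "is_centroid": int((genome_id, gene_id) == c.centroid),
                })
        _write_tsv(pd.DataFrame(rows), out / "clusters.tsv")
        done("cluster")

        stage("matrix")
        matrix = build_presence_matrix(clusters, genome_set)
        matrix.to_frame("presence").rename_axis("cluster_id").reset_index() \
            .to_csv(out / "presence.tsv", sep="\t", index=False)
        matrix.to_frame("copy_number").rename_axis("cluster_id").reset_index() \
            .to_csv(out / "copy_number.tsv", sep="\t", index=False)
        done("matrix")

        stage("partition")
        partition = partition_pangenome(matrix)
        cat = {cid: "core" for cid in partition.core}
        cat.update({cid: "accessory" for cid in partition.accessory})
        cat.update({cid: "unique" for cid in partition.unique})
        _write_tsv(
            pd.DataFrame({
                "cluster_id": matrix.cluster_ids,
                "category": [cat[c] for c in matrix.cluster_ids],
            }),
            out / "partition.tsv",
        )
        done("partition")

        newick = None
        if len(genome_set) >= 3:
            stage("tree")
            newick = cluster_frequency_tree(
                matrix, metric=config.tree_metric, linkage=config.tree_linkage)
            (out / "tree.nwk").write_text(newick + "\n")
            done("tree")

        stage("mislabels")
        declared = genome_set.declared_labels()
        flagged: list[tuple[str, str, str]] = []
        n_labeled = sum(1 for v in declared.values() if v != SPECIES_ONLY)
        if len(genome_set.labels_present()) >= 2 \
                and config.k_neighbors < n_labeled:
            flagged = detect_mislabels(
                matrix, genome_set, k_neighbors=config.k_neighbors,
                metric=config.tree_metric)
        corrected = dict(declared)
        if config.correct_mislabels:
            for genome_id, _was, inferred in flagged:
                corrected[genome_id] = inferred
        labels = corrected if config.correct_mislabels else declared
        _write_tsv(
            pd.DataFrame({
                "genome_id": [f[0] for f in flagged],
                "declared_label": [f[1] for f in flagged],
                "inferred_label": [f[2] for f in flagged],
            }),
            out / "mislabels.tsv",
        )
        done("mislabels")

        stage("markers")
        per_label: dict[str, dict] = {}
        confirmed_all: list[MarkerCandidate] = []
        screen_rows: dict[str, dict] = {
            g: {"genome_id": g} for g in genome_set.genome_ids
        }
        for label in targets:
            core = subspecies_core(matrix, genome_set, label, labels=labels)
            cands = candidate_markers(
                matrix, genome_set, label, clusters=clusters, labels=labels)
            screened = [
                specificity_screen(c, genome_set, config.screen_params,
                                   labels=labels)
                for c in cands
            ]
            confirmed = [c for c in screened if c.status == "confirmed"]
            confirmed = rank_markers(confirmed, labels)
            confirmed_all.extend(confirmed)
            for c in screened:
                col = f"{label}|{c.cluster_id}"
                for g, ident in c.screen_identities.items():
                    screen_rows[g][col] = (
                        round(ident, 4) if ident is not None else ""
                    )
            per_label[label] = {
                "genomes": sum(1 for v in labels.values() if v == label),
                "subspecies_core": len(core),
                "candidates": len(cands),
                "confirmed": len(confirmed),
            }
        with open(out / "markers.fasta", "w") as fh:
            for c in confirmed_all:
                fh.write(f">{c.target_label}|{c.cluster_id}\n{c.marker_seq}\n")
        _write_tsv(pd.DataFrame(list(screen_rows.values())),
                   out / "marker_screen.tsv")
        done("markers")

        stage("assign")
        assignments = []
        for genome in genome_set:
            if genome.declared_label != SPECIES_ONLY:
                continue
            result = assign_subspecies(genome, confirmed_all,
                                       config.screen_params) \
                if confirmed_all else None
            assignments.append({
                "genome_id": genome.genome_id,
                "assigned_label": result.label if result else "unassigned",
                "best_identity": round(result.best_identity, 4) if result else 0.0,
            })
        _write_tsv(pd.DataFrame(
            assignments,
            columns=["genome_id", "assigned_label", "best_identity"],
        ), out / "assignments.tsv")
        done("assign")

        amplicon_rows = []
        if config.primer_table:
            stage("primers")
            frame = pd.read_csv(config.primer_table, sep="\t")
            for pair in primer_pairs_from_frame(frame):
                for genome in genome_set:
                    for amp in in_silico_pcr(pair, genome):
                        amplicon_rows.append({
                            "primer": pair.name, "template": amp.template_id,
                            "start": amp.start_1based, "end": amp.end_1based,
                            "length_bp": amp.length_bp,
                            "strand": amp.strand_of_forward,
                            "mismatches": amp.forward_mismatches
                            + amp.reverse_mismatches,
                        })
            _write_tsv(pd.DataFrame(
                amplicon_rows,
                columns=["primer", "template", "start", "end", "length_bp",
                         "strand", "mismatches"],
            ), out / "amplicons.tsv")
            done("primers")

        summary = {
            "n_genomes": len(genome_set),
            "genes_in": total_gene_count(genome_set),
            "n_clusters": len(clusters),
            "partition": {
                "core": len(partition.core),
                "accessory": len(partition.accessory),
                "unique": len(partition.unique),
            },
            "label_mode": "corrected" if config.correct_mislabels else "declared",
            "labels": per_label,
            "mislabels": [list(f) for f in flagged],
            "assignments": assignments,
            "n_amplicons": len(amplicon_rows) if config.primer_table else None,
        }
        (out / "run_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


# --- product label compliance ------------------------------------------

_GENUS = r"(?:l\.|lactobacillus)"


@dataclass
class LabelClaim:
    product_id: str
    claim_text: str
    normalized: str  # canonical trinomial | "species-only" | "unspecified"
    compliant: bool


def _canonical(epithet: str) -> str:
    return f"L. delbrueckii subsp. {epithet}"


def normalize_label(claim_text: str, product_id: str = "") -> LabelClaim:
    """Classify a product label claim against trinomial nomenclature.

    Full trinomials are compliant; abbreviated binomials of a subspecies
    epithet ("L. bulgaricus") normalize to the trinomial but are
    non-compliant; "L. delbrueckii" without a subspecies is species-only;
    anything else ("lactic acid bacteria") is unspecified.
    """
    if not claim_text or not claim_text.strip():
        raise ValidationError("empty claim text")
    text = " ".join(claim_text.split()).lower()
    m = re.search(_GENUS + r"\s+delbrueckii\s+(?:subsp|ssp)\.?\s+([a-z]+)", text)
    if m and m.group(1) in SUBSPECIES_EPITHETS:
        return LabelClaim(product_id, claim_text, _canonical(m.group(1)), True)
    m = re.search(_GENUS + r"\s+([a-z]+)", text)
    if m:
        epithet = m.group(1)
        if epithet == "delbrueckii":
            return LabelClaim(product_id, claim_text, "species-only", False)
        if epithet in SUBSPECIES_EPITHETS:
            return LabelClaim(product_id, claim_text, _canonical(epithet), False)
    return LabelClaim(product_id, claim_text, "unspecified", False)


def monitoring_report(claims: list[LabelClaim],
                      detections: dict[str, str]) -> tuple[pd.DataFrame, dict]:
    """Compare normalized claims with detected subspecies, per product.

    Claim compliance (nomenclature) and claim-vs-detection agreement are
    reported as separate columns.  Every claimed product must have a
    detection entry.
    """
    missing = [c.product_id for c in claims if c.product_id not in detections]
    if missing:
        raise ValidationError(
            f"products without detection entry: {', '.join(missing)}")
    rows = []
    n_compliant = n_noncompliant = n_unspecified = n_agree = 0
    for claim in claims:
        detected = detections[claim.product_id]
        det_epithet = detected.split()[-1].lower() if detected else ""
        if claim.normalized.startswith("L. delbrueckii subsp."):
            claim_epithet = claim.normalized.split()[-1]
            agreement = "match" if claim_epithet == det_epithet else "mismatch"
            if claim.compliant:
                n_compliant += 1
            else:
                n_noncompliant += 1
        else:
            agreement = "not_evaluable"
            n_unspecified += 1
        if agreement == "match":
            n_agree += 1
        rows.append({
            "product_id": claim.product_id,
            "label_claim": claim.claim_text,
            "normalized_claim": claim.normalized,
            "compliant": claim.compliant,
            "detected_subspecies": detected,
            "agreement": agreement,
        })
    frame = pd.DataFrame(rows, columns=[
        "product_id", "label_claim", "normalized_claim", "compliant",
        "detected_subspecies", "agreement",
    ])
    summary = {
        "n_products": len(claims),
        "n_compliant": n_compliant,
        "n_noncompliant": n_noncompliant,
        "n_unspecified": n_unspecified,
        "n_detection_agree": n_agree,
    }
    return frame, summary
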