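"""Subspecies-specific marker selection and the in silico specificity screen.

A candidate marker for a target subspecies is a gene family present in
every genome of the target and in no other genome — the set difference
between the per-subspecies core genome and the rest of the pangenome.  Each
candidate's nucleotide sequence (the cluster centroid's CDS) is then
screened against every genome's CDS complement; the best alignment identity
per genome forms the heatmap row.  A marker is *confirmed* when it is found
at >= ``presence_identity`` (default 95%) with sufficient coverage in all
target genomes and stays below ``absence_identity_ceiling`` (default 70%),
or has no hit at all, everywhere else.  Identities between the ceiling and
the presence threshold are a dead zone: such hits reject the candidate
rather than count as absence.

Screen identity is marker-relative: matches in the best free-end-gap
alignment divided by marker length, so a short accidental alignment against
an unrelated gene cannot masquerade as presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

from .errors import ValidationError
from .genome_io import SPECIES_ONLY, GenomeRecord, GenomeSet
from .pangenome import (
    GeneCluster,
    PresenceAbsenceMatrix,
    _kmers,
    subspecies_core,
)

_SCREEN_KMER = 11  # nt word size for skipping obviously unrelated CDS


def _make_screen_aligner():
    # BLASTN-like scoring: heavy gap costs keep accidental alignments of
    # unrelated genes from chaining matches into inflated identities.
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_internal_gap_score = -5.0
    aligner.extend_internal_gap_score = -2.0
    aligner.end_gap_score = 0.0
    return aligner


_SCREEN_ALIGNER = _make_screen_aligner()


@dataclass
class ScreenParams:
    presence_identity: float = 0.95
    presence_coverage: float = 0.90
    absence_identity_ceiling: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.presence_identity <= 1:
            raise ValidationError("presence_identity must be in (0, 1]")
        if not 0 < self.presence_coverage <= 1:
            raise ValidationError("presence_coverage must be in (0, 1]")
        if not self.absence_identity_ceiling < self.presence_identity:
            raise ValidationError(
                "absence_identity_ceiling must be below presence_identity"
            )


@dataclass
class MarkerCandidate:
    """A gene family proposed as specific to one subspecies."""

    cluster_id: str
    target_label: str
    marker_seq: str
    screen_identities: dict[str, float | None] = field(default_factory=dict)
    screen_coverages: dict[str, float | None] = field(default_factory=dict)
    status: str = "candidate"  # candidate | confirmed | rejected


def screen_identity(marker_seq: str, cds_seq: str) -> tuple[float, float]:
    """Marker-relative identity and coverage of one marker/CDS alignment."""
    if not marker_seq or not cds_seq:
        raise ValidationError("empty sequence")
    aln = _SCREEN_ALIGNER.align(marker_seq, cds_seq)[0]
    row_m, row_c = str(aln[0]), str(aln[1])
    first = last = -1
    for i, (x, y) in enumerate(zip(row_m, row_c)):
        if x != "-" and y != "-":
            if first < 0:
                first = i
            last = i
    if first < 0:
        return 0.0, 0.0
    matches = 0
    marker_in_span = 0
    for i in range(first, last + 1):
        x, y = row_m[i], row_c[i]
        if x != "-":
            marker_in_span += 1
            if x == y:
                matches += 1
    return matches / len(marker_seq), marker_in_span / len(marker_seq)


def best_hit(marker_seq: str, genome: GenomeRecord,
             ) -> tuple[float, float] | None:
    """Best (identity, coverage) of a marker against one genome's CDS set.

    CDS sharing no 11-mer with the marker are skipped; a genome with no
    surviving CDS is a no-hit (``None``), not an error.
    """
    marker_kmers = (
        _kmers(marker_seq, _SCREEN_KMER) if len(marker_seq) >= _SCREEN_KMER else None
    )
    best: tuple[float, float] | None = None
    for cds in genome.cds_nt.values():
        if not cds:
            continue
        if (
            marker_kmers is not None
            and len(cds) >= _SCREEN_KMER
            and not (marker_kmers & _kmers(cds, _SCREEN_KMER))
        ):
            continue
        ident, cov = screen_identity(marker_seq, cds)
        if best is None or (ident, cov) > best:
            best = (ident, cov)
    return best


def candidate_markers(matrix: PresenceAbsenceMatrix, genome_set: GenomeSet,
                      target_label: str,
                      clusters: list[GeneCluster] | None = None,
                      labels: dict[str, str] | None = None,
                      ) -> list[MarkerCandidate]:
    """Families in the target's core genome and absent from every non-target.

    Genomes registered only at species level are excluded from both sides
    of the comparison (they are queries, not references).  When ``clusters``
    are supplied, each candidate carries its centroid CDS as marker
    sequence.
    """
    labels = labels or genome_set.declared_labels()
    if target_label not in set(labels.values()):
        raise ValidationError(f"no genome carries label {target_label!r}")
    core = subspecies_core(matrix, genome_set, target_label, labels=labels)
    non_target = [
        g for g in matrix.genome_ids
        if labels.get(g) not in (target_label, SPECIES_ONLY)
    ]
    by_id = {c.cluster_id: c for c in clusters} if clusters else {}
    out = []
    for cid in matrix.cluster_ids:  # keep matrix row order
        if cid not in core:
            continue
        if any(g in non_target for g in matrix.genomes_with(cid)):
            continue
        marker_seq = ""
        if cid in by_id:
            genome_id, gene_id = by_id[cid].centroid
            marker_seq = genome_set.get(genome_id).cds_nt[gene_id]
        out.append(MarkerCandidate(
            cluster_id=cid, target_label=target_label, marker_seq=marker_seq,
        ))
    return out


def specificity_screen(candidate: MarkerCandidate, genome_set: GenomeSet,
                       params: ScreenParams | None = None,
                       labels: dict[str, str] | None = None,
                       ) -> MarkerCandidate:
    """Screen one candidate against every genome and decide its status.

    Fills ``screen_identities`` (the heatmap row) for all genomes; the
    candidate is confirmed iff the presence rule holds in every target
    genome and the absence rule in every non-target genome.  Species-only
    genomes are screened for the record but do not influence the decision.
    """
    params = params or ScreenParams()
    labels = labels or genome_set.declared_labels()
    if not candidate.marker_seq:
        raise ValidationError(f"{candidate.cluster_id}: empty marker sequence")
    idents: dict[str, float | None] = {}
    covs: dict[str, float | None] = {}
    for genome in genome_set:
        hit = best_hit(candidate.marker_seq, genome) if genome.cds_count else None
        idents[genome.genome_id] = hit[0] if hit else None
        covs[genome.genome_id] = hit[1] if hit else None

    present_ok = True
    absent_ok = True
    for genome in genome_set:
        lbl = labels.get(genome.genome_id)
        ident = idents[genome.genome_id]
        cov = covs[genome.genome_id]
        if lbl == candidate.target_label:
            if ident is None or ident < params.presence_identity \
                    or cov is None or cov < params.presence_coverage:
                present_ok = False
        elif lbl != SPECIES_ONLY:
            if ident is not None and ident >= params.absence_identity_ceiling:
                absent_ok = False
    status = "confirmed" if (present_ok and absent_ok) else "rejected"
    return replace(candidate, screen_identities=idents, screen_coverages=covs,
                   status=status)


def rank_markers(confirmed: list[MarkerCandidate],
                 labels: dict[str, str]) -> list[MarkerCandidate]:
    """Order confirmed markers by (mean target identity − max non-target
    identity), descending; the separation a qPCR assay cares about."""

    def score(c: MarkerCandidate) -> float:
        target = [
            v for g, v in c.screen_identities.items()
            if labels.get(g) == c.target_label and v is not None
        ]
        other = [
            v for g, v in c.screen_identities.items()
            if labels.get(g) not in (c.target_label, SPECIES_ONLY)
            and v is not None
        ]
        mean_t = sum(target) / len(target) if target else 0.0
        max_o = max(other) if other else 0.0
        return mean_t - max_o

    return sorted(confirmed, key=lambda c: (-score(c), c.cluster_id))


class AssignmentResult(NamedTuple):
    label: str  # subspecies | "unassigned" | "conflict"
    best_identity: float
    matched_labels: tuple[str, ...]


def assign_subspecies(genome: GenomeRecord, panel: list[MarkerCandidate],
                      params: ScreenParams | None = None) -> AssignmentResult:
    """Assign a genome to a subspecies via a panel of confirmed markers.

    The genome is screened against every marker; it takes the label of the
    best marker meeting the presence rule.  No qualifying marker →
    ``unassigned``; qualifying markers of two different labels →
    ``conflict`` (both reported).
    """
    params = params or ScreenParams()
    if not panel:
        raise ValidationError("empty marker panel")
    best_overall = 0.0
    qualifying: dict[str, float] = {}
    for marker in panel:
        hit = best_hit(marker.marker_seq, genome) if genome.cds_count else None
        if hit is None:
            continue
        ident, cov = hit
        best_overall = max(best_overall, ident)
        if ident >= params.presence_identity and cov >= params.presence_coverage:
            prev = qualifying.get(marker.target_label, 0.0)
            qualifying[marker.target_label] = max(prev, ident)
    if not qualifying:
        return AssignmentResult("unassigned", best_overall, ())
    matched = tuple(sorted(qualifying, key=lambda l: (-qualifying[l], l)))
    if len(matched) > 1:
        return AssignmentResult("conflict", max(qualifying.values()), matched)
    return AssignmentResult(matched[0], qualifying[matched[0]], matched)
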