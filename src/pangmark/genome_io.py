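"""Manifest-driven genome input/output.

A *genome* here is a labeled bag of protein-coding sequences (CDS); the
assembly itself is never touched.  The on-disk layout is a TSV manifest
(columns ``genome_id``, ``label``, ``cds_fasta``, ``accession``) pointing at
one nucleotide multi-FASTA per genome, optionally accompanied by a matching
``.faa`` protein file with the same gene ids in the same order.  A manifest
comment line ``#label_vocabulary: a,b,c`` declares the closed set of
subspecies labels; the sentinel label ``species_only`` marks genomes
registered only at species level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InputError, ValidationError

log = logging.getLogger(__name__)

SPECIES_ONLY = "species_only"
MANIFEST_COLUMNS = ("genome_id", "label", "cds_fasta", "accession")


def translate_cds(nt: str) -> tuple[str, bool]:
    """Standard-table translation of a CDS, trailing stop removed.

    Returns ``(protein, has_internal_stop)``.  A trailing partial codon is
    ignored; internal stops are retained as ``*`` so downstream alignment
    still sees the full-length product.
    """
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa, "*" in aa


@dataclass
class GenomeRecord:
    """One labeled genome with its CDS sequences.

    ``cds_nt`` maps stable gene ids to uppercase nucleotide sequences in a
    stable order; ``cds_aa``, when present, mirrors it index-for-index.
    """

    genome_id: str
    declared_label: str
    cds_nt: dict[str, str]
    cds_aa: dict[str, str] | None = None
    genome_length_bp: int = 0
    source_accession: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")
        if self.cds_aa is not None and list(self.cds_aa) != list(self.cds_nt):
            raise ValidationError(
                f"{self.genome_id}: protein gene ids do not mirror nucleotide gene ids"
            )
        if self.genome_length_bp < 0:
            raise ValidationError(f"{self.genome_id}: negative genome length")
        if self.genome_length_bp == 0:
            self.genome_length_bp = sum(len(s) for s in self.cds_nt.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cds_nt)

    @property
    def cds_count(self) -> int:
        return len(self.cds_nt)

    def proteins(self) -> dict[str, str]:
        """Protein sequences, translating from nucleotide when no .faa was given."""
        if self.cds_aa is not None:
            return self.cds_aa
        out: dict[str, str] = {}
        n_internal = 0
        for gid, nt in self.cds_nt.items():
            aa, internal = translate_cds(nt)
            out[gid] = aa
            n_internal += internal
        if n_internal:
            log.warning(
                "%s: %d CDS translate with internal stop codons (kept)",
                self.genome_id, n_internal,
            )
        return out


@dataclass
class GenomeSet:
    """An ordered collection of genomes sharing one label vocabulary."""

    genomes: list[GenomeRecord]
    label_vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate genome_id(s): {', '.join(dup)}")
        if not self.label_vocabulary:
            self.label_vocabulary = {
                g.declared_label for g in self.genomes
                if g.declared_label != SPECIES_ONLY
            }
        for g in self.genomes:
            if g.declared_label != SPECIES_ONLY and g.declared_label not in self.label_vocabulary:
                raise ValidationError(
                    f"{g.genome_id}: label {g.declared_label!r} outside vocabulary"
                )
        self._by_id = {g.genome_id: g for g in self.genomes}

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def get(self, genome_id: str) -> GenomeRecord:
        try:
            return self._by_id[genome_id]
        except KeyError:
            raise ValidationError(f"unknown genome_id {genome_id!r}") from None

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def declared_labels(self) -> dict[str, str]:
        return {g.genome_id: g.declared_label for g in self.genomes}

    def labels_present(self) -> list[str]:
        """Subspecies labels carried by at least one genome, sorted."""
        return sorted({
            g.declared_label for g in self.genomes
            if g.declared_label != SPECIES_ONLY
        })


def load_genome_set(manifest_path, sequence_dir=None) -> GenomeSet:
    """Read a manifest TSV plus per-genome CDS FASTA files.

    FASTA paths in the manifest resolve relative to ``sequence_dir``
    (default: the manifest's directory).  A sibling ``.faa`` file with the
    same stem, when present, supplies protein sequences.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"manifest not found: {manifest_path}")
    base = Path(sequence_dir) if sequence_dir is not None else manifest_path.parent

    vocab: set[str] = set()
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in manifest_path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("label_vocabulary:"):
                vocab = {
                    t.strip() for t in body.split(":", 1)[1].split(",") if t.strip()
                }
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [h.strip() for h in fields]
            missing = [c for c in MANIFEST_COLUMNS if c not in header]
            if missing:
                raise ValidationError(
                    f"manifest missing column(s): {', '.join(missing)}"
                )
            continue
        rows.append(dict(zip(header, fields)))
    if not rows:
        raise ValidationError(f"empty manifest: {manifest_path}")

    genomes = []
    for row in rows:
        gid = row["genome_id"].strip()
        fasta = base / row["cds_fasta"].strip()
        if not fasta.exists():
            raise InputError(f"manifest row {gid!r}: CDS file not found: {fasta}")
        cds_nt: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id in cds_nt:
                raise ValidationError(f"{gid}: duplicate gene id {rec.id!r} in {fasta}")
            cds_nt[rec.id] = str(rec.seq).upper()
        cds_aa = None
        faa = fasta.with_suffix(".faa")
        if faa.exists():
            cds_aa = {
                rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(faa), "fasta")
            }
        genomes.append(GenomeRecord(
            genome_id=gid,
            declared_label=row["label"].strip(),
            cds_nt=cds_nt,
            cds_aa=cds_aa,
            source_accession=row.get("accession", "").strip(),
        ))
    return GenomeSet(genomes, label_vocabulary=vocab)


def write_genome_set(genome_set: GenomeSet, out_dir,
                     manifest_name: str = "manifest.tsv") -> Path:
    """Write one CDS FASTA per genome plus a manifest; returns the manifest path.

    Output is byte-deterministic: one sequence per line, genomes and genes in
    set order.  Round-trips through :func:`load_genome_set`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        "#label_vocabulary: " + ",".join(sorted(genome_set.label_vocabulary)),
        "\t".join(MANIFEST_COLUMNS),
    ]
    for g in genome_set:
        fname = f"{g.genome_id}.fna"
        with open(out_dir / fname, "w") as fh:
            for gene_id, seq in g.cds_nt.items():
                fh.write(f">{gene_id}\n{seq}\n")
        if g.cds_aa is not None:
            with open(out_dir / f"{g.genome_id}.faa", "w") as fh:
                for gene_id, seq in g.cds_aa.items():
                    fh.write(f">{gene_id}\n{seq}\n")
        lines.append("\t".join([g.genome_id, g.declared_label, fname,
                                g.source_accession]))
    manifest = out_dir / manifest_name
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def genome_summary(genome: GenomeRecord):
    """``(length_bp, gc_percent, cds_count)`` for one genome.

    GC is 100·(G+C)/(A+C+G+T) over CDS bases; ambiguity codes are excluded
    from numerator and denominator.  An empty genome reports GC as ``None``.
    """
    gc = 0
    at = 0
    for seq in genome.cds_nt.values():
        for ch in seq:
            if ch in "GC":
                gc += 1
            elif ch in "AT":
                at += 1
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else None
    return genome.genome_length_bp, gc_percent, genome.cds_count


def total_gene_count(genome_set: GenomeSet) -> int:
    """Total number of CDS over all genomes in the set."""
    return sum(g.cds_count for g in genome_set)


def summary_table(genome_set: GenomeSet):
    """Per-genome summary as a DataFrame mirroring the survey-table columns."""
    import pandas as pd

    rows = []
    for g in genome_set:
        length, gcp, n = genome_summary(g)
        rows.append({
            "genome_id": g.genome_id,
            "length_bp": length,
            "gc_percent": round(gcp, 2) if gcp is not None else None,
            "cds_count": n,
            "label": g.declared_label,
        })
    return pd.DataFrame(rows)
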