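"""Sequence and annotation I/O with a single, fixed coordinate convention.

All coordinates inside the package are 0-based half-open on the forward
genomic strand; exon lists are stored in ascending genomic order regardless
of strand, and transcript order is applied only at translation time. GFF3
input/output uses the standard 1-based inclusive convention, converted at
exactly one place (here).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

DNA_CHARS = frozenset("ACGTN")
# '*' is tolerated in protein records so that pseudoprotein translations
# (internal stop codons rendered as '*') can round-trip through FASTA.
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

STOP_CODONS = ("TAA", "TAG", "TGA")


class SeqIOError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


@dataclass
class SeqRecord:
    """A named uppercase sequence, either DNA (ACGTN) or protein (20 aa + X/*)."""

    id: str
    seq: str
    kind: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("empty sequence id")
        if not self.seq:
            raise SeqIOError(f"empty sequence for id {self.id!r}")
        if self.kind not in ("dna", "protein"):
            raise SeqIOError(f"unknown sequence kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A stranded multi-exon coding gene model.

    ``exons`` are 0-based half-open genomic intervals, sorted ascending and
    pairwise disjoint. ``phases`` follow the genomic exon order. A model is a
    pseudogene iff its translation contains internal stops or a frameshift
    (CDS length not divisible by three) was detected.
    """

    id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    phases: list[int] | None = None
    source: str = "HRP"
    score: float | None = None
    protein: str | None = None
    internal_stop_count: int = 0
    frameshift: bool = False
    pseudogene: bool = False
    provenance: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"model {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise SeqIOError(f"model {self.id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise SeqIOError(f"model {self.id}: exon start {s} >= end {e}")
            if s < prev_end:
                raise SeqIOError(f"model {self.id}: exons overlap or unsorted")
            prev_end = e
        if self.phases is None:
            self.phases = [0] * len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        """Genomic footprint in bp (first exon start to last exon end)."""
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def key(self) -> tuple:
        return (self.seqid, self.strand, tuple(self.exons))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_alphabet(seq: str, kind: str, ident: str) -> None:
    allowed = DNA_CHARS if kind == "dna" else PROTEIN_CHARS
    for i, c in enumerate(seq):
        if c not in allowed:
            raise SeqIOError(
                f"illegal {kind} character {c!r} at position {i} in record {ident!r}"
            )


def read_fasta(path: str | Path, kind: str) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects in file order.

    Multi-line sequences are concatenated and case-folded to upper. Duplicate
    ids and characters outside the declared alphabet raise :class:`SeqIOError`.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _check_alphabet(seq, kind, rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq, kind=kind))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _model_from_cds_rows(
    mrna_id: str, seqid: str, strand: str, rows: list[tuple[int, int, int]], source: str
) -> GeneModel:
    rows = sorted(rows)
    exons = [(s, e) for s, e, _ in rows]
    phases = [p for _, _, p in rows]
    return GeneModel(
        id=mrna_id, seqid=seqid, strand=strand, exons=exons, phases=phases, source=source
    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read a gene/mRNA/CDS GFF3 file; one model per gene (longest-CDS mRNA).

    Converts 1-based inclusive GFF3 coordinates to internal 0-based half-open.
    Minus-strand exons are stored in ascending genomic order. CDS rows without
    a Parent, or rows with end < start, raise :class:`SeqIOError`.
    """
    # Fast structural validation before handing the file to gffutils.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ftype, start, end, attrs = cols[2], int(cols[3]), int(cols[4]), cols[8]
            if end < start:
                raise SeqIOError(f"{path}:{lineno}: end {end} < start {start}")
            if ftype == "CDS" and "Parent=" not in attrs:
                raise SeqIOError(f"{path}:{lineno}: CDS row without Parent attribute")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: GeneModel | None = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            rows = []
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                phase = 0 if cds.frame in (None, ".") else int(cds.frame)
                rows.append((cds.start - 1, cds.end, phase))
            if not rows:
                continue
            model = _model_from_cds_rows(
                mrna.id, gene.seqid, gene.strand, rows, mrna.source
            )
            attrs = mrna.attributes
            if attrs.get("pseudogene", ["false"])[0] == "true":
                model.pseudogene = True
            if best is None or model.cds_length > best.cds_length:
                best = model
        if best is not None:
            models.append(best)
    return models


def write_gff3(models: list[GeneModel], path: str | Path, source: str | None = None) -> None:
    """Write models as gene/mRNA/CDS GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            src = source or m.source
            score = "." if m.score is None else f"{m.score:.3g}"
            gid = f"{m.id}.gene"
            attrs = [f"ID={m.id}"]
            attrs.append(f"Parent={gid}")
            if m.pseudogene:
                attrs.append("pseudogene=true")
            if m.class_label:
                attrs.append(f"class={m.class_label}")
            if m.provenance:
                attrs.append(f"provenance={m.provenance}")
            fh.write(
                f"{m.seqid}\t{src}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.seqid}\t{src}\tmRNA\t{m.start + 1}\t{m.end}\t{score}\t{m.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )
            for (s, e), ph in zip(m.exons, m.phases):
                fh.write(
                    f"{m.seqid}\t{src}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{ph}\tParent={m.id}\n"
                )


def write_bed6(models: list[GeneModel], path: str | Path) -> None:
    """BED6 export (one row per model) for genome-browser inspection."""
    with open(path, "w") as fh:
        for m in models:
            score = 0 if m.score is None else min(1000, int(m.score))
            fh.write(f"{m.seqid}\t{m.start}\t{m.end}\t{m.id}\t{score}\t{m.strand}\n")


def spliced_cds(model: GeneModel, genome: SeqRecord) -> str:
    """Concatenated CDS in transcript orientation (reverse-complemented on '-')."""
    if model.end > len(genome.seq):
        raise SeqIOError(f"model {model.id} exceeds bounds of {genome.id}")
    cds = "".join(genome.seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        cds = revcomp(cds)
    return cds


def extract_and_translate(model: GeneModel, genome: SeqRecord) -> tuple[str, int]:
    """Translate a gene model with the standard genetic code.

    The phase of the first transcript exon shifts the reading frame; a CDS
    length not divisible by three sets the frameshift flag (translation then
    proceeds in frame 0 over complete codons instead of raising). The trailing
    stop is dropped; internal stops are rendered '*' and counted. Updates
    ``model.protein``, ``model.internal_stop_count`` and ``model.pseudogene``.
    """
    cds = spliced_cds(model, genome)
    first_phase = model.phases[-1] if model.strand == "-" else model.phases[0]
    cds = cds[first_phase:]
    if len(cds) % 3 != 0:
        model.frameshift = True
        cds = cds[: len(cds) // 3 * 3]
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    n_internal = protein.count("*")
    model.protein = protein
    model.internal_stop_count = n_internal
    model.pseudogene = n_internal > 0 or model.frameshift
    return protein, n_internal


def six_frame_stop_profile(dna: str) -> tuple[int, int, int, int, int, int]:
    """Count stop codons (TAA/TAG/TGA) in each of the six reading frames.

    Returns (+1, +2, +3, -1, -2, -3); reverse frames are read on the reverse
    complement. Frames shorter than one codon report 0.
    """
    dna = dna.upper()
    _check_alphabet(dna, "dna", "<six_frame_stop_profile>")
    if len(dna) < 3:
        raise SeqIOError("six_frame_stop_profile requires length >= 3")

    def _count(s: str, offset: int) -> int:
        n = 0
        for i in range(offset, len(s) - 2, 3):
            if s[i : i + 3] in STOP_CODONS:
                n += 1
        return n

    rc = revcomp(dna)
    return (
        _count(dna, 0),
        _count(dna, 1),
        _count(dna, 2),
        _count(rc, 0),
        _count(rc, 1),
        _count(rc, 2),
    )
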