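"""Synthetic genomes with known NB-LRR truth for offline benchmarking.

The generator emulates the situations that make automated R-gene annotation
hard: clustered tandem NB-LRR paralogs with introns, diverged family
members, transposable-element-like ORF decoys, and a deliberately defective
"automated" annotation in which some genes are omitted entirely, adjacent
genes are fused into one model, single genes are split into two, or the
nucleotide-binding domain of a protein is degraded below the profile-scan
threshold while its motif content survives.

R-proteins are assembled from the same consensus blocks that underlie the
bundled domain profiles (CC/TIR/RPW8 + an NB block of 200 residues + a
leucine-rich repeat array), mutated to a target identity, and encoded into
codons with phase-0 GT...AG introns. Every truth model round-trips: its
translation from the generated genome equals the generated protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import domains
from .domains import AA, ProfileLibrary
from .seqio import GeneModel, SeqRecord, extract_and_translate, write_fasta, write_gff3

# codon table for encoding proteins (standard code, no stops)
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

for _codon, _aa in sorted(_tbl.forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)

# residues used at LRR anchor / non-anchor positions (the detector requires
# hydrophobic anchors and non-hydrophobic elsewhere)
_LRR_ANCHOR_SET = "LIVF"
_LRR_OTHER_SET = "ADEGHKNQRSTC"
_LINKER_SET = "ADEGHKNPQRST"

FULL_LENGTH_BLOCKS = {
    "CNL": ["CC", "NB", "LRR"],
    "TNL": ["TIR", "NB", "LRR"],
    "RNL": ["RPW8", "NB", "LRR"],
    "NL": ["NB", "LRR"],
}


class SynthError(ValueError):
    pass


def _rand_from(alphabet: str, n: int, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def lrr_block(n_units: int, rng: np.random.Generator) -> str:
    """Tandem 8-residue LRR units with hydrophobic anchors at 0/3/5/7."""
    units = []
    for _ in range(n_units):
        unit = list(_rand_from(_LRR_OTHER_SET, 8, rng))
        for pos in domains.LRR_ANCHORS:
            unit[pos] = _LRR_ANCHOR_SET[rng.integers(len(_LRR_ANCHOR_SET))]
        units.append("".join(unit))
    return "".join(units)


def _blocks_for_label(class_label: str) -> list[str]:
    if class_label in FULL_LENGTH_BLOCKS:
        return list(FULL_LENGTH_BLOCKS[class_label])
    tokens = class_label.split("-")
    for t in tokens:
        if t not in ("CC", "TIR", "RPW8", "NB", "LRR"):
            raise SynthError(f"unknown domain token {t!r} in class {class_label!r}")
    return tokens


def _mutate(
    protein: list[str],
    lrr_span: tuple[int, int] | None,
    n_mut: int,
    rng: np.random.Generator,
) -> None:
    """In-place substitutions; inside the LRR array the hydrophobic
    periodicity is preserved (anchors stay hydrophobic, other positions stay
    non-hydrophobic) so that divergence does not erase the repeat signal."""
    L = len(protein)
    positions = rng.choice(L, size=min(n_mut, L), replace=False)
    for p in positions:
        cur = protein[p]
        if lrr_span and lrr_span[0] <= p < lrr_span[1]:
            off = (p - lrr_span[0]) % 8
            pool = _LRR_ANCHOR_SET if off in domains.LRR_ANCHORS else _LRR_OTHER_SET
        else:
            pool = AA
        choices = [a for a in pool if a != cur]
        protein[p] = choices[rng.integers(len(choices))]


def generate_rgene(
    class_label: str,
    identity: float,
    rng: np.random.Generator,
    library: ProfileLibrary | None = None,
    lrr_units: int = 12,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Build an R-protein of the requested class at a target identity.

    The protein is assembled from the bundled domain-consensus blocks (NB is
    200 residues, matching the average NB domain length) joined by short
    linkers, then mutated to ``identity``. The result is verified closed-loop:
    the package's own detectors must classify it as ``class_label`` (a few
    retries with fresh substitutions; unreachable identities raise).

    Returns (protein, domain truth) with block coordinates per domain kind.
    """
    if not (0.5 < identity <= 1.0):
        raise SynthError("identity must be in (0.5, 1]")
    lib = library or _default_library()
    blocks = _blocks_for_label(class_label)
    last_err = None
    for _attempt in range(8):
        parts: list[str] = [_rand_from(_LINKER_SET, int(rng.integers(8, 14)), rng)]
        truth: dict[str, tuple[int, int]] = {}
        pos = len(parts[0])
        for bi, kind in enumerate(blocks):
            if kind == "LRR":
                block = lrr_block(lrr_units, rng)
            elif kind == "CC":
                block = lib["CC_RXN"].consensus
            else:
                block = lib[kind].consensus
            truth[kind] = (pos, pos + len(block))
            parts.append(block)
            pos += len(block)
            if bi < len(blocks) - 1:
                linker = _rand_from(_LINKER_SET, int(rng.integers(15, 26)), rng)
                parts.append(linker)
                pos += len(linker)
        parts.append(_rand_from(_LINKER_SET, int(rng.integers(8, 14)), rng))
        protein = list("".join(parts))
        n_mut = int(round(len(protein) * (1.0 - identity)))
        _mutate(protein, truth.get("LRR"), n_mut, rng)
        seq = "".join(protein)
        arch = domains.annotate_protein(seq, lib)
        if arch.class_label == class_label:
            return seq, truth
        last_err = arch.class_label
    raise SynthError(
        f"could not generate class {class_label!r} at identity {identity}"
        f" (last classification: {last_err!r})"
    )


def weaken_nb(
    protein: str,
    nb_span: tuple[int, int],
    rng: np.random.Generator,
    library: ProfileLibrary | None = None,
    target_fraction: float = 0.9,
) -> str:
    """Degrade the NB region until its best profile score drops below
    ``target_fraction`` x threshold, mutating only the C-terminal half of the
    NB block so that motif content in the N-terminal half stays intact."""
    lib = library or _default_library()
    nb = lib["NB"]
    target = target_fraction * nb.threshold
    s, e = nb_span
    half = (s + e) // 2
    prot = list(protein)
    candidates = list(range(half, e))
    rng.shuffle(candidates)
    for p in candidates:
        scores = domains.window_scores("".join(prot), nb.matrix)
        if len(scores) == 0 or scores.max() <= target:
            break
        cur = prot[p]
        choices = [a for a in AA if a != cur]
        prot[p] = choices[rng.integers(len(choices))]
    return "".join(prot)


_LIBRARY: ProfileLibrary | None = None


def _default_library() -> ProfileLibrary:
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = ProfileLibrary.bundled()
    return _LIBRARY


def encode_gene(
    protein: str,
    rng: np.random.Generator,
    n_introns: int = 0,
    intron_length: tuple[int, int] = (40, 2000),
) -> tuple[str, list[tuple[int, int]]]:
    """Encode a protein as a gene sequence with phase-0 GT...AG introns.

    Returns (gene_dna, exons) with exon coordinates local to the gene
    sequence. The CDS uses random synonymous codons plus a TAA stop; introns
    are inserted between codons.
    """
    codons = [
        _CODONS[a][rng.integers(len(_CODONS[a]))] if a in _CODONS else "NNN"
        for a in protein
    ]
    codons.append("TAA")
    n_codons = len(codons)
    n_introns = min(n_introns, n_codons - 2)
    sites = sorted(rng.choice(np.arange(1, n_codons), size=n_introns, replace=False))
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    prev = 0
    for site in list(sites) + [n_codons]:
        exon_seq = "".join(codons[prev:site])
        exons.append((pos, pos + len(exon_seq)))
        parts.append(exon_seq)
        pos += len(exon_seq)
        if site < n_codons:
            ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
            intron = "GT" + _rand_from("ACGT", max(0, ilen - 4), rng) + "AG"
            parts.append(intron)
            pos += len(intron)
        prev = site
    return "".join(parts), exons


@dataclass
class GenomeSpec:
    """Study conditions for one synthetic benchmark genome.

    Defaults describe the standard benchmark: a 500-kb assembly carrying 30
    clustered full-length NB-LRR genes (class mix dominated by CNL, as in
    real repertoires), TE-like decoy ORFs, ordinary background genes, and a
    defective annotation with 10 omitted genes, one fused pair and one split
    gene.
    """

    length: int = 500_000
    classes: list[str] = field(
        default_factory=lambda: ["CNL"] * 23 + ["TNL"] * 5 + ["RNL"] + ["NL"]
    )
    identity_range: tuple[float, float] = (0.82, 0.95)
    cluster_size_range: tuple[int, int] = (1, 4)
    cluster_gap_range: tuple[int, int] = (1000, 5000)
    locus_gap_range: tuple[int, int] = (3000, 8000)
    introns_per_gene: tuple[int, int] = (1, 3)
    intron_length: tuple[int, int] = (40, 2000)
    n_te_decoys: int = 8
    n_background_genes: int = 25
    n_omitted: int = 10
    n_fused: int = 1
    n_split: int = 1
    n_weakened: int = 0
    seqid: str = "chr_syn"

    @classmethod
    def from_yaml(cls, path) -> "GenomeSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        spec = cls()
        for key, value in data.items():
            if not hasattr(spec, key):
                raise SynthError(f"unknown genome spec field {key!r}")
            default = getattr(spec, key)
            if isinstance(default, tuple):
                value = tuple(value)
            setattr(spec, key, value)
        return spec


@dataclass
class SyntheticTruth:
    """A generated genome with its truth and defective annotations."""

    genome: SeqRecord
    truth_models: list[GeneModel]
    defective_annotation: list[GeneModel]
    defect_log: list[tuple[str, str]]  # (gene id, omitted|fused|split|weakened)
    seed: int
    clusters: list[list[str]] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, GeneModel]:
        return {m.id: m for m in self.truth_models}

    def proteome(self) -> list[SeqRecord]:
        out = []
        for m in self.defective_annotation:
            if m.protein:
                out.append(SeqRecord(id=m.id, seq=m.protein, kind="protein"))
        return out

    def rgene_ids(self) -> list[str]:
        return [m.id for m in self.truth_models if m.id.startswith("rgene")]

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out / "genome.fa")
        write_fasta(self.proteome(), out / "proteome.faa")
        write_gff3(self.truth_models, out / "truth.gff3", source="synthetic_truth")
        write_gff3(
            self.defective_annotation, out / "defective.gff3", source="synthetic_auto"
        )
        with open(out / "defects.tsv", "w") as fh:
            fh.write("gene_id\tdefect\n")
            for gid, defect in self.defect_log:
                fh.write(f"{gid}\t{defect}\n")


def _implant(
    model_id: str,
    gene_dna: str,
    local_exons: list[tuple[int, int]],
    offset: int,
    strand: str,
    seqid: str,
) -> GeneModel:
    Lg = len(gene_dna)
    if strand == "+":
        exons = [(offset + s, offset + e) for s, e in local_exons]
    else:
        exons = sorted((offset + Lg - e, offset + Lg - s) for s, e in local_exons)
    return GeneModel(id=model_id, seqid=seqid, strand=strand, exons=exons, source="synthetic")


def generate_genome_with_truth(
    spec: GenomeSpec, rng: np.random.Generator | int
) -> SyntheticTruth:
    """Generate a genome, its truth annotation, and a defective annotation.

    Genes are implanted at non-overlapping loci; cluster members sit 1-5 kb
    apart on the chromosome. TE decoys are intronless random ORFs verified
    not to classify as full-length NB-LRRs. The defective annotation is the
    truth minus omitted R-genes, with the requested fused/split models and
    proteins re-translated from the genome.
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    lib = _default_library()
    from .seqio import revcomp

    # --- build gene payloads -------------------------------------------------
    payloads: list[tuple[str, str, list[tuple[int, int]], str, str]] = []
    # (id, gene_dna, local_exons, strand, kind)
    weakened_ids: list[str] = []
    n_weakened = min(spec.n_weakened, len(spec.classes))
    for gi, cls in enumerate(spec.classes):
        ident = float(rng.uniform(*spec.identity_range))
        protein, truth_spans = generate_rgene(cls, ident, rng, lib)
        gid = f"rgene_{gi + 1:03d}"
        if gi < n_weakened and "NB" in truth_spans:
            protein = weaken_nb(protein, truth_spans["NB"], rng, lib)
            weakened_ids.append(gid)
        n_int = int(rng.integers(spec.introns_per_gene[0], spec.introns_per_gene[1] + 1))
        dna, exons = encode_gene(protein, rng, n_int, spec.intron_length)
        strand = "+" if rng.random() < 0.5 else "-"
        payloads.append((gid, dna, exons, strand, "rgene"))

    for ti in range(spec.n_te_decoys):
        for _ in range(5):
            prot = _rand_from(AA, int(rng.integers(250, 351)), rng)
            if not domains.annotate_protein(prot, lib).full_length:
                break
        dna, exons = encode_gene(prot, rng, 0)
        strand = "+" if rng.random() < 0.5 else "-"
        payloads.append((f"te_{ti + 1:03d}", dna, exons, strand, "te"))

    for bi in range(spec.n_background_genes):
        prot = _rand_from(AA, int(rng.integers(150, 401)), rng)
        n_int = int(rng.integers(0, 3))
        dna, exons = encode_gene(prot, rng, n_int, (40, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        payloads.append((f"bg_{bi + 1:03d}", dna, exons, strand, "bg"))

    # --- cluster structure over R-genes -------------------------------------
    r_indices = [i for i, p in enumerate(payloads) if p[4] == "rgene"]
    clusters: list[list[int]] = []
    i = 0
    while i < len(r_indices):
        size = int(rng.integers(spec.cluster_size_range[0], spec.cluster_size_range[1] + 1))
        clusters.append(r_indices[i : i + size])
        i += size

    # fused defects need same-strand adjacent cluster members: merge
    # singleton clusters and align strands where required
    if spec.n_fused > 0:
        need = spec.n_fused - sum(1 for c in clusters if len(c) >= 2)
        while need > 0:
            singles = [ci for ci, c in enumerate(clusters) if len(c) == 1]
            if len(singles) < 2:
                break
            clusters[singles[0]].extend(clusters[singles[1]])
            del clusters[singles[1]]
            need -= 1
        weakened_payload = set(range(n_weakened))
        forced = 0
        for c in clusters:
            if forced >= spec.n_fused:
                break
            pair = next(
                (
                    (a, b)
                    for a, b in zip(c, c[1:])
                    if a not in weakened_payload and b not in weakened_payload
                ),
                None,
            )
            if pair is None:
                continue
            a, b = pair
            if payloads[a][3] != payloads[b][3]:
                gid, dna, exons, _, kind = payloads[b]
                payloads[b] = (gid, dna, exons, payloads[a][3], kind)
            forced += 1
    other_indices = [i for i, p in enumerate(payloads) if p[4] != "rgene"]
    rng.shuffle(other_indices)

    # lay out: alternate clusters and single non-R loci along the chromosome
    layout_units: list[list[int]] = [list(c) for c in clusters]
    for oi in other_indices:
        layout_units.insert(int(rng.integers(0, len(layout_units) + 1)), [oi])

    chunks: list[str] = []
    pos = 0
    placements: dict[int, int] = {}
    for unit in layout_units:
        gap = int(rng.integers(*spec.locus_gap_range))
        chunks.append(_rand_from("ACGT", gap, rng))
        pos += gap
        for k, pi in enumerate(unit):
            if k > 0:
                cgap = int(rng.integers(*spec.cluster_gap_range))
                chunks.append(_rand_from("ACGT", cgap, rng))
                pos += cgap
            placements[pi] = pos
            dna = payloads[pi][1]
            # genes on the minus strand are implanted reverse-complemented
            chunks.append(revcomp(dna) if payloads[pi][3] == "-" else dna)
            pos += len(dna)
    tail = spec.length - pos
    if tail < 0:
        raise SynthError(
            f"genome spec infeasible: loci need {pos} bp > length {spec.length}"
        )
    chunks.append(_rand_from("ACGT", tail, rng))
    genome_seq = "".join(chunks)
    if len(genome_seq) != spec.length:
        raise SynthError("internal layout error")

    genome = SeqRecord(id=spec.seqid, seq=genome_seq, kind="dna")

    truth_models: list[GeneModel] = []
    for pi, (gid, dna, local_exons, strand, kind) in enumerate(payloads):
        model = _implant(gid, dna, local_exons, placements[pi], strand, spec.seqid)
        extract_and_translate(model, genome)
        truth_models.append(model)
    truth_models.sort(key=lambda m: m.start)

    # --- defective annotation ------------------------------------------------
    by_id = {m.id: m for m in truth_models}
    defect_log: list[tuple[str, str]] = [(gid, "weakened") for gid in weakened_ids]
    id_clusters = [[payloads[pi][0] for pi in c] for c in clusters]

    # choose fused pairs: same-strand adjacent cluster members
    fused_pairs: list[tuple[str, str]] = []
    for cl in id_clusters:
        if len(fused_pairs) >= spec.n_fused:
            break
        for a, b in zip(cl, cl[1:]):
            if by_id[a].strand == by_id[b].strand and a not in weakened_ids and b not in weakened_ids:
                fused_pairs.append((a, b))
                break
    if len(fused_pairs) < spec.n_fused:
        raise SynthError("not enough same-strand adjacent pairs for fused defects")
    fused_ids = {g for pair in fused_pairs for g in pair}

    # choose split genes: multi-exon R-genes not otherwise touched
    split_ids: list[str] = []
    for m in truth_models:
        if len(split_ids) >= spec.n_split:
            break
        if (
            m.id.startswith("rgene")
            and len(m.exons) >= 2
            and m.id not in fused_ids
            and m.id not in weakened_ids
        ):
            split_ids.append(m.id)
    if len(split_ids) < spec.n_split:
        raise SynthError("not enough multi-exon genes for split defects")

    # choose omitted genes among the remaining R-genes
    protected = fused_ids | set(split_ids) | set(weakened_ids)
    omit_pool = [m.id for m in truth_models if m.id.startswith("rgene") and m.id not in protected]
    if len(omit_pool) < spec.n_omitted:
        raise SynthError("not enough R-genes available for omission defects")
    omitted = set(
        str(x) for x in rng.choice(omit_pool, size=spec.n_omitted, replace=False)
    )

    defective: list[GeneModel] = []
    handled: set[str] = set(omitted)
    for gid in omitted:
        defect_log.append((gid, "omitted"))
    for a, b in fused_pairs:
        ma, mb = by_id[a], by_id[b]
        lo, hi = (ma, mb) if ma.start <= mb.start else (mb, ma)
        fused = GeneModel(
            id=f"{a}_fused",
            seqid=ma.seqid,
            strand=ma.strand,
            exons=lo.exons + hi.exons,
            source="synthetic_auto",
        )
        defective.append(fused)
        handled.update((a, b))
        defect_log.append((a, "fused"))
        defect_log.append((b, "fused"))
    for gid in split_ids:
        m = by_id[gid]
        cut = len(m.exons) // 2
        for part, exs in (("a", m.exons[:cut]), ("b", m.exons[cut:])):
            defective.append(
                GeneModel(
                    id=f"{gid}_split{part}",
                    seqid=m.seqid,
                    strand=m.strand,
                    exons=list(exs),
                    source="synthetic_auto",
                )
            )
        handled.add(gid)
        defect_log.append((gid, "split"))
    for m in truth_models:
        if m.id in handled:
            continue
        defective.append(
            GeneModel(
                id=m.id,
                seqid=m.seqid,
                strand=m.strand,
                exons=list(m.exons),
                phases=list(m.phases),
                source="synthetic_auto",
            )
        )
    for m in defective:
        extract_and_translate(m, genome)
    defective.sort(key=lambda m: m.start)

    return SyntheticTruth(
        genome=genome,
        truth_models=truth_models,
        defective_annotation=defective,
        defect_log=sorted(defect_log),
        seed=seed,
        clusters=id_clusters,
    )
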