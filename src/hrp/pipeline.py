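"""The double-pass NB-LRR annotation pipeline.

Pass 1 (PDS, protein domain search) scans the predicted proteome with the
bundled domain detectors, classifies every protein, and extracts the
nucleotide-binding (NB) domain regions of full-length NB-LRRs. Those NB
regions are decomposed into short motifs (EM discovery, up to 19 motifs of
width 4-7), and the motif set is used to rescue proteome entries whose
domain evidence fell below the profile thresholds but whose motif content
is intact.

Pass 2 uses every full-length protein from pass 1 as a query for spliced
homology prediction directly on the genome assembly. Predicted models are
filtered by the maximum gene span (default 20 kb, strictly greater dropped)
and by strand-aware overlap clustering that keeps the model encoding the
longest protein. Surviving models are re-translated, re-annotated with the
domain detectors, classified and flagged as pseudogenes when their coding
sequence contains internal stops or a frameshift.

Any pass-1 locus (full-length, partial or motif-rescued) that pass 2 did
not re-model is carried into the output unchanged, so the homology pass can
re-model but never silently drop a pass-1 locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import domains, genehom, motifs as motifs_mod
from .domains import DomainArchitecture, ProfileLibrary
from .genehom import GeneCandidate, GeneHomConfig, GenomeIndex
from .seqio import (
    GeneModel,
    SeqRecord,
    extract_and_translate,
    write_fasta,
    write_gff3,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable thresholds of the double-pass procedure."""

    n_motifs: int = 19
    min_w: int = 4
    max_w: int = 7
    rescue_min_motifs: int = 3
    rescue_max_pvalue: float = 1e-5
    rescue_max_evalue: float = 10.0
    min_lrr_repeats: int = 3
    max_aligns_per_region: int = 6
    max_chains_per_query_region: int = 2
    rbh_confidence_threshold: float = 1.0
    seed: int = 0
    genehom: GeneHomConfig = field(default_factory=GeneHomConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        gh = data.pop("genehom", {})
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise PipelineError("config", f"unknown config field {k!r}")
            setattr(cfg, k, v)
        for k, v in gh.items():
            if not hasattr(cfg.genehom, k):
                raise PipelineError("config", f"unknown genehom config field {k!r}")
            setattr(cfg.genehom, k, v)
        return cfg


@dataclass
class ReportRecord:
    id: str
    seqid: str
    start: int
    end: int
    strand: str
    class_label: str
    full_length: bool
    pseudogene: bool
    provenance: str  # PDS | motif-rescue | homology-pass


@dataclass
class AnnotationReport:
    """Per-gene records plus the class-count summary (Table-1-style layout:
    full-length classes first, then partial labels, plus pseudogene count)."""

    records: list[ReportRecord]

    FULL_CLASSES = ("CNL", "TNL", "RNL", "NL")

    @property
    def full_length_counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.FULL_CLASSES}
        for r in self.records:
            if r.full_length:
                out[r.class_label] += 1
        return out

    @property
    def partial_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if not r.full_length:
                out[r.class_label] = out.get(r.class_label, 0) + 1
        return dict(sorted(out.items()))

    @property
    def pseudogene_count(self) -> int:
        return sum(1 for r in self.records if r.pseudogene)

    def summary(self) -> dict:
        full = self.full_length_counts
        return {
            "full_length": full,
            "total_full_length": sum(full.values()),
            "partial": self.partial_counts,
            "total_partial": sum(self.partial_counts.values()),
            "pseudogenes": self.pseudogene_count,
            "total": len(self.records),
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tseqid\tstart\tend\tstrand\tclass\tfull_length\tpseudogene\tprovenance\n")
            for r in self.records:
                fh.write(
                    f"{r.id}\t{r.seqid}\t{r.start}\t{r.end}\t{r.strand}\t"
                    f"{r.class_label}\t{int(r.full_length)}\t{int(r.pseudogene)}\t{r.provenance}\n"
                )

    def to_json(self, path) -> None:
        data = {
            "summary": self.summary(),
            "genes": [vars(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class HRPResult:
    report: AnnotationReport
    models: list[GeneModel]
    motifs: list[motifs_mod.MotifModel]
    rescued_ids: list[str]
    pass1_full: dict[str, DomainArchitecture]
    pass1_partial: dict[str, DomainArchitecture]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff3(self.models, out / "hrp.gff3", source="HRP")
        proteins = [
            SeqRecord(id=m.id, seq=m.protein, kind="protein")
            for m in self.models
            if m.protein
        ]
        write_fasta(proteins, out / "hrp_proteins.faa")
        self.report.to_tsv(out / "report.tsv")
        self.report.to_json(out / "report.json")
        if self.motifs:
            motifs_mod.write_meme(self.motifs, out / "motifs.meme.txt")


def pass1_pds(
    proteome: list[SeqRecord],
    library: ProfileLibrary,
    config: PipelineConfig,
) -> tuple[dict[str, DomainArchitecture], dict[str, DomainArchitecture], dict[str, str]]:
    """Scan and classify every proteome entry; extract NB regions.

    Returns (full-length architectures by id, partial architectures by id,
    NB-domain subsequences of full-length proteins by id). Proteins with no
    detected domain are absent from both dictionaries.
    """
    full: dict[str, DomainArchitecture] = {}
    partial: dict[str, DomainArchitecture] = {}
    nb_seqs: dict[str, str] = {}
    for rec in proteome:
        arch = domains.annotate_protein(
            rec.seq, library, min_lrr_repeats=config.min_lrr_repeats
        )
        if arch.full_length:
            full[rec.id] = arch
            nb_hits = [h for h in arch.hits if h.kind == "NB"]
            if nb_hits:
                h = nb_hits[0]
                nb_seqs[rec.id] = rec.seq[h.start : h.end]
        elif arch.class_label != "none":
            partial[rec.id] = arch
    return full, partial, nb_seqs


def motif_rescue(
    proteome: list[SeqRecord],
    motifs: list[motifs_mod.MotifModel],
    already_found: set[str],
    config: PipelineConfig,
) -> dict[str, dict[int, float]]:
    """Proteins outside ``already_found`` whose motif content satisfies the
    rescue rule: at least ``rescue_min_motifs`` distinct motifs with best-hit
    p-value below ``rescue_max_pvalue`` and a combined E-value (QFAST over
    the per-motif best p-values, scaled by the proteome size) at most
    ``rescue_max_evalue``. Returns the per-motif best p-values as evidence.
    """
    if not motifs:
        return {}
    n_db = len(proteome)
    rescued: dict[str, dict[int, float]] = {}
    for rec in proteome:
        if rec.id in already_found:
            continue
        if len(rec.seq) < max(m.width for m in motifs):
            continue
        best = motifs_mod.best_hit_pvalues(rec.seq, motifs, rec.id)
        strong = {mid: p for mid, p in best.items() if p < config.rescue_max_pvalue}
        if len(strong) < config.rescue_min_motifs:
            continue
        _, evalue = motifs_mod.combined_evalue(list(best.values()), n_db)
        if evalue <= config.rescue_max_evalue:
            rescued[rec.id] = strong
    return rescued


def filter_models(
    candidates: list[GeneCandidate], config: PipelineConfig
) -> list[GeneCandidate]:
    """Apply the span filter, then strand-aware overlap resolution.

    Models spanning strictly more than ``max_span`` bp are dropped. Remaining
    same-strand models overlapping by >= 1 bp are clustered single-linkage;
    each cluster keeps the model encoding the longest protein (ties: higher
    alignment score, then smaller start). Opposite-strand overlaps are kept.
    """
    max_span = config.genehom.max_span
    kept = [c for c in candidates if c.model.span <= max_span]
    out: list[GeneCandidate] = []
    by_group: dict[tuple[str, str], list[GeneCandidate]] = {}
    for c in kept:
        by_group.setdefault((c.model.seqid, c.model.strand), []).append(c)
    for group in by_group.values():
        group.sort(key=lambda c: c.model.start)
        cluster: list[GeneCandidate] = []
        cluster_end = -1
        for c in group + [None]:
            if c is not None and (not cluster or c.model.start < cluster_end):
                cluster.append(c)
                cluster_end = max(cluster_end, c.model.end)
                continue
            if cluster:
                best = max(
                    cluster,
                    key=lambda x: (
                        len(x.model.protein or ""),
                        x.score,
                        -x.model.start,
                    ),
                )
                out.append(best)
            if c is not None:
                cluster = [c]
                cluster_end = c.model.end
    out.sort(key=lambda c: (c.model.seqid, c.model.start))
    return out


def _covered(model: GeneModel, accepted: list[GeneModel]) -> bool:
    return any(
        a.seqid == model.seqid
        and a.strand == model.strand
        and a.start < model.end
        and model.start < a.end
        for a in accepted
    )


def _select_chains(
    tagged_chains: list[tuple[str, genehom.Chain]], config: PipelineConfig
) -> list[tuple[str, genehom.Chain]]:
    """Pick the chains worth spliced-aligning, best-first.

    A chain is skipped when enough higher-scoring chains overlapping its
    footprint (same strand) were already accepted, or when its query already
    holds its per-locus quota there. Counting overlaps against individual
    accepted footprints (rather than merged regions) keeps a low-scoring
    chain that straddles two gene loci from welding them together."""
    tagged = sorted(tagged_chains, key=lambda t: (-t[1].score, t[0]))
    accepted: dict[str, list[tuple[int, int, str]]] = {"+": [], "-": []}
    selected: list[tuple[str, genehom.Chain]] = []
    for qid, chain in tagged:
        lo, hi = chain.s_min, chain.s_max
        overlapping = [
            (alo, ahi, aqid)
            for alo, ahi, aqid in accepted[chain.strand]
            if lo < ahi and alo < hi
        ]
        if len(overlapping) >= config.max_aligns_per_region:
            continue
        if sum(1 for _, _, aqid in overlapping if aqid == qid) >= config.max_chains_per_query_region:
            continue
        accepted[chain.strand].append((lo, hi, qid))
        selected.append((qid, chain))
    return selected


def homology_pass(
    queries: dict[str, str],
    genome: SeqRecord,
    config: PipelineConfig,
) -> list[GeneCandidate]:
    """Run seeding and chaining for every query, pool chains across queries,
    spliced-align the best chains per genomic region, and E-filter."""
    gcfg = config.genehom
    index = GenomeIndex(genome, k=gcfg.k)
    tagged: list[tuple[str, genehom.Chain]] = []
    for qid, qseq in sorted(queries.items()):
        hsps = genehom.seed_and_extend(qseq, genome, gcfg, index=index)
        for chain in genehom.chain_hsps(
            hsps, gcfg.max_span, gcfg.max_intron, gcfg.intron_open, gcfg.intron_per_nt
        ):
            tagged.append((qid, chain))
    selected = _select_chains(tagged, config)
    candidates: list[GeneCandidate] = []
    serial = 0
    for qid, chain in selected:
        serial += 1
        cand = genehom.candidate_from_chain(
            qid, queries[qid], genome, chain, gcfg, f"HRP_{serial:04d}"
        )
        if cand is not None and cand.evalue <= gcfg.evalue_cutoff:
            candidates.append(cand)
    return candidates


def _annotate_models(
    models: list[GeneModel],
    genome: SeqRecord,
    library: ProfileLibrary,
    config: PipelineConfig,
) -> None:
    for m in models:
        if m.protein is None:
            extract_and_translate(m, genome)
        arch = domains.annotate_protein(
            m.protein, library, min_lrr_repeats=config.min_lrr_repeats
        )
        m.class_label = arch.class_label


def run_hrp(
    genome: SeqRecord,
    proteome: list[SeqRecord],
    annotation: list[GeneModel],
    config: PipelineConfig | None = None,
    library: ProfileLibrary | None = None,
) -> HRPResult:
    """The full double-pass procedure on one assembly.

    ``annotation`` is the automated gene annotation whose proteome is being
    scanned; its models provide the genomic loci of pass-1 hits. Returns the
    report plus the final, mutually non-overlapping (per strand) model set.
    """
    config = config or PipelineConfig()
    library = library or domains.ProfileLibrary.bundled()
    ann_by_id = {m.id: m for m in annotation}

    try:
        full, partial, nb_seqs = pass1_pds(proteome, library, config)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("pass1-pds", str(exc)) from exc

    discovered: list[motifs_mod.MotifModel] = []
    if len(nb_seqs) >= 2:
        try:
            discovered = motifs_mod.discover_motifs(
                list(nb_seqs.values()),
                n_motifs=config.n_motifs,
                min_w=config.min_w,
                max_w=config.max_w,
                seed=config.seed,
            )
        except motifs_mod.MotifError as exc:
            raise PipelineError("motif-discovery", str(exc)) from exc

    try:
        rescued = motif_rescue(proteome, discovered, set(full), config)
    except Exception as exc:
        raise PipelineError("motif-rescue", str(exc)) from exc

    # Pass-2 queries are bona fide full-length R-proteins: pseudoprotein
    # translations carrying internal stops (e.g. two genes fused into one
    # model by the automated annotation) are kept as pass-1 loci but do not
    # seed the homology pass - their loci are re-modelled by clean queries.
    queries = {
        rec.id: rec.seq
        for rec in proteome
        if rec.id in full and "*" not in rec.seq
    }
    try:
        candidates = homology_pass(queries, genome, config)
    except Exception as exc:
        raise PipelineError("homology-pass", str(exc)) from exc

    for c in candidates:
        extract_and_translate(c.model, genome)
    try:
        final_candidates = filter_models(candidates, config)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    models: list[GeneModel] = [c.model for c in final_candidates]
    for c in final_candidates:
        c.model.provenance = "homology-pass"

    # Reconciliation: pass-1 loci not re-modelled by pass 2 are carried over.
    carried: list[tuple[GeneModel, str]] = []
    for pid in sorted(full) + sorted(partial):
        ann = ann_by_id.get(pid)
        if ann is None:
            continue
        if not _covered(ann, models + [m for m, _ in carried]):
            carried.append((ann, "PDS"))
    for pid in sorted(rescued):
        ann = ann_by_id.get(pid)
        if ann is None:
            continue
        if not _covered(ann, models + [m for m, _ in carried]):
            carried.append((ann, "motif-rescue"))
    for ann, prov in carried:
        ann.provenance = prov
        models.append(ann)

    _annotate_models(models, genome, library, config)
    models.sort(key=lambda m: (m.seqid, m.start, m.id))

    records = [
        ReportRecord(
            id=m.id,
            seqid=m.seqid,
            start=m.start,
            end=m.end,
            strand=m.strand,
            class_label=m.class_label or "none",
            full_length=m.class_label in AnnotationReport.FULL_CLASSES,
            pseudogene=m.pseudogene,
            provenance=m.provenance or "homology-pass",
        )
        for m in models
    ]
    return HRPResult(
        report=AnnotationReport(records=records),
        models=models,
        motifs=discovered,
        rescued_ids=sorted(rescued),
        pass1_full=full,
        pass1_partial=partial,
    )


def mine_alleles(
    query: SeqRecord,
    genome: SeqRecord,
    config: PipelineConfig | None = None,
    library: ProfileLibrary | None = None,
) -> HRPResult:
    """Single-query allele mining: spliced homology prediction of one
    characterized R-protein against an assembly, with the same filtering and
    re-annotation as the full pipeline (no proteome pass)."""
    config = config or PipelineConfig()
    library = library or domains.ProfileLibrary.bundled()
    candidates = homology_pass({query.id: query.seq}, genome, config)
    for c in candidates:
        extract_and_translate(c.model, genome)
    final = filter_models(candidates, config)
    models = [c.model for c in final]
    for m in models:
        m.provenance = "homology-pass"
    _annotate_models(models, genome, library, config)
    models.sort(key=lambda m: (m.seqid, m.start, m.id))
    records = [
        ReportRecord(
            id=m.id, seqid=m.seqid, start=m.start, end=m.end, strand=m.strand,
            class_label=m.class_label or "none",
            full_length=m.class_label in AnnotationReport.FULL_CLASSES,
            pseudogene=m.pseudogene, provenance="homology-pass",
        )
        for m in models
    ]
    return HRPResult(
        report=AnnotationReport(records=records),
        models=models, motifs=[], rescued_ids=[], pass1_full={}, pass1_partial={},
    )
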