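"""Comparison of two gene-model sets and two proteomes.

``match_models`` pairs models from two annotations of the same assembly by
same-strand CDS overlap and reports, per pair, the shared-coding fraction
(shared coding bases over the union of coding bases) and whether the
intron-exon structures are identical. The aggregate shared-CDS percentage
over all matched pairs summarizes how similar two annotations are.

``rbh_pairs`` estimates gene-gene correspondences between two proteomes as
reciprocal best hits under ungapped BLOSUM62 scoring, with a normalized
confidence (best score divided by the self-score of the smaller protein).
This is a deliberate simplification of full ortholog clustering: the
external tool the confidence threshold of 1 refers to uses its own score
scale, so the normalized cutoff here is not numerically comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genehom import B62, encode_protein_b62, self_score
from .seqio import GeneModel, SeqRecord

# Fraction of the smaller protein's self-score required at the default
# confidence threshold of 1 (scaled linearly with the threshold).
RBH_BASE_CONFIDENCE = 0.25


@dataclass
class ModelMatch:
    id_a: str
    id_b: str
    overlap_bp: int
    cds_overlap_fraction: float
    structure_identical: bool


@dataclass
class ModelComparison:
    matches: list[ModelMatch]
    unmatched_a: list[str]
    unmatched_b: list[str]

    @property
    def aggregate_shared_cds_percent(self) -> float:
        """100 * total shared coding bases / total union coding bases over
        all matched pairs."""
        shared = sum(m.overlap_bp for m in self.matches)
        union = sum(
            round(m.overlap_bp / m.cds_overlap_fraction) for m in self.matches
        )
        return 100.0 * shared / union if union else 0.0

    @property
    def structure_identical_count(self) -> int:
        return sum(1 for m in self.matches if m.structure_identical)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\toverlap_bp\tcds_overlap_fraction\tstructure_identical\n")
            for m in self.matches:
                fh.write(
                    f"{m.id_a}\t{m.id_b}\t{m.overlap_bp}\t"
                    f"{m.cds_overlap_fraction:.4f}\t{int(m.structure_identical)}\n"
                )

    def summary(self) -> dict:
        return {
            "n_matches": len(self.matches),
            "structure_identical": self.structure_identical_count,
            "aggregate_shared_cds_percent": round(self.aggregate_shared_cds_percent, 2),
            "unmatched_a": len(self.unmatched_a),
            "unmatched_b": len(self.unmatched_b),
        }


def _interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def match_models(set_a: list[GeneModel], set_b: list[GeneModel]) -> ModelComparison:
    """Pair models with same seqid/strand and >= 1 bp CDS overlap.

    Both model sets must be on the same assembly coordinates. The shared
    fraction is computed on the union of the two models' coding bases;
    identical exon boundary sets imply fraction 1.0.
    """
    matches: list[ModelMatch] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for ma in set_a:
        for mb in set_b:
            if ma.seqid != mb.seqid or ma.strand != mb.strand:
                continue
            shared = _interval_overlap(ma.exons, mb.exons)
            if shared < 1:
                continue
            union = ma.cds_length + mb.cds_length - shared
            matches.append(
                ModelMatch(
                    id_a=ma.id,
                    id_b=mb.id,
                    overlap_bp=shared,
                    cds_overlap_fraction=shared / union,
                    structure_identical=ma.exons == mb.exons,
                )
            )
            matched_a.add(ma.id)
            matched_b.add(mb.id)
    return ModelComparison(
        matches=matches,
        unmatched_a=[m.id for m in set_a if m.id not in matched_a],
        unmatched_b=[m.id for m in set_b if m.id not in matched_b],
    )


def best_ungapped_score(a: str, b: str) -> int:
    """Best ungapped local alignment score between two proteins (maximum
    positive-sum segment over every diagonal of the BLOSUM62 score matrix)."""
    ea, eb = encode_protein_b62(a), encode_protein_b62(b)
    best = 0
    la, lb = len(ea), len(eb)
    for diag in range(-(la - 1), lb):
        if diag >= 0:
            qa, qb = ea[: lb - diag], eb[diag:][: la]
        else:
            qa, qb = ea[-diag:][:lb], eb[: la + diag]
        n = min(len(qa), len(qb))
        if n == 0:
            continue
        scores = B62[qa[:n], qb[:n]].astype(np.int64)
        # maximum subarray: best segment ending at k is c[k] - min prefix
        c = np.cumsum(scores)
        prev_min = np.minimum.accumulate(np.concatenate(([0], c[:-1])))
        diag_best = int((c - prev_min).max())
        if diag_best > best:
            best = diag_best
    return best


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    score: int
    confidence: float


def rbh_pairs(
    proteome_a: list[SeqRecord],
    proteome_b: list[SeqRecord],
    confidence_threshold: float = 1.0,
) -> list[OrthologPair]:
    """Reciprocal-best ortholog pairing under ungapped BLOSUM62 scoring.

    All-vs-all best ungapped scores; pairs that are mutual bests and whose
    confidence (score / self-score of the smaller protein) reaches
    ``RBH_BASE_CONFIDENCE * confidence_threshold`` are emitted.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("rbh_pairs requires two non-empty proteomes")
    cutoff = RBH_BASE_CONFIDENCE * confidence_threshold
    scores = np.zeros((len(proteome_a), len(proteome_b)), dtype=np.int64)
    for i, ra in enumerate(proteome_a):
        for j, rb in enumerate(proteome_b):
            scores[i, j] = best_ungapped_score(ra.seq, rb.seq)
    pairs: list[OrthologPair] = []
    best_for_a = scores.argmax(axis=1)
    best_for_b = scores.argmax(axis=0)
    for i, ra in enumerate(proteome_a):
        j = int(best_for_a[i])
        if int(best_for_b[j]) != i:
            continue
        rb = proteome_b[j]
        smaller = ra.seq if len(ra.seq) <= len(rb.seq) else rb.seq
        denom = self_score(smaller)
        conf = scores[i, j] / denom if denom > 0 else 0.0
        if conf >= cutoff:
            pairs.append(
                OrthologPair(id_a=ra.id, id_b=rb.id, score=int(scores[i, j]), confidence=float(conf))
            )
    return pairs
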