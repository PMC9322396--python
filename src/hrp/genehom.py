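"""Full-length homology gene prediction on genomic DNA.

The homology pass turns a full-length R-protein query into gene models
directly on the assembly, in three stages:

1. ``seed_and_extend`` — exact amino-acid k-mer matches between the query
   and all six translated reading frames seed ungapped extensions under
   BLOSUM62 with X-drop termination, yielding HSPs (high-scoring segment
   pairs) in genomic coordinates.
2. ``chain_hsps`` — colinear same-strand HSPs are chained by dynamic
   programming (subject gaps bounded by the maximum intron length, chain
   footprints bounded by the maximum gene span).
3. ``spliced_align`` — codon-aware local alignment of the query against a
   genomic window around each chain, with introns permitted only between
   codons at canonical GT...AG boundaries, producing an exon-resolved
   :class:`~hrp.seqio.GeneModel`.

Candidate significance uses Karlin-Altschul statistics for ungapped
BLOSUM62 scoring, E = K * m * n * exp(-lambda * S); candidates above the
E-value cutoff (default 0.01) are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import GeneModel, SeqRecord, revcomp

_B62 = substitution_matrices.load("BLOSUM62")
B62_ALPHABET = str(_B62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
B62_INDEX = {a: i for i, a in enumerate(B62_ALPHABET)}
B62 = np.array(_B62, dtype=np.int64)
_X = B62_INDEX["X"]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# codon (5-ary) -> index into the BLOSUM62 alphabet of the encoded residue
_CODON_AA = np.full(125, _X, dtype=np.int64)
for _i, _a in enumerate("ACGT"):
    for _j, _b in enumerate("ACGT"):
        for _k, _c in enumerate("ACGT"):
            _aa = str(Seq(_a + _b + _c).translate())
            _CODON_AA[_i * 25 + _j * 5 + _k] = B62_INDEX.get(_aa, _X)


def encode_protein_b62(protein: str) -> np.ndarray:
    return np.array([B62_INDEX.get(a, _X) for a in protein], dtype=np.int64)


def encode_dna(dna: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c, 4) for c in dna], dtype=np.int64)


def self_score(protein: str) -> int:
    e = encode_protein_b62(protein)
    return int(B62[e, e].sum())


@dataclass
class KarlinParams:
    """Ungapped BLOSUM62 Karlin-Altschul parameters (raw-score units)."""

    lam: float = 0.3176
    K: float = 0.134

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


@dataclass
class HSP:
    """Ungapped translated alignment segment.

    ``q_start/q_end`` are protein coordinates on the query; ``s_start/s_end``
    are genomic nucleotide coordinates on the forward strand (0-based
    half-open); ``s_end - s_start == 3 * (q_end - q_start)``.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: int
    score: int

    def diagonal(self) -> tuple[str, int, int]:
        return (self.strand, self.frame, self.q_start * 3 - (self.s_start if self.strand == "+" else -self.s_end))


@dataclass
class Chain:
    hsps: list[HSP]
    score: float
    strand: str

    @property
    def s_min(self) -> int:
        return min(h.s_start for h in self.hsps)

    @property
    def s_max(self) -> int:
        return max(h.s_end for h in self.hsps)

    @property
    def footprint(self) -> int:
        return self.s_max - self.s_min


@dataclass
class GeneCandidate:
    query_id: str
    model: GeneModel
    score: int  # protein-level alignment score (intron costs excluded)
    path_score: float  # DP score including intron costs (drives the E-value)
    evalue: float
    n_introns: int
    chain: Chain | None = None


@dataclass
class GeneHomConfig:
    k: int = 4
    xdrop: int = 20
    min_hsp_score: int = 50
    # Hard bound on intron length in both chaining and spliced alignment.
    # A jump from one gene onto an adjacent paralog must traverse at least
    # one gene body plus the intergenic gap, so a cap modestly above the
    # realistic intron range excludes such chimeric joins structurally.
    max_intron: int = 2200
    min_intron: int = 40
    max_span: int = 20000
    gap_open: int = 11
    gap_extend: int = 1
    # Intron cost in BLOSUM62 score units: open + per_nt * length (an exact
    # binary fraction so dynamic-programming scores stay exactly
    # representable). Kept shallow enough that a diverged exon is still
    # worth reaching across a long intron.
    intron_open: int = 15
    intron_per_nt: float = 1.0 / 64.0
    # Maximum window flank around a chain footprint for spliced alignment.
    # The flank actually used per side is adaptive: wide enough to reach
    # query residues the chain left uncovered (plus one intron), small when
    # the chain already spans the whole query.
    flank: int = 3000
    evalue_cutoff: float = 0.01
    max_chains_per_region: int = 3
    karlin: KarlinParams = field(default_factory=KarlinParams)


class GenomeIndex:
    """Six-frame translation plus amino-acid k-mer index of one sequence."""

    def __init__(self, genome: SeqRecord, k: int = 4):
        self.genome = genome
        self.k = k
        self.length = len(genome.seq)
        self.frames: list[tuple[str, int, str]] = []
        fwd = genome.seq
        rev = revcomp(fwd)
        for f in range(3):
            sub = fwd[f : f + (len(fwd) - f) // 3 * 3]
            self.frames.append(("+", f, str(Seq(sub).translate())))
        for f in range(3):
            sub = rev[f : f + (len(rev) - f) // 3 * 3]
            self.frames.append(("-", f, str(Seq(sub).translate())))
        self.kmer_positions: dict[str, list[tuple[int, int]]] = {}
        for fid, (_, _, aa) in enumerate(self.frames):
            for t in range(len(aa) - k + 1):
                self.kmer_positions.setdefault(aa[t : t + k], []).append((fid, t))

    def to_genome(self, fid: int, t_start: int, t_end: int) -> tuple[int, int, str, int]:
        """Map an aa interval on translated frame ``fid`` to forward-strand
        genomic nt coordinates."""
        strand, f, _ = self.frames[fid]
        if strand == "+":
            return f + 3 * t_start, f + 3 * t_end, "+", f
        L = self.length
        return L - f - 3 * t_end, L - f - 3 * t_start, "-", f


def _extend_ungapped(qv: list[int], tv: list[int], qs: int, ts: int, k: int,
                     xdrop: int) -> tuple[int, int, int]:
    """X-drop extension of a k-length seed at (qs, ts) in protein space.

    Returns (q_lo, q_hi, score) where [q_lo, q_hi) is the maximal-scoring
    extension span on the query (subject offset is on the same diagonal).
    """
    B = B62
    core = 0
    for i in range(k):
        core += B[qv[qs + i]][tv[ts + i]]
    # right
    best_r, run = 0, 0
    i = qs + k
    j = ts + k
    hi = qs + k
    nq, nt = len(qv), len(tv)
    while i < nq and j < nt:
        run += B[qv[i]][tv[j]]
        if run > best_r:
            best_r = run
            hi = i + 1
        elif best_r - run > xdrop:
            break
        i += 1
        j += 1
    # left
    best_l, run = 0, 0
    i = qs - 1
    j = ts - 1
    lo = qs
    while i >= 0 and j >= 0:
        run += B[qv[i]][tv[j]]
        if run > best_l:
            best_l = run
            lo = i
        elif best_l - run > xdrop:
            break
        i -= 1
        j -= 1
    return lo, hi, int(core + best_r + best_l)


def seed_and_extend(
    query: str,
    genome: SeqRecord,
    config: GeneHomConfig | None = None,
    index: GenomeIndex | None = None,
) -> list[HSP]:
    """Seed exact k-mer matches in all six frames and extend ungapped.

    HSPs scoring below ``min_hsp_score`` are discarded; on each diagonal,
    HSPs contained within an equal-or-higher-scoring HSP are merged away.
    """
    cfg = config or GeneHomConfig()
    if len(query) < cfg.k:
        return []
    if index is None or index.k != cfg.k:
        index = GenomeIndex(genome, k=cfg.k)
    qv = [B62_INDEX.get(a, _X) for a in query]

    # gather seeds per (frame, diagonal)
    seeds: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qs in range(len(query) - cfg.k + 1):
        kmer = query[qs : qs + cfg.k]
        for fid, t in index.kmer_positions.get(kmer, ()):
            seeds.setdefault((fid, qs - t), []).append((t, qs))

    frame_enc: dict[int, list[int]] = {}
    hsps: list[HSP] = []
    for (fid, _diag), positions in seeds.items():
        if fid not in frame_enc:
            frame_enc[fid] = [B62_INDEX.get(a, _X) for a in index.frames[fid][2]]
        tv = frame_enc[fid]
        positions.sort()
        covered_end = -1
        diag_hsps: list[tuple[int, int, int]] = []
        for t, qs in positions:
            if t < covered_end:
                continue
            lo, hi, score = _extend_ungapped(qv, tv, qs, t, cfg.k, cfg.xdrop)
            covered_end = t + (hi - qs)
            if score >= cfg.min_hsp_score:
                diag_hsps.append((lo, hi, score))
        # merge contained/duplicate segments on this diagonal
        diag_hsps.sort(key=lambda x: (-x[2], x[0]))
        kept: list[tuple[int, int, int]] = []
        for lo, hi, score in diag_hsps:
            if any(lo >= klo and hi <= khi for klo, khi, _ in kept):
                continue
            kept.append((lo, hi, score))
        t0 = positions[0][0] - positions[0][1]  # t - qs on this diagonal
        for lo, hi, score in kept:
            ts, te = lo + t0, hi + t0
            s_start, s_end, strand, frame = index.to_genome(fid, ts, te)
            hsps.append(
                HSP(q_start=lo, q_end=hi, s_start=s_start, s_end=s_end,
                    strand=strand, frame=frame, score=score)
            )
    hsps.sort(key=lambda h: (h.s_start, h.q_start, -h.score))
    return hsps


def _chain_compatible(a: HSP, b: HSP, max_intron: int) -> bool:
    """Can ``b`` follow ``a`` in a colinear chain (strand-aware)?"""
    if a.strand != b.strand:
        return False
    if not (b.q_start > a.q_start and b.q_end > a.q_end):
        return False
    if a.strand == "+":
        return (
            b.s_start > a.s_start and b.s_end > a.s_end
            and b.s_start - a.s_end <= max_intron
        )
    return (
        b.s_start < a.s_start and b.s_end < a.s_end
        and a.s_start - b.s_end <= max_intron
    )


def chain_hsps(
    hsps: list[HSP],
    max_span: int = 20000,
    max_intron: int = 10000,
    gap_open: float = 15.0,
    gap_per_nt: float = 1.0 / 64.0,
) -> list[Chain]:
    """Maximum-score colinear chains by DP, best-first extraction.

    Joins require consistent query and subject order, subject gaps at most
    ``max_intron``, and a chain footprint at most ``max_span`` (larger
    assemblies of HSPs are split into separate chains). Each join is charged
    ``gap_open + gap_per_nt * subject_gap`` (the aligner's intron cost
    shape), so a chain that hops a multi-kilobase intergenic gap to collect
    HSPs from an adjacent paralog scores below the pure single-gene chain.
    """
    chains: list[Chain] = []
    remaining = list(hsps)
    while remaining:
        order = sorted(
            range(len(remaining)),
            key=lambda i: (remaining[i].s_start if remaining[i].strand == "+"
                           else -remaining[i].s_end),
        )
        best_score = [0.0] * len(remaining)
        pred = [-1] * len(remaining)
        lo_end = [0] * len(remaining)  # chain min s_start (+) / max s_end (-)
        for oi, i in enumerate(order):
            h = remaining[i]
            best_score[i] = float(h.score)
            lo_end[i] = h.s_start if h.strand == "+" else h.s_end
            for j in (order[k] for k in range(oi)):
                g = remaining[j]
                if not _chain_compatible(g, h, max_intron):
                    continue
                foot = (h.s_end - lo_end[j]) if h.strand == "+" else (lo_end[j] - h.s_start)
                if foot > max_span:
                    continue
                gap = (h.s_start - g.s_end) if h.strand == "+" else (g.s_start - h.s_end)
                cand = best_score[j] + h.score - gap_open - gap_per_nt * max(0, gap)
                if cand > best_score[i]:
                    best_score[i] = cand
                    pred[i] = j
                    lo_end[i] = lo_end[j]
        top = max(range(len(remaining)), key=lambda i: best_score[i])
        members = []
        i = top
        while i != -1:
            members.append(i)
            i = pred[i]
        members.reverse()
        chain_hs = [remaining[i] for i in members]
        chains.append(
            Chain(hsps=chain_hs, score=best_score[top], strand=chain_hs[0].strand)
        )
        used = set(members)
        remaining = [h for i, h in enumerate(remaining) if i not in used]
    chains.sort(key=lambda c: (-c.score, c.s_min))
    return chains


def spliced_align(
    query: str,
    window_seq: str,
    config: GeneHomConfig | None = None,
) -> tuple[list[tuple[int, int]], int, int, int, tuple[int, int]] | None:
    """Codon-aware local alignment of a protein against a DNA window.

    Introns are permitted only between codons, must start with GT and end
    with AG, and must be at least ``min_intron`` nt long; an intron of
    length L costs ``intron_open + intron_per_nt * L``. Gaps are affine
    (open 11 / extend 1, in BLOSUM62 units; a length-1 gap costs the
    opening penalty).

    Returns (exons, path_score, protein_score, n_introns, (q_start, q_end))
    with exons as 0-based half-open intervals in window coordinates;
    ``path_score`` includes intron costs while ``protein_score`` excludes
    them. Returns ``None`` when no positive-scoring alignment exists.
    """
    cfg = config or GeneHomConfig()
    m = len(query)
    n = len(window_seq)
    if m == 0 or n < 3:
        return None
    qv = encode_protein_b62(query)
    gv = encode_dna(window_seq)
    codon_idx = gv[:-2] * 25 + gv[1:-1] * 5 + gv[2:]
    aa_code = _CODON_AA[codon_idx]  # aa of codon starting at position j

    # All scores are multiples of 1/64 and small, so float32 keeps them exact.
    NEG = np.float32(-1e18)
    open_p, ext_p = float(cfg.gap_open), float(cfg.gap_extend)
    ic0, ic1 = float(cfg.intron_open), float(cfg.intron_per_nt)
    mi = cfg.min_intron
    # width of the legal donor window for an acceptor at j: d in
    # [j - max_intron, j - min_intron]
    W = max(1, cfg.max_intron - mi + 1)

    # boundary arrays over j = 0..n
    donor = np.zeros(n + 1, dtype=bool)  # intron may start at boundary d
    donor[: n - 1] = (gv[:-1] == 2) & (gv[1:] == 3)  # GT
    acceptor = np.zeros(n + 1, dtype=bool)  # intron may end at boundary j
    acceptor[2:] = (gv[:-1] == 0) & (gv[1:] == 2)  # AG

    # sub_j = score of aligning q_i with codon ENDING at boundary j
    sub_base = np.full(n + 1, NEG, dtype=np.float32)

    M = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    SplV = np.full((m + 1, n + 1), NEG, dtype=np.float32)

    jpos = np.arange(n + 1)
    jcost = (np.float32(ic1) * jpos).astype(np.float32)  # exact: ic1 = 1/64

    def _trailing_window_max(a: np.ndarray, width: int) -> np.ndarray:
        """wm[t] = max(a[max(0, t-width+1) : t+1]) via the two-pass
        block prefix/suffix-maximum decomposition."""
        nval = len(a)
        nblk = -(-nval // width)
        pad = nblk * width - nval
        ap = np.concatenate([a, np.full(pad, NEG, dtype=a.dtype)])
        blocks = ap.reshape(nblk, width)
        pre = np.maximum.accumulate(blocks, axis=1).ravel()[:nval]
        suf = np.maximum.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].ravel()
        wm = pre.copy()
        idx = np.arange(nval) - width + 1
        valid = idx >= 0
        wm[valid] = np.maximum(pre[valid], suf[idx[valid]])
        return wm

    def row_spl(H: np.ndarray, i: int) -> None:
        # intron d..j costs ic0 + ic1*(j-d); fold the length term into the
        # donor values so a windowed maximum over d suffices
        dv = np.where(donor, H + jcost, NEG)
        wmax = _trailing_window_max(dv, W)
        sv = np.full(n + 1, NEG, dtype=np.float32)
        if n + 1 > mi:
            ok = acceptor[mi:]
            sv[mi:] = np.where(
                ok, wmax[: n + 1 - mi] - np.float32(ic0) - jcost[mi:], NEG
            )
        SplV[i] = sv

    H_prev = np.full(n + 1, NEG, dtype=np.float32)
    row_spl(H_prev, 0)

    for i in range(1, m + 1):
        Brow = B62[qv[i - 1]].astype(np.float32)
        sub = sub_base.copy()
        sub[3:] = Brow[aa_code]
        start_or_prev = np.full(n + 1, NEG, dtype=np.float32)
        start_or_prev[3:] = np.maximum(
            np.float32(0.0), np.maximum(H_prev[:-3], SplV[i - 1][:-3])
        )
        M[i] = sub + start_or_prev
        Ix[i] = np.maximum(H_prev - np.float32(open_p), Ix[i - 1] - np.float32(ext_p))
        base = np.maximum(M[i], Ix[i])
        # Iy: codon insertions (stride-3 within-row affine recurrence)
        iy = np.full(n + 1, NEG, dtype=np.float32)
        for c in range(3):
            b = base[c::3]
            if len(b) < 2:
                continue
            u = np.arange(len(b), dtype=np.float32)
            A = b + u * np.float32(ext_p)
            run = np.empty_like(A)
            run[0] = NEG
            np.maximum.accumulate(A[:-1], out=run[1:])
            iy[c::3] = run - np.float32(open_p - ext_p) - u * np.float32(ext_p)
        Iy[i] = iy
        H_prev = np.maximum(base, iy)
        row_spl(H_prev, i)

    best_val = M[1:].max() if m >= 1 else 0.0
    if best_val <= 0:
        return None
    flat = int(np.argmax(M[1:]))
    bi = flat // (n + 1) + 1
    bj = flat % (n + 1)

    # traceback (all stored values are integer-valued; exact comparisons)
    def heq(a: float, b: float) -> bool:
        return abs(a - b) < 0.5

    introns: list[tuple[int, int]] = []
    consumed_min, consumed_max = bj, bj
    i, j, state = bi, bj, "M"
    q_end = bi
    q_start = bi
    guard = 0
    while True:
        guard += 1
        if guard > 10 * (m + n + 10):
            raise RuntimeError("spliced_align traceback failed to terminate")
        if state == "M":
            sub = float(B62[qv[i - 1]][aa_code[j - 3]])
            rem = float(M[i][j]) - sub
            consumed_min = min(consumed_min, j - 3)
            q_start = i - 1
            hp = float(max(M[i - 1][j - 3], Ix[i - 1][j - 3], Iy[i - 1][j - 3]))
            sp = float(SplV[i - 1][j - 3])
            if heq(rem, 0.0):
                break  # local alignment start
            if hp >= sp and heq(rem, hp):
                i, j, state = i - 1, j - 3, "H"
            elif heq(rem, sp):
                # recover the donor: scan the legal window for the position
                # whose H value reproduces the stored splice score
                p = j - 3
                d = -1
                for cand in range(p - mi, max(-1, p - cfg.max_intron - 1), -1):
                    if not donor[cand]:
                        continue
                    hval = float(
                        max(M[i - 1][cand], Ix[i - 1][cand], Iy[i - 1][cand])
                    )
                    if heq(sp, hval - ic0 - ic1 * (p - cand)):
                        d = cand
                        break
                if d < 0:
                    raise RuntimeError("spliced_align traceback lost the donor")
                introns.append((d, p))
                consumed_min = min(consumed_min, d)
                i, j, state = i - 1, d, "H"
            else:
                raise RuntimeError("spliced_align traceback inconsistency (M)")
        elif state == "H":
            if M[i][j] >= Ix[i][j] and M[i][j] >= Iy[i][j]:
                state = "M"
            elif Ix[i][j] >= Iy[i][j]:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            # query deletion: consumes query only
            hp = float(max(M[i - 1][j], Ix[i - 1][j], Iy[i - 1][j]))
            if heq(float(Ix[i][j]), hp - open_p):
                i, state = i - 1, "H"
            elif heq(float(Ix[i][j]), float(Ix[i - 1][j]) - ext_p):
                i, state = i - 1, "Ix"
            else:
                raise RuntimeError("spliced_align traceback inconsistency (Ix)")
        else:  # Iy: codon insertion(s) in the genome
            val = Iy[i][j]
            k = 1
            found = False
            while j - 3 * k >= 0:
                cand = max(M[i][j - 3 * k], Ix[i][j - 3 * k]) - open_p - (k - 1) * ext_p
                if heq(val, cand):
                    consumed_min = min(consumed_min, j - 3 * k)
                    j = j - 3 * k
                    state = "M" if M[i][j] >= Ix[i][j] else "Ix"
                    found = True
                    break
                k += 1
            if not found:
                raise RuntimeError("spliced_align traceback inconsistency (Iy)")

    g_start, g_end = consumed_min, consumed_max
    introns.sort()
    exons: list[tuple[int, int]] = []
    pos = g_start
    for d, a in introns:
        if d > pos:
            exons.append((pos, d))
        pos = a
    if g_end > pos:
        exons.append((pos, g_end))
    path_score = float(best_val)
    intron_cost = sum(cfg.intron_open + cfg.intron_per_nt * (a - d) for d, a in introns)
    protein_score = int(round(best_val + intron_cost))
    return exons, path_score, protein_score, len(introns), (q_start, q_end)


def candidate_from_chain(
    query_id: str,
    query: str,
    genome: SeqRecord,
    chain: Chain,
    config: GeneHomConfig,
    model_id: str,
) -> GeneCandidate | None:
    """Spliced-align the query in a window around a chain's footprint."""
    q_min = min(h.q_start for h in chain.hsps)
    q_max = max(h.q_end for h in chain.hsps)

    def _need(missing_aa: int) -> int:
        # at least one intron's reach: repeat slippage inside LRR arrays can
        # make a chain look like it covers the whole query when an outer
        # exon is still missing
        return min(config.flank, 3 * max(0, missing_aa) + config.max_intron + 300)

    need_nterm = _need(q_min)
    need_cterm = _need(len(query) - q_max)
    # on '-', the query N-terminus maps to the genomic right of the footprint
    left, right = (
        (need_nterm, need_cterm) if chain.strand == "+" else (need_cterm, need_nterm)
    )
    a = max(0, chain.s_min - left)
    b = min(len(genome.seq), chain.s_max + right)
    window = genome.seq[a:b]
    if chain.strand == "-":
        window = revcomp(window)
    res = spliced_align(query, window, config)
    if res is None:
        return None
    exons_w, path_score, protein_score, n_introns, _qspan = res
    if chain.strand == "+":
        exons = [(a + s, a + e) for s, e in exons_w]
    else:
        L = b - a
        exons = sorted((a + L - e, a + L - s) for s, e in exons_w)
    model = GeneModel(
        id=model_id,
        seqid=genome.id,
        strand=chain.strand,
        exons=exons,
        source="HRP",
        score=float(protein_score),
    )
    m = len(query)
    n_total = 2 * len(genome.seq)
    ev = config.karlin.evalue(path_score, m, n_total)
    return GeneCandidate(
        query_id=query_id, model=model, score=protein_score,
        path_score=path_score, evalue=ev, n_introns=n_introns, chain=chain,
    )


def predict_homologs(
    query_id: str,
    query: str,
    genome: SeqRecord,
    config: GeneHomConfig | None = None,
    index: GenomeIndex | None = None,
) -> list[GeneCandidate]:
    """Seed -> chain -> spliced-align; E-value-filtered candidates.

    At most ``max_chains_per_region`` chains per overlapping genomic region
    (per strand) are carried into the alignment stage; candidates with
    E > ``evalue_cutoff`` are removed and the rest sorted by E ascending.
    """
    cfg = config or GeneHomConfig()
    hsps = seed_and_extend(query, genome, cfg, index=index)
    chains = chain_hsps(
        hsps, cfg.max_span, cfg.max_intron, cfg.intron_open, cfg.intron_per_nt
    )
    regions: dict[str, list[list[int]]] = {"+": [], "-": []}  # [lo, hi, count]
    candidates: list[GeneCandidate] = []
    serial = 0
    for chain in chains:
        lo, hi = chain.s_min, chain.s_max
        hit = None
        for reg in regions[chain.strand]:
            if lo < reg[1] and reg[0] < hi:
                hit = reg
                break
        if hit is not None:
            if hit[2] >= cfg.max_chains_per_region:
                continue
            hit[2] += 1
            hit[0] = min(hit[0], lo)
            hit[1] = max(hit[1], hi)
        else:
            regions[chain.strand].append([lo, hi, 1])
        serial += 1
        cand = candidate_from_chain(
            query_id, query, genome, chain, cfg, f"{query_id}-h{serial}"
        )
        if cand is not None and cand.evalue <= cfg.evalue_cutoff:
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.evalue, -c.score))
    return candidates
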