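"""Seeding, chaining and spliced alignment against brute-force oracles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest

from hrp import genehom, synth
from hrp.genehom import (
    B62,
    B62_INDEX,
    Chain,
    GeneHomConfig,
    HSP,
    GenomeIndex,
    chain_hsps,
    predict_homologs,
    seed_and_extend,
    self_score,
    spliced_align,
)
from hrp.seqio import SeqRecord, revcomp

from conftest import encode_protein, random_dna, random_protein


# --- brute-force HSP oracle --------------------------------------------------


def brute_hsps(query, genome, cfg):
    """Extend from every matching k-mer pair in every frame (no skipping),
    then apply the same containment merge as the implementation."""
    index = GenomeIndex(genome, k=cfg.k)
    qv = [B62_INDEX.get(a, B62_INDEX["X"]) for a in query]
    out = set()
    for fid, (strand, frame, aa) in enumerate(index.frames):
        tv = [B62_INDEX.get(a, B62_INDEX["X"]) for a in aa]
        for t in range(len(aa) - cfg.k + 1):
            for qs in range(len(query) - cfg.k + 1):
                if query[qs : qs + cfg.k] != aa[t : t + cfg.k]:
                    continue
                lo, hi, score = genehom._extend_ungapped(qv, tv, qs, t, cfg.k, cfg.xdrop)
                if score >= cfg.min_hsp_score:
                    ts, te = lo + (t - qs), hi + (t - qs)
                    s_start, s_end, st, fr = index.to_genome(fid, ts, te)
                    out.add((lo, hi, s_start, s_end, st, fr, score))
    # drop segments contained in an equal-or-higher-scoring one on the same diagonal
    final = set()
    for h in out:
        contained = False
        for g in out:
            if g == h:
                continue
            same_diag = (
                g[4] == h[4]
                and g[5] == h[5]
                and (g[2] - 3 * g[0] == h[2] - 3 * h[0] if h[4] == "+" else g[3] + 3 * g[0] == h[3] + 3 * h[0])
            )
            if same_diag and g[0] <= h[0] and h[1] <= g[1] and g[6] >= h[6] and (g[0], g[1]) != (h[0], h[1]):
                contained = True
                break
        if not contained:
            final.add(h)
    return final


def _hsp_key(h):
    return (h.q_start, h.q_end, h.s_start, h.s_end, h.strand, h.frame, h.score)


def test_exact_copy_yields_full_length_hsp_with_self_score():
    rng = np.random.default_rng(0)
    prot = random_protein(100, rng)
    genome = SeqRecord(
        id="g", seq=random_dna(1500, rng) + encode_protein(prot, rng) + random_dna(1500, rng),
        kind="dna",
    )
    hsps = seed_and_extend(prot, genome)
    assert len(hsps) == 1
    h = hsps[0]
    assert (h.q_start, h.q_end) == (0, 100)
    assert (h.s_start, h.s_end) == (1500, 1800)
    assert h.score == self_score(prot)


def test_no_shared_kmer_means_empty():
    genome = SeqRecord(id="g", seq="AC" * 200, kind="dna")
    assert seed_and_extend("W" * 30, genome) == []


def test_seed_and_extend_matches_brute_force_on_fixtures():
    cfg = GeneHomConfig()
    rng = np.random.default_rng(17)
    for trial in range(50):
        prot = random_protein(30, rng)
        g = list(random_dna(1200, rng))
        # implant 0-2 (possibly diverged) copies of fragments of the query
        for _ in range(int(rng.integers(0, 3))):
            frag = list(prot[int(rng.integers(0, 10)) : int(rng.integers(20, 31))])
            for q in rng.choice(len(frag), size=int(rng.integers(0, 4)), replace=False):
                frag[q] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            dna = encode_protein("".join(frag), rng)
            if rng.random() < 0.5:
                dna = revcomp(dna)
            pos = int(rng.integers(0, len(g) - len(dna)))
            g[pos : pos + len(dna)] = dna
        genome = SeqRecord(id="g", seq="".join(g), kind="dna")
        got = {_hsp_key(h) for h in seed_and_extend(prot, genome, cfg)}
        want = brute_hsps(prot, genome, cfg)
        assert got == want, f"fixture {trial}"


# --- chaining ---------------------------------------------------------------


def _mk(qs, qe, ss, strand="+", score=100):
    return HSP(q_start=qs, q_end=qe, s_start=ss, s_end=ss + 3 * (qe - qs),
               strand=strand, frame=0, score=score)


def brute_best_chain(hsps, max_span, max_intron, gap_open=15.0, gap_per_nt=1.0 / 64.0):
    """Enumerate every subset, keep feasible colinear chains, maximize score."""
    best = 0.0
    for r in range(1, len(hsps) + 1):
        for combo in combinations(range(len(hsps)), r):
            members = [hsps[i] for i in combo]
            if len({h.strand for h in members}) != 1:
                continue
            members.sort(key=lambda h: h.s_start if h.strand == "+" else -h.s_end)
            ok = True
            score = float(members[0].score)
            for a, b in zip(members, members[1:]):
                if not genehom._chain_compatible(a, b, max_intron):
                    ok = False
                    break
                gap = (b.s_start - a.s_end) if b.strand == "+" else (a.s_start - b.s_end)
                score += b.score - gap_open - gap_per_nt * max(0, gap)
            foot = max(h.s_end for h in members) - min(h.s_start for h in members)
            if ok and foot <= max_span:
                best = max(best, score)
    return best


def test_three_colinear_hsps_form_one_chain():
    hsps = [_mk(0, 50, 1000), _mk(60, 110, 1500), _mk(120, 170, 2100)]
    chains = chain_hsps(hsps)
    assert len(chains) == 1
    assert len(chains[0].hsps) == 3


def test_chain_dp_matches_subset_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(40):
        n = int(rng.integers(2, 9))
        hsps = []
        for _ in range(n):
            qs = int(rng.integers(0, 150))
            qe = qs + int(rng.integers(10, 60))
            ss = int(rng.integers(0, 4000))
            hsps.append(_mk(qs, qe, ss, score=int(rng.integers(50, 300))))
        chains = chain_hsps(hsps, max_span=20000, max_intron=2200)
        got = max(c.score for c in chains)
        want = brute_best_chain(hsps, 20000, 2200)
        assert got == pytest.approx(want)


def test_distant_hsp_groups_split_into_two_chains():
    hsps = [_mk(0, 50, 1000), _mk(60, 110, 51_000)]
    chains = chain_hsps(hsps)
    assert len(chains) == 2


# --- spliced alignment -------------------------------------------------------


def naive_spliced_score(query, window, cfg):
    """The same recurrence with explicit loops (no vectorization tricks)."""
    m, n = len(query), len(window)
    qv = genehom.encode_protein_b62(query)
    gv = genehom.encode_dna(window)
    NEG = -1e15

    def aa_at(j):  # codon ending at boundary j
        c = gv[j - 3] * 25 + gv[j - 2] * 5 + gv[j - 1]
        return genehom._CODON_AA[c]

    donor = [j < n - 1 and gv[j] == 2 and gv[j + 1] == 3 for j in range(n + 1)]
    acceptor = [j >= 2 and gv[j - 2] == 0 and gv[j - 1] == 2 for j in range(n + 1)]

    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    Spl = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            if j >= 3:
                prev = max(0.0, H[i - 1][j - 3], Spl[i - 1][j - 3])
                M[i][j] = B62[qv[i - 1]][aa_at(j)] + prev
            Ix[i][j] = max(H[i - 1][j] - cfg.gap_open, Ix[i - 1][j] - cfg.gap_extend)
            base = max(M[i][j], Ix[i][j])
            k = 1
            while j - 3 * k >= 0:
                cand = max(M[i][j - 3 * k], Ix[i][j - 3 * k]) - cfg.gap_open - (k - 1) * cfg.gap_extend
                Iy[i][j] = max(Iy[i][j], cand)
                k += 1
            H[i][j] = max(base, Iy[i][j])
            best = max(best, M[i][j])
        for j in range(n + 1):
            if not acceptor[j]:
                continue
            for d in range(max(0, j - cfg.max_intron), j - cfg.min_intron + 1):
                if donor[d]:
                    cost = cfg.intron_open + cfg.intron_per_nt * (j - d)
                    Spl[i][j] = max(Spl[i][j], H[i][d] - cost)
    return best


def test_spliced_dp_equals_naive_recurrence_on_tiny_instances():
    cfg = GeneHomConfig(min_intron=10, max_intron=60, intron_open=5, flank=100)
    rng = np.random.default_rng(31)
    for trial in range(25):
        m = int(rng.integers(5, 21))
        prot = random_protein(m, rng)
        if rng.random() < 0.7:
            cds = encode_protein(prot, rng)
            cut = 3 * int(rng.integers(1, m))
            intron = "GT" + random_dna(int(rng.integers(8, 40)), rng) + "AG"
            core = cds[:cut] + intron + cds[cut:]
        else:
            core = random_dna(60, rng)
        window = random_dna(10, rng) + core + random_dna(10, rng)
        window = window[:120]
        res = spliced_align(prot, window, cfg)
        got = 0 if res is None else res[1]
        want = naive_spliced_score(prot, window, cfg)
        assert got == pytest.approx(want), f"fixture {trial}"


def test_two_exon_truth_boundaries_recovered_exactly():
    rng = np.random.default_rng(41)
    prot = random_protein(120, rng)
    cds = encode_protein(prot, rng)
    intron = "GT" + random_dna(296, rng) + "AG"
    gene = cds[:150] + intron + cds[150:]
    window = random_dna(500, rng) + gene + random_dna(500, rng)
    exons, path_score, S, ni, _ = spliced_align(prot, window)
    assert exons == [(500, 650), (950, 1160)]
    assert ni == 1
    assert S == self_score(prot)


def test_intronless_copy_reduces_to_single_exon():
    rng = np.random.default_rng(43)
    prot = random_protein(80, rng)
    window = random_dna(200, rng) + encode_protein(prot, rng) + random_dna(200, rng)
    exons, _, S, ni, _ = spliced_align(prot, window)
    assert exons == [(200, 440)]
    assert ni == 0
    assert S == self_score(prot)


# --- candidates and statistics -----------------------------------------------


def test_evalue_strictly_decreasing_in_score():
    kp = genehom.KarlinParams()
    evs = [kp.evalue(s, 400, 1_000_000) for s in range(50, 400, 25)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


def test_implanted_homolog_found_with_exact_cds_and_tiny_evalue():
    rng = np.random.default_rng(47)
    prot = random_protein(150, rng)
    cds = encode_protein(prot, rng)
    intron = "GT" + random_dna(148, rng) + "AG"
    gene = cds[:180] + intron + cds[180:]
    genome = SeqRecord(
        id="g", seq=random_dna(3000, rng) + gene + random_dna(3000, rng), kind="dna"
    )
    cands = predict_homologs("q", prot, genome)
    assert cands
    top = cands[0]
    assert top.evalue < 0.01
    assert top.model.exons == [(3000, 3180), (3332, 3000 + len(gene))]


def test_strand_symmetry_of_predictions():
    rng = np.random.default_rng(53)
    prot = random_protein(120, rng)
    cds = encode_protein(prot, rng)
    seq = random_dna(2000, rng) + cds + random_dna(2000, rng)
    fwd = SeqRecord(id="g", seq=seq, kind="dna")
    rev = SeqRecord(id="g", seq=revcomp(seq), kind="dna")
    a = predict_homologs("q", prot, fwd)
    b = predict_homologs("q", prot, rev)
    assert len(a) == len(b) == 1
    L = len(seq)
    assert a[0].score == b[0].score
    assert a[0].model.strand != b[0].model.strand
    mirrored = sorted((L - e, L - s) for s, e in b[0].model.exons)
    assert mirrored == a[0].model.exons


def test_candidate_protein_realigns_to_reported_score(small_truth, library):
    """Every returned model's translation aligns back to its query at the
    reported protein-level score (checked with an independent aligner)."""
    from Bio import Align
    from hrp.seqio import extract_and_translate

    rng = np.random.default_rng(59)
    prot, _ = synth.generate_rgene("CNL", 1.0, rng, library)
    cds = encode_protein(prot, rng)
    intron = "GT" + random_dna(500, rng) + "AG"
    gene = cds[:300] + intron + cds[300:]
    genome = SeqRecord(
        id="g", seq=random_dna(2500, rng) + gene + random_dna(2500, rng), kind="dna"
    )
    cands = predict_homologs("q", prot, genome)
    assert cands
    top = cands[0]
    predicted, _ = extract_and_translate(top.model, genome)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = genehom._B62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    assert aligner.score(prot, predicted) == top.score


def test_null_random_genomes_yield_no_candidates():
    rng = np.random.default_rng(61)
    prot, _ = synth.generate_rgene("CNL", 0.9, rng)
    bad = 0
    for i in range(10):
        g = SeqRecord(id=f"n{i}", seq=random_dna(50_000, np.random.default_rng(900 + i)), kind="dna")
        if predict_homologs("q", prot, g):
            bad += 1
    assert bad <= 1
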