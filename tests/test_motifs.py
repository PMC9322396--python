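"""EM motif discovery, exact scan p-values, and QFAST combination."""

import math
from itertools import product

import numpy as np
import pytest

from hrp import motifs
from hrp.motifs import MotifError, MotifModel

from conftest import AA20, random_protein


def _implant_fixture(n=50, length=60, word="WNDKAR", seed=1):
    rng = np.random.default_rng(seed)
    seqs, sites = [], []
    for _ in range(n):
        s = list(random_protein(length, rng))
        p = int(rng.integers(0, length - len(word)))
        s[p : p + len(word)] = word
        seqs.append("".join(s))
        sites.append(p)
    return seqs, sites


def test_implanted_word_recovered_with_sites():
    seqs, sites = _implant_fixture()
    found = motifs.discover_motifs(seqs, n_motifs=3)
    first = found[0]
    # consensus within Hamming distance 1 of the implanted word (allowing a
    # one-column frame offset when the accepted width differs from 6)
    def hamming_vs_word(cons):
        best = 99
        for off in range(-2, 3):
            d = sum(
                1
                for i, c in enumerate("WNDKAR")
                if not (0 <= i + off < len(cons)) or cons[i + off] != c
            )
            best = min(best, d)
        return best

    assert hamming_vs_word(first.consensus) <= 1
    recovered = 0
    for s, p in zip(seqs, sites):
        hits = motifs.motif_hit_pvalue(s, first)
        best = min(hits, key=lambda h: h.pvalue)
        if abs(best.position - p) <= abs(first.width - 6):
            recovered += 1
    assert recovered >= 45


def test_widths_and_count_respect_defaults():
    seqs, _ = _implant_fixture(n=20, seed=3)
    found = motifs.discover_motifs(seqs)
    assert len(found) <= 19
    assert all(4 <= m.width <= 7 for m in found)


def test_identical_sequences_give_substring_consensus():
    seq = "MKWVRNDKARLLEWQHP" * 2
    found = motifs.discover_motifs([seq] * 10, n_motifs=1)
    assert found[0].consensus in seq
    assert found[0].nsites == 10


def test_fewer_than_two_sequences_errors():
    with pytest.raises(MotifError):
        motifs.discover_motifs(["MKWVRNDKAR"])


def test_single_residue_content_is_degenerate():
    with pytest.raises(MotifError, match="degenerate"):
        motifs.discover_motifs(["AAAAAAAAAA", "AAAAAAAA"])


def test_discovery_is_deterministic():
    seqs, _ = _implant_fixture(n=15, seed=9)
    a = motifs.discover_motifs(seqs, n_motifs=4)
    b = motifs.discover_motifs(seqs, n_motifs=4)
    assert len(a) == len(b)
    for ma, mb in zip(a, b):
        assert ma.width == mb.width
        np.testing.assert_array_equal(ma.counts, mb.counts)


# --- exact p-values ----------------------------------------------------------


def _motif_from_counts(counts, alphabet, nsites):
    counts = np.asarray(counts, dtype=float)
    bg = np.full(len(alphabet), 1.0 / len(alphabet))
    freqs = counts / counts.sum(axis=1, keepdims=True)
    log_odds = np.log2(np.maximum(freqs, 1e-12) / bg)
    return MotifModel(
        id=1, width=counts.shape[0], counts=counts, log_odds=log_odds,
        background=bg, nsites=nsites, alphabet=alphabet,
    )


def test_width_one_pvalue_is_background_frequency():
    counts = np.zeros((1, 20))
    counts[0, AA20.index("L")] = 10
    m = _motif_from_counts(counts, AA20, 10)
    (hit,) = motifs.motif_hit_pvalue("L", m)
    assert hit.pvalue == pytest.approx(0.05)


def test_width3_pvalues_match_enumeration_on_reduced_alphabet():
    rng = np.random.default_rng(4)
    alphabet = "ACGT"
    counts = rng.integers(1, 20, size=(3, 4)).astype(float)
    m = _motif_from_counts(counts, alphabet, 20)
    ints = np.rint(m.log_odds * 100).astype(int)
    # enumeration oracle over all 64 windows
    word_scores = {}
    for word in product(range(4), repeat=3):
        word_scores[word] = sum(int(ints[j, a]) for j, a in enumerate(word))
    def exact_p(s):
        return sum(0.25 ** 3 for w, ws in word_scores.items() if ws >= s)

    for word in product(range(4), repeat=3):
        protein = "".join(alphabet[a] for a in word)
        (hit,) = motifs.motif_hit_pvalue(protein, m)
        assert hit.pvalue == pytest.approx(exact_p(word_scores[word]), rel=1e-12)


def test_minimum_score_has_pvalue_one():
    counts = np.ones((2, 4))
    counts[0, 0] = 50
    counts[1, 1] = 50
    m = _motif_from_counts(counts, "ACGT", 50)
    # "TT" is the least likely word under this motif: minimum score, p = 1
    (hit,) = motifs.motif_hit_pvalue("TT", m)
    assert hit.pvalue == 1.0


def test_null_best_hit_pvalues_not_anticonservative():
    """Empirical P(p <= t) under the background stays at or below t (up to
    the integer-rescaling resolution) for single-window scans."""
    rng = np.random.default_rng(8)
    counts = rng.integers(1, 30, size=(5, 20)).astype(float)
    m = _motif_from_counts(counts, AA20, 30)
    n = 10_000
    ps = []
    for _ in range(n):
        w = random_protein(5, rng)
        ps.append(motifs.motif_hit_pvalue(w, m)[0].pvalue)
    ps = np.sort(ps)
    for t in (0.01, 0.05, 0.1, 0.5):
        emp = np.searchsorted(ps, t, side="right") / n
        assert emp <= t * 1.3 + 0.01


# --- QFAST combination -------------------------------------------------------


def test_combined_single_p_reduces_to_p():
    cp, E = motifs.combined_evalue([0.05], 100)
    assert cp == pytest.approx(0.05)
    assert E == pytest.approx(5.0)


def test_combined_two_p_closed_form():
    cp, _ = motifs.combined_evalue([0.1, 0.1], 100)
    assert cp == pytest.approx(0.01 * (1 + math.log(100)))


def test_combined_boundary_all_ones():
    cp, E = motifs.combined_evalue([1.0, 1.0], 100)
    assert cp == 1.0 and E == 100.0


def test_combined_rejects_nonpositive():
    with pytest.raises(MotifError):
        motifs.combined_evalue([0.0, 0.5], 10)


def test_combined_monotone_and_bounded():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = int(rng.integers(1, 8))
        ps = rng.uniform(1e-12, 1.0, size=n)
        cp, _ = motifs.combined_evalue(list(ps), 1)
        assert 0.0 < cp <= 1.0
        k = int(rng.integers(0, n))
        bumped = ps.copy()
        bumped[k] = min(1.0, bumped[k] * 1.5 + 1e-12)
        cp2, _ = motifs.combined_evalue(list(bumped), 1)
        assert cp2 >= cp - 1e-15


def test_meme_round_trip(tmp_path):
    seqs, _ = _implant_fixture(n=12, seed=5)
    found = motifs.discover_motifs(seqs, n_motifs=3)
    p = tmp_path / "m.meme.txt"
    motifs.write_meme(found, p)
    back = motifs.read_meme(p)
    assert [m.width for m in back] == [m.width for m in found]
    assert [m.consensus for m in back] == [m.consensus for m in found]
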