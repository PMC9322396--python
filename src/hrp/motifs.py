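"""EM motif discovery on NB-domain sequences and exact-p-value motif scanning.

``discover_motifs`` decomposes a set of protein sequences (in the pipeline:
the nucleotide-binding domain regions of full-length NB-LRR proteins) into
short ungapped motifs with a ZOOPS ("zero or one occurrence per sequence")
EM, discovering motifs sequentially and erasing the sites of each accepted
motif before the next round. Defaults mirror the pipeline's discovery
settings: up to 19 motifs of width 4-7.

``motif_hit_pvalue`` scores every window of a protein with a motif's
log-odds matrix and attaches an exact p-value, computed by staged
convolution of the integer-rescaled (1/100 bit precision) per-position
score distributions under the background.

``combined_evalue`` combines per-motif best p-values with the product
formula (QFAST): for q = prod p_i over n motifs,
combined_p = q * sum_{k<n} (-ln q)^k / k!, and E = combined_p * N for a
database of N sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .domains import AA, AA_INDEX

PSEUDOCOUNT = 0.01  # times background, per count-matrix cell
EM_TOL = 1e-4
EM_MAX_ITER = 50


class MotifError(ValueError):
    pass


@dataclass
class MotifModel:
    id: int
    width: int
    counts: np.ndarray  # (width, A) nonnegative
    log_odds: np.ndarray  # (width, A), bits
    background: np.ndarray  # (A,)
    nsites: int
    alphabet: str = AA
    consensus: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            self.consensus = "".join(
                self.alphabet[j] for j in self.counts.argmax(axis=1)
            )


@dataclass
class MotifHit:
    motif_id: int
    protein_id: str
    position: int
    score: float  # summed log-odds, bits
    pvalue: float


def _encode(seq: str, alphabet: str) -> np.ndarray:
    index = {a: i for i, a in enumerate(alphabet)}
    return np.array([index.get(a, -1) for a in seq], dtype=np.int64)


def _background(encoded: list[np.ndarray], n_letters: int) -> np.ndarray:
    counts = np.zeros(n_letters)
    for e in encoded:
        valid = e[e >= 0]
        counts += np.bincount(valid, minlength=n_letters)
    if counts.sum() == 0:
        raise MotifError("no scorable residues in input")
    bg = (counts + 1.0) / (counts.sum() + n_letters)
    return bg


def _window_loglik(e: np.ndarray, mask: np.ndarray, log_theta: np.ndarray,
                   log_bg: np.ndarray) -> np.ndarray:
    """log P(window | motif) - log P(window | bg) for every start; masked or
    out-of-alphabet windows get -inf."""
    w = log_theta.shape[0]
    n = len(e) - w + 1
    if n <= 0:
        return np.zeros(0)
    ratio = np.full(len(e), -np.inf)
    ok = (e >= 0) & ~mask
    # per-position log-odds for each motif column
    out = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(w):
        col = np.where(ok[j : j + n], log_theta[j, np.clip(e[j : j + n], 0, None)]
                       - log_bg[np.clip(e[j : j + n], 0, None)], np.nan)
        bad |= np.isnan(col)
        out += np.nan_to_num(col)
    out[bad] = -np.inf
    return out


def _zoops_em(encoded: list[np.ndarray], masks: list[np.ndarray], w: int,
              bg: np.ndarray, n_letters: int) -> tuple[np.ndarray, float, list[int | None]]:
    """Run ZOOPS EM for one width. Returns (theta, llr, site per sequence)."""
    log_bg = np.log(bg)
    # deterministic init: most frequent unmasked exact w-mer (ties: lexicographic)
    counts: dict[tuple, int] = {}
    for e, m in zip(encoded, masks):
        for i in range(len(e) - w + 1):
            win = e[i : i + w]
            if (win >= 0).all() and not m[i : i + w].any():
                counts[tuple(win)] = counts.get(tuple(win), 0) + 1
    if not counts:
        return np.zeros((w, n_letters)), -np.inf, [None] * len(encoded)
    seed = min(counts, key=lambda k: (-counts[k], k))
    theta = np.tile(bg * 0.3, (w, 1))
    for j, a in enumerate(seed):
        theta[j, a] += 0.7
    theta /= theta.sum(axis=1, keepdims=True)
    gamma = 0.5

    prev_ll = -np.inf
    z_list: list[np.ndarray] = []
    for _ in range(EM_MAX_ITER):
        log_theta = np.log(theta)
        ll = 0.0
        z_list = []
        for e, m in zip(encoded, masks):
            lw = _window_loglik(e, m, log_theta, log_bg)
            if len(lw) == 0:
                z_list.append(np.zeros(0))
                continue
            npos = np.isfinite(lw).sum()
            if npos == 0:
                z_list.append(np.zeros(len(lw)))
                continue
            # P(site at i) prior = gamma / npos; P(no site) = 1 - gamma
            with np.errstate(over="ignore"):
                site_terms = np.where(np.isfinite(lw),
                                      (gamma / npos) * np.exp(np.minimum(lw, 700.0)),
                                      0.0)
            denom = (1.0 - gamma) + site_terms.sum()
            z = site_terms / denom
            z_list.append(z)
            ll += math.log(denom)
        if abs(ll - prev_ll) < EM_TOL:
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        new_counts = np.full((w, n_letters), PSEUDOCOUNT) * bg
        tot_z = 0.0
        n_seq_with_pos = 0
        for e, z in zip(encoded, z_list):
            n = len(z)
            if n == 0:
                continue
            n_seq_with_pos += 1
            tot_z += z.sum()
            for j in range(w):
                col = e[j : j + n]
                sel = (col >= 0) & (z > 1e-12)
                if sel.any():
                    new_counts[j] += np.bincount(
                        col[sel], weights=z[sel], minlength=n_letters
                    )
        theta = new_counts / new_counts.sum(axis=1, keepdims=True)
        gamma = min(0.999, max(1e-3, tot_z / max(1, n_seq_with_pos)))

    sites: list[int | None] = []
    for z in z_list:
        if len(z) and z.sum() > 0.5:
            sites.append(int(z.argmax()))
        else:
            sites.append(None)
    return theta, prev_ll, sites


def discover_motifs(
    sequences: list[str],
    n_motifs: int = 19,
    min_w: int = 4,
    max_w: int = 7,
    seed: int = 0,
    alphabet: str = AA,
) -> list[MotifModel]:
    """Sequential ZOOPS motif discovery with site erasure.

    For each motif, EM runs at every width in [min_w, max_w]; the width with
    the best total log-likelihood ratio is accepted, its sites are masked,
    and discovery continues (up to ``n_motifs`` motifs, stopping early when
    fewer than two sequences carry a site). The procedure is deterministic
    for fixed inputs; ``seed`` is accepted for interface stability but the
    initialization is already deterministic (most frequent exact word).
    """
    if len(sequences) < 2:
        raise MotifError("motif discovery requires at least 2 sequences")
    if any(len(s) < max_w for s in sequences):
        raise MotifError(f"every sequence must be at least max_w={max_w} long")
    n_letters = len(alphabet)
    encoded = [_encode(s, alphabet) for s in sequences]
    distinct = set()
    for e in encoded:
        distinct.update(int(x) for x in e[e >= 0])
    if len(distinct) < 2:
        raise MotifError("degenerate input: single-residue content")
    bg = _background(encoded, n_letters)
    masks = [np.zeros(len(e), dtype=bool) for e in encoded]

    motifs: list[MotifModel] = []
    n_seq = len(sequences)
    # Width selection pays for free parameters (BIC-style) so that a weakly
    # conserved flanking column does not inflate the accepted width.
    width_penalty = 0.5 * (n_letters - 1) * math.log(max(2, n_seq))
    for motif_id in range(1, n_motifs + 1):
        best = None
        for w in range(min_w, max_w + 1):
            theta, llr, sites = _zoops_em(encoded, masks, w, bg, n_letters)
            crit = llr - width_penalty * w
            if best is None or crit > best[4]:
                best = (theta, llr, sites, w, crit)
        theta, llr, sites, w, _ = best
        nsites = sum(1 for s in sites if s is not None)
        if nsites < 2 or not np.isfinite(llr):
            break
        counts = np.full((w, n_letters), PSEUDOCOUNT) * bg
        for e, s in zip(encoded, sites):
            if s is None:
                continue
            for j in range(w):
                a = e[s + j]
                if a >= 0:
                    counts[j, a] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        log_odds = np.log2(freqs / bg)
        motifs.append(
            MotifModel(
                id=motif_id, width=w, counts=counts, log_odds=log_odds,
                background=bg.copy(), nsites=nsites, alphabet=alphabet,
            )
        )
        for m, s in zip(masks, sites):
            if s is not None:
                m[s : s + w] = True
    return motifs


def motif_sites(motif_index: int, motifs: list[MotifModel]) -> MotifModel:
    return motifs[motif_index]


def _int_scores(motif: MotifModel) -> np.ndarray:
    """Log-odds rescaled to integers at 1/100-bit precision."""
    return np.rint(motif.log_odds * 100.0).astype(np.int64)


def score_distribution(motif: MotifModel) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer window score under the background.

    Staged convolution over motif columns; returns (probabilities, offset)
    where probabilities[k] = P(score == k + offset).
    """
    ints = _int_scores(motif)
    bg = motif.background
    dist = np.array([1.0])
    offset = 0
    for j in range(motif.width):
        col = ints[j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (hi - lo))
        for a in range(len(bg)):
            sh = int(col[a]) - lo
            new[sh : sh + len(dist)] += dist * bg[a]
        dist = new
        offset += lo
    return dist, offset


def motif_hit_pvalue(
    protein: str, motif: MotifModel, protein_id: str = ""
) -> list[MotifHit]:
    """Score every window of ``protein`` with the motif; exact p-values.

    The p-value of an observed score s is P(score >= s) for a random window
    drawn from the motif's background, computed on the integer-rescaled
    score scale (so the observed score is rescaled identically).
    """
    w = motif.width
    e = _encode(protein, motif.alphabet)
    n = len(e) - w + 1
    if n <= 0:
        return []
    ints = _int_scores(motif)
    dist, offset = score_distribution(motif)
    # survival[k] = P(score >= k + offset)
    survival = np.cumsum(dist[::-1])[::-1]
    max_score = offset + len(dist) - 1

    # column-mean fallback for unknown residues (X / '*')
    col_mean = np.rint(ints.mean(axis=1)).astype(np.int64)
    window_int = np.zeros(n, dtype=np.int64)
    for j in range(w):
        col = np.where(e[j : j + n] >= 0, ints[j, np.clip(e[j : j + n], 0, None)],
                       col_mean[j])
        window_int += col
    hits = []
    for i in range(n):
        s = int(window_int[i])
        if s > max_score:
            p = float(survival[-1])
        elif s <= offset:
            p = 1.0
        else:
            p = float(survival[s - offset])
        hits.append(
            MotifHit(
                motif_id=motif.id, protein_id=protein_id, position=i,
                score=s / 100.0, pvalue=min(1.0, max(p, 5e-324)),
            )
        )
    return hits


def best_hit_pvalues(protein: str, motifs: list[MotifModel],
                     protein_id: str = "") -> dict[int, float]:
    """Best (smallest) hit p-value per motif for one protein."""
    out = {}
    for m in motifs:
        hits = motif_hit_pvalue(protein, m, protein_id)
        if hits:
            out[m.id] = min(h.pvalue for h in hits)
    return out


def combined_evalue(best_pvalues: list[float], database_size: int) -> tuple[float, float]:
    """QFAST combination of per-motif p-values.

    q = prod p_i; combined_p = q * sum_{k=0}^{n-1} (-ln q)^k / k!;
    E = combined_p * database_size. Each p must lie in (0, 1].
    """
    n = len(best_pvalues)
    if n < 1:
        raise MotifError("combined_evalue requires at least one p-value")
    for p in best_pvalues:
        if not (0.0 < p <= 1.0):
            raise MotifError(f"p-value out of (0,1]: {p}")
    ln_q = sum(math.log(p) for p in best_pvalues)
    if ln_q == 0.0:
        return 1.0, float(database_size)
    # combined_p = exp(ln_q) * sum_k exp(k*ln(-ln_q) - lgamma(k+1))
    ln_neg = math.log(-ln_q)
    total = 0.0
    for k in range(n):
        total += math.exp(ln_q + k * ln_neg - math.lgamma(k + 1))
    combined_p = min(1.0, total)
    return combined_p, combined_p * database_size


def write_meme(motifs: list[MotifModel], path) -> None:
    """Serialize motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + motifs[0].alphabet + "\n\n")
        fh.write("Background letter frequencies\n")
        bg = motifs[0].background
        fh.write(
            " ".join(f"{a} {f:.5f}" for a, f in zip(motifs[0].alphabet, bg)) + "\n\n"
        )
        for m in motifs:
            freqs = m.counts / m.counts.sum(axis=1, keepdims=True)
            fh.write(f"MOTIF M{m.id} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(m.alphabet)} "
                f"w= {m.width} nsites= {m.nsites} E= 0\n"
            )
            for row in freqs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    """Read motifs from MEME minimal text format (as written by write_meme)."""
    motifs: list[MotifModel] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    alphabet = AA
    bg = np.full(20, 0.05)
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
        elif line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[j]) for j in range(1, len(parts), 2)])
            i += 1
        elif line.startswith("MOTIF"):
            mid = int(line.split()[1].lstrip("M"))
            header = lines[i + 1]
            fields = dict(
                zip(header.split(":")[1].split()[0::2], header.split(":")[1].split()[1::2])
            )
            w = int(fields["w="]) if "w=" in fields else int(header.split("w=")[1].split()[0])
            nsites = int(header.split("nsites=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 2 + j].split()])
            freqs = np.array(rows)
            counts = freqs * nsites
            log_odds = np.log2(np.maximum(freqs, 1e-300) / bg)
            motifs.append(
                MotifModel(
                    id=mid, width=w, counts=counts, log_odds=log_odds,
                    background=bg.copy(), nsites=nsites, alphabet=alphabet,
                )
            )
            i += 1 + w
        i += 1
    return motifs
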