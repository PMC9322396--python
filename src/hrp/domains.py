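"""R-protein domain detection, architecture assembly and class assignment.

Domain evidence comes from three detectors:

* ``scan_profile`` — ungapped sliding-window scan of a position-specific
  scoring matrix (PSSM, log-odds bits over the 20 amino acids). The bundled
  profiles cover the nucleotide-binding (NB) domain, the TIR domain, the
  Rx-N coiled-coil domain and the RPW8 domain; they are built at load time
  from small seed alignments shipped with the package.
* ``detect_lrr`` — a degenerate-repeat detector for the leucine-rich repeat
  region, scoring tiled 8-residue frames against an LxxLxLxL-type consensus
  with hydrophobic anchors.
* ``detect_coiled_coil`` — a sliding-window heptad-propensity heuristic for
  coiled-coil segments, from a bundled per-residue propensity table.

Ordered domain hits are assembled into a :class:`DomainArchitecture` and
assigned the standard NB-LRR class labels: full-length CNL / TNL / RNL / NL
(coiled-coil, TIR, RPW8 or no recognized N-terminal domain, respectively,
ahead of NB and LRR), or a partial label joining the detected domains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Hydrophobic residues accepted at LRR anchor positions.
LRR_HYDROPHOBIC = frozenset("LIVF")
# Anchor positions of the 8-residue LRR frame (LxxLxLxL).
LRR_ANCHORS = (0, 3, 5, 7)

FULL_LENGTH_NTERM = {"CC": "CNL", "TIR": "TNL", "RPW8": "RNL"}


@dataclass
class DomainHit:
    kind: str  # NB | TIR | CC_RXN | CC_COILS | RPW8 | LRR
    start: int
    end: int
    score: float
    repeats: int = 0

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class DomainArchitecture:
    kinds: list[str]  # ordered by hit start, CC evidence collapsed to "CC"
    hits: list[DomainHit]
    class_label: str = ""
    full_length: bool = False


@dataclass
class Profile:
    kind: str
    accession: str
    matrix: np.ndarray  # (length, 20) log-odds bits
    threshold: float
    consensus: str

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


class ProfileLibrary:
    """Bundled PSSMs for the NB, TIR, Rx-N (CC) and RPW8 domains.

    Matrices are built from the seed alignments under ``hrp/data/profiles``
    against a uniform background; bit-score thresholds are fixed in the
    bundled metadata. Accession labels (e.g. PF00931 for NB) are carried as
    metadata only.
    """

    def __init__(self, profiles: dict[str, Profile]):
        self.profiles = profiles

    def __getitem__(self, kind: str) -> Profile:
        return self.profiles[kind]

    def __iter__(self):
        return iter(self.profiles.values())

    @classmethod
    def bundled(cls) -> "ProfileLibrary":
        base = resources.files("hrp") / "data" / "profiles"
        meta = json.loads((base / "meta.json").read_text())
        profiles: dict[str, Profile] = {}
        for kind, info in meta.items():
            seqs = _read_alignment((base / info["alignment"]).read_text())
            matrix, consensus = build_pssm(seqs)
            profiles[kind] = Profile(
                kind=kind,
                accession=info["accession"],
                matrix=matrix,
                threshold=float(info["threshold"]),
                consensus=consensus,
            )
        return cls(profiles)


def _read_alignment(text: str) -> list[str]:
    seqs, cur = [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
                cur = []
        else:
            cur.append(line.strip())
    if cur:
        seqs.append("".join(cur))
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("seed alignment rows have unequal lengths")
    return seqs


def build_pssm(
    aligned_seqs: list[str], pseudocount: float = 1.0
) -> tuple[np.ndarray, str]:
    """Log-odds (bits) PSSM from an ungapped alignment, uniform background.

    Per column: p = (counts + pseudocount * bg) / (n + pseudocount), scores
    log2(p / bg). Returns the matrix and the majority-rule consensus.
    """
    n = len(aligned_seqs)
    length = len(aligned_seqs[0])
    bg = 1.0 / 20.0
    counts = np.zeros((length, 20))
    for seq in aligned_seqs:
        for j, a in enumerate(seq):
            if a in AA_INDEX:
                counts[j, AA_INDEX[a]] += 1
    p = (counts + pseudocount * bg) / (n + pseudocount)
    matrix = np.log2(p / bg)
    consensus = "".join(AA[int(j)] for j in counts.argmax(axis=1))
    return matrix, consensus


def encode_protein(protein: str) -> np.ndarray:
    """Indices into the 20-letter alphabet; X/*/unknown mapped to -1."""
    return np.array([AA_INDEX.get(a, -1) for a in protein], dtype=np.int64)


def window_scores(protein: str, matrix: np.ndarray) -> np.ndarray:
    """Score of every length-L window of ``protein`` under the PSSM.

    Unknown residues (X, '*') contribute the column mean, keeping scans
    tolerant of pseudoprotein translations.
    """
    L = matrix.shape[0]
    idx = encode_protein(protein)
    n = len(idx) - L + 1
    if n <= 0:
        return np.zeros(0)
    col_mean = matrix.mean(axis=1)
    # contrib[i, j] = score of residue i when placed at profile column j.
    contrib = np.empty((len(idx), L))
    valid = idx >= 0
    contrib[valid] = matrix[:, idx[valid]].T
    contrib[~valid] = col_mean[None, :]
    # Window w score = sum_j contrib[w + j, j].
    scores = np.zeros(n)
    for j in range(L):
        scores += contrib[j : j + n, j]
    return scores


def _greedy_merge(windows: list[tuple[int, float]], L: int, kind: str) -> list[DomainHit]:
    """Merge overlapping above-threshold windows into maximal-scoring
    non-overlapping hits, greedily by score (ties: smaller start)."""
    order = sorted(windows, key=lambda t: (-t[1], t[0]))
    accepted: list[DomainHit] = []
    for start, score in order:
        hit = DomainHit(kind=kind, start=start, end=start + L, score=float(score))
        if not any(hit.overlaps(a) for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return accepted


def scan_profile(
    protein: str, profile: Profile, threshold: float | None = None
) -> list[DomainHit]:
    """All non-overlapping PSSM windows scoring at or above threshold.

    A protein shorter than the profile yields an empty result.
    """
    thr = profile.threshold if threshold is None else threshold
    scores = window_scores(protein, profile.matrix)
    windows = [(i, s) for i, s in enumerate(scores) if s >= thr]
    return _greedy_merge(windows, profile.length, profile.kind)


def _lrr_frame_matches(protein: str, start: int) -> bool:
    """An 8-residue LRR frame matches when >= 3 of the 4 anchor positions are
    hydrophobic (L/I/V/F) and at most one non-anchor position is."""
    frame = protein[start : start + 8]
    anchors = sum(1 for i in LRR_ANCHORS if frame[i] in LRR_HYDROPHOBIC)
    others = sum(
        1 for i in range(8) if i not in LRR_ANCHORS and frame[i] in LRR_HYDROPHOBIC
    )
    return anchors >= 3 and others <= 1


def detect_lrr(protein: str, min_repeats: int = 3) -> list[DomainHit]:
    """Detect leucine-rich repeat regions as runs of tiled matching frames.

    For every start offset, consecutive 8-residue frames (step 8) that each
    match the degenerate consensus are chained; runs of at least
    ``min_repeats`` frames become hits with ``repeats`` = frame count and
    score = total matched anchor positions. Overlapping runs from different
    offsets are reduced to the best-scoring non-overlapping set.
    """
    n = len(protein)
    runs: list[tuple[int, float]] = []  # (start, score) with repeats encoded
    raw: list[DomainHit] = []
    matches = [False] * max(0, n - 7)
    for s in range(len(matches)):
        matches[s] = _lrr_frame_matches(protein, s)
    for offset in range(min(8, max(0, n - 7))):
        s = offset
        run_start = None
        run_len = 0
        while s < len(matches) + 8:
            ok = s < len(matches) and matches[s]
            if ok:
                if run_start is None:
                    run_start = s
                    run_len = 0
                run_len += 1
            if not ok or s + 8 >= len(matches) + 8:
                if run_start is not None and run_len >= min_repeats:
                    raw.append(
                        DomainHit(
                            kind="LRR",
                            start=run_start,
                            end=run_start + 8 * run_len,
                            score=float(run_len),
                            repeats=run_len,
                        )
                    )
                run_start = None
                run_len = 0
            s += 8
    raw.sort(key=lambda h: (-h.score, h.start))
    accepted: list[DomainHit] = []
    for hit in raw:
        if not any(hit.overlaps(a) for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return accepted


_COILS_TABLE: dict[str, dict[str, float]] | None = None


def _coils_table() -> dict[str, dict[str, float]]:
    global _COILS_TABLE
    if _COILS_TABLE is None:
        base = resources.files("hrp") / "data"
        _COILS_TABLE = json.loads((base / "coils.json").read_text())
    return _COILS_TABLE


def coiled_coil_probabilities(
    protein: str, window: int = 21, steepness: float = 6.0, midpoint: float = 0.8
) -> np.ndarray:
    """Per-window coiled-coil probability (best register of 7).

    Window score is the geometric mean of per-position propensities (core
    table at heptad positions a/d, otherwise the non-core table), mapped to a
    probability with a logistic on the log geometric mean.
    """
    table = _coils_table()
    core = np.array([table["core"].get(a, 0.3) for a in protein])
    other = np.array([table["other"].get(a, 0.3) for a in protein])
    n = len(protein) - window + 1
    if n <= 0:
        return np.zeros(0)
    log_core = np.log(core)
    log_other = np.log(other)
    best = np.full(n, -np.inf)
    pos = np.arange(len(protein))
    for register in range(7):
        is_core = np.isin((pos + register) % 7, (0, 3))
        logs = np.where(is_core, log_core, log_other)
        csum = np.concatenate([[0.0], np.cumsum(logs)])
        mean_log = (csum[window:] - csum[:-window]) / window
        best = np.maximum(best, mean_log)
    return 1.0 / (1.0 + np.exp(-steepness * (best - midpoint)))


def detect_coiled_coil(
    protein: str, window: int = 21, prob_threshold: float = 0.5
) -> list[DomainHit]:
    """Coiled-coil segments: contiguous windows above ``prob_threshold`` are
    merged into one hit whose score is the peak probability."""
    probs = coiled_coil_probabilities(protein, window=window)
    hits: list[DomainHit] = []
    i = 0
    n = len(probs)
    while i < n:
        if probs[i] > prob_threshold:
            j = i
            while j < n and probs[j] > prob_threshold:
                j += 1
            hits.append(
                DomainHit(
                    kind="CC_COILS",
                    start=i,
                    end=j - 1 + window,
                    score=float(probs[i:j].max()),
                )
            )
            i = j
        else:
            i += 1
    return hits


def build_architecture(hits: list[DomainHit]) -> DomainArchitecture:
    """Assemble ordered domain evidence on one protein.

    Overlapping hits of the same kind keep the higher score (tie: smaller
    start); Rx-N and Coils evidence collapses to a single CC token at the
    earliest start of either.
    """
    by_kind: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_kind.setdefault(h.kind, []).append(h)
    kept: list[DomainHit] = []
    for kind, group in by_kind.items():
        group = sorted(group, key=lambda h: (-h.score, h.start))
        chosen: list[DomainHit] = []
        for h in group:
            if not any(h.overlaps(c) for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    cc = [h for h in kept if h.kind in ("CC_RXN", "CC_COILS")]
    rest = [h for h in kept if h.kind not in ("CC_RXN", "CC_COILS")]
    if cc:
        first = min(cc, key=lambda h: h.start)
        rest.append(
            DomainHit(
                kind="CC",
                start=first.start,
                end=max(h.end for h in cc),
                score=max(h.score for h in cc),
            )
        )
    rest.sort(key=lambda h: (h.start, h.end))
    arch = DomainArchitecture(kinds=[h.kind for h in rest], hits=rest)
    arch.class_label = classify_architecture(arch)
    arch.full_length = arch.class_label in ("CNL", "TNL", "RNL", "NL")
    return arch


def classify_architecture(arch: DomainArchitecture | list[str]) -> str:
    """Class label from the ordered domain kind list.

    Full-length means NB followed (later start) by LRR; the label is then
    CNL / TNL / RNL according to the earliest N-terminal domain (CC, TIR or
    RPW8) preceding NB, or NL when none is detected. Anything else is a
    partial label joining the ordered kinds with '-'; an empty architecture
    is "none".
    """
    kinds = arch if isinstance(arch, list) else arch.kinds
    if not kinds:
        return "none"
    nb_positions = [i for i, k in enumerate(kinds) if k == "NB"]
    for nb_i in nb_positions:
        if any(k == "LRR" for k in kinds[nb_i + 1 :]):
            for k in kinds[:nb_i]:
                if k in FULL_LENGTH_NTERM:
                    return FULL_LENGTH_NTERM[k]
            return "NL"
    return "-".join(kinds)


def annotate_protein(
    protein: str, library: ProfileLibrary, min_lrr_repeats: int = 3
) -> DomainArchitecture:
    """Run all detectors on one protein and assemble the architecture."""
    hits: list[DomainHit] = []
    for profile in library:
        hits.extend(scan_profile(protein, profile))
    hits.extend(detect_lrr(protein, min_repeats=min_lrr_repeats))
    hits.extend(detect_coiled_coil(protein))
    return build_architecture(hits)


def write_hits_tsv(hits_by_protein: dict[str, list[DomainHit]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tkind\tstart\tend\tscore\trepeats\n")
        for pid, hits in hits_by_protein.items():
            for h in sorted(hits, key=lambda x: x.start):
                fh.write(f"{pid}\t{h.kind}\t{h.start}\t{h.end}\t{h.score:.2f}\t{h.repeats}\n")
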