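"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: translation uses a
literal codon table, alignment a hand-rolled Gotoh DP, superposition a
numerical search over rotations, and ORF finding exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# --- translation -----------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> str:
    """Table-driven translation; stops at the first stop codon."""
    aas = []
    for i in range(0, len(cds) - 2, 3):
        aa = _CODON_TABLE[cds[i : i + 3].upper()]
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


# --- ORF enumeration -------------------------------------------------------


def find_orf_oracle(mrna: str) -> tuple[int, str] | None:
    """Enumerate every ATG..stop ORF; longest wins, ties to smallest start."""
    mrna = mrna.upper()
    best = None
    for start in range(len(mrna) - 2):
        if mrna[start : start + 3] != "ATG":
            continue
        for pos in range(start, len(mrna) - 2, 3):
            if _CODON_TABLE.get(mrna[pos : pos + 3]) == "*":
                cand = (pos + 3 - start, -start)
                if best is None or cand > best:
                    best = cand
                break
    if best is None:
        return None
    length, neg_start = best
    start = -neg_start
    return start, mrna[start : start + length]


# --- global affine alignment (Gotoh) --------------------------------------


def gotoh_score(a: str, b: str, sub, open_score: float, extend_score: float):
    """Optimal global alignment score with affine gaps.

    ``open_score`` is the score of the first gapped position and
    ``extend_score`` of each additional one (Biopython convention).
    """
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_score + (i - 1) * extend_score
    for j in range(1, m + 1):
        Y[0, j] = open_score + (j - 1) * extend_score
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_score, X[i - 1, j] + extend_score,
                          Y[i - 1, j] + open_score)
            Y[i, j] = max(M[i, j - 1] + open_score, Y[i, j - 1] + extend_score,
                          X[i, j - 1] + open_score)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def pairing_score(
    a: str, b: str, pairs, sub, open_score: float, extend_score: float
) -> float:
    """Score of the best global alignment whose match columns are ``pairs``."""

    def gap_cost(k: int) -> float:
        return 0.0 if k == 0 else open_score + (k - 1) * extend_score

    score = 0.0
    prev_a, prev_b = 0, 0
    for ai, bi in pairs:
        score += gap_cost(ai - 1 - prev_a) + gap_cost(bi - 1 - prev_b)
        score += sub[a[ai - 1], b[bi - 1]]
        prev_a, prev_b = ai, bi
    score += gap_cost(len(a) - prev_a) + gap_cost(len(b) - prev_b)
    return float(score)


# --- rotational minimization ----------------------------------------------


def min_rmsd_oracle(P: np.ndarray, Q: np.ndarray, n_starts: int = 60,
                    seed: int = 0) -> float:
    """Minimum RMSD over proper rotations via multi-start numeric search."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = P0 @ R.T - Q0
        return np.sqrt((d**2).sum() / len(P0))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=rng).as_rotvec() for _ in range(n_starts)
    ]
    for s in starts:
        res = minimize(rmsd_of, s, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)
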