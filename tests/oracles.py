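"""Independent brute-force oracles used to pin the analysis implementations.

Everything here is written from first principles — its own hard-coded
genetic code table, plain-Python loops, and dense linear algebra — and
deliberately shares no code path with the package (which builds its tables
from Biopython and computes with vectorised numpy / sklearn / scipy).
"""

import math

import numpy as np

# standard genetic code, written out by hand ('*' = stop)
ORACLE_CODE = {
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

ORACLE_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in ORACLE_CODE.items():
    if _aa not in "*MW":
        ORACLE_FAMILIES.setdefault(_aa, []).append(_codon)
for _aa in ORACLE_FAMILIES:
    ORACLE_FAMILIES[_aa].sort()


def enc_wright_oracle(counts: dict[str, float]) -> float:
    """Step-by-step Wright ENc on a codon->count mapping."""
    f_by_k: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in ORACLE_FAMILIES.items():
        k = len(codons)
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f_by_k[k].append((n * sum_p2 - 1.0) / (n - 1.0))
    fbar = {}
    for k, vals in f_by_k.items():
        fbar[k] = sum(vals) / len(vals) if vals else None
    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(fbar[k] is None or fbar[k] <= 0 for k in (2, 3, 4, 6)):
        return float("nan")
    enc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return min(enc, 61.0)


def _pseudo_ref(ref: dict[str, float]) -> dict[str, float]:
    out = dict(ref)
    for codons in ORACLE_FAMILIES.values():
        if any(ref.get(c, 0) == 0 for c in codons):
            for c in codons:
                out[c] = ref.get(c, 0) + 1.0
    return out


def milc_oracle(gene: dict[str, float], ref: dict[str, float]) -> float:
    ref = _pseudo_ref(ref)
    total_m = 0.0
    length = 0.0
    dof = 0.0
    for aa, codons in ORACLE_FAMILIES.items():
        n = sum(gene.get(c, 0) for c in codons)
        if n == 0:
            continue
        ref_total = sum(ref[c] for c in codons)
        m = 0.0
        for c in codons:
            nc = gene.get(c, 0)
            if nc > 0:
                m += nc * math.log((nc / n) / (ref[c] / ref_total))
        total_m += 2.0 * m
        length += n
        dof += len(codons) - 1
    correction = dof / length - 0.5
    return total_m / length - correction


def b_oracle(gene: dict[str, float], ref: dict[str, float]) -> float:
    ref = _pseudo_ref(ref)
    length = sum(gene.get(c, 0)
                 for codons in ORACLE_FAMILIES.values() for c in codons)
    b = 0.0
    for aa, codons in ORACLE_FAMILIES.items():
        n = sum(gene.get(c, 0) for c in codons)
        if n == 0:
            continue
        ref_total = sum(ref[c] for c in codons)
        dist = sum(abs(gene.get(c, 0) / n - ref[c] / ref_total)
                   for c in codons)
        b += (n / length) * dist
    return b


def rscu_oracle(counts: dict[str, float]) -> dict[str, float]:
    out = {}
    for aa, codons in ORACLE_FAMILIES.items():
        k = len(codons)
        n = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = 0.0 if n == 0 else counts.get(c, 0) / (n / k)
    return out


def pca_oracle(matrix: np.ndarray):
    """Centered PCA via eigendecomposition of the covariance matrix.

    Returns (scores, eigenvalues) with components ordered by decreasing
    variance; component signs are arbitrary.
    """
    x = matrix - matrix.mean(axis=0)
    cov = x.T @ x / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return x @ evecs[:, order], evals[order]


def linkage_oracle(points: np.ndarray, method: str) -> list[frozenset]:
    """Naive agglomerative clustering (single or complete linkage) on
    Euclidean distances; returns the merge history as sets of row indices.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []

    def dist(a, b):
        pair = [math.dist(points[i], points[j]) for i in a for j in b]
        return min(pair) if method == "single" else max(pair)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return merges
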