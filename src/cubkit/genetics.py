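"""Standard genetic code tables and the synonymous-family structure.

Every downstream statistic (RSCU, ENc, CAI, MILC, ...) shares the codon
ordering and the family partition defined here.  The code is fixed to the
standard nuclear genetic code (NCBI translation table 1): 61 sense codons,
3 stops, and 18 synonymous families once the single-codon amino acids
Met (ATG) and Trp (TGG) are set aside — 9 two-fold, 1 three-fold (Ile),
5 four-fold (Val, Pro, Thr, Ala, Gly) and 3 six-fold (Leu, Ser, Arg)
families covering 59 codons.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

_aa_to_codons: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _aa_to_codons.setdefault(CODON_TO_AA[_codon], []).append(_codon)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(cs)) for aa, cs in sorted(_aa_to_codons.items())
}

SINGLE_CODON_AAS = frozenset(aa for aa, cs in AA_TO_CODONS.items() if len(cs) == 1)
#: amino acid -> synonymous codons, multi-codon families only (18 families, 59 codons)
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: cs for aa, cs in AA_TO_CODONS.items() if len(cs) >= 2
}
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in FAMILIES.items()}
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in FAMILIES if DEGENERACY[aa] == k) for k in (2, 3, 4, 6)
}
FOURFOLD_AAS = frozenset(DEGENERACY_CLASSES[4])

#: the 59 family codons in fixed lexicographic order (column order of all wide tables)
FAMILY_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if c in CODON_TO_AA and CODON_TO_AA[c] in FAMILIES
)
FAMILY_CODON_IDS = np.array([CODON_INDEX[c] for c in FAMILY_CODONS])

#: codons excluded from RSCU-style matrices by default: Met, Trp and the stops
DEFAULT_EXCLUDED_CODONS: tuple[str, ...] = ("ATG", "TAA", "TAG", "TGA", "TGG")

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in BASES for b in BASES)

# ---------------------------------------------------------------------------
# integer-encoded views used by the vectorised shuffling / counting kernels
# ---------------------------------------------------------------------------

#: (64, 3) base index of each codon position
CODON_BASE_IDX = np.array(
    [[BASE_INDEX[b] for b in c] for c in CODONS], dtype=np.int8
)

# synonymous groups for sequence randomisation: the 18 families, Met, Trp,
# and the stop codons as one interchangeable group (21 groups total)
_groups: list[tuple[str, tuple[str, ...]]] = [(aa, cs) for aa, cs in FAMILIES.items()]
_groups += [("M", AA_TO_CODONS["M"]), ("W", AA_TO_CODONS["W"]), ("*", STOP_CODONS)]
GROUP_NAMES = tuple(name for name, _ in _groups)
GROUP_MEMBERS = [np.array([CODON_INDEX[c] for c in cs]) for _, cs in _groups]
GROUP_OF_CODON = np.empty(64, dtype=np.int8)
for _gid, (_name, _cs) in enumerate(_groups):
    for _c in _cs:
        GROUP_OF_CODON[CODON_INDEX[_c]] = _gid
GROUP_SIZE = np.array([len(m) for m in GROUP_MEMBERS])

# (64, max_family) member table for uniform synonymous resampling
_maxk = int(GROUP_SIZE.max())
SYN_MEMBER_TABLE = np.zeros((64, _maxk), dtype=np.int8)
SYN_FAMILY_SIZE = np.zeros(64, dtype=np.int8)
for _i in range(64):
    _members = GROUP_MEMBERS[GROUP_OF_CODON[_i]]
    SYN_MEMBER_TABLE[_i, : len(_members)] = _members
    SYN_FAMILY_SIZE[_i] = len(_members)

_BASE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i

_IDX_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = _BASE_LUT[raw]
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode_bases(arr: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`."""
    return _IDX_TO_BASE[np.asarray(arr, dtype=np.int8)].tobytes().decode()


def codons_to_ids(codons) -> np.ndarray:
    """Map an iterable of codon strings to integer codon ids (0..63)."""
    return np.array([CODON_INDEX[c] for c in codons], dtype=np.int8)


def bases_to_codon_ids(bases: np.ndarray) -> np.ndarray:
    """Fold a base-index array (length divisible by 3) into codon ids."""
    b = bases.reshape(-1, 3).astype(np.int16)
    return (b[:, 0] * 16 + b[:, 1] * 4 + b[:, 2]).astype(np.int8)


def codon_ids_to_bases(codon_ids: np.ndarray) -> np.ndarray:
    """Expand codon ids back into a flat base-index array."""
    return CODON_BASE_IDX[np.asarray(codon_ids, dtype=np.int8)].ravel()


def translate_ids(codon_ids: np.ndarray) -> str:
    """Translate codon ids to a protein string ('*' for stops)."""
    out = []
    for cid in np.asarray(codon_ids):
        codon = CODONS[int(cid)]
        out.append(CODON_TO_AA.get(codon, "*"))
    return "".join(out)
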