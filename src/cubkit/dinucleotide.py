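"""Dinucleotide over-/under-representation by permutation z-scores.

For each coding sequence the observed count of each of the 16 overlapping
dinucleotides (all three reading frames, i.e. codon positions 1-2, 2-3 and
3-1 of the next codon) is compared against a null distribution obtained by
randomising the sequence under one of three models:

base
    shuffle (replace=False) or resample (replace=True) individual bases;
codon
    shuffle or resample whole codons, preserving the reading frame;
syncodon
    replace each codon by a synonymous one (same amino acid under the
    standard code), preserving the protein exactly.  With replace=True a
    codon is drawn uniformly from its family; with replace=False the gene's
    own codons are permuted within each family, preserving codon counts.

The statistic is a count-based z-score:
``z_d = (obs_d - mean_perm(d)) / sd_perm(d)`` with the sample (n-1) standard
deviation over the permutation replicates.  Cells whose permutation
distribution is degenerate (sd = 0) are reported as NaN, not 0.
"""

from __future__ import annotations

import logging
import zlib
from typing import Iterable

import numpy as np
import pandas as pd

from .genetics import (
    DINUCLEOTIDES,
    GROUP_OF_CODON,
    SYN_FAMILY_SIZE,
    SYN_MEMBER_TABLE,
    codon_ids_to_bases,
    encode_bases,
)
from .seqio import CDSRecord, OrganismCollection

logger = logging.getLogger(__name__)

MODELS = ("base", "codon", "syncodon")


def dinuc_counts(seq) -> np.ndarray:
    """Overlapping dinucleotide counts (5'->3'), length-16 vector in
    lexicographic order AA, AC, ..., TT.  Sums to len(seq) - 1."""
    if isinstance(seq, str):
        arr = encode_bases(seq)
    else:
        arr = np.asarray(seq, dtype=np.int8)
    if arr.size < 2:
        logger.warning("sequence shorter than 2 nt: all dinucleotide counts zero")
        return np.zeros(16, dtype=np.int64)
    pairs = arr[:-1].astype(np.int16) * 4 + arr[1:]
    return np.bincount(pairs, minlength=16).astype(np.int64)


def _record_rng(global_seed: int, organism: str, rec_id: str) -> np.random.Generator:
    # stable per-record stream independent of collection order
    tag = zlib.crc32(f"{organism}\x00{rec_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(global_seed), tag]))


class _Shuffler:
    """Precomputed randomisation kernel for one record."""

    def __init__(self, record: CDSRecord, model: str, replace: bool):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        self.model = model
        self.replace = replace
        self.bases = encode_bases(record.nucleotides)
        self.codon_ids = record.codon_ids()
        if model == "syncodon":
            groups = GROUP_OF_CODON[self.codon_ids]
            # positions sorted by synonymous group; permuting position order
            # within groups realises a uniform within-family shuffle
            self._by_group = np.argsort(groups, kind="stable")
            self._groups = groups
            self._sorted_codons = self.codon_ids[self._by_group]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One randomised base-index array."""
        if self.model == "base":
            if self.replace:
                return rng.choice(self.bases, size=self.bases.size, replace=True)
            return rng.permutation(self.bases)
        if self.model == "codon":
            n = self.codon_ids.size
            idx = (rng.integers(0, n, size=n) if self.replace
                   else rng.permutation(n))
            return codon_ids_to_bases(self.codon_ids[idx])
        # syncodon
        if self.replace:
            sizes = SYN_FAMILY_SIZE[self.codon_ids]
            pick = np.floor(rng.random(self.codon_ids.size) * sizes).astype(int)
            new = SYN_MEMBER_TABLE[self.codon_ids, pick]
            return codon_ids_to_bases(new)
        keys = rng.random(self.codon_ids.size)
        order = np.lexsort((keys, self._groups))
        new = np.empty_like(self.codon_ids)
        new[order] = self._sorted_codons
        return codon_ids_to_bases(new)


def shuffle_null(
    record: CDSRecord,
    model: str,
    replace: bool = False,
    rng: np.random.Generator | None = None,
) -> str:
    """One randomised sequence from the chosen null model."""
    if rng is None:
        rng = np.random.default_rng()
    from .genetics import decode_bases

    return decode_bases(_Shuffler(record, model, replace).draw(rng))


def zscores_for_record(
    record: CDSRecord,
    model: str,
    permutations: int = 100,
    replace: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Length-16 z-score vector for one record (NaN where sd = 0)."""
    if permutations < 2:
        raise ValueError("permutations must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    shuf = _Shuffler(record, model, replace)
    obs = dinuc_counts(shuf.bases).astype(float)
    perm = np.empty((permutations, 16))
    for i in range(permutations):
        perm[i] = dinuc_counts(shuf.draw(rng))
    mean = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    return z


def dinuc_zscores(
    collections: Iterable[OrganismCollection],
    model: str = "base",
    permutations: int = 100,
    replace: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-record dinucleotide z-score table.

    One row per (organism, id) with 16 z columns plus model / permutations /
    seed / replace metadata.  Each record gets its own RNG stream derived
    from ``(seed, organism, id)``, so results do not depend on collection
    order and a fixed seed is bit-reproducible.
    """
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        for rec in coll.records:
            rng = _record_rng(seed, coll.name, rec.id)
            z = zscores_for_record(rec, model, permutations, replace, rng)
            if np.isnan(z).any():
                logger.warning(
                    "%s/%s: %d dinucleotide cells degenerate under the %s null",
                    coll.name, rec.id, int(np.isnan(z).sum()), model,
                )
            rows.append([coll.name, rec.id, *z.tolist()])
    df = pd.DataFrame(rows, columns=["organism", "id", *DINUCLEOTIDES])
    df["model"] = model
    df["permutations"] = permutations
    df["seed"] = seed
    df["replace"] = replace
    return df
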