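"""Nucleotide composition: positional GC content, PR2 coordinates and the
neutrality (GC12 ~ GC3) regression.

These are the classical diagnostics for separating mutation pressure from
selection: under pure mutational drift GC12 tracks GC3 with slope near 1,
and third-position purine/pyrimidine parity holds (PR2 point at 0.5, 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import CODON_BASE_IDX, CODON_TO_AA, CODONS, FOURFOLD_AAS
from .seqio import CDSRecord, OrganismCollection

logger = logging.getLogger(__name__)

# base indices: A=0, C=1, G=2, T=3
_IS_GC = np.array([False, True, True, False])
_FOURFOLD_CODON = np.array(
    [CODON_TO_AA.get(c) in FOURFOLD_AAS for c in CODONS]
)


@dataclass(frozen=True)
class GCMetrics:
    gc_all: float
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


@dataclass(frozen=True)
class ThirdPositionCounts:
    a3: int
    t3: int
    g3: int
    c3: int
    fold4_only: bool = False

    @property
    def total(self) -> int:
        return self.a3 + self.t3 + self.g3 + self.c3


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int
    stderr: float = float("nan")


def gc_metrics(record: CDSRecord) -> GCMetrics:
    """GC fraction overall and at each codon position."""
    ids = record.codon_ids()
    if ids.size == 0:
        raise ValueError(f"record {record.id} has no codons")
    bases = CODON_BASE_IDX[ids]  # (n_codons, 3)
    gc = _IS_GC[bases]
    g1, g2, g3 = gc.mean(axis=0)
    return GCMetrics(gc_all=float(gc.mean()), gc1=float(g1),
                     gc2=float(g2), gc3=float(g3))


def gc_table(collections: Iterable[OrganismCollection]) -> pd.DataFrame:
    """Per-record GC metrics: (organism, id, gc_all, gc1, gc2, gc3, gc12)."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        for rec in coll.records:
            if rec.aa_length == 0:
                logger.warning("%s/%s skipped: zero codons", coll.name, rec.id)
                continue
            m = gc_metrics(rec)
            rows.append((coll.name, rec.id, m.gc_all, m.gc1, m.gc2, m.gc3, m.gc12))
    return pd.DataFrame(
        rows, columns=["organism", "id", "gc_all", "gc1", "gc2", "gc3", "gc12"]
    )


def third_position_counts(
    record: CDSRecord, fold4_only: bool = False
) -> ThirdPositionCounts:
    """Base counts at codon position 3.

    With ``fold4_only`` the tally is restricted to codons of the five
    fourfold-degenerate families (Val, Pro, Thr, Ala, Gly), where the third
    base is free of amino-acid constraint; six-fold families' four-fold
    sub-boxes are not included.
    """
    ids = record.codon_ids()
    if fold4_only:
        ids = ids[_FOURFOLD_CODON[ids]]
    third = CODON_BASE_IDX[ids, 2] if ids.size else np.empty(0, dtype=np.int8)
    counts = np.bincount(third, minlength=4)
    return ThirdPositionCounts(a3=int(counts[0]), t3=int(counts[3]),
                               g3=int(counts[2]), c3=int(counts[1]),
                               fold4_only=fold4_only)


def pr2_point(counts: ThirdPositionCounts) -> tuple[float, float]:
    """Parity-rule-2 coordinates: x = G3/(G3+C3), y = A3/(A3+T3).

    (0.5, 0.5) is the parity origin where A equals T and G equals C.
    """
    gc = counts.g3 + counts.c3
    at = counts.a3 + counts.t3
    if gc == 0 or at == 0:
        raise ValueError("PR2 point undefined: zero G3+C3 or A3+T3")
    return counts.g3 / gc, counts.a3 / at


def pr2_table(
    collections: Iterable[OrganismCollection], fold4_only: bool = True
) -> pd.DataFrame:
    """PR2 coordinates per record; undefined records are excluded with a warning."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        for rec in coll.records:
            counts = third_position_counts(rec, fold4_only=fold4_only)
            try:
                x, y = pr2_point(counts)
            except ValueError:
                logger.warning("%s/%s excluded from PR2: no qualifying codons",
                               coll.name, rec.id)
                continue
            rows.append((coll.name, rec.id, x, y))
    return pd.DataFrame(rows, columns=["organism", "id", "gc_bias", "at_bias"])


def neutrality_fit(gc12, gc3) -> NeutralityFit:
    """OLS regression of per-gene GC12 on GC3.

    Slope near 1 indicates mutation pressure acting uniformly across codon
    positions; slope near 0 indicates selection constraining positions 1-2.
    """
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    if gc12.shape != gc3.shape:
        raise ValueError("gc12 and gc3 must be paired vectors")
    if gc12.size < 3:
        raise ValueError("neutrality fit requires at least 3 genes")
    if np.ptp(gc3) == 0:
        raise ValueError("GC3 is constant; neutrality slope undefined")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue) ** 2, pvalue=float(res.pvalue),
                         n=int(gc12.size), stderr=float(res.stderr))


def neutrality_table(gc: pd.DataFrame) -> pd.DataFrame:
    """One neutrality fit per organism from a per-record GC table."""
    rows = []
    for organism, sub in gc.groupby("organism", sort=False):
        try:
            fit = neutrality_fit(sub["gc12"], sub["gc3"])
        except ValueError as exc:
            logger.warning("neutrality fit skipped for %s: %s", organism, exc)
            continue
        rows.append((organism, fit.slope, fit.intercept, fit.r2,
                     fit.pvalue, fit.n))
    return pd.DataFrame(
        rows, columns=["organism", "slope", "intercept", "r2", "pvalue", "n"]
    )
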