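"""Gene-level codon usage bias indices.

All indices operate on length-64 codon count vectors (lexicographic codon
order, see :mod:`cubkit.genetics`).  Synonymous-family statistics use the
18 multi-codon families (59 codons); ATG, TGG and the stop codons never
enter them.  Host-requiring indices (CAI, MELP, FOP, E) take the pooled
codon counts of a host reference set, ideally highly expressed genes;
MILC, B and MCB fall back to the organism's own pooled counts when no host
is given.

Zero counts in a reference are handled by a single family-level pseudocount
policy: whenever any codon of a family has zero reference count, 1 is added
to every codon of that family (logged).  This keeps reference frequencies
strictly positive without changing families that are fully observed.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .genetics import (
    CODON_INDEX,
    DEGENERACY_CLASSES,
    FAMILIES,
    FAMILY_CODONS,
)
from .seqio import OrganismCollection

logger = logging.getLogger(__name__)

#: per family: (amino acid, degeneracy, codon id array)
FAMILY_INDEX = [
    (aa, len(cs), np.array([CODON_INDEX[c] for c in cs]))
    for aa, cs in FAMILIES.items()
]
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}
_POS_IN_59 = {CODON_INDEX[c]: i for i, c in enumerate(FAMILY_CODONS)}
#: per family: positions of its codons within the 59-codon order
FAMILY_POS = {aa: np.array([_POS_IN_59[int(i)] for i in ids])
              for aa, _, ids in FAMILY_INDEX}


def as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (64,):
        raise ValueError("expected a length-64 codon count vector")
    if (arr < 0).any():
        raise ValueError("codon counts must be non-negative")
    return arr


def family_pseudocount(reference) -> np.ndarray:
    """Reference counts with +1 added to every codon of any family that
    contains a zero-count member."""
    ref = as_counts(reference).copy()
    for aa, k, ids in FAMILY_INDEX:
        if (ref[ids] == 0).any():
            logger.info("pseudocount applied to reference family %s", aa)
            ref[ids] += 1.0
    return ref


# ---------------------------------------------------------------------------
# effective number of codons
# ---------------------------------------------------------------------------

def enc_wright(counts) -> float:
    """Wright's effective number of codons.

    Per amino acid with n >= 2 codons observed, the codon homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); class averages over amino acids of
    degeneracy k give ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.
    Missing classes: an empty three-fold class is replaced by the mean of
    the two- and four-fold averages; an empty (or zero) two-, four- or
    six-fold class leaves plain ENc undefined (NaN) — use
    :func:`enc_modified` for short genes.
    """
    c = as_counts(counts)
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n < 2:
            continue
        p = c[ids] / n
        f = (n * (p ** 2).sum() - 1.0) / (n - 1.0)
        f_by_class[k].append(f)
    fbar: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        vals = f_by_class[k]
        fbar[k] = float(np.mean(vals)) if vals else np.nan
    if np.isnan(fbar[3]) and not (np.isnan(fbar[2]) or np.isnan(fbar[4])):
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(np.isnan(fbar[k]) or fbar[k] <= 0 for k in (2, 3, 4, 6)):
        return float("nan")
    enc = 2.0 + sum(_CLASS_SIZES[k] / fbar[k] for k in (2, 3, 4, 6))
    return min(enc, 61.0)


def enc_modified(counts) -> float:
    """Pseudocounted effective number of codons.

    Family homozygosity is computed from pseudocounted frequencies
    p~_i = (n_i + 1) / (n + k), so every family (including absent ones,
    which become uniform) contributes and the estimator is defined for any
    non-empty gene.  Class aggregation and the cap at 61 follow
    :func:`enc_wright`.
    """
    c = as_counts(counts)
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        p = (c[ids] + 1.0) / (n + k)
        f_by_class[k].append(float((p ** 2).sum()))
    enc = 2.0 + sum(
        _CLASS_SIZES[k] / float(np.mean(f_by_class[k])) for k in (2, 3, 4, 6)
    )
    return min(enc, 61.0)


# ---------------------------------------------------------------------------
# reference-based indices
# ---------------------------------------------------------------------------

def milc(counts, reference, return_correction: bool = False):
    """MILC: Measure Independent of Length and Composition.

    Per amino acid, M_a = 2 * sum_c n_c * ln(f_c / g_c), with f the gene's
    within-family codon frequencies and g the reference's; MILC is
    sum_a M_a / L minus the correction C = sum_a (k_a - 1)/L - 0.5, where L
    is the number of family codons in the gene and the sums run over amino
    acids present in it.
    """
    c = as_counts(counts)
    ref = family_pseudocount(reference)
    total_m = 0.0
    length = 0.0
    dof = 0.0
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n == 0:
            continue
        f = c[ids] / n
        g = ref[ids] / ref[ids].sum()
        used = c[ids] > 0
        total_m += 2.0 * float((c[ids][used] * np.log(f[used] / g[used])).sum())
        length += n
        dof += k - 1
    if length == 0:
        return (float("nan"), float("nan")) if return_correction else float("nan")
    correction = dof / length - 0.5
    value = total_m / length - correction
    if return_correction:
        return value, correction
    return value


def b_index(counts, reference) -> float:
    """Karlin-Mrazek codon usage difference B(gene | reference).

    B = sum_a p_a * sum_c |f(c|a, gene) - f(c|a, ref)| with p_a the amino
    acid frequency among the gene's family codons; range [0, 2].
    """
    c = as_counts(counts)
    ref = family_pseudocount(reference)
    length = sum(c[ids].sum() for _, _, ids in FAMILY_INDEX)
    if length == 0:
        return float("nan")
    b = 0.0
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n == 0:
            continue
        f = c[ids] / n
        g = ref[ids] / ref[ids].sum()
        b += (n / length) * float(np.abs(f - g).sum())
    return b


def mcb(counts, reference) -> float:
    """Maximum-likelihood codon bias (Urrutia & Hurst).

    Per amino acid with n_a >= 2, B_a = sum_c (f_c - g_c)^2 / g_c; the gene
    statistic is sum_a B_a * log10(n_a) / sum_a n_a.  Zero when the gene
    matches the reference frequencies, non-negative otherwise.
    """
    c = as_counts(counts)
    ref = family_pseudocount(reference)
    num = 0.0
    den = 0.0
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n < 2:
            continue
        f = c[ids] / n
        g = ref[ids] / ref[ids].sum()
        num += float(((f - g) ** 2 / g).sum()) * np.log10(n)
        den += n
    if den == 0:
        return float("nan")
    return num / den


def cai_weights(reference) -> pd.Series:
    """Sharp-Li relative adaptiveness weights from a reference count table.

    w_c = n_c / max over the codon's family, computed on pseudocounted
    reference counts; family maxima are exactly 1 and all weights positive.
    """
    ref = family_pseudocount(reference)
    w = pd.Series(0.0, index=list(FAMILY_CODONS))
    for aa, k, ids in FAMILY_INDEX:
        fam = ref[ids]
        w.iloc[FAMILY_POS[aa]] = fam / fam.max()
    return w


def cai(counts, weights: pd.Series) -> float:
    """Codon adaptation index: count-weighted geometric mean of the
    reference weights over the gene's family codons (ATG/TGG/stops excluded).
    """
    c = as_counts(counts)
    w = weights.reindex(list(FAMILY_CODONS)).to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("CAI weights must be strictly positive")
    ids = np.array([CODON_INDEX[cod] for cod in FAMILY_CODONS])
    n = c[ids]
    total = n.sum()
    if total == 0:
        return float("nan")
    return float(np.exp((n * np.log(w)).sum() / total))


def optimal_codons(reference) -> frozenset[str]:
    """The most frequent reference codon of each family (ties: all tied
    codons are optimal, logged)."""
    ref = family_pseudocount(reference)
    optimal: set[str] = set()
    for aa, k, ids in FAMILY_INDEX:
        fam = ref[ids]
        best = fam == fam.max()
        if best.sum() > 1:
            logger.info("FOP: tie in family %s; %d codons marked optimal",
                        aa, int(best.sum()))
        optimal.update(FAMILY_CODONS[p] for p in FAMILY_POS[aa][best])
    return frozenset(optimal)


def fop(counts, optimal_set: Iterable[str]) -> float:
    """Frequency of optimal codons among the gene's family codons."""
    c = as_counts(counts)
    optimal_set = set(optimal_set)
    total = 0.0
    opt = 0.0
    for codon in FAMILY_CODONS:
        n = c[CODON_INDEX[codon]]
        total += n
        if codon in optimal_set:
            opt += n
    if total == 0:
        return float("nan")
    return opt / total


def melp(counts, host_reference, self_reference) -> float:
    """MILC-based expression level predictor.

    MELP = MILC(gene | organism background) / MILC(gene | host reference);
    values above 1 suggest reference-like (putatively highly expressed)
    codon usage.  Undefined (NaN) when the denominator MILC is <= 0.
    """
    num = milc(counts, self_reference)
    den = milc(counts, host_reference)
    if not np.isfinite(den) or den <= 0:
        logger.warning("MELP undefined: host-referenced MILC = %s", den)
        return float("nan")
    return num / den


def e_index(counts, host_reference, self_reference) -> float:
    """Karlin-Mrazek expression measure.

    E = B(gene | organism background) / B(gene | host reference); above 1
    indicates usage closer to the reference set than to the background.
    A gene identical to both usages yields 1 by convention.
    """
    num = b_index(counts, self_reference)
    den = b_index(counts, host_reference)
    if den == 0:
        if num == 0:
            return 1.0
        logger.warning("E undefined: zero host-referenced B with nonzero background B")
        return float("nan")
    return num / den


def rscu(counts) -> pd.Series:
    """Relative synonymous codon usage over the 59 family codons.

    RSCU_c = n_c / ((1/k) * family total); a family with zero total gets
    RSCU 0 for all members (flagged via log).  Nonzero families sum to k.
    """
    c = as_counts(counts)
    out = pd.Series(0.0, index=list(FAMILY_CODONS))
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n == 0:
            logger.debug("RSCU family %s absent; members set to 0", aa)
            continue
        vals = c[ids] / (n / k)
        out.iloc[FAMILY_POS[aa]] = vals
    return out


# ---------------------------------------------------------------------------
# collection-level tables
# ---------------------------------------------------------------------------

def _per_record_table(collections, fn, index_name, reference_used):
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        for rec in coll.records:
            rows.append((coll.name, rec.id, fn(coll, rec)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = reference_used
    df.attrs["index"] = index_name
    return df


def enc_table(collections, modified: bool = False) -> pd.DataFrame:
    fn = enc_modified if modified else enc_wright
    name = "enc_modified" if modified else "enc"
    return _per_record_table(
        collections, lambda coll, rec: fn(rec.codon_counts()), name, "none"
    )


def _host_or_self(collections, host):
    """Yield (collection, reference counts) pairs, caching pooled counts."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    host_counts = host.pooled_counts() if host is not None else None
    for coll in collections:
        ref = host_counts if host_counts is not None else coll.pooled_counts()
        yield coll, ref


def milc_table(collections, host: OrganismCollection | None = None) -> pd.DataFrame:
    rows = []
    for coll, ref in _host_or_self(collections, host):
        for rec in coll.records:
            rows.append((coll.name, rec.id, milc(rec.codon_counts(), ref)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = "host" if host is not None else "none"
    df.attrs["index"] = "milc"
    return df


def b_table(collections, host: OrganismCollection | None = None) -> pd.DataFrame:
    rows = []
    for coll, ref in _host_or_self(collections, host):
        for rec in coll.records:
            rows.append((coll.name, rec.id, b_index(rec.codon_counts(), ref)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = "host" if host is not None else "none"
    df.attrs["index"] = "b"
    return df


def mcb_table(collections, host: OrganismCollection | None = None) -> pd.DataFrame:
    rows = []
    for coll, ref in _host_or_self(collections, host):
        for rec in coll.records:
            rows.append((coll.name, rec.id, mcb(rec.codon_counts(), ref)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = "host" if host is not None else "none"
    df.attrs["index"] = "mcb"
    return df


def _require_host(host, index_name):
    if host is None:
        raise ValueError(
            f"{index_name} requires a host reference gene set and cannot "
            f"operate without it"
        )


def cai_table(collections, host: OrganismCollection) -> pd.DataFrame:
    _require_host(host, "CAI")
    weights = cai_weights(host.pooled_counts())
    return _per_record_table(
        collections, lambda coll, rec: cai(rec.codon_counts(), weights),
        "cai", "host",
    )


def melp_table(collections, host: OrganismCollection) -> pd.DataFrame:
    _require_host(host, "MELP")
    host_counts = host.pooled_counts()
    rows = []
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    for coll in collections:
        self_counts = coll.pooled_counts()
        for rec in coll.records:
            rows.append((coll.name, rec.id,
                         melp(rec.codon_counts(), host_counts, self_counts)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = "host"
    df.attrs["index"] = "melp"
    return df


def fop_table(collections, host: OrganismCollection) -> pd.DataFrame:
    _require_host(host, "FOP")
    optimal = optimal_codons(host.pooled_counts())
    return _per_record_table(
        collections, lambda coll, rec: fop(rec.codon_counts(), optimal),
        "fop", "host",
    )


def e_table(collections, host: OrganismCollection) -> pd.DataFrame:
    _require_host(host, "E")
    host_counts = host.pooled_counts()
    rows = []
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    for coll in collections:
        self_counts = coll.pooled_counts()
        for rec in coll.records:
            rows.append((coll.name, rec.id,
                         e_index(rec.codon_counts(), host_counts, self_counts)))
    df = pd.DataFrame(rows, columns=["organism", "id", "value"])
    df["reference_used"] = "host"
    df.attrs["index"] = "e"
    return df


def rscu_table(collections, per: str = "sequence") -> pd.DataFrame:
    """Wide RSCU table: 59 codon columns in fixed lexicographic order.

    ``per='sequence'`` gives one row per record (index: organism, id);
    ``per='organism'`` gives the organism mean of per-sequence RSCU.
    """
    if per not in ("sequence", "organism"):
        raise ValueError("per must be 'sequence' or 'organism'")
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    index = []
    for coll in collections:
        for rec in coll.records:
            rows.append(rscu(rec.codon_counts()))
            index.append((coll.name, rec.id))
    df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["organism", "id"])
    )
    if per == "organism":
        df = df.groupby(level="organism", sort=False).mean()
    return df
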