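"""Parasite-host codon co-adaptation: the similarity index (SiD) and the
relative codon deoptimization index (RCDI).

SiD compares a parasite's RSCU profile with the host's through a cosine:
SiD = (1 - R)/2 with R = cos(rscu_parasite, rscu_host), so 0 means
identical relative codon preferences and 0.5 maximal divergence.  RCDI
compares a gene's within-family codon frequencies to the host's; 1 means
host-matched usage and values above 1 increasing deoptimization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cub_indices import FAMILY_INDEX, FAMILY_POS, as_counts, rscu_table
from .genetics import FAMILY_CODONS
from .seqio import OrganismCollection

logger = logging.getLogger(__name__)


def sid(rscu_parasite, rscu_host) -> float:
    """Similarity index between two RSCU vectors on the common 59-codon order.

    R = a.b / sqrt(|a|^2 |b|^2); SiD = (1 - R)/2, in [0, 0.5] for the
    non-negative RSCU vectors.
    """
    a = np.asarray(rscu_parasite, dtype=float)
    b = np.asarray(rscu_host, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RSCU vectors must share the same codon order")
    na = np.sqrt((a ** 2).sum())
    nb = np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        raise ValueError("SiD undefined for a zero-norm RSCU vector")
    if np.array_equal(a, b):
        return 0.0
    r = min(float(a @ b) / (na * nb), 1.0)
    return (1.0 - r) / 2.0


def sid_table(
    collections, host: OrganismCollection, per_sequence: bool = False
) -> pd.DataFrame:
    """SiD of each parasite organism against the host.

    By default the organism-mean parasite RSCU is compared against the
    host-mean RSCU (one row per organism); ``per_sequence`` reports one row
    per parasite record instead.
    """
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    host_rscu = rscu_table(host, per="organism").iloc[0].to_numpy()
    rows = []
    if per_sequence:
        wide = rscu_table(collections, per="sequence")
        for (organism, rec_id), vec in wide.iterrows():
            rows.append((organism, rec_id, sid(vec.to_numpy(), host_rscu)))
        return pd.DataFrame(rows, columns=["organism", "id", "sid"])
    wide = rscu_table(collections, per="organism")
    for organism, vec in wide.iterrows():
        rows.append((organism, sid(vec.to_numpy(), host_rscu)))
    return pd.DataFrame(rows, columns=["organism", "sid"])


def host_frequencies(reference) -> pd.Series:
    """Within-family relative codon frequencies of a reference count table.

    CiF_h(c) = n_c / family total, after the family pseudocount (any family
    with a zero-count member gets +1 on every member), so all frequencies
    are strictly positive and each family sums to 1.
    """
    ref = as_counts(reference).copy()
    out = pd.Series(0.0, index=list(FAMILY_CODONS))
    for aa, k, ids in FAMILY_INDEX:
        fam = ref[ids]
        if (fam == 0).any():
            logger.info("host frequencies: pseudocount applied to family %s", aa)
            fam = fam + 1.0
        out.iloc[FAMILY_POS[aa]] = fam / fam.sum()
    return out


def rcdi(counts, host_freqs: pd.Series) -> float:
    """Relative codon deoptimization index of one gene against host usage.

    RCDI = sum_c (CiF_a(c) / CiF_h(c)) * N_c / N over the gene's family
    codons (ATG, TGG and stops excluded), where CiF_a is the gene's
    within-family relative frequency of codon c, N_c its count and N the
    total family-codon count.  Equals 1 when the gene matches host usage.
    """
    c = as_counts(counts)
    h = host_freqs.reindex(list(FAMILY_CODONS)).to_numpy(dtype=float)
    if (h <= 0).any():
        raise ValueError("host frequencies must be strictly positive")
    total = 0.0
    acc = 0.0
    for aa, k, ids in FAMILY_INDEX:
        n = c[ids].sum()
        if n == 0:
            continue
        cif_gene = c[ids] / n
        cif_host = h[FAMILY_POS[aa]]
        acc += float(((cif_gene / cif_host) * c[ids]).sum())
        total += n
    if total == 0:
        return float("nan")
    return acc / total


def rcdi_table(collections, host: OrganismCollection) -> pd.DataFrame:
    """RCDI per parasite record against the host's pooled codon frequencies."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    freqs = host_frequencies(host.pooled_counts())
    rows = []
    for coll in collections:
        for rec in coll.records:
            rows.append((coll.name, rec.id, rcdi(rec.codon_counts(), freqs)))
    return pd.DataFrame(rows, columns=["organism", "id", "rcdi"])
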