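"""Reading, validating and quality-filtering FASTA coding sequences.

An analysis run works on many parasite collections (one FASTA file per
organism, file name = organism name) plus exactly one host collection of
reference CDS.  Validation is a reported outcome, never an exception: every
parsed record ends up in the QC report as retained, rejected (with a
reason) or filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetics import CODON_INDEX, STOP_CODONS, codons_to_ids

logger = logging.getLogger(__name__)

QC_COLUMNS = ["organism", "id", "aa_length", "status", "reason"]


@dataclass(frozen=True)
class CDSRecord:
    """One validated coding sequence, decomposed into codons."""

    id: str
    organism: str
    nucleotides: str
    codons: tuple[str, ...]
    internal_stops: bool = False

    @property
    def aa_length(self) -> int:
        return len(self.codons)

    def codon_ids(self) -> np.ndarray:
        return codons_to_ids(self.codons)

    def codon_counts(self) -> np.ndarray:
        """Counts over the 64 codons, lexicographic order."""
        counts = np.zeros(64, dtype=np.int64)
        for c in self.codons:
            counts[CODON_INDEX[c]] += 1
        return counts


@dataclass
class OrganismCollection:
    """A named set of CDS records for one organism."""

    name: str
    records: list[CDSRecord]
    role: str = "parasite"  # parasite | host
    qc: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=QC_COLUMNS)
    )

    def __len__(self) -> int:
        return len(self.records)

    def pooled_counts(self) -> np.ndarray:
        """Pooled codon counts over all records."""
        counts = np.zeros(64, dtype=np.int64)
        for rec in self.records:
            counts += rec.codon_counts()
        return counts


@dataclass(frozen=True)
class ValidationPolicy:
    """How raw sequences are cleaned before codon decomposition.

    drop_trailing
        Drop a trailing 1-2 nt partial codon (with a warning) instead of
        rejecting the record.
    reject_ambiguous
        Reject any sequence containing a non-ACGT character after
        upper-casing; records are never silently altered.
    flag_internal_stops
        Keep records with in-frame internal stop codons but mark them.
        Stops never enter synonymous-family statistics regardless.
    """

    drop_trailing: bool = True
    reject_ambiguous: bool = True
    flag_internal_stops: bool = True


DEFAULT_POLICY = ValidationPolicy()


def validate_cds(
    seq_id: str,
    organism: str,
    raw: str,
    policy: ValidationPolicy = DEFAULT_POLICY,
) -> tuple[CDSRecord | None, dict]:
    """Validate one raw sequence.

    Returns ``(record, qc_row)``; ``record`` is None when the sequence is
    rejected, and the QC row carries the reason.
    """
    seq = str(raw).upper().replace("U", "T")
    tail = len(seq) % 3
    if tail:
        if not policy.drop_trailing:
            row = dict(organism=organism, id=seq_id, aa_length=0,
                       status="rejected", reason="length not multiple of 3")
            return None, row
        logger.warning("%s/%s: dropped trailing %d nt partial codon",
                       organism, seq_id, tail)
        seq = seq[: len(seq) - tail]
    if not seq:
        return None, dict(organism=organism, id=seq_id, aa_length=0,
                          status="rejected", reason="empty sequence")
    if policy.reject_ambiguous and any(b not in "ACGT" for b in seq):
        return None, dict(organism=organism, id=seq_id, aa_length=0,
                          status="rejected", reason="ambiguous base")
    codons = tuple(seq[i: i + 3] for i in range(0, len(seq), 3))
    internal = any(c in STOP_CODONS for c in codons[:-1])
    if internal and not policy.flag_internal_stops:
        return None, dict(organism=organism, id=seq_id, aa_length=len(codons),
                          status="rejected", reason="internal stop codon")
    rec = CDSRecord(id=seq_id, organism=organism, nucleotides=seq,
                    codons=codons, internal_stops=internal)
    reason = "internal stop codon (flagged)" if internal else ""
    row = dict(organism=organism, id=seq_id, aa_length=len(codons),
               status="retained", reason=reason)
    return rec, row


def _read_one(path, sep: str, role: str,
              policy: ValidationPolicy) -> OrganismCollection:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read FASTA file: {path}")
    name = path.stem
    records: list[CDSRecord] = []
    rows: list[dict] = []
    seen: dict[str, int] = {}
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise ValueError(f"no FASTA records found in {path}")
    for entry in parsed:
        header = entry.description
        rec_id = header.split(sep, 1)[0] if sep in header else header
        rec_id = rec_id.strip()
        n_seen = seen.get(rec_id, 0)
        seen[rec_id] = n_seen + 1
        if n_seen:
            logger.warning("%s: duplicate record id %r, suffixed as %r",
                           name, rec_id, f"{rec_id}_{n_seen + 1}")
            rec_id = f"{rec_id}_{n_seen + 1}"
        rec, row = validate_cds(rec_id, name, str(entry.seq), policy)
        rows.append(row)
        if rec is not None:
            records.append(rec)
    qc = pd.DataFrame(rows, columns=QC_COLUMNS)
    n_rej = int((qc["status"] == "rejected").sum())
    if n_rej:
        logger.warning("%s: rejected %d of %d records", name, n_rej, len(qc))
    return OrganismCollection(name=name, records=records, role=role, qc=qc)


def read_collections(
    paths: Sequence, sep: str = "|",
    policy: ValidationPolicy = DEFAULT_POLICY,
) -> list[OrganismCollection]:
    """Read one FASTA file per parasite organism.

    The organism name is the file basename without extension; each record id
    is the header text before the first occurrence of ``sep`` (the whole
    header when ``sep`` is absent).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if len(sep) != 1:
        raise ValueError(f"sep must be a single character, got {sep!r}")
    collections = [_read_one(p, sep, "parasite", policy) for p in paths]
    names = [c.name for c in collections]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate organism names: {sorted(names)}")
    return collections


def read_host(path, sep: str = "|",
              policy: ValidationPolicy = DEFAULT_POLICY) -> OrganismCollection:
    """Read the single host reference FASTA; only one host is permitted."""
    if isinstance(path, (list, tuple, set)):
        raise TypeError("only one host selection is permitted; pass a single path")
    if len(sep) != 1:
        raise ValueError(f"sep must be a single character, got {sep!r}")
    coll = _read_one(path, sep, "host", policy)
    if not coll.records:
        raise ValueError(f"host file {path} contains no valid CDS after validation")
    return coll


def length_table(collections: Iterable[OrganismCollection]) -> pd.DataFrame:
    """One row per retained record: (organism, id, aa_length)."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        if not coll.records:
            logger.warning("collection %s has no retained records", coll.name)
        for rec in coll.records:
            rows.append((coll.name, rec.id, rec.aa_length))
    return pd.DataFrame(rows, columns=["organism", "id", "aa_length"])


def filter_by_length(
    collections: Sequence[OrganismCollection],
    cut_off_down: int,
    cut_off_up: int,
) -> list[OrganismCollection]:
    """Retain records with cut_off_down <= aa_length <= cut_off_up (inclusive).

    Cutoffs are in amino acids (codons).  Returns new collections; the QC
    report of each collection is updated with ``filtered_length`` rows.
    """
    single = isinstance(collections, OrganismCollection)
    if single:
        collections = [collections]
    if not (0 <= cut_off_down < cut_off_up):
        raise ValueError(
            f"invalid length bounds: require 0 <= down < up, "
            f"got ({cut_off_down}, {cut_off_up})"
        )
    out = []
    for coll in collections:
        keep, dropped_ids = [], set()
        for rec in coll.records:
            if cut_off_down <= rec.aa_length <= cut_off_up:
                keep.append(rec)
            else:
                dropped_ids.add(rec.id)
        qc = coll.qc.copy()
        mask = qc["id"].isin(dropped_ids) & (qc["status"] == "retained")
        qc.loc[mask, "status"] = "filtered_length"
        qc.loc[mask, "reason"] = (
            f"aa_length outside [{cut_off_down}, {cut_off_up}]"
        )
        if dropped_ids:
            logger.info("%s: length filter removed %d of %d records",
                        coll.name, len(dropped_ids), len(coll.records))
        out.append(replace_collection(coll, records=keep, qc=qc))
    return out[0] if single else out


def replace_collection(coll: OrganismCollection, **kwargs) -> OrganismCollection:
    fields = dict(name=coll.name, records=coll.records, role=coll.role, qc=coll.qc)
    fields.update(kwargs)
    return OrganismCollection(**fields)


def qc_report(collections: Iterable[OrganismCollection]) -> pd.DataFrame:
    """Concatenated QC report over all collections (conserves parsed counts)."""
    if isinstance(collections, OrganismCollection):
        collections = [collections]
    frames = [c.qc for c in collections]
    if not frames:
        return pd.DataFrame(columns=QC_COLUMNS)
    return pd.concat(frames, ignore_index=True)
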