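"""Deterministic synthetic CDS generator.

Sequences are drawn codon by codon: an amino-acid sequence comes either
from a fixed protein template or from a random draw over amino acids, and
each residue is then encoded by a synonymous codon sampled from a
per-family weight profile.  A JSON "truth" sidecar records the normalised
per-family codon frequencies, the expected GC3 and every generation
parameter, so recovery tests can close the loop against the analysis
modules.  The same spec and seed always produce byte-identical FASTA.

Defaults emulate a small viral CDS study: a few dozen genes per organism
with lengths of a few hundred codons, i.e. the scale of influenza /
coronavirus proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genetics import FAMILIES
from .seqio import CDSRecord, OrganismCollection

_DEGENERATE_AAS = tuple(FAMILIES)  # the 18 multi-codon amino acids


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic organism.

    codon_weights maps codons to non-negative sampling weights, normalised
    within each synonymous family; omitted codons get weight 0 and omitted
    families are uniform.  gc3_bias in (0, 1) is a convenience alternative:
    within every family a codon ending in G/C gets weight ``gc3_bias`` and
    one ending in A/T gets ``1 - gc3_bias``.
    """

    name: str
    n_sequences: int = 30
    min_aa: int = 150
    max_aa: int = 450
    codon_weights: Mapping[str, float] | None = None
    gc3_bias: float | None = None
    protein: str | None = None
    aa_freqs: Mapping[str, float] | None = None
    seed: int = 0
    add_start: bool = True
    add_stop: bool = True
    role: str = "parasite"
    extra_header: str = field(default="synthetic")


def _weights_from_gc3(bias: float) -> dict[str, float]:
    if not 0 < bias < 1:
        raise ValueError("gc3_bias must be in (0, 1)")
    weights = {}
    for aa, codons in FAMILIES.items():
        for c in codons:
            weights[c] = bias if c[2] in "GC" else 1.0 - bias
    return weights


def family_profiles(spec: GeneratorSpec) -> dict[str, np.ndarray]:
    """Normalised per-family codon sampling frequencies implied by the spec."""
    if spec.codon_weights is not None and spec.gc3_bias is not None:
        raise ValueError("give codon_weights or gc3_bias, not both")
    if spec.gc3_bias is not None:
        raw = _weights_from_gc3(spec.gc3_bias)
    else:
        raw = dict(spec.codon_weights or {})
    profiles = {}
    for aa, codons in FAMILIES.items():
        mentioned = any(c in raw for c in codons)
        w = np.array([float(raw.get(c, 0.0)) for c in codons])
        if (w < 0).any():
            raise ValueError(f"negative codon weight in family {aa}")
        if w.sum() == 0:
            if mentioned:
                raise ValueError(
                    f"degenerate weights: family {aa} has zero total weight"
                )
            w = np.ones(len(codons))  # unspecified family: uniform
        profiles[aa] = w / w.sum()
    return profiles


def _aa_distribution(spec: GeneratorSpec) -> tuple[list[str], np.ndarray]:
    freqs = spec.aa_freqs or {aa: 1.0 for aa in _DEGENERATE_AAS}
    aas = [aa for aa in freqs if aa in FAMILIES]
    if not aas:
        raise ValueError("aa_freqs must include at least one degenerate amino acid")
    p = np.array([float(freqs[aa]) for aa in aas])
    if (p < 0).any() or p.sum() == 0:
        raise ValueError("degenerate amino-acid frequencies")
    return aas, p / p.sum()


def expected_gc3(spec: GeneratorSpec) -> float:
    """GC3 expectation over family codons under the spec's distributions."""
    profiles = family_profiles(spec)
    aas, p = _aa_distribution(spec)
    if spec.protein is not None:
        counts = {aa: spec.protein.count(aa) for aa in FAMILIES}
        total = sum(counts.values())
        if total == 0:
            raise ValueError("protein template has no degenerate amino acids")
        weights = {aa: counts[aa] / total for aa in FAMILIES}
    else:
        weights = dict(zip(aas, p))
    gc3 = 0.0
    for aa, prof in profiles.items():
        w_aa = weights.get(aa, 0.0)
        if w_aa == 0:
            continue
        is_gc = np.array([c[2] in "GC" for c in FAMILIES[aa]])
        gc3 += w_aa * float(prof[is_gc].sum())
    return gc3


def _draw_record(spec: GeneratorSpec, profiles, aas, aa_p, idx: int,
                 rng: np.random.Generator) -> CDSRecord:
    if spec.protein is not None:
        protein = spec.protein
    else:
        length = int(rng.integers(spec.min_aa, spec.max_aa + 1))
        protein = "".join(np.array(aas)[rng.choice(len(aas), size=length, p=aa_p)])
    codons: list[str] = []
    if spec.add_start:
        codons.append("ATG")
    for aa in protein:
        fam = FAMILIES[aa]
        codons.append(fam[int(rng.choice(len(fam), p=profiles[aa]))])
    if spec.add_stop:
        codons.append("TAA")
    seq = "".join(codons)
    rec_id = f"{spec.name}_{idx:04d}"
    return CDSRecord(id=rec_id, organism=spec.name, nucleotides=seq,
                     codons=tuple(codons))


def generate_collection(
    spec: GeneratorSpec, out_dir=None
) -> tuple[OrganismCollection, dict]:
    """Generate one organism; optionally write FASTA plus a truth sidecar.

    Returns the in-memory collection and the truth dictionary (normalised
    family frequencies, expected GC3 and the generation parameters).
    """
    if spec.n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if not 0 < spec.min_aa <= spec.max_aa:
        raise ValueError("require 0 < min_aa <= max_aa")
    profiles = family_profiles(spec)
    aas, aa_p = _aa_distribution(spec)
    rng = np.random.default_rng(spec.seed)
    records = [
        _draw_record(spec, profiles, aas, aa_p, i, rng)
        for i in range(spec.n_sequences)
    ]
    coll = OrganismCollection(name=spec.name, records=records, role=spec.role)
    truth = {
        "name": spec.name,
        "seed": spec.seed,
        "n_sequences": spec.n_sequences,
        "min_aa": spec.min_aa,
        "max_aa": spec.max_aa,
        "gc3_bias": spec.gc3_bias,
        "protein_template": spec.protein,
        "expected_gc3": expected_gc3(spec),
        "family_frequencies": {
            aa: {c: float(p) for c, p in zip(FAMILIES[aa], prof)}
            for aa, prof in profiles.items()
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / f"{spec.name}.fasta"
        with open(fasta, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}|{spec.extra_header}\n")
                for i in range(0, len(rec.nucleotides), 70):
                    fh.write(rec.nucleotides[i: i + 70] + "\n")
        with open(out_dir / f"{spec.name}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return coll, truth


def generate_host(spec: GeneratorSpec, out_dir=None):
    """Generate a host reference collection (role=host)."""
    host_spec = GeneratorSpec(**{**spec.__dict__, "role": "host"})
    return generate_collection(host_spec, out_dir=out_dir)
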