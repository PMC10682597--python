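import numpy as np
import pytest

from cubkit.genetics import CODON_INDEX, FAMILIES
from cubkit.seqio import CDSRecord, OrganismCollection
from cubkit.simulate import GeneratorSpec, generate_collection, generate_host


def make_record(seq: str, rec_id: str = "r1", organism: str = "org") -> CDSRecord:
    seq = seq.upper()
    codons = tuple(seq[i: i + 3] for i in range(0, len(seq) - len(seq) % 3, 3))
    return CDSRecord(id=rec_id, organism=organism,
                     nucleotides="".join(codons), codons=codons)


def counts_from(mapping: dict[str, float]) -> np.ndarray:
    c = np.zeros(64)
    for codon, n in mapping.items():
        c[CODON_INDEX[codon]] = n
    return c


def uniform_counts(per_family: float = 60.0) -> np.ndarray:
    """Counts with uniform usage inside every family."""
    c = np.zeros(64)
    for codons in FAMILIES.values():
        for codon in codons:
            c[CODON_INDEX[codon]] = per_family / len(codons)
    return c


@pytest.fixture(scope="session")
def small_study():
    """Three parasite collections with distinct GC3 biases plus a host."""
    colls = []
    for i, bias in enumerate([0.3, 0.5, 0.7]):
        spec = GeneratorSpec(name=f"virus{i}", n_sequences=12, min_aa=80,
                             max_aa=160, gc3_bias=bias, seed=100 + i)
        colls.append(generate_collection(spec)[0])
    host_spec = GeneratorSpec(name="host", n_sequences=20, min_aa=100,
                              max_aa=200, gc3_bias=0.6, seed=999)
    host, _ = generate_host(host_spec)
    return colls, host


@pytest.fixture(scope="session")
def fasta_study(tmp_path_factory):
    """The same kind of study written to FASTA files on disk."""
    root = tmp_path_factory.mktemp("fasta_study")
    paths = []
    for i, bias in enumerate([0.35, 0.65]):
        spec = GeneratorSpec(name=f"flu{i}", n_sequences=8, min_aa=60,
                             max_aa=120, gc3_bias=bias, seed=10 + i)
        generate_collection(spec, out_dir=root / "parasites")
        paths.append(root / "parasites" / f"flu{i}.fasta")
    host_spec = GeneratorSpec(name="human", n_sequences=12, min_aa=80,
                              max_aa=150, gc3_bias=0.55, seed=77)
    generate_host(host_spec, out_dir=root / "host")
    return paths, root / "host" / "human.fasta"
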