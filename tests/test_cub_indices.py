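import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cubkit.cub_indices import (
    b_index,
    cai,
    cai_table,
    cai_weights,
    e_index,
    enc_modified,
    enc_wright,
    fop,
    mcb,
    melp,
    milc,
    optimal_codons,
    rscu,
    rscu_table,
)
from cubkit.genetics import CODON_INDEX, CODONS, FAMILIES
from cubkit.simulate import GeneratorSpec, generate_collection
from conftest import counts_from, uniform_counts
from oracles import (
    ORACLE_FAMILIES,
    b_oracle,
    enc_wright_oracle,
    milc_oracle,
    rscu_oracle,
)


def one_codon_per_family(n: float = 10.0) -> np.ndarray:
    c = np.zeros(64)
    for codons in FAMILIES.values():
        c[CODON_INDEX[codons[0]]] = n
    return c


def random_counts(rng, scale=200) -> np.ndarray:
    c = np.zeros(64)
    for codons in FAMILIES.values():
        weights = rng.dirichlet(np.ones(len(codons)) * rng.uniform(0.2, 3.0))
        total = rng.integers(0, scale)
        c[[CODON_INDEX[x] for x in codons]] = rng.multinomial(total, weights)
    return c


TOY_TABLES = [
    {"GAA": 3, "GAG": 1, "TTT": 5, "TTC": 2, "GCA": 4, "GCC": 1, "GCG": 2,
     "GCT": 3, "ATT": 2, "ATC": 2, "ATA": 1, "CTG": 6, "CTA": 1, "TCT": 2,
     "AGC": 3, "AAA": 4, "AAG": 4},
    {"GGT": 7, "GGC": 1, "CAA": 2, "CAG": 5, "CGT": 3, "AGA": 2, "TAT": 1,
     "TAC": 4, "GTG": 8, "GTT": 2, "CCC": 3, "CCG": 3, "ACA": 5},
]


class TestENc:
    def test_one_codon_per_family_is_twenty_exactly(self):
        assert enc_wright(one_codon_per_family()) == 20.0

    def test_uniform_usage_approaches_sixty_one(self):
        c = uniform_counts(per_family=10000.0)
        assert enc_wright(c) == pytest.approx(61.0, abs=0.5)

    @pytest.mark.parametrize("table", TOY_TABLES)
    def test_matches_independent_oracle(self, table):
        assert enc_wright(counts_from(table)) == pytest.approx(
            enc_wright_oracle(table), abs=1e-9
        )

    def test_missing_threefold_class_uses_two_four_mean(self):
        table = {c: 5 for fam in ORACLE_FAMILIES.values() for c in fam
                 if fam != ORACLE_FAMILIES["I"]}
        assert enc_wright(counts_from(table)) == pytest.approx(
            enc_wright_oracle(table), abs=1e-9
        )

    def test_undefined_when_whole_class_absent(self):
        # only a four-fold family observed: two-fold class empty
        assert np.isnan(enc_wright(counts_from({"GCA": 5, "GCC": 3})))

    def test_modified_defined_on_one_codon_gene(self):
        c = counts_from({"GCA": 1})
        assert np.isnan(enc_wright(c))
        assert 20.0 <= enc_modified(c) <= 61.0

    def test_modified_approaches_twenty_from_above(self):
        small = enc_modified(one_codon_per_family(50))
        large = enc_modified(one_codon_per_family(50000))
        assert small > large > 20.0
        assert large == pytest.approx(20.0, abs=0.05)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bounds_on_fuzzed_counts(self, seed):
        c = random_counts(np.random.default_rng(seed))
        w = enc_wright(c)
        if not np.isnan(w):
            assert 20.0 <= w <= 61.0
        assert 20.0 <= enc_modified(c) <= 61.0


class TestMILC:
    def test_identity_gene_leaves_only_correction(self):
        gene = random_counts(np.random.default_rng(1)) + 1  # all codons used
        ref = gene * 10
        value, correction = milc(gene, ref, return_correction=True)
        assert abs(value) <= abs(correction) + 1e-12

    def test_divergence_increases_milc(self):
        ref = uniform_counts(600)
        near = counts_from({"GAA": 30, "GAG": 30})
        far = counts_from({"GAA": 55, "GAG": 5})
        assert milc(far, ref) > milc(near, ref)

    @pytest.mark.parametrize("table", TOY_TABLES)
    def test_matches_independent_oracle(self, table):
        ref = {c: 7 if c[0] in "AG" else 3 for c in CODONS
               if any(c in fam for fam in ORACLE_FAMILIES.values())}
        assert milc(counts_from(table), counts_from(ref)) == pytest.approx(
            milc_oracle(table, ref), abs=1e-9
        )

    def test_reference_scaling_invariance(self):
        gene = counts_from(TOY_TABLES[0])
        ref = uniform_counts(590)
        assert milc(gene, ref) == pytest.approx(milc(gene, ref * 7), abs=1e-12)


class TestBIndex:
    def test_identity_is_zero(self):
        gene = random_counts(np.random.default_rng(2)) + 1
        assert b_index(gene, gene * 5) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_two_fold_usage_is_maximal(self):
        gene = counts_from({"GAA": 10})
        ref = counts_from({c: 1000 for fam in FAMILIES.values() for c in fam
                           if c != "GAA"})
        assert b_index(gene, ref) == pytest.approx(2.0, abs=0.02)

    @pytest.mark.parametrize("table", TOY_TABLES)
    def test_matches_independent_oracle(self, table):
        ref = {c: 5 if c[2] in "GC" else 2 for fam in ORACLE_FAMILIES.values()
               for c in fam}
        assert b_index(counts_from(table), counts_from(ref)) == pytest.approx(
            b_oracle(table, ref), abs=1e-9
        )

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_range_zero_two(self, seed):
        rng = np.random.default_rng(seed)
        gene, ref = random_counts(rng), random_counts(rng) + 1
        val = b_index(gene, ref)
        if not np.isnan(val):
            assert 0.0 <= val <= 2.0


class TestMCB:
    def test_identity_is_zero(self):
        gene = random_counts(np.random.default_rng(3)) + 1
        assert mcb(gene, gene * 4) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_under_divergence(self):
        ref = uniform_counts(600)
        near = counts_from({"GCA": 16, "GCC": 14, "GCG": 15, "GCT": 15})
        far = counts_from({"GCA": 45, "GCC": 5, "GCG": 5, "GCT": 5})
        assert mcb(far, ref) > mcb(near, ref) >= 0.0


class TestCAI:
    def test_optimal_gene_scores_one(self):
        ref = counts_from({"GAA": 9, "GAG": 1, "TTT": 8, "TTC": 2})
        gene = counts_from({"GAA": 5, "TTT": 5})
        assert cai(gene, cai_weights(ref)) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        ref = counts_from({"GAA": 4, "GAG": 1})
        gene = counts_from({"GAA": 1, "GAG": 1})
        assert cai(gene, cai_weights(ref)) == pytest.approx(0.5)

    def test_uniform_reference_is_uninformative(self):
        weights = cai_weights(uniform_counts(5900))
        rng = np.random.default_rng(0)
        gene = random_counts(rng) + 1
        assert cai(gene, weights) == pytest.approx(1.0)

    def test_weights_have_family_maxima_of_one(self, small_study):
        _, host = small_study
        w = cai_weights(host.pooled_counts())
        assert (w > 0).all()
        for codons in FAMILIES.values():
            assert w[list(codons)].max() == pytest.approx(1.0)


class TestFOP:
    def test_extreme_genes(self):
        ref = counts_from({"GAA": 9, "GAG": 1})
        opt = optimal_codons(ref)
        assert "GAA" in opt
        assert fop(counts_from({"GAA": 7}), opt) == 1.0
        assert fop(counts_from({"GAG": 7}), opt) == 0.0

    def test_fractional_count(self):
        ref = counts_from({"GAA": 9, "GAG": 1, "TTT": 9, "TTC": 1})
        opt = optimal_codons(ref)
        gene = counts_from({"GAA": 4, "GAG": 6})
        assert fop(gene, opt) == pytest.approx(0.4)

    def test_ties_make_both_codons_optimal(self):
        ref = counts_from({"GAA": 5, "GAG": 5})
        opt = optimal_codons(ref)
        assert {"GAA", "GAG"} <= opt


class TestMELPAndE:
    def _study(self):
        host, _ = generate_collection(
            GeneratorSpec(name="host", n_sequences=15, min_aa=150, max_aa=250,
                          gc3_bias=0.8, seed=41))
        virus, _ = generate_collection(
            GeneratorSpec(name="virus", n_sequences=15, min_aa=150, max_aa=250,
                          gc3_bias=0.25, seed=42))
        return host, virus

    def test_host_like_gene_scores_above_one(self):
        host, virus = self._study()
        background = virus.pooled_counts()
        host_counts = host.pooled_counts()
        hostlike = host.records[0].codon_counts()
        assert melp(hostlike, host_counts, background) > 1.0
        assert e_index(hostlike, host_counts, background) > 1.0

    def test_background_like_gene_scores_below_one(self):
        host, virus = self._study()
        background = virus.pooled_counts()
        host_counts = host.pooled_counts()
        viruslike = virus.records[0].codon_counts()
        assert melp(viruslike, host_counts, background) < 1.0
        assert e_index(viruslike, host_counts, background) < 1.0

    def test_e_identity_convention(self):
        gene = random_counts(np.random.default_rng(4)) + 1
        assert e_index(gene, gene * 3, gene * 2) == pytest.approx(1.0)


class TestRSCU:
    def test_uniform_usage_gives_ones(self):
        values = rscu(uniform_counts(590))
        assert np.allclose(values.to_numpy(), 1.0)

    def test_sixfold_concentration(self):
        values = rscu(counts_from({"CTG": 12}))
        assert values["CTG"] == pytest.approx(6.0)
        assert values["CTA"] == 0.0

    def test_two_codon_example(self):
        values = rscu(counts_from({"GAA": 3, "GAG": 1}))
        assert values["GAA"] == pytest.approx(1.5)
        assert values["GAG"] == pytest.approx(0.5)

    @pytest.mark.parametrize("table", TOY_TABLES)
    def test_matches_independent_oracle(self, table):
        values = rscu(counts_from(table))
        expected = rscu_oracle(table)
        for codon, val in expected.items():
            assert values[codon] == pytest.approx(val, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_family_sums_equal_degeneracy(self, seed):
        c = random_counts(np.random.default_rng(seed))
        values = rscu(c)
        for codons in FAMILIES.values():
            total = sum(c[CODON_INDEX[x]] for x in codons)
            if total > 0:
                assert values[list(codons)].sum() == pytest.approx(
                    len(codons), abs=1e-9
                )


class TestTables:
    def test_record_order_invariance(self, small_study):
        colls, host = small_study
        table = cai_table(colls, host)
        reversed_colls = [type(c)(name=c.name, records=list(reversed(c.records)),
                                  role=c.role, qc=c.qc) for c in colls]
        table_rev = cai_table(reversed_colls, host)
        merged = table.merge(table_rev, on=["organism", "id"])
        assert np.allclose(merged["value_x"], merged["value_y"])

    def test_host_required_indices_refuse_without_host(self, small_study):
        colls, _ = small_study
        with pytest.raises(ValueError, match="reference"):
            cai_table(colls, None)

    def test_rscu_wide_table_has_59_lexicographic_columns(self, small_study):
        colls, _ = small_study
        wide = rscu_table(colls, per="sequence")
        assert wide.shape[1] == 59
        assert list(wide.columns) == sorted(wide.columns)

    def test_organism_means_average_per_sequence_rows(self, small_study):
        colls, _ = small_study
        per_seq = rscu_table([colls[0]], per="sequence")
        per_org = rscu_table([colls[0]], per="organism")
        assert np.allclose(per_seq.mean(axis=0), per_org.iloc[0])
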