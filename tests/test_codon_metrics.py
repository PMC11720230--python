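"""Composition profiles, RSCU, ENC, CAI, CBI/FOP, GRAVY.

ENC and RSCU are additionally checked against independent brute-force
oracles written directly from their defining formulas, and RSCU against
the seqinr R implementation on one gene."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.codon_metrics import (
    CodonCountTable,
    cai,
    cai_weights,
    cbi_fop,
    composition_profile,
    compute_gene_indices,
    count_codons,
    enc,
    gravy_aromo,
    pool_counts,
    rscu,
)
from cubkit.genetic_code import (
    DEGENERATE_AAS,
    ENC_CLASSES,
    GENETIC_CODE,
    SYNONYMOUS_CODONS,
)
from cubkit.sequence_io import CodingSequence

from conftest import make_cds, random_count_table


# -- independent oracles ----------------------------------------------------

def brute_force_rscu(table: CodonCountTable) -> dict[str, float]:
    out = {}
    for aa in DEGENERATE_AAS:
        codons = GENETIC_CODE[aa]
        total = sum(table[c] for c in codons)
        for c in codons:
            out[c] = table[c] / (total / len(codons)) if total else math.nan
    return out


def brute_force_enc(table: CodonCountTable) -> float:
    f_by_class = {}
    for k, aas in ENC_CLASSES.items():
        fs = []
        for aa in aas:
            counts = [table[c] for c in GENETIC_CODE[aa]]
            n = sum(counts)
            if n <= 1:
                continue
            s = sum((x / n) ** 2 for x in counts)
            fs.append((n * s - 1) / (n - 1))
        if fs:
            f_by_class[k] = sum(fs) / len(fs)
    if 3 not in f_by_class and 2 in f_by_class and 4 in f_by_class:
        f_by_class[3] = (f_by_class[2] + f_by_class[4]) / 2
    if any(k not in f_by_class for k in (2, 3, 4, 6)):
        return math.nan
    weights = {2: 9, 3: 1, 4: 5, 6: 3}
    total = 2.0
    for k, w in weights.items():
        total += w / f_by_class[k] if f_by_class[k] > 0 else math.inf
    return min(61.0, max(20.0, total))


# -- counting ---------------------------------------------------------------

class TestCountCodons:
    def test_direct_count(self):
        t = count_codons(CodingSequence("g", "ATGAAAAAATAA"))
        assert t["ATG"] == 1 and t["AAA"] == 2 and t["TAA"] == 1
        assert t.total == 4

    def test_pooling_is_elementwise_sum(self):
        a = count_codons(CodingSequence("a", "ATGAAATAA"))
        b = count_codons(CodingSequence("b", "ATGGGGTAA"))
        pooled = pool_counts([a, b])
        assert pooled["ATG"] == 2 and pooled["AAA"] == 1 and pooled["GGG"] == 1

    def test_empty_pool_is_zero(self):
        assert pool_counts([]).total == 0

    def test_frame_error(self):
        with pytest.raises(ValueError):
            count_codons(CodingSequence("g", "ATGA"))


# -- composition ------------------------------------------------------------

class TestComposition:
    def test_gc3s_excludes_start_and_stop(self):
        prof = composition_profile(CodingSequence("g", "ATGGGGCCCTAA"))
        assert prof.GC3s == 1.0  # over {GGG, CCC} only

    def test_at_only_third_positions(self):
        # body codons AAA and TTT: synonymous, third bases A/T only
        prof = composition_profile(make_cds(["AAA", "TTT"] * 3))
        assert prof.GC3s == 0.0
        assert prof.A3s + prof.T3s == 1.0

    def test_gc12_is_mean_of_gc1_gc2(self, uniform_gene):
        prof = composition_profile(uniform_gene)
        assert prof.GC12 == pytest.approx((prof.GC1 + prof.GC2) / 2)

    def test_third_base_fractions_sum_to_one(self, rng):
        for _ in range(20):
            codons = list(rng.choice(SYNONYMOUS_CODONS, size=50))
            prof = composition_profile(make_cds(codons))
            total = prof.A3s + prof.T3s + prof.C3s + prof.G3s
            assert total == pytest.approx(1.0)


# -- RSCU -------------------------------------------------------------------

class TestRscu:
    def test_lysine_family_by_hand(self):
        t = CodonCountTable.from_mapping({"AAA": 2, "AAG": 1})
        values = rscu(t)
        assert values["AAA"] == pytest.approx(4 / 3, abs=1e-9)
        assert values["AAG"] == pytest.approx(2 / 3, abs=1e-9)

    def test_uniform_usage_gives_all_ones(self, uniform_gene):
        values = rscu(count_codons(uniform_gene))
        for codon in SYNONYMOUS_CODONS:
            assert values[codon] == pytest.approx(1.0)

    def test_family_sums_equal_family_sizes(self, rng):
        for _ in range(30):
            values = rscu(random_count_table(rng))
            for aa in DEGENERATE_AAS:
                fam = [values[c] for c in GENETIC_CODE[aa]]
                if not any(math.isnan(v) for v in fam):
                    assert sum(fam) == pytest.approx(len(fam))

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            t = random_count_table(rng)
            expected = brute_force_rscu(t)
            got = rscu(t)
            for codon, v in expected.items():
                if math.isnan(v):
                    assert math.isnan(got[codon])
                else:
                    assert got[codon] == pytest.approx(v, abs=1e-12)

    def test_stop_family_only_with_flag(self):
        t = CodonCountTable.from_mapping({"TAA": 2, "TAG": 1, "TGA": 3, "AAA": 4})
        assert "TAA" not in rscu(t)
        values = rscu(t, include_stops=True)
        assert values["TGA"] == pytest.approx(3 * 3 / 6)

    def test_matches_seqinr_reference(self, rng, tmp_path):
        """Cross-check against the seqinr R package on one random gene."""
        codons = list(rng.choice(SYNONYMOUS_CODONS, size=200))
        seq = "".join(codons)
        script = tmp_path / "rscu.R"
        script.write_text(
            'suppressMessages(library(seqinr))\n'
            f'v <- s2c(tolower("{seq}"))\n'
            'r <- uco(v, index="rscu")\n'
            'write.csv(data.frame(codon=toupper(names(r)), rscu=as.numeric(r)), '
            f'"{tmp_path / "out.csv"}", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        import pandas as pd

        ref = pd.read_csv(tmp_path / "out.csv").set_index("codon")["rscu"]
        ours = rscu(count_codons(seq))
        for codon in SYNONYMOUS_CODONS:
            if not math.isnan(ours[codon]):
                assert ours[codon] == pytest.approx(ref[codon], abs=1e-6)


# -- ENC --------------------------------------------------------------------

class TestEnc:
    def test_single_codon_per_family_is_20(self):
        # two copies of one codon per degenerate family -> F = 1 everywhere
        body = [GENETIC_CODE[aa][0] for aa in DEGENERATE_AAS] * 2
        assert enc(count_codons(make_cds(body))) == pytest.approx(20.0)

    def test_uniform_usage_tends_to_61(self):
        body = [c for aa in DEGENERATE_AAS for c in GENETIC_CODE[aa]] * 40
        assert enc(count_codons(make_cds(body))) == pytest.approx(61.0, abs=0.5)

    def test_range_contract(self, rng):
        for _ in range(50):
            value = enc(random_count_table(rng))
            if not math.isnan(value):
                assert 20.0 <= value <= 61.0

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            t = random_count_table(rng, max_count=15)
            expected = brute_force_enc(t)
            got = enc(t)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_sparse_table_undefined_not_error(self):
        t = CodonCountTable.from_mapping({"AAA": 5, "AAG": 3})  # only one 2-fold family
        assert math.isnan(enc(t))

    def test_scale_invariance_limit(self):
        # uniform table: ENC increases toward 61 as counts grow
        body = [c for aa in DEGENERATE_AAS for c in GENETIC_CODE[aa]]
        values = []
        for k in (1, 5, 25, 125):
            t = count_codons(make_cds(body * k))
            values.append(enc(t))
        assert values == sorted(values)
        assert values[-1] == pytest.approx(61.0, abs=0.1)


# -- CAI --------------------------------------------------------------------

class TestCai:
    def test_weights_with_pseudocount(self):
        ref = CodonCountTable.from_mapping({"GCT": 10, "GCC": 5, "GCA": 0, "GCG": 0})
        w = cai_weights(ref)
        assert w["GCT"] == 1.0
        assert w["GCC"] == 0.5
        assert w["GCA"] == pytest.approx(0.05)
        assert w["GCG"] == pytest.approx(0.05)

    def test_weights_scale_invariant(self, rng):
        t = random_count_table(rng)
        doubled = CodonCountTable(t.counts * 2)
        assert cai_weights(t) == cai_weights(doubled)

    def test_max_codon_only_gene_has_cai_1(self, rng):
        ref = random_count_table(rng)
        w = cai_weights(ref)
        best = [max(GENETIC_CODE[aa], key=lambda c: w[c]) for aa in DEGENERATE_AAS]
        gene = count_codons(make_cds(best * 3))
        assert cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        ref = CodonCountTable.from_mapping({"AAA": 8, "AAG": 2, "GGA": 4, "GGC": 1})
        w = cai_weights(ref)
        gene = CodonCountTable.from_mapping({"AAA": 1, "GGC": 1})
        assert cai(gene, w) == pytest.approx(math.sqrt(1.0 * 0.25))

    def test_invariant_to_duplication(self, rng):
        ref = random_count_table(rng)
        w = cai_weights(ref)
        t = random_count_table(rng)
        doubled = CodonCountTable(t.counts * 2)
        assert cai(t, w) == pytest.approx(cai(doubled, w))

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            cai_weights(CodonCountTable.zeros())


# -- CBI / FOP --------------------------------------------------------------

class TestCbiFop:
    OPT = frozenset(GENETIC_CODE[aa][0] for aa in DEGENERATE_AAS)

    def test_all_optimal_gene(self):
        gene = count_codons(make_cds(sorted(self.OPT) * 2))
        cbi_val, fop = cbi_fop(gene, self.OPT)
        assert fop == 1.0
        assert cbi_val == pytest.approx(1.0)

    def test_random_uniform_usage_has_cbi_near_zero(self, rng):
        """Expectation of CBI over uniform codon choice is ~0."""
        values = []
        for _ in range(1000):
            codons = list(rng.choice(SYNONYMOUS_CODONS, size=120))
            cbi_val, _ = cbi_fop(count_codons(make_cds(codons)), self.OPT)
            values.append(cbi_val)
        assert abs(float(np.mean(values))) < 0.02

    def test_fop_bounds(self, rng):
        for _ in range(20):
            _, fop = cbi_fop(random_count_table(rng), self.OPT)
            assert 0.0 <= fop <= 1.0

    def test_empty_optimal_set_errors(self, rng):
        with pytest.raises(ValueError):
            cbi_fop(random_count_table(rng), frozenset())


# -- protein ----------------------------------------------------------------

class TestGravyAromo:
    @pytest.mark.parametrize(
        "protein, gravy, aromo",
        [("III", 4.5, 0.0), ("FYW", None, 1.0), ("MK", None, 0.0)],
    )
    def test_known_values(self, protein, gravy, aromo):
        g, a = gravy_aromo(protein)
        if gravy is not None:
            assert g == pytest.approx(gravy)
        assert a == pytest.approx(aromo)

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            gravy_aromo("MKX")


# -- property tests ---------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(st.lists(st.sampled_from(SYNONYMOUS_CODONS), min_size=30, max_size=150))
def test_rscu_family_sums_property(codons):
    values = rscu(count_codons(make_cds(codons)))
    for aa in DEGENERATE_AAS:
        fam = [values[c] for c in GENETIC_CODE[aa]]
        if not any(math.isnan(v) for v in fam):
            assert sum(fam) == pytest.approx(len(fam))


@settings(max_examples=30, deadline=None)
@given(st.lists(st.sampled_from(SYNONYMOUS_CODONS), min_size=60, max_size=200))
def test_enc_in_range_and_matches_oracle(codons):
    t = count_codons(make_cds(codons))
    value, expected = enc(t), brute_force_enc(t)
    if math.isnan(expected):
        assert math.isnan(value)
    else:
        assert 20.0 <= value <= 61.0
        assert value == pytest.approx(expected, abs=1e-9)


def test_gene_indices_table_shape_and_ranges(rng):
    from cubkit.synthetic_data import SimulationScenario, simulate_genes

    sc = SimulationScenario(name="t", n_genes=60, length_range=(100, 150), s_sel=0.3,
                            preferred_codons=("AAA", "GCT"))
    genes, _ = simulate_genes(sc, seed=3)
    df = compute_gene_indices(genes)
    assert len(df) == 60
    assert ((df["ENC"] >= 20) & (df["ENC"] <= 61)).all()
    assert ((df["CAI"] > 0) & (df["CAI"] <= 1)).all()
    assert ((df["FOP"] >= 0) & (df["FOP"] <= 1)).all()
    assert (df["L_sym"] <= df["L_aa"]).all()
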