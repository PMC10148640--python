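"""Generator behaviour: catalogs, 3'-biased transcriptome spots, genome reads."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from oracles import ShareOracle, oracle_identity
from termipep import (ExpressionProgram, make_catalog, simulate_genome_reads,
                      simulate_rnaseq, uniform_program)
from termipep.synth import (CatalogError, MAX_IDENTITY, PERIPHERAL_GENES,
                            _start_distribution, matchable_truth_counts)

FIXED_IDS = {
    "gonadulin", "igf", "dilp7", "atirpin", "birpin", "cirpin", "brovirpin",
    "akh", "neuroparsin", "sifamide", "smyamide", "allatostatin-a",
    "hansolin", "cnmamide", "vitellogenin", "hexamerin",
    "vitellogenin-receptor",
}


class TestCatalog:
    def test_fixed_inventory(self):
        cat = make_catalog(0, 0, 0, seed=1)
        assert set(cat.gene_ids()) == FIXED_IDS
        ilps = set(cat.category_ids("ilp"))
        assert ilps == {"gonadulin", "igf", "dilp7", "atirpin", "birpin",
                        "cirpin", "brovirpin"}
        assert {g.gene_id for g in cat if g.peripheral} == set(PERIPHERAL_GENES)

    def test_deterministic_under_seed(self):
        a = make_catalog(5, 2, 5, seed=1)
        b = make_catalog(5, 2, 5, seed=1)
        assert [g.cds for g in a] == [g.cds for g in b]
        c = make_catalog(5, 2, 5, seed=2)
        assert [g.cds for g in a] != [g.cds for g in c]

    def test_protein_genes_much_longer(self):
        cat = make_catalog(3, 2, 2, seed=3)
        np_max = max(len(g.cds) for g in cat
                     if g.category in ("neuropeptide", "ilp"))
        prot_min = min(len(g.cds) for g in cat if g.category == "protein")
        assert prot_min >= 5 * np_max

    def test_pairwise_identity_below_threshold(self):
        """All-pairs global-alignment identity stays under the decoy bound."""
        cat = make_catalog(5, 2, 5, seed=1)
        worst = max(
            oracle_identity(a.cds, b.cds)
            for a, b in itertools.combinations(cat.genes, 2)
        )
        assert worst < MAX_IDENTITY

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_catalog(-1, 0, 0, seed=1)


class TestRnaseq:
    def test_zero_abundance_gene_emits_no_reads(self, mini_catalog):
        lam = {g.gene_id: 1.0 for g in mini_catalog}
        lam["g0"] = 0.0
        prog = ExpressionProgram({"w": lam})
        rs = simulate_rnaseq(mini_catalog, prog, "w", 500, seed=4)
        assert rs.truth["counts"]["g0"] == 0
        assert all(o["gene"] != "g0" for o in rs.truth["origins"])

    def test_all_zero_abundance_rejected(self, mini_catalog):
        with pytest.raises(ValueError):
            ExpressionProgram({"w": {g.gene_id: 0.0 for g in mini_catalog}})

    def test_truth_counts_sum_to_originals(self, mini_catalog, basic_program):
        rs = simulate_rnaseq(mini_catalog, basic_program, "w", 1000,
                             dup_rate=0.2, seed=5)
        n_dup = rs.truth["n_duplicates"]
        assert n_dup == 200
        assert sum(rs.truth["counts"].values()) == 1000 - n_dup
        assert len(rs.spots) == 1000

    def test_duplicate_dialects(self, mini_catalog, basic_program):
        fresh = simulate_rnaseq(mini_catalog, basic_program, "w", 400,
                                dup_rate=0.25, seed=6)
        same = simulate_rnaseq(mini_catalog, basic_program, "w", 400,
                               dup_rate=0.25, seed=6, dup_same_id=True)
        assert fresh.n_distinct_spots() == 400
        assert same.n_distinct_spots() == 300
        # duplicate re-emissions carry their source spot's sequence
        by_id = dict(fresh.spots)
        for o in fresh.truth["origins"]:
            if o["dup_of"]:
                assert by_id[o["spot_id"]] == by_id[o["dup_of"]]

    def test_determinism(self, mini_catalog, basic_program):
        a = simulate_rnaseq(mini_catalog, basic_program, "w", 300, seed=7,
                            error_rate=0.01)
        b = simulate_rnaseq(mini_catalog, basic_program, "w", 300, seed=7,
                            error_rate=0.01)
        assert a.spots == b.spots

    def test_biased_start_positions_match_closed_form(self):
        """Monte-Carlo mean fractional start vs the power-law density mean."""
        from termipep import Catalog, GeneRecord
        from conftest import random_cds

        gene = GeneRecord("long", "long", random_cds(42, 3000), "protein",
                          False, 0)
        cat = Catalog([gene])
        prog = ExpressionProgram({"w": {"long": 1.0}})
        L = 100
        for bias in (0.0, 2.0):
            rs = simulate_rnaseq(cat, prog, "w", 5000, bias=bias, seed=8)
            starts = np.array([o["start"] for o in rs.truth["origins"]])
            frac = starts / (3000 - L)
            w = _start_distribution(3000, L, bias)
            expected = np.average(np.arange(w.size) / (3000 - L), weights=w)
            se = frac.std(ddof=1) / np.sqrt(frac.size)
            assert abs(frac.mean() - expected) < 3 * se
            if bias == 2.0:
                assert frac.mean() > 0.5
            else:
                assert abs(expected - 0.5) < 1e-9

    def test_three_prime_half_coverage_exceeds_five_prime(self, mini_catalog,
                                                          basic_program):
        """One-sided binomial test on read midpoints at the default bias."""
        rs = simulate_rnaseq(mini_catalog, basic_program, "w", 5000,
                             bias=1.5, seed=9)
        three_prime = n = 0
        for o in rs.truth["origins"]:
            mid = o["start"] + 50
            n += 1
            three_prime += mid >= o["tlen"] / 2
        p = sps.binomtest(three_prime, n, 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_structural_load_dilutes_neuropeptide_share(self, full_catalog):
        """Doubling the structural load halves the expected neuropeptide
        share, per the closed-form sampling probabilities."""
        prog = uniform_program(full_catalog, ["a", "b"], protein_level=100.0,
                               structural_load={"b": 2.0})
        oracle = ShareOracle(full_catalog, prog)
        cats = ("neuropeptide", "ilp")
        share_a = oracle.expected_share("a", cats)
        share_b = oracle.expected_share("b", cats)
        assert 1.7 < share_a / share_b < 2.0  # approaches 2 as proteins dominate
        rs_a = simulate_rnaseq(full_catalog, prog, "a", 8000, seed=10)
        rs_b = simulate_rnaseq(full_catalog, prog, "b", 8000, seed=11)

        def observed(rs):
            counts = rs.truth["counts"]
            npc = sum(counts[g] for g in full_catalog.category_ids(*cats))
            return npc / sum(counts.values())

        assert observed(rs_a) == pytest.approx(share_a, abs=0.01)
        assert observed(rs_b) == pytest.approx(share_b, abs=0.01)

    def test_matchable_truth_excludes_utr_fragments(self, mini_catalog,
                                                    basic_program):
        rs = simulate_rnaseq(mini_catalog, basic_program, "w", 800, seed=12)
        mt = matchable_truth_counts(rs, mini_catalog, min_overlap=40)
        for g in mini_catalog.gene_ids():
            assert mt[g] <= rs.truth["counts"][g]


class TestGenomeReads:
    def test_mean_depth_near_target(self):
        from conftest import random_cds

        contig = random_cds(13, 10_000)
        rs = simulate_genome_reads({"c": contig}, coverage=20, read_len=100,
                                   seed=1)
        depth = len(rs.spots) * 100 / 10_000
        assert abs(depth - 20) / 20 < 0.1
        # per-base coverage from the recorded starts
        cov = np.zeros(10_000)
        for o in rs.truth["origins"]:
            cov[o["start"]:o["start"] + 100] += 1
        assert abs(cov.mean() - 20) / 20 < 0.1

    def test_truth_records_embedded_genes(self):
        from conftest import random_cds

        rs = simulate_genome_reads({"c": random_cds(14, 2000)}, coverage=5,
                                   seed=2, embedded_genes={"c": ["lgr4"]})
        assert rs.truth["embedded_genes"] == {"c": ["lgr4"]}
        assert "lgr3" not in {g for gs in rs.truth["embedded_genes"].values()
                              for g in gs}

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome_reads({"c": "ACGT" * 10}, coverage=5,
                                  read_len=100, seed=0)

    def test_determinism(self):
        from conftest import random_cds

        contigs = {"c": random_cds(15, 3000)}
        a = simulate_genome_reads(contigs, coverage=8, seed=3)
        b = simulate_genome_reads(contigs, coverage=8, seed=3)
        assert a.spots == b.spots


def test_igf_splice_variant_duplicates_cds():
    cat = make_catalog(0, 0, 0, seed=1, igf_splice_variant=True)
    assert cat["igf-b"].cds == cat["igf"].cds
    # a read from the shared CDS hits both isoforms
    from termipep import MatchParams, build_index, match_read

    idx = build_index(cat)
    read = cat["igf"].cds[50:150]
    assert {"igf", "igf-b"} <= match_read(read, idx, MatchParams())
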