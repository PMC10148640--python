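"""Normalisation, caste tables, correlations, QC flags."""

import numpy as np
import pytest

from conftest import random_cds
from termipep import (Catalog, GeneRecord, SpotCountTable, build_index,
                      caste_table, correlate, count_spots, make_catalog,
                      normalize, qc_flags, simulate_rnaseq, uniform_program)
from termipep.expr import ExpressionProfile


def _np_catalog():
    genes = [
        GeneRecord("akh", "AKH", random_cds(70, 210), "neuropeptide", True, 0),
        GeneRecord("npA", "npA", random_cds(71, 210), "neuropeptide", False, 0),
        GeneRecord("npB", "npB", random_cds(72, 210), "neuropeptide", False, 0),
    ]
    return Catalog(genes)


def _table(counts, n_total, set_id="s"):
    return SpotCountTable(set_id, counts, n_total)


class TestNormalize:
    def test_peripheral_exclusion_forced_example(self):
        cat = _np_catalog()
        tab = _table({"akh": 900, "npA": 50, "npB": 50}, 10_000)
        prof = normalize(tab, cat, tau=0.5)
        assert prof.excluded == {"akh"}
        assert prof.frac == {"npA": 0.5, "npB": 0.5}
        assert prof.spm["akh"] == pytest.approx(1e6 * 900 / 10_000)

    def test_single_nonzero_neuropeptide(self):
        cat = _np_catalog()
        prof = normalize(_table({"akh": 0, "npA": 7, "npB": 0}, 100), cat)
        assert prof.frac["npA"] == 1.0

    def test_zero_denominator_flags_undefined(self):
        cat = _np_catalog()
        prof = normalize(_table({"akh": 0, "npA": 0, "npB": 0}, 100), cat)
        assert prof.frac is None and not prof.frac_defined

    def test_fractions_sum_to_one(self):
        cat = _np_catalog()
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = {g: int(c) for g, c in
                      zip(cat.gene_ids(), rng.integers(0, 500, 3))}
            if sum(counts.values()) == 0:
                continue
            prof = normalize(_table(counts, 10_000), cat, tau=0.25)
            if prof.frac:
                assert sum(prof.frac.values()) == pytest.approx(1.0)

    def test_scale_invariance(self):
        cat = _np_catalog()
        a = normalize(_table({"akh": 3, "npA": 11, "npB": 5}, 1000), cat)
        b = normalize(_table({"akh": 30, "npA": 110, "npB": 50}, 10_000), cat)
        assert a.frac == pytest.approx(b.frac)
        for g in a.spm:
            assert a.spm[g] == pytest.approx(b.spm[g])

    def test_exclusion_strictly_raises_remaining_fractions(self):
        cat = _np_catalog()
        counts = _table({"akh": 400, "npA": 50, "npB": 50}, 1000)
        keep = normalize(counts, cat, tau=0.9)    # akh stays in D
        drop = normalize(counts, cat, tau=0.25)   # akh excluded
        assert drop.excluded == {"akh"} and keep.excluded == set()
        for g in ("npA", "npB"):
            assert drop.frac[g] > keep.frac[g]

    def test_structural_load_contrast(self, full_catalog):
        """Spots-per-million fakes a ~2x caste difference that the
        neuropeptide fraction cancels."""
        prog = uniform_program(full_catalog, ["a", "b"], protein_level=100.0,
                               structural_load={"b": 2.0})
        idx = build_index(full_catalog)
        ratios_m, ratios_f = [], []
        for s in range(3):
            pa = normalize(count_spots(
                simulate_rnaseq(full_catalog, prog, "a", 6000, seed=80 + s),
                idx), full_catalog)
            pb = normalize(count_spots(
                simulate_rnaseq(full_catalog, prog, "b", 6000, seed=90 + s),
                idx), full_catalog)
            genes = [g for g in pa.frac if g in pb.frac
                     and pa.frac[g] > 0 and pb.frac[g] > 0]
            # geometric means: ratios at sparse counts are log-symmetric
            ratios_m.append(np.exp(np.mean(
                [np.log(pa.spm[g] / pb.spm[g]) for g in genes])))
            ratios_f.append(np.exp(np.mean(
                [np.log(pa.frac[g] / pb.frac[g]) for g in genes])))
        assert np.mean(ratios_m) > 1.5
        assert 0.8 < np.mean(ratios_f) < 1.25


class TestCasteTable:
    def _profiles(self, values_by_caste):
        out = {}
        for caste, reps in values_by_caste.items():
            out[caste] = [
                ExpressionProfile(f"{caste}-{i}", spm=dict(v), frac=dict(v),
                                  excluded=set(), tau=0.25)
                for i, v in enumerate(reps)
            ]
        return out

    def test_identical_profiles_fold_one_single_group(self):
        v = {"x": 0.5, "y": 0.5}
        comp = caste_table(self._profiles({"a": [v], "b": [v], "c": [v]}),
                           pseudocount=0.0)
        assert comp.table.loc["x", "fold"] == pytest.approx(1.0)
        assert set(comp.groups["x"].values()) == {"highest"}

    def test_zero_mean_without_pseudocount_flagged(self):
        comp = caste_table(self._profiles(
            {"a": [{"x": 0.4}], "b": [{"x": 0.0}]}), pseudocount=0.0)
        assert not comp.table.loc["x", "defined"]

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            caste_table({"a": []})

    def test_three_way_grouping_and_fold(self):
        vals = {"a": 1.7, "b": 0.6, "c": 0.1, "d": 0.1, "e": 0.1}
        profs = self._profiles({c: [{"x": v}] for c, v in vals.items()})
        comp = caste_table(profs, pseudocount=0.0)
        assert comp.groups["x"]["a"] == "highest"
        assert comp.groups["x"]["b"] == "intermediate"
        assert {comp.groups["x"][c] for c in "cde"} == {"lowest"}
        assert comp.table.loc["x", "fold"] == pytest.approx(17.0)

    def test_programmed_fold_recovered_from_simulation(self, np_catalog):
        """A compensated 17:6:1 abundance program for one gene comes back
        from simulated counts within 25 %."""
        from termipep import ExpressionProgram

        lam = {c: {g.gene_id: 1.0 for g in np_catalog} for c in "abc"}
        for caste, level in zip("abc", (3.4, 1.2, 0.2)):
            lam[caste]["hansolin"] = level
            lam[caste]["cnmamide"] = 1.0 + (3.4 - level)  # keep totals equal
        prog = ExpressionProgram(lam)
        idx = build_index(np_catalog)
        profs = {}
        for ci, caste in enumerate("abc"):
            profs[caste] = [
                normalize(count_spots(simulate_rnaseq(
                    np_catalog, prog, caste, 5000, seed=300 + 10 * ci + r),
                    idx), np_catalog)
                for r in range(3)
            ]
        comp = caste_table(profs, measure="frac", pseudocount=0.0)
        fold = comp.table.loc["hansolin", "fold"]
        assert abs(fold - 17.0) / 17.0 < 0.25


class TestCorrelate:
    def _profiles_from(self, pairs):
        return [ExpressionProfile(f"s{i}", spm={"x": x, "y": y}, frac=None,
                                  excluded=set(), tau=0.25)
                for i, (x, y) in enumerate(pairs)]

    def test_identity_is_perfect(self):
        profs = self._profiles_from([(v, v) for v in range(10)])
        res = correlate(profs, "x", "y")
        assert res.rho == pytest.approx(1.0) and res.n == 10

    def test_constant_vector_undefined(self):
        profs = self._profiles_from([(1.0, v) for v in range(5)])
        res = correlate(profs, "x", "y")
        assert not res.defined and np.isnan(res.rho)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            correlate(self._profiles_from([(1, 2), (3, 4)]), "x", "y")

    def test_anticorrelated_program_beats_bootstrap_null(self):
        """Simulated atirpin-down-when-vitellogenin-up profiles give a
        negative rank correlation outside the permutation null band."""
        cat = make_catalog(seed=5)
        idx = build_index(cat)
        profiles = []
        rng = np.random.default_rng(6)
        for i in range(10):
            vg = 10.0 + 40.0 * (i / 9)
            lam = {g.gene_id: 1.0 for g in cat}
            lam["vitellogenin"] = vg
            lam["atirpin"] = 51.0 - vg
            from termipep import ExpressionProgram

            prog = ExpressionProgram({"w": lam})
            rs = simulate_rnaseq(cat, prog, "w", 2500, seed=400 + i)
            profiles.append(normalize(count_spots(rs, idx), cat))
        res = correlate(profiles, "atirpin", "vitellogenin", measure="spm")
        assert res.defined and res.rho < 0
        xs = [p for p, _ in res.pairs]
        ys = [q for _, q in res.pairs]
        from scipy import stats as sps

        null = []
        for _ in range(200):
            perm = rng.permutation(ys)
            null.append(abs(sps.spearmanr(xs, perm).statistic))
        assert abs(res.rho) > np.quantile(null, 0.95)


class TestQC:
    def test_missing_brain_markers_with_ovary_signature(self, full_catalog):
        counts = {g: 0 for g in full_catalog.gene_ids()}
        counts["brovirpin"] = 500
        counts["vitellogenin-receptor"] = 300
        counts["hansolin"] = 40
        tab = _table(counts, 200_000)
        flags = qc_flags(tab, full_catalog, min_marker_spots=5,
                         depth_floor=100_000)
        assert {"missing_brain_markers", "ovary_signature"} <= flags.flags

    def test_clean_sample_unflagged(self, full_catalog):
        counts = {g: 50 for g in full_catalog.gene_ids()}
        counts["brovirpin"] = 0
        flags = qc_flags(_table(counts, 200_000), full_catalog,
                         min_marker_spots=5, depth_floor=100_000)
        assert flags.flags == set()

    def test_blacklisted_gene_contamination(self, full_catalog):
        counts = {g: 50 for g in full_catalog.gene_ids()}
        counts["brovirpin"] = 0
        counts["neuroparsin"] = 20
        flags = qc_flags(_table(counts, 200_000), full_catalog,
                         species_gene_blacklist={"neuroparsin"},
                         min_marker_spots=5, depth_floor=100_000)
        assert "foreign_gene_contamination" in flags.flags
        assert flags.support["foreign_gene_contamination"] == {"neuroparsin": 20}

    def test_low_depth_flag(self, full_catalog):
        counts = {g: 5 for g in full_catalog.gene_ids()}
        flags = qc_flags(_table(counts, 500), full_catalog, depth_floor=1000)
        assert "low_depth" in flags.flags
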