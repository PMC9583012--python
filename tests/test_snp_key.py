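import math

import numpy as np
import pytest

from barcodegap.io import GenotypeMatrix
from barcodegap.snp_key import (
    classify_sample,
    filter_sites,
    load_aegilops_panel,
    screen_diagnostic,
    site_stats,
)


@pytest.fixture(scope="module")
def panel():
    return load_aegilops_panel()


def gm_from_columns(columns, species_sizes, chrom="1D"):
    """Build a matrix from per-site call strings, one char per accession."""
    accessions = []
    species_of = {}
    for sp, size in species_sizes.items():
        for i in range(size):
            acc = f"{sp}{i}"
            accessions.append(acc)
            species_of[acc] = sp
    sites = [(chrom, 100 + i, f"{chrom}:{100 + i}") for i in range(len(columns))]
    calls = np.array([list(c) for c in columns], dtype="<U1").T
    return GenotypeMatrix(sites, accessions, species_of, calls)


class TestSiteStats:
    def test_published_panel_first_site(self, panel):
        gm, _ = panel
        st = site_stats(gm)[0]  # 1D:170914803 -- 11 C, 3 G of 14
        assert gm.sites[0] == ("1D", 170914803, "1D:170914803")
        assert st.major_allele == "C"
        assert st.major_af_printed == pytest.approx(0.78571)
        assert st.alleles == ["C", "G"]

    def test_all_panel_frequencies_match_printed_values(self, panel):
        gm, meta = panel
        recomputed = [s.major_af_printed for s in site_stats(gm)]
        printed = meta["major_allele_frequency"].tolist()
        assert len(recomputed) == 30
        for got, want in zip(recomputed, printed):
            assert got == pytest.approx(want, abs=5e-6)

    def test_monomorphic_site_frequency_one(self):
        gm = gm_from_columns(["AAAA"], {"x": 4})
        st = site_stats(gm)[0]
        assert st.major_af == 1.0 and st.alleles == ["A"]

    def test_het_calls_split_between_alleles(self):
        # Y = C/T: 2 C, 1 T, 1 Y -> C: 2.5/4, missing excluded from denominator
        gm = gm_from_columns(["CCTY."], {"x": 5})
        st = site_stats(gm)[0]
        assert st.major_allele == "C"
        assert st.major_af == pytest.approx(2.5 / 4)
        assert st.het_fraction == pytest.approx(1 / 5)
        assert st.missing_fraction == pytest.approx(1 / 5)

    def test_all_missing_site_undefined(self):
        gm = gm_from_columns(["...."], {"x": 4})
        st = site_stats(gm)[0]
        assert math.isnan(st.major_af) and st.major_allele is None

    def test_matches_brute_force_tally(self, rng):
        alphabet = list("ACGT.RY")
        cols = ["".join(rng.choice(alphabet, size=12)) for _ in range(40)]
        gm = gm_from_columns(cols, {"x": 12})
        from barcodegap.io import HET_TO_ALLELES
        for col, st in zip(cols, site_stats(gm)):
            counts: dict[str, float] = {}
            for c in col:
                if c in "ACGT":
                    counts[c] = counts.get(c, 0) + 1
                elif c in HET_TO_ALLELES:
                    for a in HET_TO_ALLELES[c]:
                        counts[a] = counts.get(a, 0) + 0.5
            non_missing = sum(1 for c in col if c != ".")
            if non_missing == 0:
                assert math.isnan(st.major_af)
                continue
            assert st.major_af == pytest.approx(max(counts.values()) / non_missing)
            assert st.missing_fraction == pytest.approx(col.count(".") / 12)
            assert st.het_fraction == pytest.approx(
                sum(col.count(h) for h in "RYSWKM") / 12)


class TestFilterSites:
    def test_monomorphic_site_removed(self):
        gm = gm_from_columns(["AAAAAAAAAA", "AAAAACCCCC"], {"x": 10})
        kept = filter_sites(gm)
        assert kept.n_sites == 1 and kept.sites[0][1] == 101

    def test_missing_fraction_threshold(self):
        gm = gm_from_columns(["AC.AACCAA."], {"x": 10})  # 20% missing
        assert filter_sites(gm, max_missing=0.05).n_sites == 0
        assert filter_sites(gm, max_missing=0.25).n_sites == 1

    def test_het_fraction_threshold(self):
        gm = gm_from_columns(["ACYYYAACCA"], {"x": 10})  # 30% het
        assert filter_sites(gm, max_het=0.20).n_sites == 0
        assert filter_sites(gm, max_het=0.50).n_sites == 1

    def test_matches_independent_three_predicate_scan(self, rng):
        alphabet = list("AACCGT.Y")
        cols = ["".join(rng.choice(alphabet, size=14)) for _ in range(1000)]
        gm = gm_from_columns(cols, {"x": 14})
        kept = filter_sites(gm)
        expected = []
        from barcodegap.io import HET_TO_ALLELES
        for sid, col in zip(gm.site_ids, cols):
            counts: dict[str, float] = {}
            for c in col:
                if c in "ACGT":
                    counts[c] = counts.get(c, 0) + 1
                elif c in HET_TO_ALLELES:
                    for a in HET_TO_ALLELES[c]:
                        counts[a] = counts.get(a, 0) + 0.5
            nm = sum(1 for c in col if c != ".")
            if nm == 0:
                continue
            maf = max(counts.values()) / nm
            miss = col.count(".") / 14
            het = sum(col.count(h) for h in "RYSWKM") / 14
            if maf <= 0.95 and miss <= 0.05 and het <= 0.20:
                expected.append(sid)
        assert kept.site_ids == expected

    def test_idempotent(self, rng):
        alphabet = list("AACCGT.Y")
        cols = ["".join(rng.choice(alphabet, size=10)) for _ in range(200)]
        gm = gm_from_columns(cols, {"x": 10})
        once = filter_sites(gm)
        twice = filter_sites(once)
        assert twice.site_ids == once.site_ids
        assert (twice.calls == once.calls).all()

    def test_threshold_range_validated(self, panel):
        gm, _ = panel
        with pytest.raises(ValueError):
            filter_sites(gm, max_missing=1.5)


class TestScreenDiagnostic:
    def test_single_private_allele_diagnoses_one_species(self):
        # biuncialis-like {C}, juvenalis-like {G}, columnaris-like {C}
        gm = gm_from_columns(["CCCCC" + "GGG" + "CCCCCC"],
                             {"biun": 5, "juv": 3, "col": 6})
        key = screen_diagnostic(gm)
        assert len(key) == 1
        assert key.sites[0].diagnosed_species == ["juv"]

    def test_within_species_polymorphism_keeps_other_private(self):
        # col = {A, C} overlaps biun = {C}; juv = {G} stays private
        gm = gm_from_columns(["CCCCC" + "GGG" + "ACCCCC"],
                             {"biun": 5, "juv": 3, "col": 6})
        key = screen_diagnostic(gm)
        assert len(key) == 1
        assert key.sites[0].diagnosed_species == ["juv"]
        assert key.sites[0].species_alleles["col"] == frozenset("AC")

    def test_shared_allele_everywhere_not_retained(self):
        gm = gm_from_columns(["TTTTT" + "TTT" + "TTTTTT",
                              "ATTTT" + "TAT" + "TTTTTA"],
                             {"biun": 5, "juv": 3, "col": 6})
        assert len(screen_diagnostic(gm)) == 0

    def test_het_call_shares_both_alleles(self):
        # juv would be private {G}, but a het K (G/T) in col shares G
        gm = gm_from_columns(["TTTTT" + "GGG" + "KTTTTT"],
                             {"biun": 5, "juv": 3, "col": 6})
        assert len(screen_diagnostic(gm)) == 0

    def test_published_panel_retains_all_thirty_sites(self, panel):
        gm, _ = panel
        key = screen_diagnostic(gm)
        assert len(key) == 30
        assert key.site_ids() == gm.site_ids

    def test_invariant_to_accession_and_species_order(self, panel):
        gm, _ = panel
        perm = np.random.default_rng(5).permutation(gm.n_accessions)
        shuffled = GenotypeMatrix(
            list(gm.sites),
            [gm.accessions[i] for i in perm],
            dict(gm.species_of),
            gm.calls[perm],
        )
        k1 = screen_diagnostic(gm)
        k2 = screen_diagnostic(shuffled, species_list=list(reversed(k1.species)))
        assert k1.site_ids() == k2.site_ids()
        for s1, s2 in zip(k1.sites, k2.sites):
            assert s1.diagnosed_species == s2.diagnosed_species
            assert s1.species_alleles == s2.species_alleles

    def test_fewer_than_two_species_rejected(self):
        gm = gm_from_columns(["AAAA"], {"x": 4})
        with pytest.raises(ValueError):
            screen_diagnostic(gm)


class TestClassifySample:
    def test_panel_juvenalis_column_classified(self, panel):
        gm, _ = panel
        key = screen_diagnostic(gm)
        idx = gm.accessions.index("W-43")
        calls = dict(zip(gm.site_ids, gm.calls[idx]))
        res = classify_sample(key, calls)
        assert res["verdict"] == "Ae. juvenalis"
        assert res["sites_used"] == 30

    def test_every_panel_accession_recovers_its_species(self, panel):
        gm, _ = panel
        key = screen_diagnostic(gm)
        for i, acc in enumerate(gm.accessions):
            res = classify_sample(key, dict(zip(gm.site_ids, gm.calls[i])))
            assert res["verdict"] == gm.species_of[acc], acc

    def test_all_missing_unclassified(self, panel):
        gm, _ = panel
        key = screen_diagnostic(gm)
        res = classify_sample(key, {sid: "." for sid in gm.site_ids})
        assert res["verdict"] is None and res["sites_used"] == 0

    def test_even_vote_split_is_tie(self):
        gm = gm_from_columns(["AAGGG", "TTCCC"], {"p": 2, "q": 3})
        key = screen_diagnostic(gm)
        assert len(key) == 2
        # call matches p's private allele at site 1 and q's at site 2: 1-1 tie
        votes = classify_sample(key, {key.sites[0].site_id: "A",
                                      key.sites[1].site_id: "C"})
        assert votes["verdict"] is None

    def test_unknown_sites_ignored_and_reported(self, panel):
        gm, _ = panel
        key = screen_diagnostic(gm)
        idx = gm.accessions.index("W-9")
        calls = dict(zip(gm.site_ids, gm.calls[idx]))
        calls["9Z:1"] = "A"
        res = classify_sample(key, calls)
        assert res["ignored_sites"] == ["9Z:1"]
        assert res["verdict"] == "Ae. columnaris"
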