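"""Seed matching against the exhaustive window oracle, site mutagenesis
postconditions, conservation flags and E-box scanning."""

import numpy as np
import pytest

from crcscreen.motifs import (MotifHit, SeedSite, conservation_flag,
                              find_seed_sites, mutate_sms, scan_ebox)
from crcscreen.simulate import MIR205_5P, gen_sequences

# miRNA with positions 2-8 = GAGGUAG (a let-7-family-style seed)
MIR = "UGAGGUAGUAGGUUGUAUAGUU"

_COMP = str.maketrans("ACGT", "TGCA")


def window_oracle(mirna, utr):
    """Brute-force oracle: slide every window and test each site
    definition independently, then keep the most specific per locus."""
    mir = mirna.upper().replace("U", "T")
    seq = utr.upper().replace("U", "T")
    seed6 = mir[1:7].translate(_COMP)[::-1]
    m8 = mir[7].translate(_COMP)
    out = []
    for i in range(len(seq) - 5):
        if "N" in seq[max(i - 1, 0):i + 7]:
            continue
        if seq[i:i + 6] != seed6:
            continue
        m8_ok = i >= 1 and seq[i - 1] == m8
        a1_ok = i + 6 < len(seq) and seq[i + 6] == "A"
        if m8_ok and a1_ok:
            out.append(("8mer", i - 1, i + 7))
        elif m8_ok:
            out.append(("7mer-m8", i - 1, i + 6))
        elif a1_ok:
            out.append(("7mer-A1", i, i + 7))
        else:
            out.append(("6mer", i, i + 6))
    return sorted(out)


class TestFindSeedSites:
    def test_forced_8mer(self):
        utr = "GGGG" + "CTACCTCA" + "GGGG"
        sites = find_seed_sites(MIR, utr)
        assert [(s.site_type, s.start, s.end) for s in sites] == \
            [("8mer", 4, 12)]
        assert sites[0].matched_seq == "CTACCTCA"

    def test_terminal_a_mutation_downgrades_to_7mer_m8(self):
        utr = "GGGG" + "CTACCTCG" + "GGGG"
        sites = find_seed_sites(MIR, utr)
        assert [(s.site_type, s.start, s.end) for s in sites] == \
            [("7mer-m8", 4, 11)]

    def test_matched_seq_equals_utr_slice(self):
        utr = "AATACCTCAGGTACCTCTT"
        for s in find_seed_sites(MIR, utr):
            assert s.matched_seq == utr[s.start:s.end]

    def test_equals_window_oracle_on_seeded_utrs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            utr = "".join(rng.choice(bases, size=3000))
            # salt with partial/complete site material to hit all classes
            utr = utr[:50] + "CTACCTCA" + utr[58:500] + "TACCTC" + utr[506:]
            got = sorted((s.site_type, s.start, s.end)
                         for s in find_seed_sites(MIR, utr))
            assert got == window_oracle(MIR, utr)

    def test_reverse_complement_strand_specific(self):
        utr = "GGGG" + "CTACCTCA" + "GGGG"
        rc = utr.translate(_COMP)[::-1]
        assert find_seed_sites(MIR, rc) == []

    def test_n_windows_skipped_with_warning(self):
        utr = "GGGG" + "CTANCTCA" + "GGGGCTACCTCAGG"
        with pytest.warns(UserWarning, match="ambiguous"):
            sites = find_seed_sites(MIR, utr)
        assert len(sites) == 1
        assert (sites[0].site_type, sites[0].start) == ("8mer", 16)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            find_seed_sites("UGAGGUA", "ACGTACGT")


class TestConservation:
    def test_identical_orthologs_all_conserved(self):
        utr = "GGGG" + "CTACCTCA" + "GGGGGG"
        sites = find_seed_sites(MIR, utr)
        flagged = conservation_flag(sites, MIR, {"a": utr, "b": utr,
                                                 "c": utr})
        assert all(s.conserved is True for s in flagged)

    def test_scrambled_seed_not_conserved(self):
        utr = "GGGG" + "CTACCTCA" + "GGGGGG"
        scrambled = "GGGG" + "GATGGAGA" + "GGGGGG"
        sites = find_seed_sites(MIR, utr)
        flagged = conservation_flag(sites, MIR,
                                    {"a": scrambled, "b": scrambled},
                                    k=1)
        assert all(s.conserved is False for s in flagged)

    def test_offset_mapping(self):
        utr = "GGGG" + "CTACCTCA" + "GGGGGG"
        shifted = "TT" + utr  # ortholog with a 2-nt 5' extension
        sites = find_seed_sites(MIR, utr)
        flagged = conservation_flag(sites, MIR, {"a": shifted, "b": shifted},
                                    k=2, offsets={"a": 2, "b": 2})
        assert all(s.conserved is True for s in flagged)

    def test_alignment_mapping_with_gaps(self):
        utr = "GGGG" + "CTACCTCA" + "GGG"
        orth = "GG" + "CTACCTCA" + "GGG"  # 2 nt deleted upstream
        aln = {"ref": "GGGGCTACCTCAGGG",
               "a": "--GGCTACCTCAGGG",
               "b": "--GGCTACCTCAGGG"}
        sites = find_seed_sites(MIR, utr)
        flagged = conservation_flag(sites, MIR, {"a": orth, "b": orth}, k=2,
                                    alignment=aln, reference="ref")
        assert all(s.conserved is True for s in flagged)

    def test_unmappable_site_unknown(self):
        utr = "GGGG" + "CTACCTCA" + "GGGGGG"
        sites = find_seed_sites(MIR, utr)
        flagged = conservation_flag(sites, MIR, {"a": "GG", "b": "GG"}, k=1)
        assert all(s.conserved is None for s in flagged)

    def test_generator_truth_recovered(self):
        utrs, orthologs, _, truth = gen_sequences(
            n_utrs=6, conservation_p=0.6, seed=5)
        k = truth.params["n_orthologs"] // 2 + 1
        for uid, seq in utrs.items():
            sites = find_seed_sites(MIR205_5P, seq)
            flagged = conservation_flag(sites, MIR205_5P, orthologs[uid],
                                        k=k)
            expect = {t["core_start"]: len(t["conserved_in"]) >= k
                      for t in truth.extras["sites"][uid]}
            for s in flagged:
                assert s.conserved == expect[s.core_start]


class TestMutateSMS:
    def test_postconditions(self):
        utr = "GGGG" + "CTACCTCA" + "GGGGGG"
        site = find_seed_sites(MIR, utr)[0]
        mutated = mutate_sms(utr, site)
        assert len(mutated) == len(utr)
        assert mutated[:site.start] == utr[:site.start]
        assert mutated[site.end:] == utr[site.end:]
        hits = [s for s in find_seed_sites(MIR, mutated)
                if s.start < site.end and s.end > site.start]
        assert hits == []

    def test_never_regains_site_over_seeded_utrs(self, rng):
        bases = np.array(list("ACGT"))
        regained = 0
        for _ in range(200):
            utr = "".join(rng.choice(bases, size=400))
            pos = int(rng.integers(10, 380))
            utr = utr[:pos] + "CTACCTCA" + utr[pos + 8:]
            for site in find_seed_sites(MIR, utr):
                mutated = mutate_sms(utr, site)
                again = [s for s in find_seed_sites(MIR, mutated)
                         if s.start < site.end and s.end > site.start]
                regained += bool(again)
        assert regained == 0

    def test_out_of_bounds_rejected(self):
        site = SeedSite("6mer", 90, 96, "TACCTC")
        with pytest.raises(ValueError, match="bounds"):
            mutate_sms("ACGTACGT", site)


class TestScanEbox:
    def test_canonical_myc_box(self):
        hits = scan_ebox("AAACACGTGAAA")
        assert [(h.motif_id, h.start, h.end) for h in hits] == \
            [("MYC", 3, 9)]

    def test_palindrome_reported_once_per_position(self):
        hits = scan_ebox("CACGTGCACGTG")
        assert [(h.start, h.strand) for h in hits] == [(0, "+"), (6, "+")]

    def test_non_palindromic_motif_hits_both_strands(self):
        hits = scan_ebox("AACACCTGAA", motifs={"CAGGTG": "EBOX_VAR"})
        assert [(h.start, h.strand) for h in hits] == [(2, "-")]

    def test_generator_truth_recovered(self):
        _, _, promoters, truth = gen_sequences(n_promoters=5, seed=9)
        for pid, seq in promoters.items():
            got = sorted((h.motif_id, h.start, h.end)
                         for h in scan_ebox(seq))
            want = sorted((t["motif_id"], t["start"], t["end"])
                          for t in truth.extras["motifs"][pid])
            assert got == want

    def test_empty_result_valid(self):
        assert scan_ebox("ATATATATAT") == []
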