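"""Motif model, information content, consensus, folding-energy proxy."""

import re

import numpy as np
import pytest

import tiercall as tc
from tiercall.errors import InputError
from tiercall.motif_structure import (
    MIN_HAIRPIN_LOOP,
    PAIR_ENERGY,
    MotifModel,
    write_motif_json,
)
from tiercall.synthetic_data import SimConfig, generate_genome, plant_cleavage_sites

from conftest import sites_df


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


class TestWindows:
    def test_plus_strand_window(self):
        genome = tc.Genome([("c", "AAAA" + "GATTT" + "CCCC")])  # motif at [4, 9)
        w = tc.extract_site_windows(sites_df([("c", 6, "+")]), genome)
        assert w == ["GATTT"]

    def test_minus_strand_window_is_reverse_complement(self):
        # want transcript window "GATTT" on the minus strand at pos 6:
        # genomic [4, 9) must be revcomp("GATTT") = "AAATC"
        genome = tc.Genome([("c", "AAAA" + "AAATC" + "CCCC")])
        w = tc.extract_site_windows(sites_df([("c", 6, "-")]), genome)
        assert w == ["GATTT"]

    def test_boundary_sites_skipped_with_warning(self):
        genome = tc.Genome([("c", "ACGTACGTAC")])
        with pytest.warns(UserWarning, match="skipped"):
            w = tc.extract_site_windows(sites_df([("c", 1, "+"), ("c", 5, "+")]), genome)
        assert len(w) == 1

    def test_planted_sites_yield_motif_windows(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=60_000, n_genes=15, n_planted_sites=40, seed=7
        )
        genome, ann = generate_genome(cfg)
        truth = plant_cleavage_sites(genome, ann, cfg)
        keys = [(s.chrom, s.pos, s.strand) for s in truth.planted_sites]
        windows = tc.extract_site_windows(sites_df(keys), truth.genome)
        assert len(windows) == len(keys)
        assert all(re.match(r"^[AG][ACGT][AT]TT$", w) for w in windows)


# ---------------------------------------------------------------------------
# PFM / information content / consensus
# ---------------------------------------------------------------------------


class TestMotifModel:
    def test_tally(self):
        model = tc.position_frequency_matrix(["AATTT", "GGTTT"])
        assert model.n == 2
        assert model.counts[0, 0] == 1 and model.counts[2, 0] == 1  # A, G at col 0
        assert model.counts[3, 2] == 2  # T at col 2
        assert (model.counts.sum(axis=0) == model.n).all()

    def test_windows_with_n_are_excluded(self):
        model = tc.position_frequency_matrix(["AATTT", "GNTTT"])
        assert model.n == 1

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            tc.position_frequency_matrix([])

    def test_sampled_consensus_frequencies(self):
        rng = np.random.default_rng(23)
        windows = [
            "AG"[rng.integers(2)] + "ACGT"[rng.integers(4)] + "AT"[rng.integers(2)] + "TT"
            for _ in range(10_000)
        ]
        f = tc.position_frequency_matrix(windows).frequencies
        assert f[0, 0] == pytest.approx(0.5, abs=0.02)  # A in R column
        assert f[2, 0] == pytest.approx(0.5, abs=0.02)  # G in R column
        assert f[0, 2] == pytest.approx(0.5, abs=0.02)  # A in W column
        assert f[3, 3] == 1.0 and f[3, 4] == 1.0

    def test_information_content_closed_form(self):
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[3, 0] = 100  # all T
        r, e_n = tc.information_content(MotifModel(counts=counts, n=100))
        assert e_n == pytest.approx(3 / (200 * np.log(2)), rel=1e-12)
        assert r[0] == pytest.approx(2 - e_n, rel=1e-12)
        assert r[0] == pytest.approx(1.9784, abs=1e-4)

    def test_uniform_column_clips_to_zero(self):
        counts = np.full((4, 1), 25, dtype=np.int64)
        r, _ = tc.information_content(MotifModel(counts=counts, n=100))
        assert r[0] == 0.0

    def test_pure_column_approaches_two_bits(self):
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[0, 0] = 10**9
        r, _ = tc.information_content(MotifModel(counts=counts, n=10**9))
        assert r[0] == pytest.approx(2.0, abs=1e-6)

    def test_ic_invariant_under_window_relabeling(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(300)]
        m1 = tc.position_frequency_matrix(windows)
        m2 = tc.position_frequency_matrix(list(reversed(windows)))
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_iupac_mapping(self):
        counts = np.array([[50], [3], [45], [2]], dtype=np.int64)  # A,C,G,T
        assert tc.consensus_call(MotifModel(counts=counts, n=100)) == "R"
        near_uniform = np.array([[26], [25], [25], [24]], dtype=np.int64)
        assert tc.consensus_call(MotifModel(counts=near_uniform, n=100)) == "N"

    def test_rna_display_marks_the_cut(self):
        assert tc.format_rna_consensus("RNWTT") == "RN↓WUU"

    def test_motif_json_payload(self, tmp_path):
        model = tc.position_frequency_matrix(["GATTT", "AAATT", "GCTTT", "AGATT"])
        payload = write_motif_json(model, tmp_path / "m.json")
        assert payload["n"] == 4
        assert len(payload["consensus_dna"]) == 5
        assert payload["error_bar_total_height_bits"] == pytest.approx(
            2 * 3 / (2 * 4 * np.log(2)), abs=1e-6
        )


# ---------------------------------------------------------------------------
# Folding-energy proxy
# ---------------------------------------------------------------------------


def enumerate_min_energy(seq: str) -> float:
    """Exhaustive minimum over all nested structures (oracle, n <= ~12)."""
    s = seq.upper().replace("U", "T")

    def best(i: int, j: int) -> float:
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return 0.0
        candidates = [best(i + 1, j)]
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            pe = PAIR_ENERGY.get((s[i], s[k]))
            if pe is not None:
                candidates.append(pe + best(i + 1, k - 1) + best(k + 1, j))
        return min(candidates)

    return best(0, len(s) - 1)


class TestFoldEnergy:
    def test_unpairable_and_short_sequences(self):
        assert tc.fold_energy("AAAAA") == 0.0
        assert tc.fold_energy("GC") == 0.0

    def test_triple_gc_hairpin(self):
        assert tc.fold_energy("GGGAAAACCC") == -9.0

    def test_accepts_rna_alphabet(self):
        assert tc.fold_energy("GGGAAAACCC") == tc.fold_energy("GGGAAAACCC".replace("T", "U"))

    def test_rejects_illegal_characters(self):
        with pytest.raises(InputError):
            tc.fold_energy("ACGX")

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert tc.fold_energy(seq) == enumerate_min_energy(seq), seq

    def test_reversal_symmetry(self):
        # reversal maps each pair (a,b) to (b,a); the energy table is
        # symmetric under that swap (GC/CG, AU/UA, GU/UG), so the minimum
        # is invariant.  Plain reverse-complement is NOT a symmetry: the
        # wobble pair G-T maps to A-C, which cannot pair.
        rng = np.random.default_rng(8)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 25))))
            assert tc.fold_energy(seq) == tc.fold_energy(seq[::-1])


# ---------------------------------------------------------------------------
# Context profiles
# ---------------------------------------------------------------------------


class TestContextProfiles:
    def test_all_at_genome_gives_unit_au_fraction(self):
        genome = tc.Genome([("c", "AT" * 300)])
        prof = tc.au_content_profile(sites_df([("c", 300, "+")]), genome, flank=20, window=10)
        assert np.allclose(prof.mean, 1.0)

    def test_gc_genome_with_planted_motif_elevates_only_motif_offsets(self):
        seq = list("G" * 400)
        seq[198:203] = list("AATTT")  # site at pos 200
        genome = tc.Genome([("c", "".join(seq))])
        prof = tc.au_content_profile(sites_df([("c", 200, "+")]), genome, flank=30, window=10)
        d = dict(zip(prof.offsets, prof.mean))
        assert d[-30] == 0.0
        assert d[-2] == pytest.approx(0.5)  # window [-2, 8) covers all 5 AT bases
        assert d[20] == 0.0

    def test_minus_strand_profile_uses_transcript_orientation(self):
        # AT-rich block strictly downstream (transcript) of a minus-strand site
        seq = list("G" * 400)
        seq[180:190] = list("A" * 10)  # genomic [180,190) = transcript offsets 10..19
        genome = tc.Genome([("c", "".join(seq))])
        prof = tc.au_content_profile(sites_df([("c", 199, "-")]), genome, flank=30, window=10)
        d = dict(zip(prof.offsets, prof.mean))
        assert d[10] == pytest.approx(1.0)
        assert d[-20] == 0.0

    def test_all_a_genome_has_zero_fold_energy_profile(self):
        genome = tc.Genome([("c", "A" * 500)])
        prof = tc.mfe_profile(sites_df([("c", 250, "+")]), genome, flank=20, window=20, step=10)
        assert np.allclose(prof.mean, 0.0)

    def test_hairpin_away_from_site_scores_lower_than_au_rich_site(self):
        seq = list("A" * 240 + "T" * 60)  # AT-only: weak pairing everywhere
        seq[250:270] = list("GGGGGGGGGGCCCCCCCCCC")  # strong hairpin at +~110
        genome = tc.Genome([("c", "".join(seq))])
        site = sites_df([("c", 140, "+")])
        prof = tc.mfe_profile(site, genome, flank=120, window=30, step=10)
        d = dict(zip(prof.offsets, prof.mean))
        assert min(d[100], d[110]) < d[0] - 10
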