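import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import certain_ppm, random_ppm, record
from oracles import brute_motif_distance
from prescan.motif_dictionary import (
    PFM,
    PPM,
    InvalidMatrixError,
    MotifParseError,
    collapse_similar,
    column_ic,
    curate,
    dedup_consensus,
    load_dictionary,
    motif_distance,
    parse_motifs,
    pfm_to_ppm,
    ppm_to_iupac,
    save_dictionary,
    trim_ppm,
    write_motifs,
)


class TestPfmToPpm:
    def test_uniform_counts(self):
        pfm = PFM("m", np.ones((4, 1)))
        ppm = pfm_to_ppm(pfm, 0.8)
        assert np.allclose(ppm.probs, 0.25)

    def test_zero_column_gets_pseudocount_only(self):
        ppm = pfm_to_ppm(PFM("m", np.zeros((4, 2))), 0.8)
        assert np.allclose(ppm.probs, 0.25)

    def test_hand_computed_column(self):
        pfm = PFM("m", np.array([[8.0], [0.0], [0.0], [0.0]]))
        ppm = pfm_to_ppm(pfm, 0.8)
        assert ppm.probs[0, 0] == pytest.approx(8.2 / 8.8)
        assert ppm.probs[1, 0] == pytest.approx(0.2 / 8.8)

    def test_columns_sum_to_one(self, rng):
        counts = rng.integers(0, 50, size=(4, 9)).astype(float)
        ppm = pfm_to_ppm(PFM("m", counts))
        assert np.allclose(ppm.probs.sum(axis=0), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidMatrixError):
            PFM("m", np.array([[-1.0], [1.0], [1.0], [1.0]]))

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(InvalidMatrixError):
            pfm_to_ppm(PFM("m", np.ones((4, 1))), 0.0)


class TestColumnIC:
    def test_uniform_is_zero(self):
        assert column_ic([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)

    def test_certain_base_is_two(self):
        assert column_ic([1, 0, 0, 0]) == pytest.approx(2.0)

    def test_half_half(self):
        assert column_ic([0.5, 0.5, 0, 0]) == pytest.approx(1.0)

    def test_rejects_bad_sum(self):
        with pytest.raises(InvalidMatrixError):
            column_ic([0.5, 0.5, 0.5, 0.5])

    @given(st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4))
    def test_range(self, raw):
        col = np.array(raw) / sum(raw)
        assert -1e-9 <= column_ic(col) <= 2 + 1e-9


def ppm_from_ic(ics):
    """Build a PPM whose per-column IC roughly matches the given values:
    IC 0 -> uniform, IC 1 -> (0.5,0.5,0,0), IC 2 -> certain."""
    cols = []
    for ic in ics:
        if ic == 0:
            cols.append([0.25] * 4)
        elif ic == 1:
            cols.append([0.5, 0.5, 0.0, 0.0])
        elif ic == 2:
            cols.append([1.0, 0.0, 0.0, 0.0])
        else:  # ~0.3 bits
            cols.append([0.53, 0.17, 0.15, 0.15])
    return PPM("m", np.array(cols).T)


class TestTrim:
    def test_strict_trims_flanks(self):
        ppm = ppm_from_ic([0, 0, 2, 2, 2, 2, 0])
        trimmed = trim_ppm(ppm)
        assert trimmed.width == 4
        assert np.allclose(trimmed.probs, ppm.probs[:, 2:6])

    def test_all_uniform_discarded(self):
        assert trim_ppm(ppm_from_ic([0, 0, 0, 0, 0])) is None

    def test_relaxed_rescues_narrow_strict_result(self):
        # IC pattern (0, .3, .2, .3, .3): strict keeps only the last two
        # columns; relaxed keeps columns 1..4
        cols = [
            [0.25, 0.25, 0.25, 0.25],
            [0.53, 0.17, 0.15, 0.15],
            [0.45, 0.19, 0.18, 0.18],
            [0.53, 0.17, 0.15, 0.15],
            [0.53, 0.17, 0.15, 0.15],
        ]
        ppm = PPM("m", np.array(cols).T)
        ics = [column_ic(c) for c in ppm.probs.T]
        assert ics[0] < 0.25 and ics[2] < 0.25 and ics[1] > 0.25
        trimmed = trim_ppm(ppm)
        assert trimmed.width == 4
        assert np.allclose(trimmed.probs, ppm.probs[:, 1:5])

    def test_relaxed_still_too_narrow_discards(self):
        assert trim_ppm(ppm_from_ic([0, 2, 2, 0])) is None

    def test_wide_informative_matrix_untouched(self):
        ppm = ppm_from_ic([2, 2, 1, 2, 2])
        assert trim_ppm(ppm).width == 5


class TestIupac:
    def test_certain_base(self):
        assert ppm_to_iupac(ppm_from_ic([2])) == "A"

    def test_two_base_degeneracy(self):
        assert ppm_to_iupac(ppm_from_ic([1])) == "M"  # A/C at 0.5 each

    def test_uniform_is_n(self):
        assert ppm_to_iupac(ppm_from_ic([0])) == "N"

    def test_deterministic_boundary(self):
        ppm = PPM("m", np.array([[0.25], [0.25], [0.25], [0.25]]))
        assert ppm_to_iupac(ppm) == "N"


class TestDedupConsensus:
    def test_identical_pair_one_removed(self):
        a, b = record("a", "ACGTAC"), record("b", "ACGTAC")
        kept, removed = dedup_consensus([a, b])
        assert [r.motif_id for r in kept] == ["a"]  # id tie-break
        assert removed[0].motif_id == "b" and removed[0].kept_id == "a"

    def test_large_ppm_difference_keeps_both(self):
        a = record("a", "AAAA", p=0.97)
        b = record("b", "AAAA", p=0.85)  # same consensus, |dPPM| mean > 0.05
        diff = np.mean(np.abs(a.ppm.probs - b.ppm.probs))
        assert diff > 0.05
        kept, removed = dedup_consensus([a, b])
        assert len(kept) == 2 and not removed

    def test_different_widths_both_kept(self):
        kept, removed = dedup_consensus([record("a", "AAAA"), record("b", "AAAAA")])
        assert len(kept) == 2

    def test_lower_ic_member_removed(self):
        strong = record("strong", "ACGT", p=0.97)
        weak = record("weak", "ACGT", p=0.95)
        kept, removed = dedup_consensus([weak, strong])
        assert [r.motif_id for r in kept] == ["strong"]

    def test_never_increases_size(self, rng):
        records = [
            record(f"m{i}", "".join(rng.choice(list("ACGT"), size=6)))
            for i in range(12)
        ]
        kept, removed = dedup_consensus(records)
        assert len(kept) + len(removed) == len(records)
        assert len(kept) <= len(records)


class TestMotifDistance:
    def test_identical_is_zero(self):
        ppm = certain_ppm("m", "ACGTAG")
        assert motif_distance(ppm, ppm) == pytest.approx(0.0, abs=1e-12)

    def test_reverse_complement_is_zero(self):
        ppm = certain_ppm("m", "ACGTAG")
        assert motif_distance(ppm, ppm.reverse_complement()) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_symmetric(self, rng):
        a, b = random_ppm(rng, "a"), random_ppm(rng, "b")
        assert motif_distance(a, b) == pytest.approx(motif_distance(b, a))

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            a, b = random_ppm(rng, "a"), random_ppm(rng, "b")
            assert motif_distance(a, b) == pytest.approx(
                brute_motif_distance(a.probs, b.probs)
            )

    def test_anticorrelated_polymers(self):
        a = certain_ppm("a", "AAAAAA", p=1.0 - 3e-9)
        b = certain_ppm("b", "CCCCCC", p=1.0 - 3e-9)
        assert motif_distance(a, b) == pytest.approx(
            brute_motif_distance(a.probs, b.probs)
        )
        assert motif_distance(a, b) > 1.0  # anti-correlated

    def test_short_overlap_impossible(self):
        a = PPM("a", np.array([[1.0], [0.0], [0.0], [0.0]]))
        b = PPM("b", np.array([[1.0], [0.0], [0.0], [0.0]]))
        assert motif_distance(a, b) == 1.0


class TestCollapseSimilar:
    def test_three_identical_kept_one(self):
        records = [record(f"m{i}", "ACGTAC") for i in range(3)]
        kept, removed = collapse_similar(records)
        assert len(kept) == 1 and len(removed) == 2

    def test_no_close_pairs_identity(self):
        records = [record("a", "AAAAAA"), record("b", "CGCGCG")]
        kept, removed = collapse_similar(records)
        assert len(kept) == 2 and not removed

    def test_single_linkage_chain(self):
        # a == b and b == c byte-wise => one group of 3 even though the
        # threshold is tiny
        a = record("a", "ACGTAC", p=0.97)
        b = record("b", "ACGTAC", p=0.97)
        c = record("c", "ACGTAC", p=0.97)
        kept, removed = collapse_similar([a, b, c])
        assert len(kept) == 1
        assert {e.kept_id for e in removed} == {kept[0].motif_id}

    def test_kept_has_max_ic(self):
        strong = record("s", "ACGTAC", p=0.99)
        weak = record("w", "ACGTAC", p=0.99)
        kept, _ = collapse_similar([weak, strong])
        assert kept[0].avg_information_content >= weak.avg_information_content


class TestCurate:
    def test_provenance_covers_all_removals(self):
        from prescan.motif_dictionary import MotifRecord

        records = [
            record("a", "ACGTAC"),
            record("b", "ACGTAC"),  # consensus duplicate
            MotifRecord("u", PPM("u", np.full((4, 4), 0.25))),  # trim discard
        ]
        dictionary = curate(records)
        assert len(dictionary) == 1
        steps = {e.motif_id: e.step for e in dictionary.provenance}
        assert steps["u"] == "trim_discard"
        assert steps["b"] == "consensus_dedup"
        ids = [e.motif_id for e in dictionary.provenance]
        assert len(ids) == len(set(ids))  # each removed motif appears once

    def test_retained_width_at_least_four(self, rng):
        records = [
            record(f"m{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 9)))))
            for i in range(10)
        ]
        dictionary = curate(records)
        assert all(r.width >= 4 for r in dictionary)

    def test_order_insensitive_size(self, rng):
        records = [
            record(f"m{i}", "".join(rng.choice(list("ACGT"), size=6)))
            for i in range(10)
        ]
        d1 = curate(records)
        d2 = curate(records[::-1])
        assert len(d1) == len(d2)
        assert set(d1.motif_ids) == set(d2.motif_ids)


class TestParsers:
    def test_jaspar_roundtrip(self, tmp_path, rng):
        pfm = PFM("MA0001", rng.integers(0, 30, size=(4, 6)).astype(float))
        path = tmp_path / "motifs.jaspar"
        write_motifs([pfm], path, "jaspar_counts")
        parsed = parse_motifs(path, "jaspar_counts")
        assert len(parsed) == 1
        assert parsed[0].motif_id == "MA0001"
        assert parsed[0].counts.shape == (4, 6)
        assert np.allclose(parsed[0].counts, pfm.counts, atol=1e-6)

    def test_meme_roundtrip(self, tmp_path, rng):
        ppm = random_ppm(rng, "meme1", width=5)
        path = tmp_path / "motifs.meme"
        write_motifs([ppm], path, "meme_probs")
        parsed = parse_motifs(path, "meme_probs")
        assert parsed[0].pseudocount_applied == 0.0
        assert np.allclose(parsed[0].probs.sum(axis=0), 1.0)
        assert np.allclose(parsed[0].probs, ppm.probs, atol=1e-5)

    def test_transfac_roundtrip(self, tmp_path, rng):
        pfm = PFM("T0001", rng.integers(0, 20, size=(4, 7)).astype(float))
        path = tmp_path / "motifs.transfac"
        write_motifs([pfm], path, "transfac_like")
        parsed = parse_motifs(path, "transfac_like")
        assert np.allclose(parsed[0].counts, pfm.counts, atol=1e-6)

    def test_ragged_rows_error_names_line(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">bad\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(MotifParseError, match="line"):
            parse_motifs(path, "jaspar_counts")

    def test_non_numeric_cell_error(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">bad\nA [ 1 x 3 ]\nC [ 1 2 3 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(MotifParseError, match="line 2"):
            parse_motifs(path, "jaspar_counts")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            parse_motifs(path, "nonsense")


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, rng):
        records = [
            record("a", "ACGTAC", genes=["GENE1"], dbd_superfamily="helix-turn-helix"),
            record("b", "GGGTTT"),
        ]
        dictionary = curate(records)
        save_dictionary(dictionary, tmp_path / "dict")
        loaded = load_dictionary(tmp_path / "dict")
        assert set(loaded.motif_ids) == set(dictionary.motif_ids)
        original = dictionary.get("a")
        restored = loaded.get("a")
        assert np.allclose(original.ppm.probs, restored.ppm.probs, atol=1e-9)
        assert restored.genes == ["GENE1"]
        assert restored.dbd_superfamily == "helix-turn-helix"
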