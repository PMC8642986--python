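"""K2P distances, marker summaries and barcode-gap analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekit.distmat import (
    DistanceMatrix,
    barcode_gap,
    k2p_distance,
    p_distance,
    pairwise_matrix,
    partition_distances,
    summarize_marker,
)
from barcodekit.seq_io import MarkerAlignment, SpecimenRecord

from conftest import random_labeled_matrix


def _k2p_closed_form(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    @pytest.mark.parametrize(
        "n_ts,n_tv,expected",
        [
            # 20 bp: frozen values from the closed form at high precision
            (2, 0, 0.11157177565710485),
            (2, 2, 0.23412335979791865),
        ],
    )
    def test_closed_form_examples(self, n_ts, n_tv, expected):
        a = "ACGT" * 5
        b = list(a)
        ts = {"A": "G", "C": "T", "G": "A", "T": "C"}
        tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for p in range(n_ts):
            b[p] = ts[b[p]]
        for p in range(n_ts, n_ts + n_tv):
            b[p] = tv[b[p]]
        d = k2p_distance(a, "".join(b))
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(_k2p_closed_form(n_ts / 20, n_tv / 20), abs=1e-12)

    def test_gap_and_ambiguity_sites_excluded(self):
        # pairwise deletion: only the 4 clean columns are compared
        a = "ACGTRN-A"
        b = "ACGTA-NG"
        # comparable: cols 0-3 and 7; one transition at col 7 (A->G)
        assert k2p_distance(a, b) == pytest.approx(_k2p_closed_form(1 / 5, 0))

    def test_min_overlap_missing(self):
        assert np.isnan(k2p_distance("A---", "-CGT", min_overlap=1))
        assert np.isnan(k2p_distance("ACGT", "ACGT", min_overlap=5))

    def test_saturation_sentinel(self):
        # all transversions: Q = 1 -> 1-2Q < 0 -> saturated
        assert np.isinf(k2p_distance("AAAA", "CCCC"))

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="unequal"):
            k2p_distance("ACGT", "ACG")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_k2p_at_least_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 80))
        b = "".join(rng.choice(bases, 80))
        k2p = k2p_distance(a, b)
        if np.isfinite(k2p):
            assert k2p >= p_distance(a, b) - 1e-12


class TestPairwiseMatrix:
    def test_identical_sequences_all_zero(self):
        aln = MarkerAlignment("mk", {f"s{i}": "ACGTAC" * 10 for i in range(3)})
        m = pairwise_matrix(aln, min_overlap=1)
        assert np.all(m.d == 0)

    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(1)
        chars = np.array(list("ACGT-NR"))
        seqs = {
            f"s{i}": "".join(rng.choice(chars, 90, p=[0.2, 0.2, 0.2, 0.2, 0.1, 0.05, 0.05]))
            for i in range(10)
        }
        aln = MarkerAlignment("mk", seqs)
        m = pairwise_matrix(aln, min_overlap=20)
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i >= j:
                    continue
                ref = k2p_distance(seqs[a], seqs[b], min_overlap=20)
                if np.isnan(ref):
                    assert np.isnan(m.d[i, j])
                else:
                    assert m.d[i, j] == pytest.approx(ref, abs=1e-12)

    def test_gap_only_overlap_is_missing(self):
        aln = MarkerAlignment(
            "mk", {"a": "ACGT----", "b": "----ACGT", "c": "ACGTACGT"}
        )
        m = pairwise_matrix(aln, min_overlap=1)
        assert np.isnan(m.get("a", "b"))
        assert np.isfinite(m.get("a", "c"))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(6)}
        m = pairwise_matrix(MarkerAlignment("mk", seqs), min_overlap=1)
        assert np.allclose(m.d, m.d.T)
        assert np.all(np.diag(m.d) == 0)


class TestPartition:
    def test_two_by_two_counts(self):
        specimens = [
            SpecimenRecord(s, sp, site_id="X")
            for s, sp in [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]
        ]
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0)
        m = DistanceMatrix(["a1", "a2", "b1", "b2"], d, np.full((4, 4), 50))
        intra, inter = partition_distances(m, specimens)
        assert len(intra) == 2 and len(inter) == 4

    def test_all_conspecific_no_inter(self):
        specimens = [SpecimenRecord(f"s{i}", "A", site_id="X") for i in range(3)]
        d = np.ones((3, 3)) * 0.1
        np.fill_diagonal(d, 0)
        m = DistanceMatrix([f"s{i}" for i in range(3)], d, np.full((3, 3), 50))
        intra, inter = partition_distances(m, specimens)
        assert len(intra) == 3 and inter == []

    def test_counts_match_enumeration_and_hybrids_excluded(self):
        rng = np.random.default_rng(3)
        m, specimens = random_labeled_matrix(rng, n_species=5)
        specimens[0].group = "hybrid"
        intra, inter = partition_distances(m, specimens)
        sp = {r.specimen_id: r.species for r in specimens if r.group != "hybrid"}
        exp_intra = exp_inter = 0
        for i, a in enumerate(m.ids):
            for j in range(i + 1, len(m.ids)):
                b = m.ids[j]
                if a in sp and b in sp:
                    if sp[a] == sp[b]:
                        exp_intra += 1
                    else:
                        exp_inter += 1
        assert len(intra) == exp_intra and len(inter) == exp_inter


class TestMarkerSummary:
    def test_identical_alignment(self):
        specimens = [SpecimenRecord(f"s{i}", "A", site_id="X") for i in range(3)]
        aln = MarkerAlignment("mk", {f"s{i}": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" for i in range(3)})
        s = summarize_marker(aln, specimens, min_overlap=10)
        assert s.variable_sites == 0
        assert s.max_intraspecific == 0

    def test_hand_counted_columns(self):
        # 3 sequences x 10 columns, counts tallied by hand:
        # col0 A/A/G variable; col3 gap in s3; col5 N in s2 (not variable,
        # A/A remain); col7 C/T variable; col9 gap+variable
        aln = MarkerAlignment(
            "mk",
            {
                "s1": "ACGTAAACTA",
                "s2": "ACGTANACTG",
                "s3": "GCG-AAATT-",
            },
        )
        specimens = [SpecimenRecord(s, "Sp", site_id="X") for s in ("s1", "s2", "s3")]
        s = summarize_marker(aln, specimens, min_overlap=1)
        assert s.alignment_length == 10
        assert s.gap_columns == 2  # cols 3 and 9
        assert s.variable_sites == 3  # cols 0, 7, 9
        # GC over unambiguous bases: count G+C among all A/C/G/T chars
        flat = "".join(aln.sequences.values()).replace("-", "").replace("N", "")
        expected_gc = 100.0 * sum(c in "GC" for c in flat) / len(flat)
        assert s.gc_content == pytest.approx(expected_gc)

    def test_valid_conspecific_counting(self):
        seqs = {"a1": "ACGT" * 20, "a2": "ACGT" * 20, "b1": "ACGT" * 20}
        specimens = [
            SpecimenRecord("a1", "A", site_id="X"),
            SpecimenRecord("a2", "A", site_id="X"),
            SpecimenRecord("b1", "B", site_id="X"),
        ]
        s = summarize_marker(MarkerAlignment("mk", seqs), specimens, min_overlap=10)
        assert s.n_species == 2
        assert s.n_species_valid == 1  # only A has >= 2 sequences
        assert s.pct_valid_conspecifics == pytest.approx(100.0 * 2 / 3)


class TestBarcodeGap:
    def _matrix(self, ids, d):
        d = np.asarray(d, float)
        return DistanceMatrix(ids, d, np.full(d.shape, 99))

    def test_clear_gap_both_species(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = [
            [0, 0.01, 0.2, 0.2],
            [0.01, 0, 0.2, 0.2],
            [0.2, 0.2, 0, 0.01],
            [0.2, 0.2, 0.01, 0],
        ]
        specimens = [SpecimenRecord(s, s[0].upper(), site_id="X") for s in ids]
        g = barcode_gap(self._matrix(ids, d), specimens)
        assert g.percent_with_gap == 100.0
        assert g.table["has_gap"].all()

    def test_overlapping_species_fails_strictly(self):
        # B's nearest heterospecific (0.05 to a2) is closer than its
        # farthest conspecific pair (0.08)
        ids = ["a1", "a2", "b1", "b2"]
        d = [
            [0, 0.01, 0.30, 0.30],
            [0.01, 0, 0.05, 0.30],
            [0.30, 0.05, 0, 0.08],
            [0.30, 0.30, 0.08, 0],
        ]
        specimens = [SpecimenRecord(s, s[0].upper(), site_id="X") for s in ids]
        g = barcode_gap(self._matrix(ids, d), specimens)
        row_b = g.table.set_index("species").loc["B"]
        assert not row_b["has_gap"]
        assert g.percent_with_gap == 50.0

    def test_tie_counts_as_no_gap(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = [
            [0, 0.1, 0.1, 0.2],
            [0.1, 0, 0.2, 0.2],
            [0.1, 0.2, 0, 0.05],
            [0.2, 0.2, 0.05, 0],
        ]
        specimens = [SpecimenRecord(s, s[0].upper(), site_id="X") for s in ids]
        g = barcode_gap(self._matrix(ids, d), specimens)
        assert not g.table.set_index("species").loc["A"]["has_gap"]  # 0.1 == 0.1

    def test_single_species_errors(self):
        ids = ["a1", "a2"]
        specimens = [SpecimenRecord(s, "A", site_id="X") for s in ids]
        with pytest.raises(ValueError, match="2 species"):
            barcode_gap(self._matrix(ids, [[0, 0.1], [0.1, 0]]), specimens)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m, specimens = random_labeled_matrix(rng, n_species=4)
            g = barcode_gap(m, specimens)
            sp = {r.specimen_id: r.species for r in specimens}
            for _, row in g.table.iterrows():
                mine = [i for i, s in enumerate(m.ids) if sp[s] == row["species"]]
                others = [i for i, s in enumerate(m.ids) if sp[s] != row["species"]]
                intra = [m.d[i, j] for i in mine for j in mine if i < j]
                inter = [m.d[i, j] for i in mine for j in others]
                if len(mine) >= 2:
                    assert row["max_intra"] == pytest.approx(max(intra))
                    assert row["has_gap"] == (min(inter) > max(intra))
                else:
                    assert np.isnan(row["max_intra"]) and not row["counted"]
                assert row["min_inter"] == pytest.approx(min(inter))

    def test_percentage_invariant_under_relabeling(self):
        rng = np.random.default_rng(12)
        m, specimens = random_labeled_matrix(rng, n_species=4)
        g1 = barcode_gap(m, specimens)
        # reorder specimens and rename species
        perm = rng.permutation(len(m.ids))
        m2 = m.subset([m.ids[i] for i in perm])
        renamed = [
            SpecimenRecord(r.specimen_id, "Genus " + r.species, site_id=r.site_id)
            for r in specimens
        ]
        g2 = barcode_gap(m2, renamed)
        assert g1.percent_with_gap == g2.percent_with_gap
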