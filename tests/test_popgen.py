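"""Core statistics: p-distances, π, Dxy, Da, site classes, Tajima's D,
Fisher's exact test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from haplospread.alignment import Alignment, InputError
from haplospread.popgen import (
    divergence_summary,
    fisher_exact_2x2,
    nucleotide_diversity,
    pairwise_distances,
    tajimas_d,
)

from conftest import random_alignment


def brute_force_distance(seq_a: str, seq_b: str, columns) -> float:
    """Column-by-column p-distance oracle."""
    diff = sum(1 for j in columns if seq_a[j] != seq_b[j])
    return diff / len(columns)


def enumeration_fisher(table) -> Fraction:
    """Exact two-tailed Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


class TestPairwiseDistances:
    def test_hand_case(self):
        aln = Alignment.from_records(
            [("s1", "AAAAAAAAAA"), ("s2", "AAAAAAAAAT"), ("s3", "AAAAAAAATT")]
        )
        dm = pairwise_distances(aln)
        assert dm.d[0, 1] == pytest.approx(0.1)
        assert dm.d[0, 2] == pytest.approx(0.2)
        assert dm.d[1, 2] == pytest.approx(0.1)

    def test_identical_sequences_zero(self):
        aln = Alignment.from_records([("s1", "ACGT"), ("s2", "ACGT")])
        assert pairwise_distances(aln).d[0, 1] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            aln = random_alignment(rng, 8, 30, missing_rate=0.05)
            miss = aln.missing_mask()
            columns = [j for j in range(30) if not miss[:, j].any()]
            if not columns:
                continue
            dm = pairwise_distances(aln)
            seqs = dict(aln.records())
            for i in range(8):
                for j in range(i + 1, 8):
                    expected = brute_force_distance(
                        seqs[aln.ids[i]], seqs[aln.ids[j]], columns
                    )
                    assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal(self, rng):
        dm = pairwise_distances(random_alignment(rng, 6, 25))
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestDiversityAndDivergence:
    def test_pi_hand_case(self):
        aln = Alignment.from_records(
            [("s1", "AAAAAAAAAA"), ("s2", "AAAAAAAAAT"), ("s3", "AAAAAAAATT")]
        )
        assert nucleotide_diversity(aln) == pytest.approx((0.1 + 0.2 + 0.1) / 3)

    def test_pi_monomorphic_zero(self):
        aln = Alignment.from_records([("s1", "ACGT"), ("s2", "ACGT")])
        assert nucleotide_diversity(aln) == 0.0

    def test_pi_requires_two_sequences(self):
        with pytest.raises(InputError):
            nucleotide_diversity(Alignment.from_records([("s1", "ACGT")]))

    def test_dxy_da_hand_case(self):
        x = Alignment.from_records([("x1", "AAAA")])
        y = Alignment.from_records([("y1", "AAAT"), ("y2", "AATT")])
        s = divergence_summary(x, y)
        assert s.dxy == pytest.approx(0.375)
        assert s.da == pytest.approx(0.25)

    def test_da_zero_for_identical_monomorphic_groups(self):
        """Two monomorphic, identical groups have dxy = da = 0.  (For
        *polymorphic* duplicated samples da is negative: the cross-group
        mean includes zero-distance self-pairs, so dxy < pi.)"""
        x = Alignment.from_records([("x1", "ACGT"), ("x2", "ACGT")])
        y = Alignment.from_records([("y1", "ACGT"), ("y2", "ACGT")])
        s = divergence_summary(x, y)
        assert s.dxy == 0.0 and s.da == 0.0
        xp = Alignment.from_records([("x1", "ACGT"), ("x2", "ACTT")])
        yp = Alignment.from_records([("y1", "ACGT"), ("y2", "ACTT")])
        assert divergence_summary(xp, yp).da == pytest.approx(-0.125)

    def test_da_identity_random_alignments(self, rng):
        """da == dxy - (piX + piY)/2 to machine precision (shared site set)."""
        for _ in range(50):
            nx, ny = rng.integers(2, 6, size=2)
            aln = random_alignment(rng, int(nx + ny), 25, missing_rate=0.05)
            ids = list(aln.ids)
            x, y = aln.subset(ids[:nx]), aln.subset(ids[nx:])
            try:
                s = divergence_summary(x, y)
            except InputError:
                continue  # all columns lost to complete deletion
            assert s.da == pytest.approx(s.dxy - (s.pi_x + s.pi_y) / 2, abs=1e-15)

    def test_dxy_symmetric(self, rng):
        aln = random_alignment(rng, 7, 30)
        ids = list(aln.ids)
        x, y = aln.subset(ids[:3]), aln.subset(ids[3:])
        assert divergence_summary(x, y).dxy == pytest.approx(
            divergence_summary(y, x).dxy
        )


class TestSiteClassification:
    @pytest.mark.parametrize(
        "x_col,y_col,label",
        [
            ("AA", "TT", "fixed"),
            ("AT", "AT", "shared"),
            ("AT", "AA", "private_x"),
            ("AA", "AT", "private_y"),
            ("AT", "CG", "fixed"),  # disjoint allele sets, both polymorphic
        ],
    )
    def test_single_column_labels(self, x_col, y_col, label):
        x = Alignment.from_records([(f"x{i}", c) for i, c in enumerate(x_col)])
        y = Alignment.from_records([(f"y{i}", c) for i, c in enumerate(y_col)])
        s = divergence_summary(x, y)
        assert [sl.label for sl in s.site_labels] == [label]

    def test_labels_partition_variable_columns(self, rng):
        """Every variable column receives exactly one label and the counts
        add up."""
        for _ in range(20):
            aln = random_alignment(rng, 8, 30, alphabet="ACGT")
            ids = list(aln.ids)
            s = divergence_summary(aln.subset(ids[:4]), aln.subset(ids[4:]))
            assert s.fixed + s.shared + s.private_x + s.private_y == len(s.site_labels)
            assert len({sl.column for sl in s.site_labels}) == len(s.site_labels)


class TestTajimasD:
    def test_hand_derived_n4_case(self):
        """n=4 with one singleton and one doubleton site: D ≈ +0.59."""
        aln = Alignment.from_records(
            [("s1", "AA"), ("s2", "AA"), ("s3", "AT"), ("s4", "TT")]
        )
        st = tajimas_d(aln)
        assert st.s == 2
        assert st.k_hat == pytest.approx(7 / 6)
        assert st.tajima_d == pytest.approx(0.5916, abs=5e-4)

    def test_matches_independent_reference(self, rng):
        """Agrees with dendropy's implementation on random alignments."""
        import dendropy
        from dendropy.calculate import popgenstat

        for _ in range(10):
            aln = random_alignment(rng, 8, 30)
            try:
                ours = tajimas_d(aln).tajima_d
            except InputError:
                continue
            mat = dendropy.DnaCharacterMatrix.from_dict(dict(aln.records()))
            assert ours == pytest.approx(popgenstat.tajimas_d(mat), abs=1e-9)

    def test_sign_intermediate_vs_singletons(self):
        """All intermediate-frequency sites give D>0; all singletons D<0."""
        inter = Alignment.from_records(
            [(f"s{i}", "AAAA" if i < 4 else "TTTT") for i in range(8)]
        )
        assert tajimas_d(inter).tajima_d > 0
        rows = []
        for i in range(8):
            row = ["A"] * 8
            row[i] = "T"
            rows.append((f"s{i}", "".join(row)))
        assert tajimas_d(Alignment.from_records(rows)).tajima_d < 0

    def test_zero_when_khat_equals_watterson(self):
        """n=4 with 8 singleton and 3 doubleton sites has k_hat == S/a1
        exactly (both equal 6), so D = 0."""
        cols = []
        for i in range(8):  # singleton columns
            col = ["A"] * 4
            col[i % 4] = "T"
            cols.append(col)
        for i in range(3):  # doubleton columns
            col = ["A"] * 4
            col[i % 4] = col[(i + 1) % 4] = "T"
            cols.append(col)
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        st = tajimas_d(
            Alignment.from_records([(f"s{i}", r) for i, r in enumerate(rows)])
        )
        assert st.s == 11
        assert st.k_hat == pytest.approx(6.0)
        assert st.tajima_d == pytest.approx(0.0, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(InputError):
            tajimas_d(Alignment.from_records([("s1", "AT"), ("s2", "TA"), ("s3", "AT")]))
        with pytest.raises(InputError):
            tajimas_d(
                Alignment.from_records([(f"s{i}", "ACGT") for i in range(5)])
            )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[6, 0], [0, 6]], 2 / 924),
            ([[1, 1], [1, 1]], 1.0),
            ([[1, 9], [10, 2]], 1232 / 646646),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-7)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(60):
            t = rng.integers(1, 12, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                float(enumeration_fisher(t)), rel=1e-7
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[0, 0], [3, 4]])
        with pytest.raises(InputError):
            fisher_exact_2x2([[0, 3], [0, 4]])
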