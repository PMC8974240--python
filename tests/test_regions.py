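import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelqtl.phenostats import TraitMatrix
from panelqtl.regions import (
    GeneAnnotation,
    QtlRegion,
    apply_stringency,
    assign_names,
    call_clusters,
    coloc,
    genes_near,
    merge_panels,
    pick_peak,
    pivot_allele_effects,
)
from tests.conftest import make_assoc


def brute_force_clusters(positions, extend):
    """O(n^2) transitive-closure oracle: two SNPs share a cluster iff they
    are connected by a chain of consecutive gaps <= extend."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = sorted((positions[i], positions[j]))
            between = sorted(p for p in positions if lo <= p <= hi)
            ok = all(b - a <= extend for a, b in zip(between, between[1:]))
            if ok:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(positions[i])
    return {frozenset(g) for g in groups.values()}


class TestCallClusters:
    def test_stated_rules_example(self):
        recs = [make_assoc(p) for p in (1_000_000, 1_150_000, 1_400_000)]
        cls = call_clusters(recs)
        assert len(cls) == 2
        assert cls[0].snp_span == (1_000_000, 1_150_000)
        assert cls[0].region == (950_000, 1_200_000)
        assert cls[1].snp_span == (1_400_000, 1_400_000)
        assert cls[1].region == (1_350_000, 1_450_000)

    def test_boundary_clamp(self):
        cls = call_clusters([make_assoc(30_000)])
        assert cls[0].region == (1, 80_000)

    def test_empty_when_nothing_significant(self):
        assert call_clusters([make_assoc(100, mlp=4.9)]) == []

    def test_threshold_strictly_greater(self):
        assert call_clusters([make_assoc(100, mlp=5.0)]) == []
        assert len(call_clusters([make_assoc(100, mlp=5.0001)])) == 1

    def test_oracle_equivalence_random_layouts(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = rng.integers(1, 60)
            positions = sorted(set(rng.integers(1, 5_000_000, size=n).tolist()))
            recs = [make_assoc(int(p)) for p in positions]
            cls = call_clusters(recs)
            got = {frozenset(r.pos for r in c.members) for c in cls}
            assert got == brute_force_clusters(positions, 200_000)

    def test_every_sig_snp_in_exactly_one_cluster(self):
        rng = np.random.default_rng(3)
        positions = sorted(set(rng.integers(1, 3_000_000, size=80).tolist()))
        mlps = rng.uniform(2, 9, size=len(positions))
        recs = [make_assoc(int(p), mlp=float(q)) for p, q in zip(positions, mlps)]
        cls = call_clusters(recs)
        member_pos = [r.pos for c in cls for r in c.members]
        sig_pos = [r.pos for r in recs if r.minus_log10_p > 5]
        assert sorted(member_pos) == sorted(sig_pos)

    def test_regions_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        positions = sorted(set(rng.integers(1, 10_000_000, size=100).tolist()))
        cls = call_clusters([make_assoc(int(p)) for p in positions])
        regions = sorted(c.region for c in cls)
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            assert e1 < s2  # guaranteed since 2*flank < extend


class TestStringency:
    def test_single_snp_flag(self):
        cls = apply_stringency(call_clusters([make_assoc(100_000)]))
        assert cls[0].single_snp and not cls[0].claimed

    def test_all_rare_flag(self):
        recs = [make_assoc(100_000, n_alt=3), make_assoc(150_000, n_alt=5)]
        cls = apply_stringency(call_clusters(recs))
        assert cls[0].all_rare

    def test_not_all_rare(self):
        recs = [make_assoc(100_000, n_alt=3), make_assoc(150_000, n_alt=8)]
        cls = apply_stringency(call_clusters(recs))
        assert not cls[0].all_rare
        assert cls[0].claimed


class TestMergePanels:
    def _clusters(self, spec):
        """spec: list of (panel, positions, effect)"""
        out = []
        for panel, positions, eff in spec:
            recs = [make_assoc(p, eff=eff, panel=panel) for p in positions]
            out.extend(apply_stringency(call_clusters(recs, panel=panel)))
        return out

    def test_gap_700kb_same_sign_merges(self):
        cls = self._clusters([
            ("A", [5_000_000, 5_200_000], 1.0),
            ("B", [5_900_000, 6_000_000], 1.0),
        ])
        qtls = merge_panels(cls)
        assert len(qtls) == 1
        assert (qtls[0].start, qtls[0].end) == (4_950_000, 6_050_000)
        assert qtls[0].panels == ["A", "B"]

    def test_gap_700kb_opposite_sign_splits(self):
        cls = self._clusters([
            ("A", [5_000_000, 5_200_000], 1.0),
            ("B", [5_900_000, 6_000_000], -1.0),
        ])
        assert len(merge_panels(cls)) == 2

    def test_gap_over_800kb_splits(self):
        cls = self._clusters([
            ("A", [5_000_000, 5_200_000], 1.0),
            ("B", [6_100_000, 6_200_000], 1.0),
        ])
        assert len(merge_panels(cls)) == 2

    def test_sign_flip_inside_string_two_overlapping_qtl(self):
        # no gap > 800 kb, internal sign change -> exactly 2 QTL whose
        # +-50 kb regions overlap
        recs = [make_assoc(9_000_000, eff=40.4), make_assoc(9_034_052, eff=40.4),
                make_assoc(9_060_000, eff=-32.86), make_assoc(9_100_000, eff=-32.86)]
        cls = apply_stringency(call_clusters(recs))
        qtls = merge_panels(cls)
        assert len(qtls) == 2
        (q1, q2) = sorted(qtls, key=lambda q: q.start)
        assert q1.effect_sign == 1 and q2.effect_sign == -1
        assert q1.end >= q2.start  # overlapping regions

    def test_order_invariance(self):
        spec = [("B", [5_900_000, 6_000_000], 1.0),
                ("A", [5_000_000, 5_200_000], 1.0),
                ("C", [7_500_000, 7_600_000], -1.0)]
        qtls1 = merge_panels(self._clusters(spec))
        qtls2 = merge_panels(self._clusters(list(reversed(spec))))
        key = lambda q: (q.chromosome, q.start, q.end)
        assert sorted((key(q) for q in qtls1)) == sorted(key(q) for q in qtls2)

    def test_mixed_traits_rejected(self):
        cls = self._clusters([("A", [1_000_000, 1_100_000], 1.0)])
        other = apply_stringency(call_clusters(
            [make_assoc(2_000_000, trait="As"), make_assoc(2_100_000, trait="As")]))
        with pytest.raises(ValueError):
            merge_panels(cls + other)

    def test_flagged_clusters_excluded_from_claims(self):
        cls = self._clusters([("A", [1_000_000], 1.0)])  # single SNP
        assert merge_panels(cls) == []
        assert len(merge_panels(cls, claimed_only=False)) == 1


class TestPickPeakAndNames:
    def test_max_mlp(self):
        recs = [make_assoc(100, mlp=5.2), make_assoc(200, mlp=7.8), make_assoc(300, mlp=6.1)]
        q = QtlRegion("q", "Si", "1", 1, 400, members=recs)
        assert pick_peak(q).pos == 200

    def test_tie_smallest_position(self):
        recs = [make_assoc(200, mlp=6.0), make_assoc(100, mlp=6.0)]
        q = QtlRegion("q", "Si", "1", 1, 400, members=recs)
        assert pick_peak(q).pos == 100

    def test_tie_panel_name(self):
        recs = [make_assoc(100, mlp=6.0, panel="B"), make_assoc(100, mlp=6.0, panel="A")]
        q = QtlRegion("q", "Si", "1", 1, 400, members=recs)
        assert pick_peak(q).panel == "A"

    def test_singleton(self):
        rec = make_assoc(100)
        q = QtlRegion("q", "Si", "1", 1, 400, members=[rec])
        assert pick_peak(q) is rec

    def test_empty_raises(self):
        q = QtlRegion("q", "Si", "1", 1, 400, members=[make_assoc(10)])
        q.members = []
        with pytest.raises(ValueError):
            pick_peak(q)

    def test_names_with_ordinals(self):
        qtls = [
            QtlRegion("", "Si", "9", 14_000_000, 15_000_000, members=[make_assoc(14_500_000)]),
            QtlRegion("", "Si", "9", 6_000_000, 8_000_000, members=[make_assoc(7_000_000)]),
            QtlRegion("", "Si", "12", 16_000_000, 17_000_000, members=[make_assoc(16_500_000)]),
        ]
        named = assign_names(qtls, "Si")
        assert [q.name for q in named] == ["qSi9-1", "qSi9-2", "qSi12"]
        assert named[0].start < named[1].start

    def test_names_empty(self):
        assert assign_names([], "Si") == []

    def test_size_mb_consistency(self):
        q = QtlRegion("q", "As", "1", 13_461_779, 13_617_444, members=[make_assoc(13_500_000)])
        assert q.size_mb == round((q.end - q.start) / 1e6, 3) == 0.156


class TestColoc:
    def _qtl(self, trait, start, end, chrom="1"):
        mid = (start + end) // 2
        return QtlRegion("", trait, chrom, start, end,
                         members=[make_assoc(start + 50_000, trait=trait, chrom=chrom),
                                  make_assoc(end - 50_000, trait=trait, chrom=chrom)])

    def test_overlapping_intervals_gap_zero(self):
        qa = self._qtl("StHD", 22_692_755, 24_617_484)
        qb = self._qtl("As", 21_981_983, 24_449_843)
        pairs = coloc([qa], [qb])
        assert len(pairs) == 1
        assert pairs[0].gap == 0

    def test_gap_400kb_colocated(self):
        qa = self._qtl("StHD", 1, 2_000_000)
        qb = self._qtl("As", 2_400_000, 3_000_000)
        pairs = coloc([qa], [qb])
        assert len(pairs) == 1
        assert pairs[0].basis == "end_gap"
        assert pairs[0].gap == 400_000

    def test_gap_600kb_not_colocated(self):
        qa = self._qtl("StHD", 1, 2_000_000)
        qb = self._qtl("As", 2_600_000, 3_000_000)
        assert coloc([qa], [qb]) == []

    def test_symmetric(self):
        qa = self._qtl("StHD", 1, 2_000_000)
        qb = self._qtl("As", 1_500_000, 3_000_000)
        ab = coloc([qa], [qb])
        ba = coloc([qb], [qa])
        assert len(ab) == len(ba) == 1
        assert ab[0].gap == ba[0].gap

    def test_different_chromosomes(self):
        qa = self._qtl("StHD", 1, 2_000_000, chrom="1")
        qb = self._qtl("As", 1, 2_000_000, chrom="2")
        assert coloc([qa], [qb]) == []

    def test_same_trait_rejected(self):
        qa = self._qtl("Si", 1, 2_000_000)
        qb = self._qtl("Si", 1, 2_000_000)
        with pytest.raises(ValueError):
            coloc([qa], [qb])


class TestPivot:
    def _setup(self, values_a, values_b):
        import numpy as np
        from panelqtl.simulate import GenotypeMatrix
        dosages = np.array([[0.0], [2.0]])
        snp_map = pd.DataFrame({"snp": ["s0"], "chrom": ["1"], "pos": [100],
                                "ref": ["A"], "alt": ["G"]})
        G = GenotypeMatrix(dosages, snp_map, ["a1", "a2"], ["X", "X"])
        tm = TraitMatrix(values=pd.DataFrame(
            {"T1": values_a, "T2": values_b}, index=["a1", "a2"]))
        peak = make_assoc(100, snp="s0")
        peak = type(peak)(**{**peak.__dict__, "common_allele": "A",
                             "alt_allele": "G", "n_common": 1, "n_alt": 1,
                             "pct_alt": 50.0})
        return peak, G, tm

    def test_two_accession_hand_arithmetic(self):
        peak, G, tm = self._setup([1.0, 3.0], [10.0, 6.0])
        table = pivot_allele_effects(peak, G, tm, ["T1", "T2"])
        assert table.loc["T1", "diff"] == pytest.approx(2.0)
        assert table.loc["T2", "diff"] == pytest.approx(-4.0)
        assert not table.loc["T2", "concordant"]

    def test_constant_trait_zero_diff(self):
        peak, G, tm = self._setup([5.0, 5.0], [1.0, 2.0])
        table = pivot_allele_effects(peak, G, tm, ["T1"])
        assert table.loc["T1", "diff"] == 0.0

    def test_empty_allele_class_not_estimable(self):
        import numpy as np
        from panelqtl.simulate import GenotypeMatrix
        dosages = np.array([[0.0], [0.0]])
        snp_map = pd.DataFrame({"snp": ["s0"], "chrom": ["1"], "pos": [100],
                                "ref": ["A"], "alt": ["G"]})
        G = GenotypeMatrix(dosages, snp_map, ["a1", "a2"], ["X", "X"])
        tm = TraitMatrix(values=pd.DataFrame({"T1": [1.0, 2.0]}, index=["a1", "a2"]))
        peak = make_assoc(100, snp="s0")
        table = pivot_allele_effects(peak, G, tm, ["T1"])
        assert not table.loc["T1", "estimable"]


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 5_000_000), st.floats(3.0, 9.0)),
                    min_size=1, max_size=40, unique_by=lambda t: t[0]))
    def test_sig_snps_partitioned(self, layout):
        recs = [make_assoc(p, mlp=q) for p, q in layout]
        clusters = call_clusters(recs)
        member_pos = sorted(r.pos for c in clusters for r in c.members)
        assert member_pos == sorted(r.pos for r in recs if r.minus_log10_p > 5.0)
        for c in clusters:
            lo, hi = c.region
            assert lo <= c.snp_span[0] and hi >= c.snp_span[1]

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 8_000_000),
                              st.sampled_from([-1.0, 1.0])),
                    min_size=2, max_size=30, unique_by=lambda t: t[0]),
           st.permutations(["A", "B", "C"]))
    def test_merge_panel_order_invariant(self, layout, panel_order):
        thirds = np.array_split(sorted(layout), 3)
        def build(order):
            clusters = []
            for panel, chunk in zip(order, thirds):
                recs = [make_assoc(int(p), eff=float(e), panel=panel)
                        for p, e in chunk]
                if recs:
                    clusters.extend(apply_stringency(call_clusters(recs, panel=panel)))
            return merge_panels(clusters, claimed_only=False)
        key = lambda q: (q.start, q.end, tuple(r.pos for r in q.members))
        assert sorted(map(key, build(["A", "B", "C"]))) == \
            sorted(map(key, build(panel_order)))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(1, 3_000_000), st.integers(1, 2_000_000),
           st.integers(1, 3_000_000), st.integers(1, 2_000_000))
    def test_coloc_symmetry(self, s1, l1, s2, l2):
        qa = QtlRegion("", "Si", "1", s1, s1 + l1,
                       members=[make_assoc(s1 + l1 // 2, trait="Si")])
        qb = QtlRegion("", "As", "1", s2, s2 + l2,
                       members=[make_assoc(s2 + l2 // 2, trait="As")])
        ab = coloc([qa], [qb])
        ba = coloc([qb], [qa])
        assert len(ab) == len(ba)
        if ab:
            assert ab[0].gap == ba[0].gap and ab[0].basis == ba[0].basis


class TestGenesNear:
    def _qtl(self):
        return QtlRegion("qSi1", "Si", "1", 2_000_000, 3_000_000,
                         members=[make_assoc(2_500_000)])

    def test_window_inclusion(self):
        genes = [
            GeneAnnotation("inside", "1", 2_400_000, 2_500_000),
            GeneAnnotation("near", "1", 3_900_000, 3_950_000),      # 0.9 Mb away
            GeneAnnotation("far", "1", 4_000_001, 4_100_000),       # > 1 Mb away
        ]
        table = genes_near([self._qtl()], genes)
        assert list(table["gene_id"]) == ["inside", "near"]
        assert table.iloc[0]["distance"] == 0

    def test_chromosome_mismatch_warns(self):
        genes = [GeneAnnotation("g", "7", 1, 10)]
        with pytest.warns(UserWarning, match="not present"):
            table = genes_near([self._qtl()], genes)
        assert table.empty

    def test_invalid_gene_interval(self):
        with pytest.raises(ValueError):
            GeneAnnotation("g", "1", 10, 5)
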