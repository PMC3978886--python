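"""Filter cascade, interval intersection and panel prioritisation."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import snptrace as st
from snptrace.panel_design import (
    AnnotationIncompleteError,
    FilterConfig,
    PanelShortfallError,
    af_balance_score,
    merge_regions,
    read_bed,
    total_length,
)
from snptrace.synthetic import generate_design_fixture

R = st.Region


def brute_force_intersection(region_sets, span=12_000):
    """Per-base membership oracle over small coordinates."""
    chroms = {r.chrom for rs in region_sets for r in rs}
    out = []
    for chrom in sorted(chroms):
        member = np.ones(span, dtype=bool)
        for rs in region_sets:
            cover = np.zeros(span, dtype=bool)
            for r in rs:
                if r.chrom == chrom:
                    cover[r.start:r.end] = True
            member &= cover
        # bool runs -> intervals
        edges = np.flatnonzero(np.diff(np.concatenate(([0], member.view(np.int8), [0]))))
        for s, e in edges.reshape(-1, 2):
            out.append(R(chrom, int(s), int(e)))
    return out


intervals = hst.lists(
    hst.tuples(hst.integers(0, 9_900), hst.integers(1, 100)).map(
        lambda t: R("1", t[0], t[0] + t[1])
    ),
    min_size=1,
    max_size=8,
)


class TestIntersectRegions:
    def test_nested_overlap(self):
        res = st.intersect_regions([[R("1", 0, 100)], [R("1", 50, 150)], [R("1", 60, 70)]])
        assert [(r.start, r.end) for r in res] == [(60, 70)]

    def test_empty_set_annihilates(self):
        assert st.intersect_regions([[R("1", 0, 100)], []]) == []

    def test_split_intersection_and_length(self):
        res = st.intersect_regions([[R("1", 0, 10), R("1", 20, 30)], [R("1", 5, 25)]])
        assert [(r.start, r.end) for r in res] == [(5, 10), (20, 25)]
        assert total_length(res) == 10

    def test_malformed_interval_reports_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t10\t20\n1\t30\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bed)

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("# header\n1\t0\t100\n2\t50\t80\n")
        regions = read_bed(bed)
        assert regions == [R("1", 0, 100), R("2", 50, 80)]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hst.lists(intervals, min_size=1, max_size=4))
    def test_matches_per_base_oracle(self, region_sets):
        got = st.intersect_regions(region_sets)
        assert got == brute_force_intersection(region_sets)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(intervals)
    def test_self_intersection_is_merge(self, regions):
        assert st.intersect_regions([regions, regions]) == merge_regions(regions)

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
    def test_matches_bedtools(self, tmp_path, rng):
        """Independent cross-check against BEDTools multiinter/merge."""
        sets = []
        for i in range(3):
            regions = [
                R("1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, 15), rng.integers(1, 400, 15))
            ]
            path = tmp_path / f"{i}.bed"
            path.write_text(
                "".join(f"{r.chrom}\t{r.start}\t{r.end}\n" for r in sorted(
                    regions, key=lambda r: r.start))
            )
            sets.append((path, regions))
        merged = []
        for path, _ in sets:
            out = subprocess.run(
                ["bedtools", "merge", "-i", str(path)],
                capture_output=True, text=True, check=True,
            ).stdout
            mpath = path.with_suffix(".merged.bed")
            mpath.write_text(out)
            merged.append(mpath)
        # successive pairwise bedtools intersect
        cur = merged[0]
        for nxt in merged[1:]:
            out = subprocess.run(
                ["bedtools", "intersect", "-a", str(cur), "-b", str(nxt)],
                capture_output=True, text=True, check=True,
            ).stdout
            cur = cur.with_suffix(".x.bed")
            cur.write_text(out)
        expected = read_bed(cur)
        got = st.intersect_regions([regions for _, regions in sets])
        assert got == expected


def _passing(seed=0):
    cands, _ = generate_design_fixture(seed, n_passing=1, n_single_fail=0, n_multi_fail=0)
    return cands[0]


class TestPrimaryFilters:
    def test_complementary_pair_fails_only_allele_criterion(self):
        cand = _passing()
        cand.alleles = ("A", "T")
        _, report = st.apply_primary_filters([cand])
        row = report.outcomes.iloc[0]
        assert not row["biallelic_non_complementary"]
        assert row.drop("biallelic_non_complementary").all()

    def test_high_gc_fails_only_gc_criterion(self):
        cand = _passing()
        cand.flank_gc = 0.60
        _, report = st.apply_primary_filters([cand])
        row = report.outcomes.iloc[0]
        assert not row["flank_gc_band"]
        assert row.drop("flank_gc_band").all()

    @pytest.mark.parametrize("seed", range(25))
    def test_fixture_plan_is_reproduced(self, seed):
        """The audit report equals the fixture's planted ground truth."""
        cands, expected = generate_design_fixture(seed)
        survivors, report = st.apply_primary_filters(cands)
        assert report.to_frame().equals(expected.to_frame())
        assert (report.outcomes.values == expected.outcomes.values).all()
        assert [c.rsid for c in survivors] == list(
            expected.outcomes.index[expected.outcomes.all(axis=1)]
        )

    def test_counts_are_balanced_and_survivors_pass_all(self):
        cands, _ = generate_design_fixture(3)
        survivors, report = st.apply_primary_filters(cands)
        for _, _, n_in, n_pass, n_fail in report.criteria:
            assert n_pass + n_fail == n_in == len(cands)
        assert len(survivors) == int(report.survivors_mask.sum())

    def test_idempotent(self):
        cands, _ = generate_design_fixture(5)
        once, _ = st.apply_primary_filters(cands)
        twice, _ = st.apply_primary_filters(once)
        assert [c.rsid for c in twice] == [c.rsid for c in once]

    def test_missing_annotation_names_variant_and_field(self):
        cand = _passing()
        cand.flank_gc = None
        with pytest.raises(AnnotationIncompleteError, match="flank_gc"):
            st.apply_primary_filters([cand])

    def test_class_summary_covers_four_classes(self):
        cands, _ = generate_design_fixture(1)
        _, report = st.apply_primary_filters(cands)
        assert set(report.class_summary()["class"]) == {
            "substitution", "technical", "allele_frequency", "functional_neutrality",
        }


class TestSecondaryFilters:
    @pytest.mark.parametrize("dist,ok", [(9, False), (10, True)])
    def test_exon_boundary_distance(self, dist, ok):
        cand = _passing()
        cand.exon_distance = dist
        survivors, _ = st.apply_secondary_filters([cand])
        assert bool(survivors) is ok

    @pytest.mark.parametrize("score,ok", [(101.0, False), (100.0, True)])
    def test_offtarget_similarity(self, score, ok):
        cand = _passing()
        cand.similarity_score = score
        survivors, _ = st.apply_secondary_filters([cand])
        assert bool(survivors) is ok

    def test_linked_pair_loses_one(self):
        a, b = _passing(1), _passing(2)
        a.chrom, b.chrom = "1", "2"
        a.ld_partners = {b.rsid: 0.9}
        b.ld_partners = {a.rsid: 0.9}
        survivors, _ = st.apply_secondary_filters([a, b])
        assert len(survivors) == 1

    def test_same_chromosome_proximity_fallback(self):
        a, b = _passing(1), _passing(2)
        a.chrom = b.chrom = "7"
        a.pos, b.pos = 1_000_000, 1_500_000  # <1 Mb apart, no LD annotation
        survivors, _ = st.apply_secondary_filters([a, b])
        assert len(survivors) == 1
        b.pos = 2_500_001
        survivors, _ = st.apply_secondary_filters([a, b])
        assert len(survivors) == 2


class TestPrioritize:
    def _cand(self, rsid, afs, chrom="1", pos=None):
        c = _passing(0)
        c.rsid = rsid
        c.pop_afs = {p: af for p, af in zip(("CEU", "CHB", "JPT", "YRI"), afs)}
        c.chrom = chrom
        c.pos = pos if pos is not None else sum(ord(ch) for ch in rsid) * 10**5 + 1
        return c

    def test_balanced_af_wins(self):
        best = self._cand("rsA", [0.5] * 4, chrom="1")
        worse = self._cand("rsB", [0.3] * 4, chrom="2")
        panel = st.prioritize([worse, best], k=1)
        assert [s.rsid for s in panel] == ["rsA"]

    def test_k_equals_n_returns_all_sorted(self):
        cands = [
            self._cand(f"rs{i}", [0.5 - 0.05 * i] * 4, chrom=str(i + 1))
            for i in range(4)
        ]
        panel = st.prioritize(list(reversed(cands)), k=4)
        assert [s.rsid for s in panel] == ["rs0", "rs1", "rs2", "rs3"]

    def test_score_invariant_under_allele_relabelling(self):
        c = self._cand("rsA", [0.3, 0.6, 0.45, 0.8])
        flipped = self._cand("rsA", [0.7, 0.4, 0.55, 0.2])
        pops = ("CEU", "CHB", "JPT", "YRI")
        assert af_balance_score(c, pops) == pytest.approx(af_balance_score(flipped, pops))

    def test_shortfall_reports_achievable_size(self):
        a = self._cand("rsA", [0.5] * 4, chrom="1", pos=100)
        b = self._cand("rsB", [0.5] * 4, chrom="1", pos=200)  # linked fallback
        with pytest.raises(PanelShortfallError, match="1"):
            st.prioritize([a, b], k=2)

    def test_greedy_matches_bruteforce_reference(self, rng):
        """Greedy pick equals an independent best-score-first enumeration."""
        cands = []
        for i in range(50):
            cands.append(
                self._cand(
                    f"rs{i:03d}",
                    rng.uniform(0.2, 0.8, size=4).round(3),
                    chrom=str(rng.integers(1, 23)),
                    pos=int(rng.integers(1, 10**8)),
                )
            )
        cfg = FilterConfig()
        pops = cfg.populations

        def reference(k, max_per_chrom):
            order = sorted(cands, key=lambda c: (af_balance_score(c, pops), c.rsid))
            picked, per_chrom = [], {}
            for c in order:
                if len(picked) == k:
                    break
                if per_chrom.get(c.chrom, 0) >= (max_per_chrom or 10**9):
                    continue
                if any(
                    c.chrom == p.chrom and abs(c.pos - p.pos) <= cfg.ld_fallback_distance
                    for p in picked
                ):
                    continue
                picked.append(c)
                per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
            return [c.rsid for c in picked]

        for k, cap in [(5, None), (10, 1), (20, 2)]:
            expected = reference(k, cap)
            if len(expected) < k:
                with pytest.raises(PanelShortfallError):
                    st.prioritize(cands, k, cap)
            else:
                assert [s.rsid for s in st.prioritize(cands, k, cap)] == expected
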