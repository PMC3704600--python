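"""Known-miRNA variant unification, role assignment and annotation classes."""

import numpy as np
import pandas as pd
import pytest

from soymir.design import library_ids, make_design
from soymir.reads import process_libraries
from soymir.simulate import SimConfig, Simulator
from soymir.variants import (
    UnifiedVariant,
    aggregate_window_counts,
    align_to_precursors,
    arm_of,
    assign_roles,
    compare_to_annotation,
    detect_multiple_mirnas,
    most_abundant_per_arm,
    run_known_analysis,
    unify_variants,
    variants_table,
)

L2 = ["L1", "L2"]


def frame(rows):
    """Arm frame from (sequence, offset, count_L1, count_L2) tuples."""
    return pd.DataFrame(
        [
            {"sequence": s, "precursor_id": "p1", "offset": o, "arm": "5p",
             "L1": c1, "L2": c2}
            for s, o, c1, c2 in rows
        ]
    )


class TestArmAssignment:
    def test_fully_left_is_5p(self):
        assert arm_of(10, 21, 60) == "5p"

    def test_fully_right_is_3p(self):
        assert arm_of(62, 21, 60) == "3p"

    def test_spanning_midpoint_is_loop(self):
        assert arm_of(50, 21, 60) == "loop-spanning"

    def test_alignment_reports_all_occurrences_and_arms(self):
        pre = {"p1": "ACGTAC" * 20}  # 120 nt, repeats -> multiple offsets
        tag = pre["p1"][10:31]
        al = align_to_precursors([tag], pre)
        offsets = sorted(a.offset for a in al)
        assert 10 in offsets and len(offsets) > 1
        assert all(pre["p1"][a.offset : a.offset + 21] == tag for a in al)

    def test_simulated_mature_aligns_on_planted_arm(self, small_sim):
        truth = small_sim["truth"]
        p = truth.known()[0]
        al = align_to_precursors([p.mature_seq], {p.precursor_id: p.sequence})
        assert any(a.offset == p.mature_offset and a.arm == "5p" for a in al)


class TestMostAbundant:
    def test_top_tag_by_count(self):
        f = frame([("A" * 21, 10, 50, 0), ("C" * 21, 12, 7, 0)])
        top = most_abundant_per_arm(f, None, "L1")
        assert top.iloc[0]["sequence"] == "A" * 21

    def test_tie_breaks_to_smaller_offset(self):
        f = frame([("C" * 21, 14, 5, 0), ("A" * 21, 12, 5, 0)])
        top = most_abundant_per_arm(f, None, "L1")
        assert top.iloc[0]["offset"] == 12

    def test_zero_read_arm_omitted(self):
        f = frame([("A" * 21, 10, 0, 3)])
        assert most_abundant_per_arm(f, None, "L1").empty


class TestUnify:
    def test_clear_majority_within_closeness_unifies(self):
        # T top in 2 of 3 libraries, the other winner within 2-fold -> T
        f = pd.DataFrame(
            [
                {"sequence": "A" * 21, "precursor_id": "p1", "offset": 10,
                 "arm": "5p", "L1": 100, "L2": 80, "L3": 60},
                {"sequence": "C" * 21, "precursor_id": "p1", "offset": 12,
                 "arm": "5p", "L1": 10, "L2": 20, "L3": 90},
            ]
        )
        v = unify_variants(f, ["L1", "L2", "L3"])
        assert v.unifiable and v.sequence == "A" * 21

    def test_large_count_swings_are_non_unifiable(self):
        f = frame([("A" * 21, 10, 500, 1), ("C" * 21, 14, 2, 400)])
        v = unify_variants(f, L2)
        assert not v.unifiable and v.sequence is None

    def test_majority_across_16_libraries(self):
        libs = library_ids()
        rows = []
        for i, lib in enumerate(libs):
            a = 100 if i < 14 else 40
            b = 60 if i < 14 else 80
            rows.append((lib, a, b))
        df = pd.DataFrame(
            [
                {"sequence": "A" * 21, "precursor_id": "p1", "offset": 10, "arm": "5p",
                 **{lib: a for lib, a, _ in rows}},
                {"sequence": "C" * 21, "precursor_id": "p1", "offset": 12, "arm": "5p",
                 **{lib: b for lib, _, b in rows}},
            ]
        )
        v = unify_variants(df, libs)
        assert v.unifiable and v.sequence == "A" * 21

    def test_genotype_partition_flags_variety_specific(self, genotype_of):
        libs = library_ids()
        tol = [l for l in libs if genotype_of[l] == "tolerant"]
        df = pd.DataFrame(
            [
                {"sequence": "A" * 21, "precursor_id": "p1", "offset": 10, "arm": "5p",
                 **{l: (500 if l in tol else 5) for l in libs}},
                {"sequence": "C" * 21, "precursor_id": "p1", "offset": 13, "arm": "5p",
                 **{l: (5 if l in tol else 500) for l in libs}},
            ]
        )
        v = unify_variants(df, libs, genotype_of=genotype_of)
        assert not v.unifiable and v.variety_specific

    def test_invalid_majority_frac(self):
        f = frame([("A" * 21, 10, 5, 5)])
        with pytest.raises(ValueError):
            unify_variants(f, L2, majority_frac=1.5)

    def test_agrees_with_exhaustive_rule_application(self, genotype_of):
        """Oracle equivalence: brute-force application of the stated rule over
        every candidate tag on randomized small fixtures."""
        rng = np.random.default_rng(42)
        libs = library_ids()
        for trial in range(25):
            n_tags = int(rng.integers(2, 5))
            seqs = [chr(65 + k) * 21 for k in range(n_tags)]
            counts = rng.integers(0, 40, size=(n_tags, 16))
            df = pd.DataFrame(
                [
                    {"sequence": seqs[k], "precursor_id": "p1", "offset": 10 + k,
                     "arm": "5p", **{l: int(counts[k, i]) for i, l in enumerate(libs)}}
                    for k in range(n_tags)
                ]
            )
            if counts.sum() == 0:
                continue
            v = unify_variants(df, libs)
            # --- independent re-derivation ---
            supporting = [i for i in range(16) if counts[:, i].sum() > 0]
            winners = {}
            for i in supporting:
                col = counts[:, i]
                cand = [k for k in range(n_tags) if col[k] == col[col > 0].max() and col[k] > 0]
                winners[i] = min(cand, key=lambda k: (10 + k, seqs[k]))
            tally = {}
            for w in winners.values():
                tally[w] = tally.get(w, 0) + 1
            top_n = max(tally.values())
            tied = [k for k, c in tally.items() if c == top_n]
            T = max(tied, key=lambda k: (counts[k].sum(), seqs[k]))
            ok = tally[T] > 0.5 * len(supporting)
            if ok:
                for i, w in winners.items():
                    if w != T and counts[w, i] > 0 and counts[T, i] / counts[w, i] < 0.5:
                        ok = False
                        break
            assert v.unifiable == ok, f"trial {trial}"
            if ok:
                assert v.sequence == seqs[T]


class TestWindowAggregation:
    def test_hand_summed_example(self):
        f = frame([("A" * 21, 10, 100, 0), ("C" * 21, 9, 8, 0), ("G" * 21, 12, 5, 0)])
        agg = aggregate_window_counts(10, f, L2, window=2)
        assert agg["L1"] == 113

    def test_window_zero_recovers_exact_count(self):
        f = frame([("A" * 21, 10, 100, 0), ("C" * 21, 9, 8, 0)])
        assert aggregate_window_counts(10, f, L2, window=0)["L1"] == 100

    def test_offset_outside_window_excluded(self):
        f = frame([("A" * 21, 10, 100, 0), ("C" * 21, 13, 7, 0)])
        assert aggregate_window_counts(10, f, L2, window=2)["L1"] == 100

    def test_monotone_in_window_size(self):
        f = frame([("A" * 21, 10, 50, 3), ("C" * 21, 8, 9, 1), ("G" * 21, 14, 2, 8)])
        prev = -1
        for w in range(0, 6):
            tot = sum(aggregate_window_counts(10, f, L2, window=w).values())
            assert tot >= prev
            prev = tot


class TestRoles:
    def test_higher_arm_total_is_mirna(self):
        v5 = UnifiedVariant("p1", "5p", "A" * 21, 10, window_counts={"L1": 10_000})
        v3 = UnifiedVariant("p1", "3p", "C" * 21, 60, window_counts={"L1": 600})
        assign_roles([v5, v3])
        assert v5.role == "miRNA" and v3.role == "miRNA*"

    def test_single_read_star_still_reported(self):
        v5 = UnifiedVariant("p1", "5p", "A" * 21, 10, window_counts={"L1": 9000})
        v3 = UnifiedVariant("p1", "3p", "C" * 21, 60, window_counts={"L1": 1})
        assign_roles([v5, v3])
        assert v3.role == "miRNA*"

    def test_arm_switch_flagged_when_winning_arm_differs(self):
        v5 = UnifiedVariant("p1", "5p", "A" * 21, 10, window_counts={"L1": 100, "L2": 5})
        v3 = UnifiedVariant("p1", "3p", "C" * 21, 60, window_counts={"L1": 4, "L2": 90})
        tops = pd.DataFrame(
            [
                {"library": "L1", "arm": "5p", "count": 100},
                {"library": "L2", "arm": "3p", "count": 90},
            ]
        )
        assign_roles([v5, v3], tops)
        assert v5.arm_switch and v3.arm_switch


class TestAnnotation:
    def make_variant(self, pre, seq, off):
        return UnifiedVariant("p1", arm_of(off, len(seq), len(pre) // 2), seq, off)

    def test_identical(self):
        pre = "A" * 30 + "TTTT" + "G" * 30
        v = self.make_variant(pre, pre[2:23], 2)
        assert compare_to_annotation(v, pre, pre[2:23]) == "identical"

    def test_shifted_same_arm(self):
        rng = np.random.default_rng(0)
        from soymir.seqs import random_seq

        pre = random_seq(rng, 90)
        v = self.make_variant(pre, pre[2:23], 2)
        assert compare_to_annotation(v, pre, pre[4:25]) == "shifted-same-arm"

    def test_opposite_arm(self):
        from soymir.seqs import random_seq

        pre = random_seq(np.random.default_rng(1), 90)
        v = self.make_variant(pre, pre[2:23], 2)
        assert compare_to_annotation(v, pre, pre[60:81]) == "opposite-arm"

    def test_annotation_absent_warns_novel_arm(self):
        from soymir.seqs import random_seq

        pre = random_seq(np.random.default_rng(2), 90)
        v = self.make_variant(pre, pre[2:23], 2)
        with pytest.warns(UserWarning):
            assert compare_to_annotation(v, pre, "T" * 21) == "novel-arm"

    def test_simulated_annotation_classes_near_half_identical(
        self, small_sim, small_processed, libs, genotype_of
    ):
        truth = small_sim["truth"]
        tags = small_processed["tags"]
        pre = {p.precursor_id: p.sequence for p in truth.known()}
        ann = {p.mature_id: p.annotated_seq for p in truth.known()}
        vs = run_known_analysis(tags, pre, libs, ann, genotype_of)
        classes = [v.annotation_class for v in vs if v.role == "miRNA" and v.annotation_class]
        frac = classes.count("identical") / len(classes)
        assert abs(frac - 0.5) <= 0.2
        assert "opposite-arm" in classes


@pytest.fixture(scope="module")
def fixture_sim(tmp_path_factory):
    """Small study with the special annotation-refinement fixtures enabled."""
    cfg = SimConfig(
        seed=19, depth=20_000, chrom_len=60_000,
        include_multi_duplex=True, include_arm_switch=True,
        include_non_unifiable=True, include_variety_specific=True,
    )
    sim = Simulator(cfg)
    truth = sim.build_truth()
    fq = sim.simulate_libraries(tmp_path_factory.mktemp("fixture_libs"))
    tags, hits, stats = process_libraries(fq, truth.genome, cfg.adapter3)
    pre = {p.precursor_id: p.sequence for p in truth.known()}
    geno = {d.library_id: d.genotype for d in make_design()}
    vs = run_known_analysis(tags, pre, library_ids(), None, geno)
    return {"truth": truth, "variants": vs, "table": variants_table(vs, library_ids())}


class TestRefinementFixtures:
    def test_truth_recovery_on_clean_precursors(self, fixture_sim):
        truth = fixture_sim["truth"]
        tbl = fixture_sim["table"]
        mir = tbl[tbl.role == "miRNA"].set_index("precursor_id")
        clean = [
            p for p in truth.known()
            if not (p.arm_switch or p.non_unifiable or p.variety_specific)
            and p.mean >= 1.0
        ]
        recovered = sum(
            1 for p in clean
            if p.precursor_id in mir.index
            and p.mature_seq in set(np.atleast_1d(mir.loc[p.precursor_id, "sequence"]))
        )
        assert recovered / len(clean) >= 0.9

    def test_multi_duplex_precursor_yields_secondary_variant(self, fixture_sim):
        truth = fixture_sim["truth"]
        pid = next(p.precursor_id for p in truth.known() if p.mature2_seq)
        tbl = fixture_sim["table"]
        names = set(tbl[tbl.precursor_id == pid]["name"])
        assert any(n.endswith("-2") for n in names)
        assert any(n.endswith("-1") for n in names)

    def test_arm_switch_precursor_flagged(self, fixture_sim):
        truth = fixture_sim["truth"]
        pid = next(p.precursor_id for p in truth.known() if p.arm_switch)
        sub = fixture_sim["table"]
        assert sub[sub.precursor_id == pid]["arm_switch"].any()

    def test_non_unifiable_precursor_reported_without_sole_sequence(self, fixture_sim):
        truth = fixture_sim["truth"]
        pid = next(p.precursor_id for p in truth.known() if p.non_unifiable)
        sub = fixture_sim["table"]
        row = sub[(sub.precursor_id == pid) & (sub.arm == "5p")]
        assert not row["unifiable"].iloc[0]

    def test_variety_specific_precursor_flagged(self, fixture_sim):
        truth = fixture_sim["truth"]
        pid = next(p.precursor_id for p in truth.known() if p.variety_specific)
        sub = fixture_sim["table"]
        row = sub[(sub.precursor_id == pid) & (sub.arm == "5p")]
        assert row["variety_specific"].iloc[0]


class TestSecondaryDetection:
    def test_overlapping_runner_up_not_emitted(self):
        f = frame([("A" * 21, 10, 5000, 0), ("C" * 21, 12, 400, 0)])
        primary = {"5p": UnifiedVariant("p1", "5p", "A" * 21, 10, role="miRNA")}
        out = detect_multiple_mirnas("N" * 120, primary, {"5p": f}, L2)
        assert out == []

    def test_secondary_without_star_not_emitted(self):
        f = frame([("A" * 21, 10, 5000, 0), ("C" * 21, 40, 400, 0)])
        primary = {"5p": UnifiedVariant("p1", "5p", "A" * 21, 10, role="miRNA")}
        out = detect_multiple_mirnas("N" * 150, primary, {"5p": f}, L2)
        assert out == []


class TestDeterminism:
    def test_result_independent_of_library_processing_order(
        self, small_sim, small_processed, libs, genotype_of
    ):
        truth = small_sim["truth"]
        tags = small_processed["tags"]
        pre = {p.precursor_id: p.sequence for p in truth.known()[:8]}
        a = variants_table(run_known_analysis(tags, pre, libs, None, genotype_of), libs)
        rev = list(reversed(libs))
        b = variants_table(run_known_analysis(tags, pre, rev, None, genotype_of), rev)
        a = a.sort_values("name").reset_index(drop=True)
        b = b.sort_values("name").reset_index(drop=True)
        pd.testing.assert_frame_equal(a[["name", "sequence", "role"]], b[["name", "sequence", "role"]])
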