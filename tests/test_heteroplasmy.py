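"""Candidate calling, AF classification, circular merge, filters, burden,
and gene-level enrichment."""

import numpy as np
import pandas as pd
import pytest

from mtbrain.heteroplasmy import (
    ALLELE_COLUMNS,
    MT_LENGTH,
    MtVariant,
    annotate_and_enrich,
    call_candidates,
    classify_heteroplasmy,
    compute_burden,
    default_annotation,
    filter_numt_contamination,
    in_control_region,
    shift_merge,
    shifted_to_original,
)
from mtbrain.synthetic import (
    GenerativeParams,
    generate_cohort,
    generate_pileup,
    make_shifted_pileup,
)


def _pileup_row(pos, ref, **alleles):
    row = {"pos": pos, "ref": ref, **{a: 0 for a in ALLELE_COLUMNS}}
    row.update(alleles)
    return row


def _variant(pos=100, ref="A", alt="G", alt_count=50, depth=1000, flags=()):
    return MtVariant(pos, ref, alt, alt_count, depth, set(flags))


class TestCandidates:
    def test_af_arithmetic(self):
        df = pd.DataFrame([_pileup_row(10, "A", A=95, G=5)])
        (v,) = call_candidates(df)
        assert (v.position, v.alt, v.allele_fraction) == (10, "G", 0.05)

    def test_no_alt_reads_no_candidate(self):
        df = pd.DataFrame([_pileup_row(10, "A", A=100)])
        assert call_candidates(df) == []

    def test_depth_and_alt_floors(self):
        df = pd.DataFrame(
            [_pileup_row(10, "A", A=40, G=5), _pileup_row(11, "C", C=98, T=2)]
        )
        assert call_candidates(df, min_depth=50, min_alt_reads=3) == []

    def test_matches_brute_force_oracle(self, random_pileup):
        """Vectorized caller must equal exhaustive per-position enumeration."""
        got = {
            (v.position, v.alt, v.alt_count, v.depth)
            for v in call_candidates(random_pileup, min_depth=60, min_alt_reads=5)
        }
        expected = set()
        for _, row in random_pileup.iterrows():
            depth = sum(int(row[a]) for a in ALLELE_COLUMNS)
            if depth < 60:
                continue
            for a in ALLELE_COLUMNS:
                if a != row["ref"] and int(row[a]) >= 5:
                    expected.add((int(row["pos"]), a, int(row[a]), depth))
        assert got == expected


class TestClassification:
    @pytest.mark.parametrize(
        "alt_count,depth,expected_flags",
        [
            (5, 100, set()),            # AF 0.05: heteroplasmic
            (95, 100, {"homoplasmic_like"}),  # AF 0.95
            (3, 100, set()),            # AF 0.03 exactly: closed interval
            (90, 100, set()),           # AF 0.90 exactly
            (2, 100, {"low_maf"}),
        ],
    )
    def test_af_band(self, alt_count, depth, expected_flags):
        v = classify_heteroplasmy(_variant(alt_count=alt_count, depth=depth))
        assert v.filter_flags == expected_flags

    def test_monotonicity_in_af_band(self, rng):
        """Widening the AF band never decreases the heteroplasmy burden."""
        variants = [
            _variant(pos=int(p), alt_count=int(a), depth=200)
            for p, a in zip(
                rng.choice(MT_LENGTH, 60, replace=False) + 1,
                rng.integers(1, 200, 60),
            )
        ]

        def burden(lo, hi):
            calls = [
                classify_heteroplasmy(_variant(v.position, v.ref, v.alt, v.alt_count, v.depth), lo, hi)
                for v in variants
            ]
            return compute_burden(calls)

        for lo in (0.01, 0.03, 0.10):
            assert burden(lo, 0.90) >= burden(lo + 0.02, 0.90)
        for hi in (0.5, 0.9):
            assert burden(0.03, hi + 0.05) >= burden(0.03, hi)


class TestShiftMerge:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=200)
    @given(
        pos=st.integers(min_value=1, max_value=MT_LENGTH),
        shift=st.integers(min_value=0, max_value=MT_LENGTH - 1),
    )
    def test_rotation_round_trip(self, pos, shift):
        """Rotating then un-rotating any circular coordinate is the identity."""
        s = (pos - shift - 1) % MT_LENGTH + 1
        assert shifted_to_original(s, shift) == pos

    def test_coordinate_mapping(self):
        assert shifted_to_original(1, shift=8000) == 8001
        assert shifted_to_original(MT_LENGTH - 8000 + 1, shift=8000) == 1
        assert shifted_to_original(MT_LENGTH, shift=8000) == 8000
        with pytest.raises(ValueError):
            shifted_to_original(0)

    def test_duplicate_resolved_by_window_membership(self):
        # position 8000 is outside the control region -> standard call wins once
        std = [_variant(pos=8000)]
        shifted = [_variant(pos=MT_LENGTH, ref="A", alt="G")]  # maps to 8000
        merged = shift_merge(std, shifted)
        assert len(merged) == 1 and merged[0].position == 8000

    def test_junction_window_comes_from_shifted_set(self):
        std = [_variant(pos=100), _variant(pos=5000)]
        # shifted coordinate for original 100 under shift 8000:
        s = (100 - 8000 - 1) % MT_LENGTH + 1
        shifted = [_variant(pos=s)]
        merged = shift_merge(std, shifted)
        assert [v.position for v in merged] == [100, 5000]
        # the control-region record is the shifted one (same coords here)
        assert in_control_region(merged[0].position)

    def test_circular_origin_invariance(self):
        """Calling on any rotation of the pileup yields the same original-coordinate set."""
        params = GenerativeParams.for_region("DLPFC", n=2, coverage_noise=0.0)
        g = np.random.default_rng(42)
        cohort = generate_cohort(params, g)
        pileups, _ = generate_pileup(cohort, params, g)
        for sid, pile in pileups.items():
            base = {
                (v.position, v.alt, v.alt_count)
                for v in call_candidates(pile, min_depth=50, min_alt_reads=3)
            }
            for offset in (1, 577, 8000, 16000):
                rot = make_shifted_pileup(pile, offset)
                rot_calls = call_candidates(rot, min_depth=50, min_alt_reads=3)
                mapped = {
                    (shifted_to_original(v.position, offset), v.alt, v.alt_count)
                    for v in rot_calls
                }
                assert mapped == base, f"{sid} offset {offset}"


class TestFilters:
    def test_numt_rule_arithmetic(self):
        # default multiplier k=2: 40 alt reads <= 2 * cov_nuc(30) = 60 -> flagged
        v = filter_numt_contamination([_variant(alt_count=40, depth=20000)], 30, 20000)[0]
        assert "numt_suspect" in v.filter_flags
        v2 = filter_numt_contamination([_variant(alt_count=61, depth=20000)], 30, 20000)[0]
        assert "numt_suspect" not in v2.filter_flags

    def test_zero_contamination_never_flags(self):
        vs = [_variant(alt_count=c) for c in (100, 200, 900)]
        out = filter_numt_contamination(vs, 1.0, 1000.0, contamination_level=0.0)
        assert all("contamination_suspect" not in v.filter_flags for v in out)

    def test_contamination_threshold(self):
        v = filter_numt_contamination(
            [_variant(alt_count=15, depth=1000)], 1.0, 1000.0, contamination_level=0.02
        )[0]
        assert "contamination_suspect" in v.filter_flags

    def test_flag_order_invariance(self):
        """Burden is the same whichever filter predicate is applied first."""
        vs1 = [classify_heteroplasmy(_variant(alt_count=c, depth=1000)) for c in (25, 60, 950)]
        vs1 = filter_numt_contamination(vs1, 20.0, 1000.0, 0.03)
        vs2 = filter_numt_contamination(
            [_variant(alt_count=c, depth=1000) for c in (25, 60, 950)], 20.0, 1000.0, 0.03
        )
        vs2 = [classify_heteroplasmy(v) for v in vs2]
        assert compute_burden(vs1) == compute_burden(vs2)
        for a, b in zip(vs1, vs2):
            assert a.filter_flags == b.filter_flags

    def test_planted_artifacts_removed_truths_retained(self):
        """On generator pileups: NUMTs/homoplasmies are filtered, clear heteroplasmies kept."""
        params = GenerativeParams.for_region("DLPFC", n=4, contamination=0.02)
        g = np.random.default_rng(5)
        cohort = generate_cohort(params, g)
        pileups, truth = generate_pileup(cohort, params, g)
        for sid, pile in pileups.items():
            cov_mt = float(
                cohort.loc[cohort.sample_id == sid, "mtdnacn_true"].iloc[0] * 30 / 2
            )
            calls = [classify_heteroplasmy(v) for v in call_candidates(pile)]
            calls = filter_numt_contamination(calls, 30.0, cov_mt, 0.02)
            kept = {(v.position, v.alt) for v in calls if v.classification == "heteroplasmic"}
            t = truth[truth.sample_id == sid]
            for _, r in t.iterrows():
                key = (r["pos"], r["alt"])
                if r["kind"] == "heteroplasmy" and r["af_true"] >= 0.05:
                    assert key in kept, f"true heteroplasmy lost: {sid} {key}"
                elif r["kind"] in ("numt", "homoplasmy", "contamination"):
                    assert key not in kept, f"artifact survived: {sid} {r['kind']} {key}"


class TestBurdenAndEnrichment:
    def test_burden_counts_only_heteroplasmic(self):
        assert compute_burden([]) == 0
        calls = [
            _variant(pos=1), _variant(pos=2), _variant(pos=3),
            _variant(pos=4, flags=("low_maf",)), _variant(pos=5, flags=("numt_suspect",)),
        ]
        assert compute_burden(calls) == 3

    def test_annotation_covers_genome(self):
        ann = default_annotation()
        lengths = (ann["end"] - ann["start"] + 1).sum()
        assert lengths == MT_LENGTH

    def test_all_variants_in_control_region_no_gene_enrichment(self):
        calls = [_variant(pos=p) for p in (16100, 16200, 300, 400)]
        res = annotate_and_enrich(calls, default_annotation())
        genes = res[res.feature.str.startswith("MT-")]
        assert (genes["count"] == 0).all()
        assert (genes["p_bonferroni"] == 1.0).all()

    def test_single_gene_concentration_hits_binomial_tail(self):
        from scipy.stats import binom

        ann = default_annotation()
        nd1 = ann[ann.feature == "MT-ND1"]
        pos = int(nd1.iloc[0]["start"]) + 1
        n = 6
        calls = [_variant(pos=pos + i) for i in range(n)]
        res = annotate_and_enrich(calls, ann)
        L_g = int((nd1["end"] - nd1["start"] + 1).sum())
        expected = binom.sf(n - 1, n, L_g / MT_LENGTH)
        row = res[res.feature == "MT-ND1"].iloc[0]
        assert row["count"] == n
        assert row["p_enrichment"] == pytest.approx(expected, rel=1e-12)

    def test_null_calibration_is_conservative(self, rng):
        """Uniform positions: per-gene p-values stochastically dominate uniform.

        Binomial tail p-values are discrete, hence conservative; the
        calibration check is P(p <= alpha) <= alpha + Monte-Carlo slack.
        """
        ann = default_annotation()
        pvals = []
        for _ in range(200):
            pos = rng.integers(1, MT_LENGTH + 1, 25)
            calls = [_variant(pos=int(p)) for p in pos]
            res = annotate_and_enrich(calls, ann)
            pvals.extend(res["p_enrichment"].tolist())
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.10, 0.25):
            frac = (pvals <= alpha).mean()
            mc = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert frac <= alpha + mc, f"anti-conservative at alpha={alpha}: {frac:.3f}"

    def test_overlapping_annotation_rejected(self):
        bad = pd.DataFrame(
            [
                {"feature": "a", "start": 1, "end": 10000},
                {"feature": "b", "start": 9999, "end": MT_LENGTH},
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            annotate_and_enrich([], bad)
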