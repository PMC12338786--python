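"""Conservation, exposure, secondary structure and GO coherence gates."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimtriage.features import (
    FeatureSet,
    build_reference_profile,
    classify_exposure,
    default_sasa_thresholds,
    feature_gate,
    go_ancestor_closure,
    go_cc_coherent,
    jsd_column_score,
    motif_conservation,
    ss_profile,
)
from slimtriage.fixtures import (
    GO_CANDIDATE_TERM,
    GO_REFERENCE_TERM,
    GO_UNRELATED_TERM,
)
from slimtriage.motifs import AMINO_ACIDS, MotifMatch

UNIFORM = {aa: 0.05 for aa in AMINO_ACIDS}


def jsd_oracle(p, q):
    """Direct Jensen-Shannon divergence, log base 2, mixing weight 1/2."""
    keys = set(p) | set(q)
    total = 0.0
    for k in keys:
        pv, qv = p.get(k, 0.0), q.get(k, 0.0)
        m = 0.5 * (pv + qv)
        if pv > 0:
            total += 0.5 * pv * math.log2(pv / m)
        if qv > 0:
            total += 0.5 * qv * math.log2(qv / m)
    return total


class TestJSD:
    def test_background_column_scores_zero(self):
        assert jsd_column_score(UNIFORM, UNIFORM) == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_column_against_uniform(self):
        score = jsd_column_score(["W"] * 10, UNIFORM)
        assert score == pytest.approx(jsd_oracle({"W": 1.0}, UNIFORM), abs=1e-9)
        assert score == pytest.approx(0.855, abs=0.005)

    def test_gap_fraction_scales_linearly(self):
        full = jsd_column_score(["W"] * 10, UNIFORM)
        half = jsd_column_score(["W"] * 5 + ["-"] * 5, UNIFORM)
        assert half == pytest.approx(full / 2)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            jsd_column_score([], UNIFORM)

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 5), min_size=20, max_size=20).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_symmetric_bounded_zero_iff_equal(self, counts):
        total = sum(counts)
        p = {aa: c / total for aa, c in zip(AMINO_ACIDS, counts) if c}
        forward = jsd_column_score(p, UNIFORM)
        # symmetry of the underlying divergence
        backward = jsd_oracle(UNIFORM, p)
        assert forward == pytest.approx(backward, abs=1e-9)
        assert 0.0 <= forward <= 1.0
        if p == UNIFORM:
            assert forward == pytest.approx(0.0, abs=1e-12)


class TestConservation:
    MSA = [
        ("q", "MW-NPAY"),
        ("h1", "MWKNPAY"),
        ("h2", "-WRNPAY"),
    ]

    def test_motif_columns_mapped_through_gapped_query(self):
        # query residues 3..6 = NPAY sit in alignment columns 4..7
        prof = motif_conservation(self.MSA, "q", 3, 6)
        assert len(prof.column_scores) == 4
        assert prof.n_sequences == 3
        conserved = jsd_column_score(["N"] * 3, None)
        assert prof.motif_mean == pytest.approx(conserved)

    def test_span_past_query_end_rejected(self):
        with pytest.raises(ValueError):
            motif_conservation(self.MSA, "q", 5, 9)

    def test_single_sequence_flagged(self):
        prof = motif_conservation([("q", "MNPAY")], "q", 2, 5)
        assert prof.n_sequences == 1
        assert all(0 <= s <= 1 for s in prof.column_scores)


class TestExposure:
    def test_zero_sasa_buried_for_every_type(self):
        prof = classify_exposure([0.0] * 20, AMINO_ACIDS)
        assert set(prof.classes) == {"buried"}

    def test_huge_sasa_exposed_for_every_type(self):
        hi = max(default_sasa_thresholds().values()) + 1
        prof = classify_exposure([hi] * 20, AMINO_ACIDS)
        assert set(prof.classes) == {"exposed"}

    def test_half_exposed_fraction(self):
        thr = default_sasa_thresholds()
        sasa = [thr["A"] + 1, 0.0, thr["W"] + 1, 0.0]
        prof = classify_exposure(sasa, "AAWW")
        assert prof.exposed_fraction == pytest.approx(0.5)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            classify_exposure([1.0], "Z")


class TestSSProfile:
    MATCH = MotifMatch("p", "cls", 1, 4, "NPAY")

    @pytest.mark.parametrize(
        "ss,expected",
        [("CCCC", (0, 0, 1)), ("HHHH", (1, 0, 0)), ("HHCC", (0.5, 0, 0.5))],
    )
    def test_fractions(self, ss, expected):
        assert ss_profile(ss, self.MATCH) == pytest.approx(expected)

    def test_fractions_sum_to_one(self):
        assert sum(ss_profile("HECC", self.MATCH)) == pytest.approx(1.0)

    def test_short_string_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ss_profile("HH", self.MATCH)


def closure_oracle(terms, graph):
    """Brute-force ancestor walk (excluding the root), independent of networkx
    reachability helpers."""
    out = set()
    frontier = [t for t in terms if t in graph]
    while frontier:
        t = frontier.pop()
        if t not in out:
            out.add(t)
            frontier.extend(graph.successors(t))
    return {t for t in out if graph.out_degree(t) > 0}


class TestGO:
    def test_identical_terms_coherent(self, toy_ontology):
        assert go_cc_coherent([GO_REFERENCE_TERM], [GO_REFERENCE_TERM], toy_ontology)

    def test_disjoint_closures_incoherent(self, toy_ontology):
        assert not go_cc_coherent(
            [GO_UNRELATED_TERM], [GO_REFERENCE_TERM], toy_ontology
        )

    def test_descendant_of_reference_coherent(self, toy_ontology):
        assert go_cc_coherent([GO_CANDIDATE_TERM], [GO_REFERENCE_TERM], toy_ontology)

    def test_closure_matches_brute_force_walk(self, toy_ontology):
        for terms in ([GO_CANDIDATE_TERM], [GO_UNRELATED_TERM], [GO_REFERENCE_TERM]):
            assert go_ancestor_closure(terms, toy_ontology) == closure_oracle(
                terms, toy_ontology
            )

    def test_unknown_term_skipped_with_warning(self, toy_ontology):
        with pytest.warns(UserWarning, match="unknown GO term"):
            assert go_ancestor_closure(["GO:9999999"], toy_ontology) == frozenset()

    def test_monotone_under_reference_growth(self, toy_ontology):
        cand = [GO_CANDIDATE_TERM]
        ref = [GO_REFERENCE_TERM]
        assert go_cc_coherent(cand, ref, toy_ontology)
        assert go_cc_coherent(cand, ref + [GO_UNRELATED_TERM], toy_ontology)


def feature_set(cons_mean=0.8, ss=(0, 0, 1.0), exposed=1.0, terms=(GO_REFERENCE_TERM,)):
    from slimtriage.features import ConservationProfile, ExposureProfile

    n = 4
    n_exposed = round(exposed * n)
    return FeatureSet(
        conservation=ConservationProfile([cons_mean] * n, cons_mean, 8, [0.0] * n),
        ss_fractions=ss,
        exposure=ExposureProfile(
            [100.0] * n,
            [0.5] * n,
            ["exposed"] * n_exposed + ["buried"] * (n - n_exposed),
        ),
        go_terms=frozenset(terms),
    )


class TestFeatureGate:
    def test_self_consistency(self, toy_ontology):
        fs = feature_set()
        profile = build_reference_profile([fs])
        assert feature_gate(fs, profile, toy_ontology).passed

    def test_low_conservation_reason(self, toy_ontology):
        profile = build_reference_profile([feature_set(cons_mean=0.8)])
        res = feature_gate(feature_set(cons_mean=0.5), profile, toy_ontology)
        assert not res.passed and not res.conservation_pass
        assert any("conservation" in r for r in res.reasons)

    def test_multiple_failures_all_reported(self, toy_ontology):
        profile = build_reference_profile([feature_set()])
        bad = feature_set(cons_mean=0.1, ss=(1.0, 0, 0), exposed=0.0,
                          terms=(GO_UNRELATED_TERM,))
        res = feature_gate(bad, profile, toy_ontology)
        assert not res.passed
        assert len(res.reasons) == 4

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_reference_profile([])
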