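import numpy as np
import pytest

from earlyfold.errors import (
    DegenerateSpreadError,
    UnboundedDivergenceError,
    ZeroHydrophobicityError,
)
from earlyfold.fod import (
    HydrophobicityScale,
    compute_rd,
    effective_positions,
    fod_profile,
    hydrophobicity_profile_export,
    kl_divergence,
    observed_distribution,
    status_runs,
    theoretical_distribution,
    trim_classify,
    uniform_reference,
)
from earlyfold.synthetic_data import make_fod_case, make_trim_case


@pytest.fixture(scope="module")
def rank_scale():
    return HydrophobicityScale.rank_scale()


class TestScale:
    def test_packaged_default_is_normalized(self):
        scale = HydrophobicityScale.kyte_doolittle_normalized()
        vals = np.array(list(scale.values.values()))
        assert vals.min() == 0.0 and vals.max() == 1.0 and len(vals) == 20

    def test_missing_letter_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            HydrophobicityScale({"A": 1.0})

    def test_negative_rejected(self):
        vals = {aa: 0.5 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        vals["W"] = -0.1
        with pytest.raises(ValueError, match="invalid"):
            HydrophobicityScale(vals)

    def test_tsv_round_trip(self, rank_scale, tmp_path):
        path = tmp_path / "scale.tsv"
        rank_scale.to_tsv(path)
        back = HydrophobicityScale.from_tsv(path)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert back[aa] == pytest.approx(rank_scale[aa], abs=1e-6)


class TestEffectivePositions:
    def test_ca_mode_returns_ca_coords(self):
        case = make_fod_case(True, n=25, seed=0)
        pts, kept = effective_positions(case.domain)
        assert np.allclose(pts, case.domain.ca_coords())
        assert kept == list(range(1, 26))

    def test_incomplete_residue_skipped_with_map(self):
        case = make_fod_case(True, n=25, seed=1)
        case.domain.residues[10].complete = False
        with pytest.warns(UserWarning, match="skipped"):
            pts, kept = effective_positions(case.domain)
        assert len(pts) == 24 and 11 not in kept

    def test_unsupported_mode(self):
        case = make_fod_case(True, n=25, seed=2)
        with pytest.raises(ValueError, match="mode"):
            effective_positions(case.domain, mode="side-chain-centroid")


class TestTheoretical:
    def test_symmetric_pair(self):
        t = theoretical_distribution([[-3.0, 0, 0], [3.0, 0, 0]])
        assert t == pytest.approx([0.5, 0.5])

    def test_normalization(self, rng):
        t = theoretical_distribution(rng.normal(size=(40, 3)))
        assert t.sum() == pytest.approx(1.0, abs=1e-12)

    def test_collinear_hand_case(self):
        d = 6.0
        t = theoretical_distribution([[-d, 0, 0], [0, 0, 0], [d, 0, 0]])
        # 1-D Gaussian with sigma = d/3: ends at exp(-4.5) relative to middle
        e = np.exp(-4.5)
        expect = np.array([e, 1.0, e]) / (1 + 2 * e)
        assert t == pytest.approx(expect, abs=1e-12)
        assert t[1] == t.max()

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateSpreadError):
            theoretical_distribution(np.zeros((4, 3)))

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 5
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([10.0, -4.0, 2.0])
        assert theoretical_distribution(moved) == pytest.approx(
            theoretical_distribution(pts), abs=1e-9
        )


class TestObserved:
    def test_distant_pair_reduces_to_self_terms(self, rank_scale):
        pts = [[0.0, 0, 0], [30.0, 0, 0]]
        o = observed_distribution(pts, ["I", "Y"], rank_scale)
        h1, h2 = rank_scale["I"], rank_scale["Y"]
        assert o == pytest.approx([h1 / (h1 + h2), h2 / (h1 + h2)], abs=1e-12)

    def test_coincident_pair_hand_evaluation(self, rank_scale):
        # each residue collects its self term 2*Hr_i plus the shared
        # pair term (h1 + h2) at g(0) = 1
        h1, h2 = rank_scale["I"], rank_scale["Y"]
        o = observed_distribution([[0.0, 0, 0], [0.0, 0, 0]], ["I", "Y"], rank_scale)
        expect = np.array([3 * h1 + h2, 3 * h2 + h1])
        assert o == pytest.approx(expect / expect.sum(), abs=1e-12)

    def test_equal_hydrophobicity_coincident_pair_is_symmetric(self, rank_scale):
        o = observed_distribution([[0.0, 0, 0], [0.0, 0, 0]], ["I", "I"], rank_scale)
        assert o == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_normalization_and_nonnegativity(self, rank_scale, rng):
        pts = rng.normal(size=(30, 3)) * 6
        aas = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30)
        o = observed_distribution(pts, aas, rank_scale)
        assert o.sum() == pytest.approx(1.0, abs=1e-12) and (o >= 0).all()

    def test_zero_scale_rejected(self):
        flat = HydrophobicityScale({aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"})
        with pytest.raises(ZeroHydrophobicityError):
            observed_distribution([[0, 0, 0], [5, 0, 0]], ["A", "C"], flat)

    def test_rigid_motion_invariance(self, rank_scale, rng):
        pts = rng.normal(size=(25, 3)) * 5
        aas = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 25)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T - 7.0
        assert observed_distribution(moved, aas, rank_scale) == pytest.approx(
            observed_distribution(pts, aas, rank_scale), abs=1e-9
        )


class TestKL:
    def test_identity_is_zero(self, rng):
        p = rng.dirichlet(np.ones(10))
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_one_bit_closed_form(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_term_by_term_oracle(self):
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.6, 0.3, 0.1])
        expect = sum(pi * np.log2(pi / qi) for pi, qi in zip(p, q))
        assert kl_divergence(p, q) == pytest.approx(expect, abs=1e-12)

    def test_unbounded(self):
        with pytest.raises(UnboundedDivergenceError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])


class TestRD:
    def test_o_equals_t_gives_zero(self):
        t = np.array([0.5, 0.3, 0.2])
        r = uniform_reference(3)
        assert compute_rd(t, t, r) == 0.0

    def test_o_equals_r_gives_one(self):
        t = np.array([0.5, 0.3, 0.2])
        r = uniform_reference(3)
        assert compute_rd(r, t, r) == 1.0

    def test_small_vector_oracle(self):
        o = np.array([0.4, 0.35, 0.25])
        t = np.array([0.6, 0.3, 0.1])
        r = uniform_reference(3)
        expect = kl_divergence(o, t) / (kl_divergence(o, t) + kl_divergence(o, r))
        assert compute_rd(o, t, r) == pytest.approx(expect, abs=1e-12)

    def test_log_base_invariance(self, rng):
        o = rng.dirichlet(np.ones(20))
        t = rng.dirichlet(np.ones(20))
        r = uniform_reference(20)
        assert compute_rd(o, t, r, base=2.0) == pytest.approx(
            compute_rd(o, t, r, base=np.e), abs=1e-12
        )

    def test_degenerate_all_equal_warns_zero(self):
        r = uniform_reference(4)
        with pytest.warns(UserWarning, match="RD defined as 0"):
            assert compute_rd(r, r, r) == 0.0

    def test_rd_always_in_unit_interval(self, rng):
        for _ in range(20):
            o = rng.dirichlet(np.ones(15))
            t = rng.dirichlet(np.ones(15))
            rd = compute_rd(o, t, uniform_reference(15))
            assert 0.0 <= rd <= 1.0


class TestTrimClassify:
    def test_already_compliant_stops_immediately(self, rank_scale):
        case = make_fod_case(True, n=40, seed=0)
        status = trim_classify(case.domain, case.scale)
        assert status.removal_order == []
        assert set(status.labels) == {"C"}
        assert status.origin_compliant

    def test_planted_inversions_are_removed_first(self):
        hits = total = engaged = 0
        for seed in range(8):
            case = make_trim_case(n=60, k=14, seed=seed)
            status = trim_classify(case.domain, case.scale)
            if status.removal_order and not status.never_compliant:
                engaged += 1
                hits += sum(
                    1 for i in status.removal_order if i in case.planted_noncore
                )
                total += len(status.removal_order)
        assert engaged >= 3
        assert hits / total >= 0.7

    def test_trimming_soundness_and_termination(self):
        for seed in range(5):
            case = make_fod_case(False, n=30, seed=seed)
            status = trim_classify(case.domain, case.scale)
            assert len(status.removal_order) <= 30 - 5 or status.never_compliant
            if not status.never_compliant:
                assert status.final_rd < 0.5
            else:
                assert set(l for l in status.labels if l) == {"N"}

    def test_noncompliant_labels_match_removals(self):
        case = make_trim_case(n=60, k=16, seed=3)
        status = trim_classify(case.domain, case.scale)
        removed = {i for i, l in enumerate(status.labels, start=1) if l == "N"}
        assert removed == set(status.removal_order)


class TestStatusRuns:
    def test_single_qualifying_run(self):
        assert status_runs("CNNNNC") == [("N", 2, 5)]

    def test_all_compliant(self):
        assert status_runs("C" * 10) == [("C", 1, 10)]

    def test_alternating_yields_nothing(self):
        assert status_runs("CN" * 5) == []

    def test_undefined_breaks_runs(self):
        assert status_runs("CCC-CCC") == []
        assert status_runs("CCCC-NNNN") == [("C", 1, 4), ("N", 6, 9)]

    def test_min_len_parameter(self):
        assert status_runs("CCC", min_len=3) == [("C", 1, 3)]


class TestProfileExport:
    def test_four_values_match_scale(self, rank_scale):
        vals = hydrophobicity_profile_export("ACDE", rank_scale)
        assert vals == pytest.approx([rank_scale[a] for a in "ACDE"])

    def test_unknown_letter_rejected(self, rank_scale):
        with pytest.raises(ValueError, match="unknown"):
            hydrophobicity_profile_export("AXAA", rank_scale)

    def test_homopolymer(self, rank_scale):
        vals = hydrophobicity_profile_export("AAAA", rank_scale)
        assert len(set(vals)) == 1


def test_fod_profile_invariants():
    case = make_fod_case(True, n=45, seed=9)
    profile = fod_profile(case.domain, case.scale)
    assert profile.T.sum() == pytest.approx(1.0, abs=1e-9)
    assert profile.O.sum() == pytest.approx(1.0, abs=1e-9)
    assert profile.R_u.sum() == pytest.approx(1.0, abs=1e-9)
    assert profile.rd == pytest.approx(
        profile.d_ot / (profile.d_ot + profile.d_or), abs=1e-12
    )


def test_separation_on_synthetic_classes():
    """Median RD of core-compliant clouds sits below 0.5, anti-core above."""
    rds_c = [fod_profile(c.domain, c.scale).rd
             for c in (make_fod_case(True, 60, s) for s in range(20))]
    rds_a = [fod_profile(c.domain, c.scale).rd
             for c in (make_fod_case(False, 60, s) for s in range(20))]
    assert np.median(rds_c) < 0.5 < np.median(rds_a)
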