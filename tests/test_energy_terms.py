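import numpy as np
import pytest
from scipy.special import erf

from ssescore import energy_terms as et
from ssescore import features
from ssescore import statistics_builder as sb
from ssescore import synthetic_fixtures as sf
from ssescore._geometry import rotation_about_axis
from ssescore.model_io import (AA3, AA1_TO_3, HELIX, STRAND, AminoAcid,
                               ProteinModel, SSE)
from ssescore.transitions import step_down


def gas_model(n, seed, spread=18.0):
    """Single-SSE model with random anchors (for brute-force oracles)."""
    rng = np.random.default_rng(seed)
    anchors = rng.uniform(0, spread, size=(n, 3))
    residues = [
        AminoAcid("A", i + 1, AA3[rng.integers(0, 20)], anchors[i])
        for i in range(n)
    ]
    return ProteinModel([SSE(HELIX, residues)])


class TestNeighborCount:
    def _pair_model(self, distance):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 5, "LEU", np.array([distance, 0.0, 0.0]))
        return ProteinModel(
            [SSE(HELIX, [r1]),
             SSE(HELIX, [r2])], n_residues=5,
        )

    def test_isolated_residue_zero(self):
        model = self._pair_model(30.0)
        assert features.neighbor_counts(model)[0] == pytest.approx(0.0)

    def test_neighbor_at_lower_threshold_contributes_one(self):
        model = self._pair_model(4.0)
        assert features.neighbor_counts(model)[0] == pytest.approx(1.0)

    def test_neighbor_at_upper_threshold_contributes_zero(self):
        model = self._pair_model(11.4)
        assert features.neighbor_counts(model)[0] == pytest.approx(0.0)

    def test_half_cosine_midpoint(self):
        model = self._pair_model(7.7)
        assert features.neighbor_counts(model)[0] == pytest.approx(0.5)

    def test_sequence_separation_below_three_ignored(self):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 2, "LEU", np.array([4.0, 0, 0]))
        model = ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])])
        assert features.neighbor_counts(model)[0] == pytest.approx(0.0)

    def test_brute_force_oracle(self):
        model = gas_model(10, seed=1, spread=12.0)
        nc = features.neighbor_counts(model)
        res = model.residues
        for i in range(len(res)):
            expected = 0.0
            for j in range(len(res)):
                if i == j or abs(res[i].seq_id - res[j].seq_id) < 3:
                    continue
                d = np.linalg.norm(res[i].anchor - res[j].anchor)
                expected += step_down(d, 4.0, 11.4)
            assert nc[i] == pytest.approx(expected, abs=1e-9)

    def test_single_residue_api(self):
        model = self._pair_model(7.7)
        assert et.neighbor_count(0, model) == pytest.approx(0.5)


class TestEnvironmentScore:
    def test_empty_model_scores_zero(self, tables):
        model = ProteinModel([])
        assert et.score_environment(model, tables.environment) == 0.0

    def test_single_residue_is_table_lookup_at_zero(self, tables):
        model = ProteinModel([SSE(HELIX, [AminoAcid("A", 1, "ALA", np.zeros(3))])])
        expected = tables.environment["ALA"].evaluate(0.0)
        assert et.score_environment(model, tables.environment) == pytest.approx(expected)

    def test_brute_force_sum_oracle(self, tables):
        model = gas_model(9, seed=2, spread=10.0)
        nc = features.neighbor_counts(model)
        expected = sum(
            tables.environment[r.aa_type].evaluate(v)
            for r, v in zip(model.residues, nc)
        )
        assert et.score_environment(model, tables.environment) == pytest.approx(expected)


class TestAAPairScore:
    def test_pair_below_sequence_separation_excluded(self, tables):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 12, "LEU", np.array([5.0, 0, 0]))  # sep 11
        model = ProteinModel([SSE(HELIX, [r1]), SSE(STRAND, [r2])],
                             n_residues=12)
        assert et.score_aa_pair(model, tables.pair) == 0.0

    def test_pair_beyond_support_scores_zero(self, tables):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 14, "LEU", np.array([25.0, 0, 0]))
        model = ProteinModel([SSE(HELIX, [r1]), SSE(STRAND, [r2])],
                             n_residues=14)
        assert et.score_aa_pair(model, tables.pair) == 0.0

    def test_exhaustive_enumeration_oracle(self, tables):
        model = gas_model(10, seed=3)
        expected = 0.0
        res = model.residues
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                if abs(res[i].seq_id - res[j].seq_id) < 12:
                    continue
                d = np.linalg.norm(res[i].anchor - res[j].anchor)
                key = sb.pair_key(res[i].aa_type, res[j].aa_type)
                expected += tables.pair[key].evaluate(d)
        assert et.score_aa_pair(model, tables.pair) == pytest.approx(expected)


class TestLoopLengthScore:
    def test_single_sse_scores_zero(self, tables):
        model = ProteinModel([sf.ideal_sse(HELIX, 8, "A" * 8)])
        assert et.score_loop_length(model, tables.loop) == 0.0

    def test_known_tip_geometry_is_table_lookup(self, tables, toy_bundle):
        (n_loop, tip_d, _), = features.loop_features(toy_bundle)
        expected = tables.loop.evaluate(float(n_loop), tip_d)
        assert et.score_loop_length(toy_bundle, tables.loop) == pytest.approx(expected)

    def test_forced_long_bridge_strongly_positive(self, tables):
        s1 = sf.ideal_sse(STRAND, 5, "ADEFG", start_seq=1)
        s2 = sf.ideal_sse(STRAND, 5, "IKLRV", start_seq=8,
                          t=np.array([40.0, 0.0, 0.0]))
        model = ProteinModel([s1, s2])
        assert et.score_loop_length(model, tables.loop) > 3.0


class TestSSEContacts:
    def test_single_sse_both_terms_zero(self, tables):
        model = ProteinModel([sf.ideal_sse(HELIX, 10, "A" * 10)])
        contacts = et.score_sse_contacts(model, tables.packing)
        assert contacts["strand_pairing"] == 0.0
        assert contacts["sse_packing"] == 0.0

    def test_trained_sheet_scores_favorably(self, tables, toy_sheet):
        contacts = et.score_sse_contacts(toy_sheet, tables.packing)
        assert contacts["strand_pairing"] < 0.0

    def test_distant_helices_contribute_zero(self, tables):
        h1 = sf.ideal_sse(HELIX, 8, "A" * 8, start_seq=1)
        h2 = sf.ideal_sse(HELIX, 8, "A" * 8, start_seq=20,
                          t=np.array([25.0, 0.0, 0.0]))
        model = ProteinModel([h1, h2])
        contacts = et.score_sse_contacts(model, tables.packing)
        assert contacts["sse_packing"] == pytest.approx(0.0, abs=1e-9)

    def test_short_sses_excluded(self, tables):
        h1 = sf.ideal_sse(HELIX, 6, "A" * 6, start_seq=1)
        h2 = sf.ideal_sse(HELIX, 6, "A" * 6, start_seq=20,
                          t=np.array([10.0, 0.0, 0.0]))
        model = ProteinModel([h1, h2])
        contacts = et.score_sse_contacts(model, tables.packing)
        assert contacts["sse_packing"] == 0.0


class TestContactOrderAndRg:
    def test_no_contacts_gives_zero(self):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 10, "LEU", np.array([30.0, 0, 0]))
        model = ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])])
        assert features.contact_order_norm(model) == 0.0

    def test_single_contact_closed_form(self):
        # one contact at separation s in an n-residue protein -> s^2 / n
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 8, "LEU", np.array([5.0, 0, 0]))
        model = ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])],
                             n_residues=8)
        assert features.contact_order_norm(model) == pytest.approx(49.0 / 8.0)

    def test_contact_order_brute_force_oracle(self):
        model = gas_model(12, seed=4, spread=14.0)
        res = model.residues
        seps = []
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                if np.linalg.norm(res[i].anchor - res[j].anchor) <= 8.0:
                    seps.append(abs(res[i].seq_id - res[j].seq_id))
        expected = np.mean(seps) ** 2 / model.n_residues
        assert features.contact_order_norm(model) == pytest.approx(expected)

    def test_rg_single_point_zero(self):
        model = ProteinModel([SSE(HELIX, [AminoAcid("A", 1, "ALA", np.zeros(3))])])
        assert features.squared_radius_of_gyration(model) == 0.0

    def test_rg_two_points_two_angstrom(self):
        r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
        r2 = AminoAcid("A", 5, "LEU", np.array([2.0, 0, 0]))
        model = ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])])
        # each anchor 1 A from the centroid -> mean squared distance 1.0
        assert features.squared_radius_of_gyration(model) == pytest.approx(1.0)

    def test_rg_cloud_direct_formula_oracle(self):
        model = gas_model(50, seed=5)
        anchors = model.anchors()
        expected = np.mean(
            np.sum((anchors - anchors.mean(axis=0)) ** 2, axis=1)
        ) / model.n_residues
        assert features.radius_of_gyration_norm(model) == pytest.approx(expected)


class TestSSAgreement:
    def _helix_model(self):
        return ProteinModel([sf.ideal_sse(HELIX, 5, "AAAAA")])

    def test_probability_at_mean_contributes_zero(self):
        model = self._helix_model()
        mu, _ = et.SSAgreementParams().mu_sigma("psipred", "H")
        preds = {r.seq_id: (0.1, mu, 0.1) for r in model.residues}
        assert et.score_ss_agreement(model, preds, "psipred") == pytest.approx(0.0)

    def test_table_defaults(self):
        params = et.SSAgreementParams()
        assert params.mu_sigma("psipred", "H") == (0.76, 0.20)
        assert params.mu_sigma("jufo", "E") == (0.58, 0.24)

    def test_one_sigma_above_mean(self):
        model = self._helix_model()
        mu, sigma = et.SSAgreementParams().mu_sigma("psipred", "H")
        preds = {r.seq_id: (0.1, mu + sigma, 0.1) for r in model.residues}
        expected = 5 * -erf(1.0 / np.sqrt(2.0))
        assert et.score_ss_agreement(model, preds, "psipred") == pytest.approx(expected)
        assert expected == pytest.approx(5 * -0.6826894, abs=1e-5)

    def test_missing_prediction_is_error(self):
        model = self._helix_model()
        with pytest.raises(KeyError):
            et.score_ss_agreement(model, {1: (0.1, 0.8, 0.1)}, "psipred")


class TestPenalties:
    def _two_residue_model(self, distance, aa="ALA"):
        r1 = AminoAcid("A", 1, aa, np.zeros(3))
        r2 = AminoAcid("A", 6, aa, np.array([distance, 0.0, 0.0]))
        return ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])],
                            n_residues=6)

    def _params(self, d_min=5.0):
        return et.ClashParams(aa_min_distance=np.full((20, 20), d_min))

    def test_aa_clash_zero_at_allowed_distance(self):
        params = self._params(5.0)
        assert et.score_aa_clash(self._two_residue_model(5.0), params) == 0.0

    def test_aa_clash_max_one_angstrom_below(self):
        params = self._params(5.0)
        assert et.score_aa_clash(self._two_residue_model(4.0), params) == pytest.approx(1.0)
        assert et.score_aa_clash(self._two_residue_model(3.0), params) == pytest.approx(1.0)

    def test_aa_clash_ramp_midpoint(self):
        params = self._params(5.0)
        assert et.score_aa_clash(self._two_residue_model(4.5), params) == pytest.approx(0.5)

    def _strand_pair(self, separation):
        s1 = sf.ideal_sse(STRAND, 5, "ADEFG", start_seq=1)
        s2 = sf.ideal_sse(STRAND, 5, "IKLRV", start_seq=10,
                          t=np.array([0.0, separation, 0.0]))
        return ProteinModel([s1, s2], n_residues=14)

    def test_sse_clash_strands_zero_at_three_angstrom(self, clash_params):
        assert et.score_sse_clash(self._strand_pair(3.0), clash_params) == 0.0
        assert et.score_sse_clash(self._strand_pair(5.0), clash_params) == 0.0

    def test_sse_clash_full_below_two_angstrom(self, clash_params):
        assert et.score_sse_clash(self._strand_pair(1.9), clash_params) > 0.9

    def test_sse_clash_ramp_midpoint(self, clash_params):
        # each of the 3 selected fragment pairs contributes the 0.5 ramp value
        model = self._strand_pair(2.5)
        n_entries = len(features.packing_contacts(model))
        v = et.score_sse_clash(model, clash_params)
        assert v == pytest.approx(0.5 * n_entries, abs=0.05 * n_entries)

    def test_helix_pair_at_five_angstrom_no_clash(self, clash_params):
        h1 = sf.ideal_sse(HELIX, 8, "A" * 8, start_seq=1)
        h2 = sf.ideal_sse(HELIX, 8, "A" * 8, start_seq=20,
                          t=np.array([5.0, 0.0, 0.0]))
        model = ProteinModel([h1, h2])
        assert et.score_sse_clash(model, clash_params) == 0.0

    def test_loop_closure_zero_within_limit(self, clash_params):
        model = self._strand_pair(4.75)
        assert et.score_loop_closure(model, clash_params) == 0.0

    def test_loop_closure_positive_beyond_limit(self):
        params = et.ClashParams(
            aa_min_distance=np.full((20, 20), 1.0),
            loop_closure_slope=2.0, loop_closure_intercept=2.0,
        )
        s1 = sf.ideal_sse(STRAND, 5, "ADEFG", start_seq=1)
        s2 = sf.ideal_sse(STRAND, 5, "IKLRV", start_seq=8,
                          t=np.array([40.0, 0.0, 0.0]))
        model = ProteinModel([s1, s2])
        assert et.score_loop_closure(model, params) > 0.0

    def test_loop_closure_regression_oracle(self):
        # synthetic sample with a known 95th-percentile line d = 2.5 n + 3
        rng = np.random.default_rng(0)
        samples = []
        for n in range(1, 21):
            limit = 2.5 * n + 3.0
            samples.extend((n, d) for d in rng.uniform(0, limit, 400))
        slope, intercept = et.fit_loop_closure(samples, percentile=95.0)
        # 95th percentile of U(0, limit) is 0.95 * limit
        assert slope == pytest.approx(0.95 * 2.5, rel=0.05)
        assert intercept == pytest.approx(0.95 * 3.0, abs=0.8)

    def test_fit_aa_min_distances_rule(self):
        # two models with a known closest pair distance: first bin with >= 2
        # counts at 0.05 A resolution defines the threshold
        def pair(d):
            r1 = AminoAcid("A", 1, "ALA", np.zeros(3))
            r2 = AminoAcid("A", 6, "LEU", np.array([d, 0.0, 0.0]))
            return ProteinModel([SSE(HELIX, [r1]), SSE(HELIX, [r2])],
                                n_residues=6)
        models = [pair(4.02), pair(4.03), pair(6.0)]
        mat = et.fit_aa_min_distances(models, min_count=2)
        i, j = AA3.index("ALA"), AA3.index("LEU")
        assert mat[i, j] == pytest.approx(4.00)
        assert mat[j, i] == mat[i, j]


class TestGlobalProperties:
    def _predictions(self, model):
        rng = np.random.default_rng(0)
        return {
            "psipred": sf.synth_predictions(model, 0.9, rng),
            "jufo": sf.synth_predictions(model, 0.8, rng, method="jufo"),
        }

    def test_all_terms_rigid_invariant(self, tables, clash_params, fixture_db):
        model = fixture_db[6]
        preds = self._predictions(model)
        s0 = et.score_all(model, tables, clash_params, preds)
        R = rotation_about_axis([1.0, -0.5, 2.0], 113.0)
        t = np.array([7.0, 21.0, -4.0])
        s1 = et.score_all(model.transformed(R, t), tables, clash_params, preds)
        for name in et.TERM_NAMES:
            assert s1[name] == pytest.approx(s0[name], abs=1e-6), name

    def test_swapping_sse_argument_order_invariant(self, tables, toy_sheet):
        reordered = ProteinModel(list(reversed([s.copy() for s in toy_sheet.sses])),
                                 n_residues=toy_sheet.n_residues)
        c0 = et.score_sse_contacts(toy_sheet, tables.packing)
        c1 = et.score_sse_contacts(reordered, tables.packing)
        assert c1["strand_pairing"] == pytest.approx(c0["strand_pairing"], abs=1e-9)
        assert c1["sse_packing"] == pytest.approx(c0["sse_packing"], abs=1e-9)

    def test_penalties_nonnegative_and_zero_on_fixture_natives(
            self, tables, clash_params, fixture_db):
        for model in fixture_db[:16]:
            s = et.score_all(model, tables, clash_params)
            assert s["aa_clash"] == 0.0
            assert s["sse_clash"] == 0.0
            assert s["loop_closure"] == 0.0

    def test_penalties_nonnegative_on_decoys(self, tables, clash_params,
                                             fixture_db):
        rng = np.random.default_rng(9)
        for model in fixture_db[:6]:
            decoy = sf.make_decoy(model, rng)
            s = et.score_all(decoy, tables, clash_params)
            assert s["aa_clash"] >= 0.0
            assert s["sse_clash"] >= 0.0
            assert s["loop_closure"] >= 0.0

    def test_statistical_terms_continuous_under_perturbation(
            self, tables, clash_params, fixture_db):
        model = fixture_db[3]
        preds = self._predictions(model)
        s0 = et.score_all(model, tables, clash_params, preds)
        eps = 1e-5
        shifted = model.transformed(np.eye(3), np.zeros(3))
        # move one whole SSE by epsilon: every term must change O(eps)
        sses = [s.copy() for s in model.sses]
        sses[1] = sses[1].transformed(np.eye(3), np.array([eps, 0.0, 0.0]))
        shifted = ProteinModel(sses, n_residues=model.n_residues)
        s1 = et.score_all(shifted, tables, clash_params, preds)
        for name in et.TERM_NAMES:
            assert abs(s1[name] - s0[name]) < 1e-2, name
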