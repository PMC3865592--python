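"""Splice-site model training, scoring and three-way consensus loss calls."""

import numpy as np
import pytest

from splicevar.splice_annotator import classify
from splicevar.splice_predictor import (
    METHODS,
    PredictionError,
    PredictorParams,
    batch_predict,
    bundled_training_sequences,
    default_models,
    load_models,
    predict,
    save_models,
    score_window,
    train,
)

DONOR_WT = "CAGGTAAGT"
ACCEPTOR_WT = "CTCTCTCTCTCTCTCTCT" + "AG" + "GTC"


class TestTrain:
    def test_wmm_closed_form_with_pseudocount(self):
        model = train([DONOR_WT] * 10, "donor", "wmm", pseudocount=0.5)
        # donor +1 column: 10 G observations
        p_g = (10 + 0.5) / (10 + 4 * 0.5)
        assert model.probs[3, 2] == pytest.approx(p_g)

    @pytest.mark.parametrize("method", METHODS)
    def test_probability_rows_normalized(self, method):
        model = train(bundled_training_sequences("donor"), "donor", method)
        assert np.allclose(model.probs.sum(axis=1), 1.0)
        if model.cond is not None:
            assert np.allclose(model.cond.sum(axis=2), 1.0)

    def test_wam_learns_deterministic_dinucleotide(self):
        # G at +1 is always followed by T at +2 in the training set
        model = train(bundled_training_sequences("donor"), "donor", "wam",
                      pseudocount=0.1)
        g, t = 2, 3
        assert model.cond[3, g, t] == pytest.approx((20 + 0.1) / (20 + 0.4))

    def test_ragged_training_rejected(self):
        with pytest.raises(PredictionError, match="ragged"):
            train(["ACGT", "ACG"], "donor", "wmm")

    def test_too_few_sequences_rejected(self):
        with pytest.raises(PredictionError, match="at least 2"):
            train([DONOR_WT], "donor", "wmm")


class TestScore:
    def test_degenerate_training_consensus_scores_one(self):
        for method in METHODS:
            model = train([DONOR_WT] * 10, "donor", method)
            assert score_window(model, DONOR_WT) == pytest.approx(1.0)

    def test_background_sequence_scores_at_floor(self):
        # uniform training -> zero information; log-odds raw max is ~0
        model = train(["ACGT" * 2 + "A", "CGTA" * 2 + "C", "GTAC" * 2 + "G",
                       "TACG" * 2 + "T"], "donor", "wmm", pseudocount=0.1)
        assert 0.0 <= score_window(model, DONOR_WT) <= 1.0

    @pytest.mark.parametrize("method", METHODS)
    def test_gt_destroying_mutation_below_threshold(self, method, models):
        mut = DONOR_WT[:3] + "AT" + DONOR_WT[5:]  # GT -> AT
        model = models["donor"][method]
        assert score_window(model, mut) < PredictorParams().recognition_threshold
        assert score_window(model, DONOR_WT) >= PredictorParams().recognition_threshold

    def test_length_mismatch_rejected(self, models):
        with pytest.raises(PredictionError, match="length"):
            score_window(models["donor"]["wmm"], "CAGGT")

    def test_n_scores_as_background(self, models):
        model = models["donor"]["wmm"]
        with_n = DONOR_WT[:8] + "N"
        assert 0 < score_window(model, with_n) <= score_window(model, DONOR_WT)

    @pytest.mark.parametrize("kind,wt,core_positions", [
        ("donor", DONOR_WT, [3, 4, 7]),      # +1, +2, +5
        ("acceptor", ACCEPTOR_WT, [18, 19]),  # -2, -1
    ])
    def test_core_mutations_always_score_below_wild_type(self, kind, wt,
                                                         core_positions, models):
        for method in METHODS:
            model = models[kind][method]
            wt_score = score_window(model, wt)
            for i in core_positions:
                for b in "ACGT":
                    if b == wt[i]:
                        continue
                    mut = wt[:i] + b + wt[i + 1:]
                    assert score_window(model, mut) < wt_score


class TestPredict:
    def test_identical_windows_guarded(self, models):
        with pytest.raises(PredictionError, match="identical"):
            predict(DONOR_WT, DONOR_WT, models["donor"])

    def test_canonical_donor_plus_one_lost(self, models):
        mut = DONOR_WT[:3] + "A" + DONOR_WT[4:]
        p = predict(DONOR_WT, mut, models["donor"])
        assert p.effect == "donor_lost" and p.consensus
        assert all(s.wt_recognized and not s.mut_recognized
                   for s in p.per_method.values())
        assert 0.0 <= p.probability <= 1.0

    def test_acceptor_minus_one_lost(self, models):
        mut = ACCEPTOR_WT[:19] + "A" + ACCEPTOR_WT[20:]
        p = predict(ACCEPTOR_WT, mut, models["acceptor"])
        assert p.effect == "acceptor_lost" and p.consensus

    def test_uninformative_position_keeps_site(self, models):
        mut = DONOR_WT[:8] + "A"  # weak +6 position
        p = predict(DONOR_WT, mut, models["donor"])
        assert p.effect == "none" and not p.consensus

    def test_determinism(self, models):
        mut = DONOR_WT[:3] + "A" + DONOR_WT[4:]
        a = predict(DONOR_WT, mut, models["donor"])
        b = predict(DONOR_WT, mut, models["donor"])
        assert a == b

    def test_consensus_monotone_under_method_removal(self, models):
        mut = DONOR_WT[:3] + "A" + DONOR_WT[4:]
        full = predict(DONOR_WT, mut, models["donor"])
        assert full.consensus
        for drop in METHODS:
            subset = {m: mod for m, mod in models["donor"].items() if m != drop}
            assert predict(DONOR_WT, mut, subset).consensus

    def test_probability_monotone_in_score_drop(self, models):
        benign = DONOR_WT[:8] + "A"
        kill = DONOR_WT[:3] + "A" + DONOR_WT[4:]
        p_benign = predict(DONOR_WT, benign, models["donor"])
        p_kill = predict(DONOR_WT, kill, models["donor"])
        assert p_kill.probability > p_benign.probability


class TestBatchPredict:
    def test_planted_loss_found_among_scenarios(self, scenarios, models):
        from splicevar import cross_match, parse_pileup

        for name in ("gnaq_skip", "hook1_retention", "abcc3_cryptic",
                     "apc_homozygous", "klhdc1_low_expression",
                     "dnah9_not_expressed"):
            sc = scenarios[name]
            variants = cross_match(parse_pileup(sc.paths["tumor_pileup"]),
                                   parse_pileup(sc.paths["normal_pileup"]))
            anns = [a for v in variants for a in classify(v, [sc.transcript])]
            preds = batch_predict(anns, sc.genome, [sc.transcript], models)
            losses = [p for p in preds if p.consensus]
            assert len(losses) == 1, name
            truth = sc.truth["annotation"]
            assert losses[0].effect == f"{truth['side']}_lost", name

    def test_effect_side_matches_annotation_side(self, scenarios, models):
        from splicevar import cross_match, parse_pileup

        for sc in scenarios.values():
            if sc.truth["annotation"] is None:
                continue
            variants = cross_match(parse_pileup(sc.paths["tumor_pileup"]),
                                   parse_pileup(sc.paths["normal_pileup"]))
            anns = [a for v in variants for a in classify(v, [sc.transcript])]
            for p in batch_predict(anns, sc.genome, [sc.transcript], models):
                assert p.kind == p.annotation.side

    def test_all_wild_type_fixture_has_no_losses(self, scenarios, models):
        sc = scenarios["negative_control"]
        from splicevar import cross_match, parse_pileup

        variants = cross_match(parse_pileup(sc.paths["tumor_pileup"]),
                               parse_pileup(sc.paths["normal_pileup"]))
        assert variants == []


class TestSerialization:
    def test_json_round_trip_preserves_scores(self, models, tmp_path):
        path = tmp_path / "models.json"
        save_models(models, path)
        loaded = load_models(path)
        for kind in models:
            for method in models[kind]:
                assert score_window(loaded[kind][method], DONOR_WT if kind == "donor"
                                    else ACCEPTOR_WT) == pytest.approx(
                    score_window(models[kind][method], DONOR_WT if kind == "donor"
                                 else ACCEPTOR_WT)
                )
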