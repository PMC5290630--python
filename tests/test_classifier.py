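"""Rule verdicts, joint criteria, location patterns and cohort evaluation."""

import numpy as np
import pytest

from dystrokit import (
    BMD,
    DMD,
    NA,
    ClassifierConfig,
    JointCriterion,
    PredictionRecord,
    ProteinResult,
    classify_cohort,
    classify_patient,
    evaluate,
    frame_verdict,
    joint_verdict,
    length_verdict,
    make_cohort,
    parse_mutation,
    pattern_verdict,
    stopgain_verdict,
)
from dystrokit.simulate import CohortParams


def _pr(length):
    return ProteinResult("A" * length, length, False, False, 1)


class TestRuleVerdicts:
    def test_frame_rule_classic_pair(self, dystrophin_like):
        assert frame_verdict(parse_mutation("exon45-47del"), dystrophin_like) == BMD
        assert frame_verdict(parse_mutation("exon45del"), dystrophin_like) == DMD

    def test_frame_rule_nonsense_is_na(self, splice_nonsense_model):
        assert frame_verdict(parse_mutation("c.90C>A"), splice_nonsense_model) == NA

    @pytest.mark.parametrize(
        "length,expected",
        [(2999, DMD), (3000, BMD), (3342, BMD), (3685, BMD), (3686, DMD), (0, DMD)],
    )
    def test_length_rule_boundaries(self, length, expected):
        assert length_verdict(_pr(length), ClassifierConfig()) == expected

    @pytest.mark.parametrize("count,expected", [(1, BMD), (0, DMD), (2, DMD), (7, DMD)])
    def test_stopgain_rule(self, count, expected):
        assert stopgain_verdict(count, ClassifierConfig()) == expected

    def test_config_rejects_inverted_window(self):
        with pytest.raises(ValueError):
            ClassifierConfig(length_low=4000, length_high=3685)


class TestJointVerdict:
    @pytest.mark.parametrize(
        "votes,criterion,expected",
        [
            ((DMD, DMD, BMD), JointCriterion.MAJORITY, DMD),
            ((DMD, BMD, BMD), JointCriterion.MAJORITY, BMD),
            ((DMD, BMD, BMD), JointCriterion.ANY, DMD),
            ((BMD, BMD, BMD), JointCriterion.ANY, BMD),
            ((BMD, BMD, BMD), JointCriterion.MAJORITY, BMD),
            ((NA, DMD, BMD), JointCriterion.MAJORITY, BMD),
            ((NA, DMD, BMD), JointCriterion.ANY, DMD),
        ],
    )
    def test_vote_combinations(self, votes, criterion, expected):
        assert joint_verdict(votes, criterion) == expected

    def test_all_na_is_an_error(self):
        with pytest.raises(ValueError):
            joint_verdict((NA, NA, NA))

    def test_any_calls_superset_of_majority(self, minigene, minigene_cfg):
        """Every patient called DMD under MAJORITY is called DMD under ANY."""
        cohort = make_cohort(minigene, CohortParams(n_patients=150, seed=5), minigene_cfg)
        import dataclasses

        any_cfg = dataclasses.replace(minigene_cfg, joint_criterion=JointCriterion.ANY)
        maj_cfg = dataclasses.replace(
            minigene_cfg, joint_criterion=JointCriterion.MAJORITY
        )
        preds_any = classify_cohort(cohort, minigene, cfg=any_cfg)
        preds_maj = classify_cohort(cohort, minigene, cfg=maj_cfg)
        called_any = {p.patient_id for p in preds_any if p.joint_verdict == DMD}
        called_maj = {p.patient_id for p in preds_maj if p.joint_verdict == DMD}
        assert called_maj <= called_any


class TestPatterns:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("exon10-46del", DMD),   # 37 rod exons: above the 35-exon limit
            ("exon10-44del", BMD),   # 35 rod exons: at the limit
            ("exon3-7del", BMD),     # within exons 2-8
            ("exon5-12del", DMD),    # removes ABD material and rod material
            ("exon45-47del", BMD),   # hotspot-sized rod deletion
            ("exon71-74del", BMD),   # syntrophin-binding region
            ("exon66del", DMD),      # cysteine-rich domain (in-frame here)
            ("c.30A>G", NA),         # missense in ABD: no pattern
        ],
    )
    def test_location_patterns(self, dystrophin_like, default_dmap, text, expected):
        ms = parse_mutation(text, dystrophin_like)
        if text == "c.30A>G":  # align the substitution with the model sequence
            t = dystrophin_like.c_to_t(30)
            ref = dystrophin_like.spliced_sequence[t - 1]
            alt = "A" if ref != "A" else "G"
            ms = parse_mutation(f"c.30{ref}>{alt}", dystrophin_like)
        assert pattern_verdict(ms, dystrophin_like, default_dmap) == expected

    def test_pattern_overrides_joint(self, dystrophin_like, default_dmap):
        # a small in-frame cysteine-rich deletion: all three rules vote BMD,
        # the location pattern overrides the joint verdict to DMD
        plain = ClassifierConfig.scaled_to(dystrophin_like)
        with_patterns = ClassifierConfig.scaled_to(
            dystrophin_like, patterns_enabled=True
        )
        rec_plain = classify_patient(
            "p", "exon66del", dystrophin_like, cfg=plain, dmap=default_dmap
        )
        rec_pat = classify_patient(
            "p", "exon66del", dystrophin_like, cfg=with_patterns, dmap=default_dmap
        )
        assert rec_plain.joint_verdict == BMD
        assert rec_pat.pattern_verdict == DMD
        assert rec_pat.joint_verdict == DMD


class TestClassifyPatient:
    def test_splice_plus_nonsense_combination(self, splice_nonsense_model):
        """Skipping the frameshifting exon neutralises the downstream nonsense
        change; the frame rule calls the skip DMD."""
        cfg = ClassifierConfig.scaled_to(splice_nonsense_model)
        rec = classify_patient(
            "p", "c.85+1G>A plus c.90C>A", splice_nonsense_model, cfg=cfg
        )
        assert rec.frame_verdict == DMD  # 22-nt skip shifts the frame
        assert not rec.filtered
        # compare with the nonsense alone: premature stop at codon 30
        rec_sub = classify_patient("q", "c.90C>A", splice_nonsense_model, cfg=cfg)
        assert rec_sub.protein_length_aa == 29
        assert rec.protein_length_aa != rec_sub.protein_length_aa

    def test_unparseable_record_filtered_not_crashed(self, minigene, minigene_cfg):
        rec = classify_patient("p", "c.1335ins680", minigene, cfg=minigene_cfg)
        assert rec.filtered
        assert rec.joint_verdict == NA

    def test_in_frame_rod_deletion_all_rules_bmd(self, dystrophin_like):
        cfg = ClassifierConfig.scaled_to(dystrophin_like)
        rec = classify_patient("p", "exon50-52del", dystrophin_like, cfg=cfg)
        assert (rec.frame_verdict, rec.length_verdict, rec.stopgain_verdict) == (
            BMD, BMD, BMD,
        )
        assert rec.joint_verdict == BMD

    def test_frameshifting_dup_all_rules_dmd(self, minigene, minigene_cfg):
        base = minigene.spliced_sequence[minigene.c_to_t(60) - 1]
        rec = classify_patient("p", f"c.60dup{base}", minigene, cfg=minigene_cfg)
        assert rec.frame_verdict == DMD
        assert rec.stopgain_verdict == DMD
        assert rec.joint_verdict == DMD


class TestEvaluation:
    def _records(self, triples):
        return [
            PredictionRecord(
                patient_id=f"p{i}",
                mutation_text="exon2del",
                joint_verdict=pred,
                mutation_class=cls,
                observed_phenotype=obs,
            )
            for i, (pred, obs, cls) in enumerate(triples)
        ]

    def test_tabulated_confusion_counts(self):
        """5161 correct DMD + 520 falsely-BMD of 5681 gives the canonical
        90.8% accuracy / 9.2% FNR split."""
        from dystrokit.classifier import LARGE

        triples = [(DMD, DMD, LARGE)] * 5161 + [(BMD, DMD, LARGE)] * 520
        summ = evaluate(self._records(triples), method="joint")
        row = summ.row(LARGE)
        assert row["n_total"] == 5681
        assert row["accuracy"] == 90.8
        assert row["fnr"] == 9.2
        assert row["fpr"] == 0.0

    def test_all_correct(self):
        from dystrokit.classifier import LARGE

        summ = evaluate(self._records([(DMD, DMD, LARGE)] * 10), method="joint")
        row = summ.row(LARGE)
        assert (row["accuracy"], row["fpr"], row["fnr"]) == (100.0, 0.0, 0.0)

    def test_counts_match_brute_force_tally(self, minigene, minigene_cfg):
        cohort = make_cohort(minigene, CohortParams(n_patients=120, seed=9), minigene_cfg)
        preds = classify_cohort(cohort, minigene, cfg=minigene_cfg)
        summ = evaluate(preds, method="joint")
        for cls in summ.table["class"]:
            if cls == "total":
                continue
            subset = [
                p
                for p in preds
                if p.mutation_class == cls
                and not p.filtered
                and p.joint_verdict != NA
                and p.observed_phenotype in (DMD, BMD)
            ]
            row = summ.row(cls)
            assert row["n_correct"] == sum(
                p.joint_verdict == p.observed_phenotype for p in subset
            )
            assert row["n_fp"] == sum(
                p.observed_phenotype == BMD and p.joint_verdict == DMD for p in subset
            )
            assert row["n_fn"] == sum(
                p.observed_phenotype == DMD and p.joint_verdict == BMD for p in subset
            )
            assert row["n_total"] == len(subset)
            assert row["n_correct"] + row["n_fp"] + row["n_fn"] == row["n_total"]

    def test_rates_sum_to_100(self, minigene, minigene_cfg):
        cohort = make_cohort(minigene, CohortParams(n_patients=200, seed=3), minigene_cfg)
        preds = classify_cohort(cohort, minigene, cfg=minigene_cfg)
        for method in ("frame", "length", "stopgain", "joint"):
            summ = evaluate(preds, method=method)
            for _, row in summ.table.iterrows():
                if row["n_total"] == 0:
                    continue
                assert row["accuracy"] + row["fpr"] + row["fnr"] == pytest.approx(
                    100.0, abs=0.11
                )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([])

    def test_rounding_half_up(self):
        from dystrokit.classifier import _pct

        assert _pct(1, 16) == 6.3      # 6.25 rounds up
        assert _pct(5161, 5681) == 90.8
        assert _pct(520, 5681) == 9.2
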