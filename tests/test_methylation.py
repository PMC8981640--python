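"""Block building, differential selection, SVM training/calibration,
Youden cutoff, Methyl Score calls, and the QC projections."""

import numpy as np
import pandas as pd
import pytest

from too_integrate.cohort import cohort_fixture, fixture_methyl_diagnoses
from too_integrate.integrate import DiagnosisRelationship, LesionLabel
from too_integrate.methylation import (
    BinaryTOOModel,
    DegenerateROCError,
    MBSMatrix,
    OriginCall,
    ScoringError,
    build_blocks,
    call_from_score,
    infer_patient_from_scores,
    methyl_score,
    pca_projection,
    roc_auc,
    select_differential_blocks,
    train_model,
    youden_cutoff,
)
from too_integrate.cgp import TOO
from too_integrate.profiles import Site
from too_integrate.synthetic import (
    MethylCohortSpec,
    gen_methylation_cohort,
    gen_methylation_sites,
)


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting AUC oracle (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBuildBlocks:
    @staticmethod
    def _tidy(positions, samples=("s1", "s2"), beta=0.42, chrom="1"):
        rows = [
            {"chrom": chrom, "pos": p, "sample_id": s, "beta": beta}
            for p in positions
            for s in samples
        ]
        return pd.DataFrame(rows)

    def test_gap_rule_splits_runs(self):
        sites = self._tidy([100, 200, 300, 2000, 2100, 2200])
        blocks, mbs = build_blocks(sites, max_gap=500, min_sites=3)
        assert [len(b.member_sites) for b in blocks] == [3, 3]
        assert blocks[0].start == 100 and blocks[0].end == 300
        assert blocks[1].start == 2000 and blocks[1].end == 2200

    def test_min_sites_drops_short_runs(self):
        sites = self._tidy([100, 200, 5000, 5100, 5200, 5300])
        blocks, _ = build_blocks(sites, max_gap=500, min_sites=3)
        assert len(blocks) == 1 and blocks[0].start == 5000

    def test_constant_beta_gives_constant_block_values(self):
        sites = self._tidy([100, 200, 300], beta=0.42)
        _, mbs = build_blocks(sites)
        assert np.allclose(mbs.values.to_numpy(), 0.42)

    def test_chromosome_change_breaks_blocks(self):
        a = self._tidy([100, 200, 300], chrom="1")
        b = self._tidy([350, 450, 550], chrom="2")
        blocks, _ = build_blocks(pd.concat([a, b], ignore_index=True))
        assert sorted(bl.chrom for bl in blocks) == ["1", "2"]

    def test_mismatched_site_sets_rejected(self):
        sites = self._tidy([100, 200, 300])
        sites = sites[~((sites.sample_id == "s2") & (sites.pos == 300))]
        with pytest.raises(ValueError, match="s2"):
            build_blocks(sites)

    def test_block_means_match_double_loop_oracle(self):
        spec = MethylCohortSpec(n_blocks=40, n_differential=4, seed=11)
        sites, _, _ = gen_methylation_sites(spec)
        blocks, mbs = build_blocks(sites, max_gap=500, min_sites=3)
        for block in blocks[:10]:
            for sample in mbs.sample_ids[:8]:
                manual = [
                    float(row.beta)
                    for row in sites.itertuples()
                    if row.sample_id == sample
                    and row.chrom == block.chrom
                    and row.pos in block.member_sites
                ]
                assert mbs.values.loc[sample, block.block_id] == pytest.approx(
                    sum(manual) / len(manual)
                )


class TestDifferentialSelection:
    def test_max_delta_block_wins(self):
        values = pd.DataFrame(
            {"A": [0.1, 0.1, 0.5, 0.5], "B": [0.40, 0.40, 0.45, 0.45]},
            index=["s1", "s2", "s3", "s4"],
        )
        from too_integrate.methylation import MethylationBlock

        blocks = [MethylationBlock(b, "1", i * 1000, i * 1000 + 200, (i * 1000,))
                  for i, b in enumerate(values.columns)]
        labels = pd.Series([0, 0, 1, 1], index=values.index)
        mbs = MBSMatrix(values=values, blocks=blocks, labels=labels)
        assert select_differential_blocks(mbs, 1) == ["A"]
        with pytest.raises(ValueError, match="top_m"):
            select_differential_blocks(mbs, 3)

    def test_planted_blocks_recovered(self, small_cohort):
        spec, mbs, planted = small_cohort
        recovered = []
        for seed in range(20):
            cohort, truth = gen_methylation_cohort(
                MethylCohortSpec(n_blocks=300, n_differential=30, seed=seed)
            )
            view = cohort.contrast_view(Site.STOMACH)
            picked = set(select_differential_blocks(view, 30))
            recovered.append(len(picked & set(truth[Site.STOMACH])) / 30)
        assert np.mean(recovered) >= 0.9

    def test_permuted_labels_break_recovery(self):
        cohort, truth = gen_methylation_cohort(
            MethylCohortSpec(n_blocks=300, n_differential=30, seed=42)
        )
        view = cohort.contrast_view(Site.STOMACH)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(
            rng.permutation(view.labels.to_numpy()), index=view.labels.index
        )
        broken = MBSMatrix(values=view.values, blocks=view.blocks, labels=shuffled)
        picked = set(select_differential_blocks(broken, 30))
        overlap = len(picked & set(truth[Site.STOMACH])) / 30
        assert overlap < 0.5  # far below the signal-driven ~100% recovery


class TestYoudenCutoff:
    def test_symmetric_separated_scores(self):
        assert youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_signal_free_scores_fall_back_to_half(self):
        # J <= 0 at every midpoint; the tie rule lands on 0.5.
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [1, 0, 1, 0]
        assert youden_cutoff(scores, labels) == pytest.approx(0.5)

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateROCError):
            youden_cutoff([0.4, 0.4, 0.4], [0, 1, 0])

    def test_cutoff_maximizes_j(self, rng):
        scores = rng.uniform(0, 1, 60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        cut = youden_cutoff(scores, labels)

        def j_at(t):
            pos = scores > t
            sens = (pos & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pos & (labels == 0)).sum() / (labels == 0).sum()
            return sens + spec - 1

        grid = np.linspace(0.001, 0.999, 999)
        assert j_at(cut) >= max(j_at(t) for t in grid) - 1e-12


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.uniform(0, 1, 1000)
        labels = rng.integers(0, 2, 1000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_label_complement_identity(self, rng):
        scores = rng.permutation(np.linspace(0.01, 0.99, 40))  # tie-free
        labels = rng.integers(0, 2, 40)
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestTraining:
    def test_separable_cohort_trains_cleanly(self, small_cohort):
        _, mbs, _ = small_cohort
        model = train_model(mbs.contrast_view(Site.STOMACH), Site.STOMACH,
                            top_m=40, seed=7)
        assert model.cv_auc >= 0.98
        assert 0.4 <= model.cutoff <= 0.6
        assert len(model.selected_blocks) == 40

    def test_shuffled_labels_give_chance_auc(self):
        cohort, _ = gen_methylation_cohort(
            MethylCohortSpec(n_blocks=300, n_differential=30, seed=5)
        )
        view = cohort.contrast_view(Site.CERVIX)
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(20):
            shuffled = pd.Series(
                rng.permutation(view.labels.to_numpy()), index=view.labels.index
            )
            null_view = MBSMatrix(values=view.values, blocks=view.blocks, labels=shuffled)
            model = train_model(null_view, Site.CERVIX, top_m=30,
                                seed=int(rng.integers(2**31)))
            aucs.append(model.cv_auc)
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_single_label_and_fold_limits_rejected(self, small_cohort):
        _, mbs, _ = small_cohort
        view = mbs.contrast_view(Site.STOMACH)
        only_lung = MBSMatrix(
            values=view.values[view.labels == 0],
            blocks=view.blocks,
            labels=view.labels[view.labels == 0],
        )
        with pytest.raises(ValueError):
            train_model(only_lung, Site.STOMACH, seed=0)
        with pytest.raises(ValueError, match="folds"):
            train_model(view, Site.STOMACH, folds=30, seed=0)

    def test_calibration_is_monotone(self, small_cohort):
        _, mbs, _ = small_cohort
        view = mbs.contrast_view(Site.COLON_RECTUM)
        model = train_model(view, Site.COLON_RECTUM, top_m=40, seed=7)
        decisions = model.decision(view.values[model.selected_blocks].to_numpy())
        scores = np.asarray(model.calibration(decisions))
        assert np.array_equal(np.argsort(decisions), np.argsort(scores))
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_model_json_round_trip(self, small_cohort, tmp_path):
        _, mbs, _ = small_cohort
        model = train_model(mbs.contrast_view(Site.STOMACH), Site.STOMACH,
                            top_m=20, seed=3)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BinaryTOOModel.from_json(path)
        assert back.selected_blocks == model.selected_blocks
        assert back.cutoff == model.cutoff
        assert np.allclose(back.weights, model.weights)
        sample = mbs.values.iloc[0]
        assert methyl_score(back, sample).score == pytest.approx(
            methyl_score(model, sample).score
        )


class TestScoring:
    def test_cutoff_rule(self):
        assert call_from_score(0.475).call is OriginCall.LC_ORIGIN
        assert call_from_score(0.537).call is OriginCall.NON_LC_ORIGIN
        assert call_from_score(0.5).call is OriginCall.INDETERMINATE

    def test_held_out_queries_scored_correctly(self, small_cohort):
        spec, mbs, _ = small_cohort
        model = train_model(mbs.contrast_view(Site.STOMACH), Site.STOMACH,
                            top_m=40, seed=7)
        query, _ = gen_methylation_cohort(
            MethylCohortSpec(n_blocks=400, n_differential=40, seed=spec.seed,
                             sample_seed=spec.seed + 1)
        )
        correct = 0
        view = query.contrast_view(Site.STOMACH)
        for sid in view.sample_ids:
            result = methyl_score(model, view.values.loc[sid])
            want = OriginCall.LC_ORIGIN if view.labels[sid] == 0 else OriginCall.NON_LC_ORIGIN
            correct += result.call is want
        assert correct / len(view.sample_ids) >= 0.95

    def test_missing_blocks_refused(self, small_cohort):
        _, mbs, _ = small_cohort
        model = train_model(mbs.contrast_view(Site.STOMACH), Site.STOMACH,
                            top_m=40, seed=7)
        sample = mbs.values.iloc[0].drop(model.selected_blocks[:3])
        with pytest.raises(ScoringError, match=model.selected_blocks[0]):
            methyl_score(model, sample)


class TestPatientInference:
    @pytest.mark.parametrize(
        "lung,extra,organ,relationship,too",
        [
            (0.259, 0.647, Site.COLON_RECTUM,
             DiagnosisRelationship.MULTIPLE_PRIMARY, TOO.NOT_APPLICABLE),
            (0.531, 0.720, Site.STOMACH,
             DiagnosisRelationship.METASTATIC, TOO.STOMACH),
            (0.491, 0.455, Site.COLON_RECTUM,
             DiagnosisRelationship.METASTATIC, TOO.LUNG),
            (0.6, 0.4, Site.COLON_RECTUM,
             DiagnosisRelationship.INDETERMINATE, TOO.INCONCLUSIVE),
        ],
    )
    def test_score_pairs(self, lung, extra, organ, relationship, too):
        diag = infer_patient_from_scores(
            call_from_score(lung, sample_id="PX"),
            call_from_score(extra, sample_id="PX"),
            organ,
        )
        assert diag.relationship is relationship
        assert diag.too is too

    def test_single_sample_gives_lesion_label_only(self):
        diag = infer_patient_from_scores(None, call_from_score(0.751, sample_id="PX"),
                                         Site.STOMACH)
        assert diag.extra_label is LesionLabel.P
        assert diag.relationship is DiagnosisRelationship.NOT_EVALUABLE

    def test_both_missing_rejected(self):
        with pytest.raises(ValueError):
            infer_patient_from_scores(None, None, Site.STOMACH)


class TestReferenceScores:
    def test_all_29_scores_give_conclusive_expected_labels(self):
        """Cutoff 0.5 applied to the printed scores reproduces every
        per-lesion label with no indeterminates."""
        n_scores = 0
        for p in cohort_fixture():
            for score, expected in (
                (p.methyl_lung, p.expected["methyl_lung"]),
                (p.methyl_extra, p.expected["methyl_extra"]),
            ):
                if score is None:
                    assert expected is None
                    continue
                n_scores += 1
                assert call_from_score(score).call is not OriginCall.INDETERMINATE
        assert n_scores == 29

        diags = fixture_methyl_diagnoses()
        for p in cohort_fixture():
            if p.patient_id not in diags:
                continue
            d = diags[p.patient_id]
            if p.expected["methyl_lung"] is not None:
                assert d.lung_label.value == p.expected["methyl_lung"], p.patient_id
            if p.expected["methyl_extra"] is not None:
                assert d.extra_label.value == p.expected["methyl_extra"], p.patient_id

    def test_two_sample_patients_all_conclusive(self):
        diags = fixture_methyl_diagnoses()
        two_sample = [p for p in cohort_fixture() if p.n_methyl_samples == 2]
        assert len(two_sample) == 14
        assert all(diags[p.patient_id].conclusive for p in two_sample)


class TestPCA:
    def test_identical_samples_identical_coordinates(self):
        from too_integrate.methylation import MethylationBlock

        values = pd.DataFrame(
            [[0.2, 0.8, 0.5]] * 2 + [[0.7, 0.1, 0.4]],
            index=["a", "b", "c"],
            columns=["B1", "B2", "B3"],
        )
        blocks = [MethylationBlock(b, "1", i, i + 10, (i,)) for i, b in enumerate(values.columns)]
        coords = pca_projection(MBSMatrix(values=values, blocks=blocks), n_components=2)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_tissues_separate_in_pc_space(self):
        cohort, _ = gen_methylation_cohort(
            MethylCohortSpec(n_blocks=300, n_differential=30, seed=21)
        )
        view = cohort.contrast_view(Site.CERVIX)
        coords = pca_projection(view, n_components=2)
        lung = coords[view.labels == 0].to_numpy()
        cervix = coords[view.labels == 1].to_numpy()
        between = np.linalg.norm(lung.mean(0) - cervix.mean(0))
        within = np.concatenate(
            [
                np.linalg.norm(lung - lung.mean(0), axis=1),
                np.linalg.norm(cervix - cervix.mean(0), axis=1),
            ]
        ).mean()
        assert between > 3 * within

    def test_component_variance_ordering(self, small_cohort):
        _, mbs, _ = small_cohort
        coords = pca_projection(mbs, n_components=2)
        assert coords["PC1"].var() >= coords["PC2"].var()

    def test_excess_components_rejected(self):
        from too_integrate.methylation import MethylationBlock

        values = pd.DataFrame([[0.1, 0.2], [0.3, 0.4]], index=["a", "b"], columns=["B1", "B2"])
        blocks = [MethylationBlock(b, "1", i, i + 10, (i,)) for i, b in enumerate(values.columns)]
        with pytest.raises(ValueError):
            pca_projection(MBSMatrix(values=values, blocks=blocks), n_components=2)
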