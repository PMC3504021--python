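"""Discovery engine: stratification, ranking, nearest-mean, AUC,
multiple sampling and forward selection against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crlmsig.cohort import ExpressionStudy, records_to_frame
from crlmsig.discovery import (
    DiscoveryConfig,
    NearestMeanModel,
    RiskStratification,
    _cox_z,
    _metric_scores,
    _ranks_desc_abs,
    _stratified_draw,
    combined_auc,
    forward_select,
    multiple_sampling,
    rank_genes,
    stratify_risk,
    validate_signature,
)


def _expr(X, samples=None):
    X = np.asarray(X, float)
    genes = [f"G{i:03d}" for i in range(X.shape[0])]
    samples = samples or [f"P{i:03d}" for i in range(X.shape[1])]
    return ExpressionStudy(pd.DataFrame(X, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# risk stratification


@pytest.mark.parametrize(
    "dfs, event, expected",
    [
        (10.0, 1, "high"),  # recurrence within a year
        (14.0, 0, "low"),  # follow-up exceeds the threshold
        (14.0, 1, "low"),  # late recurrence is still low risk
        (8.0, 0, "unlabelable"),  # censored too early to call
        (12.0, 1, "high"),  # boundary: at the threshold counts as high
    ],
)
def test_stratify_default_rule(make_record, dfs, event, expected):
    clin = records_to_frame([make_record(dfs_months=dfs, event=event)])
    assert stratify_risk(clin).iloc[0] == expected


def test_stratify_strict_rule_labels_fewer(make_record):
    records = [
        make_record(patient_id=f"P{i}", dfs_months=d, event=e)
        for i, (d, e) in enumerate([(4, 1), (10, 1), (18, 0), (30, 0)])
    ]
    clin = records_to_frame(records)
    default = stratify_risk(clin)
    strict = stratify_risk(clin, RiskStratification(6.0, 24.0))
    assert (strict != "unlabelable").sum() < (default != "unlabelable").sum()
    assert strict.tolist() == ["high", "unlabelable", "unlabelable", "low"]


def test_stratify_rejects_negative_dfs(make_record):
    clin = records_to_frame([make_record()])
    clin.loc[0, "dfs_months"] = -1.0
    with pytest.raises(ValueError):
        stratify_risk(clin)


def test_inverted_rule_rejected():
    with pytest.raises(ValueError):
        RiskStratification(high_max_months=24, low_min_months=12)


# ---------------------------------------------------------------------------
# gene ranking


def _labels(n_high, n_low):
    ids = [f"P{i:03d}" for i in range(n_high + n_low)]
    return pd.Series(["high"] * n_high + ["low"] * n_low, index=ids)


def test_snr_separated_gene_ranks_first_and_flat_gene_last():
    X = np.vstack(
        [
            [2, 2, 2.01, 0, 0, 0.01],  # near-perfect separation
            [1, 1, 1, 1, 1, 1],  # identical everywhere -> NaN score
            [0.5, 0.4, 0.6, 0.4, 0.5, 0.6],  # weak
        ]
    )
    out = rank_genes(_expr(X), _labels(3, 3), "snr")
    assert out["rank"].tolist() == [1.0, 3.0, 2.0]
    assert np.isnan(out["score"].iloc[1])


def test_equal_means_gene_ranks_after_nonzero_scores():
    X = np.vstack(
        [
            [1.0, 1.2, 0.8, 1.1, 0.9, 1.0],  # same mean both classes -> snr ~ 0
            [2, 2.2, 1.8, 0, 0.1, -0.1],
        ]
    )
    out = rank_genes(_expr(X), _labels(3, 3), "snr")
    assert out["rank"].iloc[1] == 1.0
    assert out["rank"].iloc[0] == 2.0


def test_welch_t_matches_brute_force_on_five_genes():
    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (5, 12))
    labels = _labels(5, 7)
    out = rank_genes(_expr(X), labels, "tstat")
    ref = sps.ttest_ind(X[:, :5], X[:, 5:], axis=1, equal_var=False).statistic
    assert np.allclose(out["score"], ref)
    assert sorted(out["rank"]) == [1, 2, 3, 4, 5]
    order_ref = np.argsort(-np.abs(ref))
    assert np.argsort(out["rank"].to_numpy()).tolist() == order_ref.tolist()


def test_cox_ranking_matches_lifelines_wald_z():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(9)
    n = 50
    X = rng.normal(0, 1, (4, n))
    t = rng.exponential(np.exp(-0.5 * X[0]) * 10)
    e = (rng.random(n) < 0.8).astype(int)
    z = _cox_z(X, t, e)
    for i in range(4):
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": X[i]}), "t", "e"
        )
        assert z[i] == pytest.approx(float(cph.summary["z"].iloc[0]), abs=1e-3)


def test_rank_ties_broken_by_gene_order():
    scores = np.array([0.5, 0.5, 1.0, np.nan])
    assert _ranks_desc_abs(scores).tolist() == [2.0, 3.0, 1.0, 4.0]


def test_rank_genes_requires_two_per_class():
    X = np.zeros((2, 3))
    with pytest.raises(ValueError):
        rank_genes(_expr(X), _labels(1, 2), "snr")


# ---------------------------------------------------------------------------
# combined AUC


def test_auc_perfect_and_all_ties():
    auc, _ = combined_auc([3, 4, 1, 2], ["high", "high", "low", "low"], n_boot=0)
    assert auc == 1.0
    auc, _ = combined_auc([1, 1, 1, 1], ["high", "high", "low", "low"], n_boot=0)
    assert auc == 0.5


def test_auc_equals_exhaustive_pair_counting():
    rng = np.random.default_rng(10)
    scores = rng.normal(0, 1, 8).round(1)  # rounding forces some ties
    labels = np.array(["high"] * 4 + ["low"] * 4)
    auc, _ = combined_auc(scores, labels, n_boot=0)
    wins = sum(
        1.0 if sh > sl else 0.5 if sh == sl else 0.0
        for sh in scores[:4]
        for sl in scores[4:]
    )
    assert auc == pytest.approx(wins / 16)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        combined_auc([1, 2], ["high", "high"], n_boot=0)


def test_auc_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(11)
    s = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
    lab = ["high"] * 40 + ["low"] * 40
    auc, ci = combined_auc(s, lab, n_boot=300, seed=1)
    assert ci[0] < auc < ci[1]
    assert 0.5 < auc < 1.0


# ---------------------------------------------------------------------------
# nearest-mean classifier


def test_sample_equal_to_high_centroid_predicted_high():
    rng = np.random.default_rng(12)
    X = np.hstack([rng.normal(1, 0.1, (3, 4)), rng.normal(-1, 0.1, (3, 4))])
    high = np.array([True] * 4 + [False] * 4)
    model = NearestMeanModel.fit(X, high, ["G000", "G001", "G002"])
    probe = model.train_mean[:, None] + model.train_sd[:, None] * model.centroid_high[:, None]
    out = model.predict_expr(_expr(probe, ["Q1"]))
    assert out.loc["Q1", "predicted"] == "high"
    assert out.loc["Q1", "score"] < 0


def test_equidistant_sample_ties_to_high():
    X = np.array([[1.0, 1.1, -1.0, -1.1], [1.0, 0.9, -1.0, -0.9]])
    model = NearestMeanModel.fit(X, np.array([True, True, False, False]), ["G000", "G001"])
    # centroids are symmetric, so the gene-space origin is equidistant
    probe = model.train_mean[:, None]
    out = model.predict_expr(_expr(probe, ["Q1"]))
    assert out.loc["Q1", "score"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc["Q1", "predicted"] == "high"


def test_predictions_match_hand_computed_correlations():
    rng = np.random.default_rng(13)
    X = rng.normal(0, 1, (3, 6))
    high = np.array([True, True, True, False, False, False])
    model = NearestMeanModel.fit(X, high, ["G000", "G001", "G002"])
    Z = (X - model.train_mean[:, None]) / model.train_sd[:, None]
    out = model.predict_expr(_expr(X))
    for j, sid in enumerate([f"P{i:03d}" for i in range(6)]):
        ch = np.corrcoef(Z[:, j], model.centroid_high)[0, 1]
        cl = np.corrcoef(Z[:, j], model.centroid_low)[0, 1]
        assert out.loc[sid, "score"] == pytest.approx(cl - ch, abs=1e-12)


def test_single_gene_signature_uses_signed_distance():
    X = np.array([[2.0, 2.2, 1.8, -2.0, -2.2, -1.8]])
    high = np.array([True, True, True, False, False, False])
    model = NearestMeanModel.fit(X, high, ["G000"])
    out = model.predict_expr(_expr(np.array([[2.1, -2.1]]), ["A", "B"]))
    assert out.loc["A", "predicted"] == "high"
    assert out.loc["B", "predicted"] == "low"


# ---------------------------------------------------------------------------
# multiple sampling


def _toy_training(n_genes=60, n=30, effect=0.0, seed=14):
    rng = np.random.default_rng(seed)
    n_high = n // 2
    X = rng.normal(0, 1, (n_genes, n))
    X[:10, :n_high] += effect
    expr = _expr(X)
    labels = _labels(n_high, n - n_high)
    time = pd.Series(
        np.r_[rng.uniform(2, 11, n_high), rng.uniform(13, 40, n - n_high)],
        index=labels.index,
    )
    event = pd.Series(np.r_[np.ones(n_high, int), (rng.random(n - n_high) < 0.5).astype(int)],
                      index=labels.index)
    return expr, labels, time, event


def test_single_iteration_equals_manual_pass():
    """iterations=1 reproduces a hand-driven split-rank-fit-predict pass
    executed step by step with the same seeded draw."""
    expr, labels, time, event = _toy_training()
    cfg = DiscoveryConfig(n_iterations=1, top_k=15, seed=42, n_boot=0)
    res = multiple_sampling(expr, labels, time, event, cfg)

    # manual replay
    rng = np.random.default_rng(42)
    X = expr.values.to_numpy()
    high = (labels == "high").to_numpy()
    train = _stratified_draw(rng, high, cfg.subsample_fraction)
    tt, ee = time.to_numpy(), event.to_numpy()
    combined = np.zeros(X.shape[0])
    for m in cfg.metrics:
        combined += _ranks_desc_abs(
            _metric_scores(m, X[:, train], high[train], tt[train], ee[train],
                           cox_iter=cfg.cox_newton_iter)
        )
    combined /= 3
    assert np.allclose(res.avg_rank.to_numpy(), combined)
    top = np.lexsort((np.arange(X.shape[0]), combined))[:15]
    model = NearestMeanModel.fit(X[top][:, train], high[train],
                                 [expr.genes[i] for i in top])
    held = np.flatnonzero(~train)
    manual = -model._scores_from_block(X[top][:, held])
    assert np.allclose(np.sort(res.pooled["risk_score"].to_numpy()), np.sort(manual))


def test_planted_signature_recovered_in_top_ranks():
    expr, labels, time, event = _toy_training(effect=2.0)
    cfg = DiscoveryConfig(n_iterations=60, top_k=15, seed=2, n_boot=0)
    res = multiple_sampling(expr, labels, time, event, cfg)
    top15 = set(res.top_genes(15))
    planted = {f"G{i:03d}" for i in range(10)}
    assert len(planted & top15) >= 8
    assert res.auc > 0.8


def test_null_data_auc_near_half():
    expr, labels, time, event = _toy_training(effect=0.0, seed=15)
    # survival shuffled so not even time correlates with labels
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(labels))
    time = pd.Series(time.to_numpy()[perm], index=time.index)
    event = pd.Series(event.to_numpy()[perm], index=event.index)
    res = multiple_sampling(
        expr, labels, time, event, DiscoveryConfig(n_iterations=150, top_k=15, seed=3, n_boot=0)
    )
    assert 0.35 < res.auc < 0.65


def test_too_few_labeled_samples_rejected():
    expr, labels, time, event = _toy_training(n=6)
    labels.iloc[:] = ["high", "high", "low", "low", "low", "low"]
    with pytest.raises(ValueError):
        multiple_sampling(expr, labels, time, event, DiscoveryConfig(n_iterations=1))


# ---------------------------------------------------------------------------
# forward selection


def test_flat_accuracy_curve_selects_smallest_size():
    # separation so strong that every prefix classifies perfectly: the
    # accuracy curve is flat at 1 and the tie rule picks k = 1.  Signs
    # alternate because the correlation-based classifier needs an
    # expression *pattern* across genes, not a common shift.
    rng = np.random.default_rng(18)
    X = rng.normal(0, 0.2, (5, 8))
    X[:, :4] += 5.0 * np.where(np.arange(5) % 2 == 0, 1.0, -1.0)[:, None]
    expr = _expr(X)
    labels = _labels(4, 4)
    rank = pd.Series(np.arange(1.0, 6.0), index=expr.genes)
    sig = forward_select(expr, labels, rank, max_size=5)
    assert np.allclose(sig.accuracy_curve["accuracy"], 1.0)
    assert sig.size == 1


def _brute_force_loocv(X, high, max_size):
    """Exhaustive LOOCV oracle with explicit per-size refits."""
    n = X.shape[1]
    acc = np.zeros(max_size)
    for k in range(1, max_size + 1):
        correct = 0
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            mu = X[:k, tr].mean(1)
            sd = X[:k, tr].std(1, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            Z = (X[:k] - mu[:, None]) / sd[:, None]
            ch, cl = Z[:, tr & high].mean(1), Z[:, tr & ~high].mean(1)
            z = Z[:, i]
            if k == 1:
                risk = abs(z[0] - cl[0]) - abs(z[0] - ch[0])
            else:
                risk = np.corrcoef(z, ch)[0, 1] - np.corrcoef(z, cl)[0, 1]
            correct += (risk >= 0) == high[i]
        acc[k - 1] = correct / n
    return acc


def test_loocv_curve_matches_exhaustive_oracle():
    rng = np.random.default_rng(16)
    X = rng.normal(0, 1, (3, 6))
    X[0, :3] += 1.5
    expr = _expr(X)
    labels = _labels(3, 3)
    rank = pd.Series([1.0, 2.0, 3.0], index=expr.genes)
    sig = forward_select(expr, labels, rank, max_size=3)
    oracle = _brute_force_loocv(X, np.array([True] * 3 + [False] * 3), 3)
    assert np.allclose(sig.accuracy_curve["accuracy"], oracle)


def test_forward_select_finds_planted_block():
    expr, labels, time, event = _toy_training(n_genes=40, n=40, effect=2.5, seed=17)
    rank = pd.Series(np.arange(1.0, 41.0), index=expr.genes)  # planted genes first
    sig = forward_select(expr, labels, rank, max_size=20)
    assert sig.loocv_accuracy > 0.8
    assert 1 <= sig.size <= 20


# ---------------------------------------------------------------------------
# validation


def test_validation_overlap_is_hard_error():
    expr, labels, time, event = _toy_training(n=10)
    model = NearestMeanModel.fit(
        expr.values.to_numpy()[:5], (labels == "high").to_numpy(), expr.genes[:5].tolist()
    )
    clin = pd.DataFrame(
        {
            "patient_id": expr.samples,
            "dfs_months": time.to_numpy(),
            "event": event.to_numpy(),
        }
    )
    with pytest.raises(ValueError, match="overlap"):
        validate_signature(model, expr, clin, training_ids=[expr.samples[0]])


def test_resubstitution_accuracy_not_below_loocv(planted_cohort):
    records, study, clinical = planted_cohort
    labels = stratify_risk(clinical)
    rank = rank_genes(study, labels, "tstat")["rank"]
    sig = forward_select(study, labels, rank, max_size=30)
    preds = sig.model.predict_expr(study)
    lab = labels[labels.isin(["high", "low"])]
    resub = (preds.loc[lab.index, "predicted"] == lab).mean()
    assert resub >= sig.loocv_accuracy - 0.02


def test_validation_detects_planted_signal(planted_cohort):
    records, study, clinical = planted_cohort
    train_ids = clinical["patient_id"][:75].tolist()
    val_ids = clinical["patient_id"][75:].tolist()
    labels = stratify_risk(clinical[clinical["patient_id"].isin(train_ids)])
    expr_train = study.subset_samples(train_ids)
    rank = rank_genes(expr_train, labels, "tstat")["rank"]
    sig = forward_select(expr_train, labels, rank, max_size=30)
    report = validate_signature(
        sig.model,
        study.subset_samples(val_ids),
        clinical[clinical["patient_id"].isin(val_ids)],
        training_ids=train_ids,
    )
    assert report.logrank is not None
    assert report.logrank.p_value < 0.05
    assert report.logrank.hazard_ratio != 1.0
    assert set(report.predictions.index) == set(val_ids)
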