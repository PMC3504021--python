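"""Gene-signature discovery by multiple random sampling.

The procedure this module implements estimates a prognostic gene
signature for dichotomized disease-free survival (high risk = recurrence
within one year) and, crucially, an honest estimate of its predictive
power:

1.  Label training patients high/low risk from (DFS, event).
2.  Repeat (default 1000 times): draw a stratified 2/3 subsample of the
    labeled training patients; rank all genes on the subsample by three
    metrics — signal-to-noise ratio, Welch t statistic and the Wald z of
    a univariate Cox fit — and average the three ranks; fit a
    nearest-mean (centroid) classifier on the top-75 genes; score the
    held-out 1/3.
3.  Pool the held-out scores over all iterations into one combined ROC
    AUC (~0.5 when expression carries no outcome information), and
    average each gene's rank over iterations.
4.  Grow the final signature by forward selection along the averaged
    ranking, keeping the size with the best leave-one-out (LOOCV)
    accuracy on the training set.
5.  Validate the frozen signature on patients never seen during
    discovery: predict their risk class and compare DFS between the
    predicted classes (Kaplan-Meier, Mantel-Cox log-rank, Cox HR).

Continuous classifier scores follow the nearest-mean convention: the raw
score is corr(sample, low centroid) - corr(sample, high centroid), with
score <= 0 predicting high risk; pooled scores are reported as *risk
scores* (the negative), so that higher = more high-risk-like and the
combined AUC reads in the usual orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import ExpressionStudy
from . import survival as surv

logger = logging.getLogger(__name__)

__all__ = [
    "RiskStratification",
    "DiscoveryConfig",
    "NearestMeanModel",
    "MultipleSamplingResult",
    "Signature",
    "ValidationReport",
    "stratify_risk",
    "rank_genes",
    "multiple_sampling",
    "combined_auc",
    "forward_select",
    "validate_signature",
    "discover_signature",
]


# ---------------------------------------------------------------------------
# risk stratification


@dataclass
class RiskStratification:
    """Dichotomization rule mapping (DFS, event) to a risk label.

    high: recurrence observed at dfs <= high_max_months.
    low:  dfs > low_min_months (event or censoring beyond that point —
          either way the patient is known to have stayed recurrence-free
          past the threshold).
    unlabelable: censored at or before high_max_months without an event —
          too short a follow-up to call either way.  The default rule is
          the one-year split; (6, 24) gives the stricter variant.
    """

    high_max_months: float = 12.0
    low_min_months: float = 12.0

    def __post_init__(self) -> None:
        if self.high_max_months > self.low_min_months:
            raise ValueError("high_max_months must be <= low_min_months")


def stratify_risk(clinical: pd.DataFrame, rule: RiskStratification | None = None) -> pd.Series:
    """Label each patient high / low / unlabelable under ``rule``.

    Returns a Series indexed by patient_id.
    """
    rule = rule or RiskStratification()
    dfs = clinical["dfs_months"].to_numpy(dtype=float)
    ev = clinical["event"].to_numpy(dtype=int)
    if np.any(dfs < 0):
        raise ValueError("negative DFS time")
    lab = np.where(
        (ev == 1) & (dfs <= rule.high_max_months),
        "high",
        np.where(dfs > rule.low_min_months, "low", "unlabelable"),
    )
    return pd.Series(lab, index=clinical["patient_id"].to_numpy(), name="risk")


# ---------------------------------------------------------------------------
# per-gene ranking metrics (vectorized over genes; X is genes x samples)


def _snr(X: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Golub signal-to-noise ratio (mean_h - mean_l) / (sd_h + sd_l)."""
    xh, xl = X[:, high], X[:, ~high]
    num = xh.mean(axis=1) - xl.mean(axis=1)
    den = xh.std(axis=1, ddof=1) + xl.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = num / den
    s[den == 0] = np.nan
    return s


def _welch_t(X: np.ndarray, high: np.ndarray) -> np.ndarray:
    xh, xl = X[:, high], X[:, ~high]
    nh, nl = xh.shape[1], xl.shape[1]
    num = xh.mean(axis=1) - xl.mean(axis=1)
    den = np.sqrt(xh.var(axis=1, ddof=1) / nh + xl.var(axis=1, ddof=1) / nl)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t[den == 0] = np.nan
    return t


def _cox_z(X: np.ndarray, time: np.ndarray, event: np.ndarray, n_iter: int = 6) -> np.ndarray:
    """Wald z of a univariate Cox fit per gene (vectorized Newton solver,
    Breslow tie handling).  Genes with zero variance return NaN.

    Samples are sorted by descending time so every risk-set sum is a
    plain prefix cumsum; tied event times share the risk set running to
    the end of their tie group.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if e.sum() < 1:
        raise ValueError("Cox ranking requires at least one event")
    order = np.argsort(-t, kind="stable")
    ts, es = t[order], e[order]
    Xs = np.ascontiguousarray(np.asarray(X, dtype=float)[:, order])
    sd = Xs.std(axis=1)
    mu = Xs.mean(axis=1)
    ok = sd > 0
    Z = (Xs - mu[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    n = len(ts)
    # inclusive end index of each descending-order tie group
    last_in_group = np.r_[ts[1:] != ts[:-1], True]
    idx = np.arange(n)
    group_end = idx[last_in_group][np.searchsorted(idx[last_in_group], idx)]
    ev_idx = np.flatnonzero(es)
    end_ev = group_end[ev_idx]
    beta = np.zeros(Z.shape[0])
    info = np.ones_like(beta)
    for _ in range(n_iter):
        with np.errstate(over="ignore", invalid="ignore"):
            W = np.exp(np.minimum(np.maximum(beta[:, None] * Z, -30.0), 30.0))
            WX = W * Z
            S0 = W.cumsum(axis=1)[:, end_ev]
            S1 = WX.cumsum(axis=1)[:, end_ev]
            S2 = (WX * Z).cumsum(axis=1)[:, end_ev]
            r1 = S1 / S0
            U = (Z[:, ev_idx] - r1).sum(axis=1)
            info = (S2 / S0 - r1 * r1).sum(axis=1)
            step = np.minimum(np.maximum(U / np.maximum(info, 1e-12), -1.0), 1.0)
            beta = np.minimum(np.maximum(beta + step, -15.0), 15.0)
    with np.errstate(invalid="ignore"):
        z = beta * np.sqrt(np.maximum(info, 0.0))
    z[~ok] = np.nan
    return z


_METRICS = ("snr", "tstat", "coxhr")


def _metric_scores(
    metric: str,
    X: np.ndarray,
    high: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cox_iter: int = 6,
) -> np.ndarray:
    if metric == "snr":
        return _snr(X, high)
    if metric == "tstat":
        return _welch_t(X, high)
    if metric == "coxhr":
        return _cox_z(X, time, event, n_iter=cox_iter)
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def _ranks_desc_abs(scores: np.ndarray) -> np.ndarray:
    """Rank genes 1..G by descending |score|; ties broken by gene order
    (index), NaN scores ranked last."""
    key = np.abs(scores.copy())
    nan = ~np.isfinite(key)
    key[nan] = -np.inf
    order = np.lexsort((np.arange(len(key)), -key))
    ranks = np.empty(len(key), dtype=float)
    ranks[order] = np.arange(1, len(key) + 1)
    return ranks


def rank_genes(
    expr: ExpressionStudy,
    labels: pd.Series,
    metric: str,
    time: pd.Series | None = None,
    event: pd.Series | None = None,
) -> pd.DataFrame:
    """Score and rank every gene by one metric on the labeled samples.

    ``labels`` is a high/low Series indexed by sample id (unlabelable
    entries are ignored); ``time``/``event`` (same index) are required for
    the Cox metric.  Ranks are descending in |score| with ties broken by
    gene id; genes with zero variance in both classes get NaN scores and
    the worst ranks (with a warning).
    """
    lab = labels[labels.isin(["high", "low"])]
    samples = [s for s in lab.index if s in expr.samples]
    if len(samples) < len(lab):
        raise KeyError("labeled samples missing from expression matrix")
    X = expr.values[samples].to_numpy()
    high = (lab.loc[samples] == "high").to_numpy()
    if metric in ("snr", "tstat") and (high.sum() < 2 or (~high).sum() < 2):
        raise ValueError("need at least 2 samples per class")
    tt = ee = None
    if metric == "coxhr":
        if time is None or event is None:
            raise ValueError("coxhr metric requires time and event")
        tt = time.loc[samples].to_numpy(dtype=float)
        ee = event.loc[samples].to_numpy(dtype=int)
    scores = _metric_scores(metric, X, high, tt, ee)
    n_degenerate = int(np.sum(~np.isfinite(scores)))
    if n_degenerate:
        import warnings

        warnings.warn(f"{n_degenerate} genes with degenerate {metric} scores ranked last")
    return pd.DataFrame(
        {"score": scores, "rank": _ranks_desc_abs(scores)}, index=expr.genes
    )


# ---------------------------------------------------------------------------
# nearest-mean (centroid) classifier


@dataclass
class NearestMeanModel:
    """Nearest-mean classifier over an ordered gene list.

    Genes are standardized by the training mean and SD; the class
    centroids are per-class means of the standardized training samples.
    The continuous score of a sample is corr(sample, centroid_low) -
    corr(sample, centroid_high); score <= 0 predicts high risk (the
    conservative tie rule).  For a single-gene signature, where the
    correlation is undefined, the signed standardized distance
    |x - c_high| - |x - c_low| is used instead.
    """

    genes: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    centroid_high: np.ndarray
    centroid_low: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, high: np.ndarray, genes: list[str]) -> "NearestMeanModel":
        """Fit from a genes-x-samples block and a boolean high-risk mask."""
        if high.sum() == 0 or (~high).sum() == 0:
            raise ValueError("both classes required to fit a nearest-mean model")
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            logger.info("dropping %d zero-variance genes from model", int((~keep).sum()))
        X = X[keep]
        genes = [g for g, k in zip(genes, keep) if k]
        mu, sd = mu[keep], sd[keep]
        Z = (X - mu[:, None]) / sd[:, None]
        return cls(
            genes=genes,
            train_mean=mu,
            train_sd=sd,
            centroid_high=Z[:, high].mean(axis=1),
            centroid_low=Z[:, ~high].mean(axis=1),
        )

    def _scores_from_block(self, X: np.ndarray) -> np.ndarray:
        """Raw (low-affinity) scores for a genes-x-samples block aligned
        with ``self.genes``."""
        Z = (X - self.train_mean[:, None]) / self.train_sd[:, None]
        if len(self.genes) == 1:
            logger.info("single-gene signature: using signed standardized distance")
            return np.abs(Z[0] - self.centroid_high[0]) - np.abs(Z[0] - self.centroid_low[0])
        ch = _pearson_with(Z, self.centroid_high)
        cl = _pearson_with(Z, self.centroid_low)
        return cl - ch

    def predict_expr(self, expr: ExpressionStudy) -> pd.DataFrame:
        """Predict every sample of ``expr``.

        Returns a frame indexed by sample id with ``score`` (raw
        low-affinity score), ``risk_score`` (= -score, higher = more
        high-risk-like) and ``predicted`` class.
        """
        X = expr.values.loc[self.genes].to_numpy()
        s = self._scores_from_block(X)
        return pd.DataFrame(
            {
                "score": s,
                "risk_score": -s,
                "predicted": np.where(s <= 0, "high", "low"),
            },
            index=expr.samples,
        )


def _pearson_with(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of A (genes x samples) with c."""
    Ac = A - A.mean(axis=0, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt((Ac * Ac).sum(axis=0) * (cc * cc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Ac * cc[:, None]).sum(axis=0) / denom
    return np.where(denom > 0, out, 0.0)


# ---------------------------------------------------------------------------
# combined AUC


def combined_auc(
    scores,
    labels,
    *,
    patient_ids=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """ROC AUC of pooled risk scores: P(score_high > score_low), ties 1/2.

    ``labels`` are 'high'/'low' per score.  The 95% CI is a stratified
    bootstrap: patients (when ``patient_ids`` is given, keeping each
    patient's pooled scores together) or observations are resampled with
    replacement within each class.  ``n_boot=0`` skips the CI.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    high = lab == "high"
    low = lab == "low"
    if not high.any() or not low.any():
        raise ValueError("combined_auc requires scores from both classes")

    def _auc(sh: np.ndarray, sl: np.ndarray) -> float:
        r = rankdata(np.concatenate([sh, sl]))
        nh, nl = len(sh), len(sl)
        return (r[:nh].sum() - nh * (nh + 1) / 2) / (nh * nl)

    auc = _auc(s[high], s[low])
    if n_boot <= 0:
        return float(auc), None
    rng = np.random.default_rng(seed)
    if patient_ids is None:
        groups_h = [s[high][i : i + 1] for i in range(high.sum())]
        groups_l = [s[low][i : i + 1] for i in range(low.sum())]
    else:
        pid = np.asarray(patient_ids)
        groups_h = [s[high & (pid == p)] for p in pd.unique(pid[high])]
        groups_l = [s[low & (pid == p)] for p in pd.unique(pid[low])]
    boots = np.empty(n_boot)
    nh, nl = len(groups_h), len(groups_l)
    for b in range(n_boot):
        sh = np.concatenate([groups_h[i] for i in rng.integers(0, nh, nh)])
        sl = np.concatenate([groups_l[i] for i in rng.integers(0, nl, nl)])
        boots[b] = _auc(sh, sl)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(auc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# multiple sampling


@dataclass
class DiscoveryConfig:
    """Knobs of the multiple-sampling procedure (defaults are the
    modelled study's: 1000 iterations, 2/3 stratified subsampling,
    top 75 genes, three averaged ranking metrics)."""

    n_iterations: int = 1000
    subsample_fraction: float = 2.0 / 3.0
    top_k: int = 75
    metrics: tuple[str, ...] = _METRICS
    seed: int = 0
    n_boot: int = 2000
    max_redraws: int = 100
    #: Newton iterations of the per-gene Cox ranker inside the sampling
    #: loop; ranks are insensitive beyond a few steps
    cox_newton_iter: int = 3


@dataclass
class MultipleSamplingResult:
    """Averaged gene ranking plus pooled out-of-fold predictions."""

    avg_rank: pd.Series  # averaged combined rank per gene (lower = better)
    per_metric_avg_rank: pd.DataFrame
    pooled: pd.DataFrame  # columns: iteration, sample_id, label, risk_score
    auc: float
    auc_ci: tuple[float, float] | None
    config: DiscoveryConfig

    def top_genes(self, k: int) -> list[str]:
        order = self.avg_rank.sort_values(kind="stable")
        return order.index[:k].tolist()


def _stratified_draw(
    rng: np.random.Generator, high: np.ndarray, frac: float
) -> np.ndarray:
    """Boolean training mask drawing ~frac of each class (>=2, < class size)."""
    mask = np.zeros(len(high), dtype=bool)
    for cls_mask in (high, ~high):
        idx = np.flatnonzero(cls_mask)
        k = int(round(frac * len(idx)))
        k = min(max(k, 2), len(idx) - 1)
        mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def multiple_sampling(
    expr: ExpressionStudy,
    labels: pd.Series,
    time: pd.Series,
    event: pd.Series,
    config: DiscoveryConfig | None = None,
) -> MultipleSamplingResult:
    """Run the multiple-sampling discovery loop on the training cohort.

    Only high/low labeled samples take part.  Each iteration draws a
    stratified ``subsample_fraction`` of each class, ranks all genes per
    metric on the draw, averages the per-metric ranks into a combined
    rank, fits a nearest-mean model on the top ``top_k`` genes and scores
    the held-out samples; held-out risk scores are pooled across
    iterations and summarized as one combined AUC.  Degenerate draws
    (a class with < 2 training or 0 held-out samples) are redrawn, never
    silently accepted.
    """
    config = config or DiscoveryConfig()
    lab = labels[labels.isin(["high", "low"])]
    samples = [s for s in lab.index if s in expr.samples]
    if len(samples) < len(lab):
        missing = sorted(set(lab.index) - set(expr.samples))
        raise KeyError(f"labeled samples missing from expression matrix: {missing[:10]}")
    X = np.ascontiguousarray(expr.values[samples].to_numpy())
    high = (lab.loc[samples] == "high").to_numpy()
    tt = time.loc[samples].to_numpy(dtype=float)
    ee = event.loc[samples].to_numpy(dtype=int)
    if high.sum() < 3 or (~high).sum() < 3:
        raise ValueError("need at least 3 labeled samples per class")
    n_genes = X.shape[0]
    rng = np.random.default_rng(config.seed)

    rank_sum = np.zeros(n_genes)
    metric_rank_sum = {m: np.zeros(n_genes) for m in config.metrics}
    pooled_scores: list[np.ndarray] = []
    pooled_idx: list[np.ndarray] = []
    pooled_iter: list[np.ndarray] = []

    for it in range(config.n_iterations):
        for attempt in range(config.max_redraws):
            train = _stratified_draw(rng, high, config.subsample_fraction)
            held = ~train
            if (
                high[train].sum() >= 2
                and (~high)[train].sum() >= 2
                and held.sum() >= 1
                and ee[train].sum() >= 1
            ):
                break
            logger.info("iteration %d: degenerate draw, redrawing (attempt %d)", it, attempt + 1)
        else:
            raise RuntimeError("could not draw a non-degenerate training subsample")

        Xt = X[:, train]
        combined = np.zeros(n_genes)
        for m in config.metrics:
            scores = _metric_scores(
                m, Xt, high[train], tt[train], ee[train], cox_iter=config.cox_newton_iter
            )
            r = _ranks_desc_abs(scores)
            metric_rank_sum[m] += r
            combined += r
        combined /= len(config.metrics)
        rank_sum += combined
        top = np.lexsort((np.arange(n_genes), combined))[: config.top_k]

        model = NearestMeanModel.fit(
            Xt[top], high[train], [expr.genes[i] for i in top]
        )
        # predict the held-out third with the iteration's model
        gene_rows = [i for i, g in zip(top, [expr.genes[j] for j in top]) if g in model.genes]
        raw = model._scores_from_block(X[np.ix_(np.array(gene_rows), np.flatnonzero(held))])
        pooled_scores.append(-raw)  # risk orientation
        pooled_idx.append(np.flatnonzero(held))
        pooled_iter.append(np.full(held.sum(), it))

    sample_arr = np.asarray(samples)
    idx = np.concatenate(pooled_idx)
    pooled = pd.DataFrame(
        {
            "iteration": np.concatenate(pooled_iter),
            "sample_id": sample_arr[idx],
            "label": np.where(high[idx], "high", "low"),
            "risk_score": np.concatenate(pooled_scores),
        }
    )
    auc, ci = combined_auc(
        pooled["risk_score"],
        pooled["label"],
        patient_ids=pooled["sample_id"],
        n_boot=config.n_boot,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return MultipleSamplingResult(
        avg_rank=pd.Series(rank_sum / config.n_iterations, index=expr.genes, name="avg_rank"),
        per_metric_avg_rank=pd.DataFrame(
            {m: v / config.n_iterations for m, v in metric_rank_sum.items()}, index=expr.genes
        ),
        pooled=pooled,
        auc=auc,
        auc_ci=ci,
        config=config,
    )


# ---------------------------------------------------------------------------
# forward selection


@dataclass
class Signature:
    """The selected prognostic signature: ordered genes and the fitted
    nearest-mean model (trained on the full labeled training set)."""

    genes: list[str]
    model: NearestMeanModel
    loocv_accuracy: float
    accuracy_curve: pd.DataFrame  # columns: size, accuracy

    @property
    def size(self) -> int:
        return len(self.genes)


def _loocv_curve(X: np.ndarray, high: np.ndarray, max_size: int) -> np.ndarray:
    """LOOCV accuracy of nearest-mean for every prefix size 1..max_size.

    X rows are genes ordered by the averaged ranking.  Uses prefix sums
    over the gene axis so all sizes come out of one pass per left-out
    sample.
    """
    n = X.shape[1]
    acc = np.zeros((max_size, n), dtype=bool)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if high[tr].sum() == 0 or (~high)[tr].sum() == 0:
            continue
        mu = X[:, tr].mean(axis=1)
        sd = X[:, tr].std(axis=1, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu[:, None]) / sd[:, None]
        ch = Z[:, tr & high].mean(axis=1)
        cl = Z[:, tr & ~high].mean(axis=1)
        z = Z[:, i]
        # prefix-sum Pearson correlations for every signature size
        k = np.arange(1, max_size + 1, dtype=float)
        sz, sh_, sl_ = z.cumsum(), ch.cumsum(), cl.cumsum()
        szz, shh, sll = (z * z).cumsum(), (ch * ch).cumsum(), (cl * cl).cumsum()
        szh, szl = (z * ch).cumsum(), (z * cl).cumsum()
        with np.errstate(divide="ignore", invalid="ignore"):
            num_h = k * szh - sz * sh_
            num_l = k * szl - sz * sl_
            den_h = np.sqrt((k * szz - sz**2) * (k * shh - sh_**2))
            den_l = np.sqrt((k * szz - sz**2) * (k * sll - sl_**2))
            risk = np.where(den_h > 0, num_h / den_h, 0.0) - np.where(
                den_l > 0, num_l / den_l, 0.0
            )
        # size 1: correlation undefined; use signed standardized distance
        risk[0] = np.abs(z[0] - cl[0]) - np.abs(z[0] - ch[0])
        pred_high = risk >= 0
        acc[:, i] = pred_high == high[i]
    return acc.mean(axis=1)


def forward_select(
    expr: ExpressionStudy,
    labels: pd.Series,
    avg_rank: pd.Series,
    max_size: int = 75,
) -> Signature:
    """Select the signature size with the best training LOOCV accuracy.

    Genes enter in order of the averaged ranking (best first); for each
    prefix size the nearest-mean LOOCV accuracy over the labeled training
    samples is computed, and the smallest size attaining the maximum is
    selected.  The returned model is refitted on the full labeled
    training set at the selected size.
    """
    lab = labels[labels.isin(["high", "low"])]
    samples = [s for s in lab.index if s in expr.samples]
    order = avg_rank.sort_values(kind="stable").index.tolist()
    max_size = min(max_size, len(order))
    genes = order[:max_size]
    X = expr.values.loc[genes, samples].to_numpy()
    high = (lab.loc[samples] == "high").to_numpy()
    curve = _loocv_curve(X, high, max_size)
    best = int(np.argmax(curve))  # argmax takes the first (smallest) maximizer
    selected = genes[: best + 1]
    model = NearestMeanModel.fit(X[: best + 1], high, selected)
    return Signature(
        genes=selected,
        model=model,
        loocv_accuracy=float(curve[best]),
        accuracy_curve=pd.DataFrame(
            {"size": np.arange(1, max_size + 1), "accuracy": curve}
        ),
    )


# ---------------------------------------------------------------------------
# independent validation


@dataclass
class ValidationReport:
    predictions: pd.DataFrame  # indexed by sample id: score, risk_score, predicted
    logrank: surv.LogRankResult | None
    km_curves: dict  # predicted class -> KM frame
    metrics: dict  # dichotomous classification metrics vs the rule labels
    note: str = ""


def validate_signature(
    model: NearestMeanModel,
    expr_validation: ExpressionStudy,
    clinical_validation: pd.DataFrame,
    training_ids,
    rule: RiskStratification | None = None,
) -> ValidationReport:
    """Apply a frozen signature to never-seen patients and test DFS.

    Every validation sample is predicted (including patients that would
    be unlabelable under the discovery rule); Kaplan-Meier curves and the
    Mantel-Cox log-rank test (with Cox HR) compare DFS between the
    predicted classes.  Any overlap between training and validation ids
    is a hard error.
    """
    overlap = sorted(set(training_ids) & set(expr_validation.samples))
    if overlap:
        raise ValueError(f"training/validation overlap: {overlap[:10]}")
    preds = model.predict_expr(expr_validation)
    clin = clinical_validation.set_index("patient_id").loc[preds.index]
    note = ""
    logrank = None
    km = {}
    classes = preds["predicted"]
    if classes.nunique() == 2 and clin["event"].sum() >= 1:
        logrank = surv.logrank_test(
            clin["dfs_months"], clin["event"], classes.to_numpy()
        )
        for c in ("high", "low"):
            m = (classes == c).to_numpy()
            km[c] = surv.km_estimate(clin.loc[m, "dfs_months"], clin.loc[m, "event"])
    else:
        note = "all validation patients predicted into one class; no survival comparison"
    truth = stratify_risk(clinical_validation, rule).reindex(preds.index)
    metrics = surv.classification_metrics(classes.to_numpy(), truth.to_numpy())
    return ValidationReport(
        predictions=preds, logrank=logrank, km_curves=km, metrics=metrics, note=note
    )


def discover_signature(
    expr_train: ExpressionStudy,
    clinical_train: pd.DataFrame,
    rule: RiskStratification | None = None,
    config: DiscoveryConfig | None = None,
    max_size: int | None = None,
) -> tuple[MultipleSamplingResult, Signature, pd.Series]:
    """Full training-set discovery: stratify, multiple-sample, select.

    Returns the multiple-sampling result, the selected signature and the
    training risk labels.
    """
    config = config or DiscoveryConfig()
    labels = stratify_risk(clinical_train, rule)
    clin = clinical_train.set_index("patient_id")
    time = clin["dfs_months"]
    event = clin["event"]
    ms = multiple_sampling(expr_train, labels, time, event, config)
    sig = forward_select(
        expr_train, labels, ms.avg_rank, max_size=max_size or config.top_k
    )
    return ms, sig, labels
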