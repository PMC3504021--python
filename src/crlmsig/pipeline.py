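"""End-to-end orchestration of the discovery/validation study designs.

A run reproduces one experimental arm of a two-centre signature study:
split the cohort into training and validation sets, optionally filter by
centre or neoadjuvant-treatment status (or balance the treatment mix
across risk classes), run the multiple-sampling discovery plus forward
selection on the training set, and validate the frozen signature on the
untouched validation set.  Every run writes plain-text reports and a
manifest with the seeds, configuration and input checksums, so a run is
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionStudy
from .discovery import (
    DiscoveryConfig,
    RiskStratification,
    Signature,
    discover_signature,
    stratify_risk,
    validate_signature,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "split_cohort", "balance_treatment"]


@dataclass
class RunConfig:
    """One experimental design.

    ``center`` filters the cohort to one centre ('all', 'A', 'B');
    ``treatment`` to treated / untreated patients, or 'bias-balanced' to
    equalize the neoadjuvant-treated fraction between the high and low
    risk classes of the training set by down-sampling the majority
    treatment stratum within each class.  ``train_size``/``val_size``
    give the random split (seeded); explicit id lists override it.
    """

    rule: RiskStratification = field(default_factory=RiskStratification)
    train_size: int = 75
    val_size: int = 44
    train_ids: list[str] | None = None
    val_ids: list[str] | None = None
    center: str = "all"  # {"all", "A", "B"}
    treatment: str = "all"  # {"all", "treated", "untreated", "bias-balanced"}
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    split_seed: int = 0
    max_signature_size: int | None = None


@dataclass
class RunReport:
    signature: Signature
    auc: float
    auc_ci: tuple[float, float] | None
    avg_rank: pd.Series
    pooled_scores: pd.DataFrame  # out-of-fold scores pooled over iterations
    validation: object  # ValidationReport
    train_ids: list[str]
    val_ids: list[str]
    removed_for_balance: list[str]
    manifest: dict


def split_cohort(
    ids, train_size: int, val_size: int, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded random split into disjoint training / validation id lists."""
    ids = list(ids)
    if train_size + val_size > len(ids):
        raise ValueError(
            f"split sizes {train_size}+{val_size} exceed cohort size {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in perm[:train_size]]
    val = [ids[i] for i in perm[train_size : train_size + val_size]]
    return train, val


def balance_treatment(
    clinical: pd.DataFrame, labels: pd.Series, seed: int
) -> list[str]:
    """Ids to drop so treated/untreated are 1:1 within each risk class.

    Within each labeled risk class the majority neoadjuvant stratum is
    down-sampled (seeded) to the minority's size, so the treated fraction
    is equal between classes afterwards.  Returns the removed ids.
    """
    rng = np.random.default_rng(seed)
    clin = clinical.set_index("patient_id")
    removed: list[str] = []
    for cls in ("high", "low"):
        ids = labels.index[labels == cls]
        neo = clin.loc[ids, "neoadjuvant"]
        t_ids = list(neo.index[neo == 1])
        u_ids = list(neo.index[neo == 0])
        big, small = (t_ids, u_ids) if len(t_ids) > len(u_ids) else (u_ids, t_ids)
        n_drop = len(big) - len(small)
        if n_drop > 0:
            removed.extend(
                sorted(np.asarray(big)[rng.choice(len(big), n_drop, replace=False)])
            )
    return removed


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()


def run_pipeline(
    config: RunConfig, clinical: pd.DataFrame, expression: ExpressionStudy
) -> RunReport:
    """Execute one design end to end; see the module docstring."""
    ids = clinical["patient_id"].tolist()
    missing = sorted(set(expression.samples) - set(ids))
    extra = sorted(set(ids) - set(expression.samples))
    if missing or extra:
        raise ValueError(
            f"clinical/expression id mismatch; expression-only: {missing[:10]}, "
            f"clinical-only: {extra[:10]}"
        )
    clin = clinical.copy()
    if config.center != "all":
        clin = clin[clin["center"] == config.center]
    if config.treatment in ("treated", "untreated"):
        want = 1 if config.treatment == "treated" else 0
        clin = clin[clin["neoadjuvant"] == want]
    if clin.empty:
        raise ValueError("no patients left after filtering")
    ids = clin["patient_id"].tolist()

    if config.train_ids is not None and config.val_ids is not None:
        train_ids, val_ids = list(config.train_ids), list(config.val_ids)
        if set(train_ids) & set(val_ids):
            raise ValueError("explicit train/validation id lists overlap")
    else:
        tsize = min(config.train_size, len(ids) - 1)
        vsize = min(config.val_size, len(ids) - tsize)
        train_ids, val_ids = split_cohort(ids, tsize, vsize, config.split_seed)

    clin_train = clin[clin["patient_id"].isin(train_ids)]
    clin_val = clin[clin["patient_id"].isin(val_ids)]

    removed: list[str] = []
    if config.treatment == "bias-balanced":
        labels0 = stratify_risk(clin_train, config.rule)
        labeled = labels0[labels0.isin(["high", "low"])]
        removed = balance_treatment(clin_train, labeled, config.split_seed)
        clin_train = clin_train[~clin_train["patient_id"].isin(removed)]
        train_ids = clin_train["patient_id"].tolist()

    expr_train = expression.subset_samples(clin_train["patient_id"].tolist())
    expr_val = expression.subset_samples(clin_val["patient_id"].tolist())

    ms, sig, labels = discover_signature(
        expr_train,
        clin_train,
        rule=config.rule,
        config=config.discovery,
        max_size=config.max_signature_size,
    )
    report = validate_signature(
        sig.model, expr_val, clin_val, training_ids=train_ids, rule=config.rule
    )
    manifest = {
        "config": _config_dict(config),
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "n_labeled_train": int(labels.isin(["high", "low"]).sum()),
        "removed_for_balance": removed,
        "train_ids": sorted(train_ids),
        "val_ids": sorted(val_ids),
        "checksums": {
            "clinical": _checksum(clinical),
            "expression": _checksum(expression.values),
            "avg_rank": _checksum(ms.avg_rank.to_frame()),
            "signature": hashlib.sha256("|".join(sig.genes).encode()).hexdigest(),
        },
        "signature_size": sig.size,
        "loocv_accuracy": sig.loocv_accuracy,
        "combined_auc": ms.auc,
        "combined_auc_ci": ms.auc_ci,
        "validation_logrank_p": (
            report.logrank.p_value if report.logrank is not None else None
        ),
        "validation_hr": (
            report.logrank.hazard_ratio if report.logrank is not None else None
        ),
    }
    return RunReport(
        signature=sig,
        auc=ms.auc,
        auc_ci=ms.auc_ci,
        avg_rank=ms.avg_rank,
        pooled_scores=ms.pooled,
        validation=report,
        train_ids=train_ids,
        val_ids=val_ids,
        removed_for_balance=removed,
        manifest=manifest,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_report(report: RunReport, outdir) -> None:
    """Write the run's plain-text outputs: signature gene list (TSV),
    accuracy curve (CSV), pooled-score summary, validation KM curves and
    the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(report.signature.genes, name="gene_id").to_csv(
        out / "signature_genes.tsv", sep="\t", index=False
    )
    report.signature.accuracy_curve.to_csv(out / "accuracy_curve.csv", index=False)
    report.avg_rank.sort_values().to_csv(out / "averaged_ranking.csv")
    report.pooled_scores.to_csv(out / "pooled_scores.csv", index=False)
    report.validation.predictions.to_csv(out / "validation_predictions.csv")
    for cls, km in report.validation.km_curves.items():
        km.to_csv(out / f"km_validation_{cls}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, default=str)
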