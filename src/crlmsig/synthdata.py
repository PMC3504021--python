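"""Synthetic CRLM cohort generator.

Emulates the statistical structure of a two-centre colorectal
liver-metastasis resection study: ~119 patients, ~20,000 genes measured
as log2 ratios against a common reference, disease-free survival (DFS)
with censoring, an optional planted prognostic signature, a
neoadjuvant-chemotherapy expression shift affecting hundreds of genes,
a centre batch effect, and sample-QC annotations.

Survival model
--------------
Each patient carries a latent risk score r ~ N(0,1).  Event (recurrence)
times are exponential with log-rate linear in r; the baseline rate is
solved numerically so that the realized cohort's expected one-year event
fraction equals ``event_rate_1yr``.  Censoring times are exponential with
a rate solved so that the expected censoring fraction equals
``censor_rate`` (P(C < T) = mu / (mu + lambda) for independent
exponentials).  Planted signature genes shift by ``signature_effect``
(log2 units, split symmetrically around zero with random per-gene sign)
between patients *destined* for early recurrence (true event time within
one year) and the rest, so a nonzero effect makes expression informative
about DFS; with ``signature_effect = 0`` expression carries no outcome
information.

The neoadjuvant-treatment confound of such cohorts (treated patients are
overrepresented among early recurrences) is reproduced by making the
treatment probability increase with r, and treated patients' expression
shifts by ``treatment_effect_size`` in ``treatment_effect_genes`` genes.

All randomness flows from ``CohortSpec.seed`` through one generator; two
calls with the same spec are identical byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import ClinicalRecord, ExpressionStudy, QcAnnotation, records_to_frame

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "baseline_margins",
    "build_exclusion_manifest",
    "make_dye_swap_pair",
]

#: hazard slope on the latent risk score (log-hazard units per SD of r)
LATENT_HAZARD_SLOPE = 1.0
#: how strongly neoadjuvant-treatment probability rises with latent risk
TREATMENT_CONFOUND_SLOPE = 0.8


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults reflect the study design this package models: 119 patients
    from two centres, 20,000 genes, ~60% of patients recurring within one
    year, and (by default) no true expression signature — the null
    condition.  ``signature_effect`` is the log2-units expression
    difference between patients destined for early versus late recurrence;
    ``treatment_effect_size`` the log2 shift induced by neoadjuvant
    chemotherapy in ``treatment_effect_genes`` genes (hundreds in the
    modelled study).
    """

    n_patients: int = 119
    n_genes: int = 20000
    frac_center_a: float = 0.5
    event_rate_1yr: float = 0.6
    signature_genes: int = 0
    signature_effect: float = 0.0
    treatment_effect_genes: int = 875
    treatment_effect_size: float = 0.5
    center_batch_sd: float = 0.1
    noise_sd: float = 1.0
    censor_rate: float = 0.25
    seed: int = 0
    #: when nonzero, signature and treatment gene sets may overlap
    overlap_gene_sets: bool = False
    #: extra log-hazard per point of the Fong clinical risk score,
    #: letting DFS be driven by clinical factors (0 = off)
    fong_hazard_per_point: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients: need at least 2 patients")
        if self.n_genes < 1:
            raise ValueError("n_genes: need at least 1 gene")
        for name in ("frac_center_a", "event_rate_1yr", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: fraction must lie in [0,1], got {v}")
        if not 0.0 < self.event_rate_1yr < 1.0:
            raise ValueError(
                f"event_rate_1yr: must lie strictly in (0,1), got {self.event_rate_1yr}"
            )
        if self.censor_rate >= 1.0:
            raise ValueError("censor_rate: must be < 1")
        if self.signature_genes < 0:
            raise ValueError("signature_genes: must be >= 0")
        if self.treatment_effect_genes < 0:
            raise ValueError("treatment_effect_genes: must be >= 0")
        if not self.overlap_gene_sets and (
            self.signature_genes + self.treatment_effect_genes > self.n_genes
        ):
            raise ValueError(
                "signature_genes: signature_genes + treatment_effect_genes "
                f"({self.signature_genes} + {self.treatment_effect_genes}) "
                f"exceeds n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd: must be > 0, got {self.noise_sd}")
        if self.center_batch_sd < 0:
            raise ValueError("center_batch_sd: must be >= 0")


def _fong_points(df: pd.DataFrame) -> np.ndarray:
    """Fong clinical-risk-score points (1 each): node-positive primary,
    disease-free interval < 12 months, > 1 metastasis, largest > 5 cm,
    preoperative CEA > 200 ng/ml."""
    pts = (
        (df["nodal_status"] == "positive").astype(int)
        + (df["interval_to_metastasis"] < 12).astype(int)
        + (df["n_metastases"] > 1).astype(int)
        + (df["largest_metastasis_cm"] > 5).astype(int)
        + (df["preop_cea"] > 200).astype(int)
    )
    return pts.to_numpy(dtype=float)


def _solve_baseline_rate(eta: np.ndarray, event_rate_1yr: float) -> float:
    """Baseline exponential rate so the realized cohort's mean one-year
    event probability equals event_rate_1yr."""
    rel = np.exp(eta)

    def gap(log_lam0: float) -> float:
        lam = np.exp(log_lam0) * rel
        return float(np.mean(1.0 - np.exp(-12.0 * lam))) - event_rate_1yr

    return float(np.exp(brentq(gap, -25.0, 10.0, xtol=1e-12)))


def _solve_censor_rate(lam: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate mu with E[mu/(mu+lambda)] = censor_rate."""
    if censor_rate <= 0.0:
        return 0.0

    def gap(log_mu: float) -> float:
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + lam))) - censor_rate

    return float(np.exp(brentq(gap, -30.0, 15.0, xtol=1e-12)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinicopathological covariates with marginals close to the modelled
    cohort (64.7% male, mean age 61, 74.8% colon primaries, ~49%
    synchronous metastases, mean 2.6 metastases of ~5 cm, ...)."""
    df = pd.DataFrame(index=range(n))
    df["patient_id"] = [f"P{i + 1:03d}" for i in range(n)]
    df["sex"] = np.where(rng.random(n) < 0.647, "male", "female")
    df["age"] = np.round(np.clip(rng.normal(61.4, 11.4, n), 25, 90), 1)
    df["primary_site"] = np.where(rng.random(n) < 0.748, "colon", "rectum")
    df["differentiation"] = rng.choice(
        ["good", "moderate", "poor"], size=n, p=[0.134, 0.723, 0.143]
    )
    df["primary_stage"] = rng.choice([1, 2, 3, 4], size=n, p=[0.08, 0.22, 0.45, 0.25])
    df["nodal_status"] = rng.choice(
        ["positive", "negative", "missing"], size=n, p=[0.555, 0.336, 0.109]
    )
    synchronous = rng.random(n) < 0.487
    df["interval_to_metastasis"] = np.round(
        np.where(synchronous, rng.uniform(0.0, 2.0, n), rng.uniform(2.5, 48.0, n)), 1
    )
    df["n_metastases"] = 1 + rng.poisson(1.6, n)
    df["largest_metastasis_cm"] = np.round(np.clip(rng.lognormal(1.45, 0.55, n), 0.5, 20), 1)
    df["distribution"] = np.where(rng.random(n) < 0.42, "bilobar", "unilobar")
    df["preop_cea"] = np.round(np.clip(rng.lognormal(3.0, 1.6, n), 0.5, 2000), 1)
    df["resection_extent"] = np.where(
        df["largest_metastasis_cm"] + rng.normal(0, 2.0, n) > 5.5, "major", "minor"
    )
    df["margin"] = np.where(rng.random(n) < 0.75, "R0", "R1")
    # hepatoduodenal nodal status was not recorded in the modelled study
    df["hepatoduodenal_nodes"] = "unknown"
    return df


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ClinicalRecord], ExpressionStudy, list[QcAnnotation]]:
    """Generate one synthetic cohort: clinical records, expression, QC.

    See the module docstring for the generative model.  Reproducible:
    identical spec (including seed) yields identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_patients, spec.n_genes

    clin = _draw_clinical(rng, n)
    clin["center"] = np.where(rng.random(n) < spec.frac_center_a, "A", "B")

    # latent risk and treatment assignment (confounded with risk)
    r = rng.normal(0.0, 1.0, n)
    p_neo = _sigmoid(np.log(0.54 / 0.46) + TREATMENT_CONFOUND_SLOPE * r)
    clin["neoadjuvant"] = (rng.random(n) < p_neo).astype(int)
    p_adj = _sigmoid(np.log(0.57 / 0.43) - 0.6 * r)
    clin["adjuvant"] = (rng.random(n) < p_adj).astype(int)

    eta = LATENT_HAZARD_SLOPE * r
    if spec.fong_hazard_per_point != 0.0:
        fong = _fong_points(clin)
        eta = eta + spec.fong_hazard_per_point * (fong - fong.mean())

    lam0 = _solve_baseline_rate(eta, spec.event_rate_1yr)
    lam = lam0 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    mu = _solve_censor_rate(lam, spec.censor_rate)
    t_cens = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
    dfs = np.minimum(t_event, t_cens)
    clin["event"] = (t_event <= t_cens).astype(int)
    clin["dfs_months"] = np.maximum(np.round(dfs, 1), 0.1)

    # expression: planted signature + treatment shift + centre batch + noise
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    sig_idx = np.arange(spec.signature_genes)
    if spec.overlap_gene_sets:
        trt_idx = rng.choice(g, size=spec.treatment_effect_genes, replace=False)
    else:
        trt_idx = np.arange(spec.signature_genes, spec.signature_genes + spec.treatment_effect_genes)
    expr = rng.normal(0.0, spec.noise_sd, size=(g, n))
    if spec.signature_genes > 0 and spec.signature_effect != 0.0:
        sig_dir = rng.choice([-1.0, 1.0], size=spec.signature_genes)
        # shift between the destiny classes (true event time within one
        # year vs later), symmetric around zero
        destiny = np.where(t_event <= 12.0, 0.5, -0.5)
        expr[sig_idx] += np.outer(sig_dir * spec.signature_effect, destiny)
    trt_dir = rng.choice([-1.0, 1.0], size=spec.treatment_effect_genes)
    treated = clin["neoadjuvant"].to_numpy() == 1
    if spec.treatment_effect_genes > 0 and spec.treatment_effect_size != 0.0:
        expr[np.ix_(trt_idx, np.where(treated)[0])] += (
            trt_dir[:, None] * spec.treatment_effect_size
        )
    if spec.center_batch_sd > 0:
        batch = rng.normal(0.0, spec.center_batch_sd, g)
        in_b = clin["center"].to_numpy() == "B"
        expr[:, in_b] += batch[:, None]

    study = ExpressionStudy(
        pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=clin["patient_id"])
    )

    qc = [
        QcAnnotation(
            sample_id=pid,
            rin=round(float(v[0]), 2),
            crna_yield_ng=round(float(v[1]), 0),
            median_fragment_nt=round(float(v[2]), 0),
            cy_incorporation_pct=round(float(v[3]), 2),
            amplification_failed=False,
        )
        for pid, v in zip(
            clin["patient_id"],
            np.column_stack(
                [
                    rng.uniform(6.5, 9.5, n),
                    rng.uniform(2500, 8000, n),
                    rng.uniform(600, 1500, n),
                    rng.uniform(1.6, 2.9, n),
                ]
            ),
        )
    ]

    from .cohort import CLINICAL_COLUMNS, frame_to_records

    records = frame_to_records(clin[CLINICAL_COLUMNS])
    # attach planted truth as metadata on the study (not written to disk)
    study.planted_signature_genes = [gene_ids[i] for i in sig_idx]
    study.planted_treatment_genes = [gene_ids[i] for i in sorted(trt_idx)]
    study.latent_risk = pd.Series(r, index=clin["patient_id"].to_numpy())
    return records, study, qc


# ---------------------------------------------------------------------------
# cohort margins in the layout of a baseline (Table-1 style) summary

_MARGIN_VARS = {
    "sex": ["male", "female"],
    "primary_site": ["rectum", "colon"],
    "differentiation": ["good", "moderate", "poor"],
    "nodal_status": ["positive", "negative", "missing"],
    "neoadjuvant": [1, 0],
    "adjuvant": [1, 0],
    "resection_extent": ["minor", "major"],
    "margin": ["R0", "R1"],
    "distribution": ["bilobar", "unilobar"],
}


def baseline_margins(records) -> pd.DataFrame:
    """High-risk/low-risk x category contingency counts.

    Patients are dichotomized on DFS <= 12 months (the one-year rule that
    every patient satisfies on one side, mirroring how baseline tables
    split a full cohort).  Empty category levels are reported as 0, not
    dropped.  Returns rows (variable, level, high, low, total) with a
    leading total-patients row.
    """
    if not records:
        raise ValueError("baseline_margins requires a nonempty cohort")
    df = records_to_frame(records)
    high = df["dfs_months"] <= 12.0
    rows = [
        {
            "variable": "total",
            "level": "",
            "high": int(high.sum()),
            "low": int((~high).sum()),
            "total": len(df),
        }
    ]
    for var, levels in _MARGIN_VARS.items():
        for lev in levels:
            m = df[var] == lev
            rows.append(
                {
                    "variable": var,
                    "level": str(lev),
                    "high": int((m & high).sum()),
                    "low": int((m & ~high).sum()),
                    "total": int(m.sum()),
                }
            )
    syn = df["interval_to_metastasis"] <= 2.0
    for name, m in [("synchronous", syn), ("metachronous", ~syn)]:
        rows.append(
            {
                "variable": "interval_to_metastasis",
                "level": name,
                "high": int((m & high).sum()),
                "low": int((m & ~high).sum()),
                "total": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC-failure manifests

def build_exclusion_manifest(
    n_total: int = 148,
    n_rin_yield_fail: int = 13,
    n_amplification_fail: int = 8,
    n_labeling_fail: int = 8,
    seed: int = 0,
) -> list[QcAnnotation]:
    """A sample manifest with disjoint planted QC failures.

    Defaults reproduce the exclusion cascade of the modelled study:
    148 profiled samples of which 13 fail RIN/yield, 8 fail amplification
    and 8 fail labelling, leaving 119.
    """
    if n_rin_yield_fail + n_amplification_fail + n_labeling_fail > n_total:
        raise ValueError("more planted failures than samples")
    rng = np.random.default_rng(seed)
    out = []
    k_rin = n_rin_yield_fail
    k_amp = k_rin + n_amplification_fail
    k_lab = k_amp + n_labeling_fail
    for i in range(n_total):
        a = QcAnnotation(
            sample_id=f"S{i + 1:03d}",
            rin=round(float(rng.uniform(6.5, 9.5)), 2),
            crna_yield_ng=round(float(rng.uniform(2500, 8000)), 0),
            median_fragment_nt=round(float(rng.uniform(600, 1500)), 0),
            cy_incorporation_pct=round(float(rng.uniform(1.6, 2.9)), 2),
            amplification_failed=False,
        )
        if i < k_rin:
            a.rin = round(float(rng.uniform(2.0, 5.9)), 2)
        elif i < k_amp:
            a.amplification_failed = True
        elif i < k_lab:
            a.cy_incorporation_pct = round(float(rng.uniform(0.2, 1.4)), 2)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# raw two-channel arrays (for exercising the preprocessing stage)

def make_dye_swap_pair(
    signal: pd.Series,
    dye_bias: pd.Series | float = 0.3,
    *,
    sample_id: str = "S001",
    n_printtip_groups: int = 8,
    n_control_spots: int = 0,
    intensity_trend: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Build a dye-swap pair of raw two-channel arrays from known truth.

    ``signal`` is the per-gene biological log2 ratio (sample over
    reference); ``dye_bias`` the per-gene (or scalar) log2 dye bias, which
    does not change sign under the swap.  ``intensity_trend`` adds an
    M-vs-A curvature of that slope to exercise loess normalization.
    Returns ``(array_cy5_sample, array_cy3_sample)``.
    """
    from .preprocess import TwoChannelArray

    rng = np.random.default_rng(seed)
    genes = signal.index.to_numpy()
    ng = len(genes)
    bias = (
        dye_bias.to_numpy()
        if isinstance(dye_bias, pd.Series)
        else np.full(ng, float(dye_bias))
    )
    abundance = rng.uniform(7.0, 13.0, ng)

    def build(orientation: str, array_id: str) -> TwoChannelArray:
        s = signal.to_numpy() if orientation == "sample_cy5" else -signal.to_numpy()
        m = s + bias + intensity_trend * (abundance - abundance.mean())
        m = m + rng.normal(0.0, noise_sd, ng) if noise_sd > 0 else m
        ch1 = np.power(2.0, abundance + m / 2.0)
        ch2 = np.power(2.0, abundance - m / 2.0)
        spots = pd.DataFrame(
            {
                "spot_id": [f"{array_id}_sp{i}" for i in range(ng)],
                "gene_id": genes,
                "printtip_group": np.arange(ng) % n_printtip_groups,
                "intensity_ch1": ch1,
                "intensity_ch2": ch2,
                "control_flag": 0,
            }
        )
        if n_control_spots:
            ctrl_a = rng.uniform(7.0, 13.0, n_control_spots)
            ctrl = pd.DataFrame(
                {
                    "spot_id": [f"{array_id}_ctl{i}" for i in range(n_control_spots)],
                    "gene_id": [f"CTRL{i}" for i in range(n_control_spots)],
                    "printtip_group": np.arange(n_control_spots) % n_printtip_groups,
                    "intensity_ch1": np.power(2.0, ctrl_a),
                    "intensity_ch2": np.power(2.0, ctrl_a),
                    "control_flag": 1,
                }
            )
            spots = pd.concat([spots, ctrl], ignore_index=True)
        return TwoChannelArray(
            array_id=array_id,
            sample_id=sample_id,
            dye_orientation=orientation,
            spots=spots,
        )

    return (
        build("sample_cy5", f"{sample_id}_a1"),
        build("sample_cy3", f"{sample_id}_a2"),
    )


def write_cohort(outdir, records, study: ExpressionStudy, qc) -> dict:
    """Write a cohort to plain-text files; returns the file paths."""
    from .cohort import qc_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.csv",
        "qc": outdir / "qc.csv",
    }
    study.to_tsv(paths["expression"])
    records_to_frame(records).to_csv(paths["clinical"], index=False)
    qc_to_frame(qc).to_csv(paths["qc"], index=False)
    return {k: str(v) for k, v in paths.items()}
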