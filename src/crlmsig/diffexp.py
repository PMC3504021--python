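"""Differential expression between neoadjuvant-treated and untreated
patients via fixed-effects ANOVA with a global residual-permutation F-test.

The model works on channel-level log2 intensities of a two-colour
common-reference design.  Per gene:

    y = mu + array + dye + treatment + residual

where every channel observation carries an array id, a dye (cy5/cy3) and
a treatment level ('reference' for reference channels, 'treated' /
'untreated' for patient channels).  The treated-vs-untreated term is
tested with a hybrid F statistic whose denominator averages the
gene-specific residual mean square with the mean square pooled across
genes (weight configurable), stabilizing the per-gene variance estimate.

The null distribution is built by globally permuting residuals: one
shared permutation of the reduced-model residual rows is applied to all
genes per shuffle, which preserves the inter-gene correlation of the
null statistics.  p = (1 + #{F* >= F}) / (1 + n_perm), so p is never 0
and finite-sample valid.  Benjamini-Hochberg is applied across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import bh_adjust

__all__ = ["DiffexpDesign", "DiffexpResult", "permutation_f_test", "make_synthetic_design"]

OBS_COLUMNS = ["obs_id", "sample_id", "array_id", "dye", "treatment"]


@dataclass
class DiffexpDesign:
    """Channel-level observations plus the genes x observations matrix.

    ``obs`` has one row per channel with columns obs_id, sample_id,
    array_id, dye ('cy5'/'cy3') and treatment ('reference', 'treated',
    'untreated'); ``values`` is indexed by gene id with one column per
    obs_id, holding log2 intensities.
    """

    obs: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.obs.columns]
        if missing:
            raise ValueError(f"obs table missing columns: {missing}")
        if list(self.values.columns) != list(self.obs["obs_id"]):
            self.values = self.values[list(self.obs["obs_id"])]
        bad = set(self.obs["treatment"]) - {"reference", "treated", "untreated"}
        if bad:
            raise ValueError(f"unknown treatment levels: {sorted(bad)}")


@dataclass
class DiffexpResult:
    """Per-gene treatment test: F statistic, permutation p, BH-adjusted p,
    and the direction of change in treated patients."""

    table: pd.DataFrame  # index gene, columns F, p, p_adjusted, direction
    n_perm: int
    df_residual: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < alpha]


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series, drop_first=True).to_numpy(dtype=float)


def _design_matrices(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full and reduced model matrices plus the treated-minus-untreated
    indicator used to sign the effect."""
    n = len(obs)
    intercept = np.ones((n, 1))
    arr = _dummies(obs["array_id"])
    dye = _dummies(obs["dye"])
    is_patient = (obs["treatment"] != "reference").to_numpy(dtype=float)
    is_treated = (obs["treatment"] == "treated").to_numpy(dtype=float)
    x_reduced = np.hstack([intercept, arr, dye, is_patient[:, None]])
    x_full = np.hstack([x_reduced, is_treated[:, None]])
    contrast = is_treated - (obs["treatment"] == "untreated").to_numpy(dtype=float)
    return x_full, x_reduced, contrast


def _orth_bases(x_full: np.ndarray, x_reduced: np.ndarray):
    """Orthonormal bases: reduced column space, the 1-df treatment
    increment, and the full-model residual space."""
    n = x_full.shape[0]
    u_f, s_f, _ = np.linalg.svd(x_full, full_matrices=True)
    rank_f = int(np.sum(s_f > s_f[0] * 1e-10))
    u_r, s_r, _ = np.linalg.svd(x_reduced, full_matrices=False)
    rank_r = int(np.sum(s_r > s_r[0] * 1e-10))
    df1 = rank_f - rank_r
    if df1 < 1:
        raise ValueError(
            "treatment term is aliased with the array/dye design "
            "(confounded layout); cannot test it"
        )
    q_r = u_r[:, :rank_r]
    q_f = u_f[:, :rank_f]
    q_res = u_f[:, rank_f:]
    # treatment direction: full space minus its reduced-space component
    b = q_f - q_r @ (q_r.T @ q_f)
    ub, sb, _ = np.linalg.svd(b, full_matrices=False)
    u_t = ub[:, :df1]
    return q_r, u_t, q_res, df1, n - rank_f


def permutation_f_test(
    design: DiffexpDesign,
    n_perm: int = 5000,
    seed: int = 0,
    shrinkage_weight: float = 0.5,
    global_shuffle: bool = True,
) -> DiffexpResult:
    """Treatment F-test with a globally permuted null.

    ``shrinkage_weight`` w sets the denominator w * pooled-MSE +
    (1 - w) * gene-MSE (w = 0.5 averages the two).  With
    ``global_shuffle`` one shared residual permutation is applied to all
    genes per shuffle (the default); ``False`` permutes each gene
    independently.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    obs = design.obs
    counts = obs["treatment"].value_counts()
    for grp in ("treated", "untreated"):
        if counts.get(grp, 0) < 2:
            raise ValueError(f"need at least 2 observations in group {grp!r}")
    x_full, x_reduced, contrast = _design_matrices(obs)
    q_r, u_t, q_res, df1, df_res = _orth_bases(x_full, x_reduced)
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")

    y = design.values.to_numpy(dtype=float).T  # obs x genes
    genes = design.values.index
    fit_r = q_r @ (q_r.T @ y)
    resid_r = y - fit_r

    def f_stats(w_t: np.ndarray, w_res: np.ndarray) -> np.ndarray:
        ss_t = (w_t**2).sum(axis=0)
        rss = (w_res**2).sum(axis=0)
        # squash float-rounding residue so a constant gene is exactly null
        ss_t[ss_t < 1e-16] = 0.0
        rss[rss < 1e-16] = 0.0
        mse = rss / df_res
        pooled = mse.mean()
        den = shrinkage_weight * pooled + (1.0 - shrinkage_weight) * mse
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_t / df1) / den
        return np.where(den > 0, f, np.where(ss_t > 0, np.inf, 0.0))

    f_obs = f_stats(u_t.T @ y, q_res.T @ y)
    # effect sign: project the treated-vs-untreated contrast onto the
    # treatment direction (df1 = 1 in the two-group design)
    alpha = float(u_t[:, 0] @ contrast) if df1 == 1 else 1.0
    effect = (u_t[:, 0] @ y) * np.sign(alpha) if df1 == 1 else np.full(len(genes), np.nan)
    direction = np.where(effect > 0, "up", np.where(effect < 0, "down", "none"))

    rng = np.random.default_rng(seed)
    p_basis = np.hstack([u_t, q_res])  # (n_obs, df1 + df_res)
    count = np.ones(len(genes))  # the +1 correction
    n_obs = y.shape[0]
    for _ in range(n_perm):
        if global_shuffle:
            perm = rng.permutation(n_obs)
            w = p_basis[perm].T @ resid_r
        else:
            r_perm = np.empty_like(resid_r)
            for j in range(resid_r.shape[1]):
                r_perm[:, j] = resid_r[rng.permutation(n_obs), j]
            w = p_basis.T @ r_perm
        f_perm = f_stats(w[:df1], w[df1:])
        count += f_perm >= f_obs
    p = count / (1.0 + n_perm)
    table = pd.DataFrame(
        {"F": f_obs, "p": p, "p_adjusted": bh_adjust(p), "direction": direction},
        index=genes,
    )
    return DiffexpResult(table=table, n_perm=n_perm, df_residual=df_res)


def make_synthetic_design(
    n_samples: int = 20,
    n_genes: int = 2000,
    frac_treated: float = 0.5,
    effect_genes: int = 0,
    effect_size: float = 0.0,
    noise_sd: float = 0.5,
    array_effect_sd: float = 0.3,
    dye_effect: float = 0.2,
    seed: int = 0,
) -> DiffexpDesign:
    """Synthetic dye-swap common-reference design for the treatment test.

    Each sample is hybridized on two dye-swap arrays (4 channel
    observations per sample).  The first ``effect_genes`` genes shift by
    ``effect_size`` (alternating sign) in the patient channels of treated
    samples.  Residual noise is iid — the assumption of the fixed-effects
    model; real cohorts add biological replicate variance this generator
    deliberately omits.
    """
    rng = np.random.default_rng(seed)
    n_treated = int(round(frac_treated * n_samples))
    treated = np.array([i < n_treated for i in range(n_samples)])
    rows = []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        for rep, orient in enumerate(("sample_cy5", "sample_cy3")):
            aid = f"{sid}_a{rep + 1}"
            sample_dye = "cy5" if orient == "sample_cy5" else "cy3"
            ref_dye = "cy3" if orient == "sample_cy5" else "cy5"
            rows.append((f"{aid}_{sample_dye}", sid, aid, sample_dye,
                         "treated" if treated[i] else "untreated"))
            rows.append((f"{aid}_{ref_dye}", "reference", aid, ref_dye, "reference"))
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    n_obs = len(obs)
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.uniform(8.0, 12.0, n_genes)
    arrays = obs["array_id"].unique()
    arr_eff = dict(zip(arrays, rng.normal(0.0, array_effect_sd, len(arrays))))
    y = (
        base[:, None]
        + np.array([arr_eff[a] for a in obs["array_id"]])[None, :]
        + np.where(obs["dye"].to_numpy() == "cy5", dye_effect / 2, -dye_effect / 2)[None, :]
        + rng.normal(0.0, noise_sd, (n_genes, n_obs))
    )
    if effect_genes and effect_size:
        sign = np.where(np.arange(effect_genes) % 2 == 0, 1.0, -1.0)
        is_treated_chan = (obs["treatment"] == "treated").to_numpy()
        y[:effect_genes, is_treated_chan] += sign[:, None] * effect_size
    values = pd.DataFrame(y, index=gene_ids, columns=obs["obs_id"])
    return DiffexpDesign(obs=obs, values=values)
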