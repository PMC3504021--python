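"""Two-channel microarray preprocessing and sample QC.

Covers the standard two-colour pipeline: print-tip loess normalization of
log-ratios against mean spot intensity, dye-swap merging with per-gene
dye-bias correction, and the sample-exclusion cascade (RIN/yield ->
amplification -> labelling).

Conventions: channel 1 is Cy5, channel 2 is Cy3.  M = log2(ch1/ch2) is
kept in *dye orientation*, so the biological signal changes sign between
the two arrays of a dye-swap pair while the dye bias does not; the merge
step separates the two components exactly and returns the
sample-over-reference signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import QcAnnotation

__all__ = [
    "TwoChannelArray",
    "NormalizedProfile",
    "QcThresholds",
    "printtip_loess_normalize",
    "correct_dye_bias_and_merge",
    "qc_filter_samples",
    "read_spot_table",
]

SPOT_COLUMNS = [
    "spot_id",
    "gene_id",
    "printtip_group",
    "intensity_ch1",
    "intensity_ch2",
    "control_flag",
]

#: minimum usable spots per print-tip group before falling back to a
#: global (non-tip) loess fit
MIN_TIP_SPOTS = 20


@dataclass
class TwoChannelArray:
    """One hybridized two-colour array (sample vs common reference)."""

    array_id: str
    sample_id: str
    dye_orientation: str  # {"sample_cy5", "sample_cy3"}
    spots: pd.DataFrame  # SPOT_COLUMNS

    def __post_init__(self) -> None:
        if self.dye_orientation not in ("sample_cy5", "sample_cy3"):
            raise ValueError(f"unknown dye_orientation {self.dye_orientation!r}")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")


@dataclass
class NormalizedProfile:
    """Per-gene normalized values for one array (or a merged dye-swap pair).

    ``data`` is indexed by gene id with columns ``M`` (log2 ratio, in dye
    orientation for a single array, sample-over-reference after merging)
    and ``A`` (mean log2 intensity).
    """

    sample_id: str
    dye_orientation: str  # {"sample_cy5", "sample_cy3", "merged"}
    data: pd.DataFrame
    array_id: str | None = None

    @property
    def M(self) -> pd.Series:
        return self.data["M"]

    @property
    def A(self) -> pd.Series:
        return self.data["A"]


def _loess_fit(m: np.ndarray, a: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 locally weighted regression of M on A (tricube weights,
    3 robustness iterations), evaluated at the input points."""
    return sm.nonparametric.lowess(
        m, a, frac=span, it=3, return_sorted=False, is_sorted=False
    )


def printtip_loess_normalize(array: TwoChannelArray, span: float = 0.4) -> NormalizedProfile:
    """Print-tip loess normalization of one two-channel array.

    Within each print-tip group the loess fit of M on A is subtracted from
    M, removing intensity-dependent dye bias separately per spotting pin.
    Control spots are excluded from the fit and from the output.  Groups
    with fewer than ``MIN_TIP_SPOTS`` usable spots fall back to a global
    loess fit over all non-control spots (with a warning).  Spots mapping
    to the same gene are averaged after normalization.
    """
    spots = array.spots
    if (spots[["intensity_ch1", "intensity_ch2"]] <= 0).any().any():
        raise ValueError(f"array {array.array_id}: nonpositive spot intensity")
    work = spots[spots["control_flag"] == 0].copy()
    if work.empty:
        raise ValueError(f"array {array.array_id}: no non-control spots")
    m = np.log2(work["intensity_ch1"].to_numpy() / work["intensity_ch2"].to_numpy())
    a = 0.5 * np.log2(
        work["intensity_ch1"].to_numpy() * work["intensity_ch2"].to_numpy()
    )
    fitted = np.empty_like(m)
    global_fit = None
    for tip, idx in work.groupby("printtip_group").indices.items():
        if len(idx) >= MIN_TIP_SPOTS:
            fitted[idx] = _loess_fit(m[idx], a[idx], span)
        else:
            warnings.warn(
                f"array {array.array_id}: print-tip group {tip} has "
                f"{len(idx)} usable spots (< {MIN_TIP_SPOTS}); "
                "falling back to global loess"
            )
            if global_fit is None:
                global_fit = _loess_fit(m, a, span)
            fitted[idx] = global_fit[idx]
    work["M"] = m - fitted
    work["A"] = a
    per_gene = work.groupby("gene_id")[["M", "A"]].mean()
    if not np.all(np.isfinite(per_gene["M"].to_numpy())):
        raise ValueError(f"array {array.array_id}: non-finite normalized M values")
    return NormalizedProfile(
        sample_id=array.sample_id,
        dye_orientation=array.dye_orientation,
        data=per_gene,
        array_id=array.array_id,
    )


def correct_dye_bias_and_merge(
    profile_a: NormalizedProfile, profile_b: NormalizedProfile
) -> tuple[NormalizedProfile, pd.Series]:
    """Merge a dye-swap pair, separating biological signal from dye bias.

    With M kept in dye orientation, the swap flips the sign of the
    biological signal s but not of the per-gene dye bias b:
    M_cy5sample = s + b and M_cy3sample = -s + b.  Hence
    b = (M1 + M2) / 2 (the component that does not change sign) and the
    orientation-corrected merged signal is s = +/-(M1 - M2)/2.  Returns
    the merged sample-over-reference profile and the dye-bias series.
    """
    if profile_a.dye_orientation == profile_b.dye_orientation:
        raise ValueError(
            "dye-swap pair must have opposite orientations, both are "
            f"{profile_a.dye_orientation!r}"
        )
    ga, gb = set(profile_a.data.index), set(profile_b.data.index)
    if ga != gb:
        diff = sorted(ga.symmetric_difference(gb))
        raise ValueError(f"gene sets differ between swap profiles: {diff[:50]}")
    genes = profile_a.data.index
    m1 = profile_a.M
    m2 = profile_b.M.reindex(genes)
    bias = (m1 + m2) / 2.0
    sign = 1.0 if profile_a.dye_orientation == "sample_cy5" else -1.0
    signal = sign * (m1 - m2) / 2.0
    merged = pd.DataFrame(
        {"M": signal, "A": (profile_a.A + profile_b.A.reindex(genes)) / 2.0}, index=genes
    )
    out = NormalizedProfile(
        sample_id=profile_a.sample_id, dye_orientation="merged", data=merged
    )
    return out, bias.rename("dye_bias")


@dataclass
class QcThresholds:
    """Sample-inclusion gates (defaults follow common two-colour practice:
    RIN >= 6, cRNA yield >= 2000 ng, median fragment >= 500 nt, Cy
    incorporation between 1.5% and 3%)."""

    rin_min: float = 6.0
    crna_min_ng: float = 2000.0
    fragment_min_nt: float = 500.0
    cy_min_pct: float = 1.5
    cy_max_pct: float = 3.0


def qc_filter_samples(
    annotations: list[QcAnnotation], thresholds: QcThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the sample-exclusion cascade.

    Stages are applied in order — RIN/yield, amplification, labelling —
    and each excluded sample is attributed to the *first* failing stage.
    Returns the kept sample ids (input order) and a per-sample report with
    columns ``sample_id``, ``kept``, ``reason`` (empty when kept).
    """
    th = thresholds or QcThresholds()
    rows = []
    kept: list[str] = []
    for a in annotations:
        reason = ""
        if a.rin < th.rin_min or a.crna_yield_ng < th.crna_min_ng:
            reason = "rin_yield"
        elif a.amplification_failed:
            reason = "amplification"
        elif (
            a.median_fragment_nt < th.fragment_min_nt
            or not (th.cy_min_pct <= a.cy_incorporation_pct <= th.cy_max_pct)
        ):
            reason = "labeling"
        if not reason:
            kept.append(a.sample_id)
        rows.append({"sample_id": a.sample_id, "kept": not reason, "reason": reason})
    return kept, pd.DataFrame(rows)


def exclusion_counts(report: pd.DataFrame) -> dict:
    """Per-reason exclusion counts plus the kept count."""
    out = {"kept": int(report["kept"].sum())}
    for reason in ("rin_yield", "amplification", "labeling"):
        out[reason] = int((report["reason"] == reason).sum())
    return out


def read_spot_table(path, array_id: str, sample_id: str, dye_orientation: str) -> TwoChannelArray:
    """Read a tab-separated spot table into a TwoChannelArray."""
    spots = pd.read_csv(path, sep="\t")
    return TwoChannelArray(
        array_id=array_id, sample_id=sample_id, dye_orientation=dye_orientation, spots=spots
    )
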