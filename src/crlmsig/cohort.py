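"""Core data containers: patient records, expression matrices, sample QC.

The package works on cohorts of patients who underwent resection of
colorectal liver metastases (CRLM).  Each patient carries the
clinicopathological covariates used by the clinical risk scores, a
disease-free survival (DFS) time in months and a recurrence-event flag.
Expression data are log2 ratios of tumour RNA against a common reference,
genes in rows and samples in columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ClinicalRecord",
    "ExpressionStudy",
    "QcAnnotation",
    "CLINICAL_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "qc_to_frame",
    "frame_to_qc",
]


@dataclass
class ClinicalRecord:
    """One patient of a CRLM resection cohort.

    ``dfs_months`` is the time from liver resection to the first
    radiological sign of recurrence; ``event`` is 1 when recurrence was
    observed and 0 when the patient was censored (death or last follow-up).
    ``interval_to_metastasis`` is the time in months between diagnosis of
    the primary tumour and of the liver metastasis; a metastasis is called
    synchronous when this interval is at most two months.
    """

    patient_id: str
    center: str  # {"A", "B"}
    sex: str  # {"male", "female"}
    age: float
    primary_site: str  # {"colon", "rectum"}
    differentiation: str  # {"good", "moderate", "poor"}
    primary_stage: int  # TNM stage group 1-4
    nodal_status: str  # {"positive", "negative", "missing"}
    interval_to_metastasis: float  # months
    n_metastases: int
    largest_metastasis_cm: float
    distribution: str  # {"unilobar", "bilobar"}
    preop_cea: float  # ng/ml
    neoadjuvant: int  # 0/1
    adjuvant: int  # 0/1
    resection_extent: str  # {"minor", "major"}
    margin: str  # {"R0", "R1"}
    hepatoduodenal_nodes: str  # {"positive", "negative", "unknown"}
    dfs_months: float
    event: int

    def __post_init__(self) -> None:
        if self.dfs_months < 0:
            raise ValueError(
                f"dfs_months must be >= 0, got {self.dfs_months} "
                f"for patient {self.patient_id}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")

    @property
    def synchronous(self) -> bool:
        """Metastasis diagnosed within two months of the primary."""
        return self.interval_to_metastasis <= 2.0


CLINICAL_COLUMNS = [f.name for f in dataclasses.fields(ClinicalRecord)]


@dataclass
class QcAnnotation:
    """Sample-level wet-lab quality metrics gating inclusion.

    Mirrors the acceptance cascade of a two-colour profiling study: RNA
    integrity (RIN) and cRNA yield, amplification success, and labelling
    quality (fragment length, fluorophore incorporation).
    """

    sample_id: str
    rin: float
    crna_yield_ng: float
    median_fragment_nt: float
    cy_incorporation_pct: float
    amplification_failed: bool = False

    def __post_init__(self) -> None:
        for name in ("rin", "crna_yield_ng", "median_fragment_nt", "cy_incorporation_pct"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


QC_COLUMNS = [f.name for f in dataclasses.fields(QcAnnotation)]


class ExpressionStudy:
    """Gene x sample matrix of log2 expression ratios versus a common reference.

    Orientation is fixed package-wide: genes in rows, samples in columns.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        self.values = values.astype(float)
        self.values.index.name = "gene_id"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing}")
        return ExpressionStudy(self.values.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionStudy":
        return ExpressionStudy(self.values.loc[list(gene_ids)])

    def to_tsv(self, path) -> None:
        """Tab-separated text: first column gene id, header row of sample ids."""
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionStudy":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionStudy({self.shape[0]} genes x {self.shape[1]} samples)"


def records_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df[CLINICAL_COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(ClinicalRecord(**{k: d[k] for k in CLINICAL_COLUMNS}))
    return out


def qc_to_frame(annotations: Iterable[QcAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(a) for a in annotations])[QC_COLUMNS]


def frame_to_qc(df: pd.DataFrame) -> list[QcAnnotation]:
    return [
        QcAnnotation(**{k: row._asdict()[k] for k in QC_COLUMNS})
        for row in df.itertuples(index=False)
    ]
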