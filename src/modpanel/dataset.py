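"""Expression dataset container: genes x samples matrix plus sample sheet.

One dataset holds one cohort on one platform. ``counts`` datasets carry
normalized counts (sequencing-like cohorts; values >= 0); ``intensity``
datasets carry background-subtracted, normalized intensities
(microarray-like cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PLATFORMS = ("counts", "intensity")

SAMPLE_COLUMNS = ["sample_id", "subject_id", "timepoint", "cohort", "platform"]


class DatasetError(ValueError):
    """Raised when an expression matrix or sample sheet violates the contract."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression values with per-sample annotations.

    ``matrix`` is indexed by gene id with sample ids as columns; ``samples``
    is indexed by sample id and carries subject_id, timepoint, cohort and
    platform. All samples of one dataset share a cohort and platform.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    normalization: str = "unspecified"

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.samples.index):
            # allow sheet in any order as long as the sets match
            if set(self.matrix.columns) != set(self.samples.index):
                raise DatasetError("sample sheet and matrix columns disagree")
            self.samples = self.samples.loc[list(self.matrix.columns)]
        for col in ("subject_id", "timepoint", "cohort", "platform"):
            if col not in self.samples.columns:
                raise DatasetError(f"sample sheet lacks required column {col!r}")
        if self.samples["timepoint"].isna().any() or (self.samples["timepoint"] == "").any():
            raise DatasetError("missing timepoint labels in sample sheet")
        platforms = set(self.samples["platform"])
        if len(platforms) != 1 or platforms - set(PLATFORMS):
            raise DatasetError(f"dataset must have a single platform in {PLATFORMS}, got {platforms}")
        if len(set(self.samples["cohort"])) != 1:
            raise DatasetError("dataset must contain a single cohort")
        values = self.matrix.to_numpy()
        if not np.isfinite(values).all():
            raise DatasetError("expression matrix contains non-finite values")
        if self.platform == "counts" and (values < 0).any():
            raise DatasetError("counts platform values must be >= 0")

    @property
    def platform(self) -> str:
        return str(self.samples["platform"].iloc[0])

    @property
    def cohort(self) -> str:
        return str(self.samples["cohort"].iloc[0])

    @property
    def timepoints(self) -> list[str]:
        """Timepoint labels in sample-sheet order (first appearance)."""
        return list(dict.fromkeys(self.samples["timepoint"]))

    def samples_at(self, timepoint: str) -> list[str]:
        return list(self.samples.index[self.samples["timepoint"] == timepoint])

    def values_at(self, timepoint: str) -> pd.DataFrame:
        ids = self.samples_at(timepoint)
        if not ids:
            raise DatasetError(f"no samples at timepoint {timepoint!r}")
        return self.matrix[ids]


def load_dataset(expr_path: str | Path, samples_path: str | Path,
                 normalization: str = "unspecified") -> ExpressionDataset:
    """Read an expression TSV (first column gene id) and a sample-sheet TSV."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str).set_index("sample_id")
    return ExpressionDataset(matrix=matrix, samples=samples, normalization=normalization)


def save_dataset(ds: ExpressionDataset, expr_path: str | Path, samples_path: str | Path) -> None:
    ds.matrix.to_csv(expr_path, sep="\t", index_label="gene_id")
    ds.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
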