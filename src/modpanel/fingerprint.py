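"""Module-repertoire fingerprinting against a postpartum baseline.

The *module response* is the percentage of a module's constitutive genes
called differentially expressed versus the non-pregnant (postpartum)
reference, signed by direction: +100 means every constitutive transcript
increased, -100 every one decreased. Responses are computed either at the
group level (all samples of a timepoint tested against the reference
samples) or for a single sample (fixed fold-change and expression-difference
cut-offs against the per-gene reference mean).

Fingerprints are rendered on a fixed 2-D grid: one row per module aggregate,
one cell per module, red for up / blue for down, saturation proportional to
|response|, blank at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DatasetError, ExpressionDataset
from .repertoire import ModuleRepertoire, RepertoireError

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NULL = "null"


@dataclass(frozen=True)
class ResponseThresholds:
    """Differential-expression cut-offs.

    Group level: fold change of at least ``fc_group`` (or at most its
    reciprocal) and t-test p below ``p_group``. Individual level: fold
    change strictly above ``fc_indiv`` AND absolute expression difference
    strictly above ``diff_indiv`` (in the dataset's own normalized units).
    """

    fc_group: float = 1.5
    p_group: float = 0.1
    fc_indiv: float = 1.5
    diff_indiv: float = 10.0

    def __post_init__(self) -> None:
        if min(self.fc_group, self.fc_indiv, self.diff_indiv) <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.p_group < 1:
            raise ValueError("p_group must lie in (0, 1)")


@dataclass(frozen=True)
class BaselineSpec:
    """Per-gene reference: arithmetic mean over the reference-timepoint samples."""

    reference_timepoint: str
    reference_values: pd.Series
    n_reference_samples: int


def compute_baseline(ds: ExpressionDataset, reference_timepoint: str) -> BaselineSpec:
    """Average normalized expression of the reference (postpartum) samples, per gene."""
    ref = ds.values_at(reference_timepoint)
    return BaselineSpec(
        reference_timepoint=reference_timepoint,
        reference_values=ref.mean(axis=1),
        n_reference_samples=ref.shape[1],
    )


def _fold_change(test_mean: np.ndarray, ref_mean: np.ndarray, platform: str) -> tuple[np.ndarray, np.ndarray]:
    """FC on the linear normalized scale with a zero-denominator guard.

    Counts platform: a pseudocount of 1 is added to both means. Intensity
    platform: no pseudocount; non-positive reference means yield NaN FC and
    are flagged (the call becomes null).
    """
    if platform == "counts":
        return (test_mean + 1.0) / (ref_mean + 1.0), np.zeros(len(ref_mean), dtype=bool)
    flagged = ref_mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(flagged, np.nan, test_mean / ref_mean)
    if flagged.any():
        logger.warning("%d gene(s) with non-positive reference mean flagged null", int(flagged.sum()))
    return fc, flagged


def gene_de_group(ds: ExpressionDataset, baseline: BaselineSpec, timepoint: str,
                  thresholds: ResponseThresholds = ResponseThresholds(),
                  one_sample: bool = False, log_transform: bool = False,
                  bh_correct: bool = False) -> pd.DataFrame:
    """Group-level per-gene calls for one timepoint versus the reference.

    Default test: Welch two-sample t-test between the samples at ``timepoint``
    and the samples at the reference timepoint. ``one_sample=True`` instead
    tests the timepoint samples against the per-gene reference mean treated
    as a constant. ``log_transform`` runs the test on log2(x+1) values; fold
    changes stay on the linear normalized scale either way. ``bh_correct``
    applies a Benjamini-Hochberg adjustment across genes before the p gate
    (off by default: the stated cut-off on this path is a raw p < 0.1).

    Returns a DataFrame indexed by gene with columns fc, p, call.
    """
    test = ds.values_at(timepoint).to_numpy(dtype=float)
    if test.shape[1] < 2:
        raise DatasetError(f"need >=2 samples at {timepoint!r} for a t-statistic")
    ref_mean = baseline.reference_values.to_numpy(dtype=float)
    fc, flagged = _fold_change(test.mean(axis=1), ref_mean, ds.platform)

    t_test = np.log2(test + 1.0) if log_transform else test
    if one_sample:
        popmean = np.log2(ref_mean + 1.0) if log_transform else ref_mean
        p = stats.ttest_1samp(t_test, popmean, axis=1).pvalue
    else:
        ref = ds.values_at(baseline.reference_timepoint).to_numpy(dtype=float)
        t_ref = np.log2(ref + 1.0) if log_transform else ref
        p = stats.ttest_ind(t_test, t_ref, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    if bh_correct:
        p = _benjamini_hochberg(p)

    sig = p < thresholds.p_group
    call = np.full(len(fc), CALL_NULL, dtype=object)
    with np.errstate(invalid="ignore"):
        call[sig & (fc >= thresholds.fc_group)] = CALL_UP
        call[sig & (fc <= 1.0 / thresholds.fc_group)] = CALL_DOWN
    call[flagged | ~np.isfinite(fc)] = CALL_NULL
    return pd.DataFrame({"fc": fc, "p": p, "call": call}, index=ds.matrix.index)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def gene_de_individual(ds: ExpressionDataset, baseline: BaselineSpec, sample_id: str,
                       thresholds: ResponseThresholds = ResponseThresholds()) -> pd.DataFrame:
    """Single-sample per-gene calls: FC > fc_indiv AND DIFF > diff_indiv (conjunction).

    up: value/reference > fc_indiv and value - reference > diff_indiv;
    down symmetric. DIFF is measured in the dataset's normalized units.
    """
    if sample_id not in ds.matrix.columns:
        raise DatasetError(f"unknown sample {sample_id!r}")
    value = ds.matrix[sample_id].to_numpy(dtype=float)
    ref = baseline.reference_values.to_numpy(dtype=float)
    fc, flagged = _fold_change(value, ref, ds.platform)
    diff = value - ref
    call = np.full(len(value), CALL_NULL, dtype=object)
    with np.errstate(invalid="ignore"):
        call[(fc > thresholds.fc_indiv) & (diff > thresholds.diff_indiv)] = CALL_UP
        call[(fc < 1.0 / thresholds.fc_indiv) & (-diff > thresholds.diff_indiv)] = CALL_DOWN
    call[flagged | ~np.isfinite(fc)] = CALL_NULL
    return pd.DataFrame({"fc": fc, "diff": diff, "call": call}, index=ds.matrix.index)


def module_response(calls: pd.DataFrame, rep: ModuleRepertoire, module_id: str) -> dict:
    """Percent up / percent down / signed response for one module.

    ``response = pct_up - pct_down`` nets out mixed modules and reproduces
    the +/-100 endpoints (all up -> +100, all down -> -100). Constitutive
    genes absent from the call table count as null (logged).
    """
    genes = rep.genes_of(module_id)  # raises RepertoireError on unknown id
    present = [g for g in genes if g in calls.index]
    if len(present) < len(genes):
        logger.warning("module %s: %d constitutive gene(s) absent from call table, counted null",
                       module_id, len(genes) - len(present))
    sub = calls.loc[present, "call"]
    n = len(genes)
    pct_up = 100.0 * (sub == CALL_UP).sum() / n
    pct_down = 100.0 * (sub == CALL_DOWN).sum() / n
    return {
        "module_id": module_id,
        "aggregate_id": rep.aggregates[module_id],
        "n_genes": n,
        "pct_up": pct_up,
        "pct_down": pct_down,
        "response": pct_up - pct_down,
    }


def module_response_profile(calls: pd.DataFrame, rep: ModuleRepertoire) -> pd.DataFrame:
    """Module responses for every module of the repertoire, one row each."""
    rows = [module_response(calls, rep, mid) for mid in rep.modules]
    return pd.DataFrame(rows).set_index("module_id")


def fingerprint_profiles(ds: ExpressionDataset, rep: ModuleRepertoire,
                         reference_timepoint: str,
                         thresholds: ResponseThresholds = ResponseThresholds(),
                         timepoints: list[str] | None = None,
                         **de_kwargs) -> dict[str, pd.DataFrame]:
    """Group-level module response profile per non-reference timepoint."""
    baseline = compute_baseline(ds, reference_timepoint)
    tps = timepoints if timepoints is not None else [
        t for t in ds.timepoints if t != reference_timepoint]
    out: dict[str, pd.DataFrame] = {}
    for tp in tps:
        calls = gene_de_group(ds, baseline, tp, thresholds, **de_kwargs)
        out[tp] = module_response_profile(calls, rep)
    return out


@dataclass
class FingerprintGrid:
    """Fixed-layout grid of signed responses, ready for tabular or raster export."""

    table: pd.DataFrame = field(repr=False)  # module_id, row, col, response

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FingerprintGrid":
        return cls(table=pd.read_csv(path, sep="\t"))

    def to_png(self, path: str | Path, title: str = "") -> None:
        """Render red/blue cells at fixed positions, saturation = |response|/100."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_rows = int(self.table["row"].max()) + 1
        n_cols = int(self.table["col"].max()) + 1
        img = np.ones((n_rows, n_cols, 3))
        for _, r in self.table.iterrows():
            sat = abs(r["response"]) / 100.0
            base = np.array([1.0, 0.0, 0.0]) if r["response"] > 0 else np.array([0.0, 0.0, 1.0])
            if r["response"] != 0:
                img[int(r["row"]), int(r["col"])] = (1 - sat) + sat * base
        fig, ax = plt.subplots(figsize=(max(4, n_cols / 3), max(2, n_rows / 3)))
        ax.imshow(img, interpolation="nearest", aspect="equal")
        ax.set_xlabel("module position")
        ax.set_ylabel("aggregate")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def fingerprint_grid(profile: pd.DataFrame, rep: ModuleRepertoire) -> FingerprintGrid:
    """Place a module response profile onto the repertoire's fixed grid.

    A response of exactly 0 is a blank cell (kept in the table with value 0
    so the layout round-trips losslessly).
    """
    missing = [m for m in rep.modules if m not in profile.index]
    if missing:
        raise RepertoireError(f"profile does not cover module(s): {missing[:5]}")
    rows = [
        {"module_id": mid, "aggregate_id": rep.aggregates[mid],
         "row": rep.grid[mid][0], "col": rep.grid[mid][1],
         "response": float(profile.loc[mid, "response"])}
        for mid in rep.modules
    ]
    return FingerprintGrid(table=pd.DataFrame(rows))
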