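"""Staggered gene screening and panel assembly.

Candidate genes (the constitutive genes of the delineated module sets) pass
through three screens:

* **abundance** — genes whose median normalized count over all samples of
  the counts cohort is below 50 are excluded (the intensity cohort has no
  counts, so this screen runs on the counts cohort only);
* **correlation** — each gene's per-timepoint mean expression trajectory is
  correlated (Pearson) with the mean trajectory of its module set; genes
  with r < 0.5 or p > 0.05 in either cohort are excluded, and survivors get
  an *R score* = the average r over the two cohorts;
* **literature** — a pre-computed literature annotation gives 2 points for
  a title hit, 1 for an abstract-only hit, 0 otherwise.

The final score (literature + R) ranks survivors within each module set; at
most four genes represent a set. The panel is then supplemented up to its
target size (one representative per excluded aggregate, one per empty set,
extras from under-filled sets) and completed with housekeeping genes chosen
from a prior panel, by low coefficient of variation, and from literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .repertoire import ModuleRepertoire

logger = logging.getLogger(__name__)

FATE_SELECTED = "selected"
FATE_LOW_ABUNDANCE = "excluded_low_abundance"
FATE_LOW_CORRELATION = "excluded_low_correlation"
FATE_NOT_RANKED = "not_ranked"


@dataclass(frozen=True)
class GeneScreenConfig:
    """Thresholds and target sizes of the screening cascade."""

    min_median: float = 50.0       # abundance gate: median count < 50 excluded
    r_min: float = 0.5             # correlation gate (exclusion strictly below)
    p_max: float = 0.05            # correlation gate (exclusion strictly above)
    max_per_set: int = 4
    target_test_size: int = 176
    target_hk_size: int = 8
    relaxed_median_factor: float = 0.2  # supplement pool gate = factor * min_median


# ---------------------------------------------------------------------------
# screen 1: transcript abundance


def abundance_filter(ds_counts: ExpressionDataset, candidates: list[str],
                     min_median: float = 50.0) -> tuple[list[str], pd.DataFrame]:
    """Split candidates by median normalized count over all samples.

    Genes with median strictly below ``min_median`` are excluded (a median of
    exactly ``min_median`` passes). Candidates absent from the matrix are
    excluded with reason ``absent``.
    """
    if ds_counts.platform != "counts":
        raise ValueError("abundance screening requires the counts platform")
    medians = ds_counts.matrix.median(axis=1)
    passed: list[str] = []
    rows = []
    for g in candidates:
        if g not in medians.index:
            rows.append({"gene_id": g, "median_count": np.nan, "reason": "absent"})
            logger.warning("candidate %s absent from counts matrix, excluded", g)
        elif medians[g] < min_median:
            rows.append({"gene_id": g, "median_count": float(medians[g]),
                         "reason": f"median {medians[g]:g} < {min_median:g}"})
        else:
            passed.append(g)
    excluded = pd.DataFrame(rows, columns=["gene_id", "median_count", "reason"])
    return passed, excluded


def median_counts(ds_counts: ExpressionDataset, genes: list[str]) -> pd.Series:
    """Per-gene median over all samples; NaN for genes absent from the matrix."""
    med = ds_counts.matrix.median(axis=1)
    return pd.Series({g: float(med[g]) if g in med.index else np.nan for g in genes})


# ---------------------------------------------------------------------------
# screen 2: correlation with the module-set mean


def timepoint_mean_trajectory(ds: ExpressionDataset, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-timepoint mean expression across samples, genes x timepoints.

    Timepoints follow sample-sheet order and include the postpartum
    reference (the trajectory describes the whole study course).
    """
    cols = {tp: ds.values_at(tp).mean(axis=1) for tp in ds.timepoints}
    traj = pd.DataFrame(cols)
    return traj if genes is None else traj.reindex(genes)


def set_mean_correlation(traj: pd.DataFrame, gene: str, set_genes: list[str]) -> tuple[float, float]:
    """Pearson r (and two-sided p on n-2 df) between a gene and its set-mean trajectory.

    The gene itself is left out of the set mean to avoid self-correlation
    inflation. A zero-variance trajectory on either side yields (nan, nan).
    """
    others = [g for g in set_genes if g != gene and g in traj.index]
    if gene not in traj.index or not others:
        return float("nan"), float("nan")
    x = traj.loc[gene].to_numpy(dtype=float)
    m = traj.loc[others].mean(axis=0).to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(m) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, m)
    return float(r), float(p)


def r_score(r_by_cohort: dict[str, float]) -> float:
    """Average of the per-cohort Pearson r values (e.g. 0.8 and 0.6 -> 0.7).

    Requires an r for every cohort; genes failing the correlation gate in
    either cohort never reach this point.
    """
    if not r_by_cohort:
        raise ValueError("r_score requires at least one cohort")
    vals = list(r_by_cohort.values())
    if any(v is None or np.isnan(v) for v in vals):
        missing = [c for c, v in r_by_cohort.items() if v is None or np.isnan(v)]
        raise ValueError(f"missing r value for cohort(s): {missing}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# screen 3: literature annotation


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a literature annotation TSV (gene_id, title_hit, abstract_hit, provenance)."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("title_hit", "abstract_hit"):
        ann[col] = ann[col].astype(int).astype(bool)
    if "provenance" not in ann.columns:
        ann["provenance"] = ""
    return ann.set_index("gene_id")


def literature_score(annotations: pd.DataFrame, gene: str) -> int:
    """2 for a title hit, 1 for an abstract-only hit, 0 otherwise (or no row)."""
    if gene not in annotations.index:
        return 0
    row = annotations.loc[gene]
    if bool(row["title_hit"]):
        return 2
    if bool(row["abstract_hit"]):
        return 1
    return 0


# ---------------------------------------------------------------------------
# scoring cascade over all sets


def score_genes(ds_counts: ExpressionDataset, ds_intensity: ExpressionDataset,
                rep: ModuleRepertoire, set_modules: dict[str, list[str]],
                annotations: pd.DataFrame,
                cfg: GeneScreenConfig = GeneScreenConfig()) -> pd.DataFrame:
    """Run the full screening cascade; one audit row per (set, candidate gene).

    ``set_modules`` maps a set key (e.g. ``"A28/S1"``) to its member module
    ids. Every candidate ends with exactly one fate; selection fates are
    assigned afterwards by :func:`select_genes_per_set`.
    """
    traj_a = timepoint_mean_trajectory(ds_counts)
    traj_b = timepoint_mean_trajectory(ds_intensity)
    med = ds_counts.matrix.median(axis=1)
    rows: list[dict] = []
    for set_key, modules in set_modules.items():
        genes = rep.genes_of_modules(modules)
        for gene in genes:
            rec: dict = {
                "gene_id": gene, "set_key": set_key,
                "median_count": float(med[gene]) if gene in med.index else np.nan,
                "r_a": np.nan, "p_a": np.nan, "r_b": np.nan, "p_b": np.nan,
                "r_score": np.nan, "lit_score": np.nan, "final_score": np.nan,
            }
            if gene not in med.index or rec["median_count"] < cfg.min_median:
                rec["fate"] = FATE_LOW_ABUNDANCE
                rec["fate_reason"] = ("absent from counts matrix" if gene not in med.index
                                      else f"median {rec['median_count']:g} < {cfg.min_median:g}")
                rows.append(rec)
                continue
            r_a, p_a = set_mean_correlation(traj_a, gene, genes)
            r_b, p_b = set_mean_correlation(traj_b, gene, genes)
            rec.update(r_a=r_a, p_a=p_a, r_b=r_b, p_b=p_b)
            bad = []
            for label, r, p in (("a", r_a, p_a), ("b", r_b, p_b)):
                if np.isnan(r):
                    bad.append(f"cohort {label}: constant trajectory")
                elif r < cfg.r_min or p > cfg.p_max:
                    bad.append(f"cohort {label}: r={r:.3f}, p={p:.3g}")
            if bad:
                rec["fate"] = FATE_LOW_CORRELATION
                rec["fate_reason"] = "; ".join(bad)
                rows.append(rec)
                continue
            rec["r_score"] = r_score({"a": r_a, "b": r_b})
            rec["lit_score"] = literature_score(annotations, gene)
            rec["final_score"] = rec["lit_score"] + rec["r_score"]
            rec["fate"] = FATE_NOT_RANKED  # provisional until per-set selection
            rec["fate_reason"] = "survivor awaiting ranking"
            rows.append(rec)
    return pd.DataFrame(rows)


def select_genes_per_set(records: pd.DataFrame, max_per_set: int = 4) -> dict[str, list[str]]:
    """Pick up to ``max_per_set`` survivors per set by final score.

    Ordering: final score desc, then R score desc, then gene id. Sets with
    fewer survivors contribute all of them (flagged short in the records);
    sets with zero survivors are simply absent from the result. Mutates the
    ``fate``/``fate_reason`` columns of selected rows in place.
    """
    selections: dict[str, list[str]] = {}
    survivors = records[records["fate"].isin((FATE_NOT_RANKED, FATE_SELECTED))]
    for set_key, grp in survivors.groupby("set_key", sort=False):
        ranked = grp.sort_values(["final_score", "r_score", "gene_id"],
                                 ascending=[False, False, True], kind="mergesort")
        chosen = list(ranked["gene_id"].iloc[:max_per_set])
        selections[set_key] = chosen
        sel_mask = (records["set_key"] == set_key) & records["gene_id"].isin(chosen)
        records.loc[sel_mask, "fate"] = FATE_SELECTED
        records.loc[sel_mask, "fate_reason"] = f"top {max_per_set} of set by final score"
        if len(chosen) < max_per_set:
            logger.info("set %s is short: %d survivor(s) < cap %d", set_key, len(chosen), max_per_set)
    return selections


# ---------------------------------------------------------------------------
# panel assembly


@dataclass
class PanelDesign:
    """Final panel: per-set core genes, supplements, housekeeping."""

    core: dict[str, list[str]]                     # set key -> genes
    supplements: list[tuple[str, str]] = field(default_factory=list)  # (source, gene)
    housekeeping: list[tuple[str, str]] = field(default_factory=list)
    target_test_size: int = 176
    target_hk_size: int = 8

    @property
    def test_genes(self) -> list[str]:
        out = [g for genes in self.core.values() for g in genes]
        out += [g for _, g in self.supplements]
        return out

    @property
    def all_genes(self) -> list[str]:
        return self.test_genes + [g for _, g in self.housekeeping]

    def as_table(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "source": key, "role": "test"}
                for key, genes in self.core.items() for g in genes]
        rows += [{"gene_id": g, "source": src, "role": "test"} for src, g in self.supplements]
        rows += [{"gene_id": g, "source": src, "role": "housekeeping"} for src, g in self.housekeeping]
        return pd.DataFrame(rows, columns=["gene_id", "source", "role"])


class PanelAssemblyError(RuntimeError):
    """Raised when a panel cannot be filled to its target size."""


def _rank_supplement_pool(genes: list[str], med: pd.Series, annotations: pd.DataFrame,
                          relaxed_median: float, taken: set[str]) -> list[str]:
    """Supplement ranking: literature score desc, then median count desc, then gene id."""
    pool = [g for g in genes
            if g not in taken and g in med.index and med[g] >= relaxed_median]
    pool.sort(key=lambda g: (-literature_score(annotations, g), -float(med[g]), g))
    return pool


def supplement_panel(core: dict[str, list[str]],
                     excluded_aggregates: list[str],
                     empty_sets: list[str],
                     short_sets: dict[str, list[str]],
                     ds_counts: ExpressionDataset,
                     annotations: pd.DataFrame,
                     rep: ModuleRepertoire,
                     set_modules: dict[str, list[str]],
                     cfg: GeneScreenConfig = GeneScreenConfig()) -> PanelDesign:
    """Fill the panel to its target test size.

    Adds (i) one representative gene from each aggregate excluded by the
    response filter, (ii) one gene from each set where no gene qualified,
    then (iii) extra genes from under-filled sets until the target is
    reached. Supplements are drawn from genes passing a relaxed abundance
    gate, ranked by literature score then median count. ``short_sets`` maps
    set key -> remaining (unselected) genes of the set.
    """
    med = ds_counts.matrix.median(axis=1)
    relaxed = cfg.relaxed_median_factor * cfg.min_median
    design = PanelDesign(core={k: list(v) for k, v in core.items()},
                         target_test_size=cfg.target_test_size,
                         target_hk_size=cfg.target_hk_size)
    taken = set(design.test_genes)
    if len(taken) < len(design.test_genes):
        logger.warning("duplicate gene(s) across core sets collapsed in the panel")

    shortfalls: list[str] = []
    for agg in excluded_aggregates:
        pool = _rank_supplement_pool(rep.genes_of_modules(rep.modules_of(agg)),
                                     med, annotations, relaxed, taken)
        if not pool:
            shortfalls.append(f"aggregate {agg}")
            continue
        design.supplements.append((f"excluded_aggregate:{agg}", pool[0]))
        taken.add(pool[0])
    for set_key in empty_sets:
        pool = _rank_supplement_pool(rep.genes_of_modules(set_modules[set_key]),
                                     med, annotations, relaxed, taken)
        if not pool:
            shortfalls.append(f"empty set {set_key}")
            continue
        design.supplements.append((f"empty_set:{set_key}", pool[0]))
        taken.add(pool[0])
    if shortfalls:
        raise PanelAssemblyError("no eligible supplement gene for: " + ", ".join(shortfalls))

    if len(design.test_genes) > cfg.target_test_size:
        raise PanelAssemblyError(
            f"core + mandatory supplements ({len(design.test_genes)}) exceed target "
            f"{cfg.target_test_size}")

    # top up from under-filled sets, best-ranked extras first across all short sets
    extras: list[tuple[str, str]] = []
    for set_key, remaining in short_sets.items():
        for g in _rank_supplement_pool(remaining, med, annotations, relaxed, taken):
            extras.append((set_key, g))
    extras.sort(key=lambda t: (-literature_score(annotations, t[1]), -float(med[t[1]]), t[1]))
    for set_key, g in extras:
        if len(design.test_genes) >= cfg.target_test_size:
            break
        if g in taken:
            continue
        design.supplements.append((f"extra:{set_key}", g))
        taken.add(g)

    n = len(design.test_genes)
    if n != cfg.target_test_size:
        raise PanelAssemblyError(
            f"cannot reach target of {cfg.target_test_size} test genes: have {n} "
            f"(shortfall {cfg.target_test_size - n})")
    return design


def percent_cv(ds: ExpressionDataset, genes: list[str]) -> pd.Series:
    """Per-gene coefficient of variation, 100 * sd / mean, over all samples."""
    sub = ds.matrix.reindex(genes)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * sd / mean


def select_housekeeping(ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                        prior_panel: list[str], literature_hk: list[str],
                        n_total: int = 8, exclude: set[str] | None = None) -> list[tuple[str, str]]:
    """Choose housekeeping genes: 4 from a prior panel, 2 by low %CV, 2 from literature.

    Prior-panel genes are taken in the given order, restricted to genes
    present in both datasets. The low-CV pair minimizes the mean of the two
    per-dataset %CV values among genes present in both datasets and not
    already chosen (or on the ``exclude`` list, e.g. the test genes).
    """
    exclude = set(exclude or ())
    n_prior, n_cv, n_lit = 4, 2, n_total - 6
    present = [g for g in ds_a.matrix.index if g in ds_b.matrix.index]

    prior = [g for g in prior_panel if g in present and g not in exclude][:n_prior]
    if len(prior) < n_prior:
        raise PanelAssemblyError(
            f"prior panel supplies only {len(prior)} usable gene(s), need {n_prior}")
    chosen = [("prior_panel", g) for g in prior]
    used = set(prior) | exclude

    lit = [g for g in literature_hk if g not in used][:n_lit]
    if len(lit) < n_lit:
        raise PanelAssemblyError(
            f"literature housekeeping list supplies only {len(lit)} usable gene(s), need {n_lit}")
    used |= set(lit)

    cv_pool = [g for g in present if g not in used]
    if len(cv_pool) < n_cv:
        raise PanelAssemblyError("too few genes for the low-CV housekeeping slots")
    mean_cv = (percent_cv(ds_a, cv_pool) + percent_cv(ds_b, cv_pool)) / 2.0
    low_cv = list(mean_cv.sort_values(kind="mergesort").index[:n_cv])
    chosen += [("low_cv", g) for g in low_cv]
    chosen += [("literature", g) for g in lit]
    return chosen


def chip_capacity(n_chips: int = 2, wells_per_chip: int = 96, hk_wells: int = 8) -> int:
    """Test-gene slots on a multi-chip qPCR layout reserving housekeeping wells per chip.

    Two 96-assay microfluidic chips, each reserving 8 wells for the (shared)
    housekeeping genes, leave 2 x 88 = 176 slots for test genes.
    """
    if min(n_chips, wells_per_chip, hk_wells) < 0 or hk_wells >= wells_per_chip:
        raise ValueError("invalid chip layout")
    return n_chips * (wells_per_chip - hk_wells)
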