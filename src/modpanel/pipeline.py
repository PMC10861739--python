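"""End-to-end panel design: fingerprint -> delineate -> screen -> assemble.

The orchestration is config-driven and fully audited: every stage writes a
TSV of its decisions and the run report carries per-stage counts that must
satisfy the conservation identity (candidates = survivors + exclusions at
every stage). Outputs are pure functions of inputs + config, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import delineation as dl
from . import fingerprint as fp
from . import genes as gs
from .dataset import ExpressionDataset, load_dataset
from .genes import GeneScreenConfig, PanelDesign
from .repertoire import ModuleRepertoire, load_repertoire

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DelineationConfig:
    threshold: float = 10.0
    top_k: int = 10
    max_sets: int = 3
    cut_height: float = 0.5
    aggregate_rule: str = "any_module"
    singleton_rule: str = "first"


@dataclass
class CohortSpec:
    """Where one cohort's files live and how its timepoints are interpreted."""

    expr: str = ""
    samples: str = ""
    reference_timepoint: str = ""
    pregnancy_timepoints: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    """Validated top-level configuration for the end-to-end design run."""

    seed: int = 0
    out_dir: str = "modpanel_out"
    repertoire: dict[str, str] = field(default_factory=dict)   # gmt, meta
    cohort_a: CohortSpec = field(default_factory=CohortSpec)   # counts cohort
    cohort_b: CohortSpec = field(default_factory=CohortSpec)   # intensity cohort
    annotations: str = ""
    prior_hk: str = ""
    literature_hk: str = ""
    thresholds: fp.ResponseThresholds = field(default_factory=fp.ResponseThresholds)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    genes: GeneScreenConfig = field(default_factory=GeneScreenConfig)
    one_sample: bool = False
    log_transform: bool = False
    bh_correct: bool = False
    grids_png: bool = False


_SECTION_TYPES = {
    "thresholds": fp.ResponseThresholds,
    "delineation": DelineationConfig,
    "genes": GeneScreenConfig,
    "cohort_a": CohortSpec,
    "cohort_b": CohortSpec,
}


def load_config(path: str | Path, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys at every level.

    ``overrides`` maps dotted keys (``genes.min_median``) to replacement
    values, mirroring the CLI's ``--set`` option.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if key:
            raw.setdefault(section, {})[key] = value
        else:
            raw[section] = value
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            bad = set(value) - set(cls.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown key(s) in {key!r}: {sorted(bad)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


@dataclass
class DesignResult:
    """Everything the end-to-end run produced, for inspection or export."""

    panel: PanelDesign
    records: pd.DataFrame
    selections: dict[str, list[str]]
    set_modules: dict[str, list[str]]
    retained_aggregates: list[str]
    delineation: dl.DelineationResult
    profiles: dict[str, dict[str, pd.DataFrame]]  # cohort -> timepoint -> profile
    report: dict[str, Any]


def design_panel(rep: ModuleRepertoire,
                 ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                 annotations: pd.DataFrame,
                 prior_hk: list[str], literature_hk: list[str],
                 reference_a: str, reference_b: str,
                 pregnancy_a: list[str] | None = None,
                 pregnancy_b: list[str] | None = None,
                 thresholds: fp.ResponseThresholds = fp.ResponseThresholds(),
                 delineation_cfg: DelineationConfig = DelineationConfig(),
                 gene_cfg: GeneScreenConfig = GeneScreenConfig(),
                 **de_kwargs) -> DesignResult:
    """Run the full design chain in memory.

    ``ds_a`` must be the counts cohort (it drives the abundance screen and
    aggregate retention); ``ds_b`` the intensity cohort. Pregnancy
    timepoints default to every non-postpartum label before the reference.
    """
    if ds_a.platform != "counts":
        raise ValueError("cohort A must be the counts cohort")
    preg_a = pregnancy_a or [t for t in ds_a.timepoints if t != reference_a][:4]
    preg_b = pregnancy_b or [t for t in ds_b.timepoints if t != reference_b][:4]

    profiles_a = fp.fingerprint_profiles(ds_a, rep, reference_a, thresholds, **de_kwargs)
    profiles_b = fp.fingerprint_profiles(ds_b, rep, reference_b, thresholds, **de_kwargs)
    traj_a = dl.build_trajectories({t: profiles_a[t] for t in preg_a}, ds_a.cohort, preg_a)
    traj_b = dl.build_trajectories({t: profiles_b[t] for t in preg_b}, ds_b.cohort, preg_b)

    retained = dl.select_aggregates(traj_a, rep, threshold=delineation_cfg.threshold,
                                    rule=delineation_cfg.aggregate_rule)
    excluded_aggs = [a for a in rep.aggregate_order if a not in retained]
    delres = dl.delineate_all(traj_a, traj_b, rep, retained,
                              top_k=delineation_cfg.top_k,
                              threshold=delineation_cfg.threshold,
                              max_sets=delineation_cfg.max_sets,
                              cut_height=delineation_cfg.cut_height,
                              singleton_rule=delineation_cfg.singleton_rule)
    set_modules = {f"{agg}/{label}": list(mods)
                   for agg, assignment in delres.assignments.items()
                   for label, mods in assignment.sets}

    records = gs.score_genes(ds_a, ds_b, rep, set_modules, annotations, gene_cfg)
    selections = gs.select_genes_per_set(records, max_per_set=gene_cfg.max_per_set)
    empty_sets = [k for k in set_modules if not selections.get(k)]
    short_sets: dict[str, list[str]] = {}
    for key in set_modules:
        chosen = selections.get(key, [])
        if 0 < len(chosen) < gene_cfg.max_per_set:
            all_genes = rep.genes_of_modules(set_modules[key])
            short_sets[key] = [g for g in all_genes if g not in chosen]
    core = {k: v for k, v in selections.items() if v}

    panel = gs.supplement_panel(core, excluded_aggs, empty_sets, short_sets,
                                ds_a, annotations, rep, set_modules, gene_cfg)
    panel.housekeeping = gs.select_housekeeping(ds_a, ds_b, prior_hk, literature_hk,
                                                n_total=gene_cfg.target_hk_size,
                                                exclude=set(panel.test_genes))

    n_candidates = len(records)
    fates = records["fate"].value_counts().to_dict()
    n_low_ab = int(fates.get(gs.FATE_LOW_ABUNDANCE, 0))
    n_low_corr = int(fates.get(gs.FATE_LOW_CORRELATION, 0))
    n_selected = int(fates.get(gs.FATE_SELECTED, 0))
    n_not_ranked = int(fates.get(gs.FATE_NOT_RANKED, 0))
    n_survivors = n_selected + n_not_ranked
    supplements_by_source: dict[str, int] = {}
    for src, _ in panel.supplements:
        supplements_by_source[src.split(":")[0]] = supplements_by_source.get(src.split(":")[0], 0) + 1
    report: dict[str, Any] = {
        "n_aggregates": rep.n_aggregates,
        "n_retained_aggregates": len(retained),
        "n_excluded_aggregates": len(excluded_aggs),
        "n_sets": len(set_modules),
        "n_empty_sets": len(empty_sets),
        "n_short_sets": len(short_sets),
        "n_candidates": n_candidates,
        "n_excluded_low_abundance": n_low_ab,
        "pct_excluded_low_abundance": round(100.0 * n_low_ab / n_candidates, 1) if n_candidates else 0.0,
        "n_excluded_low_correlation": n_low_corr,
        "n_excluded_cumulative_after_correlation": n_low_ab + n_low_corr,
        "n_survivors": n_survivors,
        "n_core_selected": n_selected,
        "pct_eliminated": round(100.0 * (n_candidates - n_selected) / n_candidates, 1) if n_candidates else 0.0,
        "supplements_by_source": supplements_by_source,
        "n_supplements": len(panel.supplements),
        "n_test_genes": len(panel.test_genes),
        "n_housekeeping": len(panel.housekeeping),
        "n_panel_total": len(panel.all_genes),
        "conservation_ok": n_candidates == n_low_ab + n_low_corr + n_selected + n_not_ranked,
    }
    return DesignResult(panel=panel, records=records, selections=selections,
                        set_modules=set_modules, retained_aggregates=retained,
                        delineation=delres,
                        profiles={ds_a.cohort: profiles_a, ds_b.cohort: profiles_b},
                        report=report)


def write_outputs(result: DesignResult, rep: ModuleRepertoire, out_dir: str | Path,
                  grids_png: bool = False) -> None:
    """Write panel, audit records, set table, fingerprint grids and the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.panel.as_table().to_csv(out / "panel.tsv", sep="\t", index=False)
    result.records.to_csv(out / "gene_records.tsv", sep="\t", index=False)
    result.delineation.as_table().to_csv(out / "module_sets.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    grids = out / "grids"
    grids.mkdir(exist_ok=True)
    for cohort, profiles in result.profiles.items():
        for tp, profile in profiles.items():
            grid = fp.fingerprint_grid(profile, rep)
            stem = f"{cohort}_{tp}".replace("/", "-")
            grid.to_tsv(grids / f"{stem}.tsv")
            if grids_png:
                grid.to_png(grids / f"{stem}.png", title=f"{cohort} {tp}")
    lines = [f"{k}\t{v}" for k, v in sorted(result.report.items())]
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def run_design(cfg: RunConfig) -> DesignResult:
    """File-driven wrapper: load all inputs named in the config, run, write outputs."""
    rep = load_repertoire(cfg.repertoire["gmt"], cfg.repertoire["meta"])
    ds_a = load_dataset(cfg.cohort_a.expr, cfg.cohort_a.samples)
    ds_b = load_dataset(cfg.cohort_b.expr, cfg.cohort_b.samples)
    ann = gs.load_annotations(cfg.annotations)
    prior = [line.strip() for line in Path(cfg.prior_hk).read_text().splitlines() if line.strip()]
    lit = [line.strip() for line in Path(cfg.literature_hk).read_text().splitlines() if line.strip()]
    result = design_panel(rep, ds_a, ds_b, ann, prior, lit,
                          reference_a=cfg.cohort_a.reference_timepoint,
                          reference_b=cfg.cohort_b.reference_timepoint,
                          pregnancy_a=cfg.cohort_a.pregnancy_timepoints or None,
                          pregnancy_b=cfg.cohort_b.pregnancy_timepoints or None,
                          thresholds=cfg.thresholds, delineation_cfg=cfg.delineation,
                          gene_cfg=cfg.genes, one_sample=cfg.one_sample,
                          log_transform=cfg.log_transform, bh_correct=cfg.bh_correct)
    write_outputs(result, rep, cfg.out_dir, grids_png=cfg.grids_png)
    return result
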