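"""Synthetic longitudinal pregnancy cohorts with planted ground truth.

Two generators live here.

:func:`simulate_study` produces a full synthetic study: a fixed module
repertoire (paper-scale default: 38 aggregates / 382 modules x 10 genes), a
counts cohort emulating a sequencing design (6 timepoints T1, T2, T3, D,
P1, P2 with 15/15/15/15/13/15 subjects, negative-binomial noise around
log-normal baselines) and an intensity cohort emulating an unpaired
microarray design (5 gestational windows with 38/37/37/35/17 samples,
log-normal multiplicative noise), plus literature annotations and
housekeeping gene lists. Modules carry planted trajectory shapes — a
down-then-rebound decline toward delivery and an up-trend peaking in the
third trimester, plus a transient mid-pregnancy shape and a null shape —
and planted module sets, panel genes (title-level literature hits) and
low-abundance genes, so every pipeline stage can be checked against known
truth.

:func:`simulate_selection_scenario` produces a deterministic, noise-free
screening scenario at the published design scale: 46 module sets holding
2,530 candidate genes of which 894 sit below the abundance gate, survivor
counts of 4+/3/2 per set across 33/6/1 sets (plus 6 sets with no
qualifying gene), 16 quiet aggregates, and housekeeping sources — so the
selection arithmetic can be recomputed end to end by running the screening
code itself.

Postpartum timepoints carry multiplier 1 by construction, making the
postpartum baseline well defined. Samples are independent draws per
timepoint (no subject-level autocorrelation), matching the unpaired design
of the intensity cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .repertoire import ModuleRepertoire, build_repertoire

LOG2_FC_GATE = math.log2(1.5)

# per-pregnancy-stage log2 effects (4 stages, postpartum = 0)
SHAPES: dict[str, tuple[float, float, float, float]] = {
    "down_rebound": (-0.2, -0.65, -1.0, -1.3),   # decline to delivery, rebound postpartum
    "up_t3": (0.2, 0.65, 1.0, 0.8),              # rise, peaking in the third trimester
    "transient_mid": (0.25, 1.0, 0.5, 0.1),      # transient mid-pregnancy burst
    "null": (0.0, 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of one synthetic cohort."""

    name: str
    platform: str
    timepoints: tuple[str, ...]
    n_per_timepoint: tuple[int, ...]
    reference_timepoint: str
    pregnancy_timepoints: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_timepoint))


SEQ_DESIGN = CohortDesign(
    name="seq", platform="counts",
    timepoints=("T1", "T2", "T3", "D", "P1", "P2"),
    n_per_timepoint=(15, 15, 15, 15, 13, 15),
    reference_timepoint="P2",
    pregnancy_timepoints=("T1", "T2", "T3", "D"),
)

ARRAY_DESIGN = CohortDesign(
    name="array", platform="intensity",
    timepoints=("W04-15", "W16-23", "W24-31", "W32-40", "PP"),
    n_per_timepoint=(38, 37, 37, 35, 17),
    reference_timepoint="PP",
    pregnancy_timepoints=("W04-15", "W16-23", "W24-31", "W32-40"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the study generator; outputs are pure functions of this + seed."""

    seed: int = 0
    n_aggregates: int = 38
    n_modules: int = 382
    genes_per_module: int = 10
    n_responsive_aggregates: int = 22
    n_triple_set_aggregates: int = 2     # responsive aggregates carrying a third, singleton set
    n_short3_sets: int = 6               # sets planted with exactly 3 qualifying genes
    n_short2_sets: int = 1               # sets planted with exactly 2
    n_empty_sets: int = 6                # sets planted with no qualifying gene
    panel_genes_per_set: int = 4
    effect_scale: float = 1.0            # 0 -> all-null study
    nb_dispersion: float = 0.1
    baseline_meanlog: float = 6.0        # natural-log scale for counts baselines
    baseline_sdlog: float = 1.5
    intensity_noise_sd: float = 0.15     # per-sample log2 noise, intensity platform
    jitter_range: tuple[float, float] = (0.8, 1.2)  # per-gene effect-size jitter
    decoy_abstract_fraction: float = 0.2
    cohorts: tuple[CohortDesign, ...] = (SEQ_DESIGN, ARRAY_DESIGN)

    def __post_init__(self) -> None:
        if min(self.n_aggregates, self.n_modules, self.genes_per_module) <= 0:
            raise ValueError("repertoire shape counts must be positive")
        if self.n_modules < self.n_aggregates:
            raise ValueError("need at least one module per aggregate")

    @classmethod
    def miniature(cls, seed: int = 0) -> "SimulationConfig":
        """A small, fast shape for unit tests: 6 aggregates x 5 modules x 10 genes."""
        return cls(seed=seed, n_aggregates=6, n_modules=30, genes_per_module=10,
                   n_responsive_aggregates=3, n_triple_set_aggregates=0,
                   n_short3_sets=1, n_short2_sets=1, n_empty_sets=1)


@dataclass
class PlantedTruth:
    """Ground truth embedded by the generator, for recovery testing."""

    module_shape: dict[str, str]
    gene_jitter: dict[str, float]
    sets: dict[str, list[tuple[str, list[str]]]]   # aggregate -> [(expected label, modules)]
    responsive_aggregates: list[str]
    panel_genes: dict[str, list[str]]              # expected set key -> planted panel genes
    abundance_class: dict[str, str]                # gene -> high | low | mid | natural
    extra_genes: list[str] = field(default_factory=list)  # unannotated background + HK genes
    prior_hk: list[str] = field(default_factory=list)
    literature_hk: list[str] = field(default_factory=list)

    @property
    def all_panel_genes(self) -> list[str]:
        return [g for genes in self.panel_genes.values() for g in genes]

    def stage_effect(self, module: str, stage: int) -> float:
        return SHAPES[self.module_shape[module]][stage]


def simulate_repertoire(cfg: SimulationConfig) -> ModuleRepertoire:
    """Deterministic synthetic repertoire of the configured shape.

    Modules are spread as evenly as possible over aggregates (the default
    382-over-38 shape gives two aggregates one extra module); ids follow the
    ``A<i>`` / ``M<i>.<j>`` / ``G<n>`` pattern.
    """
    base, extra = divmod(cfg.n_modules, cfg.n_aggregates)
    module_genes: dict[str, list[str]] = {}
    module_aggregate: dict[str, str] = {}
    gene_counter = 0
    for a in range(cfg.n_aggregates):
        agg = f"A{a + 1}"
        n_mods = base + (1 if a < extra else 0)
        for j in range(n_mods):
            mid = f"M{a + 1}.{j + 1}"
            genes = [f"G{gene_counter + k:05d}" for k in range(cfg.genes_per_module)]
            gene_counter += cfg.genes_per_module
            module_genes[mid] = genes
            module_aggregate[mid] = agg
    return build_repertoire(module_genes, module_aggregate)


def plant_truth(cfg: SimulationConfig, rep: ModuleRepertoire) -> PlantedTruth:
    """Assign planted shapes, sets, panel genes and abundance classes.

    Responsive aggregates get a 3-module and a 2-module set with opposed
    shapes (decline vs rise); the first ``n_triple_set_aggregates`` also get
    a singleton set with the transient shape. Remaining modules are null.
    Set categories (full / 3-gene / 2-gene / empty) are assigned from the
    end of the global set list, so the defaults reproduce a 33/6/1/6 split
    over 46 sets.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    responsive = [f"A{i + 1}" for i in range(cfg.n_responsive_aggregates)]
    module_shape: dict[str, str] = {m: "null" for m in rep.modules}
    sets: dict[str, list[tuple[str, list[str]]]] = {}

    global_sets: list[tuple[str, list[str]]] = []  # (set key, modules)
    for idx, agg in enumerate(responsive):
        mods = rep.modules_of(agg)
        major_down = idx < cfg.n_responsive_aggregates // 2
        shapes = ["down_rebound", "up_t3"] if major_down else ["up_t3", "down_rebound"]
        sizes = [3, 2]
        if idx < cfg.n_triple_set_aggregates and len(mods) >= 6:
            sizes.append(1)
            shapes.append("transient_mid")
        sizes = [s for s in sizes if s <= len(mods)]
        agg_sets: list[tuple[str, list[str]]] = []
        cursor = 0
        for s_idx, (size, shape) in enumerate(zip(sizes, shapes)):
            members = mods[cursor:cursor + size]
            cursor += size
            for m in members:
                module_shape[m] = shape
            label = f"S{s_idx + 1}"
            agg_sets.append((label, members))
            global_sets.append((f"{agg}/{label}", members))
        sets[agg] = agg_sets

    # set categories from the end of the global list
    n_sets = len(global_sets)
    n_empty = min(cfg.n_empty_sets, n_sets)
    n_short2 = min(cfg.n_short2_sets, max(0, n_sets - n_empty))
    n_short3 = min(cfg.n_short3_sets, max(0, n_sets - n_empty - n_short2))
    category: dict[str, str] = {}
    for i, (key, _) in enumerate(global_sets):
        tail = n_sets - 1 - i
        if tail < n_empty:
            category[key] = "empty"
        elif tail < n_empty + n_short2:
            category[key] = "short2"
        elif tail < n_empty + n_short2 + n_short3:
            category[key] = "short3"
        else:
            category[key] = "full"

    panel_genes: dict[str, list[str]] = {}
    abundance_class: dict[str, str] = {}
    n_planted = {"full": cfg.panel_genes_per_set, "short3": 3, "short2": 2, "empty": 0}
    for key, members in global_sets:
        genes = rep.genes_of_modules(members)
        cat = category[key]
        k = min(n_planted[cat], len(genes))
        planted = genes[:k]
        if planted:
            panel_genes[key] = planted
        for g in planted:
            abundance_class[g] = "high"
        for g in genes[k:]:
            if cat == "empty":
                abundance_class[g] = "mid"
            elif cat in ("short3", "short2"):
                abundance_class[g] = "low"
            else:
                abundance_class[g] = "low" if rng.random() < 0.2 else "high"

    for g in rep.all_genes:
        abundance_class.setdefault(g, "natural")

    lo, hi = cfg.jitter_range
    gene_jitter = {g: float(rng.uniform(lo, hi)) for g in rep.all_genes}

    prior_hk = [f"HKP{i}" for i in range(1, 5)]
    literature_hk = ["HKL1", "HKL2"]
    extra = prior_hk + literature_hk + [f"BG{i:02d}" for i in range(1, 15)]
    for g in extra:
        gene_jitter[g] = 1.0
        abundance_class[g] = "natural"
    return PlantedTruth(module_shape=module_shape, gene_jitter=gene_jitter, sets=sets,
                        responsive_aggregates=responsive, panel_genes=panel_genes,
                        abundance_class=abundance_class, extra_genes=extra,
                        prior_hk=prior_hk, literature_hk=literature_hk)


def _baselines(cfg: SimulationConfig, truth: PlantedTruth, genes: list[str],
               rng: np.random.Generator, platform: str) -> np.ndarray:
    """Per-gene baseline expression; abundance classes steer the counts gate."""
    draw = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=len(genes))
    if platform != "counts":
        return draw  # no abundance gate on the intensity platform
    out = np.empty(len(genes))
    for i, g in enumerate(genes):
        cls = truth.abundance_class.get(g, "natural")
        # class baselines keep the abundance-gate outcome invariant to the
        # planted trajectory: the per-gene median multiplier stays within
        # [0.58, 1.7], so low/mid genes stay under the 50-count gate and
        # mid genes stay above the relaxed supplement gate
        if cls == "high":
            out[i] = max(200.0, draw[i])
        elif cls == "low":
            out[i] = float(np.clip(rng.lognormal(3.0, 0.4), 12.0, 26.0))
        elif cls == "mid":
            out[i] = float(rng.uniform(20.0, 26.0))
        else:
            out[i] = draw[i]
    return out


def simulate_cohort(cfg: SimulationConfig, cohort: str, rep: ModuleRepertoire,
                    truth: PlantedTruth) -> ExpressionDataset:
    """Generate one cohort's expression matrix and sample sheet.

    Counts platform: gamma-Poisson (negative binomial) draws around
    baseline x 2^(shape effect x jitter). Intensity platform: log2-normal
    multiplicative noise. Postpartum timepoints have effect 0.
    """
    designs = {d.name: d for d in cfg.cohorts}
    if cohort not in designs:
        raise ValueError(f"unknown cohort {cohort!r}; have {sorted(designs)}")
    design = designs[cohort]
    stream = 1 + list(designs).index(cohort)
    rng = np.random.default_rng([cfg.seed, stream])

    genes = rep.all_genes + truth.extra_genes
    gene_module: dict[str, str] = {}
    for mid, gs in rep.modules.items():
        for g in gs:
            gene_module.setdefault(g, mid)
    base = _baselines(cfg, truth, genes, rng, design.platform)
    jitter = np.array([truth.gene_jitter.get(g, 1.0) for g in genes])

    stage_of = {tp: i for i, tp in enumerate(design.pregnancy_timepoints)}
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for tp, n in zip(design.timepoints, design.n_per_timepoint):
        stage = stage_of.get(tp)  # None for postpartum
        eff = np.zeros(len(genes))
        if stage is not None:
            for i, g in enumerate(genes):
                mid = gene_module.get(g)
                if mid is not None:
                    eff[i] = SHAPES[truth.module_shape[mid]][stage]
        mean = base * np.power(2.0, eff * cfg.effect_scale * jitter)
        for s in range(n):
            sid = f"{cohort}_{tp}_{s + 1:02d}"
            if design.platform == "counts":
                lam = rng.gamma(shape=1.0 / cfg.nb_dispersion,
                                scale=mean * cfg.nb_dispersion)
                columns[sid] = rng.poisson(lam).astype(float)
                subject = f"{cohort}_subj{s + 1:02d}"  # longitudinal: same subjects revisit
            else:
                noise = rng.normal(0.0, cfg.intensity_noise_sd, size=len(genes))
                columns[sid] = mean * np.power(2.0, noise)
                subject = f"{cohort}_{tp}_subj{s + 1:02d}"  # unpaired design
            meta_rows.append({"sample_id": sid, "subject_id": subject, "timepoint": tp,
                              "cohort": cohort, "platform": design.platform})
    matrix = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    norm = "median-of-ratios counts" if design.platform == "counts" else "background-subtracted quantile"
    return ExpressionDataset(matrix=matrix, samples=samples, normalization=norm)


def simulate_annotations(cfg: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Literature annotation table: planted panel genes get title hits, a
    configurable fraction of decoys get abstract-only hits."""
    rng = np.random.default_rng([cfg.seed, 9])
    planted = set(truth.all_panel_genes)
    provenance = "synthetic literature screen: <gene> AND (pregnancy OR pregnant OR gravid)"
    rows = []
    for g in sorted(planted):
        rows.append({"gene_id": g, "title_hit": 1, "abstract_hit": 1, "provenance": provenance})
    all_genes = sorted(truth.gene_jitter)
    for g in all_genes:
        if g in planted:
            continue
        if rng.random() < cfg.decoy_abstract_fraction:
            rows.append({"gene_id": g, "title_hit": 0, "abstract_hit": 1, "provenance": provenance})
    ann = pd.DataFrame(rows, columns=["gene_id", "title_hit", "abstract_hit", "provenance"])
    ann["title_hit"] = ann["title_hit"].astype(bool)
    ann["abstract_hit"] = ann["abstract_hit"].astype(bool)
    return ann.set_index("gene_id")


@dataclass
class SimulatedStudy:
    """Bundle of everything the pipeline needs, plus the planted truth."""

    config: SimulationConfig
    repertoire: ModuleRepertoire
    truth: PlantedTruth
    cohort_a: ExpressionDataset      # counts platform
    cohort_b: ExpressionDataset      # intensity platform
    annotations: pd.DataFrame
    prior_hk: list[str]
    literature_hk: list[str]


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the full synthetic study (repertoire, both cohorts, annotations)."""
    rep = simulate_repertoire(cfg)
    truth = plant_truth(cfg, rep)
    ds_a = simulate_cohort(cfg, cfg.cohorts[0].name, rep, truth)
    ds_b = simulate_cohort(cfg, cfg.cohorts[1].name, rep, truth)
    ann = simulate_annotations(cfg, truth)
    return SimulatedStudy(config=cfg, repertoire=rep, truth=truth, cohort_a=ds_a,
                          cohort_b=ds_b, annotations=ann,
                          prior_hk=truth.prior_hk, literature_hk=truth.literature_hk)


# ---------------------------------------------------------------------------
# deterministic noise-free selection scenario


@dataclass
class SelectionScenario:
    """Noise-free screening scenario at the published design scale.

    46 module sets (one 55-gene module each) spread over 22 responsive
    aggregates, 16 quiet aggregates, 2,530 candidate genes of which 894 sit
    below the abundance gate, and survivor counts planted at 5/3/2/0 per set
    across 33/6/1/6 sets. Gene values are exact trajectory multiples (no
    sampling noise) so every screening count is reproducible bit-exactly by
    running the selection code.
    """

    repertoire: ModuleRepertoire
    ds_counts: ExpressionDataset
    ds_intensity: ExpressionDataset
    annotations: pd.DataFrame
    set_modules: dict[str, list[str]]
    excluded_aggregates: list[str]
    prior_hk: list[str]
    literature_hk: list[str]
    candidate_genes: list[str]


def _scenario_trajectory(shape: str, timepoints: list[str], stages: dict[str, int],
                         ripple_tp: str | None = None) -> np.ndarray:
    mult = []
    for tp in timepoints:
        e = SHAPES[shape][stages[tp]] if tp in stages else 0.0
        m = 2.0 ** e
        if ripple_tp is not None and tp == ripple_tp:
            m *= 1.01
        mult.append(m)
    return np.array(mult)


def simulate_selection_scenario(seed: int = 0) -> SelectionScenario:
    """Build the deterministic screening scenario (see :class:`SelectionScenario`)."""
    rng = np.random.default_rng([seed, 5])
    n_sets_per_cat = {"full": 33, "short3": 6, "short2": 1, "empty": 6}
    survivors_per_cat = {"full": 5, "short3": 3, "short2": 2, "empty": 0}
    low_per_cat = {"full": 14, "short3": 16, "short2": 6, "empty": 55}
    genes_per_set = 55

    # 22 responsive aggregates: the first two hold 3 sets, the rest 2 (46 sets)
    sets_per_agg = [3, 3] + [2] * 20
    shapes_cycle = ["down_rebound", "up_t3", "transient_mid"]
    categories = (["full"] * 33 + ["short3"] * 6 + ["short2"] * 1 + ["empty"] * 6)

    module_genes: dict[str, list[str]] = {}
    module_aggregate: dict[str, str] = {}
    set_modules: dict[str, list[str]] = {}
    set_meta: list[tuple[str, str, str]] = []  # (set key, module, category)
    gene_counter = 0
    set_idx = 0
    for a, n_sets in enumerate(sets_per_agg):
        agg = f"A{a + 1}"
        for s in range(n_sets):
            mid = f"M{a + 1}.{s + 1}"
            genes = [f"G{gene_counter + k:05d}" for k in range(genes_per_set)]
            gene_counter += genes_per_set
            module_genes[mid] = genes
            module_aggregate[mid] = agg
            key = f"{agg}/S{s + 1}"
            set_modules[key] = [mid]
            set_meta.append((key, mid, categories[set_idx]))
            set_idx += 1
    excluded_aggregates = [f"A{a + 1}" for a in range(22, 38)]
    for a in range(22, 38):
        agg = f"A{a + 1}"
        mid = f"M{a + 1}.1"
        module_genes[mid] = [f"Q{a + 1}_{k}" for k in range(3)]
        module_aggregate[mid] = agg

    rep = build_repertoire(module_genes, module_aggregate)

    tps_a = ["T1", "T2", "T3", "D", "P1", "P2"]
    stages_a = {"T1": 0, "T2": 1, "T3": 2, "D": 3}
    tps_b = ["W04-15", "W16-23", "W24-31", "W32-40", "PP"]
    stages_b = {tp: i for i, tp in enumerate(tps_b[:4])}

    hk = {"prior": [f"HKP{i}" for i in range(1, 5)],
          "cv": ["HKC1", "HKC2"], "lit": ["HKL1", "HKL2"]}
    all_hk = hk["prior"] + hk["cv"] + hk["lit"]

    rows_a: dict[str, np.ndarray] = {}
    rows_b: dict[str, np.ndarray] = {}
    ann_rows: list[dict] = []
    provenance = "synthetic literature screen: <gene> AND (pregnancy OR pregnant OR gravid)"

    def annotate(gene: str, title: int, abstract: int) -> None:
        ann_rows.append({"gene_id": gene, "title_hit": title, "abstract_hit": abstract,
                         "provenance": provenance})

    candidate_genes: list[str] = []
    for key, mid, cat in set_meta:
        genes = module_genes[mid]
        candidate_genes.extend(genes)
        shape = shapes_cycle[int(key.split("/S")[1]) - 1]
        n_surv = survivors_per_cat[cat]
        n_low = low_per_cat[cat]
        surv, low = genes[:n_surv], genes[n_surv:n_surv + n_low]
        decoys = genes[n_surv + n_low:]
        traj_a = _scenario_trajectory(shape, tps_a, stages_a)
        traj_b = _scenario_trajectory(shape, tps_b, stages_b)
        # decoy ripple sits on a postpartum timepoint: orthogonal to every
        # pregnancy shape, so flat decoys cannot sneak past the correlation gate
        flat_a = _scenario_trajectory("null", tps_a, stages_a, ripple_tp="P1")
        flat_b = _scenario_trajectory("null", tps_b, stages_b, ripple_tp=tps_b[1])
        for i, g in enumerate(surv):
            base = 200.0 + 5.0 * i
            rows_a[g] = base * traj_a
            rows_b[g] = (90.0 + 4.0 * i) * traj_b
            # the intended top picks carry title hits; the 5th survivor of a
            # full set only an abstract hit, so ranking is unambiguous
            if i < min(n_surv, 4):
                annotate(g, 1, 1)
            else:
                annotate(g, 0, 1)
        for i, g in enumerate(low):
            # kept below the abundance gate even under the largest trajectory
            # multiplier (median multiple <= 1.36, so base <= 35 stays under 50)
            base = 25.0 if cat == "empty" else float(np.clip(12.0 + (i * 5) % 24, 11.0, 35.0))
            rows_a[g] = base * traj_a
            rows_b[g] = 40.0 * traj_b
            if cat == "empty" and i == 0:
                annotate(g, 0, 1)  # deterministic supplement pick for the empty set
        for i, g in enumerate(decoys):
            base = 200.0 + (i % 17)
            rows_a[g] = base * flat_a
            rows_b[g] = 80.0 * flat_b
            if cat == "short2" and i < 2:
                annotate(g, 0, 1)  # the two designated top-up extras
                rows_a[g] = 400.0 * flat_a

    for a in range(22, 38):
        for i, g in enumerate(module_genes[f"M{a + 1}.1"]):
            rows_a[g] = np.array([25.0, 15.0, 8.0][i]) * _scenario_trajectory(
                "null", tps_a, stages_a, ripple_tp="T3")
            rows_b[g] = 50.0 * _scenario_trajectory("null", tps_b, stages_b, ripple_tp=tps_b[2])
            if i == 0:
                annotate(g, 0, 1)  # deterministic supplement pick for the quiet aggregate

    # only the designated low-CV pair is perfectly flat in BOTH datasets;
    # prior/literature genes get a ripple in the counts data so the %CV rank
    # is unambiguous
    for g in all_hk:
        level = 300.0 + 10.0 * all_hk.index(g)
        ripple = None if g in hk["cv"] else "D"
        rows_a[g] = level * _scenario_trajectory("null", tps_a, stages_a, ripple_tp=ripple)
        rows_b[g] = level * _scenario_trajectory("null", tps_b, stages_b)

    def dataset(rows: dict[str, np.ndarray], tps: list[str], cohort: str,
                platform: str) -> ExpressionDataset:
        cols: dict[str, np.ndarray] = {}
        meta = []
        vals = pd.DataFrame(rows).T  # genes x timepoints
        vals.columns = tps
        for tp in tps:
            for s in range(2):  # two identical samples per timepoint
                sid = f"{cohort}_{tp}_{s + 1}"
                cols[sid] = vals[tp].to_numpy()
                meta.append({"sample_id": sid, "subject_id": f"{cohort}_{tp}_{s + 1}",
                             "timepoint": tp, "cohort": cohort, "platform": platform})
        return ExpressionDataset(matrix=pd.DataFrame(cols, index=vals.index),
                                 samples=pd.DataFrame(meta).set_index("sample_id"),
                                 normalization="noise-free scenario")

    ds_a = dataset(rows_a, tps_a, "seq", "counts")
    ds_b = dataset(rows_b, tps_b, "array", "intensity")
    ann = pd.DataFrame(ann_rows).drop_duplicates("gene_id").set_index("gene_id")
    ann["title_hit"] = ann["title_hit"].astype(bool)
    ann["abstract_hit"] = ann["abstract_hit"].astype(bool)
    del rng  # reserved for future stochastic variants; scenario is noise-free
    return SelectionScenario(repertoire=rep, ds_counts=ds_a, ds_intensity=ds_b,
                             annotations=ann, set_modules=set_modules,
                             excluded_aggregates=excluded_aggregates,
                             prior_hk=hk["prior"], literature_hk=hk["lit"],
                             candidate_genes=candidate_genes)
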