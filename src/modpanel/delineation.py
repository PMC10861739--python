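"""Module-set delineation by cross-cohort co-clustering.

Working from group-level module response trajectories over the pregnancy
timepoints (postpartum reference excluded), this stage

1. retains module aggregates whose response clears a 10% cut-off,
2. ranks the qualifying modules of each aggregate and keeps the top 10,
3. hierarchically clusters their trajectories in each cohort independently
   (distance = 1 - Pearson r, average linkage, fixed tree cut), and
4. delineates module sets as the blocks of the *meet* of the two cohort
   partitions — modules grouped together only if they co-cluster in BOTH
   cohorts — labelling at most three sets S1..S3 per aggregate by
   decreasing size and collecting the rest into a non-co-clustered (NS)
   bucket.

Consistent co-clustering across cohorts is the primary criterion: it keeps
cohort-specific artifacts out of the sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

Partition = list[set[str]]


@dataclass(frozen=True)
class ModuleTrajectory:
    """Signed module response per pregnancy timepoint, for one cohort."""

    module_id: str
    cohort: str
    values: tuple[float, ...]

    @property
    def avg_abs_response(self) -> float:
        return float(np.mean(np.abs(self.values)))


def build_trajectories(profiles: dict[str, pd.DataFrame], cohort: str,
                       pregnancy_timepoints: list[str] | None = None) -> dict[str, ModuleTrajectory]:
    """Assemble per-module trajectories from per-timepoint response profiles.

    ``profiles`` maps timepoint label -> module response profile (as produced
    by :func:`modpanel.fingerprint.fingerprint_profiles`); timepoint order is
    either given explicitly or taken from the dict's insertion order.
    """
    tps = pregnancy_timepoints if pregnancy_timepoints is not None else list(profiles)
    modules = list(profiles[tps[0]].index)
    out = {}
    for mid in modules:
        values = tuple(float(profiles[tp].loc[mid, "response"]) for tp in tps)
        out[mid] = ModuleTrajectory(module_id=mid, cohort=cohort, values=values)
    return out


def select_aggregates(trajectories: dict[str, ModuleTrajectory], rep,
                      threshold: float = 10.0,
                      rule: str = "any_module") -> list[str]:
    """Retain aggregates whose modules clear the response cut-off.

    ``rule="any_module"`` (default): retain an aggregate iff at least one
    constitutive module has mean |response| >= threshold.
    ``rule="aggregate_mean"``: retain iff the mean over constitutive modules
    of mean |response| >= threshold. The two readings diverge on aggregates
    with a single strong module among quiet ones; divergences are logged.
    """
    if rule not in ("any_module", "aggregate_mean"):
        raise ValueError(f"unknown aggregate rule {rule!r}")
    retained: list[str] = []
    for agg in rep.aggregate_order:
        mids = rep.modules_of(agg)
        if not mids:
            raise ValueError(f"aggregate {agg!r} has no modules")
        avgs = [trajectories[m].avg_abs_response for m in mids]
        by_any = max(avgs) >= threshold
        by_mean = float(np.mean(avgs)) >= threshold
        if by_any != by_mean:
            logger.info("aggregate %s: any_module=%s aggregate_mean=%s (rules diverge)",
                        agg, by_any, by_mean)
        if (rule == "any_module" and by_any) or (rule == "aggregate_mean" and by_mean):
            retained.append(agg)
    return retained


def rank_top_modules(aggregate_id: str, trajectories: dict[str, ModuleTrajectory], rep,
                     k: int = 10, threshold: float = 10.0) -> list[str]:
    """Top-k modules of an aggregate with mean |response| strictly above threshold.

    Sorted by descending mean |response|, ties broken by module id; an empty
    result is allowed (the aggregate then yields no sets).
    """
    qualifying = [(trajectories[m].avg_abs_response, m)
                  for m in rep.modules_of(aggregate_id)
                  if trajectories[m].avg_abs_response > threshold]
    qualifying.sort(key=lambda t: (-t[0], t[1]))
    return [m for _, m in qualifying[:k]]


def cluster_modules(trajectories: dict[str, ModuleTrajectory], module_ids: list[str],
                    cut_height: float = 0.5, method: str = "average") -> Partition:
    """Partition modules by agglomerative clustering of their trajectories.

    Distance = 1 - Pearson correlation, given linkage, tree cut at a fixed
    cophenetic distance. Constant (zero-variance) trajectories have no
    defined correlation: each becomes its own singleton cluster, with a
    logged warning. Singletons are permitted generally.
    """
    if len(module_ids) == 1:
        return [{module_ids[0]}]
    mat = np.array([trajectories[m].values for m in module_ids], dtype=float)
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant trajectory(ies) set aside as singletons: %s",
                       int(constant.sum()),
                       [m for m, c in zip(module_ids, constant) if c])
    variable_ids = [m for m, c in zip(module_ids, constant) if not c]
    partition: Partition = [{m} for m, c in zip(module_ids, constant) if c]
    if len(variable_ids) == 1:
        partition.append({variable_ids[0]})
        return partition
    if not variable_ids:
        return partition
    vmat = np.array([trajectories[m].values for m in variable_ids], dtype=float)
    corr = np.corrcoef(vmat)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=cut_height, criterion="distance")
    for lab in np.unique(labels):
        partition.append({variable_ids[i] for i in np.where(labels == lab)[0]})
    return partition


@dataclass(frozen=True)
class ModuleSetAssignment:
    """Ordered module sets (S1..S3) plus the NS bucket for one aggregate."""

    aggregate_id: str
    sets: tuple[tuple[str, tuple[str, ...]], ...]  # (label, module ids)
    ns: tuple[str, ...]

    @property
    def all_modules(self) -> set[str]:
        out = set(self.ns)
        for _, mids in self.sets:
            out |= set(mids)
        return out

    def as_rows(self) -> list[dict]:
        rows = [{"aggregate_id": self.aggregate_id, "set_label": lab, "module_id": m}
                for lab, mids in self.sets for m in mids]
        rows += [{"aggregate_id": self.aggregate_id, "set_label": "NS", "module_id": m}
                 for m in self.ns]
        return rows


def meet_partition(partition_a: Partition, partition_b: Partition) -> Partition:
    """Meet (coarsest common refinement) of two partitions over the same elements.

    Two modules land in the same block iff they share a cluster in BOTH
    partitions.
    """
    elems_a = {m for blk in partition_a for m in blk}
    elems_b = {m for blk in partition_b for m in blk}
    if elems_a != elems_b:
        raise ValueError("partitions cover different module sets")
    block_a = {m: i for i, blk in enumerate(partition_a) for m in blk}
    block_b = {m: i for i, blk in enumerate(partition_b) for m in blk}
    groups: dict[tuple[int, int], set[str]] = {}
    for m in elems_a:
        groups.setdefault((block_a[m], block_b[m]), set()).add(m)
    return list(groups.values())


def delineate_sets(partition_a: Partition, partition_b: Partition,
                   aggregate_id: str = "", max_sets: int = 3,
                   singleton_rule: str = "first") -> ModuleSetAssignment:
    """Delineate consistently co-clustering module sets from two cohort partitions.

    Candidate sets are the blocks of the partition meet with >= 2 modules.
    A singleton meet-block is additionally admitted when it forms a distinct
    (singleton) cluster on its own — under ``singleton_rule="first"``
    (default) judged in the first (primary) cohort's partition, under
    ``"any"`` in either cohort. Candidates are ranked by decreasing size,
    ties broken by smallest module id; the top ``max_sets`` become S1, S2,
    S3 and everything else goes to the NS bucket.
    """
    if singleton_rule not in ("first", "any"):
        raise ValueError(f"unknown singleton rule {singleton_rule!r}")
    meet = meet_partition(partition_a, partition_b)
    singletons_a = {next(iter(blk)) for blk in partition_a if len(blk) == 1}
    singletons_b = {next(iter(blk)) for blk in partition_b if len(blk) == 1}
    admissible = singletons_a if singleton_rule == "first" else singletons_a | singletons_b

    candidates: list[set[str]] = []
    ns: set[str] = set()
    for blk in meet:
        if len(blk) >= 2 or next(iter(blk)) in admissible:
            candidates.append(blk)
        else:
            ns |= blk
    candidates.sort(key=lambda blk: (-len(blk), min(blk)))
    labelled = candidates[:max_sets]
    for blk in candidates[max_sets:]:
        ns |= blk
    sets = tuple((f"S{i + 1}", tuple(sorted(blk))) for i, blk in enumerate(labelled))
    return ModuleSetAssignment(aggregate_id=aggregate_id, sets=sets, ns=tuple(sorted(ns)))


@dataclass
class DelineationResult:
    """All module-set assignments plus the audit trail of per-cohort partitions."""

    assignments: dict[str, ModuleSetAssignment]
    partitions: dict[str, tuple[Partition, Partition]] = field(default_factory=dict)

    def as_table(self) -> pd.DataFrame:
        rows = [r for a in self.assignments.values() for r in a.as_rows()]
        return pd.DataFrame(rows, columns=["aggregate_id", "set_label", "module_id"])

    @property
    def set_keys(self) -> list[str]:
        """Keys like ``A28/S1`` for every labelled (non-NS) set."""
        return [f"{agg}/{lab}" for agg, a in self.assignments.items() for lab, _ in a.sets]


def delineate_all(trajectories_a: dict[str, ModuleTrajectory],
                  trajectories_b: dict[str, ModuleTrajectory],
                  rep, retained_aggregates: list[str],
                  top_k: int = 10, threshold: float = 10.0,
                  max_sets: int = 3, cut_height: float = 0.5,
                  singleton_rule: str = "first") -> DelineationResult:
    """Run ranking, per-cohort clustering and set delineation per retained aggregate.

    Ranking uses the primary (first) cohort's trajectories; both cohorts are
    clustered independently over the same ranked module list.
    """
    assignments: dict[str, ModuleSetAssignment] = {}
    partitions: dict[str, tuple[Partition, Partition]] = {}
    for agg in retained_aggregates:
        ranked = rank_top_modules(agg, trajectories_a, rep, k=top_k, threshold=threshold)
        if not ranked:
            logger.info("aggregate %s: no module above %.1f%%, no sets", agg, threshold)
            assignments[agg] = ModuleSetAssignment(aggregate_id=agg, sets=(), ns=())
            continue
        part_a = cluster_modules(trajectories_a, ranked, cut_height=cut_height)
        part_b = cluster_modules(trajectories_b, ranked, cut_height=cut_height)
        partitions[agg] = (part_a, part_b)
        assignments[agg] = delineate_sets(part_a, part_b, aggregate_id=agg,
                                          max_sets=max_sets, singleton_rule=singleton_rule)
    return DelineationResult(assignments=assignments, partitions=partitions)
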