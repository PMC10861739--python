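"""Fixed blood transcriptional module repertoire: gene -> module -> aggregate.

A *module* is a reusable set of co-expressed genes; modules with correlated
behaviour across reference cohorts are grouped into *aggregates*, one grid
row each in the fingerprint display. The repertoire is fixed: it is defined
once and re-applied unchanged to new datasets, so validation is strict and
layout positions are stable across calls.

Gene-set membership travels as a standard GMT file (tab-separated:
module id, description, gene ids); aggregate membership and grid layout,
which GMT has no slot for, travel as a 3-column TSV
(module_id, aggregate_id, grid_position).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class RepertoireError(ValueError):
    """Raised when a repertoire file violates the repertoire contract."""


@dataclass(frozen=True)
class ModuleRepertoire:
    """Validated gene -> module -> aggregate mapping with fixed grid layout.

    Parameters
    ----------
    modules
        Ordered gene-id list per module id. Gene ids are opaque,
        case-sensitive strings (typically HGNC symbols).
    aggregates
        Aggregate id per module id; every module belongs to exactly one.
    grid
        Fixed ``(row, column)`` per module: row is the aggregate index in
        first-appearance order, column the position within the aggregate row.
    """

    modules: dict[str, list[str]]
    aggregates: dict[str, str]
    grid: dict[str, tuple[int, int]]
    aggregate_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if set(self.modules) != set(self.aggregates) or set(self.modules) != set(self.grid):
            raise RepertoireError("modules, aggregates and grid must cover the same module ids")
        for mid, genes in self.modules.items():
            if not genes:
                raise RepertoireError(f"module {mid!r} has an empty gene list")
            dup = [g for g, k in Counter(genes).items() if k > 1]
            if dup:
                raise RepertoireError(f"module {mid!r} lists duplicate gene ids: {sorted(dup)}")
        if len(set(self.grid.values())) != len(self.grid):
            raise RepertoireError("grid positions must be unique per module")
        if not self.aggregate_order:
            seen: list[str] = []
            for mid in self.modules:
                agg = self.aggregates[mid]
                if agg not in seen:
                    seen.append(agg)
            object.__setattr__(self, "aggregate_order", tuple(seen))
        multi = [g for g, k in Counter(g for gs in self.modules.values() for g in gs).items() if k > 1]
        if multi:
            logger.warning("%d gene(s) appear in more than one module (allowed)", len(multi))

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def n_aggregates(self) -> int:
        return len(self.aggregate_order)

    def modules_of(self, aggregate_id: str) -> list[str]:
        """Module ids belonging to one aggregate, in repertoire order."""
        return [m for m, a in self.aggregates.items() if a == aggregate_id]

    def genes_of(self, module_id: str) -> list[str]:
        try:
            return list(self.modules[module_id])
        except KeyError:
            raise RepertoireError(f"unknown module id {module_id!r}") from None

    def genes_of_modules(self, module_ids: Iterable[str]) -> list[str]:
        """Union of constitutive genes over several modules (order-preserving)."""
        out: list[str] = []
        seen: set[str] = set()
        for mid in module_ids:
            for g in self.genes_of(mid):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    @property
    def all_genes(self) -> list[str]:
        return self.genes_of_modules(self.modules)


@dataclass(frozen=True)
class RepertoireStats:
    n_modules: int
    n_aggregates: int
    genes_per_module: dict[str, int]


def repertoire_stats(rep: ModuleRepertoire) -> RepertoireStats:
    """Exact size summary of a repertoire."""
    return RepertoireStats(
        n_modules=rep.n_modules,
        n_aggregates=rep.n_aggregates,
        genes_per_module={m: len(g) for m, g in rep.modules.items()},
    )


def load_repertoire(geneset_path: str | Path, metadata_path: str | Path) -> ModuleRepertoire:
    """Load and validate a repertoire from a GMT gene-set file plus layout TSV.

    The GMT file holds one module per line (``module_id<TAB>description<TAB>
    gene...``); the metadata TSV holds a header line then
    ``module_id<TAB>aggregate_id<TAB>grid_position`` rows. Every GMT module
    must appear in the metadata. Genes present in expression data but absent
    from every module are permissible downstream (simply unannotated).
    """
    modules: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(geneset_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise RepertoireError(f"{geneset_path}:{lineno}: GMT line needs id, description and >=1 gene")
        mid = parts[0]
        if mid in modules:
            raise RepertoireError(f"duplicate module id {mid!r} in {geneset_path}")
        genes = [g for g in parts[2:] if g]
        if not genes:
            raise RepertoireError(f"module {mid!r} has an empty gene list")
        modules[mid] = genes

    aggregates: dict[str, str] = {}
    positions: dict[str, int] = {}
    meta_lines = Path(metadata_path).read_text().splitlines()
    for lineno, line in enumerate(meta_lines[1:], 2):  # skip header
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise RepertoireError(f"{metadata_path}:{lineno}: expected module_id, aggregate_id, grid_position")
        mid, agg, pos = parts[0], parts[1], parts[2]
        if mid in aggregates:
            raise RepertoireError(f"duplicate module id {mid!r} in {metadata_path}")
        aggregates[mid] = agg
        positions[mid] = int(pos)

    missing = sorted(set(modules) - set(aggregates))
    if missing:
        raise RepertoireError(f"module(s) missing from metadata: {missing}")
    extra = sorted(set(aggregates) - set(modules))
    if extra:
        raise RepertoireError(f"metadata row(s) for unknown module(s): {extra}")

    agg_order: list[str] = []
    for mid in modules:
        if aggregates[mid] not in agg_order:
            agg_order.append(aggregates[mid])
    grid = {mid: (agg_order.index(aggregates[mid]), positions[mid]) for mid in modules}
    return ModuleRepertoire(modules=modules, aggregates=aggregates, grid=grid,
                            aggregate_order=tuple(agg_order))


def save_repertoire(rep: ModuleRepertoire, geneset_path: str | Path, metadata_path: str | Path) -> None:
    """Write a repertoire back to GMT + metadata TSV (round-trips bit-exact on ids)."""
    with open(geneset_path, "w") as fh:
        for mid, genes in rep.modules.items():
            fh.write("\t".join([mid, f"module {mid}", *genes]) + "\n")
    with open(metadata_path, "w") as fh:
        fh.write("module_id\taggregate_id\tgrid_position\n")
        for mid in rep.modules:
            fh.write(f"{mid}\t{rep.aggregates[mid]}\t{rep.grid[mid][1]}\n")


def build_repertoire(module_genes: Mapping[str, Iterable[str]],
                     module_aggregate: Mapping[str, str]) -> ModuleRepertoire:
    """Construct a repertoire in memory, assigning grid columns by position within each aggregate."""
    modules = {m: list(g) for m, g in module_genes.items()}
    aggregates = dict(module_aggregate)
    agg_order: list[str] = []
    for mid in modules:
        if aggregates[mid] not in agg_order:
            agg_order.append(aggregates[mid])
    col_counter: Counter[str] = Counter()
    grid: dict[str, tuple[int, int]] = {}
    for mid in modules:
        agg = aggregates[mid]
        grid[mid] = (agg_order.index(agg), col_counter[agg])
        col_counter[agg] += 1
    return ModuleRepertoire(modules=modules, aggregates=aggregates, grid=grid,
                            aggregate_order=tuple(agg_order))
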