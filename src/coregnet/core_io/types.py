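"""Shared domain vocabulary: regulators, regulatory networks, expression data."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import pandas as pd

from ..errors import DomainError, IntegrityError


class RegulatorKind(enum.Enum):
    TF = "TF"
    MIRNA_FAMILY = "MIRNA_FAMILY"


class Condition(enum.Enum):
    NORMAL = "normal"
    TUMOR = "tumor"


@dataclass(frozen=True)
class Regulator:
    """A transcriptional or post-transcriptional regulator.

    For a TF, ``members`` is the singleton set of its gene symbol; for a
    miRNA family it is the set of mature miRNA names collapsed into the
    family.
    """

    id: str
    kind: RegulatorKind
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("regulator id must be non-empty")
        if not self.members:
            raise DomainError(f"regulator {self.id!r} has no members")


class RegulatorTargetNetwork:
    """Bipartite regulator -> target-gene network (one regulatory layer)."""

    def __init__(
        self,
        regulators: Iterable[Regulator],
        edges: Iterable[Tuple[str, str]],
        universe: Optional[Iterable[str]] = None,
    ) -> None:
        self.regulators: Dict[str, Regulator] = {r.id: r for r in regulators}
        self.edges: Set[Tuple[str, str]] = set(edges)
        for rid, _ in self.edges:
            if rid not in self.regulators:
                raise IntegrityError(f"edge references unknown regulator {rid!r}")
        self.universe: Set[str] = set(universe) if universe is not None else set()
        self.universe.update(t for _, t in self.edges)
        self._targets: Dict[str, FrozenSet[str]] = {}

    def targets(self, regulator_id: str) -> FrozenSet[str]:
        if regulator_id not in self.regulators:
            raise KeyError(regulator_id)
        if not self._targets:
            tmp: Dict[str, Set[str]] = {rid: set() for rid in self.regulators}
            for rid, gene in self.edges:
                tmp[rid].add(gene)
            self._targets = {rid: frozenset(g) for rid, g in tmp.items()}
        return self._targets[regulator_id]

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatorTargetNetwork):
            return NotImplemented
        return (
            self.regulators == other.regulators
            and self.edges == other.edges
            and self.universe == other.universe
        )


@dataclass
class UpstreamNetwork:
    """Directed regulator -> regulator edges (who regulates whom upstream)."""

    edges: Set[Tuple[str, str]] = field(default_factory=set)
    kinds: Dict[str, RegulatorKind] = field(default_factory=dict)
    allow_self_loops: bool = False

    def add_edge(self, source: str, dest: str) -> None:
        if source == dest and not self.allow_self_loops:
            raise IntegrityError(f"self-loop {source!r} -> {dest!r} not permitted")
        self.edges.add((source, dest))

    def successors(self, node: str) -> Set[str]:
        return {d for s, d in self.edges if s == node}

    def predecessors(self, node: str) -> Set[str]:
        return {s for s, d in self.edges if d == node}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class ExpressionDataset:
    """Entity x sample expression matrix with per-sample tissue/condition labels.

    ``values`` rows are entities (mRNAs or mature miRNAs) and columns are
    sample ids; ``sample_meta`` is indexed by sample id with columns
    ``tissue`` and ``condition``. Missing values are NaN.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_meta: pd.DataFrame,
        entity_kind: Optional[Mapping[str, str]] = None,
    ) -> None:
        if values.index.has_duplicates:
            dupes = sorted(values.index[values.index.duplicated()].unique())
            raise IntegrityError(f"duplicated entity ids: {dupes}")
        missing = [s for s in values.columns if s not in sample_meta.index]
        if missing:
            raise IntegrityError(
                "samples missing from metadata: " + ", ".join(sorted(missing))
            )
        # metadata rows for samples absent from the matrix are dropped
        self.values = values
        self.sample_meta = sample_meta.loc[list(values.columns)]
        self.entity_kind = dict(entity_kind) if entity_kind else {}
        for col in ("tissue", "condition"):
            if col not in self.sample_meta.columns:
                raise IntegrityError(f"sample metadata lacks column {col!r}")
        bad = set(self.sample_meta["condition"]) - {c.value for c in Condition}
        if bad:
            raise IntegrityError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def samples_for(self, condition: "Condition | str") -> list:
        label = condition.value if isinstance(condition, Condition) else condition
        mask = self.sample_meta["condition"] == label
        return list(self.sample_meta.index[mask])
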