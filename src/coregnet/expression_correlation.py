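"""Expression-correlation contrasts of enriched pairs vs background.

Pearson correlations between the two regulators of each pair are pooled
across tissues within a condition; the foreground (enriched pairs)
distribution is compared to the background (all other same-kind pairs)
with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core_io.types import Condition, ExpressionDataset, Regulator, RegulatorKind
from .errors import DomainError
from .pair_enrichment import CoregulationPair, PairKind

log = logging.getLogger(__name__)

MIN_COMPLETE_OBS = 3


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN pairs removed pairwise.

    Returns NaN (not an exception) when either vector is constant after
    removal; raises :class:`DomainError` on length mismatch or fewer than
    three complete observations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DomainError("vectors must be 1-D and of equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < MIN_COMPLETE_OBS:
        raise DomainError(f"need >= {MIN_COMPLETE_OBS} complete observations, got {xa.size}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def regulator_expression(
    reg: Regulator, expr: ExpressionDataset, condition: "Condition | str"
) -> np.ndarray:
    """Expression vector of a regulator restricted to one condition.

    A TF maps to its gene's mRNA row; a miRNA family to the per-sample
    mean over its measured mature members (NaN-aware). Raises
    :class:`LookupError` when no member is measured.
    """
    samples = expr.samples_for(condition)
    if reg.kind is RegulatorKind.TF:
        ids = [m for m in sorted(reg.members) if m in expr.values.index]
        if reg.id in expr.values.index:
            ids = [reg.id]
        if not ids:
            raise LookupError(f"TF {reg.id!r} has no expression row")
        return expr.values.loc[ids[0], samples].to_numpy(dtype=float)
    members = [m for m in sorted(reg.members) if m in expr.values.index]
    if not members:
        raise LookupError(f"family {reg.id!r} has no measured member")
    block = expr.values.loc[members, samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(block, axis=0)


@dataclass
class CorrelationSummary:
    pair_kind: PairKind
    condition: Condition
    foreground_r: List[float] = field(default_factory=list)
    background_r: List[float] = field(default_factory=list)
    ks_stat: float = float("nan")
    ks_p: float = float("nan")
    n_pairs_used: int = 0
    n_pairs_skipped: int = 0
    insufficient_n: bool = False


def _pair_r(
    pair: CoregulationPair,
    regulators: Mapping[str, Regulator],
    expr: ExpressionDataset,
    condition: "Condition | str",
) -> Optional[float]:
    try:
        xa = regulator_expression(regulators[pair.reg_a], expr, condition)
        ya = regulator_expression(regulators[pair.reg_b], expr, condition)
        r = pearson(xa, ya)
    except (LookupError, DomainError):
        return None
    if math.isnan(r):
        return None
    return r


def correlation_distributions(
    enriched_pairs: Sequence[CoregulationPair],
    all_pairs: Sequence[CoregulationPair],
    regulators: Mapping[str, Regulator],
    expr: ExpressionDataset,
    condition: "Condition | str",
) -> Dict[PairKind, CorrelationSummary]:
    """Foreground-vs-background correlation distributions per pair kind.

    Background = same-kind pairs from ``all_pairs`` that are not in the
    enriched set. Pairs whose expression cannot be resolved (missing rows,
    constant vectors, < 3 complete observations) are skipped and counted.
    """
    cond = condition if isinstance(condition, Condition) else Condition(condition)
    enriched_keys = {p.key for p in enriched_pairs}
    out: Dict[PairKind, CorrelationSummary] = {}
    for kind in PairKind:
        fg = [p for p in enriched_pairs if p.pair_kind is kind]
        bg = [p for p in all_pairs if p.pair_kind is kind and p.key not in enriched_keys]
        if not fg and not bg:
            continue
        summary = CorrelationSummary(pair_kind=kind, condition=cond)
        for pair_list, sink in ((fg, summary.foreground_r), (bg, summary.background_r)):
            for pair in pair_list:
                r = _pair_r(pair, regulators, expr, cond)
                if r is None:
                    summary.n_pairs_skipped += 1
                else:
                    sink.append(r)
                    summary.n_pairs_used += 1
        if fg and not summary.foreground_r:
            raise DomainError(
                f"no resolvable foreground expression for kind {kind.value} "
                f"({summary.n_pairs_skipped} pairs skipped)"
            )
        if len(summary.foreground_r) >= MIN_COMPLETE_OBS and len(summary.background_r) >= MIN_COMPLETE_OBS:
            ks = stats.ks_2samp(summary.foreground_r, summary.background_r)
            summary.ks_stat = float(ks.statistic)
            summary.ks_p = float(ks.pvalue)
        else:
            summary.insufficient_n = True
        out[kind] = summary
    return out
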