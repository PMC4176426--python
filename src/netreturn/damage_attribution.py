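"""Partition nut losses between birds and non-bird causes; compare strata.

Netted branches exclude birds, so their losses estimate the baseline rate
of non-bird loss (storms, tree health, natural abortion). On open
branches some nuts disappear completely and cannot be assigned by
inspection; the attribution rule assigns the baseline share of those
disappearances to non-bird causes and the remainder to birds. With a
5.9% baseline, 50 disappeared nuts split as 3 non-bird and 47 bird.

Two rate summaries are exposed and kept distinct:

* ``mean_rate`` — the mean of per-branch rates, with its SEM, matching
  how field results are usually reported (each branch is the sampling
  unit);
* ``pooled_rate`` — lost nuts over total nuts across the stratum, the
  quantity the likelihood-ratio contrast operates on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy

from netreturn.experiment_data import BranchRecord

Outcome = Literal["bird", "nonbird"]


class InsufficientDataError(ValueError):
    """Raised when a stratum or treatment group holds no usable records."""


@dataclass(frozen=True)
class StratumSummary:
    """Loss-rate summary for one stratum (or the pooled experiment)."""

    phase: str
    stratum: str
    outcome: str
    n_branches: int
    mean_rate: float       # mean of per-branch rates
    sem_rate: float        # SEM of per-branch rates (0 for n=1, with warning)
    pooled_rate: float     # lost nuts / total nuts across branches


@dataclass(frozen=True)
class ProportionTestResult:
    """Likelihood-ratio (deviance) test of equal per-nut loss rates."""

    statistic: float
    df: int
    p_value: float


def _round_half_up(x: float) -> int:
    # small epsilon guards against float representations like 2.9499999…
    return int(math.floor(x + 0.5 + 1e-9))


def nonbird_baseline(
    records: Iterable[BranchRecord], phase: str
) -> tuple[float, float]:
    """Baseline non-bird loss rate from netted branches in ``phase``.

    Returns ``(mean, sem)`` of per-branch ``nonbird_loss / initial_count``
    over netted branches. With a single branch the SEM is undefined and
    reported as 0 with a warning.

    Raises
    ------
    InsufficientDataError
        If no netted records exist in the phase.
    """
    rates = [r.rate("nonbird") for r in records if r.treatment == "netted" and r.phase == phase]
    if not rates:
        raise InsufficientDataError(f"no netted records in phase {phase!r}")
    mean = float(np.mean(rates))
    if len(rates) == 1:
        warnings.warn("SEM undefined for a single branch; reporting 0", stacklevel=2)
        return mean, 0.0
    sem = float(np.std(rates, ddof=1) / math.sqrt(len(rates)))
    return mean, sem


def attribute_losses(record: BranchRecord, baseline: float) -> BranchRecord:
    """Split a record's unattributed disappearances into bird / non-bird.

    The non-bird share is ``round(unattributed × baseline)`` (half-up to
    whole nuts); the remainder goes to birds. Count conservation holds by
    construction and ``unattributed_loss`` becomes 0.

    Raises
    ------
    ValueError
        If the record is netted (netted branches have no bird component
        to attribute) or the baseline is outside [0, 1].
    """
    if record.treatment != "open":
        raise ValueError("attribution applies to open branches only")
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline must be within [0, 1], got {baseline}")
    if record.unattributed_loss == 0:
        return record
    to_nonbird = _round_half_up(record.unattributed_loss * baseline)
    to_bird = record.unattributed_loss - to_nonbird
    return record.replace(
        bird_loss=record.bird_loss + to_bird,
        nonbird_loss=record.nonbird_loss + to_nonbird,
        unattributed_loss=0,
    )


def attribute_all(records: Sequence[BranchRecord]) -> list[BranchRecord]:
    """Attribute every open record using the phase's own netted baseline.

    Phases are handled independently: each phase's baseline comes from
    its own netted branches. Netted records pass through unchanged.
    """
    baselines = {}
    out: list[BranchRecord] = []
    for record in records:
        if record.treatment == "netted" or record.unattributed_loss == 0:
            out.append(record)
            continue
        if record.phase not in baselines:
            baselines[record.phase] = nonbird_baseline(records, record.phase)[0]
        out.append(attribute_losses(record, baselines[record.phase]))
    return out


def _open_in_phase(records: Iterable[BranchRecord], phase: str) -> list[BranchRecord]:
    selected = [r for r in records if r.treatment == "open" and r.phase == phase]
    for r in selected:
        if r.unattributed_loss:
            raise ValueError(
                "records contain unattributed losses; run attribute_all/"
                "attribute_losses first"
            )
    return selected


def summarize(
    records: Iterable[BranchRecord],
    phase: str,
    group_by: Literal["pooled", "row_location", "block_id"] = "pooled",
    outcome: Outcome = "bird",
) -> list[StratumSummary]:
    """Per-stratum loss-rate summaries for open branches in ``phase``.

    ``group_by='pooled'`` yields a single summary across the phase;
    ``'row_location'`` splits edge vs interior; ``'block_id'`` splits by
    almond block. Empty strata are omitted with a warning. The result is
    independent of record order.
    """
    selected = _open_in_phase(records, phase)
    if group_by == "pooled":
        groups = {"pooled": selected}
    else:
        groups = {}
        for r in selected:
            groups.setdefault(getattr(r, group_by), []).append(r)
    summaries = []
    for stratum in sorted(groups):
        members = groups[stratum]
        if not members:
            warnings.warn(f"stratum {stratum!r} is empty; omitted", stacklevel=2)
            continue
        # sorting makes the float aggregation exactly permutation-invariant
        rates = np.sort([r.rate(outcome) for r in members])
        if len(rates) == 1:
            warnings.warn("SEM undefined for a single branch; reporting 0", stacklevel=2)
            sem = 0.0
        else:
            sem = float(np.std(rates, ddof=1) / math.sqrt(len(rates)))
        total = sum(r.initial_count for r in members)
        lost = sum(getattr(r, f"{outcome}_loss") for r in members)
        summaries.append(
            StratumSummary(
                phase=phase,
                stratum=str(stratum),
                outcome=outcome,
                n_branches=len(members),
                mean_rate=float(np.mean(rates)),
                sem_rate=sem,
                pooled_rate=lost / total if total else 0.0,
            )
        )
    return summaries


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    # log-likelihood up to the binomial coefficient, which cancels in the LRT
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def compare_strata(
    records: Iterable[BranchRecord],
    phase: str,
    outcome: Outcome = "bird",
    group_by: Literal["row_location", "block_id"] = "row_location",
) -> ProportionTestResult:
    """Likelihood-ratio test for a stratum effect on per-nut loss rates.

    Pools nuts within each stratum and compares a binomial model with one
    loss probability per stratum against a single common probability. The
    deviance is chi-square distributed with (strata − 1) degrees of
    freedom under the null of equal rates. The statistic is zero exactly
    when the pooled stratum rates coincide.

    Raises
    ------
    InsufficientDataError
        If fewer than two strata have records, or a stratum has no nuts.
    """
    selected = _open_in_phase(records, phase)
    groups: dict[str, list[BranchRecord]] = {}
    for r in selected:
        groups.setdefault(getattr(r, group_by), []).append(r)
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need at least two {group_by} strata, found {len(groups)}"
        )
    n = np.array([sum(r.initial_count for r in groups[g]) for g in sorted(groups)], dtype=float)
    k = np.array(
        [sum(getattr(r, f"{outcome}_loss") for r in groups[g]) for g in sorted(groups)],
        dtype=float,
    )
    if np.any(n == 0):
        raise InsufficientDataError("a stratum contains zero nuts")
    p_alt = k / n
    p_null = k.sum() / n.sum()
    statistic = 2.0 * (_binom_loglik(k, n, p_alt) - _binom_loglik(k, n, p_null))
    statistic = max(statistic, 0.0)  # clip float residue at the boundary
    df = len(groups) - 1
    return ProportionTestResult(
        statistic=statistic, df=df, p_value=float(stats.chi2.sf(statistic, df))
    )
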