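"""Survival-curve construction and the AUSC synergy statistic.

The synergy score used across the cell-line panel is the *relative decrease
in the area under the survival curve* (AUSC) between a secondary-drug
dose–response curve measured alone and the same curve measured after
pretreatment with a fixed dose of the primary drug:

    delta_AUSC_rel = (AUSC_single - AUSC_combo) / AUSC_single

Both curves are first normalized to untreated controls, then each curve is
*anchor-normalized* — divided by its own zero-secondary-dose value — so that
the pretreatment drug's single-agent toxicity is removed and only the shape
of the secondary-drug response is compared.  The AUSC itself is a composite
trapezoid integral of survival fraction against either log10(dose) (the
default, matching serial-dilution dose layouts) or the point index.

Positive scores indicate synergy (the combination curve lies below the
single-agent curve); negative scores indicate apparent antagonism, which
anchor normalization can produce for lines strongly sensitive to the
pretreatment drug alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .io_tables import PlateRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "SynergyScore",
    "DensitometryResult",
    "PanelSummary",
    "NormalizationError",
    "InsufficientDataError",
    "AnchorError",
    "GridError",
    "normalize_viability",
    "anchor_normalize",
    "ausc",
    "delta_ausc",
    "panel_screen",
    "densitometry",
    "curves_from_records",
]

AxisMode = Literal["log10_dose", "index"]


class NormalizationError(ValueError):
    """Control signal missing or nonpositive."""


class InsufficientDataError(ValueError):
    """Fewer usable points than the operation requires."""


class AnchorError(ValueError):
    """Curve lacks a positive zero-dose anchor point."""


class GridError(ValueError):
    """Two curves that must share a dose grid do not."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Mean survival fraction versus secondary-drug dose for one condition.

    Doses are in nM and strictly increasing; the first may be 0.  Survival
    values are unitless fractions (values above 1 are legal before anchor
    normalization).  ``sem`` holds the standard error of the mean across
    biological replicates.
    """

    cell_line: str
    condition: str
    doses: tuple[float, ...]
    survival: tuple[float, ...]
    sem: tuple[float, ...]
    n_replicates: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "survival", tuple(float(s) for s in self.survival))
        object.__setattr__(self, "sem", tuple(float(s) for s in self.sem))
        if not (len(self.doses) == len(self.survival) == len(self.sem)):
            raise ValueError("doses, survival and sem must have equal length")
        if len(self.doses) < 2:
            raise InsufficientDataError("a survival curve needs at least 2 dose points")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be nonnegative")
        if any(s < 0 for s in self.survival):
            raise ValueError("survival fractions must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def has_zero_dose(self) -> bool:
        return self.doses[0] == 0.0


@dataclass(frozen=True)
class SynergyScore:
    """AUSC comparison between a single-agent and a combination curve."""

    cell_line: str
    ezh2i: str
    ausc_single: float
    ausc_combo: float
    delta_ausc_abs: float
    delta_ausc_rel: float
    axis_mode: AxisMode
    n_doses: int

    def __post_init__(self) -> None:
        if self.ausc_single > 0:
            expected = (self.ausc_single - self.ausc_combo) / self.ausc_single
            if abs(expected - self.delta_ausc_rel) > 1e-9:
                raise ValueError("delta_ausc_rel inconsistent with AUSC values")


@dataclass(frozen=True)
class DensitometryResult:
    """Western-blot H3K27me3/H3 ratio relative to the untreated control."""

    condition: str
    h3k27me3_signal: float
    h3_total_signal: float
    relative_methylation: float


@dataclass(frozen=True)
class PanelSummary:
    """Panel-wide synergy screen output, sorted by descending synergy."""

    scores: tuple[SynergyScore, ...]
    call_threshold: float
    n_called: int
    n_skipped: int = 0


def _default_control(rec: PlateRecord) -> bool:
    return rec.primary_dose == 0.0 and rec.secondary_dose == 0.0


def normalize_viability(
    records: Sequence[PlateRecord],
    control_condition: Callable[[PlateRecord], bool] | None = None,
    *,
    cell_line: str | None = None,
    condition: str = "",
) -> SurvivalCurve:
    """Build a survival curve from raw well signals.

    Every signal is divided by the pooled mean of the control wells
    (``control_condition``, default: wells with both doses zero — the
    media-treated control).  Replicates are normalized individually before
    averaging, so the SEM reflects biological-replicate spread of the
    normalized values.  If the records are flagged ``is_normalized`` they
    are used as viability fractions directly.
    """
    if not records:
        raise InsufficientDataError("no plate records supplied")
    control_condition = control_condition or _default_control
    if cell_line is None:
        lines = {r.cell_line for r in records}
        if len(lines) != 1:
            raise ValueError(f"records span multiple cell lines {sorted(lines)}; pass cell_line")
        cell_line = lines.pop()

    pre_normalized = all(r.is_normalized for r in records)
    if pre_normalized:
        ctrl_mean = 1.0
    else:
        ctrl = [r.signal for r in records if control_condition(r)]
        if not ctrl:
            raise NormalizationError("no control wells matched the control condition")
        ctrl_mean = float(np.mean(ctrl))
        if ctrl_mean <= 0:
            raise NormalizationError("control mean signal is not positive")

    curve_recs = [r for r in records if not control_condition(r)] or list(records)
    by_dose: dict[float, list[float]] = {}
    for r in curve_recs:
        by_dose.setdefault(r.secondary_dose, []).append(r.signal / ctrl_mean)
    # the dose-0 anchor for this arm: if the control wells themselves sit at
    # secondary dose 0 in the same arm they define survival 1.0 there
    if 0.0 not in by_dose:
        ctrl_at_zero = [r for r in records if control_condition(r) and r.secondary_dose == 0.0]
        if ctrl_at_zero:
            by_dose[0.0] = [r.signal / ctrl_mean for r in ctrl_at_zero]
    if len(by_dose) < 2:
        raise InsufficientDataError("need at least 2 distinct secondary doses")

    doses = sorted(by_dose)
    means, sems = [], []
    for d in doses:
        vals = np.asarray(by_dose[d], dtype=float)
        means.append(float(vals.mean()))
        sems.append(float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    n_rep = max(len(v) for v in by_dose.values())
    return SurvivalCurve(
        cell_line=cell_line,
        condition=condition,
        doses=tuple(doses),
        survival=tuple(means),
        sem=tuple(sems),
        n_replicates=n_rep,
    )


def anchor_normalize(curve: SurvivalCurve) -> SurvivalCurve:
    """Divide the whole curve by its zero-dose survival.

    This isolates curve *shape* from the pretreatment drug's own toxicity:
    after anchoring, the zero-dose point is exactly 1 and any uniform kill
    applied by the pretreatment cancels.  Idempotent.
    """
    if not curve.has_zero_dose:
        raise AnchorError(f"curve {curve.condition!r} has no zero-dose point to anchor on")
    anchor = curve.survival[0]
    if anchor <= 0:
        raise AnchorError(f"zero-dose survival is {anchor}; cannot anchor")
    return replace(
        curve,
        survival=tuple(s / anchor for s in curve.survival),
        sem=tuple(s / anchor for s in curve.sem),
    )


def _axis_coords(curve: SurvivalCurve, axis_mode: AxisMode) -> tuple[np.ndarray, np.ndarray]:
    doses = np.asarray(curve.doses, dtype=float)
    surv = np.asarray(curve.survival, dtype=float)
    if axis_mode == "log10_dose":
        mask = doses > 0  # log10(0) undefined; the anchor point carries no area
        doses, surv = doses[mask], surv[mask]
        if len(doses) < 2:
            raise InsufficientDataError(
                "log10_dose axis needs >= 2 nonzero-dose points"
            )
        return np.log10(doses), surv
    if axis_mode == "index":
        return np.arange(len(doses), dtype=float), surv
    raise ValueError(f"unknown axis_mode {axis_mode!r}")


def ausc(curve: SurvivalCurve, axis_mode: AxisMode = "log10_dose") -> float:
    """Area under the survival curve by the composite trapezoidal method.

    Under ``log10_dose`` the x axis is log10 of the nonzero doses (the
    zero-dose anchor is excluded); under ``index`` it is the 0-based point
    index, giving unit spacing regardless of the dilution scheme.
    """
    x, y = _axis_coords(curve, axis_mode)
    return float(np.trapezoid(y, x))


def delta_ausc(
    single_agent: SurvivalCurve,
    combination: SurvivalCurve,
    axis_mode: AxisMode = "log10_dose",
    *,
    ezh2i: str | None = None,
) -> SynergyScore:
    """Relative AUSC decrease from single-agent to combination curve.

    Both curves must be anchor-normalized and share an identical
    secondary-drug dose grid.  Positive values mean the combination curve
    lies lower (synergy); the score is in (-inf, 1].
    """
    if single_agent.doses != combination.doses:
        raise GridError(
            f"dose grids differ: {single_agent.doses} vs {combination.doses}"
        )
    a_single = ausc(single_agent, axis_mode)
    a_combo = ausc(combination, axis_mode)
    if a_single <= 0:
        raise ZeroDivisionError(
            "single-agent AUSC is zero; relative decrease undefined"
        )
    return SynergyScore(
        cell_line=single_agent.cell_line,
        ezh2i=ezh2i if ezh2i is not None else combination.condition,
        ausc_single=a_single,
        ausc_combo=a_combo,
        delta_ausc_abs=a_single - a_combo,
        delta_ausc_rel=(a_single - a_combo) / a_single,
        axis_mode=axis_mode,
        n_doses=len(single_agent.doses),
    )


def panel_screen(
    panel: Iterable[tuple[SurvivalCurve, SurvivalCurve]],
    axis_mode: AxisMode = "log10_dose",
    *,
    call_threshold: float = 0.1,
    anchor: bool = True,
) -> PanelSummary:
    """Score a panel of (single-agent, combination) curve pairs.

    Each pair yields one :class:`SynergyScore`; pairs whose single-agent
    curve is missing or unusable are skipped with a warning.  Scores are
    returned sorted by descending synergy, with a count of lines exceeding
    ``call_threshold`` (a reporting convenience, not a statistical test).
    """
    scores: list[SynergyScore] = []
    n_skipped = 0
    for single, combo in panel:
        if single is None:
            logger.warning("cell line %r missing its single-agent curve; skipped",
                           combo.cell_line if combo is not None else "?")
            n_skipped += 1
            continue
        try:
            if anchor:
                single = anchor_normalize(single)
                combo = anchor_normalize(combo)
            scores.append(delta_ausc(single, combo, axis_mode))
        except (AnchorError, GridError, InsufficientDataError, ZeroDivisionError) as exc:
            logger.warning("cell line %r skipped: %s", single.cell_line, exc)
            n_skipped += 1
    scores.sort(key=lambda s: s.delta_ausc_rel, reverse=True)
    n_called = sum(1 for s in scores if s.delta_ausc_rel > call_threshold)
    return PanelSummary(
        scores=tuple(scores),
        call_threshold=call_threshold,
        n_called=n_called,
        n_skipped=n_skipped,
    )


def densitometry(
    treated: tuple[float, float],
    untreated_ref: tuple[float, float],
    *,
    condition: str = "",
) -> DensitometryResult:
    """Relative H3K27 tri-methylation from dual-channel western densitometry.

    Each argument is a ``(h3k27me3_signal, total_h3_signal)`` pair.  The
    treated me3/H3 ratio is divided by the untreated ratio, so 1.0 means no
    change from the untreated control.
    """
    me3_t, h3_t = treated
    me3_u, h3_u = untreated_ref
    if min(me3_t, h3_t, me3_u, h3_u) < 0:
        raise ValueError("densitometry signals must be nonnegative")
    if h3_t <= 0 or h3_u <= 0:
        raise ValueError("total-H3 signal must be positive")
    ref_ratio = me3_u / h3_u
    if ref_ratio <= 0:
        raise ValueError("untreated me3/H3 ratio must be positive")
    return DensitometryResult(
        condition=condition,
        h3k27me3_signal=me3_t,
        h3_total_signal=h3_t,
        relative_methylation=(me3_t / h3_t) / ref_ratio,
    )


def curves_from_records(
    records: Sequence[PlateRecord],
) -> dict[str, dict[str, SurvivalCurve]]:
    """Group plate records into per-line, per-arm survival curves.

    Within each cell line, wells are split into arms by (primary drug,
    primary dose, schedule).  The untreated wells (both doses zero) are the
    normalization control shared by all arms of that line.  Returns
    ``{cell_line: {arm_label: curve}}`` with arm labels like ``"CTRL"`` or
    ``"EPZ-6438@5.0uM"``; curves are normalized to the untreated control but
    *not* anchor-normalized.
    """
    by_line: dict[str, list[PlateRecord]] = {}
    for r in records:
        by_line.setdefault(r.cell_line, []).append(r)
    out: dict[str, dict[str, SurvivalCurve]] = {}
    for line, recs in by_line.items():
        arms: dict[tuple, list[PlateRecord]] = {}
        for r in recs:
            if r.primary_dose > 0 and r.primary_drug:
                key = (r.primary_drug, r.primary_dose, r.schedule)
            else:
                key = (None, 0.0, r.schedule)
            arms.setdefault(key, []).append(r)
        controls = [r for r in recs if _default_control(r)]
        out[line] = {}
        for (drug, dose, schedule), arm_recs in arms.items():
            label = "CTRL" if drug is None else f"{drug}@{dose:g}uM"
            pool = arm_recs + [c for c in controls if c not in arm_recs]
            try:
                curve = normalize_viability(
                    pool, _default_control, cell_line=line, condition=label
                )
            except (NormalizationError, InsufficientDataError) as exc:
                logger.warning("arm %s/%s unusable: %s", line, label, exc)
                continue
            out[line][label] = curve
    return out
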