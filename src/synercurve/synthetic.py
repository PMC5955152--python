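"""Synthetic viability panels and DE tables with known ground truth.

Two generators provide a no-download test bed for the whole pipeline:

* :func:`simulate_viability_panel` draws plate readouts from a Hill
  dose–response model.  Pretreatment synergy is modeled as a potency
  (EC50) shift of the secondary drug applied only in the combination arm of
  selected lines; pretreatment single-agent toxicity is a uniform kill
  fraction, which anchor normalization must cancel.  Noise is
  multiplicative lognormal, matching positive, scale-proportional
  luminescence readouts.
* :func:`simulate_de_tables` emits three generic-dialect DE tables (agent
  A, agent B, combination) with planted shared and combination-unique
  effect genes, null genes with uniform p-values, and Benjamini–Hochberg
  FDR columns, plus the ground-truth membership lists.

All randomness flows from one explicit seed through one generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_tables import DERecord, PlateRecord

__all__ = [
    "HillSpec",
    "ComboSpec",
    "DESimSpec",
    "SimulatedDE",
    "hill_survival",
    "simulate_viability_panel",
    "simulate_de_tables",
]

PLATE_SCALE = 1.0e4  # arbitrary luminescence units for a fully viable well

DEFAULT_DOSES = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)  # nM, serial-ish dilution


@dataclass(frozen=True)
class HillSpec:
    """Parameters of the sigmoidal kill curve for the secondary drug.

    ``emax`` is the maximal kill fraction (1 = complete kill at saturating
    dose), ``ec50`` the half-effect concentration in nM, ``hill`` the slope,
    ``noise_sigma`` the scale of multiplicative lognormal well noise.
    """

    emax: float = 0.95
    ec50: float = 10.0  # nM
    hill: float = 1.5
    noise_sigma: float = 0.05
    n_replicates: int = 3
    doses: tuple[float, ...] = DEFAULT_DOSES

    def __post_init__(self) -> None:
        if not (0.0 <= self.emax <= 1.0):
            raise ValueError("emax must be in [0,1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        d = tuple(float(x) for x in self.doses)
        if len(d) < 3 or d[0] != 0.0 or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("doses must start at 0 and be strictly increasing")
        object.__setattr__(self, "doses", d)


@dataclass(frozen=True)
class ComboSpec:
    """Combination-arm parameters on top of a base Hill curve.

    ``potency_shift`` is the fold-reduction of the secondary drug's EC50
    produced by pretreatment (1 = no synergy); ``pretreat_kill`` is the
    viability fraction lost to the pretreatment drug alone, applied
    uniformly across the combination arm.
    """

    base: HillSpec = field(default_factory=HillSpec)
    potency_shift: float = 4.0
    pretreat_kill: float = 0.2
    ezh2i_name: str = "EZH2i"
    ezh2i_dose_uM: float = 5.0
    secondary_name: str = "panobinostat"
    schedule: str = "pretreat_4d"

    def __post_init__(self) -> None:
        if self.potency_shift < 1:
            raise ValueError("potency_shift must be >= 1 (1 encodes no synergy)")
        if not (0.0 <= self.pretreat_kill < 1.0):
            raise ValueError("pretreat_kill must be in [0,1)")


def hill_survival(dose: float, emax: float, ec50: float, hill: float) -> float:
    """Noise-free survival fraction of the Hill kill model at one dose."""
    if dose == 0.0:
        return 1.0
    frac = dose**hill / (dose**hill + ec50**hill)
    return 1.0 - emax * frac


def simulate_viability_panel(
    spec: ComboSpec,
    n_lines: int,
    synergy_lines: Sequence[int] | None,
    seed: int,
) -> list[PlateRecord]:
    """Simulate a cell-line panel with CTRL and pretreatment arms.

    Each line contributes two arms over the same secondary-drug dose grid:
    a control arm (no pretreatment) and a combination arm.  Lines listed in
    ``synergy_lines`` (indices, 0-based; ``None`` = all lines) receive the
    EC50 potency shift in their combination arm; every combination-arm well
    additionally loses ``pretreat_kill`` of viability.  Deterministic for a
    given seed.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    synergy = set(range(n_lines)) if synergy_lines is None else set(synergy_lines)
    if synergy - set(range(n_lines)):
        raise ValueError("synergy_lines contains indices outside the panel")
    base = spec.base
    records: list[PlateRecord] = []
    for i in range(n_lines):
        line = f"HMCL{i + 1:02d}"
        for arm in ("CTRL", "COMBO"):
            combo = arm == "COMBO"
            ec50_eff = base.ec50 / spec.potency_shift if (combo and i in synergy) else base.ec50
            pre = 1.0 - spec.pretreat_kill if combo else 1.0
            for dose in base.doses:
                mean_surv = pre * hill_survival(dose, base.emax, ec50_eff, base.hill)
                for rep in range(1, base.n_replicates + 1):
                    eps = rng.normal(0.0, base.noise_sigma) if base.noise_sigma > 0 else 0.0
                    records.append(
                        PlateRecord(
                            cell_line=line,
                            primary_drug=spec.ezh2i_name if combo else None,
                            primary_dose=spec.ezh2i_dose_uM if combo else 0.0,
                            secondary_drug=spec.secondary_name if dose > 0 else None,
                            secondary_dose=dose,
                            schedule=spec.schedule,
                            replicate=rep,
                            signal=PLATE_SCALE * mean_surv * math.exp(eps),
                        )
                    )
    return records


@dataclass(frozen=True)
class DESimSpec:
    """Parameters of the three-condition DE-table generator.

    Effect genes are drawn from the clearly expressed fraction of the
    transcriptome (baseline FPKM >= ``expressed_fpkm_min``): an effect
    planted below the expression floor could never be called by a filter
    that requires FPKM >= 1, so such genes stay null.  The combination
    retains ``frac_shared_combo`` of each single agent's effects and adds
    ``frac_unique_combo`` of all genes as combination-only effects, biased
    toward upregulation (``unique_up_bias``) as expected when two
    transcriptional repressor systems are inhibited together.
    """

    n_genes: int = 10_000
    frac_up_a: float = 0.04
    frac_down_a: float = 0.015
    frac_up_b: float = 0.005
    frac_down_b: float = 0.005
    frac_shared_combo: float = 0.8
    frac_unique_combo: float = 0.10
    unique_up_bias: float = 0.75
    effect_log2fc: float = 2.0
    baseline_fpkm_log_mean: float = 1.0  # natural-log scale
    baseline_fpkm_log_sd: float = 1.5
    dispersion: float = 0.2  # lognormal sigma on each observed FPKM
    expressed_fpkm_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_up_a,
            self.frac_down_a,
            self.frac_up_b,
            self.frac_down_b,
            self.frac_shared_combo,
            self.frac_unique_combo,
            self.unique_up_bias,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0,1]")
        planted = (
            self.frac_up_a
            + self.frac_down_a
            + self.frac_up_b
            + self.frac_down_b
            + self.frac_unique_combo
        )
        if planted > 1.0:
            raise ValueError("planted fractions sum to more than 1")
        if self.n_genes < 1 or self.effect_log2fc <= 0:
            raise ValueError("n_genes must be >= 1 and effect_log2fc positive")
        if self.dispersion < 0 or self.baseline_fpkm_log_sd <= 0:
            raise ValueError("invalid noise parameters")


@dataclass(frozen=True)
class SimulatedDE:
    """Three DE tables plus the planted ground truth."""

    agent_a: tuple[DERecord, ...]
    agent_b: tuple[DERecord, ...]
    combo: tuple[DERecord, ...]
    truth_a_up: frozenset[str]
    truth_a_down: frozenset[str]
    truth_b_up: frozenset[str]
    truth_b_down: frozenset[str]
    truth_combo_up: frozenset[str]
    truth_combo_down: frozenset[str]
    truth_unique: frozenset[str]

    def truth_dict(self) -> dict[str, list[str]]:
        return {
            "agent_a_up": sorted(self.truth_a_up),
            "agent_a_down": sorted(self.truth_a_down),
            "agent_b_up": sorted(self.truth_b_up),
            "agent_b_down": sorted(self.truth_b_down),
            "combo_up": sorted(self.truth_combo_up),
            "combo_down": sorted(self.truth_combo_down),
            "unique_to_combo": sorted(self.truth_unique),
        }


def _make_table(
    rng: np.random.Generator,
    genes: np.ndarray,
    baseline: np.ndarray,
    true_l2fc: np.ndarray,
    dispersion: float,
    condition: str,
) -> tuple[DERecord, ...]:
    n = len(genes)
    obs_c = baseline * np.exp(rng.normal(0.0, dispersion, n))
    obs_t = baseline * 2.0**true_l2fc * np.exp(rng.normal(0.0, dispersion, n))
    with np.errstate(divide="ignore"):
        l2fc = np.log2(obs_t / obs_c)
    # p-values from a z-model: planted effects shift the test statistic by
    # effect / (noise of the log2FC estimate)
    fc_noise_sd = math.sqrt(2.0) * dispersion / math.log(2.0) if dispersion > 0 else 1.0
    z = true_l2fc / fc_noise_sd + rng.normal(0.0, 1.0, n)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return tuple(
        DERecord(
            gene_id=str(g),
            fpkm_control=float(c),
            fpkm_treated=float(t),
            log2_fc=float(f),
            p_value=float(pv),
            fdr=float(q),
            condition=condition,
        )
        for g, c, t, f, pv, q in zip(genes, obs_c, obs_t, l2fc, p, fdr)
    )


def simulate_de_tables(spec: DESimSpec) -> SimulatedDE:
    """Generate agent-A, agent-B and combination DE tables with truth lists.

    Null genes carry log2FC measurement noise around 0 and uniform-ish
    p-values (their z statistic is standard normal); planted genes carry
    log2 effects of mean magnitude ``effect_log2fc`` (jittered ±25%) and
    correspondingly small p-values.  FDR columns are Benjamini–Hochberg
    within each table.  Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = np.array([f"G{i:06d}" for i in range(n)])
    baseline = rng.lognormal(spec.baseline_fpkm_log_mean, spec.baseline_fpkm_log_sd, n)

    expressed = np.flatnonzero(baseline >= spec.expressed_fpkm_min)
    counts = {
        "up_a": round(spec.frac_up_a * n),
        "down_a": round(spec.frac_down_a * n),
        "up_b": round(spec.frac_up_b * n),
        "down_b": round(spec.frac_down_b * n),
        "unique": round(spec.frac_unique_combo * n),
    }
    need = sum(counts.values())
    if need > len(expressed):
        raise ValueError(
            f"requested {need} effect genes but only {len(expressed)} genes "
            f"have baseline FPKM >= {spec.expressed_fpkm_min}"
        )
    chosen = rng.choice(expressed, size=need, replace=False)
    idx: dict[str, np.ndarray] = {}
    offset = 0
    for key, k in counts.items():
        idx[key] = chosen[offset : offset + k]
        offset += k
    n_uniq_up = round(spec.unique_up_bias * counts["unique"])
    idx["unique_up"] = idx["unique"][:n_uniq_up]
    idx["unique_down"] = idx["unique"][n_uniq_up:]

    def effects(k: int) -> np.ndarray:
        # mean magnitude effect_log2fc, jittered uniformly by +/-25%
        return spec.effect_log2fc * rng.uniform(0.75, 1.25, k)

    l2fc_a = np.zeros(n)
    l2fc_a[idx["up_a"]] = effects(len(idx["up_a"]))
    l2fc_a[idx["down_a"]] = -effects(len(idx["down_a"]))
    l2fc_b = np.zeros(n)
    l2fc_b[idx["up_b"]] = effects(len(idx["up_b"]))
    l2fc_b[idx["down_b"]] = -effects(len(idx["down_b"]))

    # the combination keeps frac_shared_combo of each agent's effects ...
    l2fc_c = np.zeros(n)
    for source in (l2fc_a, l2fc_b):
        hit = np.flatnonzero(source)
        keep = hit[rng.random(len(hit)) < spec.frac_shared_combo]
        l2fc_c[keep] = source[keep]
    # ... and adds the combination-only block
    l2fc_c[idx["unique_up"]] = effects(len(idx["unique_up"]))
    l2fc_c[idx["unique_down"]] = -effects(len(idx["unique_down"]))

    table_a = _make_table(rng, genes, baseline, l2fc_a, spec.dispersion, "agent_a")
    table_b = _make_table(rng, genes, baseline, l2fc_b, spec.dispersion, "agent_b")
    table_c = _make_table(rng, genes, baseline, l2fc_c, spec.dispersion, "combo")

    def gset(i: np.ndarray) -> frozenset[str]:
        return frozenset(genes[i])

    return SimulatedDE(
        agent_a=table_a,
        agent_b=table_b,
        combo=table_c,
        truth_a_up=gset(idx["up_a"]),
        truth_a_down=gset(idx["down_a"]),
        truth_b_up=gset(idx["up_b"]),
        truth_b_down=gset(idx["down_b"]),
        truth_combo_up=frozenset(genes[np.flatnonzero(l2fc_c > 0)]),
        truth_combo_down=frozenset(genes[np.flatnonzero(l2fc_c < 0)]),
        truth_unique=gset(idx["unique"]),
    )
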