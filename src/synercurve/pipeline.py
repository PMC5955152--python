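"""End-to-end orchestration: screen, desets and simulate runs.

Each run function consumes a :class:`RunConfig`, writes its tabular outputs
as CSV/TSV and a JSON summary that embeds the fully resolved configuration
(provenance), and returns the summary dict.  Reruns with the same inputs,
config and seed are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .de_sets import FilterSpec, GeneSet, filter_de, unique_to_combination, venn_counts
from .dose_response import AxisMode, curves_from_records, panel_screen
from .io_tables import (
    read_de_table,
    read_viability_table,
    write_de_table,
    write_viability_table,
)
from .synthetic import ComboSpec, DESimSpec, simulate_de_tables, simulate_viability_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen", "run_desets", "run_simulate_viability", "run_simulate_de"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Built from a YAML file with flat keys mirroring the CLI flags; CLI flags
    override file values.
    """

    viability_table: str | None = None
    de_tables: tuple[str, ...] = ()
    de_dialect: str = "generic"
    single_agent_arm: str = "CTRL"
    combo_arm: str | None = None  # None = the unique non-CTRL arm per line
    axis_mode: AxisMode = "log10_dose"
    call_threshold: float = 0.1
    fdr_max: float = 0.05
    fpkm_min: float = 1.0
    fc_min: float = 2.0
    direction_aware: bool = False
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "de_tables" in data:
            data["de_tables"] = tuple(data["de_tables"])
        return cls(**data)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(fdr_max=self.fdr_max, fpkm_min=self.fpkm_min, fc_min=self.fc_min)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["de_tables"] = list(d["de_tables"])
        d["software_version"] = __version__
        return d


def _write_summary(summary: dict, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_screen(config: RunConfig) -> dict:
    """Viability table -> per-line synergy scores CSV + JSON summary.

    For each cell line the control-arm curve is paired with each
    pretreatment-arm curve; lines lacking either arm are skipped with a
    warning.  Output CSV columns: cell_line, ezh2i, ausc_single,
    ausc_combo, delta_ausc_abs, delta_ausc_rel, axis_mode, n_doses.
    """
    if not config.viability_table:
        raise FileNotFoundError("screen run requires a viability table path")
    path = Path(config.viability_table)
    if not path.exists():
        raise FileNotFoundError(f"viability table not found: {path}")
    records = read_viability_table(path)
    curves = curves_from_records(records)

    pairs = []
    grids: dict[str, list[float]] = {}
    for line, arms in sorted(curves.items()):
        single = arms.get(config.single_agent_arm)
        combo_labels = (
            [config.combo_arm]
            if config.combo_arm
            else [a for a in arms if a != config.single_agent_arm]
        )
        if single is None:
            logger.warning("line %r has no %r arm; skipped", line, config.single_agent_arm)
            continue
        for label in combo_labels:
            combo = arms.get(label)
            if combo is None:
                logger.warning("line %r has no %r arm; skipped", line, label)
                continue
            pairs.append((single, combo))
            grids[line] = list(single.doses)

    summary_panel = panel_screen(
        pairs, config.axis_mode, call_threshold=config.call_threshold
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "synergy.csv"
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write(
            "cell_line,ezh2i,ausc_single,ausc_combo,delta_ausc_abs,delta_ausc_rel,axis_mode,n_doses\n"
        )
        for s in summary_panel.scores:
            fh.write(
                f"{s.cell_line},{s.ezh2i},{s.ausc_single!r},{s.ausc_combo!r},"
                f"{s.delta_ausc_abs!r},{s.delta_ausc_rel!r},{s.axis_mode},{s.n_doses}\n"
            )
    summary = {
        "config": config.as_dict(),
        "n_lines_scored": len(summary_panel.scores),
        "n_skipped": summary_panel.n_skipped,
        "call_threshold": summary_panel.call_threshold,
        "n_called": summary_panel.n_called,
        "dose_grids": grids,
        "scores": [
            {
                "cell_line": s.cell_line,
                "ezh2i": s.ezh2i,
                "delta_ausc_rel": s.delta_ausc_rel,
                "delta_ausc_abs": s.delta_ausc_abs,
            }
            for s in summary_panel.scores
        ],
        "outputs": {"synergy_csv": str(csv_path)},
    }
    _write_summary(summary, out_dir, "screen_summary.json")
    return summary


def _geneset_counts(gs: GeneSet) -> dict:
    return {"up": len(gs.up), "down": len(gs.down), "total": len(gs)}


def run_desets(config: RunConfig) -> dict:
    """DE tables -> per-condition counts, Venn regions and unique lists.

    Counts are reported at the configured fold-change threshold and at the
    lenient 1.5-fold threshold.  With three tables (agent A, agent B,
    combination, in argument order) the unique-to-combination gene list is
    written alongside the Venn regions; with a single table only the counts
    section is produced.
    """
    if not config.de_tables:
        raise FileNotFoundError("desets run requires at least one DE table path")
    for t in config.de_tables:
        if not Path(t).exists():
            raise FileNotFoundError(f"DE table not found: {t}")
    spec = config.filter_spec()
    lenient = FilterSpec(fdr_max=spec.fdr_max, fpkm_min=spec.fpkm_min, fc_min=1.5)

    tables = []
    for t in config.de_tables:
        name = Path(t).stem
        tables.append((name, read_de_table(t, config.de_dialect, condition=name)))

    sets = {name: filter_de(tab, spec) for name, tab in tables}
    sets_lenient = {name: filter_de(tab, lenient) for name, tab in tables}

    summary: dict = {
        "config": config.as_dict(),
        "counts": {
            name: {
                f"fc_{spec.fc_min:g}": _geneset_counts(sets[name]),
                "fc_1.5": _geneset_counts(sets_lenient[name]),
            }
            for name, _ in tables
        },
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if len(tables) >= 2:
        venn = venn_counts(list(sets.values()), direction_aware=config.direction_aware)
        summary["venn_regions"] = {
            "&".join(sorted(region)): n for region, n in sorted(
                venn.region_counts.items(), key=lambda kv: sorted(kv[0])
            )
        }
    if len(tables) == 3:
        (name_a, _), (name_b, _), (name_c, _) = tables
        uniq = unique_to_combination(sets[name_a], sets[name_b], sets[name_c])
        summary["unique_to_combination"] = {
            "up": sorted(uniq.up),
            "down": sorted(uniq.down),
            "counts": _geneset_counts(uniq),
        }
        with open(out_dir / "unique_to_combination.txt", "w", encoding="utf-8") as fh:
            for g in sorted(uniq.members):
                fh.write(g + "\n")
    _write_summary(summary, out_dir, "desets_summary.json")
    return summary


def run_simulate_viability(
    spec: ComboSpec, n_lines: int, synergy_lines: Sequence[int] | None, seed: int, out: str | Path
) -> dict:
    records = simulate_viability_panel(spec, n_lines, synergy_lines, seed)
    write_viability_table(records, out)
    return {"n_records": len(records), "out": str(out), "seed": seed}


def run_simulate_de(spec: DESimSpec, out_dir: str | Path) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_de_tables(spec)
    for name, table in (
        ("agent_a", sim.agent_a),
        ("agent_b", sim.agent_b),
        ("combo", sim.combo),
    ):
        write_de_table(table, out_dir / f"{name}.tsv")
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(sim.truth_dict(), fh, indent=2)
        fh.write("\n")
    return {"out_dir": str(out_dir), "n_genes": spec.n_genes, "seed": spec.seed}
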