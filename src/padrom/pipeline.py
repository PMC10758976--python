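"""End-to-end orchestration: generate/load -> ROM -> statistics -> comfort.

``run_pipeline`` takes a single serialisable :class:`RunConfig`, produces the
long-format ROM table, per-joint-plane condition-comparison statistics
(means +- SD, GG-corrected RM-ANOVA, partial eta-squared, LSD significance
markers), normalised ROM (pad / no-pads), the survey summary and the
comfort-ROM correlation report, and writes everything beside a copy of the
config and a run log.  Outputs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import comfort as cf
from .rom import (
    CONDITIONS,
    DYNAMIC_PLANES,
    DYNAMIC_TASKS,
    PAD_CONDITIONS,
    STATIC_TASKS,
    TASK_PHASES,
    ExtractionConfig,
    condition_matrix,
    extract_study_records,
    normalize_rom,
)
from .stats import classify_eta_sq, lsd_posthoc, rm_anova_gg
from .synth import GeneratorConfig, generate_study, generate_survey

logger = logging.getLogger("padrom.pipeline")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_condition_tables"]

_FLOAT_FMT = "%.9g"


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    output_dir: str = "padrom_run"
    input_dir: Optional[str] = None  # study directory; None -> synthesise
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    alpha: float = 0.05
    seed: int = 0
    resume: bool = False
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        self.generator.seed = self.seed

    # -- YAML round trip (factor dicts use joined string keys) ------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["static_factors"] = {"|".join(k): v for k, v in gen["static_factors"].items()}
        gen["dynamic_factors"] = {"|".join(k): v for k, v in gen["dynamic_factors"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.get("generator", {}))
        for key in ("static_factors", "dynamic_factors"):
            if key in gen:
                gen[key] = {tuple(k.split("|")): v for k, v in gen[key].items()}
        d["generator"] = GeneratorConfig(**gen) if gen else GeneratorConfig()
        d["extraction"] = ExtractionConfig(**d.get("extraction", {}))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    output_dir: Path
    rom_table: pd.DataFrame
    stats_static: pd.DataFrame
    stats_wrist: pd.DataFrame
    stats_slap: pd.DataFrame
    normalized: pd.DataFrame
    comfort_summary: pd.DataFrame
    correlations: pd.DataFrame


# ------------------------------------------------------------ statistics


def _stats_row(mat: pd.DataFrame, alpha: float) -> dict:
    res = rm_anova_gg(mat)
    row: dict = {}
    for cond in CONDITIONS:
        row[f"{cond}_mean"] = float(mat[cond].mean())
        row[f"{cond}_sd"] = float(mat[cond].std(ddof=1))
    row.update(
        F=res.f_stat,
        p=res.p_value,
        gg_epsilon=res.gg_epsilon,
        eta_sq=res.partial_eta_sq,
        effect_band=classify_eta_sq(res.partial_eta_sq),
    )
    markers = {cond: [] for cond in CONDITIONS}
    if res.p_value < alpha:
        post = lsd_posthoc(mat)
        for a, b in post.significant_pairs(alpha):
            markers[a].append(str(CONDITIONS.index(b) + 1))
            markers[b].append(str(CONDITIONS.index(a) + 1))
    for cond in CONDITIONS:
        row[f"{cond}_sig"] = ",".join(sorted(markers[cond], key=int))
    return row


def _stats_table(rom_table: pd.DataFrame, rows: list[tuple], alpha: float) -> pd.DataFrame:
    out = {}
    for label, task, plane, phase in rows:
        mat = condition_matrix(rom_table, task, plane, phase)
        if mat.shape[1] < 2 or mat.isna().any().any():
            missing = mat.columns[mat.isna().any()].tolist() if mat.size else "all"
            raise ValueError(f"incomplete design for {label}: missing cells in {missing}")
        out[label] = _stats_row(mat, alpha)
    df = pd.DataFrame.from_dict(out, orient="index")
    if isinstance(df.index, pd.MultiIndex):
        df.index.names = ["task", "phase", "joint_plane"]
    else:
        df.index.name = "variable"
    return df


def _normalized_table(rom_table: pd.DataFrame) -> pd.DataFrame:
    cell = (
        rom_table.groupby(["task", "phase", "joint_plane", "condition"])["rom_deg"]
        .mean()
        .unstack("condition")
    )
    rows = []
    for idx, row in cell.iterrows():
        control = row["no_pads"]
        for pad in PAD_CONDITIONS:
            rows.append(
                {
                    "task": idx[0],
                    "phase": idx[1],
                    "joint_plane": idx[2],
                    "condition": pad,
                    "normalized_rom": normalize_rom(row[pad], control),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ comfort


def _comfort_outputs(
    rom_table: pd.DataFrame,
    survey: pd.DataFrame,
    stats_dynamic: pd.DataFrame,
    alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    means = cf.aggregate_likert(survey)
    comfort = cf.comfort_score(means)
    sig_dynamic = stats_dynamic[stats_dynamic["p"] < alpha].index.tolist()

    def dyn_total(cond: str) -> float:
        if not sig_dynamic:
            return 0.0
        total = 0.0
        sel = rom_table[rom_table["task"].isin(DYNAMIC_TASKS)]
        cell = sel.groupby(["task", "phase", "joint_plane", "condition"])["rom_deg"].mean()
        for label in sig_dynamic:
            task, phase, plane = label
            total += float(cell.loc[(task, phase, plane, cond)])
        return total

    rows = []
    for pad in PAD_CONDITIONS:
        static_total = cf.total_rom(rom_table, pad, tasks=STATIC_TASKS)
        rows.append(
            {
                "pad": pad,
                "comfort": float(comfort[pad]),
                "static_total_rom": static_total,
                "dynamic_total_rom": dyn_total(pad),
            }
        )
    summary = pd.DataFrame(rows).set_index("pad")
    summary["total_rom"] = summary["static_total_rom"] + summary["dynamic_total_rom"]
    for prot in cf.PROTECTORS:
        for q in cf.QUESTIONS:
            summary[f"{prot}_{q}_mean"] = [means.loc[p, (prot, q)] for p in summary.index]

    corr_rows = []
    for label, col in [
        ("static", "static_total_rom"),
        ("dynamic", "dynamic_total_rom"),
        ("combined", "total_rom"),
    ]:
        roms = summary[col]
        if roms.nunique() <= 1:
            corr_rows.append({"tasks": label, "rho": np.nan, "p": np.nan, "band": "undefined"})
            continue
        sums = [
            cf.PadComfortSummary(pad, means.loc[[pad]], float(comfort[pad]), float(roms[pad]))
            for pad in summary.index
        ]
        rho, p, band = cf.comfort_rom_correlation(sums)
        corr_rows.append({"tasks": label, "rho": rho, "p": p, "band": band})
    return summary, pd.DataFrame(corr_rows).set_index("tasks")


# ------------------------------------------------------------ formatting


def make_condition_tables(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Render a stats table as publication-style strings.

    Means are shown to one decimal as ``mean +- sd`` with the indices of
    significantly different conditions as a superscript list; F, p and
    eta_p^2 are rounded to three decimals.
    """
    out = pd.DataFrame(index=stats_table.index)
    for cond in CONDITIONS:
        cells = []
        for _, row in stats_table.iterrows():
            sup = row[f"{cond}_sig"]
            cells.append(
                f"{row[f'{cond}_mean']:.1f} ± {row[f'{cond}_sd']:.1f}"
                + (f"^{sup}" if sup else "")
            )
        out[cond] = cells
    out["p"] = ["<0.01" if p < 0.01 else f"{p:.3f}" for p in stats_table["p"]]
    out["F"] = [f"{v:.3f}" for v in stats_table["F"]]
    out["eta_sq"] = [f"{v:.3f}" for v in stats_table["eta_sq"]]
    return out


# ------------------------------------------------------------ pipeline


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all outputs to the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("padrom")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        config.save(out / "config.yaml")
        rom_path = out / "rom_table.csv"
        if config.resume and rom_path.exists():
            logger.info("resuming from existing ROM table %s", rom_path)
            rom_table = pd.read_csv(rom_path)
        else:
            if config.input_dir is not None:
                from .io import load_study_trials

                trials = load_study_trials(config.input_dir)
            else:
                logger.info("synthesising study with seed %d", config.seed)
                trials = (trial for trial, _ in generate_study(config.generator))
            rom_table = extract_study_records(trials, config.extraction)
            rom_table.to_csv(rom_path, index=False, float_format=_FLOAT_FMT)

        stats_static = _stats_table(
            rom_table,
            [(task, task, task, "static") for task in STATIC_TASKS],
            config.alpha,
        )
        dyn_rows = {
            "wrist_shot": [], "slap_shot": [],
        }
        for task in DYNAMIC_TASKS:
            for phase in TASK_PHASES[task]:
                for plane in DYNAMIC_PLANES:
                    for side in ("l", "r"):
                        dyn_rows[task].append(
                            ((task, phase, f"{plane}_{side}"), task, f"{plane}_{side}", phase)
                        )
        stats_wrist = _stats_table(rom_table, dyn_rows["wrist_shot"], config.alpha)
        stats_slap = _stats_table(rom_table, dyn_rows["slap_shot"], config.alpha)
        normalized = _normalized_table(rom_table)

        if config.input_dir is not None:
            from .io import read_survey_csv

            survey = read_survey_csv(Path(config.input_dir) / "survey.csv")
        else:
            survey = generate_survey(config.generator)
        stats_dynamic = pd.concat([stats_wrist, stats_slap])
        comfort_summary, correlations = _comfort_outputs(
            rom_table, survey, stats_dynamic, config.alpha
        )

        def _write(df: pd.DataFrame, name: str, index: bool = True) -> None:
            df.to_csv(out / name, index=index, float_format=_FLOAT_FMT)

        for table, name in [
            (stats_static, "stats_static.csv"),
            (stats_wrist, "stats_wrist.csv"),
            (stats_slap, "stats_slap.csv"),
            (comfort_summary, "comfort_summary.csv"),
            (correlations, "correlation_report.csv"),
        ]:
            _write(table, name)
        _write(normalized, "normalized_rom.csv", index=False)
        for table, name in [
            (stats_static, "table_static.csv"),
            (stats_wrist, "table_wrist.csv"),
            (stats_slap, "table_slap.csv"),
        ]:
            make_condition_tables(table).to_csv(out / name)
        logger.info("pipeline complete: %d ROM rows", len(rom_table))
        return RunResult(
            out, rom_table, stats_static, stats_wrist, stats_slap,
            normalized, comfort_summary, correlations,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
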