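"""Likert survey aggregation and the comfort-mobility relationship.

After each pad condition the players rate four statements on a 1-5 Likert
scale (1 = strongly disagree .. 5 = strongly agree), separately for the
shoulder and the elbow protector: Q1 comfort, Q2 safety, Q3 perceived
motion restriction, Q4 willingness to wear.  Scores are treated as ordinal
for testing (Friedman / Wilcoxon, see :mod:`padrom.stats`) but averaged for
descriptive ranking.  The objective counterpart is the total upper-body ROM
per pad (condition means summed over a stated task set); comfort and total
ROM are related by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rom import PAD_CONDITIONS
from .stats import classify_correlation, spearman_corr

__all__ = [
    "QUESTIONS",
    "PROTECTORS",
    "LikertResponse",
    "PadComfortSummary",
    "aggregate_likert",
    "rank_pads",
    "total_rom",
    "comfort_score",
    "comfort_rom_correlation",
]

QUESTIONS = ("q1_comfort", "q2_safe", "q3_restricts", "q4_would_wear")
PROTECTORS = ("shoulder", "elbow")


@dataclass(frozen=True)
class LikertResponse:
    """One participant's answer to one question for one protector of one pad."""

    participant_id: str
    pad: str
    protector: str
    question: str
    score: int

    def __post_init__(self) -> None:
        if self.pad not in PAD_CONDITIONS:
            raise ValueError(f"unknown pad {self.pad!r}")
        if self.protector not in PROTECTORS:
            raise ValueError(f"unknown protector {self.protector!r}")
        if self.question not in QUESTIONS:
            raise ValueError(f"unknown question {self.question!r}")
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"score must be an integer 1-5, got {self.score}")


@dataclass
class PadComfortSummary:
    """Per-pad survey means and the matching objective ROM totals."""

    pad: str
    question_means: pd.DataFrame  # protector x question means, values in [1, 5]
    comfort: float  # pooled comfort score used for the correlation
    total_rom_deg: Optional[float] = None
    restriction_fraction: Optional[float] = None


def _as_frame(responses) -> pd.DataFrame:
    if isinstance(responses, pd.DataFrame):
        df = responses.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "participant": r.participant_id,
                    "pad": r.pad,
                    "protector": r.protector,
                    "question": r.question,
                    "score": r.score,
                }
                for r in responses
            ]
        )
    required = {"participant", "pad", "protector", "question", "score"}
    if df.empty or not required.issubset(df.columns):
        raise ValueError(f"survey data must have columns {sorted(required)}")
    return df


def aggregate_likert(responses) -> pd.DataFrame:
    """Mean score per pad x protector x question.

    Requires a complete design: every participant answers every question once
    per pad per protector; duplicates and missing participants are errors.
    """
    df = _as_frame(responses)
    keys = ["participant", "pad", "protector", "question"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate responses for keys {df[dup][keys].values.tolist()}")
    counts = df.groupby(["pad", "protector", "question"])["participant"].nunique()
    if counts.nunique() != 1 or len(counts) != len(PAD_CONDITIONS) * len(PROTECTORS) * len(QUESTIONS):
        raise ValueError("incomplete survey: a participant or cell is missing")
    means = df.groupby(["pad", "protector", "question"])["score"].mean().unstack(["protector", "question"])
    return means.reindex(list(PAD_CONDITIONS))


def rank_pads(means: pd.Series) -> pd.Series:
    """Rank pads by descending mean score, ties sharing the average rank."""
    return means.rank(ascending=False, method="average")


def comfort_score(
    means: pd.DataFrame, include_restricts_reverse: bool = False
) -> pd.Series:
    """Per-pad comfort level: mean Q1 pooled over shoulder and elbow protectors.

    With ``include_restricts_reverse`` the reverse-coded Q3 (6 - score) is
    pooled in as well.
    """
    cols = [(prot, "q1_comfort") for prot in PROTECTORS]
    pooled = means[cols].mean(axis=1)
    if include_restricts_reverse:
        rev = 6.0 - means[[(prot, "q3_restricts") for prot in PROTECTORS]].mean(axis=1)
        pooled = 0.5 * (pooled + rev)
    return pooled


def total_rom(
    rom_table: pd.DataFrame,
    condition: str,
    tasks: Optional[Sequence[str]] = None,
    phases: Optional[Sequence[str]] = None,
) -> float:
    """Condition-mean ROM summed over the selected task/plane/phase rows."""
    sel = rom_table[rom_table["condition"] == condition]
    if tasks is not None:
        sel = sel[sel["task"].isin(tasks)]
    if phases is not None:
        sel = sel[sel["phase"].isin(phases)]
    if sel.empty:
        raise ValueError(f"no ROM rows selected for condition {condition!r}")
    cell_means = sel.groupby(["task", "phase", "joint_plane"])["rom_deg"].mean()
    return float(cell_means.sum())


def comfort_rom_correlation(summaries: Sequence[PadComfortSummary]) -> tuple[float, float, str]:
    """Spearman correlation of per-pad comfort vs total ROM, with its band."""
    usable = [s for s in summaries if s.total_rom_deg is not None]
    if len(usable) < 3:
        raise ValueError("need at least 3 pads with both comfort and total ROM")
    comfort = np.array([s.comfort for s in usable], dtype=float)
    roms = np.array([s.total_rom_deg for s in usable], dtype=float)
    rho, p = spearman_corr(comfort, roms)
    return rho, p, classify_correlation(rho)
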