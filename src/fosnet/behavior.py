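"""Behavioral scoring for the conditioned taste aversion (CTA) paradigm.

Four procedures:

* **CTA strength** — the ratio of day-2 to day-1 Boost intake (D2/D1) for
  the same animal; lower = stronger aversion. Animals that drank less than
  a minimum volume on day 1 never received the conditioning injection and
  are ineligible.
* **Weight-adjusted intake** — mL consumed per kg body weight, the
  standard dosing normalisation, used to compare intake across sexes.
* **USV block scoring** — task-day ultrasonic vocalizations are scored in
  ten 1-minute blocks; a block counts for the 55 kHz channel when it holds
  more than 10 calls, and for the 22 kHz channel when it holds more than
  1 call. The score per channel is the percentage of the 10 blocks that
  qualify, so scores are multiples of 10. An animal's emitter class
  (none / only22 / only55 / both) follows from which percentages are
  positive.
* **Nausea time-sampling** — pica, lying-on-belly and ptosis are each
  scored 0-3 in two consecutive 15-second blocks every 5 minutes for one
  hour (24 blocks per behavior); summaries report the summed score and the
  per-block mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import IntegrityError, SchemaError, NAUSEA_BEHAVIORS
from .registries import ConditionRegistry, SEXES

__all__ = [
    "IneligibleSubjectError",
    "CTAResult",
    "USVScore",
    "NauseaSummary",
    "cta_ratio",
    "weight_adjusted_intake",
    "score_drinking",
    "usv_block_score",
    "score_usv_table",
    "tally_emitters",
    "nausea_summary",
    "summarize_nausea_table",
    "DEFAULT_MIN_D1_ML",
    "DEFAULT_THR_55",
    "DEFAULT_THR_22",
    "SESSION_EPOCHS",
    "BLOCKS_PER_EPOCH",
    "MAX_BLOCK_SCORE",
]

DEFAULT_MIN_D1_ML = 1.0  # minimum day-1 intake for conditioning eligibility
DEFAULT_THR_55 = 10  # block counts if 55 kHz calls > this
DEFAULT_THR_22 = 1  # block counts if 22 kHz calls > this
N_USV_BLOCKS = 10
SESSION_EPOCHS = 12  # one observation epoch every 5 min for 1 h
BLOCKS_PER_EPOCH = 2  # two consecutive 15-s blocks per epoch
MAX_BLOCK_SCORE = 3

EMITTER_CLASSES = ("none", "only22", "only55", "both")


class IneligibleSubjectError(ValueError):
    """Day-1 intake below the eligibility minimum; subject excluded from CTA."""


@dataclass(frozen=True)
class CTAResult:
    subject_id: str
    d2_d1_ratio: float
    intake_per_kg_d1: float


@dataclass(frozen=True)
class USVScore:
    subject_id: str
    pct_blocks_55: float
    pct_blocks_22: float
    emitter_class: str


@dataclass(frozen=True)
class NauseaSummary:
    subject_id: str
    behavior: str
    total_score: int
    mean_block_score: float
    n_blocks_observed: int


def cta_ratio(intake_d1: float, intake_d2: float, min_d1: float = DEFAULT_MIN_D1_ML) -> float:
    """D2/D1 consumption ratio; lower values indicate stronger aversion.

    Raises :class:`IneligibleSubjectError` when day-1 intake is below
    ``min_d1`` (such animals were never conditioned).
    """
    if intake_d1 < 0 or intake_d2 < 0:
        raise ValueError("intakes must be non-negative")
    if intake_d1 < min_d1:
        raise IneligibleSubjectError(
            f"day-1 intake {intake_d1} mL below eligibility minimum {min_d1} mL"
        )
    return intake_d2 / intake_d1


def weight_adjusted_intake(intake_ml: float, body_weight_g: float) -> float:
    """Intake normalised to body weight, in mL per kg."""
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    if intake_ml < 0:
        raise ValueError("intake must be non-negative")
    return intake_ml / (body_weight_g / 1000.0)


def score_drinking(
    records: pd.DataFrame, min_d1: float = DEFAULT_MIN_D1_ML
) -> tuple[pd.DataFrame, list[str]]:
    """Score a behavior table (see :func:`fosnet.io.load_behavior_table`).

    Returns (scores, excluded): per-subject D2/D1 ratio and weight-adjusted
    day-1 intake for eligible subjects, plus the ids of subjects excluded
    for drinking less than ``min_d1`` on day 1.
    """
    rows, excluded = [], []
    for rec in records.itertuples(index=False):
        per_kg = weight_adjusted_intake(rec.intake_d1, rec.body_weight)
        try:
            ratio = cta_ratio(rec.intake_d1, rec.intake_d2, min_d1=min_d1)
        except IneligibleSubjectError:
            excluded.append(rec.subject_id)
            continue
        rows.append(
            {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "condition": rec.condition,
                "licl_dose": rec.licl_dose,
                "d2_d1_ratio": ratio,
                "intake_per_kg_d1": per_kg,
            }
        )
    cols = ["subject_id", "sex", "condition", "licl_dose", "d2_d1_ratio", "intake_per_kg_d1"]
    return pd.DataFrame(rows, columns=cols), excluded


def usv_block_score(
    subject_id: str,
    counts_55: Sequence[int],
    counts_22: Sequence[int],
    thr55: int = DEFAULT_THR_55,
    thr22: int = DEFAULT_THR_22,
    strict: bool = True,
) -> USVScore:
    """Score one animal's task-day USV record.

    ``strict`` applies the block rule as a strict inequality (count > thr);
    ``strict=False`` relaxes it to count >= thr.
    """
    c55 = np.asarray(counts_55)
    c22 = np.asarray(counts_22)
    if c55.shape != (N_USV_BLOCKS,) or c22.shape != (N_USV_BLOCKS,):
        raise SchemaError(
            f"USV records need exactly {N_USV_BLOCKS} 1-minute blocks per channel"
        )
    if (c55 < 0).any() or (c22 < 0).any():
        raise ValueError("USV counts must be non-negative")
    op = np.greater if strict else np.greater_equal
    pct55 = 100.0 * op(c55, thr55).sum() / N_USV_BLOCKS
    pct22 = 100.0 * op(c22, thr22).sum() / N_USV_BLOCKS
    if pct55 > 0 and pct22 > 0:
        cls = "both"
    elif pct55 > 0:
        cls = "only55"
    elif pct22 > 0:
        cls = "only22"
    else:
        cls = "none"
    return USVScore(str(subject_id), float(pct55), float(pct22), cls)


def score_usv_table(
    usv: pd.DataFrame,
    thr55: int = DEFAULT_THR_55,
    thr22: int = DEFAULT_THR_22,
    strict: bool = True,
) -> pd.DataFrame:
    """Score every subject of a wide USV table; keeps sex/condition labels."""
    cols55 = [f"khz55_min_{i}" for i in range(1, 11)]
    cols22 = [f"khz22_min_{i}" for i in range(1, 11)]
    rows = []
    for rec in usv.itertuples(index=False):
        d = rec._asdict()
        score = usv_block_score(
            d["subject_id"],
            [d[c] for c in cols55],
            [d[c] for c in cols22],
            thr55=thr55,
            thr22=thr22,
            strict=strict,
        )
        rows.append(
            {
                "subject_id": score.subject_id,
                "sex": d["sex"],
                "condition": d["condition"],
                "pct_blocks_55": score.pct_blocks_55,
                "pct_blocks_22": score.pct_blocks_22,
                "emitter_class": score.emitter_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "sex", "condition", "pct_blocks_55", "pct_blocks_22", "emitter_class"],
    )


def tally_emitters(
    scored: pd.DataFrame, conditions: ConditionRegistry | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Count emitting animals per condition x emitter class x sex.

    ``scored`` is the output of :func:`score_usv_table`. Returns
    ``(tally, none_counts)``: the tally has one row per condition present,
    hierarchical columns (only22|both|only55) x (F|M) plus a ``Total``
    column counting emitters in the row; animals of class "none" are not
    counted in any cell and are reported separately per condition.
    """
    conditions = conditions or ConditionRegistry()
    if scored["subject_id"].duplicated().any():
        raise IntegrityError("each subject must be scored exactly once")
    present = conditions.subset(scored["condition"])
    class_order = ("only22", "both", "only55")
    cols = pd.MultiIndex.from_tuples(
        [(c, s) for c in class_order for s in SEXES] + [("Total", "")],
    )
    tally = pd.DataFrame(0, index=list(present), columns=cols)
    none_counts = pd.Series(0, index=list(present), name="none")
    for rec in scored.itertuples(index=False):
        cond = conditions.canonical(rec.condition)
        if rec.emitter_class == "none":
            none_counts[cond] += 1
            continue
        if rec.emitter_class not in class_order:
            raise ValueError(f"unknown emitter class {rec.emitter_class!r}")
        tally.at[cond, (rec.emitter_class, rec.sex)] += 1
    tally[("Total", "")] = tally.loc[:, list(class_order)].sum(axis=1)
    return tally, none_counts


def nausea_summary(subject_id: str, behavior: str, scores: Iterable[int]) -> NauseaSummary:
    """Summarise one subject's block scores for one nausea behavior.

    A complete session has 24 blocks (12 epochs x 2 consecutive 15-s
    blocks); partial sessions are allowed and reflected in
    ``n_blocks_observed``.
    """
    if behavior not in NAUSEA_BEHAVIORS:
        raise ValueError(f"behavior must be one of {NAUSEA_BEHAVIORS}")
    scores = list(scores)
    max_blocks = SESSION_EPOCHS * BLOCKS_PER_EPOCH
    if len(scores) > max_blocks:
        raise ValueError(f"at most {max_blocks} blocks per behavior per session")
    if not scores:
        raise ValueError("no observed blocks")
    for s in scores:
        if s != int(s) or not (0 <= s <= MAX_BLOCK_SCORE):
            raise ValueError(f"block scores must be integers in 0..{MAX_BLOCK_SCORE}, got {s}")
    total = int(sum(scores))
    return NauseaSummary(
        subject_id=str(subject_id),
        behavior=behavior,
        total_score=total,
        mean_block_score=total / len(scores),
        n_blocks_observed=len(scores),
    )


def summarize_nausea_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, behavior) nausea summaries from a long observation table."""
    rows = []
    for (subject, behavior), grp in obs.groupby(["subject_id", "behavior"], sort=True):
        s = nausea_summary(subject, behavior, grp["score"].tolist())
        rows.append(
            {
                "subject_id": s.subject_id,
                "behavior": s.behavior,
                "total_score": s.total_score,
                "mean_block_score": s.mean_block_score,
                "n_blocks_observed": s.n_blocks_observed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "behavior", "total_score", "mean_block_score", "n_blocks_observed"],
    )
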