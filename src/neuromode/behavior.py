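"""n-back behaviour scoring, performance grouping and improvement indices.

Scores are target-trial accuracies (target-ACC) and mean reaction times of
correct target trials.  Subjects are split into low/high performance groups
(LP = 0, HP = 1) by a median split of their summed scores, after removing
subjects whose summaries lie beyond 2 SD from the cohort mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def score_nback(trials: pd.DataFrame) -> tuple[float, float]:
    """Score one trial table: (target-ACC, mean RT of correct target trials).

    target-ACC = correct target trials / total target trials.  RT averages
    only the correctly responded target trials.
    """
    targets = trials[trials["is_target"].astype(bool)]
    if len(targets) == 0:
        raise ValueError("no target trials to score")
    correct_targets = targets[targets["correct"].astype(bool)]
    target_acc = len(correct_targets) / len(targets)
    rt_s = float(correct_targets["rt_s"].mean()) if len(correct_targets) else float("nan")
    return target_acc, rt_s


def median_split(scores: pd.Series | dict, tie: str = "low") -> pd.Series:
    """Binary group labels from a median split of summed subject scores.

    Label 0 (LP) below the median, label 1 (HP) above.  Subjects exactly at
    the median go to LP when ``tie='low'`` (default) or HP when
    ``tie='high'``; the split is invariant to monotone rescaling of scores.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("median split needs at least 2 subjects")
    if s.nunique() == 1:
        raise ValueError("all scores identical; no median split exists")
    med = s.median()
    if tie == "low":
        labels = (s > med).astype(int)
    elif tie == "high":
        labels = (s >= med).astype(int)
    else:
        raise ValueError("tie must be 'low' or 'high'")
    logger.info("median split at %.4g: %d LP / %d HP", med,
                int((labels == 0).sum()), int((labels == 1).sum()))
    return labels


def exclude_extremes(tbl: pd.DataFrame, k_sd: float = 2.0, block: int = 1) -> pd.DataFrame:
    """Remove subjects whose block-``block`` ACC or RT is beyond k_sd SDs.

    Summaries are computed on the grouping block (block 1 by default, the
    block grouping is based on); a subject is removed if either its mean
    target-ACC or its mean RT deviates more than ``k_sd`` standard
    deviations from the cohort mean of that summary.
    """
    if tbl["subject"].nunique() < 3:
        raise ValueError("extreme-value exclusion needs at least 3 subjects")
    b1 = tbl[tbl["block"] == block]
    summ = b1.groupby("subject")[["target_acc", "rt_s"]].mean()
    bad = pd.Series(False, index=summ.index)
    for col in ("target_acc", "rt_s"):
        mu, sd = summ[col].mean(), summ[col].std(ddof=1)
        if sd > 0:
            bad |= (summ[col] - mu).abs() > k_sd * sd
    removed = list(summ.index[bad])
    if removed:
        logger.info("excluded %d subject(s) beyond %.3g SD: %s", len(removed), k_sd, removed)
    return tbl[~tbl["subject"].isin(removed)].reset_index(drop=True)


def group_subjects(
    tbl: pd.DataFrame,
    backs: tuple[int, ...] = (3, 4),
    block: int = 1,
    k_sd: float = 2.0,
    tie: str = "low",
) -> pd.Series:
    """Full grouping rule: exclude extremes, sum block-1 scores over the
    given back levels, median-split the sums.

    Returns labels indexed by subject id (excluded subjects absent).
    """
    kept = exclude_extremes(tbl, k_sd=k_sd, block=block)
    sel = kept[(kept["block"] == block) & (kept["back"].isin(backs))]
    sums = sel.groupby("subject")["target_acc"].sum()
    return median_split(sums, tie=tie)


def improvement_indices(tbl: pd.DataFrame) -> pd.DataFrame:
    """Per subject x back improvement: block 3 minus block 1 ACC and RT.

    Rows lacking either block are skipped with a warning.
    """
    rows = []
    for (subj, back), grp in tbl.groupby(["subject", "back"]):
        by_block = grp.set_index("block")
        if 1 not in by_block.index or 3 not in by_block.index:
            logger.warning("subject %s back %s: missing block 1 or 3; skipped", subj, back)
            continue
        rows.append(
            {
                "subject": subj,
                "back": back,
                "delta_acc": float(by_block.loc[3, "target_acc"] - by_block.loc[1, "target_acc"]),
                "delta_rt": float(by_block.loc[3, "rt_s"] - by_block.loc[1, "rt_s"]),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "back", "delta_acc", "delta_rt"])
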