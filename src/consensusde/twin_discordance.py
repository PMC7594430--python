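"""Twin discordance: eligibility, discrepancy scores, ranks, and the
fold-change / discordance correlation.

A monozygotic pair is *discordant* when any of three criteria fires: a
symptom-score separation of at least ``min_symptom_sep`` with the lower twin
below the diagnostic threshold, a T-score difference of at least
``min_tscore_diff``, or a diagnosis/treatment asymmetry.  The quantitative
discrepancy score is the absolute within-pair difference of ADHD-RS raw
subscale scores; pairs are ranked with rank 1 = most discrepant.  Per-
transcript within-pair fold changes are then correlated with the discordance
rank — in the ideal scenario for a severity biomarker, fold change decreases
monotonically with rank, i.e. r is strongly negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Group, SampleRecord, validate_pairing


@dataclass
class DiscordanceCriteria:
    """Eligibility thresholds; symptom separation and T-score gap follow the
    clinical definition (3 symptoms, 10 T-score points)."""

    min_symptom_sep: float = 3.0
    min_tscore_diff: float = 10.0
    diagnostic_threshold: float = 12.0  # ADHD-RS raw total below which a twin counts as subthreshold


def is_discordant(
    affected: SampleRecord,
    unaffected: SampleRecord,
    criteria: DiscordanceCriteria | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate the discordance criteria for one pair.

    Returns (discordant, fired_criteria).  Raises if no criterion can be
    evaluated from the available fields.
    """
    c = criteria or DiscordanceCriteria()
    fired: list[str] = []
    evaluable = False

    a_t, u_t = affected.adhd_rs_total, unaffected.adhd_rs_total
    if a_t is not None and u_t is not None:
        evaluable = True
        lower = min(a_t, u_t)
        if abs(a_t - u_t) >= c.min_symptom_sep and lower < c.diagnostic_threshold:
            fired.append("symptom_separation")

    a_s, u_s = affected.adhd_rs_tscore, unaffected.adhd_rs_tscore
    if a_s is not None and u_s is not None:
        evaluable = True
        if abs(a_s - u_s) >= c.min_tscore_diff:
            fired.append("tscore_difference")

    a_d, u_d = affected.prior_diagnosis, unaffected.prior_diagnosis
    if a_d is not None and u_d is not None:
        evaluable = True
        if a_d != u_d:
            fired.append("diagnosis_asymmetry")

    if not evaluable:
        missing = [
            f for f in ("adhd_rs_total", "adhd_rs_tscore", "prior_diagnosis")
            if getattr(affected, f) is None or getattr(unaffected, f) is None
        ]
        raise ValueError(f"no evaluable discordance criterion; missing fields: {missing}")
    return bool(fired), fired


def discrepancy_scores(rows: list[SampleRecord]) -> pd.DataFrame:
    """Per-pair absolute ADHD-RS raw-score differences.

    Pairs missing any subscale score are flagged (``valid`` = 0) and excluded
    from ranking downstream.
    """
    pairs = validate_pairing(rows)
    recs = []
    for pid in sorted(pairs):
        aff, unaff = pairs[pid]
        rec: dict = {"pair_id": pid, "valid": 1}
        for var, field in (
            ("d_inattention", "adhd_rs_inattention"),
            ("d_hyperactivity", "adhd_rs_hyperactivity"),
            ("d_total", "adhd_rs_total"),
        ):
            a, u = getattr(aff, field), getattr(unaff, field)
            if a is None or u is None:
                rec[var] = np.nan
                rec["valid"] = 0
            else:
                rec[var] = abs(a - u)
        recs.append(rec)
    return pd.DataFrame(recs)


def rank_discordance(scores: pd.DataFrame, variable: str = "d_total") -> pd.DataFrame:
    """Attach ``discordance_rank``: 1 = most discrepant; ties share the average rank."""
    if len(scores) == 0:
        raise ValueError("no pairs to rank")
    if variable not in scores.columns:
        raise ValueError(f"unknown discrepancy variable {variable!r}")
    usable = scores[scores["valid"] == 1] if "valid" in scores.columns else scores
    vals = usable[variable].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"variable {variable!r} missing for some valid pairs")
    ranks = stats.rankdata(-vals, method="average")
    out = scores.copy()
    out["discordance_rank"] = np.nan
    out.loc[usable.index, "discordance_rank"] = ranks
    return out


def correlate_discordance(
    per_pair_log2fc: np.ndarray,
    transcript_ids: list[str],
    ranks: np.ndarray,
    method: str = "pearson",
    r_thresh: float = 0.4,
) -> pd.DataFrame:
    """Correlate each transcript's per-pair fold change with the discordance rank.

    Negative r means larger expression change in more discordant pairs (the
    biomarker-consistent direction); transcripts with r <= -r_thresh are
    flagged.  Constant fold-change vectors yield a missing (NaN) r, never zero.
    """
    fc = np.asarray(per_pair_log2fc, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if fc.shape[1] != ranks.shape[0]:
        raise ValueError("fold-change columns do not match number of ranked pairs")
    if ranks.shape[0] < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    x = stats.rankdata(ranks, method="average") if method == "spearman" else ranks
    y = np.apply_along_axis(lambda v: stats.rankdata(v, method="average"), 1, fc) if method == "spearman" else fc

    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    r[denom == 0] = np.nan
    return pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "r": r,
            "n_pairs": ranks.shape[0],
            "flagged": ((r <= -r_thresh) & np.isfinite(r)).astype(int),
        }
    )
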