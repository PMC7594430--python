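"""Triple filter, cross-cohort intersection and overlap significance.

The triple filter keeps transcripts that jointly satisfy (i) prevalence at an
RPKM detectability threshold, (ii) |fold change| > ``fc_min`` (i.e. ratio
above ``fc_min`` or below 1/``fc_min``), and (iii) an uncorrected t-test p
below ``p_max`` on log2 RPKM (Welch for unpaired cohorts, paired t on
within-pair log2 differences for twins).  Cross-cohort matching is done at
gene-symbol level with direction concordance; overlap significance uses the
one-sided hypergeometric upper tail over an explicitly supplied universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import DesignError, RpkmMatrix
from .expression import fold_change, pairwise_fold_change, prevalence_mask


def triple_filter(
    rpkm: RpkmMatrix,
    affected: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    fc_min: float = 1.5,
    p_max: float = 0.01,
    tau: float = 0.01,
    phi: float = 0.70,
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Joint prevalence + fold-change + raw-p filter; one row per transcript."""
    affected = np.asarray(affected, dtype=bool)
    if pairs is not None:
        covered = sorted({i for p in pairs for i in p})
        if len(covered) != rpkm.n_samples:
            raise DesignError("paired triple filter: pairing does not cover all samples")
        aff_cols = {a for a, _ in pairs}
        if aff_cols != set(np.flatnonzero(affected)):
            raise DesignError("paired flag inconsistent with sample sheet groups")

    prev = prevalence_mask(rpkm, affected, tau, phi)
    fc = fold_change(rpkm.values, affected, pseudocount)

    # near-constant rows are expected (all-zero transcripts); their undefined
    # t yields NaN which is mapped to p = 1 below
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if pairs is None:
            logv = np.log2(rpkm.values + pseudocount)
            res = stats.ttest_ind(
                logv[:, affected], logv[:, ~affected], axis=1, equal_var=False
            )
            p_raw = res.pvalue
        else:
            diffs = pairwise_fold_change(rpkm.values, pairs, pseudocount)
            res = stats.ttest_1samp(diffs, 0.0, axis=1)
            p_raw = res.pvalue
    p_raw = np.where(np.isfinite(p_raw), p_raw, 1.0)

    ratio = fc["ratio"].to_numpy()
    pass_fc = (ratio > fc_min) | (ratio < 1.0 / fc_min)
    pass_p = p_raw < p_max
    passed = prev & pass_fc & pass_p
    return pd.DataFrame(
        {
            "transcript_id": rpkm.transcript_ids,
            "gene_symbol": rpkm.gene_symbols,
            "ratio": ratio,
            "log2fc": fc["log2fc"].to_numpy(),
            "direction": fc["direction"].to_numpy(),
            "p_raw": p_raw,
            "pass_prevalence": prev.astype(int),
            "pass_fc": pass_fc.astype(int),
            "pass_p": pass_p.astype(int),
            "passed": passed.astype(int),
        }
    )


def symbol_directions(filtered: pd.DataFrame) -> dict[str, str]:
    """Per-symbol direction from a triple-filter table, passing transcripts only.

    When a symbol has several passing isoforms, the most significant one (by
    raw p, ties by transcript id) defines the direction.
    """
    hits = filtered[filtered["passed"] == 1].sort_values(
        ["p_raw", "transcript_id"], kind="mergesort"
    )
    out: dict[str, str] = {}
    for _, row in hits.iterrows():
        out.setdefault(row["gene_symbol"], row["direction"])
    return out


def intersect_cohorts(
    set_a: dict[str, str], set_b: dict[str, str]
) -> tuple[set[str], set[str], set[str]]:
    """Symbol intersection with direction concordance.

    Returns (common, concordant, excluded): symbols present in both cohorts,
    those with the same direction, and those excluded for opposite directions.
    """
    for name, d in (("first", set_a), ("second", set_b)):
        bad = {s for s, v in d.items() if v not in ("up", "down")}
        if bad:
            raise ValueError(f"{name} cohort has symbols with undefined direction: {sorted(bad)[:5]}")
    common = set(set_a) & set(set_b)
    excluded = {s for s in common if set_a[s] != set_b[s]}
    return common, common - excluded, excluded


@dataclass
class OverlapReport:
    n1: int
    n2: int
    k_overlap: int
    universe: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "k_overlap": self.k_overlap,
            "universe": self.universe,
            "p_value": self.p_value,
        }


def overlap_test(n1: int, n2: int, k: int, universe: int) -> OverlapReport:
    """One-sided enrichment p for observing >= k shared members.

    P(X >= k) with X hypergeometric(universe, n1, n2) — the upper tail of the
    2x2 exact test.  The universe size must be supplied explicitly.
    """
    if not (0 <= k <= min(n1, n2) <= max(n1, n2) <= universe):
        raise ValueError(f"inadmissible overlap parameters n1={n1}, n2={n2}, k={k}, N={universe}")
    p = float(stats.hypergeom.sf(k - 1, universe, n1, n2))
    return OverlapReport(n1, n2, k, universe, min(1.0, max(p, 0.0)))
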