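"""Appearance-count consensus across differential-expression methods.

Each method contributes its top-K transcripts (ranked by adjusted p); the
consensus statistic for a transcript is the number of method lists it appears
in.  The resulting table is sorted by appearance count (descending), then by
the best adjusted p across methods, then transcript id, giving a deterministic
single ranked list.  A Jaccard matrix quantifies pairwise method concordance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def top_k_list(res: pd.DataFrame, k: int, rank_by: str = "p_adj") -> list[str]:
    """Top-k transcript ids, ranked by ``rank_by`` with deterministic tie-breaks.

    Ties on the primary key are broken by raw p, then lexicographically by
    transcript id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(res) == 0:
        raise ValueError("empty result set")
    if rank_by not in ("p_adj", "p_raw"):
        raise ValueError("rank_by must be 'p_adj' or 'p_raw'")
    secondary = "p_raw" if rank_by == "p_adj" else "p_adj"
    ordered = res.sort_values(
        [rank_by, secondary, "transcript_id"], kind="mergesort"
    )["transcript_id"].tolist()
    return ordered[: min(k, len(ordered))]


def consensus_rank(
    lists: dict[str, list[str]], all_results: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Combine per-method top-K lists into the appearance-count consensus table.

    Restricted to transcripts appearing in at least one list.  Invariant to the
    order in which method lists are supplied.
    """
    if not lists:
        raise ValueError("need at least one method list")
    methods = sorted(lists)
    universe: set[str] = set()
    for m, res in all_results.items():
        universe.update(res["transcript_id"])
    for m in methods:
        unknown = set(lists[m]) - universe
        if unknown:
            raise ValueError(f"method {m!r} list references unknown transcripts: {sorted(unknown)[:5]}")

    members = sorted(set().union(*(set(lists[m]) for m in methods)))
    flags = pd.DataFrame(
        {m: [t in set(lists[m]) for t in members] for m in methods},
        index=members,
    )
    best_padj = pd.Series(np.inf, index=members)
    fc_sum = pd.Series(0.0, index=members)
    fc_n = pd.Series(0, index=members)
    for m in methods:
        res = all_results[m].set_index("transcript_id")
        common = res.index.intersection(members)
        best_padj.loc[common] = np.minimum(best_padj.loc[common], res.loc[common, "p_adj"])
        fc_sum.loc[common] += res.loc[common, "log2fc"]
        fc_n.loc[common] += 1

    table = pd.DataFrame(
        {
            "transcript_id": members,
            "appearance_count": flags.to_numpy().sum(axis=1),
            "best_p_adj": best_padj.to_numpy(),
            "mean_log2fc": (fc_sum / fc_n.replace(0, np.nan)).to_numpy(),
        }
    )
    for m in methods:
        table[f"in_{m}"] = flags[m].to_numpy().astype(int)
    table = table.sort_values(
        ["appearance_count", "best_p_adj", "transcript_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(1, "consensus_rank", np.arange(1, len(table) + 1))
    return table


def jaccard_matrix(lists: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity |A n B| / |A u B| between method sets."""
    methods = sorted(lists)
    sets = {m: set(lists[m]) for m in methods}
    for m, s in sets.items():
        if not s:
            raise ValueError(f"method {m!r} has an empty set")
    mat = np.ones((len(methods), len(methods)))
    for i, a in enumerate(methods):
        for j, b in enumerate(methods):
            if i < j:
                jac = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                mat[i, j] = mat[j, i] = jac
    return pd.DataFrame(mat, index=methods, columns=methods)
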