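"""End-to-end orchestration: simulate -> filter -> DE battery -> consensus ->
triple filter -> cross-cohort -> discordance.

Every stage writes its outputs as headered TSV (JSON for the overlap report
and the run report) under the output directory; the run report reconciles
record counts across stages.  A fixed config + seed reproduces every output
byte for byte.  ``resume=True`` reloads existing stage files instead of
recomputing them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as consensus_mod
from . import cross_cohort as cc_mod
from . import de_methods, expression, synthetic, twin_discordance
from .io_model import (
    CohortConfig,
    CountMatrix,
    RpkmMatrix,
    SampleRecord,
    group_labels,
    pair_index,
    read_count_matrix,
    read_sample_sheet,
    write_count_matrix,
    write_sample_sheet,
)

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def simulate_cohorts(config: CohortConfig, seed: int, outdir: Path, resume: bool = False):
    """Generate (or reload) both cohorts; returns {cohort: (cm, rows, truth|None)}."""
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, stream, sim in (
        ("case_control", 1, synthetic.simulate_case_control),
        ("twins", 2, synthetic.simulate_twins),
    ):
        mpath = outdir / f"{name}_counts.tsv"
        spath = outdir / f"{name}_samples.csv"
        tpath = outdir / f"{name}_truth.tsv"
        if resume and mpath.exists() and spath.exists():
            cm = read_count_matrix(mpath)
            rows = read_sample_sheet(spath)
            truth = None
        else:
            cm, rows, truth = sim(config, synthetic.child_seed(seed, stream))
            write_count_matrix(cm, mpath)
            write_sample_sheet(rows, spath)
            _write_tsv(truth.to_frame(), tpath)
        out[name] = (cm, rows, truth)
    return out


def analyze_cohort(
    cm: CountMatrix,
    rows: list[SampleRecord],
    config: CohortConfig,
    outdir: Path,
    name: str,
    paired: bool,
    seed: int,
) -> dict:
    """Filter, DE battery, consensus, Jaccard and triple filter for one cohort."""
    outdir.mkdir(parents=True, exist_ok=True)
    affected = group_labels(rows, cm.sample_ids)
    pairs = pair_index(rows, cm.sample_ids) if paired else None

    rpkm = expression.compute_rpkm(cm)
    report = expression.prevalence_report(rpkm, affected, config.rpkm_tau, config.prevalence_phi)
    _write_tsv(report, outdir / f"{name}_prevalence.tsv")
    keep = report["kept"].to_numpy(dtype=bool)
    cm_f = cm.subset_transcripts(keep)
    rpkm_f = rpkm.subset_transcripts(keep)

    battery = de_methods.run_battery(cm_f, affected, config, pairs=pairs, seed=seed)
    lists = {}
    for mid, res in battery.items():
        _write_tsv(res, outdir / f"{name}_de_{mid}.tsv")
        lists[mid] = consensus_mod.top_k_list(res, config.top_k, config.rank_by)

    table = consensus_mod.consensus_rank(lists, battery)
    _write_tsv(table, outdir / f"{name}_consensus.tsv")
    jac = consensus_mod.jaccard_matrix(lists)
    jac.to_csv(outdir / f"{name}_jaccard.tsv", sep="\t", float_format=_FLOAT_FMT)

    triple = cc_mod.triple_filter(
        rpkm, affected, pairs=pairs,
        fc_min=config.fc_min, p_max=config.p_max,
        tau=config.rpkm_tau, phi=config.prevalence_phi,
        pseudocount=config.pseudocount,
    )
    _write_tsv(triple, outdir / f"{name}_triple_filter.tsv")

    return {
        "affected": affected,
        "pairs": pairs,
        "rpkm": rpkm,
        "rpkm_filtered": rpkm_f,
        "filtered_ids": set(cm_f.transcript_ids),
        "battery": battery,
        "lists": lists,
        "consensus": table,
        "triple": triple,
        "counts": {
            "universe": cm.n_transcripts,
            "prevalence_kept": int(keep.sum()),
            "consensus_members": int(len(table)),
            "triple_passed": int(triple["passed"].sum()),
        },
    }


def run_pipeline(
    config: CohortConfig,
    outdir: str | Path,
    seed: int | None = None,
    resume: bool = False,
    inputs: dict[str, tuple[str, str]] | None = None,
) -> dict:
    """Full two-cohort run; returns the run report (also written as JSON).

    ``inputs`` may map cohort name -> (count matrix path, sample sheet path) to
    run on real tables instead of simulating.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)

    if inputs:
        cohorts = {}
        for name, (mp, sp) in inputs.items():
            cohorts[name] = (read_count_matrix(mp), read_sample_sheet(sp), None)
    else:
        cohorts = simulate_cohorts(config, seed, outdir, resume=resume)

    stage_counts: dict[str, dict] = {}
    results = {}
    for name, (cm, rows, _) in cohorts.items():
        paired = name == "twins"
        res = analyze_cohort(cm, rows, config, outdir, name, paired, seed=synthetic.child_seed(seed, 3))
        results[name] = res
        stage_counts[name] = res["counts"]

    report: dict = {
        "config": config.to_dict(),
        "seed": seed,
        "stages": stage_counts,
    }

    # cross-cohort intersection (symbol level) and overlap significance
    if {"case_control", "twins"} <= set(results):
        cc, tw = results["case_control"], results["twins"]
        dirs_a = cc_mod.symbol_directions(cc["triple"])
        dirs_b = cc_mod.symbol_directions(tw["triple"])
        common, concordant, excluded = cc_mod.intersect_cohorts(dirs_a, dirs_b)
        sym = lambda ids, rpkm: {s for t, s in zip(rpkm.transcript_ids, rpkm.gene_symbols) if t in ids}
        universe = len(
            sym(cc["filtered_ids"], cc["rpkm"]) & sym(tw["filtered_ids"], tw["rpkm"])
        )
        overlap = cc_mod.overlap_test(
            len(dirs_a), len(dirs_b), len(common),
            max(universe, len(set(dirs_a) | set(dirs_b))),
        )
        concord_df = pd.DataFrame(
            sorted(
                (
                    {"gene_symbol": s, "dir_case_control": dirs_a[s], "dir_twins": dirs_b[s],
                     "concordant": int(s in concordant)}
                    for s in common
                ),
                key=lambda d: d["gene_symbol"],
            )
        )
        if len(concord_df) == 0:
            concord_df = pd.DataFrame(
                columns=["gene_symbol", "dir_case_control", "dir_twins", "concordant"]
            )
        _write_tsv(concord_df, outdir / "cross_cohort_symbols.tsv")
        with open(outdir / "overlap_report.json", "w", encoding="utf-8") as fh:
            json.dump(overlap.to_dict(), fh, indent=2, sort_keys=True)
        report["cross_cohort"] = {
            "common_symbols": len(common),
            "concordant_symbols": len(concordant),
            "excluded_opposite_direction": len(excluded),
            "overlap_p": overlap.p_value,
            "universe": overlap.universe,
        }

    # twin discordance correlation
    if "twins" in results:
        tw = results["twins"]
        _, rows, _ = cohorts["twins"]
        scores = twin_discordance.discrepancy_scores(rows)
        ranked = twin_discordance.rank_discordance(scores, "d_total")
        _write_tsv(ranked, outdir / "twins_discrepancy.tsv")
        rpkm_f: RpkmMatrix = tw["rpkm_filtered"]
        fc = expression.pairwise_fold_change(rpkm_f.values, tw["pairs"], config.pseudocount)
        corr = twin_discordance.correlate_discordance(
            fc, rpkm_f.transcript_ids, ranked["discordance_rank"].to_numpy(),
            method="pearson", r_thresh=config.r_thresh,
        )
        corr = corr.sort_values(["r", "transcript_id"], kind="mergesort", na_position="last")
        _write_tsv(corr, outdir / "twins_discordance_correlation.tsv")
        report["discordance"] = {
            "n_pairs": int(len(scores)),
            "n_flagged": int(corr["flagged"].sum()),
        }

    report["files"] = sorted(p.name for p in outdir.iterdir() if p.is_file() and p.name != "run_report.json")
    with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
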