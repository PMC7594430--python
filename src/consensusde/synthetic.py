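"""Synthetic cohort generation.

Generates count matrices with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without access to patient data:

* negative-binomial counts (variance = mu + phi * mu^2) with transcript
  baselines drawn log-uniformly over a wide dynamic range (default 18 log2
  units, emulating the very broad expression range of ribo-depleted whole-blood
  single-molecule sequencing);
* an unpaired case-control cohort (default 23 affected vs 21 unaffected) and a
  monozygotic-twin cohort (default 16 discordant pairs);
* a configurable spiked differentially-expressed fraction with specified
  log2 fold changes applied to the affected group;
* per-sample library-size variation (log-uniform, default 0.5x-2x);
* for twins, a log-normal within-pair random effect per (pair, transcript),
  shared by both twins of a pair, inducing the within-pair correlation a paired
  test exploits; and per-pair ADHD-RS discrepancy scores optionally coupled to
  the per-pair fold change of a designated transcript set.

Transcript ids, gene symbols and lengths are deterministic functions of the
transcript index so two cohorts simulated with different seeds share the same
transcript universe (as two sequencing runs of the same annotation would).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    Cohort,
    CohortConfig,
    ConfigError,
    CountMatrix,
    Group,
    SampleRecord,
)

_LENGTH_SEED = 20211
_MAX_SEED = 2**31 - 1


@dataclass
class SimTruth:
    """Ground truth behind a simulated cohort, for test oracles."""

    transcript_ids: list[str]
    mean_unaffected: np.ndarray  # baseline expected count at libsize 1
    mean_affected: np.ndarray
    log2fc: np.ndarray
    is_de: np.ndarray
    dispersion: np.ndarray
    libsize_factors: np.ndarray  # per sample
    pair_ids: list[str] = field(default_factory=list)
    discrepancy_total: np.ndarray | None = None
    coupled_ids: list[str] = field(default_factory=list)
    # per-pair realized log2 fold change for coupled transcripts,
    # shape (n_coupled, n_pairs)
    coupled_pair_log2fc: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "mean_unaffected": self.mean_unaffected,
                "mean_affected": self.mean_affected,
                "log2fc": self.log2fc,
                "is_de": self.is_de.astype(int),
                "dispersion": self.dispersion,
                "coupled": [int(t in set(self.coupled_ids)) for t in self.transcript_ids],
            }
        )


def transcript_annotation(n: int) -> tuple[list[str], list[str], np.ndarray]:
    """Deterministic ids, symbols and lengths for a universe of ``n`` transcripts."""
    ids = [f"uc{i:06d}.1" for i in range(n)]
    symbols = [f"GENE{i:05d}" for i in range(n)]
    rng = np.random.default_rng(_LENGTH_SEED)
    # transcript lengths roughly log-uniform between 200 bp and 20 kb
    lengths = np.exp(rng.uniform(np.log(200), np.log(20000), size=n)).astype(np.int64)
    return ids, symbols, lengths


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draw with variance mu + phi*mu^2; phi=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _draw_truth(config: CohortConfig, rng: np.random.Generator):
    g = config.n_transcripts
    lo, hi = config.baseline_log2_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=g)
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    log2fc = np.zeros(g)
    if n_de:
        mag = rng.uniform(config.de_log2fc[0], config.de_log2fc[1], size=n_de)
        if config.de_direction == "up":
            sign = np.ones(n_de)
        elif config.de_direction == "down":
            sign = -np.ones(n_de)
        else:
            sign = rng.choice([-1.0, 1.0], size=n_de)
        log2fc[de_idx] = mag * sign
        if config.de_min_mean is not None:
            # spiked transcripts guaranteed a detectable baseline
            floor = np.log2(config.de_min_mean)
            low = baseline[de_idx] < config.de_min_mean
            if low.any():
                baseline[de_idx[low]] = 2.0 ** rng.uniform(
                    max(lo, floor), hi, size=int(low.sum())
                )
    is_de = log2fc != 0
    dispersion = np.full(g, float(config.dispersion))
    return baseline, log2fc, is_de, dispersion


def _libsizes(config: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = config.libsize_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_case_control(
    config: CohortConfig, seed: int
) -> tuple[CountMatrix, list[SampleRecord], SimTruth]:
    """Unpaired case-control cohort; counts NB(baseline * libsize * 2^(log2fc*group))."""
    if config.n_cases < 1 or config.n_controls < 1:
        raise ConfigError("n_cases and n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    ids, symbols, lengths = transcript_annotation(config.n_transcripts)
    baseline, log2fc, is_de, disp = _draw_truth(config, rng)

    n = config.n_cases + config.n_controls
    lib = _libsizes(config, rng, n)
    affected = np.zeros(n, dtype=bool)
    affected[: config.n_cases] = True

    mean = baseline[:, None] * lib[None, :] * 2.0 ** (log2fc[:, None] * affected[None, :])
    counts = _nb_sample(rng, mean, disp[:, None])
    cm = CountMatrix(ids, symbols, lengths, counts, _cc_sample_ids(config))

    rows = []
    for i, sid in enumerate(cm.sample_ids):
        aff = bool(affected[i])
        rows.append(
            SampleRecord(
                sample_id=sid,
                cohort=Cohort.CASE_CONTROL,
                group=Group.AFFECTED if aff else Group.UNAFFECTED,
                adhd_rs_tscore=float(np.round(rng.normal(65.6 if aff else 43.0, 9.0 if aff else 5.8), 1)),
                prior_diagnosis=None,
            )
        )
    truth = SimTruth(
        ids, baseline, baseline * 2.0**log2fc, log2fc, is_de, disp, lib,
    )
    return cm, rows, truth


def _cc_sample_ids(config: CohortConfig) -> list[str]:
    return [f"CASE{i + 1:02d}" for i in range(config.n_cases)] + [
        f"CTRL{i + 1:02d}" for i in range(config.n_controls)
    ]


def _discrepancy_scores(rng: np.random.Generator, n_pairs: int):
    """Integer ADHD-RS raw scores for both twins; affected scores higher.

    Subscale scores (inattention, hyperactivity) are on 0-27; the reported
    total is also kept on the instrument's 0-27 scale.
    """
    aff_inatt = rng.integers(10, 28, size=n_pairs)
    aff_hyper = rng.integers(8, 28, size=n_pairs)
    un_inatt = np.array([rng.integers(0, a + 1) for a in aff_inatt])
    un_hyper = np.array([rng.integers(0, a + 1) for a in aff_hyper])
    aff_total = np.round((aff_inatt + aff_hyper) / 2).astype(int)
    un_total = np.round((un_inatt + un_hyper) / 2).astype(int)
    return (aff_inatt, aff_hyper, aff_total), (un_inatt, un_hyper, un_total)


def simulate_twins(
    config: CohortConfig, seed: int
) -> tuple[CountMatrix, list[SampleRecord], SimTruth]:
    """Monozygotic discordant-twin cohort.

    Both twins of a pair share a log-normal random effect per transcript
    (sd ``pair_effect_sd`` on the natural-log scale); the affected twin
    additionally carries the DE effect.  For transcripts in the coupling set,
    the per-pair log2 fold change varies across pairs with correlation
    ``coupling_rho`` to the pair's ADHD-RS total discrepancy score.
    """
    if config.n_pairs < 2:
        raise ConfigError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    ids, symbols, lengths = transcript_annotation(config.n_transcripts)
    baseline, log2fc, is_de, disp = _draw_truth(config, rng)
    g, npairs = config.n_transcripts, config.n_pairs

    (aff_in, aff_hy, aff_to), (un_in, un_hy, un_to) = _discrepancy_scores(rng, npairs)
    d_total = (aff_to - un_to).astype(float)

    # coupling set: well-expressed DE transcripts whose per-pair effect tracks
    # the discrepancy (a severity-tracking biomarker sits above the detection
    # floor, so candidates need a baseline of >= 50 expected counts)
    k = min(config.coupling_set_size, int(is_de.sum()))
    de_idx = np.flatnonzero(is_de)
    if k:
        eligible = de_idx[baseline[de_idx] >= 50.0]
        if eligible.size >= k:
            coupled_idx = np.sort(rng.choice(eligible, size=k, replace=False))
        else:
            coupled_idx = np.sort(de_idx[np.argsort(baseline[de_idx])[::-1][:k]])
    else:
        coupled_idx = np.array([], dtype=int)

    sd_d = d_total.std()
    u = (d_total - d_total.mean()) / sd_d if sd_d > 0 else np.zeros(npairs)
    rho, amp = config.coupling_rho, config.coupling_amplitude
    eps = rng.standard_normal((k, npairs))
    # per-pair log2fc for coupled transcripts: mean effect + correlated spread
    pair_log2fc = np.tile(log2fc[:, None], (1, npairs))
    if k:
        pair_log2fc[coupled_idx] = (
            log2fc[coupled_idx, None]
            + amp * (rho * u[None, :] + np.sqrt(max(0.0, 1 - rho**2)) * eps)
        )

    pair_effect = np.exp(rng.normal(0.0, config.pair_effect_sd, size=(g, npairs)))
    lib = _libsizes(config, rng, 2 * npairs)

    # sample order: P01A, P01U, P02A, ...
    mean = np.empty((g, 2 * npairs))
    for j in range(npairs):
        base_j = baseline * pair_effect[:, j]
        mean[:, 2 * j] = base_j * lib[2 * j] * 2.0 ** pair_log2fc[:, j]
        mean[:, 2 * j + 1] = base_j * lib[2 * j + 1]
    counts = _nb_sample(rng, mean, disp[:, None])

    sample_ids = []
    rows: list[SampleRecord] = []
    for j in range(npairs):
        pid = f"P{j + 1:02d}"
        for suffix, aff in (("A", True), ("U", False)):
            sid = pid + suffix
            sample_ids.append(sid)
            rows.append(
                SampleRecord(
                    sample_id=sid,
                    cohort=Cohort.TWINS,
                    group=Group.AFFECTED if aff else Group.UNAFFECTED,
                    pair_id=pid,
                    adhd_rs_inattention=float(aff_in[j] if aff else un_in[j]),
                    adhd_rs_hyperactivity=float(aff_hy[j] if aff else un_hy[j]),
                    adhd_rs_total=float(aff_to[j] if aff else un_to[j]),
                    adhd_rs_tscore=float(
                        np.round(rng.normal(62.0 if aff else 47.0, 9.0 if aff else 6.8), 1)
                    ),
                    prior_diagnosis=aff,
                )
            )
    cm = CountMatrix(ids, symbols, lengths, counts, sample_ids)
    truth = SimTruth(
        ids,
        baseline,
        baseline * 2.0**log2fc,
        log2fc,
        is_de,
        disp,
        lib,
        pair_ids=[f"P{j + 1:02d}" for j in range(npairs)],
        discrepancy_total=d_total,
        coupled_ids=[ids[i] for i in coupled_idx],
        coupled_pair_log2fc=pair_log2fc[coupled_idx] if k else None,
    )
    return cm, rows, truth


def child_seed(seed: int, stream: int) -> int:
    """Derive a reproducible sub-seed below 2**31 for an independent stream."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _MAX_SEED)
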