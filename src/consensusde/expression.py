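"""Normalized expression, prevalence filtering, fold changes, normalization factors.

RPKM here is count / (length/1e3) / (informative reads/1e6), where "informative
reads" is the column sum of the supplied count matrix.  The prevalence filter
keeps a transcript when, in at least one diagnostic group, the fraction of
samples with RPKM strictly above ``tau`` is at least ``phi``; the fraction
comparison is done in exact rational arithmetic so thresholds like 0.7 * n
never fall victim to floating-point edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_model import CountMatrix, DesignError, FormatError, RpkmMatrix


@dataclass
class NormFactors:
    """Per-sample scaling factors.

    ``relative`` factors multiply the raw library size (TMM-style, geometric
    mean 1); absolute factors (median-of-ratios size factors) already encode
    depth.  ``effective_library_sizes`` puts both on a common scale usable as a
    GLM exposure.
    """

    sample_ids: list[str]
    factors: np.ndarray
    method: str
    relative: bool = True

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise FormatError("normalization factors must be positive and finite")

    def effective_library_sizes(self, cm: CountMatrix) -> np.ndarray:
        lib = cm.library_sizes().astype(float)
        if self.relative:
            return lib * self.factors
        geo = np.exp(np.mean(np.log(lib)))
        return self.factors / np.exp(np.mean(np.log(self.factors))) * geo

    @classmethod
    def none(cls, cm: CountMatrix) -> "NormFactors":
        return cls(list(cm.sample_ids), np.ones(cm.n_samples), "none")


def compute_rpkm(cm: CountMatrix) -> RpkmMatrix:
    """Reads per kilobase of transcript per million informative reads."""
    totals = cm.library_sizes()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DesignError(
            f"sample(s) with zero total counts: {[cm.sample_ids[i] for i in zero]}"
        )
    values = cm.counts / (cm.lengths_bp[:, None] / 1e3) / (totals[None, :] / 1e6)
    return RpkmMatrix(
        list(cm.transcript_ids),
        list(cm.gene_symbols),
        cm.lengths_bp,
        values,
        list(cm.sample_ids),
    )


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


def prevalence_mask(
    rpkm: RpkmMatrix,
    affected: np.ndarray,
    tau: float = 0.01,
    phi: float | Fraction = 0.70,
) -> np.ndarray:
    """Boolean keep-mask: RPKM > tau in a fraction >= phi of at least one group."""
    affected = np.asarray(affected, dtype=bool)
    if affected.shape[0] != rpkm.n_samples:
        raise DesignError("group labels do not match sample count")
    n_a, n_u = int(affected.sum()), int((~affected).sum())
    if n_a == 0 or n_u == 0:
        raise DesignError("both diagnostic groups must be non-empty")
    phi_f = _as_fraction(phi)
    above = rpkm.values > tau
    k_a = above[:, affected].sum(axis=1)
    k_u = above[:, ~affected].sum(axis=1)
    keep = np.array(
        [
            Fraction(int(ka), n_a) >= phi_f or Fraction(int(ku), n_u) >= phi_f
            for ka, ku in zip(k_a, k_u)
        ]
    )
    return keep


def prevalence_filter(
    rpkm: RpkmMatrix,
    affected: np.ndarray,
    tau: float = 0.01,
    phi: float | Fraction = 0.70,
) -> set[str]:
    """Transcript ids passing the prevalence filter."""
    keep = prevalence_mask(rpkm, affected, tau, phi)
    return {t for t, k in zip(rpkm.transcript_ids, keep) if k}


def prevalence_report(
    rpkm: RpkmMatrix, affected: np.ndarray, tau: float = 0.01, phi: float | Fraction = 0.70
) -> pd.DataFrame:
    affected = np.asarray(affected, dtype=bool)
    keep = prevalence_mask(rpkm, affected, tau, phi)
    above = rpkm.values > tau
    return pd.DataFrame(
        {
            "transcript_id": rpkm.transcript_ids,
            "frac_affected": above[:, affected].mean(axis=1),
            "frac_unaffected": above[:, ~affected].mean(axis=1),
            "kept": keep.astype(int),
        }
    )


def fold_change(
    values: np.ndarray, affected: np.ndarray, pseudocount: float = 0.25
) -> pd.DataFrame:
    """Group-mean ratio (affected over unaffected) with a stabilizing pseudocount.

    Returns a frame with ``ratio``, ``log2fc`` and ``direction`` columns.
    """
    affected = np.asarray(affected, dtype=bool)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if affected.sum() == 0 or (~affected).sum() == 0:
        raise DesignError("both groups must be non-empty")
    values = np.asarray(values, dtype=float)
    m_a = values[:, affected].mean(axis=1)
    m_u = values[:, ~affected].mean(axis=1)
    ratio = (m_a + pseudocount) / (m_u + pseudocount)
    log2fc = np.log2(ratio)
    direction = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "flat"))
    return pd.DataFrame({"ratio": ratio, "log2fc": log2fc, "direction": direction})


def pairwise_fold_change(
    values: np.ndarray, pairs: list[tuple[int, int]], pseudocount: float = 0.25
) -> np.ndarray:
    """Per-pair log2 fold change (affected over unaffected), shape (G, n_pairs)."""
    if not pairs:
        raise DesignError("no pairs supplied")
    values = np.asarray(values, dtype=float)
    aff = np.array([a for a, _ in pairs])
    unaff = np.array([u for _, u in pairs])
    return np.log2((values[:, aff] + pseudocount) / (values[:, unaff] + pseudocount))


# ---------------------------------------------------------------------------
# normalization factors


def _choose_tmm_reference(cm: CountMatrix) -> int:
    # sample whose 75th CPM percentile is closest to the mean of those percentiles
    lib = cm.library_sizes().astype(float)
    q = np.percentile(cm.counts / lib[None, :], 75, axis=0)
    return int(np.argmin(np.abs(q - q.mean())))


def tmm_factors(cm: CountMatrix, ref_sample: int | str | None = None) -> NormFactors:
    """Trimmed mean of M-values normalization.

    M-values (log2 relative expression vs the reference) are trimmed 30% on
    each side, absolute expression (A) 5% on each side, and the kept M-values
    averaged with inverse delta-method variance weights.  Factors are rescaled
    to geometric mean 1.
    """
    if cm.n_samples < 2:
        raise DesignError("TMM requires at least 2 samples")
    if ref_sample is None:
        ref = _choose_tmm_reference(cm)
    elif isinstance(ref_sample, str):
        ref = cm.sample_ids.index(ref_sample)
    else:
        ref = int(ref_sample)
    lib = cm.library_sizes().astype(float)
    y_r = cm.counts[:, ref].astype(float)
    n_r = lib[ref]
    log_factors = np.zeros(cm.n_samples)
    for s in range(cm.n_samples):
        if s == ref:
            continue
        y_s = cm.counts[:, s].astype(float)
        n_s = lib[s]
        ok = (y_s > 0) & (y_r > 0) & (y_s < n_s) & (y_r < n_r)
        if not ok.any():
            raise DesignError(
                f"sample {cm.sample_ids[s]!r} shares no usable transcripts with the reference"
            )
        p_s, p_r = y_s[ok] / n_s, y_r[ok] / n_r
        m = np.log2(p_s / p_r)
        a = 0.5 * np.log2(p_s * p_r)
        w = 1.0 / ((n_s - y_s[ok]) / (n_s * y_s[ok]) + (n_r - y_r[ok]) / (n_r * y_r[ok]))
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        log_factors[s] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(list(cm.sample_ids), factors, "tmm", relative=True)


def median_of_ratios_factors(cm: CountMatrix) -> NormFactors:
    """Per-sample median of count ratios to the per-transcript geometric mean.

    Only transcripts with a nonzero count in every sample contribute.
    """
    counts = cm.counts.astype(float)
    ok = np.all(counts > 0, axis=1)
    if not ok.any():
        raise DesignError("no transcript has nonzero counts in every sample")
    sub = counts[ok]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return NormFactors(list(cm.sample_ids), factors, "median_of_ratios", relative=False)
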