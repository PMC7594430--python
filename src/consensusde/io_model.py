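"""Shared data model and tabular I/O.

Every stage of the pipeline consumes and emits one of the containers defined
here.  Counts are kept at transcript (isoform) resolution throughout: collapsing
isoforms to genes can mask changes restricted to an alternatively spliced
transcript, so gene symbols exist only for cross-cohort matching.

File dialects: the count matrix is tab-separated (first three columns
``transcript_id``, ``gene_symbol``, ``length_bp``, then one column per sample);
the sample sheet is comma-separated.  Both are UTF-8 with '.' as the decimal
point.  Missing optional clinical fields are empty strings on disk and ``None``
in memory — never zero.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file violates the expected tabular format or a container invariant."""


class DesignError(ValueError):
    """Sample metadata is inconsistent with the requested study design."""


class ConfigError(ValueError):
    """A configuration value is outside its admissible range."""


class Cohort(str, enum.Enum):
    CASE_CONTROL = "case_control"
    TWINS = "twins"


class Group(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"


MATRIX_META_COLUMNS = ("transcript_id", "gene_symbol", "length_bp")


@dataclass
class CountMatrix:
    """Integer read counts per transcript per sample.

    ``counts`` has shape (n_transcripts, n_samples); ``lengths_bp`` is the
    transcript length in bases used by the RPKM calculation.
    """

    transcript_ids: list[str]
    gene_symbols: list[str]
    lengths_bp: np.ndarray
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.transcript_ids = list(map(str, self.transcript_ids))
        self.gene_symbols = list(map(str, self.gene_symbols))
        self.lengths_bp = np.asarray(self.lengths_bp)
        self.counts = np.asarray(self.counts)
        self.sample_ids = list(map(str, self.sample_ids))
        g, s = self.counts.shape
        if not (len(self.transcript_ids) == len(self.gene_symbols) == len(self.lengths_bp) == g):
            raise FormatError("transcript annotation length does not match count matrix rows")
        if len(self.sample_ids) != s:
            raise FormatError("sample id list does not match count matrix columns")
        if len(set(self.transcript_ids)) != g:
            raise FormatError("duplicate transcript ids")
        if len(set(self.sample_ids)) != s:
            raise FormatError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise FormatError("counts must be integers")
        if self.counts.min(initial=0) < 0:
            raise FormatError("negative count")
        if not np.issubdtype(self.lengths_bp.dtype, np.integer):
            if np.issubdtype(self.lengths_bp.dtype, np.floating) and np.all(
                self.lengths_bp == np.floor(self.lengths_bp)
            ):
                self.lengths_bp = self.lengths_bp.astype(np.int64)
            else:
                raise FormatError("lengths must be integers")
        if self.lengths_bp.min(initial=1) < 1:
            raise FormatError("transcript length < 1 bp")
        self.counts = self.counts.astype(np.int64)
        self.lengths_bp = self.lengths_bp.astype(np.int64)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total informative reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_transcripts(self, mask_or_ids) -> "CountMatrix":
        idx = _row_index(self.transcript_ids, mask_or_ids)
        return CountMatrix(
            [self.transcript_ids[i] for i in idx],
            [self.gene_symbols[i] for i in idx],
            self.lengths_bp[idx],
            self.counts[idx],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "length_bp", self.lengths_bp)
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.insert(0, "transcript_id", self.transcript_ids)
        return df


@dataclass
class RpkmMatrix:
    """Reads per kilobase per million informative reads; same axes as CountMatrix."""

    transcript_ids: list[str]
    gene_symbols: list[str]
    lengths_bp: np.ndarray
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite RPKM value")
        if self.values.min(initial=0.0) < 0:
            raise FormatError("negative RPKM value")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_transcripts(self, mask_or_ids) -> "RpkmMatrix":
        idx = _row_index(self.transcript_ids, mask_or_ids)
        return RpkmMatrix(
            [self.transcript_ids[i] for i in idx],
            [self.gene_symbols[i] for i in idx],
            self.lengths_bp[idx],
            self.values[idx],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "length_bp", self.lengths_bp)
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.insert(0, "transcript_id", self.transcript_ids)
        return df


def _row_index(ids: Sequence[str], mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape[0] != len(ids):
            raise FormatError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    pos = {t: i for i, t in enumerate(ids)}
    try:
        return np.array([pos[t] for t in mask_or_ids], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"unknown transcript id {exc.args[0]!r}") from exc


@dataclass
class SampleRecord:
    """One row of the sample sheet.

    Raw ADHD-RS subscale scores (parent rated) lie on the instrument's 0-27
    range; T scores are standardized and unrestricted.  ``pair_id`` is required
    for the twin cohort and forbidden to be partial.
    """

    sample_id: str
    cohort: Cohort
    group: Group
    pair_id: str | None = None
    adhd_rs_inattention: float | None = None
    adhd_rs_hyperactivity: float | None = None
    adhd_rs_total: float | None = None
    adhd_rs_tscore: float | None = None
    prior_diagnosis: bool | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cohort, str):
            self.cohort = Cohort(self.cohort.lower())
        if isinstance(self.group, str):
            self.group = Group(self.group.lower())
        for name in ("adhd_rs_inattention", "adhd_rs_hyperactivity", "adhd_rs_total"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 27):
                raise FormatError(f"{name}={v} outside ADHD-RS raw-score range [0, 27]")
        if self.cohort is Cohort.TWINS and not self.pair_id:
            raise DesignError(f"sample {self.sample_id}: twins cohort requires a pair_id")


def validate_pairing(rows: Sequence[SampleRecord]) -> dict[str, tuple[SampleRecord, SampleRecord]]:
    """Check the twin-pairing invariant and return pair_id -> (affected, unaffected).

    Every pair_id must occur exactly twice, once per group.
    """
    twins = [r for r in rows if r.cohort is Cohort.TWINS]
    by_pair: dict[str, list[SampleRecord]] = {}
    for r in twins:
        by_pair.setdefault(r.pair_id, []).append(r)
    pairs: dict[str, tuple[SampleRecord, SampleRecord]] = {}
    for pid, members in by_pair.items():
        if len(members) != 2:
            raise DesignError(f"pair {pid!r} has {len(members)} members, expected 2")
        groups = {m.group for m in members}
        if groups != {Group.AFFECTED, Group.UNAFFECTED}:
            raise DesignError(f"pair {pid!r} must contain one affected and one unaffected twin")
        aff = next(m for m in members if m.group is Group.AFFECTED)
        unaff = next(m for m in members if m.group is Group.UNAFFECTED)
        pairs[pid] = (aff, unaff)
    return pairs


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Thresholds, method battery, design flags and simulation parameters.

    The filtering constants default to the design's standard values: transcripts
    must exceed ``rpkm_tau`` = 0.01 RPKM in ``prevalence_phi`` = 70% of at least
    one group; the consensus takes the ``top_k`` = 100 transcripts per method;
    the triple filter requires fold change > ``fc_min`` = 1.5 and uncorrected
    p < ``p_max`` = 0.01.
    """

    # thresholds
    rpkm_tau: float = 0.01
    prevalence_phi: float = 0.70
    fc_min: float = 1.5
    p_max: float = 0.01
    top_k: int = 100
    r_thresh: float = 0.4
    pseudocount: float = 0.25

    # method battery
    methods: list[str] = field(
        default_factory=lambda: [
            "exact-tmm", "glm-lrt-tmm", "exact-deges", "wald-mor", "mod-t", "clr-mc",
        ]
    )
    rank_by: str = "p_adj"
    prior_df: float = 10.0
    n_mc: int = 128

    # design
    seed: int = 0
    paired: bool = False

    # simulation
    n_transcripts: int = 2000
    n_cases: int = 23
    n_controls: int = 21
    n_pairs: int = 16
    dispersion: float = 0.2
    de_fraction: float = 0.1
    de_log2fc: tuple[float, float] = (0.585, 3.0)
    de_direction: str = "both"  # both | up | down
    de_min_mean: float | None = None
    baseline_log2_range: tuple[float, float] = (-5.0, 13.0)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    pair_effect_sd: float = 0.2
    coupling_set_size: int = 5
    coupling_rho: float = 0.8
    coupling_amplitude: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_phi <= 1):
            raise ConfigError("prevalence_phi must lie in (0, 1]")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.fc_min <= 1:
            raise ConfigError("fc_min must exceed 1")
        if not (0 < self.p_max < 1):
            raise ConfigError("p_max must lie in (0, 1)")
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if not (0 <= self.de_fraction <= 1):
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.pair_effect_sd < 0:
            raise ConfigError("pair_effect_sd must be >= 0")
        if self.de_direction not in ("both", "up", "down"):
            raise ConfigError("de_direction must be 'both', 'up' or 'down'")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if not (-1 <= self.coupling_rho <= 1):
            raise ConfigError("coupling_rho must lie in [-1, 1]")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ConfigError("libsize_range must be a positive, ordered interval")
        lo, hi = self.baseline_log2_range
        if hi <= lo:
            raise ConfigError("baseline_log2_range must be ordered")
        self.de_log2fc = tuple(self.de_log2fc)  # type: ignore[assignment]
        self.baseline_log2_range = tuple(self.baseline_log2_range)  # type: ignore[assignment]
        self.libsize_range = tuple(self.libsize_range)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a tab-separated count matrix.

    Expects the header ``transcript_id  gene_symbol  length_bp  <sample...>``;
    column order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_symbol": str})
    for col in MATRIX_META_COLUMNS:
        if col not in df.columns[:3]:
            raise FormatError(f"count matrix must start with columns {MATRIX_META_COLUMNS}")
    sample_cols = [c for c in df.columns if c not in MATRIX_META_COLUMNS]
    if not sample_cols:
        raise FormatError("count matrix has no sample columns")
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError("non-numeric count value")
    if np.issubdtype(counts.dtype, np.floating):
        if np.isnan(counts).any() or not np.all(counts == np.floor(counts)):
            raise FormatError("counts must be non-missing integers")
        counts = counts.astype(np.int64)
    return CountMatrix(
        df["transcript_id"].tolist(),
        df["gene_symbol"].tolist(),
        df["length_bp"].to_numpy(),
        counts,
        sample_cols,
    )


_OPTIONAL_NUMERIC = (
    "adhd_rs_inattention",
    "adhd_rs_hyperactivity",
    "adhd_rs_total",
    "adhd_rs_tscore",
)


def write_sample_sheet(rows: Sequence[SampleRecord], path: str | Path) -> None:
    recs = []
    for r in rows:
        d = dataclasses.asdict(r)
        d["cohort"] = r.cohort.value
        d["group"] = r.group.value
        if r.prior_diagnosis is None:
            d["prior_diagnosis"] = ""
        else:
            d["prior_diagnosis"] = str(bool(r.prior_diagnosis)).lower()
        for k in _OPTIONAL_NUMERIC + ("pair_id",):
            if d[k] is None:
                d[k] = ""
        recs.append(d)
    pd.DataFrame(recs).to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read and validate a comma-separated sample sheet.

    Enum fields are case-insensitive; the twin-pairing invariant (each pair_id
    exactly twice, one affected + one unaffected) is enforced.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"sample sheet missing required columns {sorted(required - set(df.columns))}")
    rows: list[SampleRecord] = []
    for _, rec in df.iterrows():
        kwargs: dict = {
            "sample_id": rec["sample_id"],
            "cohort": rec["cohort"],
            "group": rec["group"],
            "pair_id": rec.get("pair_id", "") or None,
        }
        for k in _OPTIONAL_NUMERIC:
            raw = rec.get(k, "")
            kwargs[k] = float(raw) if raw not in ("", None) else None
        raw = rec.get("prior_diagnosis", "")
        if raw in ("", None):
            kwargs["prior_diagnosis"] = None
        elif raw.strip().lower() in ("true", "1", "yes"):
            kwargs["prior_diagnosis"] = True
        elif raw.strip().lower() in ("false", "0", "no"):
            kwargs["prior_diagnosis"] = False
        else:
            raise FormatError(f"unparseable prior_diagnosis value {raw!r}")
        try:
            rows.append(SampleRecord(**kwargs))
        except ValueError as exc:
            if isinstance(exc, (FormatError, DesignError)):
                raise
            raise FormatError(str(exc)) from exc
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in sample sheet")
    validate_pairing(rows)
    return rows


def group_labels(rows: Sequence[SampleRecord], sample_ids: Sequence[str]) -> np.ndarray:
    """Boolean array aligned with ``sample_ids``: True = affected."""
    by_id = {r.sample_id: r for r in rows}
    missing = [s for s in sample_ids if s not in by_id]
    if missing:
        raise DesignError(f"samples missing from sample sheet: {missing[:5]}")
    return np.array([by_id[s].group is Group.AFFECTED for s in sample_ids], dtype=bool)


def pair_index(rows: Sequence[SampleRecord], sample_ids: Sequence[str]) -> list[tuple[int, int]]:
    """(affected_column, unaffected_column) per pair, ordered by pair_id."""
    pairs = validate_pairing([r for r in rows if r.cohort is Cohort.TWINS])
    if not pairs:
        raise DesignError("no twin pairs in sample sheet")
    col = {s: i for i, s in enumerate(sample_ids)}
    out = []
    for pid in sorted(pairs):
        aff, unaff = pairs[pid]
        if aff.sample_id not in col or unaff.sample_id not in col:
            raise DesignError(f"pair {pid!r} member missing from count matrix")
        out.append((col[aff.sample_id], col[unaff.sample_id]))
    return out
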