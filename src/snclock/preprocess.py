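"""Sample QC, TMM/CPM normalization, detection filters and composition summaries.

The QC rule follows the Extracellular RNA Communication Consortium standard:
a sample is kept when at least 100,000 reads aligned to annotated transcripts
and the transcriptome/total read ratio exceeds 0.5 (strictly). Counts are then
scaled to counts-per-million over effective library sizes, where the effective
size is the raw library size times a trimmed-mean-of-M-values (TMM) factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "QCThresholds",
    "AgeGrouping",
    "DetectionRule",
    "qc_filter",
    "tmm_factors",
    "cpm",
    "detection_filter",
    "composition_summary",
]

META_READ_COLUMNS = ("total_reads", "transcriptome_reads")


@dataclass(frozen=True)
class QCThresholds:
    """Minimum transcriptome-aligned reads and transcriptome/total ratio."""

    min_transcriptome_reads: int = 100_000
    min_transcriptome_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.min_transcriptome_reads <= 0 or self.min_transcriptome_ratio <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class AgeGrouping:
    """Closed age intervals per group; defaults young 20-30, adult 31-60, aged 61+."""

    boundaries: dict = field(
        default_factory=lambda: {
            "young": (20, 30),
            "adult": (31, 60),
            "aged": (61, math.inf),
        }
    )

    def __post_init__(self) -> None:
        ivals = sorted(self.boundaries.values())
        for (lo1, hi1), (lo2, _) in zip(ivals, ivals[1:]):
            if lo1 > hi1 or hi1 >= lo2:
                raise ValueError("age intervals must be ordered and disjoint")

    @property
    def labels(self) -> list[str]:
        return sorted(self.boundaries, key=lambda g: self.boundaries[g][0])

    def assign(self, ages) -> pd.Series:
        """Group label per age; raises if an age falls outside every interval."""
        ages = pd.Series(ages)
        out = pd.Series(index=ages.index, dtype=object)
        for label, (lo, hi) in self.boundaries.items():
            out[(ages >= lo) & (ages <= hi)] = label
        missing = out.isna()
        if missing.any():
            bad = ages[missing].iloc[0]
            raise ValueError(f"age {bad} falls outside every age-group interval")
        return out


@dataclass(frozen=True)
class DetectionRule:
    """Expressed-gene rule: >= min_cpm CPM in >= min_fraction of a group's samples."""

    min_cpm: float = 1.0
    min_fraction: float = 0.30
    scope: str = "any_group"  # or "all_groups"

    def __post_init__(self) -> None:
        if self.min_cpm <= 0:
            raise ValueError("min_cpm must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.scope not in ("any_group", "all_groups"):
            raise ValueError(f"unknown scope {self.scope!r}")


def qc_filter(
    meta: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[list, pd.DataFrame]:
    """Apply the read-depth QC rule; returns retained sample ids and an audit table.

    A sample passes when transcriptome_reads >= min_transcriptome_reads and
    transcriptome_reads / total_reads > min_transcriptome_ratio (strict).
    """
    for col in META_READ_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks required column {col!r}")
        bad = meta.index[meta[col].isna()]
        if len(bad):
            raise ValueError(f"sample {bad[0]!r} has missing {col!r}")
    ratio = meta["transcriptome_reads"] / meta["total_reads"]
    enough_reads = meta["transcriptome_reads"] >= thresholds.min_transcriptome_reads
    enough_ratio = ratio > thresholds.min_transcriptome_ratio
    audit = pd.DataFrame(
        {
            "transcriptome_reads": meta["transcriptome_reads"],
            "transcriptome_ratio": ratio,
            "fail_reads": ~enough_reads,
            "fail_ratio": ~enough_ratio,
            "retained": enough_reads & enough_ratio,
        },
        index=meta.index,
    )
    return list(meta.index[audit["retained"]]), audit


def _quantile_ref_column(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Reference sample: 75th-percentile count fraction closest to the mean."""
    f75 = np.quantile(counts, 0.75, axis=0) / lib_sizes
    if np.median(f75) < 1e-20:
        return int(np.argmax(np.sqrt(counts).sum(axis=0)))
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("sample shares no positively expressed genes with the reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factor per sample.

    Per sample vs a reference sample, gene-wise log2 ratios (M) and average
    log2 abundances (A) are computed over genes positive in both; the most
    extreme 30% of M (each side) and 5% of A are discarded and the factor is
    the inverse-variance-weighted mean of the remaining M, exponentiated.
    Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    x = counts.to_numpy(dtype=np.float64)
    if lib_sizes is None:
        lib = x.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=np.float64)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    expressed = x.sum(axis=1) > 0
    x = x[expressed]
    ref = _quantile_ref_column(x, lib)
    f = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million over effective library sizes: count / (lib * factor) * 1e6."""
    x = counts.to_numpy(dtype=np.float64)
    lib = (
        x.sum(axis=0)
        if lib_sizes is None
        else lib_sizes.reindex(counts.columns).to_numpy(dtype=np.float64)
    )
    if np.any(lib <= 0):
        raise ValueError("zero library size; remove empty samples first")
    if factors is None:
        eff = lib
    else:
        fac = factors.reindex(counts.columns).to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(fac)) or np.any(fac <= 0):
            raise ValueError("normalization factors must be positive and finite")
        eff = lib * fac
    return pd.DataFrame(x / eff * 1e6, index=counts.index, columns=counts.columns)


def _group_detection(
    expr: pd.DataFrame, groups: pd.Series, rule: DetectionRule, labels: list[str]
) -> pd.DataFrame:
    """Per-group boolean: gene detected (>= min_cpm in >= min_fraction of samples)."""
    out = {}
    for label in labels:
        cols = groups.index[groups == label]
        if len(cols) == 0:
            warnings.warn(f"age group {label!r} is empty and cannot qualify genes")
            out[label] = pd.Series(False, index=expr.index)
            continue
        frac = (expr[cols] >= rule.min_cpm).sum(axis=1) / len(cols)
        out[label] = frac >= rule.min_fraction
    return pd.DataFrame(out)


def detection_filter(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: AgeGrouping = AgeGrouping(),
    rule: DetectionRule = DetectionRule(),
) -> list:
    """Genes detected in at least one age group (or all, per ``rule.scope``).

    ``expr`` is a genes x samples CPM matrix; ``meta`` supplies each sample's
    age. Returns gene ids in the input order.
    """
    groups = grouping.assign(meta.loc[expr.columns, "age"])
    det = _group_detection(expr, groups, rule, grouping.labels)
    keep = det.any(axis=1) if rule.scope == "any_group" else det.all(axis=1)
    return list(expr.index[keep])


def composition_summary(
    expr: pd.DataFrame,
    biotypes: pd.Series,
    meta: pd.DataFrame,
    grouping: AgeGrouping = AgeGrouping(),
    rule: DetectionRule = DetectionRule(min_cpm=10.0),
) -> pd.DataFrame:
    """Biotype composition of highly expressed genes per age group.

    For each age group, restricts to genes meeting the detection rule within
    that group and tabulates: number of genes per biotype, its share of the
    group's highly expressed genes, summed CPM per biotype over the group's
    samples, and its share of total CPM. Shares sum to 1 per group.
    """
    biotypes = biotypes.reindex(expr.index)
    if biotypes.isna().any():
        raise ValueError("every gene needs a biotype annotation")
    groups = grouping.assign(meta.loc[expr.columns, "age"])
    det = _group_detection(expr, groups, rule, grouping.labels)
    rows = []
    for label in grouping.labels:
        cols = groups.index[groups == label]
        genes = expr.index[det[label]]
        counts_by_bio = biotypes.loc[genes].value_counts()
        cpm_by_bio = (
            expr.loc[genes, cols].sum(axis=1).groupby(biotypes.loc[genes]).sum()
            if len(genes)
            else pd.Series(dtype=float)
        )
        n_total = counts_by_bio.sum()
        cpm_total = cpm_by_bio.sum()
        for bio in sorted(biotypes.unique()):
            n = int(counts_by_bio.get(bio, 0))
            total = float(cpm_by_bio.get(bio, 0.0))
            rows.append(
                {
                    "group": label,
                    "biotype": bio,
                    "n_genes": n,
                    "gene_share": n / n_total if n_total else 0.0,
                    "total_cpm": total,
                    "cpm_share": total / cpm_total if cpm_total else 0.0,
                }
            )
    return pd.DataFrame(rows)
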