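"""Replicated expression time series: container, I/O and preprocessing.

The central object is :class:`ExpressionTimeSeries`, a dense (gene, time,
replicate) array of expression values together with a mask of originally
missing entries.  Values are expected to arrive already variance-stabilised
(e.g. log TPM); this module never applies log or TPM transforms itself.

Preprocessing mirrors the model's assumptions: each gene temporal profile
(one gene, one replicate, all time points) is centred to mean zero across
time without rescaling its variance, and isolated missing time points are
filled by linear interpolation against the actual sampling times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTimeSeries",
    "GeneClassAnnotation",
    "read_timeseries",
    "write_timeseries",
    "center_profiles",
    "interpolate_missing",
    "drop_zero_variance",
    "read_annotation",
]

logger = logging.getLogger(__name__)

#: warn when the ratio of the largest to smallest sampling gap exceeds this;
#: autoregressive fits assume roughly similar spacing between time points.
GAP_RATIO_WARN = 4.0


@dataclass(frozen=True)
class ExpressionTimeSeries:
    """Expression values for ``p`` genes at ``T`` times over ``R`` replicates.

    Parameters
    ----------
    gene_ids
        Ordered unique gene labels, length ``p``.
    time_points
        Strictly increasing sampling times, length ``T`` (real units, e.g.
        hours; spacing need not be uniform).
    replicate_ids
        Replicate labels, length ``R``.
    values
        Array of shape ``(p, T, R)``.  Entries flagged in ``missing_mask``
        are NaN until :func:`interpolate_missing` fills them.
    missing_mask
        Boolean array of shape ``(p, T, R)`` marking originally missing
        (gene, time, replicate) entries.
    """

    gene_ids: tuple[str, ...]
    time_points: np.ndarray
    replicate_ids: tuple[str, ...]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "replicate_ids", tuple(str(r) for r in self.replicate_ids))
        tp = np.asarray(self.time_points, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "values", vals)
        if self.missing_mask is None:
            object.__setattr__(self, "missing_mask", np.isnan(vals))
        else:
            object.__setattr__(self, "missing_mask", np.asarray(self.missing_mask, dtype=bool))

        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if tp.ndim != 1 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing")
        expected = (len(self.gene_ids), tp.size, len(self.replicate_ids))
        if vals.shape != expected:
            raise ValueError(f"values shape {vals.shape} != (p, T, R) = {expected}")
        if self.missing_mask.shape != expected:
            raise ValueError("missing_mask shape must match values")
        if tp.size >= 2:
            gaps = np.diff(tp)
            ratio = gaps.max() / gaps.min()
            if ratio > GAP_RATIO_WARN:
                logger.warning(
                    "time point spacing is uneven (max/min gap ratio %.2f > %.1f); "
                    "lagged regression assumes similarly-spaced samples",
                    ratio,
                    GAP_RATIO_WARN,
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.time_points.size

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass(frozen=True)
class GeneClassAnnotation:
    """A named gene class (e.g. TF / immune / metabolic) as a member set."""

    class_name: str
    members: frozenset[str]

    def restricted_to(self, universe: set[str]) -> "GeneClassAnnotation":
        return GeneClassAnnotation(self.class_name, frozenset(self.members & universe))


def read_timeseries(path, layout: str = "long") -> ExpressionTimeSeries:
    """Read an expression time series from a TSV file.

    ``long`` layout (canonical) has header columns
    ``gene  time  replicate  value``.  ``wide`` layout has one row per gene
    and one column per sample, with sample columns named ``<time>:<replicate>``.
    Absent (gene, time, replicate) combinations are recorded as missing, not
    zero-filled.
    """
    if layout == "long":
        return _read_long(path)
    if layout == "wide":
        return _read_wide(path)
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def _read_long(path) -> ExpressionTimeSeries:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "replicate": str},
        float_precision="round_trip",
    )
    required = ["gene", "time", "replicate", "value"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long TSV is missing columns {missing_cols} in {path}")

    value = pd.to_numeric(df["value"], errors="coerce")
    bad = value.isna() & df["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"non-numeric value {df['value'].iloc[row]!r} at line {row + 2} of {path}"
        )
    df = df.assign(value=value)

    dup = df.duplicated(subset=["gene", "time", "replicate"], keep=False)
    if dup.any():
        g, t, r = df.loc[dup, ["gene", "time", "replicate"]].iloc[0]
        raise ValueError(f"duplicate (gene, time, replicate) triple ({g}, {t}, {r}) in {path}")

    genes = list(dict.fromkeys(df["gene"]))
    times = np.array(sorted(df["time"].unique()), dtype=float)
    reps = sorted(df["replicate"].unique())

    p, T, R = len(genes), times.size, len(reps)
    values = np.full((p, T, R), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(reps)}
    values[
        df["gene"].map(gi).to_numpy(),
        df["time"].astype(float).map(ti).to_numpy(),
        df["replicate"].map(ri).to_numpy(),
    ] = df["value"].to_numpy()
    return ExpressionTimeSeries(tuple(genes), times, tuple(reps), values)


def _read_wide(path) -> ExpressionTimeSeries:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    if "gene" not in df.columns:
        raise ValueError(f"wide TSV must have a 'gene' column in {path}")
    sample_cols = [c for c in df.columns if c != "gene"]
    parsed = []
    for c in sample_cols:
        try:
            t_str, r = c.split(":", 1)
            parsed.append((float(t_str), r, c))
        except ValueError:
            raise ValueError(
                f"wide column {c!r} is not of the form '<time>:<replicate>' in {path}"
            ) from None
    if df["gene"].duplicated().any():
        g = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene row {g!r} in {path}")

    genes = list(df["gene"])
    times = np.array(sorted({t for t, _, _ in parsed}), dtype=float)
    reps = sorted({r for _, r, _ in parsed})
    values = np.full((len(genes), times.size, len(reps)), np.nan)
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(reps)}
    for t, r, c in parsed:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value {df[c].iloc[row]!r} at line {row + 2} of {path}")
        values[:, ti[t], ri[r]] = col.to_numpy()
    return ExpressionTimeSeries(tuple(genes), times, tuple(reps), values)


def write_timeseries(ts: ExpressionTimeSeries, path) -> None:
    """Write in the canonical long layout; missing entries are omitted."""
    rows = []
    for i, g in enumerate(ts.gene_ids):
        for j, t in enumerate(ts.time_points):
            for k, r in enumerate(ts.replicate_ids):
                if not ts.missing_mask[i, j, k]:
                    rows.append((g, repr(float(t)), r, repr(float(ts.values[i, j, k]))))
    df = pd.DataFrame(rows, columns=["gene", "time", "replicate", "value"])
    df.to_csv(path, sep="\t", index=False)


def center_profiles(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Subtract each (gene, replicate) profile's mean across time.

    Variance is deliberately not rescaled: standardising to unit variance
    would over-weight the weak effects of genes with low variability.
    Idempotent.
    """
    if ts.has_missing:
        raise ValueError("missing entries present; run interpolate_missing first")
    centered = ts.values - ts.values.mean(axis=1, keepdims=True)
    return replace(ts, values=centered, missing_mask=np.zeros_like(ts.missing_mask))


def interpolate_missing(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Fill missing entries by linear interpolation against sampling times.

    Interpolation is linear in the real time coordinate, not the index.
    Missing values at the first or last time point are an error (no
    extrapolation is performed).
    """
    if not ts.has_missing:
        return ts
    values = ts.values.copy()
    tp = ts.time_points
    for i, g in enumerate(ts.gene_ids):
        for k, r in enumerate(ts.replicate_ids):
            miss = ts.missing_mask[i, :, k]
            if not miss.any():
                continue
            if miss[0] or miss[-1]:
                raise ValueError(
                    f"gene {g!r} replicate {r!r} is missing a terminal time point; "
                    "linear interpolation cannot extrapolate"
                )
            obs = ~miss
            values[i, miss, k] = np.interp(tp[miss], tp[obs], values[i, obs, k])
    return replace(ts, values=values, missing_mask=np.zeros_like(ts.missing_mask))


def drop_zero_variance(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Drop genes whose values are constant across all samples.

    Constant profiles carry no temporal signal and destabilise leave-one-out
    cross-validation; dropped genes are reported via the module logger.
    """
    flat = ts.values.reshape(ts.n_genes, -1)
    keep = ~np.all(np.isclose(flat, flat[:, :1]), axis=1)
    if keep.all():
        return ts
    dropped = [g for g, k in zip(ts.gene_ids, keep) if not k]
    logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), ", ".join(dropped))
    return ExpressionTimeSeries(
        tuple(g for g, k in zip(ts.gene_ids, keep) if k),
        ts.time_points,
        ts.replicate_ids,
        ts.values[keep],
        ts.missing_mask[keep],
    )


def read_annotation(path, class_name: str) -> GeneClassAnnotation:
    """Read a gene class from a plain-text file, one gene label per line."""
    with open(path, encoding="utf-8") as fh:
        members = frozenset(line.strip() for line in fh if line.strip())
    return GeneClassAnnotation(class_name, members)
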