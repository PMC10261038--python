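"""GC-TOF-MS peak-area matrix container and preprocessing.

A :class:`MetaboliteMatrix` holds a peaks x samples table of peak areas plus
per-peak metadata (annotation, internal-standard flag). Samples are named
``<line_id>.<replicate>``. Preprocessing turns raw areas into an analysis
matrix in two steps:

1. :func:`is_normalize` — divide each sample by a scale factor derived from
   the stable-isotope internal-standard (IS) peaks, removing sample-level
   technical variation (injection volume, detector drift);
2. :func:`impute_and_log2` — replace zeros/missing values, then log2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetaboliteMatrix", "is_normalize", "impute_and_log2", "count_annotated"]

_META_COLUMNS = ["annotation", "is_internal_standard"]


@dataclass
class MetaboliteMatrix:
    """Peak-area matrix with peak metadata.

    Attributes
    ----------
    peaks : DataFrame
        Indexed by ``peak_id``; columns ``annotation`` (metabolite name or
        ``"unknown"``) and ``is_internal_standard`` (bool). May carry an
        ``is_consumed`` flag after normalization.
    data : DataFrame
        Indexed by ``peak_id``, one column per sample named
        ``<line_id>.<replicate>``; areas are >= 0 or NaN (missing).
    scale : str
        ``"linear"`` for raw/normalized areas, ``"log2"`` after transform.
    normalized : bool
        Whether internal-standard normalization has been applied.
    """

    peaks: pd.DataFrame
    data: pd.DataFrame
    scale: str = "linear"
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.peaks.index.equals(self.data.index):
            raise ValueError("peaks and data must share the same peak_id index")
        for col in _META_COLUMNS:
            if col not in self.peaks.columns:
                raise ValueError(f"peak metadata missing column {col!r}")
        if self.scale == "linear" and (self.data.to_numpy() < 0).any():
            raise ValueError("peak areas must be nonnegative")

    # -- sample metadata -------------------------------------------------
    @property
    def sample_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> pd.DataFrame:
        """Sample metadata derived from column names ``line.replicate``."""
        lines, reps = [], []
        for name in self.data.columns:
            line, _, rep = name.rpartition(".")
            lines.append(line)
            reps.append(int(rep))
        return pd.DataFrame(
            {"sample": self.data.columns, "line_id": lines, "replicate": reps}
        ).set_index("sample")

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for line in self.samples["line_id"]:
            seen.setdefault(line, None)
        return list(seen)

    def columns_for(self, line_id: str) -> list[str]:
        meta = self.samples
        return list(meta.index[meta["line_id"] == line_id])

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.peaks.copy(), self.data.copy(), scale=self.scale, normalized=self.normalized
        )

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = pd.concat([self.peaks[_META_COLUMNS], self.data], axis=1)
        out.index.name = "peak_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, *, scale: str = "linear", normalized: bool = False) -> "MetaboliteMatrix":
        df = pd.read_csv(path, index_col="peak_id")
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"matrix file {path} missing column(s): {missing}")
        peaks = df[_META_COLUMNS].copy()
        peaks["is_internal_standard"] = peaks["is_internal_standard"].astype(bool)
        data = df.drop(columns=_META_COLUMNS).astype(float)
        return cls(peaks, data, scale=scale, normalized=normalized)


def is_normalize(
    matrix: MetaboliteMatrix, is_map: dict[str, str] | None = None
) -> tuple[MetaboliteMatrix, pd.Series]:
    """Internal-standard normalization by per-sample geometric-mean scaling.

    Each sample's scale factor is the geometric mean of its IS peak areas
    divided by the grand geometric mean of IS areas across all samples; every
    peak area in the sample is divided by that factor. IS rows are retained
    (flagged ``is_consumed``) and normalized along with the rest, which makes
    the operation idempotent: a second application finds unit factors.

    ``is_map`` optionally assigns a specific IS peak to individual peaks
    (``{peak_id: is_peak_id}``, e.g. matching compound class); a mapped peak
    is scaled by its own standard's per-sample factor instead of the pooled
    one. Unmapped peaks use the pooled factor.

    Returns the normalized matrix and the pooled per-sample factors.
    """
    if matrix.scale != "linear":
        raise ValueError("is_normalize expects a linear-scale matrix")
    is_mask = matrix.peaks["is_internal_standard"].to_numpy(dtype=bool)
    if not is_mask.any():
        raise ValueError("no internal-standard peaks flagged")
    is_block = matrix.data.loc[is_mask]
    bad = [
        str(s)
        for s in is_block.columns
        if is_block[s].isna().any() or (is_block[s] <= 0).any()
    ]
    if bad:
        raise ValueError(f"internal standard missing or nonpositive in sample(s): {', '.join(bad)}")
    log_is = np.log(is_block.to_numpy(dtype=float))
    per_sample = np.exp(log_is.mean(axis=0))
    grand = np.exp(log_is.mean())
    factors = pd.Series(per_sample / grand, index=matrix.data.columns, name="scale_factor")

    out = matrix.copy()
    out.data = out.data.div(factors, axis=1)
    if is_map:
        is_ids = set(matrix.peaks.index[is_mask])
        bad_targets = set(is_map.values()) - is_ids
        if bad_targets:
            raise ValueError(f"is_map targets are not IS peaks: {sorted(bad_targets)}")
        for peak_id, is_peak in is_map.items():
            row = matrix.data.loc[is_peak]
            own = row / np.exp(np.mean(np.log(row.to_numpy(dtype=float))))
            out.data.loc[peak_id] = matrix.data.loc[peak_id] / own
    out.normalized = True
    out.peaks = out.peaks.copy()
    out.peaks["is_consumed"] = out.peaks["is_internal_standard"]
    return out, factors


def impute_and_log2(matrix: MetaboliteMatrix, mode: str = "halfmin") -> MetaboliteMatrix:
    """Missing-value imputation followed by log2 transformation.

    ``halfmin`` (default) replaces zeros/missing with half the smallest
    positive value of that peak across samples, which keeps fold changes of
    low-abundance peaks bounded; ``offset`` computes ``log2(x + 1)`` with
    missing treated as 0. Peaks missing in every sample are dropped with a
    warning.
    """
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    if mode not in ("halfmin", "offset"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    values = matrix.data.to_numpy(dtype=float)
    if values.size and np.nanmin(values) < 0:
        raise ValueError("negative peak areas")

    out = matrix.copy()
    positive_any = (out.data > 0).any(axis=1)
    n_dropped = int((~positive_any).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} peak(s) missing in all samples", stacklevel=2)
        out.data = out.data.loc[positive_any]
        out.peaks = out.peaks.loc[positive_any]

    if mode == "halfmin":
        filled = out.data.copy()
        for peak in filled.index:
            row = filled.loc[peak]
            mask = row.isna() | (row <= 0)
            if mask.any():
                half_min = row[row > 0].min() / 2.0
                filled.loc[peak, mask[mask].index] = half_min
        out.data = np.log2(filled)
    else:
        out.data = np.log2(out.data.fillna(0.0) + 1.0)
    out.scale = "log2"
    return out


def count_annotated(matrix: MetaboliteMatrix) -> dict[str, int]:
    """Number of detected peaks and of peaks with a known annotation.

    Internal-standard peaks carry their compound annotation and therefore
    count as known.
    """
    annotations = matrix.peaks["annotation"].astype(str)
    return {
        "n_peaks": int(len(annotations)),
        "n_known": int((annotations.str.lower() != "unknown").sum()),
    }
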