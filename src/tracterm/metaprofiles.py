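"""Scaled metagene matrices and TES-downstream heat maps.

Rows are TUs, oriented 5'->3' on each TU's own strand; gene bodies are
length-normalized into a fixed number of bins (mean within bin, equal base
partition with the remainder spread left-to-right) while flanks stay at
single-base resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TUAnnotation


@dataclass
class MetaMatrix:
    """TU x meta-position matrix with a recorded axis layout.

    ``axis`` labels each column block; ``excluded`` lists TUs flagged out of
    the mean (too short to fill the body bins).  ``mean_curve`` is the column
    mean over the non-excluded rows.
    """

    matrix: np.ndarray
    tu_ids: list[str]
    columns: list[str]
    axis: str
    excluded: list[str]

    @property
    def mean_curve(self) -> np.ndarray:
        keep = [i for i, t in enumerate(self.tu_ids) if t not in self.excluded]
        if not keep:
            return np.full(self.matrix.shape[1], np.nan)
        sub = self.matrix[keep]
        defined = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_sum = np.nansum(sub, axis=0)
        return np.where(defined > 0, col_sum / np.maximum(defined, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.tu_ids, columns=self.columns)


def _bin_edges(n_bases: int, n_bins: int) -> np.ndarray:
    base, rem = divmod(n_bases, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def _oriented(values: dict, tu: TUAnnotation, lo: int, hi: int) -> np.ndarray:
    """Slice a dense per-base track sense-oriented, zero-padded at the edges."""
    arr = values[(tu.chrom, tu.strand)]
    out = np.zeros(hi - lo, dtype=float)
    s, e = max(lo, 0), min(hi, len(arr))
    if e > s:
        out[s - lo:e - lo] = arr[s:e]
    return out if tu.strand == "+" else out[::-1]


def scaled_metaprofile(
    values: dict[tuple[str, str], np.ndarray],
    tus: list[TUAnnotation],
    upstream_bp: int = 200,
    body_bins: int = 100,
    downstream_bp: int = 3000,
) -> MetaMatrix:
    """Per-TU meta-rows: unscaled upstream flank, length-normalized body,
    unscaled downstream flank.

    ``values`` is any dense per-(chrom, strand) track (counts, CPM, or log2
    change).  TUs shorter than ``body_bins`` bases are kept as rows but
    flagged and excluded from the mean curve.
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    n_cols = upstream_bp + body_bins + downstream_bp
    rows = []
    excluded = []
    for tu in tus:
        if tu.strand == "+":
            lo, hi = tu.start - upstream_bp, tu.end + downstream_bp
        else:
            lo, hi = tu.start - downstream_bp, tu.end + upstream_bp
        window = _oriented(values, tu, lo, hi)
        up = window[:upstream_bp]
        body = window[upstream_bp:upstream_bp + tu.body_length]
        down = window[upstream_bp + tu.body_length:]
        row = np.empty(n_cols)
        row[:upstream_bp] = up
        if tu.body_length < body_bins:
            excluded.append(tu.tu_id)
            row[upstream_bp:upstream_bp + body_bins] = np.nan
        else:
            edges = _bin_edges(tu.body_length, body_bins)
            for i in range(body_bins):
                row[upstream_bp + i] = body[edges[i]:edges[i + 1]].mean()
        row[upstream_bp + body_bins:] = down
        rows.append(row)
    columns = (
        [f"up{upstream_bp - i}" for i in range(upstream_bp)]
        + [f"body{i + 1}" for i in range(body_bins)]
        + [f"down{i + 1}" for i in range(downstream_bp)]
    )
    return MetaMatrix(
        np.vstack(rows) if rows else np.empty((0, n_cols)),
        [tu.tu_id for tu in tus],
        columns,
        axis=f"up{upstream_bp}|body x{body_bins}|down{downstream_bp} "
             "(0-based half-open, sense-oriented)",
        excluded=excluded,
    )


def downstream_heatmap(
    values: dict[tuple[str, str], np.ndarray],
    tus: list[TUAnnotation],
    window: int = 3000,
) -> MetaMatrix:
    """Per-TU per-base track over [TES, TES+window), sense-oriented."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for tu in tus:
        ds, de = (tu.end, tu.end + window) if tu.strand == "+" else (
            tu.start - window, tu.start
        )
        rows.append(_oriented(values, tu, ds, de))
    return MetaMatrix(
        np.vstack(rows) if rows else np.empty((0, window)),
        [tu.tu_id for tu in tus],
        [f"tes+{i + 1}" for i in range(window)],
        axis=f"TES downstream {window} bp (sense-oriented)",
        excluded=[],
    )


def sort_rows_by_sum(meta: MetaMatrix) -> MetaMatrix:
    """Rows in decreasing row-sum order; equal sums keep input order."""
    with np.errstate(invalid="ignore"):
        sums = np.nansum(meta.matrix, axis=1)
    order = np.argsort(-sums, kind="stable")
    return MetaMatrix(
        meta.matrix[order],
        [meta.tu_ids[i] for i in order],
        meta.columns,
        meta.axis,
        meta.excluded,
    )
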