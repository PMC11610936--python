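"""Normalization, per-base log2 differentials, stabilized-end calling,
region aggregation, TU selection, and condition-comparison statistics.

The calling logic mirrors the field's hard fold-change convention: a
position's end signal is "stabilized" in a depletion condition when its
pseudocounted CPM log2 ratio against the paired control reaches a threshold
(default >= 1) and the treatment carries a minimum raw count.  No per-position
hypothesis tests are computed — thresholds, not p-values, define the call
set, and every threshold is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import STRANDS, EndProfile, TUAnnotation

DEFAULT_PSEUDOCOUNT = 1.0  # CPM units, added to numerator and denominator


def _check_pair(treatment: EndProfile, control: EndProfile) -> None:
    if treatment.flavor != control.flavor or treatment.epap != control.epap:
        raise ValueError(
            "treatment and control must share flavor and EPAP status "
            f"({treatment.flavor}/{treatment.epap} vs "
            f"{control.flavor}/{control.epap})"
        )
    if treatment.chrom_sizes != control.chrom_sizes:
        raise ValueError("treatment and control are on different genomes")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_cpm(profile: EndProfile) -> dict[tuple[str, str], np.ndarray]:
    """Per-base counts-per-million track: count * 1e6 / library_size."""
    lib = profile.library_size
    if lib <= 0:
        raise ValueError("cannot CPM-normalize a profile with zero library size")
    return {key: arr * (1e6 / lib) for key, arr in profile.counts.items()}


def region_rpkm(profile: EndProfile, chrom: str, strand: str,
                start: int, end: int) -> float:
    """Reads per kilobase per million mapped reads over [start, end)."""
    lib = profile.library_size
    if lib <= 0:
        raise ValueError("zero library size")
    if end <= start:
        raise ValueError("empty region")
    total = int(profile.array(chrom, strand)[start:end].sum())
    return total * 1e9 / (lib * (end - start))


# ---------------------------------------------------------------------------
# Fold-change tracks
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeTrack:
    """Per-base log2(treatment/control) in CPM with a recorded pseudocount.

    ``values`` holds dense float arrays with NaN wherever neither sample has
    signal (the ratio is defined only at covered positions).
    """

    values: dict[tuple[str, str], np.ndarray]
    pseudocount: float
    treatment_id: str
    control_id: str
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.values:
            self.values[key] = np.full(self.chrom_sizes[chrom], np.nan)
        return self.values[key]


def log2_ratio_track(
    treatment: EndProfile,
    control: EndProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTrack:
    """log2((cpm_t + pc) / (cpm_c + pc)) at every covered position."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    _check_pair(treatment, control)
    cpm_t = normalize_cpm(treatment)
    cpm_c = normalize_cpm(control)
    values = {}
    for chrom, size in treatment.chrom_sizes.items():
        for strand in STRANDS:
            t = cpm_t.get((chrom, strand), np.zeros(size))
            c = cpm_c.get((chrom, strand), np.zeros(size))
            covered = (t > 0) | (c > 0)
            out = np.full(size, np.nan)
            out[covered] = np.log2(
                (t[covered] + pseudocount) / (c[covered] + pseudocount)
            )
            values[(chrom, strand)] = out
    return FoldChangeTrack(
        values, pseudocount, treatment.sample_id, control.sample_id,
        dict(treatment.chrom_sizes),
    )


# ---------------------------------------------------------------------------
# Stabilized-end calling
# ---------------------------------------------------------------------------

@dataclass
class EndCallSet:
    """Positions whose end signal is stabilized in the depletion condition.

    ``calls`` columns: chrom, pos, strand, treat_count, ctrl_count, log2fc.
    """

    calls: pd.DataFrame
    min_log2: float
    min_count: int
    pseudocount: float
    treatment_id: str = ""
    control_id: str = ""

    def __len__(self) -> int:
        return len(self.calls)

    def subset(self, mask) -> "EndCallSet":
        return EndCallSet(
            self.calls[mask].reset_index(drop=True),
            self.min_log2, self.min_count, self.pseudocount,
            self.treatment_id, self.control_id,
        )


_CALL_COLUMNS = ["chrom", "pos", "strand", "treat_count", "ctrl_count", "log2fc"]


def call_stabilized_ends(
    treatment: EndProfile,
    control: EndProfile,
    min_log2: float = 1.0,
    min_count: int = 1,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EndCallSet:
    """Return exactly the positions passing both calling thresholds."""
    if min_log2 < 0:
        raise ValueError("min_log2 must be >= 0")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    fc = log2_ratio_track(treatment, control, pseudocount)
    rows = []
    for chrom in sorted(treatment.chrom_sizes):
        for strand in STRANDS:
            t = treatment.array(chrom, strand)
            c = control.array(chrom, strand)
            lfc = fc.array(chrom, strand)
            with np.errstate(invalid="ignore"):
                mask = (t >= min_count) & (lfc >= min_log2)
            for pos in np.nonzero(mask)[0]:
                rows.append(
                    (chrom, int(pos), strand, int(t[pos]), int(c[pos]),
                     float(lfc[pos]))
                )
    calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    return EndCallSet(
        calls, min_log2, min_count, pseudocount,
        treatment.sample_id, control.sample_id,
    )


def filter_calls_to_regions(
    calls: EndCallSet,
    regions: list[tuple[str, int, int, str]],
    match_strand: bool = True,
) -> EndCallSet:
    """Keep calls inside any region (chrom, start, end, strand)."""
    if not len(calls.calls):
        return calls
    keep = np.zeros(len(calls.calls), dtype=bool)
    for chrom, start, end, strand in regions:
        m = (
            (calls.calls.chrom == chrom)
            & (calls.calls.pos >= start)
            & (calls.calls.pos < end)
        )
        if match_strand:
            m &= calls.calls.strand == strand
        keep |= m.to_numpy()
    return calls.subset(keep)


def tu_regions(
    tus: list[TUAnnotation],
    part: str = "span",
    downstream_window: int = 3000,
    upstream_window: int = 0,
) -> list[tuple[str, int, int, str]]:
    """Region tuples for a TU stratum: 'body', 'downstream', or 'span'
    (body plus downstream window, plus an optional sense-upstream window)."""
    regions = []
    for tu in tus:
        if part == "body":
            s, e = tu.start, tu.end
        elif part == "downstream":
            s, e = tu.downstream_interval(downstream_window)
        elif part == "span":
            ds, de = tu.downstream_interval(downstream_window)
            s, e = min(tu.start, ds), max(tu.end, de)
            if upstream_window:
                if tu.strand == "+":
                    s = max(0, s - upstream_window)
                else:
                    e = e + upstream_window
        else:
            raise ValueError(f"unknown region part {part!r}")
        regions.append((tu.chrom, s, e, tu.strand))
    return regions


# ---------------------------------------------------------------------------
# Region aggregation and TU selection
# ---------------------------------------------------------------------------

@dataclass
class RegionSignalTable:
    """Per-TU body and TES-downstream signal for one treatment/control pair.

    ``table`` columns: tu_id, biotype, exon_count, body_raw_t/c,
    down_raw_t/c, body_cpm_t/c, down_cpm_t/c, body_log2, down_log2.
    """

    table: pd.DataFrame
    downstream_window: int
    pseudocount: float
    treatment_id: str = ""
    control_id: str = ""


def region_signal(
    treatment: EndProfile,
    control: EndProfile,
    tus: list[TUAnnotation],
    downstream_window: int = 3000,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RegionSignalTable:
    """Strand-aware CPM sums over TU bodies and TES-downstream windows."""
    if downstream_window <= 0:
        raise ValueError("downstream window must be positive")
    _check_pair(treatment, control)
    lib_t, lib_c = treatment.library_size, control.library_size
    if lib_t <= 0 or lib_c <= 0:
        raise ValueError("zero library size")
    rows = []
    for tu in tus:
        ds, de = tu.downstream_interval(downstream_window)
        body_t = int(treatment.array(tu.chrom, tu.strand)[tu.start:tu.end].sum())
        body_c = int(control.array(tu.chrom, tu.strand)[tu.start:tu.end].sum())
        down_t = int(treatment.array(tu.chrom, tu.strand)[ds:de].sum())
        down_c = int(control.array(tu.chrom, tu.strand)[ds:de].sum())
        b_t, b_c = body_t * 1e6 / lib_t, body_c * 1e6 / lib_c
        d_t, d_c = down_t * 1e6 / lib_t, down_c * 1e6 / lib_c
        rows.append(
            dict(
                tu_id=tu.tu_id, biotype=tu.biotype, exon_count=tu.exon_count,
                body_raw_t=body_t, body_raw_c=body_c,
                down_raw_t=down_t, down_raw_c=down_c,
                body_cpm_t=b_t, body_cpm_c=b_c,
                down_cpm_t=d_t, down_cpm_c=d_c,
                body_log2=float(np.log2((b_t + pseudocount) / (b_c + pseudocount))),
                down_log2=float(np.log2((d_t + pseudocount) / (d_c + pseudocount))),
            )
        )
    return RegionSignalTable(
        pd.DataFrame(rows), downstream_window, pseudocount,
        treatment.sample_id, control.sample_id,
    )


def select_flank_stabilized_tus(
    table: RegionSignalTable,
    flank_min_log2: float = 1.5,
    body_max_log2: float = 0.5,
) -> list[str]:
    """TUs whose TES flank is stabilized without a gene-body increase.

    Returns the tu_ids with downstream log2 change >= ``flank_min_log2`` and
    body log2 change <= ``body_max_log2``, in table order.
    """
    df = table.table
    mask = (df.down_log2 >= flank_min_log2) & (df.body_log2 <= body_max_log2)
    return df.loc[mask, "tu_id"].tolist()


# ---------------------------------------------------------------------------
# Condition-comparison statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    a_in_b: float   # % of a's positions with a b position within tolerance
    b_in_a: float
    tolerance: int

    @property
    def symmetric(self) -> float:
        return 0.5 * (self.a_in_b + self.b_in_a)


def _positions_by_key(calls: EndCallSet):
    out = {}
    for (chrom, strand), grp in calls.calls.groupby(["chrom", "strand"]):
        out[(chrom, strand)] = np.sort(grp.pos.to_numpy())
    return out


def _directional(a_pos, b_pos, tol) -> float:
    total = sum(len(v) for v in a_pos.values())
    if total == 0:
        return float("nan")
    hit = 0
    for key, pos in a_pos.items():
        b = b_pos.get(key)
        if b is None or not len(b):
            continue
        idx = np.searchsorted(b, pos)
        left = np.abs(b[np.clip(idx - 1, 0, len(b) - 1)] - pos) <= tol
        right = np.abs(b[np.clip(idx, 0, len(b) - 1)] - pos) <= tol
        hit += int(np.count_nonzero(left | right))
    return 100.0 * hit / total


def end_position_concordance(
    a: EndCallSet, b: EndCallSet, tolerance: int = 0
) -> ConcordanceResult:
    """Percentage of end positions shared between two call sets within ±tolerance.

    Both directions are computed; ``.symmetric`` is their mean.  Positions
    only match within the same chromosome and strand.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a_pos, b_pos = _positions_by_key(a), _positions_by_key(b)
    return ConcordanceResult(
        _directional(a_pos, b_pos, tolerance),
        _directional(b_pos, a_pos, tolerance),
        tolerance,
    )


def body_downstream_fc_correlation(table: RegionSignalTable) -> float:
    """Pearson r of per-TU body vs. downstream log2 change.

    A coefficient near 1 indicates a uniform change of transcription flux
    (body and flank scale together), as opposed to a termination defect,
    which inflates the flank only.
    """
    df = table.table
    if len(df) < 3:
        raise ValueError("need at least 3 TUs for a correlation")
    r, _ = stats.pearsonr(df.body_log2, df.down_log2)
    return float(r)


def last_detected_position(
    profile: EndProfile,
    tu: TUAnnotation,
    max_downstream: int = 10000,
    smooth: int = 21,
    floor_cpm: float = 0.1,
) -> int | None:
    """Most 3' position within TES+max_downstream whose smoothed CPM (running
    mean over ``smooth`` bases) exceeds ``floor_cpm``; None if nothing does."""
    lib = profile.library_size
    if lib <= 0:
        raise ValueError("zero library size")
    ds, de = tu.downstream_interval(max_downstream)
    lo = min(tu.start, ds)
    hi = max(tu.end, de)
    arr = profile.array(tu.chrom, tu.strand)[lo:hi] * (1e6 / lib)
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(arr, kernel, mode="same")
    above = np.nonzero(sm > floor_cpm)[0]
    if not len(above):
        return None
    return int(lo + above[-1]) if tu.strand == "+" else int(lo + above[0])
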