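"""Terminal k-mer extraction, enrichment ranking, background-corrected
T-fraction statistics, T-run location, and the distance-binned T-tract
meta-analysis.

All motifs are reported as the coding-strand DNA equivalent of the RNA
3' terminus: the k bases ending at (and including) a called end position,
read 5'->3' on the called end's own strand.  A T-run on the coding strand
of a minus-strand TU is an A-run in the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import EndCallSet, FoldChangeTrack
from .io import TUAnnotation
from .seqs import revcomp

_DNA = set("ACGT")


class KmerWindowError(ValueError):
    """The k-mer window extends beyond the sequence."""


# ---------------------------------------------------------------------------
# Terminal k-mers
# ---------------------------------------------------------------------------

def terminal_kmer(
    seqs: dict[str, str], chrom: str, pos: int, strand: str, k: int = 6
) -> str | None:
    """Coding-strand k-mer whose last base is the called 3'-end position.

    Plus strand: reference bases [pos-k+1, pos+1); minus strand: reverse
    complement of reference bases [pos, pos+k).  Returns None (skip) when the
    window contains an ambiguous base; raises on an out-of-bounds window.
    """
    seq = seqs[chrom]
    if strand == "+":
        start = pos - k + 1
        if start < 0 or pos >= len(seq):
            raise KmerWindowError(f"window [{start},{pos + 1}) outside {chrom}")
        kmer = seq[start:pos + 1]
    elif strand == "-":
        if pos < 0 or pos + k > len(seq):
            raise KmerWindowError(f"window [{pos},{pos + k}) outside {chrom}")
        kmer = revcomp(seq[pos:pos + k])
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if set(kmer) - _DNA:
        return None
    return kmer


@dataclass
class KmerTable:
    """Ranked counts of terminal k-mers over a call set.

    ``table`` columns: kmer, count, rank (1-based; ties broken
    lexicographically).  ``sum(count) + skipped`` equals the number of calls
    (or the summed weights in count-weighted mode).
    """

    table: pd.DataFrame
    k: int
    total: int
    skipped: int
    weight: str
    source: str = ""

    def top(self, n: int = 5) -> list[str]:
        return self.table.kmer.head(n).tolist()

    def count_of(self, kmer: str) -> int:
        hit = self.table.loc[self.table.kmer == kmer, "count"]
        return int(hit.iloc[0]) if len(hit) else 0

    def rank_of(self, kmer: str) -> int | None:
        hit = self.table.loc[self.table.kmer == kmer, "rank"]
        return int(hit.iloc[0]) if len(hit) else None


def count_terminal_kmers(
    calls: EndCallSet,
    seqs: dict[str, str],
    k: int = 6,
    weight: str = "unique_positions",
) -> KmerTable:
    """Tally coding-strand terminal k-mers at every called end position.

    ``weight='unique_positions'`` counts each called position once (the
    default); ``'count_weighted'`` weights by the treatment read count.
    Boundary and ambiguous-base windows are skipped, and the skip total is
    recorded so counts are conserved.
    """
    if weight not in ("unique_positions", "count_weighted"):
        raise ValueError(f"unknown weighting mode {weight!r}")
    counts: dict[str, int] = {}
    total = 0
    skipped = 0
    for row in calls.calls.itertuples(index=False):
        w = 1 if weight == "unique_positions" else int(row.treat_count)
        total += w
        try:
            kmer = terminal_kmer(seqs, row.chrom, int(row.pos), row.strand, k)
        except KmerWindowError:
            skipped += w
            continue
        if kmer is None:
            skipped += w
            continue
        counts[kmer] = counts.get(kmer, 0) + w
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["kmer", "count"],
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return KmerTable(df, k, total, skipped, weight, calls.treatment_id)


def is_t_run_kmer(kmer: str, min_t: int = 4) -> bool:
    """Whether a k-mer contains a run of ``min_t`` or more consecutive Ts."""
    return "T" * min_t in kmer


# ---------------------------------------------------------------------------
# T-fraction statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFractionResult:
    """Terminal-base T fraction of called ends vs. the genomic background.

    The background is the coding-strand T frequency over the supplied regions
    (strand-aware: reference A counts as T on the minus strand).  ``z`` is the
    normal-approximation z-score of the difference.
    """

    end_fraction: float
    genomic_fraction: float
    n_ends: int
    n_bases: int

    @property
    def stderr(self) -> float:
        se2 = self.end_fraction * (1 - self.end_fraction) / max(self.n_ends, 1)
        se2 += self.genomic_fraction * (1 - self.genomic_fraction) / max(
            self.n_bases, 1
        )
        return float(np.sqrt(se2))

    @property
    def z(self) -> float:
        se = self.stderr
        if se == 0:
            return 0.0
        return (self.end_fraction - self.genomic_fraction) / se


def t_fraction_statistic(
    calls: EndCallSet,
    seqs: dict[str, str],
    regions: list[tuple[str, int, int, str]],
) -> TFractionResult:
    """Fraction of called ends terminating at a coding-strand T, vs. the
    T frequency of the same (strand-aware) genomic regions."""
    if not regions:
        raise ValueError("empty region set")
    if not len(calls.calls):
        raise ValueError("empty call set: end fraction undefined")
    n_t = 0
    for row in calls.calls.itertuples(index=False):
        base = seqs[row.chrom][int(row.pos)]
        if row.strand == "-":
            base = revcomp(base)
        n_t += base == "T"
    g_t = 0
    g_n = 0
    for chrom, start, end, strand in regions:
        window = seqs[chrom][max(0, start):end]
        target = "T" if strand == "+" else "A"
        g_t += window.count(target)
        g_n += len(window)
    if g_n == 0:
        raise ValueError("regions cover zero bases")
    return TFractionResult(
        n_t / len(calls.calls), g_t / g_n, len(calls.calls), g_n
    )


# ---------------------------------------------------------------------------
# T-runs and distance bins
# ---------------------------------------------------------------------------

@dataclass
class TRunSet:
    """Maximal coding-strand T-runs per TU search window.

    ``runs`` columns: chrom, start, end (reference, half-open), strand,
    run_length, tu_id, offset (sense distance of the run's 5'-most base from
    the TU's TSS; negative for runs upstream of the TSS).
    """

    runs: pd.DataFrame
    min_run: int

    def __len__(self) -> int:
        return len(self.runs)


_RUN_COLS = ["chrom", "start", "end", "strand", "run_length", "tu_id", "offset"]


def find_t_runs(
    seqs: dict[str, str],
    tus: list[TUAnnotation],
    min_run: int = 6,
    downstream_window: int = 5000,
) -> TRunSet:
    """Locate maximal T-runs of length >= min_run on each TU's coding strand.

    The search window runs from the TSS to ``downstream_window`` bases past
    the TES (sense direction).  Runs are maximal within the window; a run
    touching the window edge is reported at its in-window extent.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    pattern = re.compile("T{%d,}" % min_run)
    rows = []
    for tu in tus:
        seq = seqs[tu.chrom]
        if tu.strand == "+":
            lo, hi = tu.start, min(len(seq), tu.end + downstream_window)
            window = seq[lo:hi]
        else:
            lo, hi = max(0, tu.start - downstream_window), tu.end
            window = revcomp(seq[lo:hi])
        for m in pattern.finditer(window):
            off = m.start()  # sense distance from TSS
            if tu.strand == "+":
                s, e = lo + m.start(), lo + m.end()
            else:
                s, e = hi - m.end(), hi - m.start()
            rows.append(
                (tu.chrom, s, e, tu.strand, m.end() - m.start(), tu.tu_id, off)
            )
    return TRunSet(pd.DataFrame(rows, columns=_RUN_COLS), min_run)


def write_t_runs_bed(runs: TRunSet, path) -> None:
    """BED6 with the run length in the score column."""
    with open(path, "w") as fh:
        for r in runs.runs.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.tu_id}\t{r.run_length}"
                f"\t{r.strand}\n"
            )


@dataclass
class BinnedRuns:
    """T-runs grouped by TSS-distance bin.

    ``bins`` maps a (lo_kb, hi_kb) label to the run sub-table whose sense
    start offset falls in [lo_kb*1000, hi_kb*1000); runs outside every bin
    are dropped and counted.
    """

    bins: dict[tuple[float, float], pd.DataFrame]
    dropped: int


DEFAULT_BINS_KB = ((0, 1), (1, 2), (2, 3), (3, 4))


def motif_distance_bins(
    runs: TRunSet,
    bins_kb=DEFAULT_BINS_KB,
) -> BinnedRuns:
    """Assign each run to the TSS-distance bin containing its start."""
    edges = sorted(bins_kb)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
        if b_lo < a_hi:
            raise ValueError("overlapping distance bins")
    out = {tuple(b): [] for b in bins_kb}
    dropped = 0
    for idx, r in runs.runs.iterrows():
        placed = False
        for lo, hi in bins_kb:
            # half-open in bases: [lo kb, hi kb)
            if lo * 1000 <= r.offset < hi * 1000:
                out[(lo, hi)].append(idx)
                placed = True
                break
        if not placed:
            dropped += 1
    return BinnedRuns(
        {
            b: runs.runs.loc[idxs].reset_index(drop=True)
            for b, idxs in out.items()
        },
        dropped,
    )


def stabilized_counts_per_bin(
    calls: EndCallSet,
    binned: BinnedRuns,
    weight: str = "count_weighted",
) -> dict[tuple[float, float], int]:
    """Tally of stabilized ends falling inside each bin's T-runs.

    ``count_weighted`` sums treatment read counts of calls within run bodies;
    ``unique_positions`` counts distinct called positions.
    """
    if weight not in ("unique_positions", "count_weighted"):
        raise ValueError(f"unknown weighting mode {weight!r}")
    out = {}
    df = calls.calls
    for b, runs in binned.bins.items():
        total = 0
        for r in runs.itertuples(index=False):
            m = (
                (df.chrom == r.chrom)
                & (df.strand == r.strand)
                & (df.pos >= r.start)
                & (df.pos < r.end)
            )
            if weight == "unique_positions":
                total += int(m.sum())
            else:
                total += int(df.loc[m, "treat_count"].sum())
        out[b] = total
    return out


# ---------------------------------------------------------------------------
# Fold change over motifs (length-normalized meta-curves)
# ---------------------------------------------------------------------------

def _bin_edges(n_bases: int, n_bins: int) -> np.ndarray:
    """Equal base partition, remainder spread left-to-right."""
    base = n_bases // n_bins
    rem = n_bases % n_bins
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def fc_over_motifs(
    fc: FoldChangeTrack,
    binned: BinnedRuns,
    flank: int = 10,
    body_bins: int = 6,
    undefined_as_zero: bool = True,
) -> pd.DataFrame:
    """Mean log2-change meta-curve over the runs of each distance bin.

    Each run is length-normalized to ``body_bins`` meta-positions with
    ``flank`` fixed single bases on each side (sense-oriented).  Positions
    uncovered in both samples count as zero change by default (coverage 0 vs
    0 is no stabilization), matching signal-intensity metaplots; with
    ``undefined_as_zero=False`` they are dropped from the mean instead.  An
    empty bin yields an all-NaN row.  Rows are bins; columns meta-positions.
    """
    n_cols = 2 * flank + body_bins
    rows = {}
    for b, runs in binned.bins.items():
        curves = []
        for r in runs.itertuples(index=False):
            arr = fc.array(r.chrom, r.strand)
            if undefined_as_zero:
                arr = np.nan_to_num(arr, nan=0.0)
            if r.strand == "+":
                lo, hi = r.start - flank, r.end + flank
                if lo < 0 or hi > len(arr):
                    continue
                window = arr[lo:hi]
            else:
                lo, hi = r.start - flank, r.end + flank
                if lo < 0 or hi > len(arr):
                    continue
                window = arr[lo:hi][::-1]
            body = window[flank:flank + r.run_length]
            edges = _bin_edges(r.run_length, body_bins)
            meta = np.empty(n_cols)
            meta[:flank] = window[:flank]
            for i in range(body_bins):
                seg = body[edges[i]:edges[i + 1]]
                seg = seg[~np.isnan(seg)]
                meta[flank + i] = seg.mean() if len(seg) else np.nan
            meta[flank + body_bins:] = window[flank + r.run_length:]
            curves.append(meta)
        if curves:
            stack = np.vstack(curves)
            defined = (~np.isnan(stack)).sum(axis=0)
            with np.errstate(invalid="ignore"):
                col_sum = np.nansum(stack, axis=0)
            rows[b] = np.where(defined > 0, col_sum / np.maximum(defined, 1), np.nan)
        else:
            rows[b] = np.full(n_cols, np.nan)
    cols = (
        [f"up{flank - i}" for i in range(flank)]
        + [f"body{i + 1}" for i in range(body_bins)]
        + [f"down{i + 1}" for i in range(flank)]
    )
    return pd.DataFrame(
        {f"{lo:g}-{hi:g}kb": rows[(lo, hi)] for lo, hi in binned.bins},
        index=cols,
    ).T
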