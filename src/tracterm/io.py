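"""Readers and writers for the on-disk formats the pipeline touches.

Canonical formats are all plain text: FASTA for the genome, BED6+2 for the
transcription-unit (TU) annotation, stranded bedGraph pairs (UCSC dialect,
0-based half-open) for per-base read-end count tracks, and a YAML manifest
mapping samples to conditions and paired controls.

All coordinates in this package are 0-based, half-open, on the reference
(plus) strand of the genome.  Readers reject malformed input rather than
silently repairing it, and every writer/reader pair round-trips bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")
FLAVORS = ("three_prime", "five_prime", "active_site")
CONDITIONS = ("CTRL", "dEXOSC3", "dXRN2", "dINT", "dINT_dEXOSC3")

_IUPAC = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed external input (bad FASTA/BED/bedGraph/manifest)."""


# ---------------------------------------------------------------------------
# Transcription units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TUAnnotation:
    """One transcription unit with a normalized body interval [start, end).

    ``tss``/``tes`` are derived from the strand: on ``+`` the TSS is ``start``
    and the TES is ``end``; on ``-`` the TSS is ``end`` and the TES ``start``,
    so the body is always ``[min, max)`` in reference coordinates.
    """

    tu_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exon_count: int
    pas_score: float | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r} for {self.tu_id}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid body interval for {self.tu_id}")
        if self.exon_count < 1:
            raise FormatError(f"exon_count must be >= 1 for {self.tu_id}")
        if self.pas_score is not None and not (0.0 <= self.pas_score <= 1.0):
            raise FormatError(f"pas_score outside [0,1] for {self.tu_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def body_length(self) -> int:
        return self.end - self.start

    @property
    def monoexonic(self) -> bool:
        return self.exon_count == 1

    def downstream_interval(self, window: int) -> tuple[int, int]:
        """Reference interval of the ``window`` bases 3' of the TES."""
        if window <= 0:
            raise ValueError("downstream window must be positive")
        if self.strand == "+":
            return self.end, self.end + window
        return max(0, self.start - window), self.start

    def transcript_to_ref(self, offset: int) -> int:
        """Map a sense-strand offset from the TSS to a reference position."""
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset

    def ref_to_transcript(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos


# ---------------------------------------------------------------------------
# End profiles
# ---------------------------------------------------------------------------

@dataclass
class EndProfile:
    """Stranded per-base integer counts of read-end positions for one sample.

    Counts are stored densely per (chrom, strand); ``library_size`` is always
    the grand total.  ``flavor`` distinguishes 3'-end, 5'-end, and polymerase
    active-site (mNET-style) tracks; ``epap`` records whether nonadenylated
    3' ends were made detectable by in vitro polyadenylation.
    """

    counts: dict[tuple[str, str], np.ndarray]
    chrom_sizes: dict[str, int]
    flavor: str = "three_prime"
    epap: bool = True
    sample_id: str = ""

    def __post_init__(self):
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}")
        for (chrom, strand), arr in self.counts.items():
            if strand not in STRANDS:
                raise ValueError(f"bad strand key {strand!r}")
            if chrom not in self.chrom_sizes:
                raise ValueError(f"counts for unknown chrom {chrom!r}")
            if len(arr) != self.chrom_sizes[chrom]:
                raise ValueError(f"count array length mismatch on {chrom}")
            if np.any(arr < 0):
                raise ValueError("negative counts")

    @classmethod
    def empty(cls, chrom_sizes, flavor="three_prime", epap=True, sample_id=""):
        counts = {
            (c, s): np.zeros(n, dtype=np.int64)
            for c, n in chrom_sizes.items()
            for s in STRANDS
        }
        return cls(counts, dict(chrom_sizes), flavor, epap, sample_id)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.counts:
            self.counts[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.int64)
        return self.counts[key]

    @property
    def library_size(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts.values()))

    def nonzero(self):
        """Yield (chrom, strand, positions, counts) for covered positions."""
        for (chrom, strand), arr in sorted(self.counts.items()):
            pos = np.nonzero(arr)[0]
            if len(pos):
                yield chrom, strand, pos, arr[pos]


@dataclass(frozen=True)
class Sample:
    """A loaded end profile plus its experimental condition and paired control."""

    profile: EndProfile
    condition: str
    control_id: str | None = None

    @property
    def sample_id(self) -> str:
        return self.profile.sample_id


@dataclass
class SampleSet:
    samples: list[Sample]
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    genome_path: str | None = None
    annotation_path: str | None = None

    def __post_init__(self):
        by_id = {s.sample_id: s for s in self.samples}
        if len(by_id) != len(self.samples):
            raise FormatError("duplicate sample ids in sample set")
        for s in self.samples:
            if s.condition not in CONDITIONS:
                raise FormatError(f"unknown condition {s.condition!r}")
            if s.control_id is not None:
                if s.control_id not in by_id:
                    raise FormatError(
                        f"sample {s.sample_id!r} names missing control {s.control_id!r}"
                    )
                ctrl = by_id[s.control_id]
                if (ctrl.profile.flavor, ctrl.profile.epap) != (
                    s.profile.flavor,
                    s.profile.epap,
                ):
                    raise FormatError(
                        f"sample {s.sample_id!r} paired with control of different "
                        "flavor or EPAP status"
                    )

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def pairs(self):
        """Yield (treatment, control) Sample pairs for every depletion sample."""
        for s in self.samples:
            if s.control_id is not None:
                yield s, self[s.control_id]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into {name: uppercase sequence}.

    Lowercase bases are uppercased; characters outside the IUPAC nucleotide
    alphabet are rejected.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"non-IUPAC characters {sorted(bad)} in FASTA record {rec.id!r}"
            )
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Annotation (BED6+2, optional 9th pas_score column)
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand", "biotype", "exon_count"]


def read_annotation(path) -> list[TUAnnotation]:
    """Parse a BED6+2 TU annotation (9th column = optional PAS strength score)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as e:
        raise FormatError(f"ragged annotation table in {path}: {e}") from e
    if df.shape[1] not in (8, 9):
        raise FormatError(
            f"expected 8 or 9 tab-separated columns in {path}, got {df.shape[1]}"
        )
    df.columns = _BED_COLS + (["pas_score"] if df.shape[1] == 9 else [])
    tus = []
    for row in df.itertuples(index=False):
        if row.strand not in STRANDS:
            raise FormatError(f"invalid strand {row.strand!r} in annotation")
        pas = None
        if hasattr(row, "pas_score") and row.pas_score not in (".", "", None):
            pas = float(row.pas_score)
        try:
            start, end, exons = int(row.start), int(row.end), int(row.exon_count)
        except ValueError as e:
            raise FormatError(f"non-integer coordinate/exon_count field: {e}") from e
        tus.append(
            TUAnnotation(
                tu_id=row.name,
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
                biotype=row.biotype,
                exon_count=exons,
                pas_score=pas,
            )
        )
    return tus


def write_annotation(tus: list[TUAnnotation], path) -> None:
    with open(path, "w") as fh:
        for tu in tus:
            fields = [
                tu.chrom, str(tu.start), str(tu.end), tu.tu_id, ".", tu.strand,
                tu.biotype, str(tu.exon_count),
                "." if tu.pas_score is None else f"{tu.pas_score:g}",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_bedgraph_strand(path, chrom_sizes, out_profile, strand):
    with open(path) as fh:
        last_end: dict[str, int] = {}
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = parts
            try:
                start, end = int(start), int(end)
                count = int(value)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative value")
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            if start < last_end.get(chrom, 0):
                raise FormatError(
                    f"{path}:{lineno}: overlapping or unsorted intervals"
                )
            last_end[chrom] = end
            out_profile.array(chrom, strand)[start:end] += count


def read_bedgraph_pair(
    plus_path,
    minus_path,
    chrom_sizes: dict[str, int],
    flavor: str = "three_prime",
    epap: bool = True,
    sample_id: str = "",
) -> EndProfile:
    """Read a stranded bedGraph pair into an EndProfile.

    Intervals are expanded to per-base counts; values must be non-negative
    integers, and intervals within one file must be sorted and non-overlapping.
    """
    profile = EndProfile.empty(chrom_sizes, flavor, epap, sample_id)
    _read_bedgraph_strand(plus_path, chrom_sizes, profile, "+")
    _read_bedgraph_strand(minus_path, chrom_sizes, profile, "-")
    return profile


def write_bedgraph_pair(profile: EndProfile, plus_path, minus_path) -> None:
    """Write an EndProfile as a stranded bedGraph pair (runs of equal counts merged)."""
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        for (chrom, strand) in sorted(profile.counts):
            arr = profile.counts[(chrom, strand)]
            fh = handles[strand]
            nz = np.nonzero(arr)[0]
            if not len(nz):
                continue
            # merge adjacent equal-count positions into intervals
            breaks = np.nonzero(
                (np.diff(nz) != 1) | (np.diff(arr[nz]) != 0)
            )[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(nz) - 1]))
            for i0, i1 in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{nz[i0]}\t{nz[i1] + 1}\t{arr[nz[i0]]}\n"
                )
    finally:
        for fh in handles.values():
            fh.close()


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(path, genome_rel, annotation_rel, sample_entries) -> None:
    """Write the sample manifest.

    ``sample_entries`` is a list of dicts with keys id, condition, flavor,
    epap, control (or None), plus, minus — paths relative to the manifest.
    """
    doc = {
        "genome": genome_rel,
        "annotation": annotation_rel,
        "samples": sample_entries,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_manifest(path) -> SampleSet:
    """Load a manifest and every referenced track into a validated SampleSet."""
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("genome", "annotation", "samples"):
        if key not in doc:
            raise FormatError(f"manifest missing key {key!r}")
    genome_path = os.path.join(base, doc["genome"])
    annotation_path = os.path.join(base, doc["annotation"])
    seqs = read_fasta(genome_path)
    chrom_sizes = {name: len(s) for name, s in seqs.items()}
    samples = []
    for entry in doc["samples"]:
        for key in ("id", "condition", "flavor", "epap", "plus", "minus"):
            if key not in entry:
                raise FormatError(f"manifest sample entry missing {key!r}")
        plus = os.path.join(base, entry["plus"])
        minus = os.path.join(base, entry["minus"])
        for p in (plus, minus):
            if not os.path.exists(p):
                raise FormatError(f"manifest references missing file {p}")
        profile = read_bedgraph_pair(
            plus, minus, chrom_sizes,
            flavor=entry["flavor"], epap=bool(entry["epap"]),
            sample_id=entry["id"],
        )
        samples.append(
            Sample(profile, entry["condition"], entry.get("control") or None)
        )
    return SampleSet(samples, chrom_sizes, genome_path, annotation_path)
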