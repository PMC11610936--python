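"""Stochastic simulator of nascent RNAPII transcription and termination.

The generative model plants sequence elements onto a synthetic genome —
coding-strand T-runs (DNA-directed terminators), polyadenylation sites,
snRNA 3' boxes, and G-rich pause elements — and walks polymerases from each
TSS.  Four termination/cleavage routes compete:

* **DNA-directed**: at a T-run of length L starting d bases from the TSS a
  polymerase terminates with per-T hazard ``p_term_per_T * 2**(-d/halfdist)``,
  i.e. overall ``1 - (1 - p*2**(-d/h))**L``.  The exponential decay in d
  models the gradual maturation of the elongation complex to a
  termination-resistant state over the first kilobases.
* **Torpedo**: after PAS cleavage the polymerase is chased down by the XRN2
  exonuclease and terminates a geometric distance past the PAS, snapping to
  a nearby planted G-rich pause element.  PAS cleavage also resets the
  maturation clock (the post-PAS polymerase reverts to a termination-prone
  "sitting duck" state), so downstream T-runs regain activity.
* **Integrator attenuation**: a fraction of initiated polymerases terminate
  promoter-proximally; snRNA 3' boxes are cleaved by Integrator without
  terminating the polymerase.
* **Runoff**: anything else stops at a hard cap downstream of the TES.

Depletion conditions toggle branches: ``dEXOSC3`` turns exosome decay off
(released nonadenylated 3' ends become fully detectable), ``dXRN2`` disables
the torpedo, ``dINT`` zeroes attenuation and 3'-box cleavage while raising
initiation flux by ``1/(1 - attenuation_p)``, and ``dINT_dEXOSC3`` combines
the last two.  Rendering then turns the event list into end-count profiles
of three flavors (3' ends ±EPAP, capped/cleavage 5' ends, and polymerase
active-site positions), each with its own detection logic.

Identical config + seed gives bit-identical output; each (condition, flavor)
sample draws from its own child RNG stream so adding a sample never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    EndProfile,
    Sample,
    TUAnnotation,
    write_annotation,
    write_bedgraph_pair,
    write_fasta,
    write_manifest,
)

BIOTYPES = ("snRNA_like", "mono_nc", "multiexonic_long", "short_coding", "rdh_like")
MECHANISMS = (
    "dna_directed",
    "torpedo",
    "attenuation",
    "three_prime_box_cleavage",
    "pas_cleavage",
    "runoff",
)

#: biotypes whose TES cleavage yields a stable nonadenylated product
#: (snRNA 3' box / RDH stem-loop) rather than a polyadenylated mRNA
_NONADENYLATED_CLEAVERS = ("snRNA_like", "rdh_like")


@dataclass(frozen=True)
class TUSpec:
    """Blueprint for one planted transcription unit.

    Offsets are sense-strand distances from the TSS (so a terminator at
    offset > body_length lies downstream of the TES); pause-site offsets are
    measured downstream of the TES.
    """

    biotype: str
    body_length: int
    strand: str = "+"
    exon_count: int = 1
    has_three_prime_box: bool = False
    pas_strength: float = 0.0
    planted_terminators: tuple[tuple[int, int], ...] = ()  # (offset, run_length)
    planted_pause_sites: tuple[int, ...] = ()  # offsets downstream of TES
    attenuation_p: float | None = None  # per-TU INT sensitivity (None: config)

    def __post_init__(self):
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.body_length < 1 or self.exon_count < 1:
            raise ValueError("body_length and exon_count must be >= 1")
        if not (0.0 <= self.pas_strength <= 1.0):
            raise ValueError("pas_strength outside [0,1]")
        for off, run in self.planted_terminators:
            if run < 4:
                raise ValueError(
                    f"terminator run_length {run} < 4 (minimal functional tract)"
                )
            if off < 0:
                raise ValueError("negative terminator offset")
        for off in self.planted_pause_sites:
            if off < 0:
                raise ValueError("negative pause-site offset")
        if self.attenuation_p is not None and not (0.0 <= self.attenuation_p < 1.0):
            raise ValueError("attenuation_p outside [0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int | None = None  # None: computed from the TU layout
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tu_specs: tuple[TUSpec, ...] = ()
    n_polymerases_per_tu: int = 250
    p_term_per_T: float = 0.15
    maturation_halfdist: float = 1000.0
    torpedo_mean_dist: float = 200.0
    attenuation_p: float = 0.3
    attenuation_mean_dist: float = 150.0
    exosome_survival: float = 0.2
    depth: int = 5                  # max reads emitted per event
    runoff_extra: int = 5000        # hard cap: TES + runoff_extra
    pause_len: int = 12             # planted G-element length (bases)
    pause_snap_window: int = 50     # torpedo end snaps to a pause site this close
    pause_weight: float = 50.0      # active-site dwell weight per pause base
    trap_factor: float = 10.0       # extra pause dwell when the torpedo is disabled
    xrn2_5p_survival: float = 0.3   # cleavage-product 5' end survival with XRN2 active
    post_pas_reset: bool = True     # PAS cleavage resets the maturation clock
    margin: int = 6500              # flanking bases reserved per TU side
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for name in (
            "p_term_per_T", "attenuation_p", "exosome_survival", "xrn2_5p_survival"
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]")
        if self.n_polymerases_per_tu < 0 or self.depth < 0:
            raise ValueError("n_polymerases_per_tu and depth must be >= 0")
        if self.maturation_halfdist <= 0 or self.torpedo_mean_dist <= 0:
            raise ValueError("distance scales must be positive")


@dataclass
class SyntheticGenome:
    """Synthetic reference: sequence + TU annotation + planted-element registry.

    ``registry`` columns: tu_id, kind ('t_run'|'pause'|'cleavage_site'),
    chrom, start, end (reference, half-open), strand, run_length,
    offset (sense distance of the element start from the TU's TSS).
    """

    seqs: dict[str, str]
    tus: list[TUAnnotation]
    registry: pd.DataFrame
    config: SimulationConfig
    tu_specs: dict[str, TUSpec] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


@dataclass
class GroundTruth:
    """Realized termination/cleavage events for one condition.

    ``events`` columns: tu_id, pol, mechanism, chrom, strand, pos (reference
    position of the RNA 3'-end base), offset (sense distance of that base from
    the TSS), released, adenylated, exosome_sensitive.  ``n_initiated`` maps
    tu_id -> number of initiated polymerases (after any dINT flux increase).
    """

    events: pd.DataFrame
    condition: str
    n_initiated: dict[str, int]


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _scrub_background_runs(seq: np.ndarray, max_run: int = 3) -> np.ndarray:
    """Cap spontaneous A/T homopolymer runs in the random background.

    Functional T-tracts (>= 4 Ts on either strand) must exist only where the
    config plants them, so the ground-truth registry is exhaustive; every
    fourth base of a longer background run is substituted.
    """
    import re

    buf = bytearray(seq.tobytes())
    for pattern, repl in ((rb"T{%d,}" % (max_run + 1), ord(b"C")),
                          (rb"A{%d,}" % (max_run + 1), ord(b"G"))):
        for m in re.finditer(pattern, bytes(buf)):
            for i in range(m.start() + max_run, m.end(), max_run + 1):
                buf[i] = repl
    return np.frombuffer(bytes(buf), dtype="S1").copy()


def build_synthetic_genome(config: SimulationConfig) -> SyntheticGenome:
    """Lay TUs along one chromosome and plant every configured element.

    T-runs are written onto the coding strand (A-runs in the reference for
    minus-strand TUs), pause elements as G-runs, and a cleavage site is
    registered at the TES for every TU with a PAS or 3' box.  Two planted
    elements of the same TU may not overlap.
    """
    if not config.tu_specs:
        raise ValueError("config.tu_specs is empty")
    rng = _child_rng(config.seed, "genome")
    margin = config.margin
    chrom = "chrS"

    # layout: margin | TU1 body | margin | margin | TU2 body | ...
    placements = []
    cursor = margin
    for i, spec in enumerate(config.tu_specs):
        start = cursor
        placements.append((f"tu{i:03d}", spec, start))
        cursor = start + spec.body_length + 2 * margin
    needed = cursor
    length = config.genome_length if config.genome_length is not None else needed
    if length < needed:
        raise ValueError(
            f"genome_length {length} shorter than TU footprints + flanks ({needed})"
        )

    seq = rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"), size=length, p=config.base_composition
    )
    seq = _scrub_background_runs(seq)

    tus: list[TUAnnotation] = []
    tu_specs: dict[str, TUSpec] = {}
    reg_rows = []

    def plant(tu, element_offset, elem_len, base, kind, run_length, claimed):
        """Write elem_len copies of `base` on the coding strand at a sense offset."""
        if tu.strand == "+":
            s = tu.start + element_offset
            e = s + elem_len
            fill = base
        else:
            e = tu.end - element_offset
            s = e - elem_len
            fill = {"T": "A", "G": "C"}[base]
        if s < 0 or e > length:
            raise ValueError(f"planted element outside genome bounds for {tu.tu_id}")
        for (cs, ce) in claimed:
            if s - 1 < ce and cs < e + 1:
                raise ValueError(
                    f"overlapping planted elements for {tu.tu_id} at [{s},{e})"
                )
        claimed.append((s - 1, e + 1))
        seq[s:e] = fill.encode()
        # guard bases keep the planted run maximal (registry == sequence truth)
        guard = b"C" if kind == "t_run" else b"A"
        if s - 1 >= 0:
            seq[s - 1] = guard
        if e < length:
            seq[e] = guard
        reg_rows.append(
            dict(
                tu_id=tu.tu_id, kind=kind, chrom=chrom, start=s, end=e,
                strand=tu.strand, run_length=run_length, offset=element_offset,
            )
        )

    for tu_id, spec, start in placements:
        tu = TUAnnotation(
            tu_id=tu_id,
            chrom=chrom,
            start=start,
            end=start + spec.body_length,
            strand=spec.strand,
            biotype=spec.biotype,
            exon_count=spec.exon_count,
            pas_score=spec.pas_strength if spec.pas_strength > 0 else None,
        )
        claimed: list[tuple[int, int]] = []
        for off, run in spec.planted_terminators:
            plant(tu, off, run, "T", "t_run", run, claimed)
        for off in spec.planted_pause_sites:
            plant(
                tu, spec.body_length + off, config.pause_len, "G", "pause",
                config.pause_len, claimed,
            )
        if spec.pas_strength > 0 or spec.has_three_prime_box:
            # registered only (no sequence written): the product 3'-end base
            cs = tu.transcript_to_ref(spec.body_length - 1)
            reg_rows.append(
                dict(
                    tu_id=tu_id, kind="cleavage_site", chrom=chrom,
                    start=cs, end=cs + 1, strand=tu.strand,
                    run_length=0, offset=spec.body_length - 1,
                )
            )
        tus.append(tu)
        tu_specs[tu_id] = spec

    registry = pd.DataFrame(
        reg_rows,
        columns=["tu_id", "kind", "chrom", "start", "end", "strand",
                 "run_length", "offset"],
    )
    return SyntheticGenome(
        seqs={chrom: seq.tobytes().decode()},
        tus=tus,
        registry=registry,
        config=config,
        tu_specs=tu_specs,
    )


# ---------------------------------------------------------------------------
# Polymerase walk
# ---------------------------------------------------------------------------

def _condition_flags(condition: str) -> tuple[bool, bool, bool]:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    int_off = condition in ("dINT", "dINT_dEXOSC3")
    exo_off = condition in ("dEXOSC3", "dINT_dEXOSC3")
    xrn2_off = condition == "dXRN2"
    return int_off, exo_off, xrn2_off


def simulate_polymerases(
    genome: SyntheticGenome, condition: str, seed: int | None = None
) -> GroundTruth:
    """Walk polymerases through every TU under one depletion condition.

    Returns the full event list with mechanism tags; one polymerase can yield
    a cleavage event plus a downstream termination event.
    """
    cfg = genome.config
    int_off, _exo_off, xrn2_off = _condition_flags(condition)
    if seed is None:
        seed = cfg.seed
    rng = _child_rng(seed, f"walk:{condition}")

    rows = []
    n_initiated = {}

    for tu in genome.tus:
        spec = genome.tu_specs[tu.tu_id]
        tu_atten = (
            cfg.attenuation_p if spec.attenuation_p is None else spec.attenuation_p
        )
        atten_p = 0.0 if int_off else tu_atten
        n = cfg.n_polymerases_per_tu
        if int_off and tu_atten < 1.0:
            n = int(round(n / (1.0 - tu_atten)))  # attenuated flux released
        n_initiated[tu.tu_id] = n

        body = spec.body_length
        runoff_off = body + cfg.runoff_extra
        terms = sorted(spec.planted_terminators)
        pause_offs = sorted(body + p for p in spec.planted_pause_sites)
        nonadenylated_cleaver = spec.biotype in _NONADENYLATED_CLEAVERS
        cleavage_on = spec.pas_strength > 0 and not (
            int_off and spec.biotype == "snRNA_like"
        )

        def emit(pol, mech, offset, released, adenylated, exo_sensitive):
            rows.append(
                (
                    tu.tu_id, pol, mech, tu.chrom, tu.strand,
                    tu.transcript_to_ref(offset), offset,
                    released, adenylated, exo_sensitive,
                )
            )

        for pol in range(n):
            if rng.random() < atten_p:
                # geometric release distance truncated to the body (inverse CDF)
                q = 1.0 - 1.0 / cfg.attenuation_mean_dist
                u = rng.random()
                off = int(np.log1p(-u * (1.0 - q ** body)) / np.log(q))
                emit(pol, "attenuation", min(off, body - 1), True, False, True)
                continue

            cleaved_at = None  # sense offset of the cleavage site
            torpedo_at = None  # sense offset of the torpedo termination
            terminated = False

            # ordered checkpoints: terminators interleaved with the TES
            checkpoints = [(off, run) for off, run in terms]
            checkpoints.append((body, None))  # TES / cleavage checkpoint
            checkpoints.sort(key=lambda t: t[0])

            for off, run in checkpoints:
                if torpedo_at is not None and off > torpedo_at:
                    break
                if run is None:
                    # TES: cleavage (3' box / PAS) without terminating RNAPII
                    if cleavage_on and rng.random() < spec.pas_strength:
                        cleaved_at = body
                        if nonadenylated_cleaver:
                            emit(pol, "three_prime_box_cleavage", body - 1,
                                 True, False, False)
                        else:
                            emit(pol, "pas_cleavage", body - 1, True, True, False)
                            if not xrn2_off:
                                dist = int(rng.geometric(1.0 / cfg.torpedo_mean_dist))
                                cand = body + dist
                                near = [
                                    p for p in pause_offs
                                    if abs(p + cfg.pause_len // 2 - cand)
                                    <= cfg.pause_snap_window
                                ]
                                if near:
                                    cand = near[0] + cfg.pause_len // 2
                                torpedo_at = cand
                    continue
                # T-run checkpoint
                d = off
                if cfg.post_pas_reset and cleaved_at is not None:
                    d = off - cleaved_at
                s = cfg.p_term_per_T * 2.0 ** (-d / cfg.maturation_halfdist)
                for j in range(run):
                    if rng.random() < s:
                        emit(pol, "dna_directed", off + j, True, False, True)
                        terminated = True
                        break
                if terminated:
                    break

            if terminated:
                continue
            if torpedo_at is not None:
                emit(pol, "torpedo", torpedo_at, False, False, False)
            else:
                emit(pol, "runoff", runoff_off, True, False, True)

    events = pd.DataFrame(
        rows,
        columns=[
            "tu_id", "pol", "mechanism", "chrom", "strand", "pos", "offset",
            "released", "adenylated", "exosome_sensitive",
        ],
    )
    return GroundTruth(events, condition, n_initiated)


# ---------------------------------------------------------------------------
# Rendering end profiles
# ---------------------------------------------------------------------------

def render_end_profile(
    genome: SyntheticGenome,
    truth: GroundTruth,
    flavor: str = "three_prime",
    epap: bool = True,
    depth: int | None = None,
    seed: int | None = None,
    sample_id: str | None = None,
) -> EndProfile:
    """Turn a ground-truth event list into a stranded end-count profile.

    * ``three_prime``: released nonadenylated ends need ``epap=True``;
      polyadenylated mRNA ends appear in both ±EPAP; exosome-sensitive ends
      are detected with probability ``exosome_survival`` unless the condition
      depletes EXOSC3.  Each event emits Binomial(depth, p_detect) reads.
    * ``five_prime``: capped TSS 5' ends for every initiated polymerase plus
      cleavage-product 5' ends (XRN2-degraded unless the torpedo is off);
      EPAP treatment is undefined for this flavor and rejected.
    * ``active_site``: snapshot positions sampled along each polymerase's
      traversed path in proportion to dwell (``depth`` = expected reads per
      kilobase of weighted dwell), with extra dwell weight on planted G-rich
      pause elements (amplified when the torpedo is disabled).
    """
    cfg = genome.config
    _int_off, exo_off, xrn2_off = _condition_flags(truth.condition)
    if flavor == "five_prime" and epap:
        raise ValueError("five_prime flavor with EPAP treatment is undefined")
    if depth is None:
        depth = cfg.depth
    if seed is None:
        seed = cfg.seed
    if sample_id is None:
        sample_id = f"{truth.condition}.{flavor}.{'EPAP' if epap else 'noEPAP'}"
    rng = _child_rng(seed, f"render:{truth.condition}:{flavor}:{int(epap)}")
    profile = EndProfile.empty(genome.chrom_sizes, flavor, epap, sample_id)
    ev = truth.events
    tus = {tu.tu_id: tu for tu in genome.tus}

    if flavor == "three_prime":
        for row in ev.itertuples(index=False):
            if not row.released:
                continue
            if not row.adenylated and not epap:
                continue
            p = 1.0
            if row.exosome_sensitive and not exo_off:
                p = cfg.exosome_survival
            count = int(rng.binomial(depth, p)) if p < 1.0 else depth
            if count:
                profile.array(row.chrom, row.strand)[row.pos] += count

    elif flavor == "five_prime":
        for tu_id, n in truth.n_initiated.items():
            tu = tus[tu_id]
            tss_pos = tu.transcript_to_ref(0)
            profile.array(tu.chrom, tu.strand)[tss_pos] += n * depth
        cleavages = ev[ev.mechanism.isin(["three_prime_box_cleavage", "pas_cleavage"])]
        for row in cleavages.itertuples(index=False):
            tu = tus[row.tu_id]
            # product 5' end: first base downstream of the cleavage point
            pos5 = tu.transcript_to_ref(row.offset + 1)
            p = 1.0 if xrn2_off else cfg.xrn2_5p_survival
            count = int(rng.binomial(depth, p)) if p < 1.0 else depth
            if count:
                profile.array(tu.chrom, tu.strand)[pos5] += count

    elif flavor == "active_site":
        terminal = ev[ev.mechanism.isin(["dna_directed", "torpedo", "attenuation",
                                         "runoff"])]
        # per-TU cumulative dwell weights over sense offsets
        cumw: dict[str, np.ndarray] = {}
        for tu_id, spec in genome.tu_specs.items():
            max_off = spec.body_length + cfg.runoff_extra + 1
            w = np.ones(max_off)
            for p_off in spec.planted_pause_sites:
                s = spec.body_length + p_off
                weight = cfg.pause_weight
                if xrn2_off:
                    weight *= cfg.trap_factor  # sitting-duck accumulation
                w[s:s + cfg.pause_len] = weight
            cumw[tu_id] = np.cumsum(w)
        for row in terminal.itertuples(index=False):
            tu = tus[row.tu_id]
            cw = cumw[row.tu_id]
            end = min(row.offset, len(cw) - 1)
            total = cw[end]
            # occupancy ~ flux x dwell: reads per polymerase scale with the
            # weighted path length (depth = expected reads per kb of dwell)
            n_reads = int(rng.poisson(depth * total / 1000.0))
            if not n_reads:
                continue
            u = rng.random(n_reads) * total
            offs = np.searchsorted(cw, u, side="right")
            arr = profile.array(tu.chrom, tu.strand)
            if tu.strand == "+":
                np.add.at(arr, tu.start + offs, 1)
            else:
                np.add.at(arr, tu.end - 1 - offs, 1)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")

    return profile


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_tu_specs() -> tuple[TUSpec, ...]:
    """24 TUs covering the five biotype classes the analysis stratifies.

    Multiexonic TUs carry one T6+ terminator per kilobase bin out to 4 kb from
    the TSS (the distance-dependence design); snRNA-, RDH-, and short-coding
    TUs carry terminators downstream of the TES; G-rich pause elements sit
    downstream of PAS-containing TUs.
    """
    specs: list[TUSpec] = []
    strands = "+-"
    run_cycle = (6, 7, 8)
    atten_cycle = (0.15, 0.3, 0.45, 0.6)  # variable Integrator sensitivity
    for i in range(4):
        specs.append(
            TUSpec(
                biotype="snRNA_like", body_length=200, strand=strands[i % 2],
                exon_count=1, has_three_prime_box=True, pas_strength=0.9,
                planted_terminators=((200 + 300 + 60 * i, 7),
                                     (200 + 800 + 60 * i, 6)),
                attenuation_p=atten_cycle[i % 4],
            )
        )
    for i in range(4):
        specs.append(
            TUSpec(
                biotype="mono_nc", body_length=800, strand=strands[i % 2],
                exon_count=1,
                planted_terminators=((250 + 40 * i, 6), (600 + 40 * i, 8)),
                attenuation_p=atten_cycle[(i + 1) % 4],
            )
        )
    for i in range(8):
        pas = 0.9 if i < 4 else 0.3
        specs.append(
            TUSpec(
                biotype="multiexonic_long", body_length=6000, strand=strands[i % 2],
                exon_count=8, pas_strength=pas,
                planted_terminators=tuple(
                    (400 + 1000 * b + 37 * i, run_cycle[(i + b) % 3])
                    for b in range(4)
                ),
                planted_pause_sites=(250, 900),
                attenuation_p=atten_cycle[i % 4],
            )
        )
    for i in range(4):
        specs.append(
            TUSpec(
                biotype="short_coding", body_length=2000, strand=strands[i % 2],
                exon_count=3, pas_strength=0.85,
                planted_terminators=((2000 + 250 + 45 * i, 7),
                                     (2000 + 700 + 45 * i, 6)),
                planted_pause_sites=(1200,),
                attenuation_p=atten_cycle[(i + 2) % 4],
            )
        )
    for i in range(4):
        specs.append(
            TUSpec(
                biotype="rdh_like", body_length=500, strand=strands[i % 2],
                exon_count=1, has_three_prime_box=True, pas_strength=0.8,
                planted_terminators=((500 + 200 + 55 * i, 6),
                                     (500 + 550 + 55 * i, 8)),
                attenuation_p=atten_cycle[(i + 3) % 4],
            )
        )
    return tuple(specs)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions of the simulator."""
    cfg = SimulationConfig(tu_specs=default_tu_specs(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def flank_selection_fixture_config(seed: int = 0) -> SimulationConfig:
    """Fifteen short protein-coding TUs for the TES-flank selection filter.

    Five TUs carry T-runs only downstream of the TES (flank-only
    stabilization under exosome loss), five carry body and flank runs, and
    five carry none and cleave every transcript (unchanged).  Attenuation is
    off so gene-body signal is exosome-insensitive unless a body run is
    planted; the torpedo chase is long enough that cleaved polymerases reach
    the flank runs.
    """
    specs: list[TUSpec] = []
    strands = "+-"
    body = 2000
    for i in range(5):  # flank-only
        specs.append(
            TUSpec(
                biotype="short_coding", body_length=body, strand=strands[i % 2],
                exon_count=3, pas_strength=0.9,
                planted_terminators=((body + 250 + 40 * i, 7),
                                     (body + 700 + 40 * i, 6)),
                attenuation_p=0.0,
            )
        )
    for i in range(5):  # body + flank
        specs.append(
            TUSpec(
                biotype="short_coding", body_length=body, strand=strands[i % 2],
                exon_count=3, pas_strength=0.9,
                planted_terminators=((300 + 40 * i, 7), (650 + 40 * i, 6),
                                     (body + 250 + 40 * i, 7),
                                     (body + 700 + 40 * i, 6)),
                attenuation_p=0.0,
            )
        )
    for i in range(5):  # unchanged
        specs.append(
            TUSpec(
                biotype="short_coding", body_length=body, strand=strands[i % 2],
                exon_count=3, pas_strength=1.0, attenuation_p=0.0,
            )
        )
    return SimulationConfig(
        tu_specs=tuple(specs), attenuation_p=0.0, torpedo_mean_dist=600.0,
        exosome_survival=0.1,  # strong planted contrast (~10x detection)
        seed=seed,
    )


#: (condition, flavor, epap) triples rendered by the standard fixture bundle
DEFAULT_SAMPLE_PLAN: tuple[tuple[str, str, bool], ...] = (
    ("CTRL", "three_prime", True),
    ("dEXOSC3", "three_prime", True),
    ("dINT", "three_prime", True),
    ("dINT_dEXOSC3", "three_prime", True),
    ("dXRN2", "three_prime", True),
    ("CTRL", "three_prime", False),
    ("dEXOSC3", "three_prime", False),
    ("CTRL", "five_prime", False),
    ("dINT", "five_prime", False),
    ("CTRL", "active_site", False),
    ("dXRN2", "active_site", False),
    ("dINT", "active_site", False),
)


def sample_id_for(condition: str, flavor: str, epap: bool) -> str:
    short = {"three_prime": "3p", "five_prime": "5p", "active_site": "as"}[flavor]
    tag = "EPAP" if epap else "noEPAP"
    return f"{condition}.{short}.{tag}"


def simulate_sample_set(
    config: SimulationConfig,
    plan: tuple[tuple[str, str, bool], ...] = DEFAULT_SAMPLE_PLAN,
) -> tuple[SyntheticGenome, dict[str, GroundTruth], list[Sample]]:
    """Build the genome, walk every needed condition once, render the plan."""
    genome = build_synthetic_genome(config)
    truths = {
        cond: simulate_polymerases(genome, cond)
        for cond in sorted({c for c, _, _ in plan})
    }
    samples = []
    for cond, flavor, epap in plan:
        profile = render_end_profile(
            genome, truths[cond], flavor=flavor, epap=epap,
            sample_id=sample_id_for(cond, flavor, epap),
        )
        control = (
            None if cond == "CTRL" else sample_id_for("CTRL", flavor, epap)
        )
        samples.append(Sample(profile, cond, control))
    return genome, truths, samples


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    genome: SyntheticGenome,
    samples: list[Sample],
    out_dir,
    truths: dict[str, GroundTruth] | None = None,
    overwrite: bool = False,
) -> str:
    """Write FASTA + annotation + bedGraph pairs + manifest (+ ground truth).

    Re-reading the bundle through :func:`tracterm.io.load_manifest` reproduces
    every profile position-by-position.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    if not overwrite and any(
        not name.startswith(".") for name in os.listdir(out_dir)
    ):
        raise FileExistsError(f"output directory {out_dir} is not empty")

    write_fasta(genome.seqs, os.path.join(out_dir, "genome.fa"))
    write_annotation(genome.tus, os.path.join(out_dir, "tus.bed"))
    genome.registry.to_csv(
        os.path.join(out_dir, "planted_elements.tsv"), sep="\t", index=False
    )
    entries = []
    for s in samples:
        plus = f"{s.sample_id}.plus.bedgraph"
        minus = f"{s.sample_id}.minus.bedgraph"
        write_bedgraph_pair(
            s.profile, os.path.join(out_dir, plus), os.path.join(out_dir, minus)
        )
        entries.append(
            dict(
                id=s.sample_id, condition=s.condition, flavor=s.profile.flavor,
                epap=bool(s.profile.epap), control=s.control_id,
                plus=plus, minus=minus,
            )
        )
    write_manifest(
        os.path.join(out_dir, "manifest.yaml"), "genome.fa", "tus.bed", entries
    )
    if truths:
        pd.concat(
            [t.events.assign(condition=c) for c, t in sorted(truths.items())],
            ignore_index=True,
        ).to_csv(os.path.join(out_dir, "ground_truth.tsv"), sep="\t", index=False)
    return str(out_dir)
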