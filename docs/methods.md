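# Methods

## The generative model

`tracterm.simulate` draws a single synthetic chromosome and walks
polymerases through a configurable roster of transcription units (TUs).
The model is deliberately mechanistic rather than phenomenological: each
read in every output track traces to exactly one termination or cleavage
event with a mechanism tag, so analysis results can be checked against
planted truth.

**Genome.** Background sequence is i.i.d. over {A, C, G, T} with
configurable composition (uniform by default). Spontaneous A/T homopolymer
runs of four or more bases are scrubbed from the background (every fourth
base substituted), and planted runs receive non-T guard bases on both
sides. Functional T-tracts therefore exist only where the configuration
plants them, which makes the planted-element registry exhaustive — the
analysis-versus-registry tests depend on that exactness. TUs are laid out
with 6.5-kb flanks so that runoff transcription (TES + 5 kb cap) never
crosses a neighbor.

**Termination routes.** For a polymerase at a T-run of length L whose
start lies d bases from the TSS (sense direction), the per-T termination
hazard is

    s(d) = p_term_per_T * 2^(-d / maturation_halfdist)

and the run terminates the polymerase with probability `1 − (1 − s)^L`,
at the first T for which the hazard fires (so 3′ ends distribute over the
run body). The exponential decay in d models the maturation of the
elongation complex to a termination-resistant state over the first
kilobases; `maturation_halfdist` (default 1,000 bases) is the distance at
which susceptibility halves. PAS cleavage at the TES (probability
`pas_strength` per TU) produces a polyadenylated mRNA 3′ end and, when
XRN2 is present, a torpedo chase terminating the polymerase a
Geometric(`torpedo_mean_dist` = 200 bases) distance past the PAS, snapped
to a planted G-rich pause element within 50 bases. Cleavage also resets
the maturation clock: the post-PAS polymerase reverts to a
termination-prone state, so T-runs downstream of the TES regain full
activity (this is what lets short protein-coding TUs terminate
DNA-directedly in their 3′ flanks). Integrator attenuates a per-TU
fraction of initiations (`attenuation_p`, default 0.3, varied 0.15–0.6
across the default roster to mimic the wide range of Integrator
sensitivity between genes) with a truncated-geometric release position
(mean 150 bases), and cleaves snRNA 3′ boxes without terminating the
polymerase. Polymerases that neither terminate nor get chased stop at
TES + 5 kb ("runoff").

**Depletion conditions.** `dEXOSC3` raises the detection probability of
exosome-sensitive 3′ ends from `exosome_survival` (default 0.2) to 1;
`dXRN2` disables the torpedo branch; `dINT` zeroes attenuation and snRNA
3′-box cleavage and multiplies initiation flux by `1/(1 − attenuation_p)`
per TU (the attenuated polymerases are released into productive
elongation — Integrator loss increases snRNA transcription without
changing where it terminates); `dINT_dEXOSC3` combines the last two. RDH
(replication-dependent histone)-like TUs keep their cleavage under `dINT`
because their 3′-end machinery is U7/CPSF73-based, not Integrator-based.

**Rendering.** Three track flavors are rendered from the event list, each
from its own child RNG stream (one stream per condition × flavor, so
adding a sample never perturbs another):

* *three_prime*: released nonadenylated ends require `epap=True`;
  polyadenylated mRNA ends appear in ±EPAP alike; exosome-sensitive ends
  are detected with probability `exosome_survival` unless EXOSC3 is
  depleted. Each event emits Binomial(depth = 5, p) reads at its exact
  3′-end base.
* *five_prime*: capped TSS 5′ ends for every initiated polymerase plus
  cleavage-product 5′ ends, the latter degraded by XRN2 (survival 0.3)
  unless XRN2 is depleted. EPAP treatment is undefined for this flavor and
  rejected.
* *active_site*: polymerase-position (mNET-style) reads sampled along each
  polymerase's traversed path in proportion to dwell time, Poisson with
  `depth` expected reads per kilobase of weighted path. Planted pause
  elements carry 50× dwell weight, multiplied by a further 10× when the
  torpedo is disabled — the "sitting duck" polymerases that cleaved their
  PAS but cannot be terminated accumulate on pause sites. Occupancy
  proportional to flux × residence time is essential here: a fixed read
  count per polymerase distorts body/downstream comparisons.

**Default roster.** 24 TUs on alternating strands: 4 snRNA-like (200-b
bodies, 3′ boxes, T-runs 300/800 bases past the TES), 4 monoexonic
noncoding (800 b, promoter-proximal runs), 8 long multiexonic (6-kb
bodies, strong or weak PASs, one T6–T8 run per kilobase bin out to 4 kb
from the TSS, two G-rich pause elements past the TES), 4 short coding
(2-kb bodies, PAS plus flank T-runs), and 4 RDH-like (500 b, nonadenylated
cleavage plus flank runs). 250 polymerases per TU per condition (6,000
total) keep every stage within seconds on one CPU while leaving dozens of
events per planted element.

## The analysis

Counts are integers; normalization is counts-per-million (CPM) of the
whole library; region summaries add the per-kilobase factor (RPKM) where
stated. Fold changes use `log2((CPM_t + pc)/(CPM_c + pc))` with a
pseudocount of 1 CPM recorded in every output; the track is defined
wherever either sample has signal. Stabilized-end calling applies the hard
thresholds of the field (log2 ≥ 1, treatment count ≥ 1 by default) — no
per-position hypothesis tests are computed, because the procedure being
implemented uses fold-change thresholds, not p-values; inventing a test
would misrepresent it.

Terminal k-mers are reported as the coding-strand DNA equivalent of the
RNA 3′ terminus: reference bases `[pos−k+1, pos]` on the plus strand, the
reverse complement of `[pos, pos+k−1]` on the minus strand. Windows
containing N are skipped and counted, never imputed. 3′-seq tables count
each called position once by default (the read-weighted mode exists and is
recorded); active-site (mNET-analog) tables are read-count weighted, since
pause-trapped polymerases carry the reads that motif heat maps of that
assay display. The T-fraction statistic compares the terminal-base T
fraction of calls against the strand-aware T frequency of the searched
regions, with a two-sample binomial z-score.

T-runs are located as maximal coding-strand runs (regex scan of the
sense-oriented window, TSS to TES plus a configurable downstream window).
The TSS-distance binning (0–1/1–2/2–3/3–4 kb, half-open in bases) is
restricted to multiexonic TUs whose bodies span the binned range (≥ 4 kb);
shorter TUs would place their TES-flank runs — which terminate via the
post-PAS-reset route — into distal bins and conflate two different
regimes. Fold-change meta-curves over runs length-normalize the run body
to 6 meta-positions with 10 fixed flanking bases, treating positions
uncovered in both samples as zero change (0 vs. 0 coverage is no
stabilization).

Region tables sum body (`[TSS, TES)`) and TES-downstream windows (3 kb
default) per TU, strand-aware; the flank-selection filter returns TUs with
downstream log2 change ≥ 1.5 and body log2 change ≤ 0.5. End-position
concordance is the percentage of one call set's positions with a match in
the other within ±tolerance (default 0, exact base), computed in both
directions with the symmetric mean reported; the pipeline also reports it
restricted to snRNA TES-downstream windows, where termination positions
are expected to be condition-invariant. The "last detected position" of a
coverage track (used for end-of-termination-zone summaries) is the most 3′
position within TES + 10 kb whose 21-base running-mean CPM exceeds a 0.1
floor; width and floor are configurable.

## Numerical and design choices

* Coordinates are 0-based, half-open, reference-strand throughout,
  including bedGraph output; minus-strand TU offsets are sense distances
  mapped through `ref = end − 1 − offset`.
* k-mer ties are broken lexicographically; heat-map row sorting is stable
  (equal sums keep input order); metagene bin edges partition bases
  equally with the remainder spread left-to-right.
* Readers reject malformed input (non-IUPAC bases, `.` strands,
  overlapping bedGraph intervals, negative counts, dangling control
  references, mixed-flavor pairings) rather than repairing it.
* Determinism: every random draw comes from
  `SeedSequence([seed, crc32(label)])` child streams; identical
  config + seed gives byte-identical bundles and reports.
* The TES-flank selection fixture (15 short-coding TUs: 5 flank-only, 5
  body+flank, 5 unchanged) uses attenuation 0, a 600-base torpedo chase
  (so cleaved polymerases reach the flank runs), and exosome survival 0.1,
  i.e. a ~10-fold planted detection contrast — comfortably above the
  1.5-log2 selection threshold so that the filter, not sampling noise, is
  what the test exercises.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: point 3′-end
counts concentrated at planted termination positions; EPAP-dependent
detectability of nonadenylated ends; condition-dependent stabilization
(exosome decay off under EXOSC3 depletion, torpedo off under XRN2
depletion, attenuation and 3′-box cleavage off under Integrator
depletion); G-rich pausing downstream of cleaved PASs; and variable
Integrator sensitivity across TUs. It does not model read-level artifacts
(sequencing error, mappability, internal priming), replicate structure,
chromatin, or spike-in normalization. Consequences worth knowing:

* Library composition shifts under depletion are strong at desk scale
  (the simulated libraries are rich in exosome-sensitive ends), so CPM
  fold changes at proximal, high-count positions are damped while sparse
  distal positions sit on the pseudocount floor. Per-base fold-change
  *peak heights* over T-runs are therefore not monotone in TSS distance
  even though event counts are; distance dependence is read off the
  stabilized-read counts per bin, which are robust to both effects.
* Passing tests show the pipeline recovers planted signals under the
  model's assumptions; they do not certify performance on real libraries
  with replicate noise, mappability gaps, or spike-in-normalized depth.
* Simulated 3′ ends are single-base exact; real 3′-seq has ±1–2 base
  uncertainty, which is why the concordance statistic exposes a tolerance
  parameter (both exact and binned modes are provided).
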