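# tracterm

Detection of **DNA-directed (T-tract) transcription termination of RNA
polymerase II** from stranded, single-nucleotide RNA 3′-end profiles, with a
stochastic simulator of nascent transcription that generates every input the
analysis needs — genome, annotation, and condition-dependent end-count
tracks — together with ground truth for each planted signal.

## The scientific problem

Mammalian RNAPII termination is classically coupled to polyadenylation-site
(PAS) cleavage followed by the XRN2 "torpedo" exonuclease. A second,
DNA-encoded mechanism terminates polymerases directly over runs of
thymidines on the coding strand (the nascent RNA carries the complementary
U-run, a weak dA:rU hybrid). These termination products are nonadenylated
and rapidly destroyed by the nuclear exosome, so they become visible only
when 3′-end sequencing is combined with (i) in vitro polyadenylation by
*E. coli* poly(A) polymerase (EPAP), which makes nonadenylated 3′ ends
sequenceable, and (ii) depletion of the exosome subunit EXOSC3, which
stabilizes the released RNAs. `tracterm` implements the computational side
of that logic for anyone analyzing 3′-seq / TT-seq / mNET-seq-style count
tracks across factor-depletion conditions:

* per-base log2 fold-change tracks `log2((CPM_t + pc) / (CPM_c + pc))` and
  **stabilized-end calling** (log2 change ≥ 1 by default, thresholds recorded
  in every output);
* **terminal k-mer tables**: the k bases of the coding strand ending at each
  called 3′-end position (k = 6 by default), ranked by count;
* a **background-corrected T-fraction statistic**: the fraction of called
  ends terminating at a coding-strand T versus the T frequency of the same
  genomic regions, with a normal-approximation z-score;
* **T-run location and TSS-distance binning** (0–1, 1–2, 2–3, 3–4 kb) with
  fold-change meta-curves over the runs, testing whether susceptibility to
  T-tract termination decays as the elongation complex matures;
* **region aggregation and TU selection**: gene-body vs. TES-downstream
  signal per transcription unit, and the filter selecting TUs whose 3′ flank
  is stabilized (log2 ≥ 1.5) without any gene-body increase;
* **end-position concordance** between conditions and scaled metagene /
  downstream heat-map matrices.

The simulator encodes the mechanistic model as a generative process:
polymerases walk from each TSS; a T-run of length L at distance d from the
TSS terminates them with probability `1 − (1 − p·2^(−d/h))^L`; PAS cleavage
launches a geometric torpedo chase that snaps to G-rich pause elements; the
Integrator complex attenuates a per-TU fraction of initiations and cleaves
snRNA 3′ boxes; everything else runs off at a hard cap. Depletion conditions
(`dEXOSC3`, `dXRN2`, `dINT`, `dINT_dEXOSC3`) toggle the corresponding
branches, and rendering applies the EPAP/exosome detection rules per flavor
(3′-end, 5′-end, or active-site/mNET-style occupancy).

## Worked example

```python
import tracterm as tt

tt.run_simulate("bundle", config=tt.default_config(seed=1))
summary = tt.run_analyze("bundle/manifest.yaml", "report")

pair = summary["pairs"]["dEXOSC3.3p.EPAP__vs__CTRL.3p.EPAP"]
print(pair["n_calls"])             # 1709
print(pair["top_hexamers"])        # ['TTTTTT', 'CTTTTT', 'GTTTTT', 'ACTTTT', 'AGGTTT']
print(pair["t_fraction"])          # {'end': 0.340, 'genomic': 0.250, 'z': 7.80}
print(pair["stabilized_per_bin"])  # {'0-1kb': 1575, '1-2kb': 555, '2-3kb': 230, '3-4kb': 65}
```

Reading the numbers: 1,709 positions gained ≥2-fold 3′-end signal when the
exosome was depleted. Ranking the coding-strand hexamers ending at those
positions puts `TTTTTT` first, with further T-rich variants behind it — the
termination products end on T-tracts. That is not a base-composition
artifact: 34.0% of called ends terminate at a T against a 25.0% genomic T
frequency over the same regions (z ≈ 7.8). Binning stabilized end reads at
T6+ runs by distance from the TSS gives 1575 / 555 / 230 / 65 — termination
at T-tracts fades as the polymerase moves away from the promoter, the
maturation effect the simulator plants with a 1-kb half-distance.

The same pipeline runs from the shell:

```bash
tracterm simulate --out bundle --seed 1
tracterm analyze --manifest bundle/manifest.yaml --out report
tracterm compare report report --tolerance 0
```

`report/` contains one TSV per stage (calls, hexamer tables, T-fraction,
distance bins, region tables, selected TUs, metaprofiles, concordance), a
`run_summary.json` recording every threshold, pseudocount, seed and version,
and PNG figures regenerated purely from the TSVs.

## File formats

Plain text throughout: FASTA for genomes; BED6+2 for TU annotation (columns
7–8 are biotype and exon count, optional column 9 a PAS-strength score in
[0, 1]); stranded bedGraph pairs (`<sample>.plus.bedgraph` /
`.minus.bedgraph`, UCSC dialect, 0-based half-open) for per-base end counts;
a YAML manifest mapping each sample to its condition, flavor, EPAP status
and paired control. All coordinates in the package are 0-based, half-open,
on the reference strand.

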