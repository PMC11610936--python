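"""End-to-end orchestration: simulate a fixture bundle, analyze a manifest
into a report directory of TSV tables (plus figures regenerated from the
TSVs), and compare reports.

Every stage writes a machine-readable TSV; ``run_summary.json`` records all
thresholds, the pseudocount, the seed, and the package version so that a
report is reproducible from its inputs alone.  Analysis is deterministic:
reruns on identical inputs produce byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    call_stabilized_ends,
    end_position_concordance,
    filter_calls_to_regions,
    log2_ratio_track,
    region_signal,
    select_flank_stabilized_tus,
    tu_regions,
)
from .io import FormatError, load_manifest, read_annotation, read_fasta
from .metaprofiles import downstream_heatmap, scaled_metaprofile, sort_rows_by_sum
from .motifs import (
    count_terminal_kmers,
    fc_over_motifs,
    find_t_runs,
    motif_distance_bins,
    stabilized_counts_per_bin,
    t_fraction_statistic,
    write_t_runs_bed,
)
from .simulate import (
    SimulationConfig,
    default_config,
    simulate_sample_set,
    write_fixture_bundle,
)

logger = logging.getLogger("tracterm")

_FLOAT_FMT = "%.6g"


@dataclass
class AnalysisParams:
    """Tunable thresholds and windows of the analysis stage."""

    min_log2: float = 1.0
    min_count: int = 1
    pseudocount: float = 1.0
    downstream_window: int = 3000
    antisense_window: int = 3000
    snrna_search_window: int = 4000
    tu_flank_min_log2: float = 1.5
    tu_body_max_log2: float = 0.5
    k: int = 6
    min_run: int = 6
    bins_kb: tuple = ((0, 1), (1, 2), (2, 3), (3, 4))
    kmer_weight: str = "unique_positions"
    active_site_kmer_weight: str = "count_weighted"  # mNET tallies read ends
    concordance_tolerance: int = 0


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(
    out_dir,
    config: SimulationConfig | None = None,
    seed: int = 0,
    overwrite: bool = False,
) -> str:
    """Generate the standard fixture bundle under ``out_dir``."""
    if config is None:
        config = default_config(seed=seed)
    genome, truths, samples = simulate_sample_set(config)
    path = write_fixture_bundle(genome, samples, out_dir, truths, overwrite)
    logger.info("simulate: wrote bundle to %s (%d samples)", path, len(samples))
    return path


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def run_analyze(
    manifest_path,
    report_dir,
    params: AnalysisParams | None = None,
    make_figures: bool = True,
) -> dict:
    """Run every analysis stage on a manifest; returns the run summary dict.

    Stage order: stabilized-end calling -> terminal hexamers -> T-fraction ->
    T-run distance bins -> TU selection -> metaprofiles -> concordance.
    """
    params = params or AnalysisParams()
    os.makedirs(report_dir, exist_ok=True)
    sset = load_manifest(manifest_path)
    seqs = read_fasta(sset.genome_path)
    tus = read_annotation(sset.annotation_path)
    pairs = list(sset.pairs())
    if not any(t.profile.flavor == "three_prime" for t, _ in pairs):
        raise FormatError("no depletion pairs: manifest has no paired 3'-end samples")

    summary: dict = {
        "version": __version__,
        "params": asdict(params),
        "inputs": {
            "manifest": _file_hash(manifest_path),
            "genome": _file_hash(sset.genome_path),
            "annotation": _file_hash(sset.annotation_path),
        },
        "pairs": {},
    }

    snrna = [tu for tu in tus if tu.biotype == "snRNA_like"]
    pas_tus = [tu for tu in tus if (tu.pas_score or 0) > 0 and tu.exon_count > 1]
    # distance-binned T-run analysis needs bodies spanning the binned range,
    # otherwise TES-flank effects of short TUs masquerade as distal bins
    max_bin_bp = int(max(hi for _, hi in params.bins_kb) * 1000)
    binnable = [tu for tu in tus
                if tu.exon_count > 1 and tu.body_length >= max_bin_bp]

    call_sets = {}
    for treatment, control in pairs:
        pair_id = f"{treatment.sample_id}__vs__{control.sample_id}"
        logger.info("analyze: calling %s", pair_id)
        calls = call_stabilized_ends(
            treatment.profile, control.profile,
            min_log2=params.min_log2, min_count=params.min_count,
            pseudocount=params.pseudocount,
        )
        call_sets[pair_id] = calls
        _write_tsv(calls.calls, os.path.join(report_dir, f"calls.{pair_id}.tsv"))

        pair_weight = (
            params.active_site_kmer_weight
            if treatment.profile.flavor == "active_site"
            else params.kmer_weight
        )
        kt = count_terminal_kmers(calls, seqs, k=params.k, weight=pair_weight)
        _write_tsv(kt.table, os.path.join(report_dir, f"hexamers.{pair_id}.tsv"))

        pair_summary = {
            "n_calls": len(calls),
            "treatment": treatment.sample_id,
            "control": control.sample_id,
            "condition": treatment.condition,
            "flavor": treatment.profile.flavor,
            "epap": treatment.profile.epap,
            "top_hexamers": kt.top(5),
        }

        if pas_tus and len(calls):
            # ends downstream of cleaved PASs (multiexonic, PAS-scored TUs)
            ds_calls = filter_calls_to_regions(
                calls, tu_regions(pas_tus, "downstream", params.downstream_window)
            )
            ds_kt = count_terminal_kmers(
                ds_calls, seqs, k=params.k, weight=pair_weight
            )
            _write_tsv(
                ds_kt.table,
                os.path.join(report_dir, f"hexamers_pas_downstream.{pair_id}.tsv"),
            )
            pair_summary["top_hexamers_pas_downstream"] = ds_kt.top(5)
            pair_summary["n_calls_pas_downstream"] = len(ds_calls)

        if treatment.profile.flavor == "active_site" and snrna:
            # occupancy analog: does the depletion scale body and downstream
            # signal together (flux change) or the flank only (termination
            # defect)?
            occ_table = region_signal(
                treatment.profile, control.profile, snrna,
                downstream_window=params.downstream_window,
                pseudocount=params.pseudocount,
            )
            _write_tsv(
                occ_table.table,
                os.path.join(report_dir, f"regions_snrna.{pair_id}.tsv"),
            )
            if len(snrna) >= 3:
                from .differential import body_downstream_fc_correlation

                pair_summary["body_downstream_r_snrna"] = (
                    body_downstream_fc_correlation(occ_table)
                )

        if treatment.profile.flavor == "three_prime" and len(calls):
            span = tu_regions(tus, "span", params.downstream_window)
            span_calls = filter_calls_to_regions(calls, span)
            if len(span_calls):
                tf = t_fraction_statistic(span_calls, seqs, span)
                _write_tsv(
                    pd.DataFrame(
                        [dict(end_fraction=tf.end_fraction,
                              genomic_fraction=tf.genomic_fraction,
                              n_ends=tf.n_ends, n_bases=tf.n_bases, z=tf.z)]
                    ),
                    os.path.join(report_dir, f"t_fraction.{pair_id}.tsv"),
                )
                pair_summary["t_fraction"] = dict(
                    end=tf.end_fraction, genomic=tf.genomic_fraction, z=tf.z
                )
            if snrna:
                sn_regions = tu_regions(
                    snrna, "downstream", params.snrna_search_window
                )
                sn_calls = filter_calls_to_regions(calls, sn_regions)
                sn_kt = count_terminal_kmers(
                    sn_calls, seqs, k=params.k, weight=params.kmer_weight
                )
                _write_tsv(
                    sn_kt.table,
                    os.path.join(report_dir, f"hexamers_snrna.{pair_id}.tsv"),
                )
                pair_summary["top_hexamers_snrna"] = sn_kt.top(5)

            table = region_signal(
                treatment.profile, control.profile, tus,
                downstream_window=params.downstream_window,
                pseudocount=params.pseudocount,
            )
            _write_tsv(
                table.table, os.path.join(report_dir, f"regions.{pair_id}.tsv")
            )
            selected = select_flank_stabilized_tus(
                table, params.tu_flank_min_log2, params.tu_body_max_log2
            )
            pd.DataFrame({"tu_id": selected}).to_csv(
                os.path.join(report_dir, f"selected_tus.{pair_id}.tsv"),
                sep="\t", index=False,
            )
            pair_summary["n_selected_tus"] = len(selected)

            fc = log2_ratio_track(
                treatment.profile, control.profile, params.pseudocount
            )
            if binnable:
                runs = find_t_runs(
                    seqs, binnable, min_run=params.min_run,
                    downstream_window=0,
                )
                binned = motif_distance_bins(runs, params.bins_kb)
                per_bin = stabilized_counts_per_bin(calls, binned)
                _write_tsv(
                    pd.DataFrame(
                        [
                            dict(bin=f"{lo:g}-{hi:g}kb", n_runs=len(binned.bins[(lo, hi)]),
                                 stabilized_end_reads=per_bin[(lo, hi)])
                            for lo, hi in params.bins_kb
                        ]
                    ),
                    os.path.join(report_dir, f"distance_bins.{pair_id}.tsv"),
                )
                curve = fc_over_motifs(fc, binned)
                curve.insert(0, "bin", curve.index)
                _write_tsv(
                    curve.reset_index(drop=True),
                    os.path.join(report_dir, f"motif_metacurve.{pair_id}.tsv"),
                )
                pair_summary["stabilized_per_bin"] = {
                    f"{lo:g}-{hi:g}kb": per_bin[(lo, hi)]
                    for lo, hi in params.bins_kb
                }

            hm = sort_rows_by_sum(
                downstream_heatmap(fc.values, tus, params.downstream_window)
            )
            hm_df = hm.to_frame().reset_index(names="tu_id")
            _write_tsv(
                hm_df, os.path.join(report_dir, f"downstream_heatmap.{pair_id}.tsv")
            )

            # scaled metagene of the log2 change: gene body (length-normalized)
            # plus the downstream window, mean over TUs
            meta = scaled_metaprofile(
                fc.values, tus, upstream_bp=200, body_bins=100,
                downstream_bp=params.downstream_window,
            )
            _write_tsv(
                pd.DataFrame([meta.mean_curve], columns=meta.columns),
                os.path.join(report_dir, f"metaprofile.{pair_id}.tsv"),
            )

        summary["pairs"][pair_id] = pair_summary

    if pas_tus:
        write_t_runs_bed(
            find_t_runs(seqs, tus, min_run=params.min_run),
            os.path.join(report_dir, "t_runs.bed"),
        )

    # cross-condition concordance over 3'-end call sets, both genome-wide
    # and restricted to snRNA TES-downstream windows (where the termination
    # positions are expected to be condition-invariant)
    p3 = [pid for pid, c in call_sets.items() if len(c)]
    scoped = {"global": call_sets}
    if snrna:
        sn_regions = tu_regions(snrna, "downstream", params.snrna_search_window)
        scoped["snrna_downstream"] = {
            pid: filter_calls_to_regions(call_sets[pid], sn_regions)
            for pid in p3
        }
    conc_rows = []
    for scope, sets in scoped.items():
        for i, a in enumerate(p3):
            for b_ in p3[i:]:
                res = end_position_concordance(
                    sets[a], sets[b_], params.concordance_tolerance
                )
                conc_rows.append(
                    dict(scope=scope, a=a, b=b_, a_in_b=res.a_in_b,
                         b_in_a=res.b_in_a, symmetric=res.symmetric)
                )
    if conc_rows:
        _write_tsv(
            pd.DataFrame(conc_rows), os.path.join(report_dir, "concordance.tsv")
        )

    with open(os.path.join(report_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if make_figures:
        try:
            from . import plots

            plots.render_report_figures(report_dir)
        except Exception as e:  # figures are presentation-only
            logger.warning("figure rendering failed: %s", e)

    return summary


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------

def run_compare(report_a, report_b, out_path=None, tolerance: int = 0) -> pd.DataFrame:
    """Pairwise end-position concordance across the call sets of two reports."""
    from .differential import EndCallSet

    def load_calls(report):
        out = {}
        for name in sorted(os.listdir(report)):
            if name.startswith("calls.") and name.endswith(".tsv"):
                df = pd.read_csv(os.path.join(report, name), sep="\t")
                out[name[len("calls."):-len(".tsv")]] = EndCallSet(
                    df, float("nan"), 1, float("nan")
                )
        return out

    a_sets, b_sets = load_calls(report_a), load_calls(report_b)
    if not a_sets or not b_sets:
        raise FormatError("reports contain no call sets")

    def genomes_compatible():
        sa = json.load(open(os.path.join(report_a, "run_summary.json")))
        sb = json.load(open(os.path.join(report_b, "run_summary.json")))
        return sa["inputs"]["genome"] == sb["inputs"]["genome"]

    if os.path.exists(os.path.join(report_a, "run_summary.json")) and os.path.exists(
        os.path.join(report_b, "run_summary.json")
    ):
        if not genomes_compatible():
            raise ValueError("reports derive from different genomes")

    rows = []
    for na, ca in a_sets.items():
        for nb, cb in b_sets.items():
            res = end_position_concordance(ca, cb, tolerance)
            rows.append(
                dict(a=na, b=nb, a_in_b=res.a_in_b, b_in_a=res.b_in_a,
                     symmetric=res.symmetric)
            )
    df = pd.DataFrame(rows)
    if out_path:
        _write_tsv(df, out_path)
    return df
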