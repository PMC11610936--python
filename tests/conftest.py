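import numpy as np
import pytest

import tracterm as tt
from tracterm.io import EndProfile


def make_profile(size=1000, chrom="chrS", flavor="three_prime", epap=True,
                 sample_id="s", **positions):
    """Profile from {strand: {pos: count}} keyword maps 'plus'/'minus'."""
    prof = EndProfile.empty({chrom: size}, flavor, epap, sample_id)
    for strand_name, strand in (("plus", "+"), ("minus", "-")):
        for pos, count in positions.get(strand_name, {}).items():
            prof.array(chrom, strand)[pos] = count
    return prof


@pytest.fixture(scope="session")
def default_genome():
    return tt.build_synthetic_genome(tt.default_config(seed=1))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle") / "b"
    tt.run_simulate(out, config=tt.default_config(seed=1))
    return out


@pytest.fixture(scope="session")
def default_report(default_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("report") / "r"
    summary = tt.run_analyze(default_bundle / "manifest.yaml", out,
                             make_figures=False)
    return out, summary


@pytest.fixture()
def two_tu_config():
    """Minimal two-TU config (one per strand) for fast unit tests."""
    specs = (
        tt.TUSpec(biotype="mono_nc", body_length=800, strand="+",
                  planted_terminators=((500, 6),)),
        tt.TUSpec(biotype="mono_nc", body_length=800, strand="-",
                  planted_terminators=((500, 6),)),
    )
    return tt.SimulationConfig(tu_specs=specs, seed=1)
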