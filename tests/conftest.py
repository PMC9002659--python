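import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dupscape.pipeline import PipelineConfig, run_pipeline
from dupscape.simulate import canonical_config, build_genome, simulate_genome


@pytest.fixture(scope="session")
def canonical_sim(tmp_path_factory):
    """Canonical synthetic genome written to disk, plus its config."""
    outdir = tmp_path_factory.mktemp("canonical_sim")
    config = canonical_config(seed=1)
    paths = simulate_genome(config, outdir)
    return {"config": config, "paths": paths, "outdir": outdir}


@pytest.fixture(scope="session")
def canonical_result():
    """Canonical synthetic genome in memory."""
    return build_genome(canonical_config(seed=1))


@pytest.fixture(scope="session")
def canonical_run(canonical_sim, tmp_path_factory):
    """Full pipeline run on the canonical genome."""
    outdir = tmp_path_factory.mktemp("canonical_run")
    paths = canonical_sim["paths"]
    config = PipelineConfig(
        gff3=str(paths["gff3"]), cds=str(paths["cds"]), proteins=str(paths["proteins"]),
        domains=str(paths["domains"]), outdir=str(outdir), seed=1)
    report = run_pipeline(config)
    return {"config": config, "report": report, "outdir": outdir,
            "sim": canonical_sim}


def expected_duplication_sets(config, result):
    """Truth-derived expectations for the canonical genome.

    Segmental genes: sources and copies of every segmental event.  Tandem
    genes: tandem-event members plus segmental genes whose source/copy rank
    distance is within the tandem threshold (those are 'both').
    """
    genome = result.genome
    seg, tandem = set(), set()
    for row in result.truth_duplications:
        gid, src = row["gene_id"], row["source_gene_id"]
        if row["event_type"] == "segmental":
            seg |= {gid, src}
            if abs(genome.gene(gid).rank - genome.gene(src).rank) <= 10:
                tandem |= {gid, src}
        else:
            tandem.add(src)
            tandem.add(gid)
    return seg, tandem
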