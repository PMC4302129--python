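import numpy as np
import pandas as pd
import pytest

from haplopaint import pipeline, simulate


@pytest.fixture(scope="session")
def default_result() -> pipeline.PipelineResult:
    """One full default-scale run (48 accessions x 16 fragments, two-round
    skewed coverage, 1% read error), shared across end-to-end tests."""
    cfg = pipeline.PipelineConfig(seed=1)
    return pipeline.run_pipeline(cfg)


def small_cohort_config(seed: int = 11, **overrides) -> simulate.SimulationConfig:
    """Compact study: 4 fragments, 8 accessions, exact constant coverage."""
    n = overrides.pop("n_fragments", 4)
    design = [
        simulate.pure_design("reA", "reticulata", n),
        simulate.pure_design("reB", "reticulata", n),
        simulate.pure_design("maA", "maxima", n),
        simulate.pure_design("maB", "maxima", n),
        simulate.pure_design("meA", "medica", n),
        simulate.pure_design("miA", "micrantha", n),
        simulate.f1_design("hyb_f1", "reticulata", "maxima", n, nominal="hybrid"),
        simulate.offspring_design("child", "reA", "maA", n, nominal="hybrid"),
    ]
    cfg = dict(
        n_fragments=n,
        fragment_length_bp=300,
        haplotypes_per_taxon=4,
        cohort_design=design,
        coverage_model=simulate.CoverageModel("constant", round_means=(60.0,)),
        short_read_fraction=0.0,
        seed=seed,
    )
    cfg.update(overrides)
    return simulate.SimulationConfig(**cfg)


@pytest.fixture(scope="session")
def small_run():
    cfg = small_cohort_config()
    return simulate.simulate_run(cfg), cfg


@pytest.fixture()
def toy_gm():
    """5 accessions x 4 loci with missing data and a triallelic locus."""
    from haplopaint.popgen import GenotypeMatrix

    gt = pd.DataFrame(
        {
            "L1": ["A/A", "A/T", "T/T", "A/T", "A/A"],
            "L2": ["C/C", "C/C", "C/G", np.nan, "G/G"],
            "L3": ["A/G", "A/A", "G/T", "A/T", "A/A"],
            "L4": ["T/T", "T/T", "T/T", "T/T", "T/T"],
        },
        index=["p1", "p2", "p3", "q1", "q2"],
    )
    loci = pd.DataFrame(
        {
            "fragment": ["f1", "f1", "f2", "f2"],
            "position": [10, 50, 7, 90],
            "region": ["exon", "exon", "intron", "intron"],
        },
        index=["L1", "L2", "L3", "L4"],
    )
    groups = pd.Series(
        {"p1": "P", "p2": "P", "p3": "P", "q1": "Q", "q2": "Q"}, name="group"
    )
    return GenotypeMatrix(gt, loci, groups)
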