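"""Shared driver plumbing: one deterministic default-scale study run.

Every numbered script re-derives the same run from seed 1, so each can be
executed independently while all of them describe a single consistent
analysis. Large raw artifacts (FASTQ) go under scratch/; the tables the
narrative cites go under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1

_cached = {}


def study_run():
    from haplopaint import pipeline

    if "res" not in _cached:
        cfg = pipeline.PipelineConfig(seed=SEED)
        _cached["res"] = pipeline.run_pipeline(cfg)
    return _cached["res"]


def outdirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH
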