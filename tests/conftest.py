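"""Shared fixtures: a small synthetic dataset for unit tests and one
full-scale study run shared by the end-to-end acceptance checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from srnaloc import synthetic
from srnaloc.pipeline import RunConfig, run_pipeline


def make_reads(rows: list[tuple]) -> pd.DataFrame:
    """Rows: (sequence, chrom, start, end, strand, count, n_hits, library_id)."""
    return pd.DataFrame(
        rows,
        columns=["sequence", "chrom", "start", "end", "strand", "count", "n_hits", "library_id"],
    )


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


def match_loci_to_truth(loci: pd.DataFrame, truth: pd.DataFrame, min_jaccard: float = 0.5):
    """Per truth locus the best-Jaccard selected locus; returns
    (n_recovered, matched locus indices, best class per selected locus)."""
    matched: set = set()
    rec = 0
    for _, t in truth.iterrows():
        sub = loci[
            (loci["chrom"] == t["chrom"])
            & (loci["start"] <= t["end"])
            & (loci["end"] >= t["start"])
        ]
        bj, best = 0.0, None
        for i, l in sub.iterrows():
            j = jaccard((t["start"], t["end"]), (l["start"], l["end"]))
            if j > bj:
                bj, best = j, i
        if bj >= min_jaccard:
            rec += 1
            matched.add(best)
    return rec, matched


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted dataset for unit-level checks (not sized for the
    depth-sensitive RPKM heuristic)."""
    genome = synthetic.generate_genome(1, 200_000, 1)
    archetypes = synthetic.default_archetypes(n_loci=10)
    libraries = synthetic.default_libraries()
    reads, truth = synthetic.simulate_libraries(genome, archetypes, libraries, seed=3)
    return {"genome": genome, "archetypes": archetypes, "libraries": libraries,
            "reads": reads, "truth": truth}


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full-scale pipeline run under the default study conditions
    (600 planted loci over a 2 x 2 Mb genome), shared by the end-to-end
    recovery checks."""
    run_dir = tmp_path_factory.mktemp("study") / "run"
    cfg = RunConfig(seed=1)
    run_pipeline(cfg, run_dir)
    truth = pd.read_csv(run_dir / "truth.tsv", sep="\t")
    return {"run_dir": run_dir, "cfg": cfg, "truth": truth}
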