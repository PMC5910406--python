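"""Pipeline orchestration: simulate -> segment -> annotate -> classify ->
report, driven by a single YAML config, with a manifest of checksums.

Stages communicate only through files in the run directory, so any stage
can be re-run from cached predecessors (or replaced by an external tool
producing the same formats).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from srnaloc import ioutils, synthetic
from srnaloc.features import annotate_loci
from srnaloc.mca import (
    build_indicator_matrix,
    class_hierarchy,
    enrichment_tests,
    find_paragons,
    fit_mca,
    gap_statistic,
    kmeans_cluster,
    nmi,
    select_dimensions,
)
from srnaloc.segmentation import SegmentationParams, call_expression, filter_reads, segment

STAGES = ["simulate", "segment", "annotate", "classify", "report"]


@dataclass
class RunConfig:
    """Resolved run configuration; every stage reads only from here."""

    seed: int = 1
    # synthetic data
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_loci_per_class: int = 200
    expression: float = 5000.0
    depth: float | None = None
    background_rate: float = 0.005
    # segmentation
    segmentation: dict = field(default_factory=dict)
    # classification
    n_dims: int = 6
    k: int | None = None            # None: gap-selected
    k_range: list = field(default_factory=lambda: list(range(1, 9)))
    gap_B: int = 20
    stability_B: int = 0            # 0 disables the (slow) stability sweep
    stability_dims: list = field(default_factory=lambda: [2, 4, 6])
    stability_ks: list = field(default_factory=lambda: [2, 3, 4])
    hierarchy_ks: list = field(default_factory=lambda: [2, 3])
    n_paragons: int = 1

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _mark_path(outdir: Path, mark: str) -> Path:
    return outdir / f"chip_{mark.replace('/', '_')}.bed"


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    genome = synthetic.generate_genome(cfg.n_chrom, cfg.chrom_length, cfg.seed)
    archetypes = synthetic.default_archetypes(cfg.n_loci_per_class, cfg.expression)
    libraries = synthetic.default_libraries()
    reads, truth = synthetic.simulate_libraries(
        genome, archetypes, libraries, seed=cfg.seed, depth=cfg.depth,
        background_rate=cfg.background_rate,
    )
    meth = synthetic.simulate_methylation(genome, truth, archetypes, seed=cfg.seed + 1)
    chip = synthetic.simulate_chip(genome, truth, archetypes, seed=cfg.seed + 2)
    annot = synthetic.make_annotations(genome, truth, archetypes, seed=cfg.seed + 3)
    genome.to_csv(outdir / "genome.tsv", sep="\t", index=False)
    ioutils.write_alignments(reads, outdir / "reads.tsv")
    ioutils.write_libraries(libraries, outdir / "libraries.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ioutils.write_methylation(meth, outdir / "methylation.tsv")
    for mark, df in chip.items():
        ioutils.write_bed_reads(df, _mark_path(outdir, mark))
    ioutils.write_annotations_gff3(annot, outdir / "annotations.gff3")
    (outdir / "config_echo.yaml").write_text(cfg.to_yaml())


def stage_segment(cfg: RunConfig, outdir: Path) -> None:
    reads = ioutils.read_alignments(outdir / "reads.tsv")
    libraries = ioutils.read_libraries(outdir / "libraries.tsv")
    genome = pd.read_csv(outdir / "genome.tsv", sep="\t")
    span = float(genome.groupby("chrom")["end"].max().sum())
    res = segment(reads, libraries, cfg.segmentation_params(), genome_span=span)
    ioutils.write_loci_bed(res.loci, outdir / "loci.bed")
    ioutils.write_likelihoods(res.likelihoods, outdir / "likelihoods.tsv")
    sf = pd.DataFrame(sorted(res.scaling_factors.items()), columns=["library_id", "scaling_factor"])
    sf.to_csv(outdir / "scaling_factors.tsv", sep="\t", index=False)
    log = {
        "n_loci": int(len(res.loci)),
        "fp_expected": res.fp_expected,
        "fp_percentage": res.fp_percentage,
    }
    (outdir / "segment_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def stage_annotate(cfg: RunConfig, outdir: Path) -> None:
    loci = ioutils.read_loci_bed(outdir / "loci.bed")
    lik = ioutils.read_likelihoods(outdir / "likelihoods.tsv")
    reads = ioutils.read_alignments(outdir / "reads.tsv")
    libraries = ioutils.read_libraries(outdir / "libraries.tsv")
    params = cfg.segmentation_params()
    reads = filter_reads(reads, params=params)
    annot = ioutils.read_annotations(outdir / "annotations.gff3")
    meth = ioutils.read_methylation(outdir / "methylation.tsv")
    chip = {}
    for path in sorted(outdir.glob("chip_*.bed")):
        mark = path.stem.removeprefix("chip_")
        chip[mark] = ioutils.read_bed_reads(path)
    ft = annotate_loci(
        loci, reads, libraries, lik, annotations=annot, methylation=meth,
        chip=chip, params=params, seed=cfg.seed + 4,
    )
    ioutils.write_feature_table(ft, outdir / "features.tsv")


def stage_classify(cfg: RunConfig, outdir: Path) -> None:
    ft = ioutils.read_feature_table(outdir / "features.tsv")
    Z, _ = build_indicator_matrix(ft)
    model = fit_mca(Z)
    eig = pd.DataFrame(
        {"eigenvalue": model.eigenvalues, "explained_pct": model.explained_variance}
    )
    eig.to_csv(outdir / "eigenvalues.tsv", sep="\t", index_label="dimension")
    d = min(cfg.n_dims, model.row_coords.shape[1])
    coords = model.row_coords.iloc[:, :d]
    curve, k_hat = gap_statistic(coords, cfg.k_range, B_ref=cfg.gap_B, seed=cfg.seed + 5)
    curve.to_csv(outdir / "gap.tsv", sep="\t", index=False)
    if cfg.stability_B > 0:
        stab, _ = select_dimensions(
            Z, cfg.stability_ks, cfg.stability_dims, B=cfg.stability_B, seed=cfg.seed + 6
        )
        stab.to_csv(outdir / "stability.tsv", sep="\t", index=False)
    # cluster-number choice: the gap curve plus NMI against the held-out
    # annotation-overlap features (which never enter the MCA); when the
    # one-SE rule does not settle below the top of the range, the k that
    # maximises held-out NMI decides
    held_out = [c for c in ft.columns if c.startswith("overlap_")]
    nmi_by_k = {}
    for kk in cfg.k_range:
        if kk < 2 or kk > len(ft):
            continue
        cand = kmeans_cluster(coords, kk, seed=cfg.seed + 7)
        nmi_by_k[kk] = float(np.mean([
            nmi(cand.assignments.to_numpy(), ft[c].to_numpy()) for c in held_out
        ])) if held_out else 0.0
    k_nmi = max(nmi_by_k, key=nmi_by_k.get) if nmi_by_k else 2
    k = cfg.k or (max(k_hat, 2) if k_hat < max(cfg.k_range) else k_nmi)
    pd.DataFrame(
        {"k": list(nmi_by_k), "held_out_nmi": list(nmi_by_k.values())}
    ).to_csv(outdir / "nmi_by_k.tsv", sep="\t", index=False)
    clustering = kmeans_cluster(coords, k, seed=cfg.seed + 7)
    assign = clustering.assignments.rename("class").to_frame()
    assign.to_csv(outdir / "assignments.tsv", sep="\t", index_label="locus_id")
    enr = enrichment_tests(clustering.assignments, ft)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    ks = sorted({k} | {kk for kk in cfg.hierarchy_ks if kk < k})
    clusterings = {
        kk: kmeans_cluster(coords, kk, seed=cfg.seed + 7).assignments for kk in ks
    }
    class_hierarchy(clusterings).to_csv(outdir / "hierarchy.tsv", sep="\t", index=False)
    paragons = find_paragons(clustering, coords, cfg.n_paragons)
    pd.DataFrame(
        [(cls, lid) for cls, lids in paragons.items() for lid in lids],
        columns=["class", "locus_id"],
    ).to_csv(outdir / "paragons.tsv", sep="\t", index=False)
    held_out = [c for c in ft.columns if c.startswith("overlap_")]
    nmi_rows = [
        {"feature": c, "nmi": nmi(clustering.assignments.to_numpy(), ft[c].to_numpy())}
        for c in held_out
    ]
    pd.DataFrame(nmi_rows).to_csv(outdir / "nmi.tsv", sep="\t", index=False)
    (outdir / "classify_log.json").write_text(
        json.dumps({"k_gap": int(k_hat), "k_heldout_nmi": int(k_nmi),
                    "k_used": int(k), "dims": int(d)},
                   indent=2, sort_keys=True)
    )


def percentage(count: float, total: float) -> float:
    """Percentage reported to the precision used in prose: one decimal at
    10% or more, two decimals below."""
    if total == 0:
        return 0.0
    p = 100.0 * count / total
    return round(p, 1) if p >= 10 else round(p, 2)


def report(run_dir: str | os.PathLike) -> dict:
    """Summarise a completed run: locus counts, the false-positive
    estimate, ubiquity histograms over all and wild-type-only replicate
    groups, class sizes, top enrichments and paragons."""
    outdir = Path(run_dir)
    lik = ioutils.read_likelihoods(outdir / "likelihoods.tsv")
    libraries = ioutils.read_libraries(outdir / "libraries.tsv")
    seg_log = json.loads((outdir / "segment_log.json").read_text())
    calls = call_expression(lik)
    n_loci = len(lik)
    per_group = calls.sum(axis=0).to_dict()
    n_expressed = calls.sum(axis=1)
    hist = n_expressed.value_counts().sort_index()
    wt_groups = sorted(libraries.loc[libraries["is_wild_type"], "replicate_group"].unique())
    wt_calls = calls[[g for g in calls.columns if g in wt_groups]]
    wt_any = wt_calls.any(axis=1)
    wt_n = wt_calls.loc[wt_any].sum(axis=1)
    out = {
        "n_loci": int(n_loci),
        "fp_expected": seg_log["fp_expected"],
        "fp_percentage": percentage(seg_log["fp_expected"], n_loci),
        "loci_per_group": {str(g): int(v) for g, v in per_group.items()},
        "ubiquity_histogram": {int(k): int(v) for k, v in hist.items()},
        "pct_single_group": percentage(int((n_expressed == 1).sum()), n_loci),
        "pct_all_groups": percentage(int((n_expressed == len(calls.columns)).sum()), n_loci),
        "n_wt_loci": int(wt_any.sum()),
        "pct_wt_single_group": percentage(int((wt_n == 1).sum()), max(int(wt_any.sum()), 1)),
        "pct_wt_all_groups": percentage(
            int((wt_n == len(wt_calls.columns)).sum()), max(int(wt_any.sum()), 1)
        ),
    }
    assign_path = outdir / "assignments.tsv"
    if assign_path.exists():
        assign = pd.read_csv(assign_path, sep="\t", index_col="locus_id")["class"]
        out["class_sizes"] = assign.value_counts().sort_index().to_dict()
        enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
        top = enr.nsmallest(10, "adjusted_p")[["class", "feature", "level", "sign", "adjusted_p"]]
        out["top_enrichments"] = top.to_dict("records")
        paragons = pd.read_csv(outdir / "paragons.tsv", sep="\t")
        out["paragons"] = dict(zip(paragons["class"], paragons["locus_id"]))
    (outdir / "report.json").write_text(json.dumps(out, indent=2, sort_keys=True, default=str))
    return out


def run_pipeline(
    cfg: RunConfig, run_dir: str | os.PathLike, stages: list[str] | None = None
) -> dict:
    """Run the requested stages in order (all by default) and write the
    manifest.  Re-running a later stage uses the cached outputs of its
    predecessors in ``run_dir``."""
    outdir = Path(run_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    funcs = {
        "simulate": stage_simulate,
        "segment": stage_segment,
        "annotate": stage_annotate,
        "classify": stage_classify,
    }
    for s in STAGES:
        if s not in stages:
            continue
        if s == "report":
            report(outdir)
        else:
            try:
                funcs[s](cfg, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {s!r} failed: {exc}") from exc
    manifest = {
        "config_hash": hashlib.sha256(cfg.to_yaml().encode()).hexdigest(),
        "seed": cfg.seed,
        "stages": stages,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
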