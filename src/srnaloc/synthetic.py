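"""Synthetic sRNA datasets with planted locus classes.

The generator builds a toy multi-chromosome genome partitioned into
arm / pericentromere / centromere zones, plants non-overlapping sRNA loci
belonging to archetype classes, and simulates replicate sequencing
libraries (wild-type and mutant), per-cytosine methylation tables, ChIP
read sets and annotation interval sets carrying the statistical structure
the analysis assumes: negative-binomial read totals per locus and library,
class-conditional read length / strand / 5' base / multimapping
distributions, class-conditional loss of expression in mutants, and
class-conditional methylation and chromatin signals.

All simulation parameters are artifact choices: the default archetypes are
caricatures of the three broad biological groupings of plant sRNA loci
(gene-associated 21-nt strand-biased loci; PolV-dependent 24-nt methylated
promoter-proximal loci; PolV-independent 24-nt TE/IR-associated highly
repetitive loci) and are deliberately well separated so that recovery of
the planted structure is a meaningful end-to-end check of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
READ_LENGTHS = np.arange(15, 31)
CONTEXTS = ("CpG", "CHG", "CHH")


class PlacementError(RuntimeError):
    """Raised when an archetype's loci cannot be placed in their zone."""


@dataclass
class ClassArchetype:
    """Generative description of one planted locus class."""

    name: str
    n_loci: int
    width_range: tuple[int, int]
    size_profile: Mapping[int, float]          # read length -> probability
    strand_bias: float                          # P(plus strand), in [0.5, 1]
    five_prime_probs: Mapping[str, float]       # base -> probability
    multimap_dist: Mapping[int, float]          # genomic hits -> probability
    expression: float = 100.0                   # mean reads per WT library
    expression_groups: Sequence[str] | None = None   # None: all WT groups
    mutant_loss: Mapping[str, float] = field(default_factory=dict)
    meth_level: Mapping[str, float] = field(default_factory=dict)
    mark_rates: Mapping[str, float] = field(default_factory=dict)
    overlap_features: Sequence[str] = ()
    zone: str = "arm"
    nb_size: float = 5.0

    def __post_init__(self) -> None:
        for probs, what in (
            (self.size_profile, "size_profile"),
            (self.five_prime_probs, "five_prime_probs"),
            (self.multimap_dist, "multimap_dist"),
        ):
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} must sum to 1 (got {total})")
        for g, r in self.mutant_loss.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retained fraction for {g} outside [0, 1]")
        if self.width_range[0] <= 0 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be positive and ordered")
        if any(m < 1 for m in self.multimap_dist):
            raise ValueError("multimap counts must be >= 1")


ZONES = ("arm", "pericentromere", "centromere")
_ZONE_FRACTIONS = (0.4, 0.3, 0.3)


def generate_genome(n_chrom: int, length: int, seed: int = 0) -> pd.DataFrame:
    """Toy genome: each chromosome is partitioned into three contiguous
    zones (arm, pericentromere, centromere).  Deterministic given the
    arguments; the seed is accepted for interface symmetry."""
    if length < 10_000:
        raise ValueError("chromosome length must be at least 10 kb")
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rows = []
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        bounds = [1]
        acc = 0.0
        for f in _ZONE_FRACTIONS[:-1]:
            acc += f
            bounds.append(int(round(acc * length)) + 1)
        bounds.append(length + 1)
        for zone, s, e in zip(ZONES, bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "zone": zone, "start": s, "end": e - 1})
    return pd.DataFrame(rows)


def default_archetypes(n_loci: int = 200, expression: float = 5000.0) -> list[ClassArchetype]:
    """Three well-separated default archetypes."""
    sz21 = {21: 0.80, 22: 0.15, 20: 0.05}
    sz24 = {24: 0.80, 23: 0.15, 22: 0.05}
    return [
        ClassArchetype(
            name="gene21",
            n_loci=n_loci,
            width_range=(80, 300),
            size_profile=sz21,
            strand_bias=0.95,
            five_prime_probs={"A": 0.2, "C": 0.5, "G": 0.1, "T": 0.2},
            multimap_dist={1: 0.95, 2: 0.05},
            expression=expression,
            expression_groups=("flower_1", "flower_2"),
            mutant_loss={"dcl234": 0.0, "rdr2": 1.0, "polIV": 1.0, "polV": 1.0},
            meth_level={"CpG": 0.03, "CHG": 0.02, "CHH": 0.02},
            mark_rates={"H3": 0.25, "H3K4me2": 0.75, "H3K9me2": 0.01},
            overlap_features=("gene", "expression"),
            zone="arm",
        ),
        ClassArchetype(
            name="rddm24",
            n_loci=n_loci,
            width_range=(120, 500),
            size_profile=sz24,
            strand_bias=0.5,
            five_prime_probs={"A": 0.7, "C": 0.05, "G": 0.1, "T": 0.15},
            multimap_dist={1: 0.9, 2: 0.1},
            expression=expression,
            expression_groups=None,
            mutant_loss={"dcl234": 0.0, "rdr2": 0.0, "polIV": 0.0, "polV": 0.0},
            meth_level={"CpG": 0.85, "CHG": 0.7, "CHH": 0.6},
            mark_rates={"H3": 0.08, "H3K4me2": 0.01, "H3K9me2": 0.06},
            overlap_features=("promoter", "RC/Helitron", "mobile"),
            zone="pericentromere",
        ),
        ClassArchetype(
            name="het24",
            n_loci=n_loci,
            width_range=(400, 1200),
            size_profile=sz24,
            strand_bias=0.5,
            five_prime_probs={"A": 0.35, "C": 0.2, "G": 0.25, "T": 0.2},
            multimap_dist={5: 0.2, 10: 0.4, 20: 0.4},
            expression=expression,
            expression_groups=None,
            mutant_loss={"dcl234": 0.9, "rdr2": 0.0, "polIV": 0.0, "polV": 1.0},
            meth_level={"CpG": 0.9, "CHG": 0.8, "CHH": 0.55},
            mark_rates={"H3": 0.7, "H3K4me2": 0.05, "H3K9me2": 0.7},
            overlap_features=("LTR/Gypsy", "IR", "easiRNA"),
            zone="centromere",
        ),
    ]


WT_GROUPS = (
    "flower_1", "flower_2", "leaf_1", "leaf_2", "leaf_3", "root_1", "root_2",
    "seedling_1", "seedling_2", "silique_1",
)


def default_libraries() -> pd.DataFrame:
    """Default metadata: ten wild-type replicate groups (one library each,
    emulating diverse tissues at varying depth) and one two-library group
    per mutant genotype."""
    rows = [(f"{g}_r1", g, "WT", True) for g in WT_GROUPS]
    for genotype in ("dcl234", "rdr2", "polIV", "polV"):
        for i in (1, 2):
            rows.append((f"{genotype}_r{i}", genotype, genotype, False))
    return pd.DataFrame(rows, columns=["library_id", "replicate_group", "genotype", "is_wild_type"])


# ---------------------------------------------------------------------------
# locus placement

def place_loci(
    genome: pd.DataFrame,
    archetypes: Sequence[ClassArchetype],
    rng: np.random.Generator,
    min_gap: int = 200,
    max_extra_gap: int = 300,
) -> pd.DataFrame:
    """Plant non-overlapping loci inside each archetype's target zone,
    spaced by at least ``min_gap`` so segmentation can separate them."""
    rows = []
    lid = 0
    for arch in archetypes:
        zones = genome[genome["zone"] == arch.zone].reset_index(drop=True)
        if len(zones) == 0:
            raise PlacementError(f"no {arch.zone} zone for archetype {arch.name}")
        cursors = {i: int(zones.at[i, "start"]) + min_gap for i in zones.index}
        placed = 0
        zi = 0
        attempts = 0
        while placed < arch.n_loci:
            if attempts > arch.n_loci * (len(zones) + 2):
                raise PlacementError(
                    f"cannot place {arch.n_loci} loci of archetype {arch.name}"
                )
            attempts += 1
            i = zones.index[zi % len(zones)]
            zi += 1
            width = int(rng.integers(arch.width_range[0], arch.width_range[1] + 1))
            gap = int(rng.integers(0, max_extra_gap))
            start = cursors[i] + gap
            end = start + width - 1
            if end > int(zones.at[i, "end"]) - min_gap:
                cursors[i] = int(zones.at[i, "end"])  # zone exhausted
                if all(cursors[j] >= int(zones.at[j, "end"]) for j in zones.index):
                    raise PlacementError(
                        f"cannot place {arch.n_loci} loci of archetype {arch.name}"
                    )
                continue
            cursors[i] = end + min_gap
            lid += 1
            rows.append({
                "locus_id": f"TRUTH{lid:05d}", "chrom": zones.at[i, "chrom"],
                "start": start, "end": end, "class_name": arch.name,
            })
            placed += 1
    truth = pd.DataFrame(rows)
    return truth.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# read simulation

def _random_seq(rng: np.random.Generator, length: int, first: str) -> str:
    rest = rng.integers(0, 4, size=length - 1)
    return first + "".join(BASES[i] for i in rest)


def simulate_libraries(
    genome: pd.DataFrame,
    archetypes: Sequence[ClassArchetype],
    libraries: pd.DataFrame,
    seed: int = 0,
    depth: float | None = None,
    background_rate: float = 0.005,
    mean_stack: float = 8.0,
    max_stacks: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate aligned reads for every library and the ground truth.

    Per locus and library the read total is negative-binomial with mean
    depth_factor x class expression, scaled by the mutant's retained
    fraction for mutant libraries and zeroed outside the archetype's
    expression groups for wild-type libraries.  Totals are split into at
    most ``max_stacks`` read stacks carrying class-conditional lengths,
    strands, 5' bases and multimap counts.  Background noise reads
    (count 1, single-mapping) are scattered uniformly outside the planted
    loci; their number is ``background_rate`` times the library's depth
    (its expected planted read total unless ``depth`` is given).
    """
    rng = np.random.default_rng(seed)
    truth = place_loci(genome, archetypes, rng)
    arch_by_name = {a.name: a for a in archetypes}
    wt_groups = sorted(libraries.loc[libraries["is_wild_type"], "replicate_group"].unique())
    depth_factor = {
        lib: float(np.exp(rng.normal(0.0, 0.25)))
        for lib in libraries["library_id"]
    }
    reads_rows: list[tuple] = []
    expected = {lib: np.zeros(len(truth)) for lib in libraries["library_id"]}

    for li, lib in libraries.iterrows():
        lib_id = lib["library_id"]
        group = lib["replicate_group"]
        genotype = lib["genotype"]
        is_wt = bool(lib["is_wild_type"])
        for ti, t in truth.iterrows():
            arch = arch_by_name[t["class_name"]]
            if is_wt:
                groups = arch.expression_groups or wt_groups
                base = arch.expression if group in groups else 0.0
            else:
                base = arch.expression * float(arch.mutant_loss.get(genotype, 1.0))
            mean = base * depth_factor[lib_id]
            expected[lib_id][ti] = mean
            if mean <= 0:
                continue
            p = arch.nb_size / (arch.nb_size + mean)
            total = int(rng.negative_binomial(arch.nb_size, p))
            if total == 0:
                continue
            n_stacks = min(total, 1 + int(rng.poisson(min(total / mean_stack, max_stacks - 1))))
            parts = rng.multinomial(total, np.full(n_stacks, 1.0 / n_stacks))
            lens = np.array(sorted(arch.size_profile))
            lprobs = np.array([arch.size_profile[l] for l in lens], dtype=float)
            mm = np.array(sorted(arch.multimap_dist))
            mprobs = np.array([arch.multimap_dist[m] for m in mm], dtype=float)
            fp = np.array([arch.five_prime_probs.get(b, 0.0) for b in BASES])
            for cnt in parts[parts > 0]:
                rl = int(rng.choice(lens, p=lprobs))
                start = int(rng.integers(t["start"], max(t["start"], t["end"] - rl + 1) + 1))
                strand = "+" if rng.random() < arch.strand_bias else "-"
                m = int(rng.choice(mm, p=mprobs))
                base5 = str(rng.choice(BASES, p=fp))
                seq = _random_seq(rng, rl, base5)
                reads_rows.append(
                    (seq, t["chrom"], start, start + rl - 1, strand, int(cnt), m, lib_id)
                )
        # background noise outside planted loci, 0.5% of the library depth
        lib_depth = depth if depth is not None else float(expected[lib_id].sum())
        n_bg = int(round(background_rate * lib_depth * (depth_factor[lib_id] if depth is not None else 1.0)))
        reads_rows.extend(
            _background_reads(rng, genome, truth, n_bg, lib_id)
        )

    reads = pd.DataFrame(
        reads_rows,
        columns=["sequence", "chrom", "start", "end", "strand", "count", "n_hits", "library_id"],
    )
    for lib_id in libraries["library_id"]:
        truth[f"mean_{lib_id}"] = expected[lib_id]
    return reads.reset_index(drop=True), truth


def _background_reads(
    rng: np.random.Generator,
    genome: pd.DataFrame,
    truth: pd.DataFrame,
    n: int,
    lib_id: str,
) -> list[tuple]:
    """Uniform single-count background reads placed outside planted loci."""
    chroms = genome.groupby("chrom")["end"].max()
    occupied = {
        c: sub[["start", "end"]].sort_values("start").to_numpy()
        for c, sub in truth.groupby("chrom")
    }
    out = []
    names = list(chroms.index)
    lens = chroms.to_numpy().astype(float)
    probs = lens / lens.sum()
    made = 0
    while made < n:
        c = str(rng.choice(names, p=probs))
        L = int(chroms[c])
        rl = int(rng.choice([21, 22, 23, 24]))
        start = int(rng.integers(1, L - rl + 1))
        end = start + rl - 1
        iv = occupied.get(c)
        if iv is not None:
            j = np.searchsorted(iv[:, 0], end, side="right")
            if j > 0 and iv[:j, 1].max() >= start:
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _random_seq(rng, rl, BASES[int(rng.integers(0, 4))])
        out.append((seq, c, start, end, strand, 1, 1, lib_id))
        made += 1
    return out


# ---------------------------------------------------------------------------
# methylation and chromatin

def simulate_methylation(
    genome: pd.DataFrame,
    truth: pd.DataFrame,
    archetypes: Sequence[ClassArchetype],
    seed: int = 0,
    background: float = 0.05,
    spacing: int = 8,
    concentration: float = 20.0,
    coverage_mean: float = 20.0,
) -> pd.DataFrame:
    """Per-cytosine methylation proportions, one row per (position,
    context).  Cytosines sit on a regular grid (one context per grid
    point, cycling CpG/CHG/CHH); proportions are Beta-distributed around
    the class mean inside planted loci and around ``background`` outside.
    A degenerate mean of 0 or 1 yields exactly that value."""
    rng = np.random.default_rng(seed)
    arch_by_name = {a.name: a for a in archetypes}
    rows = []
    for chrom, sub in genome.groupby("chrom"):
        L = int(sub["end"].max())
        pos = np.arange(spacing, L, spacing)
        ctx_idx = (pos // spacing) % 3
        t = truth[truth["chrom"] == chrom]
        starts = t["start"].to_numpy()
        ends = t["end"].to_numpy()
        cls = t["class_name"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        for p, ci, ins, jj in zip(pos, ctx_idx, inside, j):
            ctx = CONTEXTS[ci]
            mean = background
            if ins:
                mean = float(arch_by_name[cls[jj]].meth_level.get(ctx, background))
            if mean <= 0.0:
                prop = 0.0
            elif mean >= 1.0:
                prop = 1.0
            else:
                prop = float(rng.beta(mean * concentration, (1 - mean) * concentration))
            cov = 1 + int(rng.poisson(coverage_mean))
            rows.append((chrom, int(p), ctx, prop, cov))
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "proportion", "coverage"])


def simulate_chip(
    genome: pd.DataFrame,
    truth: pd.DataFrame,
    archetypes: Sequence[ClassArchetype],
    seed: int = 0,
    read_length: int = 50,
    background_rate: float = 0.002,
) -> dict[str, pd.DataFrame]:
    """ChIP read sets for H3 and every histone mark any archetype
    mentions.  Per locus and mark the read count is Poisson with rate
    mark_rate x width; background reads cover the rest of the genome at a
    low uniform rate.  H3 is always generated."""
    rng = np.random.default_rng(seed)
    arch_by_name = {a.name: a for a in archetypes}
    marks = sorted({m for a in archetypes for m in a.mark_rates} | {"H3"})
    genome_len = float(genome.groupby("chrom")["end"].max().sum())
    chroms = genome.groupby("chrom")["end"].max()
    names = list(chroms.index)
    lens = chroms.to_numpy().astype(float)
    probs = lens / lens.sum()
    out: dict[str, list] = {m: [] for m in marks}
    for _, t in truth.iterrows():
        arch = arch_by_name[t["class_name"]]
        width = int(t["end"]) - int(t["start"]) + 1
        for mark in marks:
            rate = float(arch.mark_rates.get(mark, 0.0))
            k = int(rng.poisson(rate * width)) if rate > 0 else 0
            if k == 0:
                continue
            starts = rng.integers(int(t["start"]), int(t["end"]) + 1, size=k)
            for s in starts:
                out[mark].append((t["chrom"], int(s), int(s) + read_length - 1, "+"))
    for mark in marks:
        n_bg = int(rng.poisson(background_rate * genome_len))
        for _ in range(n_bg):
            c = str(rng.choice(names, p=probs))
            s = int(rng.integers(1, int(chroms[c]) + 1))
            out[mark].append((c, s, s + read_length - 1, "+"))
    return {
        m: pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        for m, rows in out.items()
    }


# ---------------------------------------------------------------------------
# annotations

def make_annotations(
    genome: pd.DataFrame,
    truth: pd.DataFrame,
    archetypes: Sequence[ClassArchetype],
    seed: int = 0,
    n_random: int = 50,
) -> dict[str, pd.DataFrame]:
    """Annotation interval sets consistent with each archetype's
    ``overlap_features``: loci of a class are covered by (or adjacent to,
    for promoters) intervals of the listed types, plus a few uncorrelated
    decoy intervals per type."""
    rng = np.random.default_rng(seed)
    arch_by_name = {a.name: a for a in archetypes}
    sets: dict[str, list] = {}

    def add(name: str, chrom: str, start: int, end: int, strand: str = "+") -> None:
        sets.setdefault(name, []).append((chrom, max(1, int(start)), int(end), strand))

    for _, t in truth.iterrows():
        arch = arch_by_name[t["class_name"]]
        s, e, c = int(t["start"]), int(t["end"]), t["chrom"]
        for feat in arch.overlap_features:
            if feat == "promoter":
                # gene downstream of the locus: its 500-nt upstream window
                # overlaps the locus tail without the gene itself doing so
                add("gene", c, e + 100, e + 1100, "+")
            elif feat == "gene":
                add("gene", c, s - 50, e + 50, "+")
            else:
                add(feat, c, s - 10, e + 10, "+")
    # uncorrelated decoys, placed outside planted loci
    chroms = genome.groupby("chrom")["end"].max()
    occupied = {
        c: sub[["start", "end"]].sort_values("start").to_numpy()
        for c, sub in truth.groupby("chrom")
    }
    decoy_types = ["NAT", "lincRNA", "gene", "LTR/Gypsy", "RC/Helitron"]
    for name in decoy_types:
        made = 0
        while made < n_random:
            c = str(rng.choice(list(chroms.index)))
            L = int(chroms[c])
            w = int(rng.integers(200, 1500))
            s = int(rng.integers(1, max(2, L - w)))
            iv = occupied.get(c)
            if iv is not None:
                j = np.searchsorted(iv[:, 0], s + w, side="right")
                if j > 0 and iv[:j, 1].max() >= s:
                    continue
            add(name, c, s, s + w - 1)
            made += 1
    return {
        name: pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        for name, rows in sets.items()
    }


# ---------------------------------------------------------------------------
# feature-level sampler (for cluster-selection experiments)

ARCHETYPE_SIGNATURES: dict[str, dict[str, str]] = {
    "gene21": {
        "width": "(50,2000]", "ratio_21_24": "high", "strand_ratio": "strong",
        "repetitiveness": "low", "tissue": "intermediate", "CpG": "low",
        "CHG": "low", "CHH": "low", "H3": "moderate", "H3K4me2": "high",
        "H3K9me2": "low", "dcl234_dependent": "yes", "rdr2": "independent",
        "polIV": "independent", "polV": "independent", "fp_C": "yes", "fp_A": "no",
    },
    "rddm24": {
        "width": "(50,2000]", "ratio_21_24": "low", "strand_ratio": "no",
        "repetitiveness": "low", "tissue": "common", "CpG": "high",
        "CHG": "high", "CHH": "high", "H3": "low", "H3K4me2": "low",
        "H3K9me2": "moderate", "dcl234_dependent": "yes", "rdr2": "dependent",
        "polIV": "dependent", "polV": "dependent", "fp_A": "yes", "fp_C": "no",
    },
    "het24": {
        "width": "(50,2000]", "ratio_21_24": "low", "strand_ratio": "no",
        "repetitiveness": "high", "tissue": "common", "CpG": "high",
        "CHG": "high", "CHH": "high", "H3": "high", "H3K4me2": "low",
        "H3K9me2": "high", "dcl234_dependent": "no", "rdr2": "dependent",
        "polIV": "dependent", "polV": "independent", "fp_A": "no", "fp_C": "no",
    },
}

_FEATURE_LEVELS: dict[str, list[str]] = {
    "width": ["(0,50]", "(50,2000]", "(2000,Inf]"],
    "ratio_21_24": ["low", "moderate", "high", "unknown"],
    "strand_ratio": ["strong", "medium", "no", "unknown"],
    "repetitiveness": ["low", "moderate", "high", "unknown"],
    "tissue": ["specific", "intermediate", "common"],
    "CpG": ["low", "moderate", "high", "unknown"],
    "CHG": ["low", "high", "unknown"],
    "CHH": ["low", "high", "unknown"],
    "H3": ["none", "low", "moderate", "high"],
    "H3K4me2": ["low", "moderate", "high", "unknown"],
    "H3K9me2": ["low", "moderate", "high", "unknown"],
    "dcl234_dependent": ["yes", "no"],
    "rdr2": ["independent", "unknown", "dependent"],
    "polIV": ["independent", "unknown", "dependent"],
    "polV": ["independent", "unknown", "dependent"],
    "fp_A": ["yes", "no"],
    "fp_C": ["yes", "no"],
}


def sample_feature_table(
    n_per_class: int = 200,
    seed: int = 0,
    noise: float = 0.08,
    signatures: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a categorical feature table directly from class signatures.

    Each locus takes its class's signature level per feature, flipped to a
    uniformly chosen other level with probability ``noise``.  This
    feature-level shortcut drives the dimension/cluster-selection
    experiments without the cost of full read simulation.
    """
    signatures = signatures or ARCHETYPE_SIGNATURES
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    ids = []
    i = 0
    for cls, sig in signatures.items():
        for _ in range(n_per_class):
            i += 1
            ids.append(f"SYN{i:05d}")
            labels.append(cls)
            row = {}
            for feat, level in sig.items():
                levels = _FEATURE_LEVELS[feat]
                if rng.random() < noise:
                    others = [l for l in levels if l != level]
                    row[feat] = str(rng.choice(others))
                else:
                    row[feat] = level
            rows.append(row)
    index = pd.Index(ids, name="locus_id")
    return pd.DataFrame(rows, index=index), pd.Series(labels, index=index, name="class_name")
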