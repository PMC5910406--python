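"""Per-locus categorical feature annotation.

Most features are depth-dependent estimates (a proportion, a ratio, a
rate).  Rather than thresholding the point estimate, each locus is binned
through a 95% confidence interval: if the interval sits wholly inside one
partition the locus takes that partition's label; if it crosses a single
threshold the locus is assigned to the partition nearest a feature-specific
default; if it crosses more than one threshold no annotation is recorded
("unknown").  This keeps shallowly sequenced loci from being confidently
mislabelled while still using every locus in the downstream MCA, where
"unknown" is a real categorical level.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from srnaloc.segmentation import (
    SegmentationParams,
    _fdr_prefix,
    _locus_library_counts,
    _nb_logpmf,
)

UNKNOWN = "unknown"
BASES = ("A", "C", "G", "T")


@dataclass
class IntervalEstimate:
    """A point estimate with a 95% confidence interval."""

    point: float
    lower: float
    upper: float
    n_effective: int = 0

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass
class CategoricalBinSpec:
    """Thresholds partitioning the real line into labelled bins.

    ``labels`` has one entry per partition (len(thresholds) + 1); labels may
    repeat for symmetric specifications (e.g. strand bias folded around
    0.5).  ``default_label`` names the partition toward which a
    single-threshold-crossing confidence interval is resolved.
    """

    thresholds: Sequence[float]
    labels: Sequence[str]
    default_label: str
    unknown_label: str = UNKNOWN

    def __post_init__(self) -> None:
        t = list(self.thresholds)
        if sorted(set(t)) != t:
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(t) + 1:
            raise ValueError("need len(thresholds) + 1 labels")
        if self.default_label not in self.labels:
            raise ValueError("default_label must be one of labels")

    def partition(self, value: float) -> int:
        """Index of the partition containing ``value``; partitions are
        (-inf, t0], (t0, t1], ..., (tn, inf)."""
        return int(np.searchsorted(np.asarray(self.thresholds), value, side="left"))


def bin_by_confidence_interval(est: IntervalEstimate, spec: CategoricalBinSpec) -> str:
    """The three-way CI binning rule.

    Wholly within one partition -> that partition's label; crossing exactly
    one threshold -> the candidate partition nearest the default; crossing
    more than one -> the unknown label.
    """
    lo = spec.partition(est.lower)
    hi = spec.partition(est.upper)
    if lo == hi:
        return spec.labels[lo]
    if hi - lo == 1:
        d = list(spec.labels).index(spec.default_label)
        return spec.labels[lo] if abs(lo - d) < abs(hi - d) else spec.labels[hi]
    return spec.unknown_label


DEFAULT_BIN_SPECS: dict[str, CategoricalBinSpec] = {
    "ratio_21_24": CategoricalBinSpec([0.2, 0.8], ["low", "moderate", "high"], "low"),
    "strand_ratio": CategoricalBinSpec(
        [0.1, 0.3, 0.7, 0.9], ["strong", "medium", "no", "medium", "strong"], "no"
    ),
    "repetitiveness": CategoricalBinSpec([0.2, 0.8], ["low", "moderate", "high"], "low"),
    "CpG": CategoricalBinSpec([0.3, 0.7], ["low", "moderate", "high"], "low"),
    "CHG": CategoricalBinSpec([0.3], ["low", "high"], "low"),
    "CHH": CategoricalBinSpec([0.3], ["low", "high"], "low"),
    "H3": CategoricalBinSpec([0.02, 0.1, 0.3], ["none", "low", "moderate", "high"], "none"),
    "histone_mark": CategoricalBinSpec([0.33, 0.66], ["low", "moderate", "high"], "low"),
}


def wilson_interval(count: float, nobs: float, alpha: float = 0.05) -> IntervalEstimate:
    """Wilson score interval for a binomial proportion; well behaved at
    small counts and at the 0/1 boundaries."""
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    # the Wilson interval excludes 0/1 at the boundaries; clamp the point
    point = min(max(count / nobs, float(lo)), float(hi))
    return IntervalEstimate(point=point, lower=float(lo), upper=float(hi),
                            n_effective=int(round(nobs)))


# ---------------------------------------------------------------------------
# individual features

def width_category(locus: Mapping | pd.Series) -> str:
    """Locus size bins (0, 50], (50, 2000], (2000, inf); width is
    end - start + 1 (1-based inclusive)."""
    width = int(locus["end"]) - int(locus["start"]) + 1
    if width <= 50:
        return "(0,50]"
    if width <= 2000:
        return "(50,2000]"
    return "(2000,Inf]"


def ratio_21_24(
    lengths: np.ndarray, counts: np.ndarray, spec: CategoricalBinSpec
) -> str:
    """Proportion of 21-22 nt reads among 21-24 nt reads, binned through a
    Wilson CI with default 'low'."""
    short = float(counts[(lengths >= 21) & (lengths <= 22)].sum())
    long_ = float(counts[(lengths >= 23) & (lengths <= 24)].sum())
    n = short + long_
    if n == 0:
        return spec.unknown_label
    return bin_by_confidence_interval(wilson_interval(short, n), spec)


def strand_ratio(strands: np.ndarray, counts: np.ndarray, spec: CategoricalBinSpec) -> str:
    """Proportion of reads on the plus strand, binned into five symmetric
    partitions whose labels fold around 0.5 (strong/medium/no)."""
    n = float(counts.sum())
    if n == 0:
        return spec.unknown_label
    plus = float(counts[strands == "+"].sum())
    return bin_by_confidence_interval(wilson_interval(plus, n), spec)


def repetitiveness(
    xs: np.ndarray, ms: np.ndarray, spec: CategoricalBinSpec | None = None
) -> tuple[IntervalEstimate | None, str]:
    """Repetitiveness R = 1 - sum_i(x_i / m_i) / sum_i(x_i).

    x_i is the sequenced abundance of the i-th distinct sRNA at the locus
    and m_i its number of genomic hits; R is 0 when every sRNA maps only
    here, approaching 1 when the sRNAs map to many other places.  The CI
    treats sum(x_i/m_i) as successes among sum(x_i) binomial trials.
    """
    spec = spec or DEFAULT_BIN_SPECS["repetitiveness"]
    n = float(xs.sum())
    if n == 0:
        return None, spec.unknown_label
    unique_mass = float((xs / ms).sum())
    ci = wilson_interval(unique_mass, n)
    est = IntervalEstimate(
        point=1.0 - ci.point, lower=1.0 - ci.upper, upper=1.0 - ci.lower,
        n_effective=ci.n_effective,
    )
    return est, bin_by_confidence_interval(est, spec)


def tissue_specificity(n_expressed_wt_groups: int) -> str:
    """Ubiquity of expression over wild-type replicate groups: 'common' at
    ten or more, 'intermediate' for two to nine, 'specific' at one or
    fewer."""
    if n_expressed_wt_groups >= 10:
        return "common"
    if n_expressed_wt_groups > 1:
        return "intermediate"
    return "specific"


def phasing_pvalue(
    locus: Mapping | pd.Series,
    starts: np.ndarray,
    ends: np.ndarray,
    strands: np.ndarray,
    phase: int = 21,
) -> float:
    """Hypergeometric register test for phasing within one replicate group.

    5' ends (minus-strand ends offset by +2 to account for the duplex
    overhang) are reduced to distinct positions within the locus window;
    the p-value is the hypergeometric tail probability of observing at
    least as many distinct positions on the 21-nt register anchored at the
    locus start, given the number of occupied positions.
    """
    width = int(locus["end"]) - int(locus["start"]) + 1
    if width < 3 * phase:
        return 1.0
    five = np.where(strands == "+", starts, ends + 2)
    rel = five - int(locus["start"])
    rel = rel[(rel >= 0) & (rel < width)]
    if len(rel) == 0:
        return 1.0
    occupied = np.unique(rel)
    on_register = int((occupied % phase == 0).sum())
    n_register = len(range(0, width, phase))
    return float(stats.hypergeom.sf(on_register - 1, width, n_register, len(occupied)))


def phasing_category(pvalues: Sequence[float], alpha: float = 0.05) -> str:
    """'high' when significant in more than five wild-type groups,
    'moderate' in at least one, otherwise 'none'."""
    n_sig = sum(1 for p in pvalues if p < alpha)
    if n_sig > 5:
        return "high"
    if n_sig >= 1:
        return "moderate"
    return "none"


def five_prime_preference(
    base_counts: pd.DataFrame,
    background_probs: Mapping[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus 5' base preference calls.

    ``base_counts``: loci x {A, C, G, T} counts of 21-24 nt wild-type
    reads.  For each locus and base a one-sided binomial enrichment
    p-value against the background proportion is computed;
    Benjamini-Hochberg adjustment runs over all loci x 4 tests; a base is
    preferred when the adjusted p-value is below ``alpha`` and the
    observed proportion exceeds the background.  Up to three bases can be
    preferred at one locus.
    """
    n = base_counts.sum(axis=1).to_numpy().astype(float)
    pvals = np.ones((len(base_counts), 4))
    excess = np.zeros((len(base_counts), 4), dtype=bool)
    for j, b in enumerate(BASES):
        k = base_counts[b].to_numpy().astype(float)
        p0 = float(background_probs[b])
        with np.errstate(divide="ignore", invalid="ignore"):
            pv = stats.binom.sf(k - 1, n.astype(int), p0)
        pv = np.where(n > 0, pv, 1.0)
        pvals[:, j] = pv
        excess[:, j] = np.where(n > 0, k / np.maximum(n, 1) > p0, False)
    _, adj, _, _ = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")
    adj = adj.reshape(pvals.shape)
    calls = (adj < alpha) & excess
    return pd.DataFrame(calls, index=base_counts.index, columns=list(BASES))


def methylation_category(
    proportions: np.ndarray,
    spec: CategoricalBinSpec,
    rng: np.random.Generator,
    n_boot: int = 1000,
) -> str:
    """Percentile-bootstrap CI (B resamples) of the mean per-cytosine
    methylation proportion at the locus, binned with default 'low'.
    Returns 'unknown' when no cytosine of the context overlaps."""
    vals = np.asarray(proportions, dtype=float)
    if len(vals) == 0:
        return spec.unknown_label
    point = float(vals.mean())
    if np.all(vals == vals[0]):
        lower = upper = point
    else:
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        means = vals[idx].mean(axis=1)
        lower, upper = np.percentile(means, [2.5, 97.5])
    est = IntervalEstimate(point=min(max(point, lower), upper), lower=float(lower),
                           upper=float(upper), n_effective=len(vals))
    return bin_by_confidence_interval(est, spec)


def poisson_rate_interval(k: int, width: float, alpha: float = 0.05) -> IntervalEstimate:
    """Exact (chi-square) CI for a Poisson rate per base given ``k`` reads
    over ``width`` bases."""
    lower = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return IntervalEstimate(point=k / width, lower=lower / width, upper=upper / width,
                            n_effective=k)


def h3_category(k: int, width: float, spec: CategoricalBinSpec) -> str:
    """Histone (H3) accumulation: reads per base with an exact Poisson CI.

    Bins are defined on the rate scale; since the log is monotone this is
    equivalent to binning the log-rate with log-transformed thresholds.
    """
    return bin_by_confidence_interval(poisson_rate_interval(k, width), spec)


def histone_mark_category(k_mark: int, k_h3: int, spec: CategoricalBinSpec) -> str:
    """Mark level relative to H3: the proportion k_mark / (k_mark + k_H3)
    with a Wilson CI, default 'low'; 'unknown' when neither dataset has a
    read at the locus."""
    n = k_mark + k_h3
    if n == 0:
        return spec.unknown_label
    return bin_by_confidence_interval(wilson_interval(float(k_mark), float(n)), spec)


# ---------------------------------------------------------------------------
# mutant dependency

def dcl_dependency(mutant_likelihoods: pd.Series, fdr: float = 0.05) -> pd.Series:
    """Expression-mode dependency call: loci selected as expressed in the
    mutant at the given FDR are 'independent'; all others 'dependent'."""
    p = mutant_likelihoods.to_numpy().astype(float)
    order = np.argsort(-p, kind="stable")
    n = _fdr_prefix(p, fdr)
    labels = np.full(len(p), "dependent", dtype=object)
    labels[order[:n]] = "independent"
    return pd.Series(labels, index=mutant_likelihoods.index)


def differential_dependency(
    loci: pd.DataFrame,
    reads: pd.DataFrame,
    libraries: pd.DataFrame,
    genotype: str,
    scaling: Mapping[str, float],
    fdr: float = 0.05,
    nb_size: float = 5.0,
    min_fold: float = 4.0,
    min_reads: int = 5,
    cycles: int = 3,
) -> pd.Series:
    """Differential-mode dependency call (RDR2 / PolIV / PolV).

    Wild-type and mutant counts at each locus are compared under two
    negative-binomial models with fixed dispersion sharing the wild-type
    rate: a no-loss model in which the mutant keeps the wild-type rate,
    and a loss model in which the mutant rate is at most 1/min_fold of
    the wild-type rate (min_fold keeps the alternative identifiable at
    this dispersion and replicate number).  A per-locus
    posterior of loss is formed with an empirically re-estimated mixing
    proportion; loci selected at the given FDR on the loss posterior are
    'dependent', loci selected on the complementary posterior are
    'independent', everything else (including loci with fewer than
    ``min_reads`` reads overall) is 'unknown'.
    """
    wt_libs = list(libraries.loc[libraries["is_wild_type"], "library_id"])
    mut_libs = list(libraries.loc[libraries["genotype"] == genotype, "library_id"])
    if not mut_libs:
        return pd.Series(UNKNOWN, index=loci.index, dtype=object)
    libs = wt_libs + mut_libs
    counts = _locus_library_counts(loci, reads, libs)
    sf = np.array([scaling[l] for l in libs], dtype=float)
    is_wt = np.array([l in wt_libs for l in libs])
    s_wt, s_mut = sf[is_wt].sum(), sf[~is_wt].sum()
    k_wt = counts[:, is_wt].sum(axis=1)
    k_mut = counts[:, ~is_wt].sum(axis=1)
    a = k_wt / s_wt
    b = k_mut / s_mut
    eps = 1e-9

    def loglik(rate_wt: np.ndarray, rate_mut: np.ndarray) -> np.ndarray:
        mu = np.where(is_wt[None, :], rate_wt[:, None], rate_mut[:, None]) * sf[None, :]
        return _nb_logpmf(counts, np.maximum(mu, eps), nb_size).sum(axis=1)

    ll_null = loglik(np.maximum(a, eps), np.maximum(a, eps))
    ll_loss = loglik(np.maximum(a, eps), np.minimum(b, a / min_fold))
    llr = np.clip(ll_loss - ll_null, -700, 700)
    pi = 0.5
    p = np.zeros(len(llr))
    for _ in range(cycles):
        p = 1.0 / (1.0 + (1.0 - pi) / pi * np.exp(-llr))
        pi = float(np.clip(p.mean(), 1e-4, 1 - 1e-4))
    labels = np.full(len(p), UNKNOWN, dtype=object)
    # FDR prefix plus a posterior-majority guard: the prefix rule alone
    # would spend its budget on loci whose own posterior favours no-loss
    order = np.argsort(-p, kind="stable")
    dep = order[: _fdr_prefix(p, fdr)]
    labels[dep[p[dep] > 0.5]] = "dependent"
    q = 1.0 - p
    order_q = np.argsort(-q, kind="stable")
    indep = order_q[: _fdr_prefix(q, fdr)]
    indep = indep[(q[indep] > 0.5) & (labels[indep] != "dependent")]
    labels[indep] = "independent"
    labels[(k_wt + k_mut) < min_reads] = UNKNOWN
    return pd.Series(labels, index=loci.index, dtype=object)


# ---------------------------------------------------------------------------
# interval overlap

def promoters_from_genes(genes: pd.DataFrame, length: int = 500) -> pd.DataFrame:
    """Strand-aware promoter intervals: the ``length`` nt upstream of each
    gene start (gene end + 1 .. + length for minus-strand genes)."""
    plus = genes["strand"] != "-"
    start = np.where(plus, genes["start"] - length, genes["end"] + 1)
    end = np.where(plus, genes["start"] - 1, genes["end"] + length)
    out = pd.DataFrame(
        {"chrom": genes["chrom"], "start": np.maximum(start, 1), "end": end,
         "strand": genes["strand"]}
    )
    return out[out["end"] >= out["start"]].reset_index(drop=True)


def interval_overlap(loci: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Boolean per locus: does any interval overlap it by at least one
    base?"""
    result = np.zeros(len(loci), dtype=bool)
    by_chrom = {c: sub.sort_values("start") for c, sub in intervals.groupby("chrom")}
    for i, (chrom, ls, le) in enumerate(loci[["chrom", "start", "end"]].itertuples(index=False)):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        maxend = np.maximum.accumulate(sub["end"].to_numpy())
        j = np.searchsorted(starts, le, side="right")
        result[i] = j > 0 and maxend[j - 1] >= ls
    return pd.Series(result, index=loci.index)


# ---------------------------------------------------------------------------
# feature-table orchestrator

def _reads_by_locus(loci: pd.DataFrame, reads: pd.DataFrame) -> list[np.ndarray]:
    """Positional index arrays of reads overlapping each locus."""
    out: list[np.ndarray] = [np.array([], dtype=int)] * len(loci)
    if len(reads) == 0:
        return out
    max_len = int((reads["end"] - reads["start"]).max()) + 1
    for chrom, sub in reads.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        rstart = sub["start"].to_numpy()
        rend = sub["end"].to_numpy()
        ridx = sub.index.to_numpy()
        lmask = (loci["chrom"] == chrom).to_numpy()
        for i, (ls, le) in zip(
            np.flatnonzero(lmask), loci.loc[lmask, ["start", "end"]].to_numpy()
        ):
            lo = np.searchsorted(rstart, ls - max_len, side="left")
            hi = np.searchsorted(rstart, le, side="right")
            sel = rend[lo:hi] >= ls
            out[i] = ridx[lo:hi][sel]
    return out


def annotate_loci(
    loci: pd.DataFrame,
    reads: pd.DataFrame,
    libraries: pd.DataFrame,
    likelihoods: pd.DataFrame,
    annotations: Mapping[str, pd.DataFrame] | None = None,
    methylation: pd.DataFrame | None = None,
    chip: Mapping[str, pd.DataFrame] | None = None,
    bin_specs: Mapping[str, CategoricalBinSpec] | None = None,
    dependency_factors: Mapping[str, Mapping] | None = None,
    params: SegmentationParams | None = None,
    scaling: Mapping[str, float] | None = None,
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Build the complete categorical feature table for a locus map.

    Intrinsic features (width, 21/24 ratio, strand ratio, repetitiveness,
    phasing, 5' base preference, tissue ubiquity) are computed from
    wild-type reads only, since mutant libraries do not reflect endogenous
    sRNA populations.  Extrinsic features come from the methylation table,
    the ChIP read sets and the annotation interval sets.  Every locus
    receives a label for every feature; "unknown" is a value, so the table
    has no missing cells.
    """
    from srnaloc.segmentation import call_expression, scaling_factors

    specs = dict(DEFAULT_BIN_SPECS)
    if bin_specs:
        specs.update(bin_specs)
    params = params or SegmentationParams()
    loci = loci.reset_index(drop=True)
    index = pd.Index(loci["locus_id"], name="locus_id")
    rng = np.random.default_rng(seed)

    wt_lib_ids = set(libraries.loc[libraries["is_wild_type"], "library_id"])
    wt_groups = sorted(
        libraries.loc[libraries["is_wild_type"], "replicate_group"].unique()
    )
    wt_reads = reads[reads["library_id"].isin(wt_lib_ids)].reset_index(drop=True)
    per_locus = _reads_by_locus(loci, wt_reads)

    ft: dict[str, list | pd.Series] = {}
    ft["width"] = [width_category(r) for _, r in loci.iterrows()]

    # expression calls over wild-type groups for tissue specificity
    calls = call_expression(likelihoods, params.expression_cutoff)
    wt_calls = calls[[g for g in calls.columns if g in wt_groups]]
    n_expr = wt_calls.reindex(loci["locus_id"]).fillna(False).sum(axis=1).to_numpy()
    ft["tissue"] = [tissue_specificity(int(n)) for n in n_expr]

    # intrinsic read-derived features
    lengths_all = (wt_reads["end"] - wt_reads["start"] + 1).to_numpy()
    counts_all = wt_reads["count"].to_numpy()
    strands_all = wt_reads["strand"].to_numpy()
    starts_all = wt_reads["start"].to_numpy()
    ends_all = wt_reads["end"].to_numpy()
    seqs_all = wt_reads["sequence"].to_numpy()
    nhits_all = wt_reads["n_hits"].to_numpy()
    lib_all = wt_reads["library_id"].to_numpy()
    lib_to_group = dict(zip(libraries["library_id"], libraries["replicate_group"]))

    ratio, strand_lab, rep_lab, phase_lab = [], [], [], []
    base_counts = np.zeros((len(loci), 4))
    for i, idx in enumerate(per_locus):
        lengths = lengths_all[idx]
        counts = counts_all[idx]
        ratio.append(ratio_21_24(lengths, counts, specs["ratio_21_24"]))
        strand_lab.append(strand_ratio(strands_all[idx], counts, specs["strand_ratio"]))
        # repetitiveness over distinct sequences at the locus
        seqs = seqs_all[idx]
        _, first = np.unique(seqs, return_index=True)
        xs = counts[first].astype(float)
        ms = nhits_all[idx][first].astype(float)
        _, lab = repetitiveness(xs, ms, specs["repetitiveness"])
        rep_lab.append(lab)
        # phasing per wild-type group
        pvals = []
        groups_here = np.array([lib_to_group[l] for l in lib_all[idx]])
        for g in wt_groups:
            gm = groups_here == g
            if not gm.any():
                pvals.append(1.0)
                continue
            pvals.append(
                phasing_pvalue(
                    loci.iloc[i], starts_all[idx][gm], ends_all[idx][gm],
                    strands_all[idx][gm],
                )
            )
        phase_lab.append(phasing_category(pvals))
        # 5' base counts among 21-24 nt reads
        elig = (lengths >= 21) & (lengths <= 24)
        for j, b in enumerate(BASES):
            bm = elig & (seqs_all[idx].astype("U1") == b)
            base_counts[i, j] = counts[bm].sum()
    ft["ratio_21_24"] = ratio
    ft["strand_ratio"] = strand_lab
    ft["repetitiveness"] = rep_lab
    ft["phasing"] = phase_lab

    # 5' base preference: background recomputed from all eligible WT reads
    elig_all = (lengths_all >= 21) & (lengths_all <= 24)
    first_base = seqs_all.astype("U1")
    bg_tot = counts_all[elig_all].sum()
    background = {
        b: (counts_all[elig_all & (first_base == b)].sum() / bg_tot) if bg_tot else 0.25
        for b in BASES
    }
    bc = pd.DataFrame(base_counts, index=index, columns=list(BASES))
    prefs = five_prime_preference(bc, background)
    for b in BASES:
        ft[f"fp_{b}"] = np.where(prefs[b].to_numpy(), "yes", "no")

    # methylation per context
    if methylation is not None and len(methylation):
        for ctx in ("CpG", "CHG", "CHH"):
            sub = methylation[methylation["context"] == ctx]
            sub_iv = pd.DataFrame(
                {"chrom": sub["chrom"], "start": sub["pos"], "end": sub["pos"],
                 "proportion": sub["proportion"]}
            ).reset_index(drop=True)
            by = _reads_by_locus(loci, sub_iv)
            props = sub_iv["proportion"].to_numpy()
            ft[ctx] = [
                methylation_category(props[np.asarray(ix, dtype=int)], specs[ctx], rng, n_boot)
                for ix in by
            ]
    else:
        for ctx in ("CpG", "CHG", "CHH"):
            ft[ctx] = [UNKNOWN] * len(loci)

    # histone accumulation and marks
    widths = (loci["end"] - loci["start"] + 1).to_numpy().astype(float)
    if chip:
        h3 = chip.get("H3")
        h3_counts = np.zeros(len(loci), dtype=int)
        if h3 is not None and len(h3):
            h3_counts = np.array([len(ix) for ix in _reads_by_locus(loci, h3.reset_index(drop=True))])
        ft["H3"] = [h3_category(int(k), w, specs["H3"]) for k, w in zip(h3_counts, widths)]
        for mark in sorted(chip):
            if mark == "H3":
                continue
            mk = chip[mark]
            mk_counts = np.array([len(ix) for ix in _reads_by_locus(loci, mk.reset_index(drop=True))])
            ft[mark] = [
                histone_mark_category(int(km), int(kh), specs["histone_mark"])
                for km, kh in zip(mk_counts, h3_counts)
            ]

    # pathway dependencies
    if dependency_factors is None:
        dependency_factors = default_dependency_factors(libraries)
    scaling = scaling or scaling_factors(reads)
    for factor, cfg in dependency_factors.items():
        if cfg["mode"] == "expression":
            group = cfg["group"]
            if group in likelihoods.columns:
                lab = dcl_dependency(
                    likelihoods[group].reindex(loci["locus_id"]).fillna(0.0),
                    params.fdr,
                )
                ft[factor] = np.where(lab.to_numpy() == "independent", "no", "yes")
            else:
                ft[factor] = [UNKNOWN] * len(loci)
        else:
            ft[factor] = differential_dependency(
                loci, reads, libraries, cfg["genotype"], scaling, fdr=params.fdr,
                nb_size=params.nb_size,
            ).to_numpy()

    # annotation overlap (held out from MCA by default downstream)
    if annotations:
        genes = annotations.get("gene")
        if genes is not None:
            ft["overlap_promoter"] = np.where(
                interval_overlap(loci, promoters_from_genes(genes)), "yes", "no"
            )
        for name in sorted(annotations):
            col = f"overlap_{name.replace('/', '_')}"
            ft[col] = np.where(interval_overlap(loci, annotations[name]), "yes", "no")

    table = pd.DataFrame(ft, index=index)
    assert not table.isna().any().any(), "feature table must be complete"
    return table


def default_dependency_factors(libraries: pd.DataFrame) -> dict[str, dict]:
    """Derive the dependency factors to compute from the genotypes present:
    dcl234 uses expression mode on its replicate group; rdr2/polIV/polV use
    the differential comparison against wild type."""
    factors: dict[str, dict] = {}
    mut = libraries[~libraries["is_wild_type"]]
    for genotype, sub in mut.groupby("genotype"):
        g = str(genotype)
        if g.startswith("dcl"):
            factors["dcl234_dependent"] = {
                "mode": "expression",
                "group": str(sub["replicate_group"].iloc[0]),
            }
        else:
            factors[g] = {"mode": "differential", "genotype": g}
    return factors
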