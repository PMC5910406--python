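"""Segmentation of aligned small RNA reads into expressed loci.

The procedure mirrors the standard sRNA locus-mapping workflow:

1. read filtering (length 15-30 nt, at most 1000 genomic hits, a
   low-complexity rule removing reads with >=10 identical bases in any
   11-nt window, and removal of an exclusion sequence set);
2. library scaling factors (sum of the lowest 75% of unique-sequence
   abundances, a depth surrogate robust to a few very abundant sRNAs);
3. candidate regions: maximal read-covered intervals with no internal
   uncovered gap of 100 nt or more, pooled over all libraries;
4. heuristic segmentation per replicate group: sub-intervals whose
   windowed RPKM stays above threshold, merged across sub-threshold gaps
   of at most 100 nt;
5. per-group posterior likelihoods of expression from a two-component
   negative-binomial model (background density vs expressed density),
   with mixing proportion and expressed density re-estimated over a small
   number of bootstrap cycles;
6. FDR-based selection (cumulative mean of one minus the likelihood) and
   merging of overlapping selections into the final non-overlapping map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SegmentationParams:
    """Tuning constants for read filtering and segmentation."""

    min_len: int = 15
    max_len: int = 30
    max_hits: int = 1000
    lc_window: int = 11
    lc_max_same: int = 10
    max_gap: int = 100
    rpkm_threshold: float = 1000.0
    rpkm_window: int = 50
    #: absolute floor on the windowed read mass (base-coverage sum): a
    #: window must hold more mass than a couple of stray single-copy
    #: reads regardless of library depth
    min_window_mass: float = 50.0
    fdr: float = 0.05
    expression_cutoff: float = 0.5
    bootstrap_cycles: int = 3
    nb_size: float = 5.0
    #: expressed mean is kept at least this factor above background
    signal_floor: float = 10.0
    #: expressed mean is kept at least this fraction of the library's
    #: typical per-locus read total (penalises isolated single reads)
    abundance_floor: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_len", "max_len", "max_hits", "lc_window", "lc_max_same",
                     "max_gap", "rpkm_threshold", "rpkm_window", "bootstrap_cycles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.expression_cutoff < 1.0:
            raise ValueError("expression_cutoff must lie in (0, 1)")


@dataclass
class SegmentationResult:
    loci: pd.DataFrame                  # locus_id, chrom, start, end
    likelihoods: pd.DataFrame           # locus_id x replicate_group
    scaling_factors: dict[str, float]
    fp_expected: float
    fp_percentage: float


# ---------------------------------------------------------------------------
# read filtering

def _is_low_complexity(seq: str, window: int, max_same: int) -> bool:
    """True if any window-length substring contains >= max_same copies of
    one base."""
    n = len(seq)
    if n < window:
        return False
    counts = {b: 0 for b in set(seq)}
    for b in seq[:window]:
        counts[b] += 1
    if max(counts.values()) >= max_same:
        return True
    for i in range(window, n):
        counts[seq[i]] = counts.get(seq[i], 0) + 1
        counts[seq[i - window]] -= 1
        if counts[seq[i]] >= max_same:
            return True
    return False


def filter_reads(
    reads: pd.DataFrame,
    exclusion_seqs: Iterable[str] = (),
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Apply the read-level filters; returns the retained rows.

    Retains reads of 15-30 nt mapping to at most 1000 genomic locations,
    removes low-complexity reads and any sequence in the exclusion set
    (the stand-in for known miRNA/tRNA/rRNA sequences).
    """
    params = params or SegmentationParams()
    excl = set(exclusion_seqs)
    length = reads["end"].to_numpy() - reads["start"].to_numpy() + 1
    keep = (length >= params.min_len) & (length <= params.max_len)
    keep &= reads["n_hits"].to_numpy() <= params.max_hits
    if excl:
        keep &= ~reads["sequence"].isin(excl).to_numpy()
    # low-complexity rule on the distinct sequences only
    seqs = reads.loc[keep, "sequence"].unique()
    bad = {s for s in seqs if _is_low_complexity(s, params.lc_window, params.lc_max_same)}
    if bad:
        keep &= ~reads["sequence"].isin(bad).to_numpy()
    return reads.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# scaling factors

def compute_scaling_factor(lib_reads: pd.DataFrame) -> float:
    """Library scaling factor: the sum of the lowest 75% of unique-sequence
    abundances in the library (sequence-rank reading: the ceil(0.75 n)
    least abundant distinct sequences contribute their full counts)."""
    uniq = lib_reads.drop_duplicates("sequence")
    if len(uniq) == 0:
        raise ValueError("cannot compute a scaling factor for an empty library")
    ab = np.sort(uniq["count"].to_numpy())
    m = math.ceil(0.75 * len(ab))
    return float(ab[:m].sum())


def scaling_factors(reads: pd.DataFrame) -> dict[str, float]:
    return {
        str(lib): compute_scaling_factor(sub)
        for lib, sub in reads.groupby("library_id", sort=True)
    }


# ---------------------------------------------------------------------------
# candidate regions

def find_candidate_regions(reads: pd.DataFrame, max_gap: int = 100) -> pd.DataFrame:
    """Maximal covered intervals whose internal uncovered gaps are all
    shorter than ``max_gap`` (a gap of max_gap or more splits), pooling
    reads over every library."""
    out = []
    for chrom, sub in reads.groupby("chrom", sort=True):
        iv = sub[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        cur_s, cur_e = int(iv[0, 0]), int(iv[0, 1])
        for s, e in iv[1:]:
            if int(s) - cur_e - 1 < max_gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# heuristic segmentation

def heuristic_segmentation(
    region: tuple[str, int, int],
    group_reads: pd.DataFrame,
    lib_sizes: Mapping[str, float],
    params: SegmentationParams | None = None,
) -> list[tuple[str, int, int]]:
    """Sub-intervals of one candidate region whose windowed RPKM within a
    replicate group meets the threshold, merged across sub-threshold gaps
    of at most ``max_gap`` nt.

    RPKM per base uses a moving window of ``rpkm_window`` nt:
    window count * 1e9 / (window * group library size), the group library
    size being the summed scaling factors of its libraries.
    """
    params = params or SegmentationParams()
    chrom, rs, re_ = region
    if len(group_reads) == 0:
        return []
    width = re_ - rs + 1
    starts = np.clip(group_reads["start"].to_numpy() - rs, 0, width - 1)
    ends = np.clip(group_reads["end"].to_numpy() - rs, 0, width - 1)
    counts = group_reads["count"].to_numpy().astype(float)
    # per-base coverage via a difference array
    diff = np.zeros(width + 1)
    np.add.at(diff, starts, counts)
    np.add.at(diff, ends + 1, -counts)
    cov = np.cumsum(diff)[:width]
    win = min(params.rpkm_window, width)
    kernel = np.ones(win)
    winsum = np.convolve(cov, kernel, mode="same")
    libsize = float(sum(lib_sizes[l] for l in group_reads["library_id"].unique()))
    if libsize <= 0:
        return []
    rpkm = winsum * 1e9 / (win * libsize)
    mask = (rpkm >= params.rpkm_threshold) & (winsum >= params.min_window_mass)
    if not mask.any():
        return []
    # runs of above-threshold bases
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_bounds = np.split(idx, breaks + 1)
    runs = [(int(r[0]), int(r[-1])) for r in run_bounds]
    # merge runs separated by sub-threshold gaps of at most max_gap
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 <= params.max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # trim each merged interval to its covered extent
    covered = np.flatnonzero(cov > 0)
    out = []
    for s, e in merged:
        inside = covered[(covered >= s) & (covered <= e)]
        if len(inside) == 0:
            continue
        out.append((chrom, rs + int(inside[0]), rs + int(inside[-1])))
    return out


def _assign_regions(reads: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Region index for each read (reads outside every region get -1)."""
    res = np.full(len(reads), -1, dtype=int)
    for chrom, ridx in regions.groupby("chrom", sort=False).groups.items():
        sub = regions.loc[ridx]
        rmask = (reads["chrom"] == chrom).to_numpy()
        if not rmask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pos = reads.loc[rmask, "start"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        vals = np.where(ok, np.asarray(ridx)[np.clip(j, 0, None)], -1)
        res[rmask] = vals
    return pd.Series(res, index=reads.index)


def candidate_loci(
    reads: pd.DataFrame,
    libraries: pd.DataFrame,
    sf: Mapping[str, float],
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Heuristic candidate loci: union over replicate groups, de-duplicated."""
    params = params or SegmentationParams()
    regions = find_candidate_regions(reads, params.max_gap)
    groups = libraries.groupby("replicate_group")["library_id"].apply(list)
    seen: set[tuple] = set()
    rows = []
    for group, libs in groups.items():
        greads = reads[reads["library_id"].isin(libs)]
        if len(greads) == 0:
            continue
        ridx = _assign_regions(greads, regions)
        for ri, sub in greads.groupby(ridx.to_numpy()):
            if ri < 0:
                continue
            region = (
                regions.at[ri, "chrom"],
                int(regions.at[ri, "start"]),
                int(regions.at[ri, "end"]),
            )
            for cand in heuristic_segmentation(region, sub, sf, params):
                if cand not in seen:
                    seen.add(cand)
                    rows.append(cand)
    cands = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return cands.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# posterior likelihood of expression

def _locus_library_counts(
    loci: pd.DataFrame, reads: pd.DataFrame, library_ids: Sequence[str]
) -> np.ndarray:
    """Redundant read counts overlapping each locus, per library."""
    lib_index = {l: i for i, l in enumerate(library_ids)}
    out = np.zeros((len(loci), len(library_ids)))
    reads = reads[reads["library_id"].isin(lib_index)]
    max_len = int((reads["end"] - reads["start"]).max()) + 1 if len(reads) else 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        rstart = sub["start"].to_numpy()
        rend = sub["end"].to_numpy()
        rcount = sub["count"].to_numpy().astype(float)
        rlib = sub["library_id"].map(lib_index).to_numpy()
        lmask = loci["chrom"] == chrom
        for i, (ls, le) in zip(
            np.flatnonzero(lmask.to_numpy()),
            loci.loc[lmask, ["start", "end"]].to_numpy(),
        ):
            lo = np.searchsorted(rstart, ls - max_len, side="left")
            hi = np.searchsorted(rstart, le, side="right")
            if hi <= lo:
                continue
            m = rend[lo:hi] >= ls
            np.add.at(out[i], rlib[lo:hi][m], rcount[lo:hi][m])
    return out


def _merge_intervals(loci: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals."""
    rows = []
    for chrom, sub in loci.groupby("chrom", sort=True):
        iv = sub[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        cur_s, cur_e = int(iv[0, 0]), int(iv[0, 1])
        for s, e in iv[1:]:
            if int(s) <= cur_e + 1:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _nb_logpmf(k: np.ndarray, mu: np.ndarray, size: float) -> np.ndarray:
    p = size / (size + mu)
    return stats.nbinom.logpmf(k, size, p)


def _posterior_given_model(
    counts: np.ndarray,
    mu0: np.ndarray,
    mu1: np.ndarray,
    group_cols: Mapping[str, np.ndarray],
    size: float,
    cycles: int,
) -> pd.DataFrame:
    """Posterior P(expressed) per locus per replicate group for fixed
    component means; the mixing proportion is re-estimated per group over
    ``cycles`` iterations.  Monotone non-decreasing in every count because
    both components share the NB dispersion and mu1 > mu0 everywhere."""
    loglr = _nb_logpmf(counts, mu1, size) - _nb_logpmf(counts, mu0, size)
    post = {}
    for group, cols in group_cols.items():
        llr = np.clip(loglr[:, cols].sum(axis=1), -700, 700)
        pi = 0.5
        p = np.empty(len(llr))
        for _ in range(cycles):
            p = 1.0 / (1.0 + (1.0 - pi) / pi * np.exp(-llr))
            pi = float(np.clip(p.mean(), 1e-4, 1 - 1e-4))
        post[group] = p
    return pd.DataFrame(post)


def posterior_expression_likelihood(
    loci: pd.DataFrame,
    reads: pd.DataFrame,
    libraries: pd.DataFrame,
    params: SegmentationParams | None = None,
    genome_span: float | None = None,
) -> pd.DataFrame:
    """Posterior probability that each locus is expressed in each replicate
    group.

    Counts at each locus are modelled as a two-component negative-binomial
    mixture per library: a background component with mean proportional to
    the library's out-of-locus read density, and an expressed component
    with mean proportional to the library's within-locus density.  The
    expressed density and the mixing proportion are refined over
    ``bootstrap_cycles`` re-estimation cycles, with loci weighted by their
    current posterior.  Per group, evidence multiplies over libraries.
    """
    params = params or SegmentationParams()
    libs = list(libraries["library_id"])
    counts = _locus_library_counts(loci, reads, libs)
    widths = (loci["end"] - loci["start"] + 1).to_numpy().astype(float)
    if genome_span is None:
        span = sum(
            float(sub["end"].max() - sub["start"].min() + 1)
            for _, sub in reads.groupby("chrom")
        )
    else:
        span = float(genome_span)
    total = reads.groupby("library_id")["count"].sum().reindex(libs).fillna(0).to_numpy()
    # candidates may be nested/overlapping (union over replicate groups):
    # estimate densities on the merged union so nothing is double-counted
    union = _merge_intervals(loci)
    union_width = float((union["end"] - union["start"] + 1).sum())
    in_union = _locus_library_counts(union, reads, libs).sum(axis=0)
    out_span = max(span - union_width, 0.01 * span)
    bg_density = (np.maximum(total - in_union, 0.0) + 1.0) / out_span
    mu0 = np.outer(widths, bg_density)

    group_cols = {
        str(g): np.array([libs.index(l) for l in sub["library_id"]])
        for g, sub in libraries.groupby("replicate_group", sort=True)
    }
    # initial expressed density over the union, then posterior-weighted
    theta0 = in_union / union_width
    w = np.ones(len(loci))
    post = None
    for cycle in range(params.bootstrap_cycles):
        if cycle == 0:
            theta = theta0
        else:
            denom = np.maximum((w[:, None] * widths[:, None]).sum(axis=0), 1.0)
            theta = (w[:, None] * counts).sum(axis=0) / denom
        # typical per-locus read total per library: count-weighted so it
        # tracks where the read mass is and is not diluted by a large
        # number of near-empty candidates
        wk = w[:, None] * counts
        mean_abundance = (wk * counts).sum(axis=0) / np.maximum(wk.sum(axis=0), 1.0)
        floor = params.abundance_floor * mean_abundance
        mu1 = np.maximum(widths[:, None] * theta[None, :], floor[None, :])
        mu1 = np.maximum(mu1, params.signal_floor * mu0)
        post = _posterior_given_model(
            counts, mu0, mu1, group_cols, params.nb_size, params.bootstrap_cycles
        )
        w = post.max(axis=1).to_numpy()
    post.index = loci.index
    return post


# ---------------------------------------------------------------------------
# selection, false positives, expression calls

def _fdr_prefix(p: np.ndarray, fdr: float) -> int:
    """Length of the largest descending-likelihood prefix whose mean
    (1 - likelihood) is at most ``fdr``."""
    order = np.argsort(-p, kind="stable")
    cummean = np.cumsum(1.0 - p[order]) / np.arange(1, len(p) + 1)
    ok = np.flatnonzero(cummean <= fdr)
    return 0 if len(ok) == 0 else int(ok[-1]) + 1


def select_loci(
    loci: pd.DataFrame,
    likelihoods: pd.DataFrame,
    fdr: float = 0.05,
    id_prefix: str = "ATSL",
    id_step: int = 10,
    min_expression: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select loci at the given per-group FDR and merge overlaps.

    Within each replicate group, loci are ordered by descending likelihood
    and the largest prefix whose mean (1 - likelihood) stays at or below
    ``fdr`` is retained.  A selected locus must additionally be more
    likely expressed than not (likelihood > ``min_expression``) in at
    least one group, so the prefix rule cannot spend its error budget on
    loci the model itself calls unexpressed everywhere.  The final map is
    the union over groups; overlapping selections are merged to their
    union interval, the merged likelihood per group being the maximum
    over members.  Locus ids are assigned in genomic order.
    """
    expressed_somewhere = set(
        likelihoods.index[(likelihoods > min_expression).any(axis=1)]
    )
    selected: set[int] = set()
    for g in likelihoods.columns:
        p = likelihoods[g].to_numpy().astype(float)
        order = np.argsort(-p, kind="stable")
        n = _fdr_prefix(p, fdr)
        selected.update(
            i for i in likelihoods.index[order[:n]] if i in expressed_somewhere
        )
    if not selected:
        empty = pd.DataFrame(columns=["locus_id", "chrom", "start", "end"])
        return empty, pd.DataFrame(columns=likelihoods.columns)
    sel = loci.loc[sorted(selected)].copy()
    sel_lik = likelihoods.loc[sel.index]
    # merge overlapping intervals
    merged_rows = []
    merged_lik = []
    for chrom, sub in sel.assign(_order=np.arange(len(sel))).groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur = None
        members: list = []
        for idx, row in sub.iterrows():
            if cur is None:
                cur = [chrom, int(row["start"]), int(row["end"])]
                members = [idx]
            elif int(row["start"]) <= cur[2]:
                cur[2] = max(cur[2], int(row["end"]))
                members.append(idx)
            else:
                merged_rows.append(tuple(cur))
                merged_lik.append(sel_lik.loc[members].max(axis=0))
                cur = [chrom, int(row["start"]), int(row["end"])]
                members = [idx]
        merged_rows.append(tuple(cur))
        merged_lik.append(sel_lik.loc[members].max(axis=0))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    lik = pd.DataFrame(merged_lik).reset_index(drop=True)
    # map-level FDR pass: the per-group unions each carry their own FDR
    # budget, which would accumulate junk across many groups; restrict the
    # final map so that the expected fraction of loci expressed in no
    # group (the quantity estimate_false_positives reports) stays at fdr
    q = (1.0 - lik).prod(axis=1).to_numpy()
    order_q = np.argsort(q, kind="stable")
    cummean = np.cumsum(q[order_q]) / np.arange(1, len(q) + 1)
    ok = np.flatnonzero(cummean <= fdr)
    keep = np.sort(order_q[: (int(ok[-1]) + 1) if len(ok) else 0])
    out = out.iloc[keep].reset_index(drop=True)
    lik = lik.iloc[keep].reset_index(drop=True)
    order = out.sort_values(["chrom", "start", "end"]).index
    out = out.loc[order].reset_index(drop=True)
    lik = lik.loc[order].reset_index(drop=True)
    ids = [f"{id_prefix}{(i + 1) * id_step:06d}" for i in range(len(out))]
    out.insert(0, "locus_id", ids)
    lik.index = pd.Index(ids, name="locus_id")
    return out, lik


def estimate_false_positives(likelihoods: pd.DataFrame) -> tuple[float, float]:
    """Expected number (and percentage) of selected loci that are expressed
    in no replicate group, assuming independence across groups:
    sum over loci of the product over groups of (1 - likelihood)."""
    if len(likelihoods) == 0:
        return 0.0, 0.0
    expected = float((1.0 - likelihoods).prod(axis=1).sum())
    return expected, 100.0 * expected / len(likelihoods)


def call_expression(likelihoods: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Boolean locus-by-group matrix: expressed iff likelihood strictly
    exceeds the cutoff."""
    return likelihoods > cutoff


# ---------------------------------------------------------------------------
# orchestrator

def segment(
    reads: pd.DataFrame,
    libraries: pd.DataFrame,
    params: SegmentationParams | None = None,
    exclusion_seqs: Iterable[str] = (),
    genome_span: float | None = None,
) -> SegmentationResult:
    """Run the full segmentation: filter, scale, find candidates, compute
    posteriors, select at FDR and estimate the false-positive burden."""
    params = params or SegmentationParams()
    fr = filter_reads(reads, exclusion_seqs, params)
    if len(fr) == 0:
        raise ValueError("no reads left after filtering")
    sf = scaling_factors(fr)
    cands = candidate_loci(fr, libraries, sf, params)
    if len(cands) == 0:
        empty = pd.DataFrame(columns=["locus_id", "chrom", "start", "end"])
        return SegmentationResult(empty, pd.DataFrame(), sf, 0.0, 0.0)
    lik = posterior_expression_likelihood(cands, fr, libraries, params, genome_span)
    loci, lik = select_loci(cands, lik, params.fdr)
    fp_count, fp_pct = estimate_false_positives(lik)
    return SegmentationResult(loci, lik, sf, fp_count, fp_pct)
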