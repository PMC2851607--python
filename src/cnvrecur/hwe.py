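"""Hardy-Weinberg equilibrium testing of common CNV regions.

Most common CNV regions in a healthy population are inherited, so their
integer copy numbers should behave like genotypes of a diallelic locus in
Hardy-Weinberg equilibrium (HWE).  Diallelic regions map directly:

* loss-type (copy numbers 0/1/2): 2 = reference homozygote,
  1 = heterozygote, 0 = minor-allele homozygote;
* gain-type (copy numbers 2/3/4): 2 = reference homozygote,
  3 = heterozygote, 4 = minor-allele homozygote.

Multi-allelic regions (both losses and gains observed, or copy numbers
outside the diallelic range) are excluded: unphased copy number is ambiguous
there because different allele combinations produce the same total count.

The fraction of diallelic regions that significantly depart from HWE (in at
least one population group, tested on unrelated samples only) is a quality
signal: thresholds for the recurrence statistics can be tuned by scanning a
grid and watching where the violation rate drops steepest.

The default HWE test is the conditional exact test on the heterozygote count
given the allele counts (two-sided, summing configurations no more probable
than the observed one) — appropriate for the small per-group sample sizes
typical of these studies.  An asymptotic 1-df chi-square test is available
as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma, log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import SampleGroups
from .recurrence import CommonRegion, find_composite_regions, find_cover_regions

logger = logging.getLogger("cnvrecur")

DIALLELIC_LOSS = "diallelic-loss"
DIALLELIC_GAIN = "diallelic-gain"
MULTIALLELIC = "multiallelic"

_LOSS_MAP = {2: "ref_hom", 1: "het", 0: "var_hom"}
_GAIN_MAP = {2: "ref_hom", 3: "het", 4: "var_hom"}


@dataclass(frozen=True)
class GenotypeCounts:
    """(reference homozygote, heterozygote, variant homozygote) counts."""

    n_ref_hom: int
    n_het: int
    n_var_hom: int

    def __post_init__(self):
        if min(self.n_ref_hom, self.n_het, self.n_var_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_var_hom

    @property
    def maf(self) -> float:
        """Minor-allele frequency (2*var_hom + het) / 2n, folded to [0, 0.5]."""
        if self.n == 0:
            return float("nan")
        q = (2 * self.n_var_hom + self.n_het) / (2 * self.n)
        return min(q, 1.0 - q)


@dataclass(frozen=True)
class RegionGenotypes:
    """Copy-number genotypes of all samples at one common region."""

    region_id: str
    copy_numbers: Mapping[str, int]
    allelicity: str  # diallelic-loss | diallelic-gain | multiallelic
    counts_by_group: Mapping[str, GenotypeCounts] = field(default_factory=dict)

    @property
    def diallelic(self) -> bool:
        return self.allelicity != MULTIALLELIC

    @property
    def maf_by_group(self) -> dict[str, float]:
        return {g: c.maf for g, c in self.counts_by_group.items()}


# ---------------------------------------------------------------------------
# Copy-number assignment
# ---------------------------------------------------------------------------

def assign_copy_numbers(region, calls: pd.DataFrame,
                        samples: Sequence[str]) -> dict[str, int]:
    """Integer copy number of each sample at a region.

    A sample's copy number is that of its supporting call covering the most
    bases of the region; ties go to the higher-confidence call, then the
    lower copy number.  Samples without a supporting call are diploid (2).
    """
    cn = {str(s): 2 for s in samples}
    if not region.supporting_calls:
        return cn
    sub = calls.loc[list(region.supporting_calls)]
    overlap = (np.minimum(sub["end_bp"], region.end_bp)
               - np.maximum(sub["start_bp"], region.start_bp) + 1)
    ranked = sub.assign(_ov=overlap).sort_values(
        ["_ov", "confidence", "copy_number"],
        ascending=[False, False, True], kind="mergesort")
    best = ranked.drop_duplicates("sample_id", keep="first")
    for sample, value in zip(best["sample_id"], best["copy_number"]):
        if sample in cn:
            cn[sample] = int(value)
    return cn


def genotype_region(region, calls: pd.DataFrame, samples: Sequence[str],
                    groups: SampleGroups | None = None) -> RegionGenotypes:
    """Genotype a region, classify its allelicity and count genotypes.

    Group-wise genotype counts are computed for diallelic regions only and
    are restricted to the unrelated members of each group.  With no `groups`
    every sample forms one "all" group (all treated as unrelated).
    """
    samples = [str(s) for s in samples]
    if groups is None:
        groups = SampleGroups.single_group(samples)
    cn = assign_copy_numbers(region, calls, samples)
    observed = set(cn.values())

    if observed <= {0, 1, 2} and observed != {2}:
        allelicity = DIALLELIC_LOSS
    elif observed <= {2, 3, 4} and observed != {2}:
        allelicity = DIALLELIC_GAIN
    elif observed == {2}:
        # monomorphic: no carrier left after assignment; direction follows
        # the region's own state class
        allelicity = (DIALLELIC_GAIN if getattr(region, "state_class", "loss")
                      == "gain" else DIALLELIC_LOSS)
    else:
        allelicity = MULTIALLELIC

    counts: dict[str, GenotypeCounts] = {}
    if allelicity != MULTIALLELIC:
        mapping = _GAIN_MAP if allelicity == DIALLELIC_GAIN else _LOSS_MAP
        for group in groups.group_labels:
            tally = {"ref_hom": 0, "het": 0, "var_hom": 0}
            for s in groups.unrelated_members(group):
                if s in cn:
                    tally[mapping[cn[s]]] += 1
            counts[group] = GenotypeCounts(tally["ref_hom"], tally["het"],
                                           tally["var_hom"])
    return RegionGenotypes(region_id=region.region_id, copy_numbers=cn,
                           allelicity=allelicity, counts_by_group=counts)


# ---------------------------------------------------------------------------
# HWE tests
# ---------------------------------------------------------------------------

def _exact_hwe_p(n_ref_hom: int, n_het: int, n_var_hom: int) -> float:
    """Conditional exact HWE test: two-sided p-value of the heterozygote
    count given the allele counts, summing P(h) <= P(observed)."""
    n = n_ref_hom + n_het + n_var_hom
    rare = 2 * min(n_ref_hom, n_var_hom) + n_het
    if rare == 0:
        return 1.0

    def logp(h: int) -> float:
        # log P(h heterozygotes | n, rare allele count), hypergeometric-type
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (lgamma(n + 1) - lgamma(hom_r + 1) - lgamma(h + 1)
                - lgamma(hom_c + 1) + h * log(2.0)
                + lgamma(rare + 1) + lgamma(2 * n - rare + 1)
                - lgamma(2 * n + 1))

    h_values = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = {h: logp(h) for h in h_values}
    obs = logs[n_het]
    p = sum(np.exp(lp) for lp in logs.values() if lp <= obs + 1e-10)
    return float(min(p, 1.0))


def _chisq_hwe_p(n_ref_hom: int, n_het: int, n_var_hom: int) -> float:
    from scipy.stats import chi2

    n = n_ref_hom + n_het + n_var_hom
    q = (2 * n_var_hom + n_het) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    observed = np.array([n_ref_hom, n_het, n_var_hom])
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def hwe_test(counts: GenotypeCounts, method: str = "exact") -> float:
    """p-value of the Hardy-Weinberg test for one genotype-count triple.

    Monomorphic counts (no copy of the minor allele) return p = 1 by
    convention.  ``method`` is 'exact' (conditional exact test, default) or
    'chisq' (1-df asymptotic test).
    """
    if counts.n < 1:
        raise ValueError("need at least one genotyped sample")
    if method == "exact":
        return _exact_hwe_p(counts.n_ref_hom, counts.n_het, counts.n_var_hom)
    if method == "chisq":
        return _chisq_hwe_p(counts.n_ref_hom, counts.n_het, counts.n_var_hom)
    raise ValueError(f"unknown HWE test method {method!r}")


def region_hwe_pvalues(rg: RegionGenotypes,
                       method: str = "exact") -> dict[str, float]:
    """Per-group HWE p-values for one diallelic region (empty groups skipped)."""
    return {g: hwe_test(c, method) for g, c in rg.counts_by_group.items()
            if c.n >= 1}


def violation_rate(region_genotypes: Iterable[RegionGenotypes],
                   alpha: float = 0.01, method: str = "exact") -> float:
    """Fraction of diallelic regions with HWE p < alpha in >= 1 group.

    Multi-allelic regions are excluded; raises if no diallelic region is
    available (the rate is then undefined).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    diallelic = [rg for rg in region_genotypes if rg.diallelic]
    if not diallelic:
        raise ValueError("no diallelic regions: violation rate undefined")
    violating = sum(
        any(p < alpha for p in region_hwe_pvalues(rg, method).values())
        for rg in diallelic)
    return violating / len(diallelic)


# ---------------------------------------------------------------------------
# Threshold tuning
# ---------------------------------------------------------------------------

def _summarise_grid_point(regions: list[CommonRegion], calls: pd.DataFrame,
                          samples: Sequence[str], groups: SampleGroups,
                          alpha: float, method: str) -> dict:
    row = {"n_regions": len(regions), "violation_rate": np.nan,
           "mean_maf": np.nan, "median_size_kb": np.nan}
    if not regions:
        return row
    genos = [genotype_region(r, calls, samples, groups) for r in regions]
    diallelic = [g for g in genos if g.diallelic]
    if diallelic:
        row["violation_rate"] = violation_rate(diallelic, alpha, method)
        mafs = []
        for g in diallelic:
            pooled = GenotypeCounts(
                sum(c.n_ref_hom for c in g.counts_by_group.values()),
                sum(c.n_het for c in g.counts_by_group.values()),
                sum(c.n_var_hom for c in g.counts_by_group.values()))
            if pooled.n:
                mafs.append(pooled.maf)
        row["mean_maf"] = float(np.mean(mafs)) if mafs else np.nan
    row["median_size_kb"] = float(np.median([r.size_kb for r in regions]))
    return row


def tune_thresholds(calls: pd.DataFrame, probes, groups: SampleGroups,
                    grid: Sequence, method: str = "cover",
                    alpha: float = 0.01, hwe_method: str = "exact",
                    state_handling: str = "separate",
                    n_samples: int | None = None) -> pd.DataFrame:
    """Scan a threshold grid and tabulate quality summaries per grid point.

    Parameters
    ----------
    grid
        For ``method='cover'``: a sequence of ``(confidence percentile, u)``
        pairs.  For ``method='composite'``: a sequence of score percentiles.
    groups
        Sample grouping; HWE is tested per group on unrelated samples.

    Returns
    -------
    DataFrame with one row per grid point: the setting, n_regions,
    violation_rate, mean_maf, median_size_kb, and a ``steepest_drop`` flag
    on the point after which the violation rate's first difference is most
    negative (the tuning heuristic: prefer thresholds beyond the steepest
    drop in HWE violations).
    """
    if len(grid) == 0:
        raise ValueError("empty tuning grid")
    samples = sorted(set(calls["sample_id"]) | set(groups.group_of))
    if n_samples is None:
        n_samples = len(samples)
    rows = []
    for point in grid:
        if method == "cover":
            pct, u = point
            regions = find_cover_regions(
                calls, probes, conf_percentile=pct, min_individuals=int(u),
                state_handling=state_handling, n_samples=n_samples)
            setting = {"conf_percentile": float(pct), "min_individuals": int(u)}
        elif method == "composite":
            regions, v = find_composite_regions(
                calls, probes, score_percentile=float(point),
                state_handling=state_handling, n_samples=n_samples)
            setting = {"score_percentile": float(point), "threshold_v": v}
        else:
            raise ValueError(f"unknown tuning method {method!r}")
        row = dict(setting)
        row.update(_summarise_grid_point(regions, calls, samples, groups,
                                         alpha, hwe_method))
        rows.append(row)
    table = pd.DataFrame(rows)
    table["steepest_drop"] = False
    vr = table["violation_rate"].to_numpy(dtype=float)
    if len(vr) > 1:
        diffs = np.diff(vr)
        if np.isfinite(diffs).any():
            i = int(np.nanargmin(diffs))
            if diffs[i] < 0:
                table.loc[i, "steepest_drop"] = True
    return table
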