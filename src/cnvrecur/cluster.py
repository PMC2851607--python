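"""Refinement of common regions into subregions (hierarchical clustering).

A common region discovered by the recurrence statistics often covers a
mixture of two or more partially overlapping event clusters — different
subsets of individuals whose calls pile up on different parts of the region.
To resolve these, the supporting calls are compared pairwise *within* the
common region: for calls A and B and a region of length L bases, the overlap
pattern reduces to four base counts (a, b, c, d) where ``a`` is covered by
both, ``b`` only by A, ``c`` only by B and ``d = L - a - b - c`` by neither.
The Jaccard similarity ``a / (a + b + c)`` is the fraction of the union of
the two footprints that they share; its complement is the dissimilarity fed
to agglomerative clustering.  Cutting the dendrogram so that members of a
cluster are at least ``cluster_limit`` similar (cut height
``1 - cluster_limit``) yields the subregions.  Each subregion spans the
min/max extent of its member calls, clipped back to the parent region's
boundaries when a member extends past them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io_model import region_size_kb
from .recurrence import CommonRegion

LINKAGES = ("complete", "single", "average")


@dataclass(frozen=True)
class PairOverlap:
    """Base-count summary of two calls' overlap within a common region."""

    a: int  # bases where both calls overlap the region
    b: int  # bases only the first call overlaps
    c: int  # bases only the second call overlaps
    d: int  # remaining region bases
    L: int  # region length in bases

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.a + self.b + self.c + self.d != self.L:
            raise ValueError("overlap counts must sum to the region length")


@dataclass(frozen=True)
class SubRegion:
    """A cluster of supporting calls within a parent common region.

    Boundaries are the min/max positions of the member calls, clipped to the
    parent region; summary statistics are recomputed on the members.
    """

    region_id: str
    parent_id: str
    chromosome: str
    state_class: str
    start_bp: int
    end_bp: int
    supporting_calls: tuple
    supporting_samples: tuple
    n_total_samples: int
    frequency: float
    median_confidence: float
    size_kb: float


def _span(interval) -> tuple[int, int]:
    if hasattr(interval, "start_bp"):
        return int(interval.start_bp), int(interval.end_bp)
    if isinstance(interval, (pd.Series, dict)):
        return int(interval["start_bp"]), int(interval["end_bp"])
    s, e = interval
    return int(s), int(e)


def _inclusive_len(start: int, end: int) -> int:
    return max(0, end - start + 1)


def pair_overlap(call_a, call_b, region) -> PairOverlap:
    """(a, b, c, d) base counts for two calls within a common region.

    All coordinates are 1-based inclusive; each call must overlap the region
    (callers pre-filter to supporting calls).
    """
    rs, re = _span(region)
    L = _inclusive_len(rs, re)
    sa, ea = _span(call_a)
    sb, eb = _span(call_b)
    # footprints inside the region
    fa = (max(sa, rs), min(ea, re))
    fb = (max(sb, rs), min(eb, re))
    la = _inclusive_len(*fa)
    lb = _inclusive_len(*fb)
    if la == 0 or lb == 0:
        raise ValueError("both calls must overlap the common region")
    a = _inclusive_len(max(fa[0], fb[0]), min(fa[1], fb[1]))
    b = la - a
    c = lb - a
    return PairOverlap(a=a, b=b, c=c, d=L - a - b - c, L=L)


def jaccard_dissimilarity(po: PairOverlap) -> float:
    """1 - a/(a+b+c): complement of the Jaccard similarity of the two
    footprints within the region.  Symmetric in b and c."""
    denom = po.a + po.b + po.c
    if denom == 0:
        raise ValueError("a + b + c = 0: calls do not overlap the region")
    return 1.0 - po.a / denom


def dissimilarity_matrix(members: pd.DataFrame, region) -> np.ndarray:
    """Symmetric pairwise Jaccard dissimilarity matrix of supporting calls."""
    n = len(members)
    mat = np.zeros((n, n))
    rows = list(members.itertuples())
    for i in range(n):
        for j in range(i + 1, n):
            po = pair_overlap(rows[i], rows[j], region)
            mat[i, j] = mat[j, i] = jaccard_dissimilarity(po)
    return mat


def _member_order(members: pd.DataFrame) -> pd.DataFrame:
    # fixed member ordering makes the scipy agglomeration (and hence any
    # equal-height tie-break) deterministic across runs and platforms
    return members.sort_values(["start_bp", "end_bp", "sample_id"],
                               kind="mergesort")


def refine_region(region: CommonRegion, calls: pd.DataFrame,
                  linkage: str = "complete",
                  cluster_limit: float = 0.6) -> list[SubRegion]:
    """Split a common region into subregions by clustering its supporting
    calls.

    Parameters
    ----------
    region
        Parent common region.
    calls
        The call table the region's ``supporting_calls`` index into.
    linkage
        'complete' (default), 'single' or 'average'.
    cluster_limit
        Required within-cluster similarity in [0, 1]; the dendrogram is cut
        at height ``1 - cluster_limit`` (default 0.6: members of a subregion
        are at least 60% similar).

    Returns
    -------
    list of SubRegion in genomic order; the member sets partition the
    parent's supporting calls.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if not 0 <= cluster_limit <= 1:
        raise ValueError("cluster_limit must lie in [0, 1]")
    if not region.supporting_calls:
        raise ValueError("region has no supporting calls")
    members = _member_order(calls.loc[list(region.supporting_calls)])
    n = len(members)
    if n == 1:
        labels = np.array([1])
    else:
        mat = dissimilarity_matrix(members, region)
        z = scipy_linkage(squareform(mat, checks=False), method=linkage)
        labels = fcluster(z, t=1.0 - cluster_limit, criterion="distance")

    subs = []
    for lab in np.unique(labels):
        grp = members[labels == lab]
        start = max(int(grp["start_bp"].min()), region.start_bp)
        end = min(int(grp["end_bp"].max()), region.end_bp)
        samples = tuple(sorted(set(grp["sample_id"])))
        subs.append(SubRegion(
            region_id="",  # assigned after genomic ordering below
            parent_id=region.region_id,
            chromosome=region.chromosome,
            state_class=region.state_class,
            start_bp=start, end_bp=end,
            supporting_calls=tuple(int(i) for i in grp.index),
            supporting_samples=samples,
            n_total_samples=region.n_total_samples,
            frequency=(len(samples) / region.n_total_samples
                       if region.n_total_samples else float("nan")),
            median_confidence=float(np.median(grp["confidence"].to_numpy())),
            size_kb=region_size_kb(start, end),
        ))
    subs.sort(key=lambda s: (s.start_bp, s.end_bp))
    return [replace(s, region_id=f"{region.region_id}.{k + 1}")
            for k, s in enumerate(subs)]


def refine_regions(regions: Sequence[CommonRegion], calls: pd.DataFrame,
                   linkage: str = "complete",
                   cluster_limit: float = 0.6) -> list[SubRegion]:
    """Apply :func:`refine_region` to every region, concatenating results."""
    out: list[SubRegion] = []
    for region in regions:
        out.extend(refine_region(region, calls, linkage, cluster_limit))
    return out
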