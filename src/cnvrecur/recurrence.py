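"""Per-probe recurrence statistics and common-region extraction.

Two per-probe statistics summarise how consistently a probe is hit by CNV
calls across individuals:

* **COVER** ``y_k``: the number of calls with confidence score >= a cutoff
  ``c`` whose interval contains probe ``k``.  Common regions are maximal runs
  of consecutive probes with ``y_k >= u`` (minimum number of individuals).
* **COMPOSITE** ``s_k``: the sum of confidence scores of *all* calls
  containing probe ``k`` — every call contributes, weighted by how reliable
  it is.  Common regions are maximal runs with ``s_k >= v``.

With all confidences equal to 1 and ``c = 0`` the two statistics coincide,
and region extraction at ``v = u`` reproduces COVER exactly.

Cutoffs may be given directly or resolved as percentiles: ``c`` against the
pooled confidence scores of all calls, ``v`` against the pooled per-probe
composite scores (zeros included).  Percentiles use linear interpolation
between order statistics throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import ProbeMap, region_size_kb

logger = logging.getLogger("cnvrecur")

STATE_CLASSES = ("loss", "gain", "combined")


@dataclass(frozen=True)
class ProbeTrack:
    """Per-probe statistic values for one chromosome and one state class."""

    chromosome: str
    state_class: str   # 'loss' | 'gain' | 'combined'
    kind: str          # 'cover' | 'composite'
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.state_class not in STATE_CLASSES:
            raise ValueError(f"unknown state class {self.state_class!r}")
        if self.kind not in ("cover", "composite"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if np.any(vals < 0):
            raise ValueError("track values must be non-negative")
        if self.kind == "cover" and not np.allclose(vals, np.round(vals)):
            raise ValueError("cover track values must be integer counts")


@dataclass(frozen=True)
class CommonRegion:
    """A recurrent CNV region: a maximal run of consecutive probes whose
    statistic stays at or above threshold.

    ``supporting_calls`` holds index labels into the call table of every
    qualifying call (state-matched and, for COVER, confidence-filtered) that
    overlaps at least one probe of the run; ``frequency`` is the number of
    distinct supporting samples over the total number of samples studied.
    Region bp boundaries are the positions of the run's first and last probe.
    """

    region_id: str
    chromosome: str
    state_class: str
    first_probe: int
    last_probe: int
    start_bp: int
    end_bp: int
    supporting_calls: tuple
    supporting_samples: tuple
    n_total_samples: int
    frequency: float
    median_confidence: float
    size_kb: float


@dataclass(frozen=True)
class AnalysisConfig:
    """Threshold settings for a COVER or COMPOSITE analysis.

    Exactly one of the cutoff/percentile pair should be set for the relevant
    statistic; ``state_handling`` chooses whether losses and gains are
    analysed as separate tracks (default) or pooled into one.
    """

    confidence_cutoff: float | None = None
    confidence_percentile: float | None = None
    min_individuals: int = 1
    composite_cutoff: float | None = None
    composite_percentile: float | None = None
    state_handling: str = "separate"

    def __post_init__(self):
        if self.min_individuals < 1:
            raise ValueError("min_individuals must be >= 1")
        for p in (self.confidence_percentile, self.composite_percentile):
            if p is not None and not 0 <= p <= 100:
                raise ValueError("percentiles must lie in [0, 100]")
        if self.state_handling not in ("separate", "combined"):
            raise ValueError("state_handling must be 'separate' or 'combined'")


# ---------------------------------------------------------------------------
# Threshold resolution
# ---------------------------------------------------------------------------

def resolve_confidence_cutoff(calls: pd.DataFrame, percentile: float) -> float:
    """Percentile of the pooled confidence scores of all calls.

    Linear interpolation between order statistics; percentile 0 returns the
    minimum, so filtering at percentile 0 keeps every call.
    """
    if len(calls) == 0:
        raise ValueError("cannot resolve a confidence percentile on an empty call set")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(calls["confidence"].to_numpy(), percentile))


def resolve_composite_threshold(tracks: Iterable[ProbeTrack],
                                percentile: float) -> float:
    """Percentile of the pooled per-probe composite scores, zeros included.

    Uses the lower order statistic (no interpolation): most probes carry no
    call and score 0, and any percentile at or below that zero fraction must
    resolve to a threshold of exactly 0 — the "no filtering" regime in which
    every covered probe passes.  Interpolating between order statistics
    would instead leak a small positive threshold on short pools.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no composite tracks supplied")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    pooled = np.concatenate([t.values for t in tracks])
    return float(np.percentile(pooled, percentile, method="lower"))


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

def select_calls(calls: pd.DataFrame, state_class: str = "combined",
                 min_confidence: float | None = None) -> pd.DataFrame:
    """Subset calls by state class and (optionally) confidence >= cutoff."""
    out = calls
    if state_class != "combined":
        out = out[out["state"] == state_class]
    if min_confidence is not None:
        out = out[out["confidence"] >= min_confidence]
    return out


def _warn_same_sample_overlaps(calls: pd.DataFrame) -> None:
    # two qualifying calls of one sample overlapping the same probe each
    # contribute to y_k / s_k; flag so the user knows the count can exceed
    # the number of samples
    for (sample, chrom), grp in calls.groupby(["sample_id", "chromosome"],
                                              sort=False):
        if len(grp) < 2:
            continue
        g = grp.sort_values("start_bp")
        if (g["end_bp"].to_numpy()[:-1] >= g["start_bp"].to_numpy()[1:]).any():
            logger.warning("sample %s has overlapping calls on chromosome %s; "
                           "each contributes separately to the per-probe "
                           "statistics", sample, chrom)


def _accumulate(calls: pd.DataFrame, positions: np.ndarray,
                weights: np.ndarray) -> np.ndarray:
    """Sum `weights` of the calls over the probes each call contains."""
    out = np.zeros(positions.size + 1)
    if len(calls):
        lo = np.searchsorted(positions, calls["start_bp"].to_numpy(), "left")
        hi = np.searchsorted(positions, calls["end_bp"].to_numpy(), "right")
        keep = lo < hi
        np.add.at(out, lo[keep], weights[keep])
        np.add.at(out, hi[keep], -weights[keep])
    # cancellation in the +/- cumulative sum can leave tiny negatives
    return np.maximum(np.cumsum(out[:-1]), 0.0)


def _build_tracks(calls: pd.DataFrame, probes: ProbeMap, kind: str,
                  state_class: str, unit_weights: bool) -> dict[str, ProbeTrack]:
    absent = sorted(set(calls["chromosome"]) - set(probes.chromosomes), key=str)
    if absent:
        raise ValueError(f"calls on chromosome(s) {absent} absent from the "
                         f"probe map")
    _warn_same_sample_overlaps(calls)
    tracks = {}
    for chrom in probes.chromosomes:
        pos = probes.positions(chrom)
        sub = calls[calls["chromosome"] == chrom]
        w = (np.ones(len(sub)) if unit_weights
             else sub["confidence"].to_numpy(dtype=float))
        values = _accumulate(sub, pos, w)
        if kind == "cover":
            values = np.round(values)
        tracks[chrom] = ProbeTrack(chrom, state_class, kind, values)
    return tracks


def cover_track(calls: pd.DataFrame, probes: ProbeMap, c: float = 0.0,
                state_class: str = "combined") -> dict[str, ProbeTrack]:
    """COVER statistic ``y_k`` per probe, one track per chromosome.

    ``y_k`` counts the calls of the requested state class with confidence
    >= ``c`` whose interval [start_bp, end_bp] contains probe ``k``.
    """
    qualifying = select_calls(calls, state_class, min_confidence=c)
    return _build_tracks(qualifying, probes, "cover", state_class,
                         unit_weights=True)


def composite_track(calls: pd.DataFrame, probes: ProbeMap,
                    state_class: str = "combined") -> dict[str, ProbeTrack]:
    """COMPOSITE statistic ``s_k`` per probe: summed confidence scores of all
    calls of the state class containing probe ``k``."""
    qualifying = select_calls(calls, state_class)
    return _build_tracks(qualifying, probes, "composite", state_class,
                         unit_weights=False)


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def _runs_at_or_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive indices with value >= threshold (and > 0)."""
    mask = (values >= threshold) & (values > 0)
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def extract_regions(track: ProbeTrack, threshold: float, probes: ProbeMap,
                    calls: pd.DataFrame, n_samples: int | None = None) -> list[CommonRegion]:
    """Extract common regions from one per-probe track.

    Parameters
    ----------
    track
        Track for a single chromosome.
    threshold
        ``u`` (COVER) or ``v`` (COMPOSITE).  A probe passes when its value is
        >= the threshold *and* positive, so a resolved threshold of 0 selects
        every probe covered by at least one call.
    calls
        The qualifying calls that built the track (same state class and, for
        COVER, the same confidence filter).  Supporting calls of a region are
        the qualifying calls overlapping at least one probe of its run.
    n_samples
        Total number of samples studied (denominator of the region
        frequency); defaults to the number of distinct samples in `calls`.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    pos = probes.positions(track.chromosome)
    if track.values.size != pos.size:
        raise ValueError("track length does not match the probe map")
    if n_samples is None:
        n_samples = int(calls["sample_id"].nunique())
    chrom_calls = calls[calls["chromosome"] == track.chromosome]
    starts = chrom_calls["start_bp"].to_numpy()
    ends = chrom_calls["end_bp"].to_numpy()
    first_cov = np.searchsorted(pos, starts, "left")  # first probe >= call start

    regions = []
    for i, j in _runs_at_or_above(track.values, threshold):
        lo = np.maximum(first_cov, i)
        supp = (lo <= j) & (pos[np.minimum(lo, pos.size - 1)] <= ends)
        members = chrom_calls.index[supp]
        samples = tuple(sorted(set(chrom_calls.loc[members, "sample_id"])))
        confs = chrom_calls.loc[members, "confidence"].to_numpy()
        start_bp, end_bp = int(pos[i]), int(pos[j])
        regions.append(CommonRegion(
            region_id=f"{track.chromosome}:{start_bp}-{end_bp}:{track.state_class}",
            chromosome=track.chromosome,
            state_class=track.state_class,
            first_probe=int(i), last_probe=int(j),
            start_bp=start_bp, end_bp=end_bp,
            supporting_calls=tuple(int(m) for m in members),
            supporting_samples=samples,
            n_total_samples=int(n_samples),
            frequency=len(samples) / n_samples if n_samples else float("nan"),
            median_confidence=float(np.median(confs)) if confs.size else float("nan"),
            size_kb=region_size_kb(start_bp, end_bp),
        ))
    return regions


def _sorted_regions(regions: list[CommonRegion]) -> list[CommonRegion]:
    return sorted(regions, key=lambda r: (int(r.chromosome), r.first_probe,
                                          r.state_class))


def _state_classes(state_handling: str) -> tuple[str, ...]:
    return ("combined",) if state_handling == "combined" else ("loss", "gain")


def find_cover_regions(calls: pd.DataFrame, probes: ProbeMap | None = None,
                       conf_cutoff: float | None = None,
                       conf_percentile: float | None = None,
                       min_individuals: int = 1,
                       state_handling: str = "separate",
                       n_samples: int | None = None) -> list[CommonRegion]:
    """Full COVER pipeline: resolve ``c``, build tracks, extract regions.

    Exactly one of `conf_cutoff` / `conf_percentile` may be given; with
    neither, no confidence filtering is applied (``c`` = 0 behaviour).
    """
    if conf_cutoff is not None and conf_percentile is not None:
        raise ValueError("give either conf_cutoff or conf_percentile, not both")
    if probes is None:
        probes = ProbeMap.from_calls(calls)
    if conf_percentile is not None:
        conf_cutoff = resolve_confidence_cutoff(calls, conf_percentile)
    if n_samples is None:
        n_samples = int(calls["sample_id"].nunique())
    regions = []
    for sc in _state_classes(state_handling):
        qualifying = select_calls(calls, sc, min_confidence=conf_cutoff)
        tracks = _build_tracks(qualifying, probes, "cover", sc, unit_weights=True)
        for chrom in probes.chromosomes:
            regions.extend(extract_regions(tracks[chrom], float(min_individuals),
                                           probes, qualifying, n_samples))
    return _sorted_regions(regions)


def find_composite_regions(calls: pd.DataFrame, probes: ProbeMap | None = None,
                           score_cutoff: float | None = None,
                           score_percentile: float | None = None,
                           state_handling: str = "separate",
                           n_samples: int | None = None
                           ) -> tuple[list[CommonRegion], float]:
    """Full COMPOSITE pipeline; returns (regions, resolved threshold v).

    When ``score_percentile`` is given, ``v`` is resolved against the pooled
    per-probe composite scores of every track analysed, zeros included.
    """
    if score_cutoff is not None and score_percentile is not None:
        raise ValueError("give either score_cutoff or score_percentile, not both")
    if probes is None:
        probes = ProbeMap.from_calls(calls)
    if n_samples is None:
        n_samples = int(calls["sample_id"].nunique())
    per_class = {}
    for sc in _state_classes(state_handling):
        qualifying = select_calls(calls, sc)
        per_class[sc] = (qualifying,
                         _build_tracks(qualifying, probes, "composite", sc,
                                       unit_weights=False))
    if score_percentile is not None:
        all_tracks = [t for _, tr in per_class.values() for t in tr.values()]
        score_cutoff = resolve_composite_threshold(all_tracks, score_percentile)
    v = 0.0 if score_cutoff is None else float(score_cutoff)
    regions = []
    for sc, (qualifying, tracks) in per_class.items():
        for chrom in probes.chromosomes:
            regions.extend(extract_regions(tracks[chrom], v, probes,
                                           qualifying, n_samples))
    return _sorted_regions(regions), v


def regions_from_frame(df: pd.DataFrame) -> list:
    """Rebuild CommonRegion/SubRegion objects from a region table frame.

    Rows with a non-empty ``parent_id`` become SubRegions (probe indices are
    not meaningful for them and are carried as -1).
    """
    from .cluster import SubRegion  # local import: cluster depends on us

    out = []
    for _, row in df.iterrows():
        calls = tuple(int(x) for x in str(row["supporting_calls"]).split(",") if x)
        samples = tuple(x for x in str(row["supporting_samples"]).split(",") if x)
        common = dict(
            region_id=row["region_id"], chromosome=str(row["chromosome"]),
            state_class=row["state_class"],
            start_bp=int(row["start_bp"]), end_bp=int(row["end_bp"]),
            supporting_calls=calls, supporting_samples=samples,
            n_total_samples=int(row["n_total_samples"]),
            frequency=float(row["frequency"]),
            median_confidence=float(row["median_confidence"]),
            size_kb=float(row["size_kb"]),
        )
        if str(row.get("parent_id", "") or ""):
            out.append(SubRegion(parent_id=str(row["parent_id"]), **common))
        else:
            out.append(CommonRegion(first_probe=int(row["first_probe"]),
                                    last_probe=int(row["last_probe"]), **common))
    return out
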