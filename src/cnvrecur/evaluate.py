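"""Concordance evaluation against reference CNV lists and region summaries.

A discovered region is *concordant* with a reference CNV when it is entirely
contained within the reference interval, or when their overlap covers at
least 50% of the reference interval.  Note the 50% is a fraction of the
REFERENCE region — not a reciprocal-overlap criterion, which is what most
interval toolkits default to.

Per-sample discordance is evaluated on the regions attributed to that sample
(a region is attributed to every sample among its supporting calls): the
discordance rate is the fraction of those regions concordant with none of
the sample's reference CNVs.  The same concordance rule also drives
method-versus-method comparisons of two region sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cnvrecur")


def _fields(obj) -> tuple[str, int, int, str]:
    """(chromosome, start, end, type/state) from a region-like object."""
    if hasattr(obj, "chromosome"):
        kind = getattr(obj, "state_class", None) or getattr(obj, "type", "unknown")
        return (str(obj.chromosome), int(obj.start_bp), int(obj.end_bp), kind)
    if isinstance(obj, (pd.Series, dict)):
        kind = obj.get("state_class", obj.get("type", "unknown")) or "unknown"
        return (str(obj["chromosome"]), int(obj["start_bp"]),
                int(obj["end_bp"]), kind)
    chrom, start, end = obj[:3]
    return (str(chrom), int(start), int(end), "unknown")


def _types_compatible(region_type: str, ref_type: str) -> bool:
    if "unknown" in (region_type, ref_type) or "combined" in (region_type,):
        return True
    return region_type == ref_type


def is_concordant(region, reference, match_type: bool = False) -> bool:
    """True iff `region` is contained in `reference` or their overlap covers
    at least 50% of the reference (1-based inclusive base counts).

    Different chromosomes give False.  With ``match_type``, loss/gain must
    agree unless either side's type is unknown (or the region pools states).
    """
    rc, rs, re, rkind = _fields(region)
    fc, fs, fe, fkind = _fields(reference)
    if rc != fc:
        return False
    if match_type and not _types_compatible(rkind, fkind):
        return False
    if fs <= rs and re <= fe:
        return True
    overlap = min(re, fe) - max(rs, fs) + 1
    ref_len = fe - fs + 1
    return overlap >= 0.5 * ref_len


def discordance_rate(sample_regions: Sequence, sample_reference: Sequence,
                     match_type: bool = False) -> float:
    """Fraction of a sample's regions concordant with none of its reference
    CNVs.  Empty region set -> NaN (undefined); empty reference -> 1.0."""
    regions = list(sample_regions)
    references = list(sample_reference)
    if not regions:
        return float("nan")
    if not references:
        logger.warning("empty reference CNV list: every region is discordant")
        return 1.0
    concordant = sum(
        any(is_concordant(r, ref, match_type) for ref in references)
        for r in regions)
    return (len(regions) - concordant) / len(regions)


def concordance_report(regions: Sequence, reference: pd.DataFrame,
                       match_type: bool = False) -> pd.DataFrame:
    """Per-sample concordance of discovered regions with reference CNVs.

    Parameters
    ----------
    regions
        CommonRegion/SubRegion objects (must carry ``supporting_samples``).
    reference
        Reference CNV table with columns ``sample_id, chromosome, start_bp,
        end_bp, type`` — only samples present here are evaluated.

    Returns
    -------
    DataFrame with one row per reference sample: ``sample_id,
    n_regions_evaluated, n_concordant, discordance_rate`` (rate is NaN for
    samples supporting no region).
    """
    rows = []
    for sample, refs in reference.groupby("sample_id", sort=True):
        mine = [r for r in regions if sample in r.supporting_samples]
        ref_rows = list(refs.itertuples())
        n_conc = sum(any(is_concordant(r, ref, match_type) for ref in ref_rows)
                     for r in mine)
        rate = (len(mine) - n_conc) / len(mine) if mine else float("nan")
        rows.append({"sample_id": sample, "n_regions_evaluated": len(mine),
                     "n_concordant": n_conc, "discordance_rate": rate})
    return pd.DataFrame(rows, columns=["sample_id", "n_regions_evaluated",
                                       "n_concordant", "discordance_rate"])


def mean_discordance(report: pd.DataFrame) -> float:
    """Mean per-sample discordance rate, ignoring undefined samples."""
    return float(np.nanmean(report["discordance_rate"].to_numpy(dtype=float)))


def summarize_regions(regions: Sequence) -> dict:
    """Summary statistics of a region set.

    Returns n_regions, mean_frequency, median_confidence (median across
    regions of each region's median supporting-call confidence), mean and
    median size in kb.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("cannot summarise an empty region set")
    freqs = np.array([r.frequency for r in regions], dtype=float)
    confs = np.array([r.median_confidence for r in regions], dtype=float)
    sizes = np.array([r.size_kb for r in regions], dtype=float)
    return {
        "n_regions": len(regions),
        "mean_frequency": float(np.mean(freqs)),
        "median_confidence": float(np.median(confs)),
        "mean_size_kb": float(np.mean(sizes)),
        "median_size_kb": float(np.median(sizes)),
    }


def cross_method_concordance(regions_a: Sequence, regions_b: Sequence,
                             match_type: bool = False
                             ) -> tuple[np.ndarray, pd.DataFrame]:
    """Partition `regions_a` by concordance with any region of `regions_b`.

    Returns the boolean concordance flag per region of `regions_a` and a
    two-row summary table (concordant vs not): n regions, mean frequency,
    median confidence — the layout used for method-to-method comparisons.
    """
    regions_a = list(regions_a)
    regions_b = list(regions_b)
    flags = np.array([any(is_concordant(ra, rb, match_type) for rb in regions_b)
                      for ra in regions_a], dtype=bool)
    rows = []
    for label, keep in (("concordant", flags), ("discordant", ~flags)):
        grp = [r for r, k in zip(regions_a, keep) if k]
        rows.append({
            "overlap": label,
            "n_regions": len(grp),
            "mean_frequency": (float(np.mean([r.frequency for r in grp]))
                               if grp else np.nan),
            "median_confidence": (float(np.median([r.median_confidence
                                                   for r in grp]))
                                  if grp else np.nan),
        })
    return flags, pd.DataFrame(rows)
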