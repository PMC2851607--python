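"""Domain model and I/O for segmented copy-number-variant (CNV) call tables.

The package operates on *segmented* data: per-individual CNV calls produced by
an upstream detection algorithm (typically an HMM caller running on SNP-array
intensities), each call carrying an integer copy number and a confidence score
such as a log Bayes factor.  This module defines the tabular conventions,
validation rules and readers/writers shared by the analysis modules.

Conventions
-----------
* Positions are 1-based and intervals are inclusive on both ends (the
  convention of common SNP-array CNV callers).  BED export converts to
  0-based half-open coordinates: ``bed_start = start_bp - 1``,
  ``bed_end = end_bp``.
* Only autosomes ("1".."22", with or without a "chr" prefix) are analysed;
  calls on other chromosomes are dropped with a logged count.  The diallelic
  Hardy-Weinberg machinery downstream assumes diploidy.
* A call is an aberration: copy number 2 rows are rejected (with a warning).
* Region sizes are reported in kb as ``(end_bp - start_bp) / 1000`` rounded
  to one decimal.

Calls are held in a :class:`pandas.DataFrame` with canonical columns
``sample_id, chromosome, start_bp, end_bp, copy_number, confidence, state``;
the row index labels serve as stable call identifiers throughout the package.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cnvrecur")

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: canonical column -> column name expected in input files
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "Sample",
    "chromosome": "Chr",
    "copy_number": "CN",
    "start_bp": "Start",
    "end_bp": "End",
    "confidence": "Conf",
}

CALL_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp",
                "copy_number", "confidence", "state"]


class CnvFormatError(ValueError):
    """A file or table does not conform to the expected layout."""


class CnvValidationError(ValueError):
    """A row violates a data-model invariant (e.g. start > end)."""


def normalize_chromosome(label: object) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def region_size_kb(start_bp: int, end_bp: int) -> float:
    """Region size in kb, ``(end - start) / 1000`` rounded to one decimal."""
    return round((int(end_bp) - int(start_bp)) / 1000.0, 1)


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# CNV call tables
# ---------------------------------------------------------------------------

def sort_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Sort calls by (chromosome, start, sample); index labels are preserved."""
    key = calls["chromosome"].astype(int)
    order = np.lexsort((calls["sample_id"].to_numpy(),
                        calls["start_bp"].to_numpy(),
                        key.to_numpy()))
    return calls.iloc[order]


def validate_calls(calls: pd.DataFrame, *, source: str = "<calls>",
                   line_offset: int = 0) -> pd.DataFrame:
    """Validate and normalise a canonical-column call table.

    Drops non-autosomal rows (logged) and copy-number-2 rows (warned),
    derives the ``state`` column and returns the table sorted by
    (chromosome, start, sample).  Raises on invariant violations that
    indicate corrupt input rather than out-of-scope rows.
    """
    df = calls.copy()
    for col in ("start_bp", "end_bp", "copy_number"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise CnvFormatError(f"{source}: column {col!r} is not integer: {exc}")
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    if df["confidence"].isna().any() or not np.isfinite(df["confidence"]).all():
        bad = df.index[~np.isfinite(df["confidence"].fillna(np.inf))][:1]
        raise CnvValidationError(f"{source}: non-finite confidence score "
                                 f"(first at row {bad.tolist()})")
    if (df["confidence"] < 0).any():
        raise CnvValidationError(f"{source}: negative confidence score")
    if (df["copy_number"] < 0).any():
        raise CnvValidationError(f"{source}: negative copy number")

    bad = df["start_bp"] > df["end_bp"]
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        raise CnvValidationError(
            f"{source}: start_bp > end_bp at row {pos + line_offset} "
            f"(sample {df.iloc[pos]['sample_id']!r})")

    df["sample_id"] = df["sample_id"].astype(str)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)

    non_auto = ~df["chromosome"].isin(AUTOSOMES)
    if non_auto.any():
        logger.warning("%s: dropped %d call(s) on non-autosomal chromosomes",
                       source, int(non_auto.sum()))
        df = df[~non_auto]

    neutral = df["copy_number"] == 2
    if neutral.any():
        logger.warning("%s: rejected %d call(s) with copy number 2 "
                       "(a call must be an aberration)", source,
                       int(neutral.sum()))
        df = df[~neutral]

    df["state"] = np.where(df["copy_number"] < 2, "loss", "gain")
    return sort_calls(df)


def read_cnv_calls(path: str | Path,
                   dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited per-individual CNV call table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.  The default expected columns
        are ``Sample, Chr, CN, Start, End, Conf``.
    dialect
        Optional remapping ``canonical name -> column name in the file``,
        e.g. ``{"confidence": "lbf"}``.  Unmentioned columns keep their
        defaults.

    Returns
    -------
    pandas.DataFrame
        Canonical call table sorted by (chromosome, start, sample), with a
        fresh 0..n-1 index whose labels act as call identifiers.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, sep="\t", comment="#")
    missing = [fc for fc in colmap.values() if fc not in raw.columns]
    if missing:
        raise CnvFormatError(f"{path}: missing required column(s) "
                             f"{', '.join(repr(m) for m in missing)}")
    df = pd.DataFrame({canon: raw[fc] for canon, fc in colmap.items()})
    # +2: one for the header line, one for 1-based file line numbers
    df = validate_calls(df, source=str(path), line_offset=2)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probe maps
# ---------------------------------------------------------------------------

class ProbeMap:
    """Ordered genomic probe positions per chromosome.

    Holds, for each chromosome, a strictly increasing array of probe
    positions l_1 < ... < l_M.  When no array manifest is available the grid
    is derived from the call breakpoints (:meth:`from_calls`); the per-probe
    statistics are piecewise constant between breakpoints, so that grid is
    lossless.
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size == 0:
                raise CnvFormatError(f"chromosome {chrom}: empty probe list")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise CnvFormatError(
                    f"chromosome {chrom}: probe positions not strictly increasing")
            self._pos[normalize_chromosome(chrom)] = arr

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._pos, key=int)

    def __contains__(self, chrom: str) -> bool:
        return normalize_chromosome(chrom) in self._pos

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[normalize_chromosome(chrom)]

    def n_probes(self, chrom: str) -> int:
        return int(self._pos[normalize_chromosome(chrom)].size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return (self._pos.keys() == other._pos.keys()
                and all(np.array_equal(self._pos[c], other._pos[c])
                        for c in self._pos))

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "ProbeMap":
        """Pseudo-probe grid: per chromosome, the sorted set of all distinct
        call start and end positions."""
        if len(calls) == 0:
            raise CnvFormatError("cannot derive a probe map from an empty call set")
        pos: dict[str, np.ndarray] = {}
        for chrom, grp in calls.groupby("chromosome", sort=False):
            pts = np.union1d(grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy())
            pos[chrom] = pts
        return cls(pos)

    @classmethod
    def read(cls, path: str | Path) -> "ProbeMap":
        """Read a two-column (chromosome, position) probe manifest.

        Positions are sorted per chromosome; duplicates are collapsed with a
        warning.  A header line ``Chr<TAB>Position`` is optional.
        """
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        if raw.shape[1] < 2:
            raise CnvFormatError(f"{path}: expected two columns (chromosome, position)")
        raw = raw.iloc[:, :2]
        raw.columns = ["chromosome", "position"]
        # tolerate a header row
        first = str(raw.iloc[0, 1]) if len(raw) else ""
        if len(raw) and not first.lstrip("-").isdigit():
            if first.lower() in {"position", "pos", "bp"}:
                raw = raw.iloc[1:]
            else:
                raise CnvFormatError(f"{path}: non-integer probe position {first!r}")
        if len(raw) == 0:
            raise CnvFormatError(f"{path}: empty probe manifest")
        try:
            raw["position"] = raw["position"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise CnvFormatError(f"{path}: non-integer probe position: {exc}")
        pos: dict[str, np.ndarray] = {}
        n_dup = 0
        for chrom, grp in raw.groupby(raw["chromosome"].map(normalize_chromosome)):
            uniq = np.unique(grp["position"].to_numpy())
            n_dup += len(grp) - len(uniq)
            pos[chrom] = uniq
        if n_dup:
            logger.warning("%s: collapsed %d duplicate probe position(s)", path, n_dup)
        return cls(pos)


def derive_probe_map(calls: pd.DataFrame) -> ProbeMap:
    """Convenience alias for :meth:`ProbeMap.from_calls`."""
    return ProbeMap.from_calls(calls)


def read_probe_map(path: str | Path) -> ProbeMap:
    """Convenience alias for :meth:`ProbeMap.read`."""
    return ProbeMap.read(path)


# ---------------------------------------------------------------------------
# Reference CNVs and sample groups
# ---------------------------------------------------------------------------

_TYPE_MAP = {"loss": "loss", "deletion": "loss", "del": "loss",
             "gain": "gain", "duplication": "gain", "dup": "gain",
             "unknown": "unknown", "": "unknown", "nan": "unknown"}


def read_reference_cnvs(path: str | Path) -> pd.DataFrame:
    """Read a reference CNV table (e.g. sequencing-validated events).

    Expected tab-delimited columns: ``Sample, Chr, Start, End`` and an
    optional ``Type`` (loss/deletion, gain/duplication; anything else maps
    to "unknown").
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    required = ["Sample", "Chr", "Start", "End"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CnvFormatError(f"{path}: missing required column(s) "
                             f"{', '.join(repr(m) for m in missing)}")
    df = pd.DataFrame({
        "sample_id": raw["Sample"].astype(str),
        "chromosome": raw["Chr"].map(normalize_chromosome),
        "start_bp": raw["Start"].astype(np.int64),
        "end_bp": raw["End"].astype(np.int64),
    })
    if (df["start_bp"] > df["end_bp"]).any():
        raise CnvValidationError(f"{path}: reference CNV with start > end")
    if "Type" in raw.columns:
        df["type"] = (raw["Type"].astype(str).str.strip().str.lower()
                      .map(lambda t: _TYPE_MAP.get(t, "unknown")))
    else:
        df["type"] = "unknown"
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class SampleGroups:
    """Sample -> group assignment plus the subset flagged as unrelated.

    Group-wise Hardy-Weinberg tests are carried out on the unrelated subset
    of each group only; related samples still contribute to region discovery
    and to association tests.
    """

    group_of: Mapping[str, str]
    unrelated: frozenset = field(default_factory=frozenset)

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def members(self, group: str) -> list[str]:
        return sorted(s for s, g in self.group_of.items() if g == group)

    def unrelated_members(self, group: str) -> list[str]:
        return [s for s in self.members(group) if s in self.unrelated]

    @classmethod
    def single_group(cls, samples: Iterable[str],
                     label: str = "all") -> "SampleGroups":
        samples = list(samples)
        return cls({s: label for s in samples}, frozenset(samples))

    @classmethod
    def read(cls, path: str | Path) -> "SampleGroups":
        """Read a ``Sample, Group[, Unrelated]`` table.  Without an
        ``Unrelated`` column every sample is treated as unrelated."""
        raw = pd.read_csv(path, sep="\t", comment="#")
        for col in ("Sample", "Group"):
            if col not in raw.columns:
                raise CnvFormatError(f"{path}: missing required column {col!r}")
        group_of = dict(zip(raw["Sample"].astype(str), raw["Group"].astype(str)))
        if "Unrelated" in raw.columns:
            truthy = {"1", "true", "yes", "y"}
            flags = raw["Unrelated"].astype(str).str.strip().str.lower().isin(truthy)
            unrelated = frozenset(raw.loc[flags, "Sample"].astype(str))
        else:
            unrelated = frozenset(group_of)
        return cls(group_of, unrelated)


def read_sample_groups(path: str | Path) -> SampleGroups:
    """Convenience alias for :meth:`SampleGroups.read`."""
    return SampleGroups.read(path)


# ---------------------------------------------------------------------------
# Region output
# ---------------------------------------------------------------------------

REGION_COLUMNS = [
    "region_id", "parent_id", "chromosome", "state_class",
    "first_probe", "last_probe", "start_bp", "end_bp",
    "n_supporting", "n_total_samples", "frequency",
    "median_confidence", "size_kb", "supporting_samples", "supporting_calls",
]


def regions_to_frame(regions: Iterable) -> pd.DataFrame:
    """Flatten CommonRegion/SubRegion objects into the canonical region table."""
    rows = []
    for r in regions:
        rows.append({
            "region_id": r.region_id,
            "parent_id": getattr(r, "parent_id", ""),
            "chromosome": r.chromosome,
            "state_class": r.state_class,
            "first_probe": getattr(r, "first_probe", -1),
            "last_probe": getattr(r, "last_probe", -1),
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "n_supporting": len(r.supporting_samples),
            "n_total_samples": r.n_total_samples,
            "frequency": r.frequency,
            "median_confidence": r.median_confidence,
            "size_kb": f"{r.size_kb:.1f}",
            "supporting_samples": ",".join(r.supporting_samples),
            "supporting_calls": ",".join(str(i) for i in r.supporting_calls),
        })
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions(regions: Iterable, path: str | Path, fmt: str = "tsv",
                  header_lines: Sequence[str] = ()) -> None:
    """Write regions as TSV (all summary fields) or BED (0-based half-open).

    The TSV carries every summary field and round-trips exactly through
    :func:`read_regions`.  BED lines are ``chrom  start_bp-1  end_bp  id``.
    """
    path = Path(path)
    regions = list(regions)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if fmt == "tsv":
            regions_to_frame(regions).to_csv(fh, sep="\t", index=False)
        elif fmt == "bed":
            for r in regions:
                fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t"
                         f"{r.region_id}\n")
        else:
            raise ValueError(f"unknown region format {fmt!r}")


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a region TSV written by :func:`write_regions` back into a frame."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chromosome": str, "parent_id": str,
                            "supporting_samples": str, "supporting_calls": str})
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise CnvFormatError(f"{path}: missing region column(s) {missing}")
    for col in ("parent_id", "supporting_samples", "supporting_calls"):
        df[col] = df[col].fillna("")
    return df
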