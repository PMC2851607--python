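"""Seedable generator of segmented CNV call tables with known ground truth.

The generator emulates the data a SNP-array CNV caller produces for a
population sample: a set of inherited CNV loci segregating at
Hardy-Weinberg equilibrium, each carrier emitting one call whose breakpoints
jitter around the true locus boundaries, whose confidence score grows with
region length (longer regions span more probes and yield stronger evidence),
plus sporadic low-confidence noise calls that correspond to no real locus.

Every draw flows from a single integer seed; each locus uses its own
deterministic substream, so adding a locus to a specification does not
perturb the calls generated for the others.  The same seed always yields
byte-identical tables.

Defaults model a small population-genetics study: 20 diallelic loci with
minor-allele frequencies between 0.15 and 0.45, core sizes of tens to a
couple of hundred kb, 2 kb breakpoint jitter, 100 samples and 0.5 noise
calls per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import AUTOSOMES, SampleGroups, validate_calls

# substream tags (kept < 2**31; combined with the user seed)
_LOCUS_TAG = 1_000_003
_NOISE_TAG = 999_983
_CHROM_LEN = 200_000_000  # nominal autosome length for noise placement


@dataclass(frozen=True)
class LocusSpec:
    """One planted CNV locus.

    ``maf`` may be a single minor-allele frequency or a per-group mapping.
    Confidence scores of emitted calls are drawn from
    Normal(conf_intercept + conf_slope * ln(length bp), conf_sd) truncated
    at 0, reproducing the empirical pattern that short regions carry lower
    confidence.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    state: str = "loss"  # 'loss' | 'gain'
    maf: float | Mapping[str, float] = 0.25
    jitter_sd_bp: float = 2000.0
    conf_intercept: float = 10.0
    conf_slope: float = 3.0
    conf_sd: float = 4.0

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("locus start must not exceed end")
        if self.state not in ("loss", "gain"):
            raise ValueError("locus state must be 'loss' or 'gain'")
        if self.jitter_sd_bp < 0:
            raise ValueError("jitter SD must be non-negative")
        for q in (self.maf.values() if isinstance(self.maf, Mapping)
                  else [self.maf]):
            if not 0.0 <= q <= 0.5:
                raise ValueError("minor-allele frequencies must lie in [0, 0.5]")

    def maf_for(self, group: str) -> float:
        if isinstance(self.maf, Mapping):
            return float(self.maf[group])
        return float(self.maf)


@dataclass
class TruthTable:
    """Ground truth of a simulation.

    ``genotypes`` has one row per (sample, locus) with the drawn genotype
    (copies of the variant allele, 0/1/2) and the index label of the emitted
    call (-1 for non-carriers); ``noise_calls`` lists the index labels of
    calls not linked to any locus.
    """

    loci: list[LocusSpec]
    genotypes: pd.DataFrame
    noise_calls: list[int] = field(default_factory=list)

    def carrier_frequency(self, locus_index: int) -> float:
        g = self.genotypes
        mine = g[g["locus"] == locus_index]
        return float((mine["genotype"] > 0).mean())


def default_locus_specs(n_loci: int = 20, state: str = "loss",
                        maf_low: float = 0.15,
                        maf_high: float = 0.45) -> list[LocusSpec]:
    """A deterministic spread of loci across autosomes.

    Loci cycle through chromosomes 1..22 at well-separated positions with
    core sizes from 30 to 150 kb and MAFs spaced evenly in
    [maf_low, maf_high].
    """
    specs = []
    for i in range(n_loci):
        chrom = AUTOSOMES[i % len(AUTOSOMES)]
        start = 10_000_000 + 5_000_000 * (i // len(AUTOSOMES))
        size = 30_000 + (120_000 * i) // max(n_loci - 1, 1)
        frac = i / max(n_loci - 1, 1)
        maf = round(maf_low + (maf_high - maf_low) * frac, 4)
        specs.append(LocusSpec(chromosome=chrom, start_bp=start,
                               end_bp=start + size, state=state, maf=maf))
    return specs


def _check_disjoint(loci: Sequence[LocusSpec]) -> None:
    by_chrom: dict[str, list[LocusSpec]] = {}
    for spec in loci:
        by_chrom.setdefault(str(spec.chromosome), []).append(spec)
    for chrom, specs in by_chrom.items():
        specs = sorted(specs, key=lambda s: s.start_bp)
        for left, right in zip(specs, specs[1:]):
            if right.start_bp <= left.end_bp:
                raise ValueError(f"overlapping locus specs on chromosome "
                                 f"{chrom}: truth would be ambiguous")


def _draw_confidence(rng: np.random.Generator, spec: LocusSpec,
                     length_bp: int) -> float:
    mean = spec.conf_intercept + spec.conf_slope * np.log(max(length_bp, 1))
    return float(max(0.0, rng.normal(mean, spec.conf_sd)))


def simulate_population(loci: Sequence[LocusSpec],
                        n_per_group: Mapping[str, int] | int,
                        noise_rate: float = 0.5,
                        seed: int = 0,
                        noise_conf_mean: float = 5.0,
                        noise_conf_sd: float = 2.0
                        ) -> tuple[pd.DataFrame, SampleGroups, TruthTable]:
    """Simulate a population's CNV call table from planted loci.

    Parameters
    ----------
    loci
        Planted locus specifications; loci on one chromosome must not
        overlap.
    n_per_group
        Either a mapping group label -> sample count, or a single integer
        (one group named "pop").
    noise_rate
        Expected number of spurious calls per sample (Poisson), placed
        uniformly on the autosomes away from every planted locus, with
        low confidence and a random aberrant copy number.
    seed
        Governs all randomness.

    Returns
    -------
    (calls, groups, truth): a validated canonical call table, the sample
    grouping (all samples unrelated) and the :class:`TruthTable`.
    """
    loci = list(loci)
    _check_disjoint(loci)
    if isinstance(n_per_group, int):
        n_per_group = {"pop": n_per_group}
    samples: list[tuple[str, str]] = []
    for group in sorted(n_per_group):
        width = max(3, len(str(n_per_group[group])))
        for i in range(n_per_group[group]):
            samples.append((f"{group}_{i + 1:0{width}d}", group))

    records: list[dict] = []
    truth_rows: list[dict] = []

    for li, spec in enumerate(loci):
        rng = np.random.default_rng([int(seed), _LOCUS_TAG, li])
        for sample_id, group in samples:
            q = spec.maf_for(group)
            g = int(rng.choice(3, p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2]))
            call_idx = -1
            if g > 0:
                if spec.state == "loss":
                    cn = 1 if g == 1 else 0
                else:
                    cn = 3 if g == 1 else 4
                start = int(round(spec.start_bp + rng.normal(0, spec.jitter_sd_bp)))
                end = int(round(spec.end_bp + rng.normal(0, spec.jitter_sd_bp)))
                start = max(1, start)
                end = max(start, end)
                conf = _draw_confidence(rng, spec, end - start + 1)
                call_idx = len(records)
                records.append({"sample_id": sample_id,
                                "chromosome": str(spec.chromosome),
                                "start_bp": start, "end_bp": end,
                                "copy_number": cn, "confidence": conf})
            truth_rows.append({"sample_id": sample_id, "locus": li,
                               "genotype": g, "call_index": call_idx})

    # noise calls: uniform positions rejected if they touch a planted locus
    noise_ids: list[int] = []
    rng_noise = np.random.default_rng([int(seed), _NOISE_TAG])
    planted = {str(s.chromosome): [] for s in loci}
    for s in loci:
        planted[str(s.chromosome)].append((s.start_bp, s.end_bp))
    for sample_id, _group in samples:
        for _ in range(rng_noise.poisson(noise_rate)):
            for _attempt in range(100):
                chrom = AUTOSOMES[rng_noise.integers(len(AUTOSOMES))]
                length = int(rng_noise.integers(1_000, 20_000))
                start = int(rng_noise.integers(1, _CHROM_LEN - length))
                end = start + length
                hits = any(start <= pe and end >= ps
                           for ps, pe in planted.get(chrom, []))
                if not hits:
                    break
            else:  # pragma: no cover - 100 rejections is virtually impossible
                continue
            cn = int(rng_noise.choice([0, 1, 3]))
            conf = float(max(0.0, rng_noise.normal(noise_conf_mean,
                                                   noise_conf_sd)))
            noise_ids.append(len(records))
            records.append({"sample_id": sample_id, "chromosome": chrom,
                            "start_bp": start, "end_bp": end,
                            "copy_number": cn, "confidence": conf})

    calls = pd.DataFrame.from_records(
        records, columns=["sample_id", "chromosome", "start_bp", "end_bp",
                          "copy_number", "confidence"])
    calls = validate_calls(calls, source="<simulated>")

    groups = SampleGroups({s: g for s, g in samples},
                          frozenset(s for s, _ in samples))
    truth = TruthTable(loci=loci,
                       genotypes=pd.DataFrame(
                           truth_rows, columns=["sample_id", "locus",
                                                "genotype", "call_index"]),
                       noise_calls=noise_ids)
    return calls, groups, truth


# ---------------------------------------------------------------------------
# Hand-checkable fixtures
# ---------------------------------------------------------------------------

def make_toy_fixture(name: str, seed: int = 20100322):
    """Small deterministic fixtures used throughout the test suite.

    * ``cover_toy``: 3 calls over a 5-probe grid — the worked example for
      the per-probe statistics (confidences 10, 5, 1).
    * ``figure2``: one common region supported by four calls forming two
      clearly separated pairs (two stacked left, two stacked right, small
      mutual overlap) — the canonical two-cluster refinement geometry.
    * ``hwe_grid``: genotype counts for 2,000 diallelic loci drawn exactly
      at HWE in three groups sized like a small three-population panel
      (46/29/37) — the violation-rate calibration set.
    """
    if name == "cover_toy":
        from .io_model import ProbeMap
        calls = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "chromosome": ["1", "1", "1"],
            "start_bp": [100, 200, 300],
            "end_bp": [400, 500, 300],
            "copy_number": [1, 1, 1],
            "confidence": [10.0, 5.0, 1.0],
        })
        calls = validate_calls(calls, source="cover_toy")
        probes = ProbeMap({"1": [100, 200, 300, 400, 500]})
        return calls, probes

    if name == "figure2":
        calls = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3", "s4"],
            "chromosome": ["1", "1", "1", "1"],
            "start_bp": [1001, 1051, 1401, 1451],
            "end_bp": [1550, 1600, 1950, 2000],
            "copy_number": [1, 1, 1, 1],
            "confidence": [20.0, 20.0, 20.0, 20.0],
        })
        calls = validate_calls(calls, source="figure2")
        left = frozenset({"s1", "s2"})
        right = frozenset({"s3", "s4"})
        return calls, (left, right)

    if name == "hwe_grid":
        from .hwe import GenotypeCounts
        rng = np.random.default_rng(seed)
        group_sizes = {"CEU": 46, "CHBJPT": 29, "YRI": 37}
        grid = []
        for _ in range(2000):
            q = float(rng.uniform(0.1, 0.5))
            counts = {}
            for group, n in group_sizes.items():
                draw = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q),
                                           q ** 2])
                counts[group] = GenotypeCounts(int(draw[0]), int(draw[1]),
                                               int(draw[2]))
            grid.append(counts)
        return grid

    raise ValueError(f"unknown fixture {name!r}")
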