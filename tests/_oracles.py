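"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: per-probe double loops, pure-Python
run scans and exact rational arithmetic.  None of it shares code with the
package internals it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from cnvrecur.io_model import validate_calls


def brute_force_track(calls: pd.DataFrame, positions, *, kind: str,
                      c: float = 0.0, state_class: str = "combined") -> np.ndarray:
    """Per-probe double loop: count (cover) or sum confidences (composite)."""
    values = np.zeros(len(positions))
    for k, pos in enumerate(positions):
        for row in calls.itertuples():
            if state_class != "combined" and row.state != state_class:
                continue
            if kind == "cover" and row.confidence < c:
                continue
            if row.start_bp <= pos <= row.end_bp:
                values[k] += 1 if kind == "cover" else row.confidence
    return values


def runs_oracle(values, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of indices with value >= threshold and value > 0."""
    runs, start = [], None
    for i, v in enumerate(values):
        ok = v >= threshold and v > 0
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return runs


def exact_hwe_oracle(n_ref_hom: int, n_het: int, n_var_hom: int) -> Fraction:
    """Exact-rational conditional HWE p-value.

    Enumerates every heterozygote count compatible with the allele counts;
    configuration weights are exact integers (multinomial x 2^het), so the
    two-sided tail sum involves no floating point at all.
    """
    n = n_ref_hom + n_het + n_var_hom
    minor = 2 * min(n_ref_hom, n_var_hom) + n_het
    if minor == 0:
        return Fraction(1)

    def weight(h: int) -> int:
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        return (comb(n, hom_minor) * comb(n - hom_minor, h)) * 2 ** h

    h_values = range(minor % 2, min(minor, 2 * n - minor) + 1, 2)
    weights = {h: weight(h) for h in h_values}
    w_obs = weights[n_het]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(tail, total)


def random_call_instance(rng: np.random.Generator, max_calls: int = 20,
                         max_probes: int = 50, span: int = 10_000
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """A random small single-chromosome call set plus a random probe grid."""
    n_probes = int(rng.integers(2, max_probes + 1))
    positions = np.sort(rng.choice(np.arange(1, span), n_probes, replace=False))
    n_calls = int(rng.integers(1, max_calls + 1))
    starts = rng.integers(1, span, n_calls)
    lengths = rng.integers(0, span // 4, n_calls)
    calls = pd.DataFrame({
        "sample_id": [f"s{rng.integers(1, n_calls + 1)}" for _ in range(n_calls)],
        "chromosome": ["1"] * n_calls,
        "start_bp": starts,
        "end_bp": starts + lengths,
        "copy_number": rng.choice([0, 1, 3, 4], n_calls),
        "confidence": np.round(rng.exponential(10.0, n_calls), 3),
    })
    return validate_calls(calls, source="<random>"), positions
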