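"""Downstream analyses on common CNV regions.

Once common regions are fixed, each sample gets an integer copy number at
every region (its best-overlapping supporting call; diploid 2 otherwise),
producing a samples x regions matrix.  Two standard analyses run on it:

* **Association**: per region, a carrier (copy number != 2) versus
  non-carrier by group contingency table tested with Fisher's exact test
  (exhaustive 2xk enumeration with fixed margins) or a chi-square test,
  with Benjamini-Hochberg FDR across regions.
* **PCA** of the copy-number profiles, for visualising population
  differentiation.  Columns are mean-centred (scaling optional); component
  signs are fixed by making each component's largest-magnitude loading
  positive, so results are reproducible across runs and sample orderings.
"""

from __future__ import annotations

import logging
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .hwe import assign_copy_numbers
from .io_model import SampleGroups

logger = logging.getLogger("cnvrecur")


def cn_matrix(regions: Sequence, calls: pd.DataFrame,
              samples: Sequence[str]) -> pd.DataFrame:
    """Samples x regions matrix of integer copy numbers (default 2).

    Columns follow genomic order (chromosome, start); entries use the same
    best-overlap assignment rule as the HWE module.
    """
    ordered = sorted(regions, key=lambda r: (int(r.chromosome), r.start_bp,
                                             r.end_bp, r.region_id))
    samples = [str(s) for s in samples]
    data = {}
    for region in ordered:
        cn = assign_copy_numbers(region, calls, samples)
        data[region.region_id] = [cn[s] for s in samples]
    mat = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"),
                       dtype=np.int64)
    return mat


# ---------------------------------------------------------------------------
# Association testing
# ---------------------------------------------------------------------------

def fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact conditional test for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (the two-sided convention; for k = 2 this is Fisher's classic test).
    Intended for small k (group comparisons); the enumeration is
    O(prod margins), fine for a handful of groups.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    col_totals = table.sum(axis=0)
    r = int(table[0].sum())
    n = int(table.sum())
    if r == 0 or r == n:
        return 1.0

    log_denom = lgamma(n + 1) - lgamma(r + 1) - lgamma(n - r + 1)

    def logp(xs: tuple[int, ...]) -> float:
        lp = -log_denom
        for x, m in zip(xs, col_totals):
            lp += lgamma(m + 1) - lgamma(x + 1) - lgamma(m - x + 1)
        return lp

    obs = logp(tuple(int(x) for x in table[0]))
    k = len(col_totals)
    total = 0.0

    def recurse(col: int, remaining: int, acc: list[int]):
        nonlocal total
        if col == k - 1:
            if 0 <= remaining <= col_totals[col]:
                lp = logp(tuple(acc + [remaining]))
                if lp <= obs + 1e-10:
                    total += np.exp(lp)
            return
        tail = int(col_totals[col + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(col_totals[col]), remaining)
        for x in range(lo, hi + 1):
            recurse(col + 1, remaining - x, acc + [x])

    recurse(0, r, [])
    return float(min(total, 1.0))


def _carrier_table(column: pd.Series, groups: SampleGroups,
                   labels: Sequence[str]) -> np.ndarray:
    rows = np.zeros((2, len(labels)), dtype=np.int64)
    for j, g in enumerate(labels):
        members = [s for s in groups.members(g) if s in column.index]
        vals = column.loc[members]
        rows[0, j] = int((vals != 2).sum())  # carriers
        rows[1, j] = int((vals == 2).sum())
    return rows


def _genotype_table(column: pd.Series, groups: SampleGroups,
                    labels: Sequence[str]) -> np.ndarray:
    cns = sorted(column.unique())
    rows = np.zeros((len(cns), len(labels)), dtype=np.int64)
    for j, g in enumerate(labels):
        members = [s for s in groups.members(g) if s in column.index]
        vals = column.loc[members]
        for i, cn in enumerate(cns):
            rows[i, j] = int((vals == cn).sum())
    return rows


def association_test(matrix: pd.DataFrame, groups: SampleGroups,
                     test: str = "fisher",
                     mode: str = "carrier") -> pd.DataFrame:
    """Per-region group-association tests with BH-FDR correction.

    Parameters
    ----------
    matrix
        Samples x regions copy-number matrix from :func:`cn_matrix`.
    groups
        Sample grouping (>= 2 groups required).
    test
        'fisher' (exact, default) or 'chisq'.
    mode
        'carrier' (default): 2 x k carrier/non-carrier table.
        'genotype': copy-number-level x k table (chi-square only).

    Returns
    -------
    DataFrame with columns region_id, n_carriers, p, q (BH-adjusted),
    zero_carriers flag.  Regions with no carrier get p = 1 and are flagged.
    """
    labels = groups.group_labels
    if len(labels) < 2:
        raise ValueError("association testing needs at least two groups")
    if mode not in ("carrier", "genotype"):
        raise ValueError(f"unknown association mode {mode!r}")
    if mode == "genotype" and test == "fisher":
        raise ValueError("genotype-level tables support the chi-square test only")

    rows = []
    for region_id in matrix.columns:
        col = matrix[region_id]
        n_car = int((col != 2).sum())
        if n_car == 0:
            rows.append({"region_id": region_id, "n_carriers": 0,
                         "p": 1.0, "zero_carriers": True})
            continue
        table = (_carrier_table(col, groups, labels) if mode == "carrier"
                 else _genotype_table(col, groups, labels))
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if min(table.shape) < 2:
            p = 1.0
        elif test == "fisher":
            p = fisher_exact_2xk(table)
        elif test == "chisq":
            p = float(chi2_contingency(table, correction=False).pvalue)
        else:
            raise ValueError(f"unknown association test {test!r}")
        rows.append({"region_id": region_id, "n_carriers": n_car,
                     "p": p, "zero_carriers": False})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# PCA of copy-number profiles
# ---------------------------------------------------------------------------

def pca_profiles(matrix: pd.DataFrame, n_components: int = 4,
                 center: bool = True, scale: bool = False
                 ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the samples x regions copy-number matrix.

    Returns (scores, explained variance ratio, loadings).  Scores are
    deterministic: each component's sign is chosen so its largest-magnitude
    loading is positive.  A constant (zero-variance) matrix yields all-zero
    components with a warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("PCA needs at least 2 samples and 1 region")
    x = matrix.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    n_components = int(min(n_components, min(x.shape)))

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    if total_var == 0.0:
        logger.warning("constant copy-number matrix: all components have "
                       "zero variance")
        ratio = np.zeros(n_components)
    else:
        ratio = (s[:n_components] ** 2) / total_var
    scores = u[:, :n_components] * s[:n_components]
    load = vt[:n_components].T
    # sign convention: largest |loading| of each component made positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.index, columns=comp_names),
            ratio,
            pd.DataFrame(load, index=matrix.columns, columns=comp_names))
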