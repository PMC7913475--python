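"""Alignment trimming, sequence-logo conservation profiles, and a small
distance + neighbor-joining toolkit.

Per-column information content follows the sequence-logo convention for
proteins: IC = log2(20) - H, with H the Shannon entropy of the non-gap
residue frequencies. No small-sample correction is applied by default (so
analytic test values are exact); the logo-style correction is available as a
flag. Distances are raw p-distances (mismatches over mutually ungapped
positions) because divergence figures in this domain are quoted uncorrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .core_io import GAP, Alignment, InputError

LOG2_20 = math.log2(20)


@dataclass
class ConservationProfile:
    """Per-column conservation summary of a protein alignment."""

    information_content: np.ndarray  # bits; NaN for all-gap columns
    consensus: list[str]             # '-' for all-gap columns
    frequencies: list[dict[str, float]]  # non-gap residue frequencies
    gap_fraction: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.consensus)


def _column_occupancy(aln: Alignment) -> np.ndarray:
    mat = np.array([list(g) for _, g in aln.rows])
    return (mat != GAP).mean(axis=0)


def trim_alignment(aln: Alignment, min_occupancy: float = 0.5) -> Alignment:
    """Drop leading/trailing low-occupancy columns (signal peptides, ragged
    ends); internal columns are untouched. Idempotent."""
    if not 0 < min_occupancy <= 1:
        raise InputError("min_occupancy must be in (0, 1]")
    occ = _column_occupancy(aln)
    dense = np.nonzero(occ >= min_occupancy)[0]
    if dense.size == 0:
        raise InputError(f"no alignment column reaches occupancy {min_occupancy}")
    lo, hi = int(dense[0]), int(dense[-1]) + 1
    return Alignment(rows=[(rid, g[lo:hi]) for rid, g in aln.rows])


def column_information(
    aln: Alignment, small_sample_correction: bool = False
) -> ConservationProfile:
    """WebLogo-style per-column information content.

    All-gap columns are flagged (IC = NaN, consensus '-'). With the
    correction flag, the logo small-sample term e_n = 19 / (2 ln2 n) is
    subtracted (n = non-gap count) and IC clamped at 0.
    """
    n_rows = len(aln.rows)
    ic = np.empty(aln.n_columns)
    consensus: list[str] = []
    freqs: list[dict[str, float]] = []
    gap_fraction = np.empty(aln.n_columns)
    for j in range(aln.n_columns):
        col = aln.column(j)
        residues = [c for c in col if c != GAP]
        gap_fraction[j] = 1 - len(residues) / n_rows
        if not residues:
            ic[j] = np.nan
            consensus.append(GAP)
            freqs.append({})
            continue
        counts = pd.Series(residues).value_counts()
        p = counts / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
        value = LOG2_20 - entropy
        if small_sample_correction:
            value -= 19 / (2 * math.log(2) * len(residues))
            value = max(value, 0.0)
        ic[j] = value
        # consensus: most frequent residue, ties broken alphabetically
        top = counts[counts == counts.max()].index.min()
        consensus.append(top)
        freqs.append({r: float(v) for r, v in p.sort_index().items()})
    return ConservationProfile(
        information_content=ic,
        consensus=consensus,
        frequencies=freqs,
        gap_fraction=gap_fraction,
    )


def profile_table(profile: ConservationProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": np.arange(profile.n_columns),
            "information_content": [
                "" if np.isnan(v) else f"{v:.6f}" for v in profile.information_content
            ],
            "consensus": profile.consensus,
            "gap_fraction": [f"{v:.6f}" for v in profile.gap_fraction],
        }
    )


def p_distance_matrix(aln: Alignment) -> pd.DataFrame:
    """Pairwise p-distances: mismatches / mutually non-gap positions.

    Pairs with zero comparable positions are flagged as missing (NaN).
    """
    mat = np.array([list(g) for _, g in aln.rows])
    ids = aln.ids
    k = len(ids)
    out = np.zeros((k, k))
    nongap = mat != GAP
    for i in range(k):
        for j in range(i + 1, k):
            both = nongap[i] & nongap[j]
            n = int(both.sum())
            if n == 0:
                warnings.warn(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns",
                    stacklevel=2,
                )
                out[i, j] = out[j, i] = np.nan
                continue
            mism = int((mat[i][both] != mat[j][both]).sum())
            out[i, j] = out[j, i] = mism / n
    return pd.DataFrame(out, index=ids, columns=ids)


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to 0.
    Returns an unrooted tree (trifurcating root node).
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise InputError("neighbor joining requires at least 3 taxa")
    if np.isnan(arr).any():
        raise InputError("distance matrix contains missing entries")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise InputError("distance matrix is not symmetric")
    if (arr < 0).any():
        raise InputError("distance matrix has negative entries")
    dm = DistanceMatrix(arr, ids=[str(i) for i in dist.index])
    return _skbio_nj(dm)


def long_branch_score(tree: TreeNode, tip_subset: Sequence[str]) -> float:
    """Mean pendant branch length inside the subset over the mean outside.

    Values > 1 indicate the subset sits on relatively long terminal branches
    (fast-evolving lineages). The subset must be non-empty and proper.
    """
    subset = set(tip_subset)
    tips = {t.name: (t.length or 0.0) for t in tree.tips()}
    missing = subset - tips.keys()
    if missing:
        raise InputError(f"tips not in tree: {sorted(missing)}")
    if not subset or subset == set(tips):
        raise InputError("tip subset must be non-empty and proper")
    inside = [l for name, l in tips.items() if name in subset]
    outside = [l for name, l in tips.items() if name not in subset]
    mean_out = sum(outside) / len(outside)
    if mean_out == 0:
        raise InputError("outside-subset mean branch length is zero; ratio undefined")
    return (sum(inside) / len(inside)) / mean_out
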