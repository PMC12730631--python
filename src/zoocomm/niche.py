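"""Levins niche breadth and pairwise niche overlap over resource states.

Resource states are the sample columns of an entity x sample matrix; each
entity's profile is its abundance distribution across those states.
Overlap defaults to the proportional-similarity form
``1 - 0.5 * sum|P_ij - P_kj|``; the classic Pianka product-moment form is
available behind ``method='pianka'`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError


def niche_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize an entity x state matrix into use-proportion profiles.

    Entities with zero total are excluded with a warning; an all-zero
    matrix is an error.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("abundances must be non-negative")
    totals = vals.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise UndefinedStatisticError("no entity with positive total abundance")
    dropped = list(matrix.index[~keep])
    if dropped:
        warnings.warn(f"entities with zero total excluded: {dropped}", stacklevel=2)
    return matrix.loc[keep].div(totals[keep], axis=0)


def levins_breadth(profile) -> float:
    """Levins breadth B = 1 / sum(P_j^2); 1 (specialist) to r (generalist)."""
    p = np.asarray(profile, dtype=float)
    ss = (p**2).sum()
    if ss == 0:
        raise ValidationError("profile is all-zero")
    return float(1.0 / ss)


def niche_overlap(pi, pk, method: str = "schoener") -> float:
    """Overlap of two use profiles on the same ordered resource states."""
    pi = np.asarray(pi, dtype=float)
    pk = np.asarray(pk, dtype=float)
    if pi.shape != pk.shape:
        raise ValidationError("profiles must cover the same resource states")
    if method == "schoener":
        return float(1.0 - 0.5 * np.abs(pi - pk).sum())
    if method == "pianka":
        denom = np.sqrt((pi**2).sum() * (pk**2).sum())
        if denom == 0:
            raise ValidationError("profile is all-zero")
        return float((pi * pk).sum() / denom)
    raise ValidationError(f"unknown overlap method: {method}")


def overlap_matrix(profiles: pd.DataFrame, method: str = "schoener") -> pd.DataFrame:
    """Symmetric overlap matrix with unit diagonal over all profile rows."""
    vals = profiles.to_numpy(dtype=float)
    if method == "schoener":
        out = 1.0 - 0.5 * np.abs(vals[:, None, :] - vals[None, :, :]).sum(axis=2)
    elif method == "pianka":
        norms = np.sqrt((vals**2).sum(axis=1))
        out = (vals @ vals.T) / np.outer(norms, norms)
    else:
        raise ValidationError(f"unknown overlap method: {method}")
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=profiles.index, columns=profiles.index)


def high_overlap_pairs(overlap: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Unordered pairs with overlap strictly above threshold, best first."""
    entities = overlap.index
    rows = []
    for i in range(len(entities)):
        for k in range(i + 1, len(entities)):
            o = overlap.iloc[i, k]
            if o > threshold:
                rows.append({"a": entities[i], "b": entities[k], "overlap": o})
    out = pd.DataFrame(rows, columns=["a", "b", "overlap"])
    return out.sort_values("overlap", ascending=False, ignore_index=True)


@dataclass
class NicheResult:
    breadth: pd.Series  # entity -> Levins B
    overlap: pd.DataFrame  # symmetric entity x entity
    high_pairs: pd.DataFrame  # pairs with overlap > threshold
    threshold: float


def compute_niche(matrix: pd.DataFrame, threshold: float = 0.7, method: str = "schoener") -> NicheResult:
    """Full niche analysis of an entity x sample matrix."""
    profiles = niche_profiles(matrix)
    breadth = pd.Series(
        {e: levins_breadth(profiles.loc[e]) for e in profiles.index}, name="breadth"
    ).rename_axis(profiles.index.name or "entity")
    ov = overlap_matrix(profiles, method=method)
    pairs = high_overlap_pairs(ov, threshold=threshold)
    return NicheResult(breadth=breadth, overlap=ov, high_pairs=pairs, threshold=threshold)
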