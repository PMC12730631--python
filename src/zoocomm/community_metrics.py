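"""Dominance, alpha diversity, composition percentages and Bray-Curtis.

All logarithms are base 2: Shannon diversity is reported in bits, and the
Margalef and Pielou indices use the same base so the three are mutually
consistent (J' = H'/log2 S).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError

PROPORTION_TOL = 1e-9


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > PROPORTION_TOL:
        raise ValidationError(f"proportions must sum to 1 (got {p.sum()!r})")
    return p


def shannon(p) -> float:
    """Shannon-Wiener H' = -sum p*log2(p), in bits; zero entries skipped."""
    p = _check_proportions(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def margalef(S: int, N_ind: float) -> float:
    """Margalef richness d = (S-1)/log2(N); 0 for a single species."""
    if S < 1:
        raise ValidationError("species count must be >= 1")
    if S == 1:
        return 0.0
    if N_ind <= 1:
        return float("nan")  # undefined, flagged
    return (S - 1) / np.log2(N_ind)


def pielou(H_prime: float, S: int) -> float:
    """Pielou evenness J' = H'/log2(S); NaN (undefined) when S == 1."""
    if S < 1:
        raise ValidationError("species count must be >= 1")
    if S == 1:
        return float("nan")
    return float(H_prime / np.log2(S))


def simpson(p) -> float:
    """Simpson diversity D = 1 - sum p^2."""
    p = _check_proportions(p)
    return float(1.0 - (p**2).sum())


def diversity_table(matrix: pd.DataFrame, pool: pd.Series | None = None) -> pd.DataFrame:
    """S, N, H', d, J', D per sample column (or per pooled unit).

    ``matrix`` is species x sample (counts or abundance — see module notes
    on the measure switch). ``pool`` maps sample ids to pooling labels;
    pooled units sum member columns before index computation.
    """
    if pool is not None:
        matrix = matrix.T.groupby(pool.reindex(matrix.columns).values).sum().T
    rows = []
    for unit in matrix.columns:
        col = matrix[unit].to_numpy(dtype=float)
        total = col.sum()
        S = int((col > 0).sum())
        if total <= 0:
            rows.append({"unit": unit, "S": 0, "N": 0.0, "H_prime": np.nan,
                         "d_margalef": np.nan, "J_prime": np.nan, "D_simpson": np.nan})
            continue
        p = col[col > 0] / total
        H = float(-(p * np.log2(p)).sum())
        rows.append(
            {
                "unit": unit,
                "S": S,
                "N": float(total),
                "H_prime": H,
                "d_margalef": margalef(S, total),
                "J_prime": pielou(H, S),
                "D_simpson": float(1.0 - (p**2).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("unit")


def dominance(matrix: pd.DataFrame, scope: list | None = None, threshold: float = 0.02) -> pd.DataFrame:
    """Dominance index Y = (n_i/N) * f_i over a sample scope.

    n_i/N is each species' share of pooled abundance over the scope; f_i is
    its occurrence frequency (fraction of scope samples where present).
    Dominant species satisfy Y > threshold strictly.
    """
    if scope is None:
        scope = list(matrix.columns)
    if len(scope) == 0:
        raise UndefinedStatisticError("empty scope")
    sub = matrix[scope]
    total = sub.to_numpy().sum()
    if total <= 0:
        raise UndefinedStatisticError("all-zero scope: dominance undefined")
    n_share = sub.sum(axis=1) / total
    f_occ = (sub > 0).sum(axis=1) / len(scope)
    Y = n_share * f_occ
    out = pd.DataFrame(
        {
            "n_share": n_share,
            "f_occurrence": f_occ,
            "Y": Y,
            "is_dominant": Y > threshold,
        }
    )
    out.index.name = "species_id"
    return out.sort_values("Y", ascending=False)


def composition_percentages(counts) -> pd.DataFrame:
    """Share of each class in a per-class species inventory.

    Returns fractions plus the percent rendering at two decimals used in
    reports.
    """
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise ValidationError("counts must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValidationError("zero total: composition undefined")
    frac = s / total
    return pd.DataFrame(
        {"count": s, "fraction": frac, "percent": (frac * 100).round(2)}
    )


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("vectors must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        return float("nan")  # both all-zero: undefined, flagged
    return float(1.0 - np.abs(x - y).sum() / denom)


def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis similarity between sample columns."""
    cols = matrix.columns
    vals = matrix.to_numpy(dtype=float)
    n = len(cols)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            s = bray_curtis_similarity(vals[:, i], vals[:, j])
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=cols, columns=cols)
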