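"""Interspecific association statistics on presence/absence matrices.

Overall association uses the variance-ratio test: VR compares the variance
of per-site richness with the sum of per-entity binomial variances and
equals 1 under independence. W = N * VR is referred to a chi-square with
N degrees of freedom; with significance level ``alpha`` the acceptance
region spans the alpha/2 .. 1-alpha/2 quantiles so the two-sided test has
size alpha.

Pairwise association uses the phi (point correlation) coefficient of the
2x2 co-occurrence table, which equals the Pearson correlation of the two
0/1 vectors. Pair significance is judged by chi2 = N * phi^2 against the
1-df critical value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr

from .errors import UndefinedStatisticError, ValidationError


@dataclass
class PresenceMatrix:
    values: pd.DataFrame  # entity x site, entries in {0, 1}

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence matrix entries must be 0/1")
        if self.values.shape[0] < 2:
            raise ValidationError("need at least 2 entities")
        if self.values.shape[1] < 2:
            raise ValidationError("need at least 2 sites")

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def entities(self) -> pd.Index:
        return self.values.index


def presence_absence(matrix: pd.DataFrame, threshold: float = 0.0) -> PresenceMatrix:
    """Binarize an abundance matrix: present iff abundance > threshold."""
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("abundances must be non-negative")
    return PresenceMatrix(values=(matrix > threshold).astype(int))


@dataclass
class OverallAssociation:
    sigma_T2: float
    S_T2: float
    VR: float
    W: float
    verdict: str  # positive | negative | none
    significant: bool
    chi2_lower: float
    chi2_upper: float
    alpha: float
    n_sites: int

    def to_dict(self) -> dict:
        return {
            "sigma_T2": self.sigma_T2,
            "S_T2": self.S_T2,
            "VR": self.VR,
            "W": self.W,
            "verdict": self.verdict,
            "significant": self.significant,
            "chi2_lower": self.chi2_lower,
            "chi2_upper": self.chi2_upper,
            "alpha": self.alpha,
            "n_sites": self.n_sites,
        }


def overall_variance_ratio(pm: PresenceMatrix, alpha: float = 0.05) -> OverallAssociation:
    """Variance-ratio test of overall multi-entity association.

    sigma_T2 = sum_i p_i (1 - p_i) with p_i the occupancy of entity i;
    S_T2 is the (1/N) variance of per-site richness T_j; VR = S_T2/sigma_T2
    and W = N * VR. VR > 1 indicates overall positive association, VR < 1
    negative; W outside the chi-square acceptance region marks it
    significant.
    """
    vals = pm.values.to_numpy(dtype=float)
    N = pm.n_sites
    p = vals.sum(axis=1) / N
    sigma_T2 = float((p * (1 - p)).sum())
    if sigma_T2 == 0:
        raise UndefinedStatisticError(
            "every entity is ubiquitous or absent: variance ratio undefined"
        )
    T = vals.sum(axis=0)
    S_T2 = float(((T - T.mean()) ** 2).mean())
    VR = S_T2 / sigma_T2
    W = N * VR
    lower = float(chi2.ppf(alpha / 2, N))
    upper = float(chi2.ppf(1 - alpha / 2, N))
    if VR > 1:
        verdict = "positive"
    elif VR < 1:
        verdict = "negative"
    else:
        verdict = "none"
    return OverallAssociation(
        sigma_T2=sigma_T2,
        S_T2=S_T2,
        VR=VR,
        W=W,
        verdict=verdict,
        significant=bool(W < lower or W > upper),
        chi2_lower=lower,
        chi2_upper=upper,
        alpha=alpha,
        n_sites=N,
    )


def contingency_2x2(pm: PresenceMatrix, i, k) -> tuple[int, int, int, int]:
    """(a, b, c, d): both present, A only, B only, neither."""
    x = pm.values.loc[i].to_numpy()
    y = pm.values.loc[k].to_numpy()
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    return a, b, c, d


def point_correlation(a: int, b: int, c: int, d: int) -> float:
    """Phi = (ad - bc) / sqrt((a+b)(a+c)(b+d)(c+d)); NaN on degenerate margins."""
    n = a + b + c + d
    if n < 2:
        raise ValidationError("need at least 2 sites")
    denom = (a + b) * (a + c) * (b + d) * (c + d)
    if denom == 0:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(denom))


def classify_pairs(pm: PresenceMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Phi, chi2 and significance class for every unordered entity pair.

    class is sig_positive/sig_negative when chi2 = N*phi^2 exceeds the
    1-df critical value, else positive/negative by the sign of phi
    (phi == 0 counts as positive by convention, flagged via ``zero_phi``);
    degenerate margins yield class ``undefined``.
    """
    crit = float(chi2.ppf(1 - alpha, 1))
    N = pm.n_sites
    ents = list(pm.entities)
    rows = []
    for i in range(len(ents)):
        for k in range(i + 1, len(ents)):
            a, b, c, d = contingency_2x2(pm, ents[i], ents[k])
            phi = point_correlation(a, b, c, d)
            if np.isnan(phi):
                cls, x2 = "undefined", float("nan")
            else:
                x2 = N * phi**2
                sig = x2 > crit
                if phi > 0:
                    cls = "sig_positive" if sig else "positive"
                elif phi < 0:
                    cls = "sig_negative" if sig else "negative"
                else:
                    cls = "positive"  # zero association, flagged below
            rows.append(
                {
                    "a_entity": ents[i],
                    "b_entity": ents[k],
                    "a": a, "b": b, "c": c, "d": d,
                    "phi": phi,
                    "chi2": x2,
                    "class": cls,
                    "zero_phi": phi == 0,
                }
            )
    return pd.DataFrame(rows)


def stability_summary(pairs: pd.DataFrame) -> dict:
    """Positive/negative pair counts and the stability verdict.

    A community with more positively than negatively associated pairs is
    judged stable; otherwise successional.
    """
    pos = int(pairs["class"].isin(["positive", "sig_positive"]).sum())
    neg = int(pairs["class"].isin(["negative", "sig_negative"]).sum())
    sig_pos = int((pairs["class"] == "sig_positive").sum())
    sig_neg = int((pairs["class"] == "sig_negative").sum())
    return {
        "n_pairs": int(len(pairs)),
        "positive": pos,
        "negative": neg,
        "sig_positive": sig_pos,
        "sig_negative": sig_neg,
        "undefined": int((pairs["class"] == "undefined").sum()),
        "ratio": pos / neg if neg else float("inf"),
        "verdict": "stable" if pos > neg else "successional",
    }


def pearson_pair_summary(
    matrix: pd.DataFrame,
    strong_r: float = 0.7,
    log_transform: bool = True,
) -> dict:
    """Pairwise Pearson correlations of entity abundance vectors.

    Vectors are log10(x+1)-transformed by default. Zero-variance entities
    are skipped and reported. Returns counts of positive, negative and
    strong (r > strong_r) pairs plus the full pair table.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("need at least 3 samples per entity vector")
    vals = matrix.to_numpy(dtype=float)
    if log_transform:
        vals = np.log10(vals + 1.0)
    ents = list(matrix.index)
    rows, skipped = [], []
    for i in range(len(ents)):
        for k in range(i + 1, len(ents)):
            x, y = vals[i], vals[k]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped.append((ents[i], ents[k]))
                continue
            r = float(pearsonr(x, y).statistic)
            rows.append({"a_entity": ents[i], "b_entity": ents[k], "r": r})
    pairs = pd.DataFrame(rows, columns=["a_entity", "b_entity", "r"])
    return {
        "pairs": pairs,
        "positive": int((pairs["r"] > 0).sum()),
        "negative": int((pairs["r"] < 0).sum()),
        "strong": int((pairs["r"] > strong_r).sum()),
        "skipped": skipped,
        "strong_r": strong_r,
    }


def export_network(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write classified pairs as a TSV edge list, dropping undefined pairs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["a_entity", "b_entity", "phi", "chi2", "class"]
    defined = pairs[pairs["class"] != "undefined"]
    defined[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def to_graph(pairs: pd.DataFrame):
    """Classified pairs as a networkx graph (phi/class edge attributes)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in pairs.iterrows():
        if row["class"] == "undefined":
            continue
        g.add_edge(row["a_entity"], row["b_entity"], phi=row["phi"], cls=row["class"])
    return g
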