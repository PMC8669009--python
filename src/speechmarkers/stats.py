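"""Subject aggregation and the group-comparison statistical harness.

Per-excerpt marker values are averaged to one value per subject; group
contrasts use the two-sided Mann–Whitney U test reported as a tie-corrected
normal-approximation Z (the measures are not reliably normal — checked with
Shapiro–Wilk). Relationships between markers are assessed with OLS
controlling for group membership. Covariate sensitivity analyses use a
gamma-family GLM with log link, reporting the multiplicative effect on the
mean, lambda = exp(group coefficient). Multiple comparisons are controlled
with Benjamini–Hochberg FDR (the family size can exceed the number of
p-values supplied, e.g. 96 for a 12-measure x 8-covariate table).

Sign convention for contrasts: Z > 0 when the first-listed group
stochastically exceeds the second, so a "FEP vs CON" row with negative Z
means the measure is lower in patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

MEASURES = (
    "n_word",
    "n_sentence",
    "sentence_length",
    "coherence",
    "tangentiality",
    "on_topic",
    "max_similarity",
    "ambiguous_pronouns",
    "lcc",
    "lsc",
    "lccr",
    "lscr",
)

GROUP_PAIRS = (("FEP", "CON"), ("CHR-P", "CON"), ("FEP", "CHR-P"))


@dataclass(frozen=True)
class GroupComparisonResult:
    measure: str
    group_a: str
    group_b: str
    z: float
    p: float
    n_a: int
    n_b: int
    u: float
    adjusted_p: Optional[float] = None


@dataclass(frozen=True)
class AdjustedModelResult:
    measure: str
    group_a: str
    group_b: str
    covariate: Optional[str]
    t: float
    p: float
    lam: float  # multiplicative effect on the mean, exp(group coefficient)
    n: int
    shift: float = 0.0  # affine shift applied to reach positive support
    converged: bool = True


def aggregate_subject(
    excerpt_scores: Sequence[Mapping[str, float]],
    measures: Sequence[str] = MEASURES,
) -> dict[str, float]:
    """Unweighted per-measure mean over a subject's excerpts.

    Missing (NaN) excerpt values are excluded from that measure's mean; a
    measure is missing in the profile only if missing in every excerpt.
    Also records ``n_used_<measure>`` counts.
    """
    if not excerpt_scores:
        raise ValueError("subject has zero excerpts")
    out: dict[str, float] = {}
    for m in measures:
        vals = [
            float(row[m])
            for row in excerpt_scores
            if m in row and row[m] is not None and not math.isnan(float(row[m]))
        ]
        out[m] = float(np.mean(vals)) if vals else float("nan")
        out[f"n_used_{m}"] = len(vals)
    return out


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p)."""
    x = np.asarray(values, dtype=np.float64)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk is undefined for constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def mann_whitney_z(
    a: Sequence[float],
    b: Sequence[float],
    measure: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparisonResult:
    """Two-sided Mann–Whitney U with tie-corrected normal approximation.

    U is computed from rank sums with midranks; the variance carries the
    tie correction; no continuity correction is applied. Z is oriented so
    that Z > 0 when ``a`` tends to exceed ``b``. Fully tied data give
    Z = 0, p = 1.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return GroupComparisonResult(
        measure=measure,
        group_a=group_a,
        group_b=group_b,
        z=float(z),
        p=float(p),
        n_a=n1,
        n_b=n2,
        u=float(u1),
    )


def mann_whitney_exact_p(
    a: Sequence[float], b: Sequence[float], convention: str = "mid"
) -> float:
    """Exact two-sided permutation p for the Mann–Whitney U statistic.

    Enumerates all group assignments (feasible for n <= ~8 per group).
    With ``convention="mid"`` (default) the two-sided mid-p is returned:
    P(|U - mu| > |u_obs - mu|) + 0.5 * P(|U - mu| = |u_obs - mu|), which is
    the quantity the uncorrected normal approximation estimates; an
    observation at the null centre (u_obs = mu) has p = 1 by definition of
    a two-sided test. ``convention="inclusive"`` returns the conventional
    P(|U - mu| >= |u_obs - mu|). Used as an independent oracle for the
    normal approximation.
    """
    from itertools import combinations

    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    n1 = len(x)
    combined = np.concatenate([x, y])
    n = len(combined)
    ranks = sps.rankdata(combined)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    if convention == "mid" and dev == 0:
        return 1.0
    more = equal = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        d = abs(u - mu)
        if d > dev + 1e-9:
            more += 1
        elif abs(d - dev) <= 1e-9:
            equal += 1
        total += 1
    if convention == "mid":
        return (more + 0.5 * equal) / total
    if convention == "inclusive":
        return (more + equal) / total
    raise ValueError(f"unknown convention {convention!r}")


def pairwise_measure_association(
    profiles: pd.DataFrame,
    measure_i: str,
    measure_j: str,
    group_col: str = "group",
    min_n: int = 10,
) -> tuple[float, float, int]:
    """T statistic for measure_i in OLS(measure_j ~ measure_i + group).

    Group membership enters as indicator columns (reference level dropped).
    Returns (T, p, n complete cases).
    """
    cols = [measure_i, measure_j, group_col]
    df = profiles[cols].dropna()
    n = len(df)
    if n < min_n:
        return float("nan"), float("nan"), n
    dummies = pd.get_dummies(df[group_col], drop_first=True, dtype=float)
    X = sm.add_constant(
        pd.concat([df[[measure_i]].astype(float), dummies], axis=1)
    )
    model = sm.OLS(df[measure_j].astype(float), X).fit()
    return (
        float(model.tvalues[measure_i]),
        float(model.pvalues[measure_i]),
        n,
    )


def association_matrix(
    profiles: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    group_col: str = "group",
    edge_alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All pairwise associations: (T matrix, p matrix, edge list p < alpha)."""
    t_mat = pd.DataFrame(np.nan, index=measures, columns=measures, dtype=float)
    p_mat = t_mat.copy()
    edges = []
    for i, mi in enumerate(measures):
        for j, mj in enumerate(measures):
            if i == j:
                continue
            t, p, n = pairwise_measure_association(
                profiles, mi, mj, group_col=group_col
            )
            t_mat.loc[mi, mj] = t
            p_mat.loc[mi, mj] = p
            if i < j and not math.isnan(p) and p < edge_alpha:
                edges.append({"measure_i": mi, "measure_j": mj, "t": t, "p": p, "n": n})
    return t_mat, p_mat, pd.DataFrame(edges)


def gamma_adjusted_model(
    y: Sequence[float],
    group: Sequence[str],
    covariate: Optional[Sequence[float]] = None,
    measure: str = "",
    group_a: str = "a",
    group_b: str = "b",
    covariate_name: Optional[str] = None,
) -> AdjustedModelResult:
    """Gamma GLM with log link for a two-group contrast, optional covariate.

    ``group`` holds the two group labels; the indicator is 1 for
    ``group_a``, so lambda = exp(beta) is the multiplicative effect on the
    mean of group_a relative to group_b. Measures whose values are not
    strictly positive are shifted by a recorded affine constant before
    fitting (the gamma family needs positive support); the shift is part of
    the result metadata.
    """
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(group, dtype=object)
    if covariate is not None:
        c = np.asarray(covariate, dtype=np.float64)
        keep = ~(np.isnan(y) | np.isnan(c))
        y, g, c = y[keep], g[keep], c[keep]
    else:
        keep = ~np.isnan(y)
        y, g = y[keep], g[keep]
        c = None
    labels = set(g)
    if labels != {group_a, group_b}:
        raise ValueError(
            f"group labels {sorted(labels)} do not match contrast "
            f"({group_a!r}, {group_b!r})"
        )
    shift = 0.0
    if y.min() <= 0:
        spread = np.ptp(y)
        shift = -y.min() + 0.01 * (spread if spread > 0 else 1.0)
        y = y + shift
    indicator = (g == group_a).astype(float)
    cols = {"const": np.ones_like(y), "group": indicator}
    if c is not None:
        cols[covariate_name or "covariate"] = c
    X = pd.DataFrame(cols)
    try:
        model = sm.GLM(
            y, X, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
        beta = float(model.params["group"])
        return AdjustedModelResult(
            measure=measure,
            group_a=group_a,
            group_b=group_b,
            covariate=covariate_name,
            t=float(model.tvalues["group"]),
            p=float(model.pvalues["group"]),
            lam=float(np.exp(beta)),
            n=len(y),
            shift=shift,
            converged=bool(model.converged),
        )
    except Exception as exc:
        raise RuntimeError(
            f"gamma model failed for measure {measure!r} "
            f"({group_a} vs {group_b}): {exc}"
        ) from exc


def fdr_bh(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m`` is the family size; it defaults to len(pvalues) but may be larger
    when the supplied p-values are a subset of a declared comparison family.
    Adjusted values are monotone in the raw p and capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def compare_groups(
    profiles: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    pairs: Sequence[tuple[str, str]] = GROUP_PAIRS,
    group_col: str = "group",
) -> pd.DataFrame:
    """Contrast table: one row per (measure, group pair) with Z and p.

    Pairs with fewer than 2 subjects per group are marked not computable
    (NaN Z/p) but retained, so the table shape is stable.
    """
    rows = []
    for measure in measures:
        for ga, gb in pairs:
            va = profiles.loc[profiles[group_col] == ga, measure].dropna()
            vb = profiles.loc[profiles[group_col] == gb, measure].dropna()
            if len(va) < 2 or len(vb) < 2:
                rows.append(
                    {
                        "measure": measure,
                        "group_a": ga,
                        "group_b": gb,
                        "z": float("nan"),
                        "p": float("nan"),
                        "n_a": len(va),
                        "n_b": len(vb),
                    }
                )
                continue
            res = mann_whitney_z(
                va, vb, measure=measure, group_a=ga, group_b=gb
            )
            rows.append(
                {
                    "measure": measure,
                    "group_a": ga,
                    "group_b": gb,
                    "z": res.z,
                    "p": res.p,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                }
            )
    return pd.DataFrame(rows)


def normalize_profiles(
    profiles: pd.DataFrame, measures: Sequence[str] = MEASURES
) -> pd.DataFrame:
    """Min–max scale each measure over the cohort to [0, 1].

    Used for spider-style speech-profile displays; constant measures map
    to 0.5.
    """
    out = profiles.copy()
    for m in measures:
        col = out[m].astype(float)
        lo, hi = col.min(), col.max()
        out[m] = 0.5 if hi == lo else (col - lo) / (hi - lo)
    return out
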