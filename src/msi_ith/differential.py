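"""Effect-size differential analysis and clinical contingency tests.

Components are selected by standardized effect size rather than p-value:
Cohen's d (pooled-SD mean difference) for component abundances between
pixel sets, and Cohen's h (arcsine-transformed proportion difference) for
cluster composition contrasts.  Magnitudes follow Cohen's conventions:
|effect| < 0.2 negligible, < 0.5 small, < 0.8 medium, else large.

Clinical descriptor tables are tested with Fisher's exact test — 2 x 2 by
hypergeometric tail summation and r x c by Freeman-Halton enumeration
over all tables with the observed margins (with a seeded Monte Carlo
fallback for large totals) — plus the two-sample Student's t-test for
age-like continuous covariates.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "MAGNITUDE_THRESHOLDS",
    "classify_magnitude",
    "cohens_d",
    "cohens_h",
    "differential_components",
    "overlap_sets",
    "fisher_exact",
    "students_t",
    "lhr_association",
    "LHR_ORDER",
]

#: Cohen's conventional class boundaries on the absolute effect size.
MAGNITUDE_THRESHOLDS = {"small": 0.2, "medium": 0.5, "large": 0.8}

LHR_ORDER = {"weak": 0, "intermediate": 1, "strong": 2}


def classify_magnitude(effect: float) -> str:
    a = abs(effect)
    if a < MAGNITUDE_THRESHOLDS["small"]:
        return "negligible"
    if a < MAGNITUDE_THRESHOLDS["medium"]:
        return "small"
    if a < MAGNITUDE_THRESHOLDS["large"]:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d: mean difference over the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def cohens_h(p1: float, p2: float) -> float:
    """Cohen's h: difference of arcsine-transformed proportions."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
    return float(2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2)))


def differential_components(
    abundances: np.ndarray,
    pixels_a: np.ndarray,
    pixels_b: np.ndarray,
    *,
    threshold_class: str = "medium",
    direction: str = "both",
    contrast: str = "A-vs-B",
    component_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-component Cohen's d between two pixel sets, with selection.

    Pixels are the observations, matching how spectra are grouped in the
    contrasts; components with zero pooled SD get ``d = NaN`` and are
    excluded.  ``direction`` restricts selection to components up ("up",
    mean higher in set A), down, or either way.
    """
    if threshold_class not in ("medium", "large"):
        raise ValueError("threshold_class must be 'medium' or 'large'")
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    values = np.asarray(abundances, dtype=float)
    a = values[np.asarray(pixels_a, dtype=int)]
    b = values[np.asarray(pixels_b, dtype=int)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both pixel sets need at least 2 pixels")
    na, nb = len(a), len(b)
    pooled_var = (
        (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
    ) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            pooled_var > 0, (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled_var), np.nan
        )
    magnitude = np.array(
        ["undefined" if np.isnan(x) else classify_magnitude(x) for x in d]
    )
    thr = MAGNITUDE_THRESHOLDS[threshold_class]
    selected = ~np.isnan(d) & (np.abs(d) >= thr)
    if direction == "up":
        selected &= d > 0
    elif direction == "down":
        selected &= d < 0
    ids = (
        np.asarray(component_ids)
        if component_ids is not None
        else np.arange(values.shape[1])
    )
    return pd.DataFrame(
        {
            "component_id": ids,
            "d": d,
            "magnitude": magnitude,
            "direction": np.where(np.isnan(d), "undefined", np.where(d >= 0, "up", "down")),
            "selected": selected,
            "contrast": contrast,
        }
    )


def magnitude_counts(table: pd.DataFrame) -> dict:
    """Component counts per magnitude class (heat-map style summary)."""
    return table["magnitude"].value_counts().to_dict()


def overlap_sets(set_a: set, set_b: set, set_c: set) -> dict:
    """Cardinalities of the 7 exclusive regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len(ab),
        "AC": len(ac),
        "BC": len(bc),
        "ABC": len(abc),
    }


# ---------------------------------------------------------------------------
# Exact contingency-table tests
# ---------------------------------------------------------------------------


def _drop_empty(table: np.ndarray) -> np.ndarray:
    table = table[table.sum(axis=1) > 0]
    return table[:, table.sum(axis=0) > 0]


def fisher_exact(
    table: Sequence[Sequence[int]],
    *,
    max_total: int = 10_000,
    monte_carlo: bool = False,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher's exact test for an r x c contingency table.

    The p-value sums the probabilities, under the hypergeometric model
    with fixed margins, of every table at most as probable as the
    observed one (Freeman-Halton for r x c; this reduces to the classic
    two-sided test for 2 x 2).  Empty rows or columns are ignored.  For
    totals above ``max_total`` exhaustive enumeration is refused; pass
    ``monte_carlo=True`` for a seeded Monte Carlo estimate instead.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or np.any(t < 0) or np.any(np.asarray(table) != t):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    t = _drop_empty(t)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0  # a single nonempty category cannot show association
    n = int(t.sum())
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    logfact = gammaln(np.arange(n + 1) + 1.0)
    log_const = float(logfact[rows].sum() + logfact[cols].sum() - logfact[n])
    logp_obs = log_const - float(logfact[t].sum())
    tol = 1e-7  # relative slack on the observed probability

    if monte_carlo:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols, seed=rng)
        hits = 0
        done = 0
        chunk = 100_000
        while done < n_draws:
            m = min(chunk, n_draws - done)
            samples = dist.rvs(m, method="patefield")
            logp = log_const - gammaln(samples + 1.0).sum(axis=(1, 2))
            hits += int(np.sum(logp <= logp_obs + tol))
            done += m
        return (hits + 1) / (n_draws + 1)

    if n > max_total:
        raise ValueError(
            f"table total {n} exceeds the exact enumeration bound {max_total}; "
            "call with monte_carlo=True for a seeded estimate"
        )

    r, c = t.shape
    acc = 0.0

    def recurse(i: int, j: int, col_rem: np.ndarray, row_rem: int, logp: float) -> None:
        nonlocal acc
        if i == r - 1:
            # last row fully determined by the remaining column margins
            lp = logp - float(logfact[col_rem].sum())
            if lp <= logp_obs + tol:
                acc += math.exp(lp)
            return
        if j == c - 1:
            if row_rem > col_rem[j]:
                return
            recurse(i + 1, 0, col_rem - _unit(c, j, row_rem), rows[i + 1], logp - logfact[row_rem])
            return
        hi = min(row_rem, col_rem[j])
        for v in range(hi + 1):
            recurse(i, j + 1, col_rem - _unit(c, j, v), row_rem - v, logp - logfact[v])

    def _unit(c: int, j: int, v: int) -> np.ndarray:
        u = np.zeros(c, dtype=int)
        u[j] = v
        return u

    recurse(0, 0, cols.copy(), int(rows[0]), log_const)
    return float(min(acc, 1.0))


def students_t(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sample Student's t-test (equal variances), as used for age."""
    res = stats.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float))
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Diversity vs lymphocytic host response
# ---------------------------------------------------------------------------


def lhr_association(
    simpson_by_patient: Sequence[float],
    lhr_by_patient: Sequence[str],
    groups_by_patient: Sequence[str] | None = None,
) -> dict:
    """Association between diversity and the ordinal LHR grade.

    Kruskal-Wallis of Simpson D across LHR categories plus the Spearman
    rank correlation on the ordinal coding (weak < intermediate <
    strong); when outcome groups are supplied, Fisher's exact test of the
    LHR x group table is added.
    """
    d = np.asarray(simpson_by_patient, dtype=float)
    lhr = np.asarray(lhr_by_patient)
    cats = [c for c in LHR_ORDER if c in lhr]
    if len(cats) < 2:
        raise ValueError("need at least two LHR categories")
    by_cat = [d[lhr == c] for c in cats]
    kw = stats.kruskal(*by_cat)
    codes = np.array([LHR_ORDER[c] for c in lhr])
    if np.ptp(d) == 0 or np.ptp(codes) == 0:
        rho, rho_p = 0.0, 1.0
    else:
        sp = stats.spearmanr(codes, d)
        rho, rho_p = float(sp.statistic), float(sp.pvalue)
    out = {
        "kruskal_statistic": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "categories": cats,
        "medians": {c: float(np.median(d[lhr == c])) for c in cats},
    }
    if groups_by_patient is not None:
        groups = np.asarray(groups_by_patient)
        names = sorted(set(groups))
        table = [[int(np.sum((lhr == c) & (groups == g))) for g in names] for c in cats]
        out["fisher_lhr_group_p"] = fisher_exact(table)
    return out
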