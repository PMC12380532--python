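"""High- vs weak-immunodominance statistical analysis.

Per protein, residues are labelled *high* when their ID score is at least
half the protein's maximum ID, *weak* when it is strictly between zero and
0.2 times the maximum, and *neither* otherwise. Continuous features
(physico-chemical scales, RSA, protrusion, depth, conservation, neighbor-ID)
are compared between the pooled high and weak groups with a Welch two-sample
t-test; compositional features (amino-acid identity, secondary-structure
class) are compared with a Mann-Whitney U test on per-protein proportions.
All raw p-values within one level (residue or patch) form a single
Benjamini-Hochberg family; significance is called at adjusted p <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io_formats import IDProfile

ALPHA = 0.05
HIGH_FRACTION = 0.5
WEAK_FRACTION = 0.2


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def assign_groups(scores: np.ndarray | IDProfile) -> np.ndarray:
    """Label residues high/weak/neither relative to the protein's maximum ID.

    high: id >= 0.5 * max; weak: 0 < id < 0.2 * max; neither otherwise.
    A protein with no epitopes at all (max = 0) gets all-neither labels.
    """
    if isinstance(scores, IDProfile):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise AnalysisError("empty ID profile")
    labels = np.full(scores.shape, "neither", dtype="U7")
    max_id = scores.max()
    if max_id <= 0.0:
        warnings.warn("profile has no epitope signal (max ID = 0); all labels neither",
                      stacklevel=2)
        return labels
    labels[scores >= HIGH_FRACTION * max_id] = "high"
    weak = (scores > 0.0) & (scores < WEAK_FRACTION * max_id)
    labels[weak] = "weak"
    return labels


# ---------------------------------------------------------------------------
# Two-sample tests (hand-rolled; scipy is the independent oracle in tests)
# ---------------------------------------------------------------------------

def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return 0.0, 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    # two-sided p from the t distribution CDF
    p = 2.0 * special.stdtr(df, -abs(t))
    return float(t), float(min(p, 1.0))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, normal approximation with tie correction
    and continuity correction. Returns (U1, p)."""
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    n = n1 + n2
    # tie correction on the rank variance
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts.astype(float) ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0.0:
        return float(u1), 1.0
    mu = n1 * n2 / 2.0
    u = max(u1, u2)
    z = (u - mu - 0.5) / np.sqrt(sigma2)
    p = 2.0 * special.ndtr(-z)
    return float(u1), float(min(max(p, 0.0), 1.0))


def compare_groups(
    values_high: np.ndarray,
    values_weak: np.ndarray,
    test: str = "t_test",
) -> tuple[float, float]:
    """Two-sided comparison of the high vs weak group for one feature.

    ``test`` is ``"t_test"`` (Welch, unequal variances) or
    ``"mann_whitney_u"`` (normal approximation, tie + continuity correction).
    Returns (statistic, raw p-value).
    """
    x = np.asarray(values_high, dtype=float)
    y = np.asarray(values_weak, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if test == "t_test":
        if x.size < 2 or y.size < 2:
            raise AnalysisError("t-test requires at least 2 values per group")
        return _welch_t(x, y)
    if test == "mann_whitney_u":
        if x.size < 1 or y.size < 1:
            raise AnalysisError("U-test requires at least 1 value per group")
        return _mann_whitney_u(x, y)
    raise ValueError(f"unknown test {test!r}")


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

@dataclass
class StatTestResult:
    feature: str
    level: str                      # "residue" | "patch"
    test: str                       # "t_test" | "mann_whitney_u"
    statistic: float
    p_raw: float
    p_adjusted: float
    n_high: int
    n_weak: int
    significant: bool
    mean_high: float = float("nan")
    mean_weak: float = float("nan")
    testable: bool = True


_EXCLUDED_COLUMNS = {"residue_index", "center_index", "aa", "ss3", "id_score",
                     "group", "patch_size", "protein_id"}
_COMPOSITIONAL = ("aa", "ss3")


def _continuous_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in _EXCLUDED_COLUMNS and pd.api.types.is_numeric_dtype(table[c])]


def run_analysis(
    tables: list[pd.DataFrame],
    level: str = "residue",
    pooling: str = "pooled",
    alpha: float = ALPHA,
) -> list[StatTestResult]:
    """Compare every feature between high- and weak-ID groups.

    ``tables``: one feature table per test-set protein, already restricted to
    surface residues (RSA >= 0.10) at residue level, or per-patch tables at
    patch level. Each must contain an ``id_score`` column; group labels are
    derived per protein so thresholds adapt to each protein's maximum ID.

    Continuous features are tested with Welch's t (values pooled across
    proteins by default, or per-protein means with ``pooling="per_protein"``);
    categorical columns (``aa``, ``ss3``), when present, are tested per
    category with a Mann-Whitney U across per-protein proportions. All raw
    p-values at this level are BH-adjusted as one family; zero-variance
    features are flagged untestable and excluded from the family.
    """
    if level not in ("residue", "patch"):
        raise ValueError(f"unknown level {level!r}")
    if pooling not in ("pooled", "per_protein"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if not tables:
        raise AnalysisError("no feature tables given")
    labelled = []
    for i, table in enumerate(tables):
        t = table.copy()
        t["group"] = assign_groups(t["id_score"].to_numpy())
        t["protein_id"] = t.get("protein_id", pd.Series([str(i)] * len(t))).astype(str)
        labelled.append(t)

    results: list[StatTestResult] = []

    # --- continuous features: Welch t-test -------------------------------
    cont = _continuous_columns(labelled[0])
    for feature in cont:
        highs, weaks = [], []
        for t in labelled:
            h = t.loc[t["group"] == "high", feature].to_numpy(dtype=float)
            w = t.loc[t["group"] == "weak", feature].to_numpy(dtype=float)
            h, w = h[~np.isnan(h)], w[~np.isnan(w)]
            if pooling == "per_protein":
                if h.size:
                    highs.append(h.mean())
                if w.size:
                    weaks.append(w.mean())
            else:
                highs.extend(h)
                weaks.extend(w)
        x, y = np.asarray(highs, dtype=float), np.asarray(weaks, dtype=float)
        base = dict(feature=feature, level=level, test="t_test",
                    n_high=x.size, n_weak=y.size,
                    mean_high=float(x.mean()) if x.size else float("nan"),
                    mean_weak=float(y.mean()) if y.size else float("nan"))
        if x.size < 2 or y.size < 2 or (x.var() == 0.0 and y.var() == 0.0):
            results.append(StatTestResult(statistic=float("nan"), p_raw=float("nan"),
                                          p_adjusted=float("nan"), significant=False,
                                          testable=False, **base))
            continue
        stat, p = compare_groups(x, y, "t_test")
        results.append(StatTestResult(statistic=stat, p_raw=p, p_adjusted=float("nan"),
                                      significant=False, **base))

    # --- compositional features: U-test on per-protein proportions -------
    comp_cols = [c for c in _COMPOSITIONAL if c in labelled[0].columns]
    if comp_cols:
        if len(labelled) < 2:
            raise AnalysisError(
                "compositional tests need at least 2 proteins (per-protein proportions)"
            )
        for col in comp_cols:
            categories = sorted({v for t in labelled for v in t[col].unique()})
            for cat in categories:
                prop_h, prop_w = [], []
                for t in labelled:
                    for group, acc in (("high", prop_h), ("weak", prop_w)):
                        sel = t[t["group"] == group]
                        if len(sel):
                            acc.append(float((sel[col] == cat).mean()))
                x, y = np.asarray(prop_h), np.asarray(prop_w)
                base = dict(feature=f"{col}:{cat}", level=level, test="mann_whitney_u",
                            n_high=x.size, n_weak=y.size,
                            mean_high=float(x.mean()) if x.size else float("nan"),
                            mean_weak=float(y.mean()) if y.size else float("nan"))
                if x.size < 1 or y.size < 1 or (np.all(x == x[0]) and np.all(y == y[0])
                                                and x[0] == y[0]):
                    results.append(StatTestResult(statistic=float("nan"),
                                                  p_raw=float("nan"),
                                                  p_adjusted=float("nan"),
                                                  significant=False, testable=False,
                                                  **base))
                    continue
                stat, p = compare_groups(x, y, "mann_whitney_u")
                results.append(StatTestResult(statistic=stat, p_raw=p,
                                              p_adjusted=float("nan"),
                                              significant=False, **base))

    # --- BH family over all testable features at this level --------------
    testable = [r for r in results if r.testable]
    if testable:
        adjusted = bh_adjust([r.p_raw for r in testable])
        for r, p_adj in zip(testable, adjusted):
            r.p_adjusted = float(p_adj)
            r.significant = bool(p_adj <= alpha)
    results.sort(key=lambda r: (np.isnan(r.p_adjusted), r.p_adjusted, r.feature))
    return results


def stats_table(results: list[StatTestResult]) -> pd.DataFrame:
    """Flatten StatTestResults into a DataFrame (mirrors the stats CSV)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "level": [r.level for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_high": [r.n_high for r in results],
            "n_weak": [r.n_weak for r in results],
            "mean_high": [r.mean_high for r in results],
            "mean_weak": [r.mean_weak for r in results],
            "significant": [r.significant for r in results],
            "testable": [r.testable for r in results],
        }
    )


class IDGroupAnalysis:
    """Model-style wrapper: configure the comparison, fit() runs it."""

    def __init__(self, tables: list[pd.DataFrame], level: str = "residue",
                 pooling: str = "pooled", alpha: float = ALPHA) -> None:
        self.tables = tables
        self.level = level
        self.pooling = pooling
        self.alpha = alpha

    def fit(self) -> "IDGroupAnalysisResults":
        results = run_analysis(self.tables, level=self.level,
                               pooling=self.pooling, alpha=self.alpha)
        return IDGroupAnalysisResults(results, self)


class IDGroupAnalysisResults:
    def __init__(self, results: list[StatTestResult], model: IDGroupAnalysis) -> None:
        self.results = results
        self.model = model
        self.table = stats_table(results)

    def summary(self) -> str:
        sig = self.table[self.table["significant"]]
        lines = [
            f"High- vs weak-ID comparison ({self.model.level} level, "
            f"{self.model.pooling} pooling)",
            f"features tested: {int(self.table['testable'].sum())} "
            f"(of {len(self.table)}), significant at BH alpha={self.model.alpha}: "
            f"{len(sig)}",
            "",
            self.table.drop(columns=["level"]).to_string(index=False,
                                                         float_format="%.4g"),
        ]
        return "\n".join(lines)
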