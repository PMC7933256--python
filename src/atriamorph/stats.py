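"""Cohort statistics: rank correlations, group tests, LVA association report.

The association analysis relates the per-segment wall deviations D, the
global remodeling surrogates (LAV, ASI, LAS) and the number of low-voltage
segments per patient.  Conventions:

* all p-values are two-tailed; significance is flagged at α = 0.05;
* no multiple-testing correction is applied by default (a Benjamini–Hochberg
  flag exists for reuse);
* Spearman p is an exact permutation value for n ≤ 10 and the Student-t
  approximation above; Wilcoxon tests use the exact null for small samples
  and the continuity-corrected normal approximation otherwise;
* the "extended LVA" group contrast compares patients with low voltage in
  all six segments against patients with 1–3 affected segments (counts of
  0, 4 and 5 are outside that contrast) with an equal-variance Student t by
  default (Welch by flag);
* Kolmogorov–Smirnov normality screening is a descriptive flag only — it
  never switches a test automatically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import SEGMENTS

ALPHA = 0.05
_EXACT_SPEARMAN_N = 10
_EXACT_WILCOXON_N = 12


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Returns ``(r, p)``; p is two-tailed, from exact enumeration of all rank
    permutations for n ≤ 10 and from the t approximation otherwise.

    Raises
    ------
    ValueError
        For n < 3 or a constant input (undefined correlation).
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    nx = np.linalg.norm(cx)
    ny = np.linalg.norm(cy)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("spearman undefined for a constant vector")
    r = float(cx @ cy / (nx * ny))

    if n <= _EXACT_SPEARMAN_N:
        p = _exact_permutation_p(cx, cy, nx * ny, abs(r))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def _exact_permutation_p(cx, cy, denom, r_abs, chunk=40320) -> float:
    """Two-tailed permutation p: share of rank permutations of y with
    |r| >= |r_observed| (the identity permutation is included)."""
    n = len(cx)
    thresh = r_abs * denom - 1e-12 * denom
    count = 0
    total = 0
    perms = itertools.permutations(cy)
    while True:
        block = np.array(list(itertools.islice(perms, chunk)))
        if block.size == 0:
            break
        dots = np.abs(block @ cx)
        count += int((dots >= thresh).sum())
        total += len(block)
    return count / total


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation; two-tailed p (exact beta null)."""
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise ValueError("pearson needs n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("pearson undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def t_test(
    a, b, paired: bool = False, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Student's t test, returning ``(t, df, p)`` with two-tailed p.

    ``paired`` uses the one-sample test on differences; otherwise the pooled
    equal-variance statistic (the default, matching classical usage) or Welch
    with ``equal_variance=False``.

    Raises
    ------
    ValueError
        For group sizes < 2 or a degenerate paired test (zero-variance
        differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired t-test needs equal-length samples")
        if len(a) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        d = a - b
        if np.allclose(d, d[0]) and not np.allclose(d, 0.0):
            raise ValueError("degenerate paired t-test: zero-variance differences")
        if np.allclose(d, 0.0):
            return 0.0, float(len(a) - 1), 1.0
        res = sps.ttest_rel(a, b)
        df = float(len(a) - 1)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        res = sps.ttest_ind(a, b, equal_var=equal_variance)
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def wilcoxon(a, b=None, mode: str = "signed_rank") -> tuple[float, float]:
    """Wilcoxon tests: ``signed_rank`` (paired) or ``rank_sum`` (two groups).

    Exact null distribution for small samples (combined n ≤ 12), otherwise
    the normal approximation with continuity correction.  Zero differences
    are dropped in the signed-rank test; all-zero differences raise.
    """
    a = np.asarray(a, dtype=float)
    if mode == "signed_rank":
        if b is None:
            d = a
        else:
            b = np.asarray(b, dtype=float)
            if a.shape != b.shape:
                raise ValueError("signed-rank test needs equal-length samples")
            d = a - b
        d = d[d != 0.0]
        if len(d) == 0:
            raise ValueError("signed-rank test undefined: all differences are zero")
        method = "exact" if len(d) <= _EXACT_WILCOXON_N else "approx"
        try:
            res = sps.wilcoxon(d, method=method, correction=(method == "approx"))
        except ValueError:
            res = sps.wilcoxon(d, method="approx", correction=True)
        return float(res.statistic), float(res.pvalue)
    if mode == "rank_sum":
        if b is None:
            raise ValueError("rank_sum mode needs two samples")
        b = np.asarray(b, dtype=float)
        method = "exact" if len(a) + len(b) <= _EXACT_WILCOXON_N else "asymptotic"
        try:
            res = sps.mannwhitneyu(a, b, method=method, use_continuity=True)
        except ValueError:
            res = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown wilcoxon mode {mode!r}")


def chi_square(table, yates: bool = False) -> tuple[float, float, float]:
    """Pearson chi-square on a 2×k contingency table: ``(χ², df, p)``.

    No continuity correction by default; ``yates=True`` applies it.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency table must be 2-d with nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin is all zero")
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.dof), float(res.pvalue)


def ks_normality(x) -> tuple[float, float]:
    """Kolmogorov–Smirnov screen against a fitted normal (descriptive only)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0.0:
        raise ValueError("normality screen needs n >= 3 non-constant values")
    z = (x - x.mean()) / x.std(ddof=1)
    res = sps.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (step-up), monotone."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cohort table and association report

GLOBAL_METRICS = ("LAV", "ASI", "LAS")
D_COLUMNS = tuple(f"D_{s}" for s in SEGMENTS)
LVA_COLUMNS = tuple(f"lva_{s}" for s in SEGMENTS)
REQUIRED_COLUMNS = (
    "patient_id",
    "LAV",
    "LA_A",
    "LA_P",
    "ASI",
    "AR",
    "S",
    "LAS",
    *D_COLUMNS,
    *LVA_COLUMNS,
    "lva_segment_count",
)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, id uniqueness and the label-count identity."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table["patient_id"].duplicated().any():
        raise ValueError("cohort table has duplicated patient ids")
    counts = table[list(LVA_COLUMNS)].sum(axis=1)
    if not (counts == table["lva_segment_count"]).all():
        raise ValueError("lva_segment_count does not equal the label sum")
    return table


@dataclass
class AssociationConfig:
    alpha: float = ALPHA
    welch: bool = False
    bh_correction: bool = False
    extended_count: int = 6
    comparator_counts: tuple[int, ...] = (1, 2, 3)


@dataclass
class AssociationReport:
    """Three labelled families of results.

    ``count_correlations``: Spearman of each metric vs the LVA segment count.
    ``pairwise_correlations``: Spearman grid among D values and vs LAV/ASI/LAS.
    ``group_contrasts``: extended-LVA vs 1–3-segment group t-tests on each D.
    """

    count_correlations: pd.DataFrame
    pairwise_correlations: pd.DataFrame
    group_contrasts: pd.DataFrame
    n_patients: int
    config: AssociationConfig = field(default_factory=AssociationConfig)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_patients": self.n_patients,
            "alpha": self.config.alpha,
            "count_correlations": self.count_correlations.to_dict("records"),
            "pairwise_correlations": self.pairwise_correlations.to_dict("records"),
            "group_contrasts": self.group_contrasts.to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)

    def to_csv(self, path: str | Path) -> None:
        frames = []
        for fam, df in (
            ("count_correlation", self.count_correlations),
            ("pairwise_correlation", self.pairwise_correlations),
            ("group_contrast", self.group_contrasts),
        ):
            d = df.copy()
            d.insert(0, "family", fam)
            frames.append(d)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def plot_deviation_by_count(self, path: str | Path | None = None):
        """Per-segment wall deviation against LVA segment count (the
        association the analysis is about), one panel per segment."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self._table
        fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
        for ax, seg in zip(axes.ravel(), SEGMENTS):
            ax.scatter(df["lva_segment_count"], df[f"D_{seg}"], s=12, alpha=0.7)
            ax.axhline(0.0, color="grey", lw=0.5)
            ax.set_title(seg.replace("_", " "))
            ax.set_ylabel("D (mm)")
        for ax in axes[1]:
            ax.set_xlabel("LVA segments (n)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _maybe_spearman(x, y) -> tuple[float, float, bool]:
    try:
        r, p = spearman(x, y)
        return r, p, True
    except ValueError:
        return float("nan"), float("nan"), False


def lva_association_analysis(
    table: pd.DataFrame, config: AssociationConfig | None = None
) -> AssociationReport:
    """Full association battery over a validated cohort table.

    Contrasts whose groups are too small (or correlations against a constant
    vector) are reported as not-computable rows, never raised.
    """
    config = config or AssociationConfig()
    table = validate_cohort_table(table).reset_index(drop=True)
    count = table["lva_segment_count"].to_numpy(dtype=float)
    metrics = [*D_COLUMNS, *GLOBAL_METRICS]

    rows = []
    for m in metrics:
        r, p, ok = _maybe_spearman(table[m].to_numpy(), count)
        rows.append(
            {"metric": m, "versus": "lva_segment_count", "r": r, "p": p,
             "n": len(table), "computable": ok}
        )
    count_corr = pd.DataFrame(rows)

    rows = []
    for i, m1 in enumerate(D_COLUMNS):
        for m2 in [*D_COLUMNS[i + 1:], *GLOBAL_METRICS]:
            r, p, ok = _maybe_spearman(
                table[m1].to_numpy(), table[m2].to_numpy()
            )
            rows.append(
                {"metric": m1, "versus": m2, "r": r, "p": p,
                 "n": len(table), "computable": ok}
            )
    pairwise = pd.DataFrame(rows)

    ext = table[table["lva_segment_count"] == config.extended_count]
    cmp_ = table[table["lva_segment_count"].isin(config.comparator_counts)]
    rows = []
    for m in D_COLUMNS:
        a = ext[m].to_numpy()
        b = cmp_[m].to_numpy()
        row = {
            "metric": m,
            "n_extended": len(a),
            "n_comparator": len(b),
            "mean_extended": float(np.mean(a)) if len(a) else float("nan"),
            "sd_extended": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
            "mean_comparator": float(np.mean(b)) if len(b) else float("nan"),
            "sd_comparator": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
        }
        try:
            t, df, p = t_test(a, b, paired=False, equal_variance=not config.welch)
            row.update(t=t, df=df, p=p, computable=True)
        except ValueError:
            row.update(t=float("nan"), df=float("nan"), p=float("nan"),
                       computable=False)
        rows.append(row)
    contrasts = pd.DataFrame(rows)

    for df_ in (count_corr, pairwise, contrasts):
        p = df_["p"].to_numpy(dtype=float)
        if config.bh_correction:
            mask = ~np.isnan(p)
            adj = p.copy()
            if mask.any():
                adj[mask] = benjamini_hochberg(p[mask])
            df_["p_adjusted"] = adj
            p = adj
        df_["significant"] = p < config.alpha

    report = AssociationReport(
        count_corr, pairwise, contrasts, n_patients=len(table), config=config
    )
    report._table = table  # for plotting
    return report
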