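"""Three-group differential expression: one-way ANOVA with Benjamini-Hochberg
correction, TukeyHSD post-hoc contrasts, and linear fold-change calls.

Genes are tested one at a time with sample class as the single fixed factor.
Genes passing the BH-adjusted ANOVA (q < alpha) are carried into a TukeyHSD
post-hoc comparison of every class pair; a pair is called differential when
the post-hoc p is below ``p_cut`` and the linear fold change, back-transformed
from the difference of log2 class means (2^|delta|), is at least ``fc_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .matrix import LOG2, ExpressionMatrix, StateError


def anova_bh(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene one-way fixed-effects ANOVA with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``F_stat``, ``p_anova``,
    ``q_anova``. A gene with zero between-group and zero within-group variance
    is uninformative and assigned F = 0, p = 1.
    """
    if m.space != LOG2:
        raise StateError("ANOVA expects log2-space values")
    classes = m.class_names
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups = []
    for cls in classes:
        cols = m.samples_of(cls)
        if len(cols) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        groups.append(m.values[cols].to_numpy(dtype=float))
    n_total = sum(g.shape[1] for g in groups)
    k = len(groups)
    grand = np.hstack(groups).mean(axis=1)
    ss_between = np.zeros(len(grand))
    ss_within = np.zeros(len(grand))
    for g in groups:
        gm = g.mean(axis=1)
        ss_between += g.shape[1] * (gm - grand) ** 2
        ss_within += ((g - gm[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w), 0.0)
    degenerate = (ss_within <= 0) & (ss_between <= 0)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.DataFrame({"F_stat": f, "p_anova": p, "q_anova": q}, index=m.values.index)


_SR_EXACT_LIMIT = 256  # exact quadrature below this batch size
_SR_GRID_MAX = 30.0    # sf is ~1e-12 here for moderate df; clamp beyond
_SR_GRID_POINTS = 160


@lru_cache(maxsize=32)
def _sr_log_sf_interp(k: int, df: int) -> PchipInterpolator:
    grid = np.linspace(0.0, _SR_GRID_MAX, _SR_GRID_POINTS)
    sf = np.clip(stats.studentized_range.sf(grid, k, df), 1e-300, 1.0)
    return PchipInterpolator(grid, np.log(sf))


def _studentized_range_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Upper tail of the studentized range; grid-interpolated for large batches.

    The scipy quadrature is exact but costs milliseconds per point; large
    batches share a cached monotone PCHIP interpolant of log sf per (k, df).
    The log sf is monotone and smooth, so the interpolation error is far below
    any decision threshold used downstream.
    """
    q = np.asarray(q, dtype=float)
    finite = np.isfinite(q)
    out = np.zeros_like(q)
    if q.size <= _SR_EXACT_LIMIT:
        out[finite] = stats.studentized_range.sf(np.clip(q[finite], 0, None), k, df)
        return out
    interp = _sr_log_sf_interp(int(k), int(df))
    out[finite] = np.exp(interp(np.clip(q[finite], 0.0, _SR_GRID_MAX)))
    return out


def tukey_posthoc(m: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """TukeyHSD mean differences and p-values for every class pair.

    *genes* restricts the computation (typically to the q < 0.05 ANOVA subset;
    ``None`` means all genes). The statistic is the Tukey-Kramer studentized
    range q = |mean_a - mean_b| / sqrt(MSE/2 * (1/n_a + 1/n_b)) with MSE the
    ANOVA pooled within-class variance, referred to the studentized range
    distribution with k groups and N - k degrees of freedom.

    Returns a long DataFrame with columns ``gene_id``, ``class_a``,
    ``class_b``, ``mean_diff_log2`` (mean_a - mean_b), ``p_posthoc``.
    """
    if m.space != LOG2:
        raise StateError("TukeyHSD expects log2-space values")
    classes = m.class_names
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    sub = m if genes is None else m.subset_genes(genes)
    if sub.values.shape[0] == 0:
        return pd.DataFrame(columns=["gene_id", "class_a", "class_b",
                                     "mean_diff_log2", "p_posthoc"])
    means, ns, sse = {}, {}, np.zeros(sub.values.shape[0])
    for cls in classes:
        cols = sub.samples_of(cls)
        g = sub.values[cols].to_numpy(dtype=float)
        means[cls] = g.mean(axis=1)
        ns[cls] = g.shape[1]
        sse += ((g - means[cls][:, None]) ** 2).sum(axis=1)
    n_total = sum(ns.values())
    k = len(classes)
    df_w = n_total - k
    mse = sse / df_w
    rows = []
    for a, b in combinations(classes, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.abs(diff) / se
        p = np.ones_like(diff)
        pos = se > 0
        p[pos] = _studentized_range_sf(qstat[pos], k, df_w)
        # zero pooled variance: identical means -> p = 1, distinct -> p = 0
        p[~pos & (np.abs(diff) > 0)] = 0.0
        rows.append(pd.DataFrame({
            "gene_id": sub.values.index,
            "class_a": a,
            "class_b": b,
            "mean_diff_log2": diff,
            "p_posthoc": p,
        }))
    return pd.concat(rows, ignore_index=True)


def call_de(posthoc: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 1.5) -> pd.DataFrame:
    """Flag significant contrasts: post-hoc p < p_cut and 2^|diff| >= fc_cut.

    Adds ``linear_fc`` (2^|mean_diff_log2|, always >= 1), ``significant`` and
    ``direction`` (+1 when class_a exceeds class_b, -1 otherwise, 0 at equal
    means; a zero difference is never called).
    """
    out = posthoc.copy()
    out["linear_fc"] = 2.0 ** np.abs(out["mean_diff_log2"].to_numpy(dtype=float))
    out["direction"] = np.sign(out["mean_diff_log2"].to_numpy(dtype=float)).astype(int)
    out["significant"] = (
        (out["p_posthoc"] < p_cut)
        & (out["linear_fc"] >= fc_cut)
        & (out["direction"] != 0)
    )
    return out


@dataclass
class DEResult:
    """Bundle of the DE pipeline outputs.

    ``anova``: per-gene F/p/q. ``pairwise``: TukeyHSD table restricted to the
    ANOVA-significant genes, with fold changes and call flags. ``alpha`` /
    ``p_cut`` / ``fc_cut`` record the thresholds used.
    """

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float
    p_cut: float
    fc_cut: float

    def gene_lists(self, contrast: tuple[str, str]) -> tuple[list[str], list[str]]:
        """Up- and down-regulated gene lists for contrast (test, reference)."""
        a, b = contrast
        sub = _orient(self.pairwise, a, b)
        called = sub[sub["significant"]]
        up = sorted(called.loc[called["mean_diff_log2"] > 0, "gene_id"])
        down = sorted(called.loc[called["mean_diff_log2"] < 0, "gene_id"])
        return up, down


def _orient(pairwise: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Return the pairwise table oriented as contrast a - b."""
    direct = pairwise[(pairwise["class_a"] == a) & (pairwise["class_b"] == b)]
    if len(direct):
        return direct.copy()
    flipped = pairwise[(pairwise["class_a"] == b) & (pairwise["class_b"] == a)].copy()
    if not len(flipped):
        raise ValueError(f"contrast ({a}, {b}) not present in post-hoc table")
    flipped["mean_diff_log2"] = -flipped["mean_diff_log2"]
    flipped[["class_a", "class_b"]] = [a, b]
    if "direction" in flipped:
        flipped["direction"] = -flipped["direction"]
    return flipped


def de_pipeline(m: ExpressionMatrix, alpha: float = 0.05, p_cut: float = 0.05,
                fc_cut: float = 1.5) -> DEResult:
    """ANOVA + BH, TukeyHSD on the q < alpha subset, then fold-change calls."""
    anova = anova_bh(m)
    significant = anova.index[anova["q_anova"] < alpha]
    posthoc = tukey_posthoc(m, genes=significant)
    pairwise = call_de(posthoc, p_cut=p_cut, fc_cut=fc_cut)
    return DEResult(anova, pairwise, alpha, p_cut, fc_cut)
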