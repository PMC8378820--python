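"""Gene-set enrichment: weighted Kolmogorov-Smirnov enrichment score, NES via
gene-set permutation, permutation p-values, GSEA-style FDR, and
opposite-direction restoration classification across two contrasts.

The enrichment score (ES) walks the ranked gene list: set members (hits)
increment the running sum by their |score|^p weight normalized over the set's
hits; non-members decrement by 1/(N - |S|). ES is the signed maximum
deviation of the running sum. The null distribution comes from random gene
sets of the same size drawn from the ranked list; NES divides ES by the mean
magnitude of same-sign null ES values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult, _orient


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> list[GeneSet]:
    """Read tab-separated GMT records: name, description, members..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            # keep first occurrence of each member, preserving order
            members = tuple(dict.fromkeys(g for g in parts[2:] if g))
            sets.append(GeneSet(parts[0], parts[1], members))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def rank_genes(de: DEResult, contrast: tuple[str, str],
               posthoc_all: pd.DataFrame | None = None) -> pd.Series:
    """Ranked scores s = sign(mean_diff_log2) * (-log10 p_posthoc), descending.

    *posthoc_all* supplies post-hoc statistics for every gene of the contrast
    (the DE pipeline's pairwise table only covers ANOVA-significant genes,
    which is too sparse a universe for enrichment). Ties break by gene id
    lexicographic order; p = 0 is replaced by the smallest positive double.
    """
    table = posthoc_all if posthoc_all is not None else de.pairwise
    a, b = contrast
    sub = _orient(table, a, b)
    p = np.clip(sub["p_posthoc"].to_numpy(dtype=float), np.nextafter(0, 1), 1.0)
    scores = np.sign(sub["mean_diff_log2"].to_numpy(dtype=float)) * (-np.log10(p))
    ranked = pd.Series(scores, index=sub["gene_id"].to_numpy())
    order = sorted(range(len(ranked)), key=lambda i: (-ranked.iloc[i], ranked.index[i]))
    return ranked.iloc[order]


def _es_core(hit_pos: np.ndarray, hit_weights: np.ndarray, n: int) -> float:
    """ES from sorted 0-based hit positions and their unnormalized weights."""
    k = hit_pos.size
    miss_step = 1.0 / (n - k)
    total = hit_weights.sum()
    if total > 0:
        w = hit_weights / total
    else:  # all-zero scores: equal hit weights
        w = np.full(k, 1.0 / k)
    cum = np.cumsum(w)
    after = cum - (hit_pos + 1 - np.arange(1, k + 1)) * miss_step
    before = np.concatenate([[0.0], cum[:-1]]) - (hit_pos - np.arange(k)) * miss_step
    cand = np.concatenate([after, before])
    return _signed_extreme(cand)


def _signed_extreme(values: np.ndarray) -> float:
    """Value of maximum magnitude; a +x / -x tie (to fp tolerance) resolves
    positive, so the convention is stable under summation-order noise."""
    hi = float(values.max(initial=0.0))
    lo = float(values.min(initial=0.0))
    return hi if hi >= -lo - 1e-12 else lo


def enrichment_score(ranked: pd.Series, gene_set: GeneSet,
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set.

    Raises when no member is present in the ranked list or when the set spans
    the whole list (the miss denominator would be zero).
    """
    n = len(ranked)
    members = set(gene_set.genes)
    is_hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=n)
    k = int(is_hit.sum())
    if k == 0:
        raise ValueError(f"no member of {gene_set.name!r} is in the ranked list")
    if k == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the entire ranked list")
    scores = ranked.to_numpy(dtype=float)
    w = np.abs(scores) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        hit_w = hit_w / total
    else:
        hit_w = np.where(is_hit, 1.0 / k, 0.0)
    steps = np.where(is_hit, hit_w, -1.0 / (n - k))
    running = np.cumsum(steps)
    return _signed_extreme(running), running


def _null_es(scores: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator, weight: float) -> np.ndarray:
    """Null ES values from random same-size gene sets (vectorized)."""
    n = scores.size
    w_all = np.abs(scores) ** weight
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        out[i] = _es_core(pos, w_all[pos], n)
    return out


def _signed_p(es: float, null: np.ndarray) -> float:
    """Permutation p against the same-sign null tail (uniform under the null)."""
    if es >= 0:
        same = null[null >= 0]
        extreme = int((same >= es).sum())
    else:
        same = null[null < 0]
        extreme = int((same <= es).sum())
    return (1 + extreme) / (len(same) + 1)


def _nes(es: float, null: np.ndarray) -> float:
    same = null[null >= 0] if es >= 0 else null[null < 0]
    denom = float(np.mean(np.abs(same))) if same.size else 0.0
    if not (np.isfinite(denom) and denom > 0):
        denom = float(np.mean(np.abs(null))) if null.size else 1.0
    return es / denom if denom > 0 else 0.0


def nes_and_fdr(ranked: pd.Series, gene_sets, n_perm: int = 1000,
                seed: int = 0, weight: float = 1.0) -> pd.DataFrame:
    """ES, NES, permutation p and GSEA-style FDR q for a gene-set collection.

    Gene-set permutation: each set's null is n_perm random same-size subsets
    of the ranked list. FDR q compares the observed NES distribution to the
    pooled null NES distribution tail-wise (Subramanian-style), clipped to
    [0, 1]. ``significant`` marks p < 0.05 and q <= 0.25.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    gene_sets = list(gene_sets)
    scores = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    # share one null per distinct effective set size
    present_sizes = {}
    for s in sorted(gene_sets, key=lambda s: s.name):
        members = set(s.genes) & set(ranked.index)
        present_sizes[s.name] = len(members)
    nulls = {}
    for size in sorted(set(present_sizes.values())):
        if size > 0:
            nulls[size] = _null_es(scores, size, n_perm, rng, weight)
    rows = []
    null_nes_pool = []
    for s in gene_sets:
        size = present_sizes[s.name]
        es, _ = enrichment_score(ranked, s, weight)
        null = nulls[size]
        nes = _nes(es, null)
        p = _signed_p(es, null)
        rows.append({"set": s.name, "size": size, "ES": es, "NES": nes,
                     "p_perm": p, "n_perm": n_perm})
        pos_mean = np.mean(null[null >= 0]) if (null >= 0).any() else np.nan
        neg_mean = np.mean(np.abs(null[null < 0])) if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0,
                            null / pos_mean if pos_mean else np.nan,
                            null / neg_mean if neg_mean else np.nan)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs = np.array([r["NES"] for r in rows])
    for r in rows:
        r["q_fdr"] = _gsea_fdr(r["NES"], obs, pool)
        r["significant"] = bool(r["p_perm"] < 0.05 and r["q_fdr"] <= 0.25)
    out = pd.DataFrame(rows).set_index("set")
    return out


def _gsea_fdr(nes: float, obs: np.ndarray, pool: np.ndarray) -> float:
    """Tail-wise ratio of null to observed NES exceedance fractions."""
    if pool.size == 0:
        return 1.0
    if nes >= 0:
        null_tail = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
        obs_tail = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
    else:
        null_tail = (pool <= nes).sum() / max((pool < 0).sum(), 1)
        obs_tail = (obs <= nes).sum() / max((obs < 0).sum(), 1)
    if obs_tail == 0:
        return 0.0
    return float(min(1.0, null_tail / obs_tail))


def classify_restored(dis_vs_ctrl: pd.DataFrame, trt_vs_dis: pd.DataFrame) -> pd.DataFrame:
    """Flag disease-significant sets rescued in the treatment contrast.

    A set significant in disease-vs-control is *restored* iff it is also
    significant in treated-vs-disease with opposite NES sign. Returns the
    disease table with ``restored`` plus a ``summary`` attribute holding
    counts and fractions per direction (down = NES < 0 in disease).
    """
    if set(dis_vs_ctrl.index) != set(trt_vs_dis.index):
        raise ValueError("the two contrasts were run on different gene-set collections")
    out = dis_vs_ctrl.copy()
    trt = trt_vs_dis.reindex(out.index)
    opposite = np.sign(out["NES"]) * np.sign(trt["NES"]) < 0
    out["restored"] = out["significant"] & trt["significant"] & opposite
    summary = {}
    for direction, mask in (("down", out["NES"] < 0), ("up", out["NES"] >= 0)):
        sig = out["significant"] & mask
        restored = out["restored"] & mask
        n_sig, n_res = int(sig.sum()), int(restored.sum())
        summary[direction] = {
            "n_significant": n_sig,
            "n_restored": n_res,
            "fraction_restored": n_res / n_sig if n_sig else 0.0,
        }
    out.attrs["summary"] = summary
    return out
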