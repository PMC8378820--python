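"""Per-gene isoform proportions and relative isoform expression from
transcript-level quantification tables.

Quantifications live in a long DataFrame with columns ``transcript_id``,
``gene_id``, ``sample_id``, ``abundance`` (counts or TPM, nonnegative).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("transcript_id", "gene_id", "sample_id", "abundance")

TRANSFORMS = {
    "log1p": np.log1p,
    "identity": lambda a: a,
}


def validate_quants(q: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in q.columns]
    if missing:
        raise ValueError(f"quantification table lacks columns {missing}")
    if q.duplicated(["transcript_id", "sample_id"]).any():
        raise ValueError("duplicate (transcript, sample) rows")
    a = q["abundance"].to_numpy(dtype=float)
    if not np.all(np.isfinite(a)) or a.min(initial=0) < 0:
        raise ValueError("abundances must be finite and nonnegative")
    return q


def read_quant_tables(paths, sample_ids=None, tx2gene: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combine per-sample quantification TSVs into the long format.

    Column dialects are auto-detected: transcript id from ``Name`` or
    ``transcript_id``; gene id from ``gene_id`` or via a transcript-to-gene
    map (columns ``transcript_id``, ``gene_id``); abundance from ``NumReads``,
    ``TPM`` or ``abundance``.
    """
    frames = []
    mapping = None
    if tx2gene is not None:
        mapping = dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
    for i, path in enumerate(paths):
        tab = pd.read_csv(path, sep="\t")
        tx_col = "Name" if "Name" in tab.columns else "transcript_id"
        ab_col = next((c for c in ("NumReads", "TPM", "abundance") if c in tab.columns), None)
        if tx_col not in tab.columns or ab_col is None:
            raise ValueError(f"unrecognized quantification dialect in {path}")
        frame = pd.DataFrame({
            "transcript_id": tab[tx_col],
            "abundance": tab[ab_col].astype(float),
        })
        if "gene_id" in tab.columns:
            frame["gene_id"] = tab["gene_id"]
        elif mapping is not None:
            frame["gene_id"] = frame["transcript_id"].map(mapping)
        else:
            raise ValueError("no gene_id column and no transcript-to-gene map supplied")
        frame["sample_id"] = sample_ids[i] if sample_ids else f"sample_{i + 1}"
        frames.append(frame)
    return validate_quants(pd.concat(frames, ignore_index=True))


def isoform_proportions(q: pd.DataFrame, gene: str, transform: str = "log1p") -> pd.Series:
    """Mean per-sample isoform share for one gene, in percent (sums to 100).

    Per sample, share_i = t(a_i) / sum_j t(a_j) with t the chosen transform
    (``log1p`` matches a log-normalized-counts display; ``identity`` estimates
    linear abundance shares). Samples with zero total transformed abundance
    are excluded; a gene with no usable sample is an error.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(TRANSFORMS)}")
    t = TRANSFORMS[transform]
    validate_quants(q)
    sub = q[q["gene_id"] == gene]
    if not len(sub):
        raise ValueError(f"no transcripts for gene {gene!r}")
    wide = sub.pivot(index="transcript_id", columns="sample_id", values="abundance").fillna(0.0)
    transformed = t(wide.to_numpy(dtype=float))
    totals = transformed.sum(axis=0)
    usable = totals > 0
    if not usable.any():
        raise ValueError(f"gene {gene!r} has zero total abundance in every sample")
    shares = transformed[:, usable] / totals[usable]
    return pd.Series(shares.mean(axis=1) * 100.0, index=wide.index, name="share_percent")


def relative_isoform_level(q: pd.DataFrame, target_tx: str, reference_tx: str,
                           classes: pd.Series | None = None) -> dict:
    """Per-sample target/reference abundance ratios with mean +- SEM.

    Samples where the reference is zero are dropped with a warning; when a
    *classes* Series (sample -> group) is given, per-group summaries are
    returned as well.
    """
    validate_quants(q)
    wide = q.pivot(index="transcript_id", columns="sample_id", values="abundance")
    for tx in (target_tx, reference_tx):
        if tx not in wide.index:
            raise ValueError(f"transcript {tx!r} absent from the table")
    target = wide.loc[target_tx].astype(float)
    reference = wide.loc[reference_tx].astype(float)
    ok = reference > 0
    dropped = list(reference.index[~ok])
    if dropped:
        warnings.warn(f"samples dropped (zero reference abundance): {dropped}")
    if not ok.any():
        raise ValueError("reference transcript has zero abundance in every sample")
    ratios = (target[ok] / reference[ok]).rename("ratio")
    result = {"ratios": ratios, "n": int(ok.sum()),
              "mean": float(ratios.mean()), "sem": _sem(ratios.to_numpy())}
    if classes is not None:
        groups = {}
        for cls, idx in classes.reindex(ratios.index).groupby(classes.reindex(ratios.index)).groups.items():
            vals = ratios.loc[idx].to_numpy()
            groups[cls] = {"n": len(vals), "mean": float(vals.mean()), "sem": _sem(vals)}
        result["by_class"] = groups
    return result


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))
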