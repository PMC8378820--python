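"""Synthetic inputs with planted ground truth for every pipeline stage.

The count generator emulates a three-group (control / disease / treated)
bulk RNA-seq study of a transcriptional-rescue experiment: negative-binomial
counts (variance mu + alpha*mu^2) around log-normal baseline means, a planted
fraction of disease-dysregulated genes shifted by +-effect_log2, of which a
planted fraction is restored (treated class back at control means) while the
rest stay at disease levels. Optional CV inflation below a chosen expression
level plants a recoverable noise floor. Companion generators emit gene-set
collections drawn from the planted gene classes, promoter sequences with
planted motif occurrences, transcript mixtures with fixed isoform shares, and
noisy plate readings around known assay values.

All randomness flows from one root seed through named substreams, so adding a
generator never perturbs the outputs of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gsea import GeneSet, write_gmt
from .matrix import ExpressionMatrix, write_sample_sheet

_LN2 = np.log(2.0)

# fixed substream ids: the root seed is combined with these so that streams
# are independent and stable as generators are added
_STREAMS = {
    "counts": 11,
    "gene_sets": 12,
    "promoters": 13,
    "isoforms": 14,
    "assays": 15,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for all generators. Fractions are in [0, 1]."""

    # expression study
    n_genes: int = 2000
    classes: tuple[str, str, str] = ("control", "disease", "treated")
    n_per_group: int = 6
    frac_dysregulated: float = 0.2
    frac_up_among_dys: float = 0.5
    frac_restored: float = 0.6
    effect_log2: float = 1.5
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.8
    partial_restoration: float = 0.0  # fraction of the disease effect retained after treatment
    # noise-floor injection (off unless floor_mean is set)
    floor_mean: float | None = None  # pedestal-log2 expression level
    cv_inflation: float = 5.0
    pedestal: float = 2.0
    # gene sets
    n_rescued_sets: int = 20
    n_unrescued_sets: int = 10
    set_size: int = 30
    # promoters
    n_promoters: int = 200
    promoter_length: int = 1100
    planted_motif_fraction: float = 0.3
    motif_consensus: str = "GGTACAAAATGTTCT"
    # isoform mixtures
    isoform_shares: tuple[float, ...] = (0.17, 0.83)
    n_isoform_samples: int = 6
    isoform_total_mean: float = 1000.0
    # plate assays
    assay_cv: float = 0.05
    assay_replicates: int = 6
    true_bret_ratio_exp: float = 0.30
    true_bret_ratio_ctrl: float = 0.25
    true_rlu_fold: float = 4.0
    true_qpcr_fold: float = 2.0
    true_chip_percent_input: float = 50.0
    true_copy_ratio: float = 0.202
    seed: int = 1

    def __post_init__(self):
        fracs = {
            "frac_dysregulated": self.frac_dysregulated,
            "frac_up_among_dys": self.frac_up_among_dys,
            "frac_restored": self.frac_restored,
            "planted_motif_fraction": self.planted_motif_fraction,
            "partial_restoration": self.partial_restoration,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if abs(sum(self.isoform_shares) - 1.0) > 1e-6:
            raise ValueError("isoform shares must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


# ---------------------------------------------------------------------------
# expression counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mu + alpha*mu^2 (shape n = 1/alpha)."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_counts(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Three-group NB count matrix plus a per-gene truth table.

    Truth columns: ``status`` in {null, dys_up, dys_down}; ``restored`` (bool,
    False for null genes); ``baseline_log2`` (pedestal-log2 of the control
    mean); ``noise_inflated`` (bool).
    """
    rng = _rng(cfg.seed, "counts")
    n = cfg.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]
    base_mu = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    n_dys = int(round(cfg.frac_dysregulated * n))
    dys_idx = rng.choice(n, size=n_dys, replace=False)
    n_up = int(round(cfg.frac_up_among_dys * n_dys))
    up_idx = dys_idx[:n_up]
    down_idx = dys_idx[n_up:]
    n_restored = int(round(cfg.frac_restored * n_dys))
    restored_idx = rng.permutation(dys_idx)[:n_restored]

    status = np.array(["null"] * n, dtype=object)
    status[up_idx] = "dys_up"
    status[down_idx] = "dys_down"
    restored = np.zeros(n, dtype=bool)
    restored[restored_idx] = True

    signed_effect = np.zeros(n)
    signed_effect[up_idx] = cfg.effect_log2
    signed_effect[down_idx] = -cfg.effect_log2

    class_means = {}
    for cls in cfg.classes:
        if cls == cfg.classes[0]:  # control
            shift = np.zeros(n)
        elif cls == cfg.classes[1]:  # disease
            shift = signed_effect
        else:  # treated: restored genes revert (up to partial retention)
            shift = np.where(restored, signed_effect * cfg.partial_restoration, signed_effect)
        # the effect is defined on the pedestal-log2 scale (the scale every
        # downstream stage works on), so the planted group difference of
        # log2(mu + pedestal) is exactly effect_log2 at every baseline
        class_means[cls] = np.clip(
            2.0 ** (np.log2(base_mu + cfg.pedestal) + shift) - cfg.pedestal, 0.0, None)

    inflated = np.zeros(n, dtype=bool)
    sigma_extra = np.zeros(n)
    if cfg.floor_mean is not None:
        log2_pedestal = np.log2(base_mu + cfg.pedestal)
        inflated = log2_pedestal < cfg.floor_mean
        # delta-method log2 SD of NB counts on the pedestal-log2 scale; the
        # extra jitter is applied on that same scale after the NB draw, so it
        # multiplies the log-space CV by cv_inflation without shifting the
        # gene's log2 mean (the planted floor boundary stays sharp)
        var_nb = base_mu + cfg.nb_dispersion * base_mu ** 2
        sd0 = np.sqrt(var_nb) / ((base_mu + cfg.pedestal) * _LN2)
        sigma_extra = np.where(inflated, sd0 * np.sqrt(cfg.cv_inflation ** 2 - 1.0), 0.0)

    columns, data = [], []
    for cls in cfg.classes:
        mu_cls = class_means[cls]
        for rep in range(cfg.n_per_group):
            counts = _nb_draw(rng, mu_cls, cfg.nb_dispersion)
            if inflated.any():
                jitter = rng.normal(0.0, 1.0, size=n) * sigma_extra
                noisy = (counts + cfg.pedestal) * 2.0 ** jitter - cfg.pedestal
                counts = np.where(inflated, np.clip(np.rint(noisy), 0.0, None), counts)
            data.append(counts)
            columns.append(f"{cls}_{rep + 1}")
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    classes = pd.Series([c.rsplit("_", 1)[0] for c in columns], index=columns, name="class")
    truth = pd.DataFrame({
        "status": status,
        "restored": restored,
        "baseline_log2": np.log2(base_mu + cfg.pedestal),
        "noise_inflated": inflated,
    }, index=genes)
    return ExpressionMatrix(values, classes, "linear"), truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(truth: pd.DataFrame, cfg: SyntheticConfig) -> tuple[list[GeneSet], pd.DataFrame]:
    """Direction-pure gene sets drawn from the planted gene classes.

    ``n_rescued_sets`` sets are sampled from restored dysregulated genes and
    ``n_unrescued_sets`` from non-restored dysregulated genes, alternating
    between the up- and down-regulated pools so both directions are covered.
    Returns the sets plus a truth table (set name -> rescued flag,
    direction).
    """
    rng = _rng(cfg.seed, "gene_sets")
    pools = {
        (True, "dys_up"): truth.index[(truth["status"] == "dys_up") & truth["restored"]],
        (True, "dys_down"): truth.index[(truth["status"] == "dys_down") & truth["restored"]],
        (False, "dys_up"): truth.index[(truth["status"] == "dys_up") & ~truth["restored"]],
        (False, "dys_down"): truth.index[(truth["status"] == "dys_down") & ~truth["restored"]],
    }
    sets, rows = [], []
    spec = [(True, i) for i in range(cfg.n_rescued_sets)] + \
           [(False, i) for i in range(cfg.n_unrescued_sets)]
    for number, (rescued, i) in enumerate(spec, start=1):
        direction = "dys_up" if i % 2 == 0 else "dys_down"
        pool = pools[(rescued, direction)]
        if len(pool) < cfg.set_size:
            raise ValueError(
                f"pool for rescued={rescued} {direction} has {len(pool)} genes"
                f" < set_size {cfg.set_size}")
        members = tuple(sorted(rng.choice(pool, size=cfg.set_size, replace=False)))
        name = f"set_{number:03d}"
        sets.append(GeneSet(name, "synthetic", members))
        rows.append({"set": name, "rescued": rescued,
                     "direction": "up" if direction == "dys_up" else "down"})
    return sets, pd.DataFrame(rows).set_index("set")


# ---------------------------------------------------------------------------
# promoters


def consensus_counts(consensus: str, match: float = 97.0, mismatch: float = 1.0) -> np.ndarray:
    """Sharply peaked count matrix for a consensus sequence."""
    from .motif import ALPHABET

    counts = np.full((len(consensus), 4), mismatch)
    for i, base in enumerate(consensus.upper()):
        counts[i, ALPHABET.index(base)] = match
    return counts


def simulate_promoters(cfg: SyntheticConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background promoter sequences with planted consensus motifs.

    A ``planted_motif_fraction`` of promoters receives the exact consensus at
    a recorded offset and strand. Truth columns: ``planted``, ``offset`` (-1
    when absent), ``strand``.
    """
    from .motif import ALPHABET, reverse_complement

    consensus = cfg.motif_consensus.upper()
    if not set(consensus) <= set(ALPHABET):
        raise ValueError("motif consensus must be over ACGT")
    if len(consensus) > cfg.promoter_length:
        raise ValueError("motif longer than the promoter")
    rng = _rng(cfg.seed, "promoters")
    n_planted = int(round(cfg.planted_motif_fraction * cfg.n_promoters))
    planted_flags = np.zeros(cfg.n_promoters, dtype=bool)
    planted_flags[rng.choice(cfg.n_promoters, size=n_planted, replace=False)] = True
    promoters, rows = {}, []
    bases = np.array(list(ALPHABET))
    for i in range(cfg.n_promoters):
        gene = f"prom{i + 1:04d}"
        seq = "".join(rng.choice(bases, size=cfg.promoter_length))
        offset, strand = -1, "."
        if planted_flags[i]:
            offset = int(rng.integers(0, cfg.promoter_length - len(consensus) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:offset] + insert + seq[offset + len(insert):]
        promoters[gene] = seq
        rows.append({"gene": gene, "planted": bool(planted_flags[i]),
                     "offset": offset, "strand": strand})
    return promoters, pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# isoform mixtures


def simulate_isoform_quants(cfg: SyntheticConfig, gene: str = "GENE",
                            ) -> tuple[pd.DataFrame, dict]:
    """Multinomial transcript mixtures around the planted isoform shares.

    Per sample the gene's total abundance is NB-distributed around
    ``isoform_total_mean`` and split multinomially by ``isoform_shares``.
    """
    rng = _rng(cfg.seed, "isoforms")
    shares = np.asarray(cfg.isoform_shares, dtype=float)
    tx_ids = [f"{gene}-tx{i + 1}" for i in range(len(shares))]
    rows = []
    for s in range(cfg.n_isoform_samples):
        sample = f"sample_{s + 1}"
        total = int(_nb_draw(rng, np.array([cfg.isoform_total_mean]), cfg.nb_dispersion)[0])
        counts = rng.multinomial(total, shares)
        for tx, c in zip(tx_ids, counts):
            rows.append({"transcript_id": tx, "gene_id": gene,
                         "sample_id": sample, "abundance": float(c)})
    truth = {"gene": gene, "transcripts": tx_ids,
             "shares_percent": list(100.0 * shares)}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# plate assays


def simulate_assays(cfg: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Noisy plate readings around known true assay values.

    Returns plate tables (``bret``, ``luciferase``, ``qpcr``, ``chip``,
    ``copies``) and a truth sidecar with the planted values. Multiplicative
    Gaussian noise with CV ``assay_cv``; ``assay_cv = 0`` reproduces the
    truth exactly.
    """
    rng = _rng(cfg.seed, "assays")
    reps = cfg.assay_replicates

    def noisy(value: float, n: int = reps) -> np.ndarray:
        return value * (1.0 + cfg.assay_cv * rng.normal(size=n))

    # BRET: fixed donor signal, acceptor set by the true ratio
    donor = 10000.0
    bret = pd.DataFrame({
        "well": [f"W{i + 1}" for i in range(2 * reps)],
        "condition": ["experimental"] * reps + ["no_ligand_control"] * reps,
        "em618": np.concatenate([noisy(cfg.true_bret_ratio_exp * donor),
                                 noisy(cfg.true_bret_ratio_ctrl * donor)]),
        "em460": np.concatenate([noisy(donor), noisy(donor)]),
    })
    # dual luciferase: baseline RLU 1, condition RLU = true fold
    renilla = 50.0
    luc = pd.DataFrame({
        "well": [f"W{i + 1}" for i in range(2 * reps)],
        "condition": ["baseline"] * reps + ["stimulated"] * reps,
        "firefly": np.concatenate([noisy(renilla), noisy(cfg.true_rlu_fold * renilla)]),
        "renilla": np.concatenate([noisy(renilla), noisy(renilla)]),
    })
    # qPCR: calibrator Cts fixed; sample target Ct shifted by -log2(fold)
    ct_ref, ct_tgt_cal = 20.0, 24.0
    ct_tgt_sample = ct_tgt_cal - np.log2(cfg.true_qpcr_fold)
    ct_noise = cfg.assay_cv * 2.0  # additive Ct noise, cycles
    qpcr = pd.DataFrame({
        "sample_id": ["calibrator"] * reps + ["sample"] * reps,
        "ct_target": np.concatenate([ct_tgt_cal + ct_noise * rng.normal(size=reps),
                                     ct_tgt_sample + ct_noise * rng.normal(size=reps)]),
        "ct_reference": ct_ref + ct_noise * rng.normal(size=2 * reps),
    })
    # ChIP: input fraction 1%, percent input planted
    input_fraction = 0.01
    ct_input = 22.0
    ct_adj = ct_input - np.log2(1.0 / input_fraction)
    ct_ip = ct_adj - np.log2(cfg.true_chip_percent_input / 100.0)
    chip = pd.DataFrame({
        "replicate": np.arange(1, reps + 1),
        "ct_ip": ct_ip + ct_noise * rng.normal(size=reps),
        "ct_input": ct_input + ct_noise * rng.normal(size=reps),
        "input_fraction": input_fraction,
    })
    # copy numbers per ng
    endo = 1000.0
    copies = pd.DataFrame({
        "replicate": np.arange(1, reps + 1),
        "exo_copies": noisy(cfg.true_copy_ratio * endo),
        "endo_copies": noisy(endo),
    })
    truth = {
        "mbu": (cfg.true_bret_ratio_exp - cfg.true_bret_ratio_ctrl) * 1000.0,
        "rlu_fold": cfg.true_rlu_fold,
        "qpcr_fold": cfg.true_qpcr_fold,
        "chip_percent_input": cfg.true_chip_percent_input,
        "copy_ratio": cfg.true_copy_ratio,
        "copy_percent_increase": 100.0 * cfg.true_copy_ratio,
    }
    return {"bret": bret, "luciferase": luc, "qpcr": qpcr,
            "chip": chip, "copies": copies}, truth


# ---------------------------------------------------------------------------
# bundle


def simulate_all(cfg: SyntheticConfig, outdir) -> None:
    """Write every synthetic input plus truth sidecars to *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m, truth = simulate_counts(cfg)
    m.to_tsv(out / "counts.tsv")
    write_sample_sheet(m.classes, out / "samples.csv")
    truth.to_csv(out / "genes_truth.tsv", sep="\t")
    sets, sets_truth = simulate_gene_sets(truth, cfg)
    write_gmt(sets, out / "gene_sets.gmt")
    sets_truth.to_csv(out / "gene_sets_truth.tsv", sep="\t")
    promoters, prom_truth = simulate_promoters(cfg)
    with open(out / "promoters.fa", "w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n{seq}\n")
    prom_truth.to_csv(out / "promoters_truth.tsv", sep="\t")
    quants, iso_truth = simulate_isoform_quants(cfg)
    quants.to_csv(out / "isoform_quants.tsv", sep="\t", index=False)
    plates, assay_truth = simulate_assays(cfg)
    for name, frame in plates.items():
        frame.to_csv(out / f"plate_{name}.csv", index=False)
    sidecar = {"seed": cfg.seed, "config": asdict(cfg),
               "isoforms": iso_truth, "assays": assay_truth}
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
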