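"""Reporter-assay and qPCR arithmetic with replicate-level summaries.

Implements the plate-reader conventions used throughout the study:

* NanoBRET milliBRET units: mBU = (mean 618/460 ratio of the experimental
  wells minus that of the no-ligand control wells) x 1000.
* Dual-luciferase RLU: firefly / Renilla per well, Renilla being the internal
  transfection control; optional fold over a baseline condition.
* Relative qPCR quantification: fold = 2^-ddCt where ddCt is the target-minus-
  reference Ct difference of the sample minus that of the calibrator.
* ChIP percent input: IP signal relative to the diluted chromatin input
  (input Ct adjusted by log2 of the inverse input fraction).
* Exogenous/endogenous copy ratios reported as percent increase.

All summaries are mean +- SEM with the n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class AssaySummary:
    value: float
    sem: float
    n: int


def nanobret_mbu(em618_exp, em460_exp, em618_ctrl, em460_ctrl) -> AssaySummary:
    """milliBRET units from experimental and no-ligand-control well groups.

    Wells with zero donor (460 nm) emission are excluded with a warning; an
    empty group after exclusion is an error. The replicate SEMs of the two
    condition means propagate in quadrature.
    """
    ratios = []
    for em618, em460, label in ((em618_exp, em460_exp, "experimental"),
                                (em618_ctrl, em460_ctrl, "no-ligand control")):
        em618 = np.asarray(em618, dtype=float)
        em460 = np.asarray(em460, dtype=float)
        if em618.shape != em460.shape or em618.size == 0:
            raise ValueError(f"{label} wells: emissions must be nonempty and paired")
        ok = em460 > 0
        if not ok.all():
            warnings.warn(f"{label}: {int((~ok).sum())} well(s) with zero 460 nm emission excluded")
        if not ok.any():
            raise ValueError(f"{label}: no usable well (all 460 nm emissions are zero)")
        ratios.append(em618[ok] / em460[ok])
    exp_r, ctrl_r = ratios
    mbu = (exp_r.mean() - ctrl_r.mean()) * 1000.0
    sem = float(np.hypot(_sem(exp_r), _sem(ctrl_r)) * 1000.0)
    return AssaySummary(float(mbu), sem, int(exp_r.size + ctrl_r.size))


def luciferase_rlu(firefly, renilla, conditions=None, baseline: str | None = None):
    """Firefly/Renilla RLU per well with per-condition mean +- SEM.

    Without *conditions*, returns the per-well RLU array. With them, returns
    {condition: AssaySummary}; with *baseline* also set, values are expressed
    as fold over the baseline condition mean (the baseline folds to 1).
    """
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    if firefly.shape != renilla.shape:
        raise ValueError("firefly and renilla must be paired")
    if np.any(renilla <= 0):
        raise ValueError("Renilla signal must be positive (internal control)")
    rlu = firefly / renilla
    if conditions is None:
        return rlu
    conditions = np.asarray(conditions)
    summaries = {}
    scale = 1.0
    if baseline is not None:
        base = rlu[conditions == baseline]
        if base.size == 0:
            raise ValueError(f"baseline condition {baseline!r} has no wells")
        scale = base.mean()
    for cond in dict.fromkeys(conditions.tolist()):
        vals = rlu[conditions == cond] / scale
        summaries[cond] = AssaySummary(float(vals.mean()), _sem(vals), int(vals.size))
    return summaries


def ddct_fold_change(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_calibrator: float, ct_ref_calibrator: float,
                     efficiency: float = 2.0) -> float:
    """Relative quantification: fold = efficiency^-ddCt, GAPDH-style reference.

    ddCt = (Ct_target - Ct_reference) of the sample minus the same difference
    of the calibrator; the calibrator itself folds to 1.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if any(c is None or not np.isfinite(c) for c in cts):
        raise ValueError("all four Ct values must be present and finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(efficiency ** (-ddct))


def fold_change_to_ddct(fold: float, efficiency: float = 2.0) -> float:
    """Inverse of :func:`ddct_fold_change` (round-trips to machine precision)."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return float(-np.log(fold) / np.log(efficiency))


def chip_enrichment(ct_ip: float, ct_input: float, input_fraction: float = 0.01,
                    ct_control_ip: float | None = None,
                    efficiency: float = 2.0) -> dict:
    """ChIP-qPCR percent input, optionally fold over a control IP.

    The input Ct is first adjusted for the dilution of the saved chromatin:
    Ct_adj = Ct_input - log_eff(1/input_fraction). Then
    percent_input = 100 x efficiency^(Ct_adj - Ct_ip).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adj = ct_input - np.log(1.0 / input_fraction) / np.log(efficiency)
    percent = 100.0 * efficiency ** (adj - ct_ip)
    out = {"percent_input": float(percent)}
    if ct_control_ip is not None:
        control = 100.0 * efficiency ** (adj - ct_control_ip)
        out["fold_over_control"] = float(percent / control)
    return out


def copy_ratio(exo_copies: float, endo_copies: float) -> dict:
    """Exogenous/endogenous copy-number ratio, also as percent increase."""
    if endo_copies <= 0:
        raise ValueError("endogenous copy number must be positive")
    if exo_copies < 0:
        raise ValueError("exogenous copy number must be nonnegative")
    ratio = exo_copies / endo_copies
    return {"ratio": float(ratio), "percent_increase": float(100.0 * ratio)}
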