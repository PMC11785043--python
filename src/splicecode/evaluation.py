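"""Evaluation statistics for inclusion prediction and sequence design.

Regression quality is summarised by Pearson r and the approximate
accuracy ``a``: the fraction of predictions within 0.2 of the observed
PSI (strict inequality). Differential splicing is scored as two
classification problems — dPSI+ (dPSI >= 0.15) and dPSI- (dPSI <=
-0.15) — by AUPRC (step-wise, no interpolation) and AUROC. Design runs
are summarised by the success fraction and the top-20% candidates by
objective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

DPSI_THRESHOLD = 0.15
APPROX_TOL = 0.2


def _check_lengths(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p, t = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError(f"length mismatch or empty input: {p.shape} vs {t.shape}")
    return p, t


def approx_accuracy(pred, truth, tol: float = APPROX_TOL) -> float:
    """Fraction of samples with |pred - truth| < tol."""
    p, t = _check_lengths(pred, truth)
    return float((np.abs(p - t) < tol).mean())


def pearson_r(pred, truth) -> float:
    p, t = _check_lengths(pred, truth)
    return float(np.corrcoef(p, t)[0, 1])


def changing_mask(true_dpsi, threshold: float = DPSI_THRESHOLD) -> np.ndarray:
    """Events whose inclusion changes between the two conditions."""
    return np.abs(np.asarray(true_dpsi, dtype=float)) > threshold


def dpsi_classification_metrics(
    true_dpsi,
    pred_dpsi,
    threshold: float = DPSI_THRESHOLD,
) -> dict:
    """AUPRC and AUROC for the dPSI+ and dPSI- classification tasks.

    Labels come from the true dPSI at +-threshold; scores are the
    predicted dPSI (negated for dPSI-). Single-class directions are
    reported as None with a diagnostic.
    """
    t, p = _check_lengths(true_dpsi, pred_dpsi)
    out: dict = {"threshold": threshold, "diagnostics": []}
    for name, labels, scores in (
        ("plus", t >= threshold, p),
        ("minus", t <= -threshold, -p),
    ):
        if labels.all() or not labels.any():
            out[f"auprc_{name}"] = None
            out[f"auroc_{name}"] = None
            out["diagnostics"].append(
                f"dPSI{'+' if name == 'plus' else '-'}: single-class labels, "
                "metrics undefined")
            continue
        out[f"auprc_{name}"] = float(average_precision_score(labels, scores))
        out[f"auroc_{name}"] = float(roc_auc_score(labels, scores))
    return out


@dataclass
class EvalReport:
    pearson_r: float
    approx_a: float
    n: int
    dpsi_metrics: dict = field(default_factory=dict)
    changing_pearson_r: float | None = None
    changing_approx_a: float | None = None
    n_changing: int = 0

    def as_dict(self) -> dict:
        d = {"pearson_r": self.pearson_r, "approx_a": self.approx_a, "n": self.n,
             "changing_pearson_r": self.changing_pearson_r,
             "changing_approx_a": self.changing_approx_a,
             "n_changing": self.n_changing}
        d.update(self.dpsi_metrics)
        return d


def evaluate_psi(pred, truth, true_dpsi=None, pred_dpsi=None) -> EvalReport:
    """Full regression report, optionally with the changing-events subset
    and dPSI classification metrics."""
    p, t = _check_lengths(pred, truth)
    rep = EvalReport(pearson_r=pearson_r(p, t), approx_a=approx_accuracy(p, t),
                     n=len(p))
    if true_dpsi is not None:
        mask = changing_mask(true_dpsi)
        rep.n_changing = int(mask.sum())
        if rep.n_changing >= 2:
            rep.changing_pearson_r = pearson_r(p[mask], t[mask])
            rep.changing_approx_a = approx_accuracy(p[mask], t[mask])
        if pred_dpsi is not None:
            rep.dpsi_metrics = dpsi_classification_metrics(true_dpsi, pred_dpsi)
    return rep


def design_success_rate(results, top_frac: float = 0.2, scalarize=None) -> dict:
    """Success fraction plus a summary of the best candidates.

    ``results`` are DesignResult-like objects; the top fraction is taken
    by objective value (``scalarize(oracle_values)``; defaults to the
    mean oracle value when no scalarization is given).
    """
    if not len(results):
        raise ValueError("no design results")
    succ = [r for r in results if r.success]
    if scalarize is None:
        scalarize = lambda vals: float(np.mean(list(vals.values())))
    values = np.array([scalarize(r.oracle_values) for r in results])
    k = max(1, int(np.ceil(top_frac * len(results)))) if len(results) else 0
    top = np.sort(values)[-k:] if k else np.array([])
    return {
        "n": len(results),
        "n_success": len(succ),
        "success_rate": len(succ) / len(results),
        "top_fraction": top_frac,
        "top_n": int(len(top)),
        "top_mean": float(top.mean()) if len(top) else None,
        "top_best": float(top.max()) if len(top) else None,
        "success_top_summary": {
            "n": len(succ),
            "best": (max(scalarize(r.oracle_values) for r in succ) if succ else None),
        },
    }
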