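"""RNAge score: relative transcriptional age of two sample groups.

For a signature class k with genes Ĝ_k and marker vector M_k (±1 expected
aging directions), and a test matrix with groups of sizes n and m:

* per signature gene i present in the test matrix, the Welch two-sample
  t-statistic t_i = (μ₁ − μ₂) / sqrt(S₁²/n + S₂²/m) with n−1 sample
  variances; genes absent from the test matrix get t_i = 0;
* RNAge_k = Σ t_i·M_k[i] / N_k, where N_k is the number of signature genes
  present in the test matrix;
* Percentage score_k = (number of strictly positive products A_i = t_i·M_k[i]) / N_k.

Sign convention: with signatures derived from log2(old/young) fold changes,
a positive RNAge score means group1 is transcriptionally older than group2.
Only the Welch statistic is used — no degrees of freedom or p-value.

Expression scale: when the matrix is tagged ``linear`` the scorer applies
log2(x+1) before computing t-statistics (transform policy ``auto``, the
default); ``log``-tagged matrices are used as-is.  t-statistics on raw
heavy-tailed linear values would be dominated by outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AgingSignature,
    ExpressionMatrix,
    RnageError,
    SampleGrouping,
    ValidationError,
    logger,
)

#: sentinel |t| for the degenerate zero-variance, unequal-means case
DEFAULT_T_CAP = 50.0


@dataclass
class ScoreResult:
    """RNAge score of one signature class for one two-group comparison.

    ``detail`` has one row per signature gene: ``gene``, ``t_stat``,
    ``direction``, ``product`` (A_i = t_i × direction) and
    ``present_in_test``; absent genes carry t_stat = 0.
    """

    class_label: str
    rnage_score: float
    percentage_score: float
    n_overlap: int
    detail: pd.DataFrame


def welch_t(values1, values2, t_cap: float = DEFAULT_T_CAP) -> float:
    """Welch's two-sample t-statistic (unequal variances, n−1 denominators).

    Degenerate inputs: both variances zero with equal means → 0; both
    variances zero with unequal means → ±``t_cap`` (logged).
    """
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    if x1.ndim != 1 or x2.ndim != 1 or x1.size < 2 or x2.size < 2:
        raise ValidationError("welch_t needs two 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValidationError("welch_t inputs must be finite")
    t = _welch_t_rows(x1[None, :], x2[None, :], t_cap=t_cap)
    return float(t[0])


def _welch_t_rows(X1: np.ndarray, X2: np.ndarray, t_cap: float = DEFAULT_T_CAP) -> np.ndarray:
    """Row-wise Welch t for (genes × samples) blocks of the two groups."""
    n, m = X1.shape[1], X2.shape[1]
    mu1 = X1.mean(axis=1)
    mu2 = X2.mean(axis=1)
    s1 = X1.var(axis=1, ddof=1)
    s2 = X2.var(axis=1, ddof=1)
    se = np.sqrt(s1 / n + s2 / m)
    diff = mu1 - mu2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    if np.any(degenerate):
        t = np.where(degenerate & (diff == 0), 0.0, t)
        capped = degenerate & (diff != 0)
        if np.any(capped):
            logger.info(
                "welch_t: %d gene(s) with zero variance in both groups and unequal "
                "means capped at ±%g", int(capped.sum()), t_cap,
            )
            t = np.where(capped, np.sign(diff) * t_cap, t)
    return t


def _prepare_values(expr: ExpressionMatrix, transform: str) -> np.ndarray:
    """Apply the transform policy: auto|on|off for log2(x+1)."""
    if transform not in ("auto", "on", "off"):
        raise ValueError(f"transform must be auto/on/off, got {transform!r}")
    do_log = transform == "on" or (transform == "auto" and expr.scale_tag == "linear")
    if do_log:
        if np.any(expr.values < 0):
            raise ValidationError("cannot log2(x+1)-transform negative values")
        return np.log2(expr.values + 1.0)
    return expr.values


def compute_rnage(
    expr: ExpressionMatrix,
    grouping: SampleGrouping,
    signature: AgingSignature,
    transform: str = "auto",
    t_cap: float = DEFAULT_T_CAP,
) -> ScoreResult:
    """Score one signature class on one two-group comparison.

    Raises if the signature is empty or shares no gene with the test matrix.
    """
    grouping.validate_against(expr)
    if len(signature) == 0:
        raise ValidationError(f"signature {signature.class_label} is empty")
    values = _prepare_values(expr, transform)
    gene_idx = expr.gene_index()
    sample_idx = {s: j for j, s in enumerate(expr.sample_ids)}
    cols1 = [sample_idx[s] for s in grouping.group1]
    cols2 = [sample_idx[s] for s in grouping.group2]

    genes = signature.genes
    directions = signature.directions.astype(float)
    present = np.array([g in gene_idx for g in genes])
    n_overlap = int(present.sum())
    if n_overlap == 0:
        raise RnageError(
            f"signature {signature.class_label} is disjoint from the test matrix genes"
        )
    rows = [gene_idx[g] for g, p in zip(genes, present) if p]
    t = np.zeros(len(genes))  # absent marker genes keep t_i = 0
    t[present] = _welch_t_rows(values[np.ix_(rows, cols1)], values[np.ix_(rows, cols2)], t_cap=t_cap)

    products = t * directions
    rnage_score = float(products.sum() / n_overlap)
    percentage = float((products > 0).sum() / n_overlap)
    detail = pd.DataFrame(
        {
            "gene": genes,
            "t_stat": t,
            "direction": directions.astype(int),
            "product": products,
            "present_in_test": present,
        }
    )
    return ScoreResult(
        class_label=signature.class_label,
        rnage_score=rnage_score,
        percentage_score=percentage,
        n_overlap=n_overlap,
        detail=detail,
    )


def compute_all_subscores(
    expr: ExpressionMatrix,
    grouping: SampleGrouping,
    signatures: list[AgingSignature],
    transform: str = "auto",
    t_cap: float = DEFAULT_T_CAP,
) -> tuple[list[ScoreResult], dict[str, str]]:
    """Score every signature class; per-class failures become reasoned gaps.

    Returns ``(results, failures)`` where ``failures`` maps a class label to
    the reason it could not be scored (e.g. no overlapping genes).
    """
    results: list[ScoreResult] = []
    failures: dict[str, str] = {}
    for sig in signatures:
        try:
            results.append(compute_rnage(expr, grouping, sig, transform=transform, t_cap=t_cap))
        except RnageError as exc:
            logger.warning("compute_all_subscores: class %s skipped: %s", sig.class_label, exc)
            failures[sig.class_label] = str(exc)
    return results, failures


def scores_frame(results: list[ScoreResult]) -> pd.DataFrame:
    """Tidy one-row-per-class summary (class, rnage_score, percentage_score, n_overlap)."""
    return pd.DataFrame(
        [
            {
                "class": r.class_label,
                "rnage_score": r.rnage_score,
                "percentage_score": r.percentage_score,
                "n_overlap": r.n_overlap,
            }
            for r in results
        ],
        columns=["class", "rnage_score", "percentage_score", "n_overlap"],
    )
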