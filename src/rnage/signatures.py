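"""Derivation of hierarchical, tissue-specific aging gene signatures.

Given K per-dataset young-vs-old differential-expression tables, the
procedure is:

1. Restrict to the gene universe shared by all K tables.
2. Discretize each gene's log2 fold change in each dataset to −1/0/+1 at a
   ±`lfc_threshold` cutoff (default 0.1, nonzero bins inclusive of the
   boundary).  Positive means up in aging under the log2(old/young)
   orientation.
3. Combine each gene's K p-values with Edgington's method: the combined p is
   the Irwin–Hall CDF of the sum of p-values under the uniform null.
4. Assign each gene to the first matching class of a hierarchy — Pan
   (concordant direction in every dataset), pF (concordant in the three
   fibroblast datasets), Neuronal (concordant in the three CNS datasets),
   FC (concordant in the two frontal-cortex datasets), SN (changed in the
   substantia-nigra dataset) — each class excluding genes captured by an
   earlier one, so classes are mutually exclusive by construction.
5. Within each class, rank by combined p ascending and keep the top
   ``top_n`` (default 100) genes; each kept gene carries its shared
   discretized direction in the class-defining datasets as the marker
   vector entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AgingSignature, DETable, ValidationError, logger

DEFAULT_DATASETS = (
    "Total_pF",
    "PolyA_pF",
    "PolyA_Gage_pF",
    "Total_FC",
    "PolyA_Gage_FC",
    "Total_SN",
)


@dataclass
class DatasetPanelConfig:
    """The training-dataset panel and the class-defining subsets.

    The generalized class criterion is full agreement: a gene belongs to a
    class if the absolute sum of its discretized fold changes over the
    class-defining subset equals the subset size (every dataset changed,
    same direction).  With the default six datasets this reproduces the
    6 / 3 / 3 / 2 / ≠0 criteria for Pan, pF, Neuronal, FC and SN.
    """

    dataset_ids: tuple[str, ...] = DEFAULT_DATASETS
    fibroblast_subset: tuple[str, ...] = DEFAULT_DATASETS[:3]
    neuronal_subset: tuple[str, ...] = DEFAULT_DATASETS[3:]
    fc_subset: tuple[str, ...] = DEFAULT_DATASETS[3:5]
    sn_subset: tuple[str, ...] = DEFAULT_DATASETS[5:]
    lfc_threshold: float = 0.1
    top_n: int = 100

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValidationError("lfc_threshold must be > 0")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        ids = set(self.dataset_ids)
        if len(ids) != len(self.dataset_ids):
            raise ValidationError("dataset_ids must be unique")
        for name in ("fibroblast_subset", "neuronal_subset", "fc_subset", "sn_subset"):
            subset = getattr(self, name)
            if not set(subset) <= ids:
                raise ValidationError(f"{name} is not a subset of dataset_ids")
        if not set(self.fc_subset) <= set(self.neuronal_subset):
            raise ValidationError("fc_subset must be a subset of neuronal_subset")
        if not set(self.sn_subset) <= set(self.neuronal_subset):
            raise ValidationError("sn_subset must be a subset of neuronal_subset")

    def class_subsets(self) -> list[tuple[str, tuple[str, ...]]]:
        """(class label, defining datasets) in hierarchy order G1 → G5."""
        return [
            ("Pan", tuple(self.dataset_ids)),
            ("pF", tuple(self.fibroblast_subset)),
            ("Neuronal", tuple(self.neuronal_subset)),
            ("FC", tuple(self.fc_subset)),
            ("SN", tuple(self.sn_subset)),
        ]

    def column_indices(self, subset: tuple[str, ...]) -> list[int]:
        pos = {d: i for i, d in enumerate(self.dataset_ids)}
        return [pos[d] for d in subset]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_lfc(log2fc, threshold: float = 0.1):
    """Three-way discretization of log2 fold change.

    Returns +1 if ``log2fc >= threshold``, −1 if ``log2fc <= −threshold``
    and 0 inside the open interval (both boundaries fall in the nonzero
    bins).  Accepts scalars or arrays.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    arr = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("log2fc must be finite")
    out = np.zeros(arr.shape, dtype=int)
    out[arr >= threshold] = 1
    out[arr <= -threshold] = -1
    if np.ndim(log2fc) == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# Edgington's combined p-value (Irwin–Hall CDF)
# ---------------------------------------------------------------------------

def irwin_hall_cdf(s, k: int):
    """CDF of the sum of ``k`` iid Uniform(0,1) variables.

    Closed form ``(1/k!) Σ_{j=0}^{⌊s⌋} (−1)^j C(k,j) (s−j)^k``, clamped to
    [0, 1].  Accurate in double precision for the small k (≤ tens) used in
    p-value combination.  Accepts scalars or arrays.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    s_arr = np.asarray(s, dtype=float)
    total = np.zeros(s_arr.shape)
    for j in range(k + 1):
        term = np.where(s_arr > j, (s_arr - j) ** k, 0.0)
        total += ((-1) ** j) * math.comb(k, j) * term
    total /= math.factorial(k)
    total = np.clip(total, 0.0, 1.0)
    if np.ndim(s) == 0:
        return float(total)
    return total


def combine_pvalues_edgington(pvalues) -> float:
    """Edgington's combined p: Irwin–Hall CDF of the sum of the p-values.

    Small when the p-values are collectively small; exact pass-through for a
    single p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a nonempty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("pvalues must lie in [0, 1]")
    return irwin_hall_cdf(float(p.sum()), p.size)


def _combine_rows_edgington(pmatrix: np.ndarray) -> np.ndarray:
    """Row-wise Edgington combination for an (n_genes, K) p-value matrix."""
    return irwin_hall_cdf(pmatrix.sum(axis=1), pmatrix.shape[1])


# ---------------------------------------------------------------------------
# Hierarchical class assignment
# ---------------------------------------------------------------------------

def assign_signature_class(lbar, panel: DatasetPanelConfig) -> str | None:
    """Assign one gene's discretized fold-change vector to a class.

    ``lbar`` is aligned to ``panel.dataset_ids``.  Returns the first class
    (Pan → pF → Neuronal → FC → SN) whose defining datasets all changed in
    the same direction, or ``None``.
    """
    v = np.asarray(lbar, dtype=int)
    if v.shape != (len(panel.dataset_ids),):
        raise ValidationError(
            f"lbar has length {v.size}, panel declares {len(panel.dataset_ids)} datasets"
        )
    for label, subset in panel.class_subsets():
        cols = panel.column_indices(subset)
        if abs(int(v[cols].sum())) == len(cols):
            return label
    return None


def _assign_classes_matrix(lbar: np.ndarray, panel: DatasetPanelConfig) -> np.ndarray:
    """Vectorized hierarchy over an (n_genes, K) discretized matrix.

    Returns an object array of class labels (None where unassigned)."""
    n = lbar.shape[0]
    labels = np.full(n, None, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for label, subset in panel.class_subsets():
        cols = panel.column_indices(subset)
        hit = unassigned & (np.abs(lbar[:, cols].sum(axis=1)) == len(cols))
        labels[hit] = label
        unassigned &= ~hit
    return labels


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

def derive_signatures(
    de_tables: list[DETable],
    panel: DatasetPanelConfig | None = None,
) -> tuple[list[AgingSignature], pd.DataFrame]:
    """Derive all aging signatures from one DE table per panel dataset.

    Returns ``(signatures, audit)`` where ``audit`` is the full per-gene
    assignment table (gene, L̄ per dataset, combined_p, class) over the
    shared gene universe, for inspection; ``signatures`` holds the top-N
    entries per class ranked by combined p (ties broken by larger mean
    |log2fc| over the class-defining datasets, then gene ID).

    The gene universe is the intersection of gene IDs across all tables;
    the Pan criterion is undefined for genes missing from any dataset.
    """
    if panel is None:
        panel = DatasetPanelConfig()
    by_id = {t.dataset_id: t for t in de_tables}
    missing = [d for d in panel.dataset_ids if d not in by_id]
    if missing:
        raise ValidationError(f"no DE table supplied for datasets {missing}")

    frames = []
    for d in panel.dataset_ids:
        f = by_id[d].frame.set_index("gene")[["log2fc", "pvalue"]]
        f.columns = [f"log2fc_{d}", f"pvalue_{d}"]
        frames.append(f)
    merged = pd.concat(frames, axis=1, join="inner")
    if merged.empty:
        raise ValidationError("gene universe is empty: no gene shared by all DE tables")
    merged = merged.sort_index()

    K = len(panel.dataset_ids)
    lfc = merged[[f"log2fc_{d}" for d in panel.dataset_ids]].to_numpy()
    pvals = merged[[f"pvalue_{d}" for d in panel.dataset_ids]].to_numpy()
    lbar = discretize_lfc(lfc, panel.lfc_threshold)
    combined = _combine_rows_edgington(pvals)
    labels = _assign_classes_matrix(lbar, panel)

    audit = pd.DataFrame({"gene": merged.index.to_numpy()})
    for j, d in enumerate(panel.dataset_ids):
        audit[f"lbar_{d}"] = lbar[:, j]
    audit["combined_p"] = combined
    audit["class"] = [x if x is not None else "" for x in labels]

    signatures: list[AgingSignature] = []
    for label, subset in panel.class_subsets():
        cols = panel.column_indices(subset)
        mask = labels == label
        if not mask.any():
            logger.warning("derive_signatures: no eligible genes for class %s", label)
            signatures.append(
                AgingSignature(
                    class_label=label,
                    entries=pd.DataFrame(columns=["gene", "direction", "combined_p", "rank"]),
                )
            )
            continue
        sub = pd.DataFrame(
            {
                "gene": merged.index.to_numpy()[mask],
                "combined_p": combined[mask],
                # all class-defining entries share one sign, so sign(sum) is it
                "direction": np.sign(lbar[np.ix_(mask, cols)].sum(axis=1)).astype(int),
                "_mean_abs_lfc": np.abs(lfc[np.ix_(mask, cols)]).mean(axis=1),
            }
        )
        sub = sub.sort_values(
            ["combined_p", "_mean_abs_lfc", "gene"],
            ascending=[True, False, True],
            kind="mergesort",
        ).head(panel.top_n)
        sub = sub.drop(columns="_mean_abs_lfc").reset_index(drop=True)
        sub["rank"] = np.arange(1, len(sub) + 1)
        if len(sub) < panel.top_n:
            logger.warning(
                "derive_signatures: class %s has only %d eligible genes (top_n=%d)",
                label, len(sub), panel.top_n,
            )
        signatures.append(AgingSignature(class_label=label, entries=sub))
    return signatures, audit
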