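"""In silico perturbation screen: score every perturbation against each
aging signature and call age-inducing / rejuvenating hits.

Replicates of each perturbation and their controls are matched by
perturbation ID and plate ID; each (perturbation, dose, time, plate) group
is scored against the same-plate controls with the RNAge score.  Scores are
then aggregated in two stages — plates are averaged within a
(perturbation, dose, time) condition, and condition averages are averaged
to a single value per perturbation — before a z-value is computed within
each signature class across all perturbations of the run (one run covers
one cell line's instances).  A perturbation is called an ``ager`` when its
z exceeds +k standard deviations (default k = 3) and a ``rejuvenator``
below −k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    AgingSignature,
    ExpressionMatrix,
    RnageError,
    SampleGrouping,
    ScreenMetadata,
    ValidationError,
    logger,
)
from .scoring import DEFAULT_T_CAP, compute_rnage


@dataclass
class PerturbationGroup:
    """Replicates of one perturbation condition on one plate, with the
    same-plate control instances they are scored against."""

    perturbation_id: str
    dose: str
    time: str
    plate_id: str
    treated_sample_ids: list[str]
    control_sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.treated_sample_ids) < 2 or len(self.control_sample_ids) < 2:
            raise ValidationError("perturbation groups need >= 2 treated and >= 2 control samples")
        if set(self.treated_sample_ids) & set(self.control_sample_ids):
            raise ValidationError("treated and control samples overlap")


@dataclass
class ScreenTable:
    """Screen results at both aggregation levels.

    ``condition_scores``: one row per (perturbation_id, dose, time, class)
    with the plate-averaged ``condition_score`` and ``n_plates``.
    ``perturbation_scores``: one row per (perturbation_id, class) with
    ``pert_mean_score`` (mean over conditions), ``z_value`` (standardized
    within the class across perturbations) and ``hit_flag`` in
    {ager, rejuvenator, none}.
    """

    condition_scores: pd.DataFrame
    perturbation_scores: pd.DataFrame
    k_sd: float = 3.0


def build_perturbation_groups(
    meta: ScreenMetadata,
    expr: ExpressionMatrix | None = None,
) -> list[PerturbationGroup]:
    """Match perturbation replicates with same-plate controls.

    One group per (perturbation, dose, time, plate) having >= 2 treated and
    >= 2 same-plate control instances; under-replicated combinations are
    skipped with a logged reason.  Raises if no valid group remains.
    """
    if expr is not None:
        meta.validate_against(expr)
    df = meta.frame
    controls_by_plate = {
        plate: sub["sample_id"].tolist()
        for plate, sub in df[df["is_control"]].groupby("plate_id")
    }
    groups: list[PerturbationGroup] = []
    treated = df[~df["is_control"]]
    for (pert, dose, time, plate), sub in treated.groupby(
        ["perturbation_id", "dose", "time", "plate_id"], sort=True
    ):
        ctrl = controls_by_plate.get(plate, [])
        if len(sub) < 2:
            logger.info(
                "screen: skipping %s dose=%s time=%s plate=%s: only %d treated replicate(s)",
                pert, dose, time, plate, len(sub),
            )
            continue
        if len(ctrl) < 2:
            logger.info(
                "screen: skipping %s dose=%s time=%s plate=%s: only %d control(s) on plate",
                pert, dose, time, plate, len(ctrl),
            )
            continue
        groups.append(
            PerturbationGroup(
                perturbation_id=pert,
                dose=dose,
                time=time,
                plate_id=plate,
                treated_sample_ids=sub["sample_id"].tolist(),
                control_sample_ids=ctrl,
            )
        )
    if not groups:
        raise RnageError("no scoreable perturbation group (check replicates and plate controls)")
    return groups


def score_screen(
    expr: ExpressionMatrix,
    meta: ScreenMetadata,
    signatures: list[AgingSignature],
    k_sd: float = 3.0,
    transform: str = "auto",
    t_cap: float = DEFAULT_T_CAP,
    robust: bool = False,
) -> ScreenTable:
    """Run the full screen: group, score, aggregate, standardize, call hits.

    ``robust=True`` uses median/1.4826·MAD instead of mean/SD for the
    z-values (off by default).  Signature classes with no overlap in the
    matrix are omitted with a logged reason; fewer than two distinct
    perturbations is an error (the SD of a single point is undefined).
    """
    meta.validate_against(expr)
    groups = build_perturbation_groups(meta)
    n_perts = len({g.perturbation_id for g in groups})
    if n_perts < 2:
        raise RnageError(f"screen needs >= 2 distinct perturbations, got {n_perts}")

    rows = []
    for g in groups:
        grouping = SampleGrouping(group1=g.treated_sample_ids, group2=g.control_sample_ids)
        for sig in signatures:
            if len(sig) == 0:
                continue
            try:
                res = compute_rnage(expr, grouping, sig, transform=transform, t_cap=t_cap)
            except RnageError as exc:
                logger.warning("screen: class %s omitted: %s", sig.class_label, exc)
                continue
            rows.append(
                {
                    "perturbation_id": g.perturbation_id,
                    "dose": g.dose,
                    "time": g.time,
                    "plate_id": g.plate_id,
                    "class": sig.class_label,
                    "score": res.rnage_score,
                }
            )
    if not rows:
        raise RnageError("no signature class could be scored on the screen matrix")
    plate_scores = pd.DataFrame(rows)

    # stage 1: average plates within a (perturbation, dose, time) condition
    condition = (
        plate_scores.groupby(["perturbation_id", "dose", "time", "class"], sort=True)["score"]
        .agg(condition_score="mean", n_plates="size")
        .reset_index()
    )
    # stage 2: average conditions to one value per perturbation
    pert = (
        condition.groupby(["perturbation_id", "class"], sort=True)["condition_score"]
        .mean()
        .rename("pert_mean_score")
        .reset_index()
    )

    def _standardize(sub: pd.DataFrame) -> pd.DataFrame:
        x = sub["pert_mean_score"].to_numpy()
        if robust:
            center = float(np.median(x))
            scale = 1.4826 * float(np.median(np.abs(x - center)))
        else:
            center = float(x.mean())
            scale = float(x.std(ddof=1))
        sub = sub.copy()
        sub["z_value"] = (x - center) / scale if scale > 0 else np.zeros_like(x)
        return sub

    pert = (
        pert.groupby("class", sort=True, group_keys=False)[pert.columns]
        .apply(_standardize)
        .reset_index(drop=True)
    )
    pert["hit_flag"] = np.select(
        [pert["z_value"] > k_sd, pert["z_value"] < -k_sd],
        ["ager", "rejuvenator"],
        default="none",
    )
    return ScreenTable(condition_scores=condition, perturbation_scores=pert, k_sd=k_sd)


def summarize_hits(table: ScreenTable) -> pd.DataFrame:
    """Ranked hit report: hits sorted by |z| descending within class,
    ties broken by perturbation ID for a stable order."""
    pert = table.perturbation_scores
    hits = pert[pert["hit_flag"] != "none"].copy()
    if hits.empty:
        return hits.reset_index(drop=True)
    hits["_abs_z"] = hits["z_value"].abs()
    hits = hits.sort_values(
        ["class", "_abs_z", "perturbation_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_abs_z")
    return hits.reset_index(drop=True)
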