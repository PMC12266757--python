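"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes, with planted signal so that
signature recovery, score direction and screen hit calling can be checked
against truth:

* :func:`simulate_training_tables` — K young-vs-old DE tables with
  tissue-structured planted aging genes: Pan genes shift in every dataset,
  pF genes only in the fibroblast datasets, Neuronal in the CNS datasets,
  FC in the frontal-cortex datasets, SN only in the substantia-nigra
  dataset.  Null genes have sub-threshold fold changes (with a small escape
  probability) and uniform p-values.
* :func:`simulate_cohort` — a log-scale expression matrix for a young/old
  two-group comparison, with the designated older group shifted along each
  planted gene's aging direction.
* :func:`simulate_screen` — a perturbation screen (plates, replicates,
  vehicle controls) with null perturbations plus planted age-modifying
  perturbations that shift one signature class's genes.

All draws come from ``numpy.random.default_rng`` seeded from
``SimulationConfig.seed`` (one fixed sub-stream per generator), so a fixed
seed reproduces byte-identical outputs.  Expression is simulated directly
on log2 scale (``scale_tag="log"``): the scoring method consumes log-scale
values, so no count-level realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DETable,
    ExpressionMatrix,
    SampleGrouping,
    ScreenMetadata,
    SIGNATURE_CLASSES,
    ValidationError,
)
from .signatures import DatasetPanelConfig

# fixed sub-stream ids so the three generators are independent under one seed
_STREAM_TRAINING = 0
_STREAM_COHORT = 1
_STREAM_SCREEN = 2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the training-data structure the method was built on:
    six datasets, ~10⁴ shared genes, planted effects of 1.0 log2-units,
    planted DE p-values ~ U(0, 10⁻⁴) (drawn, not fixed, so combined-p
    ranking among planted genes is non-degenerate), cohorts of 9 vs 9
    samples, and log-scale expression noise with SD 0.25.
    """

    n_genes: int = 10_000
    planted_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 200 for c in SIGNATURE_CLASSES}
    )
    effect_lfc: float = 1.0
    planted_p_scale: float = 1e-4
    noise_sd: float = 0.25
    group_sizes: tuple[int, int] = (9, 9)
    n_null_perturbations: int = 100
    pert_effect_sizes: tuple[float, ...] = (1.0,)
    lfc_threshold: float = 0.1
    #: probability that a null gene's fold change escapes the sub-threshold
    #: band (a rare-artifact channel; see the methods note)
    null_escape_prob: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted_per_class) - set(SIGNATURE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown classes in planted_per_class: {sorted(unknown)}")
        if sum(self.planted_per_class.values()) > self.n_genes:
            raise ValidationError("planted gene counts exceed n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.effect_lfc <= self.lfc_threshold:
            raise ValidationError("effect_lfc must exceed lfc_threshold")
        if min(self.group_sizes) < 2:
            raise ValidationError("group sizes must be >= 2")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene class/direction and per-perturbation
    effect class, size and sign (empty strings / zeros for nulls)."""

    genes: pd.DataFrame  # columns: gene, true_class, true_direction
    perturbations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["perturbation_id", "true_effect_class", "true_effect_size", "true_sign"]
        )
    )

    def planted_genes(self, class_label: str) -> pd.DataFrame:
        return self.genes[self.genes["true_class"] == class_label]


def write_truth(dir_path: str | Path, truth: SyntheticTruth) -> None:
    dir_path = Path(dir_path)
    truth.genes.to_csv(dir_path / "truth_genes.tsv", sep="\t", index=False)
    truth.perturbations.to_csv(dir_path / "truth_perturbations.tsv", sep="\t", index=False)


def read_truth(dir_path: str | Path) -> SyntheticTruth:
    dir_path = Path(dir_path)
    genes = pd.read_csv(dir_path / "truth_genes.tsv", sep="\t", dtype={"gene": str}, keep_default_na=False)
    perts_path = dir_path / "truth_perturbations.tsv"
    if perts_path.exists():
        perts = pd.read_csv(perts_path, sep="\t", dtype={"perturbation_id": str}, keep_default_na=False)
    else:
        perts = SyntheticTruth(genes=genes).perturbations
    return SyntheticTruth(genes=genes, perturbations=perts)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _plant_classes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign the first Σ counts genes to classes with random ±1 directions."""
    genes = _gene_ids(config.n_genes)
    true_class = [""] * config.n_genes
    true_dir = np.zeros(config.n_genes, dtype=int)
    i = 0
    for label in SIGNATURE_CLASSES:
        count = config.planted_per_class.get(label, 0)
        for _ in range(count):
            true_class[i] = label
            true_dir[i] = 1 if rng.random() < 0.5 else -1
            i += 1
    return pd.DataFrame({"gene": genes, "true_class": true_class, "true_direction": true_dir})


def simulate_training_tables(
    config: SimulationConfig,
    panel: DatasetPanelConfig | None = None,
) -> tuple[list[DETable], SyntheticTruth]:
    """Generate one DE table per panel dataset with planted class structure.

    Planted genes receive ``log2fc = ±effect_lfc + N(0, 0.1·noise_sd)`` and
    ``p ~ U(0, planted_p_scale)`` in their class-defining datasets and null
    draws elsewhere; null draws are ``p ~ U(0, 1)`` with a fold change held
    inside (−lfc_threshold, lfc_threshold) except with probability
    ``null_escape_prob``, where it lands just over the threshold.
    """
    if panel is None:
        panel = DatasetPanelConfig(lfc_threshold=config.lfc_threshold)
    rng = np.random.default_rng([config.seed, _STREAM_TRAINING])
    gene_truth = _plant_classes(config, rng)
    truth = SyntheticTruth(genes=gene_truth)
    n = config.n_genes
    directions = gene_truth["true_direction"].to_numpy().astype(float)
    class_of = gene_truth["true_class"].to_numpy()
    subsets = dict(panel.class_subsets())
    thr = config.lfc_threshold
    lfc_noise_sd = 0.1 * config.noise_sd

    tables: list[DETable] = []
    for d in panel.dataset_ids:
        # planted in this dataset = gene's class-defining subset contains d
        planted_here = np.array([c != "" and d in subsets[c] for c in class_of])
        lfc = np.empty(n)
        pvals = np.empty(n)
        # null draws for everything, then overwrite the planted entries
        base = rng.normal(0.0, lfc_noise_sd, size=n)
        inside = np.clip(base, -(thr - 1e-9), thr - 1e-9)
        escapes = rng.random(n) < config.null_escape_prob
        escape_lfc = rng.uniform(thr, 3 * thr, size=n) * np.where(rng.random(n) < 0.5, 1.0, -1.0)
        lfc = np.where(escapes, escape_lfc, inside)
        pvals = rng.uniform(0.0, 1.0, size=n)
        lfc[planted_here] = directions[planted_here] * config.effect_lfc + rng.normal(
            0.0, lfc_noise_sd, size=int(planted_here.sum())
        )
        pvals[planted_here] = rng.uniform(0.0, config.planted_p_scale, size=int(planted_here.sum()))
        tables.append(
            DETable(
                dataset_id=d,
                frame=pd.DataFrame(
                    {"gene": gene_truth["gene"], "log2fc": lfc, "pvalue": pvals}
                ),
            )
        )
    return tables, truth


def simulate_cohort(
    config: SimulationConfig,
    truth: SyntheticTruth,
    older_group: str = "group1",
    affected_classes: tuple[str, ...] | None = None,
    effect_lfc: float | None = None,
) -> tuple[ExpressionMatrix, SampleGrouping, SyntheticTruth]:
    """Simulate a two-group test cohort on log2 scale.

    Per-gene baseline ~ N(5, 1); per-sample noise ~ N(0, noise_sd); the
    designated older group (``"group1"`` or ``"group2"``) is shifted by
    ``true_direction × effect_lfc`` on the planted genes of
    ``affected_classes`` (default: all planted classes — a tissue where
    every signature applies; pass e.g. ``("Pan", "pF")`` for a fibroblast
    cohort).  ``effect_lfc=0`` gives a null cohort.
    """
    if older_group not in ("group1", "group2"):
        raise ValidationError("older_group must be 'group1' or 'group2'")
    if effect_lfc is None:
        effect_lfc = config.effect_lfc
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n, m = config.group_sizes
    genes = truth.genes["gene"].tolist()
    n_genes = len(genes)
    baseline = rng.normal(5.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n + m))

    affected = truth.genes["true_class"].isin(
        affected_classes if affected_classes is not None else SIGNATURE_CLASSES
    ).to_numpy() & (truth.genes["true_class"] != "").to_numpy()
    shift = truth.genes["true_direction"].to_numpy().astype(float) * effect_lfc
    older_cols = slice(0, n) if older_group == "group1" else slice(n, n + m)
    values[affected, older_cols] += shift[affected, None]

    group1 = [f"s1_{i + 1:02d}" for i in range(n)]
    group2 = [f"s2_{i + 1:02d}" for i in range(m)]
    expr = ExpressionMatrix(genes, group1 + group2, values, scale_tag="log")
    return expr, SampleGrouping(group1=group1, group2=group2), truth


@dataclass
class PlantedPerturbation:
    """A planted age-modifying perturbation: shifts one signature class's
    genes by ``sign × effect_size × true_direction`` in treated samples;
    one screen condition (dose) per effect size."""

    perturbation_id: str
    class_label: str
    sign: int = 1
    effect_sizes: tuple[float, ...] = (1.0,)


def simulate_screen(
    config: SimulationConfig,
    truth: SyntheticTruth,
    planted: list[PlantedPerturbation] | None = None,
    n_plates: int = 2,
    n_replicates: int = 3,
    n_controls_per_plate: int = 6,
    control_label: str = "vehicle",
) -> tuple[ExpressionMatrix, ScreenMetadata, SyntheticTruth]:
    """Simulate a perturbation screen with plates, replicates and controls.

    ``n_null_perturbations`` no-effect perturbations plus the ``planted``
    ones (default: one age-inducing perturbation on the Pan class at
    ``effect_lfc``), each profiled with ``n_replicates`` treated instances
    on each of ``n_plates`` plates; every plate also carries
    ``n_controls_per_plate`` vehicle-control instances.
    """
    if planted is None:
        planted = [
            PlantedPerturbation(
                "planted_ager", "Pan", sign=1, effect_sizes=(config.effect_lfc,)
            )
        ]
    rng = np.random.default_rng([config.seed, _STREAM_SCREEN])
    genes = truth.genes["gene"].tolist()
    n_genes = len(genes)
    baseline = rng.normal(5.0, 1.0, size=n_genes)
    directions = truth.genes["true_direction"].to_numpy().astype(float)
    class_of = truth.genes["true_class"].to_numpy()

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    shifts: list[np.ndarray | None] = []  # per-sample expression shift

    plates = [f"P{p + 1}" for p in range(n_plates)]
    zero = None
    for plate in plates:
        for c in range(n_controls_per_plate):
            sid = f"{plate}_ctl_{c + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                dict(sample_id=sid, perturbation_id=control_label, dose="-666",
                     time="24 h", plate_id=plate, is_control=True)
            )
            shifts.append(zero)

    pert_truth_rows = []
    null_ids = [f"pert_{i + 1:03d}" for i in range(config.n_null_perturbations)]
    for pid in null_ids:
        pert_truth_rows.append(
            dict(perturbation_id=pid, true_effect_class="", true_effect_size=0.0, true_sign=0)
        )
        for plate in plates:
            for r in range(n_replicates):
                sid = f"{plate}_{pid}_r{r + 1}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, perturbation_id=pid, dose="10 uM",
                         time="24 h", plate_id=plate, is_control=False)
                )
                shifts.append(zero)

    for pp in planted:
        mask = class_of == pp.class_label
        if not mask.any():
            raise ValidationError(f"no planted genes for class {pp.class_label!r} in truth")
        pert_truth_rows.append(
            dict(
                perturbation_id=pp.perturbation_id,
                true_effect_class=pp.class_label,
                true_effect_size=float(max(pp.effect_sizes)),
                true_sign=int(pp.sign),
            )
        )
        for es in pp.effect_sizes:
            shift_vec = np.where(mask, pp.sign * es * directions, 0.0)
            dose = f"{es:g} uM"
            for plate in plates:
                for r in range(n_replicates):
                    sid = f"{plate}_{pp.perturbation_id}_{es:g}_r{r + 1}"
                    sample_ids.append(sid)
                    meta_rows.append(
                        dict(sample_id=sid, perturbation_id=pp.perturbation_id, dose=dose,
                             time="24 h", plate_id=plate, is_control=False)
                    )
                    shifts.append(shift_vec)

    n_samples = len(sample_ids)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    for j, sh in enumerate(shifts):
        if sh is not None:
            values[:, j] += sh

    expr = ExpressionMatrix(genes, sample_ids, values, scale_tag="log")
    meta = ScreenMetadata(frame=pd.DataFrame(meta_rows))
    out_truth = SyntheticTruth(
        genes=truth.genes.copy(), perturbations=pd.DataFrame(pert_truth_rows)
    )
    return expr, meta, out_truth
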