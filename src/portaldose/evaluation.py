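"""Study harnesses: per-beam metric tables, variant comparison, CV reports,
and the training-data-amount study.

Every aggregate reported here is recomputable from the per-beam rows it was
derived from; reports are deterministic for fixed seeds.  Statistical
significance tests are deliberately not provided — paired differences with
seeded bootstrap confidence intervals are reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DoseDistribution
from .gamma_metrics import GammaCriteria, dose_errors, gamma_map
from .model import TDMLayer, UNet, UNetSpec, infer
from .preprocessing import NormalizationFactors, edge_correct
from .synthetic_beams import FieldPair
from .training import PreparedDataset, TrainingConfig, TwoStepResult, two_step_train

__all__ = [
    "StudyReport",
    "evaluate_beams",
    "compare_variants",
    "cv_report",
    "data_amount_study",
    "synthetic_benchmark",
]


@dataclass
class StudyReport:
    """Per-beam metric rows plus aggregates recomputed from them."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _aggregate(rows: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    metrics = ["mean_gamma", "passing_rate", "abs_error_gy", "rel_error_pct"]
    return rows.groupby(by, as_index=False)[metrics].agg(["mean", "std", "min", "max"])


def evaluate_beams(
    network: UNet,
    tdm: TDMLayer | None,
    pairs: list[FieldPair],
    norm: NormalizationFactors,
    criteria: GammaCriteria = GammaCriteria(),
    crop_px: int | None = None,
    subsample: int = 10,
    variant: str = "unet_tdm",
) -> pd.DataFrame:
    """Infer every beam and score it against its reference dose.

    The reference pPD is edge-corrected with the same border as the training
    data so that both maps live in the same preprocessed domain.
    """
    rows = []
    for pair in pairs:
        mpd = infer(network, tdm, pair.mpi, norm, crop_px=crop_px)
        from .preprocessing import default_crop_px

        cp = default_crop_px(pair.ppd.grid) if crop_px is None else crop_px
        ref = DoseDistribution(edge_correct(pair.ppd.values, cp), pair.ppd.grid)
        res = gamma_map(ref, mpd, criteria, subsample=subsample)
        abs_err, rel_err = dose_errors(ref, mpd, criteria.low_dose_threshold)
        rows.append(
            {
                "beam": pair.beam.label,
                "kind": pair.beam.kind,
                "variant": variant,
                "mean_gamma": res.mean_gamma,
                "passing_rate": res.passing_rate,
                "abs_error_gy": abs_err,
                "rel_error_pct": rel_err,
            }
        )
    return pd.DataFrame(rows)


def compare_variants(
    control_set: list[FieldPair],
    trained_unet: UNet,
    trained_unet_tdm: tuple[UNet, TDMLayer],
    norm: NormalizationFactors,
    criteria: GammaCriteria = GammaCriteria(),
    crop_px: int | None = None,
    subsample: int = 10,
    bootstrap_seed: int = 0,
    n_bootstrap: int = 1000,
) -> StudyReport:
    """Score the bare U-net against the fine-tuned U-net + TDM on one set.

    Reports all four metrics per beam per variant, paired per-beam
    differences (TDM minus bare), and seeded bootstrap confidence intervals
    of the mean paired difference.
    """
    if not control_set:
        raise ValueError("control set is empty")
    net_tdm, tdm = trained_unet_tdm
    rows = pd.concat(
        [
            evaluate_beams(
                trained_unet, None, control_set, norm, criteria, crop_px, subsample, "unet"
            ),
            evaluate_beams(
                net_tdm, tdm, control_set, norm, criteria, crop_px, subsample, "unet_tdm"
            ),
        ],
        ignore_index=True,
    )
    metrics = ["mean_gamma", "passing_rate", "abs_error_gy", "rel_error_pct"]
    a = rows[rows.variant == "unet_tdm"].set_index("beam")[metrics]
    b = rows[rows.variant == "unet"].set_index("beam")[metrics]
    paired = (a - b).reset_index()

    rng = np.random.default_rng(bootstrap_seed)
    cis = {}
    n = len(paired)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    for m in metrics:
        vals = paired[m].to_numpy()
        boots = vals[idx].mean(axis=1)
        cis[m] = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return StudyReport(
        rows=rows,
        aggregates=_aggregate(rows, ["variant", "kind"]),
        extras={"paired_differences": paired, "bootstrap_ci_95": cis},
    )


def cv_report(fold_tables: list[pd.DataFrame]) -> StudyReport:
    """Per-fold distribution summary of test-set gamma statistics.

    ``fold_tables[f]`` holds the per-beam rows of fold ``f``'s test set (as
    produced by :func:`evaluate_beams`, plus a ``fold_id`` column added
    here).  Quartiles support the usual cross-validation box plots.
    """
    rows = pd.concat(
        [t.assign(fold_id=f) for f, t in enumerate(fold_tables)], ignore_index=True
    )
    summaries = []
    for f, tbl in rows.groupby("fold_id"):
        entry = {"fold_id": f, "n_beams": len(tbl)}
        for m in ("mean_gamma", "passing_rate"):
            v = tbl[m].to_numpy()
            entry.update(
                {
                    f"{m}_mean": float(v.mean()),
                    f"{m}_median": float(np.median(v)),
                    f"{m}_q1": float(np.percentile(v, 25)),
                    f"{m}_q3": float(np.percentile(v, 75)),
                }
            )
        summaries.append(entry)
    return StudyReport(rows=rows, aggregates=pd.DataFrame(summaries))


def data_amount_study(
    sizes: list[int],
    dataset: PreparedDataset,
    control_set: list[FieldPair],
    cfg: TrainingConfig,
    spec: UNetSpec = UNetSpec(),
    k_folds: int = 1,
    seed: int = 0,
    criteria: GammaCriteria = GammaCriteria(),
    subsample: int = 5,
) -> StudyReport:
    """Learning-curve study: retrain at increasing training-set sizes.

    For each size, samples are drawn at random (seeded) from the prepared
    dataset, split 80/20 into train/validation over ``k_folds`` folds, and a
    two-step model is trained per fold; gamma statistics are measured on a
    fixed held-out control set.
    """
    n_total = len(dataset.X)
    if any(s > n_total for s in sizes):
        raise ValueError("requested size exceeds the dataset")
    if any(s < cfg.batch_size for s in sizes):
        raise ValueError("size smaller than the batch size")
    from .training import FoldSplit

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        subset = np.sort(rng.choice(n_total, size=size, replace=False))
        for fold_id in range(k_folds):
            rng_f = np.random.default_rng(
                np.random.SeedSequence([seed & 0x7FFFFFFF, size, fold_id])
            )
            perm = rng_f.permutation(subset)
            n_train = round(0.8 * size)
            fold = FoldSplit(
                fold_id=fold_id,
                train=np.sort(perm[:n_train]),
                validation=np.sort(perm[n_train:]),
                test=np.array([], dtype=int),  # scoring uses the external control set
            )
            result = two_step_train(dataset, fold, cfg, spec)
            table = evaluate_beams(
                result.network,
                result.tdm,
                control_set,
                dataset.norm,
                criteria,
                dataset.crop_px,
                subsample,
            )
            for _, r in table.iterrows():
                rows.append({"size": size, "fold_id": fold.fold_id, **r.to_dict()})
    rows = pd.DataFrame(rows)
    return StudyReport(rows=rows, aggregates=_aggregate(rows, ["size"]))


def synthetic_benchmark(
    seed: int,
    noise_sd: float | None = None,
    n_train: int = 40,
    n_validation: int = 10,
    n_test: int = 10,
    max_epochs_stage1: int = 30,
    max_epochs_finetune: int = 15,
    criteria: GammaCriteria = GammaCriteria(),
    subsample: int = 5,
) -> dict:
    """One desk-scale end-to-end experiment: simulate, train two-step, score.

    Mirrors the full-scale study design at desk scale: a randomized clinical
    training set with an 80/20-style train/validation split, held-out
    clinical control beams, and the six square evaluation beams — scored for
    both the bare U-net and the fine-tuned U-net + TDM.  Also measures how
    well the TDM layer recovered the simulator's true off-axis horn profile
    (RMS deviation over the central 80 % of the TDM field).

    Returns a flat dict of metrics; deterministic for a fixed seed.
    """
    from .synthetic_beams import (
        CALIBRATION_SIDES_MM,
        TDM_SQUARE_MM,
        desk_config,
        generate_dataset,
    )
    from .gamma_metrics import profile_extract
    from .training import FoldSplit, TrainingConfig, prepare_dataset, two_step_train

    sim = desk_config(seed=seed)
    if noise_sd is not None:
        from dataclasses import replace

        sim = replace(sim, noise_sd=noise_sd)
    n_total = n_train + n_validation + n_test
    pairs, calibration = generate_dataset(n_total, sim, seed=seed)
    dataset = prepare_dataset(pairs, calibration)
    fold = FoldSplit(
        fold_id=0,
        train=np.arange(n_train),
        validation=np.arange(n_train, n_train + n_validation),
        test=np.arange(n_train + n_validation, n_total),
    )
    cfg = TrainingConfig(
        rng_seed=seed,
        max_epochs_stage1=max_epochs_stage1,
        max_epochs_finetune=max_epochs_finetune,
    )
    result = two_step_train(dataset, fold, cfg)

    # TDM vs the simulator's true horn, central 80 % of the TDM beam's field
    grid = dataset.grid
    c = grid.center_index
    field_mm = min(TDM_SQUARE_MM, grid.side_mm)
    w = min(int(0.8 * field_mm / 2 / grid.pixel_pitch), c - 1)
    _, tdm_prof = profile_extract(result.tdm.values, grid)
    _, truth_prof = profile_extract(pairs[0].truth_horn, grid)
    sel = slice(c - w, c + w + 1)
    tdm_rms = float(np.sqrt(np.mean((tdm_prof[sel] - truth_prof[sel]) ** 2)))

    clinical_control = [pairs[i] for i in fold.test]
    squares = [calibration[s] for s in CALIBRATION_SIDES_MM if s != TDM_SQUARE_MM]
    out = {"seed": seed, "tdm_rms": tdm_rms, "n_epochs": len(result.history)}
    for name, control in (("clinical", clinical_control), ("square", squares)):
        for variant, net, tdm in (
            ("unet", result.stage1_network, None),
            ("unet_tdm", result.network, result.tdm),
        ):
            table = evaluate_beams(
                net, tdm, control, dataset.norm, criteria, dataset.crop_px, subsample, variant
            )
            out[f"{name}_{variant}_mean_gamma"] = float(table.mean_gamma.mean())
            out[f"{name}_{variant}_passing_rate"] = float(table.passing_rate.mean())
    return out
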