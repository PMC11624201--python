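"""Canned desk-scale phantom studies.

Each study builds its inputs from the phantom generators, runs the
corresponding pipeline stage end-to-end and returns the quantities a
validation report needs. The same functions back the test suite, the
examples and ``scripts/acceptance.py``, so every reported number is
recomputed from scratch at the stated problem sizes (chosen to keep a full
study suite within tens of minutes on one CPU).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ctp as ctp_mod
from .cnn_age import CnnConfig, predict_age_cnn, train_cnn_ensemble
from .fusion_eval import (auroc_delong, calibration_split_evaluate,
                          compare_r2_ftest, compare_slopes_z,
                          error_vs_time_regression, mcnemar)
from .growth import added_value, compare_added_values, fit_growth_baseline
from .io_preprocess import mirror_mask
from .nwu import relative_intensity
from .phantom import (default_ctp_spec, generate_ctp_series,
                      generate_growth_cohort, simulate_cohort,
                      simulate_thick_slices)
from .radiomics import extract_features, select_features
from .segmentation import (UNetConfig, dice, extract_ranked_components,
                           predict_probability, train_unet25d)

__all__ = ["age_model_study", "segmentation_study", "ctp_recovery_study",
           "growth_added_value_study", "build_age_table"]


def build_age_table(cohort, cnn_ensemble=None, seed: int = 0) -> pd.DataFrame:
    """Per-subject table: ots, ri, cnn_log, radiomic feature columns."""
    rows = []
    for i, (rec, vol, mask) in enumerate(cohort):
        mir = mirror_mask(mask)
        row = {"subject_id": rec.subject_id, "ots": rec.ots,
               "ri": relative_intensity(vol, mask, mir).ri}
        row.update(extract_features(vol, mask, mir).values)
        if cnn_ensemble is not None:
            row["cnn_log"] = predict_age_cnn(
                cnn_ensemble, vol, mask, seed=seed + 31 * i).log_ots
        rows.append(row)
    return pd.DataFrame(rows)


def age_model_study(n: int = 400, seed: int = 0, n_splits: int = 20,
                    thick_factor: int = 4, cnn_cfg: CnnConfig | None = None,
                    full_stats: bool = True) -> dict:
    """Train/test comparison of the four lesion-age model families.

    The cohort is split in half: the first half trains the CNN ensemble and
    the radiomic feature selection; the second half is the held-out set
    evaluated with the half-calibration split protocol for each family
    (RI linear, RI GPR, radiomics-only GPR, CNN-only GPR, CNN-R fusion).
    """
    cohort = simulate_cohort(n, seed=seed)
    half = n // 2
    train, test = cohort[:half], cohort[half:]

    cnn_cfg = cnn_cfg or CnnConfig.desk(seed=seed + 1)
    ensemble = train_cnn_ensemble(
        [(v, m, rec.ots) for rec, v, m in train], cnn_cfg)

    train_table = build_age_table(train, seed=seed + 2)
    feat_cols = [c for c in train_table.columns
                 if c.startswith(("lesion_", "diff_", "shape_"))]
    selected = select_features(train_table[feat_cols],
                               np.log(train_table["ots"].to_numpy()),
                               seed=seed + 3)

    test_table = build_age_table(test, cnn_ensemble=ensemble, seed=seed + 4)

    reports = {}
    for fam in ("ri_linear", "ri_gpr", "radiomics", "cnn", "cnn_r"):
        reports[fam] = calibration_split_evaluate(
            test_table, fam, feature_cols=selected,
            n_splits=n_splits, seed=seed + 5)

    out = dict(reports=reports, selected_features=selected,
               test_table=test_table, ensemble=ensemble, n=n)

    # thick-slice degradation: re-acquire the test half at thick slices and
    # re-extract everything; block averaging destroys the voxel-scale
    # texture the radiomic clock reads, so that family shows the
    # first-order effect (RI, a region mean, is nearly dilution-invariant)
    if thick_factor:
        thick = [(rec, *simulate_thick_slices(v, m, thick_factor))
                 for rec, v, m in test]
        thick_table = build_age_table(thick, seed=seed + 7)
        for fam, key in (("radiomics", "radiomics_thick"),
                         ("ri_gpr", "ri_gpr_thick")):
            out[key] = calibration_split_evaluate(
                thick_table, fam, feature_cols=selected,
                n_splits=n_splits, seed=seed + 5)

    # partial F: best RI model vs the fused model (undefined if the fused
    # model fails to dominate)
    n_test = len(test_table)
    try:
        out["f_test"] = compare_r2_ftest(
            reports["ri_gpr"].r2, reports["cnn_r"].r2, n_test,
            p_small=1, p_large=1 + len(selected))
    except ValueError:
        out["f_test"] = None

    if full_stats:
        out.update(_comparison_battery(test_table, selected, seed))
    return out


def _split_predictions(table: pd.DataFrame, selected, seed: int) -> dict:
    """One half-calibration split's pooled out-of-fold predictions per family
    (the paired predictions the AUROC / McNemar / error-slope battery needs)."""
    from .fusion_eval import _fit_family, _predict_family, family_columns

    rng = np.random.default_rng(seed + 6)
    n = len(table)
    perm = rng.permutation(n)
    half = n // 2
    preds = {}
    for fam in ("ri_gpr", "cnn_r"):
        cols, kind = family_columns(fam, selected)
        pred = np.full(n, np.nan)
        for cal, tst in ((perm[:half], perm[half:]),
                         (perm[half:], perm[:half])):
            model = _fit_family(table.iloc[cal], cols, kind, seed)
            pred[tst] = _predict_family(model, table.iloc[tst], cols)
        preds[fam] = pred
    return preds


def _comparison_battery(table: pd.DataFrame, selected, seed: int) -> dict:
    preds = _split_predictions(table, selected, seed)
    ots = table["ots"].to_numpy(dtype=float)
    out = {}
    for thr, key in ((4.5, "le_4p5h"), (24.0, "ge_24h")):
        labels = ots >= thr if key == "ge_24h" else ots <= thr
        # continuous log-OTS estimate scores the threshold classification
        sa = preds["cnn_r"] if key == "ge_24h" else -preds["cnn_r"]
        sb = preds["ri_gpr"] if key == "ge_24h" else -preds["ri_gpr"]
        auc_a, auc_b, z, p = auroc_delong(sa, sb, labels)
        out[f"auroc_cnn_r_{key}"] = auc_a
        out[f"auroc_ri_{key}"] = auc_b
        out[f"delong_z_{key}"] = z

    # error magnitude vs time, with slope comparison
    slopes = {}
    for fam in ("ri_gpr", "cnn_r"):
        err_min = np.abs(np.exp(preds[fam]) - ots) * 60.0
        slope, ci, se = error_vs_time_regression(err_min, ots)
        slopes[fam] = (slope, se)
        out[f"error_slope_{fam}"] = slope
    out["error_slope_z"], _ = compare_slopes_z(*slopes["ri_gpr"],
                                               *slopes["cnn_r"])

    # McNemar on window classification correctness
    from .fusion_eval import _window_of
    tw = _window_of(ots)
    correct = {fam: _window_of(np.exp(preds[fam])) == tw for fam in preds}
    try:
        chi2, p = mcnemar(correct["cnn_r"], correct["ri_gpr"])
        out["mcnemar_chi2"], out["mcnemar_p"] = chi2, p
    except ValueError:
        out["mcnemar_chi2"] = out["mcnemar_p"] = None
    return out


def segmentation_study(n_train: int = 30, n_test: int = 10, seed: int = 0,
                       cfg: UNetConfig | None = None,
                       ots_range=(6.0, 48.0)) -> dict:
    """Train the small U-Net on phantoms and score held-out phantoms.

    ``ots_range`` defaults to the subacute window, matching the two-model
    design in which each segmentation model sees its own age class.
    """
    cohort = simulate_cohort(n_train + n_test, seed=seed, ots_range=ots_range)
    cfg = cfg or UNetConfig.desk(seed=seed + 1)
    model = train_unet25d([(v, m) for _, v, m in cohort[:n_train]], cfg)
    dscs, captures, volumes = [], [], []
    for rec, v, m in cohort[n_train:]:
        comps = extract_ranked_components(predict_probability(model, v))
        d = dice(comps[0].mask, m) if comps else 0.0
        dscs.append(d)
        captures.append(d > 0.2)
        volumes.append((comps[0].mask.count() if comps else 0, m.count()))
    return dict(model=model, dscs=np.asarray(dscs),
                mean_dsc=float(np.mean(dscs)),
                top1_capture_rate=float(np.mean(captures)),
                loss_history=model.history, volumes=volumes)


def ctp_recovery_study(seed: int = 0, snr: float = 20.0) -> dict:
    """Perfusion-parameter recovery on the standard mismatch phantom.

    Noise-free recovery uses minimal truncation (the inverse problem is
    well-posed without noise); the noisy arm uses the full denoising chain
    (50 diffusion iterations) with truncation matched to the residual noise.
    """
    spec = default_ctp_spec(noise_sd=0.0)
    frames, ts, truth = generate_ctp_series(spec)
    brain = truth["brain"].copy()
    brain[spec.aif_voxel] = brain[spec.vof_voxel] = False

    maps = ctp_mod.compute_perfusion_maps(
        frames, ts, spec.aif_voxel, spec.vof_voxel, spacing=spec.spacing,
        sv_threshold_frac=0.001)
    cbf_rel = np.abs(maps.cbf[brain] - truth["cbf"][brain]) / truth["cbf"][brain]
    mtt_rel = np.abs(maps.mtt[brain] - truth["mtt"][brain]) / truth["mtt"][brain]
    tmax_err = np.abs(maps.tmax[brain] - truth["tmax"][brain])

    ref = ctp_mod.hemispheric_reference(maps.cbf, brain, "left")
    mm = ctp_mod.core_penumbra(maps, ref, brain)
    vox_ml = float(np.prod(spec.spacing)) / 1000.0
    cpr_truth = truth["core"].sum() / truth["penumbra"].sum()
    out = dict(
        cbf_rel_err_median=float(np.median(cbf_rel)),
        mtt_rel_err_median=float(np.median(mtt_rel)),
        tmax_abs_err_p90=float(np.percentile(tmax_err, 90)),
        cpr=mm.cpr, cpr_truth=float(cpr_truth),
        cpr_rel_err=float(abs(mm.cpr - cpr_truth) / cpr_truth),
        core_ml=mm.core_volume_ml,
        core_ml_truth=float(truth["core"].sum() * vox_ml),
        penumbra_ml=mm.penumbra_volume_ml,
        penumbra_ml_truth=float(truth["penumbra"].sum() * vox_ml),
    )

    # delay insensitivity: +4 s everywhere must not move CBF
    spec_d = default_ctp_spec(noise_sd=0.0)
    spec_d.true_delay = spec_d.true_delay + 4.0
    f2, t2, _ = generate_ctp_series(spec_d)
    maps_d = ctp_mod.compute_perfusion_maps(
        f2, t2, spec_d.aif_voxel, spec_d.vof_voxel, spacing=spec_d.spacing,
        sv_threshold_frac=0.001)
    out["cbf_delay_shift_median"] = float(np.median(
        np.abs(maps_d.cbf[brain] - maps.cbf[brain])
        / np.maximum(maps.cbf[brain], 1e-9)))

    # noisy arm at the stated SNR (vs mean healthy peak enhancement)
    healthy = brain & (truth["tmax"] <= 6.0)
    peak = float((frames[healthy].max(axis=-1) - spec.baseline_hu).mean())
    spec_n = default_ctp_spec(noise_sd=peak / snr, seed=seed + 1)
    fn, tn, _ = generate_ctp_series(spec_n)
    maps_n = ctp_mod.compute_perfusion_maps(
        fn, tn, spec_n.aif_voxel, spec_n.vof_voxel, spacing=spec_n.spacing,
        sv_threshold_frac=0.005, diffusion_iters=50)
    out["cbf_rel_err_median_noisy"] = float(np.median(
        np.abs(maps_n.cbf[brain] - truth["cbf"][brain]) / truth["cbf"][brain]))
    return out


def growth_added_value_study(n: int = 500, seed: int = 0) -> dict:
    """Added value of a low-noise biological-age biomarker vs chronometric
    onset time in predicting % infarct expansion."""
    table = generate_growth_cohort(n, seed=seed)
    base = fit_growth_baseline(table)
    biomarker = added_value(table, "biomarker", baseline=base)
    cots = added_value(table, "cots", baseline=base)
    z, p = compare_added_values(biomarker, cots)
    return dict(table=table, baseline=base, biomarker=biomarker, cots=cots,
                coef_z=z, coef_z_p=p)
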