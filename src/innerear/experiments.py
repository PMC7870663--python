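"""End-to-end phantom experiments shared by the analysis drivers, the
acceptance checks and the test suite.

Each experiment draws its phantoms, runs the corresponding slice of the
pipeline and returns plain dictionaries of summary numbers.  Every source of
randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .morphometry import measure_all, region_volumes
from .phantom import (
    NOISE_SIGMA_INDIVIDUAL,
    NOISE_SIGMA_SNR4,
    CohortSpec,
    PhantomParams,
    cohort_to_table,
    generate_cohort,
    generate_phantom,
    phantom_region_masks,
)
from .registration import register_sdt, transfer_meshes, voxelize_labels
from .reid import (
    PlaneFit,
    RoiSpec,
    crop_roi,
    fit_reid_plane,
    mirror_sagittal,
    reorient_landmarks,
    reorient_to_plane,
)
from .stats import gender_ancova, laterality_tests
from .surfaces import (
    extract_iso_surface,
    extract_main_surface,
    mesh_volume,
    segment_bright_structure,
    signed_distance,
)
from .template import build_template, snr_gain_report
from .validation import dice

__all__ = [
    "phantom_recovery_experiment",
    "label_transfer_experiment",
    "template_experiment",
    "statistics_experiment",
]

#: the two "subjects" used for atlas-style label transfer: size and shape
#: differences drawn once at cohort-realistic magnitudes
TRANSFER_PAIR = (
    dict(global_scale=0.97, scc_radius_lat=2.87, cochlea_base_diameter=7.6),
    dict(global_scale=1.04, scc_radius_lat=2.93, cochlea_base_diameter=7.78),
)


def _tilt_plane(rng, max_deg=8.0) -> PlaneFit:
    angle = np.deg2rad(rng.uniform(3.0, max_deg))
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(phi), np.sin(phi), 0.0])
    normal = np.array([np.sin(angle) * axis[1], -np.sin(angle) * axis[0],
                       np.cos(angle)])
    return PlaneFit(normal=normal, point=np.zeros(3), residual=0.0)


def recover_one_phantom(seed: int, scale: float, side: str) -> dict:
    """Full chain on one phantom at SNR ~4: render, tilt, Reid-fit,
    reorient, crop, mirror, measure, Otsu-segment, volumetry."""
    rng = np.random.default_rng(seed)
    params = PhantomParams(noise_sigma=NOISE_SIGMA_SNR4, global_scale=scale,
                           side=side)
    channels, truth = generate_phantom(params, seed=seed,
                                       channels=("t2like",))
    volume = channels["t2like"]
    tilt = _tilt_plane(rng)
    tilted = reorient_to_plane(volume, tilt)
    landmarks = reorient_landmarks(truth.landmarks, tilt, volume)
    plane = fit_reid_plane(landmarks)
    upright = reorient_to_plane(tilted, plane)
    landmarks = reorient_landmarks(landmarks, plane, tilted)
    center = 0.5 * (landmarks["vestibule_length_a"]
                    + landmarks["vestibule_length_b"])
    cropped = crop_roi(upright, RoiSpec(center=center))
    if side == "left":
        cropped = mirror_sagittal(cropped)
    report = measure_all(landmarks)
    distance_errors = {
        name: abs(report[name] - truth.true_measures[name])
        for name in report if not name.startswith("vol_")
    }
    threshold, _, smoothed = segment_bright_structure(cropped)
    mesh = extract_main_surface(smoothed, threshold)
    total = mesh_volume(mesh)
    volume_errors = {
        "vol_inner_ear_total": abs(total - truth.true_measures["vol_inner_ear_total"])
        / truth.true_measures["vol_inner_ear_total"]
    }
    mesh_vols = region_volumes(truth.region_meshes)
    for name, value in mesh_vols.items():
        ref = truth.true_measures[name]
        volume_errors[name] = abs(value - ref) / ref
    return {
        "max_distance_error_mm": max(distance_errors.values()),
        "max_volume_error_fraction": max(volume_errors.values()),
        "otsu_threshold": threshold,
    }


def phantom_recovery_experiment(seed: int, n_seeds: int = 10) -> dict:
    """Parameter recovery across phantoms with varied size, side and tilt."""
    rng = np.random.default_rng(seed)
    dist_errors, vol_errors = [], []
    for i in range(n_seeds):
        scale = float(rng.uniform(0.93, 1.07))
        side = "left" if i % 2 else "right"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        result = recover_one_phantom(sub_seed, scale, side)
        dist_errors.append(result["max_distance_error_mm"])
        vol_errors.append(result["max_volume_error_fraction"])
    return {
        "n_seeds": n_seeds,
        "max_distance_error_mm": float(np.max(dist_errors)),
        "max_volume_error_pct": float(np.max(vol_errors)) * 100.0,
    }


def label_transfer_experiment(registration_spacing: float = 0.3,
                              iterations: int = 40) -> dict:
    """Register one phantom's labyrinth surface onto another via SDT
    surrogates and score the transferred atlas regions."""
    from .phantom import make_truth

    p_atlas = PhantomParams(spacing=registration_spacing, **TRANSFER_PAIR[0])
    p_subject = PhantomParams(spacing=registration_spacing, **TRANSFER_PAIR[1])
    m_atlas = phantom_region_masks(p_atlas, regions=("labyrinth",))["labyrinth"]
    m_subject = phantom_region_masks(p_subject, regions=("labyrinth",))["labyrinth"]
    field = register_sdt(signed_distance(m_atlas), signed_distance(m_subject),
                         iterations=iterations)
    truth_atlas = make_truth(p_atlas, volumes=False)
    truth_subject = make_truth(p_subject, volumes=False)
    moved = transfer_meshes(truth_atlas.region_meshes, field)
    # evaluation at the atlas voxelization resolution (0.2 mm) on the
    # subject's grid
    p_eval = replace(p_subject, spacing=0.2)
    lab_eval = phantom_region_masks(p_eval, regions=("labyrinth",))["labyrinth"]

    def empty(dtype):
        return lab_eval.copy(values=np.zeros(lab_eval.shape, dtype=dtype))

    lab_mesh = extract_iso_surface(
        m_atlas.copy(values=m_atlas.values.astype(float)), 0.5)
    moved_lab = transfer_meshes({"labyrinth": lab_mesh}, field)["labyrinth"]
    from .surfaces import voxelize_mesh

    whole = voxelize_mesh(moved_lab, grid=empty(np.uint8))
    whole_dice = dice(whole, lab_eval)
    truth_labels = voxelize_labels(truth_subject.region_meshes,
                                   grid=empty(np.int16))
    moved_labels = voxelize_labels(moved, grid=empty(np.int16))
    region_dice = {}
    for label, name in truth_labels.names.items():
        label_m = [k for k, v in moved_labels.names.items() if v == name][0]
        region_dice[name] = dice(
            truth_labels.volume.copy(
                values=truth_labels.volume.values == label),
            moved_labels.volume.copy(
                values=moved_labels.volume.values == label_m),
        )
    return {
        "whole_labyrinth_dice": float(whole_dice),
        "min_region_dice": float(min(region_dice.values())),
        "region_dice": {k: float(v) for k, v in region_dice.items()},
        "final_band_mismatch_mm": field.history["final"],
        "jacobian_positive_fraction": field.jacobian_positive_fraction(),
    }


_TEMPLATE_GRID = dict(spacing=0.4, extent_mm=(36.0, 36.0, 28.0))


def template_experiment(seed: int, n_subjects: int = 8,
                        iterations: int = 3) -> dict:
    """Template construction from a small phantom cohort.

    Subjects share the canonical anatomy up to overall size, carry
    independent noise at the single-subject SNR regime, and arrive with
    random residual crop offsets (up to +-1.5 mm), which the iterative
    alignment must remove.  A second template built from a phantom and its
    sagittal mirror probes side-unbiasedness.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        params = PhantomParams(
            noise_sigma=NOISE_SIGMA_INDIVIDUAL,
            global_scale=float(np.clip(rng.normal(1.0, 0.03), 0.92, 1.08)),
            **_TEMPLATE_GRID)
        channels, _ = generate_phantom(
            params, seed=int(rng.integers(0, 2**31 - 1)),
            channels=("t2like", "cisslike", "t1like"),
            truth_meshes=False, truth_volumes=False)
        offset = rng.uniform(-1.5, 1.5, 3)
        shifted = {
            name: vol.copy(values=ndimage.shift(
                vol.values, offset / vol.spacing, order=1, mode="nearest"))
            for name, vol in channels.items()
        }
        subjects.append(shifted)
    state = build_template(subjects, iterations=iterations)
    roi = phantom_region_masks(PhantomParams(**_TEMPLATE_GRID),
                               regions=("labyrinth",))["labyrinth"]
    report = snr_gain_report(state, subjects, roi)

    mirror_noise = 0.05
    channels, _ = generate_phantom(
        PhantomParams(noise_sigma=mirror_noise, **_TEMPLATE_GRID),
        seed=int(rng.integers(0, 2**31 - 1)), channels=("t2like",),
        truth_meshes=False, truth_volumes=False)
    mirrored = {k: mirror_sagittal(v) for k, v in channels.items()}
    sym_state = build_template([channels, mirrored], iterations=iterations)
    t = sym_state.channels["t2like"].values
    asymmetry = float(np.abs(t - t[::-1, :, :]).mean())
    return {
        "n_subjects": n_subjects,
        "snr_ratio_per_channel": dict(zip(report["channel"], report["ratio"])),
        "min_snr_ratio": float(report["ratio"].min()),
        "mean_snr_ratio": report.attrs["mean_ratio"],
        "mean_displacement_mm": state.mean_displacement,
        "history_first": state.history[0],
        "history_last": state.history[-1],
        "mirror_asymmetry": asymmetry,
        "mirror_noise_sigma": mirror_noise,
    }


def statistics_experiment(seed: int, n_null: int = 100, n_power: int = 30,
                          n_ancova: int = 60) -> dict:
    """Type-I / power behaviour of the cohort statistics battery on
    generated null and effect cohorts."""
    base = int(seed) % 100_000
    measures = None
    false_pos = total = clean = 0
    for i in range(n_null):
        table = cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, seed=base * 7 + i)))
        if measures is None:
            measures = [c for c in table.columns if c.startswith("scc_")]
        results = laterality_tests(table, measures)
        n_sig = sum(r.significant for r in results)
        false_pos += n_sig
        total += len(results)
        clean += n_sig == 0
    power_hits = 0
    for i in range(n_power):
        table = cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, laterality_effect=0.10,
                       seed=base * 11 + i)))
        results = laterality_tests(table, measures)
        lat = [r for r in results if r.measure == "scc_lat_radius"][0]
        power_hits += lat.significant
    ancova_null = ancova_power = 0
    for i in range(n_ancova):
        null_table = cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, seed=base * 13 + i)))
        ancova_null += gender_ancova(
            null_table, "inner_ear_length_total").pvalue > 0.05
        effect_table = cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, sex_effect=0.05, seed=base * 13 + i)))
        ancova_power += gender_ancova(
            effect_table, "inner_ear_length_total").pvalue < 0.05
    return {
        "laterality_type1_rate": false_pos / total,
        "laterality_clean_fraction": clean / n_null,
        "laterality_power": power_hits / n_power,
        "ancova_null_retention": ancova_null / n_ancova,
        "ancova_power": ancova_power / n_ancova,
        "n_null": n_null,
        "n_power": n_power,
        "n_ancova": n_ancova,
    }
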