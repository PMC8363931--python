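"""End-to-end orchestration: simulate -> register/QC -> segment -> zones ->
quantify -> survive, as one reproducible run.

A run writes stable filenames into an output directory (cohort.csv, qc.csv,
patient_table.csv, patient_table_scaled.csv, positivity.csv, screen.csv,
manifest.json, run.log).  The single global seed is fanned out per stage via
stage-name hashing, so re-running an identical config reproduces every
numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .config import RunConfig, config_hash, stage_seed
from .fixtures import write_fixture_bundle
from .image import MultiplexImage
from .phantom import (FIBROBLAST_MARKERS, TUMOR_MARKERS, PhantomSpec,
                      default_channel_models, generate_core_phantom,
                      random_core_geometry)
from .preprocessing import RegistrationError, qc_core, register_rounds
from .quantify import (build_patient_table, classify_tumor_positivity,
                       measure_core, pool_positivity, scale_for_cox)
from .segmentation import (classify_pixels, sample_training_pixels,
                           segment_components, train_pixel_classifier)
from .zones import compute_zones

__all__ = ["simulate_cores", "run_pipeline", "PipelineError"]

log = logging.getLogger("mesozone.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and core."""


def _split_rounds(image: MultiplexImage) -> tuple[MultiplexImage,
                                                  MultiplexImage]:
    by_round: dict[int, dict[str, np.ndarray]] = {1: {}, 2: {}}
    for name in image.channel_names:
        by_round[image.round_of(name)][name] = image.channels[name]
    mk = lambda chans, rid: MultiplexImage(
        channels=chans, pixel_size_um=image.pixel_size_um,
        core_id=image.core_id, patient_id=image.patient_id,
        round_ids={n: rid for n in chans})
    return mk(by_round[1], 1), mk(by_round[2], 2)


def _apply_shift(image: MultiplexImage, dy: int, dx: int) -> MultiplexImage:
    """Simulated stage offset of a second staining round (content shifted,
    vacated border filled with background level)."""
    shifted = {}
    for name, arr in image.channels.items():
        out = np.full_like(arr, float(np.median(arr)))
        h, w = arr.shape
        ya, yb = max(0, dy), min(h, h + dy)
        xa, xb = max(0, dx), min(w, w + dx)
        out[ya:yb, xa:xb] = arr[ya - dy:yb - dy, xa - dx:xb - dx]
        shifted[name] = out
    return MultiplexImage(channels=shifted, pixel_size_um=image.pixel_size_um,
                          core_id=image.core_id, patient_id=image.patient_id,
                          round_ids=dict(image.round_ids))


def simulate_cores(config: RunConfig):
    """Simulate the cohort and every patient's cores (two staining rounds).

    The cohort's ``marker_raw`` value becomes the tumor-compartment offset of
    the effect marker, so the injected hazard acts through a quantity the
    imaging pipeline must recover.  Every other marker gets independent
    per-patient tumor/stroma offsets (null with respect to survival).
    Returns (cohort, cores) where cores maps core_id ->
    (round1, round2, truth, true_shift).
    """
    rng = np.random.default_rng(stage_seed(config.seed, "simulate"))
    cohort = generate_cohort(CohortSpec(
        n_patients=config.n_patients, beta=config.beta,
        baseline_hazard=config.baseline_hazard,
        censor_rate=config.censor_rate,
        marker_distribution=config.marker_distribution,
        seed=stage_seed(config.seed, "cohort")))

    cores = {}
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        offsets: dict[str, dict[str, float]] = {}
        for marker in FIBROBLAST_MARKERS:
            offsets[marker] = {
                "tumor": float(rng.uniform(0.05, 0.45)),
                "stroma": float(rng.uniform(0.05, 0.45)),
            }
        # the hazard-driving variable overrides the effect marker/compartment
        comp = "tumor" if config.effect_compartment == "meso" else "stroma"
        offsets.setdefault(config.effect_marker, {})[comp] = \
            float(row["marker_raw"])
        models = default_channel_models(marker_offsets=offsets)
        for c in range(config.cores_per_patient):
            core_id = f"{pid}_c{c}"
            spec = PhantomSpec(
                core_diameter_um=config.core_diameter_um,
                pixel_size_um=config.pixel_size_um,
                channel_models=models, noise_sd=config.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                zone_config=config.zone_config)
            spec = random_core_geometry(spec, rng)
            image, truth = generate_core_phantom(spec,
                                                 with_zone_truth=False)
            image.core_id = core_id
            image.patient_id = pid
            r1, r2 = _split_rounds(image)
            s = config.round2_max_shift_px
            dy, dx = (int(rng.integers(-s, s + 1)),
                      int(rng.integers(-s, s + 1))) if s else (0, 0)
            r2 = _apply_shift(r2, dy, dx)
            cores[core_id] = (r1, r2, truth, (dy, dx))
    return cohort, cores


def _train_classifier(config: RunConfig, n_phantoms: int = 4):
    """Fit the pixel classifier on a pool of training phantoms whose labels
    come from ground truth (the scribble-free simulation analogue).

    The phantoms span the same per-patient marker-offset distribution as the
    simulated cohort, so the forest learns to key on the stable channels
    (counterstain, tumor markers) rather than on any one fibroblast level.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "train"))
    feats_all, labels_all = [], []
    channel_names = None
    for _ in range(n_phantoms):
        offsets = {m: {"tumor": float(rng.uniform(0.05, 0.45)),
                       "stroma": float(rng.uniform(0.05, 0.45))}
                   for m in FIBROBLAST_MARKERS}
        spec = PhantomSpec(
            core_diameter_um=config.core_diameter_um,
            pixel_size_um=config.pixel_size_um,
            channel_models=default_channel_models(marker_offsets=offsets),
            noise_sd=config.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            zone_config=config.zone_config)
        spec = random_core_geometry(spec, rng)
        image, truth = generate_core_phantom(spec)
        channel_names = image.channel_names
        f, l = sample_training_pixels(
            image, truth.masks,
            n_per_class=config.train_pixels_per_class, rng=rng)
        feats_all.append(f)
        labels_all.append(l)
    return train_pixel_classifier(
        np.concatenate(feats_all), np.concatenate(labels_all),
        channel_names=channel_names,
        seed=stage_seed(config.seed, "forest"),
        n_estimators=config.classifier_trees)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write the run directory.  See module docs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(handler)
    t0 = time.time()
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()
        log.info("run finished in %.1f s", time.time() - t0)


def _run(config: RunConfig, out: Path) -> Path:
    markers = FIBROBLAST_MARKERS  # screened variables: 7 markers x 10 comps
    cohort, cores = simulate_cores(config)
    cohort.to_csv(out / "cohort.csv", index=False)
    if config.write_images:
        imgs, truths = [], []
        for r1, r2, truth, _ in cores.values():
            full = MultiplexImage(
                channels={**r1.channels, **r2.channels},
                pixel_size_um=r1.pixel_size_um, core_id=r1.core_id,
                patient_id=r1.patient_id,
                round_ids={**r1.round_ids, **r2.round_ids})
            imgs.append(full)
            truths.append(truth)
        write_fixture_bundle(out / "bundle", imgs, truths, cohort)

    classifier = _train_classifier(config)

    qc_rows, measurements, positivity = [], [], {}
    for core_id, (r1, r2, truth, true_shift) in cores.items():
        try:
            try:
                shift, fused = register_rounds(
                    r1, r2, reference_channel=config.reference_channel,
                    max_shift_um=config.max_shift_um)
                reg_ok = True
            except RegistrationError as exc:
                log.warning("registration failed for %s: %s", core_id, exc)
                shift, fused, reg_ok = (0, 0), None, False

            if not reg_ok:
                qc_rows.append(qc_core(
                    r1, np.zeros(r1.shape, bool),
                    config.min_tissue_fraction,
                    config.core_diameter_um, registration_ok=False))
                continue

            masks = classify_pixels(fused, classifier)
            report = qc_core(fused, masks.tissue,
                             config.min_tissue_fraction,
                             config.core_diameter_um,
                             registration_ok=True, shift_px=shift)
            qc_rows.append(report)
            if not report.passed:
                continue

            comp = segment_components(
                fused, masks, tumor_channels=TUMOR_MARKERS,
                tumor_threshold=config.tumor_threshold)
            meso_zones = compute_zones(comp.tumor, comp.stroma,
                                       config.zone_config,
                                       fused.pixel_size_um)
            vessel_zones = compute_zones(comp.vessel, comp.stroma,
                                         config.zone_config,
                                         fused.pixel_size_um)
            measurements.append(measure_core(fused, comp, meso_zones,
                                             vessel_zones, markers))
            pos = classify_tumor_positivity(
                fused, comp, config.effect_marker,
                positivity_threshold=config.positivity_threshold,
                confidence_threshold=config.confidence_threshold)
            positivity.setdefault(fused.patient_id, []).append(pos)
        except Exception as exc:
            raise PipelineError(
                f"stage failure at core {core_id}: {exc}") from exc

    pd.DataFrame([{
        "core_id": r.core_id, "tissue_fraction": r.tissue_fraction,
        "shift_y_um": r.registration_shift_um[0],
        "shift_x_um": r.registration_shift_um[1],
        "passed": r.passed, "reasons": ";".join(r.reasons),
    } for r in qc_rows]).to_csv(out / "qc.csv", index=False)

    if not measurements:
        raise PipelineError("stage failure at quantify: no core passed QC")
    table = build_patient_table(pd.concat(measurements, ignore_index=True))
    table.to_csv(out / "patient_table.csv")
    scaled = scale_for_cox(table)
    scaled.to_csv(out / "patient_table_scaled.csv")

    pd.DataFrame([vars(pool_positivity(v, pid))
                  for pid, v in positivity.items()]) \
        .to_csv(out / "positivity.csv", index=False)

    # keep the clinical columns only; marker_raw is simulation truth
    cohort_cols = cohort.drop(columns=["marker_raw"], errors="ignore")
    report = _survive(config, scaled, cohort_cols)
    report.to_csv(out / "screen.csv", index=False)

    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config),
                                        default=list)),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": config.version,
        "n_cores_simulated": len(cores),
        "n_cores_passed": int(sum(r.passed for r in qc_rows)),
        "bonferroni_m": int(report.attrs.get("bonferroni_m", 0)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out


def _survive(config: RunConfig, scaled: pd.DataFrame,
             cohort: pd.DataFrame) -> pd.DataFrame:
    from .survival import run_screen
    effect_var = f"{config.effect_marker}_{config.effect_compartment}"
    covariate_sets = {}
    if effect_var in scaled.columns:
        covariate_sets["adjusted_effect"] = [effect_var]
    return run_screen(scaled, cohort, m=config.bonferroni_m,
                      covariate_sets=covariate_sets,
                      adjusters=tuple(config.adjusters),
                      compute_ph=config.compute_ph)
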