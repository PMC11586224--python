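"""Self-validation suites: every pipeline stage checked against analytic
closed forms or generator ground truth.

Each function recomputes its quantities from scratch — simulating inputs,
running the analysis, and measuring the outcome — and returns a flat dict
of numbers.  The test suite asserts tolerances on these numbers; the
acceptance script reports them.  All randomness derives from the ``seed``
argument.

Problem sizes are desk-scale: single spheroids of ~80–160 µm diameter
with 300–600 nuclei, panels of 20–30 spheroids.
"""

from __future__ import annotations

import warnings
from typing import Dict, List

import numpy as np

from .actin import actin_ratio, ring_decompose, scale_mask
from .morphometry import (measure, measure_volume_surface, principal_axes,
                          sphericity)
from .nuclei import (NucleusSet, call_positive, detect_nuclei,
                     polarisation_index, quantify_coexpression,
                     quantify_marker, sample_intensities)
from .pipeline import RunConfig, run_pipeline
from .segmentation import SegmentationParams, segment_spheroid
from .synthetic import MarkerModel, SyntheticSpec, simulate

__all__ = [
    "sphericity_suite",
    "segmentation_suite",
    "ring_suite",
    "marker_suite",
    "classification_suite",
    "determinism_suite",
]


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())


def _digital_ellipsoid(semi_axes_vox, spacing=(1.0, 1.0, 1.0), margin=3):
    semi = np.asarray(semi_axes_vox, dtype=float)
    shape = (2 * np.ceil(semi).astype(int) + 2 * margin + 1)
    c = (shape - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    m = (((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2
         + ((xx - c[2]) / semi[2]) ** 2) <= 1.0
    return m


def _prolate_psi(a: float, b: float) -> float:
    """Closed-form Wadell sphericity of a prolate spheroid (a > b = c)."""
    e = np.sqrt(1.0 - (b / a) ** 2)
    area = 2.0 * np.pi * b**2 * (1.0 + (a / (b * e)) * np.arcsin(e))
    vol = 4.0 / 3.0 * np.pi * a * b * b
    return sphericity(vol, area)


def sphericity_suite(seed: int = 0) -> Dict[str, float]:
    """Sphericity against analytic closed forms.

    Checks ψ = 1 for the analytic sphere, the cube and 3:1:1 prolate
    closed-form values of the Wadell formula, the voxel estimator against
    the analytic prolate family 1:1:1 → 2:1:1 → 3:1:1 → 5:1:1 (monotone
    decrease), and invariance under rigid 90° rotation and translation.
    """
    out: Dict[str, float] = {}
    # analytic sphere: definitional identity, any radius
    r = 17.3
    out["sphere_psi_analytic"] = sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2)

    # cube closed form: psi = pi^(1/3) (6 s^3)^(2/3) / (6 s^2), any side
    s = 30.0
    out["cube_psi"] = sphericity(s**3, 6 * s**2)
    out["cube_psi_expected"] = 0.806

    # prolate 3:1:1 closed form: analytic prolate surface area
    out["prolate311_psi"] = _prolate_psi(3.0, 1.0)
    out["prolate311_psi_expected"] = 0.846

    # monotone decrease across axis ratios, each within 3% of closed form
    psis: List[float] = []
    for ratio in (1, 2, 3, 5):
        m = _digital_ellipsoid((20, 20, 20 * ratio))
        v, a = measure_volume_surface(m, (1, 1, 1))
        psi = sphericity(v, a)
        expected = 1.0 if ratio == 1 else _prolate_psi(20.0 * ratio, 20.0)
        psis.append(psi)
        out[f"prolate_{ratio}11_psi"] = psi
        out[f"prolate_{ratio}11_rel_err"] = abs(psi - expected) / expected
    out["monotone_decreasing"] = float(all(
        psis[i] > psis[i + 1] for i in range(len(psis) - 1)))

    # rotation / translation invariance on an asymmetric shape
    m = _digital_ellipsoid((18, 24, 40))
    v, a = measure_volume_surface(m, (1, 1, 1))
    psi0 = sphericity(v, a)
    rot = np.rot90(m, k=1, axes=(1, 2))
    v, a = measure_volume_surface(rot, (1, 1, 1))
    psi_rot = sphericity(v, a)
    shifted = np.roll(m, shift=(1, 2, 3), axis=(0, 1, 2))
    v, a = measure_volume_surface(shifted, (1, 1, 1))
    psi_shift = sphericity(v, a)
    out["rotation_rel_dev"] = abs(psi_rot - psi0) / psi0
    out["translation_rel_dev"] = abs(psi_shift - psi0) / psi0
    return out


def segmentation_suite(seed: int = 0) -> Dict[str, float]:
    """Mask quality against generator ground truth.

    3D Dice on a noiseless stack, 2D Dice at default noise, and the
    minimum-object-size filter behaviour (5,000 px object removed,
    22,500 px object kept at the 10,000 px floor).
    """
    from .segmentation import hkmeans_threshold

    out: Dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = SyntheticSpec(shape_family="sphere", radius_um=50,
                              rng_seed=seed,
                              noise_poisson_scale=0.0, noise_gaussian_sd=0.0)
        stack, truth = simulate(clean)
        mask3d = segment_spheroid(stack, "dapi", SegmentationParams(mode="3d"))
        out["dice_3d_noiseless"] = _dice(mask3d.data, truth.occupancy)

        noisy = SyntheticSpec(shape_family="sphere", radius_um=50,
                              rng_seed=seed + 1)
        stack, truth = simulate(noisy)
        mask2d = segment_spheroid(stack, "dapi", SegmentationParams(mode="2d"))
        out["dice_2d_default_noise"] = _dice(mask2d.data,
                                             truth.occupancy.any(axis=0))

    # size filter: a 150x150 object (22,500 px) survives the 10,000 px
    # floor, a ~5,000 px object does not
    img = np.full((300, 300), 10.0)
    img[10:160, 10:160] = 200.0
    big_mask, info = hkmeans_threshold(img, 2, 10_000)
    out["kept_22500px_object"] = float(big_mask.sum() == 150 * 150)
    out["threshold_between_classes"] = float(10.0 < info["threshold"] < 200.0)
    img2 = np.full((300, 300), 10.0)
    img2[10:81, 10:81] = 200.0  # 71*71 = 5041 px
    small_mask, _ = hkmeans_threshold(img2, 2, 10_000)
    out["removed_5000px_object"] = float(small_mask.sum() == 0)
    return out


def ring_suite(seed: int = 0, n_per_mode: int = 10) -> Dict[str, float]:
    """Ring decomposition: partition exactness, disk area fraction,
    uniform-intensity ratio, and cortical/central direction recovery."""
    out: Dict[str, float] = {}
    # disk at scale 0.75: inner/whole = 0.75^2 for a convex region
    yy, xx = np.mgrid[:256, :256]
    disk = (yy - 128) ** 2 + (xx - 128) ** 2 <= 100**2
    dec = ring_decompose(disk, 0.75)
    out["disk_inner_area_fraction"] = dec.area_inner / dec.area_whole
    out["partition_exact"] = float(
        dec.area_inner + dec.area_outer == dec.area_whole
        and not (dec.inner_mask & dec.outer_mask).any()
        and ((dec.inner_mask | dec.outer_mask) == dec.whole_mask).all())

    # uniform intensity inside the mask -> identical means -> ratio 1
    img = np.where(disk, 37.5, 0.0)
    dec.mean_inner = float(img[dec.inner_mask].mean())
    dec.mean_outer = float(img[dec.outer_mask].mean())
    out["uniform_intensity_ratio"] = dec.ratio_periphery_to_centre

    # direction recovery on generated spheroids at default noise
    correct = 0
    ratios = {"cortical": [], "central": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mode in ("cortical", "central"):
            for k in range(n_per_mode):
                spec = SyntheticSpec(shape_family="sphere", radius_um=50,
                                     actin_mode=mode,
                                     rng_seed=seed + 100 + k)
                stack, _ = simulate(spec)
                ratio = actin_ratio(stack).ratio_periphery_to_centre
                ratios[mode].append(ratio)
                if (ratio > 1) == (mode == "cortical"):
                    correct += 1
    out["direction_correct"] = float(correct)
    out["direction_total"] = float(2 * n_per_mode)
    out["cortical_ratio_mean"] = float(np.mean(ratios["cortical"]))
    out["central_ratio_mean"] = float(np.mean(ratios["central"]))
    return out


def _nucleus_means(spec: SyntheticSpec, channel: str):
    """Detection + intensity sampling on one simulated spheroid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate(spec)
        mask3d = segment_spheroid(stack, "dapi", SegmentationParams(mode="3d"))
        nuclei = detect_nuclei(stack, mask3d.data)
        means = sample_intensities(nuclei, stack, channel)
    return nuclei, means, truth


def marker_suite(seed: int = 0) -> Dict[str, float]:
    """Percent-positive recovery, coexpression and polarisation.

    Recovery runs the full chain (simulate → segment → detect → sample →
    call → quantify) over 20 spheroids spanning true fractions
    {0, 25, 50, 75, 100}% at n = 500 nuclei and default noise.  Positive
    calls use a manual intensity threshold calibrated once from two
    control spheroids (all-negative and all-positive), the way expression
    thresholds are set from control stainings in practice — no
    distribution-based threshold can distinguish an all-negative from an
    all-positive population, since the two differ only by a scale factor.
    """
    out: Dict[str, float] = {}

    def spec_for(p: float, rng_seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            shape_family="sphere", radius_um=50, n_nuclei=500,
            rng_seed=rng_seed,
            marker_models=(MarkerModel(name="oct4", polarisation="uniform",
                                       p_positive_inside=p),))

    # threshold calibration on control spheroids
    _, neg_means, _ = _nucleus_means(spec_for(0.0, seed + 900), "oct4")
    _, pos_means, _ = _nucleus_means(spec_for(1.0, seed + 901), "oct4")
    threshold = (np.median(neg_means) + np.median(pos_means)) / 2.0
    out["calibrated_threshold"] = float(threshold)

    errors = []
    k = 0
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        recovered = []
        for rep in range(4):
            nuclei, means, truth = _nucleus_means(
                spec_for(frac, seed + 10 * k), "oct4")
            flags, _ = call_positive(means, "manual", threshold)
            nuclei.flags["oct4"] = flags
            q = quantify_marker(nuclei, "oct4")
            true_pct = truth.true_positive_fraction["oct4"]
            errors.append(abs(q.percent_positive - true_pct))
            recovered.append(q.percent_positive)
            k += 1
        out[f"recovered_pct_at_{int(100 * frac)}"] = float(np.mean(recovered))
    out["recovery_mae_points"] = float(np.mean(errors))

    # independent coexpression: labels only, binomial expectation 20%
    rng = np.random.default_rng(seed + 2000)
    n = 10_000
    flags_a = rng.uniform(size=n) < 0.5
    flags_b = rng.uniform(size=n) < 0.4
    nucset = NucleusSet(centroids_um=np.zeros((n, 3)), scores=np.zeros(n),
                        flags={"a": flags_a, "b": flags_b})
    out["coexpression_pct"] = quantify_coexpression(nucset, "a", "b").percent_positive
    out["coexpression_n"] = float(n)

    # distal-cap polarisation with p_out = 0: index exactly 1 by construction
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = SyntheticSpec(
            shape_family="ellipsoid", semi_axes_um=(35, 35, 80),
            rng_seed=seed + 3000,
            marker_models=(MarkerModel(name="sox17", polarisation="distal_cap",
                                       cap_fraction=0.25, p_positive_inside=1.0,
                                       p_positive_outside=0.0),))
        _, truth = simulate(spec)
    gt_nuclei = NucleusSet(centroids_um=truth.nucleus_centroids_um,
                           scores=np.zeros(len(truth.nucleus_centroids_um)),
                           flags={"sox17": truth.marker_labels["sox17"]})
    out["distal_cap_polarisation_index"] = polarisation_index(
        gt_nuclei, "sox17", axis=(0.0, 0.0, 1.0))
    return out


def classification_suite(seed: int = 0, n_per_class: int = 10) -> Dict[str, float]:
    """Shape-class recovery on a generated panel at default noise.

    Simulates ``n_per_class`` spheroids per family with jittered geometry,
    segments in 3D and classifies with the default thresholds (ψ < 0.7,
    elongation ≥ 2); reports the number matching ground truth.
    """
    rng = np.random.default_rng(seed)
    specs: List[SyntheticSpec] = []
    for k in range(n_per_class):
        specs.append(SyntheticSpec(
            shape_family="sphere",
            radius_um=float(rng.uniform(40, 55)),
            rng_seed=seed + 10_000 + k))
    for k in range(n_per_class):
        main = float(rng.uniform(42, 48))
        specs.append(SyntheticSpec(
            shape_family="budded", main_radius_um=main,
            bud_radius_um=float(rng.uniform(0.40, 0.46) * main),
            bud_offset_um=main,
            rng_seed=seed + 20_000 + k))
    for k in range(n_per_class):
        short = float(rng.uniform(30, 36))
        specs.append(SyntheticSpec(
            shape_family="ellipsoid",
            semi_axes_um=(short, short, float(rng.uniform(2.1, 2.5) * short)),
            rng_seed=seed + 30_000 + k))
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in specs:
            stack, truth = simulate(spec)
            mask = segment_spheroid(stack, "dapi", SegmentationParams(mode="3d"))
            result = measure(mask.data, mask.spacing)
            if result.shape_class == truth.shape_class:
                correct += 1
    return {"classified_correct": float(correct),
            "classified_total": float(len(specs))}


def determinism_suite(seed: int = 0, out_dir=None) -> Dict[str, float]:
    """Byte-identical CSV output from two runs of an identical config."""
    import hashlib
    import tempfile
    from pathlib import Path

    base = Path(out_dir) if out_dir else Path(tempfile.mkdtemp())
    cfg = dict(
        simulate=[dict(shape_family="sphere", radius_um=35, n_nuclei=200),
                  dict(shape_family="ellipsoid", semi_axes_um=[25, 25, 55],
                       n_nuclei=200, actin_mode="central")],
        marker_channels=[], out_dir=str(base / "run"), seed=seed,
        log_level="ERROR")
    digests = []
    for _ in range(2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(RunConfig(**cfg))
        digests.append(hashlib.sha256(
            (base / "run" / "spheroids.csv").read_bytes()).hexdigest())
    return {"csv_byte_identical": float(digests[0] == digests[1])}
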