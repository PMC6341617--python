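"""Ground-truth benchmarks on synthetic scenes.

The study conditions used throughout: 1024 x 1024 px fields at
0.65 µm/pixel (a ×20 high-content objective), 200 nuclei per well, droplet
clusters around the differentiated fraction, gradient + blotch background,
Gaussian camera noise of SD 3, and a binarisation offset of -10 intensity
units (the threshold field is the local mean minus the offset, so a
negative offset raises it by a few noise SDs and keeps near-flat
background out of the foreground).  The gate threshold is fixed at 5.0 lipid-score units, which
sits far above the residual scores of undifferentiated cells (< 1) and
far below droplet-bearing cells (> 10) in this intensity regime.

These helpers back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import PixelGrid, TwoChannelImage
from .droplets import detect_droplets, subtract_background
from .pipeline import AnalysisParams, analyze_field
from .scoring import GateParams, WellResult, aggregate_well, gate_scores, whole_image_intensity
from .synthetic import GroundTruth, SceneSpec, generate_scene, render_oro
from .unmix import unmix_oro_haematoxylin

#: analysis settings used for all synthetic benchmarks
EVAL_PARAMS = AnalysisParams(offset=-10.0)
#: fixed gate on the lipid-score scale for the synthetic intensity regime
EVAL_GATE = 5.0


def make_well_spec(
    fraction: float,
    seed: int,
    n_nuclei: int = 200,
    **overrides,
) -> SceneSpec:
    """One synthetic well at the study conditions."""
    kwargs = dict(
        width_px=1024,
        height_px=1024,
        pixel_pitch_um=0.65,
        n_nuclei=n_nuclei,
        differentiated_fraction=fraction,
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


def score_scene(
    image: TwoChannelImage,
    params: AnalysisParams = EVAL_PARAMS,
    gate: float = EVAL_GATE,
    well_id: str = "well",
) -> WellResult:
    """Run the full image-level pipeline on one field and aggregate it."""
    analysis = analyze_field(image, params)
    gated = gate_scores(analysis.scores, GateParams(gate_threshold=gate))
    return aggregate_well(well_id, [gated], gate_threshold=gate)


def recover_fraction(fraction: float, seed: int) -> tuple[float, GroundTruth]:
    """Generate one well at ``fraction`` and return its adipogenic score."""
    image, truth = generate_scene(make_well_spec(fraction, seed))
    result = score_scene(image)
    assert result.adipogenic_score is not None
    return result.adipogenic_score, truth


def parameter_recovery(
    fractions=(0.0, 0.25, 0.5, 0.75, 1.0), seeds=(1, 2, 3, 4, 5)
) -> dict[float, list[float]]:
    """Recovered adipogenic scores per true differentiated fraction."""
    out: dict[float, list[float]] = {f: [] for f in fractions}
    for fraction in fractions:
        for seed in seeds:
            score, _ = recover_fraction(fraction, seed)
            out[fraction].append(score)
    return out


@dataclass(frozen=True)
class ClumpComparison:
    """Adipogenic-score and bulk-intensity shifts caused by a clump."""

    score_without: float
    score_with: float
    bulk_without: float
    bulk_with: float

    @property
    def score_shift_pp(self) -> float:
        return abs(self.score_with - self.score_without)

    @property
    def bulk_shift_pct(self) -> float:
        return 100.0 * abs(self.bulk_with - self.bulk_without) / self.bulk_without


def clump_robustness(seed: int, fraction: float = 0.25) -> ClumpComparison:
    """Same scene with and without a saturated clump covering ~10% of it.

    The per-nucleus pipeline should barely move (the clump's fused region
    exceeds the size limit and is excluded), while a plate-reader-style
    whole-image intensity readout is inflated by the saturated area.
    """
    spec = make_well_spec(fraction, seed)
    clump_r_um = np.sqrt(0.1 * spec.width_px * spec.height_px / np.pi) * spec.pixel_pitch_um
    clump = ((spec.height_px / 2, spec.width_px / 2), clump_r_um)
    image_plain, _ = generate_scene(spec)
    image_clump, _ = generate_scene(dataclasses.replace(spec, clump=clump))
    res_plain = score_scene(image_plain)
    res_clump = score_scene(image_clump)
    return ClumpComparison(
        score_without=res_plain.adipogenic_score,
        score_with=res_clump.adipogenic_score,
        bulk_without=whole_image_intensity(image_plain.lipid),
        bulk_with=whole_image_intensity(image_clump.lipid),
    )


def dead_cell_leakage(seed: int, n_dead: int = 15) -> dict[str, int]:
    """Count planted dead-cell nuclei that survive the region filters.

    Dead cells are rendered as thin high-eccentricity crescents below the
    minimum-area bound, so none should ever reach ``kept`` status.
    """
    from .binarize import BinarizationParams, binarize
    from .nuclei import (
        STATUS_KEPT,
        RegionFilterParams,
        filter_regions,
        label_components,
        split_touching,
    )

    spec = make_well_spec(0.3, seed, n_nuclei=120, n_dead_cells=n_dead)
    image, truth = generate_scene(spec)
    params = EVAL_PARAMS
    mask = binarize(
        image.nuclei, BinarizationParams(params.nuclei_kernel_um, params.offset)
    )
    regions = filter_regions(
        label_components(split_touching(mask, params.min_seed_distance_um)),
        RegionFilterParams(
            params.min_area_um2, params.max_area_um2, params.max_aspect_ratio
        ),
    )
    kept_pixels = {
        (int(r), int(c))
        for region in regions
        if region.status == STATUS_KEPT
        for r, c in region.pixel_mask
    }
    leaked = sum(
        1
        for cy, cx in truth.dead_cell_centers_px
        if (int(round(cy)), int(round(cx))) in kept_pixels
    )
    return {
        "n_dead": int(len(truth.dead_cell_centers_px)),
        "leaked": leaked,
        "n_kept": sum(1 for r in regions if r.status == STATUS_KEPT),
        "n_live_truth": int(truth.n_live),
    }


def oro_agreement(seed: int, fraction: float = 0.5, overlap: float = 0.2):
    """Adipogenic score via fluorescence vs via rendered ORO unmixing."""
    image, _ = generate_scene(make_well_spec(fraction, seed))
    fluor = score_scene(image).adipogenic_score
    unmixed = unmix_oro_haematoxylin(render_oro(image, overlap=overlap))
    oro = score_scene(unmixed).adipogenic_score
    return fluor, oro


def generate_droplet_field(
    n_droplets: int,
    radius_um: tuple[float, float],
    seed: int,
    width_px: int = 512,
    pixel_pitch_um: float = 0.325,
    intensity: float = 180.0,
    background: float = 40.0,
    noise_sd: float = 8.0,
) -> tuple[PixelGrid, np.ndarray, np.ndarray]:
    """Field of non-overlapping bright discs with known centres and radii.

    SNR (disc contrast over noise SD) is about 17 at the defaults; the
    planted geometry is the oracle for Hough-detection benchmarks.
    """
    rng = np.random.default_rng(seed)
    h = w = width_px
    canvas = np.full((h, w), background, dtype=np.float64)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    radii_px: list[float] = []
    r_max_px = (radius_um[0] + 3 * radius_um[1]) / pixel_pitch_um
    for _ in range(n_droplets):
        r_um = float(np.clip(rng.normal(*radius_um), 0.5, None))
        r_px = r_um / pixel_pitch_um
        for _attempt in range(10_000):
            cy = rng.uniform(r_px + 3, h - r_px - 3)
            cx = rng.uniform(r_px + 3, w - r_px - 3)
            if all(
                np.hypot(cy - py, cx - px) > r_px + pr + 2 * r_max_px
                for (py, px), pr in zip(centers, radii_px)
            ):
                break
        else:
            raise RuntimeError("droplet field too dense")
        r0 = max(0, int(np.floor(cy - r_px - 2)))
        r1 = min(h, int(np.ceil(cy + r_px + 2)) + 1)
        c0 = max(0, int(np.floor(cx - r_px - 2)))
        c1 = min(w, int(np.ceil(cx + r_px + 2)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(yy - cy, xx - cx)
        cov = np.clip(r_px - d + 0.5, 0.0, 1.0)
        np.maximum(
            canvas[r0:r1, c0:c1], background + intensity * cov, out=canvas[r0:r1, c0:c1]
        )
        centers.append((cy, cx))
        radii.append(r_um)
        radii_px.append(r_px)
    canvas += rng.normal(0.0, noise_sd, size=(h, w))
    grid = PixelGrid(
        np.clip(np.rint(canvas), 0, 255).astype(np.uint8), pixel_pitch_um
    )
    return grid, np.array(centers).reshape(-1, 2), np.array(radii)


def droplet_benchmark(
    seed: int,
    n_droplets: int = 20,
    radius_um: tuple[float, float] = (1.3, 0.35),
) -> dict[str, float]:
    """Recall and radius MAE of Hough detection on a planted-disc field."""
    field, centers, radii = generate_droplet_field(n_droplets, radius_um, seed)
    pitch = field.pixel_pitch_um
    bgsub = subtract_background(field, window_um=8 * (radius_um[0] + 3 * radius_um[1]))
    detections = detect_droplets(
        bgsub, r_min_um=2 * pitch, r_max_um=4.0, sensitivity=0.5, edge_percentile=99.5
    )
    matched = np.zeros(len(centers), dtype=bool)
    errors = []
    for det in detections:
        d = np.hypot(centers[:, 0] - det.center[0], centers[:, 1] - det.center[1])
        i = int(np.argmin(d))
        if not matched[i] and d[i] <= max(2.0, radii[i] / pitch):
            matched[i] = True
            errors.append(abs(det.radius_um - radii[i]) / pitch)
    recall = matched.mean() if len(centers) else 0.0
    mae_px = float(np.mean(errors)) if errors else float("nan")
    return {
        "recall": float(recall),
        "radius_mae_px": mae_px,
        "n_detections": float(len(detections)),
    }


def droplet_growth_direction(seed: int) -> tuple[float, float]:
    """Mean detected radius for an early-stage vs late-stage droplet field."""
    means = []
    for radius_um in ((0.9, 0.15), (1.8, 0.3)):
        field, _, _ = generate_droplet_field(20, radius_um, seed)
        bgsub = subtract_background(field, window_um=25.0)
        dets = detect_droplets(
            bgsub,
            r_min_um=2 * field.pixel_pitch_um,
            r_max_um=4.0,
            sensitivity=0.5,
            edge_percentile=99.5,
        )
        means.append(float(np.mean([d.radius_um for d in dets])) if dets else 0.0)
    return means[0], means[1]
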