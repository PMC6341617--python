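"""End-to-end orchestration: manifest -> binarise -> nuclei -> scores -> wells.

Per field: (unmix if bright-field) -> binarise both channels -> drop
saturated-clump-scale components -> watershed-split touching nuclei ->
label -> size/shape filters -> per-nucleus lipid scores.  Per well: pool
fields, gate, aggregate.  Exclusion accounting (too_small / too_large /
misshapen counts per field) is a first-class output, because what is NOT
counted — dead cells and non-specifically stained clumps — is the point
of the filtering stages.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binarize import (
    DEFAULT_LIPID_KERNEL_UM,
    DEFAULT_NUCLEI_KERNEL_UM,
    BinarizationParams,
    binarize,
)
from .core import AnalysisError, BinaryMask, FatsError, ParameterError, TwoChannelImage
from .io import read_field, read_manifest, write_summary_json, write_well_csv
from .nuclei import (
    STATUS_KEPT,
    RegionFilterParams,
    filter_regions,
    label_components,
    split_touching,
)
from .scoring import (
    GateParams,
    LipidScore,
    WellResult,
    aggregate_well,
    compare_to_control,
    derive_gate_threshold,
    gate_scores,
    score_nucleus,
)

log = logging.getLogger("fats")


@dataclass(frozen=True)
class AnalysisParams:
    """Every image-level tunable of the pipeline, in physical units."""

    nuclei_kernel_um: float = DEFAULT_NUCLEI_KERNEL_UM
    lipid_kernel_um: float = DEFAULT_LIPID_KERNEL_UM
    offset: float = 0.0
    min_area_um2: float = 20.0
    max_area_um2: float = 500.0
    max_aspect_ratio: float = 3.0
    #: coarse pre-split bound: components larger than this (saturated
    #: multilayer clumps, far beyond any resolvable fused nucleus group)
    #: are removed before watershed so the splitter cannot shred them
    #: into nucleus-sized fragments
    max_component_area_um2: float = 5000.0
    min_seed_distance_um: float = 6.0
    search_radius_um: float = 3.0
    intensity_mode: str = "mean"
    histogram_bins: int = 50


@dataclass
class FieldAnalysis:
    """Ungated scores plus exclusion counts for one field."""

    scores: list[LipidScore]
    exclusions: dict[str, int]


def analyze_field(image: TwoChannelImage, params: AnalysisParams) -> FieldAnalysis:
    """Run the image-level pipeline on one field; gating happens later."""
    pitch = image.pixel_pitch_um
    nuclei_mask = binarize(
        image.nuclei, BinarizationParams(params.nuclei_kernel_um, params.offset)
    )
    lipid_mask = binarize(
        image.lipid, BinarizationParams(params.lipid_kernel_um, params.offset)
    )
    # clump guard: exclude saturated-clump-scale components before splitting
    raw_regions = label_components(nuclei_mask)
    clump_count = 0
    masked = nuclei_mask.values.copy()
    for region in raw_regions:
        if region.area_um2 > params.max_component_area_um2:
            masked[tuple(region.pixel_mask.T)] = 0
            clump_count += 1
    nuclei_mask = BinaryMask(masked, pitch)
    split = split_touching(nuclei_mask, params.min_seed_distance_um)
    regions = filter_regions(
        label_components(split),
        RegionFilterParams(
            params.min_area_um2, params.max_area_um2, params.max_aspect_ratio
        ),
    )
    gate_params = GateParams(
        gate_threshold=0.0,
        search_radius_um=params.search_radius_um,
        intensity_mode=params.intensity_mode,
    )
    scores = [
        score_nucleus(r, image.lipid, lipid_mask, gate_params)
        for r in regions
        if r.status == STATUS_KEPT
    ]
    exclusions = {"too_small": 0, "too_large": clump_count, "misshapen": 0, "kept": 0}
    for r in regions:
        exclusions[r.status] += 1
    return FieldAnalysis(scores=scores, exclusions=exclusions)


@dataclass
class PipelineConfig:
    """File-level configuration wrapping :class:`AnalysisParams`."""

    manifest: Path
    output_dir: Path
    params: AnalysisParams = field(default_factory=AnalysisParams)
    gate_threshold: float | None = None
    control_wells: tuple[str, ...] = ()
    save_figures: bool = True

    # nested config-file keys -> AnalysisParams / pipeline fields
    _KEYMAP = {
        "binarize.nuclei_kernel_um": "nuclei_kernel_um",
        "binarize.lipid_kernel_um": "lipid_kernel_um",
        "binarize.offset": "offset",
        "nuclei.min_area_um2": "min_area_um2",
        "nuclei.max_area_um2": "max_area_um2",
        "nuclei.max_aspect_ratio": "max_aspect_ratio",
        "nuclei.max_component_area_um2": "max_component_area_um2",
        "nuclei.min_seed_distance_um": "min_seed_distance_um",
        "score.search_radius_um": "search_radius_um",
        "score.intensity_mode": "intensity_mode",
        "score.histogram_bins": "histogram_bins",
    }

    @classmethod
    def from_yaml(
        cls,
        manifest: str | Path,
        output_dir: str | Path,
        config_path: str | Path | None = None,
        overrides: dict[str, str] | None = None,
    ) -> "PipelineConfig":
        """Build a config from an optional YAML file plus key=value overrides."""
        flat: dict[str, object] = {}
        gate = None
        controls: tuple[str, ...] = ()
        if config_path is not None:
            with open(config_path) as fh:
                doc = yaml.safe_load(fh) or {}
            for section, values in doc.items():
                if not isinstance(values, dict):
                    raise ParameterError(f"config section {section!r} must be a mapping")
                for key, val in values.items():
                    flat[f"{section}.{key}"] = val
        for key, val in (overrides or {}).items():
            flat[key] = val
        params_kwargs: dict[str, object] = {}
        for key, val in flat.items():
            if key == "score.gate_threshold":
                gate = float(val) if val is not None else None
            elif key == "score.control_wells":
                controls = tuple(val) if isinstance(val, (list, tuple)) else (str(val),)
            elif key in cls._KEYMAP:
                attr = cls._KEYMAP[key]
                if attr == "intensity_mode":
                    params_kwargs[attr] = str(val)
                elif attr == "histogram_bins":
                    params_kwargs[attr] = int(val)
                else:
                    params_kwargs[attr] = float(val)
            else:
                raise ParameterError(
                    f"unknown config key {key!r}; accepted keys: "
                    f"{sorted(cls._KEYMAP) + ['score.gate_threshold', 'score.control_wells']}"
                )
        return cls(
            manifest=Path(manifest),
            output_dir=Path(output_dir),
            params=AnalysisParams(**params_kwargs),  # type: ignore[arg-type]
            gate_threshold=gate,
            control_wells=controls,
        )


def run_pipeline(config: PipelineConfig) -> list[WellResult]:
    """Analyse a whole plate manifest and write result files.

    One failing field does not abort the plate; its well is flagged
    partial and the error logged with well/field context.
    """
    records = read_manifest(config.manifest)
    if not records:
        raise AnalysisError("manifest contains no fields")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_well: dict[str, list[list[LipidScore]]] = {}
    partial: dict[str, bool] = {}
    exclusions: dict[str, dict[str, int]] = {}
    for record in records:
        per_well.setdefault(record.well_id, [])
        partial.setdefault(record.well_id, False)
        try:
            image = read_field(record)
            analysis = analyze_field(image, config.params)
        except FatsError as exc:
            log.error(
                "field %s/%d failed: %s", record.well_id, record.field_index, exc
            )
            partial[record.well_id] = True
            continue
        per_well[record.well_id].append(analysis.scores)
        exclusions[f"{record.well_id}/{record.field_index}"] = analysis.exclusions
        log.info(
            "field %s/%d: %d nuclei kept, exclusions %s",
            record.well_id,
            record.field_index,
            len(analysis.scores),
            analysis.exclusions,
        )

    gate = config.gate_threshold
    if gate is None:
        if not config.control_wells:
            raise ParameterError(
                "no gate_threshold configured and no control wells to derive "
                "one from; set score.gate_threshold or control wells"
            )
        control_scores = [
            s
            for well in config.control_wells
            for fld in per_well.get(well, [])
            for s in fld
        ]
        gate = derive_gate_threshold(control_scores)
        log.info("gate threshold derived from controls: %.4f", gate)

    gate_params = GateParams(gate_threshold=gate)
    results = [
        aggregate_well(
            well_id,
            [gate_scores(fld, gate_params) for fld in fields],
            histogram_bins=config.params.histogram_bins,
            gate_threshold=gate,
            partial=partial[well_id],
        )
        for well_id, fields in sorted(per_well.items())
    ]

    write_well_csv(
        results, out_dir / "wells.csv", per_nucleus_path=out_dir / "nuclei.csv"
    )
    write_summary_json(results, exclusions, out_dir / "summary.json")
    if config.save_figures:
        from .plotting import save_well_histograms

        save_well_histograms(results, out_dir)
    return results


def run_screen(config: PipelineConfig, control_ids: list[str]):
    """Analyse a plate and rank wells against control wells.

    Returns the hit table (descending delta in percentage points) and
    writes it as ``hits.csv`` in the output directory.
    """
    config = dataclasses.replace(config, control_wells=tuple(control_ids))
    results = run_pipeline(config)
    table = compare_to_control(results, list(control_ids))
    table.to_csv(Path(config.output_dir) / "hits.csv", index=False)
    return table
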