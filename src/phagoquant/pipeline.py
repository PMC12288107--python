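"""Per-section detection and study-level orchestration.

A study is described by a manifest table: one row per eye section with the
image path, an ROI/interface JSON, the cone subtype, the light condition and
the Zeitgeber time, plus an optional manual count that overrides the
automated one (mirroring the manual-quantification fallback of the original
workflow).  ``run_section`` executes
read -> project -> denoise -> mask -> detect -> filter -> density for one
row; ``run_study`` maps it over the manifest and hands the resulting dataset
to the rhythm statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .detection import DetectionParams, density_per_10um, detect_spots
from .imaging import gaussian_denoise, max_project, read_stack
from .segmentation import load_roi_json, make_rpe_mask, measure_rpe_length
from . import stats as rhythm

log = logging.getLogger("phagoquant")

VALID_SUBTYPES = {"UV", "blue", "green", "red"}
VALID_CONDITIONS = {"LD", "DD"}
VALID_ZT = {1, 3, 5, 10, 16, 18, 23}


@dataclass
class RunConfig:
    """Serializable run parameters; a copy is written next to the outputs."""

    params: DetectionParams = field(default_factory=DetectionParams)
    pixel_size_um: float | None = None
    opening_radius_px: int = 6
    out_dir: str = "phagoquant_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "pixel_size_um": self.pixel_size_um,
            "opening_radius_px": self.opening_radius_px,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


@dataclass
class SectionRecord:
    """One eye section's quantification result."""

    section_id: str
    subtype: str
    condition: str
    zt: int
    count: int
    rpe_length_um: float
    density: float
    manual_flag: bool = False


def _validate_row(row: dict) -> None:
    if row.get("subtype") not in VALID_SUBTYPES:
        raise ValueError(f"invalid subtype {row.get('subtype')!r}")
    if row.get("condition") not in VALID_CONDITIONS:
        raise ValueError(f"invalid condition {row.get('condition')!r}")
    if int(row.get("zt", -1)) not in VALID_ZT:
        raise ValueError(f"invalid Zeitgeber time {row.get('zt')!r}")


def run_section(row: dict, config: RunConfig) -> tuple[SectionRecord, pd.DataFrame]:
    """Quantify one section; returns its record and a peaks table."""
    section_id = str(row.get("section_id", Path(str(row["image"])).stem))
    try:
        _validate_row(row)
        image_path = Path(row["image"])
        roi_path = Path(row["roi"])
        for p in (image_path, roi_path):
            if not p.exists():
                raise FileNotFoundError(str(p))
        stack = read_stack(image_path, pixel_size_um=config.pixel_size_um)
        roi, polyline = load_roi_json(roi_path)
        if polyline is None:
            raise ValueError("ROI file has no interface polyline; RPE length unknown")
        polyline.pixel_size_um = stack.pixel_size_um

        opsin = gaussian_denoise(
            max_project(stack, "photoreceptor"), sigma=config.params.sigma
        )
        rpe_img = gaussian_denoise(max_project(stack, "rpe"), sigma=config.params.sigma)
        mask = make_rpe_mask(rpe_img, roi, opening_radius_px=config.opening_radius_px)
        peaks = detect_spots(opsin, config.params, mask)
        length_um = measure_rpe_length(polyline)

        manual = row.get("manual_count")
        manual_flag = manual is not None and not pd.isna(manual)
        count = int(manual) if manual_flag else len(peaks)
        density = density_per_10um(count, length_um)

        peaks_df = pd.DataFrame(
            [
                {
                    "row": p.position[0],
                    "col": p.position[1],
                    "dome_height": p.dome_height,
                    "inside_rpe": p.inside_rpe,
                }
                for p in peaks
            ],
            columns=["row", "col", "dome_height", "inside_rpe"],
        )
        record = SectionRecord(
            section_id=section_id,
            subtype=row["subtype"],
            condition=row["condition"],
            zt=int(row["zt"]),
            count=count,
            rpe_length_um=length_um,
            density=density.density,
            manual_flag=manual_flag,
        )
        return record, peaks_df
    except Exception as exc:
        raise RuntimeError(f"section {section_id!r}: {exc}") from exc


def run_study(manifest: pd.DataFrame, config: RunConfig) -> dict:
    """Process every manifest row, then run the rhythm statistics.

    Partial failures are collected under ``errors`` in the returned report
    rather than aborting the study.  Outputs (dataset CSV, per-section peak
    CSVs, stats JSON, config copy) are written under ``config.out_dir``.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    out_dir = Path(config.out_dir)
    (out_dir / "peaks").mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    records: list[SectionRecord] = []
    errors: list[str] = []
    for row in manifest.to_dict("records"):
        try:
            record, peaks = run_section(row, config)
        except RuntimeError as exc:
            log.error("%s", exc)
            errors.append(str(exc))
            continue
        records.append(record)
        peaks.to_csv(out_dir / "peaks" / f"{record.section_id}.csv", index=False)
        log.info(
            "section %s: %d peaks over %.1f um (h=%g prominence=%g)",
            record.section_id, record.count, record.rpe_length_um,
            config.params.h, config.params.prominence,
        )

    dataset = pd.DataFrame([asdict(r) for r in records])
    dataset.to_csv(out_dir / "dataset.csv", index=False)

    report: dict = {"n_sections": len(records), "errors": errors, "stats": {}}
    if len(records) > 0:
        report["stats"] = study_stats(dataset)
        (out_dir / "stats.json").write_text(
            json.dumps(report["stats"], indent=2, default=_jsonify)
        )
    return report


def study_stats(dataset: pd.DataFrame) -> dict:
    """Per-subtype one-way ANOVA suites plus the LD x DD two-way table."""
    out: dict = {}
    for condition in sorted(dataset["condition"].unique()):
        for subtype in sorted(dataset["subtype"].unique()):
            sel = dataset[
                (dataset["condition"] == condition) & (dataset["subtype"] == subtype)
            ]
            groups = rhythm.group_densities(dataset, subtype, condition)
            if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
                continue
            out[f"{subtype}_{condition}"] = rhythm.subtype_report(
                sel, subtype, condition
            )
    if dataset["condition"].nunique() == 2:
        for subtype in sorted(dataset["subtype"].unique()):
            sel = dataset[dataset["subtype"] == subtype]
            try:
                out[f"{subtype}_LDxDD"] = rhythm.two_way_anova(sel)
            except ValueError as exc:
                out[f"{subtype}_LDxDD"] = {"error": str(exc)}
    return out


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
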