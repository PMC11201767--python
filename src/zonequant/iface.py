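"""File formats, configuration, pipeline composition and reporting.

Detection tables use the QuPath export dialect (comma-separated, µm units)
so real exports drop in unchanged; zone polygons travel as GeoJSON, images
as multi-channel TIFF with pixel-size metadata, configuration as YAML, and
analysis results as a single JSON report plus tidy CSV tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import lamstats, nucdetect, synthcortex, zonegeom
from .lamstats import BinnedProfile, CouplingResult, FitResult, ModelComparison
from .nucdetect import DetectionParams
from .synthcortex import CultureConfig, GeneratorConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "MissingColumnError",
    "MalformedValueError",
    "StageError",
    "read_detections",
    "write_detections",
    "write_report",
    "run_pipeline",
    "write_image",
    "read_image",
]


class MissingColumnError(ValueError):
    pass


class MalformedValueError(ValueError):
    pass


class StageError(RuntimeError):
    pass


# ----------------------------------------------------------------------------
# Detection tables (QuPath dialect)
# ----------------------------------------------------------------------------

_FIXED_COLUMNS = {
    "Image": "image",
    "Centroid X µm": "x",
    "Centroid Y µm": "y",
    "Nucleus: Area µm^2": "nuclear_area",
    "Class": "cell_class",
}
_MANDATORY = ["Image", "Centroid X µm", "Centroid Y µm", "Nucleus: Area µm^2"]


def write_detections(cells: pd.DataFrame, path, image: str = "synthetic") -> None:
    """Write a cell table in the QuPath comma-separated dialect."""
    out = pd.DataFrame()
    out["Image"] = cells["image"] if "image" in cells else image
    out["Centroid X µm"] = cells["x"]
    out["Centroid Y µm"] = cells["y"]
    out["Nucleus: Area µm^2"] = cells["nuclear_area"]
    for col in cells.columns:
        if col.startswith("nuclear_mean_"):
            out[f"Nucleus: {col.removeprefix('nuclear_mean_')} mean"] = cells[col]
        elif col.startswith("annulus_mean_"):
            out[f"Cytoplasm: {col.removeprefix('annulus_mean_')} mean"] = cells[col]
    out["Class"] = cells["cell_class"] if "cell_class" in cells else ""
    out.to_csv(path, index=False)


def read_detections(path, dialect: str = "qupath") -> pd.DataFrame:
    """Read a QuPath-dialect detection table into the internal cell schema.

    Mandatory columns are the image name, centroid X/Y in µm, and the
    nuclear area; per-compartment channel means map to
    ``nuclear_mean_<ch>`` / ``annulus_mean_<ch>``. Unknown extra columns are
    retained untouched.
    """
    if dialect != "qupath":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, dtype=str)
    for col in _MANDATORY:
        if col not in raw.columns:
            raise MissingColumnError(f"detection table is missing mandatory column {col!r}")
    out = pd.DataFrame()
    numeric = {"Centroid X µm", "Centroid Y µm", "Nucleus: Area µm^2"}
    for col in raw.columns:
        if col in _FIXED_COLUMNS:
            name = _FIXED_COLUMNS[col]
        elif col.startswith("Nucleus: ") and col.endswith(" mean"):
            name = "nuclear_mean_" + col.removeprefix("Nucleus: ").removesuffix(" mean")
            numeric.add(col)
        elif col.startswith("Cytoplasm: ") and col.endswith(" mean"):
            name = "annulus_mean_" + col.removeprefix("Cytoplasm: ").removesuffix(" mean")
            numeric.add(col)
        else:
            name = col
        series = raw[col]
        if col in numeric:
            vals = pd.to_numeric(series, errors="coerce")
            bad = vals.isna() & series.notna() & (series.str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
                raise MalformedValueError(
                    f"malformed numeric value {series[bad].iloc[0]!r} in column {col!r}, line {row}"
                )
            series = vals
        out[name] = series
    return out


# ----------------------------------------------------------------------------
# Images
# ----------------------------------------------------------------------------


def write_image(path, image: np.ndarray, meta: dict) -> None:
    """Multi-channel TIFF with pixel-size metadata (µm/px)."""
    px = meta["pixel_size"]
    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        metadata={
            "axes": "CYX",
            "channels": meta.get("channels"),
            "origin": list(meta.get("origin", (0.0, 0.0))),
            "PixelSizeUm": px,
        },
        resolution=(1.0 / px, 1.0 / px),
    )


def read_image(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        img = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    return img, meta


# ----------------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    uc: GeneratorConfig = field(default_factory=lambda: GeneratorConfig.for_condition("UC"))
    ad: GeneratorConfig = field(default_factory=lambda: GeneratorConfig.for_condition("AD"))
    culture: CultureConfig = field(default_factory=CultureConfig)
    detection: DetectionParams = field(default_factory=lambda: DetectionParams(pixel_size=0.5))
    geometry_width: float = 1000.0
    geometry_depth: float = 2400.0
    curvature_amplitude: float = 0.0
    pixel_size: float = 0.5
    n_columns: int = 4
    truth_bypass: bool = True
    coupling_per_case_n: int = 100
    bin_size: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "uc" in d:
            d["uc"] = _generator_from_dict(d["uc"])
        if "ad" in d:
            d["ad"] = _generator_from_dict(d["ad"])
        if "culture" in d:
            d["culture"] = CultureConfig(**d["culture"])
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("profile_coeffs", "intensity_params", "cytoplasm_params"):
        if key in d:
            d[key] = tuple(d[key])
    if "size_params" in d:
        d["size_params"] = tuple(tuple(c) for c in d["size_params"])
    return GeneratorConfig(**d)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list
    started: float
    finished: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ----------------------------------------------------------------------------
# Reporting
# ----------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (FitResult, ModelComparison, CouplingResult)):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, BinnedProfile):
        return {
            "bins": _jsonable(obj.bins),
            "fit": _jsonable(obj.fit),
            "bin_size": obj.bin_size,
            "n_dropped": obj.n_dropped,
        }
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: dict, outdir) -> Path:
    """Write the JSON summary (plus tidy CSVs for tabular entries).

    Every number in the report is traceable to a pipeline stage and seed via
    the run manifest written next to it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=False)
    path = outdir / "report.json"
    payload = {"schema": "zonequant-report", "version": __version__, "results": _jsonable(results)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ----------------------------------------------------------------------------
# End-to-end pipeline
# ----------------------------------------------------------------------------


def _measure_condition(
    cells: pd.DataFrame,
    geometry: synthcortex.TissueGeometry,
    detection: DetectionParams,
    seed: int,
) -> pd.DataFrame:
    """Render each case, detect nuclei, measure compartments, classify.

    Returns a measured table in the truth schema (x/y in tissue µm,
    i53bp1/p16 columns from measured nuclear means, damage_positive from the
    valley-threshold classification).
    """
    frames = []
    for i, (case, grp) in enumerate(cells.groupby("case_id", sort=True)):
        img, meta = synthcortex.render_image(grp, geometry, seed=seed + i)
        channels = dict(zip(meta["channels"], img))
        labels = nucdetect.detect_nuclei(channels["DAPI"], detection)
        annuli = nucdetect.expand_pseudoplasm(
            labels, detection.expansion_distance, detection.pixel_size
        )
        measured = nucdetect.measure_cells(
            labels, annuli, {c: channels[c] for c in ("53BP1", "p16")}, detection.pixel_size
        )
        measured["y"] = measured["y"] + geometry.y_origin
        thr = detection.positivity_thresholds.get("53BP1")
        if thr is None:
            thr = nucdetect.histogram_valley_threshold(measured["nuclear_mean_53BP1"])
        measured = nucdetect.classify_positive(measured, "53BP1", thr)
        measured = measured.rename(
            columns={
                "nuclear_mean_53BP1": "i53bp1",
                "nuclear_mean_p16": "p16_nuclear",
                "annulus_mean_p16": "p16_cytoplasmic",
                "positive_53BP1": "damage_positive",
            }
        )
        measured["case_id"] = case
        measured["condition"] = grp["condition"].iloc[0]
        frames.append(measured)
    out = pd.concat(frames, ignore_index=True)
    out["cell_id"] = np.arange(len(out))
    return out


def analyze_cohorts(
    table: pd.DataFrame,
    zone_areas_mm2,
    culture: pd.DataFrame,
    coupling_per_case_n: int = 100,
    bin_size: int = 100,
    seed: int = 0,
) -> dict:
    """All study statistics from a pooled UC+AD cell table with zone labels."""
    results: dict = {}
    summary = lamstats.zone_summary(table, zone_areas_mm2)
    results["zone_summary"] = summary
    case = (
        summary.groupby(["case_id", "condition"])
        .apply(
            lambda g: pd.Series(
                {
                    "fraction": g["n_positive"].sum() / g["n_total"].sum(),
                    "total_density": g["n_total"].sum() / g["area_mm2"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    ad = case[case["condition"] == "AD"]
    uc = case[case["condition"] == "UC"]
    results["fig4F"] = dict(
        zip(("t", "p"), lamstats.unpaired_t(ad["total_density"], uc["total_density"]))
    )
    results["fig4G"] = {
        "ad_mean_fraction": float(ad["fraction"].mean()),
        "uc_mean_fraction": float(uc["fraction"].mean()),
        **dict(zip(("t", "p"), lamstats.unpaired_t(ad["fraction"], uc["fraction"]))),
    }
    results["fig5A_fit_linear"] = {}
    results["fig5A_fit_quadratic"] = {}
    results["fig5A_model_comparison"] = {}
    for cond, grp in summary.dropna(subset=["fraction"]).groupby("condition"):
        lin = lamstats.fit_linear(grp["zone"], grp["fraction"])
        quad = lamstats.fit_quadratic(grp["zone"], grp["fraction"])
        results["fig5A_fit_linear"][cond] = lin
        results["fig5A_fit_quadratic"][cond] = quad
        results["fig5A_model_comparison"][cond] = lamstats.compare_models(lin, quad)
    results["fig5D"] = {}
    for cond, grp in table.groupby("condition"):
        zone4 = grp[grp["zone"] == 4]
        pool = zone4 if len(zone4) >= 3 * bin_size else grp
        results["fig5D"][cond] = lamstats.size_ranked_profile(
            pool, intensity_col="i53bp1", bin_size=bin_size
        )
    for key, subset, compartment in (
        ("fig6B", "positive", "nuclear"),
        ("fig6C", "positive", "annulus"),
        ("fig6D", "negative", "nuclear"),
    ):
        results[key] = {}
        for cond, grp in table.groupby("condition"):
            means, fit = lamstats.subset_intensity_profiles(
                grp, subset=subset, compartment=compartment
            )
            results[key][cond] = {"means": means, "fit": fit}
    pos_means = (
        table[table["damage_positive"].astype(bool)]
        .groupby(["case_id", "condition", "zone"])["p16_nuclear"]
        .mean()
        .rename("mean_p16")
        .reset_index()
    )
    pos_means = pos_means[pos_means["zone"] > 0]
    results["fig6B_anova"] = lamstats.two_way_anova(pos_means, "mean_p16")
    results["fig6E"] = {
        cond: lamstats.coupling_regression(grp, per_case_n=coupling_per_case_n, seed=seed)
        for cond, grp in table.groupby("condition")
    }
    culture_res = lamstats.culture_fractions(culture)
    results["fig7B"] = culture_res["summary"]
    results["fig7B_pairwise"] = culture_res["pairwise_gh2ax"]
    results["fig7DE"] = culture_res["p27_on_gh2ax"]
    return results


def run_pipeline(config: PipelineConfig, output_dir) -> RunManifest:
    """simulate -> (render -> detect -> measure) or truth bypass -> zonate ->
    quantify -> analyze -> report, persisting intermediate artifacts.

    With ``truth_bypass`` the statistics run directly on the generator's
    ground-truth tables (no imaging), which is exact and fast; otherwise each
    case is rendered and re-detected. Fully deterministic for a fixed config.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stages = []
    stage = "simulate"
    try:
        root = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]
        geometry = synthcortex.make_geometry(
            config.geometry_width,
            config.geometry_depth,
            config.curvature_amplitude,
            config.pixel_size,
        )
        tables = []
        for gen_cfg, seed in ((config.uc, seeds[0]), (config.ad, seeds[1])):
            cells = synthcortex.sample_cells(geometry, gen_cfg, seed=seed)
            cells = synthcortex.assign_intensities(cells, gen_cfg, seed=seed + 1)
            tables.append(cells)
        truth = pd.concat(tables, ignore_index=True)
        truth["cell_id"] = np.arange(len(truth))
        truth_path = outdir / "truth_cells.csv"
        truth.to_csv(truth_path, index=False)
        stages.append({"name": stage, "outputs": [truth_path.name]})

        stage = "zonate"
        zone_sets = zonegeom.zones_from_boundaries(
            geometry.pia_polyline(), geometry.wm_polyline(), config.n_columns
        )
        zones_path = outdir / "zones.geojson"
        zones_path.write_text(json.dumps(zonegeom.zones_to_geojson(zone_sets), sort_keys=True))
        zone_areas = zonegeom.total_zone_areas(zone_sets)
        stages.append({"name": stage, "outputs": [zones_path.name]})

        stage = "quantify"
        if config.truth_bypass:
            table = truth.copy()
        else:
            table = _measure_condition(truth, geometry, config.detection, seed=seeds[2])
        table["zone"] = zonegeom.assign_zones_multi(
            table[["x", "y"]].to_numpy(), zone_sets
        )
        cells_path = outdir / "cells_zoned.csv"
        write_detections(table.assign(nuclear_mean_53BP1=table["i53bp1"]), cells_path)
        stages.append({"name": stage, "outputs": [cells_path.name]})

        stage = "culture"
        culture = synthcortex.simulate_culture(config.culture, seed=seeds[3])
        culture_path = outdir / "culture_cells.csv"
        culture.to_csv(culture_path, index=False)
        stages.append({"name": stage, "outputs": [culture_path.name]})

        stage = "analyze"
        results = analyze_cohorts(
            table,
            zone_areas,
            culture,
            coupling_per_case_n=config.coupling_per_case_n,
            bin_size=config.bin_size,
            seed=seeds[4],
        )
        stages.append({"name": stage, "outputs": []})

        stage = "report"
        report_path = write_report(results, outdir)
        stages.append({"name": stage, "outputs": [report_path.name]})
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        stages=stages,
        started=started,
        finished=time.time(),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
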