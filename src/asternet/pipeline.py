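"""End-to-end pipeline: calibrated I/O, configuration, reports.

``run_full_analysis`` chains detection and network statistics on one frame
and packages the results with provenance (config hash, input checksum,
software version) so any report can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams, VertexSet, detect_vertices
from .errors import ConfigurationError, ImageFormatError
from .frames import ImageFrame
from .network import (
    EdgeFilterPolicy,
    HomogeneityReport,
    NetworkSummary,
    filter_edges,
    summarize_network,
    tile_homogeneity,
    triangulate,
)

__all__ = [
    "HomogeneityConfig",
    "PipelineConfig",
    "RunReport",
    "read_image",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("asternet")


@dataclass(frozen=True)
class HomogeneityConfig:
    n_tiles: int = 16
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles not in (16, 64):
            raise ConfigurationError("n_tiles must be 16 or 64")
        if self.B < 100:
            raise ConfigurationError("B must be ≥ 100")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved parameters of one analysis run."""

    pixel_size_um: float
    detection: DetectionParams = field(default_factory=DetectionParams)
    edge_filter: EdgeFilterPolicy = field(default_factory=EdgeFilterPolicy)
    homogeneity: HomogeneityConfig = field(default_factory=HomogeneityConfig)
    boundary_margin_um: float | None = None  # defaults to edge_filter.max
    output_dir: str = "asternet_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigurationError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )

    def resolved_margin_um(self) -> float:
        if self.boundary_margin_um is not None:
            return self.boundary_margin_um
        return self.edge_filter.max_length_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d and isinstance(d["detection"], dict):
            d["detection"] = DetectionParams(**d["detection"])
        if "edge_filter" in d and isinstance(d["edge_filter"], dict):
            d["edge_filter"] = EdgeFilterPolicy(**d["edge_filter"])
        if "homogeneity" in d and isinstance(d["homogeneity"], dict):
            d["homogeneity"] = HomogeneityConfig(**d["homogeneity"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one analysis run produced, plus provenance."""

    summary: NetworkSummary
    homogeneity: HomogeneityReport | None
    vertices: VertexSet
    config: PipelineConfig
    provenance: dict
    is_empty: bool = False


def read_image(path: str | Path, pixel_size_um: float) -> ImageFrame:
    """Read a single-channel 2D TIFF or PNG with explicit calibration.

    Calibration is always supplied by the caller, never guessed from file
    metadata. Multi-page TIFFs and colour images are rejected: the pipeline
    is strictly 2D single-channel.
    """
    if not pixel_size_um > 0:
        raise ConfigurationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            data = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            data = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface any decoder failure
        raise ImageFormatError(f"unreadable image {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise ImageFormatError(
            f"{path} is a colour image; supply a single-channel grayscale frame"
        )
    if data.ndim != 2:
        raise ImageFormatError(
            f"{path} has shape {data.shape}; multi-page/3D inputs are not "
            "supported (2D-only pipeline)"
        )
    return ImageFrame(data.astype(np.float64), pixel_size_um)


def _sha256_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_full_analysis(image: ImageFrame, config: PipelineConfig) -> RunReport:
    """Detect vertices, triangulate, compute all statistics on one frame.

    An empty detection yields a RunReport flagged ``is_empty`` with NaN
    statistics rather than an exception, so batch callers can distinguish
    "no asters found" from a crash.
    """
    log.info(
        "analysis start: %d×%d px at %.4f μm/px",
        image.width_px, image.height_px, image.pixel_size_um,
    )
    vertices = detect_vertices(image, config.detection)
    log.info("detected %d vertices after merging", len(vertices))

    provenance = {
        "software_version": __version__,
        "config_hash": config.content_hash(),
        "input_checksum": _sha256_array(image.intensities),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "pixel_size_um": image.pixel_size_um,
        "image_shape_px": [image.height_px, image.width_px],
    }

    if len(vertices) < 4:
        log.warning("fewer than 4 vertices detected; reporting empty result")
        nan = float("nan")
        summary = NetworkSummary(
            nan, nan, nan, nan,
            len(vertices) / image.area_mm2 if image.area_mm2 > 0 else nan,
            nan, nan, len(vertices), 0,
        )
        return RunReport(summary, None, vertices, config, provenance, is_empty=True)

    summary = summarize_network(
        vertices, config.edge_filter, config.resolved_margin_um()
    )
    log.info(
        "edges: %d retained, %d short-rejected (<%g μm), %d long-rejected (>%g μm)",
        summary.n_edges_retained, summary.n_short_rejected,
        config.edge_filter.min_length_um,
        summary.n_long_rejected, config.edge_filter.max_length_um,
    )
    hom = tile_homogeneity(
        vertices,
        n_tiles=config.homogeneity.n_tiles,
        B=config.homogeneity.B,
        seed=config.homogeneity.seed,
        policy=config.edge_filter,
    )
    log.info(
        "summary: mean spacing %.2f ± %.2f μm, median degree %g, "
        "density %.0f /mm², hexagon correlation %.3f",
        summary.mean_edge_length_um, summary.sd_edge_length_um,
        summary.median_degree, summary.vertex_density_per_mm2,
        summary.hexagon_correlation,
    )
    return RunReport(summary, hom, vertices, config, provenance)


def _edges_dataframe(report: RunReport) -> pd.DataFrame:
    net = triangulate(report.vertices, report.config.resolved_margin_um())
    kept = filter_edges(net, report.config.edge_filter)
    return pd.DataFrame(
        {
            "v1": net.edges[:, 0],
            "v2": net.edges[:, 1],
            "length_um": net.lengths_um,
            "retained": kept.retained_mask,
        }
    )


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Persist a run: summary/homogeneity JSON, vertex and edge CSVs, and a
    plain-text table with the standard columns (Av Dist, Neighb,
    Vert. Dens, Corr. Hex)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "summary": out / "summary.json",
            "homogeneity": out / "homogeneity.json",
            "vertices": out / "vertices.csv",
            "edges": out / "edges.csv",
            "table": out / "report.txt",
            "provenance": out / "provenance.json",
        }
        payload = report.summary.to_dict()
        with open(paths["summary"], "w") as fh:
            json.dump(payload, fh, indent=2)
        if report.homogeneity is not None:
            report.homogeneity.to_json(paths["homogeneity"])
        report.vertices.to_csv(paths["vertices"])
        if not report.is_empty:
            _edges_dataframe(report).to_csv(paths["edges"], index=False)
        with open(paths["provenance"], "w") as fh:
            json.dump(report.provenance, fh, indent=2)

        s = report.summary
        lines = [
            f"{'Image':<16}{'Av Dist':>10}{'Neighb':>8}{'Vert. Dens':>12}{'Corr. Hex':>11}",
            f"{'analysed':<16}"
            f"{s.mean_edge_length_um:>10.1f}"
            f"{s.median_degree:>8.0f}"
            f"{s.vertex_density_per_mm2:>12,.0f}"
            f"{s.hexagon_correlation:>11.3f}",
            "",
            f"n_vertices={s.n_vertices}  n_edges_retained={s.n_edges_retained}  "
            f"sd={s.sd_edge_length_um:.2f} um  degree_IQR={s.degree_iqr:g}",
        ]
        paths["table"].write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing report under {out}: {exc}") from exc
    return paths
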