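"""Readers, writers, and the deposit's naming/schema conventions.

Vector layers are GeoJSON feature collections whose attribute table
carries exactly the four canonical fields: ``GUBID_INT`` (integer unit
id), ``P2010`` (integer population count), ``AREA`` (km², recomputed on
write) and ``POP_DENS`` (persons/km², ``P2010/AREA``, 0 for empty
units).  Merge logs are plain CSV.  Rasters are single-band ESRI ASCII
grids (``.asc``) with a tagged nodata value.

Simulated level files follow the naming convention

    <prefix>_SIMULATED_Aggregation_seed_<seed>_scale_<rho>_target_<n>.geojson

and archive output is laid out in per-level folders ``Units_<n>``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .aggregator import MergeEvent, MergeLog, SimulationArchive
from .grids import GridSpec, PopulationRaster, Raster, WeightRaster
from .landscape import AreaUnit, Tessellation

__all__ = [
    "OutputName",
    "NameError_",
    "FormatError",
    "render_name",
    "parse_name",
    "read_units",
    "write_level",
    "write_merge_log",
    "read_merge_log",
    "write_archive",
    "write_ascii_grid",
    "read_ascii_grid",
]

SUPPORTED_FORMATS = ("geojson",)
UNSUPPORTED_FORMATS = ("shapefile", "shp", "gpkg", "geopackage")

_NAME_RE = re.compile(
    r"^(?P<prefix>.+)_SIMULATED_Aggregation"
    r"_seed_(?P<seed>-?\d+)"
    r"_scale_(?P<scale>[0-9.]+)"
    r"_target_(?P<target>\d+)"
    r"\.(?P<ext>\w+)$"
)


class NameError_(ValueError):
    """A filename does not match the simulated-units naming convention."""


class FormatError(ValueError):
    """Unsupported vector format requested."""


@dataclass(frozen=True)
class OutputName:
    """Parsed parameters of one simulated level file."""

    seed: int
    scale: float
    target: int
    prefix: str = "SYN_admin"

    def render(self, ext: str = "geojson") -> str:
        scale = f"{self.scale:g}"
        return (
            f"{self.prefix}_SIMULATED_Aggregation_seed_{self.seed}"
            f"_scale_{scale}_target_{self.target}.{ext}"
        )


def render_name(name: OutputName, ext: str = "geojson") -> str:
    return name.render(ext)


def parse_name(filename: str) -> OutputName:
    """Inverse of :func:`render_name`; raises naming the offending part."""
    m = _NAME_RE.match(Path(filename).name)
    if not m:
        raise NameError_(
            f"{filename!r} does not match "
            "'<prefix>_SIMULATED_Aggregation_seed_<seed>_scale_<scale>"
            "_target_<target>.<ext>'"
        )
    return OutputName(
        prefix=m["prefix"],
        seed=int(m["seed"]),
        scale=float(m["scale"]),
        target=int(m["target"]),
    )


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def _check_format(fmt: str) -> None:
    fmt = fmt.lower().lstrip(".")
    if fmt not in SUPPORTED_FORMATS:
        raise FormatError(
            f"format {fmt!r} is not supported; supported formats: "
            f"{', '.join(SUPPORTED_FORMATS)}"
        )


def write_level(
    tess: Tessellation, path: str | Path, fmt: str = "geojson"
) -> Path:
    """Write a tessellation with the four-field schema.

    AREA is recomputed in km² from the written geometry's CRS units and
    POP_DENS from P2010/AREA (0, not NaN, for zero-population units).
    """
    _check_format(fmt)
    path = Path(path)
    features = []
    for unit in tess.units.values():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(unit.geometry),
                "properties": {
                    "GUBID_INT": int(unit.uid),
                    "P2010": int(unit.pop),
                    "AREA": unit.area,
                    "POP_DENS": unit.pop / unit.area,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if tess.crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": str(tess.crs)}}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return path


def read_units(
    path: str | Path,
    field_map: dict[str, str] | None = None,
    build_adjacency: bool = True,
) -> Tessellation:
    """Read a vector layer into a :class:`Tessellation`.

    ``field_map`` remaps attribute names, e.g. ``{"GUBID_INT": "myid"}``
    when the source schema differs.  AREA/POP_DENS on disk are ignored;
    both are recomputed from geometry.
    """
    path = Path(path)
    _check_format(path.suffix or "geojson")
    fields = {"GUBID_INT": "GUBID_INT", "P2010": "P2010"}
    if field_map:
        fields.update(field_map)
    doc = json.loads(path.read_text())
    units = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        units.append(
            AreaUnit.from_geometry(
                uid=int(props[fields["GUBID_INT"]]),
                geometry=shape(feat["geometry"]),
                pop=int(props[fields["P2010"]]),
            )
        )
    crs = None
    if "crs" in doc:
        crs = doc["crs"].get("properties", {}).get("name")
    if build_adjacency:
        return Tessellation.from_units(units, crs=crs)
    return Tessellation(units={u.uid: u for u in units}, crs=crs,
                        adjacency={u.uid: set() for u in units})


# ---------------------------------------------------------------------------
# Merge logs (CSV)
# ---------------------------------------------------------------------------

_LOG_COLUMNS = ("seed", "iteration", "target", "merged_uid", "into_uid")


def write_merge_log(log: MergeLog, path: str | Path) -> Path:
    """One CSV row per merge event, in event order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_LOG_COLUMNS)
            for e in log.events:
                writer.writerow(
                    [e.seed, e.iteration, e.target, e.merged_uid, e.into_uid]
                )
    except OSError as exc:
        raise OSError(f"could not write merge log to {path}: {exc}") from exc
    return path


def read_merge_log(path: str | Path) -> MergeLog:
    path = Path(path)
    log = MergeLog()
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            log.events.append(
                MergeEvent(
                    seed=int(row["seed"]),
                    iteration=int(row["iteration"]),
                    target=int(row["target"]),
                    merged_uid=int(row["merged_uid"]),
                    into_uid=int(row["into_uid"]),
                )
            )
    return log


# ---------------------------------------------------------------------------
# Archive layout
# ---------------------------------------------------------------------------

def write_archive(
    archive: SimulationArchive,
    out_dir: str | Path,
    prefix: str = "SYN_admin",
    fmt: str = "geojson",
) -> list[Path]:
    """Write an archive with the deposit's folder layout.

    ``Units_<target>/`` folders hold one level file per seed;
    ``Merge_Logs/`` holds one chain CSV per seed.
    """
    out_dir = Path(out_dir)
    written = []
    rho = archive.config.rho
    for (seed, target), (tess, _) in sorted(archive.results.items()):
        name = OutputName(prefix=prefix, seed=seed, scale=rho, target=target)
        dest = out_dir / f"Units_{target}" / name.render(fmt)
        written.append(write_level(tess, dest, fmt))
    for seed, log in archive.seed_logs.items():
        written.append(
            write_merge_log(log, out_dir / "Merge_Logs" / f"merge_log_seed_{seed}.csv")
        )
    return written


# ---------------------------------------------------------------------------
# Rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a single-band raster as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = raster.grid
    values = np.where(raster.nodata_mask, NODATA, raster.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {float(g.x_min)!r}\n"
        f"yllcorner {float(g.y_min)!r}\n"
        f"cellsize {float(g.pixel_size)!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.10g")
    return path


def read_ascii_grid(
    path: str | Path, cls: type[Raster] = PopulationRaster, crs: str | None = None
) -> Raster:
    """Read an ESRI ASCII grid into a raster container."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        pixel_size=header["cellsize"],
        crs=crs,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    return cls(grid=grid, values=values, nodata_mask=mask)
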