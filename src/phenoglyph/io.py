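"""Table, image and configuration I/O."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .table import FeatureTable

logger = logging.getLogger(__name__)


def read_feature_table(path: str | Path,
                       dimensional: set[str] | None = None,
                       index_col: int | str | None = 0) -> FeatureTable:
    """Read a CSV/TSV feature table (header row required).

    The delimiter is inferred from the extension (``.tsv`` -> tab).
    Duplicate column names and empty tables are errors; non-numeric
    columns load with a warning and are simply unavailable for binding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    header = pd.read_csv(path, sep=sep, nrows=0)
    cols = list(header.columns)
    dupes = [c for c in set(cols) if cols.count(c) > 1]
    # pandas mangles duplicates to "x.1"; detect both spellings
    dupes += [c for c in cols if "." in c and c.rsplit(".", 1)[0] in cols
              and c.rsplit(".", 1)[1].isdigit()]
    if dupes:
        raise ValueError(f"duplicate column names in {path.name}: "
                         f"{sorted(set(d.rsplit('.', 1)[0] for d in dupes))}")
    df = pd.read_csv(path, sep=sep, index_col=index_col)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        logger.warning("non-numeric columns (not bindable): %s", non_numeric)
    dim = frozenset(dimensional or set()) & set(df.columns)
    return FeatureTable(df, dimensional_set=dim)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(path, sep=sep)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-plane TIFF/PNG as a float array (2D or multichannel)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio
    return np.asarray(iio.imread(path), dtype=float)


def read_glyph_config(path: str | Path) -> dict:
    """Glyph-spec config: YAML mapping feature name -> element name (or a
    mapping with an ``element`` key plus style keys)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("glyph config must be a mapping of "
                         "feature name -> element name")
    return raw


@dataclass
class RunConfig:
    """Every reconstructed analysis parameter, exposed and logged per run
    so the gaps filled by this implementation stay auditable."""

    seed: int = 0
    pixel_size: float = 1.0
    # segmentation / texture
    smoothing_sigma: float = 2.0
    ser_sigma: float = 2.0
    membrane_band_px: int = 3
    glcm_levels: int = 32
    min_texture_area: int = 25
    core_threshold_factor: float = 0.7
    # QC
    mitotic_mad_factor: float = 3.0
    min_cell_area_px: float = 100.0
    # analysis
    n_clusters: int = 5
    # rendering
    colour_map: str = "viridis"
    layout_mode: str = "grid"

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Defaults < config file < explicit overrides; unknown keys are
        rejected by name."""
        values: dict = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(data, dict):
                raise ValueError("run config must be a flat mapping")
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def log(self) -> None:
        for key, value in sorted(asdict(self).items()):
            logger.info("config %s = %r", key, value)
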