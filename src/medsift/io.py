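"""Format readers/writers and reproducible run plumbing.

Tables travel as tab-separated text with a header row; gene sets as GMT
(name, description, members per line); images as single-channel TIFF or PNG;
run manifests and summaries as JSON.  ``run_stage`` validates a stage config
against a small schema, executes the stage, and writes outputs atomically
together with a manifest (inputs, parameters, seed, package version).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

logger = logging.getLogger("medsift")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    _atomic_write_text(df.to_csv(sep="\t", index=index), path)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, dict[str, Any]]:
    """Read a GMT file into {set name: {'description': ..., 'genes': [...]}}.

    Field 2 is the description (tabs beyond field 2 are members, so a
    description cannot itself contain a tab — per the GMT dialect it is a
    single field).  Duplicate set names and empty member lists are errors.
    """
    sets: dict[str, dict[str, Any]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set name {name!r}")
            sets[name] = {"description": desc, "genes": genes}
    return sets


def write_gmt(sets: dict[str, dict[str, Any]], path: str | Path) -> None:
    lines = []
    for name, body in sets.items():
        genes = body["genes"]
        if not genes:
            raise ValueError(f"gene set {name!r} has no members")
        lines.append("\t".join([name, body.get("description", "")] + list(genes)))
    _atomic_write_text("\n".join(lines) + "\n", path)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a single-channel image as TIFF (float) or PNG (8-bit scaled)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        import imageio.v3 as iio

        arr = np.asarray(image, dtype=float)
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


# ---------------------------------------------------------------------------
# atomic writes, JSON, manifests
# ---------------------------------------------------------------------------


def _atomic_write_text(text: str, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(obj: Any, path: str | Path) -> None:
    _atomic_write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n", path)


def _jsonable(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# run configuration / dispatch
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Raised when a stage config violates its schema (CLI exit code 2)."""


#: schema per stage: {field: (required, type)}; stages with randomness
#: require an explicit seed.
STAGE_SCHEMAS: dict[str, dict[str, tuple[bool, type]]] = {
    "simulate": {"seed": (True, int), "out_dir": (True, str), "n_genes": (False, int)},
    "screen": {
        "counts": (True, str),
        "out_dir": (True, str),
        "seed": (True, int),
        "alpha": (False, float),
        "n_perm": (False, int),
        "primary_fdr": (False, float),
        "secondary_fdr": (False, float),
    },
    "footprint": {
        "deltas": (True, str),
        "footprints": (True, str),
        "out_dir": (True, str),
    },
    "dynamics": {
        "matrix": (True, str),
        "metadata": (True, str),
        "reference": (True, str),
        "out_dir": (True, str),
        "grid_step_h": (False, float),
    },
    "fate": {
        "traces": (True, str),
        "out_dir": (True, str),
        "window": (False, int),
        "feature": (False, str),
    },
    "colonies": {
        "images": (True, list),
        "out_dir": (True, str),
        "blur_sigma": (False, float),
        "area_min": (False, float),
        "area_max": (False, float),
        "circularity_min": (False, float),
    },
    "classify": {
        "table": (True, str),
        "thresholds": (True, dict),
        "out_dir": (True, str),
        "min_area": (False, float),
    },
}


def validate_config(stage: str, config: dict[str, Any]) -> dict[str, Any]:
    """Validate a stage config against its schema; unknown keys rejected."""
    if stage not in STAGE_SCHEMAS:
        raise ConfigError(f"unknown stage {stage!r}; known: {sorted(STAGE_SCHEMAS)}")
    schema = STAGE_SCHEMAS[stage]
    unknown = set(config) - set(schema)
    if unknown:
        raise ConfigError(f"stage {stage!r}: unknown config keys {sorted(unknown)}")
    for key, (required, typ) in schema.items():
        if key not in config:
            if required:
                raise ConfigError(f"stage {stage!r}: missing required key {key!r}")
            continue
        val = config[key]
        if typ is float and isinstance(val, int) and not isinstance(val, bool):
            val = float(val)
            config[key] = val
        if not isinstance(val, typ):
            raise ConfigError(
                f"stage {stage!r}: key {key!r} must be {typ.__name__}, got {type(val).__name__}"
            )
    return config


def write_manifest(out_dir: str | Path, stage: str, config: dict[str, Any]) -> Path:
    from . import __version__

    manifest = {
        "stage": stage,
        "config": {k: v for k, v in config.items()},
        "package_version": __version__,
    }
    path = Path(out_dir) / "manifest.json"
    write_json(manifest, path)
    return path


def run_stage(
    stage: str,
    config: dict[str, Any],
    runner: Callable[[dict[str, Any]], dict[str, Any]],
) -> dict[str, Any]:
    """Validate config, run the stage, write summary + manifest.

    ``runner`` performs the stage work and returns a JSON-serializable
    summary; outputs and the manifest land in ``config['out_dir']``.
    """
    config = validate_config(stage, config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("[%s] starting", stage)
    summary = runner(config)
    write_json(summary, out_dir / "summary.json")
    write_manifest(out_dir, stage, config)
    logger.info("[%s] done", stage)
    return summary
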