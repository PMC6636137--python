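"""Readers and writers for the exchange formats.

All tables are comma-separated UTF-8 with a mandatory header row and
decimal points (no locale formatting).  Cell ids are 1-based in files
(matching the printed sheet) and 0-based in memory; the conversion lives
here and nowhere else.  Declared precisions: counts exact, volumes one
decimal (ul), weights four decimals (mg) — round-trips are lossless at
those precisions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .render import SheetImage
from .synthetic import GriddedSample, SpeciesComposition

__all__ = [
    "ParseError",
    "read_sample_table",
    "write_sample_table",
    "sample_summary",
    "read_gridded_table",
    "write_gridded_table",
    "write_image",
    "read_image",
    "load_config_file",
    "dump_json",
]

VOLUME_DECIMALS = 1
WEIGHT_DECIMALS = 4


class ParseError(ValueError):
    pass


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"{path}: {exc}") from exc


def _int_count(value: str, path, row: int, column: str = "count") -> int:
    try:
        f = float(value)
        i = int(f)
        if f != i:
            raise ValueError
    except ValueError:
        raise ParseError(
            f"{path}: row {row}: {column} {value!r} is not an integer"
        ) from None
    if i < 0:
        raise ParseError(f"{path}: row {row}: negative {column} {i}")
    return i


def read_sample_table(path) -> list[SpeciesComposition]:
    """Read per-sample species counts (columns sample_id, species, count).

    Same shape as a published per-sample/per-taxon count table.  Row numbers
    in error messages count the header as row 1.  Duplicate
    (sample_id, species) keys and non-integer or negative counts are
    rejected.  Species with count 0 are rejected (a listed species is
    present).
    """
    df = _read_csv(path)
    required = ["sample_id", "species", "count"]
    if list(df.columns[:3]) != required:
        raise ParseError(f"{path}: header must start with {required}, got {list(df.columns)}")

    tables: dict[str, dict[str, int]] = {}
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        sid, sp = rec.sample_id, rec.species
        key = (sid, sp)
        if key in seen:
            raise ParseError(f"{path}: row {i}: duplicate entry for {key}")
        seen.add(key)
        c = _int_count(rec.count, path, i)
        if c == 0:
            raise ParseError(f"{path}: row {i}: count 0 (a listed species must be present)")
        tables.setdefault(sid, {})[sp] = c
    return [SpeciesComposition(sid, counts) for sid, counts in tables.items()]


def write_sample_table(compositions: list[SpeciesComposition], path) -> None:
    rows = [
        {"sample_id": comp.sample_id, "species": sp, "count": comp.counts[sp]}
        for comp in compositions
        for sp in comp.species
    ]
    pd.DataFrame(rows, columns=["sample_id", "species", "count"]).to_csv(path, index=False)


def sample_summary(compositions: list[SpeciesComposition]) -> dict[str, float]:
    """Study-design statistics of a composition table.

    Returns the grand total, the per-sample mean and SD of specimen counts
    (sample SD, ddof=1), the mean species count, and the min/max sample
    sizes — the numbers a monitoring report would print for such a table.
    """
    totals = np.array([c.total for c in compositions], dtype=float)
    species = np.array([c.n_species for c in compositions], dtype=float)
    return {
        "n_samples": len(compositions),
        "total_specimens": int(totals.sum()),
        "mean_specimens": float(totals.mean()),
        "sd_specimens": float(totals.std(ddof=1)) if len(totals) > 1 else 0.0,
        "mean_species": float(species.mean()),
        "sd_species": float(species.std(ddof=1)) if len(species) > 1 else 0.0,
        "min_specimens": int(totals.min()),
        "max_specimens": int(totals.max()),
    }


# ---------------------------------------------------------------------------
# gridded samples


def write_gridded_table(samples: list[GriddedSample], path) -> None:
    """Write gridded samples as one row per (cell, species), cells 1-based.

    Per-cell measures repeat on every species row of that cell; rows are
    written for all cell x species combinations (counts may be 0) so the
    round-trip is exact.
    """
    rows = []
    for s in samples:
        vol = s.cell_volume_ul
        wet = s.cell_wet_mg
        dry = s.cell_dry_mg
        for cell in range(s.n_cells):
            for j, sp in enumerate(s.species):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "cell_id": cell + 1,
                        "species": sp,
                        "count": int(s.cell_counts[cell, j]),
                        "volume_ul": round(float(vol[cell]), VOLUME_DECIMALS) if vol is not None else "",
                        "wet_mg": round(float(wet[cell]), WEIGHT_DECIMALS) if wet is not None else "",
                        "dry_mg": round(float(dry[cell]), WEIGHT_DECIMALS) if dry is not None else "",
                    }
                )
    pd.DataFrame(
        rows,
        columns=["sample_id", "cell_id", "species", "count", "volume_ul", "wet_mg", "dry_mg"],
    ).to_csv(path, index=False)


def read_gridded_table(path) -> list[GriddedSample]:
    """Read gridded samples written by :func:`write_gridded_table`."""
    df = _read_csv(path)
    required = ["sample_id", "cell_id", "species", "count"]
    if list(df.columns[:4]) != required:
        raise ParseError(f"{path}: header must start with {required}")

    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        species = sorted(grp["species"].unique())
        cells = sorted({_int_count(c, path, 0, "cell_id") for c in grp["cell_id"]})
        n_cells = max(cells)
        counts = np.zeros((n_cells, len(species)), dtype=int)
        measures = {name: np.full(n_cells, np.nan) for name in ("volume_ul", "wet_mg", "dry_mg")}
        has_measure = {name: False for name in measures}
        sp_index = {sp: j for j, sp in enumerate(species)}
        for i, rec in enumerate(grp.itertuples(index=False), start=2):
            cell = _int_count(rec.cell_id, path, i, "cell_id") - 1
            counts[cell, sp_index[rec.species]] = _int_count(rec.count, path, i)
            for name in measures:
                raw = getattr(rec, name, "")
                if raw != "":
                    measures[name][cell] = float(raw)
                    has_measure[name] = True
        comp = SpeciesComposition(
            str(sid), {sp: int(counts[:, j].sum()) for sp, j in sp_index.items()}
        )
        samples.append(
            GriddedSample(
                comp,
                species,
                counts,
                cell_volume_ul=measures["volume_ul"] if has_measure["volume_ul"] else None,
                cell_wet_mg=measures["wet_mg"] if has_measure["wet_mg"] else None,
                cell_dry_mg=measures["dry_mg"] if has_measure["dry_mg"] else None,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# images


def write_image(image: SheetImage, path, truth_path=None) -> None:
    """Write an 8-bit grayscale PNG and, optionally, its truth CSV."""
    Image.fromarray(image.pixels, mode="L").save(path, format="PNG")
    if truth_path is not None:
        pd.DataFrame(
            {
                "specimen_id": np.arange(image.truth_count),
                "x_px": np.round(image.truth_positions[:, 0], 2)
                if image.truth_count
                else [],
                "y_px": np.round(image.truth_positions[:, 1], 2)
                if image.truth_count
                else [],
            }
        ).to_csv(truth_path, index=False)


def read_image(path, truth_path=None, scale_px_per_mm: float = 0.0, **meta) -> SheetImage:
    """Read a PNG (RGB converted by ITU-R 601 luminance) plus optional truth."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16"):
            im = im.convert("L")
        pixels = np.asarray(im, dtype=np.uint8)
    if truth_path is not None:
        truth = pd.read_csv(truth_path)
        positions = truth[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        positions = np.empty((0, 2))
    return SheetImage(
        pixels=pixels,
        scale_px_per_mm=scale_px_per_mm,
        truth_count=len(positions),
        truth_positions=positions,
        **meta,
    )


# ---------------------------------------------------------------------------
# config / json helpers


def load_config_file(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
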