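"""Intermolecular contact maps and ensemble consensus maps.

A contact map places receptor residues on the x-axis and ligand residues on
the y-axis; a cell is marked where the two residues are in contact.  The
consensus map of an ensemble shades each cell by the contact's conservation
rate CR_kl in grayscale: never in contact renders white, the most conserved
contact renders black, intermediate conservation renders proportionally
darker grey.

Two renderings are provided: an exact raster (`render_map`, one upscaled
pixel block per residue pair, bit-exact for programmatic readback, with a
sidecar recording the grey-level ↔ CR mapping and the axis labels) and a
labelled matplotlib figure (`render_figure`) for visual inspection.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .contacts import ContactSet
from .conservation import EnsembleConservation
from .errors import DataError, UsageError
from .structure_io import ComplexModel, ResidueKey


@dataclass
class MapGrid:
    """A numeric contact-map grid: values[i, j] is CR for (y_axis[i], x_axis[j])."""

    x_axis: list[ResidueKey]  # receptor residues
    y_axis: list[ResidueKey]  # ligand residues
    values: np.ndarray  # shape (len(y_axis), len(x_axis)), in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.y_axis), len(self.x_axis)):
            raise UsageError(
                f"grid shape {self.values.shape} does not match axes "
                f"({len(self.y_axis)}, {len(self.x_axis)})"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise DataError("grid values must lie in [0, 1]")


def _residue_axes(models: list[ComplexModel]) -> tuple[list[ResidueKey], list[ResidueKey]]:
    receptor: set[ResidueKey] = set()
    ligand: set[ResidueKey] = set()
    for model in models:
        receptor |= set(model.receptor_residues)
        ligand |= set(model.ligand_residues)
    return sorted(receptor), sorted(ligand)


def build_grid(cons: EnsembleConservation, models: list[ComplexModel]) -> MapGrid:
    """Consensus grid: cell (k, l) holds CR_kl, 0 where never in contact.

    Axes are the union of residues across the supplied models, in stable
    (chain, number, insertion code) order.
    """
    if not models:
        raise UsageError("empty ensemble: no models to derive the residue axes from")
    x_axis, y_axis = _residue_axes(models)
    x_index = {key: j for j, key in enumerate(x_axis)}
    y_index = {key: i for i, key in enumerate(y_axis)}
    values = np.zeros((len(y_axis), len(x_axis)))
    for (rec, lig), rate in cons.rates().items():
        values[y_index[lig], x_index[rec]] = rate
    return MapGrid(x_axis=x_axis, y_axis=y_axis, values=values)


def grid_from_contacts(contact_set: ContactSet, model: ComplexModel) -> MapGrid:
    """0/1 contact-map grid of a single model (a plain intermolecular map)."""
    x_axis, y_axis = _residue_axes([model])
    x_index = {key: j for j, key in enumerate(x_axis)}
    y_index = {key: i for i, key in enumerate(y_axis)}
    values = np.zeros((len(y_axis), len(x_axis)))
    for rec, lig in contact_set.contacts:
        values[y_index[lig], x_index[rec]] = 1.0
    return MapGrid(x_axis=x_axis, y_axis=y_axis, values=values)


def _gray_levels(values: np.ndarray, scale: str) -> tuple[np.ndarray, float]:
    if scale == "relative":
        vmax = float(values.max()) if values.size else 0.0
        if vmax == 0.0:
            vmax = 1.0  # all-white map
    elif scale == "absolute":
        vmax = 1.0
    else:
        raise UsageError(f"scale must be 'relative' or 'absolute', got {scale!r}")
    gray = np.round(255.0 * (1.0 - values / vmax)).astype(np.uint8)
    return gray, vmax


def render_map(
    grid: MapGrid,
    path: str | Path,
    scale: str = "relative",
    cell_px: int = 8,
) -> Path:
    """Write the grayscale raster PNG plus a sidecar describing the scale.

    Each residue pair becomes a ``cell_px``×``cell_px`` pixel block; grey
    level is 255*(1 - CR/vmax) where vmax is the grid maximum (relative
    scale, the default: the most conserved contact of this map is black) or
    1.0 (absolute scale: only full conservation is black).  Row 0 (top) is
    the first ligand residue; column 0 the first receptor residue.
    """
    if grid.values.size == 0:
        raise DataError("empty grid: nothing to render")
    path = Path(path)
    gray, vmax = _gray_levels(grid.values, scale)
    raster = np.kron(gray, np.ones((cell_px, cell_px), dtype=np.uint8))
    Image.fromarray(raster, mode="L").save(path)

    sidecar = path.with_suffix(path.suffix + ".scale.txt")
    lines = [
        f"scale\t{scale}",
        f"vmax\t{vmax:.17g}",
        "gray_formula\tgray = round(255 * (1 - CR / vmax)); 0=black 255=white",
        f"cell_px\t{cell_px}",
        "orientation\trow 0 (top) = first ligand residue; column 0 (left) = first receptor residue",
        "x_axis_receptor\t" + " ".join(str(k) for k in grid.x_axis),
        "y_axis_ligand\t" + " ".join(str(k) for k in grid.y_axis),
    ]
    sidecar.write_text("\n".join(lines) + "\n")
    return path


def render_figure(grid: MapGrid, path: str | Path, scale: str = "relative") -> Path:
    """Labelled consensus-map figure (matplotlib) with residue-number axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if grid.values.size == 0:
        raise DataError("empty grid: nothing to render")
    _, vmax = _gray_levels(grid.values, scale)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(
        grid.values,
        cmap="Greys",
        vmin=0.0,
        vmax=vmax,
        interpolation="nearest",
        aspect="auto",
        origin="upper",
    )
    step_x = max(1, len(grid.x_axis) // 25)
    step_y = max(1, len(grid.y_axis) // 25)
    ax.set_xticks(range(0, len(grid.x_axis), step_x))
    ax.set_xticklabels(
        [str(grid.x_axis[i]) for i in range(0, len(grid.x_axis), step_x)],
        rotation=90,
        fontsize=6,
    )
    ax.set_yticks(range(0, len(grid.y_axis), step_y))
    ax.set_yticklabels(
        [str(grid.y_axis[i]) for i in range(0, len(grid.y_axis), step_y)], fontsize=6
    )
    ax.set_xlabel("receptor residue")
    ax.set_ylabel("ligand residue")
    fig.colorbar(im, ax=ax, label="conservation rate CR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


_GRID_HEADER = (
    "receptor_chain\treceptor_number\treceptor_icode\treceptor_resname\t"
    "ligand_chain\tligand_number\tligand_icode\tligand_resname\tcr"
)


def write_grid_tsv(grid: MapGrid, path: str | Path) -> None:
    """Long-format numeric export of the grid; floats round-trip exactly."""
    rows = [_GRID_HEADER]
    for i, lig in enumerate(grid.y_axis):
        for j, rec in enumerate(grid.x_axis):
            rows.append(
                f"{rec.chain_id}\t{rec.residue_number}\t{rec.insertion_code}\t{rec.residue_name}\t"
                f"{lig.chain_id}\t{lig.residue_number}\t{lig.insertion_code}\t{lig.residue_name}\t"
                f"{grid.values[i, j]:.17g}"
            )
    Path(path).write_text("\n".join(rows) + "\n")


def read_grid_tsv(path: str | Path) -> MapGrid:
    """Re-read a grid written by :func:`write_grid_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _GRID_HEADER:
        raise DataError(f"{path}: not a grid TSV")
    cells: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for line in lines[1:]:
        rc, rn, ri, rr, lc, ln, li, lr, value = line.split("\t")
        rec = ResidueKey("receptor", rc, int(rn), ri, rr)
        lig = ResidueKey("ligand", lc, int(ln), li, lr)
        cells[(rec, lig)] = float(value)
    x_axis = sorted({rec for rec, _ in cells})
    y_axis = sorted({lig for _, lig in cells})
    values = np.zeros((len(y_axis), len(x_axis)))
    x_index = {key: j for j, key in enumerate(x_axis)}
    y_index = {key: i for i, key in enumerate(y_axis)}
    for (rec, lig), value in cells.items():
        values[y_index[lig], x_index[rec]] = value
    return MapGrid(x_axis=x_axis, y_axis=y_axis, values=values)
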