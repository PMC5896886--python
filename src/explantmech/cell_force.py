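"""Force-per-cell and tensional-stress estimates.

Given a mean tensile force, the effective sagittal sectional area (SSA,
deep force-bearing tissue only) and a mean cell sectional area, the force
borne per cell is force divided by the number of cell cross-sections in the
effective SSA; tensional stress is simply force over effective SSA
(μN/mm² ≡ Pa).

Note on the cell-area unit: the source table states the mean cell sectional
area as 625 nm², which is dimensionally inconsistent with its own per-cell
forces (a 625 nm² cross-section would imply ~fN-scale per-cell forces).
Interpreting it as 625 μm² — a 25 μm × 25 μm cell, typical for this tissue —
reproduces the printed values, and is the interpretation adopted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

from explantmech._util import round_sig

__all__ = [
    "CellForceRow",
    "force_per_cell",
    "tensional_stress",
    "build_table2",
    "DEFAULT_CELL_AREA_UM2",
]

#: Mean cell sectional area used throughout, μm² (see module docstring).
DEFAULT_CELL_AREA_UM2 = 625.0

_UM2_PER_MM2 = 1e6
_NN_PER_UN = 1e3


def force_per_cell(force_uN: float, effective_ssa_mm2: float, cell_area_um2: float) -> float:
    """Force per cell in nN: force × cell area / effective SSA.

    Equivalent to dividing the total force by the number of cell sectional
    areas tiling the effective SSA.
    """
    if not (force_uN > 0 and effective_ssa_mm2 > 0 and cell_area_um2 > 0):
        raise ValueError("force, effective SSA and cell area must all be > 0")
    n_cells = effective_ssa_mm2 * _UM2_PER_MM2 / cell_area_um2
    return force_uN / n_cells * _NN_PER_UN


def tensional_stress(force_uN: float, effective_ssa_mm2: float) -> float:
    """Tensional stress in Pa: force / effective SSA (μN/mm² ≡ Pa)."""
    if not (force_uN > 0 and effective_ssa_mm2 > 0):
        raise ValueError("force and effective SSA must be > 0")
    return force_uN / effective_ssa_mm2


@dataclass(frozen=True)
class CellForceRow:
    """One summary row: inputs plus derived per-cell force and stress.

    Full-precision derived values are retained alongside the 2-significant-
    figure values used for table reproduction.
    """

    time_hr: float
    force_uN: float
    effective_ssa_mm2: float
    cell_area_um2: float
    force_per_cell_nN: float
    stress_pa: float

    @property
    def force_per_cell_nN_2sf(self) -> float:
        return round_sig(self.force_per_cell_nN, 2)

    @property
    def stress_pa_2sf(self) -> float:
        return round_sig(self.stress_pa, 2)


def build_table2(
    rows: Sequence[Tuple[float, float, float]],
    cell_area_um2: float = DEFAULT_CELL_AREA_UM2,
) -> list:
    """Assemble the per-timepoint force/cell and stress table.

    ``rows`` are (time after G0 in hours, force in μN, effective SSA in mm²)
    triples. Returns a list of :class:`CellForceRow`; empty input yields an
    empty list.
    """
    out = []
    for time_hr, force_uN, ssa_mm2 in rows:
        out.append(
            CellForceRow(
                time_hr=float(time_hr),
                force_uN=float(force_uN),
                effective_ssa_mm2=float(ssa_mm2),
                cell_area_um2=float(cell_area_um2),
                force_per_cell_nN=force_per_cell(force_uN, ssa_mm2, cell_area_um2),
                stress_pa=tensional_stress(force_uN, ssa_mm2),
            )
        )
    return out
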