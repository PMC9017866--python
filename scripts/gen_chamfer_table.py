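"""Regenerate the chamfer correction table shipped with the package.

For each (aspect ratio, chamfer fraction) the axial magnetometric
demagnetizing factor of the chamfered cylinder is computed by
surface-charge self-energy quadrature on a fixed-topology mesh, and stored
as the ratio to the factor of the plain cylinder computed on the same
mesh, so that the leading quadrature bias cancels.

Run from the repository root:  python scripts/gen_chamfer_table.py
"""
from __future__ import annotations

import math
import sys
from pathlib import Path

import numpy as np
from numba import njit

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from chainforc.interactions import surface_mesh  # noqa: E402
from chainforc.shapes import chamfered_cylinder  # noqa: E402

ASPECTS = np.arange(1.0, 3.01, 0.25)
CHAMFERS = np.arange(0.0, 0.451, 0.05)
MESH_LEVEL = 3


@njit(cache=True)
def _self_tzz(c, n, a):
    acc = 0.0
    m = c.shape[0]
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            dx = c[i, 0] - c[j, 0]
            dy = c[i, 1] - c[j, 1]
            dz = c[i, 2] - c[j, 2]
            acc += a[i] * a[j] * n[i, 2] * n[j, 2] / math.sqrt(dx * dx + dy * dy + dz * dz)
    return acc


def axial_factor_mesh(aspect: float, chamfer: float) -> float:
    shape = chamfered_cylinder(length=aspect, diameter=1.0, chamfer_fraction=chamfer)
    c, n, a = surface_mesh(shape, MESH_LEVEL)
    return _self_tzz(c, n, a) / (4.0 * math.pi * shape.volume)


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "src" / "chainforc" / "data" / "chamfer_table.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    rows = ["aspect,chamfer,axial_ratio"]
    for p in ASPECTS:
        base = axial_factor_mesh(p, 0.0)
        for cfr in CHAMFERS:
            ratio = 1.0 if cfr == 0.0 else axial_factor_mesh(p, cfr) / base
            rows.append(f"{p:.3f},{cfr:.3f},{ratio:.6f}")
            print(rows[-1])
    out.write_text("\n".join(rows) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
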