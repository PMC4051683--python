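"""In-plane lattice analysis: chain packing and plaque indexing.

Two in-plane structures appear in oriented membrane-stack diffraction:

* the acyl-chain correlation peak near q ≈ 1.5 Å⁻¹, indexed as the [10]
  reflection of a 2-D hexagonal net (planar group p6) of hydrocarbon
  chains, from which the chain–chain distance and the gel-phase area per
  lipid follow in closed form; and
* extra reflections near 1.19 / 1.32 Å⁻¹ from immiscible crystalline
  cholesterol plaques, indexed as [110] and [200] of a 2-D monoclinic
  (oblique) lattice.

Intensity bookkeeping of the plaque and chain peaks between samples
quantifies growth of the plaque fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ObliqueLattice2D",
    "reciprocal_q",
    "fit_lattice",
    "area_per_lipid_hex",
    "plaque_intensity_change",
]


@dataclass(frozen=True)
class ObliqueLattice2D:
    """2-D oblique (monoclinic in-plane) lattice: a, b (Å), gamma (deg)."""

    a: float
    b: float
    gamma: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("lattice constants must be positive")
        if not 0 < self.gamma < 180:
            raise ValueError("gamma must lie in (0, 180) degrees")


def reciprocal_q(lattice: ObliqueLattice2D, h: int, k: int) -> float:
    """|q| of the (h,k) reflection of a 2-D oblique lattice.

    q = (2π/sin γ)·sqrt(h²/a² + k²/b² − 2hk·cos γ/(ab)).
    """
    if h == 0 and k == 0:
        raise ValueError("(0,0) is not a reflection")
    g = np.radians(lattice.gamma)
    return float(
        2.0 * np.pi / np.sin(g)
        * np.sqrt(h**2 / lattice.a**2 + k**2 / lattice.b**2
                  - 2.0 * h * k * np.cos(g) / (lattice.a * lattice.b))
    )


def fit_lattice(
    observations: list[tuple[int, int, float]],
    fixed: dict[str, float] | None = None,
    initial: ObliqueLattice2D | None = None,
) -> ObliqueLattice2D:
    """Least-squares lattice parameters from indexed peak positions.

    ``observations`` are (h, k, q) triples; ``fixed`` pins a subset of
    {a, b, gamma}.  Requires at least as many observations as free
    parameters (exact solve when determined).
    """
    fixed = dict(fixed or {})
    free = [p for p in ("a", "b", "gamma") if p not in fixed]
    if len(observations) < len(free):
        raise ValueError(
            f"{len(observations)} observation(s) cannot determine "
            f"{len(free)} free parameter(s)")
    init = initial or ObliqueLattice2D(10.0, 8.0, fixed.get("gamma", 100.0))
    x0 = [getattr(init, p) for p in free]

    def build(x):
        vals = dict(fixed)
        vals.update(dict(zip(free, x)))
        return ObliqueLattice2D(vals["a"], vals["b"], vals["gamma"])

    def resid(x):
        lat = build(x)
        return [reciprocal_q(lat, h, k) - q for h, k, q in observations]

    lb = [0.1 if p != "gamma" else 1.0 for p in free]
    ub = [np.inf if p != "gamma" else 179.0 for p in free]
    sol = least_squares(resid, x0, bounds=(lb, ub))
    if not sol.success:
        raise RuntimeError("lattice fit did not converge")
    return build(sol.x)


def area_per_lipid_hex(q_T: float) -> tuple[float, float]:
    """Gel-phase chain spacing and area per lipid from the chain peak.

    Indexing the chain-correlation peak as the [10] reflection of a
    hexagonal chain net gives the chain–chain distance
    a_T = 2π/(q_T·cos 30°), and, with two chains per lipid,
    A_L = √3·a_T².  Returns (a_T, A_L) in (Å, Å²).
    """
    if q_T <= 0:
        raise ValueError("q_T must be positive")
    a_T = 2.0 * np.pi / (q_T * np.cos(np.radians(30.0)))
    return a_T, float(np.sqrt(3.0) * a_T**2)


def _areas(table: pd.DataFrame, labels: list[str]) -> dict[str, float]:
    out = {}
    for lab in labels:
        rows = table[table["label"].astype(str).str.strip() == lab]
        if rows.empty:
            raise ValueError(f"peak table is missing required row {lab!r}")
        out[lab] = float(rows["area"].iloc[0])
    return out


def plaque_intensity_change(
    before: pd.DataFrame,
    after: pd.DataFrame,
    monoclinic_labels: tuple[str, str] = ("[110]", "[200]"),
    chain_label: str = "chain",
) -> tuple[float, float]:
    """Percent change of plaque vs chain-peak integrated intensity.

    Sums the [110] and [200] areas in each table and returns
    (100·ΔΣ/Σ_before, 100·Δchain/chain_before).  A positive plaque change
    with a negative chain change indicates growth of the crystalline
    plaque fraction at the expense of the lamellar lipid phase.
    """
    labels = list(monoclinic_labels) + [chain_label]
    b = _areas(before, labels)
    a = _areas(after, labels)
    mono_b = sum(b[lab] for lab in monoclinic_labels)
    mono_a = sum(a[lab] for lab in monoclinic_labels)
    return (100.0 * (mono_a - mono_b) / mono_b,
            100.0 * (a[chain_label] - b[chain_label]) / b[chain_label])
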