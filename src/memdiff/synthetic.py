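"""Forward simulator and fixture generator with closed-form ground truth.

Every analysis stage can be validated against a bilayer model whose
Fourier transform is known exactly: the density contrast (relative to
water) is a sum of mirrored Gaussians — positive head-group peaks near
±22 Å, a negative methyl trough at the center — so the form factors

    F_n = Σ_j w_j · A_j σ_j √(2π) · exp(−q_n²σ_j²/2) · cos(q_n z_j),

(w_j = 2 for mirrored pairs, 1 for a centered component) are available
in closed form, including their true signs.  The simulator inverts the
Lorentz correction to place Gaussian Bragg peaks of area |F_n|²/q_n on a
linear background and applies Poisson counting noise, giving seeded,
bit-reproducible intensity curves for round-trip tests.  Idealized
helical pseudo-atom peptide models connect the composition and
projection stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composition import (AMINO_ACID_FORMULAS, WATER, electrons_of_formula,
                          parse_formula, peptide_formula)
from .peakfit import SQRT2PI, Axis, FormFactorSet, IntensityCurve
from .projection import AtomicModel
from .lattice import ObliqueLattice2D, reciprocal_q

__all__ = [
    "BilayerModel",
    "default_gel_model",
    "analytic_form_factors",
    "simulate_intensity_curve",
    "make_helix_model",
    "write_fixtures",
]


@dataclass(frozen=True)
class BilayerModel:
    """Mirrored-Gaussian bilayer density contrast over one period.

    ``components`` are (center z_j ≥ 0, sigma_j, amplitude_j); a component
    with z_j > 0 implies its mirror partner at −z_j, a z_j = 0 component
    is counted once.  Amplitudes are densities relative to
    ``water_level`` (e/Å³); the methyl trough has negative amplitude.
    """

    d_spacing: float
    components: tuple[tuple[float, float, float], ...]
    water_level: float = 0.333

    def __post_init__(self):
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")
        for z, s, _ in self.components:
            if z < 0 or s <= 0:
                raise ValueError("component centers must be >= 0, widths > 0")

    def density(self, z) -> np.ndarray:
        """Absolute density ρ(z) = water_level + Σ mirrored Gaussians."""
        z = np.asarray(z, dtype=float)
        rho = np.full_like(z, self.water_level)
        for zj, sj, aj in self.components:
            rho = rho + aj * np.exp(-((z - zj) ** 2) / (2 * sj**2))
            if zj > 0:
                rho = rho + aj * np.exp(-((z + zj) ** 2) / (2 * sj**2))
        return rho

    def with_d(self, d_spacing: float) -> "BilayerModel":
        """Same bilayer, different hydration (lamellar period) — swelling."""
        return BilayerModel(d_spacing, self.components, self.water_level)


def default_gel_model(d_spacing: float = 55.07) -> BilayerModel:
    """Gel-state bilayer stand-in: head maxima at ±22 Å, methyl trough at 0."""
    return BilayerModel(
        d_spacing,
        components=(
            (22.0, 3.0, 0.20),   # phosphate head-group peaks
            (0.0, 2.5, -0.12),   # CH3 trough
        ),
    )


def analytic_form_factors(model: BilayerModel, max_order: int) -> FormFactorSet:
    """Exact Fourier coefficients of the model contrast, signs included."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    orders = np.arange(1, max_order + 1)
    q = 2.0 * np.pi * orders / model.d_spacing
    F = np.zeros_like(q)
    for zj, sj, aj in model.components:
        weight = 2.0 * np.cos(q * zj) if zj > 0 else np.ones_like(q)
        F += aj * sj * SQRT2PI * np.exp(-(q**2) * sj**2 / 2.0) * weight
    signs = np.where(F >= 0, 1, -1).astype(int)
    return FormFactorSet(model.d_spacing, orders, np.abs(F), signs)


def simulate_intensity_curve(
    ffset: FormFactorSet,
    noise_scale: float,
    background: tuple[float, float],
    seed: int,
    peak_sigma: float = 0.004,
    q_range: tuple[float, float] | None = None,
    n_points: int = 4000,
    lorentz_exponent: float = 1.0,
    axis: Axis = Axis.OUT_OF_PLANE,
) -> IntensityCurve:
    """Forward-simulate a 1-D Bragg series from form-factor magnitudes.

    Peak areas follow the inverse Lorentz correction I_n = |F_n|²/q_nᵉ;
    each reflection is a Gaussian of width ``peak_sigma`` on a linear
    background (slope, intercept).  ``noise_scale`` f > 0 applies Poisson
    counting noise scaled so the strongest point corresponds to (1/f)²
    counts (≈ f relative error); f = 0 is noiseless.  Identical seeds
    give bit-identical curves.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    q_n = ffset.q
    if q_range is None:
        q_range = (max(q_n.min() - 0.05, 1e-3), q_n.max() + 0.05)
    q = np.linspace(*q_range, n_points)
    slope, intercept = background
    y = slope * q + intercept
    areas = ffset.magnitudes**2 / q_n**lorentz_exponent
    for qn, area in zip(q_n, areas):
        y = y + area / (peak_sigma * SQRT2PI) * np.exp(-((q - qn) ** 2)
                                                       / (2 * peak_sigma**2))
    y = np.clip(y, 0.0, None)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        peak = y.max()
        if peak <= 0:
            raise ValueError("cannot scale noise for an all-zero curve")
        counts_max = (1.0 / noise_scale) ** 2
        lam = y * counts_max / peak
        y = rng.poisson(lam).astype(float) * peak / counts_max
        err = np.sqrt(np.clip(lam, 1.0, None)) * peak / counts_max
    else:
        err = None
    return IntensityCurve(axis, q, y, err)


def make_helix_model(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> AtomicModel:
    """Idealized helical pseudo-atom model of a peptide.

    One pseudo-atom per residue on an ideal α-helix (rise 1.5 Å, twist
    100°, radius 2.3 Å).  Each pseudo-atom carries the electron count of
    its residue (free amino acid minus one water); the terminal water's
    10 electrons are split 1 (H) to the first residue and 9 (OH) to the
    last, so the total equals the peptide electron count exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    zs = []
    for i, letter in enumerate(sequence):
        if letter not in AMINO_ACID_FORMULAS:
            raise ValueError(f"invalid amino-acid letter {letter!r} at position {i + 1}")
        res_e = electrons_of_formula(parse_formula(AMINO_ACID_FORMULAS[letter])) - \
            electrons_of_formula(WATER)
        zs.append(res_e)
    zs[0] += 1   # N-terminal H
    zs[-1] += 9  # C-terminal OH
    theta = np.radians(twist) * np.arange(n)
    coords = np.column_stack([radius * np.cos(theta),
                              radius * np.sin(theta),
                              rise * np.arange(n)])
    if n == 1:
        coords = np.zeros((1, 3))
    assert sum(zs) == electrons_of_formula(peptide_formula(sequence))
    return AtomicModel(tuple(sequence), np.array(zs, dtype=float), coords,
                       source_id=f"ideal-helix:{sequence}")


# ---------------------------------------------------------------------------
# fixture pack


def _write_helix_pdb(path: Path, model: AtomicModel) -> None:
    """Write pseudo-atoms as CA carbon records (electron detail is lost)."""
    lines = ["MODEL     1"]
    for i, (xyz) in enumerate(model.coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C")
    lines += ["ENDMDL", "END", ""]
    path.write_text("\n".join(lines))


def write_fixtures(outdir, seed: int) -> dict:
    """Emit a reproducible fixture pack for every pipeline stage.

    Contents: gel (d = 55.07 Å) and fluid (d = 68.97 Å) out-of-plane
    curves, a two-hydration swelling pair for sign assignment, an
    in-plane curve with the chain peak at 1.49 Å⁻¹ plus the monoclinic
    plaque reflections, and a PDB helix fixture.  A JSON manifest records
    every file with its generating parameters; regenerating with the
    same seed is bit-identical.
    """
    from .io import write_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}}

    def emit_curve(name, model, d, noise, sub_seed, max_order=10):
        ffs = analytic_form_factors(model.with_d(d), max_order)
        curve = simulate_intensity_curve(ffs, noise, (0.0, 50.0), sub_seed)
        write_curve(outdir / name, curve)
        manifest["files"][name] = {
            "kind": "out_of_plane_curve", "d_spacing": d, "noise": noise,
            "seed": sub_seed, "max_order": max_order,
            "true_signs": [int(s) for s in ffs.signs],
        }

    gel = default_gel_model()
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]
    emit_curve("gel_55.07.txt", gel, 55.07, 0.01, sub[0])
    emit_curve("swelling_60.00.txt", gel, 60.00, 0.01, sub[1])
    fluid = BilayerModel(68.97, ((24.0, 4.0, 0.12), (0.0, 4.0, -0.08)))
    emit_curve("fluid_68.97.txt", fluid, 68.97, 0.01, sub[2], max_order=4)

    # in-plane: chain peak at 1.49 plus monoclinic plaque reflections
    lat = ObliqueLattice2D(9.76, 7.56, 103.0)
    q110, q200 = reciprocal_q(lat, 1, 1), reciprocal_q(lat, 2, 0)
    q = np.linspace(0.9, 1.9, 2000)
    y = 30.0 + 10.0 * q
    for qc, sig, area in ((1.49, 0.05, 1216.0), (q110, 0.008, 73.0),
                          (q200, 0.008, 98.0)):
        y = y + area / (sig * SQRT2PI) * np.exp(-((q - qc) ** 2) / (2 * sig**2))
    counts_max = 1e4
    lam = y * counts_max / y.max()
    rng_ip = np.random.default_rng(sub[3])
    y_noisy = rng_ip.poisson(lam).astype(float) * y.max() / counts_max
    err = np.sqrt(np.clip(lam, 1.0, None)) * y.max() / counts_max
    write_curve(outdir / "inplane_gel.txt",
                IntensityCurve(Axis.IN_PLANE, q, y_noisy, err))
    manifest["files"]["inplane_gel.txt"] = {
        "kind": "in_plane_curve", "chain_q": 1.49, "seed": sub[3],
        "lattice": {"a": 9.76, "b": 7.56, "gamma": 103.0},
        "q110": q110, "q200": q200,
    }

    helix = make_helix_model("GSNKGAIIGLM")
    _write_helix_pdb(outdir / "helix_25_35.pdb", helix)
    manifest["files"]["helix_25_35.pdb"] = {
        "kind": "pdb_helix", "sequence": "GSNKGAIIGLM",
        "n_atoms": len(helix.elements),
    }

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
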