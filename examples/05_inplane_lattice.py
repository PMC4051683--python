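"""In-plane order: chain packing and the monoclinic plaque lattice.

The gel-phase chain-correlation peak indexes as the [10] reflection of a
hexagonal chain net; extra sharp reflections index on a 2-D monoclinic
lattice whose integrated intensity tracks plaque growth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from memdiff.io import read_curve
from memdiff.lattice import ObliqueLattice2D, area_per_lipid_hex, fit_lattice, \
    plaque_intensity_change, reciprocal_q
from memdiff.peakfit import Axis, chain_peak
from memdiff.synthetic import write_fixtures

# chain packing from a simulated gel-phase in-plane curve
with tempfile.TemporaryDirectory() as tmp:
    write_fixtures(Path(tmp) / "fx", seed=3)
    curve = read_curve(Path(tmp) / "fx" / "inplane_gel.txt", Axis.IN_PLANE)
q_T, sigma, area = chain_peak(curve)
a_T, A_L = area_per_lipid_hex(q_T)
print(f"chain peak q_T = {q_T:.3f} 1/A -> a_T = {a_T:.2f} A, "
      f"A_L = {A_L:.1f} A^2")

# monoclinic plaque lattice: forward positions and inverse fit
lat = ObliqueLattice2D(9.76, 7.56, 103.0)
q110, q200 = reciprocal_q(lat, 1, 1), reciprocal_q(lat, 2, 0)
print(f"[110] at {q110:.2f} 1/A, [200] at {q200:.2f} 1/A")
refit = fit_lattice([(1, 1, q110), (2, 0, q200)], fixed={"gamma": 103.0})
print(f"refit: a = {refit.a:.2f} A, b = {refit.b:.2f} A")

# plaque growth across peptide incubation (peak areas before/after)
def table(chain, p110, p200):
    return pd.DataFrame({"label": ["chain", "[110]", "[200]"],
                         "position": [1.49, q110, q200],
                         "width": [0.05, 0.008, 0.008],
                         "amplitude": [1.0, 1.0, 1.0],
                         "area": [chain, p110, p200]})

mono, chain = plaque_intensity_change(table(1216.0, 73.0, 98.0),
                                      table(552.0, 63.0, 158.0))
print(f"plaque area {mono:+.1f}%, chain peak {chain:+.1f}%")
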