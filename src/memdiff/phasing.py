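"""Phase (sign) assignment for centrosymmetric bilayer form factors.

For a centrosymmetric electron-density profile the bilayer form factor is
real, so the crystallographic phase problem reduces to choosing a sign
ν_n = ±1 for each Bragg order.  Sampling theory gives a continuous form
factor

    T(q_z) = Σ_n ν_n |F_n| · sinc(q_z d/2 − πn),   sinc(x) = sin(x)/x,

which interpolates the discrete samples ν_n|F_n| at q_n = 2πn/d.  When
the same bilayer is measured at several lamellar periods (the swelling
method), the correct sign vector is the one whose T(·), built from a
reference set, passes through the magnitudes observed at the other
periods.  The search is exhaustive over all 2^N sign vectors.

The global sign is not determined by the data (negating every ν_n
negates T); it is fixed by the bilayer-landmark convention that the
methyl trough at the bilayer center lies below the head-group maxima,
which for the synthesis in :mod:`memdiff.density` corresponds to ν_1 = −1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .peakfit import FormFactorSet

__all__ = ["SignVector", "continuous_form_factor", "assign_signs"]

MAX_ORDERS = 16


@dataclass(frozen=True)
class SignVector:
    """Sign assignment ν_n per observed order, with search diagnostics."""

    signs: tuple[int, ...]
    misfit: float = float("nan")
    degenerate: bool = False

    def __post_init__(self):
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be -1 or +1")


def continuous_form_factor(ffset: FormFactorSet, q_z, f0: float = 0.0
                           ) -> np.ndarray | float:
    """Evaluate T(q_z) for a fully sign-assigned form-factor set.

    For a centrosymmetric profile F_{−n} = F_n, so the sampling expansion
    runs over ±n: each order contributes
    ν_n|F_n|·[sinc(q d/2 − πn) + sinc(q d/2 + πn)].  The sampling
    property T(q_m) = ν_m|F_m| holds exactly (sinc(π(m∓n)) vanishes for
    positive integers m ≠ n), and T(0) = 0 when only orders n ≥ 1 are
    observed.

    ``f0`` optionally supplies the n = 0 coefficient
    F_0 = ∫(ρ−ρ_w)dz, which reflectivity does not measure but
    composition bookkeeping determines; it is hydration-invariant (added
    water has zero contrast) and sharpens the interpolation between
    Bragg samples.  It contributes f0·sinc(q d/2) and leaves the
    sampling property at n ≥ 1 untouched.
    """
    if not ffset.assigned:
        raise ValueError("all signs must be assigned before evaluating T")
    q = np.asarray(q_z, dtype=float)
    x = np.multiply.outer(q, np.full_like(ffset.orders, ffset.d_spacing / 2.0,
                                          dtype=float))
    pn = np.pi * ffset.orders
    kernel = np.sinc((x - pn) / np.pi) + np.sinc((x + pn) / np.pi)
    out = kernel @ ffset.signed
    if f0 != 0.0:
        out = out + f0 * np.sinc(q * ffset.d_spacing / 2.0 / np.pi)
    return float(out) if np.isscalar(q_z) else out


def _misfit(reference: FormFactorSet, signs: np.ndarray,
            others: list[FormFactorSet], weights: list[np.ndarray | None],
            f0: float = 0.0) -> float:
    # comparisons are limited to the band sampled by the reference set:
    # the sinc series interpolates inside [0, q_max_ref] but extrapolates
    # (unreliably) beyond the last measured order
    cand = reference.with_signs(signs)
    q_max = cand.q.max()
    total = 0.0
    for ffs, w in zip(others, weights):
        sel = ffs.q <= q_max * (1.0 + 1e-9)
        t = continuous_form_factor(cand, ffs.q[sel], f0=f0)
        resid = np.abs(t) - ffs.magnitudes[sel]
        if w is not None:
            resid = resid / w[sel]
        total += float(np.dot(resid, resid))
    return total


def assign_signs(
    ffsets: list[FormFactorSet],
    errors: list[np.ndarray] | None = None,
    f0: float = 0.0,
) -> tuple[list[FormFactorSet], SignVector]:
    """Assign signs by exhaustive search over swelling-series data.

    ``ffsets`` holds form-factor sets measured at ≥ 2 distinct lamellar
    periods.  The reference is the set with the largest d (densest q_z
    sampling); for each of the 2^N candidate sign vectors, T built on the
    reference set is evaluated at every other set's Bragg positions and
    compared with the observed magnitudes (optionally weighted by
    counting errors).  Returns all sets sign-assigned (non-reference sets
    take sign(T) at their own Bragg positions), in input order, plus the
    winning :class:`SignVector` of the reference set.

    The two-fold global ambiguity is resolved by convention ν_1 = −1
    (methyl trough below head maxima).  With a single observed order both
    signs fit equally; the convention is applied with a warning.
    """
    if len(ffsets) < 2:
        raise ValueError("swelling analysis needs form factors at >= 2 d-spacings")
    ds = np.array([f.d_spacing for f in ffsets])
    if np.min(np.abs(np.subtract.outer(ds, ds))[~np.eye(len(ds), dtype=bool)]) \
            < 0.005 * ds.max():
        raise ValueError("d-spacings closer than 0.5% are degenerate for swelling")
    ref_idx = int(np.argmax(ds))
    reference = ffsets[ref_idx]
    n_orders = len(reference.orders)
    if n_orders > MAX_ORDERS:
        raise ValueError(f"exhaustive search bounded at {MAX_ORDERS} orders")
    others = [f for i, f in enumerate(ffsets) if i != ref_idx]
    if errors is not None:
        weights = [errors[i] for i in range(len(ffsets)) if i != ref_idx]
    else:
        weights = [None] * len(others)

    def propagate(ref_assigned: FormFactorSet) -> list[FormFactorSet]:
        out = []
        for i, f in enumerate(ffsets):
            if i == ref_idx:
                out.append(ref_assigned)
            else:
                t = continuous_form_factor(ref_assigned, f.q, f0=f0)
                out.append(f.with_signs(np.where(t >= 0, 1, -1)))
        return out

    if n_orders == 1:
        warnings.warn("single order: both signs fit equally; convention nu_1 = -1")
        sv = SignVector((-1,), misfit=0.0, degenerate=True)
        return propagate(reference.with_signs([-1])), sv

    # fix nu_1 = -1 (global-flip convention) and search the remaining orders
    best: tuple[float, np.ndarray] | None = None
    scored: list[tuple[float, np.ndarray]] = []
    for tail in itertools.product((-1, 1), repeat=n_orders - 1):
        signs = np.array((-1,) + tail, dtype=int)
        m = _misfit(reference, signs, others, weights, f0=f0)
        scored.append((m, signs))
        if best is None or m < best[0]:
            best = (m, signs)
    best_misfit, best_signs = best
    # degenerate when another vector (beyond the global flip, already
    # excluded by fixing nu_1) ties with the winner
    ties = [s for m, s in scored
            if m <= best_misfit + 1e-12 * max(1.0, best_misfit)
            and not np.array_equal(s, best_signs)]
    degenerate = len(ties) > 0
    if degenerate:
        warnings.warn("sign search degenerate: multiple vectors tie at minimal misfit")
    sv = SignVector(tuple(int(s) for s in best_signs),
                    misfit=best_misfit, degenerate=degenerate)
    return propagate(reference.with_signs(best_signs)), sv
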