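"""Molecular-mechanics and implicit-solvation energy terms.

These are the ingredients of the end-point binding free energy

    ΔG_bind = ΔE_int + ΔE_vdw + ΔE_eel + ΔG_p^sol + ΔG_np^sol − TΔS

computed without any nonbonded cutoff (end-point convention; cutoffs
belong to the MD engine, not to the post-analysis).  ΔE_int cancels
identically under the single-trajectory protocol and is never computed.

The polar solvation term uses a generalized-Born model with
Hawkins–Cramer–Truhlar pairwise descreening and the Onufriev–Bashford–
Case (OBC) tanh rescaling of the effective radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    COULOMB_CONSTANT,
    DEFAULT_DIELECTRIC_IN,
    DEFAULT_DIELECTRIC_OUT,
    DEFAULT_NP_BETA,
    DEFAULT_NP_GAMMA,
)
from .topology import Topology

_MIN_DISTANCE = 1e-6  # Å; below this two atoms are considered overlapping


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class GBConfig:
    """Generalized-Born settings (OBC-II rescaling by default)."""

    alpha: float = 1.0
    beta: float = 0.8
    gamma: float = 4.85
    dielectric_in: float = DEFAULT_DIELECTRIC_IN
    dielectric_out: float = DEFAULT_DIELECTRIC_OUT
    #: dielectric offset subtracted from intrinsic radii before
    #: descreening; 0 keeps a lone atom's effective radius equal to its
    #: intrinsic radius (see docs/methods.md)
    offset: float = 0.0
    #: inverse Debye length (1/Å) for optional salt screening; 0 = none
    kappa: float = 0.0


@dataclass(frozen=True)
class FrameEnergies:
    """Δ-terms of one trajectory frame, kcal/mol."""

    e_vdw: float
    e_eel: float
    g_polar: float
    g_nonpolar: float
    frame_index: int = 0

    @property
    def enthalpy(self) -> float:
        return self.e_vdw + self.e_eel + self.g_polar + self.g_nonpolar


def lj_coulomb_interaction(top: Topology, frame: np.ndarray,
                           group_a, group_b) -> tuple[float, float]:
    """Intergroup Lennard-Jones and Coulomb energies, kcal/mol.

    Lorentz–Berthelot combination: rmin_ij = rmin_i/2 + rmin_j/2,
    ε_ij = √(ε_i ε_j).  Coulomb uses 332.0637·q_i q_j / r_ij.  No
    cutoff.  The groups must be disjoint.
    """
    a = np.asarray(sorted(group_a), dtype=int)
    b = np.asarray(sorted(group_b), dtype=int)
    if a.size == 0 or b.size == 0:
        return 0.0, 0.0
    if np.intersect1d(a, b).size:
        raise EnergeticsError("groups overlap")
    frame = np.asarray(frame, dtype=float)
    diff = frame[a][:, None, :] - frame[b][None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    if r.min() < _MIN_DISTANCE:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise EnergeticsError(
            f"atoms {a[i]} and {b[j]} overlap (r < {_MIN_DISTANCE} Å)"
        )
    rmh = top.array("lj_rmin_half")
    eps = top.array("lj_epsilon")
    q = top.charges
    rmin_ij = rmh[a][:, None] + rmh[b][None, :]
    eps_ij = np.sqrt(eps[a][:, None] * eps[b][None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = np.where(eps_ij > 0, (rmin_ij / r) ** 6, 0.0)
    e_vdw = float(np.sum(eps_ij * (x6 * x6 - 2.0 * x6)))
    e_eel = float(COULOMB_CONSTANT * np.sum(q[a][:, None] * q[b][None, :] / r))
    return e_vdw, e_eel


def gb_effective_radii(radii: np.ndarray, screens: np.ndarray,
                       coords: np.ndarray,
                       config: GBConfig = GBConfig()) -> np.ndarray:
    """Effective Born radii via HCT descreening + OBC tanh rescaling."""
    radii = np.asarray(radii, dtype=float)
    screens = np.asarray(screens, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = radii.size
    rho = radii - config.offset
    if np.any(rho <= 0):
        bad = int(np.argmin(rho))
        raise EnergeticsError(
            f"atom {bad}: offset radius non-positive ({rho[bad]:.3f} Å)"
        )
    if n == 1:
        return rho.copy()

    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(r, np.inf)
    sj = (screens * rho)[None, :]              # scaled radius of neighbor j
    rho_i = rho[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        u = 1.0 / (r + sj)
        l = 1.0 / np.maximum(np.abs(r - sj), rho_i)
        u2, l2 = u * u, l * l
        term = (
            l - u
            + 0.25 * r * (u2 - l2)
            + (0.5 / r) * np.log(u / l)
            + 0.25 * (sj ** 2 / r) * (l2 - u2)
        )
        # atom i fully inside neighbor j's descreening sphere
        engulfed = rho_i < (sj - r)
        term = term + np.where(engulfed, 2.0 * (1.0 / rho_i - l), 0.0)
        # neighbor fully inside atom i: no descreening
        term = np.where(rho_i >= r + sj, 0.0, term)
        term = np.where(np.isfinite(term), term, 0.0)

    psi = 0.5 * rho * term.sum(axis=1)
    tanh_arg = config.alpha * psi - config.beta * psi ** 2 + config.gamma * psi ** 3
    inv_reff = 1.0 / rho - np.tanh(tanh_arg) / radii
    if np.any(inv_reff <= 0):
        bad = int(np.argmin(inv_reff))
        raise EnergeticsError(f"atom {bad}: non-positive effective Born radius")
    return 1.0 / inv_reff


def gb_polar_energy(top: Topology, frame: np.ndarray, group,
                    config: GBConfig = GBConfig()) -> float:
    """Polar solvation free energy of ``group`` alone, kcal/mol.

    E = −½·k_e·(1/ε_in − 1/ε_out)·Σ_ij q_i q_j / f_GB with
    f_GB = √(r² + R_i R_j·exp(−r²/(4 R_i R_j))); self terms (i = j,
    f_GB = R_i) included.  Descreening sees only the group's atoms.
    """
    idx = np.asarray(sorted(group), dtype=int)
    if idx.size == 0:
        return 0.0
    q = top.charges[idx]
    if not np.any(q):
        return 0.0
    coords = np.asarray(frame, dtype=float)[idx]
    radii = top.array("born_radius")[idx]
    screens = top.array("gb_screen")[idx]
    reff = gb_effective_radii(radii, screens, coords, config)

    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff ** 2).sum(axis=2)
    rirj = reff[:, None] * reff[None, :]
    fgb = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    qq = q[:, None] * q[None, :]
    tau = 1.0 / config.dielectric_in - 1.0 / config.dielectric_out
    if config.kappa > 0.0:
        tau = (1.0 / config.dielectric_in
               - np.exp(-config.kappa * fgb) / config.dielectric_out)
    return float(-0.5 * COULOMB_CONSTANT * np.sum(tau * qq / fgb))


def nonpolar_energy(sasa_total: float, gamma: float = DEFAULT_NP_GAMMA,
                    beta: float = DEFAULT_NP_BETA) -> float:
    """Nonpolar solvation term γ·SASA + β, kcal/mol (SASA in Å²)."""
    if sasa_total < 0:
        raise EnergeticsError("negative SASA")
    return gamma * sasa_total + beta
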