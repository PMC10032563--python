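"""Entropy estimators for the end-point binding free energy.

Two estimators are provided, matching the two routes compared in the
study this package supports:

* **WSAS** — conformational entropy as a weighted sum of per-atom
  solvent-accessible surface areas, evaluated for complex, receptor
  and ligand from the same (single-trajectory) frames.
* **Interaction entropy** — from the exponential average of the
  protein–ligand interaction-energy fluctuations,
  TΔS = −k_B T·ln⟨exp(β ΔE_int)⟩, computed with log-sum-exp so large
  fluctuations cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE
from .sasa import SasaConfig, sasa
from .topology import Topology, Trajectory


class EntropyError(ValueError):
    pass


@dataclass(frozen=True)
class EntropyTerm:
    """TΔS in kcal/mol, tagged with the estimator that produced it."""

    t_delta_s: float
    method: str        # "wsas" | "interaction"
    n_frames: int

    def __post_init__(self):
        if not np.isfinite(self.t_delta_s):
            raise EntropyError("non-finite entropy term")


#: Nominal per-element WSAS weights, kcal/mol/Å².  The fitted values of
#: the published WSAS parameterization are per atom type and are not
#: redistributable here; these order-of-magnitude defaults exist so the
#: pipeline runs out of the box, and should be overridden for any
#: quantitative use (all tests supply explicit weights).
DEFAULT_WSAS_WEIGHTS = {
    "H": 0.0, "C": 0.0072, "N": 0.0060, "O": 0.0060, "S": 0.0094,
    "P": 0.0060,
}


def wsas_entropy(top: Topology, traj: Trajectory, group=None,
                 weights: dict[str, float] | None = None,
                 temperature: float = DEFAULT_TEMPERATURE,
                 c0: float = 0.0,
                 sasa_config: SasaConfig = SasaConfig()) -> EntropyTerm:
    """Weighted-SASA binding entropy, single-trajectory protocol.

    Per frame, TS(X) = c0 + Σ_atoms w(element)·area_atom for X in
    {complex, receptor, ligand}, with receptor and ligand coordinates
    taken from the complex frame.  TΔS is the frame average of
    TS_complex − TS_receptor − TS_ligand.  ``group`` defaults to the
    topology's ligand set; the receptor is the topology's receptor set.
    """
    weights = DEFAULT_WSAS_WEIGHTS if weights is None else weights
    ligand = sorted(top.ligand_atoms if group is None else set(group))
    receptor = sorted(set(range(top.n_atoms)) - set(ligand))
    for i in ligand + receptor:
        el = top.atoms[i].element
        if el not in weights:
            raise EntropyError(f"no WSAS weight for element {el!r}")

    def ts(frame, atoms):
        if not atoms:
            return c0
        res = sasa(top, frame, atoms, sasa_config)
        w = np.array([weights[top.atoms[i].element] for i in res.atom_indices])
        return c0 + float(np.dot(w, res.per_atom_area))

    per_frame = []
    everything = ligand + receptor
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        per_frame.append(
            ts(frame, everything) - ts(frame, receptor) - ts(frame, ligand)
        )
    return EntropyTerm(
        t_delta_s=float(np.mean(per_frame)),
        method="wsas",
        n_frames=traj.n_frames,
    )


def interaction_entropy(e_int_series, temperature: float = DEFAULT_TEMPERATURE
                        ) -> EntropyTerm:
    """Interaction entropy from a per-frame interaction-energy series.

    TΔS = −k_B T · ln⟨exp(β(E_t − ⟨E⟩))⟩ ≤ 0; invariant under adding a
    constant to the series.
    """
    series = np.asarray(e_int_series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise EntropyError("interaction entropy needs at least 2 frames")
    kbt = BOLTZMANN_KCAL * temperature
    de = series - series.mean()
    log_mean_exp = logsumexp(de / kbt) - np.log(series.size)
    return EntropyTerm(
        t_delta_s=float(-kbt * log_mean_exp),
        method="interaction",
        n_frames=int(series.size),
    )
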