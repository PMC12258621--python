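"""Free-energy landscapes from transition rate constants.

Apparent equilibrium constants between observed states are ratios of
forward and reverse rates, K_ij = k_ij / k_ji, and free-energy
differences follow dG_ij = -kBT ln K_ij.  Energies are reported in kBT
units throughout.  A piecewise landscape over
Cfree -> Cbound -> I -> O places wells by cumulative dG along the
capture pathway at a stated RNP concentration (the Cfree -> Cbound step
contributes -ln(kon_init [RNP] / koff_init) = -ln([RNP]/Kd_init) by
mass action) and barriers at -ln(k_forward) + C above a common
reference, with C an arbitrary offset (default 7 kBT) since absolute
barrier heights are not determined by rate ratios alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import RateSet, TwoStepModel

DEFAULT_BARRIER_OFFSET_KBT = 7.0


def equilibrium_constants(rates: RateSet) -> dict:
    """K_ij = k_ij / k_ji for every pair with both rates present.

    Pairs whose reverse rate is zero are flagged with K = inf.
    """
    out: dict = {}
    labels = [k for k, t in rates.occupancy.items() if t > 0]
    for i in labels:
        for j in labels:
            if i >= j:
                continue
            try:
                kij, kji = rates.rate(i, j), rates.rate(j, i)
            except ValueError:
                continue
            if kij == 0 and kji == 0:
                continue
            if kji == 0:
                out[(i, j)] = float("inf")
                out[(j, i)] = 0.0
                continue
            out[(i, j)] = kij / kji
            out[(j, i)] = kji / kij
    return out


def free_energy(K) -> float:
    """dG = -ln K, in kBT units."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("equilibrium constant must be positive")
    out = -np.log(K)
    return float(out) if out.ndim == 0 else out


@dataclass
class EnergyLandscape:
    """Piecewise landscape over (Cfree, Cbound, I, O) at fixed [RNP].

    ``wells`` maps state -> (coordinate_bp, energy_kBT) with Cfree as
    the zero-energy reference; ``barriers`` maps transition -> energy.
    """

    rnp_conc: float  # nM
    wells: dict
    barriers: dict
    barrier_offset: float = DEFAULT_BARRIER_OFFSET_KBT
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("well", name, coord, e) for name, (coord, e) in self.wells.items()
        ] + [
            ("barrier", name, coord, e)
            for name, (coord, e) in self.barriers.items()
        ]
        return pd.DataFrame(
            rows, columns=["kind", "name", "coordinate_bp", "energy_kBT"]
        )


def build_landscape(
    two_step: TwoStepModel,
    k_ic: float,
    k_io: float,
    k_oi: float,
    rnp_conc: float = 100.0,
    barrier_offset: float = DEFAULT_BARRIER_OFFSET_KBT,
    coords: dict | None = None,
) -> EnergyLandscape:
    """Construct the capture free-energy landscape at ``rnp_conc``.

    Wells accumulate dG along Cfree -> Cbound -> I -> O:

    * Cfree -> Cbound: -ln(kon_init [RNP] / koff_init)
    * Cbound -> I:     -ln(kopen / k_ic)
    * I -> O:          -ln(k_io / k_oi)

    Each forward barrier sits at (energy of the preceding well)
    - ln(k_forward) + C.  Well coordinates on the unwinding axis default
    to Cfree -5 bp (illustrative), Cbound 0, I 10, O 20 bp.
    """
    missing = [n for n, v in
               [("k_ic", k_ic), ("k_io", k_io), ("k_oi", k_oi)] if v is None or v <= 0]
    if missing:
        raise ValueError(f"missing or non-positive rates: {missing}")
    if rnp_conc <= 0:
        raise ValueError("rnp_conc must be positive")
    coords = coords or {"Cfree": -5.0, "Cbound": 0.0, "I": 10.0, "O": 20.0}
    k_bind = two_step.kon_init * rnp_conc  # pseudo-first-order, per-s
    dg_bind = -np.log(k_bind / two_step.koff_init)
    dg_open = -np.log(two_step.kopen / k_ic)
    dg_prop = -np.log(k_io / k_oi)
    e_cfree = 0.0
    e_cbound = e_cfree + dg_bind
    e_i = e_cbound + dg_open
    e_o = e_i + dg_prop
    wells = {
        "Cfree": (coords["Cfree"], e_cfree),
        "Cbound": (coords["Cbound"], float(e_cbound)),
        "I": (coords["I"], float(e_i)),
        "O": (coords["O"], float(e_o)),
    }
    c = barrier_offset

    def barrier(coord_lo, coord_hi, e_well, k_fwd):
        return ((coord_lo + coord_hi) / 2.0, float(e_well - np.log(k_fwd) + c))

    barriers = {
        "Cfree->Cbound": barrier(coords["Cfree"], coords["Cbound"], e_cfree, k_bind),
        "Cbound->I": barrier(coords["Cbound"], coords["I"], e_cbound, two_step.kopen),
        "I->O": barrier(coords["I"], coords["O"], e_i, k_io),
    }
    return EnergyLandscape(
        rnp_conc=rnp_conc,
        wells=wells,
        barriers=barriers,
        barrier_offset=barrier_offset,
        metadata={
            "kon_init_per_nM_s": two_step.kon_init,
            "kd_init_nM": two_step.kd_init,
        },
    )


def delta_delta_g(fold_forward: float, fold_reverse: float) -> float:
    """Between-enzyme difference in dG of one step from rate fold-changes.

    If enzyme B's forward rate is ``fold_forward`` times slower and its
    reverse rate ``fold_reverse`` times faster than enzyme A's, the
    equilibrium constant ratio is K_A / K_B = fold_forward * fold_reverse
    and the step's dG is higher for B by ln(fold_forward * fold_reverse)
    kBT.
    """
    if fold_forward <= 0 or fold_reverse <= 0:
        raise ValueError("fold changes must be positive")
    return float(np.log(fold_forward * fold_reverse))
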