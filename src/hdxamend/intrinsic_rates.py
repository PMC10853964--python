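"""Intrinsic (random-coil) backbone amide exchange rates.

Computes sequence- and condition-dependent intrinsic exchange rate constants
k_int for the two exchange directions:

* ``H_to_D`` — protium protein labelling in D2O (the labelling phase);
* ``D_to_H`` — deuterated amides losing label into protiated solvent
  (the back-exchange phase during quench/digestion/chromatography).

The model is the standard poly-DL-alanine reference plus additive log10
side-chain correction factors for a residue's own side chain ("L") and the
preceding residue's side chain ("R"), with acid-, base- and water-catalysed
terms each scaled to temperature by an Arrhenius activation energy:

    k_int,i = Fa * kA * 10**(lamA_i + rhoA_{i-1}) * [L+]
            + 10**(lamB_i + rhoB_{i-1}) * (Fb * kB * [OL-] + Fw * kW)

where L is the lyonium species of the solvent (D3O+/OD- in D2O) and
F* = exp(-Ea/R * (1/T - 1/293)).  Titratable groups (Asp, Glu, His,
C-terminal carboxyl) are blended between their protonated and deprotonated
factors on the linear scale using Henderson-Hasselbalch fractions at the
working pL.  Rates are returned in s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import SequenceError, AMINO_ACIDS

R_GAS_KCAL = 1.987204e-3  # kcal / (mol K)
T_REF = 293.0  # K; reference temperature of the tabulated rates

#: poly-DL-alanine reference rates, log10, at 293 K (acid/base per M per min,
#: water per min), and the solvent ion product at 293 K, per direction.
REFERENCE_RATES = {
    "H_to_D": {"log_ka": 1.62, "log_kb": 10.18, "log_kw": -1.5, "pkw": 15.05},
    "D_to_H": {"log_ka": 1.40, "log_kb": 9.87, "log_kw": -1.6, "pkw": 14.17},
}

#: activation energies, kcal/mol
EA = {"acid": 14.0, "base": 17.0, "water": 19.0}
#: van't Hoff enthalpy for the solvent ion product, kcal/mol
DH_ION = 13.35

#: side-chain / terminal pKa values used for titration blending,
#: per solvent (D2O values shifted ~+0.5 from H2O)
PKA = {
    "H_to_D": {"D": 4.48, "E": 4.93, "H": 7.42, "CT": 4.16},
    "D_to_H": {"D": 3.98, "E": 4.43, "H": 6.92, "CT": 3.66},
}

DIRECTIONS = ("H_to_D", "D_to_H")


@dataclass(frozen=True)
class ExchangeConditions:
    """Solution conditions under which intrinsic rates are evaluated.

    ``ph_read`` is the uncorrected glass-electrode reading; when the solvent
    is D2O (direction ``H_to_D``) the working pD is ``ph_read + pd_offset``.
    """

    ph_read: float
    temperature: float
    d2o_fraction: float = 1.0
    direction: str = "H_to_D"
    pd_offset: float = 0.4

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction must be in [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def pl(self) -> float:
        """Working pL (pD in D2O, pH in H2O)."""
        if self.direction == "H_to_D":
            return self.ph_read + self.pd_offset
        return self.ph_read

    def flipped(self) -> "ExchangeConditions":
        other = "D_to_H" if self.direction == "H_to_D" else "H_to_D"
        return replace(self, direction=other)


@dataclass
class RateSet:
    """Per-residue intrinsic rates (s^-1) aligned to a sequence.

    ``mask`` is True at non-exchanging positions (position 1, prolines,
    optionally position 2); ``k`` is NaN there.  The originating sequence
    and conditions are retained so the set can be recomputed for the other
    exchange direction.
    """

    k: np.ndarray
    mask: np.ndarray
    sequence: str
    conditions: ExchangeConditions

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.k.shape != self.mask.shape:
            raise ValueError("k and mask shapes differ")
        unmasked = self.k[~self.mask]
        if np.any(~np.isfinite(unmasked)) or np.any(unmasked <= 0):
            raise ValueError("unmasked intrinsic rates must be finite and > 0")

    def __len__(self) -> int:
        return self.k.size


# ---------------------------------------------------------------------------
# Correction-factor tables
# ---------------------------------------------------------------------------

_TABLE_CACHE: dict[str, dict[tuple[str, str, str], float]] = {}


def load_factor_table(direction: str, path: str | Path | None = None) -> dict:
    """Load the log10 side-chain correction factors for one direction.

    Returns ``{(residue_code, side, term): value}``.  ``path`` overrides the
    vendored data file (same CSV schema: residue, side, term, value,
    direction with direction in {HD, DH, both}).
    """
    key = f"{direction}:{path}"
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    if path is None:
        src = resources.files("hdxamend.data").joinpath("kint_factors.csv")
        df = pd.read_csv(src, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    want = {"H_to_D": "HD", "D_to_H": "DH"}[direction]
    df = df[(df["direction"] == "both") | (df["direction"] == want)]
    table = {
        (str(r.residue), str(r.side), str(r.term)): float(r.value)
        for r in df.itertuples()
    }
    _TABLE_CACHE[key] = table
    return table


def _henderson(pl: float, pka: float) -> float:
    """Fraction protonated at the working pL."""
    return 1.0 / (1.0 + 10.0 ** (pl - pka))


def _blend(table: dict, prot_code: str, deprot_code: str, side: str, term: str,
           frac_prot: float) -> float:
    """Linear-scale blend of protonated/deprotonated log10 factors."""
    a = table.get((prot_code, side, term), 0.0)
    b = table.get((deprot_code, side, term), 0.0)
    return float(np.log10(frac_prot * 10.0**a + (1.0 - frac_prot) * 10.0**b))


def _factor(table: dict, aa: str, side: str, term: str, pl: float, pka: dict) -> float:
    """log10 factor contributed by one side chain, with titration blending."""
    if aa == "D":
        return _blend(table, "D0", "D", side, term, _henderson(pl, pka["D"]))
    if aa == "E":
        return _blend(table, "E0", "E", side, term, _henderson(pl, pka["E"]))
    if aa == "H":
        return _blend(table, "H+", "H0", side, term, _henderson(pl, pka["H"]))
    return table.get((aa, side, term), 0.0)


# ---------------------------------------------------------------------------
# Rate computation
# ---------------------------------------------------------------------------


def compute_kint(
    sequence: str,
    conditions: ExchangeConditions,
    mask_second: bool = False,
    table_path: str | Path | None = None,
) -> RateSet:
    """Per-residue intrinsic exchange rates (s^-1) for ``sequence``.

    Position 1 is always masked (the N-terminal residue has a free amine,
    not a backbone amide); prolines are masked; position 2 is additionally
    masked when ``mask_second`` is set.  The N-terminal ammonium and the
    C-terminal carboxyl contribute their tabulated neighbour factors.
    """
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise SequenceError(f"unknown residue letters {sorted(bad)} in sequence")
    if not 270.0 <= conditions.temperature <= 320.0:
        warnings.warn(
            f"temperature {conditions.temperature} K outside the 270-320 K "
            "calibration range; rates are an Arrhenius extrapolation",
            stacklevel=2,
        )
    table = load_factor_table(conditions.direction, table_path)
    ref = REFERENCE_RATES[conditions.direction]
    pka = PKA[conditions.direction]
    pl = conditions.pl
    T = conditions.temperature

    fa = np.exp(-EA["acid"] / R_GAS_KCAL * (1.0 / T - 1.0 / T_REF))
    fb = np.exp(-EA["base"] / R_GAS_KCAL * (1.0 / T - 1.0 / T_REF))
    fw = np.exp(-EA["water"] / R_GAS_KCAL * (1.0 / T - 1.0 / T_REF))
    # ion product rises with temperature (van't Hoff)
    pkw = ref["pkw"] + (DH_ION / (R_GAS_KCAL * np.log(10.0))) * (1.0 / T - 1.0 / T_REF)

    ka = 10.0 ** ref["log_ka"]
    kb = 10.0 ** ref["log_kb"]
    kw = 10.0 ** ref["log_kw"]
    conc_l = 10.0 ** (-pl)
    conc_ol = 10.0 ** (pl - pkw)

    n = len(sequence)
    k = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    mask[0] = True
    if mask_second and n > 1:
        mask[1] = True
    last_pl_frac = _henderson(pl, pka["CT"])
    for i in range(n):
        aa = sequence[i]
        if aa == "P":
            mask[i] = True
        if mask[i]:
            continue
        left = sequence[i - 1]
        lam_a = _factor(table, aa, "L", "acid", pl, pka)
        lam_b = _factor(table, aa, "L", "base", pl, pka)
        rho_a = _factor(table, left, "R", "acid", pl, pka)
        rho_b = _factor(table, left, "R", "base", pl, pka)
        if i == 1:  # amide next to the N-terminal ammonium
            rho_a += table.get(("NT", "R", "acid"), 0.0)
            rho_b += table.get(("NT", "R", "base"), 0.0)
        if i == n - 1:  # the last residue's amide feels the C-terminal carboxyl
            lam_a += _blend(table, "CT0", "CT", "L", "acid", last_pl_frac)
            lam_b += _blend(table, "CT0", "CT", "L", "base", last_pl_frac)
        k_min = (
            fa * ka * 10.0 ** (lam_a + rho_a) * conc_l
            + 10.0 ** (lam_b + rho_b) * (fb * kb * conc_ol + fw * kw)
        )
        k[i] = k_min / 60.0  # per-minute tables -> s^-1
    return RateSet(k, mask, sequence, conditions)


def scale_rates_for_direction(rates: RateSet) -> RateSet:
    """Recompute a RateSet with the other direction's reference/correction
    tables (not a scalar rescaling: factors and ion products both change)."""
    mask_second = bool(rates.mask[1]) if len(rates) > 1 and rates.sequence[1] != "P" else False
    return compute_kint(rates.sequence, rates.conditions.flipped(), mask_second=mask_second)
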