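"""Scattering-length densities, contrasts and match points for proteins.

Neutron contrast-variation experiments on two-component protein complexes
hinge on four quantities that can all be computed from sequence alone:

* the coherent scattering length of each component, as a function of the
  biosynthetic deuteration level of its carbon-bound (non-labile) hydrogens
  and of the solvent D2O fraction seen by its solvent-exchangeable (labile)
  hydrogens,
* the scattering-length density (SLD) rho = sum(b) / volume,
* the contrast delta_rho = rho - rho_solvent, and
* the contrast match point (CMP): the solvent D2O fraction at which the
  volume-weighted mean contrast of a complex vanishes.

The implementation follows the standard MULCh-style bookkeeping: a fixed
labile fraction (default 95%) of N/O/S-bound hydrogens equilibrates with the
solvent, while carbon-bound hydrogens carry the expression-level deuteration.

Embedded tables
---------------
Coherent scattering lengths are the Sears (1992, Neutron News 3:26) values in
fm.  Per-residue volumes are the Zamyatnin (1972) consensus residue volumes
(A^3).  Residue formulas use the pH ~7 ionisation convention (Asp/Glu
deprotonated, Lys/Arg protonated, His neutral), which also fixes the
exchangeable-hydrogen counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Composition",
    "LabellingState",
    "SLDValue",
    "MatchPointResult",
    "composition_from_sequence",
    "solvent_sld",
    "protein_sld",
    "match_point",
    "infer_deuteration",
    "mw_from_forward_scattering",
    "theoretical_i0_per_c",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23

# Sears (1992) bound coherent scattering lengths, in fm (1 fm = 1e-5 A).
SCATTERING_LENGTH_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
    "P": 5.13,
}

_FM_TO_A = 1.0e-5  # fm -> Angstrom

# Water molecular volumes at 20 degC (A^3), from mass / (density * N_A):
# H2O: 18.0153 g/mol, 0.99821 g/cm^3 ; D2O: 20.0276 g/mol, 1.1050 g/cm^3.
V_H2O = 18.0153 / (0.99821 * 0.602214076)
V_D2O = 20.0276 / (1.1050 * 0.602214076)

# In-chain residue formulas (amino acid minus peptide-bond water), pH ~7
# ionisation.  H counts are split into labile (N/O/S-bound, incl. backbone
# amide) and non-labile (carbon-bound).
# residue: (C, N, O, S, H_labile, H_nonlabile, volume A^3, mass Da)
_RESIDUES: dict[str, tuple[int, int, int, int, int, int, float]] = {
    #     C   N  O  S  Hlab Hnon  V
    "G": (2, 1, 1, 0, 1, 2, 60.1),
    "A": (3, 1, 1, 0, 1, 4, 88.6),
    "S": (3, 1, 2, 0, 2, 4, 89.0),
    "C": (3, 1, 1, 1, 2, 4, 108.5),
    "D": (4, 1, 3, 0, 1, 3, 111.1),  # carboxylate (charge -1)
    "T": (4, 1, 2, 0, 2, 6, 116.1),
    "N": (4, 2, 2, 0, 3, 3, 114.1),
    "P": (5, 1, 1, 0, 0, 7, 112.7),
    "E": (5, 1, 3, 0, 1, 5, 138.4),  # carboxylate (charge -1)
    "V": (5, 1, 1, 0, 1, 8, 140.0),
    "Q": (5, 2, 2, 0, 3, 5, 143.8),
    "H": (6, 3, 1, 0, 2, 5, 153.2),  # neutral imidazole
    "M": (5, 1, 1, 1, 1, 8, 162.9),
    "I": (6, 1, 1, 0, 1, 10, 166.7),
    "L": (6, 1, 1, 0, 1, 10, 166.7),
    "K": (6, 2, 1, 0, 4, 9, 168.6),  # ammonium (charge +1)
    "R": (6, 4, 1, 0, 6, 7, 173.4),  # guanidinium (charge +1)
    "F": (9, 1, 1, 0, 1, 8, 189.9),
    "Y": (9, 1, 2, 0, 2, 7, 193.6),
    "W": (11, 2, 1, 0, 2, 8, 227.8),
}

_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

# AMP adduct (adenosine monophosphate, phosphodiester-linked): C10H12N5O6P,
# 2 labile H (adenine NH2), volume ~ 314 A^3 (nucleotide partial volume).
_AMP_ADDUCT = {"C": 10, "N": 5, "O": 6, "P": 1}
_AMP_H_LABILE = 2
_AMP_H_NONLABILE = 10
_AMP_VOLUME = 314.0


@dataclass(frozen=True)
class Composition:
    """Elemental composition, hydrogen partition and dry volume of a particle.

    ``atom_counts`` includes all hydrogens under key ``"H"``;
    ``n_labile_H + n_nonlabile_H`` must equal ``atom_counts["H"]``.
    Volume in A^3, mass in Da.
    """

    atom_counts: Mapping[str, float]
    n_labile_H: float
    n_nonlabile_H: float
    volume: float
    mass: float
    name: str = ""

    def __post_init__(self) -> None:
        counts = dict(self.atom_counts)
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative atom count")
        h = counts.get("H", 0.0)
        if not np.isclose(self.n_labile_H + self.n_nonlabile_H, h):
            raise ValueError(
                f"labile ({self.n_labile_H}) + non-labile ({self.n_nonlabile_H}) "
                f"hydrogens != total H count ({h})"
            )
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    def __add__(self, other: "Composition") -> "Composition":
        counts: dict[str, float] = dict(self.atom_counts)
        for k, v in other.atom_counts.items():
            counts[k] = counts.get(k, 0.0) + v
        return Composition(
            atom_counts=counts,
            n_labile_H=self.n_labile_H + other.n_labile_H,
            n_nonlabile_H=self.n_nonlabile_H + other.n_nonlabile_H,
            volume=self.volume + other.volume,
            mass=self.mass + other.mass,
            name=self.name,
        )

    def scaled(self, n: float) -> "Composition":
        return Composition(
            atom_counts={k: n * v for k, v in self.atom_counts.items()},
            n_labile_H=n * self.n_labile_H,
            n_nonlabile_H=n * self.n_nonlabile_H,
            volume=n * self.volume,
            mass=n * self.mass,
            name=self.name,
        )


@dataclass(frozen=True)
class LabellingState:
    """Deuteration state of one component in a given solvent.

    f_deut: fraction of non-labile (carbon-bound) H replaced by D.
    labile_exchange: fraction of labile H that equilibrates with the solvent.
    f_D2O: solvent D2O volume fraction.
    """

    f_deut: float = 0.0
    labile_exchange: float = 0.95
    f_D2O: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("f_deut", "labile_exchange", "f_D2O"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr}={v} outside [0, 1]")


@dataclass(frozen=True)
class SLDValue:
    """Scattering-length density and contrast vs the solvent (A^-2)."""

    rho: float
    delta_rho: float


@dataclass(frozen=True)
class MatchPointResult:
    """Solved match point (D2O volume fraction) with validity flags."""

    f_D2O: float
    in_range: bool
    degenerate: bool = False


def composition_from_sequence(
    seq: str, name: str = "", add_termini: bool = True, n_amp: int = 0
) -> Composition:
    """Summed composition of a polypeptide from its one-letter sequence.

    Residue formulas are in-chain (condensed); ``add_termini`` adds one water
    per chain for the N/C-terminal groups (both extra hydrogens labile).
    ``n_amp`` optionally appends AMP adducts (phosphodiester-linked, e.g. a
    Thr-AMP post-translational modification).
    """
    seq = "".join(seq.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {"C": 0.0, "N": 0.0, "O": 0.0, "S": 0.0, "P": 0.0}
    h_lab = 0.0
    h_non = 0.0
    volume = 0.0
    for ch in seq:
        if ch not in _RESIDUES:
            raise ValueError(f"unknown residue letter {ch!r} in sequence")
        c, n, o, s, hl, hn, v = _RESIDUES[ch]
        counts["C"] += c
        counts["N"] += n
        counts["O"] += o
        counts["S"] += s
        h_lab += hl
        h_non += hn
        volume += v
    if add_termini:
        counts["O"] += 1
        h_lab += 2  # terminal NH + OH hydrogens, both exchangeable
    if n_amp:
        for k, v in _AMP_ADDUCT.items():
            counts[k] += n_amp * v
        h_lab += n_amp * _AMP_H_LABILE
        h_non += n_amp * _AMP_H_NONLABILE
        volume += n_amp * _AMP_VOLUME
    counts["H"] = h_lab + h_non
    counts = {k: v for k, v in counts.items() if v > 0}
    mass = sum(_ATOMIC_MASS[el] * n for el, n in counts.items())
    return Composition(counts, h_lab, h_non, volume, mass, name=name or seq[:8])


def solvent_sld(f_D2O: float) -> float:
    """Solvent SLD (A^-2) at 20 degC by linear H2O/D2O interpolation.

    Buffer solutes are ignored (their effect on rho is small compared with
    the H2O/D2O span and the paper-style workflow delegates it to the
    contrast calculator's solvent model).
    """
    if not (0.0 <= f_D2O <= 1.0):
        raise ValueError(f"f_D2O={f_D2O} outside [0, 1]")
    b_h2o = (2 * SCATTERING_LENGTH_FM["H"] + SCATTERING_LENGTH_FM["O"]) * _FM_TO_A
    b_d2o = (2 * SCATTERING_LENGTH_FM["D"] + SCATTERING_LENGTH_FM["O"]) * _FM_TO_A
    rho_h = b_h2o / V_H2O
    rho_d = b_d2o / V_D2O
    return (1.0 - f_D2O) * rho_h + f_D2O * rho_d


def _total_b(comp: Composition, lab: LabellingState) -> float:
    """Total coherent scattering length (A) of a composition under labelling."""
    b_h = SCATTERING_LENGTH_FM["H"]
    b_d = SCATTERING_LENGTH_FM["D"]
    total_fm = 0.0
    for el, n in comp.atom_counts.items():
        if el == "H":
            continue
        try:
            total_fm += SCATTERING_LENGTH_FM[el] * n
        except KeyError:
            raise ValueError(f"no scattering length for element {el!r}") from None
    f_lab_d = lab.labile_exchange * lab.f_D2O
    total_fm += comp.n_nonlabile_H * ((1 - lab.f_deut) * b_h + lab.f_deut * b_d)
    total_fm += comp.n_labile_H * ((1 - f_lab_d) * b_h + f_lab_d * b_d)
    return total_fm * _FM_TO_A


def protein_sld(comp: Composition, lab: LabellingState) -> SLDValue:
    """SLD and contrast of a protein component under a labelling state."""
    if comp.volume <= 0:
        raise ValueError("zero volume")
    rho = _total_b(comp, lab) / comp.volume
    return SLDValue(rho=rho, delta_rho=rho - solvent_sld(lab.f_D2O))


def _excess_b_affine(
    comps: Sequence[tuple[Composition, float]],
    stoichiometry: Sequence[float] | None,
    labile_exchange: float,
) -> tuple[float, float]:
    """Coefficients (a0, a1) of sum_i n_i (B_i(f) - rho_s(f) V_i) = a0 + a1*f."""
    if not comps:
        raise ValueError("need at least one component")
    n = list(stoichiometry) if stoichiometry is not None else [1.0] * len(comps)
    if len(n) != len(comps):
        raise ValueError("stoichiometry length mismatch")
    a0 = 0.0
    a1 = 0.0
    rho_s0 = solvent_sld(0.0)
    rho_s1 = solvent_sld(1.0)
    b_hd = (SCATTERING_LENGTH_FM["D"] - SCATTERING_LENGTH_FM["H"]) * _FM_TO_A
    for (comp, f_deut), ni in zip(comps, n):
        b0 = _total_b(comp, LabellingState(f_deut, labile_exchange, 0.0))
        a0 += ni * (b0 - rho_s0 * comp.volume)
        a1 += ni * (comp.n_labile_H * labile_exchange * b_hd - (rho_s1 - rho_s0) * comp.volume)
    return a0, a1


def match_point(
    comps: Sequence[tuple[Composition, float]],
    stoichiometry: Sequence[float] | None = None,
    labile_exchange: float = 0.95,
) -> MatchPointResult:
    """Contrast match point of a (multi-component) particle.

    Solves the affine equation sum_i n_i * delta_rho_i(f) * V_i = 0 for the
    solvent D2O fraction f.  A solution outside [0, 1] is returned with
    ``in_range=False``; a vanishing slope yields ``degenerate=True``.
    """
    a0, a1 = _excess_b_affine(comps, stoichiometry, labile_exchange)
    scale = abs(a0) + abs(a1)
    if scale == 0 or abs(a1) < 1e-14 * scale:
        return MatchPointResult(f_D2O=float("nan"), in_range=False, degenerate=True)
    f = -a0 / a1
    return MatchPointResult(f_D2O=f, in_range=(0.0 <= f <= 1.0))


def infer_deuteration(
    hydrogenated_comp: Composition,
    deuterated_comp: Composition,
    experimental_cmp: float,
    stoichiometry: Sequence[float] | None = None,
    labile_exchange: float = 0.95,
) -> float:
    """Non-labile deuteration fraction of the labelled component from a CMP.

    Inverts :func:`match_point` over ``f_deut`` of the deuterated component:
    at the experimental match point the complex's total excess scattering
    length is zero, and that equation is affine in ``f_deut``.
    Raises ``ValueError`` (carrying the unconstrained root) if no root lies
    in [0, 1].
    """
    if not (0.0 < experimental_cmp < 1.0):
        raise ValueError("experimental CMP must lie strictly inside (0, 1)")
    n = list(stoichiometry) if stoichiometry is not None else [1.0, 1.0]
    if len(n) != 2:
        raise ValueError("stoichiometry must give counts for (hydrogenated, deuterated)")
    f = experimental_cmp
    rho_s = solvent_sld(f)
    lab_h = LabellingState(0.0, labile_exchange, f)
    # hydrogenated part: fixed
    const = n[0] * (_total_b(hydrogenated_comp, lab_h) - rho_s * hydrogenated_comp.volume)
    # deuterated part: affine in f_deut
    b_at0 = _total_b(deuterated_comp, LabellingState(0.0, labile_exchange, f))
    b_hd = (SCATTERING_LENGTH_FM["D"] - SCATTERING_LENGTH_FM["H"]) * _FM_TO_A
    slope = n[1] * deuterated_comp.n_nonlabile_H * b_hd
    const += n[1] * (b_at0 - rho_s * deuterated_comp.volume)
    if abs(slope) < 1e-300:
        raise ValueError("deuterated component has no non-labile hydrogens")
    f_deut = -const / slope
    if not (0.0 <= f_deut <= 1.0):
        raise ValueError(f"inferred deuteration {f_deut:.4f} outside [0, 1]")
    return f_deut


def theoretical_i0_per_c(
    comps: Sequence[tuple[Composition, float]],
    f_D2O: float,
    stoichiometry: Sequence[float] | None = None,
    labile_exchange: float = 0.95,
) -> float:
    """Theoretical forward scattering per mass concentration, cm^2 g^-1.

    I(0)/c = M * (delta_rho_match * vbar)^2 / N_A for a particle of molar
    mass M, mass-average contrast delta_rho (cm^-2) and partial specific
    volume vbar (cm^3/g).  Multiply by 1e-3 for cm^-1 per mg/ml.
    """
    n = list(stoichiometry) if stoichiometry is not None else [1.0] * len(comps)
    mass = sum(ni * c.mass for (c, _), ni in zip(comps, n))
    vol = sum(ni * c.volume for (c, _), ni in zip(comps, n))
    a0, a1 = _excess_b_affine(comps, stoichiometry, labile_exchange)
    excess_b = a0 + a1 * f_D2O  # A
    delta_rho = excess_b / vol * 1e16  # cm^-2
    vbar = vol * 1e-24 * AVOGADRO / mass  # cm^3/g
    return mass * (delta_rho * vbar) ** 2 / AVOGADRO


def mw_from_forward_scattering(
    i0_per_c: float,
    comps: Sequence[tuple[Composition, float]],
    f_D2O: float,
    stoichiometry: Sequence[float] | None = None,
    labile_exchange: float = 0.95,
    min_contrast: float = 1e7,
) -> float:
    """Molecular mass (Da) from I(0)/c (cm^2/g) and composition-derived contrast.

    M = (I0/c) * N_A / (delta_rho * vbar)^2, with delta_rho in cm^-2 and the
    specific volume vbar in cm^3/g derived from the composition.  Raises
    ``ValueError`` when measured at (or too close to) the match point, where
    MW is undefined.
    """
    n = list(stoichiometry) if stoichiometry is not None else [1.0] * len(comps)
    mass = sum(ni * c.mass for (c, _), ni in zip(comps, n))
    vol = sum(ni * c.volume for (c, _), ni in zip(comps, n))
    a0, a1 = _excess_b_affine(comps, stoichiometry, labile_exchange)
    delta_rho = (a0 + a1 * f_D2O) / vol * 1e16  # cm^-2
    if abs(delta_rho) < min_contrast:
        raise ValueError(
            f"contrast {delta_rho:.3g} cm^-2 below tolerance: measurement at the "
            "match point, MW undefined"
        )
    vbar = vol * 1e-24 * AVOGADRO / mass
    return i0_per_c * AVOGADRO / (delta_rho * vbar) ** 2
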