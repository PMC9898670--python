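"""Peptide specifications and sequence-level physical quantities.

A collagen peptide is written the way synthesis labs write it, e.g.
``Ac-(POG)4-QG-(POG)5-NH2``: an optional N-terminal acetyl cap, runs of
one-letter residue codes with optional ``(XYZ)n`` repeats, and an optional
C-terminal amide cap.  From the parsed chain this module computes the
three-chain (trimer) mass, the partial specific volume v-bar from consensus
residue volumes, molar extinction coefficients, and the standardisation of
sedimentation coefficients to water at 20 C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from . import residues as rd

__all__ = [
    "PeptideChain", "PeptideProperties", "BufferConditions", "SedCoefficient",
    "PeptideParseError", "parse_peptide", "render_peptide", "trimer_mass",
    "partial_specific_volume", "extinction_coefficient",
    "correct_s_to_standard", "peptide_properties",
    "ETA_20W", "RHO_20W",
]

#: Viscosity of water at 20 C, Poise.
ETA_20W = 0.010020
#: Density of water at 20 C, g/ml.
RHO_20W = 0.99823

#: Molar extinction coefficient of tyrosine at 280 nm, M^-1 cm^-1.
EPS_TYR_280 = 1280.0
#: Molar extinction coefficient per peptide bond at 214 nm, M^-1 cm^-1.
EPS_BOND_214 = 2200.0


class PeptideParseError(ValueError):
    """Raised when a peptide specification string cannot be parsed."""


@dataclass(frozen=True)
class PeptideChain:
    """One chain of a collagen peptide: residues plus terminal blocking."""

    residues: tuple[str, ...]
    n_block: str = "free"     # {"acetyl", "free"}
    c_block: str = "free"     # {"amide", "free"}
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.residues:
            raise PeptideParseError("peptide chain has no residues")
        bad = [r for r in self.residues if r not in rd.SUPPORTED_RESIDUES]
        if bad:
            raise PeptideParseError(f"unsupported residue code(s): {sorted(set(bad))}")
        if self.n_block not in ("acetyl", "free"):
            raise ValueError(f"bad n_block {self.n_block!r}")
        if self.c_block not in ("amide", "free"):
            raise ValueError(f"bad c_block {self.c_block!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_full_triplets(self) -> int:
        return len(self.residues) // 3


@dataclass(frozen=True)
class PeptideProperties:
    trimer_mass: float        # Da
    vbar: float               # ml/g
    eps280: float             # M^-1 cm^-1, per triple helix
    eps214: float             # M^-1 cm^-1, per triple helix
    n_full_triplets: int


@dataclass(frozen=True)
class BufferConditions:
    density: float            # g/ml
    viscosity: float          # Poise
    temperature: float = 20.0  # C
    label: str = ""

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("buffer density and viscosity must be positive")


class SedCondition(str, Enum):
    OBSERVED = "observed_T_B"
    STANDARD = "standard_20_w"


@dataclass(frozen=True)
class SedCoefficient:
    s: float                  # Svedberg (1e-13 s)
    condition: SedCondition = SedCondition.OBSERVED

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("sedimentation coefficient must be positive")


_TOKEN = re.compile(r"\(([A-Z]+)\)(\d+)|([A-Z]+)")


def parse_peptide(spec: str, name: str | None = None) -> PeptideChain:
    """Parse a peptide specification like ``Ac-(POG)4-QG-(POG)5-NH2``.

    Grammar: optional leading ``Ac-``, then dash-separated segments that are
    either literal residue runs (``QG``) or repeats ``(XYZ)n``, then an
    optional trailing ``-NH2``.
    """
    text = spec.strip()
    if not text:
        raise PeptideParseError("empty peptide specification")
    label = name if name is not None else spec.strip()
    n_block, c_block = "free", "free"
    if text.startswith("Ac-"):
        n_block = "acetyl"
        text = text[3:]
    if text.endswith("-NH2"):
        c_block = "amide"
        text = text[:-4]
    elif text.endswith("NH2") and len(text) > 3:
        # tolerate a missing dash before the cap
        c_block = "amide"
        text = text[:-3]
    residues: list[str] = []
    for segment in text.split("-"):
        if not segment:
            continue
        pos = 0
        for m in _TOKEN.finditer(segment):
            if m.start() != pos:
                raise PeptideParseError(
                    f"malformed segment {segment!r} near {segment[pos:m.start()]!r}")
            pos = m.end()
            if m.group(1) is not None:
                unit, count = m.group(1), int(m.group(2))
                residues.extend(unit * count)
            else:
                residues.extend(m.group(3))
        if pos != len(segment):
            raise PeptideParseError(
                f"malformed segment {segment!r} near {segment[pos:]!r}")
    if not residues:
        raise PeptideParseError(f"specification {spec!r} expands to an empty sequence")
    bad = sorted({r for r in residues if r not in rd.SUPPORTED_RESIDUES})
    if bad:
        raise PeptideParseError(f"unknown residue letter(s) {bad} in {spec!r}")
    return PeptideChain(tuple(residues), n_block, c_block, label)


def render_peptide(chain: PeptideChain) -> str:
    """Inverse of :func:`parse_peptide`: ``parse_peptide(render_peptide(c)) == c``."""
    seq = "".join(chain.residues)
    # compress leading/trailing triplet repeats for readability
    out: list[str] = []
    i = 0
    while i < len(seq):
        unit = seq[i:i + 3]
        n = 1
        while len(unit) == 3 and seq[i + 3 * n:i + 3 * (n + 1)] == unit:
            n += 1
        if len(unit) == 3 and n > 1:
            out.append(f"({unit}){n}")
            i += 3 * n
        else:
            out.append(seq[i])
            i += 1
    body = "-".join(out)
    prefix = "Ac-" if chain.n_block == "acetyl" else ""
    suffix = "-NH2" if chain.c_block == "amide" else ""
    return f"{prefix}{body}{suffix}"


def chain_mass(chain: PeptideChain) -> float:
    """Average mass of one chain in Da, blocking groups included."""
    m = sum(rd.RESIDUE_MASS[r] for r in chain.residues) + rd.WATER_MASS
    if chain.n_block == "acetyl":
        m += rd.ACETYL_MASS_INCREMENT
    if chain.c_block == "amide":
        m += rd.AMIDE_MASS_INCREMENT
    return m


def trimer_mass(chain: PeptideChain) -> float:
    """Mass of the three-chain triple helix in Da (average atomic masses)."""
    return 3.0 * chain_mass(chain)


def partial_specific_volume(chain: PeptideChain, *, hyp_mass: str = "pro",
                            include_chain_ends: bool = True) -> float:
    """Partial specific volume v-bar in ml/g from consensus residue volumes.

    Hydroxyproline has no entry in the classical volume tables, so Pro's
    parameters are substituted.  By default the substitution covers the mass
    in the ratio as well (``hyp_mass="pro"``), which makes (POG)n and (PPG)n
    indistinguishable -- the convention of composition-only calculators;
    ``hyp_mass="hyp"`` keeps hydroxyproline's true mass in the denominator.
    ``include_chain_ends`` adds the terminal H2O of the free peptide to both
    sums; it is a ~0.3% effect for a 30-residue chain.
    """
    if hyp_mass not in ("pro", "hyp"):
        raise ValueError("hyp_mass must be 'pro' or 'hyp'")
    vol = 0.0
    mass = 0.0
    for r in chain.residues:
        key = "P" if r == "O" else r
        if key not in rd.RESIDUE_VOLUME:
            raise KeyError(f"no tabulated volume for residue {r!r}")
        vol += rd.RESIDUE_VOLUME[key]
        mass += rd.RESIDUE_MASS[key if (r == "O" and hyp_mass == "pro") else r]
    if include_chain_ends:
        vol += rd.WATER_VOLUME
        mass += rd.WATER_MASS
    return vol * rd.A3_TO_ML_PER_MOL / mass


def extinction_coefficient(chain: PeptideChain, wavelength: int) -> float:
    """Molar extinction coefficient of the triple helix, M^-1 cm^-1.

    At 280 nm only tyrosines absorb (1280 per Tyr); at 214 nm every peptide
    bond contributes 2200, counting one extra amide bond per blocked terminus.
    """
    if wavelength == 280:
        return 3.0 * EPS_TYR_280 * sum(1 for r in chain.residues if r == "Y")
    if wavelength == 214:
        bonds = len(chain.residues) - 1
        if chain.n_block == "acetyl":
            bonds += 1
        if chain.c_block == "amide":
            bonds += 1
        return 3.0 * EPS_BOND_214 * bonds
    raise ValueError(f"unsupported wavelength {wavelength}; use 280 or 214")


def correct_s_to_standard(s_obs: SedCoefficient, buffer: BufferConditions,
                          vbar: float) -> SedCoefficient:
    """Correct an observed s to standard conditions (water, 20 C).

    s_20,w = s_T,B * (eta_T,B/eta_20,w) * (1 - vbar*rho)_20,w / (1 - vbar*rho)_T,B
    """
    buoy_std = 1.0 - vbar * RHO_20W
    buoy_obs = 1.0 - vbar * buffer.density
    if abs(buoy_obs) < 1e-12:
        raise ZeroDivisionError(
            "buoyancy term (1 - vbar*rho) vanishes in the measurement buffer: "
            "neutrally buoyant particle, s cannot be standardised")
    if buoy_obs * buoy_std < 0:
        raise ValueError(
            "buoyancy term changes sign between buffer and standard water "
            "(particle floats in one and sediments in the other)")
    s20w = s_obs.s * (buffer.viscosity / ETA_20W) * buoy_std / buoy_obs
    return SedCoefficient(s20w, SedCondition.STANDARD)


def peptide_properties(chain: PeptideChain, **vbar_kwargs) -> PeptideProperties:
    """Bundle of the sequence-derived physical quantities for one peptide."""
    return PeptideProperties(
        trimer_mass=trimer_mass(chain),
        vbar=partial_specific_volume(chain, **vbar_kwargs),
        eps280=extinction_coefficient(chain, 280),
        eps214=extinction_coefficient(chain, 214),
        n_full_triplets=chain.n_full_triplets,
    )
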