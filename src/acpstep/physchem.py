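"""The eight physicochemical descriptors (PCP feature family).

Net charge, charge density, isoelectric point, aliphatic index, aromaticity,
hydrophobic ratio, Boman index and instability index — the whole-peptide
descriptor set used alongside composition features for activity prediction.
Charge and pI follow the Henderson–Hasselbalch model over the ionizable
groups (free termini plus D/E/C/Y and H/K/R side chains) with the Bjellqvist
pKa set; the instability index uses the Guruprasad dipeptide weight matrix;
the Boman index averages side-chain transfer free energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import DIWV
from scipy.optimize import bisect

PCP_NAMES = (
    "net_charge",
    "charge_density",
    "isoelectric_point",
    "aliphatic_index",
    "aromaticity",
    "hydrophobic_ratio",
    "boman_index",
    "instability_index",
)

HYDROPHOBIC_SET = frozenset("ACFILMV")
AROMATIC_SET = frozenset("FWY")
ALIPHATIC_COEFF_V = 2.9  # relative side-chain volume weight for valine
ALIPHATIC_COEFF_IL = 3.9  # weight shared by isoleucine and leucine
INSTABILITY_THRESHOLD = 40.0  # above this a molecule is predicted unstable


def _read_scale(name: str) -> pd.DataFrame:
    path = resources.files("acpstep").joinpath("scales", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


@dataclass(frozen=True)
class PropertyScales:
    """Constant tables behind the descriptors.

    ``pka_basic``/``pka_acidic`` map ionizable groups (``Nterm``/``Cterm``
    or residue letters) to pKa; ``boman_scale`` maps residues to side-chain
    free energies (kcal/mol); ``diwv`` is the 400-entry dipeptide
    instability weight matrix.
    """

    pka_basic: dict[str, float]
    pka_acidic: dict[str, float]
    boman_scale: dict[str, float]
    diwv: dict[str, dict[str, float]]
    hydrophobic_set: frozenset = HYDROPHOBIC_SET
    aromatic_set: frozenset = AROMATIC_SET

    def __post_init__(self) -> None:
        n_pairs = sum(len(v) for v in self.diwv.values())
        if n_pairs != 400:
            raise ValueError(f"DIWV must have 400 entries, got {n_pairs}")
        for table in (self.pka_basic, self.pka_acidic):
            for group, pka in table.items():
                if not 0 < pka < 14:
                    raise ValueError(f"pKa out of range for {group}: {pka}")


def default_scales() -> PropertyScales:
    """Bjellqvist pKa set + Boman free-energy scale + Guruprasad DIWV."""
    pka = _read_scale("pka_bjellqvist.tsv")
    basic = dict(pka.loc[pka["sign"] == 1, ["group", "pka"]].values)
    acidic = dict(pka.loc[pka["sign"] == -1, ["group", "pka"]].values)
    boman = dict(_read_scale("boman_scale.tsv").values)
    return PropertyScales(
        pka_basic=basic, pka_acidic=acidic, boman_scale=boman, diwv=DIWV
    )


_DEFAULT = None


def _scales(scales: PropertyScales | None) -> PropertyScales:
    global _DEFAULT
    if scales is not None:
        return scales
    if _DEFAULT is None:
        _DEFAULT = default_scales()
    return _DEFAULT


def net_charge(sequence: str, pH: float = 7.0, scales: PropertyScales | None = None) -> float:
    """Henderson–Hasselbalch net charge at a given pH (elementary charges).

    Basic groups (N-terminus, H, K, R) contribute ``+1/(1+10^(pH-pKa))``,
    acidic groups (C-terminus, D, E, C, Y) ``-1/(1+10^(pKa-pH))``.
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    sc = _scales(scales)
    charge = 1.0 / (1.0 + 10 ** (pH - sc.pka_basic["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (sc.pka_acidic["Cterm"] - pH))
    for aa in sequence:
        if aa in sc.pka_basic:
            charge += 1.0 / (1.0 + 10 ** (pH - sc.pka_basic[aa]))
        elif aa in sc.pka_acidic:
            charge -= 1.0 / (1.0 + 10 ** (sc.pka_acidic[aa] - pH))
    return charge


def isoelectric_point(sequence: str, scales: PropertyScales | None = None) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH and both termini are always
    ionizable, so a unique root exists.
    """
    sc = _scales(scales)
    return float(
        bisect(lambda ph: net_charge(sequence, ph, sc), 1e-4, 14 - 1e-4, xtol=1e-4)
    )


def peptide_mw(sequence: str) -> float:
    """Average molecular weight (Da), free termini."""
    return molecular_weight(sequence, seq_type="protein")


def charge_density(sequence: str, pH: float = 7.0, scales: PropertyScales | None = None) -> float:
    """Net charge per Dalton of molecular weight."""
    return net_charge(sequence, pH, scales) / peptide_mw(sequence)


def aliphatic_index(sequence: str) -> float:
    """Ikai thermostability proxy: X_A + 2.9·X_V + 3.9·(X_I + X_L), with X
    the mole percent of each residue."""
    L = len(sequence)
    x = {aa: 100.0 * sequence.count(aa) / L for aa in "AVIL"}
    return x["A"] + ALIPHATIC_COEFF_V * x["V"] + ALIPHATIC_COEFF_IL * (x["I"] + x["L"])


def aromaticity(sequence: str) -> float:
    """Fraction of aromatic residues (F, W, Y)."""
    return sum(aa in AROMATIC_SET for aa in sequence) / len(sequence)


def hydrophobic_ratio(sequence: str) -> float:
    """Fraction of hydrophobic residues (A, C, F, I, L, M, V)."""
    return sum(aa in HYDROPHOBIC_SET for aa in sequence) / len(sequence)


def boman_index(sequence: str, scales: PropertyScales | None = None) -> float:
    """Mean side-chain free energy (kcal/mol per residue).

    Higher values indicate stronger protein-binding potential; values at or
    below 1 are read as a low off-target interaction profile.
    """
    sc = _scales(scales)
    return sum(sc.boman_scale[aa] for aa in sequence) / len(sequence)


def instability_index(sequence: str, scales: PropertyScales | None = None) -> float:
    """Guruprasad dipeptide-weight statistic, (10/L)·Σ DIWV(x_i, x_{i+1});
    values above 40 predict an unstable molecule in vivo."""
    L = len(sequence)
    if L < 2:
        raise ValueError("instability index requires at least 2 residues")
    sc = _scales(scales)
    total = sum(sc.diwv[a][b] for a, b in zip(sequence, sequence[1:]))
    return (10.0 / L) * total


def is_stable(sequence: str, scales: PropertyScales | None = None) -> bool:
    return instability_index(sequence, scales) <= INSTABILITY_THRESHOLD


def physchem_profile(
    sequence: str,
    pH: float = 7.0,
    window: tuple[str, int] | None = None,
    scales: PropertyScales | None = None,
) -> np.ndarray:
    """The 8-descriptor PCP vector, ordered as :data:`PCP_NAMES`.

    Parameters
    ----------
    window : (end, n), optional
        Restrict the computation to a terminal window: ``("N", 5)`` uses the
        first five residues, ``("C", 5)`` the last five.
    """
    if window is not None:
        end, n = window
        if n > len(sequence):
            raise ValueError(f"window {n} exceeds sequence length {len(sequence)}")
        sequence = sequence[:n] if end.upper() == "N" else sequence[-n:]
    sc = _scales(scales)
    return np.array(
        [
            net_charge(sequence, pH, sc),
            charge_density(sequence, pH, sc),
            isoelectric_point(sequence, sc),
            aliphatic_index(sequence),
            aromaticity(sequence),
            hydrophobic_ratio(sequence),
            boman_index(sequence, sc),
            instability_index(sequence, sc),
        ]
    )
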