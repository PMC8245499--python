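"""Sequence composition encoders and hybrid feature assembly.

AAC (20 amino-acid frequencies), DPC (400 overlapping dipeptide
frequencies), CKSAAP (400 frequencies of residue pairs separated by exactly
k positions) and the 8-descriptor physicochemical block compose, in a fixed
recorded order, the feature matrix a classifier sees.  The motivating
observation for keeping positional encoders alongside AAC is that two
peptides can share an identical residue composition yet arrange charge and
hydrophobicity at opposite termini — AAC cannot see the difference, DPC and
CKSAAP can.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CANONICAL_AA
from .physchem import PCP_NAMES, PropertyScales, physchem_profile

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
_PAIR_NAMES = [a + b for a in CANONICAL_AA for b in CANONICAL_AA]

VALID_COMPONENTS = ("AAC", "DPC", "CKSAAP", "PCP", "TAAC", "TPCP")


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: residue frequencies in the fixed alphabetical
    order ACDEFGHIKLMNPQRSTVWY; sums to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    v = np.zeros(20)
    for aa_ in sequence:
        v[_AA_INDEX[aa_]] += 1
    return v / len(sequence)


def cksaap(sequence: str, k: int) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs.

    Entry (a, b) counts positions i with ``x[i] == a`` and ``x[i+k+1] == b``,
    normalized by the number of such windows, L-k-1; sums to 1.  ``k = 0``
    reduces to dipeptide composition.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    L = len(sequence)
    if L < k + 2:
        raise ValueError(f"CKSAAP with k={k} needs length >= {k + 2}, got {L}")
    v = np.zeros(400)
    for i in range(L - k - 1):
        v[_AA_INDEX[sequence[i]] * 20 + _AA_INDEX[sequence[i + k + 1]]] += 1
    return v / (L - k - 1)


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: overlapping ordered pair frequencies
    (denominator L-1); sums to 1."""
    return cksaap(sequence, 0)


def terminal_aac(sequence: str, end: str, n: int = 5) -> np.ndarray:
    """AAC of the first (``end="N"``) or last (``end="C"``) n residues."""
    if n > len(sequence):
        raise ValueError(f"window {n} exceeds sequence length {len(sequence)}")
    sub = sequence[:n] if end.upper() == "N" else sequence[-n:]
    return aac(sub)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered selection of feature blocks.

    ``components`` is an ordered tuple over {"AAC", "DPC", "CKSAAP", "PCP",
    "TAAC", "TPCP"}; ``cksaap_k`` gives the exact spacings encoded when
    CKSAAP is present (one 400-dim block per k).  TAAC and TPCP are the
    terminal-window variants — amino-acid composition (20 dims per
    terminus) and the 8 physicochemical descriptors (8 per terminus) of the
    first and last ``terminal_window`` residues — exposing where a peptide
    places its charge and hydrophobicity, which whole-sequence blocks
    cannot.  Column names are stable across train and predict.
    """

    components: tuple[str, ...] = ("AAC", "DPC", "PCP")
    cksaap_k: tuple[int, ...] = (1,)
    terminal_window: int = 5

    def __post_init__(self) -> None:
        for c in self.components:
            if c not in VALID_COMPONENTS:
                raise ValueError(f"unknown feature component {c!r}")
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate feature components")
        if any(k < 0 for k in self.cksaap_k):
            raise ValueError("CKSAAP spacings must be >= 0")

    @property
    def dimension(self) -> int:
        d = 0
        for c in self.components:
            if c == "AAC":
                d += 20
            elif c == "DPC":
                d += 400
            elif c == "CKSAAP":
                d += 400 * len(self.cksaap_k)
            elif c == "PCP":
                d += 8
            elif c == "TAAC":
                d += 40
            elif c == "TPCP":
                d += 16
        return d

    @property
    def min_length(self) -> int:
        """Shortest sequence the spec can encode (PCP needs 2 residues for
        the instability dipeptides, CKSAAP needs k+2)."""
        need = 1
        if "DPC" in self.components or "PCP" in self.components:
            need = 2
        if "CKSAAP" in self.components:
            need = max(need, max(self.cksaap_k) + 2)
        if "TAAC" in self.components or "TPCP" in self.components:
            need = max(need, self.terminal_window, 2)
        return need

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for c in self.components:
            if c == "AAC":
                names += [f"AAC_{a}" for a in CANONICAL_AA]
            elif c == "DPC":
                names += [f"DPC_{p}" for p in _PAIR_NAMES]
            elif c == "CKSAAP":
                for k in self.cksaap_k:
                    names += [f"CKSAAP{k}_{p[0]}x{p[1]}" for p in _PAIR_NAMES]
            elif c == "PCP":
                names += [f"PCP_{n}" for n in PCP_NAMES]
            elif c == "TAAC":
                names += [f"TAACN_{a}" for a in CANONICAL_AA]
                names += [f"TAACC_{a}" for a in CANONICAL_AA]
            elif c == "TPCP":
                names += [f"TPCPN_{n}" for n in PCP_NAMES]
                names += [f"TPCPC_{n}" for n in PCP_NAMES]
        return names

    @classmethod
    def parse(cls, text: str) -> "FeatureSpec":
        """Parse the mini-language ``"aac+dpc+cksaap:k=1,2,3+pcp"``."""
        components: list[str] = []
        ks: tuple[int, ...] = (1,)
        for part in text.strip().split("+"):
            part = part.strip()
            if not part:
                continue
            if ":" in part:
                name, opts = part.split(":", 1)
                if name.strip().upper() != "CKSAAP" or not opts.startswith("k="):
                    raise ValueError(f"cannot parse feature component {part!r}")
                ks = tuple(int(x) for x in opts[2:].split(","))
                components.append("CKSAAP")
            else:
                components.append(part.upper())
        return cls(components=tuple(components), cksaap_k=ks)

    def __str__(self) -> str:
        parts = []
        for c in self.components:
            if c == "CKSAAP":
                parts.append("cksaap:k=" + ",".join(str(k) for k in self.cksaap_k))
            else:
                parts.append(c.lower())
        return "+".join(parts)


def encode_sequence(
    sequence: str,
    spec: FeatureSpec,
    pH: float = 7.0,
    scales: PropertyScales | None = None,
) -> np.ndarray:
    blocks = []
    for c in spec.components:
        if c == "AAC":
            blocks.append(aac(sequence))
        elif c == "DPC":
            blocks.append(dpc(sequence))
        elif c == "CKSAAP":
            blocks.extend(cksaap(sequence, k) for k in spec.cksaap_k)
        elif c == "PCP":
            blocks.append(physchem_profile(sequence, pH=pH, scales=scales))
        elif c == "TAAC":
            blocks.append(terminal_aac(sequence, "N", spec.terminal_window))
            blocks.append(terminal_aac(sequence, "C", spec.terminal_window))
        elif c == "TPCP":
            w = spec.terminal_window
            blocks.append(physchem_profile(sequence, pH=pH, window=("N", w), scales=scales))
            blocks.append(physchem_profile(sequence, pH=pH, window=("C", w), scales=scales))
    return np.concatenate(blocks)


def encode(
    ds: pd.DataFrame,
    spec: FeatureSpec,
    pH: float = 7.0,
    scales: PropertyScales | None = None,
) -> pd.DataFrame:
    """Encode a dataset frame into a feature matrix indexed by peptide id.

    Raises if any sequence is shorter than the most demanding block allows,
    listing the offending ids.
    """
    too_short = ds.loc[ds["sequence"].str.len() < spec.min_length, "id"].tolist()
    if too_short:
        raise ValueError(
            f"sequences too short for {spec} (need >= {spec.min_length}): {too_short[:10]}"
        )
    rows = [encode_sequence(s, spec, pH=pH, scales=scales) for s in ds["sequence"]]
    return pd.DataFrame(rows, index=pd.Index(ds["id"], name="id"), columns=spec.feature_names())
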