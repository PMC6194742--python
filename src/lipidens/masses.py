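"""Mass arithmetic for negative-mode LC-MS annotation.

Monoisotopic masses from molecular formulas, deprotonated and
acetate-adduct m/z, ppm deviations, neutral-loss assignment of MS2
fragments, and a light Pearson-correlation feature clustering.

Conventions (fixed because they reproduce published annotation tables
for singly-charged negative ions):

* ``[M-H]-`` is computed as M minus the hydrogen *atom* mass, without
  electron-mass correction (available behind ``electron_corrected``);
* ppm deviation is ``(calculated - observed) / calculated * 1e6``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: principal-isotope atomic masses (IUPAC/CODATA values, Da)
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

ELECTRON_MASS = 0.00054857990907
HYDROGEN_MASS = MONOISOTOPIC_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element counts parsed from a Hill-style formula string."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Accepts plain (``C28H52O5``) and underscored (``C_28_H_52_O_5_``)
        renderings."""
        clean = text.replace("_", "").strip()
        if not clean:
            raise ValueError("empty formula")
        pos = 0
        counts: dict[str, int] = {}
        while pos < len(clean):
            m = _TOKEN.match(clean, pos)
            if not m or not m.group(1):
                raise ValueError(f"unparsable formula {text!r} at position {pos}")
            elem, digits = m.group(1), m.group(2)
            if elem not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {elem!r} in {text!r}")
            count = int(digits) if digits else 1
            if count < 1:
                raise ValueError(f"element count must be positive in {text!r}")
            counts[elem] = counts.get(elem, 0) + count
            pos = m.end()
        return cls(tuple(sorted(counts.items())))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for elem, cnt in other.counts:
            merged[elem] = merged.get(elem, 0) + cnt
        return Formula(tuple(sorted(merged.items())))

    def __str__(self) -> str:
        return "".join(f"{e}{c if c > 1 else ''}" for e, c in self.counts)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Sum of principal-isotope atomic masses (Da)."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(MONOISOTOPIC_MASS[e] * c for e, c in formula.counts)


ACETIC_ACID_MASS = monoisotopic_mass("C2H4O2")  # 60.02113 Da

ADDUCT_SPECIES = ("[M-H]-", "[M+HAc-H]-")


def adduct_mz(M: float, species: str, electron_corrected: bool = False) -> float:
    """m/z of a singly-charged negative adduct of neutral mass ``M``."""
    if M <= 0:
        raise ValueError("neutral mass must be positive")
    if species not in ADDUCT_SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {ADDUCT_SPECIES}")
    mz = M - HYDROGEN_MASS
    if species == "[M+HAc-H]-":
        mz += ACETIC_ACID_MASS
    if electron_corrected:
        mz += ELECTRON_MASS
    return mz


def ppm_deviation(calculated: float, observed: float) -> float:
    """(calculated - observed) / calculated * 1e6."""
    if calculated <= 0 or observed <= 0:
        raise ValueError("m/z values must be positive")
    return (calculated - observed) / calculated * 1e6


def formula_ppm(
    formula: Formula | str,
    observed_mz: float,
    species: str = "[M-H]-",
    electron_corrected: bool = False,
) -> float:
    """ppm deviation of an observed ion against a molecular formula."""
    calc = adduct_mz(monoisotopic_mass(formula), species, electron_corrected=electron_corrected)
    return ppm_deviation(calc, observed_mz)


# ---------------------------------------------------------------------------
# neutral losses
# ---------------------------------------------------------------------------

NEUTRAL_LOSSES: Mapping[str, float] = {
    "H2O": monoisotopic_mass("H2O"),
    "CO2": monoisotopic_mass("CO2"),
    "2xH2O": 2 * monoisotopic_mass("H2O"),
    "CO2+H2O": monoisotopic_mass("CO2") + monoisotopic_mass("H2O"),
    "acetic_acid": ACETIC_ACID_MASS,
}


@dataclass(frozen=True)
class NeutralLoss:
    """A precursor-to-fragment mass difference matched to a known loss."""

    name: str
    loss_mass: float
    precursor_mz: float
    fragment_mz: float
    deviation_mda: float
    deviation_ppm: float


def match_neutral_losses(
    precursor_mz: float,
    fragments: Iterable[float],
    tolerance_mda: float = 5.0,
    losses: Mapping[str, float] | None = None,
) -> list[NeutralLoss]:
    """Assign registered neutral losses to precursor/fragment pairs.

    For each fragment, every registered loss whose mass matches
    ``precursor - fragment`` within ``tolerance_mda`` is reported;
    matches are ordered fragment by fragment, closest first.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    losses = losses or NEUTRAL_LOSSES
    out: list[NeutralLoss] = []
    for frag in fragments:
        if frag <= 0:
            raise ValueError("fragment m/z must be positive")
        observed_loss = precursor_mz - frag
        cands = []
        for name, mass in losses.items():
            dev = observed_loss - mass
            if abs(dev) * 1000.0 <= tolerance_mda:
                cands.append(
                    NeutralLoss(
                        name=name,
                        loss_mass=mass,
                        precursor_mz=precursor_mz,
                        fragment_mz=frag,
                        deviation_mda=dev * 1000.0,
                        deviation_ppm=dev / precursor_mz * 1e6,
                    )
                )
        cands.sort(key=lambda nl: abs(nl.deviation_mda))
        out.extend(cands)
    return out


# ---------------------------------------------------------------------------
# correlation clustering (light substitute for network/cluster tools)
# ---------------------------------------------------------------------------

def correlate_features(norm_matrix: pd.DataFrame, feature_a: str, feature_b: str) -> float:
    """Pearson correlation of two features across samples."""
    a = norm_matrix.loc[feature_a].to_numpy(dtype=float)
    b = norm_matrix.loc[feature_b].to_numpy(dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 common samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance feature")
    return float(np.corrcoef(a, b)[0, 1])


def cluster_correlated(norm_matrix: pd.DataFrame, threshold: float = 0.8) -> list[list[str]]:
    """Connected components of the |r| >= threshold correlation graph.

    Zero-variance features become singletons.  Groups are returned
    sorted by their first member for determinism.
    """
    ids = list(norm_matrix.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    vals = norm_matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    ok = sd > 0
    if ok.sum() >= 2 and threshold <= 1.0:
        sub = vals[ok]
        corr = np.corrcoef(sub)
        oki = np.flatnonzero(ok)
        ii, jj = np.where(np.triu(np.abs(corr) >= threshold, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(ids[oki[i]], ids[oki[j]])
    groups = [sorted(c) for c in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: grp[0])
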