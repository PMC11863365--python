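"""Topological autocorrelation descriptors (ATS, MATS, GATS).

Autocorrelation descriptors summarise how an atomic property w is distributed
across the molecular graph: for every topological lag k they aggregate over
all heavy-atom pairs (i, j) at graph distance k.

* ATS  (Broto-Moreau): sum of products  sum_{d(i,j)=k} w_i * w_j
* MATS (Moran):        spatial correlation coefficient at lag k
* GATS (Geary):        Geary's c at lag k,
      c(k) = [(N-1) * sum_{ij: d=k} (w_i - w_j)^2] / [2 W_k sum_i (w_i - wbar)^2]
  where W_k counts ordered pairs at lag k.

Values are undefined (NaN) when no pair exists at the lag or the property has
zero variance over the molecule; downstream cleaning drops such columns.

Atomic properties follow the usual QSPR weighting schemes: Z (atomic number),
m (mass), dv (valence electrons minus attached hydrogens), se/pe/are
(Sanderson / Pauling / Allred-Rochow electronegativity), p (polarizability),
v (van der Waals volume) and s (Kier-Hall intrinsic state).
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem

MAX_LAG = 8

# per-element property tables (heavy atoms occurring in lipids and common
# organics); electronegativities and polarizabilities from standard QSPR tables
_PAULING = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "P": 2.19, "S": 2.58,
            "F": 3.98, "Cl": 3.16, "Br": 2.96, "I": 2.66}
_SANDERSON = {"H": 2.592, "C": 2.746, "N": 3.194, "O": 3.654, "P": 2.515,
              "S": 2.957, "F": 4.000, "Cl": 3.475, "Br": 3.219, "I": 2.778}
_ALLRED_ROCHOW = {"H": 2.20, "C": 2.50, "N": 3.07, "O": 3.50, "P": 2.06,
                  "S": 2.44, "F": 4.10, "Cl": 2.83, "Br": 2.74, "I": 2.21}
_POLARIZABILITY = {"H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "P": 3.63,
                   "S": 2.90, "F": 0.557, "Cl": 2.18, "Br": 3.05, "I": 5.35}
_VDW_RADIUS = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
               "S": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98}

_PT = Chem.GetPeriodicTable()


def _vdw_volume(symbol: str) -> float:
    r = _VDW_RADIUS[symbol]
    return 4.0 / 3.0 * math.pi * r**3


def _intrinsic_state(atom: Chem.Atom) -> float:
    """Kier-Hall intrinsic state I = ((2/n)^2 * dv + 1) / d."""
    n = _PT.GetRow(atom.GetAtomicNum()) + 1  # principal quantum number
    dv = _PT.GetNOuterElecs(atom.GetAtomicNum()) - atom.GetTotalNumHs()
    d = atom.GetDegree()  # heavy-atom sigma connections
    if d == 0:
        return float("nan")
    return ((2.0 / n) ** 2 * dv + 1.0) / d


def atom_properties(mol: Chem.Mol) -> dict[str, np.ndarray]:
    """Per-heavy-atom property vectors for all weighting schemes."""
    syms = [a.GetSymbol() for a in mol.GetAtoms()]
    unknown = [s for s in syms if s not in _PAULING]
    if unknown:
        raise ValueError(f"no property table for element(s) {sorted(set(unknown))}")
    return {
        "Z": np.array([a.GetAtomicNum() for a in mol.GetAtoms()], float),
        "m": np.array([_PT.GetAtomicWeight(a.GetAtomicNum()) for a in mol.GetAtoms()], float),
        "dv": np.array(
            [_PT.GetNOuterElecs(a.GetAtomicNum()) - a.GetTotalNumHs() for a in mol.GetAtoms()],
            float,
        ),
        "se": np.array([_SANDERSON[s] for s in syms], float),
        "pe": np.array([_PAULING[s] for s in syms], float),
        "are": np.array([_ALLRED_ROCHOW[s] for s in syms], float),
        "p": np.array([_POLARIZABILITY[s] for s in syms], float),
        "v": np.array([_vdw_volume(s) for s in syms], float),
        "s": np.array([_intrinsic_state(a) for a in mol.GetAtoms()], float),
    }


def geary_autocorrelation(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Geary's c at one topological lag; NaN if undefined."""
    w = np.asarray(weights, float)
    n = w.size
    mask = dist == lag
    big_w = int(mask.sum())  # ordered pair count
    denom = float(np.sum((w - w.mean()) ** 2))
    if big_w == 0 or denom == 0.0 or n < 2:
        return float("nan")
    diff2 = (w[:, None] - w[None, :]) ** 2
    return float((n - 1) * np.sum(diff2[mask]) / (2.0 * big_w * denom))


def moran_autocorrelation(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Moran's I at one topological lag; NaN if undefined."""
    w = np.asarray(weights, float)
    n = w.size
    mask = dist == lag
    big_w = int(mask.sum())
    dev = w - w.mean()
    denom = float(np.sum(dev**2))
    if big_w == 0 or denom == 0.0 or n < 2:
        return float("nan")
    cross = dev[:, None] * dev[None, :]
    return float(n * np.sum(cross[mask]) / (big_w * denom))


def broto_moreau_autocorrelation(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Broto-Moreau ATS at one lag (sum over unordered pairs); NaN if no pair."""
    w = np.asarray(weights, float)
    mask = dist == lag
    if not mask.any():
        return float("nan")
    prod = w[:, None] * w[None, :]
    return float(np.sum(prod[mask]) / 2.0)


def autocorrelation_descriptors(mol: Chem.Mol, max_lag: int = MAX_LAG) -> dict[str, float]:
    """All ATS/MATS/GATS descriptors for one molecule.

    Names follow the field's convention, e.g. ``GATS6se`` = Geary
    autocorrelation at lag 6 weighted by Sanderson electronegativity.
    """
    dist = Chem.GetDistanceMatrix(mol)
    props = atom_properties(mol)
    out: dict[str, float] = {}
    for pname, w in props.items():
        for k in range(1, max_lag + 1):
            out[f"ATS{k}{pname}"] = broto_moreau_autocorrelation(w, dist, k)
            out[f"MATS{k}{pname}"] = moran_autocorrelation(w, dist, k)
            out[f"GATS{k}{pname}"] = geary_autocorrelation(w, dist, k)
    return out
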