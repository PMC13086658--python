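"""2D topological autocorrelation descriptors (Broto-Moreau, Geary).

Autocorrelation descriptors summarize how an atomic property ``w`` is
distributed over the molecular graph.  For a topological lag ``k`` (number of
bonds on the shortest path) and the set P_k of unordered heavy-atom pairs at
distance k (|P_k| = n_k):

    ATS_k(w)  = sum_{(i,j) in P_k} w_i * w_j          Broto-Moreau
    AATS_k(w) = ATS_k(w) / n_k                         averaged
    ATSC_k(w) = sum_{(i,j) in P_k} (w_i - wbar)(w_j - wbar)   centered
    GATS_k(w) = [ sum_{(i,j) in P_k} (w_i - w_j)^2 / (2 n_k) ]
                / [ sum_i (w_i - wbar)^2 / (N - 1) ]   Geary coefficient

computed on the heavy-atom graph with hydrogens folded into their heavy
atom where the property allows it.  AATS and GATS are undefined (NaN) when a
molecule has no atom pair at lag k; the cleaning cascade removes such columns.

Atomic properties
-----------------
dv : valence electron count minus attached hydrogens (Kier-Hall valence delta)
c  : Gasteiger-Marsili partial charge, hydrogen charges summed onto the heavy atom
p  : atomic polarizability, Å^3 (static dipole polarizability table)
m  : relative atomic mass

Descriptor names follow the field's convention, e.g. ``AATS5dv`` is the
averaged Broto-Moreau autocorrelation at lag 5 weighted by valence electrons,
``GATS5p`` the Geary autocorrelation at lag 5 weighted by polarizability.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

__all__ = ["autocorrelation_descriptors", "AUTOCORR_NAMES"]

MAX_LAG = 8
STATS = ("ATS", "AATS", "ATSC", "GATS")
PROPS = ("dv", "c", "p", "m")

#: static atomic dipole polarizabilities, Å^3
_POLARIZABILITY = {
    "H": 0.667, "Li": 24.3, "B": 3.03, "C": 1.76, "N": 1.10, "O": 0.802,
    "F": 0.557, "Na": 24.1, "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18,
    "K": 43.4, "Br": 3.05, "I": 5.35,
}

AUTOCORR_NAMES = [
    f"{stat}{lag}{prop}"
    for stat in STATS
    for prop in PROPS
    for lag in range(1, MAX_LAG + 1)
]


def _atom_weights(mol: Chem.Mol, prop: str) -> np.ndarray:
    """Per-heavy-atom property vector."""
    atoms = list(mol.GetAtoms())
    if prop == "dv":
        tbl = Chem.GetPeriodicTable()
        return np.array(
            [tbl.GetNOuterElecs(a.GetAtomicNum()) - a.GetTotalNumHs() for a in atoms],
            dtype=float,
        )
    if prop == "c":
        molh = Chem.AddHs(mol)
        rdPartialCharges.ComputeGasteigerCharges(molh)
        charges = np.zeros(mol.GetNumAtoms())
        for a in molh.GetAtoms():
            q = a.GetDoubleProp("_GasteigerCharge")
            if not np.isfinite(q):
                q = 0.0
            if a.GetAtomicNum() == 1:
                nbrs = a.GetNeighbors()
                if nbrs and nbrs[0].GetIdx() < mol.GetNumAtoms():
                    charges[nbrs[0].GetIdx()] += q
            elif a.GetIdx() < mol.GetNumAtoms():
                charges[a.GetIdx()] += q
        return charges
    if prop == "p":
        return np.array(
            [_POLARIZABILITY.get(a.GetSymbol(), 1.76) for a in atoms], dtype=float
        )
    if prop == "m":
        return np.array([a.GetMass() for a in atoms], dtype=float)
    raise ValueError(f"unknown atomic property {prop!r}")


def autocorrelation_descriptors(mol: Chem.Mol) -> dict[str, float]:
    """All ATS/AATS/ATSC/GATS descriptors at lags 1..8 for four weights."""
    n = mol.GetNumAtoms()
    out: dict[str, float] = {}
    if n == 0:
        return {name: np.nan for name in AUTOCORR_NAMES}
    dist = Chem.GetDistanceMatrix(mol)
    iu = np.triu_indices(n, k=1)
    dvec = dist[iu]
    for prop in PROPS:
        w = _atom_weights(mol, prop)
        wbar = w.mean()
        wc = w - wbar
        denom_var = (wc @ wc) / (n - 1) if n > 1 else np.nan
        wi, wj = w[iu[0]], w[iu[1]]
        wci, wcj = wc[iu[0]], wc[iu[1]]
        for lag in range(1, MAX_LAG + 1):
            sel = dvec == lag
            nk = int(sel.sum())
            if nk == 0:
                out[f"ATS{lag}{prop}"] = 0.0
                out[f"ATSC{lag}{prop}"] = 0.0
                out[f"AATS{lag}{prop}"] = np.nan
                out[f"GATS{lag}{prop}"] = np.nan
                continue
            ats = float(wi[sel] @ wj[sel])
            atsc = float(wci[sel] @ wcj[sel])
            out[f"ATS{lag}{prop}"] = ats
            out[f"AATS{lag}{prop}"] = ats / nk
            out[f"ATSC{lag}{prop}"] = atsc
            sq = float(((wi[sel] - wj[sel]) ** 2).sum()) / (2.0 * nk)
            out[f"GATS{lag}{prop}"] = (
                sq / denom_var if denom_var and np.isfinite(denom_var) and denom_var > 0
                else np.nan
            )
    return {name: out[name] for name in AUTOCORR_NAMES}
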