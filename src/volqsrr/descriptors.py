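"""Topological molecular descriptors for retention-index QSRR modeling.

Implements the 2D autocorrelation families (centered Broto-Moreau ATSC,
averaged AATSC, Moran MATS, Geary GATS), the vertex-adjacency information
descriptor VAdjMat, and the two spectral descriptors of the Barysz weighted
distance matrix (SM1, the first spectral moment, and VR1, the Randic-like
sum over bonds of leading-eigenvector components).

Conventions (shared with common descriptor software): autocorrelation sums
run over *ordered* atom pairs, so each unordered pair contributes twice to
both numerator and pair count; lags with no pairs and zero-variance weight
vectors yield 0 rather than an undefined value, keeping feature tables
dense.

Descriptor names combine family, lag and weighting-scheme suffix, e.g.
``AATSC4e`` (averaged centered autocorrelation, lag 4, Sanderson
electronegativity) or ``VR1_Dzs`` (VR1 on the intrinsic-state-weighted
Barysz matrix).  :func:`catalogue` lists the registered names; the seven
descriptors used by the retention-index models are in
:data:`MANDATORY_DESCRIPTORS`.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .molgraph import (
    MolecularGraph,
    PropertyTable,
    WEIGHT_SCHEMES,
    atom_weights,
    barysz_matrix,
    from_smiles,
    topological_distances,
)
from .volatiles import VolatilesTable

__all__ = [
    "MANDATORY_DESCRIPTORS",
    "atsc",
    "aatsc",
    "mats",
    "gats",
    "vadjmat",
    "sm1",
    "vr1",
    "catalogue",
    "compute_descriptor",
    "descriptor_vector",
    "descriptor_table",
]

logger = logging.getLogger(__name__)

#: the seven descriptors selected for the retention-index models
MANDATORY_DESCRIPTORS = (
    "AATSC4e", "AATSC2p", "MATS5v", "GATS6v", "VR1_Dzs", "SM1_Dzv", "VAdjMat",
)

_AUTOCORR_LAGS = range(1, 9)


def _lag_mask(g: MolecularGraph, k: int) -> tuple[np.ndarray, int]:
    d = topological_distances(g)
    mask = d == k
    np.fill_diagonal(mask, False)
    return mask, int(mask.sum())  # ordered pair count


def atsc(g: MolecularGraph, k: int, scheme: str,
         properties: PropertyTable | None = None) -> float:
    """Centered Broto-Moreau autocorrelation at topological lag ``k``:
    sum over ordered pairs (i, j) at distance k of (w_i - wbar)(w_j - wbar).
    """
    if k < 1:
        raise ValueError("lag k must be >= 1")
    w = atom_weights(g, scheme, properties)
    mask, n_k = _lag_mask(g, k)
    if n_k == 0:
        return 0.0
    c = w - w.mean()
    return float(np.outer(c, c)[mask].sum())


def aatsc(g: MolecularGraph, k: int, scheme: str,
          properties: PropertyTable | None = None) -> float:
    """Averaged centered autocorrelation: ATSC_k / (ordered pair count)."""
    if k < 1:
        raise ValueError("lag k must be >= 1")
    w = atom_weights(g, scheme, properties)
    mask, n_k = _lag_mask(g, k)
    if n_k == 0:
        return 0.0
    c = w - w.mean()
    return float(np.outer(c, c)[mask].sum() / n_k)


def mats(g: MolecularGraph, k: int, scheme: str,
         properties: PropertyTable | None = None) -> float:
    """Moran autocorrelation: AATSC_k / ((1/N) * sum (w_i - wbar)^2).

    0 by convention when the lag is empty or the weights have no variance.
    """
    w = atom_weights(g, scheme, properties)
    mask, n_k = _lag_mask(g, k)
    if n_k == 0:
        return 0.0
    c = w - w.mean()
    denom = (c ** 2).sum() / g.n_atoms
    if denom == 0:
        return 0.0
    num = np.outer(c, c)[mask].sum() / n_k
    return float(num / denom)


def gats(g: MolecularGraph, k: int, scheme: str,
         properties: PropertyTable | None = None) -> float:
    """Geary autocorrelation:
    [(1/(2 n_k)) * sum_{d=k} (w_i - w_j)^2] / [(1/(N-1)) * sum (w_i - wbar)^2].
    """
    if g.n_atoms < 2:
        raise ValueError("Geary autocorrelation needs at least two atoms")
    w = atom_weights(g, scheme, properties)
    mask, n_k = _lag_mask(g, k)
    if n_k == 0:
        return 0.0
    c = w - w.mean()
    denom = (c ** 2).sum() / (g.n_atoms - 1)
    if denom == 0:
        return 0.0
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = diff2[mask].sum() / (2.0 * n_k)
    return float(num / denom)


def vadjmat(g: MolecularGraph) -> float:
    """Vertex adjacency information (magnitude): 1 + log2(bond count);
    0 for a bondless graph."""
    m = g.n_bonds
    return 0.0 if m == 0 else 1.0 + float(np.log2(m))


def sm1(matrix: np.ndarray) -> float:
    """First spectral moment: the trace (sum of eigenvalues)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return float(np.trace(m))


def vr1(matrix: np.ndarray, bonds: Iterable[tuple[int, int, float]],
        zero_tol: float = 1e-12) -> float:
    """Randic-like eigenvector descriptor: sum over bonds (i, j) of
    |a_i * a_j| ** -1/2 with ``a`` the eigenvector of the largest eigenvalue.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    _, vecs = np.linalg.eigh(m)
    a = vecs[:, -1]  # eigh sorts eigenvalues ascending
    total = 0.0
    for i, j, _ in bonds:
        prod = abs(a[i] * a[j])
        if prod < zero_tol:
            raise ValueError(
                f"degenerate leading eigenvector: near-zero component on "
                f"bonded atoms ({i}, {j})")
        total += prod ** -0.5
    return float(total)


_NAME_RE = re.compile(
    r"^(?P<family>AATSC|ATSC|MATS|GATS)(?P<lag>[1-8])(?P<scheme>[mvepsZ])$"
    r"|^(?P<spectral>SM1|VR1)_Dz(?P<dzscheme>[mvepsZ])$"
    r"|^(?P<vadj>VAdjMat)$"
)

_FAMILY_FUNCS = {"ATSC": atsc, "AATSC": aatsc, "MATS": mats, "GATS": gats}


def catalogue() -> tuple[str, ...]:
    """All registered descriptor names: the AATSC/MATS/GATS families at lags
    1-8 over all weighting schemes, the Barysz spectral descriptors for all
    schemes, and VAdjMat (~150 features, the GA search space)."""
    names = [
        f"{fam}{k}{s}"
        for fam in ("AATSC", "MATS", "GATS")
        for k in _AUTOCORR_LAGS
        for s in WEIGHT_SCHEMES
    ]
    names += [f"SM1_Dz{s}" for s in WEIGHT_SCHEMES]
    names += [f"VR1_Dz{s}" for s in WEIGHT_SCHEMES]
    names.append("VAdjMat")
    return tuple(names)


def compute_descriptor(g: MolecularGraph, name: str,
                       properties: PropertyTable | None = None) -> float:
    """Evaluate a descriptor by registered name on a molecular graph."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unknown descriptor name {name!r}")
    if m.group("vadj"):
        return vadjmat(g)
    if m.group("spectral"):
        dz = barysz_matrix(g, m.group("dzscheme"), properties)
        if m.group("spectral") == "SM1":
            return sm1(dz)
        return vr1(dz, g.bonds)
    func = _FAMILY_FUNCS[m.group("family")]
    return func(g, int(m.group("lag")), m.group("scheme"), properties)


def descriptor_vector(g: MolecularGraph, names: Sequence[str] | None = None,
                      properties: PropertyTable | None = None) -> dict[str, float]:
    """Named descriptor values for one molecule; defaults to the full
    catalogue."""
    names = tuple(names) if names is not None else catalogue()
    out = {}
    for name in names:
        v = compute_descriptor(g, name, properties)
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for descriptor {name}")
        out[name] = v
    return out


def descriptor_table(compounds: VolatilesTable | Sequence,
                     names: Sequence[str] | None = None,
                     properties: PropertyTable | None = None) -> pd.DataFrame:
    """Descriptor matrix for the identified compounds of a volatiles table.

    Rows are keyed by compound ``row_index``; not-identified rows are
    excluded and identified rows lacking a structure are skipped with a
    logged warning.
    """
    names = tuple(names) if names is not None else catalogue()
    records = list(compounds)
    seen: set[int] = set()
    rows: dict[int, dict[str, float]] = {}
    for rec in records:
        if rec.row_index in seen:
            raise ValueError(f"duplicate compound row {rec.row_index}")
        seen.add(rec.row_index)
        if not rec.identified:
            continue
        if not rec.smiles:
            logger.warning(
                "row %d (%s): no structure available, skipped",
                rec.row_index, rec.name)
            continue
        g = from_smiles(rec.smiles)
        rows[rec.row_index] = descriptor_vector(g, names, properties)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    df.index.name = "row_index"
    return df
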