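"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a two-season volatiles
survey: descriptor tables driving retention indices through a known
partially nonlinear map (for model-recovery tests), random small organic
molecular graphs serialized to SMILES (for descriptor plumbing), n-alkane
retention-time ladders (for retention-index arithmetic), and sample
composition matrices with planted chemotype clusters (for the clustering
and rule-based chemotype calls).

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemotypes import load_rules
from .volatiles import AlkaneLadder

__all__ = [
    "QSRRSimConfig",
    "make_molecules",
    "make_qsrr_dataset",
    "make_composition_samples",
    "make_alkane_ladder",
]


@dataclass(frozen=True)
class QSRRSimConfig:
    """Configuration of the synthetic descriptor -> retention-index map.

    The target is ``ri_intercept + sum(coefficients[:-1] * x_linear) +
    coefficients[-1] * sin(x_last) + noise`` with descriptors drawn
    uniformly from [-2, 2]; the noise is Gaussian with ``noise_sd`` in
    retention-index units (default 60, the scale of typical QSRR residual
    error on a nonpolar column).  Defaults emulate a 160-compound survey
    spanning roughly RI 850-3300.
    """

    n_compounds: int = 160
    n_informative: int = 3
    n_noise: int = 50
    coefficients: tuple[float, ...] = (95.0, 60.0, 40.0)
    noise_sd: float = 60.0
    ri_intercept: float = 1600.0
    ri_band: tuple[float, float] = (850.0, 3300.0)
    seed: int = 0

    def validate(self) -> "QSRRSimConfig":
        if self.n_informative < 1 or len(self.coefficients) != self.n_informative:
            raise ValueError("coefficients must match n_informative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_compounds < 1 or self.n_noise < 0:
            raise ValueError("invalid sizes")
        return self


def make_qsrr_dataset(
    cfg: QSRRSimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Synthetic descriptor table, retention-index vector and ground truth.

    Returns (features, ri, truth) where ``truth`` records the informative
    column names, coefficients and noise level for recovery tests.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p_inf, p_noise = cfg.n_compounds, cfg.n_informative, cfg.n_noise
    X = rng.uniform(-2.0, 2.0, size=(n, p_inf + p_noise))
    coef = np.asarray(cfg.coefficients, dtype=float)
    linear = X[:, : p_inf - 1] @ coef[:-1] if p_inf > 1 else 0.0
    y = cfg.ri_intercept + linear + coef[-1] * np.sin(X[:, p_inf - 1])
    y = y + rng.normal(0.0, cfg.noise_sd, size=n)
    y = np.clip(y, *cfg.ri_band)
    names = [f"inf_{i + 1}" for i in range(p_inf)] + \
            [f"noise_{i + 1}" for i in range(p_noise)]
    features = pd.DataFrame(X, columns=names)
    ri = pd.Series(y, name="ri")
    truth = {
        "informative": names[:p_inf],
        "coefficients": list(coef),
        "sinusoidal": names[p_inf - 1],
        "noise_sd": cfg.noise_sd,
        "intercept": cfg.ri_intercept,
    }
    return features, ri, truth


def make_molecules(
    n: int, seed: int = 0, min_atoms: int = 6, max_atoms: int = 20,
    hetero_prob: float = 0.12, ring_prob: float = 0.35,
    double_bond_prob: float = 0.15,
) -> list[str]:
    """Random connected hydrogen-suppressed molecular graphs as SMILES.

    Graphs are grown as random trees over C with occasional O/N/S, with an
    optional ring closure and occasional double bonds, respecting element
    valences.  Deterministic per seed; every output parses back through
    :func:`volqsrr.molgraph.from_smiles`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 < min_atoms <= max_atoms):
        raise ValueError("need 1 < min_atoms <= max_atoms")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    max_valence = {"C": 4, "N": 3, "O": 2, "S": 2}
    out = []
    for _ in range(n):
        size = int(rng.integers(min_atoms, max_atoms + 1))
        mol = Chem.RWMol()
        elements = []
        for i in range(size):
            el = "C"
            if i > 0 and rng.random() < hetero_prob:
                el = ["O", "N", "S"][int(rng.integers(3))]
            elements.append(el)
            mol.AddAtom(Chem.Atom(el))
        used = np.zeros(size, dtype=int)
        for i in range(1, size):
            cands = [j for j in range(i)
                     if used[j] < max_valence[elements[j]]]
            j = int(cands[rng.integers(len(cands))])
            order = Chem.BondType.SINGLE
            bump = 1
            if (rng.random() < double_bond_prob
                    and elements[i] == elements[j] == "C"
                    and used[j] <= max_valence["C"] - 2):
                order = Chem.BondType.DOUBLE
                bump = 2
            mol.AddBond(i, j, order)
            used[i] += bump
            used[j] += bump
        if rng.random() < ring_prob:
            free = [i for i in range(size)
                    if used[i] < max_valence[elements[i]]]
            pairs = [(a, b) for ai, a in enumerate(free) for b in free[ai + 1:]
                     if mol.GetBondBetweenAtoms(int(a), int(b)) is None]
            if pairs:
                a, b = pairs[int(rng.integers(len(pairs)))]
                mol.AddBond(int(a), int(b), Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        out.append(Chem.MolToSmiles(m))
    return out


def make_composition_samples(
    k_clusters: int = 2, samples_per_cluster: int = 5,
    marker_levels: Sequence[tuple[str, float]] | None = None,
    seed: int = 0, n_background: int = 12, marker_sd: float = 1.5,
) -> tuple[pd.DataFrame, list[int]]:
    """Composition matrix with planted chemotype clusters and true labels.

    Each cluster is centered on a chemotype marker profile (defaults cycle
    through the packaged rule set: E-caryophyllene ~25%, beta-bisabolene
    ~20%, alpha-pinene ~25%, beta-farnesene ~22%); the remaining percentage
    is spread over background compounds by a Dirichlet draw, so rows sum to
    ~100.
    """
    if k_clusters < 1 or samples_per_cluster < 1:
        raise ValueError("cluster counts must be >= 1")
    if marker_levels is None:
        marker_levels = [
            ("E-caryophyllene", 25.0),
            ("beta-bisabolene", 20.0),
            ("alpha-pinene", 25.0),
            ("beta-farnesene", 22.0),
        ]
    if k_clusters > len(marker_levels):
        raise ValueError(
            f"at most {len(marker_levels)} planted chemotypes available")
    ranges = {}
    for rule in load_rules():
        if len(rule.markers) == 1:
            compound, lo, hi = rule.markers[0]
            ranges[compound.casefold()] = (lo, hi)
    for compound, level in marker_levels[:k_clusters]:
        lo, hi = ranges.get(compound.casefold(), (0.0, 100.0))
        if not (lo <= level <= hi):
            raise ValueError(
                f"marker level {level} for {compound} outside rule range "
                f"[{lo}, {hi}]")

    rng = np.random.default_rng(seed)
    markers = [name for name, _ in marker_levels[:k_clusters]]
    background = [f"compound_{i + 1}" for i in range(n_background)]
    columns = markers + background
    rows, labels, index = [], [], []
    for c in range(k_clusters):
        name, level = marker_levels[c]
        lo, hi = ranges.get(name.casefold(), (0.0, 100.0))
        for s in range(samples_per_cluster):
            row = dict.fromkeys(columns, 0.0)
            row[name] = float(np.clip(rng.normal(level, marker_sd), lo, hi))
            remainder = 100.0 - row[name]
            props = rng.dirichlet(np.full(n_background, 2.0))
            for comp, frac in zip(background, props):
                row[comp] = remainder * frac
            rows.append(row)
            labels.append(c)
            index.append(f"{name}_{s + 1}")
    return pd.DataFrame(rows, index=index, columns=columns), labels


def make_alkane_ladder(
    t0: float = 5.0, spacing_model: str = "linear", seed: int = 0,
    slope: float = 3.2, jitter: float = 0.3,
) -> AlkaneLadder:
    """Retention-time ladder for the C8-C32 n-alkane series.

    ``spacing_model="linear"`` gives exactly affine times (so the linear
    retention index is affine in retention time); ``"random"`` draws
    strictly positive randomized spacings around ``slope`` minutes.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    carbons = tuple(range(8, 33))
    if spacing_model == "linear":
        times = tuple(t0 + slope * (c - 8) for c in carbons)
    elif spacing_model == "random":
        rng = np.random.default_rng(seed)
        gaps = np.clip(rng.normal(slope, jitter, size=len(carbons) - 1),
                       0.1 * slope, None)
        times = tuple(np.concatenate([[t0], t0 + np.cumsum(gaps)]))
    else:
        raise ValueError(f"unknown spacing_model {spacing_model!r}")
    return AlkaneLadder(carbon_numbers=carbons, retention_times=times)
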