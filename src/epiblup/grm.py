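"""Orthogonal genomic relationship matrices.

Under Hardy-Weinberg equilibrium the NOIA parameterization makes additive
effects, dominance deviations and their pairwise interactions statistically
orthogonal. The additive incidence matrix M carries the VanRaden centering
(2-2p, 1-2p, -2p), the dominance matrix W carries (-2q^2, 2pq, -2p^2), and

    G_A  = M M' / (2 sum p_i q_i)
    G_D  = W W' / (4 sum p_i^2 q_i^2)
    G_XY = (G_X . G_Y) / (tr(G_X . G_Y) / n)      (Hadamard product, trace-scaled)

The trace scaling makes tr(G)/n = 1 exactly for every epistatic matrix, so
the associated variance components are on a comparable scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, impute_missing

COMPONENTS = ("A", "D", "AA", "AD", "DD")

_HADAMARD_COMPONENT = {
    frozenset({"A"}): "AA",
    frozenset({"A", "D"}): "AD",
    frozenset({"D"}): "DD",
}


@dataclass
class IncidenceMatrix:
    """Centered marker incidence coefficients (one row per individual)."""

    values: np.ndarray
    kind: str  # "additive" (M) or "dominance" (W)
    frequencies: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "dominance"):
            raise ValueError(f"unknown incidence kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.values.shape[1] != self.frequencies.shape[0]:
            raise ValueError("frequency vector does not match SNP columns")
        if self.values.shape[0] != len(self.individual_ids):
            raise ValueError("individual ids do not match rows")


@dataclass
class RelationshipMatrix:
    """Symmetric n x n genomic covariance structure for one genetic component."""

    values: np.ndarray
    component: str
    individual_ids: np.ndarray
    norm_constant: float

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.individual_ids):
            raise ValueError("individual ids do not match dimension")
        # store exactly symmetric
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_monomorphic(p: np.ndarray) -> None:
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNPs contribute zero columns and "
            "drop out of the normalization denominators"
        )


def additive_incidence(g: GenotypeMatrix, freqs: np.ndarray) -> IncidenceMatrix:
    """VanRaden-centered gene content: entry = code - 2p; missing -> 0."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (g.n_snps,):
        raise ValueError("frequency vector does not match SNP count")
    _check_monomorphic(freqs)
    codes = impute_missing(g, freqs)
    m = codes - 2.0 * freqs
    return IncidenceMatrix(m, "additive", freqs, g.individual_ids)


def dominance_incidence(g: GenotypeMatrix, freqs: np.ndarray) -> IncidenceMatrix:
    """Dominance-deviation coding -2q^2 / 2pq / -2p^2; missing entries -> 0.

    A missing genotype carries no heterozygosity information, and under the
    centered coding the HWE-expected value of a W entry is zero, so missing
    entries contribute nothing.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (g.n_snps,):
        raise ValueError("frequency vector does not match SNP count")
    p = freqs
    q = 1.0 - p
    w = np.zeros_like(g.values)
    codes = g.values
    w = np.where(codes == 2.0, -2.0 * q**2, w)
    w = np.where(codes == 1.0, 2.0 * p * q, w)
    w = np.where(codes == 0.0, -2.0 * p**2, w)
    w[g.missing_mask] = 0.0
    return IncidenceMatrix(w, "dominance", freqs, g.individual_ids)


def grm_additive(m: IncidenceMatrix) -> RelationshipMatrix:
    """G_A = M M' / (2 sum p q)."""
    if m.kind != "additive":
        raise ValueError("grm_additive requires an additive incidence matrix")
    p = m.frequencies
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: additive normalization is zero")
    return RelationshipMatrix(m.values @ m.values.T / denom, "A",
                              m.individual_ids, denom)


def grm_dominance(w: IncidenceMatrix) -> RelationshipMatrix:
    """G_D = W W' / (4 sum p^2 q^2)."""
    if w.kind != "dominance":
        raise ValueError("grm_dominance requires a dominance incidence matrix")
    p = w.frequencies
    denom = 4.0 * np.sum((p * (1.0 - p)) ** 2)
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: dominance normalization is zero")
    return RelationshipMatrix(w.values @ w.values.T / denom, "D",
                              w.individual_ids, denom)


def epistatic_grm(gx: RelationshipMatrix, gy: RelationshipMatrix) -> RelationshipMatrix:
    """Trace-normalized Hadamard product of two relationship matrices."""
    if gx.n != gy.n:
        raise ValueError("relationship matrices have different dimensions")
    key = frozenset({gx.component, gy.component})
    if key not in _HADAMARD_COMPONENT:
        raise ValueError(
            f"cannot combine components {gx.component} and {gy.component}; "
            "only first-order A/D inputs are supported"
        )
    had = gx.values * gy.values
    tr = np.trace(had)
    if tr <= 0.0:
        raise ValueError("Hadamard product has non-positive trace (degenerate input)")
    norm = tr / gx.n
    return RelationshipMatrix(had / norm, _HADAMARD_COMPONENT[key],
                              gx.individual_ids, norm)


def regularize(g: RelationshipMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """Add epsilon to the diagonal so Cholesky factorizations succeed."""
    if epsilon <= 0.0:
        raise ValueError("epsilon must be positive")
    v = g.values + epsilon * np.eye(g.n)
    out = RelationshipMatrix(v, g.component, g.individual_ids, g.norm_constant)
    return out


def build_grms(g: GenotypeMatrix, freqs: np.ndarray,
               components=COMPONENTS, epsilon: float = 1e-6) -> dict[str, RelationshipMatrix]:
    """Convenience: all requested relationship matrices from one genotype set,
    regularized and ready for the sampler/solver."""
    m = additive_incidence(g, freqs)
    w = dominance_incidence(g, freqs)
    ga = grm_additive(m)
    gd = grm_dominance(w)
    raw = {"A": ga, "D": gd}
    if "AA" in components:
        raw["AA"] = epistatic_grm(ga, ga)
    if "AD" in components:
        raw["AD"] = epistatic_grm(ga, gd)
    if "DD" in components:
        raw["DD"] = epistatic_grm(gd, gd)
    return {k: regularize(v, epsilon) for k, v in raw.items() if k in components}


def write_grm_tsv(g: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(g.values, index=g.individual_ids, columns=g.individual_ids)
    df.index.name = f"component={g.component};norm={float(g.norm_constant)!r}"
    df.to_csv(path, sep="\t")


def read_grm_tsv(path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = dict(item.split("=", 1) for item in str(df.index.name).split(";"))
    return RelationshipMatrix(df.to_numpy(dtype=float), meta["component"],
                              df.index.astype(str).to_numpy(dtype=object),
                              float(meta["norm"]))


def save_grm(g: RelationshipMatrix, path) -> None:
    """Compact container (written at run time; not a text format)."""
    np.savez(path, values=g.values, component=g.component,
             individual_ids=np.asarray(g.individual_ids, dtype=str),
             norm_constant=g.norm_constant)


def load_grm(path) -> RelationshipMatrix:
    with np.load(path, allow_pickle=False) as z:
        return RelationshipMatrix(z["values"], str(z["component"]),
                                  z["individual_ids"].astype(object),
                                  float(z["norm_constant"]))
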