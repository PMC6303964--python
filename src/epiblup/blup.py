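"""GBLUP at fixed variance components.

Solves Henderson's mixed-model equations for the declared genetic terms,
the permanent environmental effect and the fixed effects (including the
inbreeding-depression covariate). Each genetic effect is parameterized as
g = L u with G = L L', which turns the equations into a ridge system with
penalty sigma2_e / sigma2_g on u; candidates without records receive
genomic predictions through L and a zero permanent environmental effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg

from .design import DesignSet, ModelSpec
from .grm import RelationshipMatrix


@dataclass
class SolutionSet:
    """All effect solutions from one GBLUP solve."""

    beta: np.ndarray
    x_names: list[str]
    b: float | None                    # inbreeding depression slope
    g: dict[str, np.ndarray]           # individual-level genetic values per term
    pe: np.ndarray | None
    variances: dict[str, float]
    spec: ModelSpec
    mme_relative_residual: float

    def total_genetic(self) -> np.ndarray:
        return sum(self.g.values())

    def to_tsv(self, path, individual_ids) -> None:
        import pandas as pd

        rows = [("fixed", name, est) for name, est in zip(self.x_names, self.beta)]
        if self.b is not None:
            rows.append(("covariate", "b", self.b))
        for term, vals in self.g.items():
            rows += [(f"g_{term}", str(i), v) for i, v in zip(individual_ids, vals)]
        if self.pe is not None:
            rows += [("pe", str(i), v) for i, v in zip(individual_ids, self.pe)]
        pd.DataFrame(rows, columns=["effect", "level", "estimate"]).to_csv(
            path, sep="\t", index=False)


def solve_gblup(design: DesignSet, grms: Mapping[str, RelationshipMatrix],
                variances: Mapping[str, float],
                include_pe: bool = True) -> SolutionSet:
    """Solve the mixed-model equations with the given variance components.

    ``variances`` maps each genetic term plus "pe" and "e" to a fixed value
    (typically posterior means from the Gibbs fit, or the known truth in
    simulation studies). Terms with zero variance are shrunk entirely to
    zero rather than entering a singular system.
    """
    spec = design.spec
    var_e = float(variances["e"])
    if var_e <= 0.0:
        raise ValueError("residual variance must be positive")

    terms = [t for t in spec.terms if float(variances.get(t, 0.0)) > 0.0]
    dropped = [t for t in spec.terms if t not in terms]
    pe_on = include_pe and float(variances.get("pe", 0.0)) > 0.0

    idx = design.indiv_index
    n_ind = design.n_individuals
    n_rec = design.n_records

    if design.f_record is not None:
        C = np.column_stack([design.X, design.f_record])
    else:
        C = design.X
    p = C.shape[1]

    blocks = [C]
    L_fact = {}
    for t in terms:
        if grms[t].n != n_ind:
            raise ValueError(f"relationship matrix {t!r} dimension mismatch")
        try:
            L = linalg.cholesky(grms[t].values, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError(
                f"relationship matrix for term {t!r} is singular; regularize first"
            ) from err
        L_fact[t] = L
        blocks.append(L[idx])
    if pe_on:
        Zpe = np.zeros((n_rec, n_ind))
        Zpe[np.arange(n_rec), idx] = 1.0
        blocks.append(Zpe)

    Q = np.hstack(blocks)
    penalties = np.concatenate(
        [np.zeros(p)]
        + [np.full(n_ind, var_e / float(variances[t])) for t in terms]
        + ([np.full(n_ind, var_e / float(variances["pe"]))] if pe_on else [])
    )
    lhs = Q.T @ Q + np.diag(penalties)
    rhs = Q.T @ design.y
    try:
        cf = linalg.cho_factor(lhs)
    except linalg.LinAlgError as err:
        raise ValueError(
            "mixed-model equations are singular; check the fixed-effect "
            "design and variance inputs"
        ) from err
    theta = linalg.cho_solve(cf, rhs)
    rel_resid = float(np.linalg.norm(lhs @ theta - rhs) / max(np.linalg.norm(rhs), 1e-300))

    beta_all = theta[:p]
    pos = p
    g = {}
    for t in terms:
        u = theta[pos:pos + n_ind]
        g[t] = L_fact[t] @ u
        pos += n_ind
    for t in dropped:
        g[t] = np.zeros(n_ind)
    pe = None
    if include_pe:
        pe = theta[pos:pos + n_ind] if pe_on else np.zeros(n_ind)

    if design.f_record is not None:
        beta, b = beta_all[:-1], float(beta_all[-1])
    else:
        beta, b = beta_all, None

    return SolutionSet(
        beta=beta, x_names=list(design.x_names), b=b,
        g={t: g[t] for t in spec.terms}, pe=pe,
        variances={k: float(v) for k, v in variances.items()},
        spec=spec, mme_relative_residual=rel_resid,
    )


def corrected_phenotype(design: DesignSet, solutions: SolutionSet) -> np.ndarray:
    """y* = y - X beta_hat - f b_hat, at record level."""
    out = design.y - design.X @ solutions.beta
    if design.f_record is not None and solutions.b is not None:
        out = out - design.f_record * solutions.b
    return out


def predict_observation(solutions: SolutionSet, spec: ModelSpec,
                        indiv_index: np.ndarray) -> np.ndarray:
    """y_hat = sum of the declared genetic terms plus pe, mapped to records.

    ``indiv_index`` positions each target record in the individual ordering
    used by the solve (candidates keep their genomic predictions; their
    permanent environmental effect is zero when they had no records).
    """
    for t in spec.terms:
        if t not in solutions.g:
            raise ValueError(f"term {t!r} missing from solutions")
    total = sum(solutions.g[t] for t in spec.terms)
    if solutions.pe is not None:
        total = total + solutions.pe
    return total[np.asarray(indiv_index)]
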