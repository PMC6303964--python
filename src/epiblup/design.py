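"""Model specification and record-level design construction.

The linear model for a record on sow i is

    y = X beta + f b + Z g_A + Z g_D + Z g_AA + Z g_AD + Z g_DD + Z pe + e

with dummy-coded parity and contemporary-group fixed effects, the genomic
homozygosity covariate f (inbreeding depression), individual-level genetic
effect vectors with genomic covariance structures, an iid permanent
environmental effect per sow, and iid residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import COMPONENTS
from .phenotypes import PhenotypeRecords

# successive nesting order of the five models
NESTING = COMPONENTS  # ("A", "D", "AA", "AD", "DD")


@dataclass(frozen=True)
class ModelSpec:
    """Which genetic terms are fitted; terms must nest successively
    (A, then D, then AA, AD, DD) as in the five-model ladder."""

    terms: tuple[str, ...] = ("A",)
    inbreeding_covariate: bool = True
    fixed_effects: tuple[str, ...] = ("parity", "group")

    def __post_init__(self) -> None:
        if tuple(self.terms) != NESTING[: len(self.terms)]:
            raise ValueError(
                f"genetic terms {self.terms} do not respect the nesting "
                f"{' -> '.join(NESTING)}"
            )

    @property
    def name(self) -> str:
        label = "+".join(self.terms)
        return label if self.inbreeding_covariate else label + " (no f)"


# the five nested models of the variance-partition ladder
MODEL_LADDER = tuple(ModelSpec(terms=NESTING[: k + 1]) for k in range(len(NESTING)))


@dataclass
class DesignSet:
    """Numeric design for one fit: response, fixed effects, covariate,
    and the record -> individual map (the Z matrix in sparse index form)."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    f_record: np.ndarray | None
    indiv_index: np.ndarray
    individual_ids: np.ndarray
    spec: ModelSpec
    records: PhenotypeRecords = field(repr=False)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def record_counts(self) -> np.ndarray:
        """Number of records per individual (diagonal of Z'Z); zero for
        genotyped individuals without phenotypes (e.g. validation candidates)."""
        return np.bincount(self.indiv_index, minlength=self.n_individuals).astype(float)


def build_design(records: PhenotypeRecords, spec: ModelSpec,
                 f: pd.Series, individual_ids) -> DesignSet:
    """Assemble y, X, the centered f covariate and the record->individual map.

    ``individual_ids`` fixes the individual ordering (normally the genotype
    matrix order); every record must belong to one of them. ``f`` is the
    per-individual genomic homozygosity, centered at its mean across the
    listed individuals before entering the design so the inbreeding
    depression slope is decoupled from the intercept.
    """
    individual_ids = np.asarray(individual_ids, dtype=object)
    df = records.df
    pos = pd.Series(np.arange(len(individual_ids)), index=individual_ids)
    unknown = ~df["individual_id"].isin(pos.index)
    if unknown.any():
        bad = df.loc[unknown, "individual_id"].iloc[0]
        raise ValueError(f"record refers to unknown/ungenotyped individual {bad!r}")
    indiv_index = pos[df["individual_id"]].to_numpy(dtype=np.int64)

    blocks = [pd.Series(1.0, index=df.index, name="intercept")]
    names = ["intercept"]
    for col in spec.fixed_effects:
        dummies = pd.get_dummies(df[col].astype("category"), prefix=col,
                                 drop_first=True, dtype=float)
        blocks.append(dummies)
        names.extend(dummies.columns)
    X = pd.concat(blocks, axis=1).to_numpy(dtype=float)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after reference "
                         "level constraints; check for confounded factors")

    f_record = None
    if spec.inbreeding_covariate:
        f_all = f.reindex(individual_ids)
        if f_all.isna().any():
            raise ValueError("inbreeding vector missing for some individuals")
        f_centered = f_all.to_numpy(dtype=float) - f_all.mean()
        f_record = f_centered[indiv_index]

    return DesignSet(
        y=df["y"].to_numpy(dtype=float),
        X=X,
        x_names=list(names),
        f_record=f_record,
        indiv_index=indiv_index,
        individual_ids=individual_ids,
        spec=spec,
        records=records,
    )
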