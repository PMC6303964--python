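"""End-to-end experiments: the five-model ladder, the inbreeding-covariate
contrast, and whole/partial validation, from one configuration object.

Relationship matrices are computed once per run and shared across models;
all randomness flows from the configured seeds, so a rerun with the same
configuration reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .blup import corrected_phenotype, predict_observation, solve_gblup
from .design import MODEL_LADDER, ModelSpec, build_design
from .genotypes import QCThresholds, allele_frequencies, apply_qc, genomic_inbreeding
from .gibbs import ChainConfig, gibbs_sample, variance_ratios
from .grm import build_grms
from .simulate import scenario_sow_litter
from .validation import ValidationReport, method_r, predictive_ability, time_split


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_individuals: int = 1000
    m_snps: int = 2000
    scenario_overrides: dict = field(default_factory=dict)
    chain: ChainConfig = field(default_factory=ChainConfig.short)
    qc: QCThresholds = field(default_factory=QCThresholds)
    models: tuple[str, ...] = tuple(m.name for m in MODEL_LADDER)
    cutoff_period: int = 2
    epsilon: float = 1e-6
    out_dir: str | None = None


def _model_by_name(name: str) -> ModelSpec:
    for m in MODEL_LADDER:
        if m.name == name:
            return m
    raise ValueError(f"unknown model {name!r}; expected one of "
                     f"{[m.name for m in MODEL_LADDER]}")


def _grm_hash(grms) -> str:
    h = hashlib.sha256()
    for k in sorted(grms):
        h.update(k.encode())
        h.update(np.ascontiguousarray(grms[k].values).tobytes())
    return h.hexdigest()[:16]


@dataclass
class PreparedData:
    genotypes: object
    records: object
    truth: object
    freqs: np.ndarray
    f: object
    grms: dict
    qc_report: object
    grm_hash: str


def prepare_data(config: PipelineConfig) -> PreparedData:
    """Simulate, QC and build all relationship matrices once."""
    genotypes, records, truth = scenario_sow_litter(
        config.seed, config.n_individuals, config.m_snps,
        **config.scenario_overrides)
    genotypes, qc_report = apply_qc(genotypes, config.qc)
    freqs = allele_frequencies(genotypes)
    f = genomic_inbreeding(genotypes)
    needed = set()
    for name in config.models:
        needed.update(_model_by_name(name).terms)
    grms = build_grms(genotypes, freqs, components=tuple(sorted(needed)),
                      epsilon=config.epsilon)
    return PreparedData(genotypes, records, truth, freqs, f, grms,
                        qc_report, _grm_hash(grms))


@dataclass
class ExperimentReport:
    summaries: dict                    # model name -> VarianceSummary
    orthogonality: dict
    dic_table: dict
    inbreeding_contrast: dict | None
    validation: dict | None
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "summaries": {k: v.as_dict() for k, v in self.summaries.items()},
            "orthogonality": self.orthogonality,
            "dic_table": self.dic_table,
            "inbreeding_contrast": self.inbreeding_contrast,
            "validation": self.validation,
            "provenance": self.provenance,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def run_nested_models(config: PipelineConfig,
                      data: PreparedData | None = None) -> ExperimentReport:
    """Fit the configured nested models on shared data and relationship
    matrices; report variance summaries, orthogonality deltas and DIC."""
    data = data or prepare_data(config)
    summaries = {}
    chains = {}
    for i, name in enumerate(config.models):
        spec = _model_by_name(name)
        design = build_design(data.records, spec, data.f,
                              data.genotypes.individual_ids)
        chain = gibbs_sample(design, data.grms,
                             replace(config.chain, seed=config.chain.seed + i))
        chains[name] = chain
        summaries[name] = variance_ratios(chain, spec)

    ortho = {}
    full = config.models[-1]
    if len(config.models) > 1:
        for comp, base_model in (("var_A", config.models[0]),
                                 ("var_D", "A+D" if "A+D" in config.models else None)):
            if base_model is None or comp not in summaries[full].component_mean:
                continue
            if comp not in summaries[base_model].component_mean:
                continue
            delta = (summaries[full].component_mean[comp]
                     - summaries[base_model].component_mean[comp])
            sd = summaries[base_model].component_sd[comp]
            ortho[comp] = {"base_model": base_model, "full_model": full,
                           "delta": delta, "posterior_sd": sd,
                           "delta_in_sd": delta / sd if sd > 0 else np.inf}

    dic_table = {name: {"dic": s.dic, "p_d": s.p_d}
                 for name, s in summaries.items()}
    report = ExperimentReport(
        summaries=summaries, orthogonality=ortho, dic_table=dic_table,
        inbreeding_contrast=None, validation=None,
        provenance=_provenance(config, data),
    )
    if config.out_dir:
        report.write(config.out_dir)
        for name, chain in chains.items():
            chain.to_tsv(Path(config.out_dir) / f"chain_{name.replace('+', '')}.tsv")
    return report


def run_inbreeding_contrast(config: PipelineConfig,
                            data: PreparedData | None = None) -> dict:
    """Fit the full model with and without the genomic-inbreeding covariate
    on identical data and relationship matrices (the GDIF vs GDI contrast)."""
    data = data or prepare_data(config)
    full = _model_by_name(config.models[-1])
    out = {}
    for label, spec in (("with_f", full),
                        ("without_f", replace(full, inbreeding_covariate=False))):
        design = build_design(data.records, spec, data.f,
                              data.genotypes.individual_ids)
        chain = gibbs_sample(design, data.grms, config.chain)
        out[label] = variance_ratios(chain, spec)
    out["grm_hash"] = data.grm_hash
    return out


def run_validation(config: PipelineConfig,
                   data: PreparedData | None = None,
                   models: tuple[str, ...] = ("A", "A+D", "A+D+AA+AD+DD"),
                   variances: dict | None = None) -> dict[str, ValidationReport]:
    """Whole/partial fits and method-R + predictive-ability statistics.

    Variance components are fixed for the GBLUP solves: either supplied
    per model, or estimated once per model from the whole data by Gibbs
    sampling.
    """
    data = data or prepare_data(config)
    plan = time_split(data.records, config.cutoff_period)
    ids = data.genotypes.individual_ids
    id_pos = {i: k for k, i in enumerate(ids)}
    cand_idx = np.array([id_pos[c] for c in plan.candidates])

    reports = {}
    for name in models:
        spec = _model_by_name(name)
        design_w = build_design(plan.whole, spec, data.f, ids)
        design_p = build_design(plan.partial, spec, data.f, ids)
        if variances is not None:
            # either one mapping per model name, or one flat component mapping
            v = variances[name] if isinstance(variances.get(name), dict) else variances
        else:
            chain = gibbs_sample(design_w, data.grms, config.chain)
            s = variance_ratios(chain, spec)
            v = {t: s.component_mean[f"var_{t}"] for t in spec.terms}
            v["pe"] = s.component_mean["var_pe"]
            v["e"] = s.component_mean["var_e"]
        sol_w = solve_gblup(design_w, data.grms, v)
        sol_p = solve_gblup(design_p, data.grms, v)
        b0, b1, rho = method_r(sol_w.g["A"][cand_idx], sol_p.g["A"][cand_idx])
        sigma_a = float(np.sqrt(v["A"]))
        # predictive ability over the candidates' (future) records
        cand_mask = design_w.records.df["individual_id"].isin(plan.candidates).to_numpy()
        y_star = corrected_phenotype(design_w, sol_w)[cand_mask]
        y_hat = predict_observation(sol_p, spec,
                                    design_w.indiv_index[cand_mask])
        corr, slope = predictive_ability(y_star, y_hat)
        reports[name] = ValidationReport(
            model=name, b0=b0, b0_in_sigma_a=b0 / sigma_a, b1=b1, rho=rho,
            predictive_correlation=corr, predictive_slope=slope,
            n_candidates=len(plan.candidates),
        )
    return reports


def _provenance(config: PipelineConfig, data: PreparedData) -> dict:
    cfg = asdict(config)
    cfg["chain"] = asdict(config.chain)
    cfg["qc"] = asdict(config.qc)
    return {
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "grm_hash": data.grm_hash,
        "n_records": len(data.records),
        "n_individuals": data.genotypes.n_individuals,
        "n_snps": data.genotypes.n_snps,
    }
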