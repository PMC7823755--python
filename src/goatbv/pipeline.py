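"""End-to-end validation pipeline: fit both models, compare accuracies.

``run_validation`` performs the whole protocol on one herd for one trait:
age split, pedigree BLUP and single-step BayesC fits on the training
records, scenario classification of the validation animals, the
masked-pedigree rerun for the no-pedigree scenario, base standardization,
the inflation slope, and the combined breed-effect report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .data_prep import GenotypeSet, LactationRecord
from .evaluation import (
    ComparisonReport,
    ValidationDesign,
    age_split,
    classify_scenarios,
    combine_breed_and_J,
    inflation_slope,
    mask_parents,
    percent_gain,
    standardize_to_base,
)
from .pblup import EvaluationResult, build_design, solve_mme
from .pedigree import Pedigree, breed_composition, invert_A
from .ssbc import McmcRun, build_ssbc_model, geweke, gibbs_chain, gbv


@dataclass
class ValidationOutcome:
    """Everything one validation run produced."""

    report: ComparisonReport
    design: ValidationDesign
    ebv: EvaluationResult
    gbv: EvaluationResult
    ebv_masked: EvaluationResult | None
    gbv_masked: EvaluationResult | None
    run: McmcRun
    geweke_z: dict[str, float]


def fit_pblup(
    records: list[LactationRecord],
    pedigree: Pedigree,
    config: RunConfig,
    composition=None,
) -> EvaluationResult:
    """Fit the pedigree model on the given records."""
    comp = composition if composition is not None else breed_composition(pedigree)
    model = build_design(records, comp, pedigree, config.trait, config.variances)
    return solve_mme(model, invert_A(pedigree))


def fit_ssbc(
    records: list[LactationRecord],
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    config: RunConfig,
    composition=None,
) -> tuple[EvaluationResult, McmcRun, "object"]:
    """Fit the single-step model on the given records; returns result, chain,
    and the assembled model."""
    comp = composition if composition is not None else breed_composition(pedigree)
    model = build_ssbc_model(
        records, pedigree, comp, genotypes, config.trait, config.variances,
        pi=config.pi, w=config.w,
    )
    run = gibbs_chain(
        model,
        chain_length=config.chain.length,
        burn_in=config.chain.burn_in,
        thin=config.chain.thin,
        seed=config.chain.seed,
        fixed_variances=config.fixed_variances,
    )
    return gbv(run, model), run, model


def run_validation(
    records: list[LactationRecord],
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    config: RunConfig,
    include_masked: bool = True,
) -> ValidationOutcome:
    """The full accuracy-validation protocol for one trait."""
    herd = [(r.animal_id, pedigree.birth_order(r.animal_id)) for r in records]
    design = age_split(herd, config.training_fraction)
    training = set(design.training_ids)
    train_records = [r for r in records if r.animal_id in training]
    phenotyped = {r.animal_id for r in records}

    comp = breed_composition(pedigree)
    ebv_res = fit_pblup(train_records, pedigree, config, comp)
    gbv_res, run, model = fit_ssbc(train_records, pedigree, genotypes, config, comp)

    labels = classify_scenarios(
        design, pedigree, phenotyped,
        min_progeny=config.min_sire_progeny,
        min_dam_lactations=config.min_dam_lactations,
    )
    counts = {
        lab: sum(1 for s in labels.values() if lab in s) for lab in ("A", "B", "C", "D")
    }

    acc_e = dict(zip(ebv_res.animal_ids, ebv_res.accuracy))
    acc_g = dict(zip(gbv_res.animal_ids, gbv_res.accuracy))
    val = design.validation_ids
    mean_e = float(np.mean([acc_e[a] for a in val]))
    mean_g = float(np.mean([acc_g[a] for a in val]))
    scen_acc = {
        lab: {
            "ebv": float(np.mean([acc_e[a] for a in val if lab in labels[a]]))
            if counts[lab] else float("nan"),
            "gbv": float(np.mean([acc_g[a] for a in val if lab in labels[a]]))
            if counts[lab] else float("nan"),
        }
        for lab in ("A", "B", "C")
    }

    ebv_masked = gbv_masked = None
    if include_masked:
        targets = {a for a in val if "A" in labels[a]}
        masked_ped = mask_parents(pedigree, targets)
        design.masked_pedigree = masked_ped
        masked_comp = breed_composition(masked_ped)
        ebv_masked = fit_pblup(train_records, masked_ped, config, masked_comp)
        gbv_masked, _run_m, _model_m = fit_ssbc(
            train_records, masked_ped, genotypes, config, masked_comp
        )
        am_e = dict(zip(ebv_masked.animal_ids, ebv_masked.accuracy))
        am_g = dict(zip(gbv_masked.animal_ids, gbv_masked.accuracy))
        d_ids = sorted(targets | {a for a in val if "D" in labels[a]})
        scen_acc["D"] = {
            "ebv": float(np.mean([am_e[a] for a in d_ids])) if d_ids else float("nan"),
            "gbv": float(np.mean([am_g[a] for a in d_ids])) if d_ids else float("nan"),
        }
        counts["D"] = len(d_ids)

    # standardized comparison on the scenario-A animals (richest pedigree)
    ids = ebv_res.animal_ids
    base = set(design.training_ids)
    e_std = standardize_to_base(ebv_res.bv, ids, base)
    g_std = standardize_to_base(gbv_res.bv, ids, base)
    a_ids = [a for a in val if "A" in labels[a]]
    sel = [ids.index(a) for a in (a_ids if len(a_ids) >= 3 else val)]
    slope, corr = inflation_slope(g_std[sel], e_std[sel])

    combined = combine_breed_and_J(
        d_hat={"saanen": 0.0,
               "anto": float(run.d_draws().mean(axis=0)[0]),
               "unknown": float(run.d_draws().mean(axis=0)[1])},
        q_hat=(
            {n.removeprefix("q_"): float(v)
             for n, v in zip(run.col_names[run.q_cols], run.beta.mean(axis=0)[run.q_cols])}
            if model.include_J
            else {"saanen": 0.0, "anto": 0.0, "unknown": 0.0}
        ),
        d_draws=run.d_draws(),
        q_draws=run.q_draws() if model.include_J else np.zeros((run.n_retained, 3)),
    )

    tracer = int(np.argmax(np.abs(run.alpha.mean(axis=0)))) if run.alpha.size else 0
    gz = {
        "sigma_e2": geweke(run.sigma_e2) if run.n_retained >= 100 else float("nan"),
        "sigma_g2": geweke(run.sigma_g2) if run.n_retained >= 100 else float("nan"),
        "tracer_marker": geweke(run.alpha[:, tracer])
        if run.alpha.size and run.n_retained >= 100 else float("nan"),
    }

    report = ComparisonReport(
        trait=config.trait,
        n_validation=len(val),
        mean_ebv_accuracy=mean_e,
        mean_gbv_accuracy=mean_g,
        gain_percent=percent_gain(mean_e, mean_g) if mean_e > 0 else None,
        slope=slope,
        correlation=corr,
        scenario_accuracies=scen_acc,
        scenario_counts=counts,
        combined_breed_effects=combined,
    )
    return ValidationOutcome(
        report=report,
        design=design,
        ebv=ebv_res,
        gbv=gbv_res,
        ebv_masked=ebv_masked,
        gbv_masked=gbv_masked,
        run=run,
        geweke_z=gz,
    )


def plot_inflation(outcome: ValidationOutcome, path) -> None:
    """Scatter of standardized GBV against standardized EBV with the OLS fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = outcome.ebv.animal_ids
    base = set(outcome.design.training_ids)
    e = standardize_to_base(outcome.ebv.bv, ids, base)
    g = standardize_to_base(outcome.gbv.bv, ids, base)
    labels = outcome.design.scenario_labels
    val = outcome.design.validation_ids
    a_ids = [a for a in val if "A" in labels.get(a, set())] or val
    sel = [ids.index(a) for a in a_ids]
    x, y = e[sel], g[sel]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=12, alpha=0.6)
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, outcome.report.slope * xs + (y.mean() - outcome.report.slope * x.mean()),
            color="crimson",
            label=f"slope {outcome.report.slope:.2f}, r {outcome.report.correlation:.2f}")
    ax.set_xlabel("standardized EBV")
    ax.set_ylabel("standardized GBV")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
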