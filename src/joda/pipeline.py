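"""End-to-end orchestration of the three-step deregulation analysis.

Step 1 fits the belief mixture to each experiment's log ratios and signs
the posteriors; step 2 averages signed probabilities over each regulator's
affecting experiments (regulation scores, per population); step 3 subtracts
the populations' regulation scores (deregulation scores).  Optional stages
add the permutation test and best-hyper enrichment.  File-based runs write
every score matrix plus a manifest recording versions, seeds and a config
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as jio
from .enrichment import best_hyper_test, results_table
from .mixture import BeliefSet, MixtureFit, fit_belief_mixture, signed_probabilities
from .pathway import PathwayModel, PathwayTopology, build_model
from .scoring import (
    average_deregulation,
    decorrelation_scores,
    deregulation_scores,
    regulation_scores,
    sort_deregulation_list,
)
from .significance import permutation_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "signed_probability_matrix",
           "analyze", "run_joda"]

EXIT_INPUT_ERROR = 2
EXIT_NUMERICAL_ERROR = 3


@dataclass
class RunConfig:
    """Configuration of a file-based run.

    ``population_first`` is subtracted from ``population_second`` when
    forming deregulation scores (conventionally healthy from damaged).
    """

    ratios_first: str = ""
    ratios_second: str = ""
    topology_first: str = ""
    topology_second: str = ""
    regulators_file: str = ""
    beliefs_file: str | None = None
    replicates_first: str | None = None
    replicates_second: str | None = None
    population_first: str = "h"
    population_second: str = "d"
    default_belief: float = 0.95
    mixture: dict = field(default_factory=dict)
    run_permutation: bool = True
    n_permutations: int = 1000
    seed: int = 0
    permutation_scheme: str = "global"
    run_enrichment: bool = False
    gene_sets_file: str | None = None
    k_min: int = 10
    k_max: int = 500
    k_stride: int = 1
    universe: int | None = None
    enrichment_cutoff: float = 1e-5
    min_gene_overlap: int = 1
    output_dir: str = "joda_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """In-memory outputs of one analysis."""

    signed_probabilities: dict[str, pd.DataFrame]  # pop -> genes x experiments
    regulation: dict[str, pd.DataFrame]            # pop -> genes x regulators
    deregulation: pd.DataFrame                     # genes x regulators
    average_deregulation: pd.Series
    fits: dict[str, MixtureFit]                    # experiment id -> fit
    p_values: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    decorrelation: pd.DataFrame | None = None


def signed_probability_matrix(
    ratios: pd.DataFrame,
    model: PathwayModel,
    beliefs: list[BeliefSet] | None = None,
    mixture_config: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Step 1 for one population: fit the mixture per experiment and sign it.

    Belief sets are matched to experiments by regulator (the known targets
    of a regulator inform its own knock-down experiment only).
    """
    mixture_config = mixture_config or {}
    by_regulator = {
        bs.regulator: bs
        for bs in (beliefs or [])
        if bs.population == model.population
    }
    P = pd.DataFrame(index=ratios.index, columns=list(model.experiments),
                     dtype=float)
    fits: dict[str, MixtureFit] = {}
    for exp, reg in zip(model.experiments, model.regulators):
        if exp not in ratios.columns:
            raise KeyError(
                f"ratio matrix for population {model.population!r} lacks "
                f"experiment column {exp!r}"
            )
        fit = fit_belief_mixture(
            ratios[exp], by_regulator.get(reg),
            experiment=exp, population=model.population, **mixture_config,
        )
        P[exp] = signed_probabilities(fit, ratios[exp])
        fits[exp] = fit
        logger.info("%s", fit.summary())
    return P, fits


def analyze(
    ratios_first: pd.DataFrame,
    ratios_second: pd.DataFrame,
    topology_first: PathwayTopology,
    topology_second: PathwayTopology,
    beliefs: list[BeliefSet] | None = None,
    mixture_config: dict | None = None,
    run_permutation: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
    permutation_scheme: str = "global",
    min_gene_overlap: int = 1,
) -> AnalysisResult:
    """Run the three analysis steps on in-memory inputs.

    Deregulation is second-population minus first-population.  Genes absent
    from either ratio matrix are dropped (their count logged); the run
    aborts if fewer than ``min_gene_overlap`` genes remain.
    """
    if tuple(topology_first.regulators) != tuple(topology_second.regulators):
        raise ValueError(
            "topologies must share the regulator set; got "
            f"{list(topology_first.regulators)} vs "
            f"{list(topology_second.regulators)}"
        )
    common = ratios_first.index.intersection(ratios_second.index)
    dropped = (len(ratios_first) - len(common)) + (
        len(ratios_second) - len(common))
    if dropped:
        logger.info("dropped %d gene row(s) absent from one population", dropped)
    if len(common) < min_gene_overlap:
        raise ValueError(
            f"only {len(common)} gene(s) shared between the populations "
            f"(floor {min_gene_overlap})"
        )
    ratios_first = ratios_first.loc[common]
    ratios_second = ratios_second.loc[common]

    model_first = build_model(topology_first)
    model_second = build_model(topology_second)
    P_first, fits_first = signed_probability_matrix(
        ratios_first, model_first, beliefs, mixture_config)
    P_second, fits_second = signed_probability_matrix(
        ratios_second, model_second, beliefs, mixture_config)
    R_first = regulation_scores(P_first, model_first)
    R_second = regulation_scores(P_second, model_second)
    D = deregulation_scores(R_second, R_first)
    result = AnalysisResult(
        signed_probabilities={
            model_first.population: P_first,
            model_second.population: P_second,
        },
        regulation={
            model_first.population: R_first,
            model_second.population: R_second,
        },
        deregulation=D,
        average_deregulation=average_deregulation(D),
        fits={**fits_first, **fits_second},
    )
    if run_permutation:
        perm = permutation_test(
            P_first, P_second, model_first, model_second,
            B=n_permutations, seed=seed, scheme=permutation_scheme,
        )
        result.p_values = perm.p_values
    return result


def run_joda(config: RunConfig) -> AnalysisResult:
    """File-based end-to-end run: read inputs, analyze, write all outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    topo_first = jio.read_topology(
        config.topology_first, config.regulators_file, config.population_first)
    topo_second = jio.read_topology(
        config.topology_second, config.regulators_file, config.population_second)
    ratios_first = jio.read_matrix(config.ratios_first)
    ratios_second = jio.read_matrix(config.ratios_second)
    beliefs = (
        jio.read_beliefs(config.beliefs_file, config.default_belief)
        if config.beliefs_file else None
    )
    result = analyze(
        ratios_first, ratios_second, topo_first, topo_second,
        beliefs=beliefs, mixture_config=dict(config.mixture),
        run_permutation=config.run_permutation,
        n_permutations=config.n_permutations,
        seed=config.seed,
        permutation_scheme=config.permutation_scheme,
        min_gene_overlap=config.min_gene_overlap,
    )

    for pop, P in result.signed_probabilities.items():
        jio.write_matrix(P, out / f"signed_probabilities_{pop}.tsv")
    for pop, R in result.regulation.items():
        jio.write_matrix(R, out / f"regulation_{pop}.tsv")
    jio.write_matrix(result.deregulation, out / "deregulation.tsv")
    jio.write_ranked_list(
        result.average_deregulation.sort_values(ascending=False),
        out / "deregulation_average_ranked.tsv",
    )
    for reg in result.deregulation.columns:
        jio.write_ranked_list(
            sort_deregulation_list(result.deregulation, reg),
            out / f"deregulation_ranked_{reg}.tsv",
        )
    with open(out / "mixture_fits.txt", "wt", encoding="utf-8") as fh:
        for fit in result.fits.values():
            fh.write(fit.summary() + "\n")
    if result.p_values is not None:
        jio.write_matrix(result.p_values, out / "permutation_pvalues.tsv")

    if (config.replicates_first and config.replicates_second):
        expr_first = jio.read_matrix(config.replicates_first)
        expr_second = jio.read_matrix(config.replicates_second)
        result.decorrelation = decorrelation_scores(
            expr_first, expr_second, list(topo_first.regulators)
        )
        jio.write_matrix(result.decorrelation, out / "decorrelation.tsv")

    if config.run_enrichment and config.gene_sets_file:
        sets = jio.read_gmt(config.gene_sets_file)
        ranked = result.average_deregulation.sort_values(ascending=False)
        enr = best_hyper_test(
            ranked, sets,
            k_range=range(config.k_min, config.k_max + 1, config.k_stride),
            universe=config.universe,
            cutoff=config.enrichment_cutoff,
        )
        result.enrichment = results_table(enr)
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "joda_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "permutation_scheme": config.permutation_scheme,
        "n_permutations": config.n_permutations,
        "config_hash": config.hash(),
        "config": asdict(config),
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
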