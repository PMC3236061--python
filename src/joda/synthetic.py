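"""Synthetic two-population perturbation datasets with planted ground truth.

The generator emulates the data-generating mechanism the method assumes: a
small set of regulators is knocked down one at a time in two cell
populations; each regulator carries a signed target set per population, and
a target responds (log ratio ``s * mu`` plus noise) in exactly the
experiments that affect its regulator under that population's pathway
model.  Population-specific re-wiring of the target sets plants genes whose
regulation differs between the populations — the ground-truth deregulated
genes every downstream stage can be validated against.

Default conditions: 500 genes, the three-regulator hub pathway (active in
the damaged population only), 40 targets per regulator, effect size mu = 2
with effect noise sd 0.4 over background noise sd 0.3, a quarter of the
targets re-wired, and replicate-level matrices with three arrays per
knock-down plus six controls per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import BeliefSet
from .pathway import PathwayModel, PathwayTopology, build_model, experiment_id
from . import io as jio

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset",
           "generate", "four_gene_fixture"]

_HUB_REGULATORS = ("ATM", "RelA", "p53")
_HUB_EDGES_D = (("ATM", "RelA"), ("ATM", "p53"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation conditions; defaults are the standard study conditions."""

    n_genes: int = 500
    regulators: tuple[str, ...] = _HUB_REGULATORS
    edges_h: tuple[tuple[str, str], ...] = ()
    edges_d: tuple[tuple[str, str], ...] = _HUB_EDGES_D
    population_h: str = "h"
    population_d: str = "d"
    targets_per_regulator: int = 40
    up_fraction: float = 0.5
    effect_size: float = 2.0       # mu, log-ratio units
    effect_sd: float = 0.4         # sigma1
    background_sd: float = 0.3     # sigma0
    rewire_fraction: float = 0.25
    contamination: float = 0.0     # fraction of decoys in belief lists
    belief: float = 0.95
    replicates_per_knockdown: int = 3
    control_replicates: int = 6
    array_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    knockdown_drop: float = 2.0    # regulator's own expression drop
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("effect_sd", "background_sd", "array_sd", "baseline_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination rate must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted signed target sets; deregulation truth is derived, not stored."""

    targets: dict[str, dict[str, dict[str, int]]]  # pop -> reg -> gene -> sign
    effect_size: float

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.targets)

    def deregulated_genes(self) -> frozenset[str]:
        """Genes whose signed-target status differs between the populations.

        The symmetric difference of signed memberships, over all regulators.
        """
        pop_a, pop_b = self.populations
        dereg: set[str] = set()
        regs = set(self.targets[pop_a]) | set(self.targets[pop_b])
        for reg in regs:
            a = self.targets[pop_a].get(reg, {})
            b = self.targets[pop_b].get(reg, {})
            dereg |= {g for g in set(a) | set(b) if a.get(g) != b.get(g)}
        return frozenset(dereg)

    def frame(self) -> pd.DataFrame:
        rows = [
            (gene, pop, reg, sign)
            for pop, per_reg in self.targets.items()
            for reg, genes in per_reg.items()
            for gene, sign in sorted(genes.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene", "population", "regulator", "sign"]
        )


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SyntheticConfig
    ratios: dict[str, pd.DataFrame]       # pop -> genes x experiments
    replicates: dict[str, pd.DataFrame]   # pop -> (regulators+genes) x arrays
    beliefs: list[BeliefSet]
    topologies: dict[str, PathwayTopology]
    truth: SyntheticTruth

    @property
    def models(self) -> dict[str, PathwayModel]:
        return {pop: build_model(t) for pop, t in self.topologies.items()}

    def write(self, directory) -> None:
        """Emit every file the pipeline reads, plus the truth table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for pop, df in self.ratios.items():
            jio.write_matrix(df, directory / f"ratios_{pop}.tsv")
        for pop, df in self.replicates.items():
            jio.write_matrix(df, directory / f"replicates_{pop}.tsv")
        for pop, topo in self.topologies.items():
            jio.write_topology(
                topo,
                directory / f"topology_{pop}.tsv",
                directory / "regulators.tsv",
            )
        jio.write_beliefs(self.beliefs, directory / "beliefs.tsv")
        jio.write_truth(self.truth.frame(), directory / "truth.tsv")


def _planted_effects(
    genes: list[str],
    model: PathwayModel,
    targets: dict[str, dict[str, int]],
    mu: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted mean log-ratio and target mask, genes x experiments.

    A gene targeted by several regulators affected by one experiment sums
    their effects (logged when the signs cancel).
    """
    gpos = {g: i for i, g in enumerate(genes)}
    n_exp = len(model.experiments)
    effect = np.zeros((len(genes), n_exp))
    is_target = np.zeros((len(genes), n_exp), dtype=bool)
    for j, exp in enumerate(model.experiments):
        affected = [
            v for v in model.regulators if model.matrix.loc[exp, v] == 1
        ]
        for v in affected:
            for g, sign in targets.get(v, {}).items():
                effect[gpos[g], j] += sign * mu
                is_target[gpos[g], j] = True
    cancelled = int((is_target & (effect == 0)).sum())
    if cancelled:
        logger.info(
            "%d (gene, experiment) pair(s) with cancelling multi-regulator "
            "effects in population %r", cancelled, model.population,
        )
    return effect, is_target


def _draw_targets(
    rng: np.random.Generator,
    genes: list[str],
    config: SyntheticConfig,
) -> dict[str, dict[str, dict[str, int]]]:
    """Healthy target sets, then a re-wired copy for the damaged population."""
    def _sign() -> int:
        return 1 if rng.random() < config.up_fraction else -1

    targets_h: dict[str, dict[str, int]] = {}
    for reg in config.regulators:
        chosen = rng.choice(genes, size=config.targets_per_regulator,
                            replace=False)
        targets_h[reg] = {g: _sign() for g in chosen}
    targets_d = {reg: dict(t) for reg, t in targets_h.items()}
    n_rewire = round(config.rewire_fraction * config.targets_per_regulator)
    for reg in config.regulators:
        rewired = rng.choice(
            sorted(targets_d[reg]), size=n_rewire, replace=False
        )
        for g in rewired:
            if rng.random() < 0.5:
                targets_d[reg][g] = -targets_d[reg][g]  # sign flip
            else:
                del targets_d[reg][g]  # membership swap to a fresh gene
                pool = [x for x in genes
                        if x not in targets_d[reg] and x not in targets_h[reg]]
                targets_d[reg][str(rng.choice(pool))] = _sign()
    return {config.population_h: targets_h, config.population_d: targets_d}


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate a full two-population dataset with planted truth.

    Reproducible from ``config.seed``: ratio matrices for both populations,
    replicate-level expression matrices for the decorrelation baseline,
    belief lists (optionally contaminated with decoys), topology objects
    and the planted signed target sets.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    topologies = {
        config.population_h: PathwayTopology(
            config.population_h, config.regulators, config.edges_h),
        config.population_d: PathwayTopology(
            config.population_d, config.regulators, config.edges_d),
    }
    models = {pop: build_model(t) for pop, t in topologies.items()}
    per_pop_targets = _draw_targets(rng, genes, config)
    truth = SyntheticTruth(targets=per_pop_targets,
                           effect_size=config.effect_size)

    ratios: dict[str, pd.DataFrame] = {}
    planted: dict[str, np.ndarray] = {}
    for pop, model in models.items():
        effect, is_target = _planted_effects(
            genes, model, per_pop_targets[pop], config.effect_size
        )
        noise_sd = np.where(is_target, config.effect_sd, config.background_sd)
        values = effect + rng.normal(0.0, noise_sd)
        ratios[pop] = pd.DataFrame(
            values, index=genes, columns=list(model.experiments)
        )
        planted[pop] = effect

    replicates: dict[str, pd.DataFrame] = {}
    all_rows = list(config.regulators) + genes
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(all_rows)),
        index=all_rows,
    )
    for pop, model in models.items():
        effect, _ = _planted_effects(
            genes, model, per_pop_targets[pop], config.effect_size
        )
        cols: dict[str, np.ndarray] = {}
        for j, (exp, reg) in enumerate(
            zip(model.experiments, model.regulators)
        ):
            for r in range(1, config.replicates_per_knockdown + 1):
                mean = baseline.to_numpy(dtype=float).copy()
                mean[len(config.regulators):] += effect[:, j]
                mean[list(config.regulators).index(reg)] -= config.knockdown_drop
                cols[f"{exp}:rep{r}"] = mean + rng.normal(
                    0.0, config.array_sd, len(all_rows)
                )
        for r in range(1, config.control_replicates + 1):
            cols[f"{pop}:ctrl:rep{r}"] = baseline.to_numpy(
                dtype=float
            ) + rng.normal(0.0, config.array_sd, len(all_rows))
        replicates[pop] = pd.DataFrame(cols, index=all_rows)

    beliefs: list[BeliefSet] = []
    for pop in (config.population_h, config.population_d):
        for reg in config.regulators:
            true_targets = sorted(per_pop_targets[pop][reg])
            n_true = round((1.0 - config.contamination) * len(true_targets))
            listed = list(rng.choice(true_targets, size=n_true, replace=False))
            n_decoys = len(true_targets) - n_true
            if n_decoys:
                pool = [g for g in genes if g not in per_pop_targets[pop][reg]]
                listed += list(rng.choice(pool, size=n_decoys, replace=False))
            beliefs.append(BeliefSet(
                population=pop, regulator=reg,
                entries={g: config.belief for g in sorted(listed)},
                default_belief=config.belief,
            ))
    return SyntheticDataset(
        config=config, ratios=ratios, replicates=replicates,
        beliefs=beliefs, topologies=topologies, truth=truth,
    )


def four_gene_fixture(n_background: int = 96) -> SyntheticDataset:
    """Deterministic miniature dataset encoding the four canonical gene fates.

    Four focal genes probe the hub pathway (inactive in the healthy
    population ``h``, ATM signalling to RelA and p53 in the damaged
    population ``d``):

    * ``g1`` — up-regulated upon RelA perturbation in ``h``, down-regulated
      in the RelA-affecting experiments of ``d`` (regulation switched);
    * ``g2`` — up-regulated upon RelA perturbation in ``h``, unaffected in
      ``d`` (regulation lost);
    * ``g3`` — the same response in both populations (not deregulated);
    * ``g4`` — unaffected everywhere (pathway-independent).

    A deterministic background (null genes plus a few model-independent
    responders per experiment) makes each experiment's ratio vector large
    enough for mixture fitting; the discrimination claim concerns the focal
    genes only.  Repeated calls return identical data.
    """
    config = SyntheticConfig(
        n_genes=4 + n_background,
        targets_per_regulator=2,
        rewire_fraction=0.5,
        seed=1859,
    )
    rng = np.random.default_rng(config.seed)
    topologies = {
        "h": PathwayTopology("h", _HUB_REGULATORS, ()),
        "d": PathwayTopology("d", _HUB_REGULATORS, _HUB_EDGES_D),
    }
    focal = ["g1", "g2", "g3", "g4"]
    background = [f"b{i:03d}" for i in range(1, n_background + 1)]
    genes = focal + background
    n_responders = max(4, n_background // 6)
    responders = background[:n_responders]

    mu = config.effect_size
    ratios: dict[str, pd.DataFrame] = {}
    for pop, topo in topologies.items():
        model = build_model(topo)
        df = pd.DataFrame(0.0, index=genes, columns=list(model.experiments))
        noise = rng.normal(0.0, config.background_sd,
                           size=(len(background), len(model.experiments)))
        df.loc[background, :] = noise
        # model-independent responders: one strong response per population,
        # magnitudes jittered so no mixture component degenerates to a
        # point mass of identical values
        for g in responders:
            exp = str(rng.choice(model.experiments))
            sign = 1 if rng.random() < 0.5 else -1
            df.loc[g, exp] = sign * (mu + rng.normal(0.0, config.effect_sd))
        e = {r: experiment_id(pop, r) for r in _HUB_REGULATORS}
        if pop == "h":
            df.loc["g1", e["RelA"]] = +mu
            df.loc["g2", e["RelA"]] = +mu
            df.loc["g3", e["RelA"]] = +mu
        else:
            df.loc["g1", [e["ATM"], e["RelA"]]] = -mu
            df.loc["g3", [e["ATM"], e["RelA"]]] = +mu
        # g4 stays exactly zero everywhere
        df.loc["g4", :] = 0.0
        ratios[pop] = df

    truth = SyntheticTruth(
        targets={
            "h": {"RelA": {"g1": 1, "g2": 1, "g3": 1}},
            "d": {"RelA": {"g1": -1, "g3": 1}},
        },
        effect_size=mu,
    )
    return SyntheticDataset(
        config=config, ratios=ratios, replicates={}, beliefs=[],
        topologies=topologies, truth=truth,
    )
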