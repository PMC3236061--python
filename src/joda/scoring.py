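"""Regulation, deregulation and decorrelation scores.

Given a genes x experiments matrix of signed differential-expression
probabilities P and a pathway model, the *regulation score* of gene g for
regulator v is the mean of g's signed probabilities over the experiments
that affect v (the regulator's own knock-down plus its upstream
activators').  Negative scores indicate (possibly indirect) activation of
the gene by the regulator, positive scores inhibition: a gene activated by
v goes down when v is knocked out, so its signed probabilities are
negative.  Regulation scores lie in [-1, 1].

The *deregulation score* is the difference of a gene's regulation scores
between the two cell populations (second minus first, conventionally
damaged minus healthy) and lies in [-2, 2]; genes more activated in the
damaged cells obtain negative scores.

The *decorrelation score* is the knowledge-free baseline: the difference of
Pearson correlations between a regulator's and a gene's expression profiles
in the two populations (healthy minus damaged), also in [-2, 2].
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .pathway import PathwayModel, affecting_experiments

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "regulation_scores",
    "deregulation_scores",
    "average_deregulation",
    "decorrelation_scores",
    "sort_deregulation_list",
]


class AlignmentError(ValueError):
    """Two score matrices do not share the same gene/regulator indexing."""


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        only_a_rows = sorted(set(a.index) - set(b.index))
        only_b_rows = sorted(set(b.index) - set(a.index))
        only_a_cols = sorted(set(a.columns) - set(b.columns))
        only_b_cols = sorted(set(b.columns) - set(a.columns))
        raise AlignmentError(
            f"{what} are not aligned; genes only in first: {only_a_rows[:5]}, "
            f"only in second: {only_b_rows[:5]}; columns only in first: "
            f"{only_a_cols}, only in second: {only_b_cols}"
        )


def regulation_scores(P: pd.DataFrame, model: PathwayModel) -> pd.DataFrame:
    """Average signed probabilities over each regulator's affecting experiments.

    Parameters
    ----------
    P:
        Genes x experiments matrix of signed probabilities in [-1, 1];
        columns must carry the model's experiment identifiers.
    model:
        Pathway model of the same population.

    Returns
    -------
    DataFrame
        Genes x regulators matrix of regulation scores in [-1, 1].  Missing
        probabilities are dropped from the average; a gene with no observed
        probability across an affecting set gets a missing score (warned).
    """
    missing_cols = [e for e in model.experiments if e not in P.columns]
    if missing_cols:
        raise AlignmentError(
            f"signed-probability matrix lacks experiment column(s) "
            f"{missing_cols} required by the {model.population!r} pathway model"
        )
    out = pd.DataFrame(index=P.index, columns=list(model.regulators), dtype=float)
    for v in model.regulators:
        exps = list(affecting_experiments(model, v).experiments)
        out[v] = P[exps].mean(axis=1)  # skips NaN; all-NaN -> NaN
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} regulation score(s) missing (no observed signed "
            "probability across the affecting experiments)", UserWarning,
        )
    return out


def deregulation_scores(
    R_second: pd.DataFrame, R_first: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise difference of regulation scores between the populations.

    ``R_second`` minus ``R_first`` — by convention damaged minus healthy, so
    genes more activated in the damaged cells (lower regulation score there)
    obtain negative deregulation scores.  Scores lie in [-2, 2].
    """
    _check_aligned(R_second, R_first, "regulation-score matrices")
    return R_second - R_first


def average_deregulation(D: pd.DataFrame) -> pd.Series:
    """Per-gene deregulation averaged over the regulators.

    The default ranking statistic for enrichment of deregulated gene sets.
    """
    return D.mean(axis=1)


def decorrelation_scores(
    expr_h: pd.DataFrame,
    expr_d: pd.DataFrame,
    regulators: list[str],
) -> pd.DataFrame:
    """Knowledge-free baseline: difference of regulator-gene Pearson correlations.

    For each regulator and gene, the Pearson correlation of their expression
    profiles across arrays is computed within each population; the score is
    the healthy-cell correlation minus the damaged-cell correlation, so
    strongly negative scores indicate more activation in the damaged cells.

    Parameters
    ----------
    expr_h, expr_d:
        Genes x arrays replicate-level expression matrices; both must
        contain a row for every regulator and every gene, with >= 3 arrays.
    regulators:
        Regulator gene ids.

    Returns
    -------
    DataFrame
        Genes x regulators decorrelation scores in [-2, 2].  Zero-variance
        profiles give missing correlations (warned).
    """
    for name, expr in (("healthy", expr_h), ("damaged", expr_d)):
        if expr.shape[1] < 3:
            raise ValueError(
                f"insufficient replication: {name} expression matrix has "
                f"{expr.shape[1]} arrays, need >= 3"
            )
        absent = [r for r in regulators if r not in expr.index]
        if absent:
            raise KeyError(
                f"regulator row(s) {absent} absent from the {name} "
                "expression matrix"
            )

    if not expr_d.index.equals(expr_h.index):
        raise AlignmentError(
            "healthy and damaged expression matrices must share the same "
            "gene rows in the same order"
        )

    def _corr(expr: pd.DataFrame) -> np.ndarray:
        x = expr.to_numpy(dtype=float)
        centred = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred**2).sum(axis=1))
        zero = norms == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance expression profile(s); "
                "their correlations are reported missing", UserWarning,
            )
        norms[zero] = np.nan
        z = centred / norms[:, None]
        ridx = [expr.index.get_loc(r) for r in regulators]
        return z @ z[ridx].T  # genes x regulators

    corr_h = _corr(expr_h)
    corr_d = _corr(expr_d)
    return pd.DataFrame(
        corr_h - corr_d, index=expr_h.index, columns=list(regulators)
    )


def sort_deregulation_list(D: pd.DataFrame, regulator: str) -> pd.Series:
    """One regulator's deregulation list, sorted decreasingly.

    The top of the list holds genes more activated in the healthy cells
    (most positive scores), the bottom genes more activated in the damaged
    cells.  Ties are broken by lexicographic gene id, so the ordering is
    deterministic.
    """
    if regulator not in D.columns:
        raise KeyError(
            f"regulator {regulator!r} not among deregulation columns "
            f"{list(D.columns)}"
        )
    col = D[regulator]
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return col.loc[order]
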