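"""Belief-based partially supervised two-Gaussian mixture modelling.

For one knock-down experiment the observed data are per-gene log expression
ratios (knock-down vs. control).  A two-component Gaussian mixture is fitted
by EM: one narrow component models genes unchanged by the perturbation, one
wide component models differentially expressed genes (whose ratios sit in
both tails around zero).  Known transcription-factor targets enter as soft
labels: for a labelled gene the E-step responsibility of the differential
component is proportional to ``belief * N(x; mu_diff, sd_diff)`` and of the
unchanged component to ``(1 - belief) * N(x; mu_unch, sd_unch)`` — the belief
(default 0.95) replaces the mixing proportions as that gene's prior.
Unlabelled genes use the standard mixing-proportion prior.  With no labels
the procedure reduces exactly to plain unsupervised EM.

The posterior probability of the differential component, multiplied by the
sign of the log ratio, is the *signed probability* of differential
expression, one number per gene per experiment in [-1, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "BeliefSet",
    "MixtureFit",
    "BeliefGaussianMixture",
    "fit_belief_mixture",
    "signed_probabilities",
]

MIN_FINITE_RATIOS = 20


class InsufficientDataError(ValueError):
    """Fewer finite log-ratio values than the mixture fit requires."""


@dataclass(frozen=True)
class BeliefSet:
    """Known targets of one regulator in one population, with belief weights.

    ``entries`` maps gene id to the prior probability (strictly in (0, 1))
    that the gene is differentially expressed in the regulator's knock-down
    experiment; the conventional default is 0.95.
    """

    population: str
    regulator: str
    entries: dict[str, float] = field(default_factory=dict)
    default_belief: float = 0.95

    def __post_init__(self) -> None:
        for gene, b in self.entries.items():
            if not 0.0 < b < 1.0:
                raise ValueError(
                    f"belief for gene {gene!r} must lie strictly in (0, 1), "
                    f"got {b}"
                )

    def __len__(self) -> int:
        return len(self.entries)


class BeliefGaussianMixture(BaseEstimator):
    """Two-component 1-d Gaussian mixture with belief-weighted soft labels.

    scikit-learn style estimator.  ``fit`` takes the vector of log ratios
    and an optional per-observation belief vector (NaN = unlabelled); a
    belief ``b`` pins that observation's component prior to ``(b, 1-b)``
    toward the differential component for every E-step, in place of the
    mixing proportions.  The M-step is standard weighted maximum likelihood
    over all observations, so the EM objective (the belief-weighted
    log-likelihood) is non-decreasing.

    Parameters
    ----------
    max_iter : int
        EM iteration cap.
    tol : float
        Relative log-likelihood change declaring convergence.
    var_floor : float
        Lower bound on component variances (squared log-ratio units);
        degenerate components are floored here with a warning.
    init_weights : tuple of float
        Initial mixing proportions (unchanged, differential).
    weight_prior : float
        Strength of a Dirichlet-type prior anchoring the mixing proportions
        at ``init_weights``, expressed as a fraction of the sample size in
        pseudo-counts (MAP-EM).  When the data hold no differential signal
        the two-component likelihood is flat in the proportions and plain
        EM drifts to an arbitrary, fit-dependent split; the prior pins such
        degenerate fits near the initial proportions while being swamped by
        any real signal.  0 gives plain maximum likelihood.
    differential : {"variance"} or int
        How to identify the differential component after fitting: largest
        fitted variance (default), or a fixed component index (0 = the
        component initialised as "unchanged", 1 = as "differential").
    n_restarts : int
        Additional random-perturbation restarts of the initialisation; the
        best final log-likelihood wins.  0 keeps the deterministic
        moment-based initialisation only.
    random_state : int or None
        Seed for the restarts.

    Attributes
    ----------
    means_, sds_, weights_ : ndarray of shape (2,)
        Fitted parameters, component 0 initialised as unchanged, 1 as
        differential.
    differential_ : int
        Index of the component reported as differential.
    responsibilities_ : ndarray (n, 2)
        Final E-step responsibilities on the training data (belief-weighted
        for labelled observations).
    loglik_trace_ : ndarray
        Objective value per iteration (the log-likelihood, plus the weight
        prior term when ``weight_prior > 0``); non-decreasing.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        max_iter: int = 1000,
        tol: float = 1e-8,
        var_floor: float = 1e-6,
        init_weights: tuple[float, float] = (0.9, 0.1),
        weight_prior: float = 0.05,
        differential: str | int = "variance",
        n_restarts: int = 0,
        random_state: int | None = None,
    ) -> None:
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.init_weights = init_weights
        self.weight_prior = weight_prior
        self.differential = differential
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _initial_params(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # Unchanged component from the central half of the data (median,
        # IQR-matched sd); differential from the full-sample sd inflated x3.
        med = float(np.median(x))
        q1, q3 = np.percentile(x, [25, 75])
        sd0 = max((q3 - q1) / 1.349, np.sqrt(self.var_floor))
        sd1 = max(3.0 * float(np.std(x)), sd0 * 1.5, np.sqrt(self.var_floor))
        means = np.array([med, med])
        sds = np.array([sd0, sd1])
        weights = np.asarray(self.init_weights, dtype=float)
        return means, sds, weights / weights.sum()

    @staticmethod
    def _responsibilities(
        x: np.ndarray,
        beliefs: np.ndarray,
        means: np.ndarray,
        sds: np.ndarray,
        weights: np.ndarray,
    ) -> tuple[np.ndarray, float]:
        """E-step responsibilities and the objective value.

        ``beliefs`` is NaN for unlabelled observations.  Component order:
        (unchanged, differential); a belief b contributes prior (1-b, b).
        """
        dens = np.column_stack(
            [norm.pdf(x, means[j], sds[j]) for j in (0, 1)]
        )
        labelled = np.isfinite(beliefs)
        prior = np.tile(weights, (x.size, 1))
        if labelled.any():
            b = beliefs[labelled]
            prior[labelled, 0] = 1.0 - b
            prior[labelled, 1] = b
        joint = prior * dens
        total = joint.sum(axis=1)
        # guard against underflow far in the tails
        total = np.where(total > 0, total, np.finfo(float).tiny)
        resp = joint / total[:, None]
        loglik = float(np.log(total).sum())
        return resp, loglik

    def _em(
        self, x: np.ndarray, beliefs: np.ndarray,
        means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
    ) -> dict:
        trace = []
        converged = False
        # Dirichlet-type pseudo-counts anchoring the proportions (MAP-EM);
        # the reported objective includes the prior term so it is monotone.
        alpha = self.weight_prior * x.size * np.asarray(
            self.init_weights, dtype=float
        )

        def _objective(loglik: float, w: np.ndarray) -> float:
            return loglik + float((alpha * np.log(w)).sum())

        resp, loglik = self._responsibilities(x, beliefs, means, sds, weights)
        loglik = _objective(loglik, weights)
        trace.append(loglik)
        for _ in range(self.max_iter):
            # M-step: weighted ML over all observations (MAP for the weights)
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, np.finfo(float).tiny)
            weights = (nk + alpha) / (nk.sum() + alpha.sum())
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
            if var[1] < var[0]:
                # identifiability: the differential component is the wider
                # one; when the M-step would cross the variances the
                # constrained optimum pools them (generalized M-step)
                var[:] = (nk * var).sum() / nk.sum()
            if (var < self.var_floor).any():
                warnings.warn(
                    "mixture component variance floored at "
                    f"{self.var_floor}", RuntimeWarning,
                )
                var = np.maximum(var, self.var_floor)
            sds = np.sqrt(var)
            resp, new_loglik = self._responsibilities(
                x, beliefs, means, sds, weights
            )
            new_loglik = _objective(new_loglik, weights)
            trace.append(new_loglik)
            denom = max(abs(loglik), 1.0)
            if new_loglik - loglik <= self.tol * denom:
                converged = True
                loglik = new_loglik
                break
            loglik = new_loglik
        return {
            "means": means, "sds": sds, "weights": weights,
            "resp": resp, "trace": np.asarray(trace), "converged": converged,
        }

    # -- estimator API -----------------------------------------------------

    def fit(self, X, beliefs=None) -> "BeliefGaussianMixture":
        """Fit to a vector of log ratios.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Finite log expression ratios.
        beliefs : array-like of shape (n,), optional
            Per-observation belief of differential expression; NaN marks
            unlabelled observations.  Omitted = fully unsupervised.
        """
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < MIN_FINITE_RATIOS or not np.isfinite(x).all():
            raise InsufficientDataError(
                f"need >= {MIN_FINITE_RATIOS} finite log-ratio values, got "
                f"{int(np.isfinite(x).sum())}"
            )
        if beliefs is None:
            bel = np.full(x.size, np.nan)
        else:
            bel = np.asarray(beliefs, dtype=float).reshape(-1)
            if bel.size != x.size:
                raise ValueError(
                    f"beliefs length {bel.size} != data length {x.size}"
                )
        means, sds, weights = self._initial_params(x)
        best = self._em(x, bel, means, sds, weights)
        if self.n_restarts:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_restarts):
                jitter_means = means + rng.normal(0, sds[1] / 2, size=2)
                jitter_sds = sds * rng.uniform(0.5, 2.0, size=2)
                cand = self._em(x, bel, jitter_means, jitter_sds, weights)
                if cand["trace"][-1] > best["trace"][-1]:
                    best = cand
        self.means_ = best["means"]
        self.sds_ = best["sds"]
        self.weights_ = best["weights"]
        self.responsibilities_ = best["resp"]
        self.loglik_trace_ = best["trace"]
        self.converged_ = bool(best["converged"])
        self.n_iter_ = len(best["trace"]) - 1
        if not self.converged_:
            warnings.warn(
                f"EM did not converge within {self.max_iter} iterations; "
                "returning the best iterate", RuntimeWarning,
            )
        if self.differential == "variance":
            # ties (pooled-variance degenerate fits) resolve to component 1,
            # the one carrying the minority proportion and the beliefs
            self.differential_ = 0 if self.sds_[0] > self.sds_[1] else 1
        else:
            self.differential_ = int(self.differential)
        return self

    def predict_proba(self, X, beliefs=None) -> np.ndarray:
        """Posterior probability of the differential component.

        Labelled observations (finite ``beliefs``) get the belief-weighted
        posterior; unlabelled ones the mixing-proportion posterior.  NaN
        inputs propagate to NaN posteriors.
        """
        x = np.asarray(X, dtype=float).reshape(-1)
        if beliefs is None:
            bel = np.full(x.size, np.nan)
        else:
            bel = np.asarray(beliefs, dtype=float).reshape(-1)
        out = np.full(x.size, np.nan)
        ok = np.isfinite(x)
        if self.differential_ == 0:
            # belief is defined toward the differential component
            bel = np.where(np.isfinite(bel), 1.0 - bel, bel)
        resp, _ = self._responsibilities(
            x[ok], bel[ok], self.means_, self.sds_, self.weights_
        )
        out[ok] = resp[:, self.differential_]
        return out


@dataclass
class MixtureFit:
    """Result of fitting the belief mixture to one experiment's ratios."""

    population: str
    experiment: str
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    differential: int
    posterior: pd.Series  # P(differential | ratio) per gene; NaN if missing
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def summary(self) -> str:
        d, u = self.differential, 1 - self.differential
        return (
            f"experiment {self.experiment} (population {self.population}): "
            f"differential N({self.means[d]:+.4f}, {self.sds[d]:.4f}) "
            f"w={self.weights[d]:.3f}; "
            f"unchanged N({self.means[u]:+.4f}, {self.sds[u]:.4f}) "
            f"w={self.weights[u]:.3f}; "
            f"{self.n_iter} iterations, "
            f"{'converged' if self.converged else 'NOT converged'}"
        )


def fit_belief_mixture(
    ratios: pd.Series,
    beliefs: BeliefSet | None = None,
    *,
    experiment: str = "",
    population: str = "",
    **config,
) -> MixtureFit:
    """Fit the two-component belief mixture to one experiment's log ratios.

    Missing (NaN) ratios are excluded from fitting and yield missing
    posteriors.  Belief entries for genes absent from ``ratios`` are
    ignored with a warning.  Extra keyword arguments are forwarded to
    :class:`BeliefGaussianMixture`.
    """
    ratios = pd.Series(ratios, dtype=float)
    mask = ratios.notna()
    x = ratios[mask].to_numpy()
    if x.size < MIN_FINITE_RATIOS:
        raise InsufficientDataError(
            f"experiment {experiment!r}: need >= {MIN_FINITE_RATIOS} finite "
            f"ratios, got {x.size}"
        )
    bel_vec = np.full(x.size, np.nan)
    if beliefs is not None and len(beliefs):
        pos = {g: i for i, g in enumerate(ratios.index[mask])}
        unknown = [g for g in beliefs.entries if g not in pos]
        if unknown:
            warnings.warn(
                f"{len(unknown)} belief gene(s) absent from the data for "
                f"experiment {experiment!r} ignored "
                f"(e.g. {unknown[:3]})", UserWarning,
            )
        for g, b in beliefs.entries.items():
            if g in pos:
                bel_vec[pos[g]] = b
    est = BeliefGaussianMixture(**config).fit(x, bel_vec)
    post = pd.Series(np.nan, index=ratios.index, dtype=float)
    post[mask] = est.responsibilities_[:, est.differential_]
    return MixtureFit(
        population=population,
        experiment=experiment,
        means=est.means_,
        sds=est.sds_,
        weights=est.weights_,
        differential=est.differential_,
        posterior=post,
        loglik_trace=est.loglik_trace_,
        converged=est.converged_,
        n_iter=est.n_iter_,
    )


def signed_probabilities(fit: MixtureFit, ratios: pd.Series) -> pd.Series:
    """Signed probability of differential expression per gene, in [-1, 1].

    The posterior of the differential component is multiplied by +1 when
    the perturbation up-regulated the gene (positive log ratio) and -1 when
    it down-regulated it; an exactly zero ratio gives 0, a missing ratio a
    missing value.
    """
    ratios = pd.Series(ratios, dtype=float)
    if not ratios.index.equals(fit.posterior.index):
        raise ValueError(
            "ratio vector does not match the gene index the mixture was "
            f"fitted on for experiment {fit.experiment!r}"
        )
    return fit.posterior * np.sign(ratios)
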