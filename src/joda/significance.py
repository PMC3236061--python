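"""Permutation significance of deregulation scores.

The null hypothesis for each (gene, regulator) pair is that the gene's
deregulation score does not differ from zero.  Rather than permuting the
raw expression data, the signed differential-expression probabilities are
permuted: all finite entries of both populations' matrices are pooled,
shuffled, placed back into the original layout, and propagated through the
pathway models to permuted deregulation scores.  Permuting at this level
tests directly what the pathway models contribute to the scores, and avoids
refitting mixtures to scrambled data.

The p-value is the (add-one corrected) fraction of permutations whose
absolute deregulation score is at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway import PathwayModel

__all__ = ["PermutationResult", "permutation_test", "pvalues_from_null"]


@dataclass
class PermutationResult:
    p_values: pd.DataFrame  # genes x regulators, in [0, 1]
    n_permutations: int
    seed: int
    scheme: str

    def describe(self) -> str:
        return (
            f"permutation test: B={self.n_permutations}, seed={self.seed}, "
            f"scheme={self.scheme}"
        )


def _nanmean_scores(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Missing-aware regulation scores (genes x regulators) for array input.

    ``M`` is the binary experiments x regulators model matrix; column v of
    the result is the mean of each gene's finite entries over the
    experiments affecting v.
    """
    finite = np.isfinite(x)
    sums = np.where(finite, x, 0.0) @ M
    counts = finite.astype(float) @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def _score_arrays(P: pd.DataFrame, model: PathwayModel) -> np.ndarray:
    x = P[list(model.experiments)].to_numpy(dtype=float)
    return _nanmean_scores(x, model.matrix.to_numpy(dtype=float))


def pvalues_from_null(
    observed: np.ndarray, null: np.ndarray, add_one: bool = True
) -> np.ndarray:
    """Exceedance p-values of |observed| against a permutation null.

    ``null`` has one row per permutation, matching ``observed``'s shape.
    Ties count as exceedances (conservative).  With ``add_one`` the
    estimator is (1 + #exceedances) / (B + 1), which never returns 0.
    """
    B = null.shape[0]
    exceed = (np.abs(null) >= np.abs(observed)[None, ...]).sum(axis=0)
    if add_one:
        p = (1.0 + exceed) / (B + 1.0)
    else:
        p = exceed / float(B)
    return np.where(np.isfinite(observed), p, np.nan)


def permutation_test(
    P_h: pd.DataFrame,
    P_d: pd.DataFrame,
    model_h: PathwayModel,
    model_d: PathwayModel,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "global",
    add_one: bool = True,
) -> PermutationResult:
    """Permutation test of deregulation scores against zero.

    Parameters
    ----------
    P_h, P_d:
        Signed-probability matrices of the two populations (healthy first),
        aligned on genes.
    model_h, model_d:
        The populations' pathway models.
    B:
        Number of permutations (default 1000).
    seed:
        Seed for the shuffles; identical seed and inputs give identical
        p-values.
    scheme:
        ``"global"`` pools every finite entry of both matrices into one
        vector before shuffling (destroys gene and experiment structure
        across populations); ``"within"`` shuffles each population's pool
        separately.
    add_one:
        Use the (1 + k) / (B + 1) estimator (default); ``False`` gives the
        raw frequency k / B.

    Returns
    -------
    PermutationResult
        Genes x regulators p-value matrix (missing where the observed
        deregulation score is missing).
    """
    if B < 1:
        raise ValueError(f"number of permutations must be >= 1, got {B}")
    if scheme not in ("global", "within"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if list(P_h.index) != list(P_d.index):
        raise ValueError(
            "signed-probability matrices must be aligned on the same genes"
        )
    if list(model_h.regulators) != list(model_d.regulators):
        raise ValueError("pathway models must share the regulator set")

    x_h = P_h[list(model_h.experiments)].to_numpy(dtype=float)
    x_d = P_d[list(model_d.experiments)].to_numpy(dtype=float)
    D_obs = _score_arrays(P_d, model_d) - _score_arrays(P_h, model_h)

    rng = np.random.default_rng(seed)
    mask_h, mask_d = np.isfinite(x_h), np.isfinite(x_d)
    M_h = model_h.matrix.to_numpy(dtype=float)
    M_d = model_d.matrix.to_numpy(dtype=float)
    pool_h, pool_d = x_h[mask_h], x_d[mask_d]
    n_h = pool_h.size
    null = np.empty((B,) + D_obs.shape)
    ph = x_h.copy()
    pd_ = x_d.copy()
    for b in range(B):
        if scheme == "global":
            pool = rng.permutation(np.concatenate([pool_h, pool_d]))
            ph[mask_h] = pool[:n_h]
            pd_[mask_d] = pool[n_h:]
        else:
            ph[mask_h] = rng.permutation(pool_h)
            pd_[mask_d] = rng.permutation(pool_d)
        null[b] = _nanmean_scores(pd_, M_d) - _nanmean_scores(ph, M_h)
    p = pvalues_from_null(D_obs, null, add_one=add_one)
    return PermutationResult(
        p_values=pd.DataFrame(
            p, index=P_h.index, columns=list(model_h.regulators)
        ),
        n_permutations=B,
        seed=seed,
        scheme=scheme,
    )
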