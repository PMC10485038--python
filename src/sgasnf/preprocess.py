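"""Missing-data imputation and per-feature standardization.

Missing cells are filled by chained equations: each incomplete feature
is regressed on all other features of the same data domain with a
Bayesian linear model, sweeping the features repeatedly, and imputed
values are sampled from the posterior predictive so that the m returned
completions differ (multiple imputation). Imputation is fit within each
domain only, keeping domains separable as fusion inputs.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .datatypes import FeatureBlock, ImputationError


class ChainedEquationImputer:
    """Multiple imputation by chained equations for one feature block.

    Parameters
    ----------
    n_imputations : number of completed datasets to draw (m).
    n_sweeps : passes over the features per imputation.
    random_state : seed; draws i uses a child seed derived from it.
    """

    def __init__(self, n_imputations: int = 5, n_sweeps: int = 10,
                 random_state: int | None = None):
        self.n_imputations = n_imputations
        self.n_sweeps = n_sweeps
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_imputations": self.n_imputations, "n_sweeps": self.n_sweeps,
                "random_state": self.random_state}

    def set_params(self, **params) -> "ChainedEquationImputer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_transform(self, block: FeatureBlock) -> list[FeatureBlock]:
        if self.n_imputations < 1 or self.n_sweeps < 1:
            raise ValueError("n_imputations and n_sweeps must be >= 1")
        mask = block.mask
        fully_missing = np.where(~mask.any(axis=0))[0]
        if fully_missing.size:
            names = [block.feature_names[j] for j in fully_missing]
            raise ImputationError(
                f"feature(s) with no observed values in domain "
                f"{block.domain!r}: {names}")
        if block.is_complete():
            return [block.copy() for _ in range(self.n_imputations)]
        X = block.values.to_numpy(dtype=float)
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.n_imputations)
        completed = []
        for m in range(self.n_imputations):
            imputer = IterativeImputer(
                estimator=BayesianRidge(),
                sample_posterior=True,
                max_iter=self.n_sweeps,
                imputation_order="random",
                random_state=int(seeds[m]) % (2**31),
                tol=0.0,  # run all sweeps; draws, not convergence
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # non-convergence is expected
                Xc = imputer.fit_transform(X)
            df = pd.DataFrame(Xc, columns=block.feature_names,
                              index=block.values.index)
            completed.append(FeatureBlock(df, block.domain))
        return completed


def impute_chained(block: FeatureBlock, n_sweeps: int = 10,
                   n_imputations: int = 5, seed: int | None = None
                   ) -> list[FeatureBlock]:
    """Chained-equation multiple imputation; see ChainedEquationImputer."""
    return ChainedEquationImputer(n_imputations, n_sweeps, seed).fit_transform(block)


def pool_imputations(completed: Sequence[FeatureBlock],
                     strategy: str = "average") -> FeatureBlock:
    """Combine m completed datasets into one.

    "average" returns the cell-wise mean across imputations (the default
    downstream path feeds one pooled matrix into fusion); "first"
    returns the first draw.
    """
    if len(completed) == 0:
        raise ValueError("need at least one completed block")
    shapes = {b.values.shape for b in completed}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across imputations: {shapes}")
    if strategy == "first":
        return completed[0].copy()
    if strategy == "average":
        stack = np.stack([b.values.to_numpy(dtype=float) for b in completed])
        df = pd.DataFrame(stack.mean(axis=0), columns=completed[0].feature_names,
                          index=completed[0].values.index)
        return FeatureBlock(df, completed[0].domain)
    raise ValueError(f"unknown pooling strategy {strategy!r}")


def standardize(block: FeatureBlock) -> FeatureBlock:
    """Scale each feature to mean 0, SD 1 (population SD).

    Constant features are mapped to all-zeros with a warning. Requires a
    complete block.
    """
    if not block.is_complete():
        raise ValueError(
            f"standardize requires a complete block; domain {block.domain!r} "
            "has missing cells (impute first)")
    X = block.values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        names = [block.feature_names[j] for j in np.where(const)[0]]
        warnings.warn(f"constant feature(s) set to zero: {names}")
        sd = np.where(const, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, const] = 0.0
    df = pd.DataFrame(Z, columns=block.feature_names, index=block.values.index)
    return FeatureBlock(df, block.domain)


def log_transform_skewed(block: FeatureBlock,
                         skew_threshold: float = 2.0) -> FeatureBlock:
    """Variance-stabilizing log transform of right-skewed positive features.

    Strictly positive features whose sample skewness exceeds the
    threshold (markedly log-normal markers such as angiogenic ratios or
    cord BNP) are replaced by their natural log; other features pass
    through. Applied before standardization so single extreme values do
    not dominate Euclidean distances.
    """
    from scipy.stats import skew

    df = block.values.copy()
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size and (obs > 0).all() and skew(obs) > skew_threshold:
            df[col] = np.log(x)
    return FeatureBlock(df, block.domain)


def prepare_cohort(cohort, n_imputations: int = 5, n_sweeps: int = 10,
                   seed: int | None = 0, log_skewed: bool = True):
    """Impute, pool, log-transform skewed markers and standardize.

    Returns ``(pooled, standardized)`` dicts of complete FeatureBlocks:
    pooled keeps the natural scale (used e.g. by the clinical
    classification rule), standardized feeds the fusion.
    """
    check_patient_coverage(cohort.blocks)
    doms = list(cohort.blocks)
    seeds = np.random.SeedSequence(seed).generate_state(len(doms))
    pooled: dict[str, FeatureBlock] = {}
    standardized: dict[str, FeatureBlock] = {}
    for dom, s in zip(doms, seeds):
        completed = impute_chained(cohort.blocks[dom], n_sweeps=n_sweeps,
                                   n_imputations=n_imputations,
                                   seed=int(s) % (2**31))
        pooled[dom] = pool_imputations(completed, "average")
        pre = log_transform_skewed(pooled[dom]) if log_skewed else pooled[dom]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns are handled
            standardized[dom] = standardize(pre)
    return pooled, standardized


def check_patient_coverage(blocks: dict[str, FeatureBlock]) -> None:
    """Verify every patient has at least one observed feature overall."""
    observed = None
    for block in blocks.values():
        row_any = block.mask.any(axis=1)
        observed = row_any if observed is None else (observed | row_any)
    if observed is not None and not observed.all():
        bad = np.where(~observed)[0]
        raise ImputationError(
            f"patients with no observed feature in any domain: rows {bad.tolist()}")
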