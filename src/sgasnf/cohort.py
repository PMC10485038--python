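"""Synthetic multi-omic SGA cohort generator.

Emulates the statistical structure of a 574-pregnancy small-for-
gestational-age cohort with two latent phenotypes: an early-onset,
high-risk phenotype ("cluster A", ~37.6% of patients) and a late-onset,
lower-risk phenotype ("cluster B", ~62.4%). Four data domains are
generated per patient — clinical (gestational age at diagnosis, blood
pressures, angiogenic ratio), fetoplacental ultrasound (EFW and Doppler
z-scores), cord-blood NMR metabolomics and maternal-blood NMR
metabolomics — with per-cluster Gaussian feature distributions whose
locations and scales are calibrated to the published cluster-wise
medians and IQRs (SD taken as IQR/1.349). Right-skewed markers
(sFlt-1/PlGF ratio, cord BNP) are log-normal.

Missing data are injected per patient-row within a domain (a patient is
either measured in a domain or not), mirroring how missingness was
reported for the source cohort: blood pressure missing for 11.4% of
patients, ultrasound for 4.1%, each metabolomics panel for 31.3%.
Gestational age and the angiogenic ratio are always observed.

Outcomes are Bernoulli per patient at cluster-specific probabilities
(preeclampsia 55.1%/8.96%, stillbirth 6.94%/0%, adverse perinatal
outcome 44.4%/13.4%, abnormal cord BNP 48.3%/9.3% for clusters A/B) and
the diagnosis-to-delivery interval is exponential per cluster with a
hazard ratio of 10.5 (cluster A delivers sooner), the ground truth for
Cox-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BINARY_OUTCOMES,
    DOMAINS,
    ConfigurationError,
    FeatureBlock,
    MultiOmicCohort,
    OutcomeTable,
)

_IQR_TO_SD = 1.349  # normal-distribution IQR / SD


@dataclass(frozen=True)
class FeatureSpec:
    """Per-cluster location/scale of one synthetic feature.

    For Gaussian features ``loc``/``scale`` are the per-cluster mean and
    SD. For log-normal features ``loc`` is the per-cluster median on the
    natural scale and ``scale`` the SD of the log.
    """

    name: str
    domain: str
    loc: tuple[float, ...]
    scale: tuple[float, ...]
    lognormal: bool = False
    missable: bool = True

    def __post_init__(self) -> None:
        if len(self.loc) != len(self.scale):
            raise ConfigurationError(f"{self.name}: loc/scale length mismatch")
        if any(s <= 0 for s in self.scale):
            raise ConfigurationError(f"{self.name}: SDs must be strictly positive")


def _gauss(name, domain, medians, q1, q3, missable=True) -> FeatureSpec:
    sd = tuple((b - a) / _IQR_TO_SD for a, b in zip(q1, q3))
    return FeatureSpec(name, domain, tuple(medians), sd, missable=missable)


def _lognorm(name, domain, medians, q1, q3, missable=True) -> FeatureSpec:
    sd = tuple((math.log(b) - math.log(a)) / _IQR_TO_SD for a, b in zip(q1, q3))
    return FeatureSpec(name, domain, tuple(medians), sd, lognormal=True, missable=missable)


def default_features() -> list[FeatureSpec]:
    """Default feature panel, calibrated to the published cluster profiles.

    Per-cluster (A, B) medians and IQRs follow the reported top-NMI
    feature table; EFW is given directly as mean +/- SD. The angiogenic
    sFlt-1/PlGF ratio defaults are not reported per cluster and use
    clinically typical early- vs late-onset placental-dysfunction values.
    """
    return [
        # clinical -------------------------------------------------------
        _gauss("gestational_age_dx", "clinical", (29.9, 35.1),
               (27.1, 32.1), (32.3, 37.1), missable=False),
        _gauss("systolic_bp", "clinical", (130, 113), (119, 107), (148, 120)),
        _gauss("diastolic_bp", "clinical", (84, 73), (76, 67), (93.8, 80)),
        _gauss("mean_bp", "clinical", (99, 86.3), (90.3, 81.2), (111, 92.3)),
        _lognorm("sflt1_plgf_ratio", "clinical", (85, 12), (30, 5), (200, 30),
                 missable=False),
        # ultrasound -----------------------------------------------------
        FeatureSpec("efw", "ultrasound", (1133, 1814), (499, 567)),
        _gauss("efw_centile", "ultrasound", (1.5, 3.5), (0.5, 1.5), (3.5, 6.5)),
        _gauss("ua_pi_z", "ultrasound", (0.93, 0.13), (0.29, -0.37), (2.70, 0.53)),
        _gauss("uta_pi_z", "ultrasound", (2.63, 0.23), (1.29, -0.71), (3.55, 1.25)),
        _gauss("cpr_z", "ultrasound", (-1.90, -0.68), (-3.01, -1.41), (-0.99, 0.04)),
        _gauss("cpr_z_dx", "ultrasound", (-1.45, -0.51), (-2.25, -1.2), (-0.75, 0.17)),
        # cord-blood metabolomics ---------------------------------------
        _gauss("glutamine", "cord_metabolomics", (18.2, 15.1), (15.7, 13.1), (23.4, 17.4)),
        _gauss("creatine", "cord_metabolomics", (7.05, 4.59), (5.20, 3.36), (9.70, 5.61)),
        _gauss("ldl_hdl_particle_ratio", "cord_metabolomics", (21.6, 18.2),
               (19.1, 15.9), (26.5, 21.2)),
        _gauss("valine", "cord_metabolomics", (15.6, 14.6), (13.4, 12.9), (18.7, 16.6)),
        _gauss("tg_idl", "cord_metabolomics", (6.01, 4.45), (3.99, 3.15), (8.9, 5.77)),
        _gauss("tyrosine", "cord_metabolomics", (2.03, 1.81), (1.83, 1.54), (2.35, 2.04)),
        _lognorm("bnp", "cord_metabolomics", (43.5, 14.6), (15.6, 8.14), (130, 25.8)),
        # maternal-blood metabolomics ------------------------------------
        _gauss("tyrosine_m", "maternal_metabolomics", (1.40, 1.15),
               (1.19, 0.99), (1.68, 1.31)),
        _gauss("creatine_m", "maternal_metabolomics", (4.78, 3.52),
               (3.71, 2.70), (7.28, 4.46)),
        _gauss("oxoisovalerate_m", "maternal_metabolomics", (0.75, 0.77),
               (0.48, 0.56), (1.09, 0.96)),
        _gauss("glutamate_m", "maternal_metabolomics", (1.92, 1.62),
               (1.44, 1.18), (2.64, 2.08)),
        _gauss("tg_ldl_m", "maternal_metabolomics", (32.2, 33.8),
               (24.9, 27.1), (43.6, 42.1)),
    ]


#: Per-domain default probability that a patient's row is missing.
DEFAULT_MISSING_RATES = {
    "clinical": 0.114,  # blood-pressure columns only
    "ultrasound": 0.041,
    "cord_metabolomics": 0.313,
    "maternal_metabolomics": 0.313,
}

#: Per-outcome (cluster A, cluster B) event probabilities.
DEFAULT_OUTCOME_PROFILE = {
    "preeclampsia": (0.551, 0.0896),
    "stillbirth": (0.0694, 0.0),
    "apo": (0.444, 0.134),
    "abnormal_bnp": (0.483, 0.093),
}

#: Per-cluster mean diagnosis-to-delivery interval (weeks); the ratio of
#: the exponential hazards 1/4 and 1/42 is the ground-truth HR 10.5.
DEFAULT_INTERVAL_SCALES = (4.0, 42.0)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    The defaults reproduce the study conditions: n=574 patients, two
    phenotypes in proportions 216/574 and 358/574, published feature
    shifts, block-wise missingness, published outcome rates and a
    delivery-interval hazard ratio of 10.5.
    """

    n_patients: int = 574
    cluster_fractions: tuple[float, ...] = (216 / 574, 358 / 574)
    features: list[FeatureSpec] = field(default_factory=default_features)
    within_domain_correlation: float = 0.2
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    outcome_profile: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_OUTCOME_PROFILE.items()})
    interval_scales: tuple[float, ...] = DEFAULT_INTERVAL_SCALES
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_fractions)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if abs(sum(self.cluster_fractions) - 1.0) > 1e-12:
            raise ConfigurationError("cluster_fractions must sum to 1")
        if any(f <= 0 for f in self.cluster_fractions):
            raise ConfigurationError("cluster_fractions must be positive")
        if not (0 <= self.within_domain_correlation < 1):
            raise ConfigurationError("within_domain_correlation must be in [0,1)")
        for dom, r in self.missing_rates.items():
            if not (0 <= r < 1):
                raise ConfigurationError(f"missing rate for {dom!r} out of [0,1)")
        for name, probs in self.outcome_profile.items():
            if len(probs) != self.n_clusters:
                raise ConfigurationError(f"{name}: need one probability per cluster")
            if any(not (0 <= p <= 1) for p in probs):
                raise ConfigurationError(f"{name}: probabilities must be in [0,1]")
        if len(self.interval_scales) != self.n_clusters:
            raise ConfigurationError("need one interval scale per cluster")
        if any(s <= 0 for s in self.interval_scales):
            raise ConfigurationError("interval scales must be positive")
        for spec in self.features:
            if len(spec.loc) != self.n_clusters:
                raise ConfigurationError(
                    f"{spec.name}: need one location per cluster")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive n independent 31-bit child seeds."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def generate_outcomes(
    true_labels: np.ndarray,
    outcome_profile: dict[str, Sequence[float]],
    interval_scales: Sequence[float],
    seed: int = 0,
) -> OutcomeTable:
    """Draw binary outcomes and delivery intervals given cluster labels.

    Each binary outcome is an independent Bernoulli at its cluster's
    probability; the diagnosis-to-delivery interval is exponential with
    the cluster's mean scale. Every delivery is an observed event
    (administrative censoring is not applied by default).
    """
    labels = np.asarray(true_labels, dtype=int)
    k = int(labels.max())
    for name, probs in outcome_profile.items():
        if any(not (0 <= p <= 1) for p in probs):
            raise ConfigurationError(f"{name}: probabilities must be in [0,1]")
        if len(probs) < k:
            raise ConfigurationError(f"{name}: need a probability per cluster")
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    cols: dict[str, np.ndarray] = {}
    for name in outcome_profile:
        p = np.asarray(outcome_profile[name], dtype=float)[labels - 1]
        cols[name] = (rng.random(n) < p).astype(int)
    scales = np.asarray(interval_scales, dtype=float)[labels - 1]
    cols["interval_weeks"] = rng.exponential(scales)
    cols["event"] = np.ones(n, dtype=int)
    return OutcomeTable(pd.DataFrame(cols))


def generate_cohort(config: CohortConfig) -> MultiOmicCohort:
    """Generate a complete (no missing values) multi-omic cohort.

    Deterministic given ``config.seed``. Within a domain, features share
    an exchangeable correlation ``within_domain_correlation`` induced by
    a single per-patient latent factor.
    """
    config.validate()
    seeds = _spawn_seeds(config.seed, 3)
    rng = np.random.default_rng(seeds[0])
    n, k = config.n_patients, config.n_clusters
    labels = rng.choice(np.arange(1, k + 1), size=n, p=config.cluster_fractions)

    rho = config.within_domain_correlation
    blocks: dict[str, FeatureBlock] = {}
    for dom in DOMAINS:
        specs = [s for s in config.features if s.domain == dom]
        if not specs:
            continue
        factor = rng.standard_normal(n)  # shared within-domain factor
        data = {}
        for spec in specs:
            eps = rng.standard_normal(n)
            z = math.sqrt(rho) * factor + math.sqrt(1 - rho) * eps
            loc = np.asarray(spec.loc, dtype=float)[labels - 1]
            scale = np.asarray(spec.scale, dtype=float)[labels - 1]
            if spec.lognormal:
                data[spec.name] = np.exp(np.log(loc) + scale * z)
            else:
                data[spec.name] = loc + scale * z
        blocks[dom] = FeatureBlock(pd.DataFrame(data), dom)

    outcomes = generate_outcomes(
        labels, config.outcome_profile, config.interval_scales, seed=seeds[1])
    ids = [f"P{i:04d}" for i in range(n)]
    return MultiOmicCohort(ids, blocks, outcomes, true_labels=labels)


def inject_missingness(
    cohort: MultiOmicCohort,
    rates: Optional[dict[str, float]] = None,
    seed: int = 0,
    features: Optional[list[FeatureSpec]] = None,
) -> MultiOmicCohort:
    """Mask feature values missing-completely-at-random, per patient-row.

    For each domain, each patient's missable columns are masked with the
    domain's probability (a patient is either measured in a domain or
    not, matching how missingness was reported for the source cohort).
    The pre-missingness blocks are retained in ``complete_blocks``.
    """
    rates = dict(DEFAULT_MISSING_RATES) if rates is None else rates
    for dom, r in rates.items():
        if not (0 <= r < 1):
            raise ConfigurationError(f"missing rate for {dom!r} must be in [0,1)")
    missable = _missable_columns(cohort, features)
    rng = np.random.default_rng(seed)
    new_blocks: dict[str, FeatureBlock] = {}
    for dom, block in cohort.blocks.items():
        rate = rates.get(dom, 0.0)
        vals = block.values.copy()
        if rate > 0 and missable[dom]:
            hit = rng.random(block.n_patients) < rate
            vals.loc[hit, missable[dom]] = np.nan
        new_blocks[dom] = FeatureBlock(vals, dom)
    return MultiOmicCohort(
        patient_ids=list(cohort.patient_ids),
        blocks=new_blocks,
        outcomes=cohort.outcomes.copy(),
        true_labels=None if cohort.true_labels is None else cohort.true_labels.copy(),
        complete_blocks={d: b.copy() for d, b in cohort.blocks.items()},
    )


def _missable_columns(
    cohort: MultiOmicCohort, features: Optional[list[FeatureSpec]]
) -> dict[str, list[str]]:
    if features is None:
        features = default_features()
    spec_map = {(s.domain, s.name): s for s in features}
    out: dict[str, list[str]] = {}
    for dom, block in cohort.blocks.items():
        cols = []
        for name in block.feature_names:
            spec = spec_map.get((dom, name))
            # unknown columns default to missable
            if spec is None or spec.missable:
                cols.append(name)
        out[dom] = cols
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_cohort(cohort: MultiOmicCohort, outdir: str | Path) -> None:
    """Write one TSV per domain plus outcomes and (if present) truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for dom, block in cohort.blocks.items():
        df = block.values.copy()
        df.insert(0, "patient_id", cohort.patient_ids)
        df.to_csv(outdir / f"{dom}.tsv", sep="\t", index=False, na_rep="NA")
    out = cohort.outcomes.data.copy()
    out.insert(0, "patient_id", cohort.patient_ids)
    out.to_csv(outdir / "outcomes.tsv", sep="\t", index=False, na_rep="NA")
    if cohort.true_labels is not None:
        pd.DataFrame(
            {"patient_id": cohort.patient_ids, "true_label": cohort.true_labels}
        ).to_csv(outdir / "true_labels.tsv", sep="\t", index=False)


def read_cohort(indir: str | Path) -> MultiOmicCohort:
    """Read a cohort written by :func:`write_cohort` (or external tables
    in the same layout: one patients x features TSV per domain with a
    ``patient_id`` column and ``NA`` for missing)."""
    indir = Path(indir)
    blocks: dict[str, FeatureBlock] = {}
    ids: Optional[list[str]] = None
    for dom in DOMAINS:
        path = indir / f"{dom}.tsv"
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t", na_values="NA")
        if ids is None:
            ids = df["patient_id"].astype(str).tolist()
        blocks[dom] = FeatureBlock(df.drop(columns="patient_id"), dom)
    if ids is None:
        raise FileNotFoundError(f"no domain tables found in {indir}")
    out = pd.read_csv(indir / "outcomes.tsv", sep="\t", na_values="NA")
    outcomes = OutcomeTable(out.drop(columns="patient_id"))
    truth_path = indir / "true_labels.tsv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")["true_label"].to_numpy(dtype=int)
    return MultiOmicCohort(ids, blocks, outcomes, true_labels=truth)
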