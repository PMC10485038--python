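"""End-to-end pipeline: simulate -> impute -> fuse -> cluster -> rank ->
validate -> evaluate, as one reproducible, configured run.

All randomness flows from a single master seed which deterministically
spawns one child seed per stage; the report body (excluding timings,
which go to a separate file) is byte-identical across re-runs with the
same configuration.
"""

from __future__ import annotations

import io
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import BINARY_OUTCOMES, ClusterAssignment, MultiOmicCohort
from .cohort import CohortConfig, generate_cohort, inject_missingness, write_cohort
from .cluster import (cluster_crosstab, estimate_k, silhouette_from_similarity,
                      spectral_cluster)
from .evaluate import (bootstrap_compare, clinical_classification, contingency,
                       cox_hr, diagnostic_stats, km_logrank)
from .preprocess import prepare_cohort
from .relevance import datatype_contribution, rank_features_by_nmi
from .snf import SNFusion
from .validation import transfer_validation


@dataclass
class PipelineConfig:
    """Declarative description of a full run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    K: int = 20
    mu: float = 0.5
    T: int = 20
    k: Optional[int] = None          # None: choose by eigengap
    k_max: int = 8
    n_imputations: int = 5
    n_sweeps: int = 10
    top_n: int = 20
    ridge: float = 1e-4
    train_fraction: float = 0.702
    bootstrap_b: int = 2000
    edge_quantile: float = 0.9
    support_ratio: float = 0.5
    with_missingness: bool = True
    run_validation: bool = True
    run_evaluation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {})
        cfg = cls(**raw)
        if cohort_kwargs:
            cfg.cohort = CohortConfig(**cohort_kwargs)
        return cfg


@dataclass
class RunReport:
    config_echo: str
    seeds: dict
    cluster_sizes: list
    chosen_k: int
    best_k_eigengap: int
    model_selection: pd.DataFrame
    silhouette: float
    ari_vs_truth: Optional[float]
    nmi_ranking: pd.DataFrame
    contributions: pd.DataFrame
    validation: Optional[dict]
    diagnostics: Optional[pd.DataFrame]
    survival: Optional[dict]
    timings: dict

    def to_text(self) -> str:
        """Deterministic report body (timings are excluded)."""
        buf = io.StringIO()
        w = buf.write
        w("# sgasnf run report\n\n## configuration\n")
        w(self.config_echo + "\n")
        w("\n## stage seeds\n")
        for k, v in self.seeds.items():
            w(f"{k} = {v}\n")
        w("\n## clustering\n")
        w(f"chosen_k = {self.chosen_k}\n")
        w(f"best_k_eigengap = {self.best_k_eigengap}\n")
        w(f"cluster_sizes = {self.cluster_sizes}\n")
        w(f"silhouette = {self.silhouette:.4f}\n")
        if self.ari_vs_truth is not None:
            w(f"ari_vs_truth = {self.ari_vs_truth:.4f}\n")
        w("\n## model selection\n")
        w(self.model_selection.to_string(index=False,
                                         float_format=lambda x: f"{x:.6f}") + "\n")
        w("\n## top NMI features\n")
        w(self.nmi_ranking.head(20).to_string(
            index=False, float_format=lambda x: f"{x:.4f}") + "\n")
        w("\n## data-type contributions\n")
        w(self.contributions.to_string(index=False,
                                       float_format=lambda x: f"{x:.2f}") + "\n")
        if self.validation is not None:
            w("\n## train/test validation\n")
            w(f"accuracy = {self.validation['accuracy']:.4f}\n")
            w(f"auroc = {self.validation['auroc']:.4f}\n")
        if self.diagnostics is not None:
            w("\n## diagnostic comparison\n")
            w(self.diagnostics.to_string(index=False,
                                         float_format=lambda x: f"{x:.4f}") + "\n")
        if self.survival is not None:
            w("\n## survival\n")
            w(f"logrank_statistic = {self.survival['logrank_statistic']:.4f}\n")
            w(f"logrank_p = {self.survival['logrank_p']:.3e}\n")
            w(f"cox_hr = {self.survival['cox_hr']:.4f}\n")
            w(f"cox_hr_ci = ({self.survival['cox_ci'][0]:.4f}, "
              f"{self.survival['cox_ci'][1]:.4f})\n")
            w(f"cox_ph_test_p = {self.survival['ph_test_p']:.4f}\n")
        return buf.getvalue()


def _diag_rows(system: str, outcome: str, summary) -> dict:
    row = {"system": system, "outcome": outcome}
    for name, est in summary.as_dict().items():
        row[name] = est.value
        row[f"{name}_lo"] = est.lo
        row[f"{name}_hi"] = est.hi
    return row


def run_pipeline(config: PipelineConfig | str | Path,
                 outdir: Optional[str | Path] = None) -> RunReport:
    """Execute every stage in order; optionally write artifacts."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    timings: dict[str, float] = {}
    stage_names = ("generate", "missingness", "prepare", "cluster", "rank",
                   "validate", "evaluate")
    state = np.random.SeedSequence(config.seed).generate_state(len(stage_names))
    seeds = {name: int(s) % 2**31 for name, s in zip(stage_names, state)}

    def tic(name):
        timings[name] = time.perf_counter()

    def toc(name):
        timings[name] = time.perf_counter() - timings[name]

    tic("generate")
    cohort_cfg = config.cohort
    cohort_cfg.seed = seeds["generate"]
    cohort = generate_cohort(cohort_cfg)
    toc("generate")

    tic("missingness")
    if config.with_missingness:
        cohort = inject_missingness(cohort, cohort_cfg.missing_rates,
                                    seed=seeds["missingness"],
                                    features=cohort_cfg.features)
    toc("missingness")

    tic("prepare")
    pooled, standardized = prepare_cohort(
        cohort, n_imputations=config.n_imputations, n_sweeps=config.n_sweeps,
        seed=seeds["prepare"])
    fusion = SNFusion(K=config.K, mu=config.mu, T=config.T).fit(standardized)
    toc("prepare")

    tic("cluster")
    selection = estimate_k(fusion.fused_affinity_, k_max=config.k_max)
    best_k = selection.attrs["best_k_eigengap"]
    chosen_k = config.k if config.k is not None else best_k
    assign = spectral_cluster(fusion.fused_affinity_, chosen_k,
                              seed=seeds["cluster"])
    sil, _ = silhouette_from_similarity(fusion.fused_affinity_, assign.labels)
    ari = None
    if cohort.true_labels is not None:
        from sklearn.metrics import adjusted_rand_score
        ari = float(adjusted_rand_score(cohort.true_labels, assign.labels))
    toc("cluster")

    tic("rank")
    ranking = rank_features_by_nmi(standardized, assign, k=chosen_k,
                                   K=config.K, mu=config.mu, seed=seeds["rank"])
    contributions = datatype_contribution(
        fusion.kernels_, fusion.fused_affinity_,
        edge_quantile=config.edge_quantile, support_ratio=config.support_ratio,
        domains=fusion.domains_)
    toc("rank")

    tic("validate")
    validation = None
    if config.run_validation:
        tr = transfer_validation(
            cohort, k=chosen_k, K=config.K, mu=config.mu, T=config.T,
            top_n=config.top_n, ridge=config.ridge,
            train_fraction=config.train_fraction,
            n_imputations=config.n_imputations, n_sweeps=config.n_sweeps,
            seed=seeds["validate"])
        validation = {"accuracy": tr.accuracy, "auroc": tr.auroc,
                      "top_features": tr.top_features}
    toc("validate")

    tic("evaluate")
    diagnostics = None
    survival = None
    if config.run_evaluation:
        out = cohort.outcomes.data
        # high-risk phenotype: the cluster that delivers soonest after diagnosis
        medians = [np.median(out.loc[assign.labels == c, "interval_weeks"])
                   for c in range(1, chosen_k + 1)]
        risk_label = int(np.argmin(medians)) + 1
        flags_snf = (assign.labels == risk_label).astype(int)
        flags_clin = clinical_classification(pooled["ultrasound"].values)
        rows = []
        for outcome in BINARY_OUTCOMES:
            if outcome not in out.columns:
                continue
            y = out[outcome].to_numpy(dtype=int)
            if y.min() == y.max():
                continue  # outcome absent in this cohort draw
            rows.append(_diag_rows("snf_clusters", outcome,
                                   diagnostic_stats(contingency(flags_snf, y))))
            rows.append(_diag_rows("clinical", outcome,
                                   diagnostic_stats(contingency(flags_clin, y))))
        diagnostics = pd.DataFrame(rows)
        surv = km_logrank(out["interval_weeks"], out["event"], flags_snf)
        cov = pd.DataFrame(
            {"gestational_age_dx":
             pooled["clinical"].values["gestational_age_dx"].to_numpy()})
        cox = cox_hr(out["interval_weeks"], out["event"], flags_snf,
                     covariates=cov)
        survival = {"logrank_statistic": surv.logrank_statistic,
                    "logrank_p": surv.logrank_p,
                    "cox_hr": cox.hazard_ratio, "cox_ci": cox.ci,
                    "ph_test_p": cox.ph_test_p}
    toc("evaluate")

    cfg_echo = yaml.safe_dump(
        {"n_patients": cohort_cfg.n_patients, "K": config.K, "mu": config.mu,
         "T": config.T, "k": config.k, "k_max": config.k_max,
         "n_imputations": config.n_imputations, "n_sweeps": config.n_sweeps,
         "top_n": config.top_n, "train_fraction": config.train_fraction,
         "bootstrap_b": config.bootstrap_b, "seed": config.seed},
        sort_keys=True).strip()

    report = RunReport(
        config_echo=cfg_echo, seeds=seeds, cluster_sizes=assign.sizes.tolist(),
        chosen_k=chosen_k, best_k_eigengap=best_k, model_selection=selection,
        silhouette=sil, ari_vs_truth=ari, nmi_ranking=ranking,
        contributions=contributions, validation=validation,
        diagnostics=diagnostics, survival=survival, timings=timings)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort")
        np.savetxt(outdir / "fused_affinity.tsv", fusion.fused_affinity_,
                   delimiter="\t")
        pd.DataFrame({"patient_id": cohort.patient_ids,
                      "cluster": assign.labels}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False)
        ranking.to_csv(outdir / "nmi_ranking.tsv", sep="\t", index=False)
        contributions.to_csv(outdir / "contributions.tsv", sep="\t", index=False)
        if diagnostics is not None:
            diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(report.to_text())
        (outdir / "timings.txt").write_text(
            "".join(f"{k} = {v:.3f} s\n" for k, v in timings.items()))
    return report
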