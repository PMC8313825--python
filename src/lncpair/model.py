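"""Model/Results interface for the rank-pair prognostic cascade.

:class:`PairSignatureModel` bundles the inputs (expression, clinical,
annotation, immune gene set) with a :class:`PipelineConfig` of thresholds;
``fit()`` runs the whole cascade

    irlncRNA screen -> differential expression -> pair matrix -> validity
    filter -> univariate Cox screen -> LASSO-Cox CV -> forward-stepwise Cox
    -> risk score -> time-dependent ROC -> AIC cutpoint -> stratification

and returns a :class:`PairSignatureResults` carrying the signature, the risk
profile, AUCs, all intermediate fits, and a stage-by-stage manifest. The
downstream comparisons hang off the results object.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import coxph, downstream, io, lasso, pairing, screening
from . import signature as sigmod

__all__ = ["PipelineConfig", "PairSignatureModel", "PairSignatureResults", "StageError"]

DAYS_PER_YEAR = 365.0


class StageError(RuntimeError):
    """A pipeline stage produced an empty survivor set."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.manifest = manifest or {}


class PipelineConfig(BaseModel):
    """Every tunable threshold of the cascade, with its conventional default."""

    r_min: float = Field(0.4, ge=-1, le=1)          # irlncRNA correlation threshold
    cor_p: float = Field(0.001, gt=0, le=1)
    abs_cor: bool = False
    lfc_min: float = Field(1.0, ge=0)               # |log2FC| gate
    fdr_max: float = Field(0.05, gt=0, le=1)
    de_engine: str = "wilcoxon"
    pair_low: float = Field(0.2, gt=0, lt=1)
    pair_high: float = Field(0.8, gt=0, lt=1)
    uni_p: float = Field(0.05, ge=0, le=1)
    lambda_rule: str = "lambda_min"                 # or "lambda_1se"
    n_folds: int = Field(10, ge=2)
    ties: str = "efron"
    min_group_frac: float = Field(0.1, gt=0, lt=0.5)
    eval_years: tuple[float, ...] = (1.0, 3.0, 5.0)
    cutpoint_year: float = 5.0
    lnc_biotypes: tuple[str, ...] = tuple(sorted(io.LNCRNA_BIOTYPES))
    seed: int = 0


@dataclass
class PairSignatureResults:
    """Fitted cascade: estimates, uncertainties, diagnostics, and stage outputs."""

    model: "PairSignatureModel"
    signature: sigmod.Signature
    final_fit: coxph.CoxFit
    risk_profile: sigmod.RiskProfile
    cutpoint_scan: sigmod.CutpointScan
    roc: dict[float, sigmod.TimedROC]          # years -> TimedROC
    correlation_screen: screening.CorrelationScreen
    de: screening.DifferentialExpression
    pair_matrix: pairing.PairMatrix            # valid pairs x patients
    univariate_hits: list[tuple[str, coxph.CoxFit]]
    lasso_fit: lasso.LassoCoxFit
    manifest: dict = field(default_factory=dict)

    # -- headline quantities ----------------------------------------------
    @property
    def auc(self) -> dict[float, float]:
        return {yr: roc.auc for yr, roc in self.roc.items()}

    @property
    def cutoff(self) -> float:
        return self.risk_profile.cutoff

    def km_by_group(self) -> dict[str, coxph.KMCurve]:
        cl = self.model.clinical.aligned_to(self.risk_profile.scores.index)
        out = {}
        for grp in ("high", "low"):
            ids = [s for s in cl.sample_ids if self.risk_profile.group[s] == grp]
            sub = cl.aligned_to(ids)
            out[grp] = coxph.km_estimate(sub.os_time, sub.os_event)
        return out

    def logrank(self) -> tuple[float, float]:
        cl = self.model.clinical.aligned_to(self.risk_profile.scores.index)
        g = (self.risk_profile.group.loc[cl.sample_ids] == "high").to_numpy().astype(int)
        return coxph.logrank_test(cl.os_time, cl.os_event, g)

    # -- downstream comparisons -------------------------------------------
    def clinical_association(self, features: Iterable[str] | None = None):
        cl = self.model.clinical.aligned_to(self.risk_profile.scores.index)
        return downstream.clinical_association(self.risk_profile, cl, features)

    def independence_cox(self, ordinal_map=None):
        cl = self.model.clinical.aligned_to(self.risk_profile.scores.index)
        return downstream.independence_cox(self.risk_profile.scores, cl, ordinal_map,
                                           ties=self.model.config.ties)

    def immune_correlation(self, infil: downstream.InfiltrationTable):
        return downstream.immune_correlation(self.risk_profile, infil)

    def group_expression_compare(self, gene_list=downstream.DEFAULT_ICI_GENES):
        return downstream.group_expression_compare(self.model.expression, self.risk_profile,
                                                   gene_list)

    def drug_sensitivity_compare(self, drugs: downstream.DrugResponseTable):
        return downstream.drug_sensitivity_compare(self.risk_profile, drugs)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.manifest
        lines = [
            "Rank-pair prognostic signature",
            "=" * 62,
            f"patients: {m['n_patients']}   events: {m['n_events']}",
            f"lncRNAs in matrix:          {m['n_lnc']}",
            f"immune-related lncRNAs:     {m['n_irlnc']}",
            f"differentially expressed:   {m['n_de']} ({m['n_de_up']} up / {m['n_de_down']} down)",
            f"pairs built:                {m['n_pairs']}",
            f"valid pairs (20-80%):       {m['n_valid_pairs']}",
            f"univariate survivors:       {m['n_univariate']}",
            f"LASSO candidates:           {m['n_lasso']}  (lambda rule: "
            f"{self.lasso_fit.lambda_rule}, lambda = {self.lasso_fit.chosen_lambda:.5g})",
            f"final signature size:       {len(self.signature)}",
            "",
            "Final multivariate Cox fit (Wald):",
            self.final_fit.summary().to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "Time-dependent AUC: "
            + "  ".join(f"{yr:g}y = {auc:.3f}" for yr, auc in sorted(self.auc.items())),
            f"Risk cutoff (AIC minimum on the {self.cutpoint_scan.t_ref / DAYS_PER_YEAR:g}-year "
            f"horizon): {self.cutoff:.4f}",
            f"High risk: {self.risk_profile.n_high}   Low risk: {self.risk_profile.n_low}",
        ]
        chi2, p = self.logrank()
        lines.append(f"Log-rank high vs low: chi2 = {chi2:.2f}, p = {p:.3g}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every stage output as TSV plus a JSON manifest."""
        import json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlation_screen.results.to_csv(out / "correlations.tsv", sep="\t", index=False)
        pd.Series(self.correlation_screen.retained).to_csv(
            out / "irlncRNAs.txt", index=False, header=False
        )
        self.de.table.to_csv(out / "differential_expression.tsv", sep="\t")
        self.pair_matrix.to_tsv(out / "valid_pairs.tsv")
        uni = pd.DataFrame(
            [
                {"pair_id": pid, "beta": f.beta[0], "HR": f.hr[0], "p": f.p[0]}
                for pid, f in self.univariate_hits
            ]
        )
        uni.to_csv(out / "univariate_hits.tsv", sep="\t", index=False)
        self.final_fit.summary().to_csv(out / "signature_cox.tsv", sep="\t")
        self.risk_profile.as_frame().to_csv(out / "risk_profile.tsv", sep="\t")
        self.cutpoint_scan.as_frame().to_csv(out / "cutpoint_scan.tsv", sep="\t", index=False)
        for yr, roc in self.roc.items():
            roc.as_frame().to_csv(out / f"roc_{yr:g}y.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, default=str))


class PairSignatureModel:
    """The rank-pair prognostic model, statsmodels-style: data in, ``fit()`` out.

    Parameters
    ----------
    expression
        Gene x sample matrix with tumor/normal labels; must contain both
        lncRNAs (per ``annotation``) and immune genes.
    clinical
        Survival table for the tumor samples (cleaned).
    annotation
        gene id -> biotype map used to restrict to lncRNAs.
    immune_genes
        Curated immune-related gene identifiers.
    config
        Thresholds; defaults reproduce the conventional cascade settings.
    """

    def __init__(
        self,
        expression: io.ExpressionMatrix,
        clinical: io.ClinicalTable,
        annotation: io.GeneAnnotation,
        immune_genes: io.ImmuneGeneSet,
        config: PipelineConfig | None = None,
    ):
        self.expression = expression
        self.clinical = clinical
        self.annotation = annotation
        self.immune_genes = immune_genes
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(
        cls,
        expression_path,
        clinical_path,
        annotation_path,
        immune_genes_path,
        groups_path=None,
        config: PipelineConfig | None = None,
    ) -> "PairSignatureModel":
        expr = io.load_expression(expression_path, group_path=groups_path)
        clinical, _ = io.load_clinical(clinical_path)
        annotation = io.load_annotation(annotation_path)
        immune = io.load_gene_set(immune_genes_path)
        return cls(expr, clinical, annotation, immune, config)

    def fit(self, log=None) -> PairSignatureResults:
        cfg = self.config
        manifest: dict = {"config": cfg.model_dump(), "stages": []}

        def record(stage: str, t0: float, **counts):
            manifest["stages"].append(
                {"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **counts}
            )
            manifest.update(counts)
            if log:
                log(f"{stage}: {counts} ({manifest['stages'][-1]['seconds']}s)")

        # -- restrict to lncRNAs and immune genes --------------------------
        t0 = time.perf_counter()
        lnc_expr = io.subset_lncrnas(self.expression, self.annotation, cfg.lnc_biotypes)
        immune_present = [g for g in self.expression.gene_ids if g in self.immune_genes]
        record("subset", t0, n_genes=self.expression.n_genes, n_lnc=lnc_expr.n_genes,
               n_immune=len(immune_present))
        if not immune_present:
            raise StageError("subset", "no immune genes found in the matrix", manifest)

        # -- irlncRNA co-expression screen ---------------------------------
        t0 = time.perf_counter()
        screen = screening.screen_irlncrnas(
            self.expression, lnc_expr.gene_ids, immune_present,
            r_min=cfg.r_min, p_max=cfg.cor_p, abs_cor=cfg.abs_cor,
        )
        record("irlncRNA_screen", t0, n_irlnc=len(screen.retained))
        if not screen.retained:
            raise StageError("irlncRNA_screen", "no immune-related lncRNAs retained", manifest)

        # -- differential expression ---------------------------------------
        t0 = time.perf_counter()
        ir_expr = self.expression.subset_genes(screen.retained)
        de = screening.differential_expression(
            ir_expr, lfc_min=cfg.lfc_min, fdr_max=cfg.fdr_max, engine=cfg.de_engine
        )
        record("differential_expression", t0, n_de=len(de.de_genes),
               n_de_up=de.n_up, n_de_down=de.n_down)
        if len(de.de_genes) < 2:
            raise StageError("differential_expression", "fewer than 2 DE irlncRNAs", manifest)

        # -- pair construction on patients ---------------------------------
        t0 = time.perf_counter()
        patients = [s for s in self.expression.sample_ids
                    if s in self.clinical.data.index]
        if not patients:
            raise StageError("pairing", "no overlap between expression and clinical samples",
                             manifest)
        de_expr = self.expression.subset_genes(de.de_genes).subset_samples(patients)
        pm_all = pairing.build_pair_matrix(de_expr)
        pm = pairing.filter_valid_pairs(pm_all, cfg.pair_low, cfg.pair_high)
        record("pairing", t0, n_patients=len(patients), n_pairs=pm_all.n_pairs,
               n_valid_pairs=pm.n_pairs)
        if pm.n_pairs == 0:
            raise StageError("pairing", "no valid pairs after the frequency filter", manifest)

        clinical = self.clinical.aligned_to(patients)
        manifest["n_events"] = int(clinical.os_event.sum())

        # -- univariate Cox screen -----------------------------------------
        t0 = time.perf_counter()
        hits, uni_report = coxph.univariate_pair_screen(pm, clinical, p_max=cfg.uni_p,
                                                        ties=cfg.ties)
        record("univariate", t0, n_univariate=len(hits), **{
            "univariate_dropped_unidentifiable": uni_report["n_unidentifiable"],
            "univariate_dropped_nonconverged": uni_report["n_nonconverged"]})
        if not hits:
            raise StageError("univariate", "no pair passed the univariate screen", manifest)

        # -- LASSO-Cox ------------------------------------------------------
        t0 = time.perf_counter()
        cand_ids = [pid for pid, _ in hits]
        Xcand = pm.indicators.loc[cand_ids, clinical.sample_ids].to_numpy(dtype=float).T
        lfit = lasso.lasso_cox(
            clinical.os_time, clinical.os_event, Xcand, names=cand_ids,
            n_folds=cfg.n_folds, seed=cfg.seed, lambda_rule=cfg.lambda_rule,
        )
        selected = lfit.selected
        record("lasso", t0, n_lasso=len(selected))
        if not selected:
            raise StageError("lasso", "LASSO selected no pairs", manifest)

        # -- forward stepwise multivariate Cox ------------------------------
        t0 = time.perf_counter()
        Xsel = pm.indicators.loc[selected, clinical.sample_ids].to_numpy(dtype=float).T
        final = coxph.stepwise_cox(clinical.os_time, clinical.os_event, Xsel,
                                   names=selected, ties=cfg.ties)
        record("stepwise", t0, n_signature=final.k)
        if final.k == 0:
            raise StageError("stepwise", "stepwise selection kept no pair", manifest)
        sig = sigmod.Signature(list(zip(final.names, final.beta)))

        # -- scoring, ROC, cutpoint, stratification -------------------------
        t0 = time.perf_counter()
        scores = sigmod.risk_score(pm, sig).loc[clinical.sample_ids]
        roc = {}
        for yr in cfg.eval_years:
            t_eval = yr * DAYS_PER_YEAR
            try:
                roc[yr] = sigmod.td_roc(clinical.os_time, clinical.os_event,
                                        scores.to_numpy(), t_eval)
            except ValueError:
                continue  # horizon outside follow-up: reported absent
        scan = sigmod.aic_cutpoint(
            clinical.os_time, clinical.os_event, scores.to_numpy(),
            t_ref=cfg.cutpoint_year * DAYS_PER_YEAR,
            min_group_frac=cfg.min_group_frac, ties=cfg.ties,
        )
        profile = sigmod.stratify(scores, scan.cutoff)
        record("evaluate", t0, n_high=profile.n_high, n_low=profile.n_low,
               auc={f"{yr:g}y": round(r.auc, 4) for yr, r in roc.items()},
               cutoff=scan.cutoff)

        return PairSignatureResults(
            model=self,
            signature=sig,
            final_fit=final,
            risk_profile=profile,
            cutpoint_scan=scan,
            roc=roc,
            correlation_screen=screen,
            de=de,
            pair_matrix=pm,
            univariate_hits=hits,
            lasso_fit=lfit,
            manifest=manifest,
        )
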