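"""Synthetic cohort generator with known ground truth.

Emulates the inputs of the pipeline at desk scale: a tumor/normal FPKM-like
expression matrix in which a subset of lncRNAs shares latent factors with
immune genes (log-scale co-expression with closed-form correlation
r = a^2 / (a^2 + 1) for loading a and unit noise), a subset is
differentially expressed in tumors, survival times follow an exponential
proportional-hazards model whose log hazard is a known linear combination of
planted pair indicators, censoring is independent exponential plus an
administrative cutoff, and infiltration / IC50 tables are shifted along the
true linear predictor. Every quantity needed to audit the pipeline (planted
pairs, betas, per-sample eta) is emitted as a SimTruth.

What this generator does not emulate: batch effects, tumor subtypes,
realistic FPKM marginals beyond log-normality, or dependent censoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .downstream import DrugResponseTable, InfiltrationTable
from .io import ClinicalTable, ExpressionMatrix, GeneAnnotation, ImmuneGeneSet
from .pairing import PAIR_SEP, build_pair_matrix
from .signature import Signature, risk_score

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_expression",
    "simulate_survival",
    "simulate_downstream_tables",
    "simulate_dataset",
    "write_dataset",
]


class SimConfig(BaseModel):
    """Generative settings; the defaults define the package's study conditions."""

    n_tumor: int = Field(100, gt=0)
    n_normal: int = Field(20, gt=0)
    n_lnc: int = Field(60, gt=0)
    n_immune: int = Field(30, gt=0)
    n_coexpressed: int = Field(20, ge=0)
    n_de: int = Field(30, gt=0)
    de_log2fc: float = 2.0
    target_r: float = Field(0.7, gt=0.0, lt=1.0)
    planted_betas: tuple[float, ...] = (1.0, -1.0)
    baseline_hazard: float = Field(1.0 / 1000.0, gt=0)  # events per day
    censor_rate: float = Field(1.0 / 2000.0, ge=0)      # per day
    admin_censor_time: float = Field(3650.0, gt=0)      # days
    stage_eta_corr: float = Field(0.2, ge=-1.0, le=1.0)
    infiltration_rho: float = 0.4
    drug_gammas: dict[str, float] = Field(
        default_factory=lambda: {
            "methotrexate": -0.5, "docetaxel": 0.5, "cisplatin": 0.0, "paclitaxel": 0.0
        }
    )
    cell_types: tuple[str, ...] = (
        "B_cell", "mast_cell", "myeloid_dendritic", "NK_cell",
        "T_reg", "CD4_T_cell", "CD8_T_cell",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_counts(self):
        if self.n_coexpressed > min(self.n_lnc, self.n_immune):
            raise ValueError("n_coexpressed cannot exceed n_lnc or n_immune")
        if self.n_de > self.n_lnc:
            raise ValueError("n_de cannot exceed n_lnc")
        need = 2 * len(self.planted_betas)
        if need > min(self.n_de, self.n_coexpressed):
            raise ValueError(
                "planted pairs need 2 genes each drawn from the co-expressed "
                "differentially expressed lncRNAs; increase n_de/n_coexpressed"
            )
        return self

    @property
    def loading(self) -> float:
        """Latent-factor loading a with log-scale correlation a^2/(a^2+1) = target_r."""
        return float(np.sqrt(self.target_r / (1.0 - self.target_r)))


@dataclass
class SimTruth:
    """Planted ground truth: pairs with betas and the per-sample linear predictor."""

    planted_pairs: list[tuple[str, str, float]]
    eta: pd.Series                  # per tumor sample
    indicators: pd.DataFrame        # planted pair indicators x tumor samples
    coexpressed_lncs: list[str]
    de_lncs: list[str]
    seed: int

    @property
    def signature(self) -> Signature:
        return Signature([(f"{a}{PAIR_SEP}{b}", beta) for a, b, beta in self.planted_pairs])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [[a, b, beta] for a, b, beta in self.planted_pairs],
            "eta": {s: float(v) for s, v in self.eta.items()},
            "indicators": {
                pid: [int(v) for v in row]
                for pid, row in zip(self.indicators.index, self.indicators.to_numpy())
            },
            "samples": list(self.indicators.columns),
            "coexpressed_lncs": self.coexpressed_lncs,
            "de_lncs": self.de_lncs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_pairs=[(a, b, float(z)) for a, b, z in payload["planted_pairs"]],
            eta=pd.Series(payload["eta"]),
            indicators=pd.DataFrame(
                payload["indicators"], index=payload["samples"]
            ).T.astype(int),
            coexpressed_lncs=payload["coexpressed_lncs"],
            de_lncs=payload["de_lncs"],
            seed=payload["seed"],
        )


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    streams = {"expression": 0, "survival": 1, "downstream": 2}
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(streams[stream],))
    return np.random.default_rng(ss)


def simulate_expression(cfg: SimConfig):
    """Draw the expression matrix, annotation, immune gene set, and partial truth.

    Log2-scale model per sample s and gene g:
      lncRNA i:   x = mu_i + a*F_c(s) [if co-expressed with immune gene c]
                      + de_log2fc*1(tumor) [if DE] + eps,  eps ~ N(0,1)
      immune c:   x = mu_c + a*F_c(s) [if partnered] + eps
    Values are exponentiated (2^x) to a non-negative FPKM-like scale. The two
    member genes of each planted pair share the same baseline mean so their
    indicator frequency sits mid-range and survives the validity filter.
    """
    rng = _rng(cfg, "expression")
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lnc)]
    imm_ids = [f"IMM{i:04d}" for i in range(cfg.n_immune)]
    samples = [f"T{i:04d}" for i in range(cfg.n_tumor)] + [
        f"N{i:04d}" for i in range(cfg.n_normal)
    ]
    n = len(samples)
    is_tumor = np.array([s.startswith("T") for s in samples])

    a = cfg.loading
    mu_lnc = rng.uniform(2.0, 6.0, size=cfg.n_lnc)
    mu_imm = rng.uniform(2.0, 6.0, size=cfg.n_immune)

    # planted pairs occupy the first 2*k lncRNAs (co-expressed AND DE prefix)
    planted: list[tuple[str, str, float]] = []
    for j, beta in enumerate(cfg.planted_betas):
        ia, ib = 2 * j, 2 * j + 1
        mu_lnc[ib] = mu_lnc[ia]  # equal baselines -> informative indicator
        g1, g2 = lnc_ids[ia], lnc_ids[ib]
        if g1 > g2:
            g1, g2 = g2, g1
        planted.append((g1, g2, float(beta)))

    F = rng.standard_normal((cfg.n_coexpressed, n))  # one factor per partnered couple
    L = mu_lnc[:, None] + rng.standard_normal((cfg.n_lnc, n))
    L[: cfg.n_coexpressed] += a * F
    de_ids = lnc_ids[: cfg.n_de]
    L[: cfg.n_de, :] += cfg.de_log2fc * is_tumor[None, :]
    M = mu_imm[:, None] + rng.standard_normal((cfg.n_immune, n))
    M[: cfg.n_coexpressed] += a * F

    values = np.vstack([L, M])
    values = np.exp2(values)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=lnc_ids + imm_ids, columns=samples),
        pd.Series(np.where(is_tumor, "tumor", "normal"), index=samples),
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"biotype": ["lncRNA"] * cfg.n_lnc + ["protein_coding"] * cfg.n_immune,
             "symbol": lnc_ids + imm_ids},
            index=pd.Index(lnc_ids + imm_ids, name="gene_id"),
        )
    )
    immune_set = ImmuneGeneSet(frozenset(imm_ids))
    partial = {
        "planted_pairs": planted,
        "coexpressed_lncs": lnc_ids[: cfg.n_coexpressed],
        "de_lncs": de_ids,
    }
    return expr, annotation, immune_set, partial


def simulate_survival(expr: ExpressionMatrix, cfg: SimConfig, partial: dict | None = None):
    """Draw survival for tumor samples from the planted proportional-hazards model.

    eta = sum(beta_j * C_j) with C_j recomputed from the emitted expression
    through the strict pairing rule; event time ~ Exponential(lambda0*e^eta),
    censoring ~ min(Exponential(censor_rate), administrative cutoff); times
    below one day are rounded up to one day. Clinical stage is mildly
    correlated with eta (``stage_eta_corr``); age, gender, grade, T and N are
    independent noise covariates.
    """
    if partial is None:
        _, _, _, partial = simulate_expression(cfg)
    planted = [(a, b, float(z)) for a, b, z in partial["planted_pairs"]]
    rng = _rng(cfg, "survival")
    tumor = expr.samples_in_group("tumor")
    n = len(tumor)
    tumor_expr = expr.subset_samples(tumor)

    genes = sorted({g for a, b, _ in planted for g in (a, b)})
    pm = build_pair_matrix(tumor_expr.subset_genes(genes))
    sig = Signature([(f"{a}{PAIR_SEP}{b}", z) for a, b, z in planted])
    eta = risk_score(pm, sig)
    indicators = pm.indicators.loc[[f"{a}{PAIR_SEP}{b}" for a, b, z in planted]]

    lam = cfg.baseline_hazard * np.exp(eta.to_numpy())
    t_event = rng.exponential(1.0, size=n) / lam
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, cfg.admin_censor_time)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    os_time = np.maximum(os_time, 1.0)
    if os_event.sum() == 0:
        warnings.warn("degenerate survival simulation: every sample is censored")

    z_eta = (eta.to_numpy() - eta.to_numpy().mean()) / max(eta.to_numpy().std(), 1e-12)
    rho = cfg.stage_eta_corr
    stage_latent = rho * z_eta + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    stage = pd.cut(stage_latent, bins=np.quantile(stage_latent, [0, 0.25, 0.5, 0.75, 1.0]),
                   labels=["I", "II", "III", "IV"], include_lowest=True).astype(str)
    covars = pd.DataFrame(
        {
            "age": np.round(rng.normal(60, 10, size=n)).clip(25, 90),
            "gender": rng.choice(["female", "male"], size=n),
            "grade": rng.choice(["G1", "G2", "G3"], size=n),
            "stage": stage,
            "T": rng.choice(["T1", "T2", "T3", "T4"], size=n),
            "N": rng.choice(["N0", "N1", "N2"], size=n),
        },
        index=tumor,
    )
    clin = pd.DataFrame({"os_time": os_time, "os_event": os_event}, index=pd.Index(tumor, name="sample_id"))
    clinical = ClinicalTable(pd.concat([clin, covars], axis=1))
    truth = SimTruth(
        planted_pairs=planted,
        eta=eta,
        indicators=indicators,
        coexpressed_lncs=partial.get("coexpressed_lncs", []),
        de_lncs=partial.get("de_lncs", []),
        seed=cfg.seed,
    )
    return clinical, truth


def simulate_downstream_tables(truth: SimTruth, cfg: SimConfig):
    """Infiltration and IC50 tables shifted along the true linear predictor.

    Cell-type score = -rho * z(eta) + sqrt(1-rho^2) * noise (negative
    high-risk association by default); per-drug log-IC50 = gamma * z(eta) +
    sqrt(1-gamma^2) * noise with signed per-drug gamma.
    """
    rng = _rng(cfg, "downstream")
    samples = list(truth.eta.index)
    n = len(samples)
    e = truth.eta.to_numpy()
    z = (e - e.mean()) / max(e.std(), 1e-12)

    rows = []
    for cell in cfg.cell_types:
        rho = cfg.infiltration_rho
        score = -rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        rows.append(pd.DataFrame(
            {"sample_id": samples, "cell_type": cell, "method": "simulated", "score": score}
        ))
    infil = InfiltrationTable(pd.concat(rows, ignore_index=True))

    rows = []
    for drug, gamma in cfg.drug_gammas.items():
        log_ic50 = gamma * z + np.sqrt(max(0.0, 1 - gamma**2)) * rng.standard_normal(n)
        rows.append(pd.DataFrame({"sample_id": samples, "drug": drug, "ic50": np.exp(log_ic50)}))
    drugs = DrugResponseTable(pd.concat(rows, ignore_index=True))
    return infil, drugs


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the ground truth."""

    expression: ExpressionMatrix
    annotation: GeneAnnotation
    immune_genes: ImmuneGeneSet
    clinical: ClinicalTable
    truth: SimTruth
    infiltration: InfiltrationTable
    drugs: DrugResponseTable
    config: SimConfig


def simulate_dataset(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """One-call simulation of the complete input bundle."""
    if cfg is None:
        cfg = SimConfig()
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    expr, annotation, immune_set, partial = simulate_expression(cfg)
    clinical, truth = simulate_survival(expr, cfg, partial)
    infil, drugs = simulate_downstream_tables(truth, cfg)
    return SimulatedDataset(expr, annotation, immune_set, clinical, truth, infil, drugs, cfg)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV/JSON bundle the loaders read back."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "sample_groups.tsv",
        "clinical": out / "clinical.tsv",
        "annotation": out / "annotation.tsv",
        "immune_genes": out / "immune_genes.txt",
        "infiltration": out / "infiltration.tsv",
        "ic50": out / "ic50.tsv",
        "truth": out / "truth.json",
    }
    ds.expression.to_tsv(paths["expression"], group_path=paths["groups"])
    ds.clinical.to_tsv(paths["clinical"])
    ds.annotation.to_tsv(paths["annotation"])
    ds.immune_genes.to_file(paths["immune_genes"])
    ds.infiltration.to_tsv(paths["infiltration"])
    ds.drugs.to_tsv(paths["ic50"])
    ds.truth.to_json(paths["truth"])
    return paths
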