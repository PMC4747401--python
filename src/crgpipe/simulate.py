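"""Synthetic cell-line experiments and clinical cohorts with planted truth.

The generator emulates the two data domains the pipeline consumes:

* small-replicate drug-induced resistance experiments — parental and
  resistant lines, untreated and drug-treated at several time points, a
  few technical replicates per condition — with four planted gene classes:

  - *resistance* genes: differential drug response between resistant and
    parental cells, appearing only in the treated-resistant arm with a
    saturating time course (most of the change before 24 h).  A
    *high-expression stratum* of these carries a large absolute change at
    a small fold change (high baseline, modest log2 effect) so the AD/FC
    selection bias has known positives.
  - *drug-response* genes: induced in BOTH cell types under treatment
    (transient: peak early, decayed by 24 h).  The resistant line, having
    been cultured under chronic drug exposure, additionally carries a
    persistent fraction of this response in all its arms — which is what
    makes basally deregulated (BD) lists direction-consistent with
    inducible-in-parental (IP) lists, the confounding phenomenon the
    pipeline is built to expose.
  - *basal-difference* genes: line-to-line differences irrelevant to
    resistance.
  - *null* genes: replicate noise only.

* clinical responder / non-responder cohorts — non-responders carry the
  resistance-gene effects of the regimen's drugs, attenuated relative to
  the cell line and scaled by a per-patient heterogeneity factor;
  post-chemotherapy cohorts additionally carry treated-state effects in
  every patient; cohorts can span several datasets with per-dataset
  per-gene batch shifts.

Effects are log-additive (multiplicative on the linear intensity scale),
so both FC and AD are meaningful.  All output is bit-identical for an
identical (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import LINEAR, ExpressionMatrix, make_sample_table


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults describe a 5000-gene array with 3 replicates per condition,
    treatment times 0/6/12/24 h, two drugs, and clinical cohorts split
    over several datasets; see the package methods note for the rationale
    behind each default.
    """

    seed: int
    n_genes: int = 5000
    drugs: tuple[str, ...] = ("5-FU", "L-OHP")
    n_replicates: int = 3
    time_points: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0)

    # gene-class sizes
    n_resistance_shared: int = 60   # resistant to every drug, one direction
    n_resistance_specific: int = 60  # per drug, disjoint blocks
    n_stratum: int = 20             # high-expression/low-FC subset of shared
    n_drug_response: int = 300
    n_basal: int = 150

    # effect sizes (log2 units) and kinetics (hours)
    resistance_effect: float = 2.0
    resistance_t_sat: float = 12.0
    stratum_effect: float = 0.35
    stratum_baseline_log2: float = 12.0
    drug_response_effect: float = 2.0
    drug_response_t_peak: float = 6.0
    drug_response_t_end: float = 30.0
    chronic_imprint: float = 0.8
    basal_effect: float = 1.0

    # baseline and noise (log2 units)
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 2.0
    noise_sd_log2: float = 0.25

    # clinical cohorts: (n_responders, n_non_responders) per dataset
    clinical_datasets: tuple[tuple[int, int], ...] = ((10, 13), (9, 12), (4, 4))
    post_datasets: tuple[tuple[int, int], ...] = ((13, 17),)
    attenuation: float = 0.6
    heterogeneity_sd: float = 0.35
    batch_sd: float = 0.5
    post_treatment_level: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        n_classes = (
            self.n_resistance_shared
            + self.n_resistance_specific * len(self.drugs)
            + self.n_drug_response
            + self.n_basal
        )
        if n_classes > self.n_genes:
            raise ValueError(
                f"gene-class sizes sum to {n_classes} > n_genes={self.n_genes}"
            )
        if self.n_stratum > self.n_resistance_shared:
            raise ValueError("n_stratum must not exceed n_resistance_shared")
        for name in ("noise_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


RESISTANCE = "resistance"
DRUG_RESPONSE = "drug_response"
BASAL = "basal_difference"
NULL = "null"


@dataclass
class GroundTruth:
    """Per-gene planted truth: class, stratum, baseline, per-drug effects.

    ``table`` is indexed by gene_id with columns ``gene_class``,
    ``stratum`` (bool), ``baseline_log2``, ``dr_dir`` (drug-response
    direction, 0 for other classes) and per drug ``res_dir_<drug>``,
    ``res_effect_<drug>``, ``basal_dir_<drug>``.
    """

    table: pd.DataFrame
    drugs: tuple[str, ...]

    def resistance_genes(self, drug: str) -> list[str]:
        """Gene ids with a planted resistance effect for ``drug``."""
        col = f"res_dir_{drug}"
        return list(self.table.index[self.table[col] != 0])

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.table.index[self.table["gene_class"] == gene_class])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "drugs", ";".join(self.drugs))
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        # keep_default_na: the class label "null" must survive as a string
        table = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
        drugs = tuple(table.pop("drugs").iloc[0].split(";"))
        if table["stratum"].dtype == object:
            table["stratum"] = table["stratum"].map({"True": True, "False": False})
        table["stratum"] = table["stratum"].astype(bool)
        table["baseline_log2"] = table["baseline_log2"].astype(float)
        for col in table.columns:
            if col.startswith("res_effect_"):
                table[col] = table[col].astype(float)
        for drug in drugs:
            table[f"res_dir_{drug}"] = table[f"res_dir_{drug}"].astype(int)
            table[f"basal_dir_{drug}"] = table[f"basal_dir_{drug}"].astype(int)
        table["dr_dir"] = table["dr_dir"].astype(int)
        return cls(table=table, drugs=drugs)


def _rng(config: GeneratorConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *keys]))


def _drug_key(drug: str) -> int:
    return zlib.crc32(drug.encode())


def make_truth(config: GeneratorConfig) -> GroundTruth:
    """Draw the planted gene classes, directions and baselines."""
    rng = _rng(config, 101)
    n = config.n_genes
    width = max(4, len(str(n - 1)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(n)], name="gene_id")
    table = pd.DataFrame(
        {
            "gene_class": NULL,
            "stratum": False,
            "baseline_log2": rng.normal(
                config.baseline_mean_log2, config.baseline_sd_log2, n
            ),
            "dr_dir": 0,
        },
        index=genes,
    )
    for drug in config.drugs:
        table[f"res_dir_{drug}"] = 0
        table[f"res_effect_{drug}"] = 0.0
        table[f"basal_dir_{drug}"] = 0

    pos = 0

    def take(count: int) -> pd.Index:
        nonlocal pos
        block = genes[pos : pos + count]
        pos += count
        return block

    signs = lambda count: rng.choice([-1, 1], size=count)

    shared = take(config.n_resistance_shared)
    table.loc[shared, "gene_class"] = RESISTANCE
    shared_dir = signs(len(shared))
    for drug in config.drugs:
        table.loc[shared, f"res_dir_{drug}"] = shared_dir
        table.loc[shared, f"res_effect_{drug}"] = config.resistance_effect
    stratum = shared[: config.n_stratum]
    table.loc[stratum, "stratum"] = True
    table.loc[stratum, "baseline_log2"] = rng.normal(
        config.stratum_baseline_log2, 0.3, len(stratum)
    )
    for drug in config.drugs:
        table.loc[stratum, f"res_effect_{drug}"] = config.stratum_effect

    for drug in config.drugs:
        block = take(config.n_resistance_specific)
        table.loc[block, "gene_class"] = RESISTANCE
        table.loc[block, f"res_dir_{drug}"] = signs(len(block))
        table.loc[block, f"res_effect_{drug}"] = config.resistance_effect

    dr = take(config.n_drug_response)
    table.loc[dr, "gene_class"] = DRUG_RESPONSE
    table.loc[dr, "dr_dir"] = signs(len(dr))

    basal = take(config.n_basal)
    table.loc[basal, "gene_class"] = BASAL
    for drug in config.drugs:
        table.loc[basal, f"basal_dir_{drug}"] = signs(len(basal))

    return GroundTruth(table=table, drugs=config.drugs)


def _resistance_kinetics(t: float, config: GeneratorConfig) -> float:
    """Saturating ramp: full effect from t_sat on (abrupt change before 24 h)."""
    return min(t / config.resistance_t_sat, 1.0) if t > 0 else 0.0


def _drug_response_kinetics(t: float, config: GeneratorConfig) -> float:
    """Transient response: linear rise to t_peak, linear decay to 0 at t_end."""
    if t <= 0:
        return 0.0
    if t <= config.drug_response_t_peak:
        return t / config.drug_response_t_peak
    return max(
        0.0,
        (config.drug_response_t_end - t)
        / (config.drug_response_t_end - config.drug_response_t_peak),
    )


def generate_cellline_experiment(
    config: GeneratorConfig, drug: str, truth: GroundTruth | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """One drug-induced-resistance experiment as a linear-scale matrix.

    Conditions: {parental, resistant} x time points (t=0 is untreated) x
    replicates.  Expression is 2**(baseline + class effects + noise).
    """
    if drug not in config.drugs:
        raise ValueError(f"drug {drug!r} not in config.drugs {config.drugs}")
    if truth is None:
        truth = make_truth(config)
    rng = _rng(config, 7, _drug_key(drug))
    t_table = truth.table
    baseline = t_table["baseline_log2"].to_numpy()
    dr_eff = t_table["dr_dir"].to_numpy() * config.drug_response_effect
    res_eff = (
        t_table[f"res_dir_{drug}"].to_numpy() * t_table[f"res_effect_{drug}"].to_numpy()
    )
    basal_eff = t_table[f"basal_dir_{drug}"].to_numpy() * config.basal_effect

    columns, records = [], []
    values = []
    for line in ("parental", "resistant"):
        resistant = line == "resistant"
        for t in config.time_points:
            treated = t > 0
            delta = np.zeros(config.n_genes)
            if resistant:
                delta += basal_eff
                delta += dr_eff * config.chronic_imprint
            if treated:
                delta += dr_eff * _drug_response_kinetics(t, config)
                if resistant:
                    delta += res_eff * _resistance_kinetics(t, config)
            for r in range(1, config.n_replicates + 1):
                cond = "untr" if not treated else f"{drug}_{t:g}h"
                sid = f"{'R' if resistant else 'P'}_{cond}_r{r}"
                columns.append(sid)
                records.append(
                    {
                        "sample_id": sid,
                        "cell_line": f"synthetic-{'R' if resistant else 'P'}",
                        "resistance_status": line,
                        "drug": drug if treated else "none",
                        "treatment_time_h": t if treated else np.nan,
                        "cohort": "cell_line",
                        "response": "n/a",
                        "dataset_id": f"cellline_{drug}",
                    }
                )
                noise = rng.normal(0.0, config.noise_sd_log2, config.n_genes)
                values.append(baseline + delta + noise)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(
            np.exp2(np.column_stack(values)), index=t_table.index, columns=columns
        ),
        samples=make_sample_table(records),
        scale=LINEAR,
    )
    return matrix, truth


def _clinical_matrix(
    config: GeneratorConfig,
    truth: GroundTruth,
    regimen_drugs: Sequence[str],
    datasets: Sequence[tuple[int, int]],
    cohort: str,
    rng: np.random.Generator,
    treated_state: bool,
) -> ExpressionMatrix:
    t_table = truth.table
    baseline = t_table["baseline_log2"].to_numpy()
    res_eff = np.zeros(config.n_genes)
    for drug in regimen_drugs:
        res_eff += (
            t_table[f"res_dir_{drug}"].to_numpy()
            * t_table[f"res_effect_{drug}"].to_numpy()
        )
    dr_eff = t_table["dr_dir"].to_numpy() * config.drug_response_effect

    columns, records, values = [], [], []
    for d_idx, (n_resp, n_nonresp) in enumerate(datasets, start=1):
        dataset_id = f"{cohort}_d{d_idx}"
        batch = rng.normal(0.0, config.batch_sd, config.n_genes)
        for response, count in (("responder", n_resp), ("non_responder", n_nonresp)):
            for p in range(1, count + 1):
                h = max(0.0, rng.normal(1.0, config.heterogeneity_sd))
                delta = batch.copy()
                if response == "non_responder":
                    delta += config.attenuation * h * res_eff
                if treated_state:
                    delta += config.post_treatment_level * h * dr_eff
                noise = rng.normal(0.0, config.noise_sd_log2, config.n_genes)
                sid = f"{dataset_id}_{'NR' if response == 'non_responder' else 'R'}{p:02d}"
                columns.append(sid)
                records.append(
                    {
                        "sample_id": sid,
                        "cell_line": "",
                        "resistance_status": "n/a",
                        "drug": "none",
                        "treatment_time_h": np.nan,
                        "cohort": cohort,
                        "response": response,
                        "dataset_id": dataset_id,
                    }
                )
                values.append(baseline + delta + noise)
    return ExpressionMatrix(
        values=pd.DataFrame(
            np.exp2(np.column_stack(values)), index=t_table.index, columns=columns
        ),
        samples=make_sample_table(records),
        scale=LINEAR,
    )


def generate_clinical_cohorts(
    config: GeneratorConfig,
    truth: GroundTruth,
    regimen_drugs: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Pre- and post-chemotherapy responder/non-responder cohorts.

    Non-responders carry the attenuated, patient-scaled resistance-gene
    effects of ``regimen_drugs`` (default: all configured drugs) in the
    directions planted for the resistant cell line; post-chemotherapy
    samples additionally carry the treated-state (drug-response) effects
    in every patient.  Datasets get independent per-gene batch shifts.
    """
    drugs = tuple(regimen_drugs) if regimen_drugs is not None else config.drugs
    unknown = set(drugs) - set(config.drugs)
    if unknown:
        raise ValueError(f"unknown regimen drugs {sorted(unknown)}")
    key = sum(_drug_key(d) % 100003 for d in drugs)
    pre = _clinical_matrix(
        config, truth, drugs, config.clinical_datasets, "pre_chemo",
        _rng(config, 11, key), treated_state=False,
    )
    post = _clinical_matrix(
        config, truth, drugs, config.post_datasets, "post_chemo",
        _rng(config, 13, key), treated_state=True,
    )
    return pre, post
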