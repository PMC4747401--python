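"""End-to-end orchestration of the resistance-gene analysis graph.

On a synthetic experiment (or user-supplied matrices) the pipeline derives,
per drug and ranking method, the BD/IP/ID lists at every treatment time,
the two-drug BD_two/ID_two overlaps, the clinical CRG and ID_clinical
sets, all pairwise consistency tables, the FC-vs-AD expression-bias
report, an FC/AD trajectory table for candidate resistance genes, optional
pathway enrichment, and a reproducibility manifest.  Steps whose required
sample groups are missing are skipped with a logged reason; no step
mutates upstream artifacts, and two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .consistency import consistency_matrix, overlap_consistency
from .crg import CRGSet, id_clinical, tiered_crg
from .enrichment import GeneSetCollection, hypergeom_enrich
from .matrix import LINEAR, ExpressionMatrix
from .preprocess import delog, log2_quantile_normalize
from .ranking import (
    DirectionalGeneSet,
    compute_ad,
    compute_fc,
    define_gene_class,
    expression_bias_report,
    two_drug_intersection,
)
from .rankproduct import rank_product
from .simulate import GeneratorConfig, generate_cellline_experiment, generate_clinical_cohorts, make_truth

logger = logging.getLogger("crgpipe")


@dataclass
class AnalysisConfig:
    """Parameters of a full pipeline run.

    Either ``generator`` (synthetic mode) or ``expression_tsv`` +
    ``metadata_tsv`` must be provided.  ``top_n`` applies to every BD/IP/ID
    list; 3000 matches a ~20k-gene array, the synthetic default of 300 a
    5000-gene matrix (see the methods note).
    """

    seed: int
    out_dir: str = "crgpipe_out"
    generator: Optional[GeneratorConfig] = None
    expression_tsv: Optional[str] = None
    metadata_tsv: Optional[str] = None
    input_scale: str = LINEAR
    top_n: int = 300
    methods: tuple[str, ...] = ("fc", "ad")
    eval_times: tuple[float, ...] = (6.0, 12.0, 24.0)
    n_permutations: int = 300
    fdr_discovery: float = 0.2
    p_confirm: float = 0.05
    fdr_id_clinical: float = 0.1
    gmt_path: Optional[str] = None
    fdr_enrich: float = 0.1

    def __post_init__(self) -> None:
        if self.generator is None and (
            self.expression_tsv is None or self.metadata_tsv is None
        ):
            raise ValueError("provide a generator config or expression+metadata paths")


@dataclass
class PipelineReport:
    """Artifacts of one run: output paths plus in-memory key objects."""

    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    gene_sets: dict[str, DirectionalGeneSet] = field(default_factory=dict)
    crg: Optional[CRGSet] = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def _write_tsv(report: PipelineReport, name: str, frame: pd.DataFrame, params: str, index=False) -> None:
    path = report.out_dir / f"{name}.tsv"
    with open(path, "w") as fh:
        fh.write(f"# crgpipe {name}; {params}\n")
        frame.to_csv(fh, sep="\t", index=index)
    report.outputs[name] = path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Run the whole analysis graph and write TSV outputs plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out_dir)
    params = f"seed={config.seed} top_n={config.top_n}"

    # ------------------------------------------------------------------ inputs
    if config.generator is not None:
        gcfg = config.generator
        truth = make_truth(gcfg)
        cell_matrices = {}
        for drug in gcfg.drugs:
            m, _ = generate_cellline_experiment(gcfg, drug, truth)
            cell_matrices[drug] = m
            logger.info("simulated cell-line experiment for %s: %d x %d", drug, m.n_genes, m.n_samples)
        pre, post = generate_clinical_cohorts(gcfg, truth)
        truth.to_tsv(out_dir / "ground_truth.tsv")
        report.outputs["ground_truth"] = out_dir / "ground_truth.tsv"
        drugs = gcfg.drugs
    else:
        matrix = ExpressionMatrix.from_tsv(
            config.expression_tsv, config.metadata_tsv, config.input_scale
        )
        cell = matrix.sample_ids(cohort="cell_line")
        cell_matrix = matrix.subset_samples(cell) if cell else None
        drugs = tuple(
            sorted(set(matrix.samples["drug"]) - {"none"})
        )
        cell_matrices = {d: cell_matrix for d in drugs} if cell_matrix is not None else {}
        pre_ids = matrix.sample_ids(cohort="pre_chemo")
        post_ids = matrix.sample_ids(cohort="post_chemo")
        pre = matrix.subset_samples(pre_ids) if pre_ids else None
        post = matrix.subset_samples(post_ids) if post_ids else None

    # ------------------------------------------------- cell-line gene lists
    sets: dict[str, DirectionalGeneSet] = {}
    for drug, matrix in cell_matrices.items():
        for method in config.methods:
            for design, times in (("BD", [None]), ("IP", config.eval_times), ("ID", config.eval_times)):
                for t in times:
                    name = design if t is None else f"{design}_{t:g}"
                    key = f"{name}/{method.upper()}/{drug}"
                    try:
                        sets[key] = define_gene_class(
                            matrix, design, drug, t, method, config.top_n
                        )
                        logger.info("%s: %d genes", key, len(sets[key]))
                    except ValueError as exc:
                        report.skipped[key] = str(exc)
                        logger.warning("skipped %s: %s", key, exc)
    report.gene_sets.update(sets)

    # two-drug overlaps
    if len(drugs) >= 2:
        d1, d2 = drugs[:2]
        for method in config.methods:
            mm = method.upper()
            pairs = [("BD_two", f"BD/{mm}/{d1}", f"BD/{mm}/{d2}")]
            pairs += [
                (f"ID_two_{t:g}", f"ID_{t:g}/{mm}/{d1}", f"ID_{t:g}/{mm}/{d2}")
                for t in config.eval_times
            ]
            for name, k1, k2 in pairs:
                if k1 in sets and k2 in sets:
                    key = f"{name}/{mm}"
                    report.gene_sets[key] = two_drug_intersection(
                        sets[k1], sets[k2], label=key
                    )
                    logger.info("%s: %d genes", key, len(report.gene_sets[key]))

    for key, gset in report.gene_sets.items():
        _write_tsv(
            report,
            "geneset_" + key.replace("/", "_"),
            gset.to_frame(),
            params,
        )

    # --------------------------------------------------------- clinical CRGs
    crg_set = None
    id_clin = None
    if pre is not None and pre.n_samples:
        pre_log = log2_quantile_normalize(pre) if pre.scale == LINEAR else pre
        dataset_ids = list(dict.fromkeys(pre_log.samples["dataset_id"]))
        disc_datasets = dataset_ids[:-1] if len(dataset_ids) > 1 else dataset_ids
        conf_datasets = dataset_ids[len(disc_datasets):]

        def _classes(m, datasets):
            sub = m.subset_samples(m.sample_ids(dataset_id=set(datasets)))
            return (
                sub,
                sub.sample_ids(response="non_responder"),
                sub.sample_ids(response="responder"),
            )

        sub, nr, r = _classes(pre_log, disc_datasets)
        discovery = rank_product(
            sub, nr, r, n_permutations=config.n_permutations, seed=config.seed
        )
        _write_tsv(report, "rankprod_discovery", discovery, params, index=True)
        confirmations = []
        for i, ds in enumerate(conf_datasets, start=1):
            sub, nr, r = _classes(pre_log, [ds])
            conf = rank_product(
                sub, nr, r, n_permutations=config.n_permutations, seed=config.seed + i
            )
            confirmations.append(conf)
            _write_tsv(report, f"rankprod_confirm{i}", conf, params, index=True)
        crg_set = tiered_crg(
            discovery,
            confirmations,
            fdr_discovery=config.fdr_discovery,
            p_confirm=config.p_confirm,
            drugs=frozenset(drugs),
            label="CRG_" + "/".join(drugs),
        )
        logger.info("CRG: %d genes (%d direction conflicts)", len(crg_set), len(crg_set.conflicts))
        _write_tsv(report, "crg", crg_set.members.to_frame(), params)
        report.crg = crg_set
    else:
        report.skipped["crg"] = "no pre-chemotherapy samples"

    if post is not None and post.n_samples:
        post_log = log2_quantile_normalize(post) if post.scale == LINEAR else post
        nr = post_log.sample_ids(response="non_responder")
        r = post_log.sample_ids(response="responder")
        post_table = rank_product(
            post_log, nr, r, n_permutations=config.n_permutations, seed=config.seed + 1000
        )
        _write_tsv(report, "rankprod_post", post_table, params, index=True)
        id_clin = id_clinical(post_table, fdr_max=config.fdr_id_clinical)
        report.gene_sets["ID_clinical"] = id_clin
        _write_tsv(report, "geneset_ID_clinical", id_clin.to_frame(), params)
        logger.info("ID_clinical: %d genes", len(id_clin))
    else:
        report.skipped["id_clinical"] = "no post-chemotherapy samples"

    # -------------------------------------------------- consistency tables
    bd_ip = []
    for drug in cell_matrices:
        for method in config.methods:
            mm = method.upper()
            bd_key = f"BD/{mm}/{drug}"
            for t in config.eval_times:
                ip_key = f"IP_{t:g}/{mm}/{drug}"
                if bd_key in sets and ip_key in sets:
                    res = overlap_consistency(sets[bd_key], sets[ip_key])
                    bd_ip.append(
                        {
                            "drug": drug, "method": mm, "ip": f"IP_{t:g}",
                            "k": res.k, "s": res.s,
                            "score_percent": res.score_percent,
                            "p_binomial": res.p_binomial,
                        }
                    )
    if bd_ip:
        _write_tsv(report, "consistency_bd_ip", pd.DataFrame(bd_ip), params)
        report.tables["consistency_bd_ip"] = pd.DataFrame(bd_ip)

    for ref_name, ref_set in (("crg", crg_set.members if crg_set else None), ("id_clinical", id_clin)):
        if ref_set is None or not len(ref_set):
            report.skipped[f"consistency_vs_{ref_name}"] = "reference set empty/missing"
            continue
        rows = []
        for key, gset in report.gene_sets.items():
            if key == "ID_clinical" and ref_name == "id_clinical":
                continue
            res = overlap_consistency(gset, ref_set)
            rows.append(
                {
                    "gene_set": key, "reference": ref_set.label, "k": res.k,
                    "s": res.s, "score_percent": res.score_percent,
                    "p_binomial": res.p_binomial,
                }
            )
        table = pd.DataFrame(rows)
        _write_tsv(report, f"consistency_vs_{ref_name}", table, params)
        report.tables[f"consistency_vs_{ref_name}"] = table

    # ------------------------------------------- bias report + trajectories
    for drug, matrix in cell_matrices.items():
        t_last = config.eval_times[-1]
        fc_key, ad_key = f"ID_{t_last:g}/FC/{drug}", f"ID_{t_last:g}/AD/{drug}"
        if fc_key not in sets or ad_key not in sets:
            continue
        group_a = matrix.sample_ids(
            resistance_status="resistant", drug=drug, treatment_time_h=t_last
        )
        group_b = matrix.sample_ids(
            resistance_status="parental", drug=drug, treatment_time_h=t_last
        )
        bias = expression_bias_report(
            sets[fc_key], sets[ad_key], matrix, group_a, group_b,
            group_a_label="treated_resistant", group_b_label="treated_parental",
        )
        _write_tsv(report, f"bias_ID_{t_last:g}_{drug}", bias.to_frame(), params)

        union = sorted(sets[fc_key].genes | sets[ad_key].genes)
        traj = trajectory_table(matrix, union, drug, config.eval_times)
        _write_tsv(report, f"trajectory_ID_{drug}", traj, params)
        report.tables[f"trajectory_ID_{drug}"] = traj

    # ------------------------------------------------------------ enrichment
    if config.gmt_path:
        universe = next(iter(cell_matrices.values())).feature_ids if cell_matrices else (
            pre.feature_ids if pre is not None else post.feature_ids
        )
        collection = GeneSetCollection.from_gmt(config.gmt_path)
        for drug in cell_matrices:
            t_last = config.eval_times[-1]
            for method in config.methods:
                key = f"ID_{t_last:g}/{method.upper()}/{drug}"
                if key in sets:
                    enr = hypergeom_enrich(sets[key], collection, universe)
                    _write_tsv(
                        report,
                        "enrich_" + key.replace("/", "_"),
                        enr,
                        params + f" fdr_max={config.fdr_enrich}",
                    )

    # -------------------------------------------------------------- manifest
    manifest = {
        "crgpipe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _config_dict(config),
        "skipped": report.skipped,
        "outputs": {
            name: {"path": str(path.name), "sha256": _sha256(path)}
            for name, path in sorted(report.outputs.items())
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report.outputs["manifest"] = manifest_path
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # keep the manifest location-independent
    return d


def trajectory_table(
    matrix: ExpressionMatrix,
    genes: list[str],
    drug: str,
    times: tuple[float, ...],
) -> pd.DataFrame:
    """Per-gene log2 FC and AD between treated-resistant and treated-parental
    arms at each treatment time (the generic form of a resistance-gene
    trajectory figure)."""
    if matrix.scale != LINEAR:
        matrix = delog(matrix)
    rows = []
    for t in times:
        group_a = matrix.sample_ids(
            resistance_status="resistant", drug=drug, treatment_time_h=t
        )
        group_b = matrix.sample_ids(
            resistance_status="parental", drug=drug, treatment_time_h=t
        )
        if not group_a or not group_b:
            continue
        sub = matrix.subset_genes(genes)
        mean_a = sub.values[group_a].mean(axis=1)
        mean_b = sub.values[group_b].mean(axis=1)
        frame = pd.DataFrame(
            {
                "gene_id": genes,
                "time_h": t,
                "log2_fc": np.log2(mean_a / mean_b).to_numpy(),
                "ad": (mean_a - mean_b).to_numpy(),
            }
        )
        rows.append(frame)
    if not rows:
        raise ValueError(f"no treated sample groups found for drug {drug!r}")
    return pd.concat(rows, ignore_index=True)
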