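"""Gene-by-sample expression containers, sample annotations and TSV I/O.

The central object is :class:`ExpressionMatrix`: a genes x samples value
table (pandas DataFrame) together with a per-sample annotation table and an
explicit scale flag (``"linear"`` or ``"log2"``).  Every downstream
operation declares which scale it expects; fold changes and average
differences are defined on the linear scale, rank-product differential
expression on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

#: Annotation columns carried for every sample.  ``resistance_status`` is one
#: of {"parental", "resistant", "n/a"}; ``cohort`` one of {"cell_line",
#: "pre_chemo", "post_chemo"}; ``response`` one of {"responder",
#: "non_responder", "n/a"}; ``drug`` is "none" for untreated samples and
#: ``treatment_time_h`` is NaN unless a drug was applied.
SAMPLE_COLUMNS = [
    "cell_line",
    "resistance_status",
    "drug",
    "treatment_time_h",
    "cohort",
    "response",
    "dataset_id",
]

_RESISTANCE_STATUS = {"parental", "resistant", "n/a"}
_COHORTS = {"cell_line", "pre_chemo", "post_chemo"}
_RESPONSES = {"responder", "non_responder", "n/a"}


def make_sample_table(records: Iterable[Mapping]) -> pd.DataFrame:
    """Build a sample-annotation table from dicts keyed by ``sample_id``.

    Missing annotation columns are filled with neutral values ("n/a",
    "none" for drug, NaN for treatment time, "d1" for dataset_id).
    """
    df = pd.DataFrame(list(records))
    if "sample_id" not in df.columns:
        raise ValueError("each record needs a 'sample_id'")
    df = df.set_index("sample_id")
    defaults = {
        "cell_line": "",
        "resistance_status": "n/a",
        "drug": "none",
        "treatment_time_h": np.nan,
        "cohort": "cell_line",
        "response": "n/a",
        "dataset_id": "d1",
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df[SAMPLE_COLUMNS]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample annotations.

    Parameters
    ----------
    values
        DataFrame, rows indexed by unique feature/gene ids, columns by
        sample ids.
    samples
        DataFrame indexed by sample id with the :data:`SAMPLE_COLUMNS`
        annotations, in the same order as ``values.columns``.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValueError(f"feature ids must be unique; duplicates include {dup}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values.columns must match samples.index (same order)")
        bad = self.samples[
            (self.samples["response"] != "n/a")
            & (~self.samples["cohort"].isin({"pre_chemo", "post_chemo"}))
        ]
        if len(bad):
            raise ValueError(
                "response labels are only valid for clinical cohorts; offending "
                f"samples: {bad.index[:3].tolist()}"
            )
        treated = self.samples["drug"] != "none"
        if self.samples.loc[~treated, "treatment_time_h"].notna().any():
            raise ValueError("treatment_time_h set on samples with drug == 'none'")
        if self.scale == LINEAR and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale matrix contains negative values")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_ids(self, **query) -> list[str]:
        """Sample ids whose annotations match every ``column=value`` pair.

        A value may also be a set/list, matched by membership, e.g.
        ``sample_ids(resistance_status="resistant", drug="5-FU",
        treatment_time_h=24)``.
        """
        mask = pd.Series(True, index=self.samples.index)
        for col, val in query.items():
            if col not in self.samples.columns:
                raise KeyError(f"unknown annotation column {col!r}")
            series = self.samples[col]
            if isinstance(val, (set, frozenset, list, tuple)):
                mask &= series.isin(val)
            elif col == "treatment_time_h" and val is not None and not pd.isna(val):
                mask &= series == float(val)
            else:
                mask &= series == val
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return replace(self, values=self.values[ids], samples=self.samples.loc[ids])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(gene_ids)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), self.scale)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls,
        values_path: str | Path,
        samples_path: str | Path,
        scale: str,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        for col in SAMPLE_COLUMNS:
            if col not in samples.columns:
                raise ValueError(f"sample metadata is missing column {col!r}")
        samples = samples[SAMPLE_COLUMNS].copy()
        samples["drug"] = samples["drug"].fillna("none")
        for col in ("resistance_status", "response"):
            samples[col] = samples[col].fillna("n/a")
        samples = samples.loc[values.columns]
        return cls(values=values, samples=samples, scale=scale)


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column (probe_id, gene_id) TSV into a probe -> gene Series.

    Each probe must map to exactly one gene; many probes per gene are fine.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_id")
    probe, gene = df.columns[:2]
    mapping = df.set_index(probe)[gene]
    if not mapping.index.is_unique:
        dup = mapping.index[mapping.index.duplicated()][:3].tolist()
        raise ValueError(f"probes mapped to more than one gene: {dup}")
    return mapping
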