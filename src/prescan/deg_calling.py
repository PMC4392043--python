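"""Paired lesional/uninvolved differential-expression calling.

Implements the QC Z-score sample filter, inverted-signature (label swap)
detection and the DEG test: a signed-rank test on per-patient paired
differences with Benjamini-Hochberg adjustment, overall fold-change gates
(> 1.50 up, < 0.67 down) and a per-dataset median fold-change consistency
requirement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from prescan.enrichment import bh_adjust

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
FC_UP = 1.50
FC_DOWN = 0.67
QC_Z_CUT = 3.5
MIN_COMPLETENESS = 0.80


@dataclass
class PairedExpressionSet:
    """genes x patients log2 intensities for paired PP / PN samples."""

    genes: list[str]
    patients: list[str]
    datasets: list[str]  # dataset id per patient
    pp: np.ndarray  # genes x patients
    pn: np.ndarray
    expressed: np.ndarray | None = None  # bool per gene; default all True

    def __post_init__(self):
        self.pp = np.asarray(self.pp, dtype=float)
        self.pn = np.asarray(self.pn, dtype=float)
        if self.pp.shape != self.pn.shape:
            raise ValueError("pp and pn must have identical shapes")
        if self.pp.shape != (len(self.genes), len(self.patients)):
            raise ValueError("matrix shape does not match gene/patient lists")
        if len(self.datasets) != len(self.patients):
            raise ValueError("each patient needs exactly one dataset id")
        if self.expressed is None:
            self.expressed = np.ones(len(self.genes), dtype=bool)
        else:
            self.expressed = np.asarray(self.expressed, dtype=bool)

    @property
    def diffs(self) -> np.ndarray:
        return self.pp - self.pn

    def subset_patients(self, keep: list[str]) -> "PairedExpressionSet":
        idx = [i for i, p in enumerate(self.patients) if p in set(keep)]
        return PairedExpressionSet(
            genes=list(self.genes),
            patients=[self.patients[i] for i in idx],
            datasets=[self.datasets[i] for i in idx],
            pp=self.pp[:, idx],
            pn=self.pn[:, idx],
            expressed=self.expressed.copy(),
        )


def qc_outlier_filter(
    metrics: pd.DataFrame, z_cut: float = QC_Z_CUT
) -> tuple[list[str], list[str]]:
    """Return (kept sample ids, removed sample ids).

    ``metrics`` is indexed by sample id with a ``dataset`` column plus numeric
    metric columns.  Z-scores are computed within each dataset per metric; a
    sample is removed when any |Z| exceeds ``z_cut``.  Datasets with fewer
    than 3 samples are kept unfiltered (with a warning).
    """
    if "dataset" not in metrics.columns:
        raise ValueError("metrics table requires a 'dataset' column")
    value_cols = [c for c in metrics.columns if c != "dataset"]
    removed: set[str] = set()
    for dataset, block in metrics.groupby("dataset"):
        if len(block) < 3:
            logger.warning(
                "dataset %s has %d samples; QC Z-scores not computed", dataset, len(block)
            )
            continue
        for col in value_cols:
            values = block[col].astype(float)
            ok = values.notna()
            if ok.sum() < 3:
                continue
            v = values[ok]
            sd = v.std(ddof=1)
            if sd == 0:
                continue
            z = (v - v.mean()) / sd
            removed.update(z.index[np.abs(z) > z_cut])
    kept = [s for s in metrics.index if s not in removed]
    return kept, sorted(removed)


def detect_label_swaps(
    expr: PairedExpressionSet,
    signature_up: list[str],
    signature_down: list[str],
) -> list[str]:
    """Patients whose paired differences invert both signatures: median
    PP-PN over up-signature genes < 0 AND over down-signature genes > 0."""
    if not signature_up or not signature_down:
        raise ValueError("signatures must be non-empty")
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    up = [gene_idx[g] for g in signature_up if g in gene_idx]
    down = [gene_idx[g] for g in signature_down if g in gene_idx]
    if not up or not down:
        raise ValueError("signature genes not present in the expression set")
    diffs = expr.diffs
    flagged = []
    for j, patient in enumerate(expr.patients):
        if np.median(diffs[up, j]) < 0 and np.median(diffs[down, j]) > 0:
            flagged.append(patient)
    return flagged


@dataclass
class DEGTable:
    table: pd.DataFrame  # gene, median_fc, p, fdr, class, per-dataset medians
    per_dataset_columns: list[str] = field(default_factory=list)

    def genes_in_class(self, cls: str) -> list[str]:
        return self.table.loc[self.table["class"] == cls, "gene"].tolist()


def _gene_test(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p for median difference != 0."""
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            return 1.0
        # constant nonzero differences: signed-rank still applies
    if np.all(diffs == 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(wilcoxon(diffs, alternative="two-sided").pvalue)
        except ValueError:
            return 1.0


def call_degs(
    expr: PairedExpressionSet,
    fdr_threshold: float = FDR_THRESHOLD,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    min_completeness: float = MIN_COMPLETENESS,
) -> DEGTable:
    """Test each expressed gene's paired differences against zero and gate by
    FDR, overall median fold-change and per-dataset consistency."""
    if len(expr.patients) < 2:
        raise ValueError("need at least 2 patients")
    diffs = expr.diffs
    dataset_ids = sorted(set(expr.datasets))
    dataset_cols = {d: np.array([ds == d for ds in expr.datasets]) for d in dataset_ids}

    rows = []
    pvalues = []
    tested_idx = []
    for i, gene in enumerate(expr.genes):
        if not expr.expressed[i]:
            continue
        d = diffs[i]
        ok = ~np.isnan(d)
        if ok.mean() < min_completeness:
            continue
        d = d[ok]
        p = _gene_test(d)
        median_fc = float(2 ** np.median(d))
        per_ds = {}
        for ds, mask in dataset_cols.items():
            vals = diffs[i][mask]
            vals = vals[~np.isnan(vals)]
            per_ds[f"median_fc_{ds}"] = float(2 ** np.median(vals)) if len(vals) else np.nan
        rows.append({"gene": gene, "median_fc": median_fc, "p": p, **per_ds})
        pvalues.append(p)
        tested_idx.append(i)

    if not rows:
        raise ValueError("no genes passed the completeness filter")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(np.array(pvalues))

    ds_cols = [f"median_fc_{d}" for d in dataset_ids]
    per_ds_matrix = table[ds_cols].to_numpy()
    all_up = np.nanmin(per_ds_matrix, axis=1) > 1.0
    all_down = np.nanmax(per_ds_matrix, axis=1) < 1.0

    cls = np.full(len(table), "not_de", dtype=object)
    sig = table["fdr"].to_numpy() < fdr_threshold
    cls[sig & (table["median_fc"].to_numpy() > fc_up) & all_up] = "pp_increased"
    cls[sig & (table["median_fc"].to_numpy() < fc_down) & all_down] = "pp_decreased"
    table["class"] = cls
    return DEGTable(table, per_dataset_columns=ds_cols)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def load_expression(expr_path: str, meta_path: str) -> PairedExpressionSet:
    """Expression TSV is genes x samples; the metadata sidecar has columns
    sample_id, patient_id, dataset_id, tissue (PP or PN)."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "patient_id", "dataset_id", "tissue"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata requires columns {sorted(required)}")
    pp_meta = meta[meta["tissue"] == "PP"].set_index("patient_id")
    pn_meta = meta[meta["tissue"] == "PN"].set_index("patient_id")
    patients = [p for p in pp_meta.index if p in pn_meta.index]
    datasets = [str(pp_meta.loc[p, "dataset_id"]) for p in patients]
    pp = matrix[[pp_meta.loc[p, "sample_id"] for p in patients]].to_numpy()
    pn = matrix[[pn_meta.loc[p, "sample_id"] for p in patients]].to_numpy()
    return PairedExpressionSet(
        genes=list(matrix.index),
        patients=list(patients),
        datasets=datasets,
        pp=pp,
        pn=pn,
    )


def save_deg_table(deg: DEGTable, path: str):
    deg.table.to_csv(path, sep="\t", index=False)
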