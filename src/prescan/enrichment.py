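"""Motif enrichment in DEG upstream regions via semiparametric logistic
regression, and cross-linking of enriched motifs with TF/uDBP-encoding DEGs.

Per motif, a logistic model predicts DEG membership from the log10 match
count (linear term, whose Wald Z is the enrichment statistic) and the log10
non-masked scanned length (penalized B-spline smooth).  A motif is called
enriched when the BH-adjusted p-value is below 0.10 with Z > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

PRE_FDR_THRESHOLD = 0.10
GENE_SETS = ("pp_increased", "pp_decreased", "combined")


@dataclass
class EnrichmentResult:
    motif_id: str
    gene_set: str
    z: float
    p: float
    fdr: float = np.nan

    @property
    def is_pre(self) -> bool:
        return bool(self.fdr < PRE_FDR_THRESHOLD and self.z > 0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fit_enrichment_model(
    counts: np.ndarray,
    lengths: np.ndarray,
    labels: np.ndarray,
    spline_df: int = 5,
) -> tuple[float, float]:
    """Wald Z and two-sided p for the log10(count+1) coefficient of a
    logistic model of DEG membership, adjusting for log10 length with a
    penalized spline (penalty weight by generalized cross-validation).

    Falls back to a plain linear adjustment when the length covariate has
    too few distinct values to support a spline basis.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if not (len(counts) == len(lengths) == len(labels)):
        raise ValueError("covariates and labels must have equal length")
    if len(counts) < 50:
        raise ValueError("need at least 50 genes")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")

    x1 = np.log10(counts + 1.0)
    x2 = np.log10(lengths)
    if np.ptp(x1) == 0:
        return 0.0, 1.0  # no information in a constant covariate

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(np.unique(x2)) <= spline_df:
            exog = sm.add_constant(
                np.column_stack([x1] + ([x2] if np.ptp(x2) > 0 else []))
            )
            result = sm.GLM(labels, exog, family=sm.families.Binomial()).fit()
            z = float(result.tvalues[1])
            p = float(result.pvalues[1])
        else:
            basis = BSplines(x2[:, None], df=[spline_df], degree=[3])
            exog = sm.add_constant(x1)
            model = GLMGam(
                labels, exog=exog, smoother=basis, family=sm.families.Binomial()
            )
            try:
                alpha = model.select_penweight(criterion="gcv")[0]
            except Exception:  # pragma: no cover - optimizer hiccups
                alpha = np.array([1.0])
            result = GLMGam(
                labels,
                exog=exog,
                smoother=basis,
                alpha=alpha,
                family=sm.families.Binomial(),
            ).fit()
            z = float(result.tvalues[1])
            p = float(result.pvalues[1])
    if not np.isfinite(z):
        logger.warning("non-finite Z (possible separation); clamping")
        z = np.sign(result.params[1]) * 1e3 if np.isfinite(result.params[1]) else 0.0
        p = 0.0 if z != 0 else 1.0
    return z, p


def enrich_motifs(
    counts: pd.DataFrame,
    lengths: pd.Series,
    deg_classes: pd.Series,
    gene_sets: tuple[str, ...] = GENE_SETS,
) -> pd.DataFrame:
    """Fit the enrichment model for every motif against each DEG gene set.

    ``counts``: genes x motifs match counts; ``lengths``: per-gene non-masked
    bp; ``deg_classes``: per-gene class in {pp_increased, pp_decreased,
    not_de}.  Returns a tidy frame (motif_id, gene_set, z, p, fdr, is_pre).
    """
    genes = counts.index
    lengths = lengths.loc[genes]
    deg_classes = deg_classes.loc[genes]
    rows = []
    for gene_set in gene_sets:
        if gene_set == "combined":
            labels = deg_classes.isin(["pp_increased", "pp_decreased"]).to_numpy()
        else:
            labels = (deg_classes == gene_set).to_numpy()
        labels = labels.astype(float)
        if labels.sum() == 0 or labels.sum() == len(labels):
            logger.warning("gene set %s has a single class; skipped", gene_set)
            continue
        pvals = []
        zvals = []
        for motif in counts.columns:
            z, p = fit_enrichment_model(
                counts[motif].to_numpy(), lengths.to_numpy(), labels
            )
            zvals.append(z)
            pvals.append(p)
        fdr = bh_adjust(np.array(pvals))
        for motif, z, p, q in zip(counts.columns, zvals, pvals, fdr):
            rows.append(
                {
                    "motif_id": motif,
                    "gene_set": gene_set,
                    "z": z,
                    "p": p,
                    "fdr": q,
                    "is_pre": bool(q < PRE_FDR_THRESHOLD and z > 0),
                }
            )
    return pd.DataFrame(rows)


def select_pre_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """Per gene set, the motifs with fdr < 0.10 and z > 0."""
    sets: dict[str, set[str]] = {}
    for gene_set, block in results.groupby("gene_set"):
        chosen = block[(block["fdr"] < PRE_FDR_THRESHOLD) & (block["z"] > 0)]
        sets[gene_set] = set(chosen["motif_id"])
    for gene_set in GENE_SETS:
        sets.setdefault(gene_set, set())
    return sets


def crosslink_degs(
    deg_genes: set[str],
    motif_genes: dict[str, list[str]],
    pre_sets: dict[str, set[str]],
    universe: set[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Label each TF/uDBP-encoding gene by the PRE status of its motifs and
    test whether DEG-encoded factors interact with PREs more often.

    ``motif_genes`` maps motif_id -> associated gene symbols.  Genes with no
    motif in the dictionary are excluded from the Fisher denominator.
    Returns (per-gene table, one-sided Fisher p).
    """
    gene_to_motifs: dict[str, set[str]] = {}
    for motif, genes in motif_genes.items():
        for gene in genes:
            gene_to_motifs.setdefault(gene, set()).add(motif)
    if not gene_to_motifs:
        raise ValueError("no gene annotations on the dictionary")

    candidates = set(gene_to_motifs)
    if universe is not None:
        candidates &= universe

    up = pre_sets.get("pp_increased", set())
    down = pre_sets.get("pp_decreased", set())
    rows = []
    for gene in sorted(candidates):
        motifs = gene_to_motifs[gene]
        in_up = bool(motifs & up)
        in_down = bool(motifs & down)
        if in_up and in_down:
            cls = "both"
        elif in_up:
            cls = "pp_increased_only"
        elif in_down:
            cls = "pp_decreased_only"
        else:
            cls = "none"
        rows.append(
            {
                "gene": gene,
                "is_deg": gene in deg_genes,
                "pre_class": cls,
                "interacts_pre": cls != "none",
            }
        )
    table = pd.DataFrame(rows)
    a = int(((table["is_deg"]) & (table["interacts_pre"])).sum())
    b = int(((table["is_deg"]) & (~table["interacts_pre"])).sum())
    c = int(((~table["is_deg"]) & (table["interacts_pre"])).sum())
    d = int(((~table["is_deg"]) & (~table["interacts_pre"])).sum())
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return table, float(p)
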