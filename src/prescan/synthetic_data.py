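"""Seeded generators for every input the pipeline consumes, with ground
truth: motif sets with planted families, promoter sequences with planted
motif instances at DEG-dependent rates, paired expression matrices with
planted fold-changes/outliers/label swaps, and SNP panels engineered to
disrupt or engender motif matches.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prescan._seq import BASES, reverse_complement
from prescan.motif_dictionary import MotifRecord, PPM, column_ic
from prescan.promoter_scan import PromoterRegion
from prescan.snp_effects import SNPRecord


@dataclass
class SyntheticTruth:
    motif_families: dict[str, str] = field(default_factory=dict)
    enriched_motif_ids: list[str] = field(default_factory=list)
    deg_up: list[str] = field(default_factory=list)
    deg_down: list[str] = field(default_factory=list)
    planted_instances: dict[str, list[tuple[str, int, str]]] = field(
        default_factory=dict
    )
    snp_intent: dict[str, tuple[str, str]] = field(default_factory=dict)
    outlier_samples: list[str] = field(default_factory=list)
    swapped_patients: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif_families": self.motif_families,
                "enriched_motif_ids": self.enriched_motif_ids,
                "deg_up": self.deg_up,
                "deg_down": self.deg_down,
                "planted_instances": self.planted_instances,
                "snp_intent": self.snp_intent,
                "outlier_samples": self.outlier_samples,
                "swapped_patients": self.swapped_patients,
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def _ic_column(dominant: int, target_ic: float) -> np.ndarray:
    """Column with one dominant base whose IC equals target_ic (bisection)."""
    lo, hi = 0.2500001, 1.0 - 1e-12

    def ic_of(p: float) -> float:
        rest = (1 - p) / 3
        col = np.full(4, rest)
        col[dominant] = p
        return column_ic(col)

    for _ in range(60):
        mid = (lo + hi) / 2
        if ic_of(mid) < target_ic:
            lo = mid
        else:
            hi = mid
    p = (lo + hi) / 2
    col = np.full(4, (1 - p) / 3)
    col[dominant] = p
    return col


def generate_motifs(
    n: int,
    n_families: int = 2,
    width_range: tuple[int, int] = (6, 14),
    ic_per_column_range: tuple[float, float] = (0.8, 1.6),
    seed: int = 0,
    family_cores: list[str] | None = None,
    dirichlet_concentration: float = 300.0,
) -> tuple[list[MotifRecord], SyntheticTruth]:
    """Motif set with ``n_families`` planted families sharing perturbed core
    consensus sequences; per-column IC lands in the requested band +/- 0.2.
    """
    if n < n_families:
        raise ValueError("need n >= n_families")
    lo_ic, hi_ic = ic_per_column_range
    if not 0 < lo_ic <= hi_ic < 2.0:
        raise ValueError("infeasible IC band")
    rng = np.random.default_rng(seed)
    if family_cores is None:
        family_cores = [
            "".join(rng.choice(list(BASES), size=rng.integers(4, 6)))
            for _ in range(n_families)
        ]
    if len(family_cores) != n_families:
        raise ValueError("family_cores length must equal n_families")

    records = []
    truth = SyntheticTruth()
    for i in range(n):
        family = i % n_families
        core = family_cores[family]
        width = int(rng.integers(max(width_range[0], len(core)), width_range[1] + 1))
        offset = int(rng.integers(0, width - len(core) + 1))
        consensus = [BASES[rng.integers(4)] for _ in range(width)]
        for j, base in enumerate(core):
            consensus[offset + j] = base
        cols = []
        for base in consensus:
            target = float(rng.uniform(lo_ic, hi_ic))
            col = _ic_column(BASES.index(base), target)
            jittered = rng.dirichlet(col * dirichlet_concentration)
            if abs(column_ic(jittered / jittered.sum()) - target) <= 0.2:
                col = jittered / jittered.sum()
            cols.append(col)
        motif_id = f"syn{i:04d}"
        records.append(
            MotifRecord(
                motif_id=motif_id,
                ppm=PPM(motif_id, np.array(cols).T, pseudocount_applied=0.80),
                source="synthetic",
                genes=[f"TF_{motif_id.upper()}"],
                dbd_superfamily=f"superfamily_{family}",
                dbd_class=f"class_{family}",
            )
        )
        truth.motif_families[motif_id] = f"family_{family}"
    return records, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def consensus_sequence(record: MotifRecord) -> str:
    return "".join(BASES[i] for i in record.ppm.probs.argmax(axis=0))


def generate_promoters(
    n_genes: int,
    motifs: list[MotifRecord],
    deg_fraction: float = 0.2,
    rate_deg: float = 2.0,
    rate_bg: float = 1.0,
    upstream: int = 5000,
    downstream: int = 500,
    gc: float = 0.5,
    mask_fraction: float = 0.0,
    enriched_motif_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, list[PromoterRegion], SyntheticTruth]:
    """Per-gene contigs with planted motif consensus instances.

    DEG genes receive Poisson(rate_deg) instances of each enriched motif and
    Poisson(rate_bg) of the rest; background genes receive Poisson(rate_bg)
    of every motif.  Returns (genome dict, TSS table, regions, truth).
    """
    if rate_deg < 0 or rate_bg < 0:
        raise ValueError("rates must be non-negative")
    length = upstream + downstream
    rng = np.random.default_rng(seed)
    if enriched_motif_ids is None:
        enriched_motif_ids = [m.motif_id for m in motifs]
    enriched = set(enriched_motif_ids)

    mean_width = np.mean([m.width for m in motifs]) if motifs else 0
    expected = (rate_deg + rate_bg) * len(motifs) * mean_width
    if expected > 0.5 * length:
        raise ValueError("planting density too high to avoid overlaps")

    n_deg = int(round(deg_fraction * n_genes))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    deg_genes = set(genes[:n_deg])

    genome: dict[str, str] = {}
    regions: list[PromoterRegion] = []
    tss_rows = []
    truth = SyntheticTruth()
    truth.enriched_motif_ids = sorted(enriched)
    truth.deg_up = sorted(deg_genes)

    for gene in genes:
        seq = _random_sequence(rng, length, gc)
        occupied = np.zeros(length, dtype=bool)
        placements: list[tuple[str, int, str]] = []
        for motif in motifs:
            lam = rate_deg if (gene in deg_genes and motif.motif_id in enriched) else rate_bg
            count = int(rng.poisson(lam))
            cons = consensus_sequence(motif)
            w = len(cons)
            for _ in range(count):
                placed = False
                for _attempt in range(200):
                    pos = int(rng.integers(0, length - w + 1))
                    if occupied[pos : pos + w].any():
                        continue
                    strand = "+" if rng.random() < 0.5 else "-"
                    inst = cons if strand == "+" else reverse_complement(cons)
                    seq[pos : pos + w] = [BASES.index(b) for b in inst]
                    occupied[pos : pos + w] = True
                    placements.append((motif.motif_id, pos, strand))
                    placed = True
                    break
                if not placed:
                    raise ValueError("planting density too high to avoid overlaps")
        mask_intervals = []
        if mask_fraction > 0:
            mask_len = int(mask_fraction * length)
            for _attempt in range(200):
                start = int(rng.integers(0, length - mask_len + 1))
                if not occupied[start : start + mask_len].any():
                    mask_intervals.append((start, start + mask_len))
                    break
        sequence = "".join(BASES[i] for i in seq)
        contig = f"chr_{gene}"
        genome[contig] = sequence
        tss = upstream + 1  # 1-based; the full window covers the contig
        tss_rows.append({"gene_id": gene, "chrom": contig, "tss": tss, "strand": "+"})
        regions.append(
            PromoterRegion(
                gene_id=gene,
                chrom=contig,
                tss=tss,
                strand="+",
                sequence=sequence,
                mask_intervals=mask_intervals,
            )
        )
        truth.planted_instances[gene] = placements
    return genome, pd.DataFrame(tss_rows), regions, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

OUTLIER_METRIC_VALUE = 15.0
QC_METRICS = ("avg_background", "scale_factor", "degradation")


def generate_expression(
    n_patients: int,
    n_datasets: int,
    n_genes: int,
    n_deg_up: int = 0,
    n_deg_down: int = 0,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    sd: float = 0.5,
    n_outliers: int = 0,
    n_swaps: int = 0,
    baseline_mean: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Paired PP/PN expression with planted DEGs, QC outliers and label swaps.

    Returns (expression genes x samples, metadata, QC metrics, truth).
    PN ~ Normal(gene baseline, sd); PP = PN + log2(FC) + Normal(0, sd).
    """
    if n_patients % n_datasets != 0:
        raise ValueError("n_patients must divide evenly across datasets")
    if n_deg_up + n_deg_down > n_genes:
        raise ValueError("more DEGs than genes")
    per_dataset = n_patients // n_datasets
    if n_outliers > 0 and 2 * per_dataset < 16:
        raise ValueError(
            "planted outliers need >= 8 patients per dataset to be detectable"
        )
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    log2fc = np.zeros(n_genes)
    log2fc[:n_deg_up] = np.log2(fc_up)
    log2fc[n_deg_up : n_deg_up + n_deg_down] = np.log2(fc_down)
    baseline = rng.normal(baseline_mean, 1.0, size=n_genes)

    patients = [f"p{i:04d}" for i in range(n_patients)]
    datasets = [f"ds{i // per_dataset}" for i in range(n_patients)]

    pn = baseline[:, None] + rng.normal(0, sd, size=(n_genes, n_patients))
    pp = pn + log2fc[:, None] + rng.normal(0, sd, size=(n_genes, n_patients))

    truth = SyntheticTruth()
    truth.deg_up = genes[:n_deg_up]
    truth.deg_down = genes[n_deg_up : n_deg_up + n_deg_down]

    swap_idx = rng.choice(n_patients, size=n_swaps, replace=False) if n_swaps else []
    for j in swap_idx:
        pp[:, j], pn[:, j] = pn[:, j].copy(), pp[:, j].copy()
        truth.swapped_patients.append(patients[j])
    truth.swapped_patients.sort()

    sample_ids = []
    meta_rows = []
    columns = {}
    for j, patient in enumerate(patients):
        for tissue, matrix in (("PP", pp), ("PN", pn)):
            sid = f"{patient}_{tissue}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "dataset_id": datasets[j],
                    "tissue": tissue,
                }
            )
        columns[f"{patient}_PP"] = pp[:, j]
        columns[f"{patient}_PN"] = pn[:, j]
    expression = pd.DataFrame(columns, index=genes)
    expression.index.name = "gene"
    meta = pd.DataFrame(meta_rows)

    # QC metrics: clipped background noise so only planted outliers can
    # exceed the |Z| > 3.5 filter
    qc = pd.DataFrame(
        np.clip(rng.normal(0, 1, size=(len(sample_ids), len(QC_METRICS))), -2, 2),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=list(QC_METRICS),
    )
    qc.insert(0, "dataset", [meta_rows[i]["dataset_id"] for i in range(len(sample_ids))])
    if n_outliers:
        # two outliers sharing a (dataset, metric) slot would mask each other
        # in the within-dataset Z-score, so slots are kept unique
        slots = [(d, m) for d in sorted(set(datasets)) for m in QC_METRICS]
        if n_outliers > len(slots):
            raise ValueError(
                f"at most {len(slots)} outliers supported "
                "(one per dataset x metric slot)"
            )
        swap_patients = set(truth.swapped_patients)
        chosen_slots = [slots[i] for i in rng.choice(len(slots), n_outliers, replace=False)]
        used = set()
        for dataset, metric in chosen_slots:
            eligible = [
                s
                for s in sample_ids
                if qc.loc[s, "dataset"] == dataset
                and s.rsplit("_", 1)[0] not in swap_patients
                and s not in used
            ]
            sid = eligible[int(rng.integers(len(eligible)))]
            used.add(sid)
            qc.loc[sid, metric] = OUTLIER_METRIC_VALUE
            truth.outlier_samples.append(sid)
        truth.outlier_samples.sort()
    return expression, meta, qc, truth


# ---------------------------------------------------------------------------
# SNP panels
# ---------------------------------------------------------------------------

def _weakest_base(ppm: PPM, col: int) -> str:
    return BASES[int(np.argmin(ppm.probs[:, col]))]


def generate_snp_panel(
    n_snps: int,
    motifs: list[MotifRecord],
    fractions: tuple[float, float, float] = (0.4, 0.2, 0.4),
    enhancer_fraction: float = 0.5,
    conserved_fraction: float = 0.5,
    gc: float = 0.5,
    id_prefix: str = "rs",
    seed: int = 0,
) -> tuple[list[SNPRecord], SyntheticTruth]:
    """SNPs engineered to disrupt / engender / leave unchanged motif matches.

    fractions = (disrupt, engender, neutral) and must sum to 1.  Disrupt SNPs
    sit inside a planted consensus instance with the risk allele replacing a
    high-information base; engender SNPs sit at near-miss sites the risk
    allele completes; neutral SNPs lie in plain background sequence.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not motifs:
        raise ValueError("need at least one motif")
    rng = np.random.default_rng(seed)
    n_disrupt = int(round(fractions[0] * n_snps))
    n_engender = int(round(fractions[1] * n_snps))
    intents = (
        ["disrupt"] * n_disrupt
        + ["engender"] * n_engender
        + ["neutral"] * (n_snps - n_disrupt - n_engender)
    )
    max_width = max(m.width for m in motifs)
    radius = max_width + 4

    records = []
    truth = SyntheticTruth()
    for i, intent in enumerate(intents):
        snp_id = f"{id_prefix}{i:05d}"
        flank_codes = _random_sequence(rng, 2 * radius + 1, gc)
        motif = motifs[int(rng.integers(len(motifs)))]
        cons = consensus_sequence(motif)
        w = len(cons)
        ics = [column_ic(motif.ppm.probs[:, j]) for j in range(w)]
        col = int(np.argmax(ics))
        start = radius - col  # planted instance puts column `col` at center
        if intent in ("disrupt", "engender"):
            inst = list(cons)
            weak = _weakest_base(motif.ppm, col)
            if intent == "disrupt":
                present, risk, nonrisk = cons[col], weak, cons[col]
            else:
                inst[col] = weak
                present, risk, nonrisk = weak, cons[col], weak
            for j, base in enumerate(inst):
                flank_codes[start + j] = BASES.index(base)
            flank_codes[radius] = BASES.index(present)
            truth.snp_intent[snp_id] = (motif.motif_id, intent)
        else:
            present = BASES[flank_codes[radius]]
            others = [b for b in BASES if b != present]
            risk = others[int(rng.integers(3))]
            nonrisk = present
            truth.snp_intent[snp_id] = ("", "neutral")
        flank = "".join(BASES[c] for c in flank_codes)
        records.append(
            SNPRecord(
                snp_id=snp_id,
                chrom="chr_syn",
                pos=1000 + i,
                risk_allele=risk,
                nonrisk_allele=nonrisk,
                flank=flank,
                noncoding=True,
                enhancer=bool(rng.random() < enhancer_fraction),
                phastcons=float(
                    rng.uniform(0.5, 1.0)
                    if rng.random() < conserved_fraction
                    else rng.uniform(0.0, 0.5)
                ),
                nearest_gene=None,
            )
        )
    return records, truth


def random_snp_sampler(
    motifs: list[MotifRecord], gc: float = 0.5
) -> "callable":
    """A null sampler drawing SNPs uniformly from random background sequence
    with random alternate alleles; suitable for simulation_null."""
    max_width = max(m.width for m in motifs)
    radius = max_width + 4

    def sampler(rng: np.random.Generator, n: int) -> list[SNPRecord]:
        out = []
        for i in range(n):
            codes = _random_sequence(rng, 2 * radius + 1, gc)
            present = BASES[codes[radius]]
            others = [b for b in BASES if b != present]
            risk = others[int(rng.integers(3))]
            out.append(
                SNPRecord(
                    snp_id=f"null{i:05d}",
                    chrom="chr_null",
                    pos=i + 1,
                    risk_allele=risk,
                    nonrisk_allele=present,
                    flank="".join(BASES[c] for c in codes),
                )
            )
        return out

    return sampler


# ---------------------------------------------------------------------------
# Bundle writer (text formats only)
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str, width: int = 80):
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_snp_panel(records: list[SNPRecord], path: str):
    pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "risk_allele": s.risk_allele,
                "nonrisk_allele": s.nonrisk_allele,
                "flank": s.flank,
                "noncoding": s.noncoding,
                "enhancer": s.enhancer,
                "phastcons": s.phastcons,
            }
            for s in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bundle(out_dir: str, seed: int = 7, scale: str = "small"):
    """Generate a coherent small dataset: motifs, promoters, expression and a
    SNP panel, plus a truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    n_motifs, n_genes = (12, 60) if scale == "small" else (40, 400)
    motifs, motif_truth = generate_motifs(
        n_motifs, n_families=2, family_cores=["GAAA", "TGACT"], seed=seed
    )
    genome, tss, regions, promoter_truth = generate_promoters(
        n_genes,
        motifs,
        upstream=900,
        downstream=100,
        rate_deg=2.0,
        rate_bg=1.0,
        seed=seed + 1,
    )
    expression, meta, qc, expr_truth = generate_expression(
        n_patients=24,
        n_datasets=3,
        n_genes=n_genes,
        n_deg_up=len(promoter_truth.deg_up),
        fc_up=2.0,
        sd=0.5,
        seed=seed + 2,
    )
    snps, snp_truth = generate_snp_panel(40, motifs, seed=seed + 3)

    write_fasta(genome, os.path.join(out_dir, "genome.fa"))
    tss.to_csv(os.path.join(out_dir, "tss.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "mask.bed"), "w") as out:
        for region in regions:
            for s, e in region.mask_intervals:
                out.write(f"{region.chrom}\t{s}\t{e}\n")
    expression.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
    meta.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    qc.to_csv(os.path.join(out_dir, "qc_metrics.tsv"), sep="\t")
    write_snp_panel(snps, os.path.join(out_dir, "snps.tsv"))

    from prescan.motif_dictionary import MotifDictionary, save_dictionary

    save_dictionary(MotifDictionary(motifs), os.path.join(out_dir, "dictionary"))
    truth = SyntheticTruth(
        motif_families=motif_truth.motif_families,
        enriched_motif_ids=promoter_truth.enriched_motif_ids,
        deg_up=expr_truth.deg_up,
        deg_down=expr_truth.deg_down,
        planted_instances=promoter_truth.planted_instances,
        snp_intent=snp_truth.snp_intent,
        outlier_samples=expr_truth.outlier_samples,
        swapped_patients=expr_truth.swapped_patients,
    )
    with open(os.path.join(out_dir, "truth.json"), "w") as out:
        out.write(truth.to_json())
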