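"""Risk-allele effects on PWM matches at SNP loci.

For each SNP x motif pair, the best match score over every window that
contains the SNP base (both strands) is computed once per allele; the effect
is (psi_R - psi_NR) / psi_max.  A risk allele engenders a site when
psi_R/psi_max > 0.85 with psi_NR/psi_max < 0.75, and disrupts one in the
opposite configuration.  SNP-window scans use uniform background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from prescan._seq import BASES, encode, revcomp_matrix
from prescan.motif_dictionary import MotifDictionary
from prescan.promoter_scan import PWMModel, ppm_to_pwm

logger = logging.getLogger(__name__)

ENGENDER_HIGH = 0.85
ENGENDER_LOW = 0.75


class UnsupportedVariantError(ValueError):
    """Raised for non-SNV alleles (indels, multi-base)."""


@dataclass
class SNPRecord:
    snp_id: str
    chrom: str
    pos: int  # 1-based
    risk_allele: str
    nonrisk_allele: str
    flank: str  # centered on pos
    noncoding: bool = True
    enhancer: bool = False
    phastcons: float | None = None
    nearest_gene: str | None = None

    def __post_init__(self):
        self.risk_allele = self.risk_allele.upper()
        self.nonrisk_allele = self.nonrisk_allele.upper()
        for allele in (self.risk_allele, self.nonrisk_allele):
            if len(allele) != 1 or allele not in BASES:
                raise UnsupportedVariantError(
                    f"{self.snp_id}: only single-base alleles supported, got {allele!r}"
                )
        if self.risk_allele == self.nonrisk_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        self.flank = self.flank.upper()
        if len(self.flank) % 2 != 1:
            raise ValueError(f"{self.snp_id}: flank length must be odd")
        center = self.flank[len(self.flank) // 2]
        if center not in (self.risk_allele, self.nonrisk_allele):
            raise ValueError(
                f"{self.snp_id}: flank center {center!r} matches neither allele"
            )

    @property
    def center(self) -> int:
        return len(self.flank) // 2

    def with_allele(self, allele: str) -> str:
        c = self.center
        return self.flank[:c] + allele + self.flank[c + 1 :]


@dataclass
class RiskAlleleEffect:
    snp_id: str
    motif_id: str
    psi_r: float
    psi_nr: float
    psi_max: float

    @property
    def effect(self) -> float:
        return (self.psi_r - self.psi_nr) / self.psi_max

    @property
    def change(self) -> str:
        return classify_binding_change(self.psi_r, self.psi_nr, self.psi_max)


def _best_snp_window_score(pwm: PWMModel, sequence: str, center: int) -> float:
    """Max psi over the m windows containing position ``center``, both strands."""
    m = pwm.width
    lo = center - m + 1
    hi = center  # last window start containing the center
    if lo < 0 or hi + m > len(sequence):
        raise ValueError(
            f"flank too short for motif width {m} (need {m - 1} bases each side)"
        )
    codes = encode(sequence)
    rc = revcomp_matrix(pwm.weights)
    cols = np.arange(m)
    best = -np.inf
    for start in range(lo, hi + 1):
        window = codes[start : start + m]
        if (window < 0).any():
            continue
        best = max(
            best,
            float(pwm.weights[window, cols].sum()),
            float(rc[window, cols].sum()),
        )
    return best


def risk_allele_effect(pwm: PWMModel, snp: SNPRecord) -> RiskAlleleEffect:
    if pwm.psi_max <= 0:
        raise ValueError(f"degenerate PWM {pwm.motif_id}")
    psi_r = _best_snp_window_score(pwm, snp.with_allele(snp.risk_allele), snp.center)
    psi_nr = _best_snp_window_score(
        pwm, snp.with_allele(snp.nonrisk_allele), snp.center
    )
    return RiskAlleleEffect(snp.snp_id, pwm.motif_id, psi_r, psi_nr, pwm.psi_max)


def classify_binding_change(psi_r: float, psi_nr: float, psi_max: float) -> str:
    if psi_max <= 0:
        raise ValueError("psi_max must be positive")
    r, nr = psi_r / psi_max, psi_nr / psi_max
    if r > ENGENDER_HIGH and nr < ENGENDER_LOW:
        return "engendered"
    if r < ENGENDER_LOW and nr > ENGENDER_HIGH:
        return "disrupted"
    return "none"


def score_panel(
    dictionary: MotifDictionary,
    snps: list[SNPRecord],
    motif_ids: list[str] | None = None,
) -> list[RiskAlleleEffect]:
    """Risk-allele effects over the full SNP x motif cross product."""
    records = dictionary.records
    if motif_ids is not None:
        wanted = set(motif_ids)
        records = [r for r in records if r.motif_id in wanted]
    pwms = [ppm_to_pwm(rec.ppm) for rec in records]  # uniform background
    effects = []
    for snp in snps:
        for pwm in pwms:
            effects.append(risk_allele_effect(pwm, snp))
    return effects


@dataclass
class RiskEffectSummary:
    n_combinations: int
    n_engendered: int
    n_disrupted: int

    @property
    def n_changed(self) -> int:
        return self.n_engendered + self.n_disrupted

    @property
    def pct_engendered(self) -> float:
        return 100.0 * self.n_engendered / self.n_combinations

    @property
    def pct_disrupted(self) -> float:
        return 100.0 * self.n_disrupted / self.n_combinations

    @property
    def pct_changed(self) -> float:
        return 100.0 * self.n_changed / self.n_combinations

    @property
    def disrupted_engendered_ratio(self) -> float | None:
        if self.n_engendered == 0:
            return None  # undefined
        return self.n_disrupted / self.n_engendered


def summarize_risk_effects(effects: list[RiskAlleleEffect]) -> RiskEffectSummary:
    if not effects:
        raise ValueError("no effects to summarize")
    changes = [e.change for e in effects]
    return RiskEffectSummary(
        n_combinations=len(effects),
        n_engendered=changes.count("engendered"),
        n_disrupted=changes.count("disrupted"),
    )


def group_effect_comparison(
    effects: list[RiskAlleleEffect],
    pre_motifs: set[str],
    other_motifs: set[str],
) -> tuple[float, float, float]:
    """Compare the per-motif median risk-allele effect between two motif
    groups: (median of PRE group, median of other group, two-sided rank-sum p).
    """
    by_motif: dict[str, list[float]] = {}
    for e in effects:
        by_motif.setdefault(e.motif_id, []).append(e.effect)
    group_a = [np.median(by_motif[m]) for m in sorted(pre_motifs) if m in by_motif]
    group_b = [np.median(by_motif[m]) for m in sorted(other_motifs) if m in by_motif]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each motif group needs at least 2 scored motifs")
    stat = mannwhitneyu(group_a, group_b, alternative="two-sided")
    return float(np.median(group_a)), float(np.median(group_b)), float(stat.pvalue)


def simulation_null(
    snp_sampler,
    dictionary: MotifDictionary,
    observed: RiskEffectSummary,
    n_trials: int,
    seed: int,
    motif_ids: list[str] | None = None,
) -> dict[str, float]:
    """Empirical upper-tail p-values for the observed changed-case percentage
    and disrupted/engendered ratio against resampled SNP panels.

    ``snp_sampler(rng, n)`` must return ``n`` SNPRecords.  Per tail,
    p = (1 + #{trials >= observed}) / (1 + n_trials).
    """
    if n_trials < 100:
        logger.warning("n_trials=%d is low; empirical p-values will be coarse", n_trials)
    rng = np.random.default_rng(seed)
    n_snps = observed.n_combinations // max(
        1, len(motif_ids) if motif_ids is not None else len(dictionary)
    )
    pct_hits = 0
    ratio_hits = 0
    ratio_trials = 0
    for _ in range(n_trials):
        panel = snp_sampler(rng, n_snps)
        summary = summarize_risk_effects(score_panel(dictionary, panel, motif_ids))
        if summary.pct_changed >= observed.pct_changed:
            pct_hits += 1
        ratio = summary.disrupted_engendered_ratio
        obs_ratio = observed.disrupted_engendered_ratio
        if ratio is not None and obs_ratio is not None:
            ratio_trials += 1
            if ratio >= obs_ratio:
                ratio_hits += 1
    out = {"p_pct_changed": (1 + pct_hits) / (1 + n_trials)}
    if observed.disrupted_engendered_ratio is not None and ratio_trials:
        out["p_ratio"] = (1 + ratio_hits) / (1 + ratio_trials)
    return out


def filter_candidate_sites(
    effects: list[RiskAlleleEffect],
    snps: dict[str, SNPRecord],
    deg_encoded_motifs: set[str],
    phastcons_min: float = 0.50,
) -> pd.DataFrame:
    """Engendered/disrupted combinations where the SNP locus is conserved
    (phastcons >= min) OR the motif is recognized by a DEG-encoded factor;
    sorted by |effect| descending."""
    rows = []
    for e in effects:
        change = e.change
        if change == "none":
            continue
        snp = snps[e.snp_id]
        conserved = snp.phastcons is not None and snp.phastcons >= phastcons_min
        deg_linked = e.motif_id in deg_encoded_motifs
        if not (conserved or deg_linked):
            continue
        rows.append(
            {
                "snp_id": e.snp_id,
                "locus": f"{snp.chrom}:{snp.pos}",
                "nearest_gene": snp.nearest_gene or "",
                "motif_id": e.motif_id,
                "change": change,
                "effect": e.effect,
                "phastcons": snp.phastcons,
                "deg_encoded": deg_linked,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "locus",
            "nearest_gene",
            "motif_id",
            "change",
            "effect",
            "phastcons",
            "deg_encoded",
        ],
    )
    if len(table):
        table = table.reindex(
            table["effect"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

SNP_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "risk_allele",
    "nonrisk_allele",
    "flank",
    "noncoding",
    "enhancer",
    "phastcons",
]


def load_snp_panel(path: str) -> list[SNPRecord]:
    table = pd.read_csv(path, sep="\t")
    missing = set(SNP_COLUMNS[:6]) - set(table.columns)
    if missing:
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        records.append(
            SNPRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                risk_allele=row["risk_allele"],
                nonrisk_allele=row["nonrisk_allele"],
                flank=row["flank"],
                noncoding=bool(row.get("noncoding", True)),
                enhancer=bool(row.get("enhancer", False)),
                phastcons=(
                    None
                    if "phastcons" not in table.columns or pd.isna(row["phastcons"])
                    else float(row["phastcons"])
                ),
                nearest_gene=(
                    str(row["nearest_gene"])
                    if "nearest_gene" in table.columns and not pd.isna(row["nearest_gene"])
                    else None
                ),
            )
        )
    return records


def merge_panels(*panels: list[SNPRecord]) -> list[SNPRecord]:
    """Combine SNP lists (e.g., lead + linked), dropping duplicate ids."""
    seen = set()
    merged = []
    for panel in panels:
        for snp in panel:
            if snp.snp_id not in seen:
                seen.add(snp.snp_id)
                merged.append(snp)
    return merged


def save_effects(effects: list[RiskAlleleEffect], path: str):
    pd.DataFrame(
        [
            {
                "snp_id": e.snp_id,
                "motif_id": e.motif_id,
                "psi_r": e.psi_r,
                "psi_nr": e.psi_nr,
                "psi_max": e.psi_max,
                "effect": e.effect,
                "change": e.change,
            }
            for e in effects
        ]
    ).to_csv(path, sep="\t", index=False)
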