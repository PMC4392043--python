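"""TSS-proximal region extraction, PWM construction and match scanning.

Regions span 5 kb upstream through 500 bp downstream of the TSS in gene
orientation.  Scoring uses log2(p/f) weights; a window is a match when its
summed weight reaches 80% of the model's maximum, on either strand.  Windows
touching masked bases or Ns are skipped; overlapping matches are merged so a
contiguous run of hits counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prescan._seq import encode, reverse_complement, revcomp_matrix
from prescan.motif_dictionary import MotifDictionary, PPM

UPSTREAM = 5000
DOWNSTREAM = 500
MATCH_THRESHOLD = 0.80
UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass
class PromoterRegion:
    gene_id: str
    chrom: str
    tss: int  # 1-based genomic coordinate
    strand: str
    sequence: str
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.mask_intervals = _merge_intervals(
            [
                (max(0, s), min(len(self.sequence), e))
                for s, e in self.mask_intervals
                if e > 0 and s < len(self.sequence)
            ]
        )

    @property
    def mask_array(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.mask_intervals:
            mask[s:e] = True
        return mask

    @property
    def nonmasked_length(self) -> int:
        return len(self.sequence) - int(self.mask_array.sum())


@dataclass
class PWMModel:
    motif_id: str
    weights: np.ndarray  # 4 x m log2(p / f)
    background: np.ndarray

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def psi_max(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def argmax_sequence(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))

    @property
    def is_degenerate(self) -> bool:
        return self.psi_max <= 0


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_promoter(
    genome,
    gene_id: str,
    chrom: str,
    tss: int,
    strand: str,
    mask_intervals_genomic: list[tuple[int, int]] | None = None,
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
) -> PromoterRegion:
    """Extract the TSS window from an indexed FASTA (pyfaidx.Fasta or a
    plain dict of contig -> sequence).

    For a plus-strand gene the genomic window is 0-based
    [tss-1-upstream, tss-1+downstream); minus-strand genes take the mirrored
    window reverse-complemented so upstream sequence precedes the TSS.
    Genomic mask intervals are 0-based half-open and mapped into region-local
    coordinates.
    """
    if hasattr(genome, "keys"):
        contigs = set(genome.keys())
    else:
        contigs = {rec.name for rec in genome}
    if chrom not in contigs:
        raise KeyError(f"contig {chrom!r} absent from genome")
    contig = genome[chrom]
    contig_seq = str(contig[:]) if hasattr(contig, "__getitem__") else str(contig)
    contig_len = len(contig_seq)

    tss0 = tss - 1
    if not 0 <= tss0 < contig_len:
        raise ValueError(f"TSS {tss} outside contig {chrom} (length {contig_len})")
    if strand == "+":
        start, end = tss0 - upstream, tss0 + downstream
    else:
        start, end = tss0 - downstream + 1, tss0 + upstream + 1
    clipped_start, clipped_end = max(0, start), min(contig_len, end)
    seq = contig_seq[clipped_start:clipped_end].upper()

    local_masks = []
    for gs, ge in mask_intervals_genomic or []:
        s = max(gs, clipped_start) - clipped_start
        e = min(ge, clipped_end) - clipped_start
        if e > s:
            local_masks.append((s, e))
    if strand == "-":
        n = len(seq)
        seq = reverse_complement(seq)
        local_masks = [(n - e, n - s) for s, e in local_masks]
    return PromoterRegion(
        gene_id=gene_id,
        chrom=chrom,
        tss=tss,
        strand=strand,
        sequence=seq,
        mask_intervals=local_masks,
        truncated=(clipped_start != start or clipped_end != end),
    )


def empirical_background(regions: list[PromoterRegion]) -> np.ndarray:
    """Base frequencies over non-masked, non-N positions of all regions."""
    if not regions:
        raise ValueError("need at least one region")
    counts = np.zeros(4)
    for region in regions:
        codes = encode(region.sequence)
        usable = codes[(~region.mask_array) & (codes >= 0)]
        counts += np.bincount(usable, minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable bases in any region")
    return counts / total


def ppm_to_pwm(ppm: PPM, background: np.ndarray | None = None) -> PWMModel:
    """log2(p/f) weights; psi_max is the sum of per-column maxima."""
    f = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if f.shape != (4,) or np.any(f <= 0):
        raise ValueError("background must be 4 positive probabilities")
    with np.errstate(divide="ignore"):
        weights = np.log2(ppm.probs / f[:, None])
    return PWMModel(ppm.motif_id, weights, f)


def window_scores(pwm: PWMModel, sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(forward psi, reverse psi, valid window flag) for every window start.

    Invalid windows (containing N) carry -inf scores and valid=False.
    """
    m = pwm.width
    codes = encode(sequence)
    n_windows = len(codes) - m + 1
    if n_windows <= 0:
        empty = np.empty(0)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    cols = np.arange(m)
    fwd = pwm.weights[safe, cols].sum(axis=1)
    rc = revcomp_matrix(pwm.weights)
    rev = rc[safe, cols].sum(axis=1)
    fwd[~valid] = -np.inf
    rev[~valid] = -np.inf
    return fwd, rev, valid


def scan_pwm(
    pwm: PWMModel,
    region: PromoterRegion,
    threshold: float = MATCH_THRESHOLD,
) -> list[tuple[int, int]]:
    """Merged match intervals (0-based half-open, region-local) where
    psi/psi_max meets the threshold on either strand.  Windows overlapping a
    mask or containing N are excluded."""
    if pwm.is_degenerate:
        raise ValueError(f"degenerate PWM {pwm.motif_id}: psi_max <= 0")
    m = pwm.width
    if len(region.sequence) < m:
        return []
    fwd, rev, valid = window_scores(pwm, region.sequence)
    mask = region.mask_array
    if mask.any():
        masked_windows = np.lib.stride_tricks.sliding_window_view(mask, m).any(axis=1)
        valid = valid & ~masked_windows
    cutoff = threshold * pwm.psi_max
    hits = valid & ((fwd >= cutoff) | (rev >= cutoff))
    return _merge_intervals([(int(s), int(s) + m) for s in np.nonzero(hits)[0]])


def count_matches(pwm: PWMModel, region: PromoterRegion, threshold: float = MATCH_THRESHOLD) -> int:
    return len(scan_pwm(pwm, region, threshold))


@dataclass
class MatchMatrix:
    counts: pd.DataFrame  # genes x motifs
    lengths: pd.Series  # per-gene non-masked bp


def build_match_matrix(
    dictionary: MotifDictionary,
    regions: list[PromoterRegion],
    threshold: float = MATCH_THRESHOLD,
    background: np.ndarray | None = None,
) -> MatchMatrix:
    """Merged-match counts for every gene x motif plus scanned lengths.

    ``background`` defaults to the empirical background of the regions, per
    the promoter-scan convention; pass UNIFORM_BACKGROUND for other scans.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    if background is None:
        background = empirical_background(regions)
    pwms = [ppm_to_pwm(rec.ppm, background) for rec in dictionary.records]
    data = np.zeros((len(regions), len(pwms)), dtype=int)
    for i, region in enumerate(regions):
        for j, pwm in enumerate(pwms):
            if region.nonmasked_length < pwm.width:
                continue
            data[i, j] = count_matches(pwm, region, threshold)
    counts = pd.DataFrame(
        data,
        index=[r.gene_id for r in regions],
        columns=[p.motif_id for p in pwms],
    )
    lengths = pd.Series(
        [r.nonmasked_length for r in regions], index=counts.index, name="nonmasked_bp"
    )
    return MatchMatrix(counts, lengths)


def motif_density_fold(
    region: PromoterRegion,
    pwm: PWMModel,
    genomewide_mean_density: float,
    threshold: float = MATCH_THRESHOLD,
) -> float:
    """Region match density (matches per non-masked kb) over a genome-wide
    mean density."""
    if genomewide_mean_density <= 0:
        raise ValueError("genome-wide mean density must be positive")
    if region.nonmasked_length == 0:
        raise ValueError("region has no non-masked sequence")
    density = count_matches(pwm, region, threshold) / (region.nonmasked_length / 1000.0)
    return density / genomewide_mean_density


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def load_tss_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(table.columns):
        raise ValueError(f"TSS table requires columns {sorted(required)}")
    return table


def load_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    return intervals


def matches_to_bed(
    pwm: PWMModel,
    region: PromoterRegion,
    threshold: float = MATCH_THRESHOLD,
) -> list[str]:
    """Merged matches as BED6 lines (region-local coordinates); the score
    field holds the interval's best psi/psi_max."""
    fwd, rev, _ = window_scores(pwm, region.sequence)
    lines = []
    for start, end in scan_pwm(pwm, region, threshold):
        window_slice = slice(start, min(end, len(fwd) + start) - pwm.width + 1)
        starts = range(start, end - pwm.width + 1)
        best = max(max(fwd[s], rev[s]) for s in starts)
        ratio = best / pwm.psi_max
        lines.append(
            f"{region.gene_id}\t{start}\t{end}\t{pwm.motif_id}\t{ratio:.4f}\t+"
        )
    return lines
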