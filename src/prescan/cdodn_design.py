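"""Complex decoy oligonucleotide (cdODN) enumeration, screening and ranking.

Designs are all orderings x per-block orientations of a small set of
consensus blocks (n! * 2^n candidates; duplicates from palindromic blocks are
not collapsed).  Each design is screened against the motif dictionary for
per-motif presence at the 80% match threshold and ranked by the mean
enrichment Z of its matched motifs, with near-ties broken by specificity
(fewer matches) and then by sequence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prescan._seq import reverse_complement
from prescan.motif_dictionary import MotifDictionary
from prescan.promoter_scan import MATCH_THRESHOLD, ppm_to_pwm, window_scores

logger = logging.getLogger(__name__)

AVG_Z_TIE_WINDOW = 0.02
MAX_BLOCKS = 8


@dataclass
class CdODNCandidate:
    design_id: int
    block_order: tuple[str, ...]
    orientations: tuple[str, ...]  # per block: "fwd" | "rc"
    sequence: str
    matched_motifs: set[str] = field(default_factory=set)
    avg_z: float = float("nan")

    @property
    def n_matches(self) -> int:
        return len(self.matched_motifs)


def enumerate_designs(
    blocks: dict[str, str], spacer: str = ""
) -> list[CdODNCandidate]:
    """All n! * 2^n ordering/orientation combinations of the named blocks."""
    if not 1 <= len(blocks) <= MAX_BLOCKS:
        raise ValueError(f"need 1..{MAX_BLOCKS} blocks, got {len(blocks)}")
    for name, seq in blocks.items():
        if not seq:
            raise ValueError(f"block {name!r} is empty")
    candidates = []
    design_id = 0
    for order in itertools.permutations(sorted(blocks)):
        for orient in itertools.product(("fwd", "rc"), repeat=len(order)):
            parts = [
                blocks[name] if o == "fwd" else reverse_complement(blocks[name])
                for name, o in zip(order, orient)
            ]
            candidates.append(
                CdODNCandidate(
                    design_id=design_id,
                    block_order=order,
                    orientations=orient,
                    sequence=spacer.join(parts),
                )
            )
            design_id += 1
    return candidates


def screen_oligo(
    sequence: str,
    dictionary: MotifDictionary,
    threshold: float = MATCH_THRESHOLD,
) -> set[str]:
    """Motifs with at least one window on either strand reaching
    psi/psi_max >= threshold (uniform background); per-motif presence."""
    matched = set()
    for rec in dictionary.records:
        pwm = ppm_to_pwm(rec.ppm)
        if pwm.is_degenerate:
            logger.info("skipping degenerate PWM %s", rec.motif_id)
            continue
        if pwm.width > len(sequence):
            continue
        fwd, rev, valid = window_scores(pwm, sequence)
        if not valid.any():
            continue
        cutoff = threshold * pwm.psi_max
        if ((fwd >= cutoff) | (rev >= cutoff)).any():
            matched.add(rec.motif_id)
    return matched


def rank_designs(
    candidates: list[CdODNCandidate],
    dictionary: MotifDictionary,
    enrichment_z: dict[str, float],
    threshold: float = MATCH_THRESHOLD,
    tie_window: float = AVG_Z_TIE_WINDOW,
) -> list[CdODNCandidate]:
    """Screen and rank candidates: average matched-motif Z descending, with
    near-ties (|delta| < tie_window) broken by fewer matches, then sequence.

    Motifs missing from the Z table contribute 0 (logged).  Candidates with
    no matches rank last.
    """
    missing_logged = set()
    for cand in candidates:
        cand.matched_motifs = screen_oligo(cand.sequence, dictionary, threshold)
        if cand.matched_motifs:
            zs = []
            for motif in cand.matched_motifs:
                if motif not in enrichment_z and motif not in missing_logged:
                    logger.info("motif %s has no Z; contributing 0", motif)
                    missing_logged.add(motif)
                zs.append(enrichment_z.get(motif, 0.0))
            cand.avg_z = float(np.mean(zs))
        else:
            cand.avg_z = -np.inf

    ordered = sorted(candidates, key=lambda c: (-c.avg_z, c.n_matches, c.sequence))
    ranked: list[CdODNCandidate] = []
    i = 0
    while i < len(ordered):
        j = i
        head = ordered[i].avg_z
        while j < len(ordered) and (
            np.isinf(head) and np.isinf(ordered[j].avg_z)
            or abs(ordered[j].avg_z - head) < tie_window
        ):
            j += 1
        bucket = sorted(ordered[i:j], key=lambda c: (c.n_matches, c.sequence))
        ranked.extend(bucket)
        i = j
    return ranked


def profile_dodn(
    sequence: str,
    dictionary: MotifDictionary,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k motifs by best normalized match score over all windows/strands.

    The report carries the motif's associated genes so off-target top hits
    are visible.
    """
    rows = []
    for rec in dictionary.records:
        pwm = ppm_to_pwm(rec.ppm)
        if pwm.is_degenerate or pwm.width > len(sequence):
            continue
        fwd, rev, valid = window_scores(pwm, sequence)
        if not valid.any():
            continue
        best = float(max(fwd.max(), rev.max()))
        rows.append(
            {
                "motif_id": rec.motif_id,
                "score": best / pwm.psi_max,
                "genes": ",".join(rec.genes),
            }
        )
    table = pd.DataFrame(rows, columns=["motif_id", "score", "genes"])
    table = table.sort_values(
        ["score", "motif_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(k) if k < len(table) else table


def candidates_to_table(candidates: list[CdODNCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "design_id": c.design_id,
                "sequence": c.sequence,
                "n_matches": c.n_matches,
                "avg_z": c.avg_z,
                "order": "+".join(c.block_order),
                "orientations": "+".join(c.orientations),
            }
            for i, c in enumerate(candidates)
        ]
    )
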