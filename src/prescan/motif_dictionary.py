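"""Binding-site matrix models and dictionary curation.

Matrices move through three representations: raw counts (PFM), probabilities
after pseudocount conversion (PPM) and, downstream, log-odds weights.  The
curation pipeline trims uninformative flanks, discards matrices that become
too short and removes redundancy in two stages (same-consensus deduplication,
then distance-based collapse of near-identical matrices).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from prescan._seq import BASES, IUPAC_BY_SET, revcomp_matrix

DEFAULT_PSEUDOCOUNT = 0.80
DEFAULT_IC_THRESHOLD = 0.25
DEFAULT_MIN_WIDTH = 4
DEFAULT_PPM_DIFF = 0.05
DEFAULT_DISTANCE_THRESHOLD = 1e-14

SOURCES = (
    "hpdi",
    "jaspar",
    "uniprobe",
    "transfac",
    "encode_chipseq",
    "selex",
    "synthetic",
)


class InvalidMatrixError(ValueError):
    """Raised when a matrix violates a structural precondition."""


class MotifParseError(ValueError):
    """Parse failure carrying the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: raw (possibly fractional) base counts."""

    motif_id: str
    counts: np.ndarray  # 4 x m, rows A,C,G,T

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise InvalidMatrixError(
                f"{self.motif_id}: counts must be 4 x m with m >= 1"
            )
        if np.any(counts < 0):
            raise InvalidMatrixError(f"{self.motif_id}: negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PPM:
    """Position probability matrix; columns sum to one."""

    motif_id: str
    probs: np.ndarray  # 4 x m
    pseudocount_applied: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise InvalidMatrixError(f"{self.motif_id}: probs must be 4 x m")
        if np.any(probs < 0):
            raise InvalidMatrixError(f"{self.motif_id}: negative probabilities")
        sums = probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InvalidMatrixError(
                f"{self.motif_id}: columns must sum to 1 (got {sums})"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "PPM":
        return replace(self, probs=revcomp_matrix(self.probs))


@dataclass
class MotifRecord:
    """A curated binding-site model plus its annotations."""

    motif_id: str
    ppm: PPM
    source: str = "synthetic"
    genes: list[str] = field(default_factory=list)
    dbd_superfamily: str | None = None
    dbd_class: str | None = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def avg_information_content(self) -> float:
        return float(np.mean([column_ic(c) for c in self.ppm.probs.T]))

    @property
    def width(self) -> int:
        return self.ppm.width

    @property
    def consensus(self) -> str:
        return ppm_to_iupac(self.ppm)


@dataclass
class RemovalEvent:
    motif_id: str
    step: str  # consensus_dedup | distance_collapse | trim_discard
    kept_id: str | None


@dataclass
class MotifDictionary:
    records: list[MotifRecord]
    provenance: list[RemovalEvent] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.motif_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate motif ids in dictionary")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, motif_id: str) -> MotifRecord:
        for rec in self.records:
            if rec.motif_id == motif_id:
                return rec
        raise KeyError(motif_id)

    @property
    def motif_ids(self) -> list[str]:
        return [r.motif_id for r in self.records]


# ---------------------------------------------------------------------------
# Matrix conversion and curation operations
# ---------------------------------------------------------------------------

def pfm_to_ppm(pfm: PFM, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PPM:
    """Convert counts to probabilities, splitting the pseudocount equally
    across the four bases: p_bj = (n_bj + pc/4) / (N_j + pc)."""
    if pseudocount <= 0:
        raise InvalidMatrixError("pseudocount must be positive")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount / 4.0) / (totals + pseudocount)
    return PPM(pfm.motif_id, probs, pseudocount_applied=pseudocount)


def column_ic(column: np.ndarray) -> float:
    """Information content of one PPM column: 2 + sum p*log2(p), in bits."""
    col = np.asarray(column, dtype=float)
    if col.shape != (4,):
        raise InvalidMatrixError("column must have 4 entries")
    if abs(col.sum() - 1.0) > 1e-9:
        raise InvalidMatrixError(f"column does not sum to 1: {col}")
    nz = col[col > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def avg_ic(ppm: PPM) -> float:
    return float(np.mean([column_ic(c) for c in ppm.probs.T]))


def _strict_bounds(ic: np.ndarray, threshold: float) -> tuple[int, int] | None:
    """Keep [start, end] where both flanks begin with two consecutive
    above-threshold columns; None when no such pair exists."""
    m = len(ic)
    start = next(
        (i for i in range(m - 1) if ic[i] > threshold and ic[i + 1] > threshold),
        None,
    )
    if start is None:
        return None
    end = next(
        j for j in range(m - 1, 0, -1) if ic[j] > threshold and ic[j - 1] > threshold
    )
    return start, end


def _relaxed_bounds(ic: np.ndarray, threshold: float) -> tuple[int, int] | None:
    above = np.nonzero(ic > threshold)[0]
    if len(above) == 0:
        return None
    return int(above[0]), int(above[-1])


def trim_ppm(
    ppm: PPM,
    ic_threshold: float = DEFAULT_IC_THRESHOLD,
    min_width: int = DEFAULT_MIN_WIDTH,
) -> PPM | None:
    """Trim low-information flanks.

    The strict rule removes flank columns until two consecutive columns with
    IC above the threshold are met on each side.  When that removes every
    column or leaves fewer than ``min_width``, the relaxed rule (stop at a
    single above-threshold column) is applied to the original matrix.
    Returns None when even the relaxed result is narrower than ``min_width``.
    """
    ic = np.array([column_ic(c) for c in ppm.probs.T])
    bounds = _strict_bounds(ic, ic_threshold)
    if bounds is None or bounds[1] - bounds[0] + 1 < min_width:
        bounds = _relaxed_bounds(ic, ic_threshold)
    if bounds is None or bounds[1] - bounds[0] + 1 < min_width:
        return None
    start, end = bounds
    return replace(ppm, probs=ppm.probs[:, start : end + 1])


def ppm_to_iupac(ppm: PPM) -> str:
    """Degenerate consensus: a base joins a column's set when p >= 0.25."""
    letters = []
    for col in ppm.probs.T:
        members = frozenset(b for b, p in zip(BASES, col) if p >= 0.25)
        letters.append(IUPAC_BY_SET[members])
    return "".join(letters)


def _ordered(records: list[MotifRecord]) -> list[MotifRecord]:
    # higher avg IC first; exact ties broken by motif_id
    return sorted(records, key=lambda r: (-r.avg_information_content, r.motif_id))


def dedup_consensus(
    records: list[MotifRecord], max_ppm_diff: float = DEFAULT_PPM_DIFF
) -> tuple[list[MotifRecord], list[RemovalEvent]]:
    """Drop the lower-IC member of same-width, same-consensus pairs unless
    their matrices differ by more than ``max_ppm_diff`` on average."""
    groups: dict[tuple[int, str], list[MotifRecord]] = {}
    for rec in records:
        groups.setdefault((rec.width, rec.consensus), []).append(rec)

    kept_ids = set()
    removed: list[RemovalEvent] = []
    for key, members in groups.items():
        retained: list[MotifRecord] = []
        for rec in _ordered(members):
            superseded_by = None
            for keeper in retained:
                diff = float(np.mean(np.abs(rec.ppm.probs - keeper.ppm.probs)))
                if diff <= max_ppm_diff:
                    superseded_by = keeper
                    break
            if superseded_by is None:
                retained.append(rec)
            else:
                removed.append(
                    RemovalEvent(rec.motif_id, "consensus_dedup", superseded_by.motif_id)
                )
        kept_ids.update(r.motif_id for r in retained)

    kept = [r for r in records if r.motif_id in kept_ids]
    return kept, removed


def motif_distance(a: PPM, b: PPM, min_overlap: int = 4) -> float:
    """1 minus the best Pearson correlation over all ungapped column
    alignments of ``a`` against ``b`` and reverse-complemented ``b``.

    Correlation is computed over the flattened 4 x overlap sub-matrices;
    offsets with fewer than ``min_overlap`` aligned columns are skipped.
    Offsets where either sub-matrix is constant contribute correlation 0.
    """
    best = -1.0
    found = False
    for mat_b in (b.probs, revcomp_matrix(b.probs)):
        wa, wb = a.probs.shape[1], mat_b.shape[1]
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(wa, offset + wb)
            if hi_a - lo_a < min_overlap:
                continue
            sub_a = a.probs[:, lo_a:hi_a].ravel()
            sub_b = mat_b[:, lo_a - offset : hi_a - offset].ravel()
            if np.ptp(sub_a) == 0 or np.ptp(sub_b) == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(sub_a, sub_b)[0, 1])
            best = max(best, corr)
            found = True
    if not found:
        return 1.0
    return 1.0 - best


def collapse_similar(
    records: list[MotifRecord],
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> tuple[list[MotifRecord], list[RemovalEvent]]:
    """Single-linkage groups over pairs closer than the threshold; each group
    keeps only its highest-average-IC member."""
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if motif_distance(records[i].ppm, records[j].ppm) < distance_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[MotifRecord]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)

    kept_ids = set()
    removed: list[RemovalEvent] = []
    for members in groups.values():
        ranked = _ordered(members)
        keeper = ranked[0]
        kept_ids.add(keeper.motif_id)
        for rec in ranked[1:]:
            removed.append(
                RemovalEvent(rec.motif_id, "distance_collapse", keeper.motif_id)
            )

    kept = [r for r in records if r.motif_id in kept_ids]
    return kept, removed


def curate(
    records: list[MotifRecord],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,  # noqa: ARG001 - documented default
    ic_threshold: float = DEFAULT_IC_THRESHOLD,
    min_width: int = DEFAULT_MIN_WIDTH,
    max_ppm_diff: float = DEFAULT_PPM_DIFF,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> MotifDictionary:
    """Run trim -> consensus dedup -> distance collapse over raw records."""
    provenance: list[RemovalEvent] = []
    trimmed: list[MotifRecord] = []
    for rec in records:
        result = trim_ppm(rec.ppm, ic_threshold=ic_threshold, min_width=min_width)
        if result is None:
            provenance.append(RemovalEvent(rec.motif_id, "trim_discard", None))
        else:
            trimmed.append(replace_record_ppm(rec, result))

    deduped, removed = dedup_consensus(trimmed, max_ppm_diff=max_ppm_diff)
    provenance.extend(removed)
    collapsed, removed = collapse_similar(deduped, distance_threshold=distance_threshold)
    provenance.extend(removed)
    return MotifDictionary(collapsed, provenance)


def replace_record_ppm(rec: MotifRecord, ppm: PPM) -> MotifRecord:
    return MotifRecord(
        motif_id=rec.motif_id,
        ppm=ppm,
        source=rec.source,
        genes=list(rec.genes),
        dbd_superfamily=rec.dbd_superfamily,
        dbd_class=rec.dbd_class,
    )


# ---------------------------------------------------------------------------
# Dialect parsers and writers
# ---------------------------------------------------------------------------

def _parse_numbers(text: str, line_no: int) -> list[float]:
    cleaned = text.replace("[", " ").replace("]", " ")
    values = []
    for token in cleaned.split():
        try:
            values.append(float(token))
        except ValueError:
            raise MotifParseError(f"non-numeric cell {token!r}", line_no) from None
    return values


def _parse_jaspar_counts(lines: list[str]) -> list[PFM]:
    matrices: list[PFM] = []
    motif_id = None
    rows: list[list[float]] = []
    row_lines: list[int] = []

    def flush(line_no: int):
        nonlocal motif_id, rows, row_lines
        if motif_id is None:
            return
        if len(rows) != 4:
            raise MotifParseError(
                f"motif {motif_id!r} has {len(rows)} rows, expected 4", line_no
            )
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise MotifParseError(
                f"motif {motif_id!r} has ragged rows (widths {sorted(widths)})",
                row_lines[-1],
            )
        matrices.append(PFM(motif_id, np.array(rows)))
        motif_id, rows, row_lines = None, [], []

    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            motif_id = line[1:].split()[0]
        else:
            if motif_id is None:
                raise MotifParseError("matrix row before any '>' header", i)
            body = line
            if body[0] in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            rows.append(_parse_numbers(body, i))
            row_lines.append(i)
    flush(len(lines))
    return matrices


def _parse_meme_probs(lines: list[str]) -> list[PPM]:
    matrices: list[PPM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError("MOTIF line without an identifier", i + 1)
            motif_id = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(
                        f"motif {motif_id!r} has no probability matrix", i + 1
                    )
                i += 1
            if i == len(lines):
                raise MotifParseError(
                    f"motif {motif_id!r} has no probability matrix", i
                )
            i += 1
            cols: list[list[float]] = []
            while i < len(lines):
                row = lines[i].strip()
                if not row or row.startswith(("MOTIF", "letter-probability")):
                    break
                values = _parse_numbers(row, i + 1)
                if len(values) != 4:
                    raise MotifParseError(
                        f"expected 4 probabilities, got {len(values)}", i + 1
                    )
                cols.append(values)
                i += 1
            if not cols:
                raise MotifParseError(f"motif {motif_id!r} has an empty matrix", i)
            probs = np.array(cols).T
            probs = probs / probs.sum(axis=0)  # renormalize 6-decimal rounding
            matrices.append(PPM(motif_id, probs, pseudocount_applied=0.0))
        else:
            i += 1
    return matrices


def _parse_transfac_like(lines: list[str]) -> list[PFM]:
    matrices: list[PFM] = []
    motif_id = None
    rows: list[list[float]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split()[0]
        if tag == "ID":
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError("ID line without an identifier", i)
            motif_id = parts[1]
            rows = []
        elif tag == "P0" or tag == "PO":
            continue
        elif tag == "//":
            if motif_id is None:
                raise MotifParseError("block terminator before any ID", i)
            if not rows:
                raise MotifParseError(f"motif {motif_id!r} has no matrix rows", i)
            widths = {len(r) for r in rows}
            if len(widths) != 1:
                raise MotifParseError(
                    f"motif {motif_id!r} has ragged rows (widths {sorted(widths)})", i
                )
            matrices.append(PFM(motif_id, np.array(rows).T))
            motif_id, rows = None, []
        elif tag[0].isdigit():
            values = _parse_numbers(line, i)
            body = values[1:]  # leading token is the position index
            if len(body) < 4:
                raise MotifParseError(f"expected 4 counts, got {len(body)}", i)
            rows.append(body[:4])
        # other TRANSFAC-like annotation tags are ignored
    if motif_id is not None:
        raise MotifParseError(f"motif {motif_id!r} not terminated by //", len(lines))
    return matrices


DIALECTS = ("jaspar_counts", "meme_probs", "transfac_like")


def parse_motifs(path: str | os.PathLike, dialect: str) -> list[PFM | PPM]:
    """Parse a motif file; count dialects yield PFMs, probability dialects
    PPMs flagged ``pseudocount_applied == 0``."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    if dialect == "jaspar_counts":
        return _parse_jaspar_counts(lines)
    if dialect == "meme_probs":
        return _parse_meme_probs(lines)
    if dialect == "transfac_like":
        return _parse_transfac_like(lines)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_motifs(matrices: list[PFM | PPM], path: str | os.PathLike, dialect: str):
    with open(path, "w") as out:
        if dialect == "jaspar_counts":
            for m in matrices:
                out.write(f">{m.motif_id}\n")
                data = m.counts if isinstance(m, PFM) else m.probs
                for base, row in zip(BASES, data):
                    cells = " ".join(f"{v:.6f}" for v in row)
                    out.write(f"{base} [ {cells} ]\n")
        elif dialect == "meme_probs":
            out.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            for m in matrices:
                probs = m.probs if isinstance(m, PPM) else None
                if probs is None:
                    raise ValueError("meme_probs writer requires PPMs")
                out.write(f"MOTIF {m.motif_id}\n")
                out.write(
                    f"letter-probability matrix: alength= 4 w= {probs.shape[1]}\n"
                )
                for col in probs.T:
                    out.write(" ".join(f"{v:.6f}" for v in col) + "\n")
                out.write("\n")
        elif dialect == "transfac_like":
            for m in matrices:
                data = m.counts if isinstance(m, PFM) else m.probs
                out.write(f"ID {m.motif_id}\nP0 A C G T\n")
                for j, col in enumerate(data.T, start=1):
                    cells = " ".join(f"{v:.6f}" for v in col)
                    out.write(f"{j:02d} {cells}\n")
                out.write("//\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Dictionary serialization: TSV-indexed directory + JSON-lines provenance
# ---------------------------------------------------------------------------

def save_dictionary(dictionary: MotifDictionary, path: str | os.PathLike):
    os.makedirs(path, exist_ok=True)
    meta_rows = []
    ppm_rows = []
    for rec in dictionary.records:
        meta_rows.append(
            {
                "motif_id": rec.motif_id,
                "source": rec.source,
                "genes": ",".join(rec.genes),
                "dbd_superfamily": rec.dbd_superfamily or "",
                "dbd_class": rec.dbd_class or "",
                "width": rec.width,
                "consensus": rec.consensus,
                "avg_ic": rec.avg_information_content,
                "pseudocount_applied": rec.ppm.pseudocount_applied,
            }
        )
        for j, col in enumerate(rec.ppm.probs.T):
            ppm_rows.append(
                {
                    "motif_id": rec.motif_id,
                    "position": j,
                    "A": col[0],
                    "C": col[1],
                    "G": col[2],
                    "T": col[3],
                }
            )
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(path, "records.tsv"), sep="\t", index=False
    )
    pd.DataFrame(ppm_rows).to_csv(
        os.path.join(path, "ppms.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    with open(os.path.join(path, "provenance.jsonl"), "w") as out:
        for event in dictionary.provenance:
            out.write(
                json.dumps(
                    {
                        "motif_id": event.motif_id,
                        "step": event.step,
                        "kept_id": event.kept_id,
                    }
                )
                + "\n"
            )


def load_dictionary(path: str | os.PathLike) -> MotifDictionary:
    meta = pd.read_csv(os.path.join(path, "records.tsv"), sep="\t")
    ppms = pd.read_csv(os.path.join(path, "ppms.tsv"), sep="\t")
    records = []
    for _, row in meta.iterrows():
        block = ppms[ppms["motif_id"] == row["motif_id"]].sort_values("position")
        probs = block[["A", "C", "G", "T"]].to_numpy().T
        probs = probs / probs.sum(axis=0)
        genes = [] if pd.isna(row["genes"]) or row["genes"] == "" else str(row["genes"]).split(",")
        records.append(
            MotifRecord(
                motif_id=row["motif_id"],
                ppm=PPM(row["motif_id"], probs, float(row["pseudocount_applied"])),
                source=row["source"],
                genes=genes,
                dbd_superfamily=row["dbd_superfamily"] if isinstance(row["dbd_superfamily"], str) and row["dbd_superfamily"] else None,
                dbd_class=row["dbd_class"] if isinstance(row["dbd_class"], str) and row["dbd_class"] else None,
            )
        )
    provenance = []
    prov_path = os.path.join(path, "provenance.jsonl")
    if os.path.exists(prov_path):
        with open(prov_path) as handle:
            for line in handle:
                obj = json.loads(line)
                provenance.append(
                    RemovalEvent(obj["motif_id"], obj["step"], obj["kept_id"])
                )
    return MotifDictionary(records, provenance)
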