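"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops over every orientation, offset and window.
"""

import numpy as np

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def psi(weights, seq):
    """Summed log-odds of a window (len(seq) == weights.shape[1])."""
    return sum(weights[BASES.index(b), j] for j, b in enumerate(seq))


def brute_scan(weights, sequence, threshold, masked=()):
    """Match intervals by evaluating psi at every window on both strands,
    skipping windows with N or masked bases, then merging overlaps."""
    m = weights.shape[1]
    psi_max = sum(max(weights[:, j]) for j in range(m))
    masked = set(masked)
    hits = []
    for start in range(len(sequence) - m + 1):
        window = sequence[start : start + m]
        if "N" in window or any(p in masked for p in range(start, start + m)):
            continue
        if (
            psi(weights, window) >= threshold * psi_max
            or psi(weights, revcomp(window)) >= threshold * psi_max
        ):
            hits.append((start, start + m))
    merged = []
    for s, e in sorted(hits):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def brute_kmer_score(probs, word):
    """Max over both orientations and all start positions of the min matched
    probability."""
    best = 0.0
    m = probs.shape[1]
    for oriented in (word, revcomp(word)):
        k = len(oriented)
        for start in range(m - k + 1):
            low = min(
                probs[BASES.index(b), start + j] for j, b in enumerate(oriented)
            )
            best = max(best, low)
    return best


def brute_best_snp_score(weights, flank, center, allele):
    """Max psi over every window containing the center base, both strands,
    after substituting the allele at the center."""
    seq = flank[:center] + allele + flank[center + 1 :]
    m = weights.shape[1]
    best = -np.inf
    for start in range(len(seq) - m + 1):
        if not (start <= center < start + m):
            continue
        window = seq[start : start + m]
        if "N" in window:
            continue
        best = max(best, psi(weights, window), psi(weights, revcomp(window)))
    return best


def brute_motif_distance(probs_a, probs_b, min_overlap=4):
    """1 - best Pearson correlation over every ungapped offset of b (and its
    reverse complement) against a."""
    def rc(mat):
        return mat[::-1, ::-1]

    best = None
    for mat in (probs_b, rc(probs_b)):
        wa, wb = probs_a.shape[1], mat.shape[1]
        for offset in range(-wb + 1, wa):
            lo = max(0, offset)
            hi = min(wa, offset + wb)
            if hi - lo < min_overlap:
                continue
            x = probs_a[:, lo:hi].ravel()
            y = mat[:, lo - offset : hi - offset].ravel()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(x, y)[0, 1])
            best = corr if best is None else max(best, corr)
    return 1.0 if best is None else 1.0 - best


def bh_stepup(p):
    """Closed-form Benjamini-Hochberg step-up on a plain list."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
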