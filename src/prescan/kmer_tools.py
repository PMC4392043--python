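"""k-mer preference scores, motif similarity, nearest-neighbor DNA-binding
domain enrichment and motif clustering.

A motif's k-mer score for a word is the best "weakest link" probability over
all placements of the word in the probability matrix, taking the better of
the two 5'-3' orientations: max over start positions of min over the k
matched base probabilities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, mannwhitneyu

from prescan._seq import BASE_INDEX, BASES, reverse_complement
from prescan.motif_dictionary import MotifDictionary, MotifRecord, PPM

KMER_SIZES = (3, 4)
ALL_WORDS = tuple(
    "".join(w) for k in KMER_SIZES for w in itertools.product(BASES, repeat=k)
)  # 64 + 256 = 320 words, 3-mers first


@dataclass
class KmerProfile:
    motif_id: str
    scores: dict[str, float]  # word -> [0, 1]

    def vector(self) -> np.ndarray:
        return np.array([self.scores[w] for w in ALL_WORDS])


@dataclass
class NeighborEnrichment:
    motif_id: str
    category: str
    level: str  # "superfamily" | "class"
    neighbor_fraction: float
    n_neighbors: int
    fisher_p: float

    @property
    def score(self) -> float:
        return -math.log10(self.fisher_p) if self.fisher_p > 0 else math.inf


def _oriented_score(probs: np.ndarray, word: str) -> float:
    m = probs.shape[1]
    k = len(word)
    if m < k:
        return 0.0
    idx = [BASE_INDEX[b] for b in word]
    best = 0.0
    for start in range(m - k + 1):
        lowest = min(probs[idx[j], start + j] for j in range(k))
        best = max(best, lowest)
    return best


def kmer_score(ppm: PPM, word: str) -> float:
    """Best min-probability placement of the word, over both orientations."""
    word = word.upper()
    if not 3 <= len(word) <= 4:
        raise ValueError(f"word length must be 3 or 4, got {len(word)}")
    if any(b not in BASE_INDEX for b in word):
        raise ValueError(f"invalid characters in word {word!r}")
    return max(
        _oriented_score(ppm.probs, word),
        _oriented_score(ppm.probs, reverse_complement(word)),
    )


def kmer_profile(ppm: PPM) -> KmerProfile:
    return KmerProfile(ppm.motif_id, {w: kmer_score(ppm, w) for w in ALL_WORDS})


def profile_matrix(profiles: list[KmerProfile]) -> np.ndarray:
    return np.vstack([p.vector() for p in profiles])


def _profile_correlations(vectors: np.ndarray) -> np.ndarray:
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    return np.clip(unit @ unit.T, -1.0, 1.0)


def neighbor_dbd_enrichment(
    dictionary: MotifDictionary,
    profiles: list[KmerProfile],
    motif_id: str,
    fraction: float = 0.10,
) -> list[NeighborEnrichment]:
    """Fisher's exact enrichment of DBD categories among a motif's nearest
    neighbors (top ``fraction`` of the dictionary by profile correlation).

    Neighbor count is ceil(fraction * len(dictionary)); correlation ties at
    the cutoff are broken by motif_id.
    """
    order = {p.motif_id: i for i, p in enumerate(profiles)}
    if set(order) != set(dictionary.motif_ids):
        raise ValueError("profiles must cover exactly the dictionary motifs")
    query = order[motif_id]
    corr = _profile_correlations(profile_matrix(profiles))[query]

    others = [p.motif_id for p in profiles if p.motif_id != motif_id]
    n_neighbors = math.ceil(fraction * len(dictionary))
    ranked = sorted(others, key=lambda mid: (-corr[order[mid]], mid))
    neighbors = set(ranked[:n_neighbors])

    results = []
    for level in ("superfamily", "class"):
        annot = {
            rec.motif_id: (
                rec.dbd_superfamily if level == "superfamily" else rec.dbd_class
            )
            for rec in dictionary.records
        }
        categories = sorted({c for c in annot.values() if c})
        for category in categories:
            in_cat = {mid for mid in others if annot.get(mid) == category}
            a = len(neighbors & in_cat)
            b = len(in_cat) - a
            c = n_neighbors - a
            d = len(others) - len(in_cat) - c
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            results.append(
                NeighborEnrichment(
                    motif_id=motif_id,
                    category=category,
                    level=level,
                    neighbor_fraction=fraction,
                    n_neighbors=n_neighbors,
                    fisher_p=float(p),
                )
            )
    return results


def _split_silhouette(dist: np.ndarray, members: np.ndarray) -> float:
    """Median silhouette of a cluster's own two-way split (low = homogeneous).

    Clusters too small to split score 1.0, which penalizes fragmentation when
    choosing the number of groups.
    """
    if len(members) < 3:
        return 1.0
    sub = dist[np.ix_(members, members)]
    sub_linkage = hierarchy.linkage(squareform(sub, checks=False), method="average")
    labels = hierarchy.fcluster(sub_linkage, t=2, criterion="maxclust")
    if len(set(labels)) < 2:
        return 0.0
    sil = []
    for i in range(len(members)):
        own = labels == labels[i]
        own[i] = False
        other = labels != labels[i]
        a = sub[i, own].mean() if own.any() else 0.0
        b = sub[i, other].mean()
        denom = max(a, b)
        sil.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.median(sil))


def cluster_motifs(
    profiles: list[KmerProfile],
    seed: int = 0,
    max_groups: int = 10,
    mss_tolerance: float = 0.10,
) -> tuple[dict[str, int], dict[int, str]]:
    """Partition motifs by k-mer profile similarity and name each branch by
    its most discriminative word.

    Hierarchical (average-linkage) clustering on correlation distance; the
    number of top-level groups is the smallest k in 2..``max_groups`` whose
    median split silhouette is within ``mss_tolerance`` of the minimum.
    Returns (motif_id -> group, group -> discriminative k-mer).  The
    discriminative word minimizes the one-sided rank-sum p-value comparing
    in-branch vs out-of-branch scores.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    del seed  # deterministic; accepted for interface stability

    vectors = profile_matrix(profiles)
    corr = _profile_correlations(vectors)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0

    if dist.max() < 1e-12:
        assignment = {p.motif_id: 1 for p in profiles}
        return assignment, {1: _branch_kmer(vectors, np.ones(len(profiles), bool))}

    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    candidates = range(2, min(max_groups, len(profiles) - 1) + 1)
    mss_by_k = {}
    labels_by_k = {}
    for k in candidates:
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        per_cluster = [
            _split_silhouette(dist, np.nonzero(labels == g)[0])
            for g in np.unique(labels)
        ]
        mss_by_k[k] = float(np.median(per_cluster))
    best = min(mss_by_k.values())
    chosen = next(k for k in candidates if mss_by_k[k] <= best + mss_tolerance)
    labels = labels_by_k[chosen]

    assignment = {p.motif_id: int(g) for p, g in zip(profiles, labels)}
    branch_words = {
        int(g): _branch_kmer(vectors, labels == g) for g in np.unique(labels)
    }
    return assignment, branch_words


def _branch_kmer(vectors: np.ndarray, in_branch: np.ndarray) -> str:
    """Word whose scores are most significantly elevated within the branch."""
    out = ~in_branch
    if not out.any():
        # single group: fall back to the word with the highest mean score
        return ALL_WORDS[int(np.argmax(vectors.mean(axis=0)))]
    best_word, best_key = None, None
    for j, word in enumerate(ALL_WORDS):
        x, y = vectors[in_branch, j], vectors[out, j]
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="greater").pvalue)
        key = (p, -float(x.mean()), word)
        if best_key is None or key < best_key:
            best_word, best_key = word, key
    return best_word
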