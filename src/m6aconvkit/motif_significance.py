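"""Potential-motif identification and per-feature significance analysis.

A position of a length-L sequence is *active* when its attention value is
strictly greater than the neutral value 1/L (a uniform attention
distribution marks nothing). Maximal runs of active positions form
*active regions*; k-mers occurring inside sufficiently long regions are
aggregated over positive sequences, and the fraction of positives in
which a k-mer is active at least once is its *active occurrence*.

Feature significance summarises, per class, how often each branch of the
trained classifier emits a low / medium / high confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from m6aconvkit.network.models import (
    AttentionClassifier,
    FourBranchClassifier,
    attention_profile,
    feature_confidences,
)
from m6aconvkit.sequence_features import FEATURE_ORDER, DnaSequence, FeatureBundle, stack_bundles


@dataclass(frozen=True)
class ActiveRegion:
    """A maximal run of active positions; start/end are 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    subsequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MotifRecord:
    motif: str
    active_occurrence_pct: float
    support: int


def active_mask(s_vector: np.ndarray) -> np.ndarray:
    """Boolean mask of positions with attention strictly above 1/L."""
    s = np.asarray(s_vector, dtype=np.float64)
    if s.ndim != 1:
        raise ValueError("attention vector must be 1-D")
    if (s < -1e-9).any() or abs(s.sum() - 1.0) > 1e-6:
        raise ValueError("attention vector must be a probability distribution")
    return s > 1.0 / len(s)


def active_regions(seq: DnaSequence | str, mask: np.ndarray) -> list[ActiveRegion]:
    """Maximal runs of consecutive active positions, left to right."""
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    seq_id = seq.id if isinstance(seq, DnaSequence) else "<anonymous>"
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(bases):
        raise ValueError(f"mask length {len(mask)} != sequence length {len(bases)}")
    regions: list[ActiveRegion] = []
    start: int | None = None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append(
                ActiveRegion(
                    sequence_id=seq_id,
                    start=start + 1,
                    end=i,
                    subsequence=bases[start:i],
                )
            )
            start = None
    return regions


def aggregate_motifs(
    sequences: Sequence[DnaSequence],
    masks: Sequence[np.ndarray],
    k: int = 4,
    min_region_len: int | None = None,
) -> list[MotifRecord]:
    """Rank k-mers by the percentage of sequences whose active regions contain them.

    Each sequence contributes at most once to a k-mer's support,
    however many times the k-mer recurs. Ranking is by active
    occurrence descending, ties broken lexicographically.
    """
    if not sequences:
        raise ValueError("no sequences to aggregate")
    lengths = {len(s) for s in sequences}
    if k > min(lengths):
        raise ValueError(f"k={k} exceeds sequence length {min(lengths)}")
    if min_region_len is None:
        min_region_len = k
    support: dict[str, int] = {}
    for seq, mask in zip(sequences, masks, strict=True):
        kmers: set[str] = set()
        for region in active_regions(seq, mask):
            if len(region) < min_region_len:
                continue
            sub = region.subsequence
            kmers.update(sub[j : j + k] for j in range(len(sub) - k + 1))
        for kmer in kmers:
            support[kmer] = support.get(kmer, 0) + 1
    n = len(sequences)
    records = [
        MotifRecord(motif=m, active_occurrence_pct=100.0 * c / n, support=c)
        for m, c in support.items()
    ]
    records.sort(key=lambda r: (-r.active_occurrence_pct, r.motif))
    return records


def extract_motifs(
    model: AttentionClassifier,
    sequences: Sequence[DnaSequence],
    bundles: Sequence[FeatureBundle],
    k: int = 4,
    min_region_len: int | None = None,
    batch_size: int = 256,
) -> list[MotifRecord]:
    """Run the trained attention model over positive sequences and rank motifs."""
    if not sequences:
        raise ValueError("no positive sequences provided")
    if len(sequences) != len(bundles):
        raise ValueError("sequences and bundles must align")
    masks: list[np.ndarray] = []
    for start in range(0, len(bundles), batch_size):
        X = stack_bundles(bundles[start : start + batch_size])
        for s in attention_profile(model, X):
            masks.append(active_mask(s))
    return aggregate_motifs(sequences, masks, k=k, min_region_len=min_region_len)


@dataclass(frozen=True)
class SignificanceHistogram:
    """Per class and per feature: % of samples with confidence in each bin."""

    bin_edges: tuple[float, ...]
    bin_names: tuple[str, ...]
    #: percentages[class_label][feature] -> array of per-bin percentages
    percentages: dict[int, dict[str, np.ndarray]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, by_feature in sorted(self.percentages.items()):
            for feature, pcts in by_feature.items():
                rows.append(
                    {"class": label, "feature": feature}
                    | {name: pct for name, pct in zip(self.bin_names, pcts)}
                )
        return pd.DataFrame(rows)


_DEFAULT_BINS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
_DEFAULT_BIN_NAMES = ("low", "medium", "high")


def significance_histogram(
    model: FourBranchClassifier,
    X: Mapping[str, np.ndarray],
    labels: np.ndarray,
    bin_edges: Sequence[float] = _DEFAULT_BINS,
    bin_names: Sequence[str] | None = None,
) -> SignificanceHistogram:
    """Histogram the confidence vector per feature and class.

    ``bin_edges`` must partition [0, 1]; the default tertile bins are
    low [0, 1/3), medium [1/3, 2/3), high [2/3, 1].
    """
    conf = feature_confidences(model, X)  # (n, 4)
    return histogram_from_confidences(conf, labels, bin_edges=bin_edges, bin_names=bin_names)


def histogram_from_confidences(
    confidences: np.ndarray,
    labels: np.ndarray,
    bin_edges: Sequence[float] = _DEFAULT_BINS,
    bin_names: Sequence[str] | None = None,
) -> SignificanceHistogram:
    """Bin pre-computed confidence vectors (n, 4) per class and feature."""
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) < 2 or edges[0] != 0.0 or edges[-1] != 1.0 or list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must strictly increase from 0 to 1")
    if bin_names is None:
        bin_names = (
            _DEFAULT_BIN_NAMES
            if len(edges) == 4
            else tuple(f"bin{i}" for i in range(len(edges) - 1))
        )
    if len(bin_names) != len(edges) - 1:
        raise ValueError("need one name per bin")
    y = np.asarray(labels)
    conf = np.asarray(confidences, dtype=np.float64)
    if conf.ndim != 2 or conf.shape[1] != len(FEATURE_ORDER):
        raise ValueError("confidences must have shape (n, 4)")
    if len(y) != conf.shape[0]:
        raise ValueError("labels and inputs disagree on sample count")
    percentages: dict[int, dict[str, np.ndarray]] = {}
    for label in (0, 1):
        class_conf = conf[y == label]
        if class_conf.shape[0] == 0:
            continue
        by_feature: dict[str, np.ndarray] = {}
        for j, feature in enumerate(FEATURE_ORDER):
            # right-open bins except the last, which includes 1.0
            idx = np.minimum(
                np.digitize(class_conf[:, j], edges[1:], right=False), len(edges) - 2
            )
            counts = np.bincount(idx, minlength=len(edges) - 1)
            by_feature[feature] = 100.0 * counts / class_conf.shape[0]
        percentages[label] = by_feature
    return SignificanceHistogram(
        bin_edges=edges, bin_names=tuple(bin_names), percentages=percentages
    )
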