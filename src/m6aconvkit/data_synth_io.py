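"""Synthetic labeled-sequence and property-table generation, plus FASTA/CSV I/O.

The generator emulates the statistical structure of the 6mA benchmark:
fixed-length windows with an adenine at the center, a class-discriminating
motif planted at configurable per-class rates, and a decoy motif whose
containment frequency is matched between classes so that it cannot leak a
trivial signal (mirroring the dataset rule that the GAGG-motif rate of the
positive class — about 17% — is replicated in the negative class).

Motif containment is exact: a sequence contains a motif if and only if the
generator decided it should, so rate parameters are verifiable by plain
string search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from m6aconvkit.sequence_features import DIMER_ORDER, MONOMER_ORDER, DnaSequence, DppTable


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic labeled-sequence generator."""

    n_pos: int
    n_neg: int
    length: int = 41
    planted_motif: str = "TCGT"
    motif_rate_pos: float = 0.8
    motif_rate_neg: float = 0.0
    #: Background composition over (A, T, C, G).
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    decoy_motif: str = "GAGG"
    decoy_rate: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if self.length < 3 or self.length % 2 == 0:
            raise ValueError("length must be an odd integer >= 3 (center base reserved)")
        if abs(sum(self.background) - 1.0) > 1e-9 or any(p < 0 for p in self.background):
            raise ValueError("background composition must be non-negative and sum to 1")
        for rate in (self.motif_rate_pos, self.motif_rate_neg, self.decoy_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("motif rates must lie in [0, 1]")
        for motif in (self.planted_motif, self.decoy_motif):
            if not motif or any(c not in MONOMER_ORDER for c in motif.upper()):
                raise ValueError(f"motif {motif!r} must be a non-empty A/C/G/T string")
            if len(motif) >= self.length:
                raise ValueError(f"motif {motif!r} does not fit in length {self.length}")
        a, b = self.planted_motif.upper(), self.decoy_motif.upper()
        if a in b or b in a:
            raise ValueError("planted motif and decoy motif must not contain one another")
        object.__setattr__(self, "planted_motif", a)
        object.__setattr__(self, "decoy_motif", b)


def generate_dataset(cfg: SynthConfig) -> list[DnaSequence]:
    """Draw ``n_pos`` positive and ``n_neg`` negative sequences under ``cfg``.

    Every sequence has length ``cfg.length`` with 'A' at the center.
    Planted and decoy motifs are inserted at random offsets that never
    overlap the center or each other; background draws are rejected
    until each sequence's motif containment matches its Bernoulli draw
    exactly. Fully deterministic given ``cfg`` (including the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[DnaSequence] = []
    for label, count, rate in (
        (1, cfg.n_pos, cfg.motif_rate_pos),
        (0, cfg.n_neg, cfg.motif_rate_neg),
    ):
        tag = "pos" if label else "neg"
        for i in range(count):
            want_planted = rng.random() < rate
            want_decoy = rng.random() < cfg.decoy_rate
            bases = _draw_sequence(rng, cfg, want_planted, want_decoy)
            out.append(DnaSequence(id=f"{tag}_{i:05d}", bases=bases, label=label))
    return out


def _draw_sequence(
    rng: np.random.Generator, cfg: SynthConfig, want_planted: bool, want_decoy: bool
) -> str:
    alphabet = np.frombuffer(MONOMER_ORDER.encode(), dtype=np.uint8)
    center = (cfg.length - 1) // 2
    for _ in range(10_000):
        arr = rng.choice(alphabet, size=cfg.length, p=list(cfg.background))
        arr[center] = ord("A")
        spans: list[tuple[int, int]] = [(center, center + 1)]
        ok = True
        for motif, wanted in ((cfg.planted_motif, want_planted), (cfg.decoy_motif, want_decoy)):
            if not wanted:
                continue
            offset = _pick_offset(rng, cfg.length, len(motif), spans)
            if offset is None:
                ok = False
                break
            arr[offset : offset + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
            spans.append((offset, offset + len(motif)))
        if not ok:
            continue
        seq = arr.tobytes().decode()
        if (cfg.planted_motif in seq) == want_planted and (cfg.decoy_motif in seq) == want_decoy:
            return seq
    raise RuntimeError("could not satisfy motif-containment constraints; motifs too dense for L")


def _pick_offset(
    rng: np.random.Generator, length: int, k: int, occupied: list[tuple[int, int]]
) -> int | None:
    candidates = [
        off
        for off in range(length - k + 1)
        if all(off + k <= lo or off >= hi for lo, hi in occupied)
    ]
    if not candidates:
        return None
    return int(rng.choice(candidates))


def generate_dpp_table(
    n_properties: int = 90,
    seed: int = 0,
    n_informative: int = 0,
    n_clones: int = 0,
    signal_dimers: tuple[str, str] = ("AA", "TT"),
    signal_gap: float = 6.0,
    clone_noise: float = 0.05,
) -> DppTable:
    """Seeded random stand-in for the 90-property dinucleotide table.

    With the default arguments every property is an i.i.d. standard
    normal 16-vector. Structure can be planted for selection tests:

    * the first ``n_informative`` properties discriminate the two
      ``signal_dimers`` by ``±signal_gap/2`` (alternating sign), making
      them informative for any dataset whose classes differ in those
      dimers, while remaining mutually correlated well below 0.9;
    * the next ``n_clones`` properties are near-copies of property 0
      (alternating duplicate/negation with ``clone_noise`` jitter),
      i.e. informative but |r| > 0.9 with the topmost property;
    * all remaining properties carry identical values at the two signal
      dimers and therefore no class signal.
    """
    if n_properties < 1:
        raise ValueError("n_properties must be >= 1")
    if n_informative + n_clones > n_properties:
        raise ValueError("planted structure exceeds n_properties")
    rng = np.random.default_rng(seed)
    d0, d1 = (DIMER_ORDER.index(d) for d in signal_dimers)
    raw = rng.standard_normal((n_properties, 16))
    for j in range(n_informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        raw[j, d0] = sign * signal_gap / 2.0
        raw[j, d1] = -sign * signal_gap / 2.0
    # keep the informative set mutually near-orthogonal (|r| well below the
    # 0.9 pruning threshold) by redrawing the non-signal entries on collision
    free = [i for i in range(16) if i not in (d0, d1)]
    for j in range(1, n_informative):
        for _ in range(1000):
            r_max = max(
                abs(np.corrcoef(raw[j], raw[i])[0, 1]) for i in range(j)
            )
            if r_max <= 0.8:
                break
            raw[j, free] = rng.standard_normal(len(free))
        else:
            raise RuntimeError("could not decorrelate informative properties")
    for j in range(n_informative, n_informative + n_clones):
        sign = 1.0 if (j - n_informative) % 2 == 0 else -1.0
        raw[j] = sign * raw[0] + clone_noise * rng.standard_normal(16)
    for j in range(n_informative + n_clones, n_properties):
        shared = (raw[j, d0] + raw[j, d1]) / 2.0
        raw[j, d0] = raw[j, d1] = shared
    names = tuple(f"P{j + 1:03d}" for j in range(n_properties))
    return DppTable(names=names, raw=raw)


def generate_dimer_signal_dataset(
    n_per_class: int,
    length: int = 41,
    pos_prefix: str = "AAAAA",
    neg_prefix: str = "TTTTT",
    seed: int = 0,
) -> list[DnaSequence]:
    """Dataset whose classes differ only in a fixed dimer-bearing prefix.

    Positives start with ``pos_prefix`` and negatives with
    ``neg_prefix``; the remainder is uniform random with the center
    fixed to 'A'. Used to make specific dinucleotides (and hence
    specific physicochemical properties) class-discriminating at known
    positions.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(MONOMER_ORDER.encode(), dtype=np.uint8)
    center = (length - 1) // 2
    if max(len(pos_prefix), len(neg_prefix)) > center:
        raise ValueError("prefix may not reach the center position")
    out: list[DnaSequence] = []
    for label, prefix, tag in ((1, pos_prefix, "pos"), (0, neg_prefix, "neg")):
        for i in range(n_per_class):
            arr = rng.choice(alphabet, size=length)
            arr[: len(prefix)] = np.frombuffer(prefix.upper().encode(), dtype=np.uint8)
            arr[center] = ord("A")
            out.append(DnaSequence(id=f"{tag}_{i:05d}", bases=arr.tobytes().decode(), label=label))
    return out


# ---------------------------------------------------------------------------
# FASTA and CSV I/O
# ---------------------------------------------------------------------------


class FastaFormatError(ValueError):
    """Raised for structurally malformed FASTA input."""


def read_fasta(path: str | Path, expected_length: int | None = None) -> list[DnaSequence]:
    """Parse a (possibly line-wrapped, CRLF-tolerant) FASTA file.

    A ``label=0|1`` token in the record description becomes the
    sequence label. ``expected_length`` rejects records of any other
    length, naming the offending id.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    out: list[DnaSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        label = _label_from_description(record.description)
        seq = DnaSequence(id=record.id, bases=str(record.seq), label=label)
        if expected_length is not None and len(seq) != expected_length:
            raise ValueError(
                f"record {record.id!r}: length {len(seq)} != expected {expected_length}"
            )
        out.append(seq)
    return out


def _validate_fasta_structure(path: Path) -> None:
    previous_header_line: int | None = None
    seen_sequence = False
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\r\n")
            if not stripped:
                continue
            if stripped.startswith(">"):
                if previous_header_line is not None and not seen_sequence:
                    raise FastaFormatError(
                        f"{path}:{previous_header_line}: record has no sequence lines"
                    )
                previous_header_line = lineno
                seen_sequence = False
            else:
                if previous_header_line is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                seen_sequence = True
    if previous_header_line is not None and not seen_sequence:
        raise FastaFormatError(f"{path}:{previous_header_line}: record has no sequence lines")


def _label_from_description(description: str) -> int | None:
    for token in description.split():
        if token.startswith("label="):
            value = token[len("label=") :]
            if value not in ("0", "1"):
                raise ValueError(f"bad label token {token!r} (expected label=0 or label=1)")
            return int(value)
    return None


def write_fasta(path: str | Path, sequences: Iterable[DnaSequence], wrap: int = 60) -> None:
    """Write sequences to FASTA; labels are stored as ``label=`` description tokens."""
    records = []
    for seq in sequences:
        description = f"label={seq.label}" if seq.label is not None else ""
        records.append(SeqRecord(Seq(seq.bases), id=seq.id, description=description))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(records)


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction row: id, probability and the strict-threshold label."""

    id: str
    probability: float
    label: int = field(default=-1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        expected = int(self.probability > 0.5)
        if self.label == -1:
            object.__setattr__(self, "label", expected)
        elif self.label != expected:
            raise ValueError(
                f"label {self.label} inconsistent with probability {self.probability} "
                "under the strict > 0.5 threshold"
            )


def write_predictions(path: str | Path, records: Sequence[PredictionRecord]) -> None:
    """Write predictions as CSV with columns (id, probability, label)."""
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "probability": [r.probability for r in records],
            "label": [r.label for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    frame = pd.read_csv(path)
    return [
        PredictionRecord(id=str(row.id), probability=float(row.probability), label=int(row.label))
        for row in frame.itertuples(index=False)
    ]


def write_dpp_table(path: str | Path, table: DppTable) -> None:
    """Write a property table as TSV readable by :func:`load_dpp_table`."""
    frame = pd.DataFrame(table.raw, index=list(table.names), columns=list(DIMER_ORDER))
    frame.index.name = "property"
    frame.to_csv(path, sep="\t")


def labels_array(sequences: Sequence[DnaSequence]) -> np.ndarray:
    """Collect labels into an int array; raises if any sequence is unlabeled."""
    labels = []
    for seq in sequences:
        if seq.label is None:
            raise ValueError(f"sequence {seq.id!r} has no label")
        labels.append(seq.label)
    return np.asarray(labels, dtype=np.int64)
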