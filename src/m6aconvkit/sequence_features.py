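"""Deterministic feature encodings for fixed-length DNA windows.

Four representations are produced per sequence:

* monomer one-hot, shape ``(L, 4)``, column order A, T, C, G;
* overlapping-dimer one-hot, shape ``(L - 1, 16)``;
* dinucleotide physicochemical property (DPP) matrix, shape
  ``(L - 1, k)`` for ``k`` selected Z-normalised properties;
* a four-column matrix of ring-structure, functional-group and
  hydrogen-bonding codes plus the lingering density of each position.

The 16-dimer column ordering is lexicographic over the nucleotide order
(A, T, C, G) and is shared by the dimer one-hot encoder and the DPP
table so the two representations index dimers identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed column order of the monomer one-hot encoding.
MONOMER_ORDER: str = "ATCG"

#: Fixed column order of the dimer one-hot encoding and of DPP tables —
#: lexicographic over the nucleotide order (A, T, C, G).
DIMER_ORDER: tuple[str, ...] = tuple(a + b for a in MONOMER_ORDER for b in MONOMER_ORDER)

_MONO_INDEX = {base: i for i, base in enumerate(MONOMER_ORDER)}
_DIMER_INDEX = {dimer: i for i, dimer in enumerate(DIMER_ORDER)}

# Ring structure (purine=1), functional group (amino=1), hydrogen bonding
# (strong=1) codes per nucleotide.
_PSE_CODES = {
    "A": (1, 1, 0),
    "C": (0, 1, 1),
    "G": (1, 0, 1),
    "T": (0, 0, 0),
}


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded."""


@dataclass(frozen=True)
class DnaSequence:
    """A fixed-length DNA string over {A, C, G, T} with an optional binary label.

    Parameters
    ----------
    id : str
        Record identifier.
    bases : str
        The sequence; lower-case input is upper-cased, any character
        outside A/C/G/T (including U and IUPAC ambiguity codes) is
        rejected.
    label : int or None
        1 for a methylated (6mA) site, 0 for unmethylated, None if
        unknown.
    """

    id: str
    bases: str
    label: int | None = None

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        for pos, char in enumerate(bases):
            if char not in _MONO_INDEX:
                raise EncodingError(
                    f"sequence {self.id!r}: invalid character {char!r} at "
                    f"position {pos + 1} (only A/C/G/T allowed)"
                )
        object.__setattr__(self, "bases", bases)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"sequence {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def center_base(self) -> str:
        """Base at the center position ⌈L/2⌉ (1-based; 21 for L = 41)."""
        return self.bases[(len(self.bases) + 1) // 2 - 1]

    def require_center_adenine(self) -> None:
        """Raise unless the center base is adenine (candidate-site invariant)."""
        if self.center_base != "A":
            raise EncodingError(
                f"sequence {self.id!r}: center base is {self.center_base!r}, expected 'A'"
            )


def encode_monomer(seq: DnaSequence | str) -> np.ndarray:
    """One-hot encode each nucleotide; returns an ``(L, 4)`` matrix.

    Column order is A, T, C, G (:data:`MONOMER_ORDER`).
    """
    bases = _as_bases(seq)
    out = np.zeros((len(bases), 4), dtype=np.float64)
    for i, base in enumerate(bases):
        out[i, _MONO_INDEX[base]] = 1.0
    return out


def encode_dimer(seq: DnaSequence | str) -> np.ndarray:
    """One-hot encode the L−1 overlapping dimers; returns ``(L−1, 16)``.

    Row ``t`` encodes the dimer (N_t, N_{t+1}); columns follow
    :data:`DIMER_ORDER`.
    """
    bases = _as_bases(seq)
    if len(bases) < 2:
        raise EncodingError("dimer encoding requires a sequence of length >= 2")
    out = np.zeros((len(bases) - 1, 16), dtype=np.float64)
    for t in range(len(bases) - 1):
        out[t, _DIMER_INDEX[bases[t : t + 2]]] = 1.0
    return out


def lingering_density(seq: DnaSequence | str, i: int) -> float:
    """Frequency of the nucleotide at 1-based position ``i`` within the prefix N_1..N_i.

    Always 1.0 at ``i == 1``; lies in (0, 1] everywhere.
    """
    bases = _as_bases(seq)
    if not 1 <= i <= len(bases):
        raise EncodingError(f"position {i} out of range 1..{len(bases)}")
    prefix = bases[:i]
    return prefix.count(bases[i - 1]) / i


def encode_pse(seq: DnaSequence | str) -> np.ndarray:
    """Four-column matrix of categorical codes plus lingering density, shape ``(L, 4)``.

    Columns 1–3 are the ring-structure, functional-group and
    hydrogen-bonding codes (A→110, C→011, G→101, T→000); column 4 is
    the lingering density of the position.
    """
    bases = _as_bases(seq)
    out = np.empty((len(bases), 4), dtype=np.float64)
    counts = {base: 0 for base in MONOMER_ORDER}
    for i, base in enumerate(bases):
        counts[base] += 1
        out[i, :3] = _PSE_CODES[base]
        out[i, 3] = counts[base] / (i + 1)
    return out


@dataclass(frozen=True)
class DppTable:
    """Named dinucleotide physicochemical properties, raw and Z-normalised.

    ``raw`` and ``znorm`` are ``(n_properties, 16)`` arrays whose columns
    follow :data:`DIMER_ORDER`. ``znorm`` is None until
    :func:`znorm_dpp` is applied.
    """

    names: tuple[str, ...]
    raw: np.ndarray
    znorm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=np.float64)
        if raw.shape != (len(self.names), 16):
            raise ValueError(
                f"raw values must have shape ({len(self.names)}, 16), got {raw.shape}"
            )
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate property names: {dupes}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "raw", raw)

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown property {name!r}") from None

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        values = self.znorm if normalized else self.raw
        if values is None:
            raise ValueError("table has no Z-normalised values; call znorm_dpp first")
        return pd.DataFrame(values, index=list(self.names), columns=list(DIMER_ORDER))


def load_dpp_table(path: str | Path) -> DppTable:
    """Read a property table from TSV: first column names, 16 dimer columns.

    The dimer columns may appear in any order; they are reindexed to
    :data:`DIMER_ORDER`. Missing or extra dimer columns, non-numeric
    cells and duplicate property names are parse errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    have = set(frame.columns)
    want = set(DIMER_ORDER)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise ValueError(
            f"{path}: expected exactly the 16 dimer columns; "
            f"missing={missing or None} unexpected={extra or None}"
        )
    frame = frame[list(DIMER_ORDER)]
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate property names: {dupes}")
    for col in frame.columns:
        bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad.index[0]!r}"
            )
    return DppTable(names=tuple(str(n) for n in frame.index), raw=frame.to_numpy(float))


def znorm_dpp(table: DppTable) -> DppTable:
    """Z-score each property over its 16 dimer values (population sd).

    A constant property would divide by zero; it is mapped to an
    all-zero vector with a warning, making it self-evidently
    uninformative downstream.
    """
    mean = table.raw.mean(axis=1, keepdims=True)
    sd = table.raw.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    if constant.any():
        names = [table.names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant DPP values mapped to all-zero Z-scores: {names}")
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    znorm = (table.raw - mean) / safe_sd
    znorm[constant] = 0.0
    return DppTable(names=table.names, raw=table.raw, znorm=znorm)


def encode_dpp(
    seq: DnaSequence | str,
    table: DppTable,
    selected: Sequence[str] | None = None,
) -> np.ndarray:
    """DPP matrix of shape ``(L−1, k)``: Z-normalised property values per dimer.

    ``selected`` restricts and orders the property columns; None uses
    every property in table order. The table is Z-normalised on the fly
    if needed.
    """
    bases = _as_bases(seq)
    if len(bases) < 2:
        raise EncodingError("DPP encoding requires a sequence of length >= 2")
    if table.znorm is None:
        table = znorm_dpp(table)
    names = tuple(selected) if selected is not None else table.names
    unknown = [n for n in names if n not in table.names]
    if unknown:
        raise KeyError(f"unknown DPP properties: {unknown}")
    rows = [table.index_of(n) for n in names]
    dimer_idx = [_DIMER_INDEX[bases[t : t + 2]] for t in range(len(bases) - 1)]
    # znorm is (properties, dimers); result row t = values of the selected
    # properties at dimer (N_t, N_{t+1}).
    return table.znorm[np.ix_(rows, dimer_idx)].T.copy()


@dataclass(frozen=True)
class FeatureBundle:
    """The four feature matrices of one sequence, as fed to the four branches."""

    monomer: np.ndarray  # (L, 4)
    dimer: np.ndarray  # (L-1, 16)
    dpp: np.ndarray  # (L-1, k)
    pse: np.ndarray  # (L, 4)

    def __post_init__(self) -> None:
        L = self.monomer.shape[0]
        ok = (
            self.monomer.shape == (L, 4)
            and self.pse.shape == (L, 4)
            and self.dimer.shape[0] == L - 1
            and self.dimer.shape[1] == 16
            and self.dpp.shape[0] == L - 1
        )
        if not ok:
            raise ValueError(
                "inconsistent bundle shapes: "
                f"monomer {self.monomer.shape}, dimer {self.dimer.shape}, "
                f"dpp {self.dpp.shape}, pse {self.pse.shape}"
            )

    @property
    def length(self) -> int:
        return self.monomer.shape[0]


#: Fixed branch order used throughout training, prediction and reporting.
FEATURE_ORDER: tuple[str, ...] = ("monomer", "dimer", "dpp", "pse")


def encode_bundle(
    seq: DnaSequence | str,
    table: DppTable,
    selected: Sequence[str] | None = None,
) -> FeatureBundle:
    """Encode one sequence into all four feature matrices."""
    return FeatureBundle(
        monomer=encode_monomer(seq),
        dimer=encode_dimer(seq),
        dpp=encode_dpp(seq, table, selected),
        pse=encode_pse(seq),
    )


def stack_bundles(bundles: Sequence[FeatureBundle]) -> dict[str, np.ndarray]:
    """Stack per-sequence bundles into batched ``(n, T, C)`` arrays keyed by branch."""
    if not bundles:
        raise ValueError("no bundles to stack")
    return {name: np.stack([getattr(b, name) for b in bundles]) for name in FEATURE_ORDER}


_BUNDLE_FORMAT_VERSION = 1


def save_bundles(path: str | Path, bundles: Sequence[FeatureBundle]) -> None:
    """Cache encoded bundles in a versioned ``.npz`` container."""
    arrays = stack_bundles(bundles)
    np.savez(path, version=np.int64(_BUNDLE_FORMAT_VERSION), **arrays)


def load_bundles(path: str | Path) -> list[FeatureBundle]:
    """Load bundles written by :func:`save_bundles`."""
    with np.load(path) as data:
        if int(data["version"]) != _BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported bundle container version {int(data['version'])}")
        arrays = {name: data[name] for name in FEATURE_ORDER}
    n = arrays["monomer"].shape[0]
    return [
        FeatureBundle(**{name: arrays[name][i] for name in FEATURE_ORDER}) for i in range(n)
    ]


def _as_bases(seq: DnaSequence | str) -> str:
    if isinstance(seq, DnaSequence):
        return seq.bases
    return DnaSequence(id="<anonymous>", bases=seq).bases
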