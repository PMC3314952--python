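"""Protein sequences and per-residue property tables.

The analyses in this package are driven by three sequence-level inputs: the
amino-acid sequence itself (with wild-type numbering, so that an expression tag
can carry indices below the first native residue), a per-residue property table
(side-chain radius of gyration, persistence class for segmental motion, and the
average area buried upon folding, AABUF), and the residue intervals of the four
native helices used to summarise per-region structure propensities.

Numbering convention: residue ``k`` (1-based position in the stored string) has
index ``first_index + k - 1``. A construct with an N-terminal tag of length ``t``
is loaded with ``first_index = 1 - t`` so that tag residues carry indices <= 0
and the native part keeps its wild-type numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .errors import PropertyTableError, RegionError, SequenceError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Native helix intervals (inclusive, wild-type numbering) of Im7.
DEFAULT_HELIX_REGIONS: dict[str, tuple[int, int]] = {
    "I": (12, 25),
    "II": (31, 45),
    "III": (51, 56),
    "IV": (65, 79),
}

#: Raw side-chain radius of gyration of proline and the override applied at table
#: construction: ring closure restricts conformational space, which the intrinsic
#: relaxation model absorbs by raising Rg from 1.25 to 2.0 A.
PROLINE_RG_RAW = 1.25
PROLINE_RG_OVERRIDE = 2.0


@dataclass(frozen=True)
class ProteinSequence:
    """An ordered amino-acid sequence with wild-type-style numbering.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        One-letter codes, all from the 20-residue alphabet.
    first_index : int
        Wild-type number of the first stored residue (may be <= 0 for tagged
        constructs).
    tag_length : int
        Number of non-native N-terminal residues included in ``residues``.
    """

    id: str
    residues: str
    first_index: int = 1
    tag_length: int = 0

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for k, aa in enumerate(self.residues):
            if aa not in AMINO_ACIDS:
                raise SequenceError(
                    f"illegal residue code {aa!r} at position {k + 1} "
                    f"of sequence {self.id!r}"
                )
        if self.tag_length < 0:
            raise SequenceError("tag_length must be >= 0")
        if self.tag_length >= len(self.residues):
            raise SequenceError("tag_length must leave at least one native residue")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    @property
    def indices(self) -> np.ndarray:
        """Wild-type residue numbers, one per stored residue."""
        return np.arange(self.first_index, self.first_index + len(self.residues))

    def residue_at(self, index: int) -> str:
        """One-letter code of the residue with wild-type number ``index``."""
        k = index - self.first_index
        if not 0 <= k < len(self.residues):
            raise SequenceError(f"residue index {index} outside sequence {self.id!r}")
        return self.residues[k]

    def substituted(self, substitutions: Mapping[int, str], id: str | None = None
                    ) -> "ProteinSequence":
        """Return a copy with point substitutions ``{wild-type index: new residue}``."""
        chars = list(self.residues)
        for index, aa in substitutions.items():
            k = index - self.first_index
            if not 0 <= k < len(chars):
                raise SequenceError(f"substitution index {index} outside sequence")
            chars[k] = aa
        return ProteinSequence(
            id=id or f"{self.id}_variant",
            residues="".join(chars),
            first_index=self.first_index,
            tag_length=self.tag_length,
        )


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Per-residue-type properties: side-chain Rg (A), persistence length
    (residues) and AABUF (A^2).

    The table is total over the 20 amino acids; lookups never fail for a valid
    sequence. The proline Rg override is applied once, at construction, so that
    re-loading the same file is idempotent.
    """

    rg: Mapping[str, float]
    lam: Mapping[str, float]
    aabuf: Mapping[str, float]
    label: str = "packaged"

    def __post_init__(self) -> None:
        for table, name in ((self.rg, "rg"), (self.lam, "lambda"),
                            (self.aabuf, "aabuf")):
            missing = [aa for aa in AMINO_ACIDS if aa not in table]
            if missing:
                raise PropertyTableError(
                    f"{name} table missing residue types: {''.join(missing)}")
        if any(v <= 0 for v in self.rg.values()):
            raise PropertyTableError("all rg values must be positive")

    @classmethod
    def from_tsv(cls, path, proline_override: bool = True,
                 label: str | None = None) -> "ResiduePropertyTable":
        """Load a ``residue / rg_A / lambda / aabuf`` TSV (``#`` lines ignored)."""
        rg: dict[str, float] = {}
        lam: dict[str, float] = {}
        aabuf: dict[str, float] = {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("residue"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise PropertyTableError(f"malformed property row: {line!r}")
                aa = fields[0]
                rg[aa] = float(fields[1])
                lam[aa] = float(fields[2])
                aabuf[aa] = float(fields[3])
        if proline_override and "P" in rg:
            rg["P"] = PROLINE_RG_OVERRIDE
        return cls(rg=rg, lam=lam, aabuf=aabuf, label=label or str(path))

    @classmethod
    def default(cls) -> "ResiduePropertyTable":
        """The packaged Levitt/Rose table with the proline override applied."""
        with resources.as_file(
            resources.files("coiltools.data") / "residue_properties.tsv"
        ) as path:
            return cls.from_tsv(path, proline_override=True,
                                label="packaged Levitt-1976/Rose-1985")


@dataclass(frozen=True)
class HelixRegions:
    """Named inclusive residue intervals in wild-type numbering."""

    regions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_REGIONS))

    def __post_init__(self) -> None:
        intervals = []
        for name, (start, end) in self.regions.items():
            if start > end:
                raise RegionError(f"region {name!r}: reversed interval {start}-{end}")
            intervals.append((start, end, name))
        intervals.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise RegionError(f"regions {n1!r} and {n2!r} overlap")

    def __iter__(self):
        return iter(self.regions.items())

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.regions[name]

    def check_within(self, seq: ProteinSequence) -> None:
        lo, hi = int(seq.indices[0]), int(seq.indices[-1])
        for name, (start, end) in self.regions.items():
            if start < lo or end > hi:
                raise RegionError(
                    f"region {name!r} ({start}-{end}) outside sequence bounds "
                    f"{lo}-{hi}")


def helix_regions(overrides: Mapping[str, tuple[int, int]] | None = None
                  ) -> HelixRegions:
    """The native helix intervals, with optional per-region overrides.

    Defaults are the four Im7 helices I:12-25, II:31-45, III:51-56, IV:65-79.
    """
    regions = dict(DEFAULT_HELIX_REGIONS)
    if overrides:
        regions.update({name: (int(s), int(e)) for name, (s, e) in overrides.items()})
    return HelixRegions(regions=regions)


def load_sequence(path, first_index: int = 1, tag_length: int = 0
                  ) -> ProteinSequence:
    """Read the first record of a FASTA file as a :class:`ProteinSequence`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    record = records[0]
    return ProteinSequence(
        id=record.id,
        residues=str(record.seq).upper(),
        first_index=first_index,
        tag_length=tag_length,
    )


def im7_sequence(substitutions: Mapping[int, str] | None = None) -> ProteinSequence:
    """The packaged 87-residue wild-type Im7 sequence, optionally with point
    substitutions, e.g. ``im7_sequence({18: "A", 19: "A", 37: "A"})`` for the
    unfolded-state mimic."""
    with resources.as_file(resources.files("coiltools.data") / "im7.fasta") as path:
        wt = load_sequence(path, first_index=1, tag_length=0)
    if substitutions:
        label = "im7_" + "_".join(
            f"{wt.residue_at(i)}{i}{aa}" for i, aa in sorted(substitutions.items()))
        return wt.substituted(substitutions, id=label)
    return wt


def aabuf_profile(seq: ProteinSequence,
                  table: ResiduePropertyTable | None = None,
                  window: int = 9) -> np.ndarray:
    """Smoothed AABUF profile, min-max normalised to [0, 10].

    A sliding-window mean of the raw AABUF scale (truncated windows at the
    termini), then a linear rescale mapping the minimum to 0 and the maximum to
    10. A constant profile (e.g. a homopolymer) maps to all zeros by convention.

    Parameters
    ----------
    window : int
        Odd window length in residues, ``1 <= window <= len(seq)``.
    """
    table = table or ResiduePropertyTable.default()
    n = len(seq)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > n:
        raise ValueError("window larger than sequence")
    raw = np.array([table.aabuf[aa] for aa in seq.residues], dtype=float)
    half = window // 2
    smoothed = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = raw[lo:hi].mean()
    span = smoothed.max() - smoothed.min()
    if span == 0:
        return np.zeros(n)
    return 10.0 * (smoothed - smoothed.min()) / span
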