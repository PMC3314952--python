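"""Secondary chemical shifts and secondary-structure-propensity (SSP) scoring.

A residue's chemical shift deviates from its random-coil value when it samples
secondary structure: Calpha shifts move downfield (positive secondary shift) in
helix, Cbeta upfield. The analyses here are:

* a random-coil reference, built per residue from a base table plus (optional)
  nearest-neighbour, temperature and pH corrections;
* secondary shifts, observed minus random-coil;
* urea-difference shifts, where the random-coil term cancels exactly because
  the same sequence is compared at two denaturant concentrations;
* the windowed SSP score, which pools Calpha/Cbeta secondary shifts over a
  sliding window and expresses them as a fraction of the shift expected for
  fully formed structure: +1 means 100% helix propensity, -1 fully extended;
* per-region helicity summaries (mean SSP x 100 over a helix interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ShiftTableError
from .io import read_tsv, write_tsv
from .sequence import HelixRegions, ProteinSequence

logger = logging.getLogger(__name__)

NUCLEI = ("CA", "CB", "CO", "HA", "N", "HN")

#: Secondary-shift magnitudes (ppm) expected for fully formed structure; the
#: Calpha full-helix value of 2.6 ppm is the canonical helix-formation shift.
#: Signs here are the physical ones (helix: CA +, CB -; sheet: CA -, CB +).
FULL_HELIX_SHIFT = {"CA": 2.6, "CB": -0.4}
FULL_SHEET_SHIFT = {"CA": -1.4, "CB": 2.2}

#: Atom-name synonyms mapped onto the fixed nucleus vocabulary.
_ATOM_TO_NUCLEUS = {
    "CA": "CA", "CB": "CB", "C": "CO", "CO": "CO", "C'": "CO",
    "HA": "HA", "HA2": "HA", "N": "N", "H": "HN", "HN": "HN",
}


@dataclass
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts with solution conditions.

    ``data`` columns: residue_index, residue_type, nucleus, shift_ppm.
    One shift per (residue, nucleus); nuclei from the fixed vocabulary.
    """

    data: pd.DataFrame
    temperature_k: float | None = None
    ph: float | None = None
    urea_m: float = 0.0
    na2so4_m: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        required = {"residue_index", "residue_type", "nucleus", "shift_ppm"}
        if not required.issubset(self.data.columns):
            raise ShiftTableError(f"shift table needs columns {sorted(required)}")
        bad = set(self.data["nucleus"]) - set(NUCLEI)
        if bad:
            raise ShiftTableError(f"unknown nuclei: {sorted(bad)}")
        if not np.all(np.isfinite(self.data["shift_ppm"])):
            raise ShiftTableError("shifts must be finite")
        duplicated = self.data.duplicated(subset=["residue_index", "nucleus"])
        if duplicated.any():
            first = self.data.loc[duplicated].iloc[0]
            raise ShiftTableError(
                f"duplicate shift for residue {int(first.residue_index)} "
                f"nucleus {first.nucleus}")

    def __len__(self) -> int:
        return len(self.data)

    def nuclei(self) -> list[str]:
        return sorted(set(self.data["nucleus"]))

    def select(self, nuclei: Sequence[str]) -> "ShiftTable":
        subset = self.data[self.data["nucleus"].isin(list(nuclei))].reset_index(
            drop=True)
        return ShiftTable(subset, self.temperature_k, self.ph, self.urea_m,
                          self.na2so4_m, self.label)

    def to_tsv(self, path) -> None:
        metadata = {"label": self.label, "urea_M": self.urea_m,
                    "na2so4_M": self.na2so4_m}
        if self.temperature_k is not None:
            metadata["temperature_K"] = self.temperature_k
        if self.ph is not None:
            metadata["pH"] = self.ph
        write_tsv(path, self.data, metadata)

    @classmethod
    def from_tsv(cls, path) -> "ShiftTable":
        frame, metadata = read_tsv(path)
        return cls(
            data=frame,
            temperature_k=(float(metadata["temperature_K"])
                           if "temperature_K" in metadata else None),
            ph=float(metadata["pH"]) if "pH" in metadata else None,
            urea_m=float(metadata.get("urea_M", 0.0)),
            na2so4_m=float(metadata.get("na2so4_M", 0.0)),
            label=metadata.get("label", str(path)),
        )


def read_nmrstar_shifts(path) -> ShiftTable:
    """Read the assigned-chemical-shift loop of an NMR-STAR v3 file.

    Minimal reader for the ``_Atom_chem_shift`` loop: tag names are collected
    after ``loop_``, data rows follow until ``stop_``. Atom names are mapped
    onto the nucleus vocabulary; rows with atoms outside it (side chains,
    HA3, ...) are skipped and counted. Duplicate (residue, nucleus) rows are an
    error naming the residue.
    """
    with open(path, encoding="utf-8") as handle:
        lines = handle.readlines()

    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    reading_data = False
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop, reading_data, tags = True, False, []
            continue
        if in_loop and line.startswith("_"):
            if reading_data:
                in_loop = False
            else:
                tags.append(line.split(".")[-1] if "." in line else line[1:])
            continue
        if in_loop:
            if line == "stop_":
                if any(t in ("Val", "Chem_shift_val") for t in tags) and rows:
                    break
                in_loop, rows = False, []
                continue
            if not tags:
                continue
            reading_data = True
            if any(t in ("Val", "Chem_shift_val") for t in tags):
                rows.append(line.split())
    if not rows or not tags:
        raise ShiftTableError(f"no assigned-chemical-shift loop found in {path}")

    def column(*names):
        for name in names:
            if name in tags:
                return tags.index(name)
        return None

    seq_col = column("Seq_ID", "Comp_index_ID", "Atom_chem_shift.Seq_ID")
    comp_col = column("Comp_ID")
    atom_col = column("Atom_ID")
    val_col = column("Val", "Chem_shift_val")
    if None in (seq_col, comp_col, atom_col, val_col):
        raise ShiftTableError("chemical-shift loop lacks required tags")

    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }
    records, skipped = [], 0
    for fields in rows:
        if len(fields) <= max(seq_col, comp_col, atom_col, val_col):
            skipped += 1
            continue
        atom = fields[atom_col].upper()
        nucleus = _ATOM_TO_NUCLEUS.get(atom)
        if nucleus is None:
            skipped += 1
            continue
        try:
            residue = int(fields[seq_col])
            shift = float(fields[val_col])
        except ValueError:
            skipped += 1
            continue
        rtype = three_to_one.get(fields[comp_col].upper(), "X")
        records.append((residue, rtype, nucleus, shift))
    if skipped:
        logger.info("read_nmrstar_shifts: skipped %d rows", skipped)
    frame = pd.DataFrame(records, columns=["residue_index", "residue_type",
                                           "nucleus", "shift_ppm"])
    duplicated = frame.duplicated(subset=["residue_index", "nucleus"])
    if duplicated.any():
        first = frame.loc[duplicated].iloc[0]
        raise ShiftTableError(
            f"duplicate shift rows for residue {int(first.residue_index)} "
            f"nucleus {first.nucleus}")
    return ShiftTable(frame, label=str(path))


@dataclass(frozen=True)
class RandomCoilReference:
    """Random-coil chemical shifts: base values per (residue type, nucleus)
    plus optional neighbour, temperature and pH correction terms.

    Corrections absent from the tables contribute zero. ``t_ref_k`` is the
    temperature at which the base values apply.
    """

    base: Mapping[tuple[str, str], float]
    neighbor: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    temp_coef: Mapping[str, float] = field(default_factory=dict)
    ph_coef: Mapping[tuple[str, str], float] = field(default_factory=dict)
    t_ref_k: float = 298.15
    ph_ref: float = 7.0
    label: str = "packaged"

    def __post_init__(self) -> None:
        from .sequence import AMINO_ACIDS

        for nucleus in ("CA",):
            missing = [aa for aa in AMINO_ACIDS if (aa, nucleus) not in self.base]
            if missing:
                raise ShiftTableError(
                    f"random-coil base table missing {nucleus} for "
                    f"{''.join(missing)}")

    @classmethod
    def from_tsv(cls, path, label: str | None = None, **kwargs
                 ) -> "RandomCoilReference":
        base: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("residue"):
                    continue
                aa, nucleus, value = line.split("\t")
                base[(aa, nucleus)] = float(value)
        return cls(base=base, label=label or str(path), **kwargs)

    @classmethod
    def default(cls) -> "RandomCoilReference":
        with resources.as_file(
            resources.files("coiltools.data") / "random_coil_shifts.tsv"
        ) as path:
            return cls.from_tsv(path, label="packaged Wishart-style")


def random_coil_shifts(seq: ProteinSequence, ref: RandomCoilReference | None = None,
                       temperature_k: float = 283.15, ph: float = 7.0,
                       nuclei: Sequence[str] = ("CA", "CB")) -> ShiftTable:
    """Predicted random-coil shifts for a sequence at given conditions.

    delta_rc(i) = base(type_i) + sum over offsets in {-2,-1,+1,+2} of the
    neighbour correction for the residue type at i+offset, plus linear
    temperature and pH terms. Edge residues use only the neighbours that exist.
    """
    ref = ref or RandomCoilReference.default()
    records = []
    n = len(seq)
    for k, aa in enumerate(seq.residues):
        index = int(seq.indices[k])
        for nucleus in nuclei:
            if (aa, nucleus) not in ref.base:
                continue  # e.g. Gly CB, Pro N/HN
            value = ref.base[(aa, nucleus)]
            for offset in (-2, -1, 1, 2):
                kk = k + offset
                if 0 <= kk < n:
                    value += ref.neighbor.get(
                        (nucleus, offset, seq.residues[kk]), 0.0)
            value += ref.temp_coef.get(nucleus, 0.0) * (temperature_k - ref.t_ref_k)
            value += ref.ph_coef.get((aa, nucleus), 0.0) * (ph - ref.ph_ref)
            records.append((index, aa, nucleus, value))
    frame = pd.DataFrame(records, columns=["residue_index", "residue_type",
                                           "nucleus", "shift_ppm"])
    return ShiftTable(frame, temperature_k=temperature_k, ph=ph,
                      label=f"random-coil:{ref.label}")


def secondary_shifts(obs: ShiftTable, rc: ShiftTable) -> pd.DataFrame:
    """Per-(residue, nucleus) secondary shifts, observed minus random-coil.

    Rows present in only one table are dropped; the dropped count is recorded
    in ``frame.attrs['n_dropped']``. Raises on zero overlap.
    """
    merged = obs.data.merge(rc.data, on=["residue_index", "nucleus"],
                            suffixes=("_obs", "_rc"))
    if merged.empty:
        raise ShiftTableError("no overlapping (residue, nucleus) rows")
    out = pd.DataFrame({
        "residue_index": merged["residue_index"],
        "residue_type": merged["residue_type_obs"],
        "nucleus": merged["nucleus"],
        "delta_ppm": merged["shift_ppm_obs"] - merged["shift_ppm_rc"],
    })
    out.attrs["n_dropped"] = (len(obs.data) - len(merged)) + (len(rc.data)
                                                              - len(merged))
    return out


def urea_difference_shifts(shifts_0m: ShiftTable, shifts_6m: ShiftTable,
                           flag_ppm: float = 1.0) -> pd.DataFrame:
    """Reference-free difference shifts, delta(0 M urea) - delta(high urea).

    Random-coil terms cancel because the sequence and nuclei are identical.
    Calpha differences exceeding ``flag_ppm`` (default 1 ppm) are flagged as
    atypical — helix formation in folded proteins moves Calpha by ~2.6 ppm, so
    an unfolded state should stay well inside 1 ppm.
    """
    merged = shifts_0m.data.merge(shifts_6m.data, on=["residue_index", "nucleus"],
                                  suffixes=("_0m", "_6m"))
    if merged.empty:
        raise ShiftTableError("no overlapping (residue, nucleus) rows")
    diff = merged["shift_ppm_0m"] - merged["shift_ppm_6m"]
    out = pd.DataFrame({
        "residue_index": merged["residue_index"],
        "residue_type": merged["residue_type_0m"],
        "nucleus": merged["nucleus"],
        "delta_ppm": diff,
        "atypical": (merged["nucleus"] == "CA") & (diff.abs() > flag_ppm),
    })
    return out


@dataclass
class SSPProfile:
    """Windowed secondary-structure propensity scores, helix-positive.

    Scores are clamped to [-1, 1]; positions with fewer than two usable shift
    values in the window are undefined (NaN)."""

    residues: np.ndarray
    scores: np.ndarray
    window: int
    nuclei: tuple[str, ...]

    def score_at(self, index: int) -> float:
        where = np.nonzero(self.residues == index)[0]
        return float(self.scores[where[0]]) if len(where) else float("nan")


def ssp_profile(deltas: pd.DataFrame,
                expected_helix: Mapping[str, float] | None = None,
                expected_sheet: Mapping[str, float] | None = None,
                window: int = 5, outlier_factor: float = 3.0) -> SSPProfile:
    """Secondary-structure propensity from Calpha/Cbeta secondary shifts.

    For each residue, secondary shifts of all usable nuclei within the
    centred window are pooled; Cbeta enters with inverted sign so that helix
    is positive for every nucleus. The score is the ratio of the pooled
    observed shifts to the pooled full-structure magnitudes — full helix if
    the consensus is positive, full sheet otherwise — clamped to [-1, 1].
    A shift whose magnitude exceeds ``outlier_factor`` times its full-structure
    value is excluded as an outlier (typically a referencing or assignment
    artefact). Glycine lacks Cbeta and is scored from Calpha alone.

    Parameters
    ----------
    deltas : DataFrame
        Output of :func:`secondary_shifts` (columns residue_index, nucleus,
        delta_ppm), restricted to CA/CB.
    window : int
        Odd window length, default 5.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    expected_helix = dict(expected_helix or FULL_HELIX_SHIFT)
    expected_sheet = dict(expected_sheet or FULL_SHEET_SHIFT)
    usable = deltas[deltas["nucleus"].isin(list(expected_helix))].copy()
    if usable.empty:
        raise ShiftTableError("no usable CA/CB secondary shifts")

    # helix-positive orientation: divide by the signed full-helix value, so CB
    # (negative in helix) flips sign; magnitudes are restored via the expected
    # tables in the denominator.
    sign = usable["nucleus"].map(lambda nu: np.sign(expected_helix[nu]))
    usable["oriented"] = usable["delta_ppm"] * sign
    exp_h = usable["nucleus"].map(lambda nu: abs(expected_helix[nu]))
    exp_s = usable["nucleus"].map(lambda nu: abs(expected_sheet[nu]))
    keep = usable["delta_ppm"].abs() <= outlier_factor * np.maximum(exp_h, exp_s)
    usable = usable[keep]

    residues = np.array(sorted(set(usable["residue_index"].astype(int))))
    lo, hi = residues.min(), residues.max()
    all_residues = np.arange(lo, hi + 1)
    half = window // 2
    scores = np.full(len(all_residues), np.nan)
    grouped = {r: g for r, g in usable.groupby(usable["residue_index"].astype(int))}
    for i, center in enumerate(all_residues):
        rows = [grouped[r] for r in range(center - half, center + half + 1)
                if r in grouped]
        if not rows:
            continue
        block = pd.concat(rows)
        if len(block) < 2:
            continue
        numerator = block["oriented"].sum()
        helix_denominator = sum(abs(expected_helix[nu]) for nu in block["nucleus"])
        sheet_denominator = sum(abs(expected_sheet[nu]) for nu in block["nucleus"])
        denominator = helix_denominator if numerator >= 0 else sheet_denominator
        scores[i] = np.clip(numerator / denominator, -1.0, 1.0)
    return SSPProfile(residues=all_residues, scores=scores, window=window,
                      nuclei=tuple(sorted(set(usable["nucleus"]))))


def region_helicity(ssp: SSPProfile, regions: HelixRegions | None = None
                    ) -> dict[str, float]:
    """Mean SSP score per helix region, expressed as % helix (score x 100)."""
    regions = regions or HelixRegions()
    out: dict[str, float] = {}
    for name, (start, end) in regions:
        mask = (ssp.residues >= start) & (ssp.residues <= end)
        values = ssp.scores[mask]
        values = values[np.isfinite(values)]
        if len(values) < 2:
            raise ShiftTableError(
                f"region {name!r} overlaps fewer than 2 scored residues")
        out[name] = float(values.mean() * 100.0)
    return out
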