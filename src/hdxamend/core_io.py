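"""Shared domain types, file IO, comparison metrics and RNG plumbing.

Conventions used throughout the package:

* Residue indices are 1-based and inclusive (``start``/``end`` of a peptide
  both point at residues that belong to the peptide), following common
  HDX-MS practice.
* RFU (relative fractional uptake) is a dimensionless number in [0, 1];
  uncorrected or deliberately corrupted data may step outside that range and
  is only rejected when grossly out of bounds.
* Exposure times are seconds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: widest RFU window accepted by the readers; values beyond this are almost
#: certainly unit mistakes (percent instead of fraction, Da instead of RFU).
RFU_HARD_LIMITS = (-0.5, 1.5)

LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def get_logger(name: str, level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(level)
        logger.propagate = False
    return logger


logger = get_logger("hdxamend")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class HdxError(Exception):
    """Base class for all package errors."""


class FormatError(HdxError):
    """A file does not have the expected columns/layout."""


class StructuralError(HdxError):
    """Data are internally inconsistent (shapes, grids, invariants)."""


class AlignmentError(HdxError):
    """Two datasets that must share a peptide map / time grid do not."""


class SequenceError(HdxError):
    """A sequence contains letters outside the 20 standard amino acids."""


class DegenerateControlsError(HdxError):
    """Back-exchange control is not strictly above the forward control."""


class NoReporterError(HdxError):
    """A peptide has no reporting (exchange-competent) residues."""


class UndefinedRSquaredError(HdxError):
    """R^2 is undefined because the reference has zero variance."""


# ---------------------------------------------------------------------------
# RNG management: one seeded generator flows through every stochastic step
# ---------------------------------------------------------------------------


def make_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator; passes Generators through untouched."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed (< 2**31) for a derived stochastic component."""
    return int(rng.integers(0, 2**31 - 1))


def write_sidecar(path: str | Path, payload: dict) -> None:
    """Write run metadata (seed, parameters) next to a generated dataset."""
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with its residue span in the parent protein."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise StructuralError(
                f"peptide {self.sequence!r}: end ({self.end}) < start ({self.start})"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise StructuralError(
                f"peptide {self.sequence!r}: length {len(self.sequence)} does not "
                f"match span {self.start}-{self.end}"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"peptide {self.sequence!r}: non-standard letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def residue_indices(self) -> range:
        """1-based residue indices covered by this peptide."""
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class PeptideMap:
    """An ordered set of peptides covering (part of) one protein."""

    protein_id: str
    protein_sequence: str
    peptides: tuple[Peptide, ...]

    def __post_init__(self) -> None:
        if not self.peptides:
            raise StructuralError(f"{self.protein_id}: peptide map is empty")
        object.__setattr__(self, "peptides", tuple(self.peptides))
        n = len(self.protein_sequence)
        for pep in self.peptides:
            if pep.end > n:
                raise StructuralError(
                    f"{self.protein_id}: peptide {pep.sequence!r} ends at "
                    f"{pep.end} beyond protein length {n}"
                )
            segment = self.protein_sequence[pep.start - 1 : pep.end]
            for got, expect in zip(pep.sequence, segment):
                # 'X' marks residues whose identity is unknown (sequence
                # reconstructed from peptides alone)
                if expect != "X" and got != expect:
                    raise StructuralError(
                        f"{self.protein_id}: peptide {pep.sequence!r} at "
                        f"{pep.start}-{pep.end} does not match protein sequence "
                        f"segment {segment!r}"
                    )

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_residues(self) -> int:
        return len(self.protein_sequence)


def infer_protein_sequence(peptides: Sequence[Peptide]) -> str:
    """Reconstruct a protein sequence from peptides; 'X' where uncovered."""
    n = max(p.end for p in peptides)
    seq = ["X"] * n
    for pep in peptides:
        for offset, aa in enumerate(pep.sequence):
            idx = pep.start - 1 + offset
            if seq[idx] != "X" and seq[idx] != aa:
                raise StructuralError(
                    f"conflicting residue identities at position {idx + 1}: "
                    f"{seq[idx]} vs {aa}"
                )
            seq[idx] = aa
    return "".join(seq)


@dataclass
class UptakeTable:
    """Per-peptide RFU across exposure times for one protein.

    ``rfu[i, j]`` is the RFU of ``map.peptides[i]`` at ``times[j]``.
    """

    map: PeptideMap
    times: np.ndarray
    rfu: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.ndim != 1 or np.any(self.times <= 0):
            raise StructuralError("exposure times must be a 1-D array of positive seconds")
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("exposure times must be strictly increasing")
        expected = (self.map.n_peptides, self.times.size)
        if self.rfu.shape != expected:
            raise StructuralError(
                f"rfu matrix shape {self.rfu.shape} != (n_peptides, n_times) {expected}"
            )

    @property
    def n_times(self) -> int:
        return self.times.size

    def copy(self) -> "UptakeTable":
        return UptakeTable(self.map, self.times.copy(), self.rfu.copy(), dict(self.metadata))


CONTROL_PROVENANCES = ("experimental", "sampled", "predicted_coil", "predicted_ai")


@dataclass
class ControlTable:
    """Per-peptide back/forward exchange controls aligned to a peptide map."""

    map: PeptideMap
    rfu_back: np.ndarray
    rfu_fwd: np.ndarray
    provenance: str = "experimental"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rfu_back = np.asarray(self.rfu_back, dtype=float)
        self.rfu_fwd = np.asarray(self.rfu_fwd, dtype=float)
        n = self.map.n_peptides
        if self.rfu_back.shape != (n,) or self.rfu_fwd.shape != (n,):
            raise StructuralError("one (rfu_back, rfu_fwd) pair required per peptide")
        if self.provenance not in CONTROL_PROVENANCES:
            raise StructuralError(f"unknown provenance {self.provenance!r}")
        if np.any(self.rfu_back < 0) or np.any(self.rfu_back > 1):
            raise StructuralError("rfu_back outside [0, 1]")
        if np.any(self.rfu_fwd < 0) or np.any(self.rfu_fwd > 1):
            raise StructuralError("rfu_fwd outside [0, 1]")
        if np.any(self.rfu_back <= self.rfu_fwd):
            bad = int(np.argmax(self.rfu_back <= self.rfu_fwd))
            raise DegenerateControlsError(
                f"rfu_back <= rfu_fwd for peptide {self.map.peptides[bad].sequence!r}"
            )

    def copy(self) -> "ControlTable":
        return ControlTable(
            self.map, self.rfu_back.copy(), self.rfu_fwd.copy(), self.provenance,
            dict(self.metadata),
        )


@dataclass
class ProtectionProfile:
    """Per-residue natural-log protection factors with a reporting mask.

    ``mask[i]`` is True where residue ``i+1`` does not report (prolines,
    excluded N-terminal positions, residues without data); ``lnp`` is NaN at
    masked positions.
    """

    protein_id: str
    lnp: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.lnp = np.asarray(self.lnp, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lnp.shape != self.mask.shape or self.lnp.ndim != 1:
            raise StructuralError("lnp and mask must be 1-D arrays of equal length")
        unmasked = self.lnp[~self.mask]
        if np.any(~np.isfinite(unmasked)) or np.any(unmasked < 0):
            raise StructuralError("unmasked lnP values must be finite and >= 0")
        self.lnp = self.lnp.copy()
        self.lnp[self.mask] = np.nan

    def __len__(self) -> int:
        return self.lnp.size


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["protein", "sequence", "start", "end", "exposure_s", "rfu"]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def write_uptake_table(table: UptakeTable, path: str | Path) -> None:
    """Write an uptake table as long-format CSV (one row per peptide x time)."""
    rows = []
    for i, pep in enumerate(table.map.peptides):
        for j, t in enumerate(table.times):
            rows.append(
                (table.map.protein_id, pep.sequence, pep.start, pep.end, t,
                 round(float(table.rfu[i, j]), 6))
            )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def read_uptake_table(path: str | Path, dialect: str = "long") -> UptakeTable:
    """Read an uptake table from CSV.

    ``dialect='long'`` expects columns protein, sequence, start, end,
    exposure_s, rfu.  ``dialect='wide'`` expects protein, sequence, start,
    end plus one column per exposure time whose header is the time in
    seconds (optionally prefixed ``rfu_``), the style of per-protein text
    exports.
    """
    df = pd.read_csv(path)
    if dialect == "wide":
        _require_columns(df, ["protein", "sequence", "start", "end"], path)
        time_cols = []
        for col in df.columns:
            name = col[4:] if col.startswith("rfu_") else col
            try:
                time_cols.append((float(name), col))
            except ValueError:
                continue
        if not time_cols:
            raise FormatError(f"{path}: wide dialect needs numeric exposure columns")
        df = df.melt(
            id_vars=["protein", "sequence", "start", "end"],
            value_vars=[c for _, c in time_cols],
            var_name="exposure_s", value_name="rfu",
        )
        renames = {c: t for t, c in time_cols}
        df["exposure_s"] = df["exposure_s"].map(renames)
    elif dialect != "long":
        raise FormatError(f"unknown dialect {dialect!r}")
    _require_columns(df, _LONG_COLUMNS, path)

    lo, hi = RFU_HARD_LIMITS
    bad = df[(df["rfu"] < lo) | (df["rfu"] > hi)]
    if len(bad):
        raise ValueError(
            f"{path}: {len(bad)} RFU values outside [{lo}, {hi}] "
            f"(first at row {bad.index[0]})"
        )
    for idx, row in df.iterrows():
        if row["end"] < row["start"]:
            raise StructuralError(f"{path}: end < start at row {idx}")

    peptides: list[Peptide] = []
    seen: dict[tuple, int] = {}
    grids: list[np.ndarray] = []
    rfu_rows: list[np.ndarray] = []
    for key, grp in df.groupby(["sequence", "start", "end"], sort=False):
        # merge duplicate (sequence, start, end) rows; average replicate RFU
        grp = grp.groupby("exposure_s", as_index=False)["rfu"].mean()
        grp = grp.sort_values("exposure_s")
        if key in seen:
            continue
        seen[key] = len(peptides)
        peptides.append(Peptide(str(key[0]), int(key[1]), int(key[2])))
        grids.append(grp["exposure_s"].to_numpy(dtype=float))
        rfu_rows.append(grp["rfu"].to_numpy(dtype=float))

    times = grids[0]
    for pep, g in zip(peptides, grids):
        if g.shape != times.shape or not np.allclose(g, times):
            raise StructuralError(
                f"{path}: peptide {pep.sequence!r} has a different exposure-time "
                "grid from the first peptide"
            )
    pmap = PeptideMap(
        str(df["protein"].iloc[0]), infer_protein_sequence(peptides), tuple(peptides)
    )
    return UptakeTable(pmap, times, np.vstack(rfu_rows), {"source": str(path)})


def write_control_table(controls: ControlTable, path: str | Path) -> None:
    rows = [
        (controls.map.protein_id, pep.sequence, pep.start, pep.end,
         round(float(controls.rfu_back[i]), 6), round(float(controls.rfu_fwd[i]), 6),
         controls.provenance)
        for i, pep in enumerate(controls.map.peptides)
    ]
    pd.DataFrame(
        rows,
        columns=["protein", "sequence", "start", "end", "rfu_back", "rfu_fwd", "provenance"],
    ).to_csv(path, index=False)


def read_control_table(path: str | Path) -> ControlTable:
    df = pd.read_csv(path)
    _require_columns(df, ["protein", "sequence", "start", "end", "rfu_back", "rfu_fwd"], path)
    peptides = tuple(
        Peptide(str(r.sequence), int(r.start), int(r.end)) for r in df.itertuples()
    )
    pmap = PeptideMap(str(df["protein"].iloc[0]), infer_protein_sequence(peptides), peptides)
    provenance = str(df["provenance"].iloc[0]) if "provenance" in df.columns else "experimental"
    return ControlTable(
        pmap, df["rfu_back"].to_numpy(float), df["rfu_fwd"].to_numpy(float), provenance
    )


def write_protection_profile(
    profile: ProtectionProfile, path: str | Path, sequence: str | None = None
) -> None:
    seq = sequence or "X" * len(profile)
    rows = [
        (i + 1, seq[i], "" if profile.mask[i] else round(float(profile.lnp[i]), 6),
         int(profile.mask[i]))
        for i in range(len(profile))
    ]
    pd.DataFrame(rows, columns=["residue_index", "aa", "lnP", "mask"]).to_csv(
        path, sep="\t", index=False
    )


def read_protection_profile(path: str | Path, protein_id: str = "") -> ProtectionProfile:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["residue_index", "lnP", "mask"], path)
    df = df.sort_values("residue_index")
    mask = df["mask"].to_numpy(dtype=bool)
    lnp = pd.to_numeric(df["lnP"], errors="coerce").to_numpy(dtype=float)
    lnp[mask] = np.nan
    return ProtectionProfile(protein_id or str(path), lnp, mask)


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------


def _check_same_grid(a: UptakeTable, b: UptakeTable) -> None:
    if a.map.peptides != b.map.peptides:
        raise AlignmentError("uptake tables have different peptide maps")
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise AlignmentError("uptake tables have different exposure-time grids")


def compare_uptake(a: UptakeTable, b: UptakeTable) -> tuple[np.ndarray, float]:
    """Per-peptide and overall RMSE (in RFU units) between two uptake tables."""
    _check_same_grid(a, b)
    sq = (a.rfu - b.rfu) ** 2
    per_peptide = np.sqrt(sq.mean(axis=1))
    overall = float(np.sqrt(sq.mean()))
    return per_peptide, overall


def r_squared(est: np.ndarray, ref: np.ndarray) -> float:
    """Coefficient of determination of ``est`` against ``ref``.

    Standard 1 - SS_res/SS_tot; can be negative for fits worse than the
    reference mean.  NaN pairs (masked residues) are dropped first.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise StructuralError("r_squared: inputs must have equal length")
    keep = np.isfinite(est) & np.isfinite(ref)
    est, ref = est[keep], ref[keep]
    if est.size < 3:
        raise StructuralError("r_squared needs at least 3 commonly unmasked residues")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("reference has zero variance")
    ss_res = float(np.sum((est - ref) ** 2))
    return 1.0 - ss_res / ss_tot
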