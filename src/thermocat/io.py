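"""Domain types and file I/O for the kinetics / spectroscopy / ensemble pipeline.

All tabular data travel as RFC-4180-style CSV with a mandatory header row.
Metadata (temperature, labels, enzyme concentration) is carried in ``#``-prefixed
comment lines above the header so a table round-trips to an identical record.
Canonical internal units are kelvin, seconds, s^-1, mM, nm and Angstrom;
readers convert on input (degC -> K, min^-1 -> s^-1) based on declared unit
suffixes in column names, never on magnitude guessing.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, PER_MIN_TO_PER_S


class ThermocatError(Exception):
    """Base class for package errors."""


class SchemaError(ThermocatError):
    """A required column is missing or the schema name is unknown."""


class TableParseError(ThermocatError):
    """A cell could not be parsed as a number."""


class ValidationError(ThermocatError):
    """A record violates a domain invariant."""


class PDBFormatError(ThermocatError):
    """A multi-model PDB file is structurally inconsistent."""


class SelectionError(ThermocatError):
    """An atom selection matched nothing or could not be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsorbanceTransient:
    """A stopped-flow absorbance transient at 340 nm.

    Attributes
    ----------
    time : array, seconds, strictly increasing
    absorbance : array, AU
    temperature : kelvin
    label : free-text identifier
    """

    time: np.ndarray
    absorbance: np.ndarray
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)
        if t.shape != a.shape or t.ndim != 1:
            raise ValidationError("time and absorbance must be 1-D arrays of equal length")
        if t.size < 8:
            raise ValidationError("transient needs at least 8 points")
        if not (np.isfinite(t).all() and np.isfinite(a).all()):
            raise ValidationError("transient contains non-finite values")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time must be strictly increasing")


@dataclass(frozen=True)
class RateConcentrationSeries:
    """Observed rate vs substrate concentration at a single temperature.

    Rates are stored in s^-1 (observed rate divided by enzyme concentration
    happens downstream when k_cat is derived).
    """

    substrate_conc: np.ndarray   # mM
    rate: np.ndarray             # s^-1 observed rate
    temperature: float = 298.15  # K
    enzyme_conc: float = 1.0     # uM
    substrate: str = ""
    isotopologue: str = "protiated"

    def __post_init__(self):
        s = np.asarray(self.substrate_conc, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "rate", v)
        if s.shape != v.shape or s.ndim != 1:
            raise ValidationError("substrate_conc and rate must be 1-D arrays of equal length")
        if np.any(s < 0):
            raise ValidationError("substrate concentrations must be non-negative")
        if not (np.isfinite(s).all() and np.isfinite(v).all()):
            raise ValidationError("series contains non-finite values")
        if np.unique(s).size < 5:
            raise ValidationError("need at least 5 distinct substrate concentrations")


@dataclass(frozen=True)
class TemperatureRateSeries:
    """First-order rate constant vs temperature for one substrate/isotopologue."""

    temperature: np.ndarray      # K, strictly increasing
    rate: np.ndarray             # s^-1, > 0
    rate_se: np.ndarray | None = None
    substrate: str = ""
    isotopologue: str = "protiated"

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        k = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "rate", k)
        if t.shape != k.shape or t.ndim != 1:
            raise ValidationError("temperature and rate must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValidationError("need at least 5 temperature points")
        if np.any(t <= 0):
            raise ValidationError("temperatures must be positive kelvin")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if np.any(k <= 0):
            raise ValidationError("rates must be strictly positive (ln k is fitted)")
        if self.rate_se is not None:
            se = np.asarray(self.rate_se, dtype=float)
            object.__setattr__(self, "rate_se", se)
            if se.shape != k.shape:
                raise ValidationError("rate_se must match rate shape")
            if np.any(se < 0):
                raise ValidationError("rate_se must be non-negative")


@dataclass(frozen=True)
class ExcitationEmissionMatrix:
    """Fluorescence excitation-emission matrix (rows = excitation wavelengths)."""

    excitation_wavelengths: np.ndarray  # nm
    emission_wavelengths: np.ndarray    # nm
    intensity: np.ndarray               # (n_ex, n_em), arbitrary units
    label: str = ""

    def __post_init__(self):
        ex = np.asarray(self.excitation_wavelengths, dtype=float)
        em = np.asarray(self.emission_wavelengths, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation_wavelengths", ex)
        object.__setattr__(self, "emission_wavelengths", em)
        object.__setattr__(self, "intensity", z)
        if z.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity shape {z.shape} does not match "
                f"({ex.size} excitation, {em.size} emission) wavelengths"
            )
        if np.any(z.sum(axis=1) <= 0):
            raise ValidationError("every excitation row must have positive total intensity")


@dataclass(frozen=True)
class CoordinateEnsemble:
    """A coordinate ensemble: frames x atoms x 3 in Angstrom with atom labels."""

    coordinates: np.ndarray           # (n_frames, n_atoms, 3)
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self):
        xyz = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", xyz)
        for name in ("atom_names", "residue_names", "chain_ids"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        n_atoms = xyz.shape[1]
        for name in ("atom_names", "residue_ids", "residue_names", "chain_ids"):
            if getattr(self, name).shape != (n_atoms,):
                raise ValidationError(f"{name} must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, selection: str | np.ndarray | Callable) -> "CoordinateEnsemble":
        """Return the sub-ensemble of atoms matching *selection*.

        Selections are either a boolean mask, a callable mapping this ensemble
        to a mask, or a string of space-joined clauses combined with ``and``:
        ``name CA``, ``name C1,C4``, ``resname GLC``, ``resid 10-20``,
        ``chain A``.
        """
        mask = _selection_mask(self, selection)
        if not mask.any():
            raise SelectionError(f"selection {selection!r} matched no atoms")
        return CoordinateEnsemble(
            coordinates=self.coordinates[:, mask, :],
            atom_names=self.atom_names[mask],
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            chain_ids=self.chain_ids[mask],
            frame_times=self.frame_times,
        )

    def atom_index(self, name: str, residue_id: int | None = None) -> int:
        """Index of a single named atom (optionally within a residue)."""
        mask = self.atom_names == name
        if residue_id is not None:
            mask &= self.residue_ids == residue_id
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"atom {name!r} (residue {residue_id}) not found")
        return int(idx[0])


def _selection_mask(ens: CoordinateEnsemble, selection) -> np.ndarray:
    if callable(selection):
        return np.asarray(selection(ens), dtype=bool)
    if isinstance(selection, np.ndarray):
        return selection.astype(bool)
    if not isinstance(selection, str):
        raise SelectionError(f"unsupported selection type {type(selection)}")
    mask = np.ones(ens.n_atoms, dtype=bool)
    for clause in selection.split(" and "):
        parts = clause.strip().split(None, 1)
        if len(parts) != 2:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
        key, value = parts
        if key == "name":
            mask &= np.isin(ens.atom_names, value.split(","))
        elif key == "resname":
            mask &= np.isin(ens.residue_names, value.split(","))
        elif key == "chain":
            mask &= np.isin(ens.chain_ids, value.split(","))
        elif key == "resid":
            if "-" in value:
                lo, hi = (int(v) for v in value.split("-"))
            else:
                lo = hi = int(value)
            mask &= (ens.residue_ids >= lo) & (ens.residue_ids <= hi)
        else:
            raise SelectionError(f"unknown selection key {key!r}")
    return mask


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

_SCHEMAS = ("transient", "rates", "tempseries", "eem")

# recognised (column name -> canonical field, converter) aliases per schema
_TEMP_COLS = {
    "temperature_K": lambda x: x, "T_K": lambda x: x,
    "temperature_C": lambda x: x + CELSIUS_OFFSET, "T_C": lambda x: x + CELSIUS_OFFSET,
}
_RATE_COLS = {
    "rate_per_s": lambda x: x, "k_per_s": lambda x: x, "kcat_per_s": lambda x: x,
    "rate_per_min": lambda x: x * PER_MIN_TO_PER_S,
    "k_per_min": lambda x: x * PER_MIN_TO_PER_S,
    "kcat_per_min": lambda x: x * PER_MIN_TO_PER_S,
}
_RATE_SE_COLS = {
    "rate_se_per_s": lambda x: x,
    "rate_se_per_min": lambda x: x * PER_MIN_TO_PER_S,
}


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        else:
            break
    body = "\n".join(lines[body_start:])
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    for col in df.columns:
        if df[col].dtype == object:
            continue
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2 + body_start
            raise TableParseError(f"non-numeric or missing value in column {col!r} near line {row}")
    return df, meta


def _pick_column(df: pd.DataFrame, aliases: dict, what: str, required=True):
    hits = [c for c in df.columns if c in aliases]
    if not hits:
        if required:
            raise SchemaError(
                f"missing {what} column; expected one of {sorted(aliases)}"
            )
        return None
    col = hits[0]
    values = pd.to_numeric(df[col], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0]) + 2
        raise TableParseError(f"non-numeric value in column {col!r} at data row {row}")
    return aliases[col](values.to_numpy(dtype=float))


def read_table(path, schema: str):
    """Read a CSV table into the typed record for *schema*.

    schema is one of ``transient``, ``rates``, ``tempseries``, ``eem``.
    Units are converted to canonical (K, s, s^-1, mM, nm) based on the
    declared unit suffix of each column name.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    df, meta = _read_csv_with_meta(path)

    if schema == "transient":
        t = _pick_column(df, {"time_s": lambda x: x}, "time")
        a = _pick_column(df, {"absorbance_au": lambda x: x}, "absorbance")
        return AbsorbanceTransient(
            time=t, absorbance=a,
            temperature=float(meta.get("temperature_K", 298.15)),
            label=meta.get("label", ""),
        )

    if schema == "rates":
        s = _pick_column(df, {"substrate_conc_mM": lambda x: x}, "substrate concentration")
        v = _pick_column(df, _RATE_COLS, "rate")
        temp = _pick_column(df, _TEMP_COLS, "temperature", required=False)
        temperature = float(temp[0]) if temp is not None else float(meta.get("temperature_K", 298.15))
        return RateConcentrationSeries(
            substrate_conc=s, rate=v, temperature=temperature,
            enzyme_conc=float(meta.get("enzyme_conc_uM", 1.0)),
            substrate=meta.get("substrate", df["substrate"].iloc[0] if "substrate" in df else ""),
            isotopologue=meta.get("isotopologue", "protiated"),
        )

    if schema == "tempseries":
        t = _pick_column(df, _TEMP_COLS, "temperature")
        k = _pick_column(df, _RATE_COLS, "rate")
        se = _pick_column(df, _RATE_SE_COLS, "rate standard error", required=False)
        order = np.argsort(t)
        return TemperatureRateSeries(
            temperature=t[order], rate=k[order],
            rate_se=None if se is None else se[order],
            substrate=meta.get("substrate", df["substrate"].iloc[0] if "substrate" in df else ""),
            isotopologue=meta.get("isotopologue", "protiated"),
        )

    # eem: first column emission_nm, remaining columns one per excitation nm
    if "emission_nm" not in df.columns:
        raise SchemaError("missing emission_nm column in EEM table")
    em = df["emission_nm"].to_numpy(dtype=float)
    ex_cols = [c for c in df.columns if c != "emission_nm"]
    try:
        ex = np.array([float(c) for c in ex_cols])
    except ValueError as e:
        raise SchemaError(f"EEM excitation column headers must be wavelengths in nm: {e}")
    intensity = df[ex_cols].to_numpy(dtype=float).T
    return ExcitationEmissionMatrix(
        excitation_wavelengths=ex, emission_wavelengths=em,
        intensity=intensity, label=meta.get("label", ""),
    )


def write_table(record, path) -> None:
    """Write a typed record as CSV (canonical units, metadata in # lines)."""
    path = Path(path)
    lines = ["# units = K, s, s^-1, mM, nm"]
    if isinstance(record, AbsorbanceTransient):
        lines.append(f"# temperature_K = {record.temperature!r}")
        lines.append(f"# label = {record.label}")
        df = pd.DataFrame({"time_s": record.time, "absorbance_au": record.absorbance})
    elif isinstance(record, RateConcentrationSeries):
        lines.append(f"# temperature_K = {record.temperature!r}")
        lines.append(f"# enzyme_conc_uM = {record.enzyme_conc!r}")
        lines.append(f"# substrate = {record.substrate}")
        lines.append(f"# isotopologue = {record.isotopologue}")
        df = pd.DataFrame({"substrate_conc_mM": record.substrate_conc, "rate_per_s": record.rate})
    elif isinstance(record, TemperatureRateSeries):
        lines.append(f"# substrate = {record.substrate}")
        lines.append(f"# isotopologue = {record.isotopologue}")
        cols = {"temperature_K": record.temperature, "rate_per_s": record.rate}
        if record.rate_se is not None:
            cols["rate_se_per_s"] = record.rate_se
        df = pd.DataFrame(cols)
    elif isinstance(record, ExcitationEmissionMatrix):
        lines.append(f"# label = {record.label}")
        df = pd.DataFrame(record.intensity.T, columns=[repr(float(x)) for x in record.excitation_wavelengths])
        df.insert(0, "emission_nm", record.emission_wavelengths)
    else:
        raise SchemaError(f"cannot write record of type {type(record).__name__}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path, selection=None) -> CoordinateEnsemble:
    """Read a (possibly multi-model) PDB file into a CoordinateEnsemble.

    Frames follow MODEL numbering order; a static single structure yields one
    frame. An optional *selection* (see :meth:`CoordinateEnsemble.select`) is
    applied identically to every frame.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # AtomArrayStack; models must be congruent
    except Exception as e:
        raise PDBFormatError(f"inconsistent models in {path}: {e}") from e
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    ens = CoordinateEnsemble(
        coordinates=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        residue_names=np.asarray(stack.res_name),
        chain_ids=np.asarray(stack.chain_id),
    )
    if selection is not None:
        ens = ens.select(selection)
    return ens


def write_multimodel_pdb(ensemble: CoordinateEnsemble, path) -> None:
    """Write an ensemble as MODEL/ENDMDL blocks."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = ensemble.n_atoms
    arrays = []
    for frame in ensemble.coordinates:
        arr = struc.AtomArray(n_atoms)
        arr.coord = np.asarray(frame, dtype=np.float32)
        arr.atom_name = ensemble.atom_names.astype("U6")
        arr.res_id = ensemble.residue_ids
        arr.res_name = ensemble.residue_names.astype("U5")
        arr.chain_id = ensemble.chain_ids.astype("U4")
        arr.element = np.array([n[0] if n else "C" for n in ensemble.atom_names], dtype="U2")
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))
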