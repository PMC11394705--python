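"""Domain types for spectral and assay data, plus CSV readers/writers.

All CSV dialects used here are fixed: comma separator, ``.`` decimal point,
and ``#``-prefixed metadata lines of the form ``# key = value``.
Concentrations are carried in the units the assays use natively:
mol/L for quenching titrations, µg/mL for dose-response tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "SynchronousSpectrum",
    "EEM",
    "DoseResponseTable",
    "read_titration_table",
    "write_titration_table",
    "read_dose_response_table",
    "write_dose_response_table",
    "read_synchronous_table",
    "write_synchronous_table",
    "read_eem_table",
    "write_eem_table",
    "write_report",
    "read_report",
]


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def _require_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size >= 2 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


def _require_finite_nonnegative(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan at a single quencher concentration.

    Parameters
    ----------
    wavelengths_nm : array-like
        Emission wavelengths in nm, strictly increasing.
    intensities_au : array-like
        Fluorescence intensities (arbitrary units), finite and >= 0.
    excitation_nm : float
        Excitation wavelength (nm).
    temperature_K : float
        Absolute temperature (K), > 0.
    quencher_conc_M : float
        Quencher (ligand) concentration in mol/L, >= 0.
    a_ex, a_em : float, optional
        Absorbances at the excitation and emission wavelengths, used for
        inner-filter correction. Must be >= 0 when given.
    ife_corrected : bool
        Set by the inner-filter correction step; informational.
    """

    wavelengths_nm: np.ndarray
    intensities_au: np.ndarray
    excitation_nm: float
    temperature_K: float
    quencher_conc_M: float
    a_ex: float | None = None
    a_em: float | None = None
    ife_corrected: bool = False

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths_nm, "wavelengths_nm")
        inten = _as_float_array(self.intensities_au, "intensities_au")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities_au", inten)
        if wl.size != inten.size:
            raise ValidationError("wavelengths and intensities differ in length")
        if wl.size < 2:
            raise ValidationError("spectrum needs at least 2 points")
        _require_strictly_increasing(wl, "wavelengths_nm")
        _require_finite_nonnegative(inten, "intensities_au")
        if not self.temperature_K > 0:
            raise ValidationError("temperature_K must be > 0")
        if self.quencher_conc_M < 0:
            raise ValidationError("quencher_conc_M must be >= 0")
        for name in ("a_ex", "a_em"):
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val < 0):
                raise ValidationError(f"{name} must be finite and >= 0")

    def with_intensities(self, intensities: np.ndarray, *, ife_corrected: bool | None = None) -> "EmissionSpectrum":
        corrected = self.ife_corrected if ife_corrected is None else ife_corrected
        return replace(self, intensities_au=np.asarray(intensities, dtype=float), ife_corrected=corrected)


@dataclass(frozen=True)
class TitrationSeries:
    """Emission spectra of one preparation across increasing quencher
    concentrations at a single temperature and excitation wavelength.

    The first spectrum must have zero quencher concentration; it defines
    the unquenched reference F0. All spectra share the wavelength grid.
    """

    spectra: tuple[EmissionSpectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        if len(spectra) < 2:
            raise ValidationError("titration series needs >= 2 spectra")
        concs = np.array([s.quencher_conc_M for s in spectra])
        if concs[0] != 0.0:
            raise ValidationError("no F0 reference: first spectrum must have quencher_conc_M = 0")
        _require_strictly_increasing(concs, "quencher concentrations")
        ref = spectra[0]
        for s in spectra[1:]:
            if s.wavelengths_nm.size != ref.wavelengths_nm.size or not np.array_equal(
                s.wavelengths_nm, ref.wavelengths_nm
            ):
                raise ValidationError("all spectra must share the wavelength grid")
            if s.excitation_nm != ref.excitation_nm:
                raise ValidationError("all spectra must share excitation_nm")
            if s.temperature_K != ref.temperature_K:
                raise ValidationError("all spectra must share temperature_K")

    @property
    def excitation_nm(self) -> float:
        return self.spectra[0].excitation_nm

    @property
    def temperature_K(self) -> float:
        return self.spectra[0].temperature_K

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    @property
    def concentrations_M(self) -> np.ndarray:
        return np.array([s.quencher_conc_M for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


@dataclass(frozen=True)
class SynchronousSpectrum:
    """Synchronous scan at fixed emission-excitation offset ``delta_lambda_nm``."""

    excitation_nm: np.ndarray
    intensities_au: np.ndarray
    delta_lambda_nm: float
    quencher_conc_M: float
    temperature_K: float

    def __post_init__(self) -> None:
        ex = _as_float_array(self.excitation_nm, "excitation_nm")
        inten = _as_float_array(self.intensities_au, "intensities_au")
        object.__setattr__(self, "excitation_nm", ex)
        object.__setattr__(self, "intensities_au", inten)
        if ex.size != inten.size:
            raise ValidationError("excitation grid and intensities differ in length")
        if ex.size < 2:
            raise ValidationError("synchronous spectrum needs at least 2 points")
        _require_strictly_increasing(ex, "excitation_nm")
        _require_finite_nonnegative(inten, "intensities_au")
        if not self.delta_lambda_nm > 0:
            raise ValidationError("delta_lambda_nm must be > 0")
        if self.quencher_conc_M < 0:
            raise ValidationError("quencher_conc_M must be >= 0")
        if not self.temperature_K > 0:
            raise ValidationError("temperature_K must be > 0")


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix: intensity over an excitation x emission grid."""

    excitation_grid_nm: np.ndarray
    emission_grid_nm: np.ndarray
    intensity_matrix: np.ndarray
    quencher_conc_M: float = 0.0

    def __post_init__(self) -> None:
        ex = _as_float_array(self.excitation_grid_nm, "excitation_grid_nm")
        em = _as_float_array(self.emission_grid_nm, "emission_grid_nm")
        mat = np.asarray(self.intensity_matrix, dtype=float)
        object.__setattr__(self, "excitation_grid_nm", ex)
        object.__setattr__(self, "emission_grid_nm", em)
        object.__setattr__(self, "intensity_matrix", mat)
        _require_strictly_increasing(ex, "excitation_grid_nm")
        _require_strictly_increasing(em, "emission_grid_nm")
        if mat.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity_matrix shape {mat.shape} does not match grids ({ex.size}, {em.size})"
            )
        _require_finite_nonnegative(mat.ravel(), "intensity_matrix")
        if self.quencher_conc_M < 0:
            raise ValidationError("quencher_conc_M must be >= 0")


@dataclass(frozen=True)
class DoseResponseTable:
    """Dose-response rows: inhibitor concentration (µg/mL) with control
    absorbance ``a0`` and sample absorbance ``a1``.

    Rows are stored sorted by ascending concentration.
    """

    conc_ug_ml: np.ndarray
    a0: np.ndarray
    a1: np.ndarray

    def __post_init__(self) -> None:
        conc = _as_float_array(self.conc_ug_ml, "conc_ug_ml")
        a0 = _as_float_array(self.a0, "a0")
        a1 = _as_float_array(self.a1, "a1")
        if not (conc.size == a0.size == a1.size):
            raise ValidationError("columns differ in length")
        if conc.size < 1:
            raise ValidationError("empty dose-response table")
        order = np.argsort(conc, kind="stable")
        conc, a0, a1 = conc[order], a0[order], a1[order]
        object.__setattr__(self, "conc_ug_ml", conc)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "a1", a1)
        if np.any(conc <= 0):
            raise FormatError("concentrations must be > 0")
        _require_strictly_increasing(conc, "conc_ug_ml")
        if np.any(a0 <= 0):
            raise FormatError("a0 must be > 0 (division guard)")
        _require_finite_nonnegative(a1, "a1")

    def __len__(self) -> int:
        return self.conc_ug_ml.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"conc_ug_ml": self.conc_ug_ml, "a0": self.a0, "a1": self.a1})


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _parse_metadata_lines(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _parse_float_list(text: str) -> list[float]:
    return [float(tok) for tok in text.split(",") if tok.strip() != ""]


def read_titration_table(path, metadata: Mapping[str, object] | None = None) -> TitrationSeries:
    """Read a titration series from CSV.

    Layout: ``#``-prefixed metadata lines (``excitation_nm``,
    ``temperature_K``, optional comma-separated ``a_ex`` / ``a_em``
    schedules aligned with the concentration columns), then a header row
    whose first column is the wavelength and remaining headers are quencher
    concentrations in mol/L. Columns are re-sorted by ascending
    concentration, so column order in the file is irrelevant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, object] = dict(_parse_metadata_lines(path))
    if metadata:
        meta.update(metadata)
    try:
        excitation_nm = float(meta["excitation_nm"])  # type: ignore[arg-type]
        temperature_K = float(meta["temperature_K"])  # type: ignore[arg-type]
    except KeyError as exc:
        raise FormatError(f"missing required metadata key: {exc.args[0]}") from None

    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise FormatError("titration table needs a wavelength column and >= 2 concentration columns")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError("wavelength column must be strictly increasing")
    try:
        concs = [float(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise FormatError(f"concentration column headers must be numeric: {exc}") from None
    if 0.0 not in concs:
        raise FormatError("no F0 reference: a zero-concentration column is required")

    a_ex_raw = meta.get("a_ex")
    a_em_raw = meta.get("a_em")
    a_ex = _parse_float_list(a_ex_raw) if isinstance(a_ex_raw, str) else a_ex_raw
    a_em = _parse_float_list(a_em_raw) if isinstance(a_em_raw, str) else a_em_raw
    for name, sched in (("a_ex", a_ex), ("a_em", a_em)):
        if sched is not None and len(sched) != len(concs):
            raise FormatError(f"{name} schedule length {len(sched)} != number of concentration columns {len(concs)}")

    order = np.argsort(concs, kind="stable")
    spectra = []
    for idx in order:
        col = df.columns[1 + idx]
        inten = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(inten)):
            raise FormatError(f"NaN or non-finite intensity in column {col!r}")
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=wl,
                intensities_au=inten,
                excitation_nm=excitation_nm,
                temperature_K=temperature_K,
                quencher_conc_M=concs[idx],
                a_ex=None if a_ex is None else float(a_ex[idx]),
                a_em=None if a_em is None else float(a_em[idx]),
            )
        )
    return TitrationSeries(spectra=tuple(spectra))



def _fmt(v) -> str:
    """Full-precision decimal text for any numeric scalar."""
    return repr(float(v))

def write_titration_table(series: TitrationSeries, path) -> Path:
    """Write a titration series in the dialect :func:`read_titration_table` reads."""
    path = Path(path)
    lines = [
        f"# excitation_nm = {_fmt(series.excitation_nm)}",
        f"# temperature_K = {_fmt(series.temperature_K)}",
    ]
    a_ex = [s.a_ex for s in series.spectra]
    a_em = [s.a_em for s in series.spectra]
    if all(v is not None for v in a_ex):
        lines.append("# a_ex = " + ",".join(_fmt(v) for v in a_ex))
    if all(v is not None for v in a_em):
        lines.append("# a_em = " + ",".join(_fmt(v) for v in a_em))
    header = "wavelength_nm," + ",".join(_fmt(s.quencher_conc_M) for s in series.spectra)
    lines.append(header)
    cols = [series.wavelengths_nm] + [s.intensities_au for s in series.spectra]
    for row in zip(*cols):
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dose_response_table(path) -> DoseResponseTable:
    """Read a dose-response CSV with columns ``conc_ug_ml``, ``a0``, ``a1``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    required = {"conc_ug_ml", "a0", "a1"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    return DoseResponseTable(
        conc_ug_ml=df["conc_ug_ml"].to_numpy(dtype=float),
        a0=df["a0"].to_numpy(dtype=float),
        a1=df["a1"].to_numpy(dtype=float),
    )


def write_dose_response_table(table: DoseResponseTable, path) -> Path:
    path = Path(path)
    lines = ["conc_ug_ml,a0,a1"]
    for c, a0, a1 in zip(table.conc_ug_ml, table.a0, table.a1):
        lines.append(f"{_fmt(c)},{_fmt(a0)},{_fmt(a1)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_synchronous_table(path) -> list[SynchronousSpectrum]:
    """Read a synchronous-scan series: metadata ``delta_lambda_nm`` and
    ``temperature_K``; header ``excitation_nm`` then concentration columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_metadata_lines(path)
    try:
        delta = float(meta["delta_lambda_nm"])
        temperature_K = float(meta["temperature_K"])
    except KeyError as exc:
        raise FormatError(f"missing required metadata key: {exc.args[0]}") from None
    df = pd.read_csv(path, comment="#")
    ex = df.iloc[:, 0].to_numpy(dtype=float)
    try:
        concs = [float(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise FormatError(f"concentration column headers must be numeric: {exc}") from None
    order = np.argsort(concs, kind="stable")
    return [
        SynchronousSpectrum(
            excitation_nm=ex,
            intensities_au=df[df.columns[1 + i]].to_numpy(dtype=float),
            delta_lambda_nm=delta,
            quencher_conc_M=concs[i],
            temperature_K=temperature_K,
        )
        for i in order
    ]


def write_synchronous_table(series: Sequence[SynchronousSpectrum], path) -> Path:
    path = Path(path)
    first = series[0]
    lines = [
        f"# delta_lambda_nm = {_fmt(first.delta_lambda_nm)}",
        f"# temperature_K = {_fmt(first.temperature_K)}",
        "excitation_nm," + ",".join(_fmt(s.quencher_conc_M) for s in series),
    ]
    cols = [first.excitation_nm] + [s.intensities_au for s in series]
    for row in zip(*cols):
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_eem_table(path) -> EEM:
    """Read an EEM CSV: first column excitation_nm, headers emission wavelengths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_metadata_lines(path)
    conc = float(meta.get("quencher_conc_M", 0.0))
    df = pd.read_csv(path, comment="#")
    ex = df.iloc[:, 0].to_numpy(dtype=float)
    try:
        em = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"emission column headers must be numeric: {exc}") from None
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    return EEM(excitation_grid_nm=ex, emission_grid_nm=em, intensity_matrix=mat, quencher_conc_M=conc)


def write_eem_table(eem: EEM, path) -> Path:
    path = Path(path)
    lines = [
        f"# quencher_conc_M = {_fmt(eem.quencher_conc_M)}",
        "excitation_nm," + ",".join(_fmt(v) for v in eem.emission_grid_nm),
    ]
    for i, ex in enumerate(eem.excitation_grid_nm):
        lines.append(_fmt(ex) + "," + ",".join(_fmt(v) for v in eem.intensity_matrix[i]))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Consolidated report
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_report(results: Mapping[str, object], path) -> Path:
    """Emit ``report.json`` plus one flat CSV per tabular stage under ``path``.

    Every numeric field is serialized via ``repr`` (json float round-trip),
    so re-reading reproduces values to full precision. Empty or missing
    sections are written as explicit empty objects.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {str(k): _jsonify(v) for k, v in results.items()}
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    for stage, value in payload.items():
        if isinstance(value, dict) and value and all(
            isinstance(v, list) and v and all(isinstance(x, (int, float)) for x in v)
            for v in value.values()
        ):
            lengths = {len(v) for v in value.values()}
            if len(lengths) == 1:
                pd.DataFrame(value).to_csv(outdir / f"{stage}.csv", index=False)
    return report_path


def read_report(path) -> dict:
    """Read back a report written by :func:`write_report`."""
    report_path = Path(path)
    if report_path.is_dir():
        report_path = report_path / "report.json"
    with open(report_path) as fh:
        return json.load(fh)
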