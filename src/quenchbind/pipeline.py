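"""End-to-end orchestration: IFE correction -> quench table -> Stern-Volmer
-> double-log -> thermodynamics -> spectral shifts -> IC50, from a single
flat configuration, emitting a consolidated report."""

from __future__ import annotations

import logging
import math
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

from . import binding as _binding
from . import inhibition as _inhibition
from . import spectral as _spectral
from . import thermo as _thermo
from .datamodel import (
    read_dose_response_table,
    read_eem_table,
    read_synchronous_table,
    read_titration_table,
    write_report,
)
from .errors import QuenchBindError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("quenchbind")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults mirror the analysis constants
    (tau0 = 1e-8 s, collisional limit 2.0e10 L/(mol s), IFE base e,
    Celsius offset 273)."""

    titration_tables: tuple[str, ...] = ()
    sync15_table: str | None = None
    sync60_table: str | None = None
    eem_table: str | None = None
    dose_response_table: str | None = None
    ka_by_T: dict[float, float] = field(default_factory=dict)
    tau0_s: float = _binding.DEFAULT_TAU0_S
    kq_limit: float = _binding.COLLISIONAL_QUENCH_LIMIT
    ife_base: float = math.e
    intercept_mode: str = "free"
    celsius_offset: float = 273.0
    ic50_model: str = "4PL"
    ic50_bootstrap: int = 0
    scatter_halfwidth_nm: float = 15.0
    min_prominence: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (
            self.titration_tables
            or self.sync15_table
            or self.sync60_table
            or self.eem_table
            or self.dose_response_table
            or self.ka_by_T
        ):
            raise ValidationError("empty config: no stage has inputs")

    def effective(self) -> dict:
        out = asdict(self)
        out["titration_tables"] = list(self.titration_tables)
        out["ka_by_T"] = {float(k): float(v) for k, v in self.ka_by_T.items()}
        return out


def load_config(path, overrides: Mapping[str, object] | None = None) -> PipelineConfig:
    """Load a YAML (flat key/value) config file; ``overrides`` win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "ife_base" in raw and raw["ife_base"] in ("e", "E"):
        raw["ife_base"] = math.e
    if "titration_tables" in raw and isinstance(raw["titration_tables"], (list, tuple)):
        raw["titration_tables"] = tuple(str(p) for p in raw["titration_tables"])
    if "ka_by_T" in raw and raw["ka_by_T"]:
        raw["ka_by_T"] = {float(k): float(v) for k, v in dict(raw["ka_by_T"]).items()}
    return PipelineConfig(**raw)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.3f s", stage, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages with available inputs in dependency order.

    Stages whose inputs are missing are skipped and logged. Any stage error
    is recorded in the report's ``errors`` section; the partial report is
    still returned (and written when ``out_dir`` is given).
    """
    config.validate()
    report: dict = {"config": config.effective(), "errors": {}, "skipped": []}

    ka_by_T: dict[float, float] = dict(config.ka_by_T)

    if config.titration_tables:
        with _timed("binding"):
            section = {}
            for path in config.titration_tables:
                try:
                    series = read_titration_table(path)
                    has_abs = all(s.a_ex is not None and s.a_em is not None for s in series)
                    if has_abs:
                        series = type(series)(
                            spectra=tuple(
                                _spectral.correct_inner_filter(s, base=config.ife_base) for s in series
                            )
                        )
                    shift = _spectral.peak_shift_series(series)
                    table = _binding.build_quench_table(series)
                    sv = _binding.fit_stern_volmer(
                        table, tau0_s=config.tau0_s, intercept_mode=config.intercept_mode
                    )
                    mechanism = (
                        "undetermined"
                        if sv.negative_slope
                        else _binding.classify_mechanism(sv.k_q, limit=config.kq_limit)
                    )
                    dl = _binding.fit_double_log(table)
                    ka_by_T.setdefault(series.temperature_K, dl.k_a)
                    section[str(path)] = {
                        "temperature_K": series.temperature_K,
                        "ife_applied": has_abs,
                        "k_sv": sv.k_sv,
                        "k_q": sv.k_q,
                        "sv_intercept": sv.intercept,
                        "sv_r2": sv.r2,
                        "mechanism": mechanism,
                        "p_ka": dl.p_ka,
                        "k_a": dl.k_a,
                        "n": dl.n,
                        "dl_r2": dl.r2,
                        "excluded_rows": table.n_excluded,
                        "peak_shift_nm": shift.shift_nm,
                        "peak_shift_direction": shift.direction,
                    }
                except (QuenchBindError, OSError) as exc:
                    report["errors"][f"binding:{path}"] = str(exc)
            report["binding"] = section
    else:
        report["skipped"].append("binding")

    if ka_by_T and len(ka_by_T) >= 2:
        with _timed("thermo"):
            try:
                result = _thermo.analyze_thermodynamics(ka_by_T)
                report["thermo"] = {
                    "ka_by_T": ka_by_T,
                    "delta_h_J_mol": result.delta_h_J_mol,
                    "delta_s_J_molK": result.delta_s_J_molK,
                    "delta_g_by_T": result.delta_g_by_T,
                    "delta_h_kJ_mol": result.delta_h_J_mol / 1000.0,
                    "delta_g_kJ_mol_by_T": {T: g / 1000.0 for T, g in result.delta_g_by_T.items()},
                    "force_label": result.force_label,
                    "gas_constant_J_molK": result.gas_constant_J_molK,
                }
            except QuenchBindError as exc:
                report["errors"]["thermo"] = str(exc)
    else:
        report["skipped"].append("thermo")

    sync15 = sync60 = None
    if config.sync15_table or config.sync60_table:
        with _timed("synchronous"):
            section = {}
            try:
                if config.sync15_table:
                    sync15 = read_synchronous_table(config.sync15_table)
                    s = _spectral.peak_shift_series(sync15)
                    section["delta15_shift_nm"] = s.shift_nm
                    section["delta15_direction"] = s.direction
                if config.sync60_table:
                    sync60 = read_synchronous_table(config.sync60_table)
                    s = _spectral.peak_shift_series(sync60)
                    section["delta60_shift_nm"] = s.shift_nm
                    section["delta60_direction"] = s.direction
                if sync15 and sync60:
                    cmp_ = _spectral.residue_quench_comparison(sync15, sync60)
                    section["fraction_15"] = cmp_.fraction_15
                    section["fraction_60"] = cmp_.fraction_60
                    section["proximity"] = cmp_.label
                report["synchronous"] = section
            except (QuenchBindError, OSError) as exc:
                report["errors"]["synchronous"] = str(exc)
    else:
        report["skipped"].append("synchronous")

    if config.eem_table:
        with _timed("eem"):
            try:
                eem = read_eem_table(config.eem_table)
                peaks = _spectral.find_eem_peaks(
                    eem,
                    min_prominence=config.min_prominence,
                    scatter_halfwidth_nm=config.scatter_halfwidth_nm,
                )
                report["eem"] = {
                    "peaks": [
                        {
                            "excitation_nm": p.excitation_nm,
                            "emission_nm": p.emission_nm,
                            "intensity_au": p.intensity_au,
                            "label": p.label,
                        }
                        for p in peaks
                    ]
                }
            except (QuenchBindError, OSError) as exc:
                report["errors"]["eem"] = str(exc)
    else:
        report["skipped"].append("eem")

    if config.dose_response_table:
        with _timed("ic50"):
            try:
                table = read_dose_response_table(config.dose_response_table)
                curve = _inhibition.fit_ic50(
                    table,
                    model=config.ic50_model,
                    n_boot=config.ic50_bootstrap,
                    seed=config.seed,
                )
                report["ic50"] = {
                    "model": curve.fitted_model,
                    "ic50_ug_ml": curve.ic50,
                    "ic50_ci": list(curve.ic50_ci) if curve.ic50_ci else None,
                    "params": curve.params,
                    "residual_rmse": curve.residual_rmse,
                    "conc_ug_ml": curve.conc_ug_ml.tolist(),
                    "inhibition_pct": curve.inhibition_pct.tolist(),
                    "activation_flag": curve.activation_flag,
                }
            except (QuenchBindError, OSError) as exc:
                report["errors"]["ic50"] = str(exc)
    else:
        report["skipped"].append("ic50")

    if out_dir is not None:
        write_report(report, out_dir)
    return report
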