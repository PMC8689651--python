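"""End-to-end orchestration: per-substrate kinetics -> MMRT -> KIE -> REES.

A run is described by a single structured (YAML) config with per-substrate
blocks; every stochastic stage derives its randomness from the one top-level
seed, so a rerun with the same config is byte-identical. Each stage either
loads a CSV (see :mod:`thermocat.io`) or simulates its input from a named
scenario via :mod:`thermocat.synthetic`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .constants import PER_MIN_TO_PER_S
from .io import ThermocatError, ValidationError, read_table
from .kinetics import fit_michaelis
from .mmrt import fit_kie_pair, fit_mmrt
from .rees import csm_curve, fit_qubes
from .synthetic import NoiseSpec, SUBSTRATE_SCENARIOS, scenario_mmrt_series

logger = logging.getLogger("thermocat.pipeline")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    seed: int
    output_dir: Path
    substrates: list          # raw per-substrate blocks
    T0: float = 348.0
    reference_substrate: str | None = None
    bootstrap: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")
        missing = {"seed", "output_dir", "substrates"} - raw.keys()
        if missing:
            raise ValidationError(f"config missing keys: {sorted(missing)}")
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=(base / raw["output_dir"]).resolve(),
            substrates=raw["substrates"],
            T0=float(raw.get("T0", 348.0)),
            reference_substrate=raw.get("reference_substrate"),
            bootstrap=int(raw.get("bootstrap", 0)),
        )
        for block in cfg.substrates:
            if "name" not in block:
                raise ValidationError("every substrate block needs a name")
            for stage in ("mm", "mmrt", "rees"):
                spec = block.get(stage)
                if spec and "file" in spec:
                    p = base / spec["file"]
                    if not p.exists():
                        raise ValidationError(f"input file not found: {p}")
                    spec["file"] = str(p)
        return cfg


@dataclass
class SubstrateReport:
    """One row of the final report; None marks a not-estimated quantity."""

    substrate: str
    k_cat: float | None = None          # min^-1, as conventionally reported
    k_cat_se: float | None = None
    K_M: float | None = None            # mM
    K_M_se: float | None = None
    K_i: float | None = None            # mM
    K_i_se: float | None = None
    dCp: float | None = None            # kJ mol^-1 K^-1
    dCp_se: float | None = None
    dH_T0: float | None = None          # kJ mol^-1
    dH_T0_se: float | None = None
    dS_T0: float | None = None          # kJ mol^-1 K^-1
    dS_T0_se: float | None = None
    kie_T0: float | None = None
    ddCp_isotope: float | None = None   # dCp(D) - dCp(H)
    ddCp_isotope_se: float | None = None
    csm0: float | None = None
    qubes_A: float | None = None
    qubes_R: float | None = None
    a_over_r: float | None = None


def _substrate_seed(master: int, index: int, stage: int) -> int:
    """Deterministic per-substrate, per-stage seed below 2^31."""
    ss = np.random.SeedSequence([master, index, stage])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns {substrate: SubstrateReport}.

    Writes ``report.csv``, ``ddcp_table.csv`` (when a reference substrate is
    set) and ``run.log`` into the output directory. Raises on validation
    problems before any computation; a failing stage aborts with partial
    outputs retained on disk.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start seed=%d T0=%.2f", config.seed, config.T0)

    reports: dict[str, SubstrateReport] = {}
    try:
        for idx, block in enumerate(config.substrates):
            name = block["name"]
            rep = SubstrateReport(substrate=name)

            if "mm" in block:
                series = _load_or_sim_mm(block["mm"], name,
                                         _substrate_seed(config.seed, idx, 0))
                fit = fit_michaelis(series, inhibition=block["mm"].get("inhibition", "auto"))
                rep.k_cat = fit.k_cat / PER_MIN_TO_PER_S
                rep.k_cat_se = fit.se.get("k_cat", np.nan) / PER_MIN_TO_PER_S
                rep.K_M, rep.K_M_se = fit.K_M, fit.se.get("K_M")
                if fit.has_inhibition:
                    rep.K_i, rep.K_i_se = fit.K_i, fit.se.get("K_i")
                logger.info("%s MM fit: kcat=%.3g min^-1 K_M=%.3g mM", name,
                            rep.k_cat, rep.K_M)

            if "mmrt" in block:
                series = _load_or_sim_mmrt(block["mmrt"], name,
                                           _substrate_seed(config.seed, idx, 1))
                fit = fit_mmrt(series, T0=config.T0)
                rep.dCp, rep.dCp_se = fit.params.dCp, fit.se["dCp"]
                rep.dH_T0, rep.dH_T0_se = fit.params.dH_T0, fit.se["dH_T0"]
                rep.dS_T0, rep.dS_T0_se = fit.params.dS_T0, fit.se["dS_T0"]
                logger.info("%s MMRT fit: dCp=%.3g kJ/mol/K", name, rep.dCp)

                kie_block = block.get("kie")
                if kie_block:
                    series_D = _load_or_sim_mmrt(
                        dict(block["mmrt"], kie_divisor=kie_block.get("divisor", 1.0)),
                        name, _substrate_seed(config.seed, idx, 2),
                        isotopologue="deuterated")
                    prof = fit_kie_pair(series, series_D, T0=config.T0)
                    rep.kie_T0 = prof.kie_at(config.T0)
                    rep.ddCp_isotope = prof.ddCp
                    rep.ddCp_isotope_se = prof.ddCp_se

            if "rees" in block:
                eem = _load_or_sim_eem(block["rees"], name,
                                       _substrate_seed(config.seed, idx, 3))
                q = fit_qubes(csm_curve(eem))
                rep.csm0, rep.qubes_A, rep.qubes_R = q.csm0, q.amplitude, q.curvature
                rep.a_over_r = q.a_over_r

            reports[name] = rep
    except ThermocatError:
        _write_report(reports, out, partial=True)
        logger.exception("stage failed; partial outputs retained")
        logger.removeHandler(handler)
        raise

    _write_report(reports, out)
    if config.reference_substrate:
        tbl = ddcp_table(reports.values(), config.reference_substrate)
        tbl.to_csv(out / "ddcp_table.csv", index=False)
    logger.info("pipeline done: %d substrates", len(reports))
    logger.removeHandler(handler)
    return reports


def _load_or_sim_mm(spec, name, seed):
    if "file" in spec:
        return read_table(spec["file"], "rates")
    sim = spec["simulate"]
    sc = SUBSTRATE_SCENARIOS.get(sim.get("scenario", name), {})
    kcat = sim.get("kcat_per_s", sc.get("kcat_per_min", 60.0) * PER_MIN_TO_PER_S)
    S = np.geomspace(sim.get("S_min", 0.1), sim.get("S_max", 20.0), sim.get("n", 10))
    series, _ = synthetic.gen_mm_series(
        kcat=kcat, K_M=sim.get("K_M", sc.get("K_M", 1.0)),
        K_i=sim.get("K_i", sc.get("K_i")), substrate_conc=S,
        noise=NoiseSpec(sigma=sim.get("noise", 0.0), seed=seed), substrate=name)
    return series


def _load_or_sim_mmrt(spec, name, seed, isotopologue="protiated"):
    if "file" in spec:
        return read_table(spec["file"], "tempseries")
    sim = spec["simulate"]
    T = np.linspace(sim.get("T_min", 293.0), sim.get("T_max", 358.0), sim.get("n", 14))
    series, _ = scenario_mmrt_series(
        sim.get("scenario", name), T,
        noise=NoiseSpec(sigma=sim.get("noise", 0.0), seed=seed),
        kie_divisor=spec.get("kie_divisor", 1.0), isotopologue=isotopologue)
    return series


def _load_or_sim_eem(spec, name, seed):
    if "file" in spec:
        return read_table(spec["file"], "eem")
    sim = spec["simulate"]
    eem, _ = synthetic.gen_eem(
        csm0=sim.get("csm0", 353.0), amplitude=sim.get("A", 2.0),
        curvature=sim.get("R", 0.2), peak_width=sim.get("peak_width", 20.0),
        excitation=np.arange(292.0, 311.0), emission=np.arange(325.0, 501.0),
        noise=NoiseSpec(kind="additive-gaussian", sigma=sim.get("noise", 0.0),
                        seed=seed), label=name)
    return eem


def _report_frame(reports) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in reports]
    df = pd.DataFrame(rows)
    df.insert(0, "schema_version", REPORT_SCHEMA_VERSION)
    return df


def _write_report(reports: dict, out: Path, partial: bool = False):
    if not reports:
        return
    df = _report_frame(reports.values())
    name = "report.partial.csv" if partial else "report.csv"
    df.to_csv(out / name, index=False, float_format="%.10g")


def ddcp_table(reports, reference_substrate: str) -> pd.DataFrame:
    """Change in dCp relative to a reference substrate, with quadrature SEs.

    The reference row is exactly zero by construction.
    """
    reports = list(reports)
    by_name = {r.substrate: r for r in reports}
    if reference_substrate not in by_name:
        raise ValidationError(f"reference substrate {reference_substrate!r} not in reports")
    ref = by_name[reference_substrate]
    if ref.dCp is None:
        raise ValidationError("reference substrate has no fitted dCp")
    rows = []
    for r in reports:
        if r.dCp is None:
            continue
        if r.substrate == reference_substrate:
            ddcp, se = 0.0, 0.0
        else:
            ddcp = r.dCp - ref.dCp
            se = float(np.hypot(r.dCp_se or 0.0, ref.dCp_se or 0.0))
        rows.append({"substrate": r.substrate, "ddCp": ddcp, "ddCp_se": se})
    return pd.DataFrame(rows)
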