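"""Assembly of all metrics into a machine-readable QA report.

``run_report`` executes the metrics requested in a configuration mapping and
writes a JSON report plus per-metric CSV curves.  Each metric section either
reads a volume from disk (``input: <path>``) or generates one synthetically
(``simulate: {...}`` with phantom-truth fields).  All randomness derives from
the top-level ``seed``; re-running an identical configuration reproduces the
outputs byte-identically (no timestamps enter the report).

The report layout is a pydantic model (:class:`QAReport`); its JSON Schema is
shipped with the package under ``ctiq/schemas/qa_report.schema.json``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel

from . import phantoms
from .hu_qa import ct_number_check, measure_insert_hu, uniformity_test
from .lowcontrast import LowContrastReader, dose_match
from .mtf import mtf_from_circular_edge, mtf_from_wire, mtf_summary
from .nps import NoisePowerSpectrum
from .ssp import ssp_from_foil
from .volume import CTIQError, ImageVolume, read_volume

__version__ = "0.1.0"

__all__ = ["QAReport", "run_report", "default_full_config", "load_config",
           "report_json_schema"]


# ---------------------------------------------------------------------------
# report model
# ---------------------------------------------------------------------------

class MTFSection(BaseModel):
    f90: Optional[float] = None
    f50: Optional[float] = None
    f10: Optional[float] = None
    f2: Optional[float] = None
    curve_csv: Optional[str] = None


class SSPSection(BaseModel):
    fwhm_mm: float
    curve_csv: Optional[str] = None


class NPSSection(BaseModel):
    noise_sd: float
    peak_frequency: float
    n_rois: int
    mode: str
    curve_csv: Optional[str] = None


class UniformitySection(BaseModel):
    centre_mean: float
    peripheral_means: dict[str, float]
    diffs: dict[str, float]
    limit: float
    passed: bool


class HUCheck(BaseModel):
    value: float
    lo: float
    hi: float
    passed: bool


class HUSection(BaseModel):
    materials: dict[str, HUCheck]
    all_passed: bool


class LowContrastSection(BaseModel):
    counts: dict[str, int]
    score: int
    rule_threshold: float


class DoseMatchSection(BaseModel):
    doses: list[float]
    scores: list[float]
    reference_score: float
    base_dose: float
    matched_dose: Optional[float]
    percent_increase: Optional[float]
    reached: bool


class Provenance(BaseModel):
    software: str = "ctiq"
    version: str = __version__
    seed: int
    config: dict
    inputs: dict[str, str] = {}


class QAReport(BaseModel):
    provenance: Provenance
    mtf_wire: Optional[MTFSection] = None
    mtf_edge: Optional[MTFSection] = None
    ssp: Optional[SSPSection] = None
    nps: Optional[NPSSection] = None
    uniformity: Optional[UniformitySection] = None
    hu: Optional[HUSection] = None
    lowcontrast: Optional[LowContrastSection] = None
    dose_match: Optional[DoseMatchSection] = None


def report_json_schema() -> dict:
    """The QAReport JSON Schema shipped with the package."""
    with resources.files("ctiq.schemas").joinpath("qa_report.schema.json").open() as f:
        return json.load(f)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

_METRIC_SEED_OFFSET = {"mtf_wire": 1, "mtf_edge": 2, "ssp": 3, "nps": 4,
                       "uniformity": 5, "hu": 6, "lowcontrast": 7}


def _metric_seed(base: int, metric: str, extra: int = 0) -> int:
    return (base * 97 + 13 * _METRIC_SEED_OFFSET[metric] + extra) % (2 ** 31)


def _write_csv(path: Path, header: str, *cols: np.ndarray) -> str:
    data = np.column_stack(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.9e")
    return path.name


def _truth(sim: dict, seed: int) -> tuple[phantoms.PhantomTruth, dict]:
    """Split a ``simulate`` config into PhantomTruth fields and extras."""
    truth_fields = {f.name for f in phantoms.PhantomTruth.__dataclass_fields__.values()}
    tkw = {k: v for k, v in sim.items() if k in truth_fields}
    extra = {k: v for k, v in sim.items() if k not in truth_fields}
    if tkw.get("noise_kernel") == "dog":
        tkw["noise_kernel"] = phantoms.dog_kernel(
            extra.pop("kernel_size", 11),
            extra.pop("kernel_sigma1_px", 1.0),
            extra.pop("kernel_sigma2_px", 4.0))
    tkw.setdefault("rng_seed", seed)
    return phantoms.PhantomTruth(**tkw), extra


def _load_or_simulate(cfg: dict, metric: str, seed: int, simulate_fn
                      ) -> tuple[ImageVolume, Optional[phantoms.PhantomTruth]]:
    if "input" in cfg:
        return read_volume(cfg["input"]), None
    if "simulate" not in cfg:
        raise CTIQError(f"metric {metric!r}: config needs 'input' or 'simulate'")
    truth, extra = _truth(cfg["simulate"], _metric_seed(seed, metric))
    vol, truth = simulate_fn(truth, **extra)
    return vol, truth


def run_report(config: dict, output_dir: str | Path) -> QAReport:
    """Execute the configured metrics and write report.json + CSV curves."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    metrics = config.get("metrics", {})
    if not metrics:
        raise CTIQError("config has no 'metrics' section")
    report = QAReport(provenance=Provenance(seed=seed, config=config))
    inputs: dict[str, str] = {}

    for metric, cfg in metrics.items():
        cfg = dict(cfg or {})
        opts = cfg.get("opts", {})
        if "input" in cfg:
            inputs[metric] = str(cfg["input"])

        if metric == "mtf_wire":
            vol, _ = _load_or_simulate(cfg, metric, seed, phantoms.simulate_wire_image)
            curve = mtf_from_wire(vol, **opts)
            name = _write_csv(outdir / "mtf_wire.csv", "frequency_lpmm,modulation",
                              curve.frequencies, curve.modulation)
            report.mtf_wire = MTFSection(**mtf_summary(curve), curve_csv=name)

        elif metric == "mtf_edge":
            vol, _ = _load_or_simulate(cfg, metric, seed, phantoms.simulate_rod_image)
            curve = mtf_from_circular_edge(vol, **opts)
            name = _write_csv(outdir / "mtf_edge.csv", "frequency_lpmm,modulation",
                              curve.frequencies, curve.modulation)
            report.mtf_edge = MTFSection(**mtf_summary(curve), curve_csv=name)

        elif metric == "ssp":
            vol, _ = _load_or_simulate(cfg, metric, seed, phantoms.simulate_foil_stack)
            curve = ssp_from_foil(vol, **opts)
            name = _write_csv(outdir / "ssp.csv", "z_mm,response",
                              curve.z, curve.response)
            report.ssp = SSPSection(fwhm_mm=curve.fwhm, curve_csv=name)

        elif metric == "nps":
            if "input" in cfg:
                vols = [read_volume(p) for p in
                        ([cfg["input"]] if isinstance(cfg["input"], str)
                         else cfg["input"])]
            else:
                truth, extra = _truth(cfg["simulate"], _metric_seed(seed, metric))
                n_vol = extra.pop("n_volumes", 2)
                vols = []
                for i in range(n_vol):
                    t_i = phantoms.PhantomTruth(
                        **{**{f: getattr(truth, f) for f in
                              phantoms.PhantomTruth.__dataclass_fields__},
                           "rng_seed": _metric_seed(seed, metric, extra=i + 1)})
                    v, _ = phantoms.simulate_noise_volume(t_i, **extra)
                    vols.append(v)
            est = NoisePowerSpectrum(**opts).fit(vols)
            name = _write_csv(outdir / "nps.csv", "frequency_lpmm,power_hu2mm2",
                              est.nps1d_freq_, est.nps1d_power_)
            report.nps = NPSSection(noise_sd=est.noise_sd_,
                                    peak_frequency=est.peak_frequency_,
                                    n_rois=est.n_rois_, mode=est.mode,
                                    curve_csv=name)

        elif metric == "uniformity":
            vol, _ = _load_or_simulate(cfg, metric, seed,
                                       phantoms.simulate_noise_volume)
            rep = uniformity_test(vol, **opts)
            report.uniformity = UniformitySection(
                centre_mean=rep.centre_mean, peripheral_means=rep.peripheral_means,
                diffs=rep.diffs, limit=rep.limit, passed=rep.passed)

        elif metric == "hu":
            vol, truth = _load_or_simulate(cfg, metric, seed,
                                           phantoms.simulate_insert_module)
            layout = cfg.get("layout")
            if layout is None:
                if truth is None:
                    raise CTIQError("hu metric with file input needs a 'layout'")
                layout = phantoms.insert_layout(truth)
            measured = measure_insert_hu(vol, layout, **opts)
            checks = ct_number_check(measured)
            report.hu = HUSection(
                materials={m: HUCheck(**c) for m, c in checks.items()},
                all_passed=all(c["passed"] for c in checks.values()))

        elif metric == "lowcontrast":
            vol, truth = _load_or_simulate(cfg, metric, seed,
                                           phantoms.simulate_low_contrast_module)
            layout = cfg.get("layout")
            if layout is None:
                if truth is None:
                    raise CTIQError("lowcontrast with file input needs a 'layout'")
                layout = truth.lc_layout
            reader = LowContrastReader(**opts).fit(vol, layout)
            report.lowcontrast = LowContrastSection(
                counts={f"{k:g}%": v for k, v in sorted(reader.counts_.items())},
                score=reader.score_, rule_threshold=reader.rule_threshold)

        elif metric == "dose_match":
            res = dose_match(cfg["doses"], cfg["scores"],
                             cfg["reference_score"], cfg["base_dose"])
            report.dose_match = DoseMatchSection(
                doses=res.doses, scores=res.scores,
                reference_score=res.reference_score, base_dose=res.base_dose,
                matched_dose=res.matched_dose,
                percent_increase=res.percent_increase, reached=res.reached)

        else:
            raise CTIQError(f"unknown metric {metric!r} in config")

    report.provenance.inputs = inputs
    (outdir / "report.json").write_text(
        json.dumps(report.model_dump(), indent=1, sort_keys=True) + "\n")
    return report


def load_config(path: str | Path) -> dict:
    """Load a YAML report configuration."""
    with open(path) as f:
        return yaml.safe_load(f)


def default_full_config(seed: int = 0) -> dict:
    """A complete synthetic QA run touching every metric (desk-scale sizes)."""
    return {
        "seed": seed,
        "metrics": {
            "mtf_wire": {"simulate": {"psf_sigma": 0.1874, "grid_size": 128,
                                      "pixel_pitch": 0.05},
                         "opts": {"roi_size": 64, "annulus_inner": 24,
                                  "annulus_outer": 30}},
            "mtf_edge": {"simulate": {"psf_sigma": 0.1874, "grid_size": 256,
                                      "pixel_pitch": 0.1}},
            "ssp": {"simulate": {"slice_fwhm": 0.45, "z_increment": 0.1,
                                 "z_extent": 4.0}},
            "nps": {"simulate": {"noise_sigma_white": 20.0,
                                 "noise_kernel": "dog", "grid_size": 192,
                                 "n_slices": 6, "n_volumes": 2},
                    "opts": {"roi_size": 64, "slice_gap": 0,
                             "mode": "subtracted"}},
            "uniformity": {"simulate": {"noise_sigma_white": 5.0,
                                        "grid_size": 220, "pixel_pitch": 1.6,
                                        "n_slices": 1}},
            "hu": {"simulate": {"noise_sigma_white": 5.0, "psf_sigma": 0.4}},
            "lowcontrast": {"simulate": {"noise_sigma_white": 20.0,
                                         "psf_sigma": 0.6}},
            "dose_match": {"doses": [9.1, 9.8, 10.5, 11.6, 13.0, 14.0],
                           "scores": [10, 12, 14, 17, 20, 22],
                           "reference_score": 16, "base_dose": 9.1},
        },
    }
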