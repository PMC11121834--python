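"""Study orchestration: simulate -> measure -> quantify -> classify -> compare.

:func:`run_study` executes the whole virtual method-comparison study for a
:class:`StudyConfig`: it samples a cohort, rasterizes short-axis mask stacks
and disk-sums them (the standard method), simulates observer four-chamber
measurements and applies the cone-pyramid formula, classifies both methods
against sex-specific reference limits (the standard method defining the
reference labels), runs the full comparison statistics including a
reliability sub-study (two observers, two replicates for observer 1, on the
first 30 subjects), and writes every table to the output directory.

All randomness derives from a single seed through ``numpy`` seed sequences,
so a rerun with the same config is value-identical; every emitted file
carries the SHA-256 of the canonical config for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import (
    CohortConfig,
    LinearMeasurements,
    MaskStack,
    SubjectRecord,
    cohort_dataframe,
    phantom_pair,
    rasterize_short_axis,
    sample_cohort,
    simulate_measurements,
)
from .comparison import ComparisonResults, MethodComparison
from .cpf import (
    DEFAULT_THRESHOLDS,
    ReferenceThresholds,
    classify_rv,
    cpf_volume,
    ejection_fraction,
    index_to_bsa,
)
from .volumetry import disk_summation_volume

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyOutput", "run_study", "quantify_cohort",
           "reliability_ratings", "RELIABILITY_N"]

#: Size of the repeated-measurement reliability sub-study.
RELIABILITY_N = 30


@dataclass
class StudyConfig:
    """Configuration of one virtual study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ReferenceThresholds = field(default_factory=ReferenceThresholds)
    scenario: str = "realistic"
    seed: int = 0
    output_dir: Optional[str] = None
    export_masks: bool = False
    export_nifti: bool = False
    export_plots: bool = False

    @classmethod
    def ideal(cls, n: int = 50, seed: int = 0, **kwargs) -> "StudyConfig":
        return cls(cohort=CohortConfig.ideal(n=n, seed=seed), scenario="ideal",
                   seed=seed, **kwargs)

    @classmethod
    def realistic(cls, n: int = 70, seed: int = 0, **kwargs) -> "StudyConfig":
        return cls(cohort=CohortConfig.realistic(n=n, seed=seed),
                   scenario="realistic", seed=seed, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyOutput:
    """Everything :func:`run_study` computes, in memory."""

    config: StudyConfig
    subjects: List[SubjectRecord]
    cohort_table: pd.DataFrame
    measurements: pd.DataFrame
    results: pd.DataFrame
    report: ComparisonResults


def _measurement_rows(subject: SubjectRecord,
                      measurements: List[LinearMeasurements]) -> List[dict]:
    return [{"subject": subject.id, "observer": m.observer,
             "replicate": m.replicate, "Dd_cm": m.Dd, "Ds_cm": m.Ds,
             "Ld_cm": m.Ld, "Ls_cm": m.Ls} for m in measurements]


def _method_row(subject_id: str, sex: str, bsa: float, method: str,
                edv: float, esv: float,
                thresholds: ReferenceThresholds) -> dict:
    ef = ejection_fraction(edv, esv)
    edvi = index_to_bsa(edv, bsa)
    esvi = index_to_bsa(esv, bsa)
    flags = classify_rv(sex, edvi, esvi, ef, thresholds)
    return {"subject": subject_id, "method": method, "sex": sex, "bsa_m2": bsa,
            "edv": edv, "esv": esv, "ef": ef, "edvi": edvi, "esvi": esvi,
            "enlarged_edv": flags.enlarged_edv,
            "enlarged_esv": flags.enlarged_esv,
            "reduced_ef": flags.reduced_ef}


def quantify_cohort(
    subjects: List[SubjectRecord],
    config: CohortConfig,
    thresholds: ReferenceThresholds = DEFAULT_THRESHOLDS,
    keep_stacks: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[Tuple[str, str], MaskStack]]:
    """Quantify every subject with both methods.

    Returns ``(results, measurements, stacks)`` where ``results`` is the
    long per-subject/per-method table consumed by
    :class:`~rvquant.comparison.MethodComparison`, ``measurements`` holds all
    simulated observer readings (2 observers x 2 replicates for the first
    ``RELIABILITY_N`` subjects, observer 1 only otherwise), and ``stacks``
    maps ``(subject, phase)`` to the rasterized masks when requested.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    child_seeds = ss.spawn(len(subjects))
    result_rows: List[dict] = []
    meas_rows: List[dict] = []
    stacks: Dict[Tuple[str, str], MaskStack] = {}
    for i, subject in enumerate(subjects):
        ed, es = phantom_pair(subject)
        stack_ed = rasterize_short_axis(ed, config.slice_thickness,
                                        config.pixel_size, phase="ED")
        stack_es = rasterize_short_axis(es, config.slice_thickness,
                                        config.pixel_size, phase="ES")
        if keep_stacks:
            stacks[(subject.id, "ED")] = stack_ed
            stacks[(subject.id, "ES")] = stack_es
        std_edv = disk_summation_volume(stack_ed).volume
        std_esv = disk_summation_volume(stack_es).volume

        in_reliability = i < RELIABILITY_N
        rng = np.random.default_rng(child_seeds[i])
        meas = simulate_measurements(
            subject, noise_sd=config.noise_sd,
            n_observers=2 if in_reliability else 1,
            n_replicates=2 if in_reliability else 1,
            rng=rng, observer_bias=config.observer_bias)
        meas_rows.extend(_measurement_rows(subject, meas))
        primary = next(m for m in meas if m.observer == 1 and m.replicate == 1)
        cpf_edv = cpf_volume(primary.Dd, primary.Ld)
        cpf_esv = cpf_volume(primary.Ds, primary.Ls)

        result_rows.append(_method_row(subject.id, subject.sex, subject.bsa,
                                       "standard", std_edv, std_esv, thresholds))
        result_rows.append(_method_row(subject.id, subject.sex, subject.bsa,
                                       "cpf", cpf_edv, cpf_esv, thresholds))
    return pd.DataFrame(result_rows), pd.DataFrame(meas_rows), stacks


def reliability_ratings(measurements: pd.DataFrame
                        ) -> Dict[str, Dict[str, np.ndarray]]:
    """Repeated formula-method ratings from the measurement table.

    Builds (n, 2) rating tables per quantity: ``intra`` pairs observer 1's
    two replicates, ``inter`` pairs observer 1 (replicate 1) with observer 2
    (replicate 1).  Only subjects with all four readings are used.
    """
    need = [(1, 1), (1, 2), (2, 1)]
    cols = {}
    for obs, rep in need:
        sub = measurements[(measurements["observer"] == obs)
                           & (measurements["replicate"] == rep)]
        cols[(obs, rep)] = sub.set_index("subject")
    common = cols[(1, 1)].index
    for key in need[1:]:
        common = common.intersection(cols[key].index)
    if len(common) == 0:
        return {}

    def volumes(obs_rep):
        t = cols[obs_rep].loc[common]
        edv = np.array([cpf_volume(d, l) for d, l in zip(t["Dd_cm"], t["Ld_cm"])])
        esv = np.array([cpf_volume(d, l) for d, l in zip(t["Ds_cm"], t["Ls_cm"])])
        ef = (edv - esv) * 100.0 / edv
        return edv, esv, ef

    v11, v12, v21 = volumes((1, 1)), volumes((1, 2)), volumes((2, 1))
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for qi, label in enumerate(("RV-EDV, mL", "RV-ESV, mL", "RV-EF, %")):
        out[label] = {
            "intra": np.column_stack([v11[qi], v12[qi]]),
            "inter": np.column_stack([v11[qi], v21[qi]]),
        }
    return out


def run_study(config: StudyConfig) -> StudyOutput:
    """Execute the full virtual study; write outputs if an output dir is set."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    subjects = sample_cohort(cohort_cfg)
    logger.info("scenario %s: simulated %d subjects (seed %d)",
                config.scenario, len(subjects), config.seed)
    results, measurements, stacks = quantify_cohort(
        subjects, cohort_cfg, config.thresholds,
        keep_stacks=config.export_masks or config.export_nifti)
    table = cohort_dataframe(subjects, seed=config.seed)
    reliability = reliability_ratings(measurements)
    report = MethodComparison(results, reliability=reliability).fit()

    for method in ("standard", "cpf"):
        sub = results[results["method"] == method]
        logger.info("%s: %d enlarged EDV, %d enlarged ESV, %d reduced EF",
                    method, int(sub["enlarged_edv"].sum()),
                    int(sub["enlarged_esv"].sum()),
                    int(sub["reduced_ef"].sum()))

    if config.output_dir is not None:
        _write_outputs(config, table, measurements, results, report, stacks)
    return StudyOutput(config=config, subjects=subjects, cohort_table=table,
                       measurements=measurements, results=results,
                       report=report)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=index)


def _write_outputs(config: StudyConfig, table, measurements, results,
                   report: ComparisonResults, stacks) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    with open(out / "config.json", "w") as fh:
        json.dump({"config_sha256": h, **config.to_dict()}, fh, indent=2,
                  default=str)
    _write_csv(table, out / "cohort.csv", h)
    _write_csv(measurements, out / "measurements.csv", h)
    _write_csv(results, out / "results.csv", h)
    _write_csv(report.agreement.reset_index(), out / "agreement_table.csv", h)
    if len(report.reliability):
        _write_csv(report.reliability.reset_index(),
                   out / "reliability_table.csv", h)
    roc_rows = []
    for key, res in report.roc.items():
        if res is None:
            continue
        for t, se, sp in zip(res.thresholds, res.sensitivity, res.specificity):
            roc_rows.append({"target": key, "threshold": t,
                             "sensitivity": se, "specificity": sp})
    if roc_rows:
        _write_csv(pd.DataFrame(roc_rows), out / "roc_curves.csv", h)
    report.save_json(out / "report.json", extra={"config_sha256": h,
                                                 "scenario": config.scenario,
                                                 "seed": config.seed})
    with open(out / "study.log", "w") as fh:
        fh.write(f"config_sha256={h}\nscenario={config.scenario}\n"
                 f"seed={config.seed}\nsubjects={len(table)}\n")
        fh.write(report.summary() + "\n")
    if stacks and (config.export_masks or config.export_nifti):
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for (sid, phase), stack in stacks.items():
            if config.export_masks:
                np.savez_compressed(
                    mask_dir / f"{sid}_{phase}.npz", data=stack.data,
                    pixel_size=stack.pixel_size,
                    slice_thickness=stack.slice_thickness,
                    x0=stack.x0, y0=stack.y0)
            if config.export_nifti:
                stack.to_nifti(mask_dir / f"{sid}_{phase}.nii.gz")
    if config.export_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for q in ("edvi", "esvi", "ef"):
            for kind, meth in (("scatter", report.plot_agreement),
                               ("bland_altman", report.plot_bland_altman)):
                ax = meth(q)
                ax.figure.savefig(out / f"{kind}_{q}.png", dpi=120)
                plt.close(ax.figure)
        for target in report.roc:
            if report.roc[target] is not None:
                ax = report.plot_roc(target)
                ax.figure.savefig(out / f"roc_{target}.png", dpi=120)
                plt.close(ax.figure)
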