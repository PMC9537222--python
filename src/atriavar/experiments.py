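"""End-to-end experiment drivers and reproducible configurations.

The full study chain is: Monte-Carlo population -> exclusion screen ->
regional clustering -> slab conductivity calibration -> heterogeneous
replicate slabs -> coupling analysis.  This module wires those stages
together behind a single configuration object so that every headline
quantity (stable-model count, restitution, CV variability,
homogeneous-vs-heterogeneous conductance agreement, regional APD90) can be
recomputed from scratch with one seed.

All randomness flows through seeds derived from ``ExperimentConfig.seed``
with fixed offsets; identical configurations give identical results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .crn import ConductanceScaling, PacingProtocol, apd90_restitution
from .cv import (CVTargets, calibrate_material, cv_variability,
                 load_cv_targets)
from .population import PopulationTable, build_population
from .regions import cluster_population, load_regional_specs
from .tissue import load_materials

__all__ = ["ExperimentConfig", "AcceptanceStudy", "run_reproduction",
           "TARGET_IDS"]

#: Total population size and stable count of the full-scale study design,
#: used to express a reduced-n stable fraction on the full-study scale.
FULL_POPULATION_N = 200_000

TARGET_IDS = ("t1", "t3", "t4", "t5", "t6", "t7")


@dataclass
class ExperimentConfig:
    """Serialisable description of a scaled study run."""

    seed: int = 1
    population_n: int = 500
    pacing_beats: int = 101
    restitution_bcls: tuple = (1000.0, 800.0)
    n_replicates: int = 10
    dt_tissue: float = 0.02
    cv_tol: float = 0.5
    ra_members_required: int = 200
    conductive_materials: tuple = ("RA", "CT", "PV", "BB/PM", "ISTMO",
                                  "SAN", "CS", "LA", "FO_RING")
    output_dir: str = "results"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("restitution_bcls", "conductive_materials"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


class AcceptanceStudy:
    """Lazily built, cached pipeline state shared between targets.

    Population, clustering and per-material calibrations are computed once
    per study instance; every quantity is produced by running the pipeline,
    never read from a table.
    """

    def __init__(self, config: ExperimentConfig | None = None,
                 progress: bool = False):
        self.config = config or ExperimentConfig()
        self.progress = progress
        self._pop: PopulationTable | None = None
        self._populations: dict | None = None
        self._calibrations: dict = {}
        self.targets: CVTargets = load_cv_targets()
        self.materials = load_materials()

    # -- stage accessors --------------------------------------------------
    @property
    def population(self) -> PopulationTable:
        if self._pop is None:
            cfg = self.config
            proto = PacingProtocol(n_beats=cfg.pacing_beats)
            self._pop = build_population(cfg.population_n, cfg.seed,
                                         protocol=proto,
                                         progress=self.progress)
        return self._pop

    @property
    def populations(self) -> dict:
        if self._populations is None:
            self._populations = cluster_population(
                self.population, load_regional_specs(), warn_empty=False)
        return self._populations

    def _calibration_tol(self, material_name: str) -> float:
        """CV tolerance that resolves the hom-vs-het sigma comparison.

        Near the solution sigma ~ CV^2, so a CV tolerance ``tol`` leaves a
        relative sigma slack of about 2*tol/CV per calibration.  For slow
        materials a fixed 0.5 cm/s tolerance alone permits hom-vs-het
        differences far above the 5% band (e.g. ~8.6% at 23 cm/s), so the
        tolerance is tightened so each calibration's sigma slack stays
        below 1.25%; the configured tolerance acts as a cap.
        """
        target = self.targets.longitudinal[material_name]
        return min(self.config.cv_tol, 0.00625 * target)

    def calibration(self, material_name: str, mode: str, sigma0=None):
        key = (material_name, mode)
        if key not in self._calibrations:
            mat = self.materials[material_name]
            res = calibrate_material(
                mat, self.targets, self.populations, self.population,
                mode=mode, seed=self.config.seed + 1000,
                tol=self._calibration_tol(material_name),
                dt=self.config.dt_tissue,
                sigma0=sigma0 if sigma0 is not None else 1.0,
                calibrate_transverse=False)
            self._calibrations[key] = res
        return self._calibrations[key]

    # -- targets ----------------------------------------------------------
    def stable_count_scaled(self) -> tuple[float, int]:
        """Stable fraction scaled to the full 200,000-member design."""
        pop = self.population
        frac = pop.n_stable / pop.n
        return frac * FULL_POPULATION_N, pop.n

    def restitution_reduction(self) -> tuple[float, int]:
        """Percent APD90 reduction from BCL 1000 ms to 800 ms (baseline)."""
        bcls = self.config.restitution_bcls
        pairs = dict(apd90_restitution(ConductanceScaling(), bcls,
                                       n_beats=self.config.pacing_beats))
        reduction = (pairs[bcls[0]] - pairs[bcls[1]]) / pairs[bcls[0]] * 100.0
        return reduction, self.config.pacing_beats

    def cv_sd(self, material_name: str) -> tuple[float, int]:
        """SD of longitudinal CV over heterogeneous replicate slabs."""
        cfg = self.config
        res = self.calibration(material_name, "heterogeneous",
                               sigma0=self._hom_sigma_hint(material_name))
        mat = dataclasses.replace(self.materials[material_name],
                                  sigma_L=res.sigma_L,
                                  sigma_T=res.sigma_L *
                                  self.materials[material_name].r)
        seeds = [cfg.seed + 2000 + k for k in range(cfg.n_replicates)]
        _, _, sd = cv_variability(mat, self.populations, self.population,
                                  seeds, dt=cfg.dt_tissue)
        return sd, cfg.n_replicates

    def _hom_sigma_hint(self, material_name):
        res = self._calibrations.get((material_name, "homogeneous"))
        return res.sigma_L if res else None

    def conductance_difference(self) -> tuple[float, int]:
        """Max relative hom-vs-het calibrated sigma_L difference (%)."""
        diffs = []
        for name in self.config.conductive_materials:
            hom = self.calibration(name, "homogeneous")
            het = self.calibration(name, "heterogeneous",
                                   sigma0=hom.sigma_L)
            diffs.append(abs(het.sigma_L - hom.sigma_L) / hom.sigma_L * 100.0)
        return float(max(diffs)), len(diffs)

    def ra_apd90(self) -> tuple[float, int]:
        """Mean single-cell APD90 of the clustered RA population.

        Extends the population in seeded batches until the RA region holds
        the configured number of members.
        """
        cfg = self.config
        need = cfg.ra_members_required
        batch = 1
        while self.populations["RA"].n < need:
            extra = build_population(
                200, cfg.seed + 3000 + batch,
                protocol=PacingProtocol(n_beats=cfg.pacing_beats),
                progress=self.progress)
            extra.df["model_id"] += self._pop.n
            self._pop = PopulationTable(
                df=pd.concat([self._pop.df, extra.df], ignore_index=True),
                checkpoints=np.vstack([self._pop.checkpoints,
                                       extra.checkpoints]),
                metadata=self._pop.metadata)
            self._populations = None
            batch += 1
        rpop = self.populations["RA"]
        return float(rpop.summary.loc["APD90", "mean"]), rpop.n


def run_reproduction(config: ExperimentConfig, target_id: str,
                     study: AcceptanceStudy | None = None) -> dict:
    """Recompute one headline quantity; returns value, n and provenance."""
    if target_id not in TARGET_IDS:
        raise ValueError(f"unknown target id {target_id!r}; "
                         f"expected one of {TARGET_IDS}")
    study = study or AcceptanceStudy(config)
    dispatch = {
        "t1": study.stable_count_scaled,
        "t3": study.restitution_reduction,
        "t4": lambda: study.cv_sd("CT"),
        "t5": lambda: study.cv_sd("RA"),
        "t6": study.conductance_difference,
        "t7": study.ra_apd90,
    }
    value, n = dispatch[target_id]()
    return {"target": target_id, "value": float(value), "n": int(n),
            "seed": config.seed}
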