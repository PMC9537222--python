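"""Monte-Carlo population of conductance-varied CRN models.

The population generator draws each of the nine conductance multipliers
independently and uniformly on [0, 3] (-100% to +200% of baseline), paces
every member to steady state (101 beats at BCL 1000 ms, -45 pA/pF for 1 ms),
records a 10-s quiescent tail, extracts biomarkers from the final beat and
applies the exclusion screen.  End-of-pacing states are kept as checkpoints
so tissue nodes can be initialised from their assigned member's steady
state.

A reduced-beat fast mode exists for quick exploratory runs and is flagged in
the table metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import (BiomarkerError, BiomarkerSet, StabilityReport,
                         check_stability, compute_biomarkers)
from .crn import N_STATES, ConductanceScaling, PacingProtocol, pace_cell

__all__ = ["PopulationTable", "sample_conductances", "build_population"]

_SCALING_COLS = ["s_gNa", "s_gTo", "s_gKur", "s_gKr", "s_gKs",
                 "s_gK1", "s_gCaL", "s_gNaK", "s_gNaCa"]
_BIOMARKER_COLS = list(BiomarkerSet.NAMES)


@dataclass
class PopulationTable:
    """One row per sampled member plus end-state checkpoints and metadata.

    ``df`` columns: model_id, the 9 multipliers, the 6 biomarkers (NaN for
    members without a measurable AP), ``stable`` and ``failure_reasons``.
    ``checkpoints[i]`` is the full 21-component state of member i at the end
    of its final beat.
    """

    df: pd.DataFrame
    checkpoints: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df["model_id"].duplicated().any():
            raise ValueError("model_ids must be unique")
        if len(self.checkpoints) != len(self.df):
            raise ValueError("one checkpoint per member required")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_stable(self) -> int:
        return int(self.df["stable"].sum())

    @property
    def stable(self) -> pd.DataFrame:
        return self.df[self.df["stable"]]

    def scaling(self, model_id: int) -> ConductanceScaling:
        row = self.df.loc[self.df["model_id"] == model_id].iloc[0]
        return ConductanceScaling(*[float(row[c]) for c in _SCALING_COLS])

    def checkpoint(self, model_id: int) -> np.ndarray:
        idx = self.df.index[self.df["model_id"] == model_id][0]
        return self.checkpoints[self.df.index.get_loc(idx)]

    def biomarkers(self, model_id: int) -> BiomarkerSet:
        row = self.df.loc[self.df["model_id"] == model_id].iloc[0]
        return BiomarkerSet(row["RMP"], row["APA"], row["APD20"],
                            row["APD50"], row["APD90"])

    # -- persistence (CSV table + npz checkpoint store) -------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.df.to_csv(prefix.with_suffix(".csv"), index=False)
        np.savez_compressed(prefix.with_suffix(".npz"),
                            checkpoints=self.checkpoints,
                            **{f"meta_{k}": np.asarray(v)
                               for k, v in self.metadata.items()
                               if np.isscalar(v)})

    @classmethod
    def load(cls, prefix: str | Path) -> "PopulationTable":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        with np.load(prefix.with_suffix(".npz")) as z:
            cps = z["checkpoints"]
            meta = {k[5:]: z[k].item() for k in z.files if k.startswith("meta_")}
        return cls(df, cps, meta)


def sample_conductances(n: int, seed: int) -> list[ConductanceScaling]:
    """Draw ``n`` multiplier sets, each uniform and independent on [0, 3]."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 3.0, size=(n, 9))
    return [ConductanceScaling(*row) for row in draws]


def build_population(n: int,
                     seed: int,
                     protocol: PacingProtocol | None = None,
                     scalings: Sequence[ConductanceScaling] | None = None,
                     stability_kwargs: dict | None = None,
                     fast: bool = False,
                     progress: bool = False) -> PopulationTable:
    """Sample, pace and screen ``n`` members; never aborts on a bad member.

    ``fast=True`` switches to 20 pre-beats and a 5-s quiescent tail for
    desk-scale exploration and is recorded in the metadata; full runs use
    the 101-beat protocol.  ``scalings`` may inject explicit multiplier sets
    (e.g. the all-baseline model), bypassing sampling.  Individual
    integration failures are marked unstable.
    """
    if protocol is None:
        protocol = (PacingProtocol(n_beats=20, quiescence=5000.0)
                    if fast else PacingProtocol())
    if scalings is None:
        scalings = sample_conductances(n, seed)
    elif len(scalings) != n:
        raise ValueError("len(scalings) must equal n")
    stability_kwargs = stability_kwargs or {}

    rows = []
    cps = np.zeros((n, N_STATES))
    for i, sc in enumerate(scalings):
        if progress and i % 25 == 0:
            print(f"pacing population: {i}/{n}", flush=True)
        last, quiet, end = pace_cell(sc, protocol)
        try:
            bm = compute_biomarkers(last) if last.ok else None
        except BiomarkerError:
            bm = None
        rep = check_stability(last, quiet, bm, **stability_kwargs)
        row = {"model_id": i}
        row.update(dict(zip(_SCALING_COLS, sc.as_array())))
        if bm is not None:
            row.update(dict(zip(_BIOMARKER_COLS, bm.as_array())))
        else:
            row.update({c: np.nan for c in _BIOMARKER_COLS})
        row["stable"] = rep.stable and bm is not None
        row["failure_reasons"] = ";".join(sorted(rep.failure_reasons))
        rows.append(row)
        cps[i] = end.y

    df = pd.DataFrame(rows, columns=["model_id", *_SCALING_COLS,
                                     *_BIOMARKER_COLS, "stable",
                                     "failure_reasons"])
    meta = {"n_sampled": n, "seed": seed, "fast_mode": fast,
            **{f"protocol_{f.name}": getattr(protocol, f.name)
               for f in dataclasses.fields(protocol)}}
    return PopulationTable(df, cps, meta)
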