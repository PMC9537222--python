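"""Regional clustering of the stable population into 8 atrial populations.

Each electrophysiological atrial region (RA, RAA, LA, LAA, AVR, CT/BBra,
BBla, PM) is characterised by experimental mean and SD of five biomarkers
(RMP, APA, APD20, APD50, APD90).  A stable model belongs to a region when
all five of its biomarkers lie inside the region's mean +/- 2 SD box
(duration biomarkers are lower-clipped at 0 ms).  Membership is
non-exclusive: one model can serve several regions.  Each regional
population also designates a "mean AP model": the member whose biomarker
vector is closest (z-scored Euclidean distance) to the regional population
means; it represents the region in homogeneous tissue models.

Pulmonary-vein tissue reuses the LA population, since no complete PV
biomarker characterisation exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["RegionalSpec", "RegionalPopulation", "REGIONS",
           "load_regional_specs", "regional_box", "cluster_population",
           "mean_ap_model"]

REGIONS = ("RA", "RAA", "LA", "LAA", "AVR", "CT/BBra", "BBla", "PM")
CLUSTER_BIOMARKERS = ("RMP", "APA", "APD20", "APD50", "APD90")
#: Biomarkers that are durations and therefore cannot be negative.
_DURATIONS = ("APD20", "APD50", "APD90")


@dataclass(frozen=True)
class RegionalSpec:
    """Experimental biomarker statistics for one atrial region."""

    region: str
    means: dict
    sds: dict

    def __post_init__(self) -> None:
        for b in CLUSTER_BIOMARKERS:
            if b not in self.means or b not in self.sds:
                raise ValueError(f"missing biomarker {b} for {self.region}")
            if self.sds[b] < 0:
                raise ValueError("SD must be non-negative")


@dataclass
class RegionalPopulation:
    """Clustered member set for one region plus its summary statistics."""

    region: str
    model_ids: np.ndarray
    summary: pd.DataFrame          # index: biomarker, columns: mean, sd
    mean_model_id: int | None

    @property
    def n(self) -> int:
        return len(self.model_ids)


def load_regional_specs(path=None) -> list[RegionalSpec]:
    """Load the packaged regional biomarker table (editable CSV)."""
    if path is None:
        path = resources.files("atriavar.data") / "regional_biomarkers.csv"
    df = pd.read_csv(path)
    specs = []
    for _, row in df.iterrows():
        means = {b: float(row[f"{b}_mean"]) for b in CLUSTER_BIOMARKERS}
        sds = {b: float(row[f"{b}_sd"]) for b in CLUSTER_BIOMARKERS}
        specs.append(RegionalSpec(str(row["region"]), means, sds))
    if len(specs) != len(REGIONS):
        raise ValueError("expected exactly 8 regional specs")
    return specs


def regional_box(spec: RegionalSpec) -> dict:
    """Per-biomarker acceptance interval [mean - 2 SD, mean + 2 SD].

    Duration biomarkers are lower-clipped at 0 ms.
    """
    box = {}
    for b in CLUSTER_BIOMARKERS:
        lo = spec.means[b] - 2.0 * spec.sds[b]
        hi = spec.means[b] + 2.0 * spec.sds[b]
        if b in _DURATIONS:
            lo = max(lo, 0.0)
        box[b] = (lo, hi)
    return box


def _summarise(df: pd.DataFrame) -> pd.DataFrame:
    stats = {}
    for b in ("RMP", "APA", "APD20", "APD50", "APD90", "TRI"):
        stats[b] = (df[b].mean(), df[b].std(ddof=1) if len(df) > 1 else 0.0)
    return pd.DataFrame(stats, index=["mean", "sd"]).T


def mean_ap_model(members: pd.DataFrame) -> int:
    """Member whose 5 biomarkers are z-score-closest to the member means.

    SD-zero biomarkers (single-member or degenerate populations) do not
    contribute to the distance.  Ties break to the lowest model_id.
    """
    if len(members) == 0:
        raise ValueError("empty regional population")
    members = members.sort_values("model_id")
    x = members[list(CLUSTER_BIOMARKERS)].to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if len(members) > 1 else np.ones(x.shape[1])
    sd = np.where(sd > 0, sd, np.inf)
    d = np.sqrt((((x - mu) / sd) ** 2).sum(axis=1))
    return int(members["model_id"].to_numpy()[int(np.argmin(d))])


def cluster_population(pop, specs=None, warn_empty: bool = True) -> dict:
    """Cluster the stable members of a population into regional populations.

    Membership requires every one of the five biomarkers to lie inside the
    region's mean +/- 2 SD box; a member may belong to several regions.
    Returns ``{region: RegionalPopulation}``.  An empty region produces a
    warning, not an error.
    """
    if specs is None:
        specs = load_regional_specs()
    stable = pop.stable
    out = {}
    for spec in specs:
        box = regional_box(spec)
        mask = np.ones(len(stable), dtype=bool)
        for b, (lo, hi) in box.items():
            v = stable[b].to_numpy(float)
            mask &= (v >= lo) & (v <= hi)
        members = stable[mask]
        if len(members) == 0:
            if warn_empty:
                import warnings
                warnings.warn(f"regional population {spec.region!r} is empty")
            out[spec.region] = RegionalPopulation(
                spec.region, np.array([], dtype=int), _summarise(members),
                None)
            continue
        out[spec.region] = RegionalPopulation(
            spec.region,
            members["model_id"].to_numpy(int),
            _summarise(members),
            mean_ap_model(members),
        )
    return out
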