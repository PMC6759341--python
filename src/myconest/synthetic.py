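"""Synthetic paired intact/disturbed OTU tables with planted structure.

The generator plants the two signals the analysis chain is meant to detect:

* occupancy nested along elevation — an OTU with tolerance tau occupies a
  plant when tau + noise clears a threshold that increases with elevation,
  so high-elevation communities are tolerance-filtered subsets of
  low-elevation ones;
* disturbance response driven by tolerance — in the disturbed member of each
  pair, an OTU's relative abundance is scaled by exp(-lambda * (1 - tau)),
  plus a small opportunist chance of appearing only after disturbance.

A null variant removes both signals and equalizes tolerances so every
downstream test sees exchangeable data (type-I-error calibration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountTable, DataError, PairedDesign, SampleMetadata

__all__ = ["HabitatSpec", "SimulationParams", "SyntheticDataset", "simulate_dataset", "simulate_null_dataset"]


@dataclass(frozen=True)
class HabitatSpec:
    name: str
    elevation_range: tuple[float, float]
    n_plants: int


DEFAULT_HABITATS = (
    HabitatSpec("grassland", (630.0, 660.0), 10),
    HabitatSpec("gully", (660.0, 850.0), 10),
    HabitatSpec("slope", (660.0, 850.0), 10),
)

# habitat-specific soil chemistry means: (ph, truog_p, ca, mg, k, cec, nh3_n,
# no3_n, total_n, colony_diameter); loose qualitative contrasts only
_SOIL_MEANS = {
    "grassland": (5.4, 12.0, 180.0, 40.0, 35.0, 12.0, 8.0, 4.0, 0.25, 110.0),
    "gully": (5.9, 7.0, 150.0, 32.0, 28.0, 11.0, 5.0, 3.5, 0.22, 95.0),
    "slope": (5.0, 11.0, 160.0, 35.0, 30.0, 10.0, 7.5, 3.8, 0.20, 60.0),
}
_SOIL_SDS = (0.2, 2.0, 25.0, 6.0, 5.0, 1.5, 1.5, 0.8, 0.05, 15.0)
_SOIL_FIELDS = (
    "ph", "truog_p", "ca", "mg", "k", "cec", "nh3_n", "no3_n", "total_n",
    "colony_diameter",
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for the paired-community simulator; defaults mirror the field design."""

    habitats: tuple[HabitatSpec, ...] = DEFAULT_HABITATS
    n_otus: int = 60
    tolerance_beta: tuple[float, float] = (2.0, 2.0)
    filter_strength: float = 0.45  # kappa: elevation -> occupancy threshold slope
    base_threshold: float = 0.2
    occupancy_noise_sd: float = 0.08
    reads_per_sample: int = 20_000
    abundance_lognormal: tuple[float, float] = (0.0, 1.0)
    disturbance_rate: float = 8.0  # lambda: abundance loss for sensitive OTUs
    opportunist_prob: float = 0.02  # gamma: absent OTU appears after disturbance
    opportunist_scale: float = 0.05
    seed: int = 0

    @property
    def n_plants(self) -> int:
        return sum(h.n_plants for h in self.habitats)

    def validate(self) -> None:
        if self.n_otus < 2 or self.n_plants < 2:
            raise DataError("need at least 2 OTUs and 2 plants")
        a, b = self.tolerance_beta
        if a <= 0 or b <= 0:
            raise DataError("tolerance Beta parameters must be positive")
        if self.filter_strength < 0 or self.disturbance_rate < 0:
            raise DataError("filter_strength and disturbance_rate must be >= 0")
        if not 0 <= self.opportunist_prob <= 1:
            raise DataError("opportunist_prob must be in [0, 1]")
        if self.reads_per_sample < 1:
            raise DataError("reads_per_sample must be positive")


@dataclass
class SyntheticDataset:
    table: CountTable
    metadata: list[SampleMetadata]
    design: PairedDesign
    truth: dict = field(default_factory=dict)


def _elevation_span(habitats: tuple[HabitatSpec, ...]) -> tuple[float, float]:
    lo = min(h.elevation_range[0] for h in habitats)
    hi = max(h.elevation_range[1] for h in habitats)
    return lo, hi


def _simulate(params: SimulationParams, tolerances: np.ndarray | None) -> SyntheticDataset:
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_otus = params.n_otus
    otu_ids = [f"OTU{k + 1:03d}" for k in range(n_otus)]

    a, b = params.tolerance_beta
    if tolerances is None:
        tau = rng.beta(a, b, size=n_otus)
        base_thr = params.base_threshold
    else:
        tau = np.asarray(tolerances, dtype=float)
        # homogeneous-tolerance null: centre the threshold so occupancy ~ 1/2
        base_thr = float(tau.mean())
    abundance = rng.lognormal(*params.abundance_lognormal, size=n_otus)

    # plants, elevations, metadata
    plant_ids: list[str] = []
    habitats: list[str] = []
    elevations: list[float] = []
    p = 0
    for hab in params.habitats:
        lo, hi = hab.elevation_range
        for _ in range(hab.n_plants):
            p += 1
            plant_ids.append(f"P{p:02d}")
            habitats.append(hab.name)
            elevations.append(float(rng.uniform(lo, hi)))
    n_plants = len(plant_ids)
    years = np.where(rng.permutation(n_plants) < n_plants // 2, 2015, 2016)

    e_lo, e_hi = _elevation_span(params.habitats)
    span = max(e_hi - e_lo, 1e-9)
    thresholds = base_thr + params.filter_strength * (np.asarray(elevations) - e_lo) / span

    # occupancy: tolerance + noise clears the elevation-dependent threshold
    noise = rng.normal(0.0, params.occupancy_noise_sd, size=(n_otus, n_plants))
    occupancy = (tau[:, None] + noise) > thresholds[None, :]
    empty = np.flatnonzero(~occupancy.any(axis=0))
    if len(empty):
        raise DataError(
            f"infeasible parameters: no OTU occupies plant(s) "
            f"{[plant_ids[i] for i in empty]}; lower filter_strength/base_threshold"
        )

    survival = np.exp(-params.disturbance_rate * (1.0 - tau))
    counts = np.zeros((n_otus, 2 * n_plants), dtype=np.int64)
    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    pairs: dict[str, tuple[str, str]] = {}
    for s in range(n_plants):
        occ = occupancy[:, s]
        w_intact = abundance * occ
        opportunists = (~occ) & (rng.random(n_otus) < params.opportunist_prob)
        w_dist = abundance * occ * survival + abundance * opportunists * params.opportunist_scale
        if w_dist.sum() <= 0:
            raise DataError(f"infeasible parameters: empty disturbed community at {plant_ids[s]}")
        sid_i, sid_d = f"{plant_ids[s]}-I", f"{plant_ids[s]}-D"
        counts[:, 2 * s] = rng.multinomial(params.reads_per_sample, w_intact / w_intact.sum())
        counts[:, 2 * s + 1] = rng.multinomial(params.reads_per_sample, w_dist / w_dist.sum())
        sample_ids.extend((sid_i, sid_d))
        pairs[plant_ids[s]] = (sid_i, sid_d)
        soil_mu = _SOIL_MEANS[habitats[s]] if habitats[s] in _SOIL_MEANS else _SOIL_MEANS["grassland"]
        soil = {
            name: float(rng.normal(mu, sd))
            for name, mu, sd in zip(_SOIL_FIELDS, soil_mu, _SOIL_SDS)
        }
        for treatment, sid in (("intact", sid_i), ("disturbed", sid_d)):
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    plant_id=plant_ids[s],
                    treatment=treatment,
                    habitat=habitats[s],
                    elevation=elevations[s],
                    collection_year=int(years[s]),
                    **soil,
                )
            )

    table = CountTable(otu_ids, sample_ids, counts)
    design = PairedDesign(pairs)
    truth = {
        "tolerance": pd.Series(tau, index=otu_ids, name="tolerance"),
        "abundance": pd.Series(abundance, index=otu_ids, name="abundance"),
        "occupancy": pd.DataFrame(
            occupancy.astype(int), index=otu_ids, columns=plant_ids
        ),
        "params": params,
    }
    return SyntheticDataset(table=table, metadata=metadata, design=design, truth=truth)


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Simulate a paired dataset with nested occupancy and tolerance-driven
    disturbance response. Deterministic given ``params.seed``."""
    return _simulate(params or SimulationParams(), tolerances=None)


def simulate_null_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Signal-free variant for type-I-error calibration.

    Removes the elevation filter (kappa = 0), makes disturbance independent
    of tolerance (lambda = 0, gamma = 0), and equalizes all tolerances at the
    Beta mean so occupancy is i.i.d. across OTUs and plants — matching the
    exchangeability assumptions of every downstream test.
    """
    params = params or SimulationParams()
    a, b = params.tolerance_beta
    null_params = dataclasses.replace(
        params, filter_strength=0.0, disturbance_rate=0.0, opportunist_prob=0.0
    )
    tau = np.full(params.n_otus, a / (a + b))
    return _simulate(null_params, tolerances=tau)
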