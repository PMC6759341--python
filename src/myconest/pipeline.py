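"""End-to-end orchestration of the community analysis.

Stage order mirrors the study workflow: depth standardization, collection-year
PERMANOVA, per-plant diversity and factor correlations, habitat Tukey letters,
Mantel sweeps, habitat PERMANOVA, packed matrix + NODF significance, and
per-OTU disturbance profiles with the robustness~occurrence fit.

Combined-pair tables feed the diversity/nestedness analyses; the paired
per-treatment table feeds the Bray-Curtis impact and disturbance profiles.
Single-variable environmental factors are converted to absolute-difference
distance matrices for the Mantel sweep.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CountTable,
    DataError,
    PairedDesign,
    SampleMetadata,
    combine_paired,
    presence_absence,
    read_count_table,
    read_metadata,
    standardize_depth,
    write_count_table,
)
from .disturbance import disturbance_profiles, robustness_occurrence_fit
from .diversity import bray_curtis, dissimilarity_matrix, diversity_table
from .nestedness import nodf_significance, pack_matrix
from .perm_stats import (
    anova_tukey,
    euclidean_distance_matrix,
    mantel_test,
    pearson_correlation,
    permanova_oneway,
)

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    counts: str
    metadata: str
    outdir: str
    counts_format: str = "tsv"
    depth: int = 10_000
    n_perm: int = 9_999
    n_null: int = 1_000
    alpha: float = 0.05
    seed: int = 0
    shannon_base: float | None = None  # natural log
    mantel_alternative: str = "greater"
    log_transform: str = "cellwise"
    shortfall: str = "error"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"counts", "metadata", "outdir"} - set(raw)
        if missing:
            raise DataError(f"config missing required key(s): {sorted(missing)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _plant_metadata(
    metadata: list[SampleMetadata], design: PairedDesign
) -> dict[str, SampleMetadata]:
    """One metadata record per plant (the intact member; pairs agree on
    habitat/elevation by construction)."""
    by_sample = {m.sample_id: m for m in metadata}
    return {plant: by_sample[pair[0]] for plant, pair in design.pairs.items()}


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole chain and write one artifact per stage under ``outdir``.

    Returns a dict of in-memory stage results. Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts from completed stages
    are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name: str):
        def deco(fn):
            try:
                results[name] = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            return results[name]

        return deco

    rng = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ("standardize", "mantel", "permanova_year", "permanova_habitat", "nodf"),
            rng.spawn(5),
        )
    }

    @stage("inputs")
    def _load():
        table = read_count_table(config.counts, format=config.counts_format)
        metadata = read_metadata(config.metadata)
        design = PairedDesign.from_metadata(metadata)
        design.validate_against(metadata)
        return {"table": table, "metadata": metadata, "design": design}

    table: CountTable = results["inputs"]["table"]
    metadata: list[SampleMetadata] = results["inputs"]["metadata"]
    design: PairedDesign = results["inputs"]["design"]

    # 1. depth standardization
    @stage("standardize")
    def _standardize():
        std = standardize_depth(
            table, depth=config.depth, seed=seeds["standardize"],
            on_shortfall=config.shortfall,
        )
        write_count_table(std, outdir / "standardized_table.tsv")
        return std

    std: CountTable = results["standardize"]
    combined = combine_paired(std, design)
    plant_meta = _plant_metadata(metadata, design)
    plants = combined.sample_ids
    dm = dissimilarity_matrix(combined)
    dm.to_dataframe().to_csv(outdir / "combined_bray_curtis.tsv", sep="\t")

    # 2. collection-year PERMANOVA on combined pairs
    @stage("year_permanova")
    def _year():
        years = [str(plant_meta[p].collection_year) for p in plants]
        res = permanova_oneway(
            dm, years, n_perm=config.n_perm, seed=seeds["permanova_year"]
        )
        _dump_json(outdir / "year_permanova.json", dataclasses.asdict(res) | {"factor": "collection_year"})
        return res

    # 3. per-plant diversity + correlations vs environmental factors
    @stage("diversity_correlations")
    def _diversity():
        div = diversity_table(combined, base=config.shannon_base)
        paired_bc = [
            bray_curtis(std.column(i), std.column(d))
            for i, d in (design.pairs[p] for p in plants)
        ]
        div["paired_bray_curtis"] = paired_bc
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        factors = _factor_table(plant_meta, plants)
        rows = []
        for factor in factors.columns:
            x = factors[factor].to_numpy()
            for response in ("richness", "shannon", "paired_bray_curtis"):
                y = div[response].to_numpy(dtype=float)
                try:
                    cor = pearson_correlation(x, y)
                except DataError:
                    continue
                rows.append(
                    {"factor": factor, "response": response, "r": cor.r, "p": cor.p, "n": cor.n}
                )
        corr = pd.DataFrame(rows)
        corr.to_csv(outdir / "factor_correlations.tsv", sep="\t", index=False)
        return {"diversity": div, "correlations": corr}

    div = results["diversity_correlations"]["diversity"]

    # 4. habitat ANOVA + Tukey letters for richness, Shannon, paired BC
    @stage("habitat_tukey")
    def _tukey():
        habitats = [plant_meta[p].habitat for p in plants]
        out = {}
        frames = []
        for response in ("richness", "shannon", "paired_bray_curtis"):
            res = anova_tukey(
                div[response].to_numpy(dtype=float), habitats, alpha=config.alpha
            )
            out[response] = res
            frame = res.summary.copy()
            frame.insert(0, "response", response)
            frames.append(frame)
        pd.concat(frames).to_csv(outdir / "habitat_tukey.tsv", sep="\t", index=False)
        return out

    # 5. Mantel: community distance vs each factor's distance matrix
    @stage("mantel")
    def _mantel():
        factors = _factor_table(plant_meta, plants)
        rows = []
        for i, factor in enumerate(factors.columns):
            fd = euclidean_distance_matrix(factors[factor].to_numpy(), plants)
            try:
                res = mantel_test(
                    dm, fd, n_perm=config.n_perm, seed=seeds["mantel"] + i,
                    alternative=config.mantel_alternative,
                )
            except DataError:
                continue
            rows.append(
                {"factor": factor, "r": res.r, "p": res.p,
                 "n_perm": res.n_perm, "seed": res.seed}
            )
        frame = pd.DataFrame(rows)
        frame.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
        return frame

    # 6. habitat PERMANOVA
    @stage("habitat_permanova")
    def _habitat():
        habitats = [plant_meta[p].habitat for p in plants]
        res = permanova_oneway(
            dm, habitats, n_perm=config.n_perm, seed=seeds["permanova_habitat"]
        )
        _dump_json(outdir / "habitat_permanova.json", dataclasses.asdict(res) | {"factor": "habitat"})
        return res

    # 7. packed presence-absence matrix + NODF significance
    @stage("nestedness")
    def _nest():
        pa = presence_absence(combined)
        packed = pack_matrix(pa.counts)
        packed.to_dataframe(pa.otu_ids, pa.sample_ids).to_csv(
            outdir / "packed_matrix.tsv", sep="\t", index_label="otu_id"
        )
        pd.DataFrame(
            {
                "axis": ["row"] * len(packed.row_order) + ["column"] * len(packed.column_order),
                "packed_index": list(range(len(packed.row_order))) + list(range(len(packed.column_order))),
                "original_index": list(packed.row_order) + list(packed.column_order),
                "id": [pa.otu_ids[i] for i in packed.row_order]
                + [pa.sample_ids[j] for j in packed.column_order],
            }
        ).to_csv(outdir / "packed_matrix_orders.tsv", sep="\t", index=False)
        out = {}
        for stat in ("columns", "total"):
            res = nodf_significance(
                pa.counts, n_null=config.n_null, seed=seeds["nodf"], statistic=stat
            )
            out[stat] = res
        _dump_json(
            outdir / "nodf.json",
            {stat: dataclasses.asdict(res) for stat, res in out.items()},
        )
        return out

    # 8. disturbance profiles + robustness~occurrence fit
    @stage("disturbance")
    def _dist():
        profiles = disturbance_profiles(std, design, transform=config.log_transform)
        profiles.to_csv(outdir / "disturbance_profiles.tsv", sep="\t", index=False)
        fit = robustness_occurrence_fit(profiles)
        _dump_json(outdir / "robustness_fit.json", dataclasses.asdict(fit))
        return {"profiles": profiles, "fit": fit}

    _dump_json(
        outdir / "run_config.json",
        {"version": __version__, "config": config.to_dict(), "stage_seeds": seeds},
    )
    return results


def _factor_table(plant_meta: dict[str, SampleMetadata], plants: list[str]) -> pd.DataFrame:
    """Numeric factors shared by every plant, aligned with ``plants``."""
    per_plant = [plant_meta[p].numeric_factors() for p in plants]
    common = set(per_plant[0])
    for f in per_plant[1:]:
        common &= set(f)
    return pd.DataFrame(
        {name: [f[name] for f in per_plant] for name in sorted(common)}, index=plants
    )


def _dump_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
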