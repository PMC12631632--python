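"""End-to-end, configuration-driven analysis runs.

A :class:`RunConfig` pins every choice (inputs, grouping, metric,
permutation counts, seeds, ladder ratios) so a run is fully reproducible;
:func:`run_pipeline` executes validation, diversity tables, pairwise
Fst/Nm, AMOVA, the Mantel test against geography, NJ/PCoA, the LDSS core
ladder and core validation, writing machine-readable TSV/JSON/Newick
outputs plus a log of seeds and stage timings.  Any stage failure raises
:class:`StageError` naming the stage.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_collection, differentiation, diversity, genotype_io, tree_ordination

__all__ = ["RunConfig", "StageError", "run_pipeline", "fst_nm_table"]


class StageError(RuntimeError):
    """Pipeline failure wrapper: carries the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genotypes: str
    metadata: str
    out_dir: str
    format_name: str = "long_tsv"
    grouping: str = "by_species"
    metric: str = "dice"
    n_perm: int = 999
    seed: int = 0
    ladder_ratios: tuple[float, ...] = core_collection.DEFAULT_RATIOS
    tree_level: str = "accession"  # or "population"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "ladder_ratios" in data:
            data["ladder_ratios"] = tuple(data["ladder_ratios"])
        return cls(**data)


def fst_nm_table(fst: pd.DataFrame) -> pd.DataFrame:
    """Square table with Fst below the diagonal and the island-model Nm
    above it (the customary combined layout)."""
    nm = differentiation.nm_from_fst(fst)
    out = fst.copy().astype(float)
    labels = list(fst.index)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                out.iloc[i, j] = nm.iloc[i, j]
            elif i == j:
                out.iloc[i, j] = 0.0
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {asdict(cfg)}"]
    summary: dict = {"seed": cfg.seed}
    t0 = time.time()

    def run_stage(name, fn):
        try:
            start = time.time()
            result = fn()
            log.append(f"{name}: ok ({time.time() - start:.2f}s)")
            return result
        except Exception as exc:  # noqa: BLE001 - report stage then re-raise
            log.append(f"{name}: FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log) + "\n")
            raise StageError(name, exc) from exc

    ds = run_stage(
        "read",
        lambda: genotype_io.read_genotypes(
            cfg.genotypes, cfg.format_name, metadata=cfg.metadata
        ),
    )

    def _validate():
        report = genotype_io.validate_dataset(ds)
        pd.DataFrame(report.issues, columns=["code", "message"]).to_csv(
            out / "validation.tsv", sep="\t", index=False
        )
        return report

    run_stage("validate", _validate)

    def _diversity():
        results = {}
        for grouping in ("by_species", "by_population"):
            summ = diversity.diversity_table(ds, grouping)
            summ.to_locus_table().to_csv(out / f"diversity_locus_{grouping}.tsv", sep="\t")
            summ.per_group.to_csv(out / f"diversity_group_{grouping}.tsv", sep="\t")
            results[grouping] = summ
        ft = genotype_io.allele_frequencies(ds, "by_species")
        diversity.high_frequency_alleles(ft).to_csv(
            out / "high_frequency_alleles.tsv", sep="\t", index=False
        )
        return results

    div = run_stage("diversity", _diversity)
    summary["mean_He"] = float(div["by_species"].overall["He"])
    summary["mean_PIC"] = float(div["by_species"].overall["PIC"])

    def _diff():
        res = {}
        for level in ("species", "population"):
            fst, p = differentiation.pairwise_fst(
                ds, level, n_perm=cfg.n_perm, seed=cfg.seed
            )
            fst_nm_table(fst).to_csv(out / f"fst_nm_{level}.tsv", sep="\t")
            p.to_csv(out / f"fst_p_{level}.tsv", sep="\t")
            res[level] = fst
        return res

    fst_matrices = run_stage("differentiation", _diff)

    def _amova():
        res = differentiation.amova(
            ds, ("species_group", "population_id"), n_perm=cfg.n_perm, seed=cfg.seed
        )
        res.table.to_csv(out / "amova.tsv", sep="\t")
        return res

    amova_res = run_stage("amova", _amova)
    summary["amova_phi"] = amova_res.phi
    summary["amova_p"] = amova_res.p_values

    def _mantel():
        geo = differentiation.geo_distance_matrix(ds.meta)
        # population-level genetic distance: Phi-Fst between populations
        gen = fst_matrices["population"].loc[geo.index, geo.index]
        res = differentiation.mantel(gen, geo, n_perm=cfg.n_perm, seed=cfg.seed)
        (out / "mantel.json").write_text(
            json.dumps(
                {"r": res.r, "r2": res.r2, "p": res.p, "n_permutations": res.n_permutations},
                indent=2,
            )
        )
        return res

    mantel_res = run_stage("mantel", _mantel)
    summary["mantel_r2"] = mantel_res.r2
    summary["mantel_p"] = mantel_res.p

    def _tree():
        bm = genotype_io.to_binary_matrix(ds)
        dist = tree_ordination.genetic_distance(bm, cfg.metric, undefined="mean")
        if cfg.tree_level == "population":
            dist_t = fst_matrices["population"]
        else:
            dist_t = dist
        tree = tree_ordination.nj_tree(dist_t)
        (out / "nj_tree.nwk").write_text(tree_ordination.write_newick(tree) + "\n")
        ord_ = tree_ordination.pcoa(dist, n_axes=3)
        coords = ord_.coordinates.copy()
        coords.to_csv(out / "pcoa.tsv", sep="\t")
        return dist

    dist = run_stage("tree_pcoa", _tree)

    def _core():
        lcfg = core_collection.LdssConfig(
            target_ratios=tuple(cfg.ladder_ratios), metric=cfg.metric
        )
        ladder = core_collection.build_ladder(ds, lcfg, distance=dist)
        ladder.to_frame().to_csv(out / "core_ladder.tsv", sep="\t")
        chosen = core_collection.select_core(ladder)
        pd.Series(chosen.members, name="accession_id").to_csv(
            out / "core_members.tsv", sep="\t", index=False
        )
        validation = core_collection.validate_core(
            ds, chosen.members, metric=cfg.metric
        )
        validation.tests.to_csv(out / "core_validation.tsv", sep="\t")
        (out / "core_tree.nwk").write_text(validation.core_tree_newick + "\n")
        return ladder, chosen

    ladder, chosen = run_stage("core", _core)
    summary["core_size"] = chosen.size
    summary["core_ratio"] = chosen.ratio
    summary["core_Ra"] = chosen.ra

    log.append(f"total: {time.time() - t0:.2f}s")
    (out / "run.log").write_text("\n".join(log) + "\n")

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, float) and math.isnan(obj):
            return None
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    (out / "summary.json").write_text(json.dumps(_clean(summary), indent=2))
    return summary
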