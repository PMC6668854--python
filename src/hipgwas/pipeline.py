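"""End-to-end orchestration from a single validated configuration.

Stages run in a fixed order — simulate (optional) -> qc -> structure -> scan
-> clump -> region -> tables -> models — each writing a TSV into the output
directory; a JSON run manifest records the config hash, seed, stage timings
and output checksums so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, contingency, ld, models, popstruct, qc, region
from .io_formats import (
    add_phenotype_classes,
    case_control_status,
    read_cohort,
    read_fragment_table,
    read_ped_map,
)
from .simulate import SimConfig, make_fragment_table, simulate_cohort, write_fixtures

STAGES = ("simulate", "qc", "structure", "scan", "clump", "region", "tables", "models")


@dataclass
class PipelineConfig:
    out_dir: str = "hipgwas_run"
    seed: int = 0
    # inputs; ignored when simulate=True
    ped: str | None = None
    map: str | None = None
    cohort: str | None = None
    fragment: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    case_definition: str = "relaxed"
    qc_thresholds: dict = field(default_factory=dict)
    k_max: int = 6
    mds_axes: int = 2
    n_perm: int = 500
    region_n_perm: int = 2000
    region_chrom: str | None = None
    clump_p: float = 5e-5
    clump_r2: float = 0.70
    clump_distance: float = 7.5e6
    meff_window: int = 1000
    meff_c: float = 0.995
    force: bool = False

    KNOWN = None  # filled after definition

    def validate(self) -> None:
        if self.case_definition not in ("strict", "moderate_severe", "relaxed"):
            raise ValueError(f"unknown case_definition {self.case_definition!r}")
        if not self.simulate:
            for name in ("ped", "map", "cohort"):
                if getattr(self, name) is None:
                    raise ValueError(f"config requires {name!r} when simulate is false")
        for name in ("clump_p", "clump_r2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} out of range (0, 1]: {v}")
        if self.n_perm < 0 or self.region_n_perm < 0:
            raise ValueError("permutation counts must be >= 0")


PipelineConfig.KNOWN = {f.name for f in dataclasses.fields(PipelineConfig)} - {"KNOWN"}


def validate_config(path) -> PipelineConfig:
    """Load + schema-validate a YAML config; unknown keys are named errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - PipelineConfig.KNOWN
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: tuple = STAGES) -> dict:
    """Execute the requested stages; returns the run manifest (also written).

    Any stage failure aborts with the stage name; previously written outputs
    are inventoried in the manifest on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = round(time.time() - t0, 3)
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    try:
        if "simulate" in stages and config.simulate:
            t0 = time.time()
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            gm, cohort, truth = simulate_cohort(sim_cfg)
            causal = [gm.snps.loc[i, "snp_id"] for i, _o, _m in sim_cfg.causal_loci]
            fragment = make_fragment_table(
                gm, cohort, causal[0], causal[-1], target_rho=0.65, seed=config.seed + 1
            )
            write_fixtures(gm, cohort, out / "input", fragment=fragment, overwrite=config.force or True)
            state.update(gm=gm, cohort=cohort, truth=truth, fragment=fragment, sim_cfg=sim_cfg)
            record("simulate", t0, [out / "input" / f for f in ("genotypes.ped", "genotypes.map", "cohort.tsv", "fragment.tsv")])
        elif not config.simulate:
            gm = read_ped_map(config.ped, config.map)
            cohort = read_cohort(config.cohort)
            state.update(gm=gm, cohort=cohort)
            if config.fragment:
                state["fragment"] = read_fragment_table(config.fragment)

        if "qc" in stages:
            t0 = time.time()
            thr = qc.QcThresholds(**config.qc_thresholds)
            gm_qc, report = qc.apply_qc(state["gm"], state["cohort"], thr)
            report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
            state["gm_qc"] = gm_qc
            record("qc", t0, [out / "qc_report.tsv"])

        gm_use = state.get("gm_qc", state.get("gm"))
        cohort = state.get("cohort")
        if cohort is not None:
            cohort = add_phenotype_classes(cohort).set_index("dog_id").loc[gm_use.samples].reset_index()
            y = np.array(
                [
                    case_control_status(l, r, config.case_definition)
                    for l, r in zip(cohort["hip_left"], cohort["hip_right"])
                ]
            )
            state["y"] = y
            state["cohort_aligned"] = cohort

        if "structure" in stages:
            t0 = time.time()
            grm = popstruct.compute_grm(gm_use)
            coords = popstruct.mds_coordinates(grm, dims=config.mds_axes)
            clusters = popstruct.assign_clusters(grm, k_max=config.k_max, n_axes=config.mds_axes, seed=config.seed)
            pd.DataFrame(
                {"dog_id": gm_use.samples, "cluster": clusters.labels}
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            pd.DataFrame(
                coords, columns=[f"mds{i+1}" for i in range(coords.shape[1])]
            ).assign(dog_id=gm_use.samples).to_csv(out / "mds.tsv", sep="\t", index=False)
            state.update(grm=grm, clusters=clusters)
            record("structure", t0, [out / "clusters.tsv", out / "mds.tsv"])

        if "scan" in stages:
            t0 = time.time()
            cov_parts = []
            coh = state["cohort_aligned"]
            cov_parts.append((coh["sex"].astype(str) == "2").to_numpy(float)[:, None])
            if "clusters" in state:
                cov_parts.append(popstruct.cluster_covariates(state["clusters"].labels))
            if coh["batch"].nunique() > 1:
                cov_parts.append(
                    pd.get_dummies(coh["batch"], drop_first=True).to_numpy(float)
                )
            covariates = np.column_stack(cov_parts) if cov_parts else None
            scan = assoc.association_scan(
                gm_use,
                state["y"],
                covariates=covariates,
                kinship=state.get("grm"),
                n_perm=config.n_perm,
                seed=config.seed,
            )
            meff = assoc.simpleM_meff(gm_use, window=config.meff_window, variance_fraction=config.meff_c)
            bonf, eff = assoc.significance_thresholds(0.05, gm_use.n_snps, meff.m_eff)
            scan.attrs["m_eff"] = meff.m_eff
            scan.to_csv(out / "assoc.tsv", sep="\t", index=False)
            with open(out / "thresholds.json", "w") as fh:
                json.dump({"bonferroni": bonf, "effective": eff, "m_eff": meff.m_eff}, fh)
            state["scan"] = scan
            record("scan", t0, [out / "assoc.tsv", out / "thresholds.json"])

        if "clump" in stages and "scan" in state:
            t0 = time.time()
            clumps = ld.clump_markers(
                state["scan"],
                gm_use,
                p_threshold=config.clump_p,
                r2_threshold=config.clump_r2,
                max_distance=config.clump_distance,
            )
            clumps.to_frame().to_csv(out / "clumps.tsv", sep="\t", index=False)
            state["clumps"] = clumps
            record("clump", t0, [out / "clumps.tsv"])

        if "region" in stages:
            t0 = time.time()
            chrom = config.region_chrom
            if chrom is None and "clumps" in state and state["clumps"].n_clumps:
                index_snp = state["clumps"].clumps[0][0]
                chrom = gm_use.snps.set_index("snp_id").loc[index_snp, "chrom"]
            if chrom is not None:
                idx = np.flatnonzero((gm_use.snps["chrom"] == str(chrom)).to_numpy())
                sub = gm_use.subset(None, idx)
                ok = np.isfinite(state["y"])
                sub_cc = sub.subset(np.flatnonzero(ok), None)
                strata = state["cohort_aligned"].loc[ok, "batch"].to_numpy()
                dist, table = region.max_m2_permutation(
                    sub_cc,
                    state["y"][ok].astype(int),
                    strata,
                    n_perm=config.region_n_perm,
                    seed=config.seed,
                )
                table.to_csv(out / "region_cmh.tsv", sep="\t", index=False)
                with open(out / "region_null.json", "w") as fh:
                    json.dump(
                        {"mean_max_m2": dist.mean, "q2.5": dist.q2_5, "q97.5": dist.q97_5, "n_perm": dist.n_perm},
                        fh,
                    )
                state["region"] = (dist, table)
                record("region", t0, [out / "region_cmh.tsv", out / "region_null.json"])

        if "tables" in stages and "fragment" in state:
            t0 = time.time()
            frag = state["fragment"].set_index("dog_id").loc[gm_use.samples].reset_index()
            coh = state["cohort_aligned"]
            combined = contingency.combine_two_snp_genotypes(
                frag["snp1_genotype"].to_numpy(), frag["snp2_genotype"].to_numpy()
            )
            freq = contingency.frequency_table(
                pd.Series(frag["deletion_alleles"].to_numpy(), name="deletion"),
                pd.Series(coh["phenotype"].to_numpy(), name="phenotype"),
            )
            freq.to_csv(out / "deletion_frequencies.tsv", sep="\t")
            state["combined"] = combined
            record("tables", t0, [out / "deletion_frequencies.tsv"])

        if "models" in stages and "fragment" in state and "combined" in state:
            t0 = time.time()
            frag = state["fragment"].set_index("dog_id").loc[gm_use.samples].reset_index()
            y = state["y"]
            ok = np.isfinite(y) & pd.notna(state["combined"])
            result = models.compare_risk_models(
                y[ok].astype(int),
                frag.loc[ok, "deletion_alleles"].to_numpy(),
                state["combined"][ok],
            )
            report = pd.DataFrame(
                [
                    {
                        "model": "full",
                        "residual_df": result["full"].df_residual,
                        "residual_deviance": result["full"].residual_deviance,
                        "auc": result["roc"].auc_full,
                    },
                    {
                        "model": "reduced",
                        "residual_df": result["reduced"].df_residual,
                        "residual_deviance": result["reduced"].residual_deviance,
                        "auc": result["roc"].auc_reduced,
                    },
                ]
            )
            report["delta_deviance"] = result["deviance"].delta_deviance
            report["delta_df"] = result["deviance"].df
            report["deviance_p"] = result["deviance"].p
            report["delong_z"] = result["roc"].z
            report["delong_p"] = result["roc"].p_one_sided
            report.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
            state["models"] = result
            record("models", t0, [out / "model_comparison.tsv"])
    except Exception as err:  # annotate the failing stage for the operator
        manifest["failed"] = repr(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["state"] = state
    return manifest
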