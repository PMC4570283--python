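"""End-to-end orchestration of the analysis stages from one TOML config.

A run config names the stages to execute (in any order; they are re-sorted
into dependency order), the population roles for each analysis, and every
module parameter.  Each stage writes its outputs under the configured output
directory and the run finishes with a manifest recording package version,
seeds, input checksums and per-stage output checksums, so deterministic
stages are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .branch import pbs_scan
from .datasets import GenotypeDataset
from .f3 import f3_admixture, f3_outgroup
from .io import read_genotypes, write_truth, write_vcf
from .ld_ne import bin_r2, divergence_matrix, ne_trajectory
from .qc import ld_prune, remove_related
from .simulate import generate_tree_genotypes, haplotypes_to_genotypes, simulate_ld_haplotypes
from .trees import PopulationTree
from .wright_fisher import SimConfig, run_ensemble, scenario_actn3, scenario_lct

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate-genotypes",
    "simulate-ld",
    "qc",
    "pbs-scan",
    "f3",
    "ld-ne",
    "divergence-tree",
    "wf-sim",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``examples/pipeline.toml``)."""

    stages: list[str]
    output_dir: Path
    seed: int = 0
    input_path: Path | None = None
    input_format: str | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        run = raw.pop("run", {})
        stages = run.get("stages", [])
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}")
        return cls(
            stages=stages,
            output_dir=Path(run.get("output_dir", "isodrift_out")),
            seed=int(run.get("seed", 0)),
            input_path=Path(run["input"]) if "input" in run else None,
            input_format=run.get("input_format"),
            params=raw,
        )

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage.replace("-", "_"), {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _tree_from_params(spec: dict) -> PopulationTree:
    return PopulationTree.from_dict(
        spec.get("root", "root"),
        {c: (p[0], float(p[1]), float(p[2])) for c, p in spec["branches"].items()},
        root_spectrum=tuple(spec.get("root_spectrum", ("uniform", 0.05, 0.95))),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    dataset: GenotypeDataset | None = None
    haplotypes = hap_map = None

    if config.input_path is not None:
        dataset = read_genotypes(config.input_path, config.input_format)
        manifest["input"] = {str(config.input_path): _sha256(config.input_path)}

    for stage in sorted(config.stages, key=STAGE_ORDER.index):
        p = config.stage_params(stage)
        outputs: list[Path] = []
        logger.info("stage %s: start", stage)
        try:
            if stage == "simulate-genotypes":
                tree = _tree_from_params(p["tree"])
                dataset, truth = generate_tree_genotypes(
                    tree,
                    n_loci=int(p.get("n_loci", 20000)),
                    n_per_pop=int(p.get("n_per_pop", 25)),
                    seed=int(p.get("seed", config.seed)),
                )
                vcf_path, truth_path = out / "synthetic.vcf", out / "synthetic.truth.json"
                write_vcf(dataset, vcf_path)
                write_truth(truth, truth_path)
                outputs += [vcf_path, truth_path, vcf_path.with_suffix(".pops")]

            elif stage == "simulate-ld":
                haplotypes, hap_map = simulate_ld_haplotypes(
                    ne=int(p.get("ne", 200)),
                    n_loci=int(p.get("n_loci", 2000)),
                    map_length_cM=float(p.get("map_length_cM", 50.0)),
                    n_generations=int(p.get("n_generations", 4 * int(p.get("ne", 200)))),
                    mutation_rate=float(p.get("mutation_rate", 1e-4)),
                    sample_size=int(p.get("sample_size", 100)),
                    seed=int(p.get("seed", config.seed)),
                )
                hap_path = out / "haplotypes.tsv"
                np.savetxt(hap_path, haplotypes, fmt="%d", delimiter="\t")
                outputs.append(hap_path)

            elif stage == "qc":
                dataset = _require_dataset(dataset, stage)
                dataset, prune_rep = ld_prune(
                    dataset,
                    r2_threshold=float(p.get("r2_threshold", 0.4)),
                    window=int(p.get("window", 50)),
                    step=int(p.get("step", 5)),
                )
                dataset, ibd_rep = remove_related(
                    dataset, pihat_threshold=float(p.get("pihat_threshold", 0.6))
                )
                rep_path = out / "qc_report.tsv"
                pd.concat([prune_rep.to_frame(), ibd_rep.to_frame()]).to_csv(
                    rep_path, sep="\t", index=False
                )
                outputs.append(rep_path)

            elif stage == "pbs-scan":
                dataset = _require_dataset(dataset, stage)
                scores = pbs_scan(
                    dataset,
                    focal=p["focal"],
                    sister=p["sister"],
                    outgroup=p["outgroup"],
                    ne=float(p.get("ne", 2471)),
                    percentile=float(p.get("percentile", 99.0)),
                )
                tsv, bed = out / "pbs_scan.tsv", out / "pbs_outliers.bed"
                scores.to_tsv(tsv)
                scores.outliers_to_bed(bed)
                outputs += [tsv, bed]

            elif stage == "f3":
                dataset = _require_dataset(dataset, stage)
                mode = p.get("mode", "outgroup")
                fn = f3_outgroup if mode == "outgroup" else f3_admixture
                res = fn(
                    dataset,
                    p["o"] if mode == "outgroup" else p["target"],
                    p["a"],
                    p["b"],
                    block_size_bp=int(p.get("block_bp", 5_000_000)),
                )
                path = out / "f3.tsv"
                with open(path, "w") as fh:
                    fh.write("mode\ttriple\tf3\tse\tz\tn_snps\tn_blocks\n")
                    fh.write(
                        f"{mode}\t{';'.join(res.triple)}\t{res.f3:.6g}\t"
                        f"{res.se if res.se is not None else 'NA'}\t"
                        f"{res.z if res.z is not None else 'NA'}\t{res.n_snps}\t{res.n_blocks}\n"
                    )
                outputs.append(path)

            elif stage == "ld-ne":
                if haplotypes is not None:
                    geno = haplotypes_to_genotypes(haplotypes)
                    bins = bin_r2(
                        geno,
                        pos_cM=hap_map["pos_cM"].to_numpy(),
                        chrom=hap_map["chrom"].to_numpy(),
                        maf=float(p.get("maf", 0.05)),
                        min_pairs=int(p.get("min_pairs", 50)),
                    )
                else:
                    dataset = _require_dataset(dataset, stage)
                    bins = bin_r2(
                        dataset,
                        population=p.get("population"),
                        maf=float(p.get("maf", 0.05)),
                        min_pairs=int(p.get("min_pairs", 50)),
                    )
                traj = ne_trajectory(bins)
                path = out / "ne_trajectory.tsv"
                traj.to_tsv(path)
                outputs.append(path)

            elif stage == "divergence-tree":
                dataset = _require_dataset(dataset, stage)
                ne_param = p.get("ne", 2471)
                dm = divergence_matrix(
                    dataset.freq_table(),
                    ne=dict(ne_param) if isinstance(ne_param, dict) else float(ne_param),
                    generation_years=float(p.get("generation_years", 25.0)),
                )
                mat_path, nwk_path = out / "divergence_years.tsv", out / "divergence.nwk"
                dm.to_frame().to_csv(mat_path, sep="\t")
                nwk_path.write_text(dm.newick + "\n")
                outputs += [mat_path, nwk_path]

            elif stage == "wf-sim":
                scenario = p.pop("scenario", "custom")
                seed = int(p.pop("seed", config.seed))
                if scenario == "lct":
                    ens = scenario_lct(seed=seed, **_sim_overrides(p))
                    results = {"lct": ens}
                elif scenario == "actn3":
                    results = scenario_actn3(seed=seed, **_sim_overrides(p))
                else:
                    cfg = SimConfig(seed=seed, **_sim_overrides(p))
                    results = {"custom": run_ensemble(cfg)}
                for name, ens in results.items():
                    traj_path = out / f"wf_{name}_trajectories.tsv"
                    sum_path = out / f"wf_{name}_summary.json"
                    ens.to_tsv(traj_path)
                    sum_path.write_text(json.dumps(ens.summary, indent=2))
                    outputs += [traj_path, sum_path]
        except Exception as exc:  # noqa: BLE001 - tag and halt
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

        manifest["stages"][stage] = {
            "params": config.stage_params(stage),
            "outputs": {str(f): _sha256(f) for f in outputs if f.exists()},
        }
        logger.info("stage %s: done (%d outputs)", stage, len(outputs))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _require_dataset(dataset: GenotypeDataset | None, stage: str) -> GenotypeDataset:
    if dataset is None:
        raise StageError(
            f"stage {stage!r} needs genotypes: provide run.input or enable simulate-genotypes"
        )
    return dataset


_SIM_KEYS = {"ne", "s", "p0", "n_generations", "record_interval", "n_replicates", "threshold"}


def _sim_overrides(p: dict) -> dict:
    unknown = set(p) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown wf-sim parameters: {sorted(unknown)}")
    return {k: (int(v) if k in {"ne", "n_generations", "record_interval", "n_replicates"} else v)
            for k, v in p.items()}
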