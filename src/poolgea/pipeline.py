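"""End-to-end orchestration: simulate -> filter -> omega -> scan ->
enrich -> regions -> evaluate, with deterministic seeding and a manifest.

One root seed deterministically spawns per-stage seeds (recorded in the
manifest), so re-running a configuration reproduces every artifact
checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .datamodel import ValidationError
from .enrichment import (
    adjust_enrichment_fdr,
    attach_permutation_p,
    fold_enrichment_annotation,
    fold_enrichment_xtx,
    upper_tail,
)
from .filtering import FilterParams, apply_filter_cascade
from .model.aux import run_aux_scan
from .model.core import estimate_core_model, omega_svd
from .model.sampler import MCMCSettings
from .regions import annotate_regions, regions_from_scan
from .simulate import (
    SimConfig,
    simulate_annotation_table,
    simulate_dataset,
    simulate_pc_correlated_covariate,
)

STAGES = ("simulate", "filter", "omega", "scan", "enrich", "regions")


@dataclass
class PipelineConfig:
    """Everything one run needs, serializable to/from YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter_params: FilterParams = field(default_factory=FilterParams)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings.quick)
    covariate_rho: float = 0.0
    tail_fraction: float = 0.005
    n_permutations: int = 10_000
    region_top_k: int = 50
    region_min_snps: int = 3
    region_max_gap_bp: int = 10_000
    use_true_omega: bool = False
    gene_models_path: str | None = None
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed spawned from the root seed."""
        idx = STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % 2**31
        )

    def to_yaml(self, path) -> None:
        doc = {
            "sim": _plain(asdict(self.sim)),
            "filter_params": _plain(asdict(self.filter_params)),
            "mcmc": _plain(asdict(self.mcmc)),
            "covariate_rho": self.covariate_rho,
            "tail_fraction": self.tail_fraction,
            "n_permutations": self.n_permutations,
            "region_top_k": self.region_top_k,
            "region_min_snps": self.region_min_snps,
            "region_max_gap_bp": self.region_max_gap_bp,
            "use_true_omega": self.use_true_omega,
            "gene_models_path": self.gene_models_path,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sim = doc.pop("sim", {})
        if isinstance(sim.get("omega_spec"), list):
            sim["omega_spec"] = tuple(sim["omega_spec"])
        return cls(
            sim=SimConfig(**sim),
            filter_params=FilterParams(**doc.pop("filter_params", {})),
            mcmc=MCMCSettings(**doc.pop("mcmc", {})),
            **doc,
        )


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage, writing artifacts and a manifest into ``out_dir``.

    Stage failures raise with the stage name prefixed; reruns of the same
    config reproduce the manifest checksums bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}

    def record(stage: str, seed: int, **info) -> None:
        manifest["stages"][stage] = {"seed": seed, **info}

    try:
        stage = "simulate"
        seed = config.stage_seed(stage)
        omega_true = config.sim.omega()
        covariate, rho_hat = simulate_pc_correlated_covariate(
            omega_true, config.covariate_rho, seed=seed
        )
        matrix, pops, truth = simulate_dataset(
            config.sim, covariate=covariate, seed=seed
        )
        pio.write_pool_counts(matrix, out / "counts.tsv")
        pio.write_pool_sizes(pops, out / "poolsizes.txt")
        pio.write_covariates_baypass(covariate, out / "covariates.txt")
        (out / "truth.tsv").write_text(
            "snp_id\tbeta_true\n"
            + "".join(
                f"{s}\t{b}\n"
                for s, b in zip(truth.associated_snp_ids, truth.beta_true)
            )
        )
        record(stage, seed, achieved_rho=rho_hat, n_snps=matrix.n_snps)

        stage = "filter"
        filtered, report = apply_filter_cascade(matrix, config.filter_params)
        (out / "filter_report.tsv").write_text(report.to_tsv())
        record(stage, -1, removals=list(report.removals), n_final=report.n_final)

        stage = "omega"
        seed = config.stage_seed(stage)
        if config.use_true_omega:
            omega = omega_true
            record(stage, seed, source="generating matrix")
        else:
            _, omega = estimate_core_model(
                filtered, pops, config.mcmc, seed=seed
            )
            record(stage, seed, source="core model posterior mean")
        np.savetxt(out / "omega.tsv", omega.omega, delimiter="\t")
        _, _, frac = omega_svd(omega)
        record(stage, seed, pc1_fraction=float(frac[0]))

        stage = "scan"
        seed = config.stage_seed(stage)
        scan = run_aux_scan(
            filtered, pops, omega, covariate, config.mcmc, seed=seed
        )
        pio.write_scan_results(scan, out / "scan.tsv")
        record(stage, seed, max_bf_db=scan.max_bf_db)

        stage = "enrich"
        seed = config.stage_seed(stage)
        annot = simulate_annotation_table(scan.snp_ids, seed=seed)
        tail_idx = upper_tail(scan.bf_db, config.tail_fraction)
        tail = np.zeros(scan.n_snps, dtype=bool)
        tail[tail_idx] = True
        results = []
        for cat in sorted(set(annot.category.tolist())):
            r = fold_enrichment_annotation(
                tail_idx, annot.category, cat, covariate=scan.covariate_name
            )
            if not r.undefined:
                attach_permutation_p(
                    r, tail, annot.category == cat,
                    n_perm=config.n_permutations, seed=seed,
                )
            results.append(r)
        xtx_idx = upper_tail(scan.xtx, config.tail_fraction)
        r = fold_enrichment_xtx(
            tail_idx, xtx_idx, scan.n_snps, covariate=scan.covariate_name
        )
        if not r.undefined:
            xtx_tail = np.zeros(scan.n_snps, dtype=bool)
            xtx_tail[xtx_idx] = True
            attach_permutation_p(
                r, tail, xtx_tail, n_perm=config.n_permutations, seed=seed
            )
        results.append(r)
        adjust_enrichment_fdr(results)
        _write_enrichment(results, out / "enrichment.tsv")
        record(stage, seed, n_tests=len(results))

        stage = "regions"
        regs = regions_from_scan(
            scan,
            k=min(config.region_top_k, scan.n_snps),
            min_snps=config.region_min_snps,
            max_gap_bp=config.region_max_gap_bp,
        )
        if config.gene_models_path:
            annotate_regions(regs, pio.read_gff3(config.gene_models_path))
        _write_regions(regs, out / "regions.tsv")
        record(stage, -1, n_regions=len(regs))
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.txt")):
        manifest["checksums"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_enrichment(results, path: Path) -> None:
    lines = [
        "covariate\tcategory\ttail_size\ttail_hits\ttotal\ttotal_hits\t"
        "fold_enrichment\tdirection\tp_perm\tp_bh"
    ]
    for r in results:
        lines.append(
            f"{r.covariate}\t{r.category}\t{r.tail_size}\t{r.tail_hits}\t"
            f"{r.total}\t{r.total_hits}\t{r.fold_enrichment:.6g}\t"
            f"{r.direction}\t{r.p_perm if r.p_perm is not None else 'NA'}\t"
            f"{r.fdr_adjusted_p if r.fdr_adjusted_p is not None else 'NA'}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_regions(regions, path: Path) -> None:
    lines = ["chrom\tstart\tend\tn_snps\tlength_bp\tcovariates\tgenes"]
    for r in regions:
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_snps}\t{r.length_bp}\t"
            f"{','.join(r.covariates)}\t{','.join(r.gene_ids) or '.'}"
        )
    path.write_text("\n".join(lines) + "\n")
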