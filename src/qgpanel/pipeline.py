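"""End-to-end pipeline: QC -> structure/LD -> H2/BLUEs -> GWAS -> p_G -> prediction.

`run_pipeline` executes the full analysis from a :class:`PipelineConfig`,
writing one TSV per stage into a run directory together with a manifest
(package/library versions, seed, thresholds) and a log. Every output file
carries the global seed and a hash of the configuration in '#' header
lines, and all randomness flows from the single seed through named
substreams, so any stage can be re-run in isolation (via the CLI
subcommands, which read the stage intermediates) and reproduce the full
run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream_seed
from .geno import ld_decay_profile, pca, qc_filter
from .gwas import (
    GwasModelSpec,
    compute_grm,
    fdr_adjust,
    genotypic_variance_explained,
    run_gwas,
)
from .io import (
    read_alignment,
    read_genotypes,
    read_phenotypes_tsv,
    write_map_tsv,
    write_tsv,
)
from .pheno import compute_blues, fit_variance_components, heritability
from .predict import BayesBConfig, cross_validate

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]

log = logging.getLogger("qgpanel")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the CLI for per-stage entry points."""

    genotypes: str
    phenotypes: str
    genotype_format: str = "tsv"
    map_path: str | None = None
    alignments: list[str] = field(default_factory=list)
    traits: list[str] | None = None  # default: every trait in the phenotype table
    # QC
    maf_min: float = 0.05
    max_missing: float = 0.05
    max_het: float = 0.05
    # structure / LD
    n_pcs_report: int = 10
    ld_max_distance_cM: float = 50.0
    ld_bin_width_cM: float = 1.0
    # GWAS
    gwas_variant: str = "pc_g"
    n_pcs: int = 3
    fdr_q: float = 0.20
    # prediction
    predict_models: list[str] = field(default_factory=lambda: ["gblup", "bayesb", "rkhs"])
    n_folds: int = 5
    n_cycles: int = 100
    h_grid: list[float] = field(default_factory=lambda: [0.1, 0.5, 2.5])
    bayesb_iterations: int = 12000
    bayesb_burn_in: int = 2000
    bayesb_thinning: int = 5
    run_prediction: bool = True
    # bookkeeping
    seed: int = 0
    out_dir: str = "qgpanel_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genotypes", "phenotypes"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: path {p!r} does not exist")
        if self.map_path and not Path(self.map_path).exists():
            raise FileNotFoundError(f"config.map_path: {self.map_path!r} does not exist")
        for a in self.alignments:
            if not Path(a).exists():
                raise FileNotFoundError(f"config.alignments: {a!r} does not exist")


def config_hash(cfg) -> str:
    """Fingerprint of the analysis settings (output location excluded)."""
    if dataclasses.is_dataclass(cfg):
        cfg = dataclasses.asdict(cfg)
    cfg = {k: v for k, v in dict(cfg).items() if k != "out_dir"}
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def meta_lines(seed: int, cfg) -> list[str]:
    return [f"seed={seed}", f"config_hash={config_hash(cfg)}", f"qgpanel={__version__}"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory.

    A stage failure raises with the stage name; outputs of earlier stages
    are preserved on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = meta_lines(config.seed, config)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    state: dict = {}
    stages = [
        ("load", _stage_load),
        ("qc", _stage_qc),
        ("structure_ld", _stage_structure),
        ("pheno", _stage_pheno),
        ("gwas", _stage_gwas),
        ("p_G", _stage_pg),
    ]
    if config.run_prediction:
        stages.append(("predict", _stage_predict))
    if config.alignments:
        stages.append(("diversity", _stage_diversity))

    completed = []
    try:
        for name, fn in stages:
            log.info("stage %s: start", name)
            fn(config, state, out, hdr)
            completed.append(name)
            log.info("stage %s: done", name)
    except Exception as exc:
        log.error("stage failed: %s", exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    finally:
        manifest = {
            "qgpanel": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "config": dataclasses.asdict(config),
            "stages_completed": completed,
        }
        with open(out / "manifest.json", "w") as mfh:
            json.dump(manifest, mfh, indent=2, sort_keys=True, default=str)
        log.removeHandler(fh)
        fh.close()
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_load(cfg, state, out, hdr):
    state["geno_raw"] = read_genotypes(
        cfg.genotypes, format=cfg.genotype_format, map_path=cfg.map_path
    )
    state["pheno"] = read_phenotypes_tsv(cfg.phenotypes)
    traits = cfg.traits or sorted(state["pheno"]["trait"].unique())
    state["traits"] = traits
    log.info(
        "loaded %d lines x %d markers, %d phenotype records, traits %s",
        state["geno_raw"].n_lines,
        state["geno_raw"].n_markers,
        len(state["pheno"]),
        traits,
    )


def _stage_qc(cfg, state, out, hdr):
    geno, report = qc_filter(
        state["geno_raw"], maf_min=cfg.maf_min, max_missing=cfg.max_missing,
        max_het=cfg.max_het,
    )
    state["geno"] = geno
    write_tsv(report.to_frame(), out / "qc_report.tsv", header_lines=hdr)
    from .io import write_dosage_tsv

    write_dosage_tsv(geno, out / "genotypes_qc.tsv", header_lines=hdr)
    if geno.marker_map is not None:
        write_map_tsv(geno, out / "map_qc.tsv", header_lines=hdr)


def _stage_structure(cfg, state, out, hdr):
    res = pca(state["geno"], k=cfg.n_pcs_report)
    scores = res.scores.reset_index(names="line")
    write_tsv(scores, out / "pca_scores.tsv", header_lines=hdr)
    write_tsv(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(res.explained_variance_ratio))],
                "proportion_variance": res.explained_variance_ratio,
            }
        ),
        out / "pca_variance.tsv",
        header_lines=hdr,
    )
    state["pca"] = res
    if state["geno"].marker_map is not None and state["geno"].mapped_marker_ids():
        ld = ld_decay_profile(
            state["geno"], max_distance_cM=cfg.ld_max_distance_cM,
            bin_width_cM=cfg.ld_bin_width_cM,
        )
        write_tsv(ld.bin_summary, out / "ld_decay.tsv", header_lines=hdr)


def _stage_pheno(cfg, state, out, hdr):
    rows = []
    blues = {}
    for trait in state["traits"]:
        vc = fit_variance_components(state["pheno"], trait)
        h2 = heritability(vc)
        rows.append(
            {
                "trait": trait,
                "sigma2_G": vc.sigma2_G,
                "sigma2_E": vc.sigma2_E,
                "sigma2_e": vc.sigma2_e,
                "n_environments": vc.n_environments,
                "H2": h2,
                "converged": vc.converged,
            }
        )
        blues[trait] = compute_blues(state["pheno"], trait)
    write_tsv(pd.DataFrame(rows), out / "heritability.tsv", header_lines=hdr)
    blues_df = pd.DataFrame(blues)
    state["h2"] = {r["trait"]: r["H2"] for r in rows}
    state["blues"] = blues_df
    write_tsv(blues_df.reset_index(names="genotype"), out / "blues.tsv", header_lines=hdr)


def _stage_gwas(cfg, state, out, hdr):
    spec = GwasModelSpec(variant=cfg.gwas_variant, n_pcs=cfg.n_pcs)
    grm = compute_grm(state["geno"]) if spec.uses_kinship else None
    state["assoc"] = {}
    for trait in state["traits"]:
        assoc = run_gwas(state["blues"][trait].dropna(), state["geno"], spec, grm=grm)
        tested = assoc["p"].notna()
        flags = np.zeros(len(assoc), dtype=bool)
        flags[tested.to_numpy()] = fdr_adjust(assoc.loc[tested, "p"], q=cfg.fdr_q)
        assoc["fdr_flag"] = flags
        state["assoc"][trait] = assoc
        write_tsv(assoc, out / f"gwas_{trait}.tsv", header_lines=hdr)
    state["grm"] = grm


def _stage_pg(cfg, state, out, hdr):
    rows = []
    for trait in state["traits"]:
        assoc = state["assoc"][trait]
        mta = list(assoc.loc[assoc["fdr_flag"], "marker"])
        if not mta:
            rows.append({"trait": trait, "n_mta": 0, "total_p_G": 0.0})
            continue
        res = genotypic_variance_explained(
            state["blues"][trait].dropna(), state["geno"], mta,
            H2=state["h2"][trait], assoc=assoc,
        )
        table = res.table.assign(trait=trait)
        write_tsv(table, out / f"mta_{trait}.tsv", header_lines=hdr)
        rows.append({"trait": trait, "n_mta": len(mta), "total_p_G": res.total_p_G})
    write_tsv(pd.DataFrame(rows), out / "p_G_summary.tsv", header_lines=hdr)


def _stage_predict(cfg, state, out, hdr):
    bb = BayesBConfig(
        n_iterations=cfg.bayesb_iterations,
        burn_in=cfg.bayesb_burn_in,
        thinning=cfg.bayesb_thinning,
    )
    for trait in state["traits"]:
        res = cross_validate(
            state["blues"][trait].dropna(),
            state["geno"],
            models=tuple(cfg.predict_models),
            n_folds=cfg.n_folds,
            n_cycles=cfg.n_cycles,
            H2=state["h2"][trait],
            seed=substream_seed(cfg.seed, f"predict_{trait}"),
            bayesb_config=bb,
            h_grid=tuple(cfg.h_grid),
            grm=state.get("grm"),
        )
        write_tsv(res.records, out / f"cv_records_{trait}.tsv", header_lines=hdr)
        write_tsv(res.summary, out / f"cv_summary_{trait}.tsv", header_lines=hdr)


def _stage_diversity(cfg, state, out, hdr):
    from .diversity import gene_report

    frames = []
    for path in cfg.alignments:
        gene = Path(path).stem
        aln = read_alignment(path)
        frames.append(gene_report(gene, aln).to_frame())
    write_tsv(pd.concat(frames, ignore_index=True), out / "diversity.tsv", header_lines=hdr)
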