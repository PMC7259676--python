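"""End-to-end analysis pipeline: filter -> prune relatives -> diversity
statistics -> F_ST matrices -> isolation by distance -> Rousset dispersal ->
sex-bias test -> MDS -> haplotype network, from one configuration, with a
machine-readable run manifest. Re-running with the same inputs, config and
seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ibd_dispersal import (
    geo_distance_matrix,
    ibd_regression,
    pair_table,
    rousset_sigma,
    sex_bias_test,
)
from .io_metadata import (
    GenotypeMatrix,
    HaplotypeSet,
    SampleTable,
    filter_sites,
    read_haplotypes,
    read_metadata,
    read_vcf,
    thin_sites,
)
from .popgen_stats import (
    mean_offdiagonal,
    mito_pi_and_fst,
    pairwise_wc_fst,
    population_summaries,
)
from .relatedness import king_kinship, prune_related
from .structure_viz import build_haplotype_network, classical_mds, ibs_distance

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_in_memory"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults reproduce the study's
    printed parameters (call-rate 0.8, mac 3, kinship 0.1, 10-kb windows
    and thinning, densities 1080 and 2500 nests/km^2)."""

    vcf: str | Path | None = None
    mito_fasta: str | Path | None = None
    metadata: str | Path | None = None
    grouping: str = "region_label"
    max_missing: float = 0.8
    mac: int = 3
    kinship_threshold: float = 0.1
    window_bp: int = 10_000
    thin_bp: int = 10_000
    densities: list[float] = field(default_factory=lambda: [1080.0, 2500.0])
    mds_axes: int = 10
    permutations: int = 999
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")
        for name in ("vcf", "mito_fasta", "metadata"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    fst_nuclear: "pd.DataFrame"
    fst_mito: pd.DataFrame | None
    geo_km: pd.DataFrame
    pair_table: pd.DataFrame
    ibd: dict
    dispersal: list[dict]
    sex_bias: dict | None
    mds: pd.DataFrame
    mds_eigenvalues: np.ndarray
    network_nodes: pd.DataFrame | None
    network_edges: pd.DataFrame | None
    removed_samples: list[dict]
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_in_memory(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    mito: HaplotypeSet | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs (see :func:`run` for the
    file-based entry point)."""
    cfg = config
    cfg.validate()
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in cfg.__dict__.items()
            if k != "out_dir"  # report location must not affect report bytes
        },
        "n_samples_input": genotypes.n_samples,
        "n_sites_input": genotypes.n_sites,
    }

    with _stage("filter"):
        g = filter_sites(genotypes, cfg.max_missing, cfg.mac)
        manifest["n_sites_after_filter"] = g.n_sites

    with _stage("kinship_prune"):
        kin = king_kinship(g)
        g, removed = prune_related(kin, g, cfg.kinship_threshold)
        manifest["n_removed_related"] = len(removed)
        kept = set(g.sample_ids)
        samples_kept = samples.subset([s for s in samples.sample_ids if s in kept])
        pops = {k: v for k, v in samples_kept.groups(cfg.grouping).items() if len(v) >= 2}
        g = g.take_samples([s for ids in pops.values() for s in ids])

    with _stage("diversity"):
        mito_kept = None
        if mito is not None:
            present = set(mito.sample_ids)
            mito_kept = mito.subset([s for ids in pops.values() for s in ids if s in present])
        summary = population_summaries(g, mito_kept, pops, cfg.window_bp)

    with _stage("fst"):
        fst_nuc = pairwise_wc_fst(g, pops)
        fst_mito = None
        if mito_kept is not None:
            mito_pops = {
                k: [s for s in v if s in set(mito_kept.sample_ids)] for k, v in pops.items()
            }
            if all(len(v) >= 2 for v in mito_pops.values()):
                _, fst_mito = mito_pi_and_fst(mito_kept, mito_pops)
        manifest["mean_fst_nuclear"] = mean_offdiagonal(fst_nuc)
        if fst_mito is not None:
            manifest["mean_fst_mito"] = mean_offdiagonal(fst_mito)

    with _stage("ibd"):
        geo = geo_distance_matrix(samples_kept, cfg.grouping)
        ibd = ibd_regression(fst_nuc, geo, permutations=cfg.permutations, seed=cfg.seed)

    with _stage("dispersal"):
        dispersal = []
        for De in cfg.densities:
            try:
                est = rousset_sigma(ibd.slope_b, De).to_dict()
            except ValueError as err:
                est = {"De_per_km2": De, "error": str(err)}
            dispersal.append(est)

    sex = None
    if fst_mito is not None and len(pops) >= 3:
        with _stage("sex_bias"):
            sex = sex_bias_test(fst_nuc, fst_mito)

    with _stage("mds"):
        thinned = thin_sites(g, cfg.thin_bp)
        manifest["n_sites_after_thinning"] = thinned.n_sites
        mds = classical_mds(ibs_distance(thinned), k=cfg.mds_axes)

    nodes = edges = None
    if mito_kept is not None:
        with _stage("haplotype_network"):
            net = build_haplotype_network(
                mito_kept,
                {k: [s for s in v if s in set(mito_kept.sample_ids)] for k, v in pops.items()},
            )
            nodes, edges = net.node_frame(), net.edge_frame()

    return PipelineResult(
        summary=summary,
        fst_nuclear=fst_nuc.to_frame(),
        fst_mito=fst_mito.to_frame() if fst_mito is not None else None,
        geo_km=geo.to_frame(),
        pair_table=pair_table(fst_nuc, fst_mito, geo),
        ibd=ibd.to_dict(),
        dispersal=dispersal,
        sex_bias=sex.to_dict() if sex is not None else None,
        mds=mds.to_frame(),
        mds_eigenvalues=mds.eigenvalues,
        network_nodes=nodes,
        network_edges=edges,
        removed_samples=removed,
        manifest=manifest,
    )


def run(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline entry point: reads VCF/FASTA/TSV, runs every
    stage, writes the report bundle to ``config.out_dir`` when set."""
    config.validate()
    if config.vcf is None or config.metadata is None:
        raise ValueError("pipeline requires at least a VCF and a metadata TSV")
    genotypes = read_vcf(config.vcf)
    samples = read_metadata(config.metadata)
    mito = read_haplotypes(config.mito_fasta) if config.mito_fasta else None
    result = run_in_memory(genotypes, samples, mito, config)
    for name in ("vcf", "mito_fasta", "metadata"):
        p = getattr(config, name)
        if p is not None:
            result.manifest[f"sha256_{name}"] = _sha256(p)
    if config.out_dir is not None:
        write_report(result, config.out_dir)
    return result


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "population_summary.tsv", sep="\t", index=False)
    result.fst_nuclear.to_csv(out / "fst_nuclear.tsv", sep="\t")
    if result.fst_mito is not None:
        result.fst_mito.to_csv(out / "fst_mito.tsv", sep="\t")
    result.geo_km.to_csv(out / "geo_km.tsv", sep="\t")
    result.pair_table.to_csv(out / "pair_table.tsv", sep="\t", index=False)
    result.mds.to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"axis": [f"C{i + 1}" for i in range(len(result.mds_eigenvalues))],
         "eigenvalue": result.mds_eigenvalues}
    ).to_csv(out / "mds_eigenvalues.tsv", sep="\t", index=False)
    if result.network_nodes is not None:
        result.network_nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        result.network_edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    blob = {
        "ibd": result.ibd,
        "dispersal": result.dispersal,
        "sex_bias": result.sex_bias,
        "removed_samples": result.removed_samples,
    }
    with open(out / "ibd_dispersal.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
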