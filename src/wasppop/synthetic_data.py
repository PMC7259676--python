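"""Forward-time lattice stepping-stone simulator with sex-specific dispersal.

Emulates the study system: demes of breeding females (nests) on a 1-D or
2-D torus lattice, diploid biallelic nuclear SNPs with two-allele mutation,
a maternally inherited mitochondrial sequence with finite-sites mutation,
and optionally haplodiploid males (haploid, from unfertilized eggs). Each
offspring's mother comes from a deme displaced by a discretized Gaussian
kernel with axial SD ``sigma_f_km``; the father's deme by ``sigma_m_km``.

The simulator's truth record (sigma_f, sigma_m, De) is the oracle for the
whole pipeline: Rousset's relation b = 1/(4*pi*De*sigma^2) predicts the
isolation-by-distance slope, so parameter recovery is checkable without
any external data. Two explicit sexes are modelled so that the diploid
equal-dispersal null actually satisfies F_ST(mito) = 4F/(1+3F)
(mitochondrial Ne = Nf vs 2(Nf+Nm) autosomal gene copies).

Nuclear sites are unlinked (free recombination): gametes draw a parental
allele independently per site, matching the thinned-SNP regime downstream
analyses assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_metadata import (
    GenotypeMatrix,
    HaplotypeSet,
    SampleTable,
    write_haplotypes,
    write_metadata,
    write_vcf,
)

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate", "write_cohort", "expected_slope"]

_MITO_GENES = ("COI", "COII", "ATP6", "ATP8", "ND4", "ND5", "12S", "16S", "CytB")

# flat local projection anchored near the study area; 1 deg lat = 111.32 km
_LAT0, _LON0 = 42.0, -77.0
_KM_PER_DEG_LAT = 111.32


@dataclass
class SimulationConfig:
    """Stepping-stone simulation parameters.

    ``deme_breeders`` is the number of breeding females (nests) per deme;
    with ``deme_spacing_km`` it sets the effective breeder density
    De = deme_breeders / deme_spacing_km**2 (females per km^2, the
    nest-density analogue). An equal-sized male pool is simulated
    alongside (``deme_males``, default equal). ``sigma_f_km`` and
    ``sigma_m_km`` are axial parent-offspring dispersal SDs for the
    mother and father contribution respectively. ``sample_plan`` lists
    (deme linear index, n females, population label); the default samples
    8 females from each deme along the first half of a 1-D ring, so
    geographic distance never wraps around the torus.
    """

    lattice: tuple[int, int] = (1, 20)           # (rows, cols) demes on a torus
    deme_breeders: int = 30                      # breeding females per deme
    deme_males: int | None = None                # default: equal to deme_breeders
    deme_spacing_km: float = 1.0
    sigma_f_km: float = 0.5
    sigma_m_km: float = 0.5
    n_nuclear_sites: int = 400
    mu_nuclear: float = 1e-3                     # per site per gamete, two-allele model
    mito_length_bp: int = 1200
    mu_mito: float = 2e-4                        # per site per transmission
    burn_in: int | None = None                   # default 10 * deme_breeders
    generations: int | None = None               # default burn_in + 50
    haplodiploid: bool = True
    sample_plan: list[tuple[int, int, str]] | None = None
    seed: int = 0
    track_frequencies: bool = False   # record per-generation overall alt frequencies

    def resolved(self) -> "SimulationConfig":
        cfg = SimulationConfig(**{**self.__dict__})
        if cfg.deme_males is None:
            cfg.deme_males = cfg.deme_breeders
        if cfg.burn_in is None:
            cfg.burn_in = 10 * cfg.deme_breeders
        if cfg.generations is None:
            cfg.generations = cfg.burn_in + 50
        if cfg.sample_plan is None:
            rows, cols = cfg.lattice
            n_demes = min(10, max(2, (rows * cols) // 2))
            n_per = min(8, cfg.deme_breeders)
            cfg.sample_plan = [(d, n_per, f"D{d:02d}") for d in range(n_demes)]
        cfg.validate()
        return cfg

    def validate(self) -> None:
        rows, cols = self.lattice
        if rows < 1 or cols < 1:
            raise ValueError("lattice must have at least one deme")
        for name in ("mu_nuclear", "mu_mito"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.generations <= self.burn_in:
            raise ValueError("generations must exceed burn_in")
        if self.deme_spacing_km <= 0:
            raise ValueError("deme_spacing_km must be positive")
        for sigma, axis_len in (
            (self.sigma_f_km, None),
            (self.sigma_m_km, None),
        ):
            s = sigma / self.deme_spacing_km
            for extent in (rows, cols):
                if extent > 1 and 4.0 * s >= extent / 2.0:
                    raise ValueError(
                        f"dispersal kernel (4*sigma = {4 * s:.1f} demes) reaches "
                        f"halfway around the {extent}-deme axis: boundary artifacts"
                    )
        for deme, n, _label in self.sample_plan:
            if not 0 <= deme < rows * cols:
                raise ValueError(f"sample plan deme {deme} outside lattice")
            if n > self.deme_breeders:
                raise ValueError("cannot sample more females than a deme holds")

    def De(self) -> float:
        """Effective breeder (female) density per km^2."""
        return self.deme_breeders / self.deme_spacing_km**2

    def to_json(self) -> dict:
        d = dict(self.__dict__)
        d["lattice"] = list(self.lattice)
        if d["sample_plan"] is not None:
            d["sample_plan"] = [list(t) for t in d["sample_plan"]]
        return d


@dataclass
class SimulatedCohort:
    """A sampled cohort plus the ground truth needed to verify inference."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    mito: HaplotypeSet
    truth: dict
    pedigree: pd.DataFrame          # sample_id, mother_id (into parent_genotypes)
    parent_genotypes: GenotypeMatrix
    config: SimulationConfig = field(repr=False, default=None)


def _kernel(sigma_km: float, spacing_km: float, extent: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretized Gaussian over integer deme offsets, truncated at 4 SD
    and renormalized; a point mass at 0 when sigma is 0 or the axis is
    a single deme."""
    s = sigma_km / spacing_km
    if s == 0.0 or extent == 1:
        return np.array([0]), np.array([1.0])
    kmax = max(1, int(np.ceil(4.0 * s)))
    offsets = np.arange(-kmax, kmax + 1)
    w = np.exp(-(offsets.astype(float) ** 2) / (2.0 * s**2))
    return offsets, w / w.sum()


def _draw_parent_demes(
    rng: np.random.Generator,
    deme_r: np.ndarray,
    deme_c: np.ndarray,
    sigma_km: float,
    cfg: SimulationConfig,
) -> np.ndarray:
    rows, cols = cfg.lattice
    n = len(deme_r)
    offs_r, p_r = _kernel(sigma_km, cfg.deme_spacing_km, rows)
    offs_c, p_c = _kernel(sigma_km, cfg.deme_spacing_km, cols)
    dr = rng.choice(offs_r, size=n, p=p_r)
    dc = rng.choice(offs_c, size=n, p=p_c)
    return ((deme_r + dr) % rows) * cols + (deme_c + dc) % cols


def _gamete(rng: np.random.Generator, diploid: np.ndarray, mu: float) -> np.ndarray:
    """One recombinant gamete per row of (n, 2, L) diploid genotypes, with
    two-allele mutation at rate mu per site."""
    n, _, L = diploid.shape
    pick = rng.integers(0, 2, size=(n, L), dtype=np.uint8)
    gam = np.where(pick == 0, diploid[:, 0, :], diploid[:, 1, :])
    flips = rng.random((n, L)) < mu
    return np.bitwise_xor(gam, flips.astype(np.uint8))


def _mutate_mito(rng: np.random.Generator, seqs: np.ndarray, mu: float) -> np.ndarray:
    out = seqs.copy()
    mask = rng.random(out.shape) < mu
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return out


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Run the forward simulation and sample a cohort of females.

    Wright-Fisher within demes: every offspring independently draws its
    mother's deme through the female kernel and its father's deme through
    the male kernel (torus boundaries), then a uniform parent within that
    deme. Females are diploid; males are haploid maternal gametes when
    ``haplodiploid`` else diploid. Deterministic given ``config.seed``.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.lattice
    D = rows * cols
    Nf, Nm = cfg.deme_breeders, cfg.deme_males
    L, Lm = cfg.n_nuclear_sites, cfg.mito_length_bp

    # initial state: interior allele frequencies, one founding mito sequence
    p0 = rng.uniform(0.2, 0.8, size=L)
    F = (rng.random((D * Nf, 2, L)) < p0).astype(np.uint8)
    male_ploidy = 1 if cfg.haplodiploid else 2
    M = (rng.random((D * Nm, male_ploidy, L)) < p0).astype(np.uint8)
    mito_ref = rng.integers(0, 4, size=Lm, dtype=np.uint8)
    Mt = np.tile(mito_ref, (D * Nf, 1))

    deme_of_f = np.repeat(np.arange(D), Nf)
    deme_of_m = np.repeat(np.arange(D), Nm)
    fr, fc = deme_of_f // cols, deme_of_f % cols
    mr, mc = deme_of_m // cols, deme_of_m % cols

    def _overall_freq() -> np.ndarray:
        copies = F.sum(axis=(0, 1), dtype=np.int64) + M.sum(axis=(0, 1), dtype=np.int64)
        total = F.shape[0] * 2 + M.shape[0] * M.shape[1]
        return copies / total

    freq_traj = [_overall_freq()] if cfg.track_frequencies else None
    mothers_of_f = np.zeros(D * Nf, dtype=np.int64)
    F_prev = F
    for _gen in range(cfg.generations):
        # female offspring
        md = _draw_parent_demes(rng, fr, fc, cfg.sigma_f_km, cfg)
        mi = md * Nf + rng.integers(0, Nf, size=D * Nf)
        fd = _draw_parent_demes(rng, fr, fc, cfg.sigma_m_km, cfg)
        fi = fd * Nm + rng.integers(0, Nm, size=D * Nf)
        gam_mat = _gamete(rng, F[mi], cfg.mu_nuclear)
        if cfg.haplodiploid:
            pat = np.bitwise_xor(
                M[fi, 0, :], (rng.random((D * Nf, L)) < cfg.mu_nuclear).astype(np.uint8)
            )
        else:
            pat = _gamete(rng, M[fi], cfg.mu_nuclear)
        F_new = np.stack([gam_mat, pat], axis=1)
        Mt_new = _mutate_mito(rng, Mt[mi], cfg.mu_mito)

        # male offspring
        md_m = _draw_parent_demes(rng, mr, mc, cfg.sigma_f_km, cfg)
        mi_m = md_m * Nf + rng.integers(0, Nf, size=D * Nm)
        if cfg.haplodiploid:
            M_new = _gamete(rng, F[mi_m], cfg.mu_nuclear)[:, None, :]
        else:
            fd_m = _draw_parent_demes(rng, mr, mc, cfg.sigma_m_km, cfg)
            fi_m = fd_m * Nm + rng.integers(0, Nm, size=D * Nm)
            M_new = np.stack(
                [_gamete(rng, F[mi_m], cfg.mu_nuclear), _gamete(rng, M[fi_m], cfg.mu_nuclear)],
                axis=1,
            )

        F_prev, mothers_of_f = F, mi
        F, M, Mt = F_new, M_new, Mt_new
        if freq_traj is not None:
            freq_traj.append(_overall_freq())

    # ---- sample the final generation
    sample_idx: list[int] = []
    sample_ids: list[str] = []
    labels: list[str] = []
    demes: list[int] = []
    for deme, n, label in cfg.sample_plan:
        chosen = rng.choice(Nf, size=n, replace=False)
        for k, idx in enumerate(sorted(chosen)):
            sample_idx.append(deme * Nf + int(idx))
            sample_ids.append(f"{label}_{k:02d}")
            labels.append(label)
            demes.append(deme)
    sample_idx = np.array(sample_idx)

    positions = np.sort(rng.choice(np.arange(1, L * 1000 + 1), size=L, replace=False))
    refs = rng.choice(np.array(list("ACGT"), dtype=object), size=L)
    shift = rng.integers(1, 4, size=L)
    bases = np.array(list("ACGT"), dtype=object)
    base_idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in refs])
    alts = bases[(base_idx + shift) % 4]

    calls = F[sample_idx].sum(axis=1, dtype=np.int8)
    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(["chr1"] * L, dtype=object),
        pos=positions,
        ref=refs,
        alt=alts,
        calls=calls,
    )

    mother_ids = [f"MOTHER_{sid}" for sid in sample_ids]
    parent_calls = F_prev[mothers_of_f[sample_idx]].sum(axis=1, dtype=np.int8)
    parent_genotypes = GenotypeMatrix(
        sample_ids=mother_ids,
        chrom=genotypes.chrom.copy(),
        pos=positions.copy(),
        ref=refs.copy(),
        alt=alts.copy(),
        calls=parent_calls,
    )
    pedigree = pd.DataFrame({"sample_id": sample_ids, "mother_id": mother_ids})

    # coordinates: flat local projection of lattice positions
    deme_arr = np.array(demes)
    y_km = (deme_arr // cols) * cfg.deme_spacing_km
    x_km = (deme_arr % cols) * cfg.deme_spacing_km
    lat = _LAT0 + y_km / _KM_PER_DEG_LAT
    lon = _LON0 + x_km / (_KM_PER_DEG_LAT * np.cos(np.radians(_LAT0)))
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "site_label": labels,
                "region_label": labels,
                "latitude": lat,
                "longitude": lon,
                "year": 2015,
                "building_label": pd.NA,
            }
        )
    )

    seg = np.linspace(0, Lm, len(_MITO_GENES) + 1).astype(int)
    boundaries = [
        (g, int(seg[i]), int(seg[i + 1])) for i, g in enumerate(_MITO_GENES)
    ]
    mito_seqs = ["".join("ACGT"[c] for c in Mt[i]) for i in sample_idx]
    mito = HaplotypeSet(list(sample_ids), mito_seqs, boundaries)

    try:
        slopes = expected_slope(cfg)
    except ValueError:  # zero dispersal: no IBD prediction exists
        slopes = {"nuclear": float("nan"), "mito": float("nan")}
    truth = {
        "sigma_f_km": cfg.sigma_f_km,
        "sigma_m_km": cfg.sigma_m_km,
        "sigma_effective_km": float(
            np.sqrt((cfg.sigma_f_km**2 + cfg.sigma_m_km**2) / 2.0)
        ),
        "De_females_per_km2": cfg.De(),
        "expected_slope_nuclear_per_km": slopes["nuclear"],
        "expected_slope_mito_per_km": slopes["mito"],
        "haplodiploid": cfg.haplodiploid,
        "seed": cfg.seed,
    }
    if freq_traj is not None:
        truth["freq_trajectory"] = np.stack(freq_traj)
    return SimulatedCohort(
        genotypes=genotypes,
        samples=samples,
        mito=mito,
        truth=truth,
        pedigree=pedigree,
        parent_genotypes=parent_genotypes,
        config=cfg,
    )


def expected_slope(config: SimulationConfig) -> dict[str, float]:
    """Theoretical isolation-by-distance slopes b = 1/(4*pi*De*sigma^2).

    Nuclear: sigma^2 = (sigma_f^2 + sigma_m^2)/2 (each autosomal gene copy
    passed through a mother or a father with equal probability). Mito:
    sigma^2 = sigma_f^2 (maternal transmission only). De is the breeder
    (female) density, the study's nest-density analogue.
    """
    cfg = config
    De = cfg.De()
    sigma_eff_sq = (cfg.sigma_f_km**2 + cfg.sigma_m_km**2) / 2.0
    if sigma_eff_sq <= 0 or cfg.sigma_f_km <= 0:
        raise ValueError("expected_slope needs positive dispersal SDs")
    return {
        "nuclear": 1.0 / (4.0 * np.pi * De * sigma_eff_sq),
        "mito": 1.0 / (4.0 * np.pi * De * cfg.sigma_f_km**2),
    }


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + FASTA + metadata TSV + truth JSON; byte-deterministic
    given the cohort."""
    if cohort.genotypes.n_samples == 0:
        raise ValueError("cohort has no samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "nuclear.vcf",
        "fasta": out / "mito.fasta",
        "gene_map": out / "mito_genes.tsv",
        "metadata": out / "samples.tsv",
        "truth": out / "truth.json",
        "pedigree": out / "pedigree.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_haplotypes(cohort.mito, paths["fasta"], gene_map=paths["gene_map"])
    write_metadata(cohort.samples, paths["metadata"])
    cohort.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    truth = {k: v for k, v in cohort.truth.items() if k != "freq_trajectory"}
    truth["config"] = cohort.config.to_json()
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
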